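"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here so the whole toolkit is testable
without downloads: transcript sequences with planted microsatellites (and
rejection-sampled non-repetitive background, so truth tables are exact),
homology hit tables with known pass/fail labels, island-model genotype
panels with a Balding-Nichols F_ST target, and FPKM matrices with designated
up-/down-regulated genes.

All generators are pure functions of their seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BlastHit, GenotypeMatrix, SequenceRecord
from .ssr_mining import SsrSearchParams, find_ssrs
from .expression_profile import ExpressionMatrix

BASES = np.array(list("ACGT"))

MIN_FLANK_SEPARATION = 30  # nt of non-repetitive flank between planted tracts


@dataclass(frozen=True)
class PlantedSsrSpec:
    """One microsatellite to plant: motif repeated n_repeats times at
    ``position`` (0-based) of sequence ``seq_id``."""

    seq_id: str
    position: int
    motif: str
    n_repeats: int

    @property
    def tract(self) -> str:
        return self.motif * self.n_repeats

    @property
    def end(self) -> int:
        return self.position + len(self.tract)


@dataclass(frozen=True)
class IslandModelSpec:
    """Balding-Nichols island model: population allele frequencies are
    Dirichlet draws around ancestral frequencies with concentration
    (1-F)/F, so E[F_ST] equals ``target_fst``."""

    n_pops: int = 3
    n_individuals_per_pop: int = 50
    n_loci: int = 50
    n_alleles_per_locus: int = 4
    target_fst: float = 0.30
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")
        if self.n_alleles_per_locus < 2:
            raise ValueError("need >= 2 alleles per locus")


def _random_background(rng: np.random.Generator, length: int,
                       gc_fraction: float = 0.5) -> str:
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    return "".join(rng.choice(BASES, size=length, p=probs))


def simulate_transcriptome(
    n_seqs: int,
    length_range: tuple[int, int],
    planted: list[PlantedSsrSpec],
    seed: int,
    gc_fraction: float = 0.5,
    params: SsrSearchParams = SsrSearchParams(),
    max_tries: int = 500,
    lengths: np.ndarray | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Random transcripts with planted perfect SSR tracts.

    Background sequence is rejection-sampled so that scanning each sequence
    finds exactly the planted tracts at exactly the planted coordinates
    (no accidental SSRs, no junction extensions). Planted tracts must fit
    inside the sequence and be separated by >= 30 nt. Returns the records
    and a truth table (seq_id, start, end, motif, n_repeats).

    Pass the ``lengths`` array returned by :func:`random_planted_specs` so
    the planting plan and the sequences agree; otherwise lengths are drawn
    from ``length_range``.
    """
    rng = np.random.default_rng(seed)
    by_seq: dict[str, list[PlantedSsrSpec]] = {}
    for spec in planted:
        by_seq.setdefault(spec.seq_id, []).append(spec)

    if lengths is None:
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_seqs)
    elif len(lengths) != n_seqs:
        raise ValueError("lengths array does not match n_seqs")
    seq_ids = [f"unigene_{i+1:05d}" for i in range(n_seqs)]
    unknown = set(by_seq) - set(seq_ids)
    if unknown:
        raise ValueError(f"planted seq_ids not among generated ids: {sorted(unknown)}")

    records: list[SequenceRecord] = []
    truth_rows = []
    for sid, length in zip(seq_ids, lengths):
        specs = sorted(by_seq.get(sid, []), key=lambda s: s.position)
        for s in specs:
            if s.end > length:
                raise ValueError(f"planted tract {s} does not fit in {sid} "
                                 f"(length {length})")
        for a, b in zip(specs, specs[1:]):
            if b.position - a.end < MIN_FLANK_SEPARATION:
                raise ValueError(
                    f"planted tracts in {sid} separated by "
                    f"{b.position - a.end} nt < {MIN_FLANK_SEPARATION}")
        expected = {(s.position, s.end, s.motif * 1) for s in specs}
        for attempt in range(max_tries):
            chars = list(_random_background(rng, int(length), gc_fraction))
            for s in specs:
                chars[s.position:s.end] = list(s.tract)
            rec = SequenceRecord(sid, "".join(chars))
            found = {(l.start, l.end, l.motif) for l in find_ssrs(rec, params)}
            if found == expected:
                records.append(rec)
                break
        else:
            raise RuntimeError(
                f"could not place non-repetitive background around planted "
                f"tracts in {sid} after {max_tries} tries")
        for s in specs:
            truth_rows.append((sid, s.position, s.end, s.motif, s.n_repeats))
    truth = pd.DataFrame(
        truth_rows, columns=["seq_id", "start", "end", "motif", "n_repeats"])
    return records, truth


def random_planted_specs(n_seqs: int, length_range: tuple[int, int],
                         n_ssrs: int, seed: int,
                         motifs: tuple[str, ...] = ("AG", "CT", "GGC", "CCG",
                                                    "AAC", "AGC", "AAGT",
                                                    "AATC", "AAGTC", "AACGTC"),
                         repeat_range: tuple[int, int] = (4, 10)
                         ) -> tuple[list[PlantedSsrSpec], np.ndarray]:
    """Random planting plan: positions drawn so tracts fit with margins and
    respect the separation rule. Returns the specs and the sequence lengths
    (pass the same n_seqs/length_range/seed to simulate_transcriptome)."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_seqs)
    specs: list[PlantedSsrSpec] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    tries = 0
    while len(specs) < n_ssrs and tries < 10000:
        tries += 1
        si = int(rng.integers(0, n_seqs))
        motif = str(rng.choice(list(motifs)))
        reps = int(rng.integers(repeat_range[0], repeat_range[1] + 1))
        if reps * len(motif) < 12:
            reps = -(-12 // len(motif))
        tract_len = reps * len(motif)
        length = int(lengths[si])
        if tract_len + 2 * MIN_FLANK_SEPARATION >= length:
            continue
        pos = int(rng.integers(MIN_FLANK_SEPARATION,
                               length - tract_len - MIN_FLANK_SEPARATION))
        clash = any(pos < e + MIN_FLANK_SEPARATION
                    and p < pos + tract_len + MIN_FLANK_SEPARATION
                    for p, e in occupied.get(si, []))
        if clash:
            continue
        occupied.setdefault(si, []).append((pos, pos + tract_len))
        specs.append(PlantedSsrSpec(f"unigene_{si+1:05d}", pos, motif, reps))
    if len(specs) < n_ssrs:
        raise RuntimeError("could not place all requested SSRs")
    return specs, lengths


# ---------------------------------------------------------------------------
# Homology-hit fixtures


def simulate_blast_hits(n_hits: int, seed: int,
                        max_evalue_pass: float = 1e-10,
                        min_coverage_pass: float = 65.0,
                        min_identity_pass: float = 40.0
                        ) -> tuple[list[BlastHit], dict[str, int], pd.DataFrame]:
    """Synthetic 12-column homology hits with known pass/fail truth against
    the given thresholds. Returns (hits, query_lengths, truth) where truth
    has one row per hit with a boolean ``passes`` column."""
    rng = np.random.default_rng(seed)
    hits: list[BlastHit] = []
    qlens: dict[str, int] = {}
    rows = []
    for i in range(n_hits):
        qid = f"q{i+1:04d}"
        qlen = int(rng.integers(300, 2000))
        qlens[qid] = qlen
        should_pass = bool(rng.random() < 0.5)
        if should_pass:
            evalue = float(10.0 ** rng.uniform(-60, np.log10(max_evalue_pass)))
            cov = rng.uniform(min_coverage_pass, 100.0)
            ident = rng.uniform(min_identity_pass, 100.0)
        else:
            which = rng.integers(0, 3)
            evalue = (float(10.0 ** rng.uniform(-9, -2)) if which == 0
                      else float(10.0 ** rng.uniform(-60, -11)))
            cov = (rng.uniform(10, min_coverage_pass - 1) if which == 1
                   else rng.uniform(min_coverage_pass, 100.0))
            ident = (rng.uniform(5, min_identity_pass - 1) if which == 2
                     else rng.uniform(min_identity_pass, 100.0))
        span = max(1, int(round(cov / 100.0 * qlen)))
        q_start = int(rng.integers(1, qlen - span + 2))
        q_end = q_start + span - 1
        cov_actual = 100.0 * span / qlen
        passes = (evalue <= max_evalue_pass
                  and cov_actual >= min_coverage_pass
                  and ident >= min_identity_pass)
        align_len = max(1, span // 3)
        hit = BlastHit(
            query_id=qid, subject_id=f"TF{int(rng.integers(1, 500)):04d}",
            pct_identity=round(float(ident), 2), align_length=align_len,
            mismatches=int(rng.integers(0, align_len)), gap_opens=int(rng.integers(0, 4)),
            q_start=q_start, q_end=q_end,
            s_start=1, s_end=align_len,
            evalue=evalue, bit_score=round(float(rng.uniform(50, 900)), 1),
            query_length=qlen)
        hits.append(hit)
        rows.append((qid, hit.subject_id, passes))
    truth = pd.DataFrame(rows, columns=["query_id", "subject_id", "passes"])
    return hits, qlens, truth


# ---------------------------------------------------------------------------
# Genotype panels


def simulate_genotypes_island(spec: IslandModelSpec
                              ) -> tuple[GenotypeMatrix, dict]:
    """Balding-Nichols genotype panel.

    Per locus: ancestral frequencies ~ Dirichlet(1); each population's
    frequencies ~ Dirichlet(p_anc * (1-F)/F), giving E[F_ST] = F; diploid
    genotypes are drawn under within-population Hardy-Weinberg equilibrium.
    Allele identifiers are fragment-size-like integers (100 + 2*index).
    Returns the matrix and the true per-population frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    F = spec.target_fst
    conc = (1.0 - F) / F
    n_all = spec.n_alleles_per_locus
    loci = [f"locus_{l+1:03d}" for l in range(spec.n_loci)]
    pops = [f"Pop{p+1}" for p in range(spec.n_pops)]
    allele_ids = np.array([100 + 2 * a for a in range(n_all)])

    anc = rng.dirichlet(np.ones(n_all), size=spec.n_loci)
    pop_freqs = np.empty((spec.n_pops, spec.n_loci, n_all))
    for l in range(spec.n_loci):
        alpha = np.maximum(anc[l] * conc, 1e-6)
        pop_freqs[:, l, :] = rng.dirichlet(alpha, size=spec.n_pops)

    accessions, populations, calls = [], [], []
    for p, pop in enumerate(pops):
        for i in range(spec.n_individuals_per_pop):
            accessions.append(f"{pop}_ind{i+1:03d}")
            populations.append(pop)
            row = []
            for l in range(spec.n_loci):
                if spec.missing_rate and rng.random() < spec.missing_rate:
                    row.append(None)
                    continue
                a, b = rng.choice(n_all, size=2, p=pop_freqs[p, l])
                pair = sorted((int(allele_ids[a]), int(allele_ids[b])))
                row.append((pair[0], pair[1]))
            calls.append(row)
    gm = GenotypeMatrix(accessions, populations, loci, calls)
    truth = {"ancestral": anc, "pop_freqs": pop_freqs,
             "allele_ids": allele_ids, "loci": loci, "pops": pops}
    return gm, truth


# ---------------------------------------------------------------------------
# Expression fixtures


def simulate_fpkm(n_genes: int, time_points: list[str], n_up_all: int,
                  n_down_all: int, noise_sd: float, seed: int,
                  effect_log2fc: float = 2.0, pseudocount: float = 1.0
                  ) -> tuple[ExpressionMatrix, pd.Series]:
    """FPKM matrix with designated all-UP and all-DOWN genes.

    The first time point is the baseline. Designated genes carry a log2
    fold change of +/- ``effect_log2fc`` (plus Gaussian noise of
    ``noise_sd`` on the log2 scale) at every non-baseline time point;
    the rest get noise only. Values are constructed so the fold change
    computed with the given pseudocount is exactly effect + noise.
    Returns the matrix and per-gene truth labels (UP/DOWN/FLAT).
    """
    if n_up_all + n_down_all > n_genes:
        raise ValueError("more designated genes than genes")
    rng = np.random.default_rng(seed)
    genes = [f"TFSSR{i+1:03d}" for i in range(n_genes)]
    labels = (["UP"] * n_up_all + ["DOWN"] * n_down_all
              + ["FLAT"] * (n_genes - n_up_all - n_down_all))
    baseline = rng.uniform(8.0, 64.0, size=n_genes)
    data = {time_points[0]: baseline}
    effect = np.where(np.array(labels) == "UP", effect_log2fc,
                      np.where(np.array(labels) == "DOWN", -effect_log2fc, 0.0))
    for t in time_points[1:]:
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 0.0
        lfc = effect + noise
        data[t] = np.maximum((baseline + pseudocount) * 2.0 ** lfc - pseudocount,
                             0.0)
    em = ExpressionMatrix(pd.DataFrame(data, index=genes))
    return em, pd.Series(labels, index=genes, name="truth")
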