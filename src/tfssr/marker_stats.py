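"""Codominant-marker population-genetics statistics.

Diversity indices (PIC, observed/expected heterozygosity, Shannon I),
differentiation (Nei G_ST, Weir-Cockerham theta, two-level AMOVA with
Phi_PT), individual genetic distances, neighbor-joining, principal
coordinates analysis, a no-admixture Bayesian clustering Gibbs sampler, and
Evanno's delta-K model-selection statistic.

Missing data policy: per-locus deletion for frequency-based statistics,
pairwise deletion for distances; never imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from skbio import TreeNode

from .io_formats import GenotypeMatrix

DEFAULT_SEED = 20180214


# ---------------------------------------------------------------------------
# Containers


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele frequencies at one locus over the non-missing gene copies."""

    freqs: dict[int, float]
    n_gene_copies: int

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError("all frequencies must be > 0")

    @property
    def p(self) -> np.ndarray:
        return np.array([self.freqs[a] for a in sorted(self.freqs)])

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class AmovaResult:
    """Two-level AMOVA (among / within populations) on squared individual
    distances, with the Phi_PT differentiation statistic."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_pt: float
    n0: float
    clamped: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "MS": [self.ms_among, self.ms_within],
                "variance": [self.sigma2_among, self.sigma2_within],
                "pct": [self.pct_among, self.pct_within],
            },
            index=["among_populations", "within_populations"],
        )


@dataclass
class StructureRun:
    """One Gibbs-sampler run of the no-admixture clustering model."""

    K: int
    assignments: pd.DataFrame  # accessions x K posterior mean memberships
    ln_prob_data: float
    seed: int


@dataclass
class PcoaResult:
    """Principal coordinates: sample scores on the positive axes, all
    eigenvalues (descending), and percent variance per positive axis
    (negative eigenvalues are excluded from the denominator)."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


# ---------------------------------------------------------------------------
# Per-locus diversity statistics


def allele_frequencies(gm: GenotypeMatrix, locus: str,
                       subset: Sequence[str] | None = None) -> AlleleFrequencies:
    """Allele frequencies over 2 x (non-missing individuals) gene copies;
    missing calls are excluded entirely."""
    idx = gm.subset_indices(subset)
    j = gm.locus_index(locus)
    counts: dict[int, int] = {}
    n_copies = 0
    for i in idx:
        call = gm.calls[i][j]
        if call is None:
            continue
        for a in call:
            counts[a] = counts.get(a, 0) + 1
            n_copies += 1
    if n_copies == 0:
        raise ValueError(f"locus {locus!r}: zero non-missing calls in subset")
    return AlleleFrequencies(
        freqs={a: c / n_copies for a, c in counts.items()},
        n_gene_copies=n_copies,
    )


def expected_heterozygosity(freqs: AlleleFrequencies,
                            unbiased: bool = False) -> float:
    """He = 1 - sum(p_i^2); with ``unbiased`` the 2n/(2n-1) small-sample
    correction is applied."""
    he = 1.0 - float(np.sum(freqs.p ** 2))
    if unbiased:
        n = freqs.n_gene_copies
        he *= n / (n - 1) if n > 1 else 0.0
    return he


def observed_heterozygosity(gm: GenotypeMatrix, locus: str,
                            subset: Sequence[str] | None = None) -> float:
    """Fraction of non-missing individuals whose two alleles differ."""
    idx = gm.subset_indices(subset)
    j = gm.locus_index(locus)
    calls = [gm.calls[i][j] for i in idx]
    scored = [c for c in calls if c is not None]
    if not scored:
        raise ValueError(f"locus {locus!r}: zero non-missing calls")
    return sum(1 for a, b in scored if a != b) / len(scored)


def pic(freqs: AlleleFrequencies, formula: str = "powermarker") -> float:
    """Polymorphism information content.

    ``powermarker`` (default): 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2, the
    PIC of Botstein as computed by PowerMarker. ``homozygosity_sum``:
    sum p_i^2 (the expected homozygosity; retained as an explicitly named
    alternative because some reports print this formula under the PIC name).
    """
    p = freqs.p
    if formula == "homozygosity_sum":
        return float(np.sum(p ** 2))
    if formula != "powermarker":
        raise ValueError(f"unknown PIC formula {formula!r}")
    sum_p2 = float(np.sum(p ** 2))
    sum_p4 = float(np.sum(p ** 4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - sum_p2 - (sum_p2 ** 2 - sum_p4)


def shannon_index(freqs: AlleleFrequencies) -> float:
    """Shannon information index I = -sum p_i ln p_i."""
    p = freqs.p
    return float(-np.sum(p * np.log(p)))


def per_locus_summary(gm: GenotypeMatrix,
                      subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Na, Ho, He, Shannon I and PIC per locus (NaN where unscored)."""
    rows = []
    for locus in gm.loci:
        try:
            f = allele_frequencies(gm, locus, subset)
        except ValueError:
            rows.append((locus, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        rows.append((
            locus, f.n_alleles,
            observed_heterozygosity(gm, locus, subset),
            expected_heterozygosity(f),
            shannon_index(f),
            pic(f),
        ))
    return pd.DataFrame(
        rows, columns=["locus", "Na", "Ho", "He", "I", "PIC"]
    ).set_index("locus")


def mean_alleles_per_marker(total_alleles: int, n_markers: int) -> float:
    """Mean allele count per marker, rounded to 2 decimals."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return round(total_alleles / n_markers, 2)


def homo_hetero_ratio(n_homozygous: int, n_heterozygous: int) -> str:
    """Homozygous:heterozygous marker ratio, rounded to the nearest
    integer ratio 'x:1'."""
    if n_heterozygous <= 0:
        raise ValueError("n_heterozygous must be positive")
    return f"{round(n_homozygous / n_heterozygous)}:1"


# ---------------------------------------------------------------------------
# Differentiation


def _pop_locus_stats(gm: GenotypeMatrix, pops: Sequence[str], locus: str):
    """Per population: (n scored individuals, allele->freq, allele->het freq)."""
    members = gm.population_members()
    j = gm.locus_index(locus)
    acc_index = {a: i for i, a in enumerate(gm.accessions)}
    out = []
    for pop in pops:
        calls = [gm.calls[acc_index[a]][j] for a in members.get(pop, [])]
        scored = [c for c in calls if c is not None]
        n = len(scored)
        freq: dict[int, float] = {}
        het: dict[int, float] = {}
        if n:
            for a, b in scored:
                freq[a] = freq.get(a, 0.0) + 1.0
                freq[b] = freq.get(b, 0.0) + 1.0
                if a != b:
                    het[a] = het.get(a, 0.0) + 1.0
                    het[b] = het.get(b, 0.0) + 1.0
            freq = {a: c / (2 * n) for a, c in freq.items()}
            het = {a: het.get(a, 0.0) / n for a in freq}
        out.append((n, freq, het))
    return out


def weir_cockerham_theta(gm: GenotypeMatrix,
                         pops: Sequence[str] | None = None) -> float:
    """Multi-locus, multi-allele Weir-Cockerham (1984) theta over the given
    populations (all populations by default). Variance components a, b, c
    are summed over alleles and loci; theta = sum a / sum(a+b+c)."""
    if pops is None:
        pops = sorted(set(gm.populations))
    r = len(pops)
    if r < 2:
        raise ValueError("need at least 2 populations")
    sum_a = sum_abc = 0.0
    any_locus = False
    for locus in gm.loci:
        stats = _pop_locus_stats(gm, pops, locus)
        ns = np.array([s[0] for s in stats], dtype=float)
        if (ns == 0).any():
            continue  # locus not scored in every population
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(ns ** 2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        alleles = sorted({a for _, f, _ in stats for a in f})
        if len(alleles) < 2:
            continue
        any_locus = True
        for allele in alleles:
            p = np.array([f.get(allele, 0.0) for _, f, _ in stats])
            h = np.array([ht.get(allele, 0.0) for _, _, ht in stats])
            pbar = float(np.sum(ns * p) / (r * nbar))
            s2 = float(np.sum(ns * (p - pbar) ** 2) / ((r - 1) * nbar))
            hbar = float(np.sum(ns * h) / (r * nbar))
            a = (nbar / nc) * (
                s2 - (1.0 / (nbar - 1)) * (
                    pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2.0
            sum_a += a
            sum_abc += a + b + c
    if not any_locus:
        raise ValueError("no locus scored in all populations is polymorphic")
    if sum_abc == 0:
        return 0.0
    return sum_a / sum_abc


def nei_gst(gm: GenotypeMatrix, pops: Sequence[str] | None = None) -> float:
    """Nei's G_ST = (H_T - H_S)/H_T averaged over loci, with allele
    frequencies averaged unweighted across populations; loci with H_T = 0
    are skipped."""
    if pops is None:
        pops = sorted(set(gm.populations))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    values = []
    for locus in gm.loci:
        stats = _pop_locus_stats(gm, pops, locus)
        if any(s[0] == 0 for s in stats):
            continue
        alleles = sorted({a for _, f, _ in stats for a in f})
        pmat = np.array([[f.get(a, 0.0) for a in alleles] for _, f, _ in stats])
        hs = float(np.mean(1.0 - np.sum(pmat ** 2, axis=1)))
        pbar = pmat.mean(axis=0)
        ht = float(1.0 - np.sum(pbar ** 2))
        if ht == 0:
            continue
        values.append((ht - hs) / ht)
    if not values:
        raise ValueError("no informative locus shared by the populations")
    return float(np.mean(values))


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                 estimator: str = "weir_cockerham") -> float:
    """Pairwise fixation index between two populations."""
    if estimator == "weir_cockerham":
        return weir_cockerham_theta(gm, [pop_a, pop_b])
    if estimator == "nei_gst":
        return nei_gst(gm, [pop_a, pop_b])
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


def pairwise_fst_table(gm: GenotypeMatrix,
                       estimator: str = "weir_cockerham") -> pd.DataFrame:
    pops = sorted(set(gm.populations))
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in combinations(pops, 2):
        f = pairwise_fst(gm, a, b, estimator)
        out.loc[a, b] = out.loc[b, a] = f
    return out


# ---------------------------------------------------------------------------
# AMOVA


def amova(gm: GenotypeMatrix, distance: DistanceMatrix | None = None) -> AmovaResult:
    """Two-level AMOVA on squared individual pairwise distances.

    Partitions the total sum of squares into among- and within-population
    strata; variance components follow the expected mean squares with the
    unequal-sample-size coefficient n0; Phi_PT = sigma2_among/sigma2_total,
    clamped at zero (flagged when clamping occurred). Populations of size 1
    are excluded with a warning.
    """
    if distance is None:
        distance = genetic_distance(gm)
    members = gm.population_members()
    small = [p for p, accs in members.items() if len(accs) < 2]
    if small:
        warnings.warn(f"excluding populations of size 1 from AMOVA: {small}")
        members = {p: a for p, a in members.items() if len(a) >= 2}
    if len(members) < 2:
        raise ValueError("AMOVA needs >= 2 populations of size >= 2")
    pos = {l: i for i, l in enumerate(distance.labels)}
    d2 = distance.d ** 2

    kept = [a for accs in members.values() for a in accs]
    idx_all = [pos[a] for a in kept]
    n_total = len(idx_all)
    sub = d2[np.ix_(idx_all, idx_all)]
    ss_total = float(sub[np.triu_indices(n_total, k=1)].sum()) / n_total

    ss_within = 0.0
    sizes = []
    for accs in members.values():
        ii = [pos[a] for a in accs]
        m = d2[np.ix_(ii, ii)]
        ss_within += float(m[np.triu_indices(len(ii), k=1)].sum()) / len(ii)
        sizes.append(len(ii))
    ss_among = ss_total - ss_within

    n_pops = len(members)
    df_among = n_pops - 1
    df_within = n_total - n_pops
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_total - sum(s ** 2 for s in sizes) / n_total) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    clamped = sigma2_among < 0
    if clamped:
        sigma2_among = 0.0
    total_var = sigma2_among + sigma2_within
    if total_var == 0:
        pct_among = pct_within = 0.0
        phi = 0.0
    else:
        pct_among = 100.0 * sigma2_among / total_var
        pct_within = 100.0 * sigma2_within / total_var
        phi = sigma2_among / total_var
    return AmovaResult(
        df_among=df_among, df_within=df_within,
        ss_among=ss_among, ss_within=ss_within,
        ms_among=ms_among, ms_within=ms_within,
        sigma2_among=sigma2_among, sigma2_within=sigma2_within,
        pct_among=pct_among, pct_within=pct_within,
        phi_pt=phi, n0=n0, clamped=clamped,
    )


# ---------------------------------------------------------------------------
# Distances


def _shared_allele_distance(call_i, call_j) -> float:
    counts_i: dict[int, int] = {}
    counts_j: dict[int, int] = {}
    for a in call_i:
        counts_i[a] = counts_i.get(a, 0) + 1
    for a in call_j:
        counts_j[a] = counts_j.get(a, 0) + 1
    shared = sum(min(c, counts_j.get(a, 0)) for a, c in counts_i.items())
    return 1.0 - shared / 2.0


def _bruvo_like_distance(call_i, call_j) -> float:
    # minimal-assignment pairing of the two alleles; per-pair 1 - 2^-|delta|
    (a1, a2), (b1, b2) = call_i, call_j
    def g(x, y):
        return 1.0 - 2.0 ** (-abs(x - y))
    return min((g(a1, b1) + g(a2, b2)) / 2.0,
               (g(a1, b2) + g(a2, b1)) / 2.0)


def genetic_distance(gm: GenotypeMatrix,
                     metric: str = "shared_allele") -> DistanceMatrix:
    """Pairwise genetic distances.

    ``shared_allele`` (default, individual-level): per co-scored locus
    d = 1 - shared_alleles/2, averaged over loci; pairs with a missing
    locus drop that locus. ``bruvo_like_absolute``: fragment-size-aware
    individual distance using 1 - 2^-|size difference| under the minimal
    allele pairing. ``nei_1972_pop``: Nei's (1972) standard genetic
    distance between populations (labels are population names).
    """
    if metric == "nei_1972_pop":
        return _nei_1972_distance(gm)
    if metric not in ("shared_allele", "bruvo_like_absolute"):
        raise ValueError(f"unknown distance metric {metric!r}")
    per_locus = (_shared_allele_distance if metric == "shared_allele"
                 else _bruvo_like_distance)
    n = gm.n_accessions
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        values = []
        for l in range(gm.n_loci):
            ci, cj = gm.calls[i][l], gm.calls[j][l]
            if ci is None or cj is None:
                continue
            values.append(per_locus(ci, cj))
        if not values:
            raise ValueError(
                f"accessions {gm.accessions[i]!r} and {gm.accessions[j]!r} "
                "share no scored locus"
            )
        d[i, j] = d[j, i] = float(np.mean(values))
    return DistanceMatrix(list(gm.accessions), d)


def _nei_1972_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    pops = sorted(set(gm.populations))
    jxy = {}
    jx = {p: [] for p in pops}
    for locus in gm.loci:
        stats = dict(zip(pops, _pop_locus_stats(gm, pops, locus)))
        if any(stats[p][0] == 0 for p in pops):
            continue
        alleles = sorted({a for p in pops for a in stats[p][1]})
        vecs = {p: np.array([stats[p][1].get(a, 0.0) for a in alleles])
                for p in pops}
        for p in pops:
            jx[p].append(float(np.sum(vecs[p] ** 2)))
        for a, b in combinations(pops, 2):
            jxy.setdefault((a, b), []).append(float(np.sum(vecs[a] * vecs[b])))
    n = len(pops)
    d = np.zeros((n, n))
    for (a, b), vals in jxy.items():
        i, j = pops.index(a), pops.index(b)
        num = np.mean(vals)
        den = np.sqrt(np.mean(jx[a]) * np.mean(jx[b]))
        d[i, j] = d[j, i] = max(0.0, -np.log(num / den)) if den > 0 else 0.0
    return DistanceMatrix(pops, d)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion (ties broken by
    the smallest index pair in node-creation order); branch lengths from
    the standard formulas, with negative lengths clamped to zero and the
    deficit moved to the sibling edge. Returns an unrooted tree serialized
    with a trifurcating root.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        bi = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        parent = TreeNode()
        ci, cj = node_of[i], node_of[j]
        ci.length = bi
        cj.length = bj
        parent.extend([ci, cj])
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = (get(i, k) + get(j, k) - dij) / 2.0
            dist[(min(k, next_id), max(k, next_id))] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij, dik, djk = get(i, j), get(i, k), get(j, k)
    bi = (dij + dik - djk) / 2.0
    bj = (dij + djk - dik) / 2.0
    bk = (dik + djk - dij) / 2.0
    root = TreeNode()
    for idx, b in ((i, bi), (j, bj), (k, bk)):
        child = node_of[idx]
        child.length = max(b, 0.0)
        root.append(child)
    return root


# ---------------------------------------------------------------------------
# PCoA


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J is eigendecomposed; axes are ordered by descending
    eigenvalue; percent variance per axis is lambda_k over the sum of
    positive eigenvalues (negative eigenvalues are reported in
    ``eigenvalues`` but excluded from the denominator and yield no axis).
    """
    n = len(dm)
    if n < 2:
        raise ValueError("PCoA needs >= 2 samples")
    d2 = dm.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total_pos = evals[pos].sum()
    pct = 100.0 * evals[pos] / total_pos if total_pos > 0 else evals[pos]
    return PcoaResult(labels=list(dm.labels), coordinates=coords,
                      eigenvalues=evals, pct_variance=pct)


# ---------------------------------------------------------------------------
# Bayesian clustering (no-admixture Gibbs sampler) and Evanno delta-K


def _encode_genotypes(gm: GenotypeMatrix):
    """Integer-encode alleles per locus; missing -> -1."""
    n, L = gm.n_accessions, gm.n_loci
    n_alleles = []
    geno = np.full((n, L, 2), -1, dtype=int)
    for l in range(L):
        alleles = sorted({a for i in range(n)
                          for a in (gm.calls[i][l] or ())})
        amap = {a: ix for ix, a in enumerate(alleles)}
        n_alleles.append(max(1, len(alleles)))
        for i in range(n):
            call = gm.calls[i][l]
            if call is not None:
                geno[i, l, 0] = amap[call[0]]
                geno[i, l, 1] = amap[call[1]]
    return geno, n_alleles


def _kmeans_assignments(coords: np.ndarray, K: int,
                        rng: np.random.Generator, n_iter: int = 15,
                        restarts: int = 8) -> np.ndarray:
    """Lloyd iterations on ordination coordinates with random restarts
    (best within-cluster sum of squares wins); used to start the Gibbs
    chains near a sensible partition. Center draws come from the chain's
    own rng, so independent chains can still land in different modes."""
    n = coords.shape[0]
    best_z = np.zeros(n, dtype=int)
    best_ss = np.inf
    for _ in range(restarts):
        centers = coords[rng.choice(n, size=K, replace=False)].copy()
        z = np.zeros(n, dtype=int)
        for _ in range(n_iter):
            d = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            z = d.argmin(axis=1)
            for k in range(K):
                if (z == k).any():
                    centers[k] = coords[z == k].mean(axis=0)
        ss = sum(((coords[z == k] - coords[z == k].mean(axis=0)) ** 2).sum()
                 for k in range(K) if (z == k).any())
        if ss < best_ss:
            best_z, best_ss = z, ss
    return best_z


def structure_cluster(gm: GenotypeMatrix, K: int, n_iter: int = 200,
                      burn_in: int = 100, seed: int = DEFAULT_SEED) -> StructureRun:
    """Gibbs sampler for the no-admixture, uncorrelated-allele-frequencies
    clustering model.

    Alternates (i) Dirichlet(1 + counts) updates of per-cluster allele
    frequencies and mixture weights given assignments with (ii) multinomial
    re-sampling of individual cluster assignments given frequencies.
    Chains start from a k-means partition of the leading principal
    coordinates of the allele-sharing distance (single-site Gibbs mixes
    poorly from a uniform start when differentiation is strong); the
    k-means restart is drawn from the chain's rng, so independent seeds
    explore different modes. Returns posterior-mean membership coefficients
    (Rao-Blackwellized over the per-sweep assignment posteriors) and the
    ln P(D) estimate mean(L) - var(L)/2 over the post-burn-in mixture
    log-likelihood samples.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_accessions:
        raise ValueError(f"K={K} exceeds the number of accessions")
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    geno, n_alleles = _encode_genotypes(gm)
    n, L = gm.n_accessions, gm.n_loci
    amax = max(n_alleles)
    mask = geno >= 0
    geno_safe = np.where(mask, geno, 0)

    if K == 1:
        z = np.zeros(n, dtype=int)
    else:
        try:
            coords = pcoa(genetic_distance(gm)).coordinates[:, :5]
        except ValueError:
            coords = np.zeros((n, 0))
        if coords.shape[1] >= 1:
            z = _kmeans_assignments(np.ascontiguousarray(coords), K, rng)
        else:  # degenerate distances: fall back to a uniform random start
            z = rng.integers(0, K, size=n)
    members = np.zeros((n, K))
    ll_samples = []

    for sweep in range(burn_in + n_iter):
        # allele counts per cluster x locus x allele
        counts = np.zeros((K, L, amax))
        for copy in range(2):
            idx = geno_safe[:, :, copy]
            m = mask[:, :, copy]
            for k in range(K):
                sel = z == k
                if sel.any():
                    for l in range(L):
                        np.add.at(counts[k, l], idx[sel, l][m[sel, l]], 1.0)
        # frequencies ~ Dirichlet(1 + counts), via gamma draws
        g = rng.gamma(shape=1.0 + counts)
        for l in range(L):  # zero out padding alleles
            g[:, l, n_alleles[l]:] = 0.0
        p = g / g.sum(axis=2, keepdims=True)
        logp = np.log(np.maximum(p, 1e-300))
        # mixture weights ~ Dirichlet(1 + cluster sizes)
        sizes = np.bincount(z, minlength=K)
        gw = rng.gamma(shape=1.0 + sizes.astype(float))
        logpi = np.log(gw / gw.sum())
        # per-individual per-cluster log-likelihood
        ll = np.zeros((n, K))
        for copy in range(2):
            idx = geno_safe[:, :, copy]
            m = mask[:, :, copy]
            for k in range(K):
                contrib = logp[k][np.arange(L)[None, :], idx]
                ll[:, k] += np.where(m, contrib, 0.0).sum(axis=1)
        post_log = logpi[None, :] + ll
        norm = logsumexp(post_log, axis=1)
        post = np.exp(post_log - norm[:, None])
        # resample assignments
        u = rng.random(n)
        z = (post.cumsum(axis=1) > u[:, None]).argmax(axis=1)
        if sweep >= burn_in:
            members += post
            ll_samples.append(float(norm.sum()))

    members /= n_iter
    members /= members.sum(axis=1, keepdims=True)
    ll_arr = np.array(ll_samples)
    ln_p = float(ll_arr.mean() - 0.5 * ll_arr.var())
    assignments = pd.DataFrame(members, index=gm.accessions,
                               columns=[f"cluster_{k+1}" for k in range(K)])
    return StructureRun(K=K, assignments=assignments, ln_prob_data=ln_p,
                        seed=seed)


def evanno_delta_k(lnp: pd.DataFrame) -> pd.Series:
    """Evanno's delta-K from a runs x K table of ln P(D).

    delta-K(K) = mean over runs of |L(K+1) - 2 L(K) + L(K-1)| divided by the
    standard deviation of L(K) across runs; defined only at interior K.
    A zero standard deviation yields +inf with a warning.
    """
    ks = sorted(int(k) for k in lnp.columns)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    if len(lnp) < 2:
        raise ValueError("need >= 2 runs per K")
    lnp = lnp[[c for c in sorted(lnp.columns, key=int)]]
    arr = lnp.to_numpy(dtype=float)
    out = {}
    for pos in range(1, len(ks) - 1):
        second = np.abs(arr[:, pos + 1] - 2 * arr[:, pos] + arr[:, pos - 1])
        sd = float(np.std(arr[:, pos], ddof=1))
        if sd == 0:
            warnings.warn(f"zero sd of ln P(D) at K={ks[pos]}; delta-K infinite")
            out[ks[pos]] = float("inf") if second.mean() > 0 else 0.0
        else:
            out[ks[pos]] = float(second.mean() / sd)
    return pd.Series(out, name="delta_K")


def structure_sweep(gm: GenotypeMatrix, k_range: Sequence[int], n_runs: int,
                    n_iter: int = 200, burn_in: int = 100,
                    seed: int = DEFAULT_SEED) -> tuple[pd.DataFrame, dict]:
    """Run the clustering sampler over a K range with ``n_runs`` seeds per K.

    Returns the runs x K ln P(D) table (input to :func:`evanno_delta_k`) and
    a dict (K, run) -> StructureRun.
    """
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2 ** 31 - 1, size=(len(k_range), n_runs))
    table = pd.DataFrame(index=range(n_runs), columns=list(k_range), dtype=float)
    runs = {}
    for ki, K in enumerate(k_range):
        for r in range(n_runs):
            res = structure_cluster(gm, K, n_iter=n_iter, burn_in=burn_in,
                                    seed=int(run_seeds[ki, r]))
            table.loc[r, K] = res.ln_prob_data
            runs[(K, r)] = res
    return table, runs
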