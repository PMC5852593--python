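"""Perfect microsatellite (SSR) detection and panel classification.

A simple sequence repeat here is a maximal perfect tandem tract of a 2-6 bp
motif. Tracts are reported at the smallest qualifying unit size (an ATAT...
run is a dinucleotide SSR, never a tetranucleotide one), counted in full
repeats only, and classified two ways:

* length class — Class I (tract >= 20 nt) vs Class II (12-19 nt); longer
  tracts tend to be more polymorphic as markers;
* motif base composition — AT-rich / GC-rich / AT/GC-balanced by the GC
  fraction of the repeat unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .io_formats import SequenceRecord


class LengthClass(str, Enum):
    CLASS_I = "CLASS_I"
    CLASS_II = "CLASS_II"


class Composition(str, Enum):
    AT_RICH = "AT_RICH"
    GC_RICH = "GC_RICH"
    BALANCED = "BALANCED"


#: MISA-style per-unit minimum repeat counts, available as an override for
#: the default single total-length rule.
MISA_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 4, 5: 4, 6: 4}

DEFAULT_MOTIF_LENGTHS = frozenset({2, 3, 4, 5, 6})


@dataclass(frozen=True)
class SsrSearchParams:
    """Search thresholds.

    By default any unit size 2-6 qualifies once the perfect tract reaches
    ``min_tract_length_nt`` (12 nt, the lower bound of Class II).
    ``min_repeats_by_unit`` optionally imposes per-unit minimum repeat
    counts (e.g. ``MISA_MIN_REPEATS``) on top of the length rule.
    """

    motif_lengths: frozenset[int] = DEFAULT_MOTIF_LENGTHS
    min_tract_length_nt: int = 12
    min_repeats_by_unit: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.motif_lengths:
            raise ValueError("motif_lengths must be non-empty")
        if not set(self.motif_lengths) <= set(range(1, 7)):
            raise ValueError("motif_lengths must be within 1..6")
        if self.min_tract_length_nt < 2 * min(self.motif_lengths):
            raise ValueError(
                "min_tract_length_nt must allow at least 2 full repeats "
                "of the smallest unit"
            )
        object.__setattr__(self, "motif_lengths", frozenset(self.motif_lengths))

    def min_repeats(self, unit: int) -> int:
        """Minimum number of full repeats for a tract of this unit size."""
        by_len = -(-self.min_tract_length_nt // unit)  # ceil division
        by_unit = (self.min_repeats_by_unit or {}).get(unit, 2)
        return max(2, by_len, by_unit)


@dataclass(frozen=True)
class SsrLocus:
    """One maximal perfect microsatellite tract (full repeats only)."""

    seq_id: str
    start: int   # 0-based
    end: int     # half-open; end - start == n_repeats * unit_size
    motif: str
    unit_size: int
    n_repeats: int
    length_class: LengthClass
    composition: Composition

    @property
    def tract_length_nt(self) -> int:
        return self.n_repeats * self.unit_size


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def classify_length(tract_length_nt: int, class1_min_nt: int = 20,
                    class2_min_nt: int = 12) -> LengthClass:
    """Class I for tracts >= 20 nt, Class II for 12-19 nt.

    A tract of exactly 20 nt is Class I. Below 12 nt is an error: such a
    tract should never have reached classification.
    """
    if tract_length_nt < class2_min_nt:
        raise ValueError(
            f"tract of {tract_length_nt} nt is below the Class II minimum "
            f"({class2_min_nt} nt); it should have been filtered"
        )
    return LengthClass.CLASS_I if tract_length_nt >= class1_min_nt else LengthClass.CLASS_II


def classify_composition(motif: str) -> Composition:
    """AT-rich / GC-rich / balanced by the GC fraction of the repeat unit."""
    bad = set(motif) - set("ACGT")
    if bad or not motif:
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    gc = sum(1 for b in motif if b in "GC") / len(motif)
    if gc > 0.5:
        return Composition.GC_RICH
    if gc < 0.5:
        return Composition.AT_RICH
    return Composition.BALANCED


def find_ssrs(record: SequenceRecord,
              params: SsrSearchParams = SsrSearchParams()) -> list[SsrLocus]:
    """All maximal perfect SSR tracts in a sequence, sorted by start.

    Tracts never span N; a region qualifying at two unit sizes is reported
    once at the smallest unit (ties by leftmost start); trailing partial
    repeats are not counted.
    """
    seq = record.sequence
    n = len(seq)
    candidates: list[tuple[int, int, SsrLocus]] = []  # (unit, start, locus)
    for k in sorted(params.motif_lengths):
        min_rep = params.min_repeats(k)
        t = 0
        while t + k < n:
            if seq[t] != seq[t + k] or seq[t] == "N" or seq[t + k] == "N":
                t += 1
                continue
            # run of period-k matches starting at t
            a = t
            while t + k < n and seq[t] == seq[t + k] and seq[t + k] != "N":
                t += 1
            # matched s[a..t-1] against s[a+k..t-1+k]: tract spans [a, t+k)
            tract_len = (t - a) + k
            n_full = tract_len // k
            motif = seq[a:a + k]
            if (n_full >= min_rep and n_full * k >= params.min_tract_length_nt
                    and "N" not in motif and _is_primitive(motif)):
                end = a + n_full * k
                locus = SsrLocus(
                    seq_id=record.id, start=a, end=end, motif=motif,
                    unit_size=k, n_repeats=n_full,
                    length_class=classify_length(n_full * k,
                                                 class2_min_nt=min(12, params.min_tract_length_nt)),
                    composition=classify_composition(motif),
                )
                candidates.append((k, a, locus))
            t += 1
    # smallest unit wins on overlap; ties by leftmost start
    kept: list[SsrLocus] = []
    for _, _, loc in sorted(candidates, key=lambda c: (c[0], c[1])):
        if all(loc.end <= kl.start or loc.start >= kl.end for kl in kept):
            kept.append(loc)
    kept.sort(key=lambda l: l.start)
    return kept


def find_ssrs_many(records, params: SsrSearchParams = SsrSearchParams()
                   ) -> list[SsrLocus]:
    out: list[SsrLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, params))
    return out


def canonical_motif(motif: str, mode: str = "as_is") -> str:
    """Canonical form of a repeat unit.

    ``as_is`` (default) returns the motif unchanged — complementary or
    rotated motifs such as CCG and CGC are tallied separately. ``rotation``
    returns the lexicographically smallest rotation; ``rotation_revcomp``
    additionally minimizes over the reverse complement's rotations (the
    standard grouping that maps the 64 trimers onto 10 classes).
    """
    if mode == "as_is":
        return motif
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    if mode == "rotation":
        return min(rotations)
    if mode == "rotation_revcomp":
        comp = str.maketrans("ACGT", "TGCA")
        rc = motif.translate(comp)[::-1]
        rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
        return min(rotations)
    raise ValueError(f"unknown canonicalization mode {mode!r}")


_UNIT_NAMES = {2: "Di-nucleotide repeats", 3: "Tri-nucleotide repeats",
               4: "Tetra-nucleotide repeats", 5: "Penta-nucleotide repeats",
               6: "Hexa-nucleotide repeats"}


def summarize_panel(loci: list[SsrLocus],
                    n_sequences_searched: int | None = None,
                    n_ssr_sequences: int | None = None) -> pd.DataFrame:
    """Marker-panel summary table: counts and percentages (2 decimals, out
    of total loci) per repeat-unit size, length class and composition group.

    If ``n_sequences_searched``/``n_ssr_sequences`` are given, header rows
    report the screening universe: SSR-containing sequences as a percentage
    of sequences searched, and panel loci as a percentage of SSR-containing
    sequences.
    """
    if not loci:
        warnings.warn("empty locus panel; summary is all zeros")
    total = len(loci)

    def pct(count: int, denom: int) -> float:
        return round(100.0 * count / denom, 2) if denom else 0.0

    rows: list[tuple[str, int | None, float | None]] = []
    if n_sequences_searched is not None:
        rows.append(("No. of sequences searched", n_sequences_searched, None))
        if n_ssr_sequences is not None:
            rows.append(("SSR-containing sequences", n_ssr_sequences,
                         pct(n_ssr_sequences, n_sequences_searched)))
    if n_ssr_sequences is not None:
        rows.append(("Transcription factor SSRs", total, pct(total, n_ssr_sequences)))
    for unit in range(2, 7):
        c = sum(1 for l in loci if l.unit_size == unit)
        rows.append((_UNIT_NAMES[unit], c, pct(c, total)))
    for cls, name in [(LengthClass.CLASS_I, "Class I members"),
                      (LengthClass.CLASS_II, "Class II members")]:
        c = sum(1 for l in loci if l.length_class == cls)
        rows.append((name, c, pct(c, total)))
    for comp, name in [(Composition.GC_RICH, "GC-rich SSRs"),
                       (Composition.AT_RICH, "AT-rich SSRs"),
                       (Composition.BALANCED, "AT/GC-balanced SSRs")]:
        c = sum(1 for l in loci if l.composition == comp)
        rows.append((name, c, pct(c, total)))
    return pd.DataFrame(rows, columns=["item", "count", "pct"]).set_index("item")


def loci_to_frame(loci: list[SsrLocus]) -> pd.DataFrame:
    """Tabular form of a locus list (the mine stage's TSV layout)."""
    return pd.DataFrame(
        [(l.seq_id, l.start, l.end, l.motif, l.unit_size, l.n_repeats,
          l.tract_length_nt, l.length_class.value, l.composition.value)
         for l in loci],
        columns=["seq_id", "start", "end", "motif", "unit_size", "n_repeats",
                 "tract_nt", "length_class", "composition"],
    )


def loci_from_frame(df: pd.DataFrame) -> list[SsrLocus]:
    return [
        SsrLocus(seq_id=str(r.seq_id), start=int(r.start), end=int(r.end),
                 motif=str(r.motif), unit_size=int(r.unit_size),
                 n_repeats=int(r.n_repeats),
                 length_class=LengthClass(r.length_class),
                 composition=Composition(r.composition))
        for r in df.itertuples(index=False)
    ]
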