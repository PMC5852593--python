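"""Restrict SSR-containing transcripts to transcription-factor candidates.

Homology hits against a plant TF protein database are filtered on E-value,
query coverage and percent identity (all boundaries inclusive); each passing
query is assigned the TF family of its best hit (lowest E-value, then
highest bit score, then lexicographically smallest subject id — a total,
input-order-invariant ordering).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import BlastHit


@dataclass(frozen=True)
class TfFilterThresholds:
    max_evalue: float = 1e-10
    min_query_coverage_pct: float = 65.0
    min_identity_pct: float = 40.0

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        for p in (self.min_query_coverage_pct, self.min_identity_pct):
            if not 0 <= p <= 100:
                raise ValueError("percentage thresholds must be in [0, 100]")


@dataclass(frozen=True)
class TfAnnotation:
    seq_id: str
    tf_family: str
    best_hit: BlastHit
    query_coverage_pct: float


def query_coverage(hit: BlastHit) -> float:
    """Aligned query span as a percentage of query length:
    100 * (q_end - q_start + 1) / query_length."""
    if hit.q_end < hit.q_start:
        raise ValueError("q_end < q_start; orientation not normalized")
    return 100.0 * (hit.q_end - hit.q_start + 1) / hit.query_length


def filter_tf_hits(hits: list[BlastHit],
                   thresholds: TfFilterThresholds = TfFilterThresholds()
                   ) -> list[BlastHit]:
    """Hits passing all thresholds (evalue <= max, coverage >= min,
    identity >= min; comparisons inclusive)."""
    return [
        h for h in hits
        if h.evalue <= thresholds.max_evalue
        and query_coverage(h) >= thresholds.min_query_coverage_pct
        and h.pct_identity >= thresholds.min_identity_pct
    ]


def _hit_rank(h: BlastHit) -> tuple[float, float, str]:
    return (h.evalue, -h.bit_score, h.subject_id)


def assign_family(hits: list[BlastHit],
                  subject_family_map: dict[str, str],
                  thresholds: TfFilterThresholds = TfFilterThresholds()
                  ) -> dict[str, TfAnnotation]:
    """Per query: best passing hit and its TF family.

    Queries with no passing hit are absent from the result. A passing hit
    whose subject has no family mapping raises, naming the subject.
    """
    passing = filter_tf_hits(hits, thresholds)
    best: dict[str, BlastHit] = {}
    for h in passing:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    out: dict[str, TfAnnotation] = {}
    for qid in sorted(best):
        h = best[qid]
        if h.subject_id not in subject_family_map:
            raise KeyError(
                f"subject {h.subject_id!r} has no TF family mapping"
            )
        out[qid] = TfAnnotation(
            seq_id=qid,
            tf_family=subject_family_map[h.subject_id],
            best_hit=h,
            query_coverage_pct=query_coverage(h),
        )
    return out


def family_distribution(markers: pd.DataFrame, by: str = "unit_size"
                        ) -> pd.DataFrame:
    """Contingency table of marker counts: TF family x ``by``
    (``unit_size`` or ``composition``). Row sums are family totals."""
    if by not in ("unit_size", "composition"):
        raise ValueError("by must be 'unit_size' or 'composition'")
    tab = pd.crosstab(markers["tf_family"], markers[by])
    return tab


def annotations_to_frame(annots: dict[str, TfAnnotation]) -> pd.DataFrame:
    rows = [
        (a.seq_id, a.tf_family, a.best_hit.subject_id, a.best_hit.evalue,
         a.best_hit.bit_score, a.best_hit.pct_identity,
         round(a.query_coverage_pct, 2))
        for a in annots.values()
    ]
    return pd.DataFrame(
        rows, columns=["seq_id", "tf_family", "subject_id", "evalue",
                       "bit_score", "pct_identity", "query_coverage_pct"])
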