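"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from tfssr.io_formats import GenotypeMatrix, SequenceRecord
from tfssr.ssr_mining import SsrSearchParams


# ---------------------------------------------------------------------------
# Brute-force SSR oracle (independent of the package scanner)


def _oracle_primitive(motif: str) -> bool:
    return not any(
        len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d)
        for d in range(1, len(motif))
    )


def oracle_find_ssrs(seq: str, params: SsrSearchParams = SsrSearchParams()):
    """Brute-force maximal perfect tract scan over every unit size.

    Uses a numpy lag-comparison to find maximal period-k regions, reports
    each at its leftmost full-repeat alignment, verifies the tract against
    a regex, then applies the smallest-unit-wins / leftmost overlap rule.
    Returns a set of (start, end, motif, unit, n_repeats) tuples.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    candidates = []
    for k in sorted(params.motif_lengths):
        if n <= k:
            continue
        match = (arr[:-k] == arr[k:]) & (arr[:-k] != b"N") & (arr[k:] != b"N")
        # maximal runs of True
        idx = np.flatnonzero(match)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s_i, e_i in zip(starts, ends):
            a = int(idx[s_i])
            c = int(idx[e_i]) + 1          # run covers t in [a, c)
            tract_len = (c - a) + k
            n_full = tract_len // k
            motif = seq[a:a + k]
            if (n_full >= params.min_repeats(k)
                    and n_full * k >= params.min_tract_length_nt
                    and "N" not in motif and _oracle_primitive(motif)):
                end = a + n_full * k
                assert re.fullmatch(re.escape(motif) * n_full, seq[a:end])
                candidates.append((k, a, end, motif, n_full))
    kept = []
    for k, a, end, motif, reps in sorted(candidates):
        if all(end <= ka or a >= ke for _, ka, ke, _, _ in kept):
            kept.append((k, a, end, motif, reps))
    return {(a, end, motif, k, reps) for k, a, end, motif, reps in kept}


def repeat_enriched_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence salted with tandem repeats of random motifs, so
    scanner/oracle comparisons exercise real hits."""
    out = []
    n = 0
    while n < length:
        if rng.random() < 0.03:
            k = int(rng.integers(2, 7))
            motif = "".join(rng.choice(list("ACGT"), size=k))
            reps = int(rng.integers(2, 12))
            out.append(motif * reps)
            n += k * reps
        else:
            out.append(str(rng.choice(list("ACGTN"), p=[0.243] * 4 + [0.028])))
            n += 1
    return "".join(out)[:length]


# ---------------------------------------------------------------------------
# Genotype fixtures


def make_genotype_matrix(calls_by_acc: dict[str, tuple[str, list]],
                         loci: list[str]) -> GenotypeMatrix:
    """calls_by_acc: accession -> (population, [call, ...]) where call is a
    tuple pair or None."""
    accs = list(calls_by_acc)
    return GenotypeMatrix(
        accessions=accs,
        populations=[calls_by_acc[a][0] for a in accs],
        loci=loci,
        calls=[list(calls_by_acc[a][1]) for a in accs],
    )


@pytest.fixture
def two_fixed_pops() -> GenotypeMatrix:
    """Two populations internally identical, fixed for different alleles."""
    loci = [f"L{i}" for i in range(5)]
    calls = {}
    for i in range(4):
        calls[f"A{i}"] = ("PopA", [(100, 100)] * 5)
    for i in range(4):
        calls[f"B{i}"] = ("PopB", [(120, 120)] * 5)
    return make_genotype_matrix(calls, loci)


@pytest.fixture
def small_mixed_gm() -> GenotypeMatrix:
    """Small two-population matrix with heterozygotes and missing data."""
    loci = ["L1", "L2", "L3"]
    calls = {
        "a1": ("P1", [(100, 100), (150, 154), None]),
        "a2": ("P1", [(100, 120), (150, 150), (200, 202)]),
        "a3": ("P2", [(120, 120), (154, 154), (200, 200)]),
        "a4": ("P2", [(100, 120), (150, 154), (202, 202)]),
    }
    return make_genotype_matrix(calls, loci)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20180214)


def random_record(rng: np.random.Generator, length: int, name: str = "u1"
                  ) -> SequenceRecord:
    return SequenceRecord(name, "".join(rng.choice(list("ACGT"), size=length)))
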