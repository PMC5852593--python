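"""Flanking-primer design for SSR loci.

A native enumerator + penalty scorer in the style of Primer3 defaults:
candidate primer windows in both flanks are screened against hard
constraints (length, melting temperature, GC content, 3'-end
self-complementarity, product size), and surviving pairs are ranked by a
penalty that sums absolute deviations from the optimum Tm and length.
The amplicon always spans the full SSR tract; primers never overlap it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import SequenceRecord
from .ssr_mining import SsrLocus

# Penalty weights (per primer, summed over the pair).
W_TM = 1.0        # per degree C deviation from tm_opt
W_LENGTH = 1.0    # per base deviation from primer_len_opt

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# SantaLucia (1998) unified nearest-neighbor parameters.
# dH in kcal/mol, dS in cal/(mol K), 1 M NaCl reference.
NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
# Initiation terms per terminal base pair.
INIT_GC = (0.1, -2.8)   # (dH, dS) for a terminal G.C
INIT_AT = (2.3, 4.1)    # for a terminal A.T
R_GAS = 1.987           # cal / (K mol)
PRIMER_CONC_M = 50e-9   # total strand concentration, 50 nM
MONOVALENT_M = 0.050    # 50 mM Na+


@dataclass(frozen=True)
class PrimerConstraints:
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 20.0
    gc_max: float = 80.0
    product_size_min: int = 100
    product_size_max: int = 300
    max_end_self_complementarity: int = 3
    tm_method: str = "nn_santalucia"

    def __post_init__(self) -> None:
        if not (self.primer_len_min <= self.primer_len_opt <= self.primer_len_max):
            raise ValueError("primer length min <= opt <= max violated")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("tm min <= opt <= max violated")
        if self.product_size_min > self.product_size_max:
            raise ValueError("product size range inverted")


@dataclass(frozen=True)
class PrimerPair:
    locus: SsrLocus
    forward_seq: str
    reverse_seq: str
    forward_tm: float
    reverse_tm: float
    forward_start: int   # 0-based on the template plus strand
    reverse_start: int   # 0-based start of the plus-strand window the reverse primer binds
    product_size: int
    penalty: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage of a non-empty ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def melting_temperature(seq: str, method: str = "nn_santalucia") -> float:
    """Primer melting temperature in degrees C.

    ``wallace``: 2(A+T) + 4(G+C), the quick rule for short oligos.
    ``nn_santalucia``: unified nearest-neighbor dH/dS sum with the 50 mM
    monovalent entropy correction (0.368 cal/K per phosphate per ln[Na+])
    and total strand concentration 50 nM:
    Tm = 1000 dH / (dS_corrected + R ln(C_T/4)) - 273.15.
    """
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT character in {seq!r}")
    if method == "wallace":
        at = sum(1 for b in seq if b in "AT")
        return 2.0 * at + 4.0 * (len(seq) - at)
    if method != "nn_santalucia":
        raise ValueError(f"unknown Tm method {method!r}")
    dh = 0.0
    ds = 0.0
    for end in (seq[0], seq[-1]):
        ih, is_ = INIT_GC if end in "GC" else INIT_AT
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        pair = seq[i:i + 2]
        dh += NN_DH[pair]
        ds += NN_DS[pair]
    ds += 0.368 * (len(seq) - 1) * math.log(MONOVALENT_M)
    return 1000.0 * dh / (ds + R_GAS * math.log(PRIMER_CONC_M / 4)) - 273.15


def end_self_complementarity(seq: str) -> int:
    """Longest 3'-terminal run that is its own reverse complement
    (a proxy for 3' self-dimer propensity)."""
    best = 0
    for k in range(1, len(seq) + 1):
        tail = seq[-k:]
        if tail == reverse_complement(tail):
            best = k
    return best


def _passes_hard(seq: str, c: PrimerConstraints) -> float | None:
    """Tm if the window passes all per-primer hard constraints, else None."""
    if not (c.gc_min <= gc_content(seq) <= c.gc_max):
        return None
    tm = melting_temperature(seq, c.tm_method)
    if not (c.tm_min <= tm <= c.tm_max):
        return None
    if end_self_complementarity(seq) > c.max_end_self_complementarity:
        return None
    return tm


def design_primers(record: SequenceRecord, locus: SsrLocus,
                   constraints: PrimerConstraints = PrimerConstraints(),
                   max_pairs: int | None = 100) -> list[PrimerPair]:
    """Ranked primer pairs flanking an SSR tract.

    Returns pairs sorted by ascending penalty (ties by forward start then
    reverse start), truncated to the best ``max_pairs`` (None keeps all);
    empty when no pair satisfies the hard constraints.
    """
    if locus.seq_id != record.id or locus.end > len(record.sequence):
        raise ValueError(
            f"locus {locus.seq_id}:{locus.start}-{locus.end} is not within "
            f"record {record.id!r}"
        )
    seq = record.sequence
    c = constraints
    n = len(seq)

    # forward candidates: plus-strand windows ending at or before the tract
    fwd: list[tuple[int, int, str, float]] = []  # (start, length, seq, tm)
    lo = max(0, locus.end - c.product_size_max)
    for start in range(lo, locus.start - c.primer_len_min + 1):
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            if start + length > locus.start:
                break
            window = seq[start:start + length]
            if "N" in window:
                continue
            tm = _passes_hard(window, c)
            if tm is not None:
                fwd.append((start, length, window, tm))

    # reverse candidates: reverse-complement of plus-strand windows at or
    # after the tract
    rev: list[tuple[int, int, str, float]] = []
    hi = min(n, locus.start + c.product_size_max)
    for start in range(locus.end, hi - c.primer_len_min + 1):
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            if start + length > hi or start + length > n:
                break
            window = seq[start:start + length]
            if "N" in window:
                continue
            primer = reverse_complement(window)
            tm = _passes_hard(primer, c)
            if tm is not None:
                rev.append((start, length, primer, tm))

    if not fwd or not rev:
        return []
    f_start = np.array([f[0] for f in fwd])
    f_len = np.array([f[1] for f in fwd])
    f_tm = np.array([f[3] for f in fwd])
    r_start = np.array([r[0] for r in rev])
    r_len = np.array([r[1] for r in rev])
    r_tm = np.array([r[3] for r in rev])
    f_pen = W_TM * np.abs(f_tm - c.tm_opt) + W_LENGTH * np.abs(f_len - c.primer_len_opt)
    r_pen = W_TM * np.abs(r_tm - c.tm_opt) + W_LENGTH * np.abs(r_len - c.primer_len_opt)
    product = (r_start + r_len)[None, :] - f_start[:, None]
    ok = (product >= c.product_size_min) & (product <= c.product_size_max)
    fi, ri = np.nonzero(ok)
    if fi.size == 0:
        return []
    penalty = f_pen[fi] + r_pen[ri]
    order = np.lexsort((r_start[ri], f_start[fi], penalty))
    if max_pairs is not None:
        order = order[:max_pairs]
    pairs = [
        PrimerPair(
            locus=locus, forward_seq=fwd[fi[o]][2], reverse_seq=rev[ri[o]][2],
            forward_tm=float(f_tm[fi[o]]), reverse_tm=float(r_tm[ri[o]]),
            forward_start=int(f_start[fi[o]]), reverse_start=int(r_start[ri[o]]),
            product_size=int(product[fi[o], ri[o]]), penalty=float(penalty[o]))
        for o in order
    ]
    return pairs
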