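"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the domain types defined here:
``SequenceRecord`` (a transcript/unigene), ``BlastHit`` (one row of
12-column tabular homology output), and ``GenotypeMatrix`` (diploid
fragment-size calls, accessions x loci, with population labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

MISSING_TOKENS = {"-", "", "NA"}

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with a unique identifier.

    Sequences are upper-cased on construction; only A/C/G/T/N are allowed.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if len(seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore) with the query length
    attached so query coverage is computable."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    query_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end "
                "after orientation normalization"
            )
        if self.query_length <= 0:
            raise ValueError("query_length must be positive")


@dataclass
class GenotypeMatrix:
    """Diploid codominant genotype calls: accessions x loci.

    ``calls[i][j]`` is ``None`` (missing) or an ascending pair of positive
    integer allele identifiers (fragment sizes in bp); a homozygote is an
    identical pair. ``populations[i]`` labels accession ``i``.
    """

    accessions: list[str]
    populations: list[str]
    loci: list[str]
    calls: list[list[tuple[int, int] | None]]

    def __post_init__(self) -> None:
        if len(self.populations) != len(self.accessions):
            raise ValueError("one population label per accession required")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession names")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("call row length does not match locus count")
            for call in row:
                if call is None:
                    continue
                a, b = call
                if a > b or a <= 0:
                    raise ValueError(f"call {call} not an ascending positive pair")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def column(self, locus: str) -> list[tuple[int, int] | None]:
        j = self.locus_index(locus)
        return [row[j] for row in self.calls]

    def subset_indices(self, subset: Sequence[str] | None) -> list[int]:
        if subset is None:
            return list(range(self.n_accessions))
        idx = {a: i for i, a in enumerate(self.accessions)}
        missing = [a for a in subset if a not in idx]
        if missing:
            raise KeyError(f"accessions not in matrix: {missing}")
        return [idx[a] for a in subset]

    def population_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for acc, pop in zip(self.accessions, self.populations):
            out.setdefault(pop, []).append(acc)
        return out

    def uninformative_loci(self) -> list[str]:
        """Loci where every call is missing."""
        out = []
        for j, locus in enumerate(self.loci):
            if all(row[j] is None for row in self.calls):
                out.append(locus)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, order preserved.

    Duplicate ids raise; an empty file returns an empty list with a warning.
    Lower-case bases are upper-cased.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    if not records:
        warnings.warn(f"no records found in FASTA {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BLAST tabular

_BLAST_COLS = 12


def read_blast_tab(path: str | Path,
                   query_lengths: Mapping[str, int]) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (-outfmt 6 dialect).

    ``query_lengths`` maps query id -> nucleotide query length (computed from
    the query FASTA); coverage filtering downstream requires it. Rows with a
    query id absent from the map, or with a column count other than 12,
    raise with the offending line number.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _BLAST_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_BLAST_COLS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            qid = cols[0]
            if qid not in query_lengths:
                raise KeyError(
                    f"{path}:{lineno}: query id {qid!r} absent from the "
                    "query-length map"
                )
            hits.append(BlastHit(
                query_id=qid,
                subject_id=cols[1],
                pct_identity=float(cols[2]),
                align_length=int(cols[3]),
                mismatches=int(cols[4]),
                gap_opens=int(cols[5]),
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
                evalue=float(cols[10]),
                bit_score=float(cols[11]),
                query_length=int(query_lengths[qid]),
            ))
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, h.pct_identity, h.align_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start,
                h.s_end, h.evalue, h.bit_score)) + "\n")


# ---------------------------------------------------------------------------
# Genotype tables


def _parse_call(token: str, row_label: str, locus: str) -> tuple[int, int] | None:
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    parts = token.split("/")
    if len(parts) != 2:
        raise ValueError(
            f"malformed genotype call {token!r} at accession {row_label!r}, "
            f"locus {locus!r} (expected 'a/b')"
        )
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(
            f"malformed genotype call {token!r} at accession {row_label!r}, "
            f"locus {locus!r}: non-integer allele"
        ) from exc
    if a <= 0 or b <= 0:
        raise ValueError(
            f"non-positive allele in call {token!r} at accession "
            f"{row_label!r}, locus {locus!r}"
        )
    return (a, b) if a <= b else (b, a)  # unordered diploid: normalize ascending


def read_genotype_table(path: str | Path, sep: str | None = None) -> GenotypeMatrix:
    """Read a delimited genotype table.

    First two columns are accession and population; each remaining column is
    one locus. Diploid calls are encoded ``a/b`` (homozygote ``a/a``);
    missing is ``-``, ``NA`` or empty. Allele order within a call is
    normalized ascending. The delimiter is auto-detected (tab if any tab on
    the header line, else comma) unless given.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty genotype table {path}")
    if sep is None:
        sep = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(sep)
    if len(header) < 3:
        raise ValueError("genotype table needs accession, population and >=1 locus column")
    loci = [c.strip() for c in header[2:]]
    accessions: list[str] = []
    populations: list[str] = []
    calls: list[list[tuple[int, int] | None]] = []
    for ln in lines[1:]:
        cols = ln.split(sep)
        if len(cols) != len(header):
            raise ValueError(
                f"row for {cols[0]!r}: expected {len(header)} columns, got {len(cols)}"
            )
        acc = cols[0].strip()
        if acc in accessions:
            raise ValueError(f"duplicate accession {acc!r}")
        accessions.append(acc)
        populations.append(cols[1].strip())
        calls.append([_parse_call(tok, acc, loc) for tok, loc in zip(cols[2:], loci)])
    gm = GenotypeMatrix(accessions, populations, loci, calls)
    dead = gm.uninformative_loci()
    if dead:
        warnings.warn(f"loci with no scored calls (retained, uninformative): {dead}")
    return gm


def write_genotype_table(gm: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["accession", "population"] + gm.loci) + "\n")
        for acc, pop, row in zip(gm.accessions, gm.populations, gm.calls):
            toks = ["-" if c is None else f"{c[0]}/{c[1]}" for c in row]
            fh.write(sep.join([acc, pop] + toks) + "\n")


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode (e.g. from neighbor_joining) as Newick
    with branch lengths, ';'-terminated."""
    tree.write(str(path), format="newick")
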