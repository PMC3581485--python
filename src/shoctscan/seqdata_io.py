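"""Readers, writers and the alignment-reversal transform.

File formats handled here: FASTA (sequence databases), Stockholm 1.0 (seed
alignments), a per-protein domain-annotation TSV, and a protein → clade-path
taxonomy TSV. All residue-range coordinates are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence as TSequence

import pandas as pd
from Bio import SeqIO

from .alphabet import GAP_CHARS

ANNOTATION_COLUMNS = [
    "protein_id",
    "protein_length",
    "domain_id",
    "env_start",
    "env_end",
    "bit_score",
]


@dataclasses.dataclass(frozen=True)
class Sequence:
    """A protein sequence with an optional clade-path taxonomy label."""

    id: str
    residues: str
    taxon: Optional[str] = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has an empty body")
        if not self.residues.isupper():
            object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment: ordered (id, gapped-string) rows.

    Gap symbols are '-' and '.'; both count as unoccupied for occupancy
    computations.
    """

    rows: tuple
    ncol: int

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "Alignment":
        rows = tuple((str(i), str(s)) for i, s in rows)
        if not rows:
            raise ValueError("alignment must have at least one row")
        ncol = len(rows[0][1])
        for rid, s in rows:
            if len(s) != ncol:
                raise ValueError(
                    f"row {rid!r} has length {len(s)}, expected {ncol}"
                )
        return cls(rows=rows, ncol=ncol)

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return "".join(c for c in self.rows[i][1] if c not in GAP_CHARS)


@dataclasses.dataclass(frozen=True)
class DomainAnnotationRecord:
    """One domain envelope placed on one protein (1-based inclusive coords)."""

    protein_id: str
    protein_length: int
    domain_id: str
    env_start: int
    env_end: int
    bit_score: float

    def __post_init__(self):
        if not (1 <= self.env_start <= self.env_end <= self.protein_length):
            raise ValueError(
                f"invalid envelope {self.env_start}-{self.env_end} on "
                f"{self.protein_id!r} (length {self.protein_length})"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into a list of Sequence (uppercased, unwrapped)."""
    path = Path(path)
    seqs: list = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        body = str(rec.seq).upper()
        if not body:
            raise ValueError(f"{path}: record {rec.id!r} has an empty body")
        seqs.append(Sequence(id=rec.id, residues=body))
    return seqs


def write_fasta(seqs: TSequence, path, wrap: int = 60) -> None:
    """Write sequences as FASTA with the given line wrap (read_fasta inverts it)."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), wrap):
                fh.write(s.residues[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Stockholm
# ---------------------------------------------------------------------------

def read_stockholm(path) -> Alignment:
    """Read a single Stockholm 1.0 alignment.

    GF/GC/GS/GR annotation lines are ignored; wrapped multi-block sequences are
    concatenated; both '.' and '-' gap characters are preserved as written.
    A missing '//' terminator or unequal row lengths raise ValueError.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("# STOCKHOLM"):
        raise ValueError(f"{path}: missing '# STOCKHOLM 1.0' header")
    if not any(ln.strip() == "//" for ln in lines):
        raise ValueError(f"{path}: missing Stockholm '//' terminator")
    chunks: dict = {}
    order: list = []
    for ln in lines[1:]:
        ln = ln.rstrip()
        if not ln or ln.startswith("#"):
            continue
        if ln.strip() == "//":
            break
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed alignment line {ln!r}")
        name, chunk = parts
        if name not in chunks:
            chunks[name] = []
            order.append(name)
        chunks[name].append(chunk)
    if not order:
        raise ValueError(f"{path}: alignment contains no sequence rows")
    rows = [(name, "".join(chunks[name])) for name in order]
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal row lengths {sorted(lengths)}")
    return Alignment.from_rows(rows)


def write_stockholm(a: Alignment, path) -> None:
    """Write an Alignment as a single-block Stockholm 1.0 file."""
    width = max(len(rid) for rid, _ in a.rows)
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, s in a.rows:
            fh.write(f"{rid:<{width}} {s}\n")
        fh.write("//\n")


def reverse_alignment(a: Alignment) -> Alignment:
    """Reverse column order within every row (ids, row order, ncol preserved).

    This is the decoy construction: reversing the seed alignment destroys the
    family signal while preserving per-row residue composition exactly.
    """
    return Alignment.from_rows((rid, s[::-1]) for rid, s in a.rows)


# ---------------------------------------------------------------------------
# Annotation and taxonomy tables
# ---------------------------------------------------------------------------

def read_annotations(path) -> list:
    """Read the domain-annotation TSV, enforcing coordinate invariants per row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                DomainAnnotationRecord(
                    protein_id=row.protein_id,
                    protein_length=int(row.protein_length),
                    domain_id=row.domain_id,
                    env_start=int(row.env_start),
                    env_end=int(row.env_end),
                    bit_score=float(row.bit_score),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: line {rownum}: {e}") from e
    return records


def write_annotations(records: TSequence, path) -> None:
    df = pd.DataFrame(
        [
            (r.protein_id, r.protein_length, r.domain_id, r.env_start, r.env_end, r.bit_score)
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict:
    """Read a two-column TSV (protein_id, semicolon-separated clade path)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: taxonomy table needs two columns")
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_taxonomy(taxonomy: dict, path) -> None:
    df = pd.DataFrame(
        sorted(taxonomy.items()), columns=["protein_id", "clade_path"]
    )
    df.to_csv(path, sep="\t", index=False)
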