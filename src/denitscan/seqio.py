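"""Sequence, alignment and gene-coordinate I/O.

All coordinates are GFF3 1-based inclusive throughout the package; no
0-based conversion happens anywhere in the public contract.  Protein
residues use the 20 canonical amino-acid letters plus ``X``; selenocysteine
(``U``) and pyrrolysine (``O``) are mapped to ``X`` with a warning so the
alphabet stays closed.  Gap characters ``-`` and ``.`` are treated
identically wherever gaps are legal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import AlignmentError, FormatError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = "-."
_ALLOWED = set(AMINO_ACIDS) | {"X"}
_REMAPPED = {"U", "O"}  # selenocysteine / pyrrolysine -> X


def normalize_residues(raw: str, *, allow_gaps: bool = False, where: str = "") -> str:
    """Uppercase ``raw`` and enforce the 20+X (+gap) alphabet.

    U/O are remapped to X with a warning; any other letter raises
    :class:`FormatError` naming the offending record.
    """
    out = []
    for ch in raw.upper():
        if ch in _REMAPPED:
            warnings.warn(
                f"residue '{ch}' mapped to 'X' in {where or 'sequence'}",
                stacklevel=2,
            )
            ch = "X"
        if ch in _ALLOWED or (allow_gaps and ch in GAP_CHARS):
            out.append(ch)
        else:
            raise FormatError(
                f"illegal residue character {ch!r} in {where or 'sequence'}"
            )
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: unique id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An aligned set of sequences; rows may contain ``-``/``.`` gaps."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentError("alignment needs at least 2 rows")
        widths = {len(r.residues) for r in self.records}
        if len(widths) != 1:
            raise AlignmentError(
                "ragged alignment rows; widths seen: "
                + ", ".join(str(len(r.residues)) for r in self.records)
            )

    @property
    def ncols(self) -> int:
        return len(self.records[0].residues)

    @property
    def nrows(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneRecord:
    """A gene call: 1-based inclusive nucleotide span plus gene order rank."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    rank: int

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into normalized :class:`SequenceRecord`\\ s."""
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), where=f"record {rec.id!r}")
        if not residues:
            raise FormatError(f"record {rec.id!r} in {path} has no residues")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


_ALIGN_DIALECTS = {"aligned-fasta": "fasta", "stockholm": "stockholm"}


def read_alignment(path, dialect: str = "aligned-fasta") -> Alignment:
    """Read an alignment (aligned FASTA or Stockholm), gaps preserved.

    Stockholm ``#=GC``/``#=GR`` annotation lines are ignored; only the
    sequence rows are parsed.
    """
    if dialect not in _ALIGN_DIALECTS:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), _ALIGN_DIALECTS[dialect])
    except ValueError as exc:
        # Biopython raises on ragged fasta alignments; report row widths.
        widths = [
            f"{r.id}:{len(r.seq)}" for r in SeqIO.parse(str(path), "fasta")
        ] if dialect == "aligned-fasta" else []
        raise AlignmentError(
            f"cannot read alignment {path}: {exc}"
            + (f" (row widths: {', '.join(widths)})" if widths else "")
        ) from exc
    records = tuple(
        SequenceRecord(
            rec.id,
            normalize_residues(
                str(rec.seq), allow_gaps=True, where=f"row {rec.id!r}"
            ),
        )
        for rec in msa
    )
    return Alignment(records)


def write_alignment(msa: Alignment, path) -> None:
    """Write an alignment as aligned FASTA (gaps preserved)."""
    write_fasta(msa.records, path)


def read_gff(path) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 (CDS features, else gene features).

    Records come back sorted by (contig, start) with ``rank`` assigned per
    contig from 1.  Features must carry an ``ID`` attribute; strand ``.`` is
    rejected.
    """
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    feats = list(db.features_of_type("CDS"))
    if not feats:
        feats = list(db.features_of_type("gene"))
    if not feats:
        raise FormatError(f"no CDS or gene features in {path}")

    raw = []
    for f in feats:
        if "ID" not in f.attributes:
            raise FormatError(f"feature at {f.seqid}:{f.start} lacks an ID")
        gid = f.attributes["ID"][0]
        if f.strand not in ("+", "-"):
            raise FormatError(f"feature {gid}: strand {f.strand!r} rejected")
        if f.start > f.end:
            raise FormatError(f"feature {gid}: start {f.start} > end {f.end}")
        pid = f.attributes.get("protein_id", [gid])[0]
        raw.append((f.seqid, f.start, f.end, f.strand, gid, pid))

    raw.sort(key=lambda t: (t[0], t[1], t[2], t[4]))
    out: list[GeneRecord] = []
    rank = 0
    prev_contig = None
    for contig, start, end, strand, gid, pid in raw:
        rank = rank + 1 if contig == prev_contig else 1
        prev_contig = contig
        out.append(GeneRecord(gid, contig, start, end, strand, pid, rank))
    return out


def write_gff(genes: Sequence[GeneRecord], path) -> None:
    """Write gene records as minimal GFF3 CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            attrs = f"ID={g.gene_id};protein_id={g.protein_id}"
            fh.write(
                f"{g.contig_id}\tdenitscan\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


def dereplicate(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Drop exact full-length duplicates (case-insensitive), keeping the
    first occurrence and otherwise preserving input order."""
    seen: set[str] = set()
    out = []
    for rec in records:
        key = rec.residues.upper()
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out
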