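"""tRNA reference model: gene records, mature and precursor sequences.

A tRNA gene is described by its genomic body (no CCA), an optional intron,
5' leader / 3' trailer flanks and the annotated anticodon position.  The
mature tRNA is the spliced body with the post-transcriptional 3' CCA tail;
the precursor is leader + unspliced body + trailer.  Fragments are placed on
these two coordinate systems, 1-based inclusive throughout.

The anticodon position comes from annotation (GtRNAdb-style sidecars carry
it); no secondary-structure folding is performed.  All sequences are handled
as DNA; U is mapped to T on input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

_DNA = re.compile(r"^[ACGT]+$")
_GENE_ID = re.compile(r"^([A-Za-z]{3})-([ACGT]{3})-(\d+)$")


class ReferenceError(ValueError):
    """Raised when a gene record violates the reference model invariants."""


def as_dna(seq: str) -> str:
    """Uppercase and map U->T; reject anything outside {A,C,G,T}."""
    s = seq.strip().upper().replace("U", "T")
    if s and not _DNA.match(s):
        raise ReferenceError(f"non-DNA characters in sequence: {seq[:30]!r}")
    return s


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One tRNA gene: ``{AminoAcid}-{Anticodon}-{isodecoder}`` plus sequence.

    ``anticodon_start`` is the 1-based position of the anticodon's first
    nucleotide in the *spliced* body.  ``intron`` is a 1-based inclusive
    interval within ``body_seq`` or ``None``.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    isodecoder_index: int
    body_seq: str
    anticodon_start: int
    intron: Optional[tuple[int, int]] = None
    leader_seq: str = ""
    trailer_seq: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "body_seq", as_dna(self.body_seq))
        object.__setattr__(self, "leader_seq", as_dna(self.leader_seq))
        object.__setattr__(self, "trailer_seq", as_dna(self.trailer_seq))
        object.__setattr__(self, "anticodon", as_dna(self.anticodon))
        if not self.body_seq:
            raise ReferenceError(f"{self.gene_id}: empty body sequence")
        if len(self.anticodon) != 3:
            raise ReferenceError(f"{self.gene_id}: anticodon must be 3 nt")
        if self.isodecoder_index < 1:
            raise ReferenceError(f"{self.gene_id}: isodecoder index must be >= 1")
        if self.intron is not None:
            i0, i1 = self.intron
            if not (1 < i0 <= i1 < len(self.body_seq)):
                raise ReferenceError(
                    f"{self.gene_id}: intron {i0}..{i1} not strictly inside "
                    f"body of length {len(self.body_seq)}"
                )
        spliced = self.spliced_body
        a = self.anticodon_start
        if not (1 <= a and a + 2 <= len(spliced)):
            raise ReferenceError(f"{self.gene_id}: anticodon_start {a} out of bounds")
        if spliced[a - 1 : a + 2] != self.anticodon:
            raise ReferenceError(
                f"{self.gene_id}: anticodon {self.anticodon} not found at "
                f"position {a} of the spliced body"
            )

    @property
    def family(self) -> str:
        """Isodecoder family key, e.g. ``Gly-GCC``."""
        return f"{self.amino_acid}-{self.anticodon}"

    @property
    def spliced_body(self) -> str:
        if self.intron is None:
            return self.body_seq
        i0, i1 = self.intron
        return self.body_seq[: i0 - 1] + self.body_seq[i1:]

    @property
    def sort_key(self) -> tuple[str, str, int]:
        return (self.amino_acid, self.anticodon, self.isodecoder_index)

    @classmethod
    def from_parts(cls, gene_id: str, body_seq: str, anticodon_start: int,
                   intron: Optional[tuple[int, int]] = None,
                   leader_seq: str = "", trailer_seq: str = "") -> "TRNAGeneRecord":
        """Build a record parsing amino acid / anticodon / index from the id."""
        m = _GENE_ID.match(gene_id)
        if not m:
            raise ReferenceError(
                f"gene id {gene_id!r} does not match 'AA-Anticodon-N'"
            )
        aa, anticodon, idx = m.group(1), m.group(2), int(m.group(3))
        return cls(gene_id=gene_id, amino_acid=aa, anticodon=anticodon,
                   isodecoder_index=idx, body_seq=body_seq,
                   anticodon_start=anticodon_start, intron=intron,
                   leader_seq=leader_seq, trailer_seq=trailer_seq)


@dataclass(frozen=True)
class MatureTRNA:
    """Spliced body plus the 3' CCA tail; fragment coordinates live here."""

    gene_id: str
    seq: str
    anticodon_span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrecursorTRNA:
    """leader + unspliced body + trailer; hosts tRF-1 (trailer) fragments."""

    gene_id: str
    seq: str
    body_span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.seq)


def splice_and_cca(body_seq: str, intron: Optional[tuple[int, int]] = None) -> str:
    """Remove an intron interval (1-based inclusive) and append CCA."""
    body = as_dna(body_seq)
    if intron is None:
        return body + "CCA"
    i0, i1 = intron
    if not (1 <= i0 <= i1 <= len(body)):
        raise ReferenceError(f"intron {i0}..{i1} out of bounds for body of length {len(body)}")
    return body[: i0 - 1] + body[i1:] + "CCA"


def build_mature(gene: TRNAGeneRecord) -> MatureTRNA:
    """Splice out the intron (if any) and append CCA.

    The anticodon span is re-stated on spliced coordinates; the gene record
    already validated that the anticodon sits at ``anticodon_start`` of the
    spliced body, so here we only enforce the mature-length invariants.
    """
    spliced = gene.spliced_body
    seq = spliced + "CCA"
    a = gene.anticodon_start
    if not (14 <= a < len(seq)):
        raise ReferenceError(
            f"{gene.gene_id}: anticodon_start {a} violates 14 <= start < L"
        )
    if a + 2 > len(seq) - 3:
        raise ReferenceError(f"{gene.gene_id}: anticodon overlaps the CCA tail")
    return MatureTRNA(gene_id=gene.gene_id, seq=seq, anticodon_span=(a, a + 2))


def build_precursor(gene: TRNAGeneRecord) -> PrecursorTRNA:
    """Concatenate leader | unspliced body | trailer."""
    if not gene.body_seq:
        raise ReferenceError(f"{gene.gene_id}: empty body")
    nl = len(gene.leader_seq)
    seq = gene.leader_seq + gene.body_seq + gene.trailer_seq
    return PrecursorTRNA(
        gene_id=gene.gene_id, seq=seq,
        body_span=(nl + 1, nl + len(gene.body_seq)),
    )


@dataclass
class ReferenceSet:
    """All genes of a study with their mature and precursor sequences."""

    genes: list[TRNAGeneRecord]
    matures: dict[str, MatureTRNA] = field(init=False)
    precursors: dict[str, PrecursorTRNA] = field(init=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ReferenceError("empty reference set")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ReferenceError("duplicate gene ids in reference set")
        self.matures = {g.gene_id: build_mature(g) for g in self.genes}
        self.precursors = {g.gene_id: build_precursor(g) for g in self.genes}

    def gene(self, gene_id: str) -> TRNAGeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# File interfaces: FASTA of bodies + TSV sidecar with the annotation fields.

SIDECAR_COLUMNS = ["gene_id", "anticodon", "anticodon_start",
                   "intron_start", "intron_end", "leader", "trailer"]


def read_reference(fasta_path: str | Path, sidecar_path: str | Path) -> ReferenceSet:
    """Load tRNA gene bodies (FASTA) plus their annotation sidecar (TSV)."""
    bodies = {rec.id: as_dna(str(rec.seq))
              for rec in SeqIO.parse(str(fasta_path), "fasta")}
    side = pd.read_csv(sidecar_path, sep="\t", dtype=str).fillna("")
    missing = set(SIDECAR_COLUMNS) - set(side.columns)
    if missing:
        raise ReferenceError(f"sidecar missing columns: {sorted(missing)}")
    genes = []
    for row in side.itertuples(index=False):
        gid = row.gene_id
        if gid not in bodies:
            raise ReferenceError(f"sidecar gene {gid} absent from FASTA")
        intron = None
        if str(row.intron_start).strip():
            intron = (int(row.intron_start), int(row.intron_end))
        genes.append(TRNAGeneRecord.from_parts(
            gene_id=gid, body_seq=bodies[gid],
            anticodon_start=int(row.anticodon_start), intron=intron,
            leader_seq=str(row.leader), trailer_seq=str(row.trailer),
        ))
    return ReferenceSet(genes=genes)


def write_reference(refs: ReferenceSet, fasta_path: str | Path,
                    sidecar_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for g in refs.genes:
            fh.write(f">{g.gene_id}\n{g.body_seq}\n")
    rows = []
    for g in refs.genes:
        i0, i1 = g.intron if g.intron else ("", "")
        rows.append((g.gene_id, g.anticodon, g.anticodon_start, i0, i1,
                     g.leader_seq, g.trailer_seq))
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(
        sidecar_path, sep="\t", index=False)


def write_fasta(seqs: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA (mature/precursor export)."""
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n{seq}\n")
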