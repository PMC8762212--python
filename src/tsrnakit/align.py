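"""Adapter trimming, fragment placement and tsRNA subtype classification.

Reads are trimmed of their 3' adapter, and the insert is placed on the
mature tRNA sequences first (0 mismatches beating 1), falling back to the
precursor sequences for reads that do not map — the two-pass scheme used in
tsRNA profiling.  Placed fragments are classified into the tsRNA subtype
taxonomy and named with the ``tRF-{start}:{end}-{AA}-{Anticodon}-{iso}[-Mn]``
grammar, where ``-Mn`` marks a fragment supported by n >= 2 isodecoder genes.

Subtype taxonomy (fragment length bands, mature coordinates 1-based):

* 5' fragments (start = 1): tRF-5a 14-16 nt, tRF-5b 17-24 nt, tRF-5c
  25-32 nt, tiRNA-5 33-40 nt.
* 3' fragments (end = mature length, CCA included): tRF-3a 14-20 nt,
  tRF-3b 21-30 nt, tiRNA-3 31-40 nt.
* precursor trailer fragments: tRF-1; anything else (internal fragments,
  leader-derived) is tRF-other.

The exhaustive ``<=1`` mismatch scan is intentionally simple and exact; it
is meant for tRNA-sized reference sets (hundreds of genes), not genomes.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import ReferenceSet, TRNAGeneRecord

MIN_FRAG, MAX_FRAG = 14, 40

SUBTYPES = ("tRF-5a", "tRF-5b", "tRF-5c", "tiRNA-5",
            "tRF-3a", "tRF-3b", "tiRNA-3", "tRF-1", "tRF-other")


class CoordinateError(ValueError):
    pass


class NamingError(ValueError):
    pass


class TsrnaIdError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Adapter trimming

def trim_adapter(read: str, adapter3: str) -> tuple[Optional[str], str]:
    """Return ``(insert, "ok")`` or ``(None, reason)``.

    The insert is the read prefix before the leftmost exact occurrence of
    the first ``min(8, len(adapter3))`` adapter bases.  Reads without an
    adapter hit, or whose insert falls outside the 14-40 nt fragment range,
    are rejected.
    """
    if len(adapter3) < 6:
        raise ConfigError("3' adapter must be at least 6 nt")
    key = adapter3[: min(8, len(adapter3))]
    pos = read.find(key)
    if pos < 0:
        return None, "no_adapter"
    if pos < MIN_FRAG or pos > MAX_FRAG:
        return None, "insert_length"
    return read[:pos], "ok"


# ---------------------------------------------------------------------------
# Alignment

@dataclass(frozen=True)
class FragmentAlignment:
    """Placement of an insert on one tRNA (1-based inclusive coordinates)."""

    gene_id: str
    start: int
    end: int
    mismatches: int
    source: str           # "mature" | "precursor"
    region: str = "body"  # "body" | "leader" | "trailer"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class FragmentAligner:
    """Exhaustive Hamming-distance placement on mature then precursor tRNAs.

    All best-tier hits are returned: 0-mismatch mature hits if any exist,
    else 1-mismatch mature, else 0- then 1-mismatch precursor hits, so
    multi-mapping across isodecoders is preserved for naming.
    """

    def __init__(self, refs: ReferenceSet):
        if len(refs) == 0:
            raise ConfigError("empty reference set")
        self.refs = refs
        self._mature = [(g.gene_id, _encode(refs.matures[g.gene_id].seq))
                        for g in refs.genes]
        self._precursor = [(g.gene_id, _encode(refs.precursors[g.gene_id].seq))
                           for g in refs.genes]

    def _scan(self, arrays: Sequence[tuple[str, np.ndarray]],
              insert: np.ndarray) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
        k = insert.size
        exact: list[tuple[str, int]] = []
        onemm: list[tuple[str, int]] = []
        for gene_id, ref in arrays:
            if ref.size < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, k)
            mm = (windows != insert).sum(axis=1)
            for off in np.flatnonzero(mm == 0):
                exact.append((gene_id, int(off)))
            for off in np.flatnonzero(mm == 1):
                onemm.append((gene_id, int(off)))
        return exact, onemm

    def _region(self, gene_id: str, start: int, end: int) -> str:
        b0, b1 = self.refs.precursors[gene_id].body_span
        if end < b0:
            return "leader"
        if start > b1:
            return "trailer"
        return "body"

    def align(self, insert: str) -> list[FragmentAlignment]:
        if not (MIN_FRAG <= len(insert) <= MAX_FRAG):
            raise CoordinateError(
                f"insert length {len(insert)} outside [{MIN_FRAG}, {MAX_FRAG}]")
        arr = _encode(insert)
        k = arr.size
        exact, onemm = self._scan(self._mature, arr)
        for hits, mm in ((exact, 0), (onemm, 1)):
            if hits:
                return [FragmentAlignment(g, off + 1, off + k, mm, "mature")
                        for g, off in hits]
        exact, onemm = self._scan(self._precursor, arr)
        for hits, mm in ((exact, 0), (onemm, 1)):
            if hits:
                return [FragmentAlignment(g, off + 1, off + k, mm, "precursor",
                                          self._region(g, off + 1, off + k))
                        for g, off in hits]
        return []


def align_fragment(insert: str, refs: ReferenceSet) -> list[FragmentAlignment]:
    """One-shot convenience wrapper around :class:`FragmentAligner`."""
    return FragmentAligner(refs).align(insert)


# ---------------------------------------------------------------------------
# Classification

def classify_subtype(start: int, end: int, mature_length: int,
                     source: str = "mature", region: str = "body") -> str:
    """Assign the tsRNA subtype from placement coordinates.

    ``mature_length`` is the CCA-included length of the mature tRNA the
    fragment was placed on (ignored for precursor placements).
    """
    if start < 1 or start > end:
        raise CoordinateError(f"bad interval {start}..{end}")
    length = end - start + 1
    if not (MIN_FRAG <= length <= MAX_FRAG):
        raise CoordinateError(f"fragment length {length} outside [{MIN_FRAG}, {MAX_FRAG}]")
    if source == "precursor":
        return "tRF-1" if region == "trailer" else "tRF-other"
    if source != "mature":
        raise CoordinateError(f"unknown source {source!r}")
    if end > mature_length:
        raise CoordinateError(f"end {end} beyond mature length {mature_length}")
    if start == 1:
        if length <= 16:
            return "tRF-5a"
        if length <= 24:
            return "tRF-5b"
        if length <= 32:
            return "tRF-5c"
        return "tiRNA-5"
    if end == mature_length:
        if length <= 20:
            return "tRF-3a"
        if length <= 30:
            return "tRF-3b"
        return "tiRNA-3"
    return "tRF-other"


# ---------------------------------------------------------------------------
# Naming

_ID_RE = re.compile(
    r"^(?P<prefix>tRF|tiRNA)-(?P<start>\d+):(?P<end>\d+)"
    r"-(?P<aa>[A-Za-z]{3})-(?P<anticodon>[ACGT]{3})-(?P<iso>\d+)"
    r"(?:-M(?P<n>\d+))?$"
)


def name_tsrna(alignments: Sequence[FragmentAlignment], subtype: str,
               refs: ReferenceSet) -> str:
    """Name a best-tier alignment set with the tsRNA ID grammar.

    The amino acid / anticodon / isodecoder come from the smallest
    supporting gene (ordered by amino acid, anticodon, isodecoder index);
    ``-M{n}`` is appended when n = number of distinct supporting genes >= 2.
    """
    if not alignments:
        raise NamingError("empty alignment set")
    coords = {(a.start, a.end) for a in alignments}
    if len(coords) != 1:
        raise NamingError(f"alignments disagree on coordinates: {sorted(coords)}")
    (start, end), = coords
    genes = sorted({a.gene_id for a in alignments},
                   key=lambda gid: refs.gene(gid).sort_key)
    lead = refs.gene(genes[0])
    prefix = "tiRNA" if subtype in ("tiRNA-5", "tiRNA-3") else "tRF"
    name = f"{prefix}-{start}:{end}-{lead.amino_acid}-{lead.anticodon}-{lead.isodecoder_index}"
    if len(genes) >= 2:
        name += f"-M{len(genes)}"
    return name


def parse_tsrna_id(tsrna_id: str) -> dict:
    """Parse a tsRNA ID back into its fields (length derived)."""
    m = _ID_RE.fullmatch(tsrna_id)
    if not m:
        # locate the first offending token for the error message
        pos = 0
        for token_re, what in (
            (r"(tRF|tiRNA)-", "prefix 'tRF-' or 'tiRNA-'"),
            (r"\d+:\d+-", "coordinates 'start:end-'"),
            (r"[A-Za-z]{3}-", "3-letter amino acid"),
            (r"[ACGT]{3}-", "3-nt anticodon"),
            (r"\d+", "isodecoder index"),
            (r"(-M[2-9]\d*)?$", "optional '-Mn' suffix"),
        ):
            t = re.match(token_re, tsrna_id[pos:])
            if not t:
                raise TsrnaIdError(
                    f"malformed tsRNA id {tsrna_id!r}: expected {what} "
                    f"at position {pos}")
            pos += t.end()
        raise TsrnaIdError(f"malformed tsRNA id {tsrna_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if end < start:
        raise TsrnaIdError(f"{tsrna_id!r}: end precedes start")
    return {
        "prefix": m["prefix"],
        "start": start,
        "end": end,
        "amino_acid": m["aa"],
        "anticodon": m["anticodon"],
        "isodecoder": int(m["iso"]),
        "n_genes": int(m["n"]) if m["n"] else 1,
        "length": end - start + 1,
    }


# ---------------------------------------------------------------------------
# Species calling and counting

@dataclass
class SpeciesCall:
    """A named tsRNA species as recovered from one insert sequence."""

    tsrna_id: str
    subtype: str
    seq: str
    start: int
    end: int
    source: str
    region: str
    supporting_genes: tuple[str, ...]


def call_species(insert: str, aligner: FragmentAligner) -> Optional[SpeciesCall]:
    """Map an insert to a single named species, or None if unplaced/ambiguous.

    Reads whose best-tier hits disagree on coordinates or span more than one
    anticodon family are discarded (conservative multi-mapping rule); hits
    across isodecoders of one family merge into one ``-Mn`` species.
    """
    hits = aligner.align(insert)
    if not hits:
        return None
    refs = aligner.refs
    if len({(h.start, h.end, h.source, h.region) for h in hits}) != 1:
        return None
    if len({refs.gene(h.gene_id).family for h in hits}) != 1:
        return None
    h0 = hits[0]
    if h0.source == "mature":
        L = refs.matures[h0.gene_id].length
    else:
        L = refs.precursors[h0.gene_id].length
    subtype = classify_subtype(h0.start, h0.end, L, h0.source, h0.region)
    name = name_tsrna(hits, subtype, refs)
    genes = tuple(sorted({h.gene_id for h in hits},
                         key=lambda gid: refs.gene(gid).sort_key))
    # canonical species sequence: the reference substring of the lead gene
    ref_seq = (refs.matures if h0.source == "mature" else refs.precursors)[genes[0]].seq
    return SpeciesCall(
        tsrna_id=name, subtype=subtype, seq=ref_seq[h0.start - 1 : h0.end],
        start=h0.start, end=h0.end, source=h0.source, region=h0.region,
        supporting_genes=genes,
    )


def read_fastq_seqs(path: str | Path) -> Iterable[str]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.sequence.upper()


@dataclass
class ProfileResult:
    """Named species table with per-sample counts plus a processing log."""

    counts: pd.DataFrame          # rows tsrna_id, columns samples
    species: pd.DataFrame         # tsrna_id, subtype, length, seq, genes
    log: dict = field(default_factory=dict)


def profile_fastqs(fastq_paths: Sequence[str | Path], sample_names: Sequence[str],
                   refs: ReferenceSet, adapter3: str) -> ProfileResult:
    """Trim, place, classify and count reads from one FASTQ per sample."""
    if len(fastq_paths) != len(sample_names):
        raise ConfigError("one sample name per FASTQ required")
    aligner = FragmentAligner(refs)
    insert_counts: list[Counter] = []
    log: dict = {"samples": {}}
    for path, name in zip(fastq_paths, sample_names):
        ctr: Counter = Counter()
        rejects = Counter()
        total = 0
        for seq in read_fastq_seqs(path):
            total += 1
            insert, reason = trim_adapter(seq, adapter3)
            if insert is None:
                rejects[reason] += 1
            else:
                ctr[insert] += 1
        insert_counts.append(ctr)
        log["samples"][name] = {"reads": total, "trimmed": sum(ctr.values()),
                                "rejected": dict(rejects)}
    unique_inserts = set().union(*insert_counts) if insert_counts else set()
    calls: dict[str, SpeciesCall] = {}
    unaligned = 0
    ambiguous = 0
    for ins in sorted(unique_inserts):  # sorted for determinism
        sp = call_species(ins, aligner)
        if sp is None:
            if aligner.align(ins):
                ambiguous += 1
            else:
                unaligned += 1
            continue
        calls[ins] = sp
    by_species: dict[str, SpeciesCall] = {}
    counts: dict[str, np.ndarray] = defaultdict(
        lambda: np.zeros(len(sample_names), dtype=np.int64))
    for s, ctr in enumerate(insert_counts):
        for ins, n in ctr.items():
            sp = calls.get(ins)
            if sp is None:
                continue
            counts[sp.tsrna_id][s] += n
            by_species.setdefault(sp.tsrna_id, sp)
    ids = sorted(counts)
    count_df = pd.DataFrame(
        [counts[i] for i in ids] if ids else None,
        index=pd.Index(ids, name="tsrna_id"),
        columns=list(sample_names), dtype=np.int64,
    )
    if not ids:
        count_df = pd.DataFrame(
            np.zeros((0, len(sample_names)), dtype=np.int64),
            index=pd.Index([], name="tsrna_id"), columns=list(sample_names))
    species_df = pd.DataFrame(
        [{"tsrna_id": i, "subtype": by_species[i].subtype,
          "length": by_species[i].end - by_species[i].start + 1,
          "seq": by_species[i].seq, "source": by_species[i].source,
          "supporting_genes": ",".join(by_species[i].supporting_genes)}
         for i in ids],
        columns=["tsrna_id", "subtype", "length", "seq", "source",
                 "supporting_genes"],
    ).set_index("tsrna_id")
    log["unique_inserts"] = len(unique_inserts)
    log["unaligned_inserts"] = unaligned
    log["ambiguous_inserts_discarded"] = ambiguous
    return ProfileResult(counts=count_df, species=species_df, log=log)


def aggregate_counts(calls_per_sample: Sequence[Sequence[Optional[SpeciesCall]]],
                     sample_names: Sequence[str]) -> pd.DataFrame:
    """Aggregate per-read species calls into a count table.

    Each read contributes once to its merged species; unmapped reads
    (``None``) are skipped.  Mostly useful for small in-memory tests — the
    FASTQ path uses :func:`profile_fastqs` which deduplicates inserts first.
    """
    counts: dict[str, np.ndarray] = defaultdict(
        lambda: np.zeros(len(sample_names), dtype=np.int64))
    for s, calls in enumerate(calls_per_sample):
        for sp in calls:
            if sp is not None:
                counts[sp.tsrna_id][s] += 1
    ids = sorted(counts)
    return pd.DataFrame(
        [counts[i] for i in ids],
        index=pd.Index(ids, name="tsrna_id"), columns=list(sample_names),
        dtype=np.int64,
    ) if ids else pd.DataFrame(
        np.zeros((0, len(sample_names)), dtype=np.int64),
        index=pd.Index([], name="tsrna_id"), columns=list(sample_names))
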