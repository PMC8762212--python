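"""Seed-based mRNA target prediction and hypergeometric set enrichment.

tsRNAs can act like miRNAs: the seed (nucleotides 2-7 from the 5' end)
pairs antisense with 3'-UTR sites.  Two independent predictors are run and
intersected to suppress false positives:

* a seed-match scanner typing canonical sites (6mer, 7mer-m8, 7mer-A1,
  8mer), and
* a wobble-tolerant local duplex alignment (Smith-Waterman style, G:U
  allowed, seed pairing weighted) thresholded on its score.

Enrichment of the predicted target set against GMT gene sets uses the
one-sided hypergeometric tail with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DUPLEX_THRESHOLD = 80.0


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_of(tsrna_seq: str) -> str:
    """Seed = positions 2-7 (1-based) of the tsRNA, 5'->3'."""
    if len(tsrna_seq) < 8:
        raise ValueError(f"tsRNA shorter than 8 nt has no seed: {tsrna_seq!r}")
    return tsrna_seq[1:7]


@dataclass(frozen=True)
class TargetSite:
    gene_id: str
    position: int       # 1-based start of the 6mer core in the UTR
    site_type: str      # 6mer | 7mer-A1 | 7mer-m8 | 8mer


def find_seed_sites(utr_seq: str, tsrna_seq: str,
                    gene_id: str = "") -> list[TargetSite]:
    """All canonical seed-complementary sites of a tsRNA in one 3'-UTR.

    The 6mer core is the reverse complement of the seed.  Reading the UTR
    5'->3', the base 5' of the core pairs tsRNA position 8 (m8) and the
    base 3' of the core sits opposite tsRNA position 1 (A1, requires an A
    regardless of pairing); both extensions give an 8mer.
    """
    utr = utr_seq.upper().replace("U", "T")
    core = revcomp(seed_of(tsrna_seq))
    m8_base = (tsrna_seq[7].translate(_COMPLEMENT)
               if len(tsrna_seq) >= 8 else None)
    sites = []
    pos = utr.find(core)
    while pos >= 0:
        has_m8 = pos > 0 and m8_base is not None and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        sites.append(TargetSite(gene_id=gene_id, position=pos + 1,
                                site_type=site_type))
        pos = utr.find(core, pos + 1)
    return sites


@dataclass(frozen=True)
class DuplexParams:
    """Scoring for the wobble-tolerant local duplex alignment."""

    match: float = 5.0        # Watson-Crick pair
    wobble: float = 1.0       # G:U (DNA alphabet: G-T)
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_weight: float = 2.0  # multiplier for tsRNA positions 2-8
    seed_span: tuple[int, int] = (2, 8)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _score_matrix(params: DuplexParams) -> np.ndarray:
    """4x4 pair-score lookup, rows = tsRNA base, cols = UTR base."""
    S = np.full((4, 4), params.mismatch)
    for a in range(4):
        S[a, 3 - a] = params.match  # A-T, C-G, G-C, T-A
    S[2, 3] = S[3, 2] = params.wobble  # G:U
    return S


def _index(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)


def duplex_score(tsrna_seq: str, utr_window: str,
                 params: DuplexParams | None = None) -> float:
    """Max local alignment score of the tsRNA paired antiparallel to a UTR
    window (affine gaps); pair scores at tsRNA positions 2-8 are weighted.

    Row-vectorized Smith-Waterman: the pair matrix M of row i depends only
    on row i-1, the tsRNA-gap matrix X is a running max along the row, and
    the window-gap matrix Y is elementwise over the previous row.
    """
    params = params or DuplexParams()
    if len(utr_window) > 40:
        raise ValueError("UTR window longer than 40 nt")
    ts = tsrna_seq.upper().replace("U", "T")
    # antiparallel duplex: walk the window 3'->5' so both strands advance 5'->3'
    win = utr_window.upper().replace("U", "T")[::-1]
    n, m = len(ts), len(win)
    if n == 0 or m == 0:
        return 0.0
    S = _score_matrix(params)
    ti, wi = _index(ts), _index(win)
    lo, hi = params.seed_span
    NEG = -1e18
    go, ge = params.gap_open, params.gap_extend
    M_prev = np.full(m + 1, NEG)
    X_prev = np.full(m + 1, NEG)
    Y_prev = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        w = params.seed_weight if lo <= i <= hi else 1.0
        s_row = w * S[ti[i - 1], wi]                       # scores vs every j
        prev = np.maximum.reduce([M_prev[:-1], X_prev[:-1], Y_prev[:-1],
                                  np.zeros(m)])
        M_cur = np.full(m + 1, NEG)
        M_cur[1:] = prev + s_row
        # X[i,j] = max_{j0<j} M[i,j0] + go + ge*(j-j0-1): running max scan
        j_idx = np.arange(m + 1, dtype=float)
        A = M_cur + go - ge * (j_idx + 1)
        X_cur = np.full(m + 1, NEG)
        X_cur[1:] = ge * j_idx[1:] + np.maximum.accumulate(A[:-1])
        Y_cur = np.full(m + 1, NEG)
        Y_cur[1:] = np.maximum(M_prev[1:] + go, Y_prev[1:] + ge)
        best = max(best, float(M_cur[1:].max()))
        M_prev, X_prev, Y_prev = M_cur, X_cur, Y_cur
    return float(best)


def duplex_predicted(tsrna_seq: str, utr_seq: str,
                     threshold: float = DUPLEX_THRESHOLD,
                     params: DuplexParams | None = None,
                     window: int = 40, step: int = 20) -> bool:
    """True if any UTR window reaches the duplex score threshold."""
    utr = utr_seq.upper().replace("U", "T")
    if len(utr) <= window:
        return duplex_score(tsrna_seq, utr, params) >= threshold
    starts = list(range(0, len(utr) - window + 1, step))
    if starts[-1] != len(utr) - window:
        starts.append(len(utr) - window)
    return any(duplex_score(tsrna_seq, utr[s : s + window], params) >= threshold
               for s in starts)


@dataclass
class TargetPrediction:
    tsrna_id: str
    seed: str
    seed_genes: set[str] = field(default_factory=set)
    duplex_genes: set[str] = field(default_factory=set)

    @property
    def targets(self) -> set[str]:
        """Consensus: only genes called by both algorithms are targets."""
        return self.seed_genes & self.duplex_genes


def predict_targets(tsrnas: Mapping[str, str], utr_db: Mapping[str, str],
                    threshold: float = DUPLEX_THRESHOLD,
                    params: DuplexParams | None = None) -> dict[str, TargetPrediction]:
    """Run both predictors for each tsRNA over a UTR database.

    ``tsrnas`` maps tsrna_id -> sequence, ``utr_db`` maps gene_id -> 3'-UTR.
    """
    out = {}
    for tsrna_id, seq in tsrnas.items():
        pred = TargetPrediction(tsrna_id=tsrna_id, seed=seed_of(seq))
        for gene_id, utr in utr_db.items():
            if find_seed_sites(utr, seq, gene_id):
                pred.seed_genes.add(gene_id)
            if duplex_predicted(seq, utr, threshold, params):
                pred.duplex_genes.add(gene_id)
        out[tsrna_id] = pred
    return out


# ---------------------------------------------------------------------------
# Enrichment

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def hypergeom_enrich(query_genes: Iterable[str],
                     gene_sets: Mapping[str, Iterable[str]],
                     universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query against gene sets.

    For each term with K of the N universe genes, and a query of n genes
    overlapping it in k, p = P(X >= k), X ~ Hypergeom(N, K, n); BH FDR
    across terms.  Rows are sorted by p-value.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(query_genes) & uni
    n = len(query)
    rows = []
    for term, genes in gene_sets.items():
        members = set(genes) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = 1.0 if (k == 0 or n == 0) else float(
            hypergeom.sf(k - 1, len(uni), K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": len(uni),
                     "pvalue": min(max(p, np.finfo(float).tiny), 1.0)})
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "pvalue"])
    if len(df):
        df["fdr"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df = df.sort_values(["pvalue", "term_id"]).reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df
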