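"""CPM normalization, expressed-set logic and NB differential expression.

The DE test is a simplified DESeq2-style analysis: median-of-ratios size
factors, per-species method-of-moments negative-binomial dispersion shrunk
toward a fitted mean-dispersion trend, a Wald statistic on the log2 fold
change of normalized group means (pseudocount 0.5), and Benjamini-Hochberg
adjustment.  The Wald statistic is referred to a t distribution with
n1+n2-2 degrees of freedom, which keeps the type-I error close to nominal
at the small group sizes typical of these studies.

Significance follows the screening rule |log2FC| > 1.5 with p < 0.05
(raw p by default; the adjusted p can be thresholded instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 1.5
ALPHA = 0.05
CPM_EXPRESSED = 20.0
_PSEUDO = 0.5


class NormalizationError(ValueError):
    pass


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million of each sample's total aligned tRNA reads."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"sample(s) with zero aligned reads: {', '.join(map(str, zero.index))}")
    return counts.div(totals, axis=1) * 1e6


def expressed_sets(cpm_df: pd.DataFrame, groups: list[str],
                   threshold: float = CPM_EXPRESSED) -> dict[str, set[str]]:
    """Venn partition of species expressed (group-mean CPM >= threshold).

    Returns ``{"common", "<g1>_only", "<g2>_only"}`` for the two group
    labels in order of first appearance.
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1, g2 = labels
    masks = {}
    for g in labels:
        cols = [c for c, lab in zip(cpm_df.columns, groups) if lab == g]
        masks[g] = cpm_df[cols].mean(axis=1) >= threshold
    s1 = set(cpm_df.index[masks[g1]])
    s2 = set(cpm_df.index[masks[g2]])
    return {"common": s1 & s2, f"{g1}_only": s1 - s2, f"{g2}_only": s2 - s1}


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Species with a zero count in any sample drop out of the geometric mean
    (their log ratio is undefined); if no species is positive everywhere,
    library-size ratios are used instead with a warning.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        keep = arr[positive]
        gm = np.exp(np.log(keep).mean(axis=1, keepdims=True))
        factors = np.median(keep / gm, axis=0)
    else:
        warnings.warn("no species with nonzero counts in every sample; "
                      "falling back to library-size ratios")
        lib = arr.sum(axis=0)
        if (lib <= 0).any():
            raise NormalizationError("sample with zero total counts")
        factors = lib / np.exp(np.log(lib).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _trend_dispersion(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit dispersion ~ a/mean + b (gamma-family style parametric trend)."""
    ok = (mean > 0) & (disp > 0)
    if ok.sum() < 3:
        fallback = float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01
        return np.full_like(mean, max(fallback, 1e-8))
    X = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    a, b = max(coef[0], 0.0), max(coef[1], 1e-8)
    return np.clip(a / np.maximum(mean, 1e-8) + b, 1e-8, 10.0)


def de_test(counts: pd.DataFrame, groups: list[str],
            lfc_threshold: float = LFC_THRESHOLD, alpha: float = ALPHA,
            use_adjusted: bool = False) -> pd.DataFrame:
    """Per-species NB Wald test of group 2 vs group 1 (e.g. Cd vs Ctrl).

    Returns a frame with baseMean, log2FC, lfcSE, pvalue, padj and the
    Up/Down/NS regulation call under the screening thresholds.  All-zero
    species are excluded from testing and reported NS with p = 1.
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1, g2 = labels
    i1 = [i for i, g in enumerate(groups) if g == g1]
    i2 = [i for i, g in enumerate(groups) if g == g2]
    n1, n2 = len(i1), len(i2)
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(counts).to_numpy()
    q = counts.to_numpy(dtype=float) / sf  # normalized counts
    q1, q2 = q[:, i1], q[:, i2]
    m1, m2 = q1.mean(axis=1), q2.mean(axis=1)
    base_mean = q.mean(axis=1)
    tested = base_mean > 0

    # method-of-moments dispersion from pooled within-group variance
    v_within = (q1.var(axis=1, ddof=1) * (n1 - 1)
                + q2.var(axis=1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
    mu_pool = (m1 * n1 + m2 * n2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_disp = (v_within - mu_pool) / mu_pool**2
    raw_disp = np.where(np.isfinite(raw_disp), raw_disp, 0.0).clip(0.0, 10.0)
    trend = _trend_dispersion(mu_pool[tested], raw_disp[tested]) \
        if tested.any() else np.array([])
    disp = np.zeros_like(raw_disp)
    if tested.any():
        # shrink the noisy per-species estimate toward the trend
        w = (n1 + n2 - 2) / (n1 + n2 - 2 + 2.0)
        disp[tested] = w * raw_disp[tested] + (1 - w) * trend

    log2fc = np.log2((m2 + _PSEUDO) / (m1 + _PSEUDO))
    var_m1 = (m1 + disp * m1**2) / n1
    var_m2 = (m2 + disp * m2**2) / n2
    se = np.sqrt(var_m1 / (m1 + _PSEUDO) ** 2
                 + var_m2 / (m2 + _PSEUDO) ** 2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    df = n1 + n2 - 2
    pvalue = np.where(tested, 2 * stats.t.sf(np.abs(wald), df=df), 1.0)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)

    padj = np.ones_like(pvalue)
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]

    out = pd.DataFrame({
        "baseMean": base_mean,
        "log2FC": np.where(tested, log2fc, 0.0),
        "lfcSE": np.where(tested, se, np.nan),
        "pvalue": pvalue,
        "padj": padj,
        "tested": tested,
    }, index=counts.index)
    out["regulation"] = _regulation_calls(out, lfc_threshold, alpha, use_adjusted)
    return out


def _regulation_calls(results: pd.DataFrame, lfc_threshold: float,
                      alpha: float, use_adjusted: bool) -> pd.Series:
    p = results["padj"] if use_adjusted else results["pvalue"]
    sig = (results["log2FC"].abs() > lfc_threshold) & (p < alpha)
    if "tested" in results:
        sig &= results["tested"]
    calls = np.where(sig & (results["log2FC"] > 0), "Up",
                     np.where(sig, "Down", "NS"))
    return pd.Series(calls, index=results.index, name="regulation")


def apply_thresholds(results: pd.DataFrame, lfc_threshold: float = LFC_THRESHOLD,
                     alpha: float = ALPHA, use_adjusted: bool = False) -> pd.DataFrame:
    """Filter to significant species: |log2FC| > threshold and p < alpha
    (both strict), regulation assigned by the sign of the fold change."""
    res = results.copy()
    res["regulation"] = _regulation_calls(res, lfc_threshold, alpha, use_adjusted)
    return res[res["regulation"] != "NS"]


@dataclass(frozen=True)
class DDCtInput:
    """Ct values for the 2^-ddCt relative-expression calculation."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float


def ddct(inp: DDCtInput) -> float:
    """Relative expression by 2^-ddCt against a reference gene (e.g. RNU6)."""
    vals = [inp.ct_target_treated, inp.ct_reference_treated,
            inp.ct_target_control, inp.ct_reference_control]
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    d_treated = inp.ct_target_treated - inp.ct_reference_treated
    d_control = inp.ct_target_control - inp.ct_reference_control
    return float(2.0 ** (-(d_treated - d_control)))
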