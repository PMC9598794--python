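"""Class-wise differential expression on negative-binomial counts.

The model is deliberately lean: median-of-ratios size factors, a
method-of-moments negative-binomial dispersion per feature (variance
mu + alpha * mu^2, floored), and a Wald test on the moderated log2 fold
change of normalized group means with a delta-method standard error.
P-values are Benjamini-Hochberg adjusted within each RNA class.  There is no
dispersion shrinkage or outlier handling, so individual statistics will not
match a full GLM fit; the screening thresholds (FDR < 0.05, |log2FC| > 1 for
mRNA, FDR alone for ncRNA) are the contract.

Also here: the FPKM computation and the two screening filters applied before
downstream stages (the lncRNA candidate filter and the row-sum filter used
before co-expression analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    CountMatrix,
    DEResult,
    FeatureAnnotation,
    NormalizedMatrix,
)
from .errors import ValidationError

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5

#: Per-class significance gates: (padj threshold, |log2fc| threshold or None).
DEFAULT_THRESHOLDS: dict[str, tuple[float, float | None]] = {
    "mRNA": (0.05, 1.0),
    "lncRNA": (0.05, None),
    "miRNA": (0.05, None),
}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(cm: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples, computed
    over features with no zero count.  If no such feature exists, pass
    ``pseudo_reference=True`` to take geometric means over positive counts
    only (the "poscounts" fallback).
    """
    counts = cm.values.to_numpy(dtype=float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=cm.values.columns, name="size_factor")
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any() and not pseudo_reference:
        sub = counts[all_positive]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / ref[:, None]
    else:
        if not pseudo_reference:
            raise ValidationError(
                "no feature has positive counts in every sample; "
                "retry with pseudo_reference=True"
            )
        any_positive = (counts > 0).any(axis=1)
        sub = counts[any_positive]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / ref[:, None], np.nan)
    with np.errstate(invalid="ignore"):
        sf = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValidationError("degenerate size factors; check the count matrix")
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=cm.values.columns, name="size_factor")


def normalize_counts(cm: CountMatrix, **kw) -> NormalizedMatrix:
    sf = size_factors(cm, **kw)
    return NormalizedMatrix(cm.values / sf, sf, transform="none")


def vst_proxy(cm: CountMatrix, **kw) -> NormalizedMatrix:
    """Variance-stabilizing proxy: log2(count / size_factor + 1).

    A stand-in for a fitted mean-variance transform; tagged ``vst-proxy`` so
    downstream provenance is explicit.
    """
    sf = size_factors(cm, **kw)
    vals = np.log2(cm.values / sf + 1.0)
    return NormalizedMatrix(vals, sf, transform="vst-proxy")


def fpkm(cm: CountMatrix, ann: FeatureAnnotation) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``count * 1e9 / (length_bp * column_total)`` per feature and sample.
    """
    missing = [f for f in cm.feature_ids if f not in ann.table.index]
    if missing:
        raise ValidationError(f"features missing from annotation: {missing[:10]}")
    lengths = ann.table.loc[cm.feature_ids, "length"].to_numpy(dtype=float)
    totals = cm.values.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = [s for s, t in zip(cm.sample_ids, totals) if t == 0]
        raise ValidationError(f"zero column total for samples {bad}")
    vals = cm.values.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * totals[None, :])
    return pd.DataFrame(vals, index=cm.values.index, columns=cm.values.columns)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# the Wald test
# ---------------------------------------------------------------------------

def nb_wald_test(
    cm: CountMatrix,
    fdr: float | None = None,
    lfc_threshold: float | None = None,
    use_lfc_gate: bool | None = None,
) -> list[DEResult]:
    """Two-group negative-binomial Wald test per feature.

    Counts are normalized by median-of-ratios size factors; the log2 fold
    change is high over low on group means with pseudocount 0.5.  The NB
    dispersion is estimated per feature by pooled method of moments with a
    floor of 1e-8; the Wald statistic uses the delta-method SE of the log2
    mean difference.  BH adjustment is applied across the features given
    (i.e. within the RNA class).  Calls use the class default thresholds
    unless overridden: ``padj < fdr`` and, when the class uses the fold-change
    gate, ``|log2fc| > lfc_threshold``.
    """
    high = cm.samples_in_group("high")
    low = cm.samples_in_group("low")
    if len(high) < 2 or len(low) < 2:
        raise ValidationError(
            f"need >=2 samples per group (high={len(high)}, low={len(low)})"
        )
    cls_fdr, cls_lfc = DEFAULT_THRESHOLDS[cm.rna_class]
    if fdr is None:
        fdr = cls_fdr
    if use_lfc_gate is None:
        use_lfc_gate = cls_lfc is not None
    if lfc_threshold is None:
        lfc_threshold = cls_lfc if cls_lfc is not None else 1.0

    norm = normalize_counts(cm).values
    xh = norm[high].to_numpy(dtype=float)
    xl = norm[low].to_numpy(dtype=float)
    nh, nl = xh.shape[1], xl.shape[1]

    mh, ml = xh.mean(axis=1), xl.mean(axis=1)
    vh = xh.var(axis=1, ddof=1)
    vl = xl.var(axis=1, ddof=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # pooled method-of-moments NB dispersion: var = mu + alpha mu^2
    num = (nh - 1) * (vh - mh) + (nl - 1) * (vl - ml)
    den = (nh - 1) * mh**2 + (nl - 1) * ml**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    mh_p = mh + PSEUDOCOUNT
    ml_p = ml + PSEUDOCOUNT
    log2fc = np.log2(mh_p / ml_p)

    # delta method on log2 of a group mean of NB draws
    ln2sq = np.log(2.0) ** 2
    var_log2 = (1.0 / mh_p + alpha) / (nh * ln2sq) + (1.0 / ml_p + alpha) / (nl * ln2sq)
    se = np.sqrt(var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    padj = bh_adjust(p)

    results = []
    for i, fid in enumerate(cm.feature_ids):
        call = "ns"
        if padj[i] < fdr and log2fc[i] != 0.0:
            if not use_lfc_gate or abs(log2fc[i]) > lfc_threshold:
                call = "up" if log2fc[i] > 0 else "down"
        results.append(
            DEResult(fid, cm.rna_class, float(base_mean[i]), float(log2fc[i]),
                     float(p[i]), float(padj[i]), call)
        )
    return results


# ---------------------------------------------------------------------------
# screening filters
# ---------------------------------------------------------------------------

def coverage_proxy(cm: CountMatrix, ann: FeatureAnnotation,
                   read_length: int = 150) -> pd.DataFrame:
    """Approximate per-sample read coverage: count * read_length / length."""
    lengths = ann.table.loc[cm.feature_ids, "length"].to_numpy(dtype=float)
    vals = cm.values.to_numpy(dtype=float) * read_length / lengths[:, None]
    return pd.DataFrame(vals, index=cm.values.index, columns=cm.values.columns)


def lncrna_candidate_filter(
    ann: FeatureAnnotation,
    fpkm_table: pd.DataFrame,
    coverage_table: pd.DataFrame,
    min_length: int = 200,
    min_exons: int = 2,
    fpkm_floor: float = 0.5,
    min_coverage: float = 3.0,
) -> set[str]:
    """lncRNA candidate screen.

    Retain a feature iff transcript length >= 200 AND exon count >= 2 AND
    best-sample FPKM > 0.5 (strict) AND best-sample coverage >= 3.
    """
    ids = list(fpkm_table.index)
    missing = [f for f in ids if f not in ann.table.index] + [
        f for f in ids if f not in coverage_table.index
    ]
    if missing:
        raise ValidationError(f"features missing from inputs: {sorted(set(missing))[:10]}")
    sub = ann.table.loc[ids]
    ok = (
        (sub["length"] >= min_length)
        & (sub["exon_count"] >= min_exons)
        & (fpkm_table.loc[ids].max(axis=1) > fpkm_floor)
        & (coverage_table.loc[ids].max(axis=1) >= min_coverage)
    )
    return set(sub.index[ok])


def sum_count_filter(cm: CountMatrix, min_sum: int = 10) -> set[str]:
    """Retain features whose total count across samples exceeds ``min_sum``
    (strict, so a row summing to exactly ``min_sum`` is dropped)."""
    sums = cm.values.sum(axis=1)
    return set(sums.index[sums > min_sum])
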