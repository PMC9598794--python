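"""Small-sample validation statistics.

Relative qPCR quantification by the 2^-ddCt rule (reference-gene
normalization, calibrator = mean control dCt, amplification efficiency fixed
at 2), two-group t-tests with the usual significance stars, and Table-style
phenotype summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import SampleTable
from .errors import ValidationError


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    condition: str  # "treatment" | "control"
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if self.condition not in ("treatment", "control"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        for name, ct in (("ct_target", self.ct_target),
                         ("ct_reference", self.ct_reference)):
            if not 0 < ct < 45:
                raise ValidationError(f"{name}={ct} outside (0, 45)")


@dataclass(frozen=True)
class GroupComparison:
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n_x: int
    n_y: int
    t: float
    df: float
    p: float
    stars: str


def stars_for(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ddct_relative_expression(records: list[QpcrRecord]) -> pd.Series:
    """Per-sample relative expression 2^-ddCt.

    dCt = Ct_target - Ct_reference; ddCt subtracts the mean control dCt, so
    the geometric mean of control folds is 1 by construction.
    """
    controls = [r for r in records if r.condition == "control"]
    if not controls:
        raise ValidationError("at least one control sample is required")
    dct = {r.sample_id: r.ct_target - r.ct_reference for r in records}
    calibrator = float(np.mean([dct[r.sample_id] for r in controls]))
    folds = {sid: 2.0 ** -(d - calibrator) for sid, d in dct.items()}
    return pd.Series(folds, name="fold_change")


def two_group_t(x, y, variant: str = "student") -> GroupComparison:
    """Two-sided two-sample t-test (pooled Student by default, Welch on
    request) with significance stars."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need >= 2 observations per group")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            t, df, p = 0.0, float(x.size + y.size - 2), 1.0
        else:
            raise ValidationError("zero variance with unequal means; t undefined")
    elif variant == "student":
        res = sps.ttest_ind(x, y, equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(x.size + y.size - 2)
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        float(x.mean()), float(y.mean()),
        float(x.std(ddof=1)), float(y.std(ddof=1)),
        int(x.size), int(y.size), t, df, p, stars_for(p),
    )


def summarize_phenotypes(table: SampleTable, traits: list[str]) -> pd.DataFrame:
    """Per-trait (n, max, min, mean, SD) summary rows; sample (n-1) SD.

    A single observation gets SD 0 and a ``degenerate`` flag.
    """
    rows = []
    for trait in traits:
        if trait not in table.table.columns:
            raise ValidationError(f"missing trait column {trait!r}")
        vals = pd.to_numeric(table.table[trait], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"non-numeric values in trait {trait!r}")
        v = vals.to_numpy(dtype=float)
        degenerate = v.size < 2
        sd = 0.0 if degenerate else float(v.std(ddof=1))
        rows.append((trait, v.size, float(v.max()), float(v.min()),
                     float(v.mean()), sd, degenerate))
    return pd.DataFrame(
        rows, columns=["trait", "n", "max", "min", "mean", "sd", "degenerate"]
    ).set_index("trait")
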