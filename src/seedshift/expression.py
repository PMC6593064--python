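"""qPCR relative expression (2^-dCt) and downstream group comparisons.

Relative expression is the comparative-Ct quantity 2^-(Ct_target -
Ct_reference) per sample (reference = a housekeeping assay such as GAPDH),
log10-transformed for all statistics.  Group contrasts use Welch's t-test
(two groups; Student's available by flag) or one-way ANOVA (k groups);
transcript-vs-miRNA relationships use ordinary least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_RANGE = (0.0, 45.0)

CT_COLUMNS = ["sample_id", "group", "cell_type", "genotype", "gene",
              "ct_target", "ct_reference"]


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionValue:
    rel_expr: float
    log10_expr: float


@dataclass(frozen=True)
class GroupComparison:
    design: str                 # "two-group" or "k-group"
    statistic: float            # t or F
    p: float
    groups: dict                # label -> {"n": ..., "mean": ..., "se": ...}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def _check_ct(ct: float, name: str) -> None:
    if not (CT_RANGE[0] < ct <= CT_RANGE[1]):
        raise ExpressionError(f"{name}={ct} outside valid Ct range (0, 45]")


def relative_expression(ct_target: float, ct_reference: float) -> ExpressionValue:
    """2^-(Ct_target - Ct_reference) and its log10."""
    _check_ct(ct_target, "ct_target")
    _check_ct(ct_reference, "ct_reference")
    dct = ct_target - ct_reference
    rel = 2.0 ** (-dct)
    return ExpressionValue(rel, math.log10(rel))


def process_ct_table(records: pd.DataFrame) -> pd.DataFrame:
    """Tidy expression table from CtRecord rows: adds rel_expr / log10_expr."""
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ExpressionError(f"Ct table missing columns {sorted(missing)}")
    ct_t = records["ct_target"].to_numpy(dtype=float)
    ct_r = records["ct_reference"].to_numpy(dtype=float)
    for arr, name in ((ct_t, "ct_target"), (ct_r, "ct_reference")):
        if np.any(~((arr > CT_RANGE[0]) & (arr <= CT_RANGE[1]))):
            raise ExpressionError(f"{name} values outside (0, 45]")
    out = records.copy()
    dct = ct_t - ct_r
    out["rel_expr"] = 2.0 ** (-dct)
    out["log10_expr"] = np.log10(out["rel_expr"].to_numpy())
    return out


def group_compare(values_by_label: dict, welch: bool = True) -> GroupComparison:
    """t-test (2 groups) or one-way ANOVA (k groups) on log10 expression.

    Groups with fewer than 2 values are excluded with a warning.  Welch's
    unequal-variance t-test is the default two-group test.
    """
    usable = {}
    for label, vals in values_by_label.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            warnings.warn(f"group {label!r} has fewer than 2 values; excluded")
            continue
        usable[label] = v
    if len(usable) < 2:
        raise ExpressionError("need at least two groups with >= 2 values each")
    summaries = {lab: {"n": int(v.size), "mean": float(v.mean()),
                       "se": float(v.std(ddof=1) / math.sqrt(v.size))}
                 for lab, v in usable.items()}
    arrays = list(usable.values())
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
        return GroupComparison("two-group", float(t), float(p), summaries)
    f, p = stats.f_oneway(*arrays)
    return GroupComparison("k-group", float(f), float(p), summaries)


def linear_regression(x, y) -> RegressionResult:
    """Simple OLS of y on x with the two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ExpressionError("x and y must have equal length")
    if x.size < 3:
        raise ExpressionError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ExpressionError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue) ** 2, float(res.pvalue), int(x.size))
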