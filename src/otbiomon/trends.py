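"""Paired temporal comparisons and rank-correlation analyses for site-level
biomonitoring indices.

Two paired tests are provided: a paired-samples t test on log10-transformed
values (for positive, roughly log-normal indices) and a Wilcoxon
signed-rank test in the classical dialect — zero differences dropped,
midranks on tied |d|, tie-corrected normal variance, no continuity
correction. Spearman rank correlations are corrected for multiplicity with
the Holm step-down (sequential Bonferroni) procedure, applied one
correlation family at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import ValidationError


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    method: str
    df: Optional[int] = None


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def paired_t_log10(x, y) -> PairedTestResult:
    """Paired t test on d_i = log10(y_i) − log10(x_i), two-sided.

    Positive t means y (the later epoch, by convention) is higher. Pairs
    with a missing member are dropped first; all values must be positive.
    """
    x, y = _paired(x, y)
    if len(x) < 2:
        raise ValidationError("paired t needs at least 2 complete pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("log10 transform requires positive values")
    d = np.log10(y) - np.log10(x)
    if d.std(ddof=1) == 0:
        raise ValidationError("degenerate: zero variance of paired differences")
    res = stats.ttest_rel(np.log10(y), np.log10(x))
    return PairedTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_pairs=len(x), method="paired_t_log10", df=int(len(x) - 1),
    )


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Wilcoxon signed-rank with normal approximation, two-sided.

    Dialect: zero differences dropped; midranks on |d|; W+ compared with
    its null mean n(n+1)/4; variance n(n+1)(2n+1)/24 − Σ(t³−t)/48 over tie
    groups; no continuity correction. Positive Z means y tends to exceed x.
    """
    x, y = _paired(x, y)
    d = y - x
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValidationError("degenerate: all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        raise ValidationError("degenerate: zero variance (all |d| tied at one value)")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedTestResult(
        statistic=float(z), p_value=float(p), n_pairs=n,
        method="wilcoxon_signed_rank",
    )


def spearman(x, y) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided t-approximation p (n − 2 df)."""
    x, y = _paired(x, y)
    if len(x) < 4:
        raise ValidationError("Spearman needs at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("Spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def holm_adjust(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Holm step-down significance flags at family-wise level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def correlation_matrix(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Spearman correlations of the table's columns, with
    Holm flags computed over this family of tests.

    Rows with a missing member are dropped pair by pair; pairs with fewer
    than 4 complete cases are skipped with rho = NaN and no flag.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValidationError("need at least two variables")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            x, y = _paired(table[a], table[b])
            if len(x) < 4:
                rows.append({"var_a": a, "var_b": b, "n": len(x),
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = spearman(x, y)
            rows.append({"var_a": a, "var_b": b, "n": len(x), "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["significant"] = False
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "significant"] = holm_adjust(out.loc[tested, "p"].to_numpy(), alpha)
    return out


#: The standard epoch-comparison plan for the survey index table:
#: (variable, earlier epoch, later epoch, test). The Wilcoxon test is used
#: where an index takes tied or boundary values (stage means across many
#: sites, percentages); the log10 paired t where values are positive and
#: heavy-tailed (RPSI) or the change is near-multiplicative.
EPOCH_COMPARISONS = (
    ("mean_vdsi", "2004-06", "2010", "wilcoxon"),
    ("mean_vdsi", "2010", "2015", "t_log10"),
    ("rpsi", "2004-06", "2010", "t_log10"),
    ("rpsi", "2010", "2015", "t_log10"),
    ("pct_sterile", "2004-06", "2010", "wilcoxon"),
    ("pct_sterile", "2010", "2015", "wilcoxon"),
)


def epoch_trend_tests(
    tidy: pd.DataFrame,
    comparisons: Sequence[tuple[str, str, str, str]] = EPOCH_COMPARISONS,
) -> pd.DataFrame:
    """Run the paired epoch comparisons on a tidy (site_id, epoch) table.

    Sites missing either epoch of a pair are excluded by the join.
    Returns one row per comparison: variable, epochs, method, statistic,
    df (t only), n_pairs, p_value.
    """
    rows = []
    for variable, epoch_x, epoch_y, method in comparisons:
        a = tidy[tidy["epoch"] == epoch_x].set_index("site_id")[variable]
        b = tidy[tidy["epoch"] == epoch_y].set_index("site_id")[variable]
        joined = pd.concat({"x": a, "y": b}, axis=1).dropna()
        if method == "t_log10":
            res = paired_t_log10(joined["x"], joined["y"])
        elif method == "wilcoxon":
            res = wilcoxon_signed_rank(joined["x"], joined["y"])
        else:
            raise ValidationError(f"unknown method {method!r}")
        rows.append({
            "variable": variable, "epoch_x": epoch_x, "epoch_y": epoch_y,
            "method": res.method, "statistic": res.statistic, "df": res.df,
            "n_pairs": res.n_pairs, "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


def distance_correlations(tidy: pd.DataFrame, epoch: str, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlations of distance-to-shipping against each index for
    one epoch, Holm-corrected as one family."""
    sub = tidy[tidy["epoch"] == epoch]
    rows = []
    for variable in ("mean_vdsi", "median_vdsi", "pct_sterile", "rpsi", "condition_index"):
        x, y = _paired(sub["distance_km"], sub[variable])
        if len(x) < 4 or np.all(y == y[0]):
            rows.append({"variable": variable, "n": len(x), "rho": np.nan, "p": np.nan})
            continue
        rho, p = spearman(x, y)
        rows.append({"variable": variable, "n": len(x), "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["significant"] = False
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "significant"] = holm_adjust(out.loc[tested, "p"].to_numpy(), alpha)
    return out
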