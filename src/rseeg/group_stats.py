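"""Between-group inference: Welch's t, Hedges' g, BH-FDR, correlations.

Uncorrected two-tailed tests at alpha = 0.05 are the primary flags, with
Benjamini-Hochberg FDR flags reported alongside (applied within a measure
across its channels/pairs).  Effect sizes use Hedges' g (pooled SD with
the small-sample correction J = 1 - 3/(4(n1+n2-2)-1)).  Correlation
confidence intervals use the Fisher z transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns ``(t, df, p)``; p is two-tailed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def hedges_g(a, b) -> float:
    """Small-sample-corrected standardized mean difference (a minus b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("degenerate (zero) pooled variance")
    j = 1.0 - 3.0 / (4.0 * (na + nb - 2) - 1.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(sp2))


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags (order-independent)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def pearson_corr_ci(x, y, confidence: float = 0.95):
    """Pearson r with two-tailed p and a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(res.pvalue), float(ci.low), float(ci.high)


@dataclass
class GroupComparison:
    measure: str
    unit: str
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    g: float
    significant: bool
    fdr_significant: bool


def compare_groups(
    values: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    measure: str = "measure",
    alpha: float = 0.05,
    fdr: bool = True,
    skip_degenerate: bool = False,
):
    """Per-unit Welch tests between two groups of subjects.

    ``values``: subjects x units (channels or channel pairs), indexed by
    subject; ``groups`` maps the same index to group labels.  Returns
    ``(comparisons, summary)`` where ``comparisons`` is a tidy DataFrame
    (one row per unit, contrast group_a minus group_b) and ``summary``
    reports the unit with the smallest p together with its statistics.
    """
    ga = values.loc[groups == group_a]
    gb = values.loc[groups == group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = []
    for unit in values.columns:
        try:
            t, df, p = welch_ttest(ga[unit], gb[unit])
            g = hedges_g(ga[unit], gb[unit])
        except ValueError:
            if skip_degenerate:
                continue
            raise
        rows.append(
            GroupComparison(
                measure=measure, unit=str(unit), group_a=group_a,
                group_b=group_b, t=t, df=df, p=p, g=g,
                significant=p < alpha, fdr_significant=False,
            )
        )
    if not rows:
        return pd.DataFrame(), {
            "measure": measure, "contrast": f"{group_a}-{group_b}",
            "best_unit": None, "g": float("nan"), "t": float("nan"),
            "df": float("nan"), "p": float("nan"),
            "n_significant": 0, "n_fdr_significant": 0,
        }
    if fdr:
        flags = bh_fdr([r.p for r in rows], alpha=alpha)
        for r, f in zip(rows, flags):
            r.fdr_significant = bool(f)
    table = pd.DataFrame([vars(r) for r in rows])
    best = table.loc[table["p"].idxmin()]
    summary = {
        "measure": measure,
        "contrast": f"{group_a}-{group_b}",
        "best_unit": best["unit"],
        "g": float(best["g"]),
        "t": float(best["t"]),
        "df": float(best["df"]),
        "p": float(best["p"]),
        "n_significant": int(table["significant"].sum()),
        "n_fdr_significant": int(table["fdr_significant"].sum()),
    }
    return table, summary
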