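"""Survey-weighted prevalence tables and area-measure correlations.

Prevalences are weighted row percentages: within each level of a grouping
variable, the weighted share of records with the outcome.  The standard
error uses the Taylor-linearized weighted-proportion formula

    SE(p) = sqrt( sum_i w_i^2 (y_i - p)^2 ) / sum_i w_i

with an optional cluster-robust variant that first sums the linearized
scores within FSAs.  With equal weights the estimator reduces exactly to
the unweighted proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["weighted_prevalence", "fsa_outcome_correlations"]


def _weighted_prop(y: np.ndarray, w: np.ndarray, cluster: np.ndarray | None = None):
    sw = w.sum()
    p = float((w * y).sum() / sw)
    resid = w * (y - p)
    if cluster is None:
        var = float((resid**2).sum()) / sw**2
    else:
        totals = pd.Series(resid).groupby(pd.Series(cluster).to_numpy()).sum().to_numpy()
        var = float((totals**2).sum()) / sw**2
    return p, float(np.sqrt(var))


def weighted_prevalence(
    records: pd.DataFrame,
    outcome: str,
    by: str | None = None,
    *,
    stratum: str = "total",
    weight_col: str = "weight",
    cluster_col: str | None = None,
) -> pd.DataFrame:
    """Weighted prevalence (in %) of a binary outcome, optionally by group.

    Parameters
    ----------
    records
        Analytic table; must carry the outcome (boolean/0-1), the weights,
        and the grouping / sex columns as needed.
    outcome
        Name of the binary outcome column; missing outcomes are excluded.
    by
        Grouping column (one prevalence row per level); None for overall.
    stratum
        ``"total"`` or a sex level (``"women"`` / ``"men"``) to restrict to.
    cluster_col
        If given, use the FSA-cluster-robust variance instead of the
        independent-records linearization.

    Returns
    -------
    DataFrame with columns outcome, stratum, grouping, level, weighted_pct,
    se_pct, unweighted_n, and an ``empty`` flag for levels with no usable
    records (emitted, never silently dropped).
    """
    df = records
    if stratum != "total":
        sex_level = {"women": "woman", "men": "man"}.get(stratum, stratum)
        df = df[df["sex"] == sex_level]
    y_all = df[outcome]
    usable = y_all.notna()
    if (df[weight_col].to_numpy(dtype=float) <= 0).any():
        raise ValueError("weights must be positive")

    if by is None:
        groups = [("overall", df[usable])]
    else:
        col = df[by]
        levels = list(col.dtype.categories) if isinstance(col.dtype, pd.CategoricalDtype) \
            else sorted(col.dropna().unique(), key=str)
        groups = [(lev, df[usable & (col == lev)]) for lev in levels]

    rows = []
    for level, sub in groups:
        row = {
            "outcome": outcome,
            "stratum": stratum,
            "grouping": by or "overall",
            "level": str(level),
            "unweighted_n": int(len(sub)),
            "empty": len(sub) == 0,
        }
        if len(sub):
            y = sub[outcome].astype(float).to_numpy()
            w = sub[weight_col].to_numpy(dtype=float)
            cl = sub[cluster_col].to_numpy() if cluster_col else None
            p, se = _weighted_prop(y, w, cl)
            row["weighted_pct"] = 100.0 * p
            row["se_pct"] = 100.0 * se
        else:
            row["weighted_pct"] = np.nan
            row["se_pct"] = np.nan
        rows.append(row)
    cols = ["outcome", "stratum", "grouping", "level",
            "weighted_pct", "se_pct", "unweighted_n", "empty"]
    return pd.DataFrame(rows)[cols]


def fsa_outcome_correlations(
    records: pd.DataFrame,
    measures: list[str],
    outcomes: list[str],
    *,
    exclude: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Spearman correlations between FSA measures and binary outcomes.

    Computed at the individual level: each record carries its FSA's measure
    value.  ``exclude`` maps an outcome to measures omitted for it (the
    % living alone measure is definitionally entangled with the isolation
    index and is excluded for that outcome upstream).  Constant measures
    yield an undefined correlation, reported as NaN with a flag.

    Significance stars: ``*`` for p < .01, ``**`` for p < .001.
    """
    exclude = exclude or {}
    rows = []
    for outcome in outcomes:
        skip = set(exclude.get(outcome, []))
        for m in measures:
            if m in skip:
                rows.append({"measure": m, "outcome": outcome, "rho": np.nan,
                             "p_value": np.nan, "stars": "", "excluded": True,
                             "undefined": False, "n": 0})
                continue
            sub = records[[m, outcome]].dropna()
            x = sub[m].to_numpy(dtype=float)
            y = sub[outcome].astype(float).to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"measure": m, "outcome": outcome, "rho": np.nan,
                             "p_value": np.nan, "stars": "", "excluded": False,
                             "undefined": True, "n": len(sub)})
                continue
            rho, p = stats.spearmanr(x, y)
            stars = "**" if p < 0.001 else ("*" if p < 0.01 else "")
            rows.append({"measure": m, "outcome": outcome, "rho": float(rho),
                         "p_value": float(p), "stars": stars, "excluded": False,
                         "undefined": False, "n": len(sub)})
    return pd.DataFrame(rows)
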