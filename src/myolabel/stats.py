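"""Cohort-level statistics on label-quality metrics and decoder results.

Standard routines throughout: one-sample and paired t-tests from scipy,
the three-way analysis of variance (training paradigm x algorithm x
dataset size) through a statsmodels OLS fit. Post-hoc pairwise tests are
reported uncorrected, matching the primary reporting convention, with a
Holm-adjusted column alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

PAIRED_METRICS = (
    "mag_err_mean_pct", "mag_err_disp_pct",
    "timing_err_mean_ms", "timing_err_disp_ms", "rmse",
)


def one_sample_t(values, popmean: float = 0.0) -> dict:
    x = np.asarray(values, dtype=np.float64)
    t, p = sps.ttest_1samp(x, popmean)
    sd = x.std(ddof=1)
    d = (x.mean() - popmean) / sd if sd > 0 else np.nan
    return {"test": "one-sample t", "n": x.size, "statistic": float(t),
            "p": float(p), "effect_size": float(d)}


def paired_t(a, b) -> dict:
    """Paired t-test; degenerate zero-variance differences are reported as
    undefined (NaN statistic and p) rather than raising."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return {"test": "paired t", "n": a.size, "statistic": np.nan,
                "p": np.nan, "effect_size": np.nan}
    t, p = sps.ttest_rel(a, b)
    return {"test": "paired t", "n": a.size, "statistic": float(t),
            "p": float(p), "effect_size": float(diff.mean() / sd)}


def holm_adjust(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=np.float64)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def anova_three_way(results: pd.DataFrame) -> pd.DataFrame:
    """Type-II ANOVA of summary RMSE on paradigm, algorithm and size."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = results.rename(columns={"n_train_trials": "size"}).copy()
    factors = [f for f in ("paradigm", "algorithm", "size") if df[f].nunique() > 1]
    if not factors:
        raise ValueError("ANOVA needs at least one factor with two levels")
    model = ols("summary_rmse ~ " + " * ".join(f"C({f})" for f in factors), data=df).fit()
    table = sm.stats.anova_lm(model, typ=2).reset_index(names="term")
    table["test"] = "three-way ANOVA"
    return table


def cohort_stats(metrics: pd.DataFrame, results: pd.DataFrame | None = None) -> dict:
    """Run the cohort statistics.

    ``metrics``: one row per participant x paradigm with the label-quality
    metric columns. ``results``: optional long-format decoder results (one
    row per participant x paradigm x algorithm x size) with summary_rmse.
    Returns a dict of tidy tables: 'label_tests', and with results also
    'anova' and 'posthoc'.
    """
    if metrics["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    base = metrics.drop_duplicates("participant").sort_values("participant")
    for col in ("coupling_pct", "drift_pct"):
        rows.append({"comparison": f"{col} vs 0", **one_sample_t(base[col])})
    wide = metrics.pivot(index="participant", columns="paradigm")
    for col in PAIRED_METRICS:
        a = wide[(col, "mirror")]
        b = wide[(col, "mimic")]
        rows.append({"comparison": f"{col}: mirror vs mimic", **paired_t(a, b)})
    out = {"label_tests": pd.DataFrame(rows)}

    if results is not None:
        out["anova"] = anova_three_way(results)
        lo, hi = results["n_train_trials"].min(), results["n_train_trials"].max()
        ph = []
        for algo in sorted(results["algorithm"].unique()):
            sub = results[results["algorithm"] == algo]
            piv = sub.pivot_table(index="participant",
                                  columns=["paradigm", "n_train_trials"],
                                  values="summary_rmse")
            for paradigm in sorted(sub["paradigm"].unique()):
                ph.append({"comparison": f"{algo}/{paradigm}: {hi} vs {lo} trials",
                           **paired_t(piv[(paradigm, hi)], piv[(paradigm, lo)])})
            for size in (lo, hi):
                ph.append({"comparison": f"{algo}@{size}: mirror vs mimic",
                           **paired_t(piv[("mirror", size)], piv[("mimic", size)])})
        ph = pd.DataFrame(ph)
        ph["p_holm"] = holm_adjust(ph["p"].fillna(1.0))
        out["posthoc"] = ph
    return out
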