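"""Summary measures and statistical analyses for option-generation cohorts.

Per session the three behavioural readouts are fluency (number of valid
paths within the budget), mean uniqueness (average nearest-neighbour
distance of the session's valid paths against the pooled corpus) and
exploration area (convex hull of the MDS embedding).  On top of these the
module provides plain and partial correlations, a dependent-correlations
z test (Fisher-transformed, Steiger-style, for two correlations sharing a
variable), paired condition comparisons, an OLS model predicting
motivation from the three readouts, and the path-level mixed-effects
model of uniqueness on path duration, condition and apathy with a random
intercept per participant.  Estimation is delegated to scipy/statsmodels;
this module owns the study-specific contracts around it.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .model import Cohort

__all__ = [
    "AnalysisResult",
    "summarize",
    "correlate",
    "partial_correlate",
    "compare_correlations",
    "tradeoff_mixed_model",
    "paired_compare",
    "motivation_glm",
]


@dataclass
class AnalysisResult:
    """One statistical test: estimate, statistic, df, two-sided p."""

    method: str
    estimate: float
    statistic: float
    df: float
    pvalue: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isnan(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


# ---------------------------------------------------------------- summaries


def summarize(
    cohort: Cohort,
    path_metrics: pd.DataFrame,
    diversity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-session summary table: fluency, mean uniqueness, durations,
    hull area and covariates.

    ``path_metrics`` is the per-path table from the scoring stage
    (columns participant_id, session_index, task_kind, path_id, valid,
    duration_s, uniqueness).  Sessions present in the cohort but missing
    from the metrics raise an error naming the session.
    """
    rows = []
    for sess in cohort.iter_sessions("option_generation"):
        mask = (
            (path_metrics["participant_id"] == sess.participant_id)
            & (path_metrics["session_index"] == sess.session_index)
            & (path_metrics["task_kind"] == "option_generation")
        )
        sub = path_metrics.loc[mask]
        if len(sub) != len(sess.trajectories):
            raise ValueError(
                f"metrics missing or incomplete for session "
                f"{(sess.participant_id, sess.session_index)}: "
                f"{len(sub)} rows for {len(sess.trajectories)} paths"
            )
        valid = sub.loc[sub["valid"]]
        fluency = int(len(valid))
        row = {
            "participant_id": sess.participant_id,
            "session_index": sess.session_index,
            "condition": sess.condition,
            "fluency": fluency,
            "mean_uniqueness": float(valid["uniqueness"].mean())
            if fluency
            else np.nan,
            "mean_path_duration": float(valid["duration_s"].mean())
            if fluency
            else np.nan,
        }
        row.update(sess.covariates)
        rows.append(row)
    out = pd.DataFrame(rows)
    if diversity is not None and len(out):
        out = out.merge(
            diversity[["participant_id", "session_index", "hull_area", "stress"]],
            on=["participant_id", "session_index"],
            how="left",
        )
    return out


# ------------------------------------------------------------- correlations


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    return x, y


def correlate(x, y, method: str = "pearson") -> AnalysisResult:
    """Pearson or Spearman correlation with two-sided p."""
    x, y = _clean_xy(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to correlation")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    r = float(res.statistic)
    n = len(x)
    t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r)) if abs(r) < 1 else math.inf
    return AnalysisResult(
        method=method,
        estimate=r,
        statistic=t,
        df=n - 2,
        pvalue=float(res.pvalue),
        extra={"n": n},
    )


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear control variables")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_correlate(x, y, controls=None, method: str = "pearson") -> AnalysisResult:
    """Correlation of x and y after regressing both on the controls.

    With no controls this reduces exactly to ``correlate``.  For Spearman,
    variables are rank-transformed before residualization.  The p-value
    uses df = n - 2 - k for k controls.
    """
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        return correlate(x, y, method=method)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(controls, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[keep], y[keep], C[keep]
    n, k = len(x), C.shape[1]
    if n < k + 4:
        raise ValueError("too few complete rows for partial correlation")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        C = np.column_stack([sps.rankdata(c) for c in C.T])
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    rx = _residualize(x, C)
    ry = _residualize(y, C)
    # a variable fully explained by the controls has numerically-zero
    # residuals; its partial correlation is 0 by definition
    if np.std(rx) <= 1e-12 * max(1.0, np.std(x)) or np.std(ry) <= 1e-12 * max(
        1.0, np.std(y)
    ):
        r = 0.0
    else:
        r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * math.sqrt(df / max(1e-300, 1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return AnalysisResult(
        method=f"partial_{method}",
        estimate=r,
        statistic=t,
        df=df,
        pvalue=float(p),
        extra={"n": n, "n_controls": k},
    )


def compare_correlations(
    r_ab: float, r_ac: float, r_bc: float, n: int, dependent: bool = True
) -> AnalysisResult:
    """z test for the difference of two correlations sharing variable a.

    Default is the dependent-overlapping-correlations test (Fisher
    transforms with Steiger's correction for the correlation between the
    two coefficients through r_bc).  ``dependent=False`` gives the naive
    independent-samples Fisher z for sensitivity.
    """
    for name, r in (("r_ab", r_ab), ("r_ac", r_ac), ("r_bc", r_bc)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name}={r} outside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    z1 = math.atanh(r_ab)
    z2 = math.atanh(r_ac)
    if dependent:
        rbar2 = (r_ab**2 + r_ac**2) / 2.0
        f = min(1.0, (1.0 - r_bc) / (2.0 * (1.0 - rbar2)))
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_bc) * h))
        method = "steiger_dependent_z"
    else:
        z = (z1 - z2) / math.sqrt(2.0 / (n - 3))
        method = "independent_fisher_z"
    p = 2.0 * sps.norm.sf(abs(z))
    return AnalysisResult(
        method=method,
        estimate=r_ab - r_ac,
        statistic=float(z),
        df=float(n - 3),
        pvalue=float(p),
        extra={"n": n, "r_ab": r_ab, "r_ac": r_ac, "r_bc": r_bc},
    )


# --------------------------------------------------------------- mixed model


def tradeoff_mixed_model(
    table: pd.DataFrame,
    condition_ref: str | None = None,
    include_duration_condition: bool = False,
) -> AnalysisResult:
    """Path-level mixed model: uniqueness ~ duration + condition + apathy
    + condition x apathy, random intercept per participant.

    ``table`` needs columns participant_id, condition, duration_s,
    uniqueness, apathy.  The apathy covariate is mean-centered so the
    condition main effect is the condition contrast at a fixed duration
    and average apathy — the "uniqueness for a given fluency" surface.
    Returns the condition coefficient as the headline estimate with the
    full fixed-effect table in ``extra``.
    """
    required = {"participant_id", "condition", "duration_s", "uniqueness", "apathy"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"path-level table missing columns {sorted(missing)}")
    if (table["duration_s"] <= 0).any():
        raise ValueError("path durations must be positive")
    data = table.copy()
    levels = sorted(data["condition"].unique())
    if len(levels) < 2:
        raise ValueError("mixed model requires at least 2 conditions")
    if condition_ref is None:
        condition_ref = levels[0]
    if data["participant_id"].nunique() < 10:
        raise ValueError("mixed model requires at least 10 participants")
    data["apathy_c"] = data["apathy"] - data["apathy"].mean()
    formula = (
        f"uniqueness ~ duration_s + C(condition, Treatment('{condition_ref}'))"
        " + apathy_c"
        f" + C(condition, Treatment('{condition_ref}')):apathy_c"
    )
    if include_duration_condition:
        formula += f" + duration_s:C(condition, Treatment('{condition_ref}'))"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["participant_id"])
        try:
            fit = model.fit(reml=True)
        except Exception:
            fit = model.fit(reml=True, method="lbfgs")
        converged = bool(getattr(fit, "converged", True))
    cond_terms = [
        name
        for name in fit.fe_params.index
        if name.startswith("C(condition") and ":" not in name
    ]
    term = cond_terms[0]
    return AnalysisResult(
        method="mixedlm_random_intercept",
        estimate=float(fit.fe_params[term]),
        statistic=float(fit.tvalues[term]),
        df=float(len(data) - len(fit.fe_params)),
        pvalue=float(fit.pvalues[term]),
        extra={
            "condition_term": term,
            "fe_params": fit.fe_params.to_dict(),
            "tvalues": fit.tvalues[fit.fe_params.index].to_dict(),
            "pvalues": fit.pvalues[fit.fe_params.index].to_dict(),
            "bse": fit.bse[fit.fe_params.index].to_dict(),
            "converged": converged,
            "n_obs": int(len(data)),
            "n_participants": int(data["participant_id"].nunique()),
        },
    )


# ----------------------------------------------------------- paired compare


def paired_compare(
    summaries: pd.DataFrame,
    measure: str,
    condition_a: str,
    condition_b: str,
    transform: str = "auto",
) -> AnalysisResult:
    """Two-sided paired t test of a per-session measure between conditions.

    ``transform``: "never", "always", or "auto" (log-transform when a
    Shapiro normality pre-check of the pooled values fails at alpha=0.05
    and all values are positive).  Zero-variance differences are reported
    exactly and flagged instead of producing an infinite statistic.
    """
    pivot = summaries.pivot_table(
        index="participant_id", columns="condition", values=measure, aggfunc="mean"
    )
    for cond in (condition_a, condition_b):
        if cond not in pivot.columns:
            raise ValueError(f"condition {cond!r} absent from summaries")
    unmatched = pivot.index[pivot[[condition_a, condition_b]].isna().any(axis=1)]
    if len(unmatched):
        raise ValueError(
            f"unmatched participants for paired comparison: {list(unmatched)}"
        )
    a = pivot[condition_a].to_numpy(dtype=float)
    b = pivot[condition_b].to_numpy(dtype=float)
    pooled = np.concatenate([a, b])
    logged = False
    if transform not in ("never", "always", "auto"):
        raise ValueError(f"unknown transform policy {transform!r}")
    if transform == "always" or (
        transform == "auto"
        and np.all(pooled > 0)
        and len(pooled) >= 4
        and sps.shapiro(pooled).pvalue < 0.05
    ):
        if np.any(pooled <= 0):
            raise ValueError("log transform requires positive values")
        a, b = np.log(a), np.log(b)
        logged = True
    diff = a - b
    n = len(diff)
    if np.allclose(diff.std(ddof=1) if n > 1 else 0.0, 0.0):
        return AnalysisResult(
            method="paired_t",
            estimate=float(diff.mean()),
            statistic=math.nan,
            df=float(n - 1),
            pvalue=math.nan,
            extra={
                "measure": measure,
                "zero_variance": True,
                "log_transformed": logged,
                "n_pairs": n,
            },
        )
    res = sps.ttest_rel(a, b)
    return AnalysisResult(
        method="paired_t",
        estimate=float(diff.mean()),
        statistic=float(res.statistic),
        df=float(n - 1),
        pvalue=float(res.pvalue),
        extra={
            "measure": measure,
            "zero_variance": False,
            "log_transformed": logged,
            "n_pairs": n,
        },
    )


# ------------------------------------------------------------------- OLS GLM


def motivation_glm(summaries: pd.DataFrame) -> AnalysisResult:
    """OLS (Gaussian GLM) predicting motivation from fluency, mean
    uniqueness and hull area jointly; reports the fluency coefficient as
    the headline with the full table in ``extra``."""
    cols = ["motivation", "fluency", "mean_uniqueness"]
    use_area = "hull_area" in summaries.columns
    if use_area:
        cols.append("hull_area")
    data = summaries[cols].dropna()
    formula = "motivation ~ fluency + mean_uniqueness" + (
        " + hull_area" if use_area else ""
    )
    fit = smf.ols(formula, data).fit()
    return AnalysisResult(
        method="ols_motivation",
        estimate=float(fit.params["fluency"]),
        statistic=float(fit.tvalues["fluency"]),
        df=float(fit.df_resid),
        pvalue=float(fit.pvalues["fluency"]),
        extra={
            "params": fit.params.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "r_squared": float(fit.rsquared),
            "n_obs": int(fit.nobs),
        },
    )
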