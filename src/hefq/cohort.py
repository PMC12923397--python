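"""Longitudinal cohort statistics for regional hard-exudate volumes.

Implements the analysis pipeline applied to the per-eye visit tables:
trajectory summaries with percent-of-baseline, paired t-tests against
baseline with Bonferroni correction, complete-resolution counts, Pearson
correlation screens, a univariable linear-regression screen, and
bidirectional stepwise multivariable regression reporting standardized
betas, partial R-squared (last-entry increment, i.e. squared semi-partial
correlation) and variance-inflation diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from hefq.core import FOLLOWUP_WEEKS, CohortTable

__all__ = [
    "bonferroni",
    "summarize_trajectories",
    "paired_tests_vs_baseline",
    "PairedTestResult",
    "resolution_counts",
    "pearson_screen",
    "univariable_screen",
    "stepwise_fit",
    "partial_r2",
    "RegressionModelResult",
    "analysis_frame",
]

_REGION_COLS = {
    "total": "he_total_mm3",
    "csf": "he_csf_mm3",
    "ir": "he_ir_mm3",
    "or": "he_or_mm3",
}


def _visits(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return cohort.visits if isinstance(cohort, CohortTable) else cohort


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: ``min(1, p * m)``; never below ``p``."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(min(1.0, p * m))


def summarize_trajectories(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Per-region, per-week mean +/- SD and percent of baseline.

    Percent-of-baseline is the ratio of cohort means (week mean over
    baseline mean, over the eyes present at each week), scaled to 100 and
    rounded to one decimal for reporting — the reading under which the
    printed percentages equal the printed means' ratios.
    """
    visits = _visits(cohort)
    if (visits["week"] == 0).sum() == 0:
        raise ValueError("cohort has no baseline (week 0) rows")
    rows = []
    for region, col in _REGION_COLS.items():
        base = visits.loc[visits["week"] == 0, col]
        base_mean = base.mean()
        for week in sorted(visits["week"].unique()):
            vals = visits.loc[visits["week"] == week, col]
            mean = vals.mean()
            pct = round(100.0 * mean / base_mean, 1) if base_mean > 0 else np.nan
            rows.append(
                {
                    "region": region,
                    "week": int(week),
                    "mean_mm3": float(mean),
                    "sd_mm3": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n_eyes": int(len(vals)),
                    "percent_of_baseline": pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    """One paired comparison of a follow-up week against baseline."""

    region: str
    week: int
    n_pairs: int
    mean_difference: float
    t_statistic: float
    df: int
    p_raw: float
    p_bonferroni: float


def paired_tests_vs_baseline(
    cohort: CohortTable | pd.DataFrame,
    region: str = "total",
    weeks: Sequence[int] = FOLLOWUP_WEEKS,
    family_size: int = 4,
) -> list[PairedTestResult]:
    """Two-sided paired t-tests of each week's volume against baseline.

    Pairing is complete-case per timepoint: an eye missing that visit is
    dropped from that comparison only.  The Bonferroni family defaults to
    the four follow-up weeks within one region; the adjusted p is
    ``min(1, p * family_size)``.

    Raises
    ------
    ValueError
        If fewer than 2 complete pairs exist for some comparison.
    """
    visits = _visits(cohort)
    col = _REGION_COLS[region]
    wide = visits.pivot(index="eye_id", columns="week", values=col)
    if 0 not in wide.columns:
        raise ValueError("cohort has no baseline (week 0) rows")
    results = []
    for week in weeks:
        if week not in wide.columns:
            raise ValueError(f"no rows at week {week}")
        pair = wide[[0, week]].dropna()
        n = len(pair)
        if n < 2:
            raise ValueError(f"fewer than 2 complete pairs at week {week}")
        d = pair[week].to_numpy() - pair[0].to_numpy()
        sd = d.std(ddof=1)
        if sd == 0.0:
            t = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
            p = 1.0 if d.mean() == 0.0 else 0.0
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        results.append(
            PairedTestResult(
                region=region,
                week=int(week),
                n_pairs=n,
                mean_difference=float(d.mean()),
                t_statistic=float(t),
                df=n - 1,
                p_raw=float(p),
                p_bonferroni=bonferroni(p, family_size),
            )
        )
    return results


def resolution_counts(
    cohort: CohortTable | pd.DataFrame,
    week: int = 52,
    denominator: str | int = "analyzed",
) -> pd.DataFrame:
    """Count eyes with complete regional resolution (zero volume) at a week.

    ``denominator`` is the cohort size used for the percentage: "analyzed"
    (all distinct eyes in the table — the default), "present" (eyes with a
    row at that week), or an explicit integer.
    """
    visits = _visits(cohort)
    at_week = visits[visits["week"] == week]
    if denominator == "analyzed":
        denom = visits["eye_id"].nunique()
    elif denominator == "present":
        denom = len(at_week)
    else:
        denom = int(denominator)
    rows = []
    for region, col in _REGION_COLS.items():
        count = int((at_week[col] == 0.0).sum())
        rows.append(
            {
                "region": region,
                "week": week,
                "n_resolved": count,
                "denominator": denom,
                "percent": round(100.0 * count / denom, 1) if denom else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pearson_screen(
    df: pd.DataFrame, x_vars: Sequence[str], y_vars: Sequence[str]
) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p-values.

    Uses pairwise-complete observations; pairs with fewer than 3 complete
    observations or a zero-variance member are flagged and get NaN r.
    """
    rows = []
    for x in x_vars:
        for y in y_vars:
            sub = df[[x, y]].dropna()
            note = ""
            r = p = np.nan
            if len(sub) < 3:
                note = "fewer than 3 complete observations"
            elif sub[x].nunique() < 2 or sub[y].nunique() < 2:
                note = "zero variance"
            else:
                r, p = stats.pearsonr(sub[x], sub[y])
            rows.append(
                {"x": x, "y": y, "n": int(len(sub)), "r": float(r), "p": float(p),
                 "note": note}
            )
    return pd.DataFrame(rows)


def univariable_screen(
    df: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Simple linear regression of the outcome on each candidate.

    A candidate passes when its slope p-value is <= ``threshold`` (the
    conventional p <= 0.10 entry gate for multivariable modelling).
    Constant candidates fail with a diagnostic note.
    """
    rows = []
    for cand in candidates:
        sub = df[[outcome, cand]].dropna()
        note = ""
        slope = p = np.nan
        passed = False
        if len(sub) < 3:
            note = "fewer than 3 complete observations"
        elif sub[cand].nunique() < 2:
            note = "constant candidate"
        else:
            X = sm.add_constant(sub[cand].to_numpy(dtype=float))
            fit = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
            slope, p = float(fit.params[1]), float(fit.pvalues[1])
            passed = p <= threshold
        rows.append(
            {"candidate": cand, "n": int(len(sub)), "slope": slope, "p": p,
             "passed": passed, "note": note}
        )
    return pd.DataFrame(rows)


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    return float(sm.OLS(y, sm.add_constant(X)).fit().rsquared)


def partial_r2(
    df: pd.DataFrame, outcome: str, predictors: Sequence[str], target: str
) -> float:
    """Last-entry increment in R^2 for ``target`` given the other predictors.

    This is the squared semi-partial correlation: R^2 of the full model
    minus R^2 of the model refit without ``target``.
    """
    if target not in predictors:
        raise ValueError(f"{target!r} is not among the model predictors")
    sub = df[[outcome, *predictors]].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    full = _r2(y, sub[list(predictors)].to_numpy(dtype=float))
    rest = [p for p in predictors if p != target]
    reduced = _r2(y, sub[rest].to_numpy(dtype=float))
    return full - reduced


def _vifs(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per column of a predictor matrix."""
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        if others.shape[1] == 0:
            out[col] = 1.0
            continue
        r2 = _r2(X[col].to_numpy(dtype=float), others.to_numpy(dtype=float))
        out[col] = float(np.inf) if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class PredictorResult:
    name: str
    beta_standardized: float
    coef_raw: float
    p: float
    partial_r2: float
    vif: float


@dataclass
class RegressionModelResult:
    """Fitted stepwise model: retained predictors and fit diagnostics."""

    outcome: str
    predictors: list[PredictorResult]
    r2: float
    adjusted_r2: float
    n: int
    screen_log: pd.DataFrame | None = None
    steps: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return [p.name for p in self.predictors]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "predictors": [vars(p) for p in self.predictors],
            "steps": list(self.steps),
            "screen": (
                self.screen_log.to_dict(orient="records")
                if self.screen_log is not None
                else None
            ),
        }


def stepwise_fit(
    df: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    vif_max: float = 5.0,
    screen_log: pd.DataFrame | None = None,
) -> RegressionModelResult:
    """Bidirectional stepwise linear regression on z-scored variables.

    Forward steps add the candidate with the lowest partial p-value among
    those with p <= ``entry_p`` (ties broken lexicographically by name);
    backward steps drop retained predictors whose p rises above
    ``removal_p``.  A step that would push any predictor's variance
    inflation factor above ``vif_max`` is refused, which guards the model
    against multicollinearity.  Coefficients are reported both raw and
    standardized (fit on z-scored outcome and predictors), with the
    last-entry partial R^2 per retained predictor.
    """
    sub = df[[outcome, *candidates]].dropna().reset_index(drop=True)
    n = len(sub)
    if n < len(candidates) + 3:
        raise ValueError("too few complete observations for stepwise fitting")
    z = pd.DataFrame(
        {
            c: (sub[c] - sub[c].mean()) / sub[c].std(ddof=1)
            if sub[c].std(ddof=1) > 0
            else 0.0
            for c in (outcome, *candidates)
        }
    )
    model: list[str] = []
    steps: list[str] = []
    zy = z[outcome].to_numpy()

    def fit_p(cols: list[str]) -> pd.Series:
        fit = sm.OLS(zy, sm.add_constant(z[cols].to_numpy())).fit()
        return pd.Series(fit.pvalues[1:], index=cols)

    while True:
        changed = False
        # forward entry
        best_name, best_p = None, None
        for cand in sorted(c for c in candidates if c not in model):
            trial = model + [cand]
            if max(_vifs(z[trial]).values()) > vif_max:
                continue
            p = fit_p(trial)[cand]
            if p <= entry_p and (best_p is None or p < best_p):
                best_name, best_p = cand, p
        if best_name is not None:
            model.append(best_name)
            steps.append(f"enter {best_name} (p={best_p:.3g})")
            changed = True
        # backward removal
        while model:
            ps = fit_p(model)
            worst = ps.idxmax()
            if ps[worst] > removal_p:
                model.remove(worst)
                steps.append(f"remove {worst} (p={ps[worst]:.3g})")
                changed = True
            else:
                break
        if not changed:
            break

    if not model:
        return RegressionModelResult(
            outcome=outcome, predictors=[], r2=0.0, adjusted_r2=0.0, n=n,
            screen_log=screen_log, steps=steps,
        )
    z_fit = sm.OLS(zy, sm.add_constant(z[model].to_numpy())).fit()
    raw_fit = sm.OLS(
        sub[outcome].to_numpy(dtype=float),
        sm.add_constant(sub[model].to_numpy(dtype=float)),
    ).fit()
    vifs = _vifs(z[model])
    predictors = []
    for i, name in enumerate(model):
        predictors.append(
            PredictorResult(
                name=name,
                beta_standardized=float(z_fit.params[i + 1]),
                coef_raw=float(raw_fit.params[i + 1]),
                p=float(z_fit.pvalues[i + 1]),
                partial_r2=partial_r2(sub, outcome, model, name),
                vif=vifs[name],
            )
        )
    return RegressionModelResult(
        outcome=outcome,
        predictors=predictors,
        r2=float(z_fit.rsquared),
        adjusted_r2=float(z_fit.rsquared_adj),
        n=n,
        screen_log=screen_log,
        steps=steps,
    )


def analysis_frame(cohort: CohortTable) -> pd.DataFrame:
    """One row per eye with the variables used in the outcome analyses.

    Merges baseline covariates with baseline HE volumes, baseline and
    week-52 CST, and week-52 VA; adds a 0/1 ``pseudophakic`` indicator.
    """
    visits = cohort.visits
    base = visits[visits["week"] == 0].set_index("eye_id")
    w52 = visits[visits["week"] == 52].set_index("eye_id")
    df = cohort.covariates.set_index("eye_id").copy()
    df["he_total_baseline"] = base["he_total_mm3"]
    df["he_csf_baseline"] = base["he_csf_mm3"]
    df["he_ir_baseline"] = base["he_ir_mm3"]
    df["or_he_baseline"] = base["he_or_mm3"]
    df["cst_baseline"] = base["cst_um"]
    df["va_baseline"] = base["va_letters"]
    df["cst_w52"] = w52["cst_um"]
    df["va_w52"] = w52["va_letters"]
    df["pseudophakic"] = (df["lens_status"] == "pseudophakic").astype(float)
    return df.reset_index()
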