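"""Synthetic longitudinal cohort generator with planted truth.

Emulates a 260-eye anti-VEGF treatment cohort followed at weeks 0, 4, 12,
24 and 52: right-skewed regional hard-exudate volumes whose cohort-mean
trajectories follow configurable percent-of-baseline factors, baseline
covariates with planted Pearson correlations to baseline HE burden, and a
week-52 visual-acuity outcome generated from a linear model with planted
standardized coefficients.  Every planted parameter is returned alongside
the cohort so recovery tests have an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from hefq.core import FOLLOWUP_WEEKS, CohortTable

__all__ = [
    "TrajectoryFactors",
    "CohortParams",
    "generate_cohort",
    "apply_inclusion_filters",
    "TABLE_FACTORS",
    "REGION_BASELINE_MEANS",
]

# Generator regions: the three ETDRS regions plus the scan corners outside
# the 6-mm circle ("outside").  The total is their sum, which is why the
# CSF+IR+OR <= total invariant holds by construction.
_GEN_REGIONS = ("csf", "ir", "or", "outside")

#: Default baseline cohort-mean regional HE volumes (mm^3).  The outside
#: component is the total minus the three grid regions.
REGION_BASELINE_MEANS: dict[str, float] = {
    "csf": 0.0011,
    "ir": 0.0069,
    "or": 0.0183,
    "outside": 0.0030,
}

#: Default multiplicative trajectory factors (fraction of baseline cohort
#: mean) at each follow-up week, per region.  The outside factors are
#: derived so the summed total follows its observed trajectory.
TABLE_FACTORS: dict[str, dict[int, float]] = {
    "csf": {4: 1.000, 12: 0.727, 24: 0.545, 52: 0.364},
    "ir": {4: 1.116, 12: 1.174, 24: 1.000, 52: 0.478},
    "or": {4: 1.126, 12: 1.219, 24: 1.055, 52: 0.579},
    "outside": {4: 1.133, 12: 1.267, 24: 1.167, 52: 0.733},
}

TrajectoryFactors = Mapping[str, Mapping[int, float]]

#: Baseline covariate means and SDs for a diabetic macular edema cohort.
COVARIATE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (61.2, 10.2),
    "hba1c": (8.0, 1.7),
    "dm_duration": (16.8, 10.2),
    "mean_arterial_bp": (101.4, 12.5),
    "bmi": (33.6, 7.8),
}

#: Planted Pearson correlations between covariates and baseline total HE.
DEFAULT_CORRELATIONS: dict[str, float] = {
    "hba1c": 0.198,
    "age": -0.158,
    "dm_duration": -0.221,
}

#: Planted standardized coefficients of the week-52 VA outcome model.
DEFAULT_OUTCOME_BETAS: dict[str, float] = {
    "cst_w52": -0.300,
    "or_he_baseline": -0.280,
    "pseudophakic": -0.153,
}

#: Planted probabilities of complete regional resolution (volume exactly 0)
#: among eyes observed at a week.  Zeroing is mean-preserving: surviving
#: volumes are scaled by 1/(1-p) so cohort-mean trajectories still follow
#: the planted factors.
DEFAULT_RESOLUTION_RATES: dict[str, dict[int, float]] = {
    "csf": {52: 0.292},
    "ir": {52: 0.038},
    "or": {52: 0.004},
}


@dataclass(frozen=True)
class CohortParams:
    """Settings for :func:`generate_cohort`."""

    n_eyes: int = 260
    factors: TrajectoryFactors = field(default_factory=lambda: TABLE_FACTORS)
    baseline_means: Mapping[str, float] = field(
        default_factory=lambda: REGION_BASELINE_MEANS
    )
    #: Log-scale SD of the shared per-eye severity factor and of the
    #: per-region factor; together they set the right skew of the volumes.
    sigma_shared: float = 1.0
    sigma_region: float = 0.6
    #: Log-scale SD of the per-(eye, week, region) multiplicative visit noise
    #: (0 makes visit volumes exact multiples of baseline).
    visit_noise_sd: float = 0.25
    #: Probability an eye misses one follow-up visit (at most one is ever
    #: generated, matching the inclusion rule).
    missing_rate: float = 0.10
    correlations: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_CORRELATIONS
    )
    outcome_betas: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_OUTCOME_BETAS
    )
    resolution_rates: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: DEFAULT_RESOLUTION_RATES
    )
    #: Residual SD of the standardized outcome; "auto" scales it so the
    #: planted coefficients are the standardized betas of the generated VA.
    outcome_noise_sd: float | str = "auto"
    pseudophakic_rate: float = 0.269
    female_rate: float = 0.50
    prior_laser_rate: float = 0.346
    #: Fraction of eyes given a disqualifying signal strength (<= 3) or a
    #: zero baseline HE volume, to exercise the inclusion filter.
    low_signal_rate: float = 0.05
    zero_baseline_rate: float = 0.03
    cst_baseline_mean: float = 451.9
    cst_baseline_sd: float = 130.9
    #: Mean CST path over weeks (0, 4, 12, 24, 52) and its SD at follow-up.
    cst_week_means: tuple[float, ...] = (451.9, 410.0, 375.0, 350.0, 320.0)
    cst_week_sd: float = 110.0
    #: Correlation of follow-up CST with baseline CST.
    cst_tracking: float = 0.5
    va_baseline_mean: float = 65.8
    va_baseline_sd: float = 10.9
    va_w52_mean: float = 73.0
    va_w52_sd: float = 11.0

    def __post_init__(self) -> None:
        if self.n_eyes < 0:
            raise ValueError("n_eyes must be >= 0")
        if isinstance(self.outcome_noise_sd, str):
            if self.outcome_noise_sd != "auto":
                raise ValueError("outcome_noise_sd must be a number or 'auto'")
        elif self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be >= 0")
        if self.visit_noise_sd < 0:
            raise ValueError("visit_noise_sd must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        for region in _GEN_REGIONS:
            if region not in self.factors:
                raise ValueError(f"trajectory factors missing region {region!r}")
            for week in FOLLOWUP_WEEKS:
                if week not in self.factors[region]:
                    raise ValueError(
                        f"trajectory factors for {region!r} missing week {week}"
                    )
                if not self.factors[region][week] > 0:
                    raise ValueError("trajectory factors must be > 0")
        for region, by_week in self.resolution_rates.items():
            for week, p in by_week.items():
                if not 0 <= p < 1:
                    raise ValueError("resolution rates must be in [0, 1)")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> tuple[CohortTable, dict]:
    """Generate a synthetic cohort and the record of all planted parameters.

    Visit-week regional volume is ``baseline * factor * noise`` with
    lognormal mean-one noise, so the ratio of cohort means at a week to the
    baseline cohort mean estimates the planted factor (and equals it exactly
    when ``visit_noise_sd`` is 0 and no visits are missing).
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    n = params.n_eyes

    truth: dict = {
        "factors": {r: dict(params.factors[r]) for r in _GEN_REGIONS},
        "correlations": dict(params.correlations),
        "outcome_betas": dict(params.outcome_betas),
        "baseline_means": dict(params.baseline_means),
        "resolution_rates": {
            r: dict(w) for r, w in params.resolution_rates.items()
        },
    }
    if n == 0:
        visits = pd.DataFrame(
            columns=[
                "eye_id", "week", "va_letters", "cst_um",
                "he_total_mm3", "he_csf_mm3", "he_ir_mm3", "he_or_mm3",
            ]
        )
        cov = pd.DataFrame(columns=["eye_id"])
        return CohortTable(visits=visits, covariates=cov), truth

    eye_ids = np.array([f"eye{i:04d}" for i in range(n)])

    # Baseline regional volumes: shared lognormal severity times a
    # per-region lognormal, both mean-one, scaled to the target means.
    shared = rng.lognormal(-params.sigma_shared**2 / 2, params.sigma_shared, n)
    baseline = {}
    for region in _GEN_REGIONS:
        per = rng.lognormal(-params.sigma_region**2 / 2, params.sigma_region, n)
        baseline[region] = params.baseline_means[region] * shared * per
    zero_baseline = rng.random(n) < params.zero_baseline_rate
    for region in _GEN_REGIONS:
        baseline[region] = np.where(zero_baseline, 0.0, baseline[region])
    baseline_total = sum(baseline[r] for r in _GEN_REGIONS)

    # Covariates with planted Pearson correlation to baseline total HE.
    z_he = _standardize(baseline_total)
    cov = {"eye_id": eye_ids}
    for name, (mean, sd) in COVARIATE_MOMENTS.items():
        rho = float(params.correlations.get(name, 0.0))
        eps = rng.standard_normal(n)
        cov[name] = mean + sd * (rho * z_he + np.sqrt(max(0.0, 1 - rho**2)) * eps)
    pseudophakic = rng.random(n) < params.pseudophakic_rate
    cov["lens_status"] = np.where(pseudophakic, "pseudophakic", "phakic")
    cov["sex"] = np.where(rng.random(n) < params.female_rate, "F", "M")
    cov["prior_laser"] = rng.random(n) < params.prior_laser_rate
    signal = rng.integers(5, 11, n)
    low = rng.random(n) < params.low_signal_rate
    signal = np.where(low, rng.integers(1, 4, n), signal)
    cov["signal_strength"] = signal
    covariates = pd.DataFrame(cov)

    # CST: baseline plus correlated follow-up path.
    cst_base = np.clip(
        params.cst_baseline_mean + params.cst_baseline_sd * rng.standard_normal(n),
        150, None,
    )
    z_cst_base = _standardize(cst_base)
    cst = {0: cst_base}
    for i, week in enumerate(FOLLOWUP_WEEKS, start=1):
        eps = rng.standard_normal(n)
        cst[week] = np.clip(
            params.cst_week_means[i]
            + params.cst_week_sd
            * (params.cst_tracking * z_cst_base
               + np.sqrt(1 - params.cst_tracking**2) * eps),
            120, None,
        )

    # Week-52 VA from the planted linear outcome model on standardized scale.
    betas = params.outcome_betas
    lp = (
        betas.get("cst_w52", 0.0) * _standardize(cst[52])
        + betas.get("or_he_baseline", 0.0) * _standardize(baseline["or"])
        + betas.get("pseudophakic", 0.0) * _standardize(pseudophakic.astype(float))
    )
    if params.outcome_noise_sd == "auto":
        noise_sd = float(np.sqrt(max(0.0, 1.0 - lp.var(ddof=1)))) if n > 1 else 0.0
    else:
        noise_sd = float(params.outcome_noise_sd)
    truth["outcome_noise_sd"] = noise_sd
    va52 = params.va_w52_mean + params.va_w52_sd * (lp + noise_sd * rng.standard_normal(n))
    va_base = np.clip(
        params.va_baseline_mean + params.va_baseline_sd * rng.standard_normal(n), 0, 100
    )
    va52 = np.clip(va52, 0, 100)

    # At most one missing follow-up visit per eye.
    missing_week = np.full(n, -1)
    miss = rng.random(n) < params.missing_rate
    missing_week[miss] = rng.choice(FOLLOWUP_WEEKS, size=int(miss.sum()))

    rows = []
    for i in range(n):
        for wi, week in enumerate((0,) + FOLLOWUP_WEEKS):
            if week == missing_week[i]:
                continue
            if week == 0:
                reg = {r: baseline[r][i] for r in _GEN_REGIONS}
                va = va_base[i]
            else:
                reg = {}
                for r in _GEN_REGIONS:
                    noise = (
                        rng.lognormal(-params.visit_noise_sd**2 / 2, params.visit_noise_sd)
                        if params.visit_noise_sd > 0
                        else 1.0
                    )
                    p_res = float(params.resolution_rates.get(r, {}).get(week, 0.0))
                    if p_res > 0 and rng.random() < p_res:
                        reg[r] = 0.0
                    else:
                        reg[r] = (
                            baseline[r][i] * params.factors[r][week] * noise
                            / (1.0 - p_res)
                        )
                if week == 52:
                    va = va52[i]
                else:
                    frac = wi / 4.0
                    va = float(
                        np.clip(
                            va_base[i] + frac * (va52[i] - va_base[i])
                            + 2.0 * rng.standard_normal(),
                            0, 100,
                        )
                    )
            rows.append(
                {
                    "eye_id": eye_ids[i],
                    "week": week,
                    "va_letters": va,
                    "cst_um": cst[week][i],
                    "he_total_mm3": sum(reg.values()),
                    "he_csf_mm3": reg["csf"],
                    "he_ir_mm3": reg["ir"],
                    "he_or_mm3": reg["or"],
                }
            )
    visits = pd.DataFrame(rows)
    return CohortTable(visits=visits, covariates=covariates), truth


# Inclusion rules: eyes are excluded for a disqualifying signal strength,
# an empty baseline scan, or more than one missing follow-up visit.
_REASON_SIGNAL = "low signal strength"
_REASON_NO_HE = "no hard exudates at baseline"
_REASON_NO_BASELINE = "missing baseline visit"
_REASON_MISSING = "more than one missing follow-up visit"


def apply_inclusion_filters(cohort: CohortTable) -> tuple[CohortTable, pd.DataFrame]:
    """Apply the cohort inclusion criteria; returns (filtered cohort, log).

    Excludes eyes with signal strength <= 3, eyes with zero total HE volume
    at baseline (or no baseline visit at all), and eyes missing more than
    one of the four follow-up visits.  The log records one reason per
    excluded eye, in that order of precedence.
    """
    log_rows = []
    keep = []
    visits = cohort.visits
    cov = cohort.covariates.set_index("eye_id", drop=False)
    for eye_id in cohort.eye_ids:
        ev = visits[visits["eye_id"] == eye_id]
        weeks = set(ev["week"])
        signal = cov.loc[eye_id, "signal_strength"] if "signal_strength" in cov else 10
        if signal <= 3:
            log_rows.append({"eye_id": eye_id, "reason": _REASON_SIGNAL})
            continue
        if 0 not in weeks:
            log_rows.append({"eye_id": eye_id, "reason": _REASON_NO_BASELINE})
            continue
        baseline_total = float(ev.loc[ev["week"] == 0, "he_total_mm3"].iloc[0])
        if baseline_total == 0.0:
            log_rows.append({"eye_id": eye_id, "reason": _REASON_NO_HE})
            continue
        n_missing = sum(1 for w in FOLLOWUP_WEEKS if w not in weeks)
        if n_missing > 1:
            log_rows.append({"eye_id": eye_id, "reason": _REASON_MISSING})
            continue
        keep.append(eye_id)
    log = pd.DataFrame(log_rows, columns=["eye_id", "reason"])
    return cohort.subset(keep), log
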