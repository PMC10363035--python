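"""Replicate virtual-trial engine.

Each replicate of the study: draw AFT parameters from their estimation
uncertainty, compute every subject's location mu from their baseline
covariates and individual log(KG), draw log-normal survival times, censor by
a uniformly distributed study duration, then summarize the replicate with
per-arm Kaplan-Meier curves, landmark survival rates, and the Cox hazard
ratio (treatment vs control, Efron tie handling).  Replicates aggregate to
medians and 2.5/97.5 percentile prediction intervals.

KM estimation and the Cox fit are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError

from tgios.os_model import OSModel, linear_predictor

#: Common output grid for curve aggregation: monthly steps to 60 months.
DAYS_PER_MONTH = 365.25 / 12.0
DEFAULT_TIME_GRID = np.arange(0, 61) * DAYS_PER_MONTH


@dataclass
class SimulationConfig:
    """Controls for :func:`run_simulation`.

    ``censor_bounds`` are the (low, high) days of the uniform study-duration
    distribution used to censor simulated deaths; ``landmark_times`` are the
    days at which survival rates are read off the KM curves (default: 2
    years); ``uncertainty`` selects how AFT parameters vary across
    replicates: ``"none"`` (point estimates), ``"diagonal-normal"``
    (independent normal draws per coefficient using its SE), or
    ``"full-covariance"`` (multivariate normal; needs a covariance matrix).
    """

    n_replicates: int = 1000
    seed: int = 0
    censor_bounds: tuple[float, float] = (1278.0, 1825.0)
    landmark_times: tuple[float, ...] = (730.0,)
    uncertainty: str = "diagonal-normal"
    covariance: np.ndarray | None = None  # required for full-covariance
    time_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_TIME_GRID.copy()
    )

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        lo, hi = self.censor_bounds
        if not (0 <= lo < hi):
            raise ValueError("censor_bounds must satisfy 0 <= low < high")
        if self.uncertainty not in ("none", "diagonal-normal", "full-covariance"):
            raise ValueError(f"unknown uncertainty mode: {self.uncertainty!r}")


@dataclass
class ReplicateResult:
    """One simulated study replicate."""

    km_curves: dict          # arm -> (times, survival) step function arrays
    landmark_rates: dict     # arm -> {landmark_day: percent surviving}
    hr: float                # treatment-vs-control hazard ratio (nan if failed)


@dataclass
class SimulationSummary:
    """Median and 95% prediction-interval aggregation across replicates."""

    time_grid: np.ndarray
    curves: pd.DataFrame       # arm, time_days, median, lo, hi
    landmark: pd.DataFrame     # arm, time_days, median, lo, hi (percent)
    hr_median: float
    hr_pi: tuple[float, float]
    n_replicates: int
    n_hr_failed: int
    replicate_hrs: np.ndarray = field(repr=False, default=None)

    def to_json(self) -> str:
        import json

        doc = {
            "hr_median": self.hr_median,
            "hr_pi": list(self.hr_pi),
            "n_replicates": self.n_replicates,
            "n_hr_failed": self.n_hr_failed,
            "landmark": self.landmark.to_dict(orient="records"),
            "curves": self.curves.to_dict(orient="records"),
        }
        return json.dumps(doc, indent=2, default=float)


def sample_parameters(
    model: OSModel, mode: str, rng: np.random.Generator,
    covariance: np.ndarray | None = None,
) -> dict:
    """One draw of the AFT parameter vector from its estimation uncertainty.

    Returns a dict keyed by coefficient name (including ``intercept`` and
    ``log_scale``).  ``mode="none"`` returns the point estimates; a
    coefficient with SE 0 never varies.
    """
    rows = [model.intercept, *model.effects, model.log_scale]
    names = [r.name for r in rows]
    means = np.array([r.beta for r in rows])
    if mode == "none":
        draw = means
    elif mode == "diagonal-normal":
        ses = np.array([r.se for r in rows])
        if not np.all(np.isfinite(ses)):
            raise ValueError("diagonal-normal sampling needs finite SEs")
        draw = means + ses * rng.standard_normal(len(means))
    elif mode == "full-covariance":
        if covariance is None:
            raise ValueError("full-covariance sampling needs a covariance matrix")
        draw = rng.multivariate_normal(means, covariance)
    else:
        raise ValueError(f"unknown uncertainty mode: {mode!r}")
    return dict(zip(names, draw))


def simulate_patient(
    mu: float | np.ndarray,
    scale: float,
    censor_bounds: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate observed (time, event) for one or many patients.

    True survival T ~ LogNormal(mu, scale); study duration C ~
    Uniform(censor_bounds); the observation is (min(T, C), 1[T <= C]).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    T = rng.lognormal(mean=mu, sigma=scale)
    C = rng.uniform(censor_bounds[0], censor_bounds[1], size=mu.shape)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return time, event


def km_estimate(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate; returns (times, survival) steps.

    The returned arrays define a right-continuous step function starting at
    (0, 1).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def km_at(times: np.ndarray, surv: np.ndarray, t) -> np.ndarray:
    """Evaluate a KM step function at arbitrary times (right-continuous)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(times, t, side="right") - 1
    out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
    return out


def cox_hr(times, events, arm) -> float:
    """Treatment-vs-control hazard ratio from the Cox partial likelihood.

    ``arm`` holds "treatment"/"control" labels (or a 0/1 indicator where 1 =
    treatment).  Efron tie handling.  Returns nan when the partial
    likelihood is degenerate (e.g. all events in one arm, or no events).
    """
    arm = np.asarray(arm)
    if arm.dtype.kind in "UO":
        treat = (arm == "treatment").astype(int)
    else:
        treat = arm.astype(int)
    events = np.asarray(events, dtype=int)
    if len(np.unique(treat)) < 2:
        raise ValueError("both arms must be represented")
    if events.sum() == 0:
        return float("nan")
    if events[treat == 1].sum() == 0 or events[treat == 0].sum() == 0:
        # monotone partial likelihood: no finite MLE
        return float("nan")
    df = pd.DataFrame({"T": np.asarray(times, dtype=float),
                       "E": events, "treatment": treat})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except (_LLConvergenceError, np.linalg.LinAlgError):
        return float("nan")
    return float(np.exp(cph.params_["treatment"]))


def run_simulation(
    model: OSModel,
    subjects: pd.DataFrame,
    cfg: SimulationConfig,
) -> SimulationSummary:
    """Simulate ``cfg.n_replicates`` virtual studies and aggregate.

    ``subjects`` is one row per patient: canonical covariate columns plus
    ``log_kg`` and ``arm`` ("treatment"/"control").  The subject table is
    held fixed across replicates; parameters and outcomes are redrawn each
    replicate.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if "arm" not in subjects.columns or "log_kg" not in subjects.columns:
        raise ValueError("subjects needs 'arm' and 'log_kg' columns")
    arms = subjects["arm"].to_numpy()
    if not set(np.unique(arms)) <= {"treatment", "control"}:
        raise ValueError("arm must be 'treatment' or 'control'")
    cov_cols = subjects.drop(columns=["arm"])

    grid = np.asarray(cfg.time_grid, dtype=float)
    landmarks = tuple(cfg.landmark_times)
    arm_names = ("treatment", "control")
    arm_masks = {a: arms == a for a in arm_names}

    curves = {a: np.empty((cfg.n_replicates, len(grid))) for a in arm_names}
    rates = {a: np.empty((cfg.n_replicates, len(landmarks))) for a in arm_names}
    hrs = np.full(cfg.n_replicates, np.nan)

    for r in range(cfg.n_replicates):
        params = sample_parameters(model, cfg.uncertainty, rng, cfg.covariance)
        mu = _mu_for(model, cov_cols, params)
        scale = float(np.exp(params["log_scale"]))
        time, event = simulate_patient(mu, scale, cfg.censor_bounds, rng)
        for a in arm_names:
            m = arm_masks[a]
            kt, ks = km_estimate(time[m], event[m])
            curves[a][r] = km_at(kt, ks, grid)
            rates[a][r] = 100.0 * km_at(kt, ks, np.array(landmarks))
        hrs[r] = cox_hr(time, event, arms)

    qs = (50.0, 2.5, 97.5)
    curve_rows = []
    for a in arm_names:
        med, lo, hi = np.percentile(curves[a], qs, axis=0)
        for j, t in enumerate(grid):
            curve_rows.append((a, t, med[j], lo[j], hi[j]))
    curves_df = pd.DataFrame(
        curve_rows, columns=["arm", "time_days", "median", "lo", "hi"]
    )
    lm_rows = []
    for a in arm_names:
        med, lo, hi = np.percentile(rates[a], qs, axis=0)
        for j, t in enumerate(landmarks):
            lm_rows.append((a, t, med[j], lo[j], hi[j]))
    lm_df = pd.DataFrame(
        lm_rows, columns=["arm", "time_days", "median", "lo", "hi"]
    )
    ok = np.isfinite(hrs)
    n_failed = int((~ok).sum())
    if ok.any():
        hr_med, hr_lo, hr_hi = np.percentile(hrs[ok], qs)
    else:
        hr_med = hr_lo = hr_hi = float("nan")
    return SimulationSummary(
        time_grid=grid,
        curves=curves_df,
        landmark=lm_df,
        hr_median=float(hr_med),
        hr_pi=(float(hr_lo), float(hr_hi)),
        n_replicates=cfg.n_replicates,
        n_hr_failed=n_failed,
        replicate_hrs=hrs,
    )


def _mu_for(model: OSModel, subjects: pd.DataFrame, params: dict) -> np.ndarray:
    lk = subjects["log_kg"]
    if "subject_id" in subjects.columns:
        lk = subjects.set_index("subject_id")["log_kg"]
    return linear_predictor(model, subjects, log_kg=lk, betas=params)
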