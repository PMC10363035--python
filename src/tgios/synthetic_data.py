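"""Virtual-trial generator.

Emulates a two-arm, first-line ALK-positive NSCLC study: ~143 evaluable
subjects per arm, tumor assessments at baseline and every 8 weeks until
progression, death, or end of follow-up (up to 5 years), a small fraction of
subjects with baseline-only assessments, and overall survival generated from
the log-normal AFT model driven by each subject's *true* growth rate.

The default generating values are the published population estimates for
this design (tumor dynamics typicals/variabilities and AFT coefficients);
they are configuration, not claims about any particular dataset, and every
one of them can be overridden.  Hidden per-subject truths (individual TGI
parameters, AFT location, uncensored survival time) are kept alongside the
observed dataset so recovery experiments can compare estimates to truth, but
they are never written into the observed CSV files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tgios.os_model import OSModel, linear_predictor
from tgios.tgi_model import THETA_KEYS, ts_model
from tgios.trial_data import DAYS_PER_WEEK, TrialDataset, write_trial

#: Default tumor-dynamics generating values: typical growth/shrinkage rates
#: per arm (week^-1), typical baseline SLD (mm), log-scale random-effect
#: variances, and additive residual variance (mm^2).
DEFAULT_TGI_TRUTH = {
    "theta": {
        "kg_treatment": 0.00196,
        "ks_treatment": 0.0342,
        "kg_control": 0.00438,
        "ks_control": 0.0373,
        "ts0": 57.0,
    },
    "omega2": {
        "kg_treatment": 1.90,
        "ks_treatment": 0.943,
        "kg_control": 1.10,
        "ks_control": 0.833,
        "ts0": 0.436,
    },
    "sigma2": 42.5,
}

#: Default AFT generating coefficients (log-day scale) and their standard
#: errors.  Positive effects prolong survival.
DEFAULT_OS_COEFFICIENTS = pd.DataFrame(
    [
        ("intercept", 2.87, 0.164),
        ("log_kg", -0.642, 0.0224),
        ("albumin", 0.0262, 0.00274),
        ("ecog_ge1", -0.270, 0.0295),
        ("race_asian", 0.319, 0.0433),
        ("n_met_sites", -0.0733, 0.0147),
        ("nlr", -0.0138, 0.00263),
        ("liver_met_yes", -0.174, 0.0396),
        ("baseline_sld", -0.00122, 0.000318),
        ("line_2plus", -0.103, 0.0346),
        ("sex_female", 0.0840, 0.0300),
        ("log_scale", -0.225, 0.0155),
    ],
    columns=["parameter", "estimate", "se"],
)


def default_os_truth() -> OSModel:
    """The default AFT generating model as an :class:`OSModel`."""
    return OSModel.from_coefficients(DEFAULT_OS_COEFFICIENTS)


@dataclass
class CovariateSamplers:
    """Marginal distributions for the baseline prognostic factors.

    Chosen to be physiologically plausible for an advanced-NSCLC first-line
    population; all overridable.  Baseline SLD is not sampled here — it is
    the subject's generated true TS0.
    """

    albumin_mean: float = 40.0   # g/L
    albumin_sd: float = 4.0
    albumin_min: float = 20.0    # truncation: albumin > this
    p_ecog_ge1: float = 0.6
    p_asian: float = 0.45
    met_sites_rate: float = 1.5  # n_met_sites = 1 + Poisson(rate)
    nlr_log_mean: float = float(np.log(3.5))
    nlr_log_sd: float = 0.5
    p_liver_met: float = 0.2
    p_line_2plus: float = 0.0    # first-line study
    p_female: float = 0.55


@dataclass
class GeneratorConfig:
    """Study design and generating truths for one virtual trial."""

    n_per_arm: int = 143            # evaluable subjects per arm
    n_baseline_only: int = 17       # extra subjects with only a baseline scan
    visit_every_weeks: float = 8.0
    max_followup_weeks: float = 260.0
    tgi_truth: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_TGI_TRUTH)))
    os_truth: OSModel = field(default_factory=default_os_truth)
    covariates: CovariateSamplers = field(default_factory=CovariateSamplers)
    censor_bounds_days: tuple[float, float] = (1278.0, 1825.0)
    dropout_at_progression: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 0 or (self.n_per_arm == 0 and self.n_baseline_only == 0):
            raise ValueError("n_per_arm must be positive")
        if self.visit_every_weeks <= 0 or self.max_followup_weeks <= 0:
            raise ValueError("visit schedule must be increasing")

    @property
    def visit_schedule(self) -> np.ndarray:
        return np.arange(
            0.0, self.max_followup_weeks + 1e-9, self.visit_every_weeks
        )


@dataclass
class VirtualTrial:
    """Observed dataset plus hidden per-subject truths."""

    dataset: TrialDataset
    truth: pd.DataFrame  # subject_id, arm, ts0/kg/ks true, log_kg, mu, os_true

    def write(self, path: str | Path) -> dict:
        """Write tumor.csv / covariates.csv / os.csv plus truth.json."""
        paths = write_trial(self.dataset, path)
        tpath = Path(path) / "truth.json"
        tpath.write_text(
            json.dumps(self.truth.to_dict(orient="list"), indent=2, default=float)
        )
        paths["truth"] = tpath
        return paths


def sample_covariates(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_ids: list,
    baseline_sld: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample one covariate row per subject from the configured marginals.

    ``baseline_sld`` is normally the subjects' generated true TS0; when
    omitted it is drawn from the TS0 truth distribution.
    """
    cs = cfg.covariates
    n = len(subject_ids)
    if baseline_sld is None:
        th, om2 = cfg.tgi_truth["theta"], cfg.tgi_truth["omega2"]
        baseline_sld = np.exp(
            np.log(th["ts0"]) + np.sqrt(om2["ts0"]) * rng.standard_normal(n)
        )
    albumin = cs.albumin_mean + cs.albumin_sd * rng.standard_normal(n)
    # truncated normal by resampling the tail
    while (albumin <= cs.albumin_min).any():
        bad = albumin <= cs.albumin_min
        albumin[bad] = cs.albumin_mean + cs.albumin_sd * rng.standard_normal(bad.sum())
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "albumin": albumin,
            "ecog": (rng.random(n) < cs.p_ecog_ge1).astype(int),
            "race": np.where(rng.random(n) < cs.p_asian, "Asian", "non-Asian"),
            "n_met_sites": 1 + rng.poisson(cs.met_sites_rate, size=n),
            "nlr": np.exp(cs.nlr_log_mean + cs.nlr_log_sd * rng.standard_normal(n)),
            "liver_met": np.where(rng.random(n) < cs.p_liver_met, "yes", "no"),
            "baseline_sld": np.asarray(baseline_sld, dtype=float),
            "line_of_therapy": np.where(
                rng.random(n) < cs.p_line_2plus, "2+", "1"
            ),
            "sex": np.where(rng.random(n) < cs.p_female, "female", "male"),
        }
    )


def sample_tgi_params(
    cfg: GeneratorConfig, rng: np.random.Generator, arms: np.ndarray
) -> pd.DataFrame:
    """Draw true individual (ts0, kg, ks) log-normally around the typicals."""
    th = cfg.tgi_truth["theta"]
    om2 = cfg.tgi_truth["omega2"]
    n = len(arms)
    treat = arms == "treatment"
    kg_typ = np.where(treat, th["kg_treatment"], th["kg_control"])
    ks_typ = np.where(treat, th["ks_treatment"], th["ks_control"])
    om_kg = np.where(treat, om2["kg_treatment"], om2["kg_control"])
    om_ks = np.where(treat, om2["ks_treatment"], om2["ks_control"])
    kg = kg_typ * np.exp(np.sqrt(om_kg) * rng.standard_normal(n))
    ks = ks_typ * np.exp(np.sqrt(om_ks) * rng.standard_normal(n))
    ts0 = th["ts0"] * np.exp(np.sqrt(om2["ts0"]) * rng.standard_normal(n))
    return pd.DataFrame({"ts0": ts0, "kg": kg, "ks": ks,
                         "log_kg": np.log(kg)})


def generate_os(
    covariates: pd.DataFrame,
    log_kg: pd.Series | np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate OS outcomes from the AFT truth and uniform study-duration
    censoring.

    ``log_kg`` must be the subjects' *true* individual log growth rate (the
    generator side of the framework), not an estimate.  Returns the observed
    (subject_id, os_days, event) table and a truth table with the latent
    location mu and the uncensored survival time.
    """
    mu = linear_predictor(cfg.os_truth, covariates, log_kg=log_kg)
    scale = cfg.os_truth.scale
    n = len(mu)
    T = np.exp(mu + scale * rng.standard_normal(n))
    lo, hi = cfg.censor_bounds_days
    C = rng.uniform(lo, hi, size=n)
    os_days = np.maximum(np.minimum(T, C), 0.5)  # observed time, days
    event = (T <= C).astype(int)
    ids = covariates["subject_id"].to_numpy()
    obs = pd.DataFrame({"subject_id": ids, "os_days": os_days, "event": event})
    truth = pd.DataFrame({"subject_id": ids, "mu": mu, "os_true_days": T,
                          "censor_days": C})
    return obs, truth


def generate_trajectories(
    subjects: pd.DataFrame,
    params: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    stop_weeks: np.ndarray | None = None,
    baseline_only: np.ndarray | None = None,
) -> pd.DataFrame:
    """Noisy SLD observations on the visit schedule.

    ``subjects`` needs subject_id and arm; ``params`` the true individual
    TGI parameters (row-aligned).  Observations stop at ``stop_weeks``
    (typically the observed survival time), at detected progression (first
    visit where the true SLD exceeds the running nadir by 20% + 5 mm, if
    ``dropout_at_progression``), or at the end of follow-up.  Additive
    normal noise, truncated at 0 (SLD cannot be negative).  Subjects flagged
    ``baseline_only`` emit only their time-0 record.
    """
    schedule = cfg.visit_schedule
    sigma = float(np.sqrt(cfg.tgi_truth["sigma2"]))
    n = len(subjects)
    if stop_weeks is None:
        stop_weeks = np.full(n, np.inf)
    if baseline_only is None:
        baseline_only = np.zeros(n, dtype=bool)
    rows = []
    ids = subjects["subject_id"].to_numpy()
    arms = subjects["arm"].to_numpy()
    for i in range(n):
        p = (params["ts0"].iat[i], params["kg"].iat[i], params["ks"].iat[i])
        if baseline_only[i]:
            visits = schedule[:1]
        else:
            visits = schedule[schedule <= stop_weeks[i] + 1e-9]
            if len(visits) == 0:
                visits = schedule[:1]
        true_sld = np.atleast_1d(ts_model(visits, p))
        if cfg.dropout_at_progression and not baseline_only[i]:
            nadir = np.minimum.accumulate(true_sld)
            prog = np.nonzero(
                (true_sld > 1.2 * nadir + 5.0) & (np.arange(len(visits)) > 0)
            )[0]
            if len(prog):
                cut = prog[0] + 1  # progression visit itself is observed
                visits = visits[:cut]
                true_sld = true_sld[:cut]
        obs = np.maximum(true_sld + sigma * rng.standard_normal(len(visits)), 0.0)
        for t, y in zip(visits, obs):
            rows.append((ids[i], arms[i], float(t), float(y)))
    return pd.DataFrame(rows, columns=["subject_id", "arm", "time_weeks", "sld_mm"])


def generate_trial(cfg: GeneratorConfig | None = None,
                   seed: int | None = None) -> VirtualTrial:
    """Generate a complete virtual trial (covariates, SLD series, OS).

    Deterministic given the seed (``seed`` overrides ``cfg.seed``).
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    n_eval = 2 * cfg.n_per_arm
    n_total = n_eval + cfg.n_baseline_only
    ids = [f"S{i + 1:04d}" for i in range(n_total)]
    arms = np.array(
        ["treatment", "control"] * (n_total // 2 + 1), dtype=object
    )[:n_total]
    baseline_only = np.zeros(n_total, dtype=bool)
    baseline_only[n_eval:] = True

    params = sample_tgi_params(cfg, rng, arms)
    covs = sample_covariates(cfg, rng, ids, baseline_sld=params["ts0"].to_numpy())
    os_obs, os_truth = generate_os(covs, params["log_kg"].to_numpy(), cfg, rng)

    subjects = pd.DataFrame({"subject_id": ids, "arm": arms})
    stop_weeks = os_obs["os_days"].to_numpy() / DAYS_PER_WEEK
    tumor = generate_trajectories(
        subjects, params, cfg, rng, stop_weeks=stop_weeks,
        baseline_only=baseline_only,
    )

    dataset = TrialDataset(tumor=tumor, covariates=covs, os=os_obs)
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "arm": arms,
            "ts0": params["ts0"],
            "kg": params["kg"],
            "ks": params["ks"],
            "log_kg": params["log_kg"],
            "mu": os_truth["mu"],
            "os_true_days": os_truth["os_true_days"],
            "censor_days": os_truth["censor_days"],
            "baseline_only": baseline_only,
        }
    )
    return VirtualTrial(dataset=dataset, truth=truth)
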