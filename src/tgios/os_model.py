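"""Log-normal accelerated-failure-time model for overall survival.

Survival time T (days) is modeled as log T ~ Normal(mu, scale^2), with the
location a linear function of the individual tumor growth rate (natural log
of KG, week^-1, from the TGI model's empirical-Bayes estimates) plus baseline
prognostic factors:

    mu = b0 + b_logKG*log(KG) + b_alb*albumin + b_ecog*1[ECOG >= 1]
         + b_race*1[Asian] + b_met*min(n_met_sites, 5) + b_nlr*NLR
         + b_liver*1[liver met] + b_sld*baseline SLD + b_line*1[line 2+]
         + b_sex*1[female]

so S(t) = 1 - Phi((ln t - mu)/scale).  Fitting is censored maximum
likelihood; standard errors come from the observed information at the MLE,
with Wald z statistics and two-sided p-values per coefficient.  The scale is
estimated on the log scale (log(scale) is reported, as is conventional for
AFT software output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from tgios.trial_data import cap_met_sites

#: Covariate order of the linear predictor.  ``log_kg`` is mandatory; the
#: remaining names match the canonical covariate table after design coding.
COVARIATE_ORDER = [
    "log_kg",
    "albumin",
    "ecog_ge1",
    "race_asian",
    "n_met_sites",
    "nlr",
    "liver_met_yes",
    "baseline_sld",
    "line_2plus",
    "sex_female",
]

#: Reference level per categorical covariate (the level coded 0).
DESIGN_CODING = {
    "ecog_ge1": "ECOG >= 1 vs 0",
    "race_asian": "Asian vs non-Asian",
    "liver_met_yes": "liver metastasis yes vs no",
    "line_2plus": "line of therapy 2+ vs 1",
    "sex_female": "female vs male",
}


@dataclass(frozen=True)
class CovariateEffect:
    """One coefficient of the AFT location model, with Wald inference."""

    name: str
    beta: float
    se: float
    z: float
    p: float


@dataclass
class OSModel:
    """Fitted (or externally supplied) log-normal AFT survival model."""

    intercept: CovariateEffect
    effects: list[CovariateEffect]  # ordered as COVARIATE_ORDER (subset allowed)
    log_scale: CovariateEffect
    design_coding: dict = field(default_factory=lambda: dict(DESIGN_CODING))
    loglik: float = float("nan")
    n_events: int = 0
    n_subjects: int = 0
    dropped_constant: list = field(default_factory=list)

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale.beta))

    @property
    def covariate_names(self) -> list[str]:
        return [e.name for e in self.effects]

    def coefficients(self) -> pd.DataFrame:
        rows = [self.intercept, *self.effects, self.log_scale]
        return pd.DataFrame(
            {
                "parameter": [r.name for r in rows],
                "estimate": [r.beta for r in rows],
                "se": [r.se for r in rows],
                "z": [r.z for r in rows],
                "p": [r.p for r in rows],
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "coefficients": self.coefficients().to_dict(orient="records"),
            "design_coding": self.design_coding,
            "loglik": self.loglik,
            "n_events": self.n_events,
            "n_subjects": self.n_subjects,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OSModel":
        text = str(source)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except OSError:  # raw JSON text, not a path
            pass
        doc = json.loads(text)
        coefs = pd.DataFrame(doc["coefficients"])
        m = cls.from_coefficients(coefs)
        m.design_coding = doc.get("design_coding", dict(DESIGN_CODING))
        m.loglik = doc.get("loglik", float("nan"))
        m.n_events = doc.get("n_events", 0)
        m.n_subjects = doc.get("n_subjects", 0)
        return m

    @classmethod
    def from_coefficients(cls, table: pd.DataFrame | str | Path) -> "OSModel":
        """Build a model from a plain coefficient table (no refit needed).

        The table needs ``parameter`` and ``estimate`` columns; ``se`` is
        optional (defaults to 0, i.e. no parameter uncertainty).  Parameter
        names: ``intercept``, ``log_scale``, and entries of
        :data:`COVARIATE_ORDER`.
        """
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table)
        table = table.copy()
        if "se" not in table.columns:
            table["se"] = 0.0

        def _mk(row) -> CovariateEffect:
            beta = float(row["estimate"])
            se = float(row["se"])
            z = beta / se if se > 0 else float("nan")
            p = float(2 * norm.sf(abs(z))) if se > 0 else float("nan")
            if "z" in row and np.isfinite(row.get("z", np.nan)):
                z = float(row["z"])
            if "p" in row and np.isfinite(row.get("p", np.nan)):
                p = float(row["p"])
            return CovariateEffect(str(row["parameter"]), beta, se, z, p)

        by_name = {str(r["parameter"]): r for _, r in table.iterrows()}
        if "intercept" not in by_name or "log_scale" not in by_name:
            raise ValueError("coefficient table must contain intercept and log_scale")
        effects = [
            _mk(by_name[name]) for name in COVARIATE_ORDER if name in by_name
        ]
        extra = (
            set(by_name) - {"intercept", "log_scale"} - set(COVARIATE_ORDER)
        )
        if extra:
            raise ValueError(f"unknown coefficient names: {sorted(extra)}")
        return cls(
            intercept=_mk(by_name["intercept"]),
            effects=effects,
            log_scale=_mk(by_name["log_scale"]),
        )


def design_matrix(
    covariates: pd.DataFrame,
    log_kg: pd.Series | np.ndarray | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Design-code the covariate table into the AFT model's columns.

    ``covariates`` follows the canonical schema (see ``trial_data``);
    ``log_kg`` is the natural log of the subject's KG (week^-1), aligned by
    ``subject_id`` when given as a Series.  Missing values raise with the
    offending covariate named.
    """
    names = list(COVARIATE_ORDER) if names is None else list(names)
    df = covariates.set_index("subject_id") if "subject_id" in covariates else covariates
    out = pd.DataFrame(index=df.index)
    if "log_kg" in names:
        if log_kg is None:
            raise ValueError("missing covariate: log_kg")
        if isinstance(log_kg, pd.Series):
            out["log_kg"] = log_kg.reindex(df.index)
        else:
            out["log_kg"] = np.asarray(log_kg, dtype=float)
    built = {
        "albumin": lambda d: d["albumin"].astype(float),
        "ecog_ge1": lambda d: (d["ecog"].astype(int) >= 1).astype(float),
        "race_asian": lambda d: (d["race"] == "Asian").astype(float),
        "n_met_sites": lambda d: cap_met_sites(d["n_met_sites"].to_numpy()).astype(float),
        "nlr": lambda d: d["nlr"].astype(float),
        "liver_met_yes": lambda d: (d["liver_met"] == "yes").astype(float),
        "baseline_sld": lambda d: d["baseline_sld"].astype(float),
        "line_2plus": lambda d: (d["line_of_therapy"] == "2+").astype(float),
        "sex_female": lambda d: (d["sex"] == "female").astype(float),
    }
    source_col = {
        "albumin": "albumin", "ecog_ge1": "ecog", "race_asian": "race",
        "n_met_sites": "n_met_sites", "nlr": "nlr", "liver_met_yes": "liver_met",
        "baseline_sld": "baseline_sld", "line_2plus": "line_of_therapy",
        "sex_female": "sex",
    }
    for name in names:
        if name == "log_kg":
            continue
        col = source_col[name]
        if col not in df.columns:
            raise ValueError(f"missing covariate: {col}")
        out[name] = np.asarray(built[name](df))
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing covariate value(s) in: {bad}")
    return out


def linear_predictor(
    model: OSModel,
    covariates: pd.DataFrame,
    log_kg: pd.Series | np.ndarray | None = None,
    betas: dict | None = None,
) -> np.ndarray:
    """Location mu on the log(days) scale per subject.

    ``betas`` optionally overrides the model's coefficients (used by the
    simulator when parameters are redrawn from their uncertainty); keys are
    coefficient names including ``intercept``.
    """
    X = design_matrix(covariates, log_kg, names=model.covariate_names)
    if betas is None:
        b0 = model.intercept.beta
        bvec = np.array([e.beta for e in model.effects])
    else:
        b0 = betas["intercept"]
        bvec = np.array([betas[n] for n in model.covariate_names])
    mu = b0 + X.to_numpy() @ bvec
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite linear predictor")
    return mu


def survival_function(mu, scale: float, t) -> np.ndarray | float:
    """Log-normal survivor function S(t) = 1 - Phi((ln t - mu)/scale)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    t = np.asarray(t, dtype=float)
    if (t <= 0).any():
        raise ValueError("t must be > 0")
    z = (np.log(t) - np.asarray(mu)) / scale
    out = ndtr(-z)
    return float(out) if out.ndim == 0 else out


def _nll_and_grad(params, X, log_t, event):
    """Censored log-normal negative log-likelihood and analytic gradient.

    params = [intercept, betas..., log_scale]; X includes no intercept column.
    """
    b0 = params[0]
    betas = params[1:-1]
    log_s = params[-1]
    s = np.exp(log_s)
    mu = b0 + X @ betas
    z = (log_t - mu) / s
    ll_ev = -log_t - log_s - 0.5 * np.log(2 * np.pi) - 0.5 * z**2
    ll_cen = log_ndtr(-z)
    ll = np.where(event, ll_ev, ll_cen)

    # d ll / d mu and d ll / d log(scale)
    phi_over_sf = np.exp(norm.logpdf(z) - log_ndtr(-z))
    dmu = np.where(event, z / s, phi_over_sf / s)
    dls = np.where(event, z**2 - 1.0, z * phi_over_sf)
    grad = np.empty_like(params)
    grad[0] = dmu.sum()
    grad[1:-1] = X.T @ dmu
    grad[-1] = dls.sum()
    return -float(ll.sum()), -grad


def _numeric_hessian(fun, x, step=1e-5):
    """Hessian of a scalar function via central differences of its gradient."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        _, gp = fun(x + e)
        _, gm = fun(x - e)
        H[i] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def fit_os(
    os_records: pd.DataFrame,
    covariates: pd.DataFrame,
    log_kg: pd.Series,
    covariate_names: list[str] | None = None,
    drop_constant: bool = True,
) -> OSModel:
    """Fit the log-normal AFT model by censored maximum likelihood.

    Parameters
    ----------
    os_records
        subject_id, os_days (> 0), event (1 = death, 0 = censored).
    covariates
        Canonical covariate table; joined to ``os_records`` on subject_id.
    log_kg
        Natural log of individual KG (week^-1), indexed by subject_id —
        typically the EBE column ``log_kg`` of a population TGI fit.
    covariate_names
        Subset of :data:`COVARIATE_ORDER` to include (default: all).
    drop_constant
        Exclude zero-variance covariates (unidentifiable in this sample,
        e.g. line of therapy in a strictly first-line trial); the dropped
        names are recorded on the returned model.

    Raises
    ------
    ValueError
        If there are no events, or the design matrix is singular
        (the collinear columns are named).
    """
    from scipy.optimize import minimize

    names = list(COVARIATE_ORDER) if covariate_names is None else list(covariate_names)
    osr = os_records.set_index("subject_id")
    if isinstance(log_kg, pd.Series):
        # subjects without an individual growth-rate estimate (e.g. not TGI
        # evaluable) cannot enter the survival model
        covariates = covariates[
            covariates["subject_id"].isin(log_kg.dropna().index)
        ]
    X_df = design_matrix(covariates, log_kg, names=names)
    common = X_df.index.intersection(osr.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between OS records and covariates")
    X_df = X_df.loc[common]
    osr = osr.loc[common]
    dropped = []
    if drop_constant:
        for name in [n for n in names if n != "log_kg"]:
            if X_df[name].nunique() <= 1:
                dropped.append(name)
        if dropped:
            names = [n for n in names if n not in dropped]
            X_df = X_df[names]
    event = osr["event"].to_numpy().astype(bool)
    if event.sum() == 0:
        raise ValueError("no events: AFT model cannot be fitted")
    log_t = np.log(osr["os_days"].to_numpy(dtype=float))
    X = X_df.to_numpy(dtype=float)

    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [np.ones(len(X))]
        for j, name in enumerate(names):
            cand = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(cand) == len(cols):
                bad.append(name)
            else:
                cols.append(X[:, j])
        raise ValueError(f"singular design: collinear column(s) {bad}")

    # start from the uncensored least-squares solution
    beta0, *_ = np.linalg.lstsq(Xc, log_t, rcond=None)
    resid = log_t - Xc @ beta0
    s0 = max(float(np.std(resid)), 1e-3)
    x0 = np.concatenate([beta0, [np.log(s0)]])

    res = minimize(
        _nll_and_grad, x0, args=(X, log_t, event), jac=True, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise ValueError("AFT fit failed: non-finite likelihood")
    x_hat = res.x
    H = _numeric_hessian(lambda p: _nll_and_grad(p, X, log_t, event), x_hat)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    def _eff(i, name):
        z = x_hat[i] / se[i] if se[i] > 0 else float("nan")
        p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else float("nan")
        return CovariateEffect(name, float(x_hat[i]), float(se[i]), float(z), p)

    effects = [_eff(1 + j, name) for j, name in enumerate(names)]
    return OSModel(
        intercept=_eff(0, "intercept"),
        effects=effects,
        log_scale=_eff(len(x_hat) - 1, "log_scale"),
        loglik=-float(res.fun),
        n_events=int(event.sum()),
        n_subjects=len(common),
        dropped_constant=dropped,
    )


def aft_loglik(model: OSModel, os_records: pd.DataFrame,
               covariates: pd.DataFrame, log_kg: pd.Series) -> float:
    """Censored log-likelihood of ``os_records`` under a fitted model."""
    osr = os_records.set_index("subject_id")
    mu = linear_predictor(model, covariates, log_kg)
    X_df = design_matrix(covariates, log_kg, names=model.covariate_names)
    osr = osr.loc[X_df.index]
    log_t = np.log(osr["os_days"].to_numpy(dtype=float))
    event = osr["event"].to_numpy().astype(bool)
    s = model.scale
    z = (log_t - mu) / s
    ll = np.where(
        event,
        -log_t - np.log(s) - 0.5 * np.log(2 * np.pi) - 0.5 * z**2,
        log_ndtr(-z),
    )
    return float(ll.sum())


def select_covariates(
    os_records: pd.DataFrame,
    covariates: pd.DataFrame,
    log_kg: pd.Series,
    candidates: list[str] | None = None,
    alpha: float = 0.01,
) -> tuple[OSModel, list[dict]]:
    """Backward elimination of AFT covariates by Wald p-value.

    Starting from the full candidate set (which must include ``log_kg``;
    the tumor growth rate is the model's anchor and is never dropped), the
    least significant covariate with p >= ``alpha`` is removed and the model
    refitted, until all remaining covariates are significant.  Returns the
    final model and the elimination trace.
    """
    names = list(candidates or COVARIATE_ORDER)
    if "log_kg" not in names:
        raise ValueError("candidate set must include log_kg")
    trace: list[dict] = []
    while True:
        model = fit_os(os_records, covariates, log_kg, covariate_names=names)
        droppable = [e for e in model.effects if e.name != "log_kg"]
        worst = max(droppable, key=lambda e: e.p, default=None)
        if worst is None or worst.p < alpha:
            return model, trace
        trace.append({"dropped": worst.name, "p": worst.p,
                      "remaining": [n for n in names if n != worst.name]})
        names.remove(worst.name)
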