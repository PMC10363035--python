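"""Biexponential tumor-size model and population nonlinear mixed-effects fit.

Structural model for the sum of longest diameters (SLD, mm) at time ``t``
(weeks, 0 = treatment start), with growth rate constant ``KG`` and shrinkage
rate constant ``KS`` (both week^-1)::

    TS(t) = TS0 * exp(KG * t)                          t < 0
    TS(t) = TS0 * [exp(-KS * t) + exp(KG * t) - 1]     t >= 0

Pre-treatment the tumor grows exponentially; on treatment the observed size
is the sum of a shrinking (treatment-sensitive) and a growing (resistant)
component, which produces the characteristic decline-nadir-regrowth shape
whenever KS > KG.

Population model: individual log-parameters are the log typical values plus
subject-level normal random effects (log-normal inter-individual
variability).  KG and KS variability is arm-specific; TS0 shares a common
distribution across arms.  Residual error is additive normal.  The marginal
likelihood is maximized with a Laplace approximation: for each subject the
random-effect posterior mode is located by a damped Newton solver (analytic
gradients and Hessians), and the mode's curvature supplies the Gaussian
integral correction.  Empirical-Bayes estimates (EBEs) are those posterior
modes; eta-shrinkage quantifies how strongly they collapse toward the
typical values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tgios.trial_data import ARMS

THETA_KEYS = ["kg_treatment", "ks_treatment", "kg_control", "ks_control", "ts0"]
# random-effect component order used throughout this module
ETA_COMPONENTS = ["ts0", "kg", "ks"]

_EXP_CLIP = 60.0  # guard against overflow while the optimizer explores
_ETA_CLIP = 25.0  # random effects live well inside this on the log scale
_PENALTY = 1e30   # returned for non-finite likelihoods; dominates any real value


class ConvergenceError(RuntimeError):
    """Population fit failed to converge; ``trace`` holds per-start details."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class TGIIndividualParams:
    """Individual tumor-dynamics parameters (log-normal support: all > 0)."""

    ts0: float  # model-estimated SLD at treatment start, mm
    kg: float   # growth rate constant, week^-1
    ks: float   # shrinkage rate constant, week^-1

    def __post_init__(self):
        if not (self.ts0 > 0 and self.kg > 0 and self.ks > 0):
            raise ValueError("ts0, kg, ks must all be strictly positive")


def ts_model(t, p: TGIIndividualParams | tuple) -> np.ndarray | float:
    """Evaluate the biexponential tumor-size model at time(s) ``t`` (weeks).

    Continuous at t = 0 (both branches equal TS0).  Accepts a scalar or
    array ``t`` and either a :class:`TGIIndividualParams` or a
    ``(ts0, kg, ks)`` tuple.
    """
    if isinstance(p, TGIIndividualParams):
        ts0, kg, ks = p.ts0, p.kg, p.ks
    else:
        ts0, kg, ks = p
    t = np.asarray(t, dtype=float)
    grow = np.exp(np.clip(kg * t, -_EXP_CLIP, _EXP_CLIP))
    shrink = np.exp(np.clip(-ks * t, -_EXP_CLIP, _EXP_CLIP))
    out = np.where(t < 0, ts0 * grow, ts0 * (shrink + grow - 1.0))
    return float(out) if out.ndim == 0 else out


def nadir_time(p: TGIIndividualParams) -> float:
    """Time of minimum on-treatment tumor size: ln(KS/KG)/(KS+KG), weeks.

    Only meaningful when KS > KG (the curve actually dips before regrowth).
    """
    return float(np.log(p.ks / p.kg) / (p.ks + p.kg))


# ---------------------------------------------------------------------------
# stacked (padded) representation of the longitudinal data


@dataclass
class _Stacked:
    subject_ids: np.ndarray      # (S,) original identifiers
    arm_idx: np.ndarray          # (S,) 0 = treatment, 1 = control
    t: np.ndarray                # (S, N) padded times
    y: np.ndarray                # (S, N) padded observations
    mask: np.ndarray             # (S, N) True where a real observation sits
    n_obs: np.ndarray            # (S,)


def _stack(tumor: pd.DataFrame, include_screening: bool = True) -> _Stacked:
    df = tumor if include_screening else tumor[tumor["time_weeks"] >= 0]
    groups = list(df.groupby("subject_id", sort=True))
    S = len(groups)
    if S == 0:
        raise ValueError("no tumor records to fit")
    nmax = max(len(g) for _, g in groups)
    t = np.zeros((S, nmax))
    y = np.zeros((S, nmax))
    mask = np.zeros((S, nmax), dtype=bool)
    arm_idx = np.zeros(S, dtype=int)
    ids = []
    for s, (sid, g) in enumerate(groups):
        n = len(g)
        t[s, :n] = g["time_weeks"].to_numpy()
        y[s, :n] = g["sld_mm"].to_numpy()
        mask[s, :n] = True
        arm_idx[s] = ARMS.index(g["arm"].iloc[0])
        ids.append(sid)
    return _Stacked(np.array(ids, dtype=object), arm_idx, t, y, mask,
                    mask.sum(axis=1))


def _subject_params(stk: _Stacked, theta: np.ndarray, eta: np.ndarray):
    """Individual (ts0, kg, ks), each (S, 1), from typicals and etas."""
    kg_typ = np.where(stk.arm_idx == 0, theta[0], theta[2])[:, None]
    ks_typ = np.where(stk.arm_idx == 0, theta[1], theta[3])[:, None]
    ts0_typ = theta[4]
    ts0 = ts0_typ * np.exp(eta[:, 0:1])
    kg = kg_typ * np.exp(eta[:, 1:2])
    ks = ks_typ * np.exp(eta[:, 2:3])
    return ts0, kg, ks


def _predict_and_derivs(stk: _Stacked, ts0, kg, ks, second: bool = False):
    """Model values and derivatives w.r.t. the etas (chain rule through
    the log-normal parameterization: d(param)/d(eta) = param)."""
    t = stk.t
    kgt = np.clip(kg * t, -_EXP_CLIP, _EXP_CLIP)
    kst = np.clip(-ks * t, -_EXP_CLIP, _EXP_CLIP)
    a = np.exp(kgt)          # growth term
    b = np.exp(kst)          # shrinkage term
    pre = t < 0
    f = np.where(pre, ts0 * a, ts0 * (b + a - 1.0))
    d_kg = ts0 * t * kg * a                       # same form on both branches
    d_ks = np.where(pre, 0.0, -ts0 * t * ks * b)
    J = np.stack([f, d_kg, d_ks], axis=-1)        # (S, N, 3): [ts0, kg, ks]
    J = J * stk.mask[..., None]
    if not second:
        return f, J, None
    h_kk = ts0 * t * kg * a * (1.0 + t * kg)
    h_ss = np.where(pre, 0.0, -ts0 * t * ks * b * (1.0 - t * ks))
    # full symmetric second-derivative tensor per observation
    S_, N = t.shape
    H2 = np.zeros((S_, N, 3, 3))
    H2[..., 0, 0] = f
    H2[..., 0, 1] = H2[..., 1, 0] = d_kg
    H2[..., 0, 2] = H2[..., 2, 0] = d_ks
    H2[..., 1, 1] = h_kk
    H2[..., 2, 2] = h_ss
    H2 *= stk.mask[..., None, None]
    return f, J, H2


def _gval(stk: _Stacked, theta, eta, inv_om2, sigma2):
    ts0, kg, ks = _subject_params(stk, theta, eta)
    f, _, _ = _predict_and_derivs(stk, ts0, kg, ks)
    r = np.where(stk.mask, stk.y - f, 0.0)
    return 0.5 * np.sum(r * r, axis=1) / sigma2 + 0.5 * np.sum(
        eta * eta * inv_om2, axis=1
    )


def _solve_modes(stk: _Stacked, theta, om2, sigma2, eta0,
                 tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """Posterior modes of the random effects, all subjects simultaneously.

    Damped Newton using the Gauss-Newton Hessian (always positive definite),
    with per-subject backtracking line search.
    """
    eta = np.clip(eta0, -_ETA_CLIP, _ETA_CLIP)
    inv_om2 = 1.0 / om2
    g = _gval(stk, theta, eta, inv_om2, sigma2)
    # a stale warm start can sit in overflow territory for the new typicals
    stale = ~np.isfinite(g)
    if stale.any():
        eta[stale] = 0.0
        g = _gval(stk, theta, eta, inv_om2, sigma2)
    for _ in range(max_iter):
        ts0, kg, ks = _subject_params(stk, theta, eta)
        f, J, H2 = _predict_and_derivs(stk, ts0, kg, ks, second=True)
        r = np.where(stk.mask, stk.y - f, 0.0)
        grad = -np.einsum("snk,sn->sk", J, r) / sigma2 + eta * inv_om2
        finite = np.isfinite(grad).all(axis=1)
        H_gn = np.einsum("snk,snl->skl", J, J) / sigma2
        H_gn[:, np.arange(3), np.arange(3)] += inv_om2
        # prefer the full Newton Hessian where positive definite (the
        # Gauss-Newton approximation can crawl along curved valleys)
        H_full = H_gn - np.einsum("sn,snkl->skl", r, H2) / sigma2
        with np.errstate(invalid="ignore"):
            d1 = H_full[:, 0, 0]
            d2 = d1 * H_full[:, 1, 1] - H_full[:, 0, 1] ** 2
            d3 = np.linalg.det(H_full)
            pd_full = (
                (d1 > 0) & (d2 > 0) & (d3 > 0)
                & np.isfinite(H_full).all(axis=(1, 2))
            )
        H = np.where(pd_full[:, None, None], H_full, H_gn)
        delta = np.zeros_like(eta)
        okH = finite & np.isfinite(H).all(axis=(1, 2))
        if okH.any():
            Hok = H[okH]
            ridge = 0.0
            for _attempt in range(6):
                try:
                    Hr = Hok.copy()
                    Hr[:, np.arange(3), np.arange(3)] += ridge
                    delta[okH] = np.linalg.solve(Hr, -grad[okH][..., None])[..., 0]
                    break
                except np.linalg.LinAlgError:
                    ridge = max(ridge * 10.0, 1e-6)
        delta[~np.isfinite(delta).all(axis=1)] = 0.0
        # Newton decrement: scale-free per-subject convergence measure
        dec = -np.einsum("sk,sk->s", grad, delta)
        active = np.isfinite(dec) & (dec > tol * (1.0 + np.abs(g)))
        if not active.any():
            break
        delta[~active] = 0.0
        alpha = np.ones(len(eta))
        g_new = g
        for _ in range(35):
            eta_new = np.clip(eta + alpha[:, None] * delta, -_ETA_CLIP, _ETA_CLIP)
            g_new = _gval(stk, theta, eta_new, inv_om2, sigma2)
            worse = active & ~(g_new <= g + 1e-14)
            if not worse.any():
                break
            alpha[worse] *= 0.5
        accept = active & (g_new <= g)
        if not accept.any():
            break
        eta = np.where(accept[:, None], eta_new, eta)
        g = np.where(accept, g_new, g)
    return eta


def _laplace_loglik(stk: _Stacked, theta, om2, sigma2, eta):
    """Laplace-approximate marginal log-likelihood at given modes."""
    inv_om2 = 1.0 / om2
    ts0, kg, ks = _subject_params(stk, theta, eta)
    f, J, H2 = _predict_and_derivs(stk, ts0, kg, ks, second=True)
    r = np.where(stk.mask, stk.y - f, 0.0)
    g = 0.5 * np.sum(r * r, axis=1) / sigma2 + 0.5 * np.sum(
        eta * eta * inv_om2, axis=1
    )
    H_gn = np.einsum("snk,snl->skl", J, J) / sigma2
    H_gn[:, np.arange(3), np.arange(3)] += inv_om2
    # full Hessian of the inner objective (adds the curvature of the model)
    H_full = H_gn - np.einsum("sn,snkl->skl", r, H2) / sigma2
    sign, logdet = np.linalg.slogdet(H_full)
    sign_gn, logdet_gn = np.linalg.slogdet(H_gn)
    bad = (sign <= 0) | ~np.isfinite(logdet)
    logdet = np.where(bad, logdet_gn, logdet)
    ll = (
        -0.5 * stk.n_obs * np.log(2.0 * np.pi * sigma2)
        - 0.5 * np.sum(np.log(om2), axis=1)
        - g
        - 0.5 * logdet
    )
    return float(np.sum(ll))


def _inner_hessian(stk: _Stacked, theta, om2, sigma2, eta) -> np.ndarray:
    """Hessian of the inner objective at ``eta`` (full Newton version,
    Gauss-Newton fallback where indefinite)."""
    inv_om2 = 1.0 / om2
    ts0, kg, ks = _subject_params(stk, theta, eta)
    f, J, H2 = _predict_and_derivs(stk, ts0, kg, ks, second=True)
    r = np.where(stk.mask, stk.y - f, 0.0)
    H_gn = np.einsum("snk,snl->skl", J, J) / sigma2
    H_gn[:, np.arange(3), np.arange(3)] += inv_om2
    H_full = H_gn - np.einsum("sn,snkl->skl", r, H2) / sigma2
    with np.errstate(invalid="ignore"):
        d1 = H_full[:, 0, 0]
        d2 = d1 * H_full[:, 1, 1] - H_full[:, 0, 1] ** 2
        d3 = np.linalg.det(H_full)
        pd_full = (
            (d1 > 0) & (d2 > 0) & (d3 > 0)
            & np.isfinite(H_full).all(axis=(1, 2))
        )
    return np.where(pd_full[:, None, None], H_full, H_gn)


def _agq_loglik(stk: _Stacked, theta, om2, sigma2, eta, n_nodes: int = 5):
    """Adaptive Gauss-Hermite marginal log-likelihood.

    Tensor-product quadrature centered at each subject's posterior mode and
    scaled by the mode curvature; with one node this reduces to the Laplace
    approximation, with more nodes it corrects for non-Gaussian posterior
    mass (important with large inter-individual variability).
    """
    from numpy.polynomial.hermite import hermgauss

    x, w = hermgauss(n_nodes)
    E = np.array(np.meshgrid(x, x, x, indexing="ij")).reshape(3, -1)  # (3, M)
    W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    sumE2 = np.sum(E**2, axis=0)

    H = _inner_hessian(stk, theta, om2, sigma2, eta)
    try:
        cov = np.linalg.inv(H)
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    # quadrature points: (S, M, 3)
    pts = eta[:, None, :] + np.sqrt(2.0) * np.einsum("skl,lm->smk", L, E)
    S, M = pts.shape[0], pts.shape[1]
    inv_om2 = 1.0 / om2

    # evaluate the inner objective at every point, vectorized over S*M
    kg_typ = np.where(stk.arm_idx == 0, theta[0], theta[2])[:, None, None]
    ks_typ = np.where(stk.arm_idx == 0, theta[1], theta[3])[:, None, None]
    ts0 = theta[4] * np.exp(pts[..., 0:1])          # (S, M, 1)
    kg = kg_typ * np.exp(pts[..., 1:2])
    ks = ks_typ * np.exp(pts[..., 2:3])
    t = stk.t[:, None, :]                            # (S, 1, N)
    a = np.exp(np.clip(kg * t, -_EXP_CLIP, _EXP_CLIP))
    b = np.exp(np.clip(-ks * t, -_EXP_CLIP, _EXP_CLIP))
    f = np.where(t < 0, ts0 * a, ts0 * (b + a - 1.0))
    r = np.where(stk.mask[:, None, :], stk.y[:, None, :] - f, 0.0)
    g = 0.5 * np.sum(r * r, axis=-1) / sigma2 + 0.5 * np.sum(
        pts**2 * inv_om2[:, None, :], axis=-1
    )  # (S, M)

    logint = -g + sumE2[None, :]
    c = np.max(logint, axis=1)
    with np.errstate(divide="ignore"):
        log_quad = c + np.log(np.einsum("m,sm->s", W, np.exp(logint - c[:, None])))
    sign, logdet_cov = np.linalg.slogdet(cov)
    log_jac = 0.5 * (3 * np.log(2.0) + logdet_cov)
    ll = (
        -0.5 * stk.n_obs * np.log(2.0 * np.pi * sigma2)
        - 0.5 * np.sum(np.log(2.0 * np.pi * om2), axis=1)
        + log_quad
        + log_jac
    )
    return float(np.sum(ll))


def marginal_loglik(
    tumor: pd.DataFrame,
    theta: dict,
    omega2: dict,
    sigma2: float,
    include_screening: bool = True,
    method: str = "laplace",
    n_nodes: int = 5,
) -> float:
    """Marginal log-likelihood of tumor records at fixed parameters.

    ``theta`` and ``omega2`` are keyed by :data:`THETA_KEYS`.  ``method`` is
    ``"laplace"`` or ``"agq"`` (adaptive Gauss-Hermite with ``n_nodes`` per
    dimension).  Useful for likelihood checks against independent
    integration.
    """
    stk = _stack(tumor, include_screening)
    th = np.array([theta[k] for k in THETA_KEYS])
    om2 = _omega2_per_subject(stk, np.array([omega2[k] for k in THETA_KEYS]))
    eta = _solve_modes(stk, th, om2, sigma2, np.zeros((len(stk.n_obs), 3)))
    if method == "agq":
        return _agq_loglik(stk, th, om2, sigma2, eta, n_nodes)
    return _laplace_loglik(stk, th, om2, sigma2, eta)


def _omega2_per_subject(stk: _Stacked, om2_vec: np.ndarray) -> np.ndarray:
    """(S, 3) variance array in eta order [ts0, kg, ks] from the 5-vector
    [kg_t, ks_t, kg_c, ks_c, ts0]."""
    om_kg = np.where(stk.arm_idx == 0, om2_vec[0], om2_vec[2])
    om_ks = np.where(stk.arm_idx == 0, om2_vec[1], om2_vec[3])
    om_ts0 = np.full(len(stk.arm_idx), om2_vec[4])
    return np.stack([om_ts0, om_kg, om_ks], axis=1)


# ---------------------------------------------------------------------------
# population fit


@dataclass
class FitSettings:
    """Estimation controls for :func:`fit_population`.

    ``include_screening``: use pre-treatment (t < 0) scans via the growth
    branch.  ``fix_omega2_zero``: drop the random effects entirely and fit
    the typical values by maximum likelihood (nonlinear regression) — the
    limiting case of the mixed model as all variances go to zero.
    """

    include_screening: bool = True
    fix_omega2_zero: bool = False
    method: str = "laplace"   # marginal likelihood: "laplace" or "agq"
    agq_nodes: int = 5        # quadrature nodes per dimension for "agq"
    max_iter: int = 500
    ftol: float = 1e-10
    gtol: float = 1e-7
    n_starts: int = 3
    seed: int = 12345
    compute_rse: bool = True


@dataclass
class PopulationTGIFit:
    """Population TGI fit: typical values, variabilities, EBEs, diagnostics."""

    theta: dict            # typical values, keys THETA_KEYS
    omega2: dict           # random-effect variances (log scale), same keys
    sigma2: float          # additive residual variance, mm^2
    rse: dict              # relative standard error (%) per estimate
    shrinkage: dict        # eta-shrinkage (%) per random effect
    ebes: pd.DataFrame     # per-subject empirical-Bayes parameter estimates
    loglik: float
    converged: bool
    n_subjects: int
    trace: list = field(default_factory=list)

    def cv_percent(self) -> dict:
        """Inter-individual variability as CV% = 100 * sqrt(omega^2)."""
        return {k: 100.0 * float(np.sqrt(v)) for k, v in self.omega2.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "theta": self.theta,
            "omega2": self.omega2,
            "sigma2": self.sigma2,
            "rse": self.rse,
            "shrinkage": self.shrinkage,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "ebes": self.ebes.to_dict(orient="list"),
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PopulationTGIFit":
        text = str(source)
        try:
            p = Path(text)
            if p.exists():
                text = p.read_text()
        except OSError:  # raw JSON text, not a path
            pass
        doc = json.loads(text)
        return cls(
            theta=doc["theta"],
            omega2=doc["omega2"],
            sigma2=doc["sigma2"],
            rse=doc.get("rse", {}),
            shrinkage=doc.get("shrinkage", {}),
            ebes=pd.DataFrame(doc.get("ebes", {})),
            loglik=doc.get("loglik", float("nan")),
            converged=doc.get("converged", True),
            n_subjects=doc.get("n_subjects", 0),
        )

    def ebes_to_csv(self, path: str | Path) -> None:
        cols = ["subject_id", "arm", "ts0", "kg", "ks", "log_kg"]
        self.ebes[cols].to_csv(path, index=False)


def _init_heuristics(stk: _Stacked, rng: np.random.Generator) -> np.ndarray:
    """Data-driven starting values on the packed log scale (11-vector)."""
    S = len(stk.n_obs)
    base = np.empty(S)
    kg_h = np.full(S, np.nan)
    ks_h = np.full(S, np.nan)
    for s in range(S):
        t = stk.t[s, stk.mask[s]]
        y = np.maximum(stk.y[s, stk.mask[s]], 0.5)
        base[s] = y[np.argmin(np.abs(t))]
        i_nad = int(np.argmin(y))
        if t[i_nad] > 0 and y[i_nad] < base[s]:
            ks_h[s] = np.log(base[s] / y[i_nad]) / t[i_nad]
        if t[-1] > t[i_nad] and y[-1] > y[i_nad]:
            kg_h[s] = np.log(y[-1] / y[i_nad]) / (t[-1] - t[i_nad])

    def _arm_median(vals, arm):
        v = vals[(stk.arm_idx == arm) & np.isfinite(vals) & (vals > 0)]
        return float(np.median(v)) if len(v) else np.nan

    kg0 = [_arm_median(kg_h, 0), _arm_median(kg_h, 1)]
    ks0 = [_arm_median(ks_h, 0), _arm_median(ks_h, 1)]
    kg0 = [v if np.isfinite(v) and v > 0 else 5e-3 for v in kg0]
    ks0 = [v if np.isfinite(v) and v > 0 else 0.05 for v in ks0]
    ts0_0 = float(np.median(base))

    def _logvar(vals, fallback):
        v = vals[np.isfinite(vals) & (vals > 0)]
        if len(v) >= 5:
            return float(np.clip(np.var(np.log(v), ddof=1), 0.05, 4.0))
        return fallback

    var_base = np.var(np.log(np.maximum(base, 0.5)), ddof=1) if S >= 2 else 0.2
    om = [
        _logvar(kg_h[stk.arm_idx == 0], 0.5),
        _logvar(ks_h[stk.arm_idx == 0], 0.5),
        _logvar(kg_h[stk.arm_idx == 1], 0.5),
        _logvar(ks_h[stk.arm_idx == 1], 0.5),
        float(np.clip(np.nan_to_num(var_base, nan=0.2), 0.05, 2.0)),
    ]
    diffs = []
    for s in range(S):
        y = stk.y[s, stk.mask[s]]
        if len(y) >= 3:
            diffs.append(0.5 * np.mean(np.diff(y) ** 2))
    sig2 = float(np.clip(np.median(diffs) if diffs else 25.0, 1.0, 1e4))
    x0 = np.log(
        np.array([kg0[0], ks0[0], kg0[1], ks0[1], ts0_0] + om + [sig2])
    )
    return x0


_BOUNDS = (
    [(np.log(1e-6), np.log(2.0))] * 4
    + [(np.log(0.5), np.log(1000.0))]
    + [(np.log(1e-6), np.log(100.0))] * 5
    + [(np.log(1e-8), np.log(1e6))]
)


def _active_mask(stk: _Stacked) -> np.ndarray:
    """Parameters identifiable from the arms present in the data."""
    active = np.ones(11, dtype=bool)
    if not (stk.arm_idx == 0).any():
        active[[0, 1, 5, 6]] = False
    if not (stk.arm_idx == 1).any():
        active[[2, 3, 7, 8]] = False
    return active


def fit_population(
    tumor: pd.DataFrame,
    settings: FitSettings | None = None,
) -> PopulationTGIFit:
    """Fit the population TGI model by Laplace-approximate maximum likelihood.

    Parameters
    ----------
    tumor
        Long-format records: subject_id, arm, time_weeks, sld_mm.  Subjects
        should already have passed the evaluability filter.
    settings
        Estimation controls; see :class:`FitSettings`.

    Raises
    ------
    ConvergenceError
        If no start converges to a finite optimum (``trace`` attached).
    ValueError
        For degenerate data (all-constant SLD leaves the rates unidentified).
    """
    settings = settings or FitSettings()
    from scipy.optimize import minimize

    stk = _stack(tumor, settings.include_screening)
    if float(np.var(stk.y[stk.mask])) == 0.0:
        raise ValueError("degenerate data: all SLD values identical")

    rng = np.random.default_rng(settings.seed)
    x0_full = _init_heuristics(stk, rng)
    active = _active_mask(stk)
    if settings.fix_omega2_zero:
        return _fit_fixed_effects(stk, x0_full, active, settings)

    S = len(stk.n_obs)
    cache = {"eta": np.zeros((S, 3))}

    def _ll_at(theta, om2, sigma2, eta):
        if settings.method == "agq":
            return _agq_loglik(stk, theta, om2, sigma2, eta, settings.agq_nodes)
        return _laplace_loglik(stk, theta, om2, sigma2, eta)

    def unpack(xa):
        x = x0_full.copy()
        x[active] = xa
        theta = np.exp(x[:5])
        om2 = _omega2_per_subject(stk, np.exp(x[5:10]))
        sigma2 = float(np.exp(x[10]))
        return theta, om2, sigma2

    def nll(xa):
        theta, om2, sigma2 = unpack(xa)
        # warm start from the cached modes but never trust them blindly:
        # re-solve from zero as well and keep the better mode per subject
        eta_w = _solve_modes(stk, theta, om2, sigma2, cache["eta"])
        eta_z = _solve_modes(stk, theta, om2, sigma2, np.zeros_like(eta_w))
        inv_om2 = 1.0 / om2
        g_w = _gval(stk, theta, eta_w, inv_om2, sigma2)
        g_z = _gval(stk, theta, eta_z, inv_om2, sigma2)
        take_w = (g_w < g_z) & np.isfinite(g_w)
        eta = np.where(take_w[:, None], eta_w, eta_z)
        ll = _ll_at(theta, om2, sigma2, eta)
        if np.isfinite(ll):
            cache["eta"] = eta
            return -ll
        return _PENALTY

    def _nll_from(xa, eta0):
        """Objective with a fixed warm start (keeps each subject in the same
        posterior basin so finite differences are smooth); no cache update."""
        theta, om2, sigma2 = unpack(xa)
        eta = _solve_modes(stk, theta, om2, sigma2, eta0)
        ll = _ll_at(theta, om2, sigma2, eta)
        return -ll if np.isfinite(ll) else _PENALTY

    def grad(xa, h: float = 1e-4):
        eta0 = cache["eta"].copy()
        g = np.empty(len(xa))
        for i in range(len(xa)):
            e = np.zeros(len(xa))
            e[i] = h
            g[i] = (_nll_from(xa + e, eta0) - _nll_from(xa - e, eta0)) / (2 * h)
        return g

    bounds = [b for b, a in zip(_BOUNDS, active) if a]
    trace = []
    best = None
    for start in range(settings.n_starts):
        xa0 = x0_full[active].copy()
        if start > 0:
            xa0 = xa0 + rng.normal(0.0, 0.3, size=xa0.shape)
            xa0 = np.clip(xa0, [b[0] for b in bounds], [b[1] for b in bounds])
            cache["eta"] = np.zeros((S, 3))
        res = minimize(
            nll,
            xa0,
            jac=grad,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": settings.max_iter,
                "ftol": settings.ftol,
                "gtol": settings.gtol,
            },
        )
        trace.append(
            {"start": start, "success": bool(res.success),
             "status": int(res.status), "message": str(res.message),
             "nll": float(res.fun)}
        )
        ok = np.isfinite(res.fun) and res.fun < _PENALTY
        if ok and (best is None or res.fun < best.fun):
            best = res
        if ok and res.success:
            break
    if best is None:
        raise ConvergenceError("population TGI fit did not converge", trace)

    xa_hat = best.x
    theta, om2, sigma2 = unpack(xa_hat)
    cache["eta"] = np.zeros((S, 3))
    eta_hat = _solve_modes(stk, theta, om2, sigma2, cache["eta"], tol=1e-11)
    loglik = _ll_at(theta, om2, sigma2, eta_hat)

    x_hat = x0_full.copy()
    x_hat[active] = xa_hat
    om2_vec = np.exp(x_hat[5:10])

    rse = {}
    if settings.compute_rse:
        rse_vals = _rse_from_hessian(nll, xa_hat, cache, stk)
        labels = _param_labels()
        act_labels = [l for l, a in zip(labels, active) if a]
        rse = dict(zip(act_labels, rse_vals))

    ebes = _make_ebes(stk, theta, eta_hat)
    shrink = _shrinkage_table(stk, eta_hat, om2_vec)

    theta_d = dict(zip(THETA_KEYS, map(float, theta)))
    omega2_d = dict(zip(THETA_KEYS, map(float, om2_vec)))
    for i, k in enumerate(THETA_KEYS):
        if not active[i]:
            theta_d[k] = float("nan")
        if not active[5 + i]:
            omega2_d[k] = float("nan")
    return PopulationTGIFit(
        theta=theta_d,
        omega2=omega2_d,
        sigma2=sigma2,
        rse=rse,
        shrinkage=shrink,
        ebes=ebes,
        loglik=loglik,
        converged=bool(best.success),
        n_subjects=S,
        trace=trace,
    )


def _param_labels() -> list[str]:
    return (
        [f"theta.{k}" for k in THETA_KEYS]
        + [f"omega2.{k}" for k in THETA_KEYS]
        + ["sigma2"]
    )


def _rse_from_hessian(nll, x_hat, cache, stk, step: float = 1e-3) -> np.ndarray:
    """RSE% of the natural-scale estimates via the observed information.

    All parameters are estimated on the log scale, so the log-scale standard
    error is (to first order) the relative standard error of the natural
    estimate.
    """
    n = len(x_hat)
    H = np.empty((n, n))
    f0 = nll(x_hat)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        fp[i] = nll(x_hat + ei)
        fm[i] = nll(x_hat - ei)
        H[i, i] = (fp[i] + fm[i] - 2 * f0) / step**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = step
            ej[j] = step
            fpp = nll(x_hat + ei + ej)
            fmm = nll(x_hat - ei - ej)
            H[i, j] = H[j, i] = (
                fpp + fmm + 2 * f0 - fp[i] - fm[i] - fp[j] - fm[j]
            ) / (2 * step**2)
    try:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n, np.nan)
    return 100.0 * se


def _make_ebes(stk: _Stacked, theta, eta) -> pd.DataFrame:
    ts0, kg, ks = _subject_params(stk, theta, eta)
    return pd.DataFrame(
        {
            "subject_id": stk.subject_ids,
            "arm": [ARMS[i] for i in stk.arm_idx],
            "ts0": ts0[:, 0],
            "kg": kg[:, 0],
            "ks": ks[:, 0],
            "log_kg": np.log(kg[:, 0]),
            "eta_ts0": eta[:, 0],
            "eta_kg": eta[:, 1],
            "eta_ks": eta[:, 2],
        }
    )


def eta_shrinkage(etas: np.ndarray, omega2: float) -> float:
    """Eta-shrinkage in percent: 100 * (1 - SD(eta_EBE) / sqrt(omega^2)).

    Near 0% the EBEs carry real individual information; near 100% they have
    collapsed to the population typical value.
    """
    etas = np.asarray(etas, dtype=float)
    if len(etas) < 2:
        raise ValueError("shrinkage needs at least 2 subjects")
    if not omega2 > 0:
        raise ValueError("shrinkage undefined for omega2 <= 0")
    return float(100.0 * (1.0 - np.std(etas, ddof=1) / np.sqrt(omega2)))


def _shrinkage_table(stk: _Stacked, eta, om2_vec) -> dict:
    out = {}
    masks = {
        "kg_treatment": (stk.arm_idx == 0, 1, om2_vec[0]),
        "ks_treatment": (stk.arm_idx == 0, 2, om2_vec[1]),
        "kg_control": (stk.arm_idx == 1, 1, om2_vec[2]),
        "ks_control": (stk.arm_idx == 1, 2, om2_vec[3]),
        "ts0": (np.ones(len(stk.arm_idx), bool), 0, om2_vec[4]),
    }
    for key, (m, comp, om2) in masks.items():
        if m.sum() >= 2 and om2 > 0:
            out[key] = eta_shrinkage(eta[m, comp], om2)
        else:
            out[key] = float("nan")
    return out


def _fit_fixed_effects(stk, x0_full, active, settings) -> PopulationTGIFit:
    """Typical values only (all random-effect variances fixed at zero).

    Plain nonlinear least squares on the log-parameters; the residual
    variance is profiled out analytically (MLE denominator n).
    """
    from scipy.optimize import least_squares

    act = active.copy()
    act[5:] = False  # no omega/sigma parameters in the search
    S = len(stk.n_obs)
    zeros = np.zeros((S, 3))
    n_tot = int(stk.mask.sum())

    def unpack(xa):
        x = x0_full.copy()
        x[act] = xa
        return np.exp(x[:5])

    def residuals(xa):
        theta = unpack(xa)
        ts0, kg, ks = _subject_params(stk, theta, zeros)
        f, _, _ = _predict_and_derivs(stk, ts0, kg, ks)
        r = np.where(stk.mask, stk.y - f, 0.0)
        return np.nan_to_num(r[stk.mask], nan=1e8, posinf=1e8, neginf=-1e8)

    bounds_act = [b for b, a in zip(_BOUNDS, act) if a]
    lo = np.array([b[0] for b in bounds_act])
    hi = np.array([b[1] for b in bounds_act])
    rng = np.random.default_rng(settings.seed)
    best, trace = None, []
    for start in range(max(settings.n_starts, 3)):
        xa0 = np.clip(x0_full[act].copy(), lo, hi)
        if start > 0:
            xa0 = np.clip(xa0 + rng.normal(0.0, 0.8, size=xa0.shape), lo, hi)
        res = least_squares(residuals, xa0, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=5000)
        sse = float(2 * res.cost)
        trace.append({"start": start, "success": bool(res.success), "sse": sse})
        if np.isfinite(sse) and (best is None or sse < best_sse):
            best, best_sse = res, sse
    if best is None:
        raise ConvergenceError("fixed-effects TGI fit did not converge", trace)
    theta = unpack(best.x)
    sigma2 = best_sse / n_tot
    ebes = _make_ebes(stk, theta, zeros)
    theta_d = dict(zip(THETA_KEYS, map(float, theta)))
    for i, k in enumerate(THETA_KEYS):
        if not active[i]:
            theta_d[k] = float("nan")
    return PopulationTGIFit(
        theta=theta_d,
        omega2={k: 0.0 for k in THETA_KEYS},
        sigma2=sigma2,
        rse={},
        shrinkage={k: float("nan") for k in THETA_KEYS},
        ebes=ebes,
        loglik=-0.5 * n_tot * (np.log(2 * np.pi * sigma2) + 1.0),
        converged=bool(best.success),
        n_subjects=S,
        trace=trace,
    )


def gof_diagnostics(
    fit: PopulationTGIFit, tumor: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Goodness-of-fit table: population / individual predictions, residuals.

    Returns the per-observation table and a summary with the observed vs.
    individual-predicted Pearson correlation and the residual SD.
    """
    ebes = fit.ebes.set_index("subject_id")
    rows = []
    for sid, g in tumor.groupby("subject_id"):
        if sid not in ebes.index:
            continue
        e = ebes.loc[sid]
        arm = e["arm"]
        suffix = "treatment" if arm == "treatment" else "control"
        typ = (fit.theta["ts0"], fit.theta[f"kg_{suffix}"], fit.theta[f"ks_{suffix}"])
        ind = (e["ts0"], e["kg"], e["ks"])
        t = g["time_weeks"].to_numpy()
        y = g["sld_mm"].to_numpy()
        pred = ts_model(t, typ)
        ipred = ts_model(t, ind)
        for k in range(len(t)):
            rows.append((sid, arm, t[k], y[k], pred[k], ipred[k]))
    df = pd.DataFrame(
        rows, columns=["subject_id", "arm", "time_weeks", "observed", "pred", "ipred"]
    )
    df["residual"] = df["observed"] - df["pred"]
    df["iresidual"] = df["observed"] - df["ipred"]
    if len(df) >= 2 and df["observed"].std() > 0 and df["ipred"].std() > 0:
        corr = float(np.corrcoef(df["observed"], df["ipred"])[0, 1])
    else:
        corr = float("nan")
    summary = {
        "corr_obs_ipred": corr,
        "iresidual_sd": float(df["iresidual"].std(ddof=1)) if len(df) > 1 else float("nan"),
        "n_obs": len(df),
    }
    return df, summary
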