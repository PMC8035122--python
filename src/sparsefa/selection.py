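"""Model-complexity accounting and tuning-parameter selection.

The penalized fit at tuning vector ``eta`` has influence (hat) matrix

    A_eta = F^{1/2} (F + N E_eta)^{-1} F^{1/2},

with ``F`` the expected information at the optimum and ``E_eta`` the penalty
matrix.  Its trace is the effective degrees of freedom (edf) of the model:
edf = m at eta = 0 and edf -> m - r* as eta -> infinity, where r* counts the
penalized elements.  Model selection uses the generalized Bayesian
information criterion GBIC = -2 loglik + log(N) * edf (the AIC variant
replaces log(N) by 2).

Tuning parameters for lasso/alasso penalties can be estimated automatically
by minimizing the un-biased risk estimator (an approximate AIC)

    V(eta) = ||K - A_eta K||^2 / N + 2 gamma tr(A_eta) / N - 1,

with ``K = F^{1/2} theta + F^{-1/2} g`` built from the unpenalized score and
information, and ``gamma >= 1`` an influence factor that inflates the
complexity term to favor sparser fits.  Minimization is by Newton's method on
``log(eta)`` with analytic first derivatives and step halving, alternated
with trust-region updates of ``theta`` until the relative log-likelihood
change falls below 1e-7.

Uncertainty uses the Bayesian posterior covariance ``V_theta = (F + N E)^{-1}``
(a sandwich variant is available), giving normal-theory intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as _model
from .penalties import (
    ConfigError,
    PenaltyConfig,
    Selectors,
    adaptive_weights,
    build_penalty_matrix,
    unit_penalty_matrices,
)
from .trustregion import TRResult, maximize_penalized

LOG_ETA_MIN, LOG_ETA_MAX = np.log(1e-8), np.log(1e8)

__all__ = [
    "FitResult",
    "influence_and_edf",
    "gbic",
    "ubre",
    "ubre_gradient",
    "auto_tune",
    "grid_search",
    "posterior_uncertainty",
    "stopping_criterion",
    "prepare_alasso_weights",
]


@dataclass
class FitResult:
    """A converged penalized (or unpenalized) fit with selection metadata."""

    theta: np.ndarray
    eta: np.ndarray
    loglik: float
    edf_total: float
    edf_per_param: np.ndarray
    gbic: float
    V_theta: np.ndarray
    ci: np.ndarray  # (m, 2) 95% intervals
    converged: bool
    admissible: bool
    n_outer: int = 0
    reason: str = ""
    flags: dict = field(default_factory=dict)
    layout: object = None
    config: object = None

    def summary(self):
        labels = self.layout.describe() if self.layout is not None else [f"theta{i}" for i in range(self.theta.size)]
        return pd.DataFrame(
            {
                "parameter": labels,
                "estimate": self.theta,
                "edf": self.edf_per_param,
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
            }
        )

    def to_dict(self):
        return {
            "estimates": self.summary().to_dict(orient="records"),
            "eta": np.atleast_1d(self.eta).tolist(),
            "loglik": self.loglik,
            "edf_total": self.edf_total,
            "gbic": self.gbic,
            "converged": bool(self.converged),
            "admissible": bool(self.admissible),
            "n_outer": int(self.n_outer),
            "reason": self.reason,
            "flags": {k: bool(v) for k, v in self.flags.items()},
        }


def _psd_sqrt(F, floor_rel=1e-12):
    """Symmetric square root and inverse square root via eigendecomposition.

    Eigenvalues below ``floor_rel * max`` are floored; the returned flag
    records whether flooring was applied.
    """
    F = 0.5 * (F + F.T)
    d, U = np.linalg.eigh(F)
    top = max(d.max(), 1e-300)
    floored = bool(np.any(d < floor_rel * top))
    d = np.clip(d, floor_rel * top, None)
    sq = U @ (np.sqrt(d)[:, None] * U.T)
    isq = U @ ((1.0 / np.sqrt(d))[:, None] * U.T)
    return sq, isq, floored


def influence_and_edf(theta_hat, data, layout, config: PenaltyConfig, sel: Selectors | None = None, eta=None):
    """Influence matrix A, total edf, and per-parameter edf at a fit."""
    sel = sel or Selectors(layout)
    if eta is not None:
        config = config.with_eta(eta)
    F = _model.fisher_information(theta_hat, data, layout)
    E = build_penalty_matrix(theta_hat, config, sel)
    Fp = F + data.N * E
    Fh, _, floored = _psd_sqrt(F)
    FpinvF = np.linalg.solve(Fp, F)
    A = Fh @ np.linalg.solve(Fp, Fh)
    A = 0.5 * (A + A.T)
    edf_total = float(np.trace(A))
    edf_per = np.clip(np.diag(FpinvF), 0.0, 1.0)
    return A, edf_total, edf_per, {"eigenvalue_floored": floored}


def gbic(loglik_value, edf_total, N, kind="bic"):
    """Generalized information criterion from a log-likelihood and edf."""
    penalty = np.log(N) if kind == "bic" else 2.0
    return float(-2.0 * loglik_value + penalty * edf_total)


def _ubre_parts(theta, data, layout):
    """Quantities of the tuning criterion that do not depend on eta."""
    F = _model.fisher_information(theta, data, layout)
    g = _model.score(theta, data, layout)
    Fh, Fih, floored = _psd_sqrt(F)
    K = Fh @ theta + Fih @ g
    return F, Fh, K, floored


def ubre(theta, data, layout, config: PenaltyConfig, sel: Selectors | None = None, eta=None):
    """Un-biased risk estimator V(eta) at the current theta."""
    sel = sel or Selectors(layout)
    if eta is not None:
        config = config.with_eta(eta)
    F, Fh, K, _ = _ubre_parts(theta, data, layout)
    E = build_penalty_matrix(theta, config, sel)
    Fp = F + data.N * E
    A = Fh @ np.linalg.solve(Fp, Fh)
    r = K - A @ K
    return float(r @ r / data.N + 2.0 * config.gamma * np.trace(A) / data.N - 1.0)


def ubre_gradient(theta, data, layout, config: PenaltyConfig, sel: Selectors | None = None, eta=None):
    """Analytic gradient of V with respect to log(eta) (lasso/alasso only)."""
    sel = sel or Selectors(layout)
    if eta is not None:
        config = config.with_eta(eta)
    F, Fh, K, _ = _ubre_parts(theta, data, layout)
    Ejs = unit_penalty_matrices(theta, config, sel)
    etas = config.eta
    Fp = F + data.N * sum(e * Ej for e, Ej in zip(etas, Ejs))
    Fpinv = np.linalg.inv(Fp)
    A = Fh @ Fpinv @ Fh
    r = K - A @ K
    grad = np.empty(len(etas))
    N = data.N
    for j, Ej in enumerate(Ejs):
        dA = -N * Fh @ Fpinv @ Ej @ Fpinv @ Fh
        dV = -2.0 / N * r @ (dA @ K) + 2.0 * config.gamma / N * np.trace(dA)
        grad[j] = etas[j] * dV
    return grad


def _minimize_ubre(theta, data, layout, config, sel, eta0):
    """Newton descent of V on the log-eta scale with step halving."""
    F, Fh, K, _ = _ubre_parts(theta, data, layout)
    Ejs = unit_penalty_matrices(theta, config, sel)
    N, gamma = data.N, config.gamma

    def value_grad(rho):
        etas = np.exp(rho)
        Fp = F + N * sum(e * Ej for e, Ej in zip(etas, Ejs))
        Fpinv = np.linalg.inv(Fp)
        A = Fh @ Fpinv @ Fh
        r = K - A @ K
        V = float(r @ r / N + 2.0 * gamma * np.trace(A) / N - 1.0)
        g = np.empty(len(etas))
        for j, Ej in enumerate(Ejs):
            dA = -N * Fh @ Fpinv @ Ej @ Fpinv @ Fh
            g[j] = etas[j] * (-2.0 / N * r @ (dA @ K) + 2.0 * gamma / N * np.trace(dA))
        return V, g

    rho = np.clip(np.log(np.maximum(np.atleast_1d(eta0), 1e-8)), LOG_ETA_MIN, LOG_ETA_MAX)
    V, g = value_grad(rho)
    d = rho.size
    for _ in range(50):
        if np.max(np.abs(g)) < 1e-8:
            break
        # finite-difference Hessian of V in rho, ridge-regularized to PD
        H = np.empty((d, d))
        h = 1e-4
        for j in range(d):
            rp = rho.copy()
            rp[j] += h
            rm = rho.copy()
            rm[j] -= h
            H[:, j] = (value_grad(rp)[1] - value_grad(rm)[1]) / (2 * h)
        H = 0.5 * (H + H.T)
        w = np.linalg.eigvalsh(H)[0]
        if w < 1e-10:
            H = H + (1e-10 - w) * np.eye(d)
        step = -np.linalg.solve(H, g)
        improved = False
        for _ in range(30):
            cand = np.clip(rho + step, LOG_ETA_MIN, LOG_ETA_MAX)
            Vc, gc = value_grad(cand)
            if Vc < V - 1e-14:
                rho, V, g = cand, Vc, gc
                improved = True
                break
            step = 0.5 * step
        if not improved:
            break
    return np.exp(rho), V


def stopping_criterion(l_new, l_old, tol=1e-7):
    """Relative log-likelihood change rule for the alternating scheme."""
    return abs(l_new - l_old) / (0.1 + abs(l_new)) < tol


def prepare_alasso_weights(config: PenaltyConfig, theta_mle, sel: Selectors):
    """Fill missing adaptive-lasso weights from an unpenalized estimate."""
    terms = []
    for term in config.terms:
        if term.ptype == "alasso" and term.weights is None:
            w = adaptive_weights(theta_mle, sel, term.target, a=term.a)
            terms.append(type(term)(term.target, term.ptype, term.eta, term.a, w))
        else:
            terms.append(term)
    return PenaltyConfig(terms=terms, gamma=config.gamma, c_bar=config.c_bar)


def _finalize(tr: TRResult, data, layout, config, sel, eta, n_outer=0, reason="", vcov="bayesian"):
    A, edf_total, edf_per, flags = influence_and_edf(tr.theta, data, layout, config, sel)
    crit = gbic(tr.loglik, edf_total, data.N)
    V_theta, ci = posterior_uncertainty(tr.theta, data, layout, config, sel, vcov=vcov)
    return FitResult(
        theta=tr.theta,
        eta=np.atleast_1d(np.asarray(eta, dtype=float)),
        loglik=tr.loglik,
        edf_total=edf_total,
        edf_per_param=edf_per,
        gbic=crit,
        V_theta=V_theta,
        ci=ci,
        converged=tr.converged,
        admissible=bool(tr.admissible) if tr.admissible is not None else _model.admissibility(tr.theta, layout),
        n_outer=n_outer,
        reason=reason or tr.reason,
        flags=flags,
        layout=layout,
        config=config,
    )


def posterior_uncertainty(theta_hat, data, layout, config: PenaltyConfig, sel=None, vcov="bayesian"):
    """Posterior covariance of theta and 95% normal-theory intervals.

    ``bayesian`` gives ``(F + N E)^{-1}``; ``sandwich`` the frequentist
    ``(F + N E)^{-1} F (F + N E)^{-1}``.
    """
    sel = sel or Selectors(layout)
    F = _model.fisher_information(theta_hat, data, layout)
    E = build_penalty_matrix(theta_hat, config, sel)
    Fp = F + data.N * E
    Fh, _, _ = _psd_sqrt(Fp)
    Fpinv = np.linalg.inv(Fp)
    V = Fpinv if vcov == "bayesian" else Fpinv @ F @ Fpinv
    V = 0.5 * (V + V.T)
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    ci = np.column_stack([theta_hat - 1.96 * se, theta_hat + 1.96 * se])
    return V, ci


def auto_tune(
    data,
    spec_or_layout,
    config: PenaltyConfig,
    start=None,
    eta0=0.01,
    information_kind="fisher",
    max_outer=50,
    mle=None,
):
    """Joint estimation of theta and eta by the alternating scheme.

    Each cycle performs (i) a trust-region update of theta at the current
    tuning values and (ii) a Newton minimization of the tuning criterion V
    over log(eta), stopping when the relative change of the log-likelihood
    between cycles falls below 1e-7.  Requires lasso/alasso terms; missing
    adaptive weights are derived from the unpenalized fit, which also serves
    as the default start.
    """
    layout = (
        spec_or_layout
        if isinstance(spec_or_layout, _model.ParameterLayout)
        else _model.ParameterLayout(spec_or_layout)
    )
    if not config.supports_automatic():
        raise ConfigError("automatic tuning requires lasso or alasso penalties; use grid_search for scad/mcp")
    sel = Selectors(layout)
    if mle is None and (start is None or any(t.ptype == "alasso" and t.weights is None for t in config.terms)):
        mle = _model.fit_unpenalized(data, layout, information_kind=information_kind)
    if start is None:
        start = mle.theta
    if mle is not None:
        config = prepare_alasso_weights(config, mle.theta, sel)
    eta = np.full(len(config.terms), float(eta0)) if np.isscalar(eta0) else np.asarray(eta0, dtype=float)
    theta = np.asarray(start, dtype=float)
    ll_prev = None
    converged = False
    tr = None
    for outer in range(1, max_outer + 1):
        cfg = config.with_eta(eta)
        tr = maximize_penalized(
            data, layout, penalty=(cfg, sel), start=theta, information_kind=information_kind
        )
        theta = tr.theta
        if ll_prev is not None and stopping_criterion(tr.loglik, ll_prev):
            converged = True
            break
        ll_prev = tr.loglik
        eta, _ = _minimize_ubre(theta, data, layout, config, sel, eta)
    tr.admissible = _model.admissibility(theta, layout)
    res = _finalize(
        tr, data, layout, config.with_eta(eta), sel, eta, n_outer=outer,
        reason="outer_converged" if converged else "outer_max_iter",
    )
    res.converged = converged and tr.converged
    return res


def fit_at_eta(data, spec_or_layout, config: PenaltyConfig, eta, start=None, information_kind="fisher"):
    """Penalized fit at fixed tuning values, finished with edf/GBIC/intervals."""
    layout = (
        spec_or_layout
        if isinstance(spec_or_layout, _model.ParameterLayout)
        else _model.ParameterLayout(spec_or_layout)
    )
    sel = Selectors(layout)
    mle = None
    if start is None or any(t.ptype == "alasso" and t.weights is None for t in config.terms):
        mle = _model.fit_unpenalized(data, layout, information_kind=information_kind)
    if start is None:
        start = mle.theta
    if mle is not None:
        config = prepare_alasso_weights(config, mle.theta, sel)
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    cfg = config.with_eta(eta) if eta.size else config
    tr = maximize_penalized(
        data, layout, penalty=(cfg, sel) if cfg.terms else None, start=np.asarray(start, float),
        information_kind=information_kind,
    )
    tr.admissible = _model.admissibility(tr.theta, layout)
    return _finalize(tr, data, layout, cfg, sel, eta, reason=tr.reason)


def grid_search(
    data,
    spec_or_layout,
    config: PenaltyConfig,
    eta_grid,
    start=None,
    information_kind="fisher",
):
    """Penalized fits along a tuning grid; the lowest GBIC wins.

    ``eta_grid`` is an iterable of scalars (single tuning parameter) or
    vectors.  Fits are warm-started along the path.  Returns the selected
    :class:`FitResult` and a path table with one row per grid point.
    """
    layout = (
        spec_or_layout
        if isinstance(spec_or_layout, _model.ParameterLayout)
        else _model.ParameterLayout(spec_or_layout)
    )
    sel = Selectors(layout)
    mle = None
    if start is None or any(t.ptype == "alasso" and t.weights is None for t in config.terms):
        mle = _model.fit_unpenalized(data, layout, information_kind=information_kind)
    if start is None:
        start = mle.theta
    if mle is not None:
        config = prepare_alasso_weights(config, mle.theta, sel)
    rows, fits = [], []
    theta = np.asarray(start, dtype=float)
    failures = []
    for point in eta_grid:
        eta = np.atleast_1d(np.asarray(point, dtype=float))
        cfg = config.with_eta(eta)
        try:
            tr = maximize_penalized(data, layout, penalty=(cfg, sel), start=theta, information_kind=information_kind)
            theta = tr.theta
            _, edf_total, _, _ = influence_and_edf(tr.theta, data, layout, cfg, sel)
            crit = gbic(tr.loglik, edf_total, data.N)
            rows.append({"eta": tuple(eta) if eta.size > 1 else float(eta[0]), "loglik": tr.loglik,
                         "edf": edf_total, "gbic": crit, "converged": tr.converged})
            fits.append((crit, eta, tr))
        except (_model.NumericError, np.linalg.LinAlgError) as exc:  # pragma: no cover - defensive
            failures.append({"eta": point, "error": str(exc)})
    if not fits:
        raise RuntimeError(f"all grid fits failed: {failures}")
    best_crit, best_eta, best_tr = min(fits, key=lambda t: t[0])
    result = _finalize(best_tr, data, layout, config.with_eta(best_eta), sel, best_eta, reason="grid")
    path = pd.DataFrame(rows)
    return result, path
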