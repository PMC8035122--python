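"""Trust-region maximization of the (penalized) log-likelihood.

The penalized objective is ``l_p(theta) = l(theta) - N * P(theta)`` with the
smoothly approximated penalty ``P``.  At each outer iterate the penalty is
replaced by its local quadratic representation, giving the penalized score
``g_p = g(theta) - N E theta`` and penalized curvature ``H_p = I(theta) +
N E`` (the negative expected Hessian of ``l_p``); the penalty matrix ``E`` is
rebuilt at every accepted step.  A step is obtained by exactly solving the
dense trust-region subproblem (eigenvalue-safeguarded, More-Sorensen style),
accepted when the actual-versus-predicted reduction ratio is positive, and
the radius is adapted with textbook thresholds: expand when the ratio exceeds
0.75 on a boundary step, shrink by 4 when it falls below 0.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from . import model as _model
from .penalties import PenaltyConfig, Selectors, build_penalty_matrix, penalty_value

__all__ = ["TRResult", "solve_tr_subproblem", "maximize_penalized", "fit_penalized"]


@dataclass
class TRResult:
    theta: np.ndarray
    objective: float  # penalized log-likelihood at the solution
    loglik: float
    converged: bool
    reason: str
    n_iter: int
    grad_norm: float
    admissible: bool | None = None
    history: list = field(default_factory=list)


def solve_tr_subproblem(grad, hess, radius):
    """Minimize ``g's + s'Hs/2`` subject to ``||s|| <= radius`` (dense, exact).

    Uses the eigendecomposition of H: for the interior case the Newton step is
    returned; otherwise the boundary multiplier is found by root-finding on the
    secular equation, with the hard case handled by adding a component along
    the smallest eigenvector.
    """
    grad = np.asarray(grad, dtype=float)
    hess = np.asarray(hess, dtype=float)
    evals, Q = np.linalg.eigh(0.5 * (hess + hess.T))
    b = Q.T @ grad
    lam_min = evals[0]
    if lam_min > 0:
        s = Q @ (-b / evals)
        if np.linalg.norm(s) <= radius:
            return s
    # boundary solution: find mu >= max(0, -lam_min) with ||s(mu)|| = radius

    def snorm(mu):
        return np.linalg.norm(b / (evals + mu))

    mu_lo = max(0.0, -lam_min)
    active = np.abs(b) > 1e-14
    if not np.any(active & (np.abs(evals - lam_min) < 1e-12 * max(1.0, abs(lam_min)))) and snorm(
        mu_lo + 1e-14
    ) < radius:
        # hard case: gradient has no component along the smallest eigenspace
        mu = mu_lo
        denom = evals + mu
        denom[np.abs(denom) < 1e-14] = np.inf
        s = -b / denom
        gap = radius**2 - float(s @ s)
        tau = np.sqrt(max(gap, 0.0))
        s = Q @ s + tau * Q[:, 0]
        return s
    lo = mu_lo + 1e-14
    hi = max(lo * 2, 1.0)
    while snorm(hi) > radius:
        hi *= 4
        if hi > 1e18:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if snorm(mid) > radius:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14 * max(1.0, hi):
            break
    mu = 0.5 * (lo + hi)
    return Q @ (-b / (evals + mu))


def _objective(theta, data, layout, pen):
    ll = _model.loglik(theta, data, layout)
    if pen is None:
        return ll, ll
    config, sel = pen
    return ll - data.N * penalty_value(theta, config, sel), ll


def maximize_penalized(
    data,
    layout,
    penalty=None,
    start=None,
    information_kind="fisher",
    gtol=1e-6,
    ftol=1e-9,
    max_iter=500,
    delta0=1.0,
    delta_max=100.0,
    keep_history=False,
):
    """Trust-region ascent of the penalized log-likelihood.

    ``penalty`` is ``None`` (plain maximum likelihood) or a pair
    ``(PenaltyConfig, Selectors)``.  Convergence is declared when the max-norm
    of the penalized score falls below ``gtol * N`` or the relative objective
    change of an accepted step falls below ``ftol``.
    """
    theta = np.array(start, dtype=float)
    N = data.N
    f, ll = _objective(theta, data, layout, penalty)
    if not np.isfinite(f):
        raise _model.NumericError("objective not finite at the starting point")

    def derivatives(th):
        g = _model.score(th, data, layout)
        H = _model.information(th, data, layout, kind=information_kind)
        if penalty is not None:
            config, sel = penalty
            E = build_penalty_matrix(th, config, sel)
            g = g - N * (E @ th)
            H = H + N * E
        return g, H

    g_p, H_p = derivatives(theta)
    delta = delta0
    history = []
    converged, reason = False, "max_iter"
    it = 0
    n_rejected = 0
    while it < max_iter:
        it += 1
        if np.max(np.abs(g_p)) < gtol * N:
            converged, reason = True, "gradient"
            break
        s = solve_tr_subproblem(-g_p, H_p, delta)
        pred = float(g_p @ s - 0.5 * s @ H_p @ s)  # predicted increase of l_p
        try:
            f_trial, ll_trial = _objective(theta + s, data, layout, penalty)
        except _model.NumericError:
            f_trial = -np.inf
        ratio = (f_trial - f) / pred if pred > 0 else -np.inf
        step_norm = np.linalg.norm(s)
        if keep_history:
            history.append(dict(iter=it, lp=f, grad=float(np.max(np.abs(g_p))), delta=delta, ratio=ratio))
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("iter=%d lp=%.6f |g|=%.3e delta=%.3g r=%.3g", it, f, np.max(np.abs(g_p)), delta, ratio)
        if ratio > 0 and f_trial >= f:
            rel_change = abs(f_trial - f) / (1.0 + abs(f_trial))
            theta = theta + s
            f, ll = f_trial, ll_trial
            g_p, H_p = derivatives(theta)
            n_rejected = 0
            if rel_change < ftol:
                converged, reason = True, "objective"
                break
        else:
            n_rejected += 1
        if ratio > 0.75 and step_norm >= 0.99 * delta:
            delta = min(2 * delta, delta_max)
        elif ratio < 0.25:
            delta = delta / 4
        if delta < 1e-13:
            converged, reason = (np.max(np.abs(g_p)) < 1e-3 * N), "stalled"
            break
    return TRResult(
        theta=theta,
        objective=f,
        loglik=ll,
        converged=converged,
        reason=reason,
        n_iter=it,
        grad_norm=float(np.max(np.abs(g_p))),
        history=history,
    )


def fit_penalized(data, spec_or_layout, config: PenaltyConfig, eta=None, start=None, **kwargs):
    """Penalized fit at fixed tuning values.

    ``eta`` optionally overrides the tuning values stored in ``config``.
    The default start is the unpenalized maximum-likelihood estimate.
    """
    layout = (
        spec_or_layout
        if isinstance(spec_or_layout, _model.ParameterLayout)
        else _model.ParameterLayout(spec_or_layout)
    )
    if eta is not None:
        config = config.with_eta(eta)
    sel = Selectors(layout)
    if start is None:
        start = _model.fit_unpenalized(data, layout).theta
    res = maximize_penalized(data, layout, penalty=(config, sel), start=start, **kwargs)
    res.admissible = _model.admissibility(res.theta, layout)
    return res
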