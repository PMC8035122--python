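"""Sparsity- and invariance-inducing penalties and their smooth approximations.

Four penalty families are supported on a scalar magnitude ``t >= 0`` with
tuning ``eta``:

* lasso:          ``eta * t``
* adaptive lasso: ``eta * w * t`` with weights ``w = 1 / |theta_MLE|**a``
* scad:           ``eta*t`` for ``t <= eta``; quadratic blend up to ``a*eta``;
                  constant ``(a+1)*eta**2/2`` beyond (requires ``a > 2``)
* mcp:            ``eta*t - t**2/(2a)`` for ``t <= a*eta``; constant
                  ``a*eta**2/2`` beyond (requires ``a > 1``)

The non-differentiable absolute value is replaced everywhere by the smooth
surrogate ``|t| ~ sqrt(t**2 + c_bar)`` with a small ``c_bar`` (default 1e-8),
which deviates from ``|t|`` by ``sqrt(c_bar)`` at zero and by less than
``c_bar`` elsewhere.  Around an expansion point the approximated penalty is
represented by the quadratic form ``0.5 * theta' E theta`` with a
block-structured penalty matrix ``E``; the exact gradient of the approximated
penalty at the expansion point is then ``E theta``.

Three penalty targets exist: sparsity of the penalized loadings, and — for
multiple groups — fusion of the pairwise cross-group differences of loadings
and of intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import ParameterLayout

PENALTY_TYPES = ("lasso", "alasso", "scad", "mcp")
TARGETS = ("sparsity", "loading_diff", "intercept_diff")

__all__ = [
    "PenaltyTerm",
    "PenaltyConfig",
    "Selectors",
    "ConfigError",
    "pen_value",
    "pen_deriv",
    "shrink_weight",
    "penalty_value",
    "build_penalty_matrix",
    "unit_penalty_matrices",
    "build_selectors",
    "adaptive_weights",
]


class ConfigError(ValueError):
    """Raised for invalid penalty configurations."""


def _validate(ptype, eta, a):
    if ptype not in PENALTY_TYPES:
        raise ConfigError(f"unknown penalty type {ptype!r}")
    if eta < 0:
        raise ConfigError("tuning parameter eta must be nonnegative")
    if ptype == "scad" and not a > 2:
        raise ConfigError("scad requires shape a > 2")
    if ptype == "mcp" and not a > 1:
        raise ConfigError("mcp requires shape a > 1")
    if ptype == "alasso" and not a > 0:
        raise ConfigError("alasso requires exponent a > 0")


def pen_value(t, ptype, eta, a=3.7, w=1.0):
    """Penalty of a nonnegative magnitude ``t`` (vectorized)."""
    _validate(ptype, eta, a)
    t = np.abs(np.asarray(t, dtype=float))
    if ptype == "lasso":
        return eta * t
    if ptype == "alasso":
        return eta * w * t
    if ptype == "scad":
        out = np.where(
            t <= eta,
            eta * t,
            np.where(
                t <= a * eta,
                -(t**2 - 2 * a * eta * t + eta**2) / (2 * (a - 1)),
                (a + 1) * eta**2 / 2,
            ),
        )
        return out
    # mcp
    return np.where(t <= a * eta, eta * t - t**2 / (2 * a), a * eta**2 / 2)


def pen_deriv(t, ptype, eta, a=3.7, w=1.0):
    """First derivative of :func:`pen_value` with respect to ``t`` (t >= 0)."""
    _validate(ptype, eta, a)
    t = np.abs(np.asarray(t, dtype=float))
    if ptype == "lasso":
        return np.full_like(t, eta)
    if ptype == "alasso":
        return eta * np.asarray(w, dtype=float) * np.ones_like(t)
    if ptype == "scad":
        return np.where(t <= eta, eta, np.where(t <= a * eta, (a * eta - t) / (a - 1), 0.0))
    return np.where(t <= a * eta, eta - t / a, 0.0)


def shrink_weight(theta_tilde_q, ptype, eta, a=3.7, w=1.0, c_bar=1e-8):
    """Local quadratic shrinkage weight ``m_q`` at the expansion value.

    ``m_q = P'(sqrt(t**2 + c_bar)) / sqrt(t**2 + c_bar)``, the coefficient of
    the diagonal entry of the penalty matrix for a sparsity term.
    """
    if c_bar <= 0:
        raise ConfigError("approximation constant c_bar must be positive")
    norm = np.sqrt(np.asarray(theta_tilde_q, dtype=float) ** 2 + c_bar)
    return pen_deriv(norm, ptype, eta, a=a, w=w) / norm


@dataclass
class PenaltyTerm:
    """One penalty term: a target, a family, a tuning value and its shape."""

    target: str
    ptype: str = "lasso"
    eta: float = 0.0
    a: float = 3.7
    weights: np.ndarray | None = None  # adaptive weights (alasso), one per penalized index

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ConfigError(f"unknown penalty target {self.target!r}")
        _validate(self.ptype, self.eta, self.a)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    def weight(self, q):
        return 1.0 if self.weights is None else float(self.weights[q])


@dataclass
class PenaltyConfig:
    """Collection of penalty terms plus global smoothing settings.

    ``gamma`` is the influence factor multiplying the degrees-of-freedom term
    of the tuning criterion (``gamma >= 1`` pushes toward sparser fits);
    ``c_bar`` is the smooth-absolute-value constant.
    """

    terms: list[PenaltyTerm] = field(default_factory=list)
    gamma: float = 1.0
    c_bar: float = 1e-8

    def __post_init__(self):
        if self.c_bar <= 0:
            raise ConfigError("c_bar must be positive")
        if self.gamma < 1:
            raise ConfigError("influence factor gamma must be >= 1")

    @property
    def eta(self):
        return np.array([t.eta for t in self.terms])

    def with_eta(self, eta):
        eta = np.atleast_1d(np.asarray(eta, dtype=float))
        if eta.size != len(self.terms):
            raise ConfigError(f"eta has length {eta.size}, expected {len(self.terms)}")
        terms = [
            PenaltyTerm(t.target, t.ptype, float(e), t.a, t.weights) for t, e in zip(self.terms, eta)
        ]
        return PenaltyConfig(terms=terms, gamma=self.gamma, c_bar=self.c_bar)

    def supports_automatic(self):
        return all(t.ptype in ("lasso", "alasso") for t in self.terms)


class Selectors:
    """Index machinery behind the selector matrices.

    ``sparsity_idx`` holds the flat positions of penalized loadings.  For each
    fused parameter (penalized loading or intercept), ``pairs`` lists the
    cross-group index pairs whose absolute differences are shrunk; with G
    groups there are C(G, 2) pairs per parameter.
    """

    def __init__(self, layout: ParameterLayout):
        self.layout = layout
        self.m = layout.m
        self.sparsity_idx = layout.penalized_loading_indices()
        G, m1 = layout.spec.G, layout.m1
        self.loading_pairs = [
            [(g1 * m1 + q, g2 * m1 + q) for g1, g2 in combinations(range(G), 2)]
            for q in layout.pen_load_idx
        ]
        self.intercept_pairs = [
            [(g1 * m1 + q, g2 * m1 + q) for g1, g2 in combinations(range(G), 2)]
            for q in layout.pen_tau_idx
        ]

    def pairs(self, target):
        return self.loading_pairs if target == "loading_diff" else self.intercept_pairs

    def R(self, q):
        """Dense selector matrix with a single diagonal 1 at position q."""
        R = np.zeros((self.m, self.m))
        R[q, q] = 1.0
        return R

    def difference_matrix(self, target, j):
        """Dense pairwise-difference map for the j-th fused parameter."""
        pairs = self.pairs(target)[j]
        D = np.zeros((len(pairs), self.m))
        for row, (i, k) in enumerate(pairs):
            D[row, i] = 1.0
            D[row, k] = -1.0
        return D

    def difference_norm(self, theta, target, j):
        """L1 norm of the pairwise differences of the j-th fused parameter."""
        return float(sum(abs(theta[i] - theta[k]) for i, k in self.pairs(target)[j]))


def build_selectors(layout: ParameterLayout) -> Selectors:
    return Selectors(layout)


def _term_magnitudes(theta, term: PenaltyTerm, sel: Selectors, c_bar):
    """Per-parameter approximated L1 magnitudes for one term."""
    if term.target == "sparsity":
        vals = theta[sel.sparsity_idx]
        return np.sqrt(vals**2 + c_bar)
    norms = []
    for pairs in sel.pairs(term.target):
        diffs = np.array([theta[i] - theta[k] for i, k in pairs])
        norms.append(np.sqrt(diffs**2 + c_bar).sum())
    return np.asarray(norms)


def penalty_value(theta, config: PenaltyConfig, sel: Selectors, c_bar=None):
    """Approximated total penalty (pass ``c_bar=0`` for the exact value)."""
    theta = np.asarray(theta, dtype=float)
    cb = config.c_bar if c_bar is None else c_bar
    total = 0.0
    for term in config.terms:
        if cb == 0:
            if term.target == "sparsity":
                mags = np.abs(theta[sel.sparsity_idx])
            else:
                mags = np.array(
                    [sel.difference_norm(theta, term.target, j) for j in range(len(sel.pairs(term.target)))]
                )
        else:
            mags = _term_magnitudes(theta, term, sel, cb)
        for q, t in enumerate(mags):
            total += float(pen_value(t, term.ptype, term.eta, a=term.a, w=term.weight(q)))
    return total


def build_penalty_matrix(theta_tilde, config: PenaltyConfig, sel: Selectors):
    """Penalty matrix E at the expansion point.

    E is symmetric, zero on rows/columns of unpenalized parameters, and
    ``E theta_tilde`` is the exact gradient of the approximated penalty at the
    expansion point.  Sparsity terms contribute diagonal shrinkage weights;
    fusion terms contribute the usual graph-Laplacian pattern (+w on the two
    diagonals, -w off-diagonal) per cross-group pair.
    """
    theta = np.asarray(theta_tilde, dtype=float)
    cb = config.c_bar
    E = np.zeros((sel.m, sel.m))
    for term in config.terms:
        if term.target == "sparsity":
            for q, idx in enumerate(sel.sparsity_idx):
                E[idx, idx] += shrink_weight(theta[idx], term.ptype, term.eta, term.a, term.weight(q), cb)
        else:
            for q, pairs in enumerate(sel.pairs(term.target)):
                diffs = np.array([theta[i] - theta[k] for i, k in pairs])
                norm = np.sqrt(diffs**2 + cb).sum()
                deriv = float(pen_deriv(norm, term.ptype, term.eta, a=term.a, w=term.weight(q)))
                for (i, k), d in zip(pairs, diffs):
                    w = deriv / np.sqrt(d**2 + cb)
                    E[i, i] += w
                    E[k, k] += w
                    E[i, k] -= w
                    E[k, i] -= w
    return E


def unit_penalty_matrices(theta_tilde, config: PenaltyConfig, sel: Selectors):
    """Per-term penalty matrices at eta_j = 1, so that E = sum_j eta_j E_j.

    Valid only for lasso/alasso terms, whose shrinkage weights are linear in
    the tuning parameter; this separability underlies the automatic tuning
    procedure.
    """
    if not config.supports_automatic():
        raise ConfigError("per-term separation requires lasso or alasso penalties")
    mats = []
    for term in config.terms:
        unit = PenaltyConfig(
            terms=[PenaltyTerm(term.target, term.ptype, 1.0, term.a, term.weights)],
            gamma=config.gamma,
            c_bar=config.c_bar,
        )
        mats.append(build_penalty_matrix(theta_tilde, unit, sel))
    return mats


def adaptive_weights(theta_mle, sel: Selectors, target, a=1.0, cap=1e8):
    """Adaptive-lasso weights ``1/|reference|**a`` from an unpenalized fit.

    For fusion targets the reference magnitude is the L1 norm of the
    cross-group differences at the MLE.  Weights are capped to keep the
    penalty matrix numerically representable when a reference is ~0.
    """
    theta_mle = np.asarray(theta_mle, dtype=float)
    if target == "sparsity":
        ref = np.abs(theta_mle[sel.sparsity_idx])
    else:
        ref = np.array(
            [sel.difference_norm(theta_mle, target, j) for j in range(len(sel.pairs(target)))]
        )
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(ref, 0.0) ** a
    return np.minimum(w, cap)
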