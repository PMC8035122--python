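"""Single- and multiple-group linear factor models.

The measurement model for group ``g`` is

    x_g = tau_g + Lambda_g f_g + eps_g,
    f_g ~ N(kappa_g, Phi_g),   eps_g ~ N(0, Psi_g)  with Psi_g diagonal,

so the implied moments are ``mu_g = tau_g + Lambda_g kappa_g`` and
``Sigma_g = Lambda_g Phi_g Lambda_g' + Psi_g``.  In the single-group case the
observed variables are treated as deviations from their means and the mean
structure is dropped.

This module owns the parameterization (the flat vector ``theta`` and its
bidirectional mapping to the per-group matrices), the Gaussian log-likelihood
based on sufficient statistics, and its analytic first- and second-order
derivatives (score, expected Fisher information, and a finite-difference
observed Hessian for the single-group model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FIXED, FREE, PENALIZED = 0, 1, 2

__all__ = [
    "ModelSpec",
    "ParameterLayout",
    "DataSummary",
    "SpecificationError",
    "NumericError",
    "implied_moments",
    "loglik",
    "score",
    "information",
    "fit_unpenalized",
]


class SpecificationError(ValueError):
    """Raised when a model specification is internally inconsistent."""


class NumericError(RuntimeError):
    """Raised when a likelihood quantity cannot be evaluated (singular Sigma)."""

    def __init__(self, message, group=None):
        super().__init__(message)
        self.group = group


def _as_code(a, shape, name):
    a = np.asarray(a, dtype=int)
    if a.shape != shape:
        raise SpecificationError(f"{name} pattern has shape {a.shape}, expected {shape}")
    if not np.isin(a, (FIXED, FREE, PENALIZED)).all():
        raise SpecificationError(f"{name} pattern entries must be 0 (fixed), 1 (free) or 2 (penalized)")
    return a


@dataclass
class ModelSpec:
    """Pattern of fixed / free / penalized entries of a factor model.

    Entry codes: 0 = fixed at the corresponding ``*_fixed`` value, 1 = freely
    estimated, 2 = freely estimated and subject to penalization.  The same
    pattern is used in every group, so the total parameter count is
    ``m = m1 * G``.

    Identification is either by unit factor variances (single group; the
    diagonal of ``phi`` must then be fixed at 1) or by marker variables
    (multiple groups; one fixed nonzero loading per factor and fixed marker
    intercepts).
    """

    p: int
    r: int
    G: int = 1
    lam_code: np.ndarray = None
    lam_fixed: np.ndarray = None
    psi_code: np.ndarray = None
    psi_fixed: np.ndarray = None
    phi_code: np.ndarray = None
    phi_fixed: np.ndarray = None
    mean_structure: bool = False
    tau_code: np.ndarray = None
    tau_fixed: np.ndarray = None
    kappa_code: np.ndarray = None
    kappa_fixed: np.ndarray = None
    var_names: Sequence[str] | None = None
    factor_names: Sequence[str] | None = None

    def __post_init__(self):
        p, r = self.p, self.r
        if self.lam_code is None:
            self.lam_code = np.full((p, r), FREE)
        if self.lam_fixed is None:
            self.lam_fixed = np.zeros((p, r))
        if self.psi_code is None:
            self.psi_code = np.full(p, FREE)
        if self.psi_fixed is None:
            self.psi_fixed = np.zeros(p)
        if self.phi_code is None:
            # unit-variance convention: diagonal fixed at 1, covariances free
            self.phi_code = np.full((r, r), FREE)
            np.fill_diagonal(self.phi_code, FIXED)
        if self.phi_fixed is None:
            self.phi_fixed = np.eye(r)
        if self.mean_structure:
            if self.tau_code is None:
                self.tau_code = np.full(p, FREE)
            if self.tau_fixed is None:
                self.tau_fixed = np.zeros(p)
            if self.kappa_code is None:
                self.kappa_code = np.full(r, FREE)
            if self.kappa_fixed is None:
                self.kappa_fixed = np.zeros(r)
        self.lam_code = _as_code(self.lam_code, (p, r), "loading")
        self.lam_fixed = np.asarray(self.lam_fixed, dtype=float)
        self.psi_code = _as_code(self.psi_code, (p,), "unique-variance")
        self.psi_fixed = np.asarray(self.psi_fixed, dtype=float)
        self.phi_code = _as_code(self.phi_code, (r, r), "factor-covariance")
        self.phi_fixed = np.asarray(self.phi_fixed, dtype=float)
        if not np.array_equal(self.phi_code, self.phi_code.T):
            raise SpecificationError("factor-covariance pattern must be symmetric")
        if (self.phi_code == PENALIZED).any() or (self.psi_code == PENALIZED).any():
            raise SpecificationError("penalties are supported on loadings and intercepts only")
        if self.mean_structure:
            self.tau_code = _as_code(self.tau_code, (p,), "intercept")
            self.tau_fixed = np.asarray(self.tau_fixed, dtype=float)
            self.kappa_code = _as_code(self.kappa_code, (r,), "factor-mean")
            self.kappa_fixed = np.asarray(self.kappa_fixed, dtype=float)
            if (self.kappa_code == PENALIZED).any():
                raise SpecificationError("factor means cannot be penalized")
        if self.var_names is None:
            self.var_names = [f"x{i + 1}" for i in range(p)]
        if self.factor_names is None:
            self.factor_names = [f"f{j + 1}" for j in range(r)]

    def identification_check(self):
        """Verify each factor carries an identification device."""
        for j in range(self.r):
            unit_var = self.phi_code[j, j] == FIXED and self.phi_fixed[j, j] > 0
            col = self.lam_code[:, j]
            marker = np.any((col == FIXED) & (self.lam_fixed[:, j] != 0))
            if not (unit_var or marker):
                raise SpecificationError(
                    f"factor {self.factor_names[j]} has neither a fixed variance nor a marker loading"
                )


@dataclass
class _Entry:
    matrix: str  # 'lam' | 'tau' | 'psi' | 'phi' | 'kappa'
    i: int
    j: int
    penalized: bool


class ParameterLayout:
    """Bidirectional map between the flat vector ``theta`` and the matrices.

    Ordering is group-major.  Within a group: the penalized loadings come
    first (their count is ``q_star``), then the remaining free loadings in
    column-stacking order, then intercepts (penalized first, ``k_star`` of
    them), unique variances, vech of the factor covariance, and factor means.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        entries: list[_Entry] = []
        lam_pen = [
            _Entry("lam", i, j, True)
            for j in range(spec.r)
            for i in range(spec.p)
            if spec.lam_code[i, j] == PENALIZED
        ]
        lam_free = [
            _Entry("lam", i, j, False)
            for j in range(spec.r)
            for i in range(spec.p)
            if spec.lam_code[i, j] == FREE
        ]
        entries += lam_pen + lam_free
        self.q_star = len(lam_pen)
        self.k_star = 0
        if spec.mean_structure:
            tau_pen = [_Entry("tau", i, 0, True) for i in range(spec.p) if spec.tau_code[i] == PENALIZED]
            tau_free = [_Entry("tau", i, 0, False) for i in range(spec.p) if spec.tau_code[i] == FREE]
            entries += tau_pen + tau_free
            self.k_star = len(tau_pen)
        entries += [_Entry("psi", i, i, False) for i in range(spec.p) if spec.psi_code[i] == FREE]
        entries += [
            _Entry("phi", i, j, False)
            for j in range(spec.r)
            for i in range(j, spec.r)
            if spec.phi_code[i, j] == FREE
        ]
        if spec.mean_structure:
            entries += [_Entry("kappa", j, 0, False) for j in range(spec.r) if spec.kappa_code[j] == FREE]
        self.entries = entries
        self.m1 = len(entries)
        self.m = self.m1 * spec.G
        # flat indices (within a group block) of penalized loadings / intercepts
        self.pen_load_idx = np.arange(self.q_star)
        tau_start = self.q_star + len(lam_free)
        self.pen_tau_idx = np.arange(tau_start, tau_start + self.k_star)

    # -- packing ---------------------------------------------------------
    def unpack(self, theta):
        """Return per-group matrices (Lambda, Psi-diag, Phi, tau, kappa)."""
        spec = self.spec
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.m,):
            raise SpecificationError(f"theta has length {theta.size}, expected {self.m}")
        groups = []
        for g in range(spec.G):
            block = theta[g * self.m1 : (g + 1) * self.m1]
            lam = spec.lam_fixed.copy()
            psi = spec.psi_fixed.copy()
            phi = spec.phi_fixed.copy()
            tau = spec.tau_fixed.copy() if spec.mean_structure else None
            kappa = spec.kappa_fixed.copy() if spec.mean_structure else None
            for val, e in zip(block, self.entries):
                if e.matrix == "lam":
                    lam[e.i, e.j] = val
                elif e.matrix == "tau":
                    tau[e.i] = val
                elif e.matrix == "psi":
                    psi[e.i] = val
                elif e.matrix == "phi":
                    phi[e.i, e.j] = val
                    phi[e.j, e.i] = val
                else:
                    kappa[e.i] = val
            groups.append((lam, psi, phi, tau, kappa))
        return groups

    def pack(self, groups):
        """Inverse of :meth:`unpack`; ``groups`` is a list of matrix tuples."""
        if len(groups) != self.spec.G:
            raise SpecificationError("wrong number of groups")
        theta = np.empty(self.m)
        for g, (lam, psi, phi, tau, kappa) in enumerate(groups):
            for k, e in enumerate(self.entries):
                if e.matrix == "lam":
                    v = lam[e.i, e.j]
                elif e.matrix == "tau":
                    v = tau[e.i]
                elif e.matrix == "psi":
                    v = psi[e.i]
                elif e.matrix == "phi":
                    v = phi[e.i, e.j]
                else:
                    v = kappa[e.i]
                theta[g * self.m1 + k] = v
        return theta

    def penalized_loading_indices(self):
        """Global flat indices of penalized loadings, group by group."""
        return np.concatenate(
            [g * self.m1 + self.pen_load_idx for g in range(self.spec.G)]
        ).astype(int)

    def penalized_intercept_indices(self):
        return np.concatenate(
            [g * self.m1 + self.pen_tau_idx for g in range(self.spec.G)]
        ).astype(int)

    def describe(self):
        """Human-readable labels for every flat position."""
        spec = self.spec
        labels = []
        for g in range(spec.G):
            suff = f".g{g + 1}" if spec.G > 1 else ""
            for e in self.entries:
                if e.matrix == "lam":
                    labels.append(f"{spec.factor_names[e.j]}=~{spec.var_names[e.i]}{suff}")
                elif e.matrix == "tau":
                    labels.append(f"{spec.var_names[e.i]}~1{suff}")
                elif e.matrix == "psi":
                    labels.append(f"{spec.var_names[e.i]}~~{spec.var_names[e.i]}{suff}")
                elif e.matrix == "phi":
                    labels.append(f"{spec.factor_names[e.i]}~~{spec.factor_names[e.j]}{suff}")
                else:
                    labels.append(f"{spec.factor_names[e.i]}~1{suff}")
        return labels


@dataclass
class DataSummary:
    """Per-group sufficient statistics: sizes, ML covariances and means."""

    Ns: np.ndarray  # (G,)
    S: np.ndarray  # (G, p, p)
    xbar: np.ndarray | None = None  # (G, p)

    def __post_init__(self):
        self.Ns = np.asarray(self.Ns, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim == 2:
            self.S = self.S[None]
        if self.xbar is not None:
            self.xbar = np.asarray(self.xbar, dtype=float)
            if self.xbar.ndim == 1:
                self.xbar = self.xbar[None]
        for g, Sg in enumerate(self.S):
            if not np.allclose(Sg, Sg.T, atol=1e-10):
                raise SpecificationError(f"covariance matrix of group {g + 1} is not symmetric")
            if np.linalg.eigvalsh(Sg)[0] < -1e-8 * max(1.0, np.abs(Sg).max()):
                raise SpecificationError(f"covariance matrix of group {g + 1} is not positive semi-definite")

    @property
    def G(self):
        return len(self.Ns)

    @property
    def p(self):
        return self.S.shape[1]

    @property
    def N(self):
        return float(self.Ns.sum())

    @classmethod
    def from_raw(cls, X, groups=None):
        """Build sufficient statistics from a raw data matrix.

        Covariances use the maximum-likelihood divisor ``N_g``.  ``groups``
        is an optional vector of group labels (sorted order defines group
        numbering).
        """
        X = np.asarray(X, dtype=float)
        if groups is None:
            labels = [None]
            parts = [X]
        else:
            groups = np.asarray(groups)
            labels = sorted(np.unique(groups).tolist())
            parts = [X[groups == lab] for lab in labels]
        Ns, Ss, xbars = [], [], []
        for part in parts:
            n = part.shape[0]
            mu = part.mean(axis=0)
            xc = part - mu
            Ns.append(n)
            Ss.append(xc.T @ xc / n)
            xbars.append(mu)
        return cls(Ns=np.array(Ns), S=np.array(Ss), xbar=np.array(xbars))


# ---------------------------------------------------------------------------
# moments and likelihood
# ---------------------------------------------------------------------------

def implied_moments(theta, layout: ParameterLayout):
    """Model-implied (Sigma_g, mu_g) per group; mu_g is None without a mean structure."""
    out = []
    for lam, psi, phi, tau, kappa in layout.unpack(theta):
        sigma = lam @ phi @ lam.T + np.diag(psi)
        sigma = 0.5 * (sigma + sigma.T)
        mu = tau + lam @ kappa if layout.spec.mean_structure else None
        out.append((sigma, mu))
    return out


def _chol_terms(sigma, g):
    try:
        c = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise NumericError(f"implied covariance of group {g + 1} is singular or indefinite", group=g)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    inv = np.linalg.inv(sigma)
    return logdet, inv


def loglik(theta, data: DataSummary, layout: ParameterLayout):
    """Multivariate-normal log-likelihood from sufficient statistics."""
    spec = layout.spec
    p = spec.p
    total = 0.0
    for g, (sigma, mu) in enumerate(implied_moments(theta, layout)):
        logdet, inv = _chol_terms(sigma, g)
        W = data.S[g]
        if spec.mean_structure:
            d = data.xbar[g] - mu
            W = W + np.outer(d, d)
        total += -0.5 * data.Ns[g] * (logdet + np.trace(W @ inv) + p * np.log(2 * np.pi))
    return float(total)


def _moment_derivatives(lam, phi, layout: ParameterLayout, kappa=None):
    """Stacks dSigma/dtheta_k (m1,p,p) and dmu/dtheta_k (m1,p) for one group."""
    spec = layout.spec
    p, r = spec.p, spec.r
    m1 = layout.m1
    lam_phi = lam @ phi  # p x r
    dS = np.zeros((m1, p, p))
    dmu = np.zeros((m1, p)) if spec.mean_structure else None
    for k, e in enumerate(layout.entries):
        if e.matrix == "lam":
            i, j = e.i, e.j
            dS[k, i, :] += lam_phi[:, j]
            dS[k, :, i] += lam_phi[:, j]
            if spec.mean_structure:
                dmu[k, i] = kappa[e.j]
        elif e.matrix == "psi":
            dS[k, e.i, e.i] = 1.0
        elif e.matrix == "phi":
            i, j = e.i, e.j
            outer = np.outer(lam[:, i], lam[:, j])
            dS[k] = outer + outer.T if i != j else outer
        elif e.matrix == "tau":
            dmu[k, e.i] = 1.0
        else:  # kappa
            dmu[k] = lam[:, e.i]
    return dS, dmu


def score(theta, data: DataSummary, layout: ParameterLayout):
    """Analytic gradient of :func:`loglik` with respect to theta."""
    spec = layout.spec
    grad = np.zeros(layout.m)
    groups = layout.unpack(theta)
    for g, (lam, psi, phi, tau, kappa) in enumerate(groups):
        sigma = lam @ phi @ lam.T + np.diag(psi)
        _, inv = _chol_terms(sigma, g)
        W = data.S[g]
        if spec.mean_structure:
            mu = tau + lam @ kappa
            d = data.xbar[g] - mu
            W = W + np.outer(d, d)
        dS, dmu = _moment_derivatives(lam, phi, layout, kappa)
        T = inv @ (W - sigma) @ inv
        block = 0.5 * data.Ns[g] * np.einsum("ij,kji->k", T, dS)
        if spec.mean_structure:
            block += data.Ns[g] * dmu @ inv @ d
        grad[g * layout.m1 : (g + 1) * layout.m1] = block
    return grad


def fisher_information(theta, data: DataSummary, layout: ParameterLayout):
    """Expected (Fisher) information, block diagonal across groups."""
    spec = layout.spec
    F = np.zeros((layout.m, layout.m))
    for g, (lam, psi, phi, tau, kappa) in enumerate(layout.unpack(theta)):
        sigma = lam @ phi @ lam.T + np.diag(psi)
        _, inv = _chol_terms(sigma, g)
        dS, dmu = _moment_derivatives(lam, phi, layout, kappa)
        C = np.einsum("ij,kjl->kil", inv, dS)
        block = 0.5 * data.Ns[g] * np.einsum("kij,lji->kl", C, C)
        if spec.mean_structure:
            block += data.Ns[g] * dmu @ inv @ dmu.T
        sl = slice(g * layout.m1, (g + 1) * layout.m1)
        F[sl, sl] = 0.5 * (block + block.T)
    return F


def observed_information(theta, data: DataSummary, layout: ParameterLayout, h=1e-5):
    """Negative Hessian of the log-likelihood (single group only).

    Computed by central differences of the analytic score; accurate to about
    ``h**2`` relative, which is ample for the optimizer and for comparisons
    against the expected information.
    """
    if layout.spec.G > 1:
        raise SpecificationError("observed Hessian is only supported for single-group models")
    m = layout.m
    H = np.zeros((m, m))
    for k in range(m):
        step = h * max(1.0, abs(theta[k]))
        tp = theta.copy()
        tp[k] += step
        tm = theta.copy()
        tm[k] -= step
        H[:, k] = (score(tp, data, layout) - score(tm, data, layout)) / (2 * step)
    H = 0.5 * (H + H.T)
    return -H


def information(theta, data, layout, kind="fisher"):
    """Information matrix: ``fisher`` (expected) or ``hessian`` (observed, G=1)."""
    if kind == "fisher":
        return fisher_information(theta, data, layout)
    if kind == "hessian":
        return observed_information(theta, data, layout)
    raise ValueError(f"unknown information kind {kind!r}")


# ---------------------------------------------------------------------------
# unpenalized fitting
# ---------------------------------------------------------------------------

def default_start(data: DataSummary, layout: ParameterLayout):
    """Heuristic starting values: moderate loadings, half-variance uniquenesses."""
    spec = layout.spec
    groups = []
    for g in range(spec.G):
        lam = spec.lam_fixed.copy()
        lam[spec.lam_code != FIXED] = 0.3
        sd = np.sqrt(np.clip(np.diag(data.S[g]), 1e-3, None))
        psi = spec.psi_fixed.copy()
        psi[spec.psi_code == FREE] = 0.5 * np.diag(data.S[g])[spec.psi_code == FREE]
        phi = spec.phi_fixed.copy()
        phi[spec.phi_code == FREE] = 0.0
        free_d = (spec.phi_code.diagonal() == FREE)
        if free_d.any():
            phi[np.diag_indices(spec.r)] = np.where(free_d, 1.0, phi.diagonal())
        tau = kappa = None
        if spec.mean_structure:
            tau = spec.tau_fixed.copy()
            tau[spec.tau_code != FIXED] = data.xbar[g][spec.tau_code != FIXED]
            kappa = spec.kappa_fixed.copy()
            kappa[spec.kappa_code == FREE] = 0.0
        del sd
        groups.append((lam, psi, phi, tau, kappa))
    return layout.pack(groups)


def admissibility(theta, layout: ParameterLayout):
    """All unique variances positive, factor covariances PD, estimates finite."""
    if not np.all(np.isfinite(theta)):
        return False
    for lam, psi, phi, tau, kappa in layout.unpack(theta):
        if np.any(psi <= 0):
            return False
        if np.linalg.eigvalsh(0.5 * (phi + phi.T))[0] <= 0:
            return False
    return True


def fit_unpenalized(data: DataSummary, spec_or_layout, start=None, information_kind="fisher"):
    """Maximum-likelihood fit (no penalty) via the trust-region optimizer.

    Returns the :class:`~sparsefa.trustregion.TRResult`; its ``admissible``
    flag records whether all unique variances are positive and the factor
    covariance matrices positive definite.
    """
    from .trustregion import maximize_penalized  # local import avoids a cycle

    layout = spec_or_layout if isinstance(spec_or_layout, ParameterLayout) else ParameterLayout(spec_or_layout)
    m_max = min(data.N, data.G * layout.spec.p * (layout.spec.p + 1) / 2 + layout.spec.G * layout.spec.p)
    if layout.m > m_max:
        raise SpecificationError(f"model has {layout.m} parameters but at most {m_max:.0f} are identifiable")
    if start is None:
        start = default_start(data, layout)
    res = maximize_penalized(
        data, layout, penalty=None, start=np.asarray(start, dtype=float), information_kind=information_kind
    )
    res.admissible = admissibility(res.theta, layout)
    return res


def saturated_loglik(data: DataSummary):
    """Log-likelihood of the saturated model (Sigma_g = S_g, mu_g = xbar_g)."""
    p = data.p
    total = 0.0
    for g in range(data.G):
        sign, logdet = np.linalg.slogdet(data.S[g])
        total += -0.5 * data.Ns[g] * (logdet + p + p * np.log(2 * np.pi))
    return float(total)
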