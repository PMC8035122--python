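"""Synthetic factor-model data and Monte-Carlo performance metrics.

Two population designs are built in:

* ``sim1`` — a single-group model with p = 9 indicators and r = 3 correlated
  factors (unit variances, covariances 0.3).  Primary loadings are
  {0.85, 0.75, 0.65} and three small cross-loadings equal 0.30; six loadings
  are fixed to zero for rotational uniqueness.  Unique variances are set to
  ``1 - diag(Lambda Phi Lambda')`` so every indicator has unit variance.  All
  21 free loadings are penalized: 12 are truly nonzero and 9 truly zero.

* ``sim2-*`` — a two-group model with p = 12 indicators and r = 2 factors
  (marker variables x1 and x7 with fixed loadings 0.85 and zero intercepts).
  Under the ``null`` scenario both groups share loadings of 0.85/0.75 and
  zero intercepts; under ``small``/``medium``/``large`` the primary loading
  and intercept of x6 and x12 in group 2 deviate by 0.1/0.2/0.3.  Factor
  covariances are invariant (vech = (1, 0.3, 1)) and factor means zero.

Replicates are drawn i.i.d. from the implied normal distribution.  Estimated
parameter vectors are sign-aligned per factor, zero/nonzero status is decided
by rounding estimates to one decimal digit, and performance is summarized by
MSE, squared bias, true/false positive rates and the proportion of replicates
recovering the exact true pattern (PCTM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as _model
from .model import FIXED, FREE, PENALIZED, DataSummary, ModelSpec, ParameterLayout
from .penalties import PenaltyConfig, PenaltyTerm, Selectors
from .selection import auto_tune, grid_search
from .trustregion import fit_penalized

__all__ = [
    "PopulationPreset",
    "StudyResult",
    "make_preset",
    "generate_dataset",
    "align_signs",
    "classify_zero",
    "metrics",
    "run_study",
]


@dataclass
class PopulationPreset:
    """A population model plus the estimation specification used to fit it."""

    name: str
    spec: ModelSpec
    layout: ParameterLayout
    theta0: np.ndarray
    Sigma: np.ndarray  # (G, p, p)
    mu: np.ndarray | None  # (G, p) or None
    nonzero_idx: np.ndarray  # flat indices of truly nonzero penalized loadings (set F)
    zero_idx: np.ndarray  # flat indices of truly zero penalized loadings (set F^c)


def _sim1_matrices():
    lam = np.zeros((9, 3))
    lam[0:3, 0] = [0.85, 0.75, 0.65]
    lam[8, 0] = 0.30
    lam[2, 1] = 0.30
    lam[3:6, 1] = [0.85, 0.75, 0.65]
    lam[5, 2] = 0.30
    lam[6:9, 2] = [0.85, 0.75, 0.65]
    phi = np.full((3, 3), 0.3)
    np.fill_diagonal(phi, 1.0)
    psi = 1.0 - np.diag(lam @ phi @ lam.T)
    return lam, phi, psi


def _sim1_preset():
    lam0, phi0, psi0 = _sim1_matrices()
    lam_code = np.full((9, 3), PENALIZED)
    # r - 1 = 2 fixed zeros per column for uniqueness under rotation
    for j, rows in enumerate([(3, 6), (0, 6), (0, 3)]):
        for i in rows:
            lam_code[i, j] = FIXED
    phi_code = np.full((3, 3), FREE)
    np.fill_diagonal(phi_code, FIXED)
    spec = ModelSpec(
        p=9, r=3, G=1,
        lam_code=lam_code, lam_fixed=np.zeros((9, 3)),
        phi_code=phi_code, phi_fixed=np.eye(3),
    )
    layout = ParameterLayout(spec)
    theta0 = layout.pack([(lam0, psi0, phi0, None, None)])
    sigma = lam0 @ phi0 @ lam0.T + np.diag(psi0)
    pen = layout.penalized_loading_indices()
    nz = pen[np.abs(theta0[pen]) > 1e-12]
    z = pen[np.abs(theta0[pen]) <= 1e-12]
    return PopulationPreset("sim1", spec, layout, theta0, sigma[None], None, nz, z)


_SIM2_DELTAS = {"null": 0.0, "small": 0.1, "medium": 0.2, "large": 0.3}


def _sim2_preset(scenario):
    delta = _SIM2_DELTAS[scenario]
    p, r = 12, 2
    lam1 = np.zeros((p, r))
    lam1[0:3, 0] = 0.85
    lam1[3:6, 0] = 0.75
    lam1[6:9, 1] = 0.85
    lam1[9:12, 1] = 0.75
    tau1 = np.zeros(p)
    lam2 = lam1.copy()
    tau2 = tau1.copy()
    lam2[5, 0] -= delta  # x6 primary loading
    lam2[11, 1] -= delta  # x12 primary loading
    tau2[5] -= delta
    tau2[11] -= delta
    phi = np.array([[1.0, 0.3], [0.3, 1.0]])
    kappa = np.zeros(r)
    psi1 = 1.0 - np.diag(lam1 @ phi @ lam1.T)
    psi2 = 1.0 - np.diag(lam2 @ phi @ lam2.T)

    lam_code = np.full((p, r), PENALIZED)
    lam_fixed = np.zeros((p, r))
    for i, j in [(0, 0), (6, 1)]:  # markers: fixed loading on own factor, zero on the other
        lam_code[i, :] = FIXED
        lam_fixed[i, j] = 0.85
    tau_code = np.full(p, PENALIZED)
    tau_code[[0, 6]] = FIXED
    phi_code = np.full((r, r), FREE)
    spec = ModelSpec(
        p=p, r=r, G=2,
        lam_code=lam_code, lam_fixed=lam_fixed,
        phi_code=phi_code, phi_fixed=np.zeros((r, r)),
        mean_structure=True,
        tau_code=tau_code, tau_fixed=np.zeros(p),
        kappa_code=np.full(r, FREE), kappa_fixed=np.zeros(r),
    )
    layout = ParameterLayout(spec)
    theta0 = layout.pack([
        (lam1, psi1, phi, tau1, kappa),
        (lam2, psi2, phi, tau2, kappa),
    ])
    sig1 = lam1 @ phi @ lam1.T + np.diag(psi1)
    sig2 = lam2 @ phi @ lam2.T + np.diag(psi2)
    mu1 = tau1 + lam1 @ kappa
    mu2 = tau2 + lam2 @ kappa
    pen = layout.penalized_loading_indices()
    nz = pen[np.abs(theta0[pen]) > 1e-12]
    z = pen[np.abs(theta0[pen]) <= 1e-12]
    return PopulationPreset(
        f"sim2-{scenario}", spec, layout, theta0, np.stack([sig1, sig2]), np.stack([mu1, mu2]), nz, z
    )


def make_preset(name):
    """Build a named population preset (``sim1`` or ``sim2-<scenario>``)."""
    if name == "sim1":
        return _sim1_preset()
    if name.startswith("sim2-"):
        scenario = name.split("-", 1)[1]
        if scenario not in _SIM2_DELTAS:
            raise ValueError(f"unknown difference scenario {scenario!r}")
        return _sim2_preset(scenario)
    raise ValueError(f"unknown preset {name!r}")


def generate_dataset(preset: PopulationPreset, N, rng):
    """Draw i.i.d. multivariate-normal samples per group.

    ``N`` is the total sample size, split evenly across groups (or a
    per-group sequence).  Returns ``(X, group_labels)``; labels are None for
    a single group.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    G = preset.spec.G
    if np.isscalar(N):
        Ns = [int(N) // G] * G
        Ns[0] += int(N) - sum(Ns)
    else:
        Ns = [int(n) for n in N]
    Xs, labels = [], []
    for g in range(G):
        L = np.linalg.cholesky(preset.Sigma[g])
        Z = rng.standard_normal((Ns[g], preset.spec.p))
        X = Z @ L.T
        if preset.mu is not None:
            X = X + preset.mu[g]
        Xs.append(X)
        labels.append(np.full(Ns[g], g + 1))
    X = np.vstack(Xs)
    return (X, None) if G == 1 else (X, np.concatenate(labels))


def align_signs(theta_hat, preset: PopulationPreset):
    """Undo factor sign reversals so primary loadings match the population sign.

    For each group and factor, the free loading with the largest absolute
    population value acts as the reference; if its estimate has the opposite
    sign, the whole factor is flipped (loadings, factor covariances and
    means).  Idempotent by construction.
    """
    layout = preset.layout
    spec = preset.spec
    groups_hat = layout.unpack(np.asarray(theta_hat, dtype=float))
    groups0 = layout.unpack(preset.theta0)
    out = []
    for (lam, psi, phi, tau, kappa), (lam0, _, _, _, _) in zip(groups_hat, groups0):
        lam = lam.copy()
        phi = phi.copy()
        kappa = None if kappa is None else kappa.copy()
        for j in range(spec.r):
            free = spec.lam_code[:, j] != FIXED
            if not free.any():
                continue
            ref = np.argmax(np.abs(np.where(free, lam0[:, j], 0.0)))
            if lam0[ref, j] * lam[ref, j] < 0:
                lam[:, j] *= -1.0
                phi[j, :] *= -1.0
                phi[:, j] *= -1.0
                if kappa is not None:
                    kappa[j] *= -1.0
        out.append((lam, psi, phi, tau, kappa))
    return layout.pack(out)


def classify_zero(estimates, decimals=1):
    """True where an estimate counts as zero: ``|round(x, 1)| == 0``."""
    return np.abs(np.round(np.asarray(estimates, dtype=float), decimals)) == 0


def _difference_truth(preset: PopulationPreset, sel: Selectors):
    """True zero/nonzero status of the fused cross-group differences."""
    truths = []
    for target in ("loading_diff", "intercept_diff"):
        for pairs in sel.pairs(target):
            d = sum(abs(preset.theta0[i] - preset.theta0[k]) for i, k in pairs)
            truths.append(d > 1e-12)
    return np.asarray(truths, dtype=bool)


def _difference_estimates(theta, sel: Selectors):
    ests = []
    for target in ("loading_diff", "intercept_diff"):
        for pairs in sel.pairs(target):
            ests.append(sum(abs(theta[i] - theta[k]) for i, k in pairs))
    return np.asarray(ests)


@dataclass
class StudyResult:
    """Monte-Carlo summary of one simulation condition."""

    name: str
    L: int
    mse: float
    mse_se: float
    mse_range: tuple
    sb: float
    tpr: float
    tpr_range: tuple
    fpr: float
    fpr_se: float
    fpr_range: tuple
    pctm: float
    pctm_se: float
    pctm_loadings: float
    pctm_full: float
    extra: dict = field(default_factory=dict)

    def to_dict(self):
        d = {k: getattr(self, k) for k in (
            "name", "L", "mse", "mse_se", "sb", "tpr", "fpr", "fpr_se",
            "pctm", "pctm_se", "pctm_loadings", "pctm_full")}
        d["mse_range"] = list(self.mse_range)
        d["tpr_range"] = list(self.tpr_range)
        d["fpr_range"] = list(self.fpr_range)
        return d


def metrics(estimates, preset: PopulationPreset, name="study", include_differences=None):
    """Performance metrics over replicates of aligned estimates.

    ``estimates`` is an (L, m) array.  MSE is the replicate-average squared
    distance to the population vector, SB the squared distance of the
    replicate mean.  TPR/FPR average per-replicate classification rates over
    the truly nonzero / truly zero penalized loadings.  PCTM is the fraction
    of replicates whose full zero/nonzero pattern is exact; for multiple
    groups the primary PCTM additionally requires the cross-group
    loading/intercept differences to be correctly classified as zero or
    nonzero (a loadings-only variant is also reported).
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 2 or est.shape[0] == 0:
        raise ValueError("estimates must be a nonempty (L, m) array")
    L = est.shape[0]
    theta0 = preset.theta0
    sq = ((est - theta0) ** 2).sum(axis=1)
    mse = float(sq.mean())
    mse_se = float(sq.std(ddof=1) / np.sqrt(L)) if L > 1 else 0.0
    sb = float(((est.mean(axis=0) - theta0) ** 2).sum())

    nz, z = preset.nonzero_idx, preset.zero_idx
    nonzero_hat = ~classify_zero(est)
    tpr_l = nonzero_hat[:, nz].mean(axis=1) if nz.size else np.ones(L)
    fpr_l = nonzero_hat[:, z].mean(axis=1) if z.size else np.zeros(L)
    pen = np.concatenate([nz, z])
    truth_nonzero = np.concatenate([np.ones(nz.size, bool), np.zeros(z.size, bool)])
    correct_loadings = (nonzero_hat[:, pen] == truth_nonzero).all(axis=1)

    if include_differences is None:
        include_differences = preset.spec.G > 1
    if preset.spec.G > 1:
        sel = Selectors(preset.layout)
        truth_d = _difference_truth(preset, sel)
        d_nonzero = np.stack([~classify_zero(_difference_estimates(t, sel)) for t in est])
        correct_full = correct_loadings & (d_nonzero == truth_d).all(axis=1)
    else:
        correct_full = correct_loadings
    pctm_loadings = float(correct_loadings.mean())
    pctm_full = float(correct_full.mean())
    pctm = pctm_full if include_differences else pctm_loadings
    return StudyResult(
        name=name,
        L=L,
        mse=mse,
        mse_se=mse_se,
        mse_range=(float(sq.min()), float(sq.max())),
        sb=sb,
        tpr=float(tpr_l.mean()),
        tpr_range=(float(tpr_l.min()), float(tpr_l.max())),
        fpr=float(fpr_l.mean()),
        fpr_se=float(fpr_l.std(ddof=1) / np.sqrt(L)) if L > 1 else 0.0,
        fpr_range=(float(fpr_l.min()), float(fpr_l.max())),
        pctm=pctm,
        pctm_se=float(np.sqrt(max(pctm * (1 - pctm), 1e-12) / L)),
        pctm_loadings=pctm_loadings,
        pctm_full=pctm_full,
    )


def default_penalty_config(preset: PopulationPreset, ptype="alasso", a=2.0, gamma=4.5):
    """Estimator penalty layout used in the Monte-Carlo studies."""
    terms = [PenaltyTerm("sparsity", ptype, 0.0, a)]
    if preset.spec.G > 1:
        terms += [
            PenaltyTerm("loading_diff", ptype, 0.0, a),
            PenaltyTerm("intercept_diff", ptype, 0.0, a),
        ]
    return PenaltyConfig(terms=terms, gamma=gamma)


def _one_replicate(preset, N, estimator, config, seed_parts, information_kind, eta_grid, retry_cap=20):
    """Generate-and-fit with regeneration on inadmissible unpenalized fits."""
    for attempt in range(retry_cap):
        rng = np.random.default_rng(list(seed_parts) + [attempt])
        X, labels = generate_dataset(preset, N, rng)
        data = DataSummary.from_raw(X, labels)
        try:
            mle = _model.fit_unpenalized(data, preset.layout, information_kind=information_kind)
        except (_model.NumericError, np.linalg.LinAlgError):
            continue
        if not (mle.converged and mle.admissible):
            continue
        if estimator == "mle":
            return mle.theta
        if estimator == "auto":
            fit = auto_tune(data, preset.layout, config, mle=mle, information_kind=information_kind)
            return fit.theta
        if estimator == "grid":
            fit, _ = grid_search(data, preset.layout, config, eta_grid, start=mle.theta,
                                 information_kind=information_kind)
            return fit.theta
        raise ValueError(f"unknown estimator {estimator!r}")
    raise RuntimeError(f"no admissible replicate after {retry_cap} attempts (seed parts {seed_parts})")


def run_study(
    preset_name,
    N,
    L,
    seed,
    estimator="auto",
    ptype="alasso",
    a=2.0,
    gamma=4.5,
    information_kind="fisher",
    eta_grid=None,
    return_estimates=False,
):
    """Monte-Carlo evaluation of one condition.

    Replicates are seeded from the master ``seed`` by a counter scheme so
    regeneration of inadmissible draws is reproducible and independent of the
    evaluation order.
    """
    preset = make_preset(preset_name)
    config = default_penalty_config(preset, ptype=ptype, a=a, gamma=gamma)
    thetas = np.empty((L, preset.layout.m))
    for l in range(L):
        theta = _one_replicate(
            preset, N, estimator, config, (seed, l), information_kind, eta_grid
        )
        thetas[l] = align_signs(theta, preset)
    name = f"{preset_name}/N={N}/{estimator}-{ptype if estimator != 'mle' else 'none'}"
    result = metrics(thetas, preset, name=name)
    result.extra.update(dict(N=N, estimator=estimator, ptype=ptype, a=a, gamma=gamma, seed=seed))
    if return_estimates:
        return result, thetas
    return result
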