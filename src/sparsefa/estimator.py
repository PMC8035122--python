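"""Scikit-learn style estimator front end.

:class:`PenalizedFactorAnalysis` wraps the penalized maximum-likelihood
machinery (trust-region fitting, automatic tuning, edf/GBIC selection) behind
the familiar ``fit`` / ``transform`` API so it composes with sklearn
pipelines and model selection.  The functional modules remain the primitive
surface; the estimator only orchestrates them.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import model as _model
from .model import FIXED, FREE, PENALIZED, DataSummary, ModelSpec, ParameterLayout
from .penalties import PenaltyConfig, PenaltyTerm, Selectors
from .selection import FitResult, auto_tune, fit_at_eta, grid_search

__all__ = ["PenalizedFactorAnalysis"]


def _default_spec(p, r, G, mean_structure):
    """Echelon-identified default: lambda_ij = 0 fixed for i < j, all other
    loadings penalized, unit factor variances (G=1) or first-indicator
    markers (G>1)."""
    lam_code = np.full((p, r), PENALIZED)
    lam_fixed = np.zeros((p, r))
    if G == 1:
        for j in range(r):
            lam_code[:j, j] = FIXED
        return ModelSpec(p=p, r=r, G=1, lam_code=lam_code, lam_fixed=lam_fixed)
    # marker convention: indicator j is the marker of factor j
    tau_code = np.full(p, PENALIZED)
    for j in range(r):
        lam_code[j, :] = FIXED
        lam_fixed[j, j] = 1.0
        tau_code[j] = FIXED
    phi_code = np.full((r, r), FREE)
    return ModelSpec(
        p=p, r=r, G=G, lam_code=lam_code, lam_fixed=lam_fixed,
        phi_code=phi_code, phi_fixed=np.zeros((r, r)),
        mean_structure=True, tau_code=tau_code,
    )


class PenalizedFactorAnalysis(TransformerMixin, BaseEstimator):
    """Penalized (sparse) confirmatory/exploratory factor analysis.

    Parameters
    ----------
    n_factors : int
        Number of latent factors (ignored when ``model`` is a full spec).
    model : ModelSpec or str, optional
        Measurement model: a :class:`ModelSpec` or model-syntax text
        (``"f1 =~ x1 + x2 + x3"`` lines).  When omitted, an echelon-identified
        model with all loadings penalized is used.
    penalty : {'lasso', 'alasso', 'scad', 'mcp', 'none'}
        Penalty family on the loadings (and, with several groups, on the
        cross-group differences of loadings and intercepts).
    eta : 'auto', float, sequence or None
        Tuning strategy: ``'auto'`` estimates the tuning vector by minimizing
        the UBRE criterion (lasso/alasso only); a number or vector fixes it;
        ``None`` or 0 fits the unpenalized MLE.
    eta_grid : iterable, optional
        When given, selects eta by grid search on GBIC instead.
    a : float
        Penalty shape: adaptive-lasso exponent, or scad/mcp concavity.
    gamma : float
        Influence factor (>= 1) inflating the complexity term of the tuning
        criterion; larger values give sparser fits.
    c_bar : float
        Smooth-absolute-value constant of the differentiable approximation.
    information : {'fisher', 'hessian'}
        Curvature used by the trust-region optimizer.
    vcov : {'bayesian', 'sandwich'}
        Posterior covariance form for the intervals.

    Attributes
    ----------
    loadings_ : ndarray (p, r) or list of such per group
    uniquenesses_, factor_cov_, intercepts_, factor_means_ : fitted matrices
    theta_, eta_, edf_, gbic_, loglik_ : fitted quantities
    result_ : full :class:`~sparsefa.selection.FitResult`
    """

    def __init__(
        self,
        n_factors=1,
        model=None,
        penalty="alasso",
        eta="auto",
        eta_grid=None,
        a=2.0,
        gamma=4.5,
        c_bar=1e-8,
        information="fisher",
        vcov="bayesian",
    ):
        self.n_factors = n_factors
        self.model = model
        self.penalty = penalty
        self.eta = eta
        self.eta_grid = eta_grid
        self.a = a
        self.gamma = gamma
        self.c_bar = c_bar
        self.information = information
        self.vcov = vcov

    # ------------------------------------------------------------------
    def _resolve_spec(self, p, G, feature_names):
        if isinstance(self.model, ModelSpec):
            return self.model
        if isinstance(self.model, str):
            from .modelsyntax import parse_model

            return parse_model(self.model, feature_names, G=G)
        return _default_spec(p, self.n_factors, G, mean_structure=G > 1)

    def _penalty_config(self, layout):
        if self.penalty in (None, "none") or self.eta is None:
            return PenaltyConfig(terms=[], gamma=max(self.gamma, 1.0), c_bar=self.c_bar)
        terms = [PenaltyTerm("sparsity", self.penalty, 0.0, self.a)]
        if layout.spec.G > 1:
            if layout.q_star:
                terms.append(PenaltyTerm("loading_diff", self.penalty, 0.0, self.a))
            if layout.k_star:
                terms.append(PenaltyTerm("intercept_diff", self.penalty, 0.0, self.a))
        return PenaltyConfig(terms=terms, gamma=max(self.gamma, 1.0), c_bar=self.c_bar)

    def fit(self, X, y=None, groups=None):
        """Fit the factor model to raw data (rows = observations)."""
        feature_names = list(X.columns) if hasattr(X, "columns") else None
        X = check_array(X, ensure_min_samples=4)
        data = DataSummary.from_raw(X, groups)
        spec = self._resolve_spec(X.shape[1], data.G, feature_names)
        spec.identification_check()
        layout = ParameterLayout(spec)
        config = self._penalty_config(layout)
        unpenalized = (
            not config.terms
            or (np.isscalar(self.eta) and not isinstance(self.eta, str) and float(self.eta) == 0.0)
        )
        if unpenalized:
            mle = _model.fit_unpenalized(data, layout, information_kind=self.information)
            result = fit_at_eta(
                data, layout, PenaltyConfig(terms=[], gamma=max(self.gamma, 1.0), c_bar=self.c_bar),
                eta=[], start=mle.theta, information_kind=self.information,
            )
        elif self.eta_grid is not None:
            result, self.path_ = grid_search(
                data, layout, config, self.eta_grid, information_kind=self.information
            )
        elif isinstance(self.eta, str) and self.eta == "auto":
            result = auto_tune(data, layout, config, information_kind=self.information)
        else:
            eta = np.broadcast_to(np.atleast_1d(np.asarray(self.eta, float)), (len(config.terms),))
            result = fit_at_eta(data, layout, config, eta=eta, information_kind=self.information)
        self._store(result, data, layout)
        return self

    def _store(self, result: FitResult, data, layout):
        self.result_ = result
        self.layout_ = layout
        self.spec_ = layout.spec
        self.data_ = data
        self.theta_ = result.theta
        self.eta_ = result.eta
        self.edf_ = result.edf_total
        self.gbic_ = result.gbic
        self.loglik_ = result.loglik
        groups = layout.unpack(result.theta)
        lams, psis, phis, taus, kappas = zip(*groups)
        single = layout.spec.G == 1
        self.loadings_ = lams[0] if single else list(lams)
        self.uniquenesses_ = psis[0] if single else list(psis)
        self.factor_cov_ = phis[0] if single else list(phis)
        self.intercepts_ = None if taus[0] is None else (taus[0] if single else list(taus))
        self.factor_means_ = None if kappas[0] is None else (kappas[0] if single else list(kappas))
        self.n_features_in_ = layout.spec.p

    # ------------------------------------------------------------------
    def transform(self, X, group=0):
        """Regression-method factor scores ``E[f | x]``."""
        check_is_fitted(self, "theta_")
        X = check_array(X)
        g = 0 if self.spec_.G == 1 else int(group)
        lam, psi, phi, tau, kappa = self.layout_.unpack(self.theta_)[g]
        sigma = lam @ phi @ lam.T + np.diag(psi)
        if self.spec_.mean_structure:
            mu = tau + lam @ kappa
            xc = X - mu
            base = kappa
        else:
            xc = X - self.data_.xbar[g] if self.data_.xbar is not None else X
            base = 0.0
        return base + xc @ np.linalg.solve(sigma, lam @ phi)

    def score(self, X, y=None, groups=None):
        """Average log-likelihood per observation under the fitted model."""
        check_is_fitted(self, "theta_")
        X = check_array(X)
        data = DataSummary.from_raw(X, groups)
        return _model.loglik(self.theta_, data, self.layout_) / data.N

    def summary(self):
        check_is_fitted(self, "result_")
        return self.result_.summary()
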