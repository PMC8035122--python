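import numpy as np
import pytest

from sparsefa import (
    DataSummary,
    auto_tune,
    classify_zero,
    fit_at_eta,
    gbic,
    generate_dataset,
    grid_search,
    influence_and_edf,
    make_preset,
    posterior_uncertainty,
    ubre,
    ubre_gradient,
)
from sparsefa.model import fisher_information, fit_unpenalized
from sparsefa.penalties import ConfigError, PenaltyConfig, PenaltyTerm, Selectors
from sparsefa.selection import prepare_alasso_weights, stopping_criterion
from sparsefa.simulation import default_penalty_config


@pytest.fixture(scope="module")
def sim1_fit(sim1):
    X, _ = generate_dataset(sim1, 500, np.random.default_rng(31))
    data = DataSummary.from_raw(X)
    mle = fit_unpenalized(data, sim1.layout)
    sel = Selectors(sim1.layout)
    cfg = prepare_alasso_weights(default_penalty_config(sim1), mle.theta, sel)
    return data, mle, sel, cfg


class TestEdf:
    def test_eta_zero_full_dimension(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        A, edf, per, _ = influence_and_edf(mle.theta, data, sim1.layout, cfg.with_eta([0.0]), sel)
        assert edf == pytest.approx(sim1.layout.m, abs=1e-8)
        assert np.allclose(A, np.eye(sim1.layout.m), atol=1e-8)

    def test_eta_infinity_drops_penalized_count(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        _, edf, per, _ = influence_and_edf(mle.theta, data, sim1.layout, cfg.with_eta([1e8]), sel)
        assert edf == pytest.approx(sim1.layout.m - sim1.layout.q_star, abs=0.01)

    def test_unpenalized_parameters_have_unit_edf(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        _, _, per, _ = influence_and_edf(mle.theta, data, sim1.layout, cfg.with_eta([0.3]), sel)
        unpen = np.arange(sim1.layout.q_star, sim1.layout.m)
        assert np.all(per >= 0) and np.all(per <= 1)
        assert np.allclose(per[unpen], 1.0, atol=1e-6)

    def test_trace_two_ways(self, sim1, sim1_fit):
        """tr(A) via the hat matrix equals tr((F+NE)^{-1} F)."""
        data, mle, sel, cfg = sim1_fit
        from sparsefa.penalties import build_penalty_matrix

        A, edf, _, _ = influence_and_edf(mle.theta, data, sim1.layout, cfg.with_eta([0.07]), sel)
        F = fisher_information(mle.theta, data, sim1.layout)
        E = build_penalty_matrix(mle.theta, cfg.with_eta([0.07]), sel)
        alt = np.trace(np.linalg.solve(F + data.N * E, F))
        assert edf == pytest.approx(alt, abs=1e-8)


class TestGbic:
    def test_reduces_to_bic_at_eta_zero(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        _, edf, _, _ = influence_and_edf(mle.theta, data, sim1.layout, cfg.with_eta([0.0]), sel)
        assert gbic(mle.loglik, edf, data.N) == pytest.approx(
            -2 * mle.loglik + sim1.layout.m * np.log(data.N), abs=1e-6
        )

    def test_aic_variant(self):
        assert gbic(-100.0, 5.0, 50, kind="aic") == pytest.approx(210.0)


class TestUbre:
    def test_eta_zero_closed_form(self, sim1, sim1_fit):
        """With A = I the residual term vanishes: V = 2 gamma m / N - 1."""
        data, mle, sel, cfg = sim1_fit
        v = ubre(mle.theta, data, sim1.layout, cfg.with_eta([0.0]), sel)
        assert v == pytest.approx(2 * cfg.gamma * sim1.layout.m / data.N - 1, abs=1e-6)

    def test_gamma_shift_identity(self, sim1, sim1_fit):
        """V_gamma - V_1 = 2 (gamma - 1) tr(A) / N at any eta."""
        data, mle, sel, cfg = sim1_fit
        eta = [0.12]
        _, trA, _, _ = influence_and_edf(mle.theta, data, sim1.layout, cfg.with_eta(eta), sel)
        cfg1 = PenaltyConfig(terms=cfg.with_eta(eta).terms, gamma=1.0, c_bar=cfg.c_bar)
        v_g = ubre(mle.theta, data, sim1.layout, cfg.with_eta(eta), sel)
        v_1 = ubre(mle.theta, data, sim1.layout, cfg1, sel)
        assert v_g - v_1 == pytest.approx(2 * (cfg.gamma - 1) * trA / data.N, rel=1e-8)

    def test_gradient_matches_finite_differences(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        for eta0 in (0.01, 0.1, 1.0):
            g = ubre_gradient(mle.theta, data, sim1.layout, cfg.with_eta([eta0]), sel)
            h = 1e-6
            vp = ubre(mle.theta, data, sim1.layout, cfg.with_eta([eta0 * np.exp(h)]), sel)
            vm = ubre(mle.theta, data, sim1.layout, cfg.with_eta([eta0 * np.exp(-h)]), sel)
            assert g[0] == pytest.approx((vp - vm) / (2 * h), rel=1e-5, abs=1e-10)


class TestAutoTune:
    def test_stopping_rule_inequality(self):
        """The rule fires exactly when |l1 - l0| / (0.1 + |l1|) < 1e-7."""
        l1 = -3521.77
        on_edge = 1e-7 * (0.1 + abs(l1))
        assert stopping_criterion(l1, l1 - on_edge * 0.99)
        assert not stopping_criterion(l1, l1 - on_edge * 1.01)

    def test_recovers_sparsity_pattern_sim1(self, sim1):
        """One seeded replicate at N = 1000: every true-zero loading is
        classified zero and every true-nonzero loading retained."""
        X, _ = generate_dataset(sim1, 1000, np.random.default_rng(77))
        data = DataSummary.from_raw(X)
        fit = auto_tune(data, sim1.layout, default_penalty_config(sim1))
        assert fit.converged
        nonzero = ~classify_zero(fit.theta)
        assert not nonzero[sim1.zero_idx].any()
        assert nonzero[sim1.nonzero_idx].all()

    def test_dense_model_keeps_near_full_edf(self):
        """Data from a dense (no-zero) loading model: the selected eta is
        small and edf stays within 1 of m."""
        import sparsefa
        from sparsefa.model import FIXED, PENALIZED, ModelSpec, ParameterLayout

        lam_code = np.full((5, 1), PENALIZED)
        spec = ModelSpec(p=5, r=1, lam_code=lam_code)
        lay = ParameterLayout(spec)
        lam0 = np.full((5, 1), 0.8)
        psi0 = 1 - 0.64 * np.ones(5)
        theta0 = lay.pack([(lam0, psi0, np.eye(1), None, None)])
        sigma = lam0 @ lam0.T + np.diag(psi0)
        rng = np.random.default_rng(42)
        X = rng.multivariate_normal(np.zeros(5), sigma, size=2000, method="cholesky")
        data = DataSummary.from_raw(X)
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "alasso", 0.0, a=2.0)], gamma=4.5)
        fit = auto_tune(data, lay, cfg)
        assert fit.edf_total > lay.m - 1

    def test_scad_rejected(self, sim1, sim1_fit):
        data, _, _, _ = sim1_fit
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "scad", 0.1, a=3.7)])
        with pytest.raises(ConfigError):
            auto_tune(data, sim1.layout, cfg)


class TestGridSearch:
    def test_bracket_grid_picks_smaller_bic(self, sim1, sim1_fit):
        """Grid {~0, huge}: the winner matches whichever of the MLE-BIC and
        the fully restricted BIC is smaller."""
        data, mle, sel, cfg = sim1_fit
        fit, path = grid_search(data, sim1.layout, cfg, [1e-8, 1e6], start=mle.theta)
        assert fit.gbic == pytest.approx(path["gbic"].min())
        assert len(path) == 2

    def test_lasso_path_edf_nonincreasing(self, sim1, sim1_fit):
        """edf decreases along an increasing lasso path.  The grid stops
        before the degenerate regime where every loading is driven to zero
        and the factor covariance block loses identification (zero Fisher
        rows), after which edf is no longer meaningful."""
        data, mle, sel, _ = sim1_fit
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "lasso", 0.0)], gamma=1.0)
        _, path = grid_search(data, sim1.layout, cfg, np.geomspace(1e-4, 0.2, 10), start=mle.theta)
        edfs = path["edf"].to_numpy()
        assert np.all(np.diff(edfs) <= 1e-6)

    def test_grid_and_auto_agree_on_classification(self, sim1):
        X, _ = generate_dataset(sim1, 1000, np.random.default_rng(123))
        data = DataSummary.from_raw(X)
        cfg = default_penalty_config(sim1)
        auto_fit = auto_tune(data, sim1.layout, cfg)
        grid_fit, _ = grid_search(data, sim1.layout, cfg, np.geomspace(1e-5, 0.5, 40))
        assert np.array_equal(classify_zero(auto_fit.theta), classify_zero(grid_fit.theta))


class TestPosterior:
    def test_eta_zero_recovers_ml_covariance(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        V, _ = posterior_uncertainty(mle.theta, data, sim1.layout, cfg.with_eta([0.0]), sel)
        F = fisher_information(mle.theta, data, sim1.layout)
        assert np.allclose(V, np.linalg.inv(F), atol=1e-10)

    def test_interval_width_shrinks_with_n(self, sim1):
        widths = {}
        for N in (300, 1000):
            X, _ = generate_dataset(sim1, N, np.random.default_rng(55))
            data = DataSummary.from_raw(X)
            fit = auto_tune(data, sim1.layout, default_penalty_config(sim1))
            widths[N] = np.median(fit.ci[:, 1] - fit.ci[:, 0])
        ratio = widths[300] / widths[1000]
        assert 1.3 < ratio < 2.6  # ~sqrt(1000/300) = 1.83

    def test_coverage_near_nominal(self, sim1):
        """Stochastic spot check: across replicates and parameters the 95%
        posterior intervals cover the truth at roughly the nominal rate."""
        hits = total = 0
        for l in range(25):
            X, _ = generate_dataset(sim1, 500, np.random.default_rng([202, l]))
            data = DataSummary.from_raw(X)
            fit = auto_tune(data, sim1.layout, default_penalty_config(sim1))
            covered = (fit.ci[:, 0] <= sim1.theta0) & (sim1.theta0 <= fit.ci[:, 1])
            hits += covered.sum()
            total += covered.size
        assert 0.88 < hits / total <= 1.0

    def test_sandwich_option(self, sim1, sim1_fit):
        data, mle, sel, cfg = sim1_fit
        fit = fit_at_eta(data, sim1.layout, cfg, [0.05], start=mle.theta)
        Vb, _ = posterior_uncertainty(fit.theta, data, sim1.layout, cfg.with_eta([0.05]), sel)
        Vs, _ = posterior_uncertainty(fit.theta, data, sim1.layout, cfg.with_eta([0.05]), sel, vcov="sandwich")
        assert not np.allclose(Vb, Vs)
        assert np.all(np.diag(Vs) <= np.diag(Vb) + 1e-12)
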