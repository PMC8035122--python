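import numpy as np
import pytest

from sparsefa import Selectors, build_penalty_matrix, make_preset, penalty_value, shrink_weight
from sparsefa.penalties import (
    ConfigError,
    PenaltyConfig,
    PenaltyTerm,
    adaptive_weights,
    pen_deriv,
    pen_value,
    unit_penalty_matrices,
)


class TestScalarPenalties:
    def test_lasso_is_eta_abs(self):
        assert pen_value(0.3, "lasso", 0.1) == pytest.approx(0.03)

    def test_scad_continuous_at_breakpoints(self):
        """The scad pieces agree at |t| = eta and |t| = a*eta."""
        eta, a = 0.2, 3.7
        for b in (eta, a * eta):
            below = pen_value(b - 1e-9, "scad", eta, a=a)
            above = pen_value(b + 1e-9, "scad", eta, a=a)
            assert above == pytest.approx(below, abs=1e-8)
        assert pen_value(10.0, "scad", eta, a=a) == pytest.approx((a + 1) * eta**2 / 2)

    def test_mcp_continuous_and_constant_beyond(self):
        eta, a = 0.2, 3.0
        b = a * eta
        assert pen_value(b + 1e-9, "mcp", eta, a=a) == pytest.approx(pen_value(b - 1e-9, "mcp", eta, a=a), abs=1e-8)
        assert pen_value(5.0, "mcp", eta, a=a) == pytest.approx(a * eta**2 / 2)

    @pytest.mark.parametrize("ptype,a", [("lasso", 3.7), ("alasso", 1.0), ("scad", 3.7), ("mcp", 3.0)])
    def test_derivative_matches_numeric(self, ptype, a):
        """pen_deriv is the derivative of pen_value away from the kinks."""
        eta = 0.15
        for t in [0.01, 0.1, 0.2, 0.4, 0.8, 2.0]:
            num = (pen_value(t + 1e-7, ptype, eta, a=a) - pen_value(t - 1e-7, ptype, eta, a=a)) / 2e-7
            assert pen_deriv(t, ptype, eta, a=a) == pytest.approx(num, abs=1e-6)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ConfigError):
            pen_value(0.1, "scad", 0.1, a=2.0)
        with pytest.raises(ConfigError):
            pen_value(0.1, "mcp", 0.1, a=1.0)
        with pytest.raises(ConfigError):
            pen_value(0.1, "lasso", -0.1)


class TestShrinkWeights:
    def test_lasso_weight(self):
        assert shrink_weight(0.5, "lasso", 0.1) == pytest.approx(0.2, rel=1e-6)

    def test_alasso_weight(self):
        assert shrink_weight(0.4, "alasso", 0.2, a=1.0, w=1 / 0.8) == pytest.approx(0.625, rel=1e-6)

    def test_mcp_zero_beyond_a_eta(self):
        assert shrink_weight(0.9, "mcp", 0.2, a=3.0) == pytest.approx(0.0, abs=1e-12)

    def test_scad_inner_region(self):
        assert shrink_weight(0.05, "scad", 0.1, a=3.7) == pytest.approx(2.0, rel=1e-4)

    def test_nonnegative_and_vanishing_for_unbiased_types(self):
        """m_q >= 0 always; for alasso/scad/mcp it vanishes as |t| grows, while
        lasso keeps eta * |t| ~ m_q t^2 -> eta."""
        eta = 0.3
        big = 50.0
        for ptype, a in [("alasso", 2.0), ("scad", 3.7), ("mcp", 3.0)]:
            w = 1 / big**a if ptype == "alasso" else 1.0
            assert shrink_weight(big, ptype, eta, a=a, w=w) < 1e-4
        assert shrink_weight(big, "lasso", eta) * big == pytest.approx(eta, rel=1e-4)
        for ptype, a in [("lasso", 3.7), ("alasso", 1.0), ("scad", 3.7), ("mcp", 3.0)]:
            for t in [0.0, 0.05, 0.3, 1.0]:
                assert shrink_weight(t, ptype, eta, a=a) >= 0

    def test_weight_at_zero_is_large_but_finite(self):
        assert shrink_weight(0.0, "lasso", 1.0, c_bar=1e-8) == pytest.approx(1e4)


@pytest.fixture(scope="module")
def sim2_sel():
    preset = make_preset("sim2-null")
    return preset, Selectors(preset.layout)


class TestSelectors:
    def test_single_group_sparsity_indices(self, sim1):
        sel = Selectors(sim1.layout)
        assert sel.sparsity_idx.tolist() == list(range(21))
        R = sel.R(3)
        assert R[3, 3] == 1 and R.sum() == 1

    def test_pairwise_difference_g2(self, sim2_sel):
        preset, sel = sim2_sel
        theta = np.zeros(preset.layout.m)
        i, k = sel.loading_pairs[0][0]
        theta[i], theta[k] = 0.5, 0.3
        assert sel.difference_norm(theta, "loading_diff", 0) == pytest.approx(0.2)
        D = sel.difference_matrix("loading_diff", 0)
        assert np.abs(D @ theta).sum() == pytest.approx(0.2)

    def test_three_groups_three_pairs(self):
        from sparsefa import ModelSpec, ParameterLayout
        from sparsefa.model import PENALIZED

        spec = ModelSpec(p=3, r=1, G=3, lam_code=np.full((3, 1), PENALIZED), mean_structure=True)
        sel = Selectors(ParameterLayout(spec))
        assert all(len(pairs) == 3 for pairs in sel.loading_pairs)

    def test_invariant_theta_zero_differences(self, sim2_sel):
        preset, sel = sim2_sel
        theta = np.tile(np.arange(preset.layout.m1, dtype=float), preset.spec.G)
        for j in range(len(sel.loading_pairs)):
            assert sel.difference_norm(theta, "loading_diff", j) == 0.0


class TestPenaltyMatrix:
    def test_zero_eta_zero_matrix(self, sim1):
        sel = Selectors(sim1.layout)
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "lasso", 0.0)])
        E = build_penalty_matrix(sim1.theta0, cfg, sel)
        assert np.all(E == 0)

    def test_single_group_lasso_diagonal(self, sim1):
        sel = Selectors(sim1.layout)
        eta = 0.2
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "lasso", eta)])
        E = build_penalty_matrix(sim1.theta0, cfg, sel)
        assert np.allclose(E, np.diag(np.diag(E)))
        q = sel.sparsity_idx
        expect = eta / np.sqrt(sim1.theta0[q] ** 2 + cfg.c_bar)
        assert np.allclose(np.diag(E)[q], expect)
        off = np.setdiff1d(np.arange(sim1.layout.m), q)
        assert np.all(np.diag(E)[off] == 0)

    def test_fusion_quadratic_form_matches_direct(self, sim2_sel):
        """0.5 theta' E2 theta reproduces the locally approximated difference
        penalty term by term."""
        preset, sel = sim2_sel
        rng = np.random.default_rng(5)
        theta = preset.theta0 + 0.1 * rng.standard_normal(preset.layout.m)
        eta = 0.37
        cfg = PenaltyConfig(terms=[PenaltyTerm("loading_diff", "lasso", eta)])
        E = build_penalty_matrix(theta, cfg, sel)
        quad = 0.5 * theta @ E @ theta
        direct = 0.0
        for pairs in sel.loading_pairs:
            for i, k in pairs:
                d = theta[i] - theta[k]
                direct += 0.5 * eta * d**2 / np.sqrt(d**2 + cfg.c_bar)
        assert quad == pytest.approx(direct, rel=1e-10)

    def test_gradient_consistency(self, sim2_sel):
        """E(theta) theta equals the finite-difference gradient of the
        approximated penalty at the expansion point, for all three targets."""
        preset, sel = sim2_sel
        rng = np.random.default_rng(8)
        theta = preset.theta0 + 0.1 * rng.standard_normal(preset.layout.m)
        cfg = PenaltyConfig(
            terms=[
                PenaltyTerm("sparsity", "alasso", 0.11, a=1.0, weights=np.ones(40)),
                PenaltyTerm("loading_diff", "lasso", 0.07),
                PenaltyTerm("intercept_diff", "lasso", 0.05),
            ],
            c_bar=1e-6,
        )
        E = build_penalty_matrix(theta, cfg, sel)
        analytic = E @ theta
        h = 1e-7
        for k in list(range(5)) + [25, 47 + 3]:
            e = np.zeros_like(theta)
            e[k] = h
            num = (penalty_value(theta + e, cfg, sel) - penalty_value(theta - e, cfg, sel)) / (2 * h)
            assert analytic[k] == pytest.approx(num, abs=1e-5)

    def test_separable_unit_matrices(self, sim2_sel):
        preset, sel = sim2_sel
        cfg = PenaltyConfig(
            terms=[
                PenaltyTerm("sparsity", "lasso", 0.3),
                PenaltyTerm("loading_diff", "lasso", 0.2),
                PenaltyTerm("intercept_diff", "lasso", 0.1),
            ]
        )
        theta = preset.theta0 + 0.05
        Ejs = unit_penalty_matrices(theta, cfg, sel)
        E = build_penalty_matrix(theta, cfg, sel)
        assert np.allclose(E, 0.3 * Ejs[0] + 0.2 * Ejs[1] + 0.1 * Ejs[2])

    def test_scad_not_separable(self, sim1):
        sel = Selectors(sim1.layout)
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "scad", 0.1, a=3.7)])
        with pytest.raises(ConfigError):
            unit_penalty_matrices(sim1.theta0, cfg, sel)


class TestApproximationQuality:
    def test_cbar_limit_recovers_exact_penalty(self, sim1):
        """As c_bar -> 0 the smooth penalty converges to the exact one; the
        deviation is sqrt(c_bar) at zero and below c_bar elsewhere."""
        sel = Selectors(sim1.layout)
        theta = sim1.theta0.copy()
        eta = 0.25
        exact = eta * np.abs(theta[sel.sparsity_idx]).sum()
        for cb in (1e-6, 1e-8, 1e-10):
            cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "lasso", eta)], c_bar=cb)
            approx = penalty_value(theta, cfg, sel)
            n_zero = int((theta[sel.sparsity_idx] == 0).sum())
            bound = eta * (n_zero * np.sqrt(cb) + (21 - n_zero) * cb)
            assert 0 < approx - exact <= bound * (1 + 1e-9)

    def test_penalty_value_floor_at_zero(self, sim1):
        sel = Selectors(sim1.layout)
        cfg = PenaltyConfig(terms=[PenaltyTerm("sparsity", "lasso", 0.5)], c_bar=1e-8)
        val = penalty_value(np.zeros(sim1.layout.m), cfg, sel)
        assert val == pytest.approx(0.5 * 21 * 1e-4, rel=1e-9)


def test_adaptive_weights_from_reference(sim1):
    sel = Selectors(sim1.layout)
    theta = sim1.theta0.copy()
    w = adaptive_weights(theta, sel, "sparsity", a=2.0)
    nz = np.abs(theta[sel.sparsity_idx]) > 0
    assert np.allclose(w[nz], 1.0 / np.abs(theta[sel.sparsity_idx][nz]) ** 2)
    assert np.all(w[~nz] == 1e8)  # capped at the zero references
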