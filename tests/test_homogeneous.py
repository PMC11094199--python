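import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubam import (
    HomogeneousState,
    ModelParams,
    a_star_coefficients,
    bifurcation_scan,
    c_threshold,
    cubic_coefficients,
    integrate,
    m0_threshold,
    reproduction_number,
    rhs,
    sensitivity_indices,
    steady_states,
)
from ubam.homogeneous import as_state, sensitivity_indices_numeric

from conftest import (
    ENDEMIC_A_STAR,
    ENDEMIC_B_STAR,
    ENDEMIC_M_STAR,
    ENDEMIC_U_STAR,
    random_params,
)

param_strategy = st.builds(
    ModelParams,
    mu=st.floats(0.01, 0.2),
    alpha=st.floats(0.1, 5.0),
    beta=st.floats(0.005, 0.5),
    rho=st.floats(0.05, 1.0),
    gamma=st.floats(0.01, 0.5),
    phi=st.floats(0.01, 1.0),
    phi0=st.floats(0.005, 0.5),
    c=st.floats(0.5, 10.0),
    m0=st.floats(0.5, 10.0),
)


class TestModelParams:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="alpha"):
            ModelParams(mu=0.05, alpha=0.0, beta=0.01, rho=0.3, gamma=0.08,
                        phi=0.5, phi0=0.1, c=5, m0=4)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="phi0"):
            ModelParams(mu=0.05, alpha=2, beta=0.01, rho=0.3, gamma=0.08,
                        phi=0.5, phi0=float("nan"), c=5, m0=4)

    def test_z(self, endemic_params):
        assert endemic_params.z == pytest.approx(5.0)


class TestRhs:
    def test_piracy_free_fixed_point(self, endemic_params):
        state = HomogeneousState(u=1.0, b=0.0, a=0.0, m=endemic_params.m0)
        assert rhs(state, endemic_params) == (0.0, 0.0, 0.0, 0.0)

    def test_manual_substitution_oracle(self, media_slow_params):
        # derivatives at (0.5, 0.3, 0.2, 4) computed by hand substitution:
        # Theta = 4/9, transmission flow = 2*(5/9)*0.5*0.3 = 1/6
        du, db, da, dm = rhs(HomogeneousState(0.5, 0.3, 0.2, 4.0), media_slow_params)
        assert du == pytest.approx(0.025 - 1 / 6, abs=1e-15)
        assert db == pytest.approx(1 / 6 - 0.089, abs=1e-15)
        assert da == pytest.approx(0.064, abs=1e-15)
        assert dm == pytest.approx(0.015, abs=1e-15)

    def test_conservation_exact(self, endemic_params):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fracs = rng.dirichlet([1, 1, 1])
            state = HomogeneousState(*fracs, m=rng.uniform(1, 10))
            du, db, da, _ = rhs(state, endemic_params)
            assert abs(du + db + da) < 1e-15

    def test_nonfinite_state_rejected(self, endemic_params):
        with pytest.raises(ValueError, match="non-finite"):
            rhs(HomogeneousState(0.5, float("nan"), 0.2, 4.0), endemic_params)


class TestReproductionNumber:
    def test_endemic_set_rounds_to_3_5(self, endemic_params):
        rm = reproduction_number(endemic_params)
        assert float(f"{rm:.2g}") == 3.5

    def test_direct_evaluation(self, media_slow_params):
        # alpha*c*(beta+mu) / (mu*(c+m0)*(beta+mu+m0*gamma)) by hand:
        # 2*5*0.25 / (0.05*9*0.57) = 9.7466...
        assert reproduction_number(media_slow_params) == pytest.approx(9.747, abs=5e-4)

    def test_m0_to_zero_limit(self, endemic_params):
        p = endemic_params.replace(m0=1e-12)
        assert reproduction_number(p) == pytest.approx(
            endemic_params.alpha / endemic_params.mu, rel=1e-9
        )


class TestCubicCoefficients:
    def test_hand_evaluated_values(self, endemic_params):
        co = cubic_coefficients(endemic_params)
        assert co.p == pytest.approx(1.025, abs=1e-12)
        assert co.q == pytest.approx(6.94, abs=1e-12)
        assert co.r == pytest.approx(-0.429, abs=1e-12)

    def test_r_zero_at_unit_reproduction_number(self, endemic_params):
        # scale alpha so R_m = 1 exactly
        p = endemic_params.replace(alpha=endemic_params.alpha / reproduction_number(endemic_params))
        assert reproduction_number(p) == pytest.approx(1.0, rel=1e-12)
        assert cubic_coefficients(p).r == pytest.approx(0.0, abs=1e-12)

    def test_p_zero_when_gamma_z_equals_rho(self, endemic_params):
        p = endemic_params.replace(rho=endemic_params.gamma * endemic_params.z)
        assert cubic_coefficients(p).p == pytest.approx(0.0, abs=1e-14)

    @settings(max_examples=200, deadline=None)
    @given(param_strategy)
    def test_sign_of_r_opposite_to_threshold(self, params):
        r = cubic_coefficients(params).r
        rm = reproduction_number(params)
        if abs(rm - 1) > 1e-9:
            assert math.copysign(1, r) == math.copysign(1, 1 - rm)


class TestSteadyStates:
    def test_piracy_free_always_present(self, endemic_params):
        eqs = steady_states(endemic_params)
        e0 = [e for e in eqs if e.kind == "piracy_free"]
        assert len(e0) == 1
        s = e0[0].state
        assert (s.u, s.b, s.a, s.m) == (1.0, 0.0, 0.0, endemic_params.m0)

    def test_endemic_full_precision(self, endemic_params):
        # quadratic-formula oracle: b* = (-q + sqrt(q^2 - 4 p r)) / (2 p)
        # with (p, q, r) = (1.025, 6.94, -0.429), then back-substitution
        endemic = [e for e in steady_states(endemic_params) if e.kind == "endemic"]
        assert len(endemic) == 1
        s = endemic[0].state
        assert s.b == pytest.approx(ENDEMIC_B_STAR, abs=1e-10)
        assert s.a == pytest.approx(ENDEMIC_A_STAR, abs=1e-10)
        assert s.u == pytest.approx(ENDEMIC_U_STAR, abs=1e-10)
        assert s.m == pytest.approx(ENDEMIC_M_STAR, abs=1e-10)
        assert endemic[0].stable

    def test_endemic_matches_reference_rounding(self, endemic_params):
        endemic = [e for e in steady_states(endemic_params) if e.kind == "endemic"][0]
        assert round(endemic.state.b, 3) == 0.061
        assert round(endemic.state.a, 3) == 0.507

    def test_subcritical_only_piracy_free(self, endemic_params):
        p = endemic_params.replace(alpha=0.04)  # alpha < mu
        eqs = steady_states(p)
        assert [e.kind for e in eqs] == ["piracy_free"]
        assert eqs[0].stable

    def test_rhs_vanishes_at_equilibria(self, endemic_params):
        for eq in steady_states(endemic_params):
            derivs = rhs(eq.state, endemic_params)
            assert max(abs(d) for d in derivs) < 1e-12

    def test_uniqueness_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = random_params(rng)
            rm = reproduction_number(p)
            if abs(rm - 1) < 1e-3:
                continue
            n_endemic = sum(1 for e in steady_states(p) if e.kind == "endemic")
            assert n_endemic == (1 if rm > 1 else 0), (p, rm)


class TestAStarCoefficients:
    def test_r_a_vanishes_at_u_star_one(self, endemic_params):
        _, _, r_a = a_star_coefficients(endemic_params, 1.0)
        assert r_a == pytest.approx(0.0, abs=1e-14)

    def test_cross_equation_consistency(self, endemic_params):
        endemic = [e for e in steady_states(endemic_params) if e.kind == "endemic"][0]
        p_a, q_a, r_a = a_star_coefficients(endemic_params, endemic.state.u)
        a = endemic.state.a
        assert p_a * a * a + q_a * a + r_a == pytest.approx(0.0, abs=1e-10)

    def test_p_a_zero_at_case_boundary(self, endemic_params):
        p = endemic_params.replace(rho=endemic_params.gamma * endemic_params.z)
        p_a, _, _ = a_star_coefficients(p, 0.5)
        assert p_a == pytest.approx(0.0, abs=1e-14)


class TestSensitivities:
    def test_alpha_identically_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert sensitivity_indices(random_params(rng)).alpha == 1.0

    def test_c_closed_form(self, endemic_params):
        assert sensitivity_indices(endemic_params).c == pytest.approx(4 / 9, rel=1e-14)

    def test_signs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = sensitivity_indices(random_params(rng))
            assert s.m0 < 0 and s.gamma < 0 and s.mu < 0
            assert s.beta > 0 and s.c > 0

    def test_agrees_with_numerical_derivative(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = random_params(rng)
            closed = sensitivity_indices(p).to_dict()
            numeric = sensitivity_indices_numeric(p).to_dict()
            for name in closed:
                assert closed[name] == pytest.approx(numeric[name], rel=1e-6, abs=1e-8)


class TestThresholds:
    def test_c_threshold_value(self, threshold_params):
        assert c_threshold(threshold_params) == pytest.approx(0.24178, abs=5e-6)

    def test_c_threshold_identity(self, threshold_params):
        c_th = c_threshold(threshold_params)
        assert reproduction_number(threshold_params.replace(c=c_th)) == pytest.approx(1.0, abs=1e-9)

    def test_below_c_threshold_no_endemic(self, threshold_params):
        c_th = c_threshold(threshold_params)
        eqs = steady_states(threshold_params.replace(c=0.9 * c_th))
        assert all(e.kind == "piracy_free" for e in eqs)

    def test_c_threshold_infinite_when_alpha_small(self, threshold_params):
        assert c_threshold(threshold_params.replace(alpha=0.04)) == math.inf

    def test_m0_threshold_value(self, threshold_params):
        assert m0_threshold(threshold_params) == pytest.approx(20.955, abs=5e-4)

    def test_m0_threshold_identity(self, threshold_params):
        m0_th = m0_threshold(threshold_params)
        assert reproduction_number(threshold_params.replace(m0=m0_th)) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_m0_threshold_zero_when_alpha_small(self, threshold_params):
        assert m0_threshold(threshold_params.replace(alpha=0.04)) == 0.0


class TestIntegrate:
    def test_trajectory_conservation(self, endemic_params):
        traj = integrate(endemic_params, (0.7, 0.2, 0.1), t_end=500)
        assert np.max(np.abs(traj.u + traj.b + traj.a - 1)) < 1e-6

    def test_converges_to_endemic(self, endemic_params):
        traj = integrate(endemic_params, (0.7, 0.2, 0.1), t_end=2000)
        assert traj.final_state.b == pytest.approx(ENDEMIC_B_STAR, abs=1e-6)
        assert round(traj.final_state.b, 3) == 0.061

    def test_subcritical_converges_to_piracy_free(self, endemic_params):
        p = endemic_params.replace(alpha=0.04)
        final = integrate(p, (0.5, 0.3, 0.2), t_end=2000).final_state
        assert final.u == pytest.approx(1.0, abs=1e-6)
        assert final.b == pytest.approx(0.0, abs=1e-8)

    def test_fixed_point_stays_fixed(self, endemic_params):
        eq = [e for e in steady_states(endemic_params) if e.kind == "endemic"][0].state
        traj = integrate(endemic_params, eq, t_end=100)
        assert np.max(np.abs(traj.b - eq.b)) < 1e-7

    def test_media_floor(self, endemic_params):
        traj = integrate(endemic_params, (0.7, 0.2, 0.1), t_end=500)
        assert np.all(traj.m >= endemic_params.m0 - 1e-9)

    def test_deficit_init_assigned_to_aware(self, threshold_params, caplog):
        # (0.75, 0.22, 0) sums to 0.97; the deficit goes to a
        with caplog.at_level("WARNING"):
            state = as_state((0.75, 0.22, 0.0), threshold_params)
        assert state.a == pytest.approx(0.03)
        assert "deficit" in caplog.text

    def test_stability_labels_agree_with_dynamics(self, endemic_params):
        # perturb each equilibrium; stable ones attract, unstable ones repel
        for eq in steady_states(endemic_params):
            s = eq.state
            pert = as_state(
                (max(s.u - 0.01, 0), min(s.b + 0.01, 1), 0.0), endemic_params
            )
            pert = HomogeneousState(pert.u, pert.b, pert.a, s.m)
            final = integrate(endemic_params, pert, t_end=3000).final_state
            dist = abs(final.b - s.b) + abs(final.u - s.u)
            if eq.stable:
                assert dist < 1e-5
            else:
                assert dist > 1e-3


class TestBifurcationScan:
    def test_transcritical_structure(self, media_slow_params):
        table = bifurcation_scan(media_slow_params, np.linspace(0.01, 4, 80), param="alpha")
        assert list(table.columns) == ["swept_value", "R_m", "branch", "b_star", "stable"]
        assert table["R_m"].is_monotonic_increasing
        sub = table[table.R_m < 1 - 1e-6]
        sup = table[table.R_m > 1 + 1e-6]
        assert (sub.branch == "piracy_free").all() and sub.stable.all()
        free_sup = sup[sup.branch == "piracy_free"]
        endemic_sup = sup[sup.branch == "endemic"]
        assert not free_sup.stable.any()
        assert endemic_sup.stable.all()
        # one endemic branch point per supercritical grid value
        assert len(endemic_sup) == sup.swept_value.nunique()

    def test_scan_matches_long_time_integration(self, media_slow_params):
        values = [0.5, 1.0, 2.0, 3.0, 4.0]
        table = bifurcation_scan(media_slow_params, values, param="alpha")
        for v in values:
            p = media_slow_params.replace(alpha=v)
            b_inf = integrate(p, (0.8, 0.2, 0.0), t_end=4000).final_state.b
            rows = table[(table.swept_value == v) & (table.branch == "endemic")]
            b_scan = rows.b_star.iloc[0] if len(rows) else 0.0
            assert b_inf == pytest.approx(b_scan, abs=1e-5)

    def test_higher_rho_lowers_endemic_branch(self, media_slow_params):
        grid = np.linspace(0.5, 4, 30)
        lo = bifurcation_scan(media_slow_params.replace(rho=0.3), grid)
        hi = bifurcation_scan(media_slow_params.replace(rho=0.5), grid)
        lo_b = lo[lo.branch == "endemic"].set_index("swept_value").b_star
        hi_b = hi[hi.branch == "endemic"].set_index("swept_value").b_star
        common = lo_b.index.intersection(hi_b.index)
        assert len(common) > 10
        assert (hi_b[common] <= lo_b[common] + 1e-12).all()

    def test_unknown_parameter_rejected(self, endemic_params):
        with pytest.raises(ValueError, match="unknown parameter"):
            bifurcation_scan(endemic_params, [1.0], param="bogus")
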