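import math

import numpy as np
import pytest
from scipy import stats

import virextinct as vx
from virextinct import (
    AntiviralIntervention,
    apply_antiviral,
    derive_quantities,
)
from virextinct.kinetics import (
    burst_size_cdf,
    burst_size_pmf,
    expected_unique_infections,
    extinction_prob_inoculum,
    extinction_prob_single_cell,
    extinction_prob_single_virion,
    fraction_consumed,
    lambert_w_principal,
    prob_virion_infects,
    reproductive_number_at,
)

# ---------------------------------------------------------------------------
# independent oracles


def _nb_pmf_truncated(B, nI, mass=1 - 1e-12):
    """Burst pmf truncated where the cumulative mass reaches `mass`."""
    n, pr = nI, nI / (nI + B)
    m_max = int(stats.nbinom.ppf(mass, n, pr)) + 1
    m = np.arange(m_max + 1)
    return m, stats.nbinom.pmf(m, n, pr)


def fixed_point_extinction(B, nI, P_VI, tol=1e-14, max_iter=200_000):
    """Damped fixed-point iteration of the truncated-sum extinction relation
    P = (1 - P_VI) + P_VI * sum_m pmf(m) P^m  — independent of the
    root-finding implementation under test."""
    m, pmf = _nb_pmf_truncated(B, nI)
    P = 0.5
    for _ in range(max_iter):
        new = (1 - P_VI) + P_VI * np.sum(pmf * P**m)
        new = 0.5 * P + 0.5 * new
        if abs(new - P) < tol:
            return new
        P = new
    raise RuntimeError("oracle iteration did not converge")


# ---------------------------------------------------------------------------


class TestVirionSuccess:
    def test_baseline_printed_value(self, baseline):
        assert prob_virion_infects(baseline) == pytest.approx(0.409, abs=5e-4)

    def test_no_decay_gives_gamma(self, baseline):
        p = baseline.replace(c=1e-300, gamma=0.73)
        assert prob_virion_infects(p) == pytest.approx(0.73, rel=1e-9)

    def test_half_gamma_unit_ratio(self):
        # gamma = 0.5 and ratio = 1 -> P_VI = 0.25
        p = vx.InfectionParameters(
            beta=1.0, p=1.0, c=1.0, gamma=0.5, N_cells=1, s=1.0, tau_I=10.0
        )
        assert prob_virion_infects(p) == pytest.approx(0.25, abs=1e-12)


class TestBurstLaw:
    def test_geometric_at_zero(self, baseline):
        B = baseline.p * baseline.tau_I
        assert burst_size_pmf(0, baseline) == pytest.approx(1 / (1 + B), rel=1e-12)

    def test_small_burst_tail_probabilities(self, baseline):
        assert burst_size_cdf(5, baseline) == pytest.approx(0.27, abs=0.005)
        assert burst_size_cdf(5, baseline.replace(n_I=60)) == pytest.approx(
            0.0007, abs=0.0001
        )

    @pytest.mark.parametrize("B", [2.0, 18.8235294117647])
    @pytest.mark.parametrize("nI", [1, 2, 7, 60])
    def test_normalized_with_mean_B(self, baseline, B, nI):
        params = baseline.replace(p=B / baseline.tau_I, n_I=nI)
        m, pmf_oracle = _nb_pmf_truncated(B, nI)
        pmf = burst_size_pmf(m, params)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        assert float(np.sum(m * pmf)) == pytest.approx(B, rel=1e-9)

    def test_rejects_negative_m(self, baseline):
        with pytest.raises(ValueError):
            burst_size_pmf(-1, baseline)


class TestExtinctionSingleVirion:
    def test_fig5_printed_value(self, fig5_params):
        assert extinction_prob_single_virion(fig5_params) == pytest.approx(
            0.848170, abs=1e-5
        )

    def test_subcritical_is_one(self, baseline):
        p = apply_antiviral(
            baseline, AntiviralIntervention(mode="reduce_p", efficacy=0.95)
        )
        assert derive_quantities(p).R0 < 1
        assert extinction_prob_single_virion(p) == 1.0

    @pytest.mark.parametrize("eps", [0.0, 0.3, 0.6, 0.8])
    def test_closed_form_matches_root_nI1(self, baseline, eps):
        p = apply_antiviral(
            baseline, AntiviralIntervention(mode="reduce_p", efficacy=eps)
        )
        d = derive_quantities(p)
        closed = 1 - (d.R0 - 1) / d.B
        assert extinction_prob_single_virion(p) == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize("nI", [2, 7, 60])
    def test_matches_truncated_sum_oracle(self, baseline, nI):
        p = baseline.replace(n_I=nI)
        d = derive_quantities(p)
        oracle = fixed_point_extinction(d.B, nI, d.P_VI)
        assert extinction_prob_single_virion(p) == pytest.approx(oracle, abs=1e-8)

    def test_fixed_point_residual_and_bound(self, fig5_params):
        d = derive_quantities(fig5_params)
        P = extinction_prob_single_virion(fig5_params)
        resid = (1 - d.P_VI) + d.P_VI * (
            d.B * (1 - P) / fig5_params.n_I + 1
        ) ** -fig5_params.n_I - P
        assert abs(resid) <= 1e-10
        assert P < 1.0

    @pytest.mark.parametrize("mode", ["reduce_beta", "reduce_p", "reduce_gamma"])
    def test_monotone_in_efficacy(self, baseline, mode):
        eps_grid = np.linspace(0, 0.95, 40)
        vals = [
            extinction_prob_single_virion(
                apply_antiviral(baseline, AntiviralIntervention(mode=mode, efficacy=e))
            )
            for e in eps_grid
        ]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_large_nI_approaches_poisson_burst(self, baseline):
        p = baseline.replace(n_I=10_000)
        d = derive_quantities(p)
        spec = vx.BurstModelSpec(model="poisson", B=d.B, P_VI=d.P_VI)
        assert extinction_prob_single_virion(p) == pytest.approx(
            vx.extinction_prob_burst(spec), abs=1e-4
        )


class TestExtinctionSingleCell:
    def test_subcritical_is_one(self, baseline):
        p = apply_antiviral(
            baseline, AntiviralIntervention(mode="reduce_gamma", efficacy=0.95)
        )
        assert extinction_prob_single_cell(p) == 1.0

    def test_nI1_algebraic_reduction(self, fig5_params):
        d = derive_quantities(fig5_params)
        p_v = extinction_prob_single_virion(fig5_params)
        assert extinction_prob_single_cell(fig5_params) == pytest.approx(
            1 / (1 + d.B * (1 - p_v)), rel=1e-12
        )

    @pytest.mark.parametrize("nI", [1, 7, 60])
    def test_matches_direct_summation_oracle(self, baseline, nI):
        p = baseline.replace(n_I=nI)
        d = derive_quantities(p)
        p_v = extinction_prob_single_virion(p)
        m, pmf = _nb_pmf_truncated(d.B, nI)
        oracle = float(np.sum(pmf * p_v**m))
        assert extinction_prob_single_cell(p) == pytest.approx(oracle, abs=1e-8)


class TestExtinctionInoculum:
    def test_empty_inoculum_certain_extinction(self, baseline):
        assert extinction_prob_inoculum(baseline, V0=0, I0=0).p_ext_inoculum == 1.0

    def test_two_virions_square(self, fig5_params):
        one = extinction_prob_inoculum(fig5_params, V0=1, I0=0)
        two = extinction_prob_inoculum(fig5_params, V0=2, I0=0)
        assert two.p_ext_inoculum == pytest.approx(one.p_ext_inoculum**2, rel=1e-12)

    def test_product_law(self, fig5_params):
        r = extinction_prob_inoculum(fig5_params, V0=3, I0=2)
        assert r.p_ext_inoculum == pytest.approx(
            r.p_ext_virion**3 * r.p_ext_cell**2, rel=1e-12
        )
        assert r.establishment == pytest.approx(1 - r.p_ext_inoculum, abs=1e-15)

    def test_ten_virions_beta_antiviral_printed_value(self, baseline):
        # entry inhibitor at eps = 0.81 halves the 10-virion establishment
        p = apply_antiviral(
            baseline, AntiviralIntervention(mode="reduce_beta", efficacy=0.81)
        )
        est = extinction_prob_inoculum(p, V0=10, I0=0).establishment
        assert 100 * est == pytest.approx(48, abs=1)


class TestCriticalFractionAndFinalSize:
    def test_scenario_targets(self, baseline):
        assert vx.critical_fraction_uninfected(vx.treated_preset(0.5)) == pytest.approx(
            0.5, abs=1e-12
        )
        assert vx.critical_fraction_uninfected(
            vx.treated_preset(0.85)
        ) == pytest.approx(0.85, abs=1e-12)

    def test_baseline_direct_substitution(self, baseline):
        d = derive_quantities(baseline)
        assert vx.critical_fraction_uninfected(baseline) == pytest.approx(
            d.ratio / (baseline.gamma * d.B - 1), rel=1e-12
        )

    def test_final_size_printed_values(self):
        assert fraction_consumed(vx.treated_preset(0.5), 1, 0) == pytest.approx(
            0.796818, abs=1e-5
        )
        assert fraction_consumed(vx.treated_preset(0.85), 1, 0) == pytest.approx(
            0.284271, abs=1e-5
        )
        cells = fraction_consumed(vx.treated_preset(0.5), 1, 0) * 40_000
        assert round(cells) == 31_873

    def test_small_Tstar_limit(self, baseline):
        # for T*/N << 1 the final size approaches 1 - exp(-1/Tf)
        Tf = vx.critical_fraction_uninfected(baseline)  # ~0.081
        assert fraction_consumed(baseline, 0, 0) == pytest.approx(
            1 - math.exp(-1 / Tf), abs=1e-4
        )

    def test_zero_inoculum_limit_drops_factor(self, fig5_params):
        Tf = 0.5
        expected = 1 + Tf * lambert_w_principal(-math.exp(-1 / Tf) / Tf)
        assert fraction_consumed(fig5_params, 0, 0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_strictly_decreasing_in_Tstar(self):
        targets = np.linspace(0.2, 0.95, 16)
        vals = [fraction_consumed(vx.treated_preset(t), 1, 0) for t in targets]
        assert np.all(np.diff(vals) < 0)

    def test_cell_inoculum_enters_as_burst_equivalent(self, fig5_params):
        # I0 cells act like p*tau_I*I0 extra virions in the final size
        p = fig5_params
        lhs = fraction_consumed(p, V0=0, I0=2)
        eff_v = p.p * p.tau_I * 2
        Tf = 0.5
        inoc = p.gamma * (p.beta / p.s) * eff_v / p.c
        rhs = 1 + Tf * lambert_w_principal(
            -math.exp(-1 / Tf) / Tf * math.exp(-inoc)
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestReproductiveNumber:
    def test_endpoints(self):
        assert reproductive_number_at(1.0, 7.69, 0.3) == pytest.approx(7.69)
        assert reproductive_number_at(0.3, 7.69, 0.3) == pytest.approx(1.0)

    def test_strictly_increasing(self):
        grid = np.linspace(0.05, 1.0, 50)
        vals = [reproductive_number_at(g, 3.0, 0.4) for g in grid]
        assert np.all(np.diff(vals) > 0)

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            reproductive_number_at(0.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            reproductive_number_at(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            reproductive_number_at(0.5, 2.0, 1.0)


class TestLambertW:
    @pytest.mark.parametrize(
        "x,w", [(0.0, 0.0), (math.e, 1.0), (-1 / math.e, -1.0)]
    )
    def test_known_points(self, x, w):
        assert lambert_w_principal(x) == pytest.approx(w, abs=1e-12)

    def test_residual_contract(self):
        for x in np.concatenate(
            [np.linspace(-0.36, 5, 40), np.logspace(1, 6, 10)]
        ):
            w = lambert_w_principal(float(x))
            assert abs(w * math.exp(w) - x) <= 1e-12 * max(1.0, abs(x))
            assert w >= -1.0

    def test_below_branch_point_rejected(self):
        with pytest.raises(ValueError):
            lambert_w_principal(-1.0)


class TestExpectedUniqueInfections:
    def test_trivia(self):
        assert expected_unique_infections(5, 0) == 0.0
        assert expected_unique_infections(0, 3) == 0.0
        assert expected_unique_infections(7, 1) == pytest.approx(1.0)

    def test_two_in_two_enumeration(self):
        # 4 equiprobable placements of 2 virions in 2 cells: distinct counts
        # are 1, 2, 2, 1 -> expectation 1.5
        assert expected_unique_infections(2, 2) == pytest.approx(1.5, abs=1e-12)

    def test_sparse_limit_equals_vsuc(self):
        assert expected_unique_infections(10**9, 20) == pytest.approx(20, rel=1e-6)


class TestGammaVsPIdentity:
    @pytest.mark.parametrize("nI", [1, 2, 7, 60])
    @pytest.mark.parametrize("eps", [0.1, 0.5, 0.8])
    def test_establishment_scales_by_one_minus_eps(self, baseline, nI, eps):
        # establishment under a gamma-antiviral equals (1-eps) times that
        # under a p-antiviral at the same efficacy, for a single virion
        base = baseline.replace(n_I=nI)
        est_g = extinction_prob_inoculum(
            apply_antiviral(
                base, AntiviralIntervention(mode="reduce_gamma", efficacy=eps)
            ),
            V0=1,
            I0=0,
        ).establishment
        est_p = extinction_prob_inoculum(
            apply_antiviral(base, AntiviralIntervention(mode="reduce_p", efficacy=eps)),
            V0=1,
            I0=0,
        ).establishment
        assert est_g == pytest.approx((1 - eps) * est_p, abs=1e-10)
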