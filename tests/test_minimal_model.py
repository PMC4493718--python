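"""Closed-form single-cell and donor/acceptor model against its constraints
and the independent LP oracle."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import crowdflux as cf
from crowdflux.minimal_model import Regime


class TestThresholds:
    def test_printed_constants(self, params, th):
        # crowding onset and full-fermentation supply from the defining ratios
        assert th.u_G == pytest.approx(0.4 / 0.403, rel=1e-12)
        assert th.u_G == pytest.approx(0.9926, abs=5e-5)
        assert th.v_G == pytest.approx(0.4 / 3.92e-3, rel=1e-12)
        assert th.v_G == pytest.approx(102.04, abs=5e-3)

    def test_yield38_identity(self):
        p = cf.MinimalModelParams(f_atp_min=38.0)
        assert cf.thresholds(p).u_G0 == pytest.approx(1.0, rel=1e-14)

    def test_default_demand_is_one_crowding_onset(self, params, th):
        # f_atp_min defaults to 38 u_G, so u_G0 == u_G
        assert th.u_G0 == pytest.approx(th.u_G, rel=1e-14)

    @given(
        a_glyc=st.floats(1e-4, 1e-2),
        a_ldh_frac=st.floats(0.01, 0.99),
        a_ox=st.floats(2e-2, 1.0),
        phi=st.floats(0.05, 1.0),
        fmin_frac=st.floats(0.05, 0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_ordering_invariants(self, a_glyc, a_ldh_frac, a_ox, phi, fmin_frac):
        a_ldh = a_ldh_frac * a_glyc
        # the subsidized regime only closes when re-routed glucose buys more
        # lactate than the acceptor loses ATP for (k > c); otherwise the
        # model itself is degenerate and thresholds() refuses
        assume(38.0 / 18.0 > (2 * a_ox + a_glyc) / (a_ox - a_ldh))
        p = cf.MinimalModelParams(
            a_glyc=a_glyc, a_LDH=a_ldh, a_ox=a_ox, phi_ATP=phi,
            f_atp_min=fmin_frac * 38.0 * phi / (2 * a_ox + a_glyc),
        )
        t = cf.thresholds(p)
        assert t.u_G0 > 0
        assert t.u_G1 == pytest.approx(t.u_G + t.u_G0, rel=1e-12)
        assert t.u_G1 < t.u_G2
        assert t.u_G < t.v_G

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            cf.MinimalModelParams(a_glyc=-1.0)
        with pytest.raises(ValueError):
            cf.MinimalModelParams(phi_ATP=1.5)
        with pytest.raises(ValueError):
            cf.MinimalModelParams(f_atp_min=-3.0)


class TestSingleCell:
    def test_zero_supply(self, params):
        s = cf.single_cell_optimum(params, 0.0)
        assert s.f_glyc == s.f_ox == s.f_LDH == s.f_ATP == 0.0

    def test_below_onset_maximum_yield(self, params):
        s = cf.single_cell_optimum(params, 0.5)
        assert s.f_ATP == pytest.approx(19.0, rel=1e-14)
        assert s.f_LDH == 0.0
        assert s.f_ox == pytest.approx(1.0)

    def test_full_fermentation_point(self, params, th):
        s = cf.single_cell_optimum(params, th.v_G)
        assert s.f_ox == pytest.approx(0.0, abs=1e-10)
        assert s.f_LDH == pytest.approx(2 * th.v_G, rel=1e-10)
        assert s.f_ATP == pytest.approx(2 * th.v_G, rel=1e-10)
        assert s.f_ATP == pytest.approx(204.08, abs=0.01)

    def test_continuity_at_onset(self, params, th):
        lo = cf.single_cell_optimum(params, th.u_G - 1e-10)
        hi = cf.single_cell_optimum(params, th.u_G + 1e-10)
        for attr in ("f_glyc", "f_ox", "f_LDH", "f_ATP"):
            assert getattr(lo, attr) == pytest.approx(
                getattr(hi, attr), abs=1e-7
            )

    def test_supply_above_capacity_is_capped_and_flagged(self, params, th):
        s = cf.single_cell_optimum(params, 2 * th.v_G)
        assert s.capped
        assert s.U_G_in == pytest.approx(th.v_G)

    def test_rejects_negative_supply(self, params):
        with pytest.raises(ValueError):
            cf.single_cell_optimum(params, -0.1)

    @given(u=st.floats(0.0, 150.0))
    @settings(max_examples=150, deadline=None)
    def test_balances_and_crowding(self, u):
        p = cf.MinimalModelParams()
        t = cf.thresholds(p)
        s = cf.single_cell_optimum(p, u)
        # pyruvate balance and ATP accounting hold exactly
        assert s.f_ox + s.f_LDH == pytest.approx(2 * s.f_glyc, abs=1e-9)
        assert s.f_ATP == pytest.approx(2 * s.f_glyc + 18 * s.f_ox, abs=1e-9)
        slack = p.phi_ATP - s.crowding_load(p)
        assert slack >= -1e-10
        if u > t.u_G * (1 + 1e-9):  # crowding saturates past the onset
            assert abs(slack) <= 1e-8


class TestTwoCell:
    def test_starvation(self, two_cell_params, th2):
        with pytest.raises(cf.StarvationError):
            cf.two_cell_solution(two_cell_params, 1.9 * th2.u_G0)

    def test_glucose_shared_regime(self, two_cell_params, th2):
        u = 0.5 * (2 * th2.u_G0 + th2.u_G1)
        sol = cf.two_cell_solution(two_cell_params, u)
        assert sol.regime is Regime.GLUCOSE_SHARED
        assert sol.acceptor_min.U_G_in == pytest.approx(th2.u_G0)
        assert sol.donor.f_LDH == pytest.approx(0.0, abs=1e-12)
        assert sol.delta_U_G == 0.0
        # acceptor pinned at the survival demand
        assert sol.acceptor_min.f_ATP == pytest.approx(
            two_cell_params.f_atp_min
        )
        assert sol.acceptor_max.f_ATP == sol.acceptor_min.f_ATP

    def test_lactate_subsidized_regime(self, two_cell_params, th2):
        u = 0.5 * (th2.u_G1 + th2.u_G2)
        sol = cf.two_cell_solution(two_cell_params, u)
        assert sol.regime is Regime.LACTATE_SUBSIDIZED
        assert 0 < sol.delta_U_G < th2.u_G0
        assert sol.donor.f_LDH > 0
        assert sol.acceptor_min.f_LDH < 0  # lactate intake
        k = two_cell_params.max_yield / two_cell_params.y_ox
        assert sol.donor.f_LDH == pytest.approx(k * sol.delta_U_G, rel=1e-10)

    def test_full_sequestration(self, two_cell_params, th2):
        sol = cf.two_cell_solution(two_cell_params, 2 * th2.u_G2)
        assert sol.regime is Regime.FULL_SEQUESTRATION
        assert sol.acceptor_min.U_G_in == 0.0
        assert sol.acceptor_min.f_LDH < 0
        assert sol.delta_U_G == pytest.approx(th2.u_G0)
        assert sol.acceptor_max.f_ATP >= sol.acceptor_min.f_ATP

    def test_monotonic_in_supply(self, two_cell_params, th2):
        grid = np.linspace(2 * th2.u_G0 + 1e-9, 3 * th2.u_G2, 60)
        sols = [cf.two_cell_solution(two_cell_params, u) for u in grid]
        atp = [s.donor.f_ATP for s in sols]
        ldh = [s.donor.f_LDH for s in sols]
        assert np.all(np.diff(atp) >= -1e-9)
        assert np.all(np.diff(ldh) >= -1e-9)
        mid = [s for s in sols if s.regime is Regime.LACTATE_SUBSIDIZED]
        intake = [s.acceptor_min.U_G_in for s in mid]
        assert np.all(np.diff(intake) <= 1e-9)

    def test_continuity_at_regime_boundaries(self, two_cell_params, th2):
        for b in (th2.u_G1, th2.u_G2):
            lo = cf.two_cell_solution(two_cell_params, b - 1e-10)
            hi = cf.two_cell_solution(two_cell_params, b + 1e-10)
            for attr in ("f_glyc", "f_ox", "f_LDH", "f_ATP"):
                assert getattr(lo.donor, attr) == pytest.approx(
                    getattr(hi.donor, attr), abs=1e-7
                )

    def test_default_demand_violates_lactate_survival(self, params, th):
        # at f_atp_min = 38 u_G the acceptor cannot live on lactate alone:
        # the closed form must refuse rather than return an infeasible state
        with pytest.raises(RuntimeError):
            cf.two_cell_solution(params, 3.0)

    def test_pinned_acceptor_balances(self, two_cell_params, th2):
        p = two_cell_params
        for u in np.linspace(2 * th2.u_G0 + 1e-9, th2.u_G2, 25):
            sol = cf.two_cell_solution(p, u)
            for cell in (sol.donor, sol.acceptor_min, sol.acceptor_max):
                assert cell.f_ox + cell.f_LDH == pytest.approx(
                    2 * cell.f_glyc, abs=1e-9
                )
                assert cell.crowding_load(p) <= p.phi_ATP + 1e-9


class TestLpOracle:
    def test_boundary_both_at_minimum(self, two_cell_params, th2):
        sol = cf.lp_oracle(two_cell_params, 2 * th2.u_G0)
        assert sol.donor.f_ATP == pytest.approx(
            two_cell_params.f_atp_min, rel=1e-8
        )
        assert sol.acceptor_min.f_ATP == pytest.approx(
            two_cell_params.f_atp_min, rel=1e-8
        )

    def test_infeasible_raises_starvation(self, two_cell_params, th2):
        with pytest.raises(cf.StarvationError):
            cf.lp_oracle(two_cell_params, th2.u_G0)

    def test_decoupled_at_glucose_excess(self, two_cell_params, th2):
        # far beyond u_G2 + v_G both cells can feed on glucose alone
        sol = cf.lp_oracle(two_cell_params, th2.u_G2 + 1.5 * th2.v_G)
        ref = cf.two_cell_solution(
            two_cell_params, th2.u_G2 + 1.5 * th2.v_G
        )
        assert sol.acceptor_max.f_ATP == pytest.approx(
            ref.acceptor_max.f_ATP, rel=1e-6
        )
        # the acceptor's own crowding caps its maximum ATP
        assert ref.acceptor_max.crowding_load(two_cell_params) <= (
            two_cell_params.phi_ATP + 1e-8
        )

    def test_matches_closed_form_on_grid(self, two_cell_params, th2):
        t = th2
        grid = np.concatenate([
            np.linspace(2 * t.u_G0 + 1e-9, t.u_G1, 12),
            np.linspace(t.u_G1 + 1e-7, t.u_G2, 20),
            np.linspace(t.u_G2 + 1e-4, 1.5 * t.v_G, 20),
        ])
        for u in grid:
            a = cf.two_cell_solution(two_cell_params, u)
            b = cf.lp_oracle(two_cell_params, u)
            for attr in ("f_glyc", "f_ox", "f_LDH", "f_ATP"):
                assert getattr(a.donor, attr) == pytest.approx(
                    getattr(b.donor, attr), rel=1e-8, abs=1e-8
                )
            assert a.regime == b.regime
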