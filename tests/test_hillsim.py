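import numpy as np
import pytest

from consortia_logic import (best_rbs, consortium_response, dsc_transfer,
                             phi_from_ratio, proportion_robustness,
                             recover_parameters, scan_rbs, usc_transfer,
                             xor_response)
from consortia_logic.errors import ConsortiaLogicError, ParameterError
from consortia_logic.hillsim import (ahl_level, hill_activation,
                                     hill_repression, or_combine)

FACTORS = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


class TestTransferFunctions:
    def test_usc_is_an_and_gate(self, params):
        on = usc_transfer(params.ara_on, params.sal_on, params)
        single_a = usc_transfer(params.ara_on, 0.0, params)
        single_s = usc_transfer(0.0, params.sal_on, params)
        off = usc_transfer(0.0, 0.0, params)
        assert on / off > 100
        assert single_a < on / 20 and single_s < on / 20

    def test_usc_monotone_in_both_inducers(self, params):
        ara = np.logspace(-8, -1, 30)
        out = usc_transfer(ara, params.sal_on, params)
        assert np.all(np.diff(out) >= -1e-12)
        sal = np.logspace(-10, -3, 30)
        out = usc_transfer(params.ara_on, sal, params)
        assert np.all(np.diff(out) >= -1e-12)

    def test_dsc_is_or_and_not(self, params):
        # no AHL: OR behaviour
        assert dsc_transfer(params.ara_on, 0.0, 0.0, params) > \
            20 * dsc_transfer(0.0, 0.0, 0.0, params)
        # saturating AHL silences the cell regardless of inducers (NIMPLY)
        hi = dsc_transfer(params.ara_on, params.sal_on, 1e-5, params)
        assert hi < 0.05 * dsc_transfer(params.ara_on, 0.0, 0.0, params)

    def test_dsc_monotone_decreasing_in_ahl(self, params):
        ahl = np.logspace(-12, -5, 40)
        out = dsc_transfer(params.ara_on, 0.0, ahl, params)
        assert np.all(np.diff(out) <= 1e-12)

    def test_outputs_bounded_by_beta(self, params):
        grid = np.logspace(-10, -1, 12)
        for a in grid:
            for s in grid:
                assert 0 <= consortium_response(a, s, params) <= params.beta

    def test_leakage_floor_at_zero_inputs(self, params):
        floor = consortium_response(0.0, 0.0, params)
        assert 0 < floor < 0.05 * params.beta

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ParameterError):
            usc_transfer(-1e-6, 0.0, params)
        with pytest.raises(ParameterError):
            dsc_transfer(0.0, 0.0, -1.0, params)

    def test_or_combine_bounded_and_symmetric(self):
        u, v = 0.3, 0.8
        assert or_combine(u, v) == or_combine(v, u) <= 1.0
        assert or_combine(u, 0.0) == u

    def test_hill_limits(self):
        assert hill_activation(0.0, 1e-6, 2, 0.01) == pytest.approx(0.01)
        assert hill_repression(0.0, 1e-6, 2, 0.01) == pytest.approx(1.0)


class TestConsortium:
    def test_xor_pattern_at_defaults(self, params):
        resp = xor_response(params)
        on = min(resp.outputs[(1, 0)], resp.outputs[(0, 1)])
        off = max(resp.outputs[(0, 0)], resp.outputs[(1, 1)])
        assert on > off
        assert resp.sb_ratio >= 10

    def test_wire_silenced_at_extreme_attenuation_gives_or(self, params):
        resp = xor_response(params.replace(rbs_attenuation=1e9))
        # (1,1) is now ON too: the consortium degenerates to OR
        assert resp.outputs[(1, 1)] == pytest.approx(
            resp.outputs[(1, 0)], rel=0.05)
        assert resp.sb_ratio == pytest.approx(1.0, abs=0.1)

    def test_ahl_scales_with_population_odds(self, params):
        lo = ahl_level(params.ara_on, params.sal_on, params.replace(phi=0.1))
        hi = ahl_level(params.ara_on, params.sal_on, params.replace(phi=0.5))
        assert hi > lo

    def test_robust_across_inoculation_ratios(self, params):
        phis = [phi_from_ratio(1, d) for d in (20, 10, 5, 2, 1)]
        rows = proportion_robustness(phis, params.replace(rbs_attenuation=10))
        assert all(ok for _, _, ok in rows)

    def test_infinite_threshold_fails_everything(self, params):
        rows = proportion_robustness([0.25], params, threshold=float("inf"))
        assert not any(ok for _, _, ok in rows)

    def test_phi_bounds_guarded(self, params):
        with pytest.raises(ParameterError):
            params.replace(phi=1.0)
        with pytest.raises(ParameterError):
            params.replace(phi=0.0)


class TestRbsScan:
    def test_interior_optimum(self, params):
        table = scan_rbs(FACTORS, params)
        ratios = [sb for _, sb in table]
        k = int(np.argmax(ratios))
        assert 0 < k < len(FACTORS) - 1
        # reference RBS is too strong: leaky luxI floods the wire
        assert ratios[0] < max(ratios)
        # and far too weak RBS silences the wire entirely
        assert ratios[-1] == pytest.approx(1.0, abs=0.2)

    def test_rise_then_fall_shape(self, params):
        ratios = [sb for _, sb in scan_rbs(FACTORS, params)]
        k = int(np.argmax(ratios))
        assert all(x <= y + 1e-9 for x, y in zip(ratios[:k], ratios[1:k + 1]))
        assert all(x >= y - 1e-9 for x, y in zip(ratios[k:], ratios[k + 1:]))

    def test_more_leakage_shifts_the_optimum_up(self, params):
        base = best_rbs(FACTORS, params)[0]
        leaky = params.replace(l_ara=params.l_ara * 5,
                               l_sal=params.l_sal * 5)
        assert best_rbs(FACTORS, leaky)[0] >= base

    def test_empty_factor_list_rejected(self, params):
        with pytest.raises(ConsortiaLogicError):
            scan_rbs([], params)


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [0, 11])
    def test_binding_constants_recovered_within_twofold(self, params, seed):
        result = recover_parameters(params, seed=seed, cv=0.1)
        for k in ("K_ara", "K_sal", "K_ahl"):
            assert result[k]["fold_error"] < 2.0
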