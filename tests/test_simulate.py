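"""Generator correctness: closed forms, determinism, panel structure."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fhces import (
    KineticParams,
    PanelDesign,
    SyntheticTruth,
    default_truths,
    expected_daa_ratio,
    daa_mult_from_ratio,
    expected_ratios,
    simulate_binding_sensorgram,
    simulate_decay_sensorgram,
    simulate_dose_response,
    simulate_variant_panel,
)
from fhces.doseresponse import FourPLParams, four_pl
from fhces.errors import (
    InsufficientDesignError,
    InvalidPanelError,
    InvalidParameterError,
)


class TestBindingSensorgram:
    def test_association_plateau_is_half_rmax_at_kd(self):
        # analyte at C = K_D: Req = rmax/2
        p = KineticParams(ka=1e5, kd=1e-2, rmax=300.0, analyte_conc=1e-7)
        s = simulate_binding_sensorgram(p, t_assoc=2000, t_dissoc=50, dt=1.0,
                                        noise_sd=0.0, seed=0)
        assert s.at(2000) == pytest.approx(150.0, rel=1e-6)

    def test_association_saturates_to_req(self):
        p = KineticParams(ka=1e5, kd=1e-3, rmax=300.0, analyte_conc=250e-9)
        s = simulate_binding_sensorgram(p, t_assoc=5000, t_dissoc=50, dt=1.0,
                                        noise_sd=0.0, seed=0)
        assert s.at(5000) == pytest.approx(p.req, rel=1e-3)

    def test_seeded_determinism(self):
        p = KineticParams(ka=1e5, kd=1e-3, rmax=300.0, analyte_conc=250e-9)
        a = simulate_binding_sensorgram(p, 220, 60, 1.0, noise_sd=2.0, seed=7)
        b = simulate_binding_sensorgram(p, 220, 60, 1.0, noise_sd=2.0, seed=7)
        assert np.array_equal(a.responses, b.responses)
        c = simulate_binding_sensorgram(p, 220, 60, 1.0, noise_sd=2.0, seed=8)
        assert not np.array_equal(a.responses, c.responses)

    @given(
        ka=st.floats(1e4, 1e6), kd=st.floats(1e-4, 1e-1),
        rmax=st.floats(50, 500), conc=st.floats(1e-8, 1e-6),
    )
    def test_zero_noise_matches_closed_form_everywhere(self, ka, kd, rmax, conc):
        p = KineticParams(ka, kd, rmax, conc)
        s = simulate_binding_sensorgram(p, 220, 60, 1.0, noise_sd=0.0, seed=0)
        kobs = ka * conc + kd
        req = rmax * conc / (conc + kd / ka)
        assoc = s.times <= 220
        expected = np.where(
            assoc,
            req * (1 - np.exp(-kobs * np.minimum(s.times, 220.0))),
            req * (1 - np.exp(-kobs * 220.0)) * np.exp(-kd * (s.times - 220.0)),
        )
        np.testing.assert_allclose(s.responses, expected, atol=1e-9)

    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"dt": -1.0}, {"t_assoc": 0.0}, {"t_dissoc": -5.0},
        {"noise_sd": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        p = KineticParams(1e5, 1e-3, 300.0, 250e-9)
        args = {"t_assoc": 220.0, "t_dissoc": 60.0, "dt": 1.0,
                "noise_sd": 0.0, "seed": 0}
        args.update(kwargs)
        with pytest.raises(InvalidParameterError):
            simulate_binding_sensorgram(p, **args)


class TestDecaySensorgram:
    def test_no_fh_limit_is_pure_intrinsic_decay(self):
        s = simulate_decay_sensorgram(100.0, 2e-3, 5e-3, daa_mult=0.0,
                                      t_end=200, dt=1.0, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(
            s.responses, 100.0 * np.exp(-2e-3 * s.times), rtol=1e-12)

    def test_half_life_construction(self):
        # k_fh = ln2/175 with no intrinsic decay: half the signal at 175 s
        s = simulate_decay_sensorgram(100.0, 0.0, np.log(2) / 175, daa_mult=1.0,
                                      t_end=200, dt=1.0, noise_sd=0.0, seed=0)
        assert s.at(175.0) == pytest.approx(50.0, abs=1e-9)

    def test_monotone_in_decay_rate(self):
        lo = simulate_decay_sensorgram(100.0, 1e-3, 4e-3, 0.1, 200, 1.0, 0.0, 3)
        hi = simulate_decay_sensorgram(100.0, 1e-3, 4e-3, 1.0, 200, 1.0, 0.0, 3)
        assert lo.at(175.0) > hi.at(175.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_decay_sensorgram(100.0, -1e-3, 4e-3, 1.0, 200, 1.0, 0.0, 0)
        with pytest.raises(InvalidParameterError):
            simulate_decay_sensorgram(0.0, 1e-3, 4e-3, 1.0, 200, 1.0, 0.0, 0)


class TestDoseResponse:
    def test_midpoint_at_ec50(self):
        p = FourPLParams(bottom=0, top=100, hill=1.3, ec50=0.2)
        curve = simulate_dose_response(p, "increasing", [0.05, 0.1, 0.2, 0.4, 0.8],
                                       n_reps=3, noise_sd=0.0, seed=0)
        i = list(curve.concentrations).index(0.2)
        np.testing.assert_allclose(curve.responses[i], 50.0, atol=1e-9)

    def test_decreasing_plateau_limit(self):
        p = FourPLParams(bottom=5, top=95, hill=2, ec50=0.1)
        curve = simulate_dose_response(p, "decreasing", [0.01, 0.1, 1.0, 1e4],
                                       n_reps=1, noise_sd=0.0, seed=0)
        assert curve.responses[-1, 0] == pytest.approx(5.0, abs=1e-3)

    def test_zero_noise_matches_4pl_closed_form(self):
        p = FourPLParams(bottom=10, top=90, hill=0.8, ec50=0.5)
        grid = np.geomspace(0.01, 10, 8)
        curve = simulate_dose_response(p, "increasing", grid, 2, 0.0, 0)
        expected = four_pl(grid, 10, 90, 0.8, 0.5)
        np.testing.assert_allclose(curve.responses, np.tile(expected[:, None], (1, 2)),
                                   atol=1e-12)

    def test_seeded_determinism(self):
        p = FourPLParams(0, 100, 1, 0.1)
        grid = [0.01, 0.05, 0.2, 1.0]
        a = simulate_dose_response(p, "increasing", grid, 3, 5.0, seed=42)
        b = simulate_dose_response(p, "increasing", grid, 3, 5.0, seed=42)
        assert np.array_equal(a.responses, b.responses)

    def test_too_few_distinct_concentrations(self):
        p = FourPLParams(0, 100, 1, 0.1)
        with pytest.raises(InsufficientDesignError):
            simulate_dose_response(p, "increasing", [0.1, 0.1, 0.2], 3, 0.0, 0)


class TestPanel:
    def test_requires_exactly_one_control(self):
        with pytest.raises(InvalidPanelError):
            simulate_variant_panel([SyntheticTruth("v1", binding_mult=0.5)], seed=0)
        with pytest.raises(InvalidPanelError):
            simulate_variant_panel(
                [SyntheticTruth("a"), SyntheticTruth("b")], seed=0)

    def test_same_seed_reproduces_panel(self):
        truths = default_truths()
        a = simulate_variant_panel(truths, seed=5)
        b = simulate_variant_panel(truths, seed=5)
        assert a.yields == b.yields
        for name in a.protein_names:
            assert np.array_equal(a.binding[name].responses, b.binding[name].responses)
            assert np.array_equal(a.curves[name]["cofactor"].responses,
                                  b.curves[name]["cofactor"].responses)

    def test_zero_noise_yield_ratio_is_truth(self, noiseless_design):
        truths = [SyntheticTruth("Control"),
                  SyntheticTruth("Arg175Pro", yield_mult=0.26)]
        panel = simulate_variant_panel(truths, noiseless_design, seed=0)
        ratio = panel.yields["Arg175Pro"] / panel.yields["Control"]
        assert ratio == pytest.approx(0.26, rel=1e-12)


class TestTruthMapping:
    def test_daa_ratio_round_trip(self):
        d = PanelDesign()
        for m in [0.05, 0.3, 1.0, 1.5]:
            r = expected_daa_ratio(m, d)
            assert daa_mult_from_ratio(r, d) == pytest.approx(m, rel=1e-12)

    def test_daa_ratio_tends_to_mult_for_small_windows(self):
        # first-order limit: ratio -> multiplier as k_fh·T -> 0
        import dataclasses
        d = dataclasses.replace(PanelDesign(), k_fh=1e-6)
        assert expected_daa_ratio(0.37, d) == pytest.approx(0.37, rel=1e-3)

    def test_control_expected_ratios_all_ones(self):
        r = expected_ratios(SyntheticTruth("Control"))
        assert (r.binding_vc, r.daa_vc, r.ca_cv, r.ap_cv, r.yield_vc,
                r.hemolysis_score) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_default_panel_matches_published_extremes(self):
        d = PanelDesign()
        rats = {t.variant_name: expected_ratios(t, d) for t in default_truths(d)}
        binding = [r.binding_vc for r in rats.values()]
        assert min(binding) == pytest.approx(0.65) and max(binding) == pytest.approx(1.27)
        assert min(r.daa_vc for r in rats.values()) == pytest.approx(0.08, abs=1e-9)
        assert min(r.ca_cv for r in rats.values()) == pytest.approx(0.07)
        assert min(r.ap_cv for r in rats.values()) == pytest.approx(0.01)
        yields = [r.yield_vc for r in rats.values()]
        assert min(yields) == pytest.approx(0.26) and max(yields) == pytest.approx(1.30)
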