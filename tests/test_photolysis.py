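"""Rebinding model evaluation, single/global fits, R/T summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hemolig.equilibrium import Condition
from hemolig.exceptions import DomainError, InputError, OutOfRangeError
from hemolig.photolysis import (
    BimolecularComponent,
    GeminateComponent,
    KineticSummary,
    PhotolysisTrace,
    RebindingDecay,
    RebindingModel,
    bimolecular_constants,
    co_concentration,
    compare_conditions,
    fit_trace,
    global_fit,
    model_eval,
    rt_fractions,
    summarize,
)
from hemolig.synthetic import PRESETS, default_geminate, simulate_photolysis_trace


def simple_model(ar=0.84, kr=940.0, at=0.16, kt=240.0, gem_amp=0.08):
    return RebindingModel(
        geminate=default_geminate(gem_amp),
        R=BimolecularComponent(ar, kr),
        T=BimolecularComponent(at, kt),
    )


class TestModelEval:
    def test_t0_equals_total_amplitude(self):
        m = simple_model()
        assert model_eval(0.0, m) == pytest.approx(m.total_amplitude, abs=1e-12)

    def test_stretched_beta1_equals_plain_exponential(self):
        tau = 1e-6
        m = RebindingModel(
            geminate=(GeminateComponent(1.0, tau, 1.0),),
            R=BimolecularComponent(0.0, 1000.0),
            T=BimolecularComponent(0.0, 100.0),
        )
        t = np.geomspace(1e-9, 1e-3, 200)
        assert np.max(np.abs(model_eval(t, m) - np.exp(-t / tau))) < 1e-12

    def test_round_trip_with_generator(self):
        m = simple_model(ar=0.84, at=0.16)
        tr = simulate_photolysis_trace(m, co_atm=1.0, noise_sd=0.0)
        raw = model_eval(tr.times_s, m)
        np.testing.assert_array_equal(tr.N, raw / raw[0])

    @given(
        ar=st.floats(0.0, 1.0), at=st.floats(0.0, 1.0),
        kr=st.floats(10.0, 1e5), ratio=st.floats(1.5, 50.0),
        beta=st.floats(0.3, 1.0), tau=st.floats(1e-8, 1e-5),
    )
    def test_nonincreasing_in_time(self, ar, at, kr, ratio, beta, tau):
        m = RebindingModel(
            geminate=(GeminateComponent(0.1, tau, beta),),
            R=BimolecularComponent(ar, kr),
            T=BimolecularComponent(at, kr / ratio),
        )
        t = np.geomspace(1e-9, 1.0, 300)
        y = model_eval(t, m)
        assert np.all(np.diff(y) <= 1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            model_eval(-1.0, simple_model())

    def test_rt_relabelling(self):
        # supplied with T faster than R, the model swaps them
        m = RebindingModel(
            geminate=(), R=BimolecularComponent(0.5, 10.0),
            T=BimolecularComponent(0.2, 500.0),
        )
        assert m.R.rate_per_s > m.T.rate_per_s
        assert m.R.amplitude == 0.2


class TestFitTrace:
    def test_noiseless_round_trip(self):
        true = simple_model(ar=0.77, kr=921.2, at=0.15, kt=235.2)
        tr = simulate_photolysis_trace(true, noise_sd=0.0)
        # the generator normalises to the first sample
        true = true.scaled(1.0 / float(model_eval(tr.times_s[0], true)))
        m = fit_trace(tr)
        assert m.R.amplitude == pytest.approx(true.R.amplitude, rel=1e-3)
        assert m.T.amplitude == pytest.approx(true.T.amplitude, rel=1e-3)
        assert m.R.rate_per_s == pytest.approx(true.R.rate_per_s, rel=1e-3)
        assert m.T.rate_per_s == pytest.approx(true.T.rate_per_s, rel=1e-3)
        for g_fit, g_true in zip(m.geminate, true.geminate):
            assert g_fit.beta == pytest.approx(g_true.beta, abs=0.01)

    def test_single_bimolecular_component(self):
        true = simple_model(ar=0.92, at=0.0)
        tr = simulate_photolysis_trace(true, noise_sd=0.0)
        m = fit_trace(tr)
        assert m.T.amplitude < 0.01 * m.total_amplitude

    def test_noisy_fraction_recovery(self):
        preset = PRESETS["hb1_stripped"]
        tr = simulate_photolysis_trace(preset.rebinding_model(), noise_sd=0.01, seed=4)
        m = fit_trace(tr)
        fr, _ = rt_fractions(m)
        assert fr == pytest.approx(84.0, abs=3.0)

    def test_estimator_surface(self):
        tr = simulate_photolysis_trace(simple_model(), noise_sd=0.0)
        est = RebindingDecay().fit(tr.times_s, tr.N)
        assert est.converged_
        pred = est.predict(tr.times_s)
        assert np.max(np.abs(pred - tr.N)) < 1e-6
        assert est.get_params()["n_geminate"] == 2

    def test_too_short_trace_rejected(self):
        from hemolig.exceptions import InsufficientDataError

        t = np.geomspace(1e-4, 1e-2, 60)
        with pytest.raises(InsufficientDataError):
            RebindingDecay().fit(t, np.exp(-100 * t))


class TestGlobalFit:
    def test_shared_rates_two_pressures(self):
        preset = PRESETS["hb1_stripped"]
        cond = preset.condition()
        traces = [
            simulate_photolysis_trace(preset.rebinding_model(a), co_atm=a,
                                      noise_sd=0.0, condition=cond)
            for a in (1.0, 0.1)
        ]
        gf = global_fit(traces)
        assert gf.kon_R == pytest.approx(preset.kon_R, rel=1e-3)
        assert gf.kon_T == pytest.approx(preset.kon_T, rel=1e-3)
        # apparent rates differ 10-fold between the traces
        assert gf.models[0].R.rate_per_s == pytest.approx(
            10.0 * gf.models[1].R.rate_per_s, rel=1e-6)

    def test_atp_pair_fractions_rates_shared(self):
        stripped, with_atp = PRESETS["hb1_stripped"], PRESETS["hb1_atp"]
        traces = [
            simulate_photolysis_trace(p.rebinding_model(), co_atm=1.0,
                                      noise_sd=0.01, seed=i, condition=p.condition())
            for i, p in enumerate((stripped, with_atp))
        ]
        gf = global_fit(traces)
        fr0, _ = rt_fractions(gf.models[0])
        fr1, _ = rt_fractions(gf.models[1])
        assert fr0 == pytest.approx(84.0, abs=2.0)
        assert fr1 == pytest.approx(22.0, abs=2.0)
        # rate constants are shared by construction
        assert gf.models[0].R.rate_per_s == gf.models[1].R.rate_per_s

    def test_single_trace_degenerates_to_fit_trace(self):
        preset = PRESETS["hb1_stripped"]
        tr = simulate_photolysis_trace(preset.rebinding_model(), noise_sd=0.0,
                                       condition=preset.condition())
        gf = global_fit([tr])
        single = fit_trace(tr)
        assert gf.models[0].R.rate_per_s == pytest.approx(single.R.rate_per_s, rel=1e-9)

    def test_global_matches_independent_when_rates_truly_shared(self):
        preset = PRESETS["hb1_stripped"]
        cond = preset.condition()
        traces = [
            simulate_photolysis_trace(preset.rebinding_model(a), co_atm=a,
                                      noise_sd=0.0, condition=cond)
            for a in (1.0, 0.1)
        ]
        gf = global_fit(traces)
        for tr, m in zip(traces, gf.models):
            r_global = np.sqrt(np.mean((model_eval(tr.times_s, m) - tr.N) ** 2))
            single = fit_trace(tr)
            r_single = np.sqrt(np.mean((model_eval(tr.times_s, single) - tr.N) ** 2))
            assert r_global <= r_single + 0.01 * max(r_single, 1e-9) + 1e-9

    def test_mismatched_conditions_rejected(self):
        preset = PRESETS["hb1_stripped"]
        tr1 = simulate_photolysis_trace(preset.rebinding_model(), condition=preset.condition())
        tr2 = simulate_photolysis_trace(
            preset.rebinding_model(), condition=Condition(288.15, 7.4))
        with pytest.raises(InputError):
            global_fit([tr1, tr2])


class TestDerived:
    @pytest.mark.parametrize("ar,at,expected", [
        (1.0, 0.0, (100.0, 0.0)),
        (3.0, 1.0, (75.0, 25.0)),
        (0.84, 0.16, (84.0, 16.0)),
    ])
    def test_rt_fractions(self, ar, at, expected):
        m = simple_model(ar=ar, at=at)
        fr, ft = rt_fractions(m)
        assert (fr, ft) == pytest.approx(expected)

    def test_rt_fractions_undefined_without_bimolecular(self):
        m = RebindingModel(geminate=default_geminate(),
                           R=BimolecularComponent(0.0, 1000.0),
                           T=BimolecularComponent(0.0, 100.0))
        with pytest.raises(InputError):
            rt_fractions(m)

    def test_bimolecular_constants(self):
        m = simple_model(kr=940.0, kt=240.0)
        kon_r, kon_t = bimolecular_constants(m, 1e-3)
        assert kon_r == pytest.approx(9.4e5)
        ratio_a = kon_r / kon_t
        kon_r2, kon_t2 = bimolecular_constants(m, 3.7e-4)
        assert kon_r2 / kon_t2 == pytest.approx(ratio_a, rel=1e-12)

    def test_co_concentration(self):
        c = co_concentration(1.0, 298.15)
        assert c == pytest.approx(9.8e-4, rel=1e-6)
        assert co_concentration(0.1, 298.15) == pytest.approx(c / 10.0, rel=1e-12)
        with pytest.raises(InputError):
            co_concentration(0.0, 298.15)
        with pytest.raises(OutOfRangeError):
            co_concentration(1.0, 350.0)

    def test_compare_conditions(self):
        cond = Condition(298.15, 7.4)
        a = KineticSummary(60.0, 40.0, 9.4e5, 2.4e5, 8.0, 9.8e-4, "Hb 1", cond)
        b = KineticSummary(81.0, 19.0, 9.4e5, 2.4e5, 8.0, 9.8e-4, "Hb 1", cond)
        rep = compare_conditions(a, b)
        assert rep["delta_fR_points"] == pytest.approx(21.0)
        assert rep["delta_fR_relative_pct"] == pytest.approx(35.0)
        same = compare_conditions(a, a)
        assert same["delta_fR_points"] == 0.0
        assert same["kon_R_ratio"] == 1.0

    def test_compare_conditions_atp_pair(self):
        cond = Condition(298.15, 7.4)
        stripped = KineticSummary(84.0, 16.0, 9.4e5, 2.4e5, 8.0, 9.8e-4, "Hb 1", cond)
        atp = KineticSummary(22.0, 78.0, 9.4e5, 2.4e5, 8.0, 9.8e-4, "Hb 1", cond)
        assert compare_conditions(stripped, atp)["delta_fR_points"] == pytest.approx(-62.0)

    def test_compare_mismatched_isoforms_rejected(self):
        a = KineticSummary(60.0, 40.0, 9.4e5, 2.4e5, 8.0, 9.8e-4, "Hb 1")
        b = KineticSummary(60.0, 40.0, 9.4e5, 2.4e5, 8.0, 9.8e-4, "Hb 2")
        with pytest.raises(InputError):
            compare_conditions(a, b)

    def test_summarize(self):
        m = simple_model()
        s = summarize(m, 9.8e-4, isoform="Hb 1")
        assert s.fR_pct == pytest.approx(84.0)
        assert s.geminate_pct == pytest.approx(100 * 0.08 / 1.08)
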