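"""Preprocessing, the forward current model, and the fitting protocol."""

import dataclasses

import numpy as np
import pytest

from ambientglu.fitting import (FitSpec, error_reduction, fit_control,
                                fit_eaat_block, preprocess_trace,
                                simulate_current)
from ambientglu.glutamate import TransientParams
from ambientglu.trace import Trace

TP = TransientParams(M=5e6, r=1.23, ambient=4.7)


class TestPreprocess:
    def test_average_of_identical_trials_unchanged(self, rng):
        v = rng.normal(0, 1, 4000)
        trials = [Trace(0.0, 0.05, v.copy()) for _ in range(5)]
        out = preprocess_trace(trials, filter_cutoff=1e9, n_average=5)
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_dc_trace_through_filter_unchanged(self):
        tr = Trace(0.0, 0.05, np.full(4000, -33.0))
        out = preprocess_trace(tr, filter_cutoff=1000.0)
        np.testing.assert_allclose(out.values, -33.0, atol=1e-9)

    def test_artifact_spike_removed(self):
        v = np.zeros(2000)
        v[1000] = 5000.0  # 1-sample artifact at t = 50 ms
        tr = Trace(0.0, 0.05, v)
        out = preprocess_trace(tr, artifact_windows=[(49.5, 50.5)],
                               filter_cutoff=1e9)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)
        assert out.meta["blanked"].sum() == 20

    def test_malformed_windows_rejected(self):
        tr = Trace(0.0, 0.05, np.zeros(2000))
        with pytest.raises(ValueError):
            preprocess_trace(tr, artifact_windows=[(50.0, 40.0)])
        with pytest.raises(ValueError):
            preprocess_trace(tr, artifact_windows=[(10.0, 30.0), (20.0, 40.0)])


class TestSimulateCurrent:
    def test_no_ambient_no_train_is_flat_leak(self, scheme34):
        tp = TransientParams(M=5e6, r=1.23, ambient=0.0)
        tr = simulate_current(scheme34, tp, [], leak_offset=-12.0,
                              t_end=200.0, fs_khz=2.0)
        np.testing.assert_allclose(tr.values, -12.0, atol=1e-8)

    def test_tonic_desensitization_shrinks_first_epsc(self, scheme34, train50):
        tp0 = TransientParams(M=5e6, r=1.23, ambient=0.0)
        tp5 = TransientParams(M=5e6, r=1.23, ambient=5.0)
        tr0 = simulate_current(scheme34, tp0, train50, t_end=140.0, fs_khz=10.0)
        tr5 = simulate_current(scheme34, tp5, train50, t_end=140.0, fs_khz=10.0)
        # first fast EPSC amplitude, measured from the pre-stimulus baseline
        amp0 = np.abs(tr0.values - tr0.values[0]).max()
        amp5 = np.abs(tr5.values - tr5.values[0]).max()
        assert amp5 < amp0

    def test_slow_current_outlasts_train_by_hundreds_of_ms(self, scheme34, train50):
        tr = simulate_current(scheme34, TP, train50, t_end=3000.0, fs_khz=2.0)
        t = tr.times
        baseline = tr.values[t < 100.0].mean()
        end_of_train = 100.0 + 9 * 20.0
        excess = np.abs(tr.values - baseline)
        # the slow EPSC: current grows again after the train as cleft
        # glutamate falls through the dose-response peak ...
        post = excess[t > end_of_train + 50.0]
        t_post = t[t > end_of_train + 50.0]
        k = int(np.argmax(post))
        assert 100.0 < t_post[k] - end_of_train < 800.0
        # ... and then decays over hundreds of ms
        slow_peak = post[k]
        assert excess[np.searchsorted(t, end_of_train + 300.0)] > 0.25 * slow_peak
        assert excess[-1] < 0.25 * slow_peak


def _zero_noise_dataset(scheme34, train50):
    from ambientglu.synthetic import SyntheticCellSpec, generate_recording
    cell = SyntheticCellSpec(noise_sd=0.0, artifact_amp=0.0, n_trials=1, seed=5)
    rec = generate_recording(cell, train50, scheme34, t_end=1500.0)
    pre = {c: preprocess_trace(rec.trials[c], rec.artifact_windows)
           for c in ("control", "block")}
    return rec, pre


class TestFitting:
    def test_zero_noise_self_consistency(self, scheme34, train50):
        rec, pre = _zero_noise_dataset(scheme34, train50)
        fit = fit_control(pre["control"], train50, scheme34,
                          FitSpec(seed=1, restarts=2))
        truth = rec.truth["control"]
        for p in ("M", "r", "ambient", "g_max"):
            assert fit.params[p] == pytest.approx(truth[p], rel=0.01), p
        assert fit.objective < 1e-2 * np.sum(pre["control"].values ** 2)

    def test_determinism(self, scheme34, train50):
        _, pre = _zero_noise_dataset(scheme34, train50)
        spec = FitSpec(seed=9, restarts=1, maxfev=300)
        a = fit_control(pre["control"], train50, scheme34, spec)
        b = fit_control(pre["control"], train50, scheme34, spec)
        assert a.params == b.params and a.objective == b.objective

    def test_frozen_ambient_fits_worse_on_ambient_data(self, scheme34, train50):
        _, pre = _zero_noise_dataset(scheme34, train50)
        full = fit_control(pre["control"], train50, scheme34,
                           FitSpec(seed=1, restarts=2))
        free_na = {n: v for n, v in FitSpec().free.items() if n != "ambient"}
        no_amb = fit_control(pre["control"], train50, scheme34,
                             FitSpec(free=free_na, fixed={"ambient": 1e-3},
                                     seed=1, restarts=2))
        assert no_amb.objective > full.objective
        assert error_reduction(full, no_amb) > 0

    def test_block_refit_recovers_folds(self, scheme34, train50):
        rec, pre = _zero_noise_dataset(scheme34, train50)
        ctrl = fit_control(pre["control"], train50, scheme34,
                           FitSpec(seed=1, restarts=2))
        blk = fit_eaat_block(pre["block"], train50, scheme34, ctrl,
                             spec=FitSpec(seed=2, restarts=2))
        assert blk.params["ambient"] / ctrl.params["ambient"] == pytest.approx(2.4, rel=0.1)
        assert blk.params["M"] / ctrl.params["M"] == pytest.approx(2.3, rel=0.1)
        # inherited parameters are frozen
        for p in ("r", "g_max", "leak_offset"):
            assert blk.params[p] == ctrl.params[p]

    def test_identical_conditions_give_unit_folds(self, scheme34, train50):
        _, pre = _zero_noise_dataset(scheme34, train50)
        ctrl = fit_control(pre["control"], train50, scheme34,
                           FitSpec(seed=1, restarts=2))
        blk = fit_eaat_block(pre["control"], train50, scheme34, ctrl,
                             spec=FitSpec(seed=3, restarts=1))
        assert blk.params["ambient"] / ctrl.params["ambient"] == pytest.approx(1.0, abs=0.05)
        assert blk.params["M"] / ctrl.params["M"] == pytest.approx(1.0, abs=0.05)

    def test_block_requires_control(self, scheme34, train50):
        _, pre = _zero_noise_dataset(scheme34, train50)
        with pytest.raises(ValueError):
            fit_eaat_block(pre["block"], train50, scheme34, None)


class TestErrorReduction:
    def test_arithmetic(self):
        from ambientglu.fitting import FitResult
        mk = lambda o: FitResult(params={}, free_names=(), objective=o,
                                 residual=Trace(0, 1, np.zeros(2)))
        assert error_reduction(mk(4.0), mk(4.0)) == 0.0
        assert error_reduction(mk(2.0), mk(4.0)) == 50.0
        with pytest.raises(ZeroDivisionError):
            error_reduction(mk(1.0), mk(0.0))
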