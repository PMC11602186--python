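"""Binned sessions, movement regression, corrected averages, cross-correlation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as hst

from secothal import (
    MovementModel,
    ParameterError,
    bin_session,
    corrected_event_average,
    crosscorr,
    movement_regression,
    tuning_classification,
)
from conftest import spikes_from_rate


@pytest.fixture(scope="module")
def binned(mid_session):
    session, _ = mid_session
    return bin_session(session)


class TestBinSession:
    def test_counts_to_rates(self, mid_session):
        session, _ = mid_session
        b = bin_session(session)
        cid = session.cell_ids()[0]
        i = int(b.rates[cid].idxmax())
        lo, hi = i * 0.25, (i + 1) * 0.25
        n = np.count_nonzero((session.spikes[cid] >= lo) & (session.spikes[cid] < hi))
        assert b.rates[cid].iloc[i] == pytest.approx(n / 0.25)

    def test_stimulus_indicator_eight_bins(self, binned, mid_session):
        session, _ = mid_session
        onsets = session.schedule.onsets("tactile")
        ind = binned.predictors["puff"].to_numpy()
        for on in onsets[:5]:
            i0 = int(np.searchsorted(binned.time, on))
            assert ind[i0:i0 + 8].sum() == 8          # 2-s stimulus = 8 bins of 250 ms

    def test_grid_shared(self, binned):
        assert len(binned.predictors) == binned.n_bins
        assert all(len(binned.rates[c]) == binned.n_bins for c in binned.rates)

    def test_non_ms_bin_errors(self, mid_session):
        session, _ = mid_session
        with pytest.raises(ParameterError):
            bin_session(session, bin=0.2505)


class TestMovementRegression:
    def test_exact_linear_dependence(self, binned):
        b = replace(binned, rates=binned.rates.copy())
        b.rates["exact"] = 2.0 + 3.0 * b.predictors["whisk"]
        res = movement_regression(b, "exact")
        assert res.params["whisk"] == pytest.approx(3.0, abs=1e-8)
        assert res.params["const"] == pytest.approx(2.0, abs=1e-6)
        assert np.abs(res.residuals).max() < 1e-8

    def test_coupled_cell_recovered(self, mid_session, binned):
        session, truth = mid_session
        c = truth.cell("c006")           # pure coupling, no stimulus kernels
        res = movement_regression(binned, "c006")
        for name, true in (("whisk", c.beta_whisk), ("pupil", c.beta_pupil),
                           ("lick", c.beta_lick)):
            assert abs(res.params[name] - true) <= 3 * res.bse[name]

    def test_shuffled_predictor_not_significant(self, mid_session, binned):
        session, truth = mid_session
        rng = np.random.default_rng(0)
        hits = n = 0
        for rep in range(10):
            b = replace(binned, predictors=binned.predictors.copy())
            b.predictors["whisk"] = rng.permutation(b.predictors["whisk"].to_numpy())
            res = movement_regression(b, "c006")
            hits += int(res.pvalues["whisk"] < 0.05)
            n += 1
        assert hits <= 2        # ~ alpha, not systematic

    def test_residuals_orthogonal_to_predictors(self, binned):
        res = movement_regression(binned, "c002")
        X = binned.predictors[["whisk", "pupil", "lick"]].to_numpy()
        dots = X.T @ res.residuals / len(res.residuals)
        assert np.abs(dots).max() < 1e-8
        assert abs(res.residuals.mean()) < 1e-10

    def test_constant_shift_moves_only_intercept(self, binned):
        res0 = movement_regression(binned, "c002")
        b = replace(binned, predictors=binned.predictors.copy())
        b.predictors["whisk"] = b.predictors["whisk"] + 5.0
        res1 = movement_regression(b, "c002")
        assert res1.params["whisk"] == pytest.approx(res0.params["whisk"], rel=1e-9)
        assert res1.params["const"] == pytest.approx(
            res0.params["const"] - 5.0 * res0.params["whisk"], rel=1e-6
        )

    def test_collinear_design_errors(self, binned):
        b = replace(binned, predictors=binned.predictors.copy())
        b.predictors["pupil"] = 2.0 * b.predictors["whisk"]
        with pytest.raises(ParameterError, match="whisk|pupil"):
            MovementModel(b, "c002")

    def test_constant_predictor_errors(self, binned):
        b = replace(binned, predictors=binned.predictors.copy())
        b.predictors["lick"] = 0.0
        with pytest.raises(ParameterError, match="lick"):
            MovementModel(b, "c002")


class TestCorrectedEventAverage:
    def _stim_change(self, res, onsets):
        t, m, s = corrected_event_average(res.residuals, res.time, onsets, (-1, 1))
        stim = (t >= 0) & (t < 1)
        sem = float(np.sqrt((s[stim] ** 2).mean()))
        return m[stim].mean() - m[t < 0].mean(), sem

    def test_movement_mediated_response_removed(self, mid_session, binned):
        session, truth = mid_session
        onsets = session.schedule.onsets("tactile")
        ch, sem = self._stim_change(movement_regression(binned, "c006"), onsets)
        assert abs(ch) <= 2 * sem

    def test_direct_kernel_retained(self, mid_session, binned):
        session, truth = mid_session
        c = truth.cell("c007")           # direct kernel + movement coupling
        onsets = session.schedule.onsets("tactile")
        ch, sem = self._stim_change(movement_regression(binned, "c007"), onsets)
        true = (c.onset_amp["tactile"] * 0.1
                + c.sustained_amp["tactile"] * (1 - c.latency_true["tactile"]))
        assert abs(ch - true) <= 0.2 * true + 2 * sem

    def test_null_cell_flat(self, mid_session):
        session, truth = mid_session
        dur_ms = int(session.duration * 1000)
        b = bin_session(session)
        b = replace(b, rates=b.rates.copy())
        b.rates["null"] = np.histogram(
            spikes_from_rate(np.full(dur_ms, 9.0), 0.001, 17),
            bins=np.arange(b.n_bins + 1) * 0.25,
        )[0] / 0.25
        res = movement_regression(b, "null")
        ch, sem = self._stim_change(res, session.schedule.onsets("tactile"))
        assert abs(ch) <= 2 * sem

    def test_offset_consumption_activity_removed(self, mid_session):
        # lick-mediated post-reward firing disappears from the corrected trace
        session, truth = mid_session
        dur_ms = int(session.duration * 1000)
        rate = np.full(dur_ms, 10.0)
        aligned_lick = np.zeros(dur_ms)
        idx = np.minimum((session.licks * 1000).astype(np.int64), dur_ms - 1)
        aligned_lick[idx] = 1.0
        n_bins = dur_ms // 250
        lick_rate = np.repeat(
            aligned_lick[: n_bins * 250].reshape(n_bins, 250).sum(axis=1) / 0.25, 250
        )
        rate[: n_bins * 250] += 0.6 * lick_rate[: n_bins * 250]
        b = bin_session(session)
        b = replace(b, rates=b.rates.copy())
        b.rates["lickcell"] = np.histogram(
            spikes_from_rate(rate, 0.001, 23), bins=np.arange(b.n_bins + 1) * 0.25
        )[0] / 0.25
        res = movement_regression(b, "lickcell")
        onsets = session.schedule.onsets("tactile")
        t, m, s = corrected_event_average(res.residuals, res.time, onsets, (2, 4))
        assert abs(m.mean()) <= 2 * float(np.sqrt((s ** 2).mean()))


class TestTuning:
    def test_pure_coupling_cell(self, binned):
        res = movement_regression(binned, "c006", include_stimuli=True)
        lab = res.tuning()
        assert lab.movement_tuned and not lab.stimulus_tuned

    def test_pure_kernel_cell(self, binned):
        res = movement_regression(binned, "c008", include_stimuli=True)
        lab = tuning_classification(res)
        assert lab.stimulus_tuned and not lab.movement_tuned

    def test_requires_full_model(self, binned):
        res = movement_regression(binned, "c006", include_stimuli=False)
        with pytest.raises(ParameterError):
            tuning_classification(res)


class TestCrosscorr:
    def test_identity_peak_at_zero(self):
        x = np.random.default_rng(0).standard_normal(1000)
        xc = crosscorr(x, x, bin=0.25, max_lag=2.0)
        peak = xc.loc[xc["r"].idxmax()]
        assert peak["lag_s"] == 0.0 and peak["r"] == pytest.approx(1.0)

    def test_delayed_signal_peaks_at_negative_lag(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3000)
        y = np.roll(x, 4)                 # signal lags rate by 1 s (4 bins)
        xc = crosscorr(x, y, bin=0.25, max_lag=2.0)
        assert xc.loc[xc["r"].idxmax(), "lag_s"] == pytest.approx(-1.0)

    @given(hst.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_swap_reverses_lags(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(400)
        y = rng.standard_normal(400) + 0.3 * x
        a = crosscorr(x, y, bin=0.5, max_lag=1.5)
        b = crosscorr(y, x, bin=0.5, max_lag=1.5)
        assert np.allclose(a["r"].to_numpy(), b["r"].to_numpy()[::-1], atol=1e-12)

    def test_independent_series_bounded(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            xc = crosscorr(rng.standard_normal(2000), rng.standard_normal(2000),
                           bin=0.25, max_lag=1.0)
            ok += int(np.abs(xc["r"]).max() < 3 / np.sqrt(2000 - 4))
        assert ok >= 15   # ~95% of seeds within the white-noise bound

    def test_constant_series_flagged(self):
        xc = crosscorr(np.ones(500), np.random.default_rng(0).standard_normal(500),
                       bin=0.25)
        assert xc["undefined"].all()
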