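"""PSTHs, responsiveness classification, latencies, selectivity, quiet-span rates."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as hst

from secothal import (
    AnalysisConfig,
    ParameterError,
    classify_responses,
    event_triggered_rates,
    latency_table,
    response_latency,
    selectivity_index,
    spontaneous_rate,
    window_rate_change,
)
from secothal.neural_responses import (
    SelectivityPositionModel,
    cell_response_stats,
    non_overlapping_events,
)
from conftest import spikes_from_rate


def _rate_grid(duration, baseline, onsets, start, stop, amp):
    """Piecewise-constant rate: baseline plus amp over [onset+start, onset+stop)."""
    grid = np.full(int(duration * 1000), float(baseline))
    for on in onsets:
        i0, i1 = int((on + start) * 1000), int((on + stop) * 1000)
        grid[i0:i1] += amp
    return np.maximum(grid, 0.0)


class TestPSTH:
    def test_direct_count_example(self):
        p = event_triggered_rates(np.array([0.10, 0.30, 1.20]), np.array([0.0]),
                                  window=(0, 2), bin=0.25)
        assert np.array_equal(p.rate, [4, 4, 0, 0, 4, 0, 0, 0])

    def test_empty_spike_train(self):
        p = event_triggered_rates(np.array([]), np.arange(5.0), (0, 2), 0.25)
        assert not p.rate.any()

    def test_homogeneous_poisson_flat(self):
        onsets = np.arange(10, 10 + 200 * 10, 10.0)
        sp = spikes_from_rate(np.full(int(onsets[-1] + 10) * 1000, 20.0), 0.001, 3)
        p = event_triggered_rates(sp, onsets, (-2, 4), 0.25)
        assert np.all(np.abs(p.rate - 20.0) < 4 * p.sem + 1e-9)

    def test_errors(self):
        with pytest.raises(ParameterError):
            event_triggered_rates(np.array([1.0]), np.array([]), (0, 2), 0.25)
        with pytest.raises(ParameterError):
            event_triggered_rates(np.array([1.0]), np.array([0.0]), (0, 2), 0.3)


class TestOverlapExclusion:
    def test_symmetric_six_second_rule(self, mid_session):
        session, _ = mid_session
        ev = non_overlapping_events(session.schedule)
        for mod, other in (("tactile", "visual"), ("visual", "tactile")):
            others = session.schedule.onsets(other)
            for e in ev[mod]:
                assert np.min(np.abs(others - e.onset)) >= 6.0


class TestClassification:
    def _null_session(self, mid_session, rates):
        session, _ = mid_session
        rng = np.random.default_rng(0)
        spikes = {}
        dur_ms = int(session.duration * 1000)
        for i, lam in enumerate(rates):
            spikes[f"c{i:03d}"] = spikes_from_rate(np.full(dur_ms, lam), 0.001, 100 + i)
        return spikes

    def test_strong_puff_cell_detected_with_power(self, mid_session):
        session, _ = mid_session
        ev = non_overlapping_events(session.schedule)
        on = np.array([e.onset for e in ev["tactile"]])[:50]
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            grid = _rate_grid(session.duration, 10.0, on, 0.0, 2.0, 15.0)
            sp = spikes_from_rate(grid, 0.001, 200 + rep)
            st = cell_response_stats(sp, {"tactile": ev["tactile"][:50], "visual": ev["visual"]})
            hits += int(st["anova_p"] < 0.05 / 200 and st["p_puff"] < 0.05)
        assert hits >= 0.9 * n_rep    # power >= 0.9 even under a 200-cell Holm family

    def test_both_label_for_equal_responses(self, mid_session):
        session, _ = mid_session
        sched = session.schedule
        grid = _rate_grid(session.duration, 10.0, sched.onsets("tactile"), 0, 2, 12.0)
        for on in sched.onsets("visual"):
            grid[int(on * 1000):int((on + 2) * 1000)] += 12.0
        sp = spikes_from_rate(np.maximum(grid, 0), 0.001, 7)
        cells = pd.DataFrame(
            {"cell_id": ["x"], "region": ["POm"], "ap_um": [-1800.0], "dv_um": [3200.0],
             "ml_um": [1300.0], "dist_to_boundary_um": [400.0]}
        )
        s = replace(session, cells=cells, spikes={"x": sp})
        df = classify_responses(s)
        assert df.loc[0, "label"] == "both"
        assert abs(df.loc[0, "si"]) < 0.5

    def test_generated_cells_recovered(self, mid_session):
        session, truth = mid_session
        df = classify_responses(session).set_index("cell_id")
        for c in truth.cells:
            if c.cell_id not in df.index:
                continue
            has_t = c.sustained_amp["tactile"] != 0 or c.onset_amp["tactile"] != 0
            has_v = c.sustained_amp["visual"] != 0 or c.onset_amp["visual"] != 0
            label = df.loc[c.cell_id, "label"]
            if has_t and not has_v and c.beta_whisk == 0:
                assert label in ("puff", "both")
            if not has_t and has_v and c.beta_whisk == 0:
                assert label in ("grating", "both")

    def test_boundary_cells_never_in_outputs(self, mid_session):
        session, _ = mid_session
        cells = session.cells.copy()
        cells.loc[0, "dist_to_boundary_um"] = 10.0
        s = replace(session, cells=cells)
        df = classify_responses(s)
        assert cells.loc[0, "cell_id"] not in set(df["cell_id"])
        lat = latency_table(s)
        assert cells.loc[0, "cell_id"] not in set(lat["cell_id"])

    def test_insufficient_events_flagged(self):
        ev = {"tactile": [], "visual": []}
        st = cell_response_stats(np.array([1.0, 2.0]), ev)
        assert st["insufficient"] and np.isnan(st["anova_p"])


class TestLatency:
    def _step_spikes(self, baseline, amp, step_at, onsets, duration, seed, stop=1.0):
        grid = _rate_grid(duration, baseline, onsets, step_at, stop, amp)
        return spikes_from_rate(grid, 0.001, seed)

    def test_step_cell_latency(self):
        onsets = np.arange(10, 10 + 200 * 15, 15.0)
        sp = self._step_spikes(10.0, 50.0, 0.05, onsets, onsets[-1] + 10, 1)
        r = response_latency(sp, onsets)
        assert r.latency == pytest.approx(0.05, abs=0.0100001)
        assert r.direction == "increase"

    def test_constant_cell_no_crossing(self):
        onsets = np.arange(10, 10 + 100 * 15, 15.0)
        sp = spikes_from_rate(np.full(int(onsets[-1] + 10) * 1000, 12.0), 0.001, 2)
        r = response_latency(sp, onsets)
        assert r.rule == "none" and r.latency is None

    def test_suppressed_cell_detected_as_decrease(self):
        onsets = np.arange(10, 10 + 200 * 15, 15.0)
        grid = _rate_grid(onsets[-1] + 10, 30.0, onsets, 0.03, 1.0, -30.0)
        sp = spikes_from_rate(grid, 0.001, 3)
        r = response_latency(sp, onsets)
        assert r.direction == "decrease"
        assert r.latency == pytest.approx(0.03, abs=0.0100001)

    def test_no_anticipation_property(self):
        # detector never fires more than one bin before the true step
        onsets = np.arange(10, 10 + 100 * 15, 15.0)
        dur = onsets[-1] + 10
        early = 0
        for seed in range(25):
            true_lat = 0.02 + 0.01 * (seed % 7)
            sp = self._step_spikes(8.0, 30.0, true_lat, onsets, dur, 300 + seed)
            r = response_latency(sp, onsets)
            if r.latency is not None and r.latency < true_lat - 0.0100001:
                early += 1
        assert early == 0

    def test_silent_baseline_floored(self):
        onsets = np.arange(10, 10 + 50 * 15, 15.0)
        grid = _rate_grid(onsets[-1] + 10, 0.0, onsets, 0.1, 1.0, 40.0)
        sp = spikes_from_rate(grid, 0.001, 4)
        r = response_latency(sp, onsets)
        assert r.sigma_floored
        assert r.latency == pytest.approx(0.1, abs=0.0100001)

    def test_too_few_events_errors(self):
        with pytest.raises(ParameterError):
            response_latency(np.array([1.0]), np.arange(5.0))


class TestSelectivityIndex:
    @pytest.mark.parametrize(
        "fr_a, fr_g, fr_b, expected",
        [(10, 2, 2, 1.0), (2, 10, 2, -1.0), (8, 8, 2, 0.0), (5, 1, 3, 0.0)],
    )
    def test_examples(self, fr_a, fr_g, fr_b, expected):
        assert selectivity_index(fr_a, fr_g, fr_b) == pytest.approx(expected)

    def test_undefined_when_no_response(self):
        assert np.isnan(selectivity_index(4.0, 4.0, 4.0))

    def test_negative_rate_errors(self):
        with pytest.raises(ParameterError):
            selectivity_index(-1.0, 2.0, 2.0)

    @given(
        hst.floats(0, 50), hst.floats(0, 50), hst.floats(0, 50)
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_in_modalities(self, a, g, b):
        si = selectivity_index(a, g, b)
        flipped = selectivity_index(g, a, b)
        if not np.isnan(si):
            assert flipped == pytest.approx(-si)
            assert -1.0 <= si <= 1.0


class TestWindowRateChange:
    onsets = np.arange(10, 10 + 100 * 18, 18.0)

    def test_constant_cell_zero_change(self):
        sp = spikes_from_rate(np.full(int(self.onsets[-1] + 10) * 1000, 15.0), 0.001, 5)
        ch, sem = window_rate_change(sp, self.onsets, (2.0, 4.0))
        assert abs(ch) < 2 * sem

    def test_offset_kernel_measured_in_offset_period(self):
        grid = _rate_grid(self.onsets[-1] + 10, 12.0, self.onsets, 2.0, 4.0, 20.0)
        sp = spikes_from_rate(grid, 0.001, 6)
        ch, sem = window_rate_change(sp, self.onsets, (2.0, 4.0))
        assert ch == pytest.approx(20.0, abs=4 * sem)

    def test_suppression_measured(self):
        grid = _rate_grid(self.onsets[-1] + 10, 12.0, self.onsets, 0.0, 1.0, -5.0)
        sp = spikes_from_rate(grid, 0.001, 7)
        ch, sem = window_rate_change(sp, self.onsets, (0.0, 1.0))
        assert ch == pytest.approx(-5.0, abs=4 * sem)


class TestSpontaneousRate:
    def test_event_free_session_poisson(self, mid_session):
        session, _ = mid_session
        quiet = replace(
            session,
            schedule=replace(session.schedule, events=[]),
            licks=np.array([]),
            spikes={"q": spikes_from_rate(np.full(int(session.duration * 1000), 12.0),
                                          0.001, 8)},
            cells=session.cells.iloc[:1].assign(cell_id=["q"]),
        )
        r = spontaneous_rate(quiet, "q")
        T = session.duration - 2.0
        assert r == pytest.approx(12.0, abs=3 * np.sqrt(12.0 / T))

    def test_fully_tiled_session_flagged(self, mid_session):
        session, _ = mid_session
        from secothal.task_schedule import StimulusEvent, StimulusSchedule

        events = [StimulusEvent("tactile", float(o), 2.0, True)
                  for o in np.arange(1, 394, 7.0)]
        tiled = replace(
            session,
            schedule=StimulusSchedule(events, 400.0, session.schedule.params, "tactile"),
        )
        assert np.isnan(spontaneous_rate(tiled, session.cell_ids()[0]))

    def test_uncoupled_cell_recovers_baseline(self, mid_session):
        session, truth = mid_session
        # c008: stimulus kernels but no movement coupling; quiet spans exclude
        # events, so its quiet rate is its baseline
        c = truth.cell("c008")
        assert c.beta_whisk == 0
        r = spontaneous_rate(session, "c008")
        assert r == pytest.approx(c.baseline_rate, rel=0.10)


class TestSelectivityPositionModel:
    def _table(self, slope, seed, n=120, noise=0.15):
        rng = np.random.default_rng(seed)
        ml = rng.uniform(1000, 1700, n)
        ct = np.where(rng.uniform(size=n) < 0.5, "tactile", "visual")
        si = np.where(ct == "tactile", 0.7, 0.0) + noise * rng.standard_normal(n)
        si = si + np.where(ct == "visual", slope * (ml - 1350) / 1000.0, 0.0)
        return pd.DataFrame(
            {"si": np.clip(si, -1, 1), "ml_um": ml,
             "dv_um": rng.uniform(2800, 3600, n), "ap_um": rng.uniform(-2300, -1400, n),
             "conditioning": ct}
        )

    def test_ml_gradient_recovered(self):
        res = SelectivityPositionModel(self._table(slope=0.8, seed=1)).fit()
        term = "C(ct)[T.visual]:ml_mm"
        assert res.pvalues[term] < 0.01
        assert abs(res.params[term] - 0.8) <= 2 * res.bse[term]

    def test_null_table_calibrated(self):
        hits = 0
        terms_checked = 0
        for seed in range(12):
            res = SelectivityPositionModel(self._table(slope=0.0, seed=10 + seed)).fit()
            for term in ("ml_mm", "dv_mm", "ap_mm", "C(ct)[T.visual]:ml_mm"):
                terms_checked += 1
                hits += int(res.pvalues[term] < 0.05)
        assert hits <= 0.2 * terms_checked    # ~ nominal alpha, not systematic

    def test_permuted_positions_not_significant(self):
        t = self._table(slope=0.8, seed=3)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(15):
            tp = t.copy()
            tp["ml_um"] = rng.permutation(tp["ml_um"].to_numpy())
            res = SelectivityPositionModel(tp).fit()
            hits += int(res.pvalues["C(ct)[T.visual]:ml_mm"] < 0.05)
        assert hits <= 3

    def test_single_conditioning_drops_interactions(self):
        t = self._table(slope=0.0, seed=5)
        t["conditioning"] = "tactile"
        with pytest.warns(UserWarning, match="single conditioning"):
            res = SelectivityPositionModel(t).fit()
        assert "ml_mm" in res.params.index
        assert not any("ct" in p for p in res.params.index)

    def test_too_few_cells_errors(self):
        with pytest.raises(ParameterError):
            SelectivityPositionModel(self._table(0.0, 0, n=10))
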