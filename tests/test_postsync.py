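"""Unit and property tests for post-synchronized heat-map analysis."""

import numpy as np
import pandas as pd
import pytest

from fastfish.postsync import (
    HeatMap,
    averaged_profile,
    delta_t,
    delta_t_from_events,
    detection_efficiency,
    edge_time,
    intensity_snapshot,
    postsynchronize,
    retention_fraction,
    two_gaussian_fraction,
)

DT = 0.4


def make_traces_and_events(on_frames, dwell_frames, n_frames=200, amp=1000.0):
    """One locus per event; a clean rectangular pulse each."""
    traces = np.zeros((len(on_frames), n_frames))
    rows = []
    for i, (f_on, nf) in enumerate(zip(on_frames, dwell_frames)):
        traces[i, f_on : f_on + nf] = amp
        rows.append(
            {
                "locus": i,
                "T_on": f_on * DT,
                "T_off": (f_on + nf) * DT,
                "dwell": nf * DT,
                "censored": False,
            }
        )
    return traces, pd.DataFrame(rows)


class TestPostsynchronize:
    def test_identical_steps_align(self):
        traces, events = make_traces_and_events([20, 50, 90], [5, 5, 5])
        hm = postsynchronize(traces, events, DT, anchor="on")
        assert hm.data.shape[0] == 3
        assert np.all(hm.data[0] == hm.data[1])
        assert np.all(hm.data[1] == hm.data[2])
        # frame immediately before binding sits at the anchor column
        assert hm.data[0, hm.anchor_col] == 0.0
        assert hm.data[0, hm.anchor_col + 1] == 1000.0

    def test_off_anchor_occupancy_ends_at_zero(self):
        traces, events = make_traces_and_events([20, 60], [6, 9])
        hm = postsynchronize(traces, events, DT, anchor="off")
        # anchor column = last occupied frame; later columns empty
        assert np.all(hm.data[:, hm.anchor_col] == 1000.0)
        assert np.all(hm.data[:, hm.anchor_col + 1 :] == 0.0)

    def test_min_dwell_filter(self):
        traces, events = make_traces_and_events([20, 60, 100], [1, 2, 10])
        hm = postsynchronize(traces, events, DT, anchor="on", min_dwell=0.8)
        assert hm.n_events == 2
        assert hm.event_index.tolist() == [1, 2]

    def test_no_qualifying_events(self):
        traces, events = make_traces_and_events([20], [1])
        with pytest.raises(ValueError, match="dwell >="):
            postsynchronize(traces, events, DT, anchor="on", min_dwell=0.8)

    def test_bad_anchor(self):
        traces, events = make_traces_and_events([20], [5])
        with pytest.raises(ValueError):
            postsynchronize(traces, events, DT, anchor="sideways")

    def test_padding_outside_acquisition(self):
        traces, events = make_traces_and_events([1], [5], n_frames=30)
        hm = postsynchronize(traces, events, DT, anchor="on", pre_frames=5)
        assert np.all(hm.data[0, :5] == 0.0)  # before the movie started

    def test_partner_channel_reuses_anchors(self):
        traces, events = make_traces_and_events([20, 50], [6, 6])
        partner = np.roll(traces, 2, axis=1)  # probe rises two frames later
        hm_r = postsynchronize(traces, events, DT, anchor="on")
        hm_p = postsynchronize(partner, events, DT, anchor="on")
        assert hm_p.data.shape == hm_r.data.shape
        first_r = np.argmax(hm_r.data[0] > 0)
        first_p = np.argmax(hm_p.data[0] > 0)
        assert first_p - first_r == 2

    def test_times_axis(self):
        traces, events = make_traces_and_events([20], [5])
        hm = postsynchronize(traces, events, DT, anchor="on", pre_frames=5)
        t = hm.times()
        assert t[hm.anchor_col] == 0.0
        assert t[hm.anchor_col + 1] == pytest.approx(DT)


class TestAveragedProfile:
    def test_identical_rows(self):
        traces, events = make_traces_and_events([20, 50], [5, 5])
        hm = postsynchronize(traces, events, DT, anchor="on")
        prof = averaged_profile(hm)
        assert prof.max() == 1.0
        assert np.array_equal(prof, hm.data[0] / hm.data[0].max())

    def test_all_zero_error(self):
        hm = HeatMap(np.zeros((3, 10)), "on", 5, DT, 0.8, np.arange(3))
        with pytest.raises(ValueError):
            averaged_profile(hm)


def sigmoid_profile(n, midpoint, width=1.5):
    x = np.arange(n, dtype=float)
    return 1.0 / (1.0 + np.exp(-(x - midpoint) / width))


class TestEdgeTime:
    def test_step_edge_bracketed(self):
        prof = np.concatenate([np.zeros(10), np.ones(10)])
        e = edge_time(prof, DT)
        assert 9 * DT <= e <= 10 * DT

    def test_translation_equivariance(self):
        base = sigmoid_profile(60, 20.0)
        shifted = sigmoid_profile(60, 27.0)
        assert edge_time(shifted, DT) - edge_time(base, DT) == pytest.approx(
            7 * DT, abs=1e-6
        )

    @pytest.mark.parametrize("snr", [5, 10, 20])
    def test_sigmoid_bias_under_noise(self, snr, rng):
        """Mean edge error < 0.25 frame across noise realizations."""
        errs = []
        for _ in range(300):
            prof = sigmoid_profile(60, 25.3) + rng.normal(0, 1.0 / snr, 60)
            errs.append(edge_time(prof, 1.0) - 25.3)
        assert abs(np.mean(errs)) < 0.25

    def test_falling_edge(self):
        prof = 1.0 - sigmoid_profile(60, 30.0)
        e = edge_time(prof, DT, falling=True)
        assert e == pytest.approx(30.0 * DT, abs=0.5 * DT)

    def test_flat_profile_error(self):
        with pytest.raises(ValueError):
            edge_time(np.ones(20), DT)


class TestDeltaT:
    def test_identity_and_sign(self):
        d = delta_t(2.0, 1.2)
        assert d.delta_t == pytest.approx(0.8)
        assert delta_t(1.0, 1.0).delta_t == 0.0

    def test_from_events_exact(self):
        early = pd.DataFrame(
            {"locus": [0, 1], "T_on": [10.0, 20.0], "T_off": [14.0, 24.0]}
        )
        late = pd.DataFrame(
            {"locus": [0, 1], "T_on": [10.8, 20.4], "T_off": [14.0, 24.0]}
        )
        est = delta_t_from_events(early, late)
        assert est.delta_t == pytest.approx(0.6)
        assert est.uncertainty == pytest.approx(
            np.std([0.8, 0.4], ddof=1) / np.sqrt(2)
        )

    def test_from_events_window(self):
        early = pd.DataFrame({"locus": [0], "T_on": [10.0], "T_off": [14.0]})
        late = pd.DataFrame({"locus": [0], "T_on": [20.0], "T_off": [24.0]})
        with pytest.raises(ValueError, match="no paired events"):
            delta_t_from_events(early, late)

    def test_from_events_ignores_other_loci(self):
        early = pd.DataFrame({"locus": [0], "T_on": [10.0], "T_off": [14.0]})
        late = pd.DataFrame({"locus": [5], "T_on": [10.5], "T_off": [14.0]})
        with pytest.raises(ValueError):
            delta_t_from_events(early, late)


class TestSnapshot:
    def test_column_selection(self):
        data = np.tile(np.arange(10.0), (4, 1))
        hm = HeatMap(data, "off", 5, DT, 0.8, np.arange(4))
        assert np.all(intensity_snapshot(hm, 0) == 5.0)
        assert np.all(intensity_snapshot(hm, -2) == 3.0)
        assert intensity_snapshot(hm, 1).shape == (4,)

    def test_out_of_range(self):
        hm = HeatMap(np.zeros((2, 10)), "off", 5, DT, 0.8, np.arange(2))
        with pytest.raises(ValueError):
            intensity_snapshot(hm, 7)


class TestTwoGaussian:
    def test_planted_81_19(self, rng):
        n = 500
        hi = rng.normal(1000, 60, int(n * 0.81))
        lo = rng.normal(0, 60, n - int(n * 0.81))
        f, fit = two_gaussian_fraction(np.concatenate([hi, lo]))
        assert f == pytest.approx(0.81, abs=0.03)
        assert not fit.flags

    def test_all_high(self, rng):
        f, fit = two_gaussian_fraction(rng.normal(1000, 30, 300))
        assert f == pytest.approx(1.0)
        assert fit.flags

    def test_all_baseline(self, rng):
        f, fit = two_gaussian_fraction(rng.normal(0, 30, 300))
        assert f == pytest.approx(0.0)
        assert fit.flags

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            two_gaussian_fraction(np.arange(10.0))


class TestEstimators:
    def make_heatmap(self, rng, n=600, eff=0.8, ret=0.3):
        """Synthetic off-anchored map: probe-present rows high through the
        anchor; a 'ret' fraction of those stays high one extra column."""
        width, anchor = 12, 8
        data = rng.normal(0, 30, (n, width))
        n_hi = int(n * eff)
        data[:n_hi, : anchor + 1] += 1000.0
        n_ret = int(n_hi * ret)
        data[:n_ret, anchor + 1 : anchor + 3] += 1000.0
        return HeatMap(data, "off", anchor, DT, 0.8, np.arange(n))

    def test_detection_efficiency(self, rng):
        hm = self.make_heatmap(rng, eff=0.8)
        f, _ = detection_efficiency(hm)
        assert f == pytest.approx(0.8, abs=0.03)

    def test_retention_fraction(self, rng):
        hm = self.make_heatmap(rng, eff=0.8, ret=0.3)
        f, details = retention_fraction(hm)
        assert f == pytest.approx(0.3, abs=0.03)
        assert details["n_reference"] > 0

    def test_anchor_validation(self, rng):
        hm = HeatMap(rng.normal(0, 1, (60, 10)), "on", 5, DT, 0.8, np.arange(60))
        with pytest.raises(ValueError):
            detection_efficiency(hm)
        with pytest.raises(ValueError):
            retention_fraction(hm)

    def test_post_offset_validation(self, rng):
        hm = self.make_heatmap(rng)
        with pytest.raises(ValueError):
            retention_fraction(hm, post_offset=0)
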