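"""Unit and property tests for the forward simulator."""

import numpy as np
import pytest
from scipy import stats

from fastfish.simulate import (
    GroundTruth,
    SimulationParams,
    TranscriptionEvent,
    render_movie,
    render_traces,
    simulate_field,
    simulate_hybridization_assay,
    simulate_transcription_cycle,
)


def productive_dwell_mean(p: SimulationParams) -> float:
    return (
        1.0 / p.k_escape
        + (p.template_length - p.escape_position) / p.v_elong
        + p.end_dwell_mean
    )


def productive_dwell_sd(p: SimulationParams) -> float:
    var = (
        1.0 / p.k_escape**2
        + (p.template_length - p.escape_position) / p.v_elong**2
        + p.end_dwell_mean**2
    )
    return float(np.sqrt(var))


class TestParams:
    def test_exposure_position_default(self):
        assert SimulationParams().exposure_position == 60

    def test_hybridization_rate(self):
        p = SimulationParams()
        assert p.hybridization_rate == pytest.approx(6e6 * 500e-9)
        assert 1.0 / p.hybridization_rate == pytest.approx(1 / 3)

    def test_frame_bookkeeping(self):
        p = SimulationParams(frame_rate=2.5, duration=10.0)
        assert p.n_frames == 25
        assert p.frame_interval == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"v_elong": 0.0},
            {"probe_conc": -1.0},
            {"dark_fraction": 1.5},
            {"p_retain": -0.1},
            {"target_window": (28, 290)},  # window + footprint exceeds template
            {"escape_position": 60},  # escape at the exposure position
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)


class TestSingleCycle:
    def test_time_ordering(self, rng):
        p = SimulationParams()
        for _ in range(2000):
            ev = simulate_transcription_cycle(p, rng, t_bind=5.0)
            assert 5.0 <= ev.t_bind <= ev.t_escape <= ev.t_exposure <= ev.t_end
            assert ev.t_end <= ev.t_runoff
            if ev.kind == "productive":
                assert ev.probe_bound == (ev.t_probe_arrival < ev.t_runoff)
                if ev.probe_bound:
                    assert ev.t_probe_release >= ev.t_runoff
                    if ev.retained:
                        assert ev.t_probe_release >= ev.t_runoff + p.retain_min
                    else:
                        assert ev.t_probe_release == ev.t_runoff
            else:
                assert ev.t_escape == ev.t_exposure == ev.t_end == ev.t_runoff
                assert ev.t_probe_arrival is None

    @pytest.mark.parametrize("length", [295, 633, 910])
    def test_productive_dwell_mean(self, length, rng):
        p = SimulationParams(template_length=length)
        n = 3000
        dwells = np.array(
            [
                simulate_transcription_cycle(p, rng, productive=True).dwell
                for _ in range(n)
            ]
        )
        mu = productive_dwell_mean(p)
        se = productive_dwell_sd(p) / np.sqrt(n)
        assert abs(dwells.mean() - mu) < 4 * se

    def test_nonproductive_dwell_exponential(self, rng):
        p = SimulationParams()
        d = np.array(
            [
                simulate_transcription_cycle(p, rng, productive=False).dwell
                for _ in range(2000)
            ]
        )
        assert abs(d.mean() - p.T0_mean) < 4 * p.T0_mean / np.sqrt(d.size)
        ks = stats.kstest(d, "expon", args=(0, p.T0_mean))
        assert ks.pvalue > 0.01

    def test_probe_arrival_exponential(self, rng):
        p = SimulationParams()
        delays = np.array(
            [
                ev.t_probe_arrival - ev.t_exposure
                for ev in (
                    simulate_transcription_cycle(p, rng, productive=True)
                    for _ in range(2000)
                )
            ]
        )
        ks = stats.kstest(delays, "expon", args=(0, 1.0 / p.hybridization_rate))
        assert ks.pvalue > 0.01

    def test_latent_probe_delay_mean(self, rng):
        """Mean probe-arrival delay after polymerase binding = escape +
        elongation to exposure + hybridization wait = 0.2 + 47/300 + 1/3 s."""
        p = SimulationParams()
        lat = np.array(
            [
                ev.t_probe_arrival - ev.t_bind
                for ev in (
                    simulate_transcription_cycle(p, rng, productive=True)
                    for _ in range(4000)
                )
            ]
        )
        expect = 1 / p.k_escape + 47 / 300 + 1 / p.hybridization_rate
        assert expect == pytest.approx(0.690, abs=1e-3)
        sd = np.sqrt((1 / p.k_escape) ** 2 + 47 / 300**2 + (1 / p.hybridization_rate) ** 2)
        assert abs(lat.mean() - expect) < 4 * sd / np.sqrt(lat.size)

    def test_dark_and_retention_bernoulli(self, rng):
        p = SimulationParams()
        evs = [simulate_transcription_cycle(p, rng, productive=True) for _ in range(3000)]
        dark = np.mean([e.probe_dark for e in evs])
        assert abs(dark - p.dark_fraction) < 4 * np.sqrt(0.19 * 0.81 / 3000)
        bound = [e for e in evs if e.probe_bound]
        ret = np.mean([e.retained for e in bound])
        assert abs(ret - p.p_retain) < 4 * np.sqrt(0.28 * 0.72 / len(bound))

    def test_degenerate_fractions(self, rng):
        p_all_dark = SimulationParams(dark_fraction=1.0)
        assert all(
            simulate_transcription_cycle(p_all_dark, rng, productive=True).probe_dark
            for _ in range(50)
        )
        p_no_ret = SimulationParams(p_retain=0.0)
        assert not any(
            simulate_transcription_cycle(p_no_ret, rng, productive=True).retained
            for _ in range(50)
        )


class TestField:
    def test_no_overlap_and_geometry(self):
        p = SimulationParams(n_loci=20, duration=400.0, seed=3)
        truth = simulate_field(p)
        assert truth.loci_xy.shape == (20, 2)
        assert truth.loci_xy.min() >= 5.0
        assert truth.loci_xy.max() <= p.fov_size - 5.0
        d = np.hypot(
            *(truth.loci_xy[:, None, :] - truth.loci_xy[None, :, :]).transpose(2, 0, 1)
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= p.min_locus_separation
        by_locus = {}
        for ev in truth.events:
            by_locus.setdefault(ev.locus_id, []).append(ev)
        for evs in by_locus.values():
            for a, b in zip(evs, evs[1:]):
                assert b.t_bind >= a.t_runoff

    def test_deterministic(self):
        p = SimulationParams(n_loci=5, duration=200.0, seed=11)
        a, b = simulate_field(p), simulate_field(p)
        assert len(a.events) == len(b.events)
        assert all(
            x.t_bind == y.t_bind and x.kind == y.kind
            for x, y in zip(a.events, b.events)
        )
        assert np.array_equal(a.loci_xy, b.loci_xy)

    def test_event_table_columns(self):
        p = SimulationParams(n_loci=5, duration=200.0, seed=11)
        tab = simulate_field(p).event_table()
        for col in ("locus_id", "kind", "t_bind", "t_runoff", "probe_bound", "dwell"):
            assert col in tab.columns
        assert (tab["dwell"] >= 0).all()

    def test_impossible_separation(self):
        with pytest.raises(ValueError, match="minimum separation"):
            simulate_field(SimulationParams(n_loci=500, fov_size=20, duration=1.0))


def _one_event_truth(ev, params):
    return GroundTruth(events=[ev], loci_xy=np.array([[10.0, 10.0]]), params=params)


class TestRenderTraces:
    def make_params(self, **kw):
        kw.setdefault("n_loci", 1)
        kw.setdefault("duration", 20.0)
        kw.setdefault("noise_sd", 0.0)
        kw.setdefault("photobleach_lifetimes", (1e12, 1e12))
        return SimulationParams(**kw)

    def test_full_and_fractional_frames(self):
        p = self.make_params(rise_per_bp=0.0)
        ev = TranscriptionEvent(
            locus_id=0, kind="productive", t_bind=10.0, t_escape=10.2,
            t_exposure=10.4, t_end=11.0, t_runoff=11.2,
            t_probe_arrival=10.6, probe_dark=False, probe_bound=True,
            retained=False, t_probe_release=11.2,
        )
        traces = render_traces(_one_event_truth(ev, p))
        rn, pr = traces.rnap[0], traces.probe[0]
        # polymerase occupies frames [10.0,10.4), [10.4,10.8), [10.8,11.2) fully
        assert rn[25] == pytest.approx(1000.0)
        assert rn[26] == pytest.approx(1000.0)
        assert rn[27] == pytest.approx(1000.0)
        # boundary frames carry at most float-rounding occupancy
        assert abs(rn[24]) < 1e-6 and abs(rn[28]) < 1e-6
        # probe bound 10.6-11.2: half of frame 26, all of frame 27
        assert pr[26] == pytest.approx(500.0)
        assert pr[27] == pytest.approx(1000.0)
        assert pr[25] == 0.0 and pr[28] == 0.0

    def test_subframe_event(self):
        p = self.make_params()
        t_off = 10.0 + 0.2
        ev = TranscriptionEvent(
            locus_id=0, kind="nonproductive", t_bind=10.0, t_escape=t_off,
            t_exposure=t_off, t_end=t_off, t_runoff=t_off,
        )
        traces = render_traces(_one_event_truth(ev, p))
        assert traces.rnap[0, 25] == pytest.approx(1000.0 * 0.5)
        assert traces.rnap[0].sum() == pytest.approx(500.0)
        assert traces.probe[0].sum() == 0.0

    def test_evanescent_attenuation(self):
        p = self.make_params()
        ev = TranscriptionEvent(
            locus_id=0, kind="productive", t_bind=8.0, t_escape=8.0,
            t_exposure=8.4, t_end=12.0, t_runoff=12.0,
        )
        traces = render_traces(_one_event_truth(ev, p))
        rn = traces.rnap[0]
        active = rn[rn > 0]
        # monotone decay while elongating away from the surface
        assert np.all(np.diff(active) < 0)
        floor = 1000.0 * np.exp(-p.template_length * p.rise_per_bp / p.evanescent_decay)
        assert active.min() >= floor * 0.99

    def test_dark_probe_invisible(self):
        p = self.make_params()
        ev = TranscriptionEvent(
            locus_id=0, kind="productive", t_bind=10.0, t_escape=10.2,
            t_exposure=10.4, t_end=11.0, t_runoff=11.2,
            t_probe_arrival=10.6, probe_dark=True, probe_bound=True,
            retained=False, t_probe_release=11.2,
        )
        traces = render_traces(_one_event_truth(ev, p))
        assert traces.probe[0].sum() == 0.0

    def test_photobleach_truncates(self):
        p = self.make_params(photobleach_lifetimes=(1e-9, 1e-9))
        ev = TranscriptionEvent(
            locus_id=0, kind="productive", t_bind=10.0, t_escape=10.2,
            t_exposure=10.4, t_end=11.0, t_runoff=11.2,
            t_probe_arrival=10.6, probe_dark=False, probe_bound=True,
            retained=False, t_probe_release=11.2,
        )
        traces = render_traces(_one_event_truth(ev, p), np.random.default_rng(0))
        assert traces.rnap[0].sum() < 10.0
        assert traces.probe[0].sum() < 10.0

    def test_frame_times(self):
        p = self.make_params(duration=2.0)
        traces = render_traces(GroundTruth([], np.array([[10.0, 10.0]]), p))
        assert traces.frame_times.tolist() == pytest.approx([0.2, 0.6, 1.0, 1.4, 1.8])


class TestRenderMovie:
    def test_flux_conservation(self):
        p = SimulationParams(n_loci=4, duration=60.0, noise_sd=0.0, seed=2)
        truth = simulate_field(p)
        traces = render_traces(truth)
        movie = render_movie(traces, truth.loci_xy)
        npx = p.fov_size**2
        for f in range(0, traces.n_frames, 7):
            injected = traces.rnap[:, f].sum()
            assert movie.rnap[f].sum() - p.background * npx == pytest.approx(
                injected, abs=1e-6 * max(injected, 1.0)
            )

    def test_background_everywhere(self):
        p = SimulationParams(n_loci=1, duration=4.0, noise_sd=0.0, seed=2)
        truth = simulate_field(p)
        truth.events.clear()
        movie = render_movie(render_traces(truth), truth.loci_xy)
        assert np.all(movie.rnap == p.background)
        assert np.all(movie.probe == p.background)


class TestHybridizationAssay:
    def test_mean_and_censoring(self):
        df = simulate_hybridization_assay(6e6, 500e-9, n_targets=4000, duration=2.0, seed=1)
        assert len(df) == 4000
        tau = 1.0 / (6e6 * 500e-9)
        assert df["t_wait"].mean() == pytest.approx(tau, rel=0.1)
        assert (df["censored"] == (df["t_wait"] > 2.0)).all()

    def test_invalid(self):
        with pytest.raises(ValueError):
            simulate_hybridization_assay(0.0, 1e-9, 10, 1.0)
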