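"""Forward simulation of single-molecule transcription-cycle experiments.

The generative model mirrors a two-colour CoSMoS experiment on surface-
tethered linear DNA templates carrying a phage-polymerase promoter:

* polymerase arrivals at each template follow a Poisson process;
* an arrival is either *non-productive* (an exponential promoter dwell with
  mean ``T0_mean``, modelling closed/open complexes that never escape) or
  *productive*: an exponential promoter-escape delay (rate ``k_escape``,
  promoter opening folded in, since opening at ~30 /s is negligible),
  per-nucleotide exponential stepping at mean rate ``v_elong`` from the
  escape position to the template end (so the total elongation time is
  Gamma-distributed — a bell shape skewed to long dwells), and an
  exponential end-of-template dwell before run-off;
* the hybridization target in the nascent RNA becomes available once the
  active site passes the target 3' end plus the ~14-nt RNA footprint hidden
  inside the polymerase; the probe then arrives after an exponential wait
  with rate ``k_on_probe * probe_conc``, provided the complex has not yet
  run off;
* a ``dark_fraction`` of probes carries a non-emitting fluorophore; a
  ``p_retain`` fraction of bound probes persists on the locus for at least
  ``retain_min`` (one frame) after run-off;
* the optical model integrates occupancy over camera frames (sub-frame
  events give fractional amplitudes), attenuates the polymerase channel as
  the enzyme elongates away from the surface down the evanescent field,
  applies exponential photobleaching, renders Gaussian point-spread
  functions on a pixel grid, and adds Gaussian camera noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "TranscriptionEvent",
    "TraceSet",
    "simulate_transcription_cycle",
    "simulate_field",
    "render_traces",
    "render_movie",
    "simulate_hybridization_assay",
]


@dataclass
class SimulationParams:
    """Kinetic, optical and noise parameters of the simulated experiment.

    Times in seconds, rates in 1/s, positions in nucleotides, distances in
    nm, image coordinates in pixels.
    """

    # hybridization
    k_on_probe: float = 6e6          # /M/s, probe-target on rate
    probe_conc: float = 500e-9       # M
    # transcription cycle
    rnap_arrival_rate: float = 0.02  # /s per locus
    p_productive: float = 0.5        # fraction of arrivals that escape
    T0_mean: float = 0.14            # s, non-productive promoter dwell (with NTPs)
    k_escape: float = 5.0            # /s, promoter escape rate
    escape_position: int = 13        # nt, active-site position at escape
    v_elong: float = 300.0           # nt/s, mean elongation rate
    template_length: int = 295       # nt
    target_window: tuple[int, int] = (28, 46)  # nt, probe target in the transcript
    footprint: int = 14              # nt of nascent RNA hidden in the polymerase
    end_dwell_mean: float = 0.5      # s, dwell at the free template end
    # probe photophysics / fate
    dark_fraction: float = 0.19      # non-emitting probe fluorophores
    p_retain: float = 0.28           # probes persisting after run-off
    retain_min: float = 0.4          # s, minimum post-run-off persistence
    retain_dwell_mean: float = 1.0   # s, exponential tail of the persistence
    photobleach_lifetimes: tuple[float, float] = (500.0, 500.0)  # s (rnap, probe)
    # optics / camera
    frame_rate: float = 2.5          # Hz
    psf_sigma: float = 1.0           # px
    pixel_size: float = 200.0        # nm
    evanescent_decay: float = 100.0  # nm, TIRF field decay length
    rise_per_bp: float = 0.34        # nm per transcribed bp away from surface
    rnap_amplitude: float = 1000.0   # camera units per polymerase
    probe_amplitude: float = 1000.0  # camera units per probe
    background: float = 100.0        # camera units per pixel
    noise_sd: float = 0.0            # camera units
    fov_size: int = 48               # px, square field of view
    min_locus_separation: float = 4.0  # px, sparse-surface spot placement
    # experiment
    n_loci: int = 50
    duration: float = 600.0          # s
    seed: int = 0

    def __post_init__(self):
        for name in ("k_on_probe", "probe_conc", "k_escape", "v_elong", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_productive", "dark_fraction", "p_retain"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_window[1] + self.footprint > self.template_length:
            raise ValueError("target window + footprint must fit inside the template")
        if self.escape_position >= self.exposure_position:
            raise ValueError("escape position must precede the exposure position")

    @property
    def exposure_position(self) -> int:
        """Active-site position at which the target becomes hybridizable."""
        return self.target_window[1] + self.footprint

    @property
    def n_frames(self) -> int:
        return int(self.duration * self.frame_rate)

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def hybridization_rate(self) -> float:
        return self.k_on_probe * self.probe_conc


@dataclass
class TranscriptionEvent:
    """Ground-truth schedule of one polymerase-template encounter.

    ``t_probe_arrival`` is the latent hybridization time measured from the
    start of target exposure; ``probe_bound`` additionally requires arrival
    before run-off.  All times are absolute (seconds from acquisition start).
    """

    locus_id: int
    kind: str                      # "nonproductive" | "productive"
    t_bind: float
    t_escape: float
    t_exposure: float
    t_end: float                   # active site reaches the template end
    t_runoff: float                # polymerase departure (includes end dwell)
    t_probe_arrival: float | None = None
    probe_dark: bool = False
    probe_bound: bool = False      # arrived before run-off
    retained: bool = False
    t_probe_release: float | None = None

    @property
    def dwell(self) -> float:
        return self.t_runoff - self.t_bind


def simulate_transcription_cycle(
    params: SimulationParams,
    rng: np.random.Generator,
    locus_id: int = 0,
    t_bind: float = 0.0,
    productive: bool | None = None,
) -> TranscriptionEvent:
    """Draw the event schedule of a single polymerase-template encounter."""
    if productive is None:
        productive = rng.random() < params.p_productive

    if not productive:
        t_off = t_bind + rng.exponential(params.T0_mean)
        return TranscriptionEvent(
            locus_id=locus_id,
            kind="nonproductive",
            t_bind=t_bind,
            t_escape=t_off,
            t_exposure=t_off,
            t_end=t_off,
            t_runoff=t_off,
        )

    t_escape = t_bind + rng.exponential(1.0 / params.k_escape)
    step = 1.0 / params.v_elong
    n_to_exposure = params.exposure_position - params.escape_position
    n_to_end = params.template_length - params.exposure_position
    # per-nucleotide exponential stepping: landmark times are partial Gamma sums
    t_exposure = t_escape + rng.gamma(n_to_exposure, step)
    t_end = t_exposure + (rng.gamma(n_to_end, step) if n_to_end > 0 else 0.0)
    t_runoff = t_end + rng.exponential(params.end_dwell_mean)

    t_probe_arrival = t_exposure + rng.exponential(1.0 / params.hybridization_rate)
    probe_dark = bool(rng.random() < params.dark_fraction)
    probe_bound = t_probe_arrival < t_runoff
    retained = False
    t_probe_release = None
    if probe_bound:
        retained = bool(rng.random() < params.p_retain)
        t_probe_release = t_runoff
        if retained:
            t_probe_release += params.retain_min + rng.exponential(
                params.retain_dwell_mean
            )
    return TranscriptionEvent(
        locus_id=locus_id,
        kind="productive",
        t_bind=t_bind,
        t_escape=t_escape,
        t_exposure=t_exposure,
        t_end=t_end,
        t_runoff=t_runoff,
        t_probe_arrival=t_probe_arrival,
        probe_dark=probe_dark,
        probe_bound=probe_bound,
        retained=retained,
        t_probe_release=t_probe_release,
    )


@dataclass
class GroundTruth:
    """Events plus the field geometry they were rendered on."""

    events: list[TranscriptionEvent]
    loci_xy: np.ndarray  # (n_loci, 2) subpixel positions (x, y)
    params: SimulationParams

    def event_table(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            rows.append(
                {
                    "locus_id": ev.locus_id,
                    "kind": ev.kind,
                    "t_bind": ev.t_bind,
                    "t_escape": ev.t_escape,
                    "t_exposure": ev.t_exposure,
                    "t_end": ev.t_end,
                    "t_runoff": ev.t_runoff,
                    "t_probe_arrival": ev.t_probe_arrival,
                    "probe_dark": ev.probe_dark,
                    "probe_bound": ev.probe_bound,
                    "retained": ev.retained,
                    "t_probe_release": ev.t_probe_release,
                    "dwell": ev.dwell,
                }
            )
        return pd.DataFrame(rows)


def simulate_field(params: SimulationParams) -> GroundTruth:
    """Simulate every locus of a field of view for ``params.duration``.

    Loci are placed at random subpixel positions (with a margin keeping the
    fitting ROI inside the frame); polymerase arrivals per locus follow a
    Poisson process, with overlapping encounters at the same locus merged by
    delaying each arrival to the previous departure.
    """
    if params.n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(params.seed)
    margin = 5.0
    if params.fov_size <= 2 * margin:
        raise ValueError("fov_size too small for the 5 px fitting margin")
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < params.n_loci:
        cand = rng.uniform(margin, params.fov_size - margin, size=2)
        if all(
            np.hypot(*(cand - q)) >= params.min_locus_separation for q in placed
        ):
            placed.append(cand)
        attempts += 1
        if attempts > 10000 * params.n_loci:
            raise ValueError(
                "could not place loci with the requested minimum separation; "
                "reduce n_loci or min_locus_separation, or enlarge fov_size"
            )
    loci = np.array(placed)

    events: list[TranscriptionEvent] = []
    for locus in range(params.n_loci):
        t = 0.0
        while True:
            if params.rnap_arrival_rate <= 0:
                break
            t = t + rng.exponential(1.0 / params.rnap_arrival_rate)
            if t >= params.duration:
                break
            ev = simulate_transcription_cycle(params, rng, locus_id=locus, t_bind=t)
            events.append(ev)
            t = max(t, ev.t_runoff)  # no overlapping occupancy of one locus
    return GroundTruth(events=events, loci_xy=loci, params=params)


@dataclass
class TraceSet:
    """Per-locus, per-channel intensity time series at the frame interval."""

    rnap: np.ndarray    # (n_loci, n_frames)
    probe: np.ndarray   # (n_loci, n_frames)
    frame_times: np.ndarray  # frame centres, s
    params: SimulationParams

    @property
    def n_frames(self) -> int:
        return self.rnap.shape[1]


def _fractional_occupancy(t0: float, t1: float, n_frames: int, dt: float) -> np.ndarray:
    """Fraction of each frame interval covered by [t0, t1)."""
    k0 = max(0, int(t0 // dt))
    k1 = min(n_frames - 1, int(t1 // dt))
    out = np.zeros(n_frames)
    if t1 <= t0 or k0 > k1:
        return out
    k = np.arange(k0, k1 + 1)
    lo = k * dt
    out[k0 : k1 + 1] = np.clip(
        (np.minimum(lo + dt, t1) - np.maximum(lo, t0)) / dt, 0.0, 1.0
    )
    return out


def render_traces(truth: GroundTruth, rng: np.random.Generator | None = None) -> TraceSet:
    """Render ground-truth events into per-locus intensity traces.

    Per frame, intensity is amplitude times the fraction of the frame the
    fluorophore was present and emitting.  The polymerase channel is further
    attenuated by ``exp(-(position_nt * rise_per_bp) / evanescent_decay)``
    with the active-site position interpolated linearly between escape and
    arrival at the template end.  Photobleaching truncates each fluorophore
    after an exponential lifetime starting at its appearance.
    """
    p = truth.params
    if rng is None:
        rng = np.random.default_rng(p.seed + 1)
    nf, dt = p.n_frames, p.frame_interval
    rnap = np.zeros((p.n_loci, nf))
    probe = np.zeros((p.n_loci, nf))
    frame_times = (np.arange(nf) + 0.5) * dt

    life_rnap, life_probe = p.photobleach_lifetimes
    for ev in truth.events:
        bleach_r = ev.t_bind + rng.exponential(life_rnap)
        occ = _fractional_occupancy(ev.t_bind, min(ev.t_runoff, bleach_r), nf, dt)
        if p.rise_per_bp > 0 and ev.kind == "productive":
            pos = np.interp(
                frame_times,
                [ev.t_escape, ev.t_exposure, ev.t_end],
                [p.escape_position, p.exposure_position, p.template_length],
                left=0.0,
                right=float(p.template_length),
            )
            pos[frame_times < ev.t_escape] = 0.0
            atten = np.exp(-(pos * p.rise_per_bp) / p.evanescent_decay)
        else:
            atten = 1.0
        rnap[ev.locus_id] += p.rnap_amplitude * occ * atten

        if ev.probe_bound and not ev.probe_dark:
            bleach_p = ev.t_probe_arrival + rng.exponential(life_probe)
            occ_p = _fractional_occupancy(
                ev.t_probe_arrival, min(ev.t_probe_release, bleach_p), nf, dt
            )
            probe[ev.locus_id] += p.probe_amplitude * occ_p

    if p.noise_sd > 0:
        rnap = rnap + rng.normal(0.0, p.noise_sd, rnap.shape)
        probe = probe + rng.normal(0.0, p.noise_sd, probe.shape)
    return TraceSet(rnap=rnap, probe=probe, frame_times=frame_times, params=p)


@dataclass
class ImageStack:
    """Two-channel rendered movie, frames x height x width."""

    rnap: np.ndarray
    probe: np.ndarray
    loci_xy: np.ndarray
    params: SimulationParams


def _psf_kernel(shape: tuple[int, int], x0: float, y0: float, sigma: float) -> np.ndarray:
    """Unit-flux 2D Gaussian sampled on the pixel grid (pixel centres at ints)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))
    return g / g.sum()


def render_movie(
    traces: TraceSet,
    loci_xy: np.ndarray,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render traces into two-channel image stacks.

    Each emitting locus contributes a 2D Gaussian PSF scaled so that the
    total injected flux per frame equals the trace value (flux conservation
    before background and noise).
    """
    p = traces.params
    if rng is None:
        rng = np.random.default_rng(p.seed + 2)
    nf = traces.n_frames
    shape = (p.fov_size, p.fov_size)
    movies = []
    for channel in (traces.rnap, traces.probe):
        stack = np.full((nf, *shape), float(p.background))
        for locus, (x0, y0) in enumerate(loci_xy):
            kernel = _psf_kernel(shape, x0, y0, p.psf_sigma)
            active = np.nonzero(channel[locus] != 0)[0]
            for f in active:
                stack[f] += channel[locus, f] * kernel
        if p.noise_sd > 0:
            stack += rng.normal(0.0, p.noise_sd, stack.shape)
        movies.append(stack)
    return ImageStack(rnap=movies[0], probe=movies[1], loci_xy=np.asarray(loci_xy), params=p)


def simulate_hybridization_assay(
    k_on: float,
    conc: float,
    n_targets: int,
    duration: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential probe-arrival times at immobilized targets.

    One waiting time per target at rate ``k_on * conc``; arrivals beyond
    *duration* are flagged censored (their ``t_wait`` is the latent value).
    """
    if k_on <= 0 or conc <= 0:
        raise ValueError("k_on and conc must be > 0")
    rng = np.random.default_rng(seed)
    waits = rng.exponential(1.0 / (k_on * conc), size=n_targets)
    return pd.DataFrame(
        {
            "target_id": np.arange(n_targets),
            "t_wait": waits,
            "censored": waits > duration,
        }
    )
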