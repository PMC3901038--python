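"""Event calling and dwell-time distribution fitting.

Binding events are called from background-subtracted traces with a
hysteresis threshold (enter above ``baseline + enter_k * sigma``, leave below
``baseline + exit_k * sigma``), and their dwell times are histogrammed with
the cube-root binning rule ``N_bins = round(cbrt(2 N_events))`` with the
first and last bin centres pinned to the observed minimum and maximum.
Waiting-time histograms are fitted with a single exponential (mean T); dwell
histograms that mix non-productive promoter dwells with full transcription
cycles are fitted with an exponential + Gaussian sum, whose Gaussian mean is
the "peak dwell time" of the productive population.  Waiting times convert
to on-rates via ``k_on = 1 / (T_wait * [probe])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DwellHistogram",
    "FitResult",
    "call_events",
    "dwell_histogram",
    "fit_single_exponential",
    "fit_exp_gauss_mixture",
    "on_rate",
]


@dataclass
class DwellHistogram:
    """Dwell/waiting-time histogram with the cube-root binning rule."""

    bin_centers: np.ndarray
    probabilities: np.ndarray      # sum to 1 before any discard
    bin_width: float
    n_events: int
    n_bins: int
    first_bin_discarded: bool = False

    @property
    def used_centers(self) -> np.ndarray:
        return self.bin_centers[1:] if self.first_bin_discarded else self.bin_centers

    @property
    def used_probabilities(self) -> np.ndarray:
        return self.probabilities[1:] if self.first_bin_discarded else self.probabilities


@dataclass
class FitResult:
    """Parameters, 95% confidence intervals and goodness of a dwell fit."""

    model: str
    params: dict
    ci95: dict
    r_squared: float
    flags: list = field(default_factory=list)


def call_events(
    trace: np.ndarray,
    frame_interval: float = 0.4,
    enter_k: float = 4.0,
    exit_k: float = 2.0,
    min_frames: int = 1,
    max_gap_frames: int = 0,
    locus: int = 0,
    channel: str = "",
) -> pd.DataFrame:
    """Threshold-with-hysteresis event calling on one intensity trace.

    Baseline and noise are estimated robustly (median and scaled MAD) from
    the trace itself, so the trace must be mostly baseline.  Events touching
    the first or last frame are flagged censored.  Returned times are in
    seconds; ``T_on`` is the start time of the first frame above threshold
    and ``T_off`` the start time of the first frame back at baseline.

    ``max_gap_frames`` merges events separated by at most that many
    below-threshold frames into one.  This guards against spurious event
    splitting when a dim signal (e.g. the polymerase channel late in
    elongation, attenuated by the evanescent field) hovers near the exit
    threshold; the default of 0 performs no merging.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    if trace.size < 10:
        raise ValueError("need >= 10 frames to estimate the baseline")
    if enter_k <= exit_k:
        raise ValueError("hysteresis requires enter_k > exit_k")
    baseline = np.median(trace)
    sigma = 1.4826 * np.median(np.abs(trace - baseline))
    if sigma == 0:
        sigma = max(1e-12, 1e-6 * max(abs(trace).max(), 1.0))
    hi = baseline + enter_k * sigma
    lo = baseline + exit_k * sigma

    raw = []
    inside = False
    start = 0
    for i, v in enumerate(trace):
        if not inside and v > hi:
            inside = True
            start = i
        elif inside and v < lo:
            raw.append((start, i))
            inside = False
    if inside:
        raw.append((start, trace.size))

    merged = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= max_gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    rows = [
        (s, e, s == 0 or e == trace.size)
        for s, e in merged
        if e - s >= min_frames
    ]

    return pd.DataFrame(
        {
            "locus": locus,
            "channel": channel,
            "T_on": [r[0] * frame_interval for r in rows],
            "T_off": [r[1] * frame_interval for r in rows],
            "dwell": [(r[1] - r[0]) * frame_interval for r in rows],
            "censored": [r[2] for r in rows],
        }
    ).astype({"T_on": float, "T_off": float, "dwell": float, "censored": bool})


def dwell_histogram(dwells, discard_first: bool = False) -> DwellHistogram:
    """Histogram dwell times with ``N_bins = round(cbrt(2 N))``.

    The first and last bin centres sit at the minimum and maximum observed
    dwell.  ``discard_first`` drops the first bin from fitting (used for
    waiting-time data, where the first bin is distorted by the dead time of
    the buffer exchange).
    """
    d = np.sort(np.asarray(list(dwells), dtype=float))
    if d.size < 2:
        raise ValueError("need at least two dwell values")
    if d[0] == d[-1]:
        raise ValueError("all dwell values identical; histogram undefined")
    n_bins = max(2, int(round(np.cbrt(2 * d.size))))  # fitters need >= 3 usable bins
    width = (d[-1] - d[0]) / (n_bins - 1)
    centers = d[0] + width * np.arange(n_bins)
    edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
    counts, _ = np.histogram(d, bins=edges)
    return DwellHistogram(
        bin_centers=centers,
        probabilities=counts / d.size,
        bin_width=width,
        n_events=int(d.size),
        n_bins=n_bins,
        first_bin_discarded=discard_first,
    )


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_single_exponential(hist: DwellHistogram) -> FitResult:
    """Fit an exponential with mean T to the histogram; returns T with a 95% CI.

    The model is integrated over each bin (the first and last bins are
    effectively half-width because the bin centres are pinned to the observed
    extremes), so T is unbiased with respect to the binning scheme.
    """
    t = hist.used_centers
    p = hist.used_probabilities
    if t.size < 3:
        raise ValueError("need at least 3 usable bins")
    half = hist.bin_width / 2

    def model(t, a, tau):
        lo = np.clip(t - half, 0, None)
        hi = np.clip(t + half, 0, None)
        return a * (np.exp(-lo / tau) - np.exp(-hi / tau))

    tau0 = max(float(np.sum(t * p) / max(np.sum(p), 1e-12)), 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            model, t, p, p0=[1.0, tau0], bounds=([0, 1e-12], [np.inf, np.inf])
        )
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    yhat = model(t, *popt)
    dof = max(t.size - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    errs = np.sqrt(np.diag(pcov))
    return FitResult(
        model="exponential",
        params={"T": float(popt[1]), "amplitude": float(popt[0])},
        ci95={"T": (float(popt[1] - tcrit * errs[1]), float(popt[1] + tcrit * errs[1]))},
        r_squared=_r_squared(p, yhat),
    )


def fit_exp_gauss_mixture(dwells, discard_first: bool = False) -> FitResult:
    """Fit an exponential + Gaussian sum to a dwell-time sample.

    Model density: ``w (1/T0) exp(-t/T0) + (1-w) Normal(t; T1, sigma)``.
    The exponential captures short non-productive promoter dwells; the
    Gaussian's mean T1 is the peak dwell time of full transcription cycles.
    Degenerate fits (w or sigma pinned at a bound) are flagged.
    """
    d = np.asarray(list(dwells), dtype=float)
    if d.size < 50:
        raise ValueError("need at least 50 dwell values for the mixture fit")
    hist = dwell_histogram(d, discard_first=discard_first)
    t = hist.used_centers
    dens = hist.used_probabilities / hist.bin_width
    half = hist.bin_width / 2

    def model(t, w, tau0, mu, sig):
        # expected bin mass / width: exact integral over each bin, so the
        # narrow exponential component is not distorted by coarse bins
        lo_e, hi_e = t - half, t + half
        p_exp = np.exp(-np.clip(lo_e, 0, None) / tau0) - np.exp(
            -np.clip(hi_e, 0, None) / tau0
        )
        p_gauss = stats.norm.cdf(hi_e, mu, sig) - stats.norm.cdf(lo_e, mu, sig)
        return (w * p_exp + (1 - w) * p_gauss) / hist.bin_width

    med = float(np.median(d))
    upper = d[d > med]
    mu0 = float(upper.mean()) if upper.size else med
    sig0 = max(float(upper.std()), hist.bin_width) if upper.size > 1 else hist.bin_width
    tau0 = max(float(d[d <= med].mean()), 1e-3)
    lo = [0.0, 1e-4, t.min(), hist.bin_width / 10]
    hi_b = [1.0, max(10 * med, 1.0), t.max(), t.max()]
    p0 = [0.5, tau0, mu0, sig0]
    p0 = [min(max(v, l), h) for v, l, h in zip(p0, lo, hi_b)]
    try:
        popt, pcov = optimize.curve_fit(model, t, dens, p0=p0, bounds=(lo, hi_b), maxfev=5000)
    except RuntimeError as exc:
        raise RuntimeError(f"mixture fit did not converge: {exc}") from exc
    w, tau, mu, sig = popt
    flags = []
    if w < 1e-3 or w > 1 - 1e-3:
        flags.append("weight at bound")
    if sig <= lo[3] * 1.01:
        flags.append("sigma at bound")
    yhat = model(t, *popt)
    dof = max(t.size - 4, 1)
    tcrit = stats.t.ppf(0.975, dof)
    errs = np.sqrt(np.diag(pcov))
    names = ["w", "T0", "T1", "sigma"]
    return FitResult(
        model="exponential+gaussian",
        params={"w": float(w), "T0": float(tau), "T1": float(mu), "sigma": float(sig)},
        ci95={
            n: (float(v - tcrit * e), float(v + tcrit * e))
            for n, v, e in zip(names, popt, errs)
        },
        r_squared=_r_squared(dens, yhat),
        flags=flags,
    )


def on_rate(t_wait: float, conc: float) -> float:
    """Hybridization on-rate ``k_on = 1 / (T_wait * [probe])`` in /M/s."""
    if t_wait <= 0 or conc <= 0:
        raise ValueError("t_wait and conc must be > 0")
    return 1.0 / (t_wait * conc)
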