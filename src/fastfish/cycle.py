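"""Decomposition of the transcription cycle into rate constants.

Measured quantities — the non-productive dwell T0, the probe-arrival delay
delta T_on, the dwell-vs-template-length regression, and the hybridization
on-rate — combine into the cycle's rates:

* ``k_off = 1 / T0`` (stochastic dissociation of the closed/open complex);
* ``T_abortive = delta T_on - (T_elongation + T_hybridization)`` and
  ``k_escape = 1 / T_abortive`` (net duration of abortive cycling; promoter
  opening at ~30 /s contributes negligibly and is treated as zero);
* the slope of peak dwell vs transcribed length gives the elongation rate
  (nt/s) and its intercept the stationary time ``T_stationary`` the enzyme
  spends on the template without elongating;
* ``T_end = T_stationary - T_abortive`` (idling at the free template end);
* the promoter-search time is bounded above by one frame at the fastest
  acquisition rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CycleGeometry",
    "LengthSeriesFit",
    "KineticSummary",
    "exposure_position",
    "elongation_time",
    "hybridization_time",
    "abortive_time",
    "fit_dwell_vs_length",
    "summarize_cycle",
]


@dataclass
class CycleGeometry:
    """Template geometry of a run-off transcription assay (positions in nt)."""

    escape_position: int = 13
    target_window: tuple[int, int] = (28, 46)
    footprint: int = 14
    template_length: int = 295

    def __post_init__(self):
        if not self.escape_position < self.target_window[1] + self.footprint <= self.template_length:
            raise ValueError("escape < target end + footprint <= template length required")

    @property
    def exposure(self) -> int:
        return exposure_position(self.target_window[1], self.footprint)


@dataclass
class LengthSeriesFit:
    """Least-squares line through (template length, peak dwell) pairs."""

    slope: float          # s/nt
    intercept: float      # s, = T_stationary
    rate: float           # nt/s, = 1/slope
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    r_squared: float


@dataclass
class KineticSummary:
    """The full set of cycle quantities (times s, rates /s, speed nt/s)."""

    T_search_bound: float
    T0: float
    k_off: float
    T_abortive: float
    k_escape: float
    elongation_rate: float
    T_stationary: float
    T_end: float
    delta_t_on: float
    delta_t_off: float
    detection_efficiency: float
    retention_fraction: float
    warnings: tuple = ()


def exposure_position(target_end: int, footprint: int = 14) -> int:
    """Active-site position at which the target leaves the polymerase footprint."""
    return target_end + footprint


def elongation_time(from_pos: float, to_pos: float, rate: float) -> float:
    """Time to elongate from one position to another at *rate* nt/s."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if to_pos < from_pos:
        raise ValueError("to_pos must be >= from_pos")
    return (to_pos - from_pos) / rate


def hybridization_time(k_on: float, conc: float) -> float:
    """Mean probe-arrival time ``1 / (k_on * conc)``."""
    if k_on <= 0 or conc <= 0:
        raise ValueError("k_on and conc must be > 0")
    return 1.0 / (k_on * conc)


def abortive_time(delta_t_on: float, t_elong: float, t_hyb: float) -> float:
    """Net abortive-cycling time ``delta T_on - (T_elongation + T_hybridization)``.

    A negative result (model inconsistency) is returned as-is with a warning
    so that propagated uncertainty stays visible.
    """
    t = delta_t_on - (t_elong + t_hyb)
    if t < 0:
        warnings.warn(
            f"negative abortive time {t:.3g} s: measured delay is shorter than "
            "elongation + hybridization alone",
            stacklevel=2,
        )
    return t


def fit_dwell_vs_length(pairs) -> LengthSeriesFit:
    """Ordinary least squares of peak dwell time against transcribed length."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two (length, dwell) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct lengths")
    res = stats.linregress(x, y)
    dof = max(len(pairs) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof) if len(pairs) > 2 else np.inf
    if res.slope <= 0:
        warnings.warn("non-positive slope: dwell does not grow with length", stacklevel=2)
    return LengthSeriesFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        rate=float(1.0 / res.slope) if res.slope != 0 else float("inf"),
        slope_ci95=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        intercept_ci95=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        r_squared=float(res.rvalue**2),
    )


def summarize_cycle(
    T0: float,
    delta_t_on: float,
    geometry: CycleGeometry,
    rate: float,
    k_on: float,
    conc: float,
    t_stationary: float,
    efficiency: float,
    retention: float,
    frame_interval: float,
    delta_t_off: float = 0.0,
) -> KineticSummary:
    """Assemble the machine-readable kinetic summary of the whole cycle."""
    notes = []
    t_elong = elongation_time(geometry.escape_position, geometry.exposure, rate)
    t_hyb = hybridization_time(k_on, conc)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t_abortive = abortive_time(delta_t_on, t_elong, t_hyb)
        notes.extend(str(w.message) for w in caught)
    k_escape = 1.0 / t_abortive if t_abortive > 0 else float("nan")
    if not np.isfinite(k_escape):
        notes.append("k_escape undefined (non-positive abortive time)")
    t_end = t_stationary - t_abortive
    if t_end < 0:
        notes.append("negative end dwell (T_stationary < T_abortive)")
    return KineticSummary(
        T_search_bound=frame_interval,
        T0=T0,
        k_off=1.0 / T0,
        T_abortive=t_abortive,
        k_escape=k_escape,
        elongation_rate=rate,
        T_stationary=t_stationary,
        T_end=t_end,
        delta_t_on=delta_t_on,
        delta_t_off=delta_t_off,
        detection_efficiency=efficiency,
        retention_fraction=retention,
        warnings=tuple(notes),
    )
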