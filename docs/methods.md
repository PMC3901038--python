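# Methods

This document describes the models, estimators, numerical choices and known
limitations of the package. Every number quoted here was computed with the
code in this repository (the seeded examples and tests reproduce them).

## 1. Sequence design

**Alphabets.** Targets are RNA 19-mers over {A, U, C}; probes are their DNA
reverse complements over {A, T, G}. Excluding G from the target (and hence C
from the probe) removes stable Watson–Crick G–C self-pairing from both
strands, which is the design's route to fast hybridization.

**Composition filter.** GC fraction within [0.4, 0.6] inclusive; for a
19-mer over {A, U, C} this admits C counts 8–11 (a 27.2% yield over uniform
draws; the four-letter control retains 64.1%).

**Complexity filter.** LZ76 complexity — the number of components in the
Lempel–Ziv exhaustive parse — is used as a non-redundancy score
(`complexity_min = 9` by default). The parser allows self-overlapping
reproductions and counts a final non-exhaustive component as one component.
Calibration: a 19-character string of distinct symbols parses into 19
components; a 19-fold single-character repeat into 2. The implementation is
verified exhaustively against an independent oracle for all binary strings
of length ≤ 12 and property-tested on larger alphabets.

**Structure proxy.** A Nussinov dynamic program (Watson–Crick + G·U wobble,
minimum hairpin loop 3) counts the maximum number of nested self-pairs. It
is a propensity score used for ranking and context warnings, not a
thermodynamic model; externally computed folding energies can be supplied
and are then used for filtering and ranking.

**Known deviation.** With the faithful filter above, the mean LZ76
complexity of retained three-letter 19-mers is 7.99 ± 0.85 and the fraction
with complexity ≥ 9 is 27.5% (n > 50,000, seeded; `scripts/acceptance.py`).
The reference values for this construction are 8.1 ± 0.8 and ≈31%, derived
from a sample that retained only ~18.8% of draws where the stated filter
retains 27.2%; the additional attrition step is unspecified, and per-C-count
means (8.13 at C=8 down to 7.48 at C=11) show the removed sequences were
biased low-complexity. The four-letter mean reproduces (9.37 vs 9.3), as
does the four-letter retention (0.641 vs 0.637). The corresponding
acceptance test asserts the reference bands and therefore fails on the
three-letter mean and fraction; the deviation is stated in its docstring
rather than the tolerance being widened.

## 2. Transcription-cycle model

One polymerase–template encounter is either:

* **non-productive** — dwell ~ Exponential(T0_mean = 0.14 s); or
* **productive** — promoter escape ~ Exponential(1/k_escape = 0.2 s) at
  position +13, then per-nucleotide exponential stepping at 300 nt/s (the
  total elongation time is Gamma-distributed, giving the right-skewed
  bell-shaped dwell population), then an end dwell ~ Exponential(0.5 s)
  before run-off.

The probe target (window 28–46) leaves the polymerase footprint (14 nt) when
the active site reaches +60; probe arrival is exponential at
k_on × [probe] = 6×10⁶ × 5×10⁻⁷ = 3 /s after exposure, suppressed for a
dark fraction (0.19) of probes. After run-off a fraction p_retain (0.28) of
bound probes persists for 0.4 s plus an exponential tail (mean 1.0 s); the
0.4 s floor makes "retained" operationally equal to "visible one frame after
run-off" at the 2.5 Hz acquisition rate.

Under these defaults the latent probe delay after polymerase binding is
ΔT_on = 0.2 + 47/300 + 1/3 = 0.690 s, and mean productive dwells are
1.64 / 2.77 / 3.69 s for 295 / 633 / 910-nt templates.

**Rendering.** Traces integrate occupancy over 0.4 s frames (timestamps at
frame centers); polymerase intensity is attenuated by the evanescent field
as exp(−position × 0.34 nm/nt ÷ 100 nm) as the active site moves away from
the surface-tethered end. Movies place each locus as a 2D Gaussian PSF
(σ = 1 px) with flux conservation, constant background, and additive
Gaussian camera noise (EMCCD gain statistics are out of scope). Loci are
dart-thrown with a minimum separation (4 px default): without it ~10% of
uniformly placed loci fall within one PSF width of a neighbour, are
physically unresolvable, and corrupt ring-background trace extraction.

## 3. Localization and traces

Spot detection: Gaussian smoothing, robust threshold (median + k × scaled
MAD), local-maximum suppression; each detection is refined by a 5×5-pixel 2D
Gaussian fit (subpixel x, y). Per-frame localizations are clustered into
loci on a 1-px grid with 8-connected labelling. Co-localization offsets
between channels feed a 2D histogram whose central peak selects active loci
(2σ radial cut; for Rayleigh-distributed true offsets this retains
exp(−2) ≈ 86.5% of actives, which the selection tests assert). Traces are
the mean of the inner ROI minus the mean of its perimeter ring.

Measured precision: localization RMSE < 0.1 px with |bias| < 0.02 px at peak
SNR 10 (seeded property test, 400 trials).

## 4. Event calling and dwell fitting

Events are called with a hysteresis threshold (enter at baseline + 4σ, exit
at baseline + 2σ, robust baseline/σ from the trace itself); events touching
the movie boundary are flagged censored. `max_gap_frames` optionally merges
events separated by at most that many below-threshold frames — used on long
templates where the attenuated polymerase signal hovers near the exit
threshold (the 633-nt template renders at ~12% of initial amplitude near
run-off).

**Qualifying-dwell choice for run-off-anchored analyses.** A non-productive
dwell (mean 0.14 s) that straddles a frame boundary illuminates two partial
frames and is called with a dwell of exactly 2 frames = 0.8 s. A 0.8 s
minimum therefore passes ~19% wrong run-off anchors; run-off-anchored
analyses in this package use min_dwell = 1.2 s (3 frames), which removes
them while leaving productive dwells (≥ ~2 s on the 633-nt template)
untouched. The API default remains 0.8 s.

**Histograms and fits.** Dwell histograms use the cube-root rule
N_bins = round(∛(2N)) with the first and last bin centers pinned to the
observed extremes — which makes the extreme bins effectively half-width.
All histogram fits therefore integrate the model over each bin (differences
of the CDF, clipped at zero) rather than evaluating point densities; with
point densities the pinned-center scheme biases a fitted exponential mean by
tens of percent, with bin integration the fit agrees with the
maximum-likelihood estimator (the sample mean) within sampling error.
Waiting-time histograms fit a single exponential; dwell histograms that mix
non-productive and productive populations fit an exponential + Gaussian sum
whose Gaussian mean is the "peak dwell time". On-rates convert as
k_on = 1/(T_wait × [probe]).

## 5. Post-synchronized analysis

Events are aligned at binding ("on") or dissociation ("off") and stacked
into heat maps; the column average is the weight-averaged occupancy profile.

**Edges.** The edge of a profile is the maximum of its first derivative
refined by a parabola vertex. The derivative is smoothed with a symmetric
Gaussian kernel (σ = 2 samples) and the extremum search is confined to ±5
samples around the half-maximum crossing within the 20–80% transition band;
this keeps plateau noise from relocating the edge (mean error ≤ 0.05 frame
at SNR 5–20 on analytic sigmoids; noiseless error 0.02 frame) without
biasing it, since symmetric smoothing preserves the peak position of the
symmetric derivative of a monotone edge.

**Mode-vs-mean bias.** The profile edge tracks the *mode* of the underlying
transition-time distribution. With the exponential escape step in the model,
the delay distribution is strongly skewed: its mode (~0.4 s) sits well below
its mean (0.69 s), so the edge method alone cannot recover the mean delay.
The package therefore also provides a per-event estimator
(`delta_t_from_events`) that pairs each polymerase binding with the first
subsequent probe onset at the same locus and averages the onset differences;
it is unbiased for the mean (end-to-end: 0.69 ± 0.02 s recovered vs 0.690 s
latent). Both are exposed; the edge method remains the right tool for
sharply peaked delays.

**Detection efficiency.** Probe intensity is sampled at a fixed offset from
the run-off anchor and decomposed into two Gaussian populations
(probe present / absent); the high-component fraction is the efficiency.
The snapshot is taken at offset −1 — the last frame guaranteed fully
occupied — because the run-off frame itself (offset 0) is fractionally
occupied for roughly half the events once the attenuated polymerase signal
is near threshold, and the intermediate intensities destabilize the
decomposition. Validated against planted dark fractions {0.1, 0.19, 0.3}:
maximum error 2.4 points. The 633-nt template is used for this measurement:
its ~2.4 s exposure-to-run-off window makes kinetic misses (probe arriving
after run-off) negligible, whereas on the 295-nt template such misses are
common and observationally identical to dark probes.

**Retention.** Retention is the fraction of probe-present events still
present one frame after polymerase dissociation. Because the dim attenuated
polymerase channel crosses its exit threshold up to one frame before the
much brighter probe channel, the column at called-anchor +1 still contains
pre-run-off signal for events whose run-off falls early in the frame;
offset +2 is the first guaranteed post-run-off column. The estimator counts
events above 0.5 × the fitted probe amplitude at offset −1 (the reference
population) and above 0.25 × amplitude at offset +2 (the lower threshold
compensates partial frame coverage by retained probes), and reports the
ratio. Validated against planted retention {0.15, 0.28, 0.40}: maximum
error 2.3 points.

**Two-Gaussian decomposition.** The intensity histogram is fitted with a
two-Gaussian sum initialized from a 2-means split, with the component means
kept ordered. A unimodality pre-check guards the degenerate case: a 2-means
split of a single normal population yields halves separated by ~1.6 sd with
half-sds of ~0.6 sd (ratio ~1.3), so when the split separation is below
1.5 × the summed half-sds the sample is declared single-population and the
fraction is decided against the physical zero of the background-subtracted
intensity scale, with a flag.

## 6. Cycle decomposition

Worked arithmetic from the measured quantities:

* T_hybridization = 1/(k_on × [probe]) = 1/(6×10⁶ × 5×10⁻⁷) = 0.33 s;
* T_elongation (escape → exposure) = (60 − 13)/300 = 0.16 s;
* T_abortive = ΔT_on − (T_elongation + T_hybridization) ≈ 0.2 s, so
  k_escape ≈ 5 /s (promoter opening is treated as instantaneous);
* the peak-dwell vs template-length line has slope 1/v (3.24×10⁻³ s/nt on
  the measured triple, i.e. ~309 nt/s) and intercept T_stationary ≈ 0.71 s;
  T_end = T_stationary − T_abortive ≈ 0.5 s;
* T_search is reported only as an upper bound of one frame interval at the
  fastest acquisition rate.

Negative derived times (model inconsistencies) are returned with warnings,
never clamped, so propagated uncertainty stays visible.

## 7. Parameters (defaults)

| parameter | default | role |
|---|---|---|
| k_on_probe | 6×10⁶ /M/s | probe hybridization on-rate |
| probe_conc | 500 nM | probe concentration |
| T0_mean | 0.14 s | non-productive dwell (with NTPs) |
| k_escape | 5 /s | promoter escape rate |
| escape_position | +13 nt | escape site |
| v_elong | 300 nt/s | elongation rate |
| target_window | 28–46 nt | probe target on the transcript |
| footprint | 14 nt | nascent RNA protected by the polymerase |
| end_dwell_mean | 0.5 s | idle time at the template end |
| dark_fraction | 0.19 | non-fluorescent probes |
| p_retain | 0.28 | post-run-off probe retention |
| retain_min / retain_dwell_mean | 0.4 s / 1.0 s | retained-probe dwell |
| frame_rate | 2.5 Hz | acquisition (12.5 Hz for search-time bounds) |
| psf_sigma / pixel | 1 px / 200 nm | optics |
| evanescent decay / rise | 100 nm / 0.34 nm/nt | attenuation model |

## 8. Limitations

* Elongation is memoryless per nucleotide; pausing/backtracking at the
  template end is folded into a single exponential end dwell.
* The camera model is additive Gaussian noise; EMCCD excess noise is not
  modeled.
* The retention mechanism is phenomenological (Bernoulli + floor +
  exponential); its dwell-time tail beyond the 0.4 s floor is a free
  parameter.
* The probe-design structure check is a pairing count, not a free-energy
  model; supply external folding energies for thermodynamic filtering.
* Dwell measurements on long templates require SNR sufficient for the
  attenuated polymerase signal to clear the event-calling exit threshold
  (see `examples/03_transcription_dwell_analysis.py`); otherwise called
  dwells are truncated and the elongation slope is biased low.
* The mixing fraction of non-productive vs productive encounters
  (p_productive = 0.5) and the per-locus polymerase arrival rate (0.02 /s)
  are plausible defaults, not measured values.
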