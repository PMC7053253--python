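# Methods

## The physical model

A coated microbubble in a liquid responds to an acoustic drive with radial
oscillations governed by the classical Rayleigh–Plesset equation with an
adiabatic gas interior and viscous damping:

    R R̈ + (3/2) Ṙ² = (1/ρ) [ (p₀ + 2σ/R₀)(R₀/R)^{3γ}
                               − 2σ/R − 4μṘ/R − p₀ − (p_pp/2) sin(2πft) ]

The shell is summarised by a single constant *effective* surface tension σ:
0.07 N/m describes an elastic, clean-interface state, 0 N/m a buckled lipid
monolayer. This is a deliberately reduced description — σ is held constant
through each simulation rather than varying with radius as in
Marmottant-type shell laws, so the parametric study over σ spans the shell
states without modelling the transition dynamics.

Raising the ambient (hydrostatic) pressure compresses the bubble under gas
conservation (isothermal equilibrium between insonations):

    R₀³ (p₀ + 2σ/R₀) = C_ref,   C_ref = R_ref³ (p_ref + 2σ_ref/R_ref)

solved as the unique positive root of the cubic (Brent bracketing,
relative residual ≤ 1e−10). C_ref is computed once from the reference
state (R_ref = 2 µm, the reference σ, p_ref = 1 atm) and reused at every
(p, σ) grid cell: gas content is conserved across the buckling study.

Hydrostatic pressures are **gauge** (0 mmHg = ambient); absolute pressure
is 101 325 Pa + gauge. The amplitude prediction

    A = 27 + 20 log₁₀( (ΔR₀/ΔR_ref) · (p_ref/p₀) )   [dB]

uses absolute p₀ (gauge pressure would be singular at 0 mmHg). ΔR_ref is
the oscillation amplitude at the reference cell (0 mmHg, σ = 0.07), making
that cell exactly 27 dB.

### Numerical choices

* Integrator: LSODA (stiff-capable, adaptive), rtol 1e−8, absolute
  tolerances scaled to the bubble (1e−10·R₀ on R, 1e−10·R₀·ω on Ṙ) so the
  picometre-scale near-linear regime remains resolved; output resampled on
  a uniform grid of 200 samples per drive cycle via dense output.
* Transient handling: the first 50% of the simulated cycles (default 100
  of 200) is discarded; the oscillation amplitude is half the peak-to-peak
  radius excursion over the remaining steady window. An alternative metric
  — the f/2 Fourier line of R(t) — is available via
  `oscillation_amplitude(..., method="subharmonic_line")`; the excursion
  metric is the default because the dB prediction consumes a single ΔR₀
  scalar.
* Collapse guard: integration terminates with a `BubbleCollapseError`
  (carrying the failure time) if R falls below 2% of R₀ — the
  inertial-collapse regime where the adiabatic no-shell model stops being
  meaningful.
* Unstated constants chosen as: γ = 1.4 (adiabatic air), ρ = 998 kg/m³,
  μ = 1.0e−3 Pa·s (water at ≈21 °C), c = 1482 m/s. All configurable.

### Drive frequency for the parametric study

The experimental transmit frequencies are 1.7–7 MHz, but the drive used for
the (pressure × σ) parametric study is a free modelling choice. Linearised
analysis locates the resonances of the 2-µm bubble at ≈2.0 MHz (σ = 0.07)
and ≈1.4 MHz (σ = 0, after equilibrium regrowth). Only *below* both
resonances — the stiffness-controlled regime — do the two qualitative
behaviours of interest hold together: oscillation amplitude decreasing
with hydrostatic pressure at σ = 0.07, and increasing as the shell buckles
(σ → 0) at ambient pressure. Above resonance the pressure ordering
inverts (a stiffer, compressed bubble moves toward resonance). The
parametric study therefore defaults to a 0.5-MHz drive at 150 kPa
peak-to-peak. At that drive the σ-dependence is not globally monotone: a
nonlinear resonance crossing produces an amplitude bump near
σ ≈ 0.02–0.03, so the buckling trend is stated (and tested) at the coarse
sampling σ ∈ {0, 0.035, 0.07}.

## The synthetic RF generator

The generator emulates the statistical structure of the phantom protocol,
not the acoustics of the instrument. Each dataset (one pressure × output ×
replicate acquisition) holds 3 frames × 64 lines × 1536 samples at
fs = 50 MHz, f0 = 4 MHz by default (12 transmit cycles; the per-frequency
cycle table 5/7/10/12/16 at 1.7/2.1/3/4/5–7 MHz is encoded).

* **Subharmonic**: one f0/2 tone burst per line with constant envelope
  10^(sha/20) covering the ROI plus one pulse length of margin; its phase
  is drawn once per pulse-inversion pair and shared across the pair — a
  period-doubled component has no fixed phase relation to the transmit
  polarity, so it survives PI summation.
* **Ground truth** `sha(p, a)`: a three-segment piecewise-linear curve in
  log₁₀(output) (occurrence floor −45 dB below 50 kPa, growth to −15 dB at
  250 kPa, saturation above) plus a pressure response g(p) with g(0) = 0,
  +0.15 dB/mmHg on [0, 75], flat on [75, 125], −0.16 dB/mmHg on
  [125, 200]. The growth slope follows from continuity (≈42.9 dB/decade).
* **Fundamental**: 50 scatterers per PI pair at uniform random depths in
  the ROI band, each a rectangular f0 tone burst whose sign follows the
  transmit polarity; PI summation cancels them exactly. Amplitudes scale
  linearly with the drive. No speckle-correlation model is attempted —
  adequate for amplitude statistics, not for texture realism.
* **Noise**: `noise_sigma` (default 0.3 dB) is a per-acquisition normal
  draw added to the subharmonic level in dB — the replicate-to-replicate
  amplitude jitter of a stirred bubble population; `floor_sigma` (default
  1e−4 full scale) is additive white sample noise. A per-sample noise
  alone cannot produce a ±0.3-dB fluctuation of the ROI-mean amplitude
  (it only biases it upward), hence the two separate knobs.
* **Output map**: the instrument's "% maximum acoustic output" → kPa map
  is synthetic: log-affine with 3.5% → 30 kPa and 100% → 330 kPa, covering
  the 50–250-kPa growth window.
* **Determinism**: every acquisition derives its RNG from
  `SeedSequence([master_seed, p·1000, a·1000, replicate, salt])`;
  identical tuples give bit-identical arrays, replicates differ.
* **Hysteresis**: the post-exposure arm applies an offset profile to the
  truth — zero for exposures < 150 mmHg, else a Gaussian dip on the
  log-output axis reaching −3.2 dB at 181 kPa. The default hysteresis
  output grid (20 log-spaced points over 30–330 kPa) snaps its nearest
  point onto 181 kPa: the maximal-decrease output is by construction one
  of the measured levels.

What passing tests on this generator demonstrate: the extraction and
analysis stages are unbiased and correctly calibrated on signals with the
assumed structure. What they do not demonstrate: robustness to real-scanner
effects (beamforming, diffraction, nonlinear propagation, clutter, bubble
motion between PI transmissions), which the generator deliberately omits.

## Extraction

Pulse-inversion pairs are combined as the *average* of the (+, −) lines:
linear scattering cancels while the subharmonic keeps its single-line
amplitude (a raw sum would add 6 dB). The subharmonic band is isolated by
a 201-tap linear-phase FIR (Hamming/firwin) over f0/2 ± 20% of f0/2,
applied forward–backward (zero phase; stopband doubled, ≥ 80 dB at f0).
The design is verified at the fundamental and at half the centre
frequency, leaving a transition band of half a passband width — a 40-dB
single-pass spec cannot be met *at* the passband edges with 201 taps at
50 MHz, so stopband verification points sit one transition band out.
Envelope = analytic-signal magnitude; the measurement is
20·log₁₀(mean envelope) pooled over ROI samples × lines × frames
(dB-of-mean; `averaging="db"` switches to mean-of-dB for sensitivity
analysis — by Jensen's inequality it is never larger). The dB reference is
1.0 in container units; the pipeline only consumes dB differences, so the
reference cancels.

## Analysis

* **Pressure sensitivity**: ordinary least squares of amplitude on
  pressure within [0, 75] or [125, 200] mmHg; slope, intercept, r²,
  two-sided t-test p-value, mean |residual|. A flat response returns
  slope 0, r² 0, p 1. The operating point is the output with the largest
  |slope| among fits with p < 0.05, ties broken toward lower output
  (lower mechanical index is clinically preferable); with no significant
  fit the best slope is returned flagged non-significant.
* **Growth-phase segmentation**: continuous three-segment piecewise-linear
  least squares in log₁₀(kPa), breakpoints restricted to data abscissae
  (exhaustive pair search — deterministic and adequate at 20–40 outputs),
  subject to the middle segment being strictly steepest; a monotone line
  raises "no growth phase detected". The fit is invariant to dB offsets
  and equivariant under rescaling of the kPa axis.
* **Crossover QC**: two replicate curves pass iff their difference changes
  sign inside the growth window; a one-sided pair triggers the
  third-replicate recommendation. Identifying *which* run of three is
  erroneous is left to the user (the protocol's criterion is qualitative);
  the report only recommends.
* **Hysteresis**: per-output baseline − post differences; the maximum and
  its output (ties toward lower output) are reported, with a warning when
  the post arm is nowhere lower.

## Problem sizes

Default analyses use 3 frames × 64 lines × 1536 samples per acquisition,
12 acquisitions per sensitivity recovery (4 pressures × 3 replicates),
20 outputs per hysteresis arm, and 200 drive cycles per bubble
simulation — sizes chosen so a full pipeline pass completes in seconds on
a laptop while keeping estimator variance well below the effects measured.

## Known limitations

* Constant effective σ: no radius-dependent buckling law, no shell
  viscosity/elasticity, no radiation damping, no thermal interior, no
  bubble–bubble interaction, no dissolution.
* The generator's fundamental/subharmonic levels are not derived from the
  bubble model (the optional `physics_mode_line` couples them for
  demonstrations only, via the far-field d²V/dt² scattering law).
* No beamforming or scan conversion; the phased-array sector ROI is
  approximated as a rectangle in beam coordinates.
* The %-output → kPa map is synthetic; real instruments require their own
  calibration.
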