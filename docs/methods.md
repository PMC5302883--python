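# Methods

This note documents the models, estimators, numerical choices and known
limitations of `pigmentnoise`, in the order the analyses run.

## Thermal activation model

A pigment's spontaneous (thermal) activation is modelled as barrier crossing
with barrier energy E_a equal to a fixed fraction 0.84 of the photon energy
at the absorption peak, E_a = 0.84·N_A h c / λ_max (kcal/mol).  Treating the
molecule as m classical vibrational modes that can pool their thermal energy
(Hinshelwood statistics), the rate constant is

    k = A · e^(−x) · Σ_{j=0}^{m−1} x^j/j!,   x = E_a / (R T).

Assumptions: the 0.84 barrier fraction and the mode count m = 45 are taken
as fixed empirical model constants (m is "nominal": an effective number of
classical modes, not a spectroscopic count); A is pigment-class-specific
(closed pocket 7.19 × 10⁻⁶ s⁻¹, open pocket 1.88 × 10⁻⁴ s⁻¹) and is not
derived here.  The upper summation limit is taken as m terms
(j = 0 … m − 1): the truncated sum is then the Poisson lower tail
P(N < m | mean x) and this convention reproduces the empirical reference
predictions for both pocket classes; the alternative (m + 1 terms) changes k by a factor
~x/m ≈ 1.8 at the reference point and does not.

**Dimensional convention.**  Written per photon, h c/λ is an energy per
molecule while R T is molar; the implementation multiplies by N_A
(equivalently, uses k_B T per molecule).  This is the only reading that
reproduces the reference predictions (3.68 × 10⁻¹¹ s⁻¹ closed /
9.63 × 10⁻¹⁰ s⁻¹ open at λ_max = 481 nm, T = 310.5 K).

**Constants.**  Two presets: `precise` (CODATA 2018, default) and `printed`
(the rounded h = 1.58 × 10⁻³⁷ kcal s, c = 3.00 × 10¹⁷ nm/s,
R = 1.99 × 10⁻³ kcal K⁻¹ mol⁻¹ commonly quoted with the formula).  The
precise preset reproduces the reference predictions to ~1.3%; the rounded
constants shift k by ~12% (they shift x by −0.25, which the steep e⁻ˣ tail
amplifies).  Both presets are constructible and tested.

**Numerics.**  x ≈ 81 at the reference point, so x^j/j! overflows long
before j = 45 if formed naively.  The sum is evaluated as
exp(logsumexp_j(j ln x − ln Γ(j+1))), and e⁻ˣ·Σ is combined in the log
domain.  The identity e⁻ˣ·Σ = Q(m, x) (regularized upper incomplete gamma)
is used as an independent cross-check in the tests, together with a 50-digit
arbitrary-precision oracle; double precision agrees to better than 10⁻⁸
relative over x ∈ [0, 200], m ∈ [1, 60].

## Quantal event analysis

**Single-photon response (SPR).**  With Poisson photon capture, the
dim-flash peak current is a·N, N ~ Poisson(λ), so Var/Mean at the peak
equals the quantal amplitude a independent of λ.  The variance is taken at
the single sample of the mean-response peak (ties broken earliest); per-trial
baselines are removed using the pre-flash window.  The mean response scaled
to peak a is the SPR waveform f(t).  Continuous noise adds a positive bias
σ²/(a λ) to the estimate — negligible at the simulated noise levels but
worth remembering for very dim flashes.

**Integration time** is defined as ∫f(t)dt / max f(t) — the width of the
equivalent rectangle; for a rectangular pulse it is the duration and for a
decaying exponential it is τ.

**Detector.**  The stated identification criteria (amplitude > 30% of a,
integration time within 50–200% of the dim-flash value, evaluated at 3 Hz)
do not by themselves define a detector, so the package supplies one:
(1) zero-phase low-pass at 3 Hz (second-order Butterworth, applied forward
and backward — the analog acquisition filter's family and order are
configurable in the same module); (2) contiguous regions above 20% of the
*filtered* SPR amplitude are candidates — the SPR template is passed through
the identical filter before its amplitude is used, keeping the threshold and
the data commensurate; (3) candidates closer than one SPR integration time
are merged; (4) each candidate window is extended to the flanking
zero-crossings (capped at two integration times) before measuring amplitude
and integration time; (5) the 30% / 50–200% criteria are applied.
Overlapping extended windows are deduplicated by peak time.  Measured on the
generator defaults: false positives 0 over 6000 s of event-free noise, and a
paired bias of −0.1 events per 600-s trace at 0.005 s⁻¹ (overlapping events
merge into one detection).

**Poisson epoch analysis.**  Recordings are divided into consecutive 100-s
epochs (trailing partial epoch discarded so exposures are equal) and the
counts fitted with p(u) = wᵘe⁻ʷ/u! by maximum likelihood, which for the
Poisson law is the sample mean; the cellular rate is w / epoch length.  MLE
and least-squares histogram fitting coincide asymptotically; MLE is used
because it is exact at any epoch count.

## Power-spectrum difference method

A Poisson train of events f(t) at rate r is a stationary shot process with
one-sided PSD 2r|F(ν)|² (Campbell's theorem).  The spectrum of the full dark
recording is estimated by Welch's method (8.192-s segments, 50% overlap,
Hann window, density scaling, no per-segment detrending) and the spectrum of
the quietest segment of the recording is subtracted; what remains is the
event spectrum plus estimation noise (negative bins are preserved).

Choices worth noting:

- **Quiet segment**: the contiguous window (default 60 s) of minimum
  variance, an automated surrogate for choosing an event-free stretch by
  eye.  Discrete events inflate local variance, so the minimum avoids them.
- **No detrending**: a constant offset cancels exactly in the difference
  spectrum, whereas removing each segment's mean also removes part of every
  event's power from the lowest-frequency bins (an event contributes
  a·T_i/T_seg ≈ 10% of its amplitude to the segment mean); with detrending
  the fitted rate was ~15% low.  Slow drift is consequently *not* removed —
  the fit band's lower edge (0.1 Hz) and the difference operation are the
  drift defenses.
- **Template spectrum**: the expected contribution of one event to a
  Hann-Welch spectrum depends on where the event falls in the window, so the
  template is the cyclic-placement average of the windowed periodogram,
  computed in closed form as |F|² convolved with the window's spectral
  kernel |W|² (three bins for a periodic Hann).  With this convention the
  least-squares scale factor of the template onto the difference spectrum
  equals r × segment length exactly in expectation, and the rate is
  scale / 8.192 s.  A plain rectangular periodogram is available
  (`window="boxcar"`) and differs by the kernel smoothing of the first few
  bins.
- **Fit band** 0.1–5 Hz, DC bin excluded, unweighted least squares; a
  negative fitted scale is reported as rate 0 with the raw (signed) value
  kept in the estimate's metadata — when pooling many cells the *unclipped*
  values should be averaged, since clipping biases a pooled mean upward
  whenever single-cell estimates straddle zero.

Measured on the generator defaults: the pipeline's event-free mean rate is
0.00002 s⁻¹ (n = 40 traces), and rates 0.002–0.015 s⁻¹ are recovered within
3 SE by both this and the counting estimator over 20 seeds.

## Microspectrophotometry

Absorbance is OD = log₁₀(I_incident/I_transmitted).  Baseline correction
subtracts a line fitted over 650–700 nm (configurable; valid for pigments
peaking ≤ ~570 nm).  Normalization divides by the α-band maximum
(searched in 380–650 nm) and is idempotent.

**λ_max** is the vertex of a quadratic fitted over ±12 nm around the raw
maximum of the lightly smoothed (Savitzky–Golay, 7 points, order 3)
spectrum.  The ±12 nm half-width balances skew bias against noise: the
α-band is asymmetric, and a wider (±20 nm) window biases the vertex by
~−0.6 nm on the 2-nm grid, while ±12 nm keeps the noise-free round-trip
within ±0.35 nm and the error at 1% OD noise within ±2 nm.  A boundary peak
raises an error; a non-concave local fit falls back to the grid maximum.
The estimator is translation-equivariant and scale-invariant.

**Chromophore exchange.**  Pure-form templates (the mean spectrum of
dark-adapted, 11-cis cells and of bleached, 9-cis-regenerated cells) are
each fitted with a degree-10 polynomial on a domain rescaled to [−1, 1]
(raw wavelength powers at degree 10 are catastrophically ill-conditioned).
Each time-point spectrum is then decomposed over 510–750 nm (the
long-wavelength-pigment range; pigment-specific, configurable) as a
non-negative linear combination c₁₁·T₁₁ + c₉·T₉ (NNLS: pigment quantities
cannot be negative),
and the 9-cis fraction is c₉/(c₁₁+c₉).  On noiseless mixtures the recovered
fraction is exact to < 10⁻⁶; at 2% OD noise it is within ±0.05.  The time
course of the fraction is fitted with a(1 − e^(−t/τ)), both parameters free
(bounds a ∈ (0, 2], τ > 0; initial values from the data), with standard
errors from the fit covariance.

Photochemistry calculators: bleached fraction F = 1 − e^(−I·P·t) and photon
capture p_s = 1 − e^(−A_e·I) share one saturation law (cross-checked in
tests); collecting area inverts the latter, A_e = −ln(1−p_s)/I; chromophore
concentration is Beer–Lambert c = OD/(ε·l) with ε₃₇₃ = 36,100 M⁻¹cm⁻¹ for
9-cis retinal in ethanol (at the standard l = 1 cm cuvette the occasionally
quoted form c = OD·l/ε is numerically identical).

## Synthetic-data generator

What it emulates — and deliberately does not:

- **Dark traces** (default 600 s at 1 kHz): homogeneous Poisson event times,
  each adding one SPR template f(t) = a·(t/t_p)^q·e^((t_p−t)/τ), q = t_p/τ
  (defaults a = 1 pA, t_p = τ = 0.3 s, giving the closed-form integration
  time e^q Γ(q+1) τ (τ/t_p)^q ≈ 0.82 s, in the range of rods lacking fast
  Ca²⁺ feedback, whose enlarged quantal events make counting feasible);
  plus white Gaussian noise, the whole passed through the emulated 20-Hz
  acquisition filter.  The default noise SD (1 pA per 1 pA quantal
  amplitude) puts the event SNR at ~5 at the acquisition bandwidth and ~14
  after the 3-Hz counting filter — the regime where events are cleanly
  identifiable, as they must be for a 30%-amplitude criterion to work at
  all; at SNR 5 *after* the counting filter the criterion would be a 1.5σ
  threshold and no detector satisfying it could keep false positives below
  a few per hundred seconds.  Not emulated: 1/f instrumentation noise,
  baseline drift, amplitude variability of real quantal events, and
  truncation effects of pipette seal changes.  Passing tests therefore
  certify the estimators under Poisson-plus-Gaussian assumptions, not under
  every pathology of real recordings.
- **Flash ensembles**: per-trial photon counts ~ Poisson(A_e·I), response =
  count × SPR + filtered noise; the non-zero-trial fraction converges to
  1 − e^(−A_e·I).
- **Spectra** (300–700 nm, 2-nm steps): the α-band follows the standard
  A1-pigment nomogram parametrization (Govardovskii-style), normalized to
  exactly 1 at λ_max, with an optional log-Gaussian fallback; a linear
  baseline tilt and per-scan Gaussian noise averaged over n scans (default
  10) are added.  β-band and photoproduct absorbance are not modelled, which
  is why baseline regions and unmixing ranges avoid the short-wavelength
  side.
- **Exchange time courses**: a(1 − e^(−t/τ)) plus Gaussian error with SD
  noise_sd/√n_cells (default 0.05/√9), matching a 9-cell averaged design
  over a 3-h span.

All generators are deterministic under a fixed integer seed and independent
across seeds (a fresh `numpy` Generator per call; no shared state).

## Problem sizes and tolerances

The test suite and the acceptance script size their simulations to keep
Monte-Carlo error well inside the assertions: rate-closure checks use 20
seeds × 600-s traces per rate (3-SE criteria with the Poisson SE of the
pooled exposure); the acceptance script uses 120 simulated cells per rate
estimator, 2000 flash trials per collecting area, and 20 spectra per λ_max.
Epoch-statistics checks use ground-truth event lists at a coarse 100-Hz
sampling rate, since only the event times matter there.

## Known limitations

- The detector is tuned for positive-going, well-separated events; rates
  above ~0.05 s⁻¹ with T_i ≈ 0.8 s would merge events frequently.
- The PSD method assumes the quiet segment is representative of the
  continuous noise; strongly non-stationary noise breaks the subtraction.
- λ_max estimation assumes a single α-band peak inside the search window;
  mixed-pigment spectra should be unmixed first.
- The exchange fit forces the curve through the origin at t = 0 (no free
  offset), as the underlying exchange process requires.
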