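# Methods

## Chromophore photophysics from pH titrations

The two-state model treats a green GECI chromophore as either neutral
(protonated, band near 403 nm) or anionic (deprotonated, band near
509 nm), with total chromophore conserved during an H⁺ titration:
n_D = n_A + n_N, Δn_A = −Δn_N. With n = OD/ε per state this yields
ε_A/ε_N = −S for the ordinary-least-squares slope S of OD_A on OD_N
across pH, and, anchored by the alkaline-denatured spectrum
(ε_D = 44,000 M⁻¹cm⁻¹ at pH ≥ 11, nominally 12.5),

    ε_N = (OD_A/(−S) + OD_N)/(OD_D/ε_D),   ε_A = ε_N(−S),
    ρ_A = (OD_A/ε_A)/(OD_A/ε_A + OD_N/ε_N).

The conservation identity OD_D/ε_D = OD_A/ε_A + OD_N/ε_N then holds by
construction (to 1e-9 relative), which the test suite asserts on noisy
series as well.

Numerical choices:

- **Band quantification** is the peak OD within fixed windows
  (380–430 nm neutral, 470–540 nm anionic), not a band integral: peak
  OD carries the same units as the slope regression and is robust after
  smoothing. A 5-point median filter is applied before peak-picking
  (raw spectra are never modified); because the filter attenuates every
  Gaussian-like peak of equal width by the same factor, it cancels in
  the slope and in the ε ratio, leaving the recovered coefficients
  unbiased.
- **Baseline**: the mean OD over 600–650 nm (where protein chromophores
  do not absorb) is subtracted per spectrum when the grid covers it.
- **Denatured band**: the denatured chromophore absorbs between the two
  native windows (~447 nm), so OD_D is the peak over the full
  380–540 nm quantification range.
- **Evaluation pH** defaults to 7.2, the measurement buffer pH of the
  fluorescence assays; the ε identity is pH-independent in the
  noiseless model, so this only selects which spectrum anchors OD_A,
  OD_N.
- The slope regression is OLS with free intercept (OD_A on OD_N); the
  lower-noise band is the natural regressor and the model is exact
  under conservation regardless. Ca²⁺-free and Ca²⁺-saturated series
  are fitted separately.
- **pKa** is fitted as ρ_A(pH) = 1/(1+10^{h(pKa−pH)}) by nonlinear
  least squares (start h = 1, pKa at the half-anionic pH). Flat ρ_A
  yields NaN with a warning rather than an error.

Quantum yield is the slope ratio Φ = Φ_std·S_protein/S_std of total
integrated fluorescence against absorbance (fluorescein 0.925 for the
anionic chromophore at 470 nm, TOLLES 0.79 for the neutral at 405 nm);
values above 1 are returned with a warning. The two-photon
cross-section uses the sample/standard ratio
δ = (⟨F⟩_s η₂,std C_std)/(⟨F⟩_std η₂,s C_s)·δ_std in which pulse shape,
repetition rate, pulse width, refractive index, incident power and
collection efficiency cancel; a fluorescein reference table
(750–990 nm, 10-nm steps, approximate literature digitization,
user-overridable) is bundled.

## Titrations and kinetics

Free [Ca²⁺] of an EGTA/Ca-EGTA mixture with equal total chelator is
K_d·f/(1−f); the default K_d(EGTA) = 150 nM (pH 7.2, ~0.1 M ionic
strength, 22 °C) is overridable. Hill fits use
F = F_min + (F_max−F_min)[Ca]ʰ/(K_dʰ+[Ca]ʰ) with plateaus initialized
from the 5th/95th fluorescence percentiles, K_d from the concentration
nearest half-range, h started at 2, all parameters bounded positive
(lmfit/least-squares). Dynamic range (F_max−F_min)/F_min is reported
from the fitted plateaus by default; the raw-extreme variant is kept
separately because inaccurate background subtraction near zero
fluorescence inflates it. Curves whose fluorescence varies by less than
1 ppm of its magnitude (constant, or all points on one plateau) are
rejected as unidentifiable. Off-rates are single-exponential fits
F = F_plateau + A·e^{−k_off t}; records covering fewer than two e-folds
of decay are rejected.

## Trace metrics

ΔF/F₀ uses the mean fluorescence over a pre-stimulus baseline window
(default 1 s before onset for in vivo recordings; 0.5 s is the
slice-style convention) after optional background subtraction. The peak
is the global maximum of ΔF/F₀ within 6 s after the first onset
(configurable). Peak SNR is exactly peak ΔF/F₀ divided by the baseline
ΔF/F₀ standard deviation; zero baseline variance returns +inf with a
warning. Half-decay fits A·e^{−(t−t_peak)/τ}+c with A, τ > 0 and τ
initialized from the 1/e crossing; the reported value ln2·τ is
invariant to A and c. Ratiometric traces interpolate the reference
channel linearly onto the signal grid over the overlapping support only.
The responsive-cell test is a classical two-sample equal-variance
Student's t-test (two-tailed) of per-trial stimulus-window vs
baseline-window ΔF/F₀ means, responsive at p < 0.01; Welch's variant is
available by flag.

## iPEAQ

A photochromic cycle is a contiguous violet (405-nm) epoch (nominal
2.5 s, configurable) followed by a 488-only relaxation gap; its
contrast is (F₀−F_end)/F₀ with F₀ the violet-on plateau and F_end the
relaxed fluorescence. Amplitudes default to the mean over the trailing
25% of each epoch/gap rather than the epoch max / gap min: the
plateau-tail mean is unbiased under multiplicative noise, whereas
extreme values are biased by several noise standard deviations at
typical sampling (a ~13% contrast inflation at CV 0.02, which would
propagate to tens of percent of [Ca²⁺]); `method="extrema"` restores
the literal definition. The last cycle's relaxation window is capped at
the median inter-cycle gap so a following stimulus period cannot leak
into F_end; cycles whose gap tail remains >5% above the smoothed gap
minimum are flagged incomplete and excluded from the basal average.

Quantification: basal contrast (mean over the initial complete cycles)
→ basal [Ca²⁺] through the inverted contrast calibration → normalizing
factor k = fluor_curve(basal [Ca²⁺])/basal F → [Ca²⁺](t) =
fluor_curve⁻¹(k·F(t)). Basal F is the mean of the settled (trailing
25%) 488-only samples between cycles — the whole-gap mean would carry
the relaxation tail (~2% bias at τ = 0.5 s with 4-s gaps), consuming
the noiseless error budget. Hill inversion is closed-form,
K_d·(u/(1−u))^{1/h} with u the plateau-normalized value; during live
inversion u is clipped 0.5% from each plateau (flagged) to bound error
amplification, while an out-of-range *basal* contrast is an error.
Samples during violet epochs and within the relaxation-settle window
after each epoch are masked NaN. Multiplying the whole trace by any
gain g > 0 leaves [Ca²⁺](t) unchanged because contrast is a ratio and k
absorbs g — the property that makes the readout absolute.

## Tuning

The per-direction response is, within each trial, the mean of the top
quartile (ceil(n/4) largest) of stimulus-window ΔF/F₀ samples, averaged
over trials. This estimator is positively biased on pure noise (below
~1.3 noise SD at the default 6 trials × 4-s windows, quantified in the
tests) but robust to onset jitter. OSI is the doubled-angle resultant
magnitude normalized by the summed response; negative mean amplitudes
are clipped to 0 first, since the vector formula assumes non-negative
weights. DSI contrasts the argmax direction (ties: lowest angle) with
its 180°-opposite grid point. Both indices are invariant to positive
rescaling; the raw direction grid (not orientation-folded) is used for
both.

## Synthetic data: what it emulates and what it does not

Generators are deterministic given a seed and return ground truth.
Fluorescence noise is multiplicative Gaussian (CV-parameterized),
reflecting shot-noise-dominated imaging; tuning tables use additive
noise on the ΔF/F₀ scale. Defaults encode the study conditions the
estimators are meant for: pH series at {7, 7.2, 8, 9} plus a denatured
spectrum at 12.5; chromophore ε_A = 64,260 / ε_N = 21,420 M⁻¹cm⁻¹,
pKa 7.0, 4 µM protein; Gaussian bands at 403/509/447 nm with 25-nm
FWHM (the width parameter is FWHM, keeping cross-band bleed-through at
the window maxima below 1e-3); titrations of 12 concentrations
log-spaced two decades around K_d = 200 nM with plateaus 1/103.3;
off-rate 2 s⁻¹ sampled at 200 Hz over six e-folds; photochromic cycles
of 2.5 s violet + 4 s gap (≥ 8 relaxation time constants at the
default τ = 0.5 s), five cycles, contrast plateaus 0.75→0.05 with
K_d 250 nM over a fluorescence calibration with K_d 600 nM; AP kernels
with 10-ms rise and per-sensor decay presets (fast 409 ms half-decay,
reference 482 ms); eight drifting-grating directions × six 4-s trials
with a von Mises amplitude profile.

Not emulated: real absorption band shapes (Gaussians only), Ca²⁺
buffering/diffusion, bleaching, motion, instrument dead time, ROI
segmentation, or optics. Passing round trips therefore demonstrate the
correctness of the estimators under their stated models, not robustness
to every artifact of real recordings.

## Problem sizes and tolerances used by the verification suite

Noiseless round trips: extinction coefficients to 0.5% (exact in
practice), Hill/off-rate parameters to 1e-4 relative, iPEAQ [Ca²⁺](t)
to 1% pointwise, gain invariance to 1e-9. Under noise: Hill K_d median
error < 3% at CV 0.01 (50 seeds), k_off < 5% at CV 0.02 (50 seeds),
half-decay < 3% at CV 0.01 (50 seeds), iPEAQ basal and peak [Ca²⁺]
median error < 10% at CV 0.02 (50 seeds, peak read from a 9-sample
median-filtered trace). The responsive-cell test's type-I error is
checked at 10,000 null replicates of 6 trials (0.01 ± 0.005); the
noise-halving behaviour of peak SNR at 100 seeds (±10%).
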