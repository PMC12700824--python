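# Methods

This note documents the models behind `ffstools`, the choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Detection volume

All fluctuation analyses assume a 3D-Gaussian detection profile
`W(r) = exp(-2(x² + y²)/w_xy² - 2z²/w_z²)` with effective volume
`V_eff = π^{3/2} w_xy² w_z` and shape factor `S = w_z/w_xy`. The default
volume is solved from `V_eff = 1 fl` and `S = 6` (typical calibrated values
for an in-cell confocal FCS spot), giving `w_xy ≈ 0.311 µm`,
`w_z ≈ 1.866 µm`. `S` is always fixed, never fitted: with lag ranges
spanning a few decades the axial term is barely constrained and letting it
float destabilizes `τ_D`. Occupancy converts to concentration as
`c = N/(V_eff·N_A)`; one molecule per femtoliter is 1.66 nM.

## Photon-trace simulator

`simulate.simulate_trace` propagates point particles by free Brownian motion
(per-axis Gaussian steps of sd `sqrt(2·D·Δt)`, one step per 100 µs bin) in a
periodic cubic box of edge `6·w_z` (≈ 1400 `V_eff`), computes per-bin
expected counts `Σ n_protomers·ε·Δt·W(r)` per channel plus background, adds
a `bleed_g_to_r` fraction of the green particle signal to the red
expectation (the direction of mEGFP emission tailing into a red channel),
optionally modulates expectations by `1 + A·sin(2πt/P)` with `P =
duration/2` to mimic slow drift, and draws Poisson counts. The particle
number is fixed at `round(N·V_box/V_eff)`; occupancy fluctuations inside the
detection region arise from diffusion across its boundary, and are
Poissonian to `O(V_eff/V_box) ≈ 0.1%`.

Randomness splits from one integer seed via `numpy.random.SeedSequence`:
child 0 drives photon noise, child `1+i` is the root for species `i`, which
spawns one PCG64 stream per particle. Identical configurations reproduce
traces bit-exactly.

Choices and limitations:

* Motion is propagated once per bin. There is no intra-bin blurring of
  brightness, so PCH fits of simulated traces recover the true `ε` without
  the bin-time diffusion correction; applying the correction (appropriate
  for continuous-motion data) overcorrects by `~Δt/(3τ_D)`, under 4% for
  `τ_D ≥ 1 ms`. The discretization is inappropriate for `τ_D < ~1 ms`.
* Neutral defaults: background, bleedthrough and drift are zero unless
  enabled. Per-fluorophore brightness defaults to 1e4 counts s⁻¹, in the
  range where 20–30 s acquisitions condition both PCH and FCS fits well.
* No photophysics: blinking, photobleaching, triplet kinetics, detector
  afterpulsing and dead time are all absent. Passing tests therefore
  validate the estimators under ideal photon statistics, not robustness to
  these artifacts in real recordings.

## PCH

`pch.pch_model` implements standard one-species 3D-Gaussian PCH theory. The
single-particle count distribution is computed by 160×160 Gauss–Legendre
quadrature of `Poisson(k; ε·W)` over a cylinder of volume `V_ref =
100·V_eff` whose radius/half-height are the same multiple of the two waists;
`p(0)` is fixed by normalization. The many-particle distribution mixes
`M`-fold convolutions over a Poisson particle number with mean
`N·V_ref/V_eff`, truncated at `mean + 8·sqrt(mean)` (tail error < 1e-10);
background is folded in by a final Poisson convolution. Results are
independent of `V_ref` to better than 1e-8 (asserted by test against a
positional Monte-Carlo oracle and a second `V_ref`).

Fitting (`pch.fit_pch`) weights frequencies by multinomial standard
deviations with a one-count floor, fits `k` up to the last count observed at
least 10 times, and starts from factorial-moment estimates
(`mean = ε·N·2^{-3/2}`, `factorial variance = ε²·N/8`). Background can be
fitted or fixed. The bin-time diffusion correction is the generic
ACF-integral attenuation `c(T) = (2/T²)∫₀ᵀ(T−t)·g(t)dt` with `g` the
normalized 3D diffusion ACF shape; its exact leading order is
`1 − c = (T/3τ_D)(1 + 1/(2S²))`. The vendor implementations in common use do
not publish their exact correction; this factor is isolated behind one
function (`diffusion_bin_correction`) so an alternative can be substituted.
Brightness ratios use background-subtracted fitted `ε` by default.

Oligomer size is the brightness ratio to a monomeric (single-fluorophore)
reference measured under the same conditions; protomer concentration is
`size·N/(V_eff·N_A)`.

## FCS / FCCS

Correlations are estimated as
`G(τ) = <δF_a(t)·δF_b(t+τ)>/(<F_a><F_b>)` with symmetric (segment-local
mean) normalization. The multi-tau scheme is the community-standard m = 16
correlator: 16 unit lags, then 8 lags per stage with the series re-summed in
pairs each stage. Standard errors come from 16-block averaging; the maximum
lag is capped at a quarter block so every block supports every lag. The
correctness oracle is the O(n·m) direct estimator: multi-tau values agree
with the direct estimator to better than 1e-3 (relative to `G` at the first
lag) when both are evaluated at the same binning — at native resolution for
the first stage, on the pair-summed series for coarser stages. Comparing a
rebinned stage against the native-binning direct estimator instead mixes two
different pair sets whose purely statistical difference exceeds that
tolerance, so it is not a meaningful oracle check.

Detrending for slow drift (bleaching, focus/stage drift) rescales counts by
`(global mean)/(moving average)` with a 1 s default window, then
re-quantizes to integers by error-diffusion rounding (cumulative-sum
rounding), preserving the total count to within one photon. The method is
deliberately simple and isolated behind one function; published detrending
tools use related local-normalization schemes but do not document an exact
algorithm.

Autocorrelations are fitted with the one-species free-diffusion model
`G(τ) = (1/N)(1+τ/τ_D)^{-1}(1+τ/(S²τ_D))^{-1/2}`. Fits are unweighted over
the log-spaced lags by default: 16-block error estimates are noisy and
correlate with the per-lag fluctuations (a block containing a bright
transit raises both its `G` and its spread), and 1/se² weighting then
biases amplitude and diffusion time downward at low occupancy — a ~30%
effect at N = 0.05 on a 25 s trace, against ~2–10% unweighted. Weighting by
externally supplied error bars remains available. For
FCCS, green→red bleedthrough `β = <F_r>/<F_g>` measured on a green-only
negative control is removed by linear unmixing of the covariances
(`cov_GR = cov_gx − β·cov_gg`, `cov_RR = cov_rr − 2β·cov_gx + β²·cov_gg`,
red mean `<F_r> − β<F_g>`) before re-normalization. The cross amplitude is
fitted with `τ_D` fixed at the autocorrelation average and the amplitude
allowed to go negative, so a true zero stays well-posed. The bound fraction
of the less concentrated construct (the channel with the larger `G0`; ties
go to green) is `G0_x/G0_other`, divided by the amplitude ratio measured on
a covalent green–red fusion (the `overlap_factor` compensating imperfect
channel overlap — identically 1 in the simulator, which uses a single
detection volume), and clamped to [0, 1] with an explicit flag because noisy
amplitudes legitimately stray outside.

## Hydrodynamics

Three friction models for head-to-tail n-mers of protomers `L0 = 6 nm` long
and `d0 = 5 nm` wide (rigid straight stacking, length `n·L0` at constant
diameter; filament flexibility is ignored):

* globule — equal-volume sphere, `D ∝ n^{-1/3}`;
* prolate spheroid — Perrin factor
  `f/f0 = p^{-1/3}·sqrt(p²−1)/ln(p+sqrt(p²−1))`, `p ≥ 1`, with a series
  expansion below `p = 1+1e-7`;
* rod — Tirado–García de la Torre cylinder
  `D = kT(ln p + 0.312 + 0.565/p − 0.100/p²)/(3πηL)`, flagged outside its
  `p ≥ 2` validity range.

Both elongated models are reported side by side since figure-level "Perrin"
predictions in the literature do not always name the exact formula. The
predicted `D(2-mer)/D(10-mer)` is 1.71 for a globule, ≈ 2.47 (rod) or
≈ 2.63 (prolate) for the elongated geometries — the separation that makes
rod-vs-globule discrimination by FCS diffusion ratios possible. Viscosity
defaults to water at 293.15 K (1.0016 mPa·s); in-cell predictions use a
user-set multiplier (the recovery benchmarks use 3×, giving GFP-like
`D ≈ 25 µm²/s` for a monomer). Inverting a DLS-style hydrodynamic diameter
to a subunit count (`subunits_for_diameter`) is strongly formula-dependent
and should be read as indicative only.

## SEC calibration

Ordinary least squares of elution volume on `log10(MW)` over globular
standards (statsmodels OLS; the test oracle is the closed-form normal
equations). The largest-MW standard is treated as the void marker and
excluded by default — chromatography convention, toggleable — and its EV is
kept as the resolution limit: predicted multimer EVs below it are flagged
"beyond column resolution".

## Half-focus FRAP

The dip statistic is `1 − min(normalized unbleached intensity)` after the
bleach, with a 3-sample moving average to resist the downward noise bias of
a pointwise minimum. Both halves are normalized to their own pre-bleach
means (≥ 3 pre-bleach frames); an optional reference region corrects
acquisition photofading. The interpretation model is two well-mixed half-
compartments exchanging internally at `k_int` and with an infinite pool at
`k_ex`:

    B(t) = 1 − e^{−k_ex t}/2 − e^{−(2k_int+k_ex)t}/2
    U(t) = 1 − e^{−k_ex t}/2 + e^{−(2k_int+k_ex)t}/2

The dip is 0 for `k_int = 0`, 0.5 for a closed focus (`k_ex = 0`, mass
conservation between equal halves), ≈ 0.192 at `k_int = k_ex`, strictly
increasing in `k_int/k_ex`, and invariant under time rescaling; a measured
dip in (0, 0.5) inverts to a unique rate ratio. The simulator integrates the
ODE numerically (DOP853, rtol 1e-10) and the closed form serves as the
analytic oracle; rate fitting uses the closed form.

The free-diffusion null is the same model with fast exchange
(`k_ex/k_int = 100`) and observation noise matched to the data — a desk-
scale, closed-form stand-in for a spatial continuum simulation. Observed
dips are tested one-sided against the simulated null mean with a one-sample
t-test; an empirical p (observed mean vs resampled null means of the same
sample size) is reported alongside because the minimum statistic is mildly
skewed and the t-test runs slightly conservative at small n. Dips are
measured per focus and then averaged.

## Problem sizes used in the validation suite

The validation benchmarks use 25 s acquisitions at 100 µs bins (the study-
scale acquisition length), a five-point oligomer panel (n = 1, 2, 5, 10, 20
paired with occupancies 0.05–2, size growing with concentration as in
concentration-dependent assembly), 1e7 Monte-Carlo draws for the PCH oracle,
and 200 replicates for null-test calibration. The demo pipeline panel uses
12 cells of 8 s each; the pipeline test uses a further-reduced 6-cell, 4 s
panel, chosen so the whole suite runs on a laptop-class single core.

## Known limitations

* No photophysics or detector artifacts (see simulator section); brightness
  ratios on real data require photobleaching-stable acquisitions.
* One-species models throughout: mixtures of oligomer sizes within one
  trace fit to an intensity-weighted effective size.
* The two-compartment FRAP model ignores spatial gradients inside the focus
  and bleaching during observation.
* Rigid-rod hydrodynamics ignores filament flexibility; flexible chains
  fall between the rod and globule predictions.
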