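# ffstools

Fluorescence fluctuation spectroscopy tools for characterizing protein
oligomerization in living cells — in particular concentration-dependent,
rod-like filament assembly of the kind formed by head-to-tail
self-associating proteins.

`ffstools` is aimed at people who do (or want to reason quantitatively
about) confocal fluctuation experiments: photon counting histogram (PCH)
brightness analysis, FCS/FCCS correlation analysis, hydrodynamic shape
discrimination, half-focus FRAP, and size-exclusion chromatography
calibration. Because raw microscope photon traces are rarely shareable, the
package includes a first-class Brownian-dynamics simulator that generates
realistic two-channel photon-count traces with known ground truth, so every
estimator in the chain can be validated end to end without any instrument.

## What it computes

* **Simulation** (`ffstools.simulate`) — labeled oligomers (1–20 protomers,
  one green and/or red fluorophore per protomer) diffusing through a
  3D-Gaussian confocal volume (default 1 fl, shape factor S = 6), emitting
  Poisson counts in 100 µs bins over 20–30 s acquisitions, with optional
  detector background, green→red bleedthrough and slow drift; plus a
  two-compartment half-focus FRAP curve simulator.
* **PCH** (`ffstools.pch`) — one-species 3D-Gaussian photon counting
  histogram model and fit: molecular brightness ε (counts s⁻¹ molecule⁻¹)
  and occupancy N. Oligomer size = ε/ε(monomer reference); concentration =
  N/(V_eff·N_A).
* **FCS/FCCS** (`ffstools.fcs`) — detrending, multi-tau and direct
  correlators, one-species diffusion fits
  `G(τ) = (1/N)(1+τ/τ_D)⁻¹(1+τ/(S²τ_D))^(−1/2)` at fixed S, diffusion-time
  ratios, bleedthrough unmixing from a negative control, and the FCCS bound
  fraction `G0_x/G0_other` of the less concentrated construct.
* **Hydrodynamics** (`ffstools.hydro`) — Stokes–Einstein spheres, Perrin
  prolate spheroids and Tirado–García de la Torre rods for head-to-tail
  n-mers (6 nm × 5 nm protomers by default); predicted diffusion ratios
  that separate rods from globules; SEC calibration
  `EV = intercept + slope·log10(MW)` on globular standards and multimer EV
  prediction.
* **FRAP** (`ffstools.frap`) — half-focus normalization, the dip-depth
  confinement statistic (0 = free exchange, 0.5 = closed focus),
  two-compartment exchange-rate fitting, and a simulated free-diffusion
  null test.
* **Pipeline & CLI** (`ffstools.pipeline`, `ffstools` command) — an
  end-to-end reproduction of the analysis graph on simulated cells, with
  deterministic, seedable outputs.

## Worked example

Run the demo pipeline — 12 simulated "cells" expressing oligomers of 1–20
protomers at occupancies 0.02–1.2 in a 1 fl volume — and the downstream
analyses:

```python
from ffstools.pipeline import demo_config, run_pipeline

bundle = run_pipeline(demo_config(output_dir="out", seed=1))
for key, value in bundle["summary"].items():
    print(key, "=", value)
```

prints (seed 1):

```
size_vs_concentration_slope_per_nM = 0.5113610483948335
size_vs_concentration_r2 = 0.9094961959747018
taud_vs_size_slope_ms = 0.2164339954804279
taud_vs_size_r2 = 0.913440737983954
predicted_ratio_2_10_rod = 2.4716464992652645
predicted_ratio_2_10_prolate = 2.6265067697511646
predicted_ratio_2_10_globule = 1.7099759466766968
measured_ratio_2_10 = 1.7416833515633332
fccs_bound_fraction_head_tail_pair = 1.0
fccs_bound_fraction_same_mutant_pair = 0.017332463966228614
fccs_bleedthrough = 0.05018333453159825
frap_mean_dip = 0.21145203653782216
frap_null_mean_dip = 0.03503725336817094
frap_null_p = 4.331110644754375e-11
```

Reading these numbers: estimated oligomer size scales linearly with
estimated concentration (R² = 0.91), and diffusion time grows linearly with
oligomer size (R² = 0.91) — the signature of rod-like growth, since a
globule's τ_D would grow only as n^(1/3). The theoretical 2-mer/10-mer
diffusion-coefficient ratios show the rod (2.47) vs globule (1.71)
separation; the measured ratio from a single pair of 8 s single-cell traces
is noisy (±20–30%) and should be read from longer acquisitions (the
validation suite uses 25 s).
The FCCS block recovers the simulated green→red bleedthrough (5%), full
binding for the complementary "head/tail mutant" pair, and no binding for
the same-mutant pair. The FRAP block measures a mean unbleached-half dip of
0.21 for confined foci, far above the free-diffusion null (0.035,
p ≈ 4e-11).

Per-stage CSV tables (`pch_fits.csv`, `fcs_fits.csv`, `fccs.csv`,
`frap_dips.csv`), a flat-text `summary.txt` and a log land in the output
directory; re-running with the same seed reproduces them byte-for-byte.

The same analyses are scriptable from the shell, e.g.:

```sh
ffstools seccal --mw-monomer 35          # SEC calibration + multimer EVs
ffstools hydro --n-small 2 --n-large 10  # rod/prolate/globule D ratios
ffstools simulate --seed 3 trace.tsv     # write a simulated photon trace
ffstools pch trace.tsv                   # brightness/occupancy fit
ffstools fcs trace.tsv                   # autocorrelation + diffusion fit
```

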