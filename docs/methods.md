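# Methods

## Diffusive-mixture model of single-molecule tracks

A tracked molecule is assumed to occupy one of k ≤ 3 diffusive states:
DNA-bound ("static"), nucleoid-constrained, or freely diffusing. For a
state with diffusion constant D observed at frame interval τ, each
displacement axis is Gaussian with variance 2Dτ, so the 2-D squared
displacement x = Δx² + Δy² is exponential with mean 4Dτ (equivalently,
the jump distance is Rayleigh). Independent localization error σ per
axis per frame adds 2σ² to each axis variance, inflating the apparent
constant to D_app = D + σ²/τ. With the default σ = 30 nm and τ = 20 ms
the noise floor is σ²/τ = 0.045 µm²/s — larger than the static-state D
itself, which is why corrected estimates of the slowest component carry
little relative precision (see *Numerical choices*).

The mixture CDF

    F(x) = Σᵢ fᵢ (1 − exp(−x / 4 D_app,i τ)),  fᵢ ≥ 0, Σ fᵢ = 1

is fitted to the empirical CDF of pooled lag-1 squared displacements by
least squares. The problem is separable: for fixed {Dᵢ} the objective
is quadratic in f on the probability simplex and is solved exactly by
enumerating active sets (k ≤ 3, so at most 7 KKT systems); the outer
search over log Dᵢ uses Nelder–Mead from five log-spaced starts spanning
0.001–10 µm²/s, the best final SSE winning and ties broken by the
smallest largest-component D. This keeps the fit deterministic without
random restarts. Maximum-likelihood fitting of the same exponential
mixture is deliberately *not* the default — the CDF fit mirrors how such
data are usually displayed and assessed — but the k = 1 case is
cross-checked against the closed-form moment estimator mean(x)/4τ in the
tests (agreement within 1 %).

Model selection adds components while they pay: best k is the smallest
k whose successor improves the CDF R² by less than `delta_r2 = 1e-4`.
The threshold sits between the gain sampling noise produces when no
extra component is needed (≲ 1e-5 at a few thousand tracks) and the gain
a genuinely missing third population yields (~4e-4); a coarser threshold
in the 1e-3 range collapses three-state data onto k = 2, because two
exponentials already track such CDFs to R² ≈ 0.9996.

### What the track generator emulates — and what it does not

`simulate_tracks` draws a per-track state from the occupancy fractions
(per-step Markov switching is available but off by default so that
ground-truth fractions stay track-level and exactly recoverable),
simulates the walk inside a 3×1 µm spherocylinder with specular wall
reflection, adds per-frame Gaussian localization error, and re-reflects
observed points so nothing lies outside the outline. Slow-state
molecules can be seeded in — and confined to — a 2.0×0.7 µm nucleoid
subregion (MTase-like preset); the REase-like preset uses the whole
cell. Track lengths follow a discretized Weibull law calibrated so the
post-filter (≥ 5 steps) mean is 8 steps with ~10 % of tracks longer than
10 — a geometric law cannot meet both at once (it would put ~18 % past
10 steps). The calibration is applied after the length filter because
the acquisition statistics it mimics are quoted for analysed tracks.

Not emulated: point-spread-function rendering, blur within the 20 ms
exposure, photophysics beyond single-step disappearance, 3-D motion, or
state-dependent track length (fast molecules leaving the focal plane
sooner). Passing recovery tests therefore show the estimator chain is
correct for confined multi-state Brownian motion with localization
noise — not that real acquisitions are free of the biases above.

A bias the simulation *does* reproduce deliberately: free diffusion at
~1 µm²/s inside a 1 µm-wide cell has its long jumps truncated by the
wall, so the fitted fastest D comes out ~15–20 % low and the fastest
fraction ~2–3 points low even at very large track counts. The preset
D values (0.01, 0.35, 1.2 µm²/s) are illustrative magnitudes for the
three regimes, not measured constants.

## Confinement and the standardized cell

A confined segment is a maximal run of localizations all lying within
r_c of the run's centroid (recomputed per candidate window), spanning at
least `min_consecutive_steps`. The centroid — rather than the first
point — is the reference because it is rotation-invariant and does not
privilege the run's entry frame. Two step thresholds circulate for this
analysis, 9 and 5; both ship as presets (`results` = 9, default;
`legend` = 5) rather than silently choosing one. r_c defaults to 120 nm
= 4σ. The detector is verified against a brute-force oracle that tests
every window on 200 random fixtures.

Tracks are labelled `confined` when segments cover ≥ 90 % of steps
(an artifact-level convention, exposed as `coverage_threshold`), `free`
with no segment, `transition` otherwise.

Projection into the standardized cell is per-axis affine: translate to
the cell center, rotate the long axis onto x, scale by (3/length,
1/width). Anisotropic scaling maps every cell to exactly 3×1 µm, is
exactly invertible, and conserves counts (out-of-bounds points are
counted and reported, never dropped). Nucleoid enrichment is quantified
as the fraction of standardized localizations inside a central
2.0×0.7 µm box.

## Onset detection and delay statistics

Onset is the earliest sampled time from which the background-subtracted
intensity exceeds m·sd(background) for `consecutive = 2` samples. The
default multiplier m = 0 is the literal "rose above background" rule
and is exact for noiseless data; with measurement noise m = 0 triggers
on any positive excursion pair, so noisy analyses (and the acceptance
script) use m = 3 with the background sd estimated from negative-control
traces. Detection latency — threshold climb plus grid quantization —
affects both channels equally and cancels in red-minus-green delays,
which is why delay means are recovered to ~1 min on a 5-min grid.

Two time conventions coexist, as the data presentations do: single-cell
delays are reported relative to each cell's green onset; bulk analyses
report absolute minutes post-infection. The expression generator's
presets encode the two genotypes: C-present, red onset = green +
N(+10, 15²) min; C-deleted, + N(−15, 15²) min; green onset N(70, 8²)
min post-infection; linear rise (20 a.u./min default) after onset;
bulk = mean over cells + background, sampled every 5 min from 50 to
140 min. For single-cell simulations of the C-deleted genotype the
sampling window is widened to 0–160 min: with red onsets at
70 − 15 ± 17 min, a 50-min start would left-censor roughly a third of
red onsets and bias the recovered mean. Group means are compared with
Student's (pooled-variance) two-tailed unpaired t-test by default —
the named test for these comparisons — with Welch as an option.

The steady-state expression level is the OLS slope of
background-subtracted fluorescence against OD600 (statsmodels OLS),
insensitive to sampling times during balanced growth.

## Assay statistics

Transfer frequency = dilution-corrected transconjugants / recipients,
averaged over replicates with sample SD; all-zero numerators are
flagged "< 10⁻⁹" (the stated detection limit) rather than reported as 0.
Genotype-effect ratios divide two such means; the SD uses first-order
(delta-method) propagation for a ratio of independent means, which
reproduces all six published ±SD entries of the mating table to their
printed precision. In one block the published ratio itself (7) does not
follow from the published means (which give 6.5); the package reports
the computed value and the tests pin the reproducible quantities.
Reporting style: one decimal below 10, integers above, raw values always
retained. EOP is the no-R-M / with-R-M titer ratio (restriction → > 1);
zero plaques on the restricting strain yield a "> titer" lower bound.
Survival is the permissive/restrictive CFU ratio, dilution-corrected.

## Numerical choices and degenerate inputs

* ECDF convention: F(x₍ᵢ₎) = i/n, right-continuous, ties pooled — makes
  fits byte-reproducible.
* All-zero squared displacements return the degenerate fit (k = 1,
  D = 0, f = 1) with a warning instead of failing.
* Localization correction floors D at 0; corrected estimates of
  components near the σ²/τ floor are reported but carry an absolute
  uncertainty of a few 10⁻³ µm²/s, so recovery tests for the slowest
  preset component use ±max(25 %, 0.0045 µm²/s).
* Reflection falls back to radial clamping for points farther than one
  cell width outside the wall (unreachable at the simulated step sizes).
* Two identical zero-variance groups compare at p = 1 by convention.
* One global seed; every stage derives child seeds via SeedSequence, so
  fixed-seed runs are byte-identical.

## Problem sizes

Recovery tests use 1 500–3 000 tracks per replicate (20 seeded
replicates for the median-error claims) and 100–111 cells per
expression group. The acceptance script uses 20 000 tracks per SMT
condition — enough that the occupancy estimates stabilise to about one
point — triplicate 300-cell bulk cultures, and the published group
sizes (110/111) for single-cell timing.

## Known limitations

* The Rayleigh-mixture fit assumes free diffusion within each state;
  confinement biases the fastest component low (quantified above).
* No hidden-Markov segmentation: within-track state changes are only
  handled as the confined/transition classification, not per-frame.
* Onset detection assumes a monotone rise after onset; transient dips
  below threshold after two qualifying samples are ignored.
* The delta-method SD for ratios assumes independent numerator and
  denominator and small relative errors; at CV ≳ 0.6 (as in one
  published block) it is a first-order approximation only.
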