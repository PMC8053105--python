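# rmdynamics

Analysis pipeline for the establishment dynamics of a bacterial
restriction–modification (R-M) system entering a new host cell. When an
R-M operon — a DNA methyltransferase (MTase), a restriction endonuclease
(REase) and a C regulatory protein — arrives by horizontal transfer, the
host survives only if protective methylation precedes restriction. The
package quantifies the three observable faces of that race:

* **Single-molecule tracking.** Pooled squared displacements of tracked
  enzyme molecules at frame interval τ are decomposed into up to three
  diffusive populations. For a 2-D Brownian population, jump distances
  are Rayleigh and squared displacements exponential, so the mixture CDF
  is `F(x) = Σᵢ fᵢ (1 − exp(−x / 4Dᵢτ))` with fractions `fᵢ` on the
  simplex; the apparent `Dᵢ` absorb the localization error as `σ²/τ`.
  Fitting is constrained least squares on the empirical CDF, with
  multi-start initialisation and an R²-gain stopping rule for the number
  of components. Confinement detection (stays within 120 nm of the local
  centroid for ≥ 9 steps), confined/free/transition track classification
  and projection of pooled tracks into a standardized 3×1 µm cell complete
  the picture of where each enzyme works.
* **Expression-onset timing.** Dual-reporter (green MTase / red REase)
  time courses, single-cell or bulk, are reduced to onset times — the
  first sampled time the background-subtracted signal stays above
  threshold — and to red-minus-green delay distributions, compared
  between genotypes with a two-tailed unpaired Student's t-test.
* **Plate-assay statistics.** Conjugative transfer frequencies
  (transconjugants per recipient), genotype-effect ratios with
  delta-method error propagation `sd(a/b) = (a/b)·√((sdₐ/a)² + (sd_b/b)²)`,
  efficiency of plaque formation, and thermosensitive-plasmid survival
  ratios.

Because the underlying microscopy and mating raw data are not public,
`rmdynamics.simulate` generates all inputs with known ground truth:
multi-state Brownian tracks inside a spherocylindrical cell (optionally
nucleoid-confined), and per-cell/bulk fluorescence onset data for the
C-present (+10 min REase delay) and C-deleted (−15 min) genotypes. Every
recovery claim in the test suite is made against that ground truth.

## Worked example

Simulate MTase-like tracks (occupancies 26 % static / 42 % constrained /
32 % free, D = 0.01/0.35/1.2 µm²/s, 20 ms frames, 30 nm localization
error) and decompose the squared-displacement distribution:

```python
from rmdynamics import (CellModelParams, simulate_tracks,
                        squared_displacements, fit_rayleigh_mixture)
from rmdynamics.simulate import MTASE_LIKE

cell = CellModelParams(confine_slow_states_to_nucleoid=True)
tracks = simulate_tracks(MTASE_LIKE(seed=1), cell, n_tracks=4000)
sqd = squared_displacements(tracks, lag=1, min_steps=5)
print(fit_rayleigh_mixture(sqd, k=3, loc_sigma=0.03).summary())
```

```
Rayleigh-mixture SQD fit
========================================
components:        3
observations:      31940
lag time tau:      20.0 ms
loc. sigma used:   30.0 nm
R-squared (CDF):   0.99999
----------------------------------------
 pop   D [um^2/s]      D_app   fraction
   1       0.0107     0.0557      0.252
   2       0.2996     0.3446      0.403
   3       0.9696     1.0146      0.345
```

The slowest population (DNA-bound molecules) is recovered at 25 %
against a 26 % ground truth; the fastest D is biased low because the
cell wall truncates long jumps — expected for free diffusion at
~1 µm²/s in a 1 µm-wide cell.

Transfer-frequency ratios propagate uncertainty the same way the mating
table does:

```python
from rmdynamics import FrequencyMeasurement, ratio_with_sd
wt  = FrequencyMeasurement("WT R+C+", (), 5.8e-7, 1.9e-7, False)
noc = FrequencyMeasurement("R+C-",   (), 1.3e-7, 0.4e-7, False)
print("C+/C- =", ratio_with_sd(wt, noc))   # C+/C- = 4.5 +/- 2.0
```

A `rmdynamics` console command exposes each stage
(`simulate-tracks`, `simulate-expression`, `sqd-fit`, `confinement`,
`project`, `timing`, `assay`) and `rmdynamics all` runs the whole
pipeline end to end from one seed.

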