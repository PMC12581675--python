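# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ramanfp`. Section order follows the pipeline.

## Scope and data model

The unit of analysis is a biological sample measured repeatedly by Raman
microspectroscopy in the fingerprint region. A `Spectrum` is a strictly
ascending wavenumber axis (cm⁻¹) with intensities in arbitrary units; a
`SpectrumSet` collects a sample's replicates (axes need not match — the
common grid is established during preprocessing); a `Fingerprint` is the
averaged, baseline-corrected, normalized spectrum of one sample. Sample
metadata (`CohortTable`) carries two crossed categorical factors — group
and timepoint — and numeric phenotype columns with explicit missing values.
Spectra travel as delimited text (two-column, or wide-matrix with one
replicate per column); floats are written with full `repr` precision so
round trips are exact. No proprietary instrument formats are read.

## Synthetic cohorts

The generator emulates a three-group (young control / old control / old
hypoxia-treated) × three-timepoint (baseline, 4 d, 7 d recovery) design
with 3 samples per cell and 30 replicate spectra per sample on a
600–1800 cm⁻¹ axis at 1 cm⁻¹ — the design and replicate depth typical of
small-animal muscle studies. Each replicate is

y(ν) = s_r · Σ_b A_sb · g_b(ν) + baseline(ν) + noise

* **Band library.** Twelve Gaussian bands at the standard tissue positions
  (755, 855, 935, 1004, 1095, 1245, 1270, 1320, 1340, 1450, 1608,
  1660 cm⁻¹) with FWHM 12–21 cm⁻¹ and amplitudes 0.25–1.0 AU relative to
  the 1450 CH₂ band. Gaussian rather than Lorentzian profiles are the
  default because heavy Lorentzian tails in the crowded amide-III cluster
  pile into a pseudo-baseline that no estimator can attribute cleanly to
  signal or background, which would make ground-truth band intensities
  ill-posed at the tens-of-percent level; with Gaussian shapes cross-band
  tail contamination is sub-percent and "true ratio" is well defined.
  Lorentzian `BandSpec`s remain fully supported. The 1450/1454 and
  1660/1662 cm⁻¹ ratio endpoints are treated as query positions on single
  generated bands: a ~1 cm⁻¹ band split is below instrument resolution.
* **Effects.** Per-(group, timepoint) multiplicative factors on band
  amplitudes are the ground-truth effect sizes. The defaults give old
  controls a recovery-phase signature (1450 and the fibrosis/amide-III
  markers up, 1660 and 1320 down) while hypoxia-treated old animals stay
  near young controls — the qualitative phenotype the pipeline is meant to
  resolve. Directions were chosen so the built-in phenotype couplings
  produce the expected correlation signs (lipid/protein negative and
  nucleic acid/lipid positive against grip strength).
* **Variability.** Between-sample band amplitudes are lognormal with
  CV 5%; each replicate carries a single lognormal intensity factor
  (CV 3%), so a sample's true ratios are replicate-invariant by
  construction.
* **Baseline and noise.** A broad Gaussian fluorescence hump (amplitude
  1.5 AU, center 1000 cm⁻¹, σ 350 cm⁻¹) plus a gentle linear trend;
  additive Gaussian noise (sd 0.01 AU ≈ 1% of the tallest band),
  multiplicative noise (CV 2%), and sparse positive spikes (rate 10⁻³ per
  point, amplitude 5 AU) emulating cosmic rays. These magnitudes are chosen
  for testability — they exercise every preprocessing stage at realistic
  orders — not calibrated to a particular instrument.
* **Phenotypes.** Each phenotype is linear in a sample's *true* ratio plus
  Gaussian noise (grip strength ← lipid/protein, slope −600 g per ratio
  unit, sd 15 g; COL-I %area ← fibrosis ratio; Sirius red %area ←
  collagen denaturation). Linearity in the true ratio makes the power of
  the correlation stage analytically controllable: for a target population
  correlation r the noise sd is |slope|·sd_x·√(1/r² − 1) with sd_x the
  ratio's population sd.
* **Seeding.** A master seed spawns per-(cell, sample, stream) seeds, so
  enlarging the design never perturbs existing samples, and the entire
  output is a pure function of the design object.

Ground truth records every drawn amplitude, replicate factor, true ratio
and phenotype; re-evaluating it reproduces the noiseless spectra exactly.

What the generator does **not** emulate: physical Raman cross sections,
instrument response and etaloning, wavenumber miscalibration, spatial
heterogeneity within a tissue section, and non-Gaussian fluorescence
photobleaching dynamics. Passing tests therefore demonstrate correctness
and calibration of the *analysis*, not instrument-level fidelity.

## Preprocessing

Fixed order per replicate: despike → AsLS baseline subtraction → linear
resampling onto the target grid (default 600–1800 cm⁻¹, step 1, both
endpoints) → normalization; the fingerprint is the pointwise replicate mean
renormalized under the same mode. Normalizing after baseline removal makes
the ratios scale-free; renormalizing the mean keeps ℓ² fingerprints on the
unit sphere. Processing is per-replicate, so replicate order is irrelevant.
Whether normalization should act per replicate or once on the average is
not settled practice; both orders are supported and the default is per
replicate with final renormalization.

**Despiking.** First differences are scored with the modified z-score
(0.6745·(d − median)/MAD). A maximal run of consecutive extreme differences
(|z| > 8 by default) containing both an upward and a downward jump marks a
spike; the points strictly inside the run are replaced by linear
interpolation of the nearest unflagged neighbours (single-direction extreme
runs are flagged only at the array boundary, where one-sided jumps are the
spike signature). Monotone band flanks produce same-direction jumps and are
never touched. Limitation: two adjacent spikes of *exactly* equal height
leave the middle difference unremarkable and split the run; such doublets
pass through. The z-scale also degenerates on noise-free synthetic input
whose differences are dominated by a single smooth band — realistic noise
restores it.

**AsLS.** Weights start at 1 (a symmetric Whittaker smooth), then
w = p above the current baseline and 1 − p below, re-solved to
`max_iter` = 10 or an L1 weight-change below 1e-6, with a final solve at
the final weights. Defaults λ = 10⁵, p = 0.01 are the standard operating
range for fingerprint-region tissue spectra on a ~1 cm⁻¹ grid; both are
exposed. Second differences are index-wise (no Δν weighting), which is
adequate because resampling to a uniform grid precedes any cross-spectrum
use. The system matrix diag(w) + λ·D₂ᵀD₂ is symmetric positive definite
and pentadiagonal and is solved by banded Cholesky (`solveh_banded`);
equivalence with a dense normal-equations solve is enforced to 1e-8 in the
test suite, as is the p = 0.5 limit against an independent dense Whittaker
smoother, and monotonicity of baseline roughness in λ.

Known limitation — **edge bias**: on a downward-curving baseline the
estimate near the axis ends sits below the data, those points receive
weight p, and nothing anchors the stiff extrapolation, so the baseline sags
by up to ~2–3% of the baseline scale over the last ~2λ^(1/4) grid points
(≈ 40 cm⁻¹ at the defaults). The effect is a fixed point of the AsLS
iteration itself, not of the solver or its initialization. The interior of
the axis recovers the true background within 2% at the generator's noise
levels. None of the default band-ratio windows (1235–1672 cm⁻¹) touch the
affected margin; users who need accurate baselines at the window edges
should acquire spectra with a margin beyond the analysis region.

**Normalization.** ℓ² (default), unit trapezoidal area, or none. All-zero
input is an error (undefined scale).

## Band ratios

Band intensity is read off the fingerprint by a windowed query: `point`
(nearest grid point), `window_max` (default; robust to the few-cm⁻¹
calibration shifts implied by "~" positions), or `window_area`
(trapezoidal). Default half-windows are 10 cm⁻¹, narrowed to 5 cm⁻¹ around
the crowded 1450/1454 and 1608/1662 neighbourhoods. Ratios are computed on
the averaged fingerprint (per-replicate computation is available for
variance estimation); a non-positive denominator marks that cell missing
and is reported without aborting the run. Published label-to-band
assignments for the 1340/1450 pair differ between sources (nucleic acids
vs lipids); ratio *names* here are bound to the wavenumber pairs and the
biochemical labels are annotation only.

## Embedding and separability

PCA (full SVD, deterministic, variance fractions reported) is the reference
2-D embedding; UMAP is an optional backend with small-cohort defaults
(n_neighbors = 5, min_dist = 0.1, euclidean, fixed random_state) since
stock neighbour counts exceed a 9–27-sample cohort. Separability is scored
by k-means (10 restarts, fixed seed) on the embedding followed by the best
cluster-to-label assignment (Hungarian algorithm on the confusion matrix);
k < 2 returns 1 by convention. With random labels the score sits above
chance (≈ 0.36–0.40 for k = 3 at n = 300) because of permutation optimism —
it is a relative, not an absolute, measure.

## Inference

* **Pearson correlations** use the exact t transform
  t = r√((n−2)/(1−r²)) against t(n−2), two-sided; |r| = 1 returns the
  smallest positive double rather than dividing by zero. Default pair
  family: grip strength vs lipid/protein and vs nucleic acid/lipid, COL-I
  vs fibrosis, Sirius red vs collagen denaturation; samples are pooled
  across groups, missing phenotypes dropped pairwise with n recorded;
  p-values are unadjusted by default with Holm adjustment behind a flag.
  Note that only directly coupled pairs are guaranteed strong correlations
  in synthetic cohorts: an uncoupled ratio sharing a band with the coupled
  one (e.g. nucleic acid/lipid sharing 1340 with lipid/protein) combines a
  positive between-group and a negative within-group component and can pool
  to a weak correlation.
* **Two-way ANOVA** is fixed-effects with Type-II sums of squares (each
  main effect adjusted for the other; the interaction for both), which
  remains well defined for unbalanced complete designs — repeated-measures
  or mixed-effects structure is deliberately out of scope, and unbalanced
  data are handled by the Type-II fixed-effects path rather than a mixed
  model. Fitting is delegated to statsmodels OLS/anova_lm and verified
  against dense nested least-squares fits to 1e-8. Degenerate inputs are
  defined rather than fatal: zero-variability terms report F = 0, p = 1;
  saturated designs (one observation per cell) report sums of squares with
  F and p undefined. Post-hoc comparisons are Welch t tests between groups
  within each timepoint, Holm-adjusted as one family (Holm delegates to
  statsmodels and is oracle-checked against the stepwise definition,
  including ties). Dunnett's procedure is not implemented.
* **Significance** defaults to α = 0.05.

## Validation design and problem sizes

The acceptance layer (tests/test_acceptance.py, scripts/acceptance.py)
fixes the problem sizes: 50 random spectra × 3 λ × 2 p for solver
equivalence; 30 baseline-recovery runs (3 noise levels, sd 0–0.015 AU,
× 10 seeds) scored as max deviation outside 3 FWHM of any band relative to
the baseline scale; full-design cohorts for ratio recovery (noiseless max
error vs ground truth, and median error at additive SNR 20); 10,000
ground-truth-level cohorts of n = 18 pooled recovery samples for the
type-I error of the correlation stage and 1,000 for power at population
r = 0.9; 100 random 2×3 ANOVA designs and 1,000 Holm vectors against their
oracles; 20 seeds × effect sizes {1.0, 1.25, 1.5} (groups multiplied by
{1/m, 1, m} on the 1340 band) for separability; and a byte-level
comparison of two identically seeded demo runs. Monte-Carlo cohorts for
the correlation criteria are drawn at the ground-truth level (amplitudes →
true ratios → phenotypes) because the coupling is defined on true ratios
and the Pearson stage consumes per-sample scalars; spectral rendering and
preprocessing are exercised by the recovery, separability and end-to-end
checks instead. The baseline-recovery criterion is the one place the
pipeline misses its nominal band: the AsLS edge bias described above keeps
the interior within 2% but pushes the full-axis maximum to ~2–3% at the
higher noise levels, and the corresponding test is left failing rather
than masked.
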