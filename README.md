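# ramanfp — Raman spectral fingerprint phenotyping

`ramanfp` is a tested, reusable pipeline for Raman biospectroscopy of
tissue: it turns replicate spectra per biological sample into averaged
spectral **fingerprints**, extracts scale-free **band ratios** with
biochemical meaning, maps cohorts into low-dimensional embeddings, and links
ratios to group structure and phenotype measurements with standard
inference. It is written for studies of the 600–1800 cm⁻¹ fingerprint
region — e.g. muscle tissue across age, treatment and recovery timepoints —
where each sample is measured ~30 times and the analysis must be robust to
fluorescence background, cosmic-ray spikes and arbitrary intensity scale.

Because raw tissue spectra are rarely shareable, the package ships a
first-class **synthetic cohort generator** with known ground truth (band
amplitudes, effect sizes, phenotype couplings), so every stage of the
analysis is verifiable end to end.

## The analysis in brief

For each replicate spectrum *y(ν)*:

1. **Despiking** — cosmic-ray artifacts are detected as runs of extreme
   first differences (modified z-score) containing both an up- and a
   down-jump, and repaired by linear interpolation.
2. **Baseline correction (asymmetric least squares, AsLS)** — the
   background *z* minimizes

   Σᵢ wᵢ (yᵢ − zᵢ)² + λ Σᵢ (Δ²z)ᵢ² ,  wᵢ = p if yᵢ > zᵢ, else 1 − p,

   iterated to a fixed point (defaults λ = 10⁵, p = 0.01). Small *p* makes
   lying *below* the peaks cheap, so *z* tracks the smooth fluorescence
   hump. The solver is a banded Cholesky factorization; it is validated
   against dense normal-equations and Whittaker-smoother oracles to 1e-8.
3. **Resampling and normalization** — linear interpolation onto a common
   600–1800 cm⁻¹ grid, then ℓ² normalization; the per-sample fingerprint is
   the renormalized replicate mean.
4. **Band ratios** — windowed peak intensities at the classic fingerprint
   markers, combined into six ratios: ~1450/1660, ~1340/1660, ~1340/1450
   (cellular composition), ~1608/1662 (tissue fibrosis), ~1270/1245
   (collagen denaturation) and ~1320/1454 cm⁻¹ (structured collagen).
   Ratios are exactly invariant to intensity rescaling.
5. **Distribution mapping** — PCA (reference, deterministic) or UMAP
   (optional backend) embeddings of sample fingerprints, plus a k-means
   cluster-agreement score quantifying group separability.
6. **Inference** — two-way ANOVA (group × timepoint, Type-II sums of
   squares, Holm-adjusted post-hoc t tests) per ratio, and Pearson
   correlations between ratios and phenotypes (grip strength, collagen
   staining), with p from the exact t transform.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/03_band_ratios.py` simulates the default cohort
(3 groups × 3 timepoints × 3 samples × 30 replicates), preprocesses it and
prints the group means of the six ratios at 4 days of recovery:

```
group means at 4 d recovery:
               nucleic_acid_protein  lipid_protein  nucleic_acid_lipid  tissue_fibrosis  collagen_denaturation  structured_collagen
group
young_control                 1.124          0.835               0.741            0.407                  1.024                0.541
old_control                   1.505          0.990               0.657            0.565                  1.081                0.353
old_hypoxia                   1.208          0.877               0.726            0.420                  1.170                0.528

recovery vs ground truth: median 1.1%, max 3.7% over 162 ratio estimates
```

Old controls carry the simulated aging signature — elevated fibrosis
(0.565 vs 0.407) and depressed structured collagen — while hypoxia-treated
old samples sit near the young controls; the last line shows how closely
the full pipeline (baseline correction included) recovers the generator's
ground-truth ratios under measurement noise. `python
examples/05_statistics.py` then shows the fibrosis ratio's group term
rejecting strongly (F ≈ 36, p < 1e-6) and the coupled ratio–phenotype
pairs reaching |r| ≈ 0.8–0.96.

The same chain is available as a CLI:

```bash
ramanfp run --demo --seed 0 --out demo/     # simulate + full analysis
ramanfp sim --out data/ --seed 1            # spectra + cohort.csv + ground truth
ramanfp preprocess --in data/ --out fingerprints.csv
ramanfp ratios --fingerprints fingerprints.csv --out ratios.csv
ramanfp embed --fingerprints fingerprints.csv --method pca --out embedding.csv
ramanfp stats --ratios ratios.csv --cohort data/cohort.csv --out stats/
```

All outputs are plain CSV/JSON; `manifest.json` records seeds, versions and
content hashes, and a rerun with the same seed reproduces every data file
byte for byte.

## Layout

```
src/ramanfp/        library (io, spectra, cohort, simulate, preprocess,
                    bands, embedding, stats, pipeline, cli)
examples/           one narrative script per capability
tests/              pytest suite incl. oracle-based acceptance tests
scripts/acceptance.py
docs/methods.md     model, parameter and design documentation
```
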