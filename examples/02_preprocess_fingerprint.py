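"""Preprocess one sample's replicates into its spectral fingerprint.

Chain per replicate: despike -> AsLS baseline subtraction -> resample to a
1 cm^-1 grid -> l2 normalization; the fingerprint is the renormalized mean.
"""

import numpy as np

from ramanfp import (
    asls_baseline,
    average_to_fingerprint,
    default_design,
    simulate_cohort,
)

sets, _, _ = simulate_cohort(default_design(seed=1))
sample = sets[0]

rep = sample.replicates[0]
baseline = asls_baseline(rep)
print(f"sample {sample.sample_id}: {len(sample)} replicates, "
      f"{len(rep)} points each")
print(f"raw intensity range:      {rep.intensities.min():.3f} .. {rep.intensities.max():.3f} AU")
print(f"estimated baseline range: {baseline.min():.3f} .. {baseline.max():.3f} AU")

fp = average_to_fingerprint(sample)
print(f"fingerprint grid: {fp.wavenumbers[0]:.0f}-{fp.wavenumbers[-1]:.0f} cm^-1, "
      f"{len(fp)} points, averaged over {fp.n_replicates} replicates")
print(f"fingerprint Euclidean norm: {np.linalg.norm(fp.intensities):.12f}")
# The norm is exactly 1: fingerprints live on the unit sphere so that all
# downstream band ratios are scale-free.
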