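"""Embed sample fingerprints in 2-D and score group separability.

PCA is the deterministic reference embedding; cluster agreement is the
best label-permutation match between k-means clusters and group labels.
"""

from ramanfp import (
    FingerprintMatrix,
    average_to_fingerprint,
    cluster_agreement,
    default_design,
    embed_fingerprints,
    simulate_cohort,
)

sets, cohort, _ = simulate_cohort(default_design(seed=3))
fps = [average_to_fingerprint(s) for s in sets]
emb = embed_fingerprints(FingerprintMatrix.from_fingerprints(fps), method="pca")

print("variance fractions of the first two components:",
      [round(float(v), 3) for v in emb.variance_fractions])
meta = cohort.data.set_index("sample_id")
groups = meta.loc[emb.sample_ids, "group"].to_numpy()
timepoints = meta.loc[emb.sample_ids, "timepoint"].to_numpy()
print(f"cluster agreement with groups:     {cluster_agreement(emb, groups):.3f}")
print(f"cluster agreement with timepoints: {cluster_agreement(emb, timepoints):.3f}")
# Group structure dominates the embedding: the aging effect separates old
# controls, while hypoxia-treated old samples overlap the young controls.
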