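"""Low-dimensional embedding of sample fingerprints (distribution mapping)
and a k-means cluster-agreement score for separability testing.

PCA is the reference embedding: deterministic, seed-free, with reported
per-component variance fractions. UMAP is an optional nonlinear backend
(delegated to umap-learn) with defaults shrunk for tiny cohorts, where the
stock neighbour count would exceed the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .spectra import Fingerprint

__all__ = [
    "FingerprintMatrix",
    "EmbeddingResult",
    "embed_fingerprints",
    "cluster_agreement",
]


@dataclass
class FingerprintMatrix:
    """Sample fingerprints stacked on one shared wavenumber grid."""

    sample_ids: list[str]
    matrix: np.ndarray  # samples x grid points
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x grid)")
        if self.matrix.shape != (len(self.sample_ids), len(self.grid)):
            raise ValueError(
                f"shape mismatch: {self.matrix.shape} vs "
                f"({len(self.sample_ids)} samples, {len(self.grid)} grid points)"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("fingerprint matrix contains non-finite values")

    @classmethod
    def from_fingerprints(cls, fingerprints: list[Fingerprint]) -> "FingerprintMatrix":
        if not fingerprints:
            raise ValueError("no fingerprints given")
        grid = fingerprints[0].wavenumbers
        for f in fingerprints[1:]:
            if len(f.wavenumbers) != len(grid) or not np.array_equal(f.wavenumbers, grid):
                raise ValueError(
                    f"fingerprint {f.sample_id!r} is not on the shared grid"
                )
        return cls(
            [f.sample_id for f in fingerprints],
            np.vstack([f.intensities for f in fingerprints]),
            grid.copy(),
        )

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x 2
    method: str
    seed: int
    params: dict = field(default_factory=dict)
    variance_fractions: np.ndarray | None = None  # pca only


def embed_fingerprints(
    m: FingerprintMatrix,
    method: str = "pca",
    seed: int = 0,
    params: dict | None = None,
) -> EmbeddingResult:
    """Embed sample fingerprints into 2-D.

    ``pca`` uses a full (deterministic) SVD and also reports the variance
    fraction of each component. ``umap`` delegates to umap-learn with
    small-cohort defaults (n_neighbors=5, min_dist=0.1, euclidean metric)
    and a fixed random_state, so reruns are reproducible.
    """
    if len(m) < 3:
        raise ValueError("embedding needs at least 3 samples")
    params = dict(params or {})
    if method == "pca":
        n_comp = min(2, len(m) - 1, m.matrix.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        coords = pca.fit_transform(m.matrix)
        if coords.shape[1] < 2:  # degenerate: pad a zero second axis
            coords = np.hstack([coords, np.zeros((len(m), 2 - coords.shape[1]))])
        return EmbeddingResult(
            list(m.sample_ids), coords, "pca", seed,
            {"n_components": 2, **params},
            variance_fractions=pca.explained_variance_ratio_.copy(),
        )
    if method == "umap":
        n_neighbors = int(params.pop("n_neighbors", 5))
        if n_neighbors >= len(m):
            raise ValueError(
                f"umap n_neighbors={n_neighbors} must be below the sample count "
                f"({len(m)}); lower n_neighbors for small cohorts"
            )
        import umap  # optional dependency, imported lazily

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=float(params.pop("min_dist", 0.1)),
            metric=params.pop("metric", "euclidean"),
            random_state=seed,
            **params,
        )
        coords = np.asarray(reducer.fit_transform(m.matrix), dtype=float)
        return EmbeddingResult(
            list(m.sample_ids), coords, "umap", seed,
            {"n_neighbors": n_neighbors, "min_dist": reducer.min_dist, "metric": reducer.metric},
        )
    raise ValueError(f"unknown embedding method {method!r}")


def cluster_agreement(e: EmbeddingResult, labels, k: int | None = None, seed: int = 0) -> float:
    """Best label-permutation agreement between k-means clusters of the
    embedding and given categorical labels.

    k-means runs with 10 restarts at a fixed seed; the cluster-to-label
    assignment maximizing agreement is found on the confusion matrix
    (Hungarian algorithm). By convention k < 2 returns 1.0.
    """
    labels = np.asarray(labels)
    if len(labels) != len(e.sample_ids):
        raise ValueError("one label per embedded sample required")
    uniq = np.unique(labels)
    if k is None:
        k = len(uniq)
    if k < 2:
        return 1.0
    if len(labels) < k:
        raise ValueError("fewer samples than clusters")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(e.coordinates)
    # confusion: clusters x label levels
    conf = np.zeros((k, len(uniq)), dtype=int)
    code = {lab: j for j, lab in enumerate(uniq)}
    for a, lab in zip(assign, labels):
        conf[a, code[lab]] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(labels))
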