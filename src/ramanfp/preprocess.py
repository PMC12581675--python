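"""Spectral preprocessing: despiking, AsLS baseline correction, normalization,
resampling and replicate averaging.

The processing chain for one biological sample is fixed:

    despike -> AsLS baseline subtraction -> resample to a common grid
            -> normalize -> average replicates -> renormalize

Asymmetric least squares (AsLS) is iteratively reweighted Whittaker
smoothing: the baseline z minimizes

    sum_i w_i (y_i - z_i)^2 + lam * sum_i (Delta^2 z)_i^2

with w_i = p where y_i > z_i and w_i = 1 - p otherwise. Small p (default
0.01) makes the penalty for lying *below* the signal cheap, so z settles
under the peaks and tracks the smooth fluorescence background. Second
differences are taken index-wise; replicates are resampled onto a uniform
grid before any cross-spectrum use, so no Delta-nu weighting is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded

from .spectra import Fingerprint, Spectrum, SpectrumSet

__all__ = [
    "AsLSParams",
    "PreprocessConfig",
    "despike",
    "asls_baseline",
    "whittaker_smooth",
    "normalize",
    "preprocess_spectrum",
    "average_to_fingerprint",
]


@dataclass(frozen=True)
class AsLSParams:
    """AsLS tuning knobs.

    lam : smoothness penalty weight (unitless); larger -> stiffer baseline.
    p : asymmetry weight in (0, 1); small values keep the baseline below peaks.
    max_iter : reweighting iterations.
    tol : L1 change in the weight vector at which iteration stops.

    Defaults (1e5, 0.01, 10, 1e-6) are a standard operating range for
    fingerprint-region tissue spectra on a ~1 cm^-1 grid.
    """

    lam: float = 1e5
    p: float = 0.01
    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the full per-sample processing chain."""

    despike: bool = True
    despike_z: float = 8.0
    asls: AsLSParams = field(default_factory=AsLSParams)
    normalization: str = "l2"  # {l2, area, none}
    grid_start: float = 600.0
    grid_stop: float = 1800.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.normalization not in ("l2", "area", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if not (self.grid_start < self.grid_stop):
            raise ValueError("grid_start must be < grid_stop")

    def grid(self) -> np.ndarray:
        """Target wavenumber grid, both endpoints included."""
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


# ---------------------------------------------------------------------------
# despiking


def despike(s: Spectrum, z_threshold: float = 8.0) -> Spectrum:
    """Remove cosmic-ray spikes by first-difference outlier detection.

    First differences with modified z-score (0.6745 * (d - median) / MAD)
    above ``z_threshold`` are "extreme jumps". A maximal run of consecutive
    extreme jumps containing both an upward and a downward jump is the
    signature of a spike (or a run of spikes): the points strictly inside the
    run are flagged; a single-direction run touching the array boundary flags
    the outer points instead. Flagged points are replaced by linear
    interpolation of the nearest unflagged neighbours, which bridges flagged
    runs. Smooth spectra pass through unchanged (monotone band flanks produce
    same-direction jumps and are never flagged).
    """
    y = s.intensities
    n = len(y)
    if n < 8:
        raise ValueError("despike requires at least 8 points")
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = mad if mad > 0 else np.mean(np.abs(d - med))
    if scale == 0:  # perfectly regular signal, nothing to flag
        return s.copy()
    z = 0.6745 * (d - med) / scale

    flagged = np.zeros(n, dtype=bool)
    extreme = np.abs(z) > z_threshold
    i = 0
    while i < len(d):
        if not extreme[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(d) and extreme[j + 1]:
            j += 1
        run = d[i : j + 1]
        if (run > 0).any() and (run < 0).any():
            flagged[i + 1 : j + 1] = True
        elif i == 0:  # one-sided jump off the left edge
            flagged[0 : j + 1] = True
        elif j == len(d) - 1:  # one-sided jump at the right edge
            flagged[i + 1 : n] = True
        i = j + 1

    if not flagged.any():
        return s.copy()
    x = s.wavenumbers
    good = ~flagged
    out = y.copy()
    out[flagged] = np.interp(x[flagged], x[good], y[good])
    return Spectrum(x.copy(), out, s.label)


# ---------------------------------------------------------------------------
# Whittaker / AsLS


def _whittaker_banded(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve (diag(w) + lam * D2'D2) z = w*y with a banded Cholesky solver.

    D2 is the (n-2) x n second-difference operator; the system matrix is
    symmetric positive definite and pentadiagonal.
    """
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points for a second-difference penalty")
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.full(n - 2, 1.0)

    ab = np.zeros((3, n))
    ab[0, 2:] = lam * d2
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0 + w
    return solveh_banded(ab, w * y, lower=False)


def whittaker_smooth(y: np.ndarray, lam: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted Whittaker smoother with a squared second-difference penalty."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != y.shape or np.any(w < 0):
        raise ValueError("weights must be non-negative and match y")
    return _whittaker_banded(y, w, lam)


def asls_baseline(s: Spectrum, params: AsLSParams | None = None) -> np.ndarray:
    """Estimate the fluorescence/background baseline by AsLS.

    Returns the baseline vector z (AU, same length as the spectrum):
    iteratively reweighted Whittaker smoothing with weights p above the
    current baseline and 1-p below it, run to ``max_iter`` or until the L1
    change of the weight vector drops under ``tol``; the returned z minimizes
    the objective at the final weights.
    """
    params = params or AsLSParams()
    y = s.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    w = np.ones_like(y)
    for _ in range(params.max_iter):
        z = _whittaker_banded(y, w, params.lam)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        if np.abs(w_new - w).sum() < params.tol:
            w = w_new
            break
        w = w_new
    return _whittaker_banded(y, w, params.lam)


# ---------------------------------------------------------------------------
# normalization / resampling / averaging


def _normalize_vector(x: np.ndarray, y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return y.copy()
    if mode == "l2":
        nrm = float(np.linalg.norm(y))
        if nrm == 0.0:
            raise ValueError("cannot l2-normalize an all-zero spectrum")
        return y / nrm
    if mode == "area":
        area = float(np.trapezoid(y, x))
        if area == 0.0:
            raise ValueError("cannot area-normalize: trapezoidal integral is zero")
        return y / area
    raise ValueError(f"unknown normalization mode {mode!r}")


def normalize(s: Spectrum, mode: str = "l2") -> Spectrum:
    """Rescale a spectrum: unit Euclidean norm (l2), unit trapezoidal
    integral over the axis (area), or identity (none)."""
    return Spectrum(s.wavenumbers.copy(), _normalize_vector(s.wavenumbers, s.intensities, mode), s.label)


def _resample(s: Spectrum, grid: np.ndarray, who: str) -> np.ndarray:
    if s.wavenumbers[0] > grid[0] + 1e-9 or s.wavenumbers[-1] < grid[-1] - 1e-9:
        raise ValueError(
            f"replicate {who} covers [{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}] cm^-1 "
            f"and does not span the target grid [{grid[0]:g}, {grid[-1]:g}]"
        )
    return np.interp(grid, s.wavenumbers, s.intensities)


def preprocess_spectrum(s: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Run the per-replicate chain: despike, subtract the AsLS baseline,
    resample to the target grid, normalize."""
    config = config or PreprocessConfig()
    grid = config.grid()
    t = despike(s, config.despike_z) if config.despike else s
    z = asls_baseline(t, config.asls)
    corrected = Spectrum(t.wavenumbers, t.intensities - z, t.label)
    resampled = _resample(corrected, grid, s.label or "<unnamed>")
    return Spectrum(grid, _normalize_vector(grid, resampled, config.normalization), s.label)


def average_to_fingerprint(spectra: SpectrumSet, config: PreprocessConfig | None = None) -> Fingerprint:
    """Average a sample's preprocessed replicates into its fingerprint.

    Each replicate is processed independently (so replicate order cannot
    matter), averaged pointwise, and the mean is renormalized under the same
    mode so that e.g. an l2 fingerprint stays on the unit sphere.
    """
    config = config or PreprocessConfig()
    grid = config.grid()
    processed = []
    for i, rep in enumerate(spectra.replicates):
        who = rep.label or f"replicate {i}"
        t = despike(rep, config.despike_z) if config.despike else rep
        z = asls_baseline(t, config.asls)
        corrected = Spectrum(t.wavenumbers, t.intensities - z, t.label)
        resampled = _resample(corrected, grid, who)
        processed.append(_normalize_vector(grid, resampled, config.normalization))
    mean = np.mean(processed, axis=0)
    mean = _normalize_vector(grid, mean, config.normalization)
    return Fingerprint(spectra.sample_id, grid, mean, n_replicates=len(processed))
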