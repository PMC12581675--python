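"""Core in-memory containers for Raman spectra.

Conventions used throughout the package:

* the spectral axis is the Raman shift in cm^-1, stored strictly ascending;
* intensities are in arbitrary units (AU) — no radiometric calibration is
  attempted;
* the biological "fingerprint region" is 600–1800 cm^-1, and a *fingerprint*
  is the averaged, baseline-corrected, normalized spectrum of one biological
  sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "SpectrumSet", "Fingerprint"]


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class Spectrum:
    """One replicate Raman measurement.

    Parameters
    ----------
    wavenumbers
        Raman shift axis in cm^-1, strictly ascending.
    intensities
        Scattered intensity in arbitrary units, same length as the axis.
    label
        Optional free-text identifier (e.g. replicate name).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = _as_float_vector(self.wavenumbers, "wavenumbers")
        self.intensities = _as_float_vector(self.intensities, "intensities")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError(
                f"axis and intensities differ in length: "
                f"{len(self.wavenumbers)} vs {len(self.intensities)}"
            )
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        dv = np.diff(self.wavenumbers)
        if np.any(dv <= 0):
            raise ValueError("wavenumbers must be strictly ascending")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.intensities.copy(), self.label)


@dataclass
class SpectrumSet:
    """Replicate spectra belonging to one biological sample.

    Replicate axes need not match each other; putting everything on a common
    grid is the preprocessing stage's job.
    """

    sample_id: str
    replicates: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"SpectrumSet {self.sample_id!r} has no replicates")
        for r in self.replicates:
            if not isinstance(r, Spectrum):
                raise TypeError("replicates must be Spectrum instances")

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass
class Fingerprint:
    """Averaged, baseline-corrected, normalized spectrum of one sample."""

    sample_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = _as_float_vector(self.wavenumbers, "wavenumbers")
        self.intensities = _as_float_vector(self.intensities, "intensities")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError("axis and intensities differ in length")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def scaled(self, c: float) -> "Fingerprint":
        """Return a copy with intensities multiplied by ``c``."""
        return Fingerprint(
            self.sample_id, self.wavenumbers.copy(), self.intensities * c,
            self.n_replicates,
        )
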