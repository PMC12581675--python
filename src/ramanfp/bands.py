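"""Band intensities and the six named band ratios.

Ratios of two band intensities are scale-free biochemical composition
statistics; the default set mirrors the fingerprint-region markers commonly
used for tissue state:

========================  ==================  ==========================
name                      wavenumber pair     annotation
========================  ==================  ==========================
nucleic_acid_protein      ~1450 / ~1660       nucleic acid / protein
lipid_protein             ~1340 / ~1660       lipid / protein
nucleic_acid_lipid        ~1340 / ~1450       nucleic acid / lipid
tissue_fibrosis           ~1608 / ~1662       fibrosis marker
collagen_denaturation     ~1270 / ~1245       amide III integrity
structured_collagen       ~1320 / ~1454       collagen organization
========================  ==================  ==========================

Note: published label-to-band assignments for the 1340/1450 region are not
fully consistent across sources (1340 cm^-1 is variously read as CH
deformation of nucleic acids or of lipids); the ratio *names* here are keyed
by the wavenumber pairs, and the biochemical labels are annotation only.

Extraction is windowed (the "~" in ~1340 cm^-1): the default mode takes the
maximum over a +/-10 cm^-1 window (+/-5 cm^-1 near the crowded 1450/1454 and
1608/1662 neighbourhoods), which is robust to small calibration shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Fingerprint

__all__ = [
    "BandQuery",
    "RatioDefinition",
    "band_intensity",
    "default_ratio_set",
    "compute_ratios",
]

#: centers where a +/-5 cm^-1 half window avoids overlap with a near neighbour
_NARROW_CENTERS = frozenset({1450.0, 1454.0, 1608.0, 1662.0})


@dataclass(frozen=True)
class BandQuery:
    """Where and how to read one band intensity off a fingerprint."""

    center: float
    half_window: float = 10.0
    mode: str = "window_max"  # {point, window_max, window_area}

    def __post_init__(self) -> None:
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")
        if self.mode not in ("point", "window_max", "window_area"):
            raise ValueError(f"unknown band query mode {self.mode!r}")

    @property
    def lo(self) -> float:
        return self.center - self.half_window

    @property
    def hi(self) -> float:
        return self.center + self.half_window


@dataclass(frozen=True)
class RatioDefinition:
    name: str
    numerator: BandQuery
    denominator: BandQuery
    label: str = ""

    def __post_init__(self) -> None:
        if self.numerator.center == self.denominator.center:
            raise ValueError(f"ratio {self.name!r}: numerator equals denominator center")


def band_intensity(f: Fingerprint, q: BandQuery) -> float:
    """Read one band intensity (AU) off a fingerprint.

    point        intensity at the grid point nearest the center
    window_max   maximum over [center - hw, center + hw]
    window_area  trapezoidal integral over the window
    """
    x, y = f.wavenumbers, f.intensities
    if q.lo < x[0] or q.hi > x[-1]:
        raise ValueError(
            f"band window [{q.lo:g}, {q.hi:g}] cm^-1 outside the "
            f"fingerprint axis [{x[0]:g}, {x[-1]:g}]"
        )
    if q.mode == "point":
        return float(y[int(np.argmin(np.abs(x - q.center)))])
    sel = (x >= q.lo) & (x <= q.hi)
    if not sel.any():
        sel = np.zeros_like(sel)
        sel[int(np.argmin(np.abs(x - q.center)))] = True
    if q.mode == "window_max":
        return float(np.max(y[sel]))
    return float(np.trapezoid(y[sel], x[sel]))


def default_ratio_set(mode: str = "window_max") -> list[RatioDefinition]:
    """The six standard fingerprint-region band ratios (see module docstring)."""

    def q(center: float) -> BandQuery:
        hw = 5.0 if center in _NARROW_CENTERS else 10.0
        return BandQuery(center, hw, mode)

    return [
        RatioDefinition("nucleic_acid_protein", q(1450.0), q(1660.0), "nucleic acid/protein"),
        RatioDefinition("lipid_protein", q(1340.0), q(1660.0), "lipid/protein"),
        RatioDefinition("nucleic_acid_lipid", q(1340.0), q(1450.0), "nucleic acid/lipid"),
        RatioDefinition("tissue_fibrosis", q(1608.0), q(1662.0), "tissue fibrosis"),
        RatioDefinition("collagen_denaturation", q(1270.0), q(1245.0), "collagen denaturation"),
        RatioDefinition("structured_collagen", q(1320.0), q(1454.0), "structured collagen"),
    ]


@dataclass
class RatioTable:
    """Per-sample values for a set of ratio definitions.

    ``values`` is indexed by sample_id with one column per ratio; cells whose
    denominator intensity was <= 0 are missing (NaN) and listed in
    ``errors`` as (sample_id, ratio name, message).
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    errors: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ratio_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


def compute_ratios(
    fingerprints: list[Fingerprint] | Fingerprint,
    definitions: list[RatioDefinition] | None = None,
) -> RatioTable:
    """Evaluate band ratios on averaged fingerprints.

    A non-positive denominator intensity is recorded as an error for that
    cell (value left missing) and the computation continues.
    """
    if isinstance(fingerprints, Fingerprint):
        fingerprints = [fingerprints]
    defs = definitions if definitions is not None else default_ratio_set()
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("ratio definition names must be unique")

    errors: list[tuple[str, str, str]] = []
    rows = {}
    for f in fingerprints:
        row = {}
        for d in defs:
            num = band_intensity(f, d.numerator)
            den = band_intensity(f, d.denominator)
            if den <= 0:
                errors.append(
                    (f.sample_id, d.name, f"denominator intensity {den:g} <= 0")
                )
                row[d.name] = np.nan
            else:
                row[d.name] = num / den
        rows[f.sample_id] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    values.index.name = "sample_id"
    provenance = {
        d.name: {
            "numerator": (d.numerator.center, d.numerator.half_window, d.numerator.mode),
            "denominator": (d.denominator.center, d.denominator.half_window, d.denominator.mode),
            "label": d.label,
        }
        for d in defs
    }
    return RatioTable(values, provenance, errors)
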