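"""Seeded synthetic Raman cohorts with known ground truth.

The generator emulates a disuse-atrophy recovery study: 3 groups
(young_control, old_control, old_hypoxia) x 3 timepoints (BL, 4d, 7d) x 3
samples per cell, with 30 replicate spectra per sample on a 600-1800 cm^-1
axis. Each replicate is a sum of Lorentzian/Gaussian bands on a smooth
fluorescence background plus measurement noise:

    y(nu) = s_r * sum_b A_sb * profile_b(nu) + baseline(nu) + noise

* ``A_sb`` — per-sample band amplitudes: library amplitude x the cell's
  (group, timepoint) multiplier x a lognormal between-sample factor;
* ``s_r`` — a scalar lognormal within-sample replicate factor, so band
  ratios are identical across a sample's replicates by construction;
* noise — per-point additive Gaussian + per-point multiplicative Gaussian +
  sparse positive cosmic-ray spikes.

Group/timepoint multipliers are the ground-truth effect sizes. Phenotypes
(grip strength, collagen stains) are linear in a sample's *true* band ratio
plus Gaussian noise, which makes correlation-stage power analytically
controllable. The closely spaced 1450/1454 and 1660/1662 query points fall
on single generated bands: a ~1 cm^-1 split is below instrument resolution,
and the generator stays honest about that.

Seeding is hierarchical (master seed -> per-sample -> per-replicate), so
enlarging the design never perturbs already-generated samples.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandQuery, RatioDefinition, band_intensity, default_ratio_set
from .cohort import CohortTable
from .spectra import Fingerprint, Spectrum, SpectrumSet

__all__ = [
    "BandSpec",
    "BaselineSpec",
    "NoiseSpec",
    "PhenotypeCoupling",
    "CohortDesign",
    "GroundTruth",
    "SampleTruth",
    "default_band_library",
    "default_design",
    "simulate_spectrum",
    "simulate_cohort",
    "draw_true_ratios",
    "simulate_coupling_trials",
    "calibrate_coupling_sd",
]

# spawn-key stream tags under one (cell, sample) node
_AMPL, _REP, _PHENO = 0, 1, 2


@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: Lorentzian (width = HWHM) or Gaussian (width = sigma)."""

    center: float
    amplitude: float
    width: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-amplitude profile evaluated on the axis."""
        d = axis - self.center
        if self.shape == "lorentzian":
            w2 = self.width**2
            return w2 / (w2 + d**2)
        return np.exp(-0.5 * (d / self.width) ** 2)


@dataclass(frozen=True)
class BaselineSpec:
    """Smooth background: a low-order polynomial plus a broad Gaussian
    fluorescence hump. ``poly`` holds coefficients in ascending powers of
    (nu - 600) to keep magnitudes interpretable over the fingerprint region."""

    poly: tuple[float, ...] = (0.0,)
    hump_center: float = 1000.0
    hump_amplitude: float = 0.0
    hump_width: float = 400.0

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        x = axis - 600.0
        z = np.zeros_like(axis, dtype=float)
        for k, c in enumerate(self.poly):
            z += c * x**k
        if self.hump_amplitude:
            z += self.hump_amplitude * np.exp(
                -0.5 * ((axis - self.hump_center) / self.hump_width) ** 2
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("baseline evaluates to non-finite values")
        return z


@dataclass(frozen=True)
class NoiseSpec:
    additive_sd: float = 0.01
    multiplicative_cv: float = 0.02
    spike_rate: float = 0.001
    spike_amplitude: float = 5.0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_cv", "spike_rate", "spike_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spike_rate > 0.05:
            raise ValueError("spike_rate above 0.05 is not a spike model")

    @property
    def silent(self) -> bool:
        return self.additive_sd == 0 and self.multiplicative_cv == 0 and self.spike_rate == 0


@dataclass(frozen=True)
class PhenotypeCoupling:
    """phenotype = intercept + slope * true_ratio + N(0, noise_sd)."""

    phenotype: str
    ratio: str
    slope: float
    noise_sd: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_band_library() -> tuple[BandSpec, ...]:
    """Fingerprint-region band library for muscle-like tissue.

    Gaussian profiles (width = sigma in cm^-1, FWHM 12-21 cm^-1) with
    amplitudes in AU relative to the 1450 band. Gaussian rather than
    Lorentzian shapes keep inter-band tail overlap at the sub-percent level,
    so a band's ground-truth intensity is unambiguous: heavy Lorentzian
    tails would pile up into a pseudo-baseline under the crowded amide-III
    cluster that no baseline estimator could attribute cleanly to signal or
    background. Lorentzian bands remain available via :class:`BandSpec`.
    """
    rows = [
        (755.0, 0.30, 6.0),   # tryptophan ring breathing
        (855.0, 0.35, 7.0),   # proline / hydroxyproline
        (935.0, 0.30, 7.0),   # C-C backbone stretch
        (1004.0, 0.55, 4.0),  # phenylalanine ring breathing
        (1095.0, 0.25, 8.0),  # PO2- / C-C skeletal
        (1245.0, 0.45, 7.0),  # amide III (disordered)
        (1270.0, 0.50, 7.0),  # amide III (ordered / collagen)
        (1320.0, 0.55, 6.0),  # CH deformation, collagen organization
        (1340.0, 0.75, 6.5),  # CH2/CH3 deformation
        (1450.0, 1.00, 7.0),  # CH2 bending (queried at 1450 and 1454)
        (1608.0, 0.35, 6.0),  # Phe/Tyr ring, fibrosis marker
        (1660.0, 0.90, 9.0),  # amide I (queried at 1660 and 1662)
    ]
    return tuple(BandSpec(c, a, w, "gaussian") for c, a, w in rows)


GROUPS = ("young_control", "old_control", "old_hypoxia")
TIMEPOINTS = ("BL", "4d", "7d")

# ground-truth (group, timepoint) amplitude multipliers, keyed by band center;
# unlisted bands stay at 1. Old controls diverge during recovery (higher
# fibrosis/amide-III markers, lower 1340/1320); hypoxia-treated old animals
# stay close to young controls, the study's qualitative phenotype.
_DEFAULT_EFFECTS: dict[tuple[str, str], dict[float, float]] = {
    ("old_control", "BL"): {1340.0: 1.02, 1450.0: 1.08, 1660.0: 0.97, 1608.0: 1.10,
                            1270.0: 1.08, 1320.0: 0.95},
    ("old_control", "4d"): {1340.0: 1.05, 1450.0: 1.25, 1660.0: 0.92, 1608.0: 1.35,
                            1270.0: 1.20, 1320.0: 0.85, 1245.0: 1.10},
    ("old_control", "7d"): {1340.0: 1.04, 1450.0: 1.20, 1660.0: 0.93, 1608.0: 1.30,
                            1270.0: 1.18, 1320.0: 0.87, 1245.0: 1.08},
    ("old_hypoxia", "BL"): {1340.0: 1.02, 1450.0: 1.08, 1660.0: 0.97, 1608.0: 1.10,
                            1270.0: 1.08, 1320.0: 0.95},
    ("old_hypoxia", "4d"): {1340.0: 1.01, 1450.0: 1.05, 1660.0: 0.98, 1608.0: 1.05,
                            1270.0: 1.03, 1320.0: 0.97},
    ("old_hypoxia", "7d"): {1340.0: 1.01, 1450.0: 1.03, 1660.0: 0.99, 1608.0: 1.03,
                            1270.0: 1.02, 1320.0: 0.98},
}

_DEFAULT_COUPLINGS = (
    PhenotypeCoupling("grip_strength", "lipid_protein", slope=-600.0, noise_sd=15.0, intercept=800.0),
    PhenotypeCoupling("col1_area", "tissue_fibrosis", slope=25.0, noise_sd=1.0, intercept=2.0),
    PhenotypeCoupling("sirius_red", "collagen_denaturation", slope=-12.0, noise_sd=1.0, intercept=30.0),
)


@dataclass(frozen=True)
class CohortDesign:
    """Full specification of a synthetic cohort (a pure function of this
    object, master seed included, determines every simulated byte)."""

    axis_start: float = 600.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    groups: tuple[str, ...] = GROUPS
    timepoints: tuple[str, ...] = TIMEPOINTS
    bands: tuple[BandSpec, ...] = field(default_factory=default_band_library)
    effects: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    samples_per_cell: int = 3
    replicates_per_sample: int = 30
    between_sample_cv: float = 0.05
    within_sample_cv: float = 0.03
    baseline: BaselineSpec = BaselineSpec(poly=(0.5, -2.0e-4), hump_center=1000.0,
                                          hump_amplitude=1.5, hump_width=350.0)
    noise: NoiseSpec = NoiseSpec()
    couplings: tuple[PhenotypeCoupling, ...] = _DEFAULT_COUPLINGS
    ratio_definitions: tuple[RatioDefinition, ...] = tuple(default_ratio_set())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.samples_per_cell < 1 or self.replicates_per_sample < 1:
            raise ValueError("counts must be >= 1")
        for cell, mults in self.effects.items():
            for c, m in mults.items():
                if m <= 0:
                    raise ValueError(f"multiplier for band {c} in cell {cell} must be > 0")
        ratio_names = {d.name for d in self.ratio_definitions}
        for cp in self.couplings:
            if cp.ratio not in ratio_names:
                raise ValueError(
                    f"phenotype {cp.phenotype!r} couples to undefined ratio {cp.ratio!r}; "
                    f"known ratios: {sorted(ratio_names)}"
                )

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def cells(self) -> list[tuple[str, str]]:
        return list(itertools.product(self.groups, self.timepoints))

    def cell_multipliers(self, group: str, timepoint: str) -> np.ndarray:
        mults = self.effects.get((group, timepoint), {})
        return np.array([mults.get(b.center, 1.0) for b in self.bands])


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    """The study-design defaults, optionally overridden field-by-field."""
    return CohortDesign(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# single-spectrum generator


def simulate_spectrum(
    bands: list[BandSpec],
    baseline: BaselineSpec,
    noise: NoiseSpec,
    axis: np.ndarray,
    seed: int | np.random.SeedSequence = 0,
) -> Spectrum:
    """Render one spectrum: sum of band profiles + baseline + noise.

    Deterministic given the seed; identical seeds give bit-identical output.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("empty wavenumber axis")
    rng = np.random.default_rng(seed)
    signal = np.zeros_like(axis)
    for b in bands:
        if b.amplitude:
            signal += b.amplitude * b.profile(axis)
    y = signal + baseline.evaluate(axis)
    if not noise.silent:
        if noise.multiplicative_cv:
            y = y + signal * noise.multiplicative_cv * rng.standard_normal(axis.size)
        if noise.additive_sd:
            y = y + noise.additive_sd * rng.standard_normal(axis.size)
        if noise.spike_rate:
            spikes = rng.random(axis.size) < noise.spike_rate
            y = y + spikes * noise.spike_amplitude
    return Spectrum(axis, y)


# ---------------------------------------------------------------------------
# cohort generator with ground truth


@dataclass
class SampleTruth:
    sample_id: str
    group: str
    timepoint: str
    amplitudes: np.ndarray          # per-band, after multiplier and sample effect
    replicate_scales: np.ndarray    # scalar s_r per replicate
    true_ratios: dict[str, float]
    phenotypes: dict[str, float]


@dataclass
class GroundTruth:
    """Everything the generator drew, sufficient to re-derive the noiseless
    spectra exactly and to score downstream estimates."""

    design: CohortDesign
    samples: dict[str, SampleTruth]

    def noiseless_spectrum(self, sample_id: str, replicate: int | None = None,
                           include_baseline: bool = True) -> Spectrum:
        """Re-evaluate the stored amplitudes: the spectrum the sample would
        show with all noise terms at zero."""
        t = self.samples[sample_id]
        axis = self.design.axis()
        y = np.zeros_like(axis)
        for amp, b in zip(t.amplitudes, self.design.bands):
            y += amp * b.profile(axis)
        if replicate is not None:
            y = y * t.replicate_scales[replicate]
        if include_baseline:
            y = y + self.design.baseline.evaluate(axis)
        return Spectrum(axis, y, label=sample_id)

    def ratio_frame(self) -> pd.DataFrame:
        """True per-sample ratios, indexed by sample_id."""
        df = pd.DataFrame({sid: t.true_ratios for sid, t in self.samples.items()}).T
        df.index.name = "sample_id"
        return df

    def to_json(self, path) -> None:
        rec = {
            sid: {
                "group": t.group,
                "timepoint": t.timepoint,
                "amplitudes": {repr(b.center): a for b, a in
                               zip(self.design.bands, t.amplitudes.tolist())},
                "replicate_scales": t.replicate_scales.tolist(),
                "true_ratios": t.true_ratios,
                "phenotypes": t.phenotypes,
            }
            for sid, t in self.samples.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rec, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _true_ratios(amplitudes: np.ndarray, design: CohortDesign, axis: np.ndarray) -> dict[str, float]:
    y = np.zeros_like(axis)
    for amp, b in zip(amplitudes, design.bands):
        y += amp * b.profile(axis)
    fp = Fingerprint("truth", axis, y)
    out = {}
    for d in design.ratio_definitions:
        out[d.name] = band_intensity(fp, d.numerator) / band_intensity(fp, d.denominator)
    return out


def simulate_cohort(design: CohortDesign) -> tuple[list[SpectrumSet], CohortTable, GroundTruth]:
    """Simulate the full cohort: one SpectrumSet per sample, the cohort
    metadata table with simulated phenotypes, and the ground-truth record."""
    axis = design.axis()
    base_amps = np.array([b.amplitude for b in design.bands])
    master = design.seed

    sets: list[SpectrumSet] = []
    truth: dict[str, SampleTruth] = {}
    rows = []
    for cell_idx, (group, tp) in enumerate(design.cells()):
        mult = design.cell_multipliers(group, tp)
        for s_idx in range(design.samples_per_cell):
            sid = f"{group}_{tp}_s{s_idx + 1}"
            amp_rng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(cell_idx, s_idx, _AMPL))
            )
            sample_amps = base_amps * mult * np.exp(
                design.between_sample_cv * amp_rng.standard_normal(len(base_amps))
            )
            rep_scales = np.empty(design.replicates_per_sample)
            reps = []
            for r_idx in range(design.replicates_per_sample):
                ss = np.random.SeedSequence(master, spawn_key=(cell_idx, s_idx, _REP, r_idx))
                rep_rng = np.random.default_rng(ss)
                scale = float(np.exp(design.within_sample_cv * rep_rng.standard_normal()))
                rep_scales[r_idx] = scale
                bands = [
                    BandSpec(b.center, a * scale, b.width, b.shape)
                    for b, a in zip(design.bands, sample_amps)
                ]
                sp = simulate_spectrum(bands, design.baseline, design.noise, axis, seed=ss.spawn(1)[0])
                sp.label = f"{sid}_r{r_idx + 1}"
                reps.append(sp)
            sets.append(SpectrumSet(sid, reps))

            ratios = _true_ratios(sample_amps, design, axis)
            ph_rng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(cell_idx, s_idx, _PHENO))
            )
            phenos = {
                cp.phenotype: cp.intercept + cp.slope * ratios[cp.ratio]
                + cp.noise_sd * float(ph_rng.standard_normal())
                for cp in design.couplings
            }
            truth[sid] = SampleTruth(sid, group, tp, sample_amps, rep_scales, ratios, phenos)
            rows.append({"sample_id": sid, "group": group, "timepoint": tp, **phenos})

    table = CohortTable(
        pd.DataFrame(rows),
        group_levels=design.groups,
        timepoint_levels=design.timepoints,
    )
    return sets, table, GroundTruth(design, truth)


# ---------------------------------------------------------------------------
# fast ground-truth-level sampling for Monte Carlo studies


def _query_grid(design: CohortDesign) -> tuple[np.ndarray, list[tuple[str, np.ndarray, np.ndarray]]]:
    """Union of ratio-window grid points and, per ratio, masks for the
    numerator and denominator windows on that union grid."""
    axis = design.axis()
    masks = []
    union = np.zeros(len(axis), dtype=bool)
    per_ratio = []
    for d in design.ratio_definitions:
        sel_n = (axis >= d.numerator.lo) & (axis <= d.numerator.hi)
        sel_d = (axis >= d.denominator.lo) & (axis <= d.denominator.hi)
        union |= sel_n | sel_d
        masks.append((d.name, sel_n, sel_d))
    pts = axis[union]
    idx = np.cumsum(union) - 1
    for name, sel_n, sel_d in masks:
        per_ratio.append((name, idx[sel_n], idx[sel_d]))
    return pts, per_ratio


def draw_true_ratios(
    design: CohortDesign,
    cells: list[tuple[str, str]],
    samples_per_cell: int,
    n_cohorts: int,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, list[str]]:
    """Draw true per-sample ratios for many independent cohorts at once.

    Uses the same amplitude model as :func:`simulate_cohort` but skips
    spectral rendering (the true ratio is a deterministic function of the
    drawn amplitudes), so tens of thousands of cohorts are cheap. Returns an
    array of shape (n_cohorts, n_samples, n_ratios) and the ratio names.
    """
    rng = np.random.default_rng(seed)
    pts, per_ratio = _query_grid(design)
    profiles = np.stack([b.profile(pts) for b in design.bands])  # bands x pts
    base_amps = np.array([b.amplitude for b in design.bands])
    cell_mults = np.stack([design.cell_multipliers(g, t) for g, t in cells])

    n_samples = len(cells) * samples_per_cell
    names = [name for name, _, _ in per_ratio]
    out = np.empty((n_cohorts, n_samples, len(names)))
    chunk = max(1, int(5_000_000 / max(1, n_samples * len(pts))))
    mult_rows = np.repeat(cell_mults, samples_per_cell, axis=0)  # samples x bands
    for lo in range(0, n_cohorts, chunk):
        hi = min(lo + chunk, n_cohorts)
        eps = rng.standard_normal((hi - lo, n_samples, len(base_amps)))
        amps = base_amps * mult_rows * np.exp(design.between_sample_cv * eps)
        spectra = amps @ profiles  # cohorts x samples x pts
        for j, (_, idx_n, idx_d) in enumerate(per_ratio):
            num = spectra[..., idx_n].max(axis=-1)
            den = spectra[..., idx_d].max(axis=-1)
            out[lo:hi, :, j] = num / den
    return out, names


def simulate_coupling_trials(
    design: CohortDesign,
    ratio_name: str,
    slope: float,
    noise_sd: float,
    n_cohorts: int,
    seed: int | np.random.SeedSequence = 0,
    cells: list[tuple[str, str]] | None = None,
    samples_per_cell: int | None = None,
    intercept: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (true ratio, coupled phenotype) sample pairs for many cohorts.

    Defaults to the pooled recovery design: all groups at the 4d and 7d
    timepoints, i.e. n = 18 samples per cohort under the study's cell sizes.
    Returns arrays x, y of shape (n_cohorts, n_samples).
    """
    if cells is None:
        cells = [(g, t) for g in design.groups for t in design.timepoints if t != "BL"]
    spc = samples_per_cell if samples_per_cell is not None else design.samples_per_cell
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    s_ratio, s_noise = ss.spawn(2)
    ratios, names = draw_true_ratios(design, cells, spc, n_cohorts, s_ratio)
    if ratio_name not in names:
        raise ValueError(f"unknown ratio {ratio_name!r}; known: {names}")
    x = ratios[:, :, names.index(ratio_name)]
    rng = np.random.default_rng(s_noise)
    y = intercept + slope * x + noise_sd * rng.standard_normal(x.shape)
    return x, y


def calibrate_coupling_sd(
    design: CohortDesign,
    ratio_name: str,
    slope: float,
    target_r: float,
    seed: int | np.random.SeedSequence = 0,
    n_calibration: int = 2000,
    cells: list[tuple[str, str]] | None = None,
) -> float:
    """Phenotype noise sd giving a requested population correlation.

    With phenotype = slope * x + e, the population correlation is
    |slope| sd_x / sqrt(slope^2 sd_x^2 + sd_e^2); solving for sd_e gives
    sd_e = |slope| sd_x sqrt(1/r^2 - 1). sd_x is estimated from a large
    seeded draw of the generator's true-ratio distribution.
    """
    if not 0 < abs(target_r) < 1:
        raise ValueError("target_r must be in (0, 1) in magnitude")
    if cells is None:
        cells = [(g, t) for g in design.groups for t in design.timepoints if t != "BL"]
    ratios, names = draw_true_ratios(design, cells, design.samples_per_cell,
                                     max(1, n_calibration // (len(cells) * design.samples_per_cell)),
                                     seed)
    x = ratios[:, :, names.index(ratio_name)].ravel()
    sd_x = float(np.std(x))
    return abs(slope) * sd_x * float(np.sqrt(1.0 / target_r**2 - 1.0))
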