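"""One-command orchestration: simulate (or ingest) -> preprocess -> ratios
-> embed -> stats, with a run manifest for reproducibility.

Every stage is a pure function of its inputs plus the recorded seeds, so a
rerun with the same config and master seed reproduces every data output
byte for byte; only the manifest timestamp differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .bands import RatioTable, compute_ratios, default_ratio_set
from .cohort import CohortTable
from .embedding import FingerprintMatrix, cluster_agreement, embed_fingerprints
from .preprocess import PreprocessConfig, average_to_fingerprint
from .simulate import CohortDesign, default_design, simulate_cohort
from .spectra import Fingerprint, SpectrumSet
from .stats import (
    AlphaPolicy,
    correlate_ratios_with_phenotypes,
    two_way_anova,
)

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]

log = logging.getLogger("ramanfp")


class PipelineError(RuntimeError):
    """Stage failure, carrying the stage name for the operator."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """What to run and where to put it.

    Exactly one input source is used: a simulation design (``design``) or a
    directory of wide-matrix spectra plus a cohort.csv (``data_dir``).
    """

    out_dir: Path
    design: CohortDesign | None = None
    data_dir: Path | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    embedding_method: str = "pca"
    seed: int = 0
    alpha: AlphaPolicy = field(default_factory=AlphaPolicy)
    correlation_pairs: tuple | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.design is None) == (self.data_dir is None):
            raise ValueError("provide exactly one of design or data_dir")
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise ValueError(f"data directory {self.data_dir} does not exist")


def demo_config(out_dir, seed: int = 0) -> PipelineConfig:
    """The bundled synthetic demo: the default 3x3x3 design with 30
    replicates per sample and the built-in group effects."""
    return PipelineConfig(out_dir=Path(out_dir), design=default_design(seed=seed), seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return {f.name: _jsonable(getattr(o, f.name)) for f in dataclasses.fields(o)}
    if isinstance(o, dict):
        return {str(k): _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple, set, frozenset, np.ndarray)):
        return [_jsonable(v) for v in o]
    if isinstance(o, (str, int, float, bool)) or o is None:
        return o
    return str(o)


def _config_fingerprint(config: PipelineConfig) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_data_dir(data_dir: Path) -> tuple[list[SpectrumSet], CohortTable]:
    cohort_path = data_dir / "cohort.csv"
    if not cohort_path.exists():
        raise PipelineError("ingest", f"{cohort_path} not found")
    cohort = rio.read_cohort_table(cohort_path)
    sets = []
    for sid in cohort.sample_ids:
        path = data_dir / f"{sid}.csv"
        if not path.exists():
            raise PipelineError("ingest", f"spectra file for sample {sid!r} not found at {path}")
        sets.append(rio.read_spectrum_table(path, dialect="wide_matrix", sample_id=sid))
    return sets, cohort


def _write_fingerprints(fps: list[Fingerprint], path: Path) -> None:
    df = pd.DataFrame({"wavenumber": fps[0].wavenumbers})
    for f in fps:
        df[f.sample_id] = f.intensities
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and return the run manifest (also written to
    ``manifest.json``). On stage failure a FAILED marker file is left in the
    output directory next to any partial outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()

    manifest: dict = {
        "config_hash": _config_fingerprint(config),
        "master_seed": config.seed,
        "versions": _versions(),
        "stages": {},
        "files": {},
    }
    t0 = time.time()
    try:
        # ingest / simulate -------------------------------------------------
        if config.design is not None:
            sets, cohort, truth = simulate_cohort(config.design)
            truth.to_json(out / "ground_truth.json")
            manifest["stages"]["simulate"] = {
                "n_samples": len(sets),
                "n_spectra": int(sum(len(s) for s in sets)),
            }
        else:
            sets, cohort = _load_data_dir(Path(config.data_dir))
            manifest["stages"]["ingest"] = {
                "n_samples": len(sets),
                "n_spectra": int(sum(len(s) for s in sets)),
            }
        rio.write_cohort_table(cohort, out / "cohort.csv")
        log.info("input: %d samples, %d spectra", len(sets), sum(len(s) for s in sets))

        # preprocess --------------------------------------------------------
        fps = []
        for s in sets:
            try:
                fps.append(average_to_fingerprint(s, config.preprocess))
            except Exception as exc:
                raise PipelineError("preprocess", f"sample {s.sample_id!r}: {exc}") from exc
        _write_fingerprints(fps, out / "fingerprints.csv")
        manifest["stages"]["preprocess"] = {
            "n_fingerprints": len(fps),
            "grid_points": len(fps[0]),
        }
        log.info("preprocessed %d fingerprints", len(fps))

        # ratios ------------------------------------------------------------
        defs = default_ratio_set()
        ratio_table = compute_ratios(fps, defs)
        ratio_out = ratio_table.values.reset_index()
        ratio_out.to_csv(out / "ratios.csv", index=False)
        manifest["stages"]["ratios"] = {
            "n_rows": len(ratio_table),
            "n_ratios": len(ratio_table.ratio_names),
            "n_cell_errors": len(ratio_table.errors),
        }

        # embed ---------------------------------------------------------
        fm = FingerprintMatrix.from_fingerprints(fps)
        emb = embed_fingerprints(fm, method=config.embedding_method, seed=config.seed)
        groups = cohort.data.set_index("sample_id").loc[emb.sample_ids, "group"].to_numpy()
        agreement = cluster_agreement(emb, groups)
        emb_df = pd.DataFrame(
            {
                "sample_id": emb.sample_ids,
                "dim1": emb.coordinates[:, 0],
                "dim2": emb.coordinates[:, 1],
                "method": emb.method,
                "seed": emb.seed,
            }
        )
        emb_df.to_csv(out / "embedding.csv", index=False)
        manifest["stages"]["embed"] = {
            "method": emb.method,
            "group_cluster_agreement": agreement,
        }
        log.info("embedding (%s): group cluster agreement %.3f", emb.method, agreement)

        # stats ---------------------------------------------------------
        meta = cohort.data.set_index("sample_id")
        anova_rows, posthoc_frames = [], []
        for name in ratio_table.ratio_names:
            vals = ratio_table.values[name].dropna()
            sub = meta.loc[vals.index]
            try:
                res = two_way_anova(vals.to_numpy(), sub["group"], sub["timepoint"],
                                    response_name=name)
            except ValueError as exc:
                raise PipelineError("stats", f"ANOVA for ratio {name!r}: {exc}") from exc
            for term, row in res.table.iterrows():
                anova_rows.append({"response": name, "term": term, **row.to_dict()})
            ph = res.posthoc.copy()
            ph.insert(0, "response", name)
            posthoc_frames.append(ph)
        pd.DataFrame(anova_rows).to_csv(out / "stats" / "anova.csv", index=False)
        pd.concat(posthoc_frames, ignore_index=True).to_csv(
            out / "stats" / "posthoc.csv", index=False
        )
        corrs = correlate_ratios_with_phenotypes(
            ratio_table, cohort, pairs=config.correlation_pairs, policy=config.alpha
        )
        pd.DataFrame(
            [
                {"ratio": c.ratio, "phenotype": c.phenotype, "n": c.n, "r": c.r,
                 "p": c.p, "significant": c.significant(config.alpha)}
                for c in corrs
            ]
        ).to_csv(out / "stats" / "correlations.csv", index=False)
        manifest["stages"]["stats"] = {
            "n_anova_responses": len(ratio_table.ratio_names),
            "n_correlations": len(corrs),
        }
    except Exception as exc:
        marker.write_text(f"{exc}\n")
        raise

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "run.log", "FAILED"):
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S%z")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "ramanfp": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
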