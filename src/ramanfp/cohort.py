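"""Sample-level metadata: group, timepoint and phenotype measurements."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "MANDATORY_COLUMNS"]

MANDATORY_COLUMNS = ("sample_id", "group", "timepoint")


@dataclass
class CohortTable:
    """Per-sample design and phenotype table.

    One row per biological sample. ``group`` and ``timepoint`` are categorical
    with declared level sets; every other column is treated as a numeric
    phenotype (e.g. grip strength in g, COL-I %area, Sirius red %area) and may
    contain missing values, stored as NaN.
    """

    data: pd.DataFrame
    group_levels: tuple[str, ...] = ()
    timepoint_levels: tuple[str, ...] = ()
    phenotype_columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cohort table is missing mandatory column {col!r}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicated sample_id(s): {sorted(set(dupes))}")
        if not self.group_levels:
            self.group_levels = tuple(pd.unique(df["group"]))
        if not self.timepoint_levels:
            self.timepoint_levels = tuple(pd.unique(df["timepoint"]))
        unknown_g = set(df["group"]) - set(self.group_levels)
        unknown_t = set(df["timepoint"]) - set(self.timepoint_levels)
        if unknown_g:
            raise ValueError(f"group values outside declared levels: {sorted(unknown_g)}")
        if unknown_t:
            raise ValueError(
                f"timepoint values outside declared levels: {sorted(unknown_t)}"
            )
        pheno = [c for c in df.columns if c not in MANDATORY_COLUMNS]
        for col in pheno:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"phenotype column {col!r} is not numeric: {exc}"
                ) from None
        self.phenotype_columns = tuple(pheno)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def phenotype(self, name: str) -> pd.Series:
        """Phenotype values indexed by sample_id (NaN = missing)."""
        if name not in self.phenotype_columns:
            raise KeyError(f"unknown phenotype column {name!r}")
        return self.data.set_index("sample_id")[name]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing phenotype cells, indexed by sample_id."""
        return self.data.set_index("sample_id")[list(self.phenotype_columns)].isna()
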