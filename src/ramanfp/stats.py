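"""Inferential layer: two-way ANOVA with Holm-adjusted post-hoc tests, and
Pearson ratio-phenotype correlations.

Conventions
-----------
* Two-way ANOVA uses Type-II sums of squares (each main effect adjusted for
  the other, the interaction adjusted for both), which remains well defined
  for unbalanced complete designs; fitting is delegated to statsmodels OLS.
* Post-hoc tests compare levels of the first factor within each level of the
  second by two-sample Welch t tests, Holm-adjusted as one family.
* Pearson p-values come from the exact t transform
  t = r * sqrt((n-2) / (1-r^2)) against t(n-2), two-sided, and are reported
  unadjusted by default; Holm adjustment across the requested pair family is
  available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .bands import RatioTable
from .cohort import CohortTable

__all__ = [
    "AlphaPolicy",
    "CorrelationResult",
    "AnovaResult",
    "pearson_with_p",
    "holm_adjust",
    "two_way_anova",
    "correlate_ratios_with_phenotypes",
    "DEFAULT_CORRELATION_PAIRS",
]

#: ratio/phenotype pairs examined by default: grip strength against the
#: lipid/protein and nucleic acid/lipid ratios, type I collagen staining
#: against the fibrosis ratio, Sirius red against collagen denaturation.
DEFAULT_CORRELATION_PAIRS = (
    ("lipid_protein", "grip_strength"),
    ("nucleic_acid_lipid", "grip_strength"),
    ("tissue_fibrosis", "col1_area"),
    ("collagen_denaturation", "sirius_red"),
)


@dataclass(frozen=True)
class AlphaPolicy:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CorrelationResult:
    ratio: str
    phenotype: str
    n: int
    r: float
    p: float
    p_adjusted: float | None = None

    def significant(self, policy: AlphaPolicy = AlphaPolicy()) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return p < policy.alpha


@dataclass
class AnovaResult:
    response: str
    table: pd.DataFrame       # index: term; columns: df, sum_sq, F, p
    posthoc: pd.DataFrame     # pairwise factorA comparisons within factorB levels
    factors: tuple[str, str] = ("group", "timepoint")
    n: int = 0


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value.

    p comes from t = r*sqrt((n-2)/(1-r^2)) against the t(n-2) distribution.
    Perfect correlation returns the smallest positive float instead of
    dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.sum(xd**2)))
    sy = float(np.sqrt(np.sum(yd**2)))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.clip(np.sum(xd * yd) / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, float(np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (familywise error control).

    Sort ascending, multiply the i-th smallest by (m - i), enforce a running
    maximum, cap at 1, restore input order. Delegates to statsmodels.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def _term_eps(total_ss: float) -> float:
    return max(1e-12, 1e-12 * total_ss)


def two_way_anova(
    values,
    factor_a,
    factor_b,
    response_name: str = "value",
    factor_names: tuple[str, str] = ("group", "timepoint"),
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction, Type-II sums of squares.

    Works for balanced and unbalanced complete designs. Degenerate data with
    no variability returns F = 0, p = 1 for every term. Post-hoc pairwise
    comparisons of factor A within each level of factor B (Welch t tests)
    are Holm-adjusted as a single family.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a).astype(str)
    b = np.asarray(factor_b).astype(str)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError(
            "each factor needs at least 2 levels; use a 1-way ANOVA for a "
            "single-factor design"
        )
    df = pd.DataFrame({"y": y, "A": a, "B": b})
    model = ols("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    if model.df_resid >= 1:
        tab = anova_lm(model, typ=2)
    else:
        # saturated design (e.g. one observation per cell): report Type-II
        # sums of squares from nested fits, but no F or p is defined
        both = ols("y ~ C(A) + C(B)", data=df).fit()
        only_a = ols("y ~ C(A)", data=df).fit()
        only_b = ols("y ~ C(B)", data=df).fit()
        n_a = len(np.unique(a))
        n_b = len(np.unique(b))
        tab = pd.DataFrame(
            {
                "df": [n_a - 1.0, n_b - 1.0, (n_a - 1.0) * (n_b - 1.0), 0.0],
                "sum_sq": [
                    only_b.ssr - both.ssr,
                    only_a.ssr - both.ssr,
                    both.ssr - model.ssr,
                    model.ssr,
                ],
                "F": [np.nan] * 4,
                "PR(>F)": [np.nan] * 4,
            },
            index=["C(A)", "C(B)", "C(A):C(B)", "Residual"],
        )

    total_ss = float(np.sum((y - y.mean()) ** 2))
    eps = _term_eps(total_ss)
    out = pd.DataFrame(
        {
            "df": tab["df"].astype(float),
            "sum_sq": tab["sum_sq"].astype(float).clip(lower=0.0),
            "F": tab["F"],
            "p": tab["PR(>F)"],
        }
    )
    out.index = [
        factor_names[0],
        factor_names[1],
        f"{factor_names[0]}:{factor_names[1]}",
        "residual",
    ]
    # no-variability terms: define F = 0, p = 1 rather than 0/0
    if model.df_resid >= 1:
        for term in out.index[:-1]:
            if not np.isfinite(out.loc[term, "F"]) or out.loc[term, "sum_sq"] <= eps:
                if out.loc[term, "sum_sq"] <= eps:
                    out.loc[term, ["F", "p"]] = [0.0, 1.0]
                elif out.loc[out.index[-1], "sum_sq"] <= eps:
                    out.loc[term, ["F", "p"]] = [np.inf, 0.0]
    out.loc["residual", ["F", "p"]] = [np.nan, np.nan]

    rows = []
    for lb in pd.unique(b):
        sub = df[df["B"] == lb]
        for la1, la2 in combinations(pd.unique(sub["A"]), 2):
            y1 = sub.loc[sub["A"] == la1, "y"].to_numpy()
            y2 = sub.loc[sub["A"] == la2, "y"].to_numpy()
            if len(y1) < 2 or len(y2) < 2:
                continue
            if np.var(y1) == 0 and np.var(y2) == 0:
                p = 1.0 if y1.mean() == y2.mean() else 0.0
                tstat = 0.0 if p == 1.0 else np.inf
            else:
                tstat, p = sps.ttest_ind(y1, y2, equal_var=False)
            rows.append(
                {
                    factor_names[1]: lb,
                    "level_1": la1,
                    "level_2": la2,
                    "mean_1": y1.mean(),
                    "mean_2": y2.mean(),
                    "t": float(tstat),
                    "p_raw": float(p),
                }
            )
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        safe = posthoc["p_raw"].clip(lower=np.finfo(float).tiny, upper=1.0)
        posthoc["p_holm"] = holm_adjust(safe.to_numpy())
    return AnovaResult(response_name, out, posthoc, factor_names, n=len(y))


def correlate_ratios_with_phenotypes(
    ratios: RatioTable,
    cohort: CohortTable,
    pairs=None,
    policy: AlphaPolicy = AlphaPolicy(),
    adjust: bool = False,
) -> list[CorrelationResult]:
    """Pearson correlation of each (ratio, phenotype) pair across samples.

    Samples are joined on sample_id; missing values are dropped pairwise
    with the effective n recorded. Groups are pooled (per-group correlation
    is a matter of subsetting the inputs). With ``adjust`` on, Holm-adjusted
    p-values across the pair family are attached.
    """
    if pairs is None:
        pairs = [
            (r, p)
            for r, p in DEFAULT_CORRELATION_PAIRS
            if r in ratios.ratio_names and p in cohort.phenotype_columns
        ]
        if not pairs:
            raise ValueError("no default ratio/phenotype pairs present in the inputs")
    meta = cohort.data.set_index("sample_id")
    joined = ratios.values.join(meta, how="inner", lsuffix="_ratio")
    results: list[CorrelationResult] = []
    for ratio_name, pheno_name in pairs:
        if ratio_name not in ratios.ratio_names:
            raise ValueError(f"unknown ratio column {ratio_name!r}")
        if pheno_name not in cohort.phenotype_columns:
            raise ValueError(f"unknown phenotype column {pheno_name!r}")
        sub = joined[[ratio_name, pheno_name]].dropna()
        r, p = pearson_with_p(sub[ratio_name].to_numpy(), sub[pheno_name].to_numpy())
        results.append(CorrelationResult(ratio_name, pheno_name, len(sub), r, p))
    if adjust and results:
        adj = holm_adjust([c.p for c in results])
        for c, pa in zip(results, adj):
            c.p_adjusted = float(pa)
    return results
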