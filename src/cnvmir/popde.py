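"""Between-population differential expression by reciprocal regression.

For a population pair (a, b) the per-gene mean intensities are regressed
reciprocally (b on a, then a on b) by ordinary least squares.  Residuals
are optionally rank-transformed to normal scores, then externally
studentized; genes whose studentized residual leaves the two-sided
(1 - alpha) t interval in either direction are the pair's differentially
expressed (DE) set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence


@dataclass
class DePairResult:
    pair: tuple[str, str]
    table: pd.DataFrame  # index gene; mean_a, mean_b, stud_ab, stud_ba, outlier_ab, outlier_ba, outlier
    alpha: float

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["outlier"]])

    def direction_of(self, gene: str) -> str:
        row = self.table.loc[gene]
        if row["outlier_ab"] and row["outlier_ba"]:
            return "both"
        if row["outlier_ab"]:
            return "a_on_b"
        if row["outlier_ba"]:
            return "b_on_a"
        return "none"


def _blom_scores(x: np.ndarray) -> np.ndarray:
    """Rank -> standard-normal scores, Blom offset (r - 3/8)/(n + 1/4)."""
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _studentized_residuals(x: np.ndarray, y: np.ndarray, quartile_normalize: bool) -> np.ndarray:
    """Externally studentized residuals of the OLS fit of y on x (df = n-3).

    With the rank-normalisation the leverage structure of the original fit
    no longer applies to the transformed residuals, so studentization uses
    the internal->external t conversion on standardized scores; without it,
    the exact leave-one-out studentized residuals are used.
    """
    n = len(x)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.resid
    if np.allclose(resid, 0.0, atol=1e-12):
        warnings.warn("zero residual variance (exact collinearity); no outliers", stacklevel=3)
        return np.zeros(n)
    if not quartile_normalize:
        return np.asarray(OLSInfluence(model).resid_studentized_external)
    scores = _blom_scores(resid)
    # internally studentized analogue: scale by residual RMS with df = n-2
    internal = scores / np.sqrt(np.sum(scores**2) / (n - 2))
    # guard the sqrt: |internal| can graze sqrt(n-2) at the extremes
    denom = np.clip(n - 2 - internal**2, 1e-12, None)
    return internal * np.sqrt((n - 3) / denom)


def detect_de_pair(
    mean_a: pd.Series,
    mean_b: pd.Series,
    alpha: float = 0.05,
    quartile_normalize: bool = True,
    pair: tuple[str, str] = ("a", "b"),
    df_offset: int = 3,
) -> DePairResult:
    """Reciprocal-regression outlier detection for one population pair.

    A gene is DE when its externally studentized residual exceeds the
    two-sided t critical value t_{1-alpha/2, n-df_offset} in either
    regression direction (union rule).  ``df_offset`` = 3 corresponds to
    external studentization of a two-parameter fit.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    common = mean_a.index.intersection(mean_b.index)
    if len(common) < 10:
        raise ValueError(f"need >= 10 shared genes, got {len(common)}")
    a = mean_a.loc[common].to_numpy(dtype=float)
    b = mean_b.loc[common].to_numpy(dtype=float)
    n = len(common)
    crit = stats.t.ppf(1 - alpha / 2, n - df_offset)
    stud_ab = _studentized_residuals(a, b, quartile_normalize)  # b regressed on a
    stud_ba = _studentized_residuals(b, a, quartile_normalize)
    out_ab = np.abs(stud_ab) > crit
    out_ba = np.abs(stud_ba) > crit
    table = pd.DataFrame(
        {
            "mean_a": a,
            "mean_b": b,
            "stud_ab": stud_ab,
            "stud_ba": stud_ba,
            "outlier_ab": out_ab,
            "outlier_ba": out_ba,
            "outlier": out_ab | out_ba,
        },
        index=common,
    )
    return DePairResult(pair=pair, table=table, alpha=alpha)


def de_union(pair_results: list[DePairResult]) -> tuple[set[str], dict[tuple[str, str], int]]:
    """Union of DE sets over pairs plus the per-pair counts."""
    if not pair_results:
        raise ValueError("need at least one pair result")
    union: set[str] = set()
    per_pair: dict[tuple[str, str], int] = {}
    for res in pair_results:
        de = res.de_genes
        per_pair[res.pair] = len(de)
        union |= de
    return union, per_pair


def proportion_chi_square(hits_a: int, total_a: int, hits_b: int, total_b: int) -> float:
    """Two-tailed Pearson chi-square (1 df, no continuity correction) on a 2x2."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if hits_a > total_a or hits_b > total_b:
        raise ValueError("hits cannot exceed totals")
    table = np.array([[hits_a, total_a - hits_a], [hits_b, total_b - hits_b]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        warnings.warn("expected cell < 1; Fisher's exact test is recommended", stacklevel=2)
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))
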