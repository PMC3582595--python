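"""Within-population expression variability (coefficient of variation).

Per gene and population: M = mean intensity, sigma = sample standard
deviation (n-1), CV = sigma / M.  CV is computed on intensities as
provided (no log transform) and is undefined when M <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Gene x sample intensities with a sample -> population map."""

    values: pd.DataFrame  # index: gene IDs, columns: sample IDs
    population_of: pd.Series  # index: sample IDs, values: population labels

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.population_of.index)
        if missing:
            raise ValueError(f"samples without population label: {sorted(missing)[:5]}")
        self.population_of = self.population_of.reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def populations(self) -> list[str]:
        return sorted(self.population_of.unique())

    def samples_in(self, population: str) -> list[str]:
        return list(self.population_of.index[self.population_of == population])

    def population_means(self) -> pd.DataFrame:
        """Per-gene mean intensity per population (genes x populations)."""
        return pd.DataFrame(
            {p: self.values[self.samples_in(p)].mean(axis=1) for p in self.populations}
        )

    @classmethod
    def read(cls, matrix_path, populations_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        pops = pd.read_csv(populations_path, sep="\t", dtype=str)
        if not {"sample_id", "population"}.issubset(pops.columns):
            raise ValueError("population map needs columns sample_id, population")
        return cls(values=values, population_of=pops.set_index("sample_id")["population"])

    def write(self, matrix_path, populations_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.population_of.rename("population").rename_axis("sample_id").reset_index().to_csv(
            populations_path, sep="\t", index=False
        )


@dataclass
class CvTable:
    """Long table: one row per (gene, population) with M, sigma, CV.

    ``defined`` is False where M <= 0; those rows are excluded from group
    comparisons.
    """

    table: pd.DataFrame  # columns: gene_id, population, mean, sd, cv, defined

    def cv_series(self, population: str) -> pd.Series:
        sub = self.table[(self.table["population"] == population) & self.table["defined"]]
        return sub.set_index("gene_id")["cv"]

    @property
    def n_undefined(self) -> int:
        return int((~self.table["defined"]).sum())


def cv_table(matrix: ExpressionMatrix) -> CvTable:
    """Coefficient of variation per gene per population (sample sd, n-1)."""
    rows = []
    for pop in matrix.populations:
        cols = matrix.samples_in(pop)
        if len(cols) < 2:
            raise ValueError(f"population {pop!r} has {len(cols)} sample(s); need >= 2")
        sub = matrix.values[cols]
        m = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        defined = m > 0
        cv = pd.Series(np.where(defined, sd / m.where(defined, np.nan), np.nan), index=m.index)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": m.index,
                    "population": pop,
                    "mean": m.values,
                    "sd": sd.values,
                    "cv": cv.values,
                    "defined": defined.values,
                }
            )
        )
    return CvTable(table=pd.concat(rows, ignore_index=True))


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 20 observations and no ties;
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_cv_groups(
    cv: CvTable, population: str, group_a: set[str], group_b: set[str]
) -> tuple[float, float, float]:
    """Group mean CVs and the two-tailed rank-sum p for one population."""
    series = cv.cv_series(population)
    va = series.reindex(sorted(group_a)).dropna().to_numpy()
    vb = series.reindex(sorted(group_b)).dropna().to_numpy()
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("both groups must be non-empty after dropping undefined CVs")
    return float(np.mean(va)), float(np.mean(vb)), rank_sum_p(va, vb)
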