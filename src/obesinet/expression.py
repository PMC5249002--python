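"""Tissue-expression categorization and genome-background comparison.

Genes are placed into six mutually exclusive categories from their
transcript abundance profile across tissues (32 human tissues in the
reference classification), using detection- and fold-threshold rules:

* ``Tissue_enriched`` — one tissue at least ``fold`` times every other tissue;
* ``Group_enriched``  — a group of 2..7 tissues whose mean is at least
  ``fold`` times every tissue outside the group;
* ``Tissue_enhanced`` — some tissue at least ``fold`` times the mean of all
  other tissues;
* ``Expressed_in_all`` — detected (>= ``detect``) in every tissue;
* ``Not_detected``    — below ``detect`` everywhere;
* ``Mixed``           — everything else.

``Tissue_elevated`` consolidates the first three categories.  Genes absent
from the matrix are reported as ``Not_found``.  Category fractions of a gene
set are compared against the genome-wide fractions with a two-cell
chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError, normalize_symbol

CATEGORIES = (
    "Tissue_enriched",
    "Group_enriched",
    "Tissue_enhanced",
    "Expressed_in_all",
    "Mixed",
    "Not_detected",
)
NOT_FOUND = "Not_found"
ELEVATED = frozenset({"Tissue_enriched", "Group_enriched", "Tissue_enhanced"})


@dataclass(frozen=True)
class ClassifyParams:
    detect: float = 1.0
    fold: float = 5.0
    group_min: int = 2
    group_max: int = 7

    def __post_init__(self):
        if self.detect <= 0 or self.fold <= 0:
            raise ValidationError("detect and fold must be positive")
        if not (1 <= self.group_min <= self.group_max):
            raise ValidationError("invalid group size range")


class ExpressionMatrix:
    """genes x tissues abundance matrix backed by a pandas DataFrame."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValidationError("gene and tissue labels must be unique")
        values = frame.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValidationError("expression values must be non-negative")
        frame = frame.copy()
        frame.index = [normalize_symbol(g) for g in frame.index]
        self.frame = frame

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def profile(self, symbol: str) -> np.ndarray:
        return self.frame.loc[normalize_symbol(symbol)].to_numpy(dtype=float)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.frame.index

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="symbol")


def classify_gene(profile, params: ClassifyParams = ClassifyParams()) -> str:
    """Assign one expression category to an abundance profile.

    Precedence follows the order of :data:`CATEGORIES`.  The group-enriched
    search checks the top-m tissues for each group size m; because the top-m
    subset simultaneously maximizes the group mean and minimizes the maximum
    outside the group, this is equivalent to exhausting all subsets.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("profile must be a vector of length >= 2")
    if (x < 0).any():
        raise ValidationError("negative abundance")
    order = np.argsort(-x, kind="stable")
    xs = x[order]
    detect, fold = params.detect, params.fold

    # Tissue enriched: detected top tissue >= fold x every other tissue.
    if xs[0] >= detect and xs[0] >= fold * xs[1]:
        return "Tissue_enriched"
    # Group enriched over group sizes group_min..group_max.
    upper = min(params.group_max, x.size - 1)
    for m in range(params.group_min, upper + 1):
        group_mean = xs[:m].mean()
        outside_max = xs[m]
        if group_mean >= detect and group_mean >= fold * outside_max:
            return "Group_enriched"
    # Tissue enhanced: some tissue >= fold x mean of the others.
    total = x.sum()
    means_of_rest = (total - x) / (x.size - 1)
    enhanced = (x >= detect) & (x >= fold * means_of_rest)
    if enhanced.any():
        return "Tissue_enhanced"
    if (x >= detect).all():
        return "Expressed_in_all"
    if (x < detect).all():
        return "Not_detected"
    return "Mixed"


def tissue_elevated(category: str) -> bool:
    """True iff the category belongs to the consolidated elevated class."""
    return category in ELEVATED


def classify_set(
    symbols, matrix: ExpressionMatrix, params: ClassifyParams = ClassifyParams()
) -> pd.DataFrame:
    """Category table (symbol, category, elevated) for a gene set.

    Symbols missing from the matrix get ``Not_found``.
    """
    rows = []
    for sym in sorted({normalize_symbol(s) for s in symbols}):
        if sym in matrix:
            cat = classify_gene(matrix.profile(sym), params)
        else:
            cat = NOT_FOUND
        rows.append({"symbol": sym, "category": cat, "elevated": tissue_elevated(cat)})
    return pd.DataFrame(rows, columns=["symbol", "category", "elevated"])


@dataclass(frozen=True)
class CategoryComparison:
    subset_count: int
    subset_size: int
    genome_fraction: float
    statistic: float
    p_value: float
    stars: int


def _stars(p: float) -> int:
    if p < 0.001:
        return 3
    if p < 0.01:
        return 2
    if p < 0.05:
        return 1
    return 0


def chi_square_vs_genome(
    subset_count: int, subset_size: int, genome_fraction: float
) -> CategoryComparison:
    """Two-cell chi-square goodness-of-fit of a category fraction vs genome.

    statistic = (k - np)^2/(np) + ((n-k) - n(1-p))^2/(n(1-p)), 1 df,
    no continuity correction.
    """
    if subset_size < 1:
        raise ValidationError("subset_size must be >= 1")
    if not 0 < genome_fraction < 1:
        raise ValidationError("genome_fraction must lie strictly in (0, 1)")
    if not 0 <= subset_count <= subset_size:
        raise ValidationError("subset_count must be between 0 and subset_size")
    n, k, p = subset_size, subset_count, genome_fraction
    expected = np.array([n * p, n * (1 - p)])
    observed = np.array([k, n - k])
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, df=1))
    return CategoryComparison(k, n, p, statistic, p_value, _stars(p_value))


def compare_categories(
    category_table: pd.DataFrame,
    genome_fractions: dict[str, float],
    consolidate_not_found: bool = True,
) -> pd.DataFrame:
    """Chi-square comparison of every category fraction against the genome.

    With ``consolidate_not_found`` the ``Not_found`` genes are pooled with
    ``Not_detected`` (they remain in every denominator either way).
    """
    cats = category_table["category"].copy()
    if consolidate_not_found:
        cats = cats.replace({NOT_FOUND: "Not_detected"})
    n = len(cats)
    rows = []
    for cat in CATEGORIES + ("Tissue_elevated",):
        if cat == "Tissue_elevated":
            k = int(cats.isin(ELEVATED).sum())
        else:
            k = int((cats == cat).sum())
        p = genome_fractions.get(cat)
        if p is None or not 0 < p < 1 or n == 0:
            continue
        cmp = chi_square_vs_genome(k, n, p)
        rows.append(
            {
                "category": cat,
                "subset_count": k,
                "subset_size": n,
                "subset_fraction": k / n,
                "genome_fraction": p,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "stars": cmp.stars,
            }
        )
    return pd.DataFrame(rows)
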