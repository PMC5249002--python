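"""Specificity index (SI), permutation pSI, and tissue-overlap testing.

The SI of gene *g* in tissue *t* is its mean rank of expression fold-ratios
against every other tissue: for each other tissue *t'*, genes are ranked
(descending, average ties) by (e_gt + eps) / (e_gt' + eps), and SI_gt is the
mean of g's ranks over all t' != t.  SI = 1 marks a transcript that tops
every pairwise comparison, i.e. is maximally tissue-specific.

The pSI attaches an empirical p-value to SI via a column-permutation null:
each of B permutations independently shuffles every tissue column across
genes and SI is recomputed; null SI values are pooled within a tissue
(per-gene mode available) and

    pSI_gt = (1 + #{null SI <= SI_gt}) / (1 + B * G)

with the add-one form so pSI is always positive.  Tissue-enriched lists are
genes with pSI strictly below a threshold; candidate-list overlaps with
those lists are tested per tissue by a one-sided Fisher exact test with
Benjamini-Hochberg correction across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError, normalize_symbol
from .enrichment import bh_adjust
from .expression import ExpressionMatrix


def _si_values(values: np.ndarray, epsilon: float) -> np.ndarray:
    """SI for a raw genes x tissues array (no labels)."""
    n_genes, n_tissues = values.shape
    si = np.zeros((n_genes, n_tissues))
    for t in range(n_tissues):
        rank_sum = np.zeros(n_genes)
        for t2 in range(n_tissues):
            if t2 == t:
                continue
            ratio = (values[:, t] + epsilon) / (values[:, t2] + epsilon)
            # descending ranks, average ties
            rank_sum += stats.rankdata(-ratio, method="average")
        si[:, t] = rank_sum / (n_tissues - 1)
    return si


def specificity_index(matrix: ExpressionMatrix, epsilon: float = 1e-6) -> pd.DataFrame:
    """Mean-rank specificity index per (gene, tissue); SI >= 1 always."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    values = matrix.values
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise ValidationError("need at least 2 genes and 2 tissues")
    return pd.DataFrame(
        _si_values(values, epsilon), index=matrix.genes, columns=matrix.tissues
    )


@dataclass
class SpecificityResult:
    si: pd.DataFrame
    psi: pd.DataFrame
    B: int
    seed: int | None


def psi(
    matrix: ExpressionMatrix,
    B: int = 200,
    seed: int | None = 0,
    epsilon: float = 1e-6,
    pool: bool = True,
    permutations=None,
) -> SpecificityResult:
    """Permutation pSI per (gene, tissue).

    ``permutations`` may supply an explicit iterable of per-column index
    arrays (shape tissues x genes) replacing the seeded random shuffles;
    this is how an exhaustive null is computed on tiny matrices.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    values = matrix.values
    n_genes, n_tissues = values.shape
    si_obs = _si_values(values, epsilon)

    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = (
            np.stack([rng.permutation(n_genes) for _ in range(n_tissues)])
            for _ in range(B)
        )
        n_perm = B
    else:
        permutations = list(permutations)
        n_perm = len(permutations)

    null = np.empty((n_perm, n_genes, n_tissues))
    for b, perm in enumerate(permutations):
        shuffled = np.column_stack(
            [values[perm[t], t] for t in range(n_tissues)]
        )
        null[b] = _si_values(shuffled, epsilon)

    psi_vals = np.empty_like(si_obs)
    for t in range(n_tissues):
        if pool:
            null_t = np.sort(null[:, :, t].ravel())
        else:
            null_t = None
        for g in range(n_genes):
            if pool:
                count = np.searchsorted(null_t, si_obs[g, t], side="right")
                denom = 1 + n_perm * n_genes
            else:
                col = null[:, g, t]
                count = int((col <= si_obs[g, t]).sum())
                denom = 1 + n_perm
            psi_vals[g, t] = (1 + count) / denom

    index, columns = matrix.genes, matrix.tissues
    return SpecificityResult(
        si=pd.DataFrame(si_obs, index=index, columns=columns),
        psi=pd.DataFrame(psi_vals, index=index, columns=columns),
        B=n_perm,
        seed=seed,
    )


@dataclass
class TissueEnrichedLists:
    threshold: float
    lists: dict[str, set[str]]


def enriched_lists(result: SpecificityResult, threshold: float = 0.05) -> TissueEnrichedLists:
    """Per-tissue gene lists at pSI strictly below the threshold."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    lists = {
        tissue: set(result.psi.index[result.psi[tissue] < threshold])
        for tissue in result.psi.columns
    }
    return TissueEnrichedLists(threshold=threshold, lists=lists)


@dataclass
class OverlapTestResult:
    tissue: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_bh: float


def overlap_test(
    candidates, lists: TissueEnrichedLists, universe
) -> list[OverlapTestResult]:
    """One-sided Fisher enrichment test of a candidate list per tissue.

    Each tissue list is intersected with the universe first; BH correction
    runs across tissues; p_bh < 0.05 flags a significant tissue.
    """
    universe = {normalize_symbol(s) for s in universe}
    if not universe:
        raise ValidationError("universe must be nonempty")
    candidates = {normalize_symbol(s) for s in candidates} & universe
    N, n = len(universe), len(candidates)
    tissues = sorted(lists.lists)
    raw = []
    counts = []
    for tissue in tissues:
        tissue_set = {normalize_symbol(s) for s in lists.lists[tissue]} & universe
        K = len(tissue_set)
        k = len(candidates & tissue_set)
        # upper tail P(X >= k) of hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        raw.append(min(p, 1.0))
        counts.append((k, K))
    adjusted = bh_adjust(raw)
    return [
        OverlapTestResult(tissue=t, k=k, n=n, K=K, N=N, p_raw=p, p_bh=q)
        for t, (k, K), p, q in zip(tissues, counts, raw, adjusted)
    ]


def overlap_report(results: list[OverlapTestResult], path=None) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "tissue": r.tissue,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_bh": r.p_bh,
                "significant": r.p_bh < 0.05,
            }
            for r in results
        ]
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
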