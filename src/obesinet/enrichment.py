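"""Term-enrichment statistics: hypergeometric tail, fold enrichment, BH.

Enrichment of a gene list in annotation terms (GO terms, pathways) against
an explicit universe, with the retention filter fold >= 1.5 and BH-adjusted
p <= 0.05 (both bounds inclusive).  An optional EASE mode subtracts one hit
from the tail, the conservative variant some annotation servers apply;
default off.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError, normalize_symbol


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N, K, n).

    N is the universe size, K the term size, n the list size, k the hits.
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValidationError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N) — observed over expected hit rate."""
    if n <= 0 or K <= 0:
        raise ValidationError("n and K must be positive")
    return (k / n) / (K / N)


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# GMT term collections
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT file -> {term: (description, member set)}; symbols upper-cased."""
    terms: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:80]!r}")
        term, description, members = parts[0], parts[1], parts[2:]
        terms[term] = (description, {normalize_symbol(m) for m in members if m})
    return terms


def write_gmt(terms: Mapping[str, tuple[str, set[str]]], path) -> None:
    lines = [
        "\t".join([term, desc] + sorted(members))
        for term, (desc, members) in sorted(terms.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich_gene_list(
    genes: Iterable[str],
    terms: Mapping[str, tuple[str, set[str]]],
    universe: Iterable[str],
    fold_min: float = 1.5,
    alpha: float = 0.05,
    ease: bool = False,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment table with BH correction and the retention filter.

    Terms are intersected with the universe; terms with no hit are excluded
    before BH unless ``include_zero``.  A row is retained when
    fold >= fold_min and p_bh <= alpha.
    """
    universe = {normalize_symbol(s) for s in universe}
    if not universe:
        raise ValidationError("universe must be nonempty")
    genes = {normalize_symbol(s) for s in genes} & universe
    N, n = len(universe), len(genes)
    columns = ["term", "description", "k", "n", "K", "N", "fold", "p_raw", "p_bh", "retained"]
    rows = []
    for term in sorted(terms):
        description, members = terms[term]
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        if k == 0 and not include_zero:
            continue
        tail_k = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(tail_k, n, K, N) if n else 1.0
        fold = fold_enrichment(k, n, K, N) if n else 0.0
        rows.append(
            {"term": term, "description": description, "k": k, "n": n, "K": K,
             "N": N, "fold": fold, "p_raw": p}
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    frame = pd.DataFrame(rows)
    frame["p_bh"] = bh_adjust(frame["p_raw"])
    frame["retained"] = (frame["fold"] >= fold_min) & (frame["p_bh"] <= alpha)
    return frame[columns].sort_values(["p_bh", "term"]).reset_index(drop=True)
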