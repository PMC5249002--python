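"""Brain-specific sublist, induced PPI subnetwork, GWAS-gene prioritization.

The brain-specific sublist unites (a) genes in the brain tissue-enriched
list at pSI < 0.05 and (b) genes differentially expressed (|log2FC| > 1,
strict) in hypothalamic AGRP- or POMC-expressing neurons between fed and
food-deprived states.  The Experimental (physical PPI) network restricted
to this sublist is the brain-specific network; its GWAS-set nodes are
reported with their neighbors, degrees, dense ranks and curated
interaction-evidence quality, and finally ordered by five criteria:

1. rank group (Rank_1 before Rank_2);
2. the best dense rank achieved in the Experimental / Knowledge / Homology
   networks (sum-of-degrees mode available);
3. brain-sublist membership (both origins > one origin > absent);
4. degree in the brain-specific network;
5. best neighbor-interaction evidence quality (Very_high > High > Medium).

The ordering is lexicographic in that criterion order, ties alphabetical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core import Compendium, RANK_2, ValidationError, normalize_symbol
from .network import Network, degree_rank_all, restrict_to

QUALITY_ORDER = {"Very_high": 0, "High": 1, "Medium": 2, "unannotated": 3}


@dataclass(frozen=True)
class DegRecord:
    """Differential-expression record for one gene (any field may be None)."""

    symbol: str
    log2fc_agrp: float | None = None
    log2fc_pomc: float | None = None
    log2fc_agpo: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "symbol", normalize_symbol(self.symbol))
        if all(
            v is None or (isinstance(v, float) and math.isnan(v))
            for v in (self.log2fc_agrp, self.log2fc_pomc, self.log2fc_agpo)
        ):
            raise ValidationError(f"record {self.symbol} has no fold-change values")

    def fold_changes(self) -> list[float]:
        return [
            v
            for v in (self.log2fc_agrp, self.log2fc_pomc, self.log2fc_agpo)
            if v is not None and not math.isnan(v)
        ]


def read_deg_table(path) -> list[DegRecord]:
    """TSV columns: symbol, lfc_agrp, lfc_pomc, lfc_agpo (blanks allowed)."""
    table = pd.read_csv(path, sep="\t")
    records = []
    for row in table.itertuples(index=False):
        records.append(
            DegRecord(
                symbol=row.symbol,
                log2fc_agrp=getattr(row, "lfc_agrp", None),
                log2fc_pomc=getattr(row, "lfc_pomc", None),
                log2fc_agpo=getattr(row, "lfc_agpo", None),
            )
        )
    return records


@dataclass
class BrainSublist:
    symbols: set[str]
    origin: dict[str, set[str]]  # symbol -> subset of {"TSEA_brain", "DEG"}


def build_brain_sublist(
    tsea_brain: Iterable[str],
    deg_records: Iterable[DegRecord],
    lfc_threshold: float = 1.0,
) -> BrainSublist:
    """Union of the TSEA brain list and the strict-|log2FC| DEG set."""
    if lfc_threshold <= 0:
        raise ValidationError("lfc_threshold must be positive")
    tsea = {normalize_symbol(s) for s in tsea_brain}
    deg = {
        r.symbol
        for r in deg_records
        if any(abs(v) > lfc_threshold for v in r.fold_changes())
    }
    origin: dict[str, set[str]] = {}
    for sym in tsea:
        origin.setdefault(sym, set()).add("TSEA_brain")
    for sym in deg:
        origin.setdefault(sym, set()).add("DEG")
    return BrainSublist(symbols=tsea | deg, origin=origin)


def build_brain_network(
    experimental: Network, sublist: BrainSublist
) -> tuple[Network, list[str]]:
    """Induced PPI subgraph on the sublist plus the isolated members.

    Sublist members with no surviving edge (including those absent from
    the Experimental network altogether) are returned as isolated.
    """
    induced = restrict_to(experimental, sublist.symbols)
    # drop isolated nodes from the network proper; report them separately
    isolated = sorted(
        sym for sym in sublist.symbols if induced.degree(sym) == 0
    )
    induced.graph.remove_nodes_from(
        [v for v in list(induced.graph.nodes) if induced.graph.degree(v) == 0]
    )
    return induced, isolated


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    a, b = normalize_symbol(a), normalize_symbol(b)
    return (a, b) if a < b else (b, a)


def read_quality_annotations(path) -> dict[tuple[str, str], str]:
    """TSV columns gene_a, gene_b, quality[, note] -> canonical-pair map."""
    table = pd.read_csv(path, sep="\t")
    out = {}
    for row in table.itertuples(index=False):
        quality = str(row.quality)
        if quality not in QUALITY_ORDER:
            raise ValidationError(f"unknown evidence quality {quality!r}")
        out[_canonical_pair(row.gene_a, row.gene_b)] = quality
    return out


@dataclass
class GwasNetworkRow:
    symbol: str
    rank_group: str
    neighbors: list[tuple[str, int, int]]  # (symbol, degree, dense rank)
    n_neighbors: int
    evidence_quality: str


def gwas_table(
    brain_net: Network,
    compendium: Compendium,
    quality_annotations: Mapping[tuple[str, str], str] | None = None,
) -> list[GwasNetworkRow]:
    """Per-GWAS-gene report over the brain-specific network.

    One row per GWAS-sourced node with at least one neighbor; neighbor
    degrees and dense ranks come from the full brain network's degree
    ranking.  Row quality is the best quality annotated for any incident
    pair (curated input; never inferred).
    """
    quality_annotations = quality_annotations or {}
    ranks = degree_rank_all(brain_net)
    rows = []
    for sym in sorted(brain_net.nodes() & compendium.gwas_symbols()):
        nbrs = sorted(brain_net.neighbors(sym))
        if not nbrs:
            continue
        neighbor_info = [(n, ranks[n][0], ranks[n][1]) for n in nbrs]
        qualities = [
            quality_annotations.get(_canonical_pair(sym, n), "unannotated")
            for n in nbrs
        ]
        best = min(qualities, key=QUALITY_ORDER.__getitem__)
        rows.append(
            GwasNetworkRow(
                symbol=sym,
                rank_group=compendium[sym].rank,
                neighbors=neighbor_info,
                n_neighbors=len(neighbor_info),
                evidence_quality=best,
            )
        )
    return rows


def gwas_table_frame(rows: list[GwasNetworkRow], path=None) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "symbol": r.symbol,
                "rank_group": r.rank_group,
                "n_neighbors": r.n_neighbors,
                "neighbors": ";".join(
                    f"{n}({deg}/{rank})" for n, deg, rank in r.neighbors
                ),
                "evidence_quality": r.evidence_quality,
            }
            for r in rows
        ]
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


# ---------------------------------------------------------------------------
# five-criterion prioritization
# ---------------------------------------------------------------------------

_NO_RANK = 10**9


@dataclass
class PrioritizationReport:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def ordering(self) -> list[str]:
        return list(self.table["symbol"])


def prioritize(
    compendium: Compendium,
    nets: Mapping[str, Network],
    brain: BrainSublist,
    brain_net: Network,
    qualities: Mapping[tuple[str, str], str] | None = None,
    network_mode: str = "best_rank",
) -> PrioritizationReport:
    """Order GWAS genes lexicographically by the five ranking criteria.

    ``network_mode='best_rank'`` summarizes criterion 2 as the best dense
    rank achieved across the three networks; ``'sum_degrees'`` uses the
    total degree instead.
    """
    if network_mode not in ("best_rank", "sum_degrees"):
        raise ValidationError(f"unknown network_mode {network_mode!r}")
    qualities = qualities or {}
    rank_maps = {name: degree_rank_all(net) for name, net in nets.items()}
    rows = []
    for sym in sorted(compendium.gwas_symbols()):
        rec = compendium[sym]
        degrees = {
            name: rank_maps[name].get(sym, (0, _NO_RANK))[0] for name in nets
        }
        net_ranks = [rank_maps[name].get(sym, (0, _NO_RANK))[1] for name in nets]
        if network_mode == "best_rank":
            crit2 = min(net_ranks) if net_ranks else _NO_RANK
        else:
            crit2 = -sum(degrees.values())  # more neighbors sorts earlier
        origin = brain.origin.get(sym, set())
        crit3 = {2: 0, 1: 1, 0: 2}[len(origin)]
        brain_degree = brain_net.degree(sym)
        nbrs = sorted(brain_net.neighbors(sym))
        pair_qualities = [
            qualities.get(_canonical_pair(sym, n), "unannotated") for n in nbrs
        ]
        best_quality = (
            min(pair_qualities, key=QUALITY_ORDER.__getitem__)
            if pair_qualities
            else "unannotated"
        )
        rows.append(
            {
                "symbol": sym,
                "rank_group": rec.rank,
                "deg_experimental": degrees.get("Experimental", 0),
                "deg_knowledge": degrees.get("Knowledge", 0),
                "deg_homology": degrees.get("Homology", 0),
                "network_criterion": crit2,
                "brain_origin": "+".join(sorted(origin)) if origin else "",
                "brain_origin_level": crit3,
                "brain_degree": brain_degree,
                "evidence_quality": best_quality,
                "_sort": (
                    0 if rec.rank != RANK_2 else 1,
                    crit2,
                    crit3,
                    -brain_degree,
                    QUALITY_ORDER[best_quality],
                    sym,
                ),
            }
        )
    rows.sort(key=lambda r: r["_sort"])
    frame = pd.DataFrame(rows).drop(columns=["_sort"])
    if not frame.empty:
        frame.insert(0, "priority", range(1, len(frame) + 1))
    return PrioritizationReport(table=frame)
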