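"""Compendium data model: gene records, source merging, ranking, set arithmetic.

The compendium is a catalog of genes implicated in feeding-behavior (FB) or
body-weight (BW) regulation.  Each gene carries the set of evidence sources it
was extracted from (literature, OMIM allelic variants, OMIM full text,
obesity syndromes, GWAS meta-analyses), free-text GWAS status comments, a
coding status, and a rank reflecting whether a biological interpretation
linking it to BW/FB regulation exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The five evidence sources a compendium record may belong to.
SOURCES = (
    "Publications",
    "OMIM_allelic_variants",
    "OMIM_all_text",
    "Syndromes",
    "GWAS_meta_analysis",
)

#: Sources conferring Rank_1 directly (a curated biological interpretation).
RANK1_SOURCES = frozenset(
    {"Publications", "OMIM_allelic_variants", "OMIM_all_text", "Syndromes"}
)

#: GWAS comment tags that confer a biological interpretation on a
#: GWAS-only gene.  Matching is exact on normalized (lower-cased,
#: whitespace-collapsed) tags, never substring.
DEFAULT_BIOLOGICAL_TAGS = frozenset(
    {"biological candidate", "biologically relevant to obesity"}
)

#: The two OMIM subsets, collapsed into one "OMIM" source for 4-set views.
OMIM_SUBSETS = frozenset({"OMIM_allelic_variants", "OMIM_all_text"})

CODING_VALUES = ("protein_coding", "ncRNA", "other_noncoding")

RANK_1 = "Rank_1"
RANK_2 = "Rank_2"
UNASSIGNED = "unassigned"


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A record or argument violates a contract."""


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def normalize_tag(tag: str) -> str:
    return " ".join(str(tag).strip().lower().split())


@dataclass
class GeneRecord:
    """One compendium entry."""

    symbol: str
    sources: frozenset = frozenset()
    gwas_comments: frozenset = frozenset()
    coding: str = "protein_coding"
    rank: str = UNASSIGNED
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.symbol = normalize_symbol(self.symbol)
        self.sources = frozenset(self.sources)
        self.gwas_comments = frozenset(normalize_tag(t) for t in self.gwas_comments)
        unknown = self.sources - set(SOURCES)
        if unknown:
            raise ValidationError(
                f"unknown source label(s) {sorted(unknown)} for symbol {self.symbol}"
            )

    def merged_with(self, other: "GeneRecord") -> "GeneRecord":
        """Union-merge a duplicate row for the same symbol."""
        if other.symbol != self.symbol:
            raise ValidationError("cannot merge records with different symbols")
        annotations = dict(self.annotations)
        annotations.update(other.annotations)
        return GeneRecord(
            symbol=self.symbol,
            sources=self.sources | other.sources,
            gwas_comments=self.gwas_comments | other.gwas_comments,
            coding=self.coding if self.coding != "protein_coding" else other.coding,
            rank=self.rank if self.rank != UNASSIGNED else other.rank,
            annotations=annotations,
        )


class Compendium:
    """symbol -> GeneRecord map with per-source provenance counts."""

    def __init__(self, records: Iterable[GeneRecord] = ()) -> None:
        self.records: dict[str, GeneRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: GeneRecord) -> None:
        existing = self.records.get(record.symbol)
        self.records[record.symbol] = (
            existing.merged_with(record) if existing is not None else record
        )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.records

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self.records[normalize_symbol(symbol)]

    def __iter__(self):
        return iter(self.records.values())

    def symbols(self) -> set[str]:
        return set(self.records)

    @property
    def provenance(self) -> dict[str, int]:
        counts = {s: 0 for s in SOURCES}
        for rec in self.records.values():
            for s in rec.sources:
                counts[s] += 1
        return counts

    def gwas_symbols(self) -> set[str]:
        return {
            r.symbol for r in self.records.values() if "GWAS_meta_analysis" in r.sources
        }

    def rank_symbols(self, rank: str) -> set[str]:
        return {r.symbol for r in self.records.values() if r.rank == rank}


# ---------------------------------------------------------------------------
# ingestion / serialization
# ---------------------------------------------------------------------------

DEFAULT_DIALECT = {
    "symbol": "symbol",
    "sources": "sources",
    "gwas_comments": "gwas_comments",
    "coding": "coding",
    "rank": "rank",
    "list_sep": ";",
}


def _split_list(cell, sep: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [part.strip() for part in str(cell).split(sep) if part.strip()]


def parse_gene_table(path, dialect: Mapping | None = None) -> Compendium:
    """Read a TSV gene table into a Compendium.

    Duplicate rows for one symbol are merged by union of sources and
    comments; symbols are upper-cased.  A missing symbol column raises
    :class:`FormatError`; an unknown source label raises
    :class:`ValidationError` naming the offending row.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if d["symbol"] not in table.columns:
        raise FormatError(f"missing symbol column {d['symbol']!r} in {path}")
    comp = Compendium()
    for i, row in table.iterrows():
        try:
            rec = GeneRecord(
                symbol=row[d["symbol"]],
                sources=_split_list(row.get(d["sources"]), d["list_sep"]),
                gwas_comments=_split_list(row.get(d["gwas_comments"]), d["list_sep"]),
                coding=row.get(d["coding"], "protein_coding") or "protein_coding",
                rank=row.get(d["rank"], UNASSIGNED) or UNASSIGNED,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i + 2} of {path}: {exc}") from exc
        comp.add(rec)
    return comp


def write_gene_table(compendium: Compendium, path, dialect: Mapping | None = None) -> None:
    """Write a Compendium back to the TSV dialect of :func:`parse_gene_table`."""
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = d["list_sep"]
    rows = []
    for rec in sorted(compendium, key=lambda r: r.symbol):
        rows.append(
            {
                d["symbol"]: rec.symbol,
                d["sources"]: sep.join(sorted(rec.sources)),
                d["gwas_comments"]: sep.join(sorted(rec.gwas_comments)),
                d["coding"]: rec.coding,
                d["rank"]: rec.rank,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# merging, ranking, set arithmetic
# ---------------------------------------------------------------------------


def merge_sources(source_sets: Sequence[tuple[str, Iterable[str]]]) -> Compendium:
    """Union per-source symbol sets into one deduplicated compendium."""
    comp = Compendium()
    for label, symbols in source_sets:
        if label not in SOURCES:
            raise ValidationError(f"unknown source label {label!r}")
        for sym in symbols:
            comp.add(GeneRecord(symbol=sym, sources={label}))
    return comp


def assign_rank(
    record: GeneRecord, biological_tags: Iterable[str] = DEFAULT_BIOLOGICAL_TAGS
) -> GeneRecord:
    """Rank_1 iff the gene has any curated source or a biological GWAS tag.

    Genes present only in the GWAS meta-analysis set and lacking a comment
    conferring biological interpretation fall to Rank_2.
    """
    if not record.sources:
        raise ValidationError(f"record {record.symbol} has no sources")
    tags = frozenset(normalize_tag(t) for t in biological_tags)
    if record.sources & RANK1_SOURCES or record.gwas_comments & tags:
        return replace(record, rank=RANK_1)
    return replace(record, rank=RANK_2)


def assign_ranks(
    compendium: Compendium, biological_tags: Iterable[str] = DEFAULT_BIOLOGICAL_TAGS
) -> Compendium:
    """Apply :func:`assign_rank` to every record, in place, and return it."""
    for sym, rec in list(compendium.records.items()):
        compendium.records[sym] = assign_rank(rec, biological_tags)
    return compendium


def _effective_sources(record: GeneRecord, collapse_omim: bool) -> frozenset:
    if not collapse_omim:
        return record.sources
    collapsed = set(record.sources - OMIM_SUBSETS)
    if record.sources & OMIM_SUBSETS:
        collapsed.add("OMIM")
    return frozenset(collapsed)


def intersect_at_least(
    compendium: Compendium, k: int, collapse_omim: bool = True
) -> set[str]:
    """Symbols whose (optionally OMIM-collapsed) source count is >= k."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    return {
        rec.symbol
        for rec in compendium
        if len(_effective_sources(rec, collapse_omim)) >= k
    }


def venn_regions(named_sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Disjoint-region counts for 2 or 3 named symbol sets.

    Region keys join member names with ``&`` (e.g. ``"A&B"``); counts over
    all regions sum to the size of the union.
    """
    names = list(named_sets)
    if len(names) not in (2, 3):
        raise ValidationError("venn_regions accepts exactly 2 or 3 sets")
    sets = {name: {normalize_symbol(s) for s in named_sets[name]} for name in names}
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    # every nonempty subset of names defines one exclusive region
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            regions["&".join(combo)] = len(inside)
    return regions


def venn_report(named_sets: Mapping[str, Iterable[str]], path=None) -> dict:
    """Venn counts as a JSON-serializable report; optionally written to disk."""
    regions = venn_regions(named_sets)
    report = {
        "sets": {name: len({normalize_symbol(s) for s in v}) for name, v in named_sets.items()},
        "regions": regions,
        "union": sum(regions.values()),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
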