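"""Seeded generators for every pipeline input, plus the reported-counts fixture.

The generators emulate the shape of the pipeline's real inputs — gene
annotation tables with controlled evidence-source overlaps, expression
matrices with planted category/specificity structure, differential-
expression tables, and weighted edge lists with planted dense modules —
under a single :class:`SimConfig` whose seed makes every output
reproducible byte for byte.

``fixture_reported_counts`` emits the packaged fixture of gene lists and
counts reported in the body-weight genetics literature (multi-source genes, the
GWAS/TSEA/DEG Venn, top-degree genes, the curated neighbor-quality rows).
Gene lists that exist only in unpublished supplementary material are
represented by clearly labeled synthetic placeholder symbols.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SOURCES, Compendium, GeneRecord, ValidationError
from .expression import ExpressionMatrix

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_overlap_spec() -> dict[tuple[str, ...], int]:
    """Source-region counts consistent with the reported source-set totals.

    Realizes per-source sizes 105 / 73 / 263 / 37 / 184 and a 578-gene
    union, with the eight known triple-membership genes; the pairwise-only
    overlap split is not printed anywhere and is chosen here.
    """
    P, AV, AT, SY, GW = SOURCES
    return {
        (P,): 53,
        (AV,): 37,
        (AT,): 233,
        (SY,): 28,
        (GW,): 151,
        (P, AV): 20,
        (P, AT): 15,
        (P, GW): 10,
        (AT, GW): 15,
        (AV, SY): 8,
        (P, AV, GW): 7,
        (AV, SY, GW): 1,
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 200
    n_tissues: int = 32
    source_overlap_spec: dict = field(default_factory=_default_overlap_spec)
    #: fraction of GWAS-only genes given a biological-candidate comment,
    #: sized so the generated compendium reproduces the printed 459/119
    #: Rank_1 / Rank_2 split (32 of 151 GWAS-only genes).
    gwas_biological_fraction: float = 32 / 151
    planted_categories: dict = field(
        default_factory=lambda: {
            "Tissue_enriched": 10,
            "Group_enriched": 10,
            "Tissue_enhanced": 10,
            "Expressed_in_all": 10,
            "Mixed": 10,
            "Not_detected": 10,
        }
    )
    planted_specific: tuple = (("T1", 10, 10.0),)
    #: distinct sizes keep a stray noise bridge from merging two modules:
    #: a size-m clique's vertex weight (m-1) stays below the inclusion
    #: threshold 0.8 x (k-1) of any larger size-k clique's seed
    clique_sizes: tuple = (8, 6, 4)
    noise_edge_prob: float = 0.01
    score_distributions: dict = field(
        default_factory=lambda: {
            "STRING_like": (0.45, 0.95),
            "GeneMANIA_like": (0.02, 0.10),
            "noise": (0.05, 0.95),
        }
    )
    deg_effect: tuple = (0.3, (1.2, 3.0))  # (fraction DEG, |lfc| range)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["source_overlap_spec"] = {
            "|".join(k): v for k, v in self.source_overlap_spec.items()
        }
        return d


def write_manifest(config: SimConfig, outdir, files: list[str]) -> None:
    payload = {"config": config.manifest(), "files": files}
    Path(outdir, "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# compendium tables
# ---------------------------------------------------------------------------


def gen_compendium_tables(config: SimConfig, outdir=None) -> Compendium:
    """Compendium realizing the source-overlap spec exactly.

    GWAS comments are sprinkled deterministically (seeded) over GWAS-only
    genes so that both ranks occur after ranking.
    """
    spec = config.source_overlap_spec
    for combo, count in spec.items():
        if count < 0:
            raise ValidationError(f"negative region count for {combo}")
        for label in combo:
            if label not in SOURCES:
                raise ValidationError(f"unknown source label {label!r} in overlap spec")
    rng = config.rng(salt=1)
    comp = Compendium()
    i = 0
    gwas_only: list[str] = []
    for combo in sorted(spec, key=lambda c: (len(c), c)):
        for _ in range(spec[combo]):
            i += 1
            sym = f"SIM{i:04d}"
            comp.add(GeneRecord(symbol=sym, sources=set(combo)))
            if combo == ("GWAS_meta_analysis",):
                gwas_only.append(sym)
    n_bio = int(round(config.gwas_biological_fraction * len(gwas_only)))
    chosen = rng.choice(len(gwas_only), size=n_bio, replace=False) if n_bio else []
    for idx in sorted(chosen):
        sym = gwas_only[idx]
        rec = comp[sym]
        comp.records[sym] = GeneRecord(
            symbol=sym, sources=rec.sources, gwas_comments={"biological candidate"}
        )
    if outdir is not None:
        from .core import write_gene_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(comp, outdir / "compendium.tsv")
        write_manifest(config, outdir, ["compendium.tsv"])
    return comp


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _planted_profile(category: str, n_tissues: int, rng: np.random.Generator) -> np.ndarray:
    """A profile satisfying its category's defining predicate with margin."""
    base = rng.uniform(2.0, 4.0)
    x = np.full(n_tissues, base)
    if category == "Tissue_enriched":
        x[0] = 8.0 * base
    elif category == "Group_enriched":
        x[:] = base / 10.0  # below detection outside the group
        x[:3] = base
    elif category == "Tissue_enhanced":
        # one tissue beats fold x mean of the rest but not fold x each
        x[1] = 1.2 * base
        x[0] = 5.5 * base
    elif category == "Expressed_in_all":
        x = rng.uniform(2.0, 4.0, size=n_tissues)
    elif category == "Mixed":
        x[:] = 3.0 * base / 3.0
        x[-1] = 0.8  # below detection, above high/fold
    elif category == "Not_detected":
        x = rng.uniform(0.0, 0.5, size=n_tissues)
    else:
        raise ValidationError(f"cannot plant category {category!r}")
    return x


def gen_expression(config: SimConfig) -> ExpressionMatrix:
    """Expression matrix with planted categories, planted tissue-specific
    genes, and a log-normal background."""
    n_planted_cat = sum(config.planted_categories.values())
    n_planted_spec = sum(c for _, c, _ in config.planted_specific)
    if n_planted_cat + n_planted_spec > config.n_genes:
        raise ValidationError("planted gene counts exceed n_genes")
    rng = config.rng(salt=2)
    tissues = [f"T{i + 1}" for i in range(config.n_tissues)]
    rows, genes = [], []
    i = 0
    for category in sorted(config.planted_categories):
        for _ in range(config.planted_categories[category]):
            i += 1
            genes.append(f"CAT_{category[:6].upper()}_{i:04d}")
            rows.append(_planted_profile(category, config.n_tissues, rng))
    for tissue, count, fold in config.planted_specific:
        if tissue not in tissues:
            raise ValidationError(f"unknown planted tissue {tissue!r}")
        t = tissues.index(tissue)
        for _ in range(count):
            i += 1
            genes.append(f"SPEC_{tissue}_{i:04d}")
            base = rng.uniform(1.5, 3.0)
            profile = np.full(config.n_tissues, base)
            profile[t] = fold * base
            rows.append(profile)
    while i < config.n_genes:
        i += 1
        genes.append(f"BG_{i:04d}")
        rows.append(rng.lognormal(mean=1.0, sigma=1.0, size=config.n_tissues))
    frame = pd.DataFrame(np.vstack(rows), index=genes, columns=tissues)
    return ExpressionMatrix(frame)


def planted_category_labels(config: SimConfig) -> dict[str, str]:
    """symbol -> planted category for the category-planted genes."""
    labels = {}
    i = 0
    for category in sorted(config.planted_categories):
        for _ in range(config.planted_categories[category]):
            i += 1
            labels[f"CAT_{category[:6].upper()}_{i:04d}"] = category
    return labels


def planted_specific_symbols(config: SimConfig) -> dict[str, list[str]]:
    """tissue -> planted tissue-specific symbols."""
    out: dict[str, list[str]] = {}
    i = sum(config.planted_categories.values())
    for tissue, count, _ in config.planted_specific:
        syms = []
        for _ in range(count):
            i += 1
            syms.append(f"SPEC_{tissue}_{i:04d}")
        out[tissue] = syms
    return out


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------


def gen_deg_table(config: SimConfig, symbols: list[str]) -> pd.DataFrame:
    """DEG table over the given symbols; a seeded fraction passes |lfc| > 1."""
    rng = config.rng(salt=3)
    frac, (lo, hi) = config.deg_effect
    rows = []
    for sym in symbols:
        is_deg = rng.random() < frac
        populations = ["lfc_agrp", "lfc_pomc", "lfc_agpo"]
        row = {"symbol": sym}
        hot = rng.integers(0, len(populations))
        for j, col in enumerate(populations):
            if is_deg and j == hot:
                row[col] = float(rng.choice([-1, 1]) * rng.uniform(lo, hi))
            else:
                row[col] = float(rng.uniform(-0.9, 0.9))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def gen_edge_lists(
    config: SimConfig, symbols: list[str] | None = None, outdir=None
) -> tuple[pd.DataFrame, pd.DataFrame, list[set[str]]]:
    """STRING-like and GeneMANIA-like edge tables with planted cliques.

    Cliques are placed on disjoint symbol blocks with scores above the
    filter thresholds; Bernoulli noise edges carry scores straddling the
    STRING threshold; a sample of clique edges is duplicated into the
    GeneMANIA-like table to exercise duplicate removal on merge.
    Returns (string_table, genemania_table, planted clique vertex sets).
    """
    if any(s < 3 for s in config.clique_sizes):
        raise ValidationError("clique sizes must be >= 3")
    rng = config.rng(salt=4)
    if symbols is None:
        symbols = [f"SIM{i + 1:04d}" for i in range(config.n_genes)]
    need = sum(config.clique_sizes)
    if need > len(symbols):
        raise ValidationError("not enough symbols for the planted cliques")
    lo_s, hi_s = config.score_distributions["STRING_like"]
    lo_g, hi_g = config.score_distributions["GeneMANIA_like"]
    lo_n, hi_n = config.score_distributions["noise"]

    cliques, start = [], 0
    string_rows, gm_rows = [], []
    for size in config.clique_sizes:
        members = symbols[start : start + size]
        start += size
        cliques.append(set(members))
        for i in range(size):
            for j in range(i + 1, size):
                score = float(rng.uniform(lo_s, hi_s))
                string_rows.append((members[i], members[j], score))
                if rng.random() < 0.3:  # deliberate cross-source duplicate
                    gm_rows.append((members[i], members[j], float(rng.uniform(lo_g, hi_g))))
    clique_members = set().union(*cliques) if cliques else set()
    others = [s for s in symbols if s not in clique_members]
    pool = others + sorted(clique_members)
    for i in range(len(pool)):
        for j in range(i + 1, len(pool)):
            a, b = pool[i], pool[j]
            if any(a in c and b in c for c in cliques):
                continue
            if rng.random() < config.noise_edge_prob:
                string_rows.append((a, b, float(rng.uniform(lo_n, hi_n))))
    # edges at exactly the thresholds: strict filtering must drop them
    if len(others) >= 4:
        string_rows.append((others[0], others[1], 0.4))
        gm_rows.append((others[2], others[3], 0.01))

    string_table = pd.DataFrame(string_rows, columns=["gene_a", "gene_b", "score"])
    gm_table = pd.DataFrame(gm_rows, columns=["gene_a", "gene_b", "score"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        string_table.to_csv(outdir / "edges_string.tsv", sep="\t", index=False)
        gm_table.to_csv(outdir / "edges_genemania.tsv", sep="\t", index=False)
        write_manifest(config, outdir, ["edges_string.tsv", "edges_genemania.tsv"])
    return string_table, gm_table, cliques


# ---------------------------------------------------------------------------
# the reported-counts fixture
# ---------------------------------------------------------------------------

#: The reported multi-source genes, with their memberships.
MULTI_SOURCE_GENES = {
    "BDNF": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "MC4R": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "NTRK2": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "PCSK1": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "POMC": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "SH2B1": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "TUB": ("Publications", "OMIM_allelic_variants", "GWAS_meta_analysis"),
    "BBS4": ("Syndromes", "OMIM_allelic_variants", "GWAS_meta_analysis"),
}

#: The nine Rank_2 GWAS genes found in both the TSEA-brain and DEG groups.
RANK2_DUAL_GENES = (
    "CBLN1", "PCDH9", "DOC2A", "STXBP6", "LRP1B", "LRFN2", "RALYL",
    "LINGO2", "HS6ST3",
)

#: Synthetic placeholders for the four Rank_1 dual-evidence GWAS genes whose
#: identities are not publicly reported.
RANK1_DUAL_PLACEHOLDERS = ("DUALR1A", "DUALR1B", "DUALR1C", "DUALR1D")

#: Printed headline counts used as fixture inputs.
REPORTED_COUNTS = {
    "compendium_total": 578,
    "rank1_total": 459,
    "rank2_total": 119,
    "noncoding_total": 21,
    "source_sizes": {
        "Publications": 105,
        "OMIM_allelic_variants": 73,
        "OMIM_all_text": 263,
        "Syndromes": 37,
        "GWAS_meta_analysis": 184,
    },
    "gwas_in_networks": 85,
    "brain_tsea": 93,
    "brain_deg": 203,
    "brain_both": 45,
    "gwas_tsea": 34,
    "gwas_deg": 50,
    "gwas_both": 13,
    "table3": {
        "Experimental": (355, 1254),
        "Knowledge": (304, 2403),
        "Homology": (142, 522),
    },
}

#: Top-degree nodes of the brain-specific PPI network (degree printed).
TOP_BRAIN_DEGREES = (("ESR1", 20), ("PPARG", 11), ("AR", 10), ("STAT3", 10))

#: Curated neighbor rows for the Rank_2 GWAS genes in the brain network:
#: (gwas gene, neighbor, neighbor degree, neighbor dense rank, quality).
CURATED_QUALITY_ROWS = (
    ("ETV5", "AR", 10, 3, "Very_high"),
    ("LRP1B", "SERPINE1", 1, 12, "Very_high"),
    ("NDUFS3", "ADRB2", 7, 6, "Very_high"),
    ("NDUFS3", "PARK2", 8, 5, "Medium"),
    ("SNRPC", "TOMM40", 2, 11, "Medium"),
    ("SNRPC", "SNRPN", 1, 12, "Medium"),
    ("ERBB4", "STAT3", 10, 3, "Medium"),
    ("PRKD1", "MAPK9", 4, 9, "Medium"),
)


def fixture_gwas_venn_sets() -> dict[str, set[str]]:
    """The within-GWAS TSEA/DEG sets realizing the printed 34/50/13 split.

    The 13 dual-evidence genes are the nine printed Rank_2 genes plus four
    Rank_1 placeholders; the exclusive regions (21 TSEA-only, 37 DEG-only)
    are synthetic placeholder symbols.
    """
    dual = set(RANK2_DUAL_GENES) | set(RANK1_DUAL_PLACEHOLDERS)
    tsea_only = {f"GWASTSEA{i:02d}" for i in range(1, 22)}
    deg_only = {f"GWASDEG{i:02d}" for i in range(1, 38)}
    return {
        "TSEA_brain": dual | tsea_only,
        "DEG": dual | deg_only,
        "dual": dual,
    }


def fixture_multi_source_compendium() -> Compendium:
    """Compendium of the eight printed multi-source genes."""
    return Compendium(
        GeneRecord(symbol=sym, sources=set(sources))
        for sym, sources in MULTI_SOURCE_GENES.items()
    )


def fixture_reported_counts(outdir=None) -> dict:
    """The packaged reported-counts fixture as in-memory objects (and files)."""
    venn = fixture_gwas_venn_sets()
    bundle = {
        "multi_source": fixture_multi_source_compendium(),
        "gwas_venn": venn,
        "rank2_dual": set(RANK2_DUAL_GENES),
        "counts": REPORTED_COUNTS,
        "top_brain_degrees": TOP_BRAIN_DEGREES,
        "quality_rows": CURATED_QUALITY_ROWS,
    }
    if outdir is not None:
        from .core import write_gene_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(bundle["multi_source"], outdir / "multi_source_genes.tsv")
        for name in ("TSEA_brain", "DEG"):
            Path(outdir, f"gwas_{name.lower()}.txt").write_text(
                "\n".join(sorted(venn[name])) + "\n"
            )
        pd.DataFrame(
            list(CURATED_QUALITY_ROWS),
            columns=["gwas_gene", "neighbor", "neighbor_degree", "neighbor_rank", "quality"],
        ).to_csv(outdir / "quality_annotations.tsv", sep="\t", index=False)
        Path(outdir, "counts.json").write_text(json.dumps(REPORTED_COUNTS, indent=2))
        Path(outdir, "manifest.json").write_text(
            json.dumps(
                {
                    "fixture": "reported gene lists and counts",
                    "files": [
                        "multi_source_genes.tsv",
                        "gwas_tsea_brain.txt",
                        "gwas_deg.txt",
                        "quality_annotations.tsv",
                        "counts.json",
                    ],
                },
                indent=2,
            )
        )
    return bundle
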