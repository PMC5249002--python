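"""End-to-end pipeline: configuration, stage composition, report assembly.

``simulate_bundle`` materializes a complete synthetic input bundle from a
:class:`~obesinet.simulate.SimConfig`; ``run_pipeline`` executes every
analysis stage over an input bundle described by a :class:`PipelineConfig`
and writes every intermediate artifact, a manifest and a run log;
``make_summary`` renders the human-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import brain as brain_mod
from . import core, enrichment, mcode, network, simulate, specificity
from . import expression as expr_mod

log = logging.getLogger("obesinet")


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one pipeline run."""

    compendium: str = "compendium.tsv"
    expression: str = "expression.tsv"
    deg_table: str = "deg.tsv"
    terms_gmt: str = "terms.gmt"
    universe: str = "universe.txt"
    quality: str | None = None
    #: assoc type -> list of (edge TSV path, edge source label)
    edges: dict = field(default_factory=dict)
    genome_fractions: dict = field(default_factory=dict)
    brain_tissue: str = "T1"
    string_min: float = 0.4
    genemania_min: float = 0.01
    psi_threshold: float = 0.05
    psi_B: int = 100
    lfc: float = 1.0
    fold_min: float = 1.5
    alpha: float = 0.05
    mcode_min_size: int = 4
    mcode_min_score: float = 3.3
    seed: int = 0
    outdir: str = "obesinet_out"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise core.ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def simulate_bundle(outdir, sim: simulate.SimConfig) -> PipelineConfig:
    """Generate every pipeline input synthetically and return its config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp = simulate.gen_compendium_tables(sim, outdir)
    symbols = sorted(comp.symbols())

    matrix = simulate.gen_expression(sim)
    # expression profiles are attached to the first compendium symbols so
    # every stage operates over one symbol space
    mapping = dict(zip(matrix.genes, symbols))
    frame = matrix.frame.rename(index=mapping)
    expr_mod.ExpressionMatrix(frame).write_tsv(outdir / "expression.tsv")

    deg = simulate.gen_deg_table(sim, symbols[: min(len(symbols), sim.n_genes)])
    deg.to_csv(outdir / "deg.tsv", sep="\t", index=False)

    edge_cfg: dict[str, list] = {}
    for assoc, extra in (("Experimental", 0), ("Knowledge", 1), ("Homology", 2)):
        sub = dataclasses.replace(sim, seed=sim.seed + extra)
        string_t, gm_t, _ = simulate.gen_edge_lists(sub, symbols=symbols)
        spath = outdir / f"edges_{assoc.lower()}_string.tsv"
        string_t.to_csv(spath, sep="\t", index=False)
        edge_cfg[assoc] = [[str(spath), "STRING_like"]]
        if assoc == "Experimental":
            gpath = outdir / "edges_experimental_genemania.tsv"
            gm_t.to_csv(gpath, sep="\t", index=False)
            edge_cfg[assoc].append([str(gpath), "GeneMANIA_like"])

    # term collection: one term per planted clique block plus random terms
    rng = sim.rng(salt=9)
    terms = {}
    start = 0
    for i, size in enumerate(sim.clique_sizes):
        terms[f"MODULE_{i + 1}"] = (f"planted module {i + 1}", set(symbols[start : start + size]))
        start += size
    for i in range(5):
        pick = rng.choice(len(symbols), size=15, replace=False)
        terms[f"RANDOM_{i + 1}"] = (f"random term {i + 1}", {symbols[j] for j in pick})
    enrichment.write_gmt(terms, outdir / "terms.gmt")
    Path(outdir, "universe.txt").write_text("\n".join(symbols) + "\n")

    config = PipelineConfig(
        compendium=str(outdir / "compendium.tsv"),
        expression=str(outdir / "expression.tsv"),
        deg_table=str(outdir / "deg.tsv"),
        terms_gmt=str(outdir / "terms.gmt"),
        universe=str(outdir / "universe.txt"),
        edges=edge_cfg,
        seed=sim.seed,
        outdir=str(outdir / "results"),
    )
    config.to_file(outdir / "pipeline.yaml")
    return config


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; write artifacts, manifest and run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    artifacts: list[str] = []
    log_lines: list[str] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise StageError(name, exc) from exc
        log_lines.append(f"{name}\t{time.perf_counter() - t0:.3f}s")
        return result

    def save(name, writer):
        writer(outdir / name)
        artifacts.append(name)

    # --- compendium build + ranking ------------------------------------
    comp = stage("compendium", lambda: core.parse_gene_table(config.compendium))
    stage("rank", lambda: core.assign_ranks(comp))
    save("compendium_ranked.tsv", lambda p: core.write_gene_table(comp, p))
    bundle["compendium"] = comp
    log_lines[-2] += f"\t{len(comp)} records"

    # --- expression classification + chi-square ------------------------
    matrix = stage("expression", lambda: expr_mod.ExpressionMatrix.read_tsv(config.expression))
    categories = stage(
        "classify", lambda: expr_mod.classify_set(comp.symbols(), matrix)
    )
    save("categories.tsv", lambda p: categories.to_csv(p, sep="\t", index=False))
    genome_fracs = config.genome_fractions or _genome_fractions(matrix)
    comparison = stage(
        "chi_square", lambda: expr_mod.compare_categories(categories, genome_fracs)
    )
    save("category_comparison.tsv", lambda p: comparison.to_csv(p, sep="\t", index=False))
    bundle["categories"], bundle["category_comparison"] = categories, comparison

    # --- pSI + tissue overlap ------------------------------------------
    result = stage(
        "psi", lambda: specificity.psi(matrix, B=config.psi_B, seed=config.seed)
    )
    save("psi.tsv", lambda p: result.psi.to_csv(p, sep="\t"))
    lists = specificity.enriched_lists(result, config.psi_threshold)
    overlap = stage(
        "tsea",
        lambda: specificity.overlap_test(
            comp.gwas_symbols() & set(matrix.genes), lists, set(matrix.genes)
        ),
    )
    save("tsea_overlap.tsv", lambda p: specificity.overlap_report(overlap, p))
    bundle["psi"], bundle["tsea_lists"], bundle["tsea_overlap"] = result, lists, overlap

    # --- term enrichment ------------------------------------------------
    terms = enrichment.read_gmt(config.terms_gmt)
    universe = {
        core.normalize_symbol(s)
        for s in Path(config.universe).read_text().split()
        if s
    }
    rank1 = comp.rank_symbols(core.RANK_1)
    enriched = stage(
        "enrich",
        lambda: enrichment.enrich_gene_list(
            rank1 & universe, terms, universe, config.fold_min, config.alpha
        ),
    )
    save("enrichment.tsv", lambda p: enriched.to_csv(p, sep="\t", index=False))
    bundle["enrichment"] = enriched

    # --- networks -------------------------------------------------------
    nets: dict[str, network.Network] = {}
    summaries = []
    for assoc in network.ASSOC_TYPES:
        specs = config.edges.get(assoc, [])
        merged = network.Network(assoc)
        for path, source in specs:
            cut = config.string_min if source == "STRING_like" else config.genemania_min
            edges = network.read_edge_list(path, source=source, assoc_type=assoc)
            kept = network.filter_edges(edges, min_score=cut)
            merged = network.merge_networks(merged, network.build_network(kept, assoc))
        nets[assoc] = merged
        summaries.append(network.network_summary(merged, max(len(comp), merged.n_nodes)))
        merged.write_tsv(outdir / f"network_{assoc.lower()}.tsv")
        artifacts.append(f"network_{assoc.lower()}.tsv")
    stage("net", lambda: None)
    log_lines[-1] += "\t" + ",".join(f"{s.assoc_type}:{s.n_nodes}n/{s.n_edges}e" for s in summaries)
    bundle["networks"], bundle["summaries"] = nets, summaries

    # --- MCODE + expansion + expanded-cluster enrichment ----------------
    clusters = stage("mcode", lambda: mcode.predict_complexes(nets["Experimental"]))
    filtered = mcode.filter_clusters(
        clusters, config.mcode_min_size, config.mcode_min_score
    )
    expanded = [
        mcode.expand_first_neighbors(c, nets["Experimental"]) for c in filtered
    ]
    cluster_rows = [
        {
            "cluster": i + 1,
            "seed": c.seed,
            "score": c.score,
            "size": c.size,
            "members": ";".join(sorted(c.members)),
            "expanded_size": len(c.expanded_members),
            "expanded_members": ";".join(sorted(c.expanded_members)),
        }
        for i, c in enumerate(expanded)
    ]
    save(
        "clusters.tsv",
        lambda p: pd.DataFrame(
            cluster_rows,
            columns=["cluster", "seed", "score", "size", "members",
                     "expanded_size", "expanded_members"],
        ).to_csv(p, sep="\t", index=False),
    )
    cluster_enrichment = {}
    for i, c in enumerate(expanded):
        cluster_enrichment[i + 1] = enrichment.enrich_gene_list(
            c.expanded_members & universe, terms, universe, config.fold_min, config.alpha
        )
    bundle["clusters"], bundle["cluster_enrichment"] = expanded, cluster_enrichment

    # --- brain sublist, brain network, GWAS report, prioritization ------
    deg_records = stage("deg", lambda: brain_mod.read_deg_table(config.deg_table))
    tsea_brain = lists.lists.get(config.brain_tissue, set())
    sublist_all = brain_mod.build_brain_sublist(tsea_brain, deg_records, config.lfc)
    # the sublist lives inside the compendium
    members = sublist_all.symbols & comp.symbols()
    sublist = brain_mod.BrainSublist(
        symbols=members,
        origin={s: o for s, o in sublist_all.origin.items() if s in members},
    )
    brain_net, isolated = stage(
        "brain", lambda: brain_mod.build_brain_network(nets["Experimental"], sublist)
    )
    save(
        "brain_sublist.tsv",
        lambda p: pd.DataFrame(
            [
                {"symbol": s, "origin": "+".join(sorted(sublist.origin[s]))}
                for s in sorted(sublist.symbols)
            ],
            columns=["symbol", "origin"],
        ).to_csv(p, sep="\t", index=False),
    )
    qualities = (
        brain_mod.read_quality_annotations(config.quality) if config.quality else {}
    )
    gwas_rows = stage("gwas_table", lambda: brain_mod.gwas_table(brain_net, comp, qualities))
    save("gwas_table.tsv", lambda p: brain_mod.gwas_table_frame(gwas_rows, p))
    report = stage(
        "prioritize",
        lambda: brain_mod.prioritize(comp, nets, sublist, brain_net, qualities),
    )
    save("prioritization.tsv", lambda p: report.table.to_csv(p, sep="\t", index=False))
    bundle.update(
        brain_sublist=sublist,
        brain_network=brain_net,
        brain_isolated=isolated,
        gwas_rows=gwas_rows,
        prioritization=report,
    )

    # --- manifest + log --------------------------------------------------
    config.to_file(outdir / "config.yaml")
    artifacts.append("config.yaml")
    manifest = {
        "seed": config.seed,
        "thresholds": {
            "string_min": config.string_min,
            "genemania_min": config.genemania_min,
            "psi": config.psi_threshold,
            "lfc": config.lfc,
            "fold_min": config.fold_min,
            "alpha": config.alpha,
            "mcode_min_size": config.mcode_min_size,
            "mcode_min_score": config.mcode_min_score,
        },
        "artifacts": sorted(artifacts),
    }
    Path(outdir, "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    Path(outdir, "run.log").write_text("\n".join(log_lines) + "\n")
    bundle["manifest"] = manifest
    return bundle


def _genome_fractions(matrix) -> dict[str, float]:
    """Background category fractions computed over the whole matrix."""
    table = expr_mod.classify_set(matrix.genes, matrix)
    n = len(table)
    fracs = {
        cat: float((table["category"] == cat).sum()) / n
        for cat in expr_mod.CATEGORIES
    }
    fracs["Tissue_elevated"] = float(table["elevated"].sum()) / n
    return fracs


def _round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero to the printed precision."""
    import decimal

    q = decimal.Decimal(10) ** -digits
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def make_summary(bundle: dict) -> str:
    """Human-readable per-stage summary of a completed bundle."""
    required = ("compendium", "summaries", "categories", "prioritization")
    missing = [k for k in required if k not in bundle]
    if missing:
        raise core.ValidationError(f"incomplete bundle, missing {missing}")
    comp = bundle["compendium"]
    lines = [
        "obesinet pipeline summary",
        "(percentages rounded half away from zero)",
        "",
        f"compendium: {len(comp)} genes "
        f"(Rank_1 {len(comp.rank_symbols(core.RANK_1))}, "
        f"Rank_2 {len(comp.rank_symbols(core.RANK_2))})",
        "",
        "network\tnodes\tedges\tmean_degree\tcoverage%",
    ]
    for s in bundle["summaries"]:
        lines.append(
            f"{s.assoc_type}\t{s.n_nodes}\t{s.n_edges}"
            f"\t{_round_half_away(s.mean_degree, 1)}"
            f"\t{_round_half_away(100 * s.coverage)}"
        )
    lines.append("")
    counts = bundle["categories"]["category"].value_counts()
    lines.append("expression categories: " + ", ".join(f"{c}={n}" for c, n in counts.items()))
    for assoc, net in bundle.get("networks", {}).items():
        top = network.degree_rank(net, top_k=20)
        head = ", ".join(f"{sym}({deg})" for sym, deg, _ in top[:5])
        lines.append(f"top degrees {assoc}: {head}")
    table = bundle["prioritization"].table
    lines.append("")
    lines.append(f"prioritized GWAS genes: {len(table)}")
    if not table.empty:
        head = table.head(5)[["priority", "symbol", "rank_group", "brain_degree"]]
        lines.extend(
            f"  #{r.priority} {r.symbol} ({r.rank_group}, brain degree {r.brain_degree})"
            for r in head.itertuples(index=False)
        )
    return "\n".join(lines)
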