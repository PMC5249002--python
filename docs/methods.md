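# Methods

This note records the models and procedures `obesinet` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Compendium model and ranking

A compendium record is a gene symbol (upper-cased; aliases are *not*
resolved — symbol curation is treated as an upstream manual step, though a
column-mapping dialect lets callers remap table headers), a subset of five
evidence sources, free-text GWAS status comments, a coding status and a
rank. Duplicate rows for one symbol merge by union of sources and
comments, because overlapping source tables are the normal case, not an
error.

Ranking is a gate, not a score: Rank_1 ("a biological interpretation
exists") iff the gene has any of the four curated sources
(*Publications*, both OMIM subsets, *Syndromes*) or carries a GWAS
comment from a configurable tag set, defaulting to
`{"biological candidate", "biologically relevant to obesity"}`. Tag
matching is exact on normalized (lower-cased, whitespace-collapsed) text,
never substring — "maybe a biological candidate gene" does not confer a
rank. Consequently every Rank_2 gene is GWAS-only, an invariant the tests
assert.

Multi-source intersection counting collapses the two OMIM subsets into
one "OMIM" source by default (the four-set view used for Venn-style
reporting); the flag is off elsewhere because enrichment and ranking
treat the subsets separately. Venn reporting supports 2 or 3 sets;
larger collections are reported as membership tables instead.

## Expression categories

The six-category classification follows the fold-threshold scheme used by
tissue-expression atlases over 32 tissues, parameterized as
`detect = 1.0` (abundance units), `fold = 5.0`, group sizes 2–7:

- *Tissue enriched*: detected top tissue ≥ fold × every other tissue;
- *Group enriched*: some group of 2–7 tissues whose mean is detected and
  ≥ fold × every tissue outside the group;
- *Tissue enhanced*: some detected tissue ≥ fold × mean of the others;
- *Expressed in all* / *Not detected*: every tissue above / below
  `detect`; *Mixed* is the remainder, and genes absent from the matrix
  are *Not found*.

The group search only examines the top-*m* tissues for each *m*: the
top-*m* subset simultaneously maximizes the group mean and minimizes the
outside maximum, so it is equivalent to exhausting all subsets. This
equivalence is a tested property against a literal subset-enumeration
oracle at ≤ 10 tissues. Precedence follows the order above; the detection
guard on the ratio rules is what sends an all-zero profile to *Not
detected* rather than trivially satisfying "0 ≥ 5 × 0".

Category fractions of a gene set are compared to genome-background
fractions with the two-cell chi-square goodness-of-fit statistic
(k − np)²/np + (n − k − n(1 − p))²/(n(1 − p)), 1 df, no continuity
correction (the plain test form, with stars at p < 0.05/0.01/0.001).
*Not found* genes stay in the denominator and are pooled with *Not
detected* for reporting, mirroring how the two are plotted together.

## Specificity index and pSI

For tissue t and gene g, every other tissue t′ defines a fold ratio
(e_gt + ε)/(e_gt′ + ε) with ε = 1e−6; genes are ranked within (t, t′)
descending with average ties, and SI_gt is g's mean rank over all
t′ ≠ t. SI = 1 is the floor, attained by a transcript that tops every
comparison. SI is scale-invariant (rank-based) and its agreement with a
double-loop oracle is tested.

The null shuffles every tissue column independently across genes
(preserving the within-gene numerator correlation structure), recomputes
SI, and pools null values across genes within a tissue:

    pSI_gt = (1 + #{null SI ≤ SI_gt}) / (1 + B·G)

The add-one form keeps pSI strictly positive; pooling is the default
because per-tissue nulls stabilize at desk-scale B (a per-gene mode is
available). B defaults to 200 in benchmarks and 100 in the pipeline —
enough resolution for a 0.05 threshold at a few hundred genes. On 3 × 2
matrices the implementation is verified against complete enumeration of
all 36 joint column shuffles. Tissue-enriched lists use a *strict*
pSI < threshold comparison, so lists are nested across thresholds.
Candidate overlaps per tissue use the one-sided (enrichment)
hypergeometric tail with BH correction across tissues.

## Term enrichment

Standard hypergeometric upper tail P(X ≥ k) on the 2 × 2 table of a gene
list against an *explicit* universe (never an implicit background), fold
enrichment (k/n)/(K/N), BH step-up adjustment, and the inclusive
retention filter fold ≥ 1.5 ∧ adjusted p ≤ 0.05. Terms without hits are
excluded before BH (flag to include). An optional EASE mode subtracts
one hit from the tail — the conservative variant some hosted annotation
servers apply — and defaults to off, since the standard tail is the
cleaner reference behavior.

## Networks

Edges are canonicalized (lexicographic pair order, self-loops dropped
with a warning) and filtered *strictly*: score > 0.4 for STRING-like
scores, > 0.01 for GeneMANIA-like weights — an edge at exactly the
threshold is dropped. Merging unions canonical edge sets; a duplicate
pair keeps the maximum score, a choice made here because duplicate
removal is specified upstream without a score-reconciliation rule.
Summaries count only nodes with ≥ 1 edge (isolated compendium members
are reported separately) and define mean degree as 2E/N over those
nodes. Degree rankings are dense (ties share a rank, the next distinct
degree takes the next rank) with alphabetical tie order, and top-k lists
never cut a tied rank.

## Molecular complex detection

Vertex weight is the core-clustering coefficient: the highest core
number k in the closed neighborhood times the density of that highest
k-core. Complexes grow from the highest-weighted unvisited vertex,
including neighbors with weight strictly above seed weight × (1 − VWP),
VWP = 0.2, to a depth limit of 100; visited vertices never rejoin, so
complexes are disjoint. Vertices below the degree cutoff (2) get weight
0 and can neither seed nor join. Haircut iterates removal of members
with < 2 within-complex edges (the complex's 2-core); fluff is off by
default. Score = density × size on unordered pairs; the screening filter
keeps size ≥ 4 and score ≥ 3.3 (both inclusive), and screened clusters
may be expanded by all members' first neighbors. Ties in weight break
alphabetically, making output invariant to edge insertion order.

One behavioral consequence worth stating: two equal cliques joined by a
single bridge edge grow into *one* complex, because every vertex carries
the same weight and the inclusion threshold (80 % of the seed weight)
admits the far side of the bridge. Separation requires the cliques'
weights to differ by more than the VWP margin. The implementation is
verified against an independently coded naive reference of the full
procedure on 500 random graphs.

## Brain-specific prioritization

The brain sublist unites the brain tissue-enriched list (pSI < 0.05)
with genes whose |log2FC| is *strictly* above 1 in any of the AGRP-,
POMC- or pooled-neuron columns (a fold change of exactly 1.0 does not
qualify). The Experimental network restricted to the sublist is the
brain network; members with no surviving edge are reported as isolated
rather than silently dropped. Interaction-evidence quality
(Very_high > High > Medium > unannotated) is curated input metadata — a
TSV of gene pairs — and is never inferred by the code.

The five prioritization criteria are applied lexicographically in the
narrative order: rank group; network standing; brain-sublist membership
(both origins > one > none); brain-network degree; evidence quality.
"Network standing" is summarized as the gene's *best* (numerically
smallest) dense rank across the three networks — rank 1 means most
neighbors somewhere, and the best-achieved rank is what the sequential
screening rewards; a sum-of-degrees mode is available. Remaining ties
break alphabetically, so the ordering is a deterministic total order,
stable under input permutation.

## Synthetic data and what the benchmarks show

The generators are seeded (`SimConfig.seed`; identical configs give
byte-identical files) and emulate input *shape*, not biological content:

- **Compendium tables** realize an explicit per-region source-overlap
  specification exactly. The default specification reproduces the
  reported source structure — per-source sizes 105/73/263/37/184, a 578-gene union
  including the eight known triple-membership genes, and biological-
  candidate comments on 32 of the 151 GWAS-only genes so ranking yields
  the printed 459/119 split. The pairwise-only overlap allocation is not
  printed anywhere and was fixed here once, consistent with those
  totals.
- **Expression matrices** plant ten genes per category whose profiles
  satisfy the defining predicate with margin (e.g. an enriched gene's
  top tissue at 8× the rest), plant tissue-specific genes at 10× their
  own baseline, and draw the background log-normal (μ = 1, σ = 1),
  chosen for a realistic dynamic range.
- **Edge lists** plant fully connected modules of sizes 8/6/4 with
  scores above the filter cutoffs, Bernoulli(0.01) noise edges with
  scores straddling the STRING threshold, deliberate cross-source
  duplicates, and two edges at exactly the thresholds. The distinct
  module sizes mean a stray noise bridge cannot merge two modules: a
  size-m clique's vertex weight (m − 1) stays below the 0.8 × (k − 1)
  inclusion threshold of a larger clique's seed.
- **DEG tables** give 30 % of genes one |log2FC| draw in 1.2–3.0 and
  sub-threshold draws elsewhere.

Passing the recovery benchmarks (exact clique recovery, 100 % category
recovery, ≥ 90 % specificity recovery at pSI < 0.05 with B = 200)
demonstrates correctness of the algorithms under planted structure with
clean margins. It does not demonstrate performance on real extracts,
where effect sizes sit near thresholds, symbols disagree across sources
and score distributions are far from uniform. Headline network
statistics of the original analysis (node/edge counts, specific cluster
memberships) depend on external database extracts and are out of reach
of any synthetic benchmark; the packaged fixture therefore restricts
itself to publicly reported gene lists and counts, with clearly
labeled placeholder symbols for list regions whose membership is only
in unpublished supplementary material.

Benchmark problem sizes (200 genes, 8–32 tissues, B = 200, three planted
modules) were chosen as the smallest scales at which every planted
margin is comfortably resolvable; all tests and the acceptance script
run in seconds on one CPU.

## Known limitations

- No symbol-alias resolution or live database querying; inputs are
  flat files.
- The pSI permutation count bounds the smallest attainable pSI at
  1/(1 + B·G); very stringent thresholds need larger B.
- Fluff mode can emit overlapping complexes; the disjointness invariant
  and its tests apply to the default (fluff off).
- Reported percentages round half away from zero at the printed
  precision; two computed quantities inherited from the source material
  disagree with their printed counterparts in the last digit (a mean
  degree and a sublist union size), and the package reports the computed
  values.
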