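# Methods

## Statistical selection of shared SNPs

Each trait arrives as one or more summary-statistic files (Neale-lab-style
columns: variant, minor_AF, beta, se, pval; a column map adapts other
headers). Per file, variants with minor-allele frequency below 0.001 are
removed as low-confidence (the boundary value is kept: the filter removes
`maf < threshold`), p-values are adjusted with the Benjamini–Hochberg
step-up procedure (delegated to `statsmodels.stats.multitest`), and
variants with adjusted *p* strictly below α = 0.05 are selected.

Adjustment is **per file**, matching a per-dataset analysis; a pooled
adjustment is available by concatenating files upstream. How significant
sets should be combined across a trait's files is genuinely open; the
default is the **union** (a variant significant in any phenotype file of
the trait counts), with `intersection` and `single` as configurable
alternatives, and the chosen policy is recorded in the run log. Variant
identity normalizes to the rsid when present, else the
`chrom:pos:ref:alt` string; duplicated ids within one file keep the
smallest p-value. The two traits' sets are intersected and sorted
lexicographically, making every downstream artifact deterministic.

## The LD graph and dense-subgraph signatures

Linkage disequilibrium is consumed as a summary table (snp_a, snp_b,
chrom, D′, R², p) — the package never computes LD from genotypes. An edge
joins two shared SNPs iff they sit on the same chromosome, D′ > 0.7
(strict) and the LD-test *p* < 10⁻⁴ (strict). Pairs naming unknown SNPs
or spanning chromosomes are rejected with a warning rather than an error,
because LD tables are routinely a superset of the analysis SNPs.

"Dense subgraph" needs a formal definition; we use the **edge-density
quasi-clique**: a vertex set *S* qualifies iff
2|E(S)|/(|S|(|S|−1)) ≥ δ, with δ = 0.8 by default. Within each connected
component we report the inclusion-maximal qualifying sets of size at
least ⌈0.2·|component|⌉ (never below 2). Maximality is relative to the
qualifying family: a set is reported iff no qualifying strict superset
exists. Overlap is expected and preserved — a SNP may carry several
signature labels, or none (those SNPs are reported as unassigned).

Two notes on the size floor. First, the rounding of 0.2·|component| is
configurable (`ceil` default, `floor`, `round`): with the analysis's
component sizes, a per-chromosome floor (⌊0.2·43⌋ = 8, ⌊0.2·84⌋ = 16)
and a per-component ceiling can disagree by one SNP, and the choice is a
genuine free parameter of the definition. Second, the floor applies per
component, so small components can never yield signatures, and singleton
components (SNPs with no qualifying LD partner) never do.

Enumeration is exact for components of ≤ 15 nodes — an exhaustive scan of
all vertex subsets, feasible at 2¹⁵ — and heuristic above: at most 64
maximal cliques (dense graphs have exponentially many, so the seed list
is truncated deterministically) plus one degeneracy-peeling core are each
grown greedily, always adding the neighbour with the most links into the
current set (exactly the density-maximizing choice) while the density
stays at or above δ, then deduplicated to inclusion-maximal sets. Both
routes are deterministic: nodes are processed in sorted order and ties
break lexicographically. The exhaustive route is the oracle against which
the heuristic's behaviour is tested on small graphs; on planted-block
graphs (within-block edge probability 0.95, between-block 0.02) the
heuristic recovers each block essentially exactly.

Density comparisons use the quotient form 2m/(n(n−1)) ≥ δ throughout, so
exact boundaries such as 24/30 against δ = 0.8 behave consistently in
floating point.

## Gene mapping

SNP→gene assignment is an input table, not a live genome query, so any
annotation convention (nearest gene, overlapping transcript) can be
supplied; the packaged reference annotation pins the curated reference
assignment. A SNP annotated to several overlapping genes contributes to
each — the APOE locus, where signatures overlap neighbouring genes, is
the motivating case. Genes with at least 3 signature SNPs are reported
(inclusive), one row per gene with class, chromosome, supporting
signatures, and SNP count; unknown gene classes map to `other` with a
warning. The protein-coding subset defines the tripartite network's first
layer; an empty protein set aborts the pipeline because the downstream
stages are undefined. The gene–disease report is pure ingest: PMID counts
are echoed per gene, with an explicit "no evidence" row for genes absent
from the table.

## Bipartite networks, hub selection, validation

Interaction records are directed (regulator → target) with a non-empty
set of database-evidence codes. miRNA names are normalized
case-insensitively with an optional `hsa-` prefix on input and canonical
`hsa-miR-…` form on output, since public tables mix both.

Hub selection takes the **top 10 by degree with tie extension**: every
node whose degree is at least the 10th-ranked degree value is kept, so a
tie at the cutoff can extend the selection (on the packaged reference
networks, to 15 miRNAs and 11 lncRNAs). The alternative reading — top 10
distinct degree values — cannot be distinguished from the printed outcome
sizes alone; the implemented rule reproduces both and is recorded in the
stage manifest.

Edge validation keeps a record iff its evidence intersects the layer's
corroborating codes: {b, c, d, e, f} (miRWalk, TargetScan,
miRanda-via-starBase, miRmap, microT) for protein–miRNA and {L} (LncBase)
for miRNA–lncRNA, each beyond the originating database (a = starBase for
protein–miRNA, S for miRNA–lncRNA). A record lacking its originating code
indicates an inconsistent source table and raises. Validation is applied
to the edges induced by the selected hubs, i.e. after selection —
selected miRNAs keep their protein-side scores even when every lncRNA
edge fails validation.

## Scoring

Scores are exact `fractions.Fraction`s with denominator N_P, so ranking,
the above-average flags (strictly greater than the within-kind mean), the
above-½ flag for miRNAs, and the identity Σₘ S(m) = |pm_edges|/N_P are
all tolerance-free; decimals are rendered at 4 places in reports. Ties in
ranking order lexicographically.

## Synthetic data: what it emulates and what it does not

The generator emits summary-level tables directly, because the pipeline
consumes summaries. Default conditions: 5000 variants per trait; 127
planted shared signals (matching the scale of the motivating analysis)
split into four LD blocks over two chromosomes (20 + 23 and 40 + 37) plus
7 satellite SNPs with no qualifying LD partner; planted raw p ≤ 10⁻⁸,
conservatively below α/m so Benjamini–Hochberg must recover them; 50
additional trait-specific signals per trait so the intersection is
informative; 2% of null variants below the MAF floor. LD blocks use
within-block edge probability 0.95 (D′ ∈ [0.8, 1], p < 10⁻⁶; a spanning
path guarantees connectedness) against 0.02 between blocks with D′ ≤ 0.6,
so blocks are exactly the non-singleton components. Each block hosts
three genes taking 4, 3, and 2 consecutive SNPs — two survive the ≥3-SNP
filter, one does not. Hub miRNAs get the degree multiset
(6,6,5,5,4,4,4,3×8), which ties at rank 10 and extends top-10 selection
to 15; hub lncRNAs analogously tie to 11. Every edge carries its primary
evidence code plus each corroborating code independently with
probability 0.8.

Not emulated: realistic allele-frequency spectra, LD decay with distance,
genotype-level correlation between the two traits' p-values, multi-file
trait heterogeneity, and name collisions in interaction tables. Passing
the planted-recovery tests therefore demonstrates the pipeline's logic
(filtering, graph construction, enumeration, selection, validation,
scoring) under clean planted structure — not robustness to the messiness
of real summary files.

All randomness flows through one `numpy.random.default_rng(seed)`;
identical (seed, config) produces byte-identical TSVs.

## Curated reference tables and the synthetic bridge

The shipped tables carry the curated shared-SNP list (117 rsIDs:
43 on chromosome 19, 74 on chromosome 6), the gene/signature table, the
gene–disease PMID counts, and the two interaction-evidence matrices (49
protein–miRNA cells; 97 miRNA–lncRNA cells of which 45 carry LncBase
corroboration). The SNP-resolution assignment of shared SNPs to
signatures and genes is not part of the curated tables, so
`fixtures.synthetic_signature_bridge()` constructs a deterministic
synthetic stand-in consistent with every documented constraint (gene →
signature sets, APOE fewest / HLA-DRB1 most SNPs, rs6857 → AC011481.2,
every chromosome-19 SNP covered, ten chromosome-6 SNPs unassigned).
Because the GWAS and LD inputs behind these tables are not
redistributable, the fixture bundle enters the pipeline at the signature
stage (`start_stage: signatures`).

## Numerical and engineering choices

- Strict inequalities at every documented threshold (MAF keeps the
  boundary; significance, D′, and LD-p are strict), as stated.
- Deterministic ordering everywhere: components by descending size then
  smallest member; signatures labelled A, B, … in component/size order;
  exports insert nodes and edges sorted, so GraphML and TSV outputs are
  byte-stable for identical inputs.
- Each stage writes a manifest (parameters, input/output SHA-256 hashes,
  record counts); `run-all` equals the staged composition artifact for
  artifact.
- Degenerate inputs: empty GWAS files load as empty collections with a
  warning; an empty annotation maps no genes; components smaller than the
  signature floor yield no signatures; an empty protein layer is an error.
- Problem sizes in the test suite (5000-variant traits, 127 planted
  signals, ≤15-node exhaustive oracles, 50-graph enumeration checks) were
  chosen so the full suite exercises every route in seconds while keeping
  the exhaustive oracles exact.

## Known limitations

- The dense-subgraph search above 15 nodes is a heuristic; pathological
  components could hide a maximal quasi-clique from the truncated seed
  list. Raising `exhaustive_limit` or `max_seeds` trades time for
  completeness.
- The union combine policy treats a trait's files as exchangeable
  phenotype definitions; meta-analysis across files is out of scope.
- Gene mapping inherits whatever assignment convention the annotation
  table encodes.
- PMID-count validation is reporting only; no enrichment or literature
  mining is performed.
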