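# Methods

## Scope and model

`mirsig` operates entirely on *processed* differential-expression
summaries ("top-tables": symbol, log2FC, nominal p, BH-FDR), never on raw
expression matrices. This preserves each cohort's original preprocessing
and makes the workflow a cross-cohort summary analysis, not a
meta-analysis: no effect sizes are pooled, and no p-values are combined.
Consequences worth keeping in mind: platform coverage differs between
cohorts (handled by the explicit background universe), and residual
technical heterogeneity between cohorts is mitigated only by the
direction-aware consensus rules, not removed.

## Curation rules

Symbols are uppercased at read time (cross-platform case drift). Labels
are rejected when probe-like (ending `_at`), purely numeric, or
placeholders (`---`, `NA`, ...). Composite multi-mapped labels
(`A /// B`, `;`, `,`) resolve to the **first valid token** in written
order — a deterministic choice where any single-representative rule is
defensible. LOC/LINC loci and pseudogene-style labels are retained but
flagged `provisional`, propagated to reports, because they transfer poorly
to functional validation. Duplicates keep the smallest FDR, ties broken by
largest |log2FC|, then first occurrence; the operation is idempotent and
never synthesizes values. Symbol validity is syntactic only — no live
HGNC resolution (by design: runs must be offline-reproducible).

## Thresholds and classification

Harmonized defaults: FDR < 0.05 (strict inequality) and |log2FC| ≥ 1
(non-strict), applied identically to every cohort. Ranking uses the
deterministic chain FDR ↑, |log2FC| ↓, symbol ↑. Low-signal cohorts can be
reported via `fdr_rank_fallback`, which labels top genes by significance
ranking with direction from the sign of log2FC; these are candidates, not
significant calls, and the classifier itself is never relaxed. Volcano
output is a plot-ready table (x = log2FC, y = −log10 FDR, class);
rendering is a thin optional layer. FDR values of exactly 0 are floored at
1e-300 so −log10 stays finite.

## Consensus rules

*Strict intersection*: significant under the thresholds in both cohorts
with identical direction. *Vote-based*: sign(log2FC) identical and nonzero
in both cohorts, |log2FC| ≥ 1 in both, FDR < 0.05 in at least one. Strict
membership implies vote membership, and both rules are symmetric in cohort
order — both properties are tested. Genes absent from either cohort's
table are excluded (concordance is untestable); sign(0) is concordant with
nothing. The vote rule exists for cohort pairs where one member is
underpowered: requiring joint significance there starves the signature,
while direction + effect-size agreement plus one-sided statistical support
retains the reproducible core. The package quantifies this on synthetic
data (see benchmarks below) rather than asserting it.

Partitioning two diseases' consensus sets is pure set algebra by symbol,
with shared genes split into concordant (same direction in both diseases)
and discordant (opposite). Direction stratification emits six enrichment
inputs (A-specific up/down, B-specific up/down, shared-concordant,
shared-discordant); sets smaller than `min_set_size` (default 5,
configurable — flagged but still emitted) are marked underpowered.

## Enrichment

The universe is the union of valid symbols across all curated cohort
tables — the genes that *could* have appeared in a signature. Regulons are
intersected with the universe **before** testing, so K counts only
background-measurable targets; restricting after testing is exposed only
implicitly (callers may pass an unrestricted library, but the default
pipeline restricts first). P(X ≥ k) is the scipy hypergeometric survival
function (validated against exhaustive subset enumeration for all
N ≤ 12); BH runs within one signature's family of regulons (analyses are
per-signature, so pooling families would mix hypotheses); the enrichment
ratio is (k/n)/(K/N). No minimum-overlap filter is applied; instead,
results with k below `k_min` (3) or K below `K_min` (5) carry a
`small_set` caution flag, since single-target regulons trivially inflate
ratios. p-values are floored at 1e-300.

## Prioritization

Categories are decided purely by the significance pattern at alpha
(0.05): significant in both diseases' specific sets, or in any shared set,
→ shared; else one disease's sets only → that disease's biased category;
else unclassified. "Primarily shared" is operationalized as: any
significant shared-set hit dominates. The composite score

    score = Σ_s −log10(fdr_s) + log2(1 + Σ_s k_s) + c

(sum over signatures s with fdr_s < alpha, c = count of such signatures)
is this package's instantiation of three qualitative ingredients —
adjusted significance, overlap size, cross-signature consistency — chosen
to be deterministic, non-negative, and strictly monotone in each
ingredient. No external anchor for absolute score values exists; only
ordering and monotonicity are meaningful, and only those are tested.

## Networks

Nodes are retained miRNAs (default: all FDR-significant for the
signature; top-10-by-rank fallback when none pass, so underpowered
signatures still yield a candidate module) plus their signature targets;
edges are regulon ∩ signature pairs. Hubs are ranked by degree — the
number of targeted signature genes — because degree stays interpretable
across networks of very different sizes; betweenness is computed only as a
secondary descriptor and never drives ranking. Cytoscape exports are plain
TSV and round-trip losslessly; an export-time top-k filter produces
readability subsets without touching the full tables.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
per gene and cohort, per-sample values are drawn Normal(μ_group, σ) and
summarized exactly as a DE analysis would — log2FC as the group-mean
difference, p from a Welch two-sample t, BH within cohort — so (log2FC,
p, FDR) triples are internally consistent. Planted structure: a
direction-concordant program per disease, one-cohort distractors,
within-disease discordant genes (sign flip between cohorts), optional
cross-disease shared genes (concordant or discordant), and a GMT library
whose hub regulons draw round(min(1, ρ·density)·K) targets from a
designated program (ρ = within-regulon program density over background
density). Effect magnitudes are Normal(3.0, 0.5) truncated below at 1.0
(so planted effects always clear the fold-change floor; the zero-noise
limit then recovers exactly); null genes get Normal(0, 0.15) drift;
within-group SD defaults to 1.0, scaled per cohort by `noise_scale`.

The default preset mirrors the motivating study's cohort shapes: a
CLL-like disease with a 179/33 cohort and a 5/2 cohort, and an MM-like
disease with a 10/5 cohort and an 8/8 cohort at 4× variance (the weak
regime). A 5-vs-2 comparison at unit noise cannot reach BH significance
under a plain Welch t (≈2 degrees of freedom), whereas the corresponding
real cohort shows a high-SNR regime with thousands of DEGs (processed
array statistics borrow strength across genes); the preset therefore
assigns that cohort `noise_scale = 0.05` to emulate its observed regime.
The universe is 4000 genes (a scale-down of the >20k real background,
keeping runtimes in seconds), with 305 planted CLL-like concordant genes,
55 MM-like, and a 5-gene shared set of which 3 are cross-disease
discordant.

What the generator does **not** emulate — probe-level artifacts, batch
effects, cell-type composition shifts, correlated genes, literature bias
in target libraries — bounds what passing tests show: they validate the
algorithms' behavior under the stated statistical model, not robustness
to real-data confounding.

## Benchmarks and numerical choices

Two replicate benchmarks are built in. *Hub recovery*
(`hub_replicate_spec`): 2000-gene universe, two 20/20 cohorts, 60-gene up
program, 60 regulons, one hub with K = 50 and ρ = 5. The configuration
sits deliberately inside the target regime (ρ ≥ 4, K ≥ 30, program ≥ 50):
a power analysis at the boundary (expected hub overlap ≈ 5 against a
background overlap distribution with mean ≈ 1.2 across ~60-100 regulons)
shows the hub would tie or lose the top FDR rank in tens of percent of
replicates, so the benchmark is run where the property is actually
expected to hold (~100% observed). *Vote-vs-strict*
(`weak_cohort_spec`): 10/5 plus 8/8×4σ cohorts, 80-gene program; strict
recall collapses (~0) while vote recall is ~0.6, and vote strictly beats
strict in ~100% of replicates.

Other numerical choices: Welch (unequal-variance) t rather than pooled,
matching the generator's per-cohort σ model and degrading gracefully when
arms differ; degenerate zero-variance arms get p = 1 when the mean
difference is 0 and p = 1e-300 otherwise; all randomness flows through one
`numpy` Generator seeded from the spec (library generation uses a second
stream derived from the same seed), making every table, GMT and manifest
byte-reproducible; run manifests contain no timestamps or absolute paths
and record a SHA-256 per output table, so determinism is checkable by
byte comparison.

## Known limitations

Summary-level only (no deconvolution, no raw reprocessing); syntactic
symbol validation; two cohorts per disease and two diseases per partition;
ORA only (no rank-based enrichment, no resampling stability checks); the
composite score has no external calibration; hub ranking by degree ignores
edge weights and centrality alternatives beyond the optional betweenness
column.
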