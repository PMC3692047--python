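# Methods

This note records the model behind `generank`, the defaults that matter, the
decisions taken where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Rank machinery

Every evidence layer is a map gene → score with a sort direction (ascending
for P-values, descending for similarities and association scores). Scores
are converted to midranks — tied scores receive the mean of the positions
they span — so the rank sum is always N(N+1)/2 and two-tier layers (interval
and binary custom layers) are well defined: every gene in a tier shares one
rank. Normalized ranks r/N lie in (0, 1]. Midranking everywhere is a
deliberate choice: it preserves rank-sum conservation, makes the integration
invariant to monotone transformations of raw scores, and gives tie groups a
single unambiguous weight.

Identifier mapping supports Ensembl gene IDs, HGNC symbols and Entrez IDs.
Symbols match case-insensitively (real symbol usage is case-sloppy);
Ensembl/Entrez match exactly. `auto` detection routes `ENSG…` to Ensembl,
all-digit IDs to Entrez, everything else to symbol. A synonym that would
resolve to two genes is a construction-time error, not a first-wins pick:
a silently ambiguous index would corrupt every downstream rank. Retired or
versioned Ensembl IDs are not resolved.

## GWAS layer

Three steps: SNP→gene mapping by physical proximity, best-SNP P-value
assignment, and effective-test adjustment.

- **Window.** `window_bp` defaults to 50 kb on both sides, 1-based inclusive
  at the boundaries. A SNP may map to every gene whose extended interval
  contains it. The window is configurable and surfaced in the CLI config;
  50 kb is a common gene-assignment radius that captures proximal
  regulatory variation without flooding genes with distal SNPs.
- **Best SNP.** The gene P-value is the minimum over mapped SNPs; ties break
  on the lexicographically smallest SNP id so results are deterministic and
  independent of input order.
- **Effective tests.** `M_eff = Σ_i f(|λ_i|)`, `f(x) = 1{x ≥ 1} + (x − ⌊x⌋)`,
  over eigenvalues of the SNP correlation matrix (Li–Ji). Identity gives M,
  the all-ones matrix gives 1. Eigenvalue magnitudes are rounded to 1e-10
  before applying f, and the sum is clamped to [1, M]: f is discontinuous at
  integers, and exact structured matrices (identity, all-ones) must land on
  their closed forms despite eigensolver round-off. Absolute values handle
  the tiny negative eigenvalues a near-singular empirical correlation matrix
  produces.
- **Adjustment.** Šidák, `p_adj = 1 − (1 − p)^{M_eff}`: bounded in [p, 1],
  monotone in both arguments, exact under independence. Bonferroni
  (`min(1, p·M_eff)`) is available via `adjustment: bonferroni`. P-values of
  exactly 0 are accepted verbatim; no epsilon flooring is applied.
- **LD source.** Pairwise-complete Pearson correlation of dosages {0,1,2}
  from a user genotype panel. Monomorphic SNPs and pairs with fewer than two
  complete observations get correlation 0 off-diagonal (1 on the diagonal).
  Without a panel, `M_eff = n_snps` — the most conservative choice, since
  any true LD only lowers the effective count. When a panel covers only part
  of a gene's SNPs, the uncovered SNPs count 1 each on top of the Li–Ji
  value of the covered subset, which keeps `1 ≤ M_eff ≤ n_snps` and stays
  conservative for what the panel cannot see.

## Literature layer

The corpus arrives pre-tokenized as (document, token, count) triples with
document→gene and document→term annotation tables; tokenization and
named-entity recognition are out of scope because the contribution here is
the vector scoring, not NLP preprocessing. An entity's raw word vector is
the sum of token counts over its annotated documents. Publication-bias
normalization is tf-idf with `idf = ln(D/d_t)` followed by unit-norm
scaling — the standard treatment in this method family; a token appearing in
every document gets weight 0 and cannot drive any similarity. Entities with
no documents (or only ubiquitous tokens) have zero vectors, are flagged, and
score similarity 0, which places them at the bottom of the descending layer.
Similarities are clipped at 0 as a guard for user-supplied weighted corpora;
with non-negative counts the clip is a no-op. OR = elementwise max and
AND = elementwise min keep the combined score a similarity in [0, 1] with
exact idempotence (a single term is unchanged under either logic);
product/mean variants were rejected on those grounds.

## Network layer

Guilt by association over an undirected confidence-weighted network
(self-loops dropped, duplicate edges collapsed to the maximum confidence):
score(g) = Σ of edge confidences to distinct seed neighbors, after removing
edges below `min_confidence`. Direct neighbors only — no diffusion or
random-walk kernel; the scoring rule is a deliberate, pluggable minimal
reading of interaction propensity with a seed set, and diffusion is noted as
an extension point. A count mode (`use_confidence=False`) scores raw seed
degree. Seed genes get no automatic top rank; their own membership
contributes nothing to their score.

## Interval and custom layers

Region strings are UCSC-style `chrom:start-end` with optional thousands
separators and `chr` prefix; coordinates are 1-based and inclusive on both
ends, matching the string format (BED input is 0-based half-open and is
shifted on read). Any ≥1 bp overlap puts a gene in the top tier — the
weighting is exactly two-tier because the supported statement is only that
overlapping genes are collectively weighted higher; a graded within-tier
ordering would be an invention. Custom tables keep the best score per gene
on duplicate mapping (minimum when ascending, maximum when descending,
logged). Binary mode ranks listed genes as tier 1 against the entire
remaining universe. More than five custom layers triggers a warning (the
usual cap) but is not blocked.

## Integration

`meta(g) = (∏ r̃_l(g))^{1/k_g}` over the `k_g` layers scoring `g`
(geometric mean of normalized ranks, a rank-product variant). Chosen because
it is scale-free, monotone-invariant, and missing-data tolerant; a
`worst_rank` policy (missing layers imputed at normalized rank 1.0,
divisor = total layers) is provided for sensitivity analysis. Layers are
weighted equally by default; per-layer weights act as exponents when
configured. Genes scored by no layer are excluded from the ranking and
listed separately. Ties break by larger `n_layers_scored`, then
lexicographic gene id — chosen purely for determinism. Fisher/Stouffer-style
P-value combination was rejected: layers are ranks, not P-values.

## Benchmark protocol

Rankings under comparison are restricted to genes scored in all of them;
positive/negative gene ranks are the scores. AUC is computed as the
Mann–Whitney probability that a random positive outranks a random negative
with half-credit ties; the ROC curve sweeps the rank threshold over tied
groups, so its trapezoidal area equals the AUC identically (checked at
1e-12). The TPR cutoff is `ceil(fraction × N)` over the evaluation universe
(the intersected set, for consistency with the AUC protocol); the threshold
is the cutoff-th smallest rank and genes tied exactly at it count as inside.
Negative sampling is uniform without replacement, seeded, and excludes any
supplied gene sets.

## Synthetic data and what the benchmark shows

`SyntheticScenario` plants `n_causal` causal genes (default 20 of 1000,
spread over 5 chromosomes of 20 Mb with non-overlapping 20–60 kb genes) and
emulates each input around them:

- **GWAS**: 10,000 SNPs placed uniformly; null P-values Uniform(0,1); SNPs
  inside a causal gene body draw Beta(a, 1) with a = 0.15 — a single-knob
  signal strength with analytic density. The genotype panel (100 samples)
  carries blockwise LD: within blocks of 5 SNPs each SNP copies a shared
  template genotype with probability √r, giving pairwise dosage correlation
  r = 0.8 — the "many correlated SNPs per gene" regime the Li–Ji correction
  targets.
- **Network**: Erdős–Rényi background (p = 0.004, confidences U(0.1, 1));
  30 seed genes drawn from the non-causal background; causal–seed pairs get
  edges with probability 0.25 at confidence U(0.6, 1). Causal–seed pairs are
  governed exclusively by that process (background draws are suppressed
  there) so that setting the causal–seed probability and confidence range to
  background values yields an exactly exchangeable null.
- **Corpus**: 400 documents over 300 tokens; 80 phenotype-term documents
  draw 70% of their tokens from a 40-token signal vocabulary; every gene
  joins ~Poisson(3) background documents, and causal genes additionally join
  each term document with probability 0.08.
- **Custom**: binary list covering causal genes at recall 0.9, diluted to
  precision 0.9.
- **Regions**: a ±10 kb region around each causal gene with probability
  0.8, plus 10 random 100 kb decoy regions.

`null()` removes every planted effect (uniform P-values, background-level
causal–seed edges and confidences, no term-document enrichment, random
custom list and regions). All draws are deterministic under the scenario
seed, with one independent stream per component.

The planted benchmark (20 replicates; positives = causal genes, negatives =
10× as many genes sampled outside the causal set, seed list, and custom
list) measures integrated and per-layer AUC and TPR@5%. Under the defaults
the integrated AUC is essentially 1 and exceeds the mean single-layer AUC in
every replicate, while the null scenario sits near 0.5 (a residual ~0.52
reflects the exclusion protocol itself: negatives can never be on the custom
list, positives occasionally are, even when the list is random). These
problem sizes keep a full 20-replicate run around 10 s of compute per
condition.

**What this does and does not show.** Passing demonstrates that the
machinery recovers concordant multi-layer signal and is calibrated under the
null. It does not predict performance on real studies: real LD is not
blockwise-uniform, real interactomes are scale-free with heavy study bias,
real literature signal is far sparser and noisier than the planted
co-mention structure, and real evidence layers disagree. AUCs near 1 here
say the pipeline is correct, not that gene prioritization is easy.

## Numerical and format choices

- Šidák via `expm1`/`log1p` for small-P accuracy; endpoints p = 0 and p = 1
  are exact.
- Eigenvalue rounding (1e-10) and [1, M] clamping in Li–Ji, as above.
- Output tables are TSV with `#`-prefixed provenance lines (version, config
  hash, seed — never timestamps), floats at `%.17g`, so identical
  configurations give byte-identical files and written tables re-read
  exactly.
- Compressed GWAS input: `.gz` streams; `.zip` and `.tar`(.gz) archives must
  contain exactly one member file — multi-member archives are rejected for
  both formats for symmetry.
- Malformed summary-statistic rows are skipped and counted; duplicate SNP
  ids keep the smallest P-value; both are surfaced as warnings in the run
  report, and zero valid rows is an error.
- More than 50% unmapped identifiers in any gene list is a surfaced warning,
  not an error.

## Known limitations

- No network diffusion; a gene two steps from every seed scores 0.
- The proximity window is uniform; no gene-length or recombination-aware
  assignment.
- tf-idf is the only implemented bias normalization (the weighting hook is
  pluggable); no term-hierarchy expansion.
- No genome-build liftover, imputation, or external ID resolution.
- The interval layer is dosage-blind (amplification vs deletion is not
  distinguished).
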