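# Methods

This note documents the statistical procedures implemented in `bicfun`,
the choices made where the design was genuinely open, and what the
synthetic cohort does and does not emulate.

## Differential expression (`bicfun.deg`)

Raw counts are normalized with median-of-ratios size factors: the
per-gene geometric mean over samples (restricted to genes with nonzero
counts everywhere) serves as the reference, and each sample's factor is
the median ratio of its counts to that reference, reported without
rescaling. The two-group test models counts as negative binomial with a
gene-wise method-of-moments dispersion pooled across the two groups
(floored at 1e-8) and tests the log group-mean contrast with a Wald
statistic; a pseudocount of 0.5 stabilizes fold changes of low-expressed
genes. The Wald statistic is referred to a t distribution with
nA + nB − 2 degrees of freedom rather than a normal: the plug-in
dispersion estimate is noisy at cohort sizes of a few dozen samples per
group, and the heavier reference keeps the null type-I rate at the nominal
level (empirically ≈ 0.050 at raw p < 0.05 for n = 20/20, 2000 null
genes, versus ≈ 0.057 with a normal reference). There is no dispersion
shrinkage and no fold-change shrinkage; the implementation targets
set-level behaviour at strict thresholds (adjusted P < 0.001, |log2FC| > 1,
both strict inequalities) on well-separated effects, not per-gene inference
near the thresholds. Genes with all-zero counts in both groups are
excluded and reported. An externally produced DEG table (e.g. from a
full shrinkage-based NB fit) can be substituted anywhere a `DegTable` is
accepted.

Cancer-specific DEGs are the set difference tumor-contrast DEGs minus
normal-contrast DEGs, with the four Venn counts reported.

## Biclustering (`bicfun.biclustering`)

Both algorithms run on log2(count/size-factor + 1) expression, z-scored
per gene; constant genes are dropped.

**ISA.** From a random initial gene set, sample scores (mean expression
over the current gene set) and gene scores (mean over the current sample
set) are alternately thresholded until the (gene set, sample set) pair
repeats. Membership keeps entries whose score exceeds
`threshold × sd(score vector)`; scores are signed and only up-modules
are tracked (down-modules on z-scored data can be found by negating the
matrix). Non-converged seeds are discarded and identical fixed points
merged. Function defaults (100 seeds, initial gene-set size 20,
thresholds 2.0/2.0) suit matrices with a few dozen rows per module at
high signal-to-noise. For cohort-scale matrices (~2000 genes) the
pipeline instead seeds from single genes with 500 restarts: a random
20-gene set almost never contains enough module genes for the first
thresholding step to latch on, whereas a single module gene's profile
immediately selects the module samples. The pipeline also uses a stricter
gene threshold (3.5) than sample threshold (2.0): over a module's sample
set, genes differentially expressed across a whole tumor class score
moderately high, and the stricter cut separates the module core from that
class-level background.

**Plaid.** Layers of the form μ + α_i + β_j are peeled off the residual
matrix. Each layer is seeded from the leading singular vectors
(memberships at 50% of the extreme loading), then refined by alternately
re-fitting the layer and keeping rows (columns) for which the fitted
layer explains at least 70% of their sum of squares within the layer — a
fixed release rule. A layer is retained only if its sum of squares
exceeds the 95th percentile of layers fitted to 20 within-column
permutations of the residual; fitting stops at the first non-significant
layer. This is a deliberate simplification of the classical plaid
estimator: it finds strong additive blocks in SS order and is gated
against noise, but it does not revisit earlier layers and can stop before
weaker planted structure when a noise direction dominates the residual
spectrum (ISA complements it there).

**Jaccard.** The pair-based similarity between biclusters treats a
bicluster as the set of (gene, sample) pairs. In the default `literal`
mode the union is the product of the gene-set union and sample-set union;
the `rectangles` mode instead uses |A| + |B| − |A∩B|. The two differ only
in the descriptive similarity heatmap, never in selection.

## Cancer-specific selection (`bicfun.selection`)

For each bicluster and each tumor class, a 2×2 table of bicluster
membership against class membership is built over the entire cohort —
normal samples included, so a bicluster of tumors plus many normals can
still be class-enriched. The two-sided Fisher exact p sums the
probabilities of all margin-fixed tables whose hypergeometric probability
does not exceed the observed one; the comparison is done on exact integer
numerators, so no floating-point slack is involved. The odds ratio is the
sample cross-product ratio (reported as infinity when b·c = 0, with the
Haldane–Anscombe-corrected value alongside). Benjamini–Hochberg q-values
are computed once over the full family of bicluster × class tests;
selection requires q < 0.001 and OR > 1, the enriched class is the one
with the smaller q, and ties break toward the first tissue for
determinism. Storey-type estimation was considered and not implemented;
BH matches the correction used everywhere else in the pipeline.

## GO handling and enrichment (`bicfun.ontology`, `bicfun.enrichment`)

The OBO parser keeps non-obsolete `[Term]` stanzas of the configured
namespace (biological_process by default), turns `is_a` and
`relationship` lines into typed child→parent edges, maps `alt_id`s to
primary ids, and reports malformed input with line numbers. Only `is_a`
and `part_of` edges participate in transitive closure and annotation
propagation; regulates-family edges are stored but excluded (they encode
causal influence, not subsumption). Acyclicity of the closure-restricted
graph is enforced at construction. The in-repo parser is cross-checked
against `obonet` in the test suite.

Annotation propagation applies the true-path rule (each gene inherits
all ancestors of its terms); it is idempotent, only enlarges annotation
sets, and drops records whose terms cannot be resolved, with a logged
count. Over-representation uses the exact hypergeometric upper tail per
term, restricted to terms annotating between 3 and 2000 background genes,
BH-adjusted within each query's family at α = 0.05. All annotation
records are used; evidence-code filtering is left to preprocessing.

## Childness (`bicfun.childness`)

For a query term t and a reference DEG term set, `up(t)` is the maximum
number of DEG terms on any directed child→parent path from t (the query
term itself excluded; a `count_self` flag includes it), and `down(t)` the
mirror over descendant paths. Because the is_a/part_of-restricted graph
is a DAG, both are longest-weighted-path dynamic programs (weight 1 on
DEG terms) and run in O(V+E). The childness score is up/(up+down); terms
with no DEG relatives score 0 — they carry no evidence of refining a
DEG-level function. A bicluster's term-set score is the arithmetic mean
over its enriched terms; biclusters with no enriched terms are reported
unscored rather than assigned 0 and do not enter group comparisons. A
gene's score is the maximum over its annotated terms (used for heatmap
annotation). Functional relevance requires a term-set score strictly
above 0.6.

The cancer-specific versus other-bicluster comparison uses the two-sided
Wilcoxon rank-sum test: exact null distribution when both groups have
n ≤ 20 and no ties, otherwise the normal approximation with mid-ranks,
tie-corrected variance and continuity correction.

## Survival screen (`bicfun.survival`)

For a bicluster with enriched class c, expression of the bicluster genes
over *all* tumor samples of class c (not only bicluster members — the
screen asks whether the signature generalizes) is standardized per gene
and decomposed by PCA with samples as observations. Three stratifications
are always computed: median split on PC1, median split on PC2 (values
equal to the median go to the "low" group), and k-means with k = 2 on the
first two PCs (10 restarts, seeded). Groups are compared with the
standard two-group log-rank test (hypergeometric variance, chi-square
reference with 1 df), the usual companion of the Kaplan–Meier estimator;
a dataset with no events returns statistic 0 and p 1. A bicluster is
flagged significant when any of the three methods reaches p < 0.05, and
all three p-values are reported so stricter rules can be applied
downstream. No correction across biclusters is applied to these raw
proportions. KM curves are computed with lifelines and serialized as
step-function pairs.

## Synthetic cohort (`bicfun.synthetic`)

The generator emulates the structure the pipeline assumes, with defaults
chosen once as a realistic desk-scale cohort:

* **Design.** 2000 genes; two tissues × tumor/normal with 40 tumors and
  60 normals per tissue (public compendia are normal-heavy; the extra
  normals also let three normal modules occupy disjoint sample blocks).
  Counts are negative binomial with dispersion 0.1 around per-gene base
  means drawn log-uniformly over log2 means 3–9.
* **Gene classes.** 150 tissue-DE genes (±2 log2 between tissues, in
  tumors and normals alike — the confound), 150 cancer-DE genes (±1.2
  log2 between the two tumor classes only; cancer-specific differences
  are subtler than tissue identity), 30 genes per planted module, rest
  null.
* **Modules.** One cancer module per tumor class and three normal
  modules per normal group, each 30 genes × 15 samples with a +1.6 log2
  additive block. Under the default noise this realizes roughly +2.5
  z-units in the normalized matrix while keeping the *marginal*
  tumor-contrast log2FC of module genes near 0.8 — below the DEG
  threshold, so module terms do not leak into the DEG term set, mirroring
  the premise that bicluster functions are children of, not members of,
  the DEG-level signal. Cancer modules use disjoint gene blocks and one
  sample block per tumor group so that the survival contrast between
  module-active and inactive samples is not diluted across modules.
* **Ontology.** A complete b-ary tree (depth 4, branching 2 → 31 terms);
  edges are is_a with a 20% part_of fraction. The children of the first
  depth-1 node are the designated DEG terms (annotated by cancer-DE
  genes); the second depth-1 branch holds decoy terms (annotated by
  tissue-DE genes) and the normal-module leaves. Cancer-module terms are
  leaves under the DEG terms, so their expected childness chain is
  module term = 1, parent = 1, DEG term = 1, top ancestor = 0 → term-set
  score 0.75. Null genes receive one uniformly random non-root term.
* **Survival.** Tumor survival is exponential with baseline hazard
  1/1500 per day, multiplied by 4 for members of a cancer module, with
  administrative censoring at 5 years (~30% censoring for baseline
  samples).

What the generator does **not** emulate: library-size variation between
samples beyond size-factor noise, gene-gene correlation outside planted
blocks, batch effects between cohort sources, gene-varying dispersion
(available as an option of the NB model family but off by default),
non-exponential hazards, and annotation incompleteness. Passing tests on
this cohort therefore show that the pipeline's logic recovers the planted
structure under its own model assumptions, not that it is robust to the
full messiness of real compendia.

## Numerical and policy details

* All thresholds are strict inequalities (padj < 0.001, |log2FC| > 1,
  q < 0.001, OR > 1, childness > 0.6, p < 0.05); a value exactly at a
  threshold is excluded.
* BH adjustment is a step-up with capping at 1; inputs outside [0,1]
  raise.
* All randomness derives from one master seed via `SeedSequence` fan-out
  (cohort, ontology, ISA, Plaid, k-means); reports are byte-reproducible
  given the seed.
* Readers reject invalid values (non-integer or negative counts, unknown
  category levels, events without times) rather than coercing them.
* Problem sizes in the test suite and acceptance script — 2000-gene
  cohorts, 20 generator seeds for recovery and null controls, 1000
  random DAGs/tables for oracle comparisons — were chosen as the scale at
  which the checked properties stabilize on a single CPU.

## Known limitations

* The NB test's moment dispersion is anti-conservative for very small
  groups (< 10 per group); the t reference mitigates but does not remove
  this.
* ISA tracks up-modules only; Plaid is a simplified layer model without
  layer revisiting. FABIA and QUBIC are not implemented; their output can
  be imported through the bicluster-JSON plugin interface.
* The g:SCS-style multiple-testing correction of web enrichment services
  is replaced by BH throughout, so enrichment lists on real data will not
  match service output term-for-term.
* With every planted effect at high signal-to-noise, small spurious
  biclusters can still pass the childness filter on one or two enriched
  terms (they are rarely survival-significant); on real data the
  childness threshold interacts with annotation density in ways the toy
  ontology cannot probe.
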