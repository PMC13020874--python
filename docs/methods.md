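# Methods

This note records the models, estimators, numerical conventions and
design choices behind `paralog_fates`, and what the synthetic-data
experiments do and do not demonstrate.

## Sequence divergence (seqdiv)

dN and dS are estimated with the Nei–Gojobori (1986) unweighted counting
method. For every sense codon, each position contributes the fraction of
its three single-nucleotide neighbors that are synonymous; neighbors
that are stop codons count as non-synonymous. Site totals for a pair are
averaged across the two sequences. Codons differing at several positions
are resolved by averaging the synonymous/non-synonymous step counts over
all minimal substitution paths that avoid stop codons, with equal
weights (if every path crosses a stop, all paths are used — a rare
fallback). Proportions are corrected for multiple hits with the
Jukes–Cantor formula d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as
saturated rather than extrapolated. Codons containing gaps or ambiguity
codes are skipped pairwise, so different pairs of a family may use
different codon subsets.

The per-gene ω is a ratio of means: (mean pairwise dN)/(mean pairwise
dS) over all sequence pairs of an ortholog set, which is robust to
individual near-zero dS pairs; it is undefined (flagged) when the mean
dS is zero or every pair is saturated. A counting estimator was chosen
over maximum-likelihood codon models because it is closed-form,
fully testable against hand-evaluated oracles, and sufficient for the
asymmetry comparisons this package makes; its absolute values are not
interchangeable with ML estimates, and transition/transversion bias is
deliberately not modelled. The genetic-code table is injectable; the
standard code is the default and only bundled code.

Asymmetry between the dN distributions of two paralogs is summarized by
Cliff's δ = P(a > b) − P(a < b) over all cross-pairs (ties contribute
zero). The signed value and its magnitude are both reported; the
conventional "large" threshold 0.47 is a configurable constant applied
to the magnitude.

## Cross-species normalization (normexpr)

The pipeline runs strictly in the order raw counts → multimap filter →
TMM → log₂(RPKM+1) → stable-gene rescaling; every dataset carries a
stage tag and each step refuses out-of-order input.

* **Multimap filter.** A gene is dropped when
  |fractional − unique| / max(unique, 1) > 0.2 in *any* sample (the
  strictest reading; a summed-counts variant is available). The
  max(·, 1) denominator makes the unique = 0 case deterministic.
* **TMM.** Factors are computed per sample against a reference sample
  on single-copy orthologs only, since duplication itself perturbs
  expression: per-gene log₂ count-proportion ratios (M) and mean log
  proportions (A) on genes positive in both samples, double trimming
  (30% on M, 5% on A, each tail), and a precision-weighted mean of the
  surviving M values using inverse binomial variance weights. The
  implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
  numerical precision (cross-checked in the test suite) and feeds the
  factors into *effective library sizes* rather than rescaling counts.
* **RPKM.** RPKM = count/(length_kb × effective lib size in millions),
  reported as log₂(RPKM+1); invariant under joint rescaling of counts
  and library sizes.
* **Stable-gene rescaling.** Per sample, each single-copy ortholog's
  percent rank is computed; genes whose median rank sits in the top or
  bottom 25% are removed, and the n (default 375) genes with the
  smallest rank standard deviation define the stable set. Each sample
  is multiplied by median(reference stable expression)/median(own
  stable expression), which makes stable-gene medians exactly equal
  across samples. The reference sample is a configuration key
  (lexicographically first sample by default) — on synthetic data no
  sample is privileged.
* **Batch correction** is not implemented; a pass-through hook accepts
  an externally corrected log₂ matrix between the RPKM and rescaling
  steps.

## Expression metrics (exprmetrics)

Tissue specificity is τ = Σ(1 − xᵢ)/(N − 1) with xᵢ the value in tissue
i relative to the maximum; values are clamped at zero first, because
repeated normalization can push low-expression log₂ values slightly
negative and unclamped negatives would yield τ > 1. τ is undefined
(flagged) for all-zero profiles. When a paralog is represented by
several sequences in one species (secondary duplicates), the per-tissue
maximum is used.

Distances to the pre-duplication profile are computed for paralog A,
paralog B and the total T per (pre-species, post-species) pair, on the
tissues shared by the two species:

* **absolute** — Euclidean distance on log₂(RPKM+1); T is formed by
  summing RPKM *before* re-logging, because expression adds on the
  linear scale;
* **relative** — Euclidean distance between composition profiles
  (each tissue over the tissue sum). Composition is taken on the linear
  RPKM scale by default: under a pure dosage change (both paralogs
  scaled proportionally) linear composition is exactly invariant, which
  is the defining property separating dosage sharing from
  subfunctionalization; a log₂-ratio variant is available
  (`rel_scale="log2"`).

Pre-duplication species that themselves carry duplicates of a family
are excluded from that family's comparisons; a missing paralog is
treated as all-zero and logged. Multiple pre-duplication species yield
one distance row per (pre, post) pair rather than an average, so the
classifier's paired tests can use the full design.

## Fate classification (fates)

Significance between matched distance vectors uses a two-sided paired
sign-flip permutation test on the mean difference. For n ≤ 22 pairs with
2ⁿ−1 ≤ n_perm the full sign lattice is enumerated (exact p); otherwise
the Monte-Carlo add-one estimator p = (1 + #{|perm| ≥ |obs|})/(1 +
n_perm) is used, which coincides with the exhaustive value when
enumeration is complete. Fewer than three pairs return a sentinel p = 1
(cannot reach significance), forcing `UNCLASSIFIED`. A float tolerance
of 1e−12 guards tie comparisons so that identical vectors give exactly
p = 1. This backend replaces a phylogenetic mixed model: it is
assumption-light and deterministic under seed, but treats species pairs
as exchangeable and ignores tree structure; externally computed
p-values (e.g. from a tree-aware model) can be supplied per family.

The decision procedure, with α = 0.05 and no within-family multiple-
testing correction (each comparison is reported at face value;
Benjamini–Hochberg across families is available as an option):

1. Let P be the paralog with the lower mean absolute distance and Q the
   other. If Q is significantly above both P and T, and T is *not*
   significantly below P, the family is `ANCESTRAL_PRESERVED` with
   major paralog P ("tied with T" means p ≥ α for the P-vs-T test).
2. Otherwise, if T is strictly lowest and significantly below both
   paralogs, relative distances decide: T lowest and significantly
   below both → `SUBFUNCTIONALIZATION`; no significant relative
   differences at all → `HYPOFUNCTIONALIZATION_DOSAGE_SHARING`; any
   other relative pattern → `UNCLASSIFIED`.
3. Every remaining pattern — including the case where all three
   entities are mutually non-significant — is `UNCLASSIFIED`, with the
   reason recorded in the decision trace.

A fully redundant pair (neither expression level changed) has T roughly
twice the ancestral level, so neither rule fires: redundancy maps to
`UNCLASSIFIED` by design rather than to a dedicated category.

## Duplication timing (duptime)

Copy-number evolution on the rooted species tree is reconstructed by
Sankoff parsimony over states {0..max_copies}: the transition cost from
parent state s to child state t is cost_dup·max(0, t−s) +
cost_loss·max(0, s−t), with unit costs by default and a flag for
loss-averse costings. The root state is fixed from outgroup information
when supplied (`root_prior`), else chosen to minimize total cost with
ties toward the smaller state. Among co-optimal labelings the backtrack
prefers keeping a child in its parent's state, deferring events toward
the leaves (later duplications), then the smaller state — a
deterministic preorder tie-break; the number of co-optimal labelings is
reported. Events are read off parent→child state changes; the
duplication earliest in preorder is labelled *primary*. Every event map
satisfies a replay invariant (applying the events from the root state
reproduces all leaf counts), checked in the tests against exhaustive
enumeration on all trees up to six leaves. A single loss placed on a
branch ancestral to two or more multi-leaf clades is flagged as
potentially representing independent losses rather than silently
merged. Birth–death models and sequence-tree reconciliation are out of
scope.

## Synthetic data (synth)

The expression generator draws each family's ancestral tissue profile
i.i.d. lognormally — log₂ values Normal(4, 2) per tissue — spanning the
observed range from near-silent to highly expressed genes; defaults are
9 tissues, 2 pre-duplication and 12 post-duplication species. Scenario
constructions on the RPKM scale: `ANCESTRAL_PRESERVED_A` (A = ancestral,
B = minor_scale × ancestral, default 0.1), `SUBFUNCTIONALIZATION`
(complementary tissue masks), `HYPOFUNCTIONALIZATION` (A = s·ancestral,
B = (1−s)·ancestral, default s = 0.5), `REDUNDANT` (A = B = ancestral).
Measurement noise is Gaussian on the log₂(RPKM+1) scale (default SD
0.25), applied per (family, species) sample.

By default the two paralogs of a family share their noise vector within
a species (`noise_mode="shared"`), modelling sample-level measurement
variation — depth, library composition, dissection — that co-measured
genes experience together. This choice matters: with fully independent
per-paralog noise (`noise_mode="independent"`), the paralog total
averages two draws and is systematically *less* noisy than either
paralog, so its relative distance is significantly smaller and genuine
dosage sharing is misread as subfunctionalization. Under shared noise,
dosage sharing leaves the relative profiles of A, B and T exactly equal,
which is the scenario's defining property. Gene-level biological noise
is therefore not represented in the default configuration; the demo's
count-simulation path (Poisson counting noise, which is per-gene)
illustrates how quickly per-gene noise erodes dosage-sharing calls.
Phylogenetic autocorrelation between species is also not simulated —
each species draws independent noise — consistent with the classifier's
exchangeability assumption; passing tests therefore do not demonstrate
robustness to tree-structured expression evolution or to strong
gene-level noise, only to the modelled sample-level noise.

The codon simulator evolves a uniformly random sense-codon ancestor by
single-nucleotide proposals, uniform over (codon, position, alternative
base): proposals creating stops are rejected, synonymous changes always
accepted, non-synonymous changes accepted with probability ω. This is a
purifying-selection regime; ω > 1 is rejected as unsupported. The
expected number of proposals per codon per branch (default 0.45, i.e.
0.15 per site — moderate divergence, far from saturation) plays the
role of branch length. Because proposals are Jukes–Cantor-symmetric,
the NG86 estimator is close to unbiased here (measured mean absolute
error ≤ 0.02 for ω ≤ 0.5 at 1500 codons); mild downward bias appears at
ω = 1 where within-codon multiple hits are most frequent.

The copy-number generator applies a user-supplied or random feasible
schedule of ±1 events along branches; counts are root count plus the
net events on each root-to-leaf path, and a loss on a zero-copy lineage
is rejected.

## Problem sizes and numerical conventions

Simulation-based checks run at 200 families per scenario for classifier
recovery (n_perm = 2000), 20 replicates × 20 sequences × 1500 codons
per ω level for estimator recovery, 1000 null runs for test
calibration, and 100 random 6-leaf trees for parsimony optimality —
sizes at which every Monte-Carlo margin in the tests is comfortable on
a single CPU. Permutation seeds derive deterministically from the
top-level seed and the family name (CRC32), so results are independent
of iteration order; all generators are reproducible bit-for-bit under a
fixed seed, and the workflow manifest (SHA-256 per output, no
timestamps) makes whole-run determinism checkable.

## Known limitations

* Counting-based dN/dS, not ML: no transition/transversion or codon
  frequency modelling; values are comparable within this package only.
* The permutation backend ignores phylogenetic covariance; p-values on
  real species panels will be anti-conservative to a degree that grows
  with tree imbalance.
* The fate taxonomy has no dosage-balance or positive-dosage
  categories, and neofunctionalization is only indirectly visible as
  "evolving under less constraint".
* Relative-profile composition on the linear scale is one of two
  defensible conventions; the log₂ variant is provided and changes
  borderline subfunctionalization/dosage-sharing calls.
* Parsimony merges events that independent-loss scenarios would split;
  such reconstructions are flagged, not resolved.
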