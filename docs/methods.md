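# Methods

## Pipeline overview

The package analyzes protein-level label-free quantification (LFQ) tables
from multi-fungus, multi-substrate secretome experiments. The stages, in
order: detection filtering, per-sample normalization, replicate QC,
replicate averaging, hierarchical ordering for heat maps, and the
enzyme-class co-expression network. Each stage is a pure function over the
`AbundanceTable` / `ProteinAnnotation` containers so the drivers, the
pipeline runner and the tests all share one code path.

## Detection filter

A protein is kept within a fungus if some carbon source has it quantified
in at least `min_replicates` (default 2) of the replicates. A kept protein
is *present* on every substrate with at least one detection — the
single-replicate carry-over used by per-substrate counts. The filter is
monotone in detections by construction (adding a detection can only add
flags). If a fungus was measured with fewer than three replicates the
threshold does not adapt: two detected replicates are still required.
Detection means "has a quantified LFQ value in that raw file"; any
match-between-runs transfer happens upstream in the search engine and is
invisible here.

## Normalization

Per raw file: `x → log2(x) − t`, where `t` is Tukey's biweight of the
sample's detected log2 intensities. The estimator starts at the median,
uses the unnormalized MAD as scale, and applies bisquare weights
`(1 − u²)²` for `|u| < 1` with `u = (x − t)/(c·MAD)`.

Free parameters (`NormalizationParams`): tuning constant `c = 5`
(points beyond 5 MADs get zero weight — lenient enough to keep the bulk of
a log-normal sample, strict enough to drop decade-level outliers),
convergence `epsilon = 1e-6`, `max_iterations = 50`, and `one_step` to take
a single weighted mean instead of iterating. The iterated variant is the
default; the one-step variant is the classical textbook estimator and is
what the worked example `[1, 2, 3, 100] → 2.0545` uses. A zero MAD (more
than half the values identical) falls back to the median. The estimator is
shift-equivariant, so normalization is self-centering (the biweight of a
normalized sample is 0 to within the convergence tolerance) and two samples
differing by a constant intensity factor normalize identically.

Pipeline order is filter → normalize: normalization then sees exactly the
proteins that survive the filter. The two orders differ only through the
biweight's input set; both are available since the stages are independent
functions.

## Replicate QC and averaging

Replicate agreement is summarized as pairwise Pearson correlations between
replicate raw files over pairwise-complete proteins (undefined below three
common proteins). Replicate averaging takes the mean over *detected*
replicates only; an all-missing triple stays missing. No imputation happens
before averaging — imputed floors would drag profile averages, and a grey
"not detected" cell should remain one.

## Hierarchical ordering and profiles

Heat-map row order comes from UPGMA (average linkage) on Euclidean
distances over replicate-averaged profiles, with missing entries filled
with −10 *for the distance computation only* — the same "absent" sentinel
the network uses, so shared absence patterns cluster together. The
implementation delegates to `scipy.cluster.hierarchy.linkage`, which is
deterministic for a given input; the tests verify the merge heights against
a naive O(n³) UPGMA implementation. Display metadata records the bounds
([−5, 10] for heat maps, [−4, 8] for radar-style substrate profiles) on the
normalized log2 scale; missingness is preserved in exports.

## Enzyme-class co-expression network

**Protein adjacency.** Per fungus, over all raw files (replicate level, not
averaged — imputation precedes adjacency and nothing in between averages),
missing normalized values are set to −10 and the edge weight between two
proteins is `|Pearson r|^β`. The default β = 1 makes the edge weight
literally the (unsigned) correlation coefficient; β is exposed as the usual
soft-thresholding power for users who want a harsher adjacency. A constant
(typically all-imputed) profile has undefined correlation; its edges are
defined as 0 since it carries no co-expression signal. The diagonal is 1.

**Class collapse.** Classes are the (possibly overlapping) member sets from
the family→class map; a GH5 protein is counted in both the endoglucanase
and endomannanase classes. The interaction coefficient is the mean pairwise
edge weight between two classes; in the intra-class case both numerator and
denominator are reduced by |Sᵢ| to discard each protein's self-correlation.
A singleton class has an undefined intra-class coefficient; an empty class
yields undefined entries throughout. The implementation is the vectorized
bilinear form `MᵀEM`; tests compare it exactly against a literal
double-sum oracle on random overlapping instances.

**Averaging, strength, discretization.** Per-fungus class networks are
averaged entry-wise with undefined entries omitted; the averaged node size
is the total membership across fungi. Strength is the sum of a node's
defined incident weights with the intra-class self-loop counted once, and
is computed on the averaged, *pre-filter* network — filtering prunes
displayed edges, not the hub ranking. Continuous weights are mapped to
integers by `round(100·C)` (half-up); a weight rounding to 0 is no edge.
Averaging continuous coefficients first and discretizing once avoids
compounding rounding across fungi.

**Marginal likelihood filter.** The discretized graph is treated as T unit
edges. Under the strength-preserving null each unit edge attaches to the
pair (i, j) with probability `p_ij = k_i·k_j/(2T²)` (k = integer
strengths), so the observed weight is compared against Binomial(T, p_ij)
and an edge keeps its place when the upper-tail p-value is below α = 0.05.
Self-loops are excluded from the null and exempt from filtering — the null
is defined for distinct endpoints — and are kept as node annotations.
p-values are monotone non-increasing in the observed weight under a fixed
null, verified exhaustively on all small integer-weighted graphs.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, with
known ground truth. On the log2 scale, protein `p` in sample `(f, s, r)` is

    x = base(p) + induction(class(p), s) + noise,

`base ~ N(base_mu, base_sigma²)` once per protein, fixed additive induction
per (class, substrate), i.i.d. replicate noise, and left-censoring: the
linear intensity `2^x` is recorded only when `x` reaches the detection
threshold. On the free-sugar substrate (glucose) no enzyme class is
induced, reproducing the low CAZyme expression such controls show.

Defaults, chosen to look like a plate-grown secretome LFQ experiment:

| parameter | default | why |
|---|---|---|
| fungi × substrates × replicates | 5 × 5 × 3 | the study design the pipeline targets |
| n_proteins | 90 (48 CAZymes in 8 classes + 42 background) | small enough to iterate, large enough for stable class coefficients |
| base_mu, base_sigma | 22, 1.5 | log2 MaxLFQ intensities sit in the low-to-mid 20s–30s |
| induction effect | +6 log2 | induced enzymes dominate their substrate's secretome |
| noise_sigma | 0.8 | puts replicate Pearson r in the ~0.9 band seen in practice on dense samples |
| detection_threshold | 23 | uninduced proteins are frequently censored (~60% missing cells), like real sparse secretome tables |
| multi_annotation_rate | 0.15 | multi-domain CAZymes are common but a minority |
| predictor_error_rate | 0.1 | signal-peptide predictors agree on most proteins |

The planted structure is three co-induced class pairs with deliberately
disjoint substrate profiles — cellulases on cellulose, hemicellulases on
bagasse + birch, lignin oxidoreductases on spruce — plus two never-induced
background classes. Disjoint profiles make "planted pair" well-defined
(identical non-empty induction profiles) and identifiable; real fungi
induce cellulases on lignocellulose too, so real class networks are denser
than the synthetic ones. Other features of real data the generator does not
emulate: between-fungus proteome differences (the protein catalog and base
abundances are shared across fungi), intensity-dependent variance,
contaminant proteins, and correlated predictor errors. Passing recovery
tests therefore show the pipeline's statistics behave correctly under the
stated generative model, not that any particular biological network is
right.

Determinism: one `numpy` RNG stream seeded from `config.seed`; fixture
writing uses `%.17g` floats so files are byte-identical across runs and
read back losslessly.

## Numerical choices and degenerate inputs

- Half-up integer rounding (`floor(x + 0.5)`) for report percentages and
  weight discretization; Python's banker's rounding is never used.
- Zero LFQ intensity on input means "not quantified" and becomes missing.
- Missing predictor output counts as a "not secreted" vote.
- Empty biweight input is an error; empty class sets and singleton
  intra-class coefficients are undefined (NaN) and propagate as "omitted"
  through averaging.
- Collapse results are clipped to [0, 1] against floating-point noise at
  the boundaries.
- `p_ij` is capped at 1 defensively, though `k ≤ T` already bounds it by ½.

## Known limitations

- The WoLF-PSORT-style input must already be reduced to a boolean call; the
  package does not define the score threshold.
- The family→class map ships only the lignocellulose-relevant rows used in
  this analysis; unmapped families silently contribute no class membership
  (they still count in the category summary).
- UPGMA delegates to scipy; in the measure-zero event of exactly tied
  merge distances the tie-break is scipy's, not a documented rule.
- Genome-encoded per-class counts in the class×substrate table are user
  input, not computed — running HMM annotation pipelines is out of scope.
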