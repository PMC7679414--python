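# secretomenet

Quantitative comparison of fungal secretomes from label-free proteomics:
detection filtering, robust normalization, secretion and annotation
consensus, enzyme-class accounting, and enzyme-class co-expression networks
with significance-filtered edges.

## The problem

Lignocellulose-degrading fungi secrete large, substrate-dependent cocktails
of carbohydrate-active enzymes (CAZymes: GH, CE, PL, AA families, including
LPMOs, plus carbohydrate-binding modules). A typical study grows several
fungi on a panel of carbon sources (e.g. sugarcane bagasse, birch, spruce,
pure cellulose, and glucose as a free-sugar control), collects the
secretomes in three biological replicates, and quantifies proteins with
label-free MS (MaxQuant/MaxLFQ-style intensities). This package implements
the downstream analysis of such a study for people who have the
quantification and annotation tables in hand:

- **Detection filter** — keep a protein only if it was identified in at
  least two of three replicates on at least one carbon source; a kept
  protein then counts as present on any substrate where it appears even
  once (single-replicate carry-over).
- **Normalization** — per raw file, log2 transform and subtract Tukey's
  biweight, a robust location estimate with bisquare weights
  `(1 − u²)²`, `u = (x − t)/(c·MAD)`, so that samples share a common scale.
- **Secretion consensus** — a protein is called secreted when at least two
  of three signal-peptide predictors (SignalP-, Phobius-, WoLF-PSORT-style
  boolean calls) agree.
- **Category accounting** — each protein gets one reporting category with
  catalytic CAZy modules taking precedence over peptidase domains (a
  CE + peptidase protein counts as CE), then CBM-only, then uncharacterized.
- **Class co-expression network** — per fungus, missing normalized values
  are set to −10 and the protein adjacency is `e_vu = |PCC(v,u)|^β`
  (β = 1 by default). The protein graph is collapsed onto possibly
  overlapping enzyme classes S₁…Sₙ:

  `C_{S_i S_j} = Σ_{v∈S_i} Σ_{u∈S_j} e_vu / (|S_i|·|S_j|)`

  with both numerator and denominator reduced by |S_i| when i = j to
  remove self-correlations. Per-fungus class networks are averaged
  entry-wise (undefined entries omitted), node strength is the sum of
  incident weights, weights are discretized to integers 0–100, and edges
  are pruned with the **marginal likelihood filter**: under a
  strength-preserving null, each of the T unit edges lands on pair (i,j)
  with probability `p_ij = k_i·k_j/(2T²)`, so an observed weight w gets the
  upper-tail p-value `P(Binomial(T, p_ij) ≥ w)`; edges with p < 0.05
  survive.

Because a real study's raw data lives in proteomics repositories, the
package ships a synthetic-study generator with the same statistical shape —
log-normal abundances, substrate-dependent induction of co-regulated enzyme
classes, left-censoring at a detection threshold, multi-domain proteins and
noisy predictor calls — with known ground truth, so every stage is testable
offline.

## Worked example

The `analysis/` scripts run the whole study in sequence:

```
python analysis/01_simulate_study.py --seed 1   # writes results/study/
python analysis/02_preprocess.py
python analysis/03_cluster_heatmaps.py
python analysis/04_class_network.py
python analysis/05_report_tables.py
python analysis/06_recovery_benchmark.py
```

`01` prints the study design and the planted class pairs:

```
study: 5 fungi x 5 substrates x 3 replicates, 90 proteins
missing (below detection threshold): 60.4% of cells
planted co-induced class pairs: [('cellobiohydrolase', 'endoglucanase'),
  ('feruloyl_esterase', 'xylanase'), ('laccase', 'peroxidase')]
```

`04` builds the class network and applies the marginal likelihood filter;
all three planted pairs are among the surviving edges, with the strongest
coefficients:

```
marginal likelihood filter (alpha=0.05): 8 of 45 edges survive
  laccase -- peroxidase: C=0.681 w=68 p=1.08e-09
  feruloyl_esterase -- xylanase: C=0.842 w=84 p=2.30e-13
  endoglucanase -- cellobiohydrolase: C=0.739 w=74 p=1.72e-12
  ...
```

Here `C` is the averaged interaction coefficient (mean |PCC| between the
two classes' proteins across the five per-fungus networks), `w = round(100·C)`
its integer weight, and `p` the binomial upper-tail p-value under the
strength-preserving null. `06` repeats this over 100 independent studies:

```
100 seeds: mean ROC-AUC 0.9987, all planted pairs survive MLF in 100% of seeds
```

meaning the averaged coefficient ranks planted pairs above background pairs
essentially perfectly, and the filter retains them in every study.

The same pipeline runs from a single config file via
`secretomenet.run_pipeline({"study": {"synthetic": {"seed": 7}}, "output": "run"})`,
which writes all artifacts plus a deterministic `manifest.json`; point
`study.directory` at your own fixture-style TSVs to analyze real data.

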