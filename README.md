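# strainvar

Tools for analysing **inter- and intra-strain variability of gene expression**
in multi-strain animal panels — the kind of design used to ask whether the
hepatic transcriptome of a "control" animal depends on which strain you
bought: several inbred/outbred strains plus lines derived from crosses
between two of them, a handful of biological replicates each, measured as
log2 intensities.

The package is a library (no CLI): import it, or start from the short
narrative scripts in `examples/`.

## What it computes

* **Variance partitioning** — per gene, a one-way random-effects ANOVA
  splits variance into within-strain (W) and between-strain (B) components;
  the ratio **W/T** with T = W + B measures how much of a gene's variability
  is individual rather than strain-driven (`strainvar.variance`).
* **Moderated linear models** — gene-wise OLS with empirical-Bayes variance
  shrinkage: hyperparameters (d₀, s₀²) of a scaled inverse-χ² prior are
  estimated by moment-matching on log s², the posterior variance
  s̃² = (d₀s₀² + d·s²)/(d₀ + d) feeds moderated t/F statistics, and
  Benjamini–Hochberg adjustment yields q-values.  Two designs: cell-means
  per strain (all pairwise contrasts, M-values in log2), and an
  ancestry + AHR design where each animal carries its parental proportions
  plus a binary variant-receptor indicator (`strainvar.linear_models`).
* **Heritability** — for genes whose parents differ, the distance
  d = (Y_line − Y_low)/(Y_high − Y_low) locates each cross line in the
  parental interval; interacting loci are lines significantly outside both
  parents with consistent sign (`strainvar.heritability`).
* **DIANA clustering** — divisive hierarchical clustering with 1 − Pearson r
  distance over variance- or F-filtered, RMS-standardized genes
  (`strainvar.clustering`).
* **Enrichment** — Fisher (hypergeometric) term enrichment with a
  permutation FDR, decile/contrast enrichment matrices and the cumulative
  log₁₀ p selection rule (`strainvar.enrichment`); PWM motif enrichment
  with five permutation nulls — mono/dinucleotide shuffles, PWM column
  permutation, two background pools — and a ≥4-of-5 significance rule
  (`strainvar.tfbs`).
* **Genome mapping** — strand-aware gene tracks plus a sliding-window
  hotspot scan with permutation p-values (`strainvar.genome_map`).
* **Concordance** — qPCR 2^−ΔΔCt quantification, Welch tests, array-vs-PCR
  Pearson correlation, homolog-paired Spearman comparisons
  (`strainvar.concordance`).
* **Synthetic data** — a generator emulating the 5-population × 4-replicate
  design (3 parental strains, 2 cross lines with 0.5/0.5 ancestry, a shared
  variant-AHR effect in one parent and one line) with full ground truth
  (`strainvar.synth`), and a one-config orchestration of all stages
  (`strainvar.pipeline.run_pipeline`).

## Worked example

```python
from strainvar.synth import SimulationConfig, simulate_expression
from strainvar import linear_models as lm

X, truth = simulate_expression(SimulationConfig(n_genes=3000, seed=2))
fit = lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "ancestry_ahr")))
table = lm.ahr_effect_table(fit, q_threshold=0.05)
print(len(table), len(truth.ahr_genes))
fold, direction = lm.m_to_fold_change(table["M"].iloc[0])
print(round(table["M"].iloc[0], 2), round(fold, 1), direction)
```

prints

```
18 15
2.89 7.4 induction
```

— 18 genes pass the 5% FDR for a variant-receptor effect (15 were planted;
the strongest hit's M-value of 2.89 log2 units corresponds to a 7.4-fold
induction in animals carrying the variant allele).  Running
`python examples/02_moderated_models_and_ahr.py` reproduces this together
with the pairwise strain counts (the two cross lines are the most similar
pair).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline — simulation, variance partition, both model
fits, heritability, clustering, enrichment, motif testing, genome mapping —
from scratch on the default synthetic world with the given seed, writes all
stage artifacts under `results/pipeline/` and the JSON result object to
`--out`.
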