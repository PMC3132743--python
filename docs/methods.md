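# Methods

This note documents the statistical models, the synthetic world the test
suite runs on, and the numerical and design choices that were genuinely
open.  Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Study design assumed throughout

A panel of five populations measured on log2-intensity scale:

* three "parental" strains — `LE`, `HW`, `SD` — each genetically uniform
  within itself for modelling purposes;
* two lines — `LnA`, `LnC` — descended from LE × HW crosses, coded with
  ancestry 0.5 LE + 0.5 HW;
* a binary receptor genotype (the AHR locus): `HW` and `LnA` carry the
  variant allele, all others are wildtype;
* four biological replicates (animals) per population.

All operations generalize to other label sets, replicate counts and
(partly) unbalanced designs; the defaults encode this layout because every
downstream contract (the ancestry design's identifiability, the
heritability distance, the cross-line clustering expectation) presumes it.

## Variance partitioning

Per gene, a one-way random-effects ANOVA over strains by the method of
moments: W = pooled within-group mean square, B = max(0, (MSB − W)/n₀)
with n₀ the replicate count (balanced) or (N − Σn²ᵢ/N)/(k − 1)
(unbalanced), and ratio = W/(W + B) ∈ [0, 1].  The closed form is exact for
the balanced 5 × 4 design; zero-truncation of B produces the point mass at
ratio = 1 that dominates any panel in which most genes have no strain
effect.  REML was deliberately not used: it cannot improve on the balanced
closed form and would blur the truncation spike that is itself a meaningful
feature of the data.  Constant genes are reported with ratio 1 and a
`constant` flag rather than dropped.

Intensity bins are half-open and left-closed at 4, 8, 12 (`<4` unexpressed,
`[4,8)` low, `[8,12)` medium, `≥12` high); W/T deciles are `[(k−1)/10, k/10)`
with the last closed at 1.

Note a quantitative property of this estimator: when σ²_within = σ²_between
at k = 5 groups, the *median* estimated ratio sits near 0.54, not exactly
0.5 — the between mean square has only 4 df and its χ² skewness propagates
through the truncated ratio.  The acceptance check uses the 0.5 ± 0.05
band, which this satisfies.

## Moderated linear models

Gene-wise OLS with a shared design; two codings:

* **simple** — one indicator column per population (cell means, no
  intercept), so any pairwise contrast is a direct difference of strain
  means (the M-value, log2 units).  Ten contrasts for five populations.
* **ancestry_ahr** — one column per parental strain holding each animal's
  ancestry proportion plus an AHR column holding the binary genotype.
  Rank deficiency is a hard error: with fewer populations than the
  five-group layout the AHR column can coincide with a strain column, and
  silently aliasing it would produce a meaningless coefficient.

Empirical-Bayes moderation follows the standard moderated-t construction:
with s²_g on d df per gene, the prior s² ~ s₀²·d₀/χ²_{d₀} is fitted by
matching the first two moments of log s² to the prior predictive
(digamma/trigamma identities; the trigamma inverse is solved by bisection
to 1e-12).  Posterior variances s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) feed t
statistics on d₀ + d df and an F statistic over the contrast set via a
rank-reduced quadratic form.  Degenerate branch: when the observed spread
of log s² does not exceed pure sampling noise, d₀ = ∞ and s̃² is the
geometric-mean variance (for exactly identical variances this equals the
common value).  No intensity-dependent trend is fitted.  FDR control is
Benjamini–Hochberg step-up.

`prior_df=0` recovers ordinary t-statistics exactly; this is used as a test
identity, not an analysis option.

## Heritability

For genes whose parental strains differ, d = (Y_test − Y_low)/(Y_high −
Y_low) from the strain *means* (one Y per strain; means are the natural
summary of four replicates).  d is affine-invariant.  Genes are gated on
significant LE-vs-HW differential expression (q < 0.05 in the simple
model) before distances are computed, split by which parent is higher, and
summarized with Gaussian KDEs using Silverman's rule-of-thumb bandwidth
(overridable; the realized bandwidth is recorded per curve).

Interacting loci: a line is called when both line-vs-parent contrasts are
significant (q < 0.05) with identical signs.  Because contrasts in the
cell-means model are exactly differences of strain means, every called
`interacting_above` record has d > 1 and every `interacting_below` has
d < 0 by construction.  Transgressive segregation is not classified — two
crosses cannot distinguish it.

## Clustering

DIANA (divisive analysis) implemented from first principles: repeatedly
split the cluster of largest diameter by seeding a splinter with the object
of maximal average dissimilarity and migrating objects whose average
dissimilarity to the splinter is smaller than to the remainder; ties break
toward the lowest item index, so the tree is deterministic.  The
implementation's split sequence is frozen in the tests against a trace
obtained from the reference R implementation on a 6-item matrix.

Samples are clustered (genes as features) after filtering genes by overall
variance (> 0.25, strict) or by moderated-F p-value (< 0.001), and per-gene
mean-centering with root-mean-square scaling.  Distance is 1 − Pearson r
(range [0, 2]); genes can be clustered symmetrically by passing the matrix
transposed.  Cutting a divisive tree into k clusters applies the first
k − 1 splits in diameter order.

## Term enrichment

Fisher enrichment is the one-sided hypergeometric upper tail of the 2 × 2
overlap table; terms are flat gene sets (ontology propagation belongs to
the annotation-table builder, not the engine).  The permutation FDR draws
random same-size gene sets (set randomization; the cited desktop tool's
exact null construction is not documented anywhere reproducible) and
estimates FDR(cut) = mean null discoveries / observed discoveries at each
observed p.  Decile and contrast matrices carry log₁₀ p with per-column
set sizes exposed in `attrs["set_size"]` because unequal set sizes mean
unequal power.  The cumulative rule keeps terms with row-sum log₁₀ p ≤ a
cutoff (default −10; −5, −7.5, −20, −30 are the documented alternates).

## Motif (TFBS) analysis

The scorer is a deliberately simplified average-likelihood-ratio statistic,
not the full dynamic-programming recursion of the original library tool:
per sequence, the likelihood ratio of the pseudocount-smoothed PWM
(default 0.375/cell) against the background composition is computed for
every placement on both strands, and the score is ln of the mean ratio;
windows containing non-ACGT characters contribute ratio 0; a promoter set
scores the mean of per-sequence scores.  The five-null architecture is the
methodological core and is preserved exactly:

1. per-sequence mononucleotide shuffle (composition-preserving);
2. per-sequence dinucleotide-preserving shuffle (Altschul–Erickson
   Euler-path construction; exact dinucleotide counts and end bases);
3. random permutation of the PWM columns;
4. random same-size promoter sets from a pool of all genes;
5. the same from a pool of expressed genes (grand mean ≥ 4).

Each null yields an add-one permutation p = (1 + #{null ≥ obs})/(n + 1)
(never 0; exactly 1 is possible when every null beats the observation);
the depletion p mirrors it on the lower tail.  A motif is called enriched
when ≥ 4 of the run tests are significant at p < 0.05 **and** the motif
attains a per-sequence score ≥ 5 in at least one target promoter.

The score threshold is applied to the *best single-promoter score*, not the
set mean, as a reporting filter in the spirit of the original tool.  This
is a considered deviation: for a mixed target set (e.g. the motif present
in half the promoters), signal-free sequences score strongly negative under
the log-mean-ratio statistic (≈ −8 to −24 for sharp 15–30 bp PWMs at
2 kb), so the set mean saturates near 2 regardless of motif strength and a
set-level gate of 5 would veto genuine enrichment categorically.  The
best-promoter gate preserves the threshold's intent — demand at least one
strong match — while remaining usable.  Column permutation is powerless
against repetitive motifs (a shuffled homopolymer is itself); the
multi-test rule tolerates this documented bias.

## Genome mapping

Gene sets are ordered by chromosome and start; the hotspot scan slides
windows (default 5 Mb, half-window step) and compares each window's in-set
count against random same-size sets drawn from the universe, with add-one
p-values and BH across windows.  The scan is an explicit quantitative
extension of what is usually an eyeball claim; note the p-value floor
1/(n_perm + 1) must clear the BH correction across the number of windows,
so genome size, window size and n_perm trade off (the tests use a small
genome for this reason).

## Concordance

2^−ΔΔCt with a configurable calibrator ΔCt (defaulting to a designated
reference strain's mean ΔCt; the choice of calibrator cancels out of
fold-change *comparisons*).  Welch t-tests for PCR strain pairs; Pearson
correlation of array vs PCR log2 fold changes over matched (gene, pair)
comparisons; Spearman's rho for cross-species comparisons after collapsing
homolog multi-matches by none/mean/min/max; per-group log2-F box summaries
with Welch tests against the full gene set for cross-tissue comparisons.

## Synthetic world

The generator's defaults state one fixed world (they are not tuned per
test):

| parameter | default | rationale |
|---|---|---|
| populations | LE, HW, SD + LnA, LnC (0.5/0.5), AHR variant in HW & LnA | the study layout |
| replicates | 4 | the study layout |
| baseline mixture | 45% <4, 30% 4–8, 20% 8–12, 5% >12 | roughly half of probes unexpressed, as observed on this array generation |
| fraction strain-DE | 0.10 | several hundred DE genes per pair at desk scale |
| strain effect | ±U(1.5, 3.0) log2 | clearly detectable at n = 4 |
| fraction AHR-DE | 0.005 | ≈ the observed prevalence of receptor-dependent probes (~105/15923) |
| AHR effect | ±U(1.5, 3.0) | spans the observed M-value range |
| fraction interacting | 0.0025 | ≈ the observed 41/15923 |
| interacting offset | 1.5 × parental span beyond the nearer parent | resolvable at n = 4 |
| mixing weight d | Beta(2, 2), shared by both lines | see below |
| within-strain σ | U(0.1, 0.3) log2 | see below |

Two defaults deserve their own justification.

**Mixing weight.**  Cross-line means are convex combinations of the two
parental means at a per-gene weight d shared by both lines (the lines'
near-identity is the single strongest feature of the real data).  d is
drawn Beta(2, 2) — centrally peaked, vanishing at the endpoints — to
emulate predominantly additive inheritance.  A uniform d is available but
is *not* the default: the observed distance distributions show a strong
central peak, and a uniform d additionally makes the "≥ 90% of KDE mass
inside [0, 1]" property unreachable for purely numerical reasons (a
Silverman-bandwidth Gaussian KDE of a compactly supported uniform spills
≈ 10% of its mass past the endpoints even with zero noise).

**Noise level.**  σ_w ~ U(0.1, 0.3) is the replicate-noise range typical of
GC-RMA-normalized expressed genes and lies inside the σ_w ≤ 0.5 envelope
the cluster-structure property assumes.  With noise drawn up to 0.5,
noise-only genes pile up at the var > 0.25 filter boundary and flood the
clustering feature set; the cross lines — whose intermediate profiles have
small standardized amplitude — then lose their mutual correlation and the
lines-as-sisters structure disappears.  That regime is a property of the
filter interacting with the noise model, not of the clustering algorithm.

What the generator does **not** emulate: probe-level effects, intensity-
dependent variance trends, correlated genes (all genes are independent),
batch/circadian/gavage covariates, and genuine genetic mosaicism (d is a
per-gene abstraction, not a recombination map).  A green structural test
therefore establishes that the pipeline recovers the stated design from
data exactly shaped like its assumptions — not that it would survive every
artifact of a real array study.

## Numerical choices and degenerate inputs

* Trigamma inversion by bracketed bisection on [1e−8, 1e9], tolerance 1e−12.
* B and the ratio are clipped to [0, 1] only against floating-point spill.
* Zero residual-variance genes are excluded from hyperparameter estimation
  but still receive posterior variances.
* DIANA ties (equal diameters or equal average dissimilarities) break
  toward the lowest item index; zero-diameter multi-item clusters remain
  splittable so a k-cut always exists.
* Promoter coordinates are 1-based inclusive; a −1000..+1000 window
  therefore has 2,001 bases.  Windows truncated at a chromosome end return
  shortened with a logged warning.  Non-ACGT bases are retained in
  sequences and neutralized in scoring.
* The pipeline derives per-stage seeds by CRC-hashing the stage name into
  the root seed, so adding a stage never perturbs another stage's draws;
  all seeds stay below 2³¹.

## Known limitations

* The permutation FDR's set-randomization null is a documented stand-in
  for an undocumented legacy tool; gene-randomization nulls would differ
  in the presence of strongly overlapping terms.
* The moderated F uses a pseudo-inverse quadratic form over the supplied
  contrast set; for the full pairwise set this equals the overall
  equality-of-means test, but arbitrary deficient contrast sets are
  handled by rank reduction rather than rejected.
* `welch_pairwise` with two observations per group and one zero-variance
  group returns very small df rather than failing; p-values there are
  fragile by nature.
* The hotspot scan's windows overlap (half-window step), so BH across
  windows is conservative in spirit but not an exact FDR over disjoint
  hypotheses.
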