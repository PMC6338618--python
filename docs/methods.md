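# Methods

This note records the models, estimators and numerical conventions
implemented in `revscreen`, in enough detail to re-derive every number the
package produces.

## 1. Probe panel and read assignment

A panel is a set of DNA probes of equal length *L* (default 30 nt), one per
gene, partitioned into signature-up, signature-down and stable-control
roles. The default study panel is 46 genes: 13 signature (7 up, 6 down) and
33 controls.

A read is assigned to the probe whose first *L* bases are within
`max_mismatch` Hamming distance (default 3, inclusive). Reads matching two
or more probes equally well at the minimum distance are discarded as
ambiguous; reads shorter than *L* or beyond the tolerance go to an
`UNASSIGNED` bucket. Panel validation requires every pairwise probe distance
to exceed `2 * max_mismatch`; by the triangle inequality a read within
tolerance of one probe is then outside tolerance of every other, so
assignment is unambiguous by construction and the ambiguity branch only
triggers for user-supplied panels that skip validation. Matching is
vectorized (byte-matrix comparison in chunks), so a full screen counts in
seconds.

Rationale for `max_mismatch = 3`: at the simulated per-base substitution
rate of 0.005, the probability of a 30-mer carrying ≥ 4 errors is ~2e-5, so
tolerance 3 recovers essentially every read while the distance-separation
rule keeps misassignment impossible.

## 2. Plate model

Wells live on 384-well plates (rows A–P, columns 1–24). A layout maps each
used well to a treatment, dose (µmol/L) and exposure time (hours); defaults
are 1 µmol/L for 24 h. Every plate must carry at least two vehicle (DMSO)
wells; replicate wells of a compound are kept on one plate when the layout
is auto-built, and DMSO wells are spread evenly across the used positions.

## 3. Normalization

Size factors use median-of-ratios restricted to the stable control genes,
per plate:

- reference = geometric mean of each control gene across the plate's wells
  (genes with any zero count on the plate are dropped from the reference);
- a well's factor = median over control genes of (count / reference);
- factors are rescaled to geometric mean 1 within each plate.

Restricting to controls means treatment effects on signature genes cannot
leak into the depth estimate. If no control gene is everywhere non-zero on
a plate, the estimator falls back to total-count scaling with a warning; a
fully zero well is an error naming the well. Normalized counts are raw
counts divided by the well's factor.

## 4. Differential expression

Fold change per gene is the treated-well mean over the same-plate DMSO-well
mean of normalized counts. Testing works on log2(count + 0.5):

- ≥ 2 replicate wells: two-sample t-test against the plate's DMSO wells;
- 1 well: normal score using the DMSO wells' log2 standard deviation;
- compounds spread over plates: per-plate log2 fold changes pooled by
  inverse variance, p from the pooled z.

The pseudo-count 0.5 keeps log fold changes finite at zero counts while
biasing high-count genes negligibly. A gene is a DEG when
`max(FC, 1/FC) > 2` (strict) **and** `p < 0.05` (strict); boundary values
are excluded on both thresholds.

## 5. Reversal scoring

Genes are ranked by decreasing log2 fold change, ties broken by gene name
for determinism. The weighted running-sum enrichment score of a gene set
walks the ranking: members step the sum up by `|metric|^p / N_R`
(`N_R` = total member weight, weight exponent p = 1 by default), non-members
step down by `1/(N - N_H)`. The ES is the running sum at its largest
absolute deviation.

**Tie rule.** When the maximal positive and negative deviations tie in
magnitude, the positive extreme wins; within a sign, the earliest rank wins.
The comparison carries a 1e-12 slack so the decision does not depend on
floating-point accumulation order. This rule intentionally breaks the
ES → −ES antisymmetry under list reversal at exact ties — a measure-zero
event for continuous metrics.

The two-sided connectivity score is
`WTCS = (ES_up − ES_down) / 2` when the two halves score with strictly
opposite signs, else 0. **Reversal = −WTCS**, so a compound that drives the
up half down and the down half up scores positive. Compounds are ranked by
decreasing reversal, ties broken by compound id.

Permutation p-values draw random disjoint memberships of the same sizes
from the profile's genes (gene-label permutation), and use the two-sided
add-one estimator `(1 + #{|null| ≥ |obs|}) / (1 + n_perm)`. A null
membership landing entirely on zero metrics carries no step mass and scores
0 by continuity. Because WTCS has a point mass at 0 (concordant-sign
halves), calibration checks are run on the single-set ES, whose null is
continuous.

## 6. GSEA

For a single ranked profile, each gene set with ≥ `min_size` (default 3)
genes in the profile gets an ES, a normalized score
`NES = ES / mean(|same-sign null ES|)`, a permutation p, and a
Benjamini–Hochberg FDR across the tested sets.

## 7. Transcription-factor overlap

Given a gene → TF-set annotation, `shared_tfs` returns the TFs bound at
every queried gene plus Venn region counts keyed by the exact subset of
query genes each TF binds. `filter_tfs_by_expression` then keeps only the
shared TFs whose own expression change passes the DEG rule in the requested
direction; TFs absent from the profile are treated as non-significant.

## 8. Survival analysis

Cohorts are stratified by one gene's expression into top and bottom
fractions of size `floor(n * frac)` (default quartiles), with stable tie
order. Kaplan–Meier curves and the two-group log-rank test come from
`lifelines`. At a true hazard ratio of 3 with 100 patients per arm the test
has essentially full power; under the null its rejection rate sits at the
nominal 5%.

## 9. Synthetic-data generator

The generator exists to provide ground truth for the pipeline, under fixed
study conditions rather than tunable knobs:

- **Counts**: negative binomial with `var = µ + φ·µ²`, dispersion φ = 0.1 —
  overdispersion typical of amplicon counting.
- **Well depth**: log-normal multiplier, σ = 0.2 (σ = 0.5 in the
  size-factor recovery check) — pipetting/loading variation.
- **Sequencing error**: i.i.d. per-base substitution at rate 0.005 to a
  uniformly random other base.
- **Treatment effects**: planted multiplicative log2 shifts on signature
  genes only; controls are never perturbed.
- **Output**: one FASTQ per well, named `PLATE_ROWCOL.fastq`, alongside the
  exact truth count matrix; read totals are conserved between truth and
  files.
- **Cohorts**: one-factor log-normal expression (σ = 0.5), exponential
  survival with baseline hazard 0.02 events/month, hazard ratio applied to
  the top expression half, independent uniform censoring.

Not emulated: indels, read-quality structure, PCR duplication and
amplification bias, probe cross-hybridization, plate-position (edge)
effects, and correlated gene–gene noise. Conclusions about those failure
modes are outside the generator's warrant.

## 10. Problem sizes and headline checks

The end-to-end validation scale is a package choice: 100 compounds in
duplicate plus vehicle wells (~216 wells at 10,000 reads each), 5 planted
reversers at |log2 effect| = 2. Under these conditions all 5 planted
compounds rank in the top 10 with reversal ≈ 1, error-free screens count
back exactly, null permutation p-values are uniform (KS test), and the
log-rank simulations match their nominal operating characteristics.
`scripts/acceptance.py` re-runs all of these from a single seed.

## 11. Open design choices and limitations

- The t-test treats log2 normalized counts as approximately normal; with
  2–4 replicate wells this is a convenience, not a guarantee, and the
  permutation p on the reversal score is the more defensible inferential
  quantity.
- Inverse-variance pooling across plates assumes independent per-plate
  estimates and ignores plate-level random effects.
- The weight exponent p = 1 follows common connectivity-scoring practice;
  p = 0 reduces to the classical unweighted KS statistic and is exposed as
  a parameter.
- Gene-label permutation preserves the metric profile but not gene–gene
  correlation; with 46-gene panels a sample permutation scheme is not
  available at the per-compound level.
- The DEG thresholds (2-fold, p < 0.05) are screening conventions, not
  calibrated error rates.
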