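# revscreen

Sequencing-based drug-screen analysis for finding compounds that **reverse a
gene-expression signature** — from raw per-well FASTQ files to a ranked
compound table — plus the downstream statistics used to follow up hits
(gene-set enrichment, transcription-factor overlap, survival stratification).

## The scientific problem

A transcriptional signature ties a phenotype to the coordinated up- and
down-regulation of a small gene panel — here the motivating case is a
breast-cancer lung-metastasis signature with an up half (e.g. *MMP1*,
*PTGS2*, *ANGPTL4*, *TNC*) and a down half (e.g. *LY6E*, *RARRES3*). If a
compound pushes the up genes down and the down genes up, it opposes the
transcriptional program and is a candidate for repurposing against the
phenotype.

Targeted-panel sequencing screens make this search cheap at scale: each well
of a 384-well plate gets one compound, probes for ~46 genes (signature genes
plus a bed of stable controls) are read out by sequencing, and each well's
reads become a small count vector. The analytical chain this package
implements:

1. **Probe counting** — assign each read to a probe by Hamming distance with
   a mismatch tolerance (default ≤ 3), discarding ambiguous ties. Probe sets
   are validated so that any two probes differ by more than twice the
   tolerance, which makes assignment unambiguous by the triangle inequality.
2. **Normalization** — per-plate median-of-ratios size factors computed on
   the stable control genes only, so real treatment effects cannot masquerade
   as depth differences.
3. **Differential expression** — fold change of each treated well group
   against the same-plate vehicle (DMSO) mean, two-sample t-test across
   replicate wells (normal-score fallback for single wells, inverse-variance
   pooling across plates), and a DEG rule of fold change > 2 with p < 0.05.
4. **Reversal scoring** — genes ranked by log2 fold change; the weighted
   running-sum (Kolmogorov–Smirnov-style) enrichment score of each signature
   half, combined into a two-sided connectivity score (WTCS) and negated so
   that **positive reversal = anti-signature activity**, with permutation
   p-values from random gene memberships.
5. **Follow-up** — GSEA with BH-corrected FDR, shared-transcription-factor
   analysis of DEG groups, and Kaplan–Meier / log-rank survival stratification
   of expression cohorts.

A calibrated synthetic-data generator (negative-binomial counts, log-normal
well depths, per-base substitution errors, planted log2 effects) provides
ground truth for end-to-end validation of the whole chain.

## Worked example

Score a compound panel against a two-sided signature
(`examples/03_reversal_scoring.py` — 20 noise compounds plus one planted
reverser):

```python
from revscreen import GeneSignature, score_compounds

sig = GeneSignature("DEMO", up=set(genes[:4]), down=set(genes[4:8]))
ranked, skipped = score_compounds(profiles, sig, n_perm=199, seed=3)
print(ranked.head(3)[["compound", "reversal", "p_perm", "rank"]])
```

prints

```
compound  reversal  p_perm  rank
REVERSER  1.000000   0.005     1
     C03  0.638792   0.165     2
     C01  0.544992   0.235     3
```

The planted reverser scores the maximal reversal of 1.0 at the smallest
achievable permutation p of 1/200. The `examples/` directory has one short
script per capability (simulation + counting, normalization + DEGs, reversal
scoring, GSEA, TF overlap, survival); each prints its computed numbers.

The same chain is available as a CLI for shell pipelines
(`revscreen simulate | count | quantify | score | run --config cfg.yaml`),
reading FASTQ directories and writing TSV tables.

## Layout

- `src/revscreen/` — the library (probes, plates, simulate, counting,
  quantify, enrichment, stats, survival, tfmap, pipeline, cli)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — methods note: models, estimators, numerical choices
- `tests/` — unit, property and end-to-end acceptance tests
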