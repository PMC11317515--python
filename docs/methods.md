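# Methods

## Statistical model of the analysis

All statistics operate on log2-transformed LFQ intensities, so "2-fold"
means a log2 difference of 1. Comparisons use the two-sample Student t-test
(pooled variance, df = n_a + n_b − 2) by default, matching the convention
of two-tailed t-testing on log-scale protein intensities; a Welch variant
is available by flag. No variance moderation (Perseus' S0 or limma-style
shrinkage) is applied — p-values come from the plain t distribution, which
keeps the test exactly reproducible by an independent implementation.
Multiple testing uses the Benjamini–Hochberg step-up, applied **separately
within each comparison** over the tested proteins (the two ratiometric
comparisons share a denominator but not a p-value pool), and within the
gated set only for the stress volcano. Enrichment flags are directional:
q ≤ α *and* positive mean log2 difference; the p-value itself stays
two-sided.

The hypergeometric upper tail for ORA is computed by log-space summation of
exact terms (gammaln-based binomial coefficients), stable for
genome-scale counts. Preranked GSEA uses the weighted running-sum
statistic: hits increment by |metric|^p / Σ_hits |metric|^p, misses
decrement by 1/(N − N_hits), ES is the signed maximum deviation (positive
wins an exact magnitude tie), the null is gene permutation (random
same-size member sets), NES divides ES by the mean |null ES| of matching
sign, and the FDR q compares the observed NES with the pooled same-sign
null NES distribution. Ties in the ranking metric are broken by stable
input order. PCA scores come from SVD of the mean-centred sample-by-protein
matrix, with a deterministic sign convention (largest-magnitude score
positive).

### Open design points and how they were resolved

- **Muscle gate, "either" vs "both".** The gate keeps proteins at least
  2-fold enriched in bait proximity (i) *or* in the tissue reference (ii)
  over the negative control (iii). The inclusive "either" rule is the
  default because the gate's purpose is to include tissue-expressed
  proteins not yet near the bait at rest; `mode="both"` is available.
- **Overlap denominator.** The detection-overlap percentage is
  100 · n_shared / n_stress: the share of stress-experiment detections
  already seen at rest, the only definition consistent with treating the
  second experiment as the one being checked against the first.
- **Tested values under imputation.** t-tests use observed values whenever
  each group retains ≥ 2 observations and fall back to the imputed vectors
  otherwise. Imputation exists to keep low-abundance proteins testable; it
  should not inject noise into comparisons that are already well observed.
- **Degenerate tests.** Zero-variance comparisons raise internally and are
  mapped by the pipelines to an exclusion reason (`zero_variance`), never
  to a fabricated p-value. With fewer than two testable proteins, BH is a
  pass-through of the p-values.
- **GSEA ranking metric.** The co-IP interactor workflow ranks by signed
  log2 fold change by default; sign(log2fc)·(−log10 p) is available. The
  NES report filter keeps NES ≥ cutoff and, by default, the symmetric
  negative tail as well, since both directions are biologically readable.
- **ORA universe.** Detection-conditioned: all paired features by default
  (`all_pairs`), optionally only the significance-filtered ones.

## Synthetic data generator

The generator emulates a five-arm proximity-labeling study with planted
ground truth, one class per protein:

| class | i | ii | iii | iv − v |
|-------|---|----|-----|--------|
| bait-proximal (`PROXIMITY_TRUE`) | +e_prox | 0 | 0 | 0 |
| tissue background (`MUSCLE_CYTO`) | +e_mus | +e_mus | 0 | 0 |
| endogenous background | 0 | 0 | 0 | 0 |
| stress shift in/out | +e_mus | +e_mus | 0 | ±e_stress |
| null | 0 | 0 | 0 | 0 |

Stress-shift classes carry tissue-level enrichment at rest so that planted
stress candidates sit inside the 2-fold gate — the population whose
movement the stress volcano is designed to score. Intensities are
per-protein baseline ~ Normal(base_mean, base_sd) on the log2 scale
(shared across the two experiments: a protein's abundance is a property of
the protein) plus replicate noise ~ Normal(0, noise_sd); the stress
experiment adds a constant batch offset. Missingness is
missing-not-at-random: logit p(missing) = slope · (midpoint − intensity),
so low-abundance measurements drop out preferentially; slope ≤ 0 disables
dropout. Random streams (class assignment, baseline, noise, dropout) are
separate `numpy` generators keyed on the seed, so identical configs give
bit-identical outputs and the two experiments share class labels and
baselines.

Defaults echo the scale of the targeted study design: 1709 proteins, 4
replicates per condition, planted classes 34 bait-proximal / 77 tissue
background / 6 + 6 stress shifts (so 123 gate-true proteins carrying 12
stress candidates), base_mean 26, base_sd 2 (log2 LFQ scale), noise_sd 0.5,
dropout midpoint base_mean − 2·base_sd with slope 1, batch shift 0.5 log2
units, effects 3 / 2 / 2 log2 units.

The paired transcript/protein generator plants quadrant structure by
drawing a (transcript, protein) effect pair per feature with signs fixed by
the quadrant and magnitude `effect_omics`, then produces replicate tables
for both assays and differential tables via the package's own t-test. The
transcript side is therefore a stand-in for an external count-model DE
analysis (e.g. a negative-binomial fit with shrinkage); real transcript DE
tables in `id / log2fc / pvalue` form can be dropped in unchanged.

What the generator does **not** emulate: peptide-level quantification and
roll-up, match-between-runs artefacts, correlated (protein-complex)
effects, intensity-dependent variance, count-distributed RNA-seq data.
Passing tests therefore demonstrate the correctness and calibration of the
analysis logic under a clean log-normal LFQ model, not performance on any
real dataset.

## Preprocessing

proteinGroups-style TSVs are read with decoy filtering ("+"-flagged
Reverse / Potential contaminant / Only identified by site rows dropped),
log2 transform, and 0/empty/NaN treated as missing, per the MaxQuant
convention of writing 0 for unquantified LFQ values. Samples are
median-centred. The valid-value filter keeps proteins with ≥ 3 observed
values in at least one (role, batch) group by default — the minimum that
guarantees a defined t statistic with one value missing — and records an
exclusion reason for dropped proteins. Remaining missing values are imputed
from a downshifted normal per sample: Normal(m − 1.8·s, (0.3·s)²) with m, s
the sample's observed mean and SD (the canonical width/downshift used for
MNAR imputation in Perseus-style workflows). Imputed cells are tracked in a
separate mask and never overwrite observations.

## Verification scenarios (`proxistress.validation`)

- **Overlap arithmetic**: matrices realising given detection counts; with
  1512 shared of 1862, the overlap is 81.2%.
- **Null calibration**: 20 seeds of zero-effect data at full study scale
  (dropout and imputation active); the fraction of proteins flagged
  enriched, and stress-significant, must stay within the BH guarantee
  (≤ 0.05 + 3 binomial SE). Measured fractions are ≈ 0 because BH under a
  full null bounds the family-wise error near α per *family*, not per test.
- **Proximity spike-in**: 30 planted bait-proximal proteins at effect 3,
  noise 0.5, 4 replicates, against the default background classes. Dropout
  is disabled in the spike-in scenarios so the planted design is exactly
  realised. Measured `enriched_both` sensitivity is ≈ 0.86 with FDR 0. This
  is the attainable power of the design: a p-value-level simulation of the
  single comparison (noncentral t with ncp = 3/(0.5·√(1/2)) ≈ 8.49, df 6,
  BH at its self-consistent threshold) gives 0.89, and requiring *both*
  correlated comparisons lowers it to ≈ 0.87.
- **Stress spike-in**: 12 planted shifts at effect 2 among the gated set.
  The stress-assay noise level (0.35) was fixed by that same noncentral-t
  power analysis so that the 4-vs-4 design recovers ≥ 10 of 12 with high
  probability; measured recovery is 11–12 of 12 with correct directions.
- **Quadrant recovery**: balanced 25/25/25/25 planting at effect 2 is
  recovered within 0.2 percentage points; proportions sum to 100 exactly.
- **Imputation distribution**: ≥ 10⁴ imputed draws realise the 1.8 SD
  downshift and 0.3 SD width to three decimals.
- **Determinism**: the full pipeline is byte-identical under a repeated
  seed.

Problem sizes (seed counts, permutation counts, protein numbers) are the
package's verification defaults: large enough that binomial noise is small
against the asserted margins, small enough that the whole suite runs in a
few minutes on one CPU.

## Known limitations

- Power at the study's design point is modest: with 4 replicates and
  replicate SD 0.5, a 3-log2 planted enrichment is recovered by the
  dual-control flag at ~0.86 sensitivity, not more — a property of the
  plain t-test + BH combination, which moderated-variance methods would
  improve at the cost of exact reproducibility.
- The GSEA FDR uses the pooled-null normalisation of the original
  procedure; with few gene sets it is coarse (the permutation p-value is
  the better-calibrated quantity there).
- Quadrant assignment excludes exactly-zero fold changes ("unassigned")
  rather than inventing a sign; real data virtually never hit the boundary.
- The batch model is a single additive offset; interaction-style batch
  effects would require external correction before the combined analysis.
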