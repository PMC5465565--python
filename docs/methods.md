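# Methods

This note documents the statistical model behind `coexprior`, the defaults
and their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Donor-weighted correlation

Post-mortem brain datasets contain repeated samples per donor (multiple
regions or arrays from one brain). Treating them as independent
observations overstates the effective sample size and lets multi-sample
donors dominate correlation estimates. Every correlation in the package is
therefore a weighted Pearson correlation with weights
w_i = 1 / n_{d(i)}, where n_{d(i)} is the number of samples contributed by
the donor of sample i. Each donor then carries total weight 1, the weights
sum to the number of distinct donors, and with all-singleton donors every
formula reduces exactly to the unweighted Pearson correlation (verified to
1e-12 against `numpy.corrcoef` in the test suite). The weighted estimate is
invariant to positive affine transforms of either variable and to global
rescaling of the weights.

Degenerate (zero-variance) genes get correlation 0 with an explicit
degeneracy flag rather than being dropped, keeping matrix shapes stable for
downstream ranking. The scalar `weighted_pearson` returns NaN instead,
since a single undefined value should not masquerade as "uncorrelated".
A hard floor of 3 samples applies to any correlation; below 10 samples a
warning is emitted. The floors are our choice: correlation estimates from
a handful of brains are noise, but a hard error above 3 would forbid
legitimate exploratory use.

## The prioritisation engine

Let D be the known disease genes and C the candidates, within one dataset.

1. **Background correlation.** A random set of |C| genes is drawn without
   replacement from the eligible pool; for each drawn gene the maximum |r|
   over D is recorded; this repeats B = 1000 times and all B·|C| maxima are
   pooled. The eligible pool excludes D and C: including candidates would
   contaminate the null with exactly the signal being tested. Because a
   gene's maximum against D does not depend on which random set it appears
   in, the implementation computes each pool gene's maximum once and lets
   the B repeats resample indices; this is algebraically identical to the
   literal loop and makes B = 1000 cheap at any scale.
2. **Threshold.** For a user proportion p (default 0.2) the cutoff is the
   empirical (1 − p) quantile of the pooled maxima, using the inverse-ECDF
   (lower) definition: the smallest pooled value whose ECDF reaches 1 − p.
   p = 1 returns the pooled minimum, p = 0 the maximum, and the threshold
   is monotone non-increasing in p. Pooling across repeats (rather than
   averaging per-repeat quantiles) is the simplest rule that satisfies the
   calibration contract — on independent data the mean fraction of random
   candidates prioritised converges to p — which the acceptance suite
   verifies at p = 0.2 ± 0.03. A small (1e-9) guard in the quantile index
   absorbs floating-point noise in (1 − p)·n.
3. **Prioritisation.** A candidate is prioritised when its maximum |r| over
   D *strictly* exceeds the cutoff. The within-dataset score is the sum of
   |r| over disease genes restricted to |r| above the cutoff.

Candidates absent from a dataset (platform coverage differs) are
*untestable* there, not failed; the report carries testable-dataset counts
next to consensus counts. Cross-dataset ranking sorts by consensus count
(descending), then the above-threshold sum aggregated over prioritising
datasets only (descending), then gene symbol — the aggregation rule is our
choice, since the score is defined per dataset.

Randomness: one user-visible seed; per-dataset streams are spawned from it
deterministically (`numpy.random.SeedSequence`), so runs are byte-identical
at fixed seed and inputs.

## Cleaning strategies

**Positivity + quantile normalisation.** Input matrices are already
summarized log-scale intensities, so "background correction" reduces to a
per-column positivity floor: columns containing non-positive values are
shifted so their minimum equals 1e-6; well-behaved columns are untouched.
Quantile normalisation then maps every column onto the mean of the
per-rank order statistics; ties within a column receive the mean of the
reference values of the tied ranks. The operation is idempotent up to tie
handling.

**Regularized RUV.** Negative-control genes (default: a packaged list of
~80 standard human housekeeping genes, fully replaceable) are assumed to
carry unwanted technical/batch variation but not the biology of interest.
All rows are centered; the unwanted factors are the top k right singular
vectors (default k = 10) of the centered control submatrix; each gene is
adjusted by removing its projection onto these orthonormal factor scores,
shrunk by 1/(1+λ). λ = 0 removes the full projection (control rows end
exactly orthogonal to the factors); λ → ∞ removes nothing. The ridge
protects biological signal that is partially correlated with the unwanted
factors. When λ is not given it is selected per dataset from the grid
{0, 0.01, 0.1, 1, 10, 100} by minimizing the Kolmogorov–Smirnov distance
between the post-clean control–control correlations and the exact
independence null of Pearson's r (a Beta distribution on [−1, 1]): controls
should look mutually independent after cleaning, and over-removal (which
induces negative control correlations) is penalized just like
under-removal. This selection rule and the defaults are this package's own
design; they are configurable because no single regularization scheme is
canonical. Disease genes, candidates and user exclusions are always removed
from the control set first.

## Developmental periods

Ages map to 15 periods: 1–7 prenatal on the post-conception-week (PCW)
scale — [4,8), [8,10), [10,13), [13,16), [16,19), [19,24), [24,∞) — and
8–15 postnatal — [birth, 6 months), [6 m, 1 y), [1,6), [6,12), [12,20),
[20,40), [40,60), [60,∞) years. Intervals are half-open [lower, upper), so
a boundary age (8 PCW, 6 months, 20 years…) belongs to the later period.
The prenatal and postnatal scales are never converted into each other: the
age unit selects the block, which sidesteps the ill-defined birth point
(~38–40 PCW). Period 7 is left unbounded above on the PCW scale so the
mapping is total for any PCW age ≥ 4; PCW < 4 (pre-embryonic) is an error.
Period subsetting always recomputes donor weights on the subset.

Per-period correlation matrices (with recomputed weights) and their
elementwise differences expose developmental rewiring; period sets with
fewer than 3 samples are omitted with a warning.

## Partial correlations and matrix combination

Partial correlations come from the inverse of the correlation matrix after
linear shrinkage toward the identity, R_s = (1−s)R + sI (default s = 0.1):
p_jk = −q_jk/√(q_jj·q_kk). Shrinkage is necessary because gene panels can
exceed the sample count, making R singular; with s = 0 on a two-gene matrix
the partial equals the marginal correlation exactly. Cross-dataset
"combined" matrices are donor-count-weighted averages of per-dataset
correlation matrices over shared genes — merging intensity values across
platforms would be unsound, so only the correlation estimates are combined.

## LOOCV benchmarking

For each gene g of a known set: the disease set becomes the known set minus
g, and the candidates are g (the "defector") plus 99 decoys drawn from
genes present in at least one dataset and outside the known set. Decoys
are drawn once per trial (not per dataset) so a trial is coherent across
datasets; "not known to be associated" is operationalized as "not in the
supplied known set", keeping the harness self-contained. Confusion
matrices at each consensus requirement k pool defectors (TP/FN) and decoy
gene-trials (FP/TN); sensitivity, specificity, precision and NPV follow,
with zero-denominator cases flagged NaN rather than raised. Means across
gene sets are unweighted. Because consensus sets are nested in k, mean
sensitivity and the false-positive fraction are non-increasing in k — the
expected sensitivity/specificity trade-off of demanding replication.

## The synthetic-data generator

Expression for gene g in sample i of donor d(i):

x_gi = μ_g + δ_{g,d(i)} + Σ_m λ_gm·f_mi·1[m active in period_i]
       + Σ_u β_gu·u_ui + ε_gi

with gene baselines μ_g ~ N(8, 1) (typical log2 intensity), per-gene donor
effects δ ~ N(0, τ²) shared by a donor's samples (default τ² = 0.1σ²),
standard-normal module factors f and unwanted factors u, and noise
ε ~ N(0, σ²), σ = 1. Donors contribute 1–4 samples (drawn from a
configurable size distribution); donor ages are drawn per donor across the
15 periods and samples inherit them, so period assignment is consistent
with the metadata by construction. Housekeeping genes (default 10% of the
panel) carry no module loadings but full unwanted loadings — exactly the
negative-control premise RUV relies on.

With equal loadings λ and an always-active module, the theoretical
intra-module correlation is λ²/(λ² + σ² + τ²); the donor effect is
per-gene, so it adds variance but no gene–gene correlation, and the helper
`loading_for_correlation` inverts the exact expression (e.g. target r = 0.8
at the defaults gives λ ≈ 2.10). The unwanted-factor *loadings* β are drawn
once per simulation and shared across datasets, while the factor
*realisations* u are independent per dataset: susceptibility to technical
variation (probe affinity, GC content, transcript length) is a property of
the gene, not of the experiment. This is what makes uncleaned data produce
*recurring* false positives across datasets — the failure mode RUV exists
to fix — and it is why the cleaning comparison below is informative at all.

What the generator does **not** emulate: platform-specific intensity
distributions, heavy-tailed or count noise, correlated module factors,
gene-length or GC trends beyond the shared β, missing values, or
outlier samples. Passing tests on this generator therefore demonstrate the
pipeline's statistical logic (calibration, consensus, cleaning), not
robustness to every artefact of real microarray data.

## Problem sizes in the tests and acceptance script

The shipped checks use 3 datasets of 400–1000 genes × 100–120 samples,
B = 500–1000 permutation repeats, 20–50 replicate seeds, and 99-decoy LOOCV
over 10-gene known sets. These sizes keep every run on a laptop-class CPU
within seconds while leaving Monte-Carlo error well below the asserted
tolerances (e.g. ±0.03 around the calibrated proportion 0.2 over 50
replicates of 100 candidates).

## Known limitations

- Guilt-by-association presupposes that disease genes share co-expression
  networks; gene sets without internal co-regulation will not benefit.
- No p-values or FDR are attached to prioritisations; the proportion
  threshold controls an *expected* random-gene rate, which overestimates
  the false-positive rate only insofar as random genes are truly
  independent of the disease genes.
- Thresholds are dataset-specific and not comparable across datasets;
  consensus counts, not raw correlations, are the cross-dataset currency.
- The RUV ridge-selection heuristic targets control independence and may
  under-remove when controls are themselves co-regulated.
- Brain-region stratification and probe-level preprocessing are out of
  scope; inputs are summarized gene-level matrices.
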