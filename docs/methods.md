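# Methods

## The analysis problem

Circulating microRNAs in serum are candidate disease biomarkers: they are
stable, tissue-informative and measurable by RT-qPCR from small volumes.
In a pooled-serum discovery design, sera from several mice of one strain
are pooled, split into three technical aliquots, reverse-transcribed, and
each miRNA assay amplified in PCR triplicate, on two independent qPCR
platforms (a genome-wide discovery panel and a focused validation panel).
The analytical task is to turn the resulting quantification-cycle (Cq)
tables into (i) per-strain lists of dysregulated miRNAs that replicate
across platforms, (ii) sample-level signatures robust to genetic
background, and (iii) individual-level biomarker scores with ROC/AUC
evaluation.  `mirscreen` implements that chain, plus a generator of
synthetic Cq datasets with known injected effects so that every stage can
be validated against ground truth.

## Data model and measurement scale

Cq is log-scale by construction: one cycle ≈ one log2 unit of abundance,
lower Cq = more transcript.  A `CqTable` is a miRNA × sample matrix of Cq
with `NaN` marking no-amplification; each column carries strain, role
(pathological/control), aliquot index and PCR-replicate index.  PCR
triplicates are collapsed first by a missing-aware arithmetic mean
(`triplicate_mean`; a cell stays missing only when all replicates failed),
yielding three aliquot-level values per (miRNA, strain) — the replication
unit of every downstream test.  Detection applies an inclusive ceiling:
an assay is detected in a strain when its aliquot-mean Cq ≤ 35 cycles,
and detected overall when that holds in at least one strain.

## Normalization

Two schemes, both operating on aliquot-level tables:

**Global mean.**  The per-sample normalizer is the mean raw Cq over the
*expressed set*: endogenous assays detected in **all** samples
(complete-case, so every sample averages the same gene set; spike-ins
excluded).  Corrected Cq is `cq − normalizer(sample) + grand_normalizer`
with the grand normalizer the mean of per-sample normalizers.  Two exact
algebraic properties are enforced by tests: the per-sample mean of
corrected Cq over the expressed set equals the grand normalizer
(tolerance 1e−9), and a per-sample additive shift (RNA input variation)
moves all corrected values by one uniform constant (`shift/n_samples`,
through the grand normalizer) so every ΔCq, ΔΔCq and fold change is
exactly invariant.  The scheme assumes dysregulation is sparse or
balanced in sign; a strongly one-sided perturbation of many assays biases
the normalizer toward the effect, shrinking apparent fold changes by
roughly `n_injected/n_expressed` of the effect.

**Stable referents.**  Relative log2 abundance
`mean_referent_cq(sample) − cq`, with the arithmetic mean of the referent
Cq (equivalent to a geometric mean of linear abundances).  Used for
individual assays and cohorts; referents default to miR-29a and miR-30b.
Every referent must amplify in every sample (hard error naming both).

**Spike-in QC** reports each sample's deviation of exogenous spike-in Cq
from the spike-in's cross-sample median; the default tolerance is 1.5
cycles, chosen as a round generous bound on technical recovery variation
and fully configurable.

## Differential screen

ΔΔCq is the case mean minus control mean of normalized values (negative =
upregulated), converted by `2^(−ΔΔCq)` to the signed fold-change
convention (+r for up, −1/r for down, |FC| ≥ 1 always).  Significance per
(miRNA, strain) is a two-sided two-sample t-test on the three aliquot
values per side.  The default pools variances: both sides are technical
aliquots of the same measurement process, and at n = 3 the pooled test
holds its nominal level while the Welch correction is markedly
conservative (empirically ~0.034 rejection at α = 0.05 under the null)
because its Satterthwaite degrees of freedom are noisy at this size;
Welch remains available (`equal_var=False`) for genuinely heteroscedastic
designs.  Benjamini–Hochberg adjustment is applied within each
(platform, strain) family of detected assays — the narrowest defensible
family; the implementation delegates to `statsmodels` and is verified
against a brute-force step-up oracle.

The cross-platform **double-positive** rule calls a miRNA dysregulated in
a strain when |FC| ≥ 1.5 on both platforms (inclusive), the signs agree,
and the validation-platform p ≤ 0.05; reported FC/p are always the
validation values.  Failures carry a reason code (`fc1_below`,
`fc2_below`, `discordant_sign`, `p2_above`, `undetected`), and borderline
assays can be exempted from the FC thresholds through an explicit
allow-list recorded in the output — never silently.  An all-missing group
propagates as an undetermined record, never as FC = 0.

## Signature analysis

**Hierarchical clustering** of samples uses Euclidean distance on
corrected Cq with average linkage by default (both configurable and
recorded); assay rows with any missing value are dropped and counted.
Cluster quality at a k-cluster cut is summarized by strain purity
(fraction of samples in a cluster of their own majority strain), with
`perfect` requiring purity 1 at k = number of strains.

**NMF.**  Corrected Cq is mapped to linear relative abundance
`2^(C − corrected_cq)` with C the table maximum — non-negative by
construction and fold-preserving.  The factorization uses Lee–Seung
multiplicative updates minimizing Frobenius error (seeded uniform
initialization scaled to the data, tol 1e−6 on relative error
improvement, max 2000 iterations), written in-package because the
validation suite asserts a per-iteration non-increasing error trace; an
independent library NMF serves as a cross-check in the tests.  Default
rank is the number of genetic-background groups + 1 (backgrounds plus a
disease axis).  A factor is *background-aligned* when the between-group
variance of its per-sample coefficients exceeds the within-group
variance; each assay's `background_score` is the share of its basis mass
on such factors, and the lowest-scoring assays form the
background-insensitive candidate signature (ties broken by factor and
assay order, deterministically).

**Direct contrasts.**  Related disease models sharing one control are
compared pairwise with each other instead of against the control; the
signature is the set of assays with BH-adjusted q ≤ α and |FC| ≥
threshold in at least one pair.  Pair results are antisymmetric by
construction.

## Biomarker ROC

Cohort features are either referent-normalized log2 abundances or
per-subject log2 ratios to a single reference miRNA (Cq(reference) −
Cq(target), computed on raw Cq).  The ratio needs no normalization: both
assays share the subject's RNA input, so per-subject additive Cq shifts
cancel exactly — the practical argument for ratio features when the
reference moves in the opposite direction to the targets.  The empirical
ROC enumerates all thresholds (ties collapse to diagonal segments); AUC
is computed both as trapezoidal area and as the normalized
Mann–Whitney U with half-credit ties, which agree to 1e−12 and are
asserted against an exhaustive pair-counting oracle.  The p-value is the
two-sided Wilcoxon–Mann–Whitney test, exact for tie-free groups of ≤ 12,
normal-approximate otherwise; at 5 vs 5 the exact test is conservative
(attainable p-values are discrete).  Features are auto-oriented so the
reported AUC ≥ 0.5, with the raw orientation retained.

## Synthetic data generator

The generator is the package's ground-truth instrument, emulating the
pooled two-platform design:

    Cq(m, strain, aliquot, rep) = base(m) + background(m, group)
                                + platform(m) − log2FC(m, strain)
                                + e_aliquot + e_rep

with base Cq uniform on [20, 33] cycles, per-miRNA background shifts
shared by all strains of a genetic-background group (sd 0.5 cycles),
per-miRNA per-platform offsets (sd 0.7 cycles), and Gaussian aliquot and
replicate noise (sd 0.2 cycles each; the pooled design cannot separate
the two sources, so they default equal).  Injected disease effects enter
as −log2FC cycles in the pathological strain only.  Censoring is
deterministic at the 35-cycle ceiling (values above become missing),
with an optional stochastic-dropout flag; referent assays carry no strain
or background effects (that is what "most stable" means operationally)
and spike-ins are constant abundance with replicate noise only.  Both
platforms share base, background and injected effects but draw
independent offsets and noise.  Individual-level cohorts use one column
per subject with between-subject noise on top of the injected effect.

What the generator does *not* emulate: PCR-efficiency differences,
primer–dimer artifacts, hemolysis contamination, inter-plate calibration
drift, or correlated miRNA co-regulation.  Passing tests therefore
certify the statistical machinery under an additive Gaussian log-scale
error model with hard censoring — not robustness to those instrument- and
biology-level artifacts.

## Problem sizes in the validation suite

The suite and the reproduction script run on deliberately compact
designs: the standard simulated study uses 90 assays × 8 strains
(3 aliquots × 3 PCR replicates each), recovery is measured over 20 seeds
of a 60-assay two-strain screen with 50 balanced ±2 log2FC injections,
null calibration uses a 400-assay 7-strain null screen (~2,000 tests),
clustering purity 10 seeds, and cohort ROC 20 seeds of 5 vs 5 subjects.
These sizes give stable Monte-Carlo estimates in seconds while matching
the real design's replication structure.

## Known limitations

- Global-mean normalization is only trustworthy when dysregulation is
  sparse or sign-balanced across the expressed set (see above).
- The background-alignment heuristic for NMF factors (between- vs
  within-group coefficient variance) is a documented convention; other
  criteria could classify mixed factors differently.
- Per-strain BH families are narrow; users wanting experiment-wide FDR
  control should pool families before adjustment.
- The exact membership of a background-insensitive signature depends on
  NMF rank and seed; ranks and seeds are recorded on the model for
  reproducibility.
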