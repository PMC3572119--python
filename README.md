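# mirscreen

Analysis pipeline for serum/plasma microRNA biomarker discovery by
two-platform RT-qPCR screening.

Circulating miRNAs are attractive disease biomarkers — stable in serum,
tissue-informative, and cheap to quantify.  A common discovery design
pools sera per mouse strain, splits each pool into three technical
aliquots, amplifies every miRNA assay in PCR triplicate, and runs the
screen twice on independent qPCR platforms (genome-wide discovery, then
focused validation).  `mirscreen` turns the resulting quantification-cycle
(Cq) tables into dysregulation calls, expression signatures and biomarker
scores, and ships a synthetic-data generator with known injected effects
so every stage is testable against ground truth.

## What it computes

- **Normalization** — global-mean corrected Cq
  (`corrected = Cq − mean Cq over the expressed set + grand mean`) for
  large screens, and stable-referent normalization (miR-29a/miR-30b
  style) for individual assays; spike-in recovery QC (cel-miR-39, Sp3/Sp6
  style exogenous controls).
- **Differential screen** — detection at Cq ≤ 35, the 2^−ΔΔCt fold
  change in the signed convention (ratio 0.5 → −2), a pooled two-sample
  t-test on per-aliquot values, Benjamini–Hochberg FDR per strain, and
  the cross-platform *double positive* rule: |FC| ≥ 1.5 on both
  platforms with concordant sign and p ≤ 0.05 on the validation platform.
- **Signatures** — hierarchical clustering of sample profiles with
  strain-purity scoring; NMF (multiplicative updates) of the abundance
  matrix to score each miRNA's participation in genetic-background
  factors and rank background-insensitive candidates; direct pairwise
  contrasts among related disease models sharing one control.
- **Biomarker ROC** — referent-normalized and ratio-to-reference-miRNA
  log2 features per subject, all-thresholds empirical ROC, AUC as the
  normalized Mann–Whitney U (ties half credit), exact rank-sum p-values
  for small cohorts, and a paired comparison of the two feature schemes.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Simulate the standard study design — 8 strains in 3 genetic-background
groups, 21 assays injected with known log2 fold changes — then run the
two-platform screen:

```python
from mirscreen import (ScreenConfig, screen_platform, double_positive_screen,
                       count_dysregulated, simulate_two_platform_screens)
from mirscreen.cli import default_study_spec

spec = default_study_spec(seed=1)
platform_a, platform_b, truth = simulate_two_platform_screens(spec)

cfg = ScreenConfig()                      # Cq<=35, |FC|>=1.5, alpha=0.05
calls = double_positive_screen(
    screen_platform(platform_a, cfg), screen_platform(platform_b, cfg), cfg
)
print(count_dysregulated(calls))
```

```
strain
lmna_ki        5
mdx           13
mybpc3_ki      5
sgca          13
sgcg          13
any_strain    21
```

Each strain's count is the number of miRNAs passing the double-positive
rule against its control; `any_strain` is the union (a miRNA dysregulated
in several strains counts once).  Here the screen recovers exactly the 21
injected assays.  The per-call table carries the validation-platform fold
changes and p-values, e.g. the strongest upregulations in the `mdx`
model:

```
   mirna_id  fc_screen1  fc_screen2  p_screen2
sim-miR-002    8.732859   13.327824   0.000002
sim-miR-006    9.133770   11.646496   0.000005
sim-miR-005    6.419039    7.948804   0.000365
```

(positive FC = upregulated vs control; both platforms exceed the 1.5×
threshold with the same sign).

The same stages are available from the shell:

```sh
mirscreen pipeline --seed 1 --outdir out/    # deterministic end-to-end run
mirscreen screen --cq1 a.tsv --meta1 a_meta.tsv \
                 --cq2 b.tsv --meta2 b_meta.tsv --outdir out/
mirscreen signature nmf --cq b.tsv --meta b_meta.tsv --outdir out/
mirscreen roc --cq cohort.tsv --meta cohort_meta.tsv \
              --targets miR-206,miR-1 --ratio-ref miR-31 --out roc.tsv
```

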