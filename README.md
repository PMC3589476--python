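# mirscreen

Circulating plasma-miRNA biomarker screening — a filter-and-cascade
discovery pipeline with cross-study concordance and two-dataset
reproducibility testing, plus a synthetic plasma-array generator so every
stage can be exercised and validated without external data.

## The problem

Cell-free miRNAs in plasma are attractive minimally invasive cancer
biomarkers, but published candidate lists for breast cancer disagree
wildly. Two nuisance processes dominate plasma measurements: contamination
by miRNAs from the cellular blood compartment (erythrocytes, leukocytes,
platelets), which hemolysis can elevate up to 30-fold, and low-abundance
probes whose signal sits inside array background. `mirscreen` implements a
screening design that confronts both, and the meta-analytic machinery to
quantify how (ir)reproducible such screens are.

## What it computes

**Preprocessing and filters.** Raw probe intensities get a per-sample
background subtracted (negatives retained), are quantile-normalized (every
sample forced onto the rank-mean reference distribution), and a probe is
called *detected* in a sample iff its background-subtracted value is > 0.
Filter 1 removes probes on a blood-compartment miRNA list; Filter 2 removes
probes undetectable in more than 10% of samples (N > 7 of 70). A rescue
procedure revisits the filtered low-abundance probes, partitioning them into
mostly-negative, low-positive-mean, and evaluable buckets.

**Screening cascade.** With four cohorts — controls, pre-resection breast
cancer cases, post-resection cases, and other (lung/colorectal) cancers — a
probe is a candidate iff

1. *DE*: two-sided pooled t-test p < 0.05 (pre-resection vs control) and
   fold change between group means ≥ 2;
2. *post-resection normalization*: control vs post-resection p > 0.1
   (a true tumor-derived marker regresses once the tumor is removed);
3. *specificity*: not significantly shifted (p < 0.05) in the same
   direction in the other-cancer cohort.

No multiple-testing correction is applied anywhere, by design fidelity to
the screening convention being reproduced.

**Cross-study concordance.** Published candidate lists are harmonized as
simple directional fold changes; miRNAs reported by ≥ 2 studies are
classified consistent (unanimous direction) or inconsistent, and concordance
is |consistent| / total pooled candidates.

**Reproducibility.** For two studies on the same platform: the Pearson
correlation of per-probe log2 fold changes (p via t = r·√((n−2)/(1−r²)) on
n−2 df), and cross-evaluation of each study's top candidates (p < 0.05,
≥ 2-fold) in the other study's table — significance and direction
concordance per candidate.

**Simulator.** `simulate_dataset` generates a 1145-probe, 70-sample
(20/20/20/10) experiment with log-normal signal, additive background and
instrument noise, truncation at zero, a low-abundance probe class, 140
blood-cell probes sharing per-sample blood-count multipliers and hemolysis
spikes, and three planted effect classes (breast-cancer-specific regressing,
pan-cancer, non-regressing) recorded in a truth table.
`simulate_study_pair` plants bivariate-correlated effects across two studies
for recovery testing.

## Worked example

```sh
python examples/published_cascade.py
```

```
probes analyzed:                 46
pass DE thresholds:              44
normalize after resection:       13
fail breast-cancer specificity:  10
final candidates:                mir-708*, mir-92b*, mir-568
```

The packaged 46-probe table (group means and contrast p-values of the
differentially expressed plasma miRNAs) flows through the cascade: 13
candidates normalize toward baseline after surgery (p > 0.1), 10 of those
are also shifted the same way in lung/colorectal cancer (p < 0.05) and are
discarded as non-specific, leaving the trio miR-708*, miR-92b*, miR-568.

The other examples are one page each and print what they compute:

* `examples/cross_study_concordance.py` — five genome-wide candidate lists:
  16 overlapping miRNAs, 6 consistent vs 10 contradictory, concordance
  3.8% of 158 pooled candidates; the qPCR composite: 16 unique miRNAs
  (10 up, 6 down), only miR-21 and miR-155 corroborated.
* `examples/reproducibility_pair.py` — recovers a planted inter-study
  effect correlation (ρ = 0.8 → r ≈ 0.81) and cross-evaluates the packaged
  top-candidate tables: 1 of 46 and 3 of 26 replicate at p < 0.05, every
  one in the *opposite* direction; pooled 72-pair correlation r = 0.08.
* `examples/simulate_and_screen.py` — full pipeline on synthetic data with
  probe bookkeeping (1145 → 1005 → 477) and truth-table checking of the
  final candidates.

## Layout

| path | contents |
|---|---|
| `src/mirscreen/io.py` | domain types, miRNA name canonicalization, TSV/CSV readers |
| `src/mirscreen/preprocess.py` | background subtraction, quantile normalization, detection calls |
| `src/mirscreen/filters.py` | blood-cell and low-abundance filters, rescue partition |
| `src/mirscreen/screening.py` | t-tests, Fisher exact, fold change, DE screen, cascade |
| `src/mirscreen/cross_study.py` | consensus vote-counting, qPCR composite |
| `src/mirscreen/reproducibility.py` | fold-change correlation, top-candidate cross-evaluation |
| `src/mirscreen/simulate.py` | synthetic plasma-array generator with truth table |
| `src/mirscreen/pipeline.py` | end-to-end orchestration, YAML config, run manifests |
| `src/mirscreen/geo.py` | optional local series-matrix reader (untested convenience) |
| `src/mirscreen/data/` | transcribed published summary tables, default blood list |
| `docs/methods.md` | the model, parameter choices, and known limitations |

See `docs/methods.md` for the statistical conventions (tie handling in
quantile normalization, threshold strictness, degenerate-input rules) and
for what the simulator does and does not emulate.
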