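# Methods

This note records the statistical conventions, the simulator's model, the
parameter defaults and why they were chosen, and the known limitations of
the package. Everything stated here is computed by the test suite or the
example scripts; nothing is asserted beyond what the code demonstrates.

## Name canonicalization

Published miRNA tables mix spellings (`hsa-miR-21`, `miR-21`, `let7a`). The
canonical form strips the species prefix, lower-cases the `mir`/`let` stem,
inserts the stem–id hyphen when missing, and preserves star and arm suffixes
verbatim: `mir-92b*` and `mir-92b` are distinct identities, because starred
probes appear as first-class rows in the screening results. Identifiers that
do not match the miRNA grammar (proprietary probe ids like `HS_303_b` or
`solexa-9655-85`, entries like `U6`) pass through unchanged and act as their
own canonical names. The map is idempotent, so canonicalized artifacts can
be re-read safely.

## Preprocessing conventions

**Background subtraction** takes one non-negative background level per
sample (a scalar is broadcast). Probe-level background models are out of
scope — bead-level raw data are not available at this layer. Negative
results are retained, not clipped: they carry the detectability signal.

**Quantile normalization** maps every column onto the reference
distribution, defined as the row-wise mean of the column-sorted matrix.
Tied values within a column receive the mean of the reference values at the
ranks the tie block occupies — the standard tie convention. Consequences,
verified by tests: all columns share one sorted value multiset afterwards;
within-column ranks are preserved; the transform is exactly idempotent for
tie-free columns. It is *not* exactly idempotent when tie patterns differ
across columns (tie-block averaging deforms a column's sorted vector, which
feeds back into the next reference); the test suite asserts idempotence on
continuous data and rank/tie preservation on tied data. A single-sample
matrix has nothing to normalize against and is passed through with a
warning.

**Detection** is judged on the background-subtracted scale: detected iff
value > 0, with exactly 0 counting as undetected. The low-abundance filter
therefore consumes the detectability mask computed *before* quantile
normalization, even though downstream testing runs on normalized values.

## Filters

Filter order is fixed: blood-compartment names first, then low abundance —
the reports chain (`probes_in` of filter 2 equals `probes_kept` of filter
1), and each filter conserves probes (kept + removed = input). The
low-abundance threshold is expressed as an absolute count
N = floor(fraction × n_samples); with the default fraction 0.10 and 70
samples, N = 7 and a probe is removed iff undetected in strictly more than
7 samples.

The packaged blood-compartment list is a short, clearly labelled
placeholder of well-known blood-cell miRNAs; the published 140-entry list
the screening design used lives in an external source and is not
reconstructed here. The mechanism — remove every probe whose canonical name
is listed, where one name may match several probes and starred names never
match unstarred ones — is what is specified and tested; users supply their
own list file for real analyses.

**Low-abundance rescue** revisits the probes Filter 2 removed, in a fixed
sequential order: first the `neg75` bucket (value < 0 in strictly more than
75% of control samples *and* of pre-resection case samples), then
`low_mean` (mean over strictly positive values, pooled across control and
pre-resection samples, ≤ 100 intensity units; probes with no positive
values at all land here), then `evaluable`, on which the standard pooled
t-test runs at α = 0.05. The 75% rule uses a strict inequality; the source
convention at exactly 75% is not documented, so the choice is recorded here
rather than silently assumed. Which samples enter the positive-value mean
is likewise underdetermined in the source; the two comparison cohorts are
used, since the rescue exists to serve the case/control contrast.

## Statistical tests

* **Two-sample t**: pooled variance by default ("standard t-test"), Welch
  as an option. Degenerate rule: both groups constant and equal means →
  t = 0, p = 1; constant with unequal means is an error. Tests run on the
  normalized intensity scale by default because the published group means
  are reported on that scale; a log2 option exists for strictly positive
  matrices.
* **Fold change**: ratio of group means, larger over smaller (≥ 1), with a
  signed case-over-control log2 companion. Defined only when both means are
  strictly positive; otherwise the probe is flagged non-computable and
  fails any fold-change criterion — quantile-normalized background-
  subtracted values can legitimately be negative.
* **Fisher exact (2×2)**: two-sided p sums hypergeometric point
  probabilities ≤ the observed table's, with margins fixed (scipy's
  implementation; the test suite cross-checks an exhaustive enumeration).
* **Pearson correlation**: two-sided p from t = r·√((n−2)/(1−r²)) on n−2
  df; zero variance in either coordinate is an undefined-correlation error.

## Cascade thresholds and strictness

Stage 1 requires p < 0.05 strictly (a printed p of exactly 0.050 fails) and
fold change ≥ 2 inclusively. Stage 2 requires p > 0.1 strictly — survival
means *failing to reject* equality of control and post-resection means, so
p-values of 0.084 or 0.099 count as still-different and fail. Stage 3
disqualifies only *same-direction* significance in the other-cancer cohort;
opposite-direction significance is an anomaly worth reporting but not
evidence against breast-cancer specificity. On the packaged 46-probe table
these conventions yield 44 → 13 → 3 with the final trio
{mir-708\*, mir-92b\*, mir-568}; the strict stage-1 and stage-2 boundaries
are each load-bearing for those counts.

Top-candidate selection in the reproducibility module uses the same
strictness: p < α strictly, |log2 FC| ≥ log2(2) inclusively.

## The simulator

Per-cell intensity model:

    log2 signal(probe p, sample s) = baseline_p + effect_{class(p), cohort(s)}
                                     + N(0, signal_log2_sd)
    raw = max(0, background + signal · blood_s · hemolysis_s + N(0, noise_sd))

* `baseline_p ~ N(8, 2)` on the log2 scale (low-abundance probes:
  `N(2, 1)`), putting typical detected probes in the
  hundreds-to-thousands intensity range of the published group means, with
  an overall mean intensity near 10³.
* 45% of probes are low-abundance by default — chosen to match the observed
  share of probes removed by the >10%-undetectable filter (486 of 1008).
* 140 blood-cell probes share one per-sample multiplier
  `2^N(0, 0.5)` (blood-count variation); hemolysis is a per-sample
  Bernoulli(0.1) event multiplying blood-cell probes by U(1, 30) — the
  30-fold ceiling mirrors the reported hemolysis elevation of erythrocyte
  miRNAs. Blood-cell probes never carry planted cohort effects, so by
  construction none survives Filter 1.
* Effect classes (10 probes each by default, |log2 effect| ~ |N(2, 0.5)|
  with random sign): *bc_specific_regressing* (shifted pre-resection,
  exactly 0 post-resection and in other cancers — full regression),
  *non_regressing* (post-resection effect equals the pre-resection effect),
  *pan_cancer* (other-cancer effect equals the pre-resection effect, 0
  post-resection). This cleanly separates the cascade's two secondary
  criteria: stage 2 should reject non-regressing probes, stage 3 pan-cancer
  probes.
* `background = 30`, `noise_sd = 15` intensity units: low-abundance probes
  (signal ≈ 4) then fall below zero after background subtraction in a
  substantial fraction of samples, producing realistic detectability
  censoring, while mid-range probes are essentially always detected.
* One root seed drives a single local `numpy.random.Generator`; outputs are
  bit-reproducible given (config, seed) and no global RNG state is touched.

`simulate_study_pair` shares probe identities, classes, and baselines
between the two studies (same array, same biology) and draws each probe's
true pre-resection log2 effect from a bivariate normal with sd 1.0 and the
requested correlation ρ, for every non-blood probe; all nuisance draws are
independent per study. Estimated fold-change correlations recover ρ with a
small attenuation (measured ≈ 0.96–0.97 at ρ = 1) because group-mean
sampling noise adds independent error to each study's estimated log2 FC;
the acceptance tolerance of ±0.05 on the 20-replicate mean covers this
attenuation plus sampling error, as verified by the suite.

What the simulator does **not** emulate: batch or spatial array artifacts,
probe-specific affinities, heavy-tailed biological variation,
between-cohort age/race structure in the expression values, or the real
deposit's empirical distributions. Passing recovery tests therefore shows
the *pipeline logic* is sound under the stated generative model — not that
the model reproduces real plasma-array data.

## Problem sizes in the test suite

Simulation-based checks run at the study's own scale (1145 probes × 70
samples): the null type-I check pools eight seeds (~3 900 tests of true
nulls after filtering) and asserts the DE-positive fraction within three
binomial standard deviations of α = 0.05; correlation recovery uses 20
replicate pairs per ρ ∈ {0, 0.8, 1}. Unit-level property tests use smaller
matrices (tens of probes) where the property is scale-free. The whole suite
runs in well under a minute on one CPU.

Note the per-seed null positive fraction is noticeably more variable than a
binomial count would suggest — quantile normalization couples probes within
an array — which is why the acceptance check pools seeds rather than
asserting each seed separately.

## Data provenance inside the package

`src/mirscreen/data/` transcribes six published summary tables (candidate
lists of ten qPCR and five genome-wide studies, cohort demographics, the
46-probe contrast table, and the two top-candidate comparison tables) as
commented CSVs. Transcription conventions: footnote stars on probe names are
restored as `*` suffixes; censored p-values are stored as `<bound` and
parsed as the bound (every comparison the pipeline makes is unaffected);
fold-change signs in the comparison tables are preserved verbatim even where
they disagree with the group-means table for the same probes (a documented
inconsistency of the source material, carried as-is rather than reconciled —
the 72-pair pooled correlation is computed from the printed values). One
directional call (miR-155 in the five-study overlap table) is transcribed
per the source's own classification of that row rather than its printed
magnitudes, which contradict each other; the package follows the
classification because every derived count depends on it.

## Known limitations

* The cascade tests intensities, not log intensities, by default; for
  strongly skewed data the pooled t on intensities is only approximately
  calibrated (the null simulation keeps it within binomial tolerance, but
  real data may be heavier-tailed).
* The GEO series-matrix reader (`mirscreen.geo`) is a local-file convenience
  parser, deliberately outside the tested surface, and never fetches data.
* Real-data discovery counts (e.g. 522 probes surviving filters on the
  original deposit, its global between-study correlation of −0.024) require
  the original microarray deposits and are not reproduced here; the package
  reproduces the procedures and the published table-level computations.
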