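"""The four-cohort differential-expression screening cascade.

The design compares plasma miRNA intensities across four cohorts — healthy
controls, pre-resection breast cancer cases, post-resection cases, and
"other cancer" (lung/colorectal) cases — and selects candidates in three
sequential stages:

1. **DE screen** — pre-resection cases vs controls: two-sided t-test
   p < ``alpha_de`` AND at least ``fc_min``-fold change between group means;
2. **Post-resection normalization** — a true tumor-derived marker should
   return toward control levels after surgery: survivors must show NO
   significant control vs post-resection difference (p strictly >
   ``alpha_norm``);
3. **Breast-cancer specificity** — survivors are dropped if they are also
   significantly altered in the other-cancer cohort (p < ``alpha_spec``)
   *in the same direction*; opposite-direction significance is recorded as
   an anomaly but does not disqualify.

No multiple-testing correction is applied anywhere; unadjusted p-values are
the published convention this pipeline reproduces.

The module also carries the cohort-comparability utilities (summary-statistic
t-test for age, Fisher exact test for race) used to check that cases and
controls are demographically matched.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleSheet, COHORTS

__all__ = [
    "ScreeningConfig",
    "CascadeReport",
    "two_sample_t",
    "t_from_summary",
    "fisher_exact_2x2",
    "fold_change",
    "de_screen",
    "apply_cascade",
    "cohort_comparability",
]

TVariant = Literal["pooled", "welch"]


@dataclass
class ScreeningConfig:
    """Thresholds and test options for the cascade.

    ``alpha_de``/``fc_min`` gate stage 1, ``alpha_norm`` gates stage 2
    (survival requires p strictly greater), ``alpha_spec`` gates stage 3.
    The default test is the pooled two-sample t ("standard t-test"); Welch is
    available as a variant. Tests run on the normalized intensity scale by
    default, matching how the published group means are reported; ``log2``
    applies log2 to (strictly positive) intensities first.
    """

    alpha_de: float = 0.05
    fc_min: float = 2.0
    alpha_norm: float = 0.1
    alpha_spec: float = 0.05
    t_variant: TVariant = "pooled"
    scale: Literal["intensity", "log2"] = "intensity"

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_norm", "alpha_spec"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if not self.fc_min > 1:
            raise ValueError(f"fc_min must exceed 1, got {self.fc_min}")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test variant {self.t_variant!r}")
        if self.scale not in ("intensity", "log2"):
            raise ValueError(f"unknown testing scale {self.scale!r}")


# --------------------------------------------------------------------------
# Elementary statistics
# --------------------------------------------------------------------------


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: TVariant = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns ``(t, df, p)``.

    ``pooled`` assumes equal variances (df = n1+n2-2); ``welch`` uses the
    Satterthwaite df. If both groups have zero variance and equal means the
    conventional result is t=0, p=1; zero variance with unequal means is an
    error (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2 if variant == "pooled" else float("nan")
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: TVariant = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from sufficient statistics; returns ``(t, df, p)``.

    Algebraically identical to :func:`two_sample_t` on raw data having these
    moments.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            df = n1 + n2 - 2 if variant == "pooled" else float("nan")
            return 0.0, float(df), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table ``[[a, b], [c, d]]``.

    The two-sided p sums hypergeometric probabilities (margins fixed) of all
    tables whose point probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("table is empty")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


@dataclass(frozen=True)
class FoldChange:
    """Fold change between two group means.

    ``fc_ratio`` is the larger mean over the smaller (>= 1); ``log2_fc`` is
    signed, case over control. Both are only defined when both means are
    strictly positive; otherwise ``computable`` is False and the probe fails
    any fold-change criterion. ``direction`` is always defined, from the sign
    of (case mean - control mean).
    """

    fc_ratio: float
    log2_fc: float
    direction: str
    computable: bool


def fold_change(mean_case: float, mean_control: float) -> FoldChange:
    direction = "up" if mean_case > mean_control else "down"
    if mean_case > 0 and mean_control > 0:
        ratio = max(mean_case, mean_control) / min(mean_case, mean_control)
        return FoldChange(
            fc_ratio=float(ratio),
            log2_fc=float(np.log2(mean_case / mean_control)),
            direction=direction,
            computable=True,
        )
    return FoldChange(
        fc_ratio=float("nan"), log2_fc=float("nan"), direction=direction, computable=False
    )


# --------------------------------------------------------------------------
# DE screen and cascade
# --------------------------------------------------------------------------

#: Columns of the contrast-result table produced by :func:`de_screen`.
CONTRAST_COLUMNS = [
    "mirna",
    "mean_control",
    "mean_bc_pre",
    "mean_bc_post",
    "mean_other",
    "direction",
    "fc_ratio",
    "log2_fc",
    "fc_computable",
    "p_case",
    "p_post",
    "p_other",
    "other_direction",
]


def _vector_t(a: np.ndarray, b: np.ndarray, variant: TVariant) -> np.ndarray:
    """Row-wise two-sided t-test p-values for two probes × samples blocks."""
    with warnings.catch_warnings():
        # constant rows (probes censored to an identical value everywhere)
        # are resolved by the p=1 convention below; scipy's precision-loss
        # warning about them is expected
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled"))
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p=1 when means agree, else undefined -> nan
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    equal = a.mean(axis=1) == b.mean(axis=1)
    p[degenerate & equal] = 1.0
    return p


def de_screen(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    config: ScreeningConfig | None = None,
) -> pd.DataFrame:
    """Per-probe contrast results for the three cohort comparisons.

    Returns one row per probe with the four cohort means, the case/control
    fold change and direction, and the three two-sided t-test p-values
    (control vs pre-resection, control vs post-resection, control vs other
    cancers). All three p-values are computed for every probe; the cascade
    decides how they are used.
    """
    config = config or ScreeningConfig()
    groups: dict[str, list[str]] = {}
    for cohort in COHORTS:
        samples = sheet.samples_in(cohort)
        if len(samples) < 2:
            raise ValueError(f"cohort {cohort!r} missing or too small in sample sheet")
        missing = set(samples) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"samples absent from matrix: {sorted(missing)}")
        groups[cohort] = samples

    values = matrix.data
    if config.scale == "log2":
        if (values.to_numpy() <= 0).any():
            raise ValueError("log2 testing scale requires strictly positive intensities")
        values = np.log2(values)

    blocks = {c: values[s].to_numpy(dtype=float) for c, s in groups.items()}
    # group means are reported on the intensity scale regardless of the
    # testing scale, because the fold-change criterion is defined on means
    mean_blocks = {
        c: matrix.data[s].to_numpy(dtype=float).mean(axis=1) for c, s in groups.items()
    }

    p_case = _vector_t(blocks["control"], blocks["bc_pre"], config.t_variant)
    p_post = _vector_t(blocks["control"], blocks["bc_post"], config.t_variant)
    p_other = _vector_t(blocks["control"], blocks["other_cancer"], config.t_variant)

    rows = []
    for i, probe in enumerate(matrix.probe_ids):
        fc = fold_change(mean_blocks["bc_pre"][i], mean_blocks["control"][i])
        other_dir = (
            "up" if mean_blocks["other_cancer"][i] > mean_blocks["control"][i] else "down"
        )
        rows.append(
            {
                "mirna": probe,
                "mean_control": mean_blocks["control"][i],
                "mean_bc_pre": mean_blocks["bc_pre"][i],
                "mean_bc_post": mean_blocks["bc_post"][i],
                "mean_other": mean_blocks["other_cancer"][i],
                "direction": fc.direction,
                "fc_ratio": fc.fc_ratio,
                "log2_fc": fc.log2_fc,
                "fc_computable": fc.computable,
                "p_case": p_case[i],
                "p_post": p_post[i],
                "p_other": p_other[i],
                "other_direction": other_dir,
            }
        )
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


@dataclass
class CascadeReport:
    """Counts and candidate sets from the three cascade stages."""

    n_analyzed: int
    n_de: int
    n_normalizing: int
    n_nonspecific: int
    de_candidates: list[str]
    normalizing_candidates: list[str]
    final_candidates: list[str]

    def __post_init__(self) -> None:
        if not (self.n_de >= self.n_normalizing >= len(self.final_candidates)):
            raise ValueError("cascade counts must be non-increasing")
        if self.n_nonspecific != self.n_normalizing - len(self.final_candidates):
            raise ValueError("n_nonspecific must equal n_normalizing - |final|")

    def to_dict(self) -> dict:
        return {
            "n_analyzed": self.n_analyzed,
            "n_de": self.n_de,
            "n_normalizing": self.n_normalizing,
            "n_nonspecific": self.n_nonspecific,
            "de_candidates": list(self.de_candidates),
            "normalizing_candidates": list(self.normalizing_candidates),
            "final_candidates": list(self.final_candidates),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def apply_cascade(
    results: pd.DataFrame,
    config: ScreeningConfig | None = None,
) -> CascadeReport:
    """Run the three selection stages over a contrast-result table.

    Stage 1 keeps probes with ``p_case < alpha_de`` and a computable fold
    change >= ``fc_min``. Stage 2 keeps survivors with ``p_post`` strictly
    greater than ``alpha_norm``. Stage 3 drops survivors with ``p_other <
    alpha_spec`` in the same direction as the case/control change. A pure
    function of its inputs.
    """
    config = config or ScreeningConfig()
    if len(results) == 0:
        return CascadeReport(0, 0, 0, 0, [], [], [])

    fc_ok = results["fc_computable"].astype(bool) & (results["fc_ratio"] >= config.fc_min)
    de = (results["p_case"] < config.alpha_de) & fc_ok
    normalizing = de & (results["p_post"] > config.alpha_norm)
    nonspecific = (
        normalizing
        & (results["p_other"] < config.alpha_spec)
        & (results["other_direction"] == results["direction"])
    )
    final = normalizing & ~nonspecific

    return CascadeReport(
        n_analyzed=int(len(results)),
        n_de=int(de.sum()),
        n_normalizing=int(normalizing.sum()),
        n_nonspecific=int(nonspecific.sum()),
        de_candidates=results.loc[de, "mirna"].tolist(),
        normalizing_candidates=results.loc[normalizing, "mirna"].tolist(),
        final_candidates=results.loc[final, "mirna"].tolist(),
    )


def cohort_comparability(demographics: pd.DataFrame) -> dict:
    """Case/control comparability tests from a cohort-demographics table.

    Expects one row per cohort with columns ``cohort``, ``n``, ``age_mean``,
    ``age_sd``, ``n_african_american``, ``n_caucasian``. Returns the
    summary-statistic t-test on age and the Fisher exact test on race counts
    for control vs pre-resection cases.
    """
    rows = demographics.set_index("cohort")
    ctrl, case = rows.loc["control"], rows.loc["bc_pre"]
    t, df, p_age = t_from_summary(
        float(ctrl["age_mean"]), float(ctrl["age_sd"]), int(ctrl["n"]),
        float(case["age_mean"]), float(case["age_sd"]), int(case["n"]),
    )
    p_race = fisher_exact_2x2(
        int(ctrl["n_african_american"]), int(ctrl["n_caucasian"]),
        int(case["n_african_american"]), int(case["n_caucasian"]),
    )
    return {"age_t": t, "age_df": df, "age_p": p_age, "race_p": p_race}
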