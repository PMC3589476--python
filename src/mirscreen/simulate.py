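"""Synthetic plasma-miRNA array generator with planted effects and a truth table.

The generator emulates an Illumina-like miRNA oligoarray experiment over four
plasma cohorts (healthy controls, pre-resection breast cancer cases,
post-resection cases, other cancers) with the nuisance processes that make
circulating-miRNA screening hard:

* **additive background** plus Gaussian instrument noise, with raw
  intensities truncated at zero — after background subtraction, weak probes
  drop below zero and are censored by the detectability filter;
* a **low-abundance probe class** whose baseline sits near the background;
* a **blood-cell probe class** sharing a per-sample multiplicative factor
  (simulated blood-count variation) and, in hemolysis-event samples, an extra
  uniform elevation of up to ``hemolysis_max_fold`` (default 30);
* three **planted effect classes**: breast-cancer-specific markers that
  regress fully after resection, pan-cancer markers also shifted in the
  other-cancer cohort, and non-regressing markers still shifted
  post-resection.

Per-cell signal is log-normal: log2 intensity = probe baseline + cohort
effect + N(0, ``signal_log2_sd``). One root seed drives every draw through a
local :class:`numpy.random.Generator`; no global RNG state is touched.

:func:`simulate_study_pair` generates two studies whose per-probe true
pre-resection effects are drawn from a bivariate normal with a chosen
correlation, for exercising the reproducibility module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "SimConfig",
    "EFFECT_CLASSES",
    "simulate_dataset",
    "simulate_study_pair",
    "manifest_from_truth",
    "blood_list_from_truth",
]

EFFECT_CLASSES = (
    "null",
    "bc_specific_regressing",
    "pan_cancer",
    "non_regressing",
    "blood_cell",
    "low_abundance",
)


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the synthetic plasma-array experiment.

    Defaults mirror the screening study's design: 1145 probes over 70 samples
    (20/20/20/10 per cohort), 140 blood-cell probes, roughly 45% of probes at
    low abundance (matching the observed share of probes undetectable in more
    than 10% of samples), and hemolysis elevating blood-cell probes by up to
    30-fold. Intensity units are arbitrary; baselines put the typical
    detected probe in the hundreds-to-thousands range of the published group
    means.
    """

    n_probes: int = 1145
    n_control: int = 20
    n_bc_pre: int = 20
    n_bc_post: int = 20
    n_other: int = 10

    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    low_abundance_fraction: float = 0.45
    low_abundance_log2_mean: float = 2.0
    low_abundance_log2_sd: float = 1.0

    n_blood_cell: int = 140
    blood_log2_sd: float = 0.5
    hemolysis_prob: float = 0.1
    hemolysis_max_fold: float = 30.0

    n_bc_specific: int = 10
    n_pan_cancer: int = 10
    n_non_regressing: int = 10
    effect_log2_mean: float = 2.0
    effect_log2_sd: float = 0.5
    pair_effect_log2_sd: float = 1.0

    signal_log2_sd: float = 0.5
    noise_sd: float = 15.0
    background_level: float = 30.0

    def __post_init__(self) -> None:
        counts = (
            self.n_probes, self.n_control, self.n_bc_pre, self.n_bc_post,
            self.n_other, self.n_blood_cell, self.n_bc_specific,
            self.n_pan_cancer, self.n_non_regressing,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be non-negative")
        if self.n_control + self.n_bc_pre + self.n_bc_post + self.n_other == 0:
            raise ConfigError("cohort sizes sum to zero")
        if not 0 <= self.low_abundance_fraction <= 1:
            raise ConfigError("low_abundance_fraction must lie in [0, 1]")
        if not 0 <= self.hemolysis_prob <= 1:
            raise ConfigError("hemolysis_prob must lie in [0, 1]")
        if self.hemolysis_max_fold < 1:
            raise ConfigError("hemolysis_max_fold must be >= 1")
        n_special = (
            self.n_blood_cell + self.n_bc_specific + self.n_pan_cancer
            + self.n_non_regressing
        )
        if n_special > self.n_probes:
            raise ConfigError(
                f"special probe classes ({n_special}) exceed n_probes ({self.n_probes})"
            )

    def cohort_layout(self) -> list[tuple[str, int]]:
        return [
            ("control", self.n_control),
            ("bc_pre", self.n_bc_pre),
            ("bc_post", self.n_bc_post),
            ("other_cancer", self.n_other),
        ]


# cohort demographics used for the synthetic sample sheet (age mean/sd and
# African-American fraction per cohort, loosely matching the study population)
_DEMOGRAPHICS = {
    "control": (54.9, 9.1, 0.20),
    "bc_pre": (53.7, 9.9, 0.10),
    "bc_post": (58.8, 9.7, 0.25),
    "other_cancer": (64.2, 5.5, 0.40),
}


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each probe a disjoint class label and per-cohort log2 effects."""
    n = config.n_probes
    labels = np.full(n, "null", dtype=object)
    order = rng.permutation(n)
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        sel = order[pos:pos + k]
        pos += k
        return sel

    blood = take(config.n_blood_cell)
    bc_specific = take(config.n_bc_specific)
    pan_cancer = take(config.n_pan_cancer)
    non_regressing = take(config.n_non_regressing)
    labels[blood] = "blood_cell"
    labels[bc_specific] = "bc_specific_regressing"
    labels[pan_cancer] = "pan_cancer"
    labels[non_regressing] = "non_regressing"

    # low-abundance probes are drawn from the remaining (null) pool so the
    # class sets stay disjoint and planted effects stay detectable
    remaining = order[pos:]
    n_low = min(int(round(config.low_abundance_fraction * n)), remaining.size)
    labels[remaining[:n_low]] = "low_abundance"

    eff = pd.DataFrame(
        0.0,
        index=range(n),
        columns=["eff_bc_pre", "eff_bc_post", "eff_other"],
    )
    for idx in (bc_specific, pan_cancer, non_regressing):
        if idx.size:
            magnitude = rng.normal(config.effect_log2_mean, config.effect_log2_sd, idx.size)
            magnitude = np.abs(magnitude)
            sign = rng.choice([-1.0, 1.0], size=idx.size)
            eff.loc[idx, "eff_bc_pre"] = sign * magnitude
    # regression structure: bc-specific markers return fully to baseline after
    # resection; non-regressing markers keep their pre-resection shift;
    # pan-cancer markers are equally shifted in the other-cancer cohort
    eff.loc[non_regressing, "eff_bc_post"] = eff.loc[non_regressing, "eff_bc_pre"]
    eff.loc[pan_cancer, "eff_other"] = eff.loc[pan_cancer, "eff_bc_pre"]

    eff["class"] = labels
    return eff


def _probe_ids(n: int) -> list[str]:
    return [f"P{i+1:04d}" for i in range(n)]


def _mirna_names(classes: Sequence[str]) -> list[str]:
    counters: dict[str, int] = {}
    names = []
    for cls in classes:
        tag = "bld" if cls == "blood_cell" else "sim"
        counters[tag] = counters.get(tag, 0) + 1
        names.append(f"mir-{tag}-{counters[tag]}")
    return names


def _sample_sheet(config: SimConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    i = 0
    for cohort, size in config.cohort_layout():
        age_mean, age_sd, aa_frac = _DEMOGRAPHICS[cohort]
        for _ in range(size):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:03d}",
                    "cohort": cohort,
                    "age": int(np.clip(round(rng.normal(age_mean, age_sd)), 30, 90)),
                    "race": "african_american" if rng.random() < aa_frac else "caucasian",
                }
            )
    return SampleSheet(frame=pd.DataFrame(rows))


def simulate_dataset(
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet, pd.DataFrame]:
    """Simulate one plasma-array study.

    Returns ``(matrix, sheet, truth)`` where ``matrix`` is the raw
    probes × samples intensity table, ``sheet`` the cohort labels, and
    ``truth`` the per-probe class label, miRNA name, and true per-cohort log2
    effects. Bit-reproducible given ``(config, seed)``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    truth = _assign_classes(config, rng)
    return _realize_study(config, rng, truth)


def _realize_study(
    config: SimConfig,
    rng: np.random.Generator,
    truth: pd.DataFrame,
    baselines: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, SampleSheet, pd.DataFrame]:
    n = config.n_probes
    truth = truth.copy()
    if baselines is None:
        baselines = np.where(
            truth["class"] == "low_abundance",
            rng.normal(config.low_abundance_log2_mean, config.low_abundance_log2_sd, n),
            rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n),
        )
    truth["baseline_log2"] = baselines

    sheet = _sample_sheet(config, rng)
    cohorts = sheet.frame["cohort"].to_numpy()
    n_samples = len(cohorts)

    eff_by_cohort = {
        "control": np.zeros(n),
        "bc_pre": truth["eff_bc_pre"].to_numpy(),
        "bc_post": truth["eff_bc_post"].to_numpy(),
        "other_cancer": truth["eff_other"].to_numpy(),
    }
    log2_signal = (
        baselines[:, None]
        + np.column_stack([eff_by_cohort[c] for c in cohorts])
        + rng.normal(0.0, config.signal_log2_sd, size=(n, n_samples))
    )
    signal = np.exp2(log2_signal)

    is_blood = (truth["class"] == "blood_cell").to_numpy()
    blood_mult = np.exp2(rng.normal(0.0, config.blood_log2_sd, n_samples))
    hemolysis = rng.random(n_samples) < config.hemolysis_prob
    hemo_mult = np.where(
        hemolysis, rng.uniform(1.0, config.hemolysis_max_fold, n_samples), 1.0
    )
    signal[is_blood, :] *= (blood_mult * hemo_mult)[None, :]

    raw = np.maximum(
        0.0,
        config.background_level + signal + rng.normal(0.0, config.noise_sd, (n, n_samples)),
    )

    probe_ids = _probe_ids(n)
    truth.insert(0, "probe_id", probe_ids)
    truth.insert(1, "mirna_name", _mirna_names(truth["class"]))
    truth = truth[
        ["probe_id", "mirna_name", "class", "eff_bc_pre", "eff_bc_post", "eff_other",
         "baseline_log2"]
    ]
    matrix = ExpressionMatrix(
        data=pd.DataFrame(raw, index=probe_ids, columns=sheet.sample_ids), stage="raw"
    )
    return matrix, sheet, truth.reset_index(drop=True)


def simulate_study_pair(
    config: SimConfig | None = None,
    rho: float = 0.0,
    seed: int = 0,
) -> tuple[
    tuple[ExpressionMatrix, SampleSheet, pd.DataFrame],
    tuple[ExpressionMatrix, SampleSheet, pd.DataFrame],
]:
    """Simulate two studies with correlated true pre-resection effects.

    The studies share probe ids, probe classes, and baseline abundances (the
    same array measuring the same biology); per-probe true log2 effects for
    the pre-resection contrast are drawn, for every non-blood probe, from a
    bivariate normal with standard deviation ``pair_effect_log2_sd`` and
    correlation ``rho``. All nuisance processes (sampling noise, blood-count
    variation, hemolysis events) are drawn independently per study.
    """
    config = config or SimConfig()
    if not -1.0 <= rho <= 1.0:
        raise ConfigError(f"inter-study effect correlation must lie in [-1, 1], got {rho}")
    rng = np.random.default_rng(seed)

    base_truth = _assign_classes(config, rng)
    n = config.n_probes
    baselines = np.where(
        base_truth["class"] == "low_abundance",
        rng.normal(config.low_abundance_log2_mean, config.low_abundance_log2_sd, n),
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n),
    )

    cov = config.pair_effect_log2_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    effects = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    plantable = (base_truth["class"] != "blood_cell").to_numpy()
    effects[~plantable, :] = 0.0

    studies = []
    for k in range(2):
        truth = base_truth.copy()
        truth["eff_bc_pre"] = np.where(plantable, effects[:, k], 0.0)
        truth["eff_bc_post"] = 0.0
        truth["eff_other"] = 0.0
        studies.append(_realize_study(config, rng, truth, baselines=baselines))
    return studies[0], studies[1]


def manifest_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Probe manifest (probe id -> miRNA name) for a simulated study."""
    return truth[["probe_id", "mirna_name"]].copy()


def blood_list_from_truth(truth: pd.DataFrame) -> list[str]:
    """The simulated blood-compartment miRNA names (Filter 1 input)."""
    return truth.loc[truth["class"] == "blood_cell", "mirna_name"].tolist()
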