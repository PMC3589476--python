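"""Pre-designated probe filters and the low-abundance rescue partition.

The screening design removes two probe classes before any testing:

* **Filter 1** — probes whose miRNA is on a published list of species
  predominantly derived from the cellular blood compartment (confounded in
  plasma by blood counts and hemolysis);
* **Filter 2** — low-abundance probes, undetectable (background-subtracted
  value <= 0) in more than a set fraction of samples (default 10%).

Filters run in that order and each returns a :class:`FilterReport` so the
probe bookkeeping (e.g. 1145 → 1008 → 522) is always reconstructible.

:func:`rescue_low_abundance` revisits the probes Filter 2 discarded and
partitions them into three buckets — mostly-negative (``neg75``), low
positive mean (``low_mean``), and ``evaluable`` — then runs the standard
case/control t-test on the evaluable ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleSheet, normalize_mirna_name
from .preprocess import DetectabilityMask
from .screening import two_sample_t

__all__ = [
    "FilterReport",
    "RescueReport",
    "blood_cell_filter",
    "low_abundance_filter",
    "rescue_low_abundance",
]


@dataclass
class FilterReport:
    """Conserved bookkeeping for one filter pass."""

    name: str
    probes_in: int
    probes_removed: list[str]
    probes_kept: list[str]

    def __post_init__(self) -> None:
        if len(self.probes_removed) + len(self.probes_kept) != self.probes_in:
            raise ValueError("filter report does not conserve probes")
        if set(self.probes_removed) & set(self.probes_kept):
            raise ValueError("removed and kept probe sets overlap")

    @property
    def n_removed(self) -> int:
        return len(self.probes_removed)

    @property
    def n_kept(self) -> int:
        return len(self.probes_kept)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "probes_in": self.probes_in,
            "n_removed": self.n_removed,
            "n_kept": self.n_kept,
            "probes_removed": list(self.probes_removed),
            "probes_kept": list(self.probes_kept),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


@dataclass
class RescueReport:
    """Partition of low-abundance probes and the DE tally among evaluable ones."""

    buckets: dict[str, str]  # probe id -> {"neg75", "low_mean", "evaluable"}
    significant: list[str]
    alpha: float

    @property
    def n_neg75(self) -> int:
        return sum(1 for b in self.buckets.values() if b == "neg75")

    @property
    def n_low_mean(self) -> int:
        return sum(1 for b in self.buckets.values() if b == "low_mean")

    @property
    def n_evaluable(self) -> int:
        return sum(1 for b in self.buckets.values() if b == "evaluable")

    @property
    def n_significant(self) -> int:
        return len(self.significant)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_neg75": self.n_neg75,
            "n_low_mean": self.n_low_mean,
            "n_evaluable": self.n_evaluable,
            "n_significant": self.n_significant,
            "significant": list(self.significant),
            "buckets": dict(self.buckets),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def blood_cell_filter(
    matrix: ExpressionMatrix,
    manifest: pd.DataFrame,
    blood_list: Sequence[str],
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove every probe whose miRNA name is on the blood-compartment list.

    ``manifest`` maps probe ids to canonical miRNA names (several probes may
    share a name; a probe absent from the manifest is its own name). A list
    name matching zero probes removes nothing; a name matching k probes
    removes all k. Starred and unstarred names are distinct, so listing
    ``mir-16`` does not remove a ``mir-16*`` probe.
    """
    if manifest is None or len(manifest) == 0:
        raise ValueError("probe manifest is empty")
    blood = {normalize_mirna_name(n) for n in blood_list}
    name_of = dict(zip(manifest["probe_id"], manifest["mirna_name"]))
    removed = [p for p in matrix.probe_ids if name_of.get(p, p) in blood]
    kept = [p for p in matrix.probe_ids if name_of.get(p, p) not in blood]
    report = FilterReport(
        name="blood_cell_filter",
        probes_in=matrix.n_probes,
        probes_removed=removed,
        probes_kept=kept,
    )
    return matrix.subset_probes(kept), report


def low_abundance_filter(
    matrix: ExpressionMatrix,
    mask: DetectabilityMask,
    max_undetectable: int | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove probes undetectable in more than ``max_undetectable`` samples.

    Detectability is judged on the background-subtracted scale via ``mask``
    (computed upstream with :func:`mirscreen.preprocess.detect_mask`), even
    when ``matrix`` itself is quantile-normalized. The default threshold is
    ``floor(0.10 * n_samples)`` — with 70 samples that is N = 7, and a probe
    is removed iff it is undetected in strictly more than N samples.
    """
    if list(mask.columns) != matrix.sample_ids:
        raise ValueError("detectability mask samples do not match matrix")
    missing = set(matrix.probe_ids) - set(mask.index)
    if missing:
        raise ValueError(f"detectability mask missing probes: {sorted(missing)[:5]}...")
    if max_undetectable is None:
        max_undetectable = math.floor(0.10 * matrix.n_samples)
    aligned = mask.loc[matrix.probe_ids]
    undetected = (~aligned).sum(axis=1)
    removed = [p for p in matrix.probe_ids if undetected[p] > max_undetectable]
    kept = [p for p in matrix.probe_ids if undetected[p] <= max_undetectable]
    report = FilterReport(
        name="low_abundance_filter",
        probes_in=matrix.n_probes,
        probes_removed=removed,
        probes_kept=kept,
    )
    return matrix.subset_probes(kept), report


def rescue_low_abundance(
    filtered_matrix: ExpressionMatrix,
    sheet: SampleSheet,
    mean_floor: float = 100.0,
    neg_fraction: float = 0.75,
    alpha: float = 0.05,
) -> RescueReport:
    """Partition the probes Filter 2 removed and test the evaluable ones.

    Buckets are assigned sequentially, and a probe lands in the first one it
    qualifies for:

    * ``neg75`` — value < 0 in strictly more than ``neg_fraction`` of control
      samples AND of pre-resection case samples;
    * ``low_mean`` — mean over strictly positive values (across control and
      pre-resection samples) <= ``mean_floor`` (probes with no positive value
      at all land here too);
    * ``evaluable`` — everything else; tested control vs pre-resection with
      the standard pooled t-test at ``alpha``.
    """
    controls = sheet.samples_in("control")
    cases = sheet.samples_in("bc_pre")
    if not controls or not cases:
        raise ValueError("sample sheet must contain control and bc_pre samples")

    buckets: dict[str, str] = {}
    significant: list[str] = []
    data = filtered_matrix.data
    for probe in filtered_matrix.probe_ids:
        ctrl = data.loc[probe, controls].to_numpy(dtype=float)
        case = data.loc[probe, cases].to_numpy(dtype=float)
        if (
            np.mean(ctrl < 0) > neg_fraction
            and np.mean(case < 0) > neg_fraction
        ):
            buckets[probe] = "neg75"
            continue
        both = np.concatenate([ctrl, case])
        positive = both[both > 0]
        if positive.size == 0 or positive.mean() <= mean_floor:
            buckets[probe] = "low_mean"
            continue
        buckets[probe] = "evaluable"
        _, _, p = two_sample_t(ctrl, case, variant="pooled")
        if p < alpha:
            significant.append(probe)

    return RescueReport(buckets=buckets, significant=significant, alpha=alpha)
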