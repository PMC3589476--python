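"""Cross-study harmonization: consensus vote-counting and the qPCR composite.

Published candidate lists are harmonized as simple directional fold changes
(up or down in cancer; magnitudes are carried for display only). Two
meta-analytic read-outs are computed:

* :func:`classify_overlaps` — among miRNAs reported by at least two studies,
  which have unanimous direction (*consistent*) and which contradictory
  directions (*inconsistent*); the concordance rate divides the consistent
  count by the pooled number of candidates all studies reported (an explicit
  input, because published overlap tables usually print only the overlapping
  subset of each list).
* :func:`qpcr_composite` — deduplicate a multi-study candidate list into
  unique miRNAs with resolved direction, and find the subset corroborated by
  two or more distinct study groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ConsensusReport",
    "QpcrComposite",
    "classify_overlaps",
    "qpcr_composite",
    "render_consensus_markdown",
]


@dataclass
class ConsensusReport:
    """Cross-study direction-concordance classification."""

    directions: dict[str, dict[str, str]]  # overlapping miRNA -> {study: direction}
    consistent: list[str]
    inconsistent: list[str]
    singleton_count: int
    total_candidates: int
    max_studies_per_mirna: int

    def __post_init__(self) -> None:
        if set(self.consistent) & set(self.inconsistent):
            raise ValueError("consistent and inconsistent sets overlap")
        if set(self.consistent) | set(self.inconsistent) != set(self.directions):
            raise ValueError("every overlapping miRNA must be classified exactly once")

    @property
    def n_overlapping(self) -> int:
        return len(self.directions)

    @property
    def concordance_pct(self) -> float:
        return 100.0 * len(self.consistent) / self.total_candidates

    @property
    def inconsistency_pct(self) -> float:
        return 100.0 * len(self.inconsistent) / self.total_candidates

    def to_dict(self) -> dict:
        return {
            "n_overlapping": self.n_overlapping,
            "consistent": sorted(self.consistent),
            "inconsistent": sorted(self.inconsistent),
            "singleton_count": self.singleton_count,
            "total_candidates": self.total_candidates,
            "concordance_pct": self.concordance_pct,
            "inconsistency_pct": self.inconsistency_pct,
            "max_studies_per_mirna": self.max_studies_per_mirna,
            "directions": {m: dict(d) for m, d in self.directions.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def classify_overlaps(
    candidates: pd.DataFrame,
    totals: Mapping[str, int],
) -> ConsensusReport:
    """Classify miRNAs reported by >= 2 studies as consistent or inconsistent.

    ``candidates`` is a harmonized candidate list (columns ``study``,
    ``mirna``, ``direction``) that needs to contain at least the overlapping
    rows; ``totals`` gives each study's full candidate-list size and is the
    concordance denominator. Consistency requires unanimity across all
    reporting studies (relevant when a miRNA appears in three or more).
    Duplicate (study, miRNA) rows with conflicting directions are an input
    error; agreeing duplicates collapse.
    """
    if len(set(candidates["study"])) < 2:
        raise ValueError("need candidate lists from at least two studies")
    missing = set(candidates["study"]) - set(totals)
    if missing:
        raise ValueError(f"totals missing studies: {sorted(missing)}")

    directions: dict[str, dict[str, str]] = {}
    for (study, mirna), grp in candidates.groupby(["study", "mirna"], sort=False):
        dirs = set(grp["direction"])
        if len(dirs) > 1:
            raise ValueError(
                f"conflicting directions for ({study}, {mirna}): {sorted(dirs)}"
            )
        directions.setdefault(mirna, {})[study] = next(iter(dirs))

    overlapping = {m: d for m, d in directions.items() if len(d) >= 2}
    singleton_count = sum(1 for d in directions.values() if len(d) == 1)
    consistent = [m for m, d in overlapping.items() if len(set(d.values())) == 1]
    inconsistent = [m for m in overlapping if m not in set(consistent)]

    return ConsensusReport(
        directions=overlapping,
        consistent=consistent,
        inconsistent=inconsistent,
        singleton_count=singleton_count,
        total_candidates=int(sum(totals.values())),
        max_studies_per_mirna=max((len(d) for d in directions.values()), default=0),
    )


@dataclass
class QpcrComposite:
    """Deduplicated composite of qPCR candidate reports."""

    directions: dict[str, str]  # unique miRNA -> resolved direction
    conflicted: list[str]  # unanimity failed; excluded from the up/down tally
    corroborated: list[str]  # same direction from >= 2 distinct studies

    @property
    def n_unique(self) -> int:
        return len(self.directions) + len(self.conflicted)

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.directions.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.directions.values() if d == "down")

    def to_dict(self) -> dict:
        return {
            "n_unique": self.n_unique,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "directions": dict(self.directions),
            "conflicted": sorted(self.conflicted),
            "corroborated": sorted(self.corroborated),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def qpcr_composite(candidates: pd.DataFrame) -> QpcrComposite:
    """Deduplicate a candidate list into unique miRNAs with resolved direction.

    Direction is resolved by unanimity; conflicted miRNAs are flagged and
    excluded from the up/down tally. The corroborated set contains miRNAs
    reported with the same direction by at least two distinct studies.
    """
    directions: dict[str, str] = {}
    conflicted: list[str] = []
    corroborated: list[str] = []
    for mirna, grp in candidates.groupby("mirna", sort=False):
        dirs = set(grp["direction"])
        if len(dirs) > 1:
            conflicted.append(mirna)
            continue
        directions[mirna] = next(iter(dirs))
        if grp["study"].nunique() >= 2:
            corroborated.append(mirna)
    return QpcrComposite(
        directions=directions, conflicted=conflicted, corroborated=corroborated
    )


def render_consensus_markdown(
    report: ConsensusReport,
    magnitudes: pd.DataFrame | None = None,
) -> str:
    """Render the overlap classification as a markdown table.

    ``magnitudes`` (optional) is a candidate list with ``fold_change`` used
    for display only.
    """
    studies = sorted({s for d in report.directions.values() for s in d})
    mag: dict[tuple[str, str], float] = {}
    if magnitudes is not None and "fold_change" in magnitudes.columns:
        for _, row in magnitudes.iterrows():
            if pd.notna(row["fold_change"]):
                mag[(row["study"], row["mirna"])] = float(row["fold_change"])

    def cell(mirna: str, study: str) -> str:
        d = report.directions[mirna].get(study)
        if d is None:
            return ""
        m = mag.get((study, mirna))
        return f"{m:g} {d}" if m is not None else d

    lines = ["| miRNA | " + " | ".join(studies) + " |",
             "|---" * (len(studies) + 1) + "|"]
    for title, names in (("consistent", report.consistent),
                         ("inconsistent", report.inconsistent)):
        lines.append(f"| **{title}** |" + " |" * len(studies))
        for mirna in sorted(names):
            lines.append(
                "| " + mirna + " | " + " | ".join(cell(mirna, s) for s in studies) + " |"
            )
    lines.append("")
    lines.append(
        f"Concordance: {len(report.consistent)}/{report.total_candidates} "
        f"= {report.concordance_pct:.1f}%"
    )
    return "\n".join(lines)
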