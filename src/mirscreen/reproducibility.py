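"""Two-level reproducibility testing between a pair of array studies.

Given per-probe differential-expression summaries (log2 fold change and
unadjusted p) from two independent case/control studies on the same platform,
reproducibility is assessed at two levels:

* **global** — the Pearson correlation of log2 fold changes over all
  name-matched probes (:func:`global_fc_correlation`), with its p-value from
  the t transform on n-2 degrees of freedom;
* **outlier** — each study's top candidates (p < alpha with at least a
  ``fc_min``-fold change) are looked up in the other study's table and
  checked for significance and direction concordance
  (:func:`cross_evaluate`), plus a pooled correlation over the concatenated
  top lists (:func:`pooled_top_correlation`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "OverlapReport",
    "make_study_de",
    "study_de_from_contrasts",
    "pearson_with_p",
    "global_fc_correlation",
    "pooled_top_correlation",
    "select_top",
    "cross_evaluate",
]


@dataclass
class CorrelationReport:
    """Pearson correlation with its two-sided p-value."""

    n: int
    pearson_r: float
    p: float
    n_duplicate_names: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "p": self.p,
            "n_duplicate_names": self.n_duplicate_names,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


@dataclass
class OverlapReport:
    """Cross-evaluation of one study's top candidates in the other study."""

    top_list_id: str
    entries: pd.DataFrame  # mirna, log2_fc_own, p_own, log2_fc_other, p_other,
    #                        significant_in_other, direction_concordant
    unmatched: list[str]
    alpha: float

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_significant_in_other(self) -> int:
        return int(self.entries["significant_in_other"].sum())

    @property
    def n_direction_concordant(self) -> int:
        return int(self.entries["direction_concordant"].sum())

    def significant_entries(self) -> pd.DataFrame:
        return self.entries[self.entries["significant_in_other"]]

    def to_dict(self) -> dict:
        return {
            "top_list_id": self.top_list_id,
            "alpha": self.alpha,
            "n_entries": self.n_entries,
            "n_significant_in_other": self.n_significant_in_other,
            "n_direction_concordant": self.n_direction_concordant,
            "unmatched": list(self.unmatched),
            "entries": self.entries.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def make_study_de(
    names: Sequence[str], log2_fc: Sequence[float], p: Sequence[float], study_id: str
) -> pd.DataFrame:
    """Assemble a per-study DE table (one row per canonical name)."""
    frame = pd.DataFrame(
        {"mirna": list(names), "log2_fc": list(log2_fc), "p": list(p)}
    )
    if frame["mirna"].duplicated().any():
        dups = frame.loc[frame["mirna"].duplicated(), "mirna"].tolist()
        raise ValueError(f"duplicate names in study DE table: {dups}")
    frame["study"] = study_id
    return frame


def study_de_from_contrasts(contrasts: pd.DataFrame, study_id: str) -> pd.DataFrame:
    """Extract a study DE table from a screening contrast-result table."""
    return make_study_de(
        contrasts["mirna"], contrasts["log2_fc"], contrasts["p_case"], study_id
    )


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Sample Pearson correlation with its two-sided p (t on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("coordinates must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a coordinate")
    res = stats.pearsonr(x, y)
    return CorrelationReport(n=int(x.size), pearson_r=float(res.statistic),
                             p=float(res.pvalue))


def global_fc_correlation(
    study_a: pd.DataFrame, study_b: pd.DataFrame
) -> CorrelationReport:
    """Correlate log2 fold changes over all name-matched probes of two studies."""
    joined = study_a.merge(study_b, on="mirna", suffixes=("_a", "_b"))
    joined = joined.dropna(subset=["log2_fc_a", "log2_fc_b"])
    return pearson_with_p(joined["log2_fc_a"], joined["log2_fc_b"])


def pooled_top_correlation(pairs: pd.DataFrame) -> CorrelationReport:
    """Correlation over concatenated top-candidate fold-change pairs.

    ``pairs`` has columns ``mirna``, ``log2_fc_a``, ``log2_fc_b`` — the
    union (with duplicates kept, row-wise) of both studies' top lists with
    both studies' fold changes. Duplicated names are counted and flagged in
    the report, not collapsed.
    """
    report = pearson_with_p(pairs["log2_fc_a"], pairs["log2_fc_b"])
    report.n_duplicate_names = int(pairs["mirna"].duplicated().sum())
    return report


def select_top(study: pd.DataFrame, alpha: float = 0.05, fc_min: float = 2.0) -> pd.DataFrame:
    """Top candidates: p strictly below ``alpha`` and |log2 FC| >= log2(fc_min).

    A p-value exactly equal to ``alpha`` does not pass.
    """
    keep = (study["p"] < alpha) & (study["log2_fc"].abs() >= math.log2(fc_min))
    return study[keep.fillna(False)].reset_index(drop=True)


def cross_evaluate(
    top: pd.DataFrame,
    other: pd.DataFrame,
    alpha: float = 0.05,
    top_list_id: str = "top",
) -> OverlapReport:
    """Evaluate one study's top candidates in the other study's DE table.

    Per entry: *significant in other* iff the other study's p is strictly
    below ``alpha``; *direction concordant* iff the two log2 fold changes
    have the same (nonzero) sign. Names absent from the other study are
    reported in ``unmatched``, never dropped silently.
    """
    if len(top) == 0:
        empty = pd.DataFrame(
            columns=[
                "mirna", "log2_fc_own", "p_own", "log2_fc_other", "p_other",
                "significant_in_other", "direction_concordant",
            ]
        )
        return OverlapReport(top_list_id=top_list_id, entries=empty, unmatched=[],
                             alpha=alpha)
    other_idx = other.set_index("mirna")
    if other_idx.index.has_duplicates:
        raise ValueError("other study's DE table has duplicate names")
    rows, unmatched = [], []
    for _, entry in top.iterrows():
        name = entry["mirna"]
        if name not in other_idx.index:
            unmatched.append(name)
            continue
        o = other_idx.loc[name]
        fc_own, fc_other = float(entry["log2_fc"]), float(o["log2_fc"])
        rows.append(
            {
                "mirna": name,
                "log2_fc_own": fc_own,
                "p_own": float(entry["p"]),
                "log2_fc_other": fc_other,
                "p_other": float(o["p"]),
                "significant_in_other": bool(o["p"] < alpha),
                "direction_concordant": bool(np.sign(fc_own) * np.sign(fc_other) > 0),
            }
        )
    entries = pd.DataFrame(rows)
    return OverlapReport(top_list_id=top_list_id, entries=entries,
                         unmatched=unmatched, alpha=alpha)
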