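"""Loaders for the packaged worked-example tables.

These small CSV transcriptions of published summary tables let every
meta-analytic operation be exercised without any external download: the qPCR
candidate composite, the five-study genome-wide overlap table with per-study
candidate totals, the cohort demographics, the 46-probe contrast table the
cascade runs on, and the two cross-study top-candidate comparison tables.

Censored p-values printed as ``<bound`` are parsed as their upper bound; at
every threshold the pipeline applies, the bound and the true value fall on
the same side.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import normalize_mirna_name, read_candidate_csv, read_blood_list
from .screening import fold_change

__all__ = [
    "load_qpcr_candidates",
    "load_genomewide_overlaps",
    "load_genomewide_totals",
    "load_cohort_demographics",
    "load_top46_contrasts",
    "load_crosscheck_tables",
    "load_default_blood_list",
]


def _data_path(name: str):
    return resources.files("mirscreen.data").joinpath(name)


def load_qpcr_candidates() -> pd.DataFrame:
    """The 19 qPCR candidate reports (study, miRNA, direction, magnitude)."""
    with resources.as_file(_data_path("qpcr_candidates.csv")) as path:
        return read_candidate_csv(path)


def load_genomewide_overlaps() -> pd.DataFrame:
    """Directional calls for the 16 miRNAs overlapping >= 2 genome-wide studies."""
    with resources.as_file(_data_path("genomewide_overlaps.csv")) as path:
        return read_candidate_csv(path)


def load_genomewide_totals() -> tuple[dict[str, int], pd.DataFrame]:
    """Per-study candidate totals plus full study metadata."""
    with resources.as_file(_data_path("genomewide_studies.csv")) as path:
        meta = pd.read_csv(path, comment="#")
    totals = dict(zip(meta["study"], meta["n_candidates"].astype(int)))
    return totals, meta


def load_cohort_demographics() -> pd.DataFrame:
    """Cohort-level age and race summary of the study population."""
    with resources.as_file(_data_path("cohort_demographics.csv")) as path:
        return pd.read_csv(path, comment="#")


def _parse_p(token) -> float:
    s = str(token).strip()
    if s.startswith("<"):
        return float(s[1:])
    return float(s)


def load_top46_contrasts() -> pd.DataFrame:
    """The 46-probe contrast table in the layout :func:`apply_cascade` expects.

    Group means and p-values are transcribed; direction, fold-change ratio,
    and signed log2 fold change are recomputed from the printed means with
    the case-over-control convention.
    """
    with resources.as_file(_data_path("top46_contrasts.csv")) as path:
        raw = pd.read_csv(path, comment="#")
    rows = []
    for _, r in raw.iterrows():
        fc = fold_change(float(r["mean_bc_pre"]), float(r["mean_control"]))
        rows.append(
            {
                "mirna": normalize_mirna_name(r["mirna"]),
                "mean_control": float(r["mean_control"]),
                "mean_bc_pre": float(r["mean_bc_pre"]),
                "mean_bc_post": float(r["mean_bc_post"]),
                "mean_other": float(r["mean_other"]),
                "direction": fc.direction,
                "fc_ratio": fc.fc_ratio,
                "log2_fc": fc.log2_fc,
                "fc_computable": fc.computable,
                "p_case": _parse_p(r["p_case"]),
                "p_post": _parse_p(r["p_post"]),
                "p_other": _parse_p(r["p_other"]),
                "other_direction": "up"
                if float(r["mean_other"]) > float(r["mean_control"])
                else "down",
            }
        )
    return pd.DataFrame(rows)


def load_crosscheck_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two top-candidate cross-evaluation tables.

    Returns ``(top46, top26)`` with harmonized columns ``mirna``,
    ``log2_fc_current``, ``p_current``, ``log2_fc_zhao``, ``p_zhao``; names
    canonicalized. ``top46`` lists the screening study's own top candidates,
    ``top26`` the comparison study's.
    """
    with resources.as_file(_data_path("top46_crosscheck.csv")) as path:
        top46 = pd.read_csv(path, comment="#")
    with resources.as_file(_data_path("zhao_top26_crosscheck.csv")) as path:
        top26 = pd.read_csv(path, comment="#")
    top46["mirna"] = top46["mirna"].map(normalize_mirna_name)
    top26["mirna"] = top26["mirna"].map(normalize_mirna_name)
    top26 = top26[["mirna", "log2_fc_current", "p_current", "log2_fc_zhao", "p_zhao"]]
    return top46, top26


def load_default_blood_list() -> list[str]:
    """The editable default blood-compartment miRNA list (a placeholder, not
    the full published 140-entry list)."""
    with resources.as_file(_data_path("blood_cell_mirnas.txt")) as path:
        return read_blood_list(path)
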