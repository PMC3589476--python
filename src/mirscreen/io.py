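"""Domain types, miRNA name normalization, and tabular readers/writers.

Everything downstream of this module speaks three in-memory containers:

* :class:`ExpressionMatrix` — a probes × samples intensity table carrying a
  processing-stage tag (``raw`` → ``bg_subtracted`` → ``normalized``),
* :class:`SampleSheet` — per-sample cohort labels plus demographics,
* plain :class:`pandas.DataFrame` objects for probe manifests and published
  candidate lists.

miRNA names arrive in many spellings (``hsa-miR-21``, ``miR-21``, ``let7a``);
:func:`normalize_mirna_name` maps them all onto one canonical form so that
tables from different studies can be joined by name.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "COHORTS",
    "InvalidNameError",
    "FormatError",
    "ExpressionMatrix",
    "SampleSheet",
    "normalize_mirna_name",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_candidate_csv",
    "read_blood_list",
]

STAGES = ("raw", "bg_subtracted", "normalized")
COHORTS = ("control", "bc_pre", "bc_post", "other_cancer")


class InvalidNameError(ValueError):
    """Raised for empty or unusable miRNA name strings."""


class FormatError(ValueError):
    """Raised for malformed tabular input; the message names the offender."""


# --------------------------------------------------------------------------
# miRNA name normalization
# --------------------------------------------------------------------------

# species prefix (hsa-, mmu-, ...) then a mir/let stem, optionally hyphenated,
# followed by the numeric family id and any suffixes (arm, star, letter).
_MIRNA_RE = re.compile(r"^(?:[a-z]{3}-)?(mir|let)-?([0-9].*)$", re.IGNORECASE)


def normalize_mirna_name(raw_name: str) -> str:
    """Map a miRNA name onto its canonical form.

    The canonical form is ``mir-<id>`` / ``let-<id>``: species prefix
    stripped, stem lower-cased, a hyphen between stem and family id, and
    star/arm suffixes (``*``, ``-5p``, ``-3p``) preserved verbatim —
    ``mir-92b*`` and ``mir-92b`` are distinct identities.

    Identifiers that do not look like miRNA names (proprietary probe ids such
    as ``HS_303_b`` or ``solexa-9655-85``, or ``U6``) pass through unchanged
    and act as their own canonical names.

    Idempotent: a canonical name normalizes to itself.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise InvalidNameError("miRNA name must be a non-empty string")
    name = raw_name.strip()
    m = _MIRNA_RE.match(name)
    if m is None:
        return name
    stem, rest = m.group(1).lower(), m.group(2).lower()
    return f"{stem}-{rest}"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A probes × samples intensity table with a processing-stage tag.

    ``data`` is indexed by probe id (rows) and sample id (columns). Values
    are arbitrary intensity units; they may be negative after background
    subtraction. ``stage='raw'`` requires all values >= 0.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if not np.issubdtype(self.data.to_numpy().dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.stage == "raw" and self.data.size and float(self.data.min().min()) < 0:
            raise ValueError("stage='raw' requires non-negative intensities")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_stage(self, data: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix with the same layout and a new stage tag."""
        return ExpressionMatrix(data=data, stage=stage)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(data=self.data.loc[list(probe_ids)], stage=self.stage)


@dataclass
class SampleSheet:
    """Per-sample cohort labels plus optional demographics.

    ``frame`` must have columns ``sample_id`` and ``cohort`` (one of
    ``control``, ``bc_pre``, ``bc_post``, ``other_cancer``); ``age``,
    ``race`` and clinical fields are optional.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample_id", "cohort"} - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample ids: {dups.tolist()}")
        bad = set(self.frame["cohort"]) - set(COHORTS)
        if bad:
            raise FormatError(f"unknown cohort labels: {sorted(bad)}; expected {COHORTS}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_in(self, cohort: str) -> list[str]:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        sel = self.frame["cohort"] == cohort
        return list(self.frame.loc[sel, "sample_id"])

    def cohort_sizes(self) -> dict[str, int]:
        return {c: len(self.samples_in(c)) for c in COHORTS}


# --------------------------------------------------------------------------
# Expression matrix TSV I/O
# --------------------------------------------------------------------------


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_expression_tsv(path: str | Path, stage: str | None = None) -> ExpressionMatrix:
    """Read a probes × samples TSV (first column probe ids, header sample ids).

    The processing stage is taken from the sidecar ``<name>.meta.json`` written
    by :func:`write_expression_tsv` when present, else from ``stage``, else
    ``raw``. Ragged rows, duplicate ids, and non-numeric cells raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r and not (len(r) == 1 and not r[0].strip())]
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ids in header")
    probe_ids: list[str] = []
    values: list[list[float]] = []
    width = len(header)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}: line {lineno}: expected {width} fields, found {len(row)}"
            )
        probe_ids.append(row[0])
        try:
            values.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    if len(set(probe_ids)) != len(probe_ids):
        seen: set[str] = set()
        dups: list[str] = []
        for p in probe_ids:
            if p in seen:
                dups.append(p)
            seen.add(p)
        raise FormatError(f"{path}: duplicate probe ids: {sorted(set(dups))}")
    if stage is None:
        meta = _meta_path(path)
        if meta.exists():
            stage = json.loads(meta.read_text()).get("stage", "raw")
        else:
            stage = "raw"
    data = pd.DataFrame(values, index=probe_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(data=data, stage=stage)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at full double precision plus a stage sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["probe_id", *matrix.sample_ids])
        for probe, row in zip(matrix.probe_ids, matrix.data.to_numpy()):
            writer.writerow([probe, *(repr(float(v)) for v in row)])
    _meta_path(path).write_text(json.dumps({"stage": matrix.stage}) + "\n")


# --------------------------------------------------------------------------
# Sample sheets, probe manifests, candidate lists
# --------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, comment="#", dtype={"sample_id": str})
    return SampleSheet(frame=frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read a probe manifest CSV (columns ``probe_id``, ``mirna_name``).

    Names are canonicalized on load. A miRNA name may map to several probes;
    probe ids must be unique.
    """
    frame = pd.read_csv(path, comment="#", dtype=str)
    return build_probe_manifest(frame)


def build_probe_manifest(frame: pd.DataFrame) -> pd.DataFrame:
    missing = {"probe_id", "mirna_name"} - set(frame.columns)
    if missing:
        raise FormatError(f"probe manifest missing columns: {sorted(missing)}")
    if frame["probe_id"].duplicated().any():
        dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise FormatError(f"duplicate probe ids in manifest: {dups}")
    out = frame.loc[:, ["probe_id", "mirna_name"]].copy()
    out["mirna_name"] = out["mirna_name"].map(normalize_mirna_name)
    return out.reset_index(drop=True)


def write_probe_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


_DIRECTION_TOKENS = {
    "up": "up",
    "u": "up",
    "increased": "up",
    "down": "down",
    "dwn": "down",
    "dn": "down",
    "decreased": "down",
}


def _parse_direction(token: str, where: str) -> str:
    canon = _DIRECTION_TOKENS.get(str(token).strip().lower())
    if canon is None:
        raise FormatError(f"{where}: unknown direction token {token!r}")
    return canon


def read_candidate_csv(path: str | Path) -> pd.DataFrame:
    """Read a published candidate-miRNA list.

    Expected columns: ``study``, ``mirna``, ``direction``, ``fold_change``
    (optional magnitude, > 1 when present); any further columns (substrate,
    platform, cohort sizes) are carried through. Names are canonicalized and
    direction tokens validated (``up``/``down``, with common variants like
    ``dwn`` accepted).
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#", dtype={"study": str, "mirna": str})
    missing = {"study", "mirna", "direction"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: candidate list missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["mirna"] = frame["mirna"].map(normalize_mirna_name)
    frame["direction"] = [
        _parse_direction(tok, f"{path}: row {i}") for i, tok in enumerate(frame["direction"])
    ]
    if "fold_change" in frame.columns:
        frame["fold_change"] = pd.to_numeric(frame["fold_change"], errors="raise")
        bad = frame["fold_change"].dropna() <= 1
        if bad.any():
            raise FormatError(
                f"{path}: fold_change magnitudes must exceed 1; offending rows "
                f"{frame.index[frame['fold_change'] <= 1].tolist()}"
            )
    else:
        frame["fold_change"] = np.nan
    return frame.reset_index(drop=True)


def read_blood_list(path: str | Path) -> list[str]:
    """Read a blood-compartment miRNA list: one name per line, ``#`` comments."""
    names: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(normalize_mirna_name(line))
    return names
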