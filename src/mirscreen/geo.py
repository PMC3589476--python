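"""Optional reader for GEO series-matrix text files (local files only).

A series-matrix file is the tab-separated text export GEO provides per
series: ``!``-prefixed metadata lines, then a probes × samples value block
between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
This reader parses a file the user has already downloaded; the package never
touches the network. It exists as a convenience for running the pipeline on
a real deposit and is deliberately outside the tested surface; the accession
is a user argument with no default.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import ExpressionMatrix

__all__ = ["read_series_matrix"]


def read_series_matrix(
    path: str | Path,
    accession: str,
    stage: str = "normalized",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a local GEO series-matrix file into an expression matrix.

    ``accession`` identifies the series the caller believes the file holds
    and is checked against the file's ``!Series_geo_accession`` line when
    present. Returns ``(matrix, sample_metadata)`` where the metadata frame
    has one row per ``!Sample_*`` field and one column per sample.
    """
    path = Path(path)
    meta_rows: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    for line in path.read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith("!"):
            fields = [f.strip().strip('"') for f in line[1:].split("\t")]
            key = fields[0]
            if key == "Series_geo_accession" and fields[1:] and fields[1] != accession:
                raise ValueError(
                    f"{path}: file holds {fields[1]}, expected {accession}"
                )
            if key.startswith("Sample_"):
                meta_rows.setdefault(key, fields[1:])
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table block found")

    header, *body = [line.split("\t") for line in table_lines if line.strip()]
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    probe_ids = [row[0].strip().strip('"') for row in body]
    values = [[float(v) for v in row[1:]] for row in body]
    matrix = ExpressionMatrix(
        data=pd.DataFrame(values, index=probe_ids, columns=sample_ids, dtype=float),
        stage=stage,
    )
    metadata = pd.DataFrame(
        {k: pd.Series(v, index=sample_ids[: len(v)]) for k, v in meta_rows.items()}
    ).T
    return matrix, metadata
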