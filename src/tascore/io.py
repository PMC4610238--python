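"""Readers and writers for the plain-text interchange formats.

TSV is the canonical dialect; CSV is accepted on read (the delimiter is
sniffed from the header line).  Missing values are written as empty cells;
empty cells and ``NA`` are read as missing.  Matrix files may carry
``# key: value`` metadata comment lines before the header, which round-trip
through :func:`read_matrix` / :func:`write_matrix`.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dose_response import DoseResponseSeries
from .errors import ParseError
from .network import EDGE_COLUMNS, TargetNetwork, make_edge_frame

NA_VALUES = ["", "NA"]

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_dose_response",
    "write_dose_response",
    "read_edges",
    "write_edges",
    "write_network_summary",
    "write_json",
]


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _split_comments(path: Path) -> tuple[dict[str, str], str, int]:
    """Leading '# key: value' metadata, remaining body, body start line no."""
    metadata: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                metadata[key.strip()] = value.strip()
        else:
            break
    return metadata, "\n".join(lines[body_start:]), body_start


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an id-indexed numeric matrix from TSV or CSV.

    Returns (frame, metadata).  Rows are ids from the first column; empty
    cells and NA become NaN.  Duplicate ids and ragged rows raise
    :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    metadata, body, offset = _split_comments(path)
    lines = [ln for ln in body.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: no data rows")
    sep = _sniff_delimiter(lines[0])
    width = lines[0].count(sep)
    for i, ln in enumerate(lines[1:], start=offset + 2):
        if ln.count(sep) != width:
            raise ParseError(f"{path}: ragged row at line {i}")
    df = pd.read_csv(
        _io.StringIO(body), sep=sep, index_col=0, na_values=NA_VALUES,
        keep_default_na=False, comment=None,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate column {dup!r}")
    return df, metadata


def write_matrix(
    path: str | Path, frame: pd.DataFrame, metadata: Mapping[str, str] | None = None
) -> None:
    """Write an id-indexed matrix as TSV with '# key: value' metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", na_rep="")


def read_dose_response(path: str | Path) -> list[DoseResponseSeries]:
    """Read a long-format dose-response table into series objects.

    Expected columns: sample_id, compound_id, concentration_nM and either
    viability_pct (converted: inhibition = 100 - viability) or
    inhibition_pct.  Rows are grouped per sample x compound and sorted by
    concentration.
    """
    path = Path(path)
    _, body, _ = _split_comments(path)
    first = body.splitlines()[0] if body else ""
    sep = _sniff_delimiter(first)
    df = pd.read_csv(_io.StringIO(body), sep=sep, na_values=NA_VALUES, keep_default_na=False)
    required = {"sample_id", "compound_id", "concentration_nM"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if "inhibition_pct" in df.columns:
        response_col, orient = "inhibition_pct", "inhibition"
    elif "viability_pct" in df.columns:
        response_col, orient = "viability_pct", "viability"
    else:
        raise ParseError(f"{path}: need a viability_pct or inhibition_pct column")
    out = []
    for (s, c), grp in df.groupby(["sample_id", "compound_id"], sort=True):
        grp = grp.sort_values("concentration_nM")
        conc = grp["concentration_nM"].to_numpy(float)
        resp = grp[response_col].to_numpy(float)
        if orient == "viability":
            out.append(DoseResponseSeries.from_viability(str(s), str(c), conc, resp))
        else:
            out.append(DoseResponseSeries(str(s), str(c), conc, resp))
    return out


def write_dose_response(path: str | Path, series: Iterable[DoseResponseSeries]) -> None:
    """Write series as a long viability table (the screen's raw format)."""
    rows = []
    for s in series:
        for conc, inh in zip(s.concentrations_nM, s.responses):
            rows.append((s.sample_id, s.compound_id, conc, 100.0 - inh))
    pd.DataFrame(
        rows, columns=["sample_id", "compound_id", "concentration_nM", "viability_pct"]
    ).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a drug-target edge list TSV/CSV into the canonical layout."""
    path = Path(path)
    _, body, _ = _split_comments(path)
    first = body.splitlines()[0] if body else ""
    sep = _sniff_delimiter(first)
    df = pd.read_csv(_io.StringIO(body), sep=sep, na_values=NA_VALUES, keep_default_na=False)
    if not {"compound_id", "target_id"}.issubset(df.columns):
        raise ParseError(f"{path}: edge list needs compound_id and target_id columns")
    if "source" not in df.columns:
        df["source"] = "curated"
    return make_edge_frame(df)


def write_edges(path: str | Path, edges: pd.DataFrame | TargetNetwork) -> None:
    if isinstance(edges, TargetNetwork):
        edges = edges.edges
    edges.to_csv(path, sep="\t", index=False)


def write_network_summary(path: str | Path, network: TargetNetwork) -> None:
    """Per-target summary TSV (target_id, n_t)."""
    network.summary().to_csv(path, sep="\t", index=False)


def write_json(path: str | Path, payload: Mapping) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
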