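"""Census readers and report writers.

Census tables are CSV/TSV with a ``mass`` column (grams by convention)
and an optional ``label`` column.  Reports are TSV with a ``#``-prefixed
metadata header that echoes the exact resolved run parameters, so any
report can be re-run from its own header.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core_null import RankedCensus, prepare_census, prepare_census_from_log
from .gap_test import DiscontinuityReport

__all__ = ["read_census", "write_report", "read_report", "write_indices"]

_REPORT_COLUMNS = [
    "rank",
    "lower_label",
    "upper_label",
    "lower_mass",
    "upper_mass",
    "lower_logmass",
    "upper_logmass",
    "gap_log10",
    "percentile",
    "discontinuity",
]

_FLOAT_META = {"h_star", "threshold", "increment"}
_INT_META = {"B", "seed", "n", "grid_points"}
_BOOL_META = {"cap_exceeded"}


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_census(
    path,
    mass_column: str = "mass",
    label_column: str = "label",
    log_already: bool = False,
) -> RankedCensus:
    """Parse a CSV/TSV census table into a RankedCensus.

    The delimiter is sniffed; parse failures are reported with the
    offending file line number.  ``log_already=True`` treats the mass
    column as already log10-transformed.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: file is empty")
    sep = _sniff_delimiter(text[:4096])
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    if mass_column not in df.columns:
        raise ValueError(
            f"{path}: no '{mass_column}' column (found: {list(df.columns)})"
        )
    masses = pd.to_numeric(df[mass_column], errors="coerce")
    bad = masses.isna() & df[mass_column].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}, line {row + 2}: mass {df[mass_column][row]!r} is not numeric"
        )
    if masses.isna().any():
        row = int(masses.isna().idxmax())
        raise ValueError(f"{path}, line {row + 2}: missing mass value")
    labels = (
        df[label_column].astype(str).tolist() if label_column in df.columns else None
    )
    if log_already:
        return prepare_census_from_log(masses.to_numpy(), labels=labels)
    return prepare_census(masses.to_numpy(), labels=labels)


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".17g")
    return str(v)


def write_report(report: DiscontinuityReport, path) -> None:
    """Write a report as TSV with a ``#`` metadata header.

    Deterministic: the same report always produces the same bytes.
    """
    path = Path(path)
    lines = [f"# {k}={_fmt(report.meta[k])}" for k in sorted(report.meta)]
    lines.append("\t".join(_REPORT_COLUMNS))
    for _, row in report.table.iterrows():
        lines.append("\t".join(_fmt(row[c]) for c in _REPORT_COLUMNS))
    path.write_text("\n".join(lines) + "\n")


def read_report(path) -> DiscontinuityReport:
    """Read a TSV report back; inverse of write_report."""
    path = Path(path)
    meta = {}
    body = []
    for line in path.read_text().splitlines():
        if line.startswith("# "):
            k, _, v = line[2:].partition("=")
            if k in _FLOAT_META:
                meta[k] = float(v)
            elif k in _INT_META:
                meta[k] = int(v)
            elif k in _BOOL_META:
                meta[k] = v == "True"
            else:
                meta[k] = v
        else:
            body.append(line)
    table = pd.read_csv(
        _io.StringIO("\n".join(body)),
        sep="\t",
        dtype={"lower_label": str, "upper_label": str},
        float_precision="round_trip",
    )
    return DiscontinuityReport(table=table, meta=meta)


def write_indices(series_list, census: RankedCensus, path) -> None:
    """Write one or more classic index series as a rank-aligned TSV.

    HI (needs both neighbours) is blank at rank 1; SB aligns with the
    gap above each rank.
    """
    path = Path(path)
    n = census.n
    cols: dict[str, list] = {
        "rank": list(range(1, n)),
        "lower_label": list(census.labels[:-1]),
        "upper_label": list(census.labels[1:]),
    }
    for s in series_list:
        vals = [""] * (n - 1)
        if s.method == "HI":
            # HI[k] sits at interior entity k+1, between gaps k and k+1
            for k, v in enumerate(s.values):
                vals[k + 1] = _fmt(v)
            name = f"HI_gamma{_fmt(s.gamma)}"
        else:
            vals = [_fmt(v) for v in s.values]
            name = s.method
        cols[name] = vals
    header = "\t".join(cols)
    lines = [header]
    for i in range(n - 1):
        lines.append("\t".join(str(cols[c][i]) for c in cols))
    path.write_text("\n".join(lines) + "\n")
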