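"""Readers and writers for all on-disk tables, plus design validation.

Canonical dialect: UTF-8, tab-separated, one header row.  Exports from other
search engines can be adapted by passing a ``column_map`` that maps the
canonical PSM column names to the names found in the file.

Canonical PSM columns::

    peptide_id  protein_id  search_rank  ion_score
    isolation_interference_pct  reporter_1 .. reporter_10

Matrices are persisted as TSV with peptide row labels and pipe-joined sample
column labels (``line|timepoint_s|replicate``), preceded by a single comment
line recording the processing stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    BRIDGE,
    N_CHANNELS,
    PhosphoMatrix,
    PlexDesign,
    PsmRecord,
    PtyrlinkError,
    SampleKey,
)

PSM_COLUMNS = (
    "peptide_id",
    "protein_id",
    "search_rank",
    "ion_score",
    "isolation_interference_pct",
) + tuple(f"reporter_{i + 1}" for i in range(N_CHANNELS))


class FormatError(PtyrlinkError):
    """A file is structurally unusable (e.g., a required column is missing)."""


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number (header excluded)
    message: str


@dataclass
class PsmParseResult:
    records: list[PsmRecord]
    errors: list[RowError]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_float(value, allow_nan: bool = True) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_nan:
            return float("nan")
        raise ValueError("missing value")
    if isinstance(value, str) and value.strip() == "":
        if allow_nan:
            return float("nan")
        raise ValueError("missing value")
    return float(value)


def read_psm_table(
    path: str | Path,
    run_id: str,
    column_map: Mapping[str, str] | None = None,
) -> PsmParseResult:
    """Parse one PSM export into records, collecting per-row diagnostics.

    Rows that fail to parse (non-numeric or negative intensities, bad
    quality fields) are rejected individually and reported with their
    1-based row number; a missing required column raises :class:`FormatError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = dict(column_map or {})
    missing = [c for c in PSM_COLUMNS if colmap.get(c, c) not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    records: list[PsmRecord] = []
    errors: list[RowError] = []
    get = lambda row, c: row[colmap.get(c, c)]
    for i, (_, row) in enumerate(raw.iterrows(), start=1):
        try:
            intensities = tuple(
                _parse_float(get(row, f"reporter_{k + 1}")) for k in range(N_CHANNELS)
            )
            rec = PsmRecord(
                peptide_id=str(get(row, "peptide_id")),
                run_id=run_id,
                search_rank=int(get(row, "search_rank")),
                ion_score=_parse_float(get(row, "ion_score"), allow_nan=False),
                isolation_interference_pct=_parse_float(
                    get(row, "isolation_interference_pct"), allow_nan=False
                ),
                reporter_intensity=intensities,
                protein_id=str(get(row, "protein_id")),
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        records.append(rec)
    return PsmParseResult(records=records, errors=errors)


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "peptide_id": r.peptide_id,
            "protein_id": r.protein_id,
            "search_rank": r.search_rank,
            "ion_score": r.ion_score,
            "isolation_interference_pct": r.isolation_interference_pct,
        }
        for k, v in enumerate(r.reporter_intensity):
            row[f"reporter_{k + 1}"] = "" if math.isnan(v) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plex designs
# ---------------------------------------------------------------------------


def write_designs(designs: Mapping[str, PlexDesign], path: str | Path) -> None:
    rows = []
    for run_id in sorted(designs):
        d = designs[run_id]
        for ch in sorted(d.channel_map):
            label = d.channel_map[ch]
            if label == BRIDGE:
                rows.append(
                    dict(run_id=run_id, channel=ch, line=BRIDGE, timepoint_s="",
                         replicate="")
                )
            else:
                line, t, rep = label
                rows.append(
                    dict(run_id=run_id, channel=ch, line=line, timepoint_s=t,
                         replicate=rep)
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_designs(path: str | Path) -> dict[str, PlexDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"run_id", "channel", "line", "timepoint_s", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing column(s) {sorted(missing)}")
    designs: dict[str, PlexDesign] = {}
    for run_id, grp in df.groupby("run_id", sort=True):
        cmap: dict[int, object] = {}
        for _, row in grp.iterrows():
            ch = int(row["channel"])
            if row["line"] == BRIDGE:
                cmap[ch] = BRIDGE
            else:
                cmap[ch] = (
                    str(row["line"]),
                    int(row["timepoint_s"]),
                    int(row["replicate"]),
                )
        designs[str(run_id)] = PlexDesign(run_id=str(run_id), channel_map=cmap)
    return designs


# ---------------------------------------------------------------------------
# Crude-lysate medians
# ---------------------------------------------------------------------------


def write_crude_medians(
    medians: Mapping[str, np.ndarray], path: str | Path
) -> None:
    rows = [
        dict(run_id=run_id, channel=ch, median=repr(float(medians[run_id][ch])))
        for run_id in sorted(medians)
        for ch in range(N_CHANNELS)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_crude_medians(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"run_id", "channel", "median"} - set(df.columns)
    if missing:
        raise FormatError(f"crude-median table missing column(s) {sorted(missing)}")
    out: dict[str, np.ndarray] = {}
    for run_id, grp in df.groupby("run_id", sort=True):
        arr = np.full(N_CHANNELS, np.nan)
        for _, row in grp.iterrows():
            arr[int(row["channel"])] = float(row["median"])
        if np.isnan(arr).any():
            raise FormatError(f"run {run_id}: crude medians incomplete")
        out[str(run_id)] = arr
    return out


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def write_matrix(matrix: PhosphoMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    if isinstance(df.columns, pd.MultiIndex):
        df.columns = ["|".join(str(x) for x in tup) for tup in df.columns]
    else:
        df.columns = [f"ch{c}" for c in df.columns]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# stage={matrix.stage}"
                 + (f" run_id={matrix.run_id}" if matrix.run_id else "") + "\n")
        # shortest exact decimal repr so read -> write -> read is identity
        df.to_csv(fh, sep="\t", index_label="peptide_id",
                  float_format=lambda v: repr(float(v)))


def read_matrix(path: str | Path) -> PhosphoMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("# stage="):
        raise FormatError(f"{path.name}: missing stage comment line")
    fields = dict(item.split("=", 1) for item in header[2:].split())
    stage = fields["stage"]
    df = pd.read_csv(path, sep="\t", skiprows=1, index_col="peptide_id",
                     float_precision="round_trip")
    df.index.name = None
    if stage in ("raw_intensity", "loading_normalized"):
        df.columns = [int(c.removeprefix("ch")) for c in df.columns]
    else:
        tuples = [tuple(c.split("|")) for c in df.columns]
        if stage == "replicate_mean":
            df.columns = pd.MultiIndex.from_tuples(
                [(line, int(t)) for line, t in tuples],
                names=["line", "timepoint_s"],
            )
        else:
            df.columns = pd.MultiIndex.from_tuples(
                [(line, int(t), int(r)) for line, t, r in tuples],
                names=["line", "timepoint_s", "replicate"],
            )
    return PhosphoMatrix(values=df, stage=stage, run_id=fields.get("run_id"))


# ---------------------------------------------------------------------------
# Phenotype raw tables
# ---------------------------------------------------------------------------

CONFLUENCY_COLUMNS = ("line", "egf", "replicate", "time_h", "confluency_pct")
WOUND_COLUMNS = ("line", "egf", "replicate", "time_h", "wound_width_um")
INTERNALIZATION_COLUMNS = ("line", "replicate", "fluorescence")

#: Line label used for the untransfected normalization control.
CONTROL_LINE = "CONTROL"


def _read_checked(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(
            f"{Path(path).name}: missing required column(s) {sorted(missing)}"
        )
    return df


def read_confluency(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, CONFLUENCY_COLUMNS)


def read_wound(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, WOUND_COLUMNS)


def read_internalization(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, INTERNALIZATION_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Design validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of checking a set of plex designs against the expected
    full-factorial (line x timepoint x replicate) layout with one bridge
    channel per run."""

    passed: bool
    missing_cells: list[SampleKey] = field(default_factory=list)
    duplicate_cells: list[SampleKey] = field(default_factory=list)
    bridge_issues: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"design validation: {'PASS' if self.passed else 'FAIL'}"]
        for m in self.messages:
            lines.append(f"  - {m}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "missing_cells": [list(c) for c in self.missing_cells],
            "duplicate_cells": [list(c) for c in self.duplicate_cells],
            "bridge_issues": self.bridge_issues,
            "messages": self.messages,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def validate_design(
    designs: Mapping[str, PlexDesign],
    expected_lines: Sequence[str],
    expected_timepoints: Sequence[int],
    expected_replicates: int,
) -> ValidationReport:
    """Check bridge placement and full-factorial coverage across all runs."""
    if not designs:
        raise ValueError("validate_design requires at least one design")
    report = ValidationReport(passed=True)

    seen: dict[SampleKey, int] = {}
    for run_id in sorted(designs):
        d = designs[run_id]
        n_bridge = len(d.bridge_channels)
        if n_bridge != 1:
            report.bridge_issues.append(run_id)
            report.messages.append(
                f"run {run_id}: expected exactly 1 BRIDGE channel, found {n_bridge}"
            )
        for key in d.sample_channels().values():
            seen[key] = seen.get(key, 0) + 1

    expected = {
        (line, int(t), rep)
        for line in expected_lines
        for t in expected_timepoints
        for rep in range(1, expected_replicates + 1)
    }
    report.missing_cells = sorted(expected - set(seen))
    report.duplicate_cells = sorted(k for k, n in seen.items() if n > 1)
    unexpected = sorted(set(seen) - expected)

    for cell in report.missing_cells:
        report.messages.append(f"missing sample cell {cell}")
    for cell in report.duplicate_cells:
        report.messages.append(f"duplicated sample cell {cell}")
    for cell in unexpected:
        report.messages.append(f"unexpected sample cell {cell}")

    report.passed = not (
        report.missing_cells
        or report.duplicate_cells
        or report.bridge_issues
        or unexpected
    )
    return report
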