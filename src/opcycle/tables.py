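"""Readers and writers for the tabular text formats the pipeline uses.

All tables are plain comma- or tab-separated text with one header row;
delimiter is auto-detected from the header.  Row-level validation errors
are collected and reported together, naming the offending line, rather
than failing on the first bad cell.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .cellcycle import LabelingCurvePoint, PulseChaseObservation
from .frap import FrapTrace, detect_bleach_index

__all__ = [
    "TableValidationError",
    "read_labeling_table",
    "read_pulse_chase_table",
    "read_trace",
    "read_peaks",
    "read_gene_list",
    "write_labeling_tsv",
    "write_pulse_chase_tsv",
    "write_trace_csv",
    "write_peaks_bed",
    "write_report",
    "read_report",
    "write_sidecar",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class TableValidationError(ValueError):
    """One or more rows of an input table failed validation."""

    def __init__(self, path: str | Path, errors: list[str]):
        self.errors = errors
        msg = f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        super().__init__(msg)


def _read_delim(
    path: str | Path, required: Sequence[str], lower_all: bool = True
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.read_text().lstrip()
    if not head:
        raise TableValidationError(path, ["file is empty"])
    sep = "\t" if "\t" in head.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    if lower_all:
        df.columns = [c.strip().lower() for c in df.columns]
    else:
        # Header match is case-insensitive for the schema columns only;
        # extra columns (e.g. motif names) keep their spelling.
        df.columns = [
            c.strip().lower() if c.strip().lower() in required else c.strip()
            for c in df.columns
        ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(path, [f"missing column(s): {', '.join(missing)}"])
    return df


def _collect(path, df, row_builder):
    records, errors = [], []
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after the header line
        try:
            records.append(row_builder(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise TableValidationError(path, errors)
    return records


def read_labeling_table(path: str | Path) -> list[LabelingCurvePoint]:
    """Read a cumulative-labeling table: ``time_h, n_total, n_labeled``."""
    df = _read_delim(path, ["time_h", "n_total", "n_labeled"])
    return _collect(
        path,
        df,
        lambda r: LabelingCurvePoint(
            t=float(r["time_h"]), n_total=int(r["n_total"]), n_labeled=int(r["n_labeled"])
        ),
    )


def read_pulse_chase_table(path: str | Path) -> list[PulseChaseObservation]:
    """Read pulse-chase counts: ``t_chase_h, n_edu, n_edu_ph3``."""
    df = _read_delim(path, ["t_chase_h", "n_edu", "n_edu_ph3"])
    return _collect(
        path,
        df,
        lambda r: PulseChaseObservation(
            t_chase=float(r["t_chase_h"]), n_edu=int(r["n_edu"]), n_edu_ph3=int(r["n_edu_ph3"])
        ),
    )


def read_trace(path: str | Path, bleach_index: int | None = None) -> FrapTrace:
    """Read a photobleaching trace CSV: ``t_s, roi, reference, background``.

    ``bleach_index`` defaults to auto-detection at the largest
    single-frame drop in the ROI.
    """
    df = _read_delim(path, ["t_s", "roi", "reference", "background"])
    roi = df["roi"].to_numpy(dtype=float)
    if bleach_index is None:
        bleach_index = detect_bleach_index(roi)
    return FrapTrace(
        t=df["t_s"].to_numpy(dtype=float),
        roi=roi,
        reference=df["reference"].to_numpy(dtype=float),
        background=df["background"].to_numpy(dtype=float),
        bleach_index=bleach_index,
    )


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a motif-annotated BED-like table (0-based half-open intervals).

    The first six columns are standard BED; any further columns are
    boolean motif indicators (accepted spellings: 0/1, true/false).
    """
    df = _read_delim(path, BED_COLUMNS[:3], lower_all=False)
    df.columns = [c.lower() if c.lower() in BED_COLUMNS else c for c in df.columns]
    errors = []
    for col in ("start", "end"):
        for i, v in df[col].items():
            if float(v) != int(float(v)) or int(float(v)) < 0:
                errors.append(f"line {i + 2}: non-integer or negative {col} '{v}'")
    if errors:
        raise TableValidationError(path, errors)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["end"] <= df["start"]
    if bad.any():
        raise TableValidationError(
            path, [f"line {i + 2}: end <= start" for i in df.index[bad]]
        )
    motif_cols = [c for c in df.columns if c not in BED_COLUMNS]
    for col in motif_cols:
        df[col] = (
            df[col].astype(str).str.strip().str.lower().map(
                {"1": True, "0": False, "true": True, "false": False}
            )
        )
        if df[col].isna().any():
            i = int(df.index[df[col].isna()][0])
            raise TableValidationError(path, [f"line {i + 2}: non-boolean value in '{col}'"])
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_labeling_tsv(path: str | Path, points: Sequence[LabelingCurvePoint]) -> None:
    pd.DataFrame(
        {
            "time_h": [p.t for p in points],
            "n_total": [p.n_total for p in points],
            "n_labeled": [p.n_labeled for p in points],
        }
    ).to_csv(path, sep="\t", index=False)


def write_pulse_chase_tsv(path: str | Path, obs: Sequence[PulseChaseObservation]) -> None:
    pd.DataFrame(
        {
            "t_chase_h": [o.t_chase for o in obs],
            "n_edu": [o.n_edu for o in obs],
            "n_edu_ph3": [o.n_edu_ph3 for o in obs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_trace_csv(path: str | Path, trace: FrapTrace) -> None:
    pd.DataFrame(
        {
            "t_s": trace.t,
            "roi": trace.roi,
            "reference": trace.reference,
            "background": trace.background,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def write_peaks_bed(path: str | Path, peaks: pd.DataFrame) -> None:
    df = peaks.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_report(path: str | Path, report: dict[str, Any]) -> None:
    """Write a flat key-value report as JSON plus aligned-column text.

    The text twin goes next to the JSON with a ``.txt`` suffix.  Values
    are written at full precision in the JSON so a read-back reproduces
    them exactly.
    """
    path = Path(path)
    clean = {k: _jsonable(v) for k, v in report.items()}
    path.write_text(json.dumps(clean, indent=2) + "\n")
    width = max((len(k) for k in clean), default=0)
    lines = [f"{k.ljust(width)}  {v}" for k, v in clean.items()]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, tuple):
        return list(v)
    return v


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def write_sidecar(path: str | Path, seed: int | None, params: dict[str, Any]) -> None:
    """Log seed and generator parameters next to a written data file."""
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps({"seed": seed, "params": params}, indent=2, default=str) + "\n")
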