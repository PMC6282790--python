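"""CSV readers and writers shared across the pipeline.

All interchange is plain text.  Chromatograms are two-column CSV
(time_min, signal) with ``# key = value`` comment headers carrying the
drug label and mobile-phase concentration; retention tables are long
CSV with one row per injection.  Readers tolerate comma and tab
delimiters and ignore comment lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .retention import Chromatogram

__all__ = [
    "write_chromatogram",
    "read_chromatogram",
    "write_retention_table",
    "read_retention_table",
    "write_compound_table",
]

RETENTION_COLUMNS = ["drug", "total_conc_M", "replicate", "retention_time_min"]


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    lines = [f"# drug = {chrom.drug}"]
    if chrom.total_surfactant is not None:
        lines.append(f"# total_surfactant_M = {chrom.total_surfactant:.6g}")
    lines.append("time_min,signal")
    lines += [f"{t:.6g},{s:.8g}" for t, s in zip(chrom.time, chrom.signal)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a two-column trace; comma- or tab-delimited."""
    drug, total = "", None
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            key, value = key.strip(), value.strip()
            if key == "drug":
                drug = value
            elif key == "total_surfactant_M":
                total = float(value)
        elif line.strip():
            body.append(line)
    if not body:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if "\t" in body[0] else ","
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep=sep)
    return Chromatogram(
        time=np.asarray(df.iloc[:, 0], dtype=float),
        signal=np.asarray(df.iloc[:, 1], dtype=float),
        drug=drug,
        total_surfactant=total,
    )


def write_retention_table(
    table: pd.DataFrame,
    path: str | Path,
    *,
    cmc: float | None = None,
    seed: int | None = None,
) -> None:
    """Write a retention table with columns drug, total_conc_M, replicate,
    retention_time_min.

    Accepts either ``total_conc_M`` directly or a simulator table with
    ``c_m_M`` (micellar concentration), in which case ``cmc`` (M) is
    added back to recover the total mobile-phase concentration.
    """
    df = table.copy()
    if "total_conc_M" not in df.columns:
        if "c_m_M" not in df.columns or cmc is None:
            raise ValueError("need total_conc_M, or c_m_M plus a cmc value")
        df["total_conc_M"] = df["c_m_M"] + cmc
    df = df[RETENTION_COLUMNS]
    header = []
    if seed is not None:
        header.append(f"# seed = {seed}")
    if cmc is not None:
        header.append(f"# cmc_M = {cmc:.6g}")
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_retention_table(path: str | Path) -> pd.DataFrame:
    """Read a retention table, skipping comment lines; comma or tab."""
    text = Path(path).read_text()
    body = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not body:
        raise ValueError(f"{path}: empty retention table")
    sep = "\t" if "\t" in body[0] else ","
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body)), sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = set(RETENTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_compound_table(table: pd.DataFrame, path: str | Path, *, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        table.to_csv(fh, index=False, float_format="%.10g")
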