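"""Minimal STAR loop-table writer/reader for particle and peak tables.

Only the subset used by single-particle packages is supported: one data
block containing one ``loop_`` with ``_name`` column headers and whitespace
separated rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_star_table", "read_star_table"]


def write_star_table(df: pd.DataFrame, path, block: str = "particles") -> None:
    lines = [f"data_{block}", "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in df.iterrows():
        fields = []
        for v in row:
            if isinstance(v, (float, np.floating)):
                fields.append(f"{v:.6f}")
            elif isinstance(v, (bool, np.bool_)):
                fields.append("1" if v else "0")
            else:
                fields.append(str(v))
        lines.append("  ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_star_table(path) -> pd.DataFrame:
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            cols, rows = [], []
            continue
        if in_loop and line.startswith("_"):
            cols.append(line.split()[0].lstrip("_"))
            continue
        if in_loop and cols:
            parts = line.split()
            if len(parts) == len(cols):
                rows.append(parts)
    if not cols:
        raise ValueError(f"no loop table found in {path}")
    df = pd.DataFrame(rows, columns=cols)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass
    return df
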