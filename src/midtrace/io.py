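"""Table readers/writers and run manifests.

Conventions
-----------
* Isotopologue area tables: UTF-8 CSV, one row per sample (first column
  ``sample``), isotopologue columns named ``<metabolite>|m+<i>``.
* Design tables: columns ``sample,group,compartment,cells,is_area``.
* Two-group abundance tables: first column ``metabolite``, remaining
  columns one per sample.
Results go to files; logs go to stderr.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "channel_name",
    "parse_channel",
    "read_area_table",
    "read_design",
    "read_two_group_table",
    "area_matrix",
    "write_manifest",
]

_CHANNEL_RE = re.compile(r"^(?P<met>.+)\|m\+(?P<shift>\d+)$")

DESIGN_COLUMNS = ["sample", "group", "compartment", "cells", "is_area"]


def channel_name(metabolite: str, shift: int) -> str:
    return f"{metabolite}|m+{shift}"


def parse_channel(column: str) -> tuple[str, int]:
    m = _CHANNEL_RE.match(column)
    if not m:
        raise ValueError(f"column {column!r} is not of the form '<metabolite>|m+<i>'")
    return m.group("met"), int(m.group("shift"))


def read_area_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x isotopologue-channel area table, indexed by sample."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column must be 'sample', got {df.columns[0]!r}")
    for col in df.columns[1:]:
        parse_channel(col)  # validates naming
    df = df.set_index("sample")
    if (df.values < 0).any():
        bad = df.lt(0).any()
        raise ValueError(f"{path}: negative areas in columns {list(bad[bad].index)}")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design sheet, indexed by sample."""
    df = pd.read_csv(path)
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design sheet missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicated sample ids {dupes}")
    return df.set_index("sample")


def read_two_group_table(path: str | Path) -> pd.DataFrame:
    """Read a metabolite x sample abundance table, indexed by metabolite."""
    df = pd.read_csv(path)
    if df.columns[0] != "metabolite":
        raise ValueError(f"{path}: first column must be 'metabolite', got {df.columns[0]!r}")
    df = df.set_index("metabolite")
    if (df.values < 0).any():
        raise ValueError(f"{path}: abundances must be non-negative")
    return df


def area_matrix(areas: pd.DataFrame, metabolite: str) -> tuple[np.ndarray, list[str]]:
    """Extract the (samples x shifts) raw-area matrix for one metabolite.

    Returns the matrix (columns ordered by increasing mass shift, gaps
    zero-filled) and the ordered sample ids.
    """
    shifts: dict[int, str] = {}
    for col in areas.columns:
        met, shift = parse_channel(col)
        if met == metabolite:
            shifts[shift] = col
    if not shifts:
        raise KeyError(f"no isotopologue columns for metabolite {metabolite!r}")
    k_max = max(shifts)
    mat = np.zeros((len(areas), k_max + 1))
    for shift, col in shifts.items():
        mat[:, shift] = areas[col].to_numpy(dtype=float)
    return mat, list(areas.index)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    inputs: list[str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a reproducibility manifest next to the run's outputs."""
    import midtrace

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "versions": {
            "midtrace": midtrace.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": {
            str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
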