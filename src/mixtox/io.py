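"""Readers and writers for the pipeline's tabular formats.

All tabular I/O is plain CSV; reports and ground-truth bundles are JSON.
Writers prepend ``#``-comment header lines declaring units and the
per-component vs total-mixture concentration convention; readers skip
them.  Concentrations are serialised in uM as plain decimals (no
scientific notation above 1e-12) to keep diffs readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SCREEN_COLUMNS

__all__ = [
    "read_screen_csv",
    "write_screen_csv",
    "read_ache_csv",
    "write_ache_csv",
    "write_truth_json",
    "read_truth_json",
    "format_concentration",
]

ACHE_COLUMNS = ["condition", "concentration_uM", "replicate", "percent_activity"]

SCREEN_HEADER = (
    "# mixtox screen records: concentration_uM is per-component uM "
    "(0 = solvent control); incidence values are per-animal 0/1"
)
ACHE_HEADER = (
    "# mixtox AChE activity records: concentration_uM in uM "
    "(per sample; total for mixtures), percent_activity relative to solvent control"
)


def format_concentration(x: float) -> str:
    """Plain-decimal concentration formatting (no scientific notation)."""
    if x == 0:
        return "0"
    s = f"{float(x):.12f}".rstrip("0").rstrip(".")
    return s if s else "0"


class ScreenValidationError(ValueError):
    """Raised when a screen CSV fails validation; message lists row numbers."""


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_screen_csv(path, known_readouts=None) -> pd.DataFrame:
    """Read and validate a long-format screen CSV.

    Checks the schema, non-negative finite concentrations, finite values
    and 0/1 incidence values; ``known_readouts`` (e.g. the readouts of
    the BMR table plus any declared extras) rejects unknown readout
    names.  Malformed rows are reported with their 1-based data row
    numbers.
    """
    df = _read_csv(path)
    missing = set(SCREEN_COLUMNS) - set(df.columns)
    if missing:
        raise ScreenValidationError(f"{path}: missing columns {sorted(missing)}")
    errors = []
    conc = pd.to_numeric(df["concentration_uM"], errors="coerce")
    bad = df.index[conc.isna() | ~np.isfinite(conc) | (conc < 0)]
    for i in bad:
        errors.append(f"row {i + 1}: invalid concentration {df['concentration_uM'][i]!r}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[vals.isna() | ~np.isfinite(vals)]
    for i in bad:
        errors.append(f"row {i + 1}: non-finite value {df['value'][i]!r}")
    inc = df["is_incidence"].astype(bool)
    bad = df.index[inc & ~vals.isin([0.0, 1.0])]
    for i in bad:
        errors.append(f"row {i + 1}: incidence value {df['value'][i]!r} not in {{0, 1}}")
    if known_readouts is not None:
        unknown = sorted(set(df["readout"]) - set(known_readouts))
        if unknown:
            errors.append(f"unknown readouts (not in BMR table or declared): {unknown}")
    if errors:
        raise ScreenValidationError(f"{path}:\n" + "\n".join(errors[:50]))
    df["concentration_uM"] = conc.astype(float)
    df["value"] = vals.astype(float)
    df["is_incidence"] = inc
    df["day"] = df["day"].astype(int)
    return df[SCREEN_COLUMNS]


def write_screen_csv(records: pd.DataFrame, path) -> None:
    out = records[SCREEN_COLUMNS].copy()
    out["concentration_uM"] = out["concentration_uM"].map(format_concentration)
    out["is_incidence"] = out["is_incidence"].astype(bool)
    with open(path, "w") as fh:
        fh.write(SCREEN_HEADER + "\n")
        out.to_csv(fh, index=False)


def read_ache_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = set(ACHE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    conc = pd.to_numeric(df["concentration_uM"], errors="coerce")
    if (conc.isna() | (conc < 0)).any():
        bad = df.index[conc.isna() | (conc < 0)][0]
        raise ValueError(f"{path}: row {bad + 1}: invalid concentration")
    df["concentration_uM"] = conc.astype(float)
    df["percent_activity"] = df["percent_activity"].astype(float)
    return df[ACHE_COLUMNS]


def write_ache_csv(records: pd.DataFrame, path) -> None:
    out = records[ACHE_COLUMNS].copy()
    out["concentration_uM"] = out["concentration_uM"].map(format_concentration)
    with open(path, "w") as fh:
        fh.write(ACHE_HEADER + "\n")
        out.to_csv(fh, index=False)


def write_truth_json(truth_bundle: dict, path) -> None:
    Path(path).write_text(json.dumps(truth_bundle, indent=2, sort_keys=True) + "\n")


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
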