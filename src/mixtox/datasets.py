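"""Packaged reference tables from the planarian OP-mixture study.

Three small fixtures ship with the package:

* ``benchmark_responses`` -- the per-readout benchmark responses (BMRs)
  of the behavioral screen, by worm type, exposure day and direction;
* ``mixture_bmc_min`` -- the published minimum benchmark concentrations
  (experimental and CA-predicted) per binary mixture and worm type, with
  the log10 discrepancy ratio;
* ``ache_ic50`` -- day-12 AChE IC50s (uM, with SEs) of the seven
  organophosphorus pesticides in regenerating and adult planarians
  (ACE is censored: no significant inhibition up to 316 uM);
* ``oxon_mixture_params`` -- the in vitro CPO/MALO mixture composition.

These are inputs for replication and cross-checks, not outputs of this
package.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "READOUT_ORDER",
    "MIXTURES",
    "OPS",
    "load_benchmark_responses",
    "load_mixture_bmc_min",
    "load_ache_ic50",
    "load_oxon_mixture_params",
    "fixture_checksums",
]

#: canonical screen panel order (used for deterministic table ordering)
READOUT_ORDER = (
    "lethality",
    "stickiness",
    "speed_dark",
    "resting_dark",
    "speed_blue",
    "resting_blue",
    "wall_preference",
    "locomotor_bursts",
    "phototaxis",
    "thermotaxis",
    "scrunching",
    "noxious_rate",
    "noxious_strength",
)

#: the seven organophosphorus pesticides of the screen
OPS = ("ACE", "CPF", "DDVP", "DZN", "MAL", "PFS", "PT")

#: the 21 binary mixtures, in the order of the published summary table
MIXTURES = (
    "CPF.ACE", "CPF.DDVP", "CPF.DZN", "CPF.MAL", "CPF.PFS", "CPF.PT",
    "DDVP.ACE", "DDVP.DZN", "DDVP.MAL", "DDVP.PFS", "DDVP.PT",
    "DZN.ACE", "DZN.MAL", "DZN.PFS", "DZN.PT",
    "MAL.ACE", "MAL.PFS", "MAL.PT",
    "PFS.ACE", "PFS.PT",
    "PT.ACE",
)

_FIXTURES = resources.files("mixtox") / "fixtures"


def _read_csv(name: str, **kwargs) -> pd.DataFrame:
    with resources.as_file(_FIXTURES / name) as path:
        return pd.read_csv(path, **kwargs)


def load_benchmark_responses() -> pd.DataFrame:
    """Long-format BMR table: readout, is_incidence, worm_type, day, direction, bmr."""
    df = _read_csv("benchmark_responses.csv")
    df["is_incidence"] = df["is_incidence"].astype(bool)
    return df


def load_mixture_bmc_min() -> pd.DataFrame:
    """Published BMC_min comparison per mixture and worm type (uM; NA = no active BMC)."""
    return _read_csv("mixture_bmc_min.csv")


def load_ache_ic50() -> pd.DataFrame:
    """Day-12 AChE IC50 table (uM) for the seven OPs, both worm types."""
    return _read_csv("ache_ic50.csv")


def load_oxon_mixture_params() -> dict:
    """In vitro CPO/MALO mixture composition parameters (stored verbatim)."""
    with resources.as_file(_FIXTURES / "oxon_mixture_params.json") as path:
        return json.loads(path.read_text())


def published_ratio_consistency() -> pd.DataFrame:
    """Check the published BMC_min log10 ratios against their printed inputs.

    The published ratios were computed from full-precision BMC_min values
    and then rounded, so recomputing them from the *printed* (2-decimal)
    columns can deviate by more than the ratio's own rounding step.  The
    faithful consistency check is therefore an interval one: a printed
    ratio is consistent when it lies within the range of ratios
    achievable from inputs anywhere inside their printed-rounding
    envelopes (half a unit in the last printed decimal place), widened by
    the ratio's own half-ulp.

    Returns the table with ``ratio_recomputed``, the envelope bounds
    ``ratio_lo``/``ratio_hi``, ``abs_deviation`` of the recomputed ratio
    from the printed one, and a boolean ``consistent`` column.
    """
    import math

    raw = _read_csv("mixture_bmc_min.csv", dtype=str)

    def half_ulp(s):
        if not isinstance(s, str) or not s.strip():
            return np.nan
        s = s.strip()
        decimals = len(s.split(".")[1]) if "." in s else 0
        return 0.5 * 10.0**-decimals

    rows = []
    for _, r in raw.iterrows():
        exp_s, pred_s, ratio_s = (r["experimental_bmc_min_uM"],
                                  r["predicted_bmc_min_uM"], r["log10_ratio"])
        if not isinstance(exp_s, str) or not exp_s.strip():
            rows.append((np.nan,) * 4 + (True,))  # NA row: vacuously consistent
            continue
        e, p, printed = float(exp_s), float(pred_s), float(ratio_s)
        he, hp, hr = half_ulp(exp_s), half_ulp(pred_s), half_ulp(ratio_s)
        recomputed = math.log10(p / e)
        lo = math.log10((p - hp) / (e + he)) - hr
        hi = math.log10((p + hp) / (e - he)) + hr
        rows.append((recomputed, lo, hi, abs(recomputed - printed),
                     lo <= printed <= hi))
    out = load_mixture_bmc_min()
    out[["ratio_recomputed", "ratio_lo", "ratio_hi", "abs_deviation",
         "consistent"]] = pd.DataFrame(rows, index=out.index)
    return out


def fixture_checksums() -> dict:
    """SHA-256 of every packaged fixture, for provenance logging."""
    out = {}
    for entry in sorted(_FIXTURES.iterdir(), key=lambda e: e.name):
        if entry.name.endswith((".csv", ".json")):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out
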