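"""Classification of mixture interactions and overall potency summaries.

A mixture readout is classified by comparing the bootstrap confidence
interval of the observed BMC with the propagated interval of the Loewe
CA prediction:

* both inactive                      -> no_effect
* intervals overlap                  -> additive
* observed entirely below predicted  -> synergistic
* observed entirely above predicted  -> antagonistic
* exactly one side active            -> non-overlapping by rule; an
  absent BMC behaves as "beyond the tested range", so observed-only
  active means the mixture is more potent than predicted (synergistic)
  and predicted-only active means less potent (antagonistic).

Overall potency per mixture is summarised by BMC_min, the smallest
median BMC across all readouts and directions, and the discrepancy
statistic log10(BMC_min(predicted) / BMC_min(experimental)): positive
values mean the mixture was experimentally more potent than the additive
model predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loewe import CAPrediction

__all__ = [
    "ADDITIVE",
    "SYNERGISTIC",
    "ANTAGONISTIC",
    "NO_EFFECT",
    "InteractionCall",
    "PotencySummary",
    "classify",
    "potency_summary",
    "log10_potency_ratio",
    "heatmap_table",
]

ADDITIVE = "additive"
SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
NO_EFFECT = "no_effect"
CALLS = (ADDITIVE, SYNERGISTIC, ANTAGONISTIC, NO_EFFECT)


@dataclass(frozen=True)
class InteractionCall:
    mixture: str
    readout: str
    direction: str
    worm_type: str
    day: int
    call: str
    provenance: str = ""  # 'overlap', 'disjoint', 'one_sided', 'none'
    observed: object = None
    predicted: object = None
    flags: tuple = field(default=())

    def to_row(self) -> dict:
        return {
            "mixture": self.mixture,
            "worm_type": self.worm_type,
            "day": self.day,
            "readout": self.readout,
            "direction": self.direction,
            "call": self.call,
            "provenance": self.provenance,
            "flags": ";".join(self.flags),
        }


@dataclass(frozen=True)
class PotencySummary:
    """BMC_min comparison for one mixture and worm type.

    ``log10_ratio`` is log10(predicted / experimental); ``None`` (NA)
    when either side has no active BMC.
    """

    mixture: str
    worm_type: str
    experimental_bmc_min: float | None
    predicted_bmc_min: float | None
    log10_ratio: float | None
    min_readout_experimental: str = ""
    min_readout_predicted: str = ""

    def to_row(self) -> dict:
        return {
            "mixture": self.mixture,
            "worm_type": self.worm_type,
            "experimental_bmc_min_uM": self.experimental_bmc_min,
            "predicted_bmc_min_uM": self.predicted_bmc_min,
            "log10_ratio": self.log10_ratio,
            "min_readout_experimental": self.min_readout_experimental,
            "min_readout_predicted": self.min_readout_predicted,
        }


def _observed_interval(observed):
    """(lb, ub, active) from a BMCEstimate or a (median, lb, ub) tuple."""
    if hasattr(observed, "bmc_median"):
        act = bool(observed.active)
        lb, ub = observed.bmc_lb, observed.bmc_ub
        med = observed.bmc_median
    else:
        med, lb, ub = observed
        act = med is not None and math.isfinite(float(med))
    if act:
        lb = float(med) if lb is None or not math.isfinite(float(lb)) else float(lb)
        ub = float(med) if ub is None or not math.isfinite(float(ub)) else float(ub)
        if lb > ub:
            raise ValueError(f"malformed observed interval [{lb}, {ub}]")
    return lb, ub, act


def _predicted_interval(predicted):
    if isinstance(predicted, CAPrediction):
        act = predicted.active
        lb = predicted.interval_lb if predicted.interval_lb is not None else predicted.bmc_mix
        ub = predicted.interval_ub if predicted.interval_ub is not None else predicted.bmc_mix
    else:
        med, lb, ub = predicted
        act = med is not None and math.isfinite(float(med))
        if act and (lb is None or not math.isfinite(float(lb))):
            lb = med
        if act and (ub is None or not math.isfinite(float(ub))):
            ub = med
    if act:
        lb, ub = float(lb), float(ub)
        if lb > ub:
            raise ValueError(f"malformed predicted interval [{lb}, {ub}]")
    return lb, ub, act


def classify(
    observed,
    predicted,
    mixture: str = "",
    readout: str = "",
    direction: str = "",
    worm_type: str = "",
    day: int = 0,
    tested_range: tuple | None = None,
) -> InteractionCall:
    """Interval-comparison interaction call for one readout.

    ``observed`` is a :class:`mixtox.bmc.BMCEstimate` (or a
    ``(median, lb, ub)`` tuple, NaN marking inactive); ``predicted`` a
    :class:`mixtox.loewe.CAPrediction` or tuple.  ``tested_range``
    optionally marks intervals spanning the full tested concentration
    range with a quality flag (they are still compared literally).
    """
    olb, oub, oact = _observed_interval(observed)
    plb, pub, pact = _predicted_interval(predicted)
    readout = readout or getattr(observed, "readout", "")
    direction = direction or getattr(observed, "direction", "")
    worm_type = worm_type or getattr(observed, "worm_type", "")
    day = day or getattr(observed, "day", 0)
    mixture = mixture or getattr(observed, "condition", "")

    flags = []
    if tested_range is not None and oact:
        lo, hi = tested_range
        if olb <= lo * 1.0000001 and oub >= hi * 0.9999999:
            flags.append("observed_ci_spans_range")

    if not oact and not pact:
        call, prov = NO_EFFECT, "none"
    elif oact and pact:
        if oub < plb:
            call, prov = SYNERGISTIC, "disjoint"
        elif olb > pub:
            call, prov = ANTAGONISTIC, "disjoint"
        else:
            call, prov = ADDITIVE, "overlap"
    elif oact:
        # an absent predicted BMC behaves as beyond the tested range:
        # observed < predicted, i.e. synergy
        call, prov = SYNERGISTIC, "one_sided"
    else:
        call, prov = ANTAGONISTIC, "one_sided"

    return InteractionCall(
        mixture=mixture,
        readout=readout,
        direction=direction,
        worm_type=worm_type,
        day=int(day),
        call=call,
        provenance=prov,
        observed=observed,
        predicted=predicted,
        flags=tuple(flags),
    )


def _active_minimum(items) -> tuple[float | None, str]:
    """(smallest active median, its readout label) over estimates/predictions."""
    best, label = None, ""
    for it in items:
        if isinstance(it, CAPrediction):
            act, val = it.active, it.bmc_mix
            name = ""
        elif hasattr(it, "bmc_median"):
            act, val = bool(it.active), it.bmc_median
            name = f"{it.readout}({it.direction})"
        else:  # (readout_label, value) pair or bare value
            if isinstance(it, tuple):
                name, val = it
            else:
                name, val = "", it
            act = val is not None and math.isfinite(float(val))
        if act and val is not None and math.isfinite(float(val)):
            if best is None or float(val) < best:
                best, label = float(val), name
    return best, label


def log10_potency_ratio(predicted_min, experimental_min) -> float:
    """log10(predicted BMC_min / experimental BMC_min); NaN when undefined."""
    for v in (predicted_min, experimental_min):
        if v is None or not math.isfinite(float(v)) or float(v) <= 0:
            return float("nan")
    return math.log10(float(predicted_min) / float(experimental_min))


def potency_summary(
    observed, predicted, mixture: str = "", worm_type: str = ""
) -> PotencySummary:
    """BMC_min and log10 discrepancy ratio across all readouts/directions.

    ``observed`` is an iterable of BMC estimates (or (label, value)
    pairs); ``predicted`` an iterable of CA predictions (or pairs).  NA
    propagates: if either side has no active value the ratio is None.
    """
    exp_min, exp_label = _active_minimum(observed)
    pred_min, pred_label = _active_minimum(predicted)
    if exp_min is None or pred_min is None:
        ratio = None
    else:
        ratio = log10_potency_ratio(pred_min, exp_min)
    return PotencySummary(
        mixture=mixture,
        worm_type=worm_type,
        experimental_bmc_min=exp_min,
        predicted_bmc_min=pred_min,
        log10_ratio=ratio,
        min_readout_experimental=exp_label,
        min_readout_predicted=pred_label,
    )


def heatmap_table(calls, readout_order=None) -> pd.DataFrame:
    """Tidy long table of interaction calls for heatmap-style rendering.

    Deterministic ordering: worm type, day, mixtures alphabetical,
    readouts in ``readout_order`` (default: the canonical screen panel
    order from :mod:`mixtox.datasets`), then direction.  Duplicate keys
    are rejected.
    """
    rows = [c.to_row() for c in calls]
    if not rows:
        return pd.DataFrame(
            columns=["worm_type", "day", "mixture", "readout", "direction", "call"]
        )
    df = pd.DataFrame(rows)
    key = ["worm_type", "day", "mixture", "readout", "direction"]
    if df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)][key]
        raise ValueError(f"duplicate call keys:\n{dupes.to_string(index=False)}")
    if readout_order is None:
        from .datasets import READOUT_ORDER

        readout_order = READOUT_ORDER
    order = {r: i for i, r in enumerate(readout_order)}
    df["_r"] = df["readout"].map(lambda r: order.get(r, len(order)))
    df = df.sort_values(["worm_type", "day", "mixture", "_r", "direction"])
    df = df.drop(columns=["_r"]).reset_index(drop=True)
    return df[key + ["call", "provenance", "flags"]]
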