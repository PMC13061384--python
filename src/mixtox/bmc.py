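"""Benchmark-concentration (BMC) estimation with bootstrap confidence limits.

A benchmark concentration is the concentration at which a readout's
response first crosses its benchmark response (BMR), the per-readout
magnitude that defines an adverse effect.  The estimator here follows
the Curvep family of pipelines in spirit -- bootstrap over animals,
optional monotonisation of the concentration-response series, and a
first-crossing search with linear interpolation in log10 concentration --
but is an independent re-implementation; numeric parity with any
external package is not claimed.

Procedure per (readout, direction) series:

1. resample animals with replacement within each concentration group
   (solvent controls included);
2. recompute the per-concentration response summary: percent of animals
   responding for incidence readouts, signed percent change of the mean
   from the control mean for continuous readouts (the sign is aligned
   with the direction under test, so responses in the opposite direction
   are negative and never cross);
3. optionally enforce a non-decreasing response in concentration by
   pool-adjacent-violators (PAV);
4. scan concentrations low to high for the first crossing of the BMR and
   interpolate linearly in log10(concentration); a series that never
   reaches the BMR contributes an "inactive" iteration.

The reported BMC is the median over the finite bootstrap crossings, with
5th/95th percentile limits; the hit confidence is the fraction of
iterations yielding a finite crossing.  An estimate is "active" when the
median is finite, lies within the tested range and the hit confidence
reaches the threshold (default 0.5).

Animals scored dead contribute only to the lethality readout: their
other records are excluded before summarising (the screen's manual
lethality call masks behavior of dead animals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BMRSpec",
    "BMCEstimate",
    "BMCResults",
    "BenchmarkConcentrationModel",
    "normalize_responses",
    "estimate_bmc",
    "bmr_crossing",
    "mask_dead_animals",
    "pav_increasing",
]

LETHALITY_READOUT = "lethality"
_CONTROL_EPS = 1e-12


@dataclass(frozen=True)
class BMRSpec:
    """Benchmark response for one (readout, worm type, day, direction)."""

    readout: str
    worm_type: str
    day: int
    direction: str  # '+' or '-'
    bmr: float
    is_incidence: bool = False

    def __post_init__(self):
        if not self.bmr > 0:
            raise ValueError("BMR must be positive")
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")


@dataclass(frozen=True)
class BMCEstimate:
    """Bootstrap BMC for one readout/direction series.

    ``bmc_median`` is NaN when the series is inactive; limits are the
    5th/95th percentiles over finite bootstrap crossings.
    """

    readout: str
    direction: str
    bmc_median: float
    bmc_lb: float
    bmc_ub: float
    hit_confidence: float
    active: bool
    n_boot: int
    condition: str = ""
    worm_type: str = ""
    day: int = 0
    bmr: float = np.nan
    flags: tuple = field(default=())

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "worm_type": self.worm_type,
            "day": self.day,
            "readout": self.readout,
            "direction": self.direction,
            "bmr": self.bmr,
            "bmc_median_uM": self.bmc_median,
            "bmc_lb_uM": self.bmc_lb,
            "bmc_ub_uM": self.bmc_ub,
            "hit_confidence": self.hit_confidence,
            "active": self.active,
            "n_boot": self.n_boot,
            "flags": ";".join(self.flags),
        }


# ---------------------------------------------------------------------------
# response normalisation
# ---------------------------------------------------------------------------


def mask_dead_animals(records: pd.DataFrame) -> pd.DataFrame:
    """Drop non-lethality records of animals scored dead.

    A well whose lethality record is 1 contributes only to lethality.
    """
    if LETHALITY_READOUT not in set(records["readout"]):
        return records
    key = ["condition", "worm_type", "day", "plate_id", "well_id"]
    leth = records[records["readout"] == LETHALITY_READOUT]
    dead = leth.loc[leth["value"] >= 1, key].drop_duplicates()
    if dead.empty:
        return records
    merged = records.merge(dead.assign(_dead=True), on=key, how="left")
    keep = (merged["_dead"].isna()) | (merged["readout"] == LETHALITY_READOUT)
    return records[keep.to_numpy()]


def normalize_responses(records: pd.DataFrame, mask_dead: bool = True) -> pd.DataFrame:
    """Per-concentration response summaries from animal-level records.

    Incidence readouts become the percent of animals responding per
    concentration; continuous readouts the signed percent change of the
    per-concentration mean from the pooled in-plate control mean, emitted
    once per direction ('+' keeps the sign, '-' flips it, so each series
    reports the magnitude of change in its own direction).

    Raises on missing solvent controls; flags (and skips) continuous
    readouts whose control mean is zero.
    """
    _require_columns(records)
    if mask_dead:
        records = mask_dead_animals(records)
    out = []
    unusable = []
    for (condition, worm, day, readout), grp in records.groupby(
        ["condition", "worm_type", "day", "readout"], sort=True
    ):
        is_inc = bool(grp["is_incidence"].iloc[0])
        controls = grp[grp["concentration_uM"] == 0]
        treated = grp[grp["concentration_uM"] > 0]
        if controls.empty:
            raise ValueError(
                f"no solvent controls for {condition}/{worm}/d{day}/{readout}"
            )
        if is_inc:
            series = treated.groupby("concentration_uM")["value"]
            for conc, vals in series:
                out.append(
                    (condition, worm, day, readout, "+", conc,
                     100.0 * vals.mean(), len(vals))
                )
        else:
            ctrl_mean = controls["value"].mean()
            if abs(ctrl_mean) < _CONTROL_EPS:
                unusable.append((condition, worm, day, readout))
                continue
            series = treated.groupby("concentration_uM")["value"]
            for conc, vals in series:
                pct = 100.0 * (vals.mean() - ctrl_mean) / ctrl_mean
                for direction, signed in (("+", pct), ("-", -pct)):
                    out.append(
                        (condition, worm, day, readout, direction, conc,
                         signed, len(vals))
                    )
    df = pd.DataFrame(
        out,
        columns=[
            "condition", "worm_type", "day", "readout", "direction",
            "concentration_uM", "response", "n",
        ],
    )
    df.attrs["unusable"] = unusable
    return df


def _require_columns(records: pd.DataFrame):
    needed = {
        "condition", "concentration_uM", "worm_type", "day",
        "readout", "value", "is_incidence",
    }
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records are missing columns: {sorted(missing)}")


# ---------------------------------------------------------------------------
# monotonisation and crossing search
# ---------------------------------------------------------------------------


def pav_increasing(rows: np.ndarray) -> np.ndarray:
    """Row-wise pool-adjacent-violators, non-decreasing, uniform weights.

    ``rows`` is (m, k); each row is replaced by its least-squares
    monotone (non-decreasing) fit.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    m, k = rows.shape
    out = np.empty_like(rows)
    for i in range(m):
        # classic stack-based PAV; k is small (number of concentrations)
        means: list[float] = []
        counts: list[int] = []
        for v in rows[i]:
            means.append(float(v))
            counts.append(1)
            while len(means) > 1 and means[-2] > means[-1]:
                m2, c2 = means.pop(), counts.pop()
                m1, c1 = means.pop(), counts.pop()
                means.append((m1 * c1 + m2 * c2) / (c1 + c2))
                counts.append(c1 + c2)
        pos = 0
        for mv, cv in zip(means, counts):
            out[i, pos : pos + cv] = mv
            pos += cv
    return out


def bmr_crossing(concentrations, responses, bmr: float) -> float:
    """First BMR crossing, scanning low to high, log-linear interpolation.

    Returns NaN when the series never reaches the BMR.  A response
    exactly equal to the BMR at a tested concentration yields that
    concentration; if the lowest tested concentration already exceeds the
    BMR the crossing is reported at that concentration (no extrapolation
    below the tested range).
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    return float(_crossings(conc, resp[None, :], float(bmr))[0])


def _crossings(conc: np.ndarray, R: np.ndarray, bmr: float) -> np.ndarray:
    """Vectorised first-crossing search over bootstrap rows R (m, k)."""
    logc = np.log10(conc)
    hit = R >= bmr
    any_hit = hit.any(axis=1)
    first = np.where(any_hit, hit.argmax(axis=1), -1)
    out = np.full(R.shape[0], np.nan)

    at_floor = any_hit & (first == 0)
    out[at_floor] = conc[0]

    interp = any_hit & (first > 0)
    if np.any(interp):
        j = first[interp]
        r_hi = R[interp, j]
        r_lo = R[interp, j - 1]
        frac = (bmr - r_lo) / (r_hi - r_lo)
        logbmc = logc[j - 1] + frac * (logc[j] - logc[j - 1])
        out[interp] = 10.0**logbmc
    return out


# ---------------------------------------------------------------------------
# bootstrap estimator
# ---------------------------------------------------------------------------


def _series_arrays(records: pd.DataFrame, readout: str):
    """Animal-level value arrays per concentration plus controls."""
    grp = records[records["readout"] == readout]
    if grp.empty:
        raise ValueError(f"no records for readout {readout!r}")
    is_inc = bool(grp["is_incidence"].iloc[0])
    controls = grp.loc[grp["concentration_uM"] == 0, "value"].to_numpy(float)
    conc = np.sort(grp.loc[grp["concentration_uM"] > 0, "concentration_uM"].unique())
    values = [
        grp.loc[grp["concentration_uM"] == c, "value"].to_numpy(float) for c in conc
    ]
    return conc, values, controls, is_inc


def estimate_bmc(
    records: pd.DataFrame,
    bmr: BMRSpec,
    n_boot: int = 1000,
    seed: int | None = None,
    monotonize: bool = True,
    hit_threshold: float = 0.5,
    mask_dead: bool = True,
) -> BMCEstimate:
    """Bootstrap BMC for one readout/direction series of one condition.

    ``records`` must hold the animal-level screen records of a single
    (condition, worm type, day); the readout and direction under test
    come from ``bmr``.
    """
    _require_columns(records)
    sub = records[
        (records["worm_type"] == bmr.worm_type) & (records["day"] == bmr.day)
    ]
    conditions = sub["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(
            f"estimate_bmc expects exactly one condition, got {list(conditions)}"
        )
    if mask_dead and bmr.readout != LETHALITY_READOUT:
        sub = mask_dead_animals(sub)
    conc, values, controls, is_inc = _series_arrays(sub, bmr.readout)
    if is_inc != bmr.is_incidence:
        raise ValueError(
            f"readout kind mismatch for {bmr.readout!r}: records say "
            f"is_incidence={is_inc}, BMR spec says {bmr.is_incidence}"
        )
    if conc.size < 4:
        raise ValueError("need at least 4 positive concentrations")
    if not is_inc and controls.size == 0:
        raise ValueError("continuous readouts require solvent controls")

    flags = []
    if n_boot < 100:
        flags.append("low_n_boot")

    # drop concentration groups emptied by the lethality mask
    keep = [len(v) > 0 for v in values]
    if not all(keep):
        flags.append("empty_concentration_groups")
        conc = conc[np.asarray(keep)]
        values = [v for v, k in zip(values, keep) if k]

    rng = np.random.default_rng(seed)
    sign = 1.0 if bmr.direction == "+" else -1.0
    m, k = n_boot, conc.size

    cols = np.empty((m, k))
    for j, v in enumerate(values):
        idx = rng.integers(0, v.size, size=(m, v.size))
        cols[:, j] = v[idx].mean(axis=1)
    if is_inc:
        R = 100.0 * cols
    else:
        cidx = rng.integers(0, controls.size, size=(m, controls.size))
        ctrl = controls[cidx].mean(axis=1)
        bad = np.abs(ctrl) < _CONTROL_EPS
        ctrl[bad] = np.nan
        R = sign * 100.0 * (cols - ctrl[:, None]) / ctrl[:, None]

    if monotonize:
        R = pav_increasing(R)
    bmcs = _crossings(conc, R, bmr.bmr)

    finite = np.isfinite(bmcs)
    hit_confidence = float(finite.mean())
    if finite.any():
        med = float(np.median(bmcs[finite]))
        lb = float(np.percentile(bmcs[finite], 5))
        ub = float(np.percentile(bmcs[finite], 95))
    else:
        med = lb = ub = float("nan")
    active = (
        math.isfinite(med)
        and med <= conc.max()
        and hit_confidence >= hit_threshold
    )
    if math.isfinite(lb) and math.isfinite(ub):
        if lb <= conc.min() * 1.0000001 and ub >= conc.max() * 0.9999999:
            flags.append("ci_spans_range")
    return BMCEstimate(
        readout=bmr.readout,
        direction=bmr.direction,
        bmc_median=med,
        bmc_lb=lb,
        bmc_ub=ub,
        hit_confidence=hit_confidence,
        active=bool(active),
        n_boot=n_boot,
        condition=str(conditions[0]),
        worm_type=bmr.worm_type,
        day=bmr.day,
        bmr=bmr.bmr,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------


class BenchmarkConcentrationModel:
    """BMC estimation over a full screen record table.

    Pairs every (condition, worm type, day, readout, direction) present
    in the records with its benchmark response from ``bmr_table`` (long
    format with columns readout/worm_type/day/direction/bmr/is_incidence,
    as returned by :func:`mixtox.datasets.load_benchmark_responses`) and
    bootstraps a BMC for each.
    """

    def __init__(self, records: pd.DataFrame, bmr_table: pd.DataFrame,
                 mask_dead: bool = True):
        _require_columns(records)
        self.records = records
        self.bmr_table = bmr_table
        self.mask_dead = mask_dead

    def _specs_for(self, worm_type: str, day: int, readout: str) -> list[BMRSpec]:
        t = self.bmr_table
        sel = t[
            (t["worm_type"] == worm_type)
            & (t["day"] == day)
            & (t["readout"] == readout)
        ]
        return [
            BMRSpec(
                readout=row["readout"],
                worm_type=row["worm_type"],
                day=int(row["day"]),
                direction=row["direction"],
                bmr=float(row["bmr"]),
                is_incidence=bool(row["is_incidence"]),
            )
            for _, row in sel.iterrows()
        ]

    def fit(
        self,
        n_boot: int = 1000,
        seed: int | None = None,
        monotonize: bool = True,
        hit_threshold: float = 0.5,
    ) -> "BMCResults":
        rng = np.random.default_rng(seed)
        estimates = []
        keys = (
            self.records[["condition", "worm_type", "day", "readout"]]
            .drop_duplicates()
            .sort_values(["condition", "worm_type", "day", "readout"])
        )
        for _, key in keys.iterrows():
            specs = self._specs_for(key["worm_type"], int(key["day"]), key["readout"])
            sub = self.records[
                (self.records["condition"] == key["condition"])
                & (self.records["worm_type"] == key["worm_type"])
                & (self.records["day"] == key["day"])
            ]
            for spec in specs:
                estimates.append(
                    estimate_bmc(
                        sub,
                        spec,
                        n_boot=n_boot,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        monotonize=monotonize,
                        hit_threshold=hit_threshold,
                        mask_dead=self.mask_dead,
                    )
                )
        return BMCResults(estimates, n_boot=n_boot)


class BMCResults:
    """Collection of per-series BMC estimates with tidy export."""

    def __init__(self, estimates: Sequence[BMCEstimate], n_boot: int):
        self.estimates = list(estimates)
        self.n_boot = n_boot

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_row() for e in self.estimates])

    def get(self, condition=None, readout=None, direction=None,
            worm_type=None, day=None) -> BMCEstimate:
        """The unique estimate matching the given key fields."""
        hits = [
            e
            for e in self.estimates
            if (condition is None or e.condition == condition)
            and (readout is None or e.readout == readout)
            and (direction is None or e.direction == direction)
            and (worm_type is None or e.worm_type == worm_type)
            and (day is None or e.day == day)
        ]
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one estimate, found {len(hits)} for "
                f"{(condition, readout, direction, worm_type, day)}"
            )
        return hits[0]

    def summary(self) -> str:
        df = self.frame
        active = int(df["active"].sum()) if len(df) else 0
        lines = [
            f"Benchmark concentrations ({len(df)} series, n_boot={self.n_boot})",
            f"active: {active} / {len(df)}",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
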