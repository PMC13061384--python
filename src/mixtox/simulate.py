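"""Synthetic planarian screening and AChE assay data with known ground truth.

The generator emulates the design of a behavioral high-throughput screen
in adult and regenerating planarians: 48-well plates holding one animal
per well, five test concentrations per plate (one row of 8 wells each)
plus one row of in-plate solvent controls, three replicate plates per
condition and worm type (n = 24 animals per concentration), at least
five concentrations spanning 0.1-10 uM in semi-log steps, and a panel of
readouts that are either incidence-type (per-animal binary outcomes such
as lethality, stickiness, scrunching failure) or continuous (speed,
resting fraction, etc.).

Every simulated agent follows log-logistic concentration-response curves
per readout; binary mixtures follow either exact Loewe additivity (the
per-effect-level isobole is solved numerically, valid for unequal Hill
slopes) or a potency-shift deviation in which both components' effective
concentrations are multiplied by a shift factor (> 1 synergy, < 1
antagonism).  The noise model is a choice, not a measured property:
Bernoulli sampling for incidence readouts and additive Gaussian noise for
continuous readouts.

All randomness flows through a single integer seed; identical inputs and
seed give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .loewe import isobole_inhibition, loewe_mixture_response

__all__ = [
    "AgentTruth",
    "InteractionTruth",
    "ScreenDesign",
    "simulate_single_agent",
    "simulate_mixture",
    "simulate_ache_assay",
    "expected_single_response",
    "expected_mixture_response",
    "truth_to_dict",
]

SEMILOG_CONCENTRATIONS = (0.1, 0.316, 1.0, 3.16, 10.0)
WELLS_PER_ROW = 8

SCREEN_COLUMNS = [
    "condition",
    "concentration_uM",
    "worm_type",
    "day",
    "plate_id",
    "well_id",
    "readout",
    "direction",
    "value",
    "is_incidence",
]


@dataclass(frozen=True)
class AgentTruth:
    """Ground-truth concentration-response parameters for one agent.

    Per-readout maps must share an identical key set.  ``max_effect`` is
    on the response scale used downstream: percent of animals for
    incidence readouts (<= 100) and percent change from control for
    continuous readouts (may exceed 100 for increases).  ``direction``
    gives the sign of the continuous effect ('+' increase, '-' decrease;
    incidence readouts use '+').
    """

    name: str
    ec50: Mapping[str, float]
    hill: Mapping[str, float]
    max_effect: Mapping[str, float]
    direction: Mapping[str, str]
    is_incidence: Mapping[str, bool]
    ache_ic50: float = 1.0
    ache_hill: float = 2.0

    def __post_init__(self):
        keys = set(self.ec50)
        for attr in ("hill", "max_effect", "direction", "is_incidence"):
            if set(getattr(self, attr)) != keys:
                raise ValueError(f"per-readout map {attr!r} does not match ec50 keys")
        for r in keys:
            if not self.ec50[r] > 0:
                raise ValueError(f"EC50 for {r!r} must be positive")
            if not self.hill[r] > 0:
                raise ValueError(f"Hill slope for {r!r} must be positive")
            if self.is_incidence[r] and self.max_effect[r] > 100:
                raise ValueError(f"incidence max effect for {r!r} exceeds 100%")
            if self.direction[r] not in ("+", "-"):
                raise ValueError(f"direction for {r!r} must be '+' or '-'")
        if not (self.ache_ic50 > 0 and self.ache_hill > 0):
            raise ValueError("AChE IC50 and Hill slope must be positive")

    @property
    def readouts(self) -> tuple:
        return tuple(self.ec50)


@dataclass(frozen=True)
class InteractionTruth:
    """Ground-truth interaction model for a simulated binary mixture.

    ``loewe_additive`` is the additive null (shift factor forced to 1);
    ``potency_shift`` divides both components' effective concentrations
    (equivalently their ECx) by ``shift_factor`` for the readouts named
    in ``applies_to`` ('all' or a set of readout names).
    """

    model: str = "loewe_additive"
    shift_factor: float = 1.0
    applies_to: object = "all"

    def __post_init__(self):
        if self.model not in ("loewe_additive", "potency_shift"):
            raise ValueError(f"unknown interaction model {self.model!r}")
        if not self.shift_factor > 0:
            raise ValueError("shift_factor must be positive")
        if self.model == "loewe_additive" and self.shift_factor != 1.0:
            raise ValueError("loewe_additive requires shift_factor = 1")
        if self.applies_to != "all":
            object.__setattr__(self, "applies_to", frozenset(self.applies_to))

    def shift_for(self, readout: str) -> float:
        if self.applies_to == "all" or readout in self.applies_to:
            return self.shift_factor
        return 1.0


@dataclass(frozen=True)
class ScreenDesign:
    """Plate layout and noise settings of the simulated screen."""

    concentrations: Sequence[float] = SEMILOG_CONCENTRATIONS
    replicate_plates: int = 3
    worm_types: Sequence[str] = ("adult", "regenerating")
    days: Sequence[int] = (7, 12)
    noise_sd_continuous: float = 0.1
    control_baseline: float = 1.0
    plate_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 2 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.replicate_plates < 1:
            raise ValueError("need at least one replicate plate")

    @property
    def n_per_concentration(self) -> int:
        # 8 wells per concentration row on each plate
        return WELLS_PER_ROW * self.replicate_plates


def _fraction_of_max(c, ec50, hill):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        f = np.where(c > 0, 1.0 / (1.0 + (ec50 / np.where(c > 0, c, 1.0)) ** hill), 0.0)
    return f


def expected_single_response(truth: AgentTruth, readout: str, c):
    """Noise-free expected response (% scale) of one readout at concentration c."""
    return truth.max_effect[readout] * _fraction_of_max(
        c, truth.ec50[readout], truth.hill[readout]
    )


def expected_mixture_response(
    truthA: AgentTruth,
    truthB: AgentTruth,
    readout: str,
    c,
    interaction: InteractionTruth = InteractionTruth(),
):
    """Noise-free expected equimolar-mixture response at per-component c.

    Solves the Loewe isobole numerically on the response scale; under
    ``potency_shift`` both ECx curves are divided by the shift factor
    first.  Returns ``(response, capped)`` where ``capped`` marks
    concentrations at which the isobole could only be satisfied above the
    smaller of the two maximal effects.
    """
    s = interaction.shift_for(readout)
    curveA = (truthA.ec50[readout] / s, truthA.hill[readout], truthA.max_effect[readout])
    curveB = (truthB.ec50[readout] / s, truthB.hill[readout], truthB.max_effect[readout])
    return loewe_mixture_response(c, c, curveA, curveB)


def _emit_records(
    condition: str,
    readouts_meta: Mapping[str, tuple],  # readout -> (direction, is_incidence, c -> (resp, capped))
    design: ScreenDesign,
    seed: int | None,
) -> pd.DataFrame:
    """Shared plate-level record generation for single agents and mixtures."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    conc = np.asarray(design.concentrations, dtype=float)
    rows = {k: [] for k in SCREEN_COLUMNS}
    capped_readouts = set()

    for worm_type in design.worm_types:
        for day in design.days:
            for plate in range(1, design.replicate_plates + 1):
                plate_id = f"{worm_type[:3]}-d{day}-P{plate}"
                for readout, (direction, is_inc, resp_fn) in readouts_meta.items():
                    offset = (
                        rng.normal(0.0, design.plate_offset_sd)
                        if design.plate_offset_sd > 0
                        else 0.0
                    )
                    # concentration rows + one control row of 8 wells
                    all_conc = np.concatenate([[0.0], conc])
                    for row_idx, c in enumerate(all_conc):
                        if c > 0:
                            resp, capped = resp_fn(c)
                            if capped:
                                capped_readouts.add(readout)
                        else:
                            resp = 0.0
                        if is_inc:
                            p = min(max(resp / 100.0, 0.0), 1.0)
                            values = rng.binomial(1, p, WELLS_PER_ROW).astype(float)
                        else:
                            sign = 1.0 if direction == "+" else -1.0
                            mean = design.control_baseline * (1.0 + sign * resp / 100.0)
                            values = mean + offset + rng.normal(
                                0.0, design.noise_sd_continuous, WELLS_PER_ROW
                            )
                        for well, v in enumerate(values, start=1):
                            rows["condition"].append(condition)
                            rows["concentration_uM"].append(c)
                            rows["worm_type"].append(worm_type)
                            rows["day"].append(day)
                            rows["plate_id"].append(plate_id)
                            rows["well_id"].append(f"R{row_idx}W{well}")
                            rows["readout"].append(readout)
                            rows["direction"].append(direction)
                            rows["value"].append(float(v))
                            rows["is_incidence"].append(bool(is_inc))
    df = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    df.attrs["capped_readouts"] = sorted(capped_readouts)
    return df


def simulate_single_agent(
    truth: AgentTruth, design: ScreenDesign, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the full plate-level screen for a single agent.

    Returns a long-format record table (one row per animal x readout)
    including in-plate solvent controls (concentration 0, 8 per plate).
    """
    meta = {}
    for r in truth.readouts:
        def resp_fn(c, _r=r):
            return float(expected_single_response(truth, _r, c)), False

        meta[r] = (truth.direction[r], truth.is_incidence[r], resp_fn)
    return _emit_records(truth.name, meta, design, seed)


def simulate_mixture(
    truthA: AgentTruth,
    truthB: AgentTruth,
    interaction: InteractionTruth,
    design: ScreenDesign,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the screen for the equimolar binary mixture "A.B".

    ``concentration_uM`` is the per-component concentration: each well
    contains both agents at that concentration.  Readout panels of the
    two agents must match.  Readouts for which the Loewe effect level was
    capped at the smaller maximal effect are listed in
    ``df.attrs['capped_readouts']``.
    """
    if set(truthA.readouts) != set(truthB.readouts):
        raise ValueError("mixture components must share the same readout panel")
    meta = {}
    for r in truthA.readouts:
        if truthA.is_incidence[r] != truthB.is_incidence[r]:
            raise ValueError(f"readout {r!r} kind differs between components")
        if truthA.direction[r] != truthB.direction[r]:
            raise ValueError(f"readout {r!r} direction differs between components")

        def resp_fn(c, _r=r):
            resp, capped = expected_mixture_response(truthA, truthB, _r, c, interaction)
            return float(resp), bool(capped)

        meta[r] = (truthA.direction[r], truthA.is_incidence[r], resp_fn)
    condition = f"{truthA.name}.{truthB.name}"
    return _emit_records(condition, meta, design, seed)


def simulate_ache_assay(
    truths: Sequence[AgentTruth],
    concentrations: Sequence[float],
    fractions: Sequence[float] | None = None,
    replicates: int = 3,
    noise_sd: float = 5.0,
    seed: int = 0,
    clip: bool = False,
    noise_scale: str = "activity",
) -> pd.DataFrame:
    """Simulate an Ellman-style AChE activity assay.

    Parameters
    ----------
    truths : one AgentTruth (single agent) or two (binary mixture).
    concentrations : total chemical concentration per sample, uM.  For a
        mixture this is the *total* concentration split by ``fractions``.
    fractions : mixing fractions summing to 1 (required for two agents).
    replicates : technical replicates per concentration (default 3).
    noise_sd : Gaussian noise amplitude; percent-activity units when
        ``noise_scale='activity'``, natural-log logit units when
        ``noise_scale='logit'`` (noise added to the logit of inhibition).
    clip : clip activities into [0, 100] (default off; raw values are
        kept and the choice recorded in ``df.attrs``).

    Expected activity is ``100/(1 + (C/IC50)^h)`` for a single agent; for
    a mixture the inhibition at each total concentration solves the Loewe
    isobole of the two single-agent curves.
    """
    truths = list(truths)
    if len(truths) == 1:
        fractions = (1.0,)
    elif len(truths) == 2:
        if fractions is None:
            raise ValueError("fractions are required for a two-agent mixture")
        if abs(sum(float(f) for f in fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
    else:
        raise ValueError("simulate_ache_assay takes one or two agents")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("assay concentrations must be positive")

    if len(truths) == 1:
        t = truths[0]
        inhibition = 100.0 - 100.0 / (1.0 + (conc / t.ache_ic50) ** t.ache_hill)
        condition = t.name
    else:
        a, b = truths
        inhibition = isobole_inhibition(
            conc,
            (a.ache_ic50, a.ache_hill),
            (b.ache_ic50, b.ache_hill),
            float(fractions[0]),
            float(fractions[1]),
        )
        condition = f"{a.name}.{b.name}"

    rng = np.random.default_rng(seed)
    rows = []
    for c, inh in zip(conc, np.atleast_1d(inhibition)):
        for rep in range(1, replicates + 1):
            if noise_scale == "activity":
                act = (100.0 - inh) + rng.normal(0.0, noise_sd)
            elif noise_scale == "logit":
                q = min(max(inh / 100.0, 1e-12), 1.0 - 1e-12)
                y = math.log(q / (1.0 - q)) + rng.normal(0.0, noise_sd)
                act = 100.0 - 100.0 / (1.0 + math.exp(-y))
            else:
                raise ValueError(f"unknown noise_scale {noise_scale!r}")
            if clip:
                act = min(max(act, 0.0), 100.0)
            rows.append(
                {
                    "condition": condition,
                    "concentration_uM": float(c),
                    "replicate": rep,
                    "percent_activity": float(act),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["clipped"] = clip
    df.attrs["noise_scale"] = noise_scale
    df.attrs["fractions"] = tuple(float(f) for f in fractions)
    return df


def truth_to_dict(
    truth: AgentTruth,
    interaction: InteractionTruth | None = None,
    design: ScreenDesign | None = None,
) -> dict:
    """JSON-serialisable ground-truth bundle for companion truth files."""
    out = {
        "agent": {
            "name": truth.name,
            "ec50_uM": dict(truth.ec50),
            "hill": dict(truth.hill),
            "max_effect_pct": dict(truth.max_effect),
            "direction": dict(truth.direction),
            "is_incidence": {k: bool(v) for k, v in truth.is_incidence.items()},
            "ache_ic50_uM": truth.ache_ic50,
            "ache_hill": truth.ache_hill,
        }
    }
    if interaction is not None:
        out["interaction"] = {
            "model": interaction.model,
            "shift_factor": interaction.shift_factor,
            "applies_to": (
                "all"
                if interaction.applies_to == "all"
                else sorted(interaction.applies_to)
            ),
        }
    if design is not None:
        out["design"] = {
            "concentrations_uM": [float(c) for c in design.concentrations],
            "replicate_plates": design.replicate_plates,
            "n_per_concentration": design.n_per_concentration,
            "worm_types": list(design.worm_types),
            "days": [int(d) for d in design.days],
            "noise_sd_continuous": design.noise_sd_continuous,
            "control_baseline": design.control_baseline,
            "plate_offset_sd": design.plate_offset_sd,
            "seed": design.seed,
        }
    return out
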