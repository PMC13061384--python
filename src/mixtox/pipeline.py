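"""End-to-end orchestration: simulate -> normalise -> BMC -> predict -> classify.

The pipeline ties the stages into one reproducible run driven by a
:class:`PipelineConfig` (constructed in code or from a TOML file).  Every
stochastic stage receives an explicit seed derived from the config seed,
all stage tables are written as CSV, and a JSON report plus a plain-text
log (including fixture checksums and seeds) make a run self-describing.
Re-running with the same config reproduces all outputs byte for byte.

Bundled scenarios
-----------------
``sham``
    An agent mixed with itself under exact Loewe additivity -- the
    classic self-test: every active readout should be called additive.
``synergy``
    The same screen with a 10-fold potency shift on a subset of
    readouts; those readouts should be called synergistic.
``bmc-min-replication``
    Recomputes the log10(predicted/experimental) BMC_min discrepancy
    ratios from the packaged published table.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, io
from .bmc import BenchmarkConcentrationModel
from .interactions import classify, heatmap_table, log10_potency_ratio, potency_summary
from .loewe import predict_interval
from .simulate import (
    AgentTruth,
    InteractionTruth,
    ScreenDesign,
    simulate_mixture,
    simulate_single_agent,
    truth_to_dict,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "demo_agent_truth",
    "demo_design",
    "demo_ache_agents",
    "demo_ache_concentrations",
    "DEMO_SHIFTED_READOUTS",
]


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained on disk."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``scenario`` names a bundled scenario or ``screen_csv`` points
    at an input screen table.  All thresholds carry their defaults from
    the analysis conventions: 1000 bootstrap iterations, hit-confidence
    threshold 0.5, 10 uM prediction cap, alpha 0.05.
    """

    scenario: str | None = None
    screen_csv: str | None = None
    mixture_csv: str | None = None
    outdir: str = "mixtox-out"
    n_boot: int = 1000
    seed: int = 0
    hit_threshold: float = 0.5
    cap_uM: float = 10.0
    alpha: float = 0.05
    monotonize: bool = True
    shift_factor: float = 10.0  # used by the synergy scenario

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")
        if not 0 <= self.hit_threshold <= 1:
            raise ValueError("hit_threshold must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cap_uM <= 0:
            raise ValueError("cap_uM must be positive")
        if self.scenario is None and self.screen_csv is None:
            raise ValueError("either a scenario or a screen CSV is required")


#: readouts the bundled synergy scenario shifts by ``shift_factor``
DEMO_SHIFTED_READOUTS = ("stickiness", "speed_dark")


def demo_agent_truth(name: str = "AgentA") -> AgentTruth:
    """Ground truth of the bundled demonstration screen.

    Four adult day-12 readouts spanning both readout kinds, with EC50s
    placed inside the 0.1-10 uM tested range so that single-agent,
    additive-mixture and 10-fold-shifted BMCs all stay on-scale.
    """
    return AgentTruth(
        name=name,
        ec50={"lethality": 5.0, "stickiness": 3.16, "speed_dark": 3.0,
              "resting_dark": 1.5},
        hill={"lethality": 2.0, "stickiness": 2.0, "speed_dark": 2.0,
              "resting_dark": 2.0},
        max_effect={"lethality": 100.0, "stickiness": 100.0, "speed_dark": 80.0,
                    "resting_dark": 150.0},
        direction={"lethality": "+", "stickiness": "+", "speed_dark": "-",
                   "resting_dark": "+"},
        is_incidence={"lethality": True, "stickiness": True, "speed_dark": False,
                      "resting_dark": False},
        ache_ic50=1.0,
        ache_hill=2.0,
    )


def demo_design(seed: int = 0) -> ScreenDesign:
    """Adult day-12 arm of the screen design.

    Continuous noise is set to a per-animal CV of 15% of the control
    baseline -- the low end of what behavioral readouts show in practice.
    Appreciable animal-level variability is part of the study conditions:
    with (unrealistically) noiseless continuous data the bootstrap
    intervals collapse below the log-interpolation discretisation of the
    semi-log concentration grid and interval comparisons degenerate.
    """
    return ScreenDesign(
        worm_types=("adult",),
        days=(12,),
        noise_sd_continuous=0.15,
        seed=seed,
    )


def demo_ache_agents(shift_factor: float = 1.0) -> tuple[AgentTruth, AgentTruth]:
    """Two AChE-inhibiting agents for the enzyme-assay demonstrations.

    IC50s of 1 and 13.6 uM (a CPO/MALO-like potency gap) with Hill slope
    2 -- steep curves typical of oxon inhibition.  ``shift_factor``
    divides both IC50s, emulating a potency-shift (synergistic) mixture.
    """
    kw = dict(ec50={"x": 1.0}, hill={"x": 1.0}, max_effect={"x": 100.0},
              direction={"x": "+"}, is_incidence={"x": True}, ache_hill=2.0)
    a = AgentTruth(name="OxA", ache_ic50=1.0 / shift_factor, **kw)
    b = AgentTruth(name="OxB", ache_ic50=13.6 / shift_factor, **kw)
    return a, b


def demo_ache_concentrations(n: int = 8) -> np.ndarray:
    """Total-mixture assay grid: n log-spaced points over 1/8x to 8x the
    CA-predicted mixture IC50 of :func:`demo_ache_agents`.

    The span keeps the additive mixture's true inhibition strictly inside
    the 0.5-99.5% quantifiable band at Hill slope 2, so logit observations
    are free of deterministic clipping.
    """
    from .loewe import predict_mixture_icp

    a, b = demo_ache_agents()
    ic50mix = predict_mixture_icp(
        (a.ache_ic50, a.ache_hill), (b.ache_ic50, b.ache_hill), 50, 0.5, 0.5
    )
    return np.geomspace(ic50mix / 8.0, ic50mix * 8.0, n)


def _log(lines: list, msg: str):
    lines.append(msg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run; returns the report dict.

    Writes stage CSVs, ``report.json`` and ``run.log`` under
    ``config.outdir``.  On stage failure the outputs written so far are
    retained and :class:`PipelineError` is raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    report: dict = {"config": dataclasses.asdict(config)}
    _log(log, f"config: {dataclasses.asdict(config)}")
    _log(log, f"fixture checksums: {datasets.fixture_checksums()}")

    try:
        if config.scenario == "bmc-min-replication":
            _replicate_bmc_min(config, outdir, report, log)
        elif config.scenario in ("sham", "synergy") or config.screen_csv:
            _screen_pipeline(config, outdir, report, log)
        else:
            raise PipelineError(f"unknown scenario {config.scenario!r}")
    except PipelineError:
        raise
    except Exception as exc:  # retain partial outputs, surface the stage failure
        (outdir / "run.log").write_text("\n".join(log + [f"FAILED: {exc}"]) + "\n")
        raise PipelineError(str(exc)) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return report


def _replicate_bmc_min(config, outdir, report, log):
    out = datasets.published_ratio_consistency()
    # cross-check the ratio arithmetic against the interaction module
    check = [
        log10_potency_ratio(row["predicted_bmc_min_uM"], row["experimental_bmc_min_uM"])
        for _, row in out.iterrows()
    ]
    assert np.allclose(np.asarray(check), out["ratio_recomputed"], equal_nan=True)
    out.to_csv(outdir / "potency_summary.csv", index=False)
    finite = out["abs_deviation"].dropna()
    report["bmc_min_replication"] = {
        "n_finite": int(finite.size),
        "max_abs_deviation": float(finite.max()),
        "n_within_rounding_envelope": int(out["consistent"].sum()) - int(out["log10_ratio"].isna().sum()),
        "n_na": int(out["log10_ratio"].isna().sum()),
    }
    _log(log, f"bmc-min replication: {report['bmc_min_replication']}")


def _screen_pipeline(config, outdir, report, log):
    bmr_table = datasets.load_benchmark_responses()
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1))
             for k in ("single1", "single2", "mixture",
                       "bmc_single1", "bmc_single2", "bmc_mixture")}
    _log(log, f"stage seeds: {seeds}")

    if config.scenario in ("sham", "synergy"):
        # a mixture of an agent with itself; the two components are still
        # screened independently, as they would be for a real pair
        truth = demo_agent_truth()
        design = demo_design(seed=config.seed)
        if config.scenario == "sham":
            interaction = InteractionTruth("loewe_additive")
        else:
            interaction = InteractionTruth(
                "potency_shift",
                shift_factor=config.shift_factor,
                applies_to=DEMO_SHIFTED_READOUTS,
            )
        single1 = simulate_single_agent(truth, design, seed=seeds["single1"])
        single2 = simulate_single_agent(truth, design, seed=seeds["single2"])
        mixture = simulate_mixture(truth, truth, interaction, design,
                                   seed=seeds["mixture"])
        io.write_screen_csv(single1, outdir / "screen_component1.csv")
        io.write_screen_csv(single2, outdir / "screen_component2.csv")
        io.write_screen_csv(mixture, outdir / "screen_mixture.csv")
        io.write_truth_json(truth_to_dict(truth, interaction, design),
                            outdir / "truth.json")
        _log(log, f"simulated scenario {config.scenario!r}: "
                  f"{len(single1)}+{len(single2)} single + {len(mixture)} mixture records")
    else:
        known = set(bmr_table["readout"])
        single1 = single2 = io.read_screen_csv(config.screen_csv, known_readouts=known)
        if not config.mixture_csv:
            raise PipelineError("screen input requires a mixture CSV as well")
        mixture = io.read_screen_csv(config.mixture_csv, known_readouts=known)
        _log(log, f"read {len(single1)} single + {len(mixture)} mixture records")

    fit_kw = dict(n_boot=config.n_boot, monotonize=config.monotonize,
                  hit_threshold=config.hit_threshold)
    res_single1 = BenchmarkConcentrationModel(single1, bmr_table).fit(
        seed=seeds["bmc_single1"], **fit_kw)
    res_single2 = BenchmarkConcentrationModel(single2, bmr_table).fit(
        seed=seeds["bmc_single2"], **fit_kw)
    res_mixture = BenchmarkConcentrationModel(mixture, bmr_table).fit(
        seed=seeds["bmc_mixture"], **fit_kw)
    pd.concat([res_single1.frame, res_single2.frame, res_mixture.frame]).to_csv(
        outdir / "bmc.csv", index=False)
    _log(log, f"bootstrapped {len(res_single1.estimates)}+{len(res_single2.estimates)} "
              f"single + {len(res_mixture.estimates)} mixture BMC series")

    conc_range = (
        float(mixture["concentration_uM"][mixture["concentration_uM"] > 0].min()),
        float(mixture["concentration_uM"].max()),
    )
    calls = []
    predictions = []
    for obs in res_mixture.estimates:
        try:
            key = dict(readout=obs.readout, direction=obs.direction,
                       worm_type=obs.worm_type, day=obs.day)
            est1 = res_single1.get(**key)
            est2 = res_single2.get(**key)
        except KeyError:
            continue
        pred = predict_interval(est1, est2, cap=config.cap_uM)
        predictions.append({
            "mixture": obs.condition, "worm_type": obs.worm_type, "day": obs.day,
            "readout": obs.readout, "direction": obs.direction,
            "bmc_mix_per_component_uM": pred.bmc_mix,
            "lb_uM": pred.interval_lb, "ub_uM": pred.interval_ub,
            "rpf2": pred.rpf2, "capped": pred.capped,
        })
        calls.append(classify(obs, pred, mixture=obs.condition,
                              tested_range=conc_range))
    pd.DataFrame(predictions).to_csv(outdir / "predictions.csv", index=False)
    heatmap_table(calls).to_csv(outdir / "calls.csv", index=False)

    summaries = []
    for (mix, worm), group in pd.DataFrame(
        [{"mixture": c.mixture, "worm_type": c.worm_type, "i": i}
         for i, c in enumerate(calls)]
    ).groupby(["mixture", "worm_type"]):
        idx = group["i"].tolist()
        summaries.append(potency_summary(
            [calls[i].observed for i in idx],
            [calls[i].predicted for i in idx],
            mixture=mix, worm_type=worm,
        ).to_row())
    pd.DataFrame(summaries).to_csv(outdir / "potency_summary.csv", index=False)

    counts = pd.Series([c.call for c in calls]).value_counts().to_dict()
    report["calls"] = {k: int(v) for k, v in counts.items()}
    report["n_series"] = len(calls)
    report["potency_summaries"] = summaries
    _log(log, f"interaction calls: {report['calls']}")
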