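"""Reproducible experiment driver.

Builds HA/MA instance pairs, trains them through the checkpoint schedule,
probes every checkpoint with auditory-only testing, and assembles the three
comparisons: the cell-assembly growth curve, the dynamics comparison at the
reference checkpoint, and the control that pits the human architecture after
1000 presentations per pattern against the monkey architecture with several
times that training.

Two presets are provided.  ``desk`` (the default everywhere in this package)
is a reduced design sized for a single workstation CPU; ``paper`` mirrors
the full-scale study (12 pairs, checkpoints to 10,000).  See
docs/methods.md for the reasoning behind the desk sizes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import analyze_recording, growth_rates, summarize_and_test
from .connectivity import P0_DEFAULT, SIGMA_DEFAULT, instantiate_pair
from .params import ModelParams
from .protocol import FULL_CHECKPOINTS, TrainingSchedule, test, train

logger = logging.getLogger(__name__)

EXPERIMENTS = ("ca_curve", "dynamics", "ha1000_vs_ma10000", "all")

DESK_CHECKPOINTS = (50, 200, 500, 1000, 1500, 2000)


@dataclasses.dataclass
class ExperimentConfig:
    experiment: str = "all"
    n_pairs: int = 2
    master_seed: int = 1
    checkpoints: tuple[int, ...] = DESK_CHECKPOINTS
    dynamics_checkpoint: int = 1000
    #: training amount given to the MA member in the control comparison
    control_ma_checkpoint: int = 5000
    sigma: float = SIGMA_DEFAULT
    p0: float = P0_DEFAULT
    side: int = 25
    n_patterns: int = 14
    cells_per_pattern: int = 17
    params: ModelParams = dataclasses.field(default_factory=ModelParams)
    outdir: str | None = None

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        if self.dynamics_checkpoint not in self.checkpoints:
            raise ValueError("dynamics_checkpoint must be a checkpoint")

    @classmethod
    def desk(cls, **kw) -> "ExperimentConfig":
        return cls(**kw)

    @classmethod
    def paper(cls, **kw) -> "ExperimentConfig":
        kw.setdefault("n_pairs", 12)
        kw.setdefault("checkpoints", FULL_CHECKPOINTS)
        kw.setdefault("control_ma_checkpoint", 10000)
        return cls(**kw)

    def pair_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.master_seed)
        return [int(s) for s in ss.generate_state(self.n_pairs)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        return d


def _test_seed(pair_seed: int, checkpoint: int) -> int:
    return int(np.random.SeedSequence([pair_seed, 5, checkpoint]
                                      ).generate_state(1)[0])


def simulate_pair(pair_seed: int, config: ExperimentConfig,
                  pair_index: int = 0) -> dict[str, pd.DataFrame]:
    """Train and probe one HA/MA twin pair; returns tidy CA-size and
    dynamics tables."""
    ha, ma = instantiate_pair(pair_seed, config.sigma, config.p0,
                              config.side, config.n_patterns,
                              config.cells_per_pattern)
    need_control = config.experiment in ("ha1000_vs_ma10000", "all")
    ckpts = tuple(sorted(config.checkpoints))
    ma_ckpts = tuple(sorted(set(ckpts) | {config.control_ma_checkpoint})) \
        if need_control else ckpts

    ca_rows, dyn_rows = [], []
    for inst, inst_ckpts in ((ha, ckpts), (ma, ma_ckpts)):
        schedule = TrainingSchedule(checkpoints=inst_ckpts)
        logger.info("pair %d: training %s to %d presentations/pattern",
                    pair_index, inst.tag, inst_ckpts[-1])
        result = train(inst, config.params, schedule, pair_seed)
        areas = inst.graph.areas
        for c in inst_ckpts:
            recs = test(inst, config.params, _test_seed(pair_seed, c),
                        weights=result.checkpoints[c])
            for rec in recs:
                ca, dyn = analyze_recording(rec, areas, trials_trained=c)
                row = {"instance": pair_index, "architecture": inst.tag,
                       "checkpoint": c, "pattern": rec.pattern_id,
                       "ca_size": ca.size_total}
                row.update({f"ca_{a}": ca.size_per_area[a] for a in areas})
                ca_rows.append(row)
                for a in areas:
                    dyn_rows.append({
                        "instance": pair_index, "architecture": inst.tag,
                        "checkpoint": c, "pattern": rec.pattern_id,
                        "area": a, "t_max": dyn.t_max[a], "smp": dyn.smp[a],
                    })
    return {"ca_sizes": pd.DataFrame(ca_rows),
            "dynamics": pd.DataFrame(dyn_rows)}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured experiment end to end.

    Returns a bundle with the tidy tables, per-checkpoint aggregates, CA
    growth rates and (for >= 2 pairs) the repeated-measures statistics.
    All randomness derives from ``config.master_seed``.
    """
    tables = [simulate_pair(s, config, i)
              for i, s in enumerate(config.pair_seeds())]
    ca = pd.concat([t["ca_sizes"] for t in tables], ignore_index=True)
    dyn = pd.concat([t["dynamics"] for t in tables], ignore_index=True)

    ca_summary = (ca.groupby(["architecture", "checkpoint"])["ca_size"]
                  .mean().rename("mean_ca_size").reset_index())
    growth = {
        arch: growth_rates(sub.set_index("checkpoint")["mean_ca_size"]
                           .loc[list(sorted(config.checkpoints))])
        for arch, sub in ca_summary.groupby("architecture")
    }
    growth_df = pd.DataFrame(growth).rename_axis("checkpoint").reset_index()

    bundle: dict = {"ca_sizes": ca, "dynamics": dyn,
                    "ca_summary": ca_summary, "growth": growth_df,
                    "config": config}

    dyn_ref = dyn[dyn["checkpoint"] == config.dynamics_checkpoint]
    per_instance = (dyn_ref.groupby(["instance", "architecture", "area"])
                    [["t_max", "smp"]].mean().reset_index())
    bundle["dynamics_per_instance"] = per_instance
    if config.n_pairs >= 2:
        areas = tuple(ca.columns[5:].str.removeprefix("ca_"))
        try:
            bundle["stats"] = summarize_and_test(per_instance, areas)
        except Exception as exc:   # e.g. degenerate ANOVA at tiny n
            logger.warning("statistics failed: %s", exc)
            bundle["stats"] = {"error": str(exc)}
    else:
        bundle["stats"] = {"note": "statistics need >= 2 instance pairs"}

    if config.experiment in ("ha1000_vs_ma10000", "all"):
        control = dyn[((dyn["architecture"] == "HA") &
                       (dyn["checkpoint"] == config.dynamics_checkpoint)) |
                      ((dyn["architecture"] == "MA") &
                       (dyn["checkpoint"] == config.control_ma_checkpoint))]
        bundle["control_dynamics"] = (
            control.groupby(["instance", "architecture", "area"])
            [["t_max", "smp"]].mean().reset_index())

    if config.outdir:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["ca_sizes"].to_csv(outdir / "ca_sizes.csv", index=False)
    bundle["dynamics"].to_csv(outdir / "dynamics.csv", index=False)
    bundle["ca_summary"].to_csv(outdir / "ca_summary.csv", index=False)
    bundle["growth"].to_csv(outdir / "growth_rates.csv", index=False)
    if "control_dynamics" in bundle:
        bundle["control_dynamics"].to_csv(outdir / "control_dynamics.csv",
                                          index=False)
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump(bundle["stats"], fh, indent=2, default=float)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle["config"].to_dict(), fh, sort_keys=False)
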