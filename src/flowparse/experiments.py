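"""The three simulation campaigns and their result tables.

* **Simulation 1** — frontoparallel plane (monocular, ambiguous depth):
  self-motion component speeds {1, 2, 4, 6, 8, 10} deg/s at the probe
  crossed with object speeds {2, 6} deg/s; probe 4 deg below the FOE.
* **Simulation 2** — ground plane (monocular motion parallax): probe 2 deg
  below the FOE with a 1 deg/s component, or 4 deg below with 2 deg/s;
  probe optical speed 2.5 deg/s rightward; depth range 0.56–25 m.
* **Simulation 3** — stereo cloud of wire-frame objects (depth 0.69–1.03 m):
  Full / No-Local-Depth / No-Local-Frontal-View conditions at a 2 deg/s
  component, plus the Full condition at {1.6, 2.6, 3.6, 4.6} deg/s; probe
  4 deg from the FOE, visible for the last 200 ms of the 1 s trial, moving
  upward at 2 deg/s.

``run_campaign`` maps :func:`run_condition` over a campaign's grid and
returns an :class:`ExperimentResult` with one row per condition;
``ablate_ground_units`` reruns Simulations 1 and 3 with the MSTd
ground-pattern units toggled and reports the change in the decoded object
direction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import ModelConfig
from .model import FlowParsingModel, FlowParsingResult
from .stimuli import ProbeSpec, SceneSpec

__all__ = [
    "RunConfig", "ExperimentResult", "Condition",
    "sim1_conditions", "sim2_conditions", "sim3_conditions",
    "run_condition", "run_campaign", "ablate_ground_units",
    "human_reference",
]

SIM1_COMPONENT_SPEEDS = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
SIM1_OBJECT_SPEEDS = (2.0, 6.0)
SIM3_MASKS = ("full", "no_local_depth", "no_local_frontal_view")
SIM3_SPEED_SERIES = (1.6, 2.6, 3.6, 4.6)


@dataclass
class Condition:
    name: str
    scene: SceneSpec
    probe: ProbeSpec
    meta: Dict[str, object] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Campaign-level run settings."""

    experiment: str = "sim1"             # sim1 | sim2 | sim3
    model: ModelConfig = field(default_factory=ModelConfig)
    rng_seed: int = 0
    readout: str = "mstv"
    hold: bool = True

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# condition grids
# ---------------------------------------------------------------------------

def sim1_conditions(rng_seed: int = 0,
                    component_speeds=SIM1_COMPONENT_SPEEDS,
                    object_speeds=SIM1_OBJECT_SPEEDS) -> List[Condition]:
    out = []
    for o in object_speeds:
        for c in component_speeds:
            scene = SceneSpec(scenario="frontoparallel",
                              component_speed_at_probe=c,
                              self_motion_speed=0.5 * c,  # 0.5 m/s <-> 1 deg/s
                              duration=1.0, rng_seed=rng_seed)
            probe = ProbeSpec(offset_from_foe=(0.0, -4.0), object_speed=o,
                              object_direction=0.0, onset=0.0, offset=1.0)
            out.append(Condition(
                name=f"sim1_c{c:g}_o{o:g}", scene=scene, probe=probe,
                meta={"component": c, "object": o}))
    return out


def sim2_conditions(rng_seed: int = 0) -> List[Condition]:
    out = []
    for ecc, comp, label in ((2.0, 1.0, 5.7), (4.0, 2.0, 2.9)):
        scene = SceneSpec(scenario="ground", component_speed_at_probe=comp,
                          self_motion_speed=label,
                          depth_range=(0.56, 25.0), duration=1.0,
                          rng_seed=rng_seed)
        probe = ProbeSpec(offset_from_foe=(0.0, -ecc), object_speed=2.5,
                          object_direction=0.0, onset=0.0, offset=1.0)
        out.append(Condition(
            name=f"sim2_ecc{ecc:g}", scene=scene, probe=probe,
            meta={"eccentricity": ecc, "component": comp,
                  "translation_m_s": label}))
    return out


def sim3_conditions(rng_seed: int = 0, masks=SIM3_MASKS,
                    speed_series=SIM3_SPEED_SERIES) -> List[Condition]:
    out = []

    def cond(comp, mask, tag):
        scene = SceneSpec(scenario="cloud", component_speed_at_probe=comp,
                          self_motion_speed=0.15 * comp,  # 0.30 m/s <-> 2 deg/s
                          depth_range=(0.69, 1.03), duration=1.0,
                          stereo=True, condition_mask=mask, n_points=480,
                          rng_seed=rng_seed)
        probe = ProbeSpec(offset_from_foe=(4.0, 0.0), object_speed=2.0,
                          object_direction=90.0, onset=0.8, offset=1.0,
                          depth=0.86)
        return Condition(name=tag, scene=scene, probe=probe,
                         meta={"component": comp, "mask": mask})

    for mask in masks:
        out.append(cond(2.0, mask, f"sim3_{mask}"))
    for comp in speed_series:
        out.append(cond(comp, "full", f"sim3_full_c{comp:g}"))
    return out


_CONDITIONS = {"sim1": sim1_conditions, "sim2": sim2_conditions,
               "sim3": sim3_conditions}


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-condition summary table plus the full per-condition results."""

    table: pd.DataFrame
    results: Dict[str, FlowParsingResult]
    failures: Dict[str, str] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_condition(cfg: RunConfig, condition: Condition) -> FlowParsingResult:
    """Run the full pipeline for one condition."""
    scene = dataclasses.replace(condition.scene, rng_seed=cfg.rng_seed)
    model = FlowParsingModel.from_specs(scene, condition.probe,
                                        config=cfg.model,
                                        readout=cfg.readout)
    res = model.run(hold=cfg.hold)
    res.condition.update(condition.meta)
    res.condition["name"] = condition.name
    return res


def _row(name: str, res: FlowParsingResult) -> Dict[str, object]:
    return {
        "condition": name,
        **{k: v for k, v in res.condition.items() if k != "name"},
        "shift_final_deg": res.final_shift,
        "gain": res.final_gain,
        "stabilized": res.stabilized,
        "mstd_peak": res.mstd_peak,
        "winner_subpop": None if res.mstd_winner is None else res.mstd_winner[0],
        "winner_activity": None if res.mstd_winner is None else res.mstd_winner[4],
        "kurtosis": res.winner_kurtosis(),
        "engaged": any(res.engaged.values()),
    }


def run_campaign(cfg: RunConfig, conditions: Optional[List[Condition]] = None,
                 out_dir: Optional[Path] = None) -> ExperimentResult:
    """Run every condition of a campaign; collect partial failures."""
    if conditions is None:
        conditions = _CONDITIONS[cfg.experiment](cfg.rng_seed)
    rows, results, failures = [], {}, {}
    for cond in conditions:
        try:
            res = run_condition(cfg, cond)
        except Exception as exc:  # collected, reported at the end
            failures[cond.name] = str(exc)
            continue
        results[cond.name] = res
        rows.append(_row(cond.name, res))
    table = pd.DataFrame(rows)
    out = ExperimentResult(table=table, results=results, failures=failures)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / f"{cfg.experiment}_summary.csv")
        for name, res in results.items():
            res.trace_frame().to_csv(out_dir / f"{name}_trace.csv",
                                     index=False)
            dt_ms = 1000.0 * cfg.model.dt
            pd.DataFrame({
                "time_ms": dt_ms * np.arange(1,
                                             len(res.winner_activity_series)
                                             + 1),
                "winner_activity": res.winner_activity_series,
            }).to_csv(out_dir / f"{name}_winner.csv", index=False)
    return out


def plot_campaign(result: ExperimentResult, out_dir) -> list:
    """Figure-style summaries: gain vs. component speed and shift-vs-time
    traces.  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    df = result.table
    if "component" in df.columns and len(df) > 1:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for key, grp in df.groupby(
                df["object"] if "object" in df.columns else df["mask"]
                if "mask" in df.columns else [0] * len(df)):
            g = grp.sort_values("component")
            ax.plot(g["component"], g["gain"], "o-", label=str(key))
        ax.set_xlabel("self-motion component (deg/s)")
        ax.set_ylabel("flow-parsing gain")
        ax.set_ylim(bottom=0)
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out_dir / "gain_vs_speed.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, res in result.results.items():
        t, _, s = res.trace.as_arrays()
        ax.plot(t, s, label=name, lw=1)
    ax.set_xlabel("time from probe onset (ms)")
    ax.set_ylabel("shift toward world direction (deg)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out_dir / "shift_traces.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written


def ablate_ground_units(cfg: RunConfig,
                        conditions: Optional[List[Condition]] = None
                        ) -> pd.DataFrame:
    """Paired runs with MSTd ground units on vs. off.

    Defaults to every Simulation 1 and Simulation 3 condition; reports the
    per-condition absolute change in the final decoded object direction.
    """
    if conditions is None:
        conditions = sim1_conditions(cfg.rng_seed) + sim3_conditions(cfg.rng_seed)
    rows = []
    for cond in conditions:
        res_on = run_condition(
            cfg.replace(model=dataclasses.replace(cfg.model,
                                                  ground_units=True)), cond)
        res_off = run_condition(
            cfg.replace(model=dataclasses.replace(cfg.model,
                                                  ground_units=False)), cond)
        d_on, d_off = res_on.decoded_direction, res_off.decoded_direction
        delta = abs(((d_on - d_off) + 180.0) % 360.0 - 180.0)
        rows.append({"condition": cond.name,
                     "decoded_ground_on": d_on,
                     "decoded_ground_off": d_off,
                     "abs_delta_deg": delta})
    df = pd.DataFrame(rows)
    df.attrs["max_abs_delta_deg"] = float(df["abs_delta_deg"].max())
    return df


# ---------------------------------------------------------------------------
# packaged human reference values
# ---------------------------------------------------------------------------

def human_reference() -> pd.DataFrame:
    """Printed human flow-parsing means packaged with the model."""
    from importlib.resources import files
    path = files("flowparse.data").joinpath("human_reference.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
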