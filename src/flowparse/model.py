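"""The end-to-end competitive-dynamics model.

:class:`FlowParsingModel` wires the full circuit for one stimulus:

    GridFlow -> MT L4/6 -> { MT+ -> (depressing synapses) -> MSTd }
                           { MT- <- (feedback) <- MSTd; MT- -> MSTv }

Each input frame is integrated for ``steps_per_frame`` Euler steps
(~3.3 ms at 30 frames/s); after the last frame the final motion vectors are
held until the decoded object direction remains within a 1 deg band for five
frames' worth of steps (or a hard time cap is reached).  ``run()`` (alias
``fit()``) returns a :class:`FlowParsingResult` carrying the readout trace,
the flow-parsing gain, and MSTd diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import ModelConfig
from .feedback import FeedbackComposer
from .mstd import MSTdState, TemplateBank, feedforward_drive, \
    population_kurtosis, recurrent_step
from .pathways import SurroundKernel, SynapseState, depress, mt_minus_step, \
    mt_plus_step, mtminus_drives, mtplus_drive
from .readout import GainResult, MSTvKernel, ReadoutTrace, flow_parsing_gain, \
    mstv_drives, mstv_step, population_vector, shift_angle, \
    stabilization_check
from .stimuli import FlowSequence, GridFlow, rasterize
from .tuning import TuningBank, encode

__all__ = ["FlowParsingModel", "FlowParsingResult"]


@dataclass
class FlowParsingResult:
    """Results of one model run on one stimulus condition."""

    trace: ReadoutTrace
    gain: Optional[GainResult]
    stabilized: bool
    stabilized_step: Optional[int]
    retinal_direction: float
    world_direction: float
    shift_sign: float
    mstd_peak: float                     # max unit activity over the run
    mstd_winner: Optional[tuple]         # (subpop, j, i, activity) at end
    kurtosis: Dict[str, float]           # per subpopulation, at end of run
    engaged: Dict[str, bool]
    recurrent_signal: float
    winner_activity_series: List[float]
    condition: Dict[str, object] = field(default_factory=dict)

    @property
    def final_shift(self) -> float:
        return self.trace.final_shift

    @property
    def final_gain(self) -> float:
        return self.trace.final_gain

    @property
    def decoded_direction(self) -> float:
        d = [v for v in self.trace.decoded_deg if not np.isnan(v)]
        return d[-1] if d else float("nan")

    def winner_kurtosis(self) -> float:
        """Kurtosis of the most active subpopulation's response."""
        if self.mstd_winner is None:
            return float("nan")
        return self.kurtosis[self.mstd_winner[0]]

    def summary(self) -> pd.DataFrame:
        rows = {
            "final_shift_deg": self.final_shift,
            "flow_parsing_gain": self.final_gain,
            "stabilized": self.stabilized,
            "retinal_direction_deg": self.retinal_direction,
            "world_direction_deg": self.world_direction,
            "mstd_peak_activity": self.mstd_peak,
            "mstd_winner": None if self.mstd_winner is None
            else self.mstd_winner[0],
            "winner_kurtosis": self.winner_kurtosis(),
            "recurrent_engaged": any(self.engaged.values()),
        }
        rows.update({f"condition_{k}": v for k, v in self.condition.items()})
        return pd.DataFrame({"value": rows})

    def trace_frame(self) -> pd.DataFrame:
        t, d, s = self.trace.as_arrays()
        return pd.DataFrame({"time_ms": t, "decoded_deg": d, "shift_deg": s})


class FlowParsingModel:
    """Competitive-dynamics MT/MST model bound to one stimulus.

    Parameters
    ----------
    stimulus : FlowSequence
        The analytic stimulus (see :mod:`flowparse.stimuli`).
    config : ModelConfig, optional
        Structural and calibration parameters.
    readout : {"mstv", "mt-"}
        Population used for the object-direction readout.
    """

    def __init__(self, stimulus: FlowSequence,
                 config: Optional[ModelConfig] = None,
                 readout: str = "mstv"):
        self.seq = stimulus
        self.cfg = config or ModelConfig()
        if readout not in ("mstv", "mt-"):
            raise ValueError("readout must be 'mstv' or 'mt-'")
        self.readout_area = readout
        scene = stimulus.scene
        self.stereo = scene.stereo
        disparity_range = None
        if self.stereo:
            ds = np.concatenate([f.disparity for f in stimulus.frames
                                 if f.disparity is not None])
            disparity_range = (float(np.nanmax(ds)), float(np.nanmin(ds)))
        self.bank = TuningBank.from_config(self.cfg, scene.scenario,
                                           disparity_range)
        self.templates = TemplateBank.cached(
            self.cfg, self.bank, stereo=self.stereo,
            ground_units=self.cfg.ground_units)
        self.kernel = SurroundKernel.build(self.cfg, self.bank)
        self.mstv_kernel = MSTvKernel.build(self.cfg, self.bank)
        self.composer = FeedbackComposer(self.templates, self.bank)
        # geometry of the readout
        vel = stimulus.probe_retinal_velocity
        self.retinal_direction = float(np.rad2deg(np.arctan2(vel[1], vel[0])))
        self.world_direction = float(stimulus.probe.object_direction)
        d = shift_angle(self.world_direction, self.retinal_direction)
        self.shift_sign = 1.0 if d >= 0 else -1.0

    # ------------------------------------------------------------------
    @classmethod
    def from_specs(cls, scene, probe, config=None, **kw) -> "FlowParsingModel":
        from .stimuli import generate
        return cls(generate(scene, probe), config=config, **kw)

    # ------------------------------------------------------------------
    def _probe_cells(self, center_deg: np.ndarray):
        cfg = self.cfg
        n, c = cfg.grid_size, cfg.cell_deg
        centers = (np.arange(n) - n // 2) * c
        dx = centers[None, :] - center_deg[0]
        dy = centers[:, None] - center_deg[1]
        mask = np.hypot(dx, dy) <= self.seq.probe.diameter / 2 + 1e-9
        if not mask.any():
            iy = int(np.clip(np.rint(center_deg[1] / c) + n // 2, 0, n - 1))
            ix = int(np.clip(np.rint(center_deg[0] / c) + n // 2, 0, n - 1))
            mask[iy, ix] = True
        return mask

    def _decode(self, P: np.ndarray, M: np.ndarray, mask: np.ndarray):
        if self.readout_area == "mstv":
            sel = P[mask]                       # (cells, D[, Delta])
        else:
            sel = M[mask].mean(axis=2)          # pool speed axis of MT-
        if sel.ndim == 3:
            sel = sel.sum(axis=2)               # pool disparity
        w = sel.sum(axis=0)
        return population_vector(w, self.bank.direction_prefs)

    # ------------------------------------------------------------------
    def run(self, hold: bool = True) -> FlowParsingResult:
        cfg = self.cfg
        seq = self.seq
        grid = rasterize(seq, (cfg.grid_size, cfg.grid_size))
        dt = cfg.dt
        spf = cfg.steps_per_frame
        probe = seq.probe
        scene = seq.scene

        mt46_shape = None
        Nplus = Mm = P = syn = None
        mstd = MSTdState.zeros(self.templates)
        trace = ReadoutTrace()
        winner_series: List[float] = []
        mstd_peak = 0.0
        last_inputs = None
        probe_mask = None
        onset_ms = probe.onset * 1000.0

        def frame_inputs(f: int):
            disparity = grid.disparity[f] if self.stereo else None
            mt46 = encode(grid.vx[f], grid.vy[f], grid.occupancy[f],
                          self.bank, disparity)
            dplus = mtplus_drive(mt46, cfg)
            E, I = mtminus_drives(mt46, self.kernel, cfg)
            return dplus, E, I

        def probe_visible(f: int) -> bool:
            t = f / scene.frame_rate
            return probe.onset <= t < probe.offset

        # the object-motion pathway (MT-, MSTv, feedback delivery) has no
        # influence on the self-motion estimate, so before a late-onset
        # probe it only needs a warm-up long enough for its dynamics (time
        # constants well under 100 ms) to equilibrate
        warmup_s = 0.35
        object_path_start = max(0.0, probe.onset - warmup_s)

        n_frames = grid.n_frames
        step_count = 0
        for f in range(n_frames):
            dplus, E, I = frame_inputs(f)
            if mt46_shape is None:
                mt46_shape = E.shape
                Nplus = np.zeros(mt46_shape, dtype=np.float32)
                Mm = np.zeros(mt46_shape, dtype=np.float32)
                P = np.zeros(E.mean(axis=3).shape, dtype=np.float32)
                syn = SynapseState.fresh(mt46_shape, cfg)
            if probe_visible(f):
                pos = seq.probe_position(f)
                if pos is not None:
                    probe_mask = self._probe_cells(pos)
            last_inputs = (dplus, E, I)
            object_path = f / scene.frame_rate >= object_path_start
            for _ in range(spf):
                step_count += 1
                Nplus, Mm, P, syn, mstd = self._step(
                    Nplus, Mm, P, syn, mstd, dplus, E, I, dt,
                    object_path=object_path)
                mstd_peak = max(mstd_peak, mstd.peak_activity())
                win = mstd.winner()
                winner_series.append(win[4] if win else 0.0)
                if probe_visible(f) and probe_mask is not None:
                    dec = self._decode(P, Mm, probe_mask)
                    t_ms = step_count * dt * 1000.0 - onset_ms
                    sh = self.shift_sign * shift_angle(
                        dec, self.retinal_direction) \
                        if not np.isnan(dec) else float("nan")
                    trace.append(t_ms, dec, sh)

        # hold the final inputs until the readout stabilizes; stabilization
        # is assessed on the input-held continuation only
        stab = None
        hold_start = len(trace)
        max_steps = step_count + int(cfg.max_hold_seconds / dt)
        if hold and last_inputs is not None and probe_mask is not None:
            dplus, E, I = last_inputs
            hold_trace = ReadoutTrace()
            while stab is None and step_count < max_steps:
                for _ in range(spf):
                    step_count += 1
                    Nplus, Mm, P, syn, mstd = self._step(
                        Nplus, Mm, P, syn, mstd, dplus, E, I, dt)
                    mstd_peak = max(mstd_peak, mstd.peak_activity())
                    win = mstd.winner()
                    winner_series.append(win[4] if win else 0.0)
                    dec = self._decode(P, Mm, probe_mask)
                    t_ms = step_count * dt * 1000.0 - onset_ms
                    sh = self.shift_sign * shift_angle(
                        dec, self.retinal_direction) \
                        if not np.isnan(dec) else float("nan")
                    trace.append(t_ms, dec, sh)
                    hold_trace.append(t_ms, dec, sh)
                stab = stabilization_check(hold_trace, scene.frame_rate, spf,
                                           cfg.stabilization_band,
                                           cfg.stabilization_frames)
            if stab is not None:
                stab += hold_start

        # final numbers
        gain = None
        if len(trace) > 0:
            valid = [s for s in trace.shift_deg if not np.isnan(s)]
            trace.final_shift = valid[-1] if valid else float("nan")
            trace.stabilized_step = stab
            if valid and probe.object_speed > 0 \
                    and scene.component_speed_at_probe > 0:
                gain = flow_parsing_gain(trace.final_shift,
                                         probe.object_speed,
                                         scene.component_speed_at_probe)
                trace.final_gain = gain.gain

        kurt = {name: population_kurtosis(act)
                for name, act in mstd.activity.items()}
        return FlowParsingResult(
            trace=trace, gain=gain, stabilized=stab is not None,
            stabilized_step=stab,
            retinal_direction=self.retinal_direction,
            world_direction=self.world_direction,
            shift_sign=self.shift_sign,
            mstd_peak=mstd_peak, mstd_winner=mstd.winner(),
            kurtosis=kurt, engaged=dict(mstd.engaged),
            recurrent_signal=mstd.recurrent_signal,
            winner_activity_series=winner_series,
            condition={"scenario": scene.scenario,
                       "component_speed": scene.component_speed_at_probe,
                       "object_speed": probe.object_speed,
                       "mask": scene.condition_mask,
                       "stereo": scene.stereo})

    fit = run  # estimation-style alias

    # ------------------------------------------------------------------
    def _step(self, Nplus, Mm, P, syn, mstd, dplus, E, I, dt,
              object_path: bool = True):
        cfg = self.cfg
        Nplus = mt_plus_step(Nplus, dplus, cfg, dt)
        transmitted, syn = depress(Nplus, syn, dt)
        drives = feedforward_drive(self.templates, transmitted)
        mstd = recurrent_step(mstd, drives, self.templates, dt)
        if object_path:
            field = self.composer.compose(mstd)
            Mm = mt_minus_step(Mm, E, I, field.values, cfg, dt)
            Ev, Iv = mstv_drives(Mm, self.mstv_kernel, cfg)
            P = mstv_step(P, Ev, Iv, field.mstv_values, cfg, dt)
            self._last = (drives, field, E, I, Ev, Iv)
        return Nplus, Mm, P, syn, mstd
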