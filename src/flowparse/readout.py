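"""MSTv integration and the object-direction readout.

MSTv units integrate MT- signals pooled proportionally across speed (like
MSTd speed-summating cells) under on-center/off-surround shunting dynamics,
minus the MSTd feedback suppression.  The represented object direction is
decoded by population vector over the direction-tuned units whose receptive
fields contain the probe; the shift of the decoded angle away from the
probe's retinal direction, expressed against the self-motion component,
yields the flow-parsing gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage

from .config import ModelConfig
from ._kernels import shunt_inhibited
from .pathways import _apply_axis_matrix
from .tuning import TuningBank, circular_difference

__all__ = [
    "ReadoutTrace", "GainResult", "MSTvKernel",
    "mstv_drives", "mstv_step", "population_vector", "shift_angle",
    "flow_parsing_gain", "stabilization_check", "plateau_time",
]


# ---------------------------------------------------------------------------
# MSTv dynamics
# ---------------------------------------------------------------------------

@dataclass
class MSTvKernel:
    """Direction-similarity surround pooling for MSTv."""

    spatial_sigma: float
    dir_matrix: np.ndarray

    @classmethod
    def build(cls, cfg: ModelConfig, bank: TuningBank) -> "MSTvKernel":
        prefs = bank.direction_prefs
        dd = circular_difference(prefs[:, None], prefs[None, :])
        Dm = np.exp(-((dd / cfg.surround_dir_sigma) ** 2))
        Dm /= Dm.sum(axis=1, keepdims=True)
        return cls(spatial_sigma=cfg.mstv_radius,
                   dir_matrix=Dm.astype(np.float32))


def mstv_drives(mtminus: np.ndarray, kernel: MSTvKernel, cfg: ModelConfig):
    """Excitatory and surround-inhibitory drives to MSTv from MT-.

    MT- activity is pooled across the speed axis with uniform proportional
    weighting (mean over the speed channels), then integrated on-center /
    off-surround.
    """
    pooled = mtminus.mean(axis=3)            # (H, W, D[, Delta])
    E = cfg.mstv_center_gain * pooled
    I = ndimage.gaussian_filter(
        pooled, sigma=(kernel.spatial_sigma, kernel.spatial_sigma)
        + (0,) * (pooled.ndim - 2), mode="constant")
    I = _apply_axis_matrix(I, kernel.dir_matrix, axis=2)
    I = cfg.mstv_surround_gain * I
    return E, I.astype(pooled.dtype, copy=False)


def mstv_step(state: np.ndarray, E: np.ndarray, I_local: np.ndarray,
              feedback: Optional[np.ndarray], cfg: ModelConfig,
              dt: float) -> np.ndarray:
    """One Euler step of the MSTv shunting equation (nonnegative, <= B)."""
    return shunt_inhibited(state, E, I_local, cfg.mstv_decay,
                           cfg.mstv_bound, dt, F=feedback)


# ---------------------------------------------------------------------------
# population-vector decoding
# ---------------------------------------------------------------------------

def population_vector(weights, dir_prefs) -> float:
    """Angle (deg) of the rate-weighted sum of preferred-direction vectors.

    Invariant to uniform scaling of the weights.  Returns NaN (reported
    distinctly) for all-zero weights or a zero resultant.
    """
    w = np.asarray(weights, float)
    if w.size == 0 or not np.any(w > 0):
        return float("nan")
    th = np.deg2rad(np.asarray(dir_prefs, float))
    ju = float(np.sum(w * np.cos(th)))
    jv = float(np.sum(w * np.sin(th)))
    if np.hypot(ju, jv) < 1e-12 * w.sum():
        return float("nan")
    return float(np.rad2deg(np.arctan2(jv, ju)))


def shift_angle(decoded: float, retinal_dir: float) -> float:
    """Circular difference decoded - retinal, mapped to (-180, 180]."""
    return float(circular_difference(decoded, retinal_dir))


@dataclass
class GainResult:
    """Flow-parsing gain derived from the decoded direction shift.

    With object component o (deg/s) and self-motion component c (deg/s)
    perpendicular by design, the retinal direction is beta = atan(c/o) away
    from the world-relative direction.  A decoded shift theta toward the
    world direction leaves a residual self-motion component
    r = o * tan(beta - theta), and the gain is 1 - r/c: 0 when the retinal
    direction is decoded unchanged, 1 when the full component is removed.
    """

    component_speed: float
    object_speed: float
    shift_deg: float
    residual: float
    gain: float


def flow_parsing_gain(shift_deg: float, o: float, c: float) -> GainResult:
    """Convert a direction shift to a flow-parsing gain."""
    if not (o > 0 and c > 0):
        raise ValueError("object and component speeds must be positive")
    beta = np.degrees(np.arctan2(c, o))
    if not abs(shift_deg) < 90.0 + beta:
        raise ValueError("shift outside the defined range of the residual "
                         "tangent")
    residual = o * np.tan(np.radians(beta - shift_deg))
    gain = 1.0 - residual / c
    return GainResult(component_speed=c, object_speed=o,
                      shift_deg=float(shift_deg), residual=float(residual),
                      gain=float(gain))


# ---------------------------------------------------------------------------
# traces and stabilization
# ---------------------------------------------------------------------------

@dataclass
class ReadoutTrace:
    """Per-step decoded object direction, from probe onset onward."""

    times_ms: List[float] = field(default_factory=list)
    decoded_deg: List[float] = field(default_factory=list)
    shift_deg: List[float] = field(default_factory=list)
    final_shift: float = float("nan")
    final_gain: float = float("nan")
    stabilized_step: Optional[int] = None

    def append(self, t_ms: float, decoded: float, shift: float) -> None:
        self.times_ms.append(float(t_ms))
        self.decoded_deg.append(float(decoded))
        self.shift_deg.append(float(shift))

    def __len__(self) -> int:
        return len(self.times_ms)

    def as_arrays(self):
        return (np.asarray(self.times_ms), np.asarray(self.decoded_deg),
                np.asarray(self.shift_deg))


def stabilization_check(trace: ReadoutTrace, frame_rate: float,
                        steps_per_frame: int = 10, band_deg: float = 1.0,
                        n_frames: int = 5) -> Optional[int]:
    """First step at which the decoded angle has remained within a
    ``band_deg`` band for at least ``n_frames`` frames' worth of steps.

    Returns the step index (into the trace) or None if the trace never
    stabilizes.  NaN entries (undefined decode) break the band.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    dec = np.asarray(trace.decoded_deg, float)
    w = max(1, int(round(n_frames * steps_per_frame)))
    if len(dec) < w:
        return None
    for t in range(w - 1, len(dec)):
        win = dec[t - w + 1: t + 1]
        if np.any(np.isnan(win)):
            continue
        if win.max() - win.min() <= band_deg:
            return t
    return None


def plateau_time(trace: ReadoutTrace, frac: float = 0.05) -> float:
    """Time (ms from probe onset) of first entry into a sustained band
    within ``frac`` of the trace's final shift value."""
    t, _, s = trace.as_arrays()
    if len(s) == 0 or np.all(np.isnan(s)):
        return float("nan")
    final = s[~np.isnan(s)][-1]
    tol = abs(final) * frac
    inside = np.abs(s - final) <= tol
    inside &= ~np.isnan(s)
    # last index before which the trace was outside the band
    outside = np.where(~inside)[0]
    start = 0 if outside.size == 0 else int(outside[-1]) + 1
    if start >= len(t):
        return float(t[-1])
    return float(t[start])
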