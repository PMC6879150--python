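"""MT Layer 4/6 frontend: separable direction/speed/disparity tuning.

Input-layer MT units convert the rasterized motion field into population
activity.  Tuning is separable: a circular Gaussian over direction, a
log-Gaussian (band-pass in octaves) over speed, and a Gaussian over binocular
disparity, multiplied together.  In stereo runs a disparity-dependent
response gain (largest for near disparities, decreasing with depth) scales
the whole response; monocular runs carry no disparity axis and unit gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ModelConfig

__all__ = [
    "TuningBank", "ActivityTensor",
    "direction_response", "speed_response", "disparity_response",
    "disparity_gain", "encode",
]

_LOG_FLOOR = 1e-6  # deg/s floor inside the log for zero-speed input


def circular_difference(a, b):
    """Signed circular difference a - b wrapped to (-180, 180], degrees."""
    return (np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0


def direction_response(angle, pref, bandwidth):
    """Circular-Gaussian direction tuning, peak 1 at ``angle == pref``."""
    d = circular_difference(angle, pref)
    return np.exp(-((d / bandwidth) ** 2))


def speed_response(speed, pref, bandwidth):
    """Log-Gaussian speed tuning (bandwidth in octaves), peak 1 at ``pref``.

    Zero (and negative-floored) speeds give ~0 response for any positive
    preferred speed via a floor on the log argument.
    """
    speed = np.asarray(speed, float)
    if np.any(speed < 0):
        raise ValueError("speed must be nonnegative")
    x = np.log2(np.maximum(speed, _LOG_FLOOR) / pref)
    return np.exp(-((x / bandwidth) ** 2))


def disparity_response(disp, pref, bandwidth):
    """Gaussian disparity tuning (arcmin), peak 1 at ``disp == pref``."""
    d = (np.asarray(disp, float) - pref) / bandwidth
    return np.exp(-(d ** 2))


@dataclass
class TuningBank:
    """The frozen tuning lattice of the MT input layer.

    ``disparity_prefs`` are ordered near -> far (decreasing arcmin for the
    crossed/absolute parallax convention used by the stimuli); ``None`` for
    monocular runs.
    """

    direction_prefs: np.ndarray          # deg, 24 values 15 deg apart
    speed_prefs: np.ndarray              # deg/s, log-spaced
    disparity_prefs: Optional[np.ndarray]  # arcmin, near -> far, or None
    direction_sigma: float = 30.0
    speed_sigma: float = 1.0             # octaves
    disparity_sigma: Optional[float] = None
    gain_monocular: float = 1.0
    gain_near: float = 1.5
    gain_far: float = 1.15

    def __post_init__(self):
        self.direction_prefs = np.asarray(self.direction_prefs, float)
        self.speed_prefs = np.asarray(self.speed_prefs, float)
        if np.any(np.diff(self.speed_prefs) <= 0):
            raise ValueError("speed_prefs must be strictly increasing")
        if self.disparity_prefs is not None:
            self.disparity_prefs = np.asarray(self.disparity_prefs, float)
            d = np.diff(self.disparity_prefs)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("disparity_prefs must be strictly ordered")
            if self.disparity_sigma is None:
                self.disparity_sigma = float(np.abs(d).mean())

    @property
    def stereo(self) -> bool:
        return self.disparity_prefs is not None

    @classmethod
    def from_config(cls, cfg: ModelConfig, scenario: str,
                    disparity_range=None) -> "TuningBank":
        """Build the bank for one scenario family.

        ``disparity_range`` (near_arcmin, far_arcmin) enables the stereo
        axis: 5 preferences linearly tile the range near -> far.
        """
        disparity_prefs = None
        if disparity_range is not None:
            near, far = disparity_range
            disparity_prefs = np.linspace(near, far, cfg.n_disparities)
        gain_on = disparity_range is not None and cfg.disparity_gain_enabled
        return cls(
            direction_prefs=cfg.direction_prefs(),
            speed_prefs=cfg.speed_prefs(scenario),
            disparity_prefs=disparity_prefs,
            direction_sigma=cfg.direction_sigma,
            speed_sigma=cfg.speed_sigma_oct,
            disparity_sigma=cfg.disparity_sigma,
            gain_monocular=cfg.gain_monocular,
            gain_near=cfg.gain_binocular_near if gain_on
            else cfg.gain_monocular,
            gain_far=cfg.gain_binocular_far if gain_on
            else cfg.gain_monocular,
        )

    # -- per-cell weight maps ----------------------------------------------
    def direction_weights(self, angle_deg: np.ndarray) -> np.ndarray:
        """(..., n_directions) circular-Gaussian weights for input angles."""
        return direction_response(angle_deg[..., None],
                                  self.direction_prefs, self.direction_sigma)

    def speed_weights(self, speed: np.ndarray) -> np.ndarray:
        return speed_response(speed[..., None], self.speed_prefs,
                              self.speed_sigma)

    def disparity_weights(self, disp: np.ndarray) -> np.ndarray:
        if not self.stereo:
            raise ValueError("monocular bank has no disparity axis")
        return disparity_response(disp[..., None], self.disparity_prefs,
                                  self.disparity_sigma)


@dataclass
class ActivityTensor:
    """Nonnegative activation array for one model area.

    Axes are (y, x, direction, speed[, disparity]) for MT areas,
    (y, x, direction[, disparity]) for MSTv.
    """

    values: np.ndarray
    area_tag: str

    def __post_init__(self):
        self.values = np.asarray(self.values)

    @property
    def stereo(self) -> bool:
        return self.values.ndim == 5

    def copy(self) -> "ActivityTensor":
        return ActivityTensor(self.values.copy(), self.area_tag)


def disparity_gain(disp, bank: TuningBank):
    """Disparity-dependent response multiplier (>= 1).

    Linear in position along the near -> far preference axis, from
    ``gain_near`` at the nearest preference to ``gain_far`` at the farthest;
    monocular input gets the monocular gain (1 by default).  NaN disparities
    (no stimulus) map to the monocular gain.
    """
    if not bank.stereo:
        return np.ones_like(np.asarray(disp, float)) * bank.gain_monocular
    disp = np.asarray(disp, float)
    prefs = bank.disparity_prefs
    # fractional bin position 0 (near) .. 1 (far); prefs may be decreasing
    p = (disp - prefs[0]) / (prefs[-1] - prefs[0])
    p = np.clip(p, 0.0, 1.0)
    g = bank.gain_near + (bank.gain_far - bank.gain_near) * p
    return np.where(np.isnan(disp), bank.gain_monocular, g)


def encode(vx: np.ndarray, vy: np.ndarray, occupancy: np.ndarray,
           bank: TuningBank, disparity: Optional[np.ndarray] = None,
           dtype=np.float32) -> ActivityTensor:
    """MT L4/6 response to one rasterized frame.

    activation(y, x, d, s[, delta]) = gain * f_dir * f_speed * f_disp on the
    cell's motion vector; unoccupied cells are zero.
    """
    bad = ~np.isfinite(vx) | ~np.isfinite(vy)
    if np.any(bad & occupancy):
        iy, ix = np.argwhere(bad & occupancy)[0]
        raise ValueError(f"non-finite velocity at cell (y={iy}, x={ix})")
    angle = np.rad2deg(np.arctan2(vy, vx))
    speed = np.hypot(vx, vy)
    wd = bank.direction_weights(angle).astype(dtype)     # (H, W, D)
    ws = bank.speed_weights(speed).astype(dtype)         # (H, W, S)
    occ = occupancy.astype(dtype)
    if bank.stereo:
        if disparity is None:
            raise ValueError("stereo bank requires a disparity channel")
        dfin = np.where(np.isnan(disparity), 0.0, disparity)
        wdl = bank.disparity_weights(dfin).astype(dtype)  # (H, W, Dl)
        gain = disparity_gain(disparity, bank).astype(dtype)
        base = (occ * gain)[:, :, None, None, None]
        vals = base * wd[:, :, :, None, None] * ws[:, :, None, :, None] \
            * wdl[:, :, None, None, :]
        return ActivityTensor(vals, "MT46")
    vals = occ[:, :, None, None] * wd[:, :, :, None] * ws[:, :, None, :]
    return ActivityTensor(vals, "MT46")
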