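"""Segregated MT Layer 2/3 pathways.

``MT+`` units (reinforcing surrounds) integrate same-preference input-layer
activity over their receptive fields and project to MSTd through depressing
synapses.  ``MT-`` units (antagonistic surrounds) perform shunting
on-center/off-surround integration: excitation from like-tuned center input,
divisive inhibition from feedforward lateral signals of similarly tuned
neighbours plus the MSTd feedback suppression field, and project to MSTv.
There is no cross-talk between the two pathways.

All stateful areas follow Grossberg-style shunting dynamics integrated with
Euler steps:  dA/dt = -a A + (B - A) E - A I,  which keeps activity in
[0, B] for nonnegative excitation E and inhibition I.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from ._kernels import depress_fused, shunt_inhibited, shunt_leaky
from .config import ModelConfig
from .tuning import ActivityTensor, TuningBank, circular_difference

__all__ = [
    "SurroundKernel", "SynapseState",
    "mtplus_drive", "mt_plus_step", "mtplus_equilibrium", "depress",
    "mtminus_drives", "mt_minus_step", "shunting_step",
]


def shunting_step(A, excitation, inhibition, decay, bound, dt):
    """One Euler step of dA/dt = -a A + (B - A) E - A I (elementwise)."""
    return A + dt * (-decay * A + (bound - A) * excitation
                     - A * inhibition)


def _apply_axis_matrix(values: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    """Contract ``values`` with similarity matrix M along ``axis``."""
    out = np.tensordot(values, M, axes=([axis], [0]))
    return np.moveaxis(out, -1, axis)


# ---------------------------------------------------------------------------
# tuning-similarity surround kernels
# ---------------------------------------------------------------------------

@dataclass
class SurroundKernel:
    """Spatial + tuning-similarity pooling used by MT- lateral inhibition.

    Pooling is separable: a spatial Gaussian over (y, x) and row-normalized
    Gaussian similarity matrices over the direction axis (circular
    difference), the log-spaced speed axis (octave distance) and the
    disparity axis (bin distance).  The same-unit component is subtracted so
    an isolated unit does not inhibit itself; suppression is maximal when
    the surround carries exactly the center's preferred motion.
    """

    spatial_sigma: float
    dir_matrix: np.ndarray
    speed_matrix: np.ndarray
    disp_matrix: Optional[np.ndarray]
    self_weight: float

    @classmethod
    def build(cls, cfg: ModelConfig, bank: TuningBank,
              spatial_sigma: Optional[float] = None) -> "SurroundKernel":
        sigma = cfg.mtminus_radius if spatial_sigma is None else spatial_sigma
        # similarity weights peak at 1 for matched tuning (suppression is
        # maximal when the surround carries the center's preferred motion)
        prefs = bank.direction_prefs
        dd = circular_difference(prefs[:, None], prefs[None, :])
        Dm = np.exp(-((dd / cfg.surround_dir_sigma) ** 2))
        oct_pos = np.log2(bank.speed_prefs)
        doct = oct_pos[:, None] - oct_pos[None, :]
        Sm = np.exp(-((doct / cfg.surround_speed_sigma) ** 2))
        disp_matrix = None
        if bank.stereo:
            n = len(bank.disparity_prefs)
            db = np.arange(n)[:, None] - np.arange(n)[None, :]
            Pm = np.exp(-((db / cfg.surround_disp_sigma) ** 2))
            disp_matrix = Pm.astype(np.float32)
        # center weight of the normalized discrete spatial Gaussian
        half = max(8, int(4 * sigma) + 1)
        imp = np.zeros((2 * half + 1, 2 * half + 1))
        imp[half, half] = 1.0
        w_sp = ndimage.gaussian_filter(imp, sigma, mode="constant")[half, half]
        self_w = w_sp * Dm[0, 0] * Sm[0, 0]
        if disp_matrix is not None:
            self_w *= disp_matrix[0, 0]
        return cls(spatial_sigma=sigma, dir_matrix=Dm.astype(np.float32),
                   speed_matrix=Sm.astype(np.float32),
                   disp_matrix=disp_matrix, self_weight=float(self_w))

    def pool(self, values: np.ndarray) -> np.ndarray:
        """Similarity-weighted surround pool of an MT46 tensor, minus self."""
        out = ndimage.gaussian_filter(
            values, sigma=(self.spatial_sigma, self.spatial_sigma)
            + (0,) * (values.ndim - 2), mode="constant")
        out = _apply_axis_matrix(out, self.dir_matrix, axis=2)
        out = _apply_axis_matrix(out, self.speed_matrix, axis=3)
        if values.ndim == 5 and self.disp_matrix is not None:
            out = _apply_axis_matrix(out, self.disp_matrix, axis=4)
        out -= self.self_weight * values
        np.maximum(out, 0.0, out=out)
        return out.astype(values.dtype, copy=False)


# ---------------------------------------------------------------------------
# MT+ (reinforcing surround)
# ---------------------------------------------------------------------------

def mtplus_drive(mt46: ActivityTensor, cfg: ModelConfig) -> np.ndarray:
    """Feedforward drive to MT+: center input plus same-preference spatial
    pooling over the receptive field (the reinforcing surround)."""
    v = mt46.values
    pooled = ndimage.gaussian_filter(
        v, sigma=(cfg.mtplus_radius, cfg.mtplus_radius) + (0,) * (v.ndim - 2),
        mode="constant")
    return (cfg.mtplus_drive_gain * v
            + cfg.mtplus_surround_gain * pooled).astype(v.dtype, copy=False)


def mt_plus_step(state: np.ndarray, drive: np.ndarray, cfg: ModelConfig,
                 dt: float) -> np.ndarray:
    """One Euler step of the MT+ shunting leaky integrator."""
    return shunt_leaky(state, drive, cfg.mtplus_decay, cfg.mtplus_bound, dt)


def mtplus_equilibrium(drive: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Closed-form fixed point B*D/(a+D) of the MT+ dynamics (for checks)."""
    return cfg.mtplus_bound * drive / (cfg.mtplus_decay + drive)


# ---------------------------------------------------------------------------
# depressing synapses (MT+ -> MSTd)
# ---------------------------------------------------------------------------

@dataclass
class SynapseState:
    """Per-connection efficacy in (0, 1] with depletion/recovery dynamics.

    d e/dt = (1 - e)/tau - rate * e * N  (N = presynaptic activity); the
    transmitted signal is e * N, so sustained tonic input is attenuated to
    the steady state e* = 1 / (1 + rate * tau * N).
    """

    efficacy: np.ndarray
    recovery_tau: float = 0.5
    depletion_rate: float = 0.3

    @classmethod
    def fresh(cls, shape, cfg: ModelConfig, dtype=np.float32) -> "SynapseState":
        return cls(efficacy=np.ones(shape, dtype=dtype),
                   recovery_tau=cfg.depress_tau,
                   depletion_rate=cfg.depress_rate)

    def steady_state(self, activity):
        return 1.0 / (1.0 + self.depletion_rate * self.recovery_tau
                      * np.asarray(activity))


def depress(mtplus: np.ndarray, syn: SynapseState, dt: float):
    """Transmit MT+ activity through depressing synapses.

    Returns (transmitted signal, updated state); the transmitted signal uses
    the pre-update efficacy.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    transmitted, eff = depress_fused(syn.efficacy, mtplus, syn.recovery_tau,
                                     syn.depletion_rate, dt)
    new = SynapseState(efficacy=eff, recovery_tau=syn.recovery_tau,
                       depletion_rate=syn.depletion_rate)
    return transmitted, new


# ---------------------------------------------------------------------------
# MT- (antagonistic surround)
# ---------------------------------------------------------------------------

def mtminus_drives(mt46: ActivityTensor, kernel: SurroundKernel,
                   cfg: ModelConfig):
    """Per-frame excitatory center drive and feedforward lateral inhibition
    for MT- (both derive from the input layer, so they are constant within a
    frame)."""
    E = cfg.mtminus_center_gain * mt46.values
    I = cfg.mtminus_surround_gain * kernel.pool(mt46.values)
    return E, I


def mt_minus_step(state: np.ndarray, E: np.ndarray, I_local: np.ndarray,
                  feedback: Optional[np.ndarray], cfg: ModelConfig,
                  dt: float) -> np.ndarray:
    """One Euler step of the MT- shunting on-center/off-surround equation.

    ``feedback`` is the MSTd suppression field (may be None / all-zero early
    in a run).  Activity stays in [0, B].
    """
    return shunt_inhibited(state, E, I_local, cfg.mtminus_decay,
                           cfg.mtminus_bound, dt, F=feedback)
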