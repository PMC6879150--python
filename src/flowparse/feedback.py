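"""MSTd -> MT-/MSTv suppressive feedback.

The single most active MSTd unit broadcasts inhibition to object-motion
units whose tuning locally matches the motion pattern the winner is tuned
to: at each grid cell the winner's template prescribes a direction, a speed
(via the template's speed-quintile at that eccentricity) and — in stereo
runs — the congruent speed-disparity pairing (fast <-> near, slow <-> far).
Suppression falls off as a Gaussian of the tuning mismatch in each dimension
(circular difference for direction, log-speed difference for speed, bin
difference for disparity), multiplied across dimensions, and as a Gaussian
of the retinotopic distance between the cell and the winner's preferred
singularity.  The whole field scales with the winner's activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .mstd import (MSTdState, TemplateBank, build_ground_template,
                   build_radial_template)
from .tuning import TuningBank, circular_difference

__all__ = ["SuppressionField", "FeedbackComposer",
           "mismatch_weight", "local_template_motion", "compose"]


def mismatch_weight(w, mu, sigma):
    """Gaussian suppression weight exp(-((w - mu)/sigma)^2), peak 1 at w=mu.

    Callers supply the appropriate difference space per dimension (circular
    degrees for direction, octaves for speed, bins for disparity).
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    d = (np.asarray(w, float) - mu) / sigma
    return np.exp(-(d ** 2))


@dataclass
class SuppressionField:
    """Inhibition per (y, x, direction, speed[, disparity]).

    ``mstv_values`` is the same field pooled over the speed axis, delivered
    to MSTv (which carries no speed axis).
    """

    values: np.ndarray
    mstv_values: np.ndarray
    source_winner: Optional[Tuple[str, int, int]]
    global_scale: float


def _winner_cell(winner_sub: Tuple[str, int, int], templates: TemplateBank):
    """Map a winner's singularity-grid indices to MT-grid cell coords."""
    name, jrow, icol = winner_sub
    return (float(templates.sing_cells[jrow]),
            float(templates.sing_cells[icol]))


def local_template_motion(winner_sub: Tuple[str, int, int],
                          templates: TemplateBank, bank: TuningBank,
                          x: int, y: int):
    """Direction/speed(/disparity) the winner's template prescribes at one
    grid cell.

    Returns (direction_deg or None, speed_deg_s, disparity_bin or None);
    direction is None at the singularity itself and outside the template
    domain (above the horizon for a ground winner — no suppression there).
    The congruent disparity bin pairs the prescribed speed quintile with
    depth (fastest quintile <-> nearest bin).
    """
    name = winner_sub[0]
    j, i = _winner_cell(winner_sub, templates)
    n = templates.cfg.grid_size
    nq = templates.cfg.n_speeds
    if name == "ground":
        vx, vy, valid = build_ground_template(i, j, n)
        q = templates.quintile_map("ground", i, j)
    else:
        vx, vy, valid = build_radial_template(i, j, n)
        q = templates.quintile_map("radial", i, j)
    qv = int(np.clip(q[y, x], 0, nq - 1))
    speed = float(bank.speed_prefs[qv])
    disp_bin = None
    if bank.stereo:
        disp_bin = len(bank.disparity_prefs) - 1 - qv
    if not valid[y, x]:
        return None, speed, disp_bin
    direction = float(np.rad2deg(np.arctan2(vy[y, x], vx[y, x])))
    return direction, speed, disp_bin


class FeedbackComposer:
    """Builds the suppression field each step, caching the winner's maps.

    The winner changes rarely within a run, while its activity (the global
    scale) changes every Euler step; the per-cell direction/speed/disparity
    mismatch maps and the distance falloff are therefore cached per winner
    identity.
    """

    def __init__(self, templates: TemplateBank, bank: TuningBank):
        self.templates = templates
        self.bank = bank
        self.cfg = templates.cfg
        self._cache: Dict[Tuple[str, int, int], tuple] = {}
        # fixed congruent speed-disparity weighting (S, Delta):
        # speed pref k pairs with disparity bin (n_delta - 1 - k)
        self._w_sd = None
        if bank.stereo:
            nd = len(bank.disparity_prefs)
            S = len(bank.speed_prefs)
            ks = np.arange(S)[:, None]
            db = np.arange(nd)[None, :]
            congruent = (nd - 1) * (1 - ks / max(S - 1, 1))
            self._w_sd = mismatch_weight(db, congruent,
                                         self.cfg.feedback_disp_sigma
                                         ).astype(np.float32)

    # ------------------------------------------------------------------
    def _maps(self, key: Tuple[str, int, int, Optional[int]]):
        if key in self._cache:
            return self._cache[key]
        cfg, bank = self.cfg, self.bank
        n = cfg.grid_size
        name, jrow, icol, dpool = key
        j, i = _winner_cell((name, jrow, icol), self.templates)
        if name == "ground":
            vx, vy, valid = build_ground_template(i, j, n)
            q = self.templates.quintile_map("ground", i, j)
        else:
            vx, vy, valid = build_radial_template(i, j, n)
            q = self.templates.quintile_map("radial", i, j)
        c = np.arange(n, dtype=float)
        r = np.hypot(c[None, :] - i, c[:, None] - j)
        dist = np.exp(-((r / cfg.feedback_distance_sigma) ** 2))
        phi = np.rad2deg(np.arctan2(vy, vx))
        dmis = circular_difference(phi[:, :, None],
                                   bank.direction_prefs[None, None, :])
        wd = np.exp(-((dmis / cfg.feedback_dir_sigma) ** 2)) \
            * valid[:, :, None]
        qc = np.clip(q, 0, cfg.n_speeds - 1)
        s_pre = bank.speed_prefs[qc]                      # (H, W)
        smis = np.log2(bank.speed_prefs[None, None, :] / s_pre[:, :, None])
        ws = np.exp(-((smis / cfg.feedback_speed_sigma) ** 2))
        ws *= valid[:, :, None]
        spatial = (dist[:, :, None] * wd).astype(np.float32)  # (H, W, D)
        if self._w_sd is not None:
            nd = self._w_sd.shape[1]
            db = np.arange(nd)
            if dpool is not None:
                # disparity-tuned winner: suppression targets the winner's
                # own preferred disparity (pooled bin -> MT bin centre)
                centre = {0: 0.5, 1: 2.0, 2: 3.5}[dpool]
                wdl = mismatch_weight(db, centre, cfg.feedback_disp_sigma)
                wsd = (ws[:, :, :, None] * wdl[None, None, None, :]
                       ).astype(np.float32)               # (H, W, S, Delta)
                mstv_w = (valid[:, :, None]
                          * wdl[None, None, :]).astype(np.float32)
            else:
                # winner without disparity tuning: congruent speed-disparity
                # diagonal (fast <-> near, slow <-> far)
                wsd = (ws[:, :, :, None] * self._w_sd[None, None]
                       ).astype(np.float32)               # (H, W, S, Delta)
                # MSTv carries no speed axis: prescribe the disparity
                # congruent with the local template speed quintile
                dpre = (nd - 1) - qc                      # (H, W)
                mstv_w = mismatch_weight(db[None, None, :], dpre[:, :, None],
                                         cfg.feedback_disp_sigma)
                mstv_w = (mstv_w * valid[:, :, None]).astype(np.float32)
        else:
            wsd = ws.astype(np.float32)                   # (H, W, S)
            mstv_w = valid.astype(np.float32)             # (H, W)
        # precompose the unit-scale fields once per winner identity; each
        # step then only rescales them by the winner's current activity
        if self._w_sd is not None:
            unit = spatial[:, :, :, None, None] * wsd[:, :, None, :, :]
            unit_v = spatial[:, :, :, None] * mstv_w[:, :, None, :]
        else:
            unit = spatial[:, :, :, None] * wsd[:, :, None, :]
            unit_v = spatial * mstv_w[:, :, None]
        maps = (unit.astype(np.float32), unit_v.astype(np.float32))
        self._cache.clear()     # keep at most one winner's fields resident
        self._cache[key] = maps
        return maps

    # ------------------------------------------------------------------
    def compose(self, state: MSTdState) -> SuppressionField:
        """Suppression field for the current MSTd state."""
        win = state.winner()
        if win is None or win[4] <= 0 or not self.cfg.feedback_enabled:
            return self._zero_field()
        name, jrow, icol, extra, act = win
        dpool = None
        if self.bank.stereo:
            if name == "bandpass" and len(extra) == 2:
                dpool = extra[1]
            elif name == "summating" and len(extra) == 1:
                dpool = extra[0]
        # the suppressive signal saturates at a ceiling independent of the
        # winner's activity (keeps the shunting dynamics well inside the
        # stable Euler regime)
        scale = min(self.cfg.feedback_gain * act, self.cfg.feedback_cap)
        unit, unit_v = self._maps((name, jrow, icol, dpool))
        return SuppressionField(values=scale * unit,
                                mstv_values=scale * unit_v,
                                source_winner=(name, jrow, icol),
                                global_scale=float(scale))

    def _zero_field(self) -> SuppressionField:
        cfg, bank = self.cfg, self.bank
        n, D, S = cfg.grid_size, cfg.n_directions, cfg.n_speeds
        if bank.stereo:
            nd = len(bank.disparity_prefs)
            vals = np.zeros((n, n, D, S, nd), dtype=np.float32)
            mstv = np.zeros((n, n, D, nd), dtype=np.float32)
        else:
            vals = np.zeros((n, n, D, S), dtype=np.float32)
            mstv = np.zeros((n, n, D), dtype=np.float32)
        return SuppressionField(values=vals, mstv_values=mstv,
                                source_winner=None, global_scale=0.0)


def compose(state: MSTdState, templates: TemplateBank,
            bank: TuningBank) -> SuppressionField:
    """Functional wrapper around :class:`FeedbackComposer` (uncached)."""
    return FeedbackComposer(templates, bank).compose(state)
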