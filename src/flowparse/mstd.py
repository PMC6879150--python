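"""MSTd: global-pattern templates and the recurrent competitive network.

Four subpopulations of pattern-selective units are tiled on a 16 x 16
singularity grid (every fourth MT cell in each dimension):

* **band-pass** units match the radial direction template at one preferred
  (average) speed (and, in stereo runs, one of three pooled disparity bins);
* **speed-summating** units average the band-pass matches across speeds;
* **gradient** units (one per position) combine the radial direction
  template with an eccentricity-dependent speed map — annular subunits that
  prefer the slowest speed at the singularity and faster speeds toward the
  periphery (increasing variant) or the reverse (decreasing variant), the
  unit responding to whichever variant matches better;
* **ground** units combine the below-horizon half of the radial direction
  field with the ground-flow speed map |(j - y)| * r.

All radial templates derive from the singularity field
``Pi(i, j, x, y) = (x - i, y - j)``; ground templates from
``Lambda = (j - y) * (x - i, y - j)`` (defined at and below the horizon row
only).  Template matching is a retinotopically weighted inner product of the
(depressed) MT+ signal with the template's direction x speed(x disparity)
weights.  Because every template is a translate of a single centred kernel,
the feedforward drive of all singularities is computed at once as an FFT
cross-correlation.

The subpopulations then compete in a shunting recurrent network that
normalizes total activity: units receiving drive above an engagement
threshold recruit faster-than-linear self-excitation, which sharpens the
winner; below threshold the population evolves feedforward-only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import ClassVar, Dict, Optional, Tuple

import numpy as np
from scipy import fft as sfft

from .config import ModelConfig
from .tuning import TuningBank, circular_difference

__all__ = [
    "TemplateBank", "MSTdState",
    "build_radial_template", "build_ground_template",
    "build_gradient_subunits",
    "feedforward_drive", "recurrent_step", "population_kurtosis",
    "radial_quintile_map", "ground_quintile_map",
]

SUBPOP_ORDER = ("bandpass", "summating", "gradient", "ground")


# ---------------------------------------------------------------------------
# explicit template constructors (also used by the feedback module)
# ---------------------------------------------------------------------------

def build_radial_template(i: float, j: float, grid: int):
    """Unit-normalized radial direction field with singularity at cell (i, j).

    Returns (ux, uy, valid): unit vectors of Pi = (x - i, y - j) on the
    grid's cell lattice; the singularity cell itself is zero / invalid.
    """
    c = np.arange(grid, dtype=float)
    dx = c[None, :] - i
    dy = c[:, None] - j
    r = np.hypot(dx, dy)
    valid = r > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(valid, dx / r, 0.0)
        uy = np.where(valid, dy / r, 0.0)
    return ux, uy, valid


def build_ground_template(i: float, j: float, grid: int):
    """Ground-flow field Lambda = (j - y) * (x - i, y - j), y-up convention.

    Defined only at and below the horizon row j; above it the field is zero
    and invalid.  At the horizon row itself the vector is zero (the (j - y)
    factor vanishes), so it contributes no direction signal.
    """
    c = np.arange(grid, dtype=float)
    dx = np.broadcast_to(c[None, :] - i, (grid, grid))
    dy = np.broadcast_to(c[:, None] - j, (grid, grid))
    below = dy <= 0
    vx = np.where(below, (-dy) * dx, 0.0)
    vy = np.where(below, (-dy) * dy, 0.0)
    valid = below & (np.hypot(vx, vy) > 0)
    return vx, vy, valid


def _quintiles(values: np.ndarray, mask: np.ndarray, n_bins: int = 5):
    """Quantile-bin ``values[mask]``; returns (bin_index_map, edges).

    Cells outside the mask get bin -1.
    """
    vals = values[mask]
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1)[1:-1])
    idx = np.digitize(values, edges)
    out = np.where(mask, idx, -1)
    return out, edges


def radial_quintile_map(i: float, j: float, grid: int, n_bins: int = 5):
    """Speed-quintile index of the radial template: annuli of eccentricity.

    Quintile 0 is the slowest (central) band, n_bins-1 the fastest
    (peripheral); bin edges are eccentricity quantiles over the field.
    """
    c = np.arange(grid, dtype=float)
    r = np.hypot(c[None, :] - i, c[:, None] - j)
    q, _ = _quintiles(r, np.ones_like(r, dtype=bool), n_bins)
    return q


def ground_quintile_map(i: float, j: float, grid: int, n_bins: int = 5):
    """Speed-quintile index of the ground template ((j - y) * r profile).

    Valid (non-negative) only at and below the horizon row j.
    """
    c = np.arange(grid, dtype=float)
    dx = c[None, :] - i
    dy = c[:, None] - j
    speed = (-dy) * np.hypot(dx, dy)
    below = np.broadcast_to(dy < 0, speed.shape)
    if not below.any():
        return np.full((grid, grid), -1)
    q, _ = _quintiles(speed, below, n_bins)
    return q


def build_gradient_subunits(i: float, j: float, grid: int, n_speeds: int = 5,
                            sigma_bins: float = 1.0):
    """Annular speed-subunit weight maps of a gradient cell at (i, j).

    Returns (increasing, decreasing): arrays (n_speeds, grid, grid); map k of
    the increasing variant peaks on the annulus whose eccentricity quintile
    is k (slowest speed at the centre, fastest at the periphery); the
    decreasing variant is the increasing variant with the speed axis
    reversed.  Each map is normalized to unit sum after construction.
    """
    q = radial_quintile_map(i, j, grid, n_speeds)
    k = np.arange(n_speeds)[:, None, None]
    inc = np.exp(-(((q[None] - k) / sigma_bins) ** 2))
    inc /= inc.sum(axis=(1, 2), keepdims=True)
    dec = inc[::-1]
    return inc, dec


# ---------------------------------------------------------------------------
# template bank (FFT kernels for the full singularity grid)
# ---------------------------------------------------------------------------

def _centered_offsets(n: int, pad: int):
    """Offset coordinates u in [-(n-1), n-1] arranged on the padded circular
    lattice (index u mod pad)."""
    u = np.arange(pad)
    u = np.where(u > pad // 2, u - pad, u).astype(float)
    return u


@dataclass
class TemplateBank:
    """Precomputed MSTd template kernels for one configuration.

    Drive of every singularity is an FFT cross-correlation of the
    (direction-weighted, retinotopically weighted) centred kernel with the
    MT+ signal, normalized per template by the retinotopic mass of its
    defined cells.
    """

    cfg: ModelConfig
    bank: TuningBank
    stereo: bool
    ground_units: bool

    pad: int = field(init=False)
    sing_cells: np.ndarray = field(init=False)      # cell indices of singularities
    k_grad_inc: np.ndarray = field(init=False)      # (D, S, pad, pad//2+1)
    k_grad_dec: np.ndarray = field(init=False)      # conjugated rfft kernels
    k_ground: Optional[np.ndarray] = field(init=False)
    z_radial: np.ndarray = field(init=False)        # (m, m) full template mass
    z_ground: Optional[np.ndarray] = field(init=False)
    z_floor: float = field(init=False)              # additive evidence floor
    radial_edges: np.ndarray = field(init=False)    # quintile edges (radius)
    ground_edges: np.ndarray = field(init=False)    # quintile edges ((j-y)*r)
    dir_mass: float = field(init=False)             # sum_d of tuning overlap
    match_scale: float = field(init=False)          # perfect-match drive scale
    w_bp: np.ndarray = field(init=False)            # dense band-pass weights
    _pad_buf: Optional[np.ndarray] = field(init=False, default=None)

    def __post_init__(self):
        cfg, bank = self.cfg, self.bank
        n = cfg.grid_size
        pad = 2 * n
        self.pad = pad
        m = cfg.mstd_grid
        self.sing_cells = cfg.mstd_stride * np.arange(m)

        u = _centered_offsets(n, pad)
        ux, uy = u[None, :], u[:, None]
        r = np.hypot(ux, uy)
        infield = (np.abs(ux) < n) & (np.abs(uy) < n)
        w_r = np.where(infield, 1.0 / (1.0 + r / cfg.retinotopic_r0), 0.0)

        phi = np.rad2deg(np.arctan2(uy, ux))
        prefs = bank.direction_prefs
        # (D, pad, pad) direction-template weights, zero at the singularity
        td = np.exp(-((circular_difference(prefs[:, None, None], phi)
                       / cfg.template_dir_sigma) ** 2))
        td *= (r > 0)
        base = w_r[None] * td

        # speed-quintile edges anchored to the geometry a centred in-grid
        # template sees (offsets beyond the grid fall in the fastest bin)
        cg = np.arange(n, dtype=float) - n // 2
        r_in = np.hypot(cg[None, :], cg[:, None])
        _, self.radial_edges = _quintiles(r_in, r_in > 0)
        gs_in = (-cg[:, None]) * r_in
        below_in = np.broadcast_to(cg[:, None] < 0, gs_in.shape)
        _, self.ground_edges = _quintiles(gs_in, below_in)

        q_r = np.where(r > 0, np.digitize(r, self.radial_edges), -1)
        ks = np.arange(cfg.n_speeds)[:, None, None]
        g_inc = np.exp(-(((q_r[None] - ks) / cfg.template_speed_sigma) ** 2))
        g_inc *= (q_r >= 0)[None]
        self.k_grad_inc = np.conj(sfft.rfft2(
            base[:, None] * g_inc[None], axes=(-2, -1))).astype(np.complex64)
        self.k_grad_dec = np.conj(sfft.rfft2(
            base[:, None] * g_inc[None, ::-1],
            axes=(-2, -1))).astype(np.complex64)

        if self.ground_units:
            below = uy < 0
            gspeed = (-uy) * r
            q_g = np.where(below, np.digitize(gspeed, self.ground_edges), -1)
            g_gnd = np.exp(-(((q_g[None] - ks) / cfg.template_speed_sigma) ** 2))
            g_gnd *= (q_g >= 0)[None]
            self.k_ground = np.conj(sfft.rfft2(
                (base * below[None])[:, None] * g_gnd[None],
                axes=(-2, -1))).astype(np.complex64)
        else:
            self.k_ground = None

        # dense weight matrix for the band-pass match: the per-singularity
        # correlation is a plain inner product over (y, x, direction), which
        # BLAS evaluates faster than the padded FFT for a 16 x 16 output
        m2 = m * m
        D = len(prefs)
        w_bp = np.empty((m2, n * n * D), dtype=np.float32)
        cells = np.arange(n)
        base_f = base.astype(np.float32)          # (D, pad, pad)
        for kdx, (pj, pi) in enumerate(
                [(a, b) for a in self.sing_cells for b in self.sing_cells]):
            ry = (cells - pj) % pad
            rx = (cells - pi) % pad
            blk = base_f[:, ry][:, :, rx]         # (D, n, n)
            w_bp[kdx] = np.moveaxis(blk, 0, 2).reshape(-1)
        self.w_bp = w_bp
        self._pad_buf = None

        # per-singularity full-template mass (defined cells only); radial
        # subpopulations are normalized by the full-field template mass,
        # ground units by the mass of their below-horizon domain
        self.z_radial = self._norm(w_r * (r > 0))
        self.z_ground = self._norm(w_r * (uy < 0)) if self.ground_units else None
        # additive floor keeps heavily truncated edge templates from
        # producing spuriously large normalized matches
        self.z_floor = 0.05 * float(self.z_radial.max())

        # direction-tuning mass and the tuned-input overlap ratio: a stimulus
        # direction matched by a same-width tuning curve excites several
        # neighbouring channels, so a perfect template match integrates
        # sum_d exp(-2 (d/sigma)^2) rather than the full tuning mass
        diffs = circular_difference(prefs, 0.0) / cfg.template_dir_sigma
        self.dir_mass = float(np.exp(-(diffs ** 2)).sum())
        self.match_scale = float(np.exp(-2.0 * diffs ** 2).sum()) / self.dir_mass

    def _norm(self, kernel2d: np.ndarray) -> np.ndarray:
        """corr(ones, kernel) sampled at the singularity cells."""
        n, pad = self.cfg.grid_size, self.pad
        ones = np.zeros((pad, pad))
        ones[:n, :n] = 1.0
        c = sfft.irfft2(sfft.rfft2(ones) * np.conj(sfft.rfft2(kernel2d)),
                        s=(pad, pad))
        sc = self.sing_cells
        return np.maximum(c[np.ix_(sc, sc)], 1e-9)

    # ------------------------------------------------------------------
    _memo: ClassVar[dict] = {}

    @classmethod
    def cached(cls, cfg: ModelConfig, bank: TuningBank, stereo: bool,
               ground_units: bool) -> "TemplateBank":
        """Memoized constructor: kernel construction is deterministic given
        the configuration, so campaigns reuse one bank per configuration."""
        key = (
            tuple(sorted(
                (k, tuple(v) if isinstance(v, (list, tuple)) else v)
                for k, v in dataclasses.asdict(cfg).items())),
            tuple(bank.speed_prefs),
            None if bank.disparity_prefs is None
            else tuple(bank.disparity_prefs),
            stereo, ground_units,
        )
        if key not in cls._memo:
            if len(cls._memo) > 8:      # bound the resident kernel sets
                cls._memo.clear()
            cls._memo[key] = cls(cfg, bank, stereo=stereo,
                                 ground_units=ground_units)
        return cls._memo[key]

    @property
    def n_units_norm(self) -> int:
        """Unit count used by the competitive network's mean normalization.

        An architecture constant: it always counts the ground subpopulation,
        so toggling unused ground units does not perturb the normalization.
        """
        m2 = self.cfg.mstd_grid ** 2
        S = self.cfg.n_speeds
        if self.stereo:
            return m2 * (S * 3 + 3 + 1 + 1)
        return m2 * (S + 1 + 1 + 1)

    def quintile_map(self, kind: str, i: float, j: float) -> np.ndarray:
        """Speed-quintile index map of the template at singularity (i, j),
        using the bank's canonical (centred-template) quintile edges so the
        feedback prescriptions match the feedforward kernels.  Cells outside
        the template domain get -1."""
        n = self.cfg.grid_size
        c = np.arange(n, dtype=float)
        dx = c[None, :] - i
        dy = c[:, None] - j
        r = np.hypot(dx, dy)
        if kind == "ground":
            below = np.broadcast_to(dy < 0, r.shape)
            return np.where(below, np.digitize((-dy) * r, self.ground_edges),
                            -1)
        return np.where(r > 0, np.digitize(r, self.radial_edges), -1)

    def drive_scale(self, subpop: str) -> float:
        """Feedforward drive of a unit whose template domain is fully
        covered by matching MT+ activity at the shunting bound.  Realistic
        stimuli cover a fraction of the grid cells, so realistic drives are a
        corresponding fraction of this scale; the engagement threshold is
        expressed against it."""
        cfg = self.cfg
        gain = getattr(cfg, f"drive_gain_{subpop}")
        return gain * cfg.mtplus_bound * self.match_scale

    def engagement_threshold(self, subpop: str) -> float:
        return self.cfg.engagement_threshold * self.drive_scale(subpop)


def _pool_disparity(nplus: np.ndarray) -> np.ndarray:
    """Pool the 5 MT disparity bins to MSTd's 3 (near, mid, far) by averaging
    adjacent pairs: (0,1), (2), (3,4)."""
    near = 0.5 * (nplus[..., 0] + nplus[..., 1])
    mid = nplus[..., 2]
    far = 0.5 * (nplus[..., 3] + nplus[..., 4])
    return np.stack([near, mid, far], axis=-1)


def feedforward_drive(templates: TemplateBank, nplus: np.ndarray,
                      norms: Optional[Dict[str, np.ndarray]] = None
                      ) -> Dict[str, np.ndarray]:
    """Template-match the depressed MT+ signal against every MSTd unit.

    ``nplus``: (H, W, D, S) or (H, W, D, S, 5) array of transmitted MT+
    activity; ``norms`` are per-frame occupancy normalizations from
    :meth:`TemplateBank.occupancy_norms` (full-template masses are used when
    omitted).  Returns drives keyed by subpopulation:

    * ``bandpass``:  (m, m, S) or (m, m, S, 3)
    * ``summating``: (m, m) or (m, m, 3)  — Eq-2-style mean over speeds
    * ``gradient``:  (m, m)  — max over increasing/decreasing variants
    * ``ground``:    (m, m)  (when ground units are enabled)
    """
    cfg = templates.cfg
    stereo = nplus.ndim == 5
    if stereo != templates.stereo:
        raise ValueError("MT+ tensor and template bank disagree on stereo")
    n, pad = cfg.grid_size, templates.pad
    sc = templates.sing_cells
    if norms is None:
        norms = {"radial": templates.z_radial + templates.z_floor}
        if templates.ground_units:
            norms["ground"] = templates.z_ground + templates.z_floor
    z_rad = norms["radial"] * templates.dir_mass
    z_gnd = norms.get("ground")
    if z_gnd is not None:
        z_gnd = z_gnd * templates.dir_mass

    m = cfg.mstd_grid
    S = cfg.n_speeds
    if stereo:
        np3 = _pool_disparity(nplus)          # (H, W, D, S, 3)
        if cfg.disparity_gain_enabled:
            # the disparity-dependent gain also acts on MSTd signals
            g = np.linspace(cfg.gain_binocular_near, cfg.gain_binocular_far,
                            3).astype(nplus.dtype)
            np3 = np3 * g
        # band-pass match as a dense inner product over (y, x, direction)
        bp = (templates.w_bp @ np3.reshape(-1, S * 3)).reshape(m, m, S, 3)
        pooled = np3.mean(axis=-1)            # (H, W, D, S)
    else:
        bp = (templates.w_bp @ nplus.reshape(-1, S)).reshape(m, m, S)
        pooled = nplus

    # gradient/ground matches stay in the frequency domain: their kernels
    # vary with (direction, speed), but only a handful of inverse transforms
    # are needed after reducing over both axes
    arr = np.moveaxis(pooled, (2, 3), (0, 1))  # (D, S, H, W)
    if templates._pad_buf is None or templates._pad_buf.shape[:2] != arr.shape[:2]:
        templates._pad_buf = np.zeros(arr.shape[:-2] + (pad, pad),
                                      dtype=np.float32)
    buf = templates._pad_buf
    buf[..., :n, :n] = arr
    n_pooled = sfft.rfft2(buf, axes=(-2, -1))

    def corr(prod_hat):
        """Inverse transform of a frequency-domain correlation product,
        sampled at the singularity cells."""
        c = sfft.irfft2(prod_hat, axes=(-2, -1), s=(pad, pad))
        return np.maximum(c[..., sc, :][..., sc], 0.0)

    if stereo:
        # a disparity-selective template integrates only the inputs at its
        # preferred depth, so its match is normalized by the corresponding
        # share of the template mass (3 pooled disparity bins)
        zr_e = z_rad[:, :, None, None] / 3.0
    else:
        zr_e = z_rad[:, :, None]
    drives = {"bandpass": cfg.drive_gain_bandpass * bp / zr_e}
    drives["summating"] = (cfg.drive_gain_summating / cfg.drive_gain_bandpass
                           ) * drives["bandpass"].mean(axis=2)

    gi = corr(np.einsum('dsxy,dsxy->xy', n_pooled, templates.k_grad_inc))
    gd = corr(np.einsum('dsxy,dsxy->xy', n_pooled, templates.k_grad_dec))
    drives["gradient"] = cfg.drive_gain_gradient * np.maximum(gi, gd) / z_rad

    if templates.ground_units and templates.k_ground is not None:
        gg = corr(np.einsum('dsxy,dsxy->xy', n_pooled, templates.k_ground))
        drives["ground"] = cfg.drive_gain_ground * gg / z_gnd
    return drives


# ---------------------------------------------------------------------------
# recurrent competitive dynamics
# ---------------------------------------------------------------------------

@dataclass
class MSTdState:
    """Activities of the MSTd subpopulations plus diagnostics."""

    activity: Dict[str, np.ndarray]
    engaged: Dict[str, bool] = field(default_factory=dict)
    recurrent_signal: float = 0.0

    @classmethod
    def zeros(cls, templates: TemplateBank) -> "MSTdState":
        cfg = templates.cfg
        m = cfg.mstd_grid
        S = cfg.n_speeds
        if templates.stereo:
            act = {"bandpass": np.zeros((m, m, S, 3)),
                   "summating": np.zeros((m, m, 3))}
        else:
            act = {"bandpass": np.zeros((m, m, S)),
                   "summating": np.zeros((m, m))}
        act["gradient"] = np.zeros((m, m))
        if templates.ground_units:
            act["ground"] = np.zeros((m, m))
        return cls(activity=act,
                   engaged={k: False for k in act})

    @property
    def stereo(self) -> bool:
        return self.activity["bandpass"].ndim == 4

    def subpops(self):
        return [k for k in SUBPOP_ORDER if k in self.activity]

    def total_activity(self) -> float:
        return float(sum(a.sum() for a in self.activity.values()))

    def peak_activity(self) -> float:
        return float(max(a.max() for a in self.activity.values()))

    def winner(self) -> Tuple[str, int, int, tuple, float]:
        """Most active unit: (subpop, j_row, i_col, extra_prefs, activity).

        ``extra_prefs`` holds the unit's indices beyond position — (speed[,
        pooled disparity]) for band-pass, (pooled disparity,) for stereo
        speed-summating units, () otherwise.  Ties break to the lowest
        linear index in the fixed subpopulation order (band-pass,
        speed-summating, gradient, ground), row-major within each array.
        """
        best = None
        for name in self.subpops():
            a = self.activity[name]
            flat = int(np.argmax(a))
            val = float(a.ravel()[flat])
            if best is None or val > best[4]:
                idx = np.unravel_index(flat, a.shape)
                best = (name, int(idx[0]), int(idx[1]),
                        tuple(int(k) for k in idx[2:]), val)
        return best

    def copy(self) -> "MSTdState":
        return MSTdState(
            activity={k: v.copy() for k, v in self.activity.items()},
            engaged=dict(self.engaged),
            recurrent_signal=self.recurrent_signal)


def recurrent_step(state: MSTdState, drives: Dict[str, np.ndarray],
                   templates: TemplateBank, dt: float) -> MSTdState:
    """One Euler step of the normalizing competitive network.

    dA_i/dt = -a A_i + (B - A_i)(I_i + f(A_i)) - A_i * S,  with the broad
    population inhibition S = kappa * mean_j (I_j + f(A_j)) over *all* MSTd
    units (kappa = ``mstd_norm_pool``; the mean makes the normalization
    insensitive to how many tuning channels a run instantiates), and
    self-excitation f(A) = k A gated on units whose feedforward drive exceeds
    the engagement threshold.  The recurrent term amplifies strongly driven
    units while S normalizes the population; total steady-state activity is
    bounded by B * N / kappa.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cfg = templates.cfg
    k = cfg.mstd_recurrent_gain
    fs = {}
    total_rec = 0.0
    tot = 0.0
    for name in state.subpops():
        A = state.activity[name]
        I = drives[name]
        gamma = templates.engagement_threshold(name)
        gate = I > gamma
        f = np.where(gate, k * A, 0.0)
        fs[name] = f
        state.engaged[name] = bool(gate.any())
        total_rec += float(f.sum())
        tot += float((I + f).sum())
    S = cfg.mstd_norm_pool * tot / templates.n_units_norm
    new_act = {}
    B, a = cfg.mstd_bound, cfg.mstd_decay
    for name in state.subpops():
        A = state.activity[name]
        E = drives[name] + fs[name]
        new_act[name] = np.maximum(
            A + dt * (-a * A + (B - A) * E - A * S), 0.0)
    return MSTdState(activity=new_act, engaged=dict(state.engaged),
                     recurrent_signal=total_rec)


def population_kurtosis(activity: np.ndarray) -> float:
    """Standardized fourth central moment of a (flattened) population
    response; NaN when the variance is zero (undefined)."""
    a = np.asarray(activity, dtype=float).ravel()
    if a.size < 4:
        raise ValueError("need at least 4 units")
    mu = a.mean()
    var = ((a - mu) ** 2).mean()
    if var == 0:
        return float("nan")
    return float(((a - mu) ** 4).mean() / var ** 2)
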