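"""Analytic optic-flow stimuli for the three simulation campaigns.

Each generator produces a :class:`FlowSequence` — a time-indexed set of sparse
point motions (retinal position, retinal velocity, optional binocular
disparity) plus an embedded probe object — which :func:`rasterize` converts to
the model's 64 x 64 grid input (:class:`GridFlow`).

Stimuli are parameterized directly by retinal quantities (the self-motion
component speed at the probe, eccentricities, optical speeds): the physical
translation speeds quoted for the source experiments are treated as condition
labels, since the screen geometry needed to map between the two is not part of
the model.  Coordinates are in degrees, origin at the visual-field centre
(which is also the focus of expansion for all scenarios), x rightward,
y upward, angles CCW from +x.

Fiducial (background) points are fixed samples of the analytic velocity
field — the model consumes vectors, not dot trajectories — while the probe
translates along its retinal trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import yaml

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi

__all__ = [
    "SceneSpec", "ProbeSpec", "Frame", "FlowSequence", "GridFlow",
    "gen_frontoparallel", "gen_ground", "gen_cloud", "rasterize",
    "generate",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Parametric description of the self-motion stimulus.

    ``component_speed_at_probe`` is the retinal speed (deg/s) of the
    self-motion component at the probe's location; it fixes the overall scale
    of the flow field.  ``depth_range`` (near, far; metres) is required for
    the ground and cloud scenarios.  ``condition_mask`` implements the
    stereo-cloud ablation conditions.
    """

    scenario: str                       # frontoparallel | ground | cloud
    component_speed_at_probe: float     # deg/s
    self_motion_speed: float = 0.0      # m/s, label only
    depth_range: Optional[Tuple[float, float]] = None
    field_of_view: float = 40.0         # deg, square
    duration: float = 1.0               # s
    frame_rate: float = 30.0
    stereo: bool = False
    condition_mask: str = "full"        # full | no_local_depth | no_local_frontal_view
    n_points: int = 300
    rng_seed: int = 0
    interocular_m: float = 0.064

    def __post_init__(self):
        if self.scenario not in ("frontoparallel", "ground", "cloud"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.self_motion_speed > 0 and not self.component_speed_at_probe > 0:
            raise ValueError("component_speed_at_probe must be > 0 for nonzero self-motion")
        if self.scenario in ("ground", "cloud"):
            if self.depth_range is None:
                raise ValueError(f"{self.scenario} scenario requires depth_range")
            near, far = self.depth_range
            if not near < far:
                raise ValueError("depth_range must satisfy near < far")
        if self.condition_mask != "full" and self.scenario != "cloud":
            raise ValueError("condition_mask applies to the cloud scenario only")
        if self.condition_mask not in ("full", "no_local_depth", "no_local_frontal_view"):
            raise ValueError(f"unknown condition_mask {self.condition_mask!r}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class ProbeSpec:
    """The moving probe object embedded in the flow field.

    By experimental design the probe's object-motion component is
    perpendicular to the self-motion component at its location.
    ``object_direction`` is the world-relative retinal direction of the
    object component (deg CCW from +x).
    """

    offset_from_foe: Tuple[float, float] = (0.0, -4.0)  # deg
    object_speed: float = 2.0          # deg/s
    object_direction: float = 0.0      # deg
    diameter: float = 1.0              # deg
    onset: float = 0.0                 # s
    offset: float = 1.0                # s
    depth: Optional[float] = None      # m (cloud: centre depth)

    def __post_init__(self):
        if not (0.0 <= self.onset < self.offset):
            raise ValueError("require 0 <= onset < offset")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(*self.offset_from_foe))


# ---------------------------------------------------------------------------
# flow containers
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    pos: np.ndarray                 # (N, 2) deg
    vel: np.ndarray                 # (N, 2) deg/s
    disparity: Optional[np.ndarray] # (N,) arcmin, or None for monocular
    is_probe: np.ndarray            # (N,) bool


@dataclass
class FlowSequence:
    frames: List[Frame]
    scene: SceneSpec
    probe: ProbeSpec
    probe_retinal_velocity: np.ndarray = field(default=None)  # (2,) deg/s
    self_motion_component: np.ndarray = field(default=None)   # (2,) deg/s

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def probe_position(self, f: int) -> Optional[np.ndarray]:
        fr = self.frames[f]
        if fr.is_probe.any():
            return fr.pos[fr.is_probe].mean(axis=0)
        return None


@dataclass
class GridFlow:
    """Per-frame rasterized motion field on the model grid.

    ``disparity`` uses NaN as the no-stimulus sentinel; velocity is zero and
    ``occupancy`` False where no point projects.
    """

    vx: np.ndarray          # (F, H, W) deg/s
    vy: np.ndarray          # (F, H, W)
    disparity: np.ndarray   # (F, H, W) arcmin, NaN sentinel
    occupancy: np.ndarray   # (F, H, W) bool
    field_of_view: float
    frame_rate: float
    dropped_points: int = 0

    @property
    def n_frames(self) -> int:
        return self.vx.shape[0]

    @property
    def grid_size(self) -> int:
        return self.vx.shape[1]

    def speed(self, f: int) -> np.ndarray:
        return np.hypot(self.vx[f], self.vy[f])

    # -- serialization ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as h5:
            h5.create_dataset("vx", data=self.vx, compression="gzip")
            h5.create_dataset("vy", data=self.vy, compression="gzip")
            h5.create_dataset("disparity", data=self.disparity, compression="gzip")
            h5.create_dataset("occupancy", data=self.occupancy, compression="gzip")
            h5.attrs["field_of_view"] = self.field_of_view
            h5.attrs["frame_rate"] = self.frame_rate
            h5.attrs["dims"] = "frame,y,x"

    @classmethod
    def from_hdf5(cls, path) -> "GridFlow":
        import h5py
        with h5py.File(path, "r") as h5:
            return cls(
                vx=h5["vx"][...], vy=h5["vy"][...],
                disparity=h5["disparity"][...],
                occupancy=h5["occupancy"][...].astype(bool),
                field_of_view=float(h5.attrs["field_of_view"]),
                frame_rate=float(h5.attrs["frame_rate"]),
            )

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path, vx=self.vx, vy=self.vy, disparity=self.disparity,
            occupancy=self.occupancy,
            field_of_view=self.field_of_view, frame_rate=self.frame_rate)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _probe_components(scene: SceneSpec, probe: ProbeSpec):
    """Self-motion and object components of the probe's retinal motion.

    The self-motion component points radially away from the FOE at the
    probe's location; the object component is perpendicular to it by
    experimental design, oriented along ``probe.object_direction``.
    """
    off = np.asarray(probe.offset_from_foe, dtype=float)
    r = np.hypot(*off)
    if r == 0:
        raise ValueError("probe at the FOE: self-motion component direction undefined")
    radial = off / r
    comp = scene.component_speed_at_probe * radial
    obj_dir = np.deg2rad(probe.object_direction)
    obj = probe.object_speed * np.array([np.cos(obj_dir), np.sin(obj_dir)])
    if abs(float(obj @ comp)) > 1e-9 * max(1.0, probe.object_speed * scene.component_speed_at_probe):
        raise ValueError("object and self-motion components must be perpendicular")
    return comp, obj


def _probe_points(center: np.ndarray, diameter: float, cell: float):
    """Sample points covering the probe disk at roughly grid-cell density."""
    n = max(1, int(np.ceil(diameter / cell)) + 1)
    g = np.linspace(-diameter / 2, diameter / 2, 2 * n + 1)
    xx, yy = np.meshgrid(g, g)
    keep = xx**2 + yy**2 <= (diameter / 2) ** 2 + 1e-12
    pts = np.stack([xx[keep], yy[keep]], axis=1)
    return pts + center


def _assemble(scene, probe, bg_pos, bg_vel, bg_disp, probe_vel, probe_disp,
              probe_path_center):
    """Build frames: static background samples plus the moving probe."""
    frames = []
    cell = scene.field_of_view / 64.0
    dt = 1.0 / scene.frame_rate
    t_mid = 0.5 * (probe.onset + probe.offset)
    for f in range(scene.n_frames):
        t = f * dt
        pos, vel = bg_pos, bg_vel
        disp = bg_disp
        is_probe = np.zeros(len(bg_pos), dtype=bool)
        if probe.onset <= t < probe.offset:
            center = probe_path_center + probe_vel * (t - t_mid)
            ppts = _probe_points(center, probe.diameter, cell)
            pos = np.vstack([bg_pos, ppts])
            vel = np.vstack([bg_vel, np.tile(probe_vel, (len(ppts), 1))])
            if disp is not None:
                disp = np.concatenate([bg_disp, np.full(len(ppts), probe_disp)])
            is_probe = np.concatenate([is_probe, np.ones(len(ppts), dtype=bool)])
        frames.append(Frame(pos=pos, vel=vel, disparity=disp, is_probe=is_probe))
    comp, _ = _probe_components(scene, probe)
    return FlowSequence(frames=frames, scene=scene, probe=probe,
                        probe_retinal_velocity=np.asarray(probe_vel, float),
                        self_motion_component=comp)


def depth_to_disparity(depth_m, interocular_m: float = 0.064) -> np.ndarray:
    """Binocular parallax of a point at ``depth_m`` metres, in arcmin.

    Uses the small-angle absolute disparity IOD/Z; only the (strictly
    decreasing) ordering with depth and the relative magnitudes matter
    downstream.
    """
    return interocular_m / np.asarray(depth_m, dtype=float) * ARCMIN_PER_RAD


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_frontoparallel(scene: SceneSpec, probe: ProbeSpec) -> FlowSequence:
    """Approach toward a frontoparallel plane of dots (monocular).

    Optical acceleration is removed, so every fiducial point carries a
    constant radial velocity with speed k * (distance to FOE), with k fixed
    so the speed at the probe's eccentricity equals the configured
    self-motion component speed.
    """
    if scene.scenario != "frontoparallel":
        raise ValueError("scene.scenario must be 'frontoparallel'")
    comp, obj = _probe_components(scene, probe)
    k = scene.component_speed_at_probe / probe.eccentricity
    rng = np.random.default_rng(scene.rng_seed)
    half = scene.field_of_view / 2
    pos = rng.uniform(-half, half, size=(scene.n_points, 2))
    vel = k * pos  # radial, speed = k * distance to FOE (FOE at origin)
    probe_vel = comp + obj
    return _assemble(scene, probe, pos, vel, None, probe_vel, None,
                     np.asarray(probe.offset_from_foe, float))


def gen_ground(scene: SceneSpec, probe: ProbeSpec) -> FlowSequence:
    """Forward travel over a textured ground plane (monocular).

    With y-up image coordinates and the horizon through the FOE row, the
    ground flow of forward translation is v(x, y) = kappa * (-y) * (x, y) for
    y < 0 and zero at/above the horizon; kappa is set from the probe's
    self-motion component speed: kappa = c / ecc^2 for a probe ecc deg below
    the FOE.  The speed thus grows with angular distance below the horizon
    (motion parallax: lower in the field = nearer on the ground = faster).
    """
    if scene.scenario != "ground":
        raise ValueError("scene.scenario must be 'ground'")
    off = np.asarray(probe.offset_from_foe, float)
    if off[1] >= 0:
        raise ValueError("ground probe must lie below the horizon")
    comp, obj = _probe_components(scene, probe)
    ecc = probe.eccentricity
    kappa = scene.component_speed_at_probe / ecc**2

    near, far = scene.depth_range
    # map depth to image elevation via y = -fh/Z with fh chosen so the near
    # edge of the depth range projects to the bottom of the field
    fh = near * scene.field_of_view / 2
    y_lo = max(-scene.field_of_view / 2, -fh / near)
    y_hi = -fh / far
    rng = np.random.default_rng(scene.rng_seed)
    half = scene.field_of_view / 2
    xs = rng.uniform(-half, half, size=scene.n_points)
    ys = rng.uniform(y_lo, y_hi, size=scene.n_points)
    pos = np.stack([xs, ys], axis=1)
    vel = kappa * (-ys)[:, None] * pos
    probe_vel = comp + obj
    return _assemble(scene, probe, pos, vel, None, probe_vel, None, off)


def gen_cloud(scene: SceneSpec, probe: ProbeSpec) -> FlowSequence:
    """Forward travel through a stereo cloud of wire-frame cubes.

    Vertices uniformly fill the viewing volume (uniform in image position and
    in depth); per-vertex retinal velocity is the radial expansion
    (x, y) * T/Z of forward translation, with the translation rate T fixed so
    the probe's self-motion component matches the configured value at the
    probe's centre depth.  Per-vertex disparity follows from depth via the
    interocular distance.
    """
    if scene.scenario != "cloud":
        raise ValueError("scene.scenario must be 'cloud'")
    if not scene.stereo:
        raise ValueError("cloud scenario is stereo by design")
    comp, obj = _probe_components(scene, probe)
    near, far = scene.depth_range
    z_probe = probe.depth if probe.depth is not None else 0.5 * (near + far)
    # effective translation rate (m/s) from the probe's component speed
    T = scene.component_speed_at_probe * z_probe / probe.eccentricity

    n_cubes = max(1, scene.n_points // 8)
    rng = np.random.default_rng(scene.rng_seed)
    half = scene.field_of_view / 2
    centers_img = rng.uniform(-half, half, size=(n_cubes, 2))
    centers_z = rng.uniform(near, far, size=n_cubes)
    edge = 0.06  # m, wire-frame cube edge
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                        for sz in (-1, 1)], dtype=float) * (edge / 2)
    z = (centers_z[:, None] + corners[None, :, 2]).ravel()
    # lateral corner offsets project with 1/Z
    dimg = (np.rad2deg(corners[None, :, :2] / z.reshape(n_cubes, 8, 1)))
    pos = (centers_img[:, None, :] + dimg).reshape(-1, 2)
    vel = pos * (T / z)[:, None]
    disp = depth_to_disparity(z, scene.interocular_m)

    # condition masks (applied per vertex)
    if scene.condition_mask == "no_local_depth":
        lo = near + 0.25 * (far - near)
        hi = near + 0.75 * (far - near)
        keep = ~((z >= lo) & (z <= hi))
    elif scene.condition_mask == "no_local_frontal_view":
        keep = np.hypot(*(pos - np.asarray(probe.offset_from_foe)).T) > 4.0
    else:
        keep = np.ones(len(pos), dtype=bool)
    if not keep.any():
        raise ValueError("empty vertex set after condition mask")
    pos, vel, disp = pos[keep], vel[keep], disp[keep]

    probe_vel = comp + obj
    probe_disp = float(depth_to_disparity(z_probe, scene.interocular_m))
    return _assemble(scene, probe, pos, vel, disp, probe_vel, probe_disp,
                     np.asarray(probe.offset_from_foe, float))


_GENERATORS = {
    "frontoparallel": gen_frontoparallel,
    "ground": gen_ground,
    "cloud": gen_cloud,
}


def generate(scene: SceneSpec, probe: ProbeSpec) -> FlowSequence:
    """Dispatch to the scenario's generator."""
    return _GENERATORS[scene.scenario](scene, probe)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(seq: FlowSequence, grid: Tuple[int, int] = (64, 64)) -> GridFlow:
    """Nearest-cell rasterization of a FlowSequence.

    Multiple points in one cell are averaged (velocity and disparity); cells
    with no projected point have zero velocity, NaN disparity and False
    occupancy.  Points outside the field of view are dropped (counted in
    ``dropped_points``).  Output arrays are indexed (frame, y, x) with row 0
    at the bottom of the visual field (y-up).

    Cell (iy, ix) is centred at ((ix - nx/2) * cx, (iy - ny/2) * cy) degrees,
    so the visual-field centre (the FOE) sits exactly on the centre of cell
    (ny/2, nx/2) — and hence on an MSTd singularity-grid node.
    """
    ny, nx = grid
    if ny <= 0 or nx <= 0:
        raise ValueError("grid dims must be positive")
    fov = seq.scene.field_of_view
    cy, cx = fov / ny, fov / nx
    F = seq.n_frames
    stereo = seq.frames[0].disparity is not None or seq.scene.stereo
    vx = np.zeros((F, ny, nx))
    vy = np.zeros((F, ny, nx))
    dsp = np.full((F, ny, nx), np.nan)
    occ = np.zeros((F, ny, nx), dtype=bool)
    dropped = 0
    for f, fr in enumerate(seq.frames):
        if len(fr.pos) == 0:
            continue
        ix = np.rint(fr.pos[:, 0] / cx).astype(int) + nx // 2
        iy = np.rint(fr.pos[:, 1] / cy).astype(int) + ny // 2
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        dropped += int((~ok).sum())
        ix, iy = ix[ok], iy[ok]
        flat = iy * nx + ix
        cnt = np.bincount(flat, minlength=ny * nx).astype(float)
        has = cnt > 0
        sx = np.bincount(flat, weights=fr.vel[ok, 0], minlength=ny * nx)
        sy = np.bincount(flat, weights=fr.vel[ok, 1], minlength=ny * nx)
        vx[f].ravel()[has] = sx[has] / cnt[has]
        vy[f].ravel()[has] = sy[has] / cnt[has]
        occ[f] = has.reshape(ny, nx)
        if fr.disparity is not None:
            sd = np.bincount(flat, weights=fr.disparity[ok], minlength=ny * nx)
            dfl = dsp[f].ravel()
            dfl[has] = sd[has] / cnt[has]
    return GridFlow(vx=vx, vy=vy, disparity=dsp, occupancy=occ,
                    field_of_view=fov, frame_rate=seq.scene.frame_rate,
                    dropped_points=dropped)


# ---------------------------------------------------------------------------
# YAML config round trip (CLI support)
# ---------------------------------------------------------------------------

def load_stimulus_yaml(path):
    """Read a scene+probe YAML file into (SceneSpec, ProbeSpec)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scene_raw = dict(raw.get("scene", {}))
    if "depth_range" in scene_raw and scene_raw["depth_range"] is not None:
        scene_raw["depth_range"] = tuple(scene_raw["depth_range"])
    probe_raw = dict(raw.get("probe", {}))
    if "offset_from_foe" in probe_raw:
        probe_raw["offset_from_foe"] = tuple(probe_raw["offset_from_foe"])
    return SceneSpec(**scene_raw), ProbeSpec(**probe_raw)
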