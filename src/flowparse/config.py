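"""Model configuration.

All tunable constants of the MT/MST competitive-dynamics model live here, in a
single dataclass that can be round-tripped through YAML.  Parameters fall into
two classes:

* **structural** values fixed by the model architecture (grid resolution, the
  24 x 5 x 5 tuning lattice, the 16 x 16 MSTd singularity grid, Euler step
  size), and
* **calibration** values (tuning bandwidths, surround radii, synaptic
  depression constants, feedback sigmas, drive scales, the recurrent
  engagement threshold) whose magnitudes are not pinned down by physiology and
  were set once so the three stimulus campaigns reproduce the qualitative and
  printed quantitative behaviour of the human flow-parsing data.  See
  docs/methods.md for the rationale behind each.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass
class ModelConfig:
    # --- spatial / temporal structure -------------------------------------
    grid_size: int = 64            # MT retinotopic grid (grid_size x grid_size)
    mstd_stride: int = 4           # MSTd singularities sample every 4th MT cell
    field_of_view: float = 40.0    # deg, square
    frame_rate: float = 30.0       # input frames per second
    steps_per_frame: int = 10      # Euler steps per input frame (dt ~ 3.3 ms)

    # --- MT Layer 4/6 tuning lattice --------------------------------------
    n_directions: int = 24         # 15 deg apart
    n_speeds: int = 5
    n_disparities: int = 5         # only instantiated for stereo runs
    direction_sigma: float = 30.0  # deg, circular-Gaussian tuning width
    speed_sigma_oct: float = 1.0   # octaves, log-Gaussian tuning width
    # disparity tuning sigma defaults to one inter-preference spacing (None)
    disparity_sigma: Optional[float] = None

    # speed preferences per scenario family (deg/s, log-spaced over the
    # family's stimulus dynamic range, then frozen here for reproducibility)
    speed_prefs_frontoparallel: tuple = (3.7, 8.0, 15.7, 25.7, 41.4)
    speed_prefs_ground: tuple = (3.2, 12.5, 24.8, 42.1, 73.9)
    speed_prefs_cloud: tuple = (4.2, 6.8, 8.8, 11.5, 18.0)

    # --- disparity-dependent response gain (stereo only) -------------------
    gain_monocular: float = 1.0
    gain_binocular_near: float = 1.5
    gain_binocular_far: float = 1.15
    disparity_gain_enabled: bool = True
    interocular_m: float = 0.064   # m, used to map depth -> disparity

    # --- MT+ (reinforcing surround, feeds MSTd) ---------------------------
    mtplus_radius: float = 2.0     # grid cells, Gaussian integration sigma
    mtplus_decay: float = 5.0      # 1/s, leaky decay a
    mtplus_bound: float = 2.0      # shunting upper bound B
    mtplus_drive_gain: float = 6.0
    mtplus_surround_gain: float = 8.0  # weight of pooled neighbourhood term

    # --- MT+ -> MSTd depressing synapses ----------------------------------
    depress_rate: float = 0.3      # efficacy depletion per unit activity / s
    depress_tau: float = 0.5       # s, recovery time constant

    # --- MT- (antagonistic surround, feeds MSTv) --------------------------
    mtminus_radius: float = 3.0    # grid cells, surround sigma
    mtminus_decay: float = 10.0
    mtminus_bound: float = 1.0
    mtminus_center_gain: float = 12.0
    mtminus_surround_gain: float = 20.0
    surround_dir_sigma: float = 30.0   # deg, surround tuning-similarity width
    surround_speed_sigma: float = 1.0  # octaves
    surround_disp_sigma: float = 1.0   # disparity bins

    # --- MSTd templates & competitive network -----------------------------
    retinotopic_r0: float = 10.0   # cells, scale of 1/(1+r/r0) distance weight
    template_dir_sigma: float = 30.0   # deg, template direction acceptance
    template_speed_sigma: float = 1.0  # quintile bins, soft speed-map match
    mstd_decay: float = 3.0
    mstd_bound: float = 1.0
    mstd_norm_pool: float = 1000.0  # population-inhibition gain (x mean drive)
    mstd_recurrent_gain: float = 60.0
    engagement_threshold: float = 0.225  # fraction of normalized drive scale
    drive_gain_bandpass: float = 0.2
    drive_gain_summating: float = 0.2
    drive_gain_gradient: float = 0.17
    drive_gain_ground: float = 0.12
    ground_units: bool = True

    # --- MSTd -> MT-/MSTv suppressive feedback ----------------------------
    feedback_gain: float = 13000.0
    feedback_cap: float = 350.0          # saturation of the feedback signal
    feedback_dir_sigma: float = 45.0     # deg  (Gaussian mismatch weighting)
    feedback_speed_sigma: float = 0.75   # octaves
    feedback_disp_sigma: float = 1.0     # disparity bins
    feedback_distance_sigma: float = 16.0  # grid cells
    feedback_enabled: bool = True

    # --- MSTv -------------------------------------------------------------
    mstv_decay: float = 14.0
    mstv_bound: float = 1.0
    mstv_center_gain: float = 16.0
    mstv_surround_gain: float = 6.0
    mstv_radius: float = 3.0

    # --- run control -------------------------------------------------------
    stabilization_band: float = 1.0   # deg
    stabilization_frames: int = 5     # frames the readout must stay in band
    max_hold_seconds: float = 3.0     # cap on input-held integration

    # ----------------------------------------------------------------------
    @property
    def dt(self) -> float:
        """Euler step size in seconds."""
        return 1.0 / (self.frame_rate * self.steps_per_frame)

    @property
    def mstd_grid(self) -> int:
        return self.grid_size // self.mstd_stride

    @property
    def cell_deg(self) -> float:
        """Angular size of one grid cell (deg)."""
        return self.field_of_view / self.grid_size

    def direction_prefs(self):
        import numpy as np
        return np.arange(self.n_directions) * (360.0 / self.n_directions)

    def speed_prefs(self, scenario: str):
        import numpy as np
        key = {
            "frontoparallel": self.speed_prefs_frontoparallel,
            "ground": self.speed_prefs_ground,
            "cloud": self.speed_prefs_cloud,
        }[scenario]
        return np.asarray(key, dtype=float)

    def scaled(self, grid_size: int) -> "ModelConfig":
        """Return a copy at a reduced grid resolution.

        Receptive-field radii and the feedback distance falloff are scaled
        proportionally so the model's spatial structure (in deg) is preserved.
        Used for fast, qualitative runs; quantitative results are produced at
        the default 64 x 64 resolution.
        """
        f = grid_size / self.grid_size
        return dataclasses.replace(
            self,
            grid_size=grid_size,
            mstd_stride=max(1, round(self.mstd_stride * f)),
            mtplus_radius=self.mtplus_radius * f,
            mtminus_radius=self.mtminus_radius * f,
            mstv_radius=self.mstv_radius * f,
            retinotopic_r0=self.retinotopic_r0 * f,
            feedback_distance_sigma=self.feedback_distance_sigma * f,
            # template drives scale with per-cell stimulus coverage, which
            # grows as the cell area when the same dots land on fewer cells
            engagement_threshold=self.engagement_threshold / f ** 2,
        )

    # --- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("speed_prefs_frontoparallel", "speed_prefs_ground",
                    "speed_prefs_cloud"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)
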