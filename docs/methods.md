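# Methods

`flowparse` simulates a recurrent competitive-dynamics model of primate
MT/MST that recovers world-relative object motion during observer
self-motion ("flow parsing").  This note records the model equations, the
stimulus generators, the calibration choices, and the limits of what the
simulations show.

## The computational problem

A moving observer sees, at the retina, the sum of two motion fields: a
global pattern caused by self-motion (radial expansion from the focus of
expansion, FOE, during forward translation) and the independent motion of
any moving object.  To perceive the object's movement relative to the
stationary world, the visual system must estimate the self-motion pattern
and subtract the appropriate component from the object's retinal motion.
The amount removed is quantified by the *flow-parsing gain*: with the object
component `o` and self-motion component `c` perpendicular by experimental
design, the retinal direction lies `beta = atan(c/o)` away from the
world-relative direction; a decoded shift `theta` toward the world direction
leaves a residual `r = o * tan(beta - theta)` and a gain `1 - r/c` (0 = raw
retinal motion perceived, 1 = full world-relative recovery).

## Circuit

```
input flow field -> MT L4/6 -> MT+  --(depressing synapses)-->  MSTd
                            -> MT-  <--(suppressive feedback)--  MSTd
                               MT-  ->  MSTv  ->  population-vector readout
```

* **MT L4/6** — separable tuning on a 64 x 64 retinotopic grid: 24
  directions (circular Gaussian, sigma 30 deg), 5 speeds (log-Gaussian,
  sigma 1 octave, preferences at the quintiles of the scenario family's
  speed distribution), and in stereo runs 5 disparities (Gaussian, sigma =
  one preference spacing) with a response gain that is largest for near
  disparities (1.5) and decays to 1.15 at the far end, reflecting the
  stronger responses to binocularly viewed flow.
* **MT+** — reinforcing surrounds: same-preference spatial integration
  (Gaussian, sigma 2 cells) into a shunting leaky integrator (bound 2).
  MT+ output reaches MSTd through depressing synapses
  (`de/dt = (1-e)/tau - rate*e*N`, tau 0.5 s, rate 0.3), which attenuate
  tonic signals.
* **MSTd** — four template subpopulations on a 16 x 16 singularity grid
  (every 4th MT cell): band-pass (radial direction template x one speed
  channel x, in stereo, one of three pooled disparity bins),
  speed-summating (uniform mean over the band-pass speed channels),
  gradient (radial template with annular speed-quintile maps, increasing
  and decreasing variants sharing one unit per position), and ground
  (below-horizon template `(j - y) * (x - i, y - j)` with its own speed
  map).  A template match is the retinotopically weighted
  (`1/(1 + r/10 cells)`) inner product with the depressed MT+ signal,
  normalized by the template's defined mass; every template is a translate
  of a centred kernel, so all 256 positions are matched at once (dense
  inner product for band-pass, FFT cross-correlation for the
  speed-mapped gradient/ground kernels).  The subpopulations then compete:
  `dA/dt = -a A + (B - A)(I + f(A)) - A * S` with broad inhibition
  `S = kappa * mean(I + f)` over all units (kappa 1000) and gated linear
  self-excitation `f = k A` (k 60) for units whose drive exceeds the
  engagement threshold.  Total activity is bounded; broad, uncertain drive
  patterns produce weak winners, peaked patterns strong ones.
* **Feedback** — the single most active MSTd unit suppresses MT-/MSTv units
  that locally match its template: Gaussian mismatch weights per dimension
  (direction sigma 45 deg, log-speed sigma 0.75 octave, disparity sigma
  1 bin), a Gaussian retinotopic falloff from the winner's singularity
  (sigma 16 cells), scaled by the winner's activity with a saturation
  ceiling.  A disparity-tuned winner targets its own preferred disparity;
  winners without disparity tuning use the congruent speed-disparity
  diagonal (fast <-> near, slow <-> far).
* **MT-** — antagonistic surrounds: shunting on-center/off-surround with
  feedforward lateral inhibition from similarly tuned neighbours (spatial
  sigma 3 cells; similarity Gaussians over direction/speed/disparity with
  matched-tuning weight 1) plus the feedback field.
* **MSTv / readout** — MT- pooled uniformly over speed, integrated
  on-center/off-surround minus feedback; the object direction is the
  population vector of the direction-tuned MSTv units whose receptive
  fields contain the probe.  The decoded shift away from the probe's
  retinal direction gives the flow-parsing gain.

Integration is Euler with ten steps per 30 frames/s input frame
(dt ~ 3.3 ms).  After the last frame the final motion vectors are held
until the decoded direction stays within 1 deg for five frames' worth of
steps (cap 3 s).  The object-motion pathway is integrated from 350 ms
before probe onset (it has no influence on the self-motion estimate and its
time constants are well below 100 ms, so it is equilibrated when the probe
appears).

## Stimuli

All three campaigns are generated analytically and rasterized to the
64 x 64 grid (nearest cell; multiple points averaged; the FOE sits exactly
on a grid cell and hence on a singularity-grid node).  Stimuli are
parameterized by retinal quantities; quoted physical translation speeds are
treated as condition labels because the screen geometry that maps between
the two is not part of the model.

* **Frontoparallel plane** (monocular): 300 fixed fiducial samples of a
  constant radial field, speed = k x distance-to-FOE with k set so the
  speed at the probe's 4-deg eccentricity equals the condition's component
  speed (1–10 deg/s); probe moves horizontally at 2 or 6 deg/s for the
  whole 1-s trial.
* **Ground plane** (monocular): fixed samples of
  `v(x, y) = kappa * (-y) * (x, y)` below the horizon (y < 0), kappa from
  the component speed at the probe (1 deg/s at 2 deg below the FOE, or
  2 deg/s at 4 deg); depth range 0.56–25 m maps to an image band below the
  horizon; probe moves rightward at 2.5 deg/s.
* **Stereo cloud**: 60 wire-frame cubes x 8 vertices uniformly filling the
  image x depth (0.69–1.03 m) volume; per-vertex velocity `(x, y) * T/Z`
  with T set from the probe's 1.6–4.6 deg/s component at its 0.86-m centre
  depth; per-vertex disparity from depth via a 6.4-cm interocular distance.
  The probe appears for the last 200 ms, 4 deg from the FOE, moving upward
  at 2 deg/s.  Masks: `no_local_depth` removes vertices in the central 50%
  of the depth range; `no_local_frontal_view` removes vertices within 4 deg
  of the probe.

Fiducial points are treated as static samples of the velocity field (the
model consumes vectors, not dot trajectories); the probe translates.

## Calibration

The tuning-curve families, surround radii, synaptic constants, drive
scales, the engagement threshold, and the feedback sigmas/gain are not
fixed by the published physiology; they were calibrated once, at the
production 64 x 64 resolution, so that the three campaigns jointly
reproduce the published pattern:

* drive gains (band-pass/summating 0.2, gradient 0.17, ground 0.12) set the
  cross-scenario ordering of MSTd peak activity (frontoparallel < ground <
  stereo, with the ground peak ~33% above the frontoparallel maximum);
* the engagement threshold (0.225 of the full-coverage drive scale) sits
  between the strongest monocular drives and the disparity-gain-boosted
  stereo drives, so only the stereo cloud recruits the recurrent
  self-excitation — and loses it when the disparity gain is disabled;
* the feedback gain and the MT-/MSTv decay rates set the absolute gain
  level (the 2-deg ground condition near the human 84%) and the speed of
  the stereo readout's rise (plateau near 150 ms);
* the feedback ceiling keeps the engaged stereo winner's suppression inside
  the stable regime of the 3.3-ms Euler step.

In the reduced-resolution mode (`ModelConfig.scaled`), receptive-field
radii scale with the grid and the engagement threshold scales with the cell
area (template drives grow with per-cell stimulus coverage); reduced runs
are qualitative — quantitative results are produced at 64 x 64.

Known calibration limits: the easiest frontoparallel condition (1 deg/s
component, 6 deg/s object) mildly overcompensates (gain slightly above 1),
consistent with the model family's documented tendency to overestimate the
object angle; frontoparallel gains at fast self-motion fall below the
human 0.30–0.40 band rather than matching it (the saturating winner cannot
scale its suppression with the growing component).

## Numerical choices

* float32 state tensors; fused single-pass update kernels (numba) for the
  shunting and depression updates; dense BLAS inner products and FFT
  cross-correlations for template matching (the two agree to ~1e-7).
* Shunting updates are clipped to [0, B]; the feedback ceiling keeps
  `dt * inhibition` well below the Euler stability bound.
* Winner ties break to the lowest linear index in the fixed subpopulation
  order (band-pass, speed-summating, gradient, ground), row-major in
  position.
* The population vector returns NaN (reported distinctly) for an all-zero
  or perfectly cancelling weight profile.
* Speed-quintile edges for gradient/ground speed maps are anchored to the
  centred in-grid template geometry and shared between the feedforward
  kernels and the feedback prescriptions.

## What the synthetic stimuli do and do not show

The generators emulate the *structure* of the psychophysical displays —
their geometry, speeds, disparities, probe placement and timing — as
noise-free vector fields.  They do not model luminance, rendering,
temporal sampling artefacts, eye movements, or observer-to-observer
variability; trials are deterministic given the dot-placement seed, and
there is no sensory noise.  Passing tests therefore show that the circuit
mechanisms produce the published qualitative and quantitative pattern
under idealized input, not that the model explains individual human data
or degrades realistically with stimulus noise.

## Known limitations

* Translation-only self-motion: no rotational flow, eye/head movements or
  curved paths.
* The stereo-cloud mask conditions deviate from the published pattern: in
  *No Local Depth* the mid-depth scene content is removed, so the
  disparity-tuned winner settles at a near/far bin and its
  disparity-targeted suppression largely misses the mid-depth probe (small
  gain); in *No Local Frontal View* the 4-deg hole reaches the FOE and
  biases the local heading estimate (small negative shift).  The slowest
  stereo speed-series condition (1.6 deg/s component) barely reaches the
  slowest cloud speed channel and is sensitive to the dot layout.
* Strictly segregated pathways (no mixed MT+ -> MSTv or MT- -> MSTd
  projections), which accentuates suppression and contributes to the
  overshoot at easy conditions.
* Rate constants, bandwidths and gains are this package's own calibration,
  exposed in `ModelConfig`; none are taken from a published parameter set.
* Model runs are deterministic single runs; no attempt is made to model
  the variability behind the human error bars.
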