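# flowparse

A competitive-dynamics model of primate MT/MST that recovers
**world-relative object motion during self-motion** ("flow parsing"), for
computational neuroscientists and vision researchers who want a runnable,
calibrated implementation of the MT/MST feedback-suppression account of
object motion perception.

## The problem and the model

A moving observer's retina receives the sum of a global self-motion flow
pattern (radial expansion from the focus of expansion, FOE, during forward
translation) and the independent motion of any moving object.  Perceiving
the object's movement relative to the stationary world requires removing
the self-motion component from the object's retinal motion — and doing so
correctly requires depth, because motion parallax ties a stationary point's
retinal speed to its distance.

The model implements this with two segregated cortical pathways:

* **MT+ → MSTd** estimates the self-motion pattern.  MSTd units are tuned
  to global templates Π(i,j,x,y) = (x−i, y−j) (radial, with singularity at
  (i,j)) and Λ(i,j,x,y) ∝ (j−y)·(x−i, y−j) (ground flow, defined at and
  below the horizon row j), combined with speed pooling rules —
  band-pass B_s(w) = w_s, speed-summating U(w) = (1/ŝ)Σ_s w_s, and
  eccentricity-dependent speed-gradient maps — and, in stereo runs,
  disparity tuning with a near-to-far response gain.  The subpopulations
  compete in a normalizing recurrent network; input above an engagement
  threshold recruits self-excitation that sharpens the winner.
* **MT− → MSTv** carries object motion.  The most active MSTd unit feeds
  back suppression onto MT−/MSTv units whose direction, speed and disparity
  tuning locally match its template, weighted by the Gaussian mismatch
  W(w; μ, σ) = exp(−((w−μ)/σ)²) per dimension and by retinotopic distance
  from the winner's singularity.

The object's represented direction is decoded by population vector over the
MSTv units containing the probe:
J = (Σ_d w_d cos θ_d, Σ_d w_d sin θ_d), J̄ = atan2(J_v, J_u), and the shift
θ̌ = J̄ − θ_Obj away from the retinal direction converts to the
**flow-parsing gain**: with perpendicular object component *o* and
self-motion component *c*, β = atan(c/o), residual r = o·tan(β − θ̌), and
gain = 1 − r/c (0 = raw retinal motion, 1 = full world-relative recovery).

Three simulation campaigns mirror the psychophysical experiments the model
is compared against: approach toward a **frontoparallel dot plane**
(ambiguous depth; components 1–10 deg/s), translation over a **ground
plane** (monocular motion parallax; probe 2 or 4 deg below the FOE), and
movement through a **stereo cloud of wire-frame objects** (binocular
disparity; Full / No-Local-Depth / No-Local-Frontal-View conditions and a
self-motion speed series).  See `docs/methods.md` for the full equations,
parameters and calibration rationale.

## Worked example

```python
import flowparse as fp

scene = fp.SceneSpec(scenario="ground", component_speed_at_probe=1.0,
                     self_motion_speed=5.7, depth_range=(0.56, 25.0))
probe = fp.ProbeSpec(offset_from_foe=(0.0, -2.0), object_speed=2.5)

model = fp.FlowParsingModel.from_specs(scene, probe)
result = model.run()
print(result.summary())
print(f"decoded shift: {result.final_shift:.1f} deg   "
      f"flow-parsing gain: {result.final_gain:.2f}")
```

```
                               value
final_shift_deg             17.98393
flow_parsing_gain           0.833184
stabilized                      True
retinal_direction_deg     -21.801409
world_direction_deg              0.0
mstd_peak_activity          0.004015
mstd_winner                   ground
winner_kurtosis             4.488583
recurrent_engaged              False
...
decoded shift: 18.0 deg   flow-parsing gain: 0.83
```

The probe's retinal motion is 2.5 deg/s rightward plus a 1 deg/s downward
self-motion component (retinal direction −21.8 deg).  An MSTd ground unit
at the heading wins the competition, its feedback suppresses the
self-motion-consistent part of the object signal, and the decoded direction
shifts 18.0 deg toward the true (rightward, 0 deg) world direction — a
flow-parsing gain of 0.83, next to the 84% mean reported for human
observers in this condition.

Campaigns run through `flowparse.experiments` or the CLI:

```bash
flowparse stimgen --config scene.yaml --out stim.h5
flowparse run --experiment sim2 --out results/
flowparse report --results results/
```

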