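"""Stimulus generation and rasterization."""

import numpy as np
import pytest

from flowparse.stimuli import (Frame, FlowSequence, ProbeSpec, SceneSpec,
                               depth_to_disparity, gen_cloud,
                               gen_frontoparallel, gen_ground, generate,
                               rasterize)


# ---------------------------------------------------------------------------
# SceneSpec / ProbeSpec validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw, msg", [
    (dict(scenario="spiral", component_speed_at_probe=1.0), "scenario"),
    (dict(scenario="ground", component_speed_at_probe=1.0), "depth_range"),
    (dict(scenario="ground", component_speed_at_probe=1.0,
          depth_range=(5.0, 2.0)), "near < far"),
    (dict(scenario="frontoparallel", component_speed_at_probe=1.0,
          condition_mask="no_local_depth"), "cloud"),
])
def test_scene_spec_rejects_invalid(kw, msg):
    with pytest.raises(ValueError, match=msg):
        SceneSpec(**kw)


def test_probe_at_foe_rejected(fronto_scene):
    probe = ProbeSpec(offset_from_foe=(0.0, 0.0))
    with pytest.raises(ValueError, match="FOE"):
        gen_frontoparallel(fronto_scene, probe)


def test_ground_probe_above_horizon_rejected(ground_scene):
    probe = ProbeSpec(offset_from_foe=(0.0, 2.0))
    with pytest.raises(ValueError, match="horizon"):
        gen_ground(ground_scene, probe)


# ---------------------------------------------------------------------------
# frontoparallel flow field
# ---------------------------------------------------------------------------

def test_frontoparallel_radial_speed_law(fronto_scene, fronto_probe):
    """Fiducial speed is k * distance-to-FOE, radially outward, with the
    stated component speed at the probe's eccentricity."""
    seq = gen_frontoparallel(fronto_scene, fronto_probe)
    fr = seq.frames[0]
    bg = ~fr.is_probe
    pos, vel = fr.pos[bg], fr.vel[bg]
    r = np.hypot(pos[:, 0], pos[:, 1])
    speed = np.hypot(vel[:, 0], vel[:, 1])
    k = fronto_scene.component_speed_at_probe / fronto_probe.eccentricity
    np.testing.assert_allclose(speed, k * r, rtol=1e-12)
    # radially outward: velocity parallel to position
    cross = pos[:, 0] * vel[:, 1] - pos[:, 1] * vel[:, 0]
    np.testing.assert_allclose(cross, 0.0, atol=1e-9)
    # equal eccentricity -> equal speed (brute force over sampled pairs)
    order = np.argsort(r)
    assert np.all(np.diff(speed[order]) >= -1e-12)


def test_frontoparallel_probe_components(fronto_scene, fronto_probe):
    """Probe below the FOE: the self-motion component of its retinal motion
    is 1 deg/s downward for the 0.5 m/s condition."""
    seq = gen_frontoparallel(fronto_scene, fronto_probe)
    np.testing.assert_allclose(seq.self_motion_component, [0.0, -1.0],
                               atol=1e-12)
    np.testing.assert_allclose(seq.probe_retinal_velocity, [6.0, -1.0],
                               atol=1e-12)


def test_frontoparallel_velocity_constant_over_frames(fronto_scene,
                                                      fronto_probe):
    seq = gen_frontoparallel(fronto_scene, fronto_probe)
    v0 = seq.frames[0].vel[~seq.frames[0].is_probe]
    for fr in seq.frames[1:]:
        np.testing.assert_array_equal(fr.vel[~fr.is_probe], v0)


def test_perpendicular_components_enforced(fronto_scene):
    """Object component not perpendicular to the self-motion component is
    rejected (design of the motion-nulling experiments)."""
    bad = ProbeSpec(offset_from_foe=(0.0, -4.0), object_direction=45.0)
    with pytest.raises(ValueError, match="perpendicular"):
        gen_frontoparallel(fronto_scene, bad)


def test_determinism_same_seed(fronto_scene, fronto_probe):
    a = gen_frontoparallel(fronto_scene, fronto_probe)
    b = gen_frontoparallel(fronto_scene, fronto_probe)
    for fa, fb in zip(a.frames, b.frames):
        np.testing.assert_array_equal(fa.pos, fb.pos)
        np.testing.assert_array_equal(fa.vel, fb.vel)


# ---------------------------------------------------------------------------
# ground flow field
# ---------------------------------------------------------------------------

def test_ground_zero_flow_above_horizon(ground_scene, ground_probe):
    seq = gen_ground(ground_scene, ground_probe)
    fr = seq.frames[0]
    bg = ~fr.is_probe
    assert np.all(fr.pos[bg, 1] < 0)  # no fiducial points above the horizon


def test_ground_component_speed_at_probe(ground_scene, ground_probe):
    """2 deg eccentricity with the matching translation speed gives a 1 deg/s
    self-motion component."""
    seq = gen_ground(ground_scene, ground_probe)
    np.testing.assert_allclose(np.hypot(*seq.self_motion_component), 1.0,
                               rtol=1e-12)


def test_ground_speed_increases_down_vertical_meridian(ground_scene,
                                                       ground_probe):
    """Closed-form ground flow: speed = kappa * |y| * r grows monotonically
    with angular distance below the horizon along the meridian."""
    seq = gen_ground(ground_scene, ground_probe)
    kappa = 1.0 / ground_probe.eccentricity ** 2
    ys = -np.linspace(0.5, 15.0, 30)
    speeds = kappa * (-ys) * np.abs(ys)   # x = 0 transect
    assert np.all(np.diff(speeds) > 0)
    fr = seq.frames[0]
    bg = ~fr.is_probe
    got = np.hypot(fr.vel[bg, 0], fr.vel[bg, 1])
    r = np.hypot(fr.pos[bg, 0], fr.pos[bg, 1])
    np.testing.assert_allclose(got, kappa * (-fr.pos[bg, 1]) * r, rtol=1e-10)


# ---------------------------------------------------------------------------
# cloud (stereo) stimulus
# ---------------------------------------------------------------------------

def test_cloud_probe_component(cloud_scene, cloud_probe):
    """Probe 4 deg from the FOE: horizontal self-motion component 2 deg/s."""
    seq = gen_cloud(cloud_scene, cloud_probe)
    np.testing.assert_allclose(seq.self_motion_component, [2.0, 0.0],
                               atol=1e-12)


def test_cloud_disparity_decreases_with_depth():
    z = np.linspace(0.69, 1.03, 50)
    d = depth_to_disparity(z)
    assert np.all(np.diff(d) < 0)


def test_cloud_masks(cloud_scene, cloud_probe):
    """Mask predicates checked by brute force against the kept vertices."""
    import dataclasses
    full = gen_cloud(cloud_scene, cloud_probe)
    n_full = len(full.frames[0].pos)

    nld = dataclasses.replace(cloud_scene, condition_mask="no_local_depth")
    seq = gen_cloud(nld, cloud_probe)
    near, far = cloud_scene.depth_range
    lo, hi = near + 0.25 * (far - near), near + 0.75 * (far - near)
    disp_lo, disp_hi = depth_to_disparity([hi, lo])
    fr = seq.frames[0]
    bg = ~fr.is_probe
    in_central = (fr.disparity[bg] >= disp_lo - 1e-9) \
        & (fr.disparity[bg] <= disp_hi + 1e-9)
    assert in_central.sum() == 0
    assert len(fr.pos) < n_full

    nlf = dataclasses.replace(cloud_scene,
                              condition_mask="no_local_frontal_view")
    fr2 = gen_cloud(nlf, cloud_probe).frames[0]
    bg2 = ~fr2.is_probe
    d = np.hypot(fr2.pos[bg2, 0] - 4.0, fr2.pos[bg2, 1])
    assert np.all(d > 4.0)


def test_cloud_probe_visible_last_200ms_only(cloud_scene, cloud_probe):
    seq = gen_cloud(cloud_scene, cloud_probe)
    for f, fr in enumerate(seq.frames):
        t = f / cloud_scene.frame_rate
        if t < 0.8:
            assert not fr.is_probe.any()
        else:
            assert fr.is_probe.any()


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _seq_from_points(pos, vel, fov=40.0):
    scene = SceneSpec(scenario="frontoparallel", component_speed_at_probe=1.0,
                      field_of_view=fov, duration=1 / 30, frame_rate=30.0)
    probe = ProbeSpec(offset_from_foe=(0.0, -4.0), onset=0.0, offset=1 / 30)
    fr = Frame(pos=np.asarray(pos, float), vel=np.asarray(vel, float),
               disparity=None, is_probe=np.zeros(len(pos), bool))
    return FlowSequence(frames=[fr], scene=scene, probe=probe,
                        probe_retinal_velocity=np.zeros(2),
                        self_motion_component=np.array([0.0, -1.0]))


def test_rasterize_empty_frame():
    seq = _seq_from_points(np.zeros((0, 2)), np.zeros((0, 2)))
    gf = rasterize(seq, (64, 64))
    assert not gf.occupancy.any()
    assert np.all(gf.vx == 0) and np.all(gf.vy == 0)
    assert np.all(np.isnan(gf.disparity))


def test_rasterize_single_point_nearest_cell():
    # cell (iy, ix) centre is ((ix-32)*0.625, (iy-32)*0.625) deg
    seq = _seq_from_points([[0.625 * 3, -0.625 * 5]], [[3.0, 0.0]])
    gf = rasterize(seq, (64, 64))
    assert gf.occupancy[0].sum() == 1
    assert gf.vx[0, 27, 35] == 3.0 and gf.vy[0, 27, 35] == 0.0


def test_rasterize_averages_points_in_cell():
    p = [[0.01, 0.01], [-0.01, -0.01]]
    seq = _seq_from_points(p, [[2.0, 0.0], [4.0, 0.0]])
    gf = rasterize(seq, (64, 64))
    assert gf.vx[0, 32, 32] == pytest.approx(3.0)


def test_rasterize_drops_out_of_fov_points():
    seq = _seq_from_points([[50.0, 0.0], [0.0, 0.0]], [[1, 0], [1, 0]])
    gf = rasterize(seq, (64, 64))
    assert gf.dropped_points == 1
    assert gf.occupancy[0].sum() == 1


def test_rasterize_grid_roundtrip_hdf5(tmp_path, fronto_scene, fronto_probe):
    from flowparse.stimuli import GridFlow
    gf = rasterize(generate(fronto_scene, fronto_probe), (32, 32))
    path = tmp_path / "stim.h5"
    gf.to_hdf5(path)
    back = GridFlow.from_hdf5(path)
    np.testing.assert_array_equal(gf.vx, back.vx)
    np.testing.assert_array_equal(gf.occupancy, back.occupancy)
    assert back.field_of_view == gf.field_of_view
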