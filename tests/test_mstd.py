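"""MSTd templates, feedforward matching, and competitive dynamics."""

import dataclasses

import numpy as np
import pytest

from flowparse.config import ModelConfig
from flowparse.mstd import (MSTdState, TemplateBank, build_gradient_subunits,
                            build_ground_template, build_radial_template,
                            feedforward_drive, population_kurtosis,
                            radial_quintile_map, recurrent_step)
from flowparse.pathways import mtplus_drive, mtplus_equilibrium
from flowparse.tuning import TuningBank, encode


@pytest.fixture(scope="module")
def cfg():
    return ModelConfig().scaled(32)


@pytest.fixture(scope="module")
def bank(cfg):
    return TuningBank.from_config(cfg, "frontoparallel")


@pytest.fixture(scope="module")
def templates(cfg, bank):
    return TemplateBank(cfg, bank, stereo=False, ground_units=True)


# ---------------------------------------------------------------------------
# template fields
# ---------------------------------------------------------------------------

def test_radial_template_geometry():
    """The radial field is (x-i, y-j): zero at the singularity, rightward one
    cell to its right, and atan2(y-j, x-i) everywhere (checked cell by
    cell)."""
    i, j, n = 20, 12, 64
    ux, uy, valid = build_radial_template(i, j, n)
    assert not valid[j, i] and ux[j, i] == 0 and uy[j, i] == 0
    assert ux[j, i + 1] == pytest.approx(1.0) and uy[j, i + 1] == 0.0
    c = np.arange(n, dtype=float)
    expected = np.arctan2(c[:, None] - j, c[None, :] - i)
    got = np.arctan2(uy, ux)
    np.testing.assert_allclose(np.where(valid, got, 0),
                               np.where(valid, expected, 0), atol=1e-12)


def test_ground_template_geometry():
    """Ground field: zero at the heading point, zero vertical component on
    the horizon row, and proportional to (j-y)*(x-i, y-j) below it."""
    i, j, n = 32, 32, 64
    vx, vy, valid = build_ground_template(i, j, n)
    assert vx[j, i] == 0 and vy[j, i] == 0
    assert np.all(vy[j, :] == 0)           # horizon row: (y-j)^2 term vanishes
    assert not valid[j + 1:, :].any()      # undefined above the horizon
    rng = np.random.default_rng(1)
    for _ in range(10):
        y = rng.integers(0, j)
        x = rng.integers(0, n)
        assert vx[y, x] == pytest.approx((j - y) * (x - i))
        assert vy[y, x] == pytest.approx((j - y) * (y - j))


def test_gradient_subunits_structure():
    """Increasing-variant subunits tile eccentricity from center (slowest)
    to periphery (fastest); the decreasing variant mirrors the speed axis."""
    inc, dec = build_gradient_subunits(32, 32, 64)
    n = 64
    c = np.arange(n, dtype=float)
    r = np.hypot(c[None, :] - 32, c[:, None] - 32)
    # the slowest-speed subunit is maximally sensitive at zero eccentricity
    assert inc[0][32, 32] == pytest.approx(inc[0].max())
    # weighted mean eccentricity is strictly increasing across speed prefs
    centroids = [(inc[k] * r).sum() / inc[k].sum() for k in range(5)]
    assert all(b > a for a, b in zip(centroids, centroids[1:]))
    np.testing.assert_array_equal(dec, inc[::-1])
    np.testing.assert_allclose(inc.sum(axis=(1, 2)), 1.0, rtol=1e-9)


def test_radial_quintiles_partition_field():
    q = radial_quintile_map(32, 32, 64)
    assert q[32, 32] == 0
    counts = np.bincount(q.ravel()[q.ravel() >= 0], minlength=5)
    assert counts.min() > 0.15 * 64 * 64 / 5   # roughly equal-mass annuli


# ---------------------------------------------------------------------------
# feedforward matching
# ---------------------------------------------------------------------------

def _radial_mtplus(cfg, bank, foe_cell, speed_scale=1.0):
    """MT+ equilibrium response to a dense radial field centred on a cell."""
    n = cfg.grid_size
    c = np.arange(n, dtype=float)
    dx = c[None, :] - foe_cell[1]
    dy = c[:, None] - foe_cell[0]
    r = np.hypot(dx, dy)
    k = speed_scale * bank.speed_prefs[2] / np.median(r)
    with np.errstate(invalid="ignore"):
        vx = np.where(r > 0, k * dx, 0.0)
        vy = np.where(r > 0, k * dy, 0.0)
    occ = np.ones((n, n), bool)
    mt46 = encode(vx, vy, occ, bank)
    return mtplus_equilibrium(mtplus_drive(mt46, cfg), cfg)


def test_foe_localization_on_singularity_grid(cfg, bank, templates):
    """Noise-free radial input with the FOE on a singularity-grid node is
    localized exactly by the band-pass drive argmax."""
    for node in [(8, 8), (4, 10)]:
        cell = (templates.sing_cells[node[0]], templates.sing_cells[node[1]])
        nplus = _radial_mtplus(cfg, bank, cell)
        drives = feedforward_drive(templates, nplus)
        total = drives["bandpass"].sum(axis=2)
        assert np.unravel_index(np.argmax(total), total.shape) == node


def test_speed_pooling_rules(cfg, bank, templates):
    """Speed-summating drive is the mean of the per-speed band-pass matches;
    band-pass returns each channel unmixed."""
    nplus = _radial_mtplus(cfg, bank, (32, 32))
    drives = feedforward_drive(templates, nplus)
    np.testing.assert_allclose(drives["summating"],
                               drives["bandpass"].mean(axis=2), rtol=1e-6)


def test_drives_nonnegative_finite(cfg, bank, templates):
    rng = np.random.default_rng(3)
    nplus = rng.random((cfg.grid_size, cfg.grid_size, 24, 5)).astype(np.float32)
    drives = feedforward_drive(templates, nplus)
    for v in drives.values():
        assert np.all(v >= 0) and np.all(np.isfinite(v))


# ---------------------------------------------------------------------------
# recurrent competitive dynamics
# ---------------------------------------------------------------------------

def _drive_like(templates, value=0.0):
    state = MSTdState.zeros(templates)
    return {k: np.full_like(v, value) for k, v in state.activity.items()}


def test_zero_drive_decays(cfg, bank, templates):
    state = MSTdState.zeros(templates)
    for k in state.activity:
        state.activity[k] += 0.05
    drives = _drive_like(templates, 0.0)
    for _ in range(1500):     # ~5 s of decay at a = 3/s
        state = recurrent_step(state, drives, templates, cfg.dt)
    assert state.total_activity() < 1e-3
    assert not any(state.engaged.values())


def test_winner_sharpening_above_threshold(cfg, bank, templates):
    """With one engaged (above-threshold) unit, its share of total activity
    strictly increases over the feedforward-only outcome."""
    gamma = templates.engagement_threshold("summating")
    drives = _drive_like(templates, 0.001)
    drives["summating"][8, 8] = gamma * 1.5     # strong unit, engaged
    drives["summating"][8, 9] = gamma * 0.5     # weak unit, not engaged
    state = MSTdState.zeros(templates)
    for _ in range(3000):
        state = recurrent_step(state, drives, templates, cfg.dt)
    assert state.engaged["summating"]
    a_strong = state.activity["summating"][8, 8]
    a_weak = state.activity["summating"][8, 9]
    # feedforward-only ratio would be 3:1; recurrence amplifies the winner
    assert a_strong / a_weak > 3.5

    win = state.winner()
    assert win[0] == "summating" and (win[1], win[2]) == (8, 8)


def test_population_normalization_bound(cfg, bank, templates):
    """Total steady-state activity stays below B * N / kappa for any drive
    pattern."""
    rng = np.random.default_rng(5)
    bound = cfg.mstd_bound * templates.n_units_norm / cfg.mstd_norm_pool
    for _ in range(3):
        drives = {k: (rng.random(v.shape) * 0.3).astype(float)
                  for k, v in MSTdState.zeros(templates).activity.items()}
        state = MSTdState.zeros(templates)
        for _ in range(1500):
            state = recurrent_step(state, drives, templates, cfg.dt)
        assert state.total_activity() <= bound + 1e-6


def test_winner_tie_breaks_deterministically(templates):
    state = MSTdState.zeros(templates)
    state.activity["bandpass"][2, 3, 1] = 0.5
    state.activity["gradient"][2, 3] = 0.5
    win = state.winner()
    assert win[0] == "bandpass"   # earlier subpopulation in the fixed order


# ---------------------------------------------------------------------------
# kurtosis
# ---------------------------------------------------------------------------

def test_kurtosis_reference_values():
    rng = np.random.default_rng(0)
    gaussian = rng.normal(size=40000)
    assert population_kurtosis(gaussian) == pytest.approx(3.0, abs=0.15)
    spiked = np.zeros(1000)
    spiked[0] = 10.0
    assert population_kurtosis(spiked) > 100


def test_kurtosis_matches_brute_force():
    rng = np.random.default_rng(7)
    a = rng.random(500)
    mu, sig = a.mean(), a.std()
    expected = np.mean(((a - mu) / sig) ** 4)
    assert population_kurtosis(a) == pytest.approx(expected, rel=1e-12)


def test_kurtosis_degenerate_inputs():
    assert np.isnan(population_kurtosis(np.ones(10)))
    with pytest.raises(ValueError):
        population_kurtosis(np.ones(3))


# ---------------------------------------------------------------------------
# disparity-axis handling
# ---------------------------------------------------------------------------

def test_stereo_state_shapes_carry_three_pooled_bins():
    cfg = ModelConfig().scaled(32)
    bank = TuningBank.from_config(cfg, "cloud", disparity_range=(319.0, 214.0))
    tb = TemplateBank(cfg, bank, stereo=True, ground_units=True)
    state = MSTdState.zeros(tb)
    m, S = cfg.mstd_grid, cfg.n_speeds
    assert state.activity["bandpass"].shape == (m, m, S, 3)
    assert state.activity["summating"].shape == (m, m, 3)
    assert state.activity["gradient"].shape == (m, m)
    assert state.stereo
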