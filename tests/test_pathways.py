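"""MT+ / MT- pathway dynamics and depressing synapses."""

import dataclasses

import numpy as np
import pytest

from flowparse.config import ModelConfig
from flowparse.pathways import (SurroundKernel, SynapseState, depress,
                                mt_minus_step, mt_plus_step, mtminus_drives,
                                mtplus_drive, mtplus_equilibrium)
from flowparse.tuning import ActivityTensor, TuningBank


@pytest.fixture(scope="module")
def cfg():
    # small grid but unscaled receptive-field radii (in cells), so the
    # surround structure stays meaningful
    return dataclasses.replace(ModelConfig(), grid_size=16)


@pytest.fixture(scope="module")
def bank(cfg):
    return TuningBank.from_config(cfg, "frontoparallel")


def _uniform_tensor(cfg, d=5, s=2, value=1.0):
    n = cfg.grid_size
    vals = np.zeros((n, n, cfg.n_directions, cfg.n_speeds), np.float32)
    vals[:, :, d, s] = value
    return ActivityTensor(vals, "MT46")


def _single_cell_tensor(cfg, y, x, d=5, s=2, value=1.0):
    n = cfg.grid_size
    vals = np.zeros((n, n, cfg.n_directions, cfg.n_speeds), np.float32)
    vals[y, x, d, s] = value
    return ActivityTensor(vals, "MT46")


# ---------------------------------------------------------------------------
# MT+ (reinforcing surround)
# ---------------------------------------------------------------------------

def test_mtplus_zero_in_zero_out(cfg):
    t = ActivityTensor(np.zeros((cfg.grid_size,) * 2 + (24, 5), np.float32),
                       "MT46")
    drive = mtplus_drive(t, cfg)
    state = np.zeros_like(drive)
    out = mt_plus_step(state, drive, cfg, cfg.dt)
    assert np.all(out == 0)


def test_mtplus_reinforcement_exceeds_input(cfg):
    """Uniform full-field preferred motion drives MT+ above the single-cell
    input level at equilibrium."""
    t = _uniform_tensor(cfg)
    drive = mtplus_drive(t, cfg)
    eq = mtplus_equilibrium(drive, cfg)
    mid = cfg.grid_size // 2
    assert eq[mid, mid, 5, 2] > t.values[mid, mid, 5, 2]


def test_mtplus_converges_to_analytic_fixed_point(cfg):
    """Repeated Euler steps reach the closed-form equilibrium B*D/(a+D)."""
    t = _uniform_tensor(cfg)
    drive = mtplus_drive(t, cfg)
    state = np.zeros_like(drive)
    for _ in range(3000):
        state = mt_plus_step(state, drive, cfg, cfg.dt)
    np.testing.assert_allclose(state, mtplus_equilibrium(drive, cfg),
                               rtol=1e-4)


# ---------------------------------------------------------------------------
# depressing synapses
# ---------------------------------------------------------------------------

def test_depression_recovers_without_input(cfg):
    syn = SynapseState.fresh((4,), cfg)
    syn.efficacy[:] = 0.3
    zero = np.zeros(4, np.float32)
    for _ in range(3000):
        _, syn = depress(zero, syn, cfg.dt)
    np.testing.assert_allclose(syn.efficacy, 1.0, atol=1e-3)


def test_depression_attenuates_tonic_input(cfg):
    """Constant input: transmitted signal decays from its initial value to
    the analytic plateau e* x N with e* = 1/(1 + rate*tau*N)."""
    syn = SynapseState.fresh((1,), cfg)
    N = np.array([1.5], np.float32)
    first, syn0 = depress(N, syn, cfg.dt)
    s = syn0
    for _ in range(6000):
        out, s = depress(N, s, cfg.dt)
    assert out[0] < first[0]
    expected = syn.steady_state(1.5) * 1.5
    np.testing.assert_allclose(out, expected, rtol=1e-3)


def test_depress_rejects_bad_dt(cfg):
    syn = SynapseState.fresh((1,), cfg)
    with pytest.raises(ValueError):
        depress(np.ones(1), syn, 0.0)


# ---------------------------------------------------------------------------
# MT- (antagonistic surround)
# ---------------------------------------------------------------------------

def test_mtminus_uniform_field_strongly_suppressed(cfg, bank):
    """Matched full-field motion nearly cancels MT- (surround = center);
    an isolated patch with no surround stays close to its unsuppressed
    drive."""
    kern = SurroundKernel.build(cfg, bank)
    mid = cfg.grid_size // 2

    def equilibrium(tensor):
        E, I = mtminus_drives(tensor, kern, cfg)
        state = np.zeros_like(E)
        for _ in range(2000):
            state = mt_minus_step(state, E, I, None, cfg, cfg.dt)
        return state[mid, mid, 5, 2]

    uniform = equilibrium(_uniform_tensor(cfg))
    isolated = equilibrium(_single_cell_tensor(cfg, mid, mid))
    assert uniform < 0.6 * isolated


def test_mtminus_shunting_bound(cfg, bank):
    kern = SurroundKernel.build(cfg, bank)
    E, I = mtminus_drives(_uniform_tensor(cfg, value=50.0), kern, cfg)
    state = np.zeros_like(E)
    for _ in range(1000):
        state = mt_minus_step(state, E, I, None, cfg, cfg.dt)
        assert np.all(state >= 0)
        assert np.all(state <= cfg.mtminus_bound + 1e-6)


def test_surround_match_monotonicity(cfg, bank):
    """Holding the center fixed, surround inhibition decreases as the
    surround direction departs from the center's preferred direction."""
    kern = SurroundKernel.build(cfg, bank)
    n = cfg.grid_size
    mid = n // 2
    inhibitions = []
    for d_surround in (5, 7, 11):
        vals = np.zeros((n, n, 24, 5), np.float32)
        vals[:, :, d_surround, 2] = 1.0      # surround motion everywhere
        vals[mid, mid] = 0.0
        vals[mid, mid, 5, 2] = 1.0           # center motion fixed
        _, I = mtminus_drives(ActivityTensor(vals, "MT46"), kern, cfg)
        inhibitions.append(I[mid, mid, 5, 2])
    assert inhibitions[0] > inhibitions[1] > inhibitions[2]


def test_local_inhibition_ordering_with_depth_structure():
    """Surround at the same disparity inhibits more than surround confined
    to other disparities, which inhibits more than no surround at all."""
    cfg = dataclasses.replace(ModelConfig(), grid_size=16)
    bank = TuningBank.from_config(cfg, "cloud", disparity_range=(319.0, 214.0))
    kern = SurroundKernel.build(cfg, bank)
    n, mid = cfg.grid_size, cfg.grid_size // 2

    def inhibition(surround_bins):
        vals = np.zeros((n, n, 24, 5, 5), np.float32)
        for b in surround_bins:
            vals[:, :, 5, 2, b] = 1.0
        vals[mid, mid] = 0.0
        vals[mid, mid, 5, 2, 2] = 1.0
        _, I = mtminus_drives(ActivityTensor(vals, "MT46"), kern, cfg)
        return I[mid, mid, 5, 2, 2]

    full = inhibition([2])          # surround at the center's own disparity
    other_depth = inhibition([0, 4])  # surround at remote disparities only
    none = inhibition([])
    assert full > other_depth > none


def test_pathway_segregation(cfg, bank):
    """MT+ drive ignores the feedback field; MT- inhibition is built from
    the input layer only — the two streams share no state."""
    t = _uniform_tensor(cfg)
    d1 = mtplus_drive(t, cfg)
    kern = SurroundKernel.build(cfg, bank)
    E, I = mtminus_drives(t, kern, cfg)
    # feeding an arbitrary feedback field into MT- leaves MT+ untouched
    d2 = mtplus_drive(t, cfg)
    np.testing.assert_array_equal(d1, d2)
    assert E.shape == I.shape == d1.shape
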