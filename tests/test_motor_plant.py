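"""Comparator network, muscle power, joint kinematics and the closed loop."""

import numpy as np
import pytest

from cmcsim.cmc_core import SynapticParams
from cmcsim.motor_plant import (
    MotorConfig,
    comparator_equation,
    constant_trajectory,
    movement_error,
    muscle_power,
    run_closed_loop,
    simple_muscle_power,
    sinusoid_trajectory,
    step_comparator,
    step_trajectory,
    update_joint,
)
from cmcsim.rate_coding import RateCodingConfig

N = 100_000


def _se(p, n=N):
    return np.sqrt(max(p * (1 - p), 1.0 / n) / n)


def _vec(bit, n=N):
    return np.full(n, bit, dtype=np.uint8)


def test_comparator_quiescent_when_inputs_silent(rng):
    comp = step_comparator(_vec(0), _vec(0), MotorConfig(), rng)
    for field in ("p1", "p2", "p3", "flexor", "extensor_interneuron", "extensor"):
        assert getattr(comp, field).sum() == 0


def test_comparator_combined_state_cancels_exactly(rng):
    """DCN and motor both firing produce no movement: the shared draw makes
    the equal-strength excitation and inhibition cancel in every equation."""
    comp = step_comparator(_vec(1), _vec(1), MotorConfig(), rng)
    for field in ("p1", "p2", "p3", "flexor", "extensor_interneuron", "extensor"):
        assert getattr(comp, field).sum() == 0


def test_comparator_motor_only_drives_flexor(rng):
    """motor=1, dcn=0: flexor chains through P2 -> P3 -> flexor at 0.9^3."""
    comp = step_comparator(_vec(0), _vec(1), MotorConfig(), rng)
    assert comp.p1.sum() == 0
    assert abs(comp.p2.mean() - 0.9) < 3 * _se(0.9)
    assert abs(comp.p3.mean() - 0.81) < 3 * _se(0.81)
    assert abs(comp.flexor.mean() - 0.729) < 3 * _se(0.729)
    # extensor only sneaks through when its interneuron stays silent
    assert abs(comp.extensor.mean() - 0.0729) < 4 * _se(0.0729)
    both = (comp.flexor & comp.extensor).mean()
    assert both < 0.1  # agonist/antagonist co-activation is rare


def test_comparator_dcn_only_drives_extensor(rng):
    """dcn=1, motor=0: the antagonist pathway mirrors the flexor chain."""
    comp = step_comparator(_vec(1), _vec(0), MotorConfig(), rng)
    assert comp.p2.sum() == 0
    assert comp.flexor.sum() == 0  # DCN inhibition cancels the P3 drive exactly
    assert abs(comp.extensor.mean() - 0.729) < 3 * _se(0.729)


def test_comparator_equation_consumes_no_draws_when_inactive(rng):
    state = rng.bit_generator.state
    out = comparator_equation([(np.zeros(50, dtype=np.uint8), 1.5)], 0.15, rng)
    assert out.sum() == 0
    assert rng.bit_generator.state == state


def test_muscle_power_arithmetic():
    cfg = MotorConfig(power_scale=1.0)
    assert muscle_power(_vec(1, 100), _vec(0, 100), cfg) == pytest.approx(10.0)
    flex = np.r_[np.ones(600), np.zeros(400)].astype(np.uint8)
    ext = np.r_[np.zeros(600), np.ones(400)].astype(np.uint8)
    assert muscle_power(flex, ext, cfg) == pytest.approx(2.0)
    cfg_force = MotorConfig(power_scale=1.0, force_on_joint=0.3)
    same = _vec(1, 100)
    assert muscle_power(same, same, cfg_force) == pytest.approx(0.3)


def test_simple_muscle_power_mirrors_difference():
    cfg = MotorConfig(power_scale=1.0)
    assert simple_muscle_power(_vec(1, 100), _vec(0, 100), cfg) == pytest.approx(10.0)
    assert simple_muscle_power(_vec(1, 100), _vec(1, 100), cfg) == pytest.approx(0.0)


def test_muscle_power_rejects_empty_population():
    with pytest.raises(ValueError):
        muscle_power(np.array([]), np.array([]), MotorConfig())


@pytest.mark.parametrize(
    "pos,power,expected", [(0.5, 0.0, 0.5), (0.9, 0.3, 1.0), (0.5, -0.2, 0.3), (0.1, -0.5, 0.0)]
)
def test_update_joint_clamps(pos, power, expected):
    assert update_joint(pos, power) == pytest.approx(expected)


@pytest.mark.parametrize("a,d,e", [(0.5, 0.5, 0.0), (0.2, 0.7, 0.5), (1.0, 0.0, 1.0)])
def test_movement_error(a, d, e):
    assert movement_error(a, d) == pytest.approx(e)


def test_trajectory_generators():
    sin = sinusoid_trajectory(500, freq_hz=0.5)
    assert sin.min() >= 0.0 and sin.max() <= 1.0 and sin[0] == pytest.approx(0.5)
    assert np.all(constant_trajectory(10, 0.3) == 0.3)
    steps = step_trajectory([0.2, 0.8], 5)
    assert steps.shape == (10,) and steps[0] == 0.2 and steps[-1] == 0.8


def test_zero_muscle_strength_freezes_joint(rng):
    params = SynapticParams.homogeneous(500)
    cfg = MotorConfig(muscle_strength=0.0)
    rec = run_closed_loop(
        sinusoid_trajectory(100), params, cfg, RateCodingConfig(), rng
    )
    assert np.all(rec["actual"] == rec["actual"].iloc[0])


def test_power_is_bounded(rng):
    params = SynapticParams.homogeneous(300)
    cfg = MotorConfig(force_on_joint=-0.001)
    rec = run_closed_loop(
        sinusoid_trajectory(200), params, cfg, RateCodingConfig(), rng
    )
    bound = cfg.muscle_strength * cfg.power_scale + abs(cfg.force_on_joint)
    assert np.all(np.abs(rec["muscle_power"]) <= bound + 1e-12)


def test_closed_loop_equilibrium_regression(rng):
    """Holding a constant target, the loop settles close to it (regression
    bound frozen from reference runs of this simulator)."""
    params = SynapticParams.homogeneous(4000)
    rec = run_closed_loop(
        constant_trajectory(500, 0.5), params, MotorConfig(), RateCodingConfig(), rng
    )
    assert rec["error"].iloc[100:].mean() < 0.08


def test_closed_loop_is_reproducible():
    params = SynapticParams.homogeneous(400)
    args = (sinusoid_trajectory(150), params, MotorConfig(), RateCodingConfig())
    a = run_closed_loop(*args, np.random.default_rng(9))
    b = run_closed_loop(*args, np.random.default_rng(9))
    assert a.equals(b)


def test_closed_loop_validates_inputs(rng):
    params = SynapticParams.homogeneous(10)
    with pytest.raises(ValueError):
        run_closed_loop(np.array([0.5, 1.5]), params, MotorConfig(), RateCodingConfig(), rng)
    with pytest.raises(ValueError):
        run_closed_loop(
            np.array([0.5, 0.5]), params, MotorConfig(), RateCodingConfig(), rng,
            force_schedule=np.zeros(5),
        )
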