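import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echonav import (
    HeadHistory,
    KinematicLaws,
    RandomWalkParams,
    SonarReading,
    dlal_body_update,
    dlal_head_update,
    feasibility_check,
    fixed_head_step,
    make_strategy,
    max_body_rotation_rate,
    random_walk_step,
    rotation_magnitude,
    speed_from_distance,
    speed_from_gaze,
)
from echonav.control import turn_sign

LAWS = KinematicLaws()


def reading(d_hat=1.0, e_left=0.0, e_right=0.0, detected=True):
    return SonarReading(
        detected=detected,
        first_echo_time=2 * d_hat / 343.0,
        d_hat=d_hat,
        energy_left=e_left,
        energy_right=e_right,
    )


class TestKinematicLaws:
    @pytest.mark.parametrize(
        "d, expected",
        [(0.1, 50.0), (0.3, 50.0), (0.9, 37.5), (1.5, 25.0), (3.0, 25.0)],
    )
    def test_rotation_magnitude(self, d, expected):
        assert rotation_magnitude(d, LAWS) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "d, expected",
        [(0.0, 1.0), (0.3, 1.0), (0.9, 2.0), (1.5, 3.0), (4.0, 3.0)],
    )
    def test_speed_from_distance(self, d, expected):
        assert speed_from_distance(d, LAWS) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "phi, expected",
        [(0.0, 3.0), (22.5, 2.0), (45.0, 1.0), (-45.0, 1.0), (80.0, 1.0), (-80.0, 1.0)],
    )
    def test_speed_from_gaze(self, phi, expected):
        assert speed_from_gaze(phi, LAWS) == pytest.approx(expected)

    def test_rotation_monotone_non_increasing(self):
        d = np.linspace(0, 3, 100)
        rot = [rotation_magnitude(x, LAWS) for x in d]
        assert np.all(np.diff(rot) <= 1e-12)

    def test_head_rate_spans_500_to_1000_deg_per_s(self):
        # 50 deg and 25 deg per 50 ms interpulse interval
        assert rotation_magnitude(LAWS.d_near, LAWS) / LAWS.ipi == pytest.approx(1000.0)
        assert rotation_magnitude(LAWS.d_far, LAWS) / LAWS.ipi == pytest.approx(500.0)

    def test_per_call_displacement_5_to_15_cm(self):
        eps = 1e-12
        for d in np.linspace(0, 4, 50):
            assert 0.05 - eps <= speed_from_distance(d, LAWS) * LAWS.ipi <= 0.15 + eps
        for phi in np.linspace(-90, 90, 50):
            assert 0.05 - eps <= speed_from_gaze(phi, LAWS) * LAWS.ipi <= 0.15 + eps

    def test_invalid_laws_rejected(self):
        with pytest.raises(ValueError):
            KinematicLaws(d_near=2.0, d_far=1.0)
        with pytest.raises(ValueError):
            KinematicLaws(rotation_at_near=10.0, rotation_at_far=20.0)


class TestTurnSign:
    def test_away_from_louder_ear(self):
        assert turn_sign(reading(e_left=2.0, e_right=1.0)) == -1.0  # left louder -> right
        assert turn_sign(reading(e_left=1.0, e_right=2.0)) == 1.0  # right louder -> left

    def test_no_detection_keeps_previous(self):
        assert turn_sign(reading(detected=False), previous_sign=-1.0) == -1.0

    def test_exact_tie_fair_coin(self):
        rng = np.random.default_rng(0)
        signs = {turn_sign(reading(e_left=1.0, e_right=1.0), rng) for _ in range(50)}
        assert signs == {-1.0, 1.0}


class TestDLALHead:
    def test_turn_away_by_distance_magnitude(self):
        # close echo, left ear louder, head at 0 -> full 50 deg to the right
        new = dlal_head_update(reading(d_hat=0.1, e_left=2.0, e_right=1.0), 0.0)
        assert new == pytest.approx(-50.0)

    def test_clamped_at_limit(self):
        new = dlal_head_update(reading(d_hat=0.1, e_left=1.0, e_right=2.0), 80.0)
        assert new == pytest.approx(90.0)

    def test_far_echo_small_turn(self):
        new = dlal_head_update(reading(d_hat=3.0, e_left=1.0, e_right=2.0), 0.0)
        assert new == pytest.approx(25.0)


class TestDLALBody:
    def test_centered_head_no_rotation(self):
        h = HeadHistory()
        for i in range(5):
            h.record(0.05 * i, 0.0)
        assert dlal_body_update(h, 0.25) == 0.0

    def test_rate_law_on_delayed_angle(self):
        # body turn rate k * phi(t - tau): phi_tau = 3 deg, k = 10 /s, ipi 50 ms
        h = HeadHistory()
        h.record(0.0, 3.0)
        h.record(0.05, 40.0)
        assert dlal_body_update(h, 0.05) == pytest.approx(10.0 * 3.0 * 0.05)

    def test_interpolates_between_samples(self):
        # phi = 10 deg at now-60 ms and 20 deg at now-40 ms -> phi_tau = 15 deg
        now = 1.0
        h = HeadHistory()
        h.record(now - 0.06, 10.0)
        h.record(now - 0.04, 20.0)
        assert dlal_body_update(h, now) == pytest.approx(10.0 * 15.0 * 0.05)

    def test_empty_history_reads_zero(self):
        assert dlal_body_update(HeadHistory(), 0.0) == 0.0

    def test_history_timestamps_strictly_increasing(self):
        h = HeadHistory()
        h.record(0.0, 1.0)
        with pytest.raises(ValueError):
            h.record(0.0, 2.0)


class TestFixedHead:
    def test_close_left_louder(self):
        cmd = fixed_head_step(reading(d_hat=0.1, e_left=2.0, e_right=1.0), LAWS)
        assert cmd.delta_theta == pytest.approx(-50.0)
        assert cmd.speed == pytest.approx(1.0)
        assert cmd.delta_phi == 0.0

    def test_far_right_louder(self):
        cmd = fixed_head_step(reading(d_hat=2.0, e_left=1.0, e_right=2.0), LAWS)
        assert cmd.delta_theta == pytest.approx(25.0)
        assert cmd.speed == pytest.approx(3.0)

    def test_head_never_moves(self):
        for d in (0.1, 1.0, 3.0):
            assert fixed_head_step(reading(d_hat=d, e_right=1.0), LAWS).delta_phi == 0.0

    def test_no_detection_drives_fast_and_straightish(self):
        cmd = fixed_head_step(reading(detected=False), LAWS, previous_sign=-1.0)
        assert cmd.speed == pytest.approx(3.0)
        assert cmd.delta_theta == pytest.approx(-25.0)

    @given(
        e_left=st.floats(0.01, 10.0),
        e_right=st.floats(0.01, 10.0),
        d=st.floats(0.0, 4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_turn_directed_away_from_louder_ear(self, e_left, e_right, d):
        if e_left == e_right:
            return
        cmd = fixed_head_step(reading(d_hat=d, e_left=e_left, e_right=e_right), LAWS)
        expected = -1.0 if e_left > e_right else 1.0
        assert math.copysign(1.0, cmd.delta_theta) == expected


class TestRandomWalk:
    def test_uniform_magnitude_and_fair_sign(self):
        rng = np.random.default_rng(12)
        cmds = [random_walk_step(rng) for _ in range(100_000)]
        mags = np.array([abs(c.delta_theta) for c in cmds])
        assert mags.min() >= 25.0 and mags.max() <= 50.0
        assert np.mean(mags) == pytest.approx(37.5, abs=0.1)
        assert np.mean([c.delta_theta > 0 for c in cmds]) == pytest.approx(0.5, abs=0.01)

    def test_fixed_speed(self):
        rng = np.random.default_rng(0)
        assert all(random_walk_step(rng).speed == 2.0 for _ in range(10))

    def test_seeded_reproducibility(self):
        a = [random_walk_step(np.random.default_rng(5)) for _ in range(1)]
        b = [random_walk_step(np.random.default_rng(5)) for _ in range(1)]
        assert a == b

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            RandomWalkParams(rotation_low=50.0, rotation_high=25.0)


class TestFeasibility:
    @pytest.mark.parametrize("v, expected", [(2.0, 19.62), (1.0, 39.24)])
    def test_turn_rate_bound(self, v, expected):
        assert max_body_rotation_rate(v, G=4.0) == pytest.approx(expected)

    def test_zero_g_gives_zero(self):
        assert max_body_rotation_rate(2.0, G=0.0) == 0.0

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            max_body_rotation_rate(0.0)

    def test_default_laws_pass_at_4g(self):
        report = feasibility_check(LAWS, G=4.0)
        assert report.passed
        assert np.all(report.margin_deg >= 0)
        # endpoint margins: 1000 vs 2248 deg/s near, 500 vs 749 deg/s far
        assert report.commanded_rate_deg[0] == pytest.approx(1000.0)
        assert report.bound_deg[0] == pytest.approx(math.degrees(39.24), rel=1e-3)
        assert report.commanded_rate_deg[-1] == pytest.approx(500.0)
        assert report.bound_deg[-1] == pytest.approx(math.degrees(4 * 9.81 / 3), rel=1e-3)

    def test_tiny_g_fails(self):
        assert not feasibility_check(LAWS, G=0.1).passed


class TestStrategyObjects:
    def test_factory_names(self):
        for name in ("fixed_head", "dlal", "random_walk"):
            assert make_strategy(name).name == name
        with pytest.raises(ValueError):
            make_strategy("teleport")

    def test_dlal_strategy_head_arrival_delay(self):
        # the body follows the head angle commanded two calls earlier
        # (tau = 50 ms plus the servo swing spanning one interval)
        strat = make_strategy("dlal")
        strat.reset(np.random.default_rng(0))
        r = reading(d_hat=0.1, e_left=1.0, e_right=2.0)  # head turns left 50/call
        cmd0 = strat.step(r, 0.0, 0.0)  # head 0 -> 50
        cmd1 = strat.step(r, 50.0, 0.05)  # head 50 -> 90 (clamped)
        cmd2 = strat.step(r, 90.0, 0.10)
        assert cmd0.delta_theta == pytest.approx(0.0)
        assert cmd1.delta_theta == pytest.approx(0.0)  # phi(t-tau) still initial
        assert cmd2.delta_theta == pytest.approx(10.0 * 50.0 * 0.05)  # k*phi*ipi

    def test_commands_replayable(self):
        cmds = []
        for _ in range(2):
            strat = make_strategy("dlal")
            strat.reset(np.random.default_rng(77))
            seq = []
            phi = 0.0
            for i in range(20):
                r = reading(d_hat=0.5, e_left=1.0, e_right=1.0)  # ties -> rng draws
                cmd = strat.step(r, phi, 0.05 * i)
                phi = float(np.clip(phi + cmd.delta_phi, -90, 90))
                seq.append(cmd)
            cmds.append(seq)
        assert cmds[0] == cmds[1]
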