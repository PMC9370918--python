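import dataclasses

import numpy as np
import pytest

from liftkin import (
    CANONICAL_LANDMARKS,
    MarkerSet,
    MomentSeries,
    TrajectorySet,
    cumulative_moment,
    sagittal_frame,
    shoulder_flexion,
    shoulder_moment,
    trunk_inclination,
)
from conftest import ground_truth_palletization

IDX = {name: i for i, name in enumerate(CANONICAL_LANDMARKS)}


def make_ts(n_frames=1, **markers):
    """TrajectorySet from explicit marker positions (defaults fill a neutral
    upright pose so every canonical landmark exists)."""
    neutral = {
        "L5": (0, 0, 1.0),
        "C7": (0, 0, 1.5),
        "T8": (0, 0, 1.3),
        "STRN": (0, 0.10, 1.25),
        "RSHO_F": (0.18, 0.04, 1.45),
        "RSHO_B": (0.18, -0.04, 1.45),
        "RELB_M": (0.15, 0, 1.15),
        "RELB_L": (0.21, 0, 1.15),
        "RWRA": (0.20, 0, 0.90),
        "RWRB": (0.16, 0, 0.90),
    }
    neutral.update(markers)
    pos = np.zeros((n_frames, len(CANONICAL_LANDMARKS), 3))
    for name, xyz in neutral.items():
        pos[:, IDX[name], :] = xyz
    return TrajectorySet(pos, 50.0, MarkerSet(CANONICAL_LANDMARKS))


class TestSagittalFrame:
    def test_axis_aligned_heading(self):
        ts = make_ts(L5=(0, 0, 1.0), STRN=(0, 0.10, 1.20))
        sf = sagittal_frame(ts)
        np.testing.assert_allclose(sf.forward[0], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(sf.normal[0], [-1, 0, 0], atol=1e-12)

    def test_rotated_subject(self):
        ts = make_ts(L5=(0, 0, 1.0), STRN=(0.10, 0, 1.20))
        sf = sagittal_frame(ts)
        np.testing.assert_allclose(sf.forward[0], [1, 0, 0], atol=1e-12)

    def test_degenerate_first_frame_raises(self):
        ts = make_ts(L5=(0, 0, 1.0), STRN=(0, 0, 1.25))
        with pytest.raises(ValueError, match="frame 0"):
            sagittal_frame(ts)

    def test_degenerate_interior_frame_inherits_heading(self):
        ts = make_ts(n_frames=3)
        ts.positions[1, IDX["STRN"]] = ts.positions[1, IDX["L5"]] + [0, 0, 0.25]
        sf = sagittal_frame(ts)
        np.testing.assert_allclose(sf.forward[1], sf.forward[0], atol=1e-12)


class TestTrunkInclination:
    @pytest.mark.parametrize(
        "c7, expected",
        [
            ((0, 0, 1.5), 0.0),  # upright
            ((0, 0.5, 1.5), 45.0),  # equal forward and vertical components
            ((0, -0.2, 1.48), -np.degrees(np.arctan2(0.2, 0.48))),  # extension
        ],
    )
    def test_hand_trigonometry(self, c7, expected):
        ts = make_ts(L5=(0, 0, 1.0), C7=c7, STRN=(0, 0.10, 1.20))
        ang = trunk_inclination(ts)
        assert ang.values[0] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("heading_deg", [0, 37, 90, 180, 261])
    def test_forward_lean_positive_for_any_heading(self, heading_deg):
        h = np.radians(heading_deg)
        fwd = np.array([np.sin(h), np.cos(h), 0.0])
        ts = make_ts(
            L5=(0, 0, 1.0),
            C7=tuple(0.3 * fwd + [0, 0, 1.4]),
            STRN=tuple(0.10 * fwd + [0, 0, 1.2]),
        )
        assert trunk_inclination(ts).values[0] > 0


class TestShoulderFlexion:
    def test_neutral_hanging_arm_is_zero(self):
        ts = make_ts(
            RSHO_F=(0.18, 0.04, 1.45), RSHO_B=(0.18, -0.04, 1.45),
            RELB_M=(0.15, 0, 1.15), RELB_L=(0.21, 0, 1.15),
        )
        assert shoulder_flexion(ts).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_arm_is_ninety(self):
        ts = make_ts(
            RELB_M=(0.15, 0.30, 1.45), RELB_L=(0.21, 0.30, 1.45),
        )
        assert shoulder_flexion(ts).values[0] == pytest.approx(90.0, abs=1e-9)

    def test_flexed_trunk_vertical_arm(self):
        """Trunk flexed 30 deg forward with the arm hanging vertically: the
        arm sits 30 deg anterior to the trunk line, i.e. +30 deg flexion."""
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        L5 = np.array([0, 0, 1.0])
        d = np.array([0, s, c])  # trunk axis tilted forward
        a = np.array([0, c, -s])
        gh = L5 + 0.45 * d
        ts = make_ts(
            L5=tuple(L5), C7=tuple(L5 + 0.5 * d), T8=tuple(L5 + 0.3 * d),
            STRN=tuple(L5 + 0.25 * d + 0.10 * a),
            RSHO_F=tuple(gh + [0.18, 0, 0] + 0.04 * a),
            RSHO_B=tuple(gh + [0.18, 0, 0] - 0.04 * a),
            RELB_M=tuple(gh + [0.15, 0, 0] + [0, 0, -0.30]),
            RELB_L=tuple(gh + [0.21, 0, 0] + [0, 0, -0.30]),
        )
        assert shoulder_flexion(ts).values[0] == pytest.approx(30.0, abs=1e-6)


class TestShoulderMoment:
    def test_lever_arm_arithmetic(self):
        ts = make_ts(
            RWRA=(0.20, 0.40, 1.45), RWRB=(0.16, 0.40, 1.45),
        )
        m = shoulder_moment(ts, box_mass=10.0)
        assert m.values[0] == pytest.approx(10 * 9.81 / 2 * 0.4, abs=1e-9)

    def test_wrist_below_shoulder_zero(self):
        ts = make_ts(RWRA=(0.20, 0.0, 0.9), RWRB=(0.16, 0.0, 0.9))
        assert shoulder_moment(ts).values[0] == pytest.approx(0.0, abs=1e-9)

    def test_posterior_load_negative(self):
        ts = make_ts(RWRA=(0.20, -0.10, 1.2), RWRB=(0.16, -0.10, 1.2))
        m = shoulder_moment(ts, box_mass=10.0)
        assert m.values[0] == pytest.approx(-4.905, abs=1e-9)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            shoulder_moment(make_ts(), box_mass=-1.0)

    def test_moment_linear_in_box_mass(self):
        ts = make_ts(RWRA=(0.20, 0.33, 1.2), RWRB=(0.16, 0.31, 1.2))
        m1 = shoulder_moment(ts, box_mass=5.0).values
        m2 = shoulder_moment(ts, box_mass=15.0).values
        np.testing.assert_allclose(m2, 3 * m1, atol=1e-12)


class TestCumulativeMoment:
    def test_constant_integrand(self):
        ms = MomentSeries(np.full(100, 5.0), dt=0.02, box_mass=10.0)
        assert cumulative_moment(ms, 0, 100) == pytest.approx(10.0)

    def test_zero_moment(self):
        ms = MomentSeries(np.zeros(50), dt=0.02, box_mass=10.0)
        assert cumulative_moment(ms, 0, 50) == 0.0

    def test_ramp_matches_brute_force_sum(self):
        values = np.linspace(0, 10, 100)
        ms = MomentSeries(values, dt=0.02, box_mass=10.0)
        brute = sum(values[i] * 0.02 for i in range(20, 90))
        assert cumulative_moment(ms, 20, 90) == pytest.approx(brute, abs=1e-12)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(3)
        ms = MomentSeries(rng.standard_normal(200), dt=0.02, box_mass=10.0)
        whole = cumulative_moment(ms, 10, 190)
        parts = cumulative_moment(ms, 10, 77) + cumulative_moment(ms, 77, 190)
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_reversed_or_empty_interval_rejected(self):
        ms = MomentSeries(np.zeros(10), dt=0.02, box_mass=10.0)
        for bad in ((5, 5), (7, 3), (-1, 5), (0, 11)):
            with pytest.raises(ValueError):
                cumulative_moment(ms, *bad)


def test_rigid_motion_invariance(noise_free_session):
    """Translation and rotation about the vertical leave all three outputs
    unchanged."""
    ts, _ = noise_free_session
    sub = dataclasses.replace(ts, positions=ts.positions[2000:3000].copy())
    ang = np.radians(73.0)
    R = np.array([
        [np.cos(ang), -np.sin(ang), 0],
        [np.sin(ang), np.cos(ang), 0],
        [0, 0, 1],
    ])
    moved = dataclasses.replace(sub, positions=sub.positions @ R.T + [3.0, -2.0, 0.7])
    for a, b in (
        (trunk_inclination(sub), trunk_inclination(moved)),
        (shoulder_flexion(sub), shoulder_flexion(moved)),
        (shoulder_moment(sub), shoulder_moment(moved)),
    ):
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)


def test_round_trip_angles_match_generator_truth(processed_noise_free, noise_free_session):
    """Noise-free generated sessions: recovered trunk and shoulder series
    agree with the generator's true profiles to < 0.5 deg RMS over events."""
    _, gt = noise_free_session
    res = processed_noise_free
    truth = ground_truth_palletization(gt)
    rate = res.back.rate
    for _, row in truth.iterrows():
        i0, i1 = int(row.start_s * rate), int(row.end_s * rate)
        for rec, true in ((res.back.values, gt.trunk_deg),
                          (res.shoulder.values, gt.shoulder_deg)):
            rms = np.sqrt(np.mean((rec[i0 : i1 + 1] - true[i0 : i1 + 1]) ** 2))
            assert rms < 0.5
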