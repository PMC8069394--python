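"""Angle/COM/velocity indicators, phase aggregation and cohort statistics."""

import math

import numpy as np
import pytest

from stskit import (
    ContractError,
    IndicatorParams,
    UndefinedAngleError,
    cohort_summary,
    com,
    com_dispersion,
    compare_to_reference,
    compute_session_indicators,
    llfa,
    load_reference_values,
    phase_features,
    ubfa,
    ubta,
    ufv,
)
from stskit.indicators import TABLE_ROWS
from stskit.joints import N_JOINTS
from stskit.segmentation import Extremum, PhaseSegment
from stskit import joints as J


def pose(**joint_xyz):
    """A 25-joint pose with listed joints placed and the rest at a base point."""
    p = np.tile([0.1, 0.2, 0.3], (N_JOINTS, 1))
    for idx, xyz in joint_xyz.items():
        p[int(idx)] = xyz
    return p


# ---------------------------------------------------------------------------
# UBFA


@pytest.mark.parametrize(
    "delta, expected",
    [((0.0, 0.4), 90.0),       # vertical trunk
     ((0.4, 0.4), 45.0),       # arctan(1)
     ((-0.4, 0.4), 135.0),     # leaning back
     ((0.4, -0.4), 135.0)],    # folded from -45
)
def test_ubfa_from_trunk_offsets(delta, expected):
    dy, dz = delta
    p = pose(**{str(J.SPINE_MID): [0.0, 0.0, 1.0],
                str(J.UPPER_TRUNK): [0.3, dy, 1.0 + dz]})
    assert ubfa(p) == pytest.approx(expected, abs=1e-12)


def test_ubfa_undefined_for_coincident_trunk_joints():
    p = pose(**{str(J.SPINE_MID): [0.0, 0.5, 1.0], str(J.UPPER_TRUNK): [0.2, 0.5, 1.0]})
    with pytest.raises(UndefinedAngleError):
        ubfa(p)


# ---------------------------------------------------------------------------
# LLFA


def leg_pose(hip, knee, ankle, side="left"):
    idx = {"left": (J.HIP_LEFT, J.KNEE_LEFT, J.ANKLE_LEFT),
           "right": (J.HIP_RIGHT, J.KNEE_RIGHT, J.ANKLE_RIGHT)}[side]
    return pose(**{str(idx[0]): hip, str(idx[1]): knee, str(idx[2]): ankle})


@pytest.mark.parametrize("side", ["left", "right"])
def test_llfa_straight_vertical_limb_is_180(side):
    p = leg_pose([0, 0, 1.0], [0, 0, 0.5], [0, 0, 0.0], side)
    assert llfa(p, side) == pytest.approx(180.0)


def test_llfa_right_angle_knee():
    p = leg_pose([0, 0, 0.5], [0, 0.5, 0.5], [0, 0.5, 0.0])
    assert llfa(p, "left") == pytest.approx(90.0)


def interior_knee_angle(hip, knee, ankle):
    """Oracle: dot-product angle at the knee between knee→hip and knee→ankle."""
    u = np.asarray(hip) - np.asarray(knee)
    v = np.asarray(ankle) - np.asarray(knee)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


@pytest.mark.parametrize("side", ["left", "right"])
def test_llfa_matches_dot_product_oracle_on_sagittal_poses(side):
    rng = np.random.default_rng(123)
    for _ in range(20):
        hip = np.array([0.0, rng.uniform(-0.3, 0.3), rng.uniform(0.6, 1.0)])
        knee = hip + [0.0, rng.uniform(-0.5, 0.5), rng.uniform(-0.6, -0.1)]
        ankle = knee + [0.0, rng.uniform(-0.5, 0.5), rng.uniform(-0.6, -0.1)]
        p = leg_pose(hip, knee, ankle, side)
        expected = interior_knee_angle(hip, knee, ankle)
        assert llfa(p, side) == pytest.approx(expected, abs=1e-9)


def test_llfa_undefined_for_zero_length_segment():
    p = leg_pose([0, 0.5, 1.0], [0, 0.5, 1.0], [0, 0.5, 0.0])
    with pytest.raises(UndefinedAngleError):
        llfa(p, "left")


# ---------------------------------------------------------------------------
# UBTA


def shoulder_pose(left, right):
    return pose(**{str(J.SHOULDER_LEFT): left, str(J.SHOULDER_RIGHT): right})


def test_ubta_zero_and_45_degrees():
    assert ubta(shoulder_pose([-0.2, 0.0, 1.4], [0.2, 0.0, 1.4])) == pytest.approx(0.0)
    assert ubta(shoulder_pose([-0.2, 0.0, 1.4], [0.2, 0.4, 1.4])) == pytest.approx(45.0)


def test_ubta_left_shoulder_forward_is_negative():
    # left shoulder 5 cm forward of right, shoulders 40 cm apart
    val = ubta(shoulder_pose([-0.2, 0.05, 1.4], [0.2, 0.0, 1.4]))
    assert val < 0
    assert val == pytest.approx(math.degrees(math.atan(-0.05 / 0.4)))


def test_ubta_undefined_when_shoulders_align_mediolaterally():
    with pytest.raises(UndefinedAngleError):
        ubta(shoulder_pose([0.0, 0.1, 1.4], [0.0, 0.3, 1.4]))


# ---------------------------------------------------------------------------
# COM and dispersion


def test_com_arithmetic_and_hip_symmetry():
    p = pose(**{str(J.SPINE_MID): [0, 0, 0], str(J.HIP_RIGHT): [0, 0, 3],
                str(J.HIP_LEFT): [0, 3, 0]})
    np.testing.assert_allclose(com(p), [0.0, 1.0, 1.0])
    swapped = pose(**{str(J.SPINE_MID): [0, 0, 0], str(J.HIP_RIGHT): [0, 3, 0],
                      str(J.HIP_LEFT): [0, 0, 3]})
    np.testing.assert_allclose(com(p), com(swapped))
    coincident = pose(**{str(J.SPINE_MID): [1, 2, 3], str(J.HIP_RIGHT): [1, 2, 3],
                         str(J.HIP_LEFT): [1, 2, 3]})
    np.testing.assert_allclose(com(coincident), [1, 2, 3])


def test_com_missing_when_a_hip_is_untracked():
    p = pose(**{str(J.HIP_LEFT): [np.nan] * 3})
    assert np.isnan(com(p)).all()


def test_com_dispersion_closed_forms():
    assert com_dispersion([0.5] * 10) == 0.0
    n = 100
    alternating = 0.2 + 0.005 * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    expected_cm = 0.005 * math.sqrt(n / (n - 1)) * 100
    assert com_dispersion(alternating) == pytest.approx(expected_cm, rel=1e-12)
    assert expected_cm == pytest.approx(0.5, abs=0.01)
    # translation invariance
    assert com_dispersion(alternating + 3.7) == pytest.approx(
        com_dispersion(alternating), rel=1e-9
    )
    assert math.isnan(com_dispersion([0.1]))


# ---------------------------------------------------------------------------
# UfV


def seg(kind, t0, z0, t1, z1):
    start_kind, end_kind = ("valley", "peak") if kind == "ascending" else ("peak", "valley")
    return PhaseSegment(
        kind=kind,
        start=Extremum(kind=start_kind, index=0, t_s=t0, z_m=z0),
        end=Extremum(kind=end_kind, index=10, t_s=t1, z_m=z1),
        frame_span=(0, 10),
    )


def test_ufv_ascent_and_descent_are_positive_and_equal_for_symmetric_cycle():
    up = seg("ascending", 0.0, 0.5, 2.0, 1.0)
    down = seg("descending", 2.0, 1.0, 4.0, 0.5)
    assert ufv(up) == pytest.approx(0.25)
    assert ufv(down) == pytest.approx(0.25)
    assert ufv(up) == ufv(down)


def test_ufv_rejects_zero_duration():
    with pytest.raises(ContractError):
        ufv(seg("ascending", 1.0, 0.5, 1.0, 1.0))


# ---------------------------------------------------------------------------
# invariances


def indicator_vector(p):
    return np.array([ubfa(p), llfa(p, "left"), llfa(p, "right"), ubta(p)])


def test_angles_invariant_under_translation_and_uniform_scaling():
    rng = np.random.default_rng(5)
    for _ in range(10):
        p = rng.normal(0, 0.5, (N_JOINTS, 3))
        base = indicator_vector(p)
        shifted = p + rng.normal(0, 2.0, 3)
        np.testing.assert_allclose(indicator_vector(shifted), base, atol=1e-9)
        scaled = p * rng.uniform(0.5, 3.0)
        np.testing.assert_allclose(indicator_vector(scaled), base, atol=1e-9)


# ---------------------------------------------------------------------------
# phase aggregation


def test_phase_features_reports_ubfa_range(clean_session):
    session, truth = clean_session
    ind = compute_session_indicators(session)
    stand_range = ind.summary_row()["Stand UBFA range (deg)"]
    assert stand_range == pytest.approx(truth.ubfa_range_deg, abs=1.0)


def test_phase_features_with_no_segments_is_empty():
    from tests.conftest import make_session

    session = make_session(n=10)
    ind = phase_features(session, segments=[], nsu=0)
    assert ind.nsu == 0
    assert ind.phases == []
    assert math.isnan(ind.summary_row()["UfVup (m/s)"])


# ---------------------------------------------------------------------------
# cohort summary and reference comparison


def test_cohort_summary_of_identical_sessions_has_zero_sd(clean_session):
    session, _ = clean_session
    ind = compute_session_indicators(session)
    summary = cohort_summary([ind, ind])
    assert list(summary.table.index) == list(TABLE_ROWS)
    assert (summary.table["sd"] == 0).all()
    assert (summary.table["n"] == 2).all()
    single = cohort_summary([ind])
    assert single.table.loc["NSU", "mean"] == ind.nsu
    assert single.table.loc["NSU", "sd"] == 0.0


def test_ttest_matches_hand_computation():
    # all samples on the reference: maximally consistent
    t, p = compare_to_reference([2.0, 2.0, 2.0], 2.0, tails="two")
    assert (t, p) == (0.0, 1.0)
    # {1..5} vs 0: mean 3, sd 1.5811 → t = 3 / (1.5811/sqrt(5)) = 4.243
    t, p = compare_to_reference([1, 2, 3, 4, 5], 0.0, tails="two")
    assert t == pytest.approx(4.2426, abs=1e-3)
    assert p == pytest.approx(0.0132, abs=2e-4)
    # one-tailed in the supported direction halves the p value
    t1, p1 = compare_to_reference([1, 2, 3, 4, 5], 0.0, tails="one", direction="greater")
    assert t1 == pytest.approx(t)
    assert p1 == pytest.approx(p / 2)


def test_degenerate_ttest_off_reference_is_flagged():
    t, p = compare_to_reference([1.0, 1.0, 1.0], 0.0, tails="two")
    assert math.isnan(t) and math.isnan(p)


def test_packaged_reference_values_load():
    refs = load_reference_values()
    assert refs["UfVup (m/s)"].mean == 0.78
    assert refs["UfVdown (m/s)"].mean == 0.71
    assert refs["COM stand AP (cm)"].mean == 0.01
    assert refs["COM sit ML (cm)"].mean == 0.04
    assert all(rv.tails == "one" for rv in refs.values())
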