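import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergokit.core import (
    LUBA_MOTIONS,
    ArmSelection,
    ErgoError,
    IncompleteFrameError,
    JointMotion,
    RunConfig,
    UnsupportedMotionError,
)
from ergokit.luba import (
    MAX_GLOBAL_SCORE,
    SCORE_SCALES,
    Category,
    LubaScore,
    categorize,
    global_score,
    score_column,
    score_motion,
    score_series,
)

from conftest import make_series

JM = JointMotion

# Independent oracle: the score tables transcribed as explicit closed
# intervals (lo, hi, score] with lo exclusive / hi inclusive; magnitude flag
# marks motions scored on |angle|. Kept separate from the implementation's
# searchsorted path on purpose.
INF = float("inf")
ORACLE_INTERVALS = {
    "back_fe": [
        (-INF, -30, 15), (-30, -20, 8), (-20, -10, 4), (-10, 30, 1),
        (30, 60, 3), (60, 90, 6), (90, INF, 12),
    ],
    "back_lb": [(-INF, 10, 1), (10, 20, 4), (20, 30, 9), (30, INF, 13)],
    "back_ar": [(-INF, 20, 1), (20, 60, 3), (60, INF, 10)],
    "shoulder_fe": [
        (-INF, -60, 10), (-60, -45, 6), (-45, -20, 3), (-20, 45, 1),
        (45, 90, 3), (90, 150, 6), (150, INF, 11),
    ],
    "shoulder_aa": [
        (-INF, -30, 8), (-30, -10, 2), (-10, 30, 1), (30, 90, 3), (90, INF, 7),
    ],
    "elbow_fe": [(-INF, 45, 1), (45, 120, 3), (120, INF, 5)],
}
ORACLE_TABLE = {
    JM.BACK_FLEXION_EXTENSION: ("back_fe", False),
    JM.BACK_LATERAL_BENDING: ("back_lb", True),
    JM.BACK_AXIAL_ROTATION: ("back_ar", True),
    JM.SHOULDER_LEFT_FLEXION_EXTENSION: ("shoulder_fe", False),
    JM.SHOULDER_RIGHT_FLEXION_EXTENSION: ("shoulder_fe", False),
    JM.SHOULDER_LEFT_ABDUCTION_ADDUCTION: ("shoulder_aa", False),
    JM.SHOULDER_RIGHT_ABDUCTION_ADDUCTION: ("shoulder_aa", False),
    JM.ELBOW_LEFT_FLEXION_EXTENSION: ("elbow_fe", False),
    JM.ELBOW_RIGHT_FLEXION_EXTENSION: ("elbow_fe", False),
}


def oracle_score(motion: JointMotion, angle: float) -> int:
    key, magnitude = ORACLE_TABLE[motion]
    x = abs(angle) if magnitude else angle
    matches = [s for lo, hi, s in ORACLE_INTERVALS[key] if lo < x <= hi]
    assert len(matches) == 1, f"{motion} tables must tile the line at {x}"
    return matches[0]


def all_min_scores() -> dict[JointMotion, LubaScore]:
    return {m: LubaScore(motion=m, score=1) for m in LUBA_MOTIONS}


class TestScoreMotion:
    @pytest.mark.parametrize(
        "motion,angle,expected",
        [
            (JM.BACK_FLEXION_EXTENSION, -35.0, 15),
            (JM.BACK_FLEXION_EXTENSION, 0.0, 1),
            (JM.BACK_FLEXION_EXTENSION, 70.0, 6),
            (JM.BACK_FLEXION_EXTENSION, 95.0, 12),
            (JM.SHOULDER_LEFT_ABDUCTION_ADDUCTION, 0.0, 1),
            (JM.SHOULDER_RIGHT_ABDUCTION_ADDUCTION, -35.0, 8),
            (JM.ELBOW_LEFT_FLEXION_EXTENSION, 130.0, 5),
            (JM.BACK_LATERAL_BENDING, -25.0, 9),  # magnitude-scored
            (JM.BACK_AXIAL_ROTATION, -70.0, 10),
            (JM.SHOULDER_LEFT_FLEXION_EXTENSION, 160.0, 11),
        ],
    )
    def test_worked_examples(self, motion, angle, expected):
        assert score_motion(motion, angle).score == expected

    def test_boundaries_inclusive_as_printed(self):
        assert score_motion(JM.BACK_FLEXION_EXTENSION, 30.0).score == 1
        assert score_motion(JM.BACK_FLEXION_EXTENSION, 30.0001).score == 3
        assert score_motion(JM.BACK_FLEXION_EXTENSION, -30.0).score == 15
        assert score_motion(JM.BACK_FLEXION_EXTENSION, -29.9999).score == 8
        assert score_motion(JM.ELBOW_LEFT_FLEXION_EXTENSION, 120.0).score == 3

    def test_knee_unsupported(self):
        with pytest.raises(UnsupportedMotionError):
            score_motion(JM.KNEE_LEFT_FLEXION_EXTENSION, 10.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ErgoError):
            score_motion(JM.BACK_FLEXION_EXTENSION, float("nan"))

    @pytest.mark.parametrize("motion", LUBA_MOTIONS)
    def test_totality_on_dense_grid(self, motion):
        grid = np.arange(-360.0, 360.0001, 0.25)
        got = score_column(motion, grid)
        expected = [oracle_score(motion, a) for a in grid]
        np.testing.assert_array_equal(got, expected)

    @settings(max_examples=200, deadline=None)
    @given(
        st.sampled_from(list(LUBA_MOTIONS)),
        st.floats(min_value=-360.0, max_value=360.0, allow_nan=False),
    )
    def test_matches_oracle_on_random_angles(self, motion, angle):
        assert score_motion(motion, angle).score == oracle_score(motion, angle)

    def test_score_scales_as_printed(self):
        assert SCORE_SCALES[JM.BACK_FLEXION_EXTENSION] == (1, 3, 4, 6, 8, 12, 15)
        assert SCORE_SCALES[JM.BACK_LATERAL_BENDING] == (1, 4, 9, 13)
        assert SCORE_SCALES[JM.BACK_AXIAL_ROTATION] == (1, 3, 10)
        assert SCORE_SCALES[JM.SHOULDER_LEFT_FLEXION_EXTENSION] == (1, 3, 6, 10, 11)
        assert SCORE_SCALES[JM.SHOULDER_LEFT_ABDUCTION_ADDUCTION] == (1, 2, 3, 7, 8)
        assert SCORE_SCALES[JM.ELBOW_LEFT_FLEXION_EXTENSION] == (1, 3, 5)


class TestGlobalScore:
    def test_all_minimum_gives_zero(self):
        result = global_score(all_min_scores())
        assert result.g == 0
        assert result.category is Category.I

    def test_single_contribution(self):
        scores = all_min_scores()
        scores[JM.BACK_FLEXION_EXTENSION] = LubaScore(JM.BACK_FLEXION_EXTENSION, 6)
        result = global_score(scores)
        assert result.g == 6
        assert result.category is Category.II

    def test_maximum_is_62(self):
        scores = {m: LubaScore(m, SCORE_SCALES[m][-1]) for m in LUBA_MOTIONS}
        result = global_score(scores)
        assert result.g == 62 == MAX_GLOBAL_SCORE

    def test_arm_selected_by_sum(self):
        scores = all_min_scores()
        scores[JM.SHOULDER_RIGHT_FLEXION_EXTENSION] = LubaScore(
            JM.SHOULDER_RIGHT_FLEXION_EXTENSION, 6
        )
        scores[JM.SHOULDER_RIGHT_ABDUCTION_ADDUCTION] = LubaScore(
            JM.SHOULDER_RIGHT_ABDUCTION_ADDUCTION, 3
        )
        scores[JM.ELBOW_RIGHT_FLEXION_EXTENSION] = LubaScore(
            JM.ELBOW_RIGHT_FLEXION_EXTENSION, 3
        )
        # right sum 12 vs left sum 3, per the stated worst-arm rule
        result = global_score(scores)
        assert result.selected_arm == "right"
        assert result.g == 12

    def test_tie_goes_right(self):
        assert global_score(all_min_scores()).selected_arm == "right"

    def test_fixed_arm_policies(self):
        scores = all_min_scores()
        scores[JM.SHOULDER_LEFT_FLEXION_EXTENSION] = LubaScore(
            JM.SHOULDER_LEFT_FLEXION_EXTENSION, 11
        )
        assert global_score(scores, ArmSelection.LEFT).g == 11
        assert global_score(scores, ArmSelection.RIGHT).g == 0
        assert global_score(scores, ArmSelection.WORST_SUM).g == 11

    def test_missing_motion_rejected(self):
        scores = all_min_scores()
        del scores[JM.ELBOW_LEFT_FLEXION_EXTENSION]
        with pytest.raises(IncompleteFrameError, match="elbow_left"):
            global_score(scores)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_bounds_and_zero_iff_all_min(self, data):
        scores = {
            m: LubaScore(m, data.draw(st.sampled_from(SCORE_SCALES[m])))
            for m in LUBA_MOTIONS
        }
        result = global_score(scores)
        assert 0 <= result.g <= MAX_GLOBAL_SCORE
        back_and_arm = [
            JM.BACK_FLEXION_EXTENSION, JM.BACK_LATERAL_BENDING, JM.BACK_AXIAL_ROTATION,
        ] + [
            m for m in LUBA_MOTIONS if m.side == result.selected_arm
        ]
        if all(scores[m].score == 1 for m in back_and_arm):
            assert result.g == 0
        else:
            assert result.g > 0

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_policy_irrelevant_for_symmetric_arms(self, data):
        scores = {}
        for m in LUBA_MOTIONS:
            if m.side in (None, "left"):
                scores[m] = LubaScore(m, data.draw(st.sampled_from(SCORE_SCALES[m])))
        for m in LUBA_MOTIONS:
            if m.side == "right":
                twin = JointMotion(m.value.replace("right", "left"))
                scores[m] = LubaScore(m, scores[twin].score)
        gs = {p: global_score(scores, p).g for p in ArmSelection}
        assert len(set(gs.values())) == 1


class TestCategorize:
    @pytest.mark.parametrize(
        "g,expected",
        [(0, Category.I), (5, Category.I), (6, Category.II), (10, Category.II),
         (12, Category.III), (15, Category.III), (16, Category.IV), (62, Category.IV)],
    )
    def test_thresholds(self, g, expected):
        assert categorize(g) is expected

    def test_negative_rejected(self):
        with pytest.raises(ErgoError):
            categorize(-1)

    def test_monotone(self):
        order = [Category.I, Category.II, Category.III, Category.IV]
        cats = [order.index(categorize(g)) for g in range(0, 70)]
        assert cats == sorted(cats)

    def test_exactly_four_categories(self):
        assert len(Category) == 4
        assert {categorize(g).value for g in range(0, 63)} == {"I", "II", "III", "IV"}


class TestScoreSeries:
    def test_neutral_series_all_zero(self, neutral_series, config):
        result = score_series(neutral_series, config)
        assert len(result) == 100
        assert np.all(result.g == 0)
        assert all(c is Category.I for c in result.categories)

    def test_single_risky_frame(self, config):
        series = make_series(n=10)
        back = series.angles[JointMotion.BACK_FLEXION_EXTENSION].copy()
        back[4] = 70.0  # (60, 90] band
        series.angles[JointMotion.BACK_FLEXION_EXTENSION] = back
        result = score_series(series, config)
        assert result.g[4] == 6
        assert np.sum(result.g) == 6

    def test_matches_per_frame_oracle(self, rng, config):
        n = 200
        angles = {m: rng.uniform(-180, 180, n) for m in LUBA_MOTIONS}
        series = make_series(n=n)
        series.angles.update(angles)
        result = score_series(series, config)
        for i, frame in enumerate(series.frames()):
            per_motion = {
                m: score_motion(m, frame[m]) for m in LUBA_MOTIONS
            }
            expected = global_score(per_motion, config.arm_selection)
            assert result.g[i] == expected.g
            assert result.selected_arm[i] == expected.selected_arm
            assert result.categories[i] is expected.category
            for m in LUBA_MOTIONS:
                assert result.motion_scores[m][i] == per_motion[m].score

    def test_missing_motion_propagates(self, config):
        series = make_series(n=5, motions=LUBA_MOTIONS[:-1])
        with pytest.raises(IncompleteFrameError):
            score_series(series, config)
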