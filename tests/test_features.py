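"""Feature oracles: closed forms (semicircle arc, sinusoid SD, Parseval),
brute-force polyline sums, and generator ground truth."""

import numpy as np
import pytest

from gaitclass import (
    EffectSizes,
    FeatureError,
    GaitParams,
    MotionRecording,
    apply_severity,
    features_table,
    generate_cohort,
    generate_recording,
)
from gaitclass.features import (
    HIGH_BAND,
    LOW_BAND,
    band_energy,
    com_std,
    extract_features,
    relative_step_length,
    step_cadence,
    step_length,
    step_trajectory,
)
from gaitclass.preprocess import FootContactSeries, GaitSegment
from tests.conftest import segments_of


def _segment_from_paths(left, right, pelvis=None, left_c=(), right_c=(), fs=60):
    n = len(left)
    if pelvis is None:
        pelvis = 0.5 * (np.asarray(left) + np.asarray(right))
    rec = MotionRecording(
        "X",
        "healthy",
        0.0,
        fs,
        {
            "left_foot": np.asarray(left, float),
            "right_foot": np.asarray(right, float),
            "pelvis": np.asarray(pelvis, float),
        },
    )
    contacts = FootContactSeries(
        left=np.asarray(left_c, int), right=np.asarray(right_c, int)
    )
    return GaitSegment(rec, 0, n, contacts)


class TestStepCadence:
    def test_eleven_contacts_over_six_seconds_is_100(self):
        n = 400
        path = np.zeros((n, 3))
        seg = _segment_from_paths(
            path, path, left_c=np.arange(0, 361, 72), right_c=np.arange(36, 361, 72)
        )
        # 11 pooled contacts spanning 360 samples = 6 s -> 100 steps/min
        assert step_cadence(seg) == pytest.approx(100.0)

    def test_generator_cadence_recovered(self, noisefree_recording):
        rec, _ = noisefree_recording
        for seg in segments_of(rec):
            assert step_cadence(seg) == pytest.approx(110.0, abs=2.0)

    def test_healthy_default_in_normal_range(self, small_segments):
        for seg in small_segments:
            assert 100 <= step_cadence(seg) <= 115

    def test_insufficient_contacts_raises(self):
        path = np.zeros((10, 3))
        seg = _segment_from_paths(path, path, left_c=[3])
        with pytest.raises(FeatureError, match="nsufficient"):
            step_cadence(seg)


class TestStepLength:
    def test_single_distance(self):
        n = 20
        left = np.zeros((n, 3))
        right = np.zeros((n, 3))
        right[10:] = [0.6, 0, 0]
        seg = _segment_from_paths(left, right, left_c=[0], right_c=[10])
        assert step_length(seg) == pytest.approx(0.6)

    def test_median_of_three(self):
        n = 40
        # pooled contact positions at x = 0, 0.5, 1.1, 1.8 -> distances 0.5, 0.6, 0.7
        left = np.zeros((n, 3))
        left[20:] = [1.1, 0, 0]
        right = np.full((n, 3), [0.5, 0.0, 0.0])
        right[30:] = [1.8, 0, 0]
        seg = _segment_from_paths(left, right, left_c=[0, 20], right_c=[10, 30])
        assert step_length(seg) == pytest.approx(0.6)

    def test_generator_step_length_recovered(self, noisefree_recording):
        rec, _ = noisefree_recording
        for seg in segments_of(rec):
            assert step_length(seg) == pytest.approx(0.65, abs=0.01)


class TestStepTrajectory:
    def test_straight_swing_arc_equals_chord(self):
        n = 21
        left = np.zeros((n, 3))
        t = np.linspace(0, 1, n)[:, None]
        right = np.hstack([0.8 * t, np.zeros((n, 2))])
        seg = _segment_from_paths(left, right, left_c=[0], right_c=[n - 1])
        assert step_trajectory(seg) == pytest.approx(0.8, rel=1e-12)

    def test_semicircular_swing_arc_is_pi_r(self):
        r = 0.3
        n = 2001
        theta = np.linspace(np.pi, 0, n)
        right = np.column_stack(
            [r + r * np.cos(theta), r * np.sin(theta), np.zeros(n)]
        )
        left = np.zeros((n, 3))
        seg = _segment_from_paths(left, right, left_c=[0], right_c=[n - 1])
        assert step_trajectory(seg) == pytest.approx(np.pi * r, rel=0.01)

    def test_two_segment_polyline(self):
        pts = np.array([[0, 0, 0], [0.3, 0.1, 0], [0.6, 0, 0]])
        left = np.zeros((3, 3))
        seg = _segment_from_paths(left, pts, left_c=[0], right_c=[2])
        assert step_trajectory(seg) == pytest.approx(2 * np.sqrt(0.09 + 0.01))

    def test_matches_brute_force_polyline_sum(self, small_segments):
        """Arc length equals an independent sample-by-sample summation."""
        seg = small_segments[0]
        events = seg.contacts.pooled()
        arcs = []
        for (i0, _), (i1, side) in zip(events[:-1], events[1:]):
            path = seg.recording.joints[f"{side}_foot"][i0 : i1 + 1]
            total = 0.0
            for a, b in zip(path[:-1], path[1:]):
                total += float(np.sqrt(((b - a) ** 2).sum()))
            arcs.append(total)
        expected = float(np.median(arcs))
        assert step_trajectory(seg) == pytest.approx(expected, rel=1e-12)


class TestRelativeStepLength:
    def test_optimal_step_is_one(self):
        assert relative_step_length(0.6, 0.6) == 1.0

    def test_ratio_arithmetic(self):
        assert relative_step_length(0.6, 0.75) == pytest.approx(0.8)

    def test_invalid_inputs_raise(self):
        with pytest.raises(FeatureError):
            relative_step_length(0.6, 0.0)
        with pytest.raises(FeatureError):
            relative_step_length(0.7, 0.6)

    def test_ataxic_cohort_ratio_below_healthy(self):
        """More tortuous ataxic swings lower SL/ST at severity 1."""
        base = GaitParams(walk_length=12, n_passes=1)
        ratios = {}
        for label, severity in (("healthy", 0.0), ("ataxic", 1.0)):
            values = []
            for i in range(10):
                params = apply_severity(base, severity, EffectSizes())
                rec, _ = generate_recording(params, "X", 500 + i, label)
                for seg in segments_of(rec):
                    values.append(
                        relative_step_length(step_length(seg), step_trajectory(seg))
                    )
            ratios[label] = np.median(values)
        assert ratios["ataxic"] < ratios["healthy"]


class TestComStd:
    def test_straight_line_pelvis_is_zero(self):
        n = 200
        t = np.linspace(0, 1, n)[:, None]
        track = np.hstack([3 * t, np.zeros((n, 1)), 2 * t])
        seg = _segment_from_paths(track, track, pelvis=track, left_c=[0, 100], right_c=[50])
        assert com_std(seg) == pytest.approx(0.0, abs=1e-12)

    def test_lateral_sinusoid_sd_is_amplitude_over_sqrt2(self):
        a = 0.03
        n = 1200
        t = np.arange(n) / 60.0
        pelvis = np.column_stack(
            [1.2 * t, np.zeros(n), a * np.sin(2 * np.pi * 1.8 * t)]
        )
        feet = np.zeros((n, 3))
        seg = _segment_from_paths(feet, feet, pelvis=pelvis, left_c=[0], right_c=[1])
        assert com_std(seg) == pytest.approx(a / np.sqrt(2), rel=0.02)

    def test_severity_raises_com_std(self):
        base = GaitParams(walk_length=12, n_passes=1)
        means = {}
        for severity in (0.0, 1.0):
            values = []
            for i in range(8):
                params = apply_severity(base, severity, EffectSizes())
                rec, _ = generate_recording(params, "X", 700 + i)
                values.extend(com_std(s) for s in segments_of(rec))
            means[severity] = np.mean(values)
        assert means[1.0] > means[0.0]


class TestBandEnergy:
    def test_constant_velocity_has_zero_energy(self):
        n = 600
        t = np.linspace(0, 10, n)[:, None]
        track = np.hstack([1.2 * t, np.zeros((n, 2))])
        seg = _segment_from_paths(track, track, pelvis=track, left_c=[0], right_c=[1])
        assert band_energy(seg, LOW_BAND) == pytest.approx(0.0, abs=1e-18)
        assert band_energy(seg, HIGH_BAND) == pytest.approx(0.0, abs=1e-18)

    def test_10hz_tone_concentrates_in_low_band(self):
        n = 3000
        t = np.arange(n) / 60.0
        x = 0.01 * np.sin(2 * np.pi * 10.0 * t)
        pelvis = np.column_stack([x, np.zeros(n), np.zeros(n)])
        feet = np.zeros((n, 3))
        seg = _segment_from_paths(feet, feet, pelvis=pelvis, left_c=[0], right_c=[1])
        low = band_energy(seg, LOW_BAND)
        high = band_energy(seg, HIGH_BAND)
        total = band_energy(seg, (0.5, 29.999))
        assert low / total > 0.99
        assert high / total < 0.01

    def test_white_noise_energy_ratio_matches_bandwidths(self):
        """Flat acceleration spectrum: band energies scale ~ 12:14."""
        rng = np.random.default_rng(3)
        n = 6000
        acc = rng.normal(0, 1.0, n)
        # integrate twice to get a position whose 2nd difference is the noise
        vel = np.cumsum(acc) / 60.0
        pos = np.cumsum(vel) / 60.0
        pelvis = np.column_stack([pos, np.zeros(n), np.zeros(n)])
        feet = np.zeros((n, 3))
        seg = _segment_from_paths(feet, feet, pelvis=pelvis, left_c=[0], right_c=[1])
        ratio = band_energy(seg, LOW_BAND) / band_energy(seg, HIGH_BAND)
        assert ratio == pytest.approx(12.0 / 14.0, rel=0.10)

    def test_band_energies_bounded_by_total(self, small_segments):
        for seg in small_segments:
            low = band_energy(seg, LOW_BAND)
            high = band_energy(seg, HIGH_BAND)
            total = band_energy(seg, (0.0, 30.0))
            assert low + high <= total + 1e-9

    def test_short_segment_rejected(self):
        feet = np.zeros((30, 3))
        seg = _segment_from_paths(feet, feet, left_c=[0], right_c=[1])
        with pytest.raises(FeatureError, match="too short"):
            band_energy(seg, LOW_BAND)


class TestExtractFeatures:
    def test_valid_segment_satisfies_invariants(self, small_segments):
        for seg in small_segments:
            vec = extract_features(seg)
            vec.validate()
            assert 0 < vec.relative_step_length <= 1

    def test_deterministic(self, small_segments):
        v1 = extract_features(small_segments[0])
        v2 = extract_features(small_segments[0])
        assert v1 == v2

    def test_cohort_feature_table_shape(self, small_cohort, small_feature_table):
        table = small_feature_table
        n_passes = 3
        assert len(table) == len(small_cohort) * n_passes
        assert list(table.columns[:3]) == ["participant_id", "label", "severity"]
        assert table.notna().all().all()

    def test_feature_monotonicity_in_severity(self):
        """com_std, step-length CV and high-band energy rise with severity
        (positive rank correlation over severities 0 .. 1)."""
        from scipy.stats import spearmanr

        base = GaitParams(walk_length=12, n_passes=1)
        severities = [0.0, 0.25, 0.5, 0.75, 1.0]
        sev_col, com_col, cv_col, high_col = [], [], [], []
        for s_i, severity in enumerate(severities):
            for i in range(10):
                params = apply_severity(base, severity, EffectSizes())
                rec, gt = generate_recording(params, "X", 900 + 100 * s_i + i)
                segs = segments_of(rec)
                table = features_table(segs)
                sev_col.append(severity)
                com_col.append(table["com_std"].mean())
                cv_col.append(gt.per_step_lengths.std() / gt.per_step_lengths.mean())
                high_col.append(table["energy_high"].mean())
        for col in (com_col, cv_col, high_col):
            rho = spearmanr(sev_col, col).statistic
            assert rho > 0
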