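"""Kinematic peaks, group statistics, ANOVA, RMSE, mean trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dtcgait.cohort_analysis import (
    anova_by_group,
    anova_table,
    extract_kinematic_features,
    feature_table,
    group_mean_trajectories,
    group_statistics,
    rmse_table,
    rmse_vs_control,
)
from dtcgait.gait_io import GaitInstance, JointTrajectory, compute_angular_velocity
from dtcgait.synthetic_cohort import (
    make_archetypes,
    make_control_reference,
    sample_cohort,
)


def _instance(hip, knee, ankle, sid="S0", metadata=None):
    trajs = []
    for joint, samples in (("hip", hip), ("knee", knee), ("ankle", ankle)):
        angle = JointTrajectory(joint, "angle", samples)
        trajs += [angle, compute_angular_velocity(angle, 1.0)]
    return GaitInstance(sid, 2, trajs, metadata=metadata or {})


class TestKinematicFeatures:
    def test_sine_hip_peaks(self):
        T = 100
        t = np.arange(T)
        hip = 30 * np.sin(2 * np.pi * t / T) + 10
        inst = _instance(hip, np.zeros(T), np.zeros(T))
        feats = extract_kinematic_features(inst)
        assert feats["peak_hip_flexion"] == pytest.approx(40.0, abs=1e-6)
        assert feats["peak_hip_extension"] == pytest.approx(-20.0, abs=1e-6)

    def test_constant_knee_gives_equal_peaks(self):
        T = 100
        inst = _instance(np.zeros(T), np.full(T, 5.0), np.zeros(T))
        feats = extract_kinematic_features(inst)
        for name in ("peak_knee_flexion_stance", "peak_knee_extension_stance",
                      "peak_knee_flexion_swing", "peak_knee_extension_swing"):
            assert feats[name] == pytest.approx(5.0)

    def test_windowed_knee_peaks_split_at_boundary(self):
        T = 100
        knee = np.zeros(T)
        knee[20] = 15.0   # stance max at 20%
        knee[70] = 60.0   # swing max at 70%
        inst = _instance(np.zeros(T), knee, np.zeros(T))
        feats = extract_kinematic_features(inst, stance_boundary=60.0)
        assert feats["peak_knee_flexion_stance"] == pytest.approx(15.0)
        assert feats["peak_knee_flexion_swing"] == pytest.approx(60.0)

    def test_metadata_stance_percentage_moves_boundary(self):
        T = 100
        knee = np.zeros(T)
        knee[65] = 30.0
        inst = _instance(np.zeros(T), knee, np.zeros(T),
                         metadata={"stance_aff": 70.0})
        feats = extract_kinematic_features(inst)
        assert feats["peak_knee_flexion_stance"] == pytest.approx(30.0)
        feats_fixed = extract_kinematic_features(inst, use_metadata_boundary=False)
        assert feats_fixed["peak_knee_flexion_swing"] == pytest.approx(30.0)

    def test_plantarflexion_reported_positive(self):
        ref = make_control_reference(100)
        inst = _instance(ref.hip, ref.knee, ref.ankle)
        feats = extract_kinematic_features(inst)
        assert feats["peak_dorsiflexion"] > 0.0
        assert feats["peak_plantar_flexion"] > 0.0

    def test_flexion_never_below_extension(self):
        specs = make_archetypes(4, severity=1.0, seed=2)
        cohort = sample_cohort(specs, n_per_cluster=3, T=100, seed=2)
        for inst in cohort.instances:
            f = extract_kinematic_features(inst)
            assert f["peak_hip_flexion"] >= f["peak_hip_extension"]
            assert f["peak_knee_flexion_stance"] >= f["peak_knee_extension_stance"]
            assert f["peak_knee_flexion_swing"] >= f["peak_knee_extension_swing"]


class TestGroupStatistics:
    def test_hand_arithmetic(self):
        feats = pd.DataFrame({"v": [1.0, 2.0, 3.0]},
                             index=["a", "b", "c"])
        out = group_statistics(feats, np.array([0, 0, 0]))
        row = out[(out.feature == "v") & (out.group == "A")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)
        assert row["n"] == 3

    def test_identical_groups_identical_rows(self):
        feats = pd.DataFrame({"v": [1.0, 2.0, 1.0, 2.0]})
        out = group_statistics(feats, np.array([0, 0, 1, 1]))
        a = out[(out.group == "A")].iloc[0]
        b = out[(out.group == "B")].iloc[0]
        assert a["mean"] == b["mean"] and a["sd"] == b["sd"]

    def test_overall_mean_is_size_weighted_group_mean(self, rng):
        feats = pd.DataFrame({"v": rng.normal(size=30)})
        labels = rng.integers(0, 3, size=30)
        out = group_statistics(feats, labels)
        groups = out[out.group != "overall"]
        weighted = (groups["mean"] * groups["n"]).sum() / groups["n"].sum()
        overall = out[out.group == "overall"]["mean"].iloc[0]
        assert overall == pytest.approx(weighted, abs=1e-12)

    def test_excluded_instances_dropped(self):
        feats = pd.DataFrame({"v": [1.0, 2.0, 100.0]})
        out = group_statistics(feats, np.array([0, 0, -1]))
        assert out[out.group == "overall"]["n"].iloc[0] == 2


class TestAnova:
    def test_hand_computed_two_group_example(self):
        values = np.array([1.0, 2, 3, 11, 12, 13])
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = anova_by_group(values, labels)
        assert res.F_value == pytest.approx(150.0, abs=1e-9)
        assert res.df_between == 1 and res.df_within == 4

    def test_identical_groups_give_F_zero_p_one(self):
        res = anova_by_group(np.array([1.0, 2, 1, 2]), np.array([0, 0, 1, 1]))
        assert res.F_value == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_oracle(self, rng):
        values = rng.normal(size=60)
        labels = rng.integers(0, 6, size=60)
        res = anova_by_group(values, labels)
        groups = [values[labels == g] for g in np.unique(labels)]
        F, p = sps.f_oneway(*groups)
        assert res.F_value == pytest.approx(float(F), abs=1e-9)
        assert res.p_value == pytest.approx(float(p), abs=1e-9)

    def test_location_scale_invariance_of_F(self, rng):
        values = rng.normal(size=40)
        labels = rng.integers(0, 4, size=40)
        f0 = anova_by_group(values, labels).F_value
        assert anova_by_group(values + 100.0, labels).F_value == pytest.approx(f0)
        assert anova_by_group(values * 7.0, labels).F_value == pytest.approx(f0)

    def test_degenerate_zero_within_variance(self):
        res = anova_by_group(np.array([1.0, 1, 2, 2]), np.array([0, 0, 1, 1]))
        assert res.degenerate and res.p_value == 0.0

    def test_table_and_bonferroni(self, rng):
        feats = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        labels = rng.integers(0, 2, size=20)
        raw = anova_table(feats, labels)
        adj = anova_table(feats, labels, bonferroni=True)
        assert np.allclose(
            adj["p_value"], np.minimum(raw["p_value"] * 2, 1.0), atol=1e-12
        )


class TestRmse:
    def test_identity_is_zero(self):
        ref = make_control_reference(100)
        curves = {"hip": ref.hip, "knee": ref.knee, "ankle": ref.ankle}
        assert rmse_vs_control(curves, ref) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        ref = make_control_reference(100)
        curves = {j: ref.curve(j) + 2.0 for j in ("hip", "knee", "ankle")}
        assert rmse_vs_control(curves, ref) == pytest.approx(2.0, abs=1e-12)

    def test_matches_loop_oracle_and_joint_order_invariance(self, rng):
        ref = make_control_reference(50)
        curves = {j: rng.normal(size=50) for j in ("hip", "knee", "ankle")}
        total = sum(
            (curves[j][i] - ref.curve(j)[i]) ** 2
            for j in ("hip", "knee", "ankle")
            for i in range(50)
        )
        expect = np.sqrt(total / 150)
        assert rmse_vs_control(curves, ref) == pytest.approx(expect, abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        ref = make_control_reference(50)
        curves = {j: rng.normal(size=40) for j in ("hip", "knee", "ankle")}
        with pytest.raises(ValueError):
            rmse_vs_control(curves, ref)


class TestGroupTrajectories:
    def test_identical_members_have_zero_sd(self):
        T = 60
        ref = make_control_reference(T)
        insts = [_instance(ref.hip, ref.knee, ref.ankle, sid=f"S{i}")
                 for i in range(3)]
        means = group_mean_trajectories(insts, np.zeros(3, dtype=int))
        for joint in ("hip", "knee", "ankle"):
            mean, sd = means[0][joint]
            assert np.allclose(sd, 0.0, atol=1e-12)
            assert np.allclose(mean, ref.curve(joint), atol=1e-12)

    def test_antisymmetric_pair_averages_to_zero(self, rng):
        v = rng.normal(size=60)
        insts = [_instance(v, v, v, sid="S0"), _instance(-v, -v, -v, sid="S1")]
        means = group_mean_trajectories(insts, np.zeros(2, dtype=int))
        assert np.allclose(means[0]["hip"][0], 0.0, atol=1e-12)

    def test_pointwise_mean_matches_loop_oracle(self, rng):
        curves = [rng.normal(size=30) for _ in range(4)]
        insts = [_instance(c, c, c, sid=f"S{i}") for i, c in enumerate(curves)]
        means = group_mean_trajectories(insts, np.zeros(4, dtype=int))
        expect = np.array([np.mean([c[i] for c in curves]) for i in range(30)])
        assert np.allclose(means[0]["knee"][0], expect, atol=1e-12)

    def test_rmse_table_covers_all_groups(self, rng):
        specs = make_archetypes(3, severity=1.0, seed=1)
        cohort = sample_cohort(specs, n_per_cluster=4, T=100, seed=1)
        table = rmse_table(cohort.instances, cohort.true_labels,
                           make_control_reference(100))
        assert len(table) == 3
        assert (table["rmse"] >= 0).all()


def test_feature_table_includes_metadata_columns(rng):
    specs = make_archetypes(2, severity=1.0, seed=0)
    cohort = sample_cohort(specs, n_per_cluster=3, T=50, seed=0)
    feats = feature_table(cohort.instances)
    assert "peak_dorsiflexion" in feats.columns
    assert "velocity" in feats.columns and "fma" in feats.columns
    assert len(feats) == 6
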