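"""Error metrics: voxel differences, R^2, Dice, distance profiles, regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmrac import (
    CompartmentMasks,
    aggregate_profiles,
    dice,
    distance_maps,
    distance_profile,
    error_summary,
    joint_r2,
    regional_errors,
    relative_difference,
)


def brute_force_nearest_mm(target2d: np.ndarray, spacing) -> np.ndarray:
    """All-pairs 2D nearest-neighbor distances, the independent oracle."""
    pts = np.argwhere(target2d).astype(float)
    pts[:, 0] *= spacing[0]
    pts[:, 1] *= spacing[1]
    out = np.full(target2d.shape, np.inf)
    for i in range(target2d.shape[0]):
        for j in range(target2d.shape[1]):
            d = np.hypot(pts[:, 0] - i * spacing[0], pts[:, 1] - j * spacing[1])
            out[i, j] = d.min()
    return out


class TestRelativeDifference:
    def test_identical_images_zero(self):
        r = np.ones((6, 6, 2))
        body = np.ones_like(r, dtype=bool)
        d = relative_difference(r, r, body)
        assert np.all(d.values() == 0.0)

    def test_definition_and_zero_reference_exclusion(self):
        ref = np.array([[[1.0, 0.0]]])
        test = np.array([[[1.1, 2.0]]])
        body = np.ones_like(ref, dtype=bool)
        d = relative_difference(test, ref, body)
        assert d.valid.sum() == 1
        assert d.values()[0] == pytest.approx(10.0)

    def test_empty_valid_raises(self):
        z = np.zeros((4, 4, 1))
        with pytest.raises(ValueError, match="valid"):
            relative_difference(z, z, np.ones_like(z, dtype=bool))


class TestErrorSummary:
    def test_all_zero(self):
        r = np.ones((5, 5, 1))
        d = relative_difference(r, r, np.ones_like(r, dtype=bool))
        mean, sd, frac = error_summary(d)
        assert (mean, sd) == (0.0, 0.0)
        assert all(v == 1.0 for v in frac.values())

    def test_hand_computed_pair(self):
        ref = np.ones((1, 1, 2))
        test = np.array([[[1.10, 0.90]]])
        d = relative_difference(test, ref, np.ones_like(ref, dtype=bool))
        mean, sd, frac = error_summary(d, thresholds=(5, 20))
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(10.0)
        assert frac[5.0] == 0.0 and frac[20.0] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-80, 80), min_size=1, max_size=60))
    def test_fractions_monotone_in_threshold(self, errs):
        ref = np.ones((len(errs), 1, 1))
        test = ref * (1 + np.asarray(errs).reshape(-1, 1, 1) / 100.0)
        d = relative_difference(test, ref, np.ones_like(ref, dtype=bool))
        _, _, frac = error_summary(d, thresholds=(5, 10, 20))
        assert frac[5.0] <= frac[10.0] <= frac[20.0]


class TestJointR2:
    def test_perfect_relations(self):
        r = np.random.default_rng(0).random((10, 10, 2)) + 0.5
        m = np.ones_like(r, dtype=bool)
        assert joint_r2(r, r, m) == pytest.approx(1.0)
        assert joint_r2(2.0 * r, r, m) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(42)
        a = rng.random((100, 100, 1))
        b = rng.random((100, 100, 1))
        assert joint_r2(a, b, np.ones_like(a, dtype=bool)) < 0.01

    def test_zero_variance_raises(self):
        a = np.ones((4, 4, 1))
        with pytest.raises(ValueError, match="variance"):
            joint_r2(a, a, np.ones_like(a, dtype=bool))


class TestDice:
    def test_enumerated_cases(self):
        a = np.zeros((3, 4), dtype=bool)
        b = np.zeros((3, 4), dtype=bool)
        assert dice(a, b) == 1.0  # both empty
        a[0, :4] = True  # |a| = 4
        b[0, 1:4] = True
        b[1, :3] = True  # |b| = 6, overlap 3
        assert dice(a, b) == pytest.approx(0.6)
        assert dice(b, a) == pytest.approx(0.6)  # symmetric
        assert dice(a, a) == 1.0
        assert dice(a, np.roll(a, 2, axis=0)) == 0.0  # disjoint

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_bounded_and_symmetric(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        b = np.array([(bbits >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


def _compartments(bone2d, air2d, body2d=None, lung2d=None):
    shape = bone2d.shape + (1,)
    body = np.ones(shape, dtype=bool) if body2d is None else body2d[:, :, None]
    lung = np.zeros(shape, dtype=bool) if lung2d is None else lung2d[:, :, None]
    return CompartmentMasks(
        body=body, bone=bone2d[:, :, None] & body, air=air2d[:, :, None] & body, lung=lung
    )


class TestDistanceMaps:
    def test_single_bone_voxel_345(self):
        bone = np.zeros((12, 12), dtype=bool)
        bone[2, 3] = True
        air = np.zeros_like(bone)
        air[11, 11] = True
        cm = _compartments(bone, air)
        (d_bone, v_bone), _ = distance_maps(cm, (1.0, 1.0, 1.0))
        assert d_bone[2, 3, 0] == 0.0
        assert d_bone[5, 7, 0] == pytest.approx(5.0)  # offset (3, 4)

    def test_closer_to_air_excluded_from_bone_map(self):
        bone = np.zeros((16, 16), dtype=bool)
        air = np.zeros_like(bone)
        bone[0, 0] = True
        air[0, 12] = True
        cm = _compartments(bone, air)
        (d_bone, v_bone), (d_air, v_air) = distance_maps(cm, (1.0, 1.0, 1.0))
        # voxel at (0, 10): 10 mm from bone, 2 mm from air
        assert not v_bone[0, 10, 0] and v_air[0, 10, 0]
        # equidistant voxel (0, 6) retained in both maps
        assert v_bone[0, 6, 0] and v_air[0, 6, 0]

    def test_empty_compartment_raises(self):
        bone = np.zeros((8, 8), dtype=bool)
        air = np.zeros_like(bone)
        air[1, 1] = True
        with pytest.raises(ValueError, match="nonempty"):
            distance_maps(_compartments(bone, air), (1.0, 1.0, 1.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            nx, ny = rng.integers(8, 32, size=2)
            bone = rng.random((nx, ny)) < 0.08
            air = (rng.random((nx, ny)) < 0.08) & ~bone
            if not bone.any() or not air.any():
                continue
            sp = (float(rng.choice([1.0, 1.5, 2.0])), float(rng.choice([1.0, 1.5, 2.0])))
            cm = _compartments(bone, air)
            (d_bone, _), (d_air, _) = distance_maps(cm, (sp[0], sp[1], 1.0))
            assert np.allclose(d_bone[:, :, 0], brute_force_nearest_mm(bone, sp), atol=1e-9)
            assert np.allclose(d_air[:, :, 0], brute_force_nearest_mm(air, sp), atol=1e-9)


class TestDistanceProfile:
    def _setup(self, n=20):
        bone = np.zeros((n, n), dtype=bool)
        bone[:, :2] = True
        air = np.zeros((n, n), dtype=bool)
        air[:, -1] = True
        cm = _compartments(bone, air)
        (d_bone, v_bone), _ = distance_maps(cm, (1.0, 1.0, 1.0))
        return bone[:, :, None], d_bone, v_bone

    def test_uniform_scaling_gives_constant_bins(self):
        bone, dist, valid = self._setup()
        ref = np.full(dist.shape, 2.0)
        prof = distance_profile(0.9 * ref, ref, dist, valid, min_voxels=1)
        vals = prof["error_pct"].dropna()
        assert len(vals) > 3
        assert np.allclose(vals, -10.0)

    def test_error_only_inside_compartment(self):
        bone, dist, valid = self._setup()
        ref = np.ones(dist.shape)
        test = np.where(bone, 1.2, 1.0)
        prof = distance_profile(test, ref, dist, valid, min_voxels=1).set_index("bin")
        assert prof.loc[0, "error_pct"] == pytest.approx(20.0)
        assert np.allclose(prof.drop(index=0)["error_pct"], 0.0)

    def test_bin_edges_left_open_right_closed(self):
        bone, dist, valid = self._setup()
        prof = distance_profile(np.ones(dist.shape), np.ones(dist.shape), dist, valid,
                                min_voxels=1)
        row1 = prof.set_index("bin").loc[1]
        assert (row1["lo_mm"], row1["hi_mm"]) == (0.0, 3.0)
        # distances of exactly 3 mm fall in bin 1, 3.5 mm in bin 2
        k = np.where(dist == 0, 0, np.ceil(dist / 3.0))
        assert k[dist == 3.0].min() == 1 if (dist == 3.0).any() else True

    def test_min_count_rule(self):
        bone, dist, valid = self._setup(n=20)
        prof = distance_profile(np.ones(dist.shape), np.ones(dist.shape), dist, valid,
                                min_voxels=10**6)
        assert prof["error_pct"].isna().all()


class TestAggregateProfiles:
    def _prof(self, errs):
        return pd.DataFrame(
            {"bin": range(len(errs)), "lo_mm": 0.0, "hi_mm": 3.0,
             "n_voxels": 100, "error_pct": errs}
        )

    def test_single_subject_quartiles_collapse(self):
        agg = aggregate_profiles({"s1": self._prof([-5.0, 2.0])}).aggregate
        assert np.allclose(agg["lq"], agg["median"])
        assert np.allclose(agg["median"], agg["uq"])

    def test_three_subject_linear_interpolation(self):
        profs = {f"s{i}": self._prof([v]) for i, v in enumerate([-10.0, 0.0, 10.0])}
        agg = aggregate_profiles(profs).aggregate
        assert agg.loc[0, "lq"] == pytest.approx(-5.0)
        assert agg.loc[0, "median"] == pytest.approx(0.0)
        assert agg.loc[0, "uq"] == pytest.approx(5.0)

    def test_missing_bins_skipped_per_subject(self):
        a = self._prof([1.0, np.nan])
        b = self._prof([3.0, 7.0])
        agg = aggregate_profiles({"a": a, "b": b}).aggregate.set_index("bin")
        assert agg.loc[0, "n_subjects"] == 2
        assert agg.loc[1, "n_subjects"] == 1
        assert agg.loc[1, "median"] == pytest.approx(7.0)

    def test_quartile_ordering(self):
        rng = np.random.default_rng(3)
        profs = {f"s{i}": self._prof(list(rng.normal(0, 20, 4))) for i in range(9)}
        agg = aggregate_profiles(profs).aggregate
        assert (agg["lq"] <= agg["median"]).all() and (agg["median"] <= agg["uq"]).all()


class TestRegionalErrors:
    def test_identity_and_arithmetic(self):
        ref = np.ones((8, 8, 2))
        test = ref.copy()
        roi_a = np.zeros_like(ref, dtype=bool)
        roi_a[:4] = True
        roi_b = ~roi_a
        test[roi_b] = 0.965
        out = regional_errors(test, ref, {"a": roi_a, "b": roi_b})
        assert out["a"] == pytest.approx(0.0)
        assert out["b"] == pytest.approx(-3.5)

    def test_empty_roi_reported_missing(self):
        ref = np.ones((4, 4, 1))
        out = regional_errors(ref, ref, {"empty": np.zeros_like(ref, dtype=bool)})
        assert np.isnan(out["empty"])

    def test_order_invariant(self):
        rng = np.random.default_rng(1)
        ref = rng.random((6, 6, 2)) + 0.5
        test = ref * 1.1
        rois = {"a": ref > 1.0, "b": ref <= 1.0}
        fwd = regional_errors(test, ref, rois)
        rev = regional_errors(test, ref, dict(reversed(list(rois.items()))))
        assert fwd == rev
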