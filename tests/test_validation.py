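import numpy as np
import pytest
from scipy import stats

from rfsafe import (
    Modality,
    ShimComparison,
    align_channel_phases,
    diff_map_b1,
    diff_map_sar,
    modeling_uncertainty,
    worst_case_uncertainty,
)
from rfsafe.validation import ComparisonUncertainty, nearest_rank_quantile

from conftest import make_map


def sort_oracle(values, q):
    """Independent nearest-rank oracle: full sort, 1-based rank ceil(qN)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    rank = int(np.ceil(q * v.size))
    return v[rank - 1]


class TestDiffMaps:
    def test_identical_maps_zero(self, random_sar_map):
        diff = diff_map_sar(random_sar_map, random_sar_map)
        np.testing.assert_allclose(diff, 0.0)

    def test_hand_arithmetic_sar(self):
        sim = make_map([[1.0, 2.0], [3.0, 4.0]])
        meas = make_map([[1.0, 2.0], [3.0, 5.0]])
        np.testing.assert_allclose(
            diff_map_sar(meas, sim), [[0.0, 0.0], [0.0, 0.25]]
        )

    def test_doubled_measurement(self, random_sar_map):
        meas = random_sar_map.replace(values=2 * random_sar_map.values)
        diff = diff_map_sar(meas, random_sar_map)
        expected = random_sar_map.values / random_sar_map.in_mask_max()
        np.testing.assert_allclose(diff, expected)
        assert diff.max() == pytest.approx(1.0)

    def test_b1_identical_zero_both_conventions(self):
        b1 = make_map([[1.0, 2.0]], modality=Modality.B1)
        for conv in ("squared", "linear"):
            np.testing.assert_allclose(diff_map_b1(b1, b1, conv), 0.0)

    def test_b1_squared_hand_arithmetic(self):
        sim = make_map([[3.0, 4.0]], modality=Modality.B1)
        meas = make_map([[3.0, 5.0]], modality=Modality.B1)
        np.testing.assert_allclose(
            diff_map_b1(meas, sim, "squared"), [[0.0, 9.0 / 16.0]]
        )

    def test_b1_linear_hand_arithmetic(self):
        sim = make_map([[3.0, 4.0]], modality=Modality.B1)
        meas = make_map([[3.0, 5.0]], modality=Modality.B1)
        np.testing.assert_allclose(diff_map_b1(meas, sim, "linear"), [[0.0, 0.25]])

    def test_antisymmetry_of_numerator(self, rng):
        sim = make_map(rng.uniform(0.1, 2.0, size=(8, 8)))
        meas = make_map(rng.uniform(0.1, 2.0, size=(8, 8)))
        d1 = diff_map_sar(meas, sim)
        # swapping meas/sim negates the numerator (reference max changes)
        d2 = diff_map_sar(sim, meas)
        np.testing.assert_allclose(
            d1 * sim.in_mask_max(), -d2 * meas.in_mask_max(), rtol=1e-12
        )

    def test_grid_mismatch_instructs_resample(self):
        sim = make_map(np.ones((4, 4)))
        meas = make_map(np.ones((8, 8)))
        with pytest.raises(ValueError, match="[Rr]esample"):
            diff_map_sar(meas, sim)

    def test_zero_sim_max_rejected(self):
        sim = make_map(np.zeros((4, 4)))
        meas = make_map(np.ones((4, 4)))
        with pytest.raises(ValueError, match="> 0"):
            diff_map_sar(meas, sim)

    def test_power_normalization_mismatch_rejected(self):
        sim = make_map(np.ones((4, 4)), norm_power=8.0)
        meas = make_map(np.ones((4, 4)), norm_power=1.0)
        with pytest.raises(ValueError, match="power"):
            diff_map_sar(meas, sim)

    def test_diff_nan_outside_intersection(self):
        sim = make_map([[1.0, 2.0], [3.0, 4.0]])
        meas = make_map([[1.0, np.nan], [3.0, 4.0]])
        diff = diff_map_sar(meas, sim)
        assert np.isnan(diff[0, 1])
        assert np.isfinite(diff).sum() == 3


class TestModelingUncertainty:
    def test_all_zero_grid(self):
        assert modeling_uncertainty(np.zeros((10, 10))) == 0.0

    def test_rank_ladder(self):
        # 1000 evenly spaced values: the 0.999 nearest-rank is the 999th
        diffs = 0.001 * np.arange(1, 1001)
        assert modeling_uncertainty(diffs) == pytest.approx(0.999)

    def test_matches_sort_oracle_random_grids(self, rng):
        for _ in range(20):
            n = rng.integers(100, 10_000)
            vals = rng.normal(0, 1, size=n)
            q = rng.uniform(0.5, 0.9999)
            assert modeling_uncertainty(vals, q, clamp=False) == sort_oracle(vals, q)

    def test_normal_analytic_quantile(self):
        # 0.999 quantile of N(0, 0.1) is 0.1 * 3.0902
        sigma, n = 0.1, 100_000
        z = stats.norm.ppf(0.999)
        results = [
            modeling_uncertainty(np.random.default_rng(s).normal(0, sigma, n))
            for s in range(20)
        ]
        assert np.mean(results) == pytest.approx(sigma * z, rel=0.02)

    def test_monotone_under_constant_shift(self, rng):
        vals = rng.normal(0, 0.2, size=5000)
        base = modeling_uncertainty(vals, clamp=False)
        shifted = modeling_uncertainty(vals + 0.05, clamp=False)
        assert shifted == pytest.approx(base + 0.05, abs=1e-12)

    def test_negative_quantile_clamped(self):
        vals = -np.ones(100)
        assert modeling_uncertainty(vals) == 0.0
        assert modeling_uncertainty(vals, clamp=False) == -1.0

    def test_nan_ignored(self):
        vals = np.array([0.1, np.nan, 0.3])
        assert modeling_uncertainty(vals, 0.9) == 0.3

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            modeling_uncertainty(np.full(5, np.nan))

    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError, match="quantile"):
            nearest_rank_quantile(np.arange(10.0), 1.0)

    def test_pooling_sequence(self):
        a, b = np.zeros(50), np.full(50, 0.2)
        assert modeling_uncertainty([a, b], 0.9) == 0.2


def _cu(u, modality=Modality.B1, shim="s"):
    return ComparisonUncertainty(
        shim_name=shim, modality=modality, uncertainty=u, raw_quantile=u
    )


class TestWorstCase:
    def test_body_array_values(self):
        # 0.639 from B1 and 0.766 from SAR in the same mode -> 0.766 (77%)
        results = [
            _cu(0.639, Modality.B1, "alternating_0_180"),
            _cu(0.766, Modality.SAR, "alternating_0_180"),
            _cu(0.3, Modality.B1, "left"),
            _cu(0.5, Modality.SAR, "left"),
        ]
        res = worst_case_uncertainty(results, tier=3)
        assert res.final == pytest.approx(0.766)
        assert round(res.final * 100) == 77
        assert res.worst.modality is Modality.SAR
        assert res.worst.shim_name == "alternating_0_180"

    def test_singleton(self):
        res = worst_case_uncertainty([_cu(0.21)])
        assert res.final == 0.21

    def test_head_array_range(self):
        # per-shim B1 uncertainties 9%..21% -> worst case 21%
        res = worst_case_uncertainty(
            [_cu(u) for u in (0.09, 0.21, 0.15, 0.12)], tier=2
        )
        assert res.final == pytest.approx(0.21)

    def test_tier3_without_sar_refused(self):
        with pytest.raises(ValueError, match="temperature"):
            worst_case_uncertainty([_cu(0.2, Modality.B1)], tier=3)

    def test_tier2_without_b1_refused(self):
        with pytest.raises(ValueError, match="B1"):
            worst_case_uncertainty([_cu(0.2, Modality.SAR)], tier=2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no comparison"):
            worst_case_uncertainty([])


class TestShimComparison:
    def test_uncertainty_counts_voxels(self, rng):
        sim = make_map(rng.uniform(0.5, 2.0, size=(10, 10)))
        meas = make_map(sim.values * 1.1)
        comp = ShimComparison("s", Modality.SAR, sim=sim, meas=meas)
        res = comp.uncertainty()
        assert res.n_voxels == 100
        assert res.uncertainty > 0


class TestAlignChannelPhases:
    def _fields(self, n_channels=3, shape=(24, 24), seed=3):
        from rfsafe.synthetic import synth_channel_fields

        return synth_channel_fields(
            shape=shape, n_channels=n_channels, seed=seed
        )

    def test_identical_phases_zero_offset(self):
        fields = self._fields()
        meas = [np.rad2deg(np.angle(f)) for f in fields.b1]
        offsets = align_channel_phases(meas, fields.b1, mask=fields.mask, step_deg=5.0)
        np.testing.assert_allclose(offsets % 360.0, 0.0)

    def test_known_offsets_recovered(self):
        fields = self._fields()
        true = np.array([40.0, 125.0, 250.0])
        meas = [
            np.rad2deg(np.angle(f)) + off for f, off in zip(fields.b1, true)
        ]
        offsets = align_channel_phases(meas, fields.b1, mask=fields.mask, step_deg=5.0)
        np.testing.assert_allclose(offsets, true, atol=5.0)

    def test_modular_wrap(self):
        fields = self._fields(n_channels=1)
        meas = [np.rad2deg(np.angle(fields.b1[0])) + 370.0]
        offsets = align_channel_phases(meas, fields.b1, mask=fields.mask, step_deg=5.0)
        assert offsets[0] == pytest.approx(10.0, abs=5.0)

    def test_channel_count_mismatch(self):
        fields = self._fields(n_channels=2)
        with pytest.raises(ValueError, match="channel count"):
            align_channel_phases([np.zeros((24, 24))], fields.b1)


class TestPipelineClosure:
    def test_known_scale_error_recovered(self, rng):
        # diff + quantile on a purely scaled "measurement" must equal
        # s * q0.999(sim / max) computed directly
        from rfsafe.synthetic import NAMED_SHIMS, combine_shim, perturb_measurement, synth_channel_fields

        fields = synth_channel_fields(shape=(40, 40), seed=11)
        _, sar = combine_shim(fields, NAMED_SHIMS["zero_phase"], [1.0] * 8)
        s = 0.15
        meas = perturb_measurement(sar, scale_error=s, seed=12)
        got = modeling_uncertainty(diff_map_sar(meas, sar))
        expected = s * sort_oracle(sar.in_mask() / sar.in_mask_max(), 0.999)
        assert got == pytest.approx(expected, rel=1e-9)
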