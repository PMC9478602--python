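"""DVH engine vs exhaustive-loop oracles, quantile semantics, HI/CI."""

import numpy as np
import pytest

import bolusqa as bq
from bolusqa.dvh import DEFAULT_OAR_CONSTRAINTS, OARConstraintSet, oar_report
from bolusqa.errors import (
    AlignmentError,
    ConfigurationError,
    EmptyStructureError,
    ValidationError,
)
from bolusqa.grids import DoseGrid, StructureMask
from bolusqa.tables import hi_from_quantiles


def grid_pair(values, mask):
    values = np.asarray(values, dtype=float)
    return DoseGrid(values), StructureMask(np.asarray(mask, dtype=bool), name="s")


def brute_force_metrics(samples, qs, xs):
    """Order-statistic oracle computed by explicit sorting and counting."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    out = {"mean": s.sum() / n, "min": s[0], "max": s[-1]}
    for q in qs:
        # Dq: value at cumulative fraction (100-q)% of the sorted samples,
        # linear interpolation between order statistics
        pos = (100.0 - q) / 100.0 * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        out[f"D{q}"] = s[lo] + (pos - lo) * (s[hi] - s[lo])
    for x in xs:
        out[f"V{x}"] = 100.0 * np.sum(s >= x) / n
    return out


class TestComputeDVH:
    def test_uniform_dose_collapses_all_statistics(self):
        dose, mask = grid_pair(np.full((4, 4, 4), 5000.0), np.ones((4, 4, 4)))
        dvh = bq.compute_dvh(dose, mask)
        assert dvh.d_min == dvh.d_max == dvh.d_mean == 5000.0
        for q in (2, 50, 95, 98, 100):
            assert bq.dose_at_volume(dvh, q) == 5000.0

    def test_two_voxel_mean(self):
        values = np.zeros((2, 1, 1))
        values[0, 0, 0], values[1, 0, 0] = 100.0, 300.0
        dose, mask = grid_pair(values, np.ones((2, 1, 1)))
        assert bq.compute_dvh(dose, mask).d_mean == 200.0

    def test_mean_equals_bruteforce_on_phantom_ptv(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        dvh = bq.compute_dvh(dose_with_bolus, masks["PTV"])
        total, count = 0.0, 0
        idx = np.argwhere(masks["PTV"].mask)
        for i, j, k in idx:
            total += dose_with_bolus.values[i, j, k]
            count += 1
        assert dvh.d_mean == pytest.approx(total / count, abs=1e-9)

    def test_empty_mask_and_misalignment_raise(self):
        dose, _ = grid_pair(np.zeros((3, 3, 3)), np.ones((3, 3, 3)))
        with pytest.raises(EmptyStructureError):
            bq.compute_dvh(dose, StructureMask(np.zeros((3, 3, 3), dtype=bool)))
        shifted = StructureMask(np.ones((3, 3, 3), dtype=bool), origin=(9, 9, 9))
        with pytest.raises(AlignmentError):
            bq.compute_dvh(dose, shifted)


class TestQuantiles:
    def test_four_sample_interpolation(self):
        values = np.array([100.0, 200.0, 300.0, 400.0]).reshape(4, 1, 1)
        dose, mask = grid_pair(values, np.ones((4, 1, 1)))
        dvh = bq.compute_dvh(dose, mask)
        assert bq.dose_at_volume(dvh, 50.0) == 250.0
        assert bq.volume_at_dose(dvh, 250.0) == 50.0
        assert bq.volume_at_dose(dvh, 0.0) == 100.0
        assert bq.dose_at_volume(dvh, 100.0) == 100.0  # D100% = Dmin

    def test_quantile_monotone_on_phantom(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        dvh = bq.compute_dvh(dose_with_bolus, masks["PTV"])
        assert (
            bq.dose_at_volume(dvh, 2.0)
            >= bq.dose_at_volume(dvh, 50.0)
            >= bq.dose_at_volume(dvh, 98.0)
        )

    def test_vx_monotone_on_lung(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        dvh = bq.compute_dvh(dose_with_bolus, masks["ipsilateral_lung"])
        v5, v20, v30 = (bq.volume_at_dose(dvh, x) for x in (500.0, 2000.0, 3000.0))
        assert v5 >= v20 >= v30

    def test_out_of_range_q_raises(self):
        dose, mask = grid_pair(np.ones((2, 2, 2)), np.ones((2, 2, 2)))
        dvh = bq.compute_dvh(dose, mask)
        for q in (0.0, -5.0, 101.0):
            with pytest.raises(ValidationError):
                bq.dose_at_volume(dvh, q)

    def test_engine_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(20240917)
        for _ in range(10):
            values = rng.uniform(0, 6000, size=(10, 10, 10))
            mask = rng.random((10, 10, 10)) < 0.4
            if not mask.any():
                continue
            dose, m = grid_pair(values, mask)
            dvh = bq.compute_dvh(dose, m)
            oracle = brute_force_metrics(values[mask], qs=(2, 50, 95, 98), xs=(500, 2000))
            assert dvh.d_mean == pytest.approx(oracle["mean"], abs=1e-9)
            assert dvh.d_min == oracle["min"] and dvh.d_max == oracle["max"]
            for q in (2, 50, 95, 98):
                assert bq.dose_at_volume(dvh, q) == pytest.approx(oracle[f"D{q}"], abs=1e-9)
            for x in (500, 2000):
                assert bq.volume_at_dose(dvh, x) == pytest.approx(oracle[f"V{x}"], abs=1e-9)

    def test_inverse_consistency(self):
        """volume_at_dose(dose_at_volume(q)) returns q up to one voxel's share.

        Holds for distinct (continuous) dose samples; exact ties legitimately
        count every tied voxel.
        """
        rng = np.random.default_rng(99)
        dose, mask = grid_pair(rng.uniform(100, 6000, (12, 12, 12)), np.ones((12, 12, 12)))
        dvh = bq.compute_dvh(dose, mask)
        eps = 100.0 / dvh.dose_samples.size
        for q in (5.0, 25.0, 50.0, 75.0, 95.0):
            v = bq.volume_at_dose(dvh, bq.dose_at_volume(dvh, q))
            assert q - eps <= v <= q + eps


class TestHomogeneityConformity:
    def test_hi_from_published_quantiles(self):
        assert hi_from_quantiles(5251.0, 4977.0, 5134.0) == 0.05

    def test_hi_zero_for_uniform_dose(self):
        dose, mask = grid_pair(np.full((3, 3, 3), 4000.0), np.ones((3, 3, 3)))
        assert bq.homogeneity_index(bq.compute_dvh(dose, mask)) == 0.0

    def test_hi_nonnegative_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        values = rng.gamma(20.0, 250.0, size=(8, 8, 8))
        mask = np.ones((8, 8, 8))
        dose, m = grid_pair(values, mask)
        hi1 = bq.homogeneity_index(bq.compute_dvh(dose, m), rounded=False)
        dose2, _ = grid_pair(values * 3.7, mask)
        hi2 = bq.homogeneity_index(bq.compute_dvh(dose2, m), rounded=False)
        assert hi1 >= 0
        assert hi2 == pytest.approx(hi1, rel=1e-12)

    def test_ci_counts_covered_fraction(self):
        values = np.zeros((4, 1, 1))
        values[:2, 0, 0] = 5000.0
        dose, mask = grid_pair(values, np.ones((4, 1, 1)))
        assert bq.conformity_index(dose, mask, prescription=5000.0, iso_fraction=1.0) == 50.0
        full, fmask = grid_pair(np.full((3, 3, 3), 6000.0), np.ones((3, 3, 3)))
        assert bq.conformity_index(full, fmask, prescription=5000.0) == 100.0

    def test_ci_at_least_95_under_d95_normalization(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        ci = bq.conformity_index(dose_with_bolus, masks["PTV"], prescription=200.0, iso_fraction=1.0)
        assert ci >= 95.0

    def test_missing_prescription_raises(self):
        dose, mask = grid_pair(np.ones((2, 2, 2)), np.ones((2, 2, 2)))
        with pytest.raises(ConfigurationError):
            bq.conformity_index(dose, mask)


class TestOARReport:
    def test_row_per_requested_metric(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        rows = oar_report(dose_with_bolus, masks)
        n_requested = sum(len(v) for v in DEFAULT_OAR_CONSTRAINTS.requests.values())
        assert len(rows) == n_requested

    def test_zero_dose_report(self, phantom_default):
        ct, masks = phantom_default
        zero = DoseGrid(np.zeros(ct.shape), ct.spacing, ct.origin)
        for row in oar_report(zero, masks):
            if row["metric"].startswith("V"):
                assert row["value"] == 0.0
            if row["metric"] == "Dmean":
                assert row["value"] == 0.0

    def test_dmax_on_cord_equals_voxel_max(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        rows = oar_report(
            dose_with_bolus, masks, OARConstraintSet({"spinal_cord_PRV": ["Dmax"]})
        )
        expected = dose_with_bolus.values[masks["spinal_cord_PRV"].mask].max()
        assert rows[0]["value"] == pytest.approx(expected, abs=0.5)

    def test_missing_structure_named_in_error(self, dose_with_bolus, phantom_default):
        _, masks = phantom_default
        with pytest.raises(KeyError, match="no_such_organ"):
            oar_report(dose_with_bolus, masks, OARConstraintSet({"no_such_organ": ["Dmax"]}))
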