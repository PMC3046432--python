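"""QC rules, retention bookkeeping, Table-1 tallies, probe coverage."""

import numpy as np
import pytest

from marginspec.cohort import (
    ExclusionReason,
    SiteRecord,
    apply_retention,
    extreme_outliers,
    lymphazurin_dominant,
    make_reference_cohort,
    placement_coverage,
    tally,
)
from marginspec.spectral import WavelengthGrid, default_grid


def _flat_spectrum_with(grid, r450, r600):
    spec = np.full(len(grid), 0.15)
    spec[grid.index_of(450.0)] = r450
    spec[grid.index_of(600.0)] = r600
    return spec


class TestLymphazurinRule:
    def test_red_suppression_flags_site(self, grid):
        spec = _flat_spectrum_with(grid, 0.2, 0.1)
        assert lymphazurin_dominant(spec, grid) is True

    def test_normal_slope_retained(self, grid):
        spec = _flat_spectrum_with(grid, 0.1, 0.2)
        assert lymphazurin_dominant(spec, grid) is False

    def test_tie_retained(self, grid):
        spec = _flat_spectrum_with(grid, 0.15, 0.15)
        assert lymphazurin_dominant(spec, grid) is False

    def test_grid_not_covering_600_raises(self):
        g = WavelengthGrid(np.linspace(450, 550, 11))
        with pytest.raises(ValueError):
            lymphazurin_dominant(np.ones(11), g)


class TestExtremeOutliers:
    def test_constant_vector_has_no_outliers(self):
        assert not extreme_outliers([5.0] * 6).any()

    def test_high_outlier_flagged_with_type7_fences(self):
        """Hand computation, type-7 quartiles over [1..8, 1000]:
        Q1 = 3, Q3 = 7, IQR = 4, fences [-9, 19] -> only 1000 flagged."""
        vals = list(range(1, 9)) + [1000.0]
        q1, q3 = np.percentile(vals, [25, 75])
        mask = extreme_outliers(vals)
        assert mask.tolist() == [False] * 8 + [True]
        assert (q3 + 3 * (q3 - q1)) < 1000

    def test_symmetric_low_outlier_flagged(self):
        vals = list(range(1, 9)) + [1000.0, -1000.0]
        mask = extreme_outliers(vals)
        assert mask[-1] and mask[-2]
        assert not mask[:-2].any()

    def test_fewer_than_four_values_rejected(self):
        with pytest.raises(ValueError):
            extreme_outliers([1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def reference():
    return make_reference_cohort()


class TestReferenceBookkeeping:
    def test_input_flow_totals(self, reference):
        t = tally(reference)
        assert t.n_sites == 854
        assert t.by_top_class == {
            "normal": 715, "malignant": 48, "unidentifiable": 91
        }
        assert t.n_margins == 105 and t.n_patients == 104

    def test_stage1_retention_matches_protocol(self, reference):
        retained, t, log = apply_retention(reference, 1)
        assert t.by_top_class == {"normal": 595, "malignant": 38}
        assert t.n_margins == 101 and t.n_patients == 100
        assert len(retained) + len(log) == len(reference)

    def test_stage1_tissue_classification(self, reference):
        _, t, _ = apply_retention(reference, 1)
        expect = {"A": 324, "Mx": 112, "FA": 60, "V": 64, "FG": 24,
                  "F": 6, "FCC": 4, "FN": 1}
        for cls, n in expect.items():
            assert t.by_tissue_class[cls] == n
        assert t.by_depth_category == {
            "0 mm": 10, "0+-1 mm": 17, "1+-2 mm": 11
        }

    def test_stage2_predominant_type_restriction(self, reference):
        _, t, _ = apply_retention(reference, 2)
        assert t.by_top_class == {"normal": 408, "malignant": 32}
        assert t.n_margins == 100 and t.n_patients == 99
        assert set(t.by_tissue_class) <= {"A", "FA", "FG", "IDC", "DCIS"}

    def test_stage3_menopause_restriction(self, reference):
        _, t, _ = apply_retention(reference, 3)
        assert t.by_top_class == {"normal": 553}
        assert t.n_margins == 94
        assert t.by_menopause == {"pre": 142, "post": 411}

    def test_every_excluded_site_has_a_reason(self, reference):
        retained, _, log = apply_retention(reference, 1)
        assert all(len(v) >= 1 for v in log.values())
        retained_ids = {s.site_id for s in retained}
        assert not retained_ids & set(log)

    def test_retention_idempotent(self, reference):
        r1, t1, _ = apply_retention(reference, 2)
        r2, t2, log2 = apply_retention(r1, 2)
        assert len(r2) == len(r1) and not log2
        assert t2.by_top_class == t1.by_top_class

    def test_unknown_stage_rejected(self, reference):
        with pytest.raises(ValueError):
            apply_retention(reference, 4)

    def test_all_peri_cohort_fully_excluded_at_stage3(self):
        sites = [
            SiteRecord(f"x{i}", "p1", "m1", "normal", tissue_class="A",
                       menopause="peri")
            for i in range(5)
        ]
        retained, _, log = apply_retention(sites, 3)
        assert retained == []
        assert all(
            ExclusionReason.MENOPAUSE_UNKNOWN_STAGE3 in v for v in log.values()
        )

    def test_clean_cohort_retention_is_identity(self):
        sites = [
            SiteRecord(f"y{i}", "p1", "m1", "normal", tissue_class="FA",
                       menopause="post")
            for i in range(4)
        ]
        retained, _, log = apply_retention(sites, 1)
        assert len(retained) == 4 and not log


class TestTally:
    def test_empty_cohort_all_zero(self):
        t = tally([])
        assert t.n_sites == 0 and not t.by_top_class
        assert t.n_margins == 0 and t.n_patients == 0

    def test_subcategory_counts_sum_to_totals(self, reference):
        _, t, _ = apply_retention(reference, 1)
        assert sum(t.by_top_class.values()) == t.n_sites
        assert sum(t.by_tissue_class.values()) == t.n_sites
        assert sum(t.by_depth_category.values()) == t.by_top_class["malignant"]


class TestPlacementCoverage:
    def test_average_margin_64_holes_8_placements(self, geometry):
        n_placements, n_holes = placement_coverage((40.0, 40.0), geometry)
        assert (n_placements, n_holes) == (8, 64)

    def test_single_footprint_gives_8_holes_per_placement(self, geometry):
        n_placements, n_holes = placement_coverage((40.0, 20.0), geometry)
        assert n_holes // n_placements == 8

    def test_doubling_extent_doubles_placements(self, geometry):
        p1, h1 = placement_coverage((40.0, 40.0), geometry)
        p2, h2 = placement_coverage((80.0, 40.0), geometry)
        assert (p2, h2) == (2 * p1, 2 * h1)

    def test_too_small_extent_raises(self, geometry):
        with pytest.raises(ValueError):
            placement_coverage((10.0, 10.0), geometry)

    def test_non_multiple_extent_raises(self, geometry):
        with pytest.raises(ValueError):
            placement_coverage((41.0, 40.0), geometry)
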