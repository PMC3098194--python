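"""Positional statistics: folding, binning, occupancy null, χ² comparisons."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_occupancy, flip_cell
from plasfoci import (
    CellRecord,
    ValidationError,
    bin_half_cell,
    compare_binned,
    count_histogram,
    normalize_and_fold,
    occupancy_null_probability,
    occupancy_test,
    one_sided_fraction,
    polar_fraction,
)
from plasfoci.spatial import BinnedDistribution


@pytest.mark.parametrize(
    "length, focus, relative, folded",
    [
        (4.0, 1.0, 0.25, 0.25),
        (4.0, 3.6, 0.9, 0.1),  # pole symmetry
        (4.0, 2.0, 0.5, 0.5),  # midcell is the folding fixed point
        (2.0, 0.0, 0.0, 0.0),
    ],
)
def test_normalize_and_fold(length, focus, relative, folded):
    out = normalize_and_fold(CellRecord("c", length, (focus,)))
    assert out.relative_positions == pytest.approx((relative,))
    assert out.folded_positions == pytest.approx((folded,))


def test_focus_outside_cell_rejected():
    with pytest.raises(ValidationError, match="badcell"):
        CellRecord("badcell", 4.0, (5.0,))


class TestBinHalfCell:
    def test_one_value_per_slice(self):
        dist = bin_half_cell([0.05, 0.15, 0.25, 0.35, 0.45])
        assert dist.counts == (1, 1, 1, 1, 1)
        assert dist.fractions == pytest.approx([0.2] * 5)

    def test_boundary_goes_to_upper_bin(self):
        # half-open [a, b): a value exactly at 0.1 belongs to the second slice
        assert bin_half_cell([0.1]).counts == (0, 1, 0, 0, 0)
        # ... but the final bin is closed at midcell
        assert bin_half_cell([0.5]).counts == (0, 0, 0, 0, 1)

    def test_uniform_folding_is_flat(self):
        rng = np.random.default_rng(5)
        folded = np.minimum(u := rng.uniform(0, 1, 100_000), 1 - u)
        frac = bin_half_cell(folded).fractions
        se = math.sqrt(0.2 * 0.8 / 100_000)
        assert np.all(np.abs(frac - 0.2) < 3 * se)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_half_cell([0.6])


class TestPolarFraction:
    def test_simple_fraction(self):
        assert polar_fraction([0.05, 0.2, 0.3]) == pytest.approx(1 / 3)

    def test_empty_is_nan(self):
        assert math.isnan(polar_fraction([]))

    def test_boundary_excluded(self):
        assert polar_fraction([0.1]) == 0.0

    def test_uniform_measure(self):
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 1, 100_000)
        folded = np.minimum(u, 1 - u)
        se = math.sqrt(0.2 * 0.8 / 100_000)
        assert polar_fraction(folded, 0.1) == pytest.approx(0.2, abs=3 * se)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            polar_fraction([0.1], threshold=0.7)


class TestOccupancyNull:
    @pytest.mark.parametrize(
        "n, expected",
        [(4, 0.09375), (5, 0.234375), (6, 0.380859375), (3, 0.0), (0, 0.0)],
    )
    def test_four_quarter_values(self, n, expected):
        assert occupancy_null_probability(n, 4) == pytest.approx(expected, abs=1e-12)

    def test_trivial_single_bin(self):
        assert occupancy_null_probability(1, 1) == 1.0

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_matches_enumeration(self, k):
        for n in range(0, 11):
            assert occupancy_null_probability(n, k) == pytest.approx(
                brute_force_occupancy(n, k), abs=1e-12
            )

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_monotone_in_n_and_surjection_at_n_equals_k(self, k):
        probs = [occupancy_null_probability(n, k) for n in range(0, 40)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[k] == pytest.approx(math.factorial(k) / k**k)
        assert probs[-1] > 0.99  # -> 1 as n grows


def _uniform_stratum(n_cells, n_foci, seed):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, (n_cells, n_foci))
    return [
        CellRecord(f"c{i}", 3.0, tuple(3.0 * row)) for i, row in enumerate(pos)
    ]


class TestOccupancyTest:
    def test_all_quarters_hit(self):
        cells = [CellRecord("a", 1.0, (0.1, 0.3, 0.6, 0.9))] * 3
        res = occupancy_test(cells, n_foci=4)
        assert res.observed_fraction == 1.0
        assert res.expected_probability == pytest.approx(0.09375)

    def test_all_foci_first_quarter(self):
        cells = [CellRecord("a", 1.0, (0.01, 0.05, 0.1, 0.2))] * 3
        assert occupancy_test(cells, n_foci=4).observed_fraction == 0.0

    def test_empty_stratum_raises(self):
        with pytest.raises(ValidationError):
            occupancy_test([CellRecord("a", 1.0, (0.5,))], n_foci=4)

    def test_uniform_stratum_matches_null(self):
        # under the null the test should almost never reject; check the
        # rejection rate over seeds rather than any single draw
        p0 = 0.09375
        se = math.sqrt(p0 * (1 - p0) / 10_000)
        rejections = 0
        for seed in range(10):
            res = occupancy_test(_uniform_stratum(10_000, 4, seed), n_foci=4)
            assert res.observed_fraction == pytest.approx(p0, abs=4 * se)
            assert not res.low_expected_count
            rejections += res.p_value < 0.01
        assert rejections <= 1

    def test_low_expected_count_flag_and_binomial(self):
        cells = _uniform_stratum(20, 4, seed=4)
        res = occupancy_test(cells, n_foci=4)
        assert res.low_expected_count
        assert 0.0 <= res.binomial_p_value <= 1.0

    def test_flip_invariance(self):
        cells = _uniform_stratum(500, 5, seed=9)
        a = occupancy_test(cells, n_foci=5)
        b = occupancy_test([flip_cell(c) for c in cells], n_foci=5)
        assert a.observed_fraction == b.observed_fraction
        assert a.chi2 == pytest.approx(b.chi2)


class TestCompareBinned:
    def test_identical_distributions(self):
        d = bin_half_cell([0.05, 0.15, 0.25, 0.35, 0.45] * 10)
        chi2, df, p = compare_binned(d, d)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        edges = (0.0, 0.25, 0.5)
        a = BinnedDistribution(edges, (50, 0))
        b = BinnedDistribution(edges, (0, 50))
        chi2, df, p = compare_binned(a, b)
        assert chi2 == pytest.approx(100.0)
        assert df == 1

    def test_symmetry(self):
        a = bin_half_cell([0.05] * 5 + [0.25] * 9 + [0.45] * 3)
        b = bin_half_cell([0.05] * 7 + [0.25] * 2 + [0.45] * 8)
        assert compare_binned(a, b)[0] == pytest.approx(compare_binned(b, a)[0])

    def test_bin_subset_selects_central_slices(self):
        a = BinnedDistribution((0.0, 0.1, 0.2, 0.3, 0.4, 0.5), (90, 10, 10, 10, 10))
        b = BinnedDistribution((0.0, 0.1, 0.2, 0.3, 0.4, 0.5), (10, 10, 10, 10, 10))
        full = compare_binned(a, b)
        central = compare_binned(a, b, bin_subset=(2, 5))
        assert full[2] < 0.01  # polar excess dominates the full comparison
        assert central[0] == pytest.approx(0.0)  # central slices identical

    def test_mismatched_edges_rejected(self):
        a = bin_half_cell([0.1], n_bins=5)
        b = bin_half_cell([0.1], n_bins=4)
        with pytest.raises(ValidationError):
            compare_binned(a, b)

    def test_null_calibration_rejection_rate(self):
        # two samples from the same uniform model: p should rarely be small
        rng_rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            u1 = rng.uniform(0, 1, 400)
            u2 = rng.uniform(0, 1, 400)
            d1 = bin_half_cell(np.minimum(u1, 1 - u1))
            d2 = bin_half_cell(np.minimum(u2, 1 - u2))
            if compare_binned(d1, d2)[2] < 0.05:
                rng_rejections += 1
        assert rng_rejections / n_rep < 0.12


class TestCountHistogram:
    def test_small_population(self):
        cells = [
            CellRecord("a", 1.0, ()),
            CellRecord("b", 1.0, (0.1, 0.2)),
            CellRecord("c", 1.0, (0.3, 0.4)),
            CellRecord("d", 1.0, (0.1, 0.2, 0.3, 0.4)),
        ]
        props, mean = count_histogram(cells)
        assert props == {0: 0.25, 2: 0.5, 4: 0.25}
        assert mean == 2.0

    def test_all_empty(self):
        props, mean = count_histogram([CellRecord("a", 1.0, ())] * 3)
        assert props == {0: 1.0}
        assert mean == 0.0

    def test_empty_population_raises(self):
        with pytest.raises(ValidationError):
            count_histogram([])


class TestOneSided:
    def test_both_foci_same_side(self):
        cells = [CellRecord("a", 1.0, (0.1, 0.2))]
        assert one_sided_fraction(cells) == 1.0

    def test_opposite_poles_not_one_sided(self):
        cells = [CellRecord("a", 1.0, (0.1, 0.9))]
        assert one_sided_fraction(cells) == 0.0

    def test_central_focus_disqualifies(self):
        cells = [CellRecord("a", 1.0, (0.1, 0.45))]
        assert one_sided_fraction(cells) == 0.0

    def test_plasmid_free_cells_excluded_from_denominator(self):
        cells = [CellRecord("a", 1.0, (0.1, 0.2)), CellRecord("b", 1.0, ())]
        assert one_sided_fraction(cells) == 1.0

    def test_no_bearing_cells_raises(self):
        with pytest.raises(ValidationError):
            one_sided_fraction([CellRecord("a", 1.0, ())])

    def test_uniform_six_foci_rare(self):
        rng = np.random.default_rng(21)
        cells = [
            CellRecord(f"c{i}", 1.0, tuple(rng.uniform(0, 1, 6)))
            for i in range(10_000)
        ]
        assert one_sided_fraction(cells) < 0.01

    def test_flip_invariance(self):
        rng = np.random.default_rng(22)
        cells = [
            CellRecord(f"c{i}", 1.0, tuple(rng.uniform(0, 1, 3)))
            for i in range(500)
        ]
        flipped = [flip_cell(c) for c in cells]
        assert one_sided_fraction(cells) == one_sided_fraction(flipped)
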