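import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracershift import (
    Box3D,
    SizeBinning,
    SizePrior,
    Spacing,
    allocate_quotas,
    bin_of,
    default_binning,
    size_histogram,
    source_prior,
    subject_budget,
    update_histogram,
    update_mu,
)
from tracershift.priors import EmptyHistogramError


def cube_of_volume_cc(v_cc: float, spacing: Spacing) -> Box3D:
    edge = (v_cc * 1000.0 / spacing.voxel_volume_mm3) ** (1 / 3)
    return Box3D(0, 0, 0, edge, edge, edge)


class TestSizeBinning:
    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            SizeBinning((1.0, 1.0, 2.0))

    def test_default_binning_has_ten_bins_and_open_top(self, bins10):
        assert bins10.n_bins == 10
        assert bins10.edges[0] == pytest.approx(0.08)
        assert bins10.edges[-2] == pytest.approx(150.0)
        assert math.isinf(bins10.edges[-1])

    def test_volume_on_interior_edge_goes_to_higher_bin(self):
        binning = SizeBinning((0.0, 1.0, 2.0, 4.0, math.inf))
        assert binning.bin_of_volume(1.0) == 1
        assert binning.bin_of_volume(0.999) == 0

    def test_single_bin_always_bin_zero(self):
        binning = SizeBinning((0.0, math.inf))
        assert binning.bin_of_volume(1e-6) == 0
        assert binning.bin_of_volume(1e6) == 0

    def test_linear_scan_oracle(self):
        edges = (0.0, 1.0, 2.0, 4.0, math.inf)
        binning = SizeBinning(edges)
        assert binning.bin_of_volume(3.5) == 2  # third bin, [2, 4)
        for v in np.linspace(0.01, 20, 97):
            expected = max(i for i in range(4) if edges[i] <= v)
            assert binning.bin_of_volume(float(v)) == expected

    def test_out_of_range_volume_raises(self, bins10):
        with pytest.raises(ValueError):
            bins10.bin_of_volume(0.01)

    def test_bin_of_box(self, unit_spacing):
        binning = SizeBinning((0.0, 1.0, 2.0, 4.0, math.inf))
        assert bin_of(cube_of_volume_cc(3.5, unit_spacing), unit_spacing, binning) == 2


class TestSizeHistogram:
    def test_all_in_one_bin_is_one_hot(self, unit_spacing):
        binning = SizeBinning((0.0, 1.0, math.inf))
        boxes = [cube_of_volume_cc(0.5, unit_spacing)] * 4
        assert np.allclose(size_histogram(boxes, unit_spacing, binning), [1.0, 0.0])

    def test_balanced_two_bins(self, unit_spacing):
        binning = SizeBinning((0.0, 1.0, math.inf))
        boxes = [cube_of_volume_cc(v, unit_spacing) for v in (0.2, 0.4, 2.0, 3.0)]
        assert np.allclose(size_histogram(boxes, unit_spacing, binning), [0.5, 0.5])

    def test_counting_oracle(self, unit_spacing):
        binning = SizeBinning((0.0, 1.0, 3.0, math.inf))
        vols = [0.5, 0.7, 1.5, 2.0, 2.5, 5.0, 9.0]
        boxes = [cube_of_volume_cc(v, unit_spacing) for v in vols]
        h = size_histogram(boxes, unit_spacing, binning)
        counts = np.zeros(3)
        for b in boxes:
            counts[bin_of(b, unit_spacing, binning)] += 1
        assert np.allclose(h, counts / counts.sum())
        assert h.sum() == pytest.approx(1.0)

    def test_empty_input_raises(self, unit_spacing, bins10):
        with pytest.raises(EmptyHistogramError):
            size_histogram([], unit_spacing, bins10)


def make_prior(mu=5.0, h=(0.5, 0.5), alpha_mu=0.9, alpha_h=0.9):
    return SizePrior(mu=mu, h=h, alpha_mu=alpha_mu, alpha_h=alpha_h)


class TestUpdateMu:
    def test_fixed_point(self):
        prior = make_prior(mu=4.0)
        assert update_mu(prior, [4, 4, 4]).mu == pytest.approx(4.0)

    def test_hand_evaluated_update(self):
        prior = make_prior(mu=10.0, alpha_mu=0.9)
        assert update_mu(prior, [20, 20]).mu == pytest.approx(19.0)

    def test_small_momentum_limit_keeps_old_value(self):
        prior = make_prior(mu=10.0, alpha_mu=1e-9)
        assert update_mu(prior, [100]).mu == pytest.approx(10.0, abs=1e-5)

    def test_empty_counts_raise(self):
        with pytest.raises(ValueError):
            update_mu(make_prior(), [])

    @given(
        st.floats(0.0, 50.0),
        st.lists(st.integers(0, 40), min_size=1, max_size=10),
        st.floats(0.01, 0.99),
    )
    def test_update_is_convex_combination(self, mu, counts, alpha):
        prior = make_prior(mu=mu, alpha_mu=alpha)
        new = update_mu(prior, counts).mu
        lo, hi = sorted((mu, float(np.mean(counts))))
        assert lo - 1e-9 <= new <= hi + 1e-9

    def test_repeated_updates_converge_to_count_mean(self):
        prior = make_prior(mu=0.0, alpha_mu=0.5)
        for _ in range(40):
            prior = update_mu(prior, [3, 5, 7])
        assert prior.mu == pytest.approx(5.0, abs=1e-9)


class TestSubjectBudget:
    def test_full_lambda_gives_mu(self):
        assert subject_budget(make_prior(mu=5.0), 1.0) == 5

    def test_fractional_budget_rounds_up(self):
        # ceiling keeps at least one admission slot whenever lambda*mu > 0
        assert subject_budget(make_prior(mu=5.0), 0.5) == 3
        assert subject_budget(make_prior(mu=3.0), 0.1) == 1

    def test_zero_mu_gives_zero_budget(self):
        assert subject_budget(make_prior(mu=0.0), 0.5) == 0

    def test_invalid_lambda_raises(self):
        for lam in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                subject_budget(make_prior(), lam)


class TestUpdateHistogram:
    def test_fixed_point(self):
        prior = make_prior(h=(0.3, 0.7))
        new = update_histogram(prior, [0.3, 0.7])
        assert np.allclose(new.h, [0.3, 0.7])

    def test_hand_evaluated_update(self):
        prior = make_prior(h=(0.5, 0.5), alpha_h=0.9)
        new = update_histogram(prior, [1.0, 0.0])
        assert np.allclose(new.h, [0.95, 0.05])

    def test_small_momentum_limit(self):
        prior = make_prior(h=(0.5, 0.5), alpha_h=1e-9)
        new = update_histogram(prior, [1.0, 0.0])
        assert np.allclose(new.h, [0.5, 0.5], atol=1e-6)

    def test_wrong_length_or_negative_raises(self):
        prior = make_prior(h=(0.5, 0.5))
        with pytest.raises(ValueError):
            update_histogram(prior, [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            update_histogram(prior, [1.5, -0.5])

    def test_result_remains_normalized(self):
        prior = make_prior(h=(0.2, 0.3, 0.5), alpha_h=0.9)
        new = update_histogram(prior, [0.0, 0.0, 1.0])
        assert sum(new.h) == pytest.approx(1.0)

    def test_geometric_convergence_to_target(self):
        prior = make_prior(h=(1.0, 0.0), alpha_h=0.3)
        target = np.array([0.25, 0.75])
        gaps = []
        for _ in range(15):
            prior = update_histogram(prior, target)
            gaps.append(np.abs(prior.h_array - target).sum())
        ratios = [b / a for a, b in zip(gaps, gaps[1:]) if a > 1e-12]
        assert all(r == pytest.approx(0.7, abs=1e-6) for r in ratios)


class TestAllocateQuotas:
    def test_zero_budget_gives_all_zeros(self):
        assert np.array_equal(allocate_quotas([0.5, 0.5], 0), [0, 0])

    def test_uniform_split(self):
        assert np.array_equal(allocate_quotas([0.5, 0.5], 4), [2, 2])

    def test_hand_largest_remainder(self):
        # fractional quotas [3.3, 1.8, 0.9]; floors [3, 1, 0]; remainders
        # [.3, .8, .9] give the two leftover slots to bins 3 then 2
        assert np.array_equal(allocate_quotas([0.55, 0.30, 0.15], 6), [3, 2, 1])

    def test_tie_break_prefers_smaller_bin(self):
        # remainders are equal; the single leftover slot goes to bin 0
        assert np.array_equal(allocate_quotas([0.25, 0.25, 0.25, 0.25], 2), [1, 1, 0, 0])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
        st.integers(0, 30),
    )
    def test_apportionment_properties(self, raw, n_allow):
        h = np.asarray(raw) / np.sum(raw)
        q = allocate_quotas(h, n_allow)
        assert q.sum() == n_allow
        assert np.all(np.abs(q - h * n_allow) < 1.0)


def test_source_prior_initialization(unit_spacing):
    binning = SizeBinning((0.0, 1.0, math.inf))
    subjects = [
        [cube_of_volume_cc(0.5, unit_spacing)] * 2,
        [cube_of_volume_cc(2.0, unit_spacing)],
        [],
    ]
    prior = source_prior(subjects, unit_spacing, binning)
    assert prior.mu == pytest.approx(1.0)
    assert np.allclose(prior.h, [2 / 3, 1 / 3])
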