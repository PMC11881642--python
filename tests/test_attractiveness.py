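import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seedlink as sl


@pytest.fixture()
def source(default_community):
    return sl.Patch.from_community(default_community)


class TestGeneralAttractiveness:
    def test_empty_patch_attracts_nobody(self, default_matrix):
        patch = sl.Patch([], np.array([]))
        assert np.all(sl.general_attractiveness(patch, default_matrix) == 0)

    def test_single_plant_patch(self, default_community, default_matrix):
        patch = sl.Patch([default_community.plant_ids[3]], default_community.plant_abundances[[3]])
        expected = default_community.plant_abundances[3] * default_matrix.p_prime[3, :]
        np.testing.assert_allclose(sl.general_attractiveness(patch, default_matrix), expected)

    def test_three_plant_patch_equals_hand_sum(self, default_community, default_matrix):
        idx = [0, 7, 20]
        ids = [default_community.plant_ids[i] for i in idx]
        b = default_community.plant_abundances[idx]
        patch = sl.Patch(ids, b)
        # spreadsheet-style accumulation, one plant at a time
        expected = np.zeros(default_matrix.n_birds)
        for k, i in enumerate(idx):
            expected = expected + b[k] * default_matrix.p_prime[i, :]
        np.testing.assert_allclose(sl.general_attractiveness(patch, default_matrix), expected)

    def test_unknown_plant_rejected(self, default_matrix):
        with pytest.raises(ValueError):
            sl.general_attractiveness(sl.Patch(["nope"], np.array([1.0])), default_matrix)


class TestRelativeAttractiveness:
    def test_identical_patches_give_half(self, default_matrix, source):
        a = sl.general_attractiveness(source, default_matrix)
        np.testing.assert_allclose(sl.relative_attractiveness(a, a), 0.5)

    def test_empty_target_gives_zero(self, default_matrix, source):
        a_s = sl.general_attractiveness(source, default_matrix)
        a_t = sl.general_attractiveness(sl.Patch([], np.array([])), default_matrix)
        assert np.all(sl.relative_attractiveness(a_t, a_s) == 0)

    def test_direct_ratio(self):
        out = sl.relative_attractiveness(np.array([1.0]), np.array([3.0]))
        assert out[0] == pytest.approx(0.25)

    def test_bird_with_no_resources_anywhere(self):
        out = sl.relative_attractiveness(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(out, [0.0, 0.5])

    def test_monotone_under_adding_species(self, default_community, default_matrix, source):
        patch5 = sl.sample_target_patch(default_community, 5, seed=1)
        extra = next(
            pid for pid in default_community.plant_ids if pid not in patch5.plant_ids
        )
        idx = default_community.plant_ids.index(extra)
        patch6 = sl.Patch(
            patch5.plant_ids + [extra],
            np.append(patch5.abundances, default_community.plant_abundances[idx]),
        )
        a_s = sl.general_attractiveness(source, default_matrix)
        ra5 = sl.relative_attractiveness(sl.general_attractiveness(patch5, default_matrix), a_s)
        ra6 = sl.relative_attractiveness(sl.general_attractiveness(patch6, default_matrix), a_s)
        assert np.all(ra6 >= ra5)

    @given(richness=st.integers(min_value=0, max_value=50))
    def test_subset_target_bounded_by_half(self, default_community, default_matrix, richness):
        patch = sl.sample_target_patch(default_community, richness, seed=richness)
        a_s = sl.general_attractiveness(
            sl.Patch.from_community(default_community), default_matrix
        )
        ra = sl.relative_attractiveness(sl.general_attractiveness(patch, default_matrix), a_s)
        assert np.all(ra >= 0)
        assert np.all(ra <= 0.5 + 1e-12)


class TestAttractivenessWithoutMatching:
    def test_identical_across_birds(self, default_community):
        patch = sl.sample_target_patch(default_community, 10, seed=2)
        a = sl.attractiveness_without_matching(patch, default_community.n_birds)
        assert np.var(a) == 0.0
        assert a[0] == pytest.approx(patch.abundances.sum())

    def test_empty_patch_zero(self):
        assert np.all(sl.attractiveness_without_matching(sl.Patch([], np.array([])), 6) == 0)

    def test_linearity_in_total_abundance(self, default_community):
        full = sl.Patch.from_community(default_community)
        half = sl.Patch(full.plant_ids, full.abundances / 2.0)
        a_full = sl.attractiveness_without_matching(full, 3)
        a_half = sl.attractiveness_without_matching(half, 3)
        assert a_full[0] / a_half[0] == pytest.approx(2.0)


class TestEffectiveResourceDiversity:
    def test_equal_abundances_give_richness(self):
        patch = sl.Patch([f"p{i}" for i in range(5)], np.full(5, 9.0))
        assert sl.effective_resource_diversity(patch) == pytest.approx(5.0)

    def test_monoculture_gives_one(self):
        assert sl.effective_resource_diversity(sl.Patch(["p"], np.array([42.0]))) == pytest.approx(1.0)

    def test_hand_computed_entropy(self):
        patch = sl.Patch(["a", "b", "c"], np.array([70.0, 20.0, 10.0]))
        # exp(0.80181...) evaluated by hand
        assert sl.effective_resource_diversity(patch) == pytest.approx(2.2296, abs=1e-4)

    def test_empty_patch_zero(self):
        assert sl.effective_resource_diversity(sl.Patch([], np.array([]))) == 0.0

    def test_full_community_bounds(self, default_community):
        erd = sl.effective_resource_diversity(sl.Patch.from_community(default_community))
        assert 1.0 <= erd <= default_community.n_plants


class TestSampleTargetPatch:
    def test_richness_zero_is_empty(self, default_community):
        assert sl.sample_target_patch(default_community, 0, seed=1).richness == 0

    def test_full_richness_is_whole_community(self, default_community, default_matrix):
        patch = sl.sample_target_patch(default_community, 50, seed=1)
        assert sorted(patch.plant_ids) == sorted(default_community.plant_ids)
        a_s = sl.general_attractiveness(sl.Patch.from_community(default_community), default_matrix)
        a_t = sl.general_attractiveness(patch, default_matrix)
        np.testing.assert_allclose(sl.relative_attractiveness(a_t, a_s), 0.5)

    def test_out_of_range_rejected(self, default_community):
        with pytest.raises(ValueError):
            sl.sample_target_patch(default_community, 51, seed=1)
        with pytest.raises(ValueError):
            sl.sample_target_patch(default_community, -1, seed=1)

    def test_members_keep_community_abundances(self, default_community):
        patch = sl.sample_target_patch(default_community, 10, seed=3)
        for pid, ab in zip(patch.plant_ids, patch.abundances):
            i = default_community.plant_ids.index(pid)
            assert ab == default_community.plant_abundances[i]

    def test_uniform_inclusion_frequencies(self, default_community):
        n_samples, richness = 1000, 10
        counts = np.zeros(default_community.n_plants)
        for k in range(n_samples):
            patch = sl.sample_target_patch(default_community, richness, seed=10_000 + k)
            for pid in patch.plant_ids:
                counts[default_community.plant_ids.index(pid)] += 1
        p = richness / default_community.n_plants
        se = np.sqrt(p * (1 - p) / n_samples)
        # allow a small slack beyond 3 SE for the 50 simultaneous checks
        assert np.all(np.abs(counts / n_samples - p) <= 4 * se)
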