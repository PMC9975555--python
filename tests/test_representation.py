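"""Representational-similarity machinery: Pearson oracle agreement, pairing
cases, profiles, embeddings and filter export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blurlab.representation import (CorrelationProfile, build_pairs, embed_2d,
                                    export_first_layer_filters,
                                    paired_correlation_profile,
                                    pairwise_pearson, sb_profiles)


class TestPearson:
    def test_matches_scipy_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((50, 10))
        b = rng.standard_normal((50, 10))
        r, valid = pairwise_pearson(a, b)
        assert valid.all()
        for i in range(50):
            expect = stats.pearsonr(a[i], b[i]).statistic
            assert abs(r[i] - expect) < 1e-10

    def test_perfect_linear_relation(self):
        r, _ = pairwise_pearson(np.array([[1., 2., 3., 4.]]),
                                np.array([[2., 4., 6., 8.]]))
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_negative_case(self):
        # r([1,2,3], [3,1,2]) = -0.5 by direct formula
        r, _ = pairwise_pearson(np.array([[1., 2., 3.]]),
                                np.array([[3., 1., 2.]]))
        assert r[0] == pytest.approx(-0.5, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((20, 8)), rng.standard_normal((20, 8))
        np.testing.assert_allclose(pairwise_pearson(a, b)[0],
                                   pairwise_pearson(b, a)[0], atol=1e-14)

    def test_zero_variance_flagged_not_zeroed(self):
        a = np.array([[1., 1., 1.], [1., 2., 3.]])
        b = np.array([[1., 2., 3.], [1., 2., 3.]])
        r, valid = pairwise_pearson(a, b)
        assert not valid[0] and valid[1]


class TestPairing:
    def test_cases_partition_all_pairs(self):
        labels = np.array([0, 0, 1, 1, 2])
        same = build_pairs(labels, "same_image")
        sc = build_pairs(labels, "same_class_different_image", rng=0)
        dc = build_pairs(labels, "different_class", rng=0)
        assert len(same) == 5
        assert len(sc) == 4   # two ordered pairs within each 2-class group
        assert len(dc) == 5 * 4 - 4
        assert np.array_equal(same[:, 0], same[:, 1])
        for i, j in sc:
            assert i != j and labels[i] == labels[j]
        for i, j in dc:
            assert labels[i] != labels[j]

    def test_budget_subsampling_is_seeded(self):
        labels = np.repeat(np.arange(4), 10)
        a = build_pairs(labels, "different_class", rng=5, budget=100)
        b = build_pairs(labels, "different_class", rng=5, budget=100)
        assert len(a) == 100
        assert np.array_equal(a, b)

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            build_pairs(np.array([0, 1]), "siblings")


class TestProfiles:
    def make_acts(self, n=6, units=12, seed=0):
        rng = np.random.default_rng(seed)
        return {"conv1": rng.standard_normal((n, units)),
                "out": rng.standard_normal((n, 4))}

    def test_identical_sets_give_r_one(self):
        acts = self.make_acts()
        pairs = build_pairs(np.zeros(6, dtype=int), "same_image")
        prof = paired_correlation_profile(acts, acts, pairs, "same_image")
        for layer in prof.layers:
            assert prof.mean_r[layer] == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_capture_points_rejected(self):
        acts = self.make_acts()
        with pytest.raises(ValueError):
            paired_correlation_profile(acts, {"conv1": acts["conv1"]},
                                       np.array([[0, 0]]), "same_image")

    def test_csv_round_trip_lossless(self, tmp_path):
        acts_a, acts_b = self.make_acts(seed=2), self.make_acts(seed=3)
        pairs = build_pairs(np.array([0, 0, 1, 1, 2, 2]), "different_class",
                            rng=0)
        prof = paired_correlation_profile(acts_a, acts_b, pairs,
                                          "different_class", "a_vs_b")
        p = tmp_path / "prof.csv"
        prof.to_csv(p)
        back = CorrelationProfile.from_csv(p)
        assert back.mean_r == prof.mean_r
        assert back.n_pairs == prof.n_pairs

    def test_sb_same_image_sigma_zero_is_identity(self, tiny_dataset,
                                                  untrained_tiny_model):
        ds = tiny_dataset
        profs = sb_profiles(untrained_tiny_model, ds.test_images[:12],
                            ds.test_labels[:12], sigma=0.0, budget=50, seed=0)
        same = profs["same_image"]
        for layer in same.layers:
            assert same.mean_r[layer] == pytest.approx(1.0, abs=1e-9)

    def test_per_unit_axis_alternative(self):
        # the per-unit-across-pairs reading: one r per unit, oracle-checked
        rng = np.random.default_rng(7)
        acts_a = {"l": rng.standard_normal((20, 5))}
        acts_b = {"l": rng.standard_normal((20, 5))}
        pairs = build_pairs(np.zeros(20, dtype=int), "same_image")
        prof = paired_correlation_profile(acts_a, acts_b, pairs, "same_image",
                                          axis="pairs")
        assert prof.n_pairs["l"] == 5  # one correlation per unit
        expect = np.mean([stats.pearsonr(acts_a["l"][:, u],
                                         acts_b["l"][:, u]).statistic
                          for u in range(5)])
        assert prof.mean_r["l"] == pytest.approx(expect, abs=1e-12)

    def test_hl_identical_conditions_give_r_one(self, tiny_dataset,
                                                untrained_tiny_model):
        # "low vs low": pairing a condition with itself is the identity check
        from blurlab.stimuli import lowpass

        ds = tiny_dataset
        low = lowpass(ds.test_images[:10], 4.0)
        acts = untrained_tiny_model.activations(low)
        pairs = build_pairs(ds.test_labels[:10], "same_image")
        prof = paired_correlation_profile(acts, acts, pairs, "same_image")
        for layer in prof.layers:
            assert prof.mean_r[layer] == pytest.approx(1.0, abs=1e-9)

    def test_hl_same_image_below_sb_in_conv_layers(self, tiny_dataset,
                                                   untrained_tiny_model):
        # high-pass and low-pass versions share far less structure than
        # sharp and blurred versions of the same image
        from blurlab.representation import hl_profiles, sb_profiles

        ds = tiny_dataset
        sb = sb_profiles(untrained_tiny_model, ds.test_images, ds.test_labels,
                         sigma=4.0, budget=100, seed=0)["same_image"]
        hl = hl_profiles(untrained_tiny_model, ds.test_images, ds.test_labels,
                         band=(1.0, 2.0), sigma=4.0, budget=100,
                         seed=0)["same_image"]
        assert hl.mean_r["conv1"] < sb.mean_r["conv1"]

    def test_skip_fraction_small_on_synthetic_data(self, tiny_dataset,
                                                   untrained_tiny_model):
        ds = tiny_dataset
        profs = sb_profiles(untrained_tiny_model, ds.test_images,
                            ds.test_labels, sigma=4.0, budget=200, seed=0)
        for prof in profs.values():
            assert prof.skip_fraction() < 0.01


class TestEmbedding:
    def test_output_shape_and_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((40, 16))
        a = embed_2d(x, perplexity=5, iterations=260, seed=1)
        b = embed_2d(x, perplexity=5, iterations=260, seed=1)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_points_stay_close(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((20, 8))
        x = np.concatenate([base, base])
        xy = embed_2d(x, perplexity=5, iterations=260, seed=0)
        d_dup = np.linalg.norm(xy[:20] - xy[20:], axis=1).mean()
        d_all = np.linalg.norm(xy[None, :20] - xy[:20, None], axis=2).mean()
        assert d_dup < d_all  # duplicates land nearer than average points

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(np.ones((50, 4)), perplexity=5)

    def test_too_few_points_rejected_and_warned(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            embed_2d(rng.standard_normal((5, 3)), perplexity=30)
        with pytest.warns(UserWarning):
            embed_2d(rng.standard_normal((40, 3)), perplexity=20,
                     iterations=260, seed=0)


class TestFilterExport:
    def test_grid_contains_all_filters(self, untrained_tiny_model, tmp_path):
        res = untrained_tiny_model
        grid = export_first_layer_filters(res, path=tmp_path / "f.png")
        f = res.net.layers[0].w.shape[0]
        k = res.net.layers[0].w.shape[-1]
        ncol = int(np.ceil(np.sqrt(f)))
        nrow = int(np.ceil(f / ncol))
        assert grid.shape[0] == nrow * (k + 1) + 1
        assert (tmp_path / "f.png").exists()

    def test_brightest_pixel_is_max_weight(self, untrained_tiny_model):
        res = untrained_tiny_model
        w = res.net.layers[0].w
        grid = export_first_layer_filters(res)
        # filter 0 occupies the top-left k x k tile (offset 1 for padding)
        k = w.shape[-1]
        tile = grid[1:1 + k, 1:1 + k]
        m = np.abs(w[0]).max()
        expect = 0.5 + w[0].transpose(1, 2, 0) / (2 * m)
        np.testing.assert_allclose(tile, expect, atol=1e-12)
        ij = np.unravel_index(np.argmax(tile), tile.shape)
        assert tile[ij] == pytest.approx(0.5 + w[0].max() / (2 * m))

    def test_zero_filter_renders_mid_gray(self, untrained_tiny_model):
        res = untrained_tiny_model
        res.net.layers[0].w[1] = 0.0
        grid = export_first_layer_filters(res)
        k = res.net.layers[0].w.shape[-1]
        tile = grid[1:1 + k, (k + 1) + 1:(k + 1) + 1 + k]
        assert np.all(tile == 0.5)
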