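"""Patch statistics, constrained-entropy selection, and cue rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualcue.features import (
    DegenerateImageError,
    FeatureDictionary,
    PatchDistribution,
    binarize_image,
    check_luminance_balance,
    estimate_patch_distribution,
    exhaustive_oracle,
    patch_bits,
    render_control_cue,
    render_cue,
    select_nonoptimal_features,
    select_optimal_features,
    synthetic_natural_images,
    write_cue_set,
)


def dist_from(p: dict | np.ndarray) -> PatchDistribution:
    if isinstance(p, dict):
        full = np.zeros(512)
        for code, prob in p.items():
            full[code] = prob
    else:
        full = np.zeros(512)
        full[: len(p)] = p
    return PatchDistribution(3, full / full.sum(), 1000)


class TestBinarize:
    def test_constant_image_ties_map_to_one(self):
        assert binarize_image(np.full((5, 5), 7.0)).all()

    def test_two_level_checkerboard(self):
        img = np.array([[10.0, 200.0], [200.0, 10.0]])
        np.testing.assert_array_equal(
            binarize_image(img), np.array([[0, 1], [1, 0]])
        )

    def test_random_image_splits_near_half(self, rng):
        img = rng.uniform(size=(256, 256))
        frac = binarize_image(img).mean()
        assert 0.49 <= frac <= 0.51

    def test_otsu_rejects_constant_image(self):
        with pytest.raises(DegenerateImageError):
            binarize_image(np.full((5, 5), 3.0), method="otsu")

    def test_nonfinite_rejected(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError):
            binarize_image(img)


class TestPatchDistribution:
    def test_all_zero_image_single_code(self):
        d = estimate_patch_distribution([np.zeros((10, 10), dtype=int)], 3)
        assert d.total_count == 64
        assert d.probs[0] == 1.0
        assert d.probs[1:].sum() == 0.0

    def test_single_window(self):
        img = patch_bits(0b101010101, 3)
        d = estimate_patch_distribution([img], 3)
        assert d.total_count == 1
        assert d.probs[0b101010101] == 1.0

    def test_iid_bernoulli_near_uniform(self, rng):
        imgs = [rng.integers(0, 2, (512, 512)) for _ in range(10)]
        d = estimate_patch_distribution(imgs, 3)
        assert np.abs(d.probs - 1 / 512).max() < 0.0015

    def test_probs_are_exact_count_ratios(self, rng):
        img = rng.integers(0, 2, (20, 20))
        d = estimate_patch_distribution([img], 3)
        counts = d.probs * d.total_count
        np.testing.assert_allclose(counts, np.rint(counts), atol=1e-9)
        assert abs(d.probs.sum() - 1) < 1e-12

    def test_too_small_image_names_offender(self):
        with pytest.raises(ValueError, match="image 1"):
            estimate_patch_distribution(
                [np.zeros((5, 5), dtype=int), np.zeros((2, 2), dtype=int)], 3
            )

    def test_json_roundtrip(self, tmp_path, rng):
        img = rng.integers(0, 2, (12, 12))
        d = estimate_patch_distribution([img], 3)
        d.to_json(tmp_path / "d.json")
        d2 = PatchDistribution.from_json(tmp_path / "d.json")
        np.testing.assert_array_equal(d.probs, d2.probs)
        assert d2.total_count == d.total_count


class TestOptimalSelection:
    def test_singleton_picks_intermediate_probability(self):
        d = dist_from({0: 0.5, 1: 0.3, 2: 0.2})
        r = select_optimal_features(d, N=1, W=1.0)
        assert r.patches == (1,)
        assert r.achieved_entropy == pytest.approx(-0.3 * np.log2(0.3), abs=1e-9)

    def test_bandwidth_excludes_heavy_patches(self):
        d = dist_from({0: 0.5, 1: 0.2, 2: 0.05, 3: 0.25})
        r = select_optimal_features(d, N=2, W=0.25)
        assert set(r.patches) == {1, 2}
        expected = -0.2 * np.log2(0.2) - 0.05 * np.log2(0.05)
        assert r.achieved_entropy == pytest.approx(expected, abs=1e-9)

    def test_nonbinding_constraints_select_everything(self):
        d = dist_from({0: 0.4, 5: 0.35, 17: 0.25})
        r = select_optimal_features(d, N=512, W=1.0)
        assert set(r.patches) == {0, 5, 17}

    def test_infeasible_bandwidth_gives_empty_with_warning(self):
        d = dist_from({0: 0.6, 1: 0.4})
        with pytest.warns(UserWarning):
            r = select_optimal_features(d, N=1, W=0.1)
        assert len(r) == 0 and r.warning is not None

    def test_all_zero_probabilities_error(self):
        with pytest.raises(ValueError):
            PatchDistribution(3, np.zeros(512), 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle_small_alphabets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        p = rng.dirichlet(np.ones(n))
        d = dist_from(p)
        N = int(rng.integers(1, n + 1))
        W = float(rng.uniform(p.min() * 1.5, 1.0))
        got = select_optimal_features(d, N, W)
        _, oracle_h = exhaustive_oracle(d.probs, N, W)
        assert got.achieved_entropy == pytest.approx(oracle_h, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_entropy_monotone_in_constraints(self, seed):
        """Relaxing W (or N) never decreases the achieved entropy."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(10))
        d = dist_from(p)
        h = [select_optimal_features(d, N, W).achieved_entropy
             for N, W in [(3, 0.3), (3, 0.6), (6, 0.6), (10, 1.0)]]
        assert h[0] <= h[1] + 1e-12
        assert h[1] <= h[2] + 1e-12
        assert h[2] <= h[3] + 1e-12

    def test_heuristic_beats_greedy_baseline_on_512(self, rng):
        from dualcue.features import _greedy_by_entropy, _entropy_terms

        p = rng.dirichlet(np.full(512, 0.5))
        d = PatchDistribution(3, p, 10_000)
        r = select_optimal_features(d, 50, 0.05, force_heuristic=True)
        base = _greedy_by_entropy(d.probs, 50, 0.05)
        h_base = _entropy_terms(d.probs[base]).sum()
        assert r.achieved_entropy >= h_base - 1e-12
        assert sum(r.probs) <= 0.05 + 1e-9 and len(r) <= 50


class TestNonoptimalSelection:
    def test_picks_minimum(self):
        d = dist_from({0: 0.7, 1: 0.2, 2: 0.1})
        assert select_nonoptimal_features(d, 1).patches == (2,)

    def test_tie_broken_by_smaller_code(self):
        d = dist_from({3: 0.8, 7: 0.1, 5: 0.1})
        assert select_nonoptimal_features(d, 1).patches == (5,)

    def test_uniform_distribution_takes_smallest_codes(self):
        d = PatchDistribution(3, np.full(512, 1 / 512), 512)
        r = select_nonoptimal_features(d, 50)
        assert r.patches == tuple(range(50))

    def test_too_few_positive_patches(self):
        d = dist_from({0: 0.5, 1: 0.5})
        with pytest.raises(ValueError):
            select_nonoptimal_features(d, 3)


class TestRendering:
    def test_all_ones_patch_is_white(self):
        bmp = render_cue(2**9 - 1)
        assert bmp.pixels.shape == (9, 9)
        assert (bmp.pixels == 44.0).all()

    def test_all_zeros_patch_is_black(self):
        assert (render_cue(0).pixels == 4.0).all()

    def test_default_bitmap_is_9x9(self):
        assert render_cue(0b010101010).side_px == 9

    def test_msb_is_top_left(self):
        bmp = render_cue(1 << 8)  # only the top-left cell set
        assert (bmp.pixels[:3, :3] == 44.0).all()
        assert (bmp.pixels[3:, :] == 4.0).all() and (bmp.pixels[:3, 3:] == 4.0).all()

    def test_injective_over_codes(self):
        rendered = {render_cue(c).pixels.tobytes() for c in range(512)}
        assert len(rendered) == 512

    def test_out_of_range_code(self):
        with pytest.raises(ValueError):
            render_cue(512)

    def test_control_cues(self):
        low, high = render_control_cue("low"), render_control_cue("high")
        assert (low.pixels == 20.0).all() and (high.pixels == 23.0).all()
        assert low.background == 16.0
        weber = (high.pixels[0, 0] - high.background) / high.background
        assert weber == pytest.approx(0.4375)

    def test_write_cue_set(self, tmp_path):
        d = FeatureDictionary((0, 511, 273), 50, 0.05, 1.0, "optimal", 3)
        manifest = write_cue_set(d, tmp_path / "cues")
        lines = manifest.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 cues
        assert (tmp_path / "cues" / "cue_optimal_0511.pgm").exists()


class TestLuminanceBalance:
    def test_identical_sets_balance(self):
        d = FeatureDictionary((1, 2, 4), 10, 1.0, 1.0, "optimal", 3)
        assert check_luminance_balance(d, d).difference_cd_m2 == 0.0

    def test_all_white_vs_all_black(self):
        white = FeatureDictionary((511,), 1, 1.0, 0.0, "optimal", 3)
        black = FeatureDictionary((0,), 1, 1.0, 0.0, "nonoptimal", 3)
        bal = check_luminance_balance(white, black)
        assert bal.difference_cd_m2 == pytest.approx(40.0)
        assert not bal.balanced

    def test_equal_white_counts_balance(self):
        a = FeatureDictionary((0b000000111,), 1, 1.0, 0.0, "optimal", 3)
        b = FeatureDictionary((0b111000000,), 1, 1.0, 0.0, "nonoptimal", 3)
        assert check_luminance_balance(a, b).difference_cd_m2 == 0.0


def test_synthetic_images_are_plausible_inputs():
    imgs = synthetic_natural_images(n_images=2, size=64, seed=1)
    assert all(im.shape == (64, 64) for im in imgs)
    d = estimate_patch_distribution([binarize_image(im) for im in imgs], 3)
    # 1/f noise is spatially correlated: uniform patches dominate
    assert d.probs[0] + d.probs[511] > 10 / 512
    assert abs(d.probs.sum() - 1) < 1e-12
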