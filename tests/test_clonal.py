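"""Clonal-colour pipeline: preprocessing, quantisation, clone calling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pulsefate import clonal
from pulsefate.errors import ConfigurationError
from pulsefate.ontology import UNASSIGNED
from pulsefate.synthetic.lenti import (
    LentiMixModel,
    make_lenti_population,
    render_clone_image,
)


def rgb_table(r, g, b):
    return pd.DataFrame({"mean_r": r, "mean_g": g, "mean_b": b}).assign(
        cell_id=lambda d: np.arange(len(d))
    )


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        img = np.full((64, 64), 1200.0)
        out = clonal.subtract_background(img, ball_radius=10)
        assert np.all(out <= 1.0)

    def test_disc_peak_preserved_on_gradient(self):
        """A bright disc on a flat gradient keeps its peak height within
        5% after background removal (reference 128x128 instance)."""
        yy, xx = np.mgrid[0:128, 0:128]
        gradient = 500.0 + 2.0 * xx
        disc = ((yy - 64) ** 2 + (xx - 64) ** 2 <= 36) * 4000.0
        img = gradient + disc
        out = clonal.subtract_background(img, ball_radius=20)
        peak = out[64, 64]
        assert abs(peak - 4000.0) / 4000.0 < 0.05

    def test_opening_fallback_agrees(self):
        """The morphological-opening fallback agrees with the paraboloid
        estimator within 5% of the dynamic range on the reference instance."""
        yy, xx = np.mgrid[0:128, 0:128]
        img = 300.0 + 1.5 * yy + ((yy - 40) ** 2 + (xx - 80) ** 2 <= 25) * 3000.0
        a = clonal.subtract_background(img, ball_radius=15, method="paraboloid")
        b = clonal.subtract_background(img, ball_radius=15, method="opening")
        assert np.abs(a - b).max() < 0.05 * img.max()

    def test_zero_image(self):
        out = clonal.subtract_background(np.zeros((32, 32)), ball_radius=5)
        assert np.all(out == 0)

    def test_radius_too_large(self):
        with pytest.raises(ConfigurationError, match="radius"):
            clonal.subtract_background(np.zeros((16, 16)), ball_radius=100)


class TestSmooth:
    def test_constant_unchanged(self):
        img = np.full((40, 40), 777.0)
        assert np.allclose(clonal.smooth(img, 5), img)

    def test_impulse_spread(self):
        """A single pixel of value v becomes v/|disc| at the centre
        (direct convolution oracle)."""
        img = np.zeros((41, 41))
        img[20, 20] = 810.0
        n_disc = int(clonal._disc_footprint(5).sum())
        out = clonal.smooth(img, 5)
        assert out[20, 20] == pytest.approx(810.0 / n_disc)
        assert out.max() <= 810.0 / n_disc + 1e-9


class TestDetectCells:
    def test_single_spot(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = 1000.0 * np.exp(-(((yy - 30) ** 2 + (xx - 22) ** 2) / 18.0))
        pts = clonal.detect_cells(img, noise_tolerance=50)
        assert len(pts) == 1
        assert abs(pts[0][0] - 22) <= 2 and abs(pts[0][1] - 30) <= 2

    def test_grid_of_spots(self):
        """Well-separated spots are each detected exactly once."""
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.zeros((128, 128))
        centres = [(20, 20), (20, 100), (100, 20), (100, 100), (60, 60)]
        for cy, cx in centres:
            img += 2000.0 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / 12.0))
        pts = clonal.detect_cells(img, noise_tolerance=100)
        assert len(pts) == len(centres)

    def test_blank_image(self):
        assert len(clonal.detect_cells(np.zeros((32, 32)), 10)) == 0

    def test_invalid_tolerance(self):
        with pytest.raises(ConfigurationError):
            clonal.detect_cells(np.zeros((8, 8)), 0)


class TestSampleRoi:
    def test_uniform_channel(self):
        img = np.zeros((32, 32, 3))
        img[..., 0] = 4321.0
        recs = clonal.sample_roi_rgb(img, [(16, 16)], roi_radius=5)
        assert recs["mean_r"].iloc[0] == 4321.0
        assert recs["mean_g"].iloc[0] == 0.0

    def test_hand_built_patch(self):
        """Disc mean equals explicit pixel enumeration on an 11x11 patch."""
        rng = np.random.default_rng(0)
        img = rng.integers(0, 5000, (11, 11, 3)).astype(float)
        recs = clonal.sample_roi_rgb(img, [(5, 5)], roi_radius=3)
        fp = clonal._disc_footprint(3)
        dy, dx = np.nonzero(fp)
        expected = img[dy - 3 + 5, dx - 3 + 5, 0].mean()
        assert recs["mean_r"].iloc[0] == pytest.approx(expected)

    def test_corner_point_partial_disc(self):
        img = np.full((20, 20, 3), 100.0)
        recs = clonal.sample_roi_rgb(img, [(0, 0)], roi_radius=5)
        assert recs["mean_r"].iloc[0] == 100.0  # partial disc, same mean

    def test_empty_points(self):
        img = np.zeros((8, 8, 3))
        recs = clonal.sample_roi_rgb(img, np.empty((0, 2)))
        assert len(recs) == 0


class TestFilterExtremes:
    def test_identical_records_kept(self):
        recs = rgb_table([100.0] * 20, [200.0] * 20, [300.0] * 20)
        kept, log = clonal.filter_rgb_extremes(recs)
        assert len(kept) == 20 and len(log) == 0

    def test_known_outliers_removed(self):
        vals = [500.0] * 98 + [20000.0, 30000.0]
        recs = rgb_table(vals, [100.0] * 100, [100.0] * 100)
        kept, log = clonal.filter_rgb_extremes(recs, 0.01, 0.97)
        assert len(kept) == 98
        assert set(log["channel"]) == {"mean_r"}

    def test_too_few_records(self):
        with pytest.raises(ConfigurationError):
            clonal.filter_rgb_extremes(rgb_table([1.0] * 5, [1.0] * 5, [1.0] * 5))


class TestQuantisation:
    def test_extreme_bins(self):
        recs = rgb_table([0.0, 65535.0], [0.0, 65535.0], [0.0, 65535.0])
        q = clonal.quantise_colours(recs)
        assert list(q["colour_class"]) == [0, 511]

    def test_bin_centre_sweep_gives_512(self):
        centres = clonal.bin_centres()
        combos = list(itertools.product(centres, centres, centres))
        recs = rgb_table(*map(list, zip(*combos)))
        q = clonal.quantise_colours(recs)
        assert q["colour_class"].nunique() == 512

    def test_matches_bruteforce_binning(self, rng):
        vals = rng.integers(0, 65536, (500, 3)).astype(float)
        recs = rgb_table(vals[:, 0], vals[:, 1], vals[:, 2])
        q = clonal.quantise_colours(recs)
        expect = (
            64 * np.minimum(vals[:, 0] // 8192, 7)
            + 8 * np.minimum(vals[:, 1] // 8192, 7)
            + np.minimum(vals[:, 2] // 8192, 7)
        )
        assert np.array_equal(q["colour_class"].to_numpy(), expect.astype(int))


class TestTopKAndClones:
    def test_single_colour(self):
        recs = rgb_table([100.0] * 50, [100.0] * 50, [100.0] * 50)
        q = clonal.quantise_colours(recs)
        q, cov = clonal.top_k_reduction(q, 64)
        assert cov == 1.0
        ct = clonal.call_clones(q)
        assert ct.n_positive == 1
        assert ct.table["fraction"].iloc[0] == 1.0

    def test_constructed_coverage(self):
        """Top-64 coverage equals the sort-and-sum oracle on a constructed
        frequency vector."""
        rng = np.random.default_rng(4)
        freqs = np.concatenate([np.full(64, 14), np.full(30, 2)])
        classes = np.arange(94)
        cells = np.repeat(classes, freqs)
        q = pd.DataFrame({"cell_id": np.arange(len(cells)),
                          "colour_class": cells})
        q, cov = clonal.top_k_reduction(q, 64)
        expected = 64 * 14 / (64 * 14 + 30 * 2)
        assert cov == pytest.approx(expected)

    def test_tie_at_rank_k_broken_by_class_index(self):
        cells = [1] * 5 + [9] * 3 + [4] * 3  # tie between classes 4 and 9
        q = pd.DataFrame({"cell_id": range(len(cells)), "colour_class": cells})
        q, _ = clonal.top_k_reduction(q, 2)
        kept = set(q.loc[q["reduced_class"] != UNASSIGNED, "colour_class"])
        assert kept == {1, 4}

    def test_threshold_counting(self):
        """Exactly the groups strictly above the abundance threshold are
        positive."""
        counts = [300, 200, 11, 10, 2]  # of 10,000: 3%, 2%, 0.11%, 0.1%, 0.02%
        cells = np.repeat(np.arange(5), counts)
        filler = np.repeat(5, 10_000 - sum(counts))
        q = pd.DataFrame({
            "cell_id": np.arange(len(cells) + len(filler)),
            "colour_class": np.concatenate([cells, filler]),
        })
        q, _ = clonal.top_k_reduction(q, 10)
        ct = clonal.call_clones(q, min_fraction=0.001)
        sub = ct.table.set_index("colour_class")
        assert bool(sub.loc[2, "is_positive_clone"]) is True  # 0.11% > 0.1%
        assert bool(sub.loc[3, "is_positive_clone"]) is False  # 0.1% not >

    def test_calibrated_control_calls_64(self, default_population):
        """The 10,000-cell untreated control yields exactly 64 positive
        clonal colours with > 90% top-64 coverage."""
        recs = default_population.rename(
            columns={"r": "mean_r", "g": "mean_g", "b": "mean_b"}
        )
        q = clonal.quantise_colours(recs)
        q, cov = clonal.top_k_reduction(q, 64)
        ct = clonal.call_clones(q, 0.001)
        assert ct.n_positive == 64
        assert cov > 0.90


class TestDiversity:
    def test_single_clone(self):
        recs = rgb_table([9.0] * 30, [9.0] * 30, [9.0] * 30)
        _, ct = clonal.analyze_rgb_table(recs, low_quantile=None,
                                         high_quantile=None)
        div = clonal.clone_diversity(ct)
        assert div["richness"] == 1 and div["shannon"] == 0.0

    def test_equal_clones_closed_form(self):
        """64 equal clones: Shannon = ln 64, evenness = 1."""
        cells = np.repeat(np.arange(64), 10)
        q = pd.DataFrame({"cell_id": np.arange(len(cells)),
                          "colour_class": cells})
        q, _ = clonal.top_k_reduction(q, 64)
        ct = clonal.call_clones(q)
        div = clonal.clone_diversity(ct)
        assert div["shannon"] == pytest.approx(np.log(64))
        assert div["evenness"] == pytest.approx(1.0)

    def test_two_clone_closed_form(self):
        cells = np.repeat([0, 1], [90, 10])
        q = pd.DataFrame({"cell_id": np.arange(100), "colour_class": cells})
        q, _ = clonal.top_k_reduction(q, 64)
        div = clonal.clone_diversity(clonal.call_clones(q))
        expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert div["shannon"] == pytest.approx(expected)


class TestEndToEndImageRecovery:
    def test_clone_count_recovered_from_rendered_image(self):
        """On a rendered image at default noise the full pipeline calls
        exactly the true number of founder clones, and per-clone counts
        match the truth."""
        model = LentiMixModel(n_founders=12, seed=21)
        pop = make_lenti_population(model, 150)
        img, truth = render_clone_image(
            pop, (512, 512), cell_radius_px=9, noise_sd=80.0,
            background=200.0, seed=4, repack=True,
        )
        records = clonal.analyze_image(
            img, ball_radius=25, smooth_radius=5, noise_tolerance=800,
            roi_radius=4, background_method="opening",
        )
        assert len(records) == len(truth)
        assigned, ct = clonal.analyze_rgb_table(
            records, low_quantile=None, high_quantile=None
        )
        assert ct.n_positive == 12
        called = ct.positive["count"].sort_values().to_numpy()
        true_counts = truth["founder_id"].value_counts().sort_values().to_numpy()
        assert np.array_equal(called, true_counts)
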