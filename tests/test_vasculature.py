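"""Artery-proximity analyses: neighborhood profiles, differential marker
statistics against exact oracles, and the semantic-mask pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from pulmoplex.io import MultiplexImage
from pulmoplex.vasculature import (MacroParams, differential_markers,
                                   dilate_disk, mask_intensity_contrast,
                                   neighborhood_composition_profile,
                                   rank_sum_test, sample_controls,
                                   semantic_artery_masks)


def u_oracle(x, y):
    """Brute-force Mann-Whitney U of x: pairs won + half ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook recipe."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj


class TestRankSum:
    @pytest.mark.parametrize("x,y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1.5, 1.5, 2.0], [1.5, 3.0, 4.0]),
        ([10, 20, 30, 40], [15, 25, 35]),
        ([1, 1, 1, 2], [1, 1, 3, 3]),
    ])
    def test_statistic_matches_brute_force(self, x, y):
        u, _, _ = rank_sum_test(x, y)
        assert u == pytest.approx(u_oracle(x, y), abs=1e-9)

    def test_fully_separated_groups_have_extreme_u(self):
        u, z, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert z < 0 and p < 0.1

    def test_p_matches_reference_normal_approximation(self):
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.integers(0, 8, size=9).astype(float)
            y = rng.integers(0, 8, size=7).astype(float)
            u, _, p = rank_sum_test(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
            assert u == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestDifferential:
    def make_table(self, rng, shift=None):
        n = 40
        markers = ["CD90", "HLA-DR", "CD163", "MRC1", "CD45"]
        rows = {m: rng.lognormal(3.0, 0.2, 2 * n) for m in markers}
        t = pd.DataFrame(rows)
        t.insert(0, "cell_id", np.arange(2 * n))
        if shift:
            for m, f in shift.items():
                t.loc[:n - 1, m] *= f
        return t, np.arange(n), np.arange(n, 2 * n)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        t, a, b = self.make_table(rng)
        res = differential_markers(t, a, b, ["CD90", "CD45"])
        assert not res["significant"].any()
        assert (res["p_value"] > 0.05).all()

    def test_planted_shifts_flagged_with_correct_signs(self):
        rng = np.random.default_rng(2)
        t, a, b = self.make_table(rng, shift={"CD90": 3.0, "HLA-DR": 3.0,
                                              "CD163": 0.3, "MRC1": 0.3})
        res = differential_markers(t, a, b,
                                   ["CD90", "HLA-DR", "CD163", "MRC1", "CD45"])
        sig = res[res["significant"]].set_index("marker")
        assert set(sig.index) == {"CD90", "HLA-DR", "CD163", "MRC1"}
        assert sig.loc["CD90", "log2fc"] > 1 and sig.loc["HLA-DR", "log2fc"] > 1
        assert sig.loc["CD163", "log2fc"] < -1 and sig.loc["MRC1", "log2fc"] < -1

    def test_bh_adjustment_matches_oracle(self):
        rng = np.random.default_rng(3)
        t, a, b = self.make_table(rng, shift={"CD90": 2.0})
        res = differential_markers(t, a, b,
                                   ["CD90", "HLA-DR", "CD163", "MRC1", "CD45"])
        assert np.allclose(res["p_adj"], bh_oracle(res["p_value"]), atol=1e-9)

    def test_group_constraints(self):
        rng = np.random.default_rng(4)
        t, a, b = self.make_table(rng)
        with pytest.raises(ValueError, match="disjoint"):
            differential_markers(t, a, a, ["CD90"])
        with pytest.raises(ValueError, match="3"):
            differential_markers(t, a[:2], b, ["CD90"])


class TestNeighborhoodProfile:
    def test_simple_geometry_bins(self):
        t = pd.DataFrame({
            "cell_id": [1, 2, 3, 4, 5],
            "x_um": [0.0, 10.0, -10.0, 40.0, -40.0],
            "y_um": [0.0] * 5,
            "cell_type": ["focal", "A", "A", "B", "B"],
        })
        prof = neighborhood_composition_profile(t, [1], radius_um=50, bin_um=5)
        b10 = prof[(prof.bin_lo_um == 10.0) & (prof.cell_type == "A")]
        assert b10["pct"].iloc[0] == pytest.approx(100.0)
        b40 = prof[(prof.bin_lo_um == 40.0) & (prof.cell_type == "B")]
        assert b40["pct"].iloc[0] == pytest.approx(100.0)

    def test_matches_brute_force_neighbor_sets(self):
        rng = np.random.default_rng(5)
        n = 300
        t = pd.DataFrame({
            "cell_id": np.arange(1, n + 1),
            "x_um": rng.uniform(0, 200, n), "y_um": rng.uniform(0, 200, n),
            "cell_type": rng.choice(["A", "B"], n),
        })
        focal = t["cell_id"].iloc[:10].to_numpy()
        prof = neighborhood_composition_profile(t, focal, radius_um=50, bin_um=50)
        counted = prof["n_neighbors"].sum()
        xy = t[["x_um", "y_um"]].to_numpy()
        brute = 0
        for f in range(10):
            for j in range(n):
                if j != f and np.hypot(*(xy[f] - xy[j])) <= 50:
                    brute += 1
        assert counted == brute

    def test_empty_focal_set_rejected(self):
        t = pd.DataFrame({"cell_id": [1], "x_um": [0.0], "y_um": [0.0],
                          "cell_type": ["A"]})
        with pytest.raises(ValueError):
            neighborhood_composition_profile(t, [])

    def test_artery_close_enriched_in_vsm(self, vessel_scene):
        cfg, gt, table = vessel_scene
        focal = table.loc[table["tag"] == "artery-close", "cell_id"].to_numpy()
        prof = neighborhood_composition_profile(table, focal, radius_um=50)
        near = prof[prof.bin_hi_um <= 25.0]
        vsm_near = near[near.cell_type == "vascular smooth muscle"]["n_neighbors"].sum()
        # random immune controls for contrast
        ctrl = sample_controls(table, len(focal), focal, pool="immune", seed=0)
        prof_c = neighborhood_composition_profile(table, ctrl, radius_um=50)
        near_c = prof_c[prof_c.bin_hi_um <= 25.0]
        vsm_near_c = near_c[near_c.cell_type == "vascular smooth muscle"]["n_neighbors"].sum()
        tot, tot_c = near["n_neighbors"].sum(), near_c["n_neighbors"].sum()
        assert vsm_near / tot > vsm_near_c / max(tot_c, 1)


class TestControls:
    def table(self):
        return pd.DataFrame({
            "cell_id": np.arange(1, 21),
            "cell_type": ["immune"] * 10 + ["mesenchymal"] * 10,
            "x_um": 0.0, "y_um": 0.0,
        })

    def test_whole_pool_when_n_equals_pool(self):
        ids = sample_controls(self.table(), 8, focal_ids=[1, 2], pool="immune", seed=0)
        assert sorted(ids) == list(range(3, 11))

    def test_seeded_and_disjoint_from_focal(self):
        t = self.table()
        a = sample_controls(t, 5, focal_ids=[1, 2], pool="any", seed=7)
        b = sample_controls(t, 5, focal_ids=[1, 2], pool="any", seed=7)
        assert np.array_equal(a, b)
        assert not set(a) & {1, 2}

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            sample_controls(self.table(), 11, focal_ids=[1], pool="immune", seed=0)


def vessel_image():
    """Concentric CD144 ring inside an ACTA2 annulus, CD45 immune blobs
    close to and far from the artery."""
    H = W = 420
    yy, xx = np.mgrid[0:H, 0:W]
    d = np.hypot(yy - 140, xx - 140)
    acta2 = np.where((d > 40) & (d < 80), 180.0, 3.0)
    cd144 = np.where((d > 40) & (d < 55), 160.0, 3.0)
    cd45 = np.full((H, W), 3.0)
    close = np.hypot(yy - 140, xx - 250) < 18       # ~30 px from ACTA2 edge
    far = np.hypot(yy - 380, xx - 380) < 18         # far corner
    cd45[close | far] = 150.0
    data = np.stack([acta2, cd144, cd45]).astype(np.float32)
    return MultiplexImage(["ACTA2", "CD144", "CD45"], data), close, far


class TestSemanticMasks:
    def test_planted_vessel_masks_and_zone(self):
        img, close, far = vessel_image()
        masks = semantic_artery_masks(img)
        assert ndi.label(masks.artery_core)[1] == 1
        # mask algebra invariants
        assert np.array_equal(masks.immune_close | masks.immune_distant,
                              masks.immune)
        assert not (masks.immune_close & masks.immune_distant).any()
        assert (masks.artery_expanded & ~masks.proximity_zone).sum() == 0
        # the close blob lands in the zone, the far blob outside
        assert masks.immune_close[close].mean() > 0.9
        assert masks.immune_distant[far].mean() > 0.9

    def test_size_filter_threshold_semantics(self):
        H = W = 200
        img = np.full((H, W), 3.0)
        sq_small = (slice(10, 40), slice(10, 60))    # 1500 px
        sq_big = (slice(100, 140), slice(100, 150))  # 2000 px
        for sl in (sq_small, sq_big):
            img[sl] = 200.0
        mi = MultiplexImage(["ACTA2", "CD144", "CD45"],
                            np.stack([img, img, np.full((H, W), 3.0)]).astype(np.float32))
        params = MacroParams(blur_sigma_px={"ACTA2": 0.1, "CD144": 0.1, "CD45": 0.1})
        masks = semantic_artery_masks(mi, params)
        lab, n = ndi.label(masks.artery_core)
        sizes = sorted(np.bincount(lab.ravel())[1:])
        assert all(s >= 2000 for s in sizes)
        assert masks.artery_core[110, 110]
        assert not masks.artery_core[20, 20]

    def test_one_pixel_overlap_includes_component(self):
        H = W = 300
        acta2 = np.full((H, W), 3.0)
        cd144 = np.full((H, W), 3.0)
        acta2[50:120, 50:120] = 200.0   # core region (with CD144)
        cd144[50:120, 50:120] = 200.0
        acta2[119:121, 119:180] = 200.0  # touching arm: overlaps core at 1 row
        acta2[200:220, 200:260] = 200.0  # disjoint ACTA2 blob
        mi = MultiplexImage(["ACTA2", "CD144", "CD45"],
                            np.stack([acta2, cd144, np.full((H, W), 3.0)]).astype(np.float32))
        params = MacroParams(blur_sigma_px={"ACTA2": 0.1, "CD144": 0.1, "CD45": 0.1})
        masks = semantic_artery_masks(mi, params)
        assert masks.artery_expanded[120, 150]      # touching arm included
        assert not masks.artery_expanded[210, 230]  # disjoint blob excluded

    def test_correction_masks_replace_validation(self):
        img, _, _ = vessel_image()
        rm = np.zeros(img.data.shape[1:], dtype=bool)
        rm[:] = True
        masks = semantic_artery_masks(img, remove_mask=rm)
        assert masks.artery_core.sum() == 0
        add = np.zeros_like(rm)
        add[5:10, 5:10] = True
        masks2 = semantic_artery_masks(img, remove_mask=rm, add_mask=None)
        masks3 = semantic_artery_masks(img, add_mask=add, remove_mask=rm)
        assert masks3.artery_core.sum() == 0  # remove applied after add

    def test_missing_channel_rejected(self):
        mi = MultiplexImage(["ACTA2", "CD144"], np.zeros((2, 10, 10), dtype=np.float32))
        with pytest.raises(KeyError, match="CD45"):
            semantic_artery_masks(mi)


def test_max_filter_on_binary_equals_disk_dilation():
    rng = np.random.default_rng(6)
    mask = rng.random((80, 80)) > 0.97
    r = 9
    fast = dilate_disk(mask, r)
    fp = disk(r)
    ref = ndi.maximum_filter(mask.astype(np.uint8), footprint=fp).astype(bool)
    assert np.array_equal(fast, ref)


class TestContrast:
    def test_identical_intensities_zero_differences(self):
        img, _, _ = vessel_image()
        masks = semantic_artery_masks(img)
        flat = MultiplexImage(["m1", "m2"],
                              np.full((2,) + img.data.shape[1:], 7.0, dtype=np.float32))
        res = mask_intensity_contrast(masks, flat)
        assert np.allclose(res["mean_difference"], 0.0)

    def test_planted_offset_recovered_and_shift_invariant(self):
        img, close, far = vessel_image()
        masks = semantic_artery_masks(img)
        chan = np.full(img.data.shape[1:], 10.0, dtype=np.float32)
        chan[masks.proximity_zone] += 20.0
        other = np.full_like(chan, 5.0)
        probe = MultiplexImage(["CD90", "other"], np.stack([chan, other]))
        res = mask_intensity_contrast(masks, probe).set_index("channel")
        assert res.loc["CD90", "mean_difference"] == pytest.approx(20.0, abs=1.0)
        shifted = MultiplexImage(["CD90", "other"],
                                 np.stack([chan + 100.0, other + 100.0]))
        res2 = mask_intensity_contrast(masks, shifted)
        assert list(res2["channel"]) == list(res.reset_index()["channel"])
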