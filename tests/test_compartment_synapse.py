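import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from stretchplate import compartment_synapse as cs
from stretchplate import synthetic_data as syn


def random_blob_mask(rng, shape=(64, 64), density=0.5, smooth=2.0):
    noise = ndi.gaussian_filter(rng.normal(size=shape), smooth)
    return noise > np.quantile(noise, 1 - density)


class TestBackgroundThreshold:
    def test_threshold_is_twice_the_histogram_mode(self):
        img = np.full((100, 100), 0.05)
        img[40:60, 40:60] = 0.9
        mask = cs.background_threshold(img)
        # mode 0.05 -> threshold 0.10: only the bright square passes
        expected = img > 0.10
        np.testing.assert_array_equal(mask, expected)

    def test_constant_image_gives_empty_mask(self):
        assert not cs.background_threshold(np.full((32, 32), 0.4)).any()

    def test_synthetic_map2_area_close_to_painted_truth(self, control_scene):
        _, channels, truth, _ = control_scene
        mask = cs.background_threshold(cs.median_2x2(channels["map2"]))
        assert mask.sum() == pytest.approx(truth.viability_mask.sum(), rel=0.10)


class TestSplitCompartments:
    def test_thin_tail_lands_in_neurite_not_soma(self):
        mask = np.zeros((128, 128), dtype=bool)
        rr, cc = draw_disk((64, 40), 20)
        mask[rr, cc] = True
        mask[63:65, 60:110] = True  # 2-px-wide tail
        m = cs.split_compartments(mask, erosion_radius=4)
        assert not m.soma[63:65, 70:110].any()
        assert m.neurite[64, 90]

    def test_empty_mask_gives_empty_compartments(self):
        m = cs.split_compartments(np.zeros((32, 32), dtype=bool))
        assert not m.cell.any() and not m.soma.any() and not m.neurite.any()

    def test_compartment_invariants_on_random_masks(self, rng):
        for _ in range(200):
            mask = random_blob_mask(rng)
            m = cs.split_compartments(mask, erosion_radius=3)
            assert not (m.soma & ~m.cell).any()
            assert not (m.neurite & ~m.cell).any()
            assert not (m.soma & m.neurite).any()


def mct_oracle(image, mask, sigma=1.0, bins=256):
    """Exhaustive maximum-correlation search: evaluate the Pearson
    correlation between in-mask intensities and the thresholded
    indicator at every candidate level via np.corrcoef."""
    smooth = ndi.gaussian_filter(np.asarray(image, float), sigma) if sigma > 0 else image
    values = smooth[mask]
    lo, hi = values.min(), values.max()
    idx = np.minimum(((values - lo) / (hi - lo) * bins).astype(int), bins - 1)
    best_c, best_corr = None, -np.inf
    for c in np.unique(idx):
        fg = idx > c
        if not fg.any() or fg.all():
            continue
        corr = np.corrcoef(values, fg.astype(float))[0, 1]
        if corr > best_corr:
            best_c, best_corr = c, corr
    out = np.zeros(image.shape, dtype=bool)
    out[mask] = idx > best_c
    return out


class TestMCTThreshold:
    def test_two_level_image_recovers_the_bright_objects(self):
        img = np.full((64, 64), 0.1)
        img[10:20, 10:20] = 0.9
        img[40:50, 40:50] = 0.9
        mask = np.ones_like(img, dtype=bool)
        fg = cs.mct_threshold(img, mask, sigma=0.0)
        np.testing.assert_array_equal(fg, img > 0.5)

    def test_constant_in_mask_intensities_raise_degenerate_error(self):
        img = np.full((32, 32), 0.3)
        with pytest.raises(cs.DegenerateInputError):
            cs.mct_threshold(img, np.ones_like(img, dtype=bool))

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            cs.mct_threshold(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))

    def test_matches_exhaustive_oracle_on_quantized_random_images(self, rng):
        for _ in range(25):
            img = rng.integers(0, 16, size=(32, 32)) / 15.0
            mask = np.ones((32, 32), dtype=bool)
            fast = cs.mct_threshold(img, mask, sigma=1.0)
            slow = mct_oracle(img, mask, sigma=1.0)
            np.testing.assert_array_equal(fast, slow)

    def test_restricting_the_mask_restricts_the_output(self, rng):
        img = rng.random((48, 48))
        mask = random_blob_mask(rng, (48, 48))
        fg = cs.mct_threshold(img, mask)
        assert not (fg & ~mask).any()


class TestSynaptophysinDensity:
    def _masks(self):
        cell = np.zeros((96, 96), dtype=bool)
        rr, cc = draw_disk((48, 48), 30)
        cell[rr, cc] = True
        return cs.split_compartments(cell, erosion_radius=4)

    def test_uniformly_bright_domain_has_ratio_one(self):
        masks = self._masks()
        syn_img = np.where(masks.cell, 0.9, 0.0)
        d = cs.synaptophysin_density(syn_img, masks, sigma=0.0)
        assert d.ratio_soma == 1.0

    def test_no_signal_gives_ratio_zero(self):
        masks = self._masks()
        d = cs.synaptophysin_density(np.zeros((96, 96)), masks, sigma=0.0)
        assert d.ratio_cell == 0.0 and d.ratio_soma == 0.0

    def test_empty_domain_reports_missing_value(self):
        cell = np.zeros((64, 64), dtype=bool)
        cell[20:44, 20:44] = True
        masks = cs.CompartmentMasks(
            cell=cell, soma=np.zeros_like(cell), neurite=cell.copy()
        )
        img = np.zeros((64, 64))
        img[22:30, 22:30] = 0.9
        d = cs.synaptophysin_density(img, masks, sigma=0.0)
        assert np.isnan(d.ratio_soma)
        assert d.ratio_neurite > 0

    def test_puncta_over_half_the_soma_give_ratio_near_half(self, rng):
        masks = self._masks()
        syn_img = np.full((96, 96), 0.05) + rng.normal(0, 0.005, (96, 96))
        half = masks.soma & (np.arange(96)[None, :] < 48)
        syn_img[half] = 0.9
        d = cs.synaptophysin_density(syn_img, masks, sigma=0.0)
        assert d.ratio_soma == pytest.approx(
            half.sum() / masks.soma.sum(), abs=0.05
        )
        assert d.ratio_soma == pytest.approx(0.5, abs=0.06)

    def test_density_invariant_to_intensity_rescaling(self, rng):
        masks = self._masks()
        img = np.full((96, 96), 0.04)
        for _ in range(20):
            r, c = rng.integers(20, 76, size=2)
            rr, cc = draw_disk((r, c), 2.5, shape=img.shape)
            img[rr, cc] = 0.8
        d1 = cs.synaptophysin_density(img, masks)
        d2 = cs.synaptophysin_density(0.37 * img, masks)
        assert d1.as_dict() == pytest.approx(d2.as_dict())

    def test_adding_bright_puncta_never_decreases_the_ratio(self, rng):
        masks = self._masks()
        img = np.full((96, 96), 0.04)
        coords = [tuple(rng.integers(26, 70, size=2)) for _ in range(12)]
        for r, c in coords[:6]:
            rr, cc = draw_disk((r, c), 2.5, shape=img.shape)
            img[rr, cc] = 0.9
        d_before = cs.synaptophysin_density(img, masks)
        for r, c in coords[6:]:
            rr, cc = draw_disk((r, c), 2.5, shape=img.shape)
            img[rr, cc] = 0.9
        d_after = cs.synaptophysin_density(img, masks)
        assert d_after.ratio_cell >= d_before.ratio_cell - 1e-12


class TestCompareGroups:
    def test_identical_groups_are_not_significant(self, rng):
        vals = rng.random(10)
        df = pd.DataFrame({"cell": vals, "soma": vals, "neurite": vals})
        res = cs.compare_groups(df, df.copy())
        assert (res["p"] > 0.99).all()
        assert not res["significant"].any()

    def test_bonferroni_criterion_is_exactly_one_third_of_0_05(self):
        assert cs.BONFERRONI_ALPHA == 0.05 / 3

    def test_well_separated_groups_are_detected_reliably(self):
        detected = 0
        n_rep = 100
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            a = r.normal(0.10, 0.01, size=(12, 3))
            b = r.normal(0.15, 0.01, size=(12, 3))  # 5 pooled sd apart
            res = cs.compare_groups(
                pd.DataFrame(a, columns=cs.DOMAINS),
                pd.DataFrame(b, columns=cs.DOMAINS),
            )
            if res["significant"].all():
                detected += 1
        assert detected / n_rep > 0.99

    def test_insufficient_group_size_is_an_error(self):
        df1 = pd.DataFrame({"cell": [0.1], "soma": [0.1], "neurite": [0.1]})
        df2 = pd.DataFrame({"cell": [0.1, 0.2], "soma": [0.1, 0.2], "neurite": [0.1, 0.2]})
        with pytest.raises(ValueError):
            cs.compare_groups(df1, df2)


def test_full_field_pipeline_on_rendered_scene(control_scene):
    _, channels, truth, _ = control_scene
    density, masks = cs.analyze_field(channels["map2"], channels["synaptophysin"])
    assert 0 < density.ratio_cell < 1
    assert 0 < density.ratio_soma < 1
    assert not (masks.soma & masks.neurite).any()
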