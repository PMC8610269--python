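"""Compartment mask logic and the exposure-normalized score contract."""

import numpy as np
import pytest
from conftest import FIXED_PARAMS, noise_free_config

import cavquant as cq
from cavquant.quantify import AquaScore


def grid_image(dapi, vim, panck, cav1, exposures=None):
    exposures = exposures or {c: 100.0 for c in ("dapi", "vimentin", "panck", "cav1")}
    return cq.MultiplexCoreImage(
        channels={
            "dapi": np.asarray(dapi, float),
            "vimentin": np.asarray(vim, float),
            "panck": np.asarray(panck, float),
            "cav1": np.asarray(cav1, float),
        },
        exposure_ms=exposures,
    )


GRID_PARAMS = cq.SegmentationParams(
    threshold_method={c: "fixed" for c in ("dapi", "vimentin", "panck")},
    fixed_thresholds={c: 0.5 for c in ("dapi", "vimentin", "panck")},
    nucleus_association_radius=2,
)


class TestMasks:
    def test_double_positive_pixel_goes_to_epithelium_only(self):
        """A vimentin+/panCK+ pixel is excluded from stroma and counted once."""
        z = np.zeros((5, 5))
        dapi = z.copy()
        dapi[2, 2] = 1.0
        vim = z.copy()
        vim[2, 1] = 1.0  # stroma pixel
        vim[2, 3] = 1.0  # double positive
        panck = z.copy()
        panck[2, 3] = 1.0
        masks = cq.build_compartment_masks(grid_image(dapi, vim, z + panck, z), GRID_PARAMS)
        assert masks.epithelium[2, 3] and not masks.stroma[2, 3]
        assert masks.stroma[2, 1]
        assert not np.any(masks.stroma & masks.epithelium)

    def test_no_dapi_means_no_stroma(self):
        vim = np.ones((6, 6))
        masks = cq.build_compartment_masks(
            grid_image(np.zeros((6, 6)), vim, np.zeros((6, 6)), np.zeros((6, 6))), GRID_PARAMS
        )
        assert not masks.stroma.any()

    def test_nucleus_association_radius_limits_stroma(self):
        dapi = np.zeros((9, 9))
        dapi[4, 4] = 1.0
        vim = np.ones((9, 9))
        masks = cq.build_compartment_masks(grid_image(dapi, vim, np.zeros((9, 9)), vim), GRID_PARAMS)
        assert masks.stroma[4, 6]  # within radius 2
        assert not masks.stroma[4, 8]  # beyond radius 2

    def test_all_zero_channel_warns_and_empties_mask(self):
        z = np.zeros((4, 4))
        params = cq.SegmentationParams()  # otsu on a constant channel
        with pytest.warns(UserWarning):
            masks = cq.build_compartment_masks(grid_image(z, z, z, z), params)
        assert not masks.stroma.any() and not masks.epithelium.any()

    def test_masks_match_ground_truth_exactly(self, noise_free_core):
        image, truth = noise_free_core
        masks = cq.build_compartment_masks(image, FIXED_PARAMS)
        np.testing.assert_array_equal(masks.epithelium, truth.epithelium_mask)
        np.testing.assert_array_equal(masks.stroma, truth.stroma_mask)

    def test_min_region_px_drops_specks(self):
        dapi = np.ones((8, 8))
        vim = np.zeros((8, 8))
        vim[0, 0] = 1.0  # single-pixel region
        vim[4:7, 4:7] = 1.0  # 9-px region
        params = cq.SegmentationParams(
            threshold_method={c: "fixed" for c in ("dapi", "vimentin", "panck")},
            fixed_thresholds={c: 0.5 for c in ("dapi", "vimentin", "panck")},
            nucleus_association_radius=1,
            min_region_px=4,
        )
        masks = cq.build_compartment_masks(grid_image(dapi, vim, np.zeros((8, 8)), vim), params)
        assert not masks.stroma[0, 0]
        assert masks.stroma[5, 5]


class TestScore:
    def test_uniform_intensity_closed_form(self):
        """Uniform intensity c at reference exposure with scale 1 scores c."""
        c = 0.37
        vim = np.ones((10, 10))
        img = grid_image(np.ones((10, 10)), vim, np.zeros((10, 10)), np.full((10, 10), c))
        masks = cq.CompartmentMasks(stroma=vim.astype(bool), epithelium=np.zeros((10, 10), bool))
        score = cq.compute_aqua_score(img, masks, "stroma", scale=1.0)
        assert score.value == pytest.approx(c, rel=1e-12)
        assert score.area_px == 100

    def test_doubling_intensity_doubles_score(self):
        vim = np.ones((6, 6))
        masks = cq.CompartmentMasks(stroma=vim.astype(bool), epithelium=np.zeros((6, 6), bool))
        base = grid_image(vim, vim, np.zeros((6, 6)), np.full((6, 6), 0.2))
        double = grid_image(vim, vim, np.zeros((6, 6)), np.full((6, 6), 0.4))
        s1 = cq.compute_aqua_score(base, masks, "stroma")
        s2 = cq.compute_aqua_score(double, masks, "stroma")
        assert s2.value == pytest.approx(2 * s1.value)

    def test_doubling_exposure_halves_score(self):
        """Exposure normalization divides out the configured exposure time."""
        vim = np.ones((6, 6))
        masks = cq.CompartmentMasks(stroma=vim.astype(bool), epithelium=np.zeros((6, 6), bool))
        exp1 = {"dapi": 20.0, "vimentin": 50.0, "panck": 50.0, "cav1": 100.0}
        exp2 = dict(exp1, cav1=200.0)
        img1 = grid_image(vim, vim, np.zeros((6, 6)), np.full((6, 6), 0.2), exp1)
        img2 = grid_image(vim, vim, np.zeros((6, 6)), np.full((6, 6), 0.2), exp2)
        s1 = cq.compute_aqua_score(img1, masks, "stroma")
        s2 = cq.compute_aqua_score(img2, masks, "stroma")
        assert s2.value == pytest.approx(s1.value / 2)

    def test_exposure_invariance_of_simulated_scene(self):
        """Same scene imaged at exposure e and 2e scores identically."""
        exp1 = {"dapi": 20.0, "vimentin": 50.0, "panck": 50.0, "cav1": 40.0}
        exp2 = {k: 2 * v for k, v in exp1.items()}
        img1, truth = cq.generate_core_image(noise_free_config(exposure_times=exp1))
        img2, _ = cq.generate_core_image(noise_free_config(exposure_times=exp2))
        masks = cq.CompartmentMasks(stroma=truth.stroma_mask, epithelium=truth.epithelium_mask)
        s1 = cq.compute_aqua_score(img1, masks, "stroma")
        s2 = cq.compute_aqua_score(img2, masks, "stroma")
        assert s2.value == pytest.approx(s1.value, rel=1e-12)

    def test_mask_monotonicity(self):
        """Zero-intensity pixels dilute the score; mean-intensity pixels do not."""
        cav1 = np.zeros((4, 4))
        cav1[0, :2] = 0.6
        base_mask = np.zeros((4, 4), bool)
        base_mask[0, :2] = True
        img = grid_image(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4)), cav1)

        def score(mask):
            m = cq.CompartmentMasks(stroma=mask, epithelium=np.zeros((4, 4), bool))
            return cq.compute_aqua_score(img, m, "stroma").value

        s0 = score(base_mask)
        with_zero = base_mask.copy()
        with_zero[3, 3] = True
        assert score(with_zero) < s0
        cav1[3, 3] = 0.6  # pixel at the mask's mean intensity
        assert score(with_zero) == pytest.approx(s0)

    def test_empty_mask_is_missing_not_zero(self):
        img = grid_image(np.ones((3, 3)), np.ones((3, 3)), np.zeros((3, 3)), np.ones((3, 3)))
        masks = cq.CompartmentMasks(stroma=np.zeros((3, 3), bool), epithelium=np.zeros((3, 3), bool))
        with pytest.warns(UserWarning):
            score = cq.compute_aqua_score(img, masks, "stroma")
        assert score.missing and score.value is None

    def test_noise_free_score_equals_scale_times_concentration(self):
        """Oracle equivalence: score = scale x true concentration exactly."""
        for conc in (0.1, 0.33, 0.6):
            img, truth = cq.generate_core_image(noise_free_config(stroma_cav1_conc=conc))
            masks = cq.build_compartment_masks(img, FIXED_PARAMS)
            s = cq.compute_aqua_score(img, masks, "stroma", scale=500.0)
            assert s.value == pytest.approx(500.0 * conc, rel=1e-9)


class TestAggregation:
    @pytest.mark.parametrize(
        "scores, expected, n",
        [
            ([100.0, 200.0], 150.0, 2),
            ([152.6], 152.6, 1),
            ([100.0, None], 100.0, 1),
            ([None, float("nan")], None, 0),
            ([None, 80.0, 120.0, None], 100.0, 2),
        ],
    )
    def test_duplicate_core_mean_over_missingness_patterns(self, scores, expected, n):
        mean, n_used = cq.aggregate_duplicate_cores(scores)
        assert n_used == n
        if expected is None:
            assert mean is None
        else:
            assert mean == pytest.approx(expected)

    def test_aqua_score_objects_accepted(self):
        scores = [
            AquaScore(value=100.0, compartment="stroma", area_px=10),
            AquaScore(value=None, compartment="stroma", area_px=0),
        ]
        mean, n = cq.aggregate_duplicate_cores(scores)
        assert (mean, n) == (100.0, 1)


class TestDichotomize:
    def test_median_split(self):
        labels, cutoff = cq.dichotomize_if([1.0, 2.0, 3.0, 4.0])
        assert cutoff == 2.5
        assert list(labels) == ["low", "low", "high", "high"]

    def test_value_at_median_is_high(self):
        labels, cutoff = cq.dichotomize_if([1.0, 2.0, 3.0])
        assert cutoff == 2.0
        assert list(labels) == ["low", "high", "high"]

    def test_all_equal_all_high(self):
        labels, _ = cq.dichotomize_if([5.0, 5.0, 5.0])
        assert list(labels) == ["high"] * 3

    def test_missing_propagates(self):
        labels, _ = cq.dichotomize_if([1.0, float("nan"), 3.0])
        assert labels[1] is None

    def test_insufficient_values_error(self):
        with pytest.raises(ValueError):
            cq.dichotomize_if([1.0])
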