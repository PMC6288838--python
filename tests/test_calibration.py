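"""Bath-calibration estimator: corrections, ratios, recovery, invariances."""

import math

import numpy as np
import pytest

from lineagequant._util import spawn_rngs
from lineagequant.calibration import (build_illumination_reference,
                                      estimate_concentration,
                                      flatfield_correct,
                                      measure_autofluorescence,
                                      measure_camera_background,
                                      posterior_anterior_ratio)
from lineagequant.geometry import EmbryoGeometry
from lineagequant.optics import OpticsModel
from lineagequant.synthetic import make_bath_image, make_calibration_scene


def _reference(optics, bath_nM=300.0, seed=0, n=10):
    return build_illumination_reference(
        [make_bath_image(optics, bath_nM, seed=r) for r in spawn_rngs(seed, n)])


class TestIlluminationReference:
    def test_single_and_pairwise_mean(self):
        c = np.full((4, 4), 7.0)
        ref = build_illumination_reference([c])
        assert np.array_equal(ref.mean_bath_image, c) and ref.max_value == 7.0
        a, b = np.zeros((2, 2)), np.full((2, 2), 4.0)
        assert np.array_equal(
            build_illumination_reference([a, b]).mean_bath_image,
            np.full((2, 2), 2.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            build_illumination_reference([np.zeros((2, 2)), np.zeros((3, 3))])

    def test_averaging_shrinks_noise_sqrt_n(self, flat_optics):
        # sampling variance of a mean of 10 images is 1/10 of one image's
        singles = [make_bath_image(flat_optics, 300.0, seed=r)
                   for r in spawn_rngs(1, 30)]
        sd_one = np.std(singles[0])
        sd_ten = np.std(np.mean(singles[:10], axis=0))
        assert sd_one / sd_ten == pytest.approx(math.sqrt(10), rel=0.15)


class TestFlatfield:
    def test_constant_reference_is_identity(self, optics):
        ref = build_illumination_reference([np.full(optics.shape, 5.0)])
        img = make_bath_image(optics, 100.0, seed=0)
        assert np.allclose(flatfield_correct(img, ref), img)

    def test_reference_corrects_itself_to_its_max(self):
        ref_img = np.array([[1.0, 2.0], [4.0, 2.0]])
        ref = build_illumination_reference([ref_img])
        assert np.allclose(flatfield_correct(ref_img, ref), 4.0)

    def test_vignetted_bath_flattens_below_1pct_cv(self, optics):
        noise_free = make_bath_image(optics, 300.0, noise=False)
        ref = build_illumination_reference([noise_free])
        corr = flatfield_correct(make_bath_image(optics, 300.0, noise=False), ref)
        assert np.std(corr) / np.mean(corr) < 0.01

    def test_zero_reference_pixel_rejected(self):
        ref = build_illumination_reference([np.array([[0.0, 1.0]])])
        with pytest.raises(ValueError, match="zero"):
            flatfield_correct(np.ones((1, 2)), ref)


class TestBackgroundAndAutofluorescence:
    def test_blank_offset_recovered_exactly_without_noise(self, optics):
        blank = optics.noiseless().render(np.zeros(optics.shape), noise=False)
        assert measure_camera_background(blank) == optics.camera_offset

    def test_outside_embryo_mode_includes_bath_signal(self, optics, two_cell):
        # on a bath-containing frame, the outside-embryo region measures
        # bath + offset, NOT the pure offset: callers must use an M9 blank
        scene = make_calibration_scene(two_cell, optics, 300.0,
                                       {"AB": 0, "P1": 0}, noise=False)
        outside = measure_camera_background(scene.image, "outside_embryo",
                                            mask=scene.masks.bath)
        assert outside > optics.camera_offset + 1000

    def test_noisy_blank_within_3se(self, flat_optics):
        rng = np.random.default_rng(0)
        blank = flat_optics.render(np.zeros(flat_optics.shape), rng=rng)
        n = blank.size
        se = flat_optics.read_noise_sd / math.sqrt(n)
        assert abs(measure_camera_background(blank) - 100.0) < 3 * se

    def test_empty_region_rejected(self, optics):
        with pytest.raises(ValueError, match="empty"):
            measure_camera_background(np.ones(optics.shape), "outside_embryo",
                                      mask=np.zeros(optics.shape, bool))

    def test_autofluorescence_counts_match_generator(self, flat_optics, two_cell):
        scene = make_calibration_scene(two_cell, flat_optics, 300.0,
                                       {"AB": 0, "P1": 0}, noise=False)
        af = measure_autofluorescence(scene.image, scene.masks,
                                      flat_optics.camera_offset)
        expected = flat_optics.photons_per_nM * flat_optics.autofluorescence_nM_equiv
        assert af == pytest.approx(expected, rel=1e-9)

    def test_autofluorescence_independent_of_bath(self, flat_optics, two_cell):
        outs = []
        for bath in (150.0, 300.0):
            scene = make_calibration_scene(two_cell, flat_optics, bath,
                                           {"AB": 0, "P1": 0}, noise=False)
            outs.append(measure_autofluorescence(scene.image, scene.masks,
                                                 flat_optics.camera_offset))
        assert outs[0] == pytest.approx(outs[1], rel=1e-9)

    def test_zero_autofluorescence_scene_measures_zero(self, two_cell):
        optics = OpticsModel.default(vignette=0.0, autofluorescence_nM_equiv=0.0)
        scene = make_calibration_scene(two_cell, optics, 300.0,
                                       {"AB": 0, "P1": 0}, noise=False)
        af = measure_autofluorescence(scene.image, scene.masks,
                                      optics.camera_offset)
        assert af == pytest.approx(0.0, abs=1e-9)


class TestConcentrationEstimate:
    def test_noise_free_recovery_within_1nM(self, optics, two_cell):
        ref = build_illumination_reference(
            [make_bath_image(optics, 300.0, noise=False)])
        scene = make_calibration_scene(two_cell, optics, 300.0,
                                       {"AB": 80.0, "P1": 150.0}, noise=False)
        n2 = make_calibration_scene(two_cell, optics, 300.0,
                                    {"AB": 0, "P1": 0}, noise=False)
        af = measure_autofluorescence(n2.image, n2.masks, optics.camera_offset,
                                      ref=ref)
        ests = {(e.cell, e.compartment): e.conc_nM
                for e in estimate_concentration(scene.image, scene.masks, 300.0,
                                                optics.camera_offset, af, ref=ref)}
        assert ests[("P1", "total")] == pytest.approx(150.0, abs=1.0)
        assert ests[("AB", "total")] == pytest.approx(80.0, abs=1.0)

    def test_zero_intracellular_signal_gives_zero(self, two_cell):
        optics = OpticsModel.default(vignette=0.0, autofluorescence_nM_equiv=0.0)
        scene = make_calibration_scene(two_cell, optics, 300.0,
                                       {"AB": 0, "P1": 0}, noise=False)
        ests = estimate_concentration(scene.image, scene.masks, 300.0,
                                      optics.camera_offset, 0.0)
        assert all(e.conc_nM == pytest.approx(0.0, abs=1e-9) for e in ests)

    def test_zygote_recovery_at_150nM_bath(self, optics):
        # zygote protocol: 150 nM bath, concentration near the measured 92 nM
        geom = EmbryoGeometry.one_cell()
        ref = _reference(optics, 150.0, seed=11)
        vals = []
        for r in spawn_rngs(99, 20):
            scene = make_calibration_scene(geom, optics, 150.0, {"P0": 92.0},
                                           seed=r)
            n2 = make_calibration_scene(geom, optics, 150.0, {"P0": 0.0}, seed=r)
            af = measure_autofluorescence(n2.image, n2.masks,
                                          optics.camera_offset, ref=ref)
            ests = estimate_concentration(scene.image, scene.masks, 150.0,
                                          optics.camera_offset, af, ref=ref)
            vals.append(next(e.conc_nM for e in ests if e.compartment == "total"))
        assert np.mean(vals) == pytest.approx(92.0, rel=0.05)

    def test_scale_equivariance(self, flat_optics, two_cell):
        k = 3.0
        out = []
        for scale in (1.0, k):
            scene = make_calibration_scene(
                two_cell, flat_optics, 300.0 * scale,
                {"AB": 80.0 * scale, "P1": 150.0 * scale}, noise=False)
            ests = estimate_concentration(scene.image, scene.masks, 300.0 * scale,
                                          flat_optics.camera_offset,
                                          flat_optics.photons_per_nM
                                          * flat_optics.autofluorescence_nM_equiv)
            out.append({(e.cell, e.compartment): e.conc_nM for e in ests})
        for key in out[0]:
            assert out[1][key] == pytest.approx(k * out[0][key], rel=1e-6)

    def test_compartment_consistency(self, flat_optics, two_cell):
        # area-weighted cytoplasm/nucleus mean equals the whole-cell estimate
        scene = make_calibration_scene(
            two_cell, flat_optics, 300.0,
            {"P1": 150.0, "P1/nucleus": 500.0, "AB": 80.0}, noise=False)
        ests = {(e.cell, e.compartment): e
                for e in estimate_concentration(
                    scene.image, scene.masks, 300.0, flat_optics.camera_offset,
                    flat_optics.photons_per_nM
                    * flat_optics.autofluorescence_nM_equiv)}
        cyt, nuc = ests[("P1", "cytoplasm")], ests[("P1", "nucleus")]
        weighted = ((cyt.conc_nM * cyt.n_pixels + nuc.conc_nM * nuc.n_pixels)
                    / (cyt.n_pixels + nuc.n_pixels))
        assert weighted == pytest.approx(ests[("P1", "total")].conc_nM, rel=0.005)

    def test_uncalibratable_bath_rejected(self, two_cell):
        optics = OpticsModel.default(vignette=0.0)
        scene = make_calibration_scene(two_cell, optics, 300.0,
                                       {"AB": 0, "P1": 0}, noise=False)
        with pytest.raises(ValueError, match="uncalibratable"):
            estimate_concentration(scene.image, scene.masks, 300.0,
                                   camera_bg=1e6)

    def test_saturated_pixels_excluded_with_warning(self, two_cell):
        optics = OpticsModel.default(vignette=0.0, autofluorescence_nM_equiv=0.0)
        scene = make_calibration_scene(
            two_cell, optics, 300.0,
            {"AB": 100.0, "P1": 150.0, "P1/nucleus": 7000.0}, noise=False)
        with pytest.warns(UserWarning, match="saturated"):
            ests = estimate_concentration(scene.image, scene.masks, 300.0,
                                          optics.camera_offset,
                                          saturation=65535)
        by_key = {(e.cell, e.compartment) for e in ests}
        p1_total = next(e for e in ests if e.cell == "P1" and e.compartment == "total")
        full = two_cell.masks().cells["P1"].total.sum()
        assert p1_total.n_pixels < full            # saturated nucleus excluded
        assert ("P1", "nucleus") not in by_key     # fully saturated -> skipped


class TestPosteriorAnteriorRatio:
    def test_uniform_interior_gives_one(self, blank_embryo):
        img = np.full(blank_embryo.shape, 500.0)
        r = posterior_anterior_ratio(img, blank_embryo.embryo_mask(), 0.0, 100.0)
        assert r == pytest.approx(1.0)

    def test_step_doubled_posterior(self, blank_embryo):
        mask = blank_embryo.embryo_mask()
        ap = blank_embryo.ap_coordinate()
        img = np.zeros(blank_embryo.shape)
        img[mask] = np.where(ap[mask] > 0.5, 200.0, 100.0)
        assert posterior_anterior_ratio(img, mask, 0.0, 0.0) == pytest.approx(2.0)

    def test_linear_gradient_matches_integral_oracle(self, blank_embryo):
        # closed form: half-ellipse centroid sits at 4A/(3*pi) from the cut,
        # so a gradient a + b*x gives ratio (a + b*xc)/(a - b*xc)
        mask = blank_embryo.embryo_mask()
        A, _ = blank_embryo.axes
        a0, b0 = 50.0, 0.4
        y, x = np.mgrid[0:blank_embryo.shape[0], 0:blank_embryo.shape[1]]
        img = np.zeros(blank_embryo.shape)
        img[mask] = a0 + b0 * (x[mask] - blank_embryo.center[1])
        xc = 4 * A / (3 * math.pi)
        expected = (a0 + b0 * xc) / (a0 - b0 * xc)
        assert posterior_anterior_ratio(img, mask, 0.0, 0.0) == pytest.approx(
            expected, rel=0.01)

    def test_anterior_below_background_rejected(self, blank_embryo):
        img = np.full(blank_embryo.shape, 50.0)
        with pytest.raises(ValueError, match="anterior"):
            posterior_anterior_ratio(img, blank_embryo.embryo_mask(), 0.0, 100.0)
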