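"""Generator ground truth: noise statistics, mass balance, determinism."""

import math

import numpy as np
import pytest

from lineagequant.geometry import EmbryoGeometry, Ellipsoid
from lineagequant.optics import OpticsModel, vignette_field
from lineagequant.synthetic import (BleachEvent, bleach_for_target,
                                    default_lineage_params,
                                    make_bath_image, make_calibration_scene,
                                    make_lineage_timelapse,
                                    make_membrane_stack, make_screen_dataset,
                                    posterior_circle_center, simulate_traces)
from lineagequant.volumetrics import volumes_from_labels


class TestCalibrationScene:
    def test_zero_scene_is_pure_camera_offset(self, two_cell):
        optics = OpticsModel.default(read_noise_sd=0.0,
                                     autofluorescence_nM_equiv=0.0)
        scene = make_calibration_scene(two_cell, optics, 0.0,
                                       {"AB": 0.0, "P1": 0.0}, seed=0)
        assert np.all(scene.image == optics.camera_offset)

    def test_offset_corrected_interior_exterior_ratio(self, two_cell):
        optics = OpticsModel.default(vignette=0.0, autofluorescence_nM_equiv=0.0)
        scene = make_calibration_scene(two_cell, optics, 300.0,
                                       {"AB": 150.0, "P1": 150.0}, noise=False)
        img = scene.image - optics.camera_offset
        ratio = img[scene.masks.embryo].mean() / img[scene.masks.bath].mean()
        assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_noisy_bath_mean_within_3se(self, flat_optics, two_cell):
        # analytic Poisson+read moments: per-pixel var = p*c + sd^2
        scene = make_calibration_scene(two_cell, flat_optics, 300.0,
                                       {"AB": 0.0, "P1": 0.0}, seed=42)
        vals = scene.image[scene.masks.bath]
        expected = flat_optics.photons_per_nM * 300.0 + flat_optics.camera_offset
        se = flat_optics.pixel_noise_sd(300.0) / math.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 3 * se

    def test_unknown_compartment_rejected_by_name(self, two_cell, optics):
        with pytest.raises(ValueError, match="EMS"):
            make_calibration_scene(two_cell, optics, 300.0, {"EMS": 50.0})

    def test_doubling_concentration_doubles_signal(self, two_cell, optics):
        kw = dict(noise=False)
        a = make_calibration_scene(two_cell, optics, 150.0,
                                   {"AB": 50.0, "P1": 80.0}, **kw).image
        b = make_calibration_scene(two_cell, optics, 300.0,
                                   {"AB": 100.0, "P1": 160.0}, **kw).image
        off = optics.camera_offset
        af = optics.photons_per_nM * optics.autofluorescence_nM_equiv \
            * optics.illumination_field
        interior = make_calibration_scene(two_cell, optics, 1.0,
                                          {"AB": 0, "P1": 0}, **kw).masks.embryo
        lhs = (b - off) - af * interior
        rhs = 2 * ((a - off) - af * interior)
        assert np.allclose(lhs, rhs)

    def test_seed_determinism(self, two_cell, optics):
        a = make_calibration_scene(two_cell, optics, 300.0, {"AB": 1, "P1": 2},
                                   seed=7).image
        b = make_calibration_scene(two_cell, optics, 300.0, {"AB": 1, "P1": 2},
                                   seed=7).image
        c = make_calibration_scene(two_cell, optics, 300.0, {"AB": 1, "P1": 2},
                                   seed=8).image
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_bath_image_rejects_negative(self, optics):
        with pytest.raises(ValueError):
            make_bath_image(optics, -1.0)


class TestLineageTimelapse:
    def test_amount_conserved_across_divisions(self, trace_optics):
        params = default_lineage_params(k_syn_germline=0.0, k_deg_somatic=0.0)
        tl = make_lineage_timelapse(params, trace_optics, 60.0, 2100.0,
                                    noise=False, render=False)
        totals = tl.truth.groupby("time_s")["amount"].sum()
        assert np.allclose(totals, totals.iloc[0], rtol=1e-12)

    def test_constant_traces_without_kinetics(self, trace_optics):
        from dataclasses import replace
        p0_only = replace(default_lineage_params(k_syn_germline=0.0,
                                                 k_deg_somatic=0.0),
                          divisions=())
        tl = make_lineage_timelapse(p0_only, trace_optics, 60.0, 600.0,
                                    noise=False, render=False)
        assert tl.truth["true_conc_nM"].nunique() == 1

    def test_division_concentration_ratio_matches_hand_mass_balance(self, trace_optics):
        # f=0.58, volumes 10.1/14.7 -> ratio (0.58/10.1)/(0.42/14.7) ~= 2.01
        params = default_lineage_params(k_syn_germline=0.0, k_deg_somatic=0.0)
        tl = make_lineage_timelapse(params, trace_optics, 30.0, 960.0,
                                    noise=False, render=False)
        last = tl.truth[tl.truth.time_s == 960.0].set_index("cell")
        ratio = last.loc["P1", "true_conc_nM"] / last.loc["AB", "true_conc_nM"]
        assert ratio == pytest.approx((0.58 / 10.1) / (0.42 / 14.7), rel=1e-9)
        assert ratio == pytest.approx(2.01, abs=0.005)

    def test_single_pulse_bleach_is_spatial_at_next_frame(self, blank_embryo):
        optics = OpticsModel.default(vignette=0.0, autofluorescence_nM_equiv=0.0)
        center = posterior_circle_center(blank_embryo)
        ev = BleachEvent(75.0, center, 8.0, survival=0.4, repetitions=1)
        params = default_lineage_params(k_syn_germline=0.0, k_deg_somatic=0.0,
                                        bleaches=(ev,))
        tl = make_lineage_timelapse(params, optics, 15.0, 120.0,
                                    geometry=blank_embryo, noise=False)
        pre, post = tl.stack[4], tl.stack[5]
        r_px = 4.0 / blank_embryo.pixel_size_um
        y, x = np.mgrid[0:optics.shape[0], 0:optics.shape[1]]
        circle = (y - center[0]) ** 2 + (x - center[1]) ** 2 <= r_px ** 2
        embryo = blank_embryo.embryo_mask()
        off = optics.camera_offset
        assert np.allclose(post[circle], 0.4 * (pre[circle] - off) + off)
        assert np.allclose(post[embryo & ~circle], pre[embryo & ~circle])
        # and the frame after that is fully mixed again
        mixed = tl.stack[6]
        assert np.ptp(mixed[embryo]) < 1e-9

    def test_repeated_bleach_reaches_whole_cell_target(self, blank_embryo,
                                                       trace_optics):
        ev = bleach_for_target(blank_embryo, 0.4, 75.0)
        assert ev.repetitions == 25
        params = default_lineage_params(k_syn_germline=0.0, k_deg_somatic=0.0,
                                        bleaches=(ev,))
        tl = make_lineage_timelapse(params, trace_optics, 15.0, 120.0,
                                    geometry=blank_embryo, noise=False,
                                    render=False)
        tr = tl.truth[tl.truth.cell == "P0"].set_index("time_s")["fluor_conc_nM"]
        assert tr[60.0] == pytest.approx(92.0)
        assert tr[90.0] / tr[60.0] == pytest.approx(0.4, abs=1e-9)

    def test_bleach_outside_embryo_rejected(self, blank_embryo, trace_optics):
        ev = BleachEvent(75.0, (5.0, 5.0), 8.0, survival=0.4)
        params = default_lineage_params(bleaches=(ev,))
        with pytest.raises(ValueError, match="outside the embryo"):
            make_lineage_timelapse(params, trace_optics, 15.0, 120.0,
                                   geometry=blank_embryo, render=False)

    def test_maturation_delay_hides_new_synthesis(self, trace_optics):
        slow = default_lineage_params(k_syn_germline=0.06, k_deg_somatic=0.0,
                                      maturation_delay_s=300.0)
        tl = make_lineage_timelapse(slow, trace_optics, 30.0, 600.0,
                                    noise=False, render=False)
        tr = tl.truth[tl.truth.cell == "P0"].set_index("time_s")
        assert tr.loc[240.0, "fluor_conc_nM"] == pytest.approx(92.0)
        assert tr.loc[600.0, "fluor_conc_nM"] > 92.0
        assert tr.loc[600.0, "true_conc_nM"] == pytest.approx(92.0 + 0.06 * 600)

    def test_interval_must_be_positive(self, trace_optics):
        with pytest.raises(ValueError):
            make_lineage_timelapse(default_lineage_params(), trace_optics,
                                   0.0, 100.0, render=False)

    def test_trace_noise_shrinks_with_cell_size(self, blank_embryo, trace_optics):
        from dataclasses import replace
        params = replace(default_lineage_params(k_syn_germline=0.0,
                                                k_deg_somatic=0.0),
                         divisions=())
        reps = [simulate_traces(params, trace_optics, 60.0, 300.0,
                                geometry=blank_embryo, seed=i)["intensity"]
                for i in range(40)]
        sd = np.std([r.iloc[0] for r in reps])
        n = blank_embryo.embryo_mask().sum()
        pred = math.sqrt((trace_optics.photons_per_nM * 92 +
                          trace_optics.read_noise_sd ** 2) / n)
        assert sd == pytest.approx(pred, rel=0.5)


class TestMembraneStack:
    def test_sphere_volume_closed_form(self):
        sphere = Ellipsoid((0.0, 0.0, 0.0), (10.0, 10.0, 10.0))
        assert sphere.volume_pL == pytest.approx(4 / 3 * math.pi, rel=1e-12)
        ms = make_membrane_stack({"c": sphere}, (0.5, 0.5, 0.5), noise=False)
        assert ms.true_volumes_pL["c"] == pytest.approx(4.18879, abs=1e-4)
        vols = volumes_from_labels(ms.labels)
        assert vols["c"] == pytest.approx(ms.true_volumes_pL["c"], rel=0.02)

    def test_equal_ellipsoids_have_equal_volumes(self):
        e = (6.0, 7.0, 8.0)
        ms = make_membrane_stack(
            {"a": Ellipsoid((10.0, 10.0, 10.0), e),
             "b": Ellipsoid((10.0, 10.0, 30.0), e)}, (1.0, 0.5, 0.5),
            noise=False)
        assert ms.true_volumes_pL["a"] == ms.true_volumes_pL["b"]
        vols = volumes_from_labels(ms.labels)
        assert vols["a"] == pytest.approx(vols["b"], rel=0.01)

    def test_overlap_and_bad_voxels_rejected(self):
        e = Ellipsoid((0.0, 0.0, 0.0), (5.0, 5.0, 5.0))
        f = Ellipsoid((0.0, 0.0, 4.0), (5.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="overlap"):
            make_membrane_stack({"a": e, "b": f}, (1.0, 0.5, 0.5))
        with pytest.raises(ValueError, match="voxel"):
            make_membrane_stack({"a": e}, (0.0, 0.5, 0.5))


class TestScreenDataset:
    def test_zero_multiplier_gives_zero_signal(self):
        t = make_screen_dataset(2, 4, 1000.0, {"clone_000": 0.0}, seed=0)
        net = t.net(1)
        assert np.allclose(net.loc[net.clone == "clone_000", "net"], 0.0)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            make_screen_dataset(2, 4, 1000.0, {"clone_000": -0.5})

    def test_minimum_embryos_enforced(self):
        with pytest.raises(ValueError):
            make_screen_dataset(2, 1, 1000.0)

    def test_two_stage_rows_and_determinism(self):
        from lineagequant.synthetic import make_two_stage_screen
        a = make_two_stage_screen(3, 5, 11, 1000.0, seed=5)
        b = make_two_stage_screen(3, 5, 11, 1000.0, seed=5)
        assert a.data.equals(b.data)
        counts = a.data.groupby("stage").size()
        assert counts[1] == 4 * 5 and counts[2] == 4 * 11
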