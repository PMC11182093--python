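"""Cell detection, edits, Voronoi metrics and dark-cone discordance."""

import math

import numpy as np
import pytest

from retmap.montage import Transform2D
from retmap.mosaic import (
    ROI,
    CellMosaic,
    apply_edits,
    dark_cone_discordance,
    detect_cells,
    voronoi_metrics,
)
from retmap.scale import ModalityScale
from retmap.synthetic import (
    PhantomSpec,
    gen_mosaic,
    hex_spacing_for_density,
    render_channels,
)
from tests.conftest import match_rates

IDENT = Transform2D.identity()


def square_lattice_mosaic(spacing=10.0, lo=-30.0, hi=130.0):
    xs = np.arange(lo + spacing / 2, hi, spacing)
    pts = np.array([(x, y) for x in xs for y in xs])
    return CellMosaic("cone", "aoslo_confocal", pts, to_common=IDENT)


class TestVoronoiMetrics:
    def test_square_lattice_exact_density_and_area(self):
        vm = voronoi_metrics(
            square_lattice_mosaic(),
            ROI(center=(50.0, 50.0), width=100.0, height=100.0),
            expected_spacing=10.0,
        )
        assert vm.bounded_density == pytest.approx(10000.0, abs=1e-9)
        assert vm.mean_cell_area == pytest.approx(100.0, abs=1e-9)
        assert vm.n_bounded == 100
        assert vm.mean_spacing == pytest.approx(10.0, abs=1e-9)

    def test_hexagonal_lattice_matches_closed_form(self):
        s = 3.2
        dens = 2.0 / (math.sqrt(3.0) * s * s) * 1e6
        spec = PhantomSpec(seed=0, density=dens, field_um=120.0,
                           microns_per_pixel=0.4, jitter_fraction=0.0)
        truth = gen_mosaic(spec)
        m = CellMosaic("cone", "aoslo_confocal", truth["centers"],
                       to_common=IDENT)
        vm = voronoi_metrics(m, ROI(center=(60.0, 60.0), width=100.0,
                                    height=100.0), expected_spacing=s)
        assert vm.bounded_density == pytest.approx(dens, rel=1e-9)
        # inside the healthy foveal range
        assert 104985 <= vm.bounded_density <= 163797

    def test_density_area_identity_exact(self):
        spec = PhantomSpec(seed=1, density=12000.0, field_um=200.0,
                           microns_per_pixel=1.0)
        truth = gen_mosaic(spec)
        m = CellMosaic("cone", "aoslo_confocal", truth["centers"],
                       to_common=IDENT)
        roi = ROI(center=(100.0, 100.0), width=100.0, height=100.0)
        vm = voronoi_metrics(m, roi, expected_spacing=truth["spacing_um"])
        total_area = vm.n_bounded / vm.bounded_density * 1e6
        assert vm.bounded_density * total_area / 1e6 == pytest.approx(
            vm.n_bounded, abs=1e-9
        )
        assert vm.mean_cell_area * vm.n_bounded == pytest.approx(
            total_area, rel=1e-9
        )

    def test_poisson_phantom_recovers_intensity(self):
        lam = 5000.0  # cells/mm^2
        roi = ROI(center=(150.0, 150.0), width=250.0, height=250.0)
        rng = np.random.default_rng(10)
        dens = []
        for _ in range(50):
            n = rng.poisson(lam * 1e-6 * 300 * 300)
            pts = rng.uniform(0, 300, (n, 2))
            m = CellMosaic("cone", "aoslo_confocal", pts, to_common=IDENT)
            vm = voronoi_metrics(m, roi, expected_spacing=15.0)
            dens.append(vm.bounded_density)
        assert np.mean(dens) == pytest.approx(lam, rel=0.03)

    def test_translation_and_rotation_invariance(self):
        spec = PhantomSpec(seed=2, density=10000.0, field_um=200.0,
                           microns_per_pixel=1.0)
        pts = gen_mosaic(spec)["centers"]
        roi = ROI(center=(100.0, 100.0), width=100.0, height=100.0)
        base = voronoi_metrics(
            CellMosaic("cone", "c", pts, to_common=IDENT), roi,
            expected_spacing=10.0)
        shift = np.array([37.5, -12.25])
        roi_s = ROI(center=tuple(np.array(roi.center) + shift),
                    width=100.0, height=100.0)
        moved = voronoi_metrics(
            CellMosaic("cone", "c", pts + shift, to_common=IDENT), roi_s,
            expected_spacing=10.0)
        assert moved.bounded_density == pytest.approx(base.bounded_density,
                                                      rel=1e-9)
        # 90-degree rotation about the ROI center
        c = np.array(roi.center)
        rot = np.column_stack([-(pts - c)[:, 1], (pts - c)[:, 0]]) + c
        rot_m = voronoi_metrics(
            CellMosaic("cone", "c", rot, to_common=IDENT), roi,
            expected_spacing=10.0)
        assert rot_m.bounded_density == pytest.approx(base.bounded_density,
                                                      rel=1e-9)

    def test_too_few_cells_flagged_low_quality(self):
        m = CellMosaic("cone", "c", np.array([[50.0, 50.0]]), to_common=IDENT)
        vm = voronoi_metrics(m, ROI(center=(50.0, 50.0), width=100.0,
                                    height=100.0), expected_spacing=10.0)
        assert vm.low_quality
        assert math.isnan(vm.bounded_density)


class TestDetection:
    def test_recall_and_precision_on_standard_phantom(self, cone_phantom):
        spec, truth, channels = cone_phantom
        det = detect_cells(channels["confocal"], "cone", truth["spacing_um"],
                           channels["scale"])
        tol = 0.5 * truth["spacing_um"] / spec.microns_per_pixel
        precision, recall = match_rates(det.centers,
                                        truth["centers"] / spec.microns_per_pixel,
                                        tol)
        assert precision >= 0.99
        assert recall >= 0.99

    def test_blank_image_yields_no_centers(self):
        scale = ModalityScale("aoslo_confocal", 0.6, 0.6)
        det = detect_cells(np.full((64, 64), 0.4), "cone", 8.0, scale)
        assert det.n_cells == 0

    def test_minimum_separation_rule(self):
        from scipy import ndimage as ndi

        scale = ModalityScale("aoslo_confocal", 1.0, 1.0)
        img = np.zeros((64, 64))
        img[32, 30] = 1.0
        img[32, 32] = 0.9  # 2 px apart = 0.4 x min separation (spacing 10)
        img = ndi.gaussian_filter(img, 1.5)
        det = detect_cells(img, "cone", 10.0, scale)
        assert det.n_cells == 1

    def test_sub_nyquist_spacing_rejected(self):
        scale = ModalityScale("aoslo_confocal", 2.0, 2.0)
        with pytest.raises(ValueError, match="resolvable|Nyquist|2 px"):
            detect_cells(np.zeros((32, 32)), "cone", 3.0, scale)

    def test_detection_metrics_recover_density_across_regimes(self):
        for dens in (1000.0, 20000.0, 170000.0):
            s = hex_spacing_for_density(dens)
            px = s / 8.0
            field = 16.0 * s
            spec = PhantomSpec(seed=3, density=dens, field_um=field,
                               microns_per_pixel=px, jitter_fraction=0.08,
                               snr=12.0, psf_sigma_um=s / 6.0)
            truth = gen_mosaic(spec)
            ch = render_channels(truth["centers"], truth["dark"], spec)
            det = detect_cells(ch["confocal"], "cone", s, ch["scale"])
            det.to_common = Transform2D.from_scale_offset(px, px, 0.0, 0.0)
            half = field / 2.0
            roi = ROI(center=(half, half), width=10 * s, height=10 * s)
            vm = voronoi_metrics(det, roi, expected_spacing=s)
            assert vm.bounded_density == pytest.approx(dens, rel=0.05)


class TestEdits:
    def _mosaic(self):
        pts = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0]])
        return CellMosaic("cone", "c", pts)

    def test_empty_edit_list_is_identity(self):
        m = self._mosaic()
        out = apply_edits(m, [])
        assert np.array_equal(out.centers, m.centers)
        assert out.edit_log == []

    def test_add_then_remove_same_point_round_trips(self):
        m = self._mosaic()
        out = apply_edits(m, [
            {"op": "add", "x": 40.0, "y": 40.0},
            {"op": "remove", "x": 40.0, "y": 40.0},
        ])
        assert out.n_cells == 3
        assert len(out.edit_log) == 2

    def test_removals_reduce_count(self):
        m = self._mosaic()
        out = apply_edits(m, [{"op": "remove", "x": 10.0, "y": 10.0},
                              {"op": "remove", "x": 20.0, "y": 20.0}])
        assert out.n_cells == 1
        assert len(out.removed) == 2

    def test_unmatched_removal_logged_and_skipped(self):
        m = self._mosaic()
        out = apply_edits(m, [{"op": "remove", "x": 500.0, "y": 500.0}])
        assert out.n_cells == 3
        assert out.edit_log[-1]["status"] == "skipped_no_match"

    def test_manual_adds_tagged(self):
        out = apply_edits(self._mosaic(), [{"op": "add", "x": 1.0, "y": 2.0}])
        assert out.provenance[-1] == "manual_add"


class TestDarkCones:
    def _pair_from_truth(self, seed, dark_fraction=0.2):
        spec = PhantomSpec(seed=seed, density=12000.0, field_um=200.0,
                           microns_per_pixel=0.8,
                           dark_cone_fraction=dark_fraction)
        truth = gen_mosaic(spec)
        conf = CellMosaic("cone", "aoslo_confocal",
                          truth["centers"][~truth["dark"]], to_common=IDENT)
        split = CellMosaic("cone", "aoslo_split", truth["centers"],
                           to_common=IDENT)
        return conf, split, truth

    def test_identical_sets_fully_matched(self):
        conf, _, _ = self._pair_from_truth(0, dark_fraction=0.0)
        roi = ROI(center=(100.0, 100.0), width=150.0, height=150.0)
        res = dark_cone_discordance(conf, conf, roi, match_radius=2.0)
        assert res["n_unmatched_split"] == 0

    def test_disjoint_sets_fully_unmatched(self):
        a = CellMosaic("cone", "c", np.array([[10.0, 10.0], [20.0, 10.0]]),
                       to_common=IDENT)
        b = CellMosaic("cone", "s", np.array([[80.0, 80.0], [90.0, 90.0]]),
                       to_common=IDENT)
        roi = ROI(center=(50.0, 50.0), width=100.0, height=100.0)
        res = dark_cone_discordance(a, b, roi, match_radius=3.0)
        assert res["unmatched_fraction"] == 1.0

    def test_twenty_percent_dark_fraction_recovered(self):
        roi = ROI(center=(100.0, 100.0), width=160.0, height=160.0)
        fracs = []
        for seed in range(20):
            conf, split, _ = self._pair_from_truth(seed)
            res = dark_cone_discordance(conf, split, roi, match_radius=2.0)
            fracs.append(res["unmatched_fraction"])
        assert np.mean(fracs) == pytest.approx(0.20, abs=0.02)

    def test_detection_based_discordance(self, cone_phantom):
        # full detect -> match loop on a rendered 20%-dark phantom
        spec = PhantomSpec(seed=77, density=12000.0, field_um=200.0,
                           microns_per_pixel=0.8, dark_cone_fraction=0.2,
                           snr=12.0)
        truth = gen_mosaic(spec)
        ch = render_channels(truth["centers"], truth["dark"], spec)
        t2c = Transform2D.from_scale_offset(0.8, 0.8, 0.0, 0.0)
        conf = detect_cells(ch["confocal"], "cone", truth["spacing_um"],
                            ch["scale"], to_common=t2c)
        split = detect_cells(ch["split"], "cone", truth["spacing_um"],
                             ch["scale"], modality="aoslo_split",
                             to_common=t2c)
        roi = ROI(center=(100.0, 100.0), width=160.0, height=160.0)
        res = dark_cone_discordance(conf, split, roi,
                                    match_radius=0.5 * truth["spacing_um"])
        assert res["unmatched_fraction"] == pytest.approx(0.20, abs=0.06)
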