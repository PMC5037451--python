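import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from stretchplate import cell_morphometry as cm
from stretchplate import synthetic_data as syn

CFG = cm.MorphometryConfig()


def paint_disk(img, center, radius, value=1.0):
    rr, cc = draw_disk(center, radius, shape=img.shape)
    img[rr, cc] = value


def paint_stroke(img, p0, p1, thickness=3, value=1.0):
    rr, cc = draw_line(*p0, *p1)
    for r, c in zip(rr, cc):
        rr2, cc2 = draw_disk((r, c), thickness / 2, shape=img.shape)
        img[rr2, cc2] = value


def segment(nuc, via, config=CFG):
    nuclei = cm.segment_nuclei(nuc, config)
    seg = cm.segment_cells(via, nuclei, config)
    return cm.trace_neurites(seg, config)


class TestPreprocess:
    def test_constant_image_becomes_flat(self):
        out = cm.preprocess_live(np.full((64, 64), 0.37))
        assert np.ptp(out) == 0.0

    def test_isolated_impulse_is_removed(self):
        img = np.full((64, 64), 0.1)
        img[30, 30] = 1.0
        out = cm.preprocess_live(img)
        assert out[30, 30] == pytest.approx(out[10, 10], abs=1e-6)

    def test_linear_illumination_gradient_is_flattened(self):
        h, w = 128, 128
        img = 0.1 + 0.15 * np.linspace(0, 1, w)[None, :] * np.ones((h, 1))
        paint_disk(img, (40, 40), 8, 0.9)
        paint_disk(img, (90, 90), 8, 0.9)
        out = cm.preprocess_live(img)
        bg = np.ones((h, w), dtype=bool)
        rr, cc = draw_disk((40, 40), 14, shape=(h, w))
        bg[rr, cc] = False
        rr, cc = draw_disk((90, 90), 14, shape=(h, w))
        bg[rr, cc] = False
        assert np.ptp(out[bg]) <= 0.02

    def test_non_2d_input_is_rejected(self):
        with pytest.raises(ValueError):
            cm.preprocess_live(np.zeros((4, 4, 3)))


class TestSegmentNuclei:
    def test_blank_image_has_no_nuclei(self):
        assert cm.segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_well_separated_nuclei_are_counted_exactly(self):
        img = np.zeros((256, 256))
        centers = [(40, 40), (40, 120), (40, 200), (120, 40), (120, 120),
                   (120, 200), (200, 40), (200, 120), (200, 200), (220, 220)]
        for c in centers:
            paint_disk(img, c, 10, 0.9)
        labels = cm.segment_nuclei(img)
        assert labels.max() == 10

    def test_overlapping_nuclei_are_declumped_into_two(self):
        img = np.zeros((96, 96))
        paint_disk(img, (48, 36), 11, 0.9)
        paint_disk(img, (48, 56), 11, 0.9)
        labels = cm.segment_nuclei(img)
        assert labels.max() == 2

    def test_objects_below_minimum_area_are_removed(self):
        img = np.zeros((64, 64))
        paint_disk(img, (32, 32), 3, 0.9)  # ~28 px^2 ~ 3 um^2 < 20 um^2
        assert cm.segment_nuclei(img).max() == 0


class TestSegmentCells:
    def _base(self):
        nuc = np.zeros((192, 192))
        via = np.zeros((192, 192))
        return nuc, via

    def test_somata_with_nuclei_are_viable_cells(self):
        nuc, via = self._base()
        for c in [(50, 50), (50, 140), (140, 50)]:
            paint_disk(nuc, c, 10, 0.9)
            paint_disk(via, c, 18, 0.9)
        seg = segment(nuc, via)
        assert seg.viable_count == 3
        assert seg.dead_count == 0

    def test_calcein_negative_nucleus_is_a_dead_cell(self):
        nuc, via = self._base()
        paint_disk(nuc, (50, 50), 10, 0.9)
        paint_disk(via, (50, 50), 18, 0.9)
        paint_disk(nuc, (140, 140), 10, 0.9)  # nucleus with no viability
        seg = segment(nuc, via)
        assert seg.viable_count == 1
        assert seg.dead_count == 1

    def test_bead_without_nucleus_is_rejected_as_cell_body(self):
        nuc, via = self._base()
        paint_disk(nuc, (50, 50), 10, 0.9)
        paint_disk(via, (50, 50), 18, 0.9)
        paint_disk(via, (140, 140), 6, 0.9)  # bead-sized blob, no nucleus
        seg = segment(nuc, via)
        assert seg.viable_count == 1
        assert len(seg.rejected) == 1
        assert "no_nucleus" in seg.rejected[0]["reason"]

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            cm.segment_cells(np.zeros((4, 4)), np.zeros((5, 5), dtype=np.int32))


class TestTraceNeurites:
    def test_soma_without_neurites_yields_empty_graph(self):
        nuc = np.zeros((128, 128))
        via = np.zeros((128, 128))
        paint_disk(nuc, (64, 64), 10, 0.9)
        paint_disk(via, (64, 64), 18, 0.9)
        seg = segment(nuc, via)
        assert cm.total_skeleton_length_um(seg) == 0.0
        assert sum(seg.processes_per_soma.values()) == 0

    def test_straight_neurite_length_within_five_percent(self):
        nuc = np.zeros((128, 256))
        via = np.zeros((128, 256))
        paint_disk(nuc, (64, 40), 10, 0.9)
        paint_disk(via, (64, 40), 18, 0.9)
        paint_stroke(via, (64, 58), (64, 230), thickness=3, value=0.85)
        seg = segment(nuc, via)
        true_um = (230 - 58) * CFG.pixel_size_um
        assert cm.total_skeleton_length_um(seg) == pytest.approx(true_um, rel=0.05)

    def test_y_shaped_neurite_counts_one_process_one_branch(self):
        nuc = np.zeros((160, 256))
        via = np.zeros((160, 256))
        paint_disk(nuc, (80, 50), 10, 0.9)
        paint_disk(via, (80, 50), 18, 0.9)
        paint_stroke(via, (80, 68), (80, 150), thickness=3, value=0.85)
        paint_stroke(via, (80, 150), (40, 220), thickness=3, value=0.85)
        paint_stroke(via, (80, 150), (120, 220), thickness=3, value=0.85)
        seg = segment(nuc, via)
        assert sum(seg.processes_per_soma.values()) == 1
        assert seg.n_branches == 1

    def test_missing_pixel_size_is_an_error(self):
        nuc = np.zeros((64, 64))
        via = np.zeros((64, 64))
        nuclei = cm.segment_nuclei(nuc)
        seg = cm.segment_cells(via, nuclei)
        seg.pixel_size_um = None
        cfg = cm.MorphometryConfig.__new__(cm.MorphometryConfig)
        object.__setattr__(cfg, "pixel_size_um", None)
        with pytest.raises(ValueError):
            cm.trace_neurites(seg, cfg)

    def test_edge_arc_length_is_at_least_the_endpoint_chord(self, control_scene):
        _, channels, _, _ = control_scene
        _, seg = cm.analyze_well(channels["nuclear"], channels["viability"], CFG)
        for u, v, d in seg.skeleton.edges(data=True):
            chord = np.hypot(u[0] - v[0], u[1] - v[1]) * CFG.pixel_size_um
            assert d["length_um"] >= chord - 1e-9


class TestWellMetrics:
    def test_empty_image_gives_all_zero_metrics(self):
        metrics, _ = cm.analyze_well(
            np.zeros((64, 64)), np.zeros((64, 64)), CFG, reference_count=100
        )
        for name, value in metrics.items():
            assert value == 0.0, name

    def test_totals_are_per_cell_times_viable_count(self, control_scene):
        _, channels, _, _ = control_scene
        metrics, _ = cm.analyze_well(channels["nuclear"], channels["viability"], CFG)
        v = metrics["viable_cells_per_image"]
        assert metrics["total_neurite_length"] == pytest.approx(
            metrics["neurite_length_per_cell"] * v
        )
        assert metrics["total_processes"] == pytest.approx(
            metrics["processes_per_cell"] * v
        )

    def test_viability_uses_the_reference_count(self, control_scene):
        _, channels, truth, _ = control_scene
        metrics, _ = cm.analyze_well(
            channels["nuclear"], channels["viability"], CFG, reference_count=12
        )
        assert metrics["cell_viability"] == pytest.approx(
            100.0 * truth.viable_count / 12
        )
        no_ref, _ = cm.analyze_well(channels["nuclear"], channels["viability"], CFG)
        assert np.isnan(no_ref["cell_viability"])

    def test_counts_stable_under_whole_pixel_translation(self, control_scene):
        _, channels, _, _ = control_scene
        m0, _ = cm.analyze_well(channels["nuclear"], channels["viability"], CFG)
        nuc = np.roll(channels["nuclear"], (5, 9), axis=(0, 1))
        via = np.roll(channels["viability"], (5, 9), axis=(0, 1))
        m1, _ = cm.analyze_well(nuc, via, CFG)
        assert m1["viable_cells_per_image"] == m0["viable_cells_per_image"]
        assert m1["dead_cells_per_image"] == m0["dead_cells_per_image"]

    def test_added_isolated_dead_nucleus_increments_dead_count_only(
        self, control_scene
    ):
        _, channels, truth, _ = control_scene
        m0, _ = cm.analyze_well(channels["nuclear"], channels["viability"], CFG)
        nuc = channels["nuclear"].copy()
        # drop a calcein-negative nucleus into an empty corner
        occupied = truth.nuclear_mask | truth.viability_mask
        assert not occupied[:40, :40].any()
        paint_disk(nuc, (20, 20), 10, 0.85)
        m1, _ = cm.analyze_well(nuc, channels["viability"], CFG)
        assert m1["dead_cells_per_image"] == m0["dead_cells_per_image"] + 1
        assert m1["viable_cells_per_image"] == m0["viable_cells_per_image"]
        assert m1["total_neurite_length"] == pytest.approx(
            m0["total_neurite_length"]
        )

    def test_measured_neurite_length_non_increasing_with_injury(self):
        spec = syn.SceneSpec(seed=13)
        per_cell = []
        for level in (0.0, 0.5, 1.0):
            channels, _, _ = syn.gen_culture_image(spec, level)
            m, _ = cm.analyze_well(channels["nuclear"], channels["viability"], CFG)
            per_cell.append(m["neurite_length_per_cell"])
        assert per_cell[0] >= per_cell[1] >= per_cell[2]
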