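"""Gridding, structure assignment, and expression-energy unionization."""

import numpy as np
import pytest

from crequant.analysis import spearman_rho
from crequant.atlas import AnnotationVolume
from crequant.errors import EmptySeriesError, GridSpecError
from crequant.quantify import (
    EnergyVector,
    assign_grid_structures,
    division_summary,
    expression_energy,
    grid_section,
)
from crequant.segmentation import detect_expression, segment_section, mask_summary
from crequant.synthetic import (
    GroundTruthExpression,
    RenderParams,
    SectionImage,
    SectionTransform,
    generate_series,
    place_cells,
)

NOISELESS = RenderParams(background=0.0, texture_sd=0.0)


def make_image(pixels, tissue=None, px=10.0, position=50.0):
    pixels = np.asarray(pixels, dtype=np.uint8)
    if tissue is None:
        tissue = np.ones_like(pixels, dtype=bool)
    return SectionImage(
        pixels=pixels,
        tissue=np.asarray(tissue, dtype=bool),
        pixel_size_um=px,
        plane="coronal",
        position_um=position,
        thickness_um=25.0,
        transform=SectionTransform("coronal", position, px),
    )


class TestGridSection:
    def test_single_cell_matches_mask_summary(self, rng):
        pixels = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        img = make_image(pixels)  # 200 um image = exactly one 200 um grid
        mask = detect_expression(img, 50.0, 10.0)
        grid = grid_section(img, mask, grid_size_um=200.0)
        assert len(grid.cells) == 1
        n_det, n_tot, total = mask_summary(mask, img)
        cell = grid.cells[0]
        assert (cell.n_detected, cell.n_total, cell.sum_detected) == (n_det, n_tot, total)

    def test_grid_is_twenty_pixels_at_default_sizes(self, rng):
        img = make_image(rng.integers(0, 256, size=(60, 60)).astype(np.uint8))
        grid = grid_section(img, detect_expression(img, 0.0, 0.0), 200.0)
        # 10 um pixels, 200 um grid -> 20x20 px per full cell, 3x3 cells
        assert len(grid.cells) == 9
        assert all(c.n_total == 400 for c in grid.cells)

    def test_non_multiple_grid_rejected(self, rng):
        img = make_image(np.zeros((10, 10)))
        with pytest.raises(GridSpecError):
            grid_section(img, detect_expression(img, 0.0, 0.0), 55.0)

    def test_cells_match_per_pixel_loop_oracle(self, rng):
        for trial in range(10):
            pixels = rng.integers(0, 256, size=(60, 60)).astype(np.uint8)
            tissue = rng.random((60, 60)) < 0.8
            img = make_image(pixels, tissue)
            mask = detect_expression(img, 60.0, 20.0)
            grid = grid_section(img, mask, 200.0)
            oracle = {}
            for r in range(60):
                for c in range(60):
                    if not tissue[r, c]:
                        continue
                    key = (r // 20, c // 20)
                    tot, det, s = oracle.get(key, (0, 0, 0.0))
                    if mask.detected[r, c]:
                        det += 1
                        s += float(pixels[r, c])
                    oracle[key] = (tot + 1, det, s)
            got = {c.ij: (c.n_total, c.n_detected, c.sum_detected) for c in grid.cells}
            assert got == oracle

    def test_every_tissue_pixel_counted_once(self, rng):
        pixels = rng.integers(0, 256, size=(50, 70)).astype(np.uint8)
        tissue = rng.random((50, 70)) < 0.6
        img = make_image(pixels, tissue)
        grid = grid_section(img, detect_expression(img, 0.0, 0.0), 200.0)
        assert sum(c.n_total for c in grid.cells) == int(tissue.sum())


class TestAssignGridStructures:
    def test_interior_background_and_oracle(self, small_atlas):
        ontology, annotation, partition = small_atlas
        # image spanning the full coronal extent at z=250 (division 1)
        n = int(annotation.extent_um[0] / 10)
        img = make_image(np.zeros((n, n)), position=250.0)
        grid = grid_section(img, detect_expression(img, 0.0, 0.0), 100.0)
        grid = assign_grid_structures(grid, annotation, partition)
        lut = {}
        for cell in grid.cells:
            u, v = cell.center_uv_um
            ijk = (
                int(u // annotation.voxel_size_um),
                int(v // annotation.voxel_size_um),
                int(250.0 // annotation.voxel_size_um),
            )
            label = int(annotation.labels[ijk])
            expected = partition[label] if label else None
            assert cell.structure_id == expected
        # corners are margin background; interior must hit structures
        ids = {c.structure_id for c in grid.cells}
        assert None in ids and len(ids - {None}) >= 1

    def test_center_outside_volume_is_none(self, small_atlas):
        _, annotation, partition = small_atlas
        img = make_image(np.zeros((30, 30)), px=20.0, position=250.0)  # 600 um > 500 um extent
        grid = grid_section(img, detect_expression(img, 0.0, 0.0), 200.0)
        grid = assign_grid_structures(grid, annotation, partition)
        # grid centers at 100, 300, 500 um; 500 is outside the 500-um extent
        outer = [c for c in grid.cells if c.center_uv_um[0] > 500 or c.center_uv_um[1] > 500]
        assert all(c.structure_id is None for c in outer)


def two_structure_fixture():
    """2 leaf structures split left/right on a single 60x60 px section."""
    labels = np.zeros((6, 6, 1), dtype=np.int32)
    labels[:3, :, 0] = 101
    labels[3:, :, 0] = 102
    annotation = AnnotationVolume(100.0, labels)
    partition = {101: 101, 102: 102}
    return annotation, partition


class TestExpressionEnergy:
    def test_uniform_detection_gives_energy_equal_intensity(self):
        annotation, partition = two_structure_fixture()
        img = make_image(np.full((60, 60), 80), position=50.0)
        mask = detect_expression(img, 0.0, 0.0, k=1.0, s_min=1.0)  # all above 1
        grid = assign_grid_structures(grid_section(img, mask, 200.0), annotation, partition)
        ev = expression_energy([grid], partition)
        assert ev.energy[101] == pytest.approx(80.0)
        assert ev.energy[102] == pytest.approx(80.0)
        assert ev.whole_brain_energy == pytest.approx(80.0)

    def test_two_grid_pooling(self):
        """(det 30 / tot 100) + (det 10 / tot 100) -> E = 40/200 = 0.2."""
        annotation, partition = two_structure_fixture()
        from crequant.quantify import GridCell, GridSummary

        cells = [
            GridCell((0, 0), (100.0, 100.0), 30.0, 3, 100, 101),
            GridCell((0, 1), (300.0, 100.0), 10.0, 1, 100, 101),
        ]
        grid = GridSummary(200.0, cells, SectionTransform("coronal", 50.0, 10.0))
        ev = expression_energy([grid], partition)
        assert ev.energy[101] == pytest.approx(0.2, abs=1e-15)

    def test_empty_masks_give_zero_energy(self):
        annotation, partition = two_structure_fixture()
        img = make_image(np.full((60, 60), 20), position=50.0)
        mask = detect_expression(img, 20.0, 0.0)
        grid = assign_grid_structures(grid_section(img, mask, 200.0), annotation, partition)
        ev = expression_energy([grid], partition)
        assert all(v == 0.0 for v in ev.energy.values())

    def test_no_assigned_grids_raises(self):
        annotation, partition = two_structure_fixture()
        from crequant.quantify import GridSummary

        grid = GridSummary(200.0, [], SectionTransform("coronal", 50.0, 10.0))
        with pytest.raises(EmptySeriesError):
            expression_energy([grid], partition)

    def test_conservation_and_weighted_mean(self, small_atlas, rng):
        """Sum of per-structure detected intensity equals the grid total, and
        whole-brain energy is the pixel-weighted mean of structure energies."""
        ontology, annotation, partition = small_atlas
        gt = GroundTruthExpression(
            density={m: float(rng.integers(100, 5000)) for m in ontology.midlevel_ids}
        )
        cells = place_cells(gt, annotation, partition, seed=8)
        series = generate_series(cells, annotation, seed=9)
        grids = []
        for sec in series.sections:
            if not sec.tissue.any():
                continue
            mask = segment_section(sec)
            grids.append(assign_grid_structures(grid_section(sec, mask), annotation, partition))
        ev = expression_energy(grids, partition)
        total_detected = sum(
            c.sum_detected for g in grids for c in g.cells if c.structure_id is not None
        )
        total_pixels = sum(
            c.n_total for g in grids for c in g.cells if c.structure_id is not None
        )
        assert sum(d for _, d in ev.totals.values()) == pytest.approx(total_detected, abs=1e-9)
        assert sum(n for n, _ in ev.totals.values()) == total_pixels
        weighted = sum(ev.energy[s] * ev.totals[s][0] for s in ev.energy) / total_pixels
        assert ev.whole_brain_energy == pytest.approx(weighted, abs=1e-9)

    def test_grid_refinement_invariance(self):
        """Halving the grid size leaves E_s unchanged when structure
        boundaries align with both grids."""
        # boundary at x = 400 um aligns with both 200 um and 100 um grids
        labels = np.zeros((6, 6, 1), dtype=np.int32)
        labels[:4, :, 0] = 101
        labels[4:, :, 0] = 102
        annotation = AnnotationVolume(100.0, labels)
        partition = {101: 101, 102: 102}
        rng = np.random.default_rng(0)
        img = make_image(rng.integers(0, 256, size=(60, 60)).astype(np.uint8), position=50.0)
        mask = detect_expression(img, 60.0, 10.0)
        evs = []
        for grid_um in (200.0, 100.0):
            grid = assign_grid_structures(
                grid_section(img, mask, grid_um), annotation, partition
            )
            evs.append(expression_energy([grid], partition))
        assert evs[0].energy[101] == pytest.approx(evs[1].energy[101], abs=1e-12)
        assert evs[0].energy[102] == pytest.approx(evs[1].energy[102], abs=1e-12)

    def test_recovery_of_ground_truth_ranks(self, small_atlas):
        """Noiseless simulation: recovered energy ranks track true density."""
        ontology, annotation, partition = small_atlas
        lams = np.logspace(2.5, 4.5, len(ontology.midlevel_ids))
        gt = GroundTruthExpression(
            density={m: float(l) for m, l in zip(ontology.midlevel_ids, lams)}
        )
        cells = place_cells(gt, annotation, partition, seed=12)
        series = generate_series(cells, annotation, params=NOISELESS, seed=13)
        grids = []
        for sec in series.sections:
            if not sec.tissue.any():
                continue
            grids.append(
                assign_grid_structures(
                    grid_section(sec, segment_section(sec)), annotation, partition
                )
            )
        ev = expression_energy(grids, partition)
        common = sorted(ev.energy)
        rho = spearman_rho(
            [gt.density[s] for s in common], [ev.energy[s] for s in common]
        )
        assert rho >= 0.9


class TestDivisionSummary:
    def test_single_structure_division(self):
        annotation, partition = two_structure_fixture()
        from crequant.atlas import Ontology, StructureNode

        nodes = [
            StructureNode(1, "root", "Root", None),
            StructureNode(10, "D1", "Div 1", 1, is_division=True),
            StructureNode(101, "D1a", "Leaf a", 10, is_midlevel=True),
        ]
        ontology = Ontology(nodes, division_ids=[10], midlevel_ids=[101])
        ev = EnergyVector(
            "l", "tdTomato", "coronal",
            energy={101: 0.5}, totals={101: (100, 50.0)}, whole_brain_energy=0.5,
        )
        assert division_summary(ev, ontology)[10] == pytest.approx(0.5)

    def test_equal_totals_average(self, small_atlas):
        ontology, _, _ = small_atlas
        d = ontology.division_ids[0]
        m1, m2 = [m for m in ontology.midlevel_ids if ontology.division_of(m) == d]
        ev = EnergyVector(
            "l", "tdTomato", "coronal",
            energy={m1: 0.1, m2: 0.3},
            totals={m1: (100, 10.0), m2: (100, 30.0)},
            whole_brain_energy=0.2,
        )
        assert division_summary(ev, ontology)[d] == pytest.approx(0.2)

    def test_unequal_totals_pooled_ratio(self, small_atlas):
        ontology, _, _ = small_atlas
        d = ontology.division_ids[1]
        m1, m2 = [m for m in ontology.midlevel_ids if ontology.division_of(m) == d]
        ev = EnergyVector(
            "l", "tdTomato", "coronal",
            energy={m1: 0.1, m2: 0.3},
            totals={m1: (300, 30.0), m2: (100, 30.0)},
            whole_brain_energy=0.15,
        )
        # pooled: (30+30)/(300+100) = 0.15, not the unweighted mean 0.2
        assert division_summary(ev, ontology)[d] == pytest.approx(0.15)


class TestEnergyVectorIO:
    def test_csv_round_trip(self, tmp_path, small_atlas):
        ontology, _, _ = small_atlas
        mids = ontology.midlevel_ids
        ev = EnergyVector(
            "lineX", "cre", "sagittal",
            energy={mids[0]: 1.25, mids[1]: 0.0},
            totals={mids[0]: (400, 500.0), mids[1]: (100, 0.0)},
            whole_brain_energy=1.0,
            missing={mids[2]},
        )
        ev.to_csv(tmp_path / "e.csv", ontology=ontology)
        back = EnergyVector.from_csv(tmp_path / "e.csv")
        assert back.line_id == "lineX" and back.probe == "cre" and back.plane == "sagittal"
        assert back.energy == ev.energy
        assert back.totals == ev.totals
        assert back.missing == ev.missing
        assert back.whole_brain_energy == ev.whole_brain_energy
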