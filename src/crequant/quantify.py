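"""Gridding and unionization: from expression masks to per-structure energy.

Each masked section is tiled with 200-um grid cells (half-open intervals, so
every in-tissue pixel lands in exactly one cell); each cell's center is
projected through the section's exact transform into the atlas and assigned
to the mid-level structure of the voxel it hits. Expression energy of a
structure is then

    E_s = (sum of detected-pixel intensity over the structure's grids)
          / (number of in-tissue pixels over the structure's grids)

and the whole-brain energy is the same ratio pooled over all assigned grids.
Structures that receive no grid at all (small structures can fall between
serial sections) are reported as *missing*, not zero, and are excluded from
rank correlations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import AnnotationVolume, Ontology
from .errors import EmptySeriesError, GridSpecError
from .segmentation import ExpressionMask
from .synthetic import SectionImage, SectionTransform

DEFAULT_GRID_UM = 200.0


@dataclass
class GridCell:
    """One grid cell of one section."""

    ij: tuple[int, int]  # (row-block, col-block) index
    center_uv_um: tuple[float, float]  # in-image coords (u = col dir, v = row dir)
    sum_detected: float
    n_detected: int
    n_total: int  # in-tissue pixels in the cell
    structure_id: int | None = None


@dataclass
class GridSummary:
    """All grid cells of one section (only cells containing tissue)."""

    grid_size_um: float
    cells: list[GridCell]
    transform: SectionTransform

    def total_detected(self) -> float:
        return float(sum(c.sum_detected for c in self.cells))


def grid_section(
    image: SectionImage, mask: ExpressionMask, grid_size_um: float = DEFAULT_GRID_UM
) -> GridSummary:
    """Tile a masked section into grid cells and summarize each cell.

    The grid size must be a positive multiple of the pixel size (no
    resampling). Boundary cells may be partial. Cells without tissue are
    dropped; structure assignment is left for :func:`assign_grid_structures`.
    """
    px = image.pixel_size_um
    ratio = grid_size_um / px
    g = int(round(ratio))
    if grid_size_um <= 0 or g < 1 or abs(ratio - g) > 1e-9:
        raise GridSpecError(
            f"grid size {grid_size_um} um is not a positive multiple of the "
            f"pixel size {px} um"
        )
    nrows, ncols = image.pixels.shape
    pix = image.pixels.astype(np.float64)
    cells: list[GridCell] = []
    for i in range(0, (nrows + g - 1) // g):
        for j in range(0, (ncols + g - 1) // g):
            rs = slice(i * g, min((i + 1) * g, nrows))
            cs = slice(j * g, min((j + 1) * g, ncols))
            tissue = image.tissue[rs, cs]
            n_total = int(tissue.sum())
            if n_total == 0:
                continue
            det = mask.detected[rs, cs]
            cells.append(
                GridCell(
                    ij=(i, j),
                    center_uv_um=((j + 0.5) * grid_size_um, (i + 0.5) * grid_size_um),
                    sum_detected=float(pix[rs, cs][det].sum()),
                    n_detected=int(det.sum()),
                    n_total=n_total,
                )
            )
    return GridSummary(grid_size_um=grid_size_um, cells=cells, transform=image.transform)


def assign_grid_structures(
    grid: GridSummary,
    annotation: AnnotationVolume,
    partition: Mapping[int, int],
) -> GridSummary:
    """Fill each grid cell's structure by center-point lookup in the atlas.

    The cell center is mapped through the section transform into atlas
    micrometres and down to a voxel; the cell gets that voxel's mid-level
    structure, or None outside the brain (centers mapping outside the volume
    are likewise None, not an error).
    """
    for cell in grid.cells:
        u, v = cell.center_uv_um
        px = grid.transform.pixel_size_um
        row, col = v / px - 0.5, u / px - 0.5
        xyz = grid.transform.pixel_to_atlas(row, col)
        ijk = tuple(int(np.floor(c / annotation.voxel_size_um)) for c in np.atleast_1d(xyz).ravel())
        if not annotation.in_bounds(ijk):
            cell.structure_id = None
            continue
        label = int(annotation.labels[ijk])
        cell.structure_id = partition[label] if label != 0 else None
    return grid


@dataclass
class EnergyVector:
    """Per-structure expression energy for one image series."""

    line_id: str
    probe: str
    plane: str
    energy: dict[int, float]  # midlevel id -> E_s (covered structures only)
    totals: dict[int, tuple[int, float]]  # midlevel id -> (sum n_total, sum detected)
    whole_brain_energy: float
    missing: set[int] = field(default_factory=set)  # structures with no grids

    def values_for(self, structure_ids: Sequence[int]) -> np.ndarray:
        """Energies in a fixed structure order; NaN where missing."""
        return np.array(
            [self.energy.get(s, np.nan) for s in structure_ids], dtype=float
        )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path, ontology: Ontology | None = None) -> None:
        all_ids = sorted(set(self.energy) | self.missing)
        rows = []
        for sid in all_ids:
            n_tot, det = self.totals.get(sid, (0, 0.0))
            rows.append(
                {
                    "structure_id": sid,
                    "acronym": ontology.acronym(sid) if ontology else "",
                    "sum_detected": det,
                    "n_total": n_tot,
                    "energy": self.energy.get(sid, np.nan),
                }
            )
        header = (
            f"# line_id={self.line_id},probe={self.probe},plane={self.plane},"
            f"whole_brain_energy={self.whole_brain_energy!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(rows).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnergyVector":
        with open(path) as fh:
            header = fh.readline().strip()
            df = pd.read_csv(fh)
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").split(",") if "=" in item
        )
        energy, totals, missing = {}, {}, set()
        for r in df.itertuples():
            sid = int(r.structure_id)
            if pd.isna(r.energy):
                missing.add(sid)
            else:
                energy[sid] = float(r.energy)
                totals[sid] = (int(r.n_total), float(r.sum_detected))
        return cls(
            line_id=meta["line_id"],
            probe=meta["probe"],
            plane=meta["plane"],
            energy=energy,
            totals=totals,
            whole_brain_energy=float(meta["whole_brain_energy"]),
            missing=missing,
        )


def expression_energy(
    grids: Iterable[GridSummary],
    partition: Mapping[int, int],
    line_id: str = "line",
    probe: str = "tdTomato",
    plane: str = "coronal",
) -> EnergyVector:
    """Unionize assigned grids across a series into per-structure energy."""
    det_sum: dict[int, float] = {}
    tot_sum: dict[int, int] = {}
    n_assigned = 0
    for grid in grids:
        for cell in grid.cells:
            if cell.structure_id is None:
                continue
            n_assigned += 1
            det_sum[cell.structure_id] = det_sum.get(cell.structure_id, 0.0) + cell.sum_detected
            tot_sum[cell.structure_id] = tot_sum.get(cell.structure_id, 0) + cell.n_total
    if n_assigned == 0:
        raise EmptySeriesError("no grid in the series was assigned to any structure")
    energy = {s: det_sum[s] / tot_sum[s] for s in det_sum if tot_sum[s] > 0}
    totals = {s: (tot_sum[s], det_sum[s]) for s in det_sum}
    whole = sum(det_sum.values()) / sum(tot_sum.values())
    all_mids = set(partition.values())
    missing = all_mids - set(energy)
    return EnergyVector(
        line_id=line_id,
        probe=probe,
        plane=plane,
        energy=energy,
        totals=totals,
        whole_brain_energy=float(whole),
        missing=missing,
    )


def division_summary(ev: EnergyVector, ontology: Ontology) -> dict[int, float]:
    """Pixel-weighted energy pooled over each major division's structures.

    Division energy is the pooled ratio sum(detected)/sum(n_total) over the
    division's covered mid-level structures, consistent with the
    per-structure formula. Divisions with no covered structure map to NaN.
    """
    det: dict[int, float] = {d: 0.0 for d in ontology.division_ids}
    tot: dict[int, int] = {d: 0 for d in ontology.division_ids}
    for sid, (n_tot, d_sum) in ev.totals.items():
        div = ontology.division_of(sid)
        if div is None:
            continue
        det[div] += d_sum
        tot[div] += n_tot
    return {
        d: (det[d] / tot[d] if tot[d] > 0 else float("nan"))
        for d in ontology.division_ids
    }
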