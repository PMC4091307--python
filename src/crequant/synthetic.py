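"""Synthetic histology: ground-truth expression, cells, and section images.

This module is the forward model that stands in for the wet-lab and imaging
half of a transgenic characterization pipeline. A line's ground truth is a
per-structure density of expressing cells (cells/mm3) assigned through six
qualitative pattern categories (widespread, scattered, sparse, enriched,
restricted, restricted-but-sparse); cells are realized as a Poisson process
inside each structure's voxels; serial sections (25 um slabs sampled every
200 um) are rendered as 8-bit signal-intensity images in which each cell in
the slab appears as a small Gaussian blob over a noisy tissue background.

Gene/Cre-reporter dataset pairs are generated under three faithfulness
modes: (1) identical densities, (2) the gene's pattern plus ectopic
structures, (3) a strict subset of the gene's pattern.

Images store *signal* intensity (higher = more ISH product); real
colorimetric scans are dark-on-light and would be inverted on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .atlas import AnnotationVolume, Ontology
from .errors import InfeasiblePairError, InvalidAssignmentError

CATEGORIES = (
    "widespread", "scattered", "sparse", "enriched", "restricted",
    "restricted_sparse", "none",
)

#: Density multipliers (relative to lambda0) encoding the qualitative
#: ordering of the six visual pattern categories. "Division-wide" categories
#: apply their multiplier to every mid-level structure of the target's
#: division; targeted categories apply to the target structure itself, with
#: "enriched" additionally giving siblings a low level.
CATEGORY_MULTIPLIERS = {
    "widespread": 1.0,
    "scattered": 0.3,
    "sparse": 0.05,
    "enriched": 1.0,
    "enriched_sibling": 0.2,
    "restricted": 1.0,
    "restricted_sparse": 0.1,
}

DEFAULT_BASE_DENSITY = 5000.0  # expressing cells per mm3
DEFAULT_CELL_INTENSITY = (150.0, 20.0)  # mean, sd of per-cell amplitude


@dataclass
class GroundTruthExpression:
    """Per-structure expressing-cell density: the simulation's recoverable truth."""

    density: dict[int, float]  # midlevel id -> lambda_s (cells/mm3)
    cell_intensity: tuple[float, float] = DEFAULT_CELL_INTENSITY
    category: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, lam in self.density.items():
            if lam < 0:
                raise InvalidAssignmentError(f"negative density for structure {sid}")
        for sid in self.density:
            cat = self.category.get(sid, "none" if self.density[sid] == 0 else "custom")
            if cat == "none" and self.density[sid] != 0:
                raise InvalidAssignmentError(
                    f"structure {sid}: category 'none' with nonzero density"
                )
        self.category = {
            sid: self.category.get(sid, "none" if self.density[sid] == 0 else "custom")
            for sid in self.density
        }

    @property
    def support(self) -> set[int]:
        """Structures with nonzero density."""
        return {sid for sid, lam in self.density.items() if lam > 0}

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "structure_id": sorted(self.density),
                "lambda": [self.density[s] for s in sorted(self.density)],
                "category": [self.category[s] for s in sorted(self.density)],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruthExpression":
        df = pd.read_csv(path)
        return cls(
            density={int(r.structure_id): float(getattr(r, "lambda")) for r in df.itertuples()},
            category={int(r.structure_id): str(r.category) for r in df.itertuples()},
        )


def sample_ground_truth(
    ontology: Ontology,
    assignments: Mapping[int, str],
    base_density: float = DEFAULT_BASE_DENSITY,
    seed: int = 0,
    cell_intensity: tuple[float, float] = DEFAULT_CELL_INTENSITY,
) -> GroundTruthExpression:
    """Turn category assignments into per-structure densities.

    ``assignments`` maps a mid-level structure id (or a division id, for the
    division-wide categories) to a pattern category. Division-wide categories
    (widespread / scattered / sparse) fill every mid-level structure of the
    target's division; "restricted" and "restricted_sparse" hit only the
    target; "enriched" hits the target at full density and its division
    siblings at a low level. Deterministic given the seed (the defaults
    involve no randomness; the seed is accepted for interface stability).
    """
    del seed  # deterministic mapping; kept for a stable call signature
    mids = list(ontology.midlevel_ids)
    midset = set(mids)
    density = {sid: 0.0 for sid in mids}
    category = {sid: "none" for sid in mids}

    def division_members(div_id: int) -> list[int]:
        return [m for m in mids if ontology.division_of(m) == div_id]

    for target, cat in assignments.items():
        if cat not in CATEGORIES or cat == "none":
            raise InvalidAssignmentError(f"unknown pattern category {cat!r}")
        if target in midset:
            div = ontology.division_of(target)
            members = division_members(div) if div is not None else [target]
        elif target in set(ontology.division_ids):
            if cat in ("restricted", "restricted_sparse", "enriched"):
                raise InvalidAssignmentError(
                    f"category {cat!r} needs a mid-level target, got division {target}"
                )
            members = division_members(target)
            div = target
        else:
            raise InvalidAssignmentError(f"unknown structure id {target}")

        if cat in ("widespread", "scattered", "sparse"):
            mult = CATEGORY_MULTIPLIERS[cat]
            for m in members:
                density[m] = max(density[m], mult * base_density)
                category[m] = cat
        elif cat == "enriched":
            for m in members:
                if m == target:
                    density[m] = max(density[m], base_density)
                    category[m] = cat
                else:
                    density[m] = max(
                        density[m], CATEGORY_MULTIPLIERS["enriched_sibling"] * base_density
                    )
                    if category[m] == "none":
                        category[m] = "enriched_sibling"
        else:  # restricted / restricted_sparse
            density[target] = max(density[target], CATEGORY_MULTIPLIERS[cat] * base_density)
            category[target] = cat

    # categories for structures that stayed at zero
    category = {s: ("none" if density[s] == 0 else category[s]) for s in mids}
    return GroundTruthExpression(
        density=density, cell_intensity=cell_intensity, category=category
    )


def make_line_pair(
    gt_gene: GroundTruthExpression,
    faithfulness: int,
    seed: int = 0,
    ectopic_fraction: float = 0.5,
    dropped_fraction: float = 0.5,
) -> tuple[GroundTruthExpression, GroundTruthExpression]:
    """Derive a Cre ground truth from a gene ground truth under a faithfulness mode.

    Mode 1: identical densities. Mode 2: the gene's pattern plus ectopic
    structures (drawn uniformly from zero-density structures; ectopic density
    is the mean of the gene's positive densities). Mode 3: a strict, nonempty
    subset of the gene's pattern.
    """
    if faithfulness not in (1, 2, 3):
        raise InvalidAssignmentError(f"faithfulness must be 1, 2 or 3, got {faithfulness}")
    rng = np.random.default_rng(seed)
    gene_density = dict(gt_gene.density)
    positives = sorted(gt_gene.support)
    zeros = sorted(set(gene_density) - set(positives))

    if faithfulness == 1:
        cre = replace(
            gt_gene, density=dict(gene_density), category=dict(gt_gene.category)
        )
        return gt_gene, cre

    if faithfulness == 2:
        if not zeros:
            raise InfeasiblePairError("no zero-density structure available for ectopic expression")
        k = min(len(zeros), max(1, round(ectopic_fraction * len(positives))))
        extra = rng.choice(zeros, size=k, replace=False)
        level = float(np.mean([gene_density[s] for s in positives])) if positives else DEFAULT_BASE_DENSITY
        density = dict(gene_density)
        category = dict(gt_gene.category)
        for s in extra:
            density[int(s)] = level
            category[int(s)] = "restricted"  # ectopic focal expression
        return gt_gene, GroundTruthExpression(
            density=density, cell_intensity=gt_gene.cell_intensity, category=category
        )

    # faithfulness == 3: strict nonempty subset
    if len(positives) < 2:
        raise InfeasiblePairError(
            "subset faithfulness needs at least 2 expressed structures"
        )
    k = min(len(positives) - 1, max(1, round(dropped_fraction * len(positives))))
    dropped = rng.choice(positives, size=k, replace=False)
    density = dict(gene_density)
    category = dict(gt_gene.category)
    for s in dropped:
        density[int(s)] = 0.0
        category[int(s)] = "none"
    return gt_gene, GroundTruthExpression(
        density=density, cell_intensity=gt_gene.cell_intensity, category=category
    )


@dataclass
class CellSet:
    """Realized expressing cells in the atlas frame (micrometres)."""

    positions: np.ndarray  # (n, 3) float64, um
    amplitudes: np.ndarray  # (n,) float64
    structure_of_cell: np.ndarray  # (n,) int32 midlevel ids

    def __len__(self) -> int:
        return len(self.positions)


def place_cells(
    gt: GroundTruthExpression,
    annotation: AnnotationVolume,
    partition: Mapping[int, int],
    seed: int = 0,
) -> CellSet:
    """Poisson-realize the ground truth as point cells.

    The cell count in structure s is Poisson(lambda_s * V_s) with V_s the
    structure volume in mm3; positions are uniform within the structure's
    voxels; per-cell amplitudes are normal(mean, sd) clipped to [0, 255].
    """
    rng = np.random.default_rng(seed)
    vox_mm3 = (annotation.voxel_size_um / 1000.0) ** 3
    # group voxels by midlevel structure
    lut_leaves: dict[int, list[int]] = {}
    for leaf, mid in partition.items():
        lut_leaves.setdefault(mid, []).append(leaf)

    pos_chunks, amp_chunks, sid_chunks = [], [], []
    mean_amp, sd_amp = gt.cell_intensity
    for mid in sorted(gt.density):
        lam = gt.density[mid]
        if lam == 0:
            continue
        leaves = lut_leaves.get(mid, [])
        vox_idx = np.argwhere(np.isin(annotation.labels, leaves))
        if len(vox_idx) == 0:
            continue
        volume = len(vox_idx) * vox_mm3
        n = int(rng.poisson(lam * volume))
        if n == 0:
            continue
        pick = rng.integers(0, len(vox_idx), size=n)
        offsets = rng.uniform(0.0, 1.0, size=(n, 3))
        pos = (vox_idx[pick] + offsets) * annotation.voxel_size_um
        amp = np.clip(rng.normal(mean_amp, sd_amp, size=n), 0.0, 255.0)
        pos_chunks.append(pos)
        amp_chunks.append(amp)
        sid_chunks.append(np.full(n, mid, dtype=np.int32))

    if not pos_chunks:
        return CellSet(
            positions=np.empty((0, 3)), amplitudes=np.empty(0),
            structure_of_cell=np.empty(0, dtype=np.int32),
        )
    return CellSet(
        positions=np.concatenate(pos_chunks),
        amplitudes=np.concatenate(amp_chunks),
        structure_of_cell=np.concatenate(sid_chunks),
    )


@dataclass(frozen=True)
class SectionTransform:
    """Exact affine map between 2D section pixels and 3D atlas micrometres.

    Coronal sections are fixed-z slabs (image cols = x, rows = y); sagittal
    sections are fixed-x slabs (image cols = z, rows = y). Pixel (r, c)
    centers sit at ((c + 1/2) px, (r + 1/2) px) in-plane.
    """

    plane: str  # "coronal" | "sagittal"
    position_um: float
    pixel_size_um: float

    def pixel_to_atlas(self, rows, cols) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        u = (cols + 0.5) * self.pixel_size_um
        v = (rows + 0.5) * self.pixel_size_um
        u, v = np.broadcast_arrays(u, v)
        pos = np.full_like(u, self.position_um)
        if self.plane == "coronal":
            return np.stack([u, v, pos], axis=-1)
        return np.stack([pos, v, u], axis=-1)

    def atlas_to_pixel(self, xyz) -> tuple[np.ndarray, np.ndarray]:
        """Float (row, col) pixel coordinates of atlas points."""
        xyz = np.asarray(xyz, dtype=float)
        if self.plane == "coronal":
            u, v = xyz[..., 0], xyz[..., 1]
        else:
            u, v = xyz[..., 2], xyz[..., 1]
        return v / self.pixel_size_um - 0.5, u / self.pixel_size_um - 0.5

    def axis_coordinate(self, xyz) -> np.ndarray:
        """Coordinate of points along the sectioning axis."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz[..., 2] if self.plane == "coronal" else xyz[..., 0]

    def to_dict(self) -> dict:
        return {
            "plane": self.plane,
            "position_um": self.position_um,
            "pixel_size_um": self.pixel_size_um,
        }


@dataclass
class SectionImage:
    """One serial section: 8-bit signal-intensity pixels with exact placement."""

    pixels: np.ndarray  # uint8 (rows, cols), 0-255, higher = more signal
    tissue: np.ndarray  # bool, in-tissue pixels
    pixel_size_um: float
    plane: str
    position_um: float
    thickness_um: float
    transform: SectionTransform

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("section thickness must be positive")
        if self.pixels.shape != self.tissue.shape:
            raise ValueError("pixels and tissue mask shapes differ")


@dataclass
class RenderParams:
    """Imaging forward-model parameters (all micrometres / 8-bit units)."""

    pixel_size_um: float = 10.0
    thickness_um: float = 25.0
    background: float = 20.0  # mean in-tissue background level b0
    texture_sd: float = 5.0  # gaussian tissue texture sd
    blob_radius_um: float = 10.0  # gaussian sigma of a rendered cell


def section_geometry(
    annotation: AnnotationVolume, plane: str, pixel_size_um: float
) -> tuple[int, int]:
    """Image shape (rows, cols) covering the in-plane volume extent."""
    ex, ey, ez = annotation.extent_um
    if plane == "coronal":
        width, height = ex, ey
    elif plane == "sagittal":
        width, height = ez, ey
    else:
        raise ValueError(f"unknown plane {plane!r}")
    return int(np.floor(height / pixel_size_um + 1e-9)), int(
        np.floor(width / pixel_size_um + 1e-9)
    )


def render_section(
    cells: CellSet,
    annotation: AnnotationVolume,
    plane: str,
    position_um: float,
    params: RenderParams | None = None,
    seed: int = 0,
) -> SectionImage:
    """Render the cells of one 25-um slab as an 8-bit section image.

    Cells whose sectioning-axis coordinate lies within position +/- thickness/2
    are drawn as 2D Gaussian blobs of their amplitude on a noisy background;
    out-of-tissue pixels are 0; intensities clip to [0, 255].
    """
    params = params or RenderParams()
    extent = annotation.extent_um[2] if plane == "coronal" else annotation.extent_um[0]
    if not (0.0 <= position_um <= extent):
        raise IndexError(f"section position {position_um} outside extent [0, {extent}]")

    nrows, ncols = section_geometry(annotation, plane, params.pixel_size_um)
    transform = SectionTransform(plane, position_um, params.pixel_size_um)

    # tissue mask: label of the voxel under each pixel center
    rr, cc = np.arange(nrows), np.arange(ncols)
    pts = transform.pixel_to_atlas(rr[:, None], cc[None, :])  # (rows, cols, 3)
    vox = np.floor(pts / annotation.voxel_size_um).astype(int)
    vox = np.clip(vox, 0, np.array(annotation.dims) - 1)
    labels = annotation.labels[vox[..., 0], vox[..., 1], vox[..., 2]]
    tissue = labels != 0

    rng = np.random.default_rng(seed)
    img = np.zeros((nrows, ncols), dtype=np.float64)
    n_tissue = int(tissue.sum())
    if n_tissue:
        img[tissue] = params.background
        if params.texture_sd > 0:
            img[tissue] += rng.normal(0.0, params.texture_sd, size=n_tissue)

    if len(cells):
        axis = transform.axis_coordinate(cells.positions)
        in_slab = np.abs(axis - position_um) <= params.thickness_um / 2.0
        sigma_px = params.blob_radius_um / params.pixel_size_um
        w = int(np.ceil(3.0 * sigma_px)) + 1
        rows_f, cols_f = transform.atlas_to_pixel(cells.positions[in_slab])
        for r0, c0, amp in zip(rows_f, cols_f, cells.amplitudes[in_slab]):
            r_lo = max(int(np.floor(r0)) - w, 0)
            r_hi = min(int(np.floor(r0)) + w + 1, nrows)
            c_lo = max(int(np.floor(c0)) - w, 0)
            c_hi = min(int(np.floor(c0)) + w + 1, ncols)
            if r_lo >= r_hi or c_lo >= c_hi:
                continue
            rg = np.arange(r_lo, r_hi)[:, None]
            cg = np.arange(c_lo, c_hi)[None, :]
            d2 = (rg - r0) ** 2 + (cg - c0) ** 2
            img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-d2 / (2.0 * sigma_px**2))

    img[~tissue] = 0.0
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SectionImage(
        pixels=pixels,
        tissue=tissue,
        pixel_size_um=params.pixel_size_um,
        plane=plane,
        position_um=position_um,
        thickness_um=params.thickness_um,
        transform=transform,
    )


@dataclass
class ImageSeries:
    """Uniformly spaced serial sections from one brain (one probe, one plane)."""

    sections: list[SectionImage]
    spacing_um: float
    line_id: str
    probe: str  # "tdTomato" | "cre" | "endogenous"
    replicate_index: int = 0

    def __post_init__(self) -> None:
        planes = {s.plane for s in self.sections}
        if len(planes) > 1:
            raise ValueError("sections of a series must share a plane")
        positions = [s.position_um for s in self.sections]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("section positions must be strictly increasing")

    @property
    def plane(self) -> str:
        return self.sections[0].plane if self.sections else "coronal"

    @property
    def positions(self) -> list[float]:
        return [s.position_um for s in self.sections]

    # -- I/O: PNG per section + JSON sidecar -------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, sec in enumerate(self.sections):
            Image.fromarray(sec.pixels).save(directory / f"sec_{i:03d}.png")
            Image.fromarray(sec.tissue.astype(np.uint8) * 255).save(
                directory / f"sec_{i:03d}_tissue.png"
            )
        meta = {
            "line_id": self.line_id,
            "probe": self.probe,
            "replicate_index": self.replicate_index,
            "plane": self.plane,
            "spacing_um": self.spacing_um,
            "thickness_um": self.sections[0].thickness_um if self.sections else None,
            "pixel_size_um": self.sections[0].pixel_size_um if self.sections else None,
            "positions_um": self.positions,
            "n_sections": len(self.sections),
        }
        (directory / "series.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "ImageSeries":
        directory = Path(directory)
        meta = json.loads((directory / "series.json").read_text())
        sections = []
        for i, pos in enumerate(meta["positions_um"]):
            pixels = np.asarray(Image.open(directory / f"sec_{i:03d}.png"), dtype=np.uint8)
            tissue = (
                np.asarray(Image.open(directory / f"sec_{i:03d}_tissue.png")) > 0
            )
            sections.append(
                SectionImage(
                    pixels=pixels,
                    tissue=tissue,
                    pixel_size_um=float(meta["pixel_size_um"]),
                    plane=meta["plane"],
                    position_um=float(pos),
                    thickness_um=float(meta["thickness_um"]),
                    transform=SectionTransform(
                        meta["plane"], float(pos), float(meta["pixel_size_um"])
                    ),
                )
            )
        return cls(
            sections=sections,
            spacing_um=float(meta["spacing_um"]),
            line_id=meta["line_id"],
            probe=meta["probe"],
            replicate_index=int(meta["replicate_index"]),
        )


def generate_series(
    cells: CellSet,
    annotation: AnnotationVolume,
    plane: str = "coronal",
    spacing_um: float = 200.0,
    params: RenderParams | None = None,
    seed: int = 0,
    line_id: str = "line",
    probe: str = "tdTomato",
    replicate_index: int = 0,
) -> ImageSeries:
    """Render one serial series: slabs of the default 25-um thickness sampled
    every ``spacing_um`` along the sectioning axis.

    Section count is floor((extent - thickness)/spacing) + 1, with the first
    slab flush against the volume face.
    """
    params = params or RenderParams()
    if spacing_um < params.thickness_um:
        raise ValueError(
            f"spacing {spacing_um} um smaller than thickness {params.thickness_um} um: "
            "slabs would overlap"
        )
    extent = annotation.extent_um[2] if plane == "coronal" else annotation.extent_um[0]
    n = int(np.floor((extent - params.thickness_um) / spacing_um + 1e-9)) + 1
    positions = [params.thickness_um / 2.0 + i * spacing_um for i in range(n)]
    sections = [
        render_section(
            cells, annotation, plane, pos, params=params,
            seed=int(np.random.default_rng([seed, i]).integers(0, 2**31)),
        )
        for i, pos in enumerate(positions)
    ]
    return ImageSeries(
        sections=sections,
        spacing_um=spacing_um,
        line_id=line_id,
        probe=probe,
        replicate_index=replicate_index,
    )
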