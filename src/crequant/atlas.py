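"""Toy brain atlas: hierarchical ontology plus a 3D annotation volume.

The real reference atlas pairs a tree of ~800 named structures with a
voxel-label volume; quantified image signal is unionized onto a designated
"mid-level" antichain of structures whose leaf sets tile the whole brain.
This module builds a small analog of that machinery: a three-level ontology
(root -> major divisions -> leaf structures) and a label volume in which each
leaf occupies an axis-aligned block, so structure volumes are exactly
computable and every downstream statistic has an analytic ground truth.

Axis convention: labels are indexed ``[x, y, z]`` with x = medio-lateral,
y = dorso-ventral, z = rostro-caudal. Voxel indexing is 0-based and all
intervals are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .errors import AtlasSpecError, OntologyError, PartitionViolationError

#: Acronyms of the 12 major brain divisions used in the default configuration
#: (isocortex, olfactory areas, hippocampal formation, cortical subplate,
#: striatum, pallidum, thalamus, hypothalamus, midbrain, pons, medulla,
#: cerebellum).
DIVISION_ACRONYMS_12 = (
    "Iso", "OLF", "HPF", "CTsp", "STR", "PAL", "TH", "HY", "MB", "P", "MY", "CB",
)

DIVISION_NAMES_12 = (
    "Isocortex", "Olfactory areas", "Hippocampal formation", "Cortical subplate",
    "Striatum", "Pallidum", "Thalamus", "Hypothalamus", "Midbrain", "Pons",
    "Medulla", "Cerebellum",
)

ROOT_ID = 1


@dataclass(frozen=True)
class StructureNode:
    """One node of the structure ontology."""

    id: int
    acronym: str
    name: str
    parent_id: int | None
    is_midlevel: bool = False
    is_division: bool = False


class Ontology:
    """Hierarchical structure tree with division and mid-level designations.

    Parameters
    ----------
    nodes
        The structure nodes. Ids and acronyms must be unique; exactly one
        node may have ``parent_id is None`` (the root) and every parent id
        must refer to an existing node.
    division_ids
        Ordered ids of the major divisions (12 in the default atlas).
    midlevel_ids
        Ordered ids of the mid-level partition nodes. Must form an antichain:
        no mid-level node may be an ancestor of another.
    """

    def __init__(
        self,
        nodes: Iterable[StructureNode],
        division_ids: Iterable[int] = (),
        midlevel_ids: Iterable[int] = (),
    ) -> None:
        self.nodes: dict[int, StructureNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise OntologyError(f"duplicate structure id {node.id}")
            if node.id <= 0:
                raise OntologyError(f"structure id must be positive, got {node.id}")
            self.nodes[node.id] = node
        self.division_ids = list(division_ids)
        self.midlevel_ids = list(midlevel_ids)
        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if not self.nodes:
            raise OntologyError("empty ontology")
        acronyms = [n.acronym for n in self.nodes.values()]
        if len(set(acronyms)) != len(acronyms):
            raise OntologyError("acronyms are not unique")
        roots = [n.id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}")
        self._root_id = roots[0]
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise OntologyError(
                    f"node {node.id} references missing parent {node.parent_id}"
                )
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.id)
        # acyclic + connected: every node must reach the root by parent walk
        for node in self.nodes.values():
            seen: set[int] = set()
            cur: int | None = node.id
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id
            if self._root_id not in seen:
                raise OntologyError(f"node {node.id} is disconnected from the root")
        for did in self.division_ids:
            if did not in self.nodes:
                raise OntologyError(f"division id {did} not in ontology")
        for mid in self.midlevel_ids:
            if mid not in self.nodes:
                raise OntologyError(f"mid-level id {mid} not in ontology")
        # antichain: no mid-level node is a strict ancestor of another
        midset = set(self.midlevel_ids)
        for mid in self.midlevel_ids:
            for anc in self.ancestors(mid):
                if anc in midset:
                    raise OntologyError(
                        f"mid-level set is not an antichain: {anc} is an "
                        f"ancestor of {mid}"
                    )

    @property
    def root_id(self) -> int:
        return self._root_id

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def parent(self, node_id: int) -> int | None:
        return self.nodes[node_id].parent_id

    def ancestors(self, node_id: int) -> list[int]:
        """Strict ancestors of ``node_id``, nearest first."""
        out = []
        cur = self.nodes[node_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def is_leaf(self, node_id: int) -> bool:
        return not self._children[node_id]

    def leaf_ids(self) -> list[int]:
        return [i for i in self.nodes if self.is_leaf(i)]

    def division_of(self, node_id: int) -> int | None:
        """The unique division ancestor-or-self of a node, or None."""
        divset = set(self.division_ids)
        hits = [i for i in [node_id, *self.ancestors(node_id)] if i in divset]
        if len(hits) > 1:
            raise OntologyError(f"node {node_id} has {len(hits)} division ancestors")
        return hits[0] if hits else None

    def acronym(self, node_id: int) -> str:
        return self.nodes[node_id].acronym

    def id_of_acronym(self, acronym: str) -> int:
        for node in self.nodes.values():
            if node.acronym == acronym:
                return node.id
        raise KeyError(acronym)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": n.id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_id": n.parent_id if n.parent_id is not None else -1,
                "is_midlevel": int(n.is_midlevel),
                "is_division": int(n.is_division),
            }
            for n in self.nodes.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Ontology":
        df = pd.read_csv(path)
        nodes = [
            StructureNode(
                id=int(r.id),
                acronym=str(r.acronym),
                name=str(r.name),
                parent_id=None if int(r.parent_id) < 0 else int(r.parent_id),
                is_midlevel=bool(r.is_midlevel),
                is_division=bool(r.is_division),
            )
            for r in df.itertuples()
        ]
        return cls(
            nodes,
            division_ids=[n.id for n in nodes if n.is_division],
            midlevel_ids=[n.id for n in nodes if n.is_midlevel],
        )

    def to_json(self, path: str | Path) -> None:
        def subtree(node_id: int) -> dict:
            n = self.nodes[node_id]
            return {
                "id": n.id,
                "acronym": n.acronym,
                "name": n.name,
                "is_midlevel": n.is_midlevel,
                "is_division": n.is_division,
                "children": [subtree(c) for c in self._children[node_id]],
            }

        Path(path).write_text(json.dumps(subtree(self._root_id), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Ontology":
        tree = json.loads(Path(path).read_text())
        nodes: list[StructureNode] = []

        def walk(d: dict, parent: int | None) -> None:
            nodes.append(
                StructureNode(
                    id=int(d["id"]),
                    acronym=d["acronym"],
                    name=d["name"],
                    parent_id=parent,
                    is_midlevel=bool(d["is_midlevel"]),
                    is_division=bool(d["is_division"]),
                )
            )
            for c in d.get("children", []):
                walk(c, int(d["id"]))

        walk(tree, None)
        return cls(
            nodes,
            division_ids=[n.id for n in nodes if n.is_division],
            midlevel_ids=[n.id for n in nodes if n.is_midlevel],
        )


@dataclass
class AnnotationVolume:
    """3D voxel-label volume: 0 outside the brain, else a leaf structure id."""

    voxel_size_um: float
    labels: np.ndarray  # int32, shape (nx, ny, nz)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in micrometres."""
        return tuple(d * self.voxel_size_um for d in self.labels.shape)  # type: ignore[return-value]

    def in_bounds(self, ijk: tuple[int, int, int]) -> bool:
        return all(0 <= v < d for v, d in zip(ijk, self.labels.shape))

    def voxel_of_point(self, xyz_um) -> tuple[int, int, int]:
        """Voxel index containing an atlas point (half-open voxel cells)."""
        return tuple(int(np.floor(c / self.voxel_size_um)) for c in xyz_um)  # type: ignore[return-value]

    def structure_volume_mm3(self, leaf_ids: Iterable[int]) -> float:
        """Total volume of the voxels labeled with any of ``leaf_ids``."""
        mask = np.isin(self.labels, list(leaf_ids))
        return float(mask.sum()) * (self.voxel_size_um / 1000.0) ** 3

    def validate(self, ontology: Ontology) -> None:
        labels = np.unique(self.labels)
        labels = labels[labels != 0]
        leaves = set(ontology.leaf_ids())
        for lab in labels:
            if int(lab) not in leaves:
                raise OntologyError(f"label {int(lab)} is not an ontology leaf")
        for leaf in leaves:
            if not np.any(self.labels == leaf):
                raise OntologyError(f"leaf {leaf} has no voxels")

    # -- I/O: multi-page TIFF of z-slices + JSON sidecar --------------------

    def save(self, tiff_path: str | Path, json_path: str | Path | None = None) -> None:
        tiff_path = Path(tiff_path)
        # pages are z-slices, each page (ny, nx)
        pages = np.transpose(self.labels, (2, 1, 0)).astype(np.int32)
        tifffile.imwrite(tiff_path, pages)
        sidecar = {
            "voxel_size_um": self.voxel_size_um,
            "dims": list(self.labels.shape),
            "axis_order": "pages=z, rows=y, cols=x",
        }
        if json_path is None:
            json_path = tiff_path.with_suffix(".json")
        Path(json_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, tiff_path: str | Path, json_path: str | Path | None = None) -> "AnnotationVolume":
        tiff_path = Path(tiff_path)
        if json_path is None:
            json_path = tiff_path.with_suffix(".json")
        meta = json.loads(Path(json_path).read_text())
        pages = tifffile.imread(tiff_path)
        if pages.ndim == 2:
            pages = pages[None]
        labels = np.transpose(pages, (2, 1, 0)).astype(np.int32)
        if list(labels.shape) != list(meta["dims"]):
            raise OntologyError("annotation TIFF does not match its sidecar dims")
        return cls(voxel_size_um=float(meta["voxel_size_um"]), labels=labels)


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of the toy atlas builder.

    ``shape`` is in voxels (x, y, z); the brain occupies the volume minus a
    ``margin_voxels`` shell of background on every face. Divisions are
    rostro-caudal (z) slabs of the brain box and each division is split
    dorso-ventrally (y) into its leaf structures, optionally with seeded
    jitter of the internal boundaries.

    The defaults make every structure boundary land on a multiple of 200 um
    (25-um voxels, 200-um margin, 200-um leaf blocks, 12 mm rostro-caudal
    brain extent sampled by ~60 serial sections, 5 per division slab), so the default analysis grid tiles structures exactly and
    per-structure energies have analytic ground truth. Set ``jitter_voxels``
    to study grid cells that straddle structure borders.
    """

    n_divisions: int = 12
    leaves_per_division: int = 4
    shape: tuple[int, int, int] = (48, 48, 496)
    voxel_size_um: float = 25.0
    margin_voxels: int = 8
    jitter_voxels: int = 0
    seed: int = 0
    division_acronyms: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_divisions < 1 or self.leaves_per_division < 1:
            raise AtlasSpecError("n_divisions and leaves_per_division must be >= 1")
        if any(d <= 0 for d in self.shape):
            raise AtlasSpecError(f"volume dims must be positive, got {self.shape}")
        if self.voxel_size_um <= 0:
            raise AtlasSpecError("voxel_size_um must be positive")
        if self.margin_voxels < 0:
            raise AtlasSpecError("margin_voxels must be >= 0")
        nz_brain = self.shape[2] - 2 * self.margin_voxels
        ny_brain = self.shape[1] - 2 * self.margin_voxels
        nx_brain = self.shape[0] - 2 * self.margin_voxels
        if nx_brain < 1 or ny_brain < self.leaves_per_division or nz_brain < self.n_divisions:
            raise AtlasSpecError(
                "volume too small for the requested divisions/leaves and margin"
            )


def _split(lo: int, hi: int, n: int, jitter: int, rng: np.random.Generator) -> list[int]:
    """Boundaries of n near-equal half-open blocks of [lo, hi), with jitter."""
    bounds = [lo + round((hi - lo) * k / n) for k in range(n + 1)]
    if jitter > 0:
        for k in range(1, n):
            shift = int(rng.integers(-jitter, jitter + 1))
            cand = bounds[k] + shift
            # keep boundaries strictly increasing with >= 1 voxel per block
            if bounds[k - 1] + 1 <= cand <= bounds[k + 1] - 1:
                bounds[k] = cand
    return bounds


def build_toy_atlas(spec: AtlasSpec) -> tuple[Ontology, AnnotationVolume]:
    """Build the toy ontology and annotation volume from an :class:`AtlasSpec`.

    The ontology has ``1 + n_divisions + n_divisions * leaves_per_division``
    nodes; the mid-level set defaults to the division children (the leaves).
    Deterministic for a fixed spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.division_acronyms is not None:
        div_acr = list(spec.division_acronyms)
        if len(div_acr) != spec.n_divisions:
            raise AtlasSpecError("division_acronyms length must equal n_divisions")
        div_names = list(div_acr)
    elif spec.n_divisions == 12:
        div_acr = list(DIVISION_ACRONYMS_12)
        div_names = list(DIVISION_NAMES_12)
    else:
        div_acr = [f"D{k + 1:02d}" for k in range(spec.n_divisions)]
        div_names = [f"Division {k + 1}" for k in range(spec.n_divisions)]

    nodes = [StructureNode(ROOT_ID, "root", "Brain", None)]
    division_ids, midlevel_ids = [], []
    next_id = ROOT_ID + 1
    leaf_of: dict[tuple[int, int], int] = {}
    for d in range(spec.n_divisions):
        did = next_id
        next_id += 1
        division_ids.append(did)
        nodes.append(StructureNode(did, div_acr[d], div_names[d], ROOT_ID, is_division=True))
    for d, did in enumerate(division_ids):
        for j in range(spec.leaves_per_division):
            lid = next_id
            next_id += 1
            midlevel_ids.append(lid)
            nodes.append(
                StructureNode(
                    lid,
                    f"{div_acr[d]}{j + 1}",
                    f"{div_names[d]}, part {j + 1}",
                    did,
                    is_midlevel=True,
                )
            )
            leaf_of[(d, j)] = lid

    ontology = Ontology(nodes, division_ids, midlevel_ids)

    nx, ny, nz = spec.shape
    m = spec.margin_voxels
    labels = np.zeros(spec.shape, dtype=np.int32)
    zb = _split(m, nz - m, spec.n_divisions, spec.jitter_voxels, rng)
    for d in range(spec.n_divisions):
        yb = _split(m, ny - m, spec.leaves_per_division, spec.jitter_voxels, rng)
        for j in range(spec.leaves_per_division):
            labels[m : nx - m, yb[j] : yb[j + 1], zb[d] : zb[d + 1]] = leaf_of[(d, j)]

    annotation = AnnotationVolume(voxel_size_um=spec.voxel_size_um, labels=labels)
    annotation.validate(ontology)
    return ontology, annotation


def midlevel_partition(
    ontology: Ontology, annotation: AnnotationVolume | None = None
) -> dict[int, int]:
    """Map every leaf to its unique mid-level ancestor-or-self.

    Raises :class:`PartitionViolationError` naming the offending leaf if a
    leaf has zero or more than one mid-level ancestor-or-self. If an
    annotation is given, only checks that its nonzero labels are coverable
    leaves (the full leaf set is still validated and returned).
    """
    midset = set(ontology.midlevel_ids)
    out: dict[int, int] = {}
    for leaf in ontology.leaf_ids():
        hits = [i for i in [leaf, *ontology.ancestors(leaf)] if i in midset]
        if len(hits) != 1:
            raise PartitionViolationError(
                f"leaf {leaf} ({ontology.nodes[leaf].acronym!r}) has "
                f"{len(hits)} mid-level ancestors-or-self; expected exactly 1"
            )
        out[leaf] = hits[0]
    if annotation is not None:
        present = np.unique(annotation.labels)
        for lab in present[present != 0]:
            if int(lab) not in out:
                raise PartitionViolationError(
                    f"voxel label {int(lab)} is not covered by the mid-level partition"
                )
    return out


def voxel_structure(
    annotation: AnnotationVolume,
    partition: Mapping[int, int],
    ijk: tuple[int, int, int],
) -> int | None:
    """Mid-level structure of one voxel, or None outside the brain."""
    if not annotation.in_bounds(ijk):
        raise IndexError(f"voxel index {ijk} outside dims {annotation.dims}")
    label = int(annotation.labels[tuple(int(v) for v in ijk)])
    if label == 0:
        return None
    return partition[label]


def leaf_to_midlevel_lut(
    annotation: AnnotationVolume, partition: Mapping[int, int]
) -> np.ndarray:
    """Dense lookup table label -> mid-level id (0 -> 0) for vectorized use."""
    top = max(int(annotation.labels.max()), max(partition, default=0))
    lut = np.zeros(top + 1, dtype=np.int32)
    for leaf, mid in partition.items():
        if leaf <= top:
            lut[leaf] = mid
    return lut
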