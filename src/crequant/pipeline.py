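"""End-to-end reproducible runs: simulate -> segment -> quantify -> analyze.

A run is driven by a single :class:`RunConfig` (YAML or JSON) holding the
atlas spec, the roster of simulated lines (pattern assignments, faithfulness
category, 1-6 replicates, sectioning plane), segmentation and grid
parameters, and one top-level seed. Per-stage seeds are derived by stable
hashing of (seed, stage, line, probe, replicate), so replicates differ from
each other but the whole run is bit-reproducible. Every output table is
checksummed into a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .atlas import AnnotationVolume, AtlasSpec, Ontology, build_toy_atlas, midlevel_partition
from .errors import ConfigError
from .quantify import (
    EnergyVector,
    assign_grid_structures,
    division_summary,
    expression_energy,
    grid_section,
)
from .segmentation import segment_section
from .synthetic import (
    DEFAULT_BASE_DENSITY,
    GroundTruthExpression,
    ImageSeries,
    RenderParams,
    generate_series,
    make_line_pair,
    place_cells,
    sample_ground_truth,
)

logger = logging.getLogger("crequant")

VERSION = "0.1.0"


def derive_seed(*parts: Any) -> int:
    """Stable sub-2^31 seed from arbitrary parts (hash of their string forms)."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class LineSpec:
    """One simulated Cre line."""

    line_id: str
    assignments: dict[str, str]  # structure acronym -> pattern category
    faithfulness: int = 1
    n_replicates: int = 2
    plane: str = "coronal"

    def validate(self) -> None:
        if not 1 <= self.n_replicates <= 6:
            raise ConfigError(
                f"line {self.line_id}: n_replicates must be in 1-6, "
                f"got {self.n_replicates}"
            )
        if self.faithfulness not in (1, 2, 3):
            raise ConfigError(f"line {self.line_id}: faithfulness must be 1, 2 or 3")
        if self.plane not in ("coronal", "sagittal"):
            raise ConfigError(f"line {self.line_id}: unknown plane {self.plane!r}")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    lines: list[LineSpec]
    atlas: AtlasSpec = field(default_factory=AtlasSpec)
    base_density: float = DEFAULT_BASE_DENSITY
    render: RenderParams = field(default_factory=RenderParams)
    spacing_um: float = 200.0
    k: float = 3.0
    s_min: float = 2.0
    grid_size_um: float = 200.0
    seed: int = 0
    outdir: str = "run_out"

    def validate(self) -> None:
        self.atlas.validate()
        if not self.lines:
            raise ConfigError("config lists no lines")
        for line in self.lines:
            line.validate()

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        lines = [LineSpec(**ls) for ls in d.pop("lines", [])]
        atlas_kwargs = dict(d.pop("atlas", {}))
        if "shape" in atlas_kwargs:
            atlas_kwargs["shape"] = tuple(atlas_kwargs["shape"])
        if "division_acronyms" in atlas_kwargs and atlas_kwargs["division_acronyms"]:
            atlas_kwargs["division_acronyms"] = tuple(atlas_kwargs["division_acronyms"])
        atlas = AtlasSpec(**atlas_kwargs)
        render = RenderParams(**d.pop("render", {}))
        cfg = cls(lines=lines, atlas=atlas, render=render, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        # YAML with JSON accepted (JSON is a YAML subset)
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "lines": [asdict(ls) for ls in self.lines],
            "atlas": asdict(self.atlas),
            "base_density": self.base_density,
            "render": asdict(self.render),
            "spacing_um": self.spacing_um,
            "k": self.k,
            "s_min": self.s_min,
            "grid_size_um": self.grid_size_um,
            "seed": self.seed,
            "outdir": self.outdir,
        }


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def quantify_series(
    series: ImageSeries,
    annotation: AnnotationVolume,
    partition: Mapping[int, int],
    k: float = 3.0,
    s_min: float = 2.0,
    grid_size_um: float = 200.0,
) -> EnergyVector:
    """Segment, grid and unionize one image series into an energy vector.

    Sections that contain no tissue (slabs falling in the background margin)
    are skipped, mirroring blank slides at the ends of a real series.
    """
    grids = []
    for sec in series.sections:
        if not sec.tissue.any():
            continue
        mask = segment_section(sec, k=k, s_min=s_min)
        grid = grid_section(sec, mask, grid_size_um=grid_size_um)
        grids.append(assign_grid_structures(grid, annotation, partition))
    return expression_energy(
        grids,
        partition,
        line_id=series.line_id,
        probe=series.probe,
        plane=series.plane,
    )


def simulate_line_datasets(
    line: LineSpec,
    ontology: Ontology,
    annotation: AnnotationVolume,
    partition: Mapping[int, int],
    config: RunConfig,
    save_images_to: Path | None = None,
) -> dict[str, tuple[GroundTruthExpression, list[ImageSeries]]]:
    """Simulate the endogenous-gene and reporter datasets of one line.

    Returns {probe: (ground truth, replicate series)}, probes "endogenous"
    (the gene's own pattern) and "tdTomato" (the Cre-derived pattern under
    the line's faithfulness category).
    """
    assignments = {
        ontology.id_of_acronym(acr): cat for acr, cat in line.assignments.items()
    }
    gt_gene = sample_ground_truth(
        ontology, assignments, base_density=config.base_density,
        seed=derive_seed(config.seed, "gt", line.line_id),
    )
    _, gt_cre = make_line_pair(
        gt_gene, line.faithfulness, seed=derive_seed(config.seed, "pair", line.line_id)
    )
    out: dict[str, tuple[GroundTruthExpression, list[ImageSeries]]] = {}
    for probe, gt in (("endogenous", gt_gene), ("tdTomato", gt_cre)):
        series_list = []
        for rep in range(line.n_replicates):
            cells = place_cells(
                gt, annotation, partition,
                seed=derive_seed(config.seed, "cells", line.line_id, probe, rep),
            )
            series = generate_series(
                cells, annotation, plane=line.plane, spacing_um=config.spacing_um,
                params=config.render,
                seed=derive_seed(config.seed, "render", line.line_id, probe, rep),
                line_id=line.line_id, probe=probe, replicate_index=rep,
            )
            if save_images_to is not None:
                series.save(save_images_to / f"{line.line_id}_{probe}_r{rep}")
            series_list.append(series)
        out[probe] = (gt, series_list)
    return out


def run_pipeline(config: RunConfig, save_images: bool = False) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    tables: dict[str, str] = {}

    def emit(name: str, write) -> Path:
        path = outdir / name
        write(path)
        tables[name] = sha256_of(path)
        return path

    # stage: atlas
    try:
        ontology, annotation = build_toy_atlas(config.atlas)
        partition = midlevel_partition(ontology, annotation)
        emit("ontology.csv", ontology.to_csv)
        ontology.to_json(outdir / "ontology.json")
        annotation.save(outdir / "annotation.tiff")
    except Exception as exc:
        raise RuntimeError(f"stage 'atlas' failed: {exc}") from exc
    logger.info("atlas built in %.2fs", time.time() - t0)

    energies: dict[str, dict[str, list[EnergyVector]]] = {}
    for line in config.lines:
        t_line = time.time()
        stage = f"simulate/quantify line {line.line_id}"
        try:
            datasets = simulate_line_datasets(
                line, ontology, annotation, partition, config,
                save_images_to=(outdir / "images") if save_images else None,
            )
            energies[line.line_id] = {}
            for probe, (gt, series_list) in datasets.items():
                emit(f"ground_truth_{line.line_id}_{probe}.csv", gt.to_csv)
                evs = []
                for series in series_list:
                    ev = quantify_series(
                        series, annotation, partition,
                        k=config.k, s_min=config.s_min,
                        grid_size_um=config.grid_size_um,
                    )
                    emit(
                        f"energy_{line.line_id}_{probe}_r{series.replicate_index}.csv",
                        lambda p, ev=ev: ev.to_csv(p, ontology=ontology),
                    )
                    evs.append(ev)
                energies[line.line_id][probe] = evs
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("line %s done in %.2fs", line.line_id, time.time() - t_line)

    # stage: correlate
    try:
        results = [
            analysis.line_correlation(
                energies[line.line_id]["endogenous"],
                energies[line.line_id]["tdTomato"],
                comparison="gene_vs_reporter",
            )
            for line in config.lines
        ]
        bins = analysis.percentile_bins({r.line_id: r.mean_rho for r in results})
        corr_df = analysis.correlation_report(results, bins)
        emit("correlations.csv", lambda p: corr_df.to_csv(p, index=False))
    except Exception as exc:
        raise RuntimeError(f"stage 'correlate' failed: {exc}") from exc

    # stage: enrich (reporter exemplar = replicate 0, as one series per line)
    try:
        exemplars = [energies[line.line_id]["tdTomato"][0] for line in config.lines]
        enr = analysis.fold_change_table(exemplars)
        emit("enrichment.csv", lambda p: enr.to_csv(p, index=False))
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    manifest = {
        "version": VERSION,
        "seed": config.seed,
        "config": config.to_dict(),
        "outdir": str(outdir),
        "tables": tables,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def summarize_run(manifest: Mapping[str, Any] | str | Path, top_n: int = 5) -> str:
    """Human-readable report: per-line division summaries, bins, top fold changes.

    Regeneration from the same manifest is byte-stable. Missing tables mark
    their section unavailable instead of failing.
    """
    if not isinstance(manifest, Mapping):
        manifest = json.loads(Path(manifest).read_text())
    outdir = Path(manifest["outdir"])
    lines = [ls["line_id"] for ls in manifest["config"]["lines"]]
    chunks = [f"crequant run report (seed={manifest['seed']}, version={manifest['version']})"]

    try:
        ontology = Ontology.from_csv(outdir / "ontology.csv")
    except OSError:
        ontology = None
        chunks.append("[ontology table unavailable]")

    try:
        corr = pd.read_csv(outdir / "correlations.csv")
    except OSError:
        corr = None
        chunks.append("[correlation table unavailable]")

    try:
        enr = pd.read_csv(outdir / "enrichment.csv")
    except OSError:
        enr = None
        chunks.append("[enrichment table unavailable]")

    for line_id in lines:
        chunks.append(f"\n== line {line_id} ==")
        ev_path = outdir / f"energy_{line_id}_tdTomato_r0.csv"
        if ontology is not None and ev_path.exists():
            ev = EnergyVector.from_csv(ev_path)
            div = division_summary(ev, ontology)
            chunks.append("division energies (reporter, replicate 0):")
            for did in ontology.division_ids:
                val = div[did]
                shown = "missing" if np.isnan(val) else f"{val:.4f}"
                chunks.append(f"  {ontology.acronym(did):>5s}  {shown}")
        else:
            chunks.append("[energy table unavailable]")
        if corr is not None:
            row = corr[corr["line_id"] == line_id]
            if len(row):
                r = row.iloc[0]
                chunks.append(
                    f"gene-vs-reporter mean rho = {r.mean_rho:.3f} "
                    f"(mean rho^2 = {r.mean_rho_sq:.3f}, n_pairs = {r.n_pairs}, "
                    f"bin = {r.percentile_bin})"
                )
        if enr is not None:
            sub = enr[(enr["line_id"] == line_id) & enr["fold_change"].notna()]
            sub = sub.sort_values(
                ["fold_change", "structure_id"], ascending=[False, True]
            ).head(top_n)
            if len(sub):
                chunks.append(f"top {top_n} enriched structures (fold change over whole brain):")
                for r in sub.itertuples():
                    acr = ontology.acronym(int(r.structure_id)) if ontology else str(r.structure_id)
                    chunks.append(f"  {acr:>6s}  F = {r.fold_change:.2f}")
            else:
                chunks.append("fold changes missing (no detected expression)")
    return "\n".join(chunks) + "\n"
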