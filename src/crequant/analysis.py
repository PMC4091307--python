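"""Downstream statistics on expression-energy profiles.

Implements the comparisons used to judge how faithfully a Cre line's
recombination pattern tracks its endogenous gene: plane-matched,
replicate-averaged Spearman rank correlations between two datasets of a
line; a replicate-to-replicate baseline; quartile binning of per-line mean
correlations (high / mid / low / very low); fold-change enrichment of each
structure over the whole-brain mean with per-structure line ranking; and
two-tailed t-test group comparisons (paired, or Welch for independent
groups).

Structures missing in either profile (no grids sampled them) are dropped
pairwise before ranking — a deliberately different thing from an energy of
zero, which is kept. No expression-energy floor is applied before fold
changes, so very low-expression structures can top an enrichment ranking and
should be sanity-checked against their absolute energy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncomparableDatasetsError, UndefinedCorrelationError
from .quantify import EnergyVector

BIN_LABELS = ("high", "mid", "low", "very_low")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Positions that are NaN in either vector are dropped first. Requires at
    least 3 complete pairs and nonzero rank variance on both sides;
    otherwise raises :class:`UndefinedCorrelationError` (never a silent 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 complete pairs, got {x.size}"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CorrelationResult:
    """Replicate-averaged rank correlation between two datasets of one line."""

    line_id: str
    comparison: str  # "gene_vs_reporter" | "gene_vs_cre" | "replicate"
    pair_rhos: list[float]
    percentile_bin: str = "unbinned"

    @property
    def n_pairs(self) -> int:
        return len(self.pair_rhos)

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.pair_rhos))

    @property
    def mean_rho_sq(self) -> float:
        """Mean of the squared pair correlations (not the square of the mean)."""
        return float(np.mean(np.square(self.pair_rhos)))


def _common_profile(a: EnergyVector, b: EnergyVector) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(set(a.energy) & set(b.energy))
    return (
        np.array([a.energy[s] for s in common]),
        np.array([b.energy[s] for s in common]),
    )


def line_correlation(
    datasets_a: Sequence[EnergyVector],
    datasets_b: Sequence[EnergyVector],
    comparison: str = "gene_vs_reporter",
    line_id: str | None = None,
) -> CorrelationResult:
    """Average Spearman correlation over all plane-matched replicate pairs.

    Every cross pair (a, b) sharing a sectioning plane contributes one rho,
    computed over the structures present (non-missing) in both profiles.
    Plane-mismatched pairs are skipped; if no pair shares a plane, raises
    :class:`IncomparableDatasetsError`.
    """
    if not datasets_a or not datasets_b:
        raise IncomparableDatasetsError("both sides need at least one replicate")
    rhos = []
    for a, b in itertools.product(datasets_a, datasets_b):
        if a.plane != b.plane:
            continue
        xa, xb = _common_profile(a, b)
        rhos.append(spearman_rho(xa, xb))
    if not rhos:
        raise IncomparableDatasetsError(
            "no plane-matched replicate pair between the two datasets"
        )
    return CorrelationResult(
        line_id=line_id or datasets_a[0].line_id,
        comparison=comparison,
        pair_rhos=rhos,
    )


def replicate_baseline(lines: Mapping[str, Sequence[EnergyVector]]) -> float:
    """Mean over lines of the within-line mean pairwise replicate correlation.

    Only lines with at least one plane-matched replicate pair are eligible;
    each eligible line contributes exactly once regardless of its replicate
    count. Raises if no line is eligible.
    """
    line_means = []
    for line_id, evs in lines.items():
        rhos = []
        for a, b in itertools.combinations(evs, 2):
            if a.plane != b.plane:
                continue
            xa, xb = _common_profile(a, b)
            rhos.append(spearman_rho(xa, xb))
        if rhos:
            line_means.append(float(np.mean(rhos)))
    if not line_means:
        raise IncomparableDatasetsError(
            "no line with >= 2 plane-matched replicates"
        )
    return float(np.mean(line_means))


def percentile_bins(values: Mapping[str, float]) -> dict[str, str]:
    """Quartile-bin per-line mean correlations.

    Thresholds use the inclusive linear-interpolation quartile definition;
    boundary values assign upward (a value equal to Q3 is "high", equal to
    the median is "mid", equal to Q1 is "low"). With fewer than 4 values
    every line is "unbinned".
    """
    keys = list(values)
    if len(keys) < 4:
        return {k: "unbinned" for k in keys}
    arr = np.array([values[k] for k in keys], dtype=float)
    q1, q2, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    out = {}
    for k, v in zip(keys, arr):
        if v >= q3:
            out[k] = "high"
        elif v >= q2:
            out[k] = "mid"
        elif v >= q1:
            out[k] = "low"
        else:
            out[k] = "very_low"
    return out


def fold_change_table(
    evs: Sequence[EnergyVector],
    annotation_categories: Mapping[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """Per-(line, structure) fold change of energy over the whole-brain mean.

    F = E_s / W with W the line's whole-brain energy. No expression floor is
    applied before the ratio, so rankings should be read alongside the
    absolute energy. F is NaN (with a reason in ``note``) when the structure
    is missing or W = 0. One row per (line, structure).
    """
    rows = []
    for ev in evs:
        w = ev.whole_brain_energy
        for sid in sorted(set(ev.energy) | ev.missing):
            if sid in ev.missing:
                f, note = np.nan, "missing_energy"
            elif w == 0:
                f, note = np.nan, "zero_whole_brain"
            else:
                f, note = ev.energy[sid] / w, ""
            rows.append(
                {
                    "line_id": ev.line_id,
                    "structure_id": sid,
                    "energy": ev.energy.get(sid, np.nan),
                    "whole_brain_energy": w,
                    "fold_change": f,
                    "note": note,
                    "category": (
                        annotation_categories.get((ev.line_id, sid), "")
                        if annotation_categories
                        else ""
                    ),
                }
            )
    return pd.DataFrame(rows)


def rank_lines_for_structure(table: pd.DataFrame, structure_id: int) -> list[str]:
    """Lines sorted by descending fold change in one structure.

    Missing fold changes sort last; ties (including among missing) break by
    lexical line id. Raises ValueError for a structure absent from the table.
    """
    sub = table[table["structure_id"] == structure_id]
    if sub.empty:
        raise ValueError(f"structure {structure_id} not present in the table")
    sub = sub.copy()
    sub["_missing"] = sub["fold_change"].isna()
    sub = sub.sort_values(
        by=["_missing", "fold_change", "line_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return list(sub["line_id"])


@dataclass(frozen=True)
class GroupCompareResult:
    t: float
    df: float
    p: float


def group_compare(a: Sequence[float], b: Sequence[float], paired: bool = False) -> GroupCompareResult:
    """Two-tailed t-test between two groups of scalars.

    Paired: one-sample t on the differences (requires equal sizes, >= 2
    pairs). Unpaired: Welch's unequal-variance t (>= 2 per group). Degenerate
    zero-variance data with equal means give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal size")
        if a.size < 2:
            raise ValueError("need >= 2 pairs")
        d = a - b
        dof = float(a.size - 1)
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return GroupCompareResult(0.0, dof, 1.0)
            return GroupCompareResult(float(np.inf) * np.sign(d.mean()), dof, 0.0)
        res = stats.ttest_1samp(d, 0.0)
        return GroupCompareResult(float(res.statistic), dof, float(res.pvalue))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        dof = float(a.size + b.size - 2)
        if np.allclose(a.mean(), b.mean()):
            return GroupCompareResult(0.0, dof, 1.0)
        return GroupCompareResult(float(np.inf) * np.sign(a.mean() - b.mean()), dof, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    dof = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return GroupCompareResult(float(res.statistic), float(dof), float(res.pvalue))


def correlation_report(
    results: Sequence[CorrelationResult], bins: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Tabular report of per-line correlation results."""
    return pd.DataFrame(
        [
            {
                "line_id": r.line_id,
                "comparison": r.comparison,
                "n_pairs": r.n_pairs,
                "mean_rho": r.mean_rho,
                "mean_rho_sq": r.mean_rho_sq,
                "percentile_bin": (bins or {}).get(r.line_id, r.percentile_bin),
            }
            for r in results
        ]
    )
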