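"""Fiber-to-stimulation incidence.

A fiber counts as connected to a stimulation if, after resampling the
polyline finely enough that no voxel can be skipped between consecutive
vertices, at least one vertex falls inside a true voxel of any of the
stimulation's masks (bilateral volumes are OR-combined: one clinical
observation per setting). Membership is nearest-voxel rounding of the
inverse-affine image of the point, matching voxel-center mask semantics.

The default resampling step is half the smallest voxel edge across all
masks, which guarantees the vertex chain cannot straddle a voxel without
touching it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import CohortTable, Streamline, Tractogram

__all__ = ["IncidenceMatrix", "resample_streamline", "compute_incidence"]


@dataclass
class IncidenceMatrix:
    """Binary fiber x stimulation connectivity."""

    entries: np.ndarray  # (n_fibers, n_stims) bool
    fiber_ids: np.ndarray  # (n_fibers,) int64
    stim_ids: list[str]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=bool)
        self.fiber_ids = np.asarray(self.fiber_ids, dtype=np.int64)
        if self.entries.shape != (len(self.fiber_ids), len(self.stim_ids)):
            raise ValueError("entries shape does not match fiber/stim label counts")

    @property
    def n_fibers(self) -> int:
        return self.entries.shape[0]

    @property
    def n_stims(self) -> int:
        return self.entries.shape[1]

    def n_connected_per_fiber(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def to_triplets(self, path: str | Path) -> None:
        """Export as sparse triplet TSV (fiber_id, stim_id, 1)."""
        f_idx, s_idx = np.nonzero(self.entries)
        pd.DataFrame(
            {
                "fiber_id": self.fiber_ids[f_idx],
                "stim_id": [self.stim_ids[j] for j in s_idx],
                "value": 1,
            }
        ).to_csv(path, sep="\t", index=False)

    def to_dense(self, path: str | Path) -> None:
        """Dense 0/1 matrix writer for small instances."""
        df = pd.DataFrame(self.entries.astype(np.int8), columns=self.stim_ids)
        df.insert(0, "fiber_id", self.fiber_ids)
        df.to_csv(path, sep="\t", index=False)


def resample_streamline(s: Streamline, max_step: float) -> Streamline:
    """Subdivide segments so every inter-vertex distance is <= max_step.

    Original vertices are preserved, so the geometric path (and its arc
    length) is unchanged; a polyline already satisfying the bound is
    returned as-is.
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    pts = s.points
    seg = np.diff(pts, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if np.all(lengths <= max_step):
        return s
    out = [pts[:1]]
    for i, (length, vec) in enumerate(zip(lengths, seg)):
        n_sub = max(1, int(np.ceil(length / max_step)))
        frac = np.arange(1, n_sub + 1, dtype=np.float64)[:, None] / n_sub
        out.append(pts[i] + frac * vec)
    return Streamline(s.id, np.vstack(out))


def default_max_step(cohort: CohortTable) -> float:
    """Half the smallest voxel edge across every mask of the cohort."""
    edges = [mask.voxel_sizes.min() for rec in cohort for mask in rec.masks]
    if not edges:
        raise ValueError("cohort has no masks")
    return 0.5 * float(min(edges))


def compute_incidence(
    tractogram: Tractogram,
    cohort: CohortTable,
    max_step: float | None = None,
    space_tag: str | None = None,
) -> IncidenceMatrix:
    """Build the binary incidence matrix between fibers and stimulations.

    Parameters
    ----------
    tractogram
        Streamlines in the same world frame as the cohort's masks.
    cohort
        Stimulation records; all masks of one record are OR-combined.
    max_step
        Resampling bound in mm. Defaults to half the smallest voxel edge
        of any mask; larger values risk skipping voxels and are rejected.
    space_tag
        If given, must match the tractogram's tag (guards against mixing
        reference spaces).
    """
    if space_tag is not None and tractogram.space_tag != space_tag:
        raise ValueError(
            f"space mismatch: tractogram is {tractogram.space_tag!r}, cohort expects {space_tag!r}"
        )
    min_edge = 2.0 * default_max_step(cohort)
    if max_step is None:
        max_step = 0.5 * min_edge
    elif max_step > min_edge:
        raise ValueError(
            f"max_step {max_step} exceeds the smallest voxel edge {min_edge}; "
            "voxels could be skipped between vertices"
        )

    # Resample once, then flatten all vertices with a fiber index for
    # vectorized per-mask membership lookups.
    resampled = [resample_streamline(s, max_step) for s in tractogram]
    counts = np.array([len(s.points) for s in resampled])
    points = np.vstack([s.points for s in resampled]) if resampled else np.empty((0, 3))
    fiber_idx = np.repeat(np.arange(len(resampled)), counts)

    entries = np.zeros((len(resampled), len(cohort)), dtype=bool)
    for j, rec in enumerate(cohort):
        hit = np.zeros(len(points), dtype=bool)
        for mask in rec.masks:
            if mask.n_support == 0:
                warnings.warn(
                    f"stimulation {rec.stim_id}: mask has empty support", stacklevel=2
                )
                continue
            hit |= mask.contains(points)
        if hit.any():
            entries[np.unique(fiber_idx[hit]), j] = True
    return IncidenceMatrix(entries, tractogram.fiber_ids, cohort.stim_ids)
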