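"""Published stereotactic DBS targets for OCD and their tract overlap.

The OCD-DBS literature reports a dozen distinct surgical targets. This
module embeds their standard-space (MNI) coordinates and the average
percent Y-BOCS improvements the source studies reported, builds spherical
stand-in stimulation volumes at each coordinate pair (both hemispheres),
scores them against a fitted fiber-weight model, and correlates the
weighted tract overlap with the reported improvements. Targets without a
reported improvement (several case series report none) stay in the table
but are excluded from the correlation.

The sphere at the printed coordinate is a declared proxy for each study's
stimulation field; its radius is a parameter (default 3 mm) meant for
sensitivity sweeps rather than a claim about any device geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import compute_incidence
from .fiber_stats import FiberScoreModel
from .formats import CohortTable, MaskVolume, StimulationRecord, Tractogram
from .prediction import PredictionResult, aggregate_scores, permutation_p
from .volumes import sphere_mask

__all__ = [
    "LiteratureTarget",
    "builtin_targets",
    "sphere_stimulation",
    "score_literature_targets",
    "targets_to_csv",
]


@dataclass(frozen=True)
class LiteratureTarget:
    """One published DBS target: name, bilateral MNI coordinate, outcome."""

    name: str
    mni_xyz: tuple[float, float, float]  # x is the magnitude; expanded to +-x
    reported_improvement_pct: float | None
    target_type: str  # "tip of the electrode" or "active contacts"

    def hemisphere_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x, y, z = self.mni_xyz
        return np.array([+abs(x), y, z]), np.array([-abs(x), y, z])


# MNI coordinates and reported average %-Y-BOCS improvements of published
# OCD-DBS targets. Missing improvements are None. Three thalamic rows
# (MD, VA, iml) come from one study reporting a single 10.7% average; all
# three are kept as separate spatial points.
_TARGETS: list[tuple[str, tuple[float, float, float], float | None, str]] = [
    ("STN", (11.30, -9.90, -7.81), 32.1, "tip of the electrode"),
    ("amGPi", (15.66, -1.41, -8.22), None, "tip of the electrode"),
    ("VC/VS", (7.92, 5.51, -9.01), 7.7, "tip of the electrode"),
    ("slMFB", (8.35, -13.64, -7.00), 41.7, "active contacts"),
    ("NAcc", (6.98, 3.69, -10.55), None, "tip of the electrode"),
    ("ALIC", (13.84, 5.17, -5.04), 38.7, "tip of the electrode"),
    ("MD", (5.10, -18.17, 2.59), 10.7, "active contacts"),
    ("VA", (7.52, -12.68, 5.60), 10.7, "active contacts"),
    ("iml", (6.36, -13.99, 4.85), 10.7, "active contacts"),
    ("ITP", (6.92, -1.84, -5.13), 52.0, "tip of the electrode"),
    ("BNST", (6.33, 1.39, -4.87), None, "tip of the electrode"),
]


def builtin_targets() -> list[LiteratureTarget]:
    """All published targets, one entry per site (hemispheres via the type)."""
    return [LiteratureTarget(n, xyz, imp, tt) for n, xyz, imp, tt in _TARGETS]


def targets_to_csv(path, targets: list[LiteratureTarget] | None = None) -> None:
    targets = targets if targets is not None else builtin_targets()
    pd.DataFrame(
        [
            {
                "name": t.name,
                "mni_x": t.mni_xyz[0],
                "mni_y": t.mni_xyz[1],
                "mni_z": t.mni_xyz[2],
                "reported_improvement_pct": t.reported_improvement_pct,
                "target_type": t.target_type,
            }
            for t in targets
        ]
    ).to_csv(path, index=False)


def sphere_stimulation(
    center: np.ndarray,
    radius: float,
    grid: MaskVolume,
    stim_id: str = "sphere",
    improvement_pct: float = float("nan"),
) -> StimulationRecord:
    """A unit-amplitude spherical stimulation volume on the template grid.

    Amplitude is fixed at 1 so amplitude normalization is a no-op for
    these literature stand-ins.
    """
    mask = sphere_mask(np.asarray(center, dtype=np.float64), radius, grid)
    return StimulationRecord(
        stim_id=stim_id,
        patient_id=stim_id,
        cohort="literature",
        masks=[mask],
        amplitude=1.0,
        improvement_pct=improvement_pct,
    )


def score_literature_targets(
    targets: list[LiteratureTarget],
    radius: float,
    tractogram: Tractogram,
    model: FiberScoreModel,
    grid: MaskVolume,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> PredictionResult:
    """Correlate per-target tract overlap with reported improvements.

    Each target contributes one bilateral stimulation record (left and
    right spheres OR-combined), scored by the aggregate fiber t-score of
    the fitted model; targets without a reported improvement are excluded
    before correlating.
    """
    scored = [t for t in targets if t.reported_improvement_pct is not None]
    if len(scored) < 3:
        raise ValueError(f"need at least 3 targets with reported improvements, got {len(scored)}")
    records = []
    for t in scored:
        right, left = t.hemisphere_centers()
        rec = StimulationRecord(
            stim_id=t.name,
            patient_id=t.name,
            cohort="literature",
            masks=[sphere_mask(right, radius, grid), sphere_mask(left, radius, grid)],
            amplitude=1.0,
            improvement_pct=float(t.reported_improvement_pct),
        )
        records.append(rec)
    cohort = CohortTable(records, name="literature")
    inc = compute_incidence(tractogram, cohort)
    agg = aggregate_scores(inc, model, cohort)
    if np.ptp(agg.score) == 0:
        raise ValueError(
            "all targets received identical overlap (is the model all-zero?); "
            "correlation undefined"
        )
    return permutation_p(agg, cohort.improvements, n_perm=n_perm, seed=seed, method=method)
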