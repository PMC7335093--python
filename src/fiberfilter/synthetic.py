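"""Synthetic connectomes and stimulation cohorts with a planted effect.

Real inputs to this kind of analysis — a normative tractogram, binary
stimulation volumes and clinical outcomes — are patient data that cannot
ship with a package. The generator emulates their statistical structure:

* a coherent *planted bundle* of streamlines following one smooth
  centerline with Gaussian radial scatter (the ground-truth predictive
  tract),
* a bulk of incoherent *background* fibers (correlated random walks in a
  bounding box) standing in for the non-predictive majority of a
  whole-brain connectome,
* cohorts of spherical stimulation volumes whose outcome follows
  ``improvement = beta * overlap + noise``, where *overlap* is the
  fraction of planted fibers the stimulation sphere touches.

Every draw flows from one per-call seed through ``numpy`` seed-sequence
spawning, so each stimulation's draws are reproducible independent of
draw order. A ground-truth sidecar records every draw, sufficient to
recompute the outcomes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .connectivity import resample_streamline
from .formats import CohortTable, MaskVolume, StimulationRecord, Streamline, Tractogram
from .volumes import make_grid, sphere_mask

__all__ = [
    "BundleSpec",
    "CohortSpec",
    "make_bundle",
    "make_background",
    "make_cohort",
    "default_bundle_spec",
    "default_grid",
    "default_connectome",
    "default_cohort_specs",
]

SPACE_TAG = "synthetic"


@dataclass
class BundleSpec:
    """Geometry of a planted bundle."""

    waypoints: Sequence[Sequence[float]]
    n_fibers: int = 200
    radial_sd: float = 2.0  # mm, Gaussian scatter of fibers around the centerline
    step: float = 1.0  # mm, max vertex spacing
    label: str = "bundle"

    def __post_init__(self) -> None:
        wp = np.asarray(self.waypoints, dtype=np.float64)
        if wp.ndim != 2 or wp.shape[1] != 3 or wp.shape[0] < 2:
            raise ValueError("waypoints must be >= 2 coordinates in 3D")
        if self.n_fibers < 0 or self.radial_sd < 0 or self.step <= 0:
            raise ValueError("invalid bundle parameters")
        self.waypoints = wp


@dataclass
class CohortSpec:
    """Stimulation-cohort generator settings.

    The outcome model is linear in the overlap fraction *o* between each
    stimulation sphere and the planted bundle:
    ``improvement_pct = effect_beta * o + Normal(0, noise_sd)``.
    """

    n_stims: int = 20
    center_mean: Sequence[float] = (0.0, 4.0, 7.0)
    center_sd: Sequence[float] = (10.0, 4.0, 4.0)
    amplitude_range: tuple[float, float] = (2.0, 4.5)  # volts
    radius_map: Callable[[float], float] = lambda a: 1.5 + a  # mm per volt offset
    effect_beta: float = 60.0  # improvement units per unit overlap fraction
    noise_sd: float = 10.0  # improvement units
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        lo, hi = self.amplitude_range
        if lo <= 0 or hi < lo:
            raise ValueError("amplitude range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0 or self.n_stims < 0:
            raise ValueError("invalid cohort parameters")
        if self.radius_map(hi) <= self.radius_map(lo) and hi > lo:
            raise ValueError("radius_map must be strictly increasing")


def _centerline(waypoints: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Smooth centerline through the waypoints; returns (points, unit tangents)."""
    chord = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, waypoints, axis=0)
    n = max(int(np.ceil(u[-1] / step)) * 2, 2) + 1  # oversample, resampled later
    s = np.linspace(0.0, u[-1], n)
    pts = spline(s)
    tan = spline(s, 1)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def _normal_frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit normals per vertex spanning the plane orthogonal to the tangent."""
    ref = np.array([0.0, 0.0, 1.0])
    if np.max(np.abs(tangents @ ref)) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(tangents, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    return n1, n2


def make_bundle(spec: BundleSpec, seed: int = 0) -> Tractogram:
    """Generate a coherent bundle of smooth streamlines around one centerline.

    Each fiber is displaced from the centerline in the local normal plane
    by a Gaussian offset (sd ``radial_sd`` per axis) interpolated smoothly
    between a few stations along the arc, so individual fibers wander
    gently rather than staying parallel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    center, tan = _centerline(spec.waypoints, spec.step)
    n1, n2 = _normal_frame(tan)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(center, axis=0), axis=1))])
    s_norm = arc / arc[-1]
    stations = np.linspace(0.0, 1.0, 4)
    fibers = []
    for i in range(spec.n_fibers):
        coeff = rng.normal(0.0, spec.radial_sd, size=(2, len(stations)))
        a = CubicSpline(stations, coeff[0])(s_norm)
        b = CubicSpline(stations, coeff[1])(s_norm)
        pts = center + a[:, None] * n1 + b[:, None] * n2
        fibers.append(resample_streamline(Streamline(i, pts), spec.step))
    return Tractogram(fibers, space_tag=SPACE_TAG)


def make_background(
    n_fibers: int,
    bounding_box: Sequence[tuple[float, float]] = ((-32, 32), (-32, 32), (-32, 32)),
    length_range: tuple[float, float] = (20.0, 60.0),
    smoothness: float = 0.85,
    seed: int = 0,
    id_offset: int = 0,
    step: float = 1.0,
) -> Tractogram:
    """Incoherent background fibers: correlated random walks inside a box.

    ``smoothness`` in [0, 1) is the momentum of the walk (0 gives jagged
    white-noise paths, values near 1 nearly straight ones). Walks bounce
    off the box faces, so arc lengths land exactly in ``length_range``.
    """
    box = np.asarray(bounding_box, dtype=np.float64)
    if box.shape != (3, 2) or np.any(box[:, 1] <= box[:, 0]):
        raise ValueError("bounding box must be three nondegenerate (lo, hi) pairs")
    if not 0 <= smoothness < 1:
        raise ValueError("smoothness must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fibers = []
    for i in range(n_fibers):
        total = rng.uniform(*length_range)
        n_seg = max(2, int(np.ceil(total / step)))
        seg_len = total / n_seg
        pos = rng.uniform(box[:, 0], box[:, 1])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts = [pos]
        for _ in range(n_seg):
            kick = rng.normal(size=3)
            kick /= np.linalg.norm(kick)
            direction = smoothness * direction + (1.0 - smoothness) * kick
            direction /= np.linalg.norm(direction)
            nxt = pos + seg_len * direction
            for d in range(3):  # specular bounce keeps the walk inside the box
                if nxt[d] < box[d, 0] or nxt[d] > box[d, 1]:
                    direction[d] = -direction[d]
            nxt = pos + seg_len * direction
            nxt = np.clip(nxt, box[:, 0], box[:, 1])
            pts.append(nxt)
            pos = nxt
        fibers.append(Streamline(id_offset + i, np.array(pts)))
    return Tractogram(fibers, space_tag=SPACE_TAG)


def make_cohort(
    spec: CohortSpec, bundle: Tractogram, grid: MaskVolume
) -> tuple[CohortTable, dict]:
    """Generate a stimulation cohort whose outcomes track bundle overlap.

    For each stimulation a center is drawn from the cohort's Gaussian
    placement distribution, an amplitude from its uniform range, and a
    sphere of radius ``radius_map(amplitude)`` is voxelized on ``grid``.
    The overlap fraction *o* is the share of planted fibers passing within
    the sphere radius of the center (measured on the fiber polylines, so
    the sidecar is exact regardless of grid resolution).

    Returns the cohort plus a ground-truth sidecar (JSON-serializable)
    recording every draw, the overlaps and the planted fiber IDs.
    """
    if len(bundle) == 0:
        raise ValueError("bundle must be nonempty")
    verts = np.vstack([s.points for s in bundle])
    fiber_idx = np.repeat(np.arange(len(bundle)), [len(s.points) for s in bundle])
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_stims)
    records, truth_rows = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        center = rng.normal(np.asarray(spec.center_mean, float), np.asarray(spec.center_sd, float))
        amplitude = rng.uniform(*spec.amplitude_range)
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        radius = float(spec.radius_map(amplitude))
        close = np.linalg.norm(verts - center, axis=1) <= radius
        overlap = float(len(np.unique(fiber_idx[close])) / len(bundle))
        improvement = spec.effect_beta * overlap + noise
        records.append(
            StimulationRecord(
                stim_id=f"{spec.name}-{i:03d}",
                patient_id=f"{spec.name}-p{i:03d}",
                cohort=spec.name,
                masks=[sphere_mask(center, radius, grid)],
                amplitude=float(amplitude),
                improvement_pct=float(improvement),
            )
        )
        truth_rows.append(
            {
                "stim_id": f"{spec.name}-{i:03d}",
                "center": center.tolist(),
                "amplitude": float(amplitude),
                "radius": radius,
                "overlap": overlap,
                "noise": float(noise),
                "improvement_pct": float(improvement),
            }
        )
    truth = {
        "seed": spec.seed,
        "effect_beta": spec.effect_beta,
        "noise_sd": spec.noise_sd,
        "planted_fiber_ids": bundle.fiber_ids.tolist(),
        "stimulations": truth_rows,
    }
    return CohortTable(records, name=spec.name), truth


# ---------------------------------------------------------------------------
# default study conditions


def default_grid() -> MaskVolume:
    """72 mm cubic field of view at 1 mm isotropic resolution, centred on 0."""
    return make_grid((72, 72, 72), voxel_size=1.0)


def default_bundle_spec(n_fibers: int = 200) -> BundleSpec:
    """A gently curved 55 mm bundle crossing the field of view."""
    waypoints = [(-26.0, -6.0, 0.0), (-9.0, 4.0, 2.0), (9.0, 4.0, -2.0), (26.0, -6.0, 0.0)]
    return BundleSpec(waypoints=waypoints, n_fibers=n_fibers, radial_sd=2.0, step=1.0)


def default_connectome(
    n_planted: int = 200, n_background: int = 2000, seed: int = 1
) -> tuple[Tractogram, np.ndarray]:
    """Planted bundle plus background in one tractogram.

    Returns the combined tractogram and a boolean planted-fiber marker
    aligned with its fiber order (IDs 0..n_planted-1 are planted).
    """
    bundle = make_bundle(default_bundle_spec(n_planted), seed=seed)
    background = make_background(n_background, seed=seed + 10_000, id_offset=n_planted)
    combined = Tractogram(list(bundle) + list(background), space_tag=SPACE_TAG)
    is_planted = np.zeros(len(combined), dtype=bool)
    is_planted[:n_planted] = True
    return combined, is_planted


def default_cohort_specs(seed_a: int = 1, seed_b: int = 2) -> tuple[CohortSpec, CohortSpec]:
    """Two cohorts with distinct electrode-placement distributions.

    Cohort A sits dorsal to the bundle (offset in +z), cohort B lateral
    (offset in +y) — mimicking two surgical targets reaching the same
    tract from different approach angles, so their connected-fiber sets
    overlap without coinciding.
    """
    a = CohortSpec(center_mean=(0.0, 4.0, 7.0), seed=seed_a, name="cohortA")
    b = CohortSpec(center_mean=(0.0, 12.0, 0.0), seed=seed_b, name="cohortB")
    return a, b
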