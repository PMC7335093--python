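"""Voxel-grid helpers shared by the simulation and literature-target code."""

from __future__ import annotations

import numpy as np

from .formats import MaskVolume

__all__ = ["make_grid", "sphere_mask"]


def make_grid(
    shape: tuple[int, int, int] = (72, 72, 72),
    voxel_size: float = 1.0,
    origin: tuple[float, float, float] | None = None,
) -> MaskVolume:
    """An empty binary volume template.

    With the default origin the grid is centred on world (0, 0, 0).
    """
    shape = tuple(int(v) for v in shape)
    if origin is None:
        origin = tuple(-voxel_size * (n - 1) / 2.0 for n in shape)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = origin
    return MaskVolume(np.zeros(shape, dtype=np.uint8), affine)


def _voxel_centers(template: MaskVolume) -> np.ndarray:
    """(i, j, k, 3) array of world coordinates of every voxel center."""
    idx = np.indices(template.shape).reshape(3, -1).T.astype(np.float64)
    world = idx @ template.affine[:3, :3].T + template.affine[:3, 3]
    return world.reshape(*template.shape, 3)


def sphere_mask(center: np.ndarray, radius: float, template: MaskVolume) -> MaskVolume:
    """Binary sphere: voxels whose center lies within ``radius`` of ``center``.

    Only a bounding sub-box of the grid is evaluated, so large templates
    stay cheap.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=np.float64)
    frac = template.world_to_voxel(center[None, :])[0]
    if np.any(frac < -0.5) or np.any(frac > np.array(template.shape) - 0.5):
        raise ValueError(f"sphere center {center} lies outside the grid")
    # conservative voxel-index halo around the center
    halo = int(np.ceil(radius / template.voxel_sizes.min())) + 1
    lo = np.maximum(np.floor(frac).astype(int) - halo, 0)
    hi = np.minimum(np.ceil(frac).astype(int) + halo + 1, template.shape)
    ii, jj, kk = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    world = idx @ template.affine[:3, :3].T + template.affine[:3, 3]
    inside = np.linalg.norm(world - center, axis=1) <= radius
    data = np.zeros(template.shape, dtype=np.uint8)
    sub = inside.reshape(ii.shape)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub.astype(np.uint8)
    return MaskVolume(data, template.affine.copy())
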