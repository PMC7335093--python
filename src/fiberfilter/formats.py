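"""Core data containers and file formats.

Everything in the pipeline lives in one world frame: millimetres, RAS
orientation, 0-based voxel indices. Voxel ``(i, j, k)`` of a mask maps to
world coordinates via ``affine @ (i, j, k, 1)``. Streamline files are read
through :mod:`nibabel.streamlines`, which converts TRK's corner-origin
voxel-mm storage to world mm on load; TCK coordinates are world mm already.

Masks are binary volumes (typically volumes of tissue activated, VTAs,
exported by an upstream electrode-modelling pipeline); any strictly
positive voxel value counts as inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Streamline",
    "Tractogram",
    "MaskVolume",
    "StimulationRecord",
    "CohortTable",
    "FormatError",
    "read_tractogram",
    "write_tractogram",
    "read_mask",
    "write_mask",
    "load_cohort",
    "save_cohort",
]

#: Required columns of a cohort CSV. ``mask_paths`` holds ';'-separated
#: paths relative to the mask directory; the outcome is given either as
#: ``improvement_pct`` directly or as ``baseline_ybocs``/``postop_ybocs``.
COHORT_CSV_COLUMNS = ("stim_id", "patient_id", "cohort", "amplitude", "mask_paths")


class FormatError(ValueError):
    """A file or table violates the expected format."""


@dataclass(frozen=True)
class Streamline:
    """One white-matter trajectory: an ordered polyline in world mm (RAS)."""

    id: int
    points: np.ndarray  # (n, 3) float64

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError(f"streamline {self.id}: need an (n>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"streamline {self.id}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class Tractogram:
    """A collection of streamlines sharing one reference space."""

    streamlines: list[Streamline]
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.space_tag:
            raise ValueError("space_tag must be nonempty")
        ids = [s.id for s in self.streamlines]
        if len(set(ids)) != len(ids):
            raise ValueError("streamline IDs must be unique within a tractogram")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def fiber_ids(self) -> np.ndarray:
        return np.array([s.id for s in self.streamlines], dtype=np.int64)

    @classmethod
    def from_arrays(
        cls, arrays: Iterable[np.ndarray], space_tag: str = "synthetic", ids: Sequence[int] | None = None
    ) -> "Tractogram":
        arrays = list(arrays)
        if ids is None:
            ids = range(len(arrays))
        return cls([Streamline(int(i), a) for i, a in zip(ids, arrays)], space_tag)


@dataclass
class MaskVolume:
    """A binary voxel volume with a voxel-to-world affine."""

    data: np.ndarray  # binary, any integer/bool dtype
    affine: np.ndarray  # 4x4, invertible

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("mask affine is not invertible")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask data must be binary; binarize on load")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_support(self) -> int:
        return int(np.count_nonzero(self.data))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to fractional voxel indices (inverse affine)."""
        inv = np.linalg.inv(self.affine)
        pts = np.asarray(points, dtype=np.float64)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel membership test for world-mm points."""
        ijk = np.rint(self.world_to_voxel(points)).astype(np.int64)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.shape)), axis=1)
        hit = np.zeros(len(ijk), dtype=bool)
        if inside.any():
            sel = ijk[inside]
            hit[inside] = self.data[sel[:, 0], sel[:, 1], sel[:, 2]] > 0
        return hit


@dataclass
class StimulationRecord:
    """One stimulation setting: mask volume(s), amplitude and outcome.

    ``improvement_pct`` is the percent change of the clinical score
    (e.g. Y-BOCS), 100 * (baseline - post) / baseline — signed and
    unclamped, so worsening patients carry negative values.
    """

    stim_id: str
    patient_id: str
    cohort: str
    masks: list[MaskVolume]
    amplitude: float
    improvement_pct: float
    baseline_ybocs: float | None = None
    postop_ybocs: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"{self.stim_id}: amplitude must be positive")
        if self.baseline_ybocs is not None and self.postop_ybocs is not None:
            if self.baseline_ybocs <= 0:
                raise ValueError(f"{self.stim_id}: baseline score must be positive")
            expected = 100.0 * (self.baseline_ybocs - self.postop_ybocs) / self.baseline_ybocs
            if abs(expected - self.improvement_pct) > 1e-9:
                raise ValueError(
                    f"{self.stim_id}: improvement_pct {self.improvement_pct} inconsistent "
                    f"with scores (expected {expected})"
                )


@dataclass
class CohortTable:
    """An ordered set of stimulation records forming one analysis cohort."""

    records: list[StimulationRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        ids = [r.stim_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("stim_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def stim_ids(self) -> list[str]:
        return [r.stim_id for r in self.records]

    @property
    def improvements(self) -> np.ndarray:
        return np.array([r.improvement_pct for r in self.records], dtype=np.float64)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([r.amplitude for r in self.records], dtype=np.float64)


# ---------------------------------------------------------------------------
# streamline files


def _detect_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".trk":
        return "trk"
    if suffix == ".tck":
        return "tck"
    raise FormatError(f"cannot infer streamline dialect from suffix {suffix!r}")


def read_tractogram(path: str | Path, dialect: str = "auto", space_tag: str = "unknown") -> Tractogram:
    """Read a TRK or TCK file into world-mm RAS coordinates.

    nibabel applies the header transform on load, including TRK's
    half-voxel corner-origin shift, so all returned coordinates share the
    package's internal frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if dialect not in ("trk", "tck"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/DataError subclasses
        raise FormatError(f"{path}: malformed streamline file ({exc})") from exc
    streams = [np.asarray(s, dtype=np.float64) for s in tf.tractogram.streamlines]
    if not streams:
        warnings.warn(f"{path}: tractogram contains zero streamlines", stacklevel=2)
    return Tractogram.from_arrays(streams, space_tag=space_tag)


def write_tractogram(
    tractogram: Tractogram,
    path: str | Path,
    dialect: str = "auto",
    per_fiber_scalar: np.ndarray | None = None,
    allow_empty: bool = False,
) -> None:
    """Write streamlines to TRK or TCK.

    ``per_fiber_scalar`` (e.g. fiber t-values) is stored as per-streamline
    data in TRK, which supports it natively; for TCK it is written to a
    ``<path>.scalars.tsv`` sidecar keyed by fiber id.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = _detect_dialect(path)
    if not len(tractogram) and not allow_empty:
        raise ValueError("refusing to write an empty tractogram (pass allow_empty=True)")
    if per_fiber_scalar is not None:
        per_fiber_scalar = np.asarray(per_fiber_scalar, dtype=np.float64)
        if per_fiber_scalar.shape != (len(tractogram),):
            raise ValueError(
                f"per_fiber_scalar has length {per_fiber_scalar.shape}, "
                f"expected ({len(tractogram)},)"
            )

    streams = [s.points for s in tractogram]
    data_per_streamline = {}
    if per_fiber_scalar is not None and dialect == "trk":
        data_per_streamline["scalar"] = per_fiber_scalar[:, None]
    nt = nib.streamlines.Tractogram(
        streams, data_per_streamline=data_per_streamline or None, affine_to_rasmm=np.eye(4)
    )
    if dialect == "trk":
        header = nib.streamlines.TrkFile.create_empty_header()
        # generous bounding header; TRK needs voxel sizes and dimensions
        header["voxel_sizes"] = (1.0, 1.0, 1.0)
        header["dimensions"] = (256, 256, 256)
        header["voxel_to_rasmm"] = np.eye(4, dtype=np.float32)
        header["voxel_order"] = "RAS"
        nib.streamlines.save(nt, str(path), header=header)
    else:
        nib.streamlines.save(nt, str(path))
        if per_fiber_scalar is not None:
            sidecar = pd.DataFrame(
                {"fiber_id": tractogram.fiber_ids, "scalar": per_fiber_scalar}
            )
            sidecar.to_csv(f"{path}.scalars.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path) -> MaskVolume:
    """Read a 3D NIfTI volume and binarize it at > 0."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, got shape {data.shape}; select one volume first"
        )
    return MaskVolume(data=(data > 0).astype(np.uint8), affine=img.affine)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# cohort tables


def _improvement_from_row(row: pd.Series) -> tuple[float, float | None, float | None]:
    has_pct = "improvement_pct" in row and pd.notna(row.get("improvement_pct"))
    baseline = row.get("baseline_ybocs")
    postop = row.get("postop_ybocs")
    has_scores = pd.notna(baseline) and pd.notna(postop)
    if has_scores:
        baseline, postop = float(baseline), float(postop)
        if baseline == 0:
            raise FormatError(
                f"{row['stim_id']}: baseline score is 0; percent improvement undefined"
            )
        derived = 100.0 * (baseline - postop) / baseline
        return (float(row["improvement_pct"]) if has_pct else derived, baseline, postop)
    if has_pct:
        return float(row["improvement_pct"]), None, None
    raise FormatError(
        f"{row['stim_id']}: need improvement_pct or both baseline_ybocs and postop_ybocs"
    )


def load_cohort(csv_path: str | Path, mask_dir: str | Path | None = None, name: str | None = None) -> CohortTable:
    """Load a cohort CSV and every mask it references.

    The CSV is comma-separated UTF-8 with a mandatory header row; see
    :data:`COHORT_CSV_COLUMNS`.
    """
    csv_path = Path(csv_path)
    mask_dir = Path(mask_dir) if mask_dir is not None else csv_path.parent
    df = pd.read_csv(csv_path, encoding="utf-8")
    missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        masks = []
        for rel in str(row["mask_paths"]).split(";"):
            mpath = mask_dir / rel.strip()
            if not mpath.exists():
                raise FormatError(f"stimulation {row['stim_id']}: mask file {mpath} not found")
            masks.append(read_mask(mpath))
        pct, baseline, postop = _improvement_from_row(row)
        records.append(
            StimulationRecord(
                stim_id=str(row["stim_id"]),
                patient_id=str(row["patient_id"]),
                cohort=str(row["cohort"]),
                masks=masks,
                amplitude=float(row["amplitude"]),
                improvement_pct=pct,
                baseline_ybocs=baseline,
                postop_ybocs=postop,
            )
        )
    return CohortTable(records, name=name or csv_path.stem)


def save_cohort(cohort: CohortTable, csv_path: str | Path, mask_dir: str | Path) -> None:
    """Write a cohort to CSV plus one NIfTI mask per record per volume."""
    csv_path = Path(csv_path)
    mask_dir = Path(mask_dir)
    mask_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        rels = []
        for k, mask in enumerate(rec.masks):
            rel = f"{rec.stim_id}_mask{k}.nii.gz"
            write_mask(mask, mask_dir / rel)
            rels.append(rel)
        rows.append(
            {
                "stim_id": rec.stim_id,
                "patient_id": rec.patient_id,
                "cohort": rec.cohort,
                "amplitude": rec.amplitude,
                "mask_paths": ";".join(rels),
                "improvement_pct": rec.improvement_pct,
                "baseline_ybocs": rec.baseline_ybocs,
                "postop_ybocs": rec.postop_ybocs,
            }
        )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
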