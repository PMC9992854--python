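"""Volume containers, NIfTI I/O and resampling utilities.

Two in-memory containers are used throughout the package:

``LabelMap``
    an integer-labelled 3D grid together with its voxel spacing, a
    voxel-to-world affine and a label table describing every label id
    (name, coarse tissue class, optional contralateral partner).

``IntensityVolume``
    a real-valued 3D grid with the same geometric metadata.

All volumes are read and written as NIfTI-1 through :mod:`nibabel`; the
label table travels as a JSON sidecar next to the image file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "COARSE_CLASSES",
    "COARSE_LABEL_IDS",
    "LabelEntry",
    "LabelMap",
    "IntensityVolume",
    "FormatError",
    "MultimodalError",
    "read_volume",
    "write_volume",
    "resample",
    "group_to_coarse",
    "one_hot",
]

#: Coarse tissue classes. ``WM``/``GM``/``CSF``/``cerebellum`` are the four
#: foreground classes of the coarse segmentation task; ``background`` and
#: ``extracerebral`` complete the partition of the head.
COARSE_CLASSES = ("background", "WM", "GM", "CSF", "cerebellum", "extracerebral")

#: Canonical ids of the coarse label maps produced by :func:`group_to_coarse`.
#: Extracerebral tissue is grouped with background for the four-class task.
COARSE_LABEL_IDS: dict[str, int] = {
    "background": 0,
    "WM": 1,
    "GM": 2,
    "CSF": 3,
    "cerebellum": 4,
}


class FormatError(ValueError):
    """Raised for malformed or unsupported volume files."""


class MultimodalError(ValueError):
    """Raised when a 4D (multi-channel) file is passed where a single
    channel is expected; callers should split channels and process each
    one independently."""


@dataclass(frozen=True)
class LabelEntry:
    """One row of a label table."""

    id: int
    name: str
    coarse_class: str
    contralateral_id: int | None = None

    def __post_init__(self) -> None:
        if self.coarse_class not in COARSE_CLASSES:
            raise ValueError(
                f"unknown coarse class {self.coarse_class!r} for label "
                f"{self.id} ({self.name}); expected one of {COARSE_CLASSES}"
            )


def _check_geometry(spacing_mm: np.ndarray, affine: np.ndarray) -> None:
    if spacing_mm.shape != (3,) or np.any(spacing_mm <= 0):
        raise ValueError(f"spacing_mm must be 3 strictly positive values, got {spacing_mm}")
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")


@dataclass
class LabelMap:
    """Integer-labelled 3D grid with voxel spacing and a label dictionary."""

    grid: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray
    labels: tuple[LabelEntry, ...]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("LabelMap grid must be 3D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("LabelMap grid must be integer typed")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.spacing_mm, self.affine)
        table_ids = {e.id for e in self.labels}
        present = set(np.unique(self.grid).tolist())
        missing = present - table_ids
        if missing:
            raise ValueError(f"grid labels {sorted(missing)} absent from label table")

    @property
    def label_ids(self) -> list[int]:
        return [e.id for e in self.labels]

    def entry(self, label_id: int) -> LabelEntry:
        for e in self.labels:
            if e.id == label_id:
                return e
        raise KeyError(label_id)

    def ids_of_class(self, coarse_class: str) -> list[int]:
        return [e.id for e in self.labels if e.coarse_class == coarse_class]

    def with_grid(self, grid: np.ndarray) -> "LabelMap":
        return replace(self, grid=np.asarray(grid))


@dataclass
class IntensityVolume:
    """Real-valued 3D grid with voxel spacing and affine."""

    grid: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("IntensityVolume grid must be 3D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("IntensityVolume grid must contain finite values only")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.spacing_mm, self.affine)

    def with_grid(self, grid: np.ndarray) -> "IntensityVolume":
        return replace(self, grid=np.asarray(grid, dtype=np.float32))


def default_affine(spacing_mm: Sequence[float]) -> np.ndarray:
    """RAS affine with voxel centres at ``index * spacing`` (0-based)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


# ---------------------------------------------------------------------------
# NIfTI I/O


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".mgz"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_volume(vol: IntensityVolume | LabelMap, path: str | Path) -> None:
    """Write a volume as NIfTI-1; label maps also emit a JSON label table."""
    path = Path(path)
    if isinstance(vol, LabelMap):
        data = vol.grid.astype(np.int16)
        sidecar = [
            {
                "id": e.id,
                "name": e.name,
                "coarse_class": e.coarse_class,
                "contralateral_id": e.contralateral_id,
            }
            for e in vol.labels
        ]
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    else:
        data = vol.grid.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> IntensityVolume | LabelMap:
    """Read a NIfTI-1 volume; integer data with a label sidecar yields a
    :class:`LabelMap`, everything else an :class:`IntensityVolume`.

    4D files raise :class:`MultimodalError`: multimodal inputs must be split
    into channels upstream, each channel being processed independently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # malformed header / truncated file
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim == 4:
        raise MultimodalError(
            f"{path} is 4D with {data.shape[-1]} channels; split it into "
            "single-channel volumes and process each channel separately"
        )
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    affine = np.asarray(img.affine, dtype=float)

    sidecar = _sidecar_path(path)
    integral = np.issubdtype(data.dtype, np.integer) or (
        np.all(np.isfinite(data)) and np.allclose(data, np.round(data))
    )
    if sidecar.exists() and integral:
        rows = json.loads(sidecar.read_text())
        labels = tuple(
            LabelEntry(int(r["id"]), r["name"], r["coarse_class"], r.get("contralateral_id"))
            for r in rows
        )
        return LabelMap(data.astype(np.int32), spacing, affine, labels)
    if np.issubdtype(data.dtype, np.integer) and not sidecar.exists():
        # integer data without a table: synthesize a minimal table so the
        # invariant (every grid value in the table) holds
        labels = tuple(
            LabelEntry(int(v), f"label-{int(v)}", "background" if v == 0 else "GM")
            for v in np.unique(data)
        )
        return LabelMap(data.astype(np.int32), spacing, affine, labels)
    return IntensityVolume(data.astype(np.float32), spacing, affine)


# ---------------------------------------------------------------------------
# Resampling


def _resample_array(
    grid: np.ndarray, spacing: np.ndarray, target_spacing: np.ndarray, order: int
) -> np.ndarray:
    """Resample under the voxel-centred convention: output dims are
    ``ceil(extent / target_spacing)`` with extent = dims * spacing."""
    extent = np.asarray(grid.shape) * spacing
    new_shape = np.maximum(1, np.ceil(extent / target_spacing - 1e-9).astype(int))
    # voxel-centre coordinates of the output grid expressed in input indices
    coords = [
        (np.arange(n) + 0.5) * target_spacing[ax] / spacing[ax] - 0.5
        for ax, n in enumerate(new_shape)
    ]
    mesh = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(
        grid.astype(np.float32 if order > 0 else grid.dtype),
        np.stack(mesh),
        order=order,
        mode="nearest",
    )


def resample(
    vol: IntensityVolume | LabelMap,
    target_spacing: Sequence[float],
    mode: str = "linear",
) -> IntensityVolume | LabelMap:
    """Resample a volume to ``target_spacing`` preserving the world field of
    view. Label maps accept only nearest-neighbour interpolation."""
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError("target_spacing must be 3 positive values")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(vol, LabelMap) and mode == "linear":
        raise ValueError("label maps must be resampled with mode='nearest'")
    if np.allclose(target, vol.spacing_mm):
        return vol
    order = 1 if mode == "linear" else 0
    new_grid = _resample_array(vol.grid, vol.spacing_mm, target, order)
    affine = vol.affine.copy()
    scale = target / vol.spacing_mm
    affine[:3, :3] = affine[:3, :3] @ np.diag(scale)
    # keep voxel-centre 0 of the new grid aligned with the world position of
    # the first output sample: offset by (scale-1)/2 voxels of the old grid
    affine[:3, 3] += vol.affine[:3, :3] @ ((scale - 1.0) / 2.0)
    if isinstance(vol, LabelMap):
        return LabelMap(new_grid.astype(vol.grid.dtype), target, affine, vol.labels)
    return IntensityVolume(new_grid, target, affine)


# ---------------------------------------------------------------------------
# Label-space operations


def group_to_coarse(label_map: LabelMap) -> LabelMap:
    """Collapse a fine label map to the four-class coarse problem
    (background, WM, GM, CSF, cerebellum); extracerebral tissue is grouped
    with background. Voxel counts are conserved per coarse class."""
    lut_size = max(label_map.label_ids) + 1
    lut = np.full(lut_size, -1, dtype=np.int32)
    for e in label_map.labels:
        coarse = "background" if e.coarse_class == "extracerebral" else e.coarse_class
        lut[e.id] = COARSE_LABEL_IDS[coarse]
    if np.any(lut[np.unique(label_map.grid)] < 0):
        raise ValueError("label without a coarse_class mapping")
    entries = tuple(
        LabelEntry(v, name, name if name != "background" else "background")
        for name, v in COARSE_LABEL_IDS.items()
    )
    return LabelMap(lut[label_map.grid], label_map.spacing_mm, label_map.affine, entries)


def one_hot(label_map: LabelMap | np.ndarray, label_order: Sequence[int]) -> np.ndarray:
    """Encode a label grid as a K-channel indicator tensor (channels first).

    Channel ``k`` is the indicator of ``label_order[k]``; channels sum to
    exactly 1 at every voxel.
    """
    grid = label_map.grid if isinstance(label_map, LabelMap) else np.asarray(label_map)
    order = list(label_order)
    present = set(np.unique(grid).tolist())
    missing = present - set(order)
    if missing:
        raise ValueError(f"grid labels {sorted(missing)} missing from label_order")
    lut = np.zeros(max(present | set(order)) + 1, dtype=np.int64)
    for k, lab in enumerate(order):
        lut[lab] = k
    idx = lut[grid]
    out = np.zeros((len(order),) + grid.shape, dtype=np.float32)
    np.put_along_axis(out, idx[None], 1.0, axis=0)
    return out
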