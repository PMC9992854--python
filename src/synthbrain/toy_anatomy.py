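"""Synthetic toy anatomy: desk-scale stand-in for real training label maps.

Real training of this kind of segmentation suite starts from a large library
of whole-head anatomical label maps (tens of brain structures plus
extra-cerebral tissue). This module builds *synthetic* miniature label maps —
nested, mildly perturbed ellipsoids forming background, an extracerebral
shell, CSF, a cortical gray-matter ribbon, a white-matter core and a
cerebellum blob, plus small named subcortical blobs (thalamus, hippocampus,
amygdala, pallidum, putamen, lateral ventricles, brainstem) placed inside the
core. The construction is deterministic given a seed and rejection-free, so
fixtures never fail stochastically.

The named blobs exist so that the ten quality-control regions used by the
QC regressor (white matter, cortex, lateral ventricle, cerebellum, thalamus,
hippocampus, amygdala, pallidum, putamen, brainstem) are all present at desk
scale.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .volumes import LabelEntry, LabelMap, default_affine

__all__ = [
    "QC_REGIONS",
    "make_toy_label_map",
    "qc_region_ids",
    "toy_cortex_parcels",
]

#: The ten regions scored by the quality-control regressor.
QC_REGIONS = (
    "white matter",
    "cortex",
    "lateral ventricle",
    "cerebellum",
    "thalamus",
    "hippocampus",
    "amygdala",
    "pallidum",
    "putamen",
    "brainstem",
)

# Base structures (always present). ids 0..5.
_BASE = (
    LabelEntry(0, "background", "background"),
    LabelEntry(1, "extracerebral", "extracerebral"),
    LabelEntry(2, "csf", "CSF"),
    LabelEntry(3, "cortex", "GM"),
    LabelEntry(4, "white-matter", "WM"),
    LabelEntry(5, "cerebellum", "cerebellum"),
)

# Subcortical blob schedule: (name, coarse_class, side) taken in order for
# n_structures - 4 blobs. Paired entries receive contralateral ids.
_BLOBS = (
    ("thalamus", "GM", "L"),
    ("thalamus", "GM", "R"),
    ("hippocampus", "GM", "L"),
    ("hippocampus", "GM", "R"),
    ("amygdala", "GM", "L"),
    ("amygdala", "GM", "R"),
    ("pallidum", "GM", "L"),
    ("pallidum", "GM", "R"),
    ("putamen", "GM", "L"),
    ("putamen", "GM", "R"),
    ("lateral-ventricle", "CSF", "L"),
    ("lateral-ventricle", "CSF", "R"),
    ("brainstem", "WM", None),
    ("caudate", "GM", "L"),
    ("caudate", "GM", "R"),
)

# per-pair (dy, dz) unit offsets inside the white-matter core
_PAIR_OFFSETS = (
    (0.0, 0.0),
    (0.55, 0.45),
    (0.55, -0.45),
    (-0.55, 0.45),
    (-0.55, -0.45),
    (0.95, 0.0),
    (-0.95, 0.0),
    (0.0, 0.8),
)


def _ellipsoid(shape: np.ndarray, center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    axes = [np.arange(n, dtype=np.float32) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d = (
        ((xx - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((zz - center[2]) / radii[2]) ** 2
    )
    return d <= 1.0


def make_toy_label_map(
    shape: Sequence[int] = (32, 32, 32),
    n_structures: int = 17,
    seed: int = 0,
) -> LabelMap:
    """Build a synthetic toy whole-head label map at 1 mm isotropic spacing.

    Parameters
    ----------
    shape
        Grid dimensions; every axis must be at least 16 voxels so the nested
        shells fit with at least one voxel of thickness each.
    n_structures
        Number of anatomical structures: the 4 core structures (white
        matter, cortex, CSF, cerebellum) plus ``n_structures - 4``
        subcortical blobs. ``n_structures = 17`` yields all ten QC regions.
    seed
        Deterministic perturbation of shell radii and blob positions.
    """
    shape = np.asarray(shape, dtype=int)
    if shape.shape != (3,) or np.any(shape < 16):
        raise ValueError(f"shape must be >= 16 per axis to nest the tissue shells, got {tuple(shape)}")
    if n_structures < 4:
        raise ValueError("n_structures must be >= 4")
    n_blobs = min(n_structures - 4, len(_BLOBS))

    rng = np.random.default_rng(seed)
    c = (shape - 1) / 2.0
    s = float(shape.min())
    jit = lambda lo=0.97, hi=1.03: rng.uniform(lo, hi, size=3)

    grid = np.zeros(tuple(shape), dtype=np.int32)
    grid[_ellipsoid(shape, c, 0.47 * s * jit())] = 1  # extracerebral shell
    grid[_ellipsoid(shape, c, 0.41 * s * jit())] = 2  # CSF
    csf_mask = grid == 2
    grid[_ellipsoid(shape, c, 0.345 * s * jit())] = 3  # cortical ribbon
    grid[_ellipsoid(shape, c, 0.27 * s * jit())] = 4  # white-matter core

    # cerebellum: inferior blob, clipped to stay intracranial
    cb_center = c + np.array([0.0, 0.0, -0.24 * s]) + rng.uniform(-0.5, 0.5, 3)
    cb = _ellipsoid(shape, cb_center, np.array([0.17, 0.17, 0.13]) * s * jit())
    grid[cb & (csf_mask | (grid >= 3))] = 5

    labels = list(_BASE)
    wm_r = 0.27 * s
    dx = 0.13 * s
    blob_r = max(1.6, 0.055 * s)
    pair_scale = 0.13 * s
    pair_idx = 0
    for i in range(n_blobs):
        name, coarse, side = _BLOBS[i]
        lab_id = 6 + i
        if side is None:  # midline structure (brainstem): elongated inferior
            center = c + np.array([0.0, -0.05 * s, -0.16 * s])
            radii = np.array([blob_r, blob_r, 1.9 * blob_r])
        else:
            if side == "L":
                dy, dz = _PAIR_OFFSETS[pair_idx % len(_PAIR_OFFSETS)]
                pair_idx += 1
            center = c + np.array(
                [(-dx if side == "L" else dx), dy * pair_scale, dz * pair_scale]
            )
            radii = np.full(3, blob_r)
        center = center + rng.uniform(-0.4, 0.4, 3)
        blob = _ellipsoid(shape, center, radii)
        inside = blob & (grid == 4) if side is not None else blob & (grid >= 3)
        grid[inside] = lab_id
        partner: int | None = None
        if side == "L" and i + 1 < n_blobs:
            partner = lab_id + 1
        elif side == "R":
            partner = lab_id - 1
        labels.append(LabelEntry(lab_id, f"{name}-{side}" if side else name, coarse, partner))

    spacing = np.ones(3)
    lm = LabelMap(grid, spacing, default_affine(spacing), tuple(labels))
    # guarantee all six coarse classes survive the construction
    present = {lm.entry(v).coarse_class for v in np.unique(grid)}
    if len(present) < 6:
        raise RuntimeError(f"toy anatomy degenerate: classes {present}")
    return lm


def qc_region_ids(label_map: LabelMap) -> dict[str, list[int]]:
    """Map each QC region name to the label ids composing it (left-right
    pairs are pooled into one region)."""
    by_base: dict[str, list[int]] = {}
    for e in label_map.labels:
        base = e.name.rsplit("-", 1)[0] if e.name.endswith(("-L", "-R")) else e.name
        by_base.setdefault(base, []).append(e.id)
    naming = {
        "white matter": "white-matter",
        "cortex": "cortex",
        "lateral ventricle": "lateral-ventricle",
        "cerebellum": "cerebellum",
        "thalamus": "thalamus",
        "hippocampus": "hippocampus",
        "amygdala": "amygdala",
        "pallidum": "pallidum",
        "putamen": "putamen",
        "brainstem": "brainstem",
    }
    out: dict[str, list[int]] = {}
    for region, key in naming.items():
        if key in by_base:
            out[region] = sorted(by_base[key])
    return out


def toy_cortex_parcels(label_map: LabelMap, n_parcels: int = 4) -> LabelMap:
    """Subdivide the cortical ribbon into ``n_parcels`` angular sectors.

    Stands in for a full cortical parcellation: each cortex voxel is
    assigned to a parcel by its azimuth around the volume centre; all other
    voxels become background. Parcel ids are 1..n_parcels.
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    cortex_ids = [e.id for e in label_map.labels if e.name == "cortex"]
    if not cortex_ids:
        raise ValueError("label map has no cortex label")
    grid = label_map.grid
    c = (np.asarray(grid.shape) - 1) / 2.0
    xx, yy = np.meshgrid(
        np.arange(grid.shape[0]) - c[0],
        np.arange(grid.shape[1]) - c[1],
        indexing="ij",
    )
    theta = np.arctan2(yy, xx) + np.pi  # [0, 2pi)
    sector = np.minimum((theta / (2 * np.pi) * n_parcels).astype(np.int32), n_parcels - 1)
    sector = np.broadcast_to(sector[..., None], grid.shape)
    parcels = np.zeros_like(grid)
    mask = np.isin(grid, cortex_ids)
    parcels[mask] = sector[mask] + 1
    entries = [LabelEntry(0, "background", "background")] + [
        LabelEntry(k, f"cortex-parcel-{k}", "GM") for k in range(1, n_parcels + 1)
    ]
    return LabelMap(parcels, label_map.spacing_mm, label_map.affine, tuple(entries))
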