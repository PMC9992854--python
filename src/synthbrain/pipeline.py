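"""Inference pipeline: preprocess -> S1 -> D -> S2 -> S3 -> R.

A raw scan of any contrast and resolution is resampled to 1 mm isotropic
and min-max normalized; the coarse segmenter S1 produces a four-class
tissue segmentation, the denoiser D corrects it, the fine segmenter S2
turns image + corrected tissue priors into the structure-level
segmentation, S3 parcellates the cortex, and the QC regressor R predicts a
Dice score for ten regions from the S2 segmentation alone. All outputs are
on the 1 mm grid regardless of the native resolution of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .volumes import (
    COARSE_LABEL_IDS,
    IntensityVolume,
    LabelEntry,
    LabelMap,
    group_to_coarse,
    one_hot,
    resample,
)

__all__ = [
    "SegmentationResult",
    "QCReport",
    "preprocess",
    "harden",
    "run_pipeline",
    "qc_filter",
    "qc_dice_baseline",
]

#: Region failure threshold on the predicted Dice score: a region fails if
#: its score is strictly lower than this value.
QC_THRESHOLD = 0.65

_COARSE_ORDER = tuple(COARSE_LABEL_IDS.values())  # (0, 1, 2, 3, 4)


@dataclass
class SegmentationResult:
    """Soft + hard segmentation on the 1 mm grid."""

    soft: np.ndarray  # (K, D, H, W), channels sum to 1 per voxel
    hard: LabelMap
    label_order: tuple[int, ...]
    coarse_soft: np.ndarray | None = None  # D's corrected coarse output
    parcels: LabelMap | None = None  # cortex parcellation (if S3 present)


@dataclass
class QCReport:
    """Per-region predicted Dice with pass/fail at a fixed threshold."""

    scores: dict[str, float]
    threshold: float = QC_THRESHOLD

    @property
    def region_pass(self) -> dict[str, bool]:
        return {r: s >= self.threshold for r, s in self.scores.items()}

    @property
    def overall_pass(self) -> bool:
        return all(self.region_pass.values())


def preprocess(vol: IntensityVolume) -> IntensityVolume:
    """Resample to 1 mm isotropic and min-max normalize intensities to
    [0, 1]. A constant input normalizes to all zeros (with a warning)."""
    if not isinstance(vol, IntensityVolume):
        raise TypeError("preprocess expects a single-channel IntensityVolume")
    out = resample(vol, (1.0, 1.0, 1.0), mode="linear")
    lo, hi = float(out.grid.min()), float(out.grid.max())
    if hi - lo <= 0:
        warnings.warn("constant input volume; normalized to all zeros")
        return out.with_grid(np.zeros_like(out.grid))
    return out.with_grid((out.grid - lo) / (hi - lo))


def harden(soft: np.ndarray, label_order: Sequence[int]) -> np.ndarray:
    """Per-voxel argmax of a probability tensor; ties are broken to the
    lowest label id (deterministic)."""
    lab = np.asarray(list(label_order))
    if soft.shape[0] != lab.size:
        raise ValueError("soft channels and label_order length differ")
    maxv = soft.max(axis=0, keepdims=True)
    key = np.where(soft == maxv, lab.reshape(-1, 1, 1, 1), np.iinfo(np.int64).max)
    return key.min(axis=0).astype(np.int32)


def _coarse_label_map(grid: np.ndarray, ref: IntensityVolume) -> LabelMap:
    entries = tuple(
        LabelEntry(v, name, name if name != "background" else "background")
        for name, v in COARSE_LABEL_IDS.items()
    )
    return LabelMap(grid, ref.spacing_mm, ref.affine, entries)


def run_pipeline(
    vol: IntensityVolume | Sequence[IntensityVolume],
    handles: Mapping[str, object],
    fine_order: Sequence[int],
    fine_labels: tuple[LabelEntry, ...] | None = None,
    qc_regions: Mapping[str, Sequence[int]] | None = None,
    cortex_ids: Sequence[int] = (),
    parcel_order: Sequence[int] = (),
    qc_threshold: float = QC_THRESHOLD,
    run_qc: bool = True,
):
    """Run the hierarchical pipeline on one volume (or channel-by-channel on
    a sequence of volumes, returning one result per channel).

    ``handles`` maps ``s1``/``d``/``s2`` (required ``s1``/``s2``) and
    optionally ``s3``/``r`` to trained networks. Missing optional handles
    trigger the documented partial-pipeline behaviour: no ``d`` feeds S1's
    soft output directly to S2; no ``s3`` leaves parcels absent; no ``r``
    (or ``run_qc=False``) leaves the QC report ``None``.
    """
    if not isinstance(vol, IntensityVolume):
        results = [
            run_pipeline(
                channel, handles, fine_order, fine_labels, qc_regions,
                cortex_ids, parcel_order, qc_threshold, run_qc,
            )
            for channel in vol
        ]
        return results

    s1 = handles.get("s1")
    s2 = handles.get("s2")
    if s1 is None or s2 is None:
        raise ValueError("pipeline requires at least s1 and s2 handles")

    img = preprocess(vol)
    x = img.grid[None].astype(np.float32)

    soft1 = s1.forward(x)
    hard1 = harden(soft1, _COARSE_ORDER)
    d = handles.get("d")
    if d is not None:
        coarse_soft = d.forward(one_hot(hard1, _COARSE_ORDER))
    else:
        coarse_soft = soft1
    soft2 = s2.forward(np.concatenate([x, coarse_soft], axis=0))

    fine_order = tuple(int(v) for v in fine_order)
    hard2_grid = harden(soft2, fine_order)
    if fine_labels is None:
        fine_labels = tuple(
            LabelEntry(v, f"label-{v}", "background" if v == 0 else "GM")
            for v in fine_order
        )
    hard2 = LabelMap(hard2_grid, img.spacing_mm, img.affine, fine_labels)

    parcels = None
    s3 = handles.get("s3")
    if s3 is not None and len(cortex_ids) and len(parcel_order):
        masks = np.stack([(hard2_grid == c).astype(np.float32) for c in cortex_ids])
        soft3 = s3.forward(np.concatenate([x, masks], axis=0))
        parcel_grid = harden(soft3, parcel_order)
        parcel_grid[~np.isin(hard2_grid, list(cortex_ids))] = 0  # cortex only
        entries = tuple(
            LabelEntry(v, f"cortex-parcel-{v}" if v else "background",
                       "GM" if v else "background")
            for v in parcel_order
        )
        parcels = LabelMap(parcel_grid, img.spacing_mm, img.affine, entries)

    result = SegmentationResult(
        soft=soft2, hard=hard2, label_order=fine_order,
        coarse_soft=coarse_soft, parcels=parcels,
    )

    report = None
    r = handles.get("r")
    if run_qc and r is not None and qc_regions is not None:
        # R scores the S2 segmentation alone (its soft probabilities, whose
        # per-voxel confidence carries quality information); no image input
        scores = r.forward(soft2)
        scores = np.clip(scores, 0.0, 1.0)
        report = QCReport(
            scores={name: float(s) for name, s in zip(qc_regions, scores)},
            threshold=qc_threshold,
        )
    return result, report


def qc_filter(report: QCReport, mode: str = "whole") -> set[str]:
    """Regions retained after quality control.

    ``whole``: an empty set if any region fails (whole-scan rejection);
    ``per_structure``: exactly the regions with score >= threshold (a score
    equal to the threshold passes, since failure is *strictly below*)."""
    if mode not in ("whole", "per_structure"):
        raise ValueError(f"unknown qc_filter mode {mode!r}")
    kept = {r for r, ok in report.region_pass.items() if ok}
    if mode == "whole":
        return set(report.scores) if len(kept) == len(report.scores) else set()
    return kept


def qc_dice_baseline(d_out: LabelMap, s2_out: LabelMap) -> float:
    """Agreement baseline for QC: mean hard Dice over the four coarse tissue
    classes between the denoiser output and the S2 segmentation collapsed to
    coarse classes."""
    from .stats import hard_dice

    if d_out.grid.shape != s2_out.grid.shape:
        raise ValueError("d_out and s2_out grids differ in shape")
    s2_coarse = group_to_coarse(s2_out).grid
    dices = [
        hard_dice(d_out.grid == v, s2_coarse == v)
        for name, v in COARSE_LABEL_IDS.items()
        if name != "background"
    ]
    return float(np.mean(dices))
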