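"""Domain-randomized synthetic training data.

A label map is the only input: each training example is built by (1) random
spatial augmentation of the map (affine + smooth nonlinear deformation,
optional left-right flip with contralateral label swap), (2) sampling a
Gaussian mixture model conditioned on the deformed labels, (3) intensity
corruption (multiplicative bias field, additive noise, min-max rescaling to
[0, 1], voxel-wise gamma exponentiation), and (4) resolution simulation
(anisotropic blur, subsampling to a random slice spacing, resampling back to
the 1 mm grid). The deformed label map is the ground truth, so the
downstream segmenters always train to produce 1 mm segmentations.

Every hyperparameter of this generative model is drawn per example from a
uniform prior of wide range (domain randomization), so trained networks see
vastly varying contrast, resolution and artifacts. A ``wide_mode`` variant
of the priors, with considerably wider corruption ranges, produces the
degraded examples used to train the denoiser and the QC regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelMap, group_to_coarse, one_hot
from .toy_anatomy import toy_cortex_parcels

__all__ = [
    "ConfigurationError",
    "GenerationPriors",
    "GenerationInstance",
    "identity_instance",
    "sample_generation_instance",
    "apply_spatial_transform",
    "synthesize_gmm_image",
    "corrupt_intensities",
    "simulate_resolution",
    "generate_training_pair",
    "generate_denoiser_example",
    "generate_qc_example",
]

Range = tuple[float, float]


class ConfigurationError(ValueError):
    """Raised for invalid generator / pipeline configuration."""


@dataclass(frozen=True)
class GenerationPriors:
    """Uniform prior ranges for every synthesis hyperparameter.

    All ranges are ``(low, high)`` with ``low <= high``. The defaults mirror
    the wide domain-randomization regime used for contrast- and
    resolution-agnostic training; they are implementation choices and are
    fully configurable.
    """

    mu: Range = (0.0, 255.0)  # GMM mean per label, intensity units
    sigma: Range = (0.0, 35.0)  # GMM std per label
    rotation_deg: Range = (-15.0, 15.0)
    scaling: Range = (0.85, 1.15)
    shearing: Range = (-0.012, 0.012)
    translation_mm: Range = (-10.0, 10.0)
    nonlin_strength_mm: Range = (0.0, 4.0)
    nonlin_smooth_vox: Range = (3.0, 6.0)
    bias_log_amplitude: Range = (0.0, 0.5)
    bias_smooth_vox: Range = (6.0, 12.0)
    noise_std: Range = (0.0, 10.0)  # pre-rescale intensity units
    log_gamma: Range = (-0.35, 0.35)  # gamma = exp(draw)
    spacing_mm: Range = (1.0, 9.0)  # slice spacing along a random axis
    iso_prob: float = 0.2  # probability of an isotropic low-res draw
    flip_prob: float = 0.5
    wide_mode: bool = False

    def __post_init__(self) -> None:
        for name in (
            "mu", "sigma", "rotation_deg", "scaling", "shearing",
            "translation_mm", "nonlin_strength_mm", "nonlin_smooth_vox",
            "bias_log_amplitude", "bias_smooth_vox", "noise_std",
            "log_gamma", "spacing_mm",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"prior {name}: lower {lo} > upper {hi}")

    def widened(self) -> "GenerationPriors":
        """Corruption priors for denoiser / QC-regressor training:
        deformation, bias and noise ranges doubled, slice spacing extended.
        Each widened range pointwise contains the standard one."""
        return replace(
            self,
            rotation_deg=(self.rotation_deg[0] * 2, self.rotation_deg[1] * 2),
            translation_mm=(self.translation_mm[0] * 2, self.translation_mm[1] * 2),
            nonlin_strength_mm=(self.nonlin_strength_mm[0], self.nonlin_strength_mm[1] * 2),
            bias_log_amplitude=(self.bias_log_amplitude[0], self.bias_log_amplitude[1] * 2),
            noise_std=(self.noise_std[0], self.noise_std[1] * 2),
            log_gamma=(self.log_gamma[0] * 2, self.log_gamma[1] * 2),
            spacing_mm=(self.spacing_mm[0], max(self.spacing_mm[1], 12.0)),
            wide_mode=True,
        )


@dataclass(frozen=True)
class GenerationInstance:
    """One concrete draw of every generative hyperparameter."""

    mu: dict[int, float]  # per-label GMM mean
    sigma: dict[int, float]  # per-label GMM std
    rotation_deg: np.ndarray  # (3,)
    scaling: np.ndarray  # (3,)
    shearing: np.ndarray  # (3,)
    translation_mm: np.ndarray  # (3,)
    nonlin_strength_mm: float
    nonlin_smooth_vox: float
    bias_log_amplitude: float
    bias_smooth_vox: float
    noise_std: float
    gamma: float
    spacing_mm: np.ndarray  # (3,) target low resolution
    flip: bool
    seed: int

    def is_identity_geometry(self) -> bool:
        return (
            not self.flip
            and np.allclose(self.rotation_deg, 0)
            and np.allclose(self.scaling, 1)
            and np.allclose(self.shearing, 0)
            and np.allclose(self.translation_mm, 0)
            and self.nonlin_strength_mm == 0
        )


def identity_instance(mu: dict[int, float] | None = None,
                      sigma: dict[int, float] | None = None) -> GenerationInstance:
    """An instance that applies no geometric or intensity corruption."""
    return GenerationInstance(
        mu=mu or {}, sigma=sigma or {},
        rotation_deg=np.zeros(3), scaling=np.ones(3), shearing=np.zeros(3),
        translation_mm=np.zeros(3), nonlin_strength_mm=0.0, nonlin_smooth_vox=4.0,
        bias_log_amplitude=0.0, bias_smooth_vox=8.0, noise_std=0.0, gamma=1.0,
        spacing_mm=np.ones(3), flip=False, seed=0,
    )


def sample_generation_instance(
    priors: GenerationPriors,
    seed: int,
    label_ids: Sequence[int] = (),
) -> GenerationInstance:
    """Draw one instance of the generative model from the uniform priors.

    All parameters are drawn independently; the draw is reproducible given
    the seed. ``label_ids`` selects which labels receive GMM parameters.
    """
    rng = np.random.default_rng(seed)
    u = lambda r, size=None: rng.uniform(r[0], r[1], size=size)
    mu = {int(k): float(u(priors.mu)) for k in label_ids}
    sigma = {int(k): float(u(priors.sigma)) for k in label_ids}
    rotation = u(priors.rotation_deg, 3)
    scaling = u(priors.scaling, 3)
    shearing = u(priors.shearing, 3)
    translation = u(priors.translation_mm, 3)
    nl_strength = float(u(priors.nonlin_strength_mm))
    nl_smooth = float(u(priors.nonlin_smooth_vox))
    bias_amp = float(u(priors.bias_log_amplitude))
    bias_smooth = float(u(priors.bias_smooth_vox))
    noise = float(u(priors.noise_std))
    gamma = float(np.exp(u(priors.log_gamma)))
    iso = rng.uniform() < priors.iso_prob
    sp = float(u(priors.spacing_mm))
    if iso:
        spacing = np.full(3, max(1.0, sp))
    else:
        spacing = np.ones(3)
        spacing[rng.integers(0, 3)] = max(1.0, sp)
    flip = bool(rng.uniform() < priors.flip_prob)
    return GenerationInstance(
        mu=mu, sigma=sigma, rotation_deg=rotation, scaling=scaling,
        shearing=shearing, translation_mm=translation,
        nonlin_strength_mm=nl_strength, nonlin_smooth_vox=nl_smooth,
        bias_log_amplitude=bias_amp, bias_smooth_vox=bias_smooth,
        noise_std=noise, gamma=gamma, spacing_mm=spacing, flip=flip,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# spatial transform


def _affine_matrix(inst: GenerationInstance, center: np.ndarray) -> np.ndarray:
    """4x4 voxel-space affine (rotation, scaling, shearing, translation)
    about the grid centre. Spacing is 1 mm so mm == voxels."""
    rx, ry, rz = np.deg2rad(inst.rotation_deg)
    Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
    Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
    Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
    S = np.diag(inst.scaling)
    sh = inst.shearing
    Sh = np.array([[1, sh[0], sh[1]], [sh[0], 1, sh[2]], [sh[1], sh[2], 1]])
    M = Rz @ Ry @ Rx @ Sh @ S
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = center - M @ center + inst.translation_mm
    return A


def _nonlinear_field(
    shape: tuple[int, ...], inst: GenerationInstance, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement field (3, D, H, W) in voxels, with maximum
    magnitude equal to the drawn strength. Redraws with halved strength if
    the field folds (non-positive Jacobian) on more than 2% of voxels."""
    if inst.nonlin_strength_mm == 0:
        return np.zeros((3,) + shape, dtype=np.float32)
    # the field is low-frequency: draw it on a 4x-coarser control grid,
    # smooth there, and upsample; folding is checked on the control grid
    red = 4
    low_shape = tuple(max(2, -(-n // red)) for n in shape)
    strength = inst.nonlin_strength_mm
    for _ in range(5):
        low = rng.standard_normal((3,) + low_shape).astype(np.float32)
        for ax in range(3):
            low[ax] = ndimage.gaussian_filter(low[ax], inst.nonlin_smooth_vox / red)
        mag = np.sqrt((low**2).sum(axis=0)).max()
        if mag > 0:
            low *= strength / mag
        # Jacobian of x + u(x): folding where det(I + du/dx) <= 0
        grads = [np.gradient(low[i], float(red)) for i in range(3)]
        jac = np.zeros(low_shape + (3, 3), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                jac[..., i, j] = grads[i][j] + (1.0 if i == j else 0.0)
        det = np.linalg.det(jac)
        if (det <= 0).mean() <= 0.02:
            field = np.empty((3,) + shape, dtype=np.float32)
            for ax in range(3):
                field[ax] = ndimage.zoom(
                    low[ax], np.asarray(shape) / np.asarray(low_shape), order=1
                )
            return field
        strength /= 2.0
    return np.zeros((3,) + shape, dtype=np.float32)


def apply_spatial_transform(
    label_map: LabelMap, inst: GenerationInstance
) -> LabelMap:
    """Geometric augmentation: affine + smooth nonlinear deformation with
    nearest-neighbour label resampling (single composed resample), plus an
    optional left-right flip with contralateral label swap. The result is
    the ground-truth map for training."""
    grid = label_map.grid
    if inst.flip:
        grid = grid[::-1].copy()
        swap = np.arange(grid.max() + 1)
        for e in label_map.labels:
            if e.contralateral_id is not None:
                swap[e.id] = e.contralateral_id
        grid = swap[grid]
    if inst.is_identity_geometry():
        return label_map.with_grid(grid)

    shape = grid.shape
    center = (np.asarray(shape) - 1) / 2.0
    A = np.linalg.inv(_affine_matrix(inst, center))  # backward map
    rng = np.random.default_rng(np.random.SeedSequence([inst.seed, 0xF1E1D]))
    disp = _nonlinear_field(shape, inst, rng)
    coords = np.stack(
        np.meshgrid(*[np.arange(n, dtype=np.float32) for n in shape], indexing="ij")
    )
    warped = coords + disp
    out = np.empty_like(warped)
    for i in range(3):
        out[i] = (
            A[i, 0] * warped[0] + A[i, 1] * warped[1] + A[i, 2] * warped[2] + A[i, 3]
        )
    new_grid = ndimage.map_coordinates(grid, out, order=0, mode="constant", cval=0)
    return label_map.with_grid(new_grid)


# ---------------------------------------------------------------------------
# intensity model


def synthesize_gmm_image(label_map: LabelMap, inst: GenerationInstance) -> IntensityVolume:
    """Sample a preliminary image from the label-conditioned Gaussian
    mixture: the intensity of a voxel with label k is drawn i.i.d. from
    Normal(mu_k, sigma_k^2)."""
    grid = label_map.grid
    present = np.unique(grid)
    missing = [int(v) for v in present if int(v) not in inst.mu or int(v) not in inst.sigma]
    if missing:
        raise ConfigurationError(f"labels {missing} have no GMM parameters in the instance")
    top = int(present.max()) + 1
    mu_lut = np.zeros(top, dtype=np.float32)
    sd_lut = np.zeros(top, dtype=np.float32)
    for k in present:
        mu_lut[k] = inst.mu[int(k)]
        sd_lut[k] = inst.sigma[int(k)]
    rng = np.random.default_rng(np.random.SeedSequence([inst.seed, 0x6A9]))
    img = mu_lut[grid] + sd_lut[grid] * rng.standard_normal(grid.shape, dtype=np.float32)
    return IntensityVolume(img, label_map.spacing_mm, label_map.affine)


def _smooth_field(shape, smooth_vox, rng) -> np.ndarray:
    f = rng.standard_normal(shape).astype(np.float32)
    f = ndimage.gaussian_filter(f, smooth_vox)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def corrupt_intensities(img: IntensityVolume, inst: GenerationInstance) -> IntensityVolume:
    """In order: multiply by a smooth positive bias field, add Gaussian
    noise, min-max rescale to [0, 1], raise voxel-wise to the gamma
    exponent. A constant image at the rescale step maps to all zeros."""
    rng = np.random.default_rng(np.random.SeedSequence([inst.seed, 0xB1A5]))
    x = img.grid.astype(np.float32)
    if inst.bias_log_amplitude > 0:
        bias = np.exp(inst.bias_log_amplitude * _smooth_field(x.shape, inst.bias_smooth_vox, rng))
        x = x * bias
    if inst.noise_std > 0:
        x = x + inst.noise_std * rng.standard_normal(x.shape, dtype=np.float32)
    lo, hi = float(x.min()), float(x.max())
    x = np.zeros_like(x) if hi - lo <= 0 else (x - lo) / (hi - lo)
    if inst.gamma != 1.0:
        x = np.power(x, inst.gamma, dtype=np.float32)
    return img.with_grid(x)


def simulate_resolution(img: IntensityVolume, inst: GenerationInstance) -> IntensityVolume:
    """Low-resolution / partial-volume simulation: anisotropic Gaussian blur
    with per-axis sigma 0.85 x spacing (no blur at 1 mm), subsample to the
    drawn spacing, then resample linearly back to the 1 mm grid. Output grid
    dims always equal input dims."""
    spacing = np.maximum(1.0, np.asarray(inst.spacing_mm, dtype=float))
    if np.allclose(spacing, 1.0):
        return img
    sigma = np.where(spacing > 1.0, 0.85 * spacing, 0.0)
    x = ndimage.gaussian_filter(img.grid.astype(np.float32), sigma)
    shape = np.asarray(x.shape)
    low_shape = np.maximum(1, np.ceil(shape / spacing - 1e-9).astype(int))
    # voxel-centre sampling positions of the low-res grid in 1 mm indices
    low_coords = [
        (np.arange(n) + 0.5) * spacing[ax] - 0.5 for ax, n in enumerate(low_shape)
    ]
    mesh = np.meshgrid(*low_coords, indexing="ij")
    low = ndimage.map_coordinates(x, np.stack(mesh), order=1, mode="nearest")
    # back to the original 1 mm grid
    up_coords = [
        ((np.arange(n) + 0.5) / spacing[ax]) - 0.5 for ax, n in enumerate(shape)
    ]
    mesh = np.meshgrid(*up_coords, indexing="ij")
    up = ndimage.map_coordinates(low, np.stack(mesh), order=1, mode="nearest")
    return img.with_grid(up.astype(np.float32))


# ---------------------------------------------------------------------------
# example generation


def _reduce_target(deformed: LabelMap, target_labels: str) -> LabelMap:
    if target_labels == "fine":
        return deformed
    if target_labels == "coarse":
        return group_to_coarse(deformed)
    if target_labels == "cortex":
        return toy_cortex_parcels(deformed)
    raise ValueError(f"unknown target_labels {target_labels!r}")


def generate_training_pair(
    label_map: LabelMap,
    priors: GenerationPriors,
    target_labels: str = "fine",
    seed: int = 0,
) -> tuple[IntensityVolume, LabelMap]:
    """Full generative chain: spatial transform -> GMM sampling -> intensity
    corruption -> resolution simulation. The ground truth is the deformed
    label map reduced to the requested target space (``coarse`` for S1,
    ``fine`` for S2, ``cortex`` parcels for S3)."""
    ss = np.random.SeedSequence([int(seed), 0x7EA1]).generate_state(1)[0]
    inst = sample_generation_instance(priors, int(ss), label_map.label_ids)
    deformed = apply_spatial_transform(label_map, inst)
    img = synthesize_gmm_image(deformed, inst)
    img = corrupt_intensities(img, inst)
    img = simulate_resolution(img, inst)
    return img, _reduce_target(deformed, target_labels)


def generate_denoiser_example(
    label_map: LabelMap,
    frozen_s1,
    wide_priors: GenerationPriors,
    seed: int = 0,
    coarse_order: Sequence[int] = (0, 1, 2, 3, 4),
) -> tuple[np.ndarray, LabelMap]:
    """One denoiser training example: a heavily degraded synthetic image is
    segmented by the trained, frozen coarse segmenter S1; the denoiser input
    is S1's hardened one-hot output and the target is the deformed coarse
    ground truth."""
    if not wide_priors.wide_mode:
        raise ConfigurationError(
            "denoiser examples require widened corruption priors (wide_mode=True)"
        )
    if not getattr(frozen_s1, "frozen", False):
        raise ConfigurationError("S1 must be trained and frozen before training D")
    img, gt = generate_training_pair(label_map, wide_priors, "coarse", seed)
    soft = frozen_s1.forward(img.grid[None])
    order = list(coarse_order)
    hard = np.asarray(order)[np.argmax(soft, axis=0)]
    return one_hot(hard, order), gt


def generate_qc_example(
    label_map: LabelMap,
    frozen_pipeline: dict,
    wide_priors: GenerationPriors,
    qc_regions: dict[str, list[int]],
    seed: int = 0,
):
    """One QC-regressor example: degrade an image, segment it with the
    frozen S1 -> D -> S2 pipeline, and pair the soft fine segmentation
    with the vector of true per-region hard Dice scores against the ground
    truth."""
    from .pipeline import run_pipeline  # local import to avoid a cycle
    from .stats import hard_dice

    for name in ("s1", "d", "s2"):
        net = frozen_pipeline.get(name)
        if net is None or not getattr(net, "frozen", False):
            raise ConfigurationError(f"{name} must be trained and frozen before training R")
    table_ids = set(label_map.label_ids)
    for region, ids in qc_regions.items():
        if not set(ids) <= table_ids:
            raise ConfigurationError(f"QC region {region!r} uses ids absent from the label table")
    if not wide_priors.wide_mode:
        raise ConfigurationError("QC examples require widened corruption priors")

    img, gt = generate_training_pair(label_map, wide_priors, "fine", seed)
    result, _ = run_pipeline(
        IntensityVolume(img.grid, img.spacing_mm, img.affine),
        frozen_pipeline,
        fine_order=sorted(table_ids),
        qc_regions=qc_regions,
        run_qc=False,
    )
    seg = result.hard.grid
    dice = np.array(
        [
            hard_dice(np.isin(seg, ids), np.isin(gt.grid, ids))
            for ids in qc_regions.values()
        ],
        dtype=np.float32,
    )
    # R sees the soft fine segmentation: per-voxel confidence is part of
    # the quality signal the regressor learns from
    return result.soft, dice
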