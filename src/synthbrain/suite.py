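"""Orchestration: build and train the module chain S1 -> D -> S2 (-> S3)
and the QC regressor R with the frozen-upstream protocol.

Each module trains separately on synthetic data generated on the fly from
label maps, one fresh volume per step:

* S1 (coarse segmenter) on (image, coarse ground truth) pairs;
* D (denoiser) on S1's hardened outputs for heavily degraded images
  (widened corruption priors), with S1 frozen;
* S2 (fine segmenter) on (image + coarse prior channels, fine ground
  truth), the prior channels coming from the frozen S1 (+ D when present);
* S3 (cortex parcellator) on (image + cortex mask, parcel ground truth);
* R (QC regressor) on (one-hot fine segmentation, true per-region Dice)
  pairs from the frozen S1 -> D -> S2 pipeline under widened priors; a
  fixed pool of examples is pre-generated and cycled, since each example
  requires a full pipeline pass.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .nets import Network, build_denoiser_spec, build_regressor_spec, build_segmenter_spec, instantiate
from .pipeline import harden
from .synth import (
    ConfigurationError,
    GenerationPriors,
    generate_denoiser_example,
    generate_qc_example,
    generate_training_pair,
)
from .toy_anatomy import qc_region_ids
from .training import TrainingConfig, train_module
from .volumes import LabelMap, group_to_coarse, one_hot

__all__ = ["train_suite_module", "train_toy_suite"]

_COARSE_ORDER = (0, 1, 2, 3, 4)


def _fine_order(maps: Sequence[LabelMap]) -> tuple[int, ...]:
    return tuple(maps[0].label_ids)


def _seed_base(cfg: TrainingConfig, salt: int) -> int:
    return int(np.random.SeedSequence([cfg.seed, salt]).generate_state(1)[0] % (2**31))


def train_suite_module(
    which: str,
    maps: Sequence[LabelMap],
    priors: GenerationPriors,
    cfg: TrainingConfig,
    upstream: Mapping[str, Network] | None = None,
    scale: str = "toy",
    prior_mode: str = "pipeline",
    n_parcels: int = 4,
    r_pool: int = 64,
) -> tuple[Network, np.ndarray]:
    """Train one module; returns the trained network and its loss trace.

    ``prior_mode`` controls the coarse prior channels seen by S2 during
    training: ``pipeline`` (frozen S1, plus D if provided), ``ground_truth``
    (perfect priors), or ``zero`` (no priors).
    """
    upstream = dict(upstream or {})
    fine_order = _fine_order(maps)
    n_fine = len(fine_order)
    base = _seed_base(cfg, {"s1": 1, "d": 2, "s2": 3, "s3": 4, "r": 5}[which])

    if which == "s1":
        net = instantiate(build_segmenter_spec(len(_COARSE_ORDER), 1, scale), cfg.seed)

        def source(step: int):
            lm = maps[step % len(maps)]
            img, gt = generate_training_pair(lm, priors, "coarse", seed=base + step)
            return img.grid[None], one_hot(gt, _COARSE_ORDER)

        return train_module(net, source, cfg)

    if which == "d":
        s1 = upstream.get("s1")
        if s1 is None:
            raise ConfigurationError("training D requires a frozen s1 upstream")
        wide = priors if priors.wide_mode else priors.widened()
        net = instantiate(build_denoiser_spec(len(_COARSE_ORDER), scale), cfg.seed)

        def source(step: int):
            lm = maps[step % len(maps)]
            x, gt = generate_denoiser_example(lm, s1, wide, seed=base + step)
            return x, one_hot(gt, _COARSE_ORDER)

        return train_module(net, source, cfg, frozen_upstream=[s1])

    if which == "s2":
        s1, d = upstream.get("s1"), upstream.get("d")
        if prior_mode == "pipeline" and s1 is None:
            raise ConfigurationError("training S2 in pipeline mode requires a frozen s1")
        net = instantiate(
            build_segmenter_spec(n_fine, 1 + len(_COARSE_ORDER), scale), cfg.seed
        )
        frozen = [u for u in (s1, d) if u is not None]

        def source(step: int):
            lm = maps[step % len(maps)]
            img, gt = generate_training_pair(lm, priors, "fine", seed=base + step)
            x = img.grid[None]
            if prior_mode == "pipeline":
                coarse = s1.forward(x)
                if d is not None:
                    coarse = d.forward(one_hot(harden(coarse, _COARSE_ORDER), _COARSE_ORDER))
            elif prior_mode == "ground_truth":
                coarse = one_hot(group_to_coarse(gt), _COARSE_ORDER)
            elif prior_mode == "zero":
                coarse = np.zeros((len(_COARSE_ORDER),) + x.shape[1:], dtype=np.float32)
            else:
                raise ValueError(f"unknown prior_mode {prior_mode!r}")
            return np.concatenate([x, coarse], axis=0), one_hot(gt, fine_order)

        return train_module(net, source, cfg, frozen_upstream=frozen)

    if which == "s3":
        cortex_ids = [e.id for e in maps[0].labels if e.name == "cortex"]
        parcel_order = tuple(range(n_parcels + 1))
        net = instantiate(
            build_segmenter_spec(n_parcels + 1, 1 + len(cortex_ids), scale), cfg.seed
        )

        def source(step: int):
            lm = maps[step % len(maps)]
            img, gt = generate_training_pair(lm, priors, "cortex", seed=base + step)
            # cortex mask from the ground truth (teacher forcing at train time)
            mask = (gt.grid > 0).astype(np.float32)[None]
            return np.concatenate([img.grid[None], mask], axis=0), one_hot(gt, parcel_order)

        return train_module(net, source, cfg)

    if which == "r":
        for name in ("s1", "d", "s2"):
            if name not in upstream:
                raise ConfigurationError(f"training R requires a frozen {name} upstream")
        wide = priors if priors.wide_mode else priors.widened()
        regions = qc_region_ids(maps[0])
        net = instantiate(build_regressor_spec(len(regions), n_fine, scale), cfg.seed)
        pool = []
        for i in range(r_pool):
            lm = maps[i % len(maps)]
            pool.append(
                generate_qc_example(lm, upstream, wide, regions, seed=base + i)
            )

        def source(step: int):
            return pool[step % len(pool)]

        return train_module(
            net, source, cfg, frozen_upstream=[upstream[n] for n in ("s1", "d", "s2")]
        )

    raise ValueError(f"unknown module {which!r}")


def train_toy_suite(
    maps: Sequence[LabelMap],
    priors: GenerationPriors | None = None,
    seed: int = 0,
    steps: Mapping[str, int] | None = None,
    learning_rate: float = 1e-3,
    include_s3: bool = False,
) -> dict[str, Network]:
    """Train the desk-scale suite end to end (S1, D, S2, R and optionally
    S3), freezing each module before its consumers train. Returns the
    handle dictionary used by the inference pipeline."""
    priors = priors or GenerationPriors()
    steps = dict(steps or {})
    handles: dict[str, Network] = {}
    order = ["s1", "d", "s2"] + (["s3"] if include_s3 else []) + ["r"]
    for i, which in enumerate(order):
        cfg = TrainingConfig(
            learning_rate=learning_rate,
            steps=steps.get(which, 300),
            seed=seed + i,
            loss="sum_of_squares" if which == "r" else "soft_dice",
        )
        net, _ = train_suite_module(which, maps, priors, cfg, upstream=handles)
        handles[which] = net.freeze()
    return handles
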