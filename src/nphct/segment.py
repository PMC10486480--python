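"""Toy CSF segmentation and noisy-label simulation.

A deterministic intensity-threshold segmenter stands in for a trained
segmentation network: the downstream pipeline's contract is "any producer of
:class:`~nphct.phantom.LabelVolume`", so a learned model can be slotted in
without touching feature extraction or classification. ``corrupt_labels``
simulates the weak/noisy supervision regime under which such models are
trained.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .phantom import (
    BACKGROUND,
    CSF,
    DEFAULT_CSF_MEAN,
    DEFAULT_WG_MEAN,
    WHITE_GREY,
    IntensityVolume,
    LabelVolume,
)


def threshold_segment(
    vol: IntensityVolume,
    brain_mask: np.ndarray | str = "auto",
    threshold: float | str = "midpoint",
    csf_mean: float = DEFAULT_CSF_MEAN,
    wg_mean: float = DEFAULT_WG_MEAN,
    background_cut: float | None = None,
) -> LabelVolume:
    """Segment CSF vs white/grey matter by intensity threshold.

    Within the brain mask, voxels below the threshold become CSF and the rest
    white/grey; voxels outside the mask are background. ``threshold="midpoint"``
    uses the mean of the two configured class means. ``brain_mask="auto"``
    takes voxels above ``background_cut`` (default: halfway between the
    renderer's background fill and ``csf_mean``).
    """
    values = np.asarray(vol.values, dtype=float)
    if not np.isfinite(values).all():
        raise ParameterError("intensity volume contains non-finite values")
    if isinstance(brain_mask, str):
        if brain_mask != "auto":
            raise ParameterError(f"unknown brain_mask mode {brain_mask!r}")
        if background_cut is None:
            bg_fill = csf_mean - (wg_mean - csf_mean)
            background_cut = 0.5 * (bg_fill + csf_mean)
        mask = values > background_cut
    else:
        mask = np.asarray(brain_mask, dtype=bool)
        if mask.shape != values.shape:
            raise ParameterError("brain_mask shape does not match volume")
    if not mask.any():
        raise DegenerateInputError("brain mask is empty")
    if threshold == "midpoint":
        threshold = 0.5 * (csf_mean + wg_mean)
    labels = np.full(values.shape, BACKGROUND, dtype=np.uint8)
    labels[mask & (values < threshold)] = CSF
    labels[mask & (values >= threshold)] = WHITE_GREY
    return LabelVolume(labels=labels, voxel_spacing=vol.voxel_spacing, axial_axis=vol.axial_axis)


def corrupt_labels(vol: LabelVolume, flip_rate: float, seed: int = 0) -> LabelVolume:
    """Flip each brain voxel's CSF/white–grey label with probability ``flip_rate``.

    Background is untouched; seeded and reproducible.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ParameterError(f"flip_rate must be in [0, 1], got {flip_rate}")
    rng = np.random.default_rng(seed)
    labels = vol.labels.copy()
    brain = vol.brain_mask()
    flips = brain & (rng.random(labels.shape) < flip_rate)
    swapped = np.where(labels == CSF, WHITE_GREY, CSF).astype(labels.dtype)
    labels[flips] = swapped[flips]
    return LabelVolume(labels=labels, voxel_spacing=vol.voxel_spacing, axial_axis=vol.axial_axis)


def dice(a: LabelVolume, b: LabelVolume, label: int = CSF) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) for one label class.

    Defined as 1.0 when both sets are empty (identical empty segmentations
    agree perfectly).
    """
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma, mb = a.labels == label, b.labels == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom
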