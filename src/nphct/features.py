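"""Volumetric CSF features over label volumes.

Twelve quantities are computed globally (over all brain-containing slices)
and per axial partition 0–9 (0 most inferior, 9 most superior):

========================  =====================================================
name                      definition (per slice counts N_CSF, N_WG, image_size)
========================  =====================================================
CSF ratio                 N_CSF / (N_CSF + N_WG), counts pooled over the region
CSF/WG ratio              N_CSF / N_WG, counts pooled over the region
CSF size                  N_CSF / image_size, pooled
Brain size                N_WG / image_size, pooled
Mean/Min/Max/Std of the per-slice CSF ratio over the region's slices
Mean/Min/Max/Std of the per-slice CSF/WG ratio over the region's slices
========================  =====================================================

The unqualified "CSF ratio" of a region is the pooled-count ratio; the
slice-aggregated statistics (Mean/Min/Max/Std) are separate features. Std is
the population standard deviation (divisor n). Slices with no brain voxels
are excluded before partitioning; partitions are equal-count contiguous bins
``floor(k*i/n)`` over the n brain slices ranked inferior→superior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .phantom import CSF, WHITE_GREY, LabelVolume

#: Cap for the CSF/WG ratio when a region has CSF but no white/grey voxels;
#: keeps feature matrices finite for the selection and model-fitting stages.
DEFAULT_WG_ZERO_CAP = 1e6

_STEMS = ("CSF ratio", "CSF/WG ratio", "CSF size", "Brain size")
_AGGS = ("Mean", "Min", "Max", "Std")


@dataclass(frozen=True)
class SliceCounts:
    """Voxel counts for one axial slice."""

    n_csf: int
    n_wg: int
    image_size: int

    def __post_init__(self) -> None:
        if self.n_csf < 0 or self.n_wg < 0 or self.image_size < 0:
            raise ParameterError("counts must be >= 0")
        if self.n_csf + self.n_wg > self.image_size:
            raise ParameterError("class counts exceed slice size")

    @property
    def has_brain(self) -> bool:
        return self.n_csf + self.n_wg > 0


@dataclass(frozen=True)
class PartitionScheme:
    """Assignment of brain-containing slice indices to partitions 0..k-1.

    ``slice_indices`` are absolute axial indices ordered inferior→superior;
    ``partition_ids`` is the parallel array of partition labels.
    """

    slice_indices: tuple[int, ...]
    partition_ids: tuple[int, ...]
    k: int

    def slices_in(self, partition: int) -> tuple[int, ...]:
        return tuple(
            s for s, p in zip(self.slice_indices, self.partition_ids) if p == partition
        )


def count_slice(slice2d: np.ndarray) -> SliceCounts:
    """Count CSF and white/grey voxels in one 2D label slice."""
    arr = np.asarray(slice2d)
    return SliceCounts(
        n_csf=int((arr == CSF).sum()),
        n_wg=int((arr == WHITE_GREY).sum()),
        image_size=int(arr.size),
    )


def slice_counts(vol: LabelVolume) -> list[SliceCounts]:
    """Per-slice counts along the axial axis, inferior→superior."""
    labels = np.moveaxis(vol.labels, vol.axial_axis, 0)
    return [count_slice(labels[i]) for i in range(labels.shape[0])]


def assign_partitions(vol: LabelVolume, k: int = 10) -> PartitionScheme:
    """Split brain-containing slices into ``k`` contiguous equal-count bins.

    Slice ranked ``i`` of ``n`` (inferior→superior) goes to partition
    ``floor(k*i/n)``; partition sizes therefore differ by at most one. Slices
    without brain voxels are excluded. Raises if fewer than ``k`` brain
    slices exist.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    counts = slice_counts(vol)
    brain = [i for i, c in enumerate(counts) if c.has_brain]
    n = len(brain)
    if n < k:
        raise DegenerateInputError(f"need at least {k} brain slices, found {n}")
    ids = tuple(k * i // n for i in range(n))
    return PartitionScheme(slice_indices=tuple(brain), partition_ids=ids, k=k)


def slice_ratios(
    c: SliceCounts, wg_zero_cap: float = DEFAULT_WG_ZERO_CAP
) -> tuple[float, float, float, float]:
    """(csf_ratio, csf_wg_ratio, csf_size, brain_size) for one slice.

    Degenerate conventions: an empty slice yields all zeros; CSF with no
    white/grey yields the configured cap for the CSF/WG ratio.
    """
    if c.n_csf + c.n_wg == 0:
        return (0.0, 0.0, 0.0, 0.0)
    csf_ratio = c.n_csf / (c.n_csf + c.n_wg)
    if c.n_wg == 0:
        csf_wg = wg_zero_cap
    else:
        csf_wg = c.n_csf / c.n_wg
    size = c.image_size if c.image_size > 0 else 1
    return (csf_ratio, csf_wg, c.n_csf / size, c.n_wg / size)


def aggregate(values: list[float] | np.ndarray) -> tuple[float, float, float, float]:
    """(mean, min, max, population std) of per-slice values.

    Population standard deviation uses divisor n.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("cannot aggregate an empty list")
    return (float(arr.mean()), float(arr.min()), float(arr.max()), float(arr.std(ddof=0)))


def _region_features(region: list[SliceCounts], wg_zero_cap: float) -> dict[str, float]:
    pooled = SliceCounts(
        n_csf=sum(c.n_csf for c in region),
        n_wg=sum(c.n_wg for c in region),
        image_size=sum(c.image_size for c in region),
    )
    csf_ratio, csf_wg, csf_size, brain_size = slice_ratios(pooled, wg_zero_cap)
    per_slice = [slice_ratios(c, wg_zero_cap) for c in region]
    out = {
        "CSF ratio": csf_ratio,
        "CSF/WG ratio": csf_wg,
        "CSF size": csf_size,
        "Brain size": brain_size,
    }
    for stem, col in (("CSF ratio", 0), ("CSF/WG ratio", 1)):
        mean, mn, mx, std = aggregate([p[col] for p in per_slice])
        out[f"Mean {stem}"] = mean
        out[f"Min {stem}"] = mn
        out[f"Max {stem}"] = mx
        out[f"Std {stem}"] = std
    return out


def feature_names(k: int = 10) -> list[str]:
    """Ordered feature names: 12 global then 12 per partition 0..k-1."""
    names = [f"{s}_all".replace(" ", "_") for s in _STEMS]
    names += [f"{a} {s}_all" for s in ("CSF ratio", "CSF/WG ratio") for a in _AGGS]
    for p in range(k):
        names += [f"{s}_{p}" for s in _STEMS]
        names += [f"{a} {s}_{p}" for s in ("CSF ratio", "CSF/WG ratio") for a in _AGGS]
    return names


def extract_features(
    vol: LabelVolume,
    scheme: PartitionScheme | None = None,
    k: int = 10,
    wg_zero_cap: float = DEFAULT_WG_ZERO_CAP,
) -> pd.Series:
    """All global and per-partition features for one scan as a named Series.

    Global features carry the suffix ``_all`` (the pooled global CSF ratio is
    ``CSF_ratio_all``); partition features carry ``_0`` … ``_{k-1}``, e.g.
    ``CSF ratio_5`` or ``Std CSF ratio_9``.
    """
    if scheme is None:
        scheme = assign_partitions(vol, k=k)
    counts = slice_counts(vol)
    brain_region = [counts[i] for i in scheme.slice_indices]
    values: dict[str, float] = {}
    glob = _region_features(brain_region, wg_zero_cap)
    for key, v in glob.items():
        values[f"{key}_all".replace(" ", "_") if key in _STEMS else f"{key}_all"] = v
    for p in range(scheme.k):
        region = [counts[i] for i in scheme.slices_in(p)]
        for key, v in _region_features(region, wg_zero_cap).items():
            values[f"{key}_{p}"] = v
    return pd.Series(values, dtype=float)[feature_names(scheme.k)]


def cohort_feature_matrix(
    cohort: list[tuple[LabelVolume, int]],
    k: int = 10,
    wg_zero_cap: float = DEFAULT_WG_ZERO_CAP,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix (one row per scan) and binary label vector for a cohort."""
    rows = [extract_features(vol, k=k, wg_zero_cap=wg_zero_cap) for vol, _ in cohort]
    labels = np.array([g for _, g in cohort], dtype=int)
    return pd.DataFrame(rows).reset_index(drop=True), labels
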