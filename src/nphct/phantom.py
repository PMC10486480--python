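"""Synthetic brain phantoms for CSF volumetry.

This module generates seeded, CT-like 3D label volumes that emulate the two
diagnostic groups the downstream pipeline distinguishes:

* **NPH-like** phantoms carry enlarged central (ventricular) CSF at the
  mid-axial levels of the brain and focally enlarged sulcal CSF pockets near
  the vertex — the two morphological signatures of normal-pressure
  hydrocephalus on non-contrast CT.
* **Normal** phantoms carry small central ventricles and a peripheral CSF rim
  (age-appropriate diffuse atrophy) as their dominant CSF compartment.

Geometry is deliberately simple — an ellipsoidal head with axial cylindrical
CSF compartments — because the downstream features only need *where along
the inferior→superior axis* CSF accumulates, not anatomical realism.
Ventricles occupy the 38–63% band of brain-containing slices and focal
sulcal pockets the 80–91% band, so that under a ten-level axial partition
they load onto the mid partitions (≈4–6) and partition 8 respectively.
Several diagnosis-independent sources of variation that real CT cohorts
exhibit are modeled as well — per-slice anatomical irregularity with rare
focal spikes, heavy-tailed basal cisterns and vertex sulci, cranial-size
variation, and variable inferior scan coverage — because they shape which
feature families carry usable signal.

The module also carries the grouped total-score distribution of the published
217-subject reference cohort (112 normal, 105 NPH), which is the input to all
diagnostic-accuracy statistics in :mod:`nphct.diagnostics`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError

#: Integer codes used in every label volume.
BACKGROUND, CSF, WHITE_GREY = 0, 1, 2

#: Default intensity model for :func:`render_intensity` (HU-like, unitless).
DEFAULT_CSF_MEAN = 5.0
DEFAULT_WG_MEAN = 35.0


@dataclass(frozen=True)
class PhantomParams:
    """Parameters controlling one phantom's geometry and intensity noise.

    Parameters
    ----------
    grid_shape
        Voxels per axis, ordered (z, y, x) with z the axial (inferior→
        superior) axis. Each axis must be at least 10.
    voxel_spacing
        Millimetres per voxel along (z, y, x).
    ventricle_scale
        Dimensionless ≥ 0. Multiplies the radii of the paired central
        ventricles; 1.0 is the normal-size reference, 0 removes them.
    sulcal_scale
        Dimensionless ≥ 0. Multiplies the radii of the focal sulcal CSF
        pockets near the vertex.
    atrophy_scale
        Dimensionless ≥ 0. Controls the thickness of the thin peripheral
        CSF rim (diffuse cortical atrophy).
    noise_sd
        Standard deviation of the additive Gaussian intensity noise used by
        :func:`render_intensity` when no explicit value is given.
    head_scale
        Overall head-size factor in (0, 1.15]; 1.0 is the reference head.
        Jittered per subject in cohorts to mimic natural cranial-size
        variation (which real ratio features are invariant to, but absolute
        area features are not).
    base_cut
        Fraction (0–0.3) of the most inferior brain slices left out of the
        scan, emulating variable skull-base coverage between acquisitions.
    seed
        Seed for any stochastic stage consuming these parameters.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    ventricle_scale: float = 1.0
    sulcal_scale: float = 1.0
    atrophy_scale: float = 1.0
    noise_sd: float = 5.0
    head_scale: float = 1.0
    base_cut: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 10 for n in self.grid_shape):
            raise ParameterError(f"grid_shape must be 3 axes, each >= 10, got {self.grid_shape}")
        if not 0 < self.head_scale <= 1.15:
            raise ParameterError("head_scale must be in (0, 1.15]")
        if not 0.0 <= self.base_cut <= 0.3:
            raise ParameterError("base_cut must be in [0, 0.3]")
        for name in ("ventricle_scale", "sulcal_scale", "atrophy_scale"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ParameterError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def replace(self, **kwargs) -> "PhantomParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


#: Shipped presets for the two diagnostic groups. The NPH preset enlarges the
#: ventricles and the focal sulcal pockets; the normal preset's CSF is
#: dominated by the peripheral atrophy rim.
NORMAL_PRESET = PhantomParams(ventricle_scale=1.0, sulcal_scale=0.65, atrophy_scale=1.0)
NPH_PRESET = PhantomParams(ventricle_scale=1.8, sulcal_scale=1.5, atrophy_scale=1.0)


@dataclass
class LabelVolume:
    """A 3D voxel grid labelled background / CSF / white–grey matter."""

    labels: np.ndarray
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    axial_axis: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ParameterError("labels must be a 3D array")
        bad = ~np.isin(self.labels, (BACKGROUND, CSF, WHITE_GREY))
        if bad.any():
            raise ParameterError("labels must only contain {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def brain_mask(self) -> np.ndarray:
        """Boolean mask of voxels that are CSF or white/grey matter."""
        return self.labels != BACKGROUND


@dataclass
class IntensityVolume:
    """A 3D grid of CT-like intensities matched to a source label volume."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    axial_axis: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float], semi: Sequence[float]) -> np.ndarray:
    """Boolean mask of the axis-aligned ellipsoid ((p-c)/r)^2 <= 1."""
    if any(s <= 0 for s in semi):
        return np.zeros(tuple(shape), dtype=bool)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, semi))
    return q <= 1.0


def generate_label_volume(params: PhantomParams) -> LabelVolume:
    """Generate a deterministic brain-like label volume from ``params``.

    The head is an ellipsoid of white/grey matter spanning ~80% of axial
    slices. CSF is the union of five compartments, all kept inside the head
    and (except the rim) clipped to a 0.95-shrunken inner head so a
    parenchymal ring survives on every slice:

    * paired central ventricles: axial cylinders over the 38–63% band of
      brain slices whose cross-section radii scale with ``ventricle_scale``
      (dilation modeled as purely radial);
    * focal sulcal pockets: peripheral cylinders in the 80–91% band scaled
      by ``sulcal_scale`` and tapered with the local head section;
    * a thin peripheral rim whose thickness grows with ``atrophy_scale``;
    * basal cisterns (2–15% band) and prominent vertex sulci (82–96% band),
      both scaled by ``atrophy_scale`` with heavy-tailed seeded per-subject
      amplitudes — identical in both shipped presets, so they add realistic
      diagnosis-independent variability rather than signal.

    Every compartment's section is modulated by a seeded per-slice
    irregularity factor with rare focal spikes. Identical parameters always
    produce bit-identical output; CSF voxel count is nondecreasing in each
    of the three scale parameters.
    """
    nz, ny, nx = (int(n) for n in params.grid_shape)
    center = ((nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0)
    hs = params.head_scale
    head_semi = (0.40 * nz * hs, 0.42 * ny * hs, 0.42 * nx * hs)
    head = _ellipsoid_mask((nz, ny, nx), center, head_semi)

    # Axial extent of brain-containing slices.
    brain_z = np.flatnonzero(head.any(axis=(1, 2)))
    z0, z1 = int(brain_z[0]), int(brain_z[-1])
    nb = z1 - z0 + 1
    zgrid = np.arange(nz)[:, None, None]

    # Per-slice irregularity factors (seeded): real anatomy is not smooth
    # along z, so slice-extreme statistics vary between subjects while the
    # pooled per-region ratios stay stable.
    wobble_rng = np.random.default_rng(params.seed)
    base = 1.0 + 0.06 * wobble_rng.standard_normal(nz)
    u = wobble_rng.random(nz)
    factor = np.ones(nz)
    factor[u < 0.05] = wobble_rng.uniform(0.35, 0.65, int((u < 0.05).sum()))
    factor[u > 0.95] = wobble_rng.uniform(1.45, 1.95, int((u > 0.95).sum()))
    wobble = np.clip(base * factor, 0.3, 2.0)
    ygrid, xgrid = np.ogrid[0:ny, 0:nx]

    # Paired central ventricles: axial cylinders over the 38-63% band of
    # brain slices (dilation is modeled as purely radial, so every slice of
    # an affected partition carries the ventricular signal).
    vs = params.ventricle_scale
    vent = np.zeros((nz, ny, nx), dtype=bool)
    if vs > 0:
        v_semi_y, v_semi_x = 0.11 * ny * hs * vs, 0.19 * nx * hs * vs
        vband = (zgrid >= z0 + 0.38 * nb) & (zgrid <= z0 + 0.63 * nb)
        # normalized elliptical distance to the nearer horn, wobbled per slice
        dist = np.minimum(
            np.sqrt(
                ((ygrid - (center[1] - 0.085 * ny * hs)) / v_semi_y) ** 2
                + ((xgrid - center[2]) / v_semi_x) ** 2
            ),
            np.sqrt(
                ((ygrid - (center[1] + 0.085 * ny * hs)) / v_semi_y) ** 2
                + ((xgrid - center[2]) / v_semi_x) ** 2
            ),
        )
        vent = (dist[None, :, :] <= wobble[:, None, None]) & vband

    # Focal sulcal pockets near the vertex (top 20% of brain slices).
    ss = params.sulcal_scale
    sulci = np.zeros((nz, ny, nx), dtype=bool)
    if ss > 0:
        pz = z0 + 0.86 * nb
        # Head cross-section shrinks near the vertex; place pockets at a
        # fraction of the local section radius so they stay intra-cranial.
        frac = np.sqrt(max(0.0, 1.0 - ((pz - center[0]) / head_semi[0]) ** 2))
        ry, rx = 0.55 * frac * head_semi[1], 0.55 * frac * head_semi[2]
        r_pocket = 0.07 * min(ny, nx) * hs * ss
        # Pockets are axial cylinders spanning the 80-90% band (so the
        # affected slices stay within one partition), with the same seeded
        # per-slice radial irregularity as the ventricles.
        pdist = np.full((ny, nx), np.inf)
        for ang in (45.0, 135.0, 225.0, 315.0):
            a = np.deg2rad(ang)
            py, px = center[1] + ry * np.sin(a), center[2] + rx * np.cos(a)
            pdist = np.minimum(
                pdist, np.sqrt((ygrid - py) ** 2 + (xgrid - px) ** 2) / r_pocket
            )
        band = (zgrid >= z0 + 0.80 * nb) & (zgrid <= z0 + 0.91 * nb)
        # Pockets taper with the shrinking head section toward the vertex,
        # so the big inferior slices of the band carry the strongest signal.
        zrel_all = (np.arange(nz) - center[0]) / head_semi[0]
        sect_all = np.sqrt(np.clip(1.0 - zrel_all**2, 0.0, None))
        taper = sect_all / max(frac, 1e-9)
        sulci = (pdist[None, :, :] <= (wobble * taper)[:, None, None]) & band

    # Basal cisterns: central CSF in the lowest brain slices whose size
    # varies widely between subjects (heavy-tailed) but carries no group
    # signal under the shipped presets (it scales with atrophy_scale, which
    # is equal in both) -- whole-brain slice aggregates inherit this
    # variability, as they do on real scans.
    ats = params.atrophy_scale
    zrel = (np.arange(nz) - center[0]) / head_semi[0]
    sect = np.sqrt(np.clip(1.0 - zrel**2, 0.0, None))  # local section factor
    cist_dist = np.sqrt(
        ((ygrid - center[1])) ** 2 + ((xgrid - center[2])) ** 2
    )
    cisterns = np.zeros((nz, ny, nx), dtype=bool)
    if ats > 0:
        cistern_factor = float(np.clip(wobble_rng.lognormal(0.0, 0.6), 0.2, 2.5))
        cist_band = (zgrid >= z0 + 0.02 * nb) & (zgrid <= z0 + 0.15 * nb)
        crad = 0.45 * ats * cistern_factor * sect * min(head_semi[1], head_semi[2])
        cisterns = (cist_dist[None, :, :] <= crad[:, None, None]) & cist_band

    # Prominent vertex sulci: age-related cortical sulcal CSF near the top,
    # heavy-tailed across subjects and likewise group-neutral under the
    # shipped presets. Overlaps the focal-pocket band, so slice-extreme
    # statistics there are noisy in both groups.
    vertex = np.zeros((nz, ny, nx), dtype=bool)
    if ats > 0:
        vertex_factor = float(np.clip(wobble_rng.lognormal(0.0, 0.5), 0.2, 2.2))
        vx_band = (zgrid >= z0 + 0.82 * nb) & (zgrid <= z0 + 0.96 * nb)
        vz = z0 + 0.89 * nb
        vfrac = np.sqrt(max(0.0, 1.0 - ((vz - center[0]) / head_semi[0]) ** 2))
        vry, vrx = 0.45 * vfrac * head_semi[1], 0.45 * vfrac * head_semi[2]
        r_vx = 0.035 * min(ny, nx) * hs * ats * vertex_factor
        vdist = np.full((ny, nx), np.inf)
        for ang in (0.0, 90.0, 180.0, 270.0):
            a = np.deg2rad(ang)
            vy, vx_ = center[1] + vry * np.sin(a), center[2] + vrx * np.cos(a)
            vdist = np.minimum(
                vdist, np.sqrt((ygrid - vy) ** 2 + (xgrid - vx_) ** 2) / max(r_vx, 1e-9)
            )
        vertex = (vdist[None, :, :] <= wobble[:, None, None]) & vx_band

    # Thin peripheral rim: head minus a slightly shrunk inner ellipsoid,
    # limited to the central 90% of brain slices so no slice is pure CSF.
    rim = np.zeros((nz, ny, nx), dtype=bool)
    if ats > 0:
        shrink = 1.0 - 0.02 * ats
        inner = _ellipsoid_mask((nz, ny, nx), center, tuple(s * shrink for s in head_semi))
        rim = head & ~inner
        band = (zgrid >= z0 + 0.05 * nb) & (zgrid <= z0 + 0.95 * nb)
        rim &= band

    # Interior CSF structures never reach the cortex: clip them to a
    # shrunken head so a parenchymal ring always survives on every slice.
    inner_head = _ellipsoid_mask(
        (nz, ny, nx), center, tuple(s * 0.95 for s in head_semi)
    )
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[head] = WHITE_GREY
    labels[((vent | sulci | cisterns | vertex) & inner_head) | (rim & head)] = CSF
    # Variable inferior scan coverage: the lowest slices are not imaged.
    if params.base_cut > 0:
        labels[: z0 + int(params.base_cut * nb)] = BACKGROUND
    return LabelVolume(labels=labels, voxel_spacing=tuple(params.voxel_spacing), axial_axis=0)


def render_intensity(
    vol: LabelVolume,
    csf_mean: float = DEFAULT_CSF_MEAN,
    wg_mean: float = DEFAULT_WG_MEAN,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityVolume:
    """Render a label volume into CT-like intensities.

    Each brain voxel takes its class mean plus seeded Gaussian noise;
    background voxels take the constant ``csf_mean - (wg_mean - csf_mean)``,
    safely below the CSF class. Requires ``csf_mean < wg_mean`` (CSF is
    hypodense to parenchyma on CT).
    """
    if not csf_mean < wg_mean:
        raise ParameterError(f"csf_mean ({csf_mean}) must be < wg_mean ({wg_mean})")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    values = np.full(vol.shape, csf_mean - (wg_mean - csf_mean), dtype=np.float64)
    values[vol.labels == CSF] = csf_mean
    values[vol.labels == WHITE_GREY] = wg_mean
    if noise_sd > 0:
        brain = vol.brain_mask()
        values[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))
    return IntensityVolume(values=values, voxel_spacing=vol.voxel_spacing, axial_axis=vol.axial_axis)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One draw from a zero-truncated Gaussian (rejection; falls back to 0)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def generate_cohort(
    n_nph: int,
    n_normal: int,
    nph_params: PhantomParams = NPH_PRESET,
    normal_params: PhantomParams = NORMAL_PRESET,
    between_subject_sd: float = 0.15,
    head_scale_sd: float = 0.08,
    seed: int = 0,
) -> list[tuple[LabelVolume, int]]:
    """Generate a labelled synthetic cohort.

    Per-subject ventricle/sulcal/atrophy scales are drawn from zero-truncated
    Gaussians centred on the preset values with SD ``between_subject_sd``,
    giving overlap between groups; head size is jittered with SD
    ``head_scale_sd`` in both groups alike (cranial size varies between
    people but carries no diagnostic signal). Returns ``(volume, group)``
    pairs with group 1 = NPH, 0 = normal; NPH subjects first. Deterministic
    given seed.
    """
    if n_nph < 0 or n_normal < 0:
        raise ParameterError("cohort counts must be >= 0")
    if between_subject_sd < 0 or head_scale_sd < 0:
        raise ParameterError("jitter SDs must be >= 0")
    rng = np.random.default_rng(seed)
    cohort: list[tuple[LabelVolume, int]] = []
    for group, preset, n in ((1, nph_params, n_nph), (0, normal_params, n_normal)):
        for _ in range(n):
            p = preset.replace(
                ventricle_scale=_truncated_normal(rng, preset.ventricle_scale, between_subject_sd),
                sulcal_scale=_truncated_normal(rng, preset.sulcal_scale, between_subject_sd),
                atrophy_scale=_truncated_normal(rng, preset.atrophy_scale, between_subject_sd),
                head_scale=float(np.clip(rng.normal(preset.head_scale, head_scale_sd), 0.85, 1.15)),
                base_cut=float(rng.uniform(0.0, 0.06)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cohort.append((generate_label_volume(p), group))
    return cohort


@dataclass
class GroupedScoreTable:
    """Counts of normal and NPH subjects at each total score.

    The canonical input of the diagnostic-accuracy statistics: one row per
    total score with the number of normal and NPH subjects attaining it.
    """

    scores: np.ndarray
    n_normal: np.ndarray
    n_nph: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        self.n_normal = np.asarray(self.n_normal, dtype=int)
        self.n_nph = np.asarray(self.n_nph, dtype=int)
        if not (len(self.scores) == len(self.n_normal) == len(self.n_nph)):
            raise ParameterError("score table columns must have equal length")
        if len(np.unique(self.scores)) != len(self.scores):
            raise ParameterError("scores must be unique")
        if (self.n_normal < 0).any() or (self.n_nph < 0).any():
            raise ParameterError("counts must be >= 0")
        if self.n_normal.sum() + self.n_nph.sum() == 0:
            raise DegenerateInputError("score table has no subjects")
        order = np.argsort(self.scores)
        self.scores = self.scores[order]
        self.n_normal = self.n_normal[order]
        self.n_nph = self.n_nph[order]

    @property
    def total_normal(self) -> int:
        return int(self.n_normal.sum())

    @property
    def total_nph(self) -> int:
        return int(self.n_nph.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "n_normal": self.n_normal, "n_nph": self.n_nph}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupedScoreTable":
        df = pd.read_csv(path)
        return cls(df["score"].to_numpy(), df["n_normal"].to_numpy(), df["n_nph"].to_numpy())

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to per-subject ``(scores, labels)`` arrays (label 1 = NPH)."""
        scores = np.concatenate(
            [np.repeat(self.scores, self.n_normal), np.repeat(self.scores, self.n_nph)]
        )
        labels = np.concatenate(
            [np.zeros(self.total_normal, dtype=int), np.ones(self.total_nph, dtype=int)]
        )
        return scores, labels


def reference_score_table() -> GroupedScoreTable:
    """Grouped total-score counts of the published 217-subject reference cohort.

    112 normal and 105 NPH subjects scored 0–12 on the seven-item radiological
    point scale by consensus reading. These counts are the fixture from which
    the toolkit reproduces the reference study's diagnostic-accuracy figures.
    """
    return GroupedScoreTable(
        scores=np.arange(13),
        n_normal=[46, 30, 15, 12, 7, 1, 1, 0, 0, 0, 0, 0, 0],
        n_nph=[0, 1, 5, 7, 11, 17, 19, 19, 11, 9, 4, 2, 0],
    )


def save_volume(vol: LabelVolume | IntensityVolume, path: str | Path) -> None:
    """Write a volume to NIfTI with a diagonal affine from the voxel spacing."""
    data = vol.labels if isinstance(vol, LabelVolume) else vol.values
    affine = np.diag(list(vol.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_label_volume(path: str | Path, axial_axis: int = 0) -> LabelVolume:
    """Read a label volume from NIfTI."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(
        labels=np.asarray(img.dataobj).astype(np.uint8),
        voxel_spacing=spacing,
        axial_axis=axial_axis,
    )


def load_intensity_volume(path: str | Path, axial_axis: int = 0) -> IntensityVolume:
    """Read an intensity volume from NIfTI."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(
        values=np.asarray(img.dataobj, dtype=np.float64),
        voxel_spacing=spacing,
        axial_axis=axial_axis,
    )
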