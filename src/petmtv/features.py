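"""Metabolic and heterogeneity parameters of a segmented SUV volume.

Metabolic: SUVmax, SUVmean, SUVpeak (1.2 cm sphere at the maximum), MTV
and TLG (= MTV * SUVmean, exact identity). Heterogeneity: asphericity of
the total-MTV surface, Haralick texture statistics (entropy, energy,
contrast, local homogeneity) from a pooled symmetric 3D co-occurrence
matrix, and the area under the cumulative SUV-volume histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes, mesh_surface_area

from .imaging import Segmentation, SUVImage

__all__ = [
    "FeatureVector",
    "TextureConfig",
    "EmptySegmentationError",
    "suv_stats",
    "suv_peak",
    "tlg",
    "asphericity",
    "glcm_features",
    "csh_auc",
    "extract_all",
    "FEATURE_NAMES",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = (
    "mtv",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "tlg",
    "asp",
    "entropy",
    "energy",
    "contrast",
    "local_homogeneity",
    "csh_auc",
)


class EmptySegmentationError(ValueError):
    """Raised when a feature is requested for an empty segmentation."""


@dataclass(frozen=True)
class FeatureVector:
    """All per-patient PET parameters computed on the total MTV."""

    mtv: float  # ml
    suv_max: float
    suv_mean: float
    suv_peak: float
    tlg: float  # ml, SUV-weighted
    asp: float  # percent
    entropy: float  # bits
    energy: float
    contrast: float
    local_homogeneity: float
    csh_auc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _half_offsets() -> list[tuple[int, int, int]]:
    """The 13 unique 3D direction offsets at Chebyshev distance 1."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    offs.append((dx, dy, dz))
    return offs


@dataclass(frozen=True)
class TextureConfig:
    """Co-occurrence matrix parameters.

    Gray levels are equal-width bins over the lesion min-max range; the
    matrix is accumulated symmetrically over all offsets into a single
    pooled matrix and normalized to joint probabilities.
    """

    n_gray_levels: int = 64
    offsets: tuple[tuple[int, int, int], ...] = tuple(_half_offsets())
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")
        if not self.offsets:
            raise ValueError("at least one offset is required")


def _masked_values(image: SUVImage, seg: Segmentation) -> np.ndarray:
    seg.check_aligned(image)
    mask = seg.binary_mask
    if not mask.any():
        raise EmptySegmentationError("segmentation contains no lesion voxels")
    return image.voxels[mask]


def suv_stats(image: SUVImage, seg: Segmentation) -> tuple[float, float]:
    """(SUVmax, SUVmean) over the union of all labeled voxels."""
    vals = _masked_values(image, seg)
    return float(vals.max()), float(vals.mean())


def suv_peak(image: SUVImage, seg: Segmentation, sphere_diameter_mm: float = 12.0) -> float:
    """Mean SUV in a sphere centered at the hottest lesion voxel.

    Sphere membership is by voxel-center distance <= diameter/2. The
    sphere may reach outside the mask; parts outside the grid are
    clipped (and logged).
    """
    seg.check_aligned(image)
    mask = seg.binary_mask
    if not mask.any():
        raise EmptySegmentationError("segmentation contains no lesion voxels")

    radius = sphere_diameter_mm / 2.0
    spacing = np.asarray(image.spacing)
    reach = np.floor(radius / spacing).astype(int)
    offsets = np.stack(
        np.meshgrid(*[np.arange(-r, r + 1) for r in reach], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    offsets = offsets[np.linalg.norm(offsets * spacing, axis=1) <= radius]

    def sphere_mean(center: np.ndarray) -> float:
        idx = offsets + center
        in_grid = np.all((idx >= 0) & (idx < np.asarray(image.shape)), axis=1)
        if not in_grid.all():
            log.info("SUVpeak sphere clipped at the grid border (%d voxels dropped)",
                     int((~in_grid).sum()))
            idx = idx[in_grid]
        return float(image.voxels[idx[:, 0], idx[:, 1], idx[:, 2]].mean())

    # center at the hottest lesion voxel; ties go to the candidate whose
    # sphere mean is largest (keeps the plateau case equal to SUVmax)
    vmax = float(image.voxels[mask].max())
    candidates = np.argwhere(mask & (image.voxels == vmax))
    return max(sphere_mean(c) for c in candidates)


def tlg(mtv: float, suv_mean: float) -> float:
    """Total lesion glycolysis: MTV * SUVmean, exactly."""
    if mtv < 0:
        raise ValueError(f"mtv must be >= 0, got {mtv}")
    return mtv * suv_mean


def asphericity(
    seg: Segmentation, surface: str = "mesh", smoothing_sigma_vox: float = 0.7
) -> float:
    """Percent deviation of the total-MTV surface from a sphere's.

    ASP = 100 * ((H^3 / (36 pi V^2))^(1/3) - 1) with H the surface area
    and V the volume of the union mask; 0 for a perfect sphere. With
    ``surface="mesh"`` the area comes from a triangulated isosurface at
    level 0.5 of the lightly Gaussian-smoothed binary mask — smoothing
    (default 0.7 voxels) suppresses the staircase-area bias so a
    voxelized sphere calibrates to ASP ~ 0. ``surface="voxel"`` counts
    exposed voxel faces instead, which biases ASP upward.
    """
    mask = seg.binary_mask
    if not mask.any():
        raise EmptySegmentationError("segmentation contains no lesion voxels")
    if int(mask.sum()) == 1:
        warnings.warn("asphericity of a single-voxel mask is the cube value", stacklevel=2)

    spacing = np.asarray(seg.spacing, dtype=float)
    volume_mm3 = float(mask.sum()) * float(np.prod(spacing))

    if surface == "mesh":
        pad = 1 + int(np.ceil(3 * smoothing_sigma_vox))
        padded = np.pad(mask.astype(float), pad)
        if smoothing_sigma_vox > 0:
            smoothed = gaussian_filter(padded, smoothing_sigma_vox)
            # tiny masks can smooth entirely below the iso level; keep the
            # raw surface there instead of failing
            if smoothed.max() > 0.5:
                padded = smoothed
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        area_mm2 = float(mesh_surface_area(verts, faces))
    elif surface == "voxel":
        area_mm2 = 0.0
        face_areas = [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
        for axis, fa in enumerate(face_areas):
            padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
            area_mm2 += float(np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum()) * fa
    else:
        raise ValueError(f"unknown surface mode {surface!r}")

    ratio = area_mm2**3 / (36.0 * np.pi * volume_mm3**2)
    # the sphere is the analytic minimum; discretization of near-spheres
    # can dip marginally below it, so clamp at 0
    return max(0.0, float(100.0 * (ratio ** (1.0 / 3.0) - 1.0)))


def _quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.int64)
    q = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.int64)
    return np.clip(q, 0, n_levels - 1)


def glcm_matrix(image: SUVImage, seg: Segmentation, cfg: TextureConfig) -> np.ndarray:
    """Pooled, normalized gray-level co-occurrence matrix of the lesion.

    Both voxels of a pair must lie inside the mask. Returns the joint
    probability matrix p(i, j) of shape (n_levels, n_levels).
    """
    seg.check_aligned(image)
    mask = seg.binary_mask
    if int(mask.sum()) < 2:
        raise EmptySegmentationError("texture needs at least 2 labeled voxels")
    levels = np.full(image.shape, -1, dtype=np.int64)
    levels[mask] = _quantize(image.voxels[mask], cfg.n_gray_levels)

    counts = np.zeros((cfg.n_gray_levels, cfg.n_gray_levels), dtype=np.int64)
    for off in cfg.offsets:
        src = [slice(max(0, -o), min(s, s - o)) for o, s in zip(off, image.shape)]
        dst = [slice(max(0, o), min(s, s + o)) for o, s in zip(off, image.shape)]
        a = levels[tuple(src)]
        b = levels[tuple(dst)]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1)
        if cfg.symmetric:
            np.add.at(counts, (b[ok], a[ok]), 1)
    total = counts.sum()
    if total == 0:
        raise EmptySegmentationError("no in-mask voxel pairs for any offset")
    return counts / total


def glcm_features(
    image: SUVImage, seg: Segmentation, cfg: TextureConfig | None = None
) -> tuple[float, float, float, float]:
    """(entropy [bits], energy, contrast, local homogeneity).

    A constant-valued lesion degenerates to a single-cell matrix and
    returns (0, 1, 0, 1), flagged with a warning.
    """
    cfg = cfg or TextureConfig()
    vals = _masked_values(image, seg)
    if np.ptp(vals) == 0:
        warnings.warn("constant-valued lesion: degenerate single-bin texture", stacklevel=2)
    p = glcm_matrix(image, seg, cfg)
    i, j = np.indices(p.shape)
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    energy = float((p**2).sum())
    contrast = float((p * (i - j) ** 2).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    return entropy, energy, contrast, homogeneity


def csh_auc(image: SUVImage, seg: Segmentation, n_thresholds: int = 100) -> float:
    """Area under the cumulative SUV-volume histogram.

    F(t) is the fraction of the MTV with SUV >= t, evaluated at relative
    thresholds t = k/n * SUVmax for k = 0..n; the area is the trapezoid
    integral of F over the relative-threshold axis. 1.0 means perfectly
    uniform uptake.
    """
    vals = _masked_values(image, seg)
    vmax = float(vals.max())
    if vmax <= 0:
        raise ValueError("csh_auc requires suv_max > 0")
    rel = np.arange(n_thresholds + 1) / n_thresholds
    frac = (vals[None, :] >= rel[:, None] * vmax).mean(axis=1)
    return float(np.trapezoid(frac, rel))


def extract_all(
    image: SUVImage, seg: Segmentation, cfg: TextureConfig | None = None
) -> FeatureVector:
    """Compute the full per-patient feature vector on the total MTV."""
    suv_max, suv_mean = suv_stats(image, seg)
    mtv = seg.total_mtv
    entropy, energy, contrast, homogeneity = glcm_features(image, seg, cfg)
    return FeatureVector(
        mtv=mtv,
        suv_max=suv_max,
        suv_mean=suv_mean,
        suv_peak=suv_peak(image, seg),
        tlg=tlg(mtv, suv_mean),
        asp=asphericity(seg),
        entropy=entropy,
        energy=energy,
        contrast=contrast,
        local_homogeneity=homogeneity,
        csh_auc=csh_auc(image, seg),
    )
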