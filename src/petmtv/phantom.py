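"""Synthetic 3D PET phantoms with known ground truth.

Lesions are voxelized by the center-inside rule on a background plateau,
the ground-truth label grid is frozen *before* degradation, and the image
is then blurred with an isotropic Gaussian PSF and corrupted with
additive Gaussian noise (clipped at zero). Identical spec + seed yields
bitwise identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import SUVImage, Segmentation

__all__ = ["LesionSpec", "PhantomSpec", "PhantomSpecError", "generate_phantom", "reference_phantom_suite"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SHAPES = ("sphere", "ellipsoid", "cube", "union_of_spheres")


class PhantomSpecError(ValueError):
    """Raised for invalid or mutually conflicting lesion specifications."""


@dataclass(frozen=True)
class LesionSpec:
    """One analytic lesion.

    ``size_mm`` semantics depend on ``shape``: sphere -> (diameter,),
    ellipsoid -> (dx, dy, dz) full axis lengths, cube -> (edge,),
    union_of_spheres -> ignored (``spheres`` holds (center, diameter)
    pairs). ``gradient_suv_per_mm`` adds a linear intra-lesion ramp along
    the x axis around the lesion center.
    """

    shape: str
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, ...]
    uptake_suv: float
    gradient_suv_per_mm: float = 0.0
    spheres: tuple[tuple[tuple[float, float, float], float], ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise PhantomSpecError(f"unknown lesion shape {self.shape!r}")
        if self.shape != "union_of_spheres" and any(s <= 0 for s in self.size_mm):
            raise PhantomSpecError(f"size parameters must be > 0, got {self.size_mm}")
        if self.uptake_suv <= 0:
            raise PhantomSpecError("uptake_suv must be > 0")

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean membership of physical points (..., 3) in the shape."""
        d = coords - np.asarray(self.center_mm)
        if self.shape == "sphere":
            r = self.size_mm[0] / 2.0
            return np.sum(d**2, axis=-1) <= r**2
        if self.shape == "ellipsoid":
            half = np.asarray(self.size_mm) / 2.0
            return np.sum((d / half) ** 2, axis=-1) <= 1.0
        if self.shape == "cube":
            h = self.size_mm[0] / 2.0
            return np.all(np.abs(d) <= h, axis=-1)
        # union_of_spheres
        inside = np.zeros(coords.shape[:-1], dtype=bool)
        for center, diameter in self.spheres:
            dd = coords - np.asarray(center)
            inside |= np.sum(dd**2, axis=-1) <= (diameter / 2.0) ** 2
        return inside


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    lesions: tuple[LesionSpec, ...] = ()
    psf_fwhm_mm: float = 7.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise PhantomSpecError("psf_fwhm_mm and noise_sd must be >= 0")
        if self.background_suv < 0:
            raise PhantomSpecError("background_suv must be >= 0")
        for les in self.lesions:
            if les.uptake_suv <= self.background_suv:
                raise PhantomSpecError(
                    f"lesion uptake {les.uptake_suv} must exceed background {self.background_suv}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "PhantomSpec":
        raw = json.loads(text)
        lesions = tuple(
            LesionSpec(
                shape=l["shape"],
                center_mm=tuple(l["center_mm"]),
                size_mm=tuple(l["size_mm"]),
                uptake_suv=l["uptake_suv"],
                gradient_suv_per_mm=l.get("gradient_suv_per_mm", 0.0),
                spheres=tuple((tuple(c), d) for c, d in l.get("spheres", ())),
            )
            for l in raw.get("lesions", ())
        )
        return PhantomSpec(
            grid_shape=tuple(raw["grid_shape"]),
            spacing=tuple(raw["spacing"]),
            background_suv=raw["background_suv"],
            lesions=lesions,
            psf_fwhm_mm=raw.get("psf_fwhm_mm", 0.0),
            noise_sd=raw.get("noise_sd", 0.0),
            seed=raw.get("seed", 0),
        )


def _voxel_coords(grid_shape, spacing) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def generate_phantom(spec: PhantomSpec) -> tuple[SUVImage, Segmentation]:
    """Render a phantom spec to an SUV image plus its ground-truth labels.

    Ground truth is computed on the noiseless, unblurred lesion geometry:
    a voxel belongs to lesion k iff its center lies inside the k-th
    analytic shape. Overlapping lesions are a spec error.
    """
    coords = _voxel_coords(spec.grid_shape, spec.spacing)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    clean = np.full(spec.grid_shape, spec.background_suv, dtype=float)

    for k, lesion in enumerate(spec.lesions, start=1):
        inside = lesion.contains(coords)
        if not inside.any():
            raise PhantomSpecError(f"lesion {k} contains no voxel centers")
        if np.any(labels[inside] != 0):
            raise PhantomSpecError(f"lesion {k} overlaps a previously placed lesion")
        labels[inside] = k
        uptake = np.full(np.count_nonzero(inside), lesion.uptake_suv)
        if lesion.gradient_suv_per_mm != 0.0:
            dx = coords[inside][:, 0] - lesion.center_mm[0]
            uptake = uptake + lesion.gradient_suv_per_mm * dx
        clean[inside] = np.maximum(uptake, 0.0)

    image = clean
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in spec.spacing]
        image = gaussian_filter(image, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    return (
        SUVImage(voxels=image, spacing=spec.spacing),
        Segmentation(labels=labels, spacing=spec.spacing),
    )


def reference_phantom_suite() -> list[tuple[str, PhantomSpec, dict]]:
    """Named fixture phantoms with expected ground-truth summaries.

    Returns ``(name, spec, expected)`` triples where ``expected`` holds
    analytic or construction-time truths (lesion count, ground-truth
    volume in ml where exact).
    """
    sphere30 = PhantomSpec(
        lesions=(
            LesionSpec(shape="sphere", center_mm=(128.0, 128.0, 128.0), size_mm=(30.0,), uptake_suv=10.0),
        ),
        psf_fwhm_mm=7.0,
        noise_sd=0.0,
        seed=11,
    )
    # cube center at 130 mm: voxel centers at multiples of 4 mm, so exactly
    # 10 centers per axis fall inside [110, 150] -> ground truth 64 ml exact
    cube40 = PhantomSpec(
        lesions=(
            LesionSpec(shape="cube", center_mm=(130.0, 130.0, 130.0), size_mm=(40.0,), uptake_suv=10.0),
        ),
        psf_fwhm_mm=7.0,
        noise_sd=0.0,
        seed=12,
    )
    # secondary lesion with low contrast: exercises separate-subvolume
    # correction, and fixed-SUV thresholding diverges on it
    two_lesion = PhantomSpec(
        lesions=(
            LesionSpec(shape="sphere", center_mm=(88.0, 88.0, 128.0), size_mm=(40.0,), uptake_suv=10.0),
            LesionSpec(shape="sphere", center_mm=(180.0, 180.0, 128.0), size_mm=(24.0,), uptake_suv=3.0),
        ),
        psf_fwhm_mm=7.0,
        noise_sd=0.0,
        seed=13,
    )
    gradient = PhantomSpec(
        lesions=(
            LesionSpec(
                shape="sphere",
                center_mm=(128.0, 128.0, 128.0),
                size_mm=(40.0,),
                uptake_suv=8.0,
                gradient_suv_per_mm=0.15,
            ),
        ),
        psf_fwhm_mm=7.0,
        noise_sd=0.0,
        seed=14,
    )
    return [
        ("calibration_sphere", sphere30, {"n_lesions": 1, "analytic_volume_ml": 4.0 / 3.0 * np.pi * 15.0**3 / 1000.0}),
        ("cube", cube40, {"n_lesions": 1, "gt_volume_ml": 64.0}),
        ("two_lesion", two_lesion, {"n_lesions": 2}),
        ("gradient_sphere", gradient, {"n_lesions": 1}),
    ]
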