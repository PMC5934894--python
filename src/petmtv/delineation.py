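"""Lesion delineation by thresholding schemes and total-MTV aggregation.

Three schemes are provided: a fixed absolute SUV threshold, a relative
fraction-of-maximum threshold, and an iterative background-adapted
scheme whose threshold is ``BG + q * (Imax - BG)`` with the background
estimated from a shell around the current mask. Connectivity is the full
26-neighborhood; voxels exactly at the threshold are included (>=).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage

from .imaging import AlignmentError, Segmentation, SUVImage

__all__ = [
    "DelineationConfig",
    "CorrectionDirective",
    "BGResult",
    "delineate_fixed",
    "delineate_relative_max",
    "delineate_background_adapted",
    "apply_corrections",
    "total_mtv",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DelineationConfig:
    """Parameters of the delineation schemes.

    ``q`` is the relative fraction for the background-adapted scheme
    (0.39 by convention); the fixed relative scheme uses 0.41 and the
    absolute scheme SUV 2.5 unless overridden at the call site.
    """

    method: str = "BG"  # "BG" | "t41" | "SUV2.5"
    q: float = 0.39
    relative_fraction: float = 0.41
    absolute_threshold: float = 2.5
    shell_inner_vox: int = 2
    shell_outer_vox: int = 4
    convergence_tol: float = 0.01
    max_iterations: int = 20
    min_lesion_voxels: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.shell_outer_vox <= self.shell_inner_vox:
            raise ValueError("shell_outer_vox must exceed shell_inner_vox")


@dataclass(frozen=True)
class CorrectionDirective:
    """One manual-correction step applied to an existing segmentation.

    ``override_threshold`` re-delineates the target lesion at a new SUV
    level; ``split_subvolume`` delineates a sub-region independently and
    adds the result as new lesions.
    """

    mode: str  # "override_threshold" | "split_subvolume"
    target: Optional[int] = None
    threshold: Optional[float] = None
    region: Optional[tuple[slice, slice, slice]] = None
    relative_fraction: float = 0.39

    def __post_init__(self) -> None:
        if self.mode not in ("override_threshold", "split_subvolume"):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        if self.mode == "override_threshold" and (self.target is None or self.threshold is None):
            raise ValueError("override_threshold needs target and threshold")
        if self.mode == "split_subvolume" and self.region is None:
            raise ValueError("split_subvolume needs a region")


class BGResult(NamedTuple):
    segmentation: Segmentation
    iterations: int
    threshold: float
    converged: bool


def _label_components(
    mask: np.ndarray, spacing, min_lesion_voxels: int
) -> Segmentation:
    """26-connected components of a boolean mask, small specks removed."""
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n and min_lesion_voxels > 1:
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_lesion_voxels)
        lab[np.isin(lab, small[small > 0])] = 0
    # relabel consecutively for a stable 1..k numbering
    ids = np.unique(lab[lab > 0])
    out = np.zeros_like(lab)
    for new, old in enumerate(ids, start=1):
        out[lab == old] = new
    return Segmentation(labels=out, spacing=spacing)


def _roi_mask(shape, roi: Optional[tuple[slice, slice, slice]]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    if roi is None:
        m[...] = True
    else:
        m[roi] = True
    return m


def delineate_fixed(
    image: SUVImage,
    threshold: float,
    roi: Optional[tuple[slice, slice, slice]] = None,
    min_lesion_voxels: int = 2,
) -> Segmentation:
    """Fixed absolute threshold delineation (e.g. SUV 2.5).

    Labels are 26-connected components of ``{SUV >= threshold}`` inside
    the optional ROI; components smaller than ``min_lesion_voxels`` are
    discarded. An empty result is a valid zero-lesion segmentation.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    mask = (image.voxels >= threshold) & _roi_mask(image.shape, roi)
    return _label_components(mask, image.spacing, min_lesion_voxels)


def delineate_relative_max(
    image: SUVImage,
    fraction: float = 0.41,
    roi: Optional[tuple[slice, slice, slice]] = None,
    min_lesion_voxels: int = 2,
) -> Segmentation:
    """Relative threshold at ``fraction`` of the ROI maximum (t41 scheme)."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    roi_m = _roi_mask(image.shape, roi)
    if not roi_m.any():
        raise ValueError("empty ROI")
    vmax = float(image.voxels[roi_m].max())
    if vmax <= 0:
        raise ValueError("degenerate input: ROI maximum is zero")
    threshold = fraction * vmax
    if threshold <= float(np.median(image.voxels[roi_m])):
        log.warning(
            "relative threshold %.3g does not exceed the ROI median; "
            "result likely includes background", threshold,
        )
    mask = (image.voxels >= threshold) & roi_m
    return _label_components(mask, image.spacing, min_lesion_voxels)


def _shell_background(
    image: SUVImage,
    mask: np.ndarray,
    config: DelineationConfig,
    exclude: Optional[np.ndarray],
) -> float:
    inner = ndimage.binary_dilation(mask, _STRUCT26, iterations=config.shell_inner_vox)
    outer = ndimage.binary_dilation(mask, _STRUCT26, iterations=config.shell_outer_vox)
    shell = outer & ~inner
    if exclude is not None:
        shell &= ~exclude
    if not shell.any():
        fallback = float(np.median(image.voxels[~mask]))
        log.warning("empty background shell; falling back to global median %.3g", fallback)
        return fallback
    return float(image.voxels[shell].mean())


def delineate_background_adapted(
    image: SUVImage,
    seed: Sequence[int],
    config: DelineationConfig | None = None,
    exclude: Optional[np.ndarray] = None,
) -> BGResult:
    """Iterative background-adapted delineation around a seed voxel.

    The lesion maximum ``Imax`` is taken over the 26-connected component
    containing the seed at the bootstrap threshold ``q * SUV(seed)``.
    Each iteration thresholds at ``T_k``, keeps the component containing
    the seed, estimates the background ``BG`` as the mean SUV in a
    dilation shell around that component (minus ``exclude``), and sets
    ``T_{k+1} = BG + q * (Imax - BG)``; iteration stops once
    ``|T_{k+1} - T_k| < convergence_tol``. On a noiseless two-plateau
    image this reaches its closed-form fixed point immediately.
    """
    config = config or DelineationConfig()
    seed = tuple(int(s) for s in seed)
    seed_suv = float(image.voxels[seed])
    if seed_suv <= float(np.median(image.voxels)):
        raise ValueError(f"seed SUV {seed_suv:.3g} does not exceed the image median")

    def component_at(threshold: float) -> np.ndarray:
        lab, _ = ndimage.label(image.voxels >= threshold, structure=_STRUCT26)
        lid = lab[seed]
        if lid == 0:
            return np.zeros(image.shape, dtype=bool)
        return lab == lid

    boot = component_at(config.q * seed_suv)
    imax = float(image.voxels[boot].max()) if boot.any() else seed_suv

    t = config.q * imax
    mask = component_at(t)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        bg = _shell_background(image, mask, config, exclude)
        t_next = bg + config.q * (imax - bg)
        mask = component_at(t_next)
        if abs(t_next - t) < config.convergence_tol:
            t = t_next
            converged = True
            break
        t = t_next
    if not converged:
        warnings.warn(
            f"background-adapted delineation did not converge after "
            f"{config.max_iterations} iterations (last threshold {t:.4g})",
            stacklevel=2,
        )

    labels = np.zeros(image.shape, dtype=np.int32)
    labels[mask] = 1
    return BGResult(
        segmentation=Segmentation(labels=labels, spacing=image.spacing),
        iterations=iterations,
        threshold=float(t),
        converged=converged,
    )


def apply_corrections(
    image: SUVImage,
    seg: Segmentation,
    directives: Sequence[CorrectionDirective],
    min_lesion_voxels: int = 2,
) -> Segmentation:
    """Apply manual-correction directives and recompute total MTV."""
    seg.check_aligned(image)
    labels = seg.labels.copy()
    for d in directives:
        if d.mode == "override_threshold":
            if d.target not in seg.lesion_volumes and d.target not in np.unique(labels):
                raise ValueError(f"directive targets unknown lesion {d.target}")
            old = labels == d.target
            labels[old] = 0
            # re-grow from the thresholded field: keep components touching
            # the old lesion so the correction stays local
            cand, n = ndimage.label(image.voxels >= d.threshold, structure=_STRUCT26)
            keep = np.unique(cand[old & (cand > 0)])
            new = np.isin(cand, keep[keep > 0])
            if np.count_nonzero(new) < min_lesion_voxels:
                warnings.warn(
                    f"override_threshold {d.threshold} empties lesion {d.target}; removed",
                    stacklevel=2,
                )
            else:
                labels[new & (labels == 0)] = d.target
        else:  # split_subvolume
            region = _roi_mask(image.shape, d.region)
            if not region.any():
                raise ValueError("split_subvolume region is out of bounds / empty")
            if d.threshold is not None:
                thr = d.threshold
            else:
                local_max = float(image.voxels[region].max())
                bg = float(np.median(image.voxels[~(region | (labels > 0))]))
                thr = bg + d.relative_fraction * (local_max - bg)
            sub = (image.voxels >= thr) & region
            sub_lab, n = ndimage.label(sub, structure=_STRUCT26)
            if n == 0:
                warnings.warn("split_subvolume produced no lesion; skipped", stacklevel=2)
                continue
            next_id = int(labels.max()) + 1
            for k in range(1, n + 1):
                comp = sub_lab == k
                if np.count_nonzero(comp) < min_lesion_voxels:
                    continue
                labels[comp & (labels == 0)] = next_id
                next_id += 1
    return Segmentation(labels=labels, spacing=seg.spacing)


def total_mtv(segs: Sequence[Segmentation]) -> float:
    """Total metabolic tumor volume (ml) over several segmentations.

    Overlapping lesions are counted once: the union of all binary masks
    is measured, never the sum of per-segmentation volumes.
    """
    if not segs:
        return 0.0
    first = segs[0]
    union = np.zeros(first.labels.shape, dtype=bool)
    for s in segs:
        if s.labels.shape != first.labels.shape or not np.allclose(s.spacing, first.spacing):
            raise AlignmentError("segmentations do not share one image grid")
        union |= s.binary_mask
    voxel_ml = float(np.prod(first.spacing)) / 1000.0
    return float(np.count_nonzero(union)) * voxel_ml
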