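"""Delineation tests, including an exhaustive voxel-scan oracle.

The oracle implements thresholding plus 26-connected component labeling
with a pure-Python breadth-first search, independent of the scipy-backed
implementation under test.
"""

import dataclasses
from collections import deque

import numpy as np
import pytest

from petmtv.delineation import (
    BGResult,
    CorrectionDirective,
    DelineationConfig,
    apply_corrections,
    delineate_background_adapted,
    delineate_fixed,
    delineate_relative_max,
    total_mtv,
)
from petmtv.imaging import AlignmentError, Segmentation, SUVImage
from petmtv.phantom import LesionSpec, PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# independent oracle


def oracle_components(image, threshold, min_voxels=2):
    """Brute-force threshold + BFS 26-connectivity labeling.

    Returns a set of frozensets of voxel indices, one per component.
    """
    vox = image.voxels
    shape = vox.shape
    mask = vox >= threshold
    seen = np.zeros(shape, dtype=bool)
    neighbors = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    components = set()
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        comp = []
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for d in neighbors:
                nb = tuple(c + o for c, o in zip(cur, d))
                if all(0 <= n < s for n, s in zip(nb, shape)) and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        if len(comp) >= min_voxels:
            components.add(frozenset(comp))
    return components


def as_component_sets(seg):
    out = set()
    for lid in seg.lesion_volumes:
        out.add(frozenset(map(tuple, np.argwhere(seg.labels == lid))))
    return out


# ---------------------------------------------------------------------------


class TestDelineateFixed:
    def test_plateau_cube_exact(self, plateau_cube):
        image, gt = plateau_cube
        seg = delineate_fixed(image, 2.5)
        assert seg.total_mtv == pytest.approx(gt.total_mtv)

    def test_threshold_above_maximum(self, plateau_cube):
        image, _ = plateau_cube
        seg = delineate_fixed(image, 11.0)
        assert seg.n_lesions == 0
        assert seg.total_mtv == 0.0

    def test_two_sphere_volumes(self, plateau_two_lesion):
        image, gt = plateau_two_lesion
        seg = delineate_fixed(image, 2.5)
        assert seg.n_lesions == 2
        assert sorted(seg.lesion_volumes.values()) == pytest.approx(
            sorted(gt.lesion_volumes.values())
        )

    def test_matches_oracle_small_grid(self, small_plateau):
        image, _ = small_plateau
        for threshold in (1.5, 2.5, 4.0, 6.0):
            seg = delineate_fixed(image, threshold)
            assert as_component_sets(seg) == oracle_components(image, threshold)

    def test_monotone_in_threshold(self, small_plateau):
        image, _ = small_plateau
        thresholds = np.linspace(1.2, 9.0, 12)
        mtvs = [delineate_fixed(image, float(t)).total_mtv for t in thresholds]
        assert all(a >= b for a, b in zip(mtvs, mtvs[1:]))

    def test_invalid_threshold(self, plateau_cube):
        with pytest.raises(ValueError):
            delineate_fixed(plateau_cube[0], 0.0)


class TestDelineateRelativeMax:
    def test_effective_threshold_arithmetic(self):
        vox = np.ones((6, 6, 6))
        vox[2:4, 2:4, 2:4] = 10.0
        image = SUVImage(voxels=vox, spacing=(4.0, 4.0, 4.0))
        seg = delineate_relative_max(image, 0.41)
        # threshold 4.1: only the 8 plateau voxels qualify
        assert np.count_nonzero(seg.labels) == 8

    def test_plateau_cube_ground_truth(self, plateau_cube):
        image, gt = plateau_cube
        seg = delineate_relative_max(image, 0.41)
        assert seg.total_mtv == pytest.approx(gt.total_mtv)

    def test_matches_oracle_small_grid(self, small_plateau):
        image, _ = small_plateau
        for fraction in (0.3, 0.41, 0.6):
            threshold = fraction * float(image.voxels.max())
            seg = delineate_relative_max(image, fraction)
            assert as_component_sets(seg) == oracle_components(image, threshold)

    def test_monotone_in_fraction(self, small_plateau):
        image, _ = small_plateau
        mtvs = [delineate_relative_max(image, f).total_mtv for f in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(mtvs, mtvs[1:]))

    def test_background_only_roi_logged(self, plateau_cube, caplog):
        image, gt = plateau_cube
        roi = (slice(0, 5), slice(0, 5), slice(0, 5))  # background corner
        assert not np.any(gt.labels[roi])
        with caplog.at_level("WARNING", logger="petmtv.delineation"):
            seg = delineate_relative_max(image, 0.41, roi=roi)
        assert "background" in caplog.text
        assert np.count_nonzero(seg.labels) == np.count_nonzero(
            image.voxels[roi] >= 0.41 * image.voxels[roi].max()
        )

    def test_degenerate_all_zero_roi(self):
        image = SUVImage(voxels=np.zeros((4, 4, 4)), spacing=(4.0, 4.0, 4.0))
        with pytest.raises(ValueError, match="degenerate"):
            delineate_relative_max(image, 0.41)


class TestBackgroundAdapted:
    def test_closed_form_fixed_point(self, plateau_cube):
        image, gt = plateau_cube
        seed = tuple(np.argwhere(gt.labels > 0)[0])
        result = delineate_background_adapted(image, seed)
        # plateau 10 on background 1, q = 0.39: T = 1 + 0.39 * 9 = 4.51
        assert result.threshold == pytest.approx(4.51)
        assert result.converged
        assert result.segmentation.total_mtv == pytest.approx(gt.total_mtv)

    def test_converges_within_three_iterations(self, plateau_cube, plateau_two_lesion):
        for image, gt in (plateau_cube, plateau_two_lesion):
            seed = tuple(np.argwhere(gt.labels == 1)[0])
            result = delineate_background_adapted(image, seed)
            assert result.converged and result.iterations <= 3

    def test_zero_background_reduces_to_relative_max(self):
        vox = np.zeros((12, 12, 12))
        vox[4:8, 4:8, 4:8] = 10.0
        image = SUVImage(voxels=vox, spacing=(4.0, 4.0, 4.0))
        result = delineate_background_adapted(image, (5, 5, 5))
        assert result.threshold == pytest.approx(0.39 * 10.0)
        ref = delineate_relative_max(image, 0.39)
        assert np.array_equal(result.segmentation.binary_mask, ref.binary_mask)

    def test_blurred_sphere_volume_regression(self, blurred_sphere):
        image, gt = blurred_sphere
        seed = tuple(np.unravel_index(int(np.argmax(image.voxels)), image.shape))
        result = delineate_background_adapted(image, seed)
        assert result.segmentation.total_mtv == pytest.approx(gt.total_mtv, rel=0.15)
        # pinned regression value, measured once on this fixed-seed fixture
        assert result.segmentation.total_mtv == pytest.approx(16.064, abs=1e-3)

    def test_seed_below_median_rejected(self, plateau_cube):
        image, _ = plateau_cube
        with pytest.raises(ValueError, match="median"):
            delineate_background_adapted(image, (0, 0, 0))

    def test_non_convergence_warns(self, blurred_sphere):
        image, _ = blurred_sphere
        seed = tuple(np.unravel_index(int(np.argmax(image.voxels)), image.shape))
        cfg = DelineationConfig(max_iterations=1, convergence_tol=1e-9)
        with pytest.warns(UserWarning, match="did not converge"):
            result = delineate_background_adapted(image, seed, cfg)
        assert not result.converged


class TestApplyCorrections:
    def test_split_subvolume_recovers_missed_lesion(self, blurred_two_lesion):
        image, gt = blurred_two_lesion
        # BG run from the hot lesion's max misses the low-uptake lesion
        seed = tuple(np.unravel_index(int(np.argmax(image.voxels)), image.shape))
        bg = delineate_background_adapted(image, seed)
        assert bg.segmentation.n_lesions == 1
        second = gt.labels == 2
        lo = np.argwhere(second).min(axis=0) - 4
        hi = np.argwhere(second).max(axis=0) + 5
        region = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        corrected = apply_corrections(
            image, bg.segmentation, [CorrectionDirective(mode="split_subvolume", region=region)]
        )
        assert corrected.n_lesions == 2
        assert corrected.total_mtv == pytest.approx(sum(corrected.lesion_volumes.values()))
        assert corrected.total_mtv > bg.segmentation.total_mtv

    def test_empty_directive_list_is_identity(self, plateau_cube):
        image, _ = plateau_cube
        seg = delineate_fixed(image, 2.5)
        out = apply_corrections(image, seg, [])
        assert np.array_equal(out.labels, seg.labels)

    def test_override_above_max_removes_lesion(self, plateau_cube):
        image, _ = plateau_cube
        seg = delineate_fixed(image, 2.5)
        with pytest.warns(UserWarning, match="empties"):
            out = apply_corrections(
                image, seg,
                [CorrectionDirective(mode="override_threshold", target=1, threshold=99.0)],
            )
        assert out.total_mtv < seg.total_mtv
        assert out.n_lesions == 0

    def test_override_threshold_shrinks_lesion(self, blurred_sphere):
        image, _ = blurred_sphere
        seg = delineate_fixed(image, 2.5)
        out = apply_corrections(
            image, seg,
            [CorrectionDirective(mode="override_threshold", target=1, threshold=6.0)],
        )
        assert 0 < out.total_mtv < seg.total_mtv

    def test_unknown_target_rejected(self, plateau_cube):
        image, _ = plateau_cube
        seg = delineate_fixed(image, 2.5)
        with pytest.raises(ValueError, match="unknown lesion"):
            apply_corrections(
                image, seg,
                [CorrectionDirective(mode="override_threshold", target=9, threshold=3.0)],
            )


class TestTotalMTV:
    def test_fig_style_single_lesion(self):
        labels = np.zeros((16, 16, 16), dtype=np.int32)
        # 51 ml at 4 mm voxels: 51 / 0.064 = 796.875 -> use 797 voxels
        flat = labels.ravel()
        flat[:797] = 1
        seg = Segmentation(labels=flat.reshape(16, 16, 16), spacing=(4.0, 4.0, 4.0))
        assert total_mtv([seg]) == pytest.approx(51.008)

    def test_disjoint_additivity(self):
        a = np.zeros((10, 10, 10), dtype=np.int32)
        a.ravel()[:156] = 1  # ~10 ml at 4 mm voxels (156 * 0.064 = 9.984)
        b = np.zeros((10, 10, 10), dtype=np.int32)
        b.ravel()[500:656] = 1
        sa = Segmentation(labels=a, spacing=(4.0, 4.0, 4.0))
        sb = Segmentation(labels=b, spacing=(4.0, 4.0, 4.0))
        assert total_mtv([sa, sb]) == pytest.approx(sa.total_mtv + sb.total_mtv)

    def test_duplicate_lesion_counted_once(self):
        a = np.zeros((10, 10, 10), dtype=np.int32)
        a.ravel()[:156] = 1
        seg = Segmentation(labels=a, spacing=(4.0, 4.0, 4.0))
        assert total_mtv([seg, seg]) == pytest.approx(seg.total_mtv)

    def test_grid_mismatch(self):
        a = Segmentation(labels=np.ones((4, 4, 4), dtype=np.int32), spacing=(4.0, 4.0, 4.0))
        b = Segmentation(labels=np.ones((5, 5, 5), dtype=np.int32), spacing=(4.0, 4.0, 4.0))
        with pytest.raises(AlignmentError):
            total_mtv([a, b])


class TestSchemeAgreement:
    def test_bg_t41_high_correlation_suv25_diverges(self):
        """Across lesion sizes, background-adapted and 41%-of-max MTVs
        track each other closely; the fixed SUV 2.5 scheme breaks down on
        a low-contrast lesion."""
        bg_mtv, t41_mtv = [], []
        for diameter in (20.0, 28.0, 36.0, 44.0):
            spec = PhantomSpec(
                lesions=(
                    LesionSpec(shape="sphere", center_mm=(128.0, 128.0, 128.0),
                               size_mm=(diameter,), uptake_suv=8.0),
                ),
                psf_fwhm_mm=7.0,
                noise_sd=0.0,
            )
            image, _ = generate_phantom(spec)
            seed = tuple(np.unravel_index(int(np.argmax(image.voxels)), image.shape))
            bg_mtv.append(delineate_background_adapted(image, seed).segmentation.total_mtv)
            t41_mtv.append(delineate_relative_max(image, 0.41).total_mtv)
        assert np.corrcoef(bg_mtv, t41_mtv)[0, 1] > 0.95

        # low-contrast lesion: uptake 3 on background 1, blurred
        spec = PhantomSpec(
            lesions=(
                LesionSpec(shape="sphere", center_mm=(128.0, 128.0, 128.0),
                           size_mm=(30.0,), uptake_suv=3.0),
            ),
            psf_fwhm_mm=7.0,
            noise_sd=0.0,
        )
        image, gt = generate_phantom(spec)
        seed = tuple(np.unravel_index(int(np.argmax(image.voxels)), image.shape))
        bg = delineate_background_adapted(image, seed).segmentation.total_mtv
        suv25 = delineate_fixed(image, 2.5).total_mtv
        err_bg = abs(bg - gt.total_mtv) / gt.total_mtv
        err_25 = abs(suv25 - gt.total_mtv) / gt.total_mtv
        assert err_25 > err_bg
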