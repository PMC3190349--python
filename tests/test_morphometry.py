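"""Skeleton-based thickness, span-curve lesion length, and plate aggregation."""

import math

import numpy as np
import pytest

from oamq import morphometry as mm
from oamq import synthetic as syn
from oamq.morphometry import (
    BOUNDARY_OFFSET_PX,
    DegenerateFitError,
    SliceMask,
    UnsupportedGeometryError,
    analyze_slice,
    analyze_stack,
    cartilage_volume,
    detect_lesion_gaps,
    fit_span_curve,
    label_components,
    partition_span,
    pixel_density,
    plate_morphometry,
    skeletonize,
    slice_mean_thickness,
    slice_thickness_incl_lesion,
)


def _band_mask(rows=25, cols=70, r0=8, height=8, c0=5, width=60, spacing=0.3,
               gaps=()):
    grid = np.zeros((rows, cols), dtype=bool)
    grid[r0 : r0 + height, c0 : c0 + width] = True
    for g0, g1 in gaps:
        grid[:, g0:g1] = False
    return SliceMask(grid=grid, pixel_spacing_mm=(spacing, spacing))


class TestComponents:
    def test_two_disjoint_bands(self):
        mask = _band_mask(gaps=((30, 40),))
        comps = label_components(mask)
        assert len(comps) == 2
        assert all(c.skeleton.any() for c in comps)
        assert all((c.boundary & ~c.mask).sum() == 0 for c in comps)
        assert all((c.skeleton & ~c.mask).sum() == 0 for c in comps)

    def test_full_grid_boundary_is_frame(self):
        grid = np.ones((10, 12), dtype=bool)
        mask = SliceMask(grid=grid, pixel_spacing_mm=(0.5, 0.5))
        (comp,) = label_components(mask)
        expected = np.zeros_like(grid)
        expected[0, :] = expected[-1, :] = True
        expected[:, 0] = expected[:, -1] = True
        assert np.array_equal(comp.boundary, expected)

    def test_min_size_filter_drops_isolated_pixel(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[2, 2] = True
        grid[10:14, 5:15] = True
        mask = SliceMask(grid=grid, pixel_spacing_mm=(0.3, 0.3))
        comps = label_components(mask, min_size=5)
        assert len(comps) == 1 and comps[0].n_pixels == 40

    def test_empty_mask_gives_empty_list(self):
        mask = SliceMask(grid=np.zeros((5, 5), bool), pixel_spacing_mm=(1, 1))
        assert label_components(mask) == []


class TestSkeleton:
    def test_band_skeleton_near_centre_row(self):
        # brute-force check: every skeleton pixel within 1 px of centre row
        for height in (5, 8, 11):
            grid = np.zeros((30, 80), dtype=bool)
            r0 = 10
            grid[r0 : r0 + height, 5:75] = True
            skel = skeletonize(grid)
            rows = np.argwhere(skel)[:, 0]
            centre = r0 + (height - 1) / 2
            assert np.all(np.abs(rows - centre) <= 1.0)

    def test_one_pixel_line_is_its_own_skeleton(self):
        grid = np.zeros((10, 40), dtype=bool)
        grid[4, 5:35] = True
        skel = skeletonize(grid)
        assert np.array_equal(skel, grid)

    def test_disk_skeleton_near_centre(self):
        yy, xx = np.mgrid[0:41, 0:41]
        grid = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        skel = skeletonize(grid)
        from scipy import ndimage

        dt = ndimage.distance_transform_edt(grid)
        peak = np.unravel_index(np.argmax(dt), grid.shape)
        coords = np.argwhere(skel)
        d = np.hypot(coords[:, 0] - peak[0], coords[:, 1] - peak[1])
        assert d.min() <= 2.0  # passes near the distance-transform maximum

    def test_never_empty(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[2:4, 2:4] = True
        assert skeletonize(grid).any()


class TestSliceThickness:
    def test_band_thickness_vs_brute_force_oracle(self):
        mask = _band_mask(height=9, spacing=0.3)
        comps = label_components(mask)
        thick, n, total_d = slice_mean_thickness(comps, 0.3)
        # oracle: all-pairs nearest-skeleton search
        (comp,) = comps
        bpts = np.argwhere(comp.boundary).astype(float)
        spts = np.argwhere(comp.skeleton).astype(float)
        d = np.sqrt(((bpts[:, None, :] - spts[None, :, :]) ** 2).sum(-1)).min(1)
        oracle = 2.0 * (d.mean() + BOUNDARY_OFFSET_PX) * 0.3
        assert thick == pytest.approx(oracle, rel=1e-9)
        assert n == len(bpts)
        assert total_d == pytest.approx(d.sum(), rel=1e-9)
        # and recovers the true 2.7 mm within 15%
        assert thick == pytest.approx(2.7, rel=0.15)

    def test_one_pixel_line_degenerate_floor(self):
        grid = np.zeros((10, 40), dtype=bool)
        grid[4, 5:35] = True
        mask = SliceMask(grid=grid, pixel_spacing_mm=(0.3, 0.3))
        thick, _, _ = slice_mean_thickness(label_components(mask), 0.3)
        assert 0 < thick <= 0.3 + 1e-12  # boundary coincides with skeleton

    def test_linear_in_pixel_size(self):
        mask = _band_mask(height=8)
        comps = label_components(mask)
        t1, _, _ = slice_mean_thickness(comps, 0.3)
        t2, _, _ = slice_mean_thickness(comps, 0.6)
        assert t2 == pytest.approx(2 * t1)

    def test_anisotropic_spacing_rejected(self):
        mask = _band_mask()
        with pytest.raises(UnsupportedGeometryError):
            slice_mean_thickness(label_components(mask), (0.3, 0.4))

    def test_oracle_equivalence_random_blobs(self, rng):
        # distance computations vs brute force on small random masks
        for _ in range(5):
            grid = rng.random((40, 40)) > 0.6
            from scipy import ndimage

            grid = ndimage.binary_closing(grid)
            mask = SliceMask(grid=grid, pixel_spacing_mm=(0.5, 0.5))
            comps = label_components(mask, min_size=5)
            if not comps:
                continue
            _, n, total_d = slice_mean_thickness(comps, 0.5)
            brute = 0.0
            for comp in comps:
                bpts = np.argwhere(comp.boundary).astype(float)
                spts = np.argwhere(comp.skeleton).astype(float)
                d = np.sqrt(
                    ((bpts[:, None, :] - spts[None, :, :]) ** 2).sum(-1)
                ).min(1)
                brute += d.sum()
            assert total_d == pytest.approx(brute, rel=1e-9)


class TestGapDetection:
    def test_auto_detects_single_gap(self):
        mask = _band_mask(gaps=((30, 40),))
        comps = label_components(mask)
        pairs = detect_lesion_gaps(comps)
        assert len(pairs) == 1

    def test_single_component_no_gap(self):
        comps = label_components(_band_mask())
        assert detect_lesion_gaps(comps) == []

    def test_annotations_pass_through_and_validate(self):
        mask = _band_mask(cols=110, width=100, gaps=((30, 40), (60, 70)))
        comps = label_components(mask)
        labels = sorted(c.label for c in comps)
        assert len(labels) == 3
        pairs = detect_lesion_gaps(comps, annotations=[(labels[0], labels[1])])
        assert pairs == [(labels[0], labels[1])]
        with pytest.raises(ValueError, match="missing component label"):
            detect_lesion_gaps(comps, annotations=[(99, labels[0])])


class TestSpanCurve:
    def test_collinear_segments_fit_a_line(self):
        # exactly collinear horizontal segments: the LS quadratic is the line
        left = np.column_stack([np.full(10, 12.0), np.arange(0, 10.0)])
        right = np.column_stack([np.full(10, 12.0), np.arange(40, 50.0)])
        span = fit_span_curve(left, right)
        assert abs(span.poly_coeffs[0]) < 1e-6
        # real band skeletons have end artifacts; curvature stays tiny
        mask = _band_mask(gaps=((30, 40),))
        a, b = label_components(mask)
        span2 = fit_span_curve(a.skeleton_coords, b.skeleton_coords)
        assert abs(span2.poly_coeffs[0]) < 1e-3

    def test_exact_quadratic_recovered_vs_normal_equations(self):
        x = np.concatenate([np.arange(0, 12.0), np.arange(30, 42.0)])
        y = 0.01 * x**2 + 2.0
        pts = np.column_stack([y, x])  # (row, col) with col as abscissa
        span = fit_span_curve(pts[:12], pts[12:])
        # oracle: least squares via normal equations in the fit frame
        frame = span.frame
        xy = frame.to_frame(pts)
        X = np.column_stack([xy[:, 0] ** 2, xy[:, 0], np.ones(len(xy))])
        beta = np.linalg.solve(X.T @ X, X.T @ xy[:, 1])
        assert span.poly_coeffs == pytest.approx(tuple(beta), abs=1e-6)

    def test_symmetric_in_the_two_skeletons(self):
        mask = _band_mask(gaps=((30, 40),))
        a, b = label_components(mask)
        s1 = fit_span_curve(a.skeleton_coords, b.skeleton_coords)
        s2 = fit_span_curve(b.skeleton_coords, a.skeleton_coords)
        assert np.allclose(s1.poly_coeffs, s2.poly_coeffs, atol=1e-9)

    def test_degenerate_fit_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        # all points on a vertical line in the frame: ptp of abscissa fine,
        # but identical points collapse the design
        with pytest.raises((DegenerateFitError, ValueError)):
            fit_span_curve(pts[:3] * 0, pts[3:] * 0)


class TestPartitionSpan:
    def test_collinear_gap_length(self):
        # two 30-px bands on the same rows, 10-px gap, s = 0.5 mm
        spec = syn.PhantomSpec(
            shape="band", thickness_px=8, length_px=70, gaps=((30, 10),),
            pixel_spacing_mm=0.5, n_slices=1,
        )
        data, truth = syn.make_phantom(spec)
        mask = SliceMask(grid=data[0], pixel_spacing_mm=(0.5, 0.5))
        a, b = label_components(mask)
        span = fit_span_curve(a.skeleton_coords, b.skeleton_coords)
        lesion, overlap = partition_span(span, a, b, 0.5)
        assert lesion == pytest.approx(5.0, abs=1 * 0.5)
        assert overlap > 0

    def test_touching_bands_have_zero_lesion(self):
        mask = _band_mask()
        comps = label_components(mask)
        (comp,) = comps
        # treat the two halves of one band as an annotated pair: the span
        # never leaves cartilage
        half_a = np.argwhere(comp.skeleton[:, :35])
        left = comp.skeleton_coords[comp.skeleton_coords[:, 1] < 35]
        right = comp.skeleton_coords[comp.skeleton_coords[:, 1] >= 35]
        span = fit_span_curve(left, right)
        lesion, overlap = partition_span(span, comp, comp, 0.3)
        assert lesion == 0.0
        assert overlap > 0

    def test_discretization_stability(self):
        spec = syn.PhantomSpec(
            shape="band", thickness_px=8, length_px=70, gaps=((30, 10),),
            pixel_spacing_mm=0.5, n_slices=1,
        )
        data, _ = syn.make_phantom(spec)
        mask = SliceMask(grid=data[0], pixel_spacing_mm=(0.5, 0.5))
        a, b = label_components(mask)
        span = fit_span_curve(a.skeleton_coords, b.skeleton_coords)
        l1, _ = partition_span(span, a, b, 0.5, step_px=0.25)
        l2, _ = partition_span(span, a, b, 0.5, step_px=0.125)
        assert abs(l2 - l1) / l1 < 0.005

    def test_curved_plate_gap_recovery(self):
        spec = syn.PhantomSpec(
            shape="annulus_sector", thickness_px=8, radius_px=40,
            angular_extent_deg=120, gaps=((0, 20),), pixel_spacing_mm=0.3,
            n_slices=1,
        )
        data, truth = syn.make_phantom(spec)
        per_slice, _ = mm.analyze_stack(data, (0.3, 0.3), 1.3, auto_gaps=True)
        est = per_slice[0].total_lesion_length_mm
        assert est == pytest.approx(truth.gap_lengths_mm[0], rel=0.10)


class TestDensityAndLesionThickness:
    def _gapped(self):
        spec = syn.PhantomSpec(
            shape="band", thickness_px=8, length_px=90, gaps=((40, 10),),
            pixel_spacing_mm=0.5, n_slices=1,
        )
        data, _ = syn.make_phantom(spec)
        mask = SliceMask(grid=data[0], pixel_spacing_mm=(0.5, 0.5))
        a, b = label_components(mask)
        span = fit_span_curve(a.skeleton_coords, b.skeleton_coords)
        partition_span(span, a, b, 0.5)
        return a, b, span

    def test_density_counts_pixels_over_overlap_length(self):
        a, b, span = self._gapped()
        d = pixel_density(a, b, span)
        assert d == pytest.approx((a.n_pixels + b.n_pixels) / span.overlap_length_mm)
        assert d > 0

    def test_density_linear_in_band_height(self):
        def density_for(height):
            spec = syn.PhantomSpec(
                shape="band", thickness_px=height, length_px=90,
                gaps=((40, 10),), pixel_spacing_mm=0.5, n_slices=1,
            )
            data, _ = syn.make_phantom(spec)
            mask = SliceMask(grid=data[0], pixel_spacing_mm=(0.5, 0.5))
            a, b = label_components(mask)
            span = fit_span_curve(a.skeleton_coords, b.skeleton_coords)
            partition_span(span, a, b, 0.5)
            return pixel_density(a, b, span)

        # pixel count doubles exactly; the overlap length shifts a little
        # because thinning shortens thicker bands' skeletons more at the ends
        assert density_for(12) == pytest.approx(2 * density_for(6), rel=0.15)

    def test_zero_overlap_rejected(self):
        a, b, span = self._gapped()
        span.overlap_length_mm = 0.0
        with pytest.raises(ValueError):
            pixel_density(a, b, span)

    def test_lesion_free_identity(self):
        assert slice_thickness_incl_lesion(100.0, 40, 0.3, 0.0, 0.0) == (
            pytest.approx(2 * (100.0 / 40 + BOUNDARY_OFFSET_PX) * 0.3)
        )

    def test_equal_virtual_pixels_halve_thickness(self):
        plain = slice_thickness_incl_lesion(100.0, 40, 0.3, 0.0, 0.0)
        halved = slice_thickness_incl_lesion(100.0, 40, 0.3, 4.0, 10.0)  # n_lesion=40
        assert halved == pytest.approx(plain / 2)

    def test_any_lesion_strictly_decreases_thickness(self):
        plain = slice_thickness_incl_lesion(100.0, 40, 0.3, 0.0, 0.0)
        with_lesion = slice_thickness_incl_lesion(100.0, 40, 0.3, 1.0, 5.0)
        assert with_lesion < plain


class TestPlate:
    def test_symmetric_phantom_gives_fifty_percent(self):
        # construct per-slice results where lesion length == overlap length
        results = [
            mm.SliceMorphometry(
                slice_index=k, mean_thickness_mm=2.0,
                mean_thickness_incl_lesion_mm=1.0, total_lesion_length_mm=12.0,
                bone_interface_length_mm=12.0, n_boundary_points=100,
                n_lesion_pixels_est=100.0, pixel_density_px_per_mm=8.0,
            )
            for k in range(4)
        ]
        plate = plate_morphometry(results, 1.3)
        assert plate.lesion_area_pct == pytest.approx(50.0)

    def test_no_lesions_zero_percent(self, band_phantom):
        data, truth = band_phantom
        per_slice, plate = analyze_stack(data, (0.3, 0.3), 1.3)
        assert plate.lesion_area_pct == 0.0
        assert plate.mean_thickness_incl_lesion_mm == pytest.approx(
            per_slice[0].mean_thickness_mm
        )

    def test_lesion_pct_invariant_to_slice_spacing(self, gapped_band_phantom):
        data, _ = gapped_band_phantom
        _, p1 = analyze_stack(data, (0.5, 0.5), 1.0, auto_gaps=True)
        _, p2 = analyze_stack(data, (0.5, 0.5), 2.0, auto_gaps=True)
        assert p1.lesion_area_pct == pytest.approx(p2.lesion_area_pct)
        assert p2.lesion_area_mm2 == pytest.approx(2 * p1.lesion_area_mm2)

    def test_empty_plate_rejected(self):
        with pytest.raises(ValueError):
            plate_morphometry([], 1.3)


class TestVolume:
    def test_count_times_voxel_volume(self):
        data = np.zeros((3, 10, 10), dtype=bool)
        data[:, 2:7, 3:8] = True  # 25 px per slice
        # 75 voxels at 0.3 x 0.3 x 1.3
        assert cartilage_volume(data, (0.3, 0.3), 1.3) == pytest.approx(
            75 * 0.3 * 0.3 * 1.3
        )

    def test_empty_stack_is_zero(self):
        assert cartilage_volume(np.zeros((2, 5, 5), bool), (1, 1), 1.0) == 0.0

    def test_linear_in_slice_spacing(self, band_phantom):
        data, _ = band_phantom
        v1 = cartilage_volume(data, (0.3, 0.3), 1.0)
        v2 = cartilage_volume(data, (0.3, 0.3), 2.0)
        assert v2 == pytest.approx(2 * v1)

    def test_matches_phantom_truth_exactly(self, gapped_band_phantom):
        data, truth = gapped_band_phantom
        assert cartilage_volume(data, (0.5, 0.5), 1.3) == truth.volume_mm3


class TestAnalyzeSlice:
    def test_incl_lesion_never_exceeds_plain_thickness(self, gapped_band_phantom):
        data, _ = gapped_band_phantom
        mask = SliceMask(grid=data[0], pixel_spacing_mm=(0.5, 0.5))
        res = analyze_slice(mask, auto_gaps=True)
        assert res.mean_thickness_incl_lesion_mm <= res.mean_thickness_mm
        assert res.total_lesion_length_mm > 0

    def test_no_cartilage_slice_excluded(self):
        mask = SliceMask(grid=np.zeros((8, 8), bool), pixel_spacing_mm=(1, 1))
        assert analyze_slice(mask) is None

    def test_annotations_drive_span_selection(self, gapped_band_phantom):
        data, _ = gapped_band_phantom
        comps = label_components(
            SliceMask(grid=data[0], pixel_spacing_mm=(0.5, 0.5))
        )
        labels = tuple(sorted(c.label for c in comps))
        mask = SliceMask(
            grid=data[0], pixel_spacing_mm=(0.5, 0.5),
            lesion_annotations=(labels,),
        )
        res = analyze_slice(mask)
        assert res.total_lesion_length_mm == pytest.approx(5.0, abs=0.5)
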