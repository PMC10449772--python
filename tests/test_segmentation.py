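"""Segmentation: contour recovery, guidewire, struts, spline, scan conversion."""

import dataclasses

import numpy as np
import pytest

from octflush import GeometryError, LumenModel, PhantomSpec, StentSpec, generate_pullback
from octflush.core import angular_distance_deg
from octflush.segmentation import (
    ClassifierError,
    ContourNotFoundError,
    DegenerateFrameError,
    InsufficientStrutsError,
    RuleBasedStrutClassifier,
    SegmentationParams,
    Strut,
    build_catheter_mask,
    build_frame_masks,
    contour_to_polygon,
    detect_guidewire,
    detect_lumen_contour,
    detect_strut_candidates,
    filter_struts,
    fit_stent_contour,
    longest_circular_run,
    scan_convert_frame,
    segment_frame,
)


class TestCatheterMask:
    def test_first_80_depth_pixels_masked(self, small_meta):
        # 0.4 mm catheter at 5 um pitch: pixel centers up to 0.3975 mm
        frame = np.zeros((small_meta.n_alines, small_meta.n_depth))
        mask = build_catheter_mask(frame, small_meta)
        assert np.all(mask[:, :80])
        assert not mask[:, 80:].any()

    def test_zero_radius_empty_mask(self, small_meta):
        meta = dataclasses.replace(small_meta, catheter_radius_mm=0.0)
        frame = np.zeros((meta.n_alines, meta.n_depth))
        assert not build_catheter_mask(frame, meta).any()

    def test_catheter_beyond_depth_rejected(self, small_meta):
        meta = dataclasses.replace(small_meta, catheter_radius_mm=5.0)
        with pytest.raises(GeometryError):
            build_catheter_mask(np.zeros((meta.n_alines, meta.n_depth)), meta)

    def test_mask_covers_rendered_sheath(self, clean_pullback, small_meta):
        pb, _ = clean_pullback
        mask = build_catheter_mask(pb.frames[0], small_meta)
        # the bright sheath ring sits just inside the catheter radius
        d = small_meta.depth_centers_mm
        sheath_cols = (d > small_meta.catheter_radius_mm - 0.04) & (
            d <= small_meta.catheter_radius_mm
        )
        assert np.all(mask[:, sheath_cols])


class TestLumenContour:
    def test_recovers_offset_circle_within_two_pixels(self, clean_pullback, small_meta):
        pb, gt = clean_pullback
        contour = detect_lumen_contour(pb.frames[0], small_meta)
        err_px = np.abs(contour.radius_mm - gt.radii_mm[0]) / small_meta.axial_pitch_mm
        assert np.mean(err_px <= 2.0) >= 0.95
        assert err_px.mean() <= 2.0

    def test_periodic_and_above_catheter(self, clean_pullback, small_meta):
        pb, _ = clean_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        assert c.n_alines == small_meta.n_alines
        assert np.all(c.radius_mm >= small_meta.catheter_radius_mm)
        # periodic continuity: wrap-around jump no larger than within-frame jumps
        jumps = np.abs(np.diff(np.r_[c.radius_mm, c.radius_mm[0]]))
        assert jumps[-1] <= 0.3

    def test_pure_noise_frame_contract(self, small_meta, rng):
        frame = rng.uniform(0, 0.05, (small_meta.n_alines, small_meta.n_depth))
        with pytest.raises(ContourNotFoundError):
            detect_lumen_contour(frame, small_meta)
        lenient = SegmentationParams(strict=False)
        c = detect_lumen_contour(frame, small_meta, lenient)
        assert np.all(c.confidence == 0.0)

    def test_guidewire_sector_interpolated_and_continuous(self, stented_pullback, small_meta):
        pb, gt = stented_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        gw_mask = angular_distance_deg(small_meta.angles_deg, 200.0) <= 15.0
        assert c.interpolated[gw_mask].mean() > 0.8
        err = np.abs(c.radius_mm[gw_mask] - gt.radii_mm[0][gw_mask])
        assert err.mean() <= 4 * small_meta.axial_pitch_mm


class TestGuidewire:
    def test_sector_found_within_tolerance(self, stented_pullback, small_meta):
        pb, _ = stented_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        gw = detect_guidewire(pb.frames[0], c, small_meta)
        assert gw is not None
        assert angular_distance_deg(gw.center_deg, 200.0) <= 5.0
        assert abs(gw.width_deg - 30.0) <= 10.0

    def test_absent_guidewire_returns_none(self, clean_pullback, small_meta):
        pb, _ = clean_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        assert detect_guidewire(pb.frames[0], c, small_meta) is None

    def test_all_dark_frame_degenerate(self, clean_pullback, small_meta):
        pb, _ = clean_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        dark = np.full_like(pb.frames[0], 0.01)
        with pytest.raises(DegenerateFrameError):
            detect_guidewire(dark, c, small_meta)


class TestStrutDetection:
    def test_candidates_near_every_true_strut(self, stented_pullback, small_meta):
        pb, gt = stented_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        cands = detect_strut_candidates(pb.frames[0], c, small_meta)
        truth = gt.struts_for_frame(0)
        assert len(cands) >= len(truth)
        for t in truth:
            close = [
                cd
                for cd in cands
                if min(abs(cd.a_line - t[1]), small_meta.n_alines - abs(cd.a_line - t[1]))
                <= 1
                and abs(cd.depth_mm - t[3]) <= 2 * small_meta.axial_pitch_mm
            ]
            assert close, f"no candidate near true strut at a-line {t[1]:.0f}"

    def test_unstented_clean_frame_no_candidates(self, clean_pullback, small_meta):
        pb, _ = clean_pullback
        c = detect_lumen_contour(pb.frames[0], small_meta)
        assert detect_strut_candidates(pb.frames[0], c, small_meta) == []

    def test_bright_speck_without_shadow_rejected(self, clean_pullback, small_meta):
        """A floating bright speck has tissue visible behind it, so the
        dark-tail test rejects it."""
        pb, gt = clean_pullback
        frame = pb.frames[0].copy()
        a = 17
        p = int(gt.radii_mm[0][a] / small_meta.axial_pitch_mm) - 20  # 0.1 mm inside
        frame[a, p] = 0.95
        c = detect_lumen_contour(frame, small_meta)
        cands = detect_strut_candidates(frame, c, small_meta)
        assert all(cd.a_line != a for cd in cands)


class TestStrutFilter:
    def test_requires_classifier(self):
        with pytest.raises(ClassifierError):
            filter_struts([], None)

    def test_empty_candidates(self, strut_classifier):
        assert filter_struts([], strut_classifier) == []

    def test_same_aline_keeps_highest_score(self):
        mk = lambda: dict(
            a_line=5, angle_deg=7.5, depth_mm=1.2, peak_intensity=0.9,
            tail_contrast=0.8, dist_to_contour_mm=0.02, width_px=4,
        )

        class Fixed:
            threshold = 0.5

            def score(self, X):
                return np.array([0.9, 0.6])

        c1, c2 = Strut(**mk()), Strut(**mk())
        kept = filter_struts([c1, c2], Fixed())
        assert len(kept) == 1 and kept[0].score == pytest.approx(0.9)

    def test_recovers_true_struts_against_blood(
        self, stented_pullback, small_meta, strut_classifier
    ):
        pb, gt = stented_pullback
        ok_frames = 0
        for f in range(pb.n_frames):
            seg = segment_frame(pb.frames[f], small_meta, classifier=strut_classifier)
            truth = gt.struts_for_frame(f)
            matched = 0
            for t in truth:
                if any(
                    min(abs(s.a_line - t[1]), small_meta.n_alines - abs(s.a_line - t[1]))
                    <= 2
                    for s in seg.struts
                ):
                    matched += 1
            if matched == len(truth) and len(seg.struts) == len(truth):
                ok_frames += 1
        assert ok_frames >= pb.n_frames - 1


class TestStentContour:
    def _circle_struts(self, r=1.8, n=8):
        return [
            Strut(
                a_line=k, angle_deg=k * 360.0 / n, depth_mm=r, peak_intensity=1.0,
                tail_contrast=0.9, dist_to_contour_mm=0.03, width_px=3,
            )
            for k in range(n)
        ]

    def test_interpolating_spline_reproduces_circle_area(self, small_meta):
        sc = fit_stent_contour(self._circle_struts(), small_meta, smoothing=0.0)
        assert sc.area_mm2() == pytest.approx(np.pi * 1.8**2, rel=0.01)

    def test_two_struts_insufficient(self, small_meta):
        with pytest.raises(InsufficientStrutsError):
            fit_stent_contour(self._circle_struts()[:2], small_meta)

    def test_zero_smoothing_interpolates_to_sub_micron(self, small_meta):
        struts = self._circle_struts()
        sc = fit_stent_contour(struts, small_meta, smoothing=0.0)
        for s in struts:
            r_eval = np.interp(
                s.angle_deg, small_meta.angles_deg, sc.radius_mm, period=360.0
            )
            assert abs(r_eval - s.depth_mm) < 1e-3  # < 1 um

    def test_smoothing_tames_radial_outlier(self, small_meta):
        struts = self._circle_struts(n=12)
        struts[3] = dataclasses.replace(struts[3], depth_mm=2.4)
        truth = np.pi * 1.8**2
        exact = fit_stent_contour(struts, small_meta, smoothing=0.0).area_mm2()
        smooth = fit_stent_contour(struts, small_meta, smoothing=0.5).area_mm2()
        assert abs(smooth - truth) < abs(exact - truth)

    def test_duplicate_angles_collapsed(self, small_meta):
        struts = self._circle_struts()
        dup = dataclasses.replace(struts[0], depth_mm=2.0)
        sc = fit_stent_contour(struts + [dup], small_meta, smoothing=0.0)
        r0 = sc.radius_mm[0]
        assert r0 == pytest.approx(1.9, abs=0.02)  # mean of 1.8 and 2.0


class TestScanConversion:
    def test_single_bright_pixel_lands_at_plus_y(self, small_meta):
        frame = np.zeros((small_meta.n_alines, small_meta.n_depth))
        a90 = small_meta.n_alines // 4  # angle 90 deg
        k = int(1.0 / small_meta.axial_pitch_mm)  # radius 1 mm
        frame[a90, k] = 1.0
        cart = scan_convert_frame(frame, small_meta, 0.01, order=1)
        from octflush.segmentation import cartesian_coordinates

        c = cartesian_coordinates(small_meta, 0.01)
        X, Y = np.meshgrid(c, c)
        w = cart / cart.sum()
        assert abs((w * X).sum() - 0.0) < 0.02 and abs((w * Y).sum() - 1.0) < 0.02

    def test_constant_contour_polygon_area(self, small_meta):
        poly = contour_to_polygon(np.full(small_meta.n_alines, 1.0), small_meta)
        assert poly.area == pytest.approx(np.pi, rel=0.01)

    def test_cartesian_effective_lumen_area_matches_truth(
        self, stented_pullback, small_meta
    ):
        from octflush.segmentation import GuidewireSector, LumenContour

        _, gt = stented_pullback
        na = small_meta.n_alines
        contour = LumenContour(gt.radii_mm[0], np.ones(na), np.zeros(na, bool))
        masks = build_frame_masks(
            contour, small_meta, 0.01, guidewire=GuidewireSector(200.0, 30.0)
        )
        cart_area = masks.effective_lumen.sum() * 0.01**2
        # compare against the polar pixel-area sum (r-weighted annular sectors)
        d = small_meta.depth_centers_mm
        eff = (d[None, :] > small_meta.catheter_radius_mm) & (
            d[None, :] < gt.radii_mm[0][:, None]
        )
        eff &= ~(angular_distance_deg(small_meta.angles_deg, 200.0) <= 15.0)[:, None]
        polar_area = (
            np.broadcast_to(d, eff.shape)[eff].sum()
            * small_meta.axial_pitch_mm
            * (2 * np.pi / na)
        )
        assert cart_area == pytest.approx(polar_area, rel=0.01)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.booleans(), min_size=1, max_size=48))
@settings(max_examples=150, derandomize=True)
def test_longest_circular_run_brute_force(bits):
    mask = np.array(bits, dtype=bool)

    def brute(mask):
        n = len(mask)
        if not mask.any():
            return 0
        best = 0
        for start in range(n):
            cur = 0
            for i in range(n):
                if mask[(start + i) % n]:
                    cur += 1
                    best = max(best, cur)
                else:
                    break
        return min(best, n)

    assert longest_circular_run(mask) == brute(mask)
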