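"""Flushing-capability formula and CIS / clear-run rule semantics."""

import numpy as np
import pytest

from octflush.core import angular_distance_deg
from octflush.quality import (
    DegenerateLumenError,
    QualityParams,
    classify_cis,
    classify_clear_frame,
    classify_clear_run,
    compute_flushing_capability,
    compute_flushing_capability_polar,
    partition_segments,
    quality_report,
    summarize_quality,
)
from octflush.segmentation import (
    FrameMasks,
    GuidewireSector,
    LumenContour,
    build_frame_masks,
    scan_convert_frame,
)


def _masks_with(n_eff):
    """Minimal mask set with exactly n_eff effective-lumen pixels."""
    side = int(np.ceil(np.sqrt(n_eff)))
    lumen = np.zeros((side, side), dtype=bool)
    lumen.flat[:n_eff] = True
    return FrameMasks(
        lumen_interior=lumen,
        catheter=np.zeros_like(lumen),
        guidewire=np.zeros_like(lumen),
        pixel_size_mm=0.01,
    )


class TestFlushingFormula:
    def test_no_bright_pixels_gives_one(self):
        masks = _masks_with(500)
        frame = np.zeros(masks.lumen_interior.shape)
        assert compute_flushing_capability(frame, masks) == 1.0

    def test_direct_arithmetic_80_of_800(self):
        masks = _masks_with(800)
        frame = np.zeros(masks.lumen_interior.shape)
        idx = np.nonzero(masks.effective_lumen.ravel())[0][:80]
        frame.ravel()[idx] = 0.9
        assert compute_flushing_capability(frame, masks) == pytest.approx(0.900)

    def test_empty_effective_lumen_raises(self):
        masks = _masks_with(0)
        with pytest.raises(DegenerateLumenError):
            compute_flushing_capability(np.zeros((1, 1)), masks)

    def test_monotone_in_bright_pixels(self, rng):
        masks = _masks_with(400)
        frame = np.zeros(masks.lumen_interior.shape)
        prev = compute_flushing_capability(frame, masks)
        idx = rng.permutation(np.nonzero(masks.effective_lumen.ravel())[0])
        for k in (10, 50, 120, 300):
            frame.ravel()[idx[:k]] = 0.8
            cur = compute_flushing_capability(frame, masks)
            assert cur <= prev
            prev = cur

    def test_matches_exhaustive_scan_on_phantom(self, stented_pullback, small_meta):
        """Vectorized statistic equals a literal per-pixel Python loop."""
        pb, gt = stented_pullback
        f = 0
        na = small_meta.n_alines
        contour = LumenContour(gt.radii_mm[f], np.ones(na), np.zeros(na, bool))
        cart = scan_convert_frame(pb.frames[f], small_meta, 0.02)
        masks = build_frame_masks(
            contour, small_meta, 0.02, guidewire=GuidewireSector(200.0, 30.0)
        )
        got = compute_flushing_capability(cart, masks)
        bright = total = 0
        eff = masks.effective_lumen
        for i in range(cart.shape[0]):
            for j in range(cart.shape[1]):
                if eff[i, j]:
                    total += 1
                    if cart[i, j] > 0.35:
                        bright += 1
        assert got == 1.0 - bright / total

    def test_polar_and_cartesian_agree(self, stented_pullback, small_meta):
        pb, gt = stented_pullback
        na = small_meta.n_alines
        for f in range(pb.n_frames):
            contour = LumenContour(gt.radii_mm[f], np.ones(na), np.zeros(na, bool))
            gw = GuidewireSector(200.0, 30.0)
            cart = scan_convert_frame(pb.frames[f], small_meta, 0.01)
            masks = build_frame_masks(contour, small_meta, 0.01, guidewire=gw)
            fc = compute_flushing_capability(cart, masks)
            fp = compute_flushing_capability_polar(
                pb.frames[f], contour, small_meta, guidewire_mask=gw.aline_mask(small_meta)
            )
            assert fc == pytest.approx(fp, abs=0.01)

    def test_rotation_invariance(self, stented_pullback, small_meta):
        pb, gt = stented_pullback
        na = small_meta.n_alines
        shift = 57
        contour = LumenContour(gt.radii_mm[0], np.ones(na), np.zeros(na, bool))
        rolled = LumenContour(
            np.roll(gt.radii_mm[0], shift), np.ones(na), np.zeros(na, bool)
        )
        gw_mask = angular_distance_deg(small_meta.angles_deg, 200.0) <= 15.0
        a = compute_flushing_capability_polar(
            pb.frames[0], contour, small_meta, guidewire_mask=gw_mask
        )
        b = compute_flushing_capability_polar(
            np.roll(pb.frames[0], shift, axis=0),
            rolled,
            small_meta,
            guidewire_mask=np.roll(gw_mask, shift),
        )
        assert a == pytest.approx(b, abs=1e-12)


class TestClearFrame:
    def _uniform_frame(self, small_meta, r=1.0, dark_sector=None):
        """Wall edge at radius r, optionally a dark (occluded) sector."""
        na, nd = small_meta.n_alines, small_meta.n_depth
        frame = np.full((na, nd), 0.02)
        d = small_meta.depth_centers_mm
        wall = (d >= r) & (d < r + 0.3)
        frame[:, wall] = 0.8
        conf = np.ones(na)
        if dark_sector is not None:
            lo, hi = dark_sector
            sector = (small_meta.angles_deg >= lo) & (small_meta.angles_deg < hi)
            frame[sector] = 0.02
            conf[sector] = 0.0
        contour = LumenContour(np.full(na, r), conf, np.zeros(na, bool))
        return frame, contour

    def test_fully_visible_frame_is_clear(self, small_meta):
        frame, contour = self._uniform_frame(small_meta)
        arc, clear = classify_clear_frame(contour, frame, small_meta)
        assert arc == 360.0 and clear

    def test_half_obscured_frame_unclear(self, small_meta):
        frame, contour = self._uniform_frame(small_meta, dark_sector=(90, 270))
        arc, clear = classify_clear_frame(contour, frame, small_meta)
        assert arc == pytest.approx(180.0, abs=3.0)
        assert not clear

    def test_wraparound_arc_counts_across_zero(self, small_meta):
        # clear 300..360 and 0..220 wraps to a 280-degree arc > 270
        frame, contour = self._uniform_frame(small_meta, dark_sector=(220, 300))
        arc, clear = classify_clear_frame(contour, frame, small_meta)
        assert arc == pytest.approx(280.0, abs=3.0)
        assert clear

    def test_missing_contour_gives_zero_arc(self, small_meta):
        arc, clear = classify_clear_frame(
            None, np.zeros((small_meta.n_alines, small_meta.n_depth)), small_meta
        )
        assert arc == 0.0 and not clear


class TestSegmentRules:
    def test_partition_270_frames_at_02mm(self):
        segs = partition_segments(270, 0.2)
        assert len(segs) == 54 and all(len(s) == 5 for s in segs)

    def test_partition_drops_trailing_partial(self):
        segs = partition_segments(273, 0.2)
        assert len(segs) == 54 and segs[-1].stop == 270

    def test_partition_too_few_frames(self):
        assert partition_segments(4, 0.2) == []

    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([True, True, True, False, False], True),  # 60%
            ([True, True, False, False, False], False),  # 40%
            ([True, True, False, False], True),  # exactly 50% -> inclusive
        ],
    )
    def test_cis_threshold_inclusive(self, flags, expected):
        assert classify_cis(flags) is expected

    def test_cis_empty_segment_raises(self):
        with pytest.raises(ValueError):
            classify_cis([])

    @pytest.mark.parametrize(
        "n_cis,n_total,expected",
        [(54, 54, True), (45, 50, True), (44, 50, False)],  # 90% inclusive
    )
    def test_clear_run_threshold(self, n_cis, n_total, expected):
        flags = [True] * n_cis + [False] * (n_total - n_cis)
        assert classify_clear_run(flags) is expected

    def test_flag_definitions_are_reconstructible(self, rng):
        """Stored CIS / clear-run verdicts re-derive from per-frame flags."""
        clear = rng.random(40) < 0.8
        res = summarize_quality(rng.random(40), np.full(40, 300.0), clear, 0.2)
        for seg, flag in zip(res.segments, res.cis):
            assert flag == classify_cis(clear[list(seg)])
        assert res.clear_run == classify_clear_run(res.cis)

    def test_report_row_counts(self, rng):
        clear = np.ones(20, dtype=bool)
        res = summarize_quality(rng.random(20), np.full(20, 360.0), clear, 0.2)
        rep = quality_report(res, label="pb")
        assert len(rep) == 20 + len(res.segments) + 1
        assert (rep[rep.level == "pullback"].cis == len(res.segments)).all()
        # all frames clear -> no suboptimal segments
        assert res.cis.all()


def test_quality_params_validation():
    with pytest.raises(ValueError):
        QualityParams(bright_threshold=1.5)
    with pytest.raises(ValueError):
        QualityParams(clear_arc_min_deg=0.0)
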