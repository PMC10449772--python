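"""Pixel-based segmentation of polar intravascular OCT frames.

The pipeline per frame is: mask the catheter sheath, delineate the lumen
contour from dominant depth-direction edges, locate the guidewire shadow
sector, detect stent strut candidates as bright reflections with a dark
radial tail, refine them with a pluggable classifier, and fit a closed
periodic smoothing spline through the abluminal strut surfaces. A scan
converter resamples polar frames onto an equal-area Cartesian grid for the
pixel-counting statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Protocol, Sequence

import numpy as np
from scipy import interpolate as _interp
from scipy import ndimage as _ndi

from .core import (
    AcquisitionMeta,
    GeometryError,
    angular_distance_deg,
    polar_contour_area_mm2,
)

__all__ = [
    "SegmentationParams",
    "LumenContour",
    "GuidewireSector",
    "Strut",
    "StentContour",
    "FrameMasks",
    "SegmentationError",
    "ContourNotFoundError",
    "DegenerateFrameError",
    "InsufficientStrutsError",
    "ClassifierError",
    "build_catheter_mask",
    "detect_lumen_contour",
    "detect_guidewire",
    "detect_strut_candidates",
    "filter_struts",
    "fit_stent_contour",
    "scan_convert_frame",
    "contour_to_polygon",
    "build_frame_masks",
    "cartesian_coordinates",
    "RuleBasedStrutClassifier",
    "LogisticStrutClassifier",
    "default_strut_classifier",
    "longest_circular_run",
    "segment_frame",
    "FrameSegmentation",
]


class SegmentationError(RuntimeError):
    pass


class ContourNotFoundError(SegmentationError):
    pass


class DegenerateFrameError(SegmentationError):
    pass


class InsufficientStrutsError(SegmentationError):
    pass


class ClassifierError(SegmentationError):
    pass


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the frame segmentation.

    All intensity thresholds refer to normalized intensities in [0, 1];
    the edge threshold is a per-pixel gradient of the axially Gaussian-
    smoothed A-line.
    """

    edge_sigma_px: float = 3.0
    edge_threshold: float = 0.04
    start_margin_px: int = 8
    tissue_check_px: int = 40
    tissue_level_min: float = 0.20
    immediate_check_px: int = 6
    immediate_level_min: float = 0.30
    angular_median_window: int = 7
    max_jump_mm: float = 0.30
    min_found_fraction: float = 0.25
    strict: bool = True
    # strut detection
    strut_threshold: float = 0.60
    search_band_mm: float = 0.15
    search_band_out_mm: float = 0.05
    tail_gap_mm: float = 0.05
    tail_window_mm: float = 0.15
    shadow_threshold: float = 0.12
    # guidewire detection
    gw_dark_threshold: float = 0.08
    gw_bright_min: float = 0.50
    gw_min_width_deg: float = 10.0
    # scan conversion
    cartesian_pixel_mm: float = 0.01


@dataclass
class LumenContour:
    """Per-A-line lumen radius with confidences; periodic by construction."""

    radius_mm: np.ndarray
    confidence: np.ndarray
    interpolated: np.ndarray  # bool: replaced by circular-median interpolation

    def __post_init__(self) -> None:
        n = len(self.radius_mm)
        if not (len(self.confidence) == len(self.interpolated) == n):
            raise ValueError("contour arrays must share one length")

    @property
    def n_alines(self) -> int:
        return len(self.radius_mm)

    def area_mm2(self) -> float:
        return polar_contour_area_mm2(self.radius_mm)


@dataclass(frozen=True)
class GuidewireSector:
    center_deg: float
    width_deg: float

    def aline_mask(self, meta: AcquisitionMeta) -> np.ndarray:
        return angular_distance_deg(meta.angles_deg, self.center_deg) <= self.width_deg / 2.0


@dataclass
class Strut:
    """One detected stent strut candidate with its classifier features."""

    a_line: int
    angle_deg: float
    depth_mm: float  # radius of the reflection peak
    peak_intensity: float
    tail_contrast: float  # peak minus mean intensity of the deeper tail window
    dist_to_contour_mm: float
    width_px: float
    score: float = 1.0

    def feature_vector(self) -> np.ndarray:
        return np.array(
            [self.peak_intensity, self.tail_contrast, self.dist_to_contour_mm, self.width_px]
        )


@dataclass
class StentContour:
    """Closed periodic spline through abluminal strut points, per A-line."""

    radius_mm: np.ndarray
    smoothing: float
    source_alines: tuple[int, ...] = ()

    def area_mm2(self) -> float:
        return polar_contour_area_mm2(self.radius_mm)


@dataclass
class FrameMasks:
    """Cartesian masks sharing one raster; effective lumen is derived."""

    lumen_interior: np.ndarray
    catheter: np.ndarray
    guidewire: np.ndarray
    pixel_size_mm: float

    @property
    def effective_lumen(self) -> np.ndarray:
        return self.lumen_interior & ~self.catheter & ~self.guidewire


@dataclass
class FrameSegmentation:
    """Everything the segmentation stage knows about one frame."""

    contour: LumenContour
    guidewire: GuidewireSector | None
    struts: list[Strut] = field(default_factory=list)
    stent_contour: StentContour | None = None


# ---------------------------------------------------------------------------
# circular runs (shared with the quality rules)


def longest_circular_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values on a circular axis."""
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if n == 0 or not mask.any():
        return 0
    if mask.all():
        return n
    doubled = np.concatenate([mask, mask])
    best = cur = 0
    for v in doubled:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return min(best, n)


def _circular_run_bounds(mask: np.ndarray) -> tuple[int, int]:
    """(start index, length) of the longest circular True run."""
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if not mask.any():
        return 0, 0
    if mask.all():
        return 0, n
    doubled = np.concatenate([mask, mask])
    best_len = cur = 0
    best_start = start = 0
    for i, v in enumerate(doubled):
        if v:
            if cur == 0:
                start = i
            cur += 1
            if cur > best_len:
                best_len, best_start = cur, start
        else:
            cur = 0
    return best_start % n, min(best_len, n)


# ---------------------------------------------------------------------------
# catheter


def build_catheter_mask(frame: np.ndarray, meta: AcquisitionMeta) -> np.ndarray:
    """Polar mask of all pixels whose center radius is <= the catheter radius."""
    if meta.catheter_radius_mm >= meta.max_radius_mm:
        raise GeometryError("catheter radius reaches beyond the imaged depth")
    mask = np.zeros(frame.shape, dtype=bool)
    mask[:, meta.depth_centers_mm <= meta.catheter_radius_mm] = True
    return mask


# ---------------------------------------------------------------------------
# lumen contour


def detect_lumen_contour(
    frame: np.ndarray, meta: AcquisitionMeta, params: SegmentationParams | None = None
) -> LumenContour:
    """Delineate the lumen from dominant depth-direction intensity edges.

    Per A-line the boundary is placed at the local maximum of the axially
    Gaussian-smoothed depth gradient, at the first position beyond the
    catheter where the gradient exceeds ``edge_threshold`` and sustained
    tissue intensity follows. A-lines without a boundary (guidewire shadow,
    side branch) and angular outliers are replaced by circular-median
    interpolation and flagged.
    """
    params = params or SegmentationParams()
    na, nd = frame.shape
    pitch = meta.axial_pitch_mm

    grad = _ndi.gaussian_filter1d(frame, params.edge_sigma_px, axis=1, order=1)
    start = meta.catheter_depth_px + params.start_margin_px

    # forward mean over the next tissue_check_px pixels
    w = params.tissue_check_px
    cs = np.cumsum(np.pad(frame, ((0, 0), (1, w)), mode="edge"), axis=1)
    fwd_mean = (cs[:, 1 + w :] - cs[:, 1:-w]) / w  # mean of frame[:, k:k+w]

    candidate = (grad > params.edge_threshold) & (fwd_mean >= params.tissue_level_min)
    candidate[:, :start] = False

    # per A-line: walk the threshold crossings in depth order, snap each to
    # the local gradient peak, and accept the first whose immediate
    # following intensity looks like a tissue entry (rejects isolated
    # residual-blood specks, which are followed by dark lumen)
    win = max(2, int(round(2 * params.edge_sigma_px)))
    imm = params.immediate_check_px
    found = np.zeros(na, dtype=bool)
    peak_idx = np.zeros(na, dtype=int)
    for a in range(na):
        cols = np.nonzero(candidate[a])[0]
        prev_peak = -1
        for i in cols:
            if i <= prev_peak:
                continue
            p = i + int(np.argmax(grad[a, i : min(nd, i + win + 1)]))
            prev_peak = p
            w_imm = frame[a, p + 1 : min(nd, p + 1 + imm)]
            # mean catches weak entries, median rejects sparse bright specks
            if w_imm.mean() >= params.immediate_level_min and np.median(w_imm) >= 0.25:
                found[a] = True
                peak_idx[a] = p
                break

    if found.sum() == 0:
        if params.strict:
            raise ContourNotFoundError("no A-line yields a lumen boundary")
        r = np.full(na, 2.0 * max(meta.catheter_radius_mm, pitch))
        return LumenContour(r, np.zeros(na), np.ones(na, dtype=bool))
    if found.mean() < params.min_found_fraction and params.strict:
        raise ContourNotFoundError(
            f"lumen boundary found on only {found.mean():.0%} of A-lines"
        )

    radius = (peak_idx + 0.5) * pitch
    confidence = np.zeros(na)
    gmax = grad.max()
    if gmax > 0:
        confidence[found] = np.clip(grad[found, peak_idx[found]] / gmax, 0.0, 1.0)

    # fill missing A-lines from a low-order Fourier fit of the found radii:
    # a smooth periodic contour is low-harmonic, and the global fit is
    # insensitive to noise at the edges of a shadow gap
    angles = meta.angles_deg[:na]
    if not found.all():
        good = np.nonzero(found)[0]
        order = 4
        if good.size >= 2 * order + 3:
            th = np.deg2rad(angles[good])
            cols = [np.ones_like(th)]
            for m in range(1, order + 1):
                cols.extend([np.cos(m * th), np.sin(m * th)])
            A = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(A, radius[good], rcond=None)
            th_all = np.deg2rad(angles)
            cols = [np.ones_like(th_all)]
            for m in range(1, order + 1):
                cols.extend([np.cos(m * th_all), np.sin(m * th_all)])
            filled = np.column_stack(cols) @ coef
        else:
            filled = np.interp(angles, angles[good], radius[good], period=360.0)
        radius = np.where(found, radius, filled)

    # circular-median outlier replacement
    med = _ndi.median_filter(radius, size=params.angular_median_window, mode="wrap")
    outlier = np.abs(radius - med) > params.max_jump_mm
    radius = np.where(outlier, med, radius)
    interpolated = outlier | ~found
    confidence[interpolated] = 0.0
    radius = np.maximum(radius, meta.catheter_radius_mm)
    return LumenContour(radius, confidence, interpolated)


# ---------------------------------------------------------------------------
# guidewire


def detect_guidewire(
    frame: np.ndarray,
    contour: LumenContour,
    meta: AcquisitionMeta,
    params: SegmentationParams | None = None,
) -> GuidewireSector | None:
    """Locate the guidewire as the contiguous angular run whose deep tissue
    is near-dark while a bright superficial reflection is present.

    Returns ``None`` if no sufficiently wide sector is found.
    """
    params = params or SegmentationParams()
    na, nd = frame.shape
    d = meta.depth_centers_mm
    r = contour.radius_mm

    deep_mean = np.empty(na)
    superficial_max = np.empty(na)
    for a in range(na):
        lo = min(nd - 2, int((r[a] + 0.05) / meta.axial_pitch_mm))
        hi = min(nd, int((r[a] + 0.25) / meta.axial_pitch_mm) + 1)
        deep_mean[a] = frame[a, lo:hi].mean() if hi > lo else 0.0
        slo = meta.catheter_depth_px
        shi = max(slo + 1, int(r[a] / meta.axial_pitch_mm))
        superficial_max[a] = frame[a, slo:shi].max()

    dark = deep_mean < params.gw_dark_threshold
    if dark.all():
        raise DegenerateFrameError("entire frame is shadowed; no tissue visible")
    cand = dark & (superficial_max > params.gw_bright_min)
    start, length = _circular_run_bounds(cand)
    width = length * 360.0 / na
    if width < params.gw_min_width_deg:
        return None
    center = (start + (length - 1) / 2.0) % na * 360.0 / na
    return GuidewireSector(center_deg=center, width_deg=width)


# ---------------------------------------------------------------------------
# struts


def detect_strut_candidates(
    frame: np.ndarray,
    contour: LumenContour,
    meta: AcquisitionMeta,
    params: SegmentationParams | None = None,
    exclude_alines: np.ndarray | None = None,
) -> list[Strut]:
    """Detect bright axial reflections with a dark deeper tail near the lumen.

    Candidates are local axial maxima above ``strut_threshold`` within
    ``search_band_mm`` of the lumen contour whose mean intensity in a
    strictly deeper tail window falls below ``shadow_threshold``.
    ``exclude_alines`` (e.g. the guidewire sector) are skipped.
    """
    params = params or SegmentationParams()
    na, nd = frame.shape
    pitch = meta.axial_pitch_mm
    gap = max(1, int(round(params.tail_gap_mm / pitch)))
    tail = max(1, int(round(params.tail_window_mm / pitch)))
    out: list[Strut] = []
    for a in range(na):
        if exclude_alines is not None and exclude_alines[a]:
            continue
        r = contour.radius_mm[a]
        lo = max(meta.catheter_depth_px + 2, int((r - params.search_band_mm) / pitch))
        hi = min(nd - 2, int((r + params.search_band_out_mm) / pitch))
        if hi <= lo + 2:
            continue
        seg = frame[a, lo : hi + 1]
        is_peak = (
            (seg[1:-1] > params.strut_threshold)
            & (seg[1:-1] >= seg[:-2])
            & (seg[1:-1] >= seg[2:])
        )
        for k in np.nonzero(is_peak)[0]:
            p = lo + 1 + k
            t_lo = p + gap
            t_hi = min(nd, t_lo + tail)
            if t_hi <= t_lo:
                continue
            tail_mean = float(frame[a, t_lo:t_hi].mean())
            if tail_mean >= params.shadow_threshold:
                continue
            peak = float(frame[a, p])
            # axial half-maximum width of the reflection
            half = 0.5 * peak
            wlo = p
            while wlo > 0 and frame[a, wlo - 1] > half:
                wlo -= 1
            whi = p
            while whi < nd - 1 and frame[a, whi + 1] > half:
                whi += 1
            out.append(
                Strut(
                    a_line=a,
                    angle_deg=meta.angles_deg[a],
                    depth_mm=(p + 0.5) * pitch,
                    peak_intensity=peak,
                    tail_contrast=peak - tail_mean,
                    dist_to_contour_mm=r - (p + 0.5) * pitch,
                    width_px=float(whi - wlo + 1),
                )
            )
    return out


class StrutClassifier(Protocol):
    """Anything that scores strut candidates in [0, 1] and owns a threshold."""

    threshold: float

    def score(self, features: np.ndarray) -> np.ndarray: ...


@dataclass
class RuleBasedStrutClassifier:
    """Soft-threshold fallback scorer on peak intensity and tail contrast."""

    threshold: float = 0.5
    min_peak: float = 0.55
    min_tail_contrast: float = 0.30

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        peak, tailc = features[:, 0], features[:, 1]
        s1 = 1.0 / (1.0 + np.exp(-25.0 * (peak - self.min_peak)))
        s2 = 1.0 / (1.0 + np.exp(-25.0 * (tailc - self.min_tail_contrast)))
        return s1 * s2


class LogisticStrutClassifier:
    """Logistic-regression refinement stage trained on phantom candidates.

    A stand-in learned refinement: features are (peak intensity, tail
    contrast, distance to contour, axial width); labels come from phantom
    ground truth. The interface is pluggable so a stronger model can be
    dropped in.
    """

    threshold: float = 0.5

    def __init__(self, model=None):
        self._model = model

    def score(self, features: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise ClassifierError("classifier has not been trained")
        features = np.atleast_2d(features)
        return self._model.predict_proba(features)[:, 1]

    @classmethod
    def train_on_phantom(cls, seed: int = 1234) -> "LogisticStrutClassifier":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        from . import phantom as ph

        meta = AcquisitionMeta(n_alines=240, n_depth=420, pullback_length_mm=1.0)
        spec = ph.PhantomSpec(
            lumen=ph.LumenModel(base_radius_mm=1.6, center_offset_mm=0.2),
            stent=ph.StentSpec(n_struts=8, start_angle_deg=13.0),
            residual_blood_density=0.06,
            seed=seed,
        )
        # labels come from the tight detector's candidate pool, whose false
        # positives are residual-blood specks, not wall edges
        loose = SegmentationParams(strut_threshold=0.45)
        X, y = [], []
        pb, gt = ph.generate_pullback(spec, meta, n_frames=6)
        for f in range(pb.n_frames):
            contour = detect_lumen_contour(pb.frames[f], meta)
            cands = detect_strut_candidates(pb.frames[f], contour, meta, loose)
            truth = gt.struts_for_frame(f)
            for c in cands:
                da = np.min(
                    np.minimum(
                        np.abs(truth[:, 1] - c.a_line),
                        meta.n_alines - np.abs(truth[:, 1] - c.a_line),
                    )
                ) if truth.size else np.inf
                dd = (
                    np.min(np.abs(truth[:, 3] - c.depth_mm)) if truth.size else np.inf
                )
                label = int(da <= 2 and dd <= 3 * meta.axial_pitch_mm)
                X.append(c.feature_vector())
                y.append(label)
        X, y = np.array(X), np.array(y)
        if len(np.unique(y)) < 2:
            raise ClassifierError("phantom training set is single-class")
        model = make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=0)
        )
        model.fit(X, y)
        return cls(model)


@lru_cache(maxsize=1)
def default_strut_classifier() -> StrutClassifier:
    """Phantom-trained logistic classifier, rule-based if training degenerates."""
    try:
        return LogisticStrutClassifier.train_on_phantom()
    except ClassifierError:
        return RuleBasedStrutClassifier()


def filter_struts(
    candidates: Sequence[Strut],
    classifier: StrutClassifier,
    min_separation_deg: float = 4.0,
) -> list[Strut]:
    """Keep candidates scoring at or above the classifier threshold, then
    suppress non-maxima: within any circular window of
    ``min_separation_deg`` degrees only the highest-scoring candidate
    survives (a strut reflection spans a few adjacent A-lines)."""
    if classifier is None:
        raise ClassifierError("no classifier configured")
    if not candidates:
        return []
    X = np.array([c.feature_vector() for c in candidates])
    scores = np.asarray(classifier.score(X), dtype=float)
    passing = []
    for c, s in zip(candidates, scores):
        if s >= classifier.threshold:
            c.score = float(s)
            passing.append(c)
    if not passing:
        return []
    kept: list[Strut] = []
    for c in sorted(passing, key=lambda c: -c.score):
        if all(
            angular_distance_deg(c.angle_deg, k.angle_deg) >= min_separation_deg
            for k in kept
        ):
            kept.append(c)
    return sorted(kept, key=lambda c: c.a_line)


# ---------------------------------------------------------------------------
# stent contour


def fit_stent_contour(
    struts: Sequence[Strut],
    meta: AcquisitionMeta,
    smoothing: float = 0.0,
    strut_thickness_mm: float = 0.0,
) -> StentContour:
    """Fit a closed periodic cubic smoothing spline through the abluminal
    strut surfaces and evaluate it at every A-line angle.

    The abluminal radius of a strut is its reflection peak depth plus half
    the strut thickness. ``smoothing`` is the spline residual bound ``s``;
    0 interpolates the points exactly.
    """
    if len(struts) < 3:
        raise InsufficientStrutsError(f"need >= 3 struts, got {len(struts)}")
    by_angle: dict[float, list[float]] = {}
    for s in struts:
        by_angle.setdefault(round(s.angle_deg % 360.0, 9), []).append(
            s.depth_mm + strut_thickness_mm / 2.0
        )
    angles = np.array(sorted(by_angle))
    if angles.size < 3:
        raise InsufficientStrutsError("need >= 3 struts at distinct angles")
    radii = np.array([np.mean(by_angle[a]) for a in angles])

    x = np.deg2rad(angles)
    x = np.append(x, x[0] + 2 * np.pi)
    yv = np.append(radii, radii[0])
    k = min(3, len(angles) - 1) if len(angles) <= 3 else 3
    tck = _interp.splrep(x, yv, k=k, per=1, s=smoothing)
    theta = np.deg2rad(meta.angles_deg) % (2 * np.pi)
    out = _interp.splev(np.where(theta < x[0], theta + 2 * np.pi, theta), tck)
    return StentContour(
        radius_mm=np.asarray(out, dtype=float),
        smoothing=smoothing,
        source_alines=tuple(s.a_line for s in struts),
    )


# ---------------------------------------------------------------------------
# scan conversion


def cartesian_coordinates(
    meta: AcquisitionMeta, pixel_size_mm: float = 0.01, radius_mm: float | None = None
) -> np.ndarray:
    """1-D pixel-center coordinates of the square Cartesian grid."""
    R = radius_mm if radius_mm is not None else meta.max_radius_mm
    n = int(np.ceil(2 * R / pixel_size_mm))
    return (np.arange(n) - (n - 1) / 2.0) * pixel_size_mm


def scan_convert_frame(
    frame: np.ndarray,
    meta: AcquisitionMeta,
    pixel_size_mm: float = 0.01,
    radius_mm: float | None = None,
    order: int = 0,
) -> np.ndarray:
    """Resample a polar frame onto a square Cartesian grid.

    Pixel [iy, ix] of the output sits at ``(x=c[ix], y=c[iy])`` with ``c``
    from :func:`cartesian_coordinates`; y points toward angle 90 degrees.
    Radii beyond the imaged depth map to 0. The default is nearest-neighbor
    resampling (``order=0``): it preserves per-pixel intensity statistics,
    so pixel-count fractions on the Cartesian raster are unbiased; pass
    ``order=1`` for bilinear interpolation when rendering for display.
    """
    c = cartesian_coordinates(meta, pixel_size_mm, radius_mm)
    X, Y = np.meshgrid(c, c)
    r = np.hypot(X, Y)
    theta = np.mod(np.degrees(np.arctan2(Y, X)), 360.0)
    aline_coord = theta / (360.0 / meta.n_alines)
    depth_coord = r / meta.axial_pitch_mm - 0.5
    padded = np.vstack([frame, frame[:1]])  # angular wrap for interpolation
    return _ndi.map_coordinates(
        padded, [aline_coord, depth_coord], order=order, mode="constant", cval=0.0
    )


def contour_to_polygon(radius_mm: np.ndarray, meta: AcquisitionMeta):
    """Closed shapely polygon of a per-A-line polar contour."""
    from shapely.geometry import Polygon

    th = np.deg2rad(meta.angles_deg[: len(radius_mm)])
    return Polygon(np.column_stack([radius_mm * np.cos(th), radius_mm * np.sin(th)]))


def build_frame_masks(
    contour: LumenContour,
    meta: AcquisitionMeta,
    pixel_size_mm: float = 0.01,
    guidewire: GuidewireSector | None = None,
    radius_mm: float | None = None,
) -> FrameMasks:
    """Cartesian lumen-interior / catheter / guidewire masks for one frame.

    Equal-area Cartesian pixels make the pixel-counting denominator a true
    area. Membership is decided for the polar pixel each Cartesian pixel
    samples under nearest-neighbor scan conversion (its quantized radius
    and A-line), so mask-based pixel counts are consistent with the
    resampled image down to the boundary pixels.
    """
    if pixel_size_mm > np.min(contour.radius_mm) / 10.0:
        warnings.warn(
            "Cartesian grid coarser than a tenth of the smallest lumen radius; "
            "area estimates may be inaccurate",
            stacklevel=2,
        )
    c = cartesian_coordinates(meta, pixel_size_mm, radius_mm)
    X, Y = np.meshgrid(c, c)
    r = np.hypot(X, Y)
    theta = np.mod(np.degrees(np.arctan2(Y, X)), 360.0)
    # quantize to the nearest polar pixel (matches scan_convert_frame order=0)
    k = np.round(r / meta.axial_pitch_mm - 0.5).astype(int)
    r_q = (k + 0.5) * meta.axial_pitch_mm
    j = np.round(theta / (360.0 / meta.n_alines)).astype(int) % meta.n_alines
    lumen = r_q < contour.radius_mm[j]
    catheter = r_q <= meta.catheter_radius_mm
    if guidewire is not None:
        gw = (
            angular_distance_deg(meta.angles_deg[j], guidewire.center_deg)
            <= guidewire.width_deg / 2.0
        )
        gw &= lumen
    else:
        gw = np.zeros_like(lumen)
    return FrameMasks(
        lumen_interior=lumen, catheter=catheter, guidewire=gw, pixel_size_mm=pixel_size_mm
    )


# ---------------------------------------------------------------------------
# one-call frame segmentation


def segment_frame(
    frame: np.ndarray,
    meta: AcquisitionMeta,
    params: SegmentationParams | None = None,
    classifier: StrutClassifier | None = None,
    detect_stent: bool = True,
    stent_smoothing: float = 0.0,
) -> FrameSegmentation:
    """Run the full per-frame segmentation chain.

    Detects the lumen contour and guidewire, finds and filters strut
    candidates (skipped when ``detect_stent`` is false), and fits the stent
    contour when at least three struts survive filtering.
    """
    params = params or SegmentationParams()
    contour = detect_lumen_contour(frame, meta, params)
    gw = detect_guidewire(frame, contour, meta, params)
    struts: list[Strut] = []
    stent = None
    if detect_stent:
        excl = gw.aline_mask(meta) if gw is not None else None
        cands = detect_strut_candidates(frame, contour, meta, params, exclude_alines=excl)
        struts = filter_struts(cands, classifier or default_strut_classifier())
        if len({s.a_line for s in struts}) >= 3:
            stent = fit_stent_contour(struts, meta, smoothing=stent_smoothing)
    return FrameSegmentation(contour=contour, guidewire=gw, struts=struts, stent_contour=stent)
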