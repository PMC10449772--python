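"""Blood-flushing capability and image-quality classification.

The flushing capability of a cross section is

    1 - (bright pixels within the effective lumen) / (effective-lumen pixels)

where the effective lumen is the lumen interior minus the catheter sheath
and guidewire artifact, and a pixel is bright when its normalized
intensity exceeds a predetermined background threshold. It is computed on
the scan-converted Cartesian raster so every pixel has equal area; an
r-weighted polar mode is available and agrees closely.

Quality classification follows the clear-image-segment convention:

* a frame is *clear* when the arterial structure is visible along a
  continuous circular arc strictly greater than ``clear_arc_min`` (270 deg);
* a 1-mm longitudinal segment is a *clear image segment* (CIS) when at
  least 50% of its frames are clear (inclusive);
* a pullback is a *clear run* when at least 90% of its 1-mm segments are
  CIS (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcquisitionMeta
from .segmentation import FrameMasks, LumenContour, longest_circular_run

__all__ = [
    "QualityParams",
    "QualityResult",
    "compute_flushing_capability",
    "compute_flushing_capability_polar",
    "classify_clear_frame",
    "partition_segments",
    "classify_cis",
    "classify_clear_run",
    "quality_report",
]


class DegenerateLumenError(ValueError):
    pass


@dataclass(frozen=True)
class QualityParams:
    bright_threshold: float = 0.35
    clear_arc_min_deg: float = 270.0
    cis_clear_fraction: float = 0.5
    clear_run_fraction: float = 0.9
    segment_length_mm: float = 1.0
    aline_clear_blood_limit: float = 0.20
    aline_confidence_min: float = 0.05
    aline_structure_min: float = 0.30
    structure_band_mm: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.bright_threshold <= 1.0:
            raise ValueError("bright_threshold must lie in [0, 1]")
        if not 0.0 < self.clear_arc_min_deg <= 360.0:
            raise ValueError("clear_arc_min_deg must lie in (0, 360]")


@dataclass
class QualityResult:
    """Per-frame, per-segment and per-pullback quality summary."""

    flushing: np.ndarray  # per frame, in [0, 1]
    visible_arc_deg: np.ndarray  # per frame
    clear: np.ndarray  # per frame, bool
    segments: list[range]
    cis: np.ndarray  # per segment, bool
    clear_run: bool
    flushing_median: float
    flushing_iqr: tuple[float, float]
    params: QualityParams = field(default_factory=QualityParams)


def compute_flushing_capability(
    cartesian_frame: np.ndarray, masks: FrameMasks, params: QualityParams | None = None
) -> float:
    """Blood-flushing capability of one scan-converted frame.

    Raises
    ------
    DegenerateLumenError
        If the effective lumen contains no pixel.
    """
    params = params or QualityParams()
    eff = masks.effective_lumen
    n_eff = int(eff.sum())
    if n_eff == 0:
        raise DegenerateLumenError("degenerate lumen: effective lumen is empty")
    n_bright = int(np.count_nonzero(cartesian_frame[eff] > params.bright_threshold))
    return 1.0 - n_bright / n_eff


def compute_flushing_capability_polar(
    polar_frame: np.ndarray,
    contour: LumenContour,
    meta: AcquisitionMeta,
    params: QualityParams | None = None,
    guidewire_mask: np.ndarray | None = None,
) -> float:
    """Polar-domain flushing capability with r-weighted pixel areas.

    Each polar pixel at depth index k weighs proportionally to its physical
    area (annular sector ~ its center radius). Agrees with the Cartesian
    statistic to within the resampling error.
    """
    params = params or QualityParams()
    d = meta.depth_centers_mm
    eff = (d[None, :] > meta.catheter_radius_mm) & (
        d[None, :] < contour.radius_mm[:, None]
    )
    if guidewire_mask is not None:
        eff &= ~guidewire_mask[:, None]
    w = np.broadcast_to(d, eff.shape)[eff]
    if w.size == 0:
        raise DegenerateLumenError("degenerate lumen: effective lumen is empty")
    bright = polar_frame[eff] > params.bright_threshold
    return 1.0 - float(np.sum(w[bright]) / np.sum(w))


def classify_clear_frame(
    contour: LumenContour | None,
    polar_frame: np.ndarray,
    meta: AcquisitionMeta,
    params: QualityParams | None = None,
) -> tuple[float, bool]:
    """Visible arc (degrees) and clear flag of one frame.

    An A-line is clear iff arterial structure is visualized — either the
    lumen boundary was confidently detected, or a bright reflection (wall
    or stent strut) is present within ``structure_band_mm`` of the contour
    — and the bright-pixel fraction between the catheter and the contour
    is at most ``aline_clear_blood_limit``. A-lines behind the guidewire
    show neither wall nor strut and fail the structure test. The visible
    arc is the longest circular run of clear A-lines; the frame is clear
    iff the arc strictly exceeds ``clear_arc_min_deg``.
    """
    params = params or QualityParams()
    if contour is None:
        return 0.0, False
    na = contour.n_alines
    d = meta.depth_centers_mm
    lumen = (d[None, :] > meta.catheter_radius_mm) & (
        d[None, :] < contour.radius_mm[:, None]
    )
    counts = lumen.sum(axis=1)
    bright = ((polar_frame > params.bright_threshold) & lumen).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(counts > 0, bright / np.maximum(counts, 1), 1.0)
    band = (d[None, :] >= contour.radius_mm[:, None] - params.structure_band_mm) & (
        d[None, :] <= contour.radius_mm[:, None] + params.structure_band_mm / 3.0
    )
    structure = np.where(band, polar_frame, 0.0).max(axis=1) >= params.aline_structure_min
    visible = structure | (contour.confidence >= params.aline_confidence_min)
    clear_aline = visible & (frac <= params.aline_clear_blood_limit)
    arc = longest_circular_run(clear_aline) * 360.0 / na
    return arc, bool(arc > params.clear_arc_min_deg)


def partition_segments(
    n_frames: int, frame_spacing_mm: float, params: QualityParams | None = None
) -> list[range]:
    """Consecutive non-overlapping longitudinal segments of frames.

    Each segment spans ``round(segment_length / frame_spacing)`` frames from
    frame 0; a trailing partial segment is dropped.
    """
    params = params or QualityParams()
    if frame_spacing_mm <= 0:
        raise ValueError("frame_spacing_mm must be positive")
    per = int(round(params.segment_length_mm / frame_spacing_mm))
    if per < 1 or n_frames < per:
        return []
    return [range(i, i + per) for i in range(0, n_frames - per + 1, per)]


def classify_cis(clear_flags, params: QualityParams | None = None) -> bool:
    """CIS iff the clear fraction of the segment is >= the CIS fraction (inclusive)."""
    params = params or QualityParams()
    flags = np.asarray(clear_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty segment")
    return bool(flags.mean() >= params.cis_clear_fraction)


def classify_clear_run(cis_flags, params: QualityParams | None = None) -> bool:
    """Clear run iff the CIS fraction of the pullback is >= the run fraction (inclusive)."""
    params = params or QualityParams()
    flags = np.asarray(cis_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no segments")
    return bool(flags.mean() >= params.clear_run_fraction)


def summarize_quality(
    flushing: np.ndarray,
    arcs: np.ndarray,
    clear: np.ndarray,
    frame_spacing_mm: float,
    params: QualityParams | None = None,
) -> QualityResult:
    """Assemble per-segment CIS flags and the pullback verdict from per-frame results."""
    params = params or QualityParams()
    flushing = np.asarray(flushing, dtype=float)
    segments = partition_segments(len(flushing), frame_spacing_mm, params)
    cis = np.array([classify_cis(clear[list(s)], params) for s in segments], dtype=bool)
    run = classify_clear_run(cis, params) if len(segments) else False
    q1, q3 = (
        (float(np.percentile(flushing, 25)), float(np.percentile(flushing, 75)))
        if flushing.size
        else (float("nan"), float("nan"))
    )
    return QualityResult(
        flushing=flushing,
        visible_arc_deg=np.asarray(arcs, dtype=float),
        clear=np.asarray(clear, dtype=bool),
        segments=segments,
        cis=cis,
        clear_run=run,
        flushing_median=float(np.median(flushing)) if flushing.size else float("nan"),
        flushing_iqr=(q1, q3),
        params=params,
    )


def quality_report(result: QualityResult, label: str = "") -> pd.DataFrame:
    """Long-format report: one row per frame, per segment, plus one pullback row."""
    rows = []
    for i, (fl, arc, cl) in enumerate(
        zip(result.flushing, result.visible_arc_deg, result.clear)
    ):
        rows.append(
            {
                "pullback": label,
                "level": "frame",
                "index": i,
                "flushing": fl,
                "visible_arc_deg": arc,
                "clear": bool(cl),
                "cis": None,
                "clear_run": None,
            }
        )
    for j, flag in enumerate(result.cis):
        rows.append(
            {
                "pullback": label,
                "level": "segment",
                "index": j,
                "flushing": None,
                "visible_arc_deg": None,
                "clear": None,
                "cis": bool(flag),
                "clear_run": None,
            }
        )
    rows.append(
        {
            "pullback": label,
            "level": "pullback",
            "index": 0,
            "flushing": result.flushing_median,
            "visible_arc_deg": None,
            "clear": None,
            "cis": int(result.cis.sum()) if result.cis.size else 0,
            "clear_run": bool(result.clear_run),
        }
    )
    return pd.DataFrame(rows)
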