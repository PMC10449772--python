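"""2D/3D morphometry: lumen/stent areas, MLA/MSA, segment volumes, and
refractive-index correction.

Areas come from the polar quadrature ``A = 1/2 * sum(r_i^2) * dtheta`` on
the per-A-line contour; segment volumes integrate per-frame areas with the
rectangle rule (``area * frame_spacing``) over the frames of each 1-mm
longitudinal segment, so segment volumes tile the pullback exactly.

When the flushing medium at acquisition differs from the refractive index
the console assumed, axial distances — and in this geometry the radial
coordinate is axial depth — are mis-scaled by ``n_actual / n_reference``.
The correction multiplies measurements by ``(n_reference / n_actual)**d``
with d = 1, 2, 3 for lengths, areas and volumes; with a lower-index medium
(pentastarch, n = 1.3433, against iodine contrast, n = 1.4421) this
increases the measurement, undoing the underestimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import polar_contour_area_mm2

__all__ = [
    "RefractiveCorrection",
    "MorphometryTable",
    "contour_area",
    "minimal_areas",
    "segment_volumes",
    "apply_refractive_correction",
    "build_morphometry_table",
    "PENTASTARCH_INDEX",
    "CONTRAST_INDEX",
]

# measured refractive indices of the two flushing media at the OCT wavelength
PENTASTARCH_INDEX = 1.3433
CONTRAST_INDEX = 1.4421

_DIM_POWER = {"linear": 1, "area": 2, "volume": 3}


@dataclass(frozen=True)
class RefractiveCorrection:
    """Correction factors from the index assumed at acquisition
    (``n_reference``) to the index of the medium actually used (``n_actual``)."""

    n_reference: float
    n_actual: float

    def __post_init__(self) -> None:
        if self.n_reference <= 0 or self.n_actual <= 0:
            raise ValueError("refractive indices must be positive")

    @property
    def linear_factor(self) -> float:
        return self.n_reference / self.n_actual

    @property
    def area_factor(self) -> float:
        return self.linear_factor**2

    @property
    def volume_factor(self) -> float:
        return self.linear_factor**3


def apply_refractive_correction(
    value, dimensionality: str, corr: RefractiveCorrection
):
    """Rescale a length/area/volume measurement for the true flushing medium."""
    try:
        d = _DIM_POWER[dimensionality]
    except KeyError:
        raise ValueError(
            f"unknown dimensionality {dimensionality!r}; expected one of {sorted(_DIM_POWER)}"
        ) from None
    return np.asarray(value, dtype=float) * corr.linear_factor**d if np.ndim(value) else (
        float(value) * corr.linear_factor**d
    )


def contour_area(contour) -> float:
    """Cross-sectional area (mm^2) enclosed by a per-A-line polar contour.

    Accepts a radius array or any object with a ``radius_mm`` attribute.
    """
    radii = getattr(contour, "radius_mm", contour)
    return polar_contour_area_mm2(np.asarray(radii, dtype=float))


def minimal_areas(
    areas: Sequence[float], frame_range: range | Sequence[int] | None = None
) -> tuple[float, int]:
    """Minimum area over the matched frame range and its frame index.

    Ties resolve to the first occurrence. Entries that are None/NaN (e.g.
    stentless frames) are skipped; if every entry in the range is absent a
    ``ValueError`` is raised — an undefined minimum is absent, not 0.
    """
    areas = np.array(
        [np.nan if a is None else float(a) for a in areas], dtype=float
    )
    idxs = np.asarray(list(frame_range), dtype=int) if frame_range is not None else np.arange(
        len(areas)
    )
    if idxs.size == 0:
        raise ValueError("empty frame range")
    vals = areas[idxs]
    if np.all(np.isnan(vals)):
        raise ValueError("no defined areas in the requested range")
    k = int(np.nanargmin(vals))
    return float(vals[k]), int(idxs[k])


def segment_volumes(
    areas: Sequence[float], segments: Sequence[range], frame_spacing_mm: float
) -> np.ndarray:
    """Per-segment volumes (mm^3): rectangle-rule sum of frame areas x spacing."""
    areas = np.asarray(areas, dtype=float)
    out = np.empty(len(segments))
    for i, seg in enumerate(segments):
        idx = np.asarray(list(seg), dtype=int)
        if idx.size == 0 or idx.max() >= len(areas):
            raise ValueError(f"segment {i} is inconsistent with the area list")
        out[i] = float(np.sum(areas[idx]) * frame_spacing_mm)
    return out


@dataclass
class MorphometryTable:
    """Per-frame areas and per-segment volumes with pullback summaries."""

    frame_table: pd.DataFrame  # frame, lumen_area_mm2, stent_area_mm2
    segment_table: pd.DataFrame  # segment, slv_mm3, ssv_mm3
    mla_mm2: float
    mla_frame: int
    msa_mm2: float | None
    msa_frame: int | None
    correction: RefractiveCorrection | None = None


def build_morphometry_table(
    lumen_areas: Sequence[float],
    stent_areas: Sequence[float | None],
    segments: Sequence[range],
    frame_spacing_mm: float,
    correction: RefractiveCorrection | None = None,
    frame_range: range | None = None,
) -> MorphometryTable:
    """Assemble the full 2D/3D morphometry table for one pullback.

    ``stent_areas`` holds None/NaN for stentless frames; SSV is reported
    only for segments whose every frame has a stent area. If ``correction``
    is given all areas and volumes are refractive-corrected.
    """
    lumen = np.asarray(lumen_areas, dtype=float)
    stent = np.array([np.nan if a is None else float(a) for a in stent_areas], dtype=float)
    if len(stent) != len(lumen):
        raise ValueError("lumen and stent area lists must share one length")
    if correction is not None:
        lumen = lumen * correction.area_factor
        stent = stent * correction.area_factor

    slv = segment_volumes(lumen, segments, frame_spacing_mm)
    ssv = np.full(len(segments), np.nan)
    for i, seg in enumerate(segments):
        vals = stent[np.asarray(list(seg), dtype=int)]
        if not np.any(np.isnan(vals)):
            ssv[i] = float(np.sum(vals) * frame_spacing_mm)

    mla, mla_frame = minimal_areas(lumen, frame_range)
    try:
        msa, msa_frame = minimal_areas(stent, frame_range)
    except ValueError:
        msa, msa_frame = None, None

    frame_table = pd.DataFrame(
        {
            "frame": np.arange(len(lumen)),
            "lumen_area_mm2": lumen,
            "stent_area_mm2": stent,
        }
    )
    segment_table = pd.DataFrame(
        {"segment": np.arange(len(segments)), "slv_mm3": slv, "ssv_mm3": ssv}
    )
    return MorphometryTable(
        frame_table=frame_table,
        segment_table=segment_table,
        mla_mm2=mla,
        mla_frame=mla_frame,
        msa_mm2=msa,
        msa_frame=msa_frame,
        correction=correction,
    )
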