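"""Shared geometry conventions and core containers for polar-domain OCT.

Conventions used throughout the package:

* A polar frame is a raster indexed ``[a_line, depth]``. A-line 0 points at
  angle 0 deg, angles increase counter-clockwise with uniform spacing
  ``360 / n_alines`` degrees.
* Depth pixel ``k`` spans ``[k, k+1) * axial_pitch`` measured from the
  catheter center; its center radius is ``(k + 0.5) * axial_pitch``.
* Angles are degrees in ``[0, 360)``, depths and radii are millimetres,
  intensities are normalized to ``[0, 1]``.
* Frames are 0-indexed along the pullback; frame ``i`` sits at longitudinal
  position ``i * frame_spacing`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "PolarPullback",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when acquisition or phantom geometry is inconsistent."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry of a polar OCT pullback.

    Defaults emulate a contemporary frequency-domain intravascular OCT
    console: 100 frames/s at a 20 mm/s pullback speed gives a frame spacing
    of 0.2 mm, a 54 mm pullback, and ~20 um axial resolution sampled at a
    5 um axial pixel pitch. The A-line count per frame and the exact pixel
    pitch are conventions of this package, not published console constants.

    Parameters
    ----------
    n_alines
        A-lines (angular samples) per frame.
    n_depth
        Depth samples per A-line.
    axial_pitch_um
        Axial pixel pitch in micrometres.
    frame_spacing_mm
        Longitudinal distance between consecutive frames in millimetres.
    pullback_length_mm
        Total pullback length in millimetres.
    catheter_radius_mm
        Radius of the imaging catheter sheath.
    refractive_index
        Refractive index of the flushing medium assumed by the console when
        converting optical path length to distance.
    """

    n_alines: int = 504
    n_depth: int = 600
    axial_pitch_um: float = 5.0
    frame_spacing_mm: float = 0.2
    pullback_length_mm: float = 54.0
    catheter_radius_mm: float = 0.4
    refractive_index: float = 1.4421

    def __post_init__(self) -> None:
        if self.n_alines < 8:
            raise GeometryError(f"n_alines must be >= 8, got {self.n_alines}")
        for name in (
            "n_depth",
            "axial_pitch_um",
            "frame_spacing_mm",
            "pullback_length_mm",
            "refractive_index",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.catheter_radius_mm < 0:
            raise GeometryError("catheter_radius_mm must be non-negative")

    # -- derived geometry ---------------------------------------------------

    @property
    def axial_pitch_mm(self) -> float:
        return self.axial_pitch_um * 1e-3

    @property
    def n_frames(self) -> int:
        """Number of frames covering the pullback length at the frame spacing."""
        n = int(np.floor(self.pullback_length_mm / self.frame_spacing_mm + 1e-9)) + 1
        # invariant: frame_spacing * (n_frames - 1) <= pullback_length
        return n

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_alines) * (360.0 / self.n_alines)

    @property
    def delta_theta_rad(self) -> float:
        return 2.0 * np.pi / self.n_alines

    @property
    def depth_centers_mm(self) -> np.ndarray:
        return (np.arange(self.n_depth) + 0.5) * self.axial_pitch_mm

    @property
    def max_radius_mm(self) -> float:
        return self.n_depth * self.axial_pitch_mm

    @property
    def catheter_depth_px(self) -> int:
        """Number of leading depth pixels fully or partly inside the catheter."""
        return int(np.ceil(self.catheter_radius_mm / self.axial_pitch_mm - 1e-9))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**d)


@dataclass
class PolarPullback:
    """Stack of polar frames plus acquisition metadata; the unit of analysis.

    ``frames`` has shape ``(n_frames, n_alines, n_depth)`` with intensities
    in ``[0, 1]``.
    """

    frames: np.ndarray
    meta: AcquisitionMeta
    seed: int | None = None
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise GeometryError("frames must be a 3-D stack (frame, a_line, depth)")
        if self.frames.shape[1] != self.meta.n_alines:
            raise GeometryError(
                f"frame rows ({self.frames.shape[1]}) != meta.n_alines ({self.meta.n_alines})"
            )
        if self.frames.shape[2] != self.meta.n_depth:
            raise GeometryError(
                f"frame cols ({self.frames.shape[2]}) != meta.n_depth ({self.meta.n_depth})"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [0, 360)."""
    return np.mod(angle, 360.0)


def angular_distance_deg(a, b):
    """Smallest absolute angular distance between two angles, in degrees."""
    d = np.abs(np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0)
    return d


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded as printed in summary tables (e.g. 74/81 -> 91.4)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    return round(100.0 * numerator / denominator, ndigits)


def ratio(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Plain rounded ratio (e.g. per-patient averages: 81/43 -> 1.88)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be nonzero")
    return round(numerator / denominator, ndigits)


def polar_contour_area_mm2(radii_mm: np.ndarray) -> float:
    """Area enclosed by a periodic polar contour sampled at uniform angles.

    Uses the polar quadrature ``A = 1/2 * sum(r_i^2) * dtheta``.
    """
    r = np.asarray(radii_mm, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("contour radii must be finite")
    dtheta = 2.0 * np.pi / r.size
    return float(0.5 * np.sum(r**2) * dtheta)
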