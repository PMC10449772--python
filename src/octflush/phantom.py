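"""Synthetic polar-domain OCT pullback generator with exhaustive ground truth.

The phantom emulates what the downstream pipeline needs to see in a
contrast- or starch-flushed intravascular pullback: a dark catheter core
with a bright sheath ring, a vessel wall entered through a sharp bright
edge followed by exponentially attenuating speckled tissue, optional stent
struts (bright blobs casting radial shadows), a guidewire shadow sector
with a superficial reflection, and residual-blood "bright debris" pixels
seeded inside the effective lumen at a known density.

Blood is rendered as independent Bernoulli bright pixels so that the
pixel-counting statistics downstream have an exact combinatorial oracle:
the generator records, per frame, exactly how many bright pixels it placed
and how many effective-lumen pixels exist.

The generator is deterministic given ``(spec, meta, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import AcquisitionMeta, GeometryError, PolarPullback, wrap_angle_deg

__all__ = [
    "LumenModel",
    "StentSpec",
    "GuidewireSpec",
    "PhantomSpec",
    "PairConfig",
    "GroundTruth",
    "generate_pullback",
    "generate_paired_pullbacks",
]

# intensity of a seeded residual-blood pixel; comfortably above any sane
# background threshold yet below strut peaks
BLOOD_BRIGHTNESS = 0.85
# reference threshold used when auditing bright-pixel conservation
REFERENCE_BRIGHT_THRESHOLD = 0.35


@dataclass(frozen=True)
class LumenModel:
    """Smooth periodic lumen radius model.

    The per-frame contour is an offset circle (radius tapering linearly
    along the pullback) modulated by a second-harmonic ovality term, which
    covers the realistic range of eccentric, slightly elliptic coronary
    cross sections:

    ``r(theta, z) = offset_circle(R(z), c, phi; theta) * (1 + ovality * cos(2*(theta - psi)))``

    with ``R(z) = base_radius + slope * z``.
    """

    base_radius_mm: float = 1.5
    slope_mm_per_mm: float = 0.0
    center_offset_mm: float = 0.0
    center_offset_deg: float = 0.0
    ovality: float = 0.0
    ovality_phase_deg: float = 0.0

    def radius(self, angles_deg: np.ndarray, z_mm: float) -> np.ndarray:
        """Lumen radius (mm) at the given angles for a frame at position z."""
        R = self.base_radius_mm + self.slope_mm_per_mm * z_mm
        c = self.center_offset_mm
        if c >= R:
            raise GeometryError("lumen center offset must be smaller than the radius")
        th = np.deg2rad(angles_deg - self.center_offset_deg)
        r = c * np.cos(th) + np.sqrt(R**2 - (c * np.sin(th)) ** 2)
        if self.ovality:
            ph = np.deg2rad(angles_deg - self.ovality_phase_deg)
            r = r * (1.0 + self.ovality * np.cos(2.0 * ph))
        return r

    def scaled(self, factor: float) -> "LumenModel":
        """Radially rescaled copy (all linear dimensions multiplied)."""
        return dataclasses.replace(
            self,
            base_radius_mm=self.base_radius_mm * factor,
            slope_mm_per_mm=self.slope_mm_per_mm * factor,
            center_offset_mm=self.center_offset_mm * factor,
        )


@dataclass(frozen=True)
class StentSpec:
    """Stent rendering: ``n_struts`` struts equally spaced in angle.

    Struts sit ``standoff_mm`` inside the lumen wall (apposed struts) and
    appear as bright Gaussian blobs with a multiplicative radial shadow —
    the bright-reflection-with-dark-tail signature the detector targets.
    """

    n_struts: int = 8
    start_angle_deg: float = 0.0
    standoff_mm: float = 0.03
    thickness_mm: float = 0.08
    brightness: float = 1.0
    sigma_alines: float = 1.2
    sigma_depth_px: float = 2.0
    shadow_attenuation: float = 0.1

    def angles_deg(self) -> np.ndarray:
        return wrap_angle_deg(
            self.start_angle_deg + np.arange(self.n_struts) * 360.0 / self.n_struts
        )


@dataclass(frozen=True)
class GuidewireSpec:
    """Guidewire artifact: a superficial bright reflection plus a shadow sector."""

    center_deg: float = 90.0
    width_deg: float = 30.0
    radius_mm: float = 0.55
    brightness: float = 0.9
    shadow_attenuation: float = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic pullback."""

    lumen: LumenModel = field(default_factory=LumenModel)
    stent: StentSpec | None = None
    guidewire: GuidewireSpec | None = None
    residual_blood_density: float = 0.0
    landmark_frames: tuple[int, ...] = ()
    landmark_angle_deg: float = 0.0
    landmark_width_deg: float = 45.0
    landmark_bulge: float = 0.30
    background_level: float = 0.03
    tissue_level: float = 0.70
    edge_level: float = 0.90
    edge_width_mm: float = 0.02
    attenuation_mm: float = 0.30
    speckle_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_blood_density <= 1.0:
            raise GeometryError("residual_blood_density must lie in [0, 1]")
        if self.stent is not None and self.stent.n_struts < 1:
            raise GeometryError("stent must have at least one strut")
        if self.guidewire is not None and not 0 < self.guidewire.width_deg < 360:
            raise GeometryError("guidewire width must lie in (0, 360) degrees")


@dataclass(frozen=True)
class PairConfig:
    """How the two members of a paired acquisition differ.

    ``index_a`` / ``index_b`` are the refractive indices of the flushing
    media of members A and B. The console converts optical path to distance
    assuming a single index, so member B's radial structure appears scaled
    by ``index_b / index_a`` relative to member A — the downstream
    refractive correction with ``(n_reference=index_a, n_actual=index_b)``
    recovers member A's geometry.

    ``frame_offset_b`` shifts member B longitudinally by whole frames to
    exercise landmark-based matching.
    """

    density_a: float = 0.0
    density_b: float = 0.0
    index_a: float = 1.4421
    index_b: float = 1.3433
    frame_offset_b: int = 0

    def __post_init__(self) -> None:
        if self.index_a <= 0 or self.index_b <= 0:
            raise GeometryError("refractive indices must be positive")


@dataclass
class GroundTruth:
    """Everything the generator rendered, for use as a test oracle."""

    radii_mm: np.ndarray  # (n_frames, n_alines) true lumen radius
    lumen_area_mm2: np.ndarray  # (n_frames,)
    strut_table: np.ndarray  # (n_struts_total, 4): frame, a_line, angle_deg, radius_mm
    bright_pixel_count: np.ndarray  # (n_frames,) seeded blood pixels in effective lumen
    effective_lumen_pixel_count: np.ndarray  # (n_frames,) polar pixels in effective lumen
    blood_density: float
    guidewire: GuidewireSpec | None
    landmark_frames: tuple[int, ...]
    seed: int
    blood_brightness: float = BLOOD_BRIGHTNESS

    def struts_for_frame(self, frame: int) -> np.ndarray:
        t = self.strut_table
        return t[t[:, 0] == frame] if t.size else t.reshape(0, 4)

    @property
    def bright_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.bright_pixel_count / self.effective_lumen_pixel_count


def _guidewire_aline_mask(meta: AcquisitionMeta, gw: GuidewireSpec) -> np.ndarray:
    from .core import angular_distance_deg

    return angular_distance_deg(meta.angles_deg, gw.center_deg) <= gw.width_deg / 2.0


def _frame_radii(spec: PhantomSpec, meta: AcquisitionMeta, frame: int, z_mm: float) -> np.ndarray:
    r = spec.lumen.radius(meta.angles_deg, z_mm)
    if frame in spec.landmark_frames:
        from .core import angular_distance_deg

        sector = (
            angular_distance_deg(meta.angles_deg, spec.landmark_angle_deg)
            <= spec.landmark_width_deg / 2.0
        )
        r = np.where(sector, r * (1.0 + spec.landmark_bulge), r)
    return r


def generate_pullback(
    spec: PhantomSpec,
    meta: AcquisitionMeta | None = None,
    *,
    n_frames: int | None = None,
) -> tuple[PolarPullback, GroundTruth]:
    """Render a synthetic pullback and record its ground truth.

    Parameters
    ----------
    spec
        Phantom content description (lumen model, stent, guidewire, blood).
    meta
        Acquisition geometry; defaults to :class:`AcquisitionMeta` defaults.
    n_frames
        Number of frames to render; defaults to ``meta.n_frames`` (the full
        pullback length). Smaller values render a leading sub-pullback.

    Returns
    -------
    (PolarPullback, GroundTruth)

    Raises
    ------
    GeometryError
        If the lumen dips inside the catheter sheath anywhere.
    """
    meta = meta or AcquisitionMeta()
    nf = meta.n_frames if n_frames is None else int(n_frames)
    if nf < 1:
        raise GeometryError("need at least one frame")

    rng = np.random.default_rng(spec.seed)
    na, nd = meta.n_alines, meta.n_depth
    d = meta.depth_centers_mm  # (nd,)
    pitch = meta.axial_pitch_mm
    cr = meta.catheter_radius_mm

    gw_mask = (
        _guidewire_aline_mask(meta, spec.guidewire) if spec.guidewire is not None else None
    )

    frames = np.empty((nf, na, nd), dtype=np.float64)
    radii_all = np.empty((nf, na), dtype=np.float64)
    areas = np.empty(nf)
    bright_counts = np.zeros(nf, dtype=np.int64)
    eff_counts = np.zeros(nf, dtype=np.int64)
    strut_rows: list[tuple[float, float, float, float]] = []

    for f in range(nf):
        z = f * meta.frame_spacing_mm
        r = _frame_radii(spec, meta, f, z)  # (na,)
        if np.any(r <= cr):
            raise GeometryError(
                f"lumen radius dips inside the catheter sheath at frame {f}"
            )
        if np.any(r >= meta.max_radius_mm):
            raise GeometryError(
                f"lumen radius exceeds the imaged depth at frame {f}"
            )
        radii_all[f] = r
        areas[f] = 0.5 * np.sum(r**2) * meta.delta_theta_rad

        depth_from_wall = d[None, :] - r[:, None]  # (na, nd)

        # deterministic structure: tissue + bright entry edge + sheath ring
        structure = np.zeros((na, nd))
        tissue = depth_from_wall >= 0
        structure[tissue] = spec.tissue_level * np.exp(
            -depth_from_wall[tissue] / spec.attenuation_mm
        )
        edge = tissue & (depth_from_wall < spec.edge_width_mm)
        structure[edge] = spec.edge_level
        if cr > 0:
            sheath = (d > cr - 0.04) & (d <= cr)
            structure[:, sheath] = np.maximum(structure[:, sheath], 0.65)

        speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=(na, nd))
        floor = spec.background_level * rng.gamma(3.0, 1.0 / 3.0, size=(na, nd))
        img = structure * speckle + floor

        # stent struts: bright blob + multiplicative radial shadow
        strut_alines = np.zeros(na, dtype=bool)
        if spec.stent is not None:
            st = spec.stent
            aline_axis = np.arange(na)
            for ang in st.angles_deg():
                if spec.guidewire is not None:
                    from .core import angular_distance_deg

                    # a strut hidden behind the guidewire shadow is not
                    # rendered and not part of the ground truth
                    margin = 2 * 360.0 / na
                    if angular_distance_deg(ang, spec.guidewire.center_deg) <= (
                        spec.guidewire.width_deg / 2.0 + margin
                    ):
                        continue
                a_idx = ang / 360.0 * na
                r_strut = float(np.interp(ang, meta.angles_deg, r, period=360.0)) - st.standoff_mm
                d_idx = r_strut / pitch - 0.5
                da = np.minimum(np.abs(aline_axis - a_idx), na - np.abs(aline_axis - a_idx))
                dd = np.arange(nd) - d_idx
                blob = st.brightness * np.exp(
                    -(da[:, None] ** 2) / (2 * st.sigma_alines**2)
                    - (dd[None, :] ** 2) / (2 * st.sigma_depth_px**2)
                )
                # shadow in the A-lines the strut occludes, deeper than the strut
                occluded = da <= max(1.0, st.sigma_alines)
                deeper = d > r_strut + st.thickness_mm / 2.0
                img[np.ix_(occluded, deeper)] *= st.shadow_attenuation
                img += blob
                strut_alines |= da <= 2
                strut_rows.append((f, int(round(a_idx)) % na, ang, r_strut))

        # guidewire: superficial reflection, everything deeper shadowed
        if spec.guidewire is not None:
            gw = spec.guidewire
            deeper = d > gw.radius_mm + 0.02
            img[np.ix_(gw_mask, deeper)] *= gw.shadow_attenuation
            refl = np.abs(d - gw.radius_mm) <= 0.02
            img[np.ix_(gw_mask, refl)] = gw.brightness

        # catheter interior is optically dark
        img[:, d <= cr - 0.04] = 0.01

        np.clip(img, 0.0, 1.0, out=img)

        # residual blood: Bernoulli bright pixels in the effective lumen.
        # Strut A-lines are excluded from the bookkeeping region — strut
        # reflections are bright in-lumen structure, and keeping them out
        # makes the recorded counts an exact above-threshold census.
        eff = (d[None, :] > cr) & (depth_from_wall < 0)
        if gw_mask is not None:
            eff &= ~gw_mask[:, None]
        eff &= ~strut_alines[:, None]
        eff_counts[f] = int(eff.sum())
        if spec.residual_blood_density > 0:
            blood = eff & (rng.random((na, nd)) < spec.residual_blood_density)
            img[blood] = BLOOD_BRIGHTNESS
            bright_counts[f] = int(blood.sum())

        frames[f] = img

    gt = GroundTruth(
        radii_mm=radii_all,
        lumen_area_mm2=areas,
        strut_table=np.array(strut_rows, dtype=float).reshape(-1, 4),
        bright_pixel_count=bright_counts,
        effective_lumen_pixel_count=eff_counts,
        blood_density=spec.residual_blood_density,
        guidewire=spec.guidewire,
        landmark_frames=spec.landmark_frames,
        seed=spec.seed,
    )
    pb = PolarPullback(frames=frames, meta=meta, seed=spec.seed)
    return pb, gt


def generate_paired_pullbacks(
    spec: PhantomSpec,
    pair_cfg: PairConfig,
    meta: AcquisitionMeta | None = None,
    *,
    n_frames: int | None = None,
) -> tuple[PolarPullback, GroundTruth, PolarPullback, GroundTruth]:
    """Render two pullbacks of the same vessel under two flushing media.

    Member A uses ``density_a`` and is the reference geometry. Member B
    shares the vessel but its radial structure is scaled by
    ``index_b / index_a`` (acquisition under a medium of different
    refractive index while the console assumes member A's), carries its own
    blood density, and may be shifted longitudinally by
    ``frame_offset_b`` frames. Both members share the same noise seed, so
    with equal indices, densities and zero offset the stacks are identical.
    """
    meta = meta or AcquisitionMeta()
    scale = pair_cfg.index_b / pair_cfg.index_a

    spec_a = dataclasses.replace(spec, residual_blood_density=pair_cfg.density_a)
    pb_a, gt_a = generate_pullback(spec_a, meta, n_frames=n_frames)

    off = pair_cfg.frame_offset_b
    gw_b = spec.guidewire
    if gw_b is not None:
        gw_b = dataclasses.replace(gw_b, radius_mm=gw_b.radius_mm * scale)
    stent_b = spec.stent
    if stent_b is not None:
        stent_b = dataclasses.replace(stent_b, standoff_mm=stent_b.standoff_mm * scale)
    spec_b = dataclasses.replace(
        spec,
        lumen=spec.lumen.scaled(scale),
        stent=stent_b,
        guidewire=gw_b,
        residual_blood_density=pair_cfg.density_b,
        landmark_frames=tuple(lf + off for lf in spec.landmark_frames),
    )
    # member B's frame f images position (f - off) * spacing of the vessel
    nf = meta.n_frames if n_frames is None else int(n_frames)
    pb_b, gt_b = _generate_shifted(spec_b, meta, nf, off)
    pb_b.label, pb_a.label = "member_b", "member_a"
    return pb_a, gt_a, pb_b, gt_b


def _generate_shifted(
    spec: PhantomSpec, meta: AcquisitionMeta, nf: int, offset: int
) -> tuple[PolarPullback, GroundTruth]:
    if offset == 0:
        return generate_pullback(spec, meta, n_frames=nf)
    # render a longer pullback starting 'offset' frames earlier in z by
    # shifting the landmark frames and evaluating the lumen at z - offset*dz
    shifted_lumen = dataclasses.replace(
        spec.lumen,
        base_radius_mm=spec.lumen.base_radius_mm
        - spec.lumen.slope_mm_per_mm * offset * meta.frame_spacing_mm,
    )
    spec_shift = dataclasses.replace(spec, lumen=shifted_lumen)
    return generate_pullback(spec_shift, meta, n_frames=nf)
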