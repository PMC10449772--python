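"""End-to-end paired comparison on a phantom pullback pair.

``run_pipeline`` generates (or loads) the two members of a paired
acquisition, segments every frame, computes the quality and morphometry
layers on both, aligns the members by landmark frames, applies the
refractive correction to member B, and emits the agreement statistics —
the same segment-to-report chain a paired clinical comparison uses, with
the phantom standing in for the pullbacks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .core import AcquisitionMeta, PolarPullback
from .morphometry import (
    MorphometryTable,
    RefractiveCorrection,
    build_morphometry_table,
    contour_area,
)
from .paired_stats import AgreementReport, agreement_report, match_pullbacks
from .phantom import GroundTruth, PairConfig, PhantomSpec, generate_paired_pullbacks
from .quality import (
    QualityParams,
    QualityResult,
    classify_clear_frame,
    compute_flushing_capability,
    partition_segments,
    quality_report,
    summarize_quality,
)
from .segmentation import (
    FrameSegmentation,
    SegmentationParams,
    build_frame_masks,
    scan_convert_frame,
    segment_frame,
)

__all__ = [
    "PipelineConfig",
    "PullbackAnalysis",
    "PairedRunResult",
    "analyze_pullback",
    "run_pipeline",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and frame index."""

    def __init__(self, stage: str, frame: int | None, cause: Exception):
        super().__init__(f"stage {stage!r} failed at frame {frame}: {cause}")
        self.stage = stage
        self.frame = frame
        self.cause = cause


@dataclass
class PipelineConfig:
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    pair: PairConfig = field(default_factory=PairConfig)
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    quality_params: QualityParams = field(default_factory=QualityParams)
    n_frames: int | None = None
    correct_b: bool = True
    seed: int = 0
    out_dir: str | None = None


@dataclass
class PullbackAnalysis:
    """All per-frame products of one pullback."""

    segmentations: list[FrameSegmentation]
    lumen_areas_mm2: np.ndarray
    stent_areas_mm2: np.ndarray  # NaN where no stent contour
    quality: QualityResult
    morphometry: MorphometryTable


def analyze_pullback(
    pb: PolarPullback,
    seg_params: SegmentationParams | None = None,
    quality_params: QualityParams | None = None,
    detect_stent: bool = True,
    correction: RefractiveCorrection | None = None,
) -> PullbackAnalysis:
    """Segment every frame and compute quality + morphometry for one pullback."""
    seg_params = seg_params or SegmentationParams()
    quality_params = quality_params or QualityParams()
    meta = pb.meta
    segs: list[FrameSegmentation] = []
    lumen_areas = np.empty(pb.n_frames)
    stent_areas = np.full(pb.n_frames, np.nan)
    flushing = np.empty(pb.n_frames)
    arcs = np.empty(pb.n_frames)
    clear = np.empty(pb.n_frames, dtype=bool)

    for f in range(pb.n_frames):
        frame = pb.frames[f]
        try:
            seg = segment_frame(frame, meta, seg_params, detect_stent=detect_stent)
        except Exception as exc:  # segmentation contract violations abort the stage
            raise StageError("segmentation", f, exc) from exc
        segs.append(seg)
        lumen_areas[f] = contour_area(seg.contour)
        if seg.stent_contour is not None:
            stent_areas[f] = seg.stent_contour.area_mm2()
        try:
            cart = scan_convert_frame(frame, meta, seg_params.cartesian_pixel_mm)
            masks = build_frame_masks(
                seg.contour, meta, seg_params.cartesian_pixel_mm, guidewire=seg.guidewire
            )
            flushing[f] = compute_flushing_capability(cart, masks, quality_params)
        except Exception as exc:
            raise StageError("quality", f, exc) from exc
        arcs[f], clear[f] = classify_clear_frame(seg.contour, frame, meta, quality_params)

    quality = summarize_quality(flushing, arcs, clear, meta.frame_spacing_mm, quality_params)
    morph = build_morphometry_table(
        lumen_areas,
        stent_areas,
        quality.segments,
        meta.frame_spacing_mm,
        correction=correction,
    )
    return PullbackAnalysis(
        segmentations=segs,
        lumen_areas_mm2=lumen_areas,
        stent_areas_mm2=stent_areas,
        quality=quality,
        morphometry=morph,
    )


@dataclass
class PairedRunResult:
    analysis_a: PullbackAnalysis
    analysis_b: PullbackAnalysis
    ground_truth_a: GroundTruth
    ground_truth_b: GroundTruth
    matched_frames_a: range
    matched_frames_b: range
    area_agreement: AgreementReport
    slv_agreement: AgreementReport | None
    agreement_table: pd.DataFrame
    manifest: dict


def _corrected_areas(analysis: PullbackAnalysis, corr: RefractiveCorrection | None):
    areas = analysis.lumen_areas_mm2
    return areas * corr.area_factor if corr is not None else areas


def run_pipeline(config: PipelineConfig) -> PairedRunResult:
    """Execute the full paired phantom comparison.

    All randomness flows from ``config.seed``; re-running an identical
    config reproduces identical outputs (and identical CSV bytes when
    ``out_dir`` is set).
    """
    spec = dataclasses.replace(config.spec, seed=config.seed)
    pb_a, gt_a, pb_b, gt_b = generate_paired_pullbacks(
        spec, config.pair, config.meta, n_frames=config.n_frames
    )
    detect_stent = spec.stent is not None
    corr = None
    if config.correct_b and config.pair.index_a != config.pair.index_b:
        corr = RefractiveCorrection(
            n_reference=config.pair.index_a, n_actual=config.pair.index_b
        )

    an_a = analyze_pullback(
        pb_a, config.seg_params, config.quality_params, detect_stent=detect_stent
    )
    an_b = analyze_pullback(
        pb_b,
        config.seg_params,
        config.quality_params,
        detect_stent=detect_stent,
        correction=corr,
    )

    # landmark alignment; with no landmarks the members are taken in register
    if gt_a.landmark_frames:
        match = match_pullbacks(
            gt_a.landmark_frames, gt_b.landmark_frames, pb_a.n_frames, pb_b.n_frames
        )
        fr_a, fr_b = match.frames_a, match.frames_b
    else:
        n = min(pb_a.n_frames, pb_b.n_frames)
        fr_a, fr_b = range(n), range(n)

    areas_a = an_a.lumen_areas_mm2[list(fr_a)]
    areas_b = _corrected_areas(an_b, corr)[list(fr_b)]
    area_rep = agreement_report(areas_a, areas_b, label="lumen_area_mm2")

    # per-segment lumen volumes over the matched range
    segs = partition_segments(
        len(areas_a), config.meta.frame_spacing_mm, config.quality_params
    )
    slv_rep = None
    if segs:
        from .morphometry import segment_volumes

        slv_a = segment_volumes(areas_a, segs, config.meta.frame_spacing_mm)
        slv_b = segment_volumes(areas_b, segs, config.meta.frame_spacing_mm)
        if len(segs) >= 3:
            slv_rep = agreement_report(slv_a, slv_b, label="slv_mm3")

    rows = []
    for rep in filter(None, [area_rep, slv_rep]):
        rows.append(
            {
                "endpoint": rep.label,
                "n": rep.n,
                "mean_a": rep.mean_a,
                "sd_a": rep.sd_a,
                "mean_b": rep.mean_b,
                "sd_b": rep.sd_b,
                "mean_difference": rep.paired.mean_difference,
                "t_pvalue": rep.paired.t_pvalue,
                "wilcoxon_pvalue": rep.paired.wilcoxon_pvalue,
                "r": rep.r,
                "r2": rep.r2,
                "icc": rep.icc.icc,
                "icc_ci_lower": rep.icc.ci_lower,
                "icc_ci_upper": rep.icc.ci_upper,
                "ba_bias": rep.bland_altman.bias,
                "ba_loa_lower": rep.bland_altman.loa_lower,
                "ba_loa_upper": rep.bland_altman.loa_upper,
            }
        )
    rows.append(
        {
            "endpoint": "flushing_median",
            "n": len(fr_a),
            "mean_a": an_a.quality.flushing_median,
            "mean_b": an_b.quality.flushing_median,
        }
    )
    table = pd.DataFrame(rows)

    manifest = {
        "seed": config.seed,
        "n_frames": pb_a.n_frames,
        "matched_frames": len(fr_a),
        "n_segments": len(segs),
        "correction": dataclasses.asdict(corr) if corr else None,
        "row_counts": {"agreement": len(table)},
        "outputs": {},
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, an in (("member_a", an_a), ("member_b", an_b)):
            an.morphometry.frame_table.to_csv(out / f"{name}_frames.csv", index=False)
            an.morphometry.segment_table.to_csv(out / f"{name}_segments.csv", index=False)
            quality_report(an.quality, label=name).to_csv(
                out / f"{name}_quality.csv", index=False
            )
        table.to_csv(out / "agreement.csv", index=False)
        for f in sorted(out.glob("*.csv")):
            manifest["outputs"][f.name] = _io.file_sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PairedRunResult(
        analysis_a=an_a,
        analysis_b=an_b,
        ground_truth_a=gt_a,
        ground_truth_b=gt_b,
        matched_frames_a=fr_a,
        matched_frames_b=fr_b,
        area_agreement=area_rep,
        slv_agreement=slv_rep,
        agreement_table=table,
        manifest=manifest,
    )
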