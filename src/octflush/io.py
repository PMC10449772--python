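"""Reading and writing pullbacks and analysis products.

The canonical interchange format is a multi-page grayscale TIFF stack
(8- or 16-bit, one page per frame, rows = A-lines, columns = depth)
plus a JSON sidecar carrying the acquisition metadata, the seed, and an
echo of the generating spec. Intensities are normalized to [0, 1] on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionMeta, PolarPullback
from .phantom import GroundTruth

__all__ = [
    "write_pullback",
    "read_pullback",
    "write_ground_truth",
    "read_ground_truth",
    "file_sha256",
]

SIDECAR_NAME = "pullback.json"
STACK_NAME = "pullback.tif"


def write_pullback(pb: PolarPullback, out_dir: str | Path, bit_depth: int = 16) -> Path:
    """Write a pullback as TIFF stack + JSON sidecar; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bit_depth == 16:
        data = np.round(np.clip(pb.frames, 0, 1) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(np.clip(pb.frames, 0, 1) * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(out / STACK_NAME, data, photometric="minisblack")
    sidecar = {
        "meta": pb.meta.to_dict(),
        "seed": pb.seed,
        "label": pb.label,
        "bit_depth": bit_depth,
        "n_frames": pb.n_frames,
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return out


def read_pullback(path: str | Path) -> tuple[PolarPullback, AcquisitionMeta]:
    """Read a TIFF+sidecar pullback directory; intensities normalized to [0, 1].

    Raises ``FileNotFoundError`` for a missing sidecar and ``ValueError``
    when the stack shape contradicts the sidecar.
    """
    p = Path(path)
    stack_path = p / STACK_NAME if p.is_dir() else p
    sidecar_path = stack_path.with_name(SIDECAR_NAME)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    meta = AcquisitionMeta.from_dict(sidecar["meta"])
    data = tifffile.imread(stack_path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[1] != meta.n_alines or data.shape[2] != meta.n_depth:
        raise ValueError(
            f"stack shape {data.shape[1:]} contradicts sidecar "
            f"({meta.n_alines}, {meta.n_depth})"
        )
    if sidecar.get("n_frames") is not None and data.shape[0] != sidecar["n_frames"]:
        raise ValueError("frame count contradicts sidecar")
    scale = float(np.iinfo(data.dtype).max) if data.dtype.kind == "u" else 1.0
    frames = data.astype(np.float64) / scale
    pb = PolarPullback(
        frames=frames, meta=meta, seed=sidecar.get("seed"), label=sidecar.get("label", "")
    )
    return pb, meta


def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> Path:
    """Write phantom ground truth as JSON + per-frame CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "blood_density": gt.blood_density,
        "blood_brightness": gt.blood_brightness,
        "seed": gt.seed,
        "landmark_frames": list(gt.landmark_frames),
        "guidewire": dataclasses.asdict(gt.guidewire) if gt.guidewire else None,
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    pd.DataFrame(
        {
            "frame": np.arange(len(gt.lumen_area_mm2)),
            "lumen_area_mm2": gt.lumen_area_mm2,
            "bright_pixel_count": gt.bright_pixel_count,
            "effective_lumen_pixel_count": gt.effective_lumen_pixel_count,
        }
    ).to_csv(out / "ground_truth_frames.csv", index=False)
    pd.DataFrame(
        gt.strut_table, columns=["frame", "a_line", "angle_deg", "radius_mm"]
    ).to_csv(out / "ground_truth_struts.csv", index=False)
    pd.DataFrame(gt.radii_mm).to_csv(out / "ground_truth_radii.csv", index=False)
    return out


def read_ground_truth(path: str | Path) -> GroundTruth:
    p = Path(path)
    payload = json.loads((p / "ground_truth.json").read_text())
    frames = pd.read_csv(p / "ground_truth_frames.csv")
    struts = pd.read_csv(p / "ground_truth_struts.csv")
    radii = pd.read_csv(p / "ground_truth_radii.csv").to_numpy(dtype=float)
    from .phantom import GuidewireSpec

    gw = GuidewireSpec(**payload["guidewire"]) if payload["guidewire"] else None
    return GroundTruth(
        radii_mm=radii,
        lumen_area_mm2=frames["lumen_area_mm2"].to_numpy(),
        strut_table=struts.to_numpy(dtype=float).reshape(-1, 4),
        bright_pixel_count=frames["bright_pixel_count"].to_numpy(dtype=np.int64),
        effective_lumen_pixel_count=frames["effective_lumen_pixel_count"].to_numpy(
            dtype=np.int64
        ),
        blood_density=payload["blood_density"],
        guidewire=gw,
        landmark_frames=tuple(payload["landmark_frames"]),
        seed=payload["seed"],
        blood_brightness=payload.get("blood_brightness", 0.85),
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
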