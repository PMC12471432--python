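"""Reading and writing of acquisition stacks, images and sidecar metadata.

Stacks travel as 32-bit float multi-page TIFF (9 pages, orientation-major
page order) with a YAML sidecar carrying pixel size, fringe parameters,
background level and the noise record, so a stack can be reloaded without the
Python objects that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .reconstruct import SRImage
from .simulate import AcquisitionStack, IlluminationConfig, NoiseModel

__all__ = [
    "save_stack",
    "load_stack",
    "save_image",
    "load_image",
    "save_provenance",
]


def _meta_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".yaml")


def save_stack(stack: AcquisitionStack, tif_path: str | Path,
               meta_path: str | Path | None = None) -> tuple[Path, Path]:
    """Write the raw frames as multi-page float32 TIFF plus a YAML sidecar."""
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else _meta_path(tif_path)
    n_theta = stack.frames.shape[0]
    pages = stack.frames.reshape(n_theta * 3, *stack.shape).astype(np.float32)
    tifffile.imwrite(tif_path, pages)
    cfg = stack.illumination
    meta = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "page_order": "orientation_major",
        "n_orientations": n_theta,
        "n_phases": 3,
        "illumination": {
            "i0": float(cfg.i0),
            "m": float(cfg.m),
            "k0_cycles_per_px": float(cfg.k0_cycles_per_px),
            "thetas_deg": [float(t) for t in cfg.thetas_deg],
            "phi0_rad": float(cfg.phi0_rad),
            "dphi_rad": float(cfg.dphi_rad),
        },
        "b_out": (stack.b_out.tolist() if isinstance(stack.b_out, np.ndarray)
                  else float(stack.b_out)),
        "noise": {
            "model": stack.noise.model,
            "params": {k: float(v) for k, v in stack.noise.params.items()},
            "seed": stack.noise.seed,
        },
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    # widefield reference saved alongside for evaluation workflows
    tifffile.imwrite(tif_path.with_name(tif_path.stem + "_widefield.tif"),
                     stack.widefield.astype(np.float32))
    return tif_path, meta_path


def load_stack(tif_path: str | Path,
               meta_path: str | Path | None = None) -> AcquisitionStack:
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else _meta_path(tif_path)
    pages = tifffile.imread(tif_path).astype(float)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    n_theta = int(meta["n_orientations"])
    frames = pages.reshape(n_theta, 3, *pages.shape[-2:])
    ill = meta["illumination"]
    cfg = IlluminationConfig(
        k0_cycles_per_px=ill["k0_cycles_per_px"], i0=ill["i0"], m=ill["m"],
        thetas_deg=ill["thetas_deg"], phi0_rad=ill["phi0_rad"],
        dphi_rad=ill["dphi_rad"],
    )
    noise = NoiseModel(meta["noise"]["model"], meta["noise"]["params"],
                       meta["noise"]["seed"])
    b_out = meta["b_out"]
    if isinstance(b_out, list):
        b_out = np.asarray(b_out, dtype=float)
    wf_path = tif_path.with_name(tif_path.stem + "_widefield.tif")
    widefield = (tifffile.imread(wf_path).astype(float) if wf_path.exists()
                 else frames.mean(axis=(0, 1)))
    return AcquisitionStack(frames, widefield, b_out, noise, cfg,
                            meta["pixel_size_nm"])


def save_image(path: str | Path, image: np.ndarray) -> Path:
    """Write a single image: float32 TIFF for .tif/.tiff, 8-bit otherwise."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        scaled = np.clip(image, 0.0, 1.0) if image.dtype.kind == "f" else image
        if scaled.dtype.kind == "f":
            scaled = (scaled * 255).round().astype(np.uint8)
        iio.imwrite(path, scaled)
    return path


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(float)
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def save_provenance(path: str | Path, sr: SRImage, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = {"pixel_size_nm": sr.pixel_size_nm, **sr.provenance, **(extra or {})}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return path
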