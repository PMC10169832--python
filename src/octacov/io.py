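"""File I/O for frame sequences, masks and ground truth.

Frame dialects: multi-page TIFF stacks, per-frame PNG series, or
headerless raw float32 with a JSON sidecar declaring ``height``,
``width``, ``n_frames``, ``dtype`` and ``byte_order`` (the vendor raw
export layout is undocumented, so the reader refuses to guess).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from skimage import io as skio

__all__ = [
    "read_frames",
    "write_frames_tiff",
    "write_float_tiff",
    "write_label_tiff",
    "save_phantom",
]


def read_frames(source, dialect: str = "tiff", sidecar=None) -> np.ndarray:
    """Read a (T, H, W) frame stack.

    ``dialect``: ``"tiff"`` (multi-page stack), ``"png"`` (directory of
    per-frame images, sorted by name), or ``"raw"`` (headerless binary
    with a mandatory JSON ``sidecar``).
    """
    source = Path(source)
    if dialect == "tiff":
        arr = tifffile.imread(str(source))
        if arr.ndim == 2:
            arr = arr[None]
        return arr.astype(np.float64)
    if dialect == "png":
        files = sorted(p for p in source.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG frames in {source}")
        return np.stack([skio.imread(str(p)).astype(np.float64) for p in files])
    if dialect == "raw":
        if sidecar is None:
            raise ValueError("raw dialect requires a JSON sidecar path")
        with open(sidecar) as fh:
            meta = json.load(fh)
        dtype = np.dtype(meta.get("dtype", "float32")).newbyteorder(
            "<" if meta.get("byte_order", "little") == "little" else ">"
        )
        t, h, w = int(meta["n_frames"]), int(meta["height"]), int(meta["width"])
        data = np.fromfile(source, dtype=dtype)
        if data.size != t * h * w:
            raise ValueError(
                f"raw file holds {data.size} values, sidecar declares {t * h * w}"
            )
        return data.reshape(t, h, w).astype(np.float64)
    raise ValueError(f"unknown frame dialect {dialect!r}")


def write_frames_tiff(path, frames: np.ndarray):
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def write_float_tiff(path, image: np.ndarray):
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_label_tiff(path, labels: np.ndarray):
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds 16-bit range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def save_phantom(phantom, seq, out_dir, true_cov=None):
    """Write a phantom's frames and ground truth under ``out_dir``.

    Produces ``frames.tif`` (float32 stack), ``vessel_labels.tif`` and
    ``roi_labels.tif`` (uint16) with a JSON manifest mapping ids to names,
    plus ``centreline_truth.tif`` and optional ``true_cov.tif``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_frames_tiff(out / "frames.tif", seq.frames)
    write_label_tiff(out / "vessel_labels.tif", phantom.vessel_label_map)
    write_label_tiff(out / "centreline_truth.tif", phantom.centreline_truth)
    if true_cov is not None:
        write_float_tiff(out / "true_cov.tif", true_cov)

    roi = phantom.roi_truth
    roi_labels = np.zeros(phantom.image_shape, np.uint16)
    label_names = {}
    # primary masks only (vessels + FAZ + F-cp): influence zones and
    # quadrants are recomputed from them on load
    next_lab = 1
    for name in sorted(roi.masks):
        if name.endswith("-net") or name.startswith("Q") or name == "F-net":
            continue
        roi_labels[roi.masks[name]] = next_lab
        label_names[str(next_lab)] = name
        next_lab += 1
    roi_labels[roi.faz_mask] = next_lab
    label_names[str(next_lab)] = "FAZ"
    write_label_tiff(out / "roi_labels.tif", roi_labels)
    manifest = {
        "labels": label_names,
        "foveola_centre": [float(c) for c in phantom.fovea_centre],
        "faz_radius": phantom.faz_radius,
        "px_per_mm": phantom.px_per_mm,
        "vessel_classes": {str(k): v for k, v in phantom.vessel_class_map.items()},
    }
    with open(out / "roi_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
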