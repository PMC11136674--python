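"""Serialisation of rendered products.

Band images can be exported either as 8-bit PNGs (exposure scaling to a
white-point flux followed by gamma encoding -- a documented, lossy
quantisation) or as a lossless band-stacked float32 raster with a JSON
sidecar header recording band labels, shape and units, suitable for
hyperspectral cubes.  Label maps export bounding boxes in the normalised
YOLO text format.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np


def write_band_image(raster: np.ndarray, path, mode: str = "png8",
                     white_point: float | None = None, gamma: float = 2.2,
                     band_labels=None, units: str = "W m^-2") -> Path:
    """Write a single- or multi-band raster.

    ``png8``: clip to ``white_point`` (default: raster max), apply
    ``1/gamma`` encoding, quantise to 8 bits.  Multi-band rasters of 3
    bands become RGB PNGs.  ``float_raster``: lossless, see
    :func:`write_float_raster`.
    """
    raster = np.asarray(raster, dtype=float)
    if not np.all(np.isfinite(raster)):
        raise ValueError("raster contains non-finite values")
    path = Path(path)
    if mode == "png8":
        wp = white_point if white_point else float(raster.max()) or 1.0
        scaled = np.clip(raster / wp, 0.0, 1.0) ** (1.0 / gamma)
        img = np.round(scaled * 255.0).astype(np.uint8)
        if img.ndim == 3 and img.shape[0] in (1, 3):    # (B,H,W) -> (H,W,B)
            img = np.moveaxis(img, 0, -1).squeeze()
        iio.imwrite(path, img)
        return path
    if mode == "float_raster":
        stack = raster[None] if raster.ndim == 2 else raster
        return write_float_raster(stack, path, band_labels=band_labels,
                                  units=units)
    raise ValueError(f"unknown image mode {mode!r}")


def write_float_raster(stack: np.ndarray, path, band_labels=None,
                       units: str = "W m^-2") -> Path:
    """Band-stacked float32 raster (band-sequential, C order) + JSON header.

    The header lives next to the data file with suffix ``.hdr.json``.
    Round trips bit-exactly through :func:`read_float_raster`.
    """
    stack = np.ascontiguousarray(np.asarray(stack, dtype=np.float32))
    if stack.ndim != 3:
        raise ValueError("stack must be (bands, height, width)")
    path = Path(path)
    b, h, w = stack.shape
    labels = list(band_labels) if band_labels else [f"band{i}" for i in range(b)]
    if len(labels) != b:
        raise ValueError("band label count mismatch")
    header = {"bands": labels, "height": h, "width": w,
              "dtype": "float32", "byteorder": "little",
              "interleave": "bsq", "units": units}
    path.write_bytes(stack.astype("<f4").tobytes())
    path.with_suffix(path.suffix + ".hdr.json").write_text(
        json.dumps(header, indent=1, sort_keys=True))
    return path


def read_float_raster(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".hdr.json").read_text())
    stack = np.frombuffer(path.read_bytes(), dtype="<f4").astype(np.float32)
    stack = stack.reshape(len(header["bands"]), header["height"],
                          header["width"])
    return stack, header


def boxes_from_labels(label_map: np.ndarray, min_pixels: int = 1,
                      background=0) -> list[tuple[int, float, float, float, float]]:
    """YOLO-style boxes, one per label value with >= ``min_pixels`` pixels.

    Returns (class, x_center, y_center, width, height), all normalised to
    [0, 1]; class is the integer label value.
    """
    lm = np.asarray(label_map)
    h, w = lm.shape
    boxes = []
    for value in np.unique(lm):
        if value == background:
            continue
        rows, cols = np.nonzero(lm == value)
        if rows.size < min_pixels:
            continue
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        boxes.append((int(value),
                      (c0 + c1) / 2.0 / w, (r0 + r1) / 2.0 / h,
                      (c1 - c0) / w, (r1 - r0) / h))
    return boxes


def write_yolo_boxes(boxes, path) -> Path:
    path = Path(path)
    lines = [f"{c} {x:.6f} {y:.6f} {bw:.6f} {bh:.6f}"
             for c, x, y, bw, bh in boxes]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
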