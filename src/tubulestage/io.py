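"""Image reading/writing: TIFF or PNG, single-channel 8/16-bit.

Multi-channel inputs are reduced to grayscale with ITU-R BT.601 luma
weights (0.299 R + 0.587 G + 0.114 B) before analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import DEFAULT_MICRONS_PER_PX, SlideImage

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
        rgb = pixels[..., :3].astype(float)
        gray = rgb @ np.array(LUMA_WEIGHTS)
        return np.clip(gray, 0, np.iinfo(pixels.dtype).max if pixels.dtype.kind == "u" else 255).astype(pixels.dtype)
    raise ValueError(f"unsupported image shape {pixels.shape}")


def read_slide(path, microns_per_px: float = DEFAULT_MICRONS_PER_PX) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    return SlideImage(pixels=to_grayscale(np.asarray(pixels)), microns_per_px=microns_per_px)


def write_slide(slide: SlideImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, slide.pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, slide.pixels)
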