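"""Small shared helpers: unit conversion and integer image translation."""

from __future__ import annotations

import numpy as np


def nm_to_px(value_nm: float, pixel_size_nm: float) -> float:
    """Convert a physical length in nanometres to pixels."""
    if pixel_size_nm <= 0:
        raise ValueError(f"pixel_size_nm must be positive, got {pixel_size_nm}")
    return float(value_nm) / float(pixel_size_nm)


def um_to_px(value_um: float, pixel_size_nm: float) -> float:
    return nm_to_px(value_um * 1000.0, pixel_size_nm)


def px_to_um(value_px: float, pixel_size_nm: float) -> float:
    return float(value_px) * float(pixel_size_nm) / 1000.0


def translate_image(image: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Translate a 2-D image by an integer (dy, dx), filling vacated pixels.

    Positive ``dy`` moves content down, positive ``dx`` moves it right.
    """
    if int(dy) != dy or int(dx) != dx:
        raise ValueError(f"integer shifts required, got ({dy}, {dx})")
    dy, dx = int(dy), int(dx)
    out = np.full_like(image, fill)
    h, w = image.shape
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[ys_dst, xs_dst] = image[ys_src, xs_src]
    return out


def modal_value(image: np.ndarray) -> float:
    """Most frequent value of an image after rounding to integers.

    Used as the background estimate when filling pixels exposed by a shift.
    """
    vals = np.round(np.asarray(image, dtype=float).ravel()).astype(np.int64)
    vals -= vals.min()
    return float(np.bincount(vals).argmax() + (np.round(image).min()))
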