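"""Image stack I/O and drift correction.

Stacks are stored as multi-page TIFF (pages ordered time-major, channel
within time) with a JSON sidecar carrying the channel names, pixel size and
frame interval; reading without the sidecar fails rather than guessing a
layout.  Drift correction registers the chosen reference channel (phase
contrast in normal use) of every frame to frame 0 by integer-pixel
cross-correlation and applies the same shift to all other channels of that
time point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from bactorg.util import modal_value, translate_image

#: registration sanity limit: shifts beyond this fraction of the frame size
#: indicate a failed acquisition
MAX_SHIFT_FRACTION = 0.25


@dataclass
class ImageStack:
    """(time, channel, row, col) intensity grid with physical metadata."""

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_nm: float
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError("pixels must be 4-D (time, channel, row, col)")
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[1]} channels"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, self.channel_names.index(name)]


@dataclass
class ShiftSeries:
    """Per-frame integer (dy, dx) offsets aligning each frame to frame 0."""

    shifts: np.ndarray  # (n_frames, 2) int
    flagged_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")
        if tuple(self.shifts[0]) != (0, 0):
            raise ValueError("shift of frame 0 must be (0, 0)")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.shifts, columns=["dy", "dx"]).to_csv(path, index_label="frame")

    @classmethod
    def from_csv(cls, path) -> "ShiftSeries":
        df = pd.read_csv(path)
        return cls(df[["dy", "dx"]].to_numpy())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF plus JSON sidecar (lossless)."""
    path = Path(path)
    t, c, h, w = stack.pixels.shape
    tifffile.imwrite(path, stack.pixels.reshape(t * c, h, w))
    meta = {
        "n_frames": t,
        "channel_names": list(stack.channel_names),
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "dtype": str(stack.pixels.dtype),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    Fails explicitly when the sidecar is missing or the TIFF page count
    does not match the declared (time, channel) layout.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar}; cannot infer stack layout"
        )
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    t = int(meta["n_frames"])
    names = list(meta["channel_names"])
    c = len(names)
    if pages.shape[0] != t * c:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but metadata declares "
            f"{t} frames x {c} channels = {t * c}"
        )
    pixels = pages.reshape(t, c, *pages.shape[1:])
    return ImageStack(pixels, names, float(meta["pixel_size_nm"]), meta.get("frame_interval_s"))


def cross_correlation_shift(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) that, applied to ``moving``, best aligns it to ``reference``.

    Mean-subtracted cross-correlation computed in the frequency domain with
    zero padding (full linear correlation, so no wrap-around artifacts).
    A flat (zero-variance) input yields (0, 0).
    """
    from scipy.signal import fftconvolve

    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.std() == 0 or mov.std() == 0:
        return (0, 0)
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    corr = fftconvolve(ref, mov[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    dy = int(peak[0] - (mov.shape[0] - 1))
    dx = int(peak[1] - (mov.shape[1] - 1))
    return (dy, dx)


def register_stack(stack: ImageStack, reference_channel: str = "phase") -> tuple[ImageStack, ShiftSeries]:
    """Align every frame to frame 0 using one reference channel.

    The integer shift maximizing the cross-correlation of the reference
    channel against frame 0 is found per frame and applied to *all*
    channels of that time point.  Out-of-frame pixels are filled with the
    modal background value of the shifted frame.  Frames whose reference
    image is flat get shift (0, 0) and are flagged; shifts larger than a
    quarter of the frame size raise.
    """
    if reference_channel not in stack.channel_names:
        raise ValueError(f"reference channel {reference_channel!r} not in stack")
    ref_idx = stack.channel_names.index(reference_channel)
    ref0 = stack.pixels[0, ref_idx]
    h, w = ref0.shape
    n = stack.n_frames
    shifts = np.zeros((n, 2), dtype=int)
    flagged: list[int] = []
    out = np.array(stack.pixels, dtype=float, copy=True)
    for t in range(1, n):
        frame = stack.pixels[t, ref_idx]
        if np.asarray(frame, dtype=float).std() == 0:
            flagged.append(t)
            continue
        dy, dx = cross_correlation_shift(ref0, frame)
        if abs(dy) > MAX_SHIFT_FRACTION * h or abs(dx) > MAX_SHIFT_FRACTION * w:
            raise ValueError(
                f"frame {t}: shift ({dy}, {dx}) exceeds 25% of the frame size; "
                "acquisition likely failed"
            )
        shifts[t] = (dy, dx)
        for c in range(stack.pixels.shape[1]):
            img = stack.pixels[t, c].astype(float)
            out[t, c] = translate_image(img, dy, dx, fill=modal_value(img))
    registered = ImageStack(out, list(stack.channel_names), stack.pixel_size_nm, stack.frame_interval_s)
    return registered, ShiftSeries(shifts, flagged)
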