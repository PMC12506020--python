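"""Pearson colocalization between two fluorescence channels.

Per cell (pixels extracted with the cell mask) or per full field of view.
Records with zero variance in either channel are flagged and must be
excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ColocRecord:
    id: int
    pearson_r: float
    n_pixels: int
    flagged: bool = False


def _pearson(a: np.ndarray, b: np.ndarray, rec_id: int) -> ColocRecord:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("channels must have the same shape")
    if len(a) < 2:
        raise ValueError("need at least 2 pixels")
    if a.std() == 0 or b.std() == 0:
        return ColocRecord(rec_id, np.nan, len(a), flagged=True)
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocRecord(rec_id, r, len(a))


def pearson_per_cell(
    channelA: np.ndarray, channelB: np.ndarray, cell_mask: np.ndarray, cell_id: int = 0
) -> ColocRecord:
    """Sample Pearson correlation over the in-mask pixel pairs of one cell."""
    mask = np.asarray(cell_mask, dtype=bool)
    return _pearson(np.asarray(channelA)[mask], np.asarray(channelB)[mask], cell_id)


def pearson_per_field(channelA: np.ndarray, channelB: np.ndarray, field_id: int = 0) -> ColocRecord:
    """Pearson correlation over the full field of view (no mask)."""
    return _pearson(channelA, channelB, field_id)


def chlorophyll_gate(
    chlorophyll: np.ndarray,
    cell_masks: dict[int, np.ndarray],
    background: float | None = None,
    factor: float = 2.0,
) -> list[int]:
    """Viability pre-filter: keep cells with appreciable chlorophyll signal.

    A cell passes when its mean in-mask chlorophyll intensity exceeds
    ``factor`` times the field background (default: the median of pixels
    outside every cell).
    """
    chl = np.asarray(chlorophyll, dtype=float)
    if background is None:
        outside = np.ones_like(chl, dtype=bool)
        for m in cell_masks.values():
            outside &= ~m
        background = float(np.median(chl[outside])) if outside.any() else 0.0
    return [cid for cid, m in cell_masks.items() if chl[m].mean() > factor * background]
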