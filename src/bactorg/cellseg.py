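"""Cell segmentation post-processing and per-cell morphology.

Segmentation proper is delegated to a pluggable backend (a pretrained
neural segmenter can be slotted in as any callable mapping an image to a
label map; a built-in invert-and-threshold backend handles synthetic phase
contrast).  This module owns the surrounding processing: a 66 nm Gaussian
pre-blur, filling of intracellular holes, removal of border-touching cells
and label compaction — and computes per-cell morphology (length, width,
area and the pole-to-pole midline) from the mask via skeletonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from bactorg.util import nm_to_px, px_to_um

#: pre-segmentation Gaussian blur sigma in nanometres
PRE_BLUR_SIGMA_NM = 66.0
#: cells smaller than this (pixels) have no meaningful skeleton
MIN_CELL_PIXELS = 9


@dataclass
class CellMorphology:
    """Length, width, area and midline of one segmented cell.

    The midline is an ordered (n, 2) array of ``(x, y)`` pixel coordinates
    from pole to pole; ``length_um`` is its arc length, ``width_um`` is
    twice the mean distance from the midline to the cell boundary over the
    cylindrical (non-cap) part.
    """

    cell_id: int
    length_um: float
    width_um: float
    area_um2: float
    midline: np.ndarray

    def midline_arclength_px(self) -> np.ndarray:
        """Cumulative arc length (px) at each midline vertex."""
        d = np.hypot(*np.diff(self.midline, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(d)])


def threshold_backend(image: np.ndarray) -> np.ndarray:
    """Built-in segmenter for synthetic phase contrast: cells are dark.

    Inverts the image and applies Otsu's threshold, then labels
    4-connected components.
    """
    inv = image.max() - np.asarray(image, dtype=float)
    t = filters.threshold_otsu(inv)
    labels, _ = ndi.label(inv > t, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return labels


def segment_cells(
    phase_image: np.ndarray,
    backend: Callable[[np.ndarray], np.ndarray] | str = "threshold",
    pixel_size_nm: float = 60.0,
    override_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Produce a cleaned per-cell label map from a phase-contrast image.

    The image is blurred (sigma 66 nm), passed to the backend, then each
    cell's interior holes are filled, border-touching cells are removed and
    labels are compacted to 1..K.  ``override_labels`` replaces the backend
    output entirely (manual-correction hook) but still receives the same
    post-processing.
    """
    if override_labels is not None:
        raw = np.asarray(override_labels)
    else:
        blurred = ndi.gaussian_filter(
            np.asarray(phase_image, dtype=float), nm_to_px(PRE_BLUR_SIGMA_NM, pixel_size_nm)
        )
        if backend == "threshold":
            raw = threshold_backend(blurred)
        elif callable(backend):
            raw = np.asarray(backend(blurred))
        else:
            raise ValueError(f"unknown backend {backend!r}")
    if raw.shape != np.asarray(phase_image).shape or not np.issubdtype(raw.dtype, np.integer):
        raise ValueError("backend must return an integer label map of the image shape")

    out = np.zeros_like(raw, dtype=np.int32)
    next_label = 1
    for lab in np.unique(raw):
        if lab == 0:
            continue
        mask = raw == lab
        # one 4-connected component per label; split if the backend merged
        comps, n = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        for c in range(1, n + 1):
            comp = ndi.binary_fill_holes(comps == c)
            if (
                comp[0, :].any()
                or comp[-1, :].any()
                or comp[:, 0].any()
                or comp[:, -1].any()
            ):
                continue  # border-touching cells are ignored
            if (out[comp] != 0).any():
                raise ValueError("backend produced overlapping labels")
            out[comp] = next_label
            next_label += 1
    if next_label == 1:
        warnings.warn("segmentation produced no cells", stacklevel=2)
    return out


def _skeleton_longest_path(mask: np.ndarray) -> np.ndarray:
    """Longest geodesic path through the skeleton, as (n, 2) (x, y) coords.

    Side branches of the skeleton are discarded; returns an empty array if
    the skeleton has fewer than 2 pixels.
    """
    skel = morphology.skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if len(ys) < 2:
        return np.empty((0, 2))
    g = nx.Graph()
    pix = set(zip(ys.tolist(), xs.tolist()))
    for y, x in pix:
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) == (0, 0):
                    continue
                if (y + dy, x + dx) in pix:
                    g.add_edge((y, x), (y + dy, x + dx), weight=np.hypot(dy, dx))
    # deterministic, translation-invariant tie-breaking: scan in sorted order
    ends = sorted(n for n in g.nodes if g.degree(n) == 1)
    if len(ends) < 2:  # cycle or blob: fall back to the two most distant nodes
        ends = sorted(g.nodes)
    best, best_len = None, -1.0
    for i, a in enumerate(ends):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for b in ends[i + 1 :]:
            if b in lengths and lengths[b] > best_len:
                best_len, best = lengths[b], (a, b)
    if best is None:
        return np.empty((0, 2))
    path = nx.dijkstra_path(g, *best)
    return np.array([(x, y) for y, x in path], dtype=float)


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both midline ends along the local tangent until leaving the mask."""

    def extension(end: np.ndarray, inner: np.ndarray) -> list[np.ndarray]:
        v = end - inner
        norm = np.hypot(*v)
        if norm == 0:
            return []
        v = v / norm
        pts = []
        p = end.astype(float)
        while True:
            p = p + v * 0.5
            # half-up rounding keeps the stopping rule translation-invariant
            ix, iy = int(np.floor(p[0] + 0.5)), int(np.floor(p[1] + 0.5))
            if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) or not mask[iy, ix]:
                break
            pts.append(p.copy())
        return pts

    k = min(4, len(path) - 1)  # tangent from the last few vertices
    head = extension(path[0], path[k])
    tail = extension(path[-1], path[-1 - k])
    parts = [np.array(head[::-1])] if head else []
    parts.append(path)
    if tail:
        parts.append(np.array(tail))
    return np.vstack(parts)


def _half_chords(mask: np.ndarray, path: np.ndarray, max_r: float = 30.0) -> np.ndarray:
    """Per midline vertex: half the perpendicular chord through the cell.

    The boundary crossing is located where the bilinearly interpolated mask
    drops below 0.5 along the normal ray, on each side; the two half-widths
    are averaged, which centers the estimate even if the midline wiggles
    off-axis.
    """
    maskf = mask.astype(float)
    tang = np.gradient(path, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    ts = np.arange(0.0, max_r, 0.25)
    halves = np.empty((len(path), 2))
    for si, sgn in enumerate((1.0, -1.0)):
        # sample every ray at once: (n_points, n_steps)
        qx = path[:, 0:1] + sgn * ts[None, :] * normals[:, 0:1]
        qy = path[:, 1:2] + sgn * ts[None, :] * normals[:, 1:2]
        vals = ndi.map_coordinates(maskf, [qy.ravel(), qx.ravel()], order=1, cval=0.0).reshape(qx.shape)
        below = vals < 0.5
        first = np.argmax(below, axis=1)
        first[~below.any(axis=1)] = len(ts) - 1
        prev = np.maximum(first - 1, 0)
        v0 = vals[np.arange(len(path)), prev]
        v1 = vals[np.arange(len(path)), first]
        frac = np.where(v0 > v1, (v0 - 0.5) / np.where(v0 > v1, v0 - v1, 1.0), 0.0)
        halves[:, si] = ts[prev] + frac * 0.25
    return halves.mean(axis=1)


def _pca_midline(mask: np.ndarray) -> np.ndarray:
    """Fallback midline along the principal axis, for near-round cells."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    u = (pts - c) @ v
    return np.array([c + u.min() * v, c, c + u.max() * v])


def cell_morphology(
    label_map: np.ndarray, pixel_size_nm: float = 60.0
) -> list[CellMorphology]:
    """Compute length, width, area and midline for every labeled cell.

    The mask is skeletonized and pruned to its longest path, each end is
    extended to the boundary along the local tangent, and:

    * length = midline arc length;
    * width  = 2 x mean half-chord perpendicular to the midline over its
      cylindrical part (vertices farther from either pole than the cap
      radius); for near-round cells this reduces to the inscribed diameter;
    * area   = pixel count x pixel area.

    Cells smaller than 9 px are excluded with a warning.
    """
    px_um = px_to_um(1.0, pixel_size_nm)
    out: list[CellMorphology] = []
    for lab in np.unique(label_map):
        if lab == 0:
            continue
        mask = label_map == lab
        npx = int(mask.sum())
        if npx < MIN_CELL_PIXELS:
            warnings.warn(f"cell {lab}: only {npx} px, skeleton undefined; excluded", stacklevel=2)
            continue
        path = _skeleton_longest_path(mask)
        if len(path) < 2:
            path = _pca_midline(mask)
        else:
            path = _extend_to_boundary(path, mask)

        r_mid = _half_chords(mask, path)
        r_cap = float(r_mid.max()) if len(r_mid) else 1.0
        seg = np.hypot(*np.diff(path, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        interior = (arc >= r_cap) & (arc <= total - r_cap)
        if interior.sum() >= 1 and len(r_mid) == len(path):
            width_px = 2.0 * float(r_mid[interior].mean())
        else:
            width_px = 2.0 * r_cap
        out.append(
            CellMorphology(
                cell_id=int(lab),
                length_um=total * px_um,
                width_um=width_px * px_um,
                area_um2=npx * px_um**2,
                midline=path,
            )
        )
    return out
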