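"""Normalized cell coordinates and cross-cell localization density maps.

Each localization is re-parameterized into a three-coordinate cell frame:
``r`` the radial distance from the midline, ``l`` the arc-length position
along the midline (from projection onto it), and ``phi`` the angle from
the midline tangent, defined only beyond the midline endpoints (the polar
caps).  ``r`` and ``l`` are divided by the cell width and length giving
``r_rel`` and ``l_rel`` so that all cells share a common frame.

Counts are binned over this frame; because the bins have unequal physical
size, per-bin areas are computed per cell by classifying every mask pixel.
Counts and areas are summed across cells (optionally pooled fourfold over
the left/right x head/tail symmetry), and converted to a probability
density in µm^-2:

    density_b = (sum counts_b / sum areas_b) / total_counts * n_cells

which integrates to ``n_cells`` over the cell area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from bactorg.cellseg import CellMorphology
from bactorg.util import um_to_px


@dataclass
class CellCoordinate:
    r_rel: float
    l_rel: float
    phi: float | None  # radians, defined only in the polar caps
    region: Literal["cylindrical", "polar"]
    side: int  # +1 / -1, which side of the midline


@dataclass(frozen=True)
class BinSpec:
    """Bin edges of the normalized cell frame.

    ``r_edges`` apply to ``r_rel`` in both regions (the outermost edge is
    open-ended so boundary pixels are always captured); ``n_l_segments``
    longitudinal segments span ``l_rel`` in [0, 1]; ``phi_edges`` divide
    the polar caps into angular sectors.  Half-open intervals; a value on a
    boundary goes to the lower-index bin.
    """

    r_edges: tuple[float, ...] = (0.0, 1.0 / 6.0, 1.0 / 3.0, np.inf)
    n_l_segments: int = 8
    phi_edges: tuple[float, ...] = (0.0, np.pi / 8, np.pi / 4, 3 * np.pi / 8, np.pi)

    @property
    def n_rings(self) -> int:
        return len(self.r_edges) - 1

    @property
    def n_sectors(self) -> int:
        return len(self.phi_edges) - 1


def _midline_geometry(morphology: CellMorphology) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    mid = np.asarray(morphology.midline, dtype=float)
    seg = np.diff(mid, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    keep = seglen > 0
    if not keep.all():
        mid = np.vstack([mid[:1], mid[1:][keep]])
        seg = np.diff(mid, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    return mid, seg, arc, float(arc[-1])


def cell_coords_batch(
    points: np.ndarray,
    morphology: CellMorphology,
    pixel_size_nm: float = 60.0,
) -> list[CellCoordinate]:
    """Vectorized conversion of (n, 2) pixel (x, y) points to cell coordinates.

    A point whose closest midline point is an interior point is
    cylindrical; one whose closest point is a midline endpoint is polar,
    with ``phi`` the angle between the endpoint-to-point vector and the
    outward midline tangent.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    mid, seg, arc, total = _midline_geometry(morphology)
    width_px = um_to_px(morphology.width_um, pixel_size_nm)
    a = mid[:-1]
    ab = seg
    denom = (ab**2).sum(axis=1)
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    n = len(pts)
    rows = np.arange(n)
    tb = t[rows, best]
    r_px = np.sqrt(d2[rows, best])
    l_px = arc[best] + tb * np.hypot(ab[best, 0], ab[best, 1])
    projb = proj[rows, best]
    tangb = ab[best] / np.hypot(ab[best, 0], ab[best, 1])[:, None]
    rel = pts - projb
    cross = tangb[:, 0] * rel[:, 1] - tangb[:, 1] * rel[:, 0]
    side = np.where(cross >= 0, 1, -1)

    out: list[CellCoordinate] = []
    tang_start = seg[0] / np.hypot(*seg[0])
    tang_end = seg[-1] / np.hypot(*seg[-1])
    for i in range(n):
        at_start = l_px[i] <= 1e-9
        at_end = l_px[i] >= total - 1e-9
        if (at_start or at_end) and r_px[i] > 1e-9:
            endpoint = mid[0] if at_start else mid[-1]
            outward = -tang_start if at_start else tang_end
            v = pts[i] - endpoint
            nv = np.hypot(*v)
            cosphi = np.clip(np.dot(v, outward) / nv, -1.0, 1.0) if nv > 0 else 1.0
            out.append(
                CellCoordinate(
                    r_rel=r_px[i] / width_px,
                    l_rel=0.0 if at_start else 1.0,
                    phi=float(np.arccos(cosphi)),
                    region="polar",
                    side=int(side[i]),
                )
            )
        else:
            out.append(
                CellCoordinate(
                    r_rel=r_px[i] / width_px,
                    l_rel=l_px[i] / total,
                    phi=None,
                    region="cylindrical",
                    side=int(side[i]),
                )
            )
    return out


def to_cell_coords(
    x: float,
    y: float,
    morphology: CellMorphology,
    pixel_size_nm: float = 60.0,
    cell_mask: np.ndarray | None = None,
) -> CellCoordinate:
    """Convert one (x, y) pixel position to normalized cell coordinates."""
    if cell_mask is not None:
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < cell_mask.shape[0] and 0 <= ix < cell_mask.shape[1]) or not cell_mask[iy, ix]:
            raise ValueError(f"point ({x}, {y}) lies outside the cell mask")
    return cell_coords_batch(np.array([[x, y]]), morphology, pixel_size_nm)[0]


def from_cell_coords(
    coord: CellCoordinate, morphology: CellMorphology, pixel_size_nm: float = 60.0
) -> tuple[float, float]:
    """Reconstruct (x, y) from a cylindrical-region coordinate."""
    if coord.region != "cylindrical":
        raise ValueError("reconstruction implemented for the cylindrical region only")
    mid, seg, arc, total = _midline_geometry(morphology)
    width_px = um_to_px(morphology.width_um, pixel_size_nm)
    s = coord.l_rel * total
    i = min(np.searchsorted(arc, s, side="right") - 1, len(seg) - 1)
    t = (s - arc[i]) / np.hypot(*seg[i])
    p = mid[i] + t * seg[i]
    tang = seg[i] / np.hypot(*seg[i])
    normal = np.array([-tang[1], tang[0]])  # cross(tang, normal) > 0 side is +1
    p = p + coord.side * coord.r_rel * width_px * normal
    return float(p[0]), float(p[1])


# ---------------------------------------------------------------------------
# Binning


def _build_bin_table(spec: BinSpec) -> pd.DataFrame:
    rows = []
    bid = 0
    for ring in range(spec.n_rings):
        for segj in range(spec.n_l_segments):
            for side in (1, -1):
                rows.append(
                    dict(
                        bin_id=bid,
                        region="cylindrical",
                        ring=ring,
                        segment=segj,
                        sector=-1,
                        cap=-1,
                        side=side,
                        r_lo=spec.r_edges[ring],
                        r_hi=spec.r_edges[ring + 1],
                        l_lo=segj / spec.n_l_segments,
                        l_hi=(segj + 1) / spec.n_l_segments,
                        phi_lo=np.nan,
                        phi_hi=np.nan,
                    )
                )
                bid += 1
    for ring in range(spec.n_rings):
        for sect in range(spec.n_sectors):
            for cap in (0, 1):
                for side in (1, -1):
                    rows.append(
                        dict(
                            bin_id=bid,
                            region="polar",
                            ring=ring,
                            segment=-1,
                            sector=sect,
                            cap=cap,
                            side=side,
                            r_lo=spec.r_edges[ring],
                            r_hi=spec.r_edges[ring + 1],
                            l_lo=float(cap),
                            l_hi=float(cap),
                            phi_lo=spec.phi_edges[sect],
                            phi_hi=spec.phi_edges[sect + 1],
                        )
                    )
                    bid += 1
    return pd.DataFrame(rows)


def _bin_index(coord: CellCoordinate, spec: BinSpec, table_index: dict) -> int | None:
    r_edges = np.asarray(spec.r_edges)
    ring = int(np.searchsorted(r_edges, coord.r_rel, side="left") - 1)
    ring = max(0, min(ring, spec.n_rings - 1))
    if coord.region == "cylindrical":
        segj = int(np.floor(coord.l_rel * spec.n_l_segments))
        if coord.l_rel > 0 and coord.l_rel * spec.n_l_segments == segj:
            segj -= 1  # boundary values go to the lower-index bin
        segj = max(0, min(segj, spec.n_l_segments - 1))
        key = ("cylindrical", ring, segj, -1, -1, coord.side)
    else:
        phi_edges = np.asarray(spec.phi_edges)
        if coord.phi is None or not (phi_edges[0] <= coord.phi <= phi_edges[-1]):
            return None
        sect = int(np.searchsorted(phi_edges, coord.phi, side="left") - 1)
        sect = max(0, min(sect, spec.n_sectors - 1))
        cap = 0 if coord.l_rel == 0.0 else 1
        key = ("polar", ring, -1, sect, cap, coord.side)
    return table_index.get(key)


@dataclass
class BinGrid:
    """Per-cell localization counts and bin areas over the normalized frame."""

    bin_table: pd.DataFrame
    counts: np.ndarray  # (n_cells, n_bins) int
    areas_um2: np.ndarray  # (n_cells, n_bins)
    cell_ids: list[int]
    spec: BinSpec
    overflow: int = 0  # localizations with undefined coordinates


def bin_localizations(
    localizations: pd.DataFrame,
    morphologies: dict[int, CellMorphology],
    cell_masks: dict[int, np.ndarray],
    spec: BinSpec = BinSpec(),
    pixel_size_nm: float = 60.0,
) -> BinGrid:
    """Bin localizations and compute per-cell bin areas.

    ``localizations`` needs columns ``cell_id, x, y``.  Bin areas are found
    by classifying every mask pixel of every cell into its bin and summing
    pixel areas, so per cell the bin areas tile the cell area exactly; each
    pixel is subdivided 3 x 3 so that bins much narrower than a pixel (the
    innermost radial ring straddles the midline) receive their fair share
    of the area.
    """
    table = _build_bin_table(spec)
    index = {
        (row.region, row.ring, row.segment, row.sector, row.cap, row.side): row.bin_id
        for row in table.itertuples()
    }
    cell_ids = sorted(morphologies)
    n_bins = len(table)
    counts = np.zeros((len(cell_ids), n_bins), dtype=int)
    areas = np.zeros((len(cell_ids), n_bins), dtype=float)
    px_area = (pixel_size_nm / 1000.0) ** 2
    overflow = 0
    sub_offsets = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
    for ci, cid in enumerate(cell_ids):
        morph = morphologies[cid]
        mask = cell_masks[cid]
        ys, xs = np.nonzero(mask)
        centers = np.column_stack([xs, ys]).astype(float)
        subs = np.concatenate(
            [centers + (ox, oy) for oy in sub_offsets for ox in sub_offsets]
        )
        coords = cell_coords_batch(subs, morph, pixel_size_nm)
        for c in coords:
            b = _bin_index(c, spec, index)
            if b is None:
                overflow += 1
                continue
            areas[ci, b] += px_area / 9.0
        sel = localizations[localizations.cell_id == cid]
        if len(sel):
            loc_coords = cell_coords_batch(sel[["x", "y"]].to_numpy(), morph, pixel_size_nm)
            for c in loc_coords:
                b = _bin_index(c, spec, index)
                if b is None:
                    overflow += 1
                    continue
                counts[ci, b] += 1
    return BinGrid(table, counts, areas, cell_ids, spec, overflow)


@dataclass
class DensityMap:
    """Cross-cell probability density over the normalized frame, µm^-2."""

    bin_table: pd.DataFrame  # + summed_count, summed_area_um2, density_per_um2, sym_class
    n_cells: int
    total_counts: int
    symmetrized: bool
    flagged: bool = False

    def conservation(self) -> float:
        """Sum of density x area; equals ``n_cells`` by construction."""
        t = self.bin_table
        return float((t.density_per_um2 * t.summed_area_um2).sum())


def _sym_class(row, n_l_segments: int) -> tuple:
    if row.region == "cylindrical":
        return ("cyl", row.ring, min(row.segment, n_l_segments - 1 - row.segment))
    return ("pol", row.ring, row.sector)


def density_map(bin_grid: BinGrid, symmetrize: bool = True) -> DensityMap:
    """Aggregate a BinGrid into a probability-density map.

    Counts and areas are summed across cells; with ``symmetrize`` they are
    additionally pooled over the four symmetric equivalents of each bin
    (left/right of the midline x head/tail of the cell) and each bin
    reports its pooled class density.  Densities are probability densities:
    summed count over summed area, divided by total counts and multiplied
    by the number of cells.
    """
    table = bin_grid.bin_table.copy()
    table["summed_count"] = bin_grid.counts.sum(axis=0)
    table["summed_area_um2"] = bin_grid.areas_um2.sum(axis=0)
    n_cells = len(bin_grid.cell_ids)
    total = int(table.summed_count.sum())
    classes = [_sym_class(r, bin_grid.spec.n_l_segments) for r in table.itertuples()]
    table["sym_class"] = ["/".join(map(str, c)) for c in classes]
    flagged = total == 0
    if symmetrize:
        grp = table.groupby("sym_class")
        csum = grp.summed_count.transform("sum")
        asum = grp.summed_area_um2.transform("sum")
    else:
        csum = table.summed_count
        asum = table.summed_area_um2
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(asum > 0, csum / asum, 0.0)
    if total > 0:
        dens = dens / total * n_cells
    else:
        dens = np.zeros(len(table))
    table["density_per_um2"] = dens
    return DensityMap(table, n_cells, total, symmetrize, flagged)


def plot_density_map(dmap: DensityMap, path) -> None:
    """Render a density map as a PNG: cylindrical (ring x segment) and
    polar (ring x sector) panels, symmetry-pooled, in µm^-2."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = dmap.bin_table
    cyl = t[t.region == "cylindrical"].groupby(["ring", "segment"]).density_per_um2.mean().unstack()
    pol = t[t.region == "polar"].groupby(["ring", "sector"]).density_per_um2.mean().unstack()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3), width_ratios=[2, 1])
    im0 = axes[0].imshow(cyl.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
    axes[0].set_xlabel("longitudinal segment (l_rel)")
    axes[0].set_ylabel("radial ring (r_rel)")
    axes[0].set_title("cylindrical region")
    fig.colorbar(im0, ax=axes[0], label="density (µm$^{-2}$)")
    im1 = axes[1].imshow(pol.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
    axes[1].set_xlabel("angular sector (phi)")
    axes[1].set_title("polar caps")
    fig.colorbar(im1, ax=axes[1], label="density (µm$^{-2}$)")
    fig.suptitle(f"localization probability density, n={dmap.n_cells} cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def representative_cell(
    cell_masks: Sequence[np.ndarray], pixel_size_nm: float = 60.0
) -> tuple[np.ndarray, CellMorphology]:
    """Mean-cell mask: align masks by centroid and orientation, sum, threshold.

    Masks are rotated to a horizontal long axis about their centroid,
    centered on a common canvas and summed; the representative mask is the
    region at or above 50% of the stack's maximum.  Its morphology (midline,
    length, width) defines the drawn bin geometry.
    """
    from scipy.ndimage import rotate, shift as nd_shift
    from skimage import measure

    from bactorg.cellseg import cell_morphology

    if len(cell_masks) == 0:
        raise ValueError("no masks given")
    size = int(2 * max(max(m.shape) for m in cell_masks))
    canvas = np.zeros((size, size), dtype=float)
    for m in cell_masks:
        props = measure.regionprops(m.astype(np.uint8))[0]
        cy, cx = props.centroid
        # skimage orientation: angle of major axis w.r.t. rows; rotate to horizontal
        angle_deg = 90.0 - np.rad2deg(props.orientation)
        pad = np.zeros((size, size), dtype=float)
        oy = size // 2 - m.shape[0] // 2
        ox = size // 2 - m.shape[1] // 2
        pad[oy : oy + m.shape[0], ox : ox + m.shape[1]] = m
        pad = nd_shift(pad, (size / 2 - (cy + oy) - 0.5, size / 2 - (cx + ox) - 0.5), order=0)
        pad = rotate(pad, angle_deg, reshape=False, order=0)
        canvas += pad
    rep = canvas >= 0.5 * canvas.max()
    labels = np.zeros_like(rep, dtype=np.int32)
    labels[rep] = 1
    morph = cell_morphology(labels, pixel_size_nm)[0]
    return rep, morph
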