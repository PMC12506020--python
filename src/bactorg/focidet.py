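"""Fluorescent focus detection and per-focus / per-cell statistics.

The detector mirrors a standard single-scale Laplacian-of-Gaussian spot
finder: the cell image is sharpened with an unsharp mask, Gaussian
blurred, filtered with a scale-normalized LoG at the scale implied by the
expected blob diameter, and local maxima of the response above a quality
threshold (inside the cell mask) are reported.  Focus intensity is the sum
of *raw* pixel values within a circle of radius 2r around the detection,
r being the LoG spot radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import filters

from bactorg.cellseg import CellMorphology
from bactorg.util import px_to_um


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings; the tracking-channel defaults are blob diameter
    3.0 px and quality threshold 80.0, with config-exposed pre-processing
    (unsharp radius 2 px, amount 1.0, blur sigma 1 px)."""

    unsharp_radius: float = 2.0
    unsharp_amount: float = 1.0
    blur_sigma: float = 1.0
    blob_diameter_px: float = 3.0
    quality_threshold: float = 80.0
    subpixel: bool = False

    @property
    def log_sigma(self) -> float:
        # blob of diameter d is matched by a LoG at sigma = d / (2*sqrt(2))
        return self.blob_diameter_px / (2.0 * np.sqrt(2.0))

    @property
    def spot_radius(self) -> float:
        # radius at which the LoG response of a matched blob changes sign
        return self.log_sigma * np.sqrt(2.0)


@dataclass
class FocusDetection:
    cell_id: int
    frame: int
    x: float
    y: float
    r: float  # detection scale radius, px
    quality: float  # scale-normalized LoG response at the maximum
    intensity: float = np.nan  # summed raw intensity in the 2r circle


def log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized negative Laplacian of Gaussian (bright blobs -> peaks)."""
    return -(sigma**2) * ndi.gaussian_laplace(np.asarray(image, dtype=float), sigma)


def preprocess(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Unsharp-mask sharpening followed by Gaussian blur."""
    img = np.asarray(image, dtype=float)
    if params.unsharp_amount > 0 and params.unsharp_radius > 0:
        img = filters.unsharp_mask(
            img, radius=params.unsharp_radius, amount=params.unsharp_amount, preserve_range=True
        )
    if params.blur_sigma > 0:
        img = ndi.gaussian_filter(img, params.blur_sigma)
    return img


def _local_maxima(response: np.ndarray, mask: np.ndarray, threshold: float) -> np.ndarray:
    """(y, x) integer coordinates of in-mask 8-neighborhood maxima above threshold."""
    footprint_max = ndi.maximum_filter(response, size=3, mode="nearest")
    is_max = (response >= footprint_max) & (response > threshold) & mask
    return np.column_stack(np.nonzero(is_max))


def _quadratic_refine(response: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """1-D quadratic subpixel refinement along each axis."""
    out = [float(x), float(y)]
    for axis, (c, lo, hi) in enumerate(
        [
            (x, response[y, x - 1] if x > 0 else None, response[y, x + 1] if x + 1 < response.shape[1] else None),
            (y, response[y - 1, x] if y > 0 else None, response[y + 1, x] if y + 1 < response.shape[0] else None),
        ]
    ):
        if lo is None or hi is None:
            continue
        denom = lo - 2 * response[y, x] + hi
        if denom != 0:
            out[axis] = c + 0.5 * (lo - hi) / denom
    return out[0], out[1]


def detect_foci(
    cell_image: np.ndarray,
    cell_mask: np.ndarray,
    params: DetectionParams = DetectionParams(),
    cell_id: int = 0,
    frame: int = 0,
    raw_image: np.ndarray | None = None,
) -> list[FocusDetection]:
    """Detect diffraction-limited foci in one cell.

    Returns detections sorted by quality descending (ties broken by (y, x)
    ascending).  If ``raw_image`` is given (the unprocessed data), each
    detection's 2r-circle intensity is filled in from it.
    """
    if params.blob_diameter_px <= 0:
        raise ValueError("blob_diameter_px must be positive")
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        return []
    img = np.asarray(cell_image, dtype=float)
    work = img.copy()
    work[~cell_mask] = np.median(img[cell_mask])  # out-of-mask pixels ignored
    resp = log_response(preprocess(work, params), params.log_sigma)
    peaks = _local_maxima(resp, cell_mask, params.quality_threshold)
    dets = []
    for y, x in peaks:
        if params.subpixel:
            fx, fy = _quadratic_refine(resp, y, x)
        else:
            fx, fy = float(x), float(y)
        dets.append(
            FocusDetection(
                cell_id=cell_id,
                frame=frame,
                x=fx,
                y=fy,
                r=params.spot_radius,
                quality=float(resp[y, x]),
            )
        )
    dets.sort(key=lambda d: (-d.quality, d.y, d.x))
    if raw_image is not None:
        for d in dets:
            d.intensity = focus_intensity(raw_image, d)
    return dets


def focus_intensity(raw_cell_image: np.ndarray, detection: FocusDetection) -> float:
    """Sum of raw pixel values within Euclidean distance 2r of the detection.

    Pixels are included when their integer center lies inside the circle;
    the circle is clipped to the image, but a circle entirely outside it is
    an error.
    """
    if detection.r <= 0:
        raise ValueError("detection radius must be positive")
    img = np.asarray(raw_cell_image, dtype=float)
    rad = 2.0 * detection.r
    x0, y0 = detection.x, detection.y
    if x0 + rad < -0.5 or y0 + rad < -0.5 or x0 - rad > img.shape[1] - 0.5 or y0 - rad > img.shape[0] - 0.5:
        raise ValueError("intensity circle lies entirely outside the image")
    xlo = max(0, int(np.floor(x0 - rad)))
    xhi = min(img.shape[1] - 1, int(np.ceil(x0 + rad)))
    ylo = max(0, int(np.floor(y0 - rad)))
    yhi = min(img.shape[0] - 1, int(np.ceil(y0 + rad)))
    yy, xx = np.mgrid[ylo : yhi + 1, xlo : xhi + 1]
    inside = (xx - x0) ** 2 + (yy - y0) ** 2 <= rad**2
    return float(img[ylo : yhi + 1, xlo : xhi + 1][inside].sum())


def point_to_polyline_distance(point: tuple[float, float], polyline: np.ndarray) -> float:
    """Minimal Euclidean distance from an (x, y) point to a polyline, px."""
    p = np.asarray(point, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    if len(poly) == 1:
        return float(np.hypot(*(p - poly[0])))
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((p - proj) ** 2).sum(axis=1)).min())


@dataclass
class FocusStats:
    """Per-cell summary of detected foci."""

    cell_id: int
    focus_count: int
    intensities: list[float]
    nn_spacing_um: list[float]  # empty when fewer than 2 foci
    medial_distance_um: list[float]
    whole_cell_intensity_per_length: float


def focus_stats(
    detections: Sequence[FocusDetection],
    morphology: CellMorphology,
    pixel_size_nm: float,
    raw_cell_image: np.ndarray | None = None,
    cell_mask: np.ndarray | None = None,
) -> FocusStats:
    """Nearest-neighbor spacing, midline distance and per-length intensity.

    ``nn_spacing_um`` is the center distance to the nearest other focus
    (empty for cells with fewer than two foci); ``medial_distance_um`` the
    perpendicular distance to the midline polyline.  When the raw image and
    mask are given, the whole-cell intensity per unit length is the in-mask
    pixel sum divided by the cell length.
    """
    pts = np.array([(d.x, d.y) for d in detections], dtype=float)
    nn: list[float] = []
    if len(pts) >= 2:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = [px_to_um(v, pixel_size_nm) for v in np.sqrt(d2.min(axis=1))]
    medial = [
        px_to_um(point_to_polyline_distance((d.x, d.y), morphology.midline), pixel_size_nm)
        for d in detections
    ]
    per_len = np.nan
    if raw_cell_image is not None and cell_mask is not None and morphology.length_um > 0:
        per_len = float(np.asarray(raw_cell_image, dtype=float)[cell_mask].sum()) / morphology.length_um
    return FocusStats(
        cell_id=morphology.cell_id,
        focus_count=len(detections),
        intensities=[d.intensity for d in detections],
        nn_spacing_um=nn,
        medial_distance_um=medial,
        whole_cell_intensity_per_length=per_len,
    )
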