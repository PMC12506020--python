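"""Synthetic microscopy scenes with full ground truth.

Rod-shaped cyanobacteria (~1 µm wide, 2–4 µm long at 60 nm/pixel) are
emulated as spherocylinders.  The generator renders the channels the
downstream pipeline consumes — phase contrast, diffraction-limited foci on
confined random walks, a DAPI-like nucleoid of controllable area fraction,
polar-gradient / diffuse / punctate protein patterns, and channel pairs with
a prescribed Pearson correlation — plus stage drift, all with the true
quantities recorded before any noise is applied.

Every generator is deterministic given its seed, and ground truth never
depends on the noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from bactorg.util import nm_to_px, translate_image, um_to_px

DEFAULT_PIXEL_SIZE_NM = 60.0
#: point-spread-function sigma; 2 px at the default pixel size, so the
#: default 3 px blob-diameter detector is matched to synthetic foci
DEFAULT_PSF_SIGMA_NM = 120.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive background + Gaussian read noise, with optional shot noise.

    Parameters
    ----------
    background : float
        Mean camera offset in arbitrary detector units.
    read_sigma : float
        Standard deviation of Gaussian read noise.
    shot_noise : bool
        If True the noiseless image (including background) is replaced by a
        Poisson draw before read noise is added.
    """

    background: float = 100.0
    read_sigma: float = 5.0
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        img = np.asarray(clean, dtype=float) + self.background
        if self.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if self.read_sigma > 0:
            img = img + rng.normal(0.0, self.read_sigma, size=img.shape)
        return np.clip(img, 0.0, None)


NOISELESS = NoiseModel(background=0.0, read_sigma=0.0, shot_noise=False)
DEFAULT_NOISE = NoiseModel()


def make_cell_mask(
    length_um: float,
    width_um: float,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    orientation_deg: float = 0.0,
    margin_px: int = 5,
    shape: tuple[int, int] | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean mask of a spherocylinder (rod with hemispherical caps).

    The rod's total pole-to-pole length is ``length_um`` and its diameter is
    ``width_um``; ``length_um == width_um`` degenerates to a disk.  A pixel
    belongs to the rod when its center lies within ``width/2`` of the central
    axis segment.  The grid is sized to hold the rod plus ``margin_px`` on
    every side unless an explicit ``shape`` (and ``center`` as ``(x, y)``)
    is given, in which case the rod must fit without touching the border.
    """
    if width_um <= 0 or length_um <= 0:
        raise ValueError("cell dimensions must be positive")
    if length_um < width_um:
        raise ValueError("length_um must be >= width_um")
    L = um_to_px(length_um, pixel_size_nm)
    W = um_to_px(width_um, pixel_size_nm)
    half_seg = max(0.0, (L - W) / 2.0)
    theta = np.deg2rad(orientation_deg)
    ux, uy = np.cos(theta), np.sin(theta)

    if shape is None:
        ext_x = abs(ux) * (L - W) + W
        ext_y = abs(uy) * (L - W) + W
        shape = (int(np.ceil(ext_y)) + 2 * margin_px, int(np.ceil(ext_x)) + 2 * margin_px)
        center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    elif center is None:
        center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    px = xx - center[0]
    py = yy - center[1]
    # distance from pixel center to the central axis segment
    t = np.clip(px * ux + py * uy, -half_seg, half_seg)
    d2 = (px - t * ux) ** 2 + (py - t * uy) ** 2
    mask = d2 <= (W / 2.0) ** 2
    if not mask.any():
        raise ValueError("grid too small: empty mask")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ValueError("grid too small for the rod: mask touches the border")
    return mask


def _check_inside(mask: np.ndarray, positions: Sequence[tuple[float, float]]) -> None:
    for x, y in positions:
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]) or not mask[iy, ix]:
            raise ValueError(f"position ({x}, {y}) lies outside the cell mask")


def gaussian_spots(
    shape: tuple[int, int],
    positions: Sequence[tuple[float, float]],
    amplitudes: Sequence[float],
    sigma_px: float,
) -> np.ndarray:
    """Noiseless sum of isotropic 2-D Gaussians (peak-amplitude convention)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    for (x, y), a in zip(positions, amplitudes):
        img += a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2))
    return img


def render_foci(
    mask: np.ndarray,
    focus_positions: Sequence[tuple[float, float]],
    amplitudes: float | Sequence[float],
    psf_sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> np.ndarray:
    """Render diffraction-limited foci inside a cell mask.

    Each focus is an isotropic Gaussian of the given peak amplitude with
    sigma ``psf_sigma_nm``; the total signal above background per focus is
    ``amplitude * 2 * pi * sigma_px**2``.  Positions are ``(x, y)`` pixel
    coordinates and must lie inside the mask.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    _check_inside(mask, focus_positions)
    if np.isscalar(amplitudes):
        amplitudes = [float(amplitudes)] * len(focus_positions)
    sigma_px = nm_to_px(psf_sigma_nm, pixel_size_nm)
    clean = gaussian_spots(mask.shape, focus_positions, amplitudes, sigma_px)
    return noise.apply(clean, np.random.default_rng(seed))


def simulate_confined_walk(
    center: tuple[float, float],
    confinement_radius_um: float,
    step_sigma_um: float,
    n_frames: int,
    seed: int = 0,
) -> np.ndarray:
    """Random walk confined to a hard-walled disk about ``center``.

    Steps are isotropic Gaussian with SD ``step_sigma_um``; a proposed step
    that would leave the disk of radius ``confinement_radius_um`` is redrawn
    until it lands inside, so no position ever violates the confinement and
    in the large-step limit positions approach the uniform distribution on
    the disk (mean distance from center 2R/3).  Returns an ``(n_frames, 2)``
    array of ``(x, y)`` positions in µm.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if confinement_radius_um < 0:
        raise ValueError("confinement_radius_um must be >= 0")
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    R = float(confinement_radius_um)
    pos = np.empty((n_frames, 2), dtype=float)
    if R == 0.0:
        pos[:] = center
        return pos
    # start at a uniform random point of the disk (observation begins at an
    # arbitrary phase of the confined motion)
    theta = rng.uniform(0, 2 * np.pi)
    r0 = R * np.sqrt(rng.uniform())
    pos[0] = center + r0 * np.array([np.cos(theta), np.sin(theta)])
    if step_sigma_um == 0.0:
        pos[:] = pos[0]
        return pos
    cur = pos[0].copy()
    for i in range(1, n_frames):
        while True:
            cand = cur + rng.normal(0.0, step_sigma_um, size=2)
            if np.hypot(*(cand - center)) <= R:
                break
        cur = cand
        pos[i] = cur
    return pos


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and unit major/minor axes of a boolean mask (PCA on pixels)."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    minor = evecs[:, np.argmin(evals)]
    return centroid, major, minor


def render_nucleoid(
    mask: np.ndarray,
    area_fraction: float,
    axis: Literal["long", "short"] = "long",
    blur_sigma_nm: float = 66.0,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    cytoplasm_level: float = 50.0,
    nucleoid_level: float = 150.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a DAPI-like channel with a nucleoid of known area fraction.

    The true nucleoid is the ``area_fraction`` of mask pixels closest to the
    centroid along the chosen principal axis (``axis='short'`` compresses
    the region along the cell's short axis, ``'long'`` along its length), so
    the achieved pixel count matches the target to within one quantization
    step.  The region is rendered at ``nucleoid_level`` over a
    ``cytoplasm_level`` cytoplasm, blurred, and noised; the true pixel set
    is returned unblurred.

    Returns ``(image, true_region)``.
    """
    from scipy.ndimage import binary_erosion, gaussian_filter

    if not (0.0 < area_fraction <= 1.0):
        raise ValueError("area_fraction must be in (0, 1]")
    if axis not in ("long", "short"):
        raise ValueError(f"axis must be 'long' or 'short', got {axis!r}")
    centroid, major, minor = _principal_axes(mask)
    axis_vec = minor if axis == "short" else major
    # the nucleoid is radially centered in a real cell, so membrane-adjacent
    # pixels stay cytoplasmic: prefer interior (1 px inset) pixels and spill
    # into the rim only when the requested fraction demands it
    interior = binary_erosion(mask)
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float) - centroid
    coord = np.abs(pts @ axis_vec)
    is_interior = interior[ys, xs]
    order = np.lexsort((coord, ~is_interior))  # interior first, closest first
    k = int(round(area_fraction * len(coord)))
    k = max(1, min(k, len(coord)))
    keep = order[:k]
    region = np.zeros_like(mask)
    region[ys[keep], xs[keep]] = True

    clean = np.zeros(mask.shape, dtype=float)
    clean[mask] = cytoplasm_level
    clean[region] = nucleoid_level
    clean = gaussian_filter(clean, nm_to_px(blur_sigma_nm, pixel_size_nm))
    image = noise.apply(clean, np.random.default_rng(seed))
    return image, region


def render_mcda_pattern(
    mask: np.ndarray,
    mode: Literal["polar_gradient", "diffuse", "puncta"],
    phase: float = 0.0,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    amplitude: float = 300.0,
    decay_length_frac: float = 0.2,
    n_puncta: int = 3,
    psf_sigma_nm: float = DEFAULT_PSF_SIGMA_NM,
) -> np.ndarray:
    """Render a partitioning-protein channel in one of three regimes.

    ``polar_gradient``
        exponential decay from one pole along the long axis, with decay
        length ``decay_length_frac`` of the cell length; the bright pole is
        the low-coordinate pole for ``phase < 0.5`` and the opposite pole
        otherwise, so a phase ramp produces pole-to-pole oscillation.
    ``diffuse``
        flat ``amplitude`` inside the mask.
    ``puncta``
        ``n_puncta`` bright Gaussian spots at seed-deterministic interior
        positions.
    """
    if not (0.0 <= phase < 1.0):
        raise ValueError("phase must be in [0, 1)")
    rng = np.random.default_rng(seed)
    clean = np.zeros(mask.shape, dtype=float)
    if mode == "diffuse":
        clean[mask] = amplitude
    elif mode == "polar_gradient":
        centroid, major, _ = _principal_axes(mask)
        ys, xs = np.nonzero(mask)
        u = (np.column_stack([xs, ys]) - centroid) @ major
        u = u - u.min()  # distance from the low-coordinate pole, px
        if phase >= 0.5:
            u = u.max() - u
        lam = decay_length_frac * (u.max() if u.max() > 0 else 1.0)
        clean[ys, xs] = amplitude * np.exp(-u / lam)
    elif mode == "puncta":
        positions = puncta_positions(mask, n_puncta, seed)
        sigma_px = nm_to_px(psf_sigma_nm, pixel_size_nm)
        clean = gaussian_spots(mask.shape, positions, [amplitude] * len(positions), sigma_px)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return noise.apply(clean, rng)


def puncta_positions(mask: np.ndarray, n: int, seed: int) -> list[tuple[float, float]]:
    """Seed-deterministic well-separated interior positions for puncta mode."""
    from scipy.ndimage import distance_transform_edt

    interior = distance_transform_edt(mask) >= 3.0
    ys, xs = np.nonzero(interior if interior.any() else mask)
    rng = np.random.default_rng(seed)
    chosen: list[tuple[float, float]] = []
    order = rng.permutation(len(ys))
    for idx in order:
        p = (float(xs[idx]), float(ys[idx]))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= 6.0 for q in chosen):
            chosen.append(p)
        if len(chosen) == n:
            break
    if len(chosen) < n:  # crowded mask: fill without the separation guard
        for idx in order:
            p = (float(xs[idx]), float(ys[idx]))
            if p not in chosen:
                chosen.append(p)
            if len(chosen) == n:
                break
    return chosen


def apply_drift(stack: np.ndarray, drift_truth: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Translate each frame of a (time, channel, row, col) stack by its drift.

    ``drift_truth`` is an ``(n_frames, 2)`` array of integer ``(dy, dx)``
    shifts, one per time point, applied identically to every channel;
    the first entry must be ``(0, 0)``.  Vacated pixels are set to ``fill``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError("stack must be 4-D (time, channel, row, col)")
    drift = np.asarray(drift_truth)
    if drift.shape != (stack.shape[0], 2):
        raise ValueError("drift_truth must be (n_frames, 2)")
    if not np.all(drift == np.round(drift)):
        raise ValueError("drift shifts must be integers")
    if tuple(drift[0]) != (0, 0):
        raise ValueError("drift at frame 0 must be (0, 0)")
    out = np.empty_like(stack, dtype=float)
    for t in range(stack.shape[0]):
        dy, dx = int(drift[t, 0]), int(drift[t, 1])
        for c in range(stack.shape[1]):
            out[t, c] = translate_image(stack[t, c].astype(float), dy, dx, fill)
    return out


def render_correlated_pair(
    mask: np.ndarray,
    rho: float,
    seed: int = 0,
    mean: float = 100.0,
    sigma: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two images whose in-mask pixels have population correlation ``rho``.

    In-mask pixel pairs are bivariate normal with the given correlation;
    out-of-mask pixels are set to the common mean.  At ``rho = 1`` the
    second image is exactly the first.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    n = int(mask.sum())
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    zb = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
    a = np.full(mask.shape, mean, dtype=float)
    b = np.full(mask.shape, mean, dtype=float)
    a[mask] = mean + sigma * z1
    b[mask] = mean + sigma * zb
    return a, b


# ---------------------------------------------------------------------------
# Whole-field scenes


@dataclass
class SyntheticScene:
    """A rendered multi-channel field of view plus its ground truth.

    ``stack`` is a (time, channel, row, col) float array with channels in
    ``channel_names`` order; the drifted variant (if drift was requested) is
    in ``drifted_stack``.  All truth coordinates refer to the undrifted
    frame; per-frame stage drift is recorded separately in ``drift_truth``.
    """

    stack: np.ndarray
    channel_names: list[str]
    label_map: np.ndarray
    cell_masks: list[np.ndarray]
    focus_truth: pd.DataFrame  # cell_id, focus_id, frame, x, y, r_conf_um
    nucleoid_truth: pd.DataFrame  # cell_id, area_fraction, axis, n_pixels
    nucleoid_masks: list[np.ndarray]
    mcda_mode: str
    mcda_phases: np.ndarray
    drift_truth: np.ndarray
    drifted_stack: np.ndarray | None
    rho_truth: float | None
    seed: int
    pixel_size_nm: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_masks)

    def channel(self, name: str) -> np.ndarray:
        return self.stack[:, self.channel_names.index(name)]


def make_scene(
    n_cells: int = 6,
    n_frames: int = 1,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    cell_length_um: tuple[float, float] = (2.5, 4.0),
    cell_width_um: float = 1.0,
    n_foci_per_cell: int = 3,
    focus_amplitude: float = 500.0,
    confinement_radius_um: float = 0.1,
    step_sigma_um: float = 0.1,
    mcda_mode: str = "diffuse",
    oscillation_period_frames: int = 8,
    nucleoid_area_fraction: float = 0.6,
    nucleoid_axis: str = "long",
    rho: float | None = None,
    drift_sigma_px: float = 0.0,
    noise: NoiseModel = DEFAULT_NOISE,
    seed: int = 0,
    random_orientation: bool = True,
) -> SyntheticScene:
    """Assemble a multi-cell, multi-channel, optionally time-lapse scene.

    Cells are spherocylinders placed on a non-touching tile grid with
    random lengths and orientations.  Channels rendered: ``phase`` (dark
    cells on a bright background), ``foci`` (carboxysome-like spots on
    confined walks), ``mcda`` (per ``mcda_mode``; for ``polar_gradient``
    the bright pole alternates with ``oscillation_period_frames``),
    ``dapi`` (nucleoid at ``nucleoid_area_fraction``), and, when ``rho``
    is given, a correlated pair ``colocA``/``colocB``.
    """
    rng = np.random.default_rng(seed)
    max_len_px = um_to_px(cell_length_um[1], pixel_size_nm)
    tile = int(np.ceil(max_len_px)) + 14
    n_cols = int(np.ceil(np.sqrt(n_cells)))
    n_rows = int(np.ceil(n_cells / n_cols))
    shape = (n_rows * tile, n_cols * tile)

    label_map = np.zeros(shape, dtype=np.int32)
    cell_masks: list[np.ndarray] = []
    cell_params: list[dict] = []
    for k in range(n_cells):
        r, c = divmod(k, n_cols)
        length = float(rng.uniform(*cell_length_um))
        orient = float(rng.uniform(0.0, 180.0)) if random_orientation else 0.0
        center = ((c + 0.5) * tile - 0.5, (r + 0.5) * tile - 0.5)
        mask = make_cell_mask(
            length,
            cell_width_um,
            pixel_size_nm,
            orientation_deg=orient,
            shape=shape,
            center=center,
        )
        cell_masks.append(mask)
        label_map[mask] = k + 1
        cell_params.append({"length_um": length, "orientation_deg": orient, "center": center})

    psf_sigma_px = nm_to_px(DEFAULT_PSF_SIGMA_NM, pixel_size_nm)

    # --- focus ground truth: confined walks about points on the long axis
    focus_rows = []
    for k, (mask, par) in enumerate(zip(cell_masks, cell_params)):
        centroid, major, _ = _principal_axes(mask)
        L_px = um_to_px(par["length_um"], pixel_size_nm)
        offsets = np.linspace(-0.3, 0.3, n_foci_per_cell) * L_px
        for j, off in enumerate(offsets):
            anchor = centroid + off * major
            walk_um = simulate_confined_walk(
                (anchor[0] * pixel_size_nm / 1000.0, anchor[1] * pixel_size_nm / 1000.0),
                confinement_radius_um,
                step_sigma_um,
                max(n_frames, 10),
                seed=int(rng.integers(2**31)),
            )[:n_frames]
            for t, (x_um, y_um) in enumerate(walk_um):
                x_px = um_to_px(x_um, pixel_size_nm)
                y_px = um_to_px(y_um, pixel_size_nm)
                focus_rows.append(
                    {
                        "cell_id": k + 1,
                        "focus_id": j,
                        "frame": t,
                        "x": x_px,
                        "y": y_px,
                        "r_conf_um": confinement_radius_um,
                    }
                )
    focus_truth = pd.DataFrame(focus_rows)

    # --- nucleoid ground truth (static across frames)
    nuc_rows, nucleoid_masks, dapi_clean_cells = [], [], []
    for k, mask in enumerate(cell_masks):
        img, region = render_nucleoid(
            mask,
            nucleoid_area_fraction,
            axis=nucleoid_axis,
            noise=NOISELESS,
            seed=0,
            pixel_size_nm=pixel_size_nm,
        )
        nucleoid_masks.append(region)
        dapi_clean_cells.append(img)
        nuc_rows.append(
            {
                "cell_id": k + 1,
                "area_fraction": nucleoid_area_fraction,
                "axis": nucleoid_axis,
                "n_pixels": int(region.sum()),
            }
        )
    nucleoid_truth = pd.DataFrame(nuc_rows)
    dapi_clean = np.sum(dapi_clean_cells, axis=0)

    # --- phase contrast: dark rods on a bright background
    phase_clean = np.full(shape, 100.0)
    phase_clean[label_map > 0] = -50.0  # NoiseModel adds `background` on top

    mcda_phases = (np.arange(n_frames) % oscillation_period_frames) / oscillation_period_frames

    channel_names = ["phase", "foci", "mcda", "dapi"]
    rho_imgs = None
    if rho is not None:
        a = np.zeros(shape)
        b = np.zeros(shape)
        for mask in cell_masks:
            ai, bi = render_correlated_pair(
                mask, rho, seed=int(rng.integers(2**31)), mean=0.0, sigma=20.0
            )
            a += np.where(mask, ai, 0.0)
            b += np.where(mask, bi, 0.0)
        rho_imgs = (a, b)
        channel_names += ["colocA", "colocB"]

    stack = np.zeros((n_frames, len(channel_names)) + shape, dtype=float)
    for t in range(n_frames):
        frame_seed = int(rng.integers(2**31))
        frng = np.random.default_rng(frame_seed)
        stack[t, 0] = noise.apply(phase_clean, frng)

        sel = focus_truth[focus_truth.frame == t]
        foci_clean = gaussian_spots(
            shape,
            list(zip(sel.x, sel.y)),
            [focus_amplitude] * len(sel),
            psf_sigma_px,
        )
        stack[t, 1] = noise.apply(foci_clean, frng)

        mcda_clean = np.zeros(shape)
        for k, mask in enumerate(cell_masks):
            mcda_clean += np.where(
                mask,
                render_mcda_pattern(
                    mask,
                    mcda_mode,
                    phase=float(mcda_phases[t]),
                    noise=NOISELESS,
                    seed=seed * 1000 + k,
                    pixel_size_nm=pixel_size_nm,
                ),
                0.0,
            )
        stack[t, 2] = noise.apply(mcda_clean, frng)
        stack[t, 3] = noise.apply(dapi_clean, frng)
        if rho_imgs is not None:
            stack[t, 4] = noise.apply(rho_imgs[0], frng)
            stack[t, 5] = noise.apply(rho_imgs[1], frng)

    drift_truth = np.zeros((n_frames, 2), dtype=int)
    drifted = None
    if drift_sigma_px > 0 and n_frames > 1:
        steps = np.round(rng.normal(0, drift_sigma_px, size=(n_frames - 1, 2))).astype(int)
        drift_truth[1:] = np.cumsum(steps, axis=0)
        drifted = apply_drift(stack, drift_truth, fill=noise.background)

    return SyntheticScene(
        stack=stack,
        channel_names=channel_names,
        label_map=label_map,
        cell_masks=cell_masks,
        focus_truth=focus_truth,
        nucleoid_truth=nucleoid_truth,
        nucleoid_masks=nucleoid_masks,
        mcda_mode=mcda_mode,
        mcda_phases=mcda_phases,
        drift_truth=drift_truth,
        drifted_stack=drifted,
        rho_truth=rho,
        seed=seed,
        pixel_size_nm=pixel_size_nm,
    )


def save_scene(scene: SyntheticScene, out_dir) -> None:
    """Write a scene to disk: TIFF stack + JSON metadata + truth CSVs."""
    import json
    from pathlib import Path

    from bactorg.stackio import ImageStack, write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(
        ImageStack(scene.stack, scene.channel_names, scene.pixel_size_nm),
        out / "scene.tif",
    )
    scene.focus_truth.to_csv(out / "focus_truth.csv", index=False)
    scene.nucleoid_truth.to_csv(out / "nucleoid_truth.csv", index=False)
    pd.DataFrame(scene.drift_truth, columns=["dy", "dx"]).to_csv(
        out / "drift_truth.csv", index_label="frame"
    )
    import tifffile

    tifffile.imwrite(out / "labels.tif", scene.label_map.astype(np.uint16))
    params = {
        "seed": scene.seed,
        "pixel_size_nm": scene.pixel_size_nm,
        "mcda_mode": scene.mcda_mode,
        "rho_truth": scene.rho_truth,
        "n_cells": scene.n_cells,
    }
    (out / "scene.json").write_text(json.dumps(params, indent=2))
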