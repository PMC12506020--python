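"""Experiment orchestration: run all stages, pool replicates, remove outliers.

``run_experiment`` executes register -> segment -> focus detection ->
tracking -> nucleoid -> oscillation -> colocalization -> density map on a
synthetic scene (or user-supplied stack) and returns tidy per-cell tables;
``remove_outliers`` implements the ROUT procedure (robust center/scale
plus FDR-controlled outlier tests) on the constant model, and
``summarize_replicates`` pools technical replicates and reports per
biological replicate medians/IQRs and means/SDs.  Hypothesis testing is
deliberately left to downstream statistics tools; the tables emitted here
are their input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from bactorg import cellmap, cellseg, coloc, focidet, nucmorph, oscillo, stackio, synthgen, trackconf

DEFAULT_ROUT_Q = 0.01


# ---------------------------------------------------------------------------
# Outlier removal (ROUT, constant model)


def remove_outliers(values, method: str = "ROUT", Q: float = DEFAULT_ROUT_Q):
    """Flag outliers by the ROUT procedure applied to the constant model.

    The robust center is the median; the robust scale (RSDR) is the
    68.27th percentile of the absolute residuals corrected by n/(n-1).
    Each value's two-tailed P against a t distribution (df = n-1) is
    tested at false-discovery rate ``Q`` (step-up over the most extreme
    residuals).  Fewer than 5 values: nothing is removed and the result is
    flagged.

    Returns ``(retained_values, outlier_flags, flagged)``.
    """
    if method != "ROUT":
        raise ValueError(f"unknown method {method!r}")
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    flags = np.zeros(n, dtype=bool)
    if n < 5:
        return vals, flags, True
    res = vals - np.median(vals)
    absres = np.abs(res)
    rsdr = float(np.percentile(absres, 68.27)) * n / (n - 1)
    if rsdr == 0:
        flags = absres > 0
        return vals[~flags], flags, False
    t = absres / rsdr
    pvals = 2.0 * sps.t.sf(t, df=n - 1)
    order = np.argsort(pvals)  # most extreme first
    thresh = Q * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresh
    k = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    flags[order[:k]] = True
    return vals[~flags], flags, False


def summarize_replicates(records: pd.DataFrame, metrics: list[str] | None = None, Q: float = DEFAULT_ROUT_Q) -> pd.DataFrame:
    """Per-condition, per-biological-replicate summaries after outlier removal.

    ``records`` must carry ``condition`` and ``biological_replicate``
    columns (technical replicates are assumed already pooled into their
    biological replicate).  For each numeric metric the median, quartiles
    (linear-interpolation convention), mean and SD of the retained values
    are reported along with the retained cell count.
    """
    for col in ("condition", "biological_replicate"):
        if col not in records.columns:
            raise ValueError(f"records must carry a {col!r} column")
    if metrics is None:
        metrics = [
            c
            for c in records.columns
            if c not in ("condition", "biological_replicate", "cell_id")
            and np.issubdtype(records[c].dtype, np.number)
        ]
    rows = []
    for (cond, rep), grp in records.groupby(["condition", "biological_replicate"], sort=True):
        for m in metrics:
            vals = grp[m].dropna().to_numpy()
            if len(vals) == 0:
                continue
            retained, _, _ = remove_outliers(vals, Q=Q)
            rows.append(
                dict(
                    condition=cond,
                    biological_replicate=rep,
                    metric=m,
                    n_cells=len(retained),
                    median=float(np.median(retained)),
                    q1=float(np.percentile(retained, 25)),
                    q3=float(np.percentile(retained, 75)),
                    mean=float(np.mean(retained)),
                    sd=float(np.std(retained, ddof=1)) if len(retained) > 1 else 0.0,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end run


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_experiment(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage of the analysis on one (synthetic) experiment.

    ``config`` keys:

    * ``scene``: keyword arguments for :func:`bactorg.synthgen.make_scene`
      (or ``stack_path`` naming a TIFF written by :mod:`bactorg.stackio`);
    * ``condition``, ``biological_replicate``: labels for the tables;
    * ``detection``: overrides for :class:`bactorg.focidet.DetectionParams`;
    * ``seed``: RNG seed for the scene.

    Returns a dict with per-cell ``metrics`` (a
    :class:`pandas.DataFrame`), ``tracks``, ``confinement``, the
    :class:`bactorg.cellmap.DensityMap`, and the run ``manifest``.  When
    ``out_dir`` is given all tables are written as CSV plus a manifest
    JSON; outputs are byte-identical across reruns with identical config.
    """
    cfg = dict(config)
    condition = cfg.get("condition", "synthetic")
    replicate = cfg.get("biological_replicate", 1)
    seed = int(cfg.get("seed", 0))
    scene_cfg = dict(cfg.get("scene", {}))

    scene = synthgen.make_scene(seed=seed, **scene_cfg)
    pixel_size = scene.pixel_size_nm
    stack = stackio.ImageStack(
        scene.drifted_stack if scene.drifted_stack is not None else scene.stack,
        scene.channel_names,
        pixel_size,
    )

    # registration (no-op for driftless scenes, recovers injected drift otherwise)
    registered, shifts = stackio.register_stack(stack, reference_channel="phase")
    pixels = registered.pixels

    # segmentation on frame-0 phase contrast
    labels = cellseg.segment_cells(pixels[0, 0], backend="threshold", pixel_size_nm=pixel_size)
    morphs = {m.cell_id: m for m in cellseg.cell_morphology(labels, pixel_size)}
    masks = {cid: labels == cid for cid in morphs}

    det_params = focidet.DetectionParams(**cfg.get("detection", {}))
    foci_ch = scene.channel_names.index("foci")
    mcda_ch = scene.channel_names.index("mcda")
    dapi_ch = scene.channel_names.index("dapi")

    # focus detection per cell per frame
    detections: list[focidet.FocusDetection] = []
    for cid, mask in masks.items():
        for t in range(pixels.shape[0]):
            dets = focidet.detect_foci(
                pixels[t, foci_ch], mask, det_params, cell_id=cid, frame=t,
                raw_image=pixels[t, foci_ch],
            )
            detections.extend(dets)
    det_df = pd.DataFrame(
        [dict(cell_id=d.cell_id, frame=d.frame, x=d.x, y=d.y, r=d.r, quality=d.quality, intensity=d.intensity) for d in detections]
    )

    # tracking per cell, confinement radii
    track_rows, conf_rows = [], []
    next_track_id = 0
    if len(det_df) and pixels.shape[0] >= 2:
        for cid in morphs:
            sub = det_df[det_df.cell_id == cid]
            per_frame = [
                list(zip(sub[sub.frame == t].x, sub[sub.frame == t].y))
                for t in range(pixels.shape[0])
            ]
            tracks = trackconf.link_tracks(per_frame)
            for tr in tracks:
                tr.cell_id = cid
                tr.track_id = next_track_id
                next_track_id += 1
                for f, (x, y) in zip(tr.frames, tr.xy):
                    track_rows.append(dict(cell_id=cid, track_id=tr.track_id, frame=int(f), x=x, y=y))
                cr = trackconf.confinement_radius(tr, pixel_size)
                conf_rows.append(dict(cell_id=cid, track_id=tr.track_id, radius_px=cr.radius_px, radius_um=cr.radius_um, n_used=cr.n_used))
    tracks_df = pd.DataFrame(track_rows)
    conf_df = pd.DataFrame(conf_rows)

    # per-cell metrics
    rows = []
    for cid, morph in morphs.items():
        mask = masks[cid]
        cell_dets = [d for d in detections if d.cell_id == cid and d.frame == 0]
        fstats = focidet.focus_stats(cell_dets, morph, pixel_size, pixels[0, foci_ch], mask)
        nuc = nucmorph.analyze_cell(pixels[0, dapi_ch], mask, cell_id=cid, pixel_size_nm=pixel_size)
        prof = oscillo.oscillation_score(pixels[0, mcda_ch], mask, cell_id=cid)
        rec = dict(
            condition=condition,
            biological_replicate=replicate,
            cell_id=cid,
            length_um=morph.length_um,
            width_um=morph.width_um,
            area_um2=morph.area_um2,
            focus_count=fstats.focus_count,
            mean_focus_intensity=float(np.mean(fstats.intensities)) if fstats.intensities else np.nan,
            mean_nn_spacing_um=float(np.mean(fstats.nn_spacing_um)) if fstats.nn_spacing_um else np.nan,
            mean_medial_distance_um=float(np.mean(fstats.medial_distance_um)) if fstats.medial_distance_um else np.nan,
            whole_cell_intensity_per_length=fstats.whole_cell_intensity_per_length,
            s_comp=nuc.s_comp,
            background_b=nuc.background_b,
            oscillation_score=prof.oscillation_score,
        )
        if "colocA" in scene.channel_names:
            a = pixels[0, scene.channel_names.index("colocA")]
            b = pixels[0, scene.channel_names.index("colocB")]
            rec["pearson_r"] = coloc.pearson_per_cell(a, b, mask, cid).pearson_r
        if len(conf_df):
            cell_conf = conf_df[conf_df.cell_id == cid].radius_um
            rec["mean_confinement_radius_um"] = float(cell_conf.mean()) if len(cell_conf) else np.nan
        rows.append(rec)
    metrics = pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)

    # localization density map from frame-0 detections
    dmap = None
    if len(det_df):
        frame0 = det_df[det_df.frame == 0][["cell_id", "x", "y"]]
        frame0 = frame0[frame0.cell_id.isin(morphs)]
        grid = cellmap.bin_localizations(frame0, morphs, masks, pixel_size_nm=pixel_size)
        dmap = cellmap.density_map(grid, symmetrize=True)

    manifest = dict(
        config_hash=_config_hash(cfg),
        seed=seed,
        condition=condition,
        biological_replicate=replicate,
        n_cells_segmented=len(morphs),
        n_detections=len(det_df),
        n_tracks=int(tracks_df.track_id.nunique()) if len(tracks_df) else 0,
        registration_flagged_frames=shifts.flagged_frames,
    )

    result = dict(
        metrics=metrics,
        detections=det_df,
        tracks=tracks_df,
        confinement=conf_df,
        density_map=dmap,
        labels=labels,
        manifest=manifest,
        scene=scene,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "cell_metrics.csv", index=False)
        det_df.to_csv(out / "detections.csv", index=False)
        tracks_df.to_csv(out / "tracks.csv", index=False)
        conf_df.to_csv(out / "confinement.csv", index=False)
        if dmap is not None:
            dmap.bin_table.to_csv(out / "density_map.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result
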