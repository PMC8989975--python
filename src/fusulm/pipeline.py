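"""End-to-end pipeline: simulate, filter, map / track, and report.

All randomness flows from the single configuration seed; stage-local
seeds are spawned deterministically from it, so identical configurations
produce identical artifacts and reports (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .activation import HRFParams, build_design, delta_bv, extract_roi, glm_fit
from .clutter import process_stack
from .core import AcquisitionConfig
from .io import RunConfig, write_pd_series, write_stack, write_tracks_csv, write_ulm_maps
from .synthetic import VesselPath, make_paradigm_preset, simulate_bubble_stack, simulate_functional_stack
from .ulm import detect_bubbles, link_tracks, render_maps, track_velocities

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _array_hash(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _default_activation(grid_shape, n_active, rng) -> tuple[np.ndarray, np.ndarray]:
    """Smooth baseline vascular map and a compact activation blob."""
    import scipy.ndimage

    base = scipy.ndimage.gaussian_filter(rng.uniform(0.5, 1.5, grid_shape), 3)
    mask = np.zeros(grid_shape, dtype=bool)
    cz, cx = grid_shape[0] // 2, grid_shape[1] // 3
    zz, xx = np.ogrid[: grid_shape[0], : grid_shape[1]]
    dist = (zz - cz) ** 2 + (xx - cx) ** 2
    order = np.argsort(dist.ravel(), kind="stable")
    mask.ravel()[order[:n_active]] = True
    return base, mask


def _run_fus(config: RunConfig, out: Path, seeds: list[int]) -> dict:
    paradigm = make_paradigm_preset(config.paradigm, dt=0.1)
    acq = AcquisitionConfig(framerate=500.0, block_size=200,
                            n_blocks=int(paradigm.total_duration / 0.4), prf=5500.0,
                            angles_deg=tuple(np.linspace(-10, 10, 10)))
    rng = np.random.default_rng(seeds[0])
    baseline, mask = _default_activation(config.grid_shape, config.n_active_pixels, rng)
    hrf = HRFParams()
    stack, truth = simulate_functional_stack(
        acq, baseline, mask, config.amplitude, paradigm, hrf,
        tissue_rank=config.tissue_rank, tissue_to_blood_db=config.tissue_to_blood_db,
        noise_db=config.noise_db, seed=seeds[1], dtype=np.complex64,
    )
    series = process_stack(stack, n_remove=config.n_remove)
    write_pd_series(series, out / "power_doppler.h5")
    X = build_design(paradigm, hrf, series.n_frames, series.frame_interval)
    amap = glm_fit(series, X, alpha=config.alpha)
    roi = extract_roi(amap)
    trace = delta_bv(series, roi, paradigm)
    np.savetxt(out / "dbv_trace.csv",
               np.column_stack([trace.t, trace.dbv, trace.stim_mask.astype(int)]),
               delimiter=",", header="t,dbv,stim", comments="")
    overlap = (roi.mask & truth.activation_mask).sum() / truth.activation_mask.sum()
    return {
        "stage": "fus",
        "paradigm": config.paradigm,
        "n_pd_frames": int(series.n_frames),
        "frame_interval_s": series.frame_interval,
        "n_significant_pixels": int(amap.n_significant),
        "roi_pixels": int(roi.n_pixels),
        "true_mask_overlap": float(overlap),
        "dbv_stim_pct": trace.dbv_stim,
        "dbv_bl_pct": trace.dbv_bl,
        "expected_dbv_stim_pct": truth.expected_dbv_stim,
        "pd_hash": _array_hash(series.images),
    }


def _default_vessels(grid_shape, acq: AcquisitionConfig) -> list[VesselPath]:
    z_max = grid_shape[0] * acq.pixel_dz_mm
    x_max = grid_shape[1] * acq.pixel_dx_mm
    return [
        VesselPath(((0.25 * z_max, 0.05 * x_max), (0.30 * z_max, 0.95 * x_max)),
                   flow_speed=12.0, direction=1),
        VesselPath(((0.55 * z_max, 0.05 * x_max), (0.50 * z_max, 0.95 * x_max)),
                   flow_speed=16.0, direction=-1),
        VesselPath(((0.10 * z_max, 0.50 * x_max), (0.90 * z_max, 0.60 * x_max)),
                   flow_speed=10.0, direction=1),
    ]


def _run_ulm(config: RunConfig, out: Path, seeds: list[int]) -> dict:
    acq = AcquisitionConfig(framerate=1000.0, block_size=400, n_blocks=config.ulm_n_blocks,
                            prf=5000.0, angles_deg=(-5, -2, 0, 2, 5))
    vessels = _default_vessels(config.grid_shape, acq)
    stack, truth = simulate_bubble_stack(
        acq, vessels, config.grid_shape,
        bubbles_per_frame=config.ulm_bubbles_per_frame,
        psf_sigma_mm=config.ulm_psf_sigma_mm,
        tissue_rank=config.tissue_rank, tissue_to_bubble_db=config.tissue_to_blood_db,
        noise_db=None, seed=seeds[2],
    )
    from .clutter import svd_filter_block

    locs = []
    bs = acq.block_size
    for b in range(stack.n_t // bs):
        filt = svd_filter_block(stack.frames[:, :, b * bs : (b + 1) * bs], config.ulm_n_remove)
        for k in range(filt.shape[2]):
            locs.extend(detect_bubbles(filt[:, :, k], config.ulm_min_intensity,
                                       acq.pixel_dz_mm, acq.pixel_dx_mm,
                                       frame_index=b * bs + k))
    tracks = link_tracks(locs, config.ulm_max_link_mm, min_length=config.ulm_min_length)
    tracks = [track_velocities(t, acq.framerate) for t in tracks]
    write_tracks_csv(tracks, out / "tracks.csv")
    extent = (config.grid_shape[0] * acq.pixel_dz_mm, config.grid_shape[1] * acq.pixel_dx_mm)
    maps = render_maps(tracks, extent, pixel_um=config.ulm_pitch_um)
    write_ulm_maps(maps, out)
    speeds = np.concatenate([t.speed for t in tracks]) if tracks else np.array([np.nan])
    return {
        "stage": "ulm",
        "n_localizations": len(locs),
        "n_tracks": len(tracks),
        "n_true_tracks": len(truth.tracks),
        "speed_quantiles_mm_s": {q: float(np.nanpercentile(speeds, q)) for q in (10, 50, 90)},
        "density_total": int(maps.density.sum()),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the configured pipeline and write artifacts plus ``report.json``.

    The report records package and library versions, the configuration,
    content hashes of intermediate arrays, and the summary statistics of
    each stage. Any stage failure aborts with the stage name in the
    exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = _stage_seeds(config.seed, 4)
    import scipy

    report = {
        "versions": {"fusulm": __version__, "numpy": np.__version__, "scipy": scipy.__version__},
        "config": {**config.__dict__, "grid_shape": list(config.grid_shape)},
        "stage_seeds": seeds,
    }
    stage = config.mode
    try:
        if config.mode == "fus":
            report["results"] = _run_fus(config, out, seeds)
        else:
            report["results"] = _run_ulm(config, out, seeds)
    except Exception as exc:
        report["error"] = {"stage": stage, "cause": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
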