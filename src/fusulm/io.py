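"""File formats: HDF5 / TIFF frame stacks, Power Doppler series, track
tables, ULM maps, and YAML run configuration.

HDF5 layout for a frame stack:

* ``/frames/real`` and ``/frames/imag`` — float64 datasets (imag omitted
  for real stacks);
* ``/meta`` — group whose attributes carry the acquisition metadata
  (framerate, block_size, n_blocks, prf, angles_deg, pixel_dz_mm,
  pixel_dx_mm, depth_mm, t0).

Multi-frame 32-bit TIFF export stores magnitudes only (phase is lost,
with a warning for complex data) and embeds the metadata as a JSON image
description so the round trip is self-contained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .clutter import PowerDopplerSeries
from .core import AcquisitionConfig, FrameStack
from .ulm import Track, ULMMaps

__all__ = [
    "read_stack",
    "write_stack",
    "read_pd_series",
    "write_pd_series",
    "tracks_to_frame",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_ulm_maps",
    "RunConfig",
]

log = logging.getLogger(__name__)

_META_FIELDS = ("framerate", "block_size", "n_blocks", "pixel_dz_mm", "pixel_dx_mm", "depth_mm")


def _config_to_attrs(config: AcquisitionConfig, t0: float) -> dict:
    attrs = {f: getattr(config, f) for f in _META_FIELDS}
    if config.prf is not None:
        attrs["prf"] = config.prf
    if config.angles_deg is not None:
        attrs["angles_deg"] = np.asarray(config.angles_deg)
    attrs["t0"] = t0
    return attrs


def _attrs_to_config(attrs: dict) -> tuple[AcquisitionConfig, float]:
    missing = [f for f in _META_FIELDS if f not in attrs]
    if missing:
        raise ValueError(f"missing metadata attributes: {missing}")
    kwargs = {f: attrs[f] for f in _META_FIELDS}
    kwargs["block_size"] = int(kwargs["block_size"])
    kwargs["n_blocks"] = int(kwargs["n_blocks"])
    if "prf" in attrs and attrs["prf"] is not None:
        kwargs["prf"] = float(attrs["prf"])
    if "angles_deg" in attrs and attrs["angles_deg"] is not None:
        kwargs["angles_deg"] = tuple(np.atleast_1d(attrs["angles_deg"]).tolist())
    config = AcquisitionConfig(**kwargs)
    return config, float(attrs.get("t0", 0.0))


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack to HDF5 (lossless, complex preserved) or to a
    multi-frame float32 TIFF (magnitude only) depending on the suffix."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        if stack.is_complex:
            log.warning("TIFF stores magnitudes only: phase information of %s is lost", path.name)
        data = np.abs(stack.frames).astype(np.float32)
        meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in _config_to_attrs(stack.config, stack.t0).items()}
        # pages are time frames: (n_t, n_z, n_x)
        tifffile.imwrite(path, np.moveaxis(data, 2, 0), description=json.dumps(meta))
        return
    with h5py.File(path, "w") as f:
        g = f.create_group("frames")
        g.create_dataset("real", data=stack.frames.real)
        if stack.is_complex:
            g.create_dataset("imag", data=stack.frames.imag)
        meta = f.create_group("meta")
        for k, v in _config_to_attrs(stack.config, stack.t0).items():
            meta.attrs[k] = v


def read_stack(path: str | Path) -> FrameStack:
    """Read a frame stack written by :func:`write_stack`."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        try:
            attrs = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            raise ValueError(f"TIFF {path} carries no metadata description") from None
        config, t0 = _attrs_to_config(attrs)
        return FrameStack(frames=np.moveaxis(data, 0, 2), config=config, t0=t0)
    with h5py.File(path, "r") as f:
        if "frames" not in f or "real" not in f["frames"]:
            raise ValueError(f"{path} does not contain a /frames/real dataset")
        real = f["frames/real"][()]
        frames = real + 1j * f["frames/imag"][()] if "imag" in f["frames"] else real
        if "meta" not in f:
            raise ValueError(f"missing metadata attributes: {list(_META_FIELDS)}")
        config, t0 = _attrs_to_config(dict(f["meta"].attrs))
    return FrameStack(frames=frames, config=config, t0=t0)


def write_pd_series(series: PowerDopplerSeries, path: str | Path) -> None:
    """Power Doppler series to HDF5 (``/pd`` images, ``/t`` timestamps) or
    multi-frame float32 TIFF."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, series.images.astype(np.float32))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("pd", data=series.images)
        f.create_dataset("t", data=series.timestamps())
        meta = f.create_group("meta")
        for k, v in _config_to_attrs(series.config, series.t0).items():
            meta.attrs[k] = v
        meta.attrs["frame_interval"] = series.frame_interval
        meta.attrs["n_removed"] = series.n_removed


def read_pd_series(path: str | Path) -> PowerDopplerSeries:
    with h5py.File(path, "r") as f:
        if "pd" not in f:
            raise ValueError(f"{path} does not contain a /pd dataset")
        images = f["pd"][()]
        attrs = dict(f["meta"].attrs)
        config, t0 = _attrs_to_config(attrs)
        return PowerDopplerSeries(
            images=images,
            frame_interval=float(attrs["frame_interval"]),
            config=config,
            n_removed=int(attrs["n_removed"]),
            t0=t0,
        )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format track table: track_id, frame, z_mm, x_mm, vz, vx, speed
    (velocities NaN on each track's last point)."""
    rows = []
    for tr in tracks:
        n = tr.n_points
        vz = np.append(tr.vz, np.nan) if tr.vz is not None else np.full(n, np.nan)
        vx = np.append(tr.vx, np.nan) if tr.vx is not None else np.full(n, np.nan)
        for k in range(n):
            rows.append({
                "track_id": tr.track_id, "frame": int(tr.frames[k]),
                "z_mm": tr.z_mm[k], "x_mm": tr.x_mm[k],
                "vz": vz[k], "vx": vx[k], "speed": float(np.hypot(vz[k], vx[k])),
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "z_mm", "x_mm", "vz", "vx", "speed"])


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        vz = sub["vz"].to_numpy(float)[:-1]
        vx = sub["vx"].to_numpy(float)[:-1]
        tracks.append(Track(
            track_id=int(tid),
            frames=sub["frame"].to_numpy(int),
            z_mm=sub["z_mm"].to_numpy(float),
            x_mm=sub["x_mm"].to_numpy(float),
            intensity=np.ones(len(sub)),
            vz=None if np.all(np.isnan(vz)) else vz,
            vx=None if np.all(np.isnan(vx)) else vx,
        ))
    return tracks


def write_ulm_maps(maps: ULMMaps, out_dir: str | Path, prefix: str = "ulm") -> dict[str, Path]:
    """Write density/speed/vz maps as float32 TIFF with the pixel pitch in
    the image metadata; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res_per_um = 1.0 / maps.pixel_um
    written = {}
    for name, img in (("density", maps.density.astype(np.float32)),
                      ("speed", maps.speed.astype(np.float32)),
                      ("vz", maps.vz.astype(np.float32))):
        p = out_dir / f"{prefix}_{name}.tif"
        tifffile.imwrite(p, img, resolution=(res_per_um, res_per_um),
                         description=json.dumps({"pixel_um": maps.pixel_um}))
        written[name] = p
    return written


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Parameters of a full simulate -> filter -> map / ulm run.

    Round-trips losslessly through YAML; every stage validates its own
    parameters against the stage preconditions before execution.
    """

    seed: int = 0
    mode: str = "fus"  # "fus" or "ulm"
    paradigm: str = "corneal_mech"
    grid_shape: tuple[int, int] = (24, 24)
    amplitude: float = 0.10
    n_active_pixels: int = 50
    tissue_rank: int = 3
    tissue_to_blood_db: float = 40.0
    noise_db: float = -20.0
    n_remove: int = 60
    alpha: float = 0.05
    # ULM stage
    ulm_n_blocks: int = 2
    ulm_n_remove: int = 10
    ulm_bubbles_per_frame: float = 0.05
    ulm_psf_sigma_mm: float = 0.1
    ulm_min_intensity: float = 0.3
    ulm_max_link_mm: float = 0.03
    ulm_min_length: int = 4
    ulm_pitch_um: float = 6.5
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("fus", "ulm"):
            raise ValueError(f"mode must be 'fus' or 'ulm', got {self.mode!r}")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2**31)")
        if self.amplitude <= -1:
            raise ValueError("amplitude must be > -1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.grid_shape = tuple(int(v) for v in self.grid_shape)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
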