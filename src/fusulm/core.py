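"""Core data containers shared across the fUS / ULM pipeline.

Coordinate conventions used throughout the package:

* ``z`` is depth in mm, positive downward; ``x`` is the lateral (probe)
  axis in mm.
* Frame stacks are arrays of shape ``(n_z, n_x, n_t)``.
* The centre of pixel ``(i, j)`` sits at ``((i + 0.5) * pixel_dz,
  (j + 0.5) * pixel_dx)`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["AcquisitionConfig", "FrameStack", "StimulusParadigm"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing of an ultrafast ultrasound scan.

    Parameters
    ----------
    framerate : float
        Compound frame rate in frames/second.
    block_size : int
        Number of consecutive ultrafast frames processed together (one
        SVD-filter block yields one Power Doppler image).
    n_blocks : int
        Number of blocks in the acquisition.
    prf : float, optional
        Pulse repetition frequency in Hz (per tilted plane-wave emission).
    angles_deg : sequence of float, optional
        Tilt angles of the compounded plane waves, in degrees.
    pixel_dz_mm, pixel_dx_mm : float
        Pixel pitch in depth and lateral direction, mm.
    depth_mm : float
        Imaging depth in mm.

    Notes
    -----
    When both ``prf`` and ``angles_deg`` are given the compound framerate
    cannot exceed ``prf / len(angles_deg)``; it may be lower because real
    sequences insert dead time between compounded frames.
    """

    framerate: float
    block_size: int
    n_blocks: int = 1
    prf: float | None = None
    angles_deg: tuple[float, ...] | None = None
    pixel_dz_mm: float = 0.1
    pixel_dx_mm: float = 0.1
    depth_mm: float = 12.0

    def __post_init__(self) -> None:
        if self.framerate <= 0:
            raise ValueError(f"framerate must be > 0, got {self.framerate}")
        if int(self.block_size) != self.block_size or self.block_size < 2:
            raise ValueError(f"block_size must be an integer >= 2, got {self.block_size}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.pixel_dz_mm <= 0 or self.pixel_dx_mm <= 0:
            raise ValueError("pixel spacings must be > 0")
        if self.angles_deg is not None:
            object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
        if self.prf is not None and self.angles_deg:
            max_rate = self.prf / len(self.angles_deg)
            if self.framerate > max_rate * (1 + 1e-9):
                raise ValueError(
                    f"framerate {self.framerate} Hz exceeds prf/n_angles = "
                    f"{max_rate:.6g} Hz; plane-wave compounding cannot run faster "
                    "than one frame per angle sweep"
                )

    @property
    def n_frames(self) -> int:
        """Total number of frames, ``block_size * n_blocks``."""
        return int(self.block_size) * int(self.n_blocks)

    @property
    def block_interval_s(self) -> float:
        """Time between successive Power Doppler images, seconds."""
        return self.block_size / self.framerate

    def grid_coords(self, n_z: int, n_x: int) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (z_mm, x_mm) for an ``n_z x n_x`` grid."""
        z = (np.arange(n_z) + 0.5) * self.pixel_dz_mm
        x = (np.arange(n_x) + 0.5) * self.pixel_dx_mm
        return z, x

    def replace(self, **kwargs) -> "AcquisitionConfig":
        return replace(self, **kwargs)


def fus_preset(n_blocks: int = 1) -> AcquisitionConfig:
    """Functional-ultrasound acquisition: blocks of 200 frames at 500 Hz,
    ten plane waves spanning -10..10 degrees at 5.5 kHz PRF."""
    return AcquisitionConfig(
        framerate=500.0,
        block_size=200,
        n_blocks=n_blocks,
        prf=5500.0,
        angles_deg=tuple(np.linspace(-10.0, 10.0, 10)),
    )


def ulm_preset(n_blocks: int = 750) -> AcquisitionConfig:
    """ULM acquisition: blocks of 400 compounded frames at 1000 Hz,
    five plane waves at 5 kHz PRF, 12 mm depth."""
    return AcquisitionConfig(
        framerate=1000.0,
        block_size=400,
        n_blocks=n_blocks,
        prf=5000.0,
        angles_deg=(-5.0, -2.0, 0.0, 2.0, 5.0),
        depth_mm=12.0,
    )


@dataclass
class FrameStack:
    """A beamformed ultrafast frame stack ``(n_z, n_x, n_t)``.

    Frames may be complex (IQ data) or real. ``t0`` is the acquisition
    start time in seconds.
    """

    frames: np.ndarray
    config: AcquisitionConfig
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n_z, n_x, n_t), got shape {self.frames.shape}")
        if not np.all(np.isfinite(self.frames.view(float) if np.iscomplexobj(self.frames) else self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_z(self) -> int:
        return self.frames.shape[0]

    @property
    def n_x(self) -> int:
        return self.frames.shape[1]

    @property
    def n_t(self) -> int:
        return self.frames.shape[2]

    @property
    def is_complex(self) -> bool:
        return bool(np.iscomplexobj(self.frames))

    def block(self, b: int) -> np.ndarray:
        """Return frames of block ``b`` as a view ``(n_z, n_x, block_size)``."""
        bs = self.config.block_size
        if not 0 <= b < self.n_t // bs:
            raise IndexError(f"block {b} out of range for {self.n_t // bs} complete blocks")
        return self.frames[:, :, b * bs : (b + 1) * bs]


@dataclass(frozen=True)
class StimulusParadigm:
    """Block-design stimulation paradigm.

    The paradigm is a binary indicator over time: 1 while a stimulus is
    applied, 0 otherwise. ``onsets`` and ``durations`` are in seconds.
    """

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    total_duration: float
    dt: float = 0.1
    name: str = ""

    def __post_init__(self) -> None:
        onsets = tuple(float(o) for o in self.onsets)
        durations = tuple(float(d) for d in self.durations)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if len(onsets) != len(durations):
            raise ValueError("onsets and durations must have equal length")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if any(d <= 0 for d in durations):
            raise ValueError("durations must be > 0")
        if list(onsets) != sorted(onsets):
            raise ValueError("onsets must be sorted")
        for (o1, d1), o2 in zip(zip(onsets, durations), onsets[1:]):
            if o1 + d1 > o2:
                raise ValueError(f"stimulation at t={o1} s overlaps the next onset at t={o2} s")
        for o, d in zip(onsets, durations):
            if o < 0 or o + d > self.total_duration + 1e-9:
                raise ValueError(
                    f"stimulation [{o}, {o + d}] s falls outside total_duration={self.total_duration} s"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def indicator(self) -> np.ndarray:
        """Binary indicator sampled on ``[k*dt, (k+1)*dt)`` bins (value at the
        left edge); integrates to the total stimulated time."""
        return self.indicator_at(self.times())

    def indicator_at(self, t: np.ndarray) -> np.ndarray:
        """Indicator evaluated at arbitrary times (1 iff some onset <= t < onset+duration)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        for o, d in zip(self.onsets, self.durations):
            out[(t >= o - 1e-12) & (t < o + d - 1e-12)] = 1.0
        return out

    def frame_stim_mask(self, n_frames: int, frame_interval: float, t0: float = 0.0) -> np.ndarray:
        """Boolean per-frame stimulation mask, sampled at frame centres."""
        t = t0 + (np.arange(n_frames) + 0.5) * frame_interval
        return self.indicator_at(t) > 0.5

    @property
    def total_stim_s(self) -> float:
        return float(sum(self.durations))
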