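"""SVD clutter rejection and Power Doppler formation.

Ultrafast frame blocks are dominated by slowly varying, high-amplitude
tissue signal ("clutter"). Reshaping a block ``(n_z, n_x, n_t)`` into its
Casorati matrix ``(n_z * n_x, n_t)`` separates clutter from blood under a
singular value decomposition: tissue concentrates in the largest singular
values, blood and noise in the remainder. The filter zeroes the
``n_remove`` largest singular values; the Power Doppler image integrates
the energy of the filtered frames over the block and is proportional to
the local blood volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import AcquisitionConfig, FrameStack

__all__ = [
    "CasoratiMatrix",
    "PowerDopplerSeries",
    "svd_filter_block",
    "power_doppler",
    "process_stack",
]

log = logging.getLogger(__name__)


@dataclass
class CasoratiMatrix:
    """Space-time reshaping of a frame block: rows are pixels (raster
    order), columns are frames."""

    matrix: np.ndarray  # (n_z * n_x, n_t)
    grid_shape: tuple[int, int]
    block_index: int = 0

    @classmethod
    def from_block(cls, block: np.ndarray, block_index: int = 0) -> "CasoratiMatrix":
        block = np.asarray(block)
        if block.ndim != 3:
            raise ValueError(f"block must be 3-D, got shape {block.shape}")
        n_z, n_x, n_t = block.shape
        return cls(block.reshape(n_z * n_x, n_t), (n_z, n_x), block_index)

    def to_block(self) -> np.ndarray:
        n_z, n_x = self.grid_shape
        return self.matrix.reshape(n_z, n_x, -1)


@dataclass
class PowerDopplerSeries:
    """One Power Doppler image per filtered block.

    ``images`` has shape ``(n_blocks, n_z, n_x)``; ``frame_interval`` is
    ``block_size / framerate`` seconds. Timestamps refer to block centres.
    """

    images: np.ndarray
    frame_interval: float
    config: AcquisitionConfig
    n_removed: int
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n_blocks, n_z, n_x), got {self.images.shape}")
        if np.any(self.images < 0):
            raise ValueError("Power Doppler values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.images.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def timestamps(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_frames) + 0.5) * self.frame_interval


def _casorati_svd_filter(M: np.ndarray, n_remove: int) -> tuple[np.ndarray, np.ndarray]:
    """Remove the rank-``n_remove`` leading SVD component of ``M``.

    Returns ``(filtered, singular_values)`` where ``singular_values`` is the
    full descending spectrum. Implemented through the temporal Gram matrix
    ``M^H M`` (n_t x n_t), much cheaper than a direct SVD for the tall
    matrices produced by imaging grids.
    """
    n_t = M.shape[1]
    gram = M.conj().T @ M
    # eigh returns ascending eigenvalues; reverse to descending
    evals, evecs = scipy.linalg.eigh(gram)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    svals = np.sqrt(np.clip(evals.real, 0.0, None))
    if n_remove == 0:
        return M.copy(), svals
    V_r = evecs[:, :n_remove]  # leading right singular vectors
    filtered = M - (M @ V_r) @ V_r.conj().T
    if not np.iscomplexobj(M):
        filtered = filtered.real
    return filtered, svals


def clutter_basis(block: np.ndarray | FrameStack, n_remove: int) -> np.ndarray:
    """Estimated clutter subspace: the ``n_remove`` leading right (temporal)
    singular vectors of the block's Casorati matrix, shape ``(n_t, n_remove)``.

    The filter is the orthogonal projection onto the complement of this
    subspace; reusing the basis makes repeated filtering idempotent and
    allows applying one block's tissue subspace to another block.
    """
    if isinstance(block, FrameStack):
        block = block.frames
    block = np.asarray(block)
    M = CasoratiMatrix.from_block(block).matrix
    gram = M.conj().T @ M
    _, evecs = scipy.linalg.eigh(gram)
    return evecs[:, ::-1][:, :n_remove]


def svd_filter_block(
    block: np.ndarray | FrameStack,
    n_remove: int,
    return_spectrum: bool = False,
    basis: np.ndarray | None = None,
):
    """SVD clutter filter of one frame block.

    Zeroes the ``n_remove`` largest singular values of the block's
    Casorati matrix (descending order: "first" = largest, the tissue
    space) and reshapes back to ``(n_z, n_x, n_t)``. Equivalently, the
    block is projected onto the orthogonal complement of the leading
    temporal subspace; pass ``basis`` (from :func:`clutter_basis`) to
    reuse a previously estimated subspace — the filter is then an exact
    projection and applying it twice equals applying it once.

    Parameters
    ----------
    block : ndarray or FrameStack
        Frames ``(n_z, n_x, n_t)``, complex or real.
    n_remove : int
        Number of leading singular values to remove; ``0 <= n_remove < n_t``.
    return_spectrum : bool
        Also return the full descending singular-value spectrum (ignored
        when ``basis`` is given).
    basis : ndarray, optional
        ``(n_t, k)`` orthonormal temporal clutter basis to project out
        instead of re-estimating it from ``block``.
    """
    if isinstance(block, FrameStack):
        block = block.frames
    block = np.asarray(block)
    if block.ndim != 3:
        raise ValueError(f"block must be 3-D (n_z, n_x, n_t), got shape {block.shape}")
    n_t = block.shape[2]
    if not 0 <= n_remove < n_t:
        raise ValueError(f"n_remove must satisfy 0 <= n_remove < n_t={n_t}, got {n_remove}")
    flat = block.view(float) if np.iscomplexobj(block) else block
    if not np.all(np.isfinite(flat)):
        raise ValueError("block contains non-finite values")

    cas = CasoratiMatrix.from_block(block)
    if basis is not None:
        M = cas.matrix
        filtered = M - (M @ basis) @ basis.conj().T
        if not np.iscomplexobj(M):
            filtered = filtered.real
        return filtered.reshape(block.shape)
    filtered, svals = _casorati_svd_filter(cas.matrix, int(n_remove))
    out = filtered.reshape(block.shape)
    if return_spectrum:
        return out, svals
    return out


def power_doppler(block: np.ndarray) -> np.ndarray:
    """Power Doppler image of a (filtered) block: per-pixel integral of the
    signal energy, ``sum_t |s(z, x, t)|**2``."""
    block = np.asarray(block)
    if block.ndim != 3 or block.shape[2] == 0:
        raise ValueError(f"block must be non-empty 3-D, got shape {block.shape}")
    return np.sum(np.abs(block) ** 2, axis=2)


def process_stack(
    stack: FrameStack,
    n_remove: int,
    block_size: int | None = None,
) -> PowerDopplerSeries:
    """Filter a frame stack block by block and form the Power Doppler series.

    Each complete block of ``block_size`` frames is SVD-filtered
    independently (no overlap) and integrated into one Power Doppler
    image; trailing frames not filling a block are dropped with a warning.
    """
    if block_size is None:
        block_size = stack.config.block_size
    n_t = stack.n_t
    if block_size > n_t:
        raise ValueError(f"block_size={block_size} exceeds the stack's {n_t} frames")
    n_blocks = n_t // block_size
    leftover = n_t - n_blocks * block_size
    if leftover:
        log.warning("dropping %d trailing frames that do not fill a %d-frame block", leftover, block_size)
    images = np.empty((n_blocks, stack.n_z, stack.n_x))
    for b in range(n_blocks):
        blk = stack.frames[:, :, b * block_size : (b + 1) * block_size]
        images[b] = power_doppler(svd_filter_block(blk, n_remove))
    return PowerDopplerSeries(
        images=images,
        frame_interval=block_size / stack.config.framerate,
        config=stack.config,
        n_removed=int(n_remove),
        t0=stack.t0,
    )
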