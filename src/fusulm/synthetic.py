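"""Seeded synthetic acquisitions with ground truth.

Two generators emulate the acquisitions the pipeline consumes:

* :func:`simulate_functional_stack` — functional ultrasound series: a
  low-rank, slowly varying, high-amplitude tissue component; a weak blood
  component modelled as Doppler-shifted, temporally decorrelating complex
  speckle whose power is modulated by the stimulus response inside an
  activation mask; and additive white noise.
* :func:`simulate_bubble_stack` — ULM movies: point-like microbubbles
  flowing along vessel polylines, rendered through a Gaussian
  diffraction-scale point-spread function, over the same tissue/noise
  background.

Neither generator simulates acoustic propagation; they reproduce the
*statistical* structure the downstream analyses assume (rank-limited
clutter, spectrally separated blood, point scatterers), which is what
makes recovery experiments meaningful.

dB conventions: ``tissue_to_blood_db`` (and ``tissue_to_bubble_db``,
``noise_db``) are amplitude ratios, ``20 * log10(a_num / a_den)``, with
blood RMS amplitude as the reference for noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .activation import HRFParams, build_design, hrf_kernel
from .core import AcquisitionConfig, FrameStack, StimulusParadigm

__all__ = [
    "VesselPath",
    "TrueTrack",
    "GroundTruth",
    "make_paradigm_preset",
    "simulate_functional_stack",
    "simulate_bubble_stack",
    "simulate_pd_series",
    "PARADIGM_PRESETS",
]

#: Nominal wavelength (mm) used to convert axial speed to Doppler shift,
#: f_d = 2 * v_z / wavelength; 0.1 mm corresponds to ~15 MHz in tissue.
WAVELENGTH_MM = 0.1


# ---------------------------------------------------------------------------
# stimulation paradigm presets
# ---------------------------------------------------------------------------

def _block_train(lead: float, n: int, dur: float, gap: float, tail: float) -> tuple[list, list, float]:
    onsets = [lead + k * (dur + gap) for k in range(n)]
    total = lead + n * dur + (n - 1) * gap + tail
    return onsets, [dur] * n, total


def _corneal(dt: float) -> StimulusParadigm:
    # six 10-s corneal strokes, 20-s gaps, 30-s rest before and after
    o, d, total = _block_train(30.0, 6, 10.0, 20.0, 30.0)
    return StimulusParadigm(tuple(o), tuple(d), total, dt, name="corneal_mech")


def _von_frey(dt: float) -> StimulusParadigm:
    # four 5-s static von Frey stimulations, 55-s gaps, 60-s rest before/after
    o, d, total = _block_train(60.0, 4, 5.0, 55.0, 60.0)
    return StimulusParadigm(tuple(o), tuple(d), total, dt, name="von_frey")


def _whisker(dt: float) -> StimulusParadigm:
    # six 20-s whisker-pad trains (4 Hz within the train), 20-s gaps; the
    # indicator marks the train envelope; 30-s rest padding is this
    # package's choice (not part of the cited design)
    o, d, total = _block_train(30.0, 6, 20.0, 20.0, 30.0)
    return StimulusParadigm(tuple(o), tuple(d), total, dt, name="whisker")


def _capsaicin(dt: float) -> StimulusParadigm:
    # 60-s baseline, then one 3-min topical capsaicin application; the
    # response is phasic, so this preset is unsuited to block-design GLM
    # analysis and is provided for dBV quantification only
    return StimulusParadigm((60.0,), (180.0,), 300.0, dt, name="capsaicin")


PARADIGM_PRESETS = {
    "corneal_mech": _corneal,
    "von_frey": _von_frey,
    "whisker": _whisker,
    "capsaicin": _capsaicin,
}


def make_paradigm_preset(name: str, dt: float = 0.1) -> StimulusParadigm:
    """Stimulation paradigm preset by name.

    Presets: ``corneal_mech`` (6 x 10 s, 20-s gaps, 30-s rest padding),
    ``von_frey`` (4 x 5 s, 55-s gaps, 60-s padding), ``whisker``
    (6 x 20 s trains, 20-s gaps), ``capsaicin`` (60-s baseline then one
    180-s application; phasic, not suited to block-design GLM).
    """
    try:
        factory = PARADIGM_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown paradigm preset {name!r}; valid presets: {sorted(PARADIGM_PRESETS)}"
        ) from None
    return factory(dt)


# ---------------------------------------------------------------------------
# ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselPath:
    """Polyline vessel with constant flow speed.

    ``vertices`` is an ``(n, 2)`` array of (z, x) mm points; bubbles travel
    from the first vertex to the last when ``direction = +1`` and the
    reverse way when ``direction = -1``, at ``flow_speed`` mm/s, with a
    random lateral offset within ``radius`` mm.
    """

    vertices: tuple[tuple[float, float], ...]
    flow_speed: float
    radius: float = 0.02
    direction: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n >= 2, 2) sequence of (z, x) mm points")
        object.__setattr__(self, "vertices", tuple(map(tuple, v)))
        if self.flow_speed <= 0:
            raise ValueError("flow_speed must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")

    def travel_points(self) -> np.ndarray:
        """Vertices ordered in the direction of travel."""
        v = np.asarray(self.vertices, dtype=float)
        return v if self.direction == 1 else v[::-1]

    @property
    def length_mm(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))


@dataclass
class TrueTrack:
    """Ground-truth bubble trajectory: per-frame positions and velocities."""

    track_id: int
    frames: np.ndarray  # (n,) int
    z_mm: np.ndarray
    x_mm: np.ndarray
    vz: np.ndarray  # (n,) mm/s, instantaneous
    vx: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vz, self.vx)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    seed: int
    activation_mask: np.ndarray | None = None
    amplitude: float = 0.0
    response: np.ndarray | None = None  # stimulus response r(t), per ultrafast frame
    expected_dbv: np.ndarray | None = None  # per Power Doppler frame, percent
    expected_dbv_stim: float | None = None
    tracks: list[TrueTrack] = field(default_factory=list)
    components: dict[str, np.ndarray] | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _smooth_temporal_modes(rng: np.random.Generator, rank: int, n_t: int, framerate: float,
                           cutoff_hz: float = 10.0) -> np.ndarray:
    """Orthonormal slowly-varying temporal modes, shape (n_t, rank)."""
    if rank == 0:
        return np.zeros((n_t, 0))
    white = rng.standard_normal((n_t, rank))
    sigma_frames = framerate / (2.0 * np.pi * cutoff_hz)
    smooth = scipy.ndimage.gaussian_filter1d(white, sigma_frames, axis=0, mode="wrap")
    # add a DC-heavy first mode so clutter has the usual quasi-static part
    smooth[:, 0] += 3.0 * np.abs(smooth[:, 0]).mean() + 1.0
    q, _ = np.linalg.qr(smooth)
    return q[:, :rank]


def _smooth_spatial_patterns(rng: np.random.Generator, rank: int, shape: tuple[int, int],
                             sigma_px: float = 4.0) -> np.ndarray:
    """Unit-norm smooth spatial patterns, shape (n_z * n_x, rank)."""
    if rank == 0:
        return np.zeros((shape[0] * shape[1], 0))
    pats = np.empty((shape[0] * shape[1], rank))
    for r in range(rank):
        img = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
        img += 0.5 * np.abs(img).max()  # tissue echogenicity is positive-mean
        pats[:, r] = img.ravel() / np.linalg.norm(img)
    return pats


def _tissue_component(rng: np.random.Generator, shape: tuple[int, int], n_t: int,
                      rank: int, framerate: float, total_rms: float,
                      cdtype=np.complex128) -> np.ndarray:
    """Complex tissue clutter of exact rank ``rank`` with RMS ``total_rms``."""
    n_z, n_x = shape
    rdtype = np.float32 if cdtype == np.complex64 else np.float64
    if rank == 0 or total_rms == 0:
        return np.zeros((n_z, n_x, n_t), dtype=cdtype)
    U = _smooth_spatial_patterns(rng, rank, shape).astype(rdtype)
    V = _smooth_temporal_modes(rng, rank, n_t, framerate).astype(rdtype)
    # geometric amplitude decay across modes, as observed in clutter spectra
    amps = (10.0 ** (-0.5 * np.arange(rank))).astype(rdtype)
    M = (U * amps) @ V.T
    rms = np.sqrt(np.mean(M**2))
    M *= rdtype(total_rms / rms)
    phase = np.exp(1j * rng.uniform(0, 2 * np.pi)).astype(cdtype)
    return (M.astype(cdtype) * phase).reshape(n_z, n_x, n_t)


def _blood_speckle(rng: np.random.Generator, shape: tuple[int, int], n_t: int,
                   framerate: float, doppler_hz: float, corr_time_s: float,
                   cdtype=np.complex128) -> np.ndarray:
    """Unit-mean-power complex blood speckle, per-pixel independent.

    Models many sub-resolution scatterers translating through the
    point-spread function: a Doppler carrier at ``doppler_hz`` (axial
    motion) times a lowpass complex Gaussian envelope whose correlation
    time ``corr_time_s`` is the PSF transit time (decorrelation).
    """
    n_z, n_x = shape
    rdtype = np.float32 if cdtype == np.complex64 else np.float64
    sigma_frames = max(corr_time_s * framerate / 2.0, 1e-6)
    env = np.empty((n_z, n_x, n_t), dtype=cdtype)
    part = rng.standard_normal((n_z, n_x, n_t), dtype=rdtype)
    scipy.ndimage.gaussian_filter1d(part, sigma_frames, axis=2, mode="wrap", output=part)
    env.real = part
    rng.standard_normal((n_z, n_x, n_t), dtype=rdtype, out=part)
    scipy.ndimage.gaussian_filter1d(part, sigma_frames, axis=2, mode="wrap", output=part)
    env.imag = part
    del part
    env *= cdtype(1.0 / np.sqrt(np.mean(np.abs(env) ** 2)))
    t = np.arange(n_t) / framerate
    env *= np.exp(2j * np.pi * doppler_hz * t).astype(cdtype)
    return env


def _stim_response(paradigm: StimulusParadigm, hrf: HRFParams, n_t: int, framerate: float) -> np.ndarray:
    """Peak-normalized stimulus response r(t) at each ultrafast frame."""
    ind = paradigm.indicator()
    kernel = hrf_kernel(hrf, paradigm.dt)
    resp = np.convolve(ind, kernel)[: ind.size] * paradigm.dt
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    t = (np.arange(n_t) + 0.5) / framerate
    return np.interp(t, paradigm.times(), resp)


def _db_amp(db: float | None) -> float:
    """Amplitude ratio from dB (20 log10 convention); None or -inf -> 0."""
    if db is None or db == -math.inf:
        return 0.0
    return 10.0 ** (db / 20.0)


# ---------------------------------------------------------------------------
# functional ultrasound generator
# ---------------------------------------------------------------------------

def simulate_functional_stack(
    config: AcquisitionConfig,
    baseline_map: np.ndarray,
    activation_mask: np.ndarray | None,
    amplitude: float,
    paradigm: StimulusParadigm,
    hrf: HRFParams | None = None,
    tissue_rank: int = 3,
    tissue_to_blood_db: float = 40.0,
    noise_db: float = -20.0,
    seed: int = 0,
    doppler_hz: float = 150.0,
    blood_corr_time_s: float = 0.001,
    return_components: bool = False,
    dtype=np.complex128,
) -> tuple[FrameStack, GroundTruth]:
    """Synthetic fUS acquisition with a stimulus-locked blood-volume response.

    The per-block expected blood power at pixel ``p`` is
    ``baseline_map[p] * (1 + amplitude * r(t))`` inside ``activation_mask``
    and ``baseline_map[p]`` outside, where ``r(t)`` is the paradigm
    convolved with the HRF, peak-normalized. Tissue clutter has exact rank
    ``tissue_rank`` in every block; white complex noise sits ``noise_db``
    (amplitude dB) relative to the blood RMS.

    Returns the frame stack and a :class:`GroundTruth` carrying the mask,
    the response, and the expected dBV trace per Power Doppler frame.
    """
    baseline_map = np.asarray(baseline_map, dtype=float)
    if baseline_map.ndim != 2 or np.any(baseline_map < 0):
        raise ValueError("baseline_map must be a 2-D non-negative array")
    shape = baseline_map.shape
    if activation_mask is None:
        activation_mask = np.zeros(shape, dtype=bool)
    activation_mask = np.asarray(activation_mask, dtype=bool)
    if activation_mask.shape != shape:
        raise ValueError(
            f"activation_mask shape {activation_mask.shape} does not match baseline map {shape}"
        )
    if amplitude <= -1:
        raise ValueError("amplitude must be > -1 (blood power stays positive)")
    if not 0 <= tissue_rank < config.block_size:
        raise ValueError(f"tissue_rank must satisfy 0 <= rank < block_size={config.block_size}")
    if hrf is None:
        hrf = HRFParams()

    n_t = config.n_frames
    rng = np.random.default_rng(seed)
    rng_tissue, rng_blood, rng_noise = (np.random.default_rng(s) for s in rng.integers(0, 2**31, 3))

    cdtype = np.complex64 if np.dtype(dtype) == np.complex64 else np.complex128
    rdtype = np.float32 if cdtype == np.complex64 else np.float64

    r = _stim_response(paradigm, hrf, n_t, config.framerate)

    # blood = sqrt(power) * unit-power speckle, assembled in place
    blood = _blood_speckle(rng_blood, shape, n_t, config.framerate, doppler_hz,
                           blood_corr_time_s, cdtype=cdtype)
    blood *= np.sqrt(baseline_map).astype(rdtype)[:, :, None]
    blood[activation_mask, :] *= np.sqrt(1.0 + amplitude * r).astype(rdtype)[None, :]

    blood_rms = float(np.sqrt(np.mean(np.abs(blood) ** 2)))
    tissue = _tissue_component(rng_tissue, shape, n_t, tissue_rank, config.framerate,
                               total_rms=_db_amp(tissue_to_blood_db) * blood_rms, cdtype=cdtype)
    noise_rms = _db_amp(noise_db) * blood_rms

    def _noise_chunks(target: np.ndarray) -> None:
        # chunked along time to bound the float temporaries; the chunk
        # schedule is fixed so the stream is identical in both modes
        scale = noise_rms / np.sqrt(2)
        step = max(1, int(2e8 / (shape[0] * shape[1] * 16)))
        for a in range(0, n_t, step):
            sl = np.s_[:, :, a : a + step]
            chunk = np.empty(target[sl].shape, dtype=cdtype)
            chunk.real = rng_noise.standard_normal(chunk.shape, dtype=rdtype)
            chunk.imag = rng_noise.standard_normal(chunk.shape, dtype=rdtype)
            chunk *= cdtype(scale)
            target[sl] += chunk

    if return_components:
        noise = np.zeros(shape + (n_t,), dtype=cdtype)
        if noise_rms > 0:
            _noise_chunks(noise)
        frames = tissue + blood + noise
        components = {"tissue": tissue, "blood": blood, "noise": noise}
    else:
        components = None
        frames = blood
        frames += tissue
        del tissue
        if noise_rms > 0:
            _noise_chunks(frames)

    stack = FrameStack(frames=frames, config=config)

    # expected dBV per Power Doppler frame, from the block-mean modulation
    bs = config.block_size
    m_block = (1.0 + amplitude * r).reshape(config.n_blocks, bs).mean(axis=1)
    stim = paradigm.frame_stim_mask(config.n_blocks, config.block_interval_s)
    base = ~stim
    m_base = m_block[base].mean() if base.any() else 1.0
    expected_dbv = 100.0 * (m_block - m_base) / m_base
    expected_dbv_stim = float(expected_dbv[stim].mean()) if stim.any() else None

    components = None
    if return_components:
        components = {"tissue": tissue, "blood": blood, "noise": noise}
    truth = GroundTruth(
        seed=seed,
        activation_mask=activation_mask,
        amplitude=amplitude,
        response=r,
        expected_dbv=expected_dbv,
        expected_dbv_stim=expected_dbv_stim,
        components=components,
        params={
            "tissue_rank": tissue_rank,
            "tissue_to_blood_db": tissue_to_blood_db,
            "noise_db": noise_db,
            "doppler_hz": doppler_hz,
            "blood_corr_time_s": blood_corr_time_s,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Power Doppler level generator (for GLM calibration studies)
# ---------------------------------------------------------------------------

def simulate_pd_series(
    baseline_map: np.ndarray,
    activation_mask: np.ndarray | None,
    amplitude: float,
    paradigm: StimulusParadigm,
    hrf: HRFParams | None = None,
    n_frames: int | None = None,
    frame_interval: float = 0.4,
    noise_rel_std: float = 0.1,
    seed: int = 0,
    config: AcquisitionConfig | None = None,
):
    """Synthetic Power Doppler series, bypassing the frame-level physics.

    Each pixel follows ``baseline * (1 + amplitude * r(t)) * (1 + sigma *
    eps)`` with i.i.d. Gaussian multiplicative noise — the cheap
    substrate for GLM false-positive-rate calibration at many seeds. The
    frame-level generator is the independent route for end-to-end tests.
    """
    from .clutter import PowerDopplerSeries

    baseline_map = np.asarray(baseline_map, dtype=float)
    shape = baseline_map.shape
    if activation_mask is None:
        activation_mask = np.zeros(shape, dtype=bool)
    activation_mask = np.asarray(activation_mask, dtype=bool)
    if activation_mask.shape != shape:
        raise ValueError("activation_mask shape mismatch")
    if hrf is None:
        hrf = HRFParams()
    if config is None:
        config = AcquisitionConfig(framerate=500.0, block_size=200)
    if n_frames is None:
        n_frames = int(paradigm.total_duration / frame_interval)
    X = build_design(paradigm, hrf, n_frames, frame_interval)
    r = X[:, 0]
    rng = np.random.default_rng(seed)
    mod = np.ones((n_frames,) + shape)
    mod[:, activation_mask] = (1.0 + amplitude * r)[:, None]
    images = baseline_map[None] * mod * (1.0 + noise_rel_std * rng.standard_normal((n_frames,) + shape))
    images = np.clip(images, 1e-12, None)
    series = PowerDopplerSeries(images=images, frame_interval=frame_interval, config=config, n_removed=0)
    truth = GroundTruth(seed=seed, activation_mask=activation_mask, amplitude=amplitude, response=r)
    return series, truth


# ---------------------------------------------------------------------------
# ULM bubble-movie generator
# ---------------------------------------------------------------------------

def _path_position(points: np.ndarray, cumlen: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Position and unit tangent at arc length ``s`` along a polyline."""
    i = int(np.searchsorted(cumlen, s, side="right")) - 1
    i = min(max(i, 0), len(points) - 2)
    seg = points[i + 1] - points[i]
    seg_len = np.linalg.norm(seg)
    tangent = seg / seg_len
    pos = points[i] + tangent * (s - cumlen[i])
    return pos, tangent


def simulate_bubble_stack(
    config: AcquisitionConfig,
    vessels: list[VesselPath],
    grid_shape: tuple[int, int],
    bubbles_per_frame: float = 0.05,
    psf_sigma_mm: float = 0.1,
    tissue_rank: int = 0,
    tissue_to_bubble_db: float = 40.0,
    noise_db: float | None = None,
    seed: int = 0,
    bubble_amplitude: float = 1.0,
    n_frames: int | None = None,
    spawn_mode: str = "poisson",
) -> tuple[FrameStack, GroundTruth]:
    """Synthetic microbubble movie along vessel paths.

    New bubbles enter the field as a Poisson process with mean
    ``bubbles_per_frame`` arrivals per frame (split uniformly across
    vessels); the field is pre-seeded so occupancy is stationary from the
    first frame. Each bubble advances by ``flow_speed / framerate`` mm per
    frame along its vessel polyline (with a fixed random lateral offset
    within the vessel radius) and is rendered as a Gaussian blob of scale
    ``psf_sigma_mm`` carrying a Doppler phase set by its axial velocity.
    Ground-truth per-frame positions and velocities are recorded exactly.
    """
    if not vessels:
        raise ValueError("vessel list is empty")
    if psf_sigma_mm <= 0:
        raise ValueError("psf_sigma_mm must be > 0")
    n_z, n_x = grid_shape
    z_max, x_max = n_z * config.pixel_dz_mm, n_x * config.pixel_dx_mm
    for v in vessels:
        pts = np.asarray(v.vertices)
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > z_max) or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > x_max):
            raise ValueError(f"vessel path exits the {z_max} x {x_max} mm grid")
    if n_frames is None:
        n_frames = config.n_frames
    rng = np.random.default_rng(seed)
    rng_bub, rng_tissue, rng_noise = (np.random.default_rng(s) for s in rng.integers(0, 2**31, 3))

    if spawn_mode not in ("poisson", "regular"):
        raise ValueError("spawn_mode must be 'poisson' or 'regular'")

    # --- spawn bubbles -----------------------------------------------------
    # "poisson": memoryless arrivals (continuous infusion); "regular": one
    # bubble every 1/rate frames per vessel — a dilute steady infusion in
    # which bubbles never overlap under the PSF, for recovery experiments
    per_vessel_rate = bubbles_per_frame / len(vessels)
    bubbles = []  # (vessel, start_frame, offset, phase0)
    for vi, vessel in enumerate(vessels):
        length = vessel.length_mm
        step = vessel.flow_speed / config.framerate
        transit_frames = int(np.ceil(length / step))
        # pre-seed so the vessel is populated at t = 0
        if spawn_mode == "poisson":
            for f0 in range(-transit_frames, n_frames):
                k = rng_bub.poisson(per_vessel_rate)
                for _ in range(k):
                    offset = rng_bub.uniform(-vessel.radius, vessel.radius)
                    phase0 = rng_bub.uniform(0, 2 * np.pi)
                    bubbles.append((vi, f0, offset, phase0))
        else:
            spacing = max(int(round(1.0 / per_vessel_rate)), 1)
            jitter = int(rng_bub.integers(0, spacing))
            for f0 in range(-transit_frames + jitter, n_frames, spacing):
                offset = rng_bub.uniform(-vessel.radius, vessel.radius)
                phase0 = rng_bub.uniform(0, 2 * np.pi)
                bubbles.append((vi, f0, offset, phase0))

    frames = np.zeros((n_z, n_x, n_frames), dtype=complex)
    zc = (np.arange(n_z) + 0.5) * config.pixel_dz_mm
    xc = (np.arange(n_x) + 0.5) * config.pixel_dx_mm
    half_win = max(int(np.ceil(4 * psf_sigma_mm / min(config.pixel_dz_mm, config.pixel_dx_mm))), 2)

    tracks: list[TrueTrack] = []
    tid = 0
    for vi, f0, offset, phase0 in bubbles:
        vessel = vessels[vi]
        pts = vessel.travel_points()
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cumlen = np.concatenate([[0.0], np.cumsum(seglen)])
        length = cumlen[-1]
        step = vessel.flow_speed / config.framerate
        t_frames, t_z, t_x, t_vz, t_vx = [], [], [], [], []
        for f in range(max(f0, 0), n_frames):
            s = (f - f0) * step
            if s > length:
                break
            pos, tangent = _path_position(pts, cumlen, s)
            normal = np.array([-tangent[1], tangent[0]])
            p = pos + offset * normal
            if not (0 <= p[0] <= z_max and 0 <= p[1] <= x_max):
                continue
            vz, vx = vessel.flow_speed * tangent
            # Doppler phase accrued from axial displacement
            phase = phase0 + 2 * np.pi * (2.0 * vz / WAVELENGTH_MM) * (f - max(f0, 0)) / config.framerate
            i0 = int(round(p[0] / config.pixel_dz_mm))
            j0 = int(round(p[1] / config.pixel_dx_mm))
            zi = slice(max(i0 - half_win, 0), min(i0 + half_win + 1, n_z))
            xi = slice(max(j0 - half_win, 0), min(j0 + half_win + 1, n_x))
            gz = np.exp(-0.5 * ((zc[zi] - p[0]) / psf_sigma_mm) ** 2)
            gx = np.exp(-0.5 * ((xc[xi] - p[1]) / psf_sigma_mm) ** 2)
            frames[zi, xi, f] += bubble_amplitude * np.exp(1j * phase) * np.outer(gz, gx)
            t_frames.append(f)
            t_z.append(p[0])
            t_x.append(p[1])
            t_vz.append(vz)
            t_vx.append(vx)
        if t_frames:
            tracks.append(TrueTrack(
                track_id=tid,
                frames=np.asarray(t_frames),
                z_mm=np.asarray(t_z),
                x_mm=np.asarray(t_x),
                vz=np.asarray(t_vz),
                vx=np.asarray(t_vx),
            ))
            tid += 1

    bubble_rms = np.sqrt(np.mean(np.abs(frames) ** 2))
    if bubble_rms == 0:
        bubble_rms = bubble_amplitude  # empty movie: reference the blob peak
    tissue = _tissue_component(rng_tissue, grid_shape, n_frames, tissue_rank, config.framerate,
                               total_rms=_db_amp(tissue_to_bubble_db) * bubble_rms)
    noise_rms = _db_amp(noise_db) * bubble_rms
    if noise_rms > 0:
        frames = frames + noise_rms * (rng_noise.standard_normal(frames.shape)
                                       + 1j * rng_noise.standard_normal(frames.shape)) / np.sqrt(2)
    frames = frames + tissue

    stack = FrameStack(frames=frames, config=config)
    truth = GroundTruth(
        seed=seed,
        tracks=tracks,
        params={
            "psf_sigma_mm": psf_sigma_mm,
            "bubbles_per_frame": bubbles_per_frame,
            "tissue_rank": tissue_rank,
            "tissue_to_bubble_db": tissue_to_bubble_db,
            "noise_db": noise_db,
        },
    )
    return stack, truth
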