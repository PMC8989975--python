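"""Ultrasound localization microscopy: bubble detection, tracking,
velocimetry and super-resolved map rendering.

Microbubbles are detected as the brightest strict local maxima of the
clutter-filtered frames and refined to sub-pixel positions by an
intensity-weighted centroid. Detections in consecutive frames are linked
by optimal (Hungarian) assignment under a gating distance, velocities are
the inter-frame displacements times the framerate, and density / velocity
maps are rendered on a super-resolved grid (default pitch 6.5 um) by
counting localizations and averaging segment velocities per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.optimize

__all__ = [
    "Localization",
    "Track",
    "ULMMaps",
    "detect_bubbles",
    "link_tracks",
    "track_velocities",
    "render_maps",
    "assignment_cost",
]

#: Finite stand-in for a forbidden assignment in the gated cost matrix.
_FORBIDDEN = 1e30


@dataclass(frozen=True)
class Localization:
    """A single sub-pixel bubble detection."""

    frame: int
    z_mm: float
    x_mm: float
    intensity: float


@dataclass
class Track:
    """An assembled bubble trajectory.

    Velocities are per-segment (one fewer than points): ``vz, vx`` in
    mm/s, signed in the grid convention (z positive downward); populated
    by :func:`track_velocities`.
    """

    track_id: int
    frames: np.ndarray
    z_mm: np.ndarray
    x_mm: np.ndarray
    intensity: np.ndarray
    vz: np.ndarray | None = None
    vx: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def speed(self) -> np.ndarray:
        if self.vz is None:
            raise ValueError("velocities not computed; call track_velocities first")
        return np.hypot(self.vz, self.vx)

    @property
    def mean_speed(self) -> float:
        return float(self.speed.mean())


def detect_bubbles(
    frame: np.ndarray,
    min_intensity: float,
    pixel_dz_mm: float,
    pixel_dx_mm: float,
    neighborhood: int = 7,
    frame_index: int = 0,
    refine: str = "centroid",
) -> list[Localization]:
    """Detect bubbles as strict local maxima with sub-pixel refinement.

    A pixel is a candidate iff it is strictly greater than every other
    pixel in its ``neighborhood x neighborhood`` window and at least
    ``min_intensity``. Each candidate is refined to a sub-pixel position:
    ``refine="centroid"`` (default, deterministic) takes the
    intensity-weighted centroid over the window (clipped at the frame
    borders); ``refine="gaussian"`` fits a parabola to the log-intensity
    of the 3 pixels around the peak in each axis, which is exact for a
    Gaussian point-spread function. Complex frames are detected on their
    magnitude.
    """
    frame = np.abs(np.asarray(frame))
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {frame.shape}")
    n_z, n_x = frame.shape
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be an odd integer >= 3")
    if neighborhood > min(n_z, n_x):
        raise ValueError(f"neighborhood {neighborhood} larger than frame {frame.shape}")
    half = neighborhood // 2

    footprint = np.ones((neighborhood, neighborhood), dtype=bool)
    footprint[half, half] = False  # strict maximum: compare to neighbours only
    neigh_max = scipy.ndimage.maximum_filter(frame, footprint=footprint, mode="constant", cval=-np.inf)
    cand = (frame > neigh_max) & (frame >= min_intensity)

    if refine not in ("centroid", "gaussian"):
        raise ValueError("refine must be 'centroid' or 'gaussian'")

    def _logparab(m1: float, c0: float, p1: float, idx: int, n: int) -> float:
        # 3-point parabola through log-intensities; exact for a Gaussian blob
        if idx == 0 or idx == n - 1 or min(m1, c0, p1) <= 0:
            return float(idx)
        lm, lc, lp = np.log(m1), np.log(c0), np.log(p1)
        denom = lm - 2 * lc + lp
        if denom >= 0:
            return float(idx)
        return idx + 0.5 * (lm - lp) / denom

    locs: list[Localization] = []
    for i, j in zip(*np.nonzero(cand)):
        if refine == "gaussian":
            ci = _logparab(frame[i - 1, j] if i > 0 else 0.0, frame[i, j],
                           frame[i + 1, j] if i < n_z - 1 else 0.0, i, n_z)
            cj = _logparab(frame[i, j - 1] if j > 0 else 0.0, frame[i, j],
                           frame[i, j + 1] if j < n_x - 1 else 0.0, j, n_x)
        else:
            zi = slice(max(i - half, 0), min(i + half + 1, n_z))
            xi = slice(max(j - half, 0), min(j + half + 1, n_x))
            w = frame[zi, xi]
            tot = w.sum()
            iz = np.arange(zi.start, zi.stop)
            ix = np.arange(xi.start, xi.stop)
            ci = float((w.sum(axis=1) * iz).sum() / tot)
            cj = float((w.sum(axis=0) * ix).sum() / tot)
        locs.append(Localization(
            frame=frame_index,
            z_mm=(ci + 0.5) * pixel_dz_mm,
            x_mm=(cj + 0.5) * pixel_dx_mm,
            intensity=float(frame[i, j]),
        ))
    return locs


def assignment_cost(
    prev_xy: np.ndarray,
    next_xy: np.ndarray,
    links: list[tuple[int, int]],
    max_link_mm: float,
) -> float:
    """Score a candidate matching under the linker's objective: the sum of
    linked Euclidean distances plus ``max_link_mm`` for every unlinked
    detection on either side. Infeasible links (beyond the gate) score
    infinity. Exposed so an exhaustive oracle can score matchings
    identically to :func:`link_tracks`."""
    prev_xy = np.asarray(prev_xy, float)
    next_xy = np.asarray(next_xy, float)
    total = 0.0
    for r, c in links:
        dist = float(np.linalg.norm(prev_xy[r] - next_xy[c]))
        if dist > max_link_mm:
            return float("inf")
        total += dist
    n_unlinked = (len(prev_xy) - len(links)) + (len(next_xy) - len(links))
    return total + max_link_mm * n_unlinked


def _link_frame_pair(prev_xy: np.ndarray, next_xy: np.ndarray, max_link_mm: float) -> list[tuple[int, int]]:
    """Optimal gated assignment between two detection sets.

    Minimizes ``sum(linked distances) + max_link_mm * n_unlinked`` via the
    Hungarian algorithm on the standard birth/death-augmented cost matrix;
    pairs farther apart than ``max_link_mm`` are never linked.
    """
    n, m = len(prev_xy), len(next_xy)
    if n == 0 or m == 0:
        return []
    d = np.linalg.norm(prev_xy[:, None, :] - next_xy[None, :, :], axis=2)
    link = np.where(d <= max_link_mm, d, _FORBIDDEN)
    death = np.full((n, n), _FORBIDDEN)
    np.fill_diagonal(death, max_link_mm)
    birth = np.full((m, m), _FORBIDDEN)
    np.fill_diagonal(birth, max_link_mm)
    lower_right = np.where(link.T < _FORBIDDEN, 0.0, _FORBIDDEN)
    C = np.block([[link, death], [birth, lower_right]])
    rows, cols = scipy.optimize.linear_sum_assignment(C)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and d[r, c] <= max_link_mm:
            out.append((int(r), int(c)))
    return out


def link_tracks(
    localizations: list[Localization],
    max_link_mm: float,
    min_length: int = 4,
    max_gap: int = 0,
) -> list[Track]:
    """Assemble tracks from per-frame localizations.

    Between consecutive frames, detections are matched by optimal
    assignment (Hungarian algorithm) minimizing total Euclidean distance
    subject to each link being shorter than ``max_link_mm``. Unmatched
    detections start new tracks; a track not extended for more than
    ``max_gap`` frames (default 0: any miss) terminates. Tracks shorter
    than ``min_length`` points are discarded. Ordering is stable, so
    identical input yields identical tracks.
    """
    if max_link_mm <= 0:
        raise ValueError("max_link_mm must be > 0")
    by_frame: dict[int, list[Localization]] = {}
    for loc in localizations:
        by_frame.setdefault(loc.frame, []).append(loc)
    if not by_frame:
        return []
    frames_sorted = sorted(by_frame)

    active: list[dict] = []  # each: {"locs": [...], "last_frame": int}
    finished: list[dict] = []
    for f in range(frames_sorted[0], frames_sorted[-1] + 1):
        dets = by_frame.get(f, [])
        candidates = [tr for tr in active if f - tr["last_frame"] <= max_gap + 1]
        expired = [tr for tr in active if f - tr["last_frame"] > max_gap + 1]
        finished.extend(expired)
        if dets and candidates:
            prev_xy = np.array([[tr["locs"][-1].z_mm, tr["locs"][-1].x_mm] for tr in candidates])
            next_xy = np.array([[d.z_mm, d.x_mm] for d in dets])
            links = _link_frame_pair(prev_xy, next_xy, max_link_mm)
        else:
            links = []
        matched_tracks = {r for r, _ in links}
        matched_dets = {c for _, c in links}
        for r, c in links:
            candidates[r]["locs"].append(dets[c])
            candidates[r]["last_frame"] = f
        still_active = []
        for idx, tr in enumerate(candidates):
            if idx in matched_tracks or f - tr["last_frame"] <= max_gap:
                still_active.append(tr)
            else:
                finished.append(tr)
        for c, d in enumerate(dets):
            if c not in matched_dets:
                still_active.append({"locs": [d], "last_frame": f})
        active = still_active
    finished.extend(active)

    finished = [tr for tr in finished if len(tr["locs"]) >= min_length]
    finished.sort(key=lambda tr: (tr["locs"][0].frame, tr["locs"][0].z_mm, tr["locs"][0].x_mm))
    tracks = []
    for tid, tr in enumerate(finished):
        locs = tr["locs"]
        tracks.append(Track(
            track_id=tid,
            frames=np.array([l.frame for l in locs]),
            z_mm=np.array([l.z_mm for l in locs]),
            x_mm=np.array([l.x_mm for l in locs]),
            intensity=np.array([l.intensity for l in locs]),
        ))
    return tracks


def track_velocities(track: Track, framerate: float) -> Track:
    """Per-segment velocity vectors: displacement times framerate (mm/s),
    divided by the frame gap when gaps were closed."""
    if track.n_points < 2:
        raise ValueError("cannot compute velocities for a single-point track")
    dfr = np.diff(track.frames)
    if np.any(dfr <= 0):
        raise ValueError("track frame indices must be strictly increasing")
    track.vz = np.diff(track.z_mm) / dfr * framerate
    track.vx = np.diff(track.x_mm) / dfr * framerate
    return track


@dataclass
class ULMMaps:
    """Super-resolved rendering of a track set.

    ``density`` counts localizations per pixel; ``speed`` is the mean
    segment speed assigned to each segment's starting pixel; ``vz`` the
    signed mean axial velocity (positive = descending flow, for
    artery/vein discrimination); ``vector_*`` a coarse mean velocity
    field.
    """

    density: np.ndarray
    speed: np.ndarray
    vz: np.ndarray
    pixel_um: float
    vector_vz: np.ndarray
    vector_vx: np.ndarray
    vector_pixel_um: float
    extent_mm: tuple[float, float]

    @property
    def n_localizations(self) -> int:
        return int(self.density.sum())


def render_maps(
    tracks: list[Track],
    extent_mm: tuple[float, float],
    pixel_um: float = 6.5,
    vector_pixel_um: float = 100.0,
) -> ULMMaps:
    """Render density, speed, signed-vz and vector-field maps.

    ``extent_mm`` is the (z, x) size of the field of view; the map shape is
    ``ceil(extent / pitch)``. Density counts every track localization in
    its pixel; each segment's speed and velocity components accumulate at
    the segment's starting pixel; the vector field averages (vz, vx) on a
    coarser grid.
    """
    if pixel_um <= 0 or vector_pixel_um <= 0:
        raise ValueError("pixel pitches must be > 0")
    pitch = pixel_um / 1000.0
    vpitch = vector_pixel_um / 1000.0
    shape = (int(np.ceil(extent_mm[0] / pitch)), int(np.ceil(extent_mm[1] / pitch)))
    vshape = (int(np.ceil(extent_mm[0] / vpitch)), int(np.ceil(extent_mm[1] / vpitch)))

    density = np.zeros(shape, dtype=np.int64)
    speed_sum = np.zeros(shape)
    speed_n = np.zeros(shape, dtype=np.int64)
    vz_sum = np.zeros(shape)
    vvz = np.zeros(vshape)
    vvx = np.zeros(vshape)
    vn = np.zeros(vshape, dtype=np.int64)

    def pix(z, x, sh, pt):
        i = np.clip((np.asarray(z) / pt).astype(int), 0, sh[0] - 1)
        j = np.clip((np.asarray(x) / pt).astype(int), 0, sh[1] - 1)
        return i, j

    for tr in tracks:
        i, j = pix(tr.z_mm, tr.x_mm, shape, pitch)
        np.add.at(density, (i, j), 1)
        if tr.vz is not None and tr.n_points >= 2:
            sp = tr.speed
            si, sj = i[:-1], j[:-1]  # segment start pixels
            np.add.at(speed_sum, (si, sj), sp)
            np.add.at(vz_sum, (si, sj), tr.vz)
            np.add.at(speed_n, (si, sj), 1)
            vi, vj = pix(tr.z_mm[:-1], tr.x_mm[:-1], vshape, vpitch)
            np.add.at(vvz, (vi, vj), tr.vz)
            np.add.at(vvx, (vi, vj), tr.vx)
            np.add.at(vn, (vi, vj), 1)

    with np.errstate(invalid="ignore"):
        speed = np.where(speed_n > 0, speed_sum / np.maximum(speed_n, 1), np.nan)
        vz = np.where(speed_n > 0, vz_sum / np.maximum(speed_n, 1), np.nan)
        vector_vz = np.where(vn > 0, vvz / np.maximum(vn, 1), np.nan)
        vector_vx = np.where(vn > 0, vvx / np.maximum(vn, 1), np.nan)
    return ULMMaps(
        density=density,
        speed=speed,
        vz=vz,
        pixel_um=pixel_um,
        vector_vz=vector_vz,
        vector_vx=vector_vx,
        vector_pixel_um=vector_pixel_um,
        extent_mm=tuple(extent_mm),
    )
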