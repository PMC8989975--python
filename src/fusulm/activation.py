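"""GLM activation mapping of Power Doppler series and blood-volume
quantification.

The hemodynamic response to a stimulus is modelled by convolving the
binary stimulus paradigm with a canonical hemodynamic response function
(HRF) built from four half-cosine segments: an optional initial dip, a
rise to the unit peak, a fall to an undershoot, and a return to baseline.
A pixel-wise ordinary-least-squares fit of the Power Doppler time series
against this regressor yields Z-score and p-value maps; pixels surviving
Bonferroni correction define the activated region of interest (ROI). The
blood-volume response is expressed as a relative difference in percent,
dBV(t) = 100 * (s(t) - b) / b, with the baseline b taken as the mean over
frames where the stimulation indicator is strictly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.optimize
import scipy.stats

from .clutter import PowerDopplerSeries
from .core import StimulusParadigm

__all__ = [
    "HRFParams",
    "ActivationMap",
    "ROI",
    "DeltaBVTrace",
    "HRFFit",
    "hrf_kernel",
    "build_design",
    "glm_fit",
    "extract_roi",
    "mirror_roi",
    "delta_bv",
    "fit_hrf_params",
]

log = logging.getLogger(__name__)

#: Z-score reported for zero-residual pixels (roughly p = 1e-16).
Z_CAP = 8.2


@dataclass(frozen=True)
class HRFParams:
    """Four-half-cosine canonical HRF.

    Segments (durations in seconds, relative to a unit peak):

    1. fall from 0 to ``-c1`` over ``d1`` (initial dip),
    2. rise from ``-c1`` to ``+1`` over ``d2``,
    3. fall from ``+1`` to ``-c2`` over ``d3``,
    4. recover from ``-c2`` to 0 over ``d4`` (post-stimulus undershoot).

    With ``c1 = c2 = 0`` and ``d1 = d4 = 0`` the kernel is a single cosine
    bump. Amplitudes are non-negative and expressed relative to the peak.
    """

    d1: float = 0.0
    d2: float = 1.0
    d3: float = 2.0
    d4: float = 2.0
    c1: float = 0.0
    c2: float = 0.3

    def __post_init__(self) -> None:
        ds = (self.d1, self.d2, self.d3, self.d4)
        if any(d < 0 for d in ds):
            raise ValueError("segment durations must be >= 0")
        if self.d2 <= 0 and self.d3 <= 0:
            raise ValueError("at least one of d2, d3 must be > 0")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("dip/undershoot amplitudes must be >= 0")

    @property
    def duration(self) -> float:
        return self.d1 + self.d2 + self.d3 + self.d4

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Continuous kernel value at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        e1 = self.d1
        e2 = e1 + self.d2
        e3 = e2 + self.d3
        e4 = e3 + self.d4

        def half_cos(s, dur, start, stop):
            # half-cosine ramp from `start` to `stop` over `dur`
            return start + (stop - start) * 0.5 * (1 - np.cos(np.pi * s / dur))

        if self.d1 > 0:
            m = (t >= 0) & (t < e1)
            out[m] = half_cos(t[m], self.d1, 0.0, -self.c1)
        if self.d2 > 0:
            m = (t >= e1) & (t < e2)
            out[m] = half_cos(t[m] - e1, self.d2, -self.c1, 1.0)
        if self.d3 > 0:
            m = (t >= e2) & (t < e3)
            out[m] = half_cos(t[m] - e2, self.d3, 1.0, -self.c2)
        if self.d4 > 0:
            m = (t >= e3) & (t < e4)
            out[m] = half_cos(t[m] - e3, self.d4, -self.c2, 0.0)
        return out


def hrf_kernel(params: HRFParams, dt: float) -> np.ndarray:
    """Sample the HRF on ``t = 0, dt, 2*dt, ...`` covering its support.

    The sampled kernel is rescaled so that its maximum is exactly 1 (the
    analytic peak may fall between samples).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if params.duration <= 0:
        raise ValueError("all HRF segment durations are zero")
    n = int(np.ceil(params.duration / dt)) + 1
    k = params.evaluate(np.arange(n) * dt)
    peak = np.max(k)
    if peak <= 0:
        raise ValueError("sampled HRF has no positive peak; decrease dt")
    return k / peak


def build_design(
    paradigm: StimulusParadigm,
    hrf: HRFParams,
    n_frames: int,
    frame_interval: float,
    t0: float = 0.0,
) -> np.ndarray:
    """Design matrix ``(n_frames, 2)``: HRF-convolved stimulus regressor
    (column 0, peak-normalized) and intercept (column 1).

    The stimulus indicator is sampled at the paradigm's fine ``dt``,
    causally convolved with the HRF kernel, and interpolated at the frame
    centres ``t0 + (b + 0.5) * frame_interval``.
    """
    needed = t0 + n_frames * frame_interval
    if paradigm.total_duration < needed - 1e-9:
        raise ValueError(
            f"paradigm covers {paradigm.total_duration} s but the series spans {needed:.6g} s"
        )
    dt = paradigm.dt
    ind = paradigm.indicator()
    kernel = hrf_kernel(hrf, dt)
    resp = np.convolve(ind, kernel)[: ind.size] * dt  # causal, units of s
    t_fine = paradigm.times()
    t_frames = t0 + (np.arange(n_frames) + 0.5) * frame_interval
    reg = np.interp(t_frames, t_fine, resp)
    peak = np.max(np.abs(reg))
    if peak > 0:
        reg = reg / peak
    X = np.column_stack([reg, np.ones(n_frames)])
    return X


@dataclass
class ActivationMap:
    """Pixel-wise GLM results: Z-scores, p-values, effect sizes, and the
    Bonferroni-significant mask."""

    z: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    beta: np.ndarray
    alpha: float
    n_tests: int
    df: int

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def glm_fit(
    series: PowerDopplerSeries | np.ndarray,
    design: np.ndarray,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> ActivationMap:
    """Pixel-wise OLS fit of a Power Doppler series against the design.

    Per pixel: ``y = X @ [beta, intercept] + e``; ``t = beta / SE(beta)``;
    the p-value comes from the t distribution with residual degrees of
    freedom. By default the test is one-sided for activation (blood-volume
    increase) and ``Z = Phi^{-1}(1 - p)``. The significance mask applies
    Bonferroni correction over all pixels in the frame.
    """
    imgs = series.images if isinstance(series, PowerDopplerSeries) else np.asarray(series, float)
    if imgs.ndim != 3:
        raise ValueError("series must have shape (n_frames, n_z, n_x)")
    n_frames, n_z, n_x = imgs.shape
    X = np.asarray(design, dtype=float)
    if X.shape[0] != n_frames:
        raise ValueError(f"design has {X.shape[0]} rows for {n_frames} frames")
    n_reg = X.shape[1]
    if n_frames < n_reg + 2:
        raise ValueError(f"need at least n_regressors + 2 = {n_reg + 2} frames, got {n_frames}")
    rank = np.linalg.matrix_rank(X)
    if rank < n_reg:
        # identify which columns are linearly dependent on the previous ones
        bad = []
        for j in range(1, n_reg):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(j)
        raise ValueError(f"rank-deficient design: columns {bad} are collinear with earlier columns")

    Y = imgs.reshape(n_frames, n_z * n_x)
    XtX_inv = np.linalg.inv(X.T @ X)
    betas = XtX_inv @ (X.T @ Y)  # (n_reg, n_pix)
    resid = Y - X @ betas
    df = n_frames - n_reg
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / df
    var_beta = sigma2 * XtX_inv[0, 0]
    beta = betas[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(var_beta > 0, beta / np.sqrt(var_beta), np.inf * np.sign(beta))
    # zero-residual pixels (perfect fit): report the capped sentinel Z
    zero_resid = rss <= 1e-300
    if np.any(zero_resid):
        log.info("%d pixels have zero residual variance; Z capped at %.1f", zero_resid.sum(), Z_CAP)

    if two_sided:
        p = 2 * scipy.stats.t.sf(np.abs(tstat), df)
    else:
        p = scipy.stats.t.sf(tstat, df)
    p = np.clip(p, 1e-300, 1.0)
    z = scipy.stats.norm.isf(p)
    z = np.clip(z, -Z_CAP, Z_CAP)
    z[zero_resid & (beta > 0)] = Z_CAP

    n_tests = n_z * n_x
    mask = p < alpha / n_tests
    return ActivationMap(
        z=z.reshape(n_z, n_x),
        p=p.reshape(n_z, n_x),
        mask=mask.reshape(n_z, n_x),
        beta=beta.reshape(n_z, n_x),
        alpha=alpha,
        n_tests=n_tests,
        df=df,
    )


@dataclass
class ROI:
    """Boolean pixel mask with provenance."""

    mask: np.ndarray
    side: str = "ipsilateral"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


def extract_roi(amap: ActivationMap, side: str = "ipsilateral") -> ROI:
    """Connected component (8-connectivity) of the Bonferroni mask that
    contains the maximal Z-score; ties broken by raster order."""
    if not amap.mask.any():
        raise ValueError("no activation: no pixel survives Bonferroni correction")
    labels, _ = scipy.ndimage.label(amap.mask, structure=_STRUCT8)
    zmasked = np.where(amap.mask, amap.z, -np.inf)
    peak = np.unravel_index(np.argmax(zmasked), zmasked.shape)  # argmax = first in raster order
    comp = labels == labels[peak]
    return ROI(mask=comp, side=side, provenance={"alpha": amap.alpha, "n_tests": amap.n_tests})


def mirror_roi(roi: ROI, midline_x_mm: float, pixel_dx_mm: float, side: str = "contralateral") -> ROI:
    """Reflect an ROI about the vertical line ``x = midline_x_mm``.

    Pixel centres sit at ``(j + 0.5) * pixel_dx_mm``; the mirrored column
    index is rounded to the nearest pixel, which makes the operation an
    involution and preserves the pixel count.
    """
    n_z, n_x = roi.mask.shape
    if not 0 <= midline_x_mm <= n_x * pixel_dx_mm:
        raise ValueError(f"midline {midline_x_mm} mm outside the grid [0, {n_x * pixel_dx_mm}] mm")
    ii, jj = np.nonzero(roi.mask)
    c = 2.0 * midline_x_mm / pixel_dx_mm - 1.0  # j' = c - j in index space
    jj_m = np.round(c - jj).astype(int)
    if np.any((jj_m < 0) | (jj_m >= n_x)):
        raise ValueError("mirrored ROI falls outside the imaging grid")
    mask = np.zeros_like(roi.mask)
    mask[ii, jj_m] = True
    prov = dict(roi.provenance)
    prov["mirror_axis_x_mm"] = midline_x_mm
    return ROI(mask=mask, side=side, provenance=prov)


@dataclass
class DeltaBVTrace:
    """Relative blood-volume time course over an ROI, in percent.

    ``dbv`` averages the Power Doppler signal over the ROI, subtracts the
    baseline (mean over frames where the stimulation indicator is 0) and
    divides by it. ``dbv_bl`` is 0 by construction.
    """

    t: np.ndarray
    dbv: np.ndarray
    stim_mask: np.ndarray
    baseline_value: float
    dbv_bl: float
    dbv_stim: float


def delta_bv(series: PowerDopplerSeries, roi: ROI, paradigm: StimulusParadigm) -> DeltaBVTrace:
    """Blood-volume relative difference (percent) over an ROI.

    The ROI-averaged signal ``s(t)`` is referenced to the baseline ``b``,
    the mean of ``s`` over frames where the stimulation pattern is
    strictly 0: ``dbv(t) = 100 * (s(t) - b) / b``. Summary values are the
    means over baseline frames (0 by construction) and stimulation frames.
    """
    if roi.mask.shape != series.grid_shape:
        raise ValueError(f"ROI shape {roi.mask.shape} does not match series grid {series.grid_shape}")
    s = series.images[:, roi.mask].mean(axis=1)
    t = series.timestamps()
    stim = paradigm.frame_stim_mask(series.n_frames, series.frame_interval, series.t0)
    base = ~stim
    if not base.any():
        raise ValueError("paradigm has no baseline frames (indicator never 0)")
    b = float(s[base].mean())
    if b <= 0:
        raise ValueError(f"non-physical Power Doppler baseline {b} <= 0")
    dbv = 100.0 * (s - b) / b
    dbv_stim = float(dbv[stim].mean()) if stim.any() else float("nan")
    return DeltaBVTrace(
        t=t,
        dbv=dbv,
        stim_mask=stim,
        baseline_value=b,
        dbv_bl=float(dbv[base].mean()),
        dbv_stim=dbv_stim,
    )


@dataclass
class HRFFit:
    """Result of fitting HRF parameters to a measured dBV trace."""

    params: HRFParams
    scale: float
    cost: float
    identifiable: bool
    message: str = ""


def fit_hrf_params(
    trace: DeltaBVTrace,
    paradigm: StimulusParadigm,
    bounds: dict | None = None,
    n_starts: int = 2,
    seed: int = 0,
) -> HRFFit:
    """Bounded nonlinear least squares of the HRF shape to a measured trace.

    Optimizes ``(d1, d2, d3, d4, c1, c2, scale)`` so that
    ``scale * (paradigm (*) HRF)`` matches ``trace.dbv``. A near-zero
    fitted scale flags the durations as non-identifiable (flat trace).
    """
    lo = {"d1": 0.0, "d2": 0.05, "d3": 0.05, "d4": 0.0, "c1": 0.0, "c2": 0.0, "scale": -np.inf}
    hi = {"d1": 5.0, "d2": 10.0, "d3": 10.0, "d4": 10.0, "c1": 1.0, "c2": 1.0, "scale": np.inf}
    if bounds:
        for k, (a, b) in bounds.items():
            lo[k], hi[k] = a, b
    keys = ["d1", "d2", "d3", "d4", "c1", "c2", "scale"]
    lower = np.array([lo[k] for k in keys])
    upper = np.array([hi[k] for k in keys])

    n_frames = trace.t.size
    frame_interval = float(trace.t[1] - trace.t[0]) if n_frames > 1 else paradigm.dt
    t0 = float(trace.t[0]) - 0.5 * frame_interval

    def model(theta):
        d1, d2, d3, d4, c1, c2, scale = theta
        params = HRFParams(d1=d1, d2=d2, d3=d3, d4=d4, c1=c1, c2=c2)
        X = build_design(paradigm, params, n_frames, frame_interval, t0=t0)
        return scale * X[:, 0]

    def resid(theta):
        return model(theta) - trace.dbv

    rng = np.random.default_rng(seed)
    amp0 = trace.dbv.max() - trace.dbv.min()
    base_start = np.array([0.0, 1.0, 2.0, 2.0, 0.0, 0.1, max(amp0, 1e-6)])
    best = None
    msgs = []
    for i in range(n_starts):
        x0 = base_start.copy()
        if i > 0:
            jitter = rng.uniform(0.7, 1.4, size=7)
            x0[:4] = np.clip(x0[:4] * jitter[:4] + 0.2, lower[:4], upper[:4])
            x0 = np.clip(x0, lower, upper)
        try:
            res = scipy.optimize.least_squares(resid, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            msgs.append(str(exc))
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"HRF fit failed to converge: {'; '.join(msgs)}")
    d1, d2, d3, d4, c1, c2, scale = best.x
    data_scale = max(np.ptp(trace.dbv), 1e-12)
    identifiable = abs(scale) > 1e-3 * data_scale
    if not identifiable:
        log.warning("HRF fit: scale ~ 0, duration estimates are non-identifiable")
    return HRFFit(
        params=HRFParams(d1=d1, d2=d2, d3=d3, d4=d4, c1=c1, c2=c2),
        scale=float(scale),
        cost=float(best.cost),
        identifiable=identifiable,
        message=best.message,
    )
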