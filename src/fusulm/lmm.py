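"""Linear mixed models for evoked blood-volume responses.

Two intercept-only nested random-effect forms are supported, matching the
hierarchical structure of evoked-response data (stimulations within
acquisitions within animals):

* one-level:  Y_ik  = delta + R_i + W_ik
* two-level:  Y_ijk = delta + R_i + A_ij + W_ijk

where ``delta`` is the fixed effect (e.g. the ipsilateral-contralateral
dBV difference), ``R_i`` a zero-mean random rat effect, ``A_ij`` a
zero-mean random acquisition effect nested in rat, and ``W`` the
residual. Models are fitted by restricted maximum likelihood (REML);
the fixed effect is tested with an F test and random effects with a
likelihood-ratio test between nested fits. Responses are variance-
stabilized beforehand with the signed square root.

The REML objective is evaluated in closed form from per-group sufficient
statistics (counts, means, within-group sums of squares), so a fit costs
O(number of groups) per likelihood evaluation regardless of n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "DBVRecord",
    "LMMResult",
    "signed_sqrt",
    "fit_lmm",
    "test_fixed_effect",
    "test_random_effect",
    "check_residual_normality",
]

log = logging.getLogger(__name__)

_FORMS = ("iid", "one_level", "two_level")


def signed_sqrt(x, literal: bool = False):
    """Variance-stabilizing square-root transform of dBV values.

    Default (sign-preserving): ``sign(x) * sqrt(|x|)``, an odd, strictly
    increasing map whose inverse is ``sign(y) * y**2``. With
    ``literal=True`` negative inputs map to ``+sqrt(-x)``, which destroys
    the ordering of the data and is provided only for comparison.
    """
    x = np.asarray(x, dtype=float)
    root = np.sqrt(np.abs(x))
    out = root if literal else np.sign(x) * root
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DBVRecord:
    """One transformed dBV response in the rat/acquisition/stimulation hierarchy."""

    rat: str | int
    y: float
    acquisition: str | int | None = None
    stimulation: int | None = None
    side: str = ""
    period: str = ""


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([
            {"rat": r.rat, "acquisition": r.acquisition, "y": r.y} for r in records
        ])
    if "y" not in df or "rat" not in df:
        raise ValueError("records must provide 'rat' and 'y'")
    if "acquisition" not in df:
        df["acquisition"] = 0
    df["acquisition"] = df["acquisition"].fillna(0)
    if not np.all(np.isfinite(df["y"].to_numpy(float))):
        raise ValueError("responses contain non-finite values")
    return df


@dataclass
class _GroupStats:
    """Flattened nested sufficient statistics.

    One entry per innermost group (acquisition for the two-level form,
    whole rat for the one-level form): count, mean, within-group sum of
    squares, and the index of the rat the group belongs to.
    """

    n_g: np.ndarray
    mean_g: np.ndarray
    ssw_g: np.ndarray
    rat_idx: np.ndarray
    n_rats: int
    n_obs: int


def _nested_stats(df: pd.DataFrame, nest_acquisitions: bool) -> _GroupStats:
    n_g, mean_g, ssw_g, rat_idx = [], [], [], []
    for i, (_, sub) in enumerate(df.groupby("rat", sort=True)):
        groups = (
            [g["y"].to_numpy(float) for _, g in sub.groupby("acquisition", sort=True)]
            if nest_acquisitions
            else [sub["y"].to_numpy(float)]
        )
        for g in groups:
            n_g.append(len(g))
            mean_g.append(g.mean())
            ssw_g.append(((g - g.mean()) ** 2).sum())
            rat_idx.append(i)
    return _GroupStats(
        n_g=np.asarray(n_g, float),
        mean_g=np.asarray(mean_g),
        ssw_g=np.asarray(ssw_g),
        rat_idx=np.asarray(rat_idx),
        n_rats=int(rat_idx[-1]) + 1,
        n_obs=int(len(df)),
    )


def _reml_quantities(stats: _GroupStats, sig_r: float, sig_a: float, sig_w: float):
    """REML log-likelihood for V = sig_w I + sig_a J_acq + sig_r J_rat.

    Evaluated in closed form from the sufficient statistics via the
    Woodbury identity on the nested block structure. Returns
    ``(loglik, delta_hat, var_delta)``.
    """
    n_g, m_g, rat = stats.n_g, stats.mean_g, stats.rat_idx
    a_g = sig_w + n_g * sig_a
    logdet = float(np.sum((n_g - 1) * np.log(sig_w)) + np.sum(np.log(a_g)))
    u_i = np.bincount(rat, weights=n_g / a_g, minlength=stats.n_rats)
    v_i = np.bincount(rat, weights=n_g * m_g / a_g, minlength=stats.n_rats)
    q = float(np.sum(stats.ssw_g) / sig_w + np.sum(n_g * m_g**2 / a_g))
    shrink = 1.0 + sig_r * u_i
    logdet += float(np.sum(np.log(shrink)))
    yVy = q - sig_r * float(np.sum(v_i**2 / shrink))
    oneVone = float(np.sum(u_i / shrink))
    oneVy = float(np.sum(v_i / shrink))
    delta = oneVy / oneVone
    yPy = yVy - oneVy**2 / oneVone
    loglik = -0.5 * (logdet + np.log(oneVone) + yPy + (stats.n_obs - 1) * np.log(2 * np.pi))
    return loglik, delta, 1.0 / oneVone


@dataclass
class LMMResult:
    """REML fit of one of the nested intercept-only mixed-model forms."""

    form: str
    delta_hat: float
    se_delta: float
    sigma2_rat: float
    sigma2_acq: float | None
    sigma2_resid: float
    reml_loglik: float
    n_obs: int
    n_rats: int
    n_acquisitions: int
    flags: list[str] = field(default_factory=list)
    fstat: float | None = None
    f_df: tuple[int, int] | None = None
    f_p: float | None = None
    _df: pd.DataFrame | None = None
    _stats: _GroupStats | None = None

    def variance_components(self) -> dict[str, float]:
        out = {"rat": self.sigma2_rat, "residual": self.sigma2_resid}
        if self.sigma2_acq is not None:
            out["acquisition"] = self.sigma2_acq
        return out


def _moment_starts(stats: _GroupStats, form: str) -> list[np.ndarray]:
    """Two optimization starts: ANOVA-flavoured moments and an even split."""
    tot_ssw = float(stats.ssw_g.sum())
    n_groups = len(stats.n_g)
    sw = max(tot_ssw / max(stats.n_obs - n_groups, 1), 1e-8)
    between = max(float(np.var(stats.mean_g)), 1e-8)
    total = sw + between
    if form == "one_level":
        return [np.log([between, sw]), np.log([total / 2, total / 2])]
    rat_means = np.bincount(stats.rat_idx, weights=stats.mean_g) / np.bincount(stats.rat_idx)
    br = max(float(np.var(rat_means)), 1e-8)
    ba = max(between - br, 1e-8)
    return [np.log([br, ba, sw]), np.log([total / 3, total / 3, total / 3])]


def _unpack(theta: np.ndarray, form: str) -> tuple[float, float, float]:
    v = np.exp(np.clip(theta, -60, 60))
    if form == "one_level":
        # each rat is a single innermost group, so the rat variance lives
        # in the group (J_acq) slot and the outer slot stays zero
        return 0.0, v[0], v[1]
    return v[0], v[1], v[2]


def _pack_vars(form: str, sig: tuple[float, float, float]):
    """Map engine slots back to named components.

    The engine's nested structure is (rat, acquisition, residual); for the
    one-level form the rat effect occupies the acquisition slot (each rat
    is a single group) and the outer slot is held at zero.
    """
    sig_r, sig_a, sig_w = sig
    if form == "one_level":
        return sig_a, None, sig_w
    return sig_r, sig_a, sig_w


def fit_lmm(records, form: str = "one_level") -> LMMResult:
    """REML fit of an intercept-only nested mixed model.

    Parameters
    ----------
    records : DataFrame or list of DBVRecord
        Must provide ``rat`` and ``y``; ``acquisition`` is required for the
        two-level form.
    form : {"one_level", "two_level", "iid"}
        ``one_level``: Y = delta + R_i + W; ``two_level``:
        Y = delta + R_i + A_ij + W; ``iid``: Y = delta + W (the reduced
        model of the rat-effect likelihood-ratio test).
    """
    if form not in _FORMS:
        raise ValueError(f"form must be one of {_FORMS}, got {form!r}")
    df = _to_frame(records)
    n_obs = len(df)
    n_rats = df["rat"].nunique()
    n_acq = df.groupby("rat")["acquisition"].nunique().sum() if form == "two_level" else n_rats
    flags: list[str] = []

    if form in ("one_level", "two_level") and n_rats < 2:
        raise ValueError(f"need >= 2 rats for the {form} form, got {n_rats} (degenerate rat level)")
    if n_obs < 3:
        raise ValueError("need at least 3 observations")

    if form == "two_level":
        acq_per_rat = df.groupby("rat")["acquisition"].nunique()
        if (acq_per_rat == 1).all():
            flags.append("acquisition_variance_confounded_with_rat")
            log.warning("every rat has a single acquisition: sigma2_acq is confounded with "
                        "sigma2_rat; fitting the one-level form and reporting sigma2_acq = 0")
            inner = fit_lmm(df, form="one_level")
            return LMMResult(
                form="two_level", delta_hat=inner.delta_hat, se_delta=inner.se_delta,
                sigma2_rat=inner.sigma2_rat, sigma2_acq=0.0, sigma2_resid=inner.sigma2_resid,
                reml_loglik=inner.reml_loglik, n_obs=n_obs, n_rats=n_rats,
                n_acquisitions=int(n_acq), flags=flags + inner.flags,
                _df=df, _stats=inner._stats,
            )

    if form == "one_level":
        obs_per_rat = df.groupby("rat")["y"].size()
        if (obs_per_rat == 1).all():
            flags.append("rat_variance_confounded_with_residual")
            log.warning("one observation per rat: sigma2_rat is confounded with the residual; "
                        "fitting the iid form and reporting sigma2_rat = 0")
            inner = fit_lmm(df, form="iid")
            return LMMResult(
                form="one_level", delta_hat=inner.delta_hat, se_delta=inner.se_delta,
                sigma2_rat=0.0, sigma2_acq=None, sigma2_resid=inner.sigma2_resid,
                reml_loglik=inner.reml_loglik, n_obs=n_obs, n_rats=n_rats,
                n_acquisitions=n_rats, flags=flags + inner.flags, _df=df, _stats=inner._stats,
            )

    y = df["y"].to_numpy(float)
    if form == "iid":
        s2 = float(np.var(y, ddof=1))
        if s2 <= 0:
            raise ValueError("zero-variance responses: residual level is degenerate")
        stats = _nested_stats(df.assign(rat=0, acquisition=0), nest_acquisitions=True)
        ll, delta, var_delta = _reml_quantities(stats, 0.0, 0.0, s2)
        return LMMResult(
            form="iid", delta_hat=float(delta), se_delta=float(np.sqrt(var_delta)),
            sigma2_rat=0.0, sigma2_acq=None, sigma2_resid=s2, reml_loglik=float(ll),
            n_obs=n_obs, n_rats=n_rats, n_acquisitions=int(n_acq), flags=flags,
            _df=df, _stats=stats,
        )

    stats = _nested_stats(df, nest_acquisitions=(form == "two_level"))

    def neg_loglik(theta):
        sig = _unpack(theta, form)
        ll, *_ = _reml_quantities(stats, *sig)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for x0 in _moment_starts(stats, form):
        res = scipy.optimize.minimize(
            neg_loglik, x0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000, "maxfev": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    sig = list(_unpack(best.x, form))

    # snap vanishing components to the boundary when this does not lower
    # the restricted likelihood (tolerance 1e-9 on the log-likelihood)
    scale = float(np.var(y)) or 1.0
    ll_opt = -best.fun
    for idx in range(2):  # never snap the residual component
        if 0 < sig[idx] < 1e-8 * scale:
            trial = sig.copy()
            trial[idx] = 0.0
            ll_trial, *_ = _reml_quantities(stats, *trial)
            if ll_trial >= ll_opt - 1e-9:
                sig, ll_opt = trial, max(ll_opt, ll_trial)

    ll, delta, var_delta = _reml_quantities(stats, *sig)
    sigma2_rat, sigma2_acq, sigma2_resid = _pack_vars(form, tuple(sig))
    return LMMResult(
        form=form, delta_hat=float(delta), se_delta=float(np.sqrt(var_delta)),
        sigma2_rat=float(sigma2_rat),
        sigma2_acq=None if sigma2_acq is None else float(sigma2_acq),
        sigma2_resid=float(sigma2_resid), reml_loglik=float(ll),
        n_obs=n_obs, n_rats=n_rats, n_acquisitions=int(n_acq), flags=flags,
        _df=df, _stats=stats,
    )


def _levels_used(result: LMMResult) -> int:
    """Random-effect levels that actually absorb variance in the fit."""
    levels = 0
    if result.sigma2_rat > 0:
        levels += result.n_rats
    if result.sigma2_acq is not None and result.sigma2_acq > 0 and result.form == "two_level":
        levels += result.n_acquisitions
    return levels


def test_fixed_effect(result: LMMResult, ddf_method: str = "residual") -> LMMResult:
    """F test of the nullity of the fixed effect, H0: delta = 0.

    ``F = (delta_hat / SE)**2`` with numerator df 1. The denominator df is
    the residual df ``n_obs - 1 - (number of random-effect levels used)``
    by default, or a Satterthwaite approximation with
    ``ddf_method="satterthwaite"``. Results are stored on the LMMResult
    (``fstat``, ``f_df``, ``f_p``) and returned.
    """
    F = (result.delta_hat / result.se_delta) ** 2
    if ddf_method == "residual":
        ddf = result.n_obs - 1 - _levels_used(result)
        if ddf < 1:
            ddf = 1
            result.flags.append("denominator_df_floored_at_1")
    elif ddf_method == "satterthwaite":
        ddf = _satterthwaite_df(result)
    else:
        raise ValueError("ddf_method must be 'residual' or 'satterthwaite'")
    p = float(scipy.stats.f.sf(F, 1, ddf))
    result.fstat = float(F)
    result.f_df = (1, int(round(ddf)) if ddf_method == "residual" else ddf)
    result.f_p = p
    return result


def _free_sigmas(result: LMMResult) -> tuple[list[float], str]:
    if result.form == "one_level":
        return [result.sigma2_rat, result.sigma2_resid], "one_level"
    if result.form == "two_level":
        return [result.sigma2_rat, result.sigma2_acq or 0.0, result.sigma2_resid], "two_level"
    return [result.sigma2_resid], "iid"


def _satterthwaite_df(result: LMMResult) -> float:
    """Satterthwaite denominator df: 2 * Var(delta)^2 / Var[Var(delta)],
    with the variance of the variance estimate taken from the inverse
    observed REML information (finite differences)."""
    if result._stats is None:
        raise ValueError("fit was not produced by fit_lmm")
    sig0, form = _free_sigmas(result)
    sig0 = np.asarray(sig0, float)
    stats = result._stats

    def engine_args(s):
        if form == "one_level":
            return (0.0, s[0], s[1])
        if form == "two_level":
            return (s[0], s[1], s[2])
        return (0.0, 0.0, s[0])

    def loglik(s):
        return _reml_quantities(stats, *engine_args(s))[0]

    def var_delta(s):
        return _reml_quantities(stats, *engine_args(s))[2]

    k = len(sig0)
    h = np.maximum(1e-5 * np.abs(sig0), 1e-10)
    grad = np.empty(k)
    for i in range(k):
        sp, sm = sig0.copy(), sig0.copy()
        sp[i] += h[i]
        sm[i] = max(sm[i] - h[i], 0.0)
        grad[i] = (var_delta(sp) - var_delta(sm)) / (sp[i] - sm[i])
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            spp, spm, smp, smm = (sig0.copy() for _ in range(4))
            spp[i] += h[i]; spp[j] += h[j]
            spm[i] += h[i]; spm[j] = max(spm[j] - h[j], 0.0)
            smp[i] = max(smp[i] - h[i], 0.0); smp[j] += h[j]
            smm[i] = max(smm[i] - h[i], 0.0); smm[j] = max(smm[j] - h[j], 0.0)
            hess[i, j] = hess[j, i] = (
                loglik(spp) - loglik(spm) - loglik(smp) + loglik(smm)
            ) / ((spp[i] - smm[i]) * (spp[j] - smm[j]))
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    v = var_delta(sig0)
    denom = float(grad @ cov @ grad)
    if denom <= 0:
        return float(result.n_obs - 1)
    return float(2 * v**2 / denom)


_NESTED_PAIRS = {
    ("two_level", "one_level"), ("one_level", "iid"), ("two_level", "iid"),
    # identical forms are trivially nested: LR = 0, p = 1
    ("iid", "iid"), ("one_level", "one_level"), ("two_level", "two_level"),
}


def test_random_effect(full: LMMResult, reduced: LMMResult, boundary_mixture: bool = False):
    """Likelihood-ratio test of a random effect between nested REML fits.

    ``LR = 2 * (loglik_full - loglik_reduced)`` referred to chi-squared
    with 1 df (the plain reference; conservative for a variance component
    on the boundary). ``boundary_mixture=True`` uses the
    0.5*chi2_0 + 0.5*chi2_1 mixture instead. Returns ``(LR, p)``.
    """
    if (full.form, reduced.form) not in _NESTED_PAIRS:
        raise ValueError(
            f"models are not nested: full={full.form!r}, reduced={reduced.form!r}"
        )
    if full.n_obs != reduced.n_obs:
        raise ValueError("full and reduced fits use different data")
    lr = max(0.0, 2.0 * (full.reml_loglik - reduced.reml_loglik))
    if lr == 0.0:
        return 0.0, 1.0
    p = float(scipy.stats.chi2.sf(lr, df=1))
    if boundary_mixture:
        p = 0.5 * p
    return float(lr), p


def conditional_residuals(result: LMMResult) -> np.ndarray:
    """Residuals after subtracting the fixed effect and the BLUPs of all
    random effects (rat, and acquisition where present)."""
    if result._df is None or result._stats is None:
        raise ValueError("fit does not carry its data")
    df = result._df
    if result.form == "iid" or "rat_variance_confounded_with_residual" in result.flags:
        return df["y"].to_numpy(float) - result.delta_hat

    sig_r = result.sigma2_rat if result.form == "two_level" else 0.0
    sig_a = result.sigma2_acq if result.form == "two_level" else result.sigma2_rat
    if result.form == "two_level" and "acquisition_variance_confounded_with_rat" in result.flags:
        sig_r, sig_a = 0.0, result.sigma2_rat
    sig_w = result.sigma2_resid

    nest = result.form == "two_level" and "acquisition_variance_confounded_with_rat" not in result.flags
    out = np.empty(len(df))
    pos = 0
    for _, sub in df.groupby("rat", sort=True):
        groups = (
            [g for _, g in sub.groupby("acquisition", sort=True)] if nest else [sub]
        )
        n_j = np.array([len(g) for g in groups])
        r_j = np.array([g["y"].mean() - result.delta_hat for g in groups])
        a_j = sig_w + n_j * sig_a
        u = np.sum(n_j / a_j)
        v = np.sum(n_j * r_j / a_j)
        b_rat = sig_r * v / (1.0 + sig_r * u)
        for g, n, rbar, a in zip(groups, n_j, r_j, a_j):
            b_acq = sig_a * n * (rbar - b_rat) / a
            res = g["y"].to_numpy(float) - result.delta_hat - b_rat - b_acq
            out[pos : pos + n] = res
            pos += n
    return out


def check_residual_normality(result: LMMResult):
    """Shapiro-Wilk normality test of the conditional residuals.

    Returns ``(statistic, p)``; raises on constant residuals (the test is
    undefined there).
    """
    resid = conditional_residuals(result)
    if len(resid) < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(resid) < 1e-12 * max(1.0, np.abs(resid).max()):
        raise ValueError("residuals are constant; normality test undefined")
    stat, p = scipy.stats.shapiro(resid)
    return float(stat), float(p)
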