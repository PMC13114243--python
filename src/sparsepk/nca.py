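"""Noncompartmental analysis for sparse composite profiles.

Implements the conventional NCA quantities for a single-bolus arm:
terminal elimination rate constant (lambda_z) by a best-adjusted-R^2 scan of
log-linear terminal windows, linear-up/log-down trapezoidal AUC, AUC
extrapolation to infinity via C_last/lambda_z, IV back-extrapolated C0,
Cmax/Tmax, dose-normalized AUC, and bioavailability as the ratio of
dose-normalized extravascular to IV AUC0-inf.

Because profiles are composites across destructively sampled animals, the
AUC/Cmax quantities are computed on pooled per-timepoint summary profiles
(mean by default), while the lambda_z regression can run on raw replicate
points or on the pooled curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .study import Profile, StudyArm, pool_profile

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "NCAOptions",
    "fit_lambda_z",
    "auc_linlog",
    "extrapolate_auc",
    "back_extrapolate_c0",
    "nca_summary",
    "bioavailability",
]


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float  # 1/h, > 0
    log_intercept: float  # ln(ng/mL) intercept at t = 0
    adj_r2: float
    n_points: int
    t_start: float | None = None  # first time in the selected window

    @property
    def t_half(self) -> float:
        return float(np.log(2.0) / self.lambda_z)

    @property
    def intercept(self) -> float:
        """Back-extrapolated intercept concentration exp(log_intercept)."""
        return float(np.exp(self.log_intercept))


@dataclass(frozen=True)
class NCAResult:
    analyte: str
    route: str
    dose_ug: float
    lambda_z: float
    t_half: float
    c0: float | None  # IV only
    cmax: float
    tmax: float | None  # extravascular only
    auc_partial: float
    auc_inf: float
    pct_extrapolated: float
    auc_inf_per_dose: float
    n_lambda_points: int
    adj_r2: float

    def __post_init__(self) -> None:
        if not (self.auc_inf >= self.auc_partial >= 0):
            raise ValueError("requires auc_inf >= auc_partial >= 0")
        if not (0 <= self.pct_extrapolated < 100):
            raise ValueError("pct_extrapolated must be in [0, 100)")


@dataclass(frozen=True)
class NCAOptions:
    """Knobs for :func:`nca_summary`.

    pool : {"mean", "median", "raw"}
        Data fed to the lambda_z regression.  ``mean`` averages terminal
        concentrations per timepoint (appropriate for slowly eliminated
        analytes where terminal averaging stabilizes the composite profile);
        ``raw`` regresses on every replicate point.
    cmax_stat : {"mean", "median"}
        Pooling statistic for the summary profile used for Cmax/Tmax and AUC.
    partial_to : float, optional
        Cutoff for AUC_partial; defaults to the last quantifiable pooled time.
    """

    pool: str = "mean"
    cmax_stat: str = "mean"
    lambda_selection: str = "best_fit"
    lambda_window: tuple[float, float] | None = None
    partial_to: float | None = None


def _ols_loglinear(times: np.ndarray, concs: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(conc) on time; returns (slope, intercept, adj_r2)."""
    y = np.log(concs)
    n = times.size
    X = np.column_stack([np.ones(n), times])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(beta[1]), float(beta[0]), float(adj)


def fit_lambda_z(
    profile: Profile,
    selection: str = "best_fit",
    window: tuple[float, float] | None = None,
    min_points: int = 3,
) -> LambdaZFit:
    """Terminal elimination rate constant from a log-linear regression.

    ``best_fit`` scans every suffix window of at least ``min_points`` points
    over the distinct times strictly after Tmax (the Cmax point itself is
    excluded) and keeps the window with the highest adjusted R^2 among those
    with a negative slope; ties go to the window with more points.  A manual
    ``window=(t_lo, t_hi)`` overrides the scan (>= 2 distinct times needed).
    """
    t = profile.times
    c = profile.concs
    keep = c > 0
    t, c = t[keep], c[keep]
    if t.size < 2:
        raise ValueError("lambda_z requires >= 2 positive-concentration points")

    if selection == "manual" or window is not None:
        lo, hi = window
        sel = (t >= lo) & (t <= hi)
        if np.unique(t[sel]).size < 2:
            raise ValueError("manual lambda_z window needs >= 2 distinct times")
        slope, intercept, adj = _ols_loglinear(t[sel], c[sel])
        if slope >= 0:
            raise ValueError("no elimination: non-negative terminal slope in window")
        return LambdaZFit(-slope, intercept, adj, int(sel.sum()), float(t[sel].min()))

    if selection != "best_fit":
        raise ValueError(f"unknown lambda_z selection {selection!r}")

    # distinct-time bookkeeping so raw profiles with replicates work too
    uniq = np.unique(t)
    means = np.array([c[t == u].mean() for u in uniq])
    tmax_u = uniq[np.argmax(means)]
    post = uniq[uniq > tmax_u]
    if post.size < min_points:
        raise ValueError(
            f"best-fit lambda_z needs >= {min_points} distinct post-peak times"
        )
    best: LambdaZFit | None = None
    for start in range(post.size - min_points + 1):
        wtimes = post[start:]
        sel = np.isin(t, wtimes)
        slope, intercept, adj = _ols_loglinear(t[sel], c[sel])
        if slope >= 0:
            continue
        cand = LambdaZFit(-slope, intercept, adj, int(sel.sum()), float(wtimes[0]))
        if (
            best is None
            or cand.adj_r2 > best.adj_r2 + 1e-10
            or (abs(cand.adj_r2 - best.adj_r2) <= 1e-10 and cand.n_points > best.n_points)
        ):
            best = cand
    if best is None:
        raise ValueError("no elimination: every candidate window has non-negative slope")
    return best


def _segment_auc(t1, t2, c1, c2) -> float:
    dt = t2 - t1
    if c1 <= 0 or c2 <= 0 or c2 >= c1:
        return 0.5 * (c1 + c2) * dt  # linear-up (or degenerate) trapezoid
    return (c1 - c2) / np.log(c1 / c2) * dt  # log-down trapezoid


def _interp_conc(t1, t2, c1, c2, t) -> float:
    if c1 <= 0 or c2 <= 0 or c2 >= c1:
        return c1 + (c2 - c1) * (t - t1) / (t2 - t1)
    return float(c1 * (c2 / c1) ** ((t - t1) / (t2 - t1)))


def auc_linlog(profile: Profile, t_end: float | None = None) -> float:
    """Linear-up/log-down trapezoidal AUC (ng*h/mL).

    Rising or non-positive segments use the linear trapezoid; strictly
    declining positive segments use the log trapezoid (exact for
    mono-exponential decay through the two points).  ``t_end`` truncates the
    AUC at an interpolated cutoff within the observed range.
    """
    t = profile.times
    c = profile.concs
    if t.size < 2:
        raise ValueError("AUC requires >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("AUC requires strictly increasing times (pool first)")
    if t_end is not None:
        if t_end <= t[0]:
            raise ValueError("t_end must lie after the first point")
        if t_end > t[-1]:
            raise ValueError("t_end beyond the observed range")
    total = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        if t_end is not None and t2 >= t_end:
            if t_end > t1:
                c_cut = _interp_conc(t1, t2, c1, c2, t_end)
                total += _segment_auc(t1, t_end, c1, c_cut)
            break
        total += _segment_auc(t1, t2, c1, c2)
    return float(total)


def extrapolate_auc(profile: Profile, lambda_z: float) -> tuple[float, float]:
    """AUC0-inf = AUC_last + C_last/lambda_z, with percent extrapolated."""
    if lambda_z <= 0:
        raise ValueError("lambda_z must be > 0")
    c_last = float(profile.concs[-1])
    if c_last <= 0:
        raise ValueError("last concentration must be > 0 to extrapolate")
    auc_last = auc_linlog(profile) if len(profile) > 1 else 0.0
    tail = c_last / lambda_z
    auc_inf = auc_last + tail
    return float(auc_inf), float(100.0 * tail / auc_inf)


def back_extrapolate_c0(profile: Profile) -> float:
    """IV initial concentration by log-linear back-extrapolation.

    Extrapolates through the first two points to t = 0; if the profile is not
    declining there, falls back to the first observed concentration with a
    warning.
    """
    if len(profile) < 2:
        raise ValueError("C0 back-extrapolation requires >= 2 points")
    t1, t2 = profile.times[:2]
    c1, c2 = profile.concs[:2]
    if c1 > 0 and c2 > 0 and c2 < c1:
        slope = (np.log(c2) - np.log(c1)) / (t2 - t1)
        return float(np.exp(np.log(c1) - slope * t1))
    warnings.warn(
        "first two points not declining; using first observed concentration as C0",
        RuntimeWarning,
    )
    return float(c1)


def nca_summary(arm: StudyArm, options: NCAOptions | None = None) -> NCAResult:
    """Full NCA summary of a preprocessed arm.

    The summary (Cmax/Tmax and AUC) runs on the pooled per-timepoint profile;
    lambda_z runs on raw or pooled data per ``options.pool``.  IV profiles are
    anchored at (0, C0) by log-linear back-extrapolation; extravascular
    profiles at (0, 0).
    """
    opt = options or NCAOptions()
    pooled = pool_profile(arm, stat=opt.cmax_stat, scope="all")
    if opt.pool == "raw":
        lam_profile = pool_profile(arm, stat="raw", scope="all")
    else:
        lam_profile = pool_profile(arm, stat=opt.pool, scope="all")
    lam = fit_lambda_z(
        lam_profile,
        selection="manual" if opt.lambda_window else opt.lambda_selection,
        window=opt.lambda_window,
    )

    cmax = float(pooled.concs.max())
    is_iv = arm.route == "IV"
    tmax = None if is_iv else float(pooled.times[np.argmax(pooled.concs)])
    c0 = back_extrapolate_c0(pooled) if is_iv else None

    anchored = pooled if pooled.times[0] == 0 else pooled.prepend(
        0.0, c0 if is_iv else 0.0
    )
    partial_to = opt.partial_to if opt.partial_to is not None else float(
        anchored.times[-1]
    )
    auc_partial = auc_linlog(anchored, t_end=partial_to)
    auc_inf, pct_extrap = extrapolate_auc(anchored, lam.lambda_z)

    return NCAResult(
        analyte=arm.analyte,
        route=arm.route,
        dose_ug=arm.dose_ug,
        lambda_z=lam.lambda_z,
        t_half=lam.t_half,
        c0=c0,
        cmax=cmax,
        tmax=tmax,
        auc_partial=auc_partial,
        auc_inf=auc_inf,
        pct_extrapolated=pct_extrap,
        auc_inf_per_dose=auc_inf / arm.dose_ng,
        n_lambda_points=lam.n_points,
        adj_r2=lam.adj_r2,
    )


def bioavailability(nca_sq: NCAResult, nca_iv: NCAResult) -> float:
    """%F = 100 * dose-normalized SQ AUC0-inf / dose-normalized IV AUC0-inf."""
    if nca_sq.analyte != nca_iv.analyte:
        raise ValueError(
            f"analyte mismatch: {nca_sq.analyte!r} vs {nca_iv.analyte!r}"
        )
    if nca_sq.auc_inf_per_dose <= 0 or nca_iv.auc_inf_per_dose <= 0:
        raise ValueError("dose-normalized AUCs must be > 0")
    return 100.0 * nca_sq.auc_inf_per_dose / nca_iv.auc_inf_per_dose
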