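"""Naive-pooled maximum-likelihood fitting of macroconstant disposition models.

An IV bolus concentration-time curve for a linear n-compartment system is a
sum of n exponentials ("macroconstant" parameterization):

    C(t) = sum_i A_i * exp(-lambda_i * t),   lambda_1 > ... > lambda_n > 0

With one destructive sample per animal, between-animal random effects are not
identifiable, so all samples are pooled into a single residual-error
likelihood (naive pooling); the fixed effects alone define the unit impulse
response used downstream.

The optimizer works in an unconstrained space - log coefficients, log slowest
rate, and log gaps between successive rates - which enforces positivity and
strict rate ordering without constrained optimization.  The residual sigma is
profiled out in closed form at each structural evaluation.  Parameter CV% is
obtained from the observed information (finite-difference Hessian of -2LL)
mapped to the natural scale by the delta method, and the condition number is
taken from the correlation-scaled Hessian.

:class:`MacroexponentialModel` is a scikit-learn style estimator
(``fit(X, y)`` on times/concentrations, ``predict``, ``get_params``); the
module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ErrorModel
from .nca import fit_lambda_z, _ols_loglinear
from .study import Profile, StudyArm, pool_profile

__all__ = [
    "MacroModel",
    "MacroFit",
    "MacroexponentialModel",
    "NonIdentifiableError",
    "strip_initial_estimates",
    "neg2ll",
    "fit_macro",
    "select_model",
    "predict_conc",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class NonIdentifiableError(ValueError):
    """The data show fewer distinct exponential phases than requested terms."""


@dataclass(frozen=True)
class MacroModel:
    """A fitted (or true) polyexponential IV disposition model.

    ``terms`` are (coefficient ng/mL, rate 1/h) pairs ordered by strictly
    decreasing rate; for two terms these are (A, alpha) and (B, beta).
    """

    terms: tuple[tuple[float, float], ...]
    dose_ug: float | None = None
    error_model: ErrorModel | None = None
    analyte: str | None = None

    def __post_init__(self) -> None:
        terms = tuple((float(c), float(r)) for c, r in self.terms)
        object.__setattr__(self, "terms", terms)
        if any(c <= 0 or r <= 0 for c, r in terms):
            raise ValueError("coefficients and rates must be > 0")
        rates = [r for _, r in terms]
        if any(a <= b for a, b in zip(rates, rates[1:])):
            raise ValueError("rates must be strictly decreasing")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for c, _ in self.terms])

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.terms])

    def predict(self, times) -> np.ndarray:
        return predict_conc(self, times)

    def auc_inf(self) -> float:
        """Analytic AUC from 0 to infinity: sum_i A_i / lambda_i."""
        return float(sum(c / r for c, r in self.terms))


@dataclass(frozen=True)
class MacroFit:
    """A fitted model plus its likelihood and precision diagnostics."""

    model: MacroModel
    neg2ll: float
    aic: float
    n_params: int
    cv_pct: dict[str, float] | None
    condition_number: float | None
    converged: bool
    n_obs: int


def predict_conc(model: MacroModel, times) -> np.ndarray:
    """C(t) = sum_i A_i exp(-lambda_i t), elementwise over times >= 0."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    out = np.zeros(t.shape, dtype=float)
    for c, r in model.terms:
        out = out + c * np.exp(-r * t)
    return out


def neg2ll(model: MacroModel, profile_or_times, y=None, error_model=None) -> float:
    """-2 log-likelihood of raw points under the model's (or given) error model."""
    if y is None:
        times, yobs = profile_or_times.times, profile_or_times.concs
    else:
        times, yobs = np.asarray(profile_or_times, float), np.asarray(y, float)
    em = error_model or model.error_model
    if em is None:
        raise ValueError("an error model is required")
    return em.neg2ll(yobs, predict_conc(model, times))


# ---------------------------------------------------------------------------
# curve stripping (method of residuals) for initial estimates
# ---------------------------------------------------------------------------

def _per_time_means(t: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.unique(t)
    return uniq, np.array([c[t == u].mean() for u in uniq])


def strip_initial_estimates(profile: Profile, n_terms: int) -> MacroModel:
    """NCA-informed initial estimates by recursive curve stripping.

    The terminal log-linear regression (best adjusted-R^2 window) supplies the
    slowest term: exp(intercept) -> coefficient, slope -> rate.  Its
    back-extrapolated contribution is subtracted from the points before the
    terminal window, and the residual curve is stripped again for the faster
    terms (method of residuals).  Negative or near-zero residuals are floored
    at 1% of the point's concentration before logging; if fewer than two
    distinct early times carry residual above that floor, the earliest floored
    points are kept so the sparse single-fast-phase-point design remains
    strippable.  Raises :class:`NonIdentifiableError` when the data do not
    show ``n_terms`` distinct phases.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    keep = profile.concs > 0
    t, c = _per_time_means(profile.times[keep], profile.concs[keep])
    if t.size < 2 * n_terms:
        raise NonIdentifiableError(
            f"need >= {2 * n_terms} distinct times for {n_terms} terms"
        )

    terms: list[tuple[float, float]] = []
    cur_t, cur_c = t, c
    for k in range(n_terms, 0, -1):
        if k == 1 or cur_t.size < 4:
            slope, intercept, _ = _ols_loglinear(cur_t, cur_c)
            if slope >= 0:
                raise NonIdentifiableError("residual phase is not declining")
            rate, coeff, t_start = -slope, float(np.exp(intercept)), None
        else:
            prof = Profile(cur_t, cur_c, "mean_by_time")
            lam = fit_lambda_z(prof, min_points=min(3, cur_t.size - 1))
            rate, coeff, t_start = lam.lambda_z, lam.intercept, lam.t_start
        if terms and rate <= terms[-1][1] * 1.01:
            raise NonIdentifiableError(
                f"stripped rates not separated ({rate:.4g} vs {terms[-1][1]:.4g}); "
                f"try fewer than {n_terms} terms"
            )
        terms.append((coeff, rate))
        if k == 1:
            break
        # subtract the slow term; the residual before the terminal window
        # carries the faster phases
        early = cur_t < (t_start if t_start is not None else cur_t[-1])
        if early.sum() < 2:
            raise NonIdentifiableError(
                f"no early phase left after stripping; try fewer than {n_terms} terms"
            )
        resid = cur_c - coeff * np.exp(-rate * cur_t)
        floor = 0.01 * cur_c
        meaningful = early & (resid > floor)
        sel = np.flatnonzero(meaningful)
        if sel.size < 2:
            extra = [i for i in np.flatnonzero(early) if i not in sel]
            sel = np.sort(np.concatenate([sel, extra[: 2 - sel.size]]).astype(int))
        if sel.size < 2:
            raise NonIdentifiableError(
                f"no early phase left after stripping; try fewer than {n_terms} terms"
            )
        cur_t = cur_t[sel]
        cur_c = np.maximum(resid, floor)[sel]

    terms.reverse()  # fastest first
    rates = [r for _, r in terms]
    if any(a <= b for a, b in zip(rates, rates[1:])):
        raise NonIdentifiableError("stripped rates are not strictly decreasing")
    return MacroModel(tuple(terms))


def _heuristic_init(t: np.ndarray, y: np.ndarray, n_terms: int) -> MacroModel:
    """Fallback starting model when curve stripping cannot resolve the phases.

    The slowest term comes from the last-three-point log-linear regression.
    Each faster phase is assumed to have largely decayed by the next distinct
    sampling time, which pins its rate at ln(20)/t_next; its coefficient is
    the first-point residual back-extrapolated to t = 0.
    """
    tu, cu = _per_time_means(t, y)
    pos = cu > 0
    tu, cu = tu[pos], cu[pos]
    if tu.size < 2:
        raise NonIdentifiableError("need >= 2 distinct positive times")
    slope, intercept, _ = _ols_loglinear(tu[-3:], cu[-3:])
    if slope >= 0:
        slope = -np.log(2.0) / max(tu[-1], 1.0)  # weakly declining fallback
    beta = -slope
    B = float(np.exp(intercept))
    terms = [(B, beta)]
    for k in range(1, n_terms):
        t_next = tu[min(k, tu.size - 1)]
        rate = max(np.log(20.0) / t_next, terms[-1][1] * 5.0)
        resid = cu[0] - sum(cc * np.exp(-rr * tu[0]) for cc, rr in terms)
        coeff = max(resid, 0.1 * cu[0]) * np.exp(min(rate * tu[0], 50.0))
        terms.append((float(coeff), float(rate)))
    terms.sort(key=lambda cr: -cr[1])
    # enforce strict separation
    fixed = []
    for cc, rr in terms:
        if fixed and rr >= fixed[-1][1] * 0.99:
            rr = fixed[-1][1] * 0.5
        fixed.append((cc, rr))
    return MacroModel(tuple(fixed))


# ---------------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------------

def _pack(model: MacroModel) -> np.ndarray:
    c = np.log(model.coefficients)
    r = model.rates
    u = [np.log(r[-1])] + [np.log(a - b) for a, b in zip(r[:-1], r[1:])][::-1]
    return np.concatenate([c, u])


def _unpack(u: np.ndarray, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    coeffs = np.exp(u[:n_terms])
    slow = np.exp(u[n_terms])
    gaps = np.exp(u[n_terms + 1 :])
    rates = [slow]
    for g in gaps:
        rates.append(rates[-1] + g)
    return coeffs, np.array(rates[::-1])  # decreasing


def _model_from_u(u: np.ndarray, n_terms: int, **kw) -> MacroModel:
    coeffs, rates = _unpack(u, n_terms)
    return MacroModel(tuple(zip(coeffs, rates)), **kw)


class MacroexponentialModel(BaseEstimator, RegressorMixin):
    """Naive-pooled ML polyexponential regression, scikit-learn style.

    Parameters
    ----------
    n_terms : int
        Number of exponential terms (compartments), 1-3 typical.
    error_model : {"additive", "log_additive", "power"}
        Residual error structure; sigma is profiled out at each step.
    gamma : float
        Power-error exponent (held fixed; 1.0 = proportional error).
    n_starts : int
        Multi-start count; starts are the stripped initial estimates plus
        deterministically jittered copies.
    max_rate : float, optional
        Identifiability bound on the fastest rate.  Defaults to 5/t_min
        (t_min = earliest positive sampling time): a phase decaying faster
        than that has vanished by the first sample, so the likelihood is flat
        beyond the bound and estimates there are meaningless.
    init : MacroModel, optional
        Starting model overriding curve stripping.
    random_state : int, optional
        Seed for the jitter stream.
    compute_diagnostics : bool
        Whether to compute CV% and condition number after the fit.

    Attributes
    ----------
    model_ : MacroModel          fitted terms with the fitted error model
    sigma_ : float               profiled residual sigma
    neg2ll_, aic_ : float        fit criteria (aic = neg2ll + 2p)
    n_params_ : int              structural + error parameter count
    cv_pct_ : dict[str, float]   delta-method CV% per natural parameter
    condition_number_ : float    of the correlation-scaled Hessian
    converged_ : bool
    """

    def __init__(
        self,
        n_terms: int = 2,
        error_model: str = "additive",
        gamma: float = 1.0,
        n_starts: int = 10,
        init: MacroModel | None = None,
        random_state: int | None = None,
        compute_diagnostics: bool = True,
        max_rate: float | None = None,
    ):
        self.n_terms = n_terms
        self.error_model = error_model
        self.gamma = gamma
        self.n_starts = n_starts
        self.init = init
        self.random_state = random_state
        self.compute_diagnostics = compute_diagnostics
        self.max_rate = max_rate

    # profiled -2LL objective over structural parameters only
    def _objective(self, u: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            coeffs, rates = _unpack(u, self.n_terms)
            if np.any(~np.isfinite(coeffs)) or np.any(~np.isfinite(rates)):
                return np.inf
            if rates[0] > getattr(self, "_rate_cap", np.inf):
                return np.inf
            f = (coeffs[None, :] * np.exp(-np.outer(t, rates))).sum(axis=1)
            if np.any(~np.isfinite(f)):
                return np.inf
            n = y.size
            # floor the profiled variance so a perfect (noise-free) fit has a
            # finite, well-defined optimum instead of -inf
            if self.error_model == "additive":
                s2 = np.mean((y - f) ** 2)
                s2 = max(s2, (1e-10 * np.sqrt(np.mean(y**2))) ** 2)
                return n * (_LOG2PI + np.log(s2) + 1.0)
            if self.error_model == "log_additive":
                r = np.log(y) - np.log(f)
                s2 = max(np.mean(r**2), 1e-20)
                return n * (_LOG2PI + np.log(s2) + 1.0) + 2.0 * np.sum(np.log(y))
            # power
            w = f ** (2.0 * self.gamma)
            s2 = max(np.mean((y - f) ** 2 / w), 1e-20)
            return n * (_LOG2PI + np.log(s2) + 1.0) + 2.0 * self.gamma * np.sum(
                np.log(f)
            )

    def _profiled_sigma(self, u: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
        coeffs, rates = _unpack(u, self.n_terms)
        f = (coeffs[None, :] * np.exp(-np.outer(t, rates))).sum(axis=1)
        if self.error_model == "additive":
            s2 = max(
                np.mean((y - f) ** 2), (1e-10 * np.sqrt(np.mean(y**2))) ** 2
            )
        elif self.error_model == "log_additive":
            s2 = max(np.mean((np.log(y) - np.log(f)) ** 2), 1e-20)
        else:
            s2 = max(np.mean((y - f) ** 2 / f ** (2.0 * self.gamma)), 1e-20)
        return float(np.sqrt(s2))

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        yobs = np.asarray(y, dtype=float).ravel()
        if t.size != yobs.size:
            raise ValueError("X and y must have equal length")
        p_struct = 2 * self.n_terms
        n_params = p_struct + 1  # + profiled sigma
        if t.size <= n_params:
            raise ValueError(
                f"need more than {n_params} observations for {self.n_terms} terms"
            )
        if self.error_model in ("log_additive", "power") and np.any(yobs <= 0):
            raise ValueError(
                "nonpositive observations under a log/power error model; "
                "impute BLQ values first"
            )
        pos_t = t[t > 0]
        if self.max_rate is not None:
            self._rate_cap = float(self.max_rate)
        else:
            self._rate_cap = 5.0 / float(pos_t.min()) if pos_t.size else np.inf

        inits: list[MacroModel] = []
        if self.init is not None:
            inits.append(self.init)
        else:
            order = np.argsort(t)
            prof = Profile(
                t[order],
                yobs[order],
                "raw" if np.any(np.diff(t[order]) <= 0) else "mean_by_time",
            )
            strip_err: NonIdentifiableError | None = None
            try:
                inits.append(strip_initial_estimates(prof, self.n_terms))
            except NonIdentifiableError as exc:
                strip_err = exc
            if self.n_terms > 1:
                inits.append(_heuristic_init(t, yobs, self.n_terms))
            if not inits:
                raise strip_err
        u0s = [_pack(m) for m in inits]

        # The fastest coefficient/rate pair is often informed by a single
        # early timepoint, leaving a likelihood ridge along which
        # A * exp(-alpha * t_min) is constant.  Sweep deterministic starts
        # along that ridge so the multi-start search covers it.
        ridge_starts: list[np.ndarray] = []
        if self.n_terms > 1:
            t_min = float(t.min())
            for m in inits:
                (a0, al0), rest = m.terms[0], m.terms[1:]
                beta_next = rest[0][1]
                for factor in (0.3, 0.6, 2.0, 4.0, 8.0):
                    al1 = al0 * factor
                    if al1 <= beta_next * 1.05 or al1 * t_min > 50.0:
                        continue
                    a1 = a0 * np.exp((al1 - al0) * t_min)
                    ridge_starts.append(
                        _pack(MacroModel(((a1, al1),) + rest))
                    )

        rng = np.random.default_rng(self.random_state)
        starts = list(u0s) + ridge_starts
        i = 0
        while len(starts) < self.n_starts:
            starts.append(u0s[i % len(u0s)] + rng.normal(0.0, 0.35, size=u0s[0].size))
            i += 1

        best: tuple[float, np.ndarray, bool] | None = None
        for s in starts:
            try:
                r1 = optimize.minimize(
                    self._objective,
                    s,
                    args=(t, yobs),
                    method="Nelder-Mead",
                    options=dict(maxiter=1500, xatol=1e-7, fatol=1e-9, adaptive=True),
                )
            except (FloatingPointError, ValueError):
                continue
            fun, x, ok = float(r1.fun), r1.x, bool(r1.success)
            if np.isfinite(fun) and (best is None or fun < best[0]):
                best = (fun, x, ok)
        if best is None:
            raise RuntimeError("all optimization starts failed")

        # polish the winning start: tight simplex, then a gradient step kept
        # only when it improves the objective (finite-difference gradients are
        # unreliable on the very steep surface near a perfect fit)
        fun, x, ok = best
        r1 = optimize.minimize(
            self._objective,
            x,
            args=(t, yobs),
            method="Nelder-Mead",
            options=dict(maxiter=4000, xatol=1e-10, fatol=1e-12, adaptive=True),
        )
        if np.isfinite(r1.fun) and r1.fun <= fun:
            fun, x, ok = float(r1.fun), r1.x, ok or bool(r1.success)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r2 = optimize.minimize(
                self._objective,
                x,
                args=(t, yobs),
                method="BFGS",
                options=dict(gtol=1e-8, maxiter=200),
            )
        if np.isfinite(r2.fun) and r2.fun < fun:
            fun, x, ok = float(r2.fun), r2.x, ok or bool(r2.success)
        best = (fun, x, ok)

        u_hat = best[1]
        self.sigma_ = self._profiled_sigma(u_hat, t, yobs)
        em = ErrorModel(self.error_model, self.sigma_, self.gamma)
        self.model_ = _model_from_u(u_hat, self.n_terms, error_model=em)
        self.neg2ll_ = float(self._objective(u_hat, t, yobs))
        self.n_params_ = n_params
        self.aic_ = self.neg2ll_ + 2.0 * n_params
        self.n_obs_ = int(t.size)
        self.converged_ = bool(np.isfinite(self.neg2ll_) and best[2])
        self._u_hat = u_hat
        self._t, self._y = t, yobs

        self.cv_pct_ = None
        self.condition_number_ = None
        if self.compute_diagnostics:
            self._diagnostics(u_hat, t, yobs, em)
        return self

    # -- precision diagnostics -------------------------------------------
    def _full_neg2ll(self, theta, t, y):
        # theta = structural u plus log sigma (unprofiled likelihood)
        u = theta[:-1]
        sigma = float(np.exp(theta[-1]))
        coeffs, rates = _unpack(u, self.n_terms)
        model = MacroModel(tuple(zip(coeffs, rates)))
        em = ErrorModel(self.error_model, sigma, self.gamma)
        return em.neg2ll(y, predict_conc(model, t))

    def _diagnostics(self, u_hat, t, y, em) -> None:
        theta = np.concatenate([u_hat, [np.log(self.sigma_)]])
        try:
            H = _fd_hessian(lambda th: self._full_neg2ll(th, t, y), theta)
            d = np.sqrt(np.abs(np.diag(H)))
            if np.any(d == 0) or np.any(~np.isfinite(d)):
                raise np.linalg.LinAlgError("degenerate Hessian diagonal")
            Hs = H / np.outer(d, d)
            sv = np.linalg.svd(Hs, compute_uv=False)
            self.condition_number_ = float(sv.max() / sv.min())
            cov_theta = 2.0 * np.linalg.inv(H)  # observed information = H/2

            # delta method: natural parameters phi(theta)
            def phi(th):
                c, r = _unpack(th[:-1], self.n_terms)
                return np.concatenate([c, r, [np.exp(th[-1])]])

            J = _fd_jacobian(phi, theta)
            cov_nat = J @ cov_theta @ J.T
            nat = phi(theta)
            sd = np.sqrt(np.abs(np.diag(cov_nat)))
            names = self._param_names()
            self.cv_pct_ = {
                nm: float(100.0 * s / v) for nm, s, v in zip(names, sd, nat)
            }
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular Hessian; CV% not computable", RuntimeWarning
            )
            self.cv_pct_ = None
            self.condition_number_ = None

    def _param_names(self) -> list[str]:
        greek = ["alpha", "beta", "gamma3"]
        latin = ["A", "B", "C"]
        n = self.n_terms
        return [latin[i] for i in range(n)] + [greek[i] for i in range(n)] + ["sigma"]

    def predict(self, X):
        return predict_conc(self.model_, np.asarray(X, dtype=float).ravel())

    def to_fit(self) -> MacroFit:
        """Bundle the fitted attributes into an immutable :class:`MacroFit`."""
        return MacroFit(
            model=self.model_,
            neg2ll=self.neg2ll_,
            aic=self.aic_,
            n_params=self.n_params_,
            cv_pct=self.cv_pct_,
            condition_number=self.condition_number_,
            converged=self.converged_,
            n_obs=self.n_obs_,
        )


def _fd_hessian(fn, x0, rel_step=1e-4):
    n = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fn(x0 + ei + ej)
            fpm = fn(x0 + ei - ej)
            fmp = fn(x0 - ei + ej)
            fmm = fn(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _fd_jacobian(fn, x0, rel_step=1e-6):
    f0 = np.asarray(fn(x0))
    n = x0.size
    J = np.empty((f0.size, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x0[i]))
        xp = x0.copy()
        xm = x0.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(fn(xp)) - np.asarray(fn(xm))) / (2.0 * h)
    return J


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _arm_points(
    data, include_imputed: bool = False
) -> tuple[np.ndarray, np.ndarray, float | None, str | None]:
    if isinstance(data, StudyArm):
        samples = [
            s
            for s in data.eligible_samples()
            if include_imputed or s.status == "observed"
        ]
        if not samples:
            raise ValueError("no samples eligible for fitting")
        t = np.array([s.time_h for s in samples])
        y = np.array([s.conc_ng_ml for s in samples])
        return t, y, data.dose_ug, data.analyte
    if isinstance(data, Profile):
        return data.times, data.concs, None, None
    t, y = data
    return np.asarray(t, float), np.asarray(y, float), None, None


def fit_macro(
    data,
    n_terms: int = 2,
    error_model: str = "additive",
    gamma: float = 1.0,
    init: MacroModel | None = None,
    n_starts: int = 10,
    seed: int | None = None,
    compute_diagnostics: bool = True,
    include_imputed: bool = False,
) -> MacroFit:
    """Fit an ``n_terms`` macroconstant model to an arm/profile/point set.

    By default only quantifiable (observed) samples enter the likelihood:
    a half-LLOQ imputed value lies orders of magnitude above the model
    prediction at its timepoint whenever the true curve has decayed well
    below the assay limit, and under a log-scale error model that single
    point can dominate the fit and bias the terminal rate low.  Imputed
    values remain in NCA, where they only close the AUC tail.
    ``include_imputed=True`` restores the strict M6 dataset.
    """
    t, y, dose_ug, analyte = _arm_points(data, include_imputed)
    est = MacroexponentialModel(
        n_terms=n_terms,
        error_model=error_model,
        gamma=gamma,
        init=init,
        n_starts=n_starts,
        random_state=seed,
        compute_diagnostics=compute_diagnostics,
    ).fit(t, y)
    if dose_ug is not None:
        from dataclasses import replace as _dc_replace

        est.model_ = _dc_replace(est.model_, dose_ug=dose_ug, analyte=analyte)
    return est.to_fit()


def select_model(
    data,
    n_terms_candidates=(1, 2, 3),
    error_model: str = "additive",
    gamma: float = 1.0,
    n_starts: int = 10,
    seed: int | None = None,
    cv_flag: float = 50.0,
    cond_flag: float = 1000.0,
    include_imputed: bool = False,
) -> list[tuple[MacroFit, list[str]]]:
    """Fit candidate term counts and rank converged fits by AIC.

    Returns (fit, flags) pairs sorted by AIC; ties break toward fewer
    parameters.  Flags mark imprecise fits (any CV% above ``cv_flag``) and
    ill-conditioned ones (condition number above ``cond_flag``).  Candidates
    that fail outright are skipped; if none converge a RuntimeError carries
    the per-candidate diagnostics.
    """
    results: list[tuple[MacroFit, list[str]]] = []
    failures: dict[int, str] = {}
    for n in n_terms_candidates:
        try:
            fit = fit_macro(
                data,
                n_terms=n,
                error_model=error_model,
                gamma=gamma,
                n_starts=n_starts,
                seed=seed,
                include_imputed=include_imputed,
            )
        except (NonIdentifiableError, RuntimeError, ValueError) as exc:
            failures[n] = str(exc)
            continue
        if not fit.converged:
            failures[n] = "did not converge"
            continue
        flags = []
        if fit.cv_pct is not None and any(
            np.isfinite(v) and v > cv_flag for v in fit.cv_pct.values()
        ):
            flags.append(f"imprecise (CV% > {cv_flag:g})")
        if fit.cv_pct is None:
            flags.append("CV% not computable")
        if fit.condition_number is not None and fit.condition_number > cond_flag:
            flags.append(f"ill-conditioned (> {cond_flag:g})")
        results.append((fit, flags))
    if not results:
        raise RuntimeError(f"no candidate converged: {failures}")
    results.sort(key=lambda fr: (fr[0].aic, fr[0].n_params))
    return results
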