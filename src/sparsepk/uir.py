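"""Unit impulse responses, closed-form convolution, and staircase deconvolution.

The unit impulse response (UIR) of a drug is the plasma concentration-time
curve produced by one nanogram of dose delivered instantaneously to the
systemic circulation.  For a linear disposition system fitted as a sum of
exponentials, the UIR is the fitted polyexponential with each coefficient
divided by the dose in ng:

    UIR(t) = sum_i c_i * exp(-lambda_i * t)      [ng/mL per ng]

Convolving an absorption input rate r(tau) [ng/h] with the UIR predicts the
plasma concentration; deconvolution inverts this to recover the input.  For a
piecewise-constant ("staircase") input both directions have exact closed
forms, so no numerical quadrature is needed: a constant rate R on [a, b]
contributes, per UIR term (c, lam) and for t >= a,

    R * (c/lam) * (exp(-lam*max(0, t-b)) - exp(-lam*(t-a)))

and zero before a.  Deconvolution solves for the non-negative staircase rates
by least squares against this exact forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "UIR",
    "AbsorptionProfile",
    "uir_from_fit",
    "uir_eval",
    "uir_auc",
    "convolve_staircase",
    "simulate_first_order_sq",
    "StaircaseDeconvolver",
    "deconvolve",
]


@dataclass(frozen=True)
class UIR:
    """Dose-normalized unit impulse response.

    ``terms`` are (coefficient ng/mL per ng of dose, rate h^-1) pairs with
    strictly decreasing rates.
    """

    terms: tuple[tuple[float, float], ...]
    dose_ug: float | None = None
    analyte: str | None = None

    def __post_init__(self) -> None:
        terms = tuple((float(c), float(r)) for c, r in self.terms)
        object.__setattr__(self, "terms", terms)
        if not terms:
            raise ValueError("UIR requires at least one exponential term")
        rates = [r for _, r in terms]
        if any(c <= 0 for c, _ in terms) or any(r <= 0 for r in rates):
            raise ValueError("UIR coefficients and rates must be > 0")
        if any(r1 <= r2 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("UIR rates must be strictly decreasing")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for c, _ in self.terms])

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.terms])


def uir_from_fit(fit, dose_ug: float) -> UIR:
    """Normalize a fitted polyexponential to its dose, yielding the UIR.

    ``fit`` may be anything with a ``terms`` attribute of (coefficient ng/mL,
    rate h^-1) pairs (a fitted macroconstant model), or such a sequence
    directly.  Coefficients are divided by the dose in ng (ug * 1000).
    """
    if dose_ug is None or dose_ug <= 0:
        raise ValueError("dose_ug must be > 0")
    terms = getattr(fit, "terms", fit)
    dose_ng = dose_ug * 1000.0
    analyte = getattr(fit, "analyte", None)
    return UIR(
        tuple((c / dose_ng, r) for c, r in terms),
        dose_ug=dose_ug,
        analyte=analyte,
    )


def uir_eval(uir: UIR, t) -> np.ndarray | float:
    """Evaluate UIR(t) = sum_i c_i exp(-lambda_i t) for t >= 0 (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(t_arr)
    for c, r in uir.terms:
        out = out + c * np.exp(-r * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def uir_auc(uir: UIR) -> float:
    """Analytic area under the UIR from 0 to infinity: sum_i c_i / lambda_i."""
    return float(sum(c / r for c, r in uir.terms))


def _check_staircase(knots, rates) -> tuple[np.ndarray, np.ndarray]:
    knots = np.asarray(knots, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if knots.ndim != 1 or knots.size < 2:
        raise ValueError("knots must be a 1-D array of at least 2 times")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    if rates.shape != (knots.size - 1,):
        raise ValueError("need one rate per inter-knot interval")
    if np.any(rates < 0):
        raise ValueError("staircase rates must be non-negative")
    return knots, rates


def convolve_staircase(uir: UIR, knots, rates, times) -> np.ndarray:
    """Exact concentrations from a staircase input rate convolved with a UIR.

    Parameters
    ----------
    knots : array of m+1 strictly increasing hours
    rates : array of m non-negative input rates (ng/h), one per interval
    times : hours at which to evaluate the predicted concentration (ng/mL)
    """
    knots, rates = _check_staircase(knots, rates)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    out = np.zeros(t.shape, dtype=float)
    for a, b, rate in zip(knots[:-1], knots[1:], rates):
        if rate == 0.0:
            continue
        active = t >= a
        ta = t[active]
        for c, lam in uir.terms:
            seg = (c / lam) * (
                np.exp(-lam * np.maximum(0.0, ta - b)) - np.exp(-lam * (ta - a))
            )
            out[active] += rate * seg
    return out


def simulate_first_order_sq(uir: UIR, F: float, dose_ug: float, ka: float, times):
    """Closed-form plasma concentrations for first-order subcutaneous input.

    C(t) = F * D_ng * ka * sum_i c_i/(ka - lambda_i) * (e^(-lambda_i t) - e^(-ka t)),
    with C(0) = 0.  ``ka`` must differ from every disposition rate (the
    coincident case degenerates to a t*exp form and is rejected; perturb ka).
    """
    if not (0 < F <= 1):
        raise ValueError("F must be in (0, 1]")
    if ka <= 0:
        raise ValueError("ka must be > 0")
    if dose_ug <= 0:
        raise ValueError("dose_ug must be > 0")
    for _, lam in uir.terms:
        if abs(ka - lam) <= 1e-9 * max(ka, lam):
            raise ValueError(
                f"ka = {ka} coincides with disposition rate {lam}; "
                "perturb ka to keep the closed form valid"
            )
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    dose_ng = dose_ug * 1000.0
    out = np.zeros(t.shape, dtype=float)
    for c, lam in uir.terms:
        out += c / (ka - lam) * (np.exp(-lam * t) - np.exp(-ka * t))
    return F * dose_ng * ka * out


@dataclass(frozen=True)
class AbsorptionProfile:
    """Staircase absorption input recovered by deconvolution.

    ``rates`` (ng/h) apply on the inter-knot intervals; ``cumulative_ng``,
    ``fraction_of_dose`` and ``residual_ng`` are evaluated at the knots.
    ``residual_ng`` is the apparent absorbable amount remaining:
    F*dose - cumulative when a bioavailability F is supplied (absorbed
    meaning "reached systemic circulation"), otherwise dose - cumulative.
    """

    knots: np.ndarray
    rates: np.ndarray
    dose_ug: float
    F: float | None = None
    cumulative_ng: np.ndarray = field(init=False)
    fraction_of_dose: np.ndarray = field(init=False)
    residual_ng: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        knots, rates = _check_staircase(self.knots, self.rates)
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "rates", rates)
        if self.dose_ug <= 0:
            raise ValueError("dose_ug must be > 0")
        cum = np.concatenate(([0.0], np.cumsum(rates * np.diff(knots))))
        dose_ng = self.dose_ug * 1000.0
        avail = dose_ng * (self.F if self.F is not None else 1.0)
        object.__setattr__(self, "cumulative_ng", cum)
        object.__setattr__(self, "fraction_of_dose", cum / dose_ng)
        object.__setattr__(self, "residual_ng", avail - cum)


class StaircaseDeconvolver(BaseEstimator):
    """Non-negative least-squares deconvolution against a known UIR.

    scikit-learn style estimator: ``fit(X, y)`` takes observation times
    (hours) and concentrations (ng/mL) and estimates a non-negative staircase
    input rate on the knot grid; ``predict(X)`` returns the model
    concentrations implied by the recovered input.

    Parameters
    ----------
    uir : UIR
        Dose-normalized disposition kernel (from the IV fit).
    dose_ug : float, optional
        Dose of the deconvolved arm; defaults to ``uir.dose_ug``.
    F : float, optional
        Bioavailability used for the residual-amount bookkeeping.
    knots : array, optional
        Input-rate knot grid; defaults to 0 followed by the observation times.
    scale : {"linear", "log"}
        Objective scale.  ``linear`` is plain NNLS; ``log`` polishes the NNLS
        solution by bounded least squares on log residuals.

    Attributes
    ----------
    knots_, rates_ : staircase solution
    absorption_profile_ : AbsorptionProfile
    condition_number_ : condition number of the convolution design matrix
    """

    def __init__(self, uir=None, dose_ug=None, F=None, knots=None, scale="linear"):
        self.uir = uir
        self.dose_ug = dose_ug
        self.F = F
        self.knots = knots
        self.scale = scale

    def _design(self, knots: np.ndarray, times: np.ndarray) -> np.ndarray:
        cols = []
        m = knots.size - 1
        for k in range(m):
            rate = np.zeros(m)
            rate[k] = 1.0
            cols.append(convolve_staircase(self.uir, knots, rate, times))
        return np.column_stack(cols)

    def fit(self, X, y):
        if self.uir is None:
            raise ValueError("uir must be provided")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        t = np.asarray(X, dtype=float).ravel()
        yobs = np.asarray(y, dtype=float).ravel()
        if t.size != yobs.size or t.size < 2:
            raise ValueError("need >= 2 observed (time, concentration) points")
        order = np.argsort(t)
        t, yobs = t[order], yobs[order]
        if np.any(yobs < 0):
            raise ValueError("observed concentrations must be non-negative")

        dose_ug = self.dose_ug if self.dose_ug is not None else self.uir.dose_ug
        if dose_ug is None:
            raise ValueError("dose_ug must be supplied (not carried by the UIR)")

        if self.knots is not None:
            knots = np.asarray(self.knots, dtype=float)
        else:
            knots = np.unique(np.concatenate(([0.0], t)))
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")

        M = self._design(knots, t)
        with np.errstate(divide="ignore"):
            self.condition_number_ = float(np.linalg.cond(M))
        if self.condition_number_ > 1e8:
            warnings.warn(
                f"ill-conditioned deconvolution system "
                f"(cond = {self.condition_number_:.3g})",
                RuntimeWarning,
            )
        if np.all(yobs == 0):
            rates = np.zeros(knots.size - 1)
        else:
            rates, _ = optimize.nnls(M, yobs)
            if self.scale == "log":
                pos = yobs > 0
                floor = 1e-12 * max(yobs.max(), 1.0)

                def resid(r):
                    pred = M[pos] @ r
                    return np.log(np.maximum(pred, floor)) - np.log(yobs[pos])

                sol = optimize.least_squares(
                    resid,
                    np.maximum(rates, floor),
                    bounds=(0.0, np.inf),
                    method="trf",
                )
                rates = sol.x

        self.knots_ = knots
        self.rates_ = rates
        self.n_obs_ = int(t.size)
        self.absorption_profile_ = AbsorptionProfile(
            knots, rates, dose_ug=float(dose_ug), F=self.F
        )
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        return convolve_staircase(self.uir, self.knots_, self.rates_, t)


def deconvolve(
    uir: UIR,
    times,
    concs,
    dose_ug: float | None = None,
    F: float | None = None,
    knots=None,
    scale: str = "linear",
) -> AbsorptionProfile:
    """Recover a staircase absorption profile from observed concentrations.

    Thin functional wrapper over :class:`StaircaseDeconvolver`.
    """
    dec = StaircaseDeconvolver(
        uir=uir, dose_ug=dose_ug, F=F, knots=knots, scale=scale
    )
    dec.fit(times, concs)
    return dec.absorption_profile_
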