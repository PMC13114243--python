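"""Synthetic sparse destructive-sampling PK studies.

Emulates the study design the downstream analyses assume: single IV or SQ
bolus arms in mice, ~3 animals per timepoint each contributing exactly one
plasma sample, biexponential disposition, power or log-additive residual
error, and assay censoring at the LLOQ.  The built-in truths are the reported
cabotegravir (CAB) and medroxyprogesterone acetate (MPA) mouse disposition
parameters, stored dose-normalized so the same truth drives IV simulation,
SQ convolution and UIR checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ErrorModel
from .study import Sample, StudyArm
from .uir import UIR, convolve_staircase, simulate_first_order_sq, uir_eval

__all__ = ["TruthSpec", "default_truth", "true_concentration", "simulate_study"]

#: Nominal IV sampling schedule (hours), 3 mice per timepoint.
IV_TIMES = (0.08, 1.0, 3.0, 6.0, 8.0, 18.0, 24.0, 30.0)
SQ_MPA_TIMES = IV_TIMES + (48.0, 72.0)
SQ_CAB_TIMES = IV_TIMES + (120.0, 168.0, 336.0, 504.0, 720.0)


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for one simulated study arm.

    ``disposition`` holds the dose-normalized UIR terms (coefficient in ng/mL
    per ng of dose, rate in 1/h), strictly decreasing in rate.  ``absorption``
    is ``"bolus"`` (instantaneous input), ``"first_order"`` (rate constant
    ``ka``), or ``"staircase"`` (``staircase_knots``/``staircase_rates``).
    ``bioavailability_F`` applies to SQ arms only.
    """

    analyte: str
    route: str
    disposition: tuple[tuple[float, float], ...]
    dose_ug: float
    lloq_ng_ml: float
    schedule: tuple[tuple[float, int], ...]
    error_model: ErrorModel
    bioavailability_F: float = 1.0
    absorption: str = "bolus"
    ka: float | None = None
    staircase_knots: tuple[float, ...] | None = None
    staircase_rates: tuple[float, ...] | None = None
    animal_variability_cv: float = 0.0  # optional lognormal animal multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        UIR(self.disposition)  # validates positivity and rate ordering
        if not (0 < self.bioavailability_F <= 1):
            raise ValueError("bioavailability_F must be in (0, 1]")
        if self.dose_ug <= 0 or self.lloq_ng_ml <= 0:
            raise ValueError("dose_ug and lloq_ng_ml must be > 0")
        for t, n in self.schedule:
            if t < 0 or n < 1:
                raise ValueError("schedule entries need time >= 0 and n >= 1")
        if self.absorption == "first_order" and (self.ka is None or self.ka <= 0):
            raise ValueError("first_order absorption requires ka > 0")
        if self.absorption == "staircase":
            if self.staircase_rates is None or self.staircase_knots is None:
                raise ValueError("staircase absorption requires knots and rates")
            if any(r < 0 for r in self.staircase_rates):
                raise ValueError("staircase rates must be non-negative")

    @property
    def uir(self) -> UIR:
        return UIR(self.disposition, dose_ug=self.dose_ug, analyte=self.analyte)

    def replace(self, **kwargs) -> "TruthSpec":
        return replace(self, **kwargs)


def _schedule(times: Sequence[float], n: int = 3) -> tuple[tuple[float, int], ...]:
    return tuple((float(t), n) for t in times)


# Reported mouse disposition truths, stored dose-normalized (per ng of dose).
# CAB IV: A = 16,621 ng/mL, alpha = 4.52 1/h, B = 30,206 ng/mL,
#         beta = 0.053 1/h at 66 ug;  LLOQ 25.0 ng/mL.
# MPA IV: A = 2506 ng/mL, alpha = 10.5 1/h, B = 439 ng/mL, beta = 0.65 1/h
#         at 65 ug;  LLOQ 0.500 ng/mL.
_TRUTHS = {
    "CAB": dict(
        disposition=((16621.0 / 66000.0, 4.52), (30206.0 / 66000.0, 0.053)),
        iv_dose_ug=66.0,
        sq_dose_ug=60.0,
        lloq=25.0,
        error=ErrorModel("power", sigma=0.15, gamma=1.0),
        F=0.61,
        ka=0.3,
        sq_times=SQ_CAB_TIMES,
    ),
    "MPA": dict(
        disposition=((2506.0 / 65000.0, 10.5), (439.0 / 65000.0, 0.65)),
        iv_dose_ug=65.0,
        sq_dose_ug=60.0,
        lloq=0.500,
        error=ErrorModel("log_additive", sigma=0.15),
        F=0.42,
        ka=1.0,
        sq_times=SQ_MPA_TIMES,
    ),
}


def default_truth(analyte: str, route: str = "IV", seed: int = 0) -> TruthSpec:
    """Built-in CAB or MPA truth at the nominal study design.

    IV arms are instantaneous boluses at the reported IV doses; SQ arms use
    first-order absorption with the reported bioavailability and extended
    sampling schedules.
    """
    try:
        p = _TRUTHS[analyte.upper()]
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}; expected CAB or MPA")
    if route == "IV":
        return TruthSpec(
            analyte=analyte.upper(),
            route="IV",
            disposition=p["disposition"],
            dose_ug=p["iv_dose_ug"],
            lloq_ng_ml=p["lloq"],
            schedule=_schedule(IV_TIMES),
            error_model=p["error"],
            seed=seed,
        )
    if route == "SQ":
        return TruthSpec(
            analyte=analyte.upper(),
            route="SQ",
            disposition=p["disposition"],
            dose_ug=p["sq_dose_ug"],
            lloq_ng_ml=p["lloq"],
            schedule=_schedule(p["sq_times"]),
            error_model=p["error"],
            bioavailability_F=p["F"],
            absorption="first_order",
            ka=p["ka"],
            seed=seed,
        )
    raise ValueError(f"unknown route {route!r}")


def true_concentration(truth: TruthSpec, times) -> np.ndarray:
    """Noise-free model concentrations (ng/mL) at the given times."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    uir = truth.uir
    dose_ng = truth.dose_ug * 1000.0
    if truth.route == "IV" or truth.absorption == "bolus":
        amount = dose_ng * (truth.bioavailability_F if truth.route == "SQ" else 1.0)
        return amount * np.asarray(uir_eval(uir, t))
    if truth.absorption == "first_order":
        return simulate_first_order_sq(
            uir, truth.bioavailability_F, truth.dose_ug, truth.ka, t
        )
    return convolve_staircase(uir, truth.staircase_knots, truth.staircase_rates, t)


def simulate_study(truth: TruthSpec, seed: int | None = None) -> StudyArm:
    """Simulate one sparse destructive-sampling study arm.

    Each scheduled (time, n) contributes n animals, each with a single
    concentration drawn from the truth's error model; draws below the LLOQ
    are emitted as censored (``status="blq"``) samples with no numeric value.
    Reproducible under a fixed seed (``seed`` overrides ``truth.seed``).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    samples: list[Sample] = []
    idx = 0
    for t, n in truth.schedule:
        f = float(true_concentration(truth, t)[0])
        fvec = np.full(n, f)
        if truth.animal_variability_cv > 0:
            sd = np.sqrt(np.log1p(truth.animal_variability_cv**2))
            fvec = fvec * np.exp(rng.normal(0.0, sd, size=n))
        if truth.error_model.sigma > 0 and f > 0:
            y = truth.error_model.sample(rng, fvec)
        else:
            y = fvec
        for yi in y:
            idx += 1
            animal = f"{truth.analyte}-{truth.route}-{idx:03d}"
            if yi < truth.lloq_ng_ml:
                samples.append(Sample(animal, t, None, "blq"))
            else:
                samples.append(Sample(animal, t, float(yi), "observed"))
    return StudyArm(
        analyte=truth.analyte,
        route=truth.route,
        dose_ug=truth.dose_ug,
        lloq_ng_ml=truth.lloq_ng_ml,
        samples=samples,
    )
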