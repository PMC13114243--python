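"""Model validation: nonparametric bootstrap, visual predictive check, GOF.

The bootstrap resamples animals with replacement - by default stratified
within each timepoint, which preserves the information content of a
destructive design where every timepoint carries a fixed number of single-
sample animals - refits the model from the reference estimates, and reports
per-parameter means and percentile 95% confidence intervals over the
successful refits.

The visual predictive check (VPC) simulates replicate studies at the observed
design from the fitted fixed effects and residual model, applies LLOQ
censoring and the same M6 rule as the observed-data pipeline (optional), and
summarizes the simulated concentrations as per-timepoint 5th/50th/95th
percentile bands for overlay against the observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ErrorModel
from .macrofit import MacroFit, MacroexponentialModel, predict_conc
from .preprocess import apply_blq_m6
from .study import Sample, StudyArm

__all__ = ["BootstrapResult", "VPCResult", "bootstrap_fit", "vpc", "gof_tables"]


@dataclass(frozen=True)
class BootstrapResult:
    n_resamples: int
    n_failed_fits: int
    means: dict[str, float]
    ci_lower: dict[str, float]  # 2.5th percentile
    ci_upper: dict[str, float]  # 97.5th percentile

    def __post_init__(self) -> None:
        if self.n_failed_fits >= self.n_resamples:
            raise ValueError("all bootstrap refits failed")
        for k in self.means:
            if self.ci_lower[k] > self.ci_upper[k]:
                raise ValueError(f"inverted CI for {k}")


@dataclass(frozen=True)
class VPCResult:
    times: np.ndarray
    p5: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    n_simulations: int

    def __post_init__(self) -> None:
        if not (np.all(self.p5 <= self.p50) and np.all(self.p50 <= self.p95)):
            raise ValueError("VPC bands must be ordered p5 <= p50 <= p95")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "p5": self.p5, "p50": self.p50, "p95": self.p95}
        )


def _param_vector(fit: MacroFit) -> dict[str, float]:
    names_c = ["A", "B", "C"]
    names_r = ["alpha", "beta", "gamma3"]
    out: dict[str, float] = {}
    for i, (c, r) in enumerate(fit.model.terms):
        out[names_c[i]] = c
        out[names_r[i]] = r
    if fit.model.error_model is not None:
        out["sigma"] = fit.model.error_model.sigma
    return out


def bootstrap_fit(
    arm: StudyArm,
    reference: MacroFit,
    n_resamples: int = 250,
    seed: int | None = None,
    stratified: bool = True,
    include_imputed: bool = False,
) -> BootstrapResult:
    """Nonparametric bootstrap of a converged reference fit.

    Each resample draws animals with replacement (within-timepoint strata by
    default) and refits starting from the reference estimates (single start).
    Failed refits are counted and excluded; an error is raised if more than
    half fail.
    """
    if not reference.converged:
        raise ValueError("bootstrap requires a converged reference fit")
    em = reference.model.error_model
    if em is None:
        raise ValueError("reference fit carries no error model")
    rng = np.random.default_rng(seed)
    elig = [
        s
        for s in arm.eligible_samples()
        if include_imputed or s.status == "observed"
    ]
    if not elig:
        raise ValueError("no eligible samples")
    times = np.array([s.time_h for s in elig])
    concs = np.array([s.conc_ng_ml for s in elig])

    strata: list[np.ndarray]
    if stratified:
        strata = [np.flatnonzero(times == u) for u in np.unique(times)]
    else:
        strata = [np.arange(times.size)]

    draws: list[dict[str, float]] = []
    n_failed = 0
    n_terms = reference.model.n_terms
    for _ in range(n_resamples):
        idx = np.concatenate([rng.choice(s, size=s.size, replace=True) for s in strata])
        try:
            est = MacroexponentialModel(
                n_terms=n_terms,
                error_model=em.kind,
                gamma=em.gamma,
                init=reference.model,
                n_starts=1,
                compute_diagnostics=False,
            ).fit(times[idx], concs[idx])
            if not est.converged_:
                raise RuntimeError("refit did not converge")
            draws.append(_param_vector(est.to_fit()))
        except Exception:
            n_failed += 1
    if n_failed > n_resamples / 2:
        raise RuntimeError(
            f"bootstrap failed: {n_failed}/{n_resamples} refits unsuccessful"
        )
    frame = pd.DataFrame(draws)
    return BootstrapResult(
        n_resamples=n_resamples,
        n_failed_fits=n_failed,
        means={k: float(frame[k].mean()) for k in frame},
        ci_lower={k: float(np.percentile(frame[k], 2.5)) for k in frame},
        ci_upper={k: float(np.percentile(frame[k], 97.5)) for k in frame},
    )


def vpc(
    fit: MacroFit,
    schedule,
    lloq_ng_ml: float | None = None,
    n_sim: int = 250,
    seed: int | None = None,
    censor: bool = True,
) -> VPCResult:
    """Visual predictive check bands at the observed design.

    ``schedule`` is a sequence of (time_h, n_animals).  When ``censor`` is
    true and an LLOQ is given, each simulated dataset is censored at the LLOQ
    and passed through the M6 imputation rule before pooling, mirroring the
    observed-data pipeline; with ``censor=False`` raw simulated values are
    summarized (BLQ omitted from nothing).
    """
    em = fit.model.error_model
    if em is None:
        raise ValueError("fit carries no error model; cannot simulate")
    schedule = [(float(t), int(n)) for t, n in schedule]
    if any(n < 1 for _, n in schedule):
        raise ValueError("every scheduled timepoint needs >= 1 animal")
    rng = np.random.default_rng(seed)
    times = np.array([t for t, _ in schedule])
    f = predict_conc(fit.model, times)

    pooled: dict[float, list[float]] = {t: [] for t, _ in schedule}
    for _ in range(n_sim):
        if censor and lloq_ng_ml is not None:
            samples = []
            k = 0
            for (t, n), ft in zip(schedule, f):
                y = em.sample(rng, np.full(n, ft)) if em.sigma > 0 else np.full(n, ft)
                for yi in y:
                    k += 1
                    if yi < lloq_ng_ml:
                        samples.append(Sample(f"sim-{k}", t, None, "blq"))
                    else:
                        samples.append(Sample(f"sim-{k}", t, float(yi), "observed"))
            arm = StudyArm("SIM", "IV", 1.0, lloq_ng_ml, samples)
            try:
                arm, _ = apply_blq_m6(arm)
            except ValueError:
                continue  # an all-BLQ replicate contributes nothing
            for s in arm.eligible_samples():
                pooled[s.time_h].append(s.conc_ng_ml)
        else:
            for (t, n), ft in zip(schedule, f):
                y = em.sample(rng, np.full(n, ft)) if em.sigma > 0 else np.full(n, ft)
                pooled[t].extend(float(v) for v in y)

    keep = [t for t, _ in schedule if pooled[t]]
    p5 = np.array([np.percentile(pooled[t], 5) for t in keep])
    p50 = np.array([np.percentile(pooled[t], 50) for t in keep])
    p95 = np.array([np.percentile(pooled[t], 95) for t in keep])
    return VPCResult(np.array(keep), p5, p50, p95, n_sim)


def _running_mean(x: np.ndarray, window: int = 5) -> np.ndarray:
    if x.size == 0:
        return x
    w = min(window, x.size)
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="valid")
    return out[: x.size]


def gof_tables(fit: MacroFit, times, observed) -> pd.DataFrame:
    """Observed-vs-predicted and standardized-residual table for GOF plots.

    Residuals are standardized on the fit's own scale - (y - f)/sigma for
    additive, (ln y - ln f)/sigma for log-additive, (y - f)/(sigma f^gamma)
    for power error - so a correctly specified model yields ~N(0, 1).  A
    loess-like running-mean smoother of the residuals (in time order) is
    included for plotting.
    """
    em = fit.model.error_model
    if em is None:
        raise ValueError("fit carries no error model")
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    f = predict_conc(fit.model, t)
    resid = em.scaled_residuals(y, f)
    order = np.argsort(t)
    smooth = np.empty_like(resid)
    smooth[order] = _running_mean(resid[order])
    return pd.DataFrame(
        {
            "time_h": t,
            "observed": y,
            "predicted": f,
            "std_residual": resid,
            "residual_smooth": smooth,
        }
    )
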