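"""BLQ handling (Beal M6) and Grubbs outlier screening for sparse PK arms.

Censored (BLQ) concentrations are handled by the M6 rule: at the first
timepoint in the terminal (post-peak) region that contains BLQ samples, each
BLQ sample is imputed at half the assay LLOQ; BLQ samples at all later
timepoints are dropped.  Because every animal contributes exactly one sample,
"first BLQ value" is interpreted at the timepoint level by default; a strict
chronological per-sample mode is provided for sensitivity analysis.

Potential outliers are screened per timepoint with the classic two-sided
single-outlier Grubbs test, by default on log concentrations in the post-peak
region (decaying concentrations are right-skewed on the raw scale).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .study import Sample, StudyArm, _tmax_of_means

__all__ = [
    "PreprocessReport",
    "apply_blq_m6",
    "grubbs_screen",
    "exclude_outliers",
    "preprocess_arm",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessReport:
    """Bookkeeping of imputation/exclusion decisions for one arm."""

    n_total: int
    n_imputed: int = 0
    n_dropped_blq: int = 0
    n_excluded_outliers: int = 0

    @property
    def pct_imputed(self) -> float:
        return 100.0 * self.n_imputed / self.n_total if self.n_total else 0.0

    def __post_init__(self) -> None:
        used = self.n_imputed + self.n_dropped_blq + self.n_excluded_outliers
        if used > self.n_total:
            raise ValueError("report counts exceed n_total")


def apply_blq_m6(
    arm: StudyArm, mode: str = "timepoint"
) -> tuple[StudyArm, PreprocessReport]:
    """Impute/drop censored samples by the M6 rule (half-LLOQ first, drop rest).

    ``mode="timepoint"`` (default): every BLQ sample at the earliest post-peak
    BLQ-containing timepoint is imputed at LLOQ/2; BLQ samples at later
    timepoints are dropped.  BLQ samples at or before the peak (possible on
    extravascular arms before absorption) are dropped, never imputed.
    ``mode="per_sample"``: only the single chronologically first BLQ sample is
    imputed.
    """
    if mode not in ("timepoint", "per_sample"):
        raise ValueError(f"unknown M6 mode {mode!r}")
    numeric = [s for s in arm.samples if s.conc_ng_ml is not None]
    blq = [s for s in arm.samples if s.status == "blq"]
    if not numeric:
        raise ValueError(
            f"arm {arm.analyte}/{arm.route}: every sample is BLQ; "
            "no quantifiable data"
        )
    if not blq:
        return arm, PreprocessReport(n_total=len(arm.samples))

    tmax = _tmax_of_means(numeric)
    post_peak = sorted({s.time_h for s in blq if s.time_h > tmax})
    half_lloq = arm.lloq_ng_ml / 2.0

    if mode == "timepoint":
        impute_times = set(post_peak[:1])
        impute_first_only = False
    else:
        impute_times = set(post_peak[:1])
        impute_first_only = True

    out: list[Sample] = []
    n_imputed = n_dropped = 0
    done_one = False
    for s in sorted(arm.samples, key=lambda s: (s.time_h, s.animal_id)):
        if s.status != "blq":
            out.append(s)
            continue
        if s.time_h in impute_times and not (impute_first_only and done_one):
            out.append(replace(s, conc_ng_ml=half_lloq, status="imputed"))
            n_imputed += 1
            done_one = True
        else:
            out.append(replace(s, status="dropped_blq"))
            n_dropped += 1
    report = PreprocessReport(
        n_total=len(arm.samples), n_imputed=n_imputed, n_dropped_blq=n_dropped
    )
    return arm.with_samples(out), report


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(
    values, alpha: float = 0.05
) -> tuple[float, float, int | None]:
    """Two-sided Grubbs test on one timepoint's pooled concentrations.

    Returns ``(G, G_crit, index_of_outlier_or_None)`` where
    G = max_i |x_i - mean| / sd (sample sd, ddof=1).  With zero variance the
    test is undefined; G is reported as 0 with no outlier and a warning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    gcrit = grubbs_critical_value(n, alpha)
    s = x.std(ddof=1)
    if s == 0:
        warnings.warn("zero variance at timepoint; Grubbs test skipped", RuntimeWarning)
        return 0.0, float(gcrit), None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / s)
    return g, float(gcrit), i if g > gcrit else None


def exclude_outliers(
    arm: StudyArm, alpha: float = 0.05, scale: str = "log"
) -> tuple[StudyArm, PreprocessReport]:
    """Grubbs-screen each timepoint with >= 3 eligible samples (one pass).

    At most one sample per timepoint is excluded (single-outlier test,
    iterative re-testing deliberately not applied to avoid masking).
    ``scale="log"`` (default) screens log concentrations in the post-peak
    region; ``scale="linear"`` screens raw values everywhere.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    elig = arm.eligible_samples()
    if not elig:
        raise ValueError("no eligible samples to screen")
    tmax = _tmax_of_means(elig)
    excluded_ids: set[str] = set()
    for t in sorted({s.time_h for s in elig}):
        group = [s for s in elig if s.time_h == t]
        if len(group) < 3:
            continue
        vals = np.array([s.conc_ng_ml for s in group])
        if scale == "log" and t > tmax and np.all(vals > 0):
            vals = np.log(vals)
        _, _, idx = grubbs_screen(vals, alpha)
        if idx is not None:
            excluded_ids.add(group[idx].animal_id)
            log.info(
                "excluding animal %s at t=%g h as Grubbs outlier",
                group[idx].animal_id,
                t,
            )
    out = [
        replace(s, status="excluded_outlier")
        if s.animal_id in excluded_ids and s.eligible
        else s
        for s in arm.samples
    ]
    report = PreprocessReport(
        n_total=len(arm.samples), n_excluded_outliers=len(excluded_ids)
    )
    return arm.with_samples(out), report


def preprocess_arm(
    arm: StudyArm,
    alpha: float = 0.05,
    m6_mode: str = "timepoint",
    outlier_scale: str = "log",
) -> tuple[StudyArm, PreprocessReport]:
    """M6 BLQ handling followed by Grubbs screening; combined report."""
    arm1, r1 = apply_blq_m6(arm, mode=m6_mode)
    arm2, r2 = exclude_outliers(arm1, alpha=alpha, scale=outlier_scale)
    report = PreprocessReport(
        n_total=len(arm.samples),
        n_imputed=r1.n_imputed,
        n_dropped_blq=r1.n_dropped_blq,
        n_excluded_outliers=r2.n_excluded_outliers,
    )
    return arm2, report
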