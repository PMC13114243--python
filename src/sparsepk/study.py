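"""Domain types and long-format CSV I/O for sparse destructive-sampling PK studies.

A destructive (sparse) design yields exactly one plasma sample per animal, so a
concentration-time "profile" is a composite across animals.  The types here
keep that structure explicit: a :class:`Sample` is one animal's single
observation with a censoring/exclusion status, a :class:`StudyArm` is all
samples for one analyte x route with its dose and assay LLOQ, and a
:class:`Profile` is the (possibly pooled) concentration-time curve the
downstream analyses consume.

Raw observed concentrations are never mutated by any operation in this
package; the sample ``status`` is the only mutable annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATUSES",
    "ELIGIBLE_STATUSES",
    "Sample",
    "StudyArm",
    "Profile",
    "read_study_csv",
    "write_study_csv",
    "pool_profile",
]

#: Recognised sample statuses.  ``blq`` samples carry no numeric concentration
#: until imputation; ``dropped_blq`` and ``excluded_outlier`` samples are
#: ineligible for all downstream calculations.
STATUSES = ("observed", "blq", "imputed", "dropped_blq", "excluded_outlier")

#: Statuses whose concentrations enter pooling, NCA and model fitting.
ELIGIBLE_STATUSES = ("observed", "imputed")

CSV_COLUMNS = [
    "analyte",
    "route",
    "dose_ug",
    "animal_id",
    "time_h",
    "conc",
    "blq_flag",
    "lloq",
    "status",
]


class SchemaError(ValueError):
    """A study CSV is missing required columns."""


class DesignViolationError(ValueError):
    """The one-sample-per-animal destructive design is violated."""


@dataclass(frozen=True)
class Sample:
    """One animal's single plasma observation.

    Parameters
    ----------
    animal_id : str
        Opaque identifier; unique within a :class:`StudyArm`.
    time_h : float
        Nominal hours post-dose (non-negative).
    conc_ng_ml : float or None
        Plasma concentration in ng/mL, or ``None`` for censored (``blq``)
        samples prior to imputation.
    status : str
        One of :data:`STATUSES`.
    """

    animal_id: str
    time_h: float
    conc_ng_ml: float | None = None
    status: str = "observed"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown sample status {self.status!r}")
        if self.time_h < 0:
            raise ValueError(
                f"negative time {self.time_h} for animal {self.animal_id!r}"
            )
        if self.status == "blq":
            if self.conc_ng_ml is not None:
                raise ValueError(
                    "blq samples carry no numeric concentration until imputation"
                )
        elif self.conc_ng_ml is None:
            if self.status != "dropped_blq":
                raise ValueError(
                    f"status {self.status!r} requires a numeric concentration"
                )
        elif self.conc_ng_ml < 0:
            raise ValueError(
                f"negative concentration {self.conc_ng_ml} for animal "
                f"{self.animal_id!r}"
            )

    @property
    def eligible(self) -> bool:
        """True when this sample's concentration enters downstream analyses."""
        return self.status in ELIGIBLE_STATUSES and self.conc_ng_ml is not None


@dataclass
class StudyArm:
    """All samples for one analyte x route with dose and assay LLOQ."""

    analyte: str
    route: str
    dose_ug: float
    lloq_ng_ml: float
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dose_ug <= 0:
            raise ValueError("dose_ug must be > 0")
        if self.lloq_ng_ml <= 0:
            raise ValueError("lloq_ng_ml must be > 0")
        if self.route not in ("IV", "SQ"):
            raise ValueError(f"route must be IV or SQ, got {self.route!r}")
        seen: dict[str, float] = {}
        for s in self.samples:
            if s.animal_id in seen and seen[s.animal_id] != s.time_h:
                raise DesignViolationError(
                    f"animal {s.animal_id!r} appears at two times "
                    f"({seen[s.animal_id]} h and {s.time_h} h); destructive "
                    "sampling allows exactly one sample per animal"
                )
            seen[s.animal_id] = s.time_h

    @property
    def dose_ng(self) -> float:
        return self.dose_ug * 1000.0

    def eligible_samples(self) -> list[Sample]:
        """Samples with status in :data:`ELIGIBLE_STATUSES`, sorted by time."""
        return sorted(
            (s for s in self.samples if s.eligible), key=lambda s: s.time_h
        )

    def with_samples(self, samples: Iterable[Sample]) -> "StudyArm":
        """Copy of this arm with a replaced sample list."""
        return replace(self, samples=list(samples))

    def timepoints(self) -> list[float]:
        """Sorted distinct nominal times across all samples."""
        return sorted({s.time_h for s in self.samples})


@dataclass(frozen=True)
class Profile:
    """An ordered concentration-time curve, raw or pooled by timepoint."""

    times: np.ndarray
    concs: np.ndarray
    pooling: str = "raw"  # raw | mean_by_time | median_by_time

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concs, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concs", concs)
        if times.shape != concs.shape or times.ndim != 1:
            raise ValueError("times and concs must be 1-D arrays of equal length")
        if np.any(concs < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be sorted")
        if self.pooling != "raw" and np.any(np.diff(times) <= 0):
            raise ValueError("pooled profiles require strictly increasing times")

    def __len__(self) -> int:
        return self.times.size

    def prepend(self, time_h: float, conc: float) -> "Profile":
        """New profile with a point inserted before the first one (e.g. C0 at t=0)."""
        if len(self) and time_h >= self.times[0]:
            raise ValueError("prepended time must precede the first point")
        return Profile(
            np.concatenate(([time_h], self.times)),
            np.concatenate(([conc], self.concs)),
            self.pooling,
        )


def _arm_to_frame(arm: StudyArm) -> pd.DataFrame:
    rows = []
    for s in arm.samples:
        rows.append(
            {
                "analyte": arm.analyte,
                "route": arm.route,
                "dose_ug": arm.dose_ug,
                "animal_id": s.animal_id,
                "time_h": s.time_h,
                "conc": "" if s.conc_ng_ml is None else s.conc_ng_ml,
                "blq_flag": int(s.status in ("blq", "imputed", "dropped_blq")),
                "lloq": arm.lloq_ng_ml,
                "status": s.status,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_study_csv(arms: Sequence[StudyArm], path) -> None:
    """Write arms to a lossless long-format CSV (one row = one animal)."""
    if not arms:
        raise ValueError("arms must be non-empty")
    frames = [_arm_to_frame(a) for a in arms]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_study_csv(path) -> list[StudyArm]:
    """Read a long-format study CSV into one :class:`StudyArm` per analyte x route.

    The ``status`` column is optional on input: rows with ``blq_flag`` truthy
    and no explicit status become ``blq``; numeric rows become ``observed``.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    required = set(CSV_COLUMNS) - {"status"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"study CSV missing columns: {sorted(missing)}")
    has_status = "status" in df.columns

    arms: list[StudyArm] = []
    for (analyte, route), grp in df.groupby(["analyte", "route"], sort=True):
        dose = grp["dose_ug"].unique()
        lloq = grp["lloq"].unique()
        if len(dose) != 1 or len(lloq) != 1:
            raise ValueError(
                f"arm {analyte}/{route}: dose_ug and lloq must be constant"
            )
        samples = []
        for idx, row in grp.iterrows():
            conc = row["conc"]
            conc = None if pd.isna(conc) or conc == "" else float(conc)
            if has_status and isinstance(row["status"], str) and row["status"]:
                status = row["status"]
            else:
                status = "blq" if row["blq_flag"] else "observed"
            if status in ("blq", "dropped_blq"):
                conc = None
            t = float(row["time_h"])
            if t < 0:
                raise ValueError(f"row {idx}: negative time {t}")
            if conc is not None and conc < 0:
                raise ValueError(f"row {idx}: negative concentration {conc}")
            samples.append(
                Sample(str(row["animal_id"]), t, conc, status)
            )
        samples.sort(key=lambda s: (s.time_h, s.animal_id))
        arms.append(
            StudyArm(str(analyte), str(route), float(dose[0]), float(lloq[0]), samples)
        )
    return arms


def _tmax_of_means(samples: Sequence[Sample]) -> float:
    times = np.array([s.time_h for s in samples])
    concs = np.array([s.conc_ng_ml for s in samples])
    uniq = np.unique(times)
    means = np.array([concs[times == t].mean() for t in uniq])
    return float(uniq[np.argmax(means)])


def pool_profile(arm: StudyArm, stat: str = "mean", scope: str = "all") -> Profile:
    """Pool an arm's eligible samples into a :class:`Profile`.

    Parameters
    ----------
    stat : {"mean", "median", "raw"}
        Per-timepoint summary.  ``raw`` returns every eligible point
        individually (duplicate times allowed).
    scope : {"all", "terminal_window"}
        ``all`` pools every distinct time.  ``terminal_window`` restricts to
        the post-peak terminal phase (times strictly after the Tmax of the
        per-time mean curve), matching the practice of averaging terminal
        concentrations on composite profiles.
    """
    elig = arm.eligible_samples()
    if not elig:
        raise ValueError(f"arm {arm.analyte}/{arm.route}: no eligible samples")
    if scope not in ("all", "terminal_window"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "terminal_window":
        tmax = _tmax_of_means(elig)
        elig = [s for s in elig if s.time_h > tmax]
        if not elig:
            raise ValueError("no eligible samples after Tmax")

    times = np.array([s.time_h for s in elig])
    concs = np.array([s.conc_ng_ml for s in elig])
    if stat == "raw":
        return Profile(times, concs, "raw")
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown pooling stat {stat!r}")
    fn = np.mean if stat == "mean" else np.median
    uniq = np.unique(times)
    pooled = np.array([fn(concs[times == t]) for t in uniq])
    return Profile(uniq, pooled, f"{stat}_by_time")
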