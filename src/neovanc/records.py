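"""Event-record domain types: subjects, doses, observations, covariates.

Times are hours from each subject's first recorded dose.  PMA is carried in
days (the maturation function operates on days); weights in kg; SCr in
umol/L; concentrations in mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "DoseEvent",
    "ConcObservation",
    "CovariateRecord",
    "SubjectRecord",
    "Cohort",
]


@dataclass(frozen=True)
class DoseEvent:
    time: float                    # h since subject reference (first dose)
    amount: float                  # mg
    infusion_duration: float       # h (amount/rate; constant-rate assumption)
    occasion: Optional[int] = None  # 1-based treatment-episode index

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if not self.amount > 0:
            raise ValueError("dose amount must be positive")
        if not self.infusion_duration > 0:
            raise ValueError("infusion duration must be positive")

    @property
    def rate(self) -> float:
        return self.amount / self.infusion_duration

    @property
    def end_time(self) -> float:
        return self.time + self.infusion_duration


@dataclass(frozen=True)
class ConcObservation:
    time: float          # h
    value: float         # mg/L; for BLQ records this is the LLOQ placeholder
    blq: bool = False
    lloq: float = 1.0    # mg/L

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("observation time must be non-negative")
        if self.value < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class CovariateRecord:
    time: float                    # h
    body_weight: Optional[float] = None   # kg
    serum_creatinine: Optional[float] = None  # umol/L
    pma: Optional[float] = None    # days
    imputed_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("covariate time must be non-negative")
        if self.body_weight is not None and not self.body_weight > 0:
            raise ValueError("body weight must be positive")
        if self.serum_creatinine is not None and not self.serum_creatinine > 0:
            raise ValueError("serum creatinine must be positive")


def _is_sorted(xs) -> bool:
    return all(xs[i] <= xs[i + 1] for i in range(len(xs) - 1))


@dataclass
class SubjectRecord:
    subject_id: str
    dose_events: list[DoseEvent] = field(default_factory=list)
    observations: list[ConcObservation] = field(default_factory=list)
    covariate_series: list[CovariateRecord] = field(default_factory=list)
    sex: Optional[str] = None
    birth_weight: Optional[float] = None     # kg
    gestational_age: Optional[float] = None  # days

    def __post_init__(self):
        for name in ("dose_events", "observations", "covariate_series"):
            if not _is_sorted([r.time for r in getattr(self, name)]):
                raise ValueError(f"{name} must be time-sorted for {self.subject_id}")
        if self.birth_weight is not None and not self.birth_weight > 0:
            raise ValueError("birth weight must be positive")
        if self.gestational_age is not None and not self.gestational_age > 0:
            raise ValueError("gestational age must be positive")

    # -- covariate lookup (after imputation these never return None) --------

    def pma_at(self, t: float) -> float:
        """PMA (days) at time ``t`` hours, extended linearly at 1 day/day."""
        recs = [r for r in self.covariate_series if r.pma is not None]
        if not recs:
            raise ValueError(f"subject {self.subject_id} has no PMA record")
        r = min(recs, key=lambda r: abs(r.time - t))
        return r.pma + (t - r.time) / 24.0

    def weight_at(self, t: float) -> float:
        """Body weight (kg): linear interpolation, linear end extrapolation."""
        recs = [(r.time, r.body_weight) for r in self.covariate_series
                if r.body_weight is not None]
        if not recs:
            raise ValueError(f"subject {self.subject_id} has no weight record")
        return _interp_linear(recs, t)

    def scr_at(self, t: float) -> float:
        """SCr (umol/L): nearest record in time; ties go to the earlier one."""
        recs = [(r.time, r.serum_creatinine) for r in self.covariate_series
                if r.serum_creatinine is not None]
        if not recs:
            raise ValueError(f"subject {self.subject_id} has no SCr record")
        return _nearest(recs, t)

    def pna_first_dose_days(self) -> Optional[float]:
        """Postnatal age (days) at the first dose, if GA is known."""
        if self.gestational_age is None or not self.dose_events:
            return None
        return self.pma_at(self.dose_events[0].time) - self.gestational_age

    @property
    def occasions(self) -> list[int]:
        occ = sorted({d.occasion for d in self.dose_events if d.occasion is not None})
        return occ


def _interp_linear(recs: list[tuple[float, float]], t: float) -> float:
    recs = sorted(recs)
    if len(recs) == 1:
        return recs[0][1]
    ts = [r[0] for r in recs]
    vs = [r[1] for r in recs]
    if t <= ts[0]:
        i, j = 0, 1
    elif t >= ts[-1]:
        i, j = len(ts) - 2, len(ts) - 1
    else:
        j = next(k for k in range(1, len(ts)) if ts[k] >= t)
        i = j - 1
    if ts[j] == ts[i]:
        return vs[i]
    w = (t - ts[i]) / (ts[j] - ts[i])
    return vs[i] + w * (vs[j] - vs[i])


def _nearest(recs: list[tuple[float, float]], t: float) -> float:
    # stable sort on (|dt|, time) makes equidistant ties resolve to the earlier
    best = min(recs, key=lambda r: (abs(r[0] - t), r[0]))
    return best[1]


@dataclass
class Cohort:
    subjects: list[SubjectRecord] = field(default_factory=list)
    provenance_log: list[dict] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def get(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def logged(self, rule: str, **info) -> "Cohort":
        """Return self with a provenance entry appended (mutating log)."""
        self.provenance_log.append({"rule": rule, **info})
        return self
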