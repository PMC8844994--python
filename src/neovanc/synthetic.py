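"""Synthetic NICU cohorts with the demographic structure of the study data.

The generator draws covariates from truncated normal / log-normal families
moment-matched to the published median and IQR of the development cohort
(gestational age, postnatal age at first dose, birth weight, serum
creatinine, dose per kg), assigns realistic PMA/PNA-banded dosing intervals,
and records the simulated true random effects so that every downstream module
can be exercised against known truth.  Observations are simulated from the
population model with combined residual error and censored at the 1 mg/L
LLOQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import estimation
from .params import PopulationParameters
from .records import Cohort, ConcObservation, CovariateRecord, DoseEvent, SubjectRecord

__all__ = [
    "MarginalSpec",
    "SamplingDesign",
    "DemographicsConfig",
    "generate_cohort",
    "simulate_observations",
    "default_interval_h",
]

_Q75 = 0.6744897501960817  # standard normal 75th percentile


@dataclass(frozen=True)
class MarginalSpec:
    """A median/IQR/range summary plus the family used to emulate it."""

    median: float
    iqr: float
    lo: float
    hi: float
    family: str = "lognormal"  # or "normal"

    def __post_init__(self):
        if not (self.lo <= self.median <= self.hi):
            raise ValueError("range must contain the median")
        if self.iqr <= 0 or self.hi <= self.lo:
            raise ValueError("iqr and range must be positive")

    def from_normal(self, z: np.ndarray) -> np.ndarray:
        """Transform standard-normal draws; moment-matched, clipped to range."""
        if self.family == "normal":
            sd = self.iqr / (2.0 * _Q75)
            x = self.median + sd * z
        elif self.family == "lognormal":
            s = math.asinh(self.iqr / (2.0 * self.median)) / _Q75
            x = self.median * np.exp(s * z)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return np.clip(x, self.lo, self.hi)


@dataclass(frozen=True)
class SamplingDesign:
    """TDM sampling policy: which doses get a trough and/or a peak sample.

    Defaults mirror the guideline recommendation of one trough plus one peak:
    a trough drawn shortly before the 4th dose and a peak at the end of its
    infusion.  Dose indices are 1-based and clipped to the available doses.
    """

    troughs_before: tuple = (4,)
    peaks_after: tuple = (4,)
    trough_offset_h: float = 0.1


@dataclass(frozen=True)
class DemographicsConfig:
    """Cohort-level generating distributions (units in field names).

    The marginal summaries default to the development cohort: GA 30.1±6.9
    (24.1–41.3) weeks; PNA at first dose 17±14 (7–114) days; birth weight
    1.32±0.89 (0.44–4.14) kg; SCr 42±34 umol/L; dose 14±3 (5–31) mg/kg.
    """

    ga_weeks: MarginalSpec = MarginalSpec(30.1, 6.9, 24.1, 41.3, "normal")
    pna_days: MarginalSpec = MarginalSpec(17.0, 14.0, 7.0, 114.0)
    birth_weight_kg: MarginalSpec = MarginalSpec(1.32, 0.89, 0.44, 4.14)
    scr_umol_l: MarginalSpec = MarginalSpec(42.0, 34.0, 8.0, 252.0)
    dose_mg_per_kg: MarginalSpec = MarginalSpec(14.0, 3.0, 5.0, 31.0, "normal")
    ga_weight_corr: float = 0.6        # Gaussian-copula correlation GA vs BW
    growth_rate_per_day: float = 0.015  # mean relative weight gain
    growth_rate_sd: float = 0.005
    scr_drift_per_day: float = -0.01   # relative SCr decline with PNA
    male_fraction: float = 0.541
    n_doses_range: tuple = (6, 10)     # inclusive
    infusion_duration_h: float = 1.0
    dose_round_mg: float = 0.1
    sampling: SamplingDesign = field(default_factory=SamplingDesign)
    seed: int = 0

    _MARGINALS = ("ga_weeks", "pna_days", "birth_weight_kg", "scr_umol_l",
                  "dose_mg_per_kg")

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicsConfig":
        """Build from plain-YAML structures (marginals as mappings)."""
        kw = dict(d)
        for name in cls._MARGINALS:
            if name in kw and isinstance(kw[name], dict):
                kw[name] = MarginalSpec(**kw[name])
        if "sampling" in kw and isinstance(kw["sampling"], dict):
            sd = dict(kw["sampling"])
            for key in ("troughs_before", "peaks_after"):
                if key in sd:
                    sd[key] = tuple(sd[key])
            kw["sampling"] = SamplingDesign(**sd)
        if "n_doses_range" in kw:
            kw["n_doses_range"] = tuple(kw["n_doses_range"])
        return cls(**kw)


def default_interval_h(pma_days: float, pna_days: float) -> float:
    """PMA/PNA-banded dosing interval, after standard neonatal references."""
    pma_wk = pma_days / 7.0
    if pma_wk < 30:
        return 24.0 if pna_days <= 14 else 18.0
    if pma_wk < 37:
        return 18.0 if pna_days <= 14 else 12.0
    if pma_wk < 45:
        return 12.0 if pna_days <= 14 else 8.0
    return 6.0


def generate_cohort(n: int, cfg: DemographicsConfig | None = None,
                    pop: PopulationParameters | None = None,
                    seed: int | None = None) -> tuple[Cohort, pd.DataFrame]:
    """Generate ``n`` subjects with doses and covariates (no observations).

    Returns the cohort and a truth table holding each subject's simulated
    random effects (``eta_bsv``, ``eta_bov_1``) and true first-dose CL; the
    recorded etas are exactly those later used for simulation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or DemographicsConfig()
    pop = pop or PopulationParameters()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    z_ga = rng.standard_normal(n)
    rho = cfg.ga_weight_corr
    z_bw = rho * z_ga + math.sqrt(max(1.0 - rho * rho, 0.0)) * rng.standard_normal(n)
    ga_wk = cfg.ga_weeks.from_normal(z_ga)
    bw = cfg.birth_weight_kg.from_normal(z_bw)
    pna = cfg.pna_days.from_normal(rng.standard_normal(n))
    scr0 = cfg.scr_umol_l.from_normal(rng.standard_normal(n))
    dose_per_kg = cfg.dose_mg_per_kg.from_normal(rng.standard_normal(n))
    growth = np.clip(rng.normal(cfg.growth_rate_per_day, cfg.growth_rate_sd, n),
                     0.0, 0.03)
    eta_bsv = rng.normal(0.0, math.sqrt(pop.omega2_bsv), n)
    eta_bov = rng.normal(0.0, math.sqrt(pop.omega2_bov), n)
    sexes = np.where(rng.random(n) < cfg.male_fraction, "M", "F")
    n_doses = rng.integers(cfg.n_doses_range[0], cfg.n_doses_range[1] + 1, n)

    subjects, truth_rows = [], []
    for i in range(n):
        sid = f"SYN{i + 1:04d}"
        ga_days = float(ga_wk[i]) * 7.0
        pma0 = ga_days + float(pna[i])
        wt0 = float(bw[i]) * (1.0 + growth[i] * float(pna[i]))
        interval = default_interval_h(pma0, float(pna[i]))
        dose_mg = round(dose_per_kg[i] * wt0 / cfg.dose_round_mg) * cfg.dose_round_mg
        doses, covs = [], []
        for j in range(int(n_doses[i])):
            t = j * interval
            day = t / 24.0
            wt_t = wt0 * (1.0 + growth[i] * day)
            scr_t = float(scr0[i]) * math.exp(cfg.scr_drift_per_day * day)
            doses.append(DoseEvent(t, float(dose_mg), cfg.infusion_duration_h,
                                   occasion=1))
            covs.append(CovariateRecord(t, body_weight=wt_t,
                                        serum_creatinine=max(scr_t, 1.0),
                                        pma=pma0 + day))
        subj = SubjectRecord(sid, dose_events=doses, covariate_series=covs,
                             sex=str(sexes[i]), birth_weight=float(bw[i]),
                             gestational_age=ga_days)
        subjects.append(subj)
        cl_true = (estimation.typical_params(wt0, pma0, max(float(scr0[i]), 1.0),
                                             pop).cl
                   * math.exp(float(eta_bsv[i]) + float(eta_bov[i])))
        truth_rows.append({
            "subject_id": sid, "eta_bsv": float(eta_bsv[i]),
            "eta_bov_1": float(eta_bov[i]), "cl_true_first_dose": cl_true,
            "ga_days": ga_days, "pna_days": float(pna[i]), "pma_days": pma0,
            "birth_weight_kg": float(bw[i]), "weight_kg": wt0,
            "scr_umol_l": float(scr0[i]), "dose_mg": float(dose_mg),
            "interval_h": interval, "n_doses": int(n_doses[i]),
        })
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    cohort = Cohort(subjects=subjects).logged("generate_cohort", n=n)
    return cohort, truth


def simulate_observations(cohort: Cohort, truth: pd.DataFrame,
                          pop: PopulationParameters | None = None,
                          design: SamplingDesign | None = None,
                          seed: int = 0, lloq: float = 1.0) -> Cohort:
    """Simulate TDM concentrations at the design's trough/peak times.

    Observations are the individual model prediction at the subject's true
    etas plus combined proportional-additive noise; simulated values below
    the LLOQ are flagged BLQ and stored at the LLOQ placeholder.
    """
    pop = pop or PopulationParameters()
    design = design or SamplingDesign()
    rng = np.random.default_rng(seed)
    out = []
    for s in cohort:
        row = truth.loc[s.subject_id]
        times = []
        nd = len(s.dose_events)
        for k in design.troughs_before:
            d = s.dose_events[min(k, nd) - 1]
            times.append(max(d.time - design.trough_offset_h, 0.0))
        for k in design.peaks_after:
            d = s.dose_events[min(k, nd) - 1]
            times.append(d.end_time)
        times = sorted(set(times))
        ebov = {o: float(row.get(f"eta_bov_{o}", 0.0))
                for o in {d.occasion or 1 for d in s.dose_events}}
        preds = estimation.predict_concentrations(
            s, pop, times, eta_bsv=float(row["eta_bsv"]),
            eta_bov_by_occasion=ebov)
        obs = []
        for t, f in zip(times, preds):
            sd = math.hypot(pop.sigma_prop * f, pop.sigma_add)
            y = f + sd * rng.standard_normal()
            if y < lloq:
                obs.append(ConcObservation(t, lloq, blq=True, lloq=lloq))
            else:
                obs.append(ConcObservation(t, float(y), blq=False, lloq=lloq))
        out.append(SubjectRecord(s.subject_id, dose_events=list(s.dose_events),
                                 observations=obs,
                                 covariate_series=list(s.covariate_series),
                                 sex=s.sex, birth_weight=s.birth_weight,
                                 gestational_age=s.gestational_age))
    return Cohort(subjects=out, provenance_log=list(cohort.provenance_log)
                  ).logged("simulate_observations", seed=seed)
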