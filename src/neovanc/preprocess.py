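"""EHR-derived cleaning rules: exclusions, imputation, LLOQ handling, occasions.

The rules mirror routine clinical-data preprocessing for neonatal vancomycin
TDM datasets:

* concentration records drawn more than 7 days after the start of the last
  infusion are discarded (stale samples, likely missing dose records);
* samples drawn *during* an infusion are discarded (open interval: a sample
  exactly at the end of an infusion is a peak and is retained);
* subjects whose first dose fell within 7 days of birth are excluded, because
  maternal creatinine confounds the renal-function covariate in that window;
* SCr below its assay LLOQ (15 umol/L) is replaced by half the LLOQ
  (7.5 umol/L); vancomycin concentrations below 1 mg/L are flagged BLQ and
  retained as censored records;
* SCr is imputed nearest-in-time (ties to the earlier value), body weight by
  linear interpolation/extrapolation;
* consecutive doses separated by at most a gap threshold (default 7 days)
  share a treatment occasion.

All operations are pure (they return new cohorts) and idempotent.
"""

from __future__ import annotations

import math
from dataclasses import replace

from .records import Cohort, ConcObservation, CovariateRecord, SubjectRecord

__all__ = [
    "apply_exclusions",
    "impute_covariates",
    "apply_lloq_rules",
    "compute_pma",
    "assign_occasions",
    "preprocess",
]

SCR_LLOQ = 15.0      # umol/L
SCR_BLQ_VALUE = 7.5  # umol/L, substituted for censored SCr
VCS_LLOQ = 1.0       # mg/L


def compute_pma(gestational_age: float, postnatal_time: float) -> float:
    """Postmenstrual age (days) = gestational age + postnatal time, both in days."""
    if gestational_age < 0 or postnatal_time < 0:
        raise ValueError("ages must be non-negative")
    return gestational_age + postnatal_time


def apply_exclusions(cohort: Cohort, pna_cutoff: float = 7.0,
                     post_infusion_cutoff: float = 7.0) -> tuple[Cohort, dict]:
    """Apply the three exclusion rules; returns (cohort, report).

    Rules, in order: (1) drop observations more than ``post_infusion_cutoff``
    days after the start of the subject's last infusion; (2) drop observations
    taken strictly during an infusion; (3) drop subjects whose first dose was
    given at a postnatal age below ``pna_cutoff`` days (only applied when
    gestational age is known).
    """
    removed_late = removed_during = removed_subjects = 0
    survivors = []
    for s in cohort:
        obs = list(s.observations)
        if s.dose_events:
            t_last = s.dose_events[-1].time
            keep = [o for o in obs if (o.time - t_last) <= post_infusion_cutoff * 24.0]
            removed_late += len(obs) - len(keep)
            obs = keep
            keep = [o for o in obs
                    if not any(d.time < o.time < d.end_time for d in s.dose_events)]
            removed_during += len(obs) - len(keep)
            obs = keep
        pna = s.pna_first_dose_days()
        if pna is not None and pna < pna_cutoff:
            removed_subjects += 1
            continue
        survivors.append(replace_observations(s, obs))
    report = {
        "observations_removed_late": removed_late,
        "observations_removed_during_infusion": removed_during,
        "subjects_removed_early_onset": removed_subjects,
    }
    out = Cohort(subjects=survivors,
                 provenance_log=list(cohort.provenance_log))
    return out.logged("apply_exclusions", **report), report


def replace_observations(s: SubjectRecord, obs) -> SubjectRecord:
    return SubjectRecord(s.subject_id, dose_events=list(s.dose_events),
                         observations=list(obs),
                         covariate_series=list(s.covariate_series),
                         sex=s.sex, birth_weight=s.birth_weight,
                         gestational_age=s.gestational_age)


def impute_covariates(cohort: Cohort) -> Cohort:
    """Fill SCr, weight and PMA at every event time.

    SCr: nearest available value in time (equidistant ties take the earlier
    value).  Weight: linear interpolation, linear extrapolation on the end
    segments, constant when a single value exists.  Observed values are kept
    bit-identical; filled values carry ``imputed_flags``.
    """
    out = []
    for s in cohort:
        wt_recs = [(r.time, r.body_weight) for r in s.covariate_series
                   if r.body_weight is not None]
        scr_recs = [(r.time, r.serum_creatinine) for r in s.covariate_series
                    if r.serum_creatinine is not None]
        if not wt_recs or not scr_recs:
            raise ValueError(
                f"subject {s.subject_id} needs at least one weight and one SCr value")
        event_times = sorted({e.time for e in s.dose_events}
                             | {o.time for o in s.observations}
                             | {c.time for c in s.covariate_series})
        by_time = {c.time: c for c in s.covariate_series}
        series = []
        for t in event_times:
            base = by_time.get(t, CovariateRecord(t))
            flags = dict(base.imputed_flags)
            wt = base.body_weight
            if wt is None:
                wt = s.weight_at(t)
                flags["body_weight"] = True
            scr = base.serum_creatinine
            if scr is None:
                scr = s.scr_at(t)
                flags["serum_creatinine"] = True
            pma = base.pma
            if pma is None:
                pma = s.pma_at(t)
                flags["pma"] = True
            series.append(CovariateRecord(t, body_weight=wt, serum_creatinine=scr,
                                          pma=pma, imputed_flags=flags))
        out.append(SubjectRecord(s.subject_id, dose_events=list(s.dose_events),
                                 observations=list(s.observations),
                                 covariate_series=series, sex=s.sex,
                                 birth_weight=s.birth_weight,
                                 gestational_age=s.gestational_age))
    return Cohort(subjects=out, provenance_log=list(cohort.provenance_log)
                  ).logged("impute_covariates")


def apply_lloq_rules(cohort: Cohort, scr_lloq: float = SCR_LLOQ,
                     vcs_lloq: float = VCS_LLOQ) -> Cohort:
    """Censoring rules: SCr < LLOQ -> LLOQ/2; concentrations < LLOQ -> BLQ flag.

    BLQ concentration records are retained with the LLOQ as a placeholder
    value; they enter the likelihood only through the censored (M3) term.
    """
    out = []
    for s in cohort:
        series = []
        for c in s.covariate_series:
            if c.serum_creatinine is not None and c.serum_creatinine < scr_lloq:
                flags = dict(c.imputed_flags)
                flags["scr_blq"] = True
                c = replace(c, serum_creatinine=scr_lloq / 2.0, imputed_flags=flags)
            series.append(c)
        obs = []
        for o in s.observations:
            if not o.blq and o.value < vcs_lloq:
                o = replace(o, blq=True, value=vcs_lloq, lloq=vcs_lloq)
            elif o.blq and o.value != o.lloq:
                o = replace(o, value=o.lloq)
            obs.append(o)
        out.append(SubjectRecord(s.subject_id, dose_events=list(s.dose_events),
                                 observations=obs, covariate_series=series,
                                 sex=s.sex, birth_weight=s.birth_weight,
                                 gestational_age=s.gestational_age))
    return Cohort(subjects=out, provenance_log=list(cohort.provenance_log)
                  ).logged("apply_lloq_rules", scr_lloq=scr_lloq, vcs_lloq=vcs_lloq)


def assign_occasions(cohort: Cohort, gap_threshold: float = 7.0) -> Cohort:
    """Group doses into treatment occasions by inter-dose gap.

    Consecutive doses separated by at most ``gap_threshold`` days share an
    occasion (the threshold is inclusive); a larger gap starts a new occasion.
    Occasions are numbered from 1.  Observations inherit the occasion of the
    most recent dose.
    """
    out = []
    for s in cohort:
        doses = []
        occ = 0
        prev_t = None
        for d in s.dose_events:
            if prev_t is None or (d.time - prev_t) > gap_threshold * 24.0:
                occ += 1
            prev_t = d.time
            doses.append(replace(d, occasion=occ))
        out.append(SubjectRecord(s.subject_id, dose_events=doses,
                                 observations=list(s.observations),
                                 covariate_series=list(s.covariate_series),
                                 sex=s.sex, birth_weight=s.birth_weight,
                                 gestational_age=s.gestational_age))
    return Cohort(subjects=out, provenance_log=list(cohort.provenance_log)
                  ).logged("assign_occasions", gap_threshold=gap_threshold)


def occasion_of_observation(s: SubjectRecord, obs_time: float) -> int:
    """Occasion of the most recent dose at or before ``obs_time`` (1 if none)."""
    occ = 1
    for d in s.dose_events:
        if d.time <= obs_time and d.occasion is not None:
            occ = d.occasion
    return occ


def preprocess(cohort: Cohort, pna_cutoff: float = 7.0,
               post_infusion_cutoff: float = 7.0,
               gap_threshold: float = 7.0) -> tuple[Cohort, dict]:
    """Full cleaning pipeline: exclusions -> LLOQ rules -> imputation -> occasions."""
    cohort, report = apply_exclusions(cohort, pna_cutoff, post_infusion_cutoff)
    cohort = apply_lloq_rules(cohort)
    cohort = impute_covariates(cohort)
    cohort = assign_occasions(cohort, gap_threshold)
    return cohort, report
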