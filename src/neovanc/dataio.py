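"""Reading and writing NONMEM-style event-record CSV datasets.

Column dictionary (UTF-8 CSV, header mandatory):

======  =====================================================================
ID          subject identifier (string)
TIME_H      event time, hours from the subject's first dose (non-negative)
EVID        event code: 1 = dose, 0 = concentration observation
AMT_MG      dose amount, mg (dose rows)
RATE_MG_H   infusion rate, mg/h (dose rows; infusion_duration = AMT/RATE)
DV_MG_L     observed serum vancomycin concentration, mg/L (observation rows)
BLQ         1 if the observation is below the limit of quantification
LLOQ        lower limit of quantification, mg/L (default 1)
WT_KG       body weight, kg (carried on every row; may be blank)
SCR_UMOL_L  serum creatinine, umol/L (may be blank)
PMA_DAYS    postmenstrual age, days
OCC         treatment-episode (occasion) index (optional)
SEX         subject sex (optional, constant per subject)
BWT_KG      birth weight, kg (optional, constant per subject)
GA_DAYS     gestational age, days (optional, constant per subject; needed for
            the postnatal-age exclusion rule)
======  =====================================================================
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .records import (Cohort, ConcObservation, CovariateRecord, DoseEvent,
                      SubjectRecord)

__all__ = ["parse_dataset", "write_dataset", "COLUMNS"]

COLUMNS = ["ID", "TIME_H", "EVID", "AMT_MG", "RATE_MG_H", "DV_MG_L", "BLQ",
           "LLOQ", "WT_KG", "SCR_UMOL_L", "PMA_DAYS", "OCC", "SEX",
           "BWT_KG", "GA_DAYS"]

_MANDATORY = ["ID", "TIME_H", "EVID", "AMT_MG", "RATE_MG_H", "DV_MG_L", "BLQ",
              "WT_KG", "SCR_UMOL_L", "PMA_DAYS"]

DEFAULT_LLOQ = 1.0
DEFAULT_INFUSION_DURATION = 1.0  # h, used when RATE is absent on a dose row


class FormatError(ValueError):
    """Raised when a dataset does not conform to the column dictionary."""


def _opt(row, col):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def parse_dataset(table) -> Cohort:
    """Build a :class:`Cohort` from an event-record table.

    ``table`` is a pandas DataFrame or a path to a CSV file.  Dose rows
    (EVID=1) become :class:`DoseEvent` with ``infusion_duration =
    AMT_MG/RATE_MG_H``; observation rows (EVID=0) become
    :class:`ConcObservation`; covariates on every row are collected into the
    subject's covariate series.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    missing = [c for c in _MANDATORY if c not in table.columns]
    if missing:
        raise FormatError(f"missing mandatory columns: {missing}")
    if (pd.to_numeric(table["TIME_H"], errors="coerce") < 0).any():
        raise ValueError("negative event times are not allowed")

    subjects = []
    for sid, grp in table.groupby("ID", sort=False):
        grp = grp.sort_values("TIME_H", kind="stable")
        doses, obs, covs = [], [], []
        sex = bwt = ga = None
        for _, row in grp.iterrows():
            t = float(row["TIME_H"])
            evid = int(row["EVID"])
            if evid == 1:
                amt = float(row["AMT_MG"])
                rate = _opt(row, "RATE_MG_H")
                dur = amt / float(rate) if rate else DEFAULT_INFUSION_DURATION
                occ = _opt(row, "OCC")
                doses.append(DoseEvent(t, amt, dur,
                                       occasion=int(occ) if occ is not None else None))
            elif evid == 0:
                lloq = _opt(row, "LLOQ")
                obs.append(ConcObservation(
                    t, float(row["DV_MG_L"]),
                    blq=bool(int(_opt(row, "BLQ") or 0)),
                    lloq=float(lloq) if lloq is not None else DEFAULT_LLOQ))
            else:
                raise FormatError(f"unsupported EVID {evid} for subject {sid}")
            wt = _opt(row, "WT_KG")
            scr = _opt(row, "SCR_UMOL_L")
            pma = _opt(row, "PMA_DAYS")
            covs.append(CovariateRecord(
                t,
                body_weight=float(wt) if wt is not None else None,
                serum_creatinine=float(scr) if scr is not None else None,
                pma=float(pma) if pma is not None else None))
            sex = _opt(row, "SEX") or sex
            bwt = _opt(row, "BWT_KG") or bwt
            ga = _opt(row, "GA_DAYS") or ga
        subjects.append(SubjectRecord(
            str(sid), dose_events=doses, observations=obs, covariate_series=covs,
            sex=str(sex) if sex is not None else None,
            birth_weight=float(bwt) if bwt is not None else None,
            gestational_age=float(ga) if ga is not None else None))
    return Cohort(subjects=subjects).logged("parse_dataset", n_subjects=len(subjects))


def write_dataset(cohort: Cohort, path=None) -> pd.DataFrame:
    """Serialize a cohort back to the event-record layout (inverse of parse)."""
    rows = []
    for s in cohort:
        events = ([("dose", d) for d in s.dose_events]
                  + [("obs", o) for o in s.observations])
        events.sort(key=lambda e: (e[1].time, 0 if e[0] == "dose" else 1))
        for kind, ev in events:
            row = {c: None for c in COLUMNS}
            row.update(ID=s.subject_id, TIME_H=ev.time, SEX=s.sex,
                       BWT_KG=s.birth_weight, GA_DAYS=s.gestational_age)
            if kind == "dose":
                row.update(EVID=1, AMT_MG=ev.amount, RATE_MG_H=ev.rate,
                           OCC=ev.occasion)
            else:
                row.update(EVID=0, DV_MG_L=ev.value, BLQ=int(ev.blq),
                           LLOQ=ev.lloq)
            cov = min(s.covariate_series, key=lambda r: abs(r.time - ev.time),
                      default=None)
            if cov is not None and abs(cov.time - ev.time) < 1e-9:
                row.update(WT_KG=cov.body_weight, SCR_UMOL_L=cov.serum_creatinine,
                           PMA_DAYS=cov.pma)
            rows.append(row)
    df = pd.DataFrame(rows, columns=COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df
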