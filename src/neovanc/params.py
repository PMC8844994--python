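"""Parameter containers for the neonatal vancomycin population PK model.

The population model is a two-compartment infusion model with first-order
elimination.  Clearance carries the covariate model

    CL = TVCL * (WT/WT_ref)**0.75 * MAT(PMA) * (SCr_ref/SCr)**theta_scr

with ``MAT`` a Hill (sigmoid Emax) maturation function of postmenstrual age,
and allometric weight scaling on all four disposition parameters (exponent
0.75 on clearances, 1 on volumes).  Random effects are log-normal on CL only:
a between-subject effect (BSV) and a between-occasion effect (BOV).  Residual
error is combined proportional + additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = [
    "PopulationParameters",
    "PKParameters",
    "Regimen",
    "cv_to_omega2",
    "omega2_to_cv",
]


def cv_to_omega2(cv: float) -> float:
    """Log-normal variance ``omega2`` from a coefficient of variation.

    Inverts CV = sqrt(exp(omega2) - 1), the standard log-normal relation.
    ``cv`` is a fraction (0.123 for 12.3%).
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    return math.log1p(cv * cv)


def omega2_to_cv(omega2: float) -> float:
    """Coefficient of variation (fraction) from a log-normal variance."""
    if omega2 < 0:
        raise ValueError("omega2 must be non-negative")
    return math.sqrt(math.expm1(omega2))


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters of the two-compartment model."""

    cl: float  # clearance, L/h
    vc: float  # central volume, L
    q: float   # intercompartmental clearance, L/h
    vp: float  # peripheral volume, L

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"PK parameter {f.name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class Regimen:
    """A repeated constant-rate infusion schedule."""

    dose: float               # mg per administration
    interval: float           # h between administrations
    infusion_duration: float  # h
    n_doses: int | None = None  # None means evaluate at steady state

    def __post_init__(self):
        if not self.dose > 0:
            raise ValueError("dose must be positive")
        if not (0 < self.infusion_duration <= self.interval):
            raise ValueError("need 0 < infusion_duration <= interval")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def daily_dose(self) -> float:
        """Total dose per 24 h, mg."""
        return self.dose * 24.0 / self.interval


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, random-effect variances and residual error terms.

    Defaults are the final-model estimates for the NICU cohort the model was
    developed on.  ``omega2_*`` are variances of the log-normal random effects
    on CL; they correspond to CVs of 12.3% (BSV) and 13.3% (BOV).
    """

    tvcl: float = 0.140          # typical CL, L/h at reference covariates
    tvvc: float = 0.769          # typical central volume, L
    tvq: float = 0.147           # typical intercompartmental clearance, L/h
    tvvp: float = 0.285          # typical peripheral volume, L
    hill: float = 7.02           # Hill coefficient of the maturation function
    mat50: float = 197.0         # PMA (days) at 50% maturation
    scr_exponent: float = 0.541  # exponent of the (scr_ref/scr) renal term
    wt_exp_cl_q: float = 0.75    # allometric exponent on CL and Q (fixed)
    wt_exp_v: float = 1.0        # allometric exponent on Vc and Vp (fixed)
    omega2_bsv: float = field(default_factory=lambda: cv_to_omega2(0.123))
    omega2_bov: float = field(default_factory=lambda: cv_to_omega2(0.133))
    sigma_prop: float = 0.168    # proportional residual error (fraction)
    sigma_add: float = 1.76      # additive residual error, mg/L
    wt_ref: float = 1.0          # reference body weight, kg
    scr_ref: float = 42.0        # reference serum creatinine, umol/L

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be non-negative and finite")
        for name in ("tvcl", "tvvc", "tvq", "tvvp", "hill", "mat50", "wt_ref", "scr_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")

    @property
    def cv_bsv(self) -> float:
        """Between-subject CV of CL as a fraction."""
        return omega2_to_cv(self.omega2_bsv)

    @property
    def cv_bov(self) -> float:
        """Between-occasion CV of CL as a fraction."""
        return omega2_to_cv(self.omega2_bov)

    def replace(self, **kw) -> "PopulationParameters":
        return replace(self, **kw)

    # -- flat-file serialization (keys mirror the published symbol names) ----

    _YAML_KEYS = {
        "TVCL": "tvcl",
        "TVVc": "tvvc",
        "TVQ": "tvq",
        "TVVp": "tvvp",
        "theta_PMA_CL_Hill": "hill",
        "theta_PMA_CL_Mat50": "mat50",
        "theta_SCr_CL": "scr_exponent",
        "theta_WT_CL_Q": "wt_exp_cl_q",
        "theta_WT_V": "wt_exp_v",
        "omega2_BSV_CL": "omega2_bsv",
        "omega2_BOV_CL": "omega2_bov",
        "sigma_prop": "sigma_prop",
        "sigma_add": "sigma_add",
        "WT_ref": "wt_ref",
        "SCr_ref": "scr_ref",
    }

    def to_dict(self) -> dict:
        return {k: float(getattr(self, attr)) for k, attr in self._YAML_KEYS.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        kw = {}
        for k, v in d.items():
            if k in ("CVCL", "CVCL_BOV"):  # CVs in percent, as printed
                attr = "omega2_bsv" if k == "CVCL" else "omega2_bov"
                kw[attr] = cv_to_omega2(float(v) / 100.0)
            elif k in cls._YAML_KEYS:
                kw[cls._YAML_KEYS[k]] = float(v)
            else:
                raise KeyError(f"unknown model parameter key: {k}")
        return cls(**kw)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PopulationParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
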