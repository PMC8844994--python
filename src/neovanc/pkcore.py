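"""Structural two-compartment infusion model and covariate model.

Concentrations are computed from the analytic (biexponential) solution of the
linear mass-balance system, propagated piecewise across infusion start/stop
breakpoints.  For the 2x2 system matrix ``M`` the propagator ``exp(M*dt)`` and
the forcing integral ``int_0^dt exp(M*s) ds`` are evaluated in closed form via
the spectral decomposition, with series limits at degenerate or zero
eigenvalues, so the zero-elimination (mass-balance tests) and one-compartment
(Q -> 0) reductions fall out of the same code path.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .params import PKParameters, PopulationParameters, Regimen

__all__ = [
    "maturation",
    "alternative_maturation",
    "typical_params",
    "individual_params",
    "concentration",
    "amounts",
    "steady_state_profile",
    "auc24_ss",
    "residual_sd",
]

_DEGENERATE_TOL = 1e-10


# ---------------------------------------------------------------------------
# covariate model

def maturation(pma: float, hill: float, mat50: float) -> float:
    """Hill maturation function of postmenstrual age (days).

    Returns ``pma**hill / (pma**hill + mat50**hill)``, the fraction of adult
    (fully mature) clearance attained; equals 0.5 exactly at ``pma == mat50``
    and increases strictly with PMA.
    """
    if not pma > 0:
        raise ValueError("pma must be positive")
    if not (hill > 0 and mat50 > 0):
        raise ValueError("hill and mat50 must be positive")
    # work on the log scale to avoid overflow for large pma**hill
    r = hill * (math.log(pma) - math.log(mat50))
    return 1.0 / (1.0 + math.exp(-r))


def alternative_maturation(pma: float, kind: str, params: dict) -> float:
    """Non-sigmoidal maturation functions used only for model comparison.

    kind:
      - ``linear``: ``intercept + slope*pma``, clipped to (0, 1]
      - ``exponential``: ``scale*exp(rate*pma)``, clipped to (0, 1]
      - ``first_order``: ``1 - exp(-k*pma)`` (asymptotic exponential)
    """
    if not pma > 0:
        raise ValueError("pma must be positive")
    tiny = 1e-12
    if kind == "linear":
        v = params.get("intercept", 0.0) + params["slope"] * pma
    elif kind == "exponential":
        v = params.get("scale", 1.0) * math.exp(params["rate"] * pma)
    elif kind == "first_order":
        k = params["k"]
        if k < 0:
            raise ValueError("first_order rate k must be non-negative")
        v = -math.expm1(-k * pma)
    else:
        raise ValueError(f"unknown maturation kind: {kind!r}")
    return min(max(v, tiny), 1.0)


def typical_params(wt: float, pma: float, scr: float,
                   pop: PopulationParameters) -> PKParameters:
    """Typical-value PK parameters for a subject's covariates.

    CL carries allometric weight scaling (exponent 0.75), the Hill maturation
    multiplier and the power renal term in SCr; Q scales with weight**0.75;
    volumes scale linearly with weight.
    """
    if not (wt > 0 and pma > 0 and scr > 0):
        raise ValueError("covariates wt, pma, scr must be positive")
    wr = wt / pop.wt_ref
    f_size_cl = wr ** pop.wt_exp_cl_q
    f_mat = maturation(pma, pop.hill, pop.mat50)
    f_renal = (pop.scr_ref / scr) ** pop.scr_exponent
    return PKParameters(
        cl=pop.tvcl * f_size_cl * f_mat * f_renal,
        vc=pop.tvvc * wr ** pop.wt_exp_v,
        q=pop.tvq * f_size_cl,
        vp=pop.tvvp * wr ** pop.wt_exp_v,
    )


def individual_params(typical: PKParameters, eta_bsv: float = 0.0,
                      eta_bov: float = 0.0) -> PKParameters:
    """Apply log-normal random effects to CL (the only random parameter)."""
    if not (math.isfinite(eta_bsv) and math.isfinite(eta_bov)):
        raise ValueError("etas must be finite")
    return PKParameters(
        cl=typical.cl * math.exp(eta_bsv + eta_bov),
        vc=typical.vc, q=typical.q, vp=typical.vp,
    )


# ---------------------------------------------------------------------------
# analytic propagation of the two-compartment system
#
# state a = (amount central, amount peripheral);  da/dt = M a + u,
# M = [[-(CL+Q)/Vc, Q/Vp], [Q/Vc, -Q/Vp]],  u = (infusion rate, 0).

def _propagate(a1: float, a2: float, cl: float, vc: float, q: float, vp: float,
               rate: float, dt: float) -> tuple[float, float]:
    """Advance the amounts vector by ``dt`` hours under constant input."""
    if dt == 0.0:
        return a1, a2
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    m11 = -(k10 + k12)
    m12 = k21
    m21 = k12
    m22 = -k21
    tr = m11 + m22
    det = m11 * m22 - m12 * m21
    disc = tr * tr - 4.0 * det
    disc = disc if disc > 0.0 else 0.0
    rt = math.sqrt(disc)
    s1 = 0.5 * (tr + rt)
    s2 = 0.5 * (tr - rt)
    scale = max(1.0, abs(s1), abs(s2))
    if rt > _DEGENERATE_TOL * scale:
        # distinct eigenvalues: h(M) = (h(s1)(M-s2 I) - h(s2)(M-s1 I))/(s1-s2)
        f1 = math.exp(s1 * dt)
        f2 = math.exp(s2 * dt)
        g1 = math.expm1(s1 * dt) / s1 if s1 != 0.0 else dt
        g2 = math.expm1(s2 * dt) / s2 if s2 != 0.0 else dt
        d = s1 - s2
        ca = (f1 - f2) / d                  # coefficient of M
        cb = (f1 * (-s2) + f2 * s1) / d     # coefficient of I
        e11 = ca * m11 + cb
        e12 = ca * m12
        e21 = ca * m21
        e22 = ca * m22 + cb
        ga = (g1 - g2) / d
        gb = (g1 * (-s2) + g2 * s1) / d
        G11 = ga * m11 + gb
        G21 = ga * m21
    else:
        # repeated (or nearly repeated) eigenvalue s: exp(M dt)=e^{s dt}(I+dt(M-sI))
        s = 0.5 * tr
        f = math.exp(s * dt)
        e11 = f * (1.0 + dt * (m11 - s))
        e12 = f * dt * m12
        e21 = f * dt * m21
        e22 = f * (1.0 + dt * (m22 - s))
        if abs(s) * dt > 1e-8:
            g = math.expm1(s * dt) / s
            gp = (dt * f - g) / s
        else:
            g = dt * (1.0 + 0.5 * s * dt)
            gp = 0.5 * dt * dt
        G11 = g + gp * (m11 - s)
        G21 = gp * m21
    b1 = a1 * e11 + a2 * e12 + rate * G11
    b2 = a1 * e21 + a2 * e22 + rate * G21
    return b1, b2


def _dose_breakpoints(doses: Sequence) -> tuple[list[float], list[float]]:
    """Sorted breakpoint times and the constant total infusion rate after each.

    ``doses`` yields objects with ``time``, ``amount`` and ``infusion_duration``
    attributes (hours, mg).  Overlapping infusions superpose additively.
    """
    deltas: dict[float, float] = {}
    for d in doses:
        rate = d.amount / d.infusion_duration
        deltas[d.time] = deltas.get(d.time, 0.0) + rate
        t_end = d.time + d.infusion_duration
        deltas[t_end] = deltas.get(t_end, 0.0) - rate
    times = sorted(deltas)
    rates = []
    acc = 0.0
    for t in times:
        acc += deltas[t]
        rates.append(acc if acc > 1e-12 else 0.0)
    return times, rates


def amounts(t, doses: Sequence, params: PKParameters) -> np.ndarray:
    """Drug amounts (mg) in central and peripheral compartments at times ``t``."""
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    order = np.argsort(ts, kind="stable")
    bp, rates = _dose_breakpoints(doses)
    out = np.zeros((ts.size, 2))
    a1 = a2 = 0.0
    seg = 0  # index of the current segment start in bp
    for idx in order:
        tq = ts[idx]
        if tq < 0:
            raise ValueError("time must be non-negative")
        if not bp or tq <= bp[0]:
            continue  # before (or at start of) first dose: zero
        # advance the state across whole segments below tq
        while seg + 1 < len(bp) and bp[seg + 1] <= tq:
            a1, a2 = _propagate(a1, a2, params.cl, params.vc, params.q, params.vp,
                                rates[seg], bp[seg + 1] - bp[seg])
            seg += 1
        b1, b2 = _propagate(a1, a2, params.cl, params.vc, params.q, params.vp,
                            rates[seg], tq - bp[seg])
        out[idx, 0] = b1
        out[idx, 1] = b2
    return out


def concentration(t, doses: Sequence, params: PKParameters):
    """Serum concentration (mg/L) of the central compartment at times ``t``.

    Analytic superposed biexponential solution for any set of constant-rate
    infusions; zero before the first dose and continuous at infusion
    boundaries.
    """
    a = amounts(t, doses, params)
    c = a[:, 0] / params.vc
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(c[0])
    return c


def _cycle_operator(reg: Regimen, p: PKParameters):
    """State map over one dosing interval at steady dosing: a -> E a + b."""
    rate = reg.dose / reg.infusion_duration
    pk = (p.cl, p.vc, p.q, p.vp)
    # propagate basis vectors to obtain the affine map explicitly
    e1 = _propagate(1.0, 0.0, *pk, 0.0, reg.infusion_duration)
    e2 = _propagate(0.0, 1.0, *pk, 0.0, reg.infusion_duration)
    b_inf = _propagate(0.0, 0.0, *pk, rate, reg.infusion_duration)
    E_inf = np.array([[e1[0], e2[0]], [e1[1], e2[1]]])
    wash = reg.interval - reg.infusion_duration
    f1 = _propagate(1.0, 0.0, *pk, 0.0, wash)
    f2 = _propagate(0.0, 1.0, *pk, 0.0, wash)
    E_w = np.array([[f1[0], f2[0]], [f1[1], f2[1]]])
    E = E_w @ E_inf
    b = E_w @ np.asarray(b_inf)
    return E, b


def steady_state_profile(reg: Regimen, params: PKParameters):
    """Steady-state concentration profile over one dosing interval.

    Returns ``(profile, trough, peak)`` where ``profile`` maps time within the
    interval (0 = dose start) to concentration, ``trough`` is the value at the
    end of the interval and ``peak`` the value at the end of the infusion.
    The pre-dose state solves the fixed point of the dose-to-dose transition
    (geometric-series accumulation in closed form).
    """
    E, b = _cycle_operator(reg, params)
    a_ss = np.linalg.solve(np.eye(2) - E, b)
    rate = reg.dose / reg.infusion_duration
    a0 = (float(a_ss[0]), float(a_ss[1]))

    def profile(tau):
        taus = np.atleast_1d(np.asarray(tau, dtype=float))
        out = np.empty(taus.size)
        for i, tv in enumerate(taus):
            if not 0.0 <= tv <= reg.interval:
                raise ValueError("time must lie within the dosing interval")
            pk = (params.cl, params.vc, params.q, params.vp)
            if tv <= reg.infusion_duration:
                a = _propagate(a0[0], a0[1], *pk, rate, tv)
            else:
                a = _propagate(a0[0], a0[1], *pk, rate, reg.infusion_duration)
                a = _propagate(a[0], a[1], *pk, 0.0, tv - reg.infusion_duration)
            out[i] = a[0] / params.vc
        return out if np.asarray(tau).ndim else float(out[0])

    peak = float(profile(reg.infusion_duration))
    trough = float(profile(reg.interval))
    return profile, trough, peak


def auc24_ss(reg: Regimen, params: PKParameters) -> float:
    """Steady-state AUC over 24 h (mg*h/L): daily dose / CL, exact for linear PK."""
    return reg.daily_dose / params.cl


def residual_sd(pred: float, sigma_prop: float, sigma_add: float) -> float:
    """Combined proportional-additive residual SD at a predicted concentration."""
    if pred < 0:
        raise ValueError("pred must be non-negative")
    return math.hypot(sigma_prop * pred, sigma_add)
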