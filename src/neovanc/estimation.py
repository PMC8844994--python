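"""Individual MAP Bayesian estimation and population NLME fitting.

Individual estimation maximizes the posterior of the log-normal random
effects on CL (one between-subject effect, one between-occasion effect per
treatment episode) given a subject's concentration records.  Censored (BLQ)
records contribute through the normal CDF of the censoring event (the M3
likelihood); quantified records through a combined proportional-additive
residual model whose SD is evaluated at the *individual* prediction
(estimation "with interaction").

Population fitting maximizes the Laplace approximation of the marginal
likelihood.  Internally each subject's random effects are reparameterized to
occasion-level sums ``s_k = eta_bsv + eta_bov,k`` — an exact linear
reparameterization whose prior covariance is ``omega2_bsv * J + omega2_bov *
I`` — so the inner optimization for a single-course subject is
one-dimensional.  The public API (``PopPKModel`` / ``PopPKResults``) follows
the model/results idiom of statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr

from . import pkcore
from .params import PKParameters, PopulationParameters, omega2_to_cv
from .pkcore import _propagate, residual_sd, typical_params
from .records import Cohort, SubjectRecord

__all__ = [
    "IndividualEstimate",
    "neg2log_posterior",
    "map_estimate",
    "posterior_samples",
    "PopPKModel",
    "PopPKResults",
    "BootstrapResult",
    "bootstrap",
    "lrt_pvalue",
    "cwres",
    "variance_explained",
]

_LN2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# subject designs

@dataclass
class _Design:
    """Precompiled per-subject event structure for fast repeated prediction."""

    sid: str
    dose_t: list
    dose_occ: list          # 0-based occasion index per dose
    dose_cov: list          # (wt, scr, pma) per dose
    occasions: list         # original 1-based occasion labels, sorted
    seg_t: list             # segment start times (dose starts & infusion ends)
    seg_rate: list
    seg_dose: list          # dose index whose parameters govern the segment
    obs_t: np.ndarray       # sorted
    obs_y: np.ndarray
    obs_blq: np.ndarray
    obs_lloq: np.ndarray
    n_cont: int


def _build_design(s: SubjectRecord, obs_times=None) -> _Design:
    """Compile a subject; ``obs_times`` substitutes the observation grid."""
    if not s.dose_events:
        raise ValueError(f"subject {s.subject_id} has no dose events")
    occ_labels = sorted({d.occasion if d.occasion is not None else 1
                         for d in s.dose_events})
    occ_index = {o: i for i, o in enumerate(occ_labels)}
    dose_t, dose_occ, dose_cov = [], [], []
    deltas: dict[float, float] = {}
    for d in s.dose_events:
        dose_t.append(d.time)
        dose_occ.append(occ_index[d.occasion if d.occasion is not None else 1])
        dose_cov.append((s.weight_at(d.time), s.scr_at(d.time), s.pma_at(d.time)))
        deltas[d.time] = deltas.get(d.time, 0.0) + d.rate
        deltas[d.end_time] = deltas.get(d.end_time, 0.0) - d.rate
    seg_t = sorted(deltas)
    seg_rate, seg_dose = [], []
    acc = 0.0
    j = 0
    for t in seg_t:
        acc += deltas[t]
        seg_rate.append(acc if acc > 1e-12 else 0.0)
        while j + 1 < len(dose_t) and dose_t[j + 1] <= t:
            j += 1
        seg_dose.append(j)
    if obs_times is None:
        obs = sorted(s.observations, key=lambda o: o.time)
        obs_t = np.array([o.time for o in obs])
        obs_y = np.array([o.value for o in obs])
        obs_blq = np.array([o.blq for o in obs], dtype=bool)
        obs_lloq = np.array([o.lloq for o in obs])
    else:
        obs_t = np.sort(np.asarray(obs_times, dtype=float))
        obs_y = np.zeros_like(obs_t)
        obs_blq = np.zeros(obs_t.size, dtype=bool)
        obs_lloq = np.full(obs_t.size, 1.0)
    return _Design(s.subject_id, dose_t, dose_occ, dose_cov, occ_labels,
                   seg_t, seg_rate, seg_dose, obs_t, obs_y, obs_blq, obs_lloq,
                   int((~obs_blq).sum()))


def _dose_params(design: _Design, pop: PopulationParameters) -> list:
    """Typical (cl, vc, q, vp) per dose event from its time-matched covariates."""
    out = []
    for wt, scr, pma in design.dose_cov:
        p = typical_params(wt, pma, scr, pop)
        out.append((p.cl, p.vc, p.q, p.vp))
    return out


def _predict(design: _Design, dp: list, mult: list) -> np.ndarray:
    """Concentrations at the design's observation times.

    ``mult`` holds exp(eta) clearance multipliers per occasion; parameters are
    refreshed at each dose event (piecewise-constant covariates and occasion).
    """
    n = design.obs_t.size
    preds = np.zeros(n)
    if n == 0:
        return preds
    a1 = a2 = 0.0
    seg_t, seg_rate, seg_dose = design.seg_t, design.seg_rate, design.seg_dose
    nseg = len(seg_t)
    k = 0
    obs_t = design.obs_t
    # observations before the first dose predict zero
    while k < n and obs_t[k] <= seg_t[0]:
        k += 1
    for i in range(nseg):
        t0 = seg_t[i]
        t1 = seg_t[i + 1] if i + 1 < nseg else math.inf
        di = seg_dose[i]
        cl, vc, q, vp = dp[di]
        cl = cl * mult[design.dose_occ[di]]
        rate = seg_rate[i]
        while k < n and obs_t[k] <= t1:
            b1, _ = _propagate(a1, a2, cl, vc, q, vp, rate, obs_t[k] - t0)
            preds[k] = b1 / vc
            k += 1
        if k >= n:
            break
        if i + 1 < nseg:
            a1, a2 = _propagate(a1, a2, cl, vc, q, vp, rate, t1 - t0)
    return preds


def predict_concentrations(subject: SubjectRecord, pop: PopulationParameters,
                           times, eta_bsv: float = 0.0,
                           eta_bov_by_occasion: dict | None = None) -> np.ndarray:
    """Individual concentration predictions at arbitrary times.

    Covariates are refreshed at each dose event; the CL multiplier of a dose
    is ``exp(eta_bsv + eta_bov[occasion])``.  Times must be given sorted or
    will be evaluated in sorted order.
    """
    design = _build_design(subject, obs_times=times)
    dp = _dose_params(design, pop)
    ebov = eta_bov_by_occasion or {}
    mult = [math.exp(eta_bsv + ebov.get(o, 0.0)) for o in design.occasions]
    return _predict(design, dp, mult)


def _data_neg2ll(design: _Design, preds: np.ndarray, sigma_prop: float,
                 sigma_add: float) -> float:
    """-2 log-likelihood of the observation vector, without 2*pi constants."""
    total = 0.0
    for i in range(preds.size):
        f = preds[i]
        if not math.isfinite(f):
            raise FloatingPointError(f"non-finite prediction for {design.sid}")
        sd = math.hypot(sigma_prop * f, sigma_add)
        if design.obs_blq[i]:
            total -= 2.0 * log_ndtr((design.obs_lloq[i] - f) / sd)
        else:
            w = (design.obs_y[i] - f) / sd
            total += w * w + 2.0 * math.log(sd)
    return total


# ---------------------------------------------------------------------------
# individual MAP estimation (eta parameterization)

def _eta_layout(design: _Design, pop: PopulationParameters):
    """Names of the estimated etas: BSV first, then one BOV per occasion."""
    names = []
    if pop.omega2_bsv > 0:
        names.append("bsv")
    if pop.omega2_bov > 0:
        names += [f"bov_{o}" for o in design.occasions]
    return names


def _mult_from_etas(design: _Design, pop: PopulationParameters,
                    etas: np.ndarray) -> list:
    names = _eta_layout(design, pop)
    eb = etas[names.index("bsv")] if "bsv" in names else 0.0
    mult = []
    for i, o in enumerate(design.occasions):
        key = f"bov_{o}"
        eo = etas[names.index(key)] if key in names else 0.0
        mult.append(math.exp(eb + eo))
    return mult


def neg2log_posterior(etas, subject: SubjectRecord,
                      pop: PopulationParameters) -> float:
    """-2 log posterior (up to constants) of a subject's random effects.

    ``etas`` covers the BSV effect plus one BOV effect per occasion with any
    dose (in occasion order); effects with zero prior variance are excluded.
    Quantified observations contribute squared weighted residuals plus
    ``2 ln sd``; BLQ observations contribute the censored-likelihood term
    ``-2 ln Phi((LLOQ - pred)/sd)``; the prior contributes ``eta' Omega^-1
    eta``.
    """
    design = _build_design(subject)
    etas = np.atleast_1d(np.asarray(etas, dtype=float))
    names = _eta_layout(design, pop)
    if etas.size != len(names):
        raise ValueError(f"expected {len(names)} etas ({names}), got {etas.size}")
    return _neg2post(design, _dose_params(design, pop), pop, etas, names)


def _neg2post(design, dp, pop, etas, names):
    mult = _mult_from_etas(design, pop, etas)
    preds = _predict(design, dp, mult)
    val = _data_neg2ll(design, preds, pop.sigma_prop, pop.sigma_add)
    for name, e in zip(names, etas):
        om2 = pop.omega2_bsv if name == "bsv" else pop.omega2_bov
        val += e * e / om2
    return val


@dataclass
class IndividualEstimate:
    """MAP random effects and Laplace posterior for one subject."""

    subject_id: str
    eta_names: list
    etas: np.ndarray                    # mode, ordered as eta_names
    posterior_covariance: np.ndarray
    posterior_mode_objective: float
    derived_params_by_occasion: dict    # occasion label -> PKParameters
    occasions: list
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def eta_bsv(self) -> float:
        return float(self.etas[self.eta_names.index("bsv")]) \
            if "bsv" in self.eta_names else 0.0

    @property
    def eta_bov_by_occasion(self) -> dict:
        out = {}
        for o in self.occasions:
            key = f"bov_{o}"
            out[o] = (float(self.etas[self.eta_names.index(key)])
                      if key in self.eta_names else 0.0)
        return out

    def lncl_posterior(self, occasion: str = "current") -> tuple[float, float]:
        """Mean and variance of the posterior log-CL multiplier.

        ``occasion='current'`` uses the last observed occasion's BOV effect
        (dose adjustment within the ongoing course); ``'new'`` combines the
        BSV posterior with a fresh BOV effect drawn from its prior.
        """
        names = self.eta_names
        w = np.zeros(len(names))
        extra = 0.0
        if "bsv" in names:
            w[names.index("bsv")] = 1.0
        if occasion == "new":
            extra = self._omega2_bov
        else:
            key = f"bov_{self.occasions[-1]}"
            if key in names:
                w[names.index(key)] = 1.0
        mu = float(w @ self.etas)
        var = float(w @ self.posterior_covariance @ w) + extra
        return mu, var

    _omega2_bov: float = 0.0  # stored by map_estimate for the 'new' horizon


def _fd_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (4-point stencil for the cross terms)."""
    n = x.size
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / (h * h)
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (fun(x + ei + ej) - fun(x + ei - ej)
                                 - fun(x - ei + ej) + fun(x - ei - ej)
                                 ) / (4.0 * h * h)
    return 0.5 * (H + H.T)


def map_estimate(subject: SubjectRecord, pop: PopulationParameters,
                 n_restarts: int = 3, seed: int = 0) -> IndividualEstimate:
    """MAP Bayesian estimate of a subject's random effects.

    Quasi-Newton minimization of :func:`neg2log_posterior` starting from zero
    with jittered restarts; the posterior covariance is twice the inverse of
    the finite-difference Hessian of the -2 log posterior at the mode (the
    Laplace approximation).  Zero observations are allowed (prior mode).
    """
    design = _build_design(subject)
    names = _eta_layout(design, pop)
    dp = _dose_params(design, pop)

    def obj(x):
        return _neg2post(design, dp, pop, x, names)

    n = len(names)
    best = None
    rng = np.random.default_rng(seed)
    converged = False
    for attempt in range(1 + n_restarts):
        x0 = np.zeros(n) if attempt == 0 else rng.normal(0.0, 0.2, n)
        res = optimize.minimize(obj, x0, method="BFGS",
                                options={"gtol": 1e-7, "maxiter": 200})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success or np.linalg.norm(res.jac) < 1e-4:
            converged = True
            break
    mode = np.asarray(best.x, dtype=float)
    H = _fd_hessian(obj, mode)
    try:
        cov = 2.0 * np.linalg.inv(H)
        cov = _nearest_psd(cov)
    except np.linalg.LinAlgError:
        cov = np.full((n, n), np.nan)
        converged = False

    est = IndividualEstimate(
        subject_id=subject.subject_id, eta_names=names, etas=mode,
        posterior_covariance=cov, posterior_mode_objective=float(best.fun),
        derived_params_by_occasion=_derived_params(subject, design, pop, mode, names),
        occasions=list(design.occasions), converged=converged,
        diagnostics={"grad_norm": float(np.linalg.norm(best.jac)),
                     "n_obs": int(design.obs_t.size)})
    est._omega2_bov = pop.omega2_bov
    return est


def _derived_params(subject, design, pop, etas, names) -> dict:
    eb = etas[names.index("bsv")] if "bsv" in names else 0.0
    out = {}
    for o in design.occasions:
        key = f"bov_{o}"
        eo = etas[names.index(key)] if key in names else 0.0
        # covariates of the last dose in this occasion
        idx = max(i for i, oc in enumerate(design.dose_occ)
                  if design.occasions[oc] == o)
        wt, scr, pma = design.dose_cov[idx]
        typ = typical_params(wt, pma, scr, pop)
        out[o] = pkcore.individual_params(typ, eb, eo)
    return out


def _nearest_psd(m: np.ndarray, min_eig: float = 0.0) -> np.ndarray:
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    if w.min() < min_eig:
        warnings.warn("posterior covariance repaired to nearest PSD matrix")
        w = np.clip(w, max(min_eig, 0.0), None)
        m = (v * w) @ v.T
    return m


def posterior_samples(estimate: IndividualEstimate, n: int,
                      seed: int = 0) -> np.ndarray:
    """Multivariate-normal draws from the Laplace posterior of the etas."""
    rng = np.random.default_rng(seed)
    cov = estimate.posterior_covariance
    if not np.all(np.isfinite(cov)):
        raise ValueError("posterior covariance is not available")
    cov = _nearest_psd(cov)
    return rng.multivariate_normal(estimate.etas, cov, size=n,
                                   method="eigh")


# ---------------------------------------------------------------------------
# occasion-sum (s) parameterization used by the population fit

def _prior_s(pop: PopulationParameters, K: int):
    """Inverse covariance and log|2 pi Sigma| for s = eta_bsv + eta_bov per occ.

    Degenerate variances collapse the dimension: with omega2_bov = 0 the K
    sums coincide (dim 1, variance omega2_bsv); with omega2_bsv = 0 they are
    independent.
    """
    ob, oo = pop.omega2_bsv, pop.omega2_bov
    if ob <= 0 and oo <= 0:
        return 0, None, 0.0
    if oo <= 0:
        return 1, np.array([[1.0 / ob]]), math.log(2 * math.pi * ob)
    if ob <= 0:
        inv = np.eye(K) / oo
        return K, inv, K * math.log(2 * math.pi * oo)
    denom = oo * (oo + K * ob)
    inv = np.eye(K) / oo - (ob / denom) * np.ones((K, K))
    logdet = (K - 1) * math.log(oo) + math.log(oo + K * ob)
    return K, inv, K * _LN2PI + logdet


def _subject_laplace(design: _Design, dp, pop: PopulationParameters,
                     warm: np.ndarray | None):
    """(-2 log marginal likelihood contribution, mode) for one subject.

    Includes ``n_cont*ln(2 pi)``; the caller subtracts the dataset-wide
    constant to report an OFV on the customary scale.
    """
    K = len(design.occasions)
    dim, inv, log2pidet = _prior_s(pop, K)

    if dim == 0:  # no random effects: plain likelihood
        preds = _predict(design, dp, [1.0] * K)
        return (_data_neg2ll(design, preds, pop.sigma_prop, pop.sigma_add)
                + design.n_cont * _LN2PI), np.zeros(0)

    collapse = dim == 1 and K > 1  # omega2_bov == 0

    def obj(sv):
        mult = ([math.exp(sv[0])] * K if collapse
                else [math.exp(x) for x in sv])
        preds = _predict(design, dp, mult)
        val = _data_neg2ll(design, preds, pop.sigma_prop, pop.sigma_add)
        return val + float(sv @ inv @ sv)

    x0 = warm if warm is not None and warm.size == dim else np.zeros(dim)
    if dim == 1:
        mode = _newton_1d(lambda x: obj(np.array([x])), float(x0[0]))
        sv = np.array([mode])
        h = 1e-4
        f0 = obj(sv)
        fp = obj(sv + h); fm = obj(sv - h)
        hess = max((fp - 2 * f0 + fm) / (h * h), 1e-12)
        logdet_half = math.log(0.5 * hess)
    else:
        res = optimize.minimize(obj, x0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 200})
        sv = np.asarray(res.x)
        f0 = float(res.fun)
        H = _fd_hessian(obj, sv)
        sign, ld = np.linalg.slogdet(0.5 * H)
        logdet_half = ld if sign > 0 else math.log(1e-12)
    contrib = (f0 + design.n_cont * _LN2PI + log2pidet
               + logdet_half - dim * _LN2PI)
    return contrib, sv


def _newton_1d(f, x0: float, tol: float = 1e-9, maxiter: int = 50) -> float:
    """Safeguarded Newton minimization with finite-difference derivatives."""
    x = x0
    h = 1e-5
    for _ in range(maxiter):
        f0 = f(x)
        fp = f(x + h)
        fm = f(x - h)
        g = (fp - fm) / (2 * h)
        c = (fp - 2 * f0 + fm) / (h * h)
        if abs(g) < tol * (1.0 + abs(f0)):
            return x
        step = -g / c if c > 1e-12 else -math.copysign(0.2, g)
        if abs(step) > 1.0:
            step = math.copysign(1.0, step)
        # backtracking line search
        for _ in range(20):
            if f(x + step) <= f0 + 1e-12:
                break
            step *= 0.5
        x += step
        if abs(step) < 1e-10:
            return x
    return x


# ---------------------------------------------------------------------------
# population model

_FREE_DEFAULT = ("tvcl", "tvvc", "tvq", "tvvp", "hill", "mat50",
                 "scr_exponent", "omega2_bsv", "omega2_bov",
                 "sigma_prop", "sigma_add")
# estimable on request only (fixed at 0.75/1 by default); freeing them
# supports the likelihood-ratio comparison against free allometric exponents
_FREE_OPTIONAL = ("wt_exp_cl_q", "wt_exp_v")


class PopPKModel:
    """Nonlinear mixed-effects model of a preprocessed cohort.

    Parameters
    ----------
    cohort:
        Preprocessed :class:`Cohort` (covariates imputed, occasions assigned).
    start:
        Initial :class:`PopulationParameters`; also supplies the values of
        fixed parameters.  Allometric exponents are always fixed.
    fixed:
        Names of parameters to hold at their starting values.
    free_extra:
        Normally-fixed parameters to estimate as well (the allometric
        exponents ``wt_exp_cl_q`` / ``wt_exp_v``), for model-comparison
        experiments against freely estimated exponents.
    """

    def __init__(self, cohort: Cohort, start: PopulationParameters | None = None,
                 fixed=(), free_extra=()):
        self.cohort = cohort
        self.start = start or PopulationParameters()
        unknown = set(fixed) - set(_FREE_DEFAULT)
        if unknown:
            raise ValueError(f"unknown parameter names in fixed: {sorted(unknown)}")
        unknown = set(free_extra) - set(_FREE_OPTIONAL)
        if unknown:
            raise ValueError(f"not an optional free parameter: {sorted(unknown)}")
        self.free_names = [n for n in _FREE_DEFAULT if n not in set(fixed)
                           and getattr(self.start, n) > 0]
        self.free_names += [n for n in _FREE_OPTIONAL if n in set(free_extra)]
        self.designs = [_build_design(s) for s in cohort]
        self._warm: dict[str, np.ndarray] = {}

    # -- parameter vector <-> PopulationParameters (log scale) --------------

    def _to_pop(self, theta: np.ndarray) -> PopulationParameters:
        kw = {n: math.exp(t) for n, t in zip(self.free_names, theta)}
        return self.start.replace(**kw)

    def _theta0(self) -> np.ndarray:
        return np.array([math.log(getattr(self.start, n)) for n in self.free_names])

    def neg2loglike(self, theta: np.ndarray) -> float:
        """Laplace-approximated -2 log marginal likelihood (OFV + constant)."""
        pop = self._to_pop(theta)
        total = 0.0
        for d in self.designs:
            dp = _dose_params(d, pop)
            contrib, mode = _subject_laplace(d, dp, pop, self._warm.get(d.sid))
            self._warm[d.sid] = mode
            total += contrib
        return total

    def _grad(self, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
        g = np.empty(theta.size)
        for i in range(theta.size):
            e = np.zeros(theta.size); e[i] = h
            g[i] = (self.neg2loglike(theta + e) - self.neg2loglike(theta - e)) / (2 * h)
        return g

    def fit(self, maxiter: int = 200, compute_se: bool = True,
            verbose: bool = False) -> "PopPKResults":
        """Maximize the Laplace marginal likelihood; returns a results object."""
        theta0 = self._theta0()
        self.neg2loglike(theta0)  # populate warm starts
        it = [0]

        def cb(xk):
            it[0] += 1
            if verbose:
                print(f"iter {it[0]}: ofv={self.neg2loglike(xk):.3f}")

        res = optimize.minimize(self.neg2loglike, theta0, jac=self._grad,
                                method="L-BFGS-B", callback=cb,
                                options={"maxiter": maxiter, "ftol": 1e-10,
                                         "gtol": 1e-6})
        theta = np.asarray(res.x)
        pop = self._to_pop(theta)
        n_cont = sum(d.n_cont for d in self.designs)
        ofv = float(res.fun) - n_cont * _LN2PI

        cov = None
        if compute_se:
            H = _fd_hessian(self.neg2loglike, theta, h=5e-4)
            try:
                cov = 2.0 * np.linalg.inv(_nearest_psd(H, min_eig=1e-10))
            except np.linalg.LinAlgError:
                cov = None
        return PopPKResults(self, pop, theta, ofv, cov,
                            converged=bool(res.success), nit=int(res.nit),
                            grad_norm=float(np.max(np.abs(res.jac))))


class PopPKResults:
    """Estimates, uncertainties and diagnostics of a fitted population model."""

    def __init__(self, model: PopPKModel, params: PopulationParameters,
                 theta: np.ndarray, ofv: float, cov_log: np.ndarray | None,
                 converged: bool, nit: int, grad_norm: float):
        self.model = model
        self.params = params
        self.theta = theta
        self.ofv = ofv
        self.cov_log = cov_log
        self.converged = converged
        self.nit = nit
        self.grad_norm = grad_norm
        self._ebe = None

    @property
    def free_names(self):
        return self.model.free_names

    @property
    def bse(self) -> dict:
        """Standard errors of the log-scale estimates."""
        if self.cov_log is None:
            return {n: float("nan") for n in self.free_names}
        se = np.sqrt(np.clip(np.diag(self.cov_log), 0.0, None))
        return dict(zip(self.free_names, se))

    def conf_int(self, alpha: float = 0.10) -> pd.DataFrame:
        """CI on the natural scale: estimate * exp(+/- z * SE_log)."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        rows = []
        for n in self.free_names:
            est = getattr(self.params, n)
            se = self.bse[n]
            rows.append((n, est, est * math.exp(-z * se), est * math.exp(z * se)))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "lower",
                                           "upper"]).set_index("parameter")

    @property
    def condition_number(self) -> float:
        """Eigenvalue ratio of the correlation matrix of the estimates."""
        if self.cov_log is None:
            return float("nan")
        d = np.sqrt(np.clip(np.diag(self.cov_log), 1e-300, None))
        corr = self.cov_log / np.outer(d, d)
        w = np.linalg.eigvalsh(corr)
        wmin = max(w.min(), 1e-300)
        return float(w.max() / wmin)

    # -- empirical Bayes estimates and shrinkage ----------------------------

    def ebe_table(self) -> pd.DataFrame:
        """Per-subject MAP etas under the fitted population parameters."""
        if self._ebe is None:
            rows = []
            for s in self.model.cohort:
                est = map_estimate(s, self.params)
                row = {"subject_id": s.subject_id, "eta_bsv": est.eta_bsv}
                for occ, e in est.eta_bov_by_occasion.items():
                    row[f"eta_bov_{occ}"] = e
                rows.append(row)
            self._ebe = pd.DataFrame(rows).set_index("subject_id")
        return self._ebe

    def shrinkage(self) -> dict:
        """Eta shrinkage (1 - SD(EBE)/omega), per effect and pooled, in %."""
        ebe = self.ebe_table()
        out = {}
        pooled = []
        if self.params.omega2_bsv > 0:
            sd = float(ebe["eta_bsv"].std(ddof=1))
            om = math.sqrt(self.params.omega2_bsv)
            out["bsv"] = 100.0 * (1.0 - sd / om)
            pooled += list(ebe["eta_bsv"] / om)
        if self.params.omega2_bov > 0:
            cols = [c for c in ebe.columns if c.startswith("eta_bov")]
            vals = ebe[cols].to_numpy().ravel()
            vals = vals[~np.isnan(vals)]
            om = math.sqrt(self.params.omega2_bov)
            if vals.size > 1:
                out["bov"] = 100.0 * (1.0 - float(np.std(vals, ddof=1)) / om)
                pooled += list(vals / om)
        if pooled:
            out["pooled"] = 100.0 * (1.0 - float(np.std(pooled, ddof=1)))
        return out

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        ci = self.conf_int()
        lines = ["Population PK fit (Laplace with interaction, M3 for BLQ)",
                 f"  subjects: {len(self.model.cohort)}    "
                 f"observations: {sum(d.obs_t.size for d in self.model.designs)}",
                 f"  OFV: {self.ofv:.3f}    converged: {self.converged}"
                 f"    iterations: {self.nit}",
                 f"  condition number: {self.condition_number:.1f}"
                 " (reference limit 1000)",
                 "",
                 f"  {'parameter':<14}{'estimate':>12}{'90% CI':>26}"]
        for n in self.free_names:
            est, lo, hi = ci.loc[n, ["estimate", "lower", "upper"]]
            if n.startswith("omega2"):
                extra = f"   CV {100 * omega2_to_cv(est):.1f}%"
            else:
                extra = ""
            lines.append(f"  {n:<14}{est:>12.4g}{f'({lo:.4g}-{hi:.4g})':>26}{extra}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": self.params.to_dict(),
            "free_parameters": list(self.free_names),
            "ofv": self.ofv,
            "standard_errors_log": self.bse,
            "condition_number": self.condition_number,
            "condition_number_reference_limit": 1000.0,
            "converged": self.converged,
        }


def lrt_pvalue(dofv: float, df: int) -> float:
    """Likelihood-ratio p-value: upper-tail chi-square at |dOFV| with df."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(abs(dofv), df))


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapResult:
    n_resamples: int
    n_failed: int
    means: dict
    ci90: dict                 # parameter -> (lower, upper) percentile bounds
    estimates: pd.DataFrame    # one row per successful replicate


def bootstrap(cohort: Cohort, start: PopulationParameters, n: int = 1000,
              seed: int = 0, fixed=(), maxiter: int = 200) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement; each replicate cohort is refit
    from ``start``; non-converging replicates are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    subjects = list(cohort.subjects)
    rows = []
    n_failed = 0
    for _ in range(n):
        idx = rng.integers(0, len(subjects), size=len(subjects))
        resampled = [replace_id(subjects[i], f"B{k}") for k, i in enumerate(idx)]
        boot = Cohort(subjects=resampled)
        try:
            res = PopPKModel(boot, start, fixed=fixed).fit(
                maxiter=maxiter, compute_se=False)
            if not res.converged:
                raise RuntimeError("non-convergence")
            rows.append({name: getattr(res.params, name)
                         for name in res.free_names})
        except Exception:
            n_failed += 1
    est = pd.DataFrame(rows)
    means = {c: float(est[c].mean()) for c in est.columns}
    ci90 = {c: (float(est[c].quantile(0.05)), float(est[c].quantile(0.95)))
            for c in est.columns}
    return BootstrapResult(n_resamples=n, n_failed=n_failed, means=means,
                           ci90=ci90, estimates=est)


def replace_id(s: SubjectRecord, new_id: str) -> SubjectRecord:
    return SubjectRecord(new_id, dose_events=list(s.dose_events),
                         observations=list(s.observations),
                         covariate_series=list(s.covariate_series),
                         sex=s.sex, birth_weight=s.birth_weight,
                         gestational_age=s.gestational_age)


# ---------------------------------------------------------------------------
# conditional weighted residuals

def cwres(cohort: Cohort, pop: PopulationParameters) -> pd.DataFrame:
    """FOCE-linearized conditional weighted residuals per quantified observation.

    The model is linearized around each subject's MAP etas; the marginal mean
    and covariance of the observation vector follow from the linearization and
    the residual SD evaluated at the individual predictions (interaction).
    BLQ observations are excluded.
    """
    out = []
    for s in cohort:
        design = _build_design(s)
        keep = ~design.obs_blq
        if keep.sum() == 0:
            continue
        est = map_estimate(s, pop)
        names = est.eta_names
        dp = _dose_params(design, pop)

        def preds_at(etas):
            return _predict(design, dp, _mult_from_etas(design, pop, etas))[keep]

        f_hat = preds_at(est.etas)
        n_eta = len(names)
        G = np.empty((f_hat.size, n_eta))
        h = 1e-5
        for j in range(n_eta):
            e = np.zeros(n_eta); e[j] = h
            G[:, j] = (preds_at(est.etas + e) - preds_at(est.etas - e)) / (2 * h)
        Om = np.diag([pop.omega2_bsv if nm == "bsv" else pop.omega2_bov
                      for nm in names])
        sd = np.hypot(pop.sigma_prop * f_hat, pop.sigma_add)
        V = G @ Om @ G.T + np.diag(sd * sd)
        r = design.obs_y[keep] - f_hat + G @ est.etas
        L = np.linalg.cholesky(_nearest_psd(V, min_eig=1e-12))
        w = np.linalg.solve(L, r)
        pop_pred = _predict(design, dp, [1.0] * len(design.occasions))[keep]
        for t, y, pr, ip, c in zip(design.obs_t[keep], design.obs_y[keep],
                                   pop_pred, f_hat, w):
            out.append({"subject_id": s.subject_id, "time": t, "dv": y,
                        "pred": pr, "ipred": ip, "cwres": c})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# covariate contribution to CL variability

def variance_explained(cohort: Cohort, pop: PopulationParameters,
                       covariate_subset=("wt", "pma", "scr")) -> float:
    """Share of log-CL variability attributable to a covariate subset, in %.

    Computed as Var(log typical CL with the subset active, other covariates
    held at reference) divided by [Var(log typical CL, all active) +
    omega2_bsv + omega2_bov] across subjects (covariates at first dose).  This
    is a reconstruction of the usual "variability explained" summary; the
    exact published definition is not standardized.
    """
    subset = set(covariate_subset)
    unknown = subset - {"wt", "pma", "scr"}
    if unknown:
        raise ValueError(f"unknown covariates: {sorted(unknown)}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    lncl_sub, lncl_all = [], []
    for s in cohort:
        t0 = s.dose_events[0].time if s.dose_events else 0.0
        wt, scr, pma = s.weight_at(t0), s.scr_at(t0), s.pma_at(t0)
        for active, store in ((subset, lncl_sub), ({"wt", "pma", "scr"}, lncl_all)):
            v = math.log(pop.tvcl)
            if "wt" in active:
                v += pop.wt_exp_cl_q * math.log(wt / pop.wt_ref)
            if "pma" in active:
                v += math.log(pkcore.maturation(pma, pop.hill, pop.mat50))
            if "scr" in active:
                v += pop.scr_exponent * math.log(pop.scr_ref / scr)
            store.append(v)
    var_sub = float(np.var(lncl_sub, ddof=1)) if len(lncl_sub) > 1 else 0.0
    var_all = float(np.var(lncl_all, ddof=1)) if len(lncl_all) > 1 else 0.0
    denom = var_all + pop.omega2_bsv + pop.omega2_bov
    return 100.0 * var_sub / denom
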