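"""Goodness-of-fit tables and the prediction-corrected visual predictive check.

Both diagnostics produce plain tabular data; rendering helpers are thin
wrappers so that the numeric surface is what gets tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import _build_design, _dose_params, _predict, cwres
from .params import PopulationParameters
from .records import Cohort

__all__ = ["gof_table", "pcvpc", "VPCResult", "plot_gof", "plot_vpc"]


def gof_table(cohort: Cohort, pop: PopulationParameters) -> pd.DataFrame:
    """Per-observation table of population/individual predictions and CWRES.

    Population predictions are evaluated at zero etas, individual predictions
    at each subject's MAP etas.  BLQ observations are excluded (they carry no
    quantified value to compare against).
    """
    return cwres(cohort, pop)


@dataclass
class VPCResult:
    """Binned percentiles of prediction-corrected observations vs simulations."""

    bins: pd.DataFrame        # bin edges, n and median population prediction
    percentiles: pd.DataFrame  # observed 5/50/95 and simulated 95% CIs per bin
    blq: pd.DataFrame         # observed BLQ fraction and simulated CI per bin
    n_sim: int
    seed: int

    def coverage(self) -> float:
        """Fraction of observed bin-percentiles inside their simulated CI."""
        hits = 0
        total = 0
        for p in (5, 50, 95):
            obs = self.percentiles[f"obs_p{p}"]
            lo = self.percentiles[f"sim_p{p}_lo"]
            hi = self.percentiles[f"sim_p{p}_hi"]
            ok = (obs >= lo) & (obs <= hi)
            hits += int(ok.sum())
            total += int(ok.notna().sum())
        return hits / total if total else float("nan")


def _time_after_dose(design) -> np.ndarray:
    tad = np.empty(design.obs_t.size)
    for i, t in enumerate(design.obs_t):
        prev = [dt for dt in design.dose_t if dt <= t]
        tad[i] = t - (prev[-1] if prev else 0.0)
    return tad


def pcvpc(cohort: Cohort, pop: PopulationParameters, n_sim: int = 500,
          n_bins: int = 8, seed: int = 0, min_bin: int = 3,
          ci: float = 0.95) -> VPCResult:
    """Prediction-corrected visual predictive check with a BLQ panel.

    Observations and simulated replicates are normalized by ``bin-median
    population prediction / record's population prediction``; records are
    binned by quantiles of time after the most recent dose.  Percentile CIs
    come from the replicate-wise percentile distribution; the BLQ panel
    compares per-bin censored fractions at the assay LLOQ.  Bins with fewer
    than ``min_bin`` observations are merged with their neighbor.
    """
    designs = [_build_design(s) for s in cohort]
    pred, tad, yobs, blq, lloq = [], [], [], [], []
    for d in designs:
        dp = _dose_params(d, pop)
        p = _predict(d, dp, [1.0] * len(d.occasions))
        pred.append(p)
        tad.append(_time_after_dose(d))
        yobs.append(d.obs_y)
        blq.append(d.obs_blq)
        lloq.append(d.obs_lloq)
    pred = np.concatenate(pred)
    tad = np.concatenate(tad)
    yobs = np.concatenate(yobs)
    blq = np.concatenate(blq)
    lloq = np.concatenate(lloq)
    n_obs = yobs.size
    if n_obs == 0:
        raise ValueError("cohort has no observations")

    # quantile binning on time after dose, merging sparse bins with a neighbor
    edges = list(np.unique(np.quantile(tad, np.linspace(0, 1, n_bins + 1))))
    merged = []
    while len(edges) > 2:
        idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                      0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.where(counts < min_bin)[0]
        if small.size == 0:
            break
        b = int(small[0])
        drop = b + 1 if b == 0 else b  # merge leftmost small bin with neighbor
        merged.append(float(edges[drop]))
        del edges[drop]
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                      0, len(edges) - 2)
    bins = sorted(set(bin_idx.tolist()))

    med_pred = {b: float(np.median(pred[bin_idx == b])) for b in bins}
    corr = np.array([med_pred[b] for b in bin_idx]) / np.maximum(pred, 1e-12)

    def bin_stats(values, blq_mask):
        """Per-bin percentiles of corrected non-BLQ values and BLQ fraction."""
        pc = values * corr
        stats_, fracs = {}, {}
        for b in bins:
            m = (bin_idx == b)
            mq = m & ~blq_mask
            if mq.sum() > 0:
                stats_[b] = np.percentile(pc[mq], [5, 50, 95])
            else:
                stats_[b] = np.array([np.nan] * 3)
            fracs[b] = float(blq_mask[m].mean())
        return stats_, fracs

    obs_stats, obs_frac = bin_stats(yobs, blq)

    # per-subject generators keyed by (seed, subject id): the simulated CIs
    # are then invariant to the ordering of subjects in the cohort
    import hashlib

    def subject_rng(sid):
        h = int.from_bytes(hashlib.sha256(sid.encode()).digest()[:4], "big")
        return np.random.default_rng((seed, h))

    rngs = [subject_rng(d.sid) for d in designs]
    sim_stats = {b: [] for b in bins}
    sim_fracs = {b: [] for b in bins}
    ob, oo = math.sqrt(pop.omega2_bsv), math.sqrt(pop.omega2_bov)
    dps = [_dose_params(d, pop) for d in designs]
    for _ in range(n_sim):
        ysim = np.empty(n_obs)
        bsim = np.zeros(n_obs, dtype=bool)
        pos = 0
        for d, dp, rng in zip(designs, dps, rngs):
            K = len(d.occasions)
            eb = rng.normal(0.0, ob)
            mult = [math.exp(eb + rng.normal(0.0, oo)) for _ in range(K)]
            f = _predict(d, dp, mult)
            sd = np.hypot(pop.sigma_prop * f, pop.sigma_add)
            y = f + sd * rng.standard_normal(f.size)
            cens = y < lloq[pos:pos + f.size]
            ysim[pos:pos + f.size] = y
            bsim[pos:pos + f.size] = cens
            pos += f.size
        st, fr = bin_stats(ysim, bsim)
        for b in bins:
            sim_stats[b].append(st[b])
            sim_fracs[b].append(fr[b])

    alpha = (1.0 - ci) / 2.0
    rows = []
    for b in bins:
        arr = np.array(sim_stats[b])  # n_sim x 3
        row = {"bin": b,
               "tad_lo": float(tad[bin_idx == b].min()),
               "tad_hi": float(tad[bin_idx == b].max()),
               "n": int((bin_idx == b).sum())}
        for k, p in enumerate((5, 50, 95)):
            row[f"obs_p{p}"] = float(obs_stats[b][k])
            with np.errstate(invalid="ignore"):
                row[f"sim_p{p}_lo"] = float(np.nanquantile(arr[:, k], alpha))
                row[f"sim_p{p}_hi"] = float(np.nanquantile(arr[:, k], 1 - alpha))
        rows.append(row)
    percentiles = pd.DataFrame(rows).set_index("bin")

    blq_rows = []
    for b in bins:
        fr = np.array(sim_fracs[b])
        blq_rows.append({"bin": b, "obs_blq_fraction": obs_frac[b],
                         "sim_blq_lo": float(np.quantile(fr, alpha)),
                         "sim_blq_hi": float(np.quantile(fr, 1 - alpha))})
    blq_df = pd.DataFrame(blq_rows).set_index("bin")

    bins_df = pd.DataFrame({"bin": bins,
                            "median_pred": [med_pred[b] for b in bins],
                            "n": [int((bin_idx == b).sum()) for b in bins]}
                           ).set_index("bin")
    return VPCResult(bins=bins_df, percentiles=percentiles, blq=blq_df,
                     n_sim=n_sim, seed=seed)


# ---------------------------------------------------------------------------
# optional rendering (kept thin; the numeric tables above are the interface)

def plot_gof(table: pd.DataFrame, path=None):
    """Observed vs predicted and CWRES panels from a gof_table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, x in zip(axes[0], ("pred", "ipred")):
        ax.scatter(table[x], table["dv"], s=8, alpha=0.6)
        lim = max(table[x].max(), table["dv"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{x} (mg/L)"); ax.set_ylabel("observed (mg/L)")
    for ax, x in zip(axes[1], ("pred", "ipred")):
        ax.scatter(table[x], table["cwres"], s=8, alpha=0.6)
        ax.axhline(1.96, ls="--", c="k", lw=1); ax.axhline(-1.96, ls="--", c="k", lw=1)
        ax.set_xlabel(f"{x} (mg/L)"); ax.set_ylabel("CWRES")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_vpc(vpc: VPCResult, path=None, blq_display: float = 0.5):
    """Percentile ribbons and BLQ-fraction panel from a pcvpc result."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 8), sharex=True)
    mid = 0.5 * (vpc.percentiles["tad_lo"] + vpc.percentiles["tad_hi"])
    for p, color in ((5, "C0"), (50, "C1"), (95, "C2")):
        ax1.fill_between(mid, vpc.percentiles[f"sim_p{p}_lo"],
                         vpc.percentiles[f"sim_p{p}_hi"], alpha=0.3, color=color)
        ax1.plot(mid, vpc.percentiles[f"obs_p{p}"], color=color, marker="o",
                 label=f"observed p{p}")
    ax1.set_ylabel("prediction-corrected VC_s (mg/L)")
    ax1.legend()
    ax2.fill_between(mid, vpc.blq["sim_blq_lo"], vpc.blq["sim_blq_hi"],
                     alpha=0.3, color="C3")
    ax2.plot(mid, vpc.blq["obs_blq_fraction"], color="C3", marker="o")
    ax2.set_xlabel("time after dose (h)")
    ax2.set_ylabel("BLQ fraction")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
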