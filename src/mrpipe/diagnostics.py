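"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
pooled IVW estimate; an Egger intercept away from zero signals
directional horizontal pleiotropy; MR-PRESSO locates individual
outlying instruments by comparing observed leave-one-out residuals to
a parametric simulation under the no-pleiotropy model; leave-one-out
refits flag single instruments that drive the pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import (
    InsufficientInstrumentsError,
    MrEstimate,
    _ivw_beta_se,
    compute_ratios,
    egger,
    ivw,
    wald_ratio,
)
from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LeaveOneOutResult",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "funnel_and_forest_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return {"q_stat": self.q_stat, "df": self.df, "pval": self.pval}


def cochran_q(instruments: InstrumentSet | Sequence[HarmonizedInstrument]) -> HeterogeneityResult:
    """Cochran's Q for the fixed-effect IVW fit; df = k-1, upper-tail chi²."""
    rs = compute_ratios(instruments)
    if len(rs) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 complete instruments")
    _, _, q = _ivw_beta_se(rs.beta_exp, rs.se_exp, rs.beta_out, rs.se_out)
    df = len(rs) - 1
    return HeterogeneityResult(q_stat=q, df=df, pval=float(sps.chi2.sf(q, df)))


def egger_intercept_test(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
) -> tuple[float, float, float, str]:
    """Egger intercept, its SE and p, plus a plain-language verdict."""
    est = egger(instruments)
    verdict = (
        "no evidence of horizontal pleiotropy"
        if est.intercept_pval > 0.05
        else "evidence of horizontal pleiotropy"
    )
    return est.intercept, est.intercept_se, est.intercept_pval, verdict


# ---------------------------------------------------------------------------
# MR-PRESSO


@dataclass
class PressoResult:
    """Global, per-SNP outlier and distortion test outcomes."""

    global_rss_obs: float
    global_pval: float
    per_snp_pvals: pd.DataFrame  # columns: snp, pval_raw, pval_adj
    outlier_ids: list[str]
    beta_raw: float
    beta_corrected: float | None
    distortion_pval: float | None
    n_sim: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "global_rss_obs": self.global_rss_obs,
            "global_pval": self.global_pval,
            "per_snp": self.per_snp_pvals.to_dict(orient="records"),
            "outlier_ids": self.outlier_ids,
            "beta_raw": self.beta_raw,
            "beta_corrected": self.beta_corrected,
            "distortion_pval": self.distortion_pval,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _loo_ivw_beta(bx: np.ndarray, bo: np.ndarray, so: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW beta for each left-out index.

    Works on 1-D arrays or on (n_sim, k) matrices along the last axis.
    """
    num = bx * bo / so**2
    den = bx**2 / so**2
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def mr_presso(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    (a) *Global*: each SNP's observed residual is its squared deviation
    from the prediction of the leave-one-out IVW fit, scaled by its
    outcome variance; the total RSS is compared with RSS values from
    ``n_sim`` parametric simulations under the no-pleiotropy model.
    (b) *Outlier*: per-SNP residuals get empirical p-values from the
    same simulations, Bonferroni-adjusted by k; evaluated when the
    global test is significant.  (c) *Distortion*: when outliers are
    flagged, the shift between the all-SNP and outlier-free estimates
    is compared with shifts from removing random same-sized subsets.
    Empirical p-values use add-one smoothing so they are never zero.
    """
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")
    rs = compute_ratios(instruments)
    k = len(rs)
    if k < 3:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 3 complete instruments")
    rng = np.random.default_rng(seed)
    bx, so, bo, sx = rs.beta_exp, rs.se_out, rs.beta_out, rs.se_exp

    beta_loo = _loo_ivw_beta(bx, bo, so)
    resid_obs = (bo - beta_loo * bx) ** 2 / so**2
    rss_obs = float(resid_obs.sum())

    # simulate under the no-horizontal-pleiotropy model
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    bo_sim = rng.normal(beta_loo * bx, so, size=(n_sim, k))
    beta_loo_sim = _loo_ivw_beta(bx_sim, bo_sim, so)
    resid_sim = (bo_sim - beta_loo_sim * bx_sim) ** 2 / so**2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    pval_raw = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    pval_adj = np.minimum(pval_raw * k, 1.0)
    per_snp = pd.DataFrame(
        {"snp": rs.snp_ids, "pval_raw": pval_raw, "pval_adj": pval_adj}
    )

    outlier_ids: list[str] = []
    if global_pval < outlier_alpha:
        outlier_ids = [
            sid for sid, p in zip(rs.snp_ids, pval_adj) if p < outlier_alpha
        ]
    if len(outlier_ids) == k:
        raise InsufficientInstrumentsError(
            "all instruments flagged as outliers; no instruments remain"
        )

    beta_raw, _, _ = _ivw_beta_se(bx, sx, bo, so)
    beta_corrected = None
    distortion_pval = None
    if outlier_ids:
        keep = ~np.isin(np.array(rs.snp_ids), outlier_ids)
        beta_corrected, _, _ = _ivw_beta_se(bx[keep], sx[keep], bo[keep], so[keep])
        d_obs = (beta_raw - beta_corrected) / abs(beta_corrected)
        n_out = len(outlier_ids)
        d_sim = np.empty(n_sim)
        for b in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            mask = np.ones(k, dtype=bool)
            mask[drop] = False
            beta_b, _, _ = _ivw_beta_se(bx[mask], sx[mask], bo[mask], so[mask])
            d_sim[b] = (beta_raw - beta_b) / abs(beta_b)
        distortion_pval = float(
            (1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1)
        )

    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        per_snp_pvals=per_snp,
        outlier_ids=outlier_ids,
        beta_raw=float(beta_raw),
        beta_corrected=None if beta_corrected is None else float(beta_corrected),
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Influence diagnostics


@dataclass
class LeaveOneOutResult:
    """IVW refits with each instrument excluded, plus the all-SNP row."""

    table: pd.DataFrame  # columns: excluded, beta, se, pval, n_snps, flagged

    @property
    def flagged_ids(self) -> list[str]:
        flagged = self.table[self.table["flagged"] & (self.table["excluded"] != "none")]
        return flagged["excluded"].tolist()

    def to_dict(self) -> dict:
        return {"rows": self.table.to_dict(orient="records")}


def leave_one_out(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
) -> LeaveOneOutResult:
    """Fixed-effect IVW excluding each instrument in turn.

    An exclusion is flagged when the estimate changes sign or its
    p-value crosses 0.05 relative to the all-instrument fit.
    """
    rs = compute_ratios(instruments)
    if len(rs) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 complete instruments")
    items = (
        instruments.complete
        if isinstance(instruments, InstrumentSet)
        else [i for i in instruments if i.complete]
    )
    items = sorted(items, key=lambda i: i.snp_id)
    full = ivw(items)
    rows = []
    for excluded in items:
        subset = [i for i in items if i.snp_id != excluded.snp_id]
        est = ivw(subset)
        flagged = (
            np.sign(est.beta) != np.sign(full.beta)
            or (est.pval < 0.05) != (full.pval < 0.05)
        )
        rows.append(
            {
                "excluded": excluded.snp_id,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "n_snps": est.n_snps,
                "flagged": bool(flagged),
            }
        )
    rows.append(
        {
            "excluded": "none",
            "beta": full.beta,
            "se": full.se,
            "pval": full.pval,
            "n_snps": full.n_snps,
            "flagged": False,
        }
    )
    return LeaveOneOutResult(table=pd.DataFrame(rows))


def funnel_and_forest_data(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    method_estimates: Sequence[MrEstimate] = (),
) -> pd.DataFrame:
    """Plot-ready table for forest and funnel displays.

    One row per instrument (Wald ratio, SE, precision = 1/SE) followed
    by one row per supplied multi-SNP estimate.
    """
    items = (
        instruments.complete
        if isinstance(instruments, InstrumentSet)
        else [i for i in instruments if i.complete]
    )
    if not items:
        raise InsufficientInstrumentsError("need >= 1 complete instrument")
    items = sorted(items, key=lambda i: i.snp_id)
    rows = []
    for inst in items:
        est = wald_ratio(inst)
        rows.append(
            {
                "label": inst.snp_id,
                "kind": "single_snp",
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "precision": 1.0 / est.se,
            }
        )
    for est in method_estimates:
        rows.append(
            {
                "label": est.method,
                "kind": "method",
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "precision": 1.0 / est.se if est.se > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)
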