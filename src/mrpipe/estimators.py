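"""Causal-effect estimators for two-sample Mendelian randomization.

Every multi-SNP estimator combines per-instrument Wald ratios
r_i = beta_out_i / beta_exp_i in a different way:

* **IVW** — inverse-variance-weighted mean with first-order weights
  w_i = beta_exp_i² / se_out_i²; fixed-effect SE is (Σw)^(-1/2), the
  multiplicative-random-effects variant inflates it by
  max(1, sqrt(Q/(k-1))).
* **MR-Egger** — weighted least squares of outcome betas on exposure
  betas with a free intercept after orienting all exposure betas
  positive; a nonzero intercept indicates directional horizontal
  pleiotropy.  Inference is t-based with k-2 df and the residual
  scale is never shrunk below 1.
* **Weighted median** — the ratio at standardized cumulative weight
  0.5; consistent when at least half the weight comes from valid
  instruments.  SE by seeded parametric bootstrap.
* **Simple/weighted mode** — argmax of a normal-kernel-smoothed
  density of the ratios; consistent when the largest group of
  instruments sharing one ratio is valid.

Binary-outcome effects are reported both on the log-odds scale and as
odds ratios with Wald 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .summary_data import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MrEstimate",
    "RatioSet",
    "compute_ratios",
    "wald_ratio",
    "ivw",
    "ivw_standard_error",
    "egger",
    "weighted_median",
    "mode_estimate",
    "to_odds_scale",
    "InsufficientInstrumentsError",
]

Z95 = sps.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """Fewer usable instruments than the estimator requires."""


def to_odds_scale(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect and its Wald 95% bounds."""
    if not (se >= 0):
        raise ValueError("se must be non-negative")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z95 * se)),
        float(np.exp(beta + Z95 * se)),
    )


@dataclass(frozen=True)
class MrEstimate:
    """One estimator's causal effect with Wald interval and OR scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_: float
    or_low: float
    or_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "or": self.or_,
            "or_low": self.or_low,
            "or_high": self.or_high,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_pval=self.intercept_pval,
            )
        return d


def _finish(method: str, beta: float, se: float, n_snps: int,
            pval: float | None = None, **extra) -> MrEstimate:
    if pval is None:
        pval = 2 * sps.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    pval = float(min(max(pval, np.finfo(float).tiny), 1.0))
    or_, or_low, or_high = to_odds_scale(beta, se)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=pval,
        n_snps=n_snps,
        or_=or_,
        or_low=or_low,
        or_high=or_high,
        **extra,
    )


@dataclass(frozen=True)
class RatioSet:
    """Per-instrument Wald ratios with first-order SEs and IVW weights."""

    snp_ids: tuple[str, ...]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> np.ndarray:
        return self.se_out / np.abs(self.beta_exp)

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2

    def __len__(self) -> int:
        return len(self.snp_ids)


def compute_ratios(instruments: InstrumentSet | Sequence[HarmonizedInstrument]) -> RatioSet:
    """Extract complete instruments as aligned arrays, sorted by snp_id.

    The snp_id sort is a deterministic tie-break for rank-based
    estimators; IVW/Egger are order-invariant anyway.
    """
    items = instruments.complete if isinstance(instruments, InstrumentSet) else [
        i for i in instruments if i.complete
    ]
    items = sorted(items, key=lambda i: i.snp_id)
    bad = [i.snp_id for i in items if i.beta_exp == 0]
    if bad:
        raise ZeroDivisionError(f"beta_exp is zero for {bad}; Wald ratio undefined")
    return RatioSet(
        snp_ids=tuple(i.snp_id for i in items),
        beta_exp=np.array([i.beta_exp for i in items], dtype=float),
        se_exp=np.array([i.se_exp for i in items], dtype=float),
        beta_out=np.array([i.beta_out for i in items], dtype=float),
        se_out=np.array([i.se_out for i in items], dtype=float),
    )


def _require(rs: RatioSet, k: int, method: str) -> None:
    if len(rs) < k:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {k} complete instruments, got {len(rs)}"
        )


# ---------------------------------------------------------------------------
# Estimators


def wald_ratio(instrument: HarmonizedInstrument) -> MrEstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    if instrument.beta_exp == 0:
        raise ZeroDivisionError(f"{instrument.snp_id}: beta_exp is zero")
    if instrument.beta_out is None:
        raise ValueError(f"{instrument.snp_id}: outcome beta missing")
    beta = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return _finish("wald_ratio", beta, se, 1)


def _ivw_beta_se(beta_exp, se_exp, beta_out, se_out, effects_model="fixed"):
    """Core IVW computation on arrays; returns (beta, se, Q)."""
    w = beta_exp**2 / se_out**2
    r = beta_out / beta_exp
    beta = np.sum(w * r) / np.sum(w)
    se = np.sum(w) ** -0.5
    q = float(np.sum(w * (r - beta) ** 2))
    if effects_model == "multiplicative_random":
        k = len(w)
        if k > 1:
            se *= max(1.0, np.sqrt(q / (k - 1)))
    elif effects_model != "fixed":
        raise ValueError(f"unknown effects model {effects_model!r}")
    return float(beta), float(se), q


def ivw(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    effects_model: str = "fixed",
) -> MrEstimate:
    """Inverse-variance-weighted mean of the Wald ratios."""
    rs = compute_ratios(instruments)
    _require(rs, 2, "IVW")
    beta, se, _ = _ivw_beta_se(rs.beta_exp, rs.se_exp, rs.beta_out, rs.se_out, effects_model)
    method = "ivw_fixed" if effects_model == "fixed" else "ivw_mre"
    return _finish(method, beta, se, len(rs))


def ivw_standard_error(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
) -> float:
    """Fixed-effect IVW standard error (Σ beta_exp²/se_out²)^(-1/2).

    Needs only exposure betas and outcome SEs, so it is computable even
    when the outcome study's effect sizes are unavailable.
    """
    items = instruments.kept if isinstance(instruments, InstrumentSet) else [
        i for i in instruments if not i.dropped
    ]
    if len(items) < 2:
        raise InsufficientInstrumentsError("IVW SE needs >= 2 instruments")
    w = np.array([i.beta_exp**2 / i.se_out**2 for i in items])
    return float(np.sum(w) ** -0.5)


def egger(instruments: InstrumentSet | Sequence[HarmonizedInstrument]) -> MrEstimate:
    """MR-Egger weighted regression with a pleiotropy intercept.

    Instruments are oriented so every exposure beta is positive (the
    estimator is otherwise not invariant to allele coding); weights are
    1/se_out².  The residual scale is floored at 1 and p-values use a
    t distribution with k-2 df.
    """
    rs = compute_ratios(instruments)
    _require(rs, 3, "MR-Egger")
    sign = np.sign(rs.beta_exp)
    bx = rs.beta_exp * sign
    by = rs.beta_out * sign
    w = 1.0 / rs.se_out**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    # statsmodels scales the covariance by RSS/(k-2); floor that factor at 1
    inflate = max(1.0, fit.scale) / fit.scale
    bse = fit.bse * np.sqrt(inflate)
    k = len(rs)
    df = k - 2
    slope, slope_se = fit.params[1], bse[1]
    icpt, icpt_se = fit.params[0], bse[0]
    slope_p = 2 * sps.t.sf(abs(slope / slope_se), df)
    icpt_p = 2 * sps.t.sf(abs(icpt / icpt_se), df)
    return _finish(
        "egger",
        slope,
        slope_se,
        k,
        pval=float(slope_p),
        intercept=float(icpt),
        intercept_se=float(icpt_se),
        intercept_pval=float(icpt_p),
    )


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Ratio at standardized cumulative weight 0.5 (linear interpolation)."""
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weight[order]
    cum = (np.cumsum(w) - w / 2) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def weighted_median(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    rs = compute_ratios(instruments)
    _require(rs, 2, "weighted median")
    beta = _weighted_median_point(rs.ratio, rs.weight)
    se = _bootstrap_se(rs, n_boot, seed, _weighted_median_point)
    return _finish("weighted_median", beta, se, len(rs))


def _mode_point(ratio: np.ndarray, weight: np.ndarray, phi: float = 1.0) -> float:
    """Argmax of the weighted normal-kernel density of the ratios."""
    k = len(ratio)
    s = np.std(ratio, ddof=1) if k > 1 else 0.0
    m = sps.median_abs_deviation(ratio, scale="normal")
    h = phi * 0.9 * min(s, m) * k ** (-1 / 5)
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: the (weighted) modal value itself
        vals, idx = np.unique(ratio, return_inverse=True)
        mass = np.bincount(idx, weights=weight)
        return float(vals[np.argmax(mass)])
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
    dens = np.sum(
        weight[:, None] * sps.norm.pdf(grid[None, :], loc=ratio[:, None], scale=h),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    instruments: InstrumentSet | Sequence[HarmonizedInstrument],
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Mode-based estimator (simple or inverse-variance weighted)."""
    rs = compute_ratios(instruments)
    _require(rs, 3, "mode estimator")

    def point(ratio: np.ndarray, weight: np.ndarray) -> float:
        w = weight if weighted else np.ones_like(ratio)
        return _mode_point(ratio, w, phi)

    beta = point(rs.ratio, rs.weight)
    se = _bootstrap_se(rs, n_boot, seed, point)
    method = "weighted_mode" if weighted else "simple_mode"
    return _finish(method, beta, se, len(rs))


def _bootstrap_se(rs: RatioSet, n_boot: int, seed: int | None, point_fn) -> float:
    """Parametric bootstrap: redraw both betas from their sampling normals."""
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(rs.beta_exp, rs.se_exp)
        by = rng.normal(rs.beta_out, rs.se_out)
        nonzero = bx != 0
        ratio = by[nonzero] / bx[nonzero]
        weight = bx[nonzero] ** 2 / rs.se_out[nonzero] ** 2
        est[b] = point_fn(ratio, weight)
    return float(np.std(est, ddof=1))
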