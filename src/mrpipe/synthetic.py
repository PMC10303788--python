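"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws per-SNP allele frequencies and true exposure
effects sized to a target per-SNP variance explained, then produces
observed effect estimates for two non-overlapping studies under a
linear causal model

    gamma_i = theta * b_i + alpha_i

where ``theta`` is the causal effect and ``alpha_i`` an optional
horizontal-pleiotropy term (balanced when its mean is zero,
directional otherwise).  Planted outliers add a gross fixed offset so
outlier tests have a known answer.  Standard errors follow the
standardized-trait GWAS approximation se = (2 p (1-p) n)^(-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .summary_data import SummaryStat, write_summary_stats

__all__ = ["SyntheticConfig", "generate_two_sample", "paper_like_config"]

#: offset added to planted outliers, in units of the combined ratio SE
OUTLIER_OFFSET_SES = 10.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated two-sample dataset."""

    k: int = 10
    theta: float = 0.0
    n_exp: int = 50_000
    n_out: int = 50_000
    eaf_range: tuple[float, float] = (0.1, 0.9)
    exposure_h2_per_snp: float = 0.003
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not (0 <= self.n_outliers <= self.k):
            raise ValueError("n_outliers must be in [0, k]")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_range must satisfy 0 < lo < hi < 1")


def generate_two_sample(
    config: SyntheticConfig,
) -> tuple[list[SummaryStat], list[SummaryStat], dict]:
    """Simulate exposure and outcome summary statistics plus the truth record.

    Alleles are arbitrary (A/G throughout) and already aligned between
    the two studies — harmonization is a no-op on this output, which
    keeps the generator orthogonal to the allele-matching logic.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k

    eaf = rng.uniform(*config.eaf_range, size=k)
    var_factor = 2.0 * eaf * (1.0 - eaf)
    # size |b| so that 2 p (1-p) b^2 equals the target per-SNP h2
    b_true = np.sqrt(config.exposure_h2_per_snp / var_factor) * rng.choice(
        [-1.0, 1.0], size=k
    )
    se_exp = (var_factor * config.n_exp) ** -0.5
    se_out = (var_factor * config.n_out) ** -0.5

    has_pleio = rng.random(k) < config.pleiotropy_frac
    alpha = np.where(
        has_pleio,
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k),
        0.0,
    )
    # directional pleiotropy is defined on the exposure-increasing allele
    # (the orientation in which the Egger intercept is interpreted)
    gamma_true = config.theta * b_true + alpha * np.sign(b_true)

    outlier_idx = (
        rng.choice(k, size=config.n_outliers, replace=False)
        if config.n_outliers
        else np.array([], dtype=int)
    )
    if len(outlier_idx):
        # displace the implied ratio by a fixed number of combined SEs
        ratio_se = np.sqrt((se_out / np.abs(b_true)) ** 2)
        offset = OUTLIER_OFFSET_SES * ratio_se * np.abs(b_true)
        signs = rng.choice([-1.0, 1.0], size=len(outlier_idx))
        gamma_true = gamma_true.copy()
        gamma_true[outlier_idx] += signs * offset[outlier_idx]

    beta_exp = rng.normal(b_true, se_exp)
    beta_out = rng.normal(gamma_true, se_out)
    p_exp = 2 * sps.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2 * sps.norm.sf(np.abs(beta_out / se_out))
    tiny = np.finfo(float).tiny
    p_exp = np.clip(p_exp, tiny, 1.0)
    p_out = np.clip(p_out, tiny, 1.0)

    exposure, outcome = [], []
    for i in range(k):
        sid = f"rs{i + 1:06d}"
        exposure.append(
            SummaryStat(
                snp_id=sid, effect_allele="A", other_allele="G",
                eaf=float(eaf[i]), beta=float(beta_exp[i]), se=float(se_exp[i]),
                pval=float(p_exp[i]), n=config.n_exp,
                chrom="1", pos=(i + 1) * 1_000_000,
            )
        )
        outcome.append(
            SummaryStat(
                snp_id=sid, effect_allele="A", other_allele="G",
                eaf=float(eaf[i]), beta=float(beta_out[i]), se=float(se_out[i]),
                pval=float(p_out[i]), n=config.n_out,
                chrom="1", pos=(i + 1) * 1_000_000,
            )
        )

    truth = {
        "theta": config.theta,
        "eaf": eaf.tolist(),
        "beta_exp_true": b_true.tolist(),
        "beta_out_true": gamma_true.tolist(),
        "alpha": alpha.tolist(),
        "has_pleiotropy": has_pleio.tolist(),
        "outlier_snps": [f"rs{i + 1:06d}" for i in sorted(outlier_idx.tolist())],
        "seed": config.seed,
    }
    return exposure, outcome, truth


def paper_like_config(direction: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Config matching the packaged fixtures' scale.

    ``forward``: 5 cortisol-like instruments from a 12,597-person
    continuous-trait GWAS read against a 55,347-person case-control
    outcome.  ``reverse``: 7 ADHD-like instruments the other way
    round.  Per-SNP variance explained matches the fixtures (~0.5%
    and ~0.3% respectively).
    """
    if direction == "forward":
        base = dict(k=5, n_exp=12_597, n_out=55_347, exposure_h2_per_snp=0.005)
    elif direction == "reverse":
        base = dict(k=7, n_exp=55_347, n_out=12_597, exposure_h2_per_snp=0.003)
    else:
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    base.update(overrides)
    return SyntheticConfig(seed=seed, **base)


def write_dataset(
    exposure: Sequence[SummaryStat],
    outcome: Sequence[SummaryStat],
    truth: dict,
    outdir: str | Path,
) -> None:
    """Write exposure/outcome TSVs plus the truth record as JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary_stats(exposure, outdir / "exposure.tsv")
    write_summary_stats(outcome, outdir / "outcome.tsv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
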