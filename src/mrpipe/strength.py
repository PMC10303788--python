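"""Variance explained (R²) and instrument strength (F-statistics).

Two F conventions coexist in applied MR work and both are exposed
here.  The per-SNP F is the squared Wald z, (beta/se)², which is what
published instrument tables usually print.  The combined F for a set
of K instruments uses F = (N-K-1)/K x R²/(1-R²) with R² the summed
per-SNP variance explained 2·EAF·(1-EAF)·beta².  F > 10 is the
conventional weak-instrument cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .summary_data import SummaryStat

__all__ = [
    "StrengthReport",
    "snp_r2",
    "snp_f_stat",
    "combined_f_stat",
    "large_panel_r2",
    "strength_report",
    "WEAK_INSTRUMENT_F",
]

WEAK_INSTRUMENT_F = 10.0


def snp_r2(eaf: float, beta: float) -> float:
    """Per-SNP variance explained, 2·eaf·(1-eaf)·beta², for a standardized trait."""
    if not (0 < eaf < 1):
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def snp_f_stat(beta: float, se: float) -> float:
    """Per-SNP instrument strength: the squared Wald statistic (beta/se)²."""
    if not (se > 0):
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def combined_f_stat(r2: float, n: int, k: int) -> float:
    """Combined F over K instruments: (N-K-1)/K x R²/(1-R²)."""
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if not (n > k + 1 >= 2):
        raise ValueError(f"need n > k+1 >= 2, got n={n}, k={k}")
    return (n - k - 1) / k * r2 / (1.0 - r2)


def large_panel_r2(eaf: float, beta: float, se: float, n: int) -> float:
    """Variance-explained estimate suited to instrument panels beyond ~10 SNPs.

    Ratio form 2pq·beta² / (2pq·beta² + 2pq·n·se²), which reduces to
    beta²/(beta² + n·se²).
    """
    if not (0 < eaf < 1):
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    if not (se > 0 and n > 0):
        raise ValueError("se and n must be positive")
    num = snp_r2(eaf, beta)
    return num / (num + 2.0 * eaf * (1.0 - eaf) * n * se * se)


@dataclass
class StrengthReport:
    """Per-SNP and combined instrument-strength summary for one study."""

    per_snp: list[tuple[str, float, float]]  # (snp_id, r2, f_stat)
    combined_r2: float
    combined_f: float
    n: int
    k: int = field(default=0)

    def __post_init__(self) -> None:
        if self.k == 0:
            self.k = len(self.per_snp)
        if self.k != len(self.per_snp):
            raise ValueError("k must equal the number of per-SNP rows")

    @property
    def all_strong(self) -> bool:
        return all(f > WEAK_INSTRUMENT_F for _, _, f in self.per_snp)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp": sid, "r2": r2, "f_stat": f, "level": "per_snp"}
            for sid, r2, f in self.per_snp
        ]
        rows.append(
            {
                "snp": "combined",
                "r2": self.combined_r2,
                "f_stat": self.combined_f,
                "level": "combined",
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "per_snp": [
                {"snp": sid, "r2": r2, "f_stat": f} for sid, r2, f in self.per_snp
            ],
            "combined_r2": self.combined_r2,
            "combined_f": self.combined_f,
            "n": self.n,
            "k": self.k,
            "all_f_above_10": self.all_strong,
        }


def strength_report(stats: Sequence[SummaryStat], n: int | None = None) -> StrengthReport:
    """Build a :class:`StrengthReport` from exposure-study records.

    ``n`` defaults to the records' own sample size; per-SNP F uses the
    (beta/se)² convention and combined F the (N-K-1)/K formula.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("need at least one record")
    if n is None:
        sizes = {s.n for s in stats if s.n is not None}
        if len(sizes) != 1:
            raise ValueError("sample size n is ambiguous; pass it explicitly")
        n = sizes.pop()
    per_snp = []
    total_r2 = 0.0
    for s in stats:
        if s.beta is None or s.eaf is None:
            raise ValueError(f"{s.snp_id}: beta and eaf required for strength")
        r2 = snp_r2(s.eaf, s.beta)
        per_snp.append((s.snp_id, r2, snp_f_stat(s.beta, s.se)))
        total_r2 += r2
    k = len(per_snp)
    return StrengthReport(
        per_snp=per_snp,
        combined_r2=total_r2,
        combined_f=combined_f_stat(total_r2, n, k),
        n=n,
        k=k,
    )
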