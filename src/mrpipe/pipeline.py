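"""Bidirectional analysis driver and packaged example datasets.

A *direction* is one exposure→outcome analysis: select instruments,
harmonize alleles, assess instrument strength, run the five
estimators, then the heterogeneity, pleiotropy, outlier and
leave-one-out diagnostics.  ``run_bidirectional`` runs both causal
directions and states, per direction, whether the IVW estimate is
significant at two-sided 0.05.

Two fixture datasets — per-SNP instrument tables for morning plasma
cortisol (CORNET consortium, n = 12,597) and ADHD (PGC, n = 55,347) —
are packaged so the full pipeline runs without any download.  The
cortisol→ADHD table carries outcome SEs and p-values but no outcome
betas (its source prints none), so in that direction only SE-based
quantities are computed and point estimates are reported unavailable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import diagnostics, estimators
from .strength import StrengthReport, strength_report
from .summary_data import (
    InstrumentSet,
    SummaryStat,
    harmonize,
    read_summary_stats,
    select_instruments,
)

__all__ = [
    "AnalysisConfig",
    "DirectionReport",
    "run_direction",
    "run_bidirectional",
    "load_fixture",
    "FIXTURES",
]

logger = logging.getLogger("mrpipe")

FIXTURES = ("cortisol_to_adhd", "adhd_to_cortisol")

_FIXTURE_META = {
    "cortisol_to_adhd": {
        "exposure_name": "morning plasma cortisol",
        "outcome_name": "ADHD",
        "direction": "forward",
        "p_threshold": 5e-6,
    },
    "adhd_to_cortisol": {
        "exposure_name": "ADHD",
        "outcome_name": "morning plasma cortisol",
        "direction": "reverse",
        "p_threshold": 5e-8,
    },
}


def load_fixture(name: str) -> tuple[list[SummaryStat], list[SummaryStat]]:
    """Load a packaged instrument table pair (exposure stats, outcome stats)."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    pkg = resources.files("mrpipe") / "fixtures"
    with resources.as_file(pkg / f"{name}.exposure.tsv") as p:
        exposure = read_summary_stats(p)
    with resources.as_file(pkg / f"{name}.outcome.tsv") as p:
        outcome = read_summary_stats(p)
    return exposure, outcome


@dataclass
class AnalysisConfig:
    """Inputs and tuning for one direction of analysis."""

    exposure_path: str | Path | None = None
    outcome_path: str | Path | None = None
    fixture: str | None = None
    direction: str = "forward"
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    p_threshold: float = 5e-6
    effects_model: str = "fixed"
    eaf_window: float = 0.08
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    outdir: str | Path | None = None
    exposure_dialect: dict | None = None
    outcome_dialect: dict | None = None

    @classmethod
    def from_fixture(cls, name: str, seed: int = 0, **overrides) -> "AnalysisConfig":
        meta = _FIXTURE_META[name]
        kwargs = dict(fixture=name, seed=seed, **meta)
        kwargs.update(overrides)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class DirectionReport:
    """Everything one direction of the analysis produced."""

    config: AnalysisConfig
    instruments: InstrumentSet
    strength: StrengthReport
    estimates: list[estimators.MrEstimate]
    heterogeneity: diagnostics.HeterogeneityResult | None
    egger_intercept: tuple[float, float, float, str] | None
    presso: diagnostics.PressoResult | None
    loo: diagnostics.LeaveOneOutResult | None
    funnel: pd.DataFrame | None
    ivw_se: float
    notes: list[str] = field(default_factory=list)

    @property
    def ivw(self) -> estimators.MrEstimate | None:
        for e in self.estimates:
            if e.method.startswith("ivw"):
                return e
        return None

    @property
    def verdict(self) -> str:
        est = self.ivw
        if est is None:
            return "point estimates unavailable"
        return "causal (p<0.05)" if est.pval < 0.05 else "no evidence"

    def to_dict(self) -> dict:
        return {
            "direction": self.config.direction,
            "exposure": self.config.exposure_name,
            "outcome": self.config.outcome_name,
            "seed": self.config.seed,
            "strength": self.strength.to_dict(),
            "ivw_se": self.ivw_se,
            "estimates": [e.to_dict() for e in self.estimates],
            "heterogeneity": self.heterogeneity.to_dict() if self.heterogeneity else None,
            "egger_intercept": (
                dict(zip(("intercept", "se", "pval", "verdict"), self.egger_intercept))
                if self.egger_intercept
                else None
            ),
            "presso": self.presso.to_dict() if self.presso else None,
            "leave_one_out": self.loo.to_dict() if self.loo else None,
            "verdict": self.verdict,
            "notes": self.notes,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        if self.estimates:
            pd.DataFrame([e.to_dict() for e in self.estimates]).to_csv(
                outdir / "estimates.tsv", sep="\t", index=False
            )
        self.instruments.to_frame().to_csv(
            outdir / "harmonization.tsv", sep="\t", index=False
        )
        self.strength.to_frame().to_csv(outdir / "strength.tsv", sep="\t", index=False)
        if self.loo is not None:
            self.loo.table.to_csv(outdir / "loo.tsv", sep="\t", index=False)
        if self.funnel is not None:
            self.funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)


def _load_inputs(config: AnalysisConfig) -> tuple[list[SummaryStat], list[SummaryStat]]:
    if config.fixture:
        return load_fixture(config.fixture)
    if config.exposure_path is None or config.outcome_path is None:
        raise ValueError("either fixture or both exposure_path and outcome_path required")
    return (
        read_summary_stats(config.exposure_path, config.exposure_dialect),
        read_summary_stats(config.outcome_path, config.outcome_dialect),
    )


def run_direction(config: AnalysisConfig) -> DirectionReport:
    """Execute select → harmonize → strength → estimators → diagnostics."""
    t0 = time.perf_counter()
    exposure, outcome = _load_inputs(config)
    logger.info("loaded %d exposure / %d outcome records", len(exposure), len(outcome))

    selected = select_instruments(exposure, p_threshold=config.p_threshold)
    if len(selected) < 2:
        raise ValueError(
            f"only {len(selected)} instrument(s) pass p < {config.p_threshold}"
        )
    iset = harmonize(
        selected,
        outcome,
        eaf_window=config.eaf_window,
        exposure_name=config.exposure_name,
        outcome_name=config.outcome_name,
        direction=config.direction,
    )
    logger.info(
        "harmonized %d instruments (%d kept)", len(iset), len(iset.kept)
    )

    strength = strength_report(
        [s for s in selected if s.snp_id in {i.snp_id for i in iset.kept}]
    )
    ivw_se = estimators.ivw_standard_error(iset)

    notes: list[str] = []
    complete = iset.complete
    estimates: list[estimators.MrEstimate] = []
    het = icpt = presso = loo = funnel = None

    if len(complete) >= 2:
        estimates.append(estimators.ivw(iset, effects_model=config.effects_model))
        estimates.append(
            estimators.weighted_median(iset, n_boot=config.n_boot, seed=config.seed)
        )
        het = diagnostics.cochran_q(iset)
    if len(complete) >= 3:
        estimates.insert(1, estimators.egger(iset))
        estimates.append(
            estimators.mode_estimate(
                iset, weighted=False, n_boot=config.n_boot, seed=config.seed
            )
        )
        estimates.append(
            estimators.mode_estimate(
                iset, weighted=True, n_boot=config.n_boot, seed=config.seed
            )
        )
        icpt = diagnostics.egger_intercept_test(iset)
        presso = diagnostics.mr_presso(
            iset, n_sim=config.n_sim, seed=config.seed
        )
        loo = diagnostics.leave_one_out(iset)
        funnel = diagnostics.funnel_and_forest_data(iset, estimates)
    if not complete:
        notes.append(
            "outcome effect sizes missing: point estimates not computable; "
            "reporting SE-based quantities only"
        )
        logger.warning(notes[-1])

    report = DirectionReport(
        config=config,
        instruments=iset,
        strength=strength,
        estimates=estimates,
        heterogeneity=het,
        egger_intercept=icpt,
        presso=presso,
        loo=loo,
        funnel=funnel,
        ivw_se=ivw_se,
        notes=notes,
    )
    if config.outdir:
        report.write(config.outdir)
    logger.info(
        "direction %s finished in %.2f s", config.direction, time.perf_counter() - t0
    )
    return report


def run_bidirectional(
    forward: AnalysisConfig, reverse: AnalysisConfig
) -> dict:
    """Run both causal directions and summarize the IVW verdicts."""
    fwd = run_direction(forward)
    rev = run_direction(reverse)
    return {
        "forward": fwd,
        "reverse": rev,
        "summary": {
            "forward": {
                "exposure": forward.exposure_name,
                "outcome": forward.outcome_name,
                "verdict": fwd.verdict,
            },
            "reverse": {
                "exposure": reverse.exposure_name,
                "outcome": reverse.outcome_name,
                "verdict": rev.verdict,
            },
        },
    }
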