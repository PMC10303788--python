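"""GWAS summary-statistic records, file I/O, allele harmonization and
instrument selection.

The two-sample design combines per-SNP association estimates from an
exposure study and an outcome study.  Before any estimation the two
tables must be aligned so that both effect sizes refer to the same
effect allele ("harmonization"): swapped alleles flip the outcome beta,
strand flips are resolved by complementing, and palindromic variants
(A/T or C/G) whose allele frequency is uninformative are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStat",
    "HarmonizedInstrument",
    "InstrumentSet",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "select_instruments",
    "ConfigError",
    "ParseError",
    "HarmonizationError",
]

#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

MANDATORY_COLUMNS = ("snp", "effect_allele", "other_allele", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigError(ValueError):
    """Bad configuration: missing mandatory column, bad dialect, bad LD matrix."""


class ParseError(ValueError):
    """A data row could not be parsed or violates a record invariant."""


class HarmonizationError(ValueError):
    """Exposure and outcome studies share no usable instruments."""


@dataclass(frozen=True)
class SummaryStat:
    """One SNP's association record from a single GWAS.

    ``beta`` is on the study's native scale (SD units for a continuous
    trait, log-odds for a case-control trait) and may be missing when a
    source table prints only SE and p.  ``eaf`` is the effect-allele
    frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    se: float
    pval: float
    beta: float | None = None
    eaf: float | None = None
    n: int | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ParseError("snp_id must be non-empty")
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea == oa:
            raise ParseError(f"{self.snp_id}: effect and other allele identical ({ea})")
        if not (self.se > 0):
            raise ParseError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ParseError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ParseError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned SNP sharing one effect allele.

    Alleles are reported as oriented to the exposure study.
    ``action_taken`` records what harmonization did; records with a
    ``dropped_*`` action are retained for reporting but excluded from
    estimation.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    se_out: float
    beta_out: float | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    pval_exp: float | None = None
    pval_out: float | None = None
    palindromic: bool = False
    ambiguous: bool = False
    action_taken: str = "kept"

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ParseError(f"{self.snp_id}: standard errors must be positive")
        if self.ambiguous and not self.palindromic:
            raise ParseError(f"{self.snp_id}: ambiguous implies palindromic")
        valid = {"kept", "sign_flipped", "dropped_ambiguous", "dropped_unmatched"}
        if self.action_taken not in valid:
            raise ParseError(f"{self.snp_id}: unknown action {self.action_taken!r}")

    @property
    def dropped(self) -> bool:
        return self.action_taken.startswith("dropped")

    @property
    def complete(self) -> bool:
        """True when both effect sizes are present (usable for point estimation)."""
        return not self.dropped and self.beta_out is not None


@dataclass
class InstrumentSet:
    """An ordered collection of harmonized instruments for one direction."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument]
    direction: str = "forward"

    def __post_init__(self) -> None:
        ids = [i.snp_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            raise ParseError("duplicate snp_ids in instrument set")

    @property
    def kept(self) -> list[HarmonizedInstrument]:
        return [i for i in self.instruments if not i.dropped]

    @property
    def complete(self) -> list[HarmonizedInstrument]:
        return [i for i in self.instruments if i.complete]

    def __len__(self) -> int:
        return len(self.instruments)

    def subset(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        wanted = set(snp_ids)
        return InstrumentSet(
            self.exposure_name,
            self.outcome_name,
            [i for i in self.instruments if i.snp_id in wanted],
            self.direction,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": i.snp_id,
                "effect_allele": i.effect_allele,
                "other_allele": i.other_allele,
                "beta_exp": i.beta_exp,
                "se_exp": i.se_exp,
                "beta_out": i.beta_out,
                "se_out": i.se_out,
                "eaf_exp": i.eaf_exp,
                "eaf_out": i.eaf_out,
                "palindromic": i.palindromic,
                "ambiguous": i.ambiguous,
                "action_taken": i.action_taken,
            }
            for i in self.instruments
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def _column_map(columns: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Resolve canonical name -> file column name, honouring a rename map."""
    dialect = dict(dialect or {})
    resolved: dict[str, str] = {}
    lower = {c.lower(): c for c in columns}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in columns:
            resolved[canon] = src
        elif src.lower() in lower:
            resolved[canon] = lower[src.lower()]
    missing = [c for c in MANDATORY_COLUMNS if c not in resolved]
    if missing:
        raise ConfigError(
            f"mandatory column(s) {missing} not found in header {list(columns)}; "
            "use a dialect mapping to rename"
        )
    return resolved


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SummaryStat]:
    """Read a tab- or comma-separated summary-statistic table.

    ``dialect`` maps canonical column names (``snp``, ``beta``, ...) to
    the names used in the file.  Missing cells become missing values,
    never zero; row order is preserved.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = _column_map(df.columns, dialect)

    def _get(row: pd.Series, canon: str) -> str | None:
        if canon not in cols:
            return None
        raw = row[cols[canon]]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        raw = str(raw).strip()
        return raw or None

    def _num(row: pd.Series, canon: str, idx: int) -> float | None:
        raw = _get(row, canon)
        if raw is None:
            return None
        try:
            return float(raw.replace("−", "-"))  # tolerate unicode minus
        except ValueError as exc:
            raise ParseError(f"row {idx}: non-numeric {canon} value {raw!r}") from exc

    records: list[SummaryStat] = []
    for idx, row in df.iterrows():
        se = _num(row, "se", idx)
        pval = _num(row, "pval", idx)
        if se is None or pval is None:
            raise ParseError(f"row {idx}: se and pval are mandatory")
        n = _num(row, "n", idx)
        pos = _num(row, "pos", idx)
        try:
            records.append(
                SummaryStat(
                    snp_id=_get(row, "snp") or "",
                    effect_allele=_get(row, "effect_allele") or "",
                    other_allele=_get(row, "other_allele") or "",
                    eaf=_num(row, "eaf", idx),
                    beta=_num(row, "beta", idx),
                    se=se,
                    pval=pval,
                    n=int(n) if n is not None else None,
                    chrom=_get(row, "chr"),
                    pos=int(pos) if pos is not None else None,
                )
            )
        except ParseError as exc:
            raise ParseError(f"row {idx}: {exc}") from exc
    return records


def write_summary_stats(stats: Iterable[SummaryStat], path: str | Path) -> None:
    """Write records as a canonical tab-separated table."""
    rows = []
    for s in stats:
        rows.append(
            {
                "snp": s.snp_id,
                "chr": s.chrom,
                "pos": s.pos,
                "effect_allele": s.effect_allele,
                "other_allele": s.other_allele,
                "eaf": s.eaf,
                "beta": s.beta,
                "se": s.se,
                "pval": s.pval,
                "n": s.n,
            }
        )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


def _alleles_match(ea_e: str, oa_e: str, ea_o: str, oa_o: str) -> str | None:
    """Return 'same', 'swapped' or None for an outcome allele pair."""
    if (ea_o, oa_o) == (ea_e, oa_e):
        return "same"
    if (ea_o, oa_o) == (oa_e, ea_e):
        return "swapped"
    return None


def _complement(allele: str) -> str | None:
    if all(b in _COMPLEMENT for b in allele):
        return "".join(_COMPLEMENT[b] for b in allele)
    return None


def harmonize(
    exposure: Sequence[SummaryStat],
    outcome: Sequence[SummaryStat],
    eaf_window: float = 0.08,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    direction: str = "forward",
) -> InstrumentSet:
    """Align outcome records to the exposure study's effect alleles.

    For each SNP present in both studies: identical allele pairs are
    kept; swapped pairs flip the outcome beta sign and replace eaf with
    1-eaf; non-palindromic pairs are additionally tried on the
    complementary strand; anything else is marked ``dropped_unmatched``.
    Palindromic SNPs whose frequency is missing on either side or lies
    within ``eaf_window`` of 0.5 on both sides cannot be oriented and
    are marked ``dropped_ambiguous``.
    """
    if not exposure or not outcome:
        raise HarmonizationError("exposure and outcome lists must be nonempty")
    out_by_id = {s.snp_id: s for s in outcome}
    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        palindromic = exp.is_palindromic
        match = _alleles_match(
            exp.effect_allele, exp.other_allele, out.effect_allele, out.other_allele
        )
        if match is None and not palindromic:
            # strand flip: try the complemented outcome alleles
            cea, coa = _complement(out.effect_allele), _complement(out.other_allele)
            if cea is not None and coa is not None:
                match = _alleles_match(exp.effect_allele, exp.other_allele, cea, coa)

        beta_out = out.beta
        eaf_out = out.eaf
        if match == "swapped":
            beta_out = -beta_out if beta_out is not None else None
            eaf_out = 1 - eaf_out if eaf_out is not None else None
            action = "sign_flipped"
        elif match == "same":
            action = "kept"
        else:
            action = "dropped_unmatched"

        ambiguous = False
        if palindromic and action != "dropped_unmatched":
            if exp.eaf is None or eaf_out is None:
                ambiguous = True
            elif abs(exp.eaf - 0.5) <= eaf_window and abs(eaf_out - 0.5) <= eaf_window:
                ambiguous = True
            if ambiguous:
                action = "dropped_ambiguous"

        instruments.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                pval_exp=exp.pval,
                pval_out=out.pval,
                palindromic=palindromic,
                ambiguous=ambiguous,
                action_taken=action,
            )
        )
    if not instruments:
        raise HarmonizationError("no overlapping instruments between the two studies")
    return InstrumentSet(exposure_name, outcome_name, instruments, direction)


# ---------------------------------------------------------------------------
# Instrument selection


def select_instruments(
    stats: Sequence[SummaryStat],
    p_threshold: float = 5e-6,
    ld: np.ndarray | None = None,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
) -> list[SummaryStat]:
    """Keep strongly and independently associated variants.

    Records with ``pval < p_threshold`` survive.  When a pairwise r²
    matrix is supplied (rows/columns in ``stats`` order), a greedy
    pruning pass repeatedly keeps the smallest-p survivor and discards
    every record within ``window_kb`` kilobases on the same chromosome
    whose r² with a kept record reaches ``r2_threshold``.  Without an
    LD matrix the instruments are assumed pre-clumped.
    """
    stats = list(stats)
    if ld is not None:
        ld = np.asarray(ld, dtype=float)
        if ld.shape != (len(stats), len(stats)):
            raise ConfigError(
                f"LD matrix shape {ld.shape} does not match {len(stats)} records"
            )

    passing = [i for i, s in enumerate(stats) if s.pval < p_threshold]
    if ld is None:
        return [stats[i] for i in passing]

    def _in_window(a: SummaryStat, b: SummaryStat) -> bool:
        if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
            return True  # unknown coordinates: be conservative, prune on r2 alone
        if a.chrom != b.chrom:
            return False
        return abs(a.pos - b.pos) <= window_kb * 1000

    remaining = sorted(passing, key=lambda i: (stats[i].pval, stats[i].snp_id))
    kept: list[int] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            j
            for j in remaining
            if not (ld[best, j] >= r2_threshold and _in_window(stats[best], stats[j]))
        ]
    kept_set = set(kept)
    return [s for i, s in enumerate(stats) if i in kept_set]
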