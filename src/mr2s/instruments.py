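"""Instrument selection: genome-wide significance, LD clumping, F-statistics.

Instruments are SNPs strongly associated with the exposure (p < 5e-8 by
default), pruned to approximate linkage-equilibrium by greedy clumping
(r² < 0.01 within a 1000 kb window by default). Instrument strength is
summarized by the per-SNP F-statistic (β/σ)²; F > 10 is the conventional
bar below which weak-instrument bias is a concern.

LD is taken as explicit input (a pairwise r² table); pairs absent from the
table are treated as unlinked (r² = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ConfigurationError, InsufficientInstrumentsError, ValidationError
from .io import SummaryStatsTable, VariantAssociation

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class SelectionParams:
    """Instrument-selection criteria.

    Defaults mirror the standard extraction criterion for two-sample MR:
    p < 5e-8, r² < 0.01 within 1000 kb, and at least three instruments.
    """

    p_threshold: float = 5e-8
    r2_max: float = 0.01
    window_kb: float = 1000.0
    min_instruments: int = 3

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if not (0 <= self.r2_max <= 1):
            raise ConfigurationError("r2_max must be in [0, 1]")
        if self.window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")
        if self.min_instruments < 1:
            raise ConfigurationError("min_instruments must be >= 1")


class LdMatrix:
    """Sparse symmetric pairwise r² store keyed by unordered rsid pairs.

    Self-pairs are 1 by definition; absent pairs are unlinked (r² = 0).
    """

    def __init__(self):
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0 <= r2 <= 1):
            raise ValidationError(f"r² must be in [0, 1], got {r2} for ({a}, {b})")
        if a == b:
            return  # self-pair fixed at 1
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def pairs(self):
        return self._r2.items()

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path) -> "LdMatrix":
        """Read a three-column TSV (rsid_a, rsid_b, r2)."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            raise ConfigurationError("LD table needs columns rsid_a, rsid_b, r2")
        ld = cls()
        for a, b, r2 in df.itertuples(index=False):
            ld.set(str(a), str(b), float(r2))
        return ld

    def to_tsv(self, path) -> None:
        rows = sorted(self._r2.items())
        pd.DataFrame(
            [(a, b, r2) for (a, b), r2 in rows],
            columns=["rsid_a", "rsid_b", "r2"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP and mean F-statistics."""

    table: SummaryStatsTable
    params: SelectionParams
    f_per_snp: dict[str, float] = field(default_factory=dict)

    @property
    def mean_f(self) -> float:
        return sum(self.f_per_snp.values()) / len(self.f_per_snp)

    @property
    def weak(self) -> list[str]:
        """rsids whose F-statistic does not clear the conventional bar of 10."""
        return [r for r, f in self.f_per_snp.items() if f <= WEAK_F_THRESHOLD]

    def __len__(self) -> int:
        return len(self.table)


def select_genomewide(
    table: SummaryStatsTable, params: SelectionParams = SelectionParams()
) -> SummaryStatsTable:
    """Keep exactly the records with p strictly below the threshold, in order."""
    return SummaryStatsTable(
        study_label=table.study_label,
        trait=table.trait,
        records=[r for r in table.records if r.pval < params.p_threshold],
    )


def clump(
    table: SummaryStatsTable,
    ld: Optional[LdMatrix] = None,
    params: SelectionParams = SelectionParams(),
) -> SummaryStatsTable:
    """Greedy LD clumping.

    Repeatedly takes the smallest-p remaining SNP as an index SNP and
    discards every remaining SNP on the same chromosome within
    ``window_kb`` whose r² with the index is >= ``r2_max``. Ties in p are
    broken by rsid so the result is independent of input row order. The
    output is the index SNPs sorted by p ascending.
    """
    if ld is None:
        ld = LdMatrix()
    for rec in table.records:
        if rec.pos is None:
            raise ValidationError(f"record {rec.rsid} has no position; cannot clump")
    window_bp = params.window_kb * 1000.0
    remaining = sorted(table.records, key=lambda r: (r.pval, r.rsid))
    kept: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.r2(index.rsid, r.rsid) >= params.r2_max
            )
        ]
    return SummaryStatsTable(
        study_label=table.study_label, trait=table.trait, records=kept
    )


def compute_f(record: VariantAssociation) -> float:
    """Per-SNP F-statistic: the squared Wald z, (β/σ)²."""
    return (record.beta / record.se) ** 2


def build_instrument_set(
    table: SummaryStatsTable,
    ld: Optional[LdMatrix] = None,
    params: SelectionParams = SelectionParams(),
) -> InstrumentSet:
    """Significance filter, clump, and per-SNP F; errors if too few survive."""
    selected = select_genomewide(table, params)
    clumped = clump(selected, ld, params)
    if len(clumped) < params.min_instruments:
        raise InsufficientInstrumentsError(
            len(clumped), params.min_instruments, context=table.trait or "exposure"
        )
    f_per_snp = {r.rsid: compute_f(r) for r in clumped.records}
    return InstrumentSet(table=clumped, params=params, f_per_snp=f_per_snp)
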