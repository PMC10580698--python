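"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR requires the SNP-outcome effect to be expressed for the same
effect allele as the SNP-exposure effect. Per SNP this may require swapping
the outcome's allele labels (negating its beta), complementing its strand
(A<->T, C<->G), or both. Palindromic SNPs (A/T or C/G) are strand-ambiguous:
they can only be oriented through the effect-allele frequency, and when that
frequency is intermediate (within a symmetric band around 0.5, or missing)
the SNP is excluded as unresolvable.

The harmonized accounting is exact: every instrument rsid ends up either in
the harmonized pairs or in the exclusion log (absent_in_outcome,
palindromic_intermediate_af, allele_mismatch), never both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .instruments import InstrumentSet
from .io import SummaryStatsTable, VariantAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_AF_BAND = (0.42, 0.58)

ACTIONS = ("none", "swap", "strand_flip", "swap_and_flip")

REASON_ABSENT = "absent_in_outcome"
REASON_PALINDROMIC = "palindromic_intermediate_af"
REASON_MISMATCH = "allele_mismatch"


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-complementary ({A,T} or {C,G})."""
    return COMPLEMENT[a1] == a2


def is_intermediate_af(eaf: Optional[float], band=DEFAULT_AF_BAND) -> bool:
    """True if the frequency is missing or inside the intermediate band.

    A missing frequency is conservatively intermediate: a palindrome
    without frequency information cannot be oriented.
    """
    _check_band(band)
    if eaf is None:
        return True
    return band[0] <= eaf <= band[1]


def _check_band(band) -> None:
    lo, hi = band
    if not (0 <= lo <= hi <= 1):
        raise ValidationError(f"AF band {band} not within [0, 1]")
    if abs((lo + hi) / 2 - 0.5) > 1e-9:
        raise ValidationError(f"AF band {band} must be symmetric about 0.5")


@dataclass
class HarmonizedPair:
    """Per-SNP aligned effects: exposure (gamma, se_x), outcome (Gamma, se_y).

    ``action`` records what was done to the outcome record to express its
    effect for the exposure's effect allele.
    """

    rsid: str
    gamma: float
    se_x: float
    Gamma: float
    se_y: float
    eaf_x: Optional[float] = None
    eaf_y: Optional[float] = None
    action: str = "none"


@dataclass
class HarmonizedSet:
    """Harmonized pairs plus the per-rsid exclusion log.

    ``pairs`` and ``exclusions`` partition the input instruments.
    """

    pairs: list[HarmonizedPair] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.pairs]

    @property
    def gamma(self) -> np.ndarray:
        return np.array([p.gamma for p in self.pairs])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([p.se_x for p in self.pairs])

    @property
    def Gamma(self) -> np.ndarray:
        return np.array([p.Gamma for p in self.pairs])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([p.se_y for p in self.pairs])

    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.exclusions:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        """New set restricted to pair positions ``keep`` (exclusions dropped)."""
        return HarmonizedSet(pairs=[self.pairs[i] for i in keep])

    @classmethod
    def from_arrays(
        cls,
        gamma,
        se_x,
        Gamma,
        se_y,
        rsids: Optional[Sequence[str]] = None,
    ) -> "HarmonizedSet":
        """Build a set directly from effect arrays (simulation fast path)."""
        gamma = np.asarray(gamma, dtype=float)
        if rsids is None:
            rsids = [f"snp{i + 1}" for i in range(gamma.size)]
        pairs = [
            HarmonizedPair(rsid=r, gamma=float(g), se_x=float(sx),
                           Gamma=float(G), se_y=float(sy))
            for r, g, sx, G, sy in zip(rsids, gamma, np.asarray(se_x, float),
                                       np.asarray(Gamma, float), np.asarray(se_y, float))
        ]
        return cls(pairs=pairs)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["rsid", "reason"])


def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    band=DEFAULT_AF_BAND,
) -> tuple[Optional[HarmonizedPair], Optional[str]]:
    """Align one outcome record to the exposure's effect allele.

    Returns ``(pair, None)`` on success or ``(None, reason)`` when the SNP
    must be excluded (palindromic with intermediate/missing frequency, or
    irreconcilable alleles).
    """
    if exp.rsid != out.rsid:
        raise ValidationError(f"rsid mismatch: {exp.rsid} vs {out.rsid}")
    _check_band(band)

    ea_x, oa_x = exp.effect_allele, exp.other_allele
    ea_y, oa_y = out.effect_allele, out.other_allele
    Gamma, eaf_y = out.beta, out.eaf

    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return None, REASON_MISMATCH
        if is_intermediate_af(exp.eaf, band) or is_intermediate_af(eaf_y, band):
            return None, REASON_PALINDROMIC
        swapped = ea_y != ea_x
        if swapped:
            Gamma = -Gamma
            eaf_y = 1.0 - eaf_y
        # strand ambiguity resolved by minor/major agreement
        flipped = (exp.eaf < 0.5) != (eaf_y < 0.5)
        if flipped:
            Gamma = -Gamma
            eaf_y = 1.0 - eaf_y
        action = {
            (False, False): "none",
            (True, False): "swap",
            (False, True): "strand_flip",
            (True, True): "swap_and_flip",
        }[(swapped, flipped)]
    else:
        cea_y, coa_y = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        if (ea_y, oa_y) == (ea_x, oa_x):
            action = "none"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            action = "swap"
            Gamma = -Gamma
            eaf_y = None if eaf_y is None else 1.0 - eaf_y
        elif (cea_y, coa_y) == (ea_x, oa_x):
            action = "strand_flip"
        elif (cea_y, coa_y) == (oa_x, ea_x):
            action = "swap_and_flip"
            Gamma = -Gamma
            eaf_y = None if eaf_y is None else 1.0 - eaf_y
        else:
            return None, REASON_MISMATCH

    return (
        HarmonizedPair(
            rsid=exp.rsid,
            gamma=exp.beta,
            se_x=exp.se,
            Gamma=Gamma,
            se_y=out.se,
            eaf_x=exp.eaf,
            eaf_y=eaf_y,
            action=action,
        ),
        None,
    )


def harmonize_tables(
    instruments: Union[InstrumentSet, SummaryStatsTable],
    outcome: SummaryStatsTable,
    band=DEFAULT_AF_BAND,
) -> HarmonizedSet:
    """Harmonize every instrument against the outcome table.

    Instruments absent from the outcome are logged ``absent_in_outcome``;
    the remainder go through :func:`harmonize_pair`. The pairs and the
    exclusion log together account for every instrument exactly once.
    """
    table = instruments.table if isinstance(instruments, InstrumentSet) else instruments
    outcome_index = {r.rsid: r for r in outcome.records}
    hset = HarmonizedSet()
    for exp_rec in table.records:
        out_rec = outcome_index.get(exp_rec.rsid)
        if out_rec is None:
            hset.exclusions.append((exp_rec.rsid, REASON_ABSENT))
            continue
        pair, reason = harmonize_pair(exp_rec, out_rec, band)
        if pair is None:
            hset.exclusions.append((exp_rec.rsid, reason))
        else:
            hset.pairs.append(pair)
    return hset
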