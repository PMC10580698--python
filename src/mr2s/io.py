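"""Reading, validating and writing GWAS summary-statistics tables.

One row of a summary-statistics table is a :class:`VariantAssociation`: the
per-allele association of a single SNP with one trait in one study, on the
log-odds scale for case/control traits. Tables are tab-separated text with a
header; ``NA`` marks missing values; gzip-compressed input is accepted
transparently.

The default column dialect follows the common GWAS convention
(``SNP CHR BP EA OA EAF BETA SE P N``); a ``column_map`` adapts consortium
header variants (FinnGen, IIBDGC, ...) to the standard field names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

VALID_ALLELES = frozenset("ACGT")

#: standard field -> default column header
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

MANDATORY_FIELDS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)
OPTIONAL_FIELDS = ("eaf", "n")


@dataclass
class VariantAssociation:
    """Summary association of one SNP with one trait in one study.

    ``beta`` is the per-effect-allele effect on the log-odds scale; ``eaf``
    is the effect-allele frequency and may be missing (``None``); ``pos`` is
    1-based.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: Optional[int] = None


def validate_record(rec: VariantAssociation) -> list[str]:
    """Return the list of invariant violations for one record (empty if valid)."""
    issues: list[str] = []
    if rec.effect_allele not in VALID_ALLELES:
        issues.append(f"invalid effect allele {rec.effect_allele!r}")
    if rec.other_allele not in VALID_ALLELES:
        issues.append(f"invalid other allele {rec.other_allele!r}")
    if rec.effect_allele == rec.other_allele:
        issues.append("effect allele equals other allele")
    if not (isinstance(rec.pos, int) or float(rec.pos).is_integer()) or rec.pos < 1:
        issues.append("nonpositive or non-integer position")
    if not math.isfinite(rec.beta):
        issues.append("non-finite beta")
    if not (math.isfinite(rec.se) and rec.se > 0):
        issues.append("nonpositive se")
    if not (math.isfinite(rec.pval) and 0 < rec.pval <= 1):
        issues.append("p-value outside (0, 1]")
    if rec.eaf is not None and not (0 <= rec.eaf <= 1):
        issues.append("eaf outside [0, 1]")
    if rec.n is not None and rec.n < 1:
        issues.append("nonpositive sample size")
    return issues


@dataclass
class SummaryStatsTable:
    """Ordered collection of :class:`VariantAssociation` for one study/trait.

    rsids are unique within a table. ``reject_log`` records rows dropped at
    read time as ``(rsid, reason)``; it does not participate in equality.
    """

    study_label: str = ""
    trait: str = ""
    records: list[VariantAssociation] = field(default_factory=list)
    reject_log: list[tuple[str, str]] = field(default_factory=list, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> Optional[VariantAssociation]:
        return self._index().get(rsid)

    def _index(self) -> dict[str, VariantAssociation]:
        return {r.rsid: r for r in self.records}

    def subset(self, rsids: Iterable[str]) -> "SummaryStatsTable":
        """New table restricted to ``rsids``, preserving original row order."""
        keep = set(rsids)
        return SummaryStatsTable(
            study_label=self.study_label,
            trait=self.trait,
            records=[r for r in self.records if r.rsid in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = DEFAULT_COLUMN_MAP
        return pd.DataFrame(
            {
                cols["rsid"]: [r.rsid for r in self.records],
                cols["chrom"]: [r.chrom for r in self.records],
                cols["pos"]: pd.array([r.pos for r in self.records], dtype="Int64"),
                cols["effect_allele"]: [r.effect_allele for r in self.records],
                cols["other_allele"]: [r.other_allele for r in self.records],
                cols["eaf"]: [r.eaf for r in self.records],
                cols["beta"]: [r.beta for r in self.records],
                cols["se"]: [r.se for r in self.records],
                cols["pval"]: [r.pval for r in self.records],
                cols["n"]: pd.array([r.n for r in self.records], dtype="Int64"),
            }
        )


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata (consortium, trait, case/control counts, ancestry)."""

    consortium: str
    trait: str
    cases: Optional[int] = None
    controls: Optional[int] = None
    sample_size: Optional[int] = None
    ancestry: str = ""

    def __post_init__(self):
        if (
            self.cases is not None
            and self.controls is not None
            and self.sample_size is not None
            and self.cases + self.controls != self.sample_size
        ):
            raise ValidationError(
                f"cases ({self.cases}) + controls ({self.controls}) "
                f"!= sample size ({self.sample_size})"
            )


def _parse_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_summary_stats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    study_label: str = "",
    trait: str = "",
) -> SummaryStatsTable:
    """Read a tab-separated summary-statistics file into a validated table.

    Rows violating record invariants are dropped and logged in the returned
    table's ``reject_log``; alleles are upper-cased before validation.

    Raises
    ------
    ConfigurationError
        if a mandatory mapped column is absent from the header.
    ValidationError
        if two retained rows share an rsid.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True,
                     compression="infer", dtype={cmap["rsid"]: str, cmap["chrom"]: str})

    for fieldname in MANDATORY_FIELDS:
        if cmap[fieldname] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[fieldname]!r} (field {fieldname!r}) "
                f"missing from {path}"
            )
    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns

    table = SummaryStatsTable(study_label=study_label, trait=trait)
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        row = row._asdict()
        rsid = str(row[cmap["rsid"]])
        try:
            n_val = _parse_float(row[cmap["n"]]) if has_n else None
            rec = VariantAssociation(
                rsid=rsid,
                chrom=str(row[cmap["chrom"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                eaf=_parse_float(row[cmap["eaf"]]) if has_eaf else None,
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["pval"]]),
                n=int(n_val) if n_val is not None else None,
            )
        except (TypeError, ValueError) as exc:
            table.reject_log.append((rsid, f"unparseable row: {exc}"))
            continue
        issues = validate_record(rec)
        if issues:
            table.reject_log.append((rsid, "; ".join(issues)))
            continue
        if rsid in seen:
            raise ValidationError(f"duplicate rsid {rsid!r} in {path}")
        seen.add(rsid)
        table.records.append(rec)
    return table


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table as tab-separated text with ``NA`` for missing values.

    ``read_summary_stats(write_summary_stats(t))`` reproduces ``t``
    field-for-field (floats are written at full precision).
    """
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format=lambda x: repr(float(x)))


def validate_table(table: SummaryStatsTable) -> list[tuple[str, str]]:
    """Report all invariant violations as ``(rsid, issue)``; never raises."""
    issues: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in table.records:
        for issue in validate_record(rec):
            issues.append((rec.rsid, issue))
        if rec.rsid in seen:
            issues.append((rec.rsid, "duplicate rsid"))
        seen.add(rec.rsid)
    return issues
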