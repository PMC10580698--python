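"""DerSimonian–Laird random-effects meta-analysis of stage-level MR estimates.

Pools log-odds ratios across analysis stages (e.g. a discovery and a
replication cohort). The between-stage variance tau² is the DL moment
estimator; heterogeneity is summarized by Cochran's Q and I². When a stage
is only available as a printed OR with its 95% CI, :func:`se_from_ci`
back-transforms it to the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .estimators import Z95, _two_sided_p


@dataclass
class StageEstimate:
    """One stage's causal estimate on the log-OR scale."""

    label: str
    log_or: float
    se: float
    source: str = "direct"

    def __post_init__(self):
        if not (self.se > 0):
            raise ValidationError(f"stage {self.label!r}: se must be > 0")


@dataclass
class MetaResult:
    """Pooled log-OR with DL tau², Q, I² and the pooled OR transform."""

    pooled_log_or: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    tau2: float
    Q: float
    df: int
    p_het: float
    i2: float

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def se_from_ci(
    or_: float, lo: float, hi: float, level: float = 0.95, label: str = ""
) -> StageEstimate:
    """Back-transform a printed OR and CI to a log-OR estimate with SE.

    se = (ln hi - ln lo) / (2 z); a degenerate CI (lo == hi) is rejected
    because it implies se = 0.
    """
    if not (0 < lo <= or_ <= hi):
        raise ValidationError(
            f"CI ordering violated: need 0 < {lo} <= {or_} <= {hi}"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = (math.log(hi) - math.log(lo)) / (2.0 * z)
    return StageEstimate(label=label, log_or=math.log(or_), se=se,
                         source="back_transformed")


def dl_pool(estimates: Iterable[StageEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of >= 2 stage estimates.

    Q uses fixed-effect weights 1/se²; tau² = max(0, (Q - df)/(S1 - S2/S1));
    random-effects weights 1/(se² + tau²) give the pooled estimate;
    I² = max(0, (Q - df)/Q)·100.
    """
    ests = list(estimates)
    if len(ests) < 2:
        raise ValidationError(
            "meta-analysis needs >= 2 estimates; pass a single estimate through"
        )
    x = np.array([e.log_or for e in ests])
    se = np.array([e.se for e in ests])
    w = 1.0 / se**2
    x_fixed = float((w * x).sum() / w.sum())
    Q = float((w * (x - x_fixed) ** 2).sum())
    df = len(ests) - 1
    s1 = w.sum()
    s2 = (w**2).sum()
    tau2 = max(0.0, (Q - df) / (s1 - s2 / s1))
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * x).sum() / w_star.sum())
    pooled_se = math.sqrt(1.0 / w_star.sum())
    i2 = 0.0 if Q <= 0 else max(0.0, (Q - df) / Q) * 100.0
    return MetaResult(
        pooled_log_or=pooled,
        se=pooled_se,
        ci_low=pooled - Z95 * pooled_se,
        ci_high=pooled + Z95 * pooled_se,
        pval=_two_sided_p(pooled / pooled_se),
        tau2=tau2,
        Q=Q,
        df=df,
        p_het=float(stats.chi2.sf(Q, df)),
        i2=i2,
    )


def meta_report(
    results: Mapping[str, MetaResult],
    stages: Optional[Mapping[str, Iterable[StageEstimate]]] = None,
) -> pd.DataFrame:
    """One tidy row per exposure: pooled OR/CI, p, tau², Q, I², p_het.

    Row order follows the insertion order of ``results``; when ``stages``
    is given, the per-stage ORs are included as a readable column.
    """
    rows = []
    for exposure, res in results.items():
        lo, hi = res.or_ci
        row = {
            "exposure": exposure,
            "pooled_or": res.pooled_or,
            "or_ci_low": lo,
            "or_ci_high": hi,
            "pval": res.pval,
            "tau2": res.tau2,
            "Q": res.Q,
            "df": res.df,
            "p_het": res.p_het,
            "i2": res.i2,
        }
        if stages is not None and exposure in stages:
            row["stage_ors"] = "; ".join(
                f"{e.label}={math.exp(e.log_or):.3f}" for e in stages[exposure]
            )
        rows.append(row)
    return pd.DataFrame(rows)
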