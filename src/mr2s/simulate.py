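"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws per-SNP summary data under the linear instrumental-
variable model: each instrument j has a true exposure effect gamma_j and
the outcome effect is theta·gamma_j plus an optional direct (pleiotropic)
effect alpha_j. Observed effects are the truth plus sampling noise at
allele-frequency-dependent standard errors se = 1/sqrt(2 n p (1-p)), the
standardized-trait approximation, so study size and minor-allele frequency
drive precision exactly as in case/control GWAS tables.

Switchable violations mirror the ways real instruments fail: a pleiotropic
fraction (balanced or directional alpha_j), deliberately weak instruments,
palindromic allele pairs, planted outliers with an inflated ratio, and a
replication cohort sharing the same truth for meta-analysis. Default study
sizes echo consortium-scale IBD/ICH GWAS (tens of thousands of exposure
samples, ~3000 outcome samples); presets ``uc``/``cd``/``ibd`` reproduce
the instrument counts 26/46/54 of that design.

A single master seed spawns named substreams (truth, exposure noise,
outcome noise, replication, alleles, LD) so each stage is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet
from .instruments import LdMatrix
from .io import SummaryStatsTable, VariantAssociation

#: substream order under the master seed
_STREAMS = ("truth", "exposure", "outcome", "replication", "alleles", "ld")

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    theta is the true causal log-OR; pleio_frac of SNPs carry direct
    effects alpha ~ N(pleio_mean, pleio_sd²) (directional when
    pleio_mean != 0, balanced otherwise); weak_frac of SNPs get F drawn
    from weak_f_range instead of f_range; outlier_spec = (count,
    multiplier) plants SNPs whose outcome effect is multiplier·theta·gamma.

    The default f_range starts high enough (sqrt(72) is about 3 SDs above
    the genome-wide z cutoff) that non-weak instruments clear p < 5e-8
    after sampling noise: the generator emulates a post-selection
    instrument list, where every retained SNP is significant by
    construction.
    """

    J: int = 50
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 30_000
    n_out: int = 20_000
    pleio_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    weak_frac: float = 0.0
    palindrome_frac: float = 0.0
    outlier_spec: Optional[tuple[int, float]] = None
    n_cohorts: int = 1
    ld_block_size: int = 1
    f_range: tuple[float, float] = (72.0, 200.0)
    weak_f_range: tuple[float, float] = (4.0, 9.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("pleio_frac", "weak_frac", "palindrome_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.n_exp < 2 or self.n_out < 2:
            raise ValueError("study sizes must be >= 2")


#: instrument-count presets echoing the emulated study design
PRESETS: dict[str, SimConfig] = {
    "uc": SimConfig(J=26, theta=math.log(0.83), n_exp=27_432, n_out=3_026, seed=0),
    "cd": SimConfig(J=46, theta=math.log(0.99), n_exp=20_883, n_out=3_026, seed=0),
    "ibd": SimConfig(J=54, theta=math.log(0.97), n_exp=34_652, n_out=3_026, seed=0),
}


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    rsids: list[str]
    weak: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    palindromic: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    planted_outlier: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def outcome_mean(self) -> np.ndarray:
        """E[Gamma_j] including pleiotropy and planted outliers."""
        mean = self.theta * self.gamma + self.alpha
        if self.planted_outlier.any():
            mean = np.where(self.planted_outlier, self._outlier_mult * self.theta * self.gamma, mean)
        return mean

    _outlier_mult: float = 1.0


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _af_se(n: int, p: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * p * (1.0 - p))


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    J = config.J
    maf = rng.uniform(*config.maf_range, size=J)
    se_x = _af_se(config.n_exp, maf)
    se_y = _af_se(config.n_out, maf)

    weak = np.zeros(J, dtype=bool)
    n_weak = int(round(config.weak_frac * J))
    if n_weak:
        weak[rng.choice(J, size=n_weak, replace=False)] = True
    F = np.where(
        weak,
        rng.uniform(*config.weak_f_range, size=J),
        rng.uniform(*config.f_range, size=J),
    )
    # effect alleles are coded exposure-increasing (gamma > 0), the
    # convention under which directional pleiotropy alpha ~ N(mu, sd) is
    # defined; sign variety in emitted tables comes from allele re-coding
    gamma = se_x * np.sqrt(F)

    alpha = np.zeros(J)
    n_pleio = int(round(config.pleio_frac * J))
    if n_pleio:
        pleio_idx = rng.choice(J, size=n_pleio, replace=False)
        alpha[pleio_idx] = rng.normal(config.pleio_mean, config.pleio_sd, size=n_pleio)

    palindromic = np.zeros(J, dtype=bool)
    n_pal = int(round(config.palindrome_frac * J))
    if n_pal:
        palindromic[rng.choice(J, size=n_pal, replace=False)] = True

    planted = np.zeros(J, dtype=bool)
    mult = 1.0
    if config.outlier_spec:
        count, mult = config.outlier_spec
        candidates = np.flatnonzero(~weak)
        planted[rng.choice(candidates, size=count, replace=False)] = True

    truth = SimTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        maf=maf,
        se_x=se_x,
        se_y=se_y,
        rsids=[f"rs{i + 1}" for i in range(J)],
        weak=weak,
        palindromic=palindromic,
        planted_outlier=planted,
    )
    truth._outlier_mult = mult
    return truth


def _positions(config: SimConfig) -> tuple[list[str], list[int]]:
    """Chromosome/position layout: LD-block members sit within 100 kb of
    each other, distinct blocks are >= 5 Mb apart (outside any clump window)."""
    chroms, positions = [], []
    bs = max(1, config.ld_block_size)
    for j in range(config.J):
        block, within = divmod(j, bs)
        chroms.append(str(block % 22 + 1))
        positions.append(1_000_000 + (block // 22) * 5_000_000 + within * 10_000)
    return chroms, positions


def _alleles(truth: SimTruth, rng: np.random.Generator) -> list[tuple[str, str]]:
    out = []
    for pal in truth.palindromic:
        pool = _PALINDROMIC_PAIRS if pal else _NONPALINDROMIC_PAIRS
        out.append(pool[rng.integers(len(pool))])
    return out


def _make_table(
    label: str,
    trait: str,
    truth: SimTruth,
    beta_hat: np.ndarray,
    se: np.ndarray,
    alleles: list[tuple[str, str]],
    chroms: list[str],
    positions: list[int],
    n: int,
    swap_mask: Optional[np.ndarray] = None,
) -> SummaryStatsTable:
    records = []
    z = beta_hat / se
    pvals = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))
    for j, rsid in enumerate(truth.rsids):
        ea, oa = alleles[j]
        beta, eaf = float(beta_hat[j]), float(truth.maf[j])
        if swap_mask is not None and swap_mask[j]:
            ea, oa = oa, ea
            beta, eaf = -beta, 1.0 - eaf
        records.append(
            VariantAssociation(
                rsid=rsid, chrom=chroms[j], pos=positions[j],
                effect_allele=ea, other_allele=oa, eaf=eaf,
                beta=beta, se=float(se[j]), pval=float(pvals[j]), n=n,
            )
        )
    return SummaryStatsTable(study_label=label, trait=trait, records=records)


def simulate_two_sample(
    config: SimConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SimTruth]:
    """Draw exposure and outcome summary-statistics tables plus their truth.

    The outcome table reports a random ~30% of SNPs with swapped allele
    labels (beta negated, EAF complemented) so downstream harmonization has
    real work to do; the truth arrays are always on the exposure's allele
    orientation.
    """
    rngs = _rngs(config.seed)
    truth = _draw_truth(config, rngs["truth"])
    chroms, positions = _positions(config)
    alleles = _alleles(truth, rngs["alleles"])

    gamma_hat = rngs["exposure"].normal(truth.gamma, truth.se_x)
    Gamma_hat = rngs["outcome"].normal(truth.outcome_mean, truth.se_y)
    swap_mask = rngs["alleles"].random(config.J) < 0.3

    exposure = _make_table("sim_exposure", "exposure", truth, gamma_hat,
                           truth.se_x, alleles, chroms, positions, config.n_exp)
    outcome = _make_table("sim_outcome", "outcome", truth, Gamma_hat,
                          truth.se_y, alleles, chroms, positions, config.n_out,
                          swap_mask=swap_mask)
    return exposure, outcome, truth


def simulate_replication(
    config: SimConfig, truth: SimTruth, n_scale: float = 1.0
) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """Fresh sampling noise around the same truth (independent seed stream).

    ``n_scale`` rescales both study sizes (SEs shrink by sqrt(n_scale)).
    """
    rng = _rngs(config.seed)["replication"]
    se_x = truth.se_x / math.sqrt(n_scale)
    se_y = truth.se_y / math.sqrt(n_scale)
    chroms, positions = _positions(config)
    alleles = _alleles(truth, np.random.default_rng(
        np.random.SeedSequence([config.seed, 17]).generate_state(1)[0]))

    gamma_hat = rng.normal(truth.gamma, se_x)
    Gamma_hat = rng.normal(truth.outcome_mean, se_y)
    exposure = _make_table("sim_exposure_rep", "exposure", truth, gamma_hat,
                           se_x, alleles, chroms, positions,
                           int(config.n_exp * n_scale))
    outcome = _make_table("sim_outcome_rep", "outcome", truth, Gamma_hat,
                          se_y, alleles, chroms, positions,
                          int(config.n_out * n_scale))
    return exposure, outcome


def simulate_ld(config: SimConfig) -> LdMatrix:
    """Block-diagonal LD: within-block r² ~ U(0.2, 0.9), zero between blocks."""
    rng = _rngs(config.seed)["ld"]
    ld = LdMatrix()
    bs = max(1, config.ld_block_size)
    rsids = [f"rs{i + 1}" for i in range(config.J)]
    for start in range(0, config.J, bs):
        block = rsids[start:start + bs]
        for i in range(len(block)):
            for k in range(i + 1, len(block)):
                ld.set(block[i], block[k], float(rng.uniform(0.2, 0.9)))
    return ld


def simulate_harmonized(config: SimConfig) -> tuple[HarmonizedSet, SimTruth]:
    """Fast path for calibration studies: harmonized effects without the
    table/allele plumbing (identical noise draws to simulate_two_sample)."""
    rngs = _rngs(config.seed)
    truth = _draw_truth(config, rngs["truth"])
    gamma_hat = rngs["exposure"].normal(truth.gamma, truth.se_x)
    Gamma_hat = rngs["outcome"].normal(truth.outcome_mean, truth.se_y)
    hset = HarmonizedSet.from_arrays(gamma_hat, truth.se_x, Gamma_hat,
                                     truth.se_y, rsids=truth.rsids)
    return hset, truth


def simulate_harmonization_scenario(
    J: int,
    n_absent: int,
    n_palindromic_intermediate: int,
    seed: int = 0,
    theta: float = 0.0,
    n_exp: int = 30_000,
    n_out: int = 20_000,
) -> tuple[SummaryStatsTable, SummaryStatsTable]:
    """Exposure/outcome tables with planted harmonization exclusions.

    Exactly ``n_absent`` instruments are missing from the outcome table and
    a disjoint ``n_palindromic_intermediate`` are palindromic with EAF 0.5
    in both studies, so harmonization must retain
    J - n_absent - n_palindromic_intermediate pairs.
    """
    if n_absent + n_palindromic_intermediate > J:
        raise ValueError("planted exclusions exceed J")
    config = SimConfig(J=J, theta=theta, n_exp=n_exp, n_out=n_out, seed=seed)
    exposure, outcome, truth = simulate_two_sample(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]).generate_state(1)[0])
    chosen = rng.choice(J, size=n_absent + n_palindromic_intermediate, replace=False)
    absent = {truth.rsids[i] for i in chosen[:n_absent]}
    pal = {truth.rsids[i] for i in chosen[n_absent:]}

    for rec in exposure.records:
        if rec.rsid in pal:
            rec.effect_allele, rec.other_allele, rec.eaf = "A", "T", 0.5
    new_out = []
    for rec in outcome.records:
        if rec.rsid in absent:
            continue
        if rec.rsid in pal:
            rec.effect_allele, rec.other_allele, rec.eaf = "A", "T", 0.5
        new_out.append(rec)
    outcome.records = new_out
    return exposure, outcome
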