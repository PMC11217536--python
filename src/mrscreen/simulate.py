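"""Synthetic GWAS summary statistics with known ground truth.

Emulates the study's two data sources: a quantitative gut-microbiome
abundance GWAS (MiBioGen-like, n = 18,340) as the exposure and a rare
binary disease GWAS (FinnGen-like, 1,076 cases / 381,977 controls) as the
outcome.  The generating model is the standard instrumental-variable
structure: true instrument effects γ_j act on the exposure; the outcome
receives θ·γ_j through the exposure plus a direct (horizontally
pleiotropic) effect α_j for the invalid fraction; observed effects add
sampling noise at cohort-calibrated standard errors.  Ground truth (θ, γ,
α, planted palindromic/invalid indices) is always emitted alongside the
data so recovery tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError
from .io import LDTable, SNPAssociation, TraitRecord, is_unnamed_label

#: Cohort sizes the default SE calibration targets.
N_EXPOSURE = 18_340
N_CASES = 1_076
N_CONTROLS = 381_977

PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
NON_PALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                         ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"))

DEFAULT_LEVEL_COUNTS = {"phylum": 9, "class": 16, "order": 20, "family": 32, "genus": 119}


@dataclass
class SimulationConfig:
    """Generating parameters for one exposure/outcome summary-statistic pair.

    ``gamma_mean``/``gamma_sd`` set the true instrument effects γ_j; the
    defaults give mean per-SNP F around 100, within the 20–150 range typical
    of microbiome instruments selected at p < 1e-5.  ``se_x_scale`` and
    ``se_y_scale`` multiply the cohort-calibrated standard errors
    1/sqrt(2·eaf·(1−eaf)·n) with n = ``n_exposure`` for the quantitative
    exposure and n_eff = 4/(1/cases + 1/controls) for the binary outcome.
    ``inside_correlation`` is corr(γ_j, α_j) over the invalid instruments;
    0 means the InSIDE assumption holds.
    """

    n_snps: int = 30
    theta: float = 0.0
    gamma_mean: float = 0.12
    gamma_sd: float = 0.03
    se_x_scale: float = 1.0
    se_y_scale: float = 1.0
    prop_invalid: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_correlation: float = 0.0
    prop_palindromic: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    n_exposure: int = N_EXPOSURE
    n_cases: int = N_CASES
    n_controls: int = N_CONTROLS
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise ConfigError(f"prop_invalid outside [0,1]: {self.prop_invalid}")
        if not 0.0 <= self.prop_palindromic <= 1.0:
            raise ConfigError(f"prop_palindromic outside [0,1]: {self.prop_palindromic}")
        if self.se_x_scale <= 0 or self.se_y_scale <= 0:
            raise ConfigError("SE scales must be > 0")
        if abs(self.inside_correlation) > 1.0:
            raise ConfigError(f"|inside_correlation| > 1: {self.inside_correlation}")
        if self.n_snps < 1:
            raise ConfigError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.ld_block_size < 1 or not 0.0 <= self.ld_within_r2 <= 1.0:
            raise ConfigError("invalid LD block settings")

    @property
    def n_outcome_effective(self) -> float:
        """Effective sample size of the case/control outcome GWAS."""
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class SimulationTruth:
    """The generating parameters a recovery test checks against."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_indices: set[int]
    palindromic_indices: set[int]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.nextafter(0.0, 1.0))


def _positions(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Chromosome/position layout: LD-block members 10 kb apart (well inside
    the clumping window), distinct blocks 25 Mb apart (outside it)."""
    j = np.arange(config.n_snps)
    block = j // config.ld_block_size
    within = j % config.ld_block_size
    pos = block * 25_000_000 + within * 10_000 + 1
    return ["1"] * config.n_snps, pos


def simulate_summary_pair(config: SimulationConfig
                          ) -> tuple[list[SNPAssociation], list[SNPAssociation], SimulationTruth]:
    """Draw one exposure/outcome summary-statistics pair plus ground truth.

    γ_j ~ N(gamma_mean, gamma_sd²); α_j = 0 for valid instruments, else
    drawn with the configured mean/sd and correlation with γ_j (Gaussian
    copula); observed β_Xj = γ_j + ε_X, β_Yj = θγ_j + α_j + ε_Y with ε at
    the reported SEs.  Allele pairs are palindromic for the configured
    fraction of SNPs (identical orientation in both tables, so only
    palindromy is dropped at harmonization).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    eaf = rng.uniform(0.05, 0.95, J)
    se_x = config.se_x_scale / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    se_y = config.se_y_scale / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome_effective)

    gamma = rng.normal(config.gamma_mean, config.gamma_sd, J)

    n_invalid = round(config.prop_invalid * J)
    invalid = rng.choice(J, size=n_invalid, replace=False) if n_invalid else np.empty(0, int)
    alpha = np.zeros(J)
    if n_invalid:
        z_indep = rng.standard_normal(n_invalid)
        if config.gamma_sd > 0:
            z_gamma = (gamma[invalid] - config.gamma_mean) / config.gamma_sd
        else:
            z_gamma = np.zeros(n_invalid)
        rho = config.inside_correlation
        alpha[invalid] = (config.alpha_mean
                          + config.alpha_sd * (rho * z_gamma + math.sqrt(1 - rho ** 2) * z_indep))

    beta_x = gamma + rng.normal(0.0, se_x)
    beta_y = config.theta * gamma + alpha + rng.normal(0.0, se_y)

    n_palin = round(config.prop_palindromic * J)
    palin = rng.choice(J, size=n_palin, replace=False) if n_palin else np.empty(0, int)
    palin_set = {int(i) for i in palin}
    pair_choice = rng.integers(0, 8, J)  # index into allele-pair tables

    chroms, positions = _positions(config)
    exposure, outcome = [], []
    n_outcome_total = config.n_cases + config.n_controls
    p_x = _two_sided_p(beta_x, se_x)
    p_y = _two_sided_p(beta_y, se_y)
    for j in range(J):
        if j in palin_set:
            ea, oa = PALINDROMIC_PAIRS[pair_choice[j] % 4]
        else:
            ea, oa = NON_PALINDROMIC_PAIRS[pair_choice[j]]
        common = dict(variant_id=f"rs{j + 1}", chromosome=chroms[j],
                      position=int(positions[j]), effect_allele=ea, other_allele=oa,
                      eaf=float(eaf[j]))
        exposure.append(SNPAssociation(
            beta=float(beta_x[j]), se=float(se_x[j]), pvalue=float(p_x[j]),
            n=config.n_exposure, **common))
        outcome.append(SNPAssociation(
            beta=float(beta_y[j]), se=float(se_y[j]), pvalue=float(p_y[j]),
            n=n_outcome_total, **common))

    truth = SimulationTruth(
        theta=config.theta, gamma=gamma, alpha=alpha,
        invalid_indices={int(i) for i in invalid if alpha[i] != 0.0},
        palindromic_indices=palin_set)
    return exposure, outcome, truth


def simulate_ld_table(exposure: list[SNPAssociation], config: SimulationConfig) -> LDTable:
    """LD table matching the generator's block layout: consecutive blocks of
    ``ld_block_size`` SNPs share r² = ``ld_within_r2``; across blocks r² = 0."""
    table = LDTable()
    if config.ld_block_size < 2 or config.ld_within_r2 == 0.0:
        return table
    for start in range(0, len(exposure), config.ld_block_size):
        block = exposure[start:start + config.ld_block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                table.set(block[i].variant_id, block[j].variant_id, config.ld_within_r2)
    return table


_NAMED_STEMS = (
    "Bacteroides", "Prevotella", "Faecalibacterium", "Roseburia", "Alistipes",
    "Blautia", "Coprococcus", "Dorea", "Lachnospira", "Oscillibacter",
    "Ruminococcus", "Streptococcus", "Veillonella", "Akkermansia", "Dialister",
    "Odoribacter", "Catenibacterium", "Parabacteroides", "Intestinimonas",
    "Sutterella",
)

_UNNAMED_STEMS = ("unknowngenus", "unclassified", "Incertae Sedis")


def simulate_taxa_catalog(n_total: int = 211, n_unnamed: int = 15,
                          level_counts: dict[str, int] | None = None,
                          seed: int = 0) -> list[TraitRecord]:
    """A taxon catalog with a planted fraction of unnamed groups.

    ``level_counts`` distributes the named records over taxonomic levels and
    must sum to ``n_total − n_unnamed``.  Reproducible byte-for-byte under
    ``seed`` (which only shuffles the record order).
    """
    if level_counts is None:
        level_counts = dict(DEFAULT_LEVEL_COUNTS)
    if n_unnamed > n_total:
        raise ConfigError(f"n_unnamed={n_unnamed} > n_total={n_total}")
    if sum(level_counts.values()) != n_total - n_unnamed:
        raise ConfigError(
            f"level counts sum to {sum(level_counts.values())}, "
            f"expected {n_total - n_unnamed}")

    records = []
    idx = 0
    for level, count in level_counts.items():
        for i in range(count):
            name = f"{level}.{_NAMED_STEMS[i % len(_NAMED_STEMS)]}{i // len(_NAMED_STEMS) + 1}"
            assert not is_unnamed_label(name)
            records.append(TraitRecord(
                trait_id=f"taxon{idx:04d}", trait_name=name,
                taxonomic_level=level, is_named=True))
            idx += 1
    for i in range(n_unnamed):
        name = f"genus.{_UNNAMED_STEMS[i % len(_UNNAMED_STEMS)]}.id{i + 1}"
        records.append(TraitRecord(
            trait_id=f"taxon{idx:04d}", trait_name=name,
            taxonomic_level="genus", is_named=False))
        idx += 1

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]
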