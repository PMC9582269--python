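"""Seeded generator of two-sample GWAS summary statistics.

Data are generated directly on the summary scale: no individual-level
genotypes are simulated.  For instrument j with minor-allele frequency
maf_j and true per-allele exposure effect γ_j,

    se_exp_j  = 1 / sqrt(2·maf_j·(1−maf_j)·N_exp)
    beta_exp_j ~ Normal(γ_j, se_exp_j²)

and the outcome association, under causal effect θ (log odds per unit
exposure liability) plus a per-SNP horizontal-pleiotropy effect α_j,

    se_out_j  = 1 / sqrt(2·maf_j·(1−maf_j)·N_out·cf·(1−cf))
    beta_out_j ~ Normal(θ·γ_j + α_j, se_out_j²)

with cf the outcome case fraction (the case-control variance inflation
for a binary trait on the log-odds scale).  Exposure and outcome noise
are independent — a strict two-sample design with no participant
overlap.  True effects γ_j are drawn from Normal(0, γ_scale²) and
rejection-sampled until the instrument would reach suggestive
significance (p < 5×10⁻⁷) at N_exp, so every generated SNP is a valid
candidate instrument by construction rather than by winner's curse.

Pleiotropy modes for α_j: "none" (all zero), "balanced"
(Normal(0, sd_α²) for a random ``frac_invalid`` of instruments, zero
mean so InSIDE holds and IVW stays consistent on average) and
"directional" (Normal(μ_α, sd_α²), violating the exclusion restriction
with a common sign and biasing IVW but not, to first order, the
weighted median as long as invalid weight stays below half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import SummaryStats

__all__ = ["PleiotropyConfig", "SynthConfig", "SynthTruth", "generate",
           "generate_mvmr"]

#: significance the generator guarantees for each instrument
INSTRUMENT_P = 5e-7

#: rejection-sampling cap per SNP
_MAX_TRIES = 100_000

# non-palindromic allele pair assigned to every generated SNP
_EFFECT_ALLELE, _OTHER_ALLELE = "A", "G"


class GeneratorError(RuntimeError):
    pass


@dataclass(frozen=True, slots=True)
class PleiotropyConfig:
    """Horizontal-pleiotropy law for the invalid instruments."""

    mode: str = "none"  # none | balanced | directional
    mu_alpha: float = 0.0
    sd_alpha: float = 0.0
    frac_invalid: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ValueError("frac_invalid must lie in [0, 1]")
        if self.mode == "balanced" and self.mu_alpha != 0.0:
            raise ValueError("balanced pleiotropy requires mu_alpha = 0")


@dataclass(frozen=True, slots=True)
class SynthConfig:
    """Generative-model parameters for one exposure→outcome pair.

    Defaults mirror a cannabis-use-disorder-sized exposure GWAS
    (N ≈ 3.8×10⁵) feeding a large binary cardiovascular outcome GWAS,
    with 12 suggestive-significance instruments jointly explaining on
    the order of 0.1% of exposure variance.
    """

    k: int = 12
    n_exp: int = 384_032
    n_out: int = 500_000
    case_frac_out: float = 0.1
    theta: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.45)
    gamma_scale: float = 0.015
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be at least 3")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 < self.case_frac_out < 1.0):
            raise ValueError("case_frac_out must lie in (0, 1)")
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be positive")


@dataclass(frozen=True, slots=True)
class SynthTruth:
    """Ground truth behind one generated pair of tables."""

    gamma: np.ndarray  # true per-SNP exposure effects
    alpha: np.ndarray  # true per-SNP pleiotropic outcome effects
    theta: float

    @property
    def true_ratios(self) -> np.ndarray:
        return (self.theta * self.gamma + self.alpha) / self.gamma


def _se_exp(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_out(maf: np.ndarray, n: int, case_frac: float) -> np.ndarray:
    return 1.0 / np.sqrt(
        2.0 * maf * (1.0 - maf) * n * case_frac * (1.0 - case_frac)
    )


def _draw_gammas(
    rng: np.random.Generator,
    k: int,
    gamma_scale: float,
    se: np.ndarray,
) -> np.ndarray:
    """Rejection-sample true effects until each SNP's expected
    association reaches p < 5e-7 at the exposure sample size."""
    z_min = sps.norm.isf(INSTRUMENT_P / 2.0)
    gamma = np.zeros(k)
    pending = np.ones(k, dtype=bool)
    tries = 0
    while pending.any():
        tries += 1
        if tries > _MAX_TRIES:
            raise GeneratorError(
                "rejection sampling failed to produce instruments at "
                f"p < {INSTRUMENT_P:g}; increase gamma_scale or n_exp"
            )
        draw = rng.normal(0.0, gamma_scale, size=int(pending.sum()))
        idx = np.flatnonzero(pending)
        ok = np.abs(draw) / se[idx] > z_min
        gamma[idx[ok]] = draw[ok]
        pending[idx[ok]] = False
    return gamma


def _draw_alphas(
    rng: np.random.Generator,
    k: int,
    cfg: PleiotropyConfig,
    gamma: np.ndarray,
) -> np.ndarray:
    """Pleiotropic outcome effects for a random ``frac_invalid`` subset.

    Directional pleiotropy is defined on the exposure-increasing allele
    orientation: the drawn effect is applied with the sign of γ_j, so
    that all invalid instruments push the Wald ratio the same way (the
    convention of instrument lists oriented to the trait-raising
    allele).  Balanced pleiotropy is sign-symmetric by construction.
    """
    alpha = np.zeros(k)
    if cfg.mode == "none" or cfg.frac_invalid == 0.0:
        return alpha
    n_invalid = int(round(cfg.frac_invalid * k))
    invalid = rng.choice(k, size=n_invalid, replace=False)
    mu = 0.0 if cfg.mode == "balanced" else cfg.mu_alpha
    draw = rng.normal(mu, cfg.sd_alpha, size=n_invalid)
    if cfg.mode == "directional":
        draw = draw * np.sign(gamma[invalid])
    alpha[invalid] = draw
    return alpha


def _as_sumstats(
    trait_name: str,
    trait_type: str,
    rsids: list[str],
    chroms: np.ndarray,
    positions: np.ndarray,
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> SummaryStats:
    pval = 2.0 * sps.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": [str(c) for c in chroms],
            "pos": positions.astype(np.int64),
            "effect_allele": _EFFECT_ALLELE,
            "other_allele": _OTHER_ALLELE,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": np.int64(n),
        }
    )
    return SummaryStats(trait_name=trait_name, trait_type=trait_type,
                        table=table)


def _layout(k: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """rsids, chromosomes and positions for k mutually unlinked SNPs
    (spread across chromosomes, > 10 Mb apart)."""
    rsids = [f"rs{1_000_000 + j}" for j in range(k)]
    chroms = np.array([1 + (j % 22) for j in range(k)])
    positions = np.array(
        [1_000_000 + 20_000_000 * (j // 22) for j in range(k)]
    )
    return rsids, chroms, positions


def generate(cfg: SynthConfig) -> tuple[SummaryStats, SummaryStats,
                                        SynthTruth]:
    """Generate one (exposure, outcome) pair of summary tables plus the
    ground truth behind them.  Fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.k)
    se_exp = _se_exp(maf, cfg.n_exp)
    se_out = _se_out(maf, cfg.n_out, cfg.case_frac_out)

    gamma = _draw_gammas(rng, cfg.k, cfg.gamma_scale, se_exp)
    alpha = _draw_alphas(rng, cfg.k, cfg.pleiotropy, gamma)

    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(cfg.theta * gamma + alpha, se_out)

    rsids, chroms, positions = _layout(cfg.k)
    exposure = _as_sumstats(
        "synthetic_exposure", "binary", rsids, chroms, positions, maf,
        beta_exp, se_exp, cfg.n_exp,
    )
    outcome = _as_sumstats(
        "synthetic_outcome", "binary", rsids, chroms, positions, maf,
        beta_out, se_out, cfg.n_out,
    )
    truth = SynthTruth(gamma=gamma, alpha=alpha, theta=cfg.theta)
    return exposure, outcome, truth


@dataclass(frozen=True, slots=True)
class MvmrTruth:
    gamma1: np.ndarray
    gamma2: np.ndarray
    alpha: np.ndarray
    theta1: float
    theta2: float


def generate_mvmr(
    cfg1: SynthConfig,
    cfg2: SynthConfig,
    theta1: float,
    theta2: float,
    rho_gamma: float = 0.0,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, MvmrTruth]:
    """Generate two correlated exposures and one outcome.

    Per-SNP true effects (γ1_j, γ2_j) are bivariate normal with
    correlation ``rho_gamma``; the outcome mean is θ1·γ1_j + θ2·γ2_j
    (plus cfg1's pleiotropy law).  All randomness flows from cfg1.seed;
    cfg2 contributes sample sizes and scales only.  Instruments are
    guaranteed suggestive-significant for at least one of the two
    exposures (alternating), mimicking a union of per-exposure selected
    instrument lists.
    """
    if not (abs(rho_gamma) < 1.0):
        raise ValueError("|rho_gamma| must be below 1")
    k = cfg1.k
    rng = np.random.default_rng(cfg1.seed)
    maf = rng.uniform(cfg1.maf_range[0], cfg1.maf_range[1], size=k)
    se_exp1 = _se_exp(maf, cfg1.n_exp)
    se_exp2 = _se_exp(maf, cfg2.n_exp)
    se_out = _se_out(maf, cfg1.n_out, cfg1.case_frac_out)

    # correlated true effects: draw the "own" exposure's effect with the
    # instrument guarantee, the other exposure's effect conditionally
    own_is_exp1 = np.arange(k) % 2 == 0
    gamma1 = np.empty(k)
    gamma2 = np.empty(k)
    g_own = _draw_gammas(
        rng, k, cfg1.gamma_scale,
        np.where(own_is_exp1, se_exp1, se_exp2),
    )
    resid_sd = cfg2.gamma_scale * math.sqrt(1.0 - rho_gamma ** 2)
    g_other = (
        rho_gamma * (cfg2.gamma_scale / cfg1.gamma_scale) * g_own
        + rng.normal(0.0, resid_sd, size=k)
    )
    gamma1 = np.where(own_is_exp1, g_own, g_other)
    gamma2 = np.where(own_is_exp1, g_other, g_own)

    alpha = _draw_alphas(rng, k, cfg1.pleiotropy, gamma1)

    beta_exp1 = rng.normal(gamma1, se_exp1)
    beta_exp2 = rng.normal(gamma2, se_exp2)
    beta_out = rng.normal(theta1 * gamma1 + theta2 * gamma2 + alpha,
                          se_out)

    rsids, chroms, positions = _layout(k)
    exp1 = _as_sumstats(
        "synthetic_exposure_1", "binary", rsids, chroms, positions, maf,
        beta_exp1, se_exp1, cfg1.n_exp,
    )
    exp2 = _as_sumstats(
        "synthetic_exposure_2", "continuous", rsids, chroms, positions,
        maf, beta_exp2, se_exp2, cfg2.n_exp,
    )
    outcome = _as_sumstats(
        "synthetic_outcome", "binary", rsids, chroms, positions, maf,
        beta_out, se_out, cfg1.n_out,
    )
    truth = MvmrTruth(gamma1=gamma1, gamma2=gamma2, alpha=alpha,
                      theta1=theta1, theta2=theta2)
    return exp1, exp2, outcome, truth
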