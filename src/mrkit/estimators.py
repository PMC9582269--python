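"""Univariable two-sample MR estimators.

Per-SNP causal estimates are Wald ratios (outcome beta over exposure
beta) with delta-method standard errors.  Ratios are pooled by:

* multiplicative random-effects inverse-variance weighting (IVW) — the
  primary estimator; the fixed-effect SE is inflated by the residual
  over-dispersion, floored at 1 so it never shrinks below the
  fixed-effect SE;
* simple and weighted medians — consistent when at least half of the
  (weight of the) instruments are valid, with parametric-bootstrap SEs;
* MR-Egger regression — a weighted regression of outcome betas on
  exposure betas whose intercept measures directional pleiotropy and
  whose slope is a pleiotropy-robust causal estimate.

For binary outcomes all betas are log odds ratios, so ``exp(beta)`` of
any estimate is an odds ratio per unit increase in genetic liability to
the exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedPair

__all__ = [
    "WaldRatio",
    "MREstimate",
    "wald_ratio",
    "wald_ratios",
    "ivw_mre",
    "simple_median",
    "weighted_median",
    "egger",
]

Z95 = 1.96


class InsufficientInstrumentsError(ValueError):
    pass


class DegenerateInstrumentError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class WaldRatio:
    """Single-instrument causal estimate beta_out / beta_exp."""

    rsid: str
    ratio: float
    se_ratio: float


@dataclass(frozen=True, slots=True)
class MREstimate:
    """A method-labelled causal estimate on the log-odds scale with its
    normal-theory 95% CI and, via ``or_scale``, the odds-ratio view."""

    method: str
    beta: float
    se: float
    pval: float
    k: int
    warnings: tuple[str, ...] = ()

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, OR lower, OR upper)."""
        return (
            math.exp(self.beta),
            math.exp(self.ci_low),
            math.exp(self.ci_high),
        )

    def ci_excludes_null(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


def wald_ratio(pair: HarmonizedPair,
               se_mode: str = "first_order") -> WaldRatio:
    """Per-SNP Wald ratio with a delta-method SE.

    first_order:  se_out / |beta_exp|
    second_order: sqrt(se_out²/beta_exp² + beta_out²·se_exp²/beta_exp⁴)
    """
    if pair.beta_exp == 0.0:
        raise DegenerateInstrumentError(
            f"{pair.rsid}: exposure beta is exactly zero"
        )
    ratio = pair.beta_out / pair.beta_exp
    if se_mode == "first_order":
        se = pair.se_out / abs(pair.beta_exp)
    elif se_mode == "second_order":
        se = math.sqrt(
            pair.se_out ** 2 / pair.beta_exp ** 2
            + pair.beta_out ** 2 * pair.se_exp ** 2 / pair.beta_exp ** 4
        )
    else:
        raise ValueError(f"unknown se_mode {se_mode!r}")
    return WaldRatio(rsid=pair.rsid, ratio=ratio, se_ratio=se)


def wald_ratios(pairs: list[HarmonizedPair],
                se_mode: str = "first_order") -> list[WaldRatio]:
    """Wald ratios for every usable harmonized pair."""
    return [wald_ratio(p, se_mode) for p in pairs if p.usable]


def _arrays(ratios: list[WaldRatio]) -> tuple[np.ndarray, np.ndarray]:
    r = np.array([x.ratio for x in ratios], dtype=float)
    s = np.array([x.se_ratio for x in ratios], dtype=float)
    return r, s


def ivw_mre(ratios: list[WaldRatio]) -> MREstimate:
    """Multiplicative random-effects IVW pooling of Wald ratios.

    beta = Σ wⱼrⱼ / Σ wⱼ with wⱼ = 1/seⱼ²; the fixed-effect SE
    1/√(Σ wⱼ) is multiplied by max(1, √(Q/(k−1))) where Q is Cochran's
    heterogeneity statistic.  With first-order ratio SEs this is
    identical to a weighted no-intercept regression of outcome betas on
    exposure betas with multiplicative over-dispersion.
    """
    k = len(ratios)
    if k == 0:
        raise InsufficientInstrumentsError("no instruments")
    if k == 1:
        only = ratios[0]
        p = 2.0 * sps.norm.sf(abs(only.ratio) / only.se_ratio)
        return MREstimate(
            method="ivw_mre", beta=only.ratio, se=only.se_ratio,
            pval=float(p), k=1, warnings=("single_instrument_wald",),
        )
    r, s = _arrays(ratios)
    w = 1.0 / s ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    scale = max(1.0, math.sqrt(q / (k - 1)))
    se = se_fixed * scale
    p = float(2.0 * sps.norm.sf(abs(beta) / se))
    return MREstimate(method="ivw_mre", beta=beta, se=se, pval=p, k=k)


def ivw_fixed_beta(ratios: list[WaldRatio]) -> float:
    """Fixed-effect IVW point estimate (shared with diagnostics)."""
    r, s = _arrays(ratios)
    w = 1.0 / s ** 2
    return float(np.sum(w * r) / np.sum(w))


def _bootstrap_se(
    ratios: list[WaldRatio],
    statistic,
    boot_reps: int,
    seed: int,
) -> float:
    """Parametric bootstrap: resample each ratio from
    Normal(ratioⱼ, se_ratioⱼ) and take the SD of the statistic."""
    r, s = _arrays(ratios)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r, scale=s, size=(boot_reps, len(r)))
    stats = statistic(draws)
    return float(np.std(stats, ddof=1))


def simple_median(
    ratios: list[WaldRatio], boot_reps: int = 1000, seed: int = 0
) -> MREstimate:
    """Unweighted median of Wald ratios; SE by parametric bootstrap."""
    k = len(ratios)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"median estimators need k >= 3, got {k}"
        )
    r, _ = _arrays(ratios)
    beta = float(np.median(r))
    se = _bootstrap_se(
        ratios, lambda draws: np.median(draws, axis=1), boot_reps, seed
    )
    p = float(2.0 * sps.norm.sf(abs(beta) / se))
    return MREstimate(method="simple_median", beta=beta, se=se, pval=p, k=k)


def _weighted_median_stat(values: np.ndarray,
                          weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort values ascending; with normalized weights w̃ the standardized
    cumulative weight of the j-th order statistic is
    sⱼ = Σ_{i≤j} w̃ᵢ − w̃ⱼ/2, and the estimate interpolates the sorted
    values linearly in s at s = 0.5.
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(v[0])
    if 0.5 >= s[-1]:
        return float(v[-1])
    return float(np.interp(0.5, s, v))


def weighted_median(
    ratios: list[WaldRatio], boot_reps: int = 1000, seed: int = 0
) -> MREstimate:
    """Inverse-variance weighted median of Wald ratios.

    Consistent when instruments carrying at least 50% of the weight are
    valid.  Reduces exactly to the simple median under equal weights.
    SE by the same parametric bootstrap as :func:`simple_median`.
    """
    k = len(ratios)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"median estimators need k >= 3, got {k}"
        )
    r, s = _arrays(ratios)
    w = 1.0 / s ** 2
    beta = _weighted_median_stat(r, w)

    def stat(draws: np.ndarray) -> np.ndarray:
        return np.array(
            [_weighted_median_stat(row, w) for row in draws]
        )

    se = _bootstrap_se(ratios, stat, boot_reps, seed)
    p = float(2.0 * sps.norm.sf(abs(beta) / se))
    return MREstimate(method="weighted_median", beta=beta, se=se, pval=p,
                      k=k)


def egger(pairs: list[HarmonizedPair]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope estimate, intercept estimate).

    Weighted least squares of beta_out on beta_exp with an intercept and
    weights 1/se_out², after orienting all pairs so beta_exp > 0 (the
    InSIDE-convention orientation); coefficient SEs use the classical
    covariance with the residual scale floored at 1, and p-values come
    from a t distribution with k − 2 degrees of freedom.  A nonzero
    intercept indicates directional pleiotropy.
    """
    usable = [p for p in pairs if p.usable]
    k = len(usable)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs k >= 3 usable instruments, got {k}"
        )
    bx = np.array([p.beta_exp for p in usable], dtype=float)
    by = np.array([p.beta_out for p in usable], dtype=float)
    sy = np.array([p.se_out for p in usable], dtype=float)
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    w = 1.0 / sy ** 2

    # Weighted normal equations for [intercept, slope]
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtx = XtW @ X
    coef = np.linalg.solve(xtx, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid ** 2) / (k - 2))
    scale = max(1.0, math.sqrt(sigma2))
    cov_unit = np.linalg.inv(xtx)
    ses = scale * np.sqrt(np.diag(cov_unit))

    tdist = sps.t(df=k - 2)
    p_int = float(2.0 * tdist.sf(abs(coef[0]) / ses[0]))
    p_slope = float(2.0 * tdist.sf(abs(coef[1]) / ses[1]))
    slope = MREstimate(
        method="egger_slope", beta=float(coef[1]), se=float(ses[1]),
        pval=p_slope, k=k,
    )
    intercept = MREstimate(
        method="egger_intercept", beta=float(coef[0]), se=float(ses[0]),
        pval=p_int, k=k,
    )
    return slope, intercept
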