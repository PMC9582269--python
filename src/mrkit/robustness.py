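"""Sensitivity analyses for the IVW estimate: Cochran heterogeneity,
MR-PRESSO pleiotropy-outlier detection/correction, and leave-one-out.

MR-PRESSO works on the residual sum of squares of each instrument
against the leave-one-out IVW prediction.  The observed RSS is compared
with a simulated null in which each outcome beta is redrawn around its
leave-one-out prediction at its reported standard error; instruments
whose own residual is extreme under that null (Bonferroni-adjusted) are
flagged as pleiotropic outliers and the IVW estimate is re-computed
without them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .estimators import (
    InsufficientInstrumentsError,
    MREstimate,
    WaldRatio,
    ivw_mre,
    wald_ratios,
)
from .harmonize import HarmonizedPair

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LooRow",
    "LooTable",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class HeterogeneityResult:
    """Cochran Q with its I² summary.

    I² bands: low for I² ≤ 25%, moderate for 25% < I² ≤ 50%, high
    above 50% (the boundary at exactly 50% is assigned to moderate).
    """

    q: float
    df: int
    pval: float
    i2: float  # percentage in [0, 100]

    @property
    def band(self) -> str:
        if self.i2 <= 25.0:
            return "low"
        if self.i2 <= 50.0:
            return "moderate"
        return "high"


def cochran_q(ratios: list[WaldRatio],
              beta_pooled: float) -> HeterogeneityResult:
    """Q = Σ (1/seⱼ²)(ratioⱼ − beta_pooled)², chi-square with k−1 df;
    I² = max(0, (Q − df)/Q)·100."""
    k = len(ratios)
    if k < 2:
        raise InsufficientInstrumentsError(
            f"heterogeneity needs k >= 2, got {k}"
        )
    r = np.array([x.ratio for x in ratios])
    s = np.array([x.se_ratio for x in ratios])
    q = float(np.sum((r - beta_pooled) ** 2 / s ** 2))
    df = k - 1
    pval = float(sps.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2)


@dataclass(frozen=True, slots=True)
class PressoResult:
    global_rss: float
    global_p: float
    outlier_rsids: tuple[str, ...]
    outlier_pvals: dict = field(default_factory=dict)
    corrected: MREstimate | None = None
    distortion_p: float | None = None


class AllOutliersError(ValueError):
    """Every instrument was flagged as an outlier; no corrected estimate
    can be formed."""


def _loo_slopes(bx: np.ndarray, by: np.ndarray,
                w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted no-intercept slopes of by on bx.

    slope(−j) = (Σ w x y − wⱼxⱼyⱼ) / (Σ w x² − wⱼxⱼ²), vectorized.
    """
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx ** 2) - w * bx ** 2
    return num / den


def mr_presso(
    pairs: list[HarmonizedPair],
    nsim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Global pleiotropy test, per-instrument outlier test and
    outlier-corrected IVW estimate.

    The observed RSS is Σⱼ wⱼ (β_outⱼ − slope(−j)·β_expⱼ)² with
    wⱼ = 1/se_outⱼ².  Under the null, β_out*ⱼ ~ N(slope(−j)·β_expⱼ,
    se_outⱼ); each of ``nsim`` seeded simulations recomputes the
    leave-one-out slopes on the simulated panel, giving the null RSS
    distribution.  global_p = (1 + #{RSS* ≥ RSS}) / (nsim + 1).
    Per-instrument p-values use the same construction on the single
    observation, Bonferroni-corrected across instruments.  Designed for
    panels of more than 10 instruments; smaller panels trigger a
    warning, not an error.
    """
    usable = [p for p in pairs if p.usable]
    k = len(usable)
    if k < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs k >= 4 usable instruments, got {k}"
        )
    if k <= 10:
        warnings.warn(
            f"MR-PRESSO is intended for panels of more than 10 "
            f"instruments; k = {k}",
            UserWarning,
            stacklevel=2,
        )
    bx = np.array([p.beta_exp for p in usable], dtype=float)
    by = np.array([p.beta_out for p in usable], dtype=float)
    sy = np.array([p.se_out for p in usable], dtype=float)
    rsids = [p.rsid for p in usable]
    w = 1.0 / sy ** 2

    slopes = _loo_slopes(bx, by, w)
    obs_res = w * (by - slopes * bx) ** 2
    obs_rss = float(np.sum(obs_res))

    rng = np.random.default_rng(seed)
    sim_by = rng.normal(loc=slopes * bx, scale=sy, size=(nsim, k))
    # leave-one-out slopes recomputed inside each simulated panel
    num_tot = np.sum(w * bx * sim_by, axis=1, keepdims=True)
    den_tot = np.sum(w * bx ** 2)
    sim_slopes = (num_tot - w * bx * sim_by) / (den_tot - w * bx ** 2)
    sim_res = w * (sim_by - sim_slopes * bx) ** 2
    sim_rss = np.sum(sim_res, axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (nsim + 1))

    per_snp_p = (1 + np.sum(sim_res >= obs_res, axis=0)) / (nsim + 1)
    adj = np.minimum(1.0, per_snp_p * k)  # Bonferroni across instruments
    outlier_idx = [i for i in range(k) if adj[i] < outlier_alpha]
    outliers = tuple(rsids[i] for i in outlier_idx)
    outlier_pvals = {rsids[i]: float(adj[i]) for i in range(k)}

    corrected: MREstimate | None = None
    distortion_p: float | None = None
    if outliers:
        keep = [p for p in usable if p.rsid not in outliers]
        if not keep:
            raise AllOutliersError(
                "every instrument was flagged as a pleiotropic outlier; "
                "refusing to produce a corrected estimate"
            )
        corrected = ivw_mre(wald_ratios(keep))
        raw = ivw_mre(wald_ratios(usable))
        distortion_p = _distortion_test(
            bx, by, sy, outlier_idx, raw.beta, corrected.beta, rng
        )

    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        outlier_rsids=outliers,
        outlier_pvals=outlier_pvals,
        corrected=corrected,
        distortion_p=distortion_p,
    )


def _distortion_test(
    bx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    outlier_idx: list[int],
    beta_raw: float,
    beta_corrected: float,
    rng: np.random.Generator,
    nboot: int = 1000,
) -> float:
    """Exploratory test of whether removing the flagged outliers
    displaces the estimate more than removing random subsets of the same
    size would.  Reported for transparency only."""
    k = len(bx)
    inliers = np.array(
        [i for i in range(k) if i not in set(outlier_idx)], dtype=int
    )
    n_out = len(outlier_idx)
    if beta_corrected == 0.0:
        return float("nan")
    obs_disp = abs(beta_raw - beta_corrected) / abs(beta_corrected)
    w = 1.0 / sy ** 2
    disps = np.empty(nboot)
    for b in range(nboot):
        fake_out = rng.choice(inliers, size=n_out, replace=True)
        mask = np.ones(k, dtype=bool)
        mask[fake_out] = False
        wb, xb, yb = w[mask], bx[mask], by[mask]
        beta_b = np.sum(wb * xb * yb) / np.sum(wb * xb ** 2)
        disps[b] = abs(beta_raw - beta_b) / abs(beta_b) if beta_b else np.inf
    return float((1 + np.sum(disps >= obs_disp)) / (nboot + 1))


@dataclass(frozen=True, slots=True)
class LooRow:
    left_out: str
    estimate: MREstimate
    influential: bool


@dataclass(frozen=True, slots=True)
class LooTable:
    full: MREstimate
    rows: tuple[LooRow, ...]

    @property
    def influential_rsids(self) -> tuple[str, ...]:
        return tuple(r.left_out for r in self.rows if r.influential)


def leave_one_out(pairs: list[HarmonizedPair]) -> LooTable:
    """Re-estimate IVW k times, each omitting one instrument.

    An omitted instrument is flagged influential when dropping it
    changes whether the 95% CI excludes the null.
    """
    usable = [p for p in pairs if p.usable]
    k = len(usable)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs k >= 3 usable instruments, got {k}"
        )
    full = ivw_mre(wald_ratios(usable))
    full_sig = full.ci_excludes_null()
    rows = []
    for i in range(k):
        subset = usable[:i] + usable[i + 1:]
        est = ivw_mre(wald_ratios(subset))
        influential = est.ci_excludes_null() != full_sig
        rows.append(
            LooRow(left_out=usable[i].rsid, estimate=est,
                   influential=influential)
        )
    return LooTable(full=full, rows=tuple(rows))
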