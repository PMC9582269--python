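"""Multivariable MR: direct effects of an exposure on an outcome while
adjusting for a second, genetically correlated exposure.

The estimating equation is a weighted no-intercept regression of
outcome betas on the betas of both exposures across the union of their
instrument sets, with weights 1/se_out².  The coefficient on the
primary exposure is its direct effect, net of any pathway through the
adjustment exposure.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate
from .gwas_io import SummaryStats
from .harmonize import ProxyMap, harmonize
from .instruments import ClumpConfig, LdMatrix, clump

__all__ = [
    "MvmrPanel",
    "MvmrEstimate",
    "CollinearityError",
    "InsufficientPanelError",
    "build_mvmr_panel",
    "mvmr_ivw",
]

log = logging.getLogger(__name__)

#: condition-number threshold above which the exposure design is
#: reported as near-collinear
CONDITION_WARN = 1e3


class CollinearityError(ValueError):
    pass


class InsufficientPanelError(ValueError):
    pass


@dataclass
class MvmrPanel:
    """Per-SNP effects on two exposures and one outcome, harmonized to
    the primary exposure's effect alleles."""

    table: pd.DataFrame  # rsid, beta_exp1, se_exp1, beta_exp2, se_exp2,
    #                      beta_out, se_out
    exposure_names: tuple[str, str]
    outcome_name: str

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True, slots=True)
class MvmrEstimate:
    """Direct-effect estimates for each exposure, plus diagnostics."""

    exposure_names: tuple[str, str]
    betas: tuple[float, float]
    ses: tuple[float, float]
    pvals: tuple[float, float]
    k: int
    conditional_f: tuple[float, float]
    warnings: tuple[str, ...] = ()

    @property
    def direct(self) -> MREstimate:
        """The adjusted (direct) estimate for the primary exposure."""
        return MREstimate(
            method="mvmr_ivw",
            beta=self.betas[0],
            se=self.ses[0],
            pval=self.pvals[0],
            k=self.k,
            warnings=self.warnings,
        )


def build_mvmr_panel(
    exposure1: SummaryStats,
    exposure2: SummaryStats,
    outcome: SummaryStats,
    instruments1: list[str],
    instruments2: list[str],
    ld: LdMatrix | None = None,
    cfg: ClumpConfig | None = None,
    proxies: ProxyMap | None = None,
    instrument_source: str = "union",
) -> MvmrPanel:
    """Assemble the joint instrument panel for a two-exposure model.

    The union of the two pre-clumped instrument lists is re-clumped
    jointly (so cross-exposure LD is also broken), then every retained
    SNP is looked up in all three datasets and harmonized to exposure1's
    effect alleles; SNPs missing anywhere are dropped.  With
    ``instrument_source="primary"`` only exposure1's instruments are
    used, with exposure2's betas attached.
    """
    ld = ld or LdMatrix()
    cfg = cfg or ClumpConfig()
    if instrument_source == "union":
        wanted = list(dict.fromkeys(instruments1 + instruments2))
    elif instrument_source == "primary":
        wanted = list(instruments1)
    else:
        raise ValueError(
            f"instrument_source must be 'union' or 'primary', got "
            f"{instrument_source!r}"
        )

    # joint re-clump of the union set: build a mini SummaryStats with
    # each SNP's best (smallest) p across the two exposures
    rows = []
    idx1 = {r.rsid: r for r in exposure1.records}
    idx2 = {r.rsid: r for r in exposure2.records}
    for rsid in wanted:
        rec = None
        r1, r2 = idx1.get(rsid), idx2.get(rsid)
        if r1 is not None and r2 is not None:
            rec = r1 if r1.pval <= r2.pval else r2
        else:
            rec = r1 or r2
        if rec is None:
            continue
        rows.append(rec)
    if not rows:
        raise InsufficientPanelError("no candidate SNPs found")
    union_stats = SummaryStats.from_records(
        "mvmr_union", "continuous", rows
    )
    # keep every pre-selected SNP regardless of its p-value here; the
    # joint clump only enforces pairwise independence
    permissive = ClumpConfig(
        p_threshold=1.0 - 1e-12,
        r2_threshold=cfg.r2_threshold,
        window_kb=cfg.window_kb,
    )
    kept = clump(union_stats, ld, permissive)

    pairs1 = {
        p.rsid: p
        for p in harmonize(exposure1, outcome, kept, proxies)
        if p.usable
    }
    pairs2 = {
        p.rsid: p
        for p in harmonize(exposure1, exposure2, kept, proxies)
        if p.usable
    }

    data = []
    for rsid in kept:
        p1 = pairs1.get(rsid)
        p2 = pairs2.get(rsid)
        if p1 is None or p2 is None:
            continue
        data.append(
            {
                "rsid": rsid,
                "beta_exp1": p1.beta_exp,
                "se_exp1": p1.se_exp,
                "beta_exp2": p2.beta_out,
                "se_exp2": p2.se_out,
                "beta_out": p1.beta_out,
                "se_out": p1.se_out,
            }
        )
    if len(data) < 3:
        raise InsufficientPanelError(
            f"only {len(data)} SNPs retained with complete associations "
            f"in all three datasets; at least 3 required"
        )
    return MvmrPanel(
        table=pd.DataFrame(data),
        exposure_names=(exposure1.trait_name, exposure2.trait_name),
        outcome_name=outcome.trait_name,
    )


def mvmr_ivw(panel: MvmrPanel) -> MvmrEstimate:
    """Weighted no-intercept regression of outcome betas on both
    exposures' betas (weights 1/se_out²).

    SEs use the classical covariance with the residual scale floored at
    1; p-values from t with k − 2 df.  Conditional F statistics report
    each exposure's instrument strength given the other.
    """
    t = panel.table
    k = len(t)
    X = t[["beta_exp1", "beta_exp2"]].to_numpy(dtype=float)
    y = t["beta_out"].to_numpy(dtype=float)
    w = 1.0 / t["se_out"].to_numpy(dtype=float) ** 2

    for j, name in enumerate(panel.exposure_names):
        if np.allclose(X[:, j], 0.0):
            raise CollinearityError(
                f"exposure {name!r} has an all-zero beta column"
            )
    XtW = X.T * w
    xtx = XtW @ X
    cond = np.linalg.cond(xtx)
    warn: list[str] = []
    if not np.isfinite(cond) or cond > CONDITION_WARN ** 2:
        # cond(X'WX) ~ cond(X)^2
        rank = np.linalg.matrix_rank(xtx)
        if rank < 2:
            raise CollinearityError(
                f"exposure design is rank-deficient (rank {rank}); "
                f"exposures {panel.exposure_names} are collinear"
            )
        warn.append("near_collinear_exposures")
        warnings.warn(
            f"MVMR exposure betas are nearly collinear "
            f"(condition number {math.sqrt(cond):.3g})",
            UserWarning,
            stacklevel=2,
        )
    coef = np.linalg.solve(xtx, XtW @ y)
    resid = y - X @ coef
    df = k - 2
    sigma2 = float(np.sum(w * resid ** 2) / df)
    scale = max(1.0, math.sqrt(sigma2))
    cov_unit = np.linalg.inv(xtx)
    ses = scale * np.sqrt(np.diag(cov_unit))
    tdist = sps.t(df=df)
    pvals = tuple(float(2.0 * tdist.sf(abs(c) / s))
                  for c, s in zip(coef, ses))

    se_exp = t[["se_exp1", "se_exp2"]].to_numpy(dtype=float)
    cond_f = _conditional_f(X, se_exp, k)
    return MvmrEstimate(
        exposure_names=panel.exposure_names,
        betas=(float(coef[0]), float(coef[1])),
        ses=(float(ses[0]), float(ses[1])),
        pvals=pvals,
        k=k,
        conditional_f=cond_f,
        warnings=tuple(warn),
    )


def _conditional_f(X: np.ndarray, se_exp: np.ndarray,
                   k: int) -> tuple[float, float]:
    """Approximate conditional instrument strength per exposure.

    Each exposure's betas are regressed on the other exposure's betas
    (weights = that exposure's inverse SE²); the heterogeneity of the
    residuals relative to the exposure's measurement error, divided by
    k − 1, approximates the conditional F.  Large values mean the
    exposure retains independent instrument signal after conditioning.
    """
    out = []
    for j in (0, 1):
        other = 1 - j
        wj = 1.0 / se_exp[:, j] ** 2
        denom = np.sum(wj * X[:, other] ** 2)
        if denom == 0:
            resid = X[:, j]
        else:
            b = np.sum(wj * X[:, other] * X[:, j]) / denom
            resid = X[:, j] - b * X[:, other]
        q = float(np.sum(wj * resid ** 2))
        out.append(q / max(k - 1, 1))
    return (float(out[0]), float(out[1]))
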