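"""Mediation decomposition of a total causal effect into direct and
mediated components.

Two standard two-step decompositions are provided:

* product of coefficients — indirect = (exposure→mediator effect) ×
  (mediator→outcome effect adjusted for the exposure), with the usual
  delta-method SE;
* difference in coefficients — indirect = total − direct, where the
  direct effect comes from a multivariable MR model adjusting for the
  mediator.

In a two-sample summary-data setting the covariance between the total
and direct estimates is not identifiable, so the difference method's SE
uses an independence approximation and is flagged as such.  The
proportion mediated is indirect/total; values outside [0, 1]
(inconsistent mediation / suppression) are reported as-is with a
warning, never truncated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .estimators import MREstimate
from .mvmr import MvmrEstimate

__all__ = ["MediationResult", "mediate_product", "mediate_difference"]


@dataclass(frozen=True, slots=True)
class MediationResult:
    method: str  # "product" | "difference"
    beta_total: float
    beta_direct: float | None
    beta_indirect: float
    se_indirect: float
    prop_mediated: float | None
    flags: tuple[str, ...] = ()


def _proportion(indirect: float, total: float) -> tuple[float | None,
                                                        list[str]]:
    flags: list[str] = []
    if total == 0.0:
        return None, ["proportion_undefined_zero_total"]
    prop = indirect / total
    if not (0.0 <= prop <= 1.0):
        flags.append("inconsistent_mediation")
        warnings.warn(
            f"proportion mediated {prop:.3g} lies outside [0, 1] "
            f"(inconsistent mediation); reported untruncated",
            UserWarning,
            stacklevel=3,
        )
    return prop, flags


def mediate_product(
    a: MREstimate, b: MREstimate, total: MREstimate
) -> MediationResult:
    """Product-of-coefficients decomposition.

    ``a`` is the exposure→mediator estimate (from the exposure's
    instruments), ``b`` the mediator→outcome estimate adjusted for the
    exposure (from the mediator's instruments via multivariable MR).
    indirect = a·b with SE sqrt(a²·se_b² + b²·se_a²).
    """
    indirect = a.beta * b.beta
    se = math.sqrt(a.beta ** 2 * b.se ** 2 + b.beta ** 2 * a.se ** 2)
    prop, flags = _proportion(indirect, total.beta)
    return MediationResult(
        method="product",
        beta_total=total.beta,
        beta_direct=None,
        beta_indirect=indirect,
        se_indirect=se,
        prop_mediated=prop,
        flags=tuple(flags),
    )


def mediate_difference(
    total: MREstimate, direct: MvmrEstimate | MREstimate
) -> MediationResult:
    """Difference decomposition: indirect = total − direct.

    The recomposition total = direct + indirect holds exactly by
    construction.  The SE combines the two estimates as if independent
    (flagged ``independent_se_approximation``), which two-sample summary
    data cannot improve on.
    """
    if isinstance(direct, MvmrEstimate):
        d_beta, d_se = direct.betas[0], direct.ses[0]
    else:
        d_beta, d_se = direct.beta, direct.se
    indirect = total.beta - d_beta
    se = math.sqrt(total.se ** 2 + d_se ** 2)
    prop, flags = _proportion(indirect, total.beta)
    return MediationResult(
        method="difference",
        beta_total=total.beta,
        beta_direct=d_beta,
        beta_indirect=indirect,
        se_indirect=se,
        prop_mediated=prop,
        flags=tuple(["independent_se_approximation"] + flags),
    )
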