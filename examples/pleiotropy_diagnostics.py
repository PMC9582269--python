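"""Heterogeneity and pleiotropy diagnostics on a contaminated panel.

Forty percent of the instruments carry directional pleiotropy, and one
instrument is additionally displaced by 10 outcome standard errors.
The example shows how Cochran's Q / I-squared, the MR-Egger intercept,
MR-PRESSO and leave-one-out react.
"""

import dataclasses
import warnings

import numpy as np

from mrkit import (
    PleiotropyConfig,
    SynthConfig,
    cochran_q,
    generate,
    harmonize,
    ivw_mre,
    leave_one_out,
    mr_presso,
    wald_ratios,
)
from mrkit.estimators import egger

cfg = SynthConfig(
    theta=np.log(1.10),
    seed=7,
    pleiotropy=PleiotropyConfig(mode="directional", mu_alpha=0.02,
                                sd_alpha=0.005, frac_invalid=0.4),
)
exposure, outcome, truth = generate(cfg)
pairs = harmonize(exposure, outcome, list(exposure.table["rsid"]))

# displace one instrument into an unambiguous outlier
spiked = pairs[4]
pairs[4] = dataclasses.replace(
    spiked, beta_out=spiked.beta_out + 10 * spiked.se_out
)

ratios = wald_ratios(pairs)
ivw = ivw_mre(ratios)
het = cochran_q(ratios, ivw.beta)
slope, intercept = egger(pairs)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    presso = mr_presso(pairs, nsim=2000, seed=11)
loo = leave_one_out(pairs)

print(f"IVW OR {ivw.or_scale[0]:.3f}, p = {ivw.pval:.3g}")
print(f"Cochran Q = {het.q:.2f} (df {het.df}), p = {het.pval:.3g}, "
      f"I2 = {het.i2:.1f}% ({het.band})")
print(f"Egger intercept = {intercept.beta:.4f}, p = {intercept.pval:.3g}")
print(f"MR-PRESSO global p = {presso.global_p:.4g}, "
      f"outliers: {list(presso.outlier_rsids)}")
if presso.corrected is not None:
    print(f"outlier-corrected IVW OR {presso.corrected.or_scale[0]:.3f}")
print(f"leave-one-out influential: {list(loo.influential_rsids)}")

print(
    "\nHigh I2 and a small PRESSO global p signal that some\n"
    "instruments act on the outcome outside the exposure pathway, and\n"
    "the spiked SNP appears in the outlier list.  Outlier removal only\n"
    "repairs gross violations: the remaining directional pleiotropy\n"
    "(40% of instruments) still biases the corrected IVW away from the\n"
    "true OR of 1.10, which is why median and Egger sensitivity\n"
    "analyses are reported alongside."
)
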