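"""Univariable two-sample MR on a synthetic dataset.

Generates summary statistics for 12 instruments under a true odds
ratio of 1.10 per unit genetic liability, harmonizes exposure and
outcome, and compares the IVW, median and MR-Egger estimates.
"""

import numpy as np

from mrkit import SynthConfig, generate, harmonize, ivw_mre, wald_ratios
from mrkit.estimators import egger, simple_median, weighted_median

TRUE_OR = 1.10

cfg = SynthConfig(theta=np.log(TRUE_OR), seed=77)
exposure, outcome, truth = generate(cfg)
pairs = harmonize(exposure, outcome, list(exposure.table["rsid"]))
ratios = wald_ratios(pairs)

estimates = [
    ivw_mre(ratios),
    simple_median(ratios, boot_reps=1000, seed=1),
    weighted_median(ratios, boot_reps=1000, seed=2),
    egger(pairs)[0],
]

print(f"true OR = {TRUE_OR}, k = {len(ratios)} instruments\n")
print(f"{'method':<16}{'OR':>8}{'95% CI':>18}{'p':>10}")
for est in estimates:
    or_, lo, hi = est.or_scale
    print(f"{est.method:<16}{or_:>8.3f}{f'({lo:.3f}, {hi:.3f})':>18}"
          f"{est.pval:>10.3g}")

print(
    "\nEach line is the causal odds ratio of the outcome per unit of\n"
    "genetic liability to the exposure.  With no pleiotropy the\n"
    "methods agree up to sampling noise; MR-Egger trades precision\n"
    "for robustness, so its interval is the widest at k = 12."
)
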