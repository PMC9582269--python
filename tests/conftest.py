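import numpy as np
import pandas as pd
import pytest

from mrkit.gwas_io import CANONICAL_COLUMNS, SummaryStats


def make_stats(
    rsids,
    betas,
    ses,
    *,
    trait_name="trait",
    trait_type="binary",
    chroms=None,
    positions=None,
    eafs=None,
    pvals=None,
    n=100_000,
    effect_alleles=None,
    other_alleles=None,
):
    """Assemble a SummaryStats from parallel lists, with sensible
    defaults for the fields a test does not care about."""
    k = len(rsids)
    from scipy import stats as sps

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if pvals is None:
        pvals = 2.0 * sps.norm.sf(np.abs(betas) / ses)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": chroms if chroms is not None else ["1"] * k,
            "pos": positions if positions is not None
            else [1000 * (i + 1) for i in range(k)],
            "effect_allele": effect_alleles if effect_alleles is not None
            else ["A"] * k,
            "other_allele": other_alleles if other_alleles is not None
            else ["G"] * k,
            "eaf": eafs if eafs is not None else [0.3] * k,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n": [n] * k,
        },
        columns=list(CANONICAL_COLUMNS),
    )
    return SummaryStats(trait_name=trait_name, trait_type=trait_type,
                        table=table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
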