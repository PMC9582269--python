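"""Instrument selection and strength: p-value thresholding, greedy LD
clumping, per-SNP variance explained, F statistics and a-priori power.

LD between candidate SNPs is supplied as a precomputed pairwise r²
matrix (e.g. derived from a European 1000 Genomes reference panel);
this module never touches genotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .gwas_io import SnpRecord, SummaryStats

__all__ = [
    "ClumpConfig",
    "LdMatrix",
    "InstrumentStrength",
    "NoInstrumentsError",
    "clump",
    "snp_r2",
    "f_stat",
    "instrument_strength",
    "apriori_power",
]

log = logging.getLogger(__name__)


class NoInstrumentsError(ValueError):
    """No SNP passes the selection threshold."""


@dataclass(frozen=True, slots=True)
class ClumpConfig:
    """Greedy-clumping parameters.

    Defaults: suggestive-significance threshold 5e-7, independence cut
    r² < 0.01, distance window 10,000 kb.
    """

    p_threshold: float = 5e-7
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in [0, 1]")
        if not (self.window_kb > 0):
            raise ValueError("window_kb must be positive")


class LdMatrix:
    """Sparse symmetric pairwise-r² lookup keyed by rsid.

    Pairs absent from the table are treated as unlinked (r² = 0); the
    diagonal is implicitly 1.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {r2}")
        if a == b and r2 != 1.0:
            raise ValueError("diagonal entries must equal 1")
        self._r2[frozenset((a, b))] = r2

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def has(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self._r2

    @classmethod
    def read_tsv(cls, path) -> "LdMatrix":
        """Load r² triplets from TSV (rsid_a, rsid_b, r2)."""
        frame = pd.read_csv(str(path), sep="\t", dtype=str)
        out = cls()
        for row in frame.itertuples(index=False):
            out.set(row.rsid_a, row.rsid_b, float(row.r2))
        return out

    def write_tsv(self, path) -> None:
        with open(str(path), "wt") as fh:
            fh.write("rsid_a\trsid_b\tr2\n")
            for key, r2 in sorted(
                self._r2.items(), key=lambda kv: sorted(kv[0])
            ):
                pair = sorted(key)
                a, b = (pair[0], pair[0]) if len(pair) == 1 else pair
                fh.write(f"{a}\t{b}\t{r2:.10g}\n")


def clump(
    stats: SummaryStats, ld: LdMatrix, cfg: ClumpConfig | None = None
) -> list[str]:
    """Greedy LD clumping.

    Repeatedly take the smallest-p SNP below the significance threshold
    and discard every remaining SNP on the same chromosome within the
    distance window whose r² with it reaches the LD cut.  Ties in p are
    broken by ascending position, then rsid, so the result is
    deterministic.  Returns rsids ordered by ascending p.
    """
    cfg = cfg or ClumpConfig()
    table = stats.table
    candidates = table[table["pval"].astype(float) < cfg.p_threshold]
    if candidates.empty:
        raise NoInstrumentsError(
            f"no SNP passes p < {cfg.p_threshold:g} for trait "
            f"{stats.trait_name!r}"
        )

    rows = sorted(
        candidates.itertuples(index=False),
        key=lambda r: (float(r.pval), int(r.pos), str(r.rsid)),
    )
    window_bp = cfg.window_kb * 1000.0
    selected: list = []
    remaining = list(rows)
    while remaining:
        index = remaining.pop(0)
        selected.append(index)
        survivors = []
        for r in remaining:
            same_chrom = str(r.chrom) == str(index.chrom)
            in_window = abs(int(r.pos) - int(index.pos)) <= window_bp
            if same_chrom and in_window:
                if not ld.has(index.rsid, r.rsid):
                    log.warning(
                        "no LD entry for (%s, %s); assuming unlinked",
                        index.rsid, r.rsid,
                    )
                if ld.get(index.rsid, r.rsid) >= cfg.r2_threshold:
                    continue
            survivors.append(r)
        remaining = survivors
    return [r.rsid for r in selected]


def snp_r2(rec: SnpRecord) -> float:
    """Trait variance explained by one SNP.

    R² = 2·EAF·(1−EAF)·β² / (2·EAF·(1−EAF)·β² + 2·EAF·(1−EAF)·N·se²),
    which simplifies to β² / (β² + N·se²); the allele-frequency factor
    cancels but the full form is kept for fidelity to the usual
    presentation.
    """
    if not (0.0 < rec.eaf < 1.0):
        raise ValueError(
            f"{rec.rsid}: eaf must lie strictly inside (0, 1) to define "
            f"variance explained"
        )
    if rec.n <= 1:
        raise ValueError(f"{rec.rsid}: n must exceed 1")
    var_term = 2.0 * rec.eaf * (1.0 - rec.eaf)
    num = var_term * rec.beta ** 2
    den = var_term * rec.beta ** 2 + var_term * rec.n * rec.se ** 2
    return num / den


def f_stat(r2: float, n: int) -> float:
    """Instrument-strength F statistic: F = R²·(N−2)/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


@dataclass(frozen=True, slots=True)
class InstrumentStrength:
    rsid: str
    r2: float
    f: float


def instrument_strength(stats: SummaryStats,
                        instruments: list[str]) -> list[InstrumentStrength]:
    """Per-instrument variance explained and F statistic."""
    idx = {r.rsid: r for r in stats.records}
    out = []
    for rsid in instruments:
        rec = idx[rsid]
        r2 = snp_r2(rec)
        out.append(InstrumentStrength(rsid=rsid, r2=r2,
                                      f=f_stat(r2, rec.n)))
    return out


def apriori_power(
    total_r2: float,
    n_outcome: int,
    case_fraction: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """A-priori power for a binary-outcome MR test.

    Uses the standard non-centrality approximation for a Wald test of a
    log odds ratio estimated through instruments explaining ``total_r2``
    of the exposure variance:

        λ = N·R²·cf·(1−cf)·ln(OR)²
        power = 1 − Φ(z_{1−α/2} − √λ) + Φ(−z_{1−α/2} − √λ)
    """
    if not (0.0 <= total_r2 < 1.0):
        raise ValueError("total_r2 must lie in [0, 1)")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError("case_fraction must lie in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    lam = (
        n_outcome
        * total_r2
        * case_fraction
        * (1.0 - case_fraction)
        * math.log(or_alt) ** 2
    )
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    s = math.sqrt(lam)
    return float(sps.norm.sf(z - s) + sps.norm.cdf(-z - s))
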