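"""Aligning exposure and outcome effect estimates to shared effect alleles.

Two GWAS report each SNP relative to an arbitrary choice of effect
allele, possibly on opposite DNA strands.  Before any ratio estimate can
be formed, the outcome effect must be expressed relative to the
exposure's effect allele:

* same allele pair, same orientation → keep as-is;
* alleles swapped → negate the outcome beta and reflect its frequency;
* alleles on the opposite strand → complement, then align;
* palindromic SNPs (A/T or C/G) are strand-ambiguous: when the exposure
  frequency is close to 0.5 the orientation cannot be inferred and the
  SNP is dropped; otherwise frequency agreement decides the strand;
* instruments absent from the outcome GWAS are substituted by an LD
  proxy when one is supplied, otherwise dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .gwas_io import SnpRecord, SummaryStats

__all__ = [
    "HarmonizedPair",
    "ProxyEntry",
    "ProxyMap",
    "harmonize",
    "apply_proxies",
    "read_proxy_map",
    "write_harmonization_report",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: statuses that leave a usable effect pair
USABLE_STATUSES = frozenset({"kept", "flipped", "proxied"})

#: default half-width of the exposure-frequency window around 0.5 inside
#: which a palindromic SNP's strand is considered unresolvable
DEFAULT_PALINDROME_EAF_WINDOW = 0.08


class ProxyValidationError(ValueError):
    """A proxy entry fails the LD-quality requirement (r2 must exceed 0.60)."""


@dataclass(frozen=True, slots=True)
class HarmonizedPair:
    """Exposure and outcome effects for one instrument, on a shared
    effect allele.  ``status`` records how alignment was achieved (or
    why the SNP was lost)."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float | None
    status: str
    reason: str = ""

    @property
    def usable(self) -> bool:
        return self.status in USABLE_STATUSES


@dataclass(frozen=True, slots=True)
class ProxyEntry:
    target_rsid: str
    proxy_rsid: str
    r2: float
    # maps each target allele to the corresponding proxy allele
    allele_map: Mapping[str, str]


class ProxyMap:
    """Validated target→proxy substitution table.

    Every entry must have LD r² > 0.60 with its target; weaker proxies
    are refused at construction.
    """

    R2_MIN = 0.60

    def __init__(self, entries: Iterable[ProxyEntry] = ()):
        self._entries: dict[str, ProxyEntry] = {}
        for e in entries:
            if not (e.r2 > self.R2_MIN):
                raise ProxyValidationError(
                    f"proxy {e.proxy_rsid} for {e.target_rsid} has "
                    f"r2={e.r2}, below the {self.R2_MIN} threshold"
                )
            self._entries[e.target_rsid] = e

    def get(self, target_rsid: str) -> ProxyEntry | None:
        return self._entries.get(target_rsid)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, target_rsid: str) -> bool:
        return target_rsid in self._entries


def read_proxy_map(path) -> ProxyMap:
    """Load a proxy table from TSV with columns
    target_rsid, proxy_rsid, r2, allele_map (e.g. ``A=G,C=T``)."""
    frame = pd.read_csv(str(path), sep="\t", dtype=str)
    entries = []
    for row in frame.itertuples(index=False):
        amap = {}
        for pair in str(row.allele_map).split(","):
            tgt, prox = pair.split("=")
            amap[tgt.strip().upper()] = prox.strip().upper()
        entries.append(
            ProxyEntry(
                target_rsid=row.target_rsid,
                proxy_rsid=row.proxy_rsid,
                r2=float(row.r2),
                allele_map=amap,
            )
        )
    return ProxyMap(entries)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _complement_alleles(a1: str, a2: str) -> tuple[str, str] | None:
    try:
        return _COMPLEMENT[a1], _COMPLEMENT[a2]
    except KeyError:
        return None


def _align_one(
    exp: SnpRecord,
    out: SnpRecord,
    palindrome_eaf_window: float,
    status_if_kept: str = "kept",
) -> HarmonizedPair:
    """Orient one outcome record onto the exposure's effect allele."""
    ea, oa = exp.effect_allele, exp.other_allele

    if not exp.is_snv or not out.is_snv:
        return _dropped(exp, "dropped_missing", "non_snv_alleles")

    if _is_palindromic(ea, oa):
        if abs(exp.eaf - 0.5) < palindrome_eaf_window:
            return _dropped(exp, "dropped_palindromic",
                            "exposure_eaf_near_0.5")
        # Strand inferred from frequency agreement below; an outcome
        # frequency is required for that.
        if out.eaf is None or not (0.0 <= out.eaf <= 1.0):
            return _dropped(exp, "dropped_palindromic", "no_outcome_eaf")
        same_side = (exp.eaf - 0.5) * (out.eaf - 0.5) > 0
        if (out.effect_allele, out.other_allele) == (ea, oa):
            if same_side:
                return _pair(exp, out, flip=False, status=status_if_kept)
            return _pair(exp, out, flip=True, status="flipped")
        if (out.effect_allele, out.other_allele) == (oa, ea):
            if same_side:
                return _pair(exp, out, flip=False, status=status_if_kept)
            return _pair(exp, out, flip=True, status="flipped")
        return _dropped(exp, "dropped_missing", "allele_mismatch")

    out_ea, out_oa = out.effect_allele, out.other_allele
    if (out_ea, out_oa) == (ea, oa):
        return _pair(exp, out, flip=False, status=status_if_kept)
    if (out_ea, out_oa) == (oa, ea):
        return _pair(exp, out, flip=True, status="flipped")

    comp = _complement_alleles(out_ea, out_oa)
    if comp is not None:
        c_ea, c_oa = comp
        if (c_ea, c_oa) == (ea, oa):
            return _pair(exp, out, flip=False, status=status_if_kept)
        if (c_ea, c_oa) == (oa, ea):
            return _pair(exp, out, flip=True, status="flipped")
    return _dropped(exp, "dropped_missing", "allele_mismatch")


def _pair(exp: SnpRecord, out: SnpRecord, flip: bool,
          status: str) -> HarmonizedPair:
    beta_out = -out.beta if flip else out.beta
    eaf_out = (1.0 - out.eaf) if flip else out.eaf
    return HarmonizedPair(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        status=status,
    )


def _dropped(exp: SnpRecord, status: str, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=float("nan"),
        se_out=float("nan"),
        eaf_exp=exp.eaf,
        eaf_out=None,
        status=status,
        reason=reason,
    )


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instruments: list[str],
    proxies: ProxyMap | None = None,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> list[HarmonizedPair]:
    """Harmonize the instrument set across exposure and outcome GWAS.

    Returns one :class:`HarmonizedPair` per instrument, in instrument
    order; pairs that could not be aligned carry a ``dropped_*`` status
    and a reason, never a silently wrong orientation.
    """
    proxies = proxies if proxies is not None else ProxyMap()
    exp_idx = {r.rsid: r for r in exposure.records}
    out_idx = {r.rsid: r for r in outcome.records}

    missing_exp = [rs for rs in instruments if rs not in exp_idx]
    if missing_exp:
        raise KeyError(
            f"instruments absent from exposure GWAS: {missing_exp[:5]}"
        )

    pairs: list[HarmonizedPair] = []
    for rsid in instruments:
        exp = exp_idx[rsid]
        out = out_idx.get(rsid)
        if out is None:
            entry = proxies.get(rsid)
            if entry is None or entry.proxy_rsid not in out_idx:
                pairs.append(
                    _dropped(exp, "dropped_missing", "absent_from_outcome")
                )
                continue
            out = _proxy_as_target(exp, out_idx[entry.proxy_rsid], entry)
            if out is None:
                pairs.append(
                    _dropped(exp, "dropped_missing", "proxy_allele_mismatch")
                )
                continue
            pairs.append(
                _align_one(exp, out, palindrome_eaf_window,
                           status_if_kept="proxied")
            )
            continue
        pairs.append(_align_one(exp, out, palindrome_eaf_window))
    return pairs


def _proxy_as_target(
    exp: SnpRecord, proxy_rec: SnpRecord, entry: ProxyEntry
) -> SnpRecord | None:
    """Re-express a proxy SNP's outcome record in the target's allele
    coordinates through the entry's allele correspondence.  The proxy's
    effect size is used as-is (no attenuation by r²)."""
    inverse = {v: k for k, v in entry.allele_map.items()}
    t_ea = inverse.get(proxy_rec.effect_allele)
    t_oa = inverse.get(proxy_rec.other_allele)
    if t_ea is None or t_oa is None or t_ea == t_oa:
        return None
    return SnpRecord(
        rsid=exp.rsid,
        chrom=proxy_rec.chrom,
        pos=proxy_rec.pos,
        effect_allele=t_ea,
        other_allele=t_oa,
        eaf=proxy_rec.eaf,
        beta=proxy_rec.beta,
        se=proxy_rec.se,
        pval=proxy_rec.pval,
        n=proxy_rec.n,
    )


def apply_proxies(
    outcome: SummaryStats,
    missing: list[str],
    proxies: ProxyMap,
) -> tuple[dict[str, SnpRecord], list[str]]:
    """Resolve missing outcome rsids through the proxy map.

    Returns ``(substitutions, unproxied)``: substitutions map each
    resolvable missing rsid to the proxy's outcome record re-expressed in
    target alleles; ``unproxied`` lists rsids with no usable proxy — the
    analysis then proceeds on the reduced instrument set.
    """
    out_idx = {r.rsid: r for r in outcome.records}
    substitutions: dict[str, SnpRecord] = {}
    unproxied: list[str] = []
    for rsid in missing:
        entry = proxies.get(rsid)
        if entry is None or entry.proxy_rsid not in out_idx:
            unproxied.append(rsid)
            continue
        rec = out_idx[entry.proxy_rsid]
        target_stub = SnpRecord(
            rsid=rsid, chrom=rec.chrom, pos=rec.pos,
            effect_allele=rec.effect_allele,
            other_allele=rec.other_allele, eaf=rec.eaf, beta=rec.beta,
            se=rec.se, pval=rec.pval, n=rec.n,
        )
        mapped = _proxy_as_target(target_stub, rec, entry)
        if mapped is None:
            unproxied.append(rsid)
            continue
        substitutions[rsid] = mapped
    return substitutions, unproxied


def pairs_to_frame(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """Tabulate harmonized pairs (all statuses) as a DataFrame."""
    return pd.DataFrame(
        {
            "rsid": [p.rsid for p in pairs],
            "beta_exp": [p.beta_exp for p in pairs],
            "se_exp": [p.se_exp for p in pairs],
            "beta_out": [p.beta_out for p in pairs],
            "se_out": [p.se_out for p in pairs],
            "eaf_exp": [p.eaf_exp for p in pairs],
            "eaf_out": [p.eaf_out for p in pairs],
            "status": [p.status for p in pairs],
            "reason": [p.reason for p in pairs],
        }
    )


def write_harmonization_report(pairs: list[HarmonizedPair], path) -> None:
    pairs_to_frame(pairs)[["rsid", "status", "reason"]].to_csv(
        str(path), sep="\t", index=False
    )
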