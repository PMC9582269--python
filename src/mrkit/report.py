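"""Multiple-testing correction, results assembly, and full-pipeline
orchestration.

``run_pipeline`` wires the stages together for one exposure against a
panel of outcomes: instrument selection → harmonization → estimation
(IVW, medians, Egger) → robustness diagnostics → BH false-discovery
correction of the primary IVW p-values — optionally repeated in the
reverse direction (each outcome as exposure) and extended with
multivariable-MR adjustments and mediation decompositions.  Every
stochastic step draws from a stream derived deterministically from one
root seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .estimators import (
    MREstimate,
    egger,
    ivw_mre,
    simple_median,
    wald_ratios,
    weighted_median,
)
from .gwas_io import SummaryStats, read_sumstats
from .harmonize import ProxyMap, harmonize, read_proxy_map
from .instruments import (
    ClumpConfig,
    LdMatrix,
    NoInstrumentsError,
    clump,
    instrument_strength,
)
from .mediation import MediationResult, mediate_difference
from .mvmr import (
    InsufficientPanelError,
    MvmrEstimate,
    build_mvmr_panel,
    mvmr_ivw,
)
from .robustness import (
    HeterogeneityResult,
    LooTable,
    PressoResult,
    cochran_q,
    leave_one_out,
    mr_presso,
)

__all__ = ["bh_fdr", "OutcomePanelResult", "PipelineResult",
           "run_pipeline", "forest_table"]

log = logging.getLogger(__name__)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg q-values, aligned to the input order.

    q_(i) = min(p_(i)·m/i, q_(i+1)) over the ascending order statistics.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OutcomePanelResult:
    """Everything computed for one exposure→outcome pair."""

    exposure: str
    outcome: str
    k: int = 0
    ivw: MREstimate | None = None
    simple_median: MREstimate | None = None
    weighted_median: MREstimate | None = None
    egger_slope: MREstimate | None = None
    egger_intercept: MREstimate | None = None
    heterogeneity: HeterogeneityResult | None = None
    presso: PressoResult | None = None
    loo: LooTable | None = None
    mvmr: dict[str, MvmrEstimate] = field(default_factory=dict)
    mediation: dict[str, MediationResult] = field(default_factory=dict)
    qval: float | None = None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class PipelineResult:
    forward: list[OutcomePanelResult]
    reverse: list[OutcomePanelResult]
    instruments: list[str]
    manifest: dict


def _derive_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def analyze_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instruments: list[str],
    proxies: ProxyMap | None = None,
    se_mode: str = "first_order",
    boot_reps: int = 1000,
    presso_nsim: int = 1000,
    seed: int = 0,
    run_presso: bool = True,
) -> OutcomePanelResult:
    """Univariable MR with full diagnostics for one pair.

    Library entry point used by the pipeline; any stage error is caught
    and recorded on the result instead of propagating.
    """
    res = OutcomePanelResult(exposure=exposure.trait_name,
                             outcome=outcome.trait_name)
    seeds = _derive_seeds(seed, 3)
    try:
        pairs = harmonize(exposure, outcome, instruments, proxies)
        usable = [p for p in pairs if p.usable]
        res.k = len(usable)
        ratios = wald_ratios(pairs, se_mode)
        res.ivw = ivw_mre(ratios)
        if res.k >= 3:
            res.simple_median = simple_median(ratios, boot_reps, seeds[0])
            res.weighted_median = weighted_median(ratios, boot_reps,
                                                  seeds[1])
            res.egger_slope, res.egger_intercept = egger(pairs)
            res.loo = leave_one_out(pairs)
        if res.k >= 2:
            res.heterogeneity = cochran_q(ratios, res.ivw.beta)
        if run_presso and res.k >= 4:
            res.presso = mr_presso(pairs, nsim=presso_nsim, seed=seeds[2])
    except Exception as exc:  # tabulated, not fatal for the run
        res.error = f"{type(exc).__name__}: {exc}"
        log.error("pair %s -> %s failed: %s", res.exposure, res.outcome,
                  res.error)
    return res


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "rt") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config) -> PipelineResult:
    """Execute the full analysis described by a configuration mapping
    (or a YAML file path).

    Recognised keys: ``exposure`` (path), ``outcomes`` (list of paths),
    ``ld_matrix``/``proxies`` (optional paths), ``p_threshold``,
    ``r2_threshold``, ``window_kb``, ``se_mode``, ``boot_reps``,
    ``presso_nsim``, ``seed``, ``reverse`` (bool), ``mvmr`` (list of
    adjustment-trait paths), ``mediation`` (list of mediator paths,
    must also appear under ``mvmr``).

    A fatal error in one exposure–outcome pair is tabulated on that
    pair's result; the run continues.
    """
    t0 = time.time()
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    clump_cfg = ClumpConfig(
        p_threshold=float(cfg.get("p_threshold", 5e-7)),
        r2_threshold=float(cfg.get("r2_threshold", 0.01)),
        window_kb=float(cfg.get("window_kb", 10_000)),
    )
    se_mode = cfg.get("se_mode", "first_order")
    boot_reps = int(cfg.get("boot_reps", 1000))
    presso_nsim = int(cfg.get("presso_nsim", 1000))

    exposure = read_sumstats(cfg["exposure"], trait_type="binary")
    outcomes = [read_sumstats(p, trait_type="binary")
                for p in cfg["outcomes"]]
    ld = (LdMatrix.read_tsv(cfg["ld_matrix"])
          if cfg.get("ld_matrix") else LdMatrix())
    proxies = (read_proxy_map(cfg["proxies"])
               if cfg.get("proxies") else ProxyMap())

    instruments = clump(exposure, ld, clump_cfg)
    strengths = instrument_strength(exposure, instruments)

    pair_seeds = _derive_seeds(seed, 2 * len(outcomes) + 1)
    forward: list[OutcomePanelResult] = []
    for i, outcome in enumerate(outcomes):
        forward.append(
            analyze_pair(
                exposure, outcome, instruments, proxies,
                se_mode=se_mode, boot_reps=boot_reps,
                presso_nsim=presso_nsim, seed=pair_seeds[i],
            )
        )

    # FDR family: the primary IVW p-values of this direction
    _attach_qvals(forward)

    adjustment_paths = cfg.get("mvmr") or []
    mediator_paths = cfg.get("mediation") or []
    for adj_path in adjustment_paths:
        adj = read_sumstats(adj_path, trait_type="continuous")
        try:
            adj_instruments = clump(adj, ld, clump_cfg)
        except NoInstrumentsError as exc:
            log.error("no instruments for adjustment trait %s: %s",
                      adj.trait_name, exc)
            continue
        for res, outcome in zip(forward, outcomes):
            if res.failed:
                continue
            try:
                panel = build_mvmr_panel(
                    exposure, adj, outcome, instruments,
                    adj_instruments, ld, clump_cfg, proxies,
                    instrument_source=cfg.get("mvmr_instruments",
                                              "union"),
                )
                est = mvmr_ivw(panel)
                res.mvmr[adj.trait_name] = est
                if adj_path in mediator_paths and res.ivw is not None:
                    res.mediation[adj.trait_name] = mediate_difference(
                        res.ivw, est
                    )
            except (InsufficientPanelError, ValueError) as exc:
                log.error("MVMR %s adjusting %s failed: %s",
                          res.outcome, adj.trait_name, exc)

    reverse: list[OutcomePanelResult] = []
    if cfg.get("reverse", False):
        for i, outcome in enumerate(outcomes):
            try:
                rev_instruments = clump(outcome, ld, clump_cfg)
            except NoInstrumentsError as exc:
                rev = OutcomePanelResult(
                    exposure=outcome.trait_name,
                    outcome=exposure.trait_name,
                    error=f"NoInstrumentsError: {exc}",
                )
                reverse.append(rev)
                continue
            reverse.append(
                analyze_pair(
                    outcome, exposure, rev_instruments, proxies,
                    se_mode=se_mode, boot_reps=boot_reps,
                    presso_nsim=presso_nsim,
                    seed=pair_seeds[len(outcomes) + i],
                )
            )
        _attach_qvals(reverse)

    manifest = {
        "package_version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "n_instruments": len(instruments),
        "instruments": instruments,
        "min_f_stat": min((s.f for s in strengths), default=None),
        "total_r2": sum(s.r2 for s in strengths),
        "per_pair_k": {r.outcome: r.k for r in forward},
        "failed_pairs": [r.outcome for r in forward if r.failed],
        "elapsed_s": None,  # filled below
    }
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    return PipelineResult(
        forward=forward, reverse=reverse, instruments=instruments,
        manifest=manifest,
    )


def _attach_qvals(results: list[OutcomePanelResult]) -> None:
    ok = [r for r in results if not r.failed and r.ivw is not None]
    if not ok:
        return
    qvals = bh_fdr([r.ivw.pval for r in ok])
    for r, q in zip(ok, qvals):
        r.qval = float(q)


def forest_table(results: list[OutcomePanelResult]) -> pd.DataFrame:
    """Long-format estimates table: one row per outcome × method, with
    both log-odds and odds-ratio scales.  Failed pairs appear as
    explicit NA rows."""
    rows = []
    for res in results:
        named = [
            ("ivw_mre", res.ivw),
            ("simple_median", res.simple_median),
            ("weighted_median", res.weighted_median),
            ("egger_slope", res.egger_slope),
            ("egger_intercept", res.egger_intercept),
        ]
        any_row = False
        for method, est in named:
            if est is None:
                continue
            any_row = True
            or_, or_lo, or_hi = est.or_scale
            rows.append(
                {
                    "exposure": res.exposure,
                    "outcome": res.outcome,
                    "method": method,
                    "k": est.k,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "or": or_,
                    "or_low": or_lo,
                    "or_high": or_hi,
                    "qval": res.qval if method == "ivw_mre" else np.nan,
                }
            )
        if not any_row:
            rows.append(
                {
                    "exposure": res.exposure,
                    "outcome": res.outcome,
                    "method": "NA",
                    "k": res.k,
                    "beta": np.nan,
                    "se": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "pval": np.nan,
                    "or": np.nan,
                    "or_low": np.nan,
                    "or_high": np.nan,
                    "qval": np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the forest table, robustness report and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    forest_table(result.forward).to_csv(
        outdir / "forest_forward.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    if result.reverse:
        forest_table(result.reverse).to_csv(
            outdir / "forest_reverse.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
    _robustness_frame(result.forward).to_csv(
        outdir / "robustness_forward.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def _robustness_frame(results: list[OutcomePanelResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        het = res.heterogeneity
        rows.append(
            {
                "exposure": res.exposure,
                "outcome": res.outcome,
                "q": het.q if het else np.nan,
                "df": het.df if het else np.nan,
                "het_pval": het.pval if het else np.nan,
                "i2_pct": het.i2 if het else np.nan,
                "band": het.band if het else "NA",
                "egger_intercept": (
                    res.egger_intercept.beta if res.egger_intercept
                    else np.nan
                ),
                "egger_intercept_p": (
                    res.egger_intercept.pval if res.egger_intercept
                    else np.nan
                ),
                "presso_global_p": (
                    res.presso.global_p if res.presso else np.nan
                ),
                "presso_outliers": (
                    ",".join(res.presso.outlier_rsids)
                    if res.presso and res.presso.outlier_rsids else ""
                ),
                "loo_influential": (
                    ",".join(res.loo.influential_rsids)
                    if res.loo and res.loo.influential_rsids else ""
                ),
                "error": res.error or "",
            }
        )
    return pd.DataFrame(rows)
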