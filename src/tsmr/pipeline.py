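"""End-to-end orchestration over an exposures x outcomes grid.

For every exposure-outcome pair: genome-wide filter -> LD prune -> proxy
substitution -> harmonization -> {IVW, weighted median, MR-Egger}, a
Bonferroni threshold from that pair's final (post-harmonization) instrument
count, and an optional sensitivity re-run excluding a user-supplied variant
list.  One degenerate pair never aborts the grid; its error is recorded in
the JSON mirror instead.  Given the same config, input files and seed the
JSON mirror is byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import harmonize as hz
from . import instruments as ins
from . import mr_estimators as est
from .sumstats_io import (
    LDTable,
    MRResult,
    SummaryStatTable,
    read_ld_table,
    read_sumstats,
    write_results,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ExposureSpec:
    label: str
    path: str
    exclusion_path: str | None = None


@dataclass
class OutcomeSpec:
    label: str
    path: str


@dataclass
class AnalysisConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    out_dir: str = "mr_results"
    ld_path: str | None = None
    p_threshold: float = ins.GENOME_WIDE_P
    r2_prune: float = ins.DEFAULT_R2_PRUNE
    r2_proxy: float = ins.DEFAULT_R2_PROXY
    palindromic_policy: str = "drop"
    eaf_tolerance: float = hz.DEFAULT_EAF_TOLERANCE
    n_boot: int = est.DEFAULT_N_BOOT
    seed: int = 0
    column_map: dict | None = None

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("config needs at least one exposure and one outcome")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        exposures = [
            ExposureSpec(e["label"], e["path"], e.get("exclusions"))
            for e in raw["exposures"]
        ]
        outcomes = [OutcomeSpec(o["label"], o["path"]) for o in raw["outcomes"]]
        thresholds = raw.get("thresholds", {})
        return cls(
            exposures=exposures,
            outcomes=outcomes,
            out_dir=raw.get("out_dir", "mr_results"),
            ld_path=raw.get("ld"),
            p_threshold=float(thresholds.get("p", ins.GENOME_WIDE_P)),
            r2_prune=float(thresholds.get("r2_prune", ins.DEFAULT_R2_PRUNE)),
            r2_proxy=float(thresholds.get("r2_proxy", ins.DEFAULT_R2_PROXY)),
            palindromic_policy=raw.get("palindromic_policy", "drop"),
            eaf_tolerance=float(raw.get("eaf_tolerance", hz.DEFAULT_EAF_TOLERANCE)),
            n_boot=int(raw.get("n_boot", est.DEFAULT_N_BOOT)),
            seed=int(raw.get("seed", 0)),
            column_map=raw.get("column_map"),
        )


def _pair_seed(seed: int, index: int, stream: int = 0) -> int:
    """Stable per-pair bootstrap seed derived from the global seed."""
    return int(np.random.SeedSequence([seed, index, stream]).generate_state(1)[0] % 2**31)


def _run_estimators(
    harmonized: list[hz.HarmonizedInstrument], n_boot: int, seed: int
) -> tuple[dict[str, MRResult | None], dict[str, str]]:
    """Run all three estimators; failures become missing cells with reasons."""
    results: dict[str, MRResult | None] = {}
    reasons: dict[str, str] = {}
    for name, runner in (
        ("IVW", lambda: est.ivw(harmonized)),
        ("weighted_median", lambda: est.weighted_median(harmonized, n_boot=n_boot, seed=seed)),
        ("mr_egger", lambda: est.mr_egger(harmonized)),
    ):
        try:
            results[name] = runner()
        except (ValueError, est.DegenerateInstrumentError) as exc:
            results[name] = None
            reasons[name] = str(exc)
            logger.warning("estimator %s failed: %s", name, exc)
    return results, reasons


def _estimates_block(results: dict[str, MRResult | None], reasons: dict[str, str]) -> dict:
    return {
        name: (res.to_dict() if res is not None else {"error": reasons.get(name, "failed")})
        for name, res in results.items()
    }


def _significance_block(results: dict[str, MRResult | None], threshold: float) -> dict:
    return {
        name: (res.pval < threshold if res is not None else None)
        for name, res in results.items()
    }


def _analyse_pair(
    instruments: ins.InstrumentSet,
    exposure_table: SummaryStatTable,
    outcome_table: SummaryStatTable,
    ld: LDTable,
    cfg: AnalysisConfig,
    seed: int,
) -> tuple[dict, dict[str, MRResult | None], hz.HarmonizationResult]:
    with_proxies = ins.substitute_proxies(
        instruments, outcome_table, exposure_table, ld, r2_min=cfg.r2_proxy
    )
    harmonization = hz.harmonize_tables(
        with_proxies,
        outcome_table,
        palindromic_policy=cfg.palindromic_policy,
        eaf_tolerance=cfg.eaf_tolerance,
    )
    harmonized = harmonization.instruments
    results, reasons = _run_estimators(harmonized, cfg.n_boot, seed)
    n_final = len(harmonized)
    threshold = est.bonferroni_threshold(n_final, ALPHA)
    block = {
        "n_instruments_selected": len(instruments),
        "n_instruments_final": n_final,
        "n_proxies": sum(
            1 for p in with_proxies.provenance.values() if p.kind == "proxy"
        ),
        "bonferroni_threshold": threshold,
        "estimates": _estimates_block(results, reasons),
        "significant": _significance_block(results, threshold),
        "harmonization_actions": harmonization.action_counts(),
    }
    return block, results, harmonization


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run the full grid and write results, audit and logs under ``out_dir``.

    Returns the JSON-mirror report (also written to ``results.json``).  The
    TSV carries only pairs where all three estimators succeeded; every pair,
    including failures, appears in the JSON with a reason.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tsmr")
    root.addHandler(log_handler)
    try:
        ld = read_ld_table(cfg.ld_path) if cfg.ld_path else LDTable()
        report: dict = {"pairs": [], "config": _config_dict(cfg)}
        table_groups: dict[tuple[str, str], dict[str, MRResult]] = {}
        audit_lines = ["exposure\toutcome\tvariant_id\taction\treason"]

        pair_index = 0
        for exp_spec in cfg.exposures:
            exposure_table = read_sumstats(
                exp_spec.path, column_map=cfg.column_map, trait_label=exp_spec.label
            )
            significant = ins.filter_genomewide(exposure_table, cfg.p_threshold)
            selected = ins.prune_ld(significant, ld, r2_max=cfg.r2_prune)
            exclusion_ids = (
                ins.read_exclusion_list(exp_spec.exclusion_path)
                if exp_spec.exclusion_path
                else None
            )
            logger.info(
                "%s: %d significant, %d after LD pruning",
                exp_spec.label,
                len(significant),
                len(selected),
            )
            for out_spec in cfg.outcomes:
                pair = (exp_spec.label, out_spec.label)
                entry: dict = {"exposure": pair[0], "outcome": pair[1], "error": None}
                try:
                    outcome_table = read_sumstats(
                        out_spec.path, column_map=cfg.column_map, trait_label=out_spec.label
                    )
                    block, results, harmonization = _analyse_pair(
                        selected,
                        exposure_table,
                        outcome_table,
                        ld,
                        cfg,
                        _pair_seed(cfg.seed, pair_index),
                    )
                    entry.update(block)
                    for a in harmonization.audit:
                        audit_lines.append(
                            f"{pair[0]}\t{pair[1]}\t{a.variant_id}\t{a.action}\t{a.reason}"
                        )
                    if all(results.get(n) is not None for n in ("IVW", "weighted_median", "mr_egger")):
                        table_groups[pair] = {k: v for k, v in results.items() if v is not None}
                    if exclusion_ids is not None:
                        reduced = ins.exclude_variants(selected, exclusion_ids)
                        sens_block, _, _ = _analyse_pair(
                            reduced,
                            exposure_table,
                            outcome_table,
                            ld,
                            cfg,
                            _pair_seed(cfg.seed, pair_index, stream=1),
                        )
                        entry["sensitivity"] = sens_block
                except Exception as exc:  # per-pair failure isolation
                    entry["error"] = f"{type(exc).__name__}: {exc}"
                    logger.error("pair %s failed: %s", pair, entry["error"])
                report["pairs"].append(entry)
                pair_index += 1

        if table_groups:
            write_results(table_groups, out_dir / "results.tsv")
        (out_dir / "audit.tsv").write_text("\n".join(audit_lines) + "\n")
        (out_dir / "results.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        return report
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _config_dict(cfg: AnalysisConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


# ---------------------------------------------------------------------------
# concordance report


def compare_estimators(results_dir) -> list[dict]:
    """The qualitative robustness checklist, per pair, as machine-readable rows.

    For each successfully analysed pair: do IVW and the weighted median agree
    in sign, does the Egger intercept CI include 0 (no detected directional
    pleiotropy), and does the IVW p-value survive the pair's Bonferroni
    threshold.  Written to ``concordance.tsv`` / ``concordance.json``.
    """
    results_dir = Path(results_dir)
    report = json.loads((results_dir / "results.json").read_text())
    rows: list[dict] = []
    for entry in report["pairs"]:
        if entry.get("error"):
            continue
        estimates = entry["estimates"]
        ivw_d = estimates.get("IVW", {})
        wm_d = estimates.get("weighted_median", {})
        egger_d = estimates.get("mr_egger", {})
        if "beta" not in ivw_d or "beta" not in wm_d or "intercept" not in egger_d:
            raise ValueError(
                f"pair ({entry['exposure']}, {entry['outcome']}): missing estimator outputs"
            )
        intercept = egger_d["intercept"]
        rows.append(
            {
                "exposure": entry["exposure"],
                "outcome": entry["outcome"],
                "sign_agreement_ivw_wm": (ivw_d["beta"] >= 0) == (wm_d["beta"] >= 0),
                "egger_intercept_includes_zero": bool(
                    intercept["ci_low"] <= 0 <= intercept["ci_high"]
                ),
                "ivw_significant_bonferroni": bool(
                    ivw_d["pval"] < entry["bonferroni_threshold"]
                ),
            }
        )
    header = (
        "exposure\toutcome\tsign_agreement_ivw_wm\t"
        "egger_intercept_includes_zero\tivw_significant_bonferroni"
    )
    lines = [header] + [
        "\t".join(
            (
                r["exposure"],
                r["outcome"],
                str(r["sign_agreement_ivw_wm"]),
                str(r["egger_intercept_includes_zero"]),
                str(r["ivw_significant_bonferroni"]),
            )
        )
        for r in rows
    ]
    (results_dir / "concordance.tsv").write_text("\n".join(lines) + "\n")
    (results_dir / "concordance.json").write_text(
        json.dumps(rows, indent=2, sort_keys=True) + "\n"
    )
    return rows
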