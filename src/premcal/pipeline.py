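"""End-to-end study orchestration: simulate/ingest -> screen -> calibrate ->
purify -> DIF -> retest -> CAT, with structured artifacts.

Every artifact is JSON (or CSV for matrices), stamped with the seed and a
hash of the configuration, and byte-identical across reruns with the same
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cat import simulate_cat_study
from .data_io import (
    read_response_matrix,
    write_item_bank,
    write_ledger,
    write_response_matrix,
)
from .pcm import PCMModel, eap_scores, fit_statistics, score_responses
from .purification import PurifyConfig, run_purification_pipeline
from .retest import test_retest
from .synthetic import (
    RetestDesign,
    SimulationDesign,
    simulate_responses,
    simulate_retest,
)

__all__ = ["RunConfig", "run_full_study"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full study replication run."""

    # inputs: either paths to CSVs or a simulation request
    baseline_path: str | None = None
    retest_path: str | None = None
    simulate: bool = True
    sim_n_persons: int = 267
    sim_n_items: int = 67
    sim_theta_mean: float = -0.08
    sim_theta_sd: float = 1.90
    sim_missing_rate: float = 0.16
    sim_retest_n: int = 67
    sim_retest_correlation: float = 0.75
    sim_with_pathologies: bool = True
    # stage toggles
    run_retest: bool = True
    run_cat: bool = True
    # thresholds (purification defaults mirror the development study)
    purify: PurifyConfig = field(default_factory=PurifyConfig)
    cat_lengths: tuple[int, ...] = (19, 15, 10, 5)
    cat_n_simulees: int = 1000
    cat_prior: str = "standard"
    seed: int = 0
    out_dir: str = "premcal_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cat_lengths"] = list(self.cat_lengths)
        d["purify"] = dataclasses.asdict(self.purify)
        d["purify"]["rescore_map"] = list(self.purify.rescore_map)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded,
        so reruns into different directories stay byte-identical)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        purify_raw = raw.pop("purify", {})
        if "rescore_map" in purify_raw:
            purify_raw["rescore_map"] = tuple(purify_raw["rescore_map"])
        if "cat_lengths" in raw:
            raw["cat_lengths"] = tuple(raw["cat_lengths"])
        cfg = cls(**raw)
        cfg.purify = PurifyConfig(**purify_raw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _stamp(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash(), "premcal_version": __version__}


def _dump(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_full_study(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns a report bundle dict.

    On a stage failure the exception propagates with the stage recorded in
    its message; artifacts written by earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)
    bundle: dict = {"stamp": stamp}
    stage = "input"
    try:
        if config.simulate:
            from .synthetic import random_bank, study_pathologies

            bank = random_bank(config.sim_n_items, 5, seed=config.seed)
            design = SimulationDesign(
                bank=bank,
                n_persons=config.sim_n_persons,
                theta_mean=config.sim_theta_mean,
                theta_sd=config.sim_theta_sd,
                missing_rate=config.sim_missing_rate,
                group_probs={"service_user": 0.66, "carer": 0.15, "both": 0.12, "unreported": 0.07},
                retest=RetestDesign(config.sim_retest_n, config.sim_retest_correlation),
                pathologies=study_pathologies(bank) if config.sim_with_pathologies else [],
                seed=config.seed,
            )
            baseline, theta_true = simulate_responses(design)
            retest_m, _ = simulate_retest(design, theta_true)
            write_response_matrix(baseline, out / "baseline.csv")
            write_response_matrix(retest_m, out / "retest.csv")
        else:
            baseline = read_response_matrix(config.baseline_path)
            retest_m = read_response_matrix(config.retest_path) if config.retest_path else None

        stage = "purification"
        cfg = dataclasses.replace(config.purify, seed=config.seed)
        bank, ledger, model = run_purification_pipeline(baseline, cfg)
        write_ledger(ledger, out / "ledger.jsonl")
        write_item_bank(bank, out / "bank.json", **stamp)
        bundle["final_bank_items"] = bank.item_ids
        bundle["ledger_stages"] = ledger.stages()
        bundle["n_removed"] = len(ledger.removed_items())

        stage = "fit"
        baseline_scored = score_responses(bank, baseline)
        report = fit_statistics(model, baseline_scored)
        fit_payload = {
            **stamp,
            "model_chi2": report.model_chi2,
            "model_df": report.model_df,
            "model_p": report.model_p,
            "rmsea": report.rmsea,
            "rmsea_ci": list(report.rmsea_ci),
            "marginal_reliability": report.marginal_reliability,
            "item_fit": report.item_fit,
        }
        _dump(fit_payload, out / "fit.json")
        bundle["fit"] = fit_payload

        if config.run_retest and retest_m is not None:
            stage = "retest"
            common = [i for i in bank.item_ids if i in retest_m.item_ids]
            score_bank = bank.subset(common)
            retest_model = PCMModel(model.bank.subset(common), model.prior_mean, model.prior_sd)
            base_scores = eap_scores(retest_model, score_responses(score_bank, baseline))
            retest_scores = eap_scores(retest_model, score_responses(score_bank, retest_m))
            agree = test_retest(base_scores, retest_scores)
            retest_payload = {
                **stamp,
                "n_pairs": agree.n_pairs,
                "pearson_r": agree.pearson_r,
                "p_value": agree.p_value,
                "mean_diff": agree.mean_diff,
                "sd_diff": agree.sd_diff,
                "loa": [agree.loa_low, agree.loa_high],
                "pct_within_loa": agree.pct_within_loa,
            }
            _dump(retest_payload, out / "retest.json")
            bundle["retest"] = retest_payload

        if config.run_cat:
            stage = "cat"
            lengths = tuple(l for l in config.cat_lengths if l <= len(bank))
            if len(bank) not in lengths:
                lengths = (*lengths, len(bank))
            summaries = simulate_cat_study(
                bank,
                lengths=lengths,
                n_simulees=config.cat_n_simulees,
                theta_mean=config.sim_theta_mean,
                theta_sd=config.sim_theta_sd,
                prior=config.cat_prior,
                seed=config.seed,
            )
            cat_payload = {
                **stamp,
                "summaries": {
                    str(n): {
                        "mean_se": s.mean_se,
                        "sd_se": s.sd_se,
                        "se_range": list(s.se_range),
                        "corr_with_full_scale": s.corr_with_full_scale,
                    }
                    for n, s in summaries.items()
                },
            }
            _dump(cat_payload, out / "cat_summary.json")
            bundle["cat"] = cat_payload

        _dump({k: v for k, v in bundle.items() if k != "fit"}, out / "summary.json")
        _write_text_summary(bundle, out / "summary.txt")
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def _write_text_summary(bundle: dict, path: Path) -> None:
    lines = [
        f"premcal run (seed {bundle['stamp']['seed']}, config {bundle['stamp']['config_hash']})",
        f"final bank: {len(bundle.get('final_bank_items', []))} items "
        f"({bundle.get('n_removed', 0)} removed)",
        f"stages: {' -> '.join(bundle.get('ledger_stages', []))}",
    ]
    fit = bundle.get("fit")
    if fit:
        lines.append(
            f"fit: RMSEA {fit['rmsea']:.3f}, marginal reliability {fit['marginal_reliability']:.3f}"
        )
    rt = bundle.get("retest")
    if rt:
        lines.append(
            f"retest: r = {rt['pearson_r']:.3f} over {rt['n_pairs']} pairs, "
            f"{rt['pct_within_loa']:.1f}% within limits of agreement"
        )
    cat = bundle.get("cat")
    if cat:
        for n, s in cat["summaries"].items():
            lines.append(
                f"CAT {n} items: mean SE {s['mean_se']:.3f}, "
                f"corr with full scale {s['corr_with_full_scale']:.3f}"
            )
    path.write_text("\n".join(lines) + "\n")
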