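"""End-to-end orchestration: simulate -> preprocess -> ecology -> drivers -> staging.

Every stage writes its tables into the run directory; a consolidated
``report.json`` records filter provenance (counts surviving each step), the
headline statistics and the config hash.  Re-running a completed directory
with the same config hash is a no-op unless forced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, ecology, networks, prep, simulate
from .config import RunConfig
from .errors import PipelineError

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> dict:
    """Execute the full pipeline into ``out_dir``; returns the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    if report_path.exists() and not force:
        previous = json.loads(report_path.read_text())
        if previous.get("config_hash") == config.hash():
            logger.info("run directory up to date (config hash %s); skipping",
                        config.hash())
            return previous

    report: dict = {"config_hash": config.hash(), "stages": {}}
    rng = np.random.default_rng(config.seed)

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"stage {name!r} failed: {e}") from e

    # --- simulate -----------------------------------------------------------
    def _simulate():
        cfg = dataclasses.replace(config.simulate, seed=int(rng.integers(2**31)))
        counts, meta, tax, truth = simulate.generate_cohort(cfg)
        simulate.write_cohort(out / "cohort", counts, meta, tax, truth, cfg)
        return counts, meta, tax, truth

    counts, meta, tax, truth = stage("simulate", _simulate)
    report["stages"]["simulate"] = {
        "n_samples": int(counts.shape[0]), "n_taxa": int(counts.shape[1]),
    }

    # --- preprocess ---------------------------------------------------------
    def _preprocess():
        filtered = prep.filter_taxa(counts, tax,
                                    min_samples=config.prep.min_samples)
        rarefied = prep.rarefy(filtered, depth=config.prep.rarefy_depth,
                               seed=int(rng.integers(2**31)))
        rel = prep.to_relative(rarefied)
        meta_kept = meta.loc[rarefied.index]
        prep.write_tables(out / "preprocessed", rarefied, meta_kept, tax)
        return filtered, rarefied, rel, meta_kept

    filtered, rarefied, rel, meta_kept = stage("preprocess", _preprocess)
    report["stages"]["preprocess"] = {
        "taxa_after_filter": int(filtered.shape[1]),
        "samples_after_rarefaction": int(rarefied.shape[0]),
        "rarefy_depth": config.prep.rarefy_depth,
    }

    # --- ecology ------------------------------------------------------------
    def _ecology():
        shannon = ecology.shannon(rel)
        shannon.to_csv(out / "shannon.tsv", sep="\t", header=True)
        dm = ecology.bray_curtis(rel)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        perma = ecology.permanova(
            dm, meta_kept, ["group", "age", "gender"],
            n_perm=config.ecology.n_perm, seed=int(rng.integers(2**31)),
        )
        perma.table.to_csv(out / "permanova.tsv", sep="\t")
        pairwise = ecology.pairwise_permanova(
            dm, meta_kept, n_perm=config.ecology.n_perm,
            seed=int(rng.integers(2**31)),
        )
        pairwise.to_csv(out / "pairwise_permanova.tsv", sep="\t", index=False)
        avd_res = ecology.avd(rel, meta_kept)
        avd_res.summary.to_csv(out / "avd.tsv", sep="\t")
        upset = ecology.upset_counts(rarefied, meta_kept)
        upset.to_csv(out / "upset.tsv", sep="\t")
        so = ecology.spec_occu(rarefied, meta_kept, top_n=config.ecology.top_n)
        so.to_csv(out / "spec_occu.tsv", sep="\t", index=False)
        return perma, avd_res, upset, so

    perma, avd_res, upset, so = stage("ecology", _ecology)
    report["stages"]["ecology"] = {
        "permanova_group_r2": float(perma.table.loc["group", "r2"]),
        "permanova_group_p": float(perma.table.loc["group", "p"]),
        "n_specialists": int(so["specialist"].sum()),
    }

    # --- drivers ------------------------------------------------------------
    def _drivers():
        nc = config.network
        groups = meta_kept["group"]
        ctrl_prof = rel.loc[groups == nc.control_group]
        case_prof = rel.loc[groups == nc.case_group]
        ctrl = networks.build_network(
            ctrl_prof, nc.control_group, min_prevalence=nc.min_prevalence,
            rho_threshold=nc.rho_threshold, alpha=nc.alpha,
        )
        case = networks.build_network(
            case_prof, nc.case_group, min_prevalence=nc.min_prevalence,
            rho_threshold=nc.rho_threshold, alpha=nc.alpha,
        )
        networks.write_edges(out / "network_control.tsv", ctrl)
        networks.write_edges(out / "network_case.tsv", case)
        records = networks.score_drivers(ctrl, case)
        drivers = networks.identify_drivers(records, nc.score_quantile)
        drivers.to_csv(out / "drivers.tsv", sep="\t")
        return drivers

    drivers = stage("drivers", _drivers)
    report["stages"]["drivers"] = {
        "n_common_nodes": int(len(drivers)),
        "n_drivers": int(drivers["driver"].sum()) if len(drivers) else 0,
    }

    # --- staging model ------------------------------------------------------
    def _stage_model():
        cc = config.classifier
        reports, chosen = classify.rank_sweep(
            rarefied, tax, meta_kept, seed=int(rng.integers(2**31)),
            ranks=cc.ranks, top_k=cc.top_k, n_estimators=cc.n_estimators,
            train_fraction=cc.train_fraction,
        )
        sweep_rows = []
        for rank in cc.ranks:
            rep = reports[rank]["combined"]
            rep.confusion.to_csv(out / f"confusion_{rank}.tsv", sep="\t")
            sweep_rows.append((rank, rep.overall_accuracy,
                               rep.false_negatives))
        pd.DataFrame(sweep_rows,
                     columns=["rank", "overall_accuracy", "false_negatives"]
                     ).to_csv(out / "rank_sweep.tsv", sep="\t", index=False)
        best = reports[chosen]["combined"]
        correct = best.diagnosed.eq(meta_kept["group"].loc[best.diagnosed.index])
        bias = classify.audit_bias(correct, meta_kept)
        bias.to_csv(out / "bias_audit.tsv", sep="\t")
        model = reports[chosen]["model"]
        (out / "stage_model.json").write_text(json.dumps({
            "rank": model.rank, "features": list(model.features),
            "excluded": list(model.excluded), "vote_cutoff": model.vote_cutoff,
        }, indent=2))
        return reports, chosen, best

    reports, chosen, best = stage("stage_model", _stage_model)
    report["stages"]["stage_model"] = {
        "chosen_rank": chosen,
        "overall_accuracy": float(best.overall_accuracy),
        "false_negatives": int(best.false_negatives),
        "confusion_total": int(best.confusion.to_numpy().sum()),
    }

    report_path.write_text(json.dumps(report, indent=2))
    return report
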