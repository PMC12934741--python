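"""End-to-end experiment orchestration.

simulate -> threshold/build -> split -> train -> reconstruct ->
edge-wise evaluation -> topology statistics -> latent probing,
with every artifact written under the output directory and a manifest
recording the configuration hash and named seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import simulate_cohort, save_cohort
from .config import RunConfig, save_config
from .graphs import prepare_graphs, vector_to_symmetric
from .latent import (
    export_connectogram,
    extract_latents,
    latent_group_tests,
    one_hot_decode_difference,
    top_discriminative_dims,
)
from .netstats import graph_statistics, stats_error_report
from .recon_eval import (
    cross_scenario_predict,
    edgewise_correlation,
    groupdiff_ttest,
    preservation_fpr,
    recon_metrics,
)
from .training import make_splits, reconstruct, train_model

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_experiment(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds
    condition = config.condition_or_none()
    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seeds": seeds,
        "stages": [],
    }
    manifest["config"]["cohort"]["subdomain_sizes"] = list(
        config.cohort.subdomain_sizes
    )
    for key in ("sex_mask_blocks", "fi_mask_blocks"):
        manifest["config"]["cohort"][key] = list(
            getattr(config.cohort, key)
        )
    save_config(config, outdir / "config.yaml")

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # persist what we have, then abort
                (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise StageError(name, exc) from exc
            # timings go to the log only: the manifest must be identical
            # across reruns of the same config
            manifest["stages"].append({"name": name})
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return result

        return wrap

    from dataclasses import replace as _replace

    cohort_params = _replace(config.cohort, seed=seeds["cohort"])

    records_masks = stage("simulate")(lambda: simulate_cohort(cohort_params))
    records, sex_mask, fi_mask = records_masks
    stage("write_cohort")(
        lambda: save_cohort(outdir / "cohort", records,
                            {"sex": sex_mask, "fi": fi_mask})
    )

    plan = stage("split")(
        lambda: make_splits(
            [r.subject_id for r in records],
            test_frac=config.test_frac,
            n_splits=config.n_splits,
            val_frac=config.val_frac,
            seed=seeds["splits"],
        )
    )
    (outdir / "splits.json").write_text(
        json.dumps({"test_ids": plan.test_ids,
                    "splits": [{"train": t, "val": v} for t, v in plan.splits]})
    )

    by_id = {r.subject_id: r for r in records}
    train_ids, val_ids = plan.splits[0]
    tr = prepare_graphs([by_id[i] for i in train_ids], condition, config.tau)
    va = prepare_graphs([by_id[i] for i in val_ids], condition, config.tau)
    te_records = [by_id[i] for i in plan.test_ids]
    te = prepare_graphs(te_records, condition, config.tau)

    model_history = stage("train")(
        lambda: train_model(
            tr, va, config.model, epochs=config.epochs,
            batch_size=config.batch_size, lr=config.lr,
            weight_decay=config.weight_decay, seed=seeds["training"],
        )
    )
    model, history = model_history
    history.to_frame().to_csv(outdir / "history.csv", index=False)
    model.save(outdir / "checkpoint.npz")

    recon_mats = stage("reconstruct")(lambda: reconstruct(model, te))
    real_mats = [vector_to_symmetric(g.target, config.model.max_nodes) for g in te]

    def _eval():
        metrics = recon_metrics(real_mats, recon_mats)
        pd.DataFrame(metrics, index=["mean", "sd"]).to_csv(outdir / "recon_metrics.csv")
        labels = np.array([r.sex for r in te_records])
        scores = np.array([r.fi_score for r in te_records])
        out = {}
        if condition != "fi":
            real_map = groupdiff_ttest(real_mats, labels, config.q_edge)
            recon_map = groupdiff_ttest(recon_mats, labels, config.q_edge)
            real_map.to_csv(outdir / "edges_sex_real.csv")
            recon_map.to_csv(outdir / "edges_sex_recon.csv")
            out["sex_fpr"] = preservation_fpr(real_map, recon_map)
            out["sex_maps"] = (real_map, recon_map)
            preds = cross_scenario_predict(
                real_mats, recon_mats, labels, "sex", seed=seeds["prediction"]
            )
            pd.DataFrame({k: v.metrics for k, v in preds.items()}).to_csv(
                outdir / "prediction_sex.csv"
            )
            out["sex_preds"] = preds
        if condition != "sex":
            real_map = edgewise_correlation(real_mats, scores, config.q_edge)
            recon_map = edgewise_correlation(recon_mats, scores, config.q_edge)
            real_map.to_csv(outdir / "edges_fi_real.csv")
            recon_map.to_csv(outdir / "edges_fi_recon.csv")
            out["fi_fpr"] = preservation_fpr(real_map, recon_map)
            preds = cross_scenario_predict(
                real_mats, recon_mats, scores, "fi", seed=seeds["prediction"]
            )
            pd.DataFrame({k: v.metrics for k, v in preds.items()}).to_csv(
                outdir / "prediction_fi.csv"
            )
        fpr = {k: v for k, v in out.items() if k.endswith("_fpr")}
        (outdir / "preservation_fpr.json").write_text(json.dumps(fpr, indent=1))
        return out

    stage("recon_eval")(_eval)

    def _netstats():
        real_stats = [graph_statistics(m) for m in real_mats]
        from .graphs import threshold_sfnc
        recon_stats = [graph_statistics(threshold_sfnc(m, config.tau).values)
                       for m in recon_mats]
        rows = []
        for rec, s, kind in (
            [(r, st, "real") for r, st in zip(te_records, real_stats)]
            + [(r, st, "recon") for r, st in zip(te_records, recon_stats)]
        ):
            row = s.as_series().to_dict()
            row.update(subject_id=rec.subject_id, kind=kind)
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "graph_stats.csv", index=False)
        report = stats_error_report(real_stats, recon_stats)
        report.per_stat.to_csv(outdir / "stats_errors.csv")
        report.aggregate.to_csv(outdir / "stats_errors_aggregate.csv")
        return report

    stage("netstats")(_netstats)

    def _latent():
        latents = extract_latents(model, te, mode="sample",
                                  seed=seeds["latent_sampling"])
        latents.to_csv(outdir / "latents.csv")
        if condition == "fi":
            targets = np.array([r.fi_score for r in te_records])
            tests = latent_group_tests(latents, targets, "continuous",
                                       config.q_latent)
        else:
            targets = np.array([r.sex for r in te_records])
            tests = latent_group_tests(latents, targets, "binary",
                                       config.q_latent)
        tests.to_csv(outdir / "latent_tests.csv", index=False)
        dims = top_discriminative_dims(tests, config.top_dims)
        for d in dims:
            dm = one_hot_decode_difference(model, d, 0.0, 1.0)
            np.savetxt(outdir / f"diffmap_dim{d}.csv", dm.delta, delimiter=",")
            export_connectogram(
                dm, config.top_edges,
                csv_path=outdir / f"connectogram_dim{d}.csv",
                plot_path=outdir / f"connectogram_dim{d}.png",
            )
        return dims

    stage("latent_probe")(_latent)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
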