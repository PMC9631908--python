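"""Orchestration: curate → split → descriptors → model → validate.

``run_study`` executes the full QSAR protocol per transporter target and
writes five artifacts per target (split CSV, descriptor CSV, model JSON,
prediction report CSV, plain-text summary) plus a run manifest that makes
every number recomputable. ``run_consensus`` is the parallel entry point
for score tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons
from . import curation, descriptors as desc, io as mio, qsar
from .config import PipelineConfig, dump_config

__all__ = ["run_study", "run_consensus"]

log = logging.getLogger("matqsar")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_study(cfg: PipelineConfig, dataset=None) -> dict:
    """Run the full QSAR study; returns the manifest dictionary.

    ``dataset`` may be passed directly (e.g. a synthetic study's
    ActivityDataset); otherwise ``cfg.compound_csv`` is loaded.
    """
    t0 = time.time()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "inputs": {},
        "stages": {},
        "artifacts": {},
    }
    if dataset is None:
        if cfg.compound_csv is None:
            raise ValueError("no dataset given and no compound_csv configured")
        dataset = mio.read_compound_csv(cfg.compound_csv)
        manifest["inputs"]["compound_csv"] = {
            "path": str(cfg.compound_csv),
            "sha256": _sha256(Path(cfg.compound_csv)),
        }
    log.info("stage=load n_compounds=%d", len(dataset))

    # similarity and curation are target-independent
    t = time.time()
    sim = curation.similarity_matrix(
        dataset, n_bits=cfg.fingerprint_bits, max_path=cfg.fingerprint_max_path
    )
    retained, removed = curation.filter_dissimilar(dataset, sim, cfg.tc_removal_threshold)
    sim_retained = curation.similarity_matrix(
        retained, n_bits=cfg.fingerprint_bits, max_path=cfg.fingerprint_max_path
    )
    manifest["stages"]["curation"] = {
        "seconds": round(time.time() - t, 3),
        "n_removed": int(len(removed)),
        "removed": {str(k): float(v) for k, v in removed["mean_tc"].items()},
    }
    log.info("stage=curation removed=%d retained=%d", len(removed), len(retained))

    # descriptors: computed once for the retained set (or read externally)
    t = time.time()
    if cfg.descriptor_csv is not None:
        table = desc.read_table_csv(cfg.descriptor_csv)
        table = desc.DescriptorTable(values=table.values.loc[retained.ids], scaled=False)
        manifest["inputs"]["descriptor_csv"] = {
            "path": str(cfg.descriptor_csv),
            "sha256": _sha256(Path(cfg.descriptor_csv)),
        }
    else:
        table = desc.build_table(
            [retained.molecules[i] for i in retained.ids],
            names=cfg.descriptor_names,
            ids=retained.ids,
            seed=cfg.seed,
        )
    desc_path = outdir / "descriptors.csv"
    desc.write_table_csv(table, desc_path)
    manifest["artifacts"]["descriptors"] = str(desc_path)
    manifest["stages"]["descriptors"] = {
        "seconds": round(time.time() - t, 3),
        "n_descriptors": len(table.descriptor_names),
    }
    log.info("stage=descriptors n=%d", len(table.descriptor_names))

    summary_lines: list[str] = []
    for target in cfg.targets:
        t = time.time()
        pki = retained.pki(target)
        usable_ids = [i for i in retained.ids if np.isfinite(pki[i])]
        sub = retained.subset(usable_ids)
        sub_sim = curation.similarity_matrix(
            sub, n_bits=cfg.fingerprint_bits, max_path=cfg.fingerprint_max_path
        )
        bins = curation.bin_by_activity(sub, target)
        split = curation.assign_split(
            bins, sub_sim, sub, target, train_fraction=cfg.train_fraction, removed=removed
        )
        report = curation.split_distribution_report(split, sub, sub_sim)
        split_path = outdir / f"split_{target}.csv"
        split.to_frame().to_csv(split_path)
        manifest["artifacts"][f"split_{target}"] = str(split_path)

        train_ids, test_ids = list(split.train_ids), list(split.test_ids)
        train_table = desc.DescriptorTable(values=table.values.loc[train_ids], scaled=False)
        test_table = desc.DescriptorTable(values=table.values.loc[test_ids], scaled=False)
        scaled_train = desc.scale_table(train_table)
        y_train = pki[train_ids].to_numpy(dtype=float)
        y_test = pki[test_ids].to_numpy(dtype=float)

        candidates = qsar.select_descriptors(
            scaled_train,
            y_train,
            activity_threshold=cfg.activity_correlation_threshold,
            cross_threshold=cfg.cross_correlation_threshold,
        )
        if not candidates:
            raise ValueError(
                f"{target}: no descriptor passed the |r| > "
                f"{cfg.activity_correlation_threshold} activity-correlation filter"
            )
        model = qsar.reduce_model(
            scaled_train,
            y_train,
            candidates,
            target=target,
            gap_tol=cfg.gap_tol,
            r2_slack=cfg.r2_slack,
        )
        model_path = outdir / f"model_{target}.json"
        model.to_json(model_path)
        manifest["artifacts"][f"model_{target}"] = str(model_path)

        pred = qsar.predict(model, test_table, y_test, esd_alpha=cfg.esd_alpha)
        report_path = outdir / f"report_{target}.csv"
        pred.to_frame().to_csv(report_path, float_format="%.6g")
        manifest["artifacts"][f"report_{target}"] = str(report_path)

        manifest["stages"][f"model_{target}"] = {
            "seconds": round(time.time() - t, 3),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "candidates": candidates,
            "descriptors": list(model.descriptor_names),
            "r2": round(model.r2, 4),
            "q2": None if model.q2 is None else round(model.q2, 4),
            "r2_test": round(pred.r2_test, 4),
            "r2_predictive": round(pred.r2_predictive, 4),
            "shapiro_wilk": report["shapiro_wilk"],
        }
        summary_lines += [
            f"[{target.upper()}] n_train={len(train_ids)} n_test={len(test_ids)} "
            f"removed={len(removed)}",
            f"  descriptors: {', '.join(model.descriptor_names)}",
            f"  r2={model.r2:.3f} q2={model.q2:.3f} "
            f"test r2={pred.r2_test:.3f} (predictive r2={pred.r2_predictive:.3f})",
            f"  Shapiro-Wilk on pKi: W={report['shapiro_wilk']['W']:.3f} "
            f"p={report['shapiro_wilk']['p']:.3f}",
            f"  ESD outliers in test set: "
            f"{[cid for cid, f in zip(pred.compound_ids, pred.esd_flags) if f] or 'none'}",
        ]
        log.info(
            "stage=model target=%s r2=%.3f q2=%.3f r2_test=%.3f",
            target, model.r2, -1 if model.q2 is None else model.q2, pred.r2_test,
        )

    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    manifest["artifacts"]["summary"] = str(summary_path)
    manifest["total_seconds"] = round(time.time() - t0, 3)
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def run_consensus(cfg: PipelineConfig, score_table=None, activities=None) -> cons.RankResult:
    """Consensus-rank a score table against experimental activities."""
    if score_table is None:
        if cfg.score_csv is None:
            raise ValueError("no score table given and no score_csv configured")
        score_table = mio.read_score_csv(cfg.score_csv, cfg.higher_better)
    if activities is None:
        if cfg.compound_csv is None:
            raise ValueError("no activities given and no compound_csv configured")
        dataset = mio.read_compound_csv(cfg.compound_csv)
        target = cfg.targets[0]
        act = dataset.pki(target)
        missing = [i for i in score_table.ligand_ids if i not in act.index]
        extra = [i for i in act.index if i not in score_table.ligand_ids]
        if missing or extra:
            raise ValueError(
                f"ligand id mismatch between tables; in scores only: {missing}; "
                f"in activities only: {extra}"
            )
        activities = act[score_table.ligand_ids].to_numpy(dtype=float)
    result = cons.analyze_scores(
        score_table, activities, n_perm=cfg.n_permutations, seed=cfg.seed
    )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(outdir / "consensus_spearman.csv", float_format="%.4f")
    pd.DataFrame({"consensus_rank": result.consensus}).to_csv(
        outdir / "consensus_ranks.csv", float_format="%.4f"
    )
    _write_json(
        {
            "rho_per_function": result.rho_per_function,
            "rho_consensus": result.rho_consensus,
            "critical_values": {str(k): v for k, v in result.critical_values.items()},
            "flags": result.flags,
            "n_permutations": result.n_permutations,
            "seed": result.seed,
        },
        outdir / "consensus.json",
    )
    return result
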