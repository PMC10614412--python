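"""End-to-end orchestration: simulate → match → features → brain-age →
subtype → voxel statistics → report.

All cross-stage data flow goes through files in documented formats
(phenotype CSV, NIfTI volumes, TSV tables, JSON sidecars), so any stage
can be rerun from saved outputs. Reruns with an identical configuration
reproduce identical outputs for the deterministic stages; the run manifest
records the configuration hash and every seed used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brainage, features, subtyping, voxel_stats
from .cohort_matching import demographics_table, greedy_age_match
from .synthetic_cohort import (METRICS, CohortSpec, generate_cohort,
                               read_cohort, write_cohort)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

log = logging.getLogger("wmdev")

ALL_STAGES = ("simulate", "match", "features", "brainage", "subtype",
              "voxelstats", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "wmdev_out"
    input_dir: str | None = None          # read an existing cohort instead
    stages: tuple = ALL_STAGES
    seed: int = 0
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    match_threshold: float = 0.1
    feature_kind: str = "bundle_means"
    model: str = "svr"                    # or "rfr"
    train_fraction: float = 0.5
    regress_motion: bool = False
    k_range: tuple = (2, 10)
    n_init: int = 50
    tfce_preset: str = "volumetric"
    n_perm: int = 500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.input_dir and Path(self.input_dir).resolve() == Path(self.out_dir).resolve():
            raise ValueError("output dir must differ from input dir")
        if self.model not in ("svr", "rfr"):
            raise ValueError("model must be 'svr' or 'rfr'")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ages_for(records, ids):
    by_id = {r.subject_id: r for r in records}
    return np.array([by_id[s].age for s in ids])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in flowchart order; returns the outputs.

    Outputs (also written under ``config.out_dir``): demographics table,
    cross-validated model performance, the deviation-index table, the
    silhouette curve and cluster labels, subgroup statistics, deviation-age
    correlations, and per-bundle voxelwise significance.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": list(config.stages), "timings_s": {}}
    results: dict = {}

    def stage_enabled(name):
        return name in config.stages

    def mark(name, start):
        manifest["timings_s"][name] = round(time.time() - start, 3)
        log.info("stage %s done in %.2fs", name, manifest["timings_s"][name])

    # --- simulate / load --------------------------------------------------
    start = time.time()
    if config.input_dir:
        records, volumes = read_cohort(config.input_dir)
    else:
        spec = CohortSpec(seed=config.seed, **config.cohort)
        records, volumes = generate_cohort(spec)
        if stage_enabled("simulate"):
            write_cohort(records, volumes, out / "cohort")
    results["records"], results["volumes"] = records, volumes
    mark("simulate", start)
    if set(config.stages) <= {"simulate"}:
        _write_manifest(out, manifest)
        return results

    td = [r for r in records if r.group == "TD"]
    asd = [r for r in records if r.group == "ASD"]

    # --- match ------------------------------------------------------------
    if stage_enabled("match"):
        start = time.time()
        match = greedy_age_match(asd, td, p_threshold=config.match_threshold)
        kept = set(match.kept_a) | set(match.kept_b)
        records = [r for r in records if r.subject_id in kept]
        volumes = [v for v in volumes if v.subject_id in kept]
        td = [r for r in records if r.group == "TD"]
        asd = [r for r in records if r.group == "ASD"]
        demo = demographics_table(records)
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
        results["match"] = match
        results["demographics"] = demo
        mark("match", start)

    # --- features ---------------------------------------------------------
    start = time.time()
    feats = features.extract_features(volumes, kind=config.feature_kind)
    if config.regress_motion:
        cov = features.covariate_matrix(records,
                                        include=("sex", "handedness",
                                                 "head_motion"))
        feats = {m: features.regress_nuisance(t, cov) for m, t in feats.items()}
    results["features"] = feats
    if stage_enabled("features"):
        gm = features.extract_features(volumes, kind="global_mean")
        td_ids = [r.subject_id for r in td]
        asd_ids = [r.subject_id for r in asd]
        cc = features.case_control_compare(
            {m: t.subset(asd_ids) for m, t in gm.items()},
            {m: t.subset(td_ids) for m, t in gm.items()})
        corr = features.age_correlation_by_group(gm, records)
        pd.DataFrame([
            {"metric": m, "t": r.statistic, "p": r.p_value}
            for m, r in cc.items()
        ]).to_csv(out / "case_control.tsv", sep="\t", index=False)
        pd.DataFrame([
            {"group": g, "metric": m, "r": rp[0], "p": rp[1]}
            for g, per in corr.items() for m, rp in per.items()
        ]).to_csv(out / "age_correlation.tsv", sep="\t", index=False)
        results["case_control"] = cc
        results["age_correlation"] = corr
        mark("features", start)

    # --- brainage ---------------------------------------------------------
    if stage_enabled("brainage"):
        start = time.time()
        train_ids, test_ids = brainage.age_matched_split(
            td, fraction=config.train_fraction, seed=config.seed)
        asd_ids = [r.subject_id for r in asd]
        indices, bias_models, performance = {}, {}, {}
        for m in METRICS:
            table = feats[m]
            predictor = brainage.fit_age_model(
                table.subset(train_ids), _ages_for(td, train_ids),
                model=config.model, seed=config.seed)
            bias = brainage.estimate_bias(
                predictor, table.subset(test_ids), _ages_for(td, test_ids))
            indices[m] = brainage.compute_deviation_index(
                predictor, bias, table.subset(asd_ids), _ages_for(asd, asd_ids))
            bias_models[m] = bias
            td_ids_all = [r.subject_id for r in td]
            performance[m] = brainage.cross_validate(
                table.subset(td_ids_all), _ages_for(td, td_ids_all),
                model=config.model, seed=config.seed)
        dev = brainage.deviation_matrix(indices)
        dev.to_csv(out / "deviation_index.tsv", sep="\t")
        (out / "bias_model.json").write_text(json.dumps(
            {m: {"alpha": b.alpha, "beta": b.beta}
             for m, b in bias_models.items()}, indent=1))
        pd.DataFrame([
            {"metric": m, "mse": p.mse, "mape_percent": p.mape}
            for m, p in performance.items()
        ]).to_csv(out / "cv_performance.tsv", sep="\t", index=False)
        results.update(deviation=dev, bias_models=bias_models,
                       performance=performance, split=(train_ids, test_ids))
        mark("brainage", start)

    # --- subtype ----------------------------------------------------------
    if stage_enabled("subtype") and "deviation" in results:
        start = time.time()
        dev = results["deviation"]
        sel = subtyping.silhouette_select_k(
            dev[list(METRICS)].to_numpy(),
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            seed=config.seed, n_init=config.n_init)
        asd_by_id = {r.subject_id: r for r in asd}
        dev_records = [asd_by_id[s] for s in dev.index]
        labels = sel.labels
        if sel.chosen_k == 2:
            labels = subtyping.order_clusters_by_age(labels, dev_records)
            comparison = subtyping.subgroup_compare(labels, dev_records, dev)
            comparison.to_csv(out / "subgroup_stats.tsv", sep="\t", index=False)
            results["subgroup_stats"] = comparison
        corr = subtyping.deviation_age_correlation(dev, dev_records)
        corr.to_csv(out / "deviation_age_corr.tsv", sep="\t", index=False)
        pd.DataFrame({"subject_id": dev.index, "label": labels}).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame([{"k": k, "mean_silhouette": s}
                      for k, s in sel.silhouette_by_k.items()]).to_csv(
            out / "silhouette.tsv", sep="\t", index=False)
        results.update(selection=sel, cluster_labels=labels,
                       deviation_age_corr=corr)
        mark("subtype", start)

    # --- voxelstats -------------------------------------------------------
    if stage_enabled("voxelstats") and "cluster_labels" in results \
            and np.unique(results["cluster_labels"]).size == 2:
        start = time.time()
        asd_by_id = {r.subject_id: r for r in asd}
        dev_records = [asd_by_id[s] for s in results["deviation"].index]
        params = voxel_stats.TFCEParams.preset(config.tfce_preset)
        vox_results, bundle_table = voxel_stats.stage_specific_report(
            results["cluster_labels"], dev_records, td, volumes,
            params=params, n_perm=config.n_perm, seed=config.seed)
        bundle_table.to_csv(out / "bundle_significance.tsv", sep="\t",
                            index=False)
        results.update(voxel_results=vox_results, bundle_table=bundle_table)
        mark("voxelstats", start)

    # --- report -----------------------------------------------------------
    if stage_enabled("report"):
        report = render_report(results)
        (out / "report.txt").write_text(report)
        results["report"] = report

    manifest["runtime_s"] = round(time.time() - t0, 3)
    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))


def render_report(outputs: dict) -> str:
    """Plain-text summary of whatever stage outputs are present."""
    lines = ["White-matter developmental deviation analysis", "=" * 46, ""]
    if "demographics" in outputs:
        lines += ["Demographics", "-" * 12,
                  outputs["demographics"].to_string(index=False), ""]
    if "performance" in outputs:
        lines += ["Age-model cross-validation (5-fold)", "-" * 35]
        for m, p in outputs["performance"].items():
            lines.append(f"  {m}: MSE = {p.mse:.2f} y^2, MAPE = {p.mape:.2f}%")
        lines.append("")
    if "selection" in outputs:
        sel = outputs["selection"]
        lines += [f"Silhouette selection: chosen k = {sel.chosen_k} "
                  f"(mean silhouette "
                  f"{sel.silhouette_by_k[sel.chosen_k]:.3f})", ""]
    if "subgroup_stats" in outputs:
        lines += ["Subgroup comparison (1 = younger)", "-" * 33,
                  outputs["subgroup_stats"].to_string(index=False), ""]
    else:
        lines += ["Subgroup comparison: not available "
                  "(no two-cluster solution)", ""]
    if "deviation_age_corr" in outputs:
        lines += ["Deviation-age partial correlation", "-" * 33,
                  outputs["deviation_age_corr"].to_string(index=False), ""]
    if "bundle_table" in outputs:
        bt = outputs["bundle_table"]
        lines += ["Voxelwise significance by bundle (FWE p < 0.05)", "-" * 47,
                  bt.to_string(index=False) if len(bt) else "  none", ""]
    return "\n".join(lines) + "\n"
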