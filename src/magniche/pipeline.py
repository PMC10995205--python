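"""End-to-end orchestration of the genome-centric analysis.

Stage order: quality filter → per-site dereplication → detection filter and
library-size normalization → habitat-specificity classification → genomic
feature comparison → Fisher enrichment per annotation namespace → KEGG module
completeness → overall (cross-site) strain dereplication → ordination suite
(whole-community model, water-quality model on host-specific MAGs and coral
samples only, environmental vector fitting, and a final ordination
constrained on the high-R² variables) → abundance-weighted cluster
enrichment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import abundance as ab
from . import io as mio
from . import modules as mod
from . import ordination as ord_
from . import qc, simulate, specificity, stats

logger = logging.getLogger("magniche.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineReport:
    seed: int
    config: dict
    n_mags_input: int = 0
    n_mags_retained: int = 0
    n_site_dereplicated: int = 0
    n_overall_dereplicated: int = 0
    n_host_specific: int = 0
    n_seawater_specific: int = 0
    n_undetected: int = 0
    enriched_per_namespace: dict = field(default_factory=dict)
    modules_flagged: int = 0
    permanova: dict = field(default_factory=dict)
    envfit_significant: list = field(default_factory=list)
    significant_cluster_pairs: int = 0
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_pipeline(
    mags: Sequence[mio.MAGRecord],
    ani: pd.DataFrame,
    samples: Sequence[mio.SampleRecord],
    coverage: pd.DataFrame,
    annotations: dict[str, mio.FeatureMatrix],
    clusters: mio.FeatureMatrix | None = None,
    module_rows: Sequence[mio.ModuleRow] | None = None,
    config: mio.RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    config = config or mio.RunConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(seed=config.seed, config=dataclasses.asdict(config))
    report.n_mags_input = len(mags)

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        if out is not None:
            path = out / f"{name}.tsv"
            mio.write_table(df, path, index=index)
            report.outputs[name] = str(path)

    def stage(name: str):
        report.stages.append(name)
        logger.info("stage: %s", name)

    try:
        stage("quality_filter")
        assessments, retained = qc.filter_mags(mags, config)
        report.n_mags_retained = len(retained)
        save("quality", pd.DataFrame([dataclasses.asdict(a) for a in assessments]))

        stage("dereplicate_per_site")
        derep_site = qc.dereplicate(retained, ani, config.ani_threshold, mode="per_site")
        site_reps = [m for m in retained if m.mag_id in derep_site.representative_set]
        report.n_site_dereplicated = len(site_reps)
        save("dereplication_per_site", derep_site.to_frame())

        stage("abundance")
        rep_ids = {m.mag_id for m in site_reps}
        cov = coverage[coverage["mag_id"].isin(rep_ids)].reset_index(drop=True)
        cov = ab.apply_detection_filter(cov, config.covered_fraction_min)
        abund = ab.normalize(cov, samples)
        save("relative_abundance", abund.relative_abundance, index=True)
        save("detection", abund.detected, index=True)

        stage("specificity")
        prev = ab.prevalence(abund, samples)
        spec_results = specificity.classify_specificity(abund, prev, samples, config)
        spec_df = specificity.results_to_frame(spec_results)
        labels = (
            spec_df.set_index("mag_id")["label"] if len(spec_df)
            else pd.Series(dtype=object)
        )
        if spec_results:
            summary = specificity.summarize_specificity(spec_results, site_reps)
            report.n_host_specific = summary["counts"][specificity.HOST_SPECIFIC]
            report.n_seawater_specific = summary["counts"][specificity.SEAWATER_SPECIFIC]
            report.n_undetected = summary["counts"][specificity.UNDETECTED]
        save("specificity", spec_df)

        stage("genomic_features")
        mags_df = mio.mags_to_frame(site_reps).set_index("mag_id")
        usable = labels[labels != specificity.UNDETECTED]
        if usable.nunique() >= 2:
            feat_cmp = stats.compare_genomic_features(mags_df, usable)
        else:
            feat_cmp = pd.DataFrame()
        save("genomic_feature_tests", feat_cmp)

        stage("fisher_enrichment")
        for ns, fm in annotations.items():
            sub = mio.FeatureMatrix(
                counts=fm.counts.loc[[m for m in fm.mag_ids if m in rep_ids]],
                namespace=ns,
            )
            try:
                enr = stats.fisher_enrichment(sub, labels)
            except mio.SchemaError as exc:
                logger.warning("%s enrichment skipped: %s", ns, exc)
                report.enriched_per_namespace[ns] = 0
                continue
            n_sig = int((enr["adjusted_p"] <= 0.05).sum()) if len(enr) else 0
            report.enriched_per_namespace[ns] = n_sig
            save(f"enrichment_{ns}", enr)

        stage("module_completeness")
        if module_rows and "KO" in annotations:
            defs = mod.load_modules(module_rows)
            ko_sub = mio.FeatureMatrix(
                counts=annotations["KO"].counts.loc[
                    [m for m in annotations["KO"].mag_ids if m in rep_ids]
                ],
                namespace="KO",
            )
            completeness = mod.completeness_report(defs, ko_sub, config.module_report_min)
            report.modules_flagged = int(completeness["flag"].sum())
            save("module_completeness", completeness)

        stage("dereplicate_overall")
        derep_all = qc.dereplicate(site_reps, ani, config.ani_threshold, mode="overall")
        overall_reps = [m for m in site_reps if m.mag_id in derep_all.representative_set]
        report.n_overall_dereplicated = len(overall_reps)
        save("dereplication_overall", derep_all.to_frame())

        stage("ordination_community")
        overall_ids = [m.mag_id for m in overall_reps]
        abund_all = abund.subset(mag_ids=overall_ids)
        ok_samples = [s for s in abund_all.sample_ids if s not in abund_all.flagged_samples]
        rel = abund_all.relative_abundance[ok_samples].fillna(0.0).T
        rel = rel.loc[:, rel.sum(axis=0) > 0]
        if rel.shape[0] < 3 or rel.shape[1] < 2:
            logger.warning("too few detected MAGs/samples for ordination; stopping early")
            if out is not None:
                (out / "report.json").write_text(report.to_json())
            return report
        hel = ord_.hellinger(rel)
        dmat = ord_.bray_curtis(hel)
        meta = mio.samples_to_frame(list(samples)).set_index("sample_id").loc[ok_samples]
        perm = ord_.permanova_test(
            dmat, meta["sample_type"], n_perm=config.n_permutations, seed=config.seed
        )
        report.permanova["sample_type"] = {
            "pseudo_F": perm.pseudo_F, "R2": perm.r_squared,
            "p": perm.p_value, "n": perm.n,
        }
        cap_site = ord_.dbrda(dmat, meta["site"])
        save("community_scores", cap_site.scores, index=True)

        stage("ordination_water_quality")
        host_ids = [
            m.mag_id for m in overall_reps
            if labels.get(m.mag_id) == specificity.HOST_SPECIFIC
        ]
        coral_ids = [
            s.sample_id for s in samples
            if s.sample_type == "coral" and s.sample_id in ok_samples
        ]
        envfit_df = pd.DataFrame()
        if len(host_ids) >= 2 and len(coral_ids) >= 4:
            abund_host = abund.subset(mag_ids=host_ids, sample_ids=coral_ids)
            ok_coral = [
                s for s in abund_host.sample_ids if s not in abund_host.flagged_samples
            ]
            rel_h = abund_host.relative_abundance[ok_coral].fillna(0.0).T
            rel_h = rel_h.loc[:, rel_h.sum(axis=0) > 0]
            hel_h = ord_.hellinger(rel_h)
            d_h = ord_.bray_curtis(hel_h)
            wq = meta.loc[ok_coral, "wq_category"]
            cap_wq = ord_.dbrda(d_h, wq)
            perm_wq = ord_.permanova_test(
                d_h, wq, n_perm=config.n_permutations, seed=config.seed
            )
            report.permanova["wq_category"] = {
                "pseudo_F": perm_wq.pseudo_F, "R2": perm_wq.r_squared,
                "p": perm_wq.p_value, "n": perm_wq.n,
            }
            save("wq_scores", cap_wq.scores, index=True)
            posthoc = ord_.pairwise_posthoc(
                cap_wq.scores, wq, n_perm=config.n_permutations, seed=config.seed
            )
            save("wq_posthoc", posthoc)

            stage("envfit")
            env_cols = [
                c for c in meta.columns
                if c not in ("sample_type", "site", "wq_category", "library_size_gbp")
            ]
            env = meta.loc[ok_coral, env_cols].apply(pd.to_numeric, errors="coerce")
            env_std, removed = ord_.preprocess_env(env, config.collinearity_r)
            save("env_removed", pd.DataFrame(removed))
            envfit_df = ord_.envfit(
                cap_wq, env_std, n_perm=config.n_permutations, seed=config.seed
            )
            save("envfit", envfit_df)
            selected = (
                envfit_df[
                    (envfit_df["r_squared"] > config.envfit_r2_min)
                    & (envfit_df["adjusted_p"] <= 0.05)
                ]["variable"].tolist()
                if len(envfit_df)
                else []
            )
            report.envfit_significant = selected

            stage("ordination_env_constrained")
            if selected:
                cap_env = ord_.dbrda(d_h, env_std[selected].dropna())
                save("env_constrained_scores", cap_env.scores, index=True)

        stage("cluster_enrichment")
        if clusters is not None:
            cl_sub = mio.FeatureMatrix(
                counts=clusters.counts.loc[
                    [m for m in clusters.mag_ids if m in set(overall_ids)]
                ],
                namespace="cluster",
            )
            cl = stats.weighted_cluster_enrichment(
                cl_sub, abund_all, list(samples), factor="wq_category"
            )
            report.significant_cluster_pairs = (
                int((cl["raw_p"] < 0.05).sum()) if len(cl) else 0
            )
            save("cluster_enrichment", cl)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(report.stages[-1] if report.stages else "setup", exc) from exc

    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report


def run_pipeline_from_files(
    paths: dict[str, str | Path],
    config: mio.RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Read every input table from ``paths`` and run the pipeline.

    Required keys: mags, samples, coverage, ani. Optional: annotations_<ns>,
    clusters, modules.
    """
    config = config or mio.RunConfig()
    mags = mio.read_mags(paths["mags"])
    samples = mio.read_samples(paths["samples"])
    coverage = mio.read_coverage(paths["coverage"])
    ani = mio.read_ani(paths["ani"])
    annotations = {}
    for key, p in paths.items():
        if key.startswith("annotations_") and not key.endswith("cluster"):
            ns = key.split("_", 1)[1]
            annotations[ns] = mio.read_annotations(p, ns)
    clusters = None
    for key in ("clusters", "annotations_cluster"):
        if key in paths:
            clusters = mio.read_annotations(paths[key], "cluster")
            break
    module_rows = mio.read_modules(paths["modules"]) if "modules" in paths else None
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        mio.write_manifest(outdir, config, paths)
    return run_pipeline(
        mags, ani, samples, coverage, annotations, clusters, module_rows,
        config=config, outdir=outdir,
    )


def demo(seed: int = 7, outdir: str | Path | None = None,
         design: simulate.SimulationDesign | None = None,
         config: mio.RunConfig | None = None) -> PipelineReport:
    """Generate the default synthetic study and run the full pipeline on it."""
    design = design or simulate.SimulationDesign(seed=seed)
    study = simulate.generate_study(design)
    module_rows = simulate.generate_module_catalog(design)
    config = config or mio.RunConfig(seed=seed, n_permutations=199)
    return run_pipeline(
        study.mags, study.ani, study.samples, study.coverage,
        study.annotations, study.clusters, module_rows,
        config=config, outdir=outdir,
    )
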