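"""End-to-end orchestration of the signature-discovery workflow.

The pipeline runs each comparison (pooled disorder vs healthy, and each
disease vs healthy) through the full funnel — DEG screen, two-way
clustering, SVM training with LOOCV and weight filtering, PCA with probit
component tests and loading-threshold signature selection — intersects
the per-disease signatures into the common set, and closes with
mutual-exclusivity module discovery on the common signature genes.

Everything is a pure function of (inputs, configuration, seed); the JSON
report contains no timestamps, so identical runs produce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ExpressionMatrix
from .simulate import SimulationConfig, simulate_cohorts
from .merge import merge_studies
from .differential import student_t_test, select_degs, two_way_clustering
from .classify import (
    train_svm, gene_weights, filter_by_weight, loocv, predictive_power, roc_auc,
    SVMModel,
)
from .signature import (
    fit_pca, select_components, probit_significance, select_signature_genes,
    intersect_signatures,
)
from .mutex import binarize_alterations, mutex_mcmc, consensus_modules

log = logging.getLogger("lungsig")

__all__ = ["PipelineConfig", "run_pipeline", "validate_external_cohort"]


@dataclass
class PipelineConfig:
    """All stage thresholds plus either a simulation or input paths."""

    simulation: SimulationConfig | None = None
    expression_paths: list[str] = field(default_factory=list)
    sample_sheet_path: str | None = None
    # stage thresholds
    alpha: float = 0.05
    weight_threshold: float = 1.0
    cum_threshold: float = 0.85
    loading_threshold: float = 0.6
    probit_alpha: float = 0.05
    k_sd: float = 2.0
    t_modules: int = 2
    k_genes_per_module: int = 2
    delta: float = 0.2
    # SVM
    sigma: float = 0.1
    cost: float = 1.0
    # merge
    merge_k_genes: int = 25
    merge_k_samples: int = 5
    merge_tol: float = 1e-4
    merge_max_iter: int = 50
    # MCMC
    mcmc_iterations: int = 100_000
    mcmc_burn_in: int = 10_000
    mcmc_thinning: int = 10
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1 or not 0 <= self.probit_alpha <= 1:
            raise ValueError("alpha thresholds must lie in [0, 1]")
        if not 0 < self.cum_threshold <= 1:
            raise ValueError("cum_threshold must lie in (0, 1]")
        if not 0 <= self.loading_threshold <= 1:
            raise ValueError("loading_threshold must lie in [0, 1]")
        if self.simulation is None and not self.expression_paths:
            raise ValueError("either a simulation config or input paths required")


def _load_inputs(config: PipelineConfig):
    from .ingest import read_expression, collapse_probes
    from .containers import ProbeMatrix

    if config.simulation is not None:
        sim = config.simulation
        studies, sheet, truth = simulate_cohorts(sim)
        return list(studies.values()), truth
    mats = []
    for path in config.expression_paths:
        m = read_expression(path, config.sample_sheet_path)
        if isinstance(m, ProbeMatrix):
            m = collapse_probes(m)
        mats.append(m)
    return mats, None


def _stage(name: str, started: float, **dims) -> None:
    extra = " ".join(f"{k}={v}" for k, v in dims.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - started, extra)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the report dict (also written
    to ``<outdir>/report.json`` with all intermediate tables when an
    output directory is configured)."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    studies, truth = _load_inputs(config)
    _stage("load", t0, n_studies=len(studies))

    t0 = time.perf_counter()
    merged, merge_model = merge_studies(
        studies, k_genes=config.merge_k_genes, k_samples=config.merge_k_samples,
        tol=config.merge_tol, max_iter=config.merge_max_iter, seed=config.seed,
    )
    _stage("merge", t0, genes=merged.n_genes, samples=merged.n_samples,
           iterations=merge_model.n_iter)

    diseases = [p for p in ("IPF", "NSCLC")
                if (merged.samples["phenotype"] == p).any()]
    comparisons: dict[str, list[str]] = {}
    if len(diseases) > 1:
        comparisons["disorder_vs_healthy"] = diseases
    for d in diseases:
        comparisons[f"{d}_vs_healthy"] = [d]

    report: dict = {
        "version": __version__,
        "config": _config_echo(config),
        "merge": {"j_trace": merge_model.j_trace,
                  "n_iter": merge_model.n_iter,
                  "converged": merge_model.converged},
        "comparisons": {},
        "warnings": [],
    }
    signatures: dict[str, pd.DataFrame] = {}
    deg_tables: dict[str, pd.DataFrame] = {}

    for name, disease_group in comparisons.items():
        entry, sig, degs = _run_comparison(
            merged, name, disease_group, config, outdir, report["warnings"]
        )
        report["comparisons"][name] = entry
        if sig is not None:
            signatures[name] = sig
        if degs is not None:
            deg_tables[name] = degs

    # common signature across the two diseases
    per_disease = [f"{d}_vs_healthy" for d in diseases]
    common = None
    if len(per_disease) == 2 and all(n in signatures for n in per_disease):
        common, conflicts = intersect_signatures(
            signatures[per_disease[0]], signatures[per_disease[1]]
        )
        report["common_signature"] = {
            "n_genes": int(len(common)),
            "genes": common.index.tolist(),
            "directions": common["direction"].to_dict(),
            "direction_conflicts": conflicts,
        }
        if outdir is not None:
            common.to_csv(outdir / "common_signature.tsv", sep="\t")
    else:
        report["common_signature"] = {"n_genes": 0, "genes": [],
                                      "directions": {}, "direction_conflicts": []}
        report["warnings"].append("common signature unavailable")

    # mutual exclusivity on the common signature, per disease
    report["mutex"] = {}
    if common is not None and len(common) >= config.t_modules * config.k_genes_per_module:
        healthy = merged.subset_samples(merged.phenotype_mask("healthy"))
        for d in diseases:
            report["mutex"][d] = _run_mutex(
                merged, healthy, d, common, config, outdir, report["warnings"]
            )
    elif common is not None:
        report["warnings"].append(
            "too few common signature genes for mutual exclusivity")

    if outdir is not None:
        merge_model.to_json(outdir / "merge_model.json")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        (outdir / "report.txt").write_text(_human_report(report))
    return report


def _run_comparison(merged, name, disease_group, config, outdir, warnings_sink):
    t0 = time.perf_counter()
    sub = merged.subset_samples(merged.phenotype_mask(disease_group + ["healthy"]))
    deg_table = student_t_test(sub, disease_group)
    degs = select_degs(deg_table, alpha=config.alpha)
    entry: dict = {"n_degs": int(len(degs))}
    if outdir is not None:
        degs.to_csv(outdir / f"degs_{name}.tsv", sep="\t")
    if degs.empty:
        warnings_sink.append(f"{name}: no DEGs at alpha={config.alpha}; branch halted")
        entry["halted"] = "no_degs"
        return entry, None, None

    deg_m = sub.subset_genes(degs.index)
    twc = two_way_clustering(deg_m)
    if outdir is not None:
        (outdir / f"tree_genes_{name}.nwk").write_text(twc.gene_newick())
        (outdir / f"tree_samples_{name}.nwk").write_text(twc.sample_newick())

    svm = train_svm(deg_m, disease_group, sigma=config.sigma, cost=config.cost,
                    seed=config.seed)
    weights = gene_weights(svm)
    kept = filter_by_weight(weights, config.weight_threshold)
    entry["n_weight_filtered"] = int(len(kept))
    entry["svm_cv_accuracy"] = svm.cv_accuracy
    if outdir is not None:
        weights.to_csv(outdir / f"weights_{name}.tsv", sep="\t")

    preds = loocv(deg_m, disease_group, sigma=config.sigma, cost=config.cost,
                  seed=config.seed)
    power, correct, total = predictive_power(preds)
    pos = disease_group[0] if len(disease_group) == 1 else "disorder"
    roc_points, auc = roc_auc(preds, positive=pos)
    entry.update({"predictive_power": power, "correct": correct,
                  "total": total, "auc": auc})
    if outdir is not None:
        preds.to_csv(outdir / f"loocv_{name}.tsv", sep="\t")
        roc_points.to_csv(outdir / f"roc_{name}.tsv", sep="\t", index=False)

    if not kept:
        warnings_sink.append(
            f"{name}: no genes above weight threshold; branch halted")
        entry["halted"] = "no_weighted_genes"
        return entry, None, degs

    pca = fit_pca(sub.subset_genes(kept))
    candidates = select_components(pca, config.cum_threshold)
    labels = np.where(sub.samples["phenotype"].isin(disease_group),
                      "disease", "healthy")
    tests = probit_significance(pca.scores[candidates], labels, positive="disease")
    significant = tests.index[tests["p"] < config.probit_alpha].tolist()
    sig = select_signature_genes(
        pca, significant, degs["direction"],
        loading_threshold=config.loading_threshold, comparison=name,
    )
    entry.update({
        "candidate_pcs": candidates,
        "significant_pcs": significant,
        "probit_p": {pc: float(p) for pc, p in tests["p"].items()},
        "n_signature": int(len(sig)),
    })
    if outdir is not None:
        pca.summary().to_csv(outdir / f"pca_summary_{name}.tsv", sep="\t")
        tests.to_csv(outdir / f"probit_{name}.tsv", sep="\t")
        sig.to_csv(outdir / f"signature_{name}.tsv", sep="\t")
    if sig.empty:
        warnings_sink.append(f"{name}: empty signature set")
    _stage(name, t0, degs=len(degs), weighted=len(kept), signature=len(sig))
    return entry, sig, degs


def _run_mutex(merged, healthy, disease, common, config, outdir, warnings_sink):
    t0 = time.perf_counter()
    disease_m = merged.subset_samples(merged.phenotype_mask(disease))
    alt = binarize_alterations(
        disease_m, healthy, common["direction"], k_sd=config.k_sd)
    margins = alt.margins
    usable = int(((margins > 0) & (margins < alt.n_samples)).sum())
    entry: dict = {
        "n_genes": int(alt.values.shape[0]),
        "n_usable_genes": usable,
        "excluded_genes": alt.excluded_genes,
    }
    need = config.t_modules * config.k_genes_per_module
    if usable < need:
        warnings_sink.append(
            f"mutex[{disease}]: fewer than {need} usable genes; stage skipped")
        entry["halted"] = "too_few_genes"
        return entry
    graph = mutex_mcmc(
        alt, t=config.t_modules, k=config.k_genes_per_module,
        iterations=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
        thinning=config.mcmc_thinning, seed=config.seed,
    )
    modules = consensus_modules(graph, alt, delta=config.delta)
    entry["modules"] = [
        {"genes": m.genes, "phi": m.phi, "coverage": m.coverage,
         "per_gene_coverage": m.per_gene_coverage,
         "exclusive_counts": m.exclusive_counts}
        for m in modules
    ]
    if outdir is not None:
        alt.values.to_csv(outdir / f"alterations_{disease}.tsv", sep="\t")
        graph.edge_list().to_csv(
            outdir / f"marginal_edges_{disease}.tsv", sep="\t", index=False)
        (outdir / f"modules_{disease}.json").write_text(
            json.dumps(entry["modules"], indent=1))
    _stage(f"mutex_{disease}", t0, genes=alt.values.shape[0],
           modules=len(modules))
    return entry


def validate_external_cohort(
    signature: pd.DataFrame,
    model: SVMModel,
    cohort: ExpressionMatrix,
    disease: str | list[str],
    control: str = "healthy",
) -> dict:
    """Apply a frozen training model to an external cohort.

    Cohort genes are intersected with the model's genes; genes missing in
    the cohort are imputed at the training means (i.e. zero after
    standardization) and listed in the result. Returns common-gene count,
    per-sample predictions, predictive power and ROC/AUC.
    """
    diseases = [disease] if isinstance(disease, str) else list(disease)
    pos = model.classes[1]
    present = [g for g in model.genes if g in set(cohort.genes)]
    if not present:
        raise ValueError("no overlap between cohort genes and model genes")
    missing = [g for g in model.genes if g not in set(present)]
    mask = cohort.phenotype_mask(diseases + [control])
    sub = cohort.subset_samples(mask)
    X = np.tile(model.scaler.mean_, (sub.n_samples, 1))
    pos_idx = {g: i for i, g in enumerate(model.genes)}
    vals = sub.values.loc[present].to_numpy(dtype=float).T
    for j, g in enumerate(present):
        X[:, pos_idx[g]] = vals[:, j]
    Xs = model.scaler.transform(X)
    proba = model.calibrator.predict_proba(Xs)[
        :, list(model.calibrator.classes_).index(pos)]
    pred = model.clf.predict(Xs)
    truth = np.where(sub.samples["phenotype"].isin(diseases), pos, control)
    preds = pd.DataFrame(
        {"truth": truth, "predicted": pred, "probability": proba},
        index=pd.Index(sub.sample_ids, name="sample_id"),
    )
    power, correct, total = predictive_power(preds)
    roc_points, auc = roc_auc(preds, positive=pos)
    common_sig = int(len(signature.index.intersection(cohort.genes)))
    return {
        "n_common_genes": len(present),
        "n_common_signature_genes": common_sig,
        "imputed_genes": missing,
        "predictions": preds,
        "predictive_power": power,
        "correct": correct,
        "total": total,
        "roc": roc_points,
        "auc": auc,
    }


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    if config.simulation is not None:
        echo["simulation"] = asdict(config.simulation)
    return json.loads(json.dumps(echo, default=str, sort_keys=True))


def _human_report(report: dict) -> str:
    lines = [f"lungsig {report['version']} pipeline report", ""]
    for name, entry in report["comparisons"].items():
        lines.append(f"[{name}]")
        for key in ("n_degs", "n_weight_filtered", "predictive_power",
                    "correct", "total", "auc", "significant_pcs",
                    "n_signature", "halted"):
            if key in entry:
                lines.append(f"  {key}: {entry[key]}")
        lines.append("")
    cs = report.get("common_signature", {})
    lines.append(f"common signature genes: {cs.get('n_genes', 0)}")
    for d, entry in report.get("mutex", {}).items():
        mods = entry.get("modules", [])
        lines.append(f"mutex[{d}]: {len(mods)} modules")
        for m in mods:
            lines.append(
                f"  {'+'.join(m['genes'])} phi={m['phi']:.3g} "
                f"coverage={m['coverage']:.3f}")
    if report.get("warnings"):
        lines.append("")
        lines.append("warnings:")
        lines += [f"  - {w}" for w in report["warnings"]]
    return "\n".join(lines) + "\n"
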