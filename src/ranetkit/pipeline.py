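"""Configuration-driven orchestration of the full analysis.

Stages run in method order — simulate (optional), preprocess, DEP
discovery, enrichment, network reconstruction/scoring, regulators — each
reading its inputs from files and writing its outputs plus a manifest
entry with SHA-256 checksums, so any stage can be resumed from prior
outputs and a rerun with identical seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from ranetkit import dep, io, network as net, regulators as regs, simulate
from ranetkit.errors import RanetkitError
from ranetkit.preprocess import (
    collapse_probes_to_genes,
    combine_matrices,
    compute_fold_changes,
    cross_study_quantile_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters and paths; thresholds default to the
    pipeline's standard operating point (k=30 clusters, 95th percentile,
    membership alpha 0.05, TF/hub alpha 0.01, 100,000 resamples)."""

    out_dir: str = "pipeline_out"
    seed: int = 1
    # simulate
    simulate: bool = True
    n_studies: int = 3
    n_genes: int = 2000
    samples_per_arm: int = 5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    # preprocess
    match: str = "intersection"
    expr_paths: list[str] = field(default_factory=list)
    sample_sheet: str | None = None
    probe_map: str | None = None
    # dep discovery
    n_clusters: int = 30
    n_permutations: int = 20
    percentile: float = 95.0
    membership_alpha: float = 0.05
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    nmf_restarts: int = 1
    perm_max_iter: int = 200
    # enrichment / regulators
    n_resamples: int = 100_000
    enrichment_alpha: float = 0.05
    regulator_alpha: float = 0.01
    hub_pool: str = "all"  # "all" ppi nodes | "network" (perturbed net + neighbors)
    # inputs for network stages (auto-filled when simulating)
    ppi_path: str | None = None
    modules_gmt: str | None = None
    tf_gmt: str | None = None
    overlays_gmt: str | None = None

    def validate(self) -> None:
        for name in ("membership_alpha", "enrichment_alpha", "regulator_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise RanetkitError(f"{name} must be in (0,1), got {v}")
        if not (0 < self.percentile < 100):
            raise RanetkitError("percentile must be in (0,100)")
        if not self.simulate:
            needed = {
                "expr_paths": self.expr_paths,
                "sample_sheet": self.sample_sheet,
                "ppi_path": self.ppi_path,
                "modules_gmt": self.modules_gmt,
            }
            for k, v in needed.items():
                if not v:
                    raise RanetkitError(f"config requires {k} when simulate is off")
            for p in [*self.expr_paths, self.sample_sheet, self.ppi_path, self.modules_gmt]:
                if p and not Path(p).exists():
                    raise RanetkitError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict[str, Any] | None = None) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides or {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise RanetkitError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def fast_profile(self) -> "PipelineConfig":
        """Reduced resampling/permutation budget for quick runs."""
        cfg = PipelineConfig(**asdict(self))
        cfg.n_resamples = min(cfg.n_resamples, 10_000)
        cfg.n_permutations = min(cfg.n_permutations, 20)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(manifest: dict, stage: str, outputs: list[Path], params: dict) -> None:
    manifest["stages"][stage] = {
        "status": "completed",
        "parameters": params,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Write a full synthetic scenario and its ground truth."""
    studies, truth = simulate.generate_multistudy_expression(
        n_studies=cfg.n_studies,
        n_genes=cfg.n_genes,
        samples_per_arm=cfg.samples_per_arm,
        effect_size=cfg.effect_size,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    genes = studies[0].probe_ids
    core_truth = sorted(truth.genes_in_group("dominant_up"))
    ppi, net_truth = simulate.generate_interaction_network(
        genes, core_genes=core_truth, seed=cfg.seed + 1
    )
    modules, mod_truth = simulate.generate_annotation_sets(truth, genes, seed=cfg.seed + 2)
    tf_map, tf_truth = simulate.generate_tf_target_map(genes, core_truth, seed=cfg.seed + 3)
    overlays = simulate.generate_overlay_signatures(mod_truth, genes, seed=cfg.seed + 4)
    truth.planted_hubs = net_truth.planted_hubs
    truth.planted_tfs = tf_truth.planted_tfs
    truth.planted_module_map = mod_truth.planted_module_map

    outputs = []
    rows = []
    for st in studies:
        p = out / f"expr_{st.study_id}.tsv"
        st.values.to_csv(p, sep="\t", index_label="probe", float_format="%.6g")
        outputs.append(p)
        rows.extend((s, st.conditions[s], st.study_id) for s in st.sample_ids)
    sheet = out / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tcondition\tstudy_id\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    pmap = out / "probe_map.tsv"
    with open(pmap, "w") as fh:  # identity probe map
        for g in genes:
            fh.write(f"{g}\t{g}\n")
    ppi_p = out / "ppi.tsv"
    with open(ppi_p, "w") as fh:
        for a, b, data in sorted(ppi.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('source', 'pp')}\n")
    gmt_mod, gmt_tf, gmt_ov = out / "modules.gmt", out / "tf_targets.gmt", out / "overlays.gmt"
    io.write_gmt(modules, gmt_mod)
    io.write_gmt(tf_map, gmt_tf)
    io.write_gmt(overlays, gmt_ov)
    truth_p = out / "truth.json"
    truth.to_json(truth_p)
    outputs += [sheet, pmap, ppi_p, gmt_mod, gmt_tf, gmt_ov, truth_p]
    cfg.expr_paths = [str(out / f"expr_{st.study_id}.tsv") for st in studies]
    cfg.sample_sheet = str(sheet)
    cfg.probe_map = str(pmap)
    cfg.ppi_path = str(ppi_p)
    cfg.modules_gmt = str(gmt_mod)
    cfg.tf_gmt = str(gmt_tf)
    cfg.overlays_gmt = str(gmt_ov)
    return {"outputs": outputs, "params": {"seed": cfg.seed, "n_genes": cfg.n_genes}}


def stage_preprocess(cfg: PipelineConfig, out: Path) -> dict:
    studies = io.load_studies(cfg.expr_paths, cfg.sample_sheet)
    probe_map = io.read_probe_map(cfg.probe_map) if cfg.probe_map else None
    matrices = []
    for st in studies:
        for condition in ("disease_primary", "disease_comparator"):
            if not st.samples_with(condition):
                continue
            fc = compute_fold_changes(st, condition)
            if probe_map:
                fc, _ = collapse_probes_to_genes(fc, probe_map)
            else:
                fc.level = "gene"
            matrices.append(fc)
    normed = cross_study_quantile_normalize(matrices)
    combined = combine_matrices(normed, match=cfg.match)
    p = out / "combined_fold_changes.tsv"
    io.write_combined_matrix(combined, p)
    return {"outputs": [p], "params": {"match": cfg.match, "n_matrices": len(matrices)}}


def stage_dep(cfg: PipelineConfig, out: Path) -> dict:
    combined = io.read_combined_matrix(out / "combined_fold_changes.tsv")
    result = dep.run_dep_discovery(
        combined,
        n_clusters=cfg.n_clusters,
        alpha=cfg.membership_alpha,
        n_permutations=cfg.n_permutations,
        percentile=cfg.percentile,
        seed=cfg.seed,
        max_iter=cfg.nmf_max_iter,
        tol=cfg.nmf_tol,
        n_restarts=cfg.nmf_restarts,
        perm_max_iter=cfg.perm_max_iter,
    )
    clusters_p = out / "dep_clusters.tsv"
    with open(clusters_p, "w") as fh:
        fh.write("cluster_id\tdirection\tclass_label\tsignificant\tn_samples\tgene\tadjusted_p\n")
        for c in result.clusters:
            for gene, adj in sorted(c.member_genes):
                fh.write(
                    f"{c.cluster_id}\t{c.direction}\t{c.class_label}\t{int(c.significant)}"
                    f"\t{c.n_samples}\t{gene}\t{adj:.6g}\n"
                )
    thr_p = out / "permutation_thresholds.json"
    t = result.thresholds
    thr_p.write_text(
        json.dumps(
            {
                "gene_count_threshold": t.gene_count_threshold,
                "sample_count_threshold": t.sample_count_threshold,
                "percentile": t.percentile,
                "n_permutations": t.n_permutations,
                "basis_cutoff": t.basis_cutoff,
                "activation_cutoff": t.activation_cutoff,
            },
            indent=1,
        )
    )
    core_p = out / "core_genes.txt"
    io.write_gene_list(result.core_genes, core_p)
    return {
        "outputs": [clusters_p, thr_p, core_p],
        "params": {"n_clusters": cfg.n_clusters, "seed": cfg.seed},
    }


def stage_enrich(cfg: PipelineConfig, out: Path) -> dict:
    from ranetkit.enrichment import empirical_set_enrichment

    core = io.read_gene_list(out / "core_genes.txt")
    combined = io.read_combined_matrix(out / "combined_fold_changes.tsv")
    universe = combined.gene_ids
    annotations = io.read_gmt(cfg.modules_gmt, category="process")
    results = empirical_set_enrichment(
        query=set(core) & set(universe),
        annotations=annotations,
        universe=universe,
        n_resamples=cfg.n_resamples,
        seed=cfg.seed,
    )
    p = out / "enrichment.tsv"
    io.write_enrichment_table(results, p)
    return {"outputs": [p], "params": {"n_resamples": cfg.n_resamples}}


def stage_network(cfg: PipelineConfig, out: Path) -> dict:
    core = io.read_gene_list(out / "core_genes.txt")
    ppi = net.load_interactions(cfg.ppi_path)
    annotations = io.read_gmt(cfg.modules_gmt, category="process")
    perturbed = net.reconstruct_perturbed_network(core, annotations, ppi)
    modules = net.assign_network_modules(perturbed, annotations)
    n_nodes = perturbed.graph.number_of_nodes()
    score_rows = []
    if cfg.overlays_gmt:
        overlays = io.read_gmt(cfg.overlays_gmt, category="signature")
        for ov in overlays:
            net.overlay_signature(perturbed, ov.genes, ov.term_id)
            for m in modules:
                s = net.module_enrichment_score(
                    m, ov.genes, network_size=n_nodes, core_set_size=len(core), overlay_label=ov.term_id
                )
                score_rows.append(s)
    sif_p, gml_p, mod_p, mes_p = (
        out / "network.sif",
        out / "network.graphml",
        out / "network_modules.tsv",
        out / "module_scores.tsv",
    )
    net.write_sif(perturbed, sif_p)
    net.write_graphml(perturbed, gml_p)
    with open(mod_p, "w") as fh:
        fh.write("module_id\tgene\trole\n")
        for m in sorted(modules, key=lambda m: m.module_id):
            for g in sorted(m.genes):
                fh.write(f"{m.module_id}\t{g}\t{perturbed.graph.nodes[g].get('role', '')}\n")
    with open(mes_p, "w") as fh:
        fh.write("module_id\toverlay\toverlap\tmodule_size\tmes\n")
        for s in score_rows:
            fh.write(f"{s.module_id}\t{s.overlay_label}\t{s.overlap_count}\t{s.module_size}\t{s.score:.6g}\n")
    return {
        "outputs": [sif_p, gml_p, mod_p, mes_p],
        "params": perturbed.load_report,
    }


def stage_regulators(cfg: PipelineConfig, out: Path) -> dict:
    core = io.read_gene_list(out / "core_genes.txt")
    combined = io.read_combined_matrix(out / "combined_fold_changes.tsv")
    universe = combined.gene_ids
    ppi = net.load_interactions(cfg.ppi_path)
    annotations = io.read_gmt(cfg.modules_gmt, category="process")
    perturbed = net.reconstruct_perturbed_network(core, annotations, ppi)
    modules = net.assign_network_modules(perturbed, annotations)
    if cfg.hub_pool == "all":
        pool = sorted(ppi.nodes)
    else:
        pool = sorted(perturbed.nodes | {n for g in perturbed.nodes for n in ppi.neighbors(g)})
        pool = [p for p in pool if p in ppi.nodes]
    core_in_univ = sorted(set(core) & set(universe))
    hubs = regs.test_hubs_significance(
        ppi, pool, core_in_univ, universe,
        n_resamples=cfg.n_resamples, seed=cfg.seed, alpha=cfg.regulator_alpha,
    )
    hubs = [h for h in hubs if h.significant]
    tfs = []
    if cfg.tf_gmt:
        tf_map = io.read_gmt(cfg.tf_gmt, category="tf_targets")
        tfs = regs.identify_key_tfs(
            tf_map, core_in_univ, universe,
            n_resamples=cfg.n_resamples, seed=cfg.seed + 1, alpha=cfg.regulator_alpha,
        )
        regs.associate_candidates_with_modules(hubs + tfs, modules, tf_map)
    else:
        regs.associate_candidates_with_modules(hubs, modules)
    table = regs.prioritize_candidates(hubs + tfs, modules)
    p = out / "regulators.tsv"
    table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    return {
        "outputs": [p],
        "params": {"n_hub_candidates": len(pool), "n_key_hubs": len(hubs), "n_key_tfs": len(tfs)},
    }


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("dep", stage_dep),
    ("enrich", stage_enrich),
    ("network", stage_network),
    ("regulators", stage_regulators),
]


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to
    out_dir/manifest.json).  A stage failure leaves a partial manifest
    with the failure recorded and re-raises."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    manifest_p = out / "manifest.json"
    for name, fn in STAGES:
        if name == "simulate" and not cfg.simulate:
            continue
        logger.info("stage %s ...", name)
        try:
            res = fn(cfg, out)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            manifest["config"] = asdict(cfg)
            manifest_p.write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise
        _record(manifest, name, res["outputs"], res["params"])
    manifest["config"] = asdict(cfg)
    manifest_p.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
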