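"""Synthetic multi-study inputs with planted ground truth.

Every input the pipeline consumes can be generated here: per-study log2
intensity tables with normal / primary-disease / comparator-disease arms,
a scale-free interaction network with planted hubs, TF-target maps with
planted enriched TFs, process/disease annotation sets, and overlay
signatures.  The planted structure mirrors the statistical shape of a
multi-cohort synovium compendium: genes fall into five groups —

* ``shared_up`` / ``shared_down``: shifted by ±effect_size in both disease
  arms of every study,
* ``dominant_up`` / ``dominant_down``: shifted only in the primary arm,
* ``null``: no shift —

with i.i.d. Gaussian measurement noise and a per-study multiplicative
jitter on the effect scale, so cross-study quantile normalization has real
work to do.  Defaults follow the pipeline's intended operating point:
three studies, 2000 genes, five samples per arm, two log2 units of effect,
noise sd 0.5, and a dominant-up group of 7% of genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ranetkit.enrichment import GeneSetAnnotation
from ranetkit.network import InteractionNetwork, build_network
from ranetkit.preprocess import ExpressionStudy

#: the sixteen default process-module labels of the perturbed network
DEFAULT_MODULE_LABELS = (
    "AP", "TC", "BC", "IG", "CA", "NK", "IC", "CK",
    "CMH", "TLR", "AF", "JS", "CC", "CDS", "ECM", "MR",
)

GROUP_NAMES = ("shared_up", "dominant_up", "shared_down", "dominant_down", "null")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic scenario."""

    planted_groups: dict[str, set[str]] = field(default_factory=dict)
    planted_hubs: set[str] = field(default_factory=set)
    planted_tfs: set[str] = field(default_factory=set)
    planted_module_map: dict[str, set[str]] = field(default_factory=dict)
    seeds_used: list[int] = field(default_factory=list)

    def genes_in_group(self, name: str) -> set[str]:
        return set(self.planted_groups.get(name, set()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_groups": {k: sorted(v) for k, v in self.planted_groups.items()},
            "planted_hubs": sorted(self.planted_hubs),
            "planted_tfs": sorted(self.planted_tfs),
            "planted_module_map": {k: sorted(v) for k, v in self.planted_module_map.items()},
            "seeds_used": self.seeds_used,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_groups={k: set(v) for k, v in payload["planted_groups"].items()},
            planted_hubs=set(payload["planted_hubs"]),
            planted_tfs=set(payload["planted_tfs"]),
            planted_module_map={k: set(v) for k, v in payload["planted_module_map"].items()},
            seeds_used=list(payload["seeds_used"]),
        )


def default_group_sizes(n_genes: int) -> dict[str, int]:
    """7% of genes per planted group (the dominant-up share of a
    2000-gene scenario is 140 genes); the remainder is null."""
    k = int(round(0.07 * n_genes))
    return {"shared_up": k, "dominant_up": k, "shared_down": k, "dominant_down": k}


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_multistudy_expression(
    n_studies: int = 3,
    n_genes: int = 2000,
    samples_per_arm: int = 5,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    group_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Per-study log2 intensities with planted differential groups.

    Per study and gene, baseline ~ N(8, 1); condition offsets add
    ±effect_size for the planted groups (shared groups in both disease
    arms, dominant groups only in the primary arm), scaled by a per-study
    jitter ~ U(0.8, 1.25); measurement noise ~ N(0, noise_sd²).
    """
    if n_studies < 1 or n_genes < 1 or samples_per_arm < 1:
        raise ValueError("n_studies, n_genes and samples_per_arm must be positive")
    sizes = dict(group_sizes) if group_sizes is not None else default_group_sizes(n_genes)
    unknown = set(sizes) - set(GROUP_NAMES)
    if unknown:
        raise ValueError(f"unknown group names {sorted(unknown)}")
    if sum(sizes.values()) > n_genes:
        raise ValueError("group sizes exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    order = rng.permutation(n_genes)
    groups: dict[str, set[str]] = {}
    pos = 0
    for name in ("shared_up", "dominant_up", "shared_down", "dominant_down"):
        k = sizes.get(name, 0)
        groups[name] = {genes[i] for i in order[pos : pos + k]}
        pos += k
    groups["null"] = {genes[i] for i in order[pos:]}

    sign = np.zeros(n_genes)
    dominant_only = np.zeros(n_genes, dtype=bool)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in groups["shared_up"]:
        sign[gidx[g]] = 1.0
    for g in groups["dominant_up"]:
        sign[gidx[g]] = 1.0
        dominant_only[gidx[g]] = True
    for g in groups["shared_down"]:
        sign[gidx[g]] = -1.0
    for g in groups["dominant_down"]:
        sign[gidx[g]] = -1.0
        dominant_only[gidx[g]] = True

    arms = (
        ("normal", np.zeros(n_genes)),
        ("disease_primary", sign * effect_size),
        ("disease_comparator", np.where(dominant_only, 0.0, sign * effect_size)),
    )
    studies = []
    for s in range(1, n_studies + 1):
        baseline = rng.normal(8.0, 1.0, size=n_genes)
        jitter = rng.uniform(0.8, 1.25)
        cols, names, conds = [], [], {}
        for arm, offset in arms:
            for j in range(1, samples_per_arm + 1):
                name = f"ST{s}_{arm}_{j}"
                col = baseline + jitter * offset + rng.normal(0.0, noise_sd, size=n_genes)
                cols.append(col)
                names.append(name)
                conds[name] = arm
        values = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="probe"), columns=names)
        studies.append(ExpressionStudy(study_id=f"ST{s}", values=values, conditions=conds))
    truth = GroundTruth(planted_groups=groups, seeds_used=[seed])
    return studies, truth


def generate_interaction_network(
    genes: Sequence[str],
    attach_m: int = 2,
    n_planted_hubs: int = 5,
    core_genes: Sequence[str] = (),
    core_bias: float = 0.5,
    seed: int = 0,
) -> tuple[InteractionNetwork, GroundTruth]:
    """Scale-free (preferential-attachment) interaction graph over the
    given genes, with planted hubs wired to the core set.

    Each planted hub — chosen among non-core nodes — gains an edge to each
    core gene independently with probability ``core_bias``; the hubs are
    also wired to each other (regulator complexes), so jointly they put
    the whole targeted core set within two hops of every hub.
    """
    n = len(genes)
    if n <= attach_m:
        raise ValueError("need more nodes than the attachment parameter")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, attach_m, seed=int(rng.integers(2**31 - 1)))
    mapping = dict(enumerate(genes))
    g = nx.relabel_nodes(g, mapping)
    core = [c for c in core_genes if c in set(genes)]
    non_core = sorted(set(genes) - set(core))
    hubs: set[str] = set()
    if n_planted_hubs > 0:
        pool = non_core if len(non_core) >= n_planted_hubs else sorted(genes)
        hubs = set(rng.choice(pool, size=n_planted_hubs, replace=False))
        for h in sorted(hubs):
            wired = rng.random(len(core)) < core_bias
            for c, w in zip(core, wired):
                if w and c != h:
                    g.add_edge(h, c)
        for a in sorted(hubs):
            for b in sorted(hubs):
                if a < b:
                    g.add_edge(a, b)
    edges = [(a, b, "pp") for a, b in g.edges()]
    net = build_network(edges)
    truth = GroundTruth(planted_hubs=hubs, seeds_used=[seed])
    return net, truth


def generate_tf_target_map(
    universe: Sequence[str],
    core_genes: Sequence[str],
    n_tfs: int = 20,
    targets_per_tf: int = 50,
    n_planted_tfs: int = 4,
    core_overlap_fraction: float = 0.4,
    seed: int = 0,
) -> tuple[list[GeneSetAnnotation], GroundTruth]:
    """TF -> target GMT collection with planted core-enriched TFs.

    Background TFs draw targets uniformly from the universe (so their core
    overlap sits at the base rate); planted TFs draw
    ``core_overlap_fraction`` of their targets from the core set.
    """
    if n_tfs == 0:
        return [], GroundTruth(seeds_used=[seed])
    if n_planted_tfs > n_tfs:
        raise ValueError("more planted TFs than TFs")
    rng = np.random.default_rng(seed)
    univ = sorted(set(universe))
    core = sorted(set(core_genes) & set(univ))
    non_core = sorted(set(univ) - set(core))
    annotations = []
    planted: set[str] = set()
    for t in range(1, n_tfs + 1):
        tf_id = f"TF{t:02d}"
        if t <= n_planted_tfs:
            planted.add(tf_id)
            k_core = min(int(round(core_overlap_fraction * targets_per_tf)), len(core))
            k_rest = targets_per_tf - k_core
            targets = set(rng.choice(core, size=k_core, replace=False)) | set(
                rng.choice(non_core, size=min(k_rest, len(non_core)), replace=False)
            )
        else:
            targets = set(rng.choice(univ, size=min(targets_per_tf, len(univ)), replace=False))
        annotations.append(
            GeneSetAnnotation(tf_id, f"tf_targets:{tf_id}", "tf_targets", frozenset(targets))
        )
    truth = GroundTruth(planted_tfs=planted, seeds_used=[seed])
    return annotations, truth


def generate_annotation_sets(
    truth: GroundTruth,
    universe: Sequence[str],
    module_labels: Sequence[str] = DEFAULT_MODULE_LABELS,
    genes_per_module: int = 15,
    from_group: str = "dominant_up",
    group_fraction: float = 0.8,
    disjoint: bool = False,
    seed: int = 0,
) -> tuple[list[GeneSetAnnotation], GroundTruth]:
    """Process-module annotation terms planted on one expression group.

    Each module term draws ``group_fraction`` of its genes from the named
    planted group (default dominant_up, emulating disease-process
    annotations of the disease-dominant genes) and the rest from the whole
    universe.  With ``disjoint=True`` the group genes are partitioned so
    terms do not overlap.
    """
    rng = np.random.default_rng(seed)
    group = sorted(truth.genes_in_group(from_group) & set(universe))
    univ = sorted(set(universe))
    if not group:
        raise ValueError(f"group {from_group!r} has no genes in the universe")
    k_group = int(round(group_fraction * genes_per_module))
    annotations = []
    module_map: dict[str, set[str]] = {}
    if disjoint:
        needed = k_group * len(module_labels)
        if needed > len(group):
            raise ValueError("not enough group genes for disjoint modules")
        perm = list(rng.permutation(group))
    taken: set[str] = set()
    for i, label in enumerate(module_labels):
        if disjoint:
            chosen = set(perm[i * k_group : (i + 1) * k_group])
        else:
            chosen = set(rng.choice(group, size=min(k_group, len(group)), replace=False))
        pool = [g for g in univ if g not in chosen and (not disjoint or g not in taken)]
        fill = genes_per_module - len(chosen)
        if fill > 0:
            chosen |= set(rng.choice(pool, size=min(fill, len(pool)), replace=False))
        taken |= chosen
        module_map[label] = chosen
        annotations.append(
            GeneSetAnnotation(label, f"process:{label}", "process", frozenset(chosen))
        )
    out_truth = GroundTruth(
        planted_groups=dict(truth.planted_groups),
        planted_module_map=module_map,
        seeds_used=list(truth.seeds_used) + [seed],
    )
    return annotations, out_truth


def generate_overlay_signatures(
    truth: GroundTruth,
    universe: Sequence[str],
    labels: Sequence[str] = ("FLS_up",),
    coverage_per_module: float | Mapping[str, float] = 0.5,
    n_background: int = 0,
    outside_network: bool = False,
    seed: int = 0,
) -> list[GeneSetAnnotation]:
    """Overlay signature gene sets sampled from the planted module map.

    Per label, each module contributes ``coverage`` of its genes (a scalar
    or a per-module mapping); ``n_background`` extra genes come from the
    universe.  With ``outside_network=True`` the signature avoids all
    module genes entirely (a blood-cell-like signature disjoint from the
    tissue network).
    """
    rng = np.random.default_rng(seed)
    module_genes = set().union(*truth.planted_module_map.values()) if truth.planted_module_map else set()
    univ = sorted(set(universe))
    out = []
    for label in labels:
        genes: set[str] = set()
        if outside_network:
            pool = [g for g in univ if g not in module_genes]
            k = n_background if n_background else min(100, len(pool))
            genes = set(rng.choice(pool, size=min(k, len(pool)), replace=False))
        else:
            for mod, members in sorted(truth.planted_module_map.items()):
                cov = (
                    coverage_per_module.get(mod, 0.0)
                    if isinstance(coverage_per_module, Mapping)
                    else coverage_per_module
                )
                k = int(round(cov * len(members)))
                if k > 0:
                    genes |= set(rng.choice(sorted(members), size=k, replace=False))
            if n_background:
                pool = [g for g in univ if g not in genes]
                genes |= set(rng.choice(pool, size=min(n_background, len(pool)), replace=False))
        if genes:
            out.append(GeneSetAnnotation(label, f"signature:{label}", "signature", frozenset(genes)))
    return out
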