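"""Disease-perturbed network reconstruction and module scoring.

Starting from the core disease-dominant genes, seeds are the core genes
annotated to at least one configured process module; interactors are the
remaining core genes directly adjacent to a seed in the protein-interaction
graph.  The perturbed network is the subgraph induced on seeds plus
interactors.  Nodes group into (possibly overlapping) process modules;
unannotated interactors inherit the module(s) of the majority of their seed
neighbors (ties keep all tied modules).

Two module-level overlay statistics are provided:

* module enrichment score
  MES = (overlap / module_size) / (network_size / core_set_size) —
  the fraction of a module covered by an overlay signature, scaled by the
  network-to-core size ratio.  A ``conventional`` variant divides by the
  reciprocal background (overlay coverage of the whole core set) instead.
* target enrichment score — the fraction of a module's genes that are
  targets of a given transcription factor.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ranetkit.enrichment import GeneSetAnnotation
from ranetkit.errors import EmptySelectionError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class InteractionNetwork:
    """Undirected gene-interaction graph.

    ``graph`` is a networkx Graph whose nodes are gene ids; edges carry a
    ``source`` tag.  Node roles ('seed'/'interactor') and module lists are
    stored as node attributes after reconstruction.
    """

    graph: nx.Graph
    load_report: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))


@dataclass
class NetworkModule:
    """A named process module of the perturbed network (e.g. the sixteen
    labels AP, TC, BC, IG, CA, NK, IC, CK, CMH, TLR, AF, JS, CC, CDS, ECM,
    MR); genes may belong to several modules."""

    module_id: str
    genes: set[str]


@dataclass(frozen=True)
class ModuleScore:
    module_id: str
    overlay_label: str
    overlap_count: int
    module_size: int
    score: float


def build_network(edges: Iterable[tuple[str, str, str]]) -> InteractionNetwork:
    """Deduplicated undirected graph from (a, b, source) triples; self-loops
    dropped and counted."""
    g = nx.Graph()
    n_self, n_dup = 0, 0
    for a, b, src in edges:
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b, source=src)
    report = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_self_loops_dropped": n_self,
        "n_duplicates_dropped": n_dup,
    }
    return InteractionNetwork(graph=g, load_report=report)


def load_interactions(path: str | Path) -> InteractionNetwork:
    """Load an edge list from TSV (a <tab> b [<tab> source]) or SIF
    ("a relation b", whitespace-separated)."""
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    edges: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if is_sif:
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: SIF line needs 'source relation target...'")
            a, rel, targets = parts[0], parts[1], parts[2:]
            for b in targets:
                edges.append((a, b, rel))
        else:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: edge line needs two tab-separated ids")
            a, b = parts[0], parts[1]
            src = parts[2] if len(parts) > 2 else "pp"
            edges.append((a, b, src))
    net = build_network(edges)
    if net.graph.number_of_nodes() == 0:
        logger.warning("%s: empty interaction network", path)
    return net


def write_sif(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('source', 'pp')}\t{b}\n")


def write_graphml(net: InteractionNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    # GraphML cannot serialize lists; join module lists into strings
    for _, data in g.nodes(data=True):
        if isinstance(data.get("modules"), (list, set, tuple)):
            data["modules"] = ",".join(sorted(data["modules"]))
    nx.write_graphml(g, path)


def reconstruct_perturbed_network(
    core_genes: Iterable[str],
    process_annotations: Sequence[GeneSetAnnotation],
    ppi: InteractionNetwork,
) -> InteractionNetwork:
    """Subgraph induced on seed and interactor core genes.

    Seeds: core genes annotated to at least one process term.  Interactors:
    unannotated core genes adjacent to a seed in the interaction graph (a
    gene carrying an annotation is always a seed, never an interactor).
    Node attribute ``role`` records which is which.
    """
    core = set(core_genes)
    annotated = set()
    for ann in process_annotations:
        annotated |= ann.genes & core
    seeds = annotated
    if not seeds:
        raise EmptySelectionError("no core gene is annotated to any module term; no seeds")
    interactors = set()
    for gene in core - seeds:
        if gene in ppi.nodes and ppi.neighbors(gene) & seeds:
            interactors.add(gene)
    keep = seeds | interactors
    sub = ppi.graph.subgraph(keep).copy()
    sub.add_nodes_from(seeds - set(sub.nodes))  # seeds kept even if isolated
    for n in sub.nodes:
        sub.nodes[n]["role"] = "seed" if n in seeds else "interactor"
    report = {
        "n_seeds": len(seeds),
        "n_interactors": len(interactors),
        "n_nodes": sub.number_of_nodes(),
        "n_edges": sub.number_of_edges(),
    }
    return InteractionNetwork(graph=sub, load_report=report)


def assign_network_modules(
    network: InteractionNetwork, process_annotations: Sequence[GeneSetAnnotation]
) -> list[NetworkModule]:
    """Group network nodes into modules by their annotation terms.

    Annotated nodes join every module whose term they carry.  Interactors
    (unannotated nodes) join the module(s) most common among their
    adjacent seeds; ties keep all tied modules.  Module lists are also
    written onto the node attributes.
    """
    modules: dict[str, set[str]] = {ann.term_id: set() for ann in process_annotations}
    term_of: dict[str, set[str]] = {}
    for ann in process_annotations:
        for g in ann.genes:
            term_of.setdefault(g, set()).add(ann.term_id)
    g = network.graph
    for n in g.nodes:
        if n in term_of:
            mine = term_of[n] & set(modules)
            for m in mine:
                modules[m].add(n)
            g.nodes[n]["modules"] = sorted(mine)
    for n in g.nodes:
        if n in term_of:
            continue
        votes = Counter()
        for nb in g.neighbors(n):
            if g.nodes[nb].get("role") == "seed":
                for m in g.nodes[nb].get("modules", []):
                    votes[m] += 1
        if votes:
            top = max(votes.values())
            mine = {m for m, v in votes.items() if v == top}
            for m in mine:
                modules[m].add(n)
            g.nodes[n]["modules"] = sorted(mine)
        else:
            g.nodes[n]["modules"] = []
    return [NetworkModule(module_id=m, genes=genes) for m, genes in modules.items() if genes]


def module_enrichment_score(
    module: NetworkModule,
    overlay: Iterable[str],
    network_size: int,
    core_set_size: int,
    overlay_label: str = "overlay",
    conventional: bool = False,
) -> ModuleScore:
    """MES of an overlay signature for one module.

    MES = (|overlay ∩ module| / |module|) / (network_size / core_set_size).
    With ``conventional=True`` the background ratio is inverted
    (core_set_size / network_size), the usual fold-enrichment orientation.
    """
    if not module.genes:
        raise ValueError(f"module {module.module_id} is empty")
    if network_size <= 0 or core_set_size <= 0:
        raise ValueError("network_size and core_set_size must be positive")
    overlap = len(set(overlay) & module.genes)
    background = network_size / core_set_size
    if conventional:
        background = core_set_size / network_size
    score = (overlap / len(module.genes)) / background
    return ModuleScore(
        module_id=module.module_id,
        overlay_label=overlay_label,
        overlap_count=overlap,
        module_size=len(module.genes),
        score=score,
    )


def target_enrichment_score(
    module: NetworkModule, tf_targets: Iterable[str], overlay_label: str = "tf"
) -> ModuleScore:
    """Fraction of a module's genes that are targets of the TF."""
    if not module.genes:
        raise ValueError(f"module {module.module_id} is empty")
    overlap = len(set(tf_targets) & module.genes)
    return ModuleScore(
        module_id=module.module_id,
        overlay_label=overlay_label,
        overlap_count=overlap,
        module_size=len(module.genes),
        score=overlap / len(module.genes),
    )


def overlay_signature(
    network: InteractionNetwork, overlay: Iterable[str], label: str
) -> dict:
    """Flag network nodes in an overlay gene set; returns a summary with
    the overlap count and fraction of network nodes."""
    overlay_set = set(overlay)
    g = network.graph
    hits = 0
    for n in g.nodes:
        flag = n in overlay_set
        g.nodes[n][f"overlay_{label}"] = flag
        hits += flag
    n_nodes = g.number_of_nodes()
    return {
        "label": label,
        "overlap_count": hits,
        "network_size": n_nodes,
        "fraction": hits / n_nodes if n_nodes else 0.0,
    }
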