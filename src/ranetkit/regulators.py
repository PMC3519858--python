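"""Candidate regulators: interaction hubs and key transcription factors.

A hub candidate is scored by how many core disease-dominant genes sit in
its two-hop interaction neighborhood (first plus second neighbors, the
candidate itself excluded); a transcription factor by how many of its
targets are core genes.  Both statistics are tested against the same
resampling null: random core-sized gene sets drawn from the universe
without replacement, one-tailed empirical p = (r + 1)/(B + 1).  Candidates
are ranked within each network module by ascending p, ties broken by the
larger statistic, then gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ranetkit.enrichment import (
    GeneSetAnnotation,
    empirical_overlap_null,
    empirical_set_enrichment,
)
from ranetkit.network import InteractionNetwork, NetworkModule


@dataclass
class RegulatorCandidate:
    """One scored candidate: a PPI hub or a TF, with its statistic
    (neighborhood hit count or core-target count) and empirical p."""

    gene_id: str
    category: str  # "ppi_hub" | "tf"
    statistic: int
    empirical_p: float
    n_resamples: int
    associated_modules: list[str] = field(default_factory=list)
    rank_within_module: dict[str, int] = field(default_factory=dict)
    significant: bool = False


def two_hop_neighborhood(ppi: InteractionNetwork, regulator: str) -> set[str]:
    """First and second neighbors of a node (distance 1 or 2; the node
    itself excluded)."""
    if regulator not in ppi.nodes:
        near = sorted(ppi.nodes)[:5]
        raise KeyError(f"regulator {regulator!r} not in network; known ids start {near}")
    dist = nx.single_source_shortest_path_length(ppi.graph, regulator, cutoff=2)
    return {n for n, d in dist.items() if 0 < d <= 2}


def neighborhood_hit_count(ppi: InteractionNetwork, regulator: str, gene_set: Iterable[str]) -> int:
    """|(N1 ∪ N2)(regulator) ∩ gene_set|, the regulator excluded."""
    return len(two_hop_neighborhood(ppi, regulator) & set(gene_set))


def _resample_hits(
    target_sets: list[set[str]],
    core_set: set[str],
    universe: list[str],
    n_resamples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exceedance counts of |target_set ∩ random core-sized draw| for
    several target sets at once."""
    index = {g: i for i, g in enumerate(universe)}
    membership = np.zeros((len(universe), len(target_sets)), dtype=np.int8)
    observed = np.zeros(len(target_sets), dtype=np.int64)
    for t, ts in enumerate(target_sets):
        idx = [index[g] for g in ts if g in index]
        membership[idx, t] = 1
        observed[t] = len(ts & core_set)
    r = empirical_overlap_null(membership, len(core_set), observed, n_resamples, rng)
    return r, observed


def test_hub_significance(
    ppi: InteractionNetwork,
    regulator: str,
    core_set: Iterable[str],
    universe: Iterable[str],
    n_resamples: int = 100_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> RegulatorCandidate:
    """Test whether a regulator's two-hop neighborhood hits more core
    genes than random core-sized draws from the universe."""
    cands = test_hubs_significance(ppi, [regulator], core_set, universe, n_resamples, seed, alpha)
    return cands[0]


def test_hubs_significance(
    ppi: InteractionNetwork,
    regulators: Sequence[str],
    core_set: Iterable[str],
    universe: Iterable[str],
    n_resamples: int = 100_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> list[RegulatorCandidate]:
    """Vectorized hub test for many regulators sharing one resampling
    null (the random draws are reused across regulators)."""
    core = set(core_set)
    univ = sorted(set(universe))
    if len(core) > len(univ):
        raise ValueError("core set larger than universe")
    if not core <= set(univ):
        raise ValueError("core set must be contained in the universe")
    hoods = [two_hop_neighborhood(ppi, reg) for reg in regulators]
    rng = np.random.default_rng(seed)
    r, observed = _resample_hits(hoods, core, univ, n_resamples, rng)
    out = []
    for reg, ri, obs in zip(regulators, r, observed):
        p = (int(ri) + 1) / (n_resamples + 1)
        out.append(
            RegulatorCandidate(
                gene_id=reg,
                category="ppi_hub",
                statistic=int(obs),
                empirical_p=p,
                n_resamples=n_resamples,
                significant=p < alpha,
            )
        )
    return out


def identify_key_tfs(
    tf_target_map: Sequence[GeneSetAnnotation],
    core_set: Iterable[str],
    universe: Iterable[str],
    n_resamples: int = 100_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> list[RegulatorCandidate]:
    """TFs whose targets are enriched among the core genes (empirical
    one-tailed p < alpha).

    A TF with no targets in the universe is excluded (its p is 1 by
    construction).  Returns the selected TFs sorted by p.
    """
    core = set(core_set)
    univ = set(universe)
    usable = [ann for ann in tf_target_map if ann.genes & univ]
    if not usable:
        return []
    results = empirical_set_enrichment(
        query=core & univ,
        annotations=usable,
        universe=univ,
        n_resamples=n_resamples,
        seed=seed,
    )
    out = []
    for res in results:
        if res.empirical_p < alpha:
            out.append(
                RegulatorCandidate(
                    gene_id=res.term_id,
                    category="tf",
                    statistic=res.observed_count,
                    empirical_p=res.empirical_p,
                    n_resamples=res.n_resamples,
                    significant=True,
                )
            )
    return out


def associate_candidates_with_modules(
    candidates: Sequence[RegulatorCandidate],
    modules: Sequence[NetworkModule],
    tf_target_map: Sequence[GeneSetAnnotation] | None = None,
) -> list[RegulatorCandidate]:
    """Attach module associations.

    Hub candidates join the modules that contain them.  TFs join the
    module(s) with the highest target enrichment score among their
    targets (ties keep all tied modules).
    """
    targets_of = {ann.term_id: ann.genes for ann in (tf_target_map or [])}
    for cand in candidates:
        if cand.category == "tf" and cand.gene_id in targets_of:
            tgt = targets_of[cand.gene_id]
            scores = {
                m.module_id: len(tgt & m.genes) / len(m.genes) for m in modules if m.genes
            }
            best = max(scores.values(), default=0.0)
            cand.associated_modules = sorted(m for m, s in scores.items() if s == best and s > 0)
        else:
            cand.associated_modules = sorted(
                m.module_id for m in modules if cand.gene_id in m.genes
            )
    return list(candidates)


def prioritize_candidates(
    candidates: Sequence[RegulatorCandidate], modules: Sequence[NetworkModule]
) -> pd.DataFrame:
    """Rank candidates within each associated module.

    Sort ascending by empirical p; ties by larger statistic, then
    lexicographic gene id.  Returns a long-format table (one row per
    candidate x module) with rank_within_module, plus rank 0 rows for
    module-less candidates under module 'unassigned'.
    """
    rows = []
    for cand in candidates:
        mods = cand.associated_modules or ["unassigned"]
        for m in mods:
            rows.append(
                {
                    "module_id": m,
                    "gene_id": cand.gene_id,
                    "category": cand.category,
                    "statistic": cand.statistic,
                    "empirical_p": cand.empirical_p,
                }
            )
    df = pd.DataFrame(rows, columns=["module_id", "gene_id", "category", "statistic", "empirical_p"])
    if df.empty:
        df["rank_within_module"] = pd.Series(dtype=int)
        return df
    df["_neg_stat"] = -df["statistic"]
    df = df.sort_values(["module_id", "empirical_p", "_neg_stat", "gene_id"], kind="mergesort")
    df["rank_within_module"] = df.groupby("module_id").cumcount() + 1
    df = df.drop(columns="_neg_stat").reset_index(drop=True)
    for cand in candidates:
        sub = df[df["gene_id"] == cand.gene_id]
        cand.rank_within_module = dict(zip(sub["module_id"], sub["rank_within_module"]))
    return df
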