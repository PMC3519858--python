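"""Build cross-normalized log2 fold-change matrices from multiple studies.

Each study contributes per-condition fold-change matrices computed against
the median of its own normal samples.  Probe-level rows are collapsed to one
representative probe per gene (the probe whose largest absolute fold-change
across samples is maximal).  The per-study matrices are then flattened,
quantile-normalized as a group so that no study dominates through larger
fold-change scale, reshaped, and combined column-wise over a gene-ID match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ranetkit.errors import ConfigurationError, EmptySelectionError

logger = logging.getLogger(__name__)

#: Recognised per-sample condition labels.
CONDITIONS = ("normal", "disease_primary", "disease_comparator", "treated", "control")


@dataclass
class ExpressionStudy:
    """One study's log2-intensity matrix with per-sample condition labels.

    Parameters
    ----------
    study_id
        Stable identifier of the study.
    values
        probe x sample DataFrame of log2 intensities; index = probe ids
        (unique), columns = sample ids.
    conditions
        Mapping sample id -> condition label (one of :data:`CONDITIONS`).
    """

    study_id: str
    values: pd.DataFrame
    conditions: Mapping[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"study {self.study_id}: non-finite intensities")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"study {self.study_id}: duplicate probe ids {dup}")
        missing = set(self.values.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"study {self.study_id}: samples without condition: {sorted(missing)[:5]}")
        bad = {c for c in self.conditions.values() if c not in CONDITIONS}
        if bad:
            raise ValueError(f"study {self.study_id}: unknown condition labels {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


@dataclass
class FoldChangeMatrix:
    """Per-study log2 fold-change matrix at probe or gene level."""

    study_id: str
    values: pd.DataFrame  # probe/gene x sample
    condition: str
    level: Literal["probe", "gene"] = "probe"

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CombinedFoldChangeMatrix:
    """Gene x sample matrix pooled over studies after cross-normalization.

    ``values`` carries a 3-level column MultiIndex (study_id, sample_id,
    condition) so every column traces to exactly one source study.
    """

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_keys(self) -> list[tuple[str, str, str]]:
        return list(self.values.columns)

    def conditions(self) -> list[str]:
        return [c for (_, _, c) in self.values.columns]

    def studies(self) -> list[str]:
        return [s for (s, _, _) in self.values.columns]


def compute_fold_changes(study: ExpressionStudy, target_condition: str) -> FoldChangeMatrix:
    """log2 fold-changes of ``target_condition`` samples against the
    median intensity of the study's normal samples, per probe.

    Raises
    ------
    ConfigurationError
        If the study has no normal samples.
    EmptySelectionError
        If the study has no samples with ``target_condition``.
    """
    normal = study.samples_with("normal")
    if not normal:
        raise ConfigurationError(f"study {study.study_id}: no normal samples to normalize against")
    targets = study.samples_with(target_condition)
    if not targets:
        raise EmptySelectionError(f"study {study.study_id}: no samples with condition {target_condition!r}")
    median = study.values[normal].median(axis=1)
    fc = study.values[targets].sub(median, axis=0)
    return FoldChangeMatrix(study_id=study.study_id, values=fc, condition=target_condition, level="probe")


def collapse_probes_to_genes(
    fc: FoldChangeMatrix, probe_to_gene: Mapping[str, str]
) -> tuple[FoldChangeMatrix, dict]:
    """Collapse probe rows to one representative probe per gene.

    The representative is the probe with the largest absolute log2
    fold-change across the row's samples; ties break to the
    lexicographically smallest probe id.  Unmapped probes are dropped and
    counted in the returned report.
    """
    if fc.level != "probe":
        raise ValueError("collapse_probes_to_genes expects a probe-level matrix")
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene map")
    mapped = [p for p in fc.values.index if p in probe_to_gene]
    n_unmapped = len(fc.values.index) - len(mapped)
    if not mapped:
        raise EmptySelectionError("no probe mapped to any gene")
    sub = fc.values.loc[mapped]
    genes = pd.Series({p: probe_to_gene[p] for p in mapped}, name="gene")
    strength = sub.abs().max(axis=1)
    # sort by (gene, -strength, probe_id); first row per gene is the winner
    order = (
        pd.DataFrame({"gene": genes, "strength": strength})
        .reset_index(names="probe")
        .sort_values(["gene", "strength", "probe"], ascending=[True, False, True], kind="mergesort")
    )
    winners = order.groupby("gene", sort=True).head(1)
    collapsed = sub.loc[winners["probe"]]
    collapsed.index = pd.Index(winners["gene"].tolist(), name="gene")
    report = {
        "n_probes_in": int(len(fc.values)),
        "n_unmapped_dropped": int(n_unmapped),
        "n_genes_out": int(len(collapsed)),
    }
    out = FoldChangeMatrix(study_id=fc.study_id, values=collapsed, condition=fc.condition, level="gene")
    return out, report


def _quantile_normalize_vectors(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Quantile-normalize a group of 1-D vectors, possibly of unequal length.

    Each sorted vector is linearly interpolated onto a common grid of
    ``max(len)`` quantiles; the grid-wise mean is the reference
    distribution; each vector's values are replaced by the reference
    evaluated at their (average, for ties) normalized ranks.
    """
    L = max(len(v) for v in vectors)
    grid = np.linspace(0.0, 1.0, L)
    interp_sorted = []
    for v in vectors:
        s = np.sort(v)
        pos = np.linspace(0.0, 1.0, len(v)) if len(v) > 1 else np.array([0.5])
        interp_sorted.append(np.interp(grid, pos, s))
    reference = np.mean(interp_sorted, axis=0)
    out = []
    for v in vectors:
        # average ranks handle ties; map rank fraction onto the reference
        r = rankdata(v, method="average") - 1.0
        frac = r / (len(v) - 1) if len(v) > 1 else np.full(len(v), 0.5)
        out.append(np.interp(frac, grid, reference))
    return out


def cross_study_quantile_normalize(matrices: Sequence[FoldChangeMatrix]) -> list[FoldChangeMatrix]:
    """Flatten each matrix to a vector, quantile-normalize the vectors as a
    group, and reshape back, equalizing fold-change distributions across
    studies."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to cross-normalize")
    for m in matrices:
        if m.values.size < 2:
            raise ValueError(f"matrix {m.study_id}/{m.condition} has fewer than 2 entries")
    vectors = [m.values.to_numpy().ravel() for m in matrices]
    normed = _quantile_normalize_vectors(vectors)
    out = []
    for m, v in zip(matrices, normed):
        vals = pd.DataFrame(
            v.reshape(m.values.shape), index=m.values.index, columns=m.values.columns
        )
        out.append(FoldChangeMatrix(study_id=m.study_id, values=vals, condition=m.condition, level=m.level))
    return out


def combine_matrices(
    matrices: Sequence[FoldChangeMatrix], match: Literal["intersection", "union"] = "intersection"
) -> CombinedFoldChangeMatrix:
    """Column-wise combination of gene-level matrices over a gene-ID match.

    ``match='intersection'`` keeps genes present in every matrix (default);
    ``'union'`` keeps all genes, filling absences with NaN (flagged in the
    log).  Columns become (study_id, sample_id, condition) tuples; a
    duplicate (study, sample) pair raises.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    for m in matrices:
        if m.level != "gene":
            raise ValueError("combine_matrices expects gene-level matrices")
    seen: set[tuple[str, str]] = set()
    for m in matrices:
        for s in m.sample_ids:
            key = (m.study_id, s)
            if key in seen:
                raise ValueError(f"duplicate (study, sample) pair {key}")
            seen.add(key)
    if match == "intersection":
        genes = set(matrices[0].ids)
        for m in matrices[1:]:
            genes &= set(m.ids)
        if not genes:
            raise EmptySelectionError("gene-ID intersection across matrices is empty")
    elif match == "union":
        genes = set()
        for m in matrices:
            genes |= set(m.ids)
    else:
        raise ValueError(f"unknown match policy {match!r}")
    gene_index = pd.Index(sorted(genes), name="gene")
    blocks = []
    for m in matrices:
        block = m.values.reindex(gene_index)
        block.columns = pd.MultiIndex.from_tuples(
            [(m.study_id, s, m.condition) for s in m.sample_ids],
            names=["study_id", "sample_id", "condition"],
        )
        blocks.append(block)
    combined = pd.concat(blocks, axis=1)
    if match == "union" and combined.isna().any().any():
        logger.warning("union match produced %d missing entries", int(combined.isna().sum().sum()))
    return CombinedFoldChangeMatrix(values=combined)
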