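"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression tables and fold-change matrices are TSV with the probe/gene id
in the first column; sample metadata travels in a side-car sample sheet.
Gene sets use GMT (term, description, tab-separated genes); interaction
networks load from two-column TSV or SIF edge lists and export to SIF or
GraphML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ranetkit.enrichment import GeneSetAnnotation
from ranetkit.errors import FormatError
from ranetkit.preprocess import CombinedFoldChangeMatrix, ExpressionStudy


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a probe/gene x sample TSV of log2 intensities."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty expression table")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, condition, study_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "study_id"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: sample sheet must have columns {sorted(required)}")
    return df


def load_studies(expr_paths: Sequence[str | Path], sample_sheet: str | Path) -> list[ExpressionStudy]:
    """Assemble ExpressionStudy objects from expression TSVs plus one
    sample sheet covering all of them."""
    sheet = read_sample_sheet(sample_sheet)
    cond = dict(zip(sheet["sample_id"], sheet["condition"]))
    study_of = dict(zip(sheet["sample_id"], sheet["study_id"]))
    studies = []
    for path in expr_paths:
        df = read_expression_table(path)
        sids = {study_of.get(s) for s in df.columns}
        sids.discard(None)
        if len(sids) != 1:
            raise FormatError(f"{path}: samples map to studies {sids}; expected exactly one")
        study_id = sids.pop()
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                values=df,
                conditions={s: cond[s] for s in df.columns},
            )
        )
    return studies


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_id) -> dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe map needs two columns")
    first = df.iloc[0]
    if {"probe_id", "gene_id"} <= set(first.astype(str)):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_combined_matrix(combined: CombinedFoldChangeMatrix, path: str | Path) -> None:
    """Write a combined matrix as TSV with 'study|sample|condition' headers."""
    flat = combined.values.copy()
    flat.columns = ["|".join(c) for c in combined.values.columns]
    flat.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_combined_matrix(path: str | Path) -> CombinedFoldChangeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        cols = [tuple(c.split("|")) for c in df.columns]
        if any(len(c) != 3 for c in cols):
            raise ValueError
    except ValueError:
        raise FormatError(f"{path}: columns must be study|sample|condition") from None
    df.columns = pd.MultiIndex.from_tuples(cols, names=["study_id", "sample_id", "condition"])
    return CombinedFoldChangeMatrix(values=df)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gmt(path: str | Path, category: str = "process") -> list[GeneSetAnnotation]:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> ...

    If the description field looks like 'category:...' the prefix
    overrides the default category.
    """
    annotations = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs term, description and >=1 gene")
        term_id, desc = parts[0], parts[1]
        cat = category
        if ":" in desc:
            prefix = desc.split(":", 1)[0]
            if prefix in {"process", "disease", "tf_targets", "signature"}:
                cat = prefix
        genes = frozenset(g for g in parts[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: term {term_id} has no genes")
        annotations.append(GeneSetAnnotation(term_id=term_id, term_name=desc, category=cat, genes=genes))
    return annotations


def write_gmt(annotations: Sequence[GeneSetAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            genes = "\t".join(sorted(ann.genes))
            fh.write(f"{ann.term_id}\t{ann.term_name}\t{genes}\n")


def write_enrichment_table(results, path: str | Path) -> None:
    """Write enrichment results sorted by empirical p, with an optional BH
    column across terms."""
    from statsmodels.stats.multitest import multipletests

    rows = [
        {
            "term_id": r.term_id,
            "observed": r.observed_count,
            "term_size": r.term_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "empirical_p": r.empirical_p,
            "z_score": r.z_score,
            "n_resamples": r.n_resamples,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df["bh_adjusted_p"] = multipletests(df["empirical_p"], method="fdr_bh")[1]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
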