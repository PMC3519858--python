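"""Shared fixtures: a tiny hand-built study and one full synthetic
scenario (generated once per session) that several test modules reuse."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from ranetkit.dep import run_dep_discovery
from ranetkit.preprocess import (
    ExpressionStudy,
    combine_matrices,
    compute_fold_changes,
    cross_study_quantile_normalize,
)
from ranetkit.simulate import generate_multistudy_expression

#: operating point of the synthetic compendium used across the suite:
#: 3 studies x (5 normal + 5 primary + 5 comparator), 2000 genes, planted
#: groups of 140, effect 2.0 log2 units, noise sd 0.5; rank-4 NMF, 20
#: element permutations, 95th percentile, membership alpha 0.05
SCENARIO = dict(n_studies=3, n_genes=2000, samples_per_arm=5, effect_size=2.0, noise_sd=0.5)
DEP_PARAMS = dict(n_clusters=4, n_permutations=20, percentile=95.0, alpha=0.05)


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """Two probes, three normal + two primary + one comparator sample."""
    values = pd.DataFrame(
        {
            "n1": [5.0, 10.0],
            "n2": [6.0, 11.0],
            "n3": [7.0, 12.0],
            "d1": [8.0, 11.0],
            "d2": [6.0, 13.0],
            "o1": [9.0, 11.0],
        },
        index=pd.Index(["p1", "p2"], name="probe"),
    )
    conditions = {
        "n1": "normal",
        "n2": "normal",
        "n3": "normal",
        "d1": "disease_primary",
        "d2": "disease_primary",
        "o1": "disease_comparator",
    }
    return ExpressionStudy(study_id="S1", values=values, conditions=conditions)


def combined_matrix_for(seed: int):
    """Preprocess the synthetic scenario at one seed: per-study,
    per-condition fold changes, cross-study quantile normalization,
    gene-ID-matched combination."""
    studies, truth = generate_multistudy_expression(seed=seed, **SCENARIO)
    matrices = []
    for st in studies:
        for cond in ("disease_primary", "disease_comparator"):
            fc = compute_fold_changes(st, cond)
            fc.level = "gene"  # identity probe->gene map
            matrices.append(fc)
    combined = combine_matrices(cross_study_quantile_normalize(matrices))
    return combined, truth


def dep_result_for(seed: int):
    combined, truth = combined_matrix_for(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = run_dep_discovery(combined, seed=seed, **DEP_PARAMS)
    return combined, truth, result


@pytest.fixture(scope="session")
def scenario_seed1():
    """One fully processed scenario at seed 1 (combined matrix, ground
    truth, DEP-discovery result)."""
    return dep_result_for(1)
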