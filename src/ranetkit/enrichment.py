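"""Empirical resampling gene-set enrichment with an exact hypergeometric oracle.

The test mirrors the resampling scheme used throughout the pipeline: draw
``B`` random query-sized gene sets from the universe without replacement,
count per annotation term how often the random overlap reaches the observed
overlap, and report the one-tailed empirical p = (r + 1) / (B + 1).  Under
this null the overlap is exactly hypergeometric, which provides the
independent closed-form check; the resampling route is kept because the
same machinery generalizes to statistics with no closed form (e.g. the
two-hop neighborhood counts of the regulator stage).

P-values convert to Z-scores via the inverse standard-normal CDF at 1 - P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy.stats import hypergeom, norm

#: chunk of resamples drawn at once; bounds memory at chunk x universe floats
_CHUNK = 256


@dataclass(frozen=True)
class GeneSetAnnotation:
    """One annotation term (GO-like process, disease, TF target set or
    expression signature) and its member genes."""

    term_id: str
    term_name: str
    category: str  # process | disease | tf_targets | signature
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed overlap of a query with one term plus its empirical
    one-tailed p-value and Z-score."""

    term_id: str
    observed_count: int
    query_size: int
    universe_size: int
    term_size: int
    empirical_p: float
    z_score: float
    n_resamples: int
    seed: int


def hypergeometric_oracle(overlap: int, query_size: int, term_size: int, universe_size: int) -> float:
    """Exact P(X >= overlap) for the overlap of a random query-sized draw
    (without replacement) with a fixed term."""
    if overlap < 0 or query_size < 0 or term_size < 0:
        raise ValueError("sizes must be nonnegative")
    if query_size > universe_size or term_size > universe_size:
        raise ValueError("query/term cannot exceed the universe")
    if overlap > min(query_size, term_size):
        raise ValueError("overlap cannot exceed min(query_size, term_size)")
    return float(hypergeom.sf(overlap - 1, universe_size, term_size, query_size))


def z_from_p(p: float, floor: float | None = None) -> float:
    """Z = N^{-1}(1 - P), the upper-tail standard-normal quantile.

    Out-of-range p is clamped to ``floor`` (resp. ``1 - floor``) with a
    warning; floor defaults to 1e-16.
    """
    lo = 1e-16 if floor is None else floor
    if not (0.0 < p < 1.0):
        warnings.warn(f"p={p} outside (0,1); clamped", RuntimeWarning, stacklevel=2)
        p = min(max(p, lo), 1.0 - lo)
    return float(norm.isf(p))


def _sample_index_sets(
    rng: np.random.Generator, n_draws: int, universe_size: int, draw_size: int
) -> np.ndarray:
    """``n_draws`` uniform subsets of size ``draw_size`` (indices), drawn
    without replacement via random-key argpartition."""
    keys = rng.random((n_draws, universe_size))
    return np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]


def empirical_overlap_null(
    membership: np.ndarray,
    query_size: int,
    observed: np.ndarray,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exceedance counts for overlap statistics of many terms at once.

    ``membership`` is a (universe_size x n_terms) 0/1 matrix; per resample
    a random query-sized index set is drawn and its per-term overlap
    compared against ``observed``.
    """
    universe_size, n_terms = membership.shape
    member_f = membership.astype(np.float32)
    r = np.zeros(n_terms, dtype=np.int64)
    done = 0
    while done < n_resamples:
        c = min(_CHUNK, n_resamples - done)
        idx = _sample_index_sets(rng, c, universe_size, query_size)
        # indicator x membership matmul; counts are small ints, exact in f32
        S = np.zeros((c, universe_size), dtype=np.float32)
        S[np.arange(c)[:, None], idx] = 1.0
        counts = np.rint(S @ member_f).astype(np.int64)  # c x n_terms
        r += (counts >= observed[None, :]).sum(axis=0)
        done += c
    return r


def empirical_set_enrichment(
    query: Iterable[str],
    annotations: Sequence[GeneSetAnnotation],
    universe: Iterable[str],
    n_resamples: int = 100_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """One-tailed empirical enrichment of a query set against annotation
    terms.

    Terms are intersected with the universe first.  Per term, the
    empirical p is (r + 1)/(B + 1) with r the number of random query-sized
    draws whose overlap with the term reaches the observed overlap.
    Deterministic given ``seed``; results sorted by empirical p.
    """
    universe_set = set(universe)
    universe_list = sorted(universe_set)
    if not universe_list:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set <= universe_set:
        extra = sorted(query_set - universe_set)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    if len(query_set) > len(universe_list):
        raise ValueError("query larger than universe")
    index = {g: i for i, g in enumerate(universe_list)}
    n_univ = len(universe_list)
    terms = list(annotations)
    membership = np.zeros((n_univ, len(terms)), dtype=np.int8)
    observed = np.zeros(len(terms), dtype=np.int64)
    term_sizes = np.zeros(len(terms), dtype=np.int64)
    for t, ann in enumerate(terms):
        in_univ = [index[g] for g in ann.genes if g in index]
        membership[in_univ, t] = 1
        term_sizes[t] = len(in_univ)
        observed[t] = len(query_set & ann.genes & universe_set)
    rng = np.random.default_rng(seed)
    r = empirical_overlap_null(membership, len(query_set), observed, n_resamples, rng)
    results = []
    for t, ann in enumerate(terms):
        p = (int(r[t]) + 1) / (n_resamples + 1)
        results.append(
            EnrichmentResult(
                term_id=ann.term_id,
                observed_count=int(observed[t]),
                query_size=len(query_set),
                universe_size=n_univ,
                term_size=int(term_sizes[t]),
                empirical_p=p,
                z_score=z_from_p(p, floor=1.0 / (n_resamples + 1)),
                n_resamples=n_resamples,
                seed=seed,
            )
        )
    results.sort(key=lambda res: (res.empirical_p, res.term_id))
    return results
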