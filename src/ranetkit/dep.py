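"""Differential-expression-pattern (DEP) discovery by NMF soft clustering.

The signed combined fold-change matrix is folded into a nonnegative matrix
(two feature rows per gene: positive part and negative part), factorized by
multiplicative-update NMF into ``n_clusters`` patterns, and gene membership
is read from the basis matrix: per cluster, each gene-feature's basis
weight is standardized, converted to an upper-tail normal p-value and
Benjamini-Hochberg adjusted within the cluster; members are features with
adjusted p below alpha.  Soft clustering: a gene may belong to several
clusters, and to the up and the down pattern of the same cluster.

Cluster-level significance is calibrated by element permutation: the
matrix elements are globally shuffled, the factorization repeated, and the
same membership test plus the 95th-percentile activation cutoff measure
how many member genes and active samples a chance pattern can accrue.
Real clusters must exceed both counts strictly to be retained; retained
clusters are then classified shared vs disease-dominant from the
condition mix of their sample support, and the core disease-dominant
gene set is the union of the dominant up-regulated clusters' members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ranetkit.preprocess import CombinedFoldChangeMatrix

logger = logging.getLogger(__name__)

UP, DOWN = "up", "down"


@dataclass
class NMFResult:
    """Outcome of one (best-of-restarts) nonnegative factorization.

    ``basis`` is feature x cluster (W), ``activation`` cluster x sample
    (H).  Basis columns are L2-normalized with the scale pushed into the
    activation rows, so activation magnitudes are comparable across
    independent factorizations.
    """

    basis: pd.DataFrame
    activation: pd.DataFrame
    n_clusters: int
    reconstruction_error: float
    seed: int
    n_restarts: int
    n_iter: int
    converged: bool
    error_history: np.ndarray | None = None


@dataclass
class DEPCluster:
    """One directional DEP: the genes and samples loading on one NMF
    cluster in one direction (up- or down-regulation).

    ``associated_samples`` are the samples whose activation exceeds the
    chance-calibrated cutoff (used for the significance screen);
    ``pattern_samples`` are the samples whose activation reaches a set
    fraction of the cluster's peak — the pattern's full sample support,
    used for the shared/dominant classification.
    """

    cluster_id: int
    direction: str  # "up" | "down"
    member_genes: list[tuple[str, float]]  # (gene_id, adjusted_p)
    associated_samples: list[tuple[str, str, str]]  # (study, sample, condition)
    pattern_samples: list[tuple[str, str, str]] = field(default_factory=list)
    class_label: str = "unclassified"  # "shared" | "dominant" | "unclassified"
    significant: bool = False

    @property
    def gene_ids(self) -> set[str]:
        return {g for g, _ in self.member_genes}

    @property
    def n_members(self) -> int:
        return len({g for g, _ in self.member_genes})

    @property
    def n_samples(self) -> int:
        return len(self.associated_samples)


@dataclass
class PermutationThresholds:
    """Chance-level gene/sample counts and basis/activation cutoffs derived
    from element-permutation factorizations."""

    gene_count_threshold: int
    sample_count_threshold: int
    percentile: float
    n_permutations: int
    basis_cutoff: float
    activation_cutoff: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")
        if self.gene_count_threshold < 0 or self.sample_count_threshold < 0:
            raise ValueError("thresholds must be nonnegative")


def fold_signed_matrix(combined: CombinedFoldChangeMatrix) -> pd.DataFrame:
    """Fold a signed matrix into nonnegative up/down feature rows.

    Each gene contributes an 'up' row max(v, 0) and a 'down' row
    max(-v, 0); the original row is recovered as up - down.  The returned
    DataFrame has a (gene, direction) MultiIndex.
    """
    vals = combined.values.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("combined matrix contains non-finite entries; "
                         "use intersection matching or impute upstream")
    up = np.maximum(vals, 0.0)
    down = np.maximum(-vals, 0.0)
    genes = combined.gene_ids
    index = pd.MultiIndex.from_tuples(
        [(g, d) for d in (UP, DOWN) for g in genes], names=["gene", "direction"]
    )
    folded = pd.DataFrame(np.vstack([up, down]), index=index, columns=combined.values.columns)
    return folded


def _init_random(V: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random factors scaled by sqrt(mean(V)/k), the scale that
    makes E[WH] match the data mean."""
    scale = np.sqrt(max(V.mean(), 1e-12) / k)
    return scale * rng.random((V.shape[0], k)), scale * rng.random((k, V.shape[1]))


def _init_nndsvdar(V: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD init (NNDSVDar): each factor pair comes from
    the dominant nonnegative part of an SVD component; zeros are filled
    with small random values so multiplicative updates can move them."""
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    n, m = V.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, min(k, len(S))):
        x, y = U[:, j], Vt[j, :]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        np_x, np_y = np.linalg.norm(xp), np.linalg.norm(yp)
        nn_x, nn_y = np.linalg.norm(xn), np.linalg.norm(yn)
        if np_x * np_y >= nn_x * nn_y:
            u, v, sig = xp / (np_x + 1e-12), yp / (np_y + 1e-12), S[j] * np_x * np_y
        else:
            u, v, sig = xn / (nn_x + 1e-12), yn / (nn_y + 1e-12), S[j] * nn_x * nn_y
        W[:, j] = np.sqrt(sig) * u
        H[j, :] = np.sqrt(sig) * v
    avg = V.mean()
    small_w = W < 1e-12
    small_h = H < 1e-12
    W[small_w] = avg * rng.random(int(small_w.sum())) / 100
    H[small_h] = avg * rng.random(int(small_h.sum())) / 100
    return W, H


def _mu_nmf(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    record_history: bool,
    init: str = "nndsvdar",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Multiplicative-update NMF minimizing ||V - WH||_F.

    Updates keep factors nonnegative by construction; a small epsilon
    guards the denominators.
    """
    eps = 1e-12
    if init == "nndsvdar":
        W, H = _init_nndsvdar(V, k, rng)
    else:
        W, H = _init_random(V, k, rng)
    norm_V = np.linalg.norm(V)
    prev_err = np.inf
    history = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        H *= (W.T @ V) / ((W.T @ W) @ H + eps)
        err = float(np.linalg.norm(V - W @ H))
        if record_history:
            history.append(err)
        denom = norm_V if norm_V > 0 else 1.0
        if abs(prev_err - err) / denom < tol:
            converged = True
            break
        prev_err = err
    err = float(np.linalg.norm(V - W @ H))
    return W, H, np.asarray(history), n_iter, converged


def factorize_nmf(
    matrix: pd.DataFrame,
    n_clusters: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 1,
    record_history: bool = False,
) -> NMFResult:
    """Best-of-``n_restarts`` multiplicative-update NMF of a nonnegative
    matrix; deterministic given ``seed``.

    The first restart initializes from the nonnegative parts of an SVD
    (NNDSVDar), which reliably lands structured data in a structured
    basin; the remaining restarts are random.  Restart ``i`` uses a
    Generator seeded by SeedSequence(seed).spawn, so results are bitwise
    reproducible.  Non-convergence within ``max_iter`` warns but still
    returns the best factorization found.
    """
    V = matrix.to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative; fold the signed matrix first")
    if not (1 <= n_clusters <= min(V.shape)):
        raise ValueError(f"n_clusters must be in [1, {min(V.shape)}]")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)
    best: tuple | None = None
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        init = "nndsvdar" if i == 0 else "random"
        W, H, hist, n_iter, conv = _mu_nmf(V, n_clusters, rng, max_iter, tol, record_history, init=init)
        err = float(np.linalg.norm(V - W @ H))
        if best is None or err < best[0]:
            best = (err, W, H, hist, n_iter, conv)
    err, W, H, hist, n_iter, conv = best
    if not conv and V.any():
        warnings.warn(
            f"NMF did not converge in {max_iter} iterations (error {err:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
    # push scale into H so activation values are comparable across runs
    col_norms = np.linalg.norm(W, axis=0)
    nonzero = col_norms > 0
    W[:, nonzero] /= col_norms[nonzero]
    H[nonzero, :] *= col_norms[nonzero, None]
    cluster_ids = pd.RangeIndex(1, n_clusters + 1, name="cluster_id")
    return NMFResult(
        basis=pd.DataFrame(W, index=matrix.index, columns=cluster_ids),
        activation=pd.DataFrame(H, index=cluster_ids, columns=matrix.columns),
        n_clusters=n_clusters,
        reconstruction_error=err,
        seed=seed,
        n_restarts=n_restarts,
        n_iter=n_iter,
        converged=conv,
        error_history=hist if record_history else None,
    )


#: fraction of top loadings excluded when estimating a basis column's
#: null scale; covers the expected member share of one cluster
MEMBERSHIP_TRIM = 0.02


def _column_membership(col: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Membership mask and adjusted p for one basis column.

    The column is standardized as z = (w - m)/s where m and s are the
    mean and standard deviation of the column after excluding its top
    ``MEMBERSHIP_TRIM`` fraction of loadings — a cluster's own members
    occupy the extreme upper tail and would otherwise inflate the scale
    estimate and mask themselves.  Upper-tail normal p, BH-adjusted
    within the column.  A zero-variance column has no members.
    """
    hi = np.quantile(col, 1.0 - MEMBERSHIP_TRIM)
    base = col[col <= hi]
    sd = base.std()
    if sd == 0:
        return np.zeros(len(col), dtype=bool), np.ones(len(col))
    z = (col - base.mean()) / sd
    p = norm.sf(z)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj < alpha, adj


def _member_gene_counts(W: np.ndarray, n_genes: int, alpha: float) -> list[int]:
    """Per-cluster counts of distinct genes with a member feature (either
    direction row) — the statistic the permutation null thresholds."""
    counts = []
    for j in range(W.shape[1]):
        keep, _ = _column_membership(W[:, j], alpha)
        counts.append(int((keep[:n_genes] | keep[n_genes:]).sum()))
    return counts


def compute_membership_pvalues(result: NMFResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster gene membership from standardized basis weights.

    For each cluster column of the basis matrix the gene-features are
    standardized against the column mean and standard deviation,
    converted to one-sided upper-tail normal p-values and BH-adjusted
    within the cluster; rows with
    adjusted p < alpha become members, with the direction read from
    whether the up- or down-row carries the membership.  A zero-variance
    column yields no members.
    """
    if not isinstance(result.basis.index, pd.MultiIndex):
        raise ValueError("basis index must be a (gene, direction) MultiIndex")
    records = []
    W = result.basis
    for cid in W.columns:
        keep, adj = _column_membership(W[cid].to_numpy(), alpha)
        if not keep.any():
            logger.debug("cluster %s: no members", cid)
            continue
        for (gene, direction), ai in zip(W.index[keep], adj[keep]):
            records.append((cid, gene, direction, float(ai)))
    return pd.DataFrame(records, columns=["cluster_id", "gene", "direction", "adjusted_p"])


#: a sample expresses a cluster's pattern when its activation reaches this
#: fraction of the cluster's peak activation; a genuinely inactive arm sits
#: one-two orders of magnitude below the peak, partial activation at ~0.3-0.5
PATTERN_SUPPORT_FRACTION = 0.25


def build_dep_clusters(
    result: NMFResult,
    alpha: float,
    activation_cutoff: float,
    pattern_fraction: float = PATTERN_SUPPORT_FRACTION,
) -> list[DEPCluster]:
    """Assemble directional DEP clusters.

    Members come from the adjusted-p membership test, split by direction.
    ``associated_samples`` are those above the chance-calibrated
    activation cutoff (significance screening); ``pattern_samples`` are
    all samples at >= ``pattern_fraction`` of the cluster's peak
    activation (the support used for shared/dominant classification — a
    pattern present in many samples spreads its activation and can sit
    below the extreme-tail cutoff in every one of them, while a genuinely
    inactive arm stays far below any fraction of the peak).
    """
    members = compute_membership_pvalues(result, alpha)
    clusters: list[DEPCluster] = []
    for cid in result.activation.index:
        act = result.activation.loc[cid].to_numpy()
        cols = list(result.activation.columns)
        assoc = [tuple(c) for c, a in zip(cols, act) if a > activation_cutoff]
        peak = act.max()
        support = [tuple(c) for c, a in zip(cols, act) if peak > 0 and a >= pattern_fraction * peak]
        sub = members[members["cluster_id"] == cid]
        for direction in (UP, DOWN):
            dsub = sub[sub["direction"] == direction]
            if dsub.empty:
                continue
            clusters.append(
                DEPCluster(
                    cluster_id=int(cid),
                    direction=direction,
                    member_genes=list(zip(dsub["gene"], dsub["adjusted_p"])),
                    associated_samples=assoc,
                    pattern_samples=support,
                )
            )
    return clusters


def permutation_significance_thresholds(
    combined: CombinedFoldChangeMatrix,
    n_clusters: int,
    n_permutations: int = 20,
    percentile: float = 95.0,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    alpha: float = 0.05,
) -> PermutationThresholds:
    """Chance-level DEP size from element-permutation factorizations.

    Per permutation the matrix elements are globally shuffled (destroying
    any gene- or sample-wise structure but keeping the value
    distribution), folded and re-factorized, and two per-cluster counts
    are taken: member genes under the same adjusted-p membership test
    applied to real clusters, and samples above the permutation's
    ``percentile`` activation cutoff.

    The thresholds estimate the joint chance event "a DEP with many
    genes in many samples": the sample threshold is the ``percentile``
    across permutations of the per-permutation maximum sample count, and
    the gene threshold is the same percentile of the maximum member
    count among chance clusters that themselves exceed the sample
    threshold (0 for a permutation with no such cluster).  Chance
    clusters with very many members but one or two active samples do not
    inflate the gene threshold — such a pattern is not a DEP.  The
    basis/activation cutoffs are the across-permutation means of the
    per-permutation percentile cutoffs.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 20:
        warnings.warn(
            f"{n_permutations} permutations is small for a {percentile}th-percentile estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    vals = combined.values.to_numpy(dtype=float)
    if np.all(vals == vals.flat[0]):
        warnings.warn("constant matrix: permutation cutoffs are degenerate", RuntimeWarning, stacklevel=2)
        const = abs(float(vals.flat[0]))
        return PermutationThresholds(
            gene_count_threshold=0,
            sample_count_threshold=0,
            percentile=percentile,
            n_permutations=n_permutations,
            basis_cutoff=const,
            activation_cutoff=const,
            degenerate=True,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    per_perm: list[tuple[list[int], np.ndarray]] = []
    sample_maxima, b_cuts, a_cuts = [], [], []
    n_genes = len(combined.gene_ids)
    for it in range(n_permutations):
        perm = rng.permutation(vals.ravel()).reshape(vals.shape)
        permuted = CombinedFoldChangeMatrix(
            values=pd.DataFrame(perm, index=combined.values.index, columns=combined.values.columns)
        )
        folded = fold_signed_matrix(permuted)
        res = factorize_nmf(
            folded,
            n_clusters,
            seed=int(rng.integers(2**31 - 1)),
            max_iter=max_iter,
            tol=tol,
            n_restarts=1,
        )
        W = res.basis.to_numpy()
        H = res.activation.to_numpy()
        b_cut = float(np.percentile(W, percentile))
        a_cut = float(np.percentile(H, percentile))
        b_cuts.append(b_cut)
        a_cuts.append(a_cut)
        gene_counts = _member_gene_counts(W, n_genes, alpha)
        sample_counts = (H > a_cut).sum(axis=1)
        per_perm.append((gene_counts, sample_counts))
        sample_maxima.append(int(sample_counts.max()))
    sample_thr = int(np.ceil(np.percentile(sample_maxima, percentile)))
    cond_gene_maxima = [
        max((g for g, s in zip(gc, sc) if s > sample_thr), default=0)
        for gc, sc in per_perm
    ]
    gene_thr = int(np.ceil(np.percentile(cond_gene_maxima, percentile)))
    logger.info(
        "permutation thresholds: %d genes, %d samples (cutoffs %.4g / %.4g)",
        gene_thr, sample_thr, float(np.mean(b_cuts)), float(np.mean(a_cuts)),
    )
    return PermutationThresholds(
        gene_count_threshold=gene_thr,
        sample_count_threshold=sample_thr,
        percentile=percentile,
        n_permutations=n_permutations,
        basis_cutoff=float(np.mean(b_cuts)),
        activation_cutoff=float(np.mean(a_cuts)),
    )


def select_significant_dep_clusters(
    clusters: list[DEPCluster], thr: PermutationThresholds
) -> list[DEPCluster]:
    """Keep clusters with strictly more member genes and strictly more
    associated samples than expected by chance."""
    out = []
    for c in clusters:
        c.significant = (
            c.n_members > thr.gene_count_threshold and c.n_samples > thr.sample_count_threshold
        )
        if c.significant:
            out.append(c)
    return out


def classify_dep_clusters(
    clusters: list[DEPCluster],
    dominant_max_comparator_fraction: float = 0.2,
    shared_min_fraction: float = 0.2,
    min_dominant_studies: int = 2,
) -> list[DEPCluster]:
    """Label each cluster dominant / shared / unclassified from the
    condition mix of its associated samples.

    Among the cluster's pattern-support samples, ``f_primary`` and
    ``f_comparator`` are the fractions drawn from the primary-disease and
    comparator-disease arms.  Dominant: comparator fraction below the
    threshold and primary samples spanning at least
    ``min_dominant_studies`` studies.  Shared: both fractions at least
    ``shared_min_fraction``.  Anything else (including clusters with no
    support samples) stays unclassified.
    """
    for c in clusters:
        support = c.pattern_samples or c.associated_samples
        if not support:
            c.class_label = "unclassified"
            continue
        n = len(support)
        primary = [(s, smp) for (s, smp, cond) in support if cond == "disease_primary"]
        comparator = [(s, smp) for (s, smp, cond) in support if cond == "disease_comparator"]
        f_primary = len(primary) / n
        f_comparator = len(comparator) / n
        primary_studies = {s for s, _ in primary}
        if f_comparator < dominant_max_comparator_fraction and len(primary_studies) >= min_dominant_studies:
            c.class_label = "dominant"
        elif f_primary >= shared_min_fraction and f_comparator >= shared_min_fraction:
            c.class_label = "shared"
        else:
            c.class_label = "unclassified"
    return clusters


def classify_genes(clusters: list[DEPCluster], significant_only: bool = True) -> dict[str, str]:
    """Gene-level shared/dominant call induced by cluster memberships.

    A gene is labelled ``shared_<dir>`` when it belongs to any shared
    cluster of that direction, else ``dominant_<dir>`` when it belongs to
    a dominant cluster — evidence of comparator-arm sharing disqualifies
    dominance, mirroring the distinction between disease-dominant and
    shared regulation.  Genes in unclassified clusters only are omitted.
    With a gene in both directions the direction with the smaller best
    adjusted p wins.
    """
    best: dict[str, tuple[float, str]] = {}
    for c in clusters:
        if significant_only and not c.significant:
            continue
        if c.class_label not in ("shared", "dominant"):
            continue
        for gene, adj in c.member_genes:
            label = f"{c.class_label}_{c.direction}"
            prev = best.get(gene)
            # shared beats dominant within a direction regardless of p
            if prev is None:
                best[gene] = (adj, label)
            else:
                prev_p, prev_label = prev
                same_dir = prev_label.endswith(c.direction)
                if same_dir:
                    if prev_label.startswith("dominant") and c.class_label == "shared":
                        best[gene] = (min(adj, prev_p), label)
                    elif prev_label.startswith(c.class_label):
                        best[gene] = (min(adj, prev_p), prev_label)
                elif adj < prev_p:
                    best[gene] = (adj, label)
    return {g: label for g, (_, label) in best.items()}


def derive_core_genes(clusters: list[DEPCluster], direction: str = UP) -> set[str]:
    """Union of member genes of significant dominant clusters of the given
    direction (soft-membership duplicates collapse to a set)."""
    core: set[str] = set()
    for c in clusters:
        if c.significant and c.class_label == "dominant" and c.direction == direction:
            core |= c.gene_ids
    return core


@dataclass
class DEPDiscoveryResult:
    """Bundle of all DEP-discovery stage outputs."""

    nmf: NMFResult
    thresholds: PermutationThresholds
    clusters: list[DEPCluster]
    core_genes: set[str]


def run_dep_discovery(
    combined: CombinedFoldChangeMatrix,
    n_clusters: int = 30,
    alpha: float = 0.05,
    n_permutations: int = 20,
    percentile: float = 95.0,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 1,
    perm_max_iter: int = 200,
) -> DEPDiscoveryResult:
    """Full DEP stage: fold, factorize, permutation thresholds, cluster
    assembly, significance screen, classification, core-gene derivation."""
    folded = fold_signed_matrix(combined)
    nmf = factorize_nmf(
        folded, n_clusters, seed=seed, max_iter=max_iter, tol=tol, n_restarts=n_restarts
    )
    thr = permutation_significance_thresholds(
        combined,
        n_clusters,
        n_permutations=n_permutations,
        percentile=percentile,
        seed=seed + 1,
        max_iter=perm_max_iter,
        alpha=alpha,
    )
    clusters = build_dep_clusters(nmf, alpha=alpha, activation_cutoff=thr.activation_cutoff)
    select_significant_dep_clusters(clusters, thr)
    classify_dep_clusters(clusters)
    core = derive_core_genes(clusters, direction=UP)
    return DEPDiscoveryResult(nmf=nmf, thresholds=thr, clusters=clusters, core_genes=core)
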