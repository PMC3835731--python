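"""Co-expression hierarchy over differentially expressed genes.

Average-linkage agglomeration on pairwise gene-gene correlation, with a
Fisher-z stopping rule: merging stops when the best available merge
correlation drops below ``r* = tanh(z_cutoff / sqrt(n - 3))``, the
correlation whose Fisher z-score equals ``z_cutoff`` at n samples.  The
result is in general a forest.  Multi-scale *signatures* (stable
co-expression clusters) are the internal nodes of that forest within
size bounds, deduplicated leaf-to-root by Jaccard similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionStudy

logger = logging.getLogger(__name__)

DEFAULT_Z_CUTOFF = 0.52
DEFAULT_MIN_SIZE = 30
DEFAULT_MAX_SIZE_FRACTION = 0.8
DEFAULT_DEDUP_JACCARD = 0.9


def pairwise_correlation(
    study: ExpressionStudy,
    genes=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Gene-gene correlation over all samples (both groups).

    Zero-variance genes get correlation 0 to every other gene (with a
    warning); the diagonal is always 1.
    """
    sub = study.matrix if genes is None else study.matrix.loc[list(genes)]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 genes for pairwise correlation")
    if sub.shape[1] < 4:
        raise ValueError("need at least 4 samples for pairwise correlation")
    values = sub.to_numpy(float)
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = values.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance gene(s); correlations set to 0", flat.sum())
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=sub.index, columns=sub.index)


def fisher_tail_probability(z_cutoff: float) -> float:
    """One-sided standard-normal tail probability of a Fisher z-score.

    The default cutoff z = 0.52 corresponds to a tail of about 0.3: gene
    pairs whose correlation is consistent with noise at that level stop
    the agglomeration.
    """
    return float(stats.norm.sf(z_cutoff))


def correlation_cutoff(z_cutoff: float, n_samples: int) -> float:
    """Correlation whose Fisher z-score equals ``z_cutoff`` at n samples.

    Fisher's transformation puts a sample correlation r on the standard
    normal scale via ``z = atanh(r) * sqrt(n - 3)``; inverting gives
    ``r* = tanh(z_cutoff / sqrt(n - 3))``.
    """
    if n_samples <= 3:
        raise ValueError("Fisher z cutoff needs more than 3 samples")
    tail = fisher_tail_probability(z_cutoff)
    logger.info(
        "correlation cutoff: z=%.3g (one-sided normal tail p=%.3g) at n=%d",
        z_cutoff,
        tail,
        n_samples,
    )
    return float(np.tanh(z_cutoff / np.sqrt(n_samples - 3)))


@dataclass
class Dendrogram:
    """Average-linkage forest over DE genes.

    ``linkage_`` is the full (n-1) x 4 merge matrix on distance
    ``1 - r``; only the first ``n_kept`` merges have merge correlation
    ``1 - height >= stopped_at`` and belong to the forest.
    """

    leaves: list[str]
    linkage_: np.ndarray
    stopped_at: float
    n_kept: int

    @property
    def merge_correlations(self) -> np.ndarray:
        """Correlation at each kept merge, in merge (leaf-to-root) order."""
        return 1.0 - self.linkage_[: self.n_kept, 2]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """Kept merges as (left node id, right node id, merge correlation).

        Leaves are nodes 0..n-1; the i-th merge creates node n+i.
        """
        n = len(self.leaves)
        return [
            (int(self.linkage_[i, 0]), int(self.linkage_[i, 1]), 1.0 - self.linkage_[i, 2])
            for i in range(self.n_kept)
        ]

    def node_members(self) -> list[set[int]]:
        """Leaf-index membership of every kept internal node, merge order."""
        n = len(self.leaves)
        members: dict[int, set[int]] = {}
        out = []
        for i in range(self.n_kept):
            left, right = int(self.linkage_[i, 0]), int(self.linkage_[i, 1])
            s = set()
            for child in (left, right):
                if child < n:
                    s.add(child)
                else:
                    s |= members.pop(child)
            members[n + i] = s
            out.append(s)
        return out

    def roots(self) -> list[set[int]]:
        """Leaf-index sets of the forest roots (singletons included)."""
        n = len(self.leaves)
        members = {i: {i} for i in range(n)}
        for i in range(self.n_kept):
            left, right = int(self.linkage_[i, 0]), int(self.linkage_[i, 1])
            members[n + i] = members.pop(left) | members.pop(right)
        return list(members.values())

    def to_newick(self) -> str:
        """Kept forest in Newick, one tree per line.

        Branch lengths are height differences with height = 1 - merge
        correlation (leaves at height 0), so each tree is ultrametric.
        """
        n = len(self.leaves)
        height = {i: 0.0 for i in range(n)}
        node_repr = {i: self.leaves[i] for i in range(n)}
        for i in range(self.n_kept):
            left, right = int(self.linkage_[i, 0]), int(self.linkage_[i, 1])
            h = float(self.linkage_[i, 2])
            parts = []
            for child in (left, right):
                bl = max(h - height.pop(child), 0.0)
                parts.append(f"{node_repr.pop(child)}:{bl:.6g}")
            node_repr[n + i] = f"({parts[0]},{parts[1]})"
            height[n + i] = h
        return "\n".join(f"{node_repr[k]};" for k in sorted(node_repr))


@dataclass(frozen=True)
class Signature:
    """A gene co-expression cluster S_j extracted at some scale."""

    id: str
    genes: frozenset
    level_correlation: float

    @property
    def size(self) -> int:
        return len(self.genes)


def build_dendrogram(similarity: pd.DataFrame, cutoff_r: float) -> Dendrogram:
    """Average-linkage agglomeration on similarity, stopping below cutoff_r.

    Implemented as scipy average linkage on distance ``1 - r`` (average
    pairwise distance equals 1 minus average pairwise correlation), then
    truncating the monotone merge list at the first merge whose
    correlation falls below ``cutoff_r``.
    """
    if similarity.shape[0] < 2:
        raise ValueError("need at least 2 genes to build a dendrogram")
    sim = similarity.to_numpy(float)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    corr = 1.0 - Z[:, 2]
    below = corr < cutoff_r - 1e-12
    n_kept = int(np.argmax(below)) if below.any() else len(Z)
    return Dendrogram(
        leaves=list(similarity.index),
        linkage_=Z,
        stopped_at=float(cutoff_r),
        n_kept=n_kept,
    )


def extract_signatures(
    dendro: Dendrogram,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size_fraction: float = DEFAULT_MAX_SIZE_FRACTION,
    dedup_jaccard: float = DEFAULT_DEDUP_JACCARD,
) -> list[Signature]:
    """Multi-scale signatures from the kept forest.

    Candidates are the *stable* internal nodes with ``min_size <= size
    <= max_size_fraction * n_leaves``: a node is stable when it persists
    over a nonzero correlation interval, i.e. its merge correlation
    differs from its parent's (chains of nodes formed at one identical
    correlation are artifacts of the binary encoding and only their top
    node is a cluster).  Candidates are visited leaf-to-root (in merge
    order, i.e. decreasing correlation); a candidate is suppressed when
    its Jaccard similarity with an already-kept signature reaches
    ``dedup_jaccard`` (the earlier, smaller cluster wins).  Output is
    ordered by size ascending with ids C1, C2, ...
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not 0 < max_size_fraction <= 1:
        raise ValueError("max_size_fraction must be in (0, 1]")
    if not 0 < dedup_jaccard <= 1:
        raise ValueError("dedup_jaccard must be in (0, 1]")
    n = len(dendro.leaves)
    max_size = max_size_fraction * n
    # merge correlation of each kept node's parent, if the parent is kept
    parent_corr = np.full(dendro.n_kept, np.nan)
    for i in range(dendro.n_kept):
        for child in (int(dendro.linkage_[i, 0]), int(dendro.linkage_[i, 1])):
            if child >= n:
                parent_corr[child - n] = 1.0 - dendro.linkage_[i, 2]
    kept: list[tuple[set[int], float]] = []
    corrs = dendro.merge_correlations
    for i, (members, corr) in enumerate(zip(dendro.node_members(), corrs)):
        if not min_size <= len(members) <= max_size:
            continue
        if np.isfinite(parent_corr[i]) and abs(parent_corr[i] - corr) <= 1e-9:
            continue  # dissolves immediately into its parent: not stable
        suppressed = False
        for prev, _ in kept:
            inter = len(members & prev)
            union = len(members) + len(prev) - inter
            if inter / union >= dedup_jaccard:
                suppressed = True
                break
        if not suppressed:
            kept.append((members, float(corr)))
    if not kept:
        logger.warning("no signature candidate survived the size/dedup rules")
        return []
    kept.sort(key=lambda mc: (len(mc[0]), -mc[1]))
    leaves = dendro.leaves
    return [
        Signature(
            id=f"C{k + 1}",
            genes=frozenset(leaves[i] for i in members),
            level_correlation=corr,
        )
        for k, (members, corr) in enumerate(kept)
    ]


def signatures_to_gmt(signatures, path, description: str = "coexpression signature"):
    """Write signatures as GMT (name, description, tab-separated genes)."""
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.id, description, *sorted(sig.genes)]) + "\n")
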