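"""Score-stratified bipartite permutation of target networks.

Control miRNA target gene sets are generated by randomizing the edges
of the discretized network *within each score level* with repeated
double-edge swaps: two edges (m1,g1), (m2,g2) at the same level are
replaced by (m1,g2), (m2,g1) unless a duplicate (family, gene) edge at
any level would result, in which case the attempt is rejected and the
state left unchanged.  The rejection rule makes the proposal symmetric,
so the chain samples uniformly from the simple bipartite graphs with
the source's per-level family and gene degree sequences.  Consequently
every replicate preserves each family's target-set size |T_i| and its
total discretized-score mass exactly.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .network import TargetNetwork

logger = logging.getLogger(__name__)

DEFAULT_SWAPS_PER_EDGE = 10.0
_SEED_MOD = 2**31

try:  # numba compiles the inner swap loop; the fallback runs the same body
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _swap_level(gene, fam, exists, lo, idx1, idx2):  # pragma: no cover - jitted
    """Apply attempted double-edge swaps to the edge slice starting at lo.

    idx1/idx2 are pre-drawn edge offsets within the level; a draw whose
    swap would create a duplicate edge (or is a no-op) is rejected but
    still consumes the attempt.
    """
    for t in range(idx1.shape[0]):
        e1 = lo + idx1[t]
        e2 = lo + idx2[t]
        f1 = fam[e1]
        g1 = gene[e1]
        f2 = fam[e2]
        g2 = gene[e2]
        if f1 == f2 or g1 == g2:
            continue
        if exists[f1, g2] or exists[f2, g1]:
            continue
        exists[f1, g1] = False
        exists[f2, g2] = False
        exists[f1, g2] = True
        exists[f2, g1] = True
        gene[e1] = g2
        gene[e2] = g1


class ControlCollection:
    """Deterministic stream of stratified permutations of one network.

    Replicate ``i`` is generated with derived seed ``(seed + 1 + i)``;
    the stream is therefore reproducible and order-independent.  Edge
    arrays are indexed against fixed family/gene vocabularies shared by
    every replicate (families and genes sorted lexicographically).
    """

    def __init__(
        self,
        source: TargetNetwork,
        R: int,
        seed: int,
        n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    ):
        if not source.is_discretized:
            raise ValueError("network must be discretized before permutation")
        if R < 1:
            raise ValueError(f"R must be >= 1 (got {R})")
        if n_swaps_per_edge <= 0:
            raise ValueError("n_swaps_per_edge must be positive")
        self.source = source
        self.R = int(R)
        self.seed = int(seed)
        self.n_swaps_per_edge = float(n_swaps_per_edge)

        self.families = source.families
        self.genes = source.genes
        fam_index = {f: i for i, f in enumerate(self.families)}
        gene_index = {g: i for i, g in enumerate(self.genes)}

        # canonical edge order: (level, family, gene) for determinism
        df = source.df.sort_values(
            ["discretized_score", "family", "gene"], kind="mergesort"
        )
        self.fam_idx = df["family"].map(fam_index).to_numpy(np.int64)
        self._gene_idx0 = df["gene"].map(gene_index).to_numpy(np.int64)
        self.scores = df["discretized_score"].to_numpy(np.int64)
        self.context_scores = df["context_score"].to_numpy(float)

        levels, starts = np.unique(self.scores, return_index=True)
        bounds = np.append(starts, len(df))
        self._slices = list(zip(bounds[:-1], bounds[1:]))
        for (lo, hi), lev in zip(self._slices, levels):
            if hi - lo < 2:
                logger.debug("score level %d has < 2 edges; left untouched", lev)

        self._exists0 = np.zeros((len(self.families), len(self.genes)), dtype=bool)
        self._exists0[self.fam_idx, self._gene_idx0] = True

    def replicate_gene_idx(self, i: int) -> np.ndarray:
        """Gene index array of replicate i (family/score arrays are fixed)."""
        if not 0 <= i < self.R:
            raise IndexError(f"replicate index {i} out of range [0, {self.R})")
        rng = np.random.default_rng((self.seed + 1 + i) % _SEED_MOD)
        gene = self._gene_idx0.copy()
        exists = self._exists0.copy()
        plans = []
        for lo, hi in self._slices:
            m = int(hi - lo)
            if m < 2:
                continue
            attempts = math.ceil(self.n_swaps_per_edge * m)
            plans.append((int(lo), rng.integers(0, m, size=(2, attempts))))
        # interleave the levels in sweeps so the joint configuration mixes
        # (cross-level duplicate checks couple the strata)
        n_sweeps = max(1, math.ceil(self.n_swaps_per_edge))
        for k in range(n_sweeps):
            for lo, draws in plans:
                a = draws.shape[1]
                s, e = (a * k) // n_sweeps, (a * (k + 1)) // n_sweeps
                if s < e:
                    _swap_level(
                        gene, self.fam_idx, exists, lo, draws[0][s:e], draws[1][s:e]
                    )
        return gene

    def replicate(self, i: int) -> TargetNetwork:
        """Replicate i as a full TargetNetwork (for export/inspection)."""
        gene = self.replicate_gene_idx(i)
        df = pd.DataFrame(
            {
                "family": [self.families[f] for f in self.fam_idx],
                "gene": [self.genes[g] for g in gene],
                "context_score": self.context_scores,
                "discretized_score": self.scores,
            }
        )
        return TargetNetwork(df, K=self.source.K, b=self.source.b)

    def __len__(self) -> int:
        return self.R

    def __iter__(self):
        for i in range(self.R):
            yield self.replicate(i)


def permute_within_strata(
    net: TargetNetwork,
    seed: int,
    n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
) -> TargetNetwork:
    """One stratified permutation of ``net`` (see module docstring)."""
    coll = ControlCollection(net, 1, seed - 1, n_swaps_per_edge)
    return coll.replicate(0)


def generate_controls(
    net: TargetNetwork,
    R: int,
    seed: int,
    n_swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
) -> ControlCollection:
    """R seeded stratified permutations of ``net`` as a lazy collection."""
    return ControlCollection(net, R, seed, n_swaps_per_edge)
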