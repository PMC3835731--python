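"""Independent brute-force oracles used only by the test suite."""

from itertools import combinations, permutations, product

import numpy as np

from mirhic import TargetNetwork


def _level_configs(fams: list, genes: list) -> list[frozenset]:
    """All distinct simple assignments of the gene multiset to family stubs."""
    seen = set()
    for perm in set(permutations(genes)):
        edges = frozenset(zip(fams, perm))
        if len(edges) == len(fams):  # no duplicate edge within the level
            seen.add(edges)
    return sorted(seen, key=sorted)


def enumerate_stratified(net: TargetNetwork) -> list[frozenset]:
    """Every simple network with the source's per-level degree sequences.

    The double-edge-swap chain's stationary distribution is uniform over
    exactly this set (slot orderings per simple graph are equinumerous),
    so empirical frequencies can be compared against 1/len(result).
    """
    per_level = []
    for _, sub in net.df.groupby("discretized_score"):
        per_level.append(_level_configs(list(sub["family"]), list(sub["gene"])))
    out = []
    for combo in product(*per_level):
        edges = [e for config in combo for e in config]
        if len(set(edges)) == len(edges):  # simple across levels too
            out.append(frozenset(edges))
    return out


def exact_enrichment_pvalue(
    net: TargetNetwork, family: str, signature_genes: set
) -> float:
    """P(ES_null >= ES_obs) by exhaustive enumeration of stratified nulls.

    An edge's discretized score equals its stratum's level, so the ES of
    any rewired configuration follows from the per-level edge lists.
    """
    per_level = []
    for lev, sub in net.df.groupby("discretized_score"):
        configs = _level_configs(list(sub["family"]), list(sub["gene"]))
        per_level.append((int(lev), configs))
    obs = 0
    for lev, sub in net.df.groupby("discretized_score"):
        for f, g in zip(sub["family"], sub["gene"]):
            if f == family and g in signature_genes:
                obs += int(lev)
    count = 0
    total = 0
    for combo in product(*[configs for _, configs in per_level]):
        edges = [e for config in combo for e in config]
        if len(set(edges)) != len(edges):
            continue
        total += 1
        es_null = 0
        for (lev, _), config in zip(per_level, combo):
            for f, g in config:
                if f == family and g in signature_genes:
                    es_null += lev
        if es_null >= obs:
            count += 1
    return count / total


def naive_average_linkage(sim: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) agglomeration on similarity: merge the pair of clusters with
    the highest average inter-cluster correlation, to a single root."""
    n = sim.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            avg = float(
                np.mean([sim[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or avg > best[0]:
                best = (avg, a, b)
        avg, a, b = best
        merges.append((clusters[a], clusters[b], avg))
        clusters[min(a, b)] = clusters.pop(a) | clusters.pop(b)
    return merges


def exact_hypergeom_upper_tail(universe_size, n_marked, n_drawn, k) -> float:
    """P(overlap >= k) by enumerating all draws of size n_drawn."""
    universe = range(universe_size)
    marked = set(range(n_marked))
    hits = 0
    total = 0
    for draw in combinations(universe, n_drawn):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total
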