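"""Comparison methods: miRDeG, miRKM and the hyper-geometric test.

miRDeG runs the identical enrichment machinery with the whole
differentially expressed gene set as the only signature.  miRKM
replaces the hierarchy by k-means clusters of the DE genes (k = 5 or
10 by convention).  The hyper-geometric test scores the overlap of a
gene set with each family's targets against sampling without
replacement from the gene universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .config import RunConfig
from .enrichment import (
    MirhicRun,
    _subnetwork,
    analyze_signatures,
    q_values,
    run_mirhic,
)
from .expression import (
    ExpressionStudy,
    differential_expression,
    filter_low_expression,
)
from .hierarchy import Signature
from .network import TargetNetwork, discretize_scores
from .permutation import generate_controls

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def run_mirdeg(
    study: ExpressionStudy,
    net: TargetNetwork,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> MirhicRun:
    """miRHiC with the flat DE gene set as the single signature."""
    cfg = (config or RunConfig()).with_overrides(flat_signature=True)
    run = run_mirhic(study, net, cfg, seed)
    run.method = "miRDeG"
    return run


def kmeans_signatures(
    study: ExpressionStudy,
    de_genes: list[str],
    k: int,
    seed: int,
) -> list[Signature]:
    """k-means clusters of standardized DE expression profiles as signatures."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(de_genes):
        raise ValueError(f"k={k} exceeds the number of DE genes ({len(de_genes)})")
    profiles = study.matrix.loc[list(de_genes)].to_numpy(float)
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    profiles = (profiles - mu) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=k, random_state=seed % _SEED_MOD, n_init=10)
    labels = km.fit_predict(profiles)
    sigs = []
    for c in range(k):
        members = [g for g, lab in zip(de_genes, labels) if lab == c]
        if not members:  # KMeans reassigns empty clusters; guard anyway
            logger.warning("k-means cluster %d empty; dropped", c)
            continue
        sigs.append(
            Signature(
                id=f"KM{c + 1}",
                genes=frozenset(members),
                level_correlation=float("nan"),
            )
        )
    sigs.sort(key=lambda s: (s.size, s.id))
    return sigs


def run_mirkm(
    study: ExpressionStudy,
    net: TargetNetwork,
    k: int,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> MirhicRun:
    """miRKM: k-means signatures, then the identical ES/p/P/p_i/q chain."""
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    filtered = filter_low_expression(study, cfg.top_n, cfg.sample_fraction)
    de_table, de_genes = differential_expression(filtered, cfg.paired, cfg.de_alpha)
    if not de_genes:
        raise ValueError("no differentially expressed genes; miRKM has no input")
    sigs = kmeans_signatures(filtered, de_genes, k, seed)
    if not net.is_discretized:
        net = discretize_scores(net, cfg.K, cfg.b)
    controls = generate_controls(net, cfg.R, seed, cfg.n_swaps_per_edge)
    table, p_df, es_df = analyze_signatures(net, controls, sigs)
    sub = _subnetwork(table, p_df, sigs, net, cfg.q_threshold)
    return MirhicRun(
        table=table,
        p_matrix=p_df,
        es_matrix=es_df,
        signatures=sigs,
        de_table=de_table,
        de_genes=de_genes,
        subnetwork=sub,
        config=cfg,
        method=f"miRKM{k}",
    )


def hypergeometric_test(
    gene_set,
    family: str,
    net: TargetNetwork,
    universe,
) -> float:
    """Upper-tail hyper-geometric p for the overlap |S & T_i| in the universe.

    P(X >= k) with population size |universe|, |T_i & universe| marked,
    |S| drawn.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_set = frozenset(gene_set) & universe
    targets = net.target_sets().get(family)
    if targets is None:
        raise KeyError(f"unknown miRNA family {family!r}")
    marked = targets & universe
    k = len(gene_set & marked)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(marked), len(gene_set)))


def run_hypergeometric(
    study: ExpressionStudy,
    net: TargetNetwork,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """HG-test of the DE set against every family, on the filtered universe."""
    cfg = config or RunConfig()
    filtered = filter_low_expression(study, cfg.top_n, cfg.sample_fraction)
    _, de_genes = differential_expression(filtered, cfg.paired, cfg.de_alpha)
    if not de_genes:
        raise ValueError("no differentially expressed genes; HG-test has no input")
    universe = frozenset(filtered.genes)
    fams = net.families
    p = np.array([hypergeometric_test(de_genes, f, net, universe) for f in fams])
    return pd.DataFrame(
        {"p": p, "q": q_values(p)}, index=pd.Index(fams, name="family")
    ).sort_values(["p", "q"], kind="mergesort")
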