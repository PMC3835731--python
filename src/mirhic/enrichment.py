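"""Core statistics: enrichment scores and nested empirical significance.

For miRNA family i with target set T_i and co-expression signature S_j,
the raw enrichment score is the sum of discretized target scores over
the overlap::

    ES_ij = sum_{g in T_i & S_j} s(i, g)

Its per-signature p-value p_ij is the right-tail empirical proportion
of ES_ij(r) from R score-stratified permutations of the network.  The
P-score ``P_i = min_j p_ij`` aggregates over all scales of the
hierarchy; being a minimum of p-values it is biased toward 0, so its
significance is itself calibrated against the permutation null: each
control replicate r is scored through the identical machinery
(self-ranked within the same control ES distribution) to give P_i(r),
and ``p_i = #{r : P_i(r) <= P_i} / R``.  BH step-up q-values are
reported per family.

Empirical proportions use the plain #/R convention with >= / <= ties
counting toward significance; an observed score exceeding every control
yields p = 0, displayed as "< 1/R".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .expression import (
    ExpressionStudy,
    differential_expression,
    filter_low_expression,
)
from .hierarchy import (
    Dendrogram,
    Signature,
    build_dendrogram,
    correlation_cutoff,
    extract_signatures,
    pairwise_correlation,
    signatures_to_gmt,
)
from .network import TargetNetwork, discretize_scores
from .permutation import ControlCollection, generate_controls, njit

logger = logging.getLogger(__name__)


@njit(cache=True)
def _es_kernel(gene_idx, fam_idx, scores, sig_indptr, sig_ids, out):  # pragma: no cover
    """Accumulate each edge's score into (family, signature) cells."""
    for e in range(gene_idx.shape[0]):
        g = gene_idx[e]
        for k in range(sig_indptr[g], sig_indptr[g + 1]):
            out[fam_idx[e], sig_ids[k]] += scores[e]


# ----------------------------------------------------------------- primitives
def enrichment_score(
    signature: Signature,
    family: str,
    net: TargetNetwork,
    universe=None,
) -> tuple[frozenset, float]:
    """Overlap genes and raw enrichment score for one (family, signature).

    The overlap is restricted to ``universe`` (e.g. the filtered
    expression gene set) when given.
    """
    targets = net.target_sets().get(family)
    if targets is None:
        raise KeyError(f"unknown miRNA family {family!r}")
    overlap = signature.genes & targets
    if universe is not None:
        overlap &= frozenset(universe)
    scores = net.discretized_map()
    es = float(sum(scores[(family, g)] for g in overlap))
    return frozenset(overlap), es


def p_score(p_row) -> float:
    """P_i: the p-value of the most significant enrichment, min_j p_ij."""
    arr = np.asarray(p_row, float)
    if arr.size == 0:
        raise ValueError("P-score of an empty p-value row is undefined")
    return float(arr.min())


def empirical_pvalue(observed_P: np.ndarray, control_tensor: np.ndarray) -> np.ndarray:
    """Nested empirical p-value p_i per family.

    ``control_tensor`` holds ES_ij(r) with shape (R, families,
    signatures).  Each replicate's per-signature p-value is its
    self-inclusive right-tail rank within the control distribution,
    p_ij(r) = #{r' : ES_ij(r') >= ES_ij(r)} / R; P_i(r) = min_j; and
    p_i = #{r : P_i(r) <= P_i} / R.
    """
    P_ctrl = _control_pscores(control_tensor)
    observed_P = np.asarray(observed_P, float)
    return (P_ctrl <= observed_P[None, :]).mean(axis=0)


def _control_pscores(control_tensor: np.ndarray) -> np.ndarray:
    """P_i(r) matrix (R, families) by self-ranking the control tensor.

    For each (family, signature) column, p_ij(r) = #{r' : ES(r') >=
    ES(r)} / R computed by sort + searchsorted (equivalent to a min-rank
    but cheaper than a generic rank on large tensors).
    """
    tensor = np.asarray(control_tensor)
    R, F, J = tensor.shape
    count_lt = np.empty((R, F, J), dtype=np.int64)
    for i in range(F):
        for j in range(J):
            col = tensor[:, i, j]
            count_lt[:, i, j] = np.searchsorted(np.sort(col), col, side="left")
    p_ctrl = (R - count_lt) / R
    return p_ctrl.min(axis=2)


def q_values(p, method: str = "bh") -> np.ndarray:
    """BH step-up adjusted values, reported as q."""
    if method != "bh":
        raise ValueError(f"unsupported q-value method {method!r}")
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ the null
class EnrichmentNull:
    """Control ES tensor for a (network, controls, signatures) triple.

    Computes ES_ij(r) for every replicate once; observed networks (the
    source, or extra permuted networks in calibration experiments) are
    then scored against it cheaply.
    """

    def __init__(
        self,
        net: TargetNetwork,
        controls: ControlCollection,
        signatures: list[Signature],
    ):
        if not signatures:
            raise ValueError("need at least one signature")
        self.signatures = list(signatures)
        self.controls = controls
        self.families = controls.families
        self.R = controls.R
        gene_index = {g: i for i, g in enumerate(controls.genes)}
        J = len(signatures)
        self._M = np.zeros((len(controls.genes), J))
        for j, sig in enumerate(self.signatures):
            for g in sig.genes:
                gi = gene_index.get(g)
                if gi is not None:
                    self._M[gi, j] = 1.0
        self._edge_scores = controls.scores.astype(float)
        self._fam_idx = controls.fam_idx
        self._J = J
        self._F = len(self.families)
        # CSR-style per-gene signature membership; most genes are in none
        indptr = np.zeros(len(controls.genes) + 1, dtype=np.int64)
        cols = []
        for gi in range(len(controls.genes)):
            row = np.flatnonzero(self._M[gi])
            indptr[gi + 1] = indptr[gi] + len(row)
            cols.append(row)
        self._sig_indptr = indptr
        self._sig_ids = (
            np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        ).astype(np.int64)
        self.tensor = np.empty((self.R, self._F, J), dtype=np.float32)
        for r in range(self.R):
            self.tensor[r] = self.es_from_gene_idx(controls.replicate_gene_idx(r))
        self._P_ctrl = _control_pscores(self.tensor)

    def es_from_gene_idx(self, gene_idx: np.ndarray) -> np.ndarray:
        """ES matrix (families x signatures) for one edge configuration."""
        out = np.zeros((self._F, self._J))
        _es_kernel(
            gene_idx,
            self._fam_idx,
            self._edge_scores,
            self._sig_indptr,
            self._sig_ids,
            out,
        )
        return out

    def subset(self, signature_ids) -> "EnrichmentNull":
        """A view of this null restricted to some signatures.

        Shares the already-computed ES tensor columns, so e.g. the flat
        DE signature and the hierarchical signatures can be scored from
        one set of permutations.
        """
        ids = [s.id for s in self.signatures]
        js = [ids.index(i) for i in signature_ids]
        other = object.__new__(EnrichmentNull)
        other.signatures = [self.signatures[j] for j in js]
        other.controls = self.controls
        other.families = self.families
        other.R = self.R
        other._edge_scores = self._edge_scores
        other._fam_idx = self._fam_idx
        other._F = self._F
        other._J = len(js)
        other._M = self._M[:, js]
        indptr = np.zeros(len(self.controls.genes) + 1, dtype=np.int64)
        cols = []
        for gi in range(len(self.controls.genes)):
            row = np.flatnonzero(other._M[gi])
            indptr[gi + 1] = indptr[gi] + len(row)
            cols.append(row)
        other._sig_indptr = indptr
        other._sig_ids = (
            np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        ).astype(np.int64)
        other.tensor = np.ascontiguousarray(self.tensor[:, :, js])
        other._P_ctrl = _control_pscores(other.tensor)
        return other

    def observed_es(self) -> np.ndarray:
        """ES matrix of the source (unpermuted) network."""
        return self.es_from_gene_idx(self.controls._gene_idx0)

    def pvalues(self, es: np.ndarray) -> np.ndarray:
        """Right-tail empirical p_ij for an ES matrix (ties count)."""
        return (self.tensor >= es[None, :, :].astype(np.float32)).mean(axis=0)

    def empirical_p(self, observed_P: np.ndarray) -> np.ndarray:
        """Nested p_i for a vector of observed P-scores."""
        return (self._P_ctrl <= np.asarray(observed_P, float)[None, :]).mean(axis=0)

    def score_network(self, gene_idx: np.ndarray | None = None) -> dict:
        """Full ES -> p_ij -> P_i -> p_i chain for one edge configuration."""
        es = self.observed_es() if gene_idx is None else self.es_from_gene_idx(gene_idx)
        p = self.pvalues(es)
        P = p.min(axis=1)
        return {"ES": es, "p": p, "P": P, "empirical_p": self.empirical_p(P)}


def signature_pvalues(
    net: TargetNetwork,
    controls: ControlCollection,
    signatures: list[Signature],
) -> tuple[pd.DataFrame, EnrichmentNull]:
    """Observed p_ij matrix plus the retained control ES tensor."""
    null = EnrichmentNull(net, controls, signatures)
    p = null.pvalues(null.observed_es())
    sig_ids = [s.id for s in signatures]
    return pd.DataFrame(p, index=null.families, columns=sig_ids), null


# ----------------------------------------------------------------- pipeline
@dataclass
class MirhicRun:
    """Result bundle of one full run."""

    table: pd.DataFrame  # per family: best_signature, ES, P_score, empirical_p, q
    p_matrix: pd.DataFrame  # families x signatures observed p_ij
    es_matrix: pd.DataFrame
    signatures: list[Signature]
    de_table: pd.DataFrame
    de_genes: list[str]
    subnetwork: pd.DataFrame  # family, gene, signature, discretized_score
    config: RunConfig
    dendrogram: Dendrogram | None = None
    method: str = "miRHiC"

    def write(self, outdir) -> None:
        """Write results.tsv, subnetwork.tsv, signatures.gmt, de_table.tsv,
        config.yaml into ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        table = self.table.copy()
        table.insert(
            len(table.columns),
            "empirical_p_label",
            [
                f"<{1 / self.config.R:g}" if p == 0 else f"{p:g}"
                for p in table["empirical_p"]
            ],
        )
        table.to_csv(os.path.join(outdir, "results.tsv"), sep="\t")
        self.subnetwork.to_csv(
            os.path.join(outdir, "subnetwork.tsv"), sep="\t", index=False
        )
        signatures_to_gmt(self.signatures, os.path.join(outdir, "signatures.gmt"))
        self.de_table.to_csv(os.path.join(outdir, "de_table.tsv"), sep="\t")
        self.config.to_yaml(os.path.join(outdir, "config.yaml"))
        if self.dendrogram is not None:
            with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
                fh.write(self.dendrogram.to_newick() + "\n")

    def to_graphml(self, path) -> None:
        """Inferred bipartite sub-network as GraphML (optional export)."""
        import networkx as nx

        g = nx.Graph()
        for row in self.subnetwork.itertuples(index=False):
            g.add_node(row.family, kind="mirna_family")
            g.add_node(row.gene, kind="gene", signature=row.signature)
            g.add_edge(
                row.family, row.gene, discretized_score=int(row.discretized_score)
            )
        nx.write_graphml(g, path)


def analyze_signatures(
    net: TargetNetwork,
    controls: ControlCollection,
    signatures: list[Signature],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ES/p/P/p_i/q chain for fixed signatures; returns (table, p, ES)."""
    return analyze_from_null(EnrichmentNull(net, controls, signatures))


def analyze_from_null(
    null: EnrichmentNull,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ES/p/P/p_i/q chain against an already-computed null."""
    signatures = null.signatures
    es = null.observed_es()
    p = null.pvalues(es)
    P = p.min(axis=1)
    p_i = null.empirical_p(P)
    q = q_values(p_i)
    best_j = p.argmin(axis=1)  # ties: first signature (size-ascending order)
    sig_ids = [s.id for s in signatures]
    fams = null.families
    table = pd.DataFrame(
        {
            "best_signature": [sig_ids[j] for j in best_j],
            "ES": es[np.arange(len(fams)), best_j],
            "P_score": P,
            "empirical_p": p_i,
            "q": q,
        },
        index=pd.Index(fams, name="family"),
    ).sort_values(["empirical_p", "P_score", "family"], kind="mergesort")
    p_df = pd.DataFrame(p, index=fams, columns=sig_ids)
    es_df = pd.DataFrame(es, index=fams, columns=sig_ids)
    return table, p_df, es_df


def _flat_signature(de_genes) -> Signature:
    return Signature(id="DE", genes=frozenset(de_genes), level_correlation=float("nan"))


def hierarchy_signatures(
    study: ExpressionStudy,
    de_genes: list[str],
    config: RunConfig,
) -> tuple[list[Signature], Dendrogram]:
    """Dendrogram over DE genes and the extracted multi-scale signatures."""
    sim = pairwise_correlation(study, de_genes, config.correlation_method)
    if config.absolute_correlation:
        sim = sim.abs()
    r_cut = correlation_cutoff(config.z_cutoff, study.n_samples)
    dendro = build_dendrogram(sim, r_cut)
    sigs = extract_signatures(
        dendro,
        min_size=config.min_size,
        max_size_fraction=config.max_size_fraction,
        dedup_jaccard=config.dedup_jaccard,
    )
    return sigs, dendro


def _subnetwork(table, p_df, signatures, net, q_threshold) -> pd.DataFrame:
    by_id = {s.id: s for s in signatures}
    scores = net.discretized_map()
    targets = net.target_sets()
    rows = []
    for fam, row in table.iterrows():
        if row["q"] >= q_threshold:
            continue
        sig = by_id[row["best_signature"]]
        for g in sorted(sig.genes & targets.get(fam, frozenset())):
            rows.append((fam, g, sig.id, scores[(fam, g)]))
    return pd.DataFrame(
        rows, columns=["family", "gene", "signature", "discretized_score"]
    )


def calibration_experiment(
    study: ExpressionStudy,
    net: TargetNetwork,
    config: RunConfig | None = None,
    n_observed: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score control target sets as if observed, to check calibration.

    Generates ``n_observed`` extra stratified permutations per family
    (disjoint seeds from the null replicates), runs each through the
    full ES -> p_ij -> P_i -> p_i chain against the same null, and
    returns a long table (family, replicate, size, empirical_p).  If
    the estimator is unbiased these empirical p-values are uniform on
    [0, 1] and independent of the target-set sizes |T_i|.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    filtered = filter_low_expression(study, cfg.top_n, cfg.sample_fraction)
    _, de_genes = differential_expression(filtered, cfg.paired, cfg.de_alpha)
    if not de_genes:
        raise ValueError("no differentially expressed genes")
    sigs, _ = hierarchy_signatures(filtered, de_genes, cfg)
    if not sigs:
        sigs = [_flat_signature(de_genes)]
    if not net.is_discretized:
        net = discretize_scores(net, cfg.K, cfg.b)
    controls = generate_controls(net, cfg.R, seed, cfg.n_swaps_per_edge)
    null = EnrichmentNull(net, controls, sigs)
    observed = generate_controls(
        net, n_observed, seed + cfg.R + 1, cfg.n_swaps_per_edge
    )
    sizes = np.array([len(t) for t in map(net.target_sets().get, null.families)])
    rows = []
    for r in range(n_observed):
        scored = null.score_network(observed.replicate_gene_idx(r))
        for i, fam in enumerate(null.families):
            rows.append((fam, r, int(sizes[i]), float(scored["empirical_p"][i])))
    return pd.DataFrame(rows, columns=["family", "replicate", "size", "empirical_p"])


def run_mirhic(
    study: ExpressionStudy,
    net: TargetNetwork,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> MirhicRun:
    """The full pipeline: filter -> DE -> hierarchy -> signatures ->
    stratified controls -> ES / p_ij / P_i / p_i / q -> sub-network report."""
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    filtered = filter_low_expression(study, cfg.top_n, cfg.sample_fraction)
    de_table, de_genes = differential_expression(filtered, cfg.paired, cfg.de_alpha)
    if not de_genes:
        raise ValueError(
            "no differentially expressed genes at adjusted p < "
            f"{cfg.de_alpha}; relax de_alpha or check the group labels"
        )
    dendro = None
    if cfg.flat_signature:
        sigs = [_flat_signature(de_genes)]
    else:
        sigs, dendro = hierarchy_signatures(filtered, de_genes, cfg)
        if not sigs:
            if not cfg.fallback_to_flat:
                raise ValueError("no co-expression signature extracted")
            logger.warning(
                "no signature extracted; falling back to the flat DE signature"
            )
            sigs = [_flat_signature(de_genes)]
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
        dendrogram=dendro,
    )
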