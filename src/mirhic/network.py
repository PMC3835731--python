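"""Weighted bipartite miRNA-family -> target-gene networks.

A target network is a simple bipartite graph between miRNA families and
genes.  Each edge carries a TargetScan-style *context score* (a negative
real number; more negative means stronger predicted repression) and,
after :func:`discretize_scores`, an integer *discretized score* on the
ladder ``1, 1+b, 1+2b, ..., 1+b(K-1)``.  Discretization is rank-based:
edges are sorted by context score in decreasing order (weakest
regulation first), so the weakest 1/K of all pairs receive score 1 and
the strongest 1/K receive ``1+b(K-1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default number of score levels and level spacing
DEFAULT_K = 5
DEFAULT_B = 3

_REQUIRED = ("family", "gene", "context_score")


@dataclass(frozen=True)
class TargetPair:
    """One miRNA-family -> gene edge."""

    mirna_family: str
    gene: str
    context_score: float
    discretized_score: int | None = None


class TargetNetwork:
    """Collection of unique (family, gene) pairs with scores.

    Parameters
    ----------
    pairs
        DataFrame with columns ``family``, ``gene``, ``context_score``
        and optionally ``discretized_score``.
    K, b
        Discretization parameters, set by :func:`discretize_scores`.
    """

    def __init__(self, pairs: pd.DataFrame, K: int | None = None, b: int | None = None):
        missing = [c for c in _REQUIRED if c not in pairs.columns]
        if missing:
            raise ValueError(f"pairs table is missing column(s): {', '.join(missing)}")
        if len(pairs) == 0:
            raise ValueError("target network has no pairs")
        if pairs.duplicated(subset=["family", "gene"]).any():
            raise ValueError("duplicate (family, gene) pairs in network")
        cols = list(_REQUIRED)
        if "discretized_score" in pairs.columns:
            cols.append("discretized_score")
        self.df = pairs[cols].reset_index(drop=True)
        self.K = K
        self.b = b

    # ------------------------------------------------------------------ basic
    @property
    def n(self) -> int:
        """Total number of (family, gene) pairs, the symbol N."""
        return len(self.df)

    @property
    def is_discretized(self) -> bool:
        return "discretized_score" in self.df.columns

    @property
    def families(self) -> list[str]:
        return sorted(self.df["family"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def target_sets(self) -> dict[str, frozenset[str]]:
        """Target gene set T_i per family."""
        return {
            fam: frozenset(sub["gene"])
            for fam, sub in self.df.groupby("family", sort=True)
        }

    def discretized_map(self) -> dict[tuple[str, str], int]:
        if not self.is_discretized:
            raise ValueError("network is not discretized")
        d = self.df
        return dict(
            zip(zip(d["family"], d["gene"]), d["discretized_score"].astype(int))
        )

    def pairs(self) -> Iterator[TargetPair]:
        disc = self.is_discretized
        for row in self.df.itertuples(index=False):
            yield TargetPair(
                row.family,
                row.gene,
                float(row.context_score),
                int(row.discretized_score) if disc else None,
            )

    # ------------------------------------------------------------------- I/O
    def to_edgelist_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def to_gmt(self, path, description: str = "target set") -> None:
        """Write one GMT line per family: name, description, genes."""
        with open(path, "w") as fh:
            for fam, genes in sorted(self.target_sets().items()):
                fh.write("\t".join([fam, description, *sorted(genes)]) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        disc = f", K={self.K}, b={self.b}" if self.is_discretized else ""
        return (
            f"TargetNetwork({len(self.df['family'].unique())} families, "
            f"{len(self.df['gene'].unique())} genes, N={self.n}{disc})"
        )


def load_target_pairs(
    path,
    family_col: str = "family",
    gene_col: str = "gene",
    score_col: str = "context_score",
) -> TargetNetwork:
    """Read a TargetScan-style TSV of pre-summarized (family, gene) scores.

    The table must be tab-separated with a header.  Column names are
    configurable because TargetScan releases rename them.  The reader
    consumes one row per (family, gene) pair whose score is already the
    summarized context score; duplicate rows for the same pair are
    collapsed keeping the most negative score (with a warning when the
    duplicates disagree).
    """
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"target file {path} is empty")
    for col in (family_col, gene_col, score_col):
        if col not in df.columns:
            raise ValueError(
                f"target file {path} is missing required column {col!r} "
                f"(found: {list(df.columns)})"
            )
    df = df.rename(
        columns={family_col: "family", gene_col: "gene", score_col: "context_score"}
    )[["family", "gene", "context_score"]]
    df["context_score"] = df["context_score"].astype(float)
    dup = df.duplicated(subset=["family", "gene"], keep=False)
    if dup.any():
        conflicting = (
            df[dup].groupby(["family", "gene"])["context_score"].nunique() > 1
        ).sum()
        if conflicting:
            logger.warning(
                "%d duplicated (family, gene) pair(s) with conflicting scores; "
                "keeping the most negative",
                int(conflicting),
            )
        df = df.groupby(["family", "gene"], as_index=False, sort=False)[
            "context_score"
        ].min()
    return TargetNetwork(df)


def merge_families(
    net: TargetNetwork, family_map: Mapping[str, str]
) -> TargetNetwork:
    """Merge member miRNAs into families via ``family_map``.

    Unmapped names pass through unchanged.  The merged family's target
    set is the union of member target sets; duplicate (family, gene)
    pairs arising from the merge keep the most negative context score.
    """
    df = net.df.copy()
    unmapped = set(df["family"]) - set(family_map)
    if unmapped and family_map:
        logger.info("%d miRNA name(s) not in family map; kept as-is", len(unmapped))
    df["family"] = df["family"].map(lambda f: family_map.get(f, f))
    merged = df.groupby(["family", "gene"], as_index=False, sort=False)[
        "context_score"
    ].min()
    return TargetNetwork(merged)


def discretize_scores(
    net: TargetNetwork, K: int = DEFAULT_K, b: int = DEFAULT_B
) -> TargetNetwork:
    """Assign integer score levels by rank.

    Pairs are sorted by context score in decreasing order (least
    negative, i.e. weakest, first).  With 0-based rank r among N pairs,
    the discretized score is ``1 + b * floor(r*K/N)``, so the weakest
    1/K of pairs get 1 and the strongest 1/K get ``1+b(K-1)``.  Ties in
    context score are broken by a stable sort on (gene, family) so the
    assignment is reproducible.
    """
    if K < 1 or b < 1:
        raise ValueError(f"K and b must be positive integers (got K={K}, b={b})")
    if K > net.n:
        raise ValueError(f"K={K} exceeds the number of pairs N={net.n}")
    df = net.df.sort_values(
        ["context_score", "gene", "family"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    r = np.arange(len(df), dtype=np.int64)
    df["discretized_score"] = 1 + b * ((r * K) // len(df))
    return TargetNetwork(df, K=K, b=b)
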