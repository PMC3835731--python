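"""Seeded synthetic datasets with known truth.

Emulates the structure the method assumes in cancer transcriptomes: a
two-group expression matrix whose differentially expressed genes are
organized into correlated blocks (transcriptional modules), plus a
miRNA-family -> gene network in which one planted family concentrates
strong targets inside a single block.

Expression uses a per-block factor model: for block b with correlation
rho_b, gene values are ``sqrt(rho_b) * F_s + sqrt(1 - rho_b) * eps``
(unit variance before the noise_sd scale), so the expected within-block
pairwise correlation is exactly rho_b; case samples get the block's
mean shift delta_b on top.  Background genes are i.i.d. noise.

The planted family models a module-specific regulator: its
``n_planted_targets`` strongest-score targets sit inside one block and
the rest of its target set is drawn from background (non-block,
non-differential) genes.  Its total overlap with the DE set therefore
matches the expectation for a random family of its size, which is
precisely the regime where flat DE-set enrichment has no signal but a
hierarchy-aware test does.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionStudy
from .network import TargetNetwork

logger = logging.getLogger(__name__)

#: default study conditions
DEFAULT_N_GENES = 2000
DEFAULT_N_BLOCKS = 8
DEFAULT_BLOCK_SIZE = 60
DEFAULT_RHO = 0.7
DEFAULT_DELTA = 2.0
DEFAULT_N_CASE = 30
DEFAULT_N_CONTROL = 30
DEFAULT_N_FAMILIES = 100
DEFAULT_DEGREE_LOW = 20
DEFAULT_DEGREE_HIGH = 800
DEFAULT_PLANTED_DEGREE = 100
DEFAULT_N_PLANTED_TARGETS = 20

#: context-score ranges (negative; more negative = stronger)
BACKGROUND_SCORE_RANGE = (-0.6, -0.01)
PLANTED_SCORE_RANGE = (-1.0, -0.8)


@dataclass(frozen=True)
class BlockSpec:
    """One correlated gene block: size, factor correlation, case shift."""

    size: int
    rho: float
    delta: float


def _default_blocks() -> tuple[BlockSpec, ...]:
    # alternating up/down modules, all differentially expressed
    return tuple(
        BlockSpec(DEFAULT_BLOCK_SIZE, DEFAULT_RHO, DEFAULT_DELTA * (-1) ** i)
        for i in range(DEFAULT_N_BLOCKS)
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of one synthetic dataset."""

    seed: int
    n_genes: int = DEFAULT_N_GENES
    n_case: int = DEFAULT_N_CASE
    n_control: int = DEFAULT_N_CONTROL
    noise_sd: float = 1.0
    blocks: tuple[BlockSpec, ...] = field(default_factory=_default_blocks)
    n_families: int = DEFAULT_N_FAMILIES
    degree_low: int = DEFAULT_DEGREE_LOW
    degree_high: int = DEFAULT_DEGREE_HIGH
    planted: bool = True
    planted_family: str = "miR-planted"
    planted_degree: int = DEFAULT_PLANTED_DEGREE
    n_planted_targets: int = DEFAULT_N_PLANTED_TARGETS
    planted_block: int = 0

    def __post_init__(self):
        if sum(b.size for b in self.blocks) > self.n_genes:
            raise ValueError("blocks do not fit into n_genes")
        for b in self.blocks:
            if not 0 <= b.rho < 1:
                raise ValueError(f"block rho must be in [0, 1) (got {b.rho})")
        if self.planted and self.n_planted_targets > self.planted_degree:
            raise ValueError("planted_targets larger than planted family degree")

    # ------------------------------------------------------------- structure
    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def block_genes(self) -> list[list[str]]:
        genes = self.genes
        out, at = [], 0
        for b in self.blocks:
            out.append(genes[at : at + b.size])
            at += b.size
        return out

    @property
    def background_genes(self) -> list[str]:
        n_block = sum(b.size for b in self.blocks)
        return self.genes[n_block:]

    @property
    def planted_targets(self) -> frozenset:
        if not self.planted:
            return frozenset()
        return frozenset(self.block_genes[self.planted_block][: self.n_planted_targets])

    def to_json(self, path) -> None:
        data = {
            "seed": self.seed,
            "n_genes": self.n_genes,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "noise_sd": self.noise_sd,
            "blocks": [
                {"size": b.size, "rho": b.rho, "delta": b.delta, "genes": genes}
                for b, genes in zip(self.blocks, self.block_genes)
            ],
            "n_families": self.n_families,
            "degree_low": self.degree_low,
            "degree_high": self.degree_high,
            "planted": self.planted,
            "planted_family": self.planted_family if self.planted else None,
            "planted_targets": sorted(self.planted_targets),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _rng(truth: SyntheticTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([truth.seed, stream]))


def generate_expression(truth: SyntheticTruth) -> ExpressionStudy:
    """Factor-model two-group expression matrix for ``truth``."""
    rng = _rng(truth, 0)
    n_samples = truth.n_case + truth.n_control
    samples = [f"case{i:03d}" for i in range(truth.n_case)] + [
        f"ctrl{i:03d}" for i in range(truth.n_control)
    ]
    is_case = np.r_[np.ones(truth.n_case), np.zeros(truth.n_control)].astype(bool)
    values = np.empty((truth.n_genes, n_samples))
    at = 0
    for b in truth.blocks:
        factor = rng.standard_normal(n_samples)
        eps = rng.standard_normal((b.size, n_samples))
        block = np.sqrt(b.rho) * factor[None, :] + np.sqrt(1 - b.rho) * eps
        block = truth.noise_sd * block
        block[:, is_case] += b.delta
        values[at : at + b.size] = block
        at += b.size
    values[at:] = truth.noise_sd * rng.standard_normal((truth.n_genes - at, n_samples))
    matrix = pd.DataFrame(values, index=truth.genes, columns=samples)
    groups = pd.Series(
        np.where(is_case, "case", "control"), index=samples, name="group"
    )
    pairing = pd.Series(
        [f"P{i:03d}" for i in range(truth.n_case)]
        + [f"P{i:03d}" for i in range(truth.n_control)],
        index=samples,
        name="pair",
    ) if truth.n_case == truth.n_control else None
    return ExpressionStudy(matrix, groups, pairing)


def generate_network(
    truth: SyntheticTruth,
    n_families: int | None = None,
    degree_low: int | None = None,
    degree_high: int | None = None,
) -> TargetNetwork:
    """Random bipartite target network with the planted family forced in.

    Non-planted families draw target sets uniformly from all genes with
    log-uniform degrees (mirroring the wide spread of real miRNA
    target-set sizes); context scores are uniform on the background
    range.  The planted family gets its planted targets with scores on
    the strong (most negative) range plus background-gene targets with
    background scores.
    """
    rng = _rng(truth, 1)
    n_families = truth.n_families if n_families is None else n_families
    lo = truth.degree_low if degree_low is None else degree_low
    hi = truth.degree_high if degree_high is None else degree_high
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if not 1 <= lo <= hi <= truth.n_genes:
        raise ValueError("invalid degree range")
    genes = np.array(truth.genes)
    s_lo, s_hi = BACKGROUND_SCORE_RANGE
    rows: list[tuple[str, str, float]] = []
    n_random = n_families - (1 if truth.planted else 0)
    for i in range(n_random):
        fam = f"fam{i:03d}"
        degree = int(np.round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        degree = min(max(degree, 1), truth.n_genes)
        targets = rng.choice(genes, size=degree, replace=False)
        scores = rng.uniform(s_lo, s_hi, size=degree)
        rows.extend(zip([fam] * degree, targets, scores))
    if truth.planted:
        planted = sorted(truth.planted_targets)
        n_rest = truth.planted_degree - len(planted)
        pool = np.array(truth.background_genes)
        rest = rng.choice(pool, size=n_rest, replace=False)
        p_lo, p_hi = PLANTED_SCORE_RANGE
        rows.extend(
            zip(
                [truth.planted_family] * len(planted),
                planted,
                rng.uniform(p_lo, p_hi, size=len(planted)),
            )
        )
        rows.extend(
            zip(
                [truth.planted_family] * n_rest,
                rest,
                rng.uniform(s_lo, s_hi, size=n_rest),
            )
        )
    df = pd.DataFrame(rows, columns=["family", "gene", "context_score"])
    return TargetNetwork(df)


def generate_dataset(
    seed: int, planted: bool = True, **overrides
) -> tuple[ExpressionStudy, TargetNetwork, SyntheticTruth]:
    """Convenience: (expression study, target network, truth) for one seed."""
    truth = SyntheticTruth(seed=seed, planted=planted, **overrides)
    return generate_expression(truth), generate_network(truth), truth


def write_dataset(truth: SyntheticTruth, outdir) -> None:
    """Write expression.tsv, groups.tsv, targets.tsv and truth.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    study = generate_expression(truth)
    net = generate_network(truth)
    study.matrix.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
    ann = pd.DataFrame({"sample": study.groups.index, "group": study.groups.values})
    if study.pairing is not None:
        ann["pair"] = study.pairing.values
    ann.to_csv(os.path.join(outdir, "groups.tsv"), sep="\t", index=False)
    net.df.to_csv(os.path.join(outdir, "targets.tsv"), sep="\t", index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
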