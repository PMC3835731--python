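"""Expression matrix handling: low-expression filter and differential expression.

The matrix is assumed to hold log-scale (or otherwise t-test
appropriate) values, genes in rows and samples in columns, with a
two-group annotation (case vs control) and an optional sample pairing.
No normalization is applied here; values are used as provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 10_000
DEFAULT_SAMPLE_FRACTION = 0.3
DEFAULT_DE_ALPHA = 1e-4

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionStudy:
    """A gene x sample matrix with a case/control annotation.

    ``groups`` maps each sample (matrix column) to ``"case"`` or
    ``"control"``; ``pairing`` optionally maps samples to pair labels
    for paired designs.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    pairing: pd.Series | None = None

    def __post_init__(self):
        if self.matrix.index.duplicated().any():
            raise ValueError("gene identifiers are not unique")
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"sample(s) missing from group annotation: {missing}")
        extra = [s for s in self.groups.index if s not in self.matrix.columns]
        if extra:
            raise ValueError(f"sample(s) in group annotation not in matrix: {extra}")
        self.groups = self.groups.reindex(self.matrix.columns)
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control' (got {bad})")
        if (self.groups == CASE).sum() < 2 or (self.groups == CONTROL).sum() < 2:
            raise ValueError("need at least 2 samples per group")
        if self.pairing is not None:
            self.pairing = self.pairing.reindex(self.matrix.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def subset_genes(self, genes) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix.loc[list(genes)], self.groups, self.pairing)


def read_expression_study(matrix_path, groups_path) -> ExpressionStudy:
    """Read a genes-in-rows TSV matrix plus a (sample, group[, pair]) TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t")
    for col in ("sample", "group"):
        if col not in ann.columns:
            raise ValueError(f"groups file {groups_path} is missing column {col!r}")
    unknown = [s for s in ann["sample"] if s not in matrix.columns]
    if unknown:
        raise ValueError(
            f"sample(s) {unknown} in groups file are absent from the matrix"
        )
    groups = ann.set_index("sample")["group"]
    pairing = ann.set_index("sample")["pair"] if "pair" in ann.columns else None
    return ExpressionStudy(matrix, groups, pairing)


def filter_low_expression(
    study: ExpressionStudy,
    top_n: int = DEFAULT_TOP_N,
    sample_fraction: float = DEFAULT_SAMPLE_FRACTION,
) -> ExpressionStudy:
    """Keep genes ranking in the top ``top_n`` of at least a fraction of samples.

    A gene is kept iff its value is among the ``top_n`` highest of the
    sample in at least ``ceil(sample_fraction * n_samples)`` samples.
    Ties at the rank boundary are all kept within a sample.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    values = study.matrix.to_numpy(float)
    n_genes, n_samples = values.shape
    if top_n >= n_genes:
        logger.warning(
            "top_n=%d >= %d genes; low-expression filter keeps everything",
            top_n,
            n_genes,
        )
        return study
    # per-sample value of the top_n-th largest entry; >= keeps boundary ties
    thresh = np.sort(values, axis=0)[::-1][top_n - 1]
    in_top = values >= thresh[None, :]
    needed = math.ceil(sample_fraction * n_samples)
    keep = in_top.sum(axis=1) >= needed
    kept = study.matrix.loc[keep]
    logger.info("low-expression filter: kept %d / %d genes", len(kept), n_genes)
    return ExpressionStudy(kept, study.groups, study.pairing)


def differential_expression(
    study: ExpressionStudy,
    paired: bool = False,
    alpha: float = DEFAULT_DE_ALPHA,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene two-sided t-test with BH adjustment.

    Welch's two-sample test by default; the paired t-test when
    ``paired`` is set and a complete pairing is available.  Returns the
    full table (t_statistic, p_value, adjusted_p, log_fold_change =
    mean case - mean control) and the DE gene list at
    ``adjusted_p < alpha``.
    """
    case = study.matrix[study.case_samples].to_numpy(float)
    ctrl = study.matrix[study.control_samples].to_numpy(float)
    if paired:
        if study.pairing is None or study.pairing.isna().any():
            raise ValueError("paired test requested but pairing is incomplete")
        case_by_pair = {
            study.pairing[s]: s for s in study.case_samples
        }
        ctrl_by_pair = {study.pairing[s]: s for s in study.control_samples}
        if set(case_by_pair) != set(ctrl_by_pair):
            raise ValueError("pairing does not match case and control samples 1:1")
        pairs = sorted(case_by_pair)
        case = study.matrix[[case_by_pair[p] for p in pairs]].to_numpy(float)
        ctrl = study.matrix[[ctrl_by_pair[p] for p in pairs]].to_numpy(float)
        with np.errstate(all="ignore"):
            t, p = stats.ttest_rel(case, ctrl, axis=1)
    else:
        with np.errstate(all="ignore"):
            t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info(
            "%d gene(s) with undefined t-test (zero variance); p set to 1",
            int(degenerate.sum()),
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    adjusted = multipletests(p, method="fdr_bh")[1]
    adjusted = np.maximum(adjusted, p)  # BH never below the raw p
    table = pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "adjusted_p": adjusted,
            "log_fold_change": case.mean(axis=1) - ctrl.mean(axis=1),
        },
        index=study.matrix.index,
    )
    de_genes = list(table.index[table["adjusted_p"] < alpha])
    logger.info("differential expression: %d DE gene(s) at adjusted p < %g",
                len(de_genes), alpha)
    return table, de_genes
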