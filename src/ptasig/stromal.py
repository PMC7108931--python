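"""Lymph-node stromal subset enrichment.

Given expression of candidate PTA genes across LN stromal subsets
(FRC, LEC, BEC, ...), restrict candidates to highly expressed genes
(pooled top quartile), call genes enriched in a focal subset (fold
change AND adjusted p-value against every other subset), compute the
between-subset correlation matrix, and derive simple fold-change gene
sets (e.g. the DEAF1-dependent set: genes >3-fold higher in wild type
than knockout).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .setstats import GeneSet

__all__ = [
    "ExpressionMatrix",
    "pooled_quartile_filter",
    "call_frc_enriched",
    "subset_correlation",
    "derive_fold_change_set",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample linear-scale expression with a group label
    (subset or condition) for every sample."""

    values: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            raise InputError(f"duplicate gene ids: {sorted(v.index[v.index.duplicated()])[:5]}")
        if v.columns.has_duplicates:
            raise InputError(f"duplicate sample ids: {sorted(v.columns[v.columns.duplicated()])[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InputError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise InputError("expression matrix contains negative values")
        labels = pd.Series(self.sample_labels)
        unlabeled = set(v.columns) - set(labels.index)
        if unlabeled:
            raise InputError(f"samples without a label: {sorted(unlabeled)[:5]}")
        self.sample_labels = labels.loc[v.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for l in self.sample_labels:
            seen.setdefault(l)
        return tuple(seen)

    def samples_for(self, label: str) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels == label])

    def group_values(self, label: str) -> pd.DataFrame:
        cols = self.samples_for(label)
        if not cols:
            raise ConfigurationError(f"no samples carry label {label!r}")
        return self.values[cols]


def _check_candidates(matrix: ExpressionMatrix, candidates: Iterable[str]) -> list[str]:
    cand = list(dict.fromkeys(candidates))
    if not cand:
        raise InputError("candidate gene set is empty")
    missing = set(cand) - set(matrix.genes)
    if missing:
        raise InputError(f"{len(missing)} candidate genes absent from matrix, e.g. {sorted(missing)[:5]}")
    # preserve matrix row order for determinism
    in_cand = set(cand)
    return [g for g in matrix.genes if g in in_cand]


def pooled_quartile_filter(
    matrix: ExpressionMatrix,
    candidates: Iterable[str],
    quantile: float = 0.75,
) -> list[str]:
    """Keep candidates whose mean expression pooled across all samples
    is at or above the given quantile of pooled means over candidates.

    The cutoff is inclusive (>=) and computed with the linear-
    interpolation quantile definition, so when all candidates share one
    value everybody passes.  The quantile is defined relative to the
    candidate universe: re-applying the filter to its own output
    recomputes the cutoff and is therefore not idempotent across
    universes.
    """
    if not 0 < quantile < 1:
        raise ConfigurationError("quantile must be in (0, 1)")
    cand = _check_candidates(matrix, candidates)
    pooled = matrix.values.loc[cand].mean(axis=1)
    cut = float(np.quantile(pooled.to_numpy(), quantile))
    return [g for g in cand if pooled[g] >= cut]


def _welch_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample test; zero-variance rows fall back to
    exact comparison of means (p = 0 if they differ, 1 otherwise)."""
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(x[degenerate].mean(axis=1), y[degenerate].mean(axis=1))
        p[degenerate] = np.where(same, 1.0, 0.0)
    return p


def call_frc_enriched(
    matrix: ExpressionMatrix,
    candidates: Iterable[str],
    focal_subset: str = "FRC",
    fold_threshold: float = 3.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    fold_reference: str = "each",
) -> tuple[pd.DataFrame, list[str]]:
    """Call genes enriched in the focal subset versus the other subsets.

    A candidate is enriched iff, for EVERY non-focal subset, the
    pseudocounted fold change of subset means strictly exceeds
    ``fold_threshold`` ("greater than 3-fold") AND the Benjamini-
    Hochberg adjusted p of a Welch test on log2(x+1) is <= ``alpha``.
    Adjustment is performed across candidate genes within each
    focal-vs-other comparison.

    ``fold_reference="each"`` (default) compares against every other
    subset separately — equivalently the fold versus the highest other
    subset mean must pass.  ``"pooled"`` compares against the mean of
    all non-focal samples pooled.

    Returns the per-gene table and the enriched gene list (matrix row
    order).
    """
    if fold_threshold <= 1:
        raise ConfigurationError("fold_threshold must exceed 1")
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    if fold_reference not in ("each", "pooled"):
        raise ConfigurationError(f"unknown fold_reference {fold_reference!r}")
    labels = matrix.labels
    if focal_subset not in labels:
        raise ConfigurationError(f"focal subset {focal_subset!r} not among labels {labels}")
    for lab in labels:
        if len(matrix.samples_for(lab)) < 2:
            raise InputError(f"subset {lab!r} has fewer than 2 replicates; the test requires >= 2")

    cand = _check_candidates(matrix, candidates)
    sub = matrix.values.loc[cand]
    log = np.log2(sub.to_numpy(dtype=float) + 1.0)
    col_index = {s: i for i, s in enumerate(sub.columns)}

    focal_cols = [col_index[s] for s in matrix.samples_for(focal_subset)]
    focal_lin_mean = sub.iloc[:, focal_cols].mean(axis=1).to_numpy()
    others = [l for l in labels if l != focal_subset]
    if not others:
        raise ConfigurationError("at least two subsets are required")

    table = pd.DataFrame(index=pd.Index(cand, name="gene"))
    table[f"mean_{focal_subset}"] = focal_lin_mean
    pass_all = np.ones(len(cand), dtype=bool)

    if fold_reference == "pooled":
        pooled_cols = [col_index[s] for o in others for s in matrix.samples_for(o)]
        pooled_mean = sub.iloc[:, pooled_cols].mean(axis=1).to_numpy()

    for other in others:
        other_cols = [col_index[s] for s in matrix.samples_for(other)]
        other_lin_mean = sub.iloc[:, other_cols].mean(axis=1).to_numpy()
        if fold_reference == "each":
            ref_mean = other_lin_mean
        else:
            ref_mean = pooled_mean
        fold = (focal_lin_mean + pseudocount) / (ref_mean + pseudocount)
        p_raw = _welch_pvalues(log[:, focal_cols], log[:, other_cols])
        p_adj = stats.false_discovery_control(p_raw, method="bh")
        table[f"mean_{other}"] = other_lin_mean
        table[f"fold_vs_{other}"] = fold
        table[f"p_vs_{other}"] = p_raw
        table[f"q_vs_{other}"] = p_adj
        pass_all &= (fold > fold_threshold) & (p_adj <= alpha)

    table["is_enriched"] = pass_all
    enriched = [g for g, ok in zip(cand, pass_all) if ok]
    return table, enriched


def subset_correlation(matrix: ExpressionMatrix, genes: Iterable[str]) -> pd.DataFrame:
    """Pearson correlation between per-subset mean log2(x+1) profiles
    over a gene set.

    Pairs involving a zero-variance profile are reported as NaN.
    """
    gene_list = _check_candidates(matrix, genes)
    if len(gene_list) < 3:
        raise InputError("subset correlation requires at least 3 genes")
    labels = matrix.labels
    if len(labels) < 2:
        raise InputError("subset correlation requires at least 2 subsets")
    log = np.log2(matrix.values.loc[gene_list].astype(float) + 1.0)
    profiles = pd.DataFrame(
        {lab: log[matrix.samples_for(lab)].mean(axis=1) for lab in labels}
    )
    corr = profiles.corr(method="pearson")  # pandas leaves zero-variance pairs as NaN
    np.fill_diagonal(corr.values, 1.0)
    return corr


def derive_fold_change_set(
    expr_a: pd.Series,
    expr_b: pd.Series,
    fold_threshold: float = 3.0,
    pseudocount: float = 1.0,
    name: str = "fold_change_set",
) -> GeneSet:
    """Genes with strictly greater than ``fold_threshold``-fold higher
    (pseudocounted) expression in condition a than in condition b.

    This is how the DEAF1-dependent set is defined (genes >3-fold
    higher in wild-type than Deaf1-knockout stroma).
    """
    a = pd.Series(expr_a).astype(float)
    b = pd.Series(expr_b).astype(float)
    if set(a.index) != set(b.index):
        raise InputError("expr_a and expr_b must cover the same gene universe")
    b = b.loc[a.index]
    fold = (a + pseudocount) / (b + pseudocount)
    genes = [g for g in a.index if fold[g] > fold_threshold]
    return GeneSet.from_iterable(name, genes)
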