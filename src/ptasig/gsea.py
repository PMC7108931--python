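"""Gene set enrichment analysis (preranked, weighted running sum).

Implements the classic enrichment statistic: walk a gene ranking from
top to bottom, incrementing a running sum at gene-set hits by the
normalized |score|^weight and decrementing at misses by 1/(N - N_hits);
the enrichment score (ES) is the signed maximum deviation from zero.
Significance comes from a gene-set permutation null (random same-size
sets), with the normalized enrichment score (NES) defined as ES divided
by the mean |null ES| of the same sign, nominal p from the sign-matched
null tail with add-one smoothing, and FDR q estimated across a batch
from the pooled normalized null and observed NES distributions.

Gene-set permutation is the default null because the motivating designs
have 2-3 biological replicates per condition, far too few for phenotype
permutation to be meaningful.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, UnstableEstimateWarning
from .setstats import GeneSet
from .stromal import ExpressionMatrix

__all__ = [
    "RankedList",
    "EsResult",
    "GseaResult",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "exhaustive_null",
    "normalize_and_test",
    "gsea_batch",
    "results_table",
]

SIGMA_FLOOR_FRACTION = 0.2
SIGMA_FLOOR_ABSOLUTE = 0.2


@dataclass(frozen=True)
class RankedList:
    """Genes with scores, sorted descending; ties broken by gene id so
    the ordering is deterministic."""

    genes: tuple[str, ...]
    scores: np.ndarray
    metric_name: str = "score"

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if len(self.genes) != len(scores):
            raise InputError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("ranked list contains duplicate genes")
        if not np.isfinite(scores).all():
            raise InputError("ranked scores must be finite")
        if np.any(np.diff(scores) > 0):
            raise InputError("scores must be sorted descending; use RankedList.from_scores")

    @classmethod
    def from_scores(cls, scores: pd.Series | dict, metric_name: str = "score") -> "RankedList":
        s = pd.Series(scores).astype(float)
        if s.index.has_duplicates:
            raise InputError("duplicate genes in score vector")
        order = sorted(s.index, key=lambda g: (-s[g], str(g)))
        return cls(genes=tuple(str(g) for g in order), scores=s.loc[order].to_numpy(), metric_name=metric_name)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EsResult:
    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: tuple[str, ...]
    hit_indices: np.ndarray


@dataclass(frozen=True)
class GseaResult:
    set_name: str
    contrast: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_permutations: int
    seed: int
    error: str = ""


def rank_genes(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    metric: str = "signal-to-noise",
) -> RankedList:
    """Rank genes by a two-group differential metric on log2(x+1).

    - ``signal-to-noise``: (muA - muB) / (sdA + sdB), each group sd
      floored at max(0.2*|mu|, 0.2); requires >= 3 samples per group.
    - ``log2-fold-change``: log2((muA + 1)/(muB + 1)) on linear means;
      works with any group size.
    """
    label_a, label_b = contrast
    for lab in (label_a, label_b):
        if lab not in matrix.labels:
            raise ConfigurationError(f"label {lab!r} not present in matrix labels {matrix.labels}")
    a = np.log2(matrix.group_values(label_a).to_numpy(dtype=float) + 1.0)
    b = np.log2(matrix.group_values(label_b).to_numpy(dtype=float) + 1.0)
    if metric == "signal-to-noise":
        if a.shape[1] < 3 or b.shape[1] < 3:
            raise InputError(
                "signal-to-noise requires >= 3 samples per group "
                f"(got {a.shape[1]} vs {b.shape[1]}); use metric='log2-fold-change' instead"
            )
        mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
        sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR_FRACTION * np.abs(mu_a), SIGMA_FLOOR_ABSOLUTE))
        sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR_FRACTION * np.abs(mu_b), SIGMA_FLOOR_ABSOLUTE))
        scores = (mu_a - mu_b) / (sd_a + sd_b)
    elif metric == "log2-fold-change":
        mu_a = matrix.group_values(label_a).mean(axis=1).to_numpy()
        mu_b = matrix.group_values(label_b).mean(axis=1).to_numpy()
        scores = np.log2((mu_a + 1.0) / (mu_b + 1.0))
    else:
        raise ConfigurationError(f"unknown ranking metric {metric!r}")
    return RankedList.from_scores(pd.Series(scores, index=matrix.genes), metric_name=metric)


def _hit_mask(ranked: RankedList, gene_set: GeneSet) -> np.ndarray:
    members = gene_set.as_set
    return np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))


def _running_sums(scores: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    """Vectorized running sums for a (n_sets, N) boolean hit matrix."""
    n = scores.shape[0]
    k = hits.sum(axis=1, keepdims=True)
    w = np.abs(scores) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum(axis=1, keepdims=True)
    # all hit scores exactly zero: fall back to equal increments
    flat = denom == 0
    if flat.any():
        hit_w = np.where(flat & hits, 1.0, np.where(flat, 0.0, hit_w))
        denom = np.where(flat, np.maximum(k, 1), denom)
    inc = hit_w / denom
    dec = np.where(hits, 0.0, 1.0 / (n - k))
    return np.cumsum(inc - dec, axis=1)


def _es_from_running(running: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    peak = np.argmax(np.abs(running), axis=1)
    es = np.take_along_axis(running, peak[:, None], axis=1)[:, 0]
    return es, peak


def enrichment_score(ranked: RankedList, gene_set: GeneSet, weight: float = 1.0) -> EsResult:
    """Weighted Kolmogorov-Smirnov-like enrichment score of a gene set
    in a ranked list.

    ``weight=1`` is the standard weighted statistic; ``weight=0``
    reduces to the classical (equal-increment) KS form.  The leading
    edge is the set of hit genes at or before the running-sum extremum
    for a positive ES, and at or after it for a negative ES.
    """
    hits = _hit_mask(ranked, gene_set)
    k = int(hits.sum())
    n = len(ranked)
    if k == 0:
        raise InputError(f"gene set {gene_set.name!r} has no genes in the ranked list")
    if k == n:
        raise InputError(f"gene set {gene_set.name!r} covers the entire ranked list")
    running = _running_sums(ranked.scores, hits[None, :], weight)[0]
    es_arr, peak_arr = _es_from_running(running[None, :])
    es, peak = float(es_arr[0]), int(peak_arr[0])
    hit_idx = np.flatnonzero(hits)
    if es >= 0:
        leading = tuple(ranked.genes[i] for i in hit_idx if i <= peak)
    else:
        leading = tuple(ranked.genes[i] for i in hit_idx if i >= peak)
    return EsResult(es=es, running_sum=running, peak_index=peak, leading_edge=leading, hit_indices=hit_idx)


def permutation_null(
    ranked: RankedList,
    gene_set_size: int,
    n_perm: int,
    seed: int,
    weight: float = 1.0,
) -> np.ndarray:
    """Null ES sample from uniformly random gene sets of the given size
    (gene-set permutation), deterministic under the seed."""
    n = len(ranked)
    if not 0 < gene_set_size < n:
        raise InputError(f"gene_set_size must be in (0, {n}), got {gene_set_size}")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100 for a usable null; use exhaustive_null for tiny instances")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm, dtype=float)
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        hits = np.zeros((m, n), dtype=bool)
        # random k-subsets via partial argsort of uniform keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, gene_set_size - 1, axis=1)[:, :gene_set_size]
        np.put_along_axis(hits, idx, True, axis=1)
        running = _running_sums(ranked.scores, hits, weight)
        out[done : done + m], _ = _es_from_running(running)
        done += m
    return out


def exhaustive_null(ranked: RankedList, gene_set_size: int, weight: float = 1.0) -> np.ndarray:
    """ES of every possible gene set of the given size — the complete
    enumeration null, feasible only for tiny instances."""
    n = len(ranked)
    if not 0 < gene_set_size < n:
        raise InputError(f"gene_set_size must be in (0, {n})")
    combos = list(combinations(range(n), gene_set_size))
    hits = np.zeros((len(combos), n), dtype=bool)
    for row, combo in enumerate(combos):
        hits[row, list(combo)] = True
    running = _running_sums(ranked.scores, hits, weight)
    es, _ = _es_from_running(running)
    return es


def normalize_and_test(es: float, null: np.ndarray) -> tuple[float, float]:
    """NES and nominal p of an observed ES against a null ES sample.

    NES = es / mean(|null ES of the same sign|); nominal
    p = (1 + #{same-sign null with |null| >= |es|}) / (1 + #same-sign),
    so p is never exactly zero.  An ES of exactly 0 is treated as
    positive-signed.  If the null contains no value of the required
    sign, NES is NaN, p falls back to the add-one guard of 1.0 and an
    :class:`UnstableEstimateWarning` is emitted.
    """
    null = np.asarray(null, dtype=float)
    sign = 1.0 if es >= 0 else -1.0
    same = null[null * sign > 0]
    n_same = len(same)
    if n_same == 0:
        warnings.warn(
            "no null enrichment scores share the observed sign; the p-value and NES are unstable",
            UnstableEstimateWarning,
            stacklevel=2,
        )
        return float("nan"), 1.0
    nes = es / np.mean(np.abs(same))
    p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + n_same)
    return float(nes), float(p)


def _normalized_null(null: np.ndarray) -> np.ndarray:
    """Normalize every null ES by the mean |null ES| of its own sign —
    the null NES distribution used for batch FDR."""
    null = np.asarray(null, dtype=float)
    out = np.zeros_like(null)
    pos = null > 0
    neg = null < 0
    if pos.any():
        out[pos] = null[pos] / null[pos].mean()
    if neg.any():
        out[neg] = null[neg] / np.abs(null[neg]).mean()
    return out[pos | neg]


def _fdr_q(obs_nes: np.ndarray, pooled_null_nes: np.ndarray) -> np.ndarray:
    """Permutation FDR across the batch: for each observed NES, the
    sign-matched tail fraction of the pooled null NES distribution
    divided by the same tail fraction of the observed NES distribution,
    clipped to [0, 1].  A q of exactly 0 occurs only when no null value
    is as extreme."""
    obs = np.asarray(obs_nes, dtype=float)
    q = np.full(obs.shape, np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_tail = np.sum(pooled_null_nes >= nes)
            null_side = np.sum(pooled_null_nes >= 0)
            obs_tail = np.sum(obs[np.isfinite(obs)] >= nes)
            obs_side = np.sum(obs[np.isfinite(obs)] >= 0)
        else:
            null_tail = np.sum(pooled_null_nes <= nes)
            null_side = np.sum(pooled_null_nes < 0)
            obs_tail = np.sum(obs[np.isfinite(obs)] <= nes)
            obs_side = np.sum(obs[np.isfinite(obs)] < 0)
        if null_side == 0 or obs_side == 0 or obs_tail == 0:
            q[i] = 0.0 if null_tail == 0 else 1.0
            continue
        q[i] = min(1.0, (null_tail / null_side) / (obs_tail / obs_side))
    return q


def gsea_batch(
    contrasts: dict[str, RankedList] | Sequence[tuple[str, RankedList]],
    sets: Iterable[GeneSet],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Run GSEA for every (contrast, gene set) pair.

    The FDR q is computed within the batch from the pooled normalized
    null and observed NES distributions.  Invalid pairs (empty or
    full-cover intersections) are reported per pair with an ``error``
    message, and the batch continues.  Deterministic under ``seed``.
    """
    if isinstance(contrasts, dict):
        pairs_c = list(contrasts.items())
    else:
        pairs_c = list(contrasts)
    set_list = list(sets)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(len(pairs_c) * len(set_list)) >> 1]

    rows: list[dict] = []
    pooled_null: list[np.ndarray] = []
    i = 0
    for cname, ranked in pairs_c:
        for gs in set_list:
            sub_seed = child_seeds[i]
            i += 1
            row = {
                "contrast": cname,
                "set_name": gs.name,
                "seed": sub_seed,
            }
            try:
                hits = _hit_mask(ranked, gs)
                k = int(hits.sum())
                es_res = enrichment_score(ranked, gs, weight=weight)
                null = permutation_null(ranked, k, n_perm=n_perm, seed=sub_seed, weight=weight)
                nes, p = normalize_and_test(es_res.es, null)
                row.update(
                    size=k,
                    es=es_res.es,
                    nes=nes,
                    p_nominal=p,
                    leading_edge=es_res.leading_edge,
                    n_permutations=n_perm,
                    error="",
                )
                pooled_null.append(_normalized_null(null))
            except (InputError, ConfigurationError) as exc:
                row.update(
                    size=0, es=np.nan, nes=np.nan, p_nominal=np.nan,
                    leading_edge=(), n_permutations=n_perm, error=str(exc),
                )
            rows.append(row)

    obs_nes = np.array([r.get("nes", np.nan) for r in rows], dtype=float)
    null_nes = np.concatenate(pooled_null) if pooled_null else np.array([])
    qs = _fdr_q(obs_nes, null_nes)
    results = []
    for row, q in zip(rows, qs):
        results.append(
            GseaResult(
                set_name=row["set_name"],
                contrast=row["contrast"],
                size=row["size"],
                es=float(row["es"]),
                nes=float(row["nes"]),
                p_nominal=float(row["p_nominal"]),
                fdr_q=float(q),
                leading_edge=tuple(row["leading_edge"]),
                n_permutations=row["n_permutations"],
                seed=row["seed"],
                error=row["error"],
            )
        )
    return results


def results_table(results: Sequence[GseaResult]) -> pd.DataFrame:
    """Flatten GSEA results into the tabular output dialect."""
    return pd.DataFrame(
        {
            "contrast": [r.contrast for r in results],
            "set": [r.set_name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
            "error": [r.error for r in results],
        }
    )
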