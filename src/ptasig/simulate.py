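"""Synthetic expression data with planted, recorded ground truth.

Three generators emulate the three data sources of the signature
workflow:

- a gene x tissue atlas in which a chosen fraction of genes is
  tissue-restricted (expressed in only a few tissues) and the rest are
  broadly expressed;
- a gene x sample stromal-subset matrix (FRC/LEC/BEC) in which a chosen
  number of the restricted genes is additionally enriched in the first
  subset at a chosen fold;
- a two-condition experiment in which a chosen gene set is shifted down
  by a chosen log2 effect in the second condition.

All values are linear-scale and strictly positive: expression is built
on a log2 scale (gene-level baseline + planted offsets + Gaussian noise
of sd ``noise_sd_log2``) and exponentiated, i.e. log-normal
multiplicative noise.  "On" atlas entries sit a fixed ``on_offset_log2``
above the gene's background.  The per-gene on/off pattern is balanced so
that on and off entries each make up half of the atlas; the sample
median of all entries then falls inside the on/off gap and the
scale-free global-median expression call separates the two states
cleanly.

Everything is deterministic under ``SimConfig.seed``: each generator
draws from its own named substream, and the gene-role assignment
(which genes are restricted / subset-enriched / downregulated) is a
shared substream, so atlas and stromal matrices generated from the same
config plant consistent roles — every subset-enriched gene is also a
restricted (PTA) gene, as the signature recovery experiment requires.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .atlas import TissueAtlas
from .errors import ConfigurationError
from .stromal import ExpressionMatrix

__all__ = ["SimConfig", "SimTruth", "generate_tissue_atlas", "generate_stromal_matrix",
           "generate_condition_experiment", "planted_target_annotation"]

# substream tags (kept distinct so each output is independently reproducible)
_ROLES, _ATLAS, _STROMAL, _CONDITION = 101, 202, 303, 404


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the study conditions used
    throughout the test-bed (see docs/methods.md for rationale)."""

    n_genes: int = 2000
    n_tissues: int = 20
    frac_restricted: float = 0.3
    breadth_range: tuple[int, int] = (1, 4)
    on_offset_log2: float = 5.0
    n_target_tissues: int = 9

    subset_names: tuple[str, ...] = ("FRC", "LEC", "BEC")
    n_replicates_per_subset: int = 5
    n_frc_enriched: int = 30
    enrichment_fold: float = 4.0
    high_expression_offset_log2: float = 3.0

    condition_names: tuple[str, str] = ("GVHDneg", "GVHDpos")
    n_samples_per_condition: int = 3
    downregulated_set_size: int = 50
    effect_size_log2: float = 1.0

    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_tissues < 1:
            raise ConfigurationError("n_genes and n_tissues must be positive")
        if not 0 <= self.frac_restricted <= 1:
            raise ConfigurationError("frac_restricted must be in [0, 1]")
        lo, hi = self.breadth_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("breadth_range must satisfy 1 <= min <= max")
        if hi > self.n_tissues:
            raise ConfigurationError(
                f"breadth_range.max ({hi}) exceeds n_tissues ({self.n_tissues})"
            )
        if not 0 <= self.n_target_tissues <= self.n_tissues:
            raise ConfigurationError("n_target_tissues must be in [0, n_tissues]")
        if len(self.subset_names) < 1 or self.n_replicates_per_subset < 1:
            raise ConfigurationError("subset layout must be non-degenerate")
        if self.n_frc_enriched > self.n_genes:
            raise ConfigurationError("n_frc_enriched cannot exceed n_genes")
        if self.enrichment_fold <= 1:
            raise ConfigurationError("enrichment_fold must exceed 1")
        if self.n_samples_per_condition < 1:
            raise ConfigurationError("n_samples_per_condition must be positive")
        if self.downregulated_set_size > self.n_genes:
            raise ConfigurationError("downregulated_set_size cannot exceed n_genes")
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be non-negative")

    @property
    def n_subsets(self) -> int:
        return len(self.subset_names)

    @property
    def n_restricted(self) -> int:
        return int(round(self.frac_restricted * self.n_genes))

    def gene_ids(self) -> list[str]:
        width = max(6, len(str(self.n_genes)))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def tissue_names(self) -> list[str]:
        width = len(str(self.n_tissues))
        return [f"tissue_{i:0{width}d}" for i in range(1, self.n_tissues + 1)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth accompanying each generated matrix."""

    restricted_genes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    frc_enriched_genes: tuple[str, ...] = ()
    downregulated_genes: tuple[str, ...] = ()

    @property
    def restricted_breadth(self) -> dict[str, int]:
        return {g: len(t) for g, t in self.restricted_genes.items()}

    def to_dict(self) -> dict:
        return {
            "restricted_genes": {g: list(t) for g, t in self.restricted_genes.items()},
            "frc_enriched_genes": list(self.frc_enriched_genes),
            "downregulated_genes": list(self.downregulated_genes),
        }


def _rng(cfg: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def _baseline(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Gene-level log2 baselines from a clipped normal.

    Deviations are clipped at +/- min(3 sd, 0.49 on_offset) so the
    gene-to-gene baseline range stays strictly below the on/off offset;
    at zero noise the atlas on and off populations then never overlap
    and the global-median call is exact by construction.
    """
    dev = rng.normal(0.0, cfg.baseline_log2_sd, size=n)
    bound = min(3.0 * cfg.baseline_log2_sd, 0.49 * cfg.on_offset_log2)
    return cfg.baseline_log2_mean + np.clip(dev, -bound, bound)


def _gene_roles(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared role assignment: indices of restricted genes, of
    subset-enriched genes (a subset of the restricted ones when any are
    planted), and of condition-downregulated genes."""
    rng = _rng(cfg, _ROLES)
    restricted = np.sort(rng.choice(cfg.n_genes, size=cfg.n_restricted, replace=False))
    if cfg.n_frc_enriched == 0:
        enriched = np.array([], dtype=int)
    elif len(restricted) >= cfg.n_frc_enriched:
        enriched = np.sort(rng.choice(restricted, size=cfg.n_frc_enriched, replace=False))
    else:
        # stromal-only use with no (or too few) restricted genes
        enriched = np.sort(rng.choice(cfg.n_genes, size=cfg.n_frc_enriched, replace=False))
    down = np.sort(rng.choice(cfg.n_genes, size=cfg.downregulated_set_size, replace=False))
    return restricted, enriched, down


def _balanced_breadths(cfg: SimConfig, rng: np.random.Generator,
                       restricted_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-gene breadths: restricted genes uniform within
    ``breadth_range``; broad genes uniform above it, then nudged so the
    total number of "on" entries is as close to half of all entries as
    the bounds allow (this keeps the global median inside the on/off
    gap)."""
    lo, hi = cfg.breadth_range
    n = cfg.n_genes
    breadths = np.zeros(n, dtype=int)
    is_restricted = np.zeros(n, dtype=bool)
    is_restricted[restricted_idx] = True
    breadths[restricted_idx] = rng.integers(lo, hi + 1, size=len(restricted_idx))

    broad_idx = np.flatnonzero(~is_restricted)
    if len(broad_idx) == 0:
        return breadths, is_restricted
    b_lo, b_hi = min(hi + 1, cfg.n_tissues), cfg.n_tissues
    breadths[broad_idx] = rng.integers(b_lo, b_hi + 1, size=len(broad_idx))

    target_on = (n * cfg.n_tissues) // 2
    deficit = target_on - int(breadths.sum())
    step = 1 if deficit > 0 else -1
    guard = 0
    while deficit != 0 and guard < 20 * n:
        i = broad_idx[rng.integers(len(broad_idx))]
        new = breadths[i] + step
        if b_lo <= new <= b_hi:
            breadths[i] = new
            deficit -= step
        guard += 1
    return breadths, is_restricted


def generate_tissue_atlas(cfg: SimConfig) -> tuple[TissueAtlas, SimTruth]:
    """Tissue atlas with planted tissue-restricted genes.

    Restricted genes are "on" (background + ``on_offset_log2``) only in
    their planted tissue set; broad genes are on in more than
    ``breadth_range.max`` tissues.  The first ``n_target_tissues``
    tissues are designated disease targets.
    """
    rng = _rng(cfg, _ATLAS)
    restricted_idx, _, _ = _gene_roles(cfg)
    breadths, is_restricted = _balanced_breadths(cfg, rng, restricted_idx)

    on = np.zeros((cfg.n_genes, cfg.n_tissues), dtype=bool)
    for i in range(cfg.n_genes):
        cols = rng.choice(cfg.n_tissues, size=int(breadths[i]), replace=False)
        on[i, cols] = True

    baseline = _baseline(cfg, rng, cfg.n_genes)
    log2 = baseline[:, None] + cfg.on_offset_log2 * on
    if cfg.noise_sd_log2 > 0:
        log2 = log2 + rng.normal(0.0, cfg.noise_sd_log2, size=log2.shape)

    genes = cfg.gene_ids()
    tissues = cfg.tissue_names()
    values = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"), columns=tissues)
    atlas = TissueAtlas(values=values, target_tissues=tuple(tissues[: cfg.n_target_tissues]))

    truth = SimTruth(
        restricted_genes={
            genes[i]: tuple(int(j) for j in np.flatnonzero(on[i]))
            for i in restricted_idx
        }
    )
    return atlas, truth


def generate_stromal_matrix(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Stromal-subset matrix with genes planted as enriched in the
    first subset.

    Planted genes carry (i) a ``high_expression_offset_log2`` baseline
    boost in every subset, emulating the high stromal expression of the
    real signature genes (they must survive a pooled top-quartile
    filter), and (ii) an ``enrichment_fold``-times higher mean in the
    first subset than in every other subset.
    """
    if cfg.n_subsets < 2:
        raise ConfigurationError("generate_stromal_matrix requires >= 2 subsets")
    if cfg.n_replicates_per_subset < 2:
        raise ConfigurationError("generate_stromal_matrix requires >= 2 replicates per subset")
    rng = _rng(cfg, _STROMAL)
    _, enriched_idx, _ = _gene_roles(cfg)

    baseline = _baseline(cfg, rng, cfg.n_genes)
    baseline[enriched_idx] += cfg.high_expression_offset_log2

    n_rep = cfg.n_replicates_per_subset
    sample_names, labels, mean_cols = [], [], []
    for s_i, subset in enumerate(cfg.subset_names):
        gene_mean = baseline.copy()
        if s_i == 0:
            gene_mean[enriched_idx] += np.log2(cfg.enrichment_fold)
        for r in range(1, n_rep + 1):
            sample_names.append(f"{subset}_{r}")
            labels.append(subset)
            mean_cols.append(gene_mean)
    log2 = np.stack(mean_cols, axis=1)
    if cfg.noise_sd_log2 > 0:
        log2 = log2 + rng.normal(0.0, cfg.noise_sd_log2, size=log2.shape)

    genes = cfg.gene_ids()
    values = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"), columns=sample_names)
    matrix = ExpressionMatrix(values=values, sample_labels=pd.Series(labels, index=sample_names))
    truth = SimTruth(frc_enriched_genes=tuple(genes[i] for i in enriched_idx))
    return matrix, truth


def generate_condition_experiment(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-condition experiment in which the planted gene set is shifted
    down by ``effect_size_log2`` in the second condition."""
    rng = _rng(cfg, _CONDITION)
    _, _, down_idx = _gene_roles(cfg)

    baseline = _baseline(cfg, rng, cfg.n_genes)
    cond_a, cond_b = cfg.condition_names
    n = cfg.n_samples_per_condition
    mean_a = baseline
    mean_b = baseline.copy()
    mean_b[down_idx] -= cfg.effect_size_log2

    sample_names = [f"{cond_a}_{r}" for r in range(1, n + 1)] + [f"{cond_b}_{r}" for r in range(1, n + 1)]
    labels = [cond_a] * n + [cond_b] * n
    log2 = np.concatenate(
        [np.repeat(mean_a[:, None], n, axis=1), np.repeat(mean_b[:, None], n, axis=1)], axis=1
    )
    if cfg.noise_sd_log2 > 0:
        log2 = log2 + rng.normal(0.0, cfg.noise_sd_log2, size=log2.shape)

    genes = cfg.gene_ids()
    values = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"), columns=sample_names)
    matrix = ExpressionMatrix(values=values, sample_labels=pd.Series(labels, index=sample_names))
    truth = SimTruth(downregulated_genes=tuple(genes[i] for i in down_idx))
    return matrix, truth


def planted_target_annotation(
    n_focal: int,
    n_pool: int,
    focal_rate: float,
    pool_rate: float,
    seed: int,
):
    """Construct a synthetic PTA annotation with a planted target-tissue
    excess in the focal set, for power and calibration experiments on
    the tissue-representation test.

    Returns ``(annotation, focal_set, pool_set)`` where the annotation
    is a minimal object exposing ``in_target_tissue`` (gene -> bool):
    focal genes are target-tissue members with probability
    ``focal_rate`` and pool genes with probability ``pool_rate``.
    """
    from .setstats import GeneSet

    rng = np.random.default_rng(seed)
    focal_genes = [f"focal{i:05d}" for i in range(n_focal)]
    pool_genes = [f"pool{i:05d}" for i in range(n_pool)]
    flags = {g: bool(rng.random() < focal_rate) for g in focal_genes}
    flags.update({g: bool(rng.random() < pool_rate) for g in pool_genes})

    class _Annotation:
        in_target_tissue = flags

    return _Annotation(), GeneSet.from_iterable("focal", focal_genes), GeneSet.from_iterable("pool", pool_genes)
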