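"""Set-level statistics: Fisher's exact test against a random control
set, and hypergeometric overlap between two gene sets.

These back two analyses of the signature workflow: (i) asking whether a
focal gene set (e.g. the FRC-enriched PTA signature) is over-represented
in chronic-GVHD target tissues relative to a seeded random draw of
non-enriched PTAs, and (ii) asking whether two gene sets (e.g. the FRC
signature and a set of mTEC-repressed PTAs) share more members than
expected in a common gene universe.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .errors import ConfigurationError, DegenerateTableError, InputError

__all__ = [
    "GeneSet",
    "ContingencyResult",
    "OverlapResult",
    "TissueRepresentationResult",
    "fisher_exact_2x2",
    "tissue_representation_test",
    "hypergeometric_overlap",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers.

    Member order is preserved (it matters for GMT round-trips) but
    membership semantics are set-like.
    """

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise InputError(f"gene set {self.name!r} contains duplicates: {dupes[:5]}")

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(str(g))
        return cls(name=name, genes=tuple(seen), description=description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.as_set

    @property
    def as_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 table (a, b, c, d), its conditional-MLE odds ratio and the
    two-sided Fisher exact p-value (minimum-likelihood convention).

    The odds ratio is computed lazily on first access (the conditional
    MLE requires a root-finding pass)."""

    a: int
    b: int
    c: int
    d: int
    p_two_sided: float

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @cached_property
    def odds_ratio(self) -> float:
        return float(odds_ratio([[self.a, self.b], [self.c, self.d]], kind="conditional").statistic)


@dataclass(frozen=True)
class OverlapResult:
    observed: int
    expected: float
    fold_over_expected: float
    p_upper: float
    universe_size: int
    size_a: int
    size_b: int


@dataclass(frozen=True)
class TissueRepresentationResult:
    contingency: ContingencyResult
    control_set: GeneSet
    seed: int
    p_draws: tuple[float, ...] = field(default_factory=tuple)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    The two-sided p-value follows the minimum-likelihood convention: the
    sum of the probabilities of all tables (with the same margins) no
    more likely than the observed one.  The reported odds ratio is the
    conditional maximum-likelihood estimate.

    Raises :class:`DegenerateTableError` if any row or column margin is
    zero, in which case the conditional distribution is a point mass and
    the test is uninformative.
    """
    counts = (a, b, c, d)
    for x in counts:
        if not float(x).is_integer() or x < 0:
            raise InputError(f"contingency counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(
            f"table {((a, b), (c, d))} has a zero margin; Fisher's exact test is degenerate"
        )
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(a=a, b=b, c=c, d=d, p_two_sided=float(res.pvalue))


def tissue_representation_test(
    focal: GeneSet,
    control_pool: GeneSet,
    annotation,
    seed: int,
    n_draws: int = 1,
) -> TissueRepresentationResult:
    """Test whether the focal set is enriched for target-tissue genes
    against a random, size-matched control set.

    A control set of ``len(focal)`` genes is drawn uniformly without
    replacement from ``control_pool`` (which must be disjoint from the
    focal set), and the 2x2 table of target-tissue membership versus set
    membership is evaluated with :func:`fisher_exact_2x2`.

    ``annotation`` is a :class:`~ptasig.atlas.PtaAnnotation` (or any
    object with an ``in_target_tissue`` mapping gene -> bool covering
    focal and pool genes).

    ``n_draws > 1`` switches to a repeated-draw mode: the draw whose
    p-value is the median over ``n_draws`` independent control draws is
    reported, and all per-draw p-values are returned.
    """
    flags = annotation.in_target_tissue
    focal_genes = focal.as_set
    pool_genes = control_pool.as_set
    if focal_genes & pool_genes:
        raise InputError("control pool overlaps the focal set; they must be disjoint")
    if len(pool_genes) < len(focal_genes):
        raise InputError(
            f"control pool ({len(pool_genes)} genes) is smaller than the focal set ({len(focal_genes)})"
        )
    missing = (focal_genes | pool_genes) - set(flags.keys())
    if missing:
        raise InputError(f"{len(missing)} genes lack annotation, e.g. {sorted(missing)[:5]}")
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")

    a = int(sum(bool(flags[g]) for g in focal_genes))
    b = len(focal_genes) - a
    pool_sorted = sorted(pool_genes)

    def one_draw(draw_seed: int) -> tuple[ContingencyResult, GeneSet]:
        rng = np.random.default_rng(draw_seed)
        picked = rng.choice(len(pool_sorted), size=len(focal_genes), replace=False)
        control = [pool_sorted[i] for i in sorted(picked)]
        c = int(sum(bool(flags[g]) for g in control))
        d = len(control) - c
        return fisher_exact_2x2(a, b, c, d), GeneSet.from_iterable("random_control", control)

    if n_draws == 1:
        contingency, control = one_draw(seed)
        return TissueRepresentationResult(
            contingency=contingency, control_set=control, seed=seed, p_draws=(contingency.p_two_sided,)
        )
    draws = [one_draw(int(s)) for s in np.random.SeedSequence(seed).generate_state(n_draws) >> 1]
    ps = [r.p_two_sided for r, _ in draws]
    median_idx = int(np.argsort(ps, kind="stable")[len(ps) // 2])
    contingency, control = draws[median_idx]
    return TissueRepresentationResult(
        contingency=contingency, control_set=control, seed=seed, p_draws=tuple(ps)
    )


def hypergeometric_overlap(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene
    sets drawn from a common universe.

    ``expected = |A||B|/|U|``; ``p_upper = P(X >= observed)`` with X
    hypergeometric(|U|, |A|, |B|).  The upper tail is used because the
    question is enrichment (more overlap than chance).
    """
    u = universe.as_set
    a = set_a.as_set
    b = set_b.as_set
    if not a <= u:
        raise InputError(f"set {set_a.name!r} is not contained in the universe ({len(a - u)} genes outside)")
    if not b <= u:
        raise InputError(f"set {set_b.name!r} is not contained in the universe ({len(b - u)} genes outside)")
    if len(a) == 0 or len(b) == 0 or len(u) == 0:
        raise InputError("sets and universe must be non-empty")
    observed = len(a & b)
    expected = len(a) * len(b) / len(u)
    fold = observed / expected if expected > 0 else math.nan
    p_upper = float(stats.hypergeom.sf(observed - 1, len(u), len(a), len(b)))
    return OverlapResult(
        observed=observed,
        expected=expected,
        fold_over_expected=fold,
        p_upper=min(1.0, p_upper),
        universe_size=len(u),
        size_a=len(a),
        size_b=len(b),
    )
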