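"""PTA classification from a tissue expression atlas.

A peripheral tissue-restricted antigen (PTA) gene is one called
"expressed" in only a small number of tissues — here, fewer than 5 by
default.  This module turns a gene x tissue atlas into per-gene
expression calls, tissue breadths, PTA flags and target-tissue
membership (whether a gene is expressed in at least one of the tissues
affected by chronic GVHD).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "DEFAULT_TARGET_TISSUES",
    "TissueAtlas",
    "PtaAnnotation",
    "call_expression",
    "count_expressed_tissues",
    "classify_pta",
    "flag_target_tissues",
    "annotate_atlas",
]

#: Chronic-GVHD target tissues (deduplicated, user-overridable).
DEFAULT_TARGET_TISSUES: tuple[str, ...] = (
    "skin epidermis",
    "cornea",
    "lacrimal gland",
    "gut",
    "liver",
    "salivary gland",
    "tongue epidermis",
    "lung",
    "skeletal muscle",
)


def _dedupe(names: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for n in names:
        seen.setdefault(str(n))
    return tuple(seen)


@dataclass
class TissueAtlas:
    """Gene x tissue expression table with a designated subset of
    disease target tissues.

    ``values``: non-negative, finite, linear-scale expression with gene
    ids as index and tissue names as columns.
    """

    values: pd.DataFrame
    target_tissues: tuple[str, ...] = ()

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            raise InputError(f"duplicate gene ids in atlas: {sorted(v.index[v.index.duplicated()])[:5]}")
        if v.columns.has_duplicates:
            raise InputError(f"duplicate tissue names in atlas: {sorted(v.columns[v.columns.duplicated()])[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InputError("atlas contains non-finite values")
        if (arr < 0).any():
            raise InputError("atlas contains negative values")
        self.target_tissues = _dedupe(self.target_tissues)
        unknown = set(self.target_tissues) - set(v.columns)
        if unknown:
            raise ConfigurationError(f"target tissues not present in atlas: {sorted(unknown)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns


@dataclass
class PtaAnnotation:
    """Per-gene annotation: breadth, PTA status, expressed tissues and
    target-tissue membership.

    Backed by a DataFrame (``frame``) with columns ``breadth`` (int),
    ``is_pta`` (bool), ``expressed_tissues`` (tuple of tissue names) and
    ``in_target_tissue`` (bool), indexed by gene id.
    """

    frame: pd.DataFrame
    breadth_threshold: int = 5
    target_tissues: tuple[str, ...] = ()

    def __post_init__(self):
        required = {"breadth", "is_pta", "expressed_tissues", "in_target_tissue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"annotation frame lacks columns: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.frame.index

    @property
    def breadth(self) -> pd.Series:
        return self.frame["breadth"]

    @property
    def is_pta(self) -> pd.Series:
        return self.frame["is_pta"]

    @property
    def in_target_tissue(self) -> dict:
        return self.frame["in_target_tissue"].to_dict()

    @property
    def pta_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["is_pta"]])


def call_expression(
    atlas: TissueAtlas,
    rule: str = "global-median",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Binary expressed/not-expressed calls for every atlas entry.

    Two rules are supported:

    - ``"global-median"`` (default): a gene is called expressed in a
      tissue when its value exceeds the median of *all* atlas entries.
      Scale-free; appropriate when on/off expression is bimodal.
    - ``"absolute"``: value > ``threshold``.
    """
    if rule == "global-median":
        cut = float(np.median(atlas.values.to_numpy(dtype=float)))
    elif rule == "absolute":
        if threshold is None:
            raise ConfigurationError("the 'absolute' rule requires a threshold")
        cut = float(threshold)
    else:
        raise ConfigurationError(f"unknown expression-call rule {rule!r}")
    return atlas.values > cut


def count_expressed_tissues(calls: pd.DataFrame) -> pd.Series:
    """Per-gene breadth: the number of tissues called expressed."""
    if not calls.dtypes.map(lambda d: d == bool).all():
        raise InputError("expression calls must be boolean")
    return calls.sum(axis=1).astype(int)


def classify_pta(breadths: pd.Series, breadth_threshold: int = 5) -> pd.Series:
    """PTA flag per gene: expressed in at least one but fewer than
    ``breadth_threshold`` tissues.

    The threshold is strict ("fewer than 5"): breadth 4 passes, breadth
    5 does not.  Breadth-0 genes are excluded — a never-expressed gene
    is not a tissue-restricted antigen.
    """
    if breadth_threshold < 2:
        raise ConfigurationError("breadth_threshold must be >= 2")
    b = pd.Series(breadths).astype(int)
    if (b < 0).any():
        raise InputError("breadths must be non-negative")
    return (b >= 1) & (b < breadth_threshold)


def flag_target_tissues(calls: pd.DataFrame, atlas: TissueAtlas) -> pd.Series:
    """True for genes called expressed in at least one target tissue."""
    unknown = set(atlas.target_tissues) - set(calls.columns)
    if unknown:
        raise ConfigurationError(f"target tissues absent from the call matrix: {sorted(unknown)}")
    if not atlas.target_tissues:
        return pd.Series(False, index=calls.index)
    return calls[list(atlas.target_tissues)].any(axis=1)


def annotate_atlas(
    atlas: TissueAtlas,
    rule: str = "global-median",
    threshold: float | None = None,
    breadth_threshold: int = 5,
) -> PtaAnnotation:
    """Full annotation pass: expression calls -> breadth -> PTA flag ->
    target-tissue membership."""
    calls = call_expression(atlas, rule=rule, threshold=threshold)
    breadth = count_expressed_tissues(calls)
    is_pta = classify_pta(breadth, breadth_threshold=breadth_threshold)
    in_target = flag_target_tissues(calls, atlas)
    tissues = np.asarray(calls.columns)
    expressed = [tuple(tissues[row]) for row in calls.to_numpy(dtype=bool)]
    frame = pd.DataFrame(
        {
            "breadth": breadth,
            "is_pta": is_pta,
            "expressed_tissues": expressed,
            "in_target_tissue": in_target,
        },
        index=calls.index,
    )
    return PtaAnnotation(frame=frame, breadth_threshold=breadth_threshold, target_tissues=atlas.target_tissues)
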