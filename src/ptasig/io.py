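"""Readers and writers for the plain-text formats of the workflow.

TSV matrices (first column gene id, header row of sample/tissue names),
two-column sample-label TSVs, GMT gene-set files, RNK ranked lists,
plain-text tissue lists and JSON manifests.  All readers validate
structure and report the offending file (and line, where meaningful);
``write`` then ``read`` is the identity on the data model.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .setstats import GeneSet

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv",
    "read_labels_tsv", "write_labels_tsv",
    "read_gmt", "write_gmt",
    "read_rnk", "write_rnk",
    "read_tissue_list", "write_tissue_list",
    "read_json", "write_json", "file_sha256",
]


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Numeric gene x column matrix from TSV; rejects duplicate ids,
    ragged rows and non-finite tokens."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty or has no parsable header")
    except FileNotFoundError:
        raise InputError(f"{path}: no such file")
    if df.shape[1] == 0:
        raise InputError(f"{path}: no data columns found")
    if df.index.has_duplicates:
        dupe = df.index[df.index.duplicated()][0]
        line = int(np.flatnonzero(df.index == dupe)[-1]) + 2  # +1 header, +1 1-based
        raise InputError(f"{path}:{line}: duplicate gene id {dupe!r}")
    if df.columns.has_duplicates:
        raise InputError(f"{path}: duplicate column names")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric token in matrix body ({exc})")
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        bad_row = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0])
        raise InputError(f"{path}:{bad_row + 2}: non-finite value in row {values.index[bad_row]!r}")
    values.index.name = "gene"
    return values


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = df.index.name or "gene"
    df.to_csv(path, sep="\t")


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Two-column sample-id / label TSV (no header required)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty")
    if df.shape[1] != 2:
        raise InputError(f"{path}: expected exactly 2 columns (sample, label), got {df.shape[1]}")
    if df[0].duplicated().any():
        dupe = df[0][df[0].duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate sample id {dupe!r}")
    return pd.Series(df[1].to_numpy(), index=df[0].to_numpy())


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": labels.index, "label": labels.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT gene sets: name, description, members, tab-separated.

    Duplicate members within a set are removed with a warning;
    duplicate set names are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    try:
        lines = path.read_text().splitlines()
    except FileNotFoundError:
        raise InputError(f"{path}: no such file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise InputError(f"{path}:{lineno}: GMT line needs at least a name and one field")
        name, description, members = fields[0], fields[1], fields[2:]
        if name in names:
            raise InputError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        names.add(name)
        unique = list(dict.fromkeys(m for m in members if m))
        if len(unique) != len([m for m in members if m]):
            warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} were removed")
        sets.append(GeneSet(name=name, genes=tuple(unique), description=description))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    """Two-column gene/score ranked-list file; file order is preserved
    (ranking operations re-sort with their own documented tie-break)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: file is empty")
    if df.shape[1] != 2:
        raise InputError(f"{path}: expected 2 columns (gene, score), got {df.shape[1]}")
    if df[0].duplicated().any():
        dupe = df[0][df[0].duplicated()].iloc[0]
        raise InputError(f"{path}: duplicate gene {dupe!r}")
    try:
        scores = df[1].astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric score ({exc})")
    if not np.isfinite(scores.to_numpy()).all():
        raise InputError(f"{path}: non-finite score")
    return pd.Series(scores.to_numpy(), index=df[0].to_numpy())


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene": scores.index, "score": scores.to_numpy()}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tissue_list(path: str | Path) -> tuple[str, ...]:
    """One tissue name per line; duplicates removed, order preserved."""
    path = Path(path)
    try:
        lines = [l.strip() for l in path.read_text().splitlines()]
    except FileNotFoundError:
        raise InputError(f"{path}: no such file")
    return tuple(dict.fromkeys(l for l in lines if l))


def write_tissue_list(tissues: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(dict.fromkeys(tissues)) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray, tuple, set)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
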