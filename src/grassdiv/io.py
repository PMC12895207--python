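"""Readers and writers for the four input files and tidy outputs.

All tables are UTF-8 CSV with a header row; trees are Newick.  Readers
return validated domain objects, writers round-trip to full float
precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import (
    CommunityMatrix,
    LandUseDesign,
    PhylogeneticTree,
    TraitTable,
    ValidationError,
)

logger = logging.getLogger("grassdiv")


def read_community(path: str | Path) -> CommunityMatrix:
    """Read a plot x species abundance CSV (first column = plot ids)."""
    df = pd.read_csv(path, index_col=0)
    comm = CommunityMatrix(df)
    empty = comm.empty_species
    if empty:
        logger.warning("community %s: %d all-zero species columns retained", path, len(empty))
    return comm


def write_community(comm: CommunityMatrix, path: str | Path) -> None:
    comm.abundance.to_csv(path, index_label="plot")


def read_traits(path: str | Path, log_transform: bool = False) -> TraitTable:
    """Read a species x trait CSV.

    With ``log_transform`` the file holds raw trait values and is
    natural-log transformed on read; non-positive raw values are rejected
    (they have no logarithm and indicate a data error).  Without the flag
    the file is taken to be pre-logged and passes through unchanged.
    """
    df = pd.read_csv(path, index_col=0)
    if log_transform:
        vals = df.to_numpy(dtype=float)
        bad = (vals <= 0) & ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive raw trait value at species {df.index[i]!r}, "
                f"trait {df.columns[j]!r}; cannot log-transform"
            )
        df = np.log(df)
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.values.to_csv(path, index_label="species")


def read_tree(path: str | Path) -> PhylogeneticTree:
    """Read a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"cannot parse Newick file {path}: {exc}") from exc
    tree.is_rooted = True
    return PhylogeneticTree(tree)


def write_tree(ptree: PhylogeneticTree, path: str | Path) -> None:
    Path(path).write_text(ptree.as_newick() + "\n")


def read_design(path: str | Path) -> LandUseDesign:
    """Read a plot -> land-use CSV with columns ``plot, category``."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("design table needs columns: plot, category")
    series = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="category")
    return LandUseDesign(series)


def write_design(design: LandUseDesign, path: str | Path) -> None:
    out = design.categories.rename_axis("plot").reset_index()
    out.to_csv(path, index=False)
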