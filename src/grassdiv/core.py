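"""Core domain types for grassland diversity analysis.

The analysis chain operates on four aligned inputs: a plot x species
abundance matrix (vegetation relevés), a species x trait table on the
natural-log scale, a rooted (preferably ultrametric, time-calibrated)
phylogeny, and a plot -> land-use design table.  The types here wrap
pandas / dendropy objects, enforce the invariants the downstream metrics
rely on, and carry small utilities (grazing-load formula, taxonomic trait
imputation) that belong to the data layer rather than to any metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("grassdiv")

#: The six functional traits of the default analysis: specific leaf area
#: (SLA, mm2/mg), leaf dry matter content (LDMC, mg/g), leaf nitrogen
#: content (LNC, mg/g), leaf area (LA, mm2), seed mass (SM, mg) and plant
#: height (PH, cm); all stored natural-log transformed.
DEFAULT_TRAITS = ("SLA", "LDMC", "LNC", "LA", "SM", "PH")

#: Land-use categories: three grazing pressures plus two abandonment ages
#: (recent < 10 y, past > 10 y since grazing ceased).
LAND_USE_CATEGORIES = (
    "intensive",
    "intermediate",
    "extensive",
    "recent_abandonment",
    "past_abandonment",
)


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class CommunityMatrix:
    """Plot x species abundance matrix (cover or count units).

    Rows are plots (relevés), columns species.  Relative abundances
    p_i = abundance_i / row sum are what every abundance-weighted metric
    consumes.  All-zero species columns are retained (to keep alignment
    with trait and tree inputs) but flagged in ``empty_species``.
    """

    abundance: pd.DataFrame

    def __post_init__(self) -> None:
        ab = self.abundance
        _check_unique(ab.index, "plot ids")
        _check_unique(ab.columns, "species ids")
        vals = ab.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite abundance entries")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at plot {ab.index[i]!r}, species {ab.columns[j]!r}"
            )
        empty_plots = ab.index[vals.sum(axis=1) <= 0].tolist()
        if empty_plots:
            raise ValidationError(f"plots with no positive abundance: {empty_plots[:5]}")
        self.abundance = ab.astype(float)

    @property
    def plot_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list:
        return list(self.abundance.columns)

    @property
    def empty_species(self) -> list:
        """Species columns that are zero in every plot."""
        sums = self.abundance.sum(axis=0)
        return list(sums.index[sums <= 0])

    def relative(self) -> pd.DataFrame:
        """Row-normalized abundances (each row sums to 1)."""
        ab = self.abundance
        return ab.div(ab.sum(axis=1), axis=0)

    def subset_species(self, species: list) -> "CommunityMatrix":
        return CommunityMatrix(self.abundance.loc[:, list(species)])


@dataclass
class TraitTable:
    """Species x trait matrix on the natural-log scale.

    ``values`` may hold NaN before imputation; ``provenance`` records, per
    cell, whether a value was observed or filled from the genus / family /
    global mean.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "species ids")
        _check_unique(self.values.columns, "trait names")
        self.values = self.values.astype(float)
        if self.provenance is None:
            prov = pd.DataFrame("observed", index=self.values.index, columns=self.values.columns)
            prov = prov.where(self.values.notna(), "missing")
            self.provenance = prov

    @property
    def species_ids(self) -> list:
        return list(self.values.index)

    @property
    def trait_names(self) -> list:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def complete_for(self, species: list) -> bool:
        return not self.values.loc[list(species)].isna().to_numpy().any()

    def subset(self, species: list) -> "TraitTable":
        sp = list(species)
        return TraitTable(self.values.loc[sp].copy(), self.provenance.loc[sp].copy())


def genus_of(label: str) -> str:
    """First underscore/whitespace-delimited token of a binomial label."""
    return str(label).replace("_", " ").split()[0]


@dataclass
class PhylogeneticTree:
    """Rooted phylogeny with branch lengths in time units.

    Wraps a :class:`dendropy.Tree`.  Tip labels are species ids
    (``Genus_species``); a genus index is built from the first token of
    each label so that missing species can be grafted to congeners.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        leaves = self.tree.leaf_node_iter()
        labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise ValidationError("tree has an unlabeled tip")
            labels.append(lf.taxon.label)
        _check_unique(labels, "tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    f"missing branch length above node {edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise ValidationError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def genus_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for lab in self.tip_labels:
            idx.setdefault(genus_of(lab), []).append(lab)
        return idx

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        depths: dict[str, float] = {}
        node_depth = {self.tree.seed_node: 0.0}
        for nd in self.tree.preorder_node_iter():
            if nd is self.tree.seed_node:
                continue
            node_depth[nd] = node_depth[nd.parent_node] + (nd.edge.length or 0.0)
            if nd.is_leaf():
                depths[nd.taxon.label] = node_depth[nd]
        return depths

    def ultrametricity_deviation(self) -> float:
        """Max minus min root-to-tip depth (0 for a perfectly ultrametric tree)."""
        d = list(self.tip_depths().values())
        return float(max(d) - min(d))

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = list(self.tip_depths().values())
        scale = max(d) if max(d) > 0 else 1.0
        return (max(d) - min(d)) / scale <= rel_tol

    def clone(self) -> "PhylogeneticTree":
        return PhylogeneticTree(self.tree.clone(depth=1))

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity among species.

    ``kind`` distinguishes phylogenetic divergence (time units) from
    functional Gower dissimilarity (bounded in [0, 1]).
    """

    ids: list
    matrix: np.ndarray
    kind: str = "phylogenetic-divergence"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal not zero")
        if (m < -1e-12).any():
            raise ValidationError("negative distances")
        if self.kind == "functional-gower" and (m > 1 + 1e-9).any():
            raise ValidationError("Gower distances must lie in [0, 1]")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def subset(self, species: list) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in species]
        return DistanceMatrix(list(species), self.matrix[np.ix_(idx, idx)], self.kind)


@dataclass
class LandUseDesign:
    """Plot -> land-use category assignment."""

    categories: pd.Series  # index: plot id, values: category name

    def __post_init__(self) -> None:
        _check_unique(self.categories.index, "plot ids in design")
        bad = set(self.categories.unique()) - set(LAND_USE_CATEGORIES)
        if bad:
            raise ValidationError(
                f"unknown land-use categories {sorted(bad)}; expected one of {LAND_USE_CATEGORIES}"
            )
        self.categories = self.categories.astype(str)

    def check_covers(self, comm: CommunityMatrix) -> None:
        missing = set(comm.plot_ids) - set(self.categories.index)
        if missing:
            raise ValidationError(f"plots without a land-use category: {sorted(missing)[:5]}")

    def plots_in(self, category: str) -> list:
        return list(self.categories.index[self.categories == category])


@dataclass
class GrazingLoadParams:
    """Parameters of the optimal-cattle-load formula.

    SP: standardized grass production of the pasture (kg dry matter / ha);
    kUt: utilization coefficient, the % of standing phytomass actually
    ingested over a season; I_d: daily ingestion per head (kg/day);
    A: pasture area (ha); T: grazing-season length (days).
    """

    SP: float
    kUt: float
    I_d: float
    A: float
    T: float

    def __post_init__(self) -> None:
        for name in ("SP", "kUt", "I_d", "A", "T"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.kUt > 100:
            raise ValidationError("kUt is a percentage in (0, 100]")


def optimal_cattle_load(params: GrazingLoadParams) -> float:
    """Optimal stocking rate OL = (SP * A * kUt/100) / (I_d * T), in head.

    The numerator is the usable phytomass of the pasture over the season;
    the denominator the seasonal intake of one animal.  Used to classify
    pastures into grazing-pressure categories.
    """
    return (params.SP * params.A * params.kUt / 100.0) / (params.I_d * params.T)


def impute_traits(
    traits: TraitTable,
    taxonomy: dict[str, tuple[str, str]] | None = None,
) -> TraitTable:
    """Fill missing trait values by taxonomic means: genus, then family, then global.

    ``taxonomy`` maps species id -> (genus, family).  When omitted, the
    genus is parsed from the binomial species label and the family tier is
    unavailable.  Observed cells are never altered; provenance records the
    tier each filled value came from.
    """
    vals = traits.values.copy()
    prov = traits.provenance.copy()
    species = list(vals.index)
    if taxonomy is None:
        genus = {s: genus_of(s) for s in species}
        family = {}
    else:
        genus = {s: taxonomy[s][0] if s in taxonomy else genus_of(s) for s in species}
        family = {s: taxonomy[s][1] for s in species if s in taxonomy}

    genus_series = pd.Series([genus[s] for s in species], index=vals.index)
    family_series = pd.Series([family.get(s) for s in species], index=vals.index)

    for trait in vals.columns:
        col = vals[trait]
        if col.notna().sum() == 0:
            raise ValidationError(f"trait {trait!r} has no observed values; cannot impute")
        genus_means = col.groupby(genus_series).mean()
        family_means = col.groupby(family_series).mean() if family else pd.Series(dtype=float)
        global_mean = float(col.mean())
        for sp in col.index[col.isna()]:
            g = genus_series[sp]
            f = family_series[sp]
            if g in genus_means.index and not np.isnan(genus_means[g]):
                vals.loc[sp, trait] = genus_means[g]
                prov.loc[sp, trait] = "genus_mean"
            elif f is not None and f in family_means.index and not np.isnan(family_means[f]):
                vals.loc[sp, trait] = family_means[f]
                prov.loc[sp, trait] = "family_mean"
            else:
                vals.loc[sp, trait] = global_mean
                prov.loc[sp, trait] = "global_mean"
    return TraitTable(vals, prov)


@dataclass
class DiversityProfile:
    """Tidy per-plot diversity table: D, raoD (mean/SD over topologies), raoQ, CWMs."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def per_category_mean(self, column: str) -> pd.Series:
        return self.table.groupby("category")[column].mean()
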