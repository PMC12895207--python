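"""Per-plot taxonomic, phylogenetic and functional diversity, and CWMs.

All metrics are abundance-weighted forms of one quantity: the expected
dissimilarity between two individuals drawn at random from the plot.
With species-identity dissimilarity (0/1) this is the Gini–Simpson index
D = 1 - sum(p_i^2); with divergence time it is Rao's phylogenetic
quadratic entropy (raoD); with functional trait distance it is Rao's
functional quadratic entropy (raoQ).  Community-weighted means (CWMs)
summarize each trait as sum(p_i * x_i).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import (
    CommunityMatrix,
    DistanceMatrix,
    DiversityProfile,
    LandUseDesign,
    TraitTable,
    ValidationError,
)
from .phylo import GraftedTreeSet, divergence_matrix

logger = logging.getLogger("grassdiv")


def simpson_d(abundances: np.ndarray, variant: str = "gini") -> float:
    """Simpson diversity of one plot.

    ``gini`` (default): D = 1 - sum(p_i^2), the probability that two
    random individuals belong to different species, in [0, 1).
    ``inverse``: 1 / sum(p_i^2).
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValidationError("negative abundances")
    total = a.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = a / total
    ss = float(p @ p)
    if variant == "gini":
        return 1.0 - ss
    if variant == "inverse":
        return 1.0 / ss
    raise ValueError(f"unknown Simpson variant {variant!r}")


def rao_q(abundances: np.ndarray, d: DistanceMatrix | np.ndarray) -> float:
    """Rao's quadratic entropy Q = sum_ij p_i p_j d_ij.

    The expected dissimilarity between two individuals drawn (with
    replacement) at random from the plot.  Reduces to Gini–Simpson when
    d_ij = 1 - delta_ij.
    """
    a = np.asarray(abundances, dtype=float)
    m = d.matrix if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if len(a) != m.shape[0]:
        raise ValidationError(
            f"abundance vector length {len(a)} does not match distance matrix order {m.shape[0]}"
        )
    total = a.sum()
    if total <= 0:
        raise ValidationError("all-zero abundance vector")
    p = a / total
    return float(p @ m @ p)


def functional_distance(traits: TraitTable, metric: str = "gower") -> DistanceMatrix:
    """Pairwise functional dissimilarity among species from (log) traits.

    ``gower``: per-trait |x_i - x_j| / range, averaged over traits —
    bounded in [0, 1]; zero-range traits are excluded with a warning.
    ``euclidean_log``: Euclidean distance on the log traits as given.
    ``euclidean_z``: Euclidean distance on per-trait z-scores.
    """
    X = traits.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("traits contain missing values; impute first")
    ids = traits.species_ids

    if metric == "gower":
        ranges = X.max(axis=0) - X.min(axis=0)
        keep = ranges > 0
        if not keep.all():
            excluded = [t for t, k in zip(traits.trait_names, keep) if not k]
            logger.warning("zero-range traits excluded from Gower distance: %s", excluded)
        if not keep.any():
            # fully degenerate: all species identical
            return DistanceMatrix(ids, np.zeros((len(ids), len(ids))), "functional-gower")
        Xk = X[:, keep] / ranges[keep]
        diffs = np.abs(Xk[:, None, :] - Xk[None, :, :])
        m = diffs.mean(axis=2)
        kind = "functional-gower"
    elif metric in ("euclidean_log", "euclidean_z"):
        if metric == "euclidean_z":
            sd = X.std(axis=0, ddof=1)
            keep = sd > 0
            X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        diff = X[:, None, :] - X[None, :, :]
        m = np.sqrt((diff**2).sum(axis=2))
        kind = "functional-euclidean"
    else:
        raise ValueError(f"unknown functional distance metric {metric!r}")
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2.0
    return DistanceMatrix(ids, m, kind)


def cwm(abundances: np.ndarray, traits: TraitTable) -> pd.Series:
    """Community-weighted mean of each trait: CWM_t = sum_i p_i x_it."""
    a = np.asarray(abundances, dtype=float)
    X = traits.values
    if len(a) != len(X):
        raise ValidationError("abundance vector does not match trait table")
    present = a > 0
    if X.iloc[present].isna().to_numpy().any():
        raise ValidationError("species with positive abundance lacking trait values")
    p = a / a.sum()
    return pd.Series(p @ X.fillna(0.0).to_numpy(), index=X.columns)


def phylo_rao_over_topologies(
    community_row: pd.Series, grafted: GraftedTreeSet, convention: str = "half_patristic"
) -> tuple[float, float]:
    """Mean and SD of raoD for one plot across the grafted topologies."""
    vals = []
    species = list(community_row.index[community_row > 0])
    for ptree in grafted.trees:
        dmat = divergence_matrix(ptree, convention=convention).subset(species)
        vals.append(rao_q(community_row[species].to_numpy(), dmat))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=0))


def diversity_profile(
    comm: CommunityMatrix,
    traits: TraitTable,
    grafted: GraftedTreeSet,
    design: LandUseDesign,
    simpson_variant: str = "gini",
    functional_metric: str = "gower",
    convention: str = "half_patristic",
) -> DiversityProfile:
    """Tidy per-plot table: category, D, raoD (mean/SD over topologies), raoQ, CWMs.

    Species missing from the trees or the trait table after imputation
    are dropped (with a warning) before computing metrics; all-zero
    species columns are ignored.
    """
    design.check_covers(comm)
    tree_species = set(grafted.trees[0].tip_labels) if grafted.trees else set()
    usable = [
        s for s in comm.species_ids
        if s in tree_species and s in set(traits.species_ids)
        and not traits.values.loc[s].isna().any()
    ]
    dropped = [s for s in comm.species_ids if s not in usable]
    if dropped:
        logger.warning("dropping %d species absent from tree or traits: %s ...",
                       len(dropped), dropped[:5])
    sub = comm.subset_species(usable)
    tsub = traits.subset(usable)

    fdist = functional_distance(tsub, metric=functional_metric)
    # one divergence matrix per topology, aligned to the usable pool
    dmats = [divergence_matrix(t, convention=convention).subset(usable) for t in grafted.trees]

    rows = []
    for plot in sub.plot_ids:
        a = sub.abundance.loc[plot].to_numpy()
        D = simpson_d(a, variant=simpson_variant)
        raod_vals = np.array([rao_q(a, dm) for dm in dmats])
        raoq = rao_q(a, fdist)
        cwms = cwm(a, tsub)
        row = {
            "plot": plot,
            "category": design.categories[plot],
            "D": D,
            "raoD": float(raod_vals.mean()),
            "raoD_sd": float(raod_vals.std(ddof=0)),
            "raoQ": raoq,
        }
        for t in tsub.trait_names:
            row[f"CWM_{t}"] = float(cwms[t])
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("plot", kind="stable").reset_index(drop=True)
    return DiversityProfile(table)
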