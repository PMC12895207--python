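"""Permutation null models and standardized effect sizes (SES).

A plot's observed diversity only means "clustered" or "overdispersed"
relative to a null: here, random reassignment of phylogenetic positions
(tip shuffling) or of trait rows across the species pool actually present
in the community matrix.  SES = (observed - null mean) / null SD; negative
values indicate convergence (habitat filtering), positive values
divergence (limiting similarity).  The trait null permutes whole species
rows, so trait covariance and each trait's pool mean/variance are
preserved exactly in every randomization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import CommunityMatrix, LandUseDesign, TraitTable, ValidationError
from .diversity import functional_distance
from .phylo import GraftedTreeSet, divergence_matrix

logger = logging.getLogger("grassdiv")

SES_COLUMNS = ["plot", "metric", "observed", "null_mean", "null_sd", "ses",
               "n_randomizations", "note"]


def _rao_per_plot(P: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Rao Q for every plot at once: diag(P D P')."""
    return np.einsum("ps,st,pt->p", P, D, P, optimize=True)


def _null_rao(P: np.ndarray, D: np.ndarray, n_rand: int, rng: np.random.Generator) -> np.ndarray:
    """n_rand x n_plots matrix of Rao Q under label permutation of D."""
    S = D.shape[0]
    out = np.empty((n_rand, P.shape[0]))
    for r in range(n_rand):
        perm = rng.permutation(S)
        out[r] = _rao_per_plot(P, D[np.ix_(perm, perm)])
    return out


def _ses_frame(plots, metric: str, obs: np.ndarray, null: np.ndarray, n_rand: int) -> pd.DataFrame:
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = np.where(sd > 0, (obs - mu) / sd, np.nan)
    note = np.where(sd > 0, "", "undefined: null SD = 0")
    return pd.DataFrame({
        "plot": plots, "metric": metric, "observed": obs, "null_mean": mu,
        "null_sd": sd, "ses": ses, "n_randomizations": n_rand, "note": note,
    })


def _usable_pool(comm: CommunityMatrix, available: set) -> CommunityMatrix:
    usable = [s for s in comm.species_ids if s in available]
    if len(usable) < len(comm.species_ids):
        logger.warning("null model: %d species outside pool dropped",
                       len(comm.species_ids) - len(usable))
    return comm.subset_species(usable)


def ses_phylogenetic(
    comm: CommunityMatrix,
    grafted: GraftedTreeSet,
    n_rand: int = 999,
    seed: int | None = None,
    convention: str = "half_patristic",
) -> pd.DataFrame:
    """SES of phylogenetic Rao entropy under tip shuffling.

    The null shuffles tip labels across the phylogeny — equivalently,
    permutes rows/columns of the divergence matrix over the study species
    pool.  Computed per grafted topology, then SES is averaged across
    topologies (the per-topology spread is reported as ``ses_sd_topo``).
    """
    sub = _usable_pool(comm, set(grafted.trees[0].tip_labels))
    P = sub.relative().to_numpy()
    plots = sub.plot_ids
    rng = np.random.default_rng(seed)
    per_topo = []
    for ptree in grafted.trees:
        D = divergence_matrix(ptree, convention=convention).subset(sub.species_ids).matrix
        obs = _rao_per_plot(P, D)
        null = _null_rao(P, D, n_rand, rng)
        per_topo.append(_ses_frame(plots, "raoD_ses", obs, null, n_rand))
    stacked = pd.concat(per_topo)
    out = stacked.groupby("plot", sort=False).agg(
        observed=("observed", "mean"), null_mean=("null_mean", "mean"),
        null_sd=("null_sd", "mean"), ses=("ses", "mean"),
        ses_sd_topo=("ses", lambda s: s.std(ddof=0)),
    ).reset_index()
    out.insert(1, "metric", "raoD_ses")
    out["n_randomizations"] = n_rand
    out["note"] = ["undefined: null SD = 0" if np.isnan(v) else "" for v in out["ses"]]
    return out


def ses_functional(
    comm: CommunityMatrix,
    traits: TraitTable,
    n_rand: int = 999,
    seed: int | None = None,
    functional_metric: str = "gower",
) -> pd.DataFrame:
    """SES of functional Rao entropy under trait-row permutation.

    Permuting whole trait rows across the pool permutes the functional
    distance matrix identically (Gower ranges are pool-level and
    unchanged), so the null recomputation reduces to a label permutation
    of the distances.
    """
    sub = _usable_pool(comm, set(traits.species_ids))
    tsub = traits.subset(sub.species_ids)
    D = functional_distance(tsub, metric=functional_metric).matrix
    P = sub.relative().to_numpy()
    rng = np.random.default_rng(seed)
    obs = _rao_per_plot(P, D)
    null = _null_rao(P, D, n_rand, rng)
    return _ses_frame(sub.plot_ids, "raoQ_ses", obs, null, n_rand)


def ses_cwm(
    comm: CommunityMatrix,
    traits: TraitTable,
    n_rand: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """SES of each community-weighted mean under joint trait-row permutation.

    All traits are permuted together by species row, preserving the
    trait covariance structure of the pool in every randomization.
    Returns one row per plot x trait.
    """
    sub = _usable_pool(comm, set(traits.species_ids))
    X = traits.subset(sub.species_ids).values
    if X.isna().to_numpy().any():
        raise ValidationError("traits contain missing values; impute first")
    Xv = X.to_numpy()
    P = sub.relative().to_numpy()
    rng = np.random.default_rng(seed)
    obs = P @ Xv  # plots x traits
    S = Xv.shape[0]
    null = np.empty((n_rand,) + obs.shape)
    for r in range(n_rand):
        null[r] = P @ Xv[rng.permutation(S)]
    frames = []
    for j, trait in enumerate(X.columns):
        frames.append(_ses_frame(sub.plot_ids, f"CWM_{trait}_ses", obs[:, j], null[:, :, j], n_rand))
    return pd.concat(frames, ignore_index=True)


def one_sample_t(values) -> tuple[float, float]:
    """Classical one-sample t-test of mean == 0; returns (t, two-sided p)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValidationError("one-sample t-test needs at least 2 finite values")
    if v.std(ddof=1) == 0:
        raise ValidationError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(v, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


def summarize_ses(ses: pd.DataFrame, design: LandUseDesign) -> pd.DataFrame:
    """Per category x metric: mean SES with one-sample t-test against zero.

    Degenerate plots (undefined SES) are excluded; categories with fewer
    than 2 usable plots or zero variance report NaN statistics.
    """
    df = ses.copy()
    df["category"] = df["plot"].map(design.categories)
    rows = []
    for (cat, metric), grp in df.groupby(["category", "metric"], sort=False):
        vals = grp["ses"].to_numpy()
        vals = vals[np.isfinite(vals)]
        try:
            t, p = one_sample_t(vals)
        except ValidationError:
            t, p = np.nan, np.nan
        rows.append({"category": cat, "metric": metric, "n": len(vals),
                     "mean_ses": vals.mean() if len(vals) else np.nan,
                     "t": t, "p": p})
    return pd.DataFrame(rows)
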