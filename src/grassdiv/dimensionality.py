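"""Dimensionality of biodiversity per land-use category.

How many independent axes of information do the diversity metrics (D,
raoD, raoQ) carry within a category?  A PCA on their correlation matrix
answers this: evenly spread eigenvalues mean complementary metrics (high
dimensionality), a dominant first eigenvalue means redundancy.  Evenness
of eigenvalues (EE) quantifies the spread with Camargo's index; the
importance value (IV) of each metric aggregates component variances
weighted by the metric's squared correlation with each component, and the
Camargo evenness of the IVs summarizes how many metrics contribute.
Uncertainty in the IV evenness comes from a plot-level bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DiversityProfile, ValidationError

logger = logging.getLogger("grassdiv")

METRIC_COLUMNS = ("D", "raoD", "raoQ")


def metric_matrix(profile: DiversityProfile, category: str,
                  metrics: tuple[str, ...] = METRIC_COLUMNS) -> np.ndarray:
    """Plots x metrics matrix for one land-use category (fixed column order)."""
    tab = profile.table
    sub = tab[tab["category"] == category]
    if len(sub) == 0:
        raise ValidationError(f"no plots in category {category!r}")
    if len(sub) < 4:
        raise ValidationError(f"category {category!r} has {len(sub)} plots; need >= 4")
    M = sub.loc[:, list(metrics)].to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [m for m, s in zip(metrics, sd) if s == 0]
        raise ValidationError(f"zero-variance metric(s) in {category!r}: {bad}")
    return M


def pca_correlation(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the metric correlation matrix.

    Returns (eigenvalues desc, loadings r) where r[m, k] is the Pearson
    correlation of metric m with component k: eigenvector scaled by
    sqrt(eigenvalue), so sum_m r[m, k]^2 = lambda_k.  Eigenvector signs
    are fixed by making each component's largest-magnitude loading
    positive.
    """
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise ValidationError("non-finite entries in metric matrix")
    corr = np.corrcoef(M, rowvar=False)
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    for k in range(vec.shape[1]):
        imax = np.argmax(np.abs(vec[:, k]))
        if vec[imax, k] < 0:
            vec[:, k] = -vec[:, k]
    r = vec * np.sqrt(lam)[None, :]
    return lam, r


def camargo_evenness(values) -> float:
    """Camargo's evenness: 1 - sum_{i<j} |q_i - q_j| / S on proportions q.

    1 for perfectly even values; 1/S when a single value carries
    everything.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValidationError("Camargo evenness needs non-negative values")
    total = v.sum()
    if total <= 0:
        raise ValidationError("all-zero input to Camargo evenness")
    q = v / total
    S = len(q)
    diff = np.abs(q[:, None] - q[None, :])
    return float(1.0 - diff[np.triu_indices(S, k=1)].sum() / S)


def evenness_of_eigenvalues(lam: np.ndarray) -> float:
    """EE: Camargo evenness of the correlation-PCA eigenvalues.

    Near 1: complementary (weakly correlated) diversity metrics; near
    1/S: a single dominant dimension, i.e. redundant metrics.
    """
    return camargo_evenness(lam)


def importance_values(lam: np.ndarray, r: np.ndarray, variant: str = "r2") -> np.ndarray:
    """Importance value of each metric, normalized to sum to 1.

    raw_m = sum_k p_k * w(r[m, k]) with p_k = lambda_k / sum(lambda) the
    variance share of component k and w either the squared correlation
    (``r2``, default) or its absolute value (``abs_r``).
    """
    lam = np.asarray(lam, dtype=float)
    r = np.asarray(r, dtype=float)
    p = lam / lam.sum()
    if variant == "r2":
        raw = (r**2) @ p
    elif variant == "abs_r":
        raw = np.abs(r) @ p
    else:
        raise ValueError(f"unknown IV variant {variant!r}")
    total = raw.sum()
    if total <= 0:
        raise ValidationError("degenerate importance values (all zero)")
    return raw / total


def iv_evenness(iv: np.ndarray) -> float:
    """Camargo evenness of the importance values: high = more metrics contribute."""
    return camargo_evenness(iv)


@dataclass
class DimensionalityResult:
    category: str
    eigenvalues: np.ndarray
    loadings: np.ndarray
    EE: float
    IV: pd.Series
    IV_evenness: float
    IV_evenness_CI: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None
    metrics: tuple[str, ...] = METRIC_COLUMNS

    def as_row(self) -> dict:
        row = {"category": self.category, "EE": self.EE}
        for m in self.metrics:
            row[f"IV_{m}"] = float(self.IV[m])
        row["IV_evenness"] = self.IV_evenness
        if self.IV_evenness_CI is not None:
            row["IV_evenness_ci_low"], row["IV_evenness_ci_high"] = self.IV_evenness_CI
        row["n_boot"] = self.n_boot
        return row


def _chain(M: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, float]:
    lam, r = pca_correlation(M)
    ee = evenness_of_eigenvalues(lam)
    iv = importance_values(lam, r, variant=variant)
    return lam, r, ee, iv, iv_evenness(iv)


def bootstrap_iv_evenness(
    profile: DiversityProfile,
    category: str,
    n_boot: int = 999,
    seed: int | None = None,
    iv_variant: str = "r2",
    metrics: tuple[str, ...] = METRIC_COLUMNS,
    max_redraws: int = 100,
) -> DimensionalityResult:
    """Full dimensionality chain for one category with a percentile bootstrap.

    Plots are resampled with replacement within the category and the
    whole chain (correlation PCA -> EE -> IV -> IV evenness) recomputed;
    the 2.5/97.5 percentiles of IV evenness give the 95% CI.  Degenerate
    resamples (a zero-variance metric) are redrawn and counted.
    """
    M = metric_matrix(profile, category, metrics=metrics)
    lam, r, ee, iv, ive = _chain(M, iv_variant)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = M.shape[0]
        boots = np.empty(n_boot)
        redraws = 0
        for b in range(n_boot):
            for _attempt in range(max_redraws):
                idx = rng.integers(0, n, size=n)
                Mb = M[idx]
                if (Mb.std(axis=0, ddof=1) > 0).all():
                    break
                redraws += 1
            else:
                raise ValidationError(f"bootstrap: {max_redraws} degenerate resamples in a row")
            boots[b] = _chain(Mb, iv_variant)[4]
        if redraws:
            logger.info("bootstrap %s: %d degenerate resamples redrawn", category, redraws)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return DimensionalityResult(
        category=category, eigenvalues=lam, loadings=r, EE=ee,
        IV=pd.Series(iv, index=list(metrics)), IV_evenness=ive,
        IV_evenness_CI=ci, n_boot=n_boot, seed=seed, metrics=metrics,
    )


def dimensionality_by_category(
    profile: DiversityProfile,
    n_boot: int = 999,
    seed: int | None = None,
    iv_variant: str = "r2",
) -> pd.DataFrame:
    """Dimensionality table (EE, IVs, IV evenness, CI) for every category present."""
    cats = list(dict.fromkeys(profile.table["category"]))
    rng = np.random.default_rng(seed)
    rows = []
    for cat in cats:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = bootstrap_iv_evenness(profile, cat, n_boot=n_boot, seed=sub_seed,
                                    iv_variant=iv_variant)
        rows.append(res.as_row())
    return pd.DataFrame(rows)
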