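"""Tree completion, phylogenetic distance matrices, and Blomberg's K.

Field species lists rarely match a megaphylogeny tip-for-tip.  The
standard remedy is to graft each missing species at a random position
within its genus (repeated to yield a set of alternative topologies whose
downstream metrics are averaged).  This module implements that grafting,
the patristic / time-since-MRCA divergence matrix that Rao's quadratic
entropy consumes, and Blomberg's K statistic of phylogenetic signal with
a tip-permutation significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .core import DistanceMatrix, PhylogeneticTree, ValidationError, genus_of

logger = logging.getLogger("grassdiv")


# ---------------------------------------------------------------------------
# Divergence and covariance matrices
# ---------------------------------------------------------------------------

def _mrca_depth_matrix(ptree: PhylogeneticTree) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (tip labels, root-to-tip depths, pairwise MRCA depth matrix).

    Single postorder pass: each internal node stamps its depth as the MRCA
    depth of every cross-child leaf pair, O(n^2) overall.
    """
    tree = ptree.tree
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    node_depth: dict = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        node_depth[nd] = node_depth[nd.parent_node] + (nd.edge.length or 0.0)

    mrca = np.zeros((n, n))
    depths = np.zeros(n)
    leaves_below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = pos[nd.taxon.label]
            depths[i] = node_depth[nd]
            leaves_below[nd] = [i]
            continue
        child_sets = [leaves_below.pop(ch) for ch in nd.child_nodes()]
        d = node_depth[nd]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                mrca[np.ix_(ia, ib)] = d
                mrca[np.ix_(ib, ia)] = d
        merged = [i for s in child_sets for i in s]
        leaves_below[nd] = merged
    np.fill_diagonal(mrca, depths)
    return labels, depths, mrca


def divergence_matrix(ptree: PhylogeneticTree, convention: str = "half_patristic") -> DistanceMatrix:
    """Pairwise divergence d_ij between tips.

    ``half_patristic`` (default) is patristic distance / 2 — the time
    since the most recent common ancestor on an ultrametric tree, which
    puts Rao's phylogenetic entropy on the "mean divergence time" scale.
    ``patristic`` returns the raw path length.
    """
    if convention not in ("half_patristic", "patristic"):
        raise ValueError(f"unknown divergence convention {convention!r}")
    labels, depths, mrca = _mrca_depth_matrix(ptree)
    patristic = depths[:, None] + depths[None, :] - 2.0 * mrca
    np.fill_diagonal(patristic, 0.0)
    patristic = np.maximum(patristic, 0.0)
    d = patristic / 2.0 if convention == "half_patristic" else patristic
    return DistanceMatrix(labels, d, kind="phylogenetic-divergence")


def phylo_covariance(ptree: PhylogeneticTree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance C: C_ij = shared root-to-MRCA path length."""
    labels, _depths, mrca = _mrca_depth_matrix(ptree)
    return labels, mrca


# ---------------------------------------------------------------------------
# Random grafting of missing species
# ---------------------------------------------------------------------------

@dataclass
class GraftedTreeSet:
    """A set of alternative topologies with missing species randomly grafted."""

    trees: list[PhylogeneticTree]
    grafted_species: list[str]
    dropped_species: list[str]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trees)


def _attachment_edges(tree: dendropy.Tree, clade_root) -> list:
    """Edges available for attachment: the clade's stem plus all edges below it."""
    edges = []
    if clade_root is not tree.seed_node and clade_root.edge.length:
        edges.append(clade_root.edge)
    for nd in clade_root.preorder_iter():
        if nd is clade_root:
            continue
        if nd.edge.length and nd.edge.length > 0:
            edges.append(nd.edge)
    return edges


def _graft_one(tree: dendropy.Tree, species: str, clade_root, tip_depth: float,
               node_depth: dict, rng: np.random.Generator) -> None:
    edges = _attachment_edges(tree, clade_root)
    if not edges:
        # single zero-length stem: attach at the clade root itself
        edges = [clade_root.edge]
    lengths = np.array([e.length or 0.0 for e in edges], dtype=float)
    if lengths.sum() <= 0:
        edge = edges[int(rng.integers(len(edges)))]
        frac = 0.0
    else:
        edge = edges[int(rng.choice(len(edges), p=lengths / lengths.sum()))]
        frac = float(rng.uniform(0.0, 1.0))

    head = edge.head_node
    parent = head.parent_node
    elen = edge.length or 0.0
    depth_head = node_depth[head]
    attach_depth = depth_head - elen + frac * elen

    # split the edge at the attachment point
    new_node = dendropy.Node()
    parent.remove_child(head)
    parent.add_child(new_node)
    new_node.edge.length = attach_depth - (depth_head - elen)
    new_node.add_child(head)
    head.edge.length = depth_head - attach_depth

    leaf = dendropy.Node()
    taxon = tree.taxon_namespace.new_taxon(label=species)
    leaf.taxon = taxon
    new_node.add_child(leaf)
    leaf.edge.length = max(tip_depth - attach_depth, 0.0)

    node_depth[new_node] = attach_depth
    node_depth[leaf] = tip_depth


def graft_missing_species(
    ptree: PhylogeneticTree,
    missing: list[str],
    n_topologies: int = 1000,
    seed: int | None = None,
    taxonomy: dict[str, tuple[str, str]] | None = None,
) -> GraftedTreeSet:
    """Graft each missing species at a random point within its genus clade.

    The attachment point is drawn uniformly along the branches of the
    smallest clade spanning the genus' existing tips, including that
    clade's stem; the new tip is extended to the tree's tip depth so an
    ultrametric input stays ultrametric.  Species whose genus is absent
    fall back to their family clade when ``taxonomy`` (species ->
    (genus, family)) is supplied, and are otherwise dropped with a
    warning.  Repeated ``n_topologies`` times with independent draws.
    """
    rng_master = np.random.default_rng(seed)
    base_labels = set(ptree.tip_labels)
    missing = [m for m in missing if m not in base_labels]

    # which species can be placed at all (decided once, on the backbone)
    genus_tips = ptree.genus_index()
    fam_of: dict[str, str] = {}
    if taxonomy:
        fam_of = {sp: fam for sp, (_g, fam) in taxonomy.items()}
    family_tips: dict[str, list[str]] = {}
    if taxonomy:
        for lab in ptree.tip_labels:
            f = fam_of.get(lab)
            if f:
                family_tips.setdefault(f, []).append(lab)

    placeable: list[tuple[str, list[str]]] = []
    dropped: list[str] = []
    for sp in missing:
        g = genus_of(sp)
        if g in genus_tips:
            placeable.append((sp, genus_tips[g]))
        elif taxonomy and fam_of.get(sp) in family_tips:
            placeable.append((sp, family_tips[fam_of[sp]]))
            logger.warning("species %s: no congener in tree, grafting within family %s", sp, fam_of[sp])
        else:
            dropped.append(sp)
            logger.warning("species %s: no congener (or family) in tree; dropped", sp)

    child_seeds = rng_master.integers(0, 2**31 - 1, size=n_topologies)
    trees: list[PhylogeneticTree] = []
    for t in range(n_topologies):
        rng = np.random.default_rng(int(child_seeds[t]))
        work = ptree.tree.clone(depth=1)
        work.is_rooted = True
        node_depth = {work.seed_node: 0.0}
        for nd in work.preorder_node_iter():
            if nd is work.seed_node:
                continue
            node_depth[nd] = node_depth[nd.parent_node] + (nd.edge.length or 0.0)
        tip_depth = max(node_depth[lf] for lf in work.leaf_node_iter())

        for sp, anchor_tips in placeable:
            taxa = [work.taxon_namespace.get_taxon(a) for a in anchor_tips]
            # anchors grafted earlier in this topology also count as congeners
            extra = [work.taxon_namespace.get_taxon(s) for s, _ in placeable
                     if s != sp and genus_of(s) == genus_of(sp)]
            taxa = [tx for tx in taxa + extra if tx is not None]
            nodes = [work.find_node_for_taxon(tx) for tx in taxa]
            nodes = [nd for nd in nodes if nd is not None]
            clade_root = nodes[0] if len(nodes) == 1 else work.mrca(taxa=[nd.taxon for nd in nodes])
            _graft_one(work, sp, clade_root, tip_depth, node_depth, rng)
        trees.append(PhylogeneticTree(work))
    return GraftedTreeSet(trees, [sp for sp, _ in placeable], dropped, seed)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

@dataclass
class PhyloSignalResult:
    """Blomberg's K with a tip-permutation p-value."""

    trait: str
    K: float
    p_value: float
    n_permutations: int


def _k_ratio(x: np.ndarray, Cinv: np.ndarray) -> tuple[float, float]:
    """Return (MSE0/MSE, MSE) for trait vector x under GLS with covariance C."""
    n = len(x)
    ones = np.ones(n)
    Ci1 = Cinv @ ones
    denom = ones @ Ci1
    ahat = (Ci1 @ x) / denom
    resid = x - ahat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ (Cinv @ resid)) / (n - 1)
    return mse0 / mse, mse


def blomberg_k(
    ptree: PhylogeneticTree,
    trait_values: "np.ndarray | dict | object",
    n_permutations: int = 999,
    seed: int | None = None,
    trait_name: str = "trait",
) -> PhyloSignalResult:
    """Blomberg's K: observed MSE0/MSE scaled by its Brownian-motion expectation.

    MSE0 is the mean squared deviation of tip values from the GLS
    (phylogenetically weighted) ancestral mean; MSE the GLS mean squared
    error under the Brownian covariance C.  Under Brownian motion the
    expected ratio is (tr(C) - n / sum(C^-1)) / (n - 1), so K = 1 under
    BM, ~0 for phylogenetically random traits, > 1 for traits more
    conserved than BM.  Significance: proportion of tip-label permutations
    whose GLS MSE is <= the observed MSE (the observed arrangement counts
    in both numerator and denominator).
    """
    labels, C = phylo_covariance(ptree)
    if hasattr(trait_values, "loc"):  # pandas Series
        x = np.asarray([trait_values.loc[lab] for lab in labels], dtype=float)
    elif isinstance(trait_values, dict):
        x = np.asarray([trait_values[lab] for lab in labels], dtype=float)
    else:
        x = np.asarray(trait_values, dtype=float)
    n = len(labels)
    if len(x) != n:
        raise ValidationError("trait vector length does not match tip count")
    if np.ptp(x) == 0:
        raise ValidationError("constant trait: Blomberg's K is undefined")

    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular phylogenetic covariance matrix: {exc}") from exc

    ratio_obs, mse_obs = _k_ratio(x, Cinv)
    expected = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    K = ratio_obs / expected

    rng = np.random.default_rng(seed)
    count = 1  # observed included
    for _ in range(n_permutations):
        xp = x[rng.permutation(n)]
        _, mse_p = _k_ratio(xp, Cinv)
        if mse_p <= mse_obs:
            count += 1
    p = count / (n_permutations + 1)
    return PhyloSignalResult(trait_name, float(K), float(p), n_permutations)
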