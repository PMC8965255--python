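"""Unsigned weighted coexpression network, modules, and eigengenes.

Adjacency is ``|Pearson correlation|^beta`` across strains (unsigned
network, soft threshold beta = 7 by default), similarity is the topological
overlap matrix (TOM), and modules are cut from an average-linkage dendrogram
of ``1 - TOM`` by a recursive branch cut: a branch is split when both
children are large enough and the merge sits clearly above the children's
own merges (the cohesion gap), with the gap threshold shrinking as the
split sensitivity grows (4 = most aggressive).  This is a documented
simplification of the reference dynamic hybrid tree cut; module *properties*
(recovering planted partitions, leaving noise unassigned), not module
identity against the reference implementation, are the contract.

Each module is summarized by its eigengene — the first principal component
of the per-transcript standardized strains x members matrix, signed so the
mean correlation with members is positive — and nodes are ranked by
intra-modular connectivity (sum of within-module adjacency), whose argmax
is the hub.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class NetworkParams:
    beta: float = 7.0
    min_module_size: int = 5
    split_sensitivity: int = 4
    cut_height: float = 0.98
    correlation: str = "pearson"
    signed: bool = False

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 <= self.split_sensitivity <= 4):
            raise ValueError("split_sensitivity must be in 0..4")

    @property
    def gap_threshold(self) -> float:
        """Cohesion gap a merge must exceed to be split; monotone in the
        sensitivity (4 -> 0.05, 0 -> 0.25)."""
        return 0.25 - 0.05 * self.split_sensitivity


def adjacency(expr: pd.DataFrame, params: NetworkParams | None = None) -> pd.DataFrame:
    """a_ij = |cor(x_i, x_j)|^beta over strains; unit diagonal.

    ``expr`` is transcripts x strains.  Constant rows have no defined
    correlation and are rejected by name.
    """
    params = params or NetworkParams()
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need >=3 strains")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(expr.index[sd == 0][:5])
        raise ValueError(f"constant expression rows: {bad}")
    r = np.corrcoef(X)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** params.beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k regression over binned connectivity.

    Diagnostic for choosing the soft threshold; returns NaN when fewer than
    two bins are occupied.
    """
    A = adj.to_numpy(dtype=float)
    if A.shape[0] < 20:
        raise ValueError("need >=20 nodes for a degree-distribution fit")
    k = A.sum(axis=1) - np.diag(A)
    k = k[k > 0]
    if len(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    centers, probs = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append(k[mask].mean())
            probs.append(mask.mean())
    if len(centers) < 2:
        return float("nan")
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(probs))
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)+1-a_ij)
    with l_ij the shared-neighbor weight sum; unit diagonal."""
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    L = Ad @ Ad
    k = Ad.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (L + Ad) / (kmin + 1.0 - Ad)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleSet:
    """Transcript -> module assignment; module labels are size-ranked
    ('M1' largest); the unassigned pool is labelled 'unassigned'."""

    assignments: pd.Series  # index: transcript id, values: module label

    @property
    def labels(self) -> list[str]:
        return [l for l in self.assignments.unique() if l != "unassigned"]

    def members(self, label: str) -> list[str]:
        return list(self.assignments.index[self.assignments == label])

    @property
    def n_unassigned(self) -> int:
        return int((self.assignments == "unassigned").sum())

    def sizes(self) -> pd.Series:
        s = self.assignments[self.assignments != "unassigned"]
        return s.value_counts()


def detect_modules(
    dissimilarity: pd.DataFrame, params: NetworkParams | None = None
) -> ModuleSet:
    """Average-linkage clustering of ``1 - TOM`` with a recursive branch cut.

    A branch becomes a module when its merge height is at or below
    ``cut_height``; it is split further when both children reach
    ``min_module_size`` and the merge height exceeds the higher child merge
    by more than ``gap_threshold``.  Everything else is unassigned.
    """
    params = params or NetworkParams()
    ids = list(dissimilarity.index)
    n = len(ids)
    assignments = pd.Series("unassigned", index=pd.Index(ids))
    if n < params.min_module_size:
        return ModuleSet(assignments)

    D = dissimilarity.to_numpy(dtype=float)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    root, _ = hierarchy.to_tree(Z, rd=True)

    modules: list[list[int]] = []

    def leaves(node) -> list[int]:
        return node.pre_order(lambda x: x.id)

    def visit(node, inside: bool) -> None:
        """inside=True once the branch is below the height cutoff."""
        if node.is_leaf():
            return
        if not inside:
            if node.dist <= params.cut_height and node.get_count() >= params.min_module_size:
                visit(node, True)
            else:
                visit(node.get_left(), False)
                visit(node.get_right(), False)
            return
        L, R = node.get_left(), node.get_right()
        child_top = max(L.dist, R.dist)
        splittable = (
            L.get_count() >= params.min_module_size
            and R.get_count() >= params.min_module_size
            and (node.dist - child_top) > params.gap_threshold
        )
        if splittable:
            visit(L, True)
            visit(R, True)
        else:
            modules.append(leaves(node))

    visit(root, False)

    modules.sort(key=lambda m: (-len(m), min(m)))
    for rank, mem in enumerate(modules, start=1):
        assignments.iloc[mem] = f"M{rank}"
    return ModuleSet(assignments)


@dataclass
class ModuleEigengene:
    label: str
    scores: pd.Series  # per-strain eigengene values
    variance_explained: float
    loadings: pd.Series = field(default_factory=pd.Series)


def module_eigengene(expr: pd.DataFrame, members: list[str],
                     label: str = "") -> ModuleEigengene:
    """First principal component of the standardized strains x members
    matrix; sign fixed so the mean correlation with members is positive;
    variance explained = first eigenvalue / trace."""
    if len(members) < 2:
        raise ValueError("module must have >=2 members")
    X = expr.loc[members].to_numpy(dtype=float)  # members x strains
    sd = X.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("rank-0 module: all members constant")
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[0]  # per strain
    var_explained = float(S[0] ** 2 / np.sum(S**2))
    corr_sign = np.sign(np.mean(Z @ scores))
    if corr_sign < 0:
        scores = -scores
    loadings = Z @ scores / (np.linalg.norm(scores) ** 2)
    return ModuleEigengene(
        label,
        pd.Series(scores, index=expr.columns, name=label or "eigengene"),
        var_explained,
        pd.Series(loadings, index=members),
    )


def intramodular_connectivity(adj: pd.DataFrame, members: list[str]) -> pd.Series:
    """k_i = sum of adjacency to other module members; the argmax (ties ->
    lexicographically smallest id) is the module hub."""
    sub = adj.loc[members, members].to_numpy(dtype=float)
    k = sub.sum(axis=1) - np.diag(sub)
    out = pd.Series(k, index=pd.Index(members), name="k_within")
    return out


def module_hub(k_within: pd.Series) -> str:
    best = float(k_within.max())
    tol = 1e-9 * max(1.0, abs(best))
    return sorted(k_within.index[k_within >= best - tol])[0]
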