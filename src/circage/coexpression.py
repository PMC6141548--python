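"""Weighted co-expression modules: soft-threshold adjacency, topological
overlap, average-linkage clustering with a static tree cut, and module
eigengenes.

This is a deliberately compact, single-block network build. The adjacency
between two circRNAs is ``|pearson_cor|^beta`` with a cubic soft threshold
by default (unsigned network; ``signed=True`` uses ``((1+cor)/2)^beta``).
The topological overlap of nodes *i*, *j* combines their direct adjacency
with the weight of shared neighbours:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu

and 1 - TOM is the clustering dissimilarity. Clusters from a static cut of
the average-linkage tree smaller than ``min_module_size`` fall into module
0 (unassigned); remaining modules are labelled 1..K by decreasing size.
The module eigengene is the first principal component across samples of the
module's row-standardized submatrix, unit norm, oriented to correlate
positively with the module's mean standardized profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import NumericError
from .io_formats import JunctionCountMatrix

logger = logging.getLogger("circage")


@dataclass
class AdjacencyMatrix:
    values: np.ndarray  # symmetric, in [0,1], unit diagonal
    ids: list[str]
    beta: int

    def __post_init__(self) -> None:
        a = self.values
        if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
            raise NumericError("adjacency must be square and symmetric")
        if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
            raise NumericError("adjacency entries must lie in [0, 1]")

    def connectivity(self) -> np.ndarray:
        """k_i: adjacency sum over the off-diagonal."""
        return self.values.sum(axis=1) - np.diag(self.values)


@dataclass
class ModuleAssignment:
    labels: pd.Series  # circ_id -> module label, 0 = unassigned
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    variance_explained: pd.Series = field(default_factory=pd.Series)

    def module_ids(self, include_unassigned: bool = False) -> list[int]:
        mods = sorted(self.labels.unique())
        return [m for m in mods if include_unassigned or m != 0]


def _log2_working(norm_matrix: JunctionCountMatrix, log_transform: bool) -> np.ndarray:
    vals = norm_matrix.values.astype(float)
    return np.log2(vals + 1.0) if log_transform else vals


def adjacency(
    norm_matrix: JunctionCountMatrix,
    beta: int = 3,
    signed: bool = False,
    log_transform: bool = True,
) -> AdjacencyMatrix:
    """Soft-threshold adjacency ``|cor|^beta`` between circRNA profiles."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    x = _log2_working(norm_matrix, log_transform)
    if x.shape[1] < 3:
        raise NumericError("adjacency needs at least 3 samples")
    sd = x.std(axis=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [norm_matrix.circ_ids[i] for i in zero_var[:10]]
        raise NumericError(
            f"{zero_var.size} zero-variance row(s), e.g. {names}; drop them first"
        )
    cor = np.corrcoef(x)
    a = ((1 + cor) / 2) ** beta if signed else np.abs(cor) ** beta
    np.clip(a, 0.0, 1.0, out=a)
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2
    return AdjacencyMatrix(values=a, ids=list(norm_matrix.circ_ids), beta=beta)


def tom_similarity(adj: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency (vectorized)."""
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # l_ij = sum_u a_iu a_uj over u != i, j; (A@A) includes no diagonal terms
    # because diag(a) = 0 here.
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2
    return pd.DataFrame(tom, index=adj.ids, columns=adj.ids)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.25,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static cut.

    ``cut_height`` is the dissimilarity at which the tree is cut; clusters
    smaller than ``min_module_size`` become module 0.
    """
    if tom.shape[0] < 2:
        raise NumericError("module detection needs at least 2 circRNAs")
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index
    # relabel by decreasing size, 1..K; ties broken by original cluster id
    ordered = sorted(big, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    labels = pd.Series(
        [remap.get(c, 0) for c in raw], index=tom.index, name="module"
    )
    logger.info(
        "detected %d modules (+ module 0 with %d circRNAs) at cut %.2f",
        len(ordered), int((labels == 0).sum()), cut_height,
    )
    return ModuleAssignment(labels=labels)


def module_eigengene(
    norm_matrix: JunctionCountMatrix,
    assignment: ModuleAssignment,
    log_transform: bool = True,
    include_unassigned: bool = False,
) -> ModuleAssignment:
    """First principal component per module across samples.

    Rows are z-scored before the SVD so every circRNA contributes equally.
    Returns a new assignment carrying ``eigengenes`` (module x sample, unit
    Euclidean norm) and the fraction of module variance each explains.
    """
    x = _log2_working(norm_matrix, log_transform)
    ids = pd.Index(norm_matrix.circ_ids)
    eg_rows, ve = {}, {}
    for m in assignment.module_ids(include_unassigned=include_unassigned):
        members = assignment.labels.index[assignment.labels == m]
        if len(members) == 0:
            raise NumericError(f"module {m} is empty")
        sub = x[ids.get_indexer(members)]
        sd = sub.std(axis=1)
        if np.any(sd == 0):
            raise NumericError(f"module {m} contains zero-variance rows")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        eg_rows[m] = eig
        ve[m] = float(s[0] ** 2 / np.sum(s**2))
    eigengenes = pd.DataFrame(eg_rows, index=norm_matrix.sample_ids).T
    eigengenes.index.name = "module"
    return ModuleAssignment(
        labels=assignment.labels,
        eigengenes=eigengenes,
        variance_explained=pd.Series(ve, name="variance_explained"),
    )
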