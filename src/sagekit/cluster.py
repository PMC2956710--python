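"""Poisson-model K-means over three-stage expression profiles.

Tag counts are modeled as Poisson; a cluster centroid is a relative
expression profile c (summing to 1), and the distance of a count vector x
to a centroid is the Poisson deviance of x against the rates
lambda_j = (sum x) * c_j:

    d(x, c) = sum_j [ lambda_j - x_j + x_j ln(x_j / lambda_j) ]

with the convention 0 ln(0/lambda) = 0.  Lloyd alternation with the
maximum-likelihood centroid update (c_j proportional to the summed member
counts) monotonically decreases the total within-cluster deviance.  Because
single fits depend on initialization, cluster membership is consolidated
over many random restarts: labels are aligned across runs by greedy
centroid matching and each tag receives its modal aligned cluster
(consensus clustering).

The module also builds the between-library tree: pairwise Pearson
correlation over the union tag set (tags absent from a library enter as
zero), distance 1 - r, neighbor-joining topology and nonnegative
least-squares branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_array, check_is_fitted
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from sagekit.tagproc import TagCountTable, TagMap

CENTROID_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Profile selection
# ---------------------------------------------------------------------------

def select_clustering_tags(
    stage_counts: pd.DataFrame,
    tag_map: TagMap,
    min_combined: int = 10,
) -> pd.DataFrame:
    """Keep tags with combined raw count strictly greater than
    ``min_combined`` across the stage libraries AND a unique sense mapping.

    ``stage_counts`` is a tags x stages integer frame (one replicate).
    Returns the retained count frame plus relative-profile columns (each
    stage as a percentage of the tag's summed count).
    """
    total = stage_counts.sum(axis=1)
    keep = (total > min_combined) & pd.Series(
        [tag_map.class_of(t) == "unique_sense" for t in stage_counts.index],
        index=stage_counts.index,
    )
    kept = stage_counts.loc[keep].copy()
    rel = 100.0 * kept.div(kept.sum(axis=1), axis=0)
    rel.columns = [f"pct_{c}" for c in kept.columns]
    return pd.concat([kept, rel], axis=1)


# ---------------------------------------------------------------------------
# Poisson deviance distance
# ---------------------------------------------------------------------------

def poissonc_distance(x: Sequence[float], c: Sequence[float]) -> float:
    """Poisson deviance of a count vector against a centroid profile."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.min() < 0:
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no profile")
    if abs(c.sum() - 1.0) > 1e-6:
        raise ValueError("centroid profile must sum to 1")
    lam = total * np.maximum(c, CENTROID_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(x / lam), 0.0)
    return float(np.sum(lam - x + term))


def _deviance_matrix(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n, K) deviance of each count row against each centroid."""
    totals = X.sum(axis=1, keepdims=True)               # (n, 1)
    lam = totals[:, :, None] * centers.T[None, :, :]    # (n, p, K)
    lam = np.maximum(lam, CENTROID_FLOOR)
    Xe = X[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(Xe > 0, Xe * np.log(Xe / lam), 0.0)
    return np.sum(lam - Xe + term, axis=1)


class PoissonCKMeans(ClusterMixin, BaseEstimator):
    """K-means clustering under the Poisson deviance distance.

    Parameters
    ----------
    n_clusters : int
        Number of partitions K.
    n_init : int
        Random initializations per fit; the lowest-dispersion run is kept.
    max_iter : int
        Lloyd iteration cap per initialization.
    random_state : int, RandomState or None
        Seed for centroid initialization.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_stages) profiles, rows sum to 1.
    labels_ : modal assignment of each training row.
    inertia_ : total within-cluster Poisson deviance.
    inertia_path_ : per-iteration dispersion of the winning run
        (monotone non-increasing).
    """

    def __init__(self, n_clusters=10, n_init=1, max_iter=100, random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def _lloyd(self, X: np.ndarray, rng: np.random.RandomState):
        n = X.shape[0]
        idx = rng.choice(n, size=self.n_clusters, replace=False)
        centers = X[idx] / X[idx].sum(axis=1, keepdims=True)
        labels = None
        path = []
        for it in range(self.max_iter):
            dist = _deviance_matrix(X, centers)
            new_labels = dist.argmin(axis=1)
            # re-seed empty clusters from the worst-fit points
            empty = np.setdiff1d(np.arange(self.n_clusters), new_labels)
            if empty.size:
                worst = np.argsort(dist[np.arange(n), new_labels])[::-1]
                for k, w in zip(empty, worst):
                    new_labels[w] = k
                centers = self._update_centers(X, new_labels, centers)
                dist = _deviance_matrix(X, centers)
                new_labels = dist.argmin(axis=1)
            path.append(float(dist[np.arange(n), new_labels].sum()))
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            centers = self._update_centers(X, labels, centers)
        dist = _deviance_matrix(X, centers)
        inertia = float(dist[np.arange(n), labels].sum())
        path.append(inertia)
        return labels, centers, inertia, path, it + 1

    def _update_centers(self, X, labels, old_centers):
        centers = old_centers.copy()
        for k in range(self.n_clusters):
            members = X[labels == k]
            if len(members):
                s = members.sum(axis=0)
                centers[k] = s / s.sum()
        return centers

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(X.sum(axis=1) == 0):
            raise ValueError("all-zero count rows have no profile")
        n = X.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters={self.n_clusters} outside [1, {n}]")
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(self.n_init):
            labels, centers, inertia, path, n_iter = self._lloyd(X, rng)
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia, path, n_iter)
        self.labels_, self.cluster_centers_, self.inertia_, self.inertia_path_, self.n_iter_ = best
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=float)
        return _deviance_matrix(X, self.cluster_centers_).argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def poissonc_fit(
    profiles: np.ndarray, k: int, seed=None, n_init: int = 1
) -> PoissonCKMeans:
    """Functional wrapper: fit a :class:`PoissonCKMeans` on raw counts."""
    return PoissonCKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(profiles)


# ---------------------------------------------------------------------------
# K selection and consensus
# ---------------------------------------------------------------------------

def dispersion_curve(
    profiles: np.ndarray,
    k_range: Iterable[int] = range(2, 21),
    seed=None,
    n_init: int = 5,
) -> tuple[pd.Series, int]:
    """Best-of-restarts dispersion per K plus an elbow suggestion.

    The elbow is the K maximizing the second difference of the dispersion
    curve; K remains the caller's decision.
    """
    rng = check_random_state(seed)
    ks = sorted(k_range)
    disp = {}
    for k in ks:
        model = PoissonCKMeans(
            n_clusters=k, n_init=n_init,
            random_state=rng.randint(np.iinfo(np.int32).max),
        ).fit(profiles)
        disp[k] = model.inertia_
    curve = pd.Series(disp, name="dispersion")
    curve.index.name = "K"
    if len(ks) >= 3:
        second = {
            ks[i]: curve[ks[i - 1]] - 2 * curve[ks[i]] + curve[ks[i + 1]]
            for i in range(1, len(ks) - 1)
        }
        elbow = max(second, key=second.get)
    else:
        elbow = ks[0]
    return curve, elbow


def _align_labels(
    ref_centers: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Greedy 1-1 matching of clusters to a reference by centroid profile
    correlation; returns the permutation new->ref."""
    k = ref_centers.shape[0]
    corr = np.corrcoef(centers, ref_centers)[:k, k:]
    corr = np.nan_to_num(corr, nan=-2.0)
    perm = np.full(k, -1)
    used_ref = set()
    order = np.dstack(np.unravel_index(np.argsort(corr, axis=None)[::-1], corr.shape))[0]
    for i, j in order:
        if perm[i] == -1 and j not in used_ref:
            perm[i] = j
            used_ref.add(j)
    return perm


@dataclass
class ConsensusResult:
    labels: np.ndarray          # modal aligned cluster per tag
    stability: np.ndarray       # modal fraction per tag
    centers: np.ndarray         # centroids of the reference run
    runs: int


def consensus_cluster(
    profiles: np.ndarray, k: int, n_runs: int = 100, seed=None
) -> ConsensusResult:
    """Consensus assignment over independent random-initialization fits.

    Labels from each run are aligned to the first (reference) run by greedy
    centroid matching on profile correlation; each tag is assigned its
    modal aligned cluster, with stability the modal fraction.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = check_random_state(seed)
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    aligned = np.empty((n, n_runs), dtype=int)
    ref_centers = None
    for r in range(n_runs):
        model = PoissonCKMeans(
            n_clusters=k, random_state=rng.randint(np.iinfo(np.int32).max)
        ).fit(profiles)
        if ref_centers is None:
            ref_centers = model.cluster_centers_
            aligned[:, r] = model.labels_
        else:
            perm = _align_labels(ref_centers, model.cluster_centers_)
            aligned[:, r] = perm[model.labels_]
    # modal label and its frequency per tag
    labels = np.empty(n, dtype=int)
    stability = np.empty(n)
    for i in range(n):
        vals, counts = np.unique(aligned[i], return_counts=True)
        j = counts.argmax()
        labels[i] = vals[j]
        stability[i] = counts[j] / n_runs
    return ConsensusResult(labels, stability, ref_centers, n_runs)


def amalgamate_groups(
    centroids: np.ndarray, tol: float = 0.05
) -> dict[int, int]:
    """Assign each centroid over three ordered stages to a major trend group.

    With centroid (a, r, c) summing to 1 and tolerance ``tol`` (profile
    fraction, default 5 percentage points): group 3 if r exceeds both ends
    by tol (peak at the middle stage); group 5 if r falls below both ends
    by tol (valley); group 1 if the last stage exceeds the first by tol
    (up during progression); group 2 for the mirror (down); else group 4
    (constant).
    """
    centroids = np.asarray(centroids, dtype=float)
    out = {}
    for idx, (a, r, c) in enumerate(centroids):
        if r > max(a, c) + tol:
            grp = 3
        elif r < min(a, c) - tol:
            grp = 5
        elif c > a + tol:
            grp = 1
        elif c < a - tol:
            grp = 2
        else:
            grp = 4
        out[idx] = grp
    return out


# ---------------------------------------------------------------------------
# Library tree
# ---------------------------------------------------------------------------

@dataclass
class LibraryTree:
    tree: TreeNode
    distances: pd.DataFrame
    newick: str


def _nnls_branch_lengths(tree: TreeNode, dm: pd.DataFrame) -> None:
    """Refit branch lengths by nonnegative least squares against the
    pairwise distance matrix (edges as columns, leaf pairs as rows)."""
    tree.assign_ids()
    edges = [n for n in tree.traverse(include_self=False)]
    edge_index = {n.id: j for j, n in enumerate(edges)}
    tips = list(tree.tips())
    names = [t.name for t in tips]
    rows, targets = [], []
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            row = np.zeros(len(edges))
            # path = edges to the lowest common ancestor from both tips
            lca = tree.lowest_common_ancestor([tips[i], tips[j]])
            for tip in (tips[i], tips[j]):
                node = tip
                while node is not lca:
                    row[edge_index[node.id]] = 1.0
                    node = node.parent
            rows.append(row)
            targets.append(dm.loc[names[i], names[j]])
    lengths, _ = nnls(np.asarray(rows), np.asarray(targets))
    for n, ln in zip(edges, lengths):
        n.length = float(ln)


def tree_from_distances(d: pd.DataFrame) -> LibraryTree:
    """NJ topology + NNLS branch lengths from a symmetric distance frame."""
    dm = DistanceMatrix(d.values, ids=list(d.columns))
    tree = nj(dm)
    _nnls_branch_lengths(tree, d)
    buf = io.StringIO()
    tree.write(buf)
    return LibraryTree(tree, d, buf.getvalue().strip())


def build_library_tree(
    libraries: Sequence[TagCountTable], use_cpm: bool = False
) -> LibraryTree:
    """Pearson 1-r tree over the union tag set (zeros included).

    Topology by neighbor joining, branch lengths by nonnegative least
    squares to the 1-r distance matrix, serialized as Newick.  Raw counts
    are correlated by default; ``use_cpm`` normalizes per library first.
    """
    if len(libraries) < 3:
        raise ValueError("tree building requires at least 3 libraries")
    mat = (
        pd.DataFrame({lib.library_id: lib.to_series() for lib in libraries})
        .fillna(0.0)
    )
    if use_cpm:
        mat = 1e6 * mat / mat.sum(axis=0)
    if (mat.std(axis=0) == 0).any():
        bad = mat.columns[(mat.std(axis=0) == 0)].tolist()
        raise ValueError(f"constant library vector(s), correlation undefined: {bad}")
    r = mat.corr(method="pearson")
    d = 1.0 - r
    np.fill_diagonal(d.values, 0.0)
    return tree_from_distances(pd.DataFrame(d, index=d.index, columns=d.columns))


def has_clade(tree: TreeNode, leaf_names: Iterable[str]) -> bool:
    """True if the given leaves form a clade on the (unrooted) tree, i.e.
    some edge bipartition separates exactly that leaf set."""
    want = frozenset(leaf_names)
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=True):
        side = frozenset(t.name for t in node.tips())
        if side == want or (all_tips - side) == want:
            return True
    return False
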