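"""Jaccard similarity, UPGMA dendrograms, PCA and geographic PCoA.

The diversity-structure stage works on the binary band matrix: Jaccard
similarity between band profiles (shared bands / union of bands, over
mutually unmasked columns), average-linkage (UPGMA) clustering of the
one-minus-Jaccard distances, principal component analysis of the
variance-covariance matrix of band columns, and a classical-MDS principal
coordinate analysis of collection-site coordinates.

UPGMA conventions: merge height is half the average inter-cluster distance,
so the cophenetic distance between two leaves (twice the height of their
lowest common ancestor) equals the average-linkage distance at which their
clusters merged.  Tied minimum distances are broken toward the pair of
clusters with the lowest contained leaf indices, making trees reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import BandMatrix, ComputationError, ValidationError
from .popgen import DistanceMatrix

__all__ = [
    "Dendrogram",
    "OrdinationResult",
    "jaccard_similarity",
    "jaccard_distance",
    "upgma",
    "cophenetic_correlation",
    "pca_band",
    "pcoa_geographic",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Jaccard similarity on masked binary data
# ---------------------------------------------------------------------------

def jaccard_similarity(b: BandMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity of band profiles.

    S(i, j) = |bands present in both| / |bands present in either|, counted
    over mutually unmasked columns.  Raises if some pair shares no band at
    all (empty union).
    """
    if b.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    unmasked = ~b.mask
    present = ((b.values == 1) & unmasked).astype(float)
    inter = present @ present.T
    # columns where i carries the band and j's cell is unmasked
    p_vs_u = present @ unmasked.T.astype(float)
    union = p_vs_u + p_vs_u.T - inter
    off = ~np.eye(b.n_samples, dtype=bool)
    if (union[off] == 0).any():
        i, j = np.argwhere((union == 0) & off)[0]
        raise ComputationError(
            f"samples {b.sample_ids[i]!r} and {b.sample_ids[j]!r} have an "
            f"empty band union; Jaccard similarity undefined"
        )
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=b.sample_ids, columns=b.sample_ids)


def jaccard_distance(b: BandMatrix) -> DistanceMatrix:
    """One-minus-Jaccard genetic distance matrix."""
    sim = jaccard_similarity(b)
    d = 1.0 - sim.to_numpy()
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(sim.index), data=d, metric="one-minus-jaccard")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    height: float
    leaf: str | None = None
    children: tuple["_Node", "_Node"] | None = None

    def leaves(self) -> list[str]:
        if self.leaf is not None:
            return [self.leaf]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Rooted ultrametric binary merge tree from agglomerative clustering.

    ``merges`` records each agglomeration as (members_a, members_b, height)
    with leaf-index tuples; heights are non-decreasing and every leaf-to-root
    path has the same total height (ultrametric).
    """

    leaves: list[str]
    root: _Node
    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]]

    @property
    def height(self) -> float:
        return self.root.height

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 x LCA merge height)."""
        n = len(self.leaves)
        pos = {name: i for i, name in enumerate(self.leaves)}
        coph = np.zeros((n, n))

        def visit(node: _Node) -> list[int]:
            if node.leaf is not None:
                return [pos[node.leaf]]
            left = visit(node.children[0])
            right = visit(node.children[1])
            for i in left:
                for j in right:
                    coph[i, j] = coph[j, i] = 2.0 * node.height
            return left + right

        visit(self.root)
        return pd.DataFrame(coph, index=self.leaves, columns=self.leaves)

    def to_newick(self) -> str:
        """Newick string with branch lengths as height differences."""

        def fmt(node: _Node, parent_height: float) -> str:
            length = parent_height - node.height
            if node.leaf is not None:
                return f"{_newick_escape(node.leaf)}:{length:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{length:.10g}"

        a, b = self.root.children
        body = ",".join(fmt(c, self.root.height) for c in (a, b))
        return f"({body});"

    def cut_at_distance(self, threshold: float) -> pd.Series:
        """Cluster membership after applying merges at cophenetic distance
        <= threshold (i.e. cutting the tree at that distance)."""
        n = len(self.leaves)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for left, right, height in self.merges:
            if 2.0 * height <= threshold + 1e-12:
                ra, rb = find(left[0]), find(right[0])
                parent[rb] = ra
        roots: dict[int, int] = {}
        labels = []
        for i in range(n):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots) + 1
            labels.append(roots[r])
        return pd.Series(labels, index=self.leaves, name="cluster")

    def cut_at_similarity(self, similarity: float) -> pd.Series:
        """Cut a one-minus-similarity tree at a similarity level (e.g. 0.30)."""
        return self.cut_at_distance(1.0 - similarity)


def _newick_escape(name: str) -> str:
    if any(c in name for c in "(),:;' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration of a distance matrix.

    Merge height = average inter-cluster distance / 2 (ultrametric
    convention).  Ties are broken toward the candidate pair whose clusters
    contain the lowest leaf indices.
    """
    n = d.n
    if n < 2:
        raise ValidationError("need at least 2 samples to cluster")
    dist = d.data.astype(float).copy()
    nodes: dict[int, _Node] = {i: _Node(height=0.0, leaf=d.ids[i]) for i in range(n)}
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    active = list(range(n))
    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]] = []
    # dist is indexed by cluster id; grow it as clusters are created
    dmat = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                val = dmat[key]
                tie_key = tuple(sorted((min(members[i]), min(members[j]))))
                cand = (val, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dmin, _, i, j = best
        # keep (i, j) ordered so the lower-leaf cluster is the left child
        if min(members[j]) < min(members[i]):
            i, j = j, i
        height = dmin / 2.0
        new = _Node(height=height, children=(nodes[i], nodes[j]))
        merges.append((members[i], members[j], height))
        ni, nj = len(members[i]), len(members[j])
        for k in active:
            if k in (i, j):
                continue
            dik = dmat[(min(i, k), max(i, k))]
            djk = dmat[(min(j, k), max(j, k))]
            dmat[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        nodes[next_id] = new
        members[next_id] = tuple(sorted(members[i] + members[j]))
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Dendrogram(leaves=list(d.ids), root=nodes[active[0]], merges=merges)


def cophenetic_correlation(t: Dendrogram, d: DistanceMatrix) -> float:
    """Pearson correlation between cophenetic and input distances over pairs."""
    if set(t.leaves) != set(d.ids):
        raise ValidationError("dendrogram and distance matrix leaf sets differ")
    if len(t.leaves) <= 2:
        raise ComputationError("cophenetic correlation undefined for <= 2 leaves")
    coph = t.cophenetic_matrix().loc[d.ids, d.ids].to_numpy()
    iu = np.triu_indices(d.n, k=1)
    x, y = coph[iu], d.data[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("constant distances; correlation undefined")
    return float(pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Sample scores, eigenvalues and percent variance of an ordination."""

    scores: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    percent_variance: np.ndarray  # per axis, sums to 100 over all axes

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def pca_band(b: BandMatrix) -> OrdinationResult:
    """PCA of the band matrix on the variance-covariance matrix.

    Columns are centred but not standardised; masked cells are mean-imputed
    per column (with a warning).  Percent variance per axis is eigenvalue
    over the covariance trace.  Axis score signs are fixed so each axis's
    largest-magnitude loading is positive, making scores reproducible up to
    sample order.
    """
    if b.n_samples < 3:
        raise ValidationError("need at least 3 samples for PCA")
    if b.n_bands < 2:
        raise ValidationError("need at least 2 bands for PCA")
    x = b.values.astype(float)
    if b.mask.any():
        log.warning(
            "PCA input has %d masked cells; mean-imputing per band column",
            int(b.mask.sum()),
        )
        x = np.where(b.mask, np.nan, x)
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        x = np.where(np.isnan(x), col_mean[None, :], x)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # fix sign: largest-|loading| entry of each component made positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip
    eig = s**2 / (b.n_samples - 1)
    total = eig.sum()
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    scores = pd.DataFrame(
        u * s,
        index=b.sample_ids,
        columns=[f"PC{k + 1}" for k in range(len(s))],
    )
    return OrdinationResult(scores=scores, eigenvalues=eig, percent_variance=pct)


def pcoa_geographic(coords: pd.DataFrame) -> OrdinationResult:
    """Classical-MDS principal coordinate analysis of collection sites.

    ``coords`` must carry ``latitude``, ``longitude`` and ``altitude_m``
    columns indexed by sample id.  Samples with any missing coordinate are
    dropped with a warning.  Columns are z-scored (so metres and degrees are
    commensurable) and PCoA runs on their Euclidean distances via
    Gower double-centering (scikit-bio).
    """
    required = ["latitude", "longitude", "altitude_m"]
    missing_cols = [c for c in required if c not in coords.columns]
    if missing_cols:
        raise ValidationError(f"coordinates lack column(s) {missing_cols}")
    data = coords[required].astype(float)
    complete = data.dropna()
    dropped = set(data.index) - set(complete.index)
    if dropped:
        log.warning(
            "dropping %d sample(s) with missing coordinates: %s",
            len(dropped), sorted(dropped)[:5],
        )
    if complete.shape[0] < 3:
        raise ValidationError("need >= 3 samples with complete coordinates")
    z = complete.to_numpy()
    std = z.std(axis=0, ddof=1)
    std[std == 0] = 1.0
    z = (z - z.mean(axis=0)) / std
    dist = squareform(pdist(z, metric="euclidean"))
    res = _skbio_pcoa(dist, method="eigh")
    eig = res.eigvals.to_numpy()
    pct = 100.0 * res.proportion_explained.to_numpy()
    scores = pd.DataFrame(
        res.samples.to_numpy(),
        index=list(complete.index),
        columns=[f"PCo{k + 1}" for k in range(res.samples.shape[1])],
    )
    return OrdinationResult(scores=scores, eigenvalues=eig, percent_variance=pct)
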