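"""Linear discriminant analysis of spectra and group-overlap statistics.

Each spectrum is a point in 1117-dimensional Raman-shift space; linear
discriminant analysis (LDA) projects the labelled point cloud onto
``min(n_groups - 1, 2)`` Fisher discriminant axes — 1-D for a binary system
(e.g. two parental cell lines), 2-D for the three chromatography fractions.
Since samples are far fewer than features, the within-class scatter is
rank-deficient; the SVD-based solver handles this without explicit matrix
inversion.  Sign conventions (first nonzero loading positive, axes ordered
by discriminability) make scores reproducible run-to-run.

"Overlap" between groups quantifies how many vesicles of one group are
spectrally common with another:

* 1-D range rule — the share of group A scores lying within [min, max] of
  group B's scores;
* 2-D convex-hull rule — the share of A points inside B's score hull
  (boundary inclusive);
* classify rule — the share of A points whose nearest class centroid in
  score space is B's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import GridError, LDAError
from .spectra_io import SpectrumSet, WavenumberGrid

__all__ = [
    "LDAEmbedding",
    "OverlapReport",
    "fit_lda",
    "transform",
    "overlap_rate_range1d",
    "overlap_rate_hull2d",
    "overlap_rate_groups",
    "pooled_fraction_overlap",
]


@dataclass
class LDAEmbedding:
    """Per-spectrum discriminant scores with the fitted projection.

    scores
        (n_spectra, dims) array of LD coordinates, dims = min(n_groups-1, 2).
    projection
        (dims, n_points) loading vectors; score = (x - center) @ projection.T.
    class_means
        group label -> centroid in score space.
    """

    scores: np.ndarray
    labels: np.ndarray
    projection: np.ndarray
    center: np.ndarray
    class_means: dict
    grid: WavenumberGrid
    dims: int

    def group_scores(self, label) -> np.ndarray:
        return self.scores[self.labels == str(label)]

    @property
    def groups(self) -> list:
        seen = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class OverlapReport:
    """Overlap percentages between score groups.

    pairwise
        (group_i, group_j) -> percent of group_i points common with group_j.
    any_other
        group_i -> percent of its points common with at least one other group.
    per_fraction
        fraction -> percent (pooled two-cell-type analysis).
    """

    rule: str
    pairwise: dict = field(default_factory=dict)
    any_other: dict = field(default_factory=dict)
    per_fraction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.pairwise, self.any_other, self.per_fraction):
            for k, v in d.items():
                if not 0.0 <= v <= 100.0:
                    raise LDAError(f"overlap percent out of range for {k}: {v}")


def _fisher_directions(X: np.ndarray, labels: np.ndarray, uniq: np.ndarray,
                       dims: int):
    """Fisher discriminant loadings for n samples in p >= n dimensions.

    The data are first rotated into their SVD subspace (rank <= n - 1);
    there the within-class scatter W is eigendecomposed and inverted through
    a lightly regularized inverse square root (eigenvalues floored at
    1e-8 of the largest), which acts as a pseudo-inverse while keeping the
    null-space directions — the ones with zero within-class variance, where
    the training groups separate completely — usable.  The discriminant
    directions are the top eigenvectors of W^{-1/2} B W^{-1/2} mapped back
    to the full space, normalized to unit within-class variance.
    """
    xbar = X.mean(axis=0)
    Xc = X - xbar
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size and S[0] > 0 else 0
    if rank == 0:
        # all spectra identical: no discriminant information
        proj = np.zeros((dims, X.shape[1]))
        proj[:, :dims] = np.eye(dims)
        return proj, xbar
    V = Vt[:rank].T                      # (p, r)
    Z = Xc @ V                           # (n, r)
    r = rank
    W = np.zeros((r, r))
    B = np.zeros((r, r))
    for g in uniq:
        Zg = Z[labels == g]
        mu = Zg.mean(axis=0)
        D = Zg - mu
        W += D.T @ D
        B += Zg.shape[0] * np.outer(mu, mu)
    evals, Q = np.linalg.eigh(W)
    evals = np.clip(evals, 0.0, None)
    floor = max(evals.max(), 1e-300) * 1e-8
    inv_sqrt = Q @ np.diag(1.0 / np.sqrt(evals + floor)) @ Q.T
    M = inv_sqrt @ B @ inv_sqrt
    mvals, MV = np.linalg.eigh(M)
    order = np.argsort(mvals)[::-1][:dims]
    A = inv_sqrt @ MV[:, order]          # (r, dims), a^T W_reg a = 1
    return np.ascontiguousarray((V @ A).T), xbar


def _fix_signs(projection: np.ndarray, scores: np.ndarray):
    """Flip each discriminant axis so its first nonzero loading is positive."""
    for d in range(projection.shape[0]):
        v = projection[d]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            projection[d] = -v
            scores[:, d] = -scores[:, d]
    return projection, scores


def fit_lda(sset: SpectrumSet, labels) -> LDAEmbedding:
    """Fit Fisher LDA on a labelled spectrum set.

    Requires >= 2 groups with >= 2 spectra each.  Scores keep the input
    order; dims = min(n_groups - 1, 2).
    """
    labels = np.asarray([str(v) for v in labels])
    if len(sset) != labels.size:
        raise LDAError("labels length does not match number of spectra")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise LDAError("LDA needs at least 2 groups")
    small = uniq[counts < 2]
    if small.size:
        raise LDAError(f"groups with fewer than 2 spectra: {list(small)}")

    X = sset.intensity_matrix
    dims = min(uniq.size - 1, 2)
    projection, center = _fisher_directions(X, labels, uniq, dims)
    scores = (X - center) @ projection.T
    projection, scores = _fix_signs(projection, scores)
    class_means = {g: scores[labels == g].mean(axis=0) for g in uniq}
    return LDAEmbedding(
        scores=scores,
        labels=labels,
        projection=projection,
        center=center,
        class_means=class_means,
        grid=sset.grid,
        dims=dims,
    )


def transform(embedding: LDAEmbedding, sset: SpectrumSet) -> np.ndarray:
    """Project new spectra (same grid) into the embedding's score space."""
    if sset.grid != embedding.grid:
        raise GridError("spectrum grid does not match the LDA training grid")
    X = sset.intensity_matrix
    return (X - embedding.center) @ embedding.projection.T


def overlap_rate_range1d(scores_a, scores_b) -> float:
    """Percent of A's 1-D scores falling within [min(B), max(B)]."""
    a = np.ravel(np.asarray(scores_a, dtype=float))
    b = np.ravel(np.asarray(scores_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise LDAError("overlap_rate_range1d requires non-empty score sets")
    inside = (a >= b.min()) & (a <= b.max())
    return 100.0 * float(inside.mean())


def _points_in_hull(points: np.ndarray, hull_points: np.ndarray,
                    tol: float = 1e-9) -> np.ndarray:
    """Boundary-inclusive membership of 2-D points in the convex hull of
    ``hull_points``; degenerate hulls (a point or a segment) fall back to
    distance tests on the affine span."""
    points = np.atleast_2d(points)
    scale = max(1.0, float(np.abs(hull_points).max()))
    try:
        hull = ConvexHull(hull_points)
    except QhullError:
        c = hull_points.mean(axis=0)
        d = hull_points - c
        _, sv, vt = np.linalg.svd(d, full_matrices=False)
        eps = tol * scale
        if sv.size == 0 or sv[0] <= eps:  # all points coincide
            return np.all(np.abs(points - c) <= eps, axis=1)
        v = vt[0]
        t = d @ v
        proj = (points - c) @ v
        perp = (points - c) - np.outer(proj, v)
        return (
            (np.linalg.norm(perp, axis=1) <= eps)
            & (proj >= t.min() - eps)
            & (proj <= t.max() + eps)
        )
    A = hull.equations[:, :-1]
    b = hull.equations[:, -1]
    return np.all(points @ A.T + b <= tol * scale, axis=1)


def overlap_rate_hull2d(scores_a, scores_b) -> float:
    """Percent of A's 2-D scores inside the convex hull of B's scores
    (boundary inclusive).  B needs at least 3 points."""
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise LDAError("overlap_rate_hull2d requires non-empty score sets")
    if b.shape[0] < 3:
        raise LDAError("convex hull undefined for a group with fewer than 3 points")
    return 100.0 * float(_points_in_hull(a, b).mean())


def _classify_membership(embedding: LDAEmbedding, pts: np.ndarray,
                         group: str) -> np.ndarray:
    """Nearest-class-centroid assignment in score space."""
    centroids = {g: np.atleast_1d(m) for g, m in embedding.class_means.items()}
    names = sorted(centroids)
    dists = np.stack(
        [np.linalg.norm(np.atleast_2d(pts) - centroids[g], axis=1) for g in names]
    )
    assigned = np.array(names)[np.argmin(dists, axis=0)]
    return assigned == group


def overlap_rate_groups(embedding: LDAEmbedding, rule: str | None = None) -> OverlapReport:
    """Pairwise group-overlap report for an embedding.

    Default rule: 'hull2d' for 2-D embeddings, 'range1d' for 1-D.  The
    'classify' rule assigns each point to its nearest class centroid, so
    a point counts as common with at most one other group.
    """
    if rule is None:
        rule = "hull2d" if embedding.dims == 2 else "range1d"
    groups = embedding.groups
    if len(groups) < 2:
        raise LDAError("overlap report needs at least 2 groups")
    pairwise = {}
    any_other = {}
    for gi in groups:
        pts_i = embedding.group_scores(gi)
        common_any = np.zeros(pts_i.shape[0], dtype=bool)
        for gj in groups:
            if gj == gi:
                continue
            pts_j = embedding.group_scores(gj)
            if rule == "range1d":
                if embedding.dims != 1:
                    raise LDAError("range1d rule requires a 1-D embedding")
                member = (pts_i[:, 0] >= pts_j[:, 0].min()) & (pts_i[:, 0] <= pts_j[:, 0].max())
            elif rule == "hull2d":
                if embedding.dims != 2:
                    raise LDAError("hull2d rule requires a 2-D embedding")
                if pts_j.shape[0] < 3:
                    raise LDAError(
                        f"group {gj} has fewer than 3 points; hull undefined"
                    )
                member = _points_in_hull(pts_i, pts_j)
            elif rule == "classify":
                member = _classify_membership(embedding, pts_i, gj)
            else:
                raise ValueError(f"unknown overlap rule {rule!r}")
            pairwise[(gi, gj)] = 100.0 * float(member.mean())
            common_any |= member
        any_other[gi] = 100.0 * float(common_any.mean())
    return OverlapReport(rule=rule, pairwise=pairwise, any_other=any_other)


def pooled_fraction_overlap(set_ref: SpectrumSet, set_test: SpectrumSet,
                            fraction_labels=None,
                            fraction_key: str = "fraction") -> OverlapReport:
    """Pooled two-cell-type analysis.

    Spectra of both cell types (all fractions pooled) are embedded by a
    binary 1-D LDA on cell type; for each fraction of the *test* cell type,
    the report gives the share of its scores falling within the score range
    of the whole *reference* cell type — the vesicles whose fingerprints
    are common with the reference population.
    """
    if fraction_labels is None:
        fraction_labels = set_test.labels(fraction_key)
    fraction_labels = np.asarray([str(v) for v in fraction_labels])
    if fraction_labels.size != len(set_test):
        raise LDAError("fraction_labels length does not match test set")
    pooled = SpectrumSet(list(set_ref) + list(set_test))
    cell_labels = ["ref"] * len(set_ref) + ["test"] * len(set_test)
    emb = fit_lda(pooled, cell_labels)
    scores = emb.scores[:, 0]
    ref_scores = scores[: len(set_ref)]
    test_scores = scores[len(set_ref):]
    per_fraction = {}
    for frac in sorted(set(fraction_labels)):
        sel = fraction_labels == frac
        per_fraction[frac] = overlap_rate_range1d(test_scores[sel], ref_scores)
    return OverlapReport(rule="range1d", per_fraction=per_fraction)
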