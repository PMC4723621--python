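"""Unsupervised exploration: PCA with cross-validated rank, Ward HCA.

PCA is SVD-based on the autoscaled fused matrix. The number of significant
components is chosen by element-wise 7-fold cross-validation: matrix entries
are partitioned into folds, each fold is treated as missing in turn and
reconstructed by a rank-1 EM fit of the current residual matrix, and a
component is accepted while its predictive Q^2 exceeds a configurable limit
(0.05 by default). This is the standard chemometrics recipe behind
"significant PCs by cross validation"; the exact rule used by commercial
packages is proprietary, so both the fold count and the limit are exposed.

Clustering is agglomerative with Euclidean distance and Ward's linkage
(Ward.D2 semantics: squared distances in the objective, merge heights on
the distance scale), delegated to scipy. Tie-breaking between equal merge
heights follows scipy's nearest-neighbor chain order; with continuous data
exact ties are measure-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

__all__ = [
    "PCAModel",
    "Dendrogram",
    "pca_fit",
    "select_significant_pcs",
    "hierarchical_cluster",
    "cut_first_split",
    "dendrogram_to_newick",
]


@dataclass
class PCAModel:
    """SVD-based PCA of a centered/scaled matrix."""

    scores: np.ndarray                       # (n, A)
    loadings: np.ndarray                     # (p, A)
    singular_values: np.ndarray              # (A,)
    explained_variance_fraction: np.ndarray  # (A,) sigma_k^2 / sum sigma^2
    n_significant: int | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T


def pca_fit(X: np.ndarray, max_components: int | None = None) -> PCAModel:
    """Fit PCA by SVD of an autoscaled (or at least centered) matrix.

    Explained fractions are relative to the total variance of X (all
    singular values), not just the retained ones. Loading signs are fixed so
    each loading vector's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    limit = min(n - 1, p) if n > 1 else p
    if max_components is None:
        max_components = limit
    if max_components > limit or max_components < 1:
        raise ValueError(f"max_components must be in [1, {limit}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    A = max_components
    loadings = Vt[:A].T.copy()
    scores = U[:, :A] * s[:A]
    # deterministic sign: largest-|entry| of each loading positive
    for a in range(A):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PCAModel(
        scores=scores,
        loadings=loadings,
        singular_values=s[:A].copy(),
        explained_variance_fraction=frac[:A].copy(),
    )


def _rank1_em(E: np.ndarray, mask: np.ndarray, max_iter: int = 50, tol: float = 1e-7):
    """Leading rank-1 approximation of E with ``mask`` entries missing.

    EM scheme: impute missing entries with the current rank-1 estimate
    (starting from 0, the residual's expected value), take the leading
    singular triplet of the completed matrix, repeat. Returns the rank-1
    approximation matrix.
    """
    F = E.copy()
    F[mask] = 0.0
    approx = np.zeros_like(E)
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(F, full_matrices=False)
        new_approx = s[0] * np.outer(U[:, 0], Vt[0])
        delta = np.abs(new_approx[mask] - approx[mask]).max() if mask.any() else 0.0
        approx = new_approx
        F = E.copy()
        F[mask] = approx[mask]
        if delta <= tol * (np.abs(E).max() + 1e-30):
            break
    return approx


def select_significant_pcs(
    X: np.ndarray,
    max_components: int,
    folds: int = 7,
    seed: int = 0,
    q2_limit: float = 0.05,
) -> int:
    """Number of significant components by element-wise cross-validation.

    Components are tested sequentially on the deflated residual. For
    component a, entries of the residual are split into ``folds`` random
    groups; each group is masked, reconstructed by a rank-1 EM fit, and its
    prediction error accumulated into PRESS. The component is significant
    when Q^2 = 1 - PRESS / RSS(previous residual) exceeds ``q2_limit``.
    Testing stops at the first non-significant component.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if max_components > min(n - 1, p):
        raise ValueError("max_components exceeds matrix rank bound")
    rng = np.random.default_rng(seed)
    fold_of = rng.permuted(np.arange(n * p) % folds).reshape(n, p)
    E = X.copy()
    n_sig = 0
    for _ in range(max_components):
        rss = float(np.sum(E**2))
        if rss <= 0:
            break
        press = 0.0
        for f in range(folds):
            mask = fold_of == f
            approx = _rank1_em(E, mask)
            press += float(np.sum((approx[mask] - E[mask]) ** 2))
        q2 = 1.0 - press / rss
        if q2 <= q2_limit:
            break
        n_sig += 1
        U, s, Vt = np.linalg.svd(E, full_matrices=False)
        E = E - s[0] * np.outer(U[:, 0], Vt[0])
    return n_sig


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format merge list plus leaf labels.

    ``merges`` row k holds the two cluster indices joined at step k (leaves
    are 0..n-1, internal nodes n, n+1, ...); ``heights`` are the Ward merge
    heights on the Euclidean distance scale.
    """

    merges: np.ndarray    # (n-1, 2) int
    heights: np.ndarray   # (n-1,)
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """scipy linkage matrix (with cluster sizes recomputed)."""
        n = self.n_leaves
        sizes = np.ones(2 * n - 1)
        Z = np.zeros((n - 1, 4))
        for k in range(n - 1):
            a, b = self.merges[k]
            sizes[n + k] = sizes[a] + sizes[b]
            Z[k] = [a, b, self.heights[k], sizes[n + k]]
        return Z


def hierarchical_cluster(
    X: np.ndarray,
    labels: list[str] | None = None,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> Dendrogram:
    """Agglomerative clustering; defaults to Euclidean distance + Ward.

    Heights follow Ward.D2 semantics: the objective minimizes the increase
    in within-cluster sum of squares, and merge heights are reported on the
    Euclidean distance scale (monotone non-decreasing).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if labels is None:
        labels = [f"sample{i}" for i in range(X.shape[0])]
    if len(labels) != X.shape[0]:
        raise ValueError("labels length must match the number of samples")
    Z = hierarchy.linkage(X, method=linkage, metric=distance)
    return Dendrogram(
        merges=Z[:, :2].astype(int), heights=Z[:, 2].copy(), labels=list(labels)
    )


def _leaves_under(d: Dendrogram, node: int) -> list[int]:
    n = d.n_leaves
    stack = [node]
    out = []
    while stack:
        k = stack.pop()
        if k < n:
            out.append(k)
        else:
            a, b = d.merges[k - n]
            stack.extend((int(a), int(b)))
    return sorted(out)


def cut_first_split(d: Dendrogram) -> tuple[list[str], list[str]]:
    """The two leaf-label sets under the dendrogram root."""
    n = d.n_leaves
    a, b = d.merges[-1]
    left = [d.labels[i] for i in _leaves_under(d, int(a))]
    right = [d.labels[i] for i in _leaves_under(d, int(b))]
    return left, right


def dendrogram_to_newick(d: Dendrogram, fmt: str = "%.10g") -> str:
    """Render a dendrogram as a Newick string with ultrametric branch lengths.

    A node merged at height h sits at depth h/2 from the leaves, so two
    leaves joined at height h read ``(A:h/2,B:h/2);`` and every leaf has the
    same root-to-leaf depth.
    """
    n = d.n_leaves
    node_height = np.zeros(2 * n - 1)
    node_height[n:] = d.heights

    def render(node: int) -> str:
        if node < n:
            return _escape(d.labels[node])
        a, b = (int(x) for x in d.merges[node - n])
        h = node_height[node]
        parts = []
        for child in (a, b):
            bl = (h - node_height[child]) / 2.0
            parts.append(f"{render(child)}:{fmt % bl}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"


def _escape(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
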