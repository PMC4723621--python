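"""Double cross-validated PLS-DA, permutation testing, rank products.

The double (two-nested leave-one-out) cross-validation sets each sample
aside in turn; the remaining samples choose the latent-variable count by an
inner leave-one-out loop, a PLS-DA model is refitted with that count, and
the left-out sample is classified by a model that never saw it. Autoscaling
parameters are recomputed on every training fold and applied to the held-out
sample, so no information leaks from it into the model.

The misclassification count M over the n outer predictions is the test
statistic. Its null distribution comes from a permutation test: class labels
are shuffled (class sizes preserved) and the *entire* double CV — including
inner component selection — is re-run per permutation. The p-value uses the
add-one formula p = (1 + #{null M <= observed M}) / (1 + n_permutations).

Variable importance: the n outer models each yield a coefficient matrix B;
within each model the variables are ranked by descending |B| per class
(rank 1 = largest), and the n ranks are combined multiplicatively into a
rank product, computed as a sum of log-ranks to avoid overflow. Variables
with a low rank product were consistently near the top of the coefficient
list and are reported as the discriminators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import _kernels
from .discriminant import dummy_code

__all__ = [
    "DoubleCVResult",
    "PermutationResult",
    "RankProductTable",
    "inner_loo_select_ncomp",
    "double_cv",
    "permutation_test",
    "rank_products",
    "compute_class_stats",
    "summarize_discriminators",
]


def default_a_max(n_train: int, p: int, cap: int = 10) -> int:
    """Conventional ceiling on latent variables: min(n_train - 2, p, cap)."""
    return max(1, min(n_train - 2, p, cap))


@dataclass
class DoubleCVResult:
    """Per-left-out-sample predictions and models from the outer loop."""

    sample_ids: list[str]
    class_order: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    selected_ncomp: np.ndarray     # (n,)
    coefs: np.ndarray              # (n, p, K) coefficient matrix per model
    predictions: np.ndarray        # (n, K) continuous predictions
    variable_names: list[str] | None = None

    @property
    def n_misclassified(self) -> int:
        return sum(t != p for t, p in zip(self.true_labels, self.predicted_labels))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class PermutationResult:
    """Observed M, its permutation null, and the add-one p-value."""

    observed: int
    null_misclassifications: np.ndarray
    n_permutations: int
    seed: int

    @property
    def p_value(self) -> float:
        return (1 + int(np.sum(self.null_misclassifications <= self.observed))) / (
            1 + self.n_permutations
        )


def _validate_labels(labels: list[str], class_order: list[str] | None):
    if class_order is None:
        class_order = sorted(set(labels))
    counts = {c: labels.count(c) for c in class_order}
    present = [c for c in class_order if counts[c] > 0]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present")
    return class_order, counts


def inner_loo_select_ncomp(
    X_train: np.ndarray, y_train: list[str] | np.ndarray, a_max: int,
    class_order: list[str] | None = None,
) -> int:
    """Latent-variable count minimizing inner LOO misclassifications.

    Each inner fold rescales X on its own training rows. Ties in the
    misclassification count go to the smallest count of components.
    """
    X_train = np.asarray(X_train, dtype=float)
    n, p = X_train.shape
    if n < 3:
        raise ValueError(f"inner cross-validation needs >= 3 samples, got {n}")
    if isinstance(y_train, np.ndarray) and y_train.ndim == 2:
        Y = y_train.astype(float)
    else:
        labels = list(y_train)
        class_order, _ = _validate_labels(labels, class_order)
        Y = dummy_code(labels, class_order).indicator
    if not 1 <= a_max <= min(n - 2, p):
        raise ValueError(f"a_max must be in [1, {min(n - 2, p)}]")
    return int(_kernels.inner_loo_select(X_train, Y, a_max))


def double_cv(
    X: np.ndarray,
    labels: list[str],
    a_max: int | None = None,
    class_order: list[str] | None = None,
    sample_ids: list[str] | None = None,
    variable_names: list[str] | None = None,
    compute_coefs: bool = True,
) -> DoubleCVResult:
    """Two-nested leave-one-out cross-validated PLS-DA.

    Returns one model and one prediction per sample; the held-out sample is
    scaled with its training fold's parameters and never participates in
    scaling, component selection, or fitting.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("labels length must match the number of samples")
    if n < 3:
        raise ValueError("double cross-validation needs >= 3 samples")
    class_order, counts = _validate_labels(labels, class_order)
    singletons = [c for c in class_order if counts.get(c, 0) == 1]
    if singletons:
        i = labels.index(singletons[0])
        raise ValueError(
            f"outer fold leaving out sample {i} would lose class "
            f"{singletons[0]!r} entirely"
        )
    if a_max is None:
        a_max = default_a_max(n - 1, p)
    Y = dummy_code(labels, class_order).indicator
    pred_idx, sel, B_all, yhat = _kernels.double_cv_kernel(
        X, Y, int(a_max), compute_coefs
    )
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]
    return DoubleCVResult(
        sample_ids=list(sample_ids),
        class_order=list(class_order),
        true_labels=labels,
        predicted_labels=[class_order[i] for i in pred_idx],
        selected_ncomp=np.asarray(sel),
        coefs=B_all if compute_coefs else np.zeros((n, 0, len(class_order))),
        predictions=yhat,
        variable_names=variable_names,
    )


def permutation_test(
    X: np.ndarray,
    labels: list[str],
    a_max: int | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    class_order: list[str] | None = None,
    observed: DoubleCVResult | None = None,
) -> PermutationResult:
    """Permutation null of the double-CV misclassification count.

    Labels are shuffled with class sizes preserved and the full double CV
    (inner selection included) is re-run for each permutation. A permutation
    that fails (degenerate fold) is resampled once before erroring.
    ``observed`` allows reusing an already-computed result on true labels.
    """
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19")
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    class_order, _ = _validate_labels(labels, class_order)
    if observed is None:
        observed = double_cv(X, labels, a_max, class_order, compute_coefs=False)
    n = len(labels)
    if a_max is None:
        a_max = default_a_max(n - 1, X.shape[1])
    Y = dummy_code(labels, class_order).indicator
    rng = np.random.default_rng(seed)
    null_ms = np.empty(n_permutations, dtype=int)
    for b in range(n_permutations):
        for attempt in range(2):
            perm = rng.permutation(n)
            try:
                pred_idx, _, _, _ = _kernels.double_cv_kernel(
                    X, Y[perm], int(a_max), False
                )
                true_idx = np.argmax(Y[perm], axis=1)
                null_ms[b] = int(np.sum(pred_idx != true_idx))
                break
            except Exception:
                if attempt == 1:
                    raise
    return PermutationResult(
        observed=observed.n_misclassified,
        null_misclassifications=null_ms,
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class RankProductTable:
    """Per-variable, per-class rank summaries across the n outer models."""

    variable_names: list[str]
    class_order: list[str]
    log_rank_sum: np.ndarray     # (p, K) sum of log ranks (monotone in the product)
    geo_mean_rank: np.ndarray    # (p, K) exp(mean log rank), in [1, p]
    ranks: np.ndarray            # (n_models, p, K) per-model ranks

    def ordering(self, class_index: int = 0) -> np.ndarray:
        """Variable indices sorted by ascending rank product (most important first)."""
        return np.argsort(self.log_rank_sum[:, class_index], kind="stable")

    def to_dataframe(self, class_index: int = 0) -> pd.DataFrame:
        order = self.ordering(class_index)
        return pd.DataFrame(
            {
                "variable": [self.variable_names[j] for j in order],
                "geo_mean_rank": self.geo_mean_rank[order, class_index],
                "log_rank_sum": self.log_rank_sum[order, class_index],
            }
        )


def rank_products(result: DoubleCVResult) -> RankProductTable:
    """Combine per-model coefficient ranks into rank products.

    Within each of the n models, variables are ranked per class column by
    descending |B| (rank 1 = largest absolute coefficient; ties receive
    average ranks). Products over models are reported as log-rank sums plus
    the geometric-mean rank exp(mean log rank).
    """
    B = result.coefs
    if B.ndim != 3 or B.shape[1] == 0:
        raise ValueError("result holds no coefficient matrices")
    n_models, p, K = B.shape
    ranks = np.empty((n_models, p, K))
    for m in range(n_models):
        for k in range(K):
            ranks[m, :, k] = rankdata(-np.abs(B[m, :, k]), method="average")
    log_sum = np.log(ranks).sum(axis=0)
    geo = np.exp(log_sum / n_models)
    names = result.variable_names or [f"var{j}" for j in range(p)]
    return RankProductTable(
        variable_names=list(names),
        class_order=list(result.class_order),
        log_rank_sum=log_sum,
        geo_mean_rank=geo,
        ranks=ranks,
    )


def compute_class_stats(
    X_raw: np.ndarray, labels: list[str], class_order: list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class raw-scale mean and SD (ddof=1) for every variable."""
    X_raw = np.asarray(X_raw, dtype=float)
    labels = np.asarray(labels)
    out = {}
    for c in class_order:
        sub = X_raw[labels == c]
        sd = sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else np.zeros(X_raw.shape[1])
        out[c] = (sub.mean(axis=0), sd)
    return out


def summarize_discriminators(
    rp: RankProductTable,
    class_stats: dict[str, tuple[np.ndarray, np.ndarray]],
    top_k: int = 10,
    class_index: int = 0,
) -> pd.DataFrame:
    """Report table of the top-k discriminators with per-class raw stats.

    One row per variable, ascending rank product; per class a raw-scale mean
    and SD column plus a higher/lower flag marking where each variable is
    most abundant (the table's red/blue coding).
    """
    order = rp.ordering(class_index)[:top_k]
    rows = []
    for j in order:
        row: dict[str, object] = {
            "variable": rp.variable_names[j],
            "geo_mean_rank": rp.geo_mean_rank[j, class_index],
        }
        means = {c: class_stats[c][0][j] for c in rp.class_order}
        top_class = max(means, key=lambda c: means[c])
        for c in rp.class_order:
            row[f"mean_{c}"] = class_stats[c][0][j]
            row[f"sd_{c}"] = class_stats[c][1][j]
            row[f"level_{c}"] = "higher" if c == top_class else "lower"
        rows.append(row)
    return pd.DataFrame(rows)
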