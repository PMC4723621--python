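"""Multi-block fusion: sample alignment, autoscaling, concatenation.

Each analytical platform delivers a complete samples x variables intensity
matrix (a :class:`FeatureBlock`). Fusion restricts all blocks to the common
sample set, autoscales every variable (mean 0, unit sample SD) so that
platforms with very different intensity scales contribute equally, and
concatenates the blocks column-wise into one :class:`FusedMatrix` that keeps
per-column platform provenance.

Autoscaling of the full matrix is intended for unsupervised exploration
(PCA, HCA). Supervised cross-validation recomputes scaling parameters on
each training fold (see :mod:`metabofuse.validation`) to avoid leaking the
held-out sample into the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FeatureBlock", "FusedMatrix", "align_samples", "autoscale", "concatenate_blocks"]


@dataclass
class FeatureBlock:
    """One platform's samples x variables intensity matrix."""

    platform: str
    sample_ids: list[str]
    variable_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"block {self.platform!r}: {n} rows but {len(self.sample_ids)} sample IDs"
            )
        if p != len(self.variable_names):
            raise ValueError(
                f"block {self.platform!r}: {p} columns but {len(self.variable_names)} variable names"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"block {self.platform!r}: duplicate sample IDs")
        if len(set(self.variable_names)) != p:
            raise ValueError(f"block {self.platform!r}: duplicate variable names")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.platform!r}: non-finite value at sample "
                f"{self.sample_ids[i]!r}, variable {self.variable_names[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_names
        )


@dataclass
class FusedMatrix:
    """Column-concatenated multi-block matrix with per-column provenance.

    ``columns`` holds (platform, variable-name) pairs; ``col_means`` and
    ``col_sds`` are the autoscaling parameters computed on the full matrix
    (identity parameters when built with ``scale=False``).
    """

    sample_ids: list[str]
    columns: list[tuple[str, str]]
    values: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    scaled: bool = True

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def platforms(self) -> list[str]:
        seen: dict[str, None] = {}
        for plat, _ in self.columns:
            seen.setdefault(plat)
        return list(seen)

    def platform_slice(self, platform: str) -> np.ndarray:
        idx = [j for j, (plat, _) in enumerate(self.columns) if plat == platform]
        return self.values[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["platform", "variable"])
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


def align_samples(blocks: list[FeatureBlock]) -> list[FeatureBlock]:
    """Restrict all blocks to the shared sample IDs, in a common order.

    The canonical order is the first block's order restricted to the
    intersection. Samples dropped from any block are logged as a warning.
    """
    if not blocks:
        raise ValueError("need at least one block")
    common = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if not common:
        raise ValueError("sample ID intersection across blocks is empty")
    order = [s for s in blocks[0].sample_ids if s in common]
    aligned = []
    for b in blocks:
        dropped = [s for s in b.sample_ids if s not in common]
        if dropped:
            logger.warning(
                "align_samples: dropping %d sample(s) from block %r: %s",
                len(dropped), b.platform, ", ".join(dropped),
            )
        pos = {s: i for i, s in enumerate(b.sample_ids)}
        idx = [pos[s] for s in order]
        aligned.append(
            FeatureBlock(b.platform, list(order), list(b.variable_names), b.values[idx])
        )
    return aligned


def autoscale(matrix: np.ndarray, variable_names: list[str] | None = None):
    """Autoscale columns to mean 0 / unit sample SD (n-1 denominator).

    Zero-variance columns are removed first (autoscaling is undefined for
    them and they carry no information); the removal is logged. Returns
    ``(scaled, means, sds, kept)`` where ``kept`` is the boolean column mask.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    kept = sds > 0
    if not np.all(kept):
        names = (
            [variable_names[j] for j in np.flatnonzero(~kept)]
            if variable_names is not None
            else [str(j) for j in np.flatnonzero(~kept)]
        )
        logger.warning(
            "autoscale: removing %d zero-variance column(s): %s",
            len(names), ", ".join(names[:10]) + ("..." if len(names) > 10 else ""),
        )
    scaled = (X[:, kept] - means[kept]) / sds[kept]
    return scaled, means[kept], sds[kept], kept


def concatenate_blocks(blocks: list[FeatureBlock], scale: bool = True) -> FusedMatrix:
    """Concatenate aligned blocks column-wise into a :class:`FusedMatrix`.

    With ``scale=True`` every variable is autoscaled on the full matrix
    (zero-variance variables removed). Blocks must already share sample IDs
    and order; use :func:`align_samples` first.
    """
    if not blocks:
        raise ValueError("need at least one block")
    ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids:
            raise ValueError(
                f"block {b.platform!r} is not aligned with {blocks[0].platform!r}; "
                "run align_samples first"
            )
    parts = []
    columns: list[tuple[str, str]] = []
    means_parts = []
    sds_parts = []
    for b in blocks:
        if scale:
            scaled, mean, sd, kept = autoscale(b.values, b.variable_names)
            parts.append(scaled)
            kept_names = [n for n, k in zip(b.variable_names, kept) if k]
            columns.extend((b.platform, n) for n in kept_names)
            means_parts.append(mean)
            sds_parts.append(sd)
        else:
            parts.append(b.values)
            columns.extend((b.platform, n) for n in b.variable_names)
            means_parts.append(np.zeros(b.n_variables))
            sds_parts.append(np.ones(b.n_variables))
    return FusedMatrix(
        sample_ids=list(ids),
        columns=columns,
        values=np.hstack(parts),
        col_means=np.concatenate(means_parts),
        col_sds=np.concatenate(sds_parts),
        scaled=scale,
    )
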