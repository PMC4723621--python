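"""End-to-end orchestration: simulate -> fuse -> PCA/HCA -> double-CV PLS-DA.

`run_pipeline` either generates the six synthetic platform blocks or loads
blocks from disk, fuses them, runs the unsupervised overview and the double
cross-validated PLS-DA with permutation test and rank products, and writes
every artifact as delimited text plus a YAML manifest. Outputs are
byte-reproducible from config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .fusion import align_samples, concatenate_blocks
from .synthdata import SimulationConfig, generate_feature_blocks, generate_metadata
from .unsupervised import (
    cut_first_split,
    dendrogram_to_newick,
    hierarchical_cluster,
    pca_fit,
    select_significant_pcs,
)
from .validation import (
    compute_class_stats,
    double_cv,
    permutation_test,
    rank_products,
    summarize_discriminators,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class RunConfig:
    """Paths and analysis parameters for one pipeline run."""

    outdir: str | Path = "results/run"
    seed: int = 0
    # inputs: either paths to existing blocks + metadata, or a simulation
    block_paths: list[str] | None = None
    metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    # comparison definition
    class_column: str = "class"
    included_levels: list[str] | None = None
    # analysis parameters
    a_max: int | None = None
    n_permutations: int = 199
    pca_max_components: int = 10
    cv_folds: int = 7
    q2_limit: float = 0.05
    top_k: int = 10

    def validate(self) -> None:
        if self.block_paths is not None:
            missing = [p for p in self.block_paths if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"block path does not exist: {missing[0]}")
            if self.metadata_path is None or not Path(self.metadata_path).exists():
                raise FileNotFoundError("metadata_path must exist when loading blocks")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


@_stage("input")
def _load_inputs(config: RunConfig):
    if config.block_paths is not None:
        blocks = [io.read_feature_block(p) for p in config.block_paths]
        meta = io.read_metadata(config.metadata_path)
        return blocks, meta, None
    sim = config.simulation or SimulationConfig(seed=config.seed)
    blocks, truth = generate_feature_blocks(sim)
    meta = generate_metadata(sim)
    return blocks, meta, truth


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes artifacts."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks, meta, truth = _load_inputs(config)

    @_stage("fuse")
    def _fuse():
        aligned = align_samples(blocks)
        return concatenate_blocks(aligned, scale=True)

    fused = _fuse()
    io.write_fused_matrix(fused, outdir / "fused_matrix.tsv")
    if truth is not None:
        io.write_ground_truth(truth, outdir / "ground_truth.yaml")
    io.write_metadata(meta, outdir / "metadata.tsv")

    meta = meta.set_index("sample_id").loc[fused.sample_ids].reset_index()
    if config.class_column not in meta.columns:
        raise PipelineError(f"[compare] metadata lacks column {config.class_column!r}")
    labels_all = meta[config.class_column].astype(str).tolist()
    if config.included_levels is not None:
        keep = [i for i, l in enumerate(labels_all) if l in config.included_levels]
        if not keep:
            raise PipelineError("[compare] included_levels select no samples")
    else:
        keep = list(range(len(labels_all)))
    labels = [labels_all[i] for i in keep]
    X = fused.values[keep]
    ids = [fused.sample_ids[i] for i in keep]

    @_stage("pca")
    def _pca():
        max_c = min(config.pca_max_components, len(ids) - 1, X.shape[1])
        model = pca_fit(X, max_c)
        model.n_significant = select_significant_pcs(
            X, max_c, folds=config.cv_folds, seed=config.seed,
            q2_limit=config.q2_limit,
        )
        return model

    pca = _pca()
    scores = pd.DataFrame(
        pca.scores, index=pd.Index(ids, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(pca.n_components)],
    )
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t", float_format=io.REPORT_FLOAT_FORMAT)
    pd.DataFrame(
        {
            "component": [f"PC{k + 1}" for k in range(pca.n_components)],
            "explained_variance_pct": 100 * pca.explained_variance_fraction,
        }
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False,
             float_format=io.REPORT_FLOAT_FORMAT)

    @_stage("hca")
    def _hca():
        return hierarchical_cluster(X, labels=ids)

    dendro = _hca()
    (outdir / "dendrogram.nwk").write_text(dendrogram_to_newick(dendro) + "\n")

    @_stage("plsda-dcv")
    def _dcv():
        result = double_cv(
            X, labels, a_max=config.a_max, sample_ids=ids,
            variable_names=[f"{p}:{v}" if not v.startswith(p) else v
                            for p, v in fused.columns],
        )
        perm = permutation_test(
            X, labels, a_max=config.a_max,
            n_permutations=config.n_permutations, seed=config.seed,
            observed=result,
        )
        return result, perm

    result, perm = _dcv()
    pd.DataFrame(
        {
            "sample_id": result.sample_ids,
            "true_class": result.true_labels,
            "predicted_class": result.predicted_labels,
            "n_components": result.selected_ncomp,
        }
    ).to_csv(outdir / "dcv_predictions.tsv", sep="\t", index=False)

    @_stage("report")
    def _report():
        rp = rank_products(result)
        stats = compute_class_stats(X, labels, result.class_order)
        return rp, summarize_discriminators(rp, stats, top_k=config.top_k)

    rp, report = _report()
    report.to_csv(outdir / "rank_product_report.tsv", sep="\t", index=False,
                  float_format=io.REPORT_FLOAT_FORMAT)
    rp.to_dataframe().to_csv(outdir / "rank_products.tsv", sep="\t", index=False,
                             float_format=io.REPORT_FLOAT_FORMAT)

    left, right = cut_first_split(dendro)
    summary = {
        "n_samples": len(ids),
        "n_variables": fused.n_variables,
        "n_significant_pcs": int(pca.n_significant),
        "pc_variance_pct": [float(100 * f) for f in pca.explained_variance_fraction[:3]],
        "misclassifications": int(result.n_misclassified),
        "permutation_p": float(perm.p_value),
        "n_permutations": int(config.n_permutations),
        "first_split_sizes": [len(left), len(right)],
        "seed": int(config.seed),
    }
    io.write_manifest(
        {
            "parameters": {
                "class_column": config.class_column,
                "included_levels": config.included_levels,
                "a_max": config.a_max,
                "n_permutations": config.n_permutations,
                "cv_folds": config.cv_folds,
                "q2_limit": config.q2_limit,
                "seed": config.seed,
            },
            "summary": summary,
        },
        outdir / "manifest.yaml",
    )
    return summary
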