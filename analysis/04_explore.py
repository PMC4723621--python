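"""Unsupervised overview: PCA with cross-validated rank, Ward HCA.

Fits PCA on the fused matrix, selects the number of significant
components by element-wise 7-fold cross-validation, clusters the samples
with Euclidean distance and Ward's linkage, and reports whether the first
cluster break separates the two classes.
"""

from pathlib import Path

import pandas as pd

from metabofuse import io
from metabofuse.unsupervised import (
    cut_first_split,
    dendrogram_to_newick,
    hierarchical_cluster,
    pca_fit,
    select_significant_pcs,
)

FUSED = Path(__file__).resolve().parent.parent / "results" / "fused" / "fused_matrix.tsv"
META = Path(__file__).resolve().parent.parent / "results" / "simulated" / "metadata.tsv"
OUT = Path(__file__).resolve().parent.parent / "results" / "unsupervised"
SEED = 20260923


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fused = io.read_fused_matrix(FUSED)
    meta = io.read_metadata(META).set_index("sample_id")

    max_c = min(6, fused.n_samples - 1)
    model = pca_fit(fused.values, max_c)
    model.n_significant = select_significant_pcs(fused.values, max_c, seed=SEED)
    pct = 100 * model.explained_variance_fraction
    print(f"PCA: {model.n_significant} significant component(s) by 7-fold CV")
    print("  PC1..PC3 explained variance: "
          + ", ".join(f"{x:.1f}%" for x in pct[:3]))
    scores = pd.DataFrame(
        model.scores, index=pd.Index(fused.sample_ids, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(model.n_components)],
    )
    scores.to_csv(OUT / "pca_scores.tsv", sep="\t",
                  float_format=io.REPORT_FLOAT_FORMAT)

    dendro = hierarchical_cluster(fused.values, fused.sample_ids)
    (OUT / "dendrogram.nwk").write_text(dendrogram_to_newick(dendro) + "\n")
    left, right = cut_first_split(dendro)
    classes = meta["class"]
    purity = max(
        (classes[left].eq(c).sum() + classes[right].ne(c).sum())
        for c in classes.unique()
    ) / fused.n_samples
    print(f"HCA first split: {len(left)} vs {len(right)} samples, "
          f"class agreement {purity:.0%}")
    print(f"wrote scores and Newick dendrogram -> {OUT}")


if __name__ == "__main__":
    main()
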