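"""Fuse the six platform blocks into the autoscaled analysis matrix.

Reads the blocks written by 01_simulate.py, aligns samples, autoscales
every variable and concatenates, reproducing the study's fused shape of
44 samples x 1709 variables.
"""

from pathlib import Path

from metabofuse import io
from metabofuse.fusion import align_samples, concatenate_blocks

SIM = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT = Path(__file__).resolve().parent.parent / "results" / "fused"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    block_files = sorted(SIM.glob("block_*.tsv"))
    if not block_files:
        raise SystemExit("run analysis/01_simulate.py first")
    blocks = [io.read_feature_block(p) for p in block_files]
    fused = concatenate_blocks(align_samples(blocks))
    io.write_fused_matrix(fused, OUT / "fused_matrix.tsv")
    per_platform = {p: sum(1 for q, _ in fused.columns if q == p)
                    for p in fused.platforms}
    print(f"fused matrix: {fused.n_samples} samples x {fused.n_variables} variables")
    for platform, width in per_platform.items():
        print(f"  {platform:10s} {width:4d}")
    print(f"wrote {OUT / 'fused_matrix.tsv'}")


if __name__ == "__main__":
    main()
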