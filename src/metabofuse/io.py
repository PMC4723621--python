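"""Delimited-text readers/writers for blocks, metadata and results.

All interchange formats are tab-separated text with explicit headers:

- feature block: row 1 is ``sample_id`` followed by variable names prefixed
  with the platform tag (``gcms:v0001``); one row per sample;
- fused matrix: a two-row header (platform row, then variable row);
- metadata: plain table with a ``sample_id`` column;
- ground truth / manifests: YAML.

Result tables are printed with 12 significant digits so result files are
byte-stable across runs with the same seed; data matrices (blocks, fused
matrix) use 17 significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fusion import FeatureBlock, FusedMatrix
from .synthdata import GroundTruth

__all__ = [
    "FLOAT_FORMAT",
    "REPORT_FLOAT_FORMAT",
    "read_feature_block",
    "write_feature_block",
    "read_metadata",
    "write_metadata",
    "read_fused_matrix",
    "write_fused_matrix",
    "write_ground_truth",
    "read_ground_truth",
    "write_manifest",
]

FLOAT_FORMAT = "%.17g"       # data matrices: exact float64 round trip
REPORT_FLOAT_FORMAT = "%.12g"  # result tables: byte-stable, human-scale


def write_feature_block(block: FeatureBlock, path: str | Path) -> None:
    df = block.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_feature_block(path: str | Path, platform: str | None = None) -> FeatureBlock:
    """Read a feature block, validating IDs, names and numeric completeness.

    The platform tag is taken from the variable-name prefixes unless given
    explicitly. Errors name the offending sample/variable coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    ids = df["sample_id"].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample ID {dup.iloc[0]!r}")
    names = list(df.columns[1:])
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate variable names")
    values = np.empty((len(ids), len(names)))
    for j, name in enumerate(names):
        for i, raw in enumerate(df[name]):
            try:
                x = float(raw)  # correctly-rounded strtod: exact round trip
            except (TypeError, ValueError):
                x = np.nan
            if not np.isfinite(x):
                raise ValueError(
                    f"{path}: non-numeric or missing value at sample "
                    f"{ids[i]!r}, variable {name!r} (got {raw!r})"
                )
            values[i, j] = x
    if platform is None:
        prefixes = {n.split(":", 1)[0] for n in names if ":" in n}
        platform = prefixes.pop() if len(prefixes) == 1 else path.stem
    return FeatureBlock(platform, ids, names, values)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata must contain a 'sample_id' column")
    return meta


def write_fused_matrix(fused: FusedMatrix, path: str | Path) -> None:
    """Write a fused matrix with a two-row (platform, variable) header."""
    platforms = "\t".join(["platform"] + [p for p, _ in fused.columns])
    variables = "\t".join(["sample_id"] + [v for _, v in fused.columns])
    with open(path, "w") as fh:
        fh.write(platforms + "\n")
        fh.write(variables + "\n")
        for i, sid in enumerate(fused.sample_ids):
            row = "\t".join(FLOAT_FORMAT % x for x in fused.values[i])
            fh.write(f"{sid}\t{row}\n")


def read_fused_matrix(path: str | Path) -> FusedMatrix:
    path = Path(path)
    with open(path) as fh:
        header_platform = fh.readline().rstrip("\n").split("\t")
        header_variable = fh.readline().rstrip("\n").split("\t")
        if header_platform[0] != "platform" or header_variable[0] != "sample_id":
            raise ValueError(f"{path}: not a fused-matrix file")
        columns = list(zip(header_platform[1:], header_variable[1:]))
        ids = []
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(columns) + 1:
                raise ValueError(
                    f"{path}: ragged row for sample {parts[0]!r} "
                    f"({len(parts) - 1} values, expected {len(columns)})"
                )
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows)
    p = len(columns)
    return FusedMatrix(
        sample_ids=ids,
        columns=columns,
        values=values,
        col_means=np.zeros(p),
        col_sds=np.ones(p),
        scaled=True,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "discriminative": [[p, v] for p, v in truth.discriminative_ids],
        "class_log_means": {
            plat: [[float(x) for x in row] for row in mu]
            for plat, mu in truth.class_means.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return GroundTruth(
        discriminative_ids=[tuple(x) for x in payload["discriminative"]],
        class_means={
            plat: np.asarray(rows, dtype=float)
            for plat, rows in payload["class_log_means"].items()
        },
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
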