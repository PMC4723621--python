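"""Platform-specific data reduction and QC rules.

The rules implemented here turn aligned raw-ish instrument output into
complete feature blocks:

- GC-MS mass signals: entries below a signal-to-noise ratio of 3 are
  replaced by a seeded uniform draw in [2.4, 3.0) times the signal's noise
  estimate; signals detected (s/n >= 3) in six or fewer samples are
  discarded.
- NMR spectra: integrated into 0.01-ppm buckets and scaled to the TSP-d4
  reference region (delta 0.05 to -0.05).
- DI-MS spectra: integrated into unit-m/z buckets over 50-1000 and scaled
  to total spectrum intensity; buckets empty in every sample are dropped.
- ICP-MS: the limit of detection is three times the SD of at least seven
  blanks; an element with any sample not strictly above its LOD is dropped
  (the downstream PCA/PLS machinery assumes complete data), and measured
  reference-material means must deviate less than +/-10% from certified
  values.

"Present" for the prevalence rule means s/n >= 3 *before* randomization:
the randomized sub-noise values are placeholders, not detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import FeatureBlock

__all__ = [
    "SignalTable",
    "Spectrum",
    "ElementPanel",
    "snr_filter_randomize",
    "prevalence_filter",
    "bucket_spectrum",
    "bucket_edges",
    "scale_to_reference_region",
    "normalize_total_intensity",
    "drop_empty_buckets",
    "compute_lod",
    "apply_lod_filter",
    "validate_reference_material",
]


@dataclass
class SignalTable:
    """Mass signals x samples with a per-signal noise estimate."""

    signal_names: list[str]
    sample_ids: list[str]
    noise: np.ndarray        # (n_signals,)
    values: np.ndarray       # (n_signals, n_samples)

    def __post_init__(self) -> None:
        self.noise = np.asarray(self.noise, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.signal_names), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with names/sample IDs")
        if self.noise.shape != (len(self.signal_names),):
            raise ValueError("noise must have one entry per signal")
        bad = np.flatnonzero(self.noise <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive noise for signal {self.signal_names[bad[0]]!r}"
            )

    def snr(self) -> np.ndarray:
        return self.values / self.noise[:, None]


@dataclass
class Spectrum:
    """One sample's spectrum: strictly monotone axis + non-negative intensity."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape or self.axis.ndim != 1:
            raise ValueError("axis and intensity must be 1-D and equal length")
        d = np.diff(self.axis)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class ElementPanel:
    """Element concentrations per sample plus blank replicates."""

    elements: list[str]
    sample_ids: list[str]
    values: np.ndarray                      # (n_elements, n_samples)
    blanks: np.ndarray                      # (n_elements, n_blanks)
    certified_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.blanks = np.asarray(self.blanks, dtype=float)
        if not self.elements:
            raise ValueError("need at least one element")
        if self.values.shape != (len(self.elements), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with elements/sample IDs")
        if self.blanks.shape[0] != len(self.elements):
            raise ValueError("blanks must have one row per element")


def snr_filter_randomize(
    table: SignalTable,
    threshold: float = 3.0,
    low: float = 2.4,
    high: float = 3.0,
    seed: int = 0,
) -> SignalTable:
    """Replace sub-noise entries with a uniform draw in [low, high) x noise.

    Entries with intensity/noise strictly below ``threshold`` are replaced;
    entries at or above the threshold pass through untouched. Draws come
    from one seeded generator in fixed signal-major, sample-minor order, so
    the output is reproducible.
    """
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    below = table.snr() < threshold
    # fixed draw order: iterate the full grid, consuming one draw per entry
    draws = rng.uniform(low, high, size=values.shape)
    values[below] = (draws * table.noise[:, None])[below]
    return SignalTable(
        list(table.signal_names), list(table.sample_ids), table.noise.copy(), values
    )


def prevalence_filter(table: SignalTable, min_present: int = 7, threshold: float = 3.0) -> SignalTable:
    """Discard signals detected in fewer than ``min_present`` samples.

    Detection means s/n >= ``threshold``. With the default ``min_present=7``
    this discards signals present in <= 6 samples. Survivor order is
    preserved; applying the filter twice equals applying it once.
    """
    present = (table.snr() >= threshold).sum(axis=1)
    keep = np.flatnonzero(present >= min_present)
    return SignalTable(
        [table.signal_names[i] for i in keep],
        list(table.sample_ids),
        table.noise[keep],
        table.values[keep],
    )


def bucket_edges(start: float, stop: float, width: float) -> np.ndarray:
    """Left edges plus final right edge of the half-open bucket grid."""
    if width <= 0:
        raise ValueError("width must be > 0")
    if start >= stop:
        raise ValueError("start must be < stop")
    n_buckets = int(np.ceil((stop - start) / width - 1e-9))
    return start + width * np.arange(n_buckets + 1)


def bucket_spectrum(
    spectrum: Spectrum, width: float, start: float, stop: float
) -> np.ndarray:
    """Integrate a spectrum into equal-width, half-open buckets.

    Bucket k covers [start + k*width, start + (k+1)*width); the bucket value
    is the sum of the intensities of the axis points falling inside it.
    Points outside [start, stop) are ignored; an empty overlap yields zeros.
    """
    edges = bucket_edges(start, stop, width)
    n_buckets = edges.size - 1
    axis = spectrum.axis
    inten = spectrum.intensity
    inside = (axis >= start) & (axis < edges[-1])
    idx = np.floor((axis[inside] - start) / width).astype(int)
    idx = np.clip(idx, 0, n_buckets - 1)
    out = np.zeros(n_buckets)
    np.add.at(out, idx, inten[inside])
    return out


def scale_to_reference_region(buckets: np.ndarray, region: slice | np.ndarray) -> np.ndarray:
    """Scale a bucket vector so the reference-region sum equals 1.

    ``region`` selects the reference buckets (e.g. the TSP-d4 region,
    delta 0.05 to -0.05, for NMR). A non-positive region sum is an error.
    """
    buckets = np.asarray(buckets, dtype=float)
    ref = float(np.sum(buckets[region]))
    if ref <= 0:
        raise ValueError(f"reference-region sum must be > 0, got {ref}")
    return buckets / ref


def normalize_total_intensity(buckets: np.ndarray) -> np.ndarray:
    """Scale a bucket vector to total intensity; output sums to 1."""
    buckets = np.asarray(buckets, dtype=float)
    total = float(buckets.sum())
    if total <= 0:
        raise ValueError("total intensity must be > 0")
    return buckets / total


def drop_empty_buckets(
    bucket_matrix: np.ndarray,
    sample_ids: list[str],
    edges: np.ndarray,
    platform: str,
    fmt: str = "{left:g}-{right:g}",
) -> FeatureBlock:
    """Assemble bucket vectors into a FeatureBlock, dropping all-zero buckets.

    Variable names record the bucket boundaries as
    ``<platform>:<left>-<right>``.
    """
    X = np.asarray(bucket_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(sample_ids):
        raise ValueError("bucket matrix must be samples x buckets")
    if X.shape[1] != edges.size - 1:
        raise ValueError("edges inconsistent with bucket count")
    keep = np.flatnonzero(np.any(X != 0, axis=0))
    names = [
        f"{platform}:" + fmt.format(left=edges[j], right=edges[j + 1]) for j in keep
    ]
    return FeatureBlock(platform, list(sample_ids), names, X[:, keep])


def compute_lod(
    panel: ElementPanel, k: float = 3.0, min_blanks: int = 7
) -> np.ndarray:
    """Per-element limit of detection: k times the blank sample SD.

    Requires at least ``min_blanks`` blank replicates per element (NaN blanks
    do not count).
    """
    lods = np.empty(len(panel.elements))
    for i, el in enumerate(panel.elements):
        b = panel.blanks[i]
        b = b[np.isfinite(b)]
        if b.size < min_blanks:
            raise ValueError(
                f"element {el!r}: {b.size} blank replicate(s), need >= {min_blanks}"
            )
        lods[i] = k * np.std(b, ddof=1)
    return lods


def apply_lod_filter(panel: ElementPanel, lod: np.ndarray) -> FeatureBlock:
    """Keep only elements whose every sample is strictly above its LOD.

    Values <= LOD count as not detected; an element with any such sample is
    dropped entirely so the fused matrix stays complete. Surviving values
    pass through unchanged.
    """
    lod = np.asarray(lod, dtype=float)
    if lod.shape != (len(panel.elements),):
        raise ValueError("lod must have one entry per element")
    keep = np.flatnonzero(np.all(panel.values > lod[:, None], axis=1))
    names = [f"icpms:{panel.elements[i]}" for i in keep]
    return FeatureBlock(
        "icpms", list(panel.sample_ids), names, panel.values[keep].T
    )


def validate_reference_material(
    measured: np.ndarray, certified: np.ndarray, tol: float = 0.10
) -> np.ndarray:
    """Per-element pass/fail on the certified-reference accuracy criterion.

    An element passes iff |measured - certified| / certified < tol
    (strictly; a deviation of exactly 10% fails at the default tolerance).
    """
    measured = np.asarray(measured, dtype=float)
    certified = np.asarray(certified, dtype=float)
    if measured.shape != certified.shape:
        raise ValueError("measured and certified must have equal shape")
    if np.any(certified == 0):
        raise ValueError("certified value of 0 is not usable as a reference")
    return np.abs(measured - certified) / np.abs(certified) < tol
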