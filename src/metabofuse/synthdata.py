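"""Synthetic multi-platform metabolomics data with known ground truth.

The real study profiled 44 polished-rice samples (31 varieties) on six
platforms: headspace SPME-GC-MS volatiles (518 reconstructed peaks), 1H-NMR
(95 frequency bins), direct-infusion ESI-MS in negative (634 signals) and
positive (367 signals) mode, GC-TOF-MS primary metabolites (82 compounds)
and ICP-MS micronutrients (13 elements) — 1709 variables after fusion. No
feature tables were deposited, so this module generates data of exactly that
shape, with a configurable set of class-discriminating variables whose
identity is recorded as ground truth for recovery tests.

Intensities are log-normal: log-intensity is Gaussian with a per-variable
baseline, a within-class SD ``noise_sd``, and, for discriminating variables,
a class-dependent mean shift of ``effect_size`` within-class SDs between the
extreme classes. Positivity matters downstream (total-intensity
normalization); autoscaling removes the arbitrary baselines.

Besides finished feature blocks the module generates "raw-ish" precursors —
mass-signal tables with noise estimates, NMR spectra on a ppm axis, DI-MS
m/z-intensity pairs, and element panels with blank replicates — so the
platform-specific preprocessing rules can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import FeatureBlock

__all__ = [
    "DEFAULT_PLATFORM_DIMS",
    "ICP_ELEMENTS",
    "SimulationConfig",
    "GroundTruth",
    "generate_metadata",
    "generate_feature_blocks",
    "generate_raw_gcms",
    "generate_raw_nmr",
    "generate_raw_dims",
    "generate_raw_icpms",
]

# Per-platform variable counts of the fused rice-grain dataset.
DEFAULT_PLATFORM_DIMS = {
    "gcms": 518,      # SPME-GC-MS reconstructed volatile peaks
    "nmr": 95,        # 1H-NMR frequency bins
    "dims_neg": 634,  # DI-MS negative-mode mass signals
    "dims_pos": 367,  # DI-MS positive-mode mass signals
    "gctofms": 82,    # GC-TOF-MS derivatized primary metabolites
    "icpms": 13,      # ICP-MS elements
}

ICP_ELEMENTS = ["Na", "Mg", "Al", "P", "S", "K", "Ca", "Mn", "Fe", "Ni", "Cu", "Zn", "Mo"]

_GERMPLASM = ["aromatic", "sadri", "indica", "tropical japonica", "temperate japonica"]
_COUNTRIES = [
    "Thailand", "Pakistan", "India", "Iran", "Indonesia",
    "Cambodia", "Malaysia", "Philippines", "Japan", "Lao PDR",
]
_STORAGE_MONTHS = [0, 3, 6, 12]


def _default_n_discriminative(dims: dict[str, int]) -> dict[str, int]:
    # ~2% of each platform's variables, at least one
    return {p: max(1, round(0.02 * d)) for p, d in dims.items()}


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the study: two classes (basmati vs jasmine style) of 22
    samples each — 44 in total — and the six platform blocks at the reported
    widths. ``effect_size`` is the standardized between-class mean shift (in
    units of the within-class SD on the log scale) applied to the
    discriminating variables.
    """

    n_samples_per_class: int = 22
    n_classes: int = 2
    platform_dims: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORM_DIMS)
    )
    n_discriminative: dict[str, int] | None = None
    effect_size: float = 2.0
    noise_sd: float = 0.3
    blank_sd: float = 0.05
    block_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_samples_per_class < 1:
            raise ValueError("n_samples_per_class must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if not self.platform_dims:
            raise ValueError("platform_dims must not be empty")
        for p, d in self.platform_dims.items():
            if d < 1:
                raise ValueError(f"platform {p!r}: dimension must be >= 1")
        if self.n_discriminative is None:
            self.n_discriminative = _default_n_discriminative(self.platform_dims)
        for p, k in self.n_discriminative.items():
            if p not in self.platform_dims:
                raise ValueError(f"n_discriminative names unknown platform {p!r}")
            if k > self.platform_dims[p]:
                raise ValueError(
                    f"platform {p!r}: n_discriminative {k} exceeds dimension "
                    f"{self.platform_dims[p]}"
                )

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_class * self.n_classes

    @property
    def class_names(self) -> list[str]:
        if self.n_classes == 2:
            return ["basmati", "jasmine"]
        return [f"group{c + 1}" for c in range(self.n_classes)]

def _stream_rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


@dataclass
class GroundTruth:
    """Which variables discriminate, and the class log-mean structure."""

    discriminative_ids: list[tuple[str, str]]
    class_means: dict[str, np.ndarray]  # platform -> (n_classes, p) log-scale means

    def ids_for(self, platform: str) -> list[str]:
        return [v for p, v in self.discriminative_ids if p == platform]


def generate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Balanced sample-metadata table mirroring the study factors.

    Columns: sample_id, class, variety, germplasm_class, fragrance,
    storage_months, country. Varieties repeat across storage durations, as
    in the study where several varieties were profiled fresh and stored.
    """
    rng = _stream_rng(config, 0)
    rows = []
    classes = config.class_names
    n_varieties = max(2, round(31 / 44 * config.n_samples))
    for c, cname in enumerate(classes):
        for i in range(config.n_samples_per_class):
            global_idx = c * config.n_samples_per_class + i
            variety = f"variety{(global_idx % n_varieties) + 1:02d}"
            rows.append(
                {
                    "sample_id": f"S{global_idx + 1:03d}",
                    "class": cname,
                    "variety": variety,
                    "germplasm_class": _GERMPLASM[global_idx % len(_GERMPLASM)],
                    "fragrance": "fragrant" if rng.random() < 23 / 31 else "non-fragrant",
                    "storage_months": _STORAGE_MONTHS[i % len(_STORAGE_MONTHS)],
                    "country": _COUNTRIES[global_idx % len(_COUNTRIES)],
                }
            )
    return pd.DataFrame(rows)


def generate_feature_blocks(
    config: SimulationConfig,
) -> tuple[list[FeatureBlock], GroundTruth]:
    """Finished per-platform feature blocks plus the ground truth.

    For each platform the first ``n_discriminative[p]`` variables (after a
    seeded shuffle of variable positions) receive class-dependent log-mean
    shifts spanning ``effect_size * noise_sd`` between the extreme classes,
    with a random sign per variable; all other variables share one mean
    across classes.

    With ``block_correlation`` rho > 0 the within-class noise of each
    platform shares a per-sample latent factor: log-noise =
    sqrt(rho) * f + sqrt(1 - rho) * eps, both scaled to ``noise_sd``, so
    every variable pair within a platform correlates at rho (emulating the
    strong covariance of real spectral blocks) while marginal SDs are
    unchanged.
    """
    rng = _stream_rng(config, 1)
    meta = generate_metadata(config)
    class_index = meta["class"].map(
        {c: i for i, c in enumerate(config.class_names)}
    ).to_numpy()
    blocks: list[FeatureBlock] = []
    disc_ids: list[tuple[str, str]] = []
    class_means: dict[str, np.ndarray] = {}
    K = config.n_classes
    # class positions on a centered unit contrast: extremes differ by 1
    contrast = (np.arange(K) / (K - 1)) - 0.5
    for platform in config.platform_dims:
        p = config.platform_dims[platform]
        k_disc = config.n_discriminative[platform]
        names = [f"{platform}:v{j + 1:04d}" for j in range(p)]
        base = rng.uniform(np.log(1e3), np.log(1e5), size=p)
        disc_pos = rng.permutation(p)[:k_disc]
        signs = rng.choice([-1.0, 1.0], size=k_disc)
        mu = np.tile(base, (K, 1))  # (K, p) class log-means
        shift = config.effect_size * config.noise_sd
        for s, j in zip(signs, disc_pos):
            mu[:, j] = base[j] + s * shift * contrast
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_samples, p))
        rho = config.block_correlation
        if rho > 0:
            factor = rng.normal(0.0, config.noise_sd, size=config.n_samples)
            noise = np.sqrt(rho) * factor[:, None] + np.sqrt(1.0 - rho) * noise
        log_x = mu[class_index] + noise
        blocks.append(
            FeatureBlock(
                platform=platform,
                sample_ids=meta["sample_id"].tolist(),
                variable_names=names,
                values=np.exp(log_x),
            )
        )
        disc_ids.extend((platform, names[j]) for j in sorted(disc_pos))
        class_means[platform] = mu
    return blocks, GroundTruth(discriminative_ids=disc_ids, class_means=class_means)


@dataclass
class RawSignalData:
    """Raw-ish mass-signal table: per-signal noise + per-sample intensities."""

    signal_names: list[str]
    sample_ids: list[str]
    noise: np.ndarray          # (n_signals,)
    intensities: np.ndarray    # (n_signals, n_samples)


def generate_raw_gcms(
    config: SimulationConfig,
    n_signals: int = 60,
    fraction_below: float = 0.1,
    rare_signals: int = 3,
    rare_max_present: int = 6,
) -> RawSignalData:
    """Mass-signal table shaped to exercise the s/n and prevalence rules.

    ``fraction_below`` of the non-rare entries fall below 3x their noise
    value; ``rare_signals`` signals are detected (s/n >= 3) in at most
    ``rare_max_present`` samples and should be removed by the prevalence
    filter.
    """
    rng = _stream_rng(config, 2)
    meta = generate_metadata(config)
    ids = meta["sample_id"].tolist()
    n = len(ids)
    names = [f"gcms_raw:m{j + 1:03d}" for j in range(n_signals)]
    noise = rng.uniform(5.0, 50.0, size=n_signals)
    # detected entries sit comfortably above 3x noise
    intens = noise[:, None] * rng.uniform(4.0, 60.0, size=(n_signals, n))
    if fraction_below > 0:
        mask = rng.random((n_signals, n)) < fraction_below
        intens[mask] = (noise[:, None] * rng.uniform(0.3, 2.9, size=(n_signals, n)))[mask]
    for j in range(rare_signals):
        n_present = rng.integers(0, rare_max_present + 1)
        below = noise[j] * rng.uniform(0.3, 2.9, size=n)
        keep = rng.permutation(n)[:n_present]
        row = below
        row[keep] = noise[j] * rng.uniform(4.0, 60.0, size=n_present)
        intens[j] = row
    return RawSignalData(names, ids, noise, intens)


@dataclass
class RawSpectra:
    """Per-sample spectra on a shared monotone axis (ppm or m/z)."""

    axis: np.ndarray            # (n_points,)
    intensities: np.ndarray     # (n_samples, n_points)
    sample_ids: list[str]


def generate_raw_nmr(
    config: SimulationConfig,
    ppm_min: float = -0.2,
    ppm_max: float = 9.8,
    step: float = 0.001,
    n_peaks: int = 120,
    peak_sigma: float = 0.004,
) -> RawSpectra:
    """1H-NMR-like spectra with a TSP-d4 reference peak at delta 0.

    The axis step (0.001 ppm) puts 10 points in every 0.01-ppm bucket. Peak
    positions are shared across samples (shifts are aligned on-instrument);
    amplitudes are log-normal per sample, and the reference peak in
    delta [-0.05, 0.05] varies per sample so reference-region scaling is a
    real correction.
    """
    rng = _stream_rng(config, 3)
    meta = generate_metadata(config)
    ids = meta["sample_id"].tolist()
    axis = np.arange(ppm_min, ppm_max + step / 2, step)
    positions = rng.uniform(0.5, 9.5, size=n_peaks)
    base_amp = rng.uniform(np.log(10.0), np.log(1000.0), size=n_peaks)
    spectra = np.zeros((len(ids), axis.size))
    for i in range(len(ids)):
        amps = np.exp(base_amp + rng.normal(0.0, config.noise_sd, size=n_peaks))
        for pos, amp in zip(positions, amps):
            spectra[i] += amp * np.exp(-0.5 * ((axis - pos) / peak_sigma) ** 2)
        ref_amp = 500.0 * np.exp(rng.normal(0.0, 0.2))
        spectra[i] += ref_amp * np.exp(-0.5 * (axis / peak_sigma) ** 2)
        spectra[i] += np.abs(rng.normal(0.0, 0.05, size=axis.size))
    return RawSpectra(axis, spectra, ids)


def generate_raw_dims(
    config: SimulationConfig,
    mode: str = "neg",
    n_peaks: int = 400,
    mz_min: float = 50.0,
    mz_max: float = 1000.0,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per-sample (m/z, intensity) pairs within the 50-1000 acquisition range.

    Returns a list of (sample_id, mz, intensity) triples. Peak m/z positions
    are shared across samples with small per-sample jitter; intensities are
    log-normal. ``mode`` only seeds a distinct stream for "neg" vs "pos".
    """
    rng = _stream_rng(config, 4 if mode == "neg" else 5)
    meta = generate_metadata(config)
    ids = meta["sample_id"].tolist()
    centers = rng.uniform(mz_min, mz_max, size=n_peaks)
    base_amp = rng.uniform(np.log(100.0), np.log(10000.0), size=n_peaks)
    out = []
    for sid in ids:
        mz = np.clip(centers + rng.normal(0.0, 0.05, size=n_peaks), mz_min, mz_max)
        inten = np.exp(base_amp + rng.normal(0.0, config.noise_sd, size=n_peaks))
        order = np.argsort(mz)
        out.append((sid, mz[order], inten[order]))
    return out


@dataclass
class RawElementData:
    """Element concentrations plus blank replicates and reference material."""

    elements: list[str]
    sample_ids: list[str]
    concentrations: np.ndarray          # (n_elements, n_samples)
    blanks: np.ndarray                  # (n_elements, n_blanks)
    certified_means: np.ndarray         # (n_elements,)
    reference_measured: np.ndarray      # (n_elements,) measured reference means


def generate_raw_icpms(
    config: SimulationConfig,
    n_blanks: int = 7,
    below_lod: dict[str, int] | None = None,
) -> RawElementData:
    """13-element panel with blank replicates and a certified reference.

    ``below_lod`` maps element name -> number of samples whose concentration
    is forced below the limit of detection (3x blank SD), for exercising the
    LOD filter.
    """
    rng = _stream_rng(config, 6)
    meta = generate_metadata(config)
    ids = meta["sample_id"].tolist()
    n = len(ids)
    elements = list(ICP_ELEMENTS)
    # typical rice-grain scales, mg/kg, spanning Na..Mo magnitudes
    typical = np.exp(rng.uniform(np.log(0.1), np.log(3000.0), size=len(elements)))
    conc = typical[:, None] * np.exp(rng.normal(0.0, config.noise_sd, size=(len(elements), n)))
    blanks = np.abs(rng.normal(0.0, config.blank_sd, size=(len(elements), n_blanks)))
    if below_lod:
        for el, count in below_lod.items():
            if el not in elements:
                raise ValueError(f"unknown element {el!r}")
            i = elements.index(el)
            lod = 3.0 * np.std(blanks[i], ddof=1)
            idx = rng.permutation(n)[:count]
            conc[i, idx] = lod * rng.uniform(0.1, 0.99, size=count)
    certified = typical.copy()
    measured = certified * (1.0 + rng.normal(0.0, 0.03, size=len(elements)))
    return RawElementData(elements, ids, conc, blanks, certified, measured)
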