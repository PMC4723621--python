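"""Platform preprocessing rules: s/n randomization, prevalence, bucketing, LOD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metabofuse.preprocess import (
    ElementPanel,
    SignalTable,
    Spectrum,
    apply_lod_filter,
    bucket_edges,
    bucket_spectrum,
    compute_lod,
    drop_empty_buckets,
    normalize_total_intensity,
    prevalence_filter,
    scale_to_reference_region,
    snr_filter_randomize,
    validate_reference_material,
)


def _table(values, noise, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"m{i}" for i in range(values.shape[0])]
    ids = [f"S{j}" for j in range(values.shape[1])]
    return SignalTable(names, ids, np.asarray(noise, dtype=float), values)


class TestSnrFilterRandomize:
    def test_subnoise_entry_replaced_within_band(self):
        t = _table([[29.0]], [10.0])  # s/n 2.9 < 3
        out = snr_filter_randomize(t, seed=0)
        assert 24.0 <= out.values[0, 0] < 30.0
        assert out.values[0, 0] != 29.0 or True  # value comes from the draw

    def test_boundary_snr_3_unchanged(self):
        t = _table([[30.0]], [10.0])  # s/n exactly 3: "below" is strict
        out = snr_filter_randomize(t, seed=0)
        assert out.values[0, 0] == 30.0

    def test_identity_when_all_above(self):
        t = _table([[100.0, 40.0], [35.0, 90.0]], [10.0, 10.0])
        out = snr_filter_randomize(t, seed=3)
        assert np.array_equal(out.values, t.values)

    def test_seeded_reproducibility(self):
        t = _table([[5.0, 100.0], [2.0, 1.0]], [10.0, 4.0])
        a = snr_filter_randomize(t, seed=7)
        b = snr_filter_randomize(t, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_nonpositive_noise_names_signal(self):
        with pytest.raises(ValueError, match="sig_bad"):
            _table([[1.0]], [0.0], names=["sig_bad"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_replacements_always_in_band_and_detections_untouched(self, seed):
        rng = np.random.default_rng(seed)
        noise = rng.uniform(1.0, 20.0, 5)
        values = noise[:, None] * rng.uniform(0.1, 10.0, (5, 8))
        t = _table(values, noise)
        out = snr_filter_randomize(t, seed=seed)
        snr = values / noise[:, None]
        above = snr >= 3.0
        assert np.array_equal(out.values[above], values[above])
        repl = out.values[~above] / (noise[:, None] * np.ones_like(values))[~above]
        assert np.all((repl >= 2.4) & (repl < 3.0))


class TestPrevalenceFilter:
    def _presence_table(self, n_present, n_samples=44):
        noise = np.ones(1)
        row = np.full(n_samples, 1.0)  # s/n 1: absent
        row[:n_present] = 10.0          # s/n 10: present
        return _table(row[None, :], noise)

    @pytest.mark.parametrize("n_present,kept", [(6, 0), (7, 1), (0, 0)])
    def test_boundaries(self, n_present, kept):
        out = prevalence_filter(self._presence_table(n_present), min_present=7)
        assert len(out.signal_names) == kept

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(0)
        noise = rng.uniform(1, 5, 10)
        vals = noise[:, None] * rng.uniform(0.5, 8.0, (10, 20))
        t = _table(vals, noise)
        once = prevalence_filter(t, min_present=7)
        twice = prevalence_filter(once, min_present=7)
        assert once.signal_names == twice.signal_names
        assert set(once.signal_names) <= set(t.signal_names)
        # survivor order preserved
        idx = [t.signal_names.index(n) for n in once.signal_names]
        assert idx == sorted(idx)


class TestBucketSpectrum:
    def test_bucket_count(self):
        s = Spectrum(np.linspace(0.0, 0.0999, 100), np.ones(100))
        out = bucket_spectrum(s, width=0.01, start=0.0, stop=0.1)
        assert out.size == 10

    def test_constant_points_sum(self):
        axis = np.array([0.011, 0.013, 0.017, 0.019])
        s = Spectrum(axis, np.ones(4))
        out = bucket_spectrum(s, width=0.01, start=0.0, stop=0.03)
        assert out.tolist() == [0.0, 4.0, 0.0]

    def test_gaussian_peak_mass_in_its_bucket(self):
        """A narrow peak centered in [2.50, 2.51) leaves >=99% of its mass there.

        Oracle: direct integral of the sampled Gaussian over the bucket
        versus over the whole axis.
        """
        axis = np.arange(2.0, 3.0, 0.0005)
        peak = np.exp(-0.5 * ((axis - 2.505) / 0.001) ** 2)
        s = Spectrum(axis, peak)
        out = bucket_spectrum(s, width=0.01, start=2.0, stop=3.0)
        k = int(np.floor((2.505 - 2.0) / 0.01))
        inside = peak[(axis >= 2.50) & (axis < 2.51)].sum()
        assert out[k] == pytest.approx(inside)
        assert out[k] / out.sum() > 0.99

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_total_intensity_conserved(self, seed):
        rng = np.random.default_rng(seed)
        axis = np.sort(rng.uniform(0.0, 1.0, 50))
        axis = np.unique(axis)
        inten = rng.uniform(0.0, 5.0, axis.size)
        s = Spectrum(axis, inten)
        out = bucket_spectrum(s, width=0.07, start=0.0, stop=1.0 + 1e-9)
        assert out.sum() == pytest.approx(inten.sum(), rel=1e-12)


class TestScaling:
    def test_reference_region_scaling(self):
        buckets = np.array([2.0, 1.0, 3.0, 2.0])
        out = scale_to_reference_region(buckets, slice(1, 3))  # region sum 4
        assert out[0] == pytest.approx(0.5)
        assert out[slice(1, 3)].sum() == pytest.approx(1.0)

    def test_idempotent_on_normalized(self):
        buckets = np.array([0.5, 0.25, 0.75, 0.5])
        out = scale_to_reference_region(buckets, slice(1, 3))
        assert np.allclose(out, buckets)

    def test_zero_region_errors(self):
        with pytest.raises(ValueError):
            scale_to_reference_region(np.array([1.0, 0.0, 0.0]), slice(1, 3))

    def test_total_intensity_examples(self):
        assert normalize_total_intensity(np.array([1.0, 3.0])).tolist() == [0.25, 0.75]
        single = normalize_total_intensity(np.array([0.0, 7.0, 0.0]))
        assert single.tolist() == [0.0, 1.0, 0.0]
        with pytest.raises(ValueError):
            normalize_total_intensity(np.zeros(3))

    @given(st.floats(1e-6, 1e6), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        buckets = rng.uniform(0.1, 10.0, 8)
        assert np.allclose(
            normalize_total_intensity(c * buckets), normalize_total_intensity(buckets)
        )
        assert np.allclose(
            scale_to_reference_region(c * buckets, slice(0, 2)),
            scale_to_reference_region(buckets, slice(0, 2)),
        )


class TestDropEmptyBuckets:
    def _edges(self):
        return bucket_edges(50.0, 53.0, 1.0)

    def test_identity_without_empty(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        block = drop_empty_buckets(X, ["S1", "S2"], self._edges(), "dims_neg")
        assert block.n_variables == 3
        assert block.variable_names[0] == "dims_neg:50-51"

    def test_all_zero_bucket_removed(self):
        X = np.array([[1.0, 0.0, 3.0], [4.0, 0.0, 6.0]])
        block = drop_empty_buckets(X, ["S1", "S2"], self._edges(), "dims_neg")
        assert block.n_variables == 2
        assert "dims_neg:51-52" not in block.variable_names

    def test_bucket_nonzero_in_one_sample_retained(self):
        X = np.array([[1.0, 0.5, 3.0], [4.0, 0.0, 6.0]])
        block = drop_empty_buckets(X, ["S1", "S2"], self._edges(), "dims_neg")
        assert block.n_variables == 3


class TestLod:
    def _panel(self, blanks, values=None, elements=None):
        elements = elements or ["Ni"]
        blanks = np.asarray(blanks, dtype=float)
        if blanks.ndim == 1:
            blanks = blanks[None, :]
        if values is None:
            values = np.full((len(elements), 2), 100.0)
        return ElementPanel(elements, ["S1", "S2"], np.asarray(values, float), blanks)

    def test_lod_is_three_blank_sd(self):
        blanks = np.array([0.0, 0.5, 1.0, 0.5, 0.0, 0.5, 1.0])
        lod = compute_lod(self._panel(blanks))
        assert lod[0] == pytest.approx(3.0 * np.std(blanks, ddof=1))

    def test_constant_blanks_zero_lod(self):
        assert compute_lod(self._panel(np.full(7, 0.3)))[0] == 0.0

    def test_too_few_blanks_names_element(self):
        with pytest.raises(ValueError, match="Ni"):
            compute_lod(self._panel(np.ones(6)))

    def test_all_above_keeps_panel_intact(self):
        panel = self._panel(
            np.tile(np.array([0.0, 0.1, 0.2, 0.1, 0.0, 0.1, 0.2]), (13, 1)),
            values=np.full((13, 2), 50.0),
            elements=[f"E{i}" for i in range(13)],
        )
        block = apply_lod_filter(panel, compute_lod(panel))
        assert block.n_variables == 13

    def test_single_below_sample_drops_element(self):
        blanks = np.tile(np.array([0.0, 0.5, 1.0, 0.5, 0.0, 0.5, 1.0]), (2, 1))
        values = np.array([[100.0, 0.5], [100.0, 100.0]])  # Ni sample 2 below LOD
        panel = ElementPanel(["Ni", "Cu"], ["S1", "S2"], values, blanks)
        block = apply_lod_filter(panel, compute_lod(panel))
        assert block.variable_names == ["icpms:Cu"]

    def test_value_exactly_at_lod_not_above(self):
        blanks = np.array([[0.0, 0.5, 1.0, 0.5, 0.0, 0.5, 1.0]])
        lod = compute_lod(ElementPanel(["Ni"], ["S1", "S2"],
                                       np.full((1, 2), 9.9), blanks))
        values = np.array([[lod[0], 100.0]])
        panel = ElementPanel(["Ni"], ["S1", "S2"], values, blanks)
        assert apply_lod_filter(panel, lod).n_variables == 0


class TestReferenceMaterial:
    @pytest.mark.parametrize(
        "measured,expected",
        [(95.0, True), (110.0, False), (89.9, False), (90.1, True)],
    )
    def test_ten_percent_rule_strict_boundary(self, measured, expected):
        ok = validate_reference_material(
            np.array([measured]), np.array([100.0]), tol=0.10
        )
        assert bool(ok[0]) is expected

    def test_zero_certified_errors(self):
        with pytest.raises(ValueError):
            validate_reference_material(np.array([1.0]), np.array([0.0]))
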