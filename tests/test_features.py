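"""Fuzzy entropy, epoch energy, averaging and strength normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elindex.features import (
    FuzzyEnParams,
    average_over_epochs,
    epoch_energy,
    fuzzy_entropy,
    normalize_strength,
)
from elindex.synthdata import BAND_CENTERS_HZ, make_band_component
from ._oracles import energy_direct, fuzzyen_bruteforce

FS = 200.0


class TestFuzzyEntropy:
    def test_constant_epoch_is_zero(self):
        assert fuzzy_entropy(np.full(200, 4.2)) == 0.0

    def test_epoch_too_short(self):
        with pytest.raises(ValueError, match="epoch too short"):
            fuzzy_entropy(np.array([1.0, 2.0, 3.0]), FuzzyEnParams(m=2))

    def test_non_finite_rejected(self):
        x = np.zeros(50)
        x[3] = np.inf
        with pytest.raises(ValueError, match="invalid signal"):
            fuzzy_entropy(x)

    @pytest.mark.parametrize("convention", ["chen", "paper_literal"])
    @pytest.mark.parametrize("n_samples", [10, 50, 200])
    def test_matches_bruteforce_oracle(self, convention, n_samples):
        """Optimized FE equals the O(N^2) all-pairs enumeration to 1e-10."""
        rng = np.random.default_rng(7)
        params = FuzzyEnParams(convention=convention)
        for _ in range(10):
            x = rng.standard_normal(n_samples)
            expected = fuzzyen_bruteforce(x, convention=convention)
            assert fuzzy_entropy(x, params) == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16), c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, seed, c):
        """FE(c*x) == FE(x): the tolerance tracks the epoch SD."""
        x = np.random.default_rng(seed).standard_normal(100)
        assert fuzzy_entropy(c * x) == pytest.approx(fuzzy_entropy(x), abs=1e-9)

    def test_nonnegative_on_random_epochs(self, rng):
        """phi^(m+1) <= phi^m under the chen convention, so FE >= 0."""
        for _ in range(50):
            x = rng.standard_normal(rng.integers(10, 120))
            assert fuzzy_entropy(x) >= 0.0

    def test_noise_more_complex_than_any_band_tone(self, rng):
        """White noise carries higher FE than a pure sinusoid of matched
        variance at any band-center frequency."""
        t = np.arange(200) / FS
        noise_fe = np.mean(
            [fuzzy_entropy(rng.standard_normal(200)) for _ in range(10)]
        )
        for freq in BAND_CENTERS_HZ.values():
            tone = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            assert noise_fe > fuzzy_entropy(tone)

    def test_band_complexity_ordering(self):
        """Mean FE of band-limited components orders delta < theta < alpha < beta,
        the canonical complexity-grows-with-frequency ordering."""
        means = {}
        for band in ("delta", "theta", "alpha", "beta"):
            fes = []
            for seed in range(6):
                x = make_band_component(
                    band, 10.0, 1.0, FS, 1.0, np.random.default_rng(seed)
                )
                fes.append(fuzzy_entropy(x))
            means[band] = np.mean(fes)
        assert means["delta"] < means["theta"] < means["alpha"] < means["beta"]


class TestEpochEnergy:
    def test_zero_and_unit_vectors(self):
        assert epoch_energy(np.zeros(200)) == 0.0
        assert epoch_energy(np.ones(200)) == 200.0

    def test_matches_direct_summation(self, rng):
        x = rng.standard_normal(200) * 40.0
        assert epoch_energy(x) == pytest.approx(energy_direct(x), rel=1e-13)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16), c=st.floats(-50.0, 50.0))
    def test_quadratic_scaling(self, seed, c):
        x = np.random.default_rng(seed).standard_normal(64)
        assert epoch_energy(c * x) == pytest.approx(c * c * epoch_energy(x), rel=1e-9)

    def test_non_finite_rejected(self):
        x = np.ones(10)
        x[0] = np.nan
        with pytest.raises(ValueError, match="invalid signal"):
            epoch_energy(x)


class TestAverageOverEpochs:
    def test_examples(self, rng):
        assert average_over_epochs(np.arange(1.0, 21.0)) == 10.5
        assert average_over_epochs(np.full(20, 3.3)) == pytest.approx(3.3)
        vals = rng.standard_normal(20)
        assert average_over_epochs(vals) == pytest.approx(sum(vals) / 20, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no epochs"):
            average_over_epochs([])


class TestNormalizeStrength:
    @staticmethod
    def _table(values):
        rows = []
        bands = ["delta", "theta", "alpha", "beta"]
        for i, v in enumerate(values):
            rows.append(
                {
                    "subject": "S01",
                    "channel": "C3",
                    "band": bands[i % 4],
                    "condition": "normal" if i < 4 else "OSA",
                    "FE_mean": 0.5,
                    "E_mean": v,
                }
            )
        return pd.DataFrame(rows)

    def test_endpoints_and_linear_map(self):
        out = normalize_strength(self._table([0.0, 10.0, 1.0, 2.0]))
        got = dict(zip(out["band"], out["E_norm"]))
        assert got["delta"] == 0.0 and got["theta"] == 1.0
        out2 = normalize_strength(self._table([1.0, 2.0, 3.0, 2.0]))
        np.testing.assert_allclose(sorted(out2["E_norm"])[:3], [0.0, 0.5, 0.5])

    def test_degenerate_group_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="all-equal"):
            out = normalize_strength(self._table([2.0, 2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(out["E_norm"], 0.5)

    def test_normalization_is_within_subject_condition_groups(
        self, small_cohort_features
    ):
        _, agg = small_cohort_features
        grouped = agg.groupby(["subject", "condition"])["E_norm"]
        assert (grouped.min() == 0.0).all() and (grouped.max() == 1.0).all()
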