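import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import ecgmi
from ecgmi.features import entropies as E
from ecgmi.types import DWT_COMPONENTS, IMF_COMPONENTS

from oracles import (
    disten_bruteforce,
    fuzzen_bruteforce,
    incren_bruteforce,
    permen_bruteforce,
    renyi_bruteforce,
    sampen_bruteforce,
    tsallis_bruteforce,
)


class TestTimeDomain:
    def test_constant_series_conventions(self):
        f = ecgmi.time_domain_features(np.full(50, 2.0))
        assert f == {"min": 2, "max": 2, "mean": 2, "variance": 0, "rms": 2,
                     "skewness": 0, "kurtosis": 0}

    def test_small_series_values(self):
        f = ecgmi.time_domain_features([1.0, 2.0, 3.0, 4.0])
        assert f["mean"] == 2.5
        assert abs(f["variance"] - 5.0 / 3.0) < 1e-14
        assert abs(f["rms"] - math.sqrt(7.5)) < 1e-14
        assert f["min"] == 1 and f["max"] == 4

    def test_symmetric_series_has_zero_skewness(self, rng):
        half = rng.normal(size=500)
        x = np.concatenate([half, -half])
        f = ecgmi.time_domain_features(x)
        assert abs(f["skewness"]) < 1e-12

    def test_gaussian_kurtosis_is_noncentral_three(self, rng):
        f = ecgmi.time_domain_features(rng.normal(size=200_000))
        assert abs(f["kurtosis"] - 3.0) < 0.1

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            ecgmi.time_domain_features([1.0])


class TestRegistry:
    def test_exactly_23_unique_valid_names(self):
        reg = ecgmi.entropy_registry()
        assert len(reg) == 23
        assert len(set(reg)) == 23
        assert all(name.isidentifier() for name in reg)

    def test_every_measure_finite_on_ecg_segment(self, ecg_segment):
        for name in ecgmi.ENTROPY_NAMES:
            value = ecgmi.compute_measure(name, ecg_segment.samples)
            assert np.isfinite(value), name

    def test_unknown_measure_rejected(self):
        with pytest.raises(KeyError):
            ecgmi.compute_measure("nonexistent", np.arange(100.0))


class TestOracleEquivalence:
    """Vectorized estimators agree with independent brute-force
    implementations on short seeded series (counts exact, values 1e-12)."""

    def test_sample_entropy_matches_double_loop(self, rng):
        x = rng.normal(size=50)
        expected, a, b = sampen_bruteforce(x)
        assert a > 0 and b > 0
        got = ecgmi.compute_measure("sample", x)
        assert abs(got - expected) < 1e-12
        a2, b2 = E._sampen_counts(x, 2, 0.2 * float(np.std(x)))
        assert (a2, b2) == (a, b)

    def test_permutation_entropy_matches_pattern_census(self, rng):
        x = rng.normal(size=20)
        assert abs(ecgmi.compute_measure("permutation", x)
                   - permen_bruteforce(x)) < 1e-12

    def test_fuzzy_entropy_matches_membership_sums(self, rng):
        x = rng.normal(size=40)
        assert abs(ecgmi.compute_measure("fuzzy", x)
                   - fuzzen_bruteforce(x)) < 1e-12

    def test_renyi_tsallis_match_direct_summation(self, rng):
        x = rng.normal(size=200)
        assert abs(ecgmi.compute_measure("renyi", x) - renyi_bruteforce(x)) < 1e-12
        assert abs(ecgmi.compute_measure("tsallis", x) - tsallis_bruteforce(x)) < 1e-12

    def test_distribution_entropy_matches_pair_enumeration(self, rng):
        x = rng.normal(size=120)
        assert abs(ecgmi.compute_measure("distribution", x)
                   - disten_bruteforce(x)) < 1e-12

    def test_increment_entropy_matches_word_census(self, rng):
        x = rng.normal(size=150)
        assert abs(ecgmi.compute_measure("increment", x)
                   - incren_bruteforce(x)) < 1e-12


class TestClosedForms:
    def test_constant_series_sampen_is_zero(self):
        assert ecgmi.compute_measure("sample", np.full(60, 1.5)) == 0.0

    def test_monotone_series_permen_is_zero(self):
        assert ecgmi.compute_measure("permutation", np.arange(100.0)) == 0.0

    def test_alternating_series_attains_permen_maximum(self):
        x = np.resize([0.0, 1.0], 401)  # odd length: up/down patterns tie exactly
        assert abs(E.permutation_entropy(x, order=2) - 1.0) < 1e-12

    def test_uniform_histogram_closed_forms(self):
        x = np.repeat(np.arange(16.0), 5) + 0.25  # exactly uniform occupancy
        assert abs(E.renyi_entropy(x, alpha=2, bins=16) - math.log(16)) < 1e-12
        assert abs(E.tsallis_entropy(x, q=2, bins=16) - 0.9375) < 1e-12

    def test_renyi_alpha_to_one_limit_is_shannon(self, rng):
        x = rng.normal(size=500)
        shannon = E.shannon_entropy(x, bins=16)
        for alpha in (1 + 1e-4, 1 - 1e-4):
            assert abs(E.renyi_entropy(x, alpha=alpha, bins=16) - shannon) < 1e-3

    def test_constant_series_histogram_measures_degenerate(self):
        x = np.full(100, 3.0)
        with pytest.raises(ecgmi.DegenerateInputError):
            E.renyi_entropy(x)
        assert math.isnan(ecgmi.compute_measure("renyi", x))


class TestMeasureBehaviour:
    def test_spectral_entropy_orders_noise_above_tone(self, rng):
        n = 4096
        tone = np.sin(2 * np.pi * 32 * np.arange(n) / n)  # integer cycles
        noise = rng.normal(size=n)
        assert E.spectral_entropy(tone) <= 0.1
        assert E.spectral_entropy(noise) >= 0.9

    def test_hurst_of_linear_trend_is_persistent(self):
        assert abs(E.hurst_exponent(np.arange(512.0)) - 1.0) < 0.1

    def test_sampen_orders_noise_above_sinusoid(self, rng):
        n = 1000
        noise = rng.uniform(size=n)
        tone = np.sin(2 * np.pi * 5 * np.arange(n) / n)
        assert ecgmi.compute_measure("sample", noise) > ecgmi.compute_measure("sample", tone)

    @pytest.mark.parametrize("name", ["sample", "permutation", "fuzzy"])
    def test_affine_invariance_of_template_measures(self, rng, name):
        x = rng.normal(size=300)
        y = 3.7 * x + 11.0
        assert abs(ecgmi.compute_measure(name, x)
                   - ecgmi.compute_measure(name, y)) < 1e-9

    def test_time_domain_scaling_behaviour(self, rng):
        x = rng.normal(size=400)
        f1 = ecgmi.time_domain_features(x)
        f2 = ecgmi.time_domain_features(4.0 * x)
        for linear in ("min", "max", "mean", "rms"):
            assert abs(f2[linear] - 4.0 * f1[linear]) < 1e-9
        assert abs(f2["variance"] - 16.0 * f1["variance"]) < 1e-9
        for invariant in ("skewness", "kurtosis"):
            assert abs(f2[invariant] - f1[invariant]) < 1e-9


class TestExtraction:
    def test_full_component_set_gives_390_named_features(self, component_set):
        fv = ecgmi.extract_features(component_set)
        assert len(fv) == 390
        assert list(fv) == ecgmi.feature_names()
        assert all(np.isfinite(v) for v in fv.values())

    def test_dwt_only_subset_gives_210(self, component_set):
        partial = ecgmi.ComponentSet(
            components={k: component_set[k] for k in DWT_COMPONENTS})
        assert len(ecgmi.extract_features(partial)) == 210

    def test_imf_only_subset_gives_150(self, component_set):
        partial = ecgmi.ComponentSet(
            components={k: component_set[k] for k in IMF_COMPONENTS})
        assert len(ecgmi.extract_features(partial)) == 150

    def test_feature_count_is_30_per_present_component(self, component_set):
        partial = ecgmi.ComponentSet(
            components={k: component_set[k] for k in ("orj", "d3", "imf2")})
        assert len(ecgmi.extract_features(partial)) == 90

    def test_empty_component_set_rejected(self):
        with pytest.raises(ValueError):
            ecgmi.extract_features(ecgmi.ComponentSet(components={}))


def test_sample_entropy_separates_classes_on_synthetic_data():
    """The MI generator raises signal complexity (white-noise SD, jitter),
    so the per-segment sample entropy of the original signal differs
    between classes (rank test on 100 segments per class)."""
    values = {}
    for label, seed0 in (("MI", 1000), ("healthy", 5000)):
        vals = []
        for s in range(100):
            rec = ecgmi.generate_record(
                ecgmi.SynthConfig.for_class(label, duration=10.0, seed=seed0 + s))
            seg = ecgmi.preprocess_records([rec])[0]
            vals.append(ecgmi.compute_measure("sample", seg.samples))
        values[label] = vals
    p = mannwhitneyu(values["MI"], values["healthy"]).pvalue
    assert p < 0.01
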