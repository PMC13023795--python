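import numpy as np
import pywt
import pytest

import ecgmi
from ecgmi.decomposition import count_extrema, zero_crossings


class TestDwt:
    def test_seven_named_bands(self, ecg_segment):
        bands = ecgmi.dwt_decompose(ecg_segment)
        assert sorted(bands) == ["a6", "d1", "d2", "d3", "d4", "d5", "d6"]

    def test_zero_input_gives_zero_coefficients(self):
        bands = ecgmi.dwt_decompose(np.zeros(1024))
        assert all(np.allclose(c, 0) for c in bands.values())

    def test_energy_conservation_under_periodization(self, rng):
        # orthonormality is exact when every level's input length is even
        x = rng.normal(size=9_984)  # 9984 = 156 * 2^6
        bands = ecgmi.dwt_decompose(x)
        coeff_energy = sum(float(np.sum(c**2)) for c in bands.values())
        signal_energy = float(np.sum(x**2))
        assert abs(coeff_energy - signal_energy) / signal_energy < 1e-9

    def test_invertibility(self, rng):
        x = rng.normal(size=10_000)
        b = ecgmi.dwt_decompose(x)
        coeffs = [b["a6"]] + [b[f"d{k}"] for k in range(6, 0, -1)]
        recon = pywt.waverec(coeffs, "db6", mode="periodization")[: x.size]
        assert np.max(np.abs(recon - x)) / np.max(np.abs(x)) < 1e-8

    def test_dyadic_lengths(self, ecg_segment):
        bands = ecgmi.dwt_decompose(ecg_segment)
        n = len(ecg_segment)
        for lvl in range(1, 7):
            n = -(-n // 2)  # ceil division under periodization
            assert bands[f"d{lvl}"].size == n
        assert bands["a6"].size == n

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError, match="too short"):
            ecgmi.dwt_decompose(np.arange(10.0))


class TestEmd:
    def test_ecg_segment_yields_five_imfs(self, ecg_segment):
        imfs, _ = ecgmi.emd_decompose(ecg_segment)
        assert sorted(imfs) == ["imf1", "imf2", "imf3", "imf4", "imf5"]
        assert all(v.size == len(ecg_segment) for v in imfs.values())

    def test_monotone_ramp_has_no_oscillation_to_extract(self):
        x = np.linspace(0, 1, 500)
        imfs, residue = ecgmi.emd_decompose(x)
        assert imfs == {}
        assert np.array_equal(residue, x)

    def test_single_tone_recovered_in_first_imf(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        imfs, residue = ecgmi.emd_decompose(x)
        corr = np.corrcoef(imfs["imf1"], x)[0, 1]
        assert corr > 0.99
        total = sum(imfs.values()) + residue
        assert np.max(np.abs(total - x)) < 1e-9 * np.max(np.abs(x))

    def test_completeness_on_ecg_segment(self, ecg_segment, component_set):
        total = sum(component_set[f"imf{k}"] for k in range(1, 6)) + component_set.residue
        err = np.max(np.abs(total - ecg_segment.samples))
        assert err < 1e-9 * np.max(np.abs(ecg_segment.samples))

    def test_accepted_imfs_satisfy_zero_crossing_condition(self):
        """On a clean oscillatory mixture every accepted IMF has nearly
        equal zero-crossing and extremum counts."""
        rng = np.random.default_rng(4)
        t = np.arange(4096) / 1000.0
        x = (np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 11 * t)
             + np.sin(2 * np.pi * 2.5 * t) + 0.01 * rng.normal(size=t.size))
        imfs, _ = ecgmi.emd_decompose(x)
        assert len(imfs) >= 3
        for imf in imfs.values():
            assert abs(zero_crossings(imf) - count_extrema(imf)) <= 1

    def test_imf_dominant_frequencies_are_ordered(self):
        rng = np.random.default_rng(4)
        t = np.arange(4096) / 1000.0
        x = (np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 11 * t)
             + np.sin(2 * np.pi * 2.5 * t) + 0.01 * rng.normal(size=t.size))
        imfs, _ = ecgmi.emd_decompose(x)

        def dom_freq(sig):
            spec = np.abs(np.fft.rfft(sig))
            spec[0] = 0
            return np.argmax(spec)

        freqs = [dom_freq(imfs[name]) for name in sorted(imfs)]
        assert all(f1 >= f2 for f1, f2 in zip(freqs, freqs[1:]))


class TestComponentSet:
    def test_thirteen_components_with_contract_names(self, component_set):
        assert len(component_set) == 13
        assert component_set.names() == [
            "a6", "d1", "d2", "d3", "d4", "d5", "d6",
            "imf1", "imf2", "imf3", "imf4", "imf5", "orj",
        ]
        assert component_set.absent == []

    def test_component_lengths(self, component_set, ecg_segment):
        n = len(ecg_segment)
        assert component_set["orj"].size == n
        for k in range(1, 6):
            assert component_set[f"imf{k}"].size == n

    def test_oscillation_poor_segment_marks_absent_imfs(self):
        # a few slow cycles only: sifting exhausts the extrema early
        t = np.linspace(0, 1, 4096)
        seg = ecgmi.EcgSegment(samples=np.sin(2 * np.pi * 2 * t), label="healthy",
                               record_id="t", segment_index=0)
        cs = ecgmi.build_component_set(seg)
        n_imfs = sum(1 for name in cs.names() if name.startswith("imf"))
        assert n_imfs < 5
        assert len(cs) + len(cs.absent) == 13
        assert all(name.startswith("imf") for name in cs.absent)
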