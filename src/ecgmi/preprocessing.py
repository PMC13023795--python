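"""Denoising, segmentation and min-max normalization.

The processing order is: wavelet-denoise the whole record, min-max
normalize (record scope by default, per-segment scope available), then cut
non-overlapping fixed-length segments (default 10,000 samples; the trailing
remainder is dropped).

Denoising uses a six-level multilevel DWT with a Daubechies-6 mother
wavelet: the detail coefficients of every level are soft-thresholded with
the universal threshold ``sigma * sqrt(2 ln N)``, where ``sigma`` is the
robust noise estimate ``median(|D1|) / 0.6745``, and the signal is rebuilt
by the inverse transform.  The transform uses periodization extension so
the multilevel DWT is orthonormal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .types import DegenerateInputError, EcgRecord, EcgSegment

__all__ = [
    "DenoiseParams",
    "denoise",
    "segment",
    "segment_count",
    "normalize",
    "normalize_record",
    "preprocess_records",
]

DEFAULT_SEGMENT_LENGTH = 10_000


@dataclass(frozen=True)
class DenoiseParams:
    wavelet_name: str = "db6"
    levels: int = 6
    threshold_rule: str = "universal"
    threshold_mode: str = "soft"  # or "hard"
    threshold_scale: float = 1.0  # 0 disables thresholding (pure round-trip)

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.threshold_scale < 0:
            raise ValueError("threshold_scale must be >= 0")
        if self.wavelet_name not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"{self.wavelet_name!r} is not a discrete wavelet")
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")
        if self.threshold_mode not in ("soft", "hard"):
            raise ValueError("threshold_mode must be 'soft' or 'hard'")


def denoise(record: EcgRecord, params: DenoiseParams | None = None) -> EcgRecord:
    """Wavelet-threshold denoising; output length equals input length."""
    params = params or DenoiseParams()
    x = record.samples
    min_len = 2 ** params.levels
    if x.size < min_len:
        raise ValueError(
            f"record {record.record_id!r} has {x.size} samples; "
            f"{params.levels}-level decomposition needs at least {min_len}"
        )
    coeffs = pywt.wavedec(x, params.wavelet_name, mode="periodization", level=params.levels)
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1)) / 0.6745
    thr = params.threshold_scale * sigma * np.sqrt(2.0 * np.log(x.size))
    out = [coeffs[0]]
    if thr > 0:
        out += [pywt.threshold(c, thr, mode=params.threshold_mode) for c in coeffs[1:]]
    else:
        out += coeffs[1:]
    y = pywt.waverec(out, params.wavelet_name, mode="periodization")[: x.size]
    return record.with_samples(y)


def segment_count(record_length: int, segment_length: int = DEFAULT_SEGMENT_LENGTH) -> int:
    """Number of complete non-overlapping windows in a record."""
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    return record_length // segment_length


def segment(record: EcgRecord, segment_length: int = DEFAULT_SEGMENT_LENGTH) -> list[EcgSegment]:
    """Cut consecutive non-overlapping windows; remainder dropped."""
    n = segment_count(len(record), segment_length)
    return [
        EcgSegment(
            samples=record.samples[i * segment_length : (i + 1) * segment_length].copy(),
            label=record.label,
            record_id=record.record_id,
            segment_index=i,
        )
        for i in range(n)
    ]


def _minmax(x: np.ndarray, what: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError(f"cannot min-max normalize a constant {what}")
    return (x - lo) / (hi - lo)


def normalize(seg: EcgSegment) -> EcgSegment:
    """Min-max scale one segment to [0, 1]; attains 0 and 1 exactly."""
    return EcgSegment(
        samples=_minmax(seg.samples, f"segment {seg.segment_id}"),
        label=seg.label,
        record_id=seg.record_id,
        segment_index=seg.segment_index,
    )


def normalize_record(record: EcgRecord) -> EcgRecord:
    """Min-max scale a whole record to [0, 1]."""
    return record.with_samples(_minmax(record.samples, f"record {record.record_id}"))


def preprocess_records(
    records: list[EcgRecord],
    params: DenoiseParams | None = None,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    norm_scope: str = "record",
) -> list[EcgSegment]:
    """Full preprocessing chain: denoise -> normalize -> segment.

    ``norm_scope="record"`` (default) scales each whole denoised record to
    [0, 1] before cutting; ``"segment"`` scales each cut segment
    independently so every segment attains 0 and 1.
    """
    if norm_scope not in ("record", "segment"):
        raise ValueError("norm_scope must be 'record' or 'segment'")
    out: list[EcgSegment] = []
    for rec in records:
        den = denoise(rec, params)
        if norm_scope == "record":
            out.extend(segment(normalize_record(den), segment_length))
        else:
            out.extend(normalize(s) for s in segment(den, segment_length))
    return out
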