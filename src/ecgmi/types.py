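"""Core containers shared across the pipeline.

The unit of analysis is a labeled single-lead (Lead II) ECG time series,
either a full variable-length record or a fixed-length segment cut from one.
Labels are binary: ``"MI"`` (myocardial infarction, the positive class) or
``"healthy"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

LABELS = ("MI", "healthy")
POSITIVE_LABEL = "MI"

#: canonical component naming: original signal, six DWT detail bands,
#: the level-6 approximation, and the first five intrinsic mode functions.
COMPONENT_NAMES = (
    "orj",
    "d1", "d2", "d3", "d4", "d5", "d6", "a6",
    "imf1", "imf2", "imf3", "imf4", "imf5",
)
DWT_COMPONENTS = ("d1", "d2", "d3", "d4", "d5", "d6", "a6")
IMF_COMPONENTS = ("imf1", "imf2", "imf3", "imf4", "imf5")


class ConfigurationError(ValueError):
    """An input configuration violates a documented invariant."""


class DegenerateInputError(ValueError):
    """An input is mathematically degenerate for the requested operation."""


def _as_float_array(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D sample sequence, got shape {x.shape}")
    return x


@dataclass
class EcgRecord:
    """A labeled single-lead ECG record.

    Parameters
    ----------
    samples : array-like
        Amplitudes in millivolt.
    sampling_rate : float
        Samples per second (1000 Hz for PTB-style recordings).
    label : str
        ``"MI"`` or ``"healthy"``.
    record_id : str
        Stable identifier used in manifests and feature matrices.
    lead : str
        ECG derivation; fixed to Lead II in this package.
    meta : dict
        Free-form provenance (generator seed, beat landmarks, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    label: str
    record_id: str
    lead: str = "II"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id!r}: non-finite samples")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.label not in LABELS:
            raise ConfigurationError(f"label must be one of {LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of this record with replaced samples, metadata preserved."""
        return EcgRecord(
            samples=samples,
            sampling_rate=self.sampling_rate,
            label=self.label,
            record_id=self.record_id,
            lead=self.lead,
            meta=dict(self.meta),
        )


@dataclass
class EcgSegment:
    """A fixed-length window cut from an :class:`EcgRecord`."""

    samples: np.ndarray
    label: str
    record_id: str
    segment_index: int

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.label not in LABELS:
            raise ConfigurationError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.segment_index < 0:
            raise ValueError("segment_index must be >= 0")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def segment_id(self) -> str:
        return f"{self.record_id}#{self.segment_index}"
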