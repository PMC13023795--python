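"""Per-segment feature extraction: 30 features per signal component.

For every present component of a :class:`~ecgmi.decomposition.ComponentSet`
this module computes 7 time-domain statistics followed by the 23 registry
entropy measures, named ``"<component>_<measure>"`` (e.g. ``imf2_renyi``,
``d5_tsallis``, ``orj_permutation``).  A full 13-component set yields 390
features; the DWT bands alone yield 210 and the IMFs alone 150.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..decomposition import ComponentSet, EmdParams, build_component_set
from ..types import COMPONENT_NAMES, EcgSegment
from .entropies import (
    ENTROPY_NAMES,
    MAX_QUAD_N,
    compute_measure,
    entropy_registry,
    sample_entropy,
    permutation_entropy,
    renyi_entropy,
    tsallis_entropy,
    shannon_entropy,
    fuzzy_entropy,
)
from .timedomain import TIME_DOMAIN_NAMES, time_domain_features

__all__ = [
    "TIME_DOMAIN_NAMES",
    "ENTROPY_NAMES",
    "MEASURE_NAMES",
    "MAX_QUAD_N",
    "entropy_registry",
    "compute_measure",
    "time_domain_features",
    "sample_entropy",
    "permutation_entropy",
    "renyi_entropy",
    "tsallis_entropy",
    "shannon_entropy",
    "fuzzy_entropy",
    "extract_features",
    "feature_names",
    "extract_feature_matrix",
]

#: the 30 per-component measure names, in column order
MEASURE_NAMES = TIME_DOMAIN_NAMES + ENTROPY_NAMES


def feature_names(components: tuple[str, ...] = COMPONENT_NAMES) -> list[str]:
    """Deterministic column layout: component-major, measures in registry
    order after the 7 statistics."""
    return [f"{c}_{m}" for c in components for m in MEASURE_NAMES]


def extract_features(components: ComponentSet,
                     entropy_params: dict[str, dict] | None = None) -> dict[str, float]:
    """30 named features for every present component.

    ``entropy_params`` optionally overrides registry defaults per measure,
    e.g. ``{"sample": {"m": 3}}``.
    """
    if len(components) == 0:
        raise ValueError("component set has no present components")
    out: dict[str, float] = {}
    for comp in COMPONENT_NAMES:
        if comp not in components:
            continue
        series = components[comp]
        for name, value in time_domain_features(series).items():
            out[f"{comp}_{name}"] = value
        for name in ENTROPY_NAMES:
            params = (entropy_params or {}).get(name)
            out[f"{comp}_{name}"] = compute_measure(name, series, params)
    return out


def extract_feature_matrix(
    segments: list[EcgSegment],
    emd_params: EmdParams | None = None,
    entropy_params: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Segments -> feature matrix with ``record_id``, ``segment_index``,
    ``label`` and up to 390 named feature columns in deterministic order."""
    rows = []
    for seg in segments:
        cs = build_component_set(seg, emd_params=emd_params)
        feats = extract_features(cs, entropy_params)
        row = {"record_id": seg.record_id, "segment_index": seg.segment_index,
               "label": seg.label}
        row.update(feats)
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = ["record_id", "segment_index", "label"] + [
        c for c in feature_names() if c in df.columns
    ]
    return df.reindex(columns=ordered).astype(
        {c: np.float64 for c in ordered[3:]}
    )
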