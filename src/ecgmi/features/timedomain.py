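"""Seven time-domain summary statistics per signal component.

Conventions: variance uses the n-1 divisor; skewness and kurtosis are the
moment ratios m3 / m2^1.5 and m4 / m2^2 built from central sample moments
with divisor n (kurtosis is non-excess, so a normal distribution gives 3);
a zero-variance series reports skewness = kurtosis = 0 by convention.
"""

from __future__ import annotations

import numpy as np

TIME_DOMAIN_NAMES = ("min", "max", "mean", "variance", "rms", "skewness", "kurtosis")


def time_domain_features(series) -> dict[str, float]:
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("time-domain statistics need at least 2 samples")
    mean = float(x.mean())
    dev = x - mean
    m2 = float(np.mean(dev**2))
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": mean,
        "variance": float(x.var(ddof=1)),
        "rms": float(np.sqrt(np.mean(x**2))),
        "skewness": skew,
        "kurtosis": kurt,
    }
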