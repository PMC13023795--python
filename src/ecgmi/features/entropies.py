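"""The 23 entropy and complexity measures.

Each measure follows its literature-standard definition; per-measure
hyperparameters (embedding dimension m, tolerance r, lag, histogram bins,
scale counts, entropic orders) use the dominant conventions of the
respective literatures and live in one place — the registry built by
:func:`entropy_registry`.

Numerical conventions shared across measures:

* tolerance ``r`` defaults to ``0.2 * SD`` of the analyzed series
  (population standard deviation), recomputed per series, which makes the
  template-matching measures invariant under positive affine amplitude
  transforms;
* histogram-based measures (Shannon, Rényi, Tsallis) use a 16-bin
  equal-width amplitude histogram over ``[min, max]``;
* multiscale families evaluate scales 1-5 and report the mean over the
  scales where the base entropy is defined, so every component contributes
  exactly one value per measure;
* measures whose cost is quadratic in the series length (the template and
  distance-distribution families) evaluate on at most the first ``max_n``
  points (default 2000); estimates of these quantities are stable well
  below that length while the full 10,000-sample segment would dominate the
  pipeline runtime.

Degenerate inputs (e.g. a constant series where an amplitude histogram has
zero range, or a template search with no matches) raise
:class:`~ecgmi.types.DegenerateInputError` from the standalone functions;
the :func:`compute_measure` dispatcher converts that to a logged missing
value (NaN) so one bad component does not abort a whole extraction run.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pywt
from scipy.signal import hilbert, periodogram
from scipy.spatial.distance import cdist

from ..types import DegenerateInputError

log = logging.getLogger(__name__)

MAX_QUAD_N = 1000  # evaluation cap for O(n^2) estimators


# ---------------------------------------------------------------------------
# shared helpers

def _series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    return x


def _cap(x: np.ndarray, max_n: int | None) -> np.ndarray:
    return x[:max_n] if max_n is not None and x.size > max_n else x


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Delay-embedding matrix with rows x[i], x[i+tau], ..., x[i+(m-1)tau]."""
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError(f"series too short to embed with m={m}, tau={tau}")
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]


def _default_r(x: np.ndarray, r) -> float:
    return 0.2 * float(np.std(x)) if r is None else float(r)


def _shannon(p: np.ndarray, base: str = "nat") -> float:
    p = p[p > 0]
    h = -float(np.sum(p * np.log(p))) + 0.0  # +0.0 normalizes -0.0
    return h / np.log(2.0) if base == "bit" else h


def _hist_probs(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateInputError("cannot bin a constant series")
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return counts / counts.sum()


def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(A, B): matched template-pair counts at lengths m+1 and m.

    Richman–Moorman convention: both lengths use the first ``n - m``
    templates; matches use the Chebyshev distance with ``d <= r`` and
    self-matches excluded.
    """
    n = x.size
    nm = n - m
    if nm < 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    sim = np.abs(x[:, None] - x[None, :]) <= r
    c = sim[:nm, :nm].copy()
    for k in range(1, m):
        c &= sim[k : k + nm, k : k + nm]
    b = (int(c.sum()) - nm) // 2
    c &= sim[m : m + nm, m : m + nm]
    a = (int(c.sum()) - nm) // 2
    return a, b


# ---------------------------------------------------------------------------
# template-matching family

def sample_entropy(series, m: int = 2, r: float | None = None, tau: int = 1,
                   max_n: int | None = MAX_QUAD_N) -> float:
    """SampEn: -ln(A/B) with Chebyshev matching and no self-matches."""
    x = _cap(_series(series), max_n)
    if tau > 1:
        x = x[::tau]
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    r = _default_r(x, r)
    a, b = _sampen_counts(x, m, r)
    if b == 0 or a == 0:
        raise DegenerateInputError("no matched templates; SampEn undefined")
    return float(-np.log(a / b) + 0.0)  # +0.0 normalizes -0.0 at a == b


def fuzzy_entropy(series, m: int = 2, r: float | None = None,
                  max_n: int | None = MAX_QUAD_N) -> float:
    """FuzzEn with Gaussian membership mu = exp(-d^2 / (2 r^2)).

    Template vectors are baseline-removed (their own mean subtracted);
    distances are Chebyshev; self-pairs excluded.
    """
    x = _cap(_series(series), max_n)
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    r = _default_r(x, r)
    if r == 0.0:
        return 0.0  # constant series: all memberships are 1

    def phi(k: int) -> float:
        nv = x.size - m  # same vector count at both lengths
        v = _embed(x, k)[:nv]
        v = v - v.mean(axis=1, keepdims=True)
        d = cdist(v, v, metric="chebyshev")
        mu = np.exp(-(d**2) / (2.0 * r * r))
        return float((mu.sum() - nv) / (nv * (nv - 1)))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        raise DegenerateInputError("zero membership sum; FuzzEn undefined")
    return -float(np.log(p_m1 / p_m))


def kolmogorov_sinai_entropy(series, m: int = 2, r: float | None = None,
                             max_n: int | None = MAX_QUAD_N) -> float:
    """K2 correlation-entropy estimate ln(C_m(r) / C_{m+1}(r)).

    Correlation sums use all available templates at each length
    (Grassberger–Procaccia normalization), distinguishing this estimate
    from SampEn's fixed-template-count convention.
    """
    x = _cap(_series(series), max_n)
    if x.size <= m + 1:
        raise ValueError(f"series of length {x.size} too short for m={m}")
    r = _default_r(x, r)

    def corr_sum(k: int) -> float:
        v = _embed(x, k)
        nv = v.shape[0]
        if nv < 2:
            return 0.0
        d = cdist(v, v, metric="chebyshev")
        matches = (int((d <= r).sum()) - nv) // 2
        return matches / (nv * (nv - 1) / 2)

    c_m, c_m1 = corr_sum(m), corr_sum(m + 1)
    if c_m <= 0 or c_m1 <= 0:
        raise DegenerateInputError("empty correlation sum; K2 undefined")
    return float(np.log(c_m / c_m1))


# ---------------------------------------------------------------------------
# multiscale families (scalar summaries: mean over scales 1..n_scales)

def _mean_over_scales(variants: list[np.ndarray], m: int, r: float) -> float:
    vals = []
    for y in variants:
        if y.size <= m + 1:
            continue
        try:
            a, b = _sampen_counts(y, m, r)
        except ValueError:
            continue
        if a > 0 and b > 0:
            vals.append(-float(np.log(a / b)))
    if not vals:
        raise DegenerateInputError("SampEn undefined at every scale")
    return float(np.mean(vals))


def multiscale_entropy(series, m: int = 2, r: float | None = None,
                       n_scales: int = 5, max_n: int | None = MAX_QUAD_N) -> float:
    """Costa MSE: SampEn of non-overlapping coarse-grained series,
    tolerance fixed from the original series, averaged over scales."""
    x = _cap(_series(series), max_n)
    r = _default_r(x, r)
    grains = []
    for s in range(1, n_scales + 1):
        nb = x.size // s
        if nb <= m + 1:
            break
        grains.append(x[: nb * s].reshape(nb, s).mean(axis=1))
    if not grains:
        raise DegenerateInputError("series too short for any scale")
    return _mean_over_scales(grains, m, r)


def enhanced_multiscale_entropy(series, m: int = 2, r: float | None = None,
                                n_scales: int = 5,
                                max_n: int | None = MAX_QUAD_N) -> float:
    """Moving-average coarse-graining variant of MSE (overlapping windows
    preserve series length, reducing the variance of large-scale
    estimates), averaged over scales."""
    x = _cap(_series(series), max_n)
    r = _default_r(x, r)
    grains = []
    for s in range(1, n_scales + 1):
        if x.size - s + 1 <= m + 1:
            break
        kernel = np.full(s, 1.0 / s)
        grains.append(np.convolve(x, kernel, mode="valid"))
    if not grains:
        raise DegenerateInputError("series too short for any scale")
    return _mean_over_scales(grains, m, r)


def hierarchical_multiscale_entropy(series, m: int = 2, r: float | None = None,
                                    n_levels: int = 5,
                                    max_n: int | None = MAX_QUAD_N) -> float:
    """SampEn along the low-frequency branch of a dyadic averaging
    hierarchy (levels 0..n_levels-1), tolerance recomputed per node,
    averaged over levels."""
    x = _cap(_series(series), max_n)
    vals = []
    node = x
    for _ in range(n_levels):
        if node.size <= m + 1:
            break
        r_node = _default_r(node, r)
        try:
            a, b = _sampen_counts(node, m, r_node)
            if a > 0 and b > 0:
                vals.append(-float(np.log(a / b)))
        except ValueError:
            break
        half = node.size // 2
        node = 0.5 * (node[0 : 2 * half : 2] + node[1 : 2 * half : 2])
    if not vals:
        raise DegenerateInputError("SampEn undefined at every hierarchy level")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# ordinal / symbolic family

def permutation_entropy(series, order: int = 3, tau: int = 1,
                        normalized: bool = True) -> float:
    """Shannon entropy of ordinal-pattern frequencies (stable-argsort
    tie-break), optionally normalized by ln(order!)."""
    x = _series(series)
    if x.size <= (order - 1) * tau:
        raise ValueError(f"series of length {x.size} too short for order={order}, tau={tau}")
    windows = _embed(x, order, tau)
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    h = _shannon(counts / counts.sum())
    if normalized:
        h /= np.log(float(np.prod(np.arange(1, order + 1))))
    return float(h)


def increment_entropy(series, m: int = 2, resolution: int = 4) -> float:
    """IncrEn: entropy (bits) of words of signed, magnitude-quantized
    increments, normalized by m - 1."""
    x = _series(series)
    v = np.diff(x)
    if v.size < m:
        raise ValueError("series too short for increment words")
    sigma = float(np.std(v))
    if sigma > 0:
        q = np.minimum(resolution, np.floor(np.abs(v) * resolution / sigma))
    else:
        q = np.zeros_like(v)
    w = np.sign(v) * q
    words = _embed(w, m)
    _, counts = np.unique(words, axis=0, return_counts=True)
    return _shannon(counts / counts.sum(), base="bit") / (m - 1)


def slope_entropy(series, m: int = 3, gamma: float = 1.0, delta: float = 1e-3) -> float:
    """SlopEn: entropy of words of slope symbols in five classes split at
    +-delta and +-gamma."""
    x = _series(series)
    d = np.diff(x)
    if d.size < m - 1:
        raise ValueError("series too short for slope words")
    sym = np.where(d > gamma, 2,
          np.where(d > delta, 1,
          np.where(d >= -delta, 0,
          np.where(d >= -gamma, -1, -2)))).astype(float)
    words = _embed(sym, m - 1)
    _, counts = np.unique(words, axis=0, return_counts=True)
    return _shannon(counts / counts.sum())


def symbolic_dynamics_entropy(series, n_symbols: int = 3, m: int = 3) -> float:
    """SyDyEn: quantile (max-entropy) alphabet of ``n_symbols``, word
    length m, Shannon entropy normalized by ln(n_symbols^m)."""
    x = _series(series)
    if x.size < m + 1:
        raise ValueError("series too short for symbolic words")
    edges = np.quantile(x, np.linspace(0, 1, n_symbols + 1)[1:-1])
    sym = np.searchsorted(edges, x, side="right").astype(float)
    words = _embed(sym, m)
    _, counts = np.unique(words, axis=0, return_counts=True)
    return _shannon(counts / counts.sum()) / np.log(float(n_symbols) ** m)


def conditional_entropy(series, m: int = 2, bins: int = 6) -> float:
    """Corrected conditional entropy (Porta): E(m) - E(m-1) plus the
    single-occurrence correction perc(m) * E(1), on a 6-level equal-width
    quantization."""
    x = _series(series)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateInputError("cannot quantize a constant series")
    sym = np.minimum((bins * (x - lo) / (hi - lo)).astype(int), bins - 1).astype(float)

    def word_counts(k: int) -> np.ndarray:
        _, counts = np.unique(_embed(sym, k), axis=0, return_counts=True)
        return counts

    c_m = word_counts(m)
    e_m = _shannon(c_m / c_m.sum())
    c_prev = word_counts(m - 1)
    e_prev = _shannon(c_prev / c_prev.sum())
    c_1 = word_counts(1)
    e_1 = _shannon(c_1 / c_1.sum())
    perc = float((c_m == 1).sum()) / float(c_m.sum())
    return e_m - e_prev + perc * e_1


def attention_entropy(series) -> float:
    """AttnEn: mean Shannon entropy (bits) of the four key-pattern interval
    distributions (max-max, min-min, max-min, min-max intervals between
    strict local extrema)."""
    x = _series(series)
    mid = x[1:-1]
    maxima = np.flatnonzero((mid > x[:-2]) & (mid > x[2:])) + 1
    minima = np.flatnonzero((mid < x[:-2]) & (mid < x[2:])) + 1
    if maxima.size < 2 or minima.size < 2:
        raise DegenerateInputError("too few extrema for attention entropy")
    events = np.concatenate([maxima, minima])
    kinds = np.concatenate([np.ones(maxima.size), -np.ones(minima.size)])
    order = np.argsort(events, kind="stable")
    events, kinds = events[order], kinds[order]
    gaps = np.diff(events)
    pair = (kinds[:-1], kinds[1:])
    groups = {
        "max-max": gaps[(pair[0] == 1) & (pair[1] == 1)],
        "min-min": gaps[(pair[0] == -1) & (pair[1] == -1)],
        "max-min": gaps[(pair[0] == 1) & (pair[1] == -1)],
        "min-max": gaps[(pair[0] == -1) & (pair[1] == 1)],
    }
    hs = []
    for g in groups.values():
        if g.size == 0:
            continue
        _, counts = np.unique(g, return_counts=True)
        hs.append(_shannon(counts / counts.sum(), base="bit"))
    if not hs:
        raise DegenerateInputError("no extremum interval pairs")
    return float(np.mean(hs))


def cosine_similarity_entropy(series, m: int = 2, r: float = 0.1,
                              max_n: int | None = MAX_QUAD_N) -> float:
    """CoSiEn: binary Shannon entropy (bits) of the fraction of embedded
    vector pairs whose angular distance arccos(cos_sim)/pi is below r."""
    x = _cap(_series(series), max_n)
    if x.size <= m:
        raise ValueError("series too short to embed")
    v = _embed(x, m)
    norms = np.linalg.norm(v, axis=1)
    keep = norms > 0
    v, norms = v[keep], norms[keep]
    nv = v.shape[0]
    if nv < 2:
        raise DegenerateInputError("too few non-zero vectors")
    cos = np.clip((v @ v.T) / np.outer(norms, norms), -1.0, 1.0)
    # angular distance arccos(cos)/pi < r  <=>  cos > cos(pi * r)
    close = int(np.count_nonzero(cos > np.cos(np.pi * r)))
    n_pairs = nv * (nv - 1) // 2
    p = (close - nv) / 2 / n_pairs  # remove self-pairs, halve the symmetry
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))


def distribution_entropy(series, m: int = 2, bins: int = 64,
                         max_n: int | None = MAX_QUAD_N) -> float:
    """DistEn: normalized Shannon entropy (bits) of the histogram of all
    pairwise Chebyshev inter-vector distances."""
    x = _cap(_series(series), max_n)
    if x.size <= m:
        raise ValueError("series too short to embed")
    v = _embed(x, m)
    nv = v.shape[0]
    d = cdist(v, v, metric="chebyshev")
    dmax = float(d.max())
    if dmax == 0.0:
        return 0.0  # constant series: one occupied bin
    # histogram the full symmetric matrix, then remove the nv diagonal
    # zeros and halve (each unordered pair is counted twice)
    counts, _ = np.histogram(d, bins=bins, range=(0.0, dmax))
    counts[0] -= nv
    counts = counts // 2
    return _shannon(counts / counts.sum(), base="bit") / np.log2(bins)


def entropy_of_entropy(series, window: int = 5, states: int = 10) -> float:
    """EoE: Shannon entropy of the distribution of per-window state
    entropies (amplitude discretized into ``states`` slices over the
    global range)."""
    x = _series(series)
    n_w = x.size // window
    if n_w < 2:
        raise ValueError("series too short for entropy-of-entropy windows")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    sym = np.minimum((states * (x - lo) / (hi - lo)).astype(int), states - 1)
    wins = sym[: n_w * window].reshape(n_w, window)
    h1 = np.empty(n_w)
    for i, w in enumerate(wins):
        counts = np.bincount(w, minlength=states)
        h1[i] = _shannon(counts[counts > 0] / window)
    _, counts = np.unique(np.round(h1, 12), return_counts=True)
    return _shannon(counts / counts.sum())


def grid_distribution_entropy(series, grid: int = 3, tau: int = 1) -> float:
    """GridEn (GDE): normalized Shannon entropy of the occupancy of the
    (x_i, x_{i+tau}) plane partitioned into a grid x grid lattice."""
    x = _series(series)
    if x.size <= tau:
        raise ValueError("series too short for the requested lag")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise DegenerateInputError("cannot grid a constant series")
    u = np.minimum((grid * (x - lo) / (hi - lo)).astype(int), grid - 1)
    cell = u[:-tau] * grid + u[tau:]
    counts = np.bincount(cell, minlength=grid * grid)
    return _shannon(counts[counts > 0] / cell.size) / np.log(float(grid * grid))


def phase_entropy(series, sectors: int = 8) -> float:
    """Normalized Shannon entropy of the analytic-signal instantaneous
    phase over equal angular sectors."""
    x = _series(series)
    if x.size < 4:
        raise ValueError("series too short for the Hilbert transform")
    phase = np.angle(hilbert(x - x.mean()))
    counts, _ = np.histogram(phase, bins=sectors, range=(-np.pi, np.pi))
    if counts.sum() == 0:
        raise DegenerateInputError("empty phase histogram")
    return _shannon(counts[counts > 0] / counts.sum()) / np.log(float(sectors))


def spectral_entropy(series, normalized: bool = True) -> float:
    """Shannon entropy of the normalized periodogram (mean removed)."""
    x = _series(series)
    if x.size < 8:
        raise ValueError("series too short for a spectrum")
    _, pxx = periodogram(x, detrend="constant")
    pxx = pxx[1:]  # drop the (detrended) DC bin
    total = pxx.sum()
    if total <= 0:
        raise DegenerateInputError("zero spectral power")
    h = _shannon(pxx[pxx > 0] / total)
    return float(h / np.log(pxx.size)) if normalized else float(h)


def wavelet_entropy(series, wavelet_name: str = "db6", max_level: int = 6) -> float:
    """Shannon entropy of relative multilevel wavelet sub-band energies."""
    x = _series(series)
    level = min(max_level, pywt.dwt_max_level(x.size, wavelet_name))
    if level < 1:
        raise DegenerateInputError("series too short for any wavelet level")
    coeffs = pywt.wavedec(x - x.mean(), wavelet_name, mode="periodization", level=level)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        raise DegenerateInputError("zero signal energy")
    return _shannon(energies[energies > 0] / total)


def hurst_exponent(series, min_window: int = 8, n_windows: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent: slope of log mean(R/S) against
    log window size over logarithmically spaced window sizes."""
    x = _series(series)
    if x.size < 4 * min_window:
        raise ValueError("series too short for R/S analysis")
    sizes = np.unique(np.floor(np.logspace(
        np.log10(min_window), np.log10(x.size // 2), n_windows)).astype(int))
    log_l, log_rs = [], []
    for length in sizes:
        nb = x.size // length
        blocks = x[: nb * length].reshape(nb, length)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        walk = np.cumsum(dev, axis=1)
        rng = walk.max(axis=1) - walk.min(axis=1)
        std = blocks.std(axis=1)
        ok = std > 0
        if not ok.any():
            continue
        log_l.append(np.log(length))
        log_rs.append(np.log(np.mean(rng[ok] / std[ok])))
    if len(log_l) < 2:
        raise DegenerateInputError("R/S undefined (constant blocks)")
    slope = np.polyfit(log_l, log_rs, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# amplitude-histogram family

def shannon_entropy(series, bins: int = 16) -> float:
    """Shannon entropy (nats) of a 16-bin equal-width amplitude histogram."""
    return _shannon(_hist_probs(_series(series), bins))


def renyi_entropy(series, alpha: float = 2.0, bins: int = 16) -> float:
    """Rényi entropy ln(sum p^alpha) / (1 - alpha); alpha = 1 routes to
    Shannon."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    p = _hist_probs(_series(series), bins)
    if alpha == 1.0:
        return _shannon(p)
    p = p[p > 0]
    return float(np.log(np.sum(p**alpha)) / (1.0 - alpha))


def tsallis_entropy(series, q: float = 2.0, bins: int = 16) -> float:
    """Tsallis entropy (1 - sum p^q) / (q - 1); q = 1 routes to Shannon."""
    p = _hist_probs(_series(series), bins)
    if q == 1.0:
        return _shannon(p)
    p = p[p > 0]
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


# ---------------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class MeasureDef:
    name: str
    func: Callable[..., float]
    params: dict = field(default_factory=dict)
    reference: str = ""


def entropy_registry() -> "OrderedDict[str, MeasureDef]":
    """The 23 registered measures, in stable order.

    The order (and the inclusion of the amplitude-histogram Shannon entropy
    as the 23rd measure) is fixed so feature matrices have a deterministic
    column layout.
    """
    defs = [
        MeasureDef("attention", attention_entropy, {}, "AttnEn (Yang et al. 2020)"),
        MeasureDef("conditional", conditional_entropy, {"m": 2, "bins": 6},
                   "corrected conditional entropy (Porta et al. 1998)"),
        MeasureDef("cosine_similarity", cosine_similarity_entropy, {"m": 2, "r": 0.1},
                   "CoSiEn (Chanwimalueang & Mandic 2017)"),
        MeasureDef("distribution", distribution_entropy, {"m": 2, "bins": 64},
                   "DistEn (Li et al. 2015)"),
        MeasureDef("entropy_of_entropy", entropy_of_entropy, {"window": 5, "states": 10},
                   "EoE (Hsu et al. 2017)"),
        MeasureDef("grid_distribution", grid_distribution_entropy, {"grid": 3, "tau": 1},
                   "GridEn/GDE (Yan et al. 2019)"),
        MeasureDef("increment", increment_entropy, {"m": 2, "resolution": 4},
                   "IncrEn (Liu et al. 2016)"),
        MeasureDef("phase", phase_entropy, {"sectors": 8},
                   "analytic-signal phase entropy"),
        MeasureDef("slope", slope_entropy, {"m": 3, "gamma": 1.0, "delta": 1e-3},
                   "SlopEn (Cuesta-Frau 2019)"),
        MeasureDef("spectral", spectral_entropy, {},
                   "normalized periodogram entropy (Inouye et al. 1991)"),
        MeasureDef("symbolic_dynamics", symbolic_dynamics_entropy, {"n_symbols": 3, "m": 3},
                   "SyDyEn, max-entropy partition"),
        MeasureDef("tsallis", tsallis_entropy, {"q": 2.0, "bins": 16},
                   "Tsallis (1988), amplitude histogram"),
        MeasureDef("renyi", renyi_entropy, {"alpha": 2.0, "bins": 16},
                   "Renyi (1961), amplitude histogram"),
        MeasureDef("wavelet", wavelet_entropy, {"wavelet_name": "db6", "max_level": 6},
                   "relative sub-band energy entropy (Rosso et al. 2001)"),
        MeasureDef("hurst", hurst_exponent, {},
                   "rescaled-range exponent (Hurst 1951)"),
        MeasureDef("fuzzy", fuzzy_entropy, {"m": 2},
                   "FuzzEn, Gaussian membership (Chen et al. 2007)"),
        MeasureDef("hierarchical_multiscale", hierarchical_multiscale_entropy,
                   {"m": 2, "n_levels": 5}, "hierarchical entropy (Jiang et al. 2011)"),
        MeasureDef("kolmogorov_sinai", kolmogorov_sinai_entropy, {"m": 2},
                   "K2 correlation entropy (Grassberger & Procaccia 1983)"),
        MeasureDef("multiscale", multiscale_entropy, {"m": 2, "n_scales": 5},
                   "MSE (Costa et al. 2002)"),
        MeasureDef("permutation", permutation_entropy, {"order": 3, "tau": 1},
                   "PermEn (Bandt & Pompe 2002)"),
        MeasureDef("enhanced_multiscale", enhanced_multiscale_entropy,
                   {"m": 2, "n_scales": 5}, "moving-average MSE (Wu et al. 2013)"),
        MeasureDef("sample", sample_entropy, {"m": 2},
                   "SampEn (Richman & Moorman 2000)"),
        MeasureDef("shannon", shannon_entropy, {"bins": 16},
                   "Shannon (1948), amplitude histogram"),
    ]
    registry: OrderedDict[str, MeasureDef] = OrderedDict()
    for d in defs:
        if d.name in registry:
            raise RuntimeError(f"duplicate measure name {d.name!r}")
        if not d.name.isidentifier():
            raise RuntimeError(f"measure name {d.name!r} is not a valid suffix")
        registry[d.name] = d
    assert len(registry) == 23
    return registry


_REGISTRY = entropy_registry()
ENTROPY_NAMES = tuple(_REGISTRY)


def compute_measure(name: str, series, params: dict | None = None) -> float:
    """Dispatch one registry measure; degeneracies become NaN (logged)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown entropy measure {name!r}; known: {list(_REGISTRY)}")
    d = _REGISTRY[name]
    kwargs = dict(d.params)
    if params:
        kwargs.update(params)
    try:
        return float(d.func(series, **kwargs))
    except DegenerateInputError as exc:
        log.info("measure %s degenerate: %s", name, exc)
        return float("nan")
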