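"""Per-segment signal decomposition into 13 named component groups.

Each preprocessed segment is expanded into:

* ``orj`` — the segment itself;
* ``d1`` ... ``d6``, ``a6`` — detail and approximation *coefficient*
  sequences of a six-level db6 multilevel DWT (periodization extension, so
  the transform is orthonormal and energy-preserving);
* ``imf1`` ... ``imf5`` — the first five intrinsic mode functions from
  empirical mode decomposition.

EMD is implemented here with the standard sifting procedure: local extrema
are located, upper and lower envelopes are built by cubic-spline
interpolation (with mirror-extension of the outermost extrema past both
boundaries), the mean envelope is subtracted, and the step iterates until
the candidate satisfies the IMF conditions — the number of zero crossings
and extrema differ by at most one, and the mean envelope is near zero — as
measured by a Cauchy-type stopping criterion (relative change between
consecutive sift iterates below ``sift_stop_sd``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .types import COMPONENT_NAMES, EcgSegment

__all__ = [
    "ComponentSet",
    "EmdParams",
    "dwt_decompose",
    "emd_decompose",
    "build_component_set",
    "zero_crossings",
    "count_extrema",
]


@dataclass
class ComponentSet:
    """Mapping component name -> sample sequence for one segment.

    Components that could not be produced (e.g. a degenerate input that
    yields fewer than five IMFs) are listed in ``absent`` and do not appear
    in ``components``.
    """

    components: dict[str, np.ndarray]
    segment: EcgSegment | None = None
    absent: list[str] = field(default_factory=list)
    residue: np.ndarray | None = None

    def names(self) -> list[str]:
        return sorted(self.components)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.components[name]

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class EmdParams:
    max_imfs: int = 5
    sift_stop_sd: float = 0.2
    max_sift_iters: int = 100
    envelope_interp: str = "cubic_spline"

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.sift_stop_sd <= 0:
            raise ValueError("sift_stop_sd must be > 0")
        if self.envelope_interp != "cubic_spline":
            raise ValueError("only cubic_spline envelopes are supported")


# ---------------------------------------------------------------------------
# DWT branch

def dwt_decompose(seg: EcgSegment | np.ndarray, wavelet_name: str = "db6",
                  levels: int = 6) -> dict[str, np.ndarray]:
    """Detail (d1 finest ... d6 coarsest) and approximation (a6) coefficients."""
    x = seg.samples if isinstance(seg, EcgSegment) else np.asarray(seg, dtype=float)
    if x.size < 2 ** levels:
        raise ValueError(
            f"segment of length {x.size} too short for {levels}-level DWT "
            f"(needs >= {2 ** levels})"
        )
    coeffs = pywt.wavedec(x, wavelet_name, mode="periodization", level=levels)
    out = {f"a{levels}": coeffs[0]}
    for lvl, c in zip(range(levels, 0, -1), coeffs[1:]):
        out[f"d{lvl}"] = c
    return out


# ---------------------------------------------------------------------------
# EMD branch

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima."""
    dx = np.diff(x)
    # collapse flat steps so plateaus yield a single extremum edge
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    # forward-fill zero slopes so plateaus inherit the preceding direction
    pos = np.where(nz, np.arange(sign.size), 0)
    np.maximum.accumulate(pos, out=pos)
    filled = sign[pos]
    turn = np.diff(filled)
    maxima = np.flatnonzero(turn < 0) + 1
    minima = np.flatnonzero(turn > 0) + 1
    return maxima, minima


def count_extrema(x: np.ndarray) -> int:
    mx, mn = _local_extrema(np.asarray(x, dtype=float))
    return mx.size + mn.size


def zero_crossings(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _envelope(idx: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    t = idx.astype(float)
    v = x[idx]
    k = min(2, idx.size)
    t_pre = -t[1 : k + 1][::-1] if idx.size > 1 else -t[:1]
    v_pre = v[1 : k + 1][::-1] if idx.size > 1 else v[:1]
    t_post = 2 * (n - 1) - t[-k - 1 : -1][::-1] if idx.size > 1 else 2 * (n - 1) - t[-1:]
    v_post = v[-k - 1 : -1][::-1] if idx.size > 1 else v[-1:]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    return CubicSpline(tt, vv)(np.arange(n))


def _imf_conditions(h: np.ndarray) -> bool:
    return abs(zero_crossings(h) - count_extrema(h)) <= 1


def _sift(x: np.ndarray, params: EmdParams) -> np.ndarray | None:
    """Extract one IMF from ``x``; None if too few extrema to sift."""
    n = x.size
    h = x
    for _ in range(params.max_sift_iters):
        maxima, minima = _local_extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        upper = _envelope(maxima, h, n)
        lower = _envelope(minima, h, n)
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = float(np.sum(h * h)) + 1e-300
        sd = float(np.sum((h - h_new) ** 2)) / denom
        h = h_new
        if sd < params.sift_stop_sd and _imf_conditions(h):
            break
    return h


def emd_decompose(seg: EcgSegment | np.ndarray,
                  params: EmdParams | None = None) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Sift out up to ``max_imfs`` IMFs; returns (imfs, residue).

    The decomposition is complete by construction: the sum of the returned
    IMFs and the residue reproduces the input exactly (floating-point
    associativity aside).  Inputs without oscillation (monotone ramps)
    return zero IMFs and the input as residue.
    """
    params = params or EmdParams()
    x = seg.samples if isinstance(seg, EcgSegment) else np.asarray(seg, dtype=float)
    residue = x.astype(float).copy()
    imfs: dict[str, np.ndarray] = {}
    for k in range(1, params.max_imfs + 1):
        maxima, minima = _local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        imf = _sift(residue, params)
        if imf is None:
            break
        imfs[f"imf{k}"] = imf
        residue = residue - imf
    return imfs, residue


# ---------------------------------------------------------------------------
# Combined 13-component set

def build_component_set(
    seg: EcgSegment,
    wavelet_name: str = "db6",
    levels: int = 6,
    emd_params: EmdParams | None = None,
) -> ComponentSet:
    """Original signal + 7 DWT bands + first 5 IMFs (13 named groups)."""
    comps: dict[str, np.ndarray] = {"orj": seg.samples}
    comps.update(dwt_decompose(seg, wavelet_name, levels))
    imfs, residue = emd_decompose(seg, emd_params)
    comps.update(imfs)
    absent = [name for name in COMPONENT_NAMES if name not in comps]
    return ComponentSet(components=comps, segment=seg, absent=absent, residue=residue)
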