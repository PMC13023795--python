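"""Independent brute-force reference implementations.

These are deliberately naive (double loops, explicit enumeration) and share
no code with the package's vectorized estimators; the tests assert exact
agreement (integer template counts) or 1e-12 agreement on short series.
"""

from collections import Counter
from math import exp, log, log2

import numpy as np


def _cheb(a, b) -> float:
    return max(abs(x - y) for x, y in zip(a, b))


def sampen_bruteforce(x, m=2, r=None) -> float:
    x = list(map(float, x))
    n = len(x)
    if r is None:
        r = 0.2 * float(np.std(x))
    nm = n - m
    a = b = 0
    for i in range(nm):
        for j in range(i + 1, nm):
            if _cheb(x[i : i + m], x[j : j + m]) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return -log(a / b), a, b


def permen_bruteforce(x, order=3, tau=1, normalized=True) -> float:
    x = list(map(float, x))
    counts = Counter()
    for i in range(len(x) - (order - 1) * tau):
        window = [x[i + k * tau] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        counts[pattern] += 1
    total = sum(counts.values())
    h = -sum(c / total * log(c / total) for c in counts.values())
    if normalized:
        fact = 1
        for k in range(2, order + 1):
            fact *= k
        h /= log(fact)
    return h


def fuzzen_bruteforce(x, m=2, r=None) -> float:
    x = list(map(float, x))
    n = len(x)
    if r is None:
        r = 0.2 * float(np.std(x))

    def phi(k):
        nv = n - m
        vecs = []
        for i in range(nv):
            v = x[i : i + k]
            mu = sum(v) / k
            vecs.append([a - mu for a in v])
        total = 0.0
        for i in range(nv):
            for j in range(nv):
                if i != j:
                    d = _cheb(vecs[i], vecs[j])
                    total += exp(-(d * d) / (2 * r * r))
        return total / (nv * (nv - 1))

    return -log(phi(m + 1) / phi(m))


def histogram_probs(x, bins):
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    counts = [0] * bins
    width = (hi - lo) / bins
    for v in x:
        idx = bins - 1 if v == hi else int((v - lo) / width)
        counts[min(idx, bins - 1)] += 1
    return [c / len(x) for c in counts]


def renyi_bruteforce(x, alpha=2.0, bins=16) -> float:
    p = [q for q in histogram_probs(x, bins) if q > 0]
    if alpha == 1.0:
        return -sum(q * log(q) for q in p)
    return log(sum(q**alpha for q in p)) / (1.0 - alpha)


def tsallis_bruteforce(x, q_order=2.0, bins=16) -> float:
    p = [q for q in histogram_probs(x, bins) if q > 0]
    if q_order == 1.0:
        return -sum(q * log(q) for q in p)
    return (1.0 - sum(q**q_order for q in p)) / (q_order - 1.0)


def disten_bruteforce(x, m=2, bins=64) -> float:
    x = list(map(float, x))
    n = len(x)
    vecs = [x[i : i + m] for i in range(n - m + 1)]
    dists = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            dists.append(_cheb(vecs[i], vecs[j]))
    dmax = max(dists)
    if dmax == 0:
        return 0.0
    counts = [0] * bins
    width = dmax / bins
    for d in dists:
        idx = bins - 1 if d == dmax else int(d / width)
        counts[min(idx, bins - 1)] += 1
    total = sum(counts)
    h = -sum(c / total * log2(c / total) for c in counts if c)
    return h / log2(bins)


def incren_bruteforce(x, m=2, resolution=4) -> float:
    x = list(map(float, x))
    v = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    sigma = float(np.std(v))
    words = Counter()
    elems = []
    for d in v:
        s = (d > 0) - (d < 0)
        q = min(resolution, int(abs(d) * resolution / sigma)) if sigma > 0 else 0
        elems.append(s * q)
    for i in range(len(elems) - m + 1):
        words[tuple(elems[i : i + m])] += 1
    total = sum(words.values())
    h = -sum(c / total * log2(c / total) for c in words.values())
    return h / (m - 1)
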