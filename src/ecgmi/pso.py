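"""Binary particle swarm optimization over feature masks.

Each particle carries a binary position (the candidate feature mask) and a
real velocity.  Velocities follow the canonical update

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with fresh uniform r1, r2 per component, clamped to [-v_max, v_max]; the
new position is drawn through the sigmoid transfer function
(bit = 1 with probability 1 / (1 + exp(-v))).  An all-zero mask is repaired
by setting one uniformly chosen bit.

Fitness (lower is better) balances wrapper accuracy against subset size:

    f = w_acc * (1 - innerAcc) + w_size * |mask| / N

where ``innerAcc`` is stratified 5-fold cross-validated accuracy of a
k-nearest-neighbour classifier (k = 5, per-fold standardization) on the
masked columns.  The wrapper k-NN is evaluated with a vectorized
numpy/scipy implementation because it runs tens of thousands of times per
swarm search; the final report classifiers live in
:mod:`ecgmi.classify` and are independent of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SwarmParams",
    "Particle",
    "SwarmState",
    "update_velocity",
    "binarize_position",
    "fitness",
    "run_pso",
    "make_planted_matrix",
]


@dataclass(frozen=True)
class SwarmParams:
    n_particles: int = 30
    n_iterations: int = 100
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 6.0
    w_acc: float = 0.99
    w_size: float = 0.01
    inner_folds: int = 5
    inner_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be >= 0")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")
        if abs(self.w_acc + self.w_size - 1.0) > 1e-12:
            raise ValueError("w_acc + w_size must equal 1")

    def inertia(self, iteration: int) -> float:
        if self.n_iterations <= 1:
            return self.inertia_start
        frac = iteration / (self.n_iterations - 1)
        return self.inertia_start + (self.inertia_end - self.inertia_start) * frac


@dataclass
class Particle:
    position: np.ndarray  # binary {0,1}
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int
    fitness_history: list[float] = field(default_factory=list)


def update_velocity(particle: Particle, gbest: np.ndarray, params: SwarmParams,
                    rng: np.random.Generator, inertia: float | None = None) -> np.ndarray:
    if particle.position.shape != gbest.shape or particle.velocity.shape != gbest.shape:
        raise ValueError("position / velocity / gbest dimension mismatch")
    w = params.inertia_start if inertia is None else inertia
    r1 = rng.random(gbest.size)
    r2 = rng.random(gbest.size)
    v = (w * particle.velocity
         + params.c1 * r1 * (particle.pbest_position - particle.position)
         + params.c2 * r2 * (gbest - particle.position))
    return np.clip(v, -params.v_max, params.v_max)


def binarize_position(velocity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sigmoid transfer: bit_j = 1 iff u_j < s(v_j); all-zero masks are
    repaired by setting one uniformly chosen bit."""
    s = 1.0 / (1.0 + np.exp(-velocity))
    bits = (rng.random(velocity.size) < s).astype(np.int8)
    if not bits.any():
        bits[rng.integers(velocity.size)] = 1
    return bits


# ---------------------------------------------------------------------------
# wrapper fitness

def _stratified_fold_ids(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Per-sample fold assignment, classwise round-robin after shuffling."""
    fold = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        fold[idx] = np.arange(idx.size) % k
    return fold


def _knn_cv_accuracy(x: np.ndarray, y: np.ndarray, fold: np.ndarray,
                     k_folds: int, k: int) -> float:
    correct = 0
    for f in range(k_folds):
        test = fold == f
        train = ~test
        mu = x[train].mean(axis=0)
        sd = x[train].std(axis=0)
        sd[sd == 0] = 1.0
        xtr = (x[train] - mu) / sd
        xte = (x[test] - mu) / sd
        d = cdist(xte, xtr)
        nn = np.argpartition(d, k - 1, axis=1)[:, :k]
        votes = (y[train][nn] == 1).sum(axis=1)
        pred = (votes * 2 > k).astype(int)
        correct += int((pred == y[test]).sum())
    return correct / y.size


class _FitnessEvaluator:
    """Caches the fold assignment so every mask is scored on identical
    inner folds (and repeated masks are scored once)."""

    def __init__(self, feature_matrix: np.ndarray, labels: np.ndarray,
                 params: SwarmParams):
        self.x = np.asarray(feature_matrix, dtype=float)
        self.y = np.asarray(labels)
        if self.x.ndim != 2 or self.x.shape[0] != self.y.size:
            raise ValueError("feature matrix / labels shape mismatch")
        classes = np.unique(self.y)
        if classes.size < 2:
            raise ValueError("fitness needs at least two classes")
        self.y01 = (self.y == classes[-1]).astype(int)  # binary recode; sign irrelevant for accuracy
        self.params = params
        rng = np.random.default_rng(params.seed)
        self.fold = _stratified_fold_ids(self.y01, params.inner_folds, rng)
        self._cache: dict[bytes, float] = {}

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("empty mask reached the fitness function")
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        acc = _knn_cv_accuracy(self.x[:, mask], self.y01, self.fold,
                               self.params.inner_folds, self.params.inner_k)
        f = (self.params.w_acc * (1.0 - acc)
             + self.params.w_size * mask.sum() / mask.size)
        self._cache[key] = f
        return f


def fitness(mask: np.ndarray, feature_matrix: np.ndarray, labels: np.ndarray,
            params: SwarmParams) -> float:
    """Standalone single-mask fitness (lower is better)."""
    return _FitnessEvaluator(feature_matrix, labels, params)(mask)


# ---------------------------------------------------------------------------
# main loop

def run_pso(feature_matrix: np.ndarray, labels: np.ndarray,
            params: SwarmParams | None = None) -> tuple[np.ndarray, SwarmState]:
    """Full binary-PSO search; returns (gbest mask, final swarm state)."""
    params = params or SwarmParams()
    evaluate = _FitnessEvaluator(feature_matrix, labels, params)
    n_feat = evaluate.x.shape[1]
    rng = np.random.default_rng(params.seed)

    particles: list[Particle] = []
    for _ in range(params.n_particles):
        pos = (rng.random(n_feat) < 0.5).astype(np.int8)
        if not pos.any():
            pos[rng.integers(n_feat)] = 1
        vel = rng.uniform(-1.0, 1.0, n_feat)
        f = evaluate(pos)
        particles.append(Particle(pos, vel, pos.copy(), f))

    best = min(particles, key=lambda p: p.pbest_fitness)
    state = SwarmState(particles=particles,
                       gbest_position=best.pbest_position.copy(),
                       gbest_fitness=best.pbest_fitness,
                       iteration=0,
                       fitness_history=[best.pbest_fitness])

    for it in range(params.n_iterations):
        w = params.inertia(it)
        for p in particles:
            p.velocity = update_velocity(p, state.gbest_position, params, rng, inertia=w)
            p.position = binarize_position(p.velocity, rng)
            f = evaluate(p.position)
            if f < p.pbest_fitness:
                p.pbest_fitness = f
                p.pbest_position = p.position.copy()
                if f < state.gbest_fitness:
                    state.gbest_fitness = f
                    state.gbest_position = p.position.copy()
        state.iteration = it + 1
        state.fitness_history.append(state.gbest_fitness)

    return state.gbest_position.copy(), state


# ---------------------------------------------------------------------------
# planted-feature benchmark

def make_planted_matrix(n_samples: int = 400, n_features: int = 50,
                        n_informative: int = 5, snr: float = 2.0,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class Gaussian matrix with class-shifted means on the first
    ``n_informative`` columns (shift = snr in noise-SD units).

    Returns (X, y, informative_mask); the generation process defines the
    selection ground truth.
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], [n_samples - n_samples // 2, n_samples // 2])
    x = rng.normal(size=(n_samples, n_features))
    x[y == 1, :n_informative] += snr
    informative = np.zeros(n_features, dtype=bool)
    informative[:n_informative] = True
    perm = rng.permutation(n_samples)
    return x[perm], y[perm], informative
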