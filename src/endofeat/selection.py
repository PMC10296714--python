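"""Wrapper feature selection with binary swarm metaheuristics.

Three optimizers search the space of binary feature masks over a fused
feature matrix:

* **BDA** — binary dragonfly algorithm: each agent feels separation,
  alignment, cohesion, attraction to the best mask found so far ("food") and
  repulsion from the current worst ("enemy"); the accumulated step is turned
  into a per-bit flip probability through a v-shaped transfer function
  Tf(dx) = |dx| / sqrt(1 + dx^2).
* **MFO** — moth-flame optimization: continuous positions in [0, 1]^D spiral
  around an elite, shrinking set of "flames" via
  S(W, F) = |F - W| * exp(c r) * cos(2 pi r) + F with r ~ U(-1, 1).
* **PSO** — particle swarm optimization: velocities
  v' = I v + c1 r (pbest - p) + c2 R (gbest - p), inertia I annealed
  0.9 -> 0.4, with velocity and position clamping.

Continuous positions are binarized (threshold 0.5 by default) before
evaluation.  The fitness of a mask is a weighted sum of the holdout error of
a cheap classifier (k-NN by default) trained on the masked columns and the
selected-feature fraction; lower is better.  All three searches are elitist:
the best mask ever seen is retained and the reported history is
monotonically non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .texture import FeatureMatrix

__all__ = [
    "FeatureMask",
    "BDACoefficients",
    "SelectorConfig",
    "SelectionResult",
    "transfer_v",
    "bda_forces",
    "bda_step_update",
    "dragonfly_coefficients",
    "mfo_flame_count",
    "mfo_spiral_update",
    "pso_velocity_update",
    "binarize_position",
    "wrapper_fitness",
    "select_features",
]


@dataclass
class FeatureMask:
    """Binary mask over D features; always has at least one bit set."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be a 1-D vector")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be binary")
        if self.bits.sum() < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class BDACoefficients:
    """Dragonfly behavior weights: separation s, alignment a, cohesion c,
    food attraction f, enemy distraction e, step inertia w."""

    s: float
    a: float
    c: float
    f: float
    e: float
    w: float

    def __post_init__(self) -> None:
        vals = (self.s, self.a, self.c, self.f, self.e, self.w)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("coefficients must be finite")
        if not 0 < self.w <= 1:
            raise ValueError("inertia w must lie in (0, 1]")


@dataclass
class SelectorConfig:
    """Configuration shared by the three selectors.

    ``w_err`` and ``w_frac`` weight the holdout error and the selected
    fraction in the fitness (they must sum to 1).  The fitness classifier is
    named as ``knn-<k>``.  ``train_frac`` fixes the single stratified split
    used for every fitness evaluation of a run.
    """

    method: str = "bda"
    population: int = 20
    iterations: int = 50
    seed: int = 0
    w_err: float = 0.99
    w_frac: float = 0.01
    fitness_classifier: str = "knn-5"
    train_frac: float = 0.7
    mfo_spiral_c: float = 1.0
    pso_inertia: tuple[float, float] = (0.9, 0.4)
    pso_c1: float = 2.0
    pso_c2: float = 2.0
    pso_vmax: float = 6.0
    binarize: str = "threshold"

    def __post_init__(self) -> None:
        if self.method not in ("bda", "mfo", "pso"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.iterations < 1:
            raise ValueError("iterations must be at least 1")
        if not math.isclose(self.w_err + self.w_frac, 1.0, abs_tol=1e-9):
            raise ValueError("w_err + w_frac must equal 1")
        if not self.fitness_classifier.startswith("knn-"):
            raise ValueError("fitness classifier must be of form 'knn-<k>'")
        self.pso_inertia = tuple(self.pso_inertia)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["pso_inertia"] = list(self.pso_inertia)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectorConfig":
        return cls(**d)


@dataclass
class SelectionResult:
    mask: FeatureMask
    best_fitness: float
    history: list[float]
    method: str
    config: SelectorConfig


def transfer_v(x: float):
    """V-shaped transfer function |x| / sqrt(1 + x^2), in [0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.abs(x) / np.sqrt(1.0 + x * x)
    return float(out) if out.ndim == 0 else out


def bda_forces(X: np.ndarray, neighbors: np.ndarray, neighbor_steps: np.ndarray,
               food: np.ndarray, enemy: np.ndarray):
    """Dragonfly behavior vectors for one agent.

    Returns (separation, alignment, cohesion, food attraction, enemy
    distraction), each per dimension.  With zero neighbors the agent is its
    own (only) neighbor, making separation and cohesion vanish.
    """
    X = np.atleast_1d(np.asarray(X, dtype=float))
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    neighbor_steps = np.atleast_2d(np.asarray(neighbor_steps, dtype=float))
    if neighbors.shape[0] == 0:
        neighbors = X[None, :]
        neighbor_steps = np.zeros_like(neighbors)
    food = np.atleast_1d(np.asarray(food, dtype=float))
    enemy = np.atleast_1d(np.asarray(enemy, dtype=float))
    sep = -(X[None, :] - neighbors).sum(axis=0)
    align = neighbor_steps.mean(axis=0)
    coh = neighbors.mean(axis=0) - X
    attract = food - X
    distract = enemy - X
    return sep, align, coh, attract, distract


def bda_step_update(positions: np.ndarray, steps: np.ndarray,
                    coeffs: BDACoefficients, food: np.ndarray, enemy: np.ndarray,
                    rng: np.random.Generator):
    """One binary-dragonfly update of the whole population.

    Steps follow dX' = (s S + a A + c C + f L + e E) + w dX with a global
    neighborhood (every other agent is a neighbor); each bit then flips with
    probability Tf(dX') drawn per bit.
    """
    positions = np.asarray(positions, dtype=float)
    steps = np.asarray(steps, dtype=float)
    P = positions.shape[0]
    sum_pos = positions.sum(axis=0)
    sum_steps = steps.sum(axis=0)
    # neighbor aggregates exclude the agent itself (P >= 2 enforced by config)
    sep = (sum_pos - positions) - (P - 1) * positions
    align = (sum_steps - steps) / (P - 1)
    coh = (sum_pos - positions) / (P - 1) - positions
    attract = food[None, :] - positions
    distract = enemy[None, :] - positions
    new_steps = (coeffs.s * sep + coeffs.a * align + coeffs.c * coh
                 + coeffs.f * attract + coeffs.e * distract) + coeffs.w * steps
    flip = rng.random(positions.shape) < transfer_v(new_steps)
    new_positions = np.where(flip, 1.0 - positions, positions)
    return new_positions, new_steps


def dragonfly_coefficients(k: int, T: int, rng: np.random.Generator) -> BDACoefficients:
    """Per-iteration coefficient schedule of the original dragonfly algorithm:
    inertia w anneals linearly 0.9 -> 0.4; the exploration envelope my_c
    shrinks from 0.1 to 0 over the first half of the run."""
    frac = k / max(T - 1, 1)
    w = 0.9 - 0.5 * frac
    my_c = max(0.1 - k * 0.2 / T, 0.0)
    return BDACoefficients(
        s=2.0 * rng.random() * my_c,
        a=2.0 * rng.random() * my_c,
        c=2.0 * rng.random() * my_c,
        f=2.0 * rng.random(),
        e=my_c,
        w=w,
    )


def mfo_flame_count(M: int, k: int, T: int) -> int:
    """Flame count at iteration k of T: round(M - k (M-1) / T), at least 1.

    Rounding is half away from zero, so the count shrinks deterministically
    from M to 1 at k = T.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if not 1 <= k <= T:
        raise ValueError(f"iteration k={k} outside [1, {T}]")
    val = M - k * (M - 1) / T
    return max(1, int(math.floor(val + 0.5)))


def mfo_spiral_update(W_i: np.ndarray, F_j: np.ndarray, r, c: float = 1.0):
    """Logarithmic spiral move of moth W_i around flame F_j:
    |F - W| * exp(c r) * cos(2 pi r) + F, with r in [-1, 1] (scalar or per
    dimension)."""
    W_i = np.asarray(W_i, dtype=float)
    F_j = np.asarray(F_j, dtype=float)
    r = np.asarray(r, dtype=float)
    dist = np.abs(F_j - W_i)
    out = dist * np.exp(c * r) * np.cos(2.0 * np.pi * r) + F_j
    return float(out) if out.ndim == 0 else out


def pso_velocity_update(v, p, l_personal, l_global, I: float,
                        c1: float, c2: float, r, R):
    """PSO velocity rule v' = I v + c1 r (pbest - p) + c2 R (gbest - p)."""
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    out = (I * v + c1 * np.asarray(r, dtype=float) * (np.asarray(l_personal) - p)
           + c2 * np.asarray(R, dtype=float) * (np.asarray(l_global) - p))
    return float(out) if out.ndim == 0 else out


def binarize_position(x, rand, method: str = "threshold"):
    """Turn a continuous position in [0, 1] into a bit.

    ``threshold``: 1 iff x > 0.5 (strict, tie maps to 0).
    ``stochastic``: 1 iff rand < x.
    """
    x = np.asarray(x, dtype=float)
    rand = np.asarray(rand, dtype=float)
    if method == "threshold":
        out = (x > 0.5).astype(np.uint8)
    elif method == "stochastic":
        out = (rand < x).astype(np.uint8)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return int(out) if out.ndim == 0 else out


class _FitnessEvaluator:
    """Wrapper fitness with a single stratified holdout split fixed per run.

    fitness(mask) = w_err * (1 - holdout accuracy) + w_frac * |mask| / D
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: SelectorConfig):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.cfg = cfg
        self.D = self.X.shape[1]
        k = int(cfg.fitness_classifier.split("-", 1)[1])
        self.n_neighbors = k
        rng = np.random.default_rng(cfg.seed)
        self.train_idx, self.test_idx = _stratified_split(
            self.y, cfg.train_frac, rng)

    def __call__(self, bits: np.ndarray, rng: np.random.Generator) -> float:
        bits = np.asarray(bits).astype(np.uint8)
        if bits.sum() == 0:
            bits = bits.copy()
            bits[rng.integers(0, self.D)] = 1
        cols = np.flatnonzero(bits)
        Xtr = self.X[np.ix_(self.train_idx, cols)]
        Xte = self.X[np.ix_(self.test_idx, cols)]
        clf = KNeighborsClassifier(n_neighbors=min(self.n_neighbors, len(self.train_idx)))
        clf.fit(Xtr, self.y[self.train_idx])
        acc = float(np.mean(clf.predict(Xte) == self.y[self.test_idx]))
        return self.cfg.w_err * (1.0 - acc) + self.cfg.w_frac * (len(cols) / self.D)


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def wrapper_fitness(mask: FeatureMask | np.ndarray, X: FeatureMatrix | np.ndarray,
                    y: np.ndarray, cfg: SelectorConfig,
                    rng: np.random.Generator | None = None) -> float:
    """Fitness of one mask (lower is better); see :class:`_FitnessEvaluator`."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return _FitnessEvaluator(X, np.asarray(y), cfg)(bits, rng)


def _evaluate_population(bits: np.ndarray, evaluator: _FitnessEvaluator,
                         rng: np.random.Generator) -> np.ndarray:
    return np.array([evaluator(b, rng) for b in bits])


def _run_bda(evaluator, D, cfg, rng):
    P, T = cfg.population, cfg.iterations
    positions = (rng.random((P, D)) < 0.5).astype(float)
    steps = np.zeros((P, D))
    fitness = _evaluate_population(positions, evaluator, rng)
    best_i = int(np.argmin(fitness))
    best_bits, best_fit = positions[best_i].copy(), float(fitness[best_i])
    history = []
    for k in range(T):
        worst_i = int(np.argmax(fitness))
        coeffs = dragonfly_coefficients(k, T, rng)
        positions, steps = bda_step_update(
            positions, steps, coeffs, best_bits, positions[worst_i], rng)
        fitness = _evaluate_population(positions, evaluator, rng)
        it_best = int(np.argmin(fitness))
        if fitness[it_best] < best_fit:
            best_fit = float(fitness[it_best])
            best_bits = positions[it_best].copy()
        history.append(best_fit)
    return best_bits, best_fit, history


def _run_mfo(evaluator, D, cfg, rng):
    P, T = cfg.population, cfg.iterations
    moths = rng.random((P, D))

    def fit_of(pos):
        bits = binarize_position(pos, rng.random(pos.shape), cfg.binarize)
        return np.array([evaluator(b, rng) for b in bits])

    fitness = fit_of(moths)
    order = np.argsort(fitness)
    flames, flame_fit = moths[order].copy(), fitness[order].copy()
    best_fit = float(flame_fit[0])
    best_bits = binarize_position(flames[0], rng.random(D), cfg.binarize)
    if best_bits.sum() == 0:
        best_bits = best_bits.copy()
        best_bits[rng.integers(0, D)] = 1
    history = []
    for k in range(1, T + 1):
        n_fl = mfo_flame_count(P, k, T)
        r = rng.uniform(-1.0, 1.0, size=(P, D))
        targets = flames[np.minimum(np.arange(P), n_fl - 1)]
        moths = mfo_spiral_update(moths, targets, r, cfg.mfo_spiral_c)
        moths = np.clip(moths, 0.0, 1.0)
        fitness = fit_of(moths)
        # flames = elite of previous flames plus current moths
        pool = np.vstack([flames, moths])
        pool_fit = np.concatenate([flame_fit, fitness])
        order = np.argsort(pool_fit, kind="stable")[:P]
        flames, flame_fit = pool[order].copy(), pool_fit[order].copy()
        if flame_fit[0] < best_fit:
            best_fit = float(flame_fit[0])
            bits = binarize_position(flames[0], rng.random(D), cfg.binarize)
            if bits.sum() > 0:
                best_bits = bits
        history.append(best_fit)
    return best_bits.astype(float), best_fit, history


def _run_pso(evaluator, D, cfg, rng):
    P, T = cfg.population, cfg.iterations
    pos = rng.random((P, D))
    vel = np.zeros((P, D))
    I_hi, I_lo = cfg.pso_inertia

    def fit_of(p):
        bits = binarize_position(p, rng.random(p.shape), cfg.binarize)
        return np.array([evaluator(b, rng) for b in bits])

    fitness = fit_of(pos)
    pbest, pbest_fit = pos.copy(), fitness.copy()
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    history = []
    for k in range(T):
        inertia = I_hi - (I_hi - I_lo) * k / max(T - 1, 1)
        r = rng.random((P, D))
        R = rng.random((P, D))
        vel = pso_velocity_update(vel, pos, pbest, gbest[None, :], inertia,
                                  cfg.pso_c1, cfg.pso_c2, r, R)
        vel = np.clip(vel, -cfg.pso_vmax, cfg.pso_vmax)
        pos = np.clip(pos + vel, 0.0, 1.0)
        fitness = fit_of(pos)
        improved = fitness < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest = pbest[g].copy()
        history.append(gbest_fit)
    bits = binarize_position(gbest, rng.random(D), cfg.binarize)
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(0, D)] = 1
    return bits.astype(float), gbest_fit, history


def select_features(method: str, X: FeatureMatrix | np.ndarray, y: np.ndarray,
                    cfg: SelectorConfig | None = None) -> SelectionResult:
    """Run one swarm selector over the feature matrix.

    Fully reproducible from ``cfg.seed``; the returned history (best fitness
    so far per iteration) is monotonically non-increasing by elitism, and the
    returned mask always selects at least one feature.
    """
    if cfg is None:
        cfg = SelectorConfig(method=method)
    elif cfg.method != method:
        cfg = SelectorConfig.from_dict({**cfg.to_dict(), "method": method})
    if isinstance(X, FeatureMatrix):
        if y is None and X.labels is not None:
            y = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.shape[0] != X.shape[0]:
        raise ValueError("labels must align with feature rows")
    rng = np.random.default_rng(cfg.seed)
    evaluator = _FitnessEvaluator(X, y, cfg)
    runners = {"bda": _run_bda, "mfo": _run_mfo, "pso": _run_pso}
    best_bits, best_fit, history = runners[method](evaluator, X.shape[1], cfg, rng)
    bits = np.asarray(best_bits).astype(np.uint8)
    if bits.sum() == 0:
        bits[rng.integers(0, bits.shape[0])] = 1
    return SelectionResult(mask=FeatureMask(bits=bits), best_fitness=float(best_fit),
                           history=[float(h) for h in history], method=method,
                           config=cfg)
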