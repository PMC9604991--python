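"""Stochastic global optimizers and search-space definitions.

Two canonical population methods are provided: inertia-weight particle
swarm optimization (constriction-style coefficients) and a jDE-style
self-adaptive differential evolution (DE/rand/1/bin with per-individual
F and CR regenerated with probability 0.1).  Both minimize a black-box
objective over a box; fitness maximization is wrapped as minimization of
the negative score.  Every evaluation is archived so the full search can
be replayed or re-ranked afterwards.

Two fitting scenarios are supported: a 3-parameter search over (G, L, v)
with one shared local coupling, and an E/2-parameter search over local
couplings tied across homotopic region pairs with (G, v) held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "OptimizerRun",
    "scenario1_space",
    "scenario2_space",
    "expand_homotopic",
    "collapse_homotopic",
    "sample_box",
    "pso_minimize",
    "ade_minimize",
]


@dataclass
class SearchSpace:
    """Named box-bounded parameter space."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    scenario: str | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or len(self.names) != self.lower.size:
            raise ValueError("names and bounds have inconsistent lengths")
        if np.any(self.lower >= self.upper):
            raise ValueError("every lower bound must be below its upper bound")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class OptimizerRun:
    """Archive of a full optimization: every (x, f) evaluated."""

    best_x: np.ndarray
    best_f: float
    archive_x: np.ndarray
    archive_f: np.ndarray
    pop: int
    generations: int
    seed: int
    algorithm: str = ""

    def save_archive(self, path) -> None:
        data = np.column_stack([self.archive_x, self.archive_f])
        header = "\t".join([f"x{i}" for i in range(self.archive_x.shape[1])] + ["f"])
        np.savetxt(path, data, fmt="%.9g", delimiter="\t", header=header)


def scenario1_space(
    g_bounds=(0.0, 10.0), l_bounds=(-5.0, 6.0), v_bounds=(1.0, 40.0)
) -> SearchSpace:
    """Homogeneous ensembles: free (G, L_shared, v)."""
    lo = [g_bounds[0], l_bounds[0], v_bounds[0]]
    hi = [g_bounds[1], l_bounds[1], v_bounds[1]]
    return SearchSpace(["G", "L", "v"], np.array(lo), np.array(hi), scenario="scenario1")


def scenario2_space(n_pairs: int, l_bounds=(-5.0, 8.0)) -> SearchSpace:
    """Heterogeneous ensembles: one local coupling per homotopic pair."""
    names = [f"L_pair{i}" for i in range(n_pairs)]
    lo = np.full(n_pairs, l_bounds[0])
    hi = np.full(n_pairs, l_bounds[1])
    return SearchSpace(names, lo, hi, scenario="scenario2")


def expand_homotopic(L_half: np.ndarray, pairing: Sequence[tuple[int, int]]) -> np.ndarray:
    """Tie local couplings across hemispheres: pair k's regions share L_half[k]."""
    L_half = np.asarray(L_half, dtype=float)
    if L_half.size != len(pairing):
        raise ValueError(f"{L_half.size} values for {len(pairing)} homotopic pairs")
    flat = [i for pair in pairing for i in pair]
    E = len(flat)
    if sorted(flat) != list(range(E)):
        raise ValueError("pairing is not a perfect matching")
    L_full = np.empty(E)
    for k, (i, j) in enumerate(pairing):
        L_full[i] = L_half[k]
        L_full[j] = L_half[k]
    return L_full


def collapse_homotopic(L_full: np.ndarray, pairing: Sequence[tuple[int, int]]) -> np.ndarray:
    """Inverse of :func:`expand_homotopic` (first member of each pair)."""
    L_full = np.asarray(L_full, dtype=float)
    return np.array([L_full[i] for i, _ in pairing])


def sample_box(space: SearchSpace, n: int, seed: int) -> np.ndarray:
    """Uniform independent parameter draws within the box, shape (n, dim)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(space.lower, space.upper, size=(n, space.dim))


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    pop: int = 20,
    generations: int = 200,
    seed: int = 0,
    inertia: float = 0.7298,
    cognitive: float = 1.49618,
    social: float = 1.49618,
) -> OptimizerRun:
    """Canonical inertia-weight particle swarm optimization.

    Velocities are clamped to half the box range per dimension and
    positions are clipped to the bounds.  The initial population counts as
    generation zero, so ``pop * (generations + 1)`` evaluations are made.
    """
    if pop < 2:
        raise ValueError("pop must be >= 2")
    rng = np.random.default_rng(seed)
    span = space.upper - space.lower
    vmax = 0.5 * span
    x = rng.uniform(space.lower, space.upper, size=(pop, space.dim))
    v = rng.uniform(-vmax, vmax, size=(pop, space.dim))
    f = np.array([objective(xi) for xi in x])
    pbest_x = x.copy()
    pbest_f = f.copy()
    arch_x = [x.copy()]
    arch_f = [f.copy()]
    for _ in range(generations):
        g = int(np.argmin(pbest_f))
        r1 = rng.uniform(size=(pop, space.dim))
        r2 = rng.uniform(size=(pop, space.dim))
        v = (
            inertia * v
            + cognitive * r1 * (pbest_x - x)
            + social * r2 * (pbest_x[g] - x)
        )
        v = np.clip(v, -vmax, vmax)
        x = space.clip(x + v)
        f = np.array([objective(xi) for xi in x])
        better = f < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        arch_x.append(x.copy())
        arch_f.append(f.copy())
    g = int(np.argmin(pbest_f))
    return OptimizerRun(
        pbest_x[g].copy(),
        float(pbest_f[g]),
        np.vstack(arch_x),
        np.concatenate(arch_f),
        pop,
        generations,
        seed,
        algorithm="pso",
    )


def ade_minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    pop: int = 20,
    generations: int = 200,
    seed: int = 0,
    f_range: tuple[float, float] = (0.1, 1.0),
    regen_prob: float = 0.1,
) -> OptimizerRun:
    """Self-adaptive differential evolution (jDE-style DE/rand/1/bin).

    Each individual carries its own mutation factor F and crossover rate
    CR; with probability ``regen_prob`` either is resampled before use and
    inherited only if the trial replaces its parent (greedy selection).
    """
    if pop < 5:
        raise ValueError("pop must be >= 5 for DE/rand/1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(space.lower, space.upper, size=(pop, space.dim))
    f = np.array([objective(xi) for xi in x])
    F = np.full(pop, 0.5)
    CR = np.full(pop, 0.9)
    arch_x = [x.copy()]
    arch_f = [f.copy()]
    for _ in range(generations):
        new_x = x.copy()
        new_f = f.copy()
        for i in range(pop):
            Fi = f_range[0] + rng.uniform() * (f_range[1] - f_range[0]) if rng.uniform() < regen_prob else F[i]
            CRi = rng.uniform() if rng.uniform() < regen_prob else CR[i]
            idx = rng.choice(pop - 1, size=3, replace=False)
            idx[idx >= i] += 1
            a, b, c = x[idx]
            mutant = space.clip(a + Fi * (b - c))
            cross = rng.uniform(size=space.dim) < CRi
            cross[rng.integers(space.dim)] = True
            trial = np.where(cross, mutant, x[i])
            ft = objective(trial)
            if ft < f[i]:
                new_x[i] = trial
                new_f[i] = ft
                F[i] = Fi
                CR[i] = CRi
            arch_x.append(trial[None, :].copy())
            arch_f.append(np.array([ft]))
        x, f = new_x, new_f
    g = int(np.argmin(f))
    return OptimizerRun(
        x[g].copy(),
        float(f[g]),
        np.vstack(arch_x),
        np.concatenate(arch_f),
        pop,
        generations,
        seed,
        algorithm="ade",
    )
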