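"""Artificial Gorilla Troops Optimizer (GTO).

A population-based metaheuristic that mimics the social structure of gorilla
troops.  Candidate solutions ("gorillas") move through a box-bounded search
space via three exploration mechanisms (migration to an unknown position,
movement toward a random peer, migration to a known position) and two
exploitation mechanisms (following the silverback — the current best
solution — and violent competition around it).  Fitness is minimized
everywhere; greedy replacement keeps the incumbent unless a candidate is
strictly better, so the best score is non-increasing across iterations.

All stochastic operations draw from a single :class:`numpy.random.Generator`
threaded through the call tree, so a run is fully reproducible from its seed.
The per-operation draw order is part of the public contract (tests replay it):

``compute_coefficients``
    r4, l, r5, branch-rand, then E (per-dimension normal when the
    branch-rand >= 0.5, a single normal otherwise).
``exploration_update``
    migration-rand; then for migration: r1 per dimension; otherwise a second
    branch-rand, the peer index, r2 (scalar) and Z per dimension for the
    move-toward-peer branch, or the peer index and r3 (scalar) for the
    known-position branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GTOParams",
    "GTOCoefficients",
    "Population",
    "OptimizationResult",
    "FitnessEvaluationError",
    "init_population",
    "compute_coefficients",
    "exploration_update",
    "follow_silverback_update",
    "competition_update",
    "gto_step",
    "optimize",
]


class FitnessEvaluationError(RuntimeError):
    """A fitness call failed; carries the index of the offending solution."""

    def __init__(self, index: int, original: BaseException):
        super().__init__(f"fitness evaluation failed for solution {index}: {original}")
        self.index = index
        self.original = original


@dataclass
class GTOParams:
    """Optimizer settings.

    Parameters
    ----------
    Nmax : population size (default 10).
    Tmax : number of iterations (default 25).
    p : probability of the migration-to-unknown-position mechanism.
    beta : violence coefficient scaling the conflict vector A.
    w : exploitation switch — follow the silverback when C >= w,
        otherwise compete.
    seed : RNG seed for the whole run.
    """

    Nmax: int = 10
    Tmax: int = 25
    p: float = 0.03
    beta: float = 3.0
    w: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.Nmax < 2:
            raise ValueError(f"Nmax must be >= 2, got {self.Nmax}")
        if self.Tmax < 0:
            raise ValueError(f"Tmax must be >= 0, got {self.Tmax}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass
class GTOCoefficients:
    """Per-draw update coefficients.

    C decays as ``(cos(2 r4) + 1) * (1 - t/Tmax)``; L = C*l with l ~ U(-1, 1);
    Q = 2 r5 - 1 is the impact force in [-1, 1]; A = beta*E is the conflict
    coefficient (E a per-dimension or scalar standard-normal draw).
    """

    C: float
    L: float
    Q: float
    A: np.ndarray | float


@dataclass
class Population:
    """N box-bounded solution vectors with their fitness scores (lower is better)."""

    solutions: np.ndarray  # shape (N, D)
    scores: np.ndarray  # shape (N,)
    lb: np.ndarray  # shape (D,)
    ub: np.ndarray  # shape (D,)

    @property
    def size(self) -> int:
        return self.solutions.shape[0]

    @property
    def dim(self) -> int:
        return self.solutions.shape[1]

    @property
    def silverback_index(self) -> int:
        if self.size == 0:
            raise ValueError("empty population has no silverback")
        return int(np.argmin(self.scores))

    @property
    def silverback(self) -> np.ndarray:
        return self.solutions[self.silverback_index]

    @property
    def best_score(self) -> float:
        return float(self.scores[self.silverback_index])


@dataclass
class OptimizationResult:
    best_score: float
    best_solution: np.ndarray
    history: list[float] = field(default_factory=list)
    evaluations: int = 0
    seed: int | None = None


def _as_bounds(lb, ub, D: int) -> tuple[np.ndarray, np.ndarray]:
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (D,)).copy()
    ub = np.broadcast_to(np.asarray(ub, dtype=float), (D,)).copy()
    if np.any(lb > ub):
        bad = np.nonzero(lb > ub)[0]
        raise ValueError(f"LB > UB in dimension(s) {bad.tolist()}")
    return lb, ub


def init_population(
    Nmax: int, D: int, LB, UB, rng: np.random.Generator
) -> Population:
    """Draw N solutions uniformly in the box: ``rand * (UB - LB) + LB``."""
    if Nmax < 2:
        raise ValueError(f"Nmax must be >= 2, got {Nmax}")
    if D < 1:
        raise ValueError(f"dimension must be >= 1, got {D}")
    lb, ub = _as_bounds(LB, UB, D)
    solutions = rng.random((Nmax, D)) * (ub - lb) + lb
    scores = np.full(Nmax, np.nan)
    return Population(solutions=solutions, scores=scores, lb=lb, ub=ub)


def compute_coefficients(
    t: int,
    Tmax: int,
    beta: float,
    rng: np.random.Generator,
    dim: int | None = None,
) -> GTOCoefficients:
    """Draw the per-update coefficient set for iteration ``t``.

    The decay factor ``1 - t/Tmax`` reaches 0 at the final iteration, pulling
    the exploration amplitude C (and with it L, Z, H) to zero so the troop
    converges on the silverback.
    """
    if not 1 <= t <= Tmax:
        raise ValueError(f"iteration t={t} outside [1, {Tmax}]")
    r4 = rng.random()
    F = np.cos(2.0 * r4) + 1.0
    C = F * (1.0 - t / Tmax)
    l = rng.uniform(-1.0, 1.0)
    L = C * l
    r5 = rng.random()
    Q = 2.0 * r5 - 1.0
    branch = rng.random()
    if branch >= 0.5 and dim is not None:
        E = rng.standard_normal(dim)
    else:
        E = float(rng.standard_normal())
    A = beta * E
    return GTOCoefficients(C=C, L=L, Q=Q, A=A)


def _clip(candidate: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return np.clip(candidate, lb, ub)


def exploration_update(
    x: np.ndarray,
    pop: Population,
    coeffs: GTOCoefficients,
    p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One exploration move: migrate, follow a peer, or move to a known spot.

    With probability ``p`` the gorilla migrates to an unknown position (a
    fresh uniform sample in the box).  Otherwise a second draw decides
    between moving toward a random peer, ``L*H + (r2 - C)*Xr`` with
    ``H = Z*x`` and Z ~ U(-C, C) per dimension, and migrating to a known
    position, ``x - L*(L*(x - Xr) + r3*(x - Xr))``.  The result is clipped
    to the box.
    """
    lb, ub = pop.lb, pop.ub
    if rng.random() < p:
        r1 = rng.random(pop.dim)
        candidate = lb + r1 * (ub - lb)
    elif rng.random() >= 0.5:
        peer = int(rng.integers(pop.size))
        xr = pop.solutions[peer]
        r2 = rng.random()
        Z = rng.uniform(-coeffs.C, coeffs.C, pop.dim)
        H = Z * x
        candidate = coeffs.L * H + (r2 - coeffs.C) * xr
    else:
        peer = int(rng.integers(pop.size))
        xr = pop.solutions[peer]
        r3 = rng.random()
        candidate = x - coeffs.L * (coeffs.L * (x - xr) + r3 * (x - xr))
    return _clip(candidate, lb, ub)


def follow_silverback_update(
    x: np.ndarray, pop: Population, coeffs: GTOCoefficients
) -> np.ndarray:
    """Follow-the-silverback move: ``L*M*(x - Xsb) + x``, clipped to bounds.

    M is the troop-averaged magnitude ``(|mean of the population|^g)^(1/g)``
    with ``g = 2^L``; the silverback itself is a fixed point of this update.
    """
    if pop.size == 0:
        raise ValueError("empty population has no silverback")
    sb = pop.silverback
    g = 2.0 ** coeffs.L
    M = np.abs(pop.solutions.mean(axis=0)) ** g
    M = M ** (1.0 / g)
    candidate = coeffs.L * M * (x - sb) + x
    return _clip(candidate, pop.lb, pop.ub)


def competition_update(
    x: np.ndarray, silverback: np.ndarray, coeffs: GTOCoefficients,
    lb: np.ndarray | None = None, ub: np.ndarray | None = None,
) -> np.ndarray:
    """Competition move: ``Xsb - (Xsb*Q - x*Q)*A``, clipped to bounds."""
    candidate = silverback - (silverback * coeffs.Q - x * coeffs.Q) * coeffs.A
    if lb is not None and ub is not None:
        candidate = _clip(candidate, np.asarray(lb, float), np.asarray(ub, float))
    return candidate


def gto_step(
    pop: Population,
    t: int,
    params: GTOParams,
    fitness,
    rng: np.random.Generator,
) -> Population:
    """One GTO iteration: exploration sweep, then exploitation sweep.

    Each member generates a candidate, the candidate is evaluated, and it
    replaces the member only if strictly better (ties keep the incumbent).
    The silverback is re-identified lazily after every acceptance, so both
    phases always exploit the current best.
    """

    def _eval(candidate: np.ndarray, index: int) -> float:
        try:
            return float(fitness(candidate))
        except Exception as exc:  # pragma: no cover - error path
            raise FitnessEvaluationError(index, exc) from exc

    # Exploration: migration / peer-following / known-position moves.
    for i in range(pop.size):
        coeffs = compute_coefficients(t, params.Tmax, params.beta, rng, dim=pop.dim)
        candidate = exploration_update(pop.solutions[i], pop, coeffs, params.p, rng)
        score = _eval(candidate, i)
        if score < pop.scores[i]:
            pop.solutions[i] = candidate
            pop.scores[i] = score

    # Exploitation: follow the silverback when C >= w, compete otherwise.
    for i in range(pop.size):
        coeffs = compute_coefficients(t, params.Tmax, params.beta, rng, dim=pop.dim)
        if coeffs.C >= params.w:
            candidate = follow_silverback_update(pop.solutions[i], pop, coeffs)
        else:
            candidate = competition_update(
                pop.solutions[i], pop.silverback, coeffs, pop.lb, pop.ub
            )
        score = _eval(candidate, i)
        if score < pop.scores[i]:
            pop.solutions[i] = candidate
            pop.scores[i] = score

    return pop


def optimize(fitness, params: GTOParams, D: int, LB, UB) -> OptimizationResult:
    """Run the full optimizer: initialize, iterate Tmax steps, return the best.

    ``fitness`` maps a length-D vector to a scalar cost (lower is better).
    The returned history holds the best score after each iteration and is
    non-increasing; ``evaluations`` counts every fitness call made.
    """
    rng = np.random.default_rng(params.seed)
    n_evals = 0

    def counted(x):
        nonlocal n_evals
        n_evals += 1
        return fitness(x)

    pop = init_population(params.Nmax, D, LB, UB, rng)
    for i in range(pop.size):
        try:
            pop.scores[i] = float(counted(pop.solutions[i]))
        except Exception as exc:
            raise FitnessEvaluationError(i, exc) from exc

    history: list[float] = []
    for t in range(1, params.Tmax + 1):
        gto_step(pop, t, params, counted, rng)
        history.append(pop.best_score)

    return OptimizationResult(
        best_score=pop.best_score,
        best_solution=pop.silverback.copy(),
        history=history,
        evaluations=n_evals,
        seed=params.seed,
    )
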