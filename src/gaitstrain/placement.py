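"""Sensor-placement optimization as wrapper feature selection.

The objective is the accuracy (R^2) of an ordinary-least-squares regressor
that maps a subset of candidate strain signals to the three hip angle
channels, scored by leave-one-person-out cross-validation: for each held-out
participant the model is fitted on everyone else and evaluated on the
held-out runner, and the fitness is the mean R^2 over the three anatomical
planes and all folds.

Two search strategies are provided, mirroring the wrapper-selection
literature: greedy sequential forward selection, and a binary genetic
algorithm whose operators conserve subset cardinality (balanced one-point
crossover and interchange mutation), with roulette-wheel selection and
elitism of two.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chromosome",
    "GAConfig",
    "ObjectiveResult",
    "GAHistory",
    "lopo_linear_objective",
    "PrecomputedLOPO",
    "forward_select",
    "exhaustive_select",
    "ga_select",
    "balanced_crossover",
    "interchange_mutation",
    "roulette_select",
]


@dataclass(frozen=True)
class Chromosome:
    """Fixed-cardinality binary mask over candidate positions."""

    genes: np.ndarray  # (length,) of {0, 1}, int8

    def __post_init__(self) -> None:
        g = np.asarray(self.genes, dtype=np.int8)
        if g.ndim != 1 or not np.isin(g, (0, 1)).all():
            raise ValueError("genes must be a 1-D binary vector")
        object.__setattr__(self, "genes", g)

    @property
    def length(self) -> int:
        return self.genes.size

    @property
    def cardinality(self) -> int:
        return int(self.genes.sum())

    @property
    def subset(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.genes))

    @classmethod
    def from_subset(cls, subset, length: int) -> "Chromosome":
        g = np.zeros(length, dtype=np.int8)
        g[list(subset)] = 1
        return cls(g)

    @classmethod
    def random(cls, length: int, k: int, rng: np.random.Generator) -> "Chromosome":
        return cls.from_subset(rng.choice(length, size=k, replace=False), length)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings; defaults follow the placement study."""

    population_size: int = 30
    mating_pool_size: int = 15
    crossover_prob: float = 0.8
    mutation_prob: float = 0.5
    elite_count: int = 2
    generations: int = 150
    stagnation_limit: int = 40  # early stop after this many flat generations
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_prob <= 1.0 and 0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")
        if self.mating_pool_size > self.population_size:
            raise ValueError("mating pool cannot exceed the population")


@dataclass(frozen=True)
class ObjectiveResult:
    """Fitness of one subset: mean R^2 plus its per-plane/per-fold breakdown."""

    fitness: float
    per_plane_r2: np.ndarray  # (3,) mean over folds per plane
    per_fold_r2: np.ndarray  # (n_folds,) mean over planes per fold
    rank_deficient: bool = False


@dataclass
class GAHistory:
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    populations: list[list[Chromosome]] | None = None


def _as_indices(subset) -> np.ndarray:
    if isinstance(subset, Chromosome):
        idx = np.flatnonzero(subset.genes)
    else:
        idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if idx.size == 0:
        raise ValueError("subset must contain at least one candidate")
    return idx


def _ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """OLS with intercept; falls back to the pseudoinverse when rank-deficient."""
    design = np.column_stack([np.ones(x.shape[0]), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    return beta, rank < design.shape[1]


def _r2(y: np.ndarray, pred: np.ndarray) -> np.ndarray:
    ss_res = ((y - pred) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    return 1.0 - ss_res / ss_tot


def lopo_linear_objective(
    strains: list[np.ndarray], hip_angles: list[np.ndarray], subset
) -> ObjectiveResult:
    """Leave-one-person-out linear-regression fitness of a candidate subset.

    ``strains[p]`` is the (frames, n_candidates) strain matrix of participant
    ``p`` and ``hip_angles[p]`` the matching (frames, 3) hip angles
    (sagittal, frontal, transverse). For each fold, OLS (with intercept) maps
    the subset's strain columns to the three planes on the remaining
    participants; fitness is the mean held-out R^2 over planes and folds.
    """
    if len(strains) < 2 or len(strains) != len(hip_angles):
        raise ValueError("need >= 2 participants with matching angle matrices")
    idx = _as_indices(subset)
    n_p = len(strains)
    per_fold = np.empty(n_p)
    per_plane = np.zeros(3)
    rank_deficient = False
    for held in range(n_p):
        x_tr = np.vstack([strains[p][:, idx] for p in range(n_p) if p != held])
        y_tr = np.vstack([hip_angles[p] for p in range(n_p) if p != held])
        beta, deficient = _ols_fit(x_tr, y_tr)
        rank_deficient |= deficient
        x_te = strains[held][:, idx]
        pred = np.column_stack([np.ones(x_te.shape[0]), x_te]) @ beta
        r2 = _r2(hip_angles[held], pred)
        per_fold[held] = r2.mean()
        per_plane += r2
    per_plane /= n_p
    return ObjectiveResult(
        fitness=float(per_fold.mean()),
        per_plane_r2=per_plane,
        per_fold_r2=per_fold,
        rank_deficient=rank_deficient,
    )


class PrecomputedLOPO:
    """The same LOPO OLS objective via per-participant sufficient statistics.

    Precomputes, per participant, the Gram matrix of the full candidate set
    (with intercept), the cross-moments with the hip angles, and the target
    second moments; any subset's leave-one-person-out R^2 is then a few
    small solves instead of repeated ``lstsq`` over all frames. Exactly
    equivalent to :func:`lopo_linear_objective` (same normal equations);
    used by the optimizers, which evaluate thousands of subsets.
    """

    def __init__(self, strains: list[np.ndarray], hip_angles: list[np.ndarray]):
        if len(strains) < 2 or len(strains) != len(hip_angles):
            raise ValueError("need >= 2 participants with matching angle matrices")
        self.n_candidates = strains[0].shape[1]
        self.n_participants = len(strains)
        self._gram = []  # (P+1, P+1) with leading intercept row/col
        self._cross = []  # (P+1, 3)
        self._yy = []  # (3,)
        self._ysum = []  # (3,)
        self._n = []
        for x, y in zip(strains, hip_angles):
            design = np.column_stack([np.ones(x.shape[0]), x])
            self._gram.append(design.T @ design)
            self._cross.append(design.T @ y)
            self._yy.append((y**2).sum(axis=0))
            self._ysum.append(y.sum(axis=0))
            self._n.append(x.shape[0])
        self._gram_total = sum(self._gram)
        self._cross_total = sum(self._cross)

    def __call__(self, subset) -> float:
        return self.evaluate(subset).fitness

    def evaluate(self, subset) -> ObjectiveResult:
        idx = _as_indices(subset)
        cols = np.concatenate([[0], idx + 1])
        sel = np.ix_(cols, cols)
        n_p = self.n_participants
        per_fold = np.empty(n_p)
        per_plane = np.zeros(3)
        rank_deficient = False
        for held in range(n_p):
            g = (self._gram_total - self._gram[held])[sel]
            c = (self._cross_total - self._cross[held])[cols, :]
            try:
                beta = np.linalg.solve(g, c)
            except np.linalg.LinAlgError:
                beta = np.linalg.pinv(g) @ c
                rank_deficient = True
            g_h = self._gram[held][sel]
            c_h = self._cross[held][cols, :]
            ss_res = (
                self._yy[held]
                - 2.0 * np.einsum("ij,ij->j", beta, c_h)
                + np.einsum("ij,ik,kj->j", beta, g_h, beta)
            )
            n_h = self._n[held]
            ss_tot = self._yy[held] - self._ysum[held] ** 2 / n_h
            r2 = 1.0 - ss_res / ss_tot
            per_fold[held] = r2.mean()
            per_plane += r2
        per_plane /= n_p
        return ObjectiveResult(
            fitness=float(per_fold.mean()),
            per_plane_r2=per_plane,
            per_fold_r2=per_fold,
            rank_deficient=rank_deficient,
        )


def _fitness_of(objective, subset) -> float:
    out = objective(subset)
    return out.fitness if isinstance(out, ObjectiveResult) else float(out)


def forward_select(
    n_candidates: int, objective, k_max: int
) -> list[tuple[tuple[int, ...], float]]:
    """Greedy sequential forward selection.

    Starts from the empty subset; at each step adds the candidate that
    maximizes the objective given the already-selected positions (ties break
    to the lowest index). Returns ``[(subset, fitness)]`` for sizes
    1..k_max; subsets are nested by construction.
    """
    if not 1 <= k_max <= n_candidates:
        raise ValueError("k_max must lie in [1, n_candidates]")
    selected: list[int] = []
    out: list[tuple[tuple[int, ...], float]] = []
    for _ in range(k_max):
        best_j, best_fit = -1, -np.inf
        for j in range(n_candidates):
            if j in selected:
                continue
            fit = _fitness_of(objective, selected + [j])
            if fit > best_fit:  # strict ">" keeps the lowest index on ties
                best_j, best_fit = j, fit
        selected.append(best_j)
        out.append((tuple(sorted(selected)), best_fit))
    return out


def exhaustive_select(
    n_candidates: int, objective, k: int
) -> tuple[tuple[int, ...], float]:
    """Brute-force optimum over all cardinality-k subsets."""
    best_subset, best_fit = None, -np.inf
    for subset in itertools.combinations(range(n_candidates), k):
        fit = _fitness_of(objective, subset)
        if fit > best_fit:
            best_subset, best_fit = subset, fit
    return best_subset, best_fit


def roulette_select(
    population: list[Chromosome],
    fitnesses: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Sample ``n`` individuals with replacement, proportionally to fitness.

    Out-of-sample R^2 can be negative, so fitnesses are shifted by their
    minimum plus a small floor before normalization; a degenerate all-equal
    population falls back to uniform sampling.
    """
    f = np.asarray(fitnesses, dtype=float)
    shifted = f - f.min() + 1e-6
    total = shifted.sum()
    if not np.isfinite(total) or total <= 0 or np.allclose(f, f[0]):
        probs = np.full(len(population), 1.0 / len(population))
    else:
        probs = shifted / total
    picks = rng.choice(len(population), size=n, replace=True, p=probs)
    return [population[i] for i in picks]


def balanced_crossover(
    parent_a: Chromosome, parent_b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover constrained to conserve cardinality.

    A valid cut point is an interior position where both parents' prefixes
    contain the same number of ones (then the swapped tails automatically
    carry equal ones too, so children keep cardinality k). The point is
    drawn uniformly among valid points; if none exists, the parents are
    returned unchanged.
    """
    if parent_a.length != parent_b.length or parent_a.cardinality != parent_b.cardinality:
        raise ValueError("parents must share length and cardinality")
    ca = np.cumsum(parent_a.genes)
    cb = np.cumsum(parent_b.genes)
    valid = np.flatnonzero(ca[:-1] == cb[:-1]) + 1  # cut after index point-1
    if valid.size == 0:
        return parent_a, parent_b
    point = int(rng.choice(valid))
    ga = np.concatenate([parent_a.genes[:point], parent_b.genes[point:]])
    gb = np.concatenate([parent_b.genes[:point], parent_a.genes[point:]])
    return Chromosome(ga), Chromosome(gb)


def interchange_mutation(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Swap one random 1-gene with one random 0-gene (cardinality preserved)."""
    ones = np.flatnonzero(chrom.genes == 1)
    zeros = np.flatnonzero(chrom.genes == 0)
    if ones.size == 0 or zeros.size == 0:
        warnings.warn("interchange mutation is a no-op on all-equal chromosomes",
                      stacklevel=2)
        return chrom
    i = int(rng.choice(ones))
    j = int(rng.choice(zeros))
    g = chrom.genes.copy()
    g[i], g[j] = 0, 1
    return Chromosome(g)


def ga_select(
    n_candidates: int,
    objective,
    k: int,
    config: GAConfig | None = None,
    record_populations: bool = False,
) -> tuple[Chromosome, float, GAHistory]:
    """Binary GA search for the best cardinality-k candidate subset.

    Random cardinality-k initial population; per generation: roulette-wheel
    mating pool, balanced one-point crossover (prob ``crossover_prob``),
    interchange mutation applied per offspring (prob ``mutation_prob``), and
    the two best individuals carried over unchanged. Returns the best-ever
    chromosome, its fitness, and the per-generation history.
    """
    config = config or GAConfig()
    if not 1 <= k < n_candidates:
        raise ValueError("k must satisfy 1 <= k < n_candidates")
    rng = np.random.default_rng(config.seed)
    population = [
        Chromosome.random(n_candidates, k, rng)
        for _ in range(config.population_size)
    ]
    cache: dict[bytes, float] = {}

    def fit_of(ch: Chromosome) -> float:
        key = ch.genes.tobytes()
        if key not in cache:
            cache[key] = _fitness_of(objective, ch)
        return cache[key]

    history = GAHistory(populations=[] if record_populations else None)
    best_chrom: Chromosome | None = None
    best_fit = -np.inf
    stagnant = 0
    for _ in range(config.generations):
        fitnesses = np.array([fit_of(ch) for ch in population])
        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_fit + 1e-12:
            best_fit = float(fitnesses[gen_best])
            best_chrom = population[gen_best]
            stagnant = 0
        else:
            stagnant += 1
        history.best_fitness.append(float(fitnesses[gen_best]))
        history.mean_fitness.append(float(fitnesses.mean()))
        if history.populations is not None:
            history.populations.append(list(population))
        if stagnant >= config.stagnation_limit:
            break

        elite_idx = np.argsort(-fitnesses, kind="stable")[: config.elite_count]
        elites = [population[i] for i in elite_idx]
        pool = roulette_select(population, fitnesses, config.mating_pool_size, rng)
        offspring: list[Chromosome] = []
        while len(offspring) < config.population_size - config.elite_count:
            pa, pb = (pool[int(i)] for i in rng.integers(0, len(pool), 2))
            if rng.random() < config.crossover_prob:
                ca, cb = balanced_crossover(pa, pb, rng)
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                if rng.random() < config.mutation_prob:
                    child = interchange_mutation(child, rng)
                offspring.append(child)
        population = elites + offspring[: config.population_size - config.elite_count]

    assert best_chrom is not None
    return best_chrom, best_fit, history
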