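"""NSGA-III many-objective optimizer, written from scratch.

Implements the reference-point-based environmental selection of NSGA-III:
Das-Dennis simplex-lattice reference directions, fast nondominated sorting,
adaptive normalization (ideal point + extreme-point intercepts), association
of members to reference rays by perpendicular distance, and the niche-count
driven selection of the partially admitted front.  Variation uses simulated
binary crossover (SBX) and polynomial mutation (PM) on real-valued genomes
within box bounds.

The evolution loop is steady-state-like: each generation produces a small
batch of offspring (default 10), evaluates only those, and re-selects the
population from parents + offspring.  The canonical generational scheme
(population-size offspring) is available behind a flag.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .config import EvolutionConfig

logger = logging.getLogger(__name__)


@dataclass
class ReferenceDirectionSet:
    """Das-Dennis reference directions: all points of the p-partition
    simplex lattice in M dimensions (each sums to 1, entries >= 0)."""

    M: int
    p: int
    directions: np.ndarray

    def __len__(self) -> int:
        return len(self.directions)


def das_dennis_directions(M: int, p: int) -> ReferenceDirectionSet:
    """Enumerate the simplex-lattice directions with coordinates i/p.

    The count is C(M + p - 1, p); enumeration order is deterministic
    (lexicographic in the integer compositions).
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if p < 1:
        raise ValueError("p must be >= 1")
    points: list[list[int]] = []

    def recurse(prefix: list[int], remaining: int, dims_left: int) -> None:
        if dims_left == 1:
            points.append(prefix + [remaining])
            return
        for i in range(remaining + 1):
            recurse(prefix + [i], remaining - i, dims_left - 1)

    recurse([], p, M)
    directions = np.asarray(points, dtype=float) / p
    assert len(directions) == comb(M + p - 1, p)
    return ReferenceDirectionSet(M=M, p=p, directions=directions)


def nondominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Fast nondominated sorting (minimisation, Pareto dominance).

    Returns fronts as index arrays; front 0 holds points dominated by none.
    """
    F = np.asarray(objectives, dtype=float)
    n = len(F)
    if n == 0:
        return []
    # dominates[i, j]: i <= j everywhere and i < j somewhere
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dominates = le & lt
    dom_count = dominates.sum(axis=0)  # how many dominate column j
    dominated_by: list[np.ndarray] = [np.nonzero(dominates[i])[0] for i in range(n)]

    fronts: list[np.ndarray] = []
    current = np.nonzero(dom_count == 0)[0]
    remaining = dom_count.copy()
    while len(current):
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    nxt.append(j)
        current = np.asarray(sorted(nxt), dtype=int)
    return fronts


def _extreme_points(translated: np.ndarray) -> np.ndarray:
    """One extreme point per objective axis via the achievement
    scalarizing function with axis-aligned weights."""
    M = translated.shape[1]
    eps = 1e-6
    extremes = np.empty((M, M))
    for j in range(M):
        w = np.full(M, eps)
        w[j] = 1.0
        asf = np.max(translated / w, axis=1)
        extremes[j] = translated[np.argmin(asf)]
    return extremes


def normalize_objectives(pool: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NSGA-III adaptive normalization over the selection pool.

    Returns ``(ideal, scale)``: objectives are normalized as
    ``(f - ideal) / scale``.  The scale is the intercept of the hyperplane
    through the extreme points; when that system is degenerate (singular or
    non-positive intercepts) it falls back to the per-objective maximum of
    the translated pool, and to 1 where even that extent is zero.
    """
    pool = np.asarray(pool, dtype=float)
    ideal = pool.min(axis=0)
    translated = pool - ideal
    max_extent = translated.max(axis=0)
    scale = None
    try:
        extremes = _extreme_points(translated)
        intercepts = np.linalg.solve(extremes, np.ones(extremes.shape[0]))
        a = 1.0 / intercepts
        if np.all(np.isfinite(a)) and np.all(a > 1e-12) and np.all(a <= max_extent.max() * 2 + 1e-12):
            scale = a
    except np.linalg.LinAlgError:
        scale = None
    if scale is None:
        scale = max_extent.copy()
    scale = np.where(scale > 1e-12, scale, 1.0)
    return ideal, scale


def perpendicular_distances(points: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Distance of each point to the ray through the origin along each
    direction; shape (n_points, n_directions)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.asarray(directions, dtype=float)
    d_unit = d / np.linalg.norm(d, axis=1, keepdims=True)
    proj = points @ d_unit.T  # (n, k) scalar projections
    proj_points = proj[:, :, None] * d_unit[None, :, :]
    diff = points[:, None, :] - proj_points
    return np.linalg.norm(diff, axis=2)


def normalize_and_associate(
    members: np.ndarray,
    pool: np.ndarray,
    ref_dirs: ReferenceDirectionSet | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Associate each member with its closest reference ray.

    ``pool`` is the full selection pool used for normalization (ideal point
    and extents); ``members`` are the rows to associate.  Returns
    ``(niche_index, perpendicular_distance)`` per member.
    """
    directions = (
        ref_dirs.directions if isinstance(ref_dirs, ReferenceDirectionSet) else ref_dirs
    )
    members = np.atleast_2d(np.asarray(members, dtype=float))
    ideal, scale = normalize_objectives(pool)
    normalized = (members - ideal) / scale
    dists = perpendicular_distances(normalized, directions)
    niche = dists.argmin(axis=1)
    return niche, dists[np.arange(len(members)), niche]


def niching_select(
    last_front: np.ndarray,
    n_slots: int,
    niche_counts: np.ndarray,
    niche_of: np.ndarray,
    dist_of: np.ndarray,
    rng: np.random.Generator,
) -> list[int]:
    """Niche-preserving choice of ``n_slots`` members from the last front.

    ``niche_counts`` are counts from the already-selected members (mutated
    in place); ``niche_of`` / ``dist_of`` give each last-front member's
    associated direction and perpendicular distance.  Repeatedly: pick a
    minimal-count active direction (random tie-break); if it has no
    candidate left, deactivate it; else take the closest candidate when the
    niche is empty, a random one otherwise.
    """
    last_front = np.asarray(last_front, dtype=int)
    if n_slots > len(last_front):
        raise ValueError("n_slots exceeds the size of the last front")
    selected: list[int] = []
    available = np.ones(len(last_front), dtype=bool)
    active = np.ones(len(niche_counts), dtype=bool)
    while len(selected) < n_slots:
        counts = np.where(active, niche_counts, np.inf)
        min_count = counts.min()
        candidates_dirs = np.nonzero(counts == min_count)[0]
        j = int(rng.choice(candidates_dirs))
        members = np.nonzero(available & (niche_of == j))[0]
        if len(members) == 0:
            active[j] = False
            continue
        if niche_counts[j] == 0:
            pick = members[np.argmin(dist_of[members])]
        else:
            pick = int(rng.choice(members))
        selected.append(int(last_front[pick]))
        available[pick] = False
        niche_counts[j] += 1
    return selected


@dataclass
class Individual:
    """One candidate: a weight-vector genome plus its evaluated objectives
    and environmental-selection bookkeeping."""

    genome: np.ndarray
    objectives: np.ndarray | None = None
    rank: int | None = None
    niche: int | None = None
    niche_distance: float | None = None

    @property
    def evaluated(self) -> bool:
        return self.objectives is not None


@dataclass
class Population:
    generation: int
    individuals: list[Individual]

    def __len__(self) -> int:
        return len(self.individuals)

    def objectives(self) -> np.ndarray:
        return np.vstack([ind.objectives for ind in self.individuals])

    def genomes(self) -> np.ndarray:
        return np.vstack([ind.genome for ind in self.individuals])

    def front(self, rank: int = 0) -> list[Individual]:
        return [ind for ind in self.individuals if ind.rank == rank]


def sbx_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    eta: float,
    prob: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] | None = (0.0, 1.0),
    exchange_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover.

    With probability ``1 - prob`` the pair is copied unchanged.  Per gene, a
    spread factor beta is drawn from the SBX density with distribution index
    ``eta`` and the two children straddle the parents; before clipping, the
    per-gene child mean equals the parent mean exactly.  With probability
    ``1 - exchange_prob`` per gene, the gene pair is left untouched.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"parent length mismatch: {a.shape} vs {b.shape}")
    if not eta > 0:
        raise ValueError("eta must be > 0")
    c1, c2 = a.copy(), b.copy()
    if rng.random() >= prob:
        return c1, c2
    u = rng.random(len(a))
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    do_cross = rng.random(len(a)) < exchange_prob
    mean = 0.5 * (a + b)
    half_diff = 0.5 * beta * np.abs(a - b)
    lo = np.where(do_cross, mean - half_diff, np.minimum(a, b))
    hi = np.where(do_cross, mean + half_diff, np.maximum(a, b))
    # keep each child on its parent's side of the mean
    swap = a > b
    c1 = np.where(swap, hi, lo)
    c2 = np.where(swap, lo, hi)
    if bounds is not None:
        c1 = np.clip(c1, bounds[0], bounds[1])
        c2 = np.clip(c2, bounds[0], bounds[1])
    return c1, c2


def polynomial_mutation(
    x: np.ndarray,
    eta: float,
    prob: float,
    rng: np.random.Generator,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Bounded polynomial mutation.

    Each gene is independently perturbed with probability ``prob``; the
    perturbation density has index ``eta`` and respects the box bounds
    (it is symmetric for a gene at the interval midpoint).
    """
    if not eta > 0:
        raise ValueError("eta must be > 0")
    lo, hi = bounds
    span = hi - lo
    y = np.asarray(x, dtype=float).copy()
    mutate = rng.random(len(y)) < prob
    if not mutate.any():
        return y
    u = rng.random(len(y))
    d1 = (y - lo) / span
    d2 = (hi - y) / span
    exponent = 1.0 / (eta + 1.0)
    with np.errstate(invalid="ignore"):
        val_lo = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)
        val_hi = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)
        delta = np.where(
            u <= 0.5,
            val_lo**exponent - 1.0,
            1.0 - val_hi**exponent,
        )
    y = np.where(mutate, y + delta * span, y)
    return np.clip(y, lo, hi)


def environmental_selection(
    individuals: list[Individual],
    n_survivors: int,
    ref_dirs: ReferenceDirectionSet,
    rng: np.random.Generator,
) -> list[Individual]:
    """NSGA-III survivor selection from a combined parent+offspring pool.

    Annotates every survivor with its front rank, niche and perpendicular
    distance.  Never discards a member of a better front while keeping one
    of a worse front.
    """
    F = np.vstack([ind.objectives for ind in individuals])
    fronts = nondominated_sort(F)
    for rank, front in enumerate(fronts):
        for i in front:
            individuals[i].rank = rank

    selected: list[int] = []
    last_front: np.ndarray | None = None
    for front in fronts:
        if len(selected) + len(front) <= n_survivors:
            selected.extend(int(i) for i in front)
            if len(selected) == n_survivors:
                break
        else:
            last_front = front
            break

    if last_front is None:
        pool_idx = selected
    else:
        pool_idx = selected + [int(i) for i in last_front]
    pool = F[pool_idx]
    niche_all, dist_all = normalize_and_associate(F[pool_idx], pool, ref_dirs)
    niche_by_index = dict(zip(pool_idx, niche_all))
    dist_by_index = dict(zip(pool_idx, dist_all))

    if last_front is not None and len(selected) < n_survivors:
        niche_counts = np.zeros(len(ref_dirs), dtype=int)
        for i in selected:
            niche_counts[niche_by_index[i]] += 1
        lf = np.asarray(last_front, dtype=int)
        chosen = niching_select(
            lf,
            n_survivors - len(selected),
            niche_counts,
            np.asarray([niche_by_index[int(i)] for i in lf]),
            np.asarray([dist_by_index[int(i)] for i in lf]),
            rng,
        )
        selected.extend(chosen)

    survivors = []
    for i in selected:
        ind = individuals[i]
        ind.niche = int(niche_by_index[i])
        ind.niche_distance = float(dist_by_index[i])
        survivors.append(ind)
    return survivors


def _binary_tournament(
    population: list[Individual], rng: np.random.Generator
) -> Individual:
    i, j = rng.integers(0, len(population), size=2)
    a, b = population[i], population[j]
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    da = a.niche_distance if a.niche_distance is not None else np.inf
    db = b.niche_distance if b.niche_distance is not None else np.inf
    if da != db:
        return a if da < db else b
    return a if rng.random() < 0.5 else b


def evolve(config: EvolutionConfig, fitness) -> list[Population]:
    """Run NSGA-III and return every generation's evaluated population.

    ``fitness`` maps a genome (length ``config.n_genes``) to an objective
    vector (an ``ObjectiveVector`` or array of length ``config.M``).
    Generation 0 is a random population (uniform by default, log-uniform
    behind ``config.init``; ``population_size`` fitness calls); each later
    generation evaluates exactly ``n_offspring`` new children (or
    ``population_size`` in canonical mode).
    """
    rng = np.random.default_rng(config.seed)
    ref_dirs = das_dennis_directions(config.M, config.p)
    bounds = (config.lower, config.upper)

    def call_fitness(genome: np.ndarray) -> np.ndarray:
        try:
            obj = fitness(genome)
        except Exception:
            logger.error("fitness evaluation failed for genome %s", genome)
            raise
        arr = obj.as_array() if hasattr(obj, "as_array") else np.asarray(obj, float)
        if arr.shape != (config.M,):
            raise ValueError(f"fitness returned shape {arr.shape}, expected ({config.M},)")
        return arr

    shape = (config.population_size, config.n_genes)
    if config.init == "loguniform":
        # log-uniform over [init_floor, upper]: weights are scale factors,
        # so this spreads the initial population across decades
        lo = np.log10(config.init_floor)
        genomes = config.upper * 10.0 ** rng.uniform(lo, 0.0, size=shape)
        genomes = np.clip(genomes, config.lower, config.upper)
    else:
        genomes = rng.uniform(config.lower, config.upper, size=shape)
    if config.seed_with_ones:
        genomes[0] = np.clip(np.ones(config.n_genes), *bounds)
    population = [Individual(genome=g, objectives=call_fitness(g)) for g in genomes]
    # annotate ranks/niches of the initial population for tournaments & records
    population = environmental_selection(population, len(population), ref_dirs, rng)

    history = [Population(0, copy.deepcopy(population))]
    n_children = config.population_size if config.canonical_offspring else config.n_offspring
    for gen in range(1, config.generations + 1):
        children: list[Individual] = []
        while len(children) < n_children:
            pa = _binary_tournament(population, rng)
            pb = _binary_tournament(population, rng)
            c1, c2 = sbx_crossover(
                pa.genome,
                pb.genome,
                eta=config.sbx_eta,
                prob=config.sbx_prob,
                rng=rng,
                bounds=bounds,
                exchange_prob=config.sbx_exchange_prob,
            )
            for c in (c1, c2):
                if len(children) < n_children:
                    mutated = polynomial_mutation(
                        c, eta=config.pm_eta, prob=config.mutation_prob,
                        rng=rng, bounds=bounds,
                    )
                    children.append(Individual(genome=mutated))
        for child in children:
            child.objectives = call_fitness(child.genome)
        population = environmental_selection(
            population + children, config.population_size, ref_dirs, rng
        )
        history.append(Population(gen, copy.deepcopy(population)))
        front0 = [ind for ind in population if ind.rank == 0]
        logger.info(
            "generation %d: front-0 size %d, mean objectives %s",
            gen,
            len(front0),
            np.round(np.mean([ind.objectives for ind in front0], axis=0), 4),
        )
    return history
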