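"""Real-coded genetic algorithm for partitional clustering.

A chromosome is a flat vector of n = K*p genes: K cluster centers
concatenated. Its fitness is the same within-cluster sum-of-squares objective
K-Means minimises (lower is better). Each generation:

1. evaluate fitness of every chromosome;
2. truncation selection — keep the ``n_parents`` lowest-fitness members;
3. crossover — parent pairs swap a contiguous run of whole center blocks
   with probability ``crossover_rate`` (blocks, not single genes, so every
   child is a valid set of K centers; a single-gene swap is the p=1 case);
4. mutation — each gene is independently perturbed with probability
   ``mutation_rate`` by a zero-mean Gaussian step whose standard deviation is
   ``mutation_sd`` times the gene's search-bound width, then clipped back
   into bounds;
5. elitism — the best ``elitism`` members pass to the next generation
   unchanged, which makes the best-so-far fitness non-increasing.

The search bounds are the per-feature data ranges. One seeded NumPy
generator drives every draw, so a run is fully determined by its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .features import FeatureMatrix
from .kmeans import assign, total_within_cluster_distance
from .model import ClusterModel

__all__ = [
    "GAConfig",
    "search_bounds",
    "init_population",
    "fitness",
    "select",
    "crossover",
    "mutate",
    "GeneticClusterer",
    "ga_cluster_fit",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the genetic search.

    Defaults are the package's declared choices; the method itself fixes
    none of them.
    """

    pop_size: int = 50
    n_generations: int = 200
    n_parents: int = 20
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    mutation_sd: float = 0.05
    elitism: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be non-negative")
        if not (2 <= self.n_parents <= self.pop_size) or self.n_parents % 2:
            raise ValueError("n_parents must be even and in [2, pop_size]")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd must be non-negative")
        if not 0 <= self.elitism < self.pop_size:
            raise ValueError("elitism must lie in [0, pop_size)")


def search_bounds(X: np.ndarray) -> np.ndarray:
    """Per-feature (low, high) bounds: the data range, widened if degenerate."""
    X = np.asarray(X, dtype=float)
    low = X.min(axis=0)
    high = X.max(axis=0)
    degenerate = high - low == 0
    if degenerate.any():
        margin = np.spacing(np.abs(low[degenerate]) + 1.0)
        low[degenerate] -= margin
        high[degenerate] += margin
        warnings.warn(
            "zero-width feature range(s) widened by a machine-epsilon margin",
            stacklevel=2,
        )
    return np.column_stack([low, high])


def init_population(
    config: GAConfig, k: int, p: int, bounds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random population: (pop_size, k*p) genes within bounds."""
    low = np.tile(bounds[:, 0], k)
    high = np.tile(bounds[:, 1], k)
    return rng.uniform(low, high, size=(config.pop_size, k * p))


def fitness(genes: np.ndarray, X: np.ndarray, k: int) -> float:
    """Clustering objective of the K centers a chromosome encodes."""
    genes = np.asarray(genes, dtype=float)
    p = np.asarray(X).shape[1]
    if genes.size != k * p:
        raise ValueError(f"chromosome length {genes.size} != k*p = {k * p}")
    return total_within_cluster_distance(X, genes.reshape(k, p))


def select(population: np.ndarray, fitnesses: np.ndarray, n_parents: int) -> np.ndarray:
    """Truncation selection: the n_parents lowest-fitness members.

    Stable sort, so ties keep population order.
    """
    if n_parents > len(population):
        raise ValueError("n_parents exceeds population size")
    order = np.argsort(fitnesses, kind="stable")
    return population[order[:n_parents]].copy()


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    config: GAConfig,
    k: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Block crossover: swap a contiguous run of center blocks between parents.

    With probability ``1 - crossover_rate`` the children are plain copies.
    """
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must have equal length")
    child_a, child_b = parent_a.copy(), parent_b.copy()
    if rng.random() < config.crossover_rate:
        p = parent_a.size // k
        lo = int(rng.integers(0, k))
        hi = int(rng.integers(lo + 1, k + 1))
        sl = slice(lo * p, hi * p)
        child_a[sl], child_b[sl] = parent_b[sl].copy(), parent_a[sl].copy()
    return child_a, child_b


def mutate(
    genes: np.ndarray,
    config: GAConfig,
    bounds: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian per-gene mutation, clipped to the search bounds."""
    out = genes.copy()
    width = np.tile(bounds[:, 1] - bounds[:, 0], k)
    mask = rng.random(out.size) < config.mutation_rate
    if mask.any():
        out[mask] += rng.normal(0.0, 1.0, size=int(mask.sum())) * (
            config.mutation_sd * width[mask]
        )
        out = np.clip(out, np.tile(bounds[:, 0], k), np.tile(bounds[:, 1], k))
    return out


class GeneticClusterer(ClusterMixin, BaseEstimator):
    """GA-based clustering estimator minimising the K-Means objective.

    Parameters mirror :class:`GAConfig`; see the module docstring for the
    generational scheme. Points are labelled by nearest evolved center.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, p)
        Best-ever chromosome, reshaped.
    labels_ : ndarray of shape (N,), 0-based
    inertia_ : float
        Fitness of the best-ever chromosome.
    history_ : ndarray of shape (n_generations + 1, 3)
        Columns: generation, best fitness, mean fitness.
    n_iter_ : int
        Generations run.
    """

    def __init__(
        self,
        n_clusters=3,
        pop_size=50,
        n_generations=200,
        n_parents=20,
        crossover_rate=0.9,
        mutation_rate=0.05,
        mutation_sd=0.05,
        elitism=2,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.pop_size = pop_size
        self.n_generations = n_generations
        self.n_parents = n_parents
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.mutation_sd = mutation_sd
        self.elitism = elitism
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            pop_size=self.pop_size,
            n_generations=self.n_generations,
            n_parents=self.n_parents,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            mutation_sd=self.mutation_sd,
            elitism=self.elitism,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        n, p = X.shape
        k = self.n_clusters
        if k < 1 or k > n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {k}")
        config = self._config()
        rng = np.random.default_rng(config.seed)
        bounds = search_bounds(X)

        population = init_population(config, k, p, bounds, rng)
        fitnesses = np.array([fitness(c, X, k) for c in population])
        best_idx = int(np.argmin(fitnesses))
        best_genes = population[best_idx].copy()
        best_fitness = float(fitnesses[best_idx])
        history = [(0, best_fitness, float(fitnesses.mean()))]

        for generation in range(1, config.n_generations + 1):
            elite_order = np.argsort(fitnesses, kind="stable")[: config.elitism]
            elites = population[elite_order].copy()
            parents = select(population, fitnesses, config.n_parents)

            children = []
            pair = 0
            while len(children) < config.pop_size - config.elitism:
                a = parents[(2 * pair) % config.n_parents]
                b = parents[(2 * pair + 1) % config.n_parents]
                for child in crossover(a, b, config, k, rng):
                    if len(children) < config.pop_size - config.elitism:
                        children.append(mutate(child, config, bounds, k, rng))
                pair += 1

            population = np.vstack([elites] + children) if len(elites) else np.array(children)
            fitnesses = np.array([fitness(c, X, k) for c in population])
            gen_best = int(np.argmin(fitnesses))
            if fitnesses[gen_best] < best_fitness:
                best_fitness = float(fitnesses[gen_best])
                best_genes = population[gen_best].copy()
            history.append((generation, best_fitness, float(fitnesses.mean())))

        self.cluster_centers_ = best_genes.reshape(k, p)
        self.labels_ = assign(X, self.cluster_centers_)
        self.inertia_ = best_fitness
        self.history_ = np.array(history)
        self.n_iter_ = config.n_generations
        return self

    def predict(self, X):
        return assign(X, self.cluster_centers_)

    def score(self, X, y=None):
        return -total_within_cluster_distance(X, self.cluster_centers_)


def ga_cluster_fit(
    data: FeatureMatrix | np.ndarray, k: int, config: GAConfig | None = None
) -> ClusterModel:
    """Run the genetic search and package the result as a :class:`ClusterModel`."""
    config = config or GAConfig()
    fm = data if isinstance(data, FeatureMatrix) else None
    X = data.values if fm is not None else np.asarray(data, dtype=float)
    est = GeneticClusterer(
        n_clusters=k,
        pop_size=config.pop_size,
        n_generations=config.n_generations,
        n_parents=config.n_parents,
        crossover_rate=config.crossover_rate,
        mutation_rate=config.mutation_rate,
        mutation_sd=config.mutation_sd,
        elitism=config.elitism,
        random_state=config.seed,
    ).fit(X)
    return ClusterModel(
        centers=est.cluster_centers_,
        k=k,
        objective=est.inertia_,
        n_iterations=est.n_iter_,
        converged=True,
        method="ga",
        seed=config.seed,
        labels=est.labels_ + 1,
        centers_original=(
            fm.to_original_units(est.cluster_centers_) if fm is not None else None
        ),
        feature_names=fm.feature_names if fm is not None else None,
    )
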