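"""Evolutionary co-optimisation of the train/test split and the input mask.

The wrapper couples two resampling ideas into one genetic-algorithm
chromosome: a *split* bit per record assigning it to half `a` or half `b`,
and a *mask* bit per input variable.  Fitness of a chromosome is the mean
test accuracy of twin, independently initialised multilayer perceptrons
trained crosswise (train on a / test on b, and the reverse) on the masked
variables, minus a penalty proportional to the distributional dissimilarity
of the two halves (mean two-sample Kolmogorov-Smirnov statistic over
continuous variables, absolute prevalence difference over binaries).  The
optimiser thus searches simultaneously for a split whose halves share a
probability density and for the variable subset with the most transferable
signal.

The genetic algorithm is generational: tournament selection, uniform
crossover, bit-flip mutation, elitism, and a "doping" step that replaces
the worst few individuals with fresh random immigrants each generation to
keep the gene pool diverse.  A sequential mode (optimise the split first
with all variables, then the mask on the frozen split) is available besides
the default joint mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import features, mlp
from ._util import substream
from .evaluation import confusion_metrics

NEG_INF = float("-inf")


@dataclass
class TwistConfig:
    population_size: int = 50
    generations: int = 100
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/L per bit-string
    elite_count: int = 2
    immigrant_fraction: float = 0.05
    distribution_penalty_weight: float = 0.5
    split_tolerance: float = 0.10  # halves within +/-10% of n/2
    patience: int = 20
    mode: str = "joint"  # 'joint' | 'sequential'
    mlp_config: mlp.TrainConfig = field(
        default_factory=lambda: mlp.TrainConfig(max_epochs=100, patience=15)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "immigrant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mode not in ("joint", "sequential"):
            raise ValueError("mode must be 'joint' or 'sequential'")


@dataclass
class TwistChromosome:
    split_bits: np.ndarray  # bool per record, True = half 'a'
    mask_bits: np.ndarray  # bool per variable
    fitness: float = NEG_INF

    def key(self) -> bytes:
        return self.split_bits.tobytes() + self.mask_bits.tobytes()


@dataclass
class TwistResult:
    best: TwistChromosome
    selected_variables: list[str]
    best_trajectory: list[float]
    mean_trajectory: list[float]
    generations_run: int

    def to_dict(self) -> dict:
        return {
            "selected_variables": self.selected_variables,
            "n_selected": len(self.selected_variables),
            "fitness": self.best.fitness,
            "split_a": self.best.split_bits.astype(int).tolist(),
            "mask": self.best.mask_bits.astype(int).tolist(),
            "best_trajectory": self.best_trajectory,
            "mean_trajectory": self.mean_trajectory,
            "generations_run": self.generations_run,
        }


def distribution_similarity(table: pd.DataFrame, split_bits) -> float:
    """Distributional distance between the two halves of a split.

    Mean over variables of the two-sample KS statistic (continuous) or the
    absolute prevalence difference (binary).  Zero iff every variable's
    empirical distribution coincides across the halves.
    """
    split_bits = np.asarray(split_bits, dtype=bool).ravel()
    if split_bits.all() or (~split_bits).all():
        raise ValueError("both halves of the split must be non-empty")
    a = table.loc[split_bits]
    b = table.loc[~split_bits]
    penalties = []
    for col in table.columns:
        xa = a[col].to_numpy(dtype=float)
        xb = b[col].to_numpy(dtype=float)
        if table[col].nunique() <= 2:
            penalties.append(abs(xa.mean() - xb.mean()))
        else:
            penalties.append(float(stats.ks_2samp(xa, xb).statistic))
    return float(np.mean(penalties))


def _split_ok(split: np.ndarray, y: np.ndarray, tol: float) -> bool:
    n = split.size
    half = n / 2.0
    n_a = int(split.sum())
    if abs(n_a - half) > tol * half:
        return False
    for cls in (0, 1):
        m = y == cls
        if not (split[m].any() and (~split)[m].any()):
            return False
    return True


def _repair_split(split: np.ndarray, y: np.ndarray, tol: float, rng) -> np.ndarray:
    """Move randomly chosen records between halves until the size and
    class-presence constraints hold (stratified: rebalance within class)."""
    split = split.copy()
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} too small to split")
        n_a = int(split[idx].sum())
        target = idx.size // 2
        while abs(split[idx].sum() - idx.size / 2.0) > max(tol * idx.size / 2.0, 0.5):
            n_a = int(split[idx].sum())
            if n_a > target:
                pool = idx[split[idx]]
                split[rng.choice(pool)] = False
            else:
                pool = idx[~split[idx]]
                split[rng.choice(pool)] = True
        if not split[idx].any():
            split[rng.choice(idx)] = True
        if split[idx].all():
            split[rng.choice(idx)] = False
    return split


def chromosome_fitness(
    chrom: TwistChromosome,
    X: pd.DataFrame,
    y: np.ndarray,
    config: TwistConfig,
) -> float:
    """Twin-MLP crossover fitness minus the distribution penalty.

    Two fresh networks are trained, one per half, each tested on the half it
    never saw; the fitness is the mean of their balanced test accuracies
    (on the 0-1 scale) minus ``lambda * distribution_similarity``.  An empty
    mask is inadmissible and scores -inf.
    """
    if not chrom.mask_bits.any():
        return NEG_INF
    cols = [c for c, keep in zip(X.columns, chrom.mask_bits) if keep]
    masked = X[cols]
    lam = config.distribution_penalty_weight
    penalty = distribution_similarity(X, chrom.split_bits) if lam != 0.0 else 0.0
    accs = []
    for train_mask in (chrom.split_bits, ~chrom.split_bits):
        test_mask = ~train_mask
        cont = tuple(c for c in cols if c in features.CONTINUOUS_NAMES)
        scaled, _ = features.scale_inputs(masked, train_mask, continuous=cont)
        model, _ = mlp.train(
            scaled.loc[train_mask].to_numpy(float), y[train_mask], config.mlp_config
        )
        pred = mlp.classify(model.predict(scaled.loc[test_mask].to_numpy(float)))
        m = confusion_metrics(y[test_mask], pred)
        accs.append(m.accuracy / 100.0)
    return float(np.mean(accs) - lam * penalty)


def _random_chromosome(n: int, p: int, y, config, rng) -> TwistChromosome:
    split = rng.random(n) < 0.5
    split = _repair_split(split, y, config.split_tolerance, rng)
    mask = rng.random(p) < 0.5
    if not mask.any():
        mask[rng.integers(p)] = True
    return TwistChromosome(split_bits=split, mask_bits=mask)


def run_twist(
    X: pd.DataFrame,
    y,
    config: TwistConfig | None = None,
    optimise_mask: bool = True,
    fixed_split: np.ndarray | None = None,
) -> TwistResult:
    """Run the generational GA; fully deterministic for a fixed seed."""
    config = config or TwistConfig()
    config.validate()
    y = np.asarray(y, dtype=int).ravel()
    n, p = X.shape
    if n < 8:
        raise ValueError("sample too small for the split constraint")

    if config.mode == "sequential" and optimise_mask and fixed_split is None:
        # stage 1: balance the split with every variable in play
        stage1 = run_twist(X, y, config=_with_mode(config, "joint"), optimise_mask=False)
        return run_twist(
            X, y, config=_with_mode(config, "joint"),
            optimise_mask=True, fixed_split=stage1.best.split_bits,
        )

    rng = substream(config.seed, "twist")
    mut_mask = config.mutation_rate if config.mutation_rate is not None else 1.0 / p
    mut_split = config.mutation_rate if config.mutation_rate is not None else 1.0 / n

    def make_random() -> TwistChromosome:
        c = _random_chromosome(n, p, y, config, rng)
        if fixed_split is not None:
            c.split_bits = fixed_split.copy()
        if not optimise_mask:
            c.mask_bits = np.ones(p, dtype=bool)
        return c

    cache: dict[bytes, float] = {}

    def evaluate(c: TwistChromosome) -> None:
        k = c.key()
        if k not in cache:
            cache[k] = chromosome_fitness(c, X, y, config)
        c.fitness = cache[k]

    population = [make_random() for _ in range(config.population_size)]
    for c in population:
        evaluate(c)

    best_traj: list[float] = []
    mean_traj: list[float] = []
    stale = 0
    best_so_far = NEG_INF
    gen = 0
    for gen in range(1, config.generations + 1):
        population.sort(key=lambda c: c.fitness, reverse=True)
        elites = [
            TwistChromosome(c.split_bits.copy(), c.mask_bits.copy(), c.fitness)
            for c in population[: config.elite_count]
        ]
        offspring: list[TwistChromosome] = []
        while len(offspring) < config.population_size - len(elites):
            pa = _tournament(population, config.tournament_size, rng)
            pb = _tournament(population, config.tournament_size, rng)
            child_split = pa.split_bits.copy()
            child_mask = pa.mask_bits.copy()
            if rng.random() < config.crossover_rate:
                take = rng.random(n) < 0.5
                child_split[take] = pb.split_bits[take]
                take = rng.random(p) < 0.5
                child_mask[take] = pb.mask_bits[take]
            flip = rng.random(n) < mut_split
            child_split[flip] = ~child_split[flip]
            flip = rng.random(p) < mut_mask
            child_mask[flip] = ~child_mask[flip]
            if fixed_split is not None:
                child_split = fixed_split.copy()
            else:
                child_split = _repair_split(child_split, y, config.split_tolerance, rng)
            if not optimise_mask:
                child_mask = np.ones(p, dtype=bool)
            elif not child_mask.any():
                child_mask[rng.integers(p)] = True
            offspring.append(TwistChromosome(child_split, child_mask))
        # doping: random immigrants replace the worst offspring
        n_imm = int(round(config.immigrant_fraction * config.population_size))
        for _ in range(min(n_imm, len(offspring))):
            offspring[rng.integers(len(offspring))] = make_random()
        for c in offspring:
            evaluate(c)
        population = elites + offspring
        fits = np.array([c.fitness for c in population])
        gen_best = float(fits.max())
        best_traj.append(max(gen_best, best_so_far))
        mean_traj.append(float(np.mean(fits[np.isfinite(fits)])))
        if gen_best > best_so_far + 1e-12:
            best_so_far = gen_best
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    population.sort(key=lambda c: c.fitness, reverse=True)
    best = population[0]
    selected = [c for c, keep in zip(X.columns, best.mask_bits) if keep]
    return TwistResult(
        best=best,
        selected_variables=selected,
        best_trajectory=best_traj,
        mean_trajectory=mean_traj,
        generations_run=gen,
    )


def _with_mode(config: TwistConfig, mode: str) -> TwistConfig:
    from dataclasses import replace

    return replace(config, mode=mode)


def _tournament(population, k, rng) -> TwistChromosome:
    picks = rng.integers(0, len(population), size=max(1, k))
    return max((population[i] for i in picks), key=lambda c: c.fitness)
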