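"""GA-ACO hybrid weight initializer for the BP surrogate.

Each of the 6h+1 network weights is a "path" choice over a discrete grid
of m candidate values in [−1, 1], with a pheromone concentration per
candidate (initialized at unity).  Every iteration:

1. ants assemble candidate weight vectors by roulette selection
   proportional to pheromone, with probability α of greedily taking the
   max-pheromone candidate (the transition-constant rule);
2. each vector is scored by the forward-pass error of the corresponding
   untrained network — no backpropagation is involved;
3. a genetic step refines the ant population (fitness-proportional partner
   selection, single-point crossover, per-gene Gaussian mutation, with the
   best individual preserved unchanged);
4. pheromones evaporate by the factor ρ and the elite vectors deposit an
   amount inversely proportional to their error.

Iteration stops at the generation cap or when the best fitness plateaus
(relative change below 1e-4 across 10 iterations).  The best vector found
initializes ordinary BP training, whose epochs and error threshold mirror
the plain BP configuration.

By default candidate fitness is the RMSE over the full design table: the
metaheuristic pre-conditions the network on the whole response surface
and backpropagation then refines on the training split only.  Scoring on
the training or validation split alone is selectable via
:class:`GAACOConfig.fitness_set`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ann import (MLPSurrogate, Normalization, TrainConfig, forward,
                  init_weights, n_weights, predict_mlp, train_bp)
from .data_io import DesignTable
from .evaluate import FitMetrics, SplitSpec, metrics, split

__all__ = [
    "PheromoneField",
    "GAACOConfig",
    "ConvergenceTrace",
    "ant_construct",
    "update_pheromone",
    "ga_step",
    "run_gaaco",
    "train_gaaco_bp",
]


@dataclass
class GAACOConfig:
    """Hybrid-search configuration; values the study leaves open default to
    conventional settings for GA-ACO-BP hybrids."""

    n_ants: int = 30
    n_generations: int = 100
    m_candidates: int = 10
    candidate_range: tuple = (-1.0, 1.0)
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_scale: float = 0.1
    rho: float = 0.9  # pheromone volatilization per iteration
    alpha: float = 0.2  # transition probability constant
    alpha_mode: str = "greedy"  # "greedy" | "exponent"
    deposit_q: float = 1.0
    n_elite: int = 5
    fitness_set: str = "full"  # "full" | "train" | "validation"
    fitness_metric: str = "rmse"  # "rmse" | "mse"
    plateau_tol: float = 1e-4
    plateau_window: int = 10
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("n_ants", "n_generations", "m_candidates", "n_elite"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fitness_set not in ("full", "train", "validation"):
            raise ValueError(f"unknown fitness_set {self.fitness_set!r}")
        if self.alpha_mode not in ("greedy", "exponent"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")


class PheromoneField:
    """Per-weight-slot candidate grids with pheromone concentrations."""

    def __init__(self, n_slots: int, m: int = 10, candidate_range=(-1.0, 1.0),
                 rho: float = 0.9, alpha: float = 0.2, alpha_mode: str = "greedy"):
        if m < 1:
            raise ValueError("need at least one candidate per slot")
        self.candidates = np.tile(
            np.linspace(candidate_range[0], candidate_range[1], m), (n_slots, 1)
        )
        self.tau = np.ones((n_slots, m))  # unity initial concentration
        self.rho = rho
        self.alpha = alpha
        self.alpha_mode = alpha_mode

    @property
    def n_slots(self) -> int:
        return self.tau.shape[0]

    @property
    def m(self) -> int:
        return self.tau.shape[1]

    def nearest_candidate_index(self, vector: np.ndarray) -> np.ndarray:
        """Per slot, the index of the grid candidate closest to the value."""
        return np.abs(vector[:, None] - self.candidates).argmin(axis=1)


def ant_construct(field: PheromoneField, rng) -> np.ndarray:
    """Assemble one candidate weight vector from the pheromone field.

    Roulette selection proportional to pheromone per slot; with probability
    ``alpha`` a slot instead takes the max-pheromone candidate greedily
    (``alpha_mode="greedy"``, the default reading of the transition
    constant), or the roulette weights are raised to the power ``alpha``
    (``alpha_mode="exponent"``).
    """
    rng = np.random.default_rng(rng)
    tau = field.tau
    if field.alpha_mode == "exponent":
        weights = tau ** field.alpha
        cdf = np.cumsum(weights, axis=1)
        u = rng.random(field.n_slots) * cdf[:, -1]
        idx = (u[:, None] > cdf).sum(axis=1)
    else:
        cdf = np.cumsum(tau, axis=1)
        u = rng.random(field.n_slots) * cdf[:, -1]
        idx = (u[:, None] > cdf).sum(axis=1)
        greedy = rng.random(field.n_slots) < field.alpha
        idx = np.where(greedy, tau.argmax(axis=1), idx)
    return field.candidates[np.arange(field.n_slots), idx]


def update_pheromone(field: PheromoneField, evaluated: Sequence, n_elite: int = 5,
                     q: float = 1.0) -> PheromoneField:
    """Volatilize all pheromones by ρ, then reinforce the candidates used by
    the elite (lowest-error) ants with a deposit q / fitness.

    ``evaluated`` is a sequence of ``(vector, fitness)`` pairs; ants with
    non-finite fitness are skipped with a warning.  Updates in place and
    returns the field.
    """
    if len(evaluated) < 1:
        raise ValueError("need at least one evaluated ant")
    field.tau *= field.rho
    finite = []
    for vec, fit in evaluated:
        if not np.isfinite(fit):
            warnings.warn("skipping ant with non-finite fitness", stacklevel=2)
            continue
        finite.append((np.asarray(vec, float), float(fit)))
    finite.sort(key=lambda vf: vf[1])
    for vec, fit in finite[:n_elite]:
        idx = field.nearest_candidate_index(vec)
        field.tau[np.arange(field.n_slots), idx] += q / max(fit, 1e-12)
    return field


def ga_step(population: np.ndarray, fitnesses: np.ndarray, config: GAACOConfig,
            rng) -> np.ndarray:
    """One genetic refinement of a population of weight vectors.

    With probability ``crossover_rate`` each population slot is refilled by
    single-point crossover of two fitness-proportionally selected parents
    (selection weight 1/fitness, as fitness is an error); otherwise the
    incumbent individual passes through unchanged.  Each gene then mutates
    with probability ``mutation_rate`` by Gaussian noise of scale
    ``mutation_scale``.  The best individual is preserved unchanged
    (elitism), so with both rates zero the population is returned intact.
    """
    pop = np.asarray(population, dtype=float)
    fit = np.asarray(fitnesses, dtype=float)
    if len(pop) < 2:
        raise ValueError(f"population must have >= 2 individuals, got {len(pop)}")
    rng = np.random.default_rng(rng)
    n, n_genes = pop.shape
    sel_w = 1.0 / (fit + 1e-12)
    sel_p = sel_w / sel_w.sum()
    children = pop.copy()
    do_cx = rng.random(n) < config.crossover_rate
    parents = rng.choice(n, size=(n, 2), p=sel_p)
    cuts = rng.integers(1, n_genes, size=n)
    for i in np.flatnonzero(do_cx):
        children[i, : cuts[i]] = pop[parents[i, 0], : cuts[i]]
        children[i, cuts[i]:] = pop[parents[i, 1], cuts[i]:]
    mut = rng.random((n, n_genes)) < config.mutation_rate
    children[mut] += rng.normal(0.0, config.mutation_scale, int(mut.sum()))
    lo, hi = config.candidate_range
    children = np.clip(children, lo, hi)
    best = int(np.argmin(fit))
    children[best] = pop[best]
    return children


@dataclass
class ConvergenceTrace:
    """Best and population-mean fitness per iteration."""

    best: np.ndarray
    mean: np.ndarray

    @property
    def n_iterations(self) -> int:
        return len(self.best)


def _fitness_indices(n: int, config: GAACOConfig, train_idx, valid_idx):
    if config.fitness_set == "full":
        return np.arange(n)
    if config.fitness_set == "train":
        return np.asarray(train_idx)
    return np.asarray(valid_idx)


def run_gaaco(data: DesignTable, n_hidden: int, config: GAACOConfig,
              train_idx=None, valid_idx=None,
              normalization: Optional[Normalization] = None):
    """Run the hybrid search; returns (best weight vector, ConvergenceTrace).

    ``train_idx``/``valid_idx`` are required only when the configured
    fitness set is a split; fitness is the forward-pass error of each
    candidate network, evaluated in normalized space.
    """
    rng = np.random.default_rng(config.seed)
    nw = n_weights(n_hidden)
    norm = normalization or Normalization.fit(data.factors, data.yields)
    Xn, yn = norm.norm_x(data.factors), norm.norm_y(data.yields)
    idx = _fitness_indices(len(data), config, train_idx, valid_idx)
    Xf, yf = Xn[idx], yn[idx]

    def fitness_of(pop: np.ndarray) -> np.ndarray:
        errs = np.empty(len(pop))
        for i, w in enumerate(pop):
            e = forward(w, n_hidden, Xf) - yf
            errs[i] = float(e @ e) / len(yf)
        return np.sqrt(errs) if config.fitness_metric == "rmse" else errs

    field = PheromoneField(nw, config.m_candidates, config.candidate_range,
                           rho=config.rho, alpha=config.alpha,
                           alpha_mode=config.alpha_mode)
    best_w, best_f = None, np.inf
    trace_best, trace_mean = [], []
    for it in range(config.n_generations):
        ants = np.array([ant_construct(field, rng) for _ in range(config.n_ants)])
        fit = fitness_of(ants)
        if best_w is not None:  # cross-generation elitism
            worst = int(np.argmax(fit))
            ants[worst], fit[worst] = best_w, best_f
        children = ga_step(ants, fit, config, rng)
        fit2 = fitness_of(children)
        k = int(np.argmin(fit2))
        if fit2[k] < best_f:
            best_f, best_w = float(fit2[k]), children[k].copy()
        trace_best.append(best_f)
        trace_mean.append(float(np.mean(fit2)))
        both = list(zip(ants, fit)) + list(zip(children, fit2))
        update_pheromone(field, both, n_elite=config.n_elite, q=config.deposit_q)
        w = config.plateau_window
        if it >= w and trace_best[-w - 1] > 0 and \
                (trace_best[-w - 1] - trace_best[-1]) / trace_best[-w - 1] < config.plateau_tol:
            break
    return best_w, ConvergenceTrace(np.asarray(trace_best), np.asarray(trace_mean))


def train_gaaco_bp(data: DesignTable, split_spec: SplitSpec,
                   gaaco_config: GAACOConfig, train_config: TrainConfig,
                   n_hidden: int = 4):
    """Full hybrid protocol: GA-ACO search, then BP refinement on the
    training split; returns (net, FitMetrics over the full table, trace).

    Normalization is frozen on the full design table so the metaheuristic
    and the refinement operate in the same space.
    """
    train_table, valid_table = split(data, split_spec)
    train_ids = np.flatnonzero(np.isin(data.frame["run"], train_table.frame["run"]))
    valid_ids = np.flatnonzero(np.isin(data.frame["run"], valid_table.frame["run"]))
    norm = Normalization.fit(data.factors, data.yields)
    best_w, trace = run_gaaco(data, n_hidden, gaaco_config,
                              train_idx=train_ids, valid_idx=valid_ids,
                              normalization=norm)
    net = MLPSurrogate(n_hidden, init_weights(n_hidden, external_vector=best_w), norm)
    trained, _ = train_bp(net, train_table, train_config)
    fit = metrics(data.yields, predict_mlp(trained, data.factors))
    return trained, fit, trace
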