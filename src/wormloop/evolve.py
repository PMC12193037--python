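"""Genetic-algorithm fitting of the model's free parameters.

The fitness has two components.  The rhythm term rewards, for every muscle,
a deformation trace that both attains the target amplitude and oscillates at
the target frequency:

    F1 = sum_i [ max(0, 1 - TV_i / (4 A fre_a T)) + |1 - fre_i / fre_a| ]

where TV_i is the total variation of muscle i's deformation over the
analysed window (a sinusoid of amplitude A at fre_a gives exactly
4 A fre_a T, zeroing the first term) and a non-oscillating trace takes the
maximal frequency penalty.  The velocity term F2 = |1 - V/V_a| compares the
net forward centroid speed, projected on the worm's mean heading, against
the target observed in viscous-oil swimming.  Whole-worm fits minimise
F1 + F2; sub-circuits without meaningful displacement use F1 alone.

The optimizer is a seeded real-coded GA: tournament selection, blend
crossover, per-gene Gaussian mutation, and elitism, so the best-so-far
fitness is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import params as P
from .analysis import Trace, estimate_frequency
from .errors import IntegrationBlowUpError
from .geometry import EnvironmentParams
from .kernel import lower
from .simulate import SimulationResult, run

#: Fitness assigned to simulations that blow up or fail.
PENALTY_FITNESS = 1.0e6


@dataclass
class FitnessSpec:
    """Targets taken from forward locomotion in viscous oil."""

    target_frequency: float = 1.0  # Hz
    target_velocity: float = 126.0  # um/s
    amplitude_threshold: float = 0.5  # um, the A of the rhythm term
    horizon: float = 10.0  # s of simulation per evaluation
    burn_in: float = 0.2

    def __post_init__(self) -> None:
        if self.target_frequency <= 0 or self.target_velocity <= 0:
            raise ValueError("targets must be > 0")
        if self.amplitude_threshold <= 0:
            raise ValueError("amplitude threshold must be > 0")


def _amplitude_deficit(values: np.ndarray, dt: float, spec: FitnessSpec) -> float:
    t_eff = (len(values) - 1) * dt
    if t_eff <= 0:
        return 1.0
    tv = float(np.sum(np.abs(np.diff(values))))
    full = 4.0 * spec.amplitude_threshold * spec.target_frequency * t_eff
    return max(0.0, 1.0 - tv / full)


def rhythm_fitness(result: SimulationResult, spec: FitnessSpec,
                   amplitude_term=None) -> float:
    """F1 >= 0; zero only for full-amplitude oscillation at the target
    frequency in every muscle.

    ``amplitude_term(values, dt, spec)`` is pluggable; the default is the
    total-variation deficit described in the module docstring.
    """
    if amplitude_term is None:
        amplitude_term = _amplitude_deficit
    sl = result.burn_slice(spec.burn_in)
    dt = result.dt_output
    total = 0.0
    for j in range(result.deformation.shape[1]):
        values = result.deformation[sl, j]
        total += amplitude_term(values, dt, spec)
        fre = estimate_frequency(Trace(result.deformation[:, j], dt),
                                 burn_in=spec.burn_in)
        total += abs(1.0 - fre / spec.target_frequency)
    return total


def mean_heading(result: SimulationResult, burn_in: float = 0.2) -> np.ndarray:
    """Unit vector of the worm's mean anterior direction.

    The body frame's +x axis points tailward, so the anterior heading is the
    negative of the mean segment axis.
    """
    sl = result.burn_slice(burn_in)
    angles = np.cumsum(result.y[sl, 2:], axis=1)
    axis = np.array([np.mean(np.cos(angles)), np.mean(np.sin(angles))])
    norm = np.linalg.norm(axis)
    if norm == 0:
        return np.array([1.0, 0.0])
    return -axis / norm


def forward_velocity(result: SimulationResult, burn_in: float = 0.2) -> float:
    """Net centroid velocity (um/s) projected on the mean heading."""
    sl = result.burn_slice(burn_in)
    start = int(np.floor(burn_in * len(result.t)))
    t_eff = result.t[-1] - result.t[start]
    if t_eff <= 0:
        return 0.0
    disp = result.centroid[-1] - result.centroid[start]
    return float(disp @ mean_heading(result, burn_in)) / t_eff


def velocity_fitness(result: SimulationResult, spec: FitnessSpec) -> float:
    """F2 = |1 - V / V_a| (0 when matching the target; 1 when stationary)."""
    return abs(1.0 - forward_velocity(result, spec.burn_in) / spec.target_velocity)


@dataclass
class EAProblem:
    """A fitting task: genome layout + circuit builder + fitness targets."""

    layout: P.GenomeLayout
    builder: Callable[[Mapping[str, float]], object]
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    include_velocity: bool = False
    aliases: dict[str, str] = field(default_factory=dict)
    dt: float = 5e-4
    stride: int = 10
    init_mode: str = "perturbed"
    #: initial-condition seeds averaged per evaluation; > 1 selects
    #: oscillators whose basin is not razor-thin around one perturbation
    n_seeds: int = 1

    def decode(self, genome: np.ndarray) -> dict[str, float]:
        return P.decode(self.layout, genome, self.aliases)

    def simulate(self, params: Mapping[str, float], seed: int | None = 0,
                 duration: float | None = None) -> SimulationResult:
        config = self.builder(params)
        env = EnvironmentParams(params["C_N"], params["C_T"])
        model = lower(config, None, env)
        return run(config, duration=duration or self.fitness.horizon,
                   dt=self.dt, stride=self.stride, init_mode=self.init_mode,
                   seed=seed, model=model)


def evaluate(genome: np.ndarray, problem: EAProblem, seed: int = 0) -> float:
    """Fitness of one genome (pure function of genome, problem and seed).

    Simulation blow-ups score a large finite penalty rather than raising, so
    the GA can route around unstable parameter regions.
    """
    genome = np.asarray(genome, dtype=float)
    if not P.in_bounds(problem.layout, genome):
        raise ValueError("genome out of bounds")
    params = problem.decode(genome)
    total = 0.0
    for k in range(problem.n_seeds):
        try:
            result = problem.simulate(params, seed=seed + k)
        except (IntegrationBlowUpError, FloatingPointError, ValueError):
            return PENALTY_FITNESS
        f = rhythm_fitness(result, problem.fitness)
        if problem.include_velocity:
            f += velocity_fitness(result, problem.fitness)
        if not np.isfinite(f):
            return PENALTY_FITNESS
        total += f
    return total / problem.n_seeds


@dataclass
class EASettings:
    population: int = 60
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.1  # fraction of each gene's range
    tournament: int = 3
    elitism: int = 1
    seed: int = 0


@dataclass
class EAResult:
    best_genome: np.ndarray
    best_params: dict[str, float]
    best_fitness: float
    history: pd.DataFrame  # per-generation best/mean fitness


def optimize(
    problem: EAProblem,
    settings: EASettings | None = None,
    objective: Callable[[np.ndarray], float] | None = None,
    initial: np.ndarray | None = None,
) -> EAResult:
    """Minimise the locomotion fitness with a seeded genetic algorithm.

    ``objective`` overrides the default ``evaluate`` (used by self-tests and
    custom fits); ``initial`` seeds one individual of the first generation.
    """
    st = settings or EASettings()
    rng = np.random.default_rng(st.seed)
    layout = problem.layout
    n_genes = len(layout)
    lo = np.array([g.lower for g in layout])
    hi = np.array([g.upper for g in layout])
    span = hi - lo
    if objective is None:
        objective = lambda g: evaluate(g, problem, seed=st.seed)  # noqa: E731

    pop = np.array([P.random_genome(layout, rng) for _ in range(st.population)])
    if initial is not None:
        pop[0] = P.clip(layout, np.asarray(initial, dtype=float))
    fit = np.array([objective(g) for g in pop])

    records = []
    best_idx = int(np.argmin(fit))
    best_genome, best_fit = pop[best_idx].copy(), float(fit[best_idx])

    for gen in range(st.generations):
        order = np.argsort(fit)
        elites = pop[order[:st.elitism]].copy()
        children = list(elites)
        while len(children) < st.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, st.population, st.tournament)
                parents.append(pop[contenders[np.argmin(fit[contenders])]])
            a, b = parents
            if rng.random() < st.crossover_rate:
                mix = rng.random(n_genes)
                child = mix * a + (1.0 - mix) * b
            else:
                child = a.copy()
            mutate = rng.random(n_genes) < st.mutation_rate
            child = child + mutate * rng.normal(0.0, st.mutation_sigma * span)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[:st.population])
        fit = np.array([objective(g) for g in pop])
        # elites were copied verbatim but re-evaluated identically (pure
        # objective), so best-so-far cannot increase
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_genome = pop[gen_best].copy()
        records.append({"generation": gen, "best": best_fit,
                        "gen_best": float(fit[gen_best]),
                        "mean": float(np.mean(fit))})

    return EAResult(
        best_genome=best_genome,
        best_params=problem.decode(best_genome),
        best_fitness=best_fit,
        history=pd.DataFrame(records),
    )
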