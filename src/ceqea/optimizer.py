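"""The entropy-guided quantum evolutionary generation loop.

Each generation: observe every chromosome (class token forced on),
evaluate the composite fitness, update the best-so-far mask, select the
elite, refill the rest of the population by uniform crossover of elite
parents, rotate every chromosome toward the best-so-far mask with an
entropy-scaled step, and apply entropy-scaled phase-flip mutation.
Elitism operates on masks/records: the best-so-far mask can only
improve, so the best-fitness trace is non-decreasing by construction.

The public surface is modelled after statsmodels: build a
:class:`CEQEA` model around an accuracy evaluator, call ``fit()``, and
read estimates and diagnostics off the returned :class:`CEQEAResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EntropyProfile, population_size, rotation_step
from .fitness import FitnessConfig, FitnessRecord, composite_fitness
from .quantum import (
    BinaryMask,
    QubitChromosome,
    StabilityScores,
    init_population,
    mutation_probability,
    observe,
    phase_flip,
    rotate,
)

__all__ = ["CEQEAConfig", "GenerationTrace", "select_elites", "uniform_crossover", "run_ceqea", "CEQEA", "CEQEAResults"]


@dataclass(frozen=True)
class CEQEAConfig:
    """Hyperparameters of the evolutionary search.

    Defaults follow the reference configuration: 10 generations, base
    population 10 with entropy expansion 0.3, base rotation step 0.05
    rad with entropy scale 0.3, base mutation rate 0.15, accuracy
    weight 0.7.  ``elite_count=None`` resolves to ``max(2, ceil(P/5))``;
    ``convergence_patience=None`` disables early stopping.
    """

    generations: int = 10
    base_population: int = 10
    pop_entropy_scale: float = 0.3
    base_rotation_step: float = 0.05
    rotation_entropy_scale: float = 0.3
    mutation_base_rate: float = 0.15
    elite_count: int | None = None
    crossover_prob: float = 0.5
    accuracy_weight: float = 0.7
    convergence_patience: int | None = None
    invert_stability: bool = False

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.elite_count is not None and self.elite_count < 2:
            raise ValueError("elite_count must be >= 2")

    def resolve_elite_count(self, pop_size: int) -> int:
        n = self.elite_count if self.elite_count is not None else max(2, -(-pop_size // 5))
        return min(n, pop_size)


@dataclass
class GenerationTrace:
    """Per-generation diagnostics of one optimisation run."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_retained: list[int] = field(default_factory=list)
    best_masks: list[BinaryMask] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best_fitness)),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "retained_count": self.best_retained,
            }
        )


def _elite_indices(records: list[FitnessRecord], n: int) -> list[int]:
    if n > len(records):
        raise ValueError("elite count exceeds population size")
    order = sorted(
        range(len(records)),
        key=lambda i: (-records[i].fitness, records[i].mask.retained_count, i),
    )
    return order[:n]


def select_elites(records: list[FitnessRecord], n: int) -> list[FitnessRecord]:
    """Top-``n`` records by fitness.

    Ties broken toward fewer retained tokens, then lower population
    index, so selection is fully deterministic.
    """
    return [records[i] for i in _elite_indices(records, n)]


def uniform_crossover(
    parent_a: QubitChromosome,
    parent_b: QubitChromosome,
    p: float,
    rng: np.random.Generator,
) -> QubitChromosome:
    """Per-position amplitude-pair exchange.

    Each offspring qubit is copied whole (both amplitudes) from parent A
    with probability ``p``, else from parent B, so normalisation is
    inherited rather than re-established.
    """
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal length")
    take_a = rng.random(len(parent_a)) < p
    alpha = np.where(take_a, parent_a.alpha, parent_b.alpha)
    beta = np.where(take_a, parent_a.beta, parent_b.beta)
    return QubitChromosome(alpha, beta)


def run_ceqea(
    evaluator,
    n_tokens: int,
    entropy: EntropyProfile,
    stability: StabilityScores | None = None,
    cfg: CEQEAConfig | None = None,
    seed: int | None = None,
    collect_elites: bool = False,
    initial_population: list[QubitChromosome] | None = None,
):
    """Run the full generation loop; returns ``(best_mask, trace)``.

    ``evaluator`` is any callable ``(mask) -> accuracy in [0, 1]``.
    ``stability`` defaults to all-ones (no federated history).  With
    ``collect_elites`` the final generation's elite masks and the final
    quantum population are returned as extra elements, so a federated
    client can upload its elites and warm-start the next round.
    ``initial_population`` continues a previous run's population
    (amplitude state persists across federated rounds; the unbiased
    superposition applies to round 0 only).
    """
    cfg = cfg or CEQEAConfig()
    stability = stability or StabilityScores.ones(n_tokens)
    if len(stability.scores) != n_tokens:
        raise ValueError("stability score length must equal n_tokens")
    rng = np.random.default_rng(seed)
    fit_cfg = FitnessConfig(accuracy_weight=cfg.accuracy_weight, n_tokens=n_tokens)

    pop_size = population_size(entropy, cfg.base_population, cfg.pop_entropy_scale)
    step = rotation_step(entropy, cfg.base_rotation_step, cfg.rotation_entropy_scale)
    n_elite = cfg.resolve_elite_count(pop_size)
    if initial_population is not None:
        if len(initial_population) != pop_size or any(
            len(c) != n_tokens for c in initial_population
        ):
            raise ValueError("initial population incompatible with configuration")
        population = [c.copy() for c in initial_population]
    else:
        population = init_population(pop_size, n_tokens)

    trace = GenerationTrace()
    best_record: FitnessRecord | None = None
    stall = 0
    elites: list[FitnessRecord] = []

    for _gen in range(cfg.generations):
        # observation + evaluation
        records = []
        for chrom in population:
            mask = observe(chrom, rng, force_first=True)
            acc = float(evaluator(mask))
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"evaluator returned accuracy {acc} outside [0, 1]")
            records.append(FitnessRecord(mask, acc, composite_fitness(acc, mask, fit_cfg)))

        # best-so-far update (before rotation: generation-t information)
        gen_best = select_elites(records, 1)[0]
        if best_record is None or gen_best.fitness > best_record.fitness:
            best_record = gen_best
            stall = 0
        else:
            stall += 1

        trace.best_fitness.append(best_record.fitness)
        trace.mean_fitness.append(float(np.mean([r.fitness for r in records])))
        trace.best_retained.append(best_record.mask.retained_count)
        trace.best_masks.append(best_record.mask)

        elite_idx = _elite_indices(records, n_elite)
        elites = [records[i] for i in elite_idx]
        if cfg.convergence_patience is not None and stall >= cfg.convergence_patience:
            break

        # rotate every evaluated individual toward the best-so-far mask,
        # using its own observed mask and fitness from this generation
        rotated = [
            rotate(c, r.mask, best_record.mask, r.fitness, best_record.fitness, step)
            for c, r in zip(population, records)
        ]

        # elite chromosomes persist (post-rotation); the remaining slots
        # are refilled by uniform crossover of elite parents
        elite_chroms = [rotated[i] for i in elite_idx]
        slot_fitness = [records[i].fitness for i in elite_idx]
        new_population = list(elite_chroms)
        while len(new_population) < pop_size:
            pa, pb = rng.choice(len(elite_chroms), size=2, replace=len(elite_chroms) < 2)
            new_population.append(
                uniform_crossover(elite_chroms[int(pa)], elite_chroms[int(pb)], cfg.crossover_prob, rng)
            )
            slot_fitness.append((records[elite_idx[int(pa)]].fitness + records[elite_idx[int(pb)]].fitness) / 2)

        # entropy-scaled phase-flip mutation, qubit-wise Bernoulli draws
        f_max = max(r.fitness for r in records)
        s_vec = (1.0 - stability.scores) if cfg.invert_stability else stability.scores
        mutated = []
        for chrom, f in zip(new_population, slot_fitness):
            scale = mutation_probability(
                cfg.mutation_base_rate, min(f, f_max), f_max, entropy, 1.0
            )
            probs = scale * s_vec
            flips = np.flatnonzero(rng.random(n_tokens) < probs)
            for j in flips:
                chrom = phase_flip(chrom, int(j))
            mutated.append(chrom)
        population = mutated

    if collect_elites:
        return best_record.mask, trace, [e.mask for e in elites], population
    return best_record.mask, trace


# ---------------------------------------------------------------------------
# Model / Results presentation
# ---------------------------------------------------------------------------


class CEQEA:
    """Token-pruning model: an evaluator plus entropy context.

    Parameters
    ----------
    evaluator
        Callable ``(mask) -> accuracy in [0, 1]``.
    n_tokens
        Sequence length including the class token at position 0.
    entropy
        Client :class:`~ceqea.entropy.EntropyProfile`; defaults to the
        zero-entropy profile (single-class client).
    stability
        Optional federated token stability scores.
    config
        :class:`CEQEAConfig`; defaults are the reference configuration.
    """

    def __init__(
        self,
        evaluator,
        n_tokens: int,
        entropy: EntropyProfile | None = None,
        stability: StabilityScores | None = None,
        config: CEQEAConfig | None = None,
    ):
        self.evaluator = evaluator
        self.n_tokens = n_tokens
        self.entropy = entropy or EntropyProfile(0.0, 0.0)
        self.stability = stability
        self.config = config or CEQEAConfig()

    @classmethod
    def from_dataset(cls, features, labels, n_classes=None, config=None, seed=0, **proxy_kwargs):
        """Build the model from token features + labels with the MLP proxy."""
        from .entropy import ClassDistribution, shannon_entropy
        from .fitness import MLPProxyEvaluator

        evaluator = MLPProxyEvaluator(features, labels, n_classes=n_classes, seed=seed, **proxy_kwargs)
        profile = shannon_entropy(ClassDistribution.from_labels(labels, n_classes))
        return cls(evaluator, np.asarray(features).shape[1], entropy=profile, config=config)

    def fit(
        self,
        seed: int | None = None,
        initial_population: list[QubitChromosome] | None = None,
    ) -> "CEQEAResults":
        mask, trace, elites, population = run_ceqea(
            self.evaluator,
            self.n_tokens,
            self.entropy,
            self.stability,
            self.config,
            seed=seed,
            collect_elites=True,
            initial_population=initial_population,
        )
        return CEQEAResults(self, mask, trace, elites, population)


class CEQEAResults:
    """Fitted token-pruning result: best mask, trace, diagnostics."""

    def __init__(self, model: CEQEA, mask: BinaryMask, trace: GenerationTrace, elite_masks, final_population=None):
        self.model = model
        self.mask = mask
        self.trace = trace
        self.elite_masks = elite_masks
        self.final_population = final_population
        self.fit_config = FitnessConfig(model.config.accuracy_weight, model.n_tokens)

    @property
    def best_fitness(self) -> float:
        return self.trace.best_fitness[-1]

    @property
    def normalized_fitness(self) -> float:
        """Best fitness relative to the attainable ceiling (1.0 = optimal)."""
        return self.best_fitness / self.fit_config.max_attainable

    @property
    def retained_count(self) -> int:
        return self.mask.retained_count

    @property
    def pruning_ratio(self) -> float:
        return 1.0 - self.retained_count / self.model.n_tokens

    def trace_frame(self) -> pd.DataFrame:
        return self.trace.to_frame()

    def summary(self) -> str:
        lines = [
            "Entropy-Guided Quantum Evolutionary Token Pruning",
            "=" * 49,
            f"tokens (incl. class token)   {self.model.n_tokens}",
            f"generations run              {len(self.trace.best_fitness)}",
            f"client entropy (bits)        {self.model.entropy.entropy_bits:.4f}"
            f" / max {self.model.entropy.max_entropy_bits:.4f}",
            f"retained tokens              {self.retained_count}",
            f"pruning ratio                {100 * self.pruning_ratio:.1f}%",
            f"best composite fitness       {self.best_fitness:.4f}",
            f"normalized fitness           {self.normalized_fitness:.4f}",
            f"retained indices             {self.mask.retained_indices.tolist()}",
        ]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Best/mean fitness per generation (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.trace_frame()
        ax.plot(frame["generation"], frame["best_fitness"], label="best (so far)")
        ax.plot(frame["generation"], frame["mean_fitness"], label="generation mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("composite fitness")
        ax.legend()
        return ax
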