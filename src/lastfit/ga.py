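"""Four-parent real-coded genetic algorithm.

The engine keeps a population of 4 parents and, each generation, builds 6
children: two *inside* children per parent pair (exploration between the
parents) and one *outside* child per pair pulled toward a search-space bound
(exploitation).  Selection is elitist within fixed pools, and mutation
accepts a proposal only when it improves fitness, so the best fitness is
non-increasing across generations.  The engine is generic over the objective:
the same machinery fits patch weights and calibrates camera geometry.

The spread factor is ``beta = sqrt(2*alpha)`` for ``alpha <= 0.5`` and
``sqrt(2*(1 - alpha))`` otherwise, with one alpha drawn per crossover event
and shared across all genes of the vector, so each child pair contracts or
expands uniformly.  (The branch orientation that keeps ``beta`` in (0, 1] —
children between their parents — is the default; the reversed orientation,
which always yields ``beta >= 1``, is available behind
``GAConfig.printed_beta_rule`` for fidelity experiments.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError


# ---------------------------------------------------------------------------
# search space


@dataclass
class SearchSpace:
    """Per-gene closed interval ``[lower, upper]``.

    Genes with ``lower == upper`` are *fixed*: they are sampled at their
    single value and excluded from mutation.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ConfigurationError("lower/upper bounds must be 1-D arrays of equal length")
        if self.lower.size == 0:
            raise ConfigurationError("empty search space")
        if np.any(self.lower > self.upper):
            raise ConfigurationError("lower bound exceeds upper bound for some gene")
        if not (np.all(np.isfinite(self.lower)) and np.all(np.isfinite(self.upper))):
            raise ConfigurationError("search-space bounds must be finite")

    @property
    def n_genes(self) -> int:
        return self.lower.size

    @property
    def fixed_mask(self) -> np.ndarray:
        return self.lower == self.upper

    @property
    def all_fixed(self) -> bool:
        return bool(np.all(self.fixed_mask))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Uniform draws from every gene interval; shape (n, n_genes)."""
        u = rng.uniform(size=(n, self.n_genes))
        return self.lower + u * (self.upper - self.lower)

    def clip(self, vectors: np.ndarray) -> np.ndarray:
        return np.clip(vectors, self.lower, self.upper)

    def contains(self, vectors: np.ndarray, atol: float = 1e-12) -> bool:
        v = np.asarray(vectors)
        return bool(np.all(v >= self.lower - atol) and np.all(v <= self.upper + atol))


# ---------------------------------------------------------------------------
# configuration / results


@dataclass
class GAConfig:
    """Run-control knobs for the engine.

    max_generations : hard cap on generations (>= 1).
    stall_tolerance / stall_window : stop when the best fitness has improved
        by less than ``stall_tolerance`` over the last ``stall_window``
        generations.
    clip_to_bounds : clip children that leave the search box to the violated
        bound (only possible under the reversed beta rule).
    printed_beta_rule : use the beta branch orientation that yields
        ``beta >= 1`` (see module docstring).
    per_gene_alpha : draw an independent alpha per gene instead of one per
        crossover event.
    """

    max_generations: int = 500
    stall_tolerance: float = 1e-6
    stall_window: int = 20
    clip_to_bounds: bool = True
    printed_beta_rule: bool = False
    per_gene_alpha: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be >= 1")
        if self.stall_window < 1:
            raise ConfigurationError("stall_window must be >= 1")

    def to_dict(self) -> dict:
        return {
            "max_generations": self.max_generations,
            "stall_tolerance": self.stall_tolerance,
            "stall_window": self.stall_window,
            "clip_to_bounds": self.clip_to_bounds,
            "printed_beta_rule": self.printed_beta_rule,
            "per_gene_alpha": self.per_gene_alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class GAResult:
    best_vector: np.ndarray
    best_fitness: float
    history: list[dict]
    n_generations: int
    n_evaluations: int
    crossover_acceptances: int
    mutation_acceptances: int
    clip_events: int
    stalled: bool


# ---------------------------------------------------------------------------
# operators


def draw_beta(alpha: float, printed_rule: bool = False) -> float:
    """Spread factor from a uniform draw ``alpha``.

    Default orientation: ``sqrt(2 alpha)`` for ``alpha <= 0.5`` else
    ``sqrt(2 (1 - alpha))`` — continuous, equal to 1 at ``alpha = 0.5`` and
    bounded by 1, so inside children stay between their parents.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    hi = alpha > 0.5
    if printed_rule:
        hi = not hi
    return math.sqrt(2.0 * (1.0 - alpha)) if hi else math.sqrt(2.0 * alpha)


def crossover_inside(p_a, p_b, beta):
    """Symmetric pair of children about the parent midpoint.

    Returns ``(0.5[(p_a+p_b) + beta|p_a-p_b|], 0.5[(p_a+p_b) - beta|p_a-p_b|])``.
    Works elementwise on gene vectors.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    s = p_a + p_b
    d = beta * np.abs(p_a - p_b)
    return 0.5 * (s + d), 0.5 * (s - d)


def crossover_toward_bound(parent, bound, beta):
    """Child on the segment from a search-space bound toward a parent.

    ``bound + beta * (parent - bound)``: beta = 0 lands on the bound,
    beta = 1 recovers the parent.  Elementwise on gene vectors.
    """
    parent = np.asarray(parent, dtype=float)
    bound = np.asarray(bound, dtype=float)
    return bound + beta * (parent - bound)


def back_solve_beta(p_a: float, p_b: float, child: float) -> float:
    """Invert the inside crossover on one (parent, parent, child) triple."""
    gap = abs(p_a - p_b)
    if gap == 0:
        raise ValueError("parents coincide; beta is unidentifiable")
    return abs(2.0 * child - (p_a + p_b)) / gap


def make_children(
    parents: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
    config: GAConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Six children from four parents.

    (C1, C2) explore between (P1, P2); (C4, C5) between (P4, P3); C3 exploits
    toward the lower bound from P1 and C6 toward the upper bound from P4.
    One alpha (hence one beta) is drawn per crossover event.  Children
    leaving the box are clipped to the violated bound; the clip count is
    returned for diagnostics.
    """
    config = config or GAConfig()
    parents = np.asarray(parents, dtype=float)
    if parents.shape != (4, space.n_genes):
        raise ConfigurationError(f"expected 4 parents of {space.n_genes} genes, got {parents.shape}")

    def _beta():
        size = space.n_genes if config.per_gene_alpha else None
        a = rng.uniform(size=size)
        if config.per_gene_alpha:
            return np.array([draw_beta(ai, config.printed_beta_rule) for ai in a])
        return draw_beta(float(a), config.printed_beta_rule)

    p1, p2, p3, p4 = parents
    c1, c2 = crossover_inside(p1, p2, _beta())
    c4, c5 = crossover_inside(p4, p3, _beta())
    c3 = crossover_toward_bound(p1, space.lower, _beta())
    c6 = crossover_toward_bound(p4, space.upper, _beta())
    children = np.stack([c1, c2, c3, c4, c5, c6])
    clipped = 0
    if config.clip_to_bounds:
        before = children.copy()
        children = space.clip(children)
        clipped = int(np.sum(np.any(before != children, axis=1)))
    return children, clipped


def select_parents(
    parents: np.ndarray,
    children: np.ndarray,
    parent_fitness: np.ndarray,
    child_fitness: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Elitist pool selection of the next four parents.

    P1' = best of {P1, P2}; P3' = best of {P3, P4}; P2' = best of
    {C1, C2, C3}; P4' = best of {C4, C5, C6}; ties go to the lowest index.
    Returns the new parents, their fitness, and the chosen labels.
    """
    pf = np.asarray(parent_fitness, dtype=float)
    cf = np.asarray(child_fitness, dtype=float)
    if pf.shape != (4,) or cf.shape != (6,):
        raise ValueError("need 4 parent and 6 child fitness values")
    if np.any(np.isnan(pf)) or np.any(np.isnan(cf)):
        raise ValueError("NaN fitness encountered")
    pools = [
        (parents[:2], pf[:2], ("P1", "P2")),
        (children[:3], cf[:3], ("C1", "C2", "C3")),
        (parents[2:], pf[2:], ("P3", "P4")),
        (children[3:], cf[3:], ("C4", "C5", "C6")),
    ]
    new_parents, new_fitness, labels = [], [], []
    for vecs, fits, names in pools:
        k = int(np.argmin(fits))  # argmin takes the first minimum: lowest index
        new_parents.append(vecs[k].copy())
        new_fitness.append(float(fits[k]))
        labels.append(names[k])
    # pool order above is P1', P2', P3', P4'
    return np.stack(new_parents), np.array(new_fitness), labels


def mutate(
    parents: np.ndarray,
    parent_fitness: np.ndarray,
    space: SearchSpace,
    objective,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Accept-if-improves mutation of the population.

    (a) A fresh random vector replaces the worst parent iff it improves that
    parent's fitness.  (b) One randomly chosen non-fixed gene of a randomly
    chosen parent is redrawn from its interval iff that improves the parent.
    Acceptance events are returned as run diagnostics.
    """
    parents = np.asarray(parents, dtype=float).copy()
    fitness = np.asarray(parent_fitness, dtype=float).copy()
    log = {"parent_mutation_accepted": False, "gene_mutation_accepted": False, "evaluations": 0}

    worst = int(np.argmax(fitness))
    proposal = space.sample(rng)[0]
    f_prop = float(objective(proposal))
    log["evaluations"] += 1
    if f_prop < fitness[worst]:
        parents[worst] = proposal
        fitness[worst] = f_prop
        log["parent_mutation_accepted"] = True

    free = np.flatnonzero(~space.fixed_mask)
    if free.size:
        pi = int(rng.integers(4))
        gi = int(free[rng.integers(free.size)])
        candidate = parents[pi].copy()
        candidate[gi] = rng.uniform(space.lower[gi], space.upper[gi])
        f_cand = float(objective(candidate))
        log["evaluations"] += 1
        if f_cand < fitness[pi]:
            parents[pi] = candidate
            fitness[pi] = f_cand
            log["gene_mutation_accepted"] = True
    return parents, fitness, log


# ---------------------------------------------------------------------------
# driver


def run_ga(
    objective,
    space: SearchSpace,
    config: GAConfig | None = None,
    init_parents: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> GAResult:
    """Iterate crossover -> fitness -> selection -> mutation until stall.

    ``objective`` maps a gene vector to a scalar score (lower is better).
    Fully reproducible from ``config.seed`` (or a supplied generator).
    Stops when the best fitness has improved by less than
    ``config.stall_tolerance`` over ``config.stall_window`` generations, or
    at ``config.max_generations``.
    """
    config = config or GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if init_parents is None:
        parents = space.sample(rng, 4)
    else:
        parents = np.asarray(init_parents, dtype=float).copy()
        if parents.shape != (4, space.n_genes):
            raise ConfigurationError("init_parents must have shape (4, n_genes)")
    fitness = np.array([float(objective(p)) for p in parents])
    n_eval = 4
    if not np.all(np.isfinite(fitness)):
        raise ConfigurationError("objective is non-finite on the initial population")

    best_idx = int(np.argmin(fitness))
    best_vec = parents[best_idx].copy()
    best_fit = float(fitness[best_idx])
    history: list[dict] = []
    cross_acc = mut_acc = clip_total = 0
    stalled = False
    gen = 0

    for gen in range(1, config.max_generations + 1):
        children, clipped = make_children(parents, space, rng, config)
        clip_total += clipped
        child_fitness = np.array([float(objective(c)) for c in children])
        n_eval += 6
        prev_p2, prev_p4 = fitness[1], fitness[3]
        parents, fitness, labels = select_parents(parents, children, fitness, child_fitness)
        # a crossover "acceptance": the child drawn into the population improves
        # the slot it fills
        cross_acc += int(fitness[1] < prev_p2) + int(fitness[3] < prev_p4)
        parents, fitness, mlog = mutate(parents, fitness, space, objective, rng)
        n_eval += mlog["evaluations"]
        mut_acc += int(mlog["parent_mutation_accepted"]) + int(mlog["gene_mutation_accepted"])

        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_fit = float(fitness[gen_best])
            best_vec = parents[gen_best].copy()
        history.append(
            {
                "generation": gen,
                "best_fitness": best_fit,
                "mean_fitness": float(np.mean(fitness)),
                "selected": ",".join(labels),
                "parent_mutation_accepted": mlog["parent_mutation_accepted"],
                "gene_mutation_accepted": mlog["gene_mutation_accepted"],
            }
        )
        if gen >= config.stall_window:
            ref = history[gen - config.stall_window]["best_fitness"]
            if ref - best_fit < config.stall_tolerance:
                stalled = True
                break
        if space.all_fixed:
            stalled = True
            break

    return GAResult(
        best_vector=best_vec,
        best_fitness=best_fit,
        history=history,
        n_generations=gen,
        n_evaluations=n_eval,
        crossover_acceptances=cross_acc,
        mutation_acceptances=mut_acc,
        clip_events=clip_total,
        stalled=stalled,
    )
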