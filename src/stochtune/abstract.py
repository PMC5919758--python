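"""Abstract fitness-directed stochastic tuning model.

Each gene carries a transcriptional activity E_i.  Cellular fitness is the
negative Euclidean distance between the activity vector and an optimal
vector.  At every step each gene takes a directed step of magnitude ``k``
whose sign is sgn(dF * dE_prev) — reinforcing whatever change preceded an
improvement in fitness, reversing one that preceded a decline — plus a noise
step of magnitude ``eta`` with an independent fair random sign.  The model
performs a gradient-descent-like search in expression space without any
explicit sensing of the environment.

A threshold-gated variant models a growth-limiting gene (URA3) whose
sub-threshold expression cannot influence fitness (a competitive inhibitor
soaks it up): below the threshold that gene receives only the noise term and
performs a pure random walk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import AbstractParams, ThresholdConfig

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractState",
    "AbstractTrajectory",
    "TimeToState",
    "fitness",
    "step_abstract",
    "simulate_abstract",
    "simulate_ura3_threshold",
    "time_to_state",
]


def fitness(E: np.ndarray, E_optimal: np.ndarray) -> float:
    """Negative Euclidean distance between activity vector and optimum.

    Always <= 0, with equality iff ``E == E_optimal``.
    """
    E = np.asarray(E, dtype=float)
    E_optimal = np.asarray(E_optimal, dtype=float)
    if E.shape != E_optimal.shape:
        raise ValueError(
            f"activity vector shape {E.shape} != optimum shape {E_optimal.shape}"
        )
    return -float(np.linalg.norm(E - E_optimal))


@dataclass
class AbstractState:
    """State advanced by the tuning rule.

    ``dE_prev`` holds the realized (post-clamp) per-gene change of the
    previous step; ``F_prev`` the fitness of the previous state.
    """

    E: np.ndarray
    dE_prev: np.ndarray
    F_prev: float
    t: int = 0

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.dE_prev = np.asarray(self.dE_prev, dtype=float)
        if self.E.shape != self.dE_prev.shape:
            raise ValueError("E and dE_prev must have equal length")


@dataclass
class AbstractTrajectory:
    """Recorded output of one simulation run."""

    fitness: np.ndarray  # fitness(E_t) for t = 0..n_steps_run
    activities: np.ndarray  # thinned activity matrix, shape (n_recorded, n_genes)
    recorded_steps: np.ndarray  # step index of each recorded activity row
    params: AbstractParams
    seed: int
    gene_series: dict[int, np.ndarray] = field(default_factory=dict)  # full series
    flags: list[str] = field(default_factory=list)

    @property
    def n_steps_run(self) -> int:
        return len(self.fitness) - 1


@dataclass(frozen=True)
class TimeToState:
    """First-passage result; ``step`` is None when censored at ``horizon``."""

    step: int | None
    censored: bool
    horizon: int


def step_abstract(
    state: AbstractState,
    E_optimal: np.ndarray,
    params: AbstractParams,
    rng: np.random.Generator,
    tuning_active: np.ndarray | None = None,
) -> AbstractState:
    """Advance the state by one step of the tuning rule.

    dE_i = k * sgn(dF * dE_prev_i) + s_i * eta, with s_i an independent fair
    sign and dF the fitness change between the two preceding states
    (fitness is evaluated on the pre-update state).  Genes where
    ``tuning_active`` is False receive only the noise term.  Activities are
    clamped at ``params.clamp_min`` and the realized change is stored.
    """
    F_cur = fitness(state.E, E_optimal)
    dF = F_cur - state.F_prev
    n = state.E.shape[0]
    signs = rng.integers(0, 2, n) * 2 - 1
    dE = params.k * np.sign(dF * state.dE_prev) + signs * params.eta
    if tuning_active is not None:
        dE = np.where(tuning_active, dE, signs * params.eta)
    E_new = np.maximum(state.E + dE, params.clamp_min)
    return AbstractState(E_new, E_new - state.E, F_cur, state.t + 1)


def _resolve_init(params: AbstractParams, E_init, rng: np.random.Generator) -> np.ndarray:
    if isinstance(E_init, str):
        if E_init != "random":
            raise ValueError(f"E_init must be an array or 'random', got {E_init!r}")
        return rng.uniform(params.init_low, params.init_high, params.n_genes)
    E0 = np.asarray(E_init, dtype=float).copy()
    if E0.shape != (params.n_genes,):
        raise ValueError(f"E_init shape {E0.shape} != ({params.n_genes},)")
    return E0


def _run(
    params: AbstractParams,
    E_optimal: np.ndarray,
    E_init,
    *,
    thin: int = 1,
    track_genes: tuple[int, ...] = (),
    threshold_gene: int | None = None,
    threshold: float = 0.0,
    stop_gene: int | None = None,
    stop_level: float = 0.0,
    flags: list[str] | None = None,
) -> AbstractTrajectory:
    E_optimal = np.asarray(E_optimal, dtype=float)
    if E_optimal.shape != (params.n_genes,):
        raise ValueError(f"E_optimal shape {E_optimal.shape} != ({params.n_genes},)")
    if not np.all(np.isfinite(E_optimal)):
        raise ValueError("E_optimal contains non-finite entries")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = np.random.default_rng(params.seed)
    E0 = _resolve_init(params, E_init, rng)
    state = AbstractState(E0, np.zeros(params.n_genes), fitness(E0, E_optimal), 0)

    fit_series = np.empty(params.n_steps + 1)
    fit_series[0] = state.F_prev  # fitness(E_0)
    rec_steps = [0]
    rec_rows = [E0.copy()]
    tracked = {g: np.empty(params.n_steps + 1) for g in track_genes}
    for g in tracked:
        tracked[g][0] = E0[g]

    mask = None
    if threshold_gene is not None:
        mask = np.ones(params.n_genes, dtype=bool)

    n_run = params.n_steps
    for t in range(1, params.n_steps + 1):
        if mask is not None:
            mask[threshold_gene] = state.E[threshold_gene] >= threshold
        state = step_abstract(state, E_optimal, params, rng, tuning_active=mask)
        fit_series[t] = fitness(state.E, E_optimal)
        for g in tracked:
            tracked[g][t] = state.E[g]
        if t % thin == 0 or t == params.n_steps:
            rec_steps.append(t)
            rec_rows.append(state.E.copy())
        if stop_gene is not None and state.E[stop_gene] > stop_level:
            n_run = t
            if rec_steps[-1] != t:
                rec_steps.append(t)
                rec_rows.append(state.E.copy())
            break

    return AbstractTrajectory(
        fitness=fit_series[: n_run + 1],
        activities=np.asarray(rec_rows),
        recorded_steps=np.asarray(rec_steps),
        params=params,
        seed=params.seed,
        gene_series={g: s[: n_run + 1] for g, s in tracked.items()},
        flags=flags or [],
    )


def simulate_abstract(
    params: AbstractParams,
    E_optimal: np.ndarray,
    E_init="random",
    *,
    thin: int = 1,
    track_genes: tuple[int, ...] = (),
) -> AbstractTrajectory:
    """Simulate the tuning model; reproducible given ``params.seed``.

    ``E_init`` may be an explicit vector or ``"random"`` for a uniform draw
    on [init_low, init_high).
    """
    return _run(params, E_optimal, E_init, thin=thin, track_genes=track_genes)


def simulate_ura3_threshold(
    config: ThresholdConfig,
    E_optimal: np.ndarray | None = None,
    *,
    thin: int = 1,
    stop_above: float | None = None,
) -> AbstractTrajectory:
    """Simulate the threshold-gated variant.

    All genes but the one at ``ura3_index`` start at their optimal values;
    that gene starts at ``ura3_init`` with optimum ``ura3_optimal`` and
    receives only the noise term while its activity is below
    ``config.threshold``.  The gene's full activity series is recorded under
    ``trajectory.gene_series[ura3_index]``.  ``stop_above`` optionally ends
    the run at the first step where the gated gene exceeds that level (the
    first-passage time is all later analyses consume).
    """
    rng_init = np.random.default_rng(config.seed + 1_000_003)
    if E_optimal is None:
        E_optimal = rng_init.uniform(config.init_low, config.init_high, config.n_genes)
        E_optimal = E_optimal.copy()
        E_optimal[config.ura3_index] = config.ura3_optimal
    else:
        E_optimal = np.asarray(E_optimal, dtype=float)
    flags: list[str] = []
    if config.threshold > config.ura3_optimal:
        msg = (
            f"threshold ({config.threshold}) exceeds ura3_optimal "
            f"({config.ura3_optimal}): tuning can never engage (saturating inhibitor)"
        )
        logger.warning(msg)
        flags.append(msg)
    E_init = E_optimal.copy()
    E_init[config.ura3_index] = config.ura3_init
    return _run(
        config,
        E_optimal,
        E_init,
        thin=thin,
        track_genes=(config.ura3_index,),
        threshold_gene=config.ura3_index,
        threshold=config.threshold,
        stop_gene=config.ura3_index if stop_above is not None else None,
        stop_level=stop_above if stop_above is not None else 0.0,
        flags=flags,
    )


def time_to_state(
    trajectory: AbstractTrajectory, gene: int, level: float
) -> TimeToState:
    """First step index at which the gene's activity exceeds ``level``.

    Censored (``step=None``) when the level is never exceeded within the
    recorded trajectory.
    """
    if gene in trajectory.gene_series:
        series = trajectory.gene_series[gene]
    elif np.array_equal(
        trajectory.recorded_steps, np.arange(len(trajectory.fitness))
    ):
        series = trajectory.activities[:, gene]
    else:
        raise ValueError(
            f"gene {gene} was not tracked and activities are thinned; "
            "re-run with track_genes or thin=1"
        )
    above = np.nonzero(series > level)[0]
    horizon = len(series) - 1
    if len(above) == 0:
        return TimeToState(None, True, horizon)
    return TimeToState(int(above[0]), False, horizon)
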