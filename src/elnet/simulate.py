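"""The evolving-lattice (EL) simulation loop, its control model, and logging.

One trial holds a population of ``N = 2**n`` bit-string individuals adapting
toward a fixed random target.  Every time step, synchronously for all
individuals:

1. a hidden digit ``k`` of the target is drawn (shared by everyone);
2. each individual computes its local fitness word (agreement with the target,
   hidden digit guessed);
3. *EL model*: the set of fitness words is closed into a lattice, a principal
   ideal is drawn, and each fitness word is replaced by the join of its class
   under the smallest congruence collapsing that ideal — a global,
   systematically optimistic re-estimate;
   *control model*: no lattice; instead each 1-digit of the local fitness is
   independently degraded to 0 with an error probability derived from μ;
4. every individual keeps the digits whose (re-estimated) fitness bit is 1 and
   randomizes the rest.

All randomness comes from one seeded generator per trial, consumed in a fixed
order (hidden position → hidden-digit guesses → ideal draw → state-update
words), so a run is bit-reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .bitstate import (
    Population,
    from_string,
    local_fitness_many,
    to_string,
    update_states_many,
)
from .lattice import Lattice

__all__ = [
    "SimulationConfig",
    "TransitionRecord",
    "TransitionLog",
    "el_step",
    "control_fitness",
    "control_fitness_many",
    "run_simulation",
]

_MODELS = ("el", "control")
_LATTICE_MODES = ("generated", "full-boolean")
_IDEAL_RULES = ("uniform-L", "uniform-B")
_CONTROL_FLIPS = ("mu", "one-minus-mu")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, serializable description of one trial.

    Parameters
    ----------
    n : bit length; the population size is ``2**n``.
    steps : number of synchronous time steps to run.
    burn_in : steps discarded before any network window is measured.
    model : ``"el"`` (quotient-lattice re-estimation) or ``"control"``
        (μ-degraded local fitness, no lattice).
    mu : control-model error parameter in [0, 1]; ignored by the EL model.
    seed : RNG seed for the trial.
    target : explicit target word (int) or ``"random"``.
    lattice_mode : ``"generated"`` — close the step's fitness set under
        join/meet (default) — or ``"full-boolean"`` — use all of {0,1}^n.
    ideal_rule : how the ideal generator is drawn each step: uniformly over
        the lattice (default) or uniformly over the step's fitness set.
    control_flip : direction of μ: ``"mu"`` (default) degrades each fitness
        1-digit with probability μ, so error grows with μ; ``"one-minus-mu"``
        is the opposite convention, kept selectable for sensitivity checks.
    control_hidden : whether the control reuses the hidden-digit fitness
        before degradation (default) or the fully observed agreement word.
    """

    n: int
    steps: int
    seed: int
    burn_in: int = 200
    model: str = "el"
    mu: float = 0.0
    target: int | str = "random"
    lattice_mode: str = "generated"
    ideal_rule: str = "uniform-L"
    control_flip: str = "mu"
    control_hidden: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("bit length n must be >= 2")
        if not 0 <= self.burn_in < self.steps:
            raise ValueError("need steps > burn_in >= 0")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.lattice_mode not in _LATTICE_MODES:
            raise ValueError(f"lattice_mode must be one of {_LATTICE_MODES}")
        if self.ideal_rule not in _IDEAL_RULES:
            raise ValueError(f"ideal_rule must be one of {_IDEAL_RULES}")
        if self.control_flip not in _CONTROL_FLIPS:
            raise ValueError(f"control_flip must be one of {_CONTROL_FLIPS}")
        if self.target != "random":
            if not isinstance(self.target, int) or not 0 <= self.target < (1 << self.n):
                raise ValueError("target must be 'random' or an n-bit integer")

    @property
    def population_size(self) -> int:
        return 1 << self.n

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass(frozen=True)
class TransitionRecord:
    """One individual's state transition at one time step."""

    t: int
    individual: int
    from_state: int
    to_state: int


class TransitionLog:
    """Time-ordered record of every individual's transition in a trial.

    Stored compactly as the matrix of states: ``states[t, i]`` is individual
    ``i``'s state *before* step ``t`` (shape ``(steps + 1, N)``), so step ``t``
    contributes the N records ``states[t, i] -> states[t + 1, i]``.
    """

    def __init__(self, states: np.ndarray, n: int,
                 config: SimulationConfig | None = None,
                 target: int | None = None):
        states = np.asarray(states, dtype=np.int64)
        if states.ndim != 2 or states.shape[0] < 2:
            raise ValueError("states must be a (steps+1, N) matrix")
        self.states = states
        self.n = n
        self.config = config
        self.target = target

    @property
    def steps(self) -> int:
        return self.states.shape[0] - 1

    @property
    def population_size(self) -> int:
        return self.states.shape[1]

    @property
    def n_records(self) -> int:
        return self.steps * self.population_size

    def records(self) -> Iterator[TransitionRecord]:
        for t in range(self.steps):
            frm = self.states[t]
            to = self.states[t + 1]
            for i in range(self.population_size):
                yield TransitionRecord(t, i, int(frm[i]), int(to[i]))

    def pair_codes(self, t1: int, t2: int) -> np.ndarray:
        """Flat transition codes ``from * 2**n + to`` for steps t1 <= t < t2."""
        if not 0 <= t1 <= t2 <= self.steps:
            raise ValueError(
                f"window [{t1}, {t2}) outside log range [0, {self.steps}]"
            )
        frm = self.states[t1:t2].ravel()
        to = self.states[t1 + 1:t2 + 1].ravel()
        return frm << self.n | to

    # -- I/O ----------------------------------------------------------------
    def write_tsv(self, path) -> None:
        """Write records as TSV (t, individual, from, to), gzip by extension."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("t\tindividual\tfrom\tto\n")
            for t in range(self.steps):
                frm = self.states[t]
                to = self.states[t + 1]
                for i in range(self.population_size):
                    fh.write(
                        f"{t}\t{i}\t{to_string(int(frm[i]), self.n)}"
                        f"\t{to_string(int(to[i]), self.n)}\n"
                    )

    @classmethod
    def read_tsv(cls, path) -> "TransitionLog":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["t", "individual", "from", "to"]:
                raise ValueError(f"unrecognized transition log header: {header}")
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        if not rows:
            raise ValueError("empty transition log")
        n = len(rows[0][2])
        ts = np.array([int(r[0]) for r in rows])
        inds = np.array([int(r[1]) for r in rows])
        frm = np.array([from_string(r[2], n) for r in rows], dtype=np.int64)
        to = np.array([from_string(r[3], n) for r in rows], dtype=np.int64)
        steps = int(ts.max()) + 1
        N = int(inds.max()) + 1
        if len(rows) != steps * N:
            raise ValueError("transition log is not complete (steps x N records)")
        states = np.empty((steps + 1, N), dtype=np.int64)
        states[ts, inds] = frm
        last = ts == steps - 1
        states[steps, inds[last]] = to[last]
        # consistency: each step's destinations must equal the next step's sources
        chk = np.empty_like(states)
        chk[ts + 1, inds] = to
        if not np.array_equal(chk[1:], states[1:]):
            raise ValueError("inconsistent transition log: from/to chains disagree")
        return cls(states, n)

    def write_manifest(self, path) -> None:
        """JSON manifest with the full config needed to regenerate the log."""
        meta = {
            "format": "elnet-transition-log",
            "n": self.n,
            "steps": self.steps,
            "population_size": self.population_size,
            "target": None if self.target is None else to_string(self.target, self.n),
            "config": None if self.config is None else self.config.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# stepping


def _draw_target_and_population(config: SimulationConfig,
                                rng: np.random.Generator) -> tuple[np.ndarray, int]:
    states = rng.integers(0, 1 << config.n, size=config.population_size,
                          dtype=np.int64)
    if config.target == "random":
        target = int(rng.integers(0, 1 << config.n))
    else:
        target = int(config.target)
    return states, target


def _el_step_states(states: np.ndarray, target: int, n: int,
                    rng: np.random.Generator, lattice_mode: str,
                    ideal_rule: str) -> np.ndarray:
    k = int(rng.integers(1, n + 1))
    fitness = local_fitness_many(states, target, k, rng, n)
    if lattice_mode == "full-boolean":
        # classes of θ(↓x) in the Boolean lattice are fibers of b ∨ x, and the
        # join of the fiber of key b|x is the key itself
        x = int(rng.integers(0, 1 << n))
        global_fit = fitness | x
    else:
        lat = Lattice.generate(np.unique(fitness), n)
        if ideal_rule == "uniform-B":
            pool = np.unique(fitness)
        else:
            pool = lat.elements
        x = int(pool[int(rng.integers(pool.size))])
        lut = lat.class_top_table(x)
        global_fit = lut[fitness]
    return update_states_many(states, global_fit, rng, n)


def control_fitness(state: int, target: int, k: int, mu: float,
                    rng: np.random.Generator, n: int, *,
                    flip: str = "mu", hidden: bool = True) -> int:
    """Control-model fitness for one individual: local fitness, then erosion.

    Each 1-digit of the local fitness word is independently flipped to 0 with
    probability μ (``flip="mu"``, the default, under which the error rate
    grows with μ) or 1 − μ (``flip="one-minus-mu"``).
    """
    out = control_fitness_many(np.array([state]), target, k, mu, rng, n,
                               flip=flip, hidden=hidden)
    return int(out[0])


def control_fitness_many(states: np.ndarray, target: int, k: int, mu: float,
                         rng: np.random.Generator, n: int, *,
                         flip: str = "mu", hidden: bool = True) -> np.ndarray:
    if flip not in _CONTROL_FLIPS:
        raise ValueError(f"flip must be one of {_CONTROL_FLIPS}")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    states = np.asarray(states, dtype=np.int64)
    if hidden:
        fitness = local_fitness_many(states, target, k, rng, n)
    else:
        mask = (1 << n) - 1
        fitness = ~(states ^ target) & mask
    p = mu if flip == "mu" else 1.0 - mu
    u = rng.random(size=(states.size, n))
    weights = np.int64(1) << np.arange(n, dtype=np.int64)
    flips = ((u < p) * weights).sum(axis=1).reshape(states.shape)
    return fitness & ~flips


def _control_step_states(states: np.ndarray, target: int, n: int, mu: float,
                         rng: np.random.Generator, flip: str,
                         hidden: bool) -> np.ndarray:
    k = int(rng.integers(1, n + 1))
    fitness = control_fitness_many(states, target, k, mu, rng, n,
                                   flip=flip, hidden=hidden)
    return update_states_many(states, fitness, rng, n)


def el_step(pop: Population, target: int, rng: np.random.Generator, *,
            lattice_mode: str = "generated",
            ideal_rule: str = "uniform-L") -> tuple[Population, np.ndarray]:
    """One synchronous EL step; returns the next population and the N
    transition records as an ``(N, 2)`` array of (from, to) states."""
    new = _el_step_states(pop.members, target, pop.n, rng, lattice_mode,
                          ideal_rule)
    records = np.stack([pop.members, new], axis=1)
    return Population(new, pop.n, pop.generation + 1), records


def run_simulation(config: SimulationConfig) -> TransitionLog:
    """Run one seeded trial and return its complete transition log.

    Identical config (including seed) gives a byte-identical log.
    """
    rng = np.random.default_rng(config.seed)
    states, target = _draw_target_and_population(config, rng)
    n = config.n
    all_states = np.empty((config.steps + 1, states.size), dtype=np.int64)
    all_states[0] = states
    for t in range(config.steps):
        if config.model == "el":
            states = _el_step_states(states, target, n, rng,
                                     config.lattice_mode, config.ideal_rule)
        else:
            states = _control_step_states(states, target, n, config.mu, rng,
                                          config.control_flip,
                                          config.control_hidden)
        all_states[t + 1] = states
    return TransitionLog(all_states, n, config=config, target=target)
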