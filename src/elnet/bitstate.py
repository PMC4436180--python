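"""Bit-string states, hidden-digit local fitness, and the synchronous update rule.

An individual's state, the environmental target, and a fitness estimate are all
``n``-bit binary words.  Internally a word is an unsigned integer of declared
width ``n``; digit ``j`` of the model (1-based, written left to right as
``s_1 s_2 ... s_n``) lives at integer bit position ``j - 1``, i.e. ``s_1`` is
the least-significant bit.  Logs and fixtures serialize words as fixed-width
binary text with ``s_1`` first (so the text reads in model digit order and is
endianness-free).

The local fitness of a state against the target is a per-digit agreement
indicator: digit ``j`` of the fitness word is 1 when ``s_j == t_j``, except at
one *hidden* position ``k`` (the digit of the environment that cannot be
observed this step) where the bit is guessed uniformly at random.  More 1s
means higher fitness; the all-ones word is a fixed point of the update rule,
which keeps every digit whose fitness bit is 1 and randomizes the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Population",
    "from_string",
    "to_string",
    "hamming_distance",
    "local_fitness",
    "local_fitness_many",
    "update_state",
    "update_states_many",
]


def _check_word(x: int, n: int, name: str = "word") -> None:
    if not 0 <= int(x) < (1 << n):
        raise ValueError(f"{name} {x!r} does not fit in {n} bits")


def to_string(x: int, n: int) -> str:
    """Serialize a word as fixed-width binary text, model digit ``s_1`` first."""
    _check_word(x, n)
    return "".join("1" if (x >> j) & 1 else "0" for j in range(n))


def from_string(s: str, n: int | None = None) -> int:
    """Parse fixed-width binary text (digit ``s_1`` first) into a word."""
    if n is not None and len(s) != n:
        raise ValueError(f"expected {n} digits, got {len(s)}")
    if not s or set(s) - {"0", "1"}:
        raise ValueError(f"not a binary string: {s!r}")
    return sum(1 << j for j, c in enumerate(s) if c == "1")


def hamming_distance(a: int, b: int, n: int | None = None) -> int:
    """Number of differing digits between two equal-width words."""
    if n is not None:
        _check_word(a, n, "a")
        _check_word(b, n, "b")
    return int(a ^ b).bit_count()


@dataclass
class Population:
    """A fixed multiset of ``N = 2**n`` individual states at one time step.

    Individuals are distinguishable even when their bit patterns coincide;
    ``members[i]`` is the state of individual ``i``.  The population size is
    the conserved resource of the model and never changes.
    """

    members: np.ndarray
    n: int
    generation: int = 0

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if self.members.ndim != 1:
            raise ValueError("members must be a 1-D array of states")
        if len(self.members) != 1 << self.n:
            raise ValueError(
                f"population must hold exactly 2**n = {1 << self.n} individuals"
            )
        if self.members.min(initial=0) < 0 or self.members.max(initial=0) >= 1 << self.n:
            raise ValueError(f"states must fit in {self.n} bits")

    @property
    def size(self) -> int:
        return len(self.members)

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "Population":
        states = rng.integers(0, 1 << n, size=1 << n, dtype=np.int64)
        return cls(members=states, n=n, generation=0)


def local_fitness(state: int, target: int, k: int, rng: np.random.Generator,
                  n: int) -> int:
    """Hidden-digit local fitness of one state against the target.

    Digit ``j != k`` of the result is 1 iff ``s_j == t_j``; digit ``k`` (the
    hidden position, 1-based) is drawn uniformly from {0, 1}.
    """
    _check_word(state, n, "state")
    _check_word(target, n, "target")
    if not 1 <= k <= n:
        raise ValueError(f"hidden digit k={k} out of range 1..{n}")
    mask = (1 << n) - 1
    agree = ~(state ^ target) & mask
    kbit = 1 << (k - 1)
    hidden = int(rng.integers(0, 2))
    return (agree & ~kbit) | (kbit if hidden else 0)


def local_fitness_many(states: np.ndarray, target: int, k: int,
                       rng: np.random.Generator, n: int) -> np.ndarray:
    """Vectorized :func:`local_fitness` with one hidden-bit draw per individual.

    The hidden position ``k`` is shared (it is a property of the environment);
    the guess at that position is independent per individual.  Consumes
    ``len(states)`` hidden-bit draws from ``rng`` in individual order.
    """
    if not 1 <= k <= n:
        raise ValueError(f"hidden digit k={k} out of range 1..{n}")
    states = np.asarray(states, dtype=np.int64)
    mask = (1 << n) - 1
    agree = ~(states ^ target) & mask
    kbit = 1 << (k - 1)
    hidden = rng.integers(0, 2, size=states.shape, dtype=np.int64)
    return (agree & ~kbit) | (hidden * kbit)


def update_state(state: int, fitness: int, rng: np.random.Generator,
                 n: int) -> int:
    """Synchronous update of one state: keep 1-fitness digits, randomize 0s.

    Draws one full-width random word so the number of random draws does not
    depend on the fitness pattern (reproducibility of the stream).
    """
    _check_word(state, n, "state")
    _check_word(fitness, n, "fitness")
    mask = (1 << n) - 1
    r = int(rng.integers(0, 1 << n))
    return (state & fitness) | (r & ~fitness & mask)


def update_states_many(states: np.ndarray, fitnesses: np.ndarray,
                       rng: np.random.Generator, n: int) -> np.ndarray:
    """Vectorized :func:`update_state`; one word-sized draw per individual."""
    states = np.asarray(states, dtype=np.int64)
    fitnesses = np.asarray(fitnesses, dtype=np.int64)
    if states.shape != fitnesses.shape:
        raise ValueError("states and fitnesses must align")
    mask = (1 << n) - 1
    r = rng.integers(0, 1 << n, size=states.shape, dtype=np.int64)
    return (states & fitnesses) | (r & ~fitnesses & mask)
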