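"""Finite lattice algebra over n-bit words: closure, ideals, congruences.

The set of n-bit words ordered componentwise (``a <= b`` iff ``a_i <= b_i``
for every digit) is a distributive lattice with join = bitwise OR and meet =
bitwise AND.  Each simulation step builds the sublattice generated by the
population's fitness words, picks a principal ideal ``J = ↓x``, and collapses
the lattice by the smallest congruence θ(J) identifying all of ``J``.  The
global fitness re-estimate replaces each fitness word by the largest element
of its congruence class — always an overestimate, never an underestimate.

For a principal ideal of a distributive lattice the congruence has a closed
form: ``a ≡ b  ⟺  a ∨ x = b ∨ x``.  That O(|L|) rule is what the simulator
uses; the test suite checks it against a brute-force smallest-congruence
closure on small lattices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "join",
    "meet",
    "leq",
    "Lattice",
    "Ideal",
    "CongruencePartition",
    "generate_lattice",
    "principal_ideal",
    "congruence_classes",
    "global_fitness",
]


def join(a: int, b: int) -> int:
    """Least upper bound of two words: bitwise OR."""
    return int(a) | int(b)


def meet(a: int, b: int) -> int:
    """Greatest lower bound of two words: bitwise AND."""
    return int(a) & int(b)


def leq(a: int, b: int) -> bool:
    """Componentwise order: every 1-digit of ``a`` is a 1-digit of ``b``."""
    return (int(a) & ~int(b)) == 0


@dataclass(frozen=True)
class Ideal:
    """A principal down-set ``↓generator`` within a lattice."""

    generator: int
    members: frozenset[int]

    def __contains__(self, x: int) -> bool:
        return x in self.members

    def __len__(self) -> int:
        return len(self.members)


class CongruencePartition:
    """Partition of a lattice into congruence classes, with class joins.

    ``class_top[x]`` is the join of the class containing ``x`` — the value a
    fitness word is replaced by under global (quotient-lattice) estimation.
    """

    def __init__(self, classes: list[frozenset[int]]):
        self.classes = classes
        self.class_top: dict[int, int] = {}
        self._class_of: dict[int, int] = {}
        for idx, block in enumerate(classes):
            top = 0
            for y in block:
                top |= y
            for y in block:
                self.class_top[y] = top
                self._class_of[y] = idx

    def block_of(self, x: int) -> frozenset[int]:
        try:
            return self.classes[self._class_of[x]]
        except KeyError:
            raise ValueError(f"{x} is not a lattice element") from None

    def __len__(self) -> int:
        return len(self.classes)


class Lattice:
    """A finite set of n-bit words closed under bitwise OR and AND."""

    def __init__(self, elements: Iterable[int], n: int):
        arr = np.unique(np.asarray(list(elements), dtype=np.int64))
        if arr.size == 0:
            raise ValueError("a lattice needs at least one element")
        if arr[0] < 0 or arr[-1] >= (1 << n):
            raise ValueError(f"elements must fit in {n} bits")
        self.n = n
        self.elements = arr
        self._members = frozenset(int(x) for x in arr)
        if not self._is_closed():
            raise ValueError("element set is not closed under join/meet")

    def _is_closed(self) -> bool:
        a = self.elements[:, None]
        b = self.elements[None, :]
        got = np.union1d(np.unique(a | b), np.unique(a & b))
        return bool(np.isin(got, self.elements).all())

    # -- basic structure ---------------------------------------------------
    @property
    def top(self) -> int:
        return int(np.bitwise_or.reduce(self.elements))

    @property
    def bottom(self) -> int:
        return int(np.bitwise_and.reduce(self.elements))

    def __contains__(self, x: int) -> bool:
        return int(x) in self._members

    def __len__(self) -> int:
        return int(self.elements.size)

    def __iter__(self) -> Iterator[int]:
        return (int(x) for x in self.elements)

    # -- construction ------------------------------------------------------
    @classmethod
    def generate(cls, generators: Iterable[int], n: int) -> "Lattice":
        """Smallest lattice containing ``generators``: OR/AND closure to fixpoint."""
        current = np.unique(np.asarray(list(generators), dtype=np.int64))
        if current.size == 0:
            raise ValueError("cannot generate a lattice from an empty set")
        if current[0] < 0 or current[-1] >= (1 << n):
            raise ValueError(f"generators must fit in {n} bits")
        while True:
            a = current[:, None]
            b = current[None, :]
            nxt = np.union1d(np.unique(a | b), np.unique(a & b))
            if nxt.size == current.size:
                break
            current = nxt
        return cls(current, n)

    @classmethod
    def boolean(cls, n: int) -> "Lattice":
        """The full Boolean lattice {0,1}^n."""
        return cls(np.arange(1 << n, dtype=np.int64), n)

    # -- ideals and congruences --------------------------------------------
    def principal_ideal(self, x: int) -> Ideal:
        """The down-set ``↓x = {y in L : y <= x}``; requires ``x`` in L."""
        if x not in self:
            raise ValueError(f"{x} is not an element of the lattice")
        members = self.elements[(self.elements & ~np.int64(x)) == 0]
        return Ideal(generator=int(x), members=frozenset(int(y) for y in members))

    def congruence(self, ideal: Ideal) -> CongruencePartition:
        """Smallest congruence collapsing ``ideal`` (classes via ``a ∨ x``)."""
        if ideal.generator not in self:
            raise ValueError("ideal generator is not a lattice element")
        expected = self.principal_ideal(ideal.generator)
        if ideal.members != expected.members:
            raise ValueError("ideal is not a down-closed principal ideal of this lattice")
        keys = self.elements | np.int64(ideal.generator)
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        sorted_els = self.elements[order]
        starts = np.flatnonzero(np.r_[True, sorted_keys[1:] != sorted_keys[:-1]])
        blocks = [
            frozenset(int(y) for y in part)
            for part in np.split(sorted_els, starts[1:])
        ]
        return CongruencePartition(blocks)

    def class_top_table(self, generator: int) -> np.ndarray:
        """Fast path for the simulator: table mapping element -> class join.

        Returns an array ``lut`` of length ``2**n`` with ``lut[e]`` = join of
        the θ(↓generator)-class of ``e`` for every lattice element ``e``
        (other slots are -1).  Equivalent to building the full
        :class:`CongruencePartition`, without per-class Python sets.
        """
        keys = self.elements | np.int64(generator)
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        sorted_els = self.elements[order]
        starts = np.flatnonzero(np.r_[True, sorted_keys[1:] != sorted_keys[:-1]])
        tops = np.bitwise_or.reduceat(sorted_els, starts)
        lut = np.full(1 << self.n, -1, dtype=np.int64)
        lut[sorted_els] = np.repeat(tops, np.diff(np.r_[starts, sorted_els.size]))
        return lut

    # -- export ------------------------------------------------------------
    def hasse_edges(self) -> list[tuple[int, int]]:
        """Covering pairs (child, parent) of the Hasse diagram."""
        els = [int(x) for x in self.elements]
        edges = []
        for a in els:
            for b in els:
                if a != b and leq(a, b):
                    if not any(c != a and c != b and leq(a, c) and leq(c, b)
                               for c in els):
                        edges.append((a, b))
        return edges

    def write_hasse_tsv(self, path) -> None:
        from .bitstate import to_string

        with open(path, "w") as fh:
            fh.write("child\tparent\n")
            for a, b in self.hasse_edges():
                fh.write(f"{to_string(a, self.n)}\t{to_string(b, self.n)}\n")


def generate_lattice(generators: Iterable[int], n: int) -> Lattice:
    """Join/meet closure of a non-empty generator set (see :meth:`Lattice.generate`)."""
    return Lattice.generate(generators, n)


def principal_ideal(lattice: Lattice, x: int) -> Ideal:
    return lattice.principal_ideal(x)


def congruence_classes(lattice: Lattice, ideal: Ideal) -> CongruencePartition:
    return lattice.congruence(ideal)


def global_fitness(b: int, partition: CongruencePartition) -> int:
    """Quotient-lattice fitness re-estimate: the join of ``b``'s class.

    The result dominates ``b`` componentwise and is idempotent.
    """
    try:
        return partition.class_top[int(b)]
    except KeyError:
        raise ValueError(f"{b} is not an element of the partitioned lattice") from None
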