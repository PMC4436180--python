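"""Aggregate transition logs into weighted directed networks over time windows.

Nodes are the states observed within a window; a directed edge (including
self-loops) carries the integer count of individual transitions it received.
Because every one of the N individuals transitions every step, the total edge
weight of a window of length ``w`` is exactly ``w * N`` — the conserved
resource the model redistributes.
"""

from __future__ import annotations

import gzip
from typing import Iterator

import numpy as np

from .bitstate import from_string, to_string
from .simulate import TransitionLog

__all__ = ["TransitionNetwork", "build_network", "sliding_windows"]


class TransitionNetwork:
    """Weighted directed multigraph-as-counts over one time window.

    Edges are stored as parallel arrays (``src``, ``dst``, ``weight``); use
    :meth:`edge_dict` or :meth:`to_networkx` for mapping-style access.
    """

    def __init__(self, src: np.ndarray, dst: np.ndarray, weight: np.ndarray,
                 n: int, window: tuple[int, int]):
        self.src = np.asarray(src, dtype=np.int64)
        self.dst = np.asarray(dst, dtype=np.int64)
        self.weight = np.asarray(weight, dtype=np.int64)
        if not (self.src.shape == self.dst.shape == self.weight.shape):
            raise ValueError("src, dst, weight must align")
        if (self.weight <= 0).any():
            raise ValueError("edge weights must be positive counts")
        self.n = n
        self.window = (int(window[0]), int(window[1]))

    @classmethod
    def from_codes(cls, codes: np.ndarray, counts: np.ndarray, n: int,
                   window: tuple[int, int]) -> "TransitionNetwork":
        codes = np.asarray(codes, dtype=np.int64)
        return cls(codes >> n, codes & ((1 << n) - 1),
                   np.asarray(counts), n, window)

    # -- structure ----------------------------------------------------------
    @property
    def nodes(self) -> np.ndarray:
        return np.union1d(self.src, self.dst)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.size)

    @property
    def n_edges(self) -> int:
        return int(self.src.size)

    @property
    def total_weight(self) -> int:
        return int(self.weight.sum())

    def edge_dict(self) -> dict[tuple[int, int], int]:
        return {(int(u), int(v)): int(w)
                for u, v, w in zip(self.src, self.dst, self.weight)}

    def weight_of(self, u: int, v: int) -> int:
        hit = (self.src == u) & (self.dst == v)
        return int(self.weight[hit].sum())

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(int(x) for x in self.nodes)
        for u, v, w in zip(self.src, self.dst, self.weight):
            g.add_edge(int(u), int(v), weight=int(w))
        return g

    # -- I/O ------------------------------------------------------------------
    def write_edge_tsv(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("from\tto\tweight\n")
            for u, v, w in zip(self.src, self.dst, self.weight):
                fh.write(f"{to_string(int(u), self.n)}\t"
                         f"{to_string(int(v), self.n)}\t{int(w)}\n")

    @classmethod
    def read_edge_tsv(cls, path, window: tuple[int, int] = (0, 0)) -> "TransitionNetwork":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["from", "to", "weight"]:
                raise ValueError(f"unrecognized edge list header: {header}")
            rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
        if not rows:
            raise ValueError("empty edge list")
        n = len(rows[0][0])
        src = np.array([from_string(r[0], n) for r in rows], dtype=np.int64)
        dst = np.array([from_string(r[1], n) for r in rows], dtype=np.int64)
        w = np.array([int(r[2]) for r in rows], dtype=np.int64)
        return cls(src, dst, w, n, window)

    def write_graphml(self, path) -> None:
        import networkx as nx

        g = nx.relabel_nodes(self.to_networkx(),
                             {int(x): to_string(int(x), self.n)
                              for x in self.nodes})
        nx.write_graphml(g, path)


def build_network(log: TransitionLog, t1: int, t2: int) -> TransitionNetwork:
    """Count transitions with ``t1 <= t < t2`` into a weighted network.

    ``t1 == t2`` yields an empty network; windows outside the log raise.
    """
    codes = log.pair_codes(t1, t2)
    uniq, counts = np.unique(codes, return_counts=True)
    return TransitionNetwork.from_codes(uniq, counts, log.n, (t1, t2))


def sliding_windows(log: TransitionLog, window_len: int, stride: int = 1,
                    start: int | None = None) -> Iterator[TransitionNetwork]:
    """Yield the networks of overlapping windows, built incrementally.

    The first window is ``[start, start + window_len)`` (``start`` defaults to
    the config's burn-in, or 0 for a bare log); each next window advances by
    ``stride``.  Counts are kept in a dense table over transition codes and
    updated by removing the steps that leave and adding the steps that enter,
    so advancing costs O(stride * N) instead of a full rebuild; the yielded
    networks are exactly equal to from-scratch :func:`build_network` results.
    """
    if window_len < 1 or stride < 1:
        raise ValueError("window_len and stride must be positive")
    if start is None:
        start = log.config.burn_in if log.config is not None else 0
    if start < 0 or start + window_len > log.steps:
        raise ValueError("first window does not fit in the log")
    if 2 * log.n > 26:  # dense code table would not fit; rebuild per window
        t1 = start
        while t1 + window_len <= log.steps:
            yield build_network(log, t1, t1 + window_len)
            t1 += stride
        return
    table = np.zeros(1 << (2 * log.n), dtype=np.int64)
    codes = log.pair_codes(start, start + window_len)
    np.add.at(table, codes, 1)
    t1 = start
    while t1 + window_len <= log.steps:
        live = np.flatnonzero(table)
        yield TransitionNetwork.from_codes(live, table[live], log.n,
                                           (t1, t1 + window_len))
        old = log.pair_codes(t1, min(t1 + stride, log.steps))
        new_lo = t1 + window_len
        new_hi = min(new_lo + stride, log.steps)
        if new_hi < new_lo + stride:
            break
        np.add.at(table, log.pair_codes(new_lo, new_hi), 1)
        np.subtract.at(table, old, 1)
        t1 += stride
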