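"""The restoration list: a hierarchical elite memory against noisy-fitness
selection errors ("EA cheat").

One pyramid per working-population slot (parents 0..Omega-1, offspring
Omega..2*Omega-1) holds up to ``max_levels`` backed-up solutions sorted by
running-average fitness, best on top.  Four rules govern it — insertion,
mutation, sorting, information update — plus two comparison strategies for
solutions with unequal sampling counts.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "Solution",
    "Pyramid",
    "RestorationList",
    "Verdict",
    "compare_solutions",
    "compare_with_record",
]


@dataclass
class Solution:
    """A candidate population structure with its evaluation aggregate:
    ``sum`` of sampled cooperation levels over ``num`` samples,
    fitness = ``avg`` = sum/num."""

    graph: nx.Graph
    sum: float
    num: int

    def __post_init__(self):
        if self.num < 1:
            raise ValueError("num must be >= 1")

    @property
    def avg(self) -> float:
        return self.sum / self.num

    def add_sample(self, value: float) -> None:
        self.sum += value
        self.num += 1

    def copy(self) -> "Solution":
        return Solution(graph=self.graph.copy(), sum=self.sum, num=self.num)


def compare_solutions(a: Solution, b: Solution) -> int:
    """Strategy 1 — population comparison purely by avg (num is ignored):
    returns 1 if a is better, -1 if b is better, 0 on a tie."""
    if a.avg > b.avg:
        return 1
    if a.avg < b.avg:
        return -1
    return 0


class Verdict(enum.Enum):
    """Three-way outcome of Strategy 2."""

    RECORD_WINS = "record-wins"
    CURRENT_WINS = "current-wins"
    NEITHER = "neither"


def compare_with_record(current: Solution, adjusted: Solution,
                        record: Solution) -> Verdict:
    """Strategy 2 — compare a working solution (with its one-switch variant)
    against a backed-up record.  The record wins only when
    avg_current < avg_adjusted < avg_record; the current solution wins only
    when avg_adjusted > avg_current > avg_record."""
    if current.avg < adjusted.avg < record.avg:
        return Verdict.RECORD_WINS
    if adjusted.avg > current.avg > record.avg:
        return Verdict.CURRENT_WINS
    return Verdict.NEITHER


class Pyramid:
    """One sub-list: at most ``max_levels`` records, level 0 the top (best
    avg); sortedness by avg descending is restored after every mutating call,
    with ties keeping insertion order (stable)."""

    def __init__(self, max_levels: int):
        if max_levels < 1:
            raise ValueError("max_levels must be >= 1")
        self.max_levels = max_levels
        self.records: list[Solution] = []
        # backup of the slot's current working solution, if any (Flag_List)
        self.linked: Solution | None = None

    def __len__(self) -> int:
        return len(self.records)

    def top(self) -> Solution | None:
        return self.records[0] if self.records else None

    def sort(self) -> None:
        self.records.sort(key=lambda rec: -rec.avg)  # stable

    def insert(self, sol: Solution) -> bool:
        """Insertion rule: append at the bottom if a slot is vacant;
        otherwise evict the worst-avg record with smaller avg and
        smaller-or-equal num (exactly one eviction).  Returns False when no
        record qualifies for eviction — the solution is not backed up."""
        if len(self.records) < self.max_levels:
            self.records.append(sol)
            self.sort()
            return True
        candidates = [idx for idx, rec in enumerate(self.records)
                      if rec.avg < sol.avg and rec.num <= sol.num]
        if not candidates:
            return False
        victim = min(candidates, key=lambda idx: self.records[idx].avg)
        if self.records[victim] is self.linked:
            self.linked = None
        del self.records[victim]
        self.records.append(sol)
        self.sort()
        return True

    def mutation_replace(self, m: int, sol: Solution, alpha: float,
                         rng: np.random.Generator) -> bool:
        """Mutation rule: a better-avg solution that failed insertion may
        still take level m's place, with probability alpha**(max_levels - m)
        — the top record is the hardest to displace; alpha = 0 protects every
        record."""
        record = self.records[m]
        if not sol.avg > record.avg:
            raise ValueError("mutation rule requires sol.avg > record.avg")
        if rng.random() < alpha ** (self.max_levels - m):
            if record is self.linked:
                self.linked = None
            self.records[m] = sol
            self.sort()
            return True
        return False

    def backup(self, sol: Solution, alpha: float,
               rng: np.random.Generator) -> bool:
        """Attempt to back up: insertion rule first; if it fails, try the
        mutation rule on qualifying levels from the bottom up (at most one
        replacement)."""
        if self.insert(sol):
            return True
        if alpha <= 0.0:
            return False
        for m in range(len(self.records) - 1, -1, -1):
            if self.records[m].avg < sol.avg:
                if self.mutation_replace(m, sol, alpha, rng):
                    return True
        return False

    def synchronize(self, total: float, num: int) -> bool:
        """Information-update rule: overwrite the linked backup's aggregate
        with its ontology's (the stored graph is untouched), then re-sort."""
        if self.linked is None:
            return False
        self.linked.sum = total
        self.linked.num = num
        self.sort()
        return True


class RestorationList:
    """2*Omega pyramids; pyramid n backs up the n-th working-population slot
    (parents 0..Omega-1, offspring Omega..2*Omega-1)."""

    def __init__(self, n_pyramids: int, max_levels: int):
        if n_pyramids < 1:
            raise ValueError("need at least one pyramid")
        self.pyramids = [Pyramid(max_levels) for _ in range(n_pyramids)]

    def __len__(self) -> int:
        return len(self.pyramids)

    def __getitem__(self, i: int) -> Pyramid:
        return self.pyramids[i]

    def insert_record(self, i: int, sol: Solution) -> bool:
        return self.pyramids[i].insert(sol)

    def mutation_replace(self, i: int, m: int, sol: Solution, alpha: float,
                         rng: np.random.Generator) -> bool:
        return self.pyramids[i].mutation_replace(m, sol, alpha, rng)

    def sort_pyramid(self, i: int) -> None:
        self.pyramids[i].sort()

    def record_synchronize(self, i: int, total: float, num: int) -> bool:
        return self.pyramids[i].synchronize(total, num)

    def restore_top(self, i: int) -> Solution:
        """Return a copy of the best record of pyramid i; the list itself is
        unchanged.  Raises on an empty pyramid (callers guard)."""
        top = self.pyramids[i].top()
        if top is None:
            raise IndexError(f"pyramid {i} is empty")
        return top.copy()

    def dump(self, fh) -> None:
        """JSON-lines state dump (pyramid, level, avg, num, edge-set hash)
        for debugging and test assertions."""
        for pi, pyr in enumerate(self.pyramids):
            for level, rec in enumerate(pyr.records):
                edge_hash = hash(frozenset(
                    tuple(sorted(e)) for e in rec.graph.edges()))
                fh.write(json.dumps({
                    "pyramid": pi, "level": level, "avg": rec.avg,
                    "num": rec.num, "graph_hash": edge_hash}) + "\n")
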