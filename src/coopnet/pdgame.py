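"""Prisoner's Dilemma on graphs: payoff accumulation, synchronous strategy
updating, and the equilibrium cooperation-level evaluator.

The game is the weak dilemma R = 1, T = 1 + r, P = S = 0 (cost-to-benefit
ratio r, default 0.95).  Three synchronous update rules are provided:

``recolonize``
    Death-birth competition for each site: the occupant is retained with the
    focal-retention product ``prod_l (1 - W_l)`` over its neighbors, where
    ``W_y = (P_y - P_x) / (D * max(d_x, d_y))`` for richer neighbors
    (``D = T - S``) and 0 otherwise; on takeover a neighbor wins with
    relative probability ``W_y / sum_l W_l``.
``fermi``
    Each learner compares with one uniformly chosen neighbor and imitates it
    with the logistic probability ``1 / (1 + exp((P_learner - P_model)/k))``
    (noise amplitude k, default 0.1).
``unconditional``
    Each node copies its strictly richest neighbor (ties uniform).

One generation updates every site simultaneously from the payoffs of the
current generation.  Homogeneous states are absorbing under all three rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _kernels
from .netstruct import graph_to_arrays

__all__ = [
    "COOPERATE",
    "DEFECT",
    "PayoffParams",
    "UpdateRule",
    "EvaluationMode",
    "MODE_A",
    "MODE_B",
    "CooperationEstimate",
    "random_strategies",
    "cooperation_frequency",
    "accumulate_payoffs",
    "takeover_probability",
    "fermi_probability",
    "step_recolonize",
    "step_fermi",
    "step_unconditional",
    "evaluate_cooperation",
    "multi_sample_evaluate",
]

COOPERATE = np.int8(1)
DEFECT = np.int8(0)

_MAX_SEED = 2**31 - 1


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_MAX_SEED))


@dataclass(frozen=True)
class PayoffParams:
    """Pairwise game payoffs T (temptation), R (reward), P (punishment),
    S (sucker); must satisfy T > R >= P >= S."""

    T: float = 1.95
    R: float = 1.0
    P: float = 0.0
    S: float = 0.0

    def __post_init__(self):
        if not (self.T > self.R >= self.P >= self.S):
            raise ValueError(
                f"need T > R >= P >= S, got T={self.T}, R={self.R}, "
                f"P={self.P}, S={self.S}")

    @classmethod
    def from_ratio(cls, r: float) -> "PayoffParams":
        """Weak-dilemma parametrization R=1, T=1+r, P=S=0."""
        if r <= 0:
            raise ValueError(f"cost-to-benefit ratio must be > 0, got {r}")
        return cls(T=1.0 + r, R=1.0, P=0.0, S=0.0)

    @property
    def r(self) -> float:
        return self.T - self.R

    @property
    def D(self) -> float:
        """Payoff span T - S, the normalizer of the takeover probability."""
        return self.T - self.S


@dataclass(frozen=True)
class UpdateRule:
    """Strategy-update rule tag; ``fermi`` carries the noise amplitude k."""

    kind: str = "recolonize"
    k: float = 0.1

    _IDS = {"recolonize": _kernels.RULE_RECOLONIZE,
            "fermi": _kernels.RULE_FERMI,
            "unconditional": _kernels.RULE_UNCONDITIONAL}

    def __post_init__(self):
        if self.kind not in self._IDS:
            raise ValueError(f"unknown update rule {self.kind!r}")
        if self.kind == "fermi" and self.k <= 0:
            raise ValueError("fermi noise amplitude k must be > 0")

    @property
    def rule_id(self) -> int:
        return self._IDS[self.kind]

    @classmethod
    def recolonize(cls):
        return cls("recolonize")

    @classmethod
    def fermi(cls, k: float = 0.1):
        return cls("fermi", k=k)

    @classmethod
    def unconditional(cls):
        return cls("unconditional")


@dataclass(frozen=True)
class EvaluationMode:
    """Equilibrium-evaluation protocol: run ``transient_factor * N``
    generations, then average the cooperation frequency over the next
    ``averaging_factor * N`` generations (both rounded up).  With
    ``absolute=True`` the factors are absolute generation counts instead of
    multiples of N."""

    transient_factor: float
    averaging_factor: float
    absolute: bool = False

    def __post_init__(self):
        if self.transient_factor <= 0 or self.averaging_factor <= 0:
            raise ValueError("evaluation-mode factors must be > 0")

    def windows(self, n_nodes: int) -> tuple[int, int]:
        scale = 1 if self.absolute else n_nodes
        return (math.ceil(self.transient_factor * scale),
                math.ceil(self.averaging_factor * scale))


MODE_A = EvaluationMode(1.0, 0.1)
MODE_B = EvaluationMode(10.0, 1.0)


@dataclass
class CooperationEstimate:
    """Running aggregate of equilibrium cooperation-level samples."""

    sum: float = 0.0
    num: int = 0

    @property
    def avg(self) -> float:
        return self.sum / self.num

    def add(self, sample: float) -> None:
        self.sum += sample
        self.num += 1


# ---------------------------------------------------------------------------
# strategies and payoffs

def random_strategies(n: int, rng: np.random.Generator) -> np.ndarray:
    """Each node a cooperator or defector with equal probability."""
    return (rng.random(n) < 0.5).astype(np.int8)


def cooperation_frequency(s: np.ndarray) -> float:
    return float(np.mean(s == COOPERATE))


def accumulate_payoffs(g: nx.Graph, s: np.ndarray,
                       pp: PayoffParams) -> np.ndarray:
    """P_x = sum over neighbors y of the row payoff of (s_x, s_y):
    CC -> R, CD -> S, DC -> T, DD -> P."""
    indptr, indices, _ = graph_to_arrays(g)
    return _kernels.payoff_kernel(indptr, indices,
                                  np.asarray(s, dtype=np.int8),
                                  pp.T, pp.R, pp.P, pp.S)


def takeover_probability(P_x: float, P_y: float, d_x: int, d_y: int,
                         pp: PayoffParams) -> float:
    """Probability that neighbor y succeeds in reproducing into site x:
    (P_y - P_x) / (D * max(d_x, d_y)) when P_y > P_x, else 0."""
    if d_x < 1 or d_y < 1:
        raise ValueError("degrees must be >= 1")
    if P_y <= P_x:
        return 0.0
    return (P_y - P_x) / (pp.D * max(d_x, d_y))


def fermi_probability(P_learner: float, P_model: float, k: float) -> float:
    """Logistic imitation probability 1 / (1 + exp((P_learner-P_model)/k))."""
    return 1.0 / (1.0 + math.exp((P_learner - P_model) / k))


# ---------------------------------------------------------------------------
# synchronous steps

def _prep(g, s, pp, payoffs):
    indptr, indices, degrees = graph_to_arrays(g)
    s = np.asarray(s, dtype=np.int8)
    if payoffs is None:
        payoffs = _kernels.payoff_kernel(indptr, indices, s,
                                         pp.T, pp.R, pp.P, pp.S)
    return indptr, indices, degrees, s, np.asarray(payoffs, dtype=np.float64)


def step_recolonize(g: nx.Graph, s: np.ndarray, pp: PayoffParams,
                    rng: np.random.Generator,
                    payoffs: np.ndarray | None = None) -> np.ndarray:
    """One synchronous recolonization generation.  ``payoffs`` defaults to
    :func:`accumulate_payoffs` of the current state (overridable test hook)."""
    indptr, indices, degrees, s, pay = _prep(g, s, pp, payoffs)
    _kernels.seed_rng(_spawn_seed(rng))
    return _kernels.recolonize_step(indptr, indices, s, pay, degrees, pp.D)


def step_fermi(g: nx.Graph, s: np.ndarray, pp: PayoffParams, k: float,
               rng: np.random.Generator,
               payoffs: np.ndarray | None = None) -> np.ndarray:
    """One synchronous Fermi-rule generation."""
    if k <= 0:
        raise ValueError("k must be > 0")
    indptr, indices, _, s, pay = _prep(g, s, pp, payoffs)
    _kernels.seed_rng(_spawn_seed(rng))
    return _kernels.fermi_step(indptr, indices, s, pay, k)


def step_unconditional(g: nx.Graph, s: np.ndarray, pp: PayoffParams,
                       rng: np.random.Generator,
                       payoffs: np.ndarray | None = None) -> np.ndarray:
    """One synchronous unconditional-imitation generation."""
    indptr, indices, _, s, pay = _prep(g, s, pp, payoffs)
    _kernels.seed_rng(_spawn_seed(rng))
    return _kernels.unconditional_step(indptr, indices, s, pay)


# ---------------------------------------------------------------------------
# equilibrium evaluation

def evaluate_cooperation(g: nx.Graph, rule: UpdateRule, pp: PayoffParams,
                         mode: EvaluationMode, rng: np.random.Generator,
                         initial_state: np.ndarray | None = None,
                         _arrays=None) -> CooperationEstimate:
    """One equilibrium cooperation-level sample.

    Strategies start half cooperators / half defectors at random (or from
    ``initial_state``, a test hook); the transient window is discarded and
    the cooperation frequency is averaged over the following window.
    """
    if _arrays is None:
        _arrays = graph_to_arrays(g)
    indptr, indices, degrees = _arrays
    n = indptr.size - 1
    n_transient, n_average = mode.windows(n)
    if initial_state is None:
        init = np.full(1, -1, dtype=np.int8)
    else:
        init = np.asarray(initial_state, dtype=np.int8)
        if init.size != n:
            raise ValueError("initial_state length must equal node count")
    _kernels.seed_rng(_spawn_seed(rng))
    sample = _kernels.evaluate_kernel(
        indptr, indices, degrees, rule.rule_id, rule.k,
        pp.T, pp.R, pp.P, pp.S, pp.D, n_transient, n_average, init)
    return CooperationEstimate(sum=float(sample), num=1)


def multi_sample_evaluate(g: nx.Graph, n_samples: int, rule: UpdateRule,
                          pp: PayoffParams, mode: EvaluationMode,
                          rng: np.random.Generator) -> CooperationEstimate:
    """Aggregate ``n_samples`` independent evaluations; avg = sum / num."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    arrays = graph_to_arrays(g)
    est = CooperationEstimate()
    for _ in range(n_samples):
        est.add(evaluate_cooperation(g, rule, pp, mode, rng,
                                     _arrays=arrays).sum)
    return est
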