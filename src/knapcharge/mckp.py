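"""The ε-multiple-choice knapsack problem (ε-MCKP) and its solvers.

Standard MCKP picks exactly one item from each of m sets so the weight sum
stays below a capacity while maximising profit.  The charge-assignment
variant solved here differs in two ways: weights and capacity may be
negative (charges have either sign), and the weight sum must land inside a
window [c − ε, c + ε] around the capacity rather than merely below it.

Three solution routes are provided:

* a pseudo-polynomial dynamic program over integer-scaled, shifted weights,
  running in O(n·(c̃ + ε̃)) for n total items;
* an integer linear program (binary selection variables, two window
  constraints, one choose-one constraint per set), solved with HiGHS via
  :func:`scipy.optimize.milp`;
* exhaustive enumeration, intended as a test oracle on small instances.

A standard MCKP with capacity c reduces to ε-MCKP with capacity c/2 and
ε = c/2, so the solvers here subsume the classic problem.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = [
    "Item",
    "EpsMckpInstance",
    "IntegerInstance",
    "Solution",
    "Infeasible",
    "to_integer_instance",
    "solve_dp",
    "solve_ilp",
    "solve_bruteforce",
    "reduce_mckp_to_eps",
    "solve",
]

PROFIT_TOL = 1e-9


@dataclass(frozen=True)
class Item:
    weight: float
    profit: float


@dataclass
class EpsMckpInstance:
    """m item sets with real weights and non-negative profits, capacity c, error ε."""

    sets: list[list[Item]]
    c: float
    epsilon: float

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("instance needs at least one item set")
        for i, s in enumerate(self.sets):
            if not s:
                raise ValueError(f"item set {i + 1} is empty")
            for j, it in enumerate(s):
                if it.profit < 0:
                    raise ValueError(f"negative profit on item ({i + 1},{j + 1})")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def m(self) -> int:
        return len(self.sets)

    @property
    def n_items(self) -> int:
        return sum(len(s) for s in self.sets)

    def to_json_obj(self) -> dict:
        return {
            "sets": [[{"w": it.weight, "p": it.profit} for it in s] for s in self.sets],
            "c": self.c,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "EpsMckpInstance":
        return cls(
            [[Item(float(d["w"]), float(d["p"])) for d in s] for s in obj["sets"]],
            float(obj["c"]),
            float(obj["epsilon"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpsMckpInstance":
        return cls.from_json_obj(json.loads(Path(path).read_text()))


@dataclass
class IntegerInstance:
    """Integer-scaled instance with per-set minima shifted to zero.

    ``weights[i][j] = round(factor·w_{i,j}) − offsets[i]`` with
    ``offsets[i] = min_j round(factor·w_{i,j})``; the capacity becomes
    ``c_int = round(factor·c) − Σ_i offsets[i]`` and ``eps_int =
    round(factor·ε)``.  Feasibility of every full selection is preserved.
    """

    weights: list[list[int]]
    profits: list[list[float]]
    c_int: int
    eps_int: int
    factor: int
    offsets: list[int]


@dataclass
class Solution:
    """One selected item per set (0-based indices within each set)."""

    selection: list[int]
    total_weight: float
    total_profit: float
    feasible: bool = True
    stats: dict = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return {
            "selection": self.selection,
            "total_weight": self.total_weight,
            "total_profit": self.total_profit,
            "feasible": self.feasible,
        }


@dataclass
class Infeasible:
    """No selection lands inside [c − ε, c + ε]; carries the reachable range."""

    reason: str = "no selection satisfies the capacity window"
    achievable_min: float | None = None
    achievable_max: float | None = None
    feasible: bool = False

    def to_json_obj(self) -> dict:
        return {
            "feasible": False,
            "reason": self.reason,
            "achievable_min": self.achievable_min,
            "achievable_max": self.achievable_max,
        }


def _scale(x: float, factor: int, what: str) -> int:
    s = x * factor
    r = round(s)
    if abs(s - r) > 1e-6:
        raise ValueError(f"{what} {x!r} is not integral after scaling by {factor}")
    return int(r)


def to_integer_instance(inst: EpsMckpInstance, factor: int = 1000) -> IntegerInstance:
    """Scale weights, capacity and ε by ``factor`` and shift per-set minima to 0."""
    weights: list[list[int]] = []
    offsets: list[int] = []
    for i, s in enumerate(inst.sets):
        scaled = [
            _scale(it.weight, factor, f"weight of item ({i + 1},{j + 1})")
            for j, it in enumerate(s)
        ]
        w_star = min(scaled)
        offsets.append(w_star)
        weights.append([w - w_star for w in scaled])
    c_int = _scale(inst.c, factor, "capacity") - sum(offsets)
    eps_int = _scale(inst.epsilon, factor, "epsilon")
    profits = [[it.profit for it in s] for s in inst.sets]
    return IntegerInstance(weights, profits, c_int, eps_int, factor, offsets)


def _totals(inst: EpsMckpInstance, selection: Sequence[int], factor: int) -> tuple[float, float]:
    w_m = sum(
        _scale(inst.sets[i][j].weight, factor, "weight") for i, j in enumerate(selection)
    )
    p = sum(inst.sets[i][j].profit for i, j in enumerate(selection))
    return w_m / factor, p


def _achievable_range(ii: IntegerInstance) -> tuple[float, float]:
    lo = sum(ii.offsets)
    hi = lo + sum(max(ws) for ws in ii.weights)
    return lo / ii.factor, hi / ii.factor


def suffix_profit_layers(ii: IntegerInstance, hi: int) -> tuple[np.ndarray, int]:
    """DP profit table over transformed weights 0..hi.

    ``layers[k, d]`` is the maximum profit selecting one item from each of
    sets k..m-1 (0-based) with transformed weights summing to exactly d;
    −inf marks unreachable sums, and ``layers[m, 0] = 0`` seeds the exact-sum
    semantics.  Also returns the number of table cells touched (the DP's
    work measure, proportional to n·(c̃ + ε̃)).
    """
    m = len(ii.weights)
    width = hi + 1
    NEG = -np.inf
    layers = np.full((m + 1, width), NEG)
    layers[m, 0] = 0.0
    cells = 0
    for k in range(m - 1, -1, -1):
        prev = layers[k + 1]
        cur = layers[k]
        for w, p in zip(ii.weights[k], ii.profits[k]):
            cells += width
            if w == 0:
                cand = prev + p
            elif w > hi:
                continue
            else:
                cand = np.full(width, NEG)
                cand[w:] = prev[: width - w] + p
            np.maximum(cur, cand, out=cur)
    return layers, cells


def solve_dp(inst: EpsMckpInstance, factor: int = 1000) -> Solution | Infeasible:
    """Exact dynamic program.

    After the integer transform, ``P[k, d]`` holds the best profit reachable
    with a weight sum of exactly d over the first k sets considered;
    initialising ``P[0, d]`` to 0 only at d = 0 forces exact weight sums, and
    the optimum is the maximum of the last row over the capacity window
    ``max(c̃ − ε̃, 0) ≤ d ≤ c̃ + ε̃``.  Sets are processed in reverse order so
    that backtracking fixes set 1 first, yielding the lexicographically
    smallest co-optimal selection.
    """
    ii = to_integer_instance(inst, factor)
    hi = ii.c_int + ii.eps_int
    lo = max(ii.c_int - ii.eps_int, 0)
    if hi < 0:
        amin, amax = _achievable_range(ii)
        return Infeasible(achievable_min=amin, achievable_max=amax)
    m = inst.m
    layers, cells = suffix_profit_layers(ii, hi)
    window = layers[0, lo : hi + 1]
    if not np.any(np.isfinite(window)):
        amin, amax = _achievable_range(ii)
        return Infeasible(achievable_min=amin, achievable_max=amax)
    p_star = float(window.max())
    # backtrack: at each set pick the smallest item index that still allows
    # the remaining sets to complete an optimal selection inside [lo, hi]
    selection: list[int] = []
    remaining = p_star
    cur_lo, cur_hi = lo, hi
    for k in range(m):
        nxt = layers[k + 1]
        chosen = None
        for j, (w, p) in enumerate(zip(ii.weights[k], ii.profits[k])):
            a = max(cur_lo - w, 0)
            b = cur_hi - w
            if b < 0:
                continue
            seg = nxt[a : b + 1]
            if seg.size and float(seg.max()) >= remaining - p - PROFIT_TOL:
                chosen = (j, w, p, a, b)
                break
        assert chosen is not None, "backtracking lost the optimal solution"
        j, w, p, a, b = chosen
        selection.append(j)
        remaining -= p
        cur_lo, cur_hi = a, b
    total_w, total_p = _totals(inst, selection, factor)
    return Solution(selection, total_w, total_p, True, {"table_cells": cells, "c_int": ii.c_int, "eps_int": ii.eps_int})


def solve_ilp(inst: EpsMckpInstance, factor: int = 1000) -> Solution | Infeasible:
    """Integer linear program: binary x_{i,j}, maximise Σ x_{i,j} p_{i,j}
    s.t. c − ε ≤ Σ x_{i,j} w_{i,j} ≤ c + ε and Σ_j x_{i,j} = 1 per set.

    Weights enter the model integer-scaled so the window constraints are
    exact; solved with HiGHS through :func:`scipy.optimize.milp`.
    """
    ii = to_integer_instance(inst, factor)
    n = inst.n_items
    profits = np.array([p for ps in ii.profits for p in ps], dtype=float)
    weights = np.array([w for ws in ii.weights for w in ws], dtype=float)
    sel_rows = np.zeros((inst.m, n))
    pos = 0
    for i, s in enumerate(inst.sets):
        sel_rows[i, pos : pos + len(s)] = 1.0
        pos += len(s)
    constraints = [
        LinearConstraint(weights, ii.c_int - ii.eps_int, ii.c_int + ii.eps_int),
        LinearConstraint(sel_rows, 1.0, 1.0),
    ]
    res = milp(
        c=-profits,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(0.0, 1.0),
    )
    if res.status == 4:
        # HiGHS presolve occasionally errors out on tight equality windows
        # instead of proving infeasibility; retry without presolve
        res = milp(
            c=-profits,
            constraints=constraints,
            integrality=np.ones(n),
            bounds=Bounds(0.0, 1.0),
            options={"presolve": False},
        )
    if res.status == 2:  # problem infeasible
        amin, amax = _achievable_range(ii)
        return Infeasible(achievable_min=amin, achievable_max=amax)
    if not res.success:
        raise RuntimeError(f"ILP backend failed: status={res.status} {res.message}")
    x = np.round(res.x).astype(int)
    selection = []
    pos = 0
    for s in inst.sets:
        block = x[pos : pos + len(s)]
        selection.append(int(np.argmax(block)))
        pos += len(s)
    total_w, total_p = _totals(inst, selection, factor)
    return Solution(selection, total_w, total_p, True, {"backend": "scipy-highs"})


def solve_bruteforce(inst: EpsMckpInstance, factor: int = 1000) -> Solution | Infeasible:
    """Enumerate all full selections (test oracle; Π|N_i| ≤ 10^6).

    Ties between co-optimal selections go to the lexicographically smallest
    item-index vector.
    """
    n_comb = 1
    for s in inst.sets:
        n_comb *= len(s)
    if n_comb > 10**6:
        raise ValueError(f"too many combinations to enumerate ({n_comb})")
    scaled = [
        [_scale(it.weight, factor, "weight") for it in s] for s in inst.sets
    ]
    c_m = _scale(inst.c, factor, "capacity")
    e_m = _scale(inst.epsilon, factor, "epsilon")
    best: tuple[float, tuple[int, ...]] | None = None
    amin = sum(min(ws) for ws in scaled)
    amax = sum(max(ws) for ws in scaled)
    for sel in itertools.product(*(range(len(s)) for s in inst.sets)):
        w = sum(scaled[i][j] for i, j in enumerate(sel))
        if not (c_m - e_m <= w <= c_m + e_m):
            continue
        p = sum(inst.sets[i][j].profit for i, j in enumerate(sel))
        if best is None or p > best[0] + PROFIT_TOL:
            best = (p, sel)
    if best is None:
        return Infeasible(achievable_min=amin / factor, achievable_max=amax / factor)
    total_w, total_p = _totals(inst, list(best[1]), factor)
    return Solution(list(best[1]), total_w, total_p, True)


def reduce_mckp_to_eps(c: float) -> tuple[float, float]:
    """Reduce standard MCKP capacity c ≥ 0 to the window form: (c/2, ε = c/2),
    so the feasible window [c′ − ε, c′ + ε] becomes exactly [0, c].

    Halving can leave c′ off the 0.001 grid; solve the reduced instance with
    ``factor=2000`` to keep the integer transform exact for 3-decimal data.
    """
    if c < 0:
        raise ValueError("standard MCKP assumes c >= 0")
    return c / 2.0, c / 2.0


_SOLVERS = {"dp": solve_dp, "ilp": solve_ilp, "bruteforce": solve_bruteforce}


def solve(inst: EpsMckpInstance, solver: str = "dp", factor: int = 1000) -> Solution | Infeasible:
    try:
        fn = _SOLVERS[solver]
    except KeyError:
        raise ValueError(f"unknown solver {solver!r}; choose from {sorted(_SOLVERS)}") from None
    return fn(inst, factor)
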