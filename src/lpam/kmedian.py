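"""Exact and heuristic k-median (p-median) solvers on a distance matrix.

The k-median problem selects k medoid indices minimising the summed distance
from every point to its nearest medoid.  ``solve_exact`` certifies global
optimality either by pruned exhaustive enumeration (small instances) or by
the standard p-median integer program solved with HiGHS through
``scipy.optimize.milp``.  ``solve_clarans`` is the CLARANS randomised local
search over single-medoid swaps.

Distance matrices only need to be symmetric with a zero diagonal; negative
off-diagonal entries (which the amplified commute distance can produce on
degenerate graphs) are accepted as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = [
    "KMedianResult",
    "assign_to_medoids",
    "objective",
    "solve_exact",
    "solve_clarans",
]

#: default maximum number of candidate medoid sets for the enumeration path
DEFAULT_ENUMERATION_BUDGET = 10_000_000


@dataclass(frozen=True)
class KMedianResult:
    """Solution of a k-median instance.

    ``medoids`` is sorted ascending; ``labels[j]`` is the medoid index each
    point is assigned to (medoids are self-assigned); ``objective`` equals
    the recomputed assignment cost.
    """

    medoids: tuple[int, ...]
    labels: np.ndarray
    objective: float
    solver_tag: str
    seed: Optional[int] = None


def _as_matrix(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    return D


def assign_to_medoids(D, medoids: Iterable[int]) -> np.ndarray:
    """Assign every point to its nearest medoid.

    Ties are broken toward the medoid with the smallest index; every medoid
    is assigned to itself regardless of zero-distance ties with other medoids.
    """
    D = _as_matrix(D)
    meds = np.array(sorted(set(int(s) for s in medoids)), dtype=np.int64)
    if meds.size == 0:
        raise ValueError("medoid set must be nonempty")
    if meds[0] < 0 or meds[-1] >= D.shape[0]:
        raise ValueError("medoid index out of range")
    sub = D[:, meds]
    labels = meds[np.argmin(sub, axis=1)]  # argmin keeps the smallest index on ties
    labels[meds] = meds
    return labels


def objective(D, medoids: Iterable[int]) -> float:
    """Sum of distances from each point to its nearest medoid."""
    D = _as_matrix(D)
    meds = sorted(set(int(s) for s in medoids))
    if not meds:
        raise ValueError("medoid set must be nonempty")
    return float(D[:, meds].min(axis=1).sum())


def _result(D: np.ndarray, medoids: Sequence[int], tag: str,
            seed: Optional[int] = None) -> KMedianResult:
    meds = tuple(sorted(int(s) for s in medoids))
    labels = assign_to_medoids(D, meds)
    return KMedianResult(meds, labels, objective(D, meds), tag, seed)


def _enumerate_exact(D: np.ndarray, k: int) -> tuple[float, tuple[int, ...]]:
    """Exhaustive search over all C(m, k) medoid sets.

    Prefixes of size k-1 are walked recursively while the last medoid is
    batched in numpy.  Candidate sets are visited in lexicographic order and
    only strict improvements are kept, so the first optimum found — i.e. the
    lexicographically smallest optimal set — is returned.
    """
    m = D.shape[0]
    best_obj = math.inf
    best: tuple[int, ...] = ()

    def recurse(start: int, depth: int, cur_min: np.ndarray, prefix: tuple[int, ...]):
        nonlocal best_obj, best
        if depth == k - 1:
            tail = np.arange(start, m)
            objs = np.minimum(cur_min[:, None], D[:, tail]).sum(axis=0)
            i = int(np.argmin(objs))
            if objs[i] < best_obj:
                best_obj = float(objs[i])
                best = prefix + (int(tail[i]),)
            return
        for j in range(start, m - (k - 1 - depth)):
            recurse(j + 1, depth + 1, np.minimum(cur_min, D[:, j]), prefix + (j,))

    recurse(0, 0, np.full(m, math.inf), ())
    return best_obj, best


def _milp_exact(D: np.ndarray, k: int) -> tuple[int, ...]:
    """Standard p-median MILP: min Σ d_ij y_ij with assignment constraints.

    Facility-open variables x are binary; assignment variables y may stay
    continuous because, with Σ_j y_ij = 1 and y_ij <= x_j, an optimal basic
    solution assigns each point wholly to one open facility.
    """
    m = D.shape[0]
    n_var = m + m * m  # x_j then y_ij row-major
    c = np.concatenate([np.zeros(m), D.ravel()])

    rows, cols, vals = [], [], []
    # Σ_j y_ij = 1 for every point i
    for i in range(m):
        rows.extend([i] * m)
        cols.extend(range(m + i * m, m + (i + 1) * m))
        vals.extend([1.0] * m)
    a_assign = sparse.csr_matrix((vals, (rows, cols)), shape=(m, n_var))

    # y_ij - x_j <= 0
    rows, cols, vals = [], [], []
    r = 0
    for i in range(m):
        for j in range(m):
            rows.extend([r, r])
            cols.extend([m + i * m + j, j])
            vals.extend([1.0, -1.0])
            r += 1
    a_open = sparse.csr_matrix((vals, (rows, cols)), shape=(m * m, n_var))

    a_card = sparse.csr_matrix(
        (np.ones(m), (np.zeros(m, dtype=int), np.arange(m))), shape=(1, n_var))

    constraints = [
        LinearConstraint(a_assign, 1.0, 1.0),
        LinearConstraint(a_open, -np.inf, 0.0),
        LinearConstraint(a_card, float(k), float(k)),
    ]
    integrality = np.concatenate([np.ones(m), np.zeros(m * m)])
    res = milp(c, constraints=constraints, integrality=integrality,
               bounds=Bounds(0.0, 1.0))
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"MILP p-median solve failed: {res.message}")
    return tuple(int(j) for j in np.flatnonzero(res.x[:m] > 0.5))


def solve_exact(D, k: int,
                budget: int = DEFAULT_ENUMERATION_BUDGET) -> KMedianResult:
    """Globally optimal k-median solution.

    Uses exhaustive enumeration when C(m, k) <= ``budget`` candidate sets
    (returning the lexicographically smallest optimal medoid set), otherwise
    the p-median integer program via HiGHS (a deterministic optimum whose
    medoid set may be any optimal one).
    """
    D = _as_matrix(D)
    m = D.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    if math.comb(m, k) <= budget:
        _, meds = _enumerate_exact(D, k)
    else:
        meds = _milp_exact(D, k)
    return _result(D, meds, "exact")


def default_maxneighbor(k: int, m: int) -> int:
    """CLARANS neighbour-sampling bound: max(250, 1.25% of k·(m−k))."""
    return max(250, math.ceil(0.0125 * k * (m - k)))


def solve_clarans(D, k: int, numlocal: int = 4,
                  maxneighbor: Optional[int] = None,
                  seed: Optional[int] = None) -> KMedianResult:
    """CLARANS heuristic: randomised local search over single-medoid swaps.

    Runs ``numlocal`` restarts from random medoid sets; in each, random
    swap neighbours are sampled and the first improving swap is taken,
    declaring a local optimum after ``maxneighbor`` consecutive failures.
    Fully reproducible from ``seed``.
    """
    D = _as_matrix(D)
    m = D.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    if maxneighbor is None:
        maxneighbor = default_maxneighbor(k, m)
    rng = np.random.default_rng(seed)

    best_obj = math.inf
    best: Optional[np.ndarray] = None
    for _ in range(numlocal):
        current = rng.choice(m, size=k, replace=False)
        cur_obj = objective(D, current)
        if k < m:
            fails = 0
            member = np.zeros(m, dtype=bool)
            member[current] = True
            while fails < maxneighbor:
                pos = int(rng.integers(k))
                cand = int(rng.integers(m))
                while member[cand]:
                    cand = int(rng.integers(m))
                trial = current.copy()
                trial[pos] = cand
                trial_obj = objective(D, trial)
                if trial_obj < cur_obj:
                    member[current[pos]] = False
                    member[cand] = True
                    current, cur_obj = trial, trial_obj
                    fails = 0
                else:
                    fails += 1
        if cur_obj < best_obj:
            best_obj, best = cur_obj, current.copy()
    assert best is not None
    return _result(D, best, "clarans", seed)
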