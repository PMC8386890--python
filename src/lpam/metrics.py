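"""Scores for overlapping covers and per-cover graph statistics.

Cover-vs-cover similarity: overlapping normalised mutual information (ONMI,
LFK and max-normalised variants), the chance-corrected omega index over node
pairs, and a symmetrised best-match F1.  All three return exactly 1 for
identical covers and are symmetric in their arguments.  Per-cover graph
statistics: average internal degree and normalised cut.

The LFK ONMI treats each community as a binary membership variable over the
universe; the conditional entropy of community X against a whole cover Y is
the minimum over Y's communities of the 2×2-joint conditional entropy,
subject to the standard validity constraint h(11) + h(00) >= h(01) + h(10)
(falling back to the unconditional entropy when violated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log2
from typing import Iterable, Sequence

import numpy as np

from .graph import Cover, Graph

__all__ = ["onmi", "omega_index", "f1_best_match", "cover_stats", "CoverScore"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverScore:
    value: float
    metric_tag: str


def _community_sets(cover) -> list[frozenset]:
    """Accept a Cover or any iterable of node collections; drop empties."""
    comms = cover.communities if isinstance(cover, Cover) else cover
    return [frozenset(c) for c in comms if len(c) > 0]


def _membership(comms: Sequence[frozenset], order: dict) -> np.ndarray:
    x = np.zeros((len(comms), len(order)), dtype=bool)
    for r, c in enumerate(comms):
        for v in c:
            x[r, order[v]] = True
    return x


def _h(w: float, n: float) -> float:
    """Entropy contribution -(w/n) log2(w/n); 0 by convention when w = 0."""
    if w <= 0:
        return 0.0
    return -(w / n) * log2(w / n)


def _cover_entropies(x: np.ndarray, n: int) -> np.ndarray:
    sizes = x.sum(axis=1)
    return np.array([_h(s, n) + _h(n - s, n) for s in sizes])


def _conditional_entropies(x: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """H(X_k | Y) for each community of x, minimised over y's communities."""
    hx = _cover_entropies(x, n)
    out = np.empty(len(x))
    for i, xi in enumerate(x):
        best = hx[i]  # fallback: no valid counterpart
        for yj in y:
            d = int(np.count_nonzero(xi & yj))
            c = int(xi.sum()) - d
            b = int(yj.sum()) - d
            a = n - b - c - d
            if _h(a, n) + _h(d, n) < _h(b, n) + _h(c, n):
                continue  # validity constraint violated
            cond = (_h(a, n) + _h(b, n) + _h(c, n) + _h(d, n)
                    - _h(b + d, n) - _h(a + c, n))
            best = min(best, cond)
        out[i] = best
    return out


def onmi(a, b, universe: Iterable, variant: str = "lfk") -> CoverScore:
    """Overlapping NMI between two covers over a shared node universe.

    ``variant="lfk"`` averages per-community normalised conditional
    entropies; ``variant="max"`` normalises the mutual information by
    max(H(X), H(Y)).  Scores from the two variants are not comparable.
    """
    if variant not in ("lfk", "max"):
        raise ValueError(f"unknown ONMI variant {variant!r}")
    order = {v: i for i, v in enumerate(universe)}
    n = len(order)
    if n == 0:
        raise ValueError("universe must be nonempty")
    ca, cb = _community_sets(a), _community_sets(b)
    if not ca or not cb:
        raise ValueError("covers must contain at least one nonempty community")
    x, y = _membership(ca, order), _membership(cb, order)
    hx, hy = _cover_entropies(x, n), _cover_entropies(y, n)
    hx_given_y = _conditional_entropies(x, y, n)
    hy_given_x = _conditional_entropies(y, x, n)

    if variant == "lfk":
        # per-community normalisation; a zero-entropy community contributes 0
        with np.errstate(invalid="ignore", divide="ignore"):
            tx = np.where(hx > 0, hx_given_y / np.where(hx > 0, hx, 1.0), 0.0)
            ty = np.where(hy > 0, hy_given_x / np.where(hy > 0, hy, 1.0), 0.0)
        value = 1.0 - 0.5 * (tx.mean() + ty.mean())
    else:
        hx_tot, hy_tot = hx.sum(), hy.sum()
        info = 0.5 * ((hx_tot - hx_given_y.sum()) + (hy_tot - hy_given_x.sum()))
        denom = max(hx_tot, hy_tot)
        value = info / denom if denom > 0 else 1.0
    return CoverScore(float(value), f"onmi_{variant}")


def _pair_comembership(comms: Sequence[frozenset], order: dict) -> np.ndarray:
    """For each unordered node pair, how many communities contain both ends."""
    x = _membership(comms, order).astype(np.int64)
    co = x.T @ x
    iu = np.triu_indices(len(order), k=1)
    return co[iu]


def omega_index(a, b, universe: Iterable) -> CoverScore:
    """Chance-corrected agreement of pairwise co-membership multiplicities.

    omega = (obs - exp) / (1 - exp) where obs is the fraction of node pairs
    placed together in the same number of communities by both covers and exp
    the agreement expected from the covers' multiplicity distributions.
    Returns 1 for the degenerate obs = exp = 1 case.
    """
    order = {v: i for i, v in enumerate(universe)}
    if len(order) < 2:
        raise ValueError("omega index needs a universe of at least 2 nodes")
    ta = _pair_comembership(_community_sets(a), order)
    tb = _pair_comembership(_community_sets(b), order)
    n_pairs = ta.size
    obs = float(np.count_nonzero(ta == tb)) / n_pairs
    top = max(int(ta.max(initial=0)), int(tb.max(initial=0)))
    counts_a = np.bincount(ta, minlength=top + 1)
    counts_b = np.bincount(tb, minlength=top + 1)
    exp = float((counts_a * counts_b).sum()) / (n_pairs * n_pairs)
    if abs(1.0 - exp) < 1e-12:
        return CoverScore(1.0 if abs(obs - 1.0) < 1e-12 else 0.0, "omega")
    return CoverScore((obs - exp) / (1.0 - exp), "omega")


def f1_best_match(a, b) -> CoverScore:
    """Symmetrised best-match F1: average over both covers of each
    community's best F1 against any community of the other cover."""
    ca, cb = _community_sets(a), _community_sets(b)
    if not ca or not cb:
        raise ValueError("covers must contain at least one nonempty community")

    def one_way(xs: list[frozenset], ys: list[frozenset]) -> float:
        scores = []
        for x in xs:
            best = 0.0
            for y in ys:
                inter = len(x & y)
                if inter:
                    best = max(best, 2.0 * inter / (len(x) + len(y)))
            scores.append(best)
        return float(np.mean(scores))

    return CoverScore(0.5 * (one_way(ca, cb) + one_way(cb, ca)), "f1")


def cover_stats(g: Graph, cover) -> dict:
    """Average internal degree and normalised cut of a cover on ``g``.

    avg_internal_degree: mean over communities of 2·m_S / n_S (m_S internal
    edges).  normalized_cut: mean over communities of
    cut(S)/vol(S) + cut(S)/(vol(G) − vol(S)); a community with vol(S) = 0 or
    vol(S) = vol(G) contributes 0 and is logged.
    """
    comms = cover.communities if isinstance(cover, Cover) else list(cover)
    if any(len(c) == 0 for c in comms):
        raise ValueError("cover_stats requires nonempty communities")
    if not comms:
        raise ValueError("cover has no communities")
    vol_g = g.volume
    internal_degrees, ncuts = [], []
    for s in comms:
        s = frozenset(s)
        m_s = sum(1 for u, v in g.edges if u in s and v in s)
        cut = sum(1 for u, v in g.edges if (u in s) != (v in s))
        vol_s = 2 * m_s + cut
        internal_degrees.append(2.0 * m_s / len(s))
        if vol_s == 0 or vol_s == vol_g:
            logger.warning("community with degenerate volume %d/%d: "
                           "normalized-cut term set to 0", vol_s, vol_g)
            ncuts.append(0.0)
        else:
            ncuts.append(cut / vol_s + cut / (vol_g - vol_s))
    return {
        "avg_internal_degree": float(np.mean(internal_degrees)),
        "normalized_cut": float(np.mean(ncuts)),
    }
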