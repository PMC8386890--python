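"""Cover-comparison metrics against slow literal-formula oracles."""

import itertools
import math

import numpy as np
import pytest

import lpam

# ---------------------------------------------------------------- oracles


def _plogp(p):
    return 0.0 if p <= 0 else -p * math.log2(p)


def _onmi_oracle(cover_a, cover_b, universe, variant):
    """Literal entropy-based overlapping-NMI computed with explicit set
    arithmetic (no arrays), independent of the library implementation."""
    n = len(universe)
    uni = set(universe)
    ca = [set(c) for c in cover_a if c]
    cb = [set(c) for c in cover_b if c]

    def h_comm(x):
        return _plogp(len(x) / n) + _plogp(len(uni - x) / n)

    def cond_entropy(x, other):
        hx = h_comm(x)
        best = hx
        for y in other:
            n11 = len(x & y)
            n10 = len(x - y)
            n01 = len(y - x)
            n00 = n - n11 - n10 - n01
            if _plogp(n11 / n) + _plogp(n00 / n) < _plogp(n01 / n) + _plogp(n10 / n):
                continue
            hxy = (_plogp(n00 / n) + _plogp(n01 / n) + _plogp(n10 / n)
                   + _plogp(n11 / n))
            hy = _plogp(len(y) / n) + _plogp(len(uni - y) / n)
            best = min(best, hxy - hy)
        return best

    if variant == "lfk":
        def side(xs, ys):
            terms = []
            for x in xs:
                hx = h_comm(x)
                terms.append(cond_entropy(x, ys) / hx if hx > 0 else 0.0)
            return sum(terms) / len(terms)
        return 1.0 - 0.5 * (side(ca, cb) + side(cb, ca))
    hx_tot = sum(h_comm(x) for x in ca)
    hy_tot = sum(h_comm(y) for y in cb)
    info = 0.5 * ((hx_tot - sum(cond_entropy(x, cb) for x in ca))
                  + (hy_tot - sum(cond_entropy(y, ca) for y in cb)))
    denom = max(hx_tot, hy_tot)
    return info / denom if denom > 0 else 1.0


def _omega_oracle(cover_a, cover_b, universe):
    """Pair-by-pair omega index with explicit counting."""
    uni = sorted(universe, key=str)
    pairs = list(itertools.combinations(uni, 2))
    ta = [sum(1 for c in cover_a if u in c and v in c) for u, v in pairs]
    tb = [sum(1 for c in cover_b if u in c and v in c) for u, v in pairs]
    obs = sum(1 for a, b in zip(ta, tb) if a == b) / len(pairs)
    exp = sum(ta.count(j) * tb.count(j) for j in range(max(ta + tb) + 1)) \
        / len(pairs) ** 2
    if abs(1 - exp) < 1e-12:
        return 1.0 if abs(obs - 1) < 1e-12 else 0.0
    return (obs - exp) / (1 - exp)


def _f1_oracle(cover_a, cover_b):
    ca = [set(c) for c in cover_a if c]
    cb = [set(c) for c in cover_b if c]

    def side(xs, ys):
        total = 0.0
        for x in xs:
            best = 0.0
            for y in ys:
                tp = len(x & y)
                if tp == 0:
                    continue
                prec, rec = tp / len(y), tp / len(x)
                best = max(best, 2 * prec * rec / (prec + rec))
            total += best
        return total / len(xs)
    return 0.5 * (side(ca, cb) + side(cb, ca))


def _enumerate_small_covers(universe, max_communities=2):
    """All covers with at most two nonempty communities over the universe."""
    subsets = [frozenset(c) for r in range(1, len(universe) + 1)
               for c in itertools.combinations(universe, r)]
    covers = [[s] for s in subsets]
    covers += [[a, b] for a, b in itertools.combinations(subsets, 2)]
    return covers

# ----------------------------------------------------------------- tests

UNIVERSE6 = tuple("123456")


class TestAxioms:
    @pytest.mark.parametrize("metric", ["onmi_lfk", "onmi_max", "omega", "f1"])
    def test_identical_covers_score_one(self, metric):
        cover = lpam.Cover.from_sets([{"1", "2", "3"}, {"3", "4"}, {"5", "6"}])
        score = self._score(metric, cover, cover, UNIVERSE6)
        assert score == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("metric", ["onmi_lfk", "onmi_max", "omega", "f1"])
    def test_symmetry_and_label_invariance(self, metric):
        rng = np.random.default_rng(31)
        for _ in range(10):
            a = self._random_cover(rng)
            b = self._random_cover(rng)
            s_ab = self._score(metric, a, b, UNIVERSE6)
            s_ba = self._score(metric, b, a, UNIVERSE6)
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            # community order must not matter
            a_rev = lpam.Cover.from_sets(reversed(a.communities))
            assert self._score(metric, a_rev, b, UNIVERSE6) == pytest.approx(s_ab)
            # node relabeling must not matter
            ren = {v: v + "x" for v in UNIVERSE6}
            a2 = lpam.Cover.from_sets([{ren[v] for v in c} for c in a.communities])
            b2 = lpam.Cover.from_sets([{ren[v] for v in c} for c in b.communities])
            uni2 = tuple(ren[v] for v in UNIVERSE6)
            assert self._score(metric, a2, b2, uni2) == pytest.approx(s_ab)

    def test_bounds(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            a, b = self._random_cover(rng), self._random_cover(rng)
            assert 0.0 <= lpam.onmi(a, b, UNIVERSE6).value <= 1.0
            assert 0.0 <= lpam.onmi(a, b, UNIVERSE6, "max").value <= 1.0
            assert lpam.omega_index(a, b, UNIVERSE6).value <= 1.0
            assert 0.0 <= lpam.f1_best_match(a, b).value <= 1.0

    @staticmethod
    def _score(metric, a, b, universe):
        if metric.startswith("onmi"):
            return lpam.onmi(a, b, universe, metric.split("_")[1]).value
        if metric == "omega":
            return lpam.omega_index(a, b, universe).value
        return lpam.f1_best_match(a, b).value

    @staticmethod
    def _random_cover(rng):
        k = int(rng.integers(1, 4))
        comms = []
        while len(comms) < k:
            mask = rng.random(6) < rng.uniform(0.2, 0.9)
            if mask.any():
                comms.append({UNIVERSE6[i] for i in np.flatnonzero(mask)})
        return lpam.Cover.from_sets(comms)


class TestOnmi:
    def test_nested_cover_example_matches_oracle(self):
        a = [{"1", "2", "3"}, {"4", "5", "6"}]
        b = [{"1", "2", "3", "4", "5", "6"}]
        for variant in ("lfk", "max"):
            got = lpam.onmi(lpam.Cover.from_sets(a), lpam.Cover.from_sets(b),
                            UNIVERSE6, variant).value
            assert got == pytest.approx(_onmi_oracle(a, b, UNIVERSE6, variant))

    @pytest.mark.parametrize("variant", ["lfk", "max"])
    def test_exhaustive_three_node_covers(self, variant):
        universe = ("1", "2", "3")
        covers = _enumerate_small_covers(universe)
        for a, b in itertools.product(covers[:14], covers):
            got = lpam.onmi(lpam.Cover.from_sets(a), lpam.Cover.from_sets(b),
                            universe, variant).value
            assert got == pytest.approx(
                _onmi_oracle(a, b, universe, variant), abs=1e-12)

    def test_random_five_node_covers(self):
        rng = np.random.default_rng(13)
        universe = tuple("abcde")
        for _ in range(50):
            a = [set(np.random.default_rng(rng.integers(1 << 30)).choice(
                universe, rng.integers(1, 5), replace=False))
                for _ in range(rng.integers(1, 4))]
            b = [set(np.random.default_rng(rng.integers(1 << 30)).choice(
                universe, rng.integers(1, 5), replace=False))
                for _ in range(rng.integers(1, 4))]
            for variant in ("lfk", "max"):
                got = lpam.onmi(lpam.Cover.from_sets(a), lpam.Cover.from_sets(b),
                                universe, variant).value
                assert got == pytest.approx(
                    _onmi_oracle(a, b, universe, variant), abs=1e-12)

    def test_empty_universe_rejected(self):
        c = lpam.Cover.from_sets([{"1"}])
        with pytest.raises(ValueError):
            lpam.onmi(c, c, ())


class TestOmega:
    def test_crossed_partition_example(self):
        # a = {{1,2},{3,4}}, b = {{1,3},{2,4}} over 4 nodes: direct 6-pair table
        uni = ("1", "2", "3", "4")
        a = [{"1", "2"}, {"3", "4"}]
        b = [{"1", "3"}, {"2", "4"}]
        got = lpam.omega_index(lpam.Cover.from_sets(a),
                               lpam.Cover.from_sets(b), uni).value
        assert got == pytest.approx(_omega_oracle(a, b, uni))

    def test_exhaustive_small_covers(self):
        universe = ("1", "2", "3")
        covers = _enumerate_small_covers(universe)
        for a, b in itertools.product(covers[:14], covers):
            got = lpam.omega_index(lpam.Cover.from_sets(a),
                                   lpam.Cover.from_sets(b), universe).value
            assert got == pytest.approx(_omega_oracle(a, b, universe), abs=1e-12)

    def test_tiny_universe_rejected(self):
        c = lpam.Cover.from_sets([{"1"}])
        with pytest.raises(ValueError):
            lpam.omega_index(c, c, ("1",))


class TestF1:
    def test_closed_form_example(self):
        a = lpam.Cover.from_sets([{"1", "2", "3", "4"}])
        b = lpam.Cover.from_sets([{"1", "2"}])
        assert lpam.f1_best_match(a, b).value == pytest.approx(2.0 / 3.0)

    def test_exhaustive_small_covers(self):
        covers = _enumerate_small_covers(("1", "2", "3"))
        for a, b in itertools.product(covers[:14], covers):
            got = lpam.f1_best_match(lpam.Cover.from_sets(a),
                                     lpam.Cover.from_sets(b)).value
            assert got == pytest.approx(_f1_oracle(a, b), abs=1e-12)


class TestCoverStats:
    def test_lattice_quadrants(self, lattice8, lattice8_quadrants):
        rec = lpam.cover_stats(lattice8, lattice8_quadrants)
        assert rec["avg_internal_degree"] == pytest.approx(3.0)
        # 8/56 + 8/168 per quadrant
        assert rec["normalized_cut"] == pytest.approx(8 / 56 + 8 / 168)
        assert round(rec["normalized_cut"], 2) == 0.19

    def test_whole_graph_community(self, triangle, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="lpam.metrics"):
            rec = lpam.cover_stats(triangle, [{"a", "b", "c"}])
        assert rec["normalized_cut"] == 0.0
        assert rec["avg_internal_degree"] == pytest.approx(2.0)
        assert "degenerate" in caplog.text

    def test_empty_community_rejected(self, triangle):
        with pytest.raises(ValueError):
            lpam.cover_stats(triangle, [set()])
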