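import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methsponge.cmd_network import CandidatePair
from methsponge.sponge_predict import (
    ContingencyTable,
    count_unique_seed_sites,
    pearson_correlation,
    permutation_positive_test,
    shared_mirna_test,
)
from methsponge.types import InteractionTables, ValidationError


def point_probability(a: int, b: int, c: int, d: int) -> Fraction:
    """Hypergeometric point term, evaluated exactly from factorials."""
    n = a + b + c + d
    return Fraction(
        math.factorial(a + b) * math.factorial(c + d)
        * math.factorial(a + c) * math.factorial(b + d),
        math.factorial(a) * math.factorial(b) * math.factorial(c)
        * math.factorial(d) * math.factorial(n),
    )


def upper_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """Sum point terms over all margin-fixed tables with a' >= a."""
    total = Fraction(0)
    for a2 in range(a, min(a + b, a + c) + 1):
        b2, c2 = a + b - a2, a + c - a2
        d2 = d - (a - a2)
        if min(b2, c2, d2) < 0:
            continue
        total += point_probability(a2, b2, c2, d2)
    return float(total)


class TestSharedMirnaTest:
    def test_zero_overlap_gives_one(self):
        assert shared_mirna_test(ContingencyTable(0, 3, 2, 5, 10)) == 1.0

    def test_frozen_example_25_over_210(self):
        # a=3,b=1,c=1,d=5: tail = [C(4,3)C(6,1)+C(4,4)C(6,0)]/C(10,4) = 25/210
        p = shared_mirna_test(ContingencyTable(3, 1, 1, 5, 10))
        assert p == pytest.approx(25 / 210, abs=1e-12)
        assert upper_tail_oracle(3, 1, 1, 5) == pytest.approx(25 / 210, abs=1e-15)

    def test_point_term_all_ones(self):
        assert point_probability(1, 1, 1, 1) == Fraction(2, 3)

    def test_margin_inconsistency_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            shared_mirna_test(ContingencyTable(1, 1, 1, 1, 5))

    @given(
        st.tuples(
            st.integers(0, 8), st.integers(0, 8),
            st.integers(0, 8), st.integers(0, 8),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_enumeration_oracle(self, table):
        a, b, c, d = table
        tbl = ContingencyTable(a, b, c, d, a + b + c + d)
        assert shared_mirna_test(tbl) == pytest.approx(
            upper_tail_oracle(a, b, c, d), abs=1e-10
        )

    def test_monotone_non_increasing_in_a_at_fixed_margins(self):
        # fixed margins: row1 = a+b, col1 = a+c, n; slide a along its range
        n, row1, col1 = 18, 8, 7
        ps = []
        for a in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            b, c = row1 - a, col1 - a
            d = n - a - b - c
            ps.append(shared_mirna_test(ContingencyTable(a, b, c, d, n)))
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson_correlation(x, -x + 10)
        assert r == pytest.approx(-1.0)

    def test_frozen_three_point_example(self):
        # r = 3 / sqrt(2 * 42/9) = 0.98198...
        r, p = pearson_correlation([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(3 / np.sqrt(2 * 42 / 9), abs=1e-10)
        assert r == pytest.approx(0.9820, abs=5e-5)
        assert 0 < p < 1

    def test_constant_vector_is_error(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestPermutationTest:
    def test_perfect_correlation_attains_minimum(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        p = permutation_positive_test(x, x, n_perm=999, rng_seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 30))
        p1 = permutation_positive_test(x, y, n_perm=200, rng_seed=9)
        p2 = permutation_positive_test(x, y, n_perm=200, rng_seed=9)
        assert p1 == p2

    def test_negative_correlation_not_significant(self):
        x = np.linspace(0, 1, 25)
        p = permutation_positive_test(x, -x, n_perm=200, rng_seed=0)
        assert p > 0.9


class TestUniqueSeedSites:
    def _tables(self, records):
        mg = pd.DataFrame(
            records, columns=["mirna_id", "gene_id", "site_pos", "seed"]
        )
        cm = pd.DataFrame(
            [(f"c", m) for m in mg["mirna_id"].unique()],
            columns=["circ_id", "mirna_id"],
        )
        return InteractionTables(cm, mg)

    def test_same_seed_same_site_counts_once(self):
        inter = self._tables(
            [("m1", "g", 100, "ACGUACG"), ("m2", "g", 100, "ACGUACG")]
        )
        pair = CandidatePair("c", "g", {"m1", "m2"})
        assert count_unique_seed_sites(pair, inter) == 1

    def test_distinct_seeds_distinct_sites(self):
        inter = self._tables(
            [("m1", "g", 100, "ACGUACG"), ("m2", "g", 200, "UUUUAAA")]
        )
        pair = CandidatePair("c", "g", {"m1", "m2"})
        assert count_unique_seed_sites(pair, inter) == 2

    def test_matches_distinct_position_enumeration(self):
        # 10 miRNAs in 3 seed families over 9 positions
        rng = np.random.default_rng(4)
        seeds = ["AAAAAAA", "CCCCCCC", "GGGGGGG"]
        records = []
        positions = {}
        for i in range(10):
            seed = seeds[i % 3]
            pos = positions.setdefault(seed, int(rng.integers(1, 10)) * 100)
            records.append((f"m{i}", "g", pos, seed))
        # extra positions for some miRNAs at other genes (must not count)
        records.append(("m0", "other", 999, "AAAAAAA"))
        inter = self._tables(records)
        shared = {f"m{i}" for i in range(10)}
        pair = CandidatePair("c", "g", shared)
        expected = len({p for m, g, p, s in records if g == "g" and m in shared})
        assert count_unique_seed_sites(pair, inter) == expected

    def test_absent_driver_returns_zero(self):
        inter = self._tables([("m1", "g", 100, "ACGUACG")])
        pair = CandidatePair("c", "missing", {"m1"})
        assert count_unique_seed_sites(pair, inter) == 0
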