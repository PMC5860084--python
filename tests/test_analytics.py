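import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hocmine.analytics import (
    CooccurrenceCounts,
    choose_test,
    chi2_test,
    compare_queries,
    count_cooccurrence,
    cprob,
    fisher_exact,
    match_query,
    pmi_npmi,
    association_profile,
)
from hocmine.corpus_io import SentenceRecord


def sent(pmid, index, tokens, predicted=()):
    return SentenceRecord(
        pmid=pmid,
        index=index,
        text=" ".join(tokens),
        tokens=list(tokens),
        lemmas=[t.lower() for t in tokens],
        predicted_labels=set(predicted),
    )


class TestMatchQuery:
    corpus = [
        sent("1", 0, ["The", "P53", "protein"]),
        sent("1", 1, ["cell", "cycle", "arrest"]),
        sent("2", 0, ["cycle", "of", "cell"]),
    ]

    def test_casefold_single_token(self):
        assert match_query(self.corpus, "p53") == {("1", 0)}

    def test_phrase_requires_adjacency(self):
        assert match_query(self.corpus, "cell cycle") == {("1", 1)}

    def test_absent_query_empty(self):
        assert match_query(self.corpus, "banana") == set()

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            match_query(self.corpus, "   ")


class TestCounts:
    def test_constructed_fixture(self):
        sents = []
        for i in range(100):
            tokens = ["q"] if i < 10 else ["x"]
            predicted = {"3"} if i < 20 else set()
            sents.append(sent("p", i, tokens, predicted))
        matched = match_query(sents, "q")
        c = count_cooccurrence(sents, matched, "3")
        assert (c.N, c.n_q, c.n_h, c.n_hq) == (100, 10, 20, 10)

    def test_no_match(self):
        sents = [sent("p", 0, ["x"], {"3"})]
        c = count_cooccurrence(sents, set(), "3")
        assert c.n_q == 0 and c.n_hq == 0

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(4)
        sents = [
            sent(
                "p",
                i,
                ["q"] if rng.random() < 0.3 else ["x"],
                {"3"} if rng.random() < 0.4 else (),
            )
            for i in range(500)
        ]
        matched = match_query(sents, "q")
        c = count_cooccurrence(sents, matched, "3")
        n_q = sum(1 for s in sents if "q" in s.tokens)
        n_h = sum(1 for s in sents if "3" in s.predicted_labels)
        n_hq = sum(1 for s in sents if "q" in s.tokens and "3" in s.predicted_labels)
        assert (c.N, c.n_q, c.n_h, c.n_hq) == (500, n_q, n_h, n_hq)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_cooccurrence([], set(), "3")


class TestCprobPmiNpmi:
    def test_cprob_ratio(self):
        assert cprob(CooccurrenceCounts(100, 10, 20, 4)) == pytest.approx(0.4)

    def test_cprob_bounds(self):
        assert cprob(CooccurrenceCounts(100, 10, 20, 10)) == pytest.approx(1.0)
        assert cprob(CooccurrenceCounts(100, 0, 20, 0)) is None

    def test_printed_formula_example(self):
        pmi, npmi = pmi_npmi(CooccurrenceCounts(100, 10, 20, 10))
        assert pmi == pytest.approx(math.log(5), abs=1e-12)
        assert npmi == pytest.approx(math.log(5) / -math.log(0.1), abs=1e-12)

    def test_independence_gives_zero(self):
        pmi, npmi = pmi_npmi(CooccurrenceCounts(100, 20, 50, 10))
        assert pmi == pytest.approx(0.0, abs=1e-12)
        assert npmi == pytest.approx(0.0, abs=1e-12)

    def test_perfect_cooccurrence_gives_one(self):
        pmi, npmi = pmi_npmi(CooccurrenceCounts(100, 30, 30, 30))
        assert npmi == pytest.approx(1.0, abs=1e-12)

    def test_undefined_cases(self):
        assert pmi_npmi(CooccurrenceCounts(100, 10, 20, 0)) == (None, None)
        assert pmi_npmi(CooccurrenceCounts(100, 0, 20, 0)) == (None, None)
        # joint probability 1 leaves NPMI undefined (zero normalizer)
        pmi, npmi = pmi_npmi(CooccurrenceCounts(50, 50, 50, 50))
        assert pmi is not None and npmi is None

    @settings(max_examples=300, deadline=None)
    @given(st.data())
    def test_npmi_bounded_and_matches_arithmetic(self, data):
        N = data.draw(st.integers(min_value=1, max_value=1000), label="N")
        n_q = data.draw(st.integers(min_value=0, max_value=N), label="n_q")
        n_h = data.draw(st.integers(min_value=0, max_value=N), label="n_h")
        n_hq = data.draw(
            st.integers(min_value=max(0, n_q + n_h - N), max_value=min(n_q, n_h)),
            label="n_hq",
        )
        c = CooccurrenceCounts(N, n_q, n_h, n_hq)
        pmi, npmi = pmi_npmi(c)
        if n_hq == 0 or n_h == 0 or n_q == 0:
            assert pmi is None and npmi is None
            return
        expected_pmi = math.log((n_hq / N) / ((n_h / N) * (n_q / N)))
        assert pmi == pytest.approx(expected_pmi, abs=1e-12)
        if n_hq == N:
            assert npmi is None
        else:
            assert npmi == pytest.approx(expected_pmi / -math.log(n_hq / N), abs=1e-12)
            assert -1.0 - 1e-12 <= npmi <= 1.0 + 1e-12

    def test_pmi_symmetric_in_h_and_q(self):
        a = pmi_npmi(CooccurrenceCounts(200, 30, 70, 20))
        b = pmi_npmi(CooccurrenceCounts(200, 70, 30, 20))
        assert a == b


def fisher_oracle(table):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if 0 in (r1, r2, c1, b + d):
        return 1.0
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


class TestChooseTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (((1, 4), (3, 2)), "fisher"),
            (((50, 50), (50, 50)), "chi2"),
            (((5, 5), (5, 5)), "chi2"),  # expected counts equal 5: not < 5
        ],
    )
    def test_expected_frequency_rule(self, table, expected):
        assert choose_test(table) == expected

    def test_zero_marginal_routes_to_fisher_with_p_one(self):
        table = ((0, 0), (3, 2))
        assert choose_test(table) == "fisher"
        assert fisher_exact(table) == 1.0


class TestFisher:
    def test_uniform_table(self):
        assert fisher_exact(((5, 5), (5, 5))) == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_two_by_two(self):
        assert fisher_exact(((2, 0), (0, 2))) == pytest.approx(1 / 3, abs=1e-15)

    def test_exhaustive_small_tables_match_oracle(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        table = ((a, b), (c, d))
                        assert fisher_exact(table) == pytest.approx(
                            fisher_oracle(table), abs=1e-12
                        ), table

    def test_random_tables_match_oracle_and_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            table = ((a, b), (c, d))
            ours = fisher_exact(table)
            assert ours == pytest.approx(fisher_oracle(table), abs=1e-12)
            _, scipy_p = stats.fisher_exact([[a, b], [c, d]])
            assert ours == pytest.approx(scipy_p, abs=1e-7)


class TestChi2:
    def test_proportional_table_p_one(self):
        assert chi2_test(((20, 30), (40, 60))) == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        from scipy import stats

        table = ((30, 10), (10, 30))
        # Pearson sum: all expected counts are 20 -> chi2 = 4 * 100/20 = 20
        expected_stat = 20.0
        p = chi2_test(table)
        assert p == pytest.approx(float(stats.chi2.sf(expected_stat, df=1)), abs=1e-12)

    def test_transpose_invariance(self):
        assert chi2_test(((12, 25), (33, 41))) == pytest.approx(
            chi2_test(((12, 33), (25, 41)))
        )


class TestCompareQueries:
    def _corpus(self):
        sents = []
        for i in range(60):
            sents.append(sent("A", i, ["alpha", "filler"], {"3"} if i < 40 else ()))
        for i in range(60):
            sents.append(sent("B", i, ["beta", "filler"], {"3"} if i < 10 else ()))
        return sents

    def test_identical_queries_p_one(self, taxonomy):
        corpus = self._corpus()
        result = compare_queries(corpus, "filler", "filler", taxonomy, codes=["3"])
        assert result.per_node["3"].p_raw == pytest.approx(1.0)

    def test_bonferroni_uses_node_count(self, taxonomy):
        corpus = self._corpus()
        result = compare_queries(corpus, "alpha", "beta", taxonomy)
        assert result.n_tests == 37
        comp = result.per_node["3"]
        assert comp.p_corrected == pytest.approx(min(1.0, 37 * comp.p_raw))

    def test_constructed_effect_significant(self, taxonomy):
        corpus = self._corpus()
        result = compare_queries(corpus, "alpha", "beta", taxonomy)
        assert result.per_node["3"].p_corrected < 0.05

    def test_swap_symmetry(self, taxonomy):
        corpus = self._corpus()
        ab = compare_queries(corpus, "alpha", "beta", taxonomy, codes=["3"])
        ba = compare_queries(corpus, "beta", "alpha", taxonomy, codes=["3"])
        assert ab.per_node["3"].p_raw == pytest.approx(ba.per_node["3"].p_raw)

    def test_empty_match_rejected(self, taxonomy):
        with pytest.raises(ValueError, match="matches no sentences"):
            compare_queries(self._corpus(), "banana", "beta", taxonomy)


class TestAssociationProfile:
    def test_profile_reports_all_nodes(self, taxonomy):
        corpus = [
            sent("A", i, ["q", "w"], {"3", "3.1"} if i % 2 else {"6"})
            for i in range(20)
        ]
        result = association_profile(corpus, "q", taxonomy)
        assert set(result.per_node) == set(taxonomy.codes)
        assoc = result.per_node["3"]
        assert assoc.cprob == pytest.approx(0.5)
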