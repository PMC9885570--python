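"""ORA exactness, term-overlap accounting and TF binding-frequency statistics."""

import math

import numpy as np
import pytest

from dgnet.enrichment import (
    hypergeometric_ora,
    results_frame,
    term_overlap,
    tf_binding_frequency,
)
from dgnet.io import GeneSetLibrary


def exact_upper_tail(overlap, big_n, k_term, n_query):
    """P(X >= overlap) for X ~ Hypergeom(N, K, n), by direct summation of the
    combinatorial mass function."""
    total = 0
    for x in range(overlap, min(k_term, n_query) + 1):
        total += (
            math.comb(k_term, x)
            * math.comb(big_n - k_term, n_query - x)
            / math.comb(big_n, n_query)
        )
    return total


def _library(term_members):
    return GeneSetLibrary(
        "lib", {t: (".", frozenset(m)) for t, m in term_members.items()}
    )


class TestHypergeometricOra:
    def test_exact_example_n20(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3", "g10"}  # overlap 4
        res = hypergeometric_ora(query, universe, _library({"T": term}), 1.0)
        assert res[0].overlap == 4
        assert res[0].p == pytest.approx(exact_upper_tail(4, 20, 5, 5), abs=1e-12)

    def test_certain_event_p_one(self):
        genes = {f"g{i}" for i in range(8)}
        res = hypergeometric_ora(genes, genes, _library({"T": genes}), 1.0)
        assert res[0].p == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_term_absent_from_results(self):
        universe = {f"g{i}" for i in range(10)}
        library = _library({"HIT": {"g0", "g1"}, "MISS": {"g8", "g9"}})
        res = hypergeometric_ora({"g0", "g1"}, universe, library, 1.0)
        assert {r.term for r in res} == {"HIT"}

    def test_query_outside_universe_listed(self):
        with pytest.raises(ValueError, match="gX"):
            hypergeometric_ora({"gX"}, {"g0"}, _library({"T": {"g0"}}), 1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            hypergeometric_ora(set(), {"g0"}, _library({"T": {"g0"}}), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_cases_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        big_n = int(rng.integers(8, 26))
        universe = [f"g{i}" for i in range(big_n)]
        term = set(rng.choice(universe, size=rng.integers(1, big_n + 1), replace=False))
        query = set(rng.choice(universe, size=rng.integers(1, big_n + 1), replace=False))
        res = hypergeometric_ora(query, set(universe), _library({"T": term}), 1.0)
        overlap = len(term & query)
        if overlap == 0:
            assert res == []
        else:
            expected = exact_upper_tail(overlap, big_n, len(term), len(query))
            assert res[0].p == pytest.approx(expected, abs=1e-12)

    def test_enlarging_query_never_decreases_p(self, rng):
        universe = {f"g{i}" for i in range(30)}
        term = {f"g{i}" for i in range(8)}
        query = {"g0", "g1", "g2"}
        lib = _library({"T": term})
        p_small = hypergeometric_ora(query, universe, lib, 1.0)[0].p
        p_large = hypergeometric_ora(query | {"g20"}, universe, lib, 1.0)[0].p
        assert p_large >= p_small

    def test_bh_fdr_monotone_in_p(self, rng):
        universe = [f"g{i}" for i in range(40)]
        terms = {
            f"T{k}": set(rng.choice(universe, size=8, replace=False)) for k in range(12)
        }
        query = set(universe[:10])
        res = hypergeometric_ora(query, set(universe), _library(terms), 1.0)
        ps = [r.p for r in res]
        fdrs = [r.fdr for r in res]
        assert ps == sorted(ps)
        assert all(f >= p for p, f in zip(ps, fdrs))
        assert (np.diff(fdrs) >= -1e-12).all()

    def test_term_restricted_to_universe(self):
        universe = {f"g{i}" for i in range(10)}
        library = _library({"T": {"g0", "g1", "OUTSIDER"}})
        res = hypergeometric_ora({"g0"}, universe, library, 1.0)
        assert res[0].term_size == 2

    def test_results_frame_columns(self):
        genes = {f"g{i}" for i in range(5)}
        res = hypergeometric_ora(genes, genes, _library({"T": genes}), 1.0)
        frame = results_frame(res)
        assert list(frame.columns) == [
            "term", "overlap", "set_size", "term_size", "universe_size", "p", "fdr",
        ]


class TestTermOverlap:
    def test_identical_lists_all_shared(self):
        table, counts = term_overlap({"A": ["t1", "t2"], "B": ["t1", "t2"]})
        assert counts == {"n_terms_total": 2, "n_terms_shared": 2}

    def test_disjoint_lists_none_shared(self):
        _, counts = term_overlap({"A": ["t1"], "B": ["t2"]})
        assert counts == {"n_terms_total": 2, "n_terms_shared": 0}

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            term_overlap({"A": ["t1"]})

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"t{i}" for i in range(20)]
        sets = {
            name: set(rng.choice(pool, size=rng.integers(0, 12), replace=False))
            for name in ("A", "B", "C")
        }
        table, counts = term_overlap(sets)
        union = sets["A"] | sets["B"] | sets["C"]
        shared = {t for t in union if sum(t in s for s in sets.values()) >= 2}
        assert counts["n_terms_total"] == len(union)
        assert counts["n_terms_shared"] == len(shared)
        for _, row in table.iterrows():
            assert row["n_sets"] == sum(row[name] for name in sets)


class TestTfBindingFrequency:
    def test_every_gene_in_two_sets(self):
        lib = _library({"TF1": {"g0", "g1"}, "TF2": {"g0", "g1"}})
        summary = tf_binding_frequency({"g0", "g1"}, lib)
        assert summary.mean_tfs_per_gene == 2.0
        assert summary.tf_set == {"TF1", "TF2"}

    def test_uncovered_gene_contributes_zero(self):
        lib = _library({"TF1": {"g0"}})
        summary = tf_binding_frequency({"g0", "g1"}, lib)
        assert summary.mean_tfs_per_gene == 0.5
        assert summary.per_gene_counts["g1"] == 0

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            tf_binding_frequency(set(), _library({"TF1": {"g0"}}))

    def test_planted_poisson_rates_recovered(self):
        # plant per-gene TF membership counts: Poisson(6) for set A's genes,
        # Poisson(2) for set B's; the recovered means must sit within 3 SE
        # and their ratio near 3
        rng = np.random.default_rng(77)
        set_a = [f"a{i}" for i in range(300)]
        set_b = [f"b{i}" for i in range(300)]
        n_tfs = 40
        membership: dict[str, set] = {f"TF{k}": set() for k in range(n_tfs)}
        for genes, lam in ((set_a, 6.0), (set_b, 2.0)):
            for g in genes:
                for k in rng.choice(n_tfs, size=min(rng.poisson(lam), n_tfs), replace=False):
                    membership[f"TF{k}"].add(g)
        lib = _library({t: m for t, m in membership.items() if m})
        mean_a = tf_binding_frequency(set(set_a), lib).mean_tfs_per_gene
        mean_b = tf_binding_frequency(set(set_b), lib).mean_tfs_per_gene
        assert abs(mean_a - 6.0) <= 3 * math.sqrt(6.0 / 300)
        assert abs(mean_b - 2.0) <= 3 * math.sqrt(2.0 / 300)
        assert mean_a / mean_b == pytest.approx(3.0, rel=0.2)
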