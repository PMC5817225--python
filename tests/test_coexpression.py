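"""Fisher-z correlation p-values, percentile edge selection, and
hypergeometric GO enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from lncnet import coexpression as coex


class TestFisherZ:
    def test_identity_gives_r_one_p_capped(self):
        x = np.arange(10.0)
        r, p = coex.pcc_with_p(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert 0 < p <= 1e-12  # numerically r may sit one ulp below 1

    def test_zero_correlation_gives_p_one(self):
        assert coex.fisher_z_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_printed_example_r08_n12(self):
        """atanh(0.8)*3 = 3.296, two-sided p ~ 9.8e-4."""
        z = math.atanh(0.8) * math.sqrt(12 - 3)
        assert z == pytest.approx(3.296, abs=1e-3)
        p = coex.fisher_z_pvalue(0.8, 12)
        assert p == pytest.approx(math.erfc(z / math.sqrt(2)), rel=1e-12)
        assert p == pytest.approx(9.8e-4, abs=5e-5)

    def test_matches_erfc_oracle_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            r = float(rng.uniform(-0.999, 0.999))
            n = int(rng.integers(4, 200))
            z = abs(math.atanh(r)) * math.sqrt(n - 3)
            oracle = math.erfc(z / math.sqrt(2.0))
            assert coex.fisher_z_pvalue(r, n) == pytest.approx(oracle, rel=1e-10)

    def test_pcc_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, _ = coex.pcc_with_p(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            brute = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
            assert r == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_returns_nan_marker(self):
        r, p = coex.pcc_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)


class TestNetworkSelection:
    def _expr(self, n_lnc, n_mrna, n_samples, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"s{i}" for i in range(n_samples)]
        lnc = pd.DataFrame(rng.lognormal(1, 1, (n_lnc, n_samples)),
                           index=[f"L{i}" for i in range(n_lnc)], columns=cols)
        mrna = pd.DataFrame(rng.lognormal(1, 1, (n_mrna, n_samples)),
                            index=[f"M{i}" for i in range(n_mrna)], columns=cols)
        return lnc, mrna

    def test_edge_count_bound_before_p_filter(self):
        lnc, mrna = self._expr(1, 1000, 10)
        edges = coex.build_cnc_network(lnc, mrna, percentile=0.0001, adj_p_max=2.0)
        # ceil(0.0001*1000)=1 top + 1 bottom (ties would add, generic data has none)
        assert len(edges) == 2

    def test_planted_correlated_pair_recovered_with_positive_sign(self):
        rng = np.random.default_rng(2)
        cols = [f"s{i}" for i in range(10)]
        base = rng.normal(0, 1, 10)
        lnc = pd.DataFrame([2.0 ** (base + rng.normal(0, 0.1, 10))], index=["L0"], columns=cols)
        rows = [2.0 ** (base + rng.normal(0, 0.1, 10))] + [
            rng.lognormal(0, 1, 10) for _ in range(99)
        ]
        mrna = pd.DataFrame(rows, index=[f"M{i}" for i in range(100)], columns=cols)
        edges = coex.build_cnc_network(lnc, mrna, percentile=0.0001, adj_p_max=0.05)
        hit = [e for e in edges if e.mrna_id == "M0"]
        assert hit and hit[0].pcc > 0.9 and hit[0].sign == "positive"

    def test_sample_permutation_leaves_edges_invariant(self):
        lnc, mrna = self._expr(5, 50, 12, seed=3)
        edges1 = coex.build_cnc_network(lnc, mrna, percentile=0.01, adj_p_max=1.5)
        perm = np.random.default_rng(4).permutation(12)
        cols = [lnc.columns[i] for i in perm]
        edges2 = coex.build_cnc_network(lnc[cols], mrna[cols], percentile=0.01, adj_p_max=1.5)
        key = lambda es: sorted((e.lnc_id, e.mrna_id, round(e.pcc, 10)) for e in es)
        assert key(edges1) == key(edges2)

    def test_no_shared_samples_is_an_error(self):
        lnc, _ = self._expr(2, 2, 5)
        _, mrna = self._expr(2, 2, 5)
        mrna.columns = [f"t{i}" for i in range(5)]
        with pytest.raises(ValueError, match="share no sample"):
            coex.build_cnc_network(lnc, mrna)


class TestHypergeometric:
    def test_zero_overlap_gives_one(self):
        u = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        hood = {f"g{i}" for i in range(90, 95)}
        assert coex.hypergeometric_enrichment(hood, term, u) == pytest.approx(1.0)

    def test_everything_overlaps_gives_one(self):
        u = {f"g{i}" for i in range(20)}
        assert coex.hypergeometric_enrichment(u, u, u) == pytest.approx(1.0)

    def test_matches_direct_tail_summation(self):
        universe = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(50)}
        hood = {f"g{i}" for i in range(45, 55)}  # overlap 5, |hood| 10
        p = coex.hypergeometric_enrichment(hood, term, universe)
        N, K, n, k = 1000, 50, 10, 5
        oracle = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(n, K) + 1)
        )
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            coex.hypergeometric_enrichment(set(), set(), set())

    def test_monotone_in_overlap(self):
        u = {f"g{i}" for i in range(200)}
        term = {f"g{i}" for i in range(30)}
        last = 1.1
        for extra in range(6):
            hood = {f"g{i}" for i in range(extra)} | {f"g{i}" for i in range(100, 110 - extra)}
            p = coex.hypergeometric_enrichment(hood, term, u)
            assert p <= last + 1e-12
            last = p


class TestFunctionAnnotation:
    def _gene2go(self, mapping):
        rows = [(g, t, "biological_process") for g, terms in mapping.items() for t in terms]
        return pd.DataFrame(rows, columns=["gene_id", "go_id", "namespace"])

    def test_min_genes_rule_rejects_small_neighborhood_terms(self):
        universe_genes = {f"M{i}": ["GO:X"] if i < 4 else ["GO:Y"] for i in range(100)}
        g2g = self._gene2go(universe_genes)
        edges = [coex.CoexpressionEdge("L0", f"M{i}", 0.9, 1e-6, 1e-5) for i in range(4)]
        calls = coex.annotate_lncrna_functions(edges, g2g)
        x = next(c for c in calls if c.go_id == "GO:X")
        assert x.p_value < 0.01  # enriched...
        assert not x.annotated  # ...but only 4 genes carry the term

    def test_shared_term_neighborhood_is_annotated(self):
        mapping = {f"M{i}": ["GO:HIT"] if i < 6 else [f"GO:{i % 7}"] for i in range(120)}
        g2g = self._gene2go(mapping)
        edges = [coex.CoexpressionEdge("L0", f"M{i}", 0.9, 1e-6, 1e-5) for i in range(6)]
        calls = coex.annotate_lncrna_functions(edges, g2g)
        hit = next(c for c in calls if c.go_id == "GO:HIT")
        assert hit.annotated and hit.n_neighborhood_term_genes == 6

    def test_lncrna_without_neighbors_yields_no_calls(self):
        g2g = self._gene2go({"M0": ["GO:A"]})
        assert coex.annotate_lncrna_functions([], g2g) == []

    def test_shuffled_annotations_rarely_pass(self):
        """Label permutation calibration: with random gene->term maps, about
        1% of (lncRNA, term) tests pass at p <= 0.01."""
        rng = np.random.default_rng(5)
        genes = [f"M{i}" for i in range(300)]
        n_pass = n_tests = 0
        for rep in range(30):
            mapping = {g: [f"GO:{rng.integers(0, 20)}"] for g in genes}
            g2g = self._gene2go(mapping)
            hood = rng.choice(genes, size=15, replace=False)
            edges = [coex.CoexpressionEdge("L0", m, 0.9, 1e-6, 1e-5) for m in hood]
            for c in coex.annotate_lncrna_functions(edges, g2g, min_genes=1):
                n_tests += 1
                n_pass += c.p_value <= 0.01
        assert n_pass / n_tests < 0.05  # ~1% expected; generous stochastic bound
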