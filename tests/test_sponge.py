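import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongecerna.config import RunConfig
from spongecerna.diffexpr import size_factors
from spongecerna.pipeline import normalized_log2
from spongecerna.sponge import (
    build_group_network,
    build_sponge_network,
    candidate_pairs,
    filter_pairs,
    mirna_universe,
    shared_mirna_test,
    sponge_correlation,
)
from spongecerna.stats import hypergeom_tail
from spongecerna.synthetic import simulate_cohort, truth_eval


def enumeration_tail(k, N, K, n):
    """Brute-force hypergeometric tail: enumerate all C(N, n) draws."""
    from math import comb

    total = comb(N, n)
    hits = sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    )
    return hits / total


class TestSharedMirnaTest:
    def test_exact_tail_small_example(self):
        # N=10, K=4, n=5, m=3: enumeration gives 66/252
        universe = {f"m{i}" for i in range(10)}
        lnc = {"m0", "m1", "m2", "m3"}
        mrna = {"m0", "m1", "m2", "m8", "m9"}
        res = shared_mirna_test(lnc, mrna, universe)
        assert res["m"] == 3
        assert res["hyper_p"] == pytest.approx(66 / 252, rel=1e-12)

    def test_disjoint_sets_give_p_one(self):
        universe = {f"m{i}" for i in range(10)}
        res = shared_mirna_test({"m0"}, {"m9"}, universe)
        assert res["m"] == 0 and res["hyper_p"] == 1.0

    def test_degenerate_full_overlap(self):
        universe = {f"m{i}" for i in range(6)}
        res = shared_mirna_test(universe, universe, universe)
        assert res["m"] == 6 and res["hyper_p"] == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            shared_mirna_test({"zz"}, {"m0"}, {"m0"})

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(2, 25), st.data())
    def test_equals_enumeration_for_small_universes(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_tail(k, N, K, n) == pytest.approx(
            enumeration_tail(k, N, K, n), rel=1e-9, abs=1e-12)

    def test_monotone_nonincreasing_in_m(self):
        ps = [hypergeom_tail(m, 20, 8, 10) for m in range(0, 9)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestCandidatePairs:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["miRNA_id", "target_id"])

    def test_only_sharing_pairs_emitted(self):
        lnc = self._edges([("m1", "L1"), ("m2", "L1"), ("m3", "L2")])
        mrna = self._edges([("m1", "G1"), ("m2", "G1"), ("m9", "G2")])
        uni = {"m1", "m2", "m3", "m9"}
        pairs = candidate_pairs(lnc, mrna, uni)
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert (row["lncrna"], row["mrna"], row["shared_m"]) == ("L1", "G1", 2)
        assert set(row["shared_set"].split(";")) == {"m1", "m2"}

    def test_gene_restriction(self):
        lnc = self._edges([("m1", "L1"), ("m1", "L2")])
        mrna = self._edges([("m1", "G1")])
        pairs = candidate_pairs(lnc, mrna, {"m1"}, lnc_genes={"L2"})
        assert pairs["lncrna"].tolist() == ["L2"]

    def test_matches_single_pair_test(self):
        rng = np.random.default_rng(8)
        uni = [f"m{i}" for i in range(15)]
        lnc_rows = [(m, "L1") for m in rng.choice(uni, 6, replace=False)]
        mrna_rows = [(m, "G1") for m in rng.choice(uni, 7, replace=False)]
        pairs = candidate_pairs(self._edges(lnc_rows), self._edges(mrna_rows), set(uni))
        single = shared_mirna_test({m for m, _ in lnc_rows},
                                   {m for m, _ in mrna_rows}, set(uni))
        if single["m"] == 0:
            assert pairs.empty
        else:
            assert pairs.iloc[0]["hyper_p"] == pytest.approx(single["hyper_p"], rel=1e-12)


class TestSpongeCorrelation:
    def _pairs(self):
        return pd.DataFrame({
            "lncrna": ["L1", "L2"], "mrna": ["G1", "G2"],
            "shared_m": [3, 3], "hyper_p": [1e-4, 1e-4],
            "n_mirna_lnc": [3, 3], "n_mirna_mrna": [3, 3], "universe_n": [10, 10],
            "shared_set": ["m1;m2;m3", "m1;m2;m3"],
        })

    def _expr(self, rows, index):
        cols = [f"s{j}" for j in range(len(rows[0]))]
        return pd.DataFrame(rows, index=index, columns=cols)

    def test_identical_vectors_r_one(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        lnc = self._expr([v, v], ["L1", "L2"])
        mrna = self._expr([v, [5.0, 4.0, 3.0, 2.0, 1.0]], ["G1", "G2"])
        out = sponge_correlation(self._pairs(), lnc, mrna, lnc.columns)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert out["pearson_r"].iloc[1] == pytest.approx(-1.0)
        kept = filter_pairs(out, RunConfig())
        assert kept["lncrna"].tolist() == ["L1"]  # anti-correlated pair ineligible

    def test_zero_variance_pair_dropped(self):
        lnc = self._expr([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]], ["L1", "L2"])
        mrna = self._expr([[1, 2, 3, 4, 5], [2, 3, 4, 5, 6]], ["G1", "G2"])
        out = sponge_correlation(self._pairs(), lnc, mrna, lnc.columns)
        assert bool(out["dropped"].iloc[0]) and not bool(out["dropped"].iloc[1])
        assert filter_pairs(out)["lncrna"].tolist() == ["L2"]

    def test_too_few_samples_rejected(self):
        lnc = self._expr([[1, 2, 3]], ["L1"])
        with pytest.raises(ValueError, match="4 samples"):
            sponge_correlation(self._pairs().head(1), lnc, lnc, lnc.columns)


class TestNetwork:
    def test_empty_network_is_valid(self, tmp_path):
        net = build_sponge_network(pd.DataFrame(
            columns=["lncrna", "mrna", "pearson_r", "shared_m", "hyper_p",
                     "corr_p", "corr_p_adj", "shared_set"]), "high")
        assert net.summary()["n_edges"] == 0
        net.write(tmp_path / "empty.tsv")
        assert (tmp_path / "empty.tsv").read_text().count("\n") == 1  # header only

    def test_single_pair_graph_structure(self):
        edges = pd.DataFrame({
            "lncrna": ["L1"], "mrna": ["G1"], "pearson_r": [0.8],
            "shared_m": [3], "hyper_p": [1e-5], "shared_set": ["m1;m2;m3"],
        })
        net = build_sponge_network(edges, "low")
        g = net.graph(include_mirnas=True)
        assert g.number_of_nodes() == 5  # L1, G1 and 3 miRNAs
        assert g.has_edge("L1", "G1")
        assert net.sponge_degree()["L1"] == 1

    def test_edge_count_monotone_as_thresholds_tighten(self, small_cohort):
        c = small_cohort
        uni = mirna_universe(c.interactions["mirna_lncrna"], c.interactions["mirna_mrna"],
                             c.expression["miRNA"].genes)
        pairs = candidate_pairs(c.interactions["mirna_lncrna"],
                                c.interactions["mirna_mrna"], uni)
        log_lnc = normalized_log2(c.expression["lncRNA"], size_factors(c.expression["lncRNA"]))
        log_mrna = normalized_log2(c.expression["mRNA"], size_factors(c.expression["mRNA"]))
        samples = list(c.clinical.loc[c.clinical["risk_group_true"] == "low", "sample_id"])
        tested = sponge_correlation(pairs, log_lnc, log_mrna, samples)
        loose = RunConfig(sponge_p=0.05, corr_adj_p=0.2, sponge_min_shared=2)
        tight = RunConfig(sponge_p=0.005, corr_adj_p=0.01, sponge_min_shared=4)
        assert len(filter_pairs(tested, tight)) <= len(filter_pairs(tested, loose))

    def test_planted_triplets_recovered(self, small_cohort):
        c = small_cohort
        uni = mirna_universe(c.interactions["mirna_lncrna"], c.interactions["mirna_mrna"],
                             c.expression["miRNA"].genes)
        pairs = candidate_pairs(c.interactions["mirna_lncrna"],
                                c.interactions["mirna_mrna"], uni)
        log_lnc = normalized_log2(c.expression["lncRNA"], size_factors(c.expression["lncRNA"]))
        log_mrna = normalized_log2(c.expression["mRNA"], size_factors(c.expression["mRNA"]))
        recovered = set()
        for grp in ("low", "high"):
            samples = list(c.clinical.loc[c.clinical["risk_group_true"] == grp, "sample_id"])
            net = build_group_network(pairs, log_lnc, log_mrna, samples, grp)
            recovered |= net.pair_set()
        res = truth_eval(recovered, c.truth.pair_set())
        assert res["recall"] >= 0.6 and res["precision"] >= 0.7
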