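import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qsp import cmap, simulate
from qsp.cmap import (
    connectivity_score,
    ks_enrichment,
    permutation_pvalues,
    prioritize,
    score_query,
    summarize_max_quantile,
    summarize_most_negative,
)
from qsp.signatures import GeneSignature

from conftest import brute_force_es


class TestKSEnrichment:
    def test_single_top_gene(self):
        assert ks_enrichment(list("abcd"), {"a"}) == pytest.approx(0.75)

    def test_single_bottom_gene(self):
        assert ks_enrichment(list("abcd"), {"d"}) == pytest.approx(-1.0)

    def test_matches_enumeration_oracle_on_all_subsets(self):
        """Every non-empty proper subset of universes up to n = 8."""
        for n in range(2, 9):
            genes = [f"g{i}" for i in range(n)]
            for size in range(1, n):
                for combo in itertools.combinations(genes, size):
                    got = ks_enrichment(genes, set(combo))
                    want = brute_force_es(genes, set(combo))
                    assert got == pytest.approx(want, abs=1e-12), (n, combo)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(50):
            k = rng.integers(1, 29)
            s = set(rng.choice(genes, size=k, replace=False))
            assert -1.0 <= ks_enrichment(genes, s) <= 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ks_enrichment(list("abc"), set())

    def test_missing_genes_named(self):
        with pytest.raises(ValueError, match="zz"):
            ks_enrichment(list("abc"), {"a", "zz"})


class TestConnectivityScore:
    def test_sign_agreement_is_zero(self):
        assert connectivity_score(0.5, 0.3) == 0.0
        assert connectivity_score(-0.5, -0.3) == 0.0

    def test_opposed_signs_half_difference(self):
        assert connectivity_score(0.6, -0.4) == pytest.approx(0.5)
        assert connectivity_score(-0.6, 0.4) == pytest.approx(-0.5)

    def test_zero_es_agrees_with_anything(self):
        assert connectivity_score(0.0, 0.8) == 0.0
        assert connectivity_score(0.8, 0.0) == 0.0

    def test_rule_over_grid(self):
        """CS combine rule over a dense grid: zero on sign agreement,
        (up - down)/2 otherwise, and antisymmetric under swap."""
        grid = np.linspace(-1, 1, 101)
        for up in grid:
            for down in grid:
                cs = connectivity_score(up, down)
                if up == 0 or down == 0 or np.sign(up) == np.sign(down):
                    assert cs == 0.0
                else:
                    assert cs == pytest.approx((up - down) / 2)
                assert connectivity_score(down, up) == pytest.approx(-cs if cs != 0 else 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            connectivity_score(1.2, 0.0)


class TestScoreQuery:
    def test_one_row_per_instance(self, small_db, toy_signature):
        db, _ = small_db
        res = score_query(db, toy_signature)
        assert len(res) == db.n_instances()
        assert set(res.columns) >= {"instance_id", "ES_up", "ES_down", "CS"}

    def test_perfect_reverter_approaches_minus_one(self):
        """Up-genes at the ranking bottom and down-genes at the top give the
        most negative CS the discrete statistic allows: ES_up = -1 and
        ES_down = 1 - t/n, so CS -> -1 as the universe grows."""
        n = 2000
        universe = [f"g{i:05d}" for i in range(n)]
        sig = GeneSignature("s1", "c", "C1", up={universe[-1]}, down={universe[0]})
        scores = np.arange(n, 0, -1.0)
        meta = pd.DataFrame(
            {"compound_id": ["c1"], "cell_type": ["A"], "time": [6.0], "dose": [1.0]},
            index=pd.Index(["i1"], name="instance_id"),
        )
        from qsp.io import PerturbationDB

        db = PerturbationDB(meta=meta, profiles=pd.DataFrame({"i1": scores}, index=universe))
        res = score_query(db, sig)
        assert res["ES_up"].iloc[0] == pytest.approx(-1.0)
        assert res["ES_down"].iloc[0] == pytest.approx(1.0 - 1.0 / n)
        assert res["CS"].iloc[0] == pytest.approx(-1.0, abs=1e-3)

    def test_up_down_swap_negates_nonzero_cs(self, small_db, toy_signature):
        db, _ = small_db
        res = score_query(db, toy_signature)
        swapped = GeneSignature("sw", "c", "C1", up=toy_signature.down, down=toy_signature.up)
        res2 = score_query(db, swapped)
        nz = res["CS"] != 0
        np.testing.assert_allclose(res2.loc[nz, "CS"].to_numpy(), -res.loc[nz, "CS"].to_numpy())

    def test_empty_signature_rejected(self, small_db):
        db, _ = small_db
        empty = GeneSignature("s0", "c", "C1")
        with pytest.raises(ValueError, match="empty"):
            score_query(db, empty)

    def test_planted_reverters_score_negative(self, small_db, toy_signature):
        db, truth = small_db
        res = score_query(db, toy_signature)
        reverters = {c for c, s in truth.compound_reverter.items() if s}
        assert (res.loc[res["compound_id"].isin(reverters), "CS"] < 0).all()


class TestPermutationPvalues:
    def test_zero_cs_gets_p_one(self, small_db, toy_signature):
        db, _ = small_db
        res = score_query(db, toy_signature)
        res.loc[:, "CS"] = 0.0
        out = permutation_pvalues(db, toy_signature, res, n_perm=200, seed=0)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_extreme_cs_hits_floor(self, small_db, toy_signature):
        db, _ = small_db
        res = score_query(db, toy_signature)
        res.loc[:, "CS"] = -1.0
        out = permutation_pvalues(db, toy_signature, res, n_perm=500, seed=0)
        assert (out["p"] <= (1 + 1) / 501).all()

    def test_small_n_perm_warns(self, small_db, toy_signature):
        db, _ = small_db
        res = score_query(db, toy_signature)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_pvalues(db, toy_signature, res, n_perm=50, seed=0)

    def test_null_pvalues_uniform(self):
        """Calibration: on a pure-noise database, randomized permutation
        p-values are uniform (KS test vs U(0,1) not rejected at 0.01), and
        the conservative default is valid, P(p <= a) <= a."""
        universe = [f"g{i}" for i in range(120)]
        sig = GeneSignature("s1", "c", "C1",
                            up=set(universe[:8]), down=set(universe[8:16]))
        cfg = simulate.PerturbConfig(
            n_compounds=50, n_instances_per_compound=4, n_reverters=0, seed=21
        )
        db, _ = simulate.generate_perturbation_db(cfg, [sig], universe=universe)
        res = score_query(db, sig)
        out = permutation_pvalues(db, sig, res, n_perm=2000, seed=5, smooth=True)
        stat, p = stats.kstest(out["p"], "uniform")
        assert p > 0.01
        cons = permutation_pvalues(db, sig, res, n_perm=2000, seed=5)
        n = len(cons)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            # binomial slack on the empirical rejection rate
            assert (cons["p"] <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)


class TestSummaries:
    def _results(self, cs, compounds=None, cells=None):
        n = len(cs)
        return pd.DataFrame(
            {
                "instance_id": [f"i{k}" for k in range(n)],
                "compound_id": compounds or ["c1"] * n,
                "cell_type": cells or ["A"] * n,
                "CS": cs,
            }
        )

    def test_most_negative_minimum(self):
        out = summarize_most_negative(self._results([0.2, -0.7, -0.1]))
        assert out["summary"].iloc[0] == pytest.approx(-0.7)

    def test_most_negative_positive_scores(self):
        out = summarize_most_negative(self._results([0.3, 0.5]))
        assert out["summary"].iloc[0] == pytest.approx(0.3)

    def test_single_instance_identity(self):
        out = summarize_most_negative(self._results([-0.42]))
        assert out["summary"].iloc[0] == pytest.approx(-0.42)
        out = summarize_max_quantile(self._results([-0.42]), normalize=False)
        assert out["Q_lo"].iloc[0] == out["Q_hi"].iloc[0] == pytest.approx(-0.42)
        assert out["summary"].iloc[0] == pytest.approx(-0.42)

    def test_max_quantile_worked_case(self):
        out = summarize_max_quantile(self._results([-0.9, -0.5, 0.1]), normalize=False)
        assert out["Q_lo"].iloc[0] == pytest.approx(-0.636, abs=1e-3)
        assert out["Q_hi"].iloc[0] == pytest.approx(-0.296, abs=1e-3)
        assert out["summary"].iloc[0] == pytest.approx(-0.636, abs=1e-3)

    def test_all_negative_scores_summary_is_qlo(self):
        out = summarize_max_quantile(self._results([-0.8, -0.6, -0.3, -0.2]), normalize=False)
        assert out["summary"].iloc[0] == out["Q_lo"].iloc[0]

    def test_summary_is_extreme_quantile(self):
        rng = np.random.default_rng(3)
        cs = list(rng.uniform(-1, 1, size=9))
        out = summarize_max_quantile(
            self._results(cs, compounds=["c1"] * 5 + ["c2"] * 4), normalize=False
        )
        for _, row in out.iterrows():
            assert row["summary"] in (row["Q_lo"], row["Q_hi"])
            assert abs(row["summary"]) == pytest.approx(max(abs(row["Q_lo"]), abs(row["Q_hi"])))

    def test_cell_type_normalization_scales_by_mean_magnitude(self):
        res = self._results([-0.4, -0.2, 0.3], cells=["A", "A", "A"])
        out = summarize_max_quantile(res, normalize=True)
        # negatives scaled by mean(|-0.4|,|-0.2|) = 0.3; positive by 0.3
        norm = [-0.4 / 0.3, -0.2 / 0.3, 1.0]
        q_lo = np.percentile(norm, 33)
        assert out["Q_lo"].iloc[0] == pytest.approx(q_lo)


class TestPrioritize:
    def _summary(self, query, rows):
        return pd.DataFrame(
            [
                {"compound_id": c, "query_id": query, "summary": s, "q": q}
                for c, s, q in rows
            ]
        )

    def test_frequency_counts_queries_hit(self):
        s1 = self._summary("q1", [("a", -0.9, 0.01), ("b", -0.5, 0.01), ("c", 0.2, 0.01)])
        s2 = self._summary("q2", [("a", -0.8, 0.01), ("c", -0.1, 0.01)])
        s3 = self._summary("q3", [("b", -0.7, 0.01)])
        out = prioritize([s1, s2, s3], top_n=2, fdr_alpha=0.05).table
        assert out.set_index("compound_id").loc["a", "frequency"] == 2

    def test_positive_summary_within_top_n_retained(self):
        s1 = self._summary("q1", [("a", 0.3, 0.01)])
        out = prioritize([s1], top_n=5, fdr_alpha=0.05).table
        assert "a" in set(out["compound_id"])

    def test_fdr_filter_applies(self):
        s1 = self._summary("q1", [("a", -0.9, 0.5), ("b", -0.5, 0.01)])
        out = prioritize([s1], top_n=5, fdr_alpha=0.05).table
        assert set(out["compound_id"]) == {"b"}

    def test_tie_break_by_compound_id(self):
        s1 = self._summary("q1", [("zed", -0.9, 0.01), ("abc", -0.9, 0.01)])
        out = prioritize([s1], top_n=5, fdr_alpha=0.05).table
        # equal frequency; ranks differ by score-tie ordering (id ascending)
        assert list(out["compound_id"]) == ["abc", "zed"]

    def test_zero_queries_rejected(self):
        with pytest.raises(ValueError):
            prioritize([])


class TestReverterRecovery:
    def test_planted_reverters_top_ranked_across_seeds(self):
        """Reverters planted in the perturbation DB occupy the top
        frequency ranks of the prioritization in nearly every seed."""
        universe = [f"g{i}" for i in range(150)]
        sigs = [
            GeneSignature(f"s{k}", "c", "C1",
                          up=set(universe[20 * k : 20 * k + 10]),
                          down=set(universe[20 * k + 10 : 20 * k + 20]))
            for k in range(3)
        ]
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = simulate.PerturbConfig(
                n_compounds=20, n_instances_per_compound=3, n_reverters=3,
                reversal_strength=6.0, seed=100 + seed,
            )
            db, truth = simulate.generate_perturbation_db(cfg, sigs, universe=universe)
            summaries = []
            for sig in sigs:
                res = score_query(db, sig)
                res = permutation_pvalues(db, sig, res, n_perm=1000, seed=seed)
                summaries.append(summarize_most_negative(res, query_id=sig.index))
            table = prioritize(summaries, top_n=5, fdr_alpha=0.05).table
            reverters = {c for c, s in truth.compound_reverter.items() if s}
            if set(table["compound_id"].head(len(reverters))) == reverters:
                wins += 1
        assert wins >= n_seeds - 1
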