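"""Differential inclusion test, BH-FDR oracle, calls and rank integration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom as sp_betabinom

from qkisplice.diffsplice import (
    MethodRanking,
    bh_fdr,
    call_differential,
    integrate_method_rankings,
    intersect_evidence_sets,
)
from qkisplice.diffsplice import ranking_from_table
from qkisplice.diffsplice import test_exon_inclusion as exon_inclusion_test
from qkisplice.io import DataError
from qkisplice.stats import betabinom_loglik


def brute_bh(p):
    """Textbook step-up BH, written independently of the implementation."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        q[i] = running
    return q


class TestBhFdr:
    def test_reference_triplet(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        perm = rng.permutation(40)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_exhaustive_grid_against_oracle(self):
        """All sorted p-lists of length <= 6 on the 0.05 grid match brute BH.

        BH is permutation-equivariant (asserted above), so enumerating
        sorted lists covers every list on the grid exactly.
        """
        grid = [round(0.05 * k, 2) for k in range(1, 21)]
        for length in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, length):
                got = bh_fdr(list(combo))
                want = brute_bh(combo)
                assert np.allclose(got, want, atol=1e-12), combo

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(200)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_sm)


def binomial_lrt_oracle(ka, na, kb, nb):
    """Numeric binomial (dispersion->0) LRT statistic for cross-checking."""
    def ll(k, n, mu):
        k, n = np.asarray(k, float), np.asarray(n, float)
        return float(np.sum(k * np.log(mu) + (n - k) * np.log1p(-mu)))

    def fit(k, n):
        res = minimize_scalar(
            lambda m: -ll(k, n, min(max(m, 1e-9), 1 - 1e-9)),
            bounds=(1e-6, 1 - 1e-6), method="bounded",
        )
        return -res.fun

    alt = fit(ka, na) + fit(kb, nb)
    null = fit(np.concatenate([ka, kb]), np.concatenate([na, nb]))
    return 2.0 * (alt - null)


class TestExonInclusionTest:
    def test_identical_counts_give_p_one_delta_zero(self):
        r = exon_inclusion_test([50, 50], [50, 50], [50, 50], [50, 50])
        assert r["p_value"] >= 0.99
        assert r["delta_psi"] == 0.0

    def test_strong_effect_detected(self):
        """A=(50 inc,50 skip)x3 vs B=(90,10)x3 is decisively significant."""
        r = exon_inclusion_test([50] * 3, [50] * 3, [90] * 3, [10] * 3)
        assert r["p_value"] < 0.01
        r_chisq = exon_inclusion_test([50] * 3, [50] * 3, [90] * 3, [10] * 3,
                                      reference="chisq")
        assert r_chisq["p_value"] < 1e-3
        assert r["delta_psi"] == pytest.approx(90 / 110 - 50 / 150, abs=0.01)
        # a free shared dispersion can only absorb between-condition spread
        # under the null, so the statistic is bounded by the binomial LRT
        oracle = binomial_lrt_oracle([50] * 3, [150] * 3, [90] * 3, [110] * 3)
        assert 0 < r["stat"] <= oracle * 1.001

    def test_likelihood_machinery_matches_binomial_oracle_at_zero_dispersion(self):
        """With the precision pinned at its binomial limit, the beta-binomial
        log-likelihood ratio reproduces the numeric binomial LRT."""
        ka, na = np.array([48.0, 52, 50]), np.array([150.0, 148, 152])
        kb, nb = np.array([88.0, 91, 90]), np.array([110.0, 112, 108])
        s = 1e9

        def profile_mu(k, n):
            mu = np.clip(k.sum() / n.sum(), 1e-9, 1 - 1e-9)
            return betabinom_loglik(k, n, mu, s)

        stat_bb = 2.0 * (
            profile_mu(ka, na) + profile_mu(kb, nb)
            - profile_mu(np.concatenate([ka, kb]), np.concatenate([na, nb]))
        )
        oracle = binomial_lrt_oracle(ka, na, kb, nb)
        assert stat_bb == pytest.approx(oracle, rel=1e-4)

    def test_label_swap_flips_delta_keeps_p(self):
        a = ([40, 55, 47], [60, 45, 50])
        b = ([80, 85, 90], [20, 18, 12])
        r1 = exon_inclusion_test(*a, *b)
        r2 = exon_inclusion_test(*b, *a)
        assert r1["p_value"] == pytest.approx(r2["p_value"], rel=1e-6)
        assert r1["delta_psi"] == pytest.approx(-r2["delta_psi"], abs=1e-12)

    def test_single_replicate_reduces_to_contingency_chi2(self):
        from scipy.stats import chi2_contingency

        r = exon_inclusion_test([50], [50], [90], [10])
        stat, p, _, _ = chi2_contingency(
            [[50, 100], [90, 20]], correction=False
        )
        assert r["p_value"] == pytest.approx(p)

    def test_all_zero_counts_missing(self):
        r = exon_inclusion_test([0, 0], [0, 0], [0, 0], [0, 0])
        assert np.isnan(r["p_value"])

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            exon_inclusion_test([-1], [5], [5], [5])

    def test_power_monotone_in_coverage_and_effect(self):
        """Larger coverage and larger ΔPSI both drive the statistic up."""
        stats_cov = []
        for cov in (20, 60, 180):
            inc_a = [int(cov * 0.4)] * 3
            skip_a = [int(cov * 0.3)] * 3
            inc_b = [int(cov * 0.7)] * 3
            skip_b = [int(cov * 0.15)] * 3
            stats_cov.append(
                exon_inclusion_test(inc_a, skip_a, inc_b, skip_b)["stat"]
            )
        assert stats_cov[0] < stats_cov[1] < stats_cov[2]
        stats_eff = []
        for inc_b in (60, 80, 95):
            stats_eff.append(
                exon_inclusion_test([50] * 3, [25] * 3, [inc_b] * 3,
                                    [(100 - inc_b) // 2] * 3)["stat"]
            )
        assert stats_eff[0] < stats_eff[1] < stats_eff[2]


class TestBetabinomLoglik:
    def test_matches_scipy_betabinom(self):
        k = np.array([3.0, 7.0, 5.0])
        n = np.array([10.0, 12.0, 9.0])
        mu, s = 0.55, 17.0
        want = sp_betabinom.logpmf(k, n, mu * s, (1 - mu) * s).sum()
        assert betabinom_loglik(k, n, mu, s) == pytest.approx(want, rel=1e-10)


class TestCallDifferential:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["event_id", "delta_psi", "p_value",
                                           "stat", "q_value"])

    @pytest.mark.parametrize(
        "delta,q,called,stringent",
        [(0.04, 0.01, False, False),   # below the 5% ΔPSI threshold
         (0.25, 0.20, False, False),   # fails FDR
         (0.50, 0.001, True, True),    # passes both, above 20%
         (0.10, 0.01, True, False)],   # called but not stringent
    )
    def test_thresholds(self, delta, q, called, stringent):
        res = call_differential(
            self._results([("E1", delta, 0.001, 10.0, q)])
        )
        assert bool(res.called.iloc[0]) is called
        assert bool(res.stringent.iloc[0]) is stringent

    def test_direction_labels(self):
        res = call_differential(self._results([
            ("E1", 0.5, 1e-5, 30.0, 1e-4), ("E2", -0.5, 1e-5, 30.0, 1e-4),
        ]))
        assert res.set_index("event_id").direction.tolist() == [
            "inclusion", "skipping"]


class TestRankIntegration:
    def test_unanimous_first_stays_first(self):
        r = integrate_method_rankings([
            MethodRanking("m1", ("A", "B", "C")),
            MethodRanking("m2", ("A", "C", "B")),
            MethodRanking("m3", ("A", "B", "C")),
        ])
        assert r.event_id.iloc[0] == "A"
        assert r.integrated_rank.iloc[0] == 1

    def test_score_tie_broken_by_event_id(self):
        r = integrate_method_rankings([
            MethodRanking("m1", ("A", "B")),
            MethodRanking("m2", ("B", "A")),
        ])
        assert r.score.nunique() == 1
        assert r.event_id.tolist() == ["A", "B"]

    def test_absent_event_penalty_brute_force(self):
        """Rank-1-in-one-list vs rank-2-in-all: compare numeric rank sums."""
        nB = nC = 3
        r = integrate_method_rankings([
            MethodRanking("m1", ("solo", "x", "both")),
            MethodRanking("m2", ("x", "both", "y")),
            MethodRanking("m3", ("x", "both", "y")),
        ])
        scores = r.set_index("event_id").score
        assert scores["solo"] == 1 + (nB + 1) + (nC + 1)
        assert scores["both"] == 3 + 2 + 2
        assert scores["both"] < scores["solo"]

    def test_invariant_to_ranking_order(self):
        ms = [MethodRanking("m1", ("A", "B", "C")),
              MethodRanking("m2", ("C", "A")),
              MethodRanking("m3", ("B",))]
        r1 = integrate_method_rankings(ms)
        r2 = integrate_method_rankings(ms[::-1])
        pd.testing.assert_series_equal(r1.event_id, r2.event_id)

    def test_duplicates_rejected(self):
        with pytest.raises(DataError):
            MethodRanking("bad", ("A", "A"))


class TestIntersectEvidence:
    def test_disjoint(self):
        both, counts, _ = intersect_evidence_sets({"a", "b"}, {"c"})
        assert both == set()
        assert counts == {"only_A": 2, "both": 0, "only_B": 1}

    def test_identical(self):
        both, counts, _ = intersect_evidence_sets({"a", "b"}, {"a", "b"})
        assert both == {"a", "b"}
        assert counts["both"] == 2

    def test_partial_overlap(self):
        both, _, prov = intersect_evidence_sets({"a", "b", "c"}, {"b", "c", "d"})
        assert both == {"b", "c"}
        assert prov.set_index("gene").loc["d", "A"] == False  # noqa: E712


class TestRankingFromTable:
    def test_rmats_dialect_and_native_columns(self, tmp_path):
        f = tmp_path / "SE.MATS.JC.txt"
        f.write_text("ID\tPValue\tFDR\nE3\t0.2\t0.3\nE1\t0.001\t0.01\nE2\t0.05\t0.1\n")
        r = ranking_from_table(f, "rmats")
        assert r.events == ("E1", "E2", "E3")
        g = tmp_path / "native.tsv"
        g.write_text("event_id\tp_value\nB\t0.5\nA\t0.01\n")
        assert ranking_from_table(g, "native").events == ("A", "B")

    def test_missing_columns_rejected(self, tmp_path):
        f = tmp_path / "x.tsv"
        f.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(DataError):
            ranking_from_table(f, "x")
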