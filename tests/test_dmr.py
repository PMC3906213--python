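"""Within-pair and between-group tests, combined ranking, family screen,
skew test and cross-design overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinmeth as tm
from twinmeth.dmr import (
    DmrResults,
    PairDelta,
    between_group_test,
    combined_rank,
    cross_design_overlap,
    family_screen,
    pair_deltas,
    skew_test,
    within_pair_test,
)
from twinmeth.exceptions import DesignError, TwinMethError


def delta_from_matrix(values, design="asd", pair_ids=None) -> PairDelta:
    values = np.atleast_2d(np.asarray(values, float))
    pair_ids = pair_ids or [f"P{i + 1:02d}" for i in range(values.shape[1])]
    probes = [f"cg{i:08d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=probes, columns=pair_ids)
    return PairDelta(beta=frame, transformed=frame.copy(), design=design)


def one_sample_t_oracle(x):
    """Textbook one-sample t against 0 with a two-sided t(n-1) p-value."""
    x = np.asarray(x, float)
    n = x.size
    mean = x.sum() / n
    var = ((x - mean) ** 2).sum() / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return t, p


class TestPairDeltas:
    def test_orientation_is_affected_minus_unaffected(self, small_cohort,
                                                      small_preprocessed):
        pp = small_preprocessed
        sheet = small_cohort.sample_sheet
        delta = pair_deltas(pp.beta, pp.transformed, sheet, "asd")
        pair = delta.pairs[0]
        members = sheet[sheet["pair_id"] == pair]
        affected = members.loc[members["asd_affected"], "sample_id"].iloc[0]
        well = members.loc[~members["asd_affected"], "sample_id"].iloc[0]
        expected = pp.beta[affected] - pp.beta[well]
        np.testing.assert_allclose(delta.beta[pair], expected)

    def test_identical_twins_give_zero(self):
        beta = pd.DataFrame({"P01-A": [0.5, 0.6], "P01-B": [0.5, 0.6],
                             "P02-A": [0.2, 0.3], "P02-B": [0.2, 0.3]})
        sheet = pd.DataFrame(
            {
                "sample_id": ["P01-A", "P01-B", "P02-A", "P02-B"],
                "pair_id": ["P01", "P01", "P02", "P02"],
                "member": ["A", "B", "A", "B"],
                "group": ["discordant_asd"] * 4,
                "asd_affected": [True, False, True, False],
            }
        )
        delta = pair_deltas(beta, beta, sheet, "asd")
        assert (delta.beta.to_numpy() == 0).all()

    def test_pair_without_unique_affected_is_error(self):
        beta = pd.DataFrame({"P01-A": [0.5], "P01-B": [0.5]})
        sheet = pd.DataFrame(
            {
                "sample_id": ["P01-A", "P01-B"],
                "pair_id": ["P01", "P01"],
                "member": ["A", "B"],
                "group": ["discordant_asd"] * 2,
                "asd_affected": [True, True],
            }
        )
        with pytest.raises(DesignError, match="unique affected"):
            pair_deltas(beta, beta, sheet, "asd")


class TestWithinPairTest:
    def test_matches_closed_form_oracle(self):
        deltas = [0.04, 0.06, 0.08, 0.08, 0.10, 0.10]
        records, _ = within_pair_test(delta_from_matrix([deltas]))
        t_exp, p_exp = one_sample_t_oracle(deltas)
        assert records["t"].iloc[0] == pytest.approx(t_exp, rel=1e-12)
        assert records["p_value"].iloc[0] == pytest.approx(p_exp, rel=1e-12)

    def test_symmetric_deltas_give_t_zero_p_one(self):
        records, _ = within_pair_test(
            delta_from_matrix([[-0.05, 0.05, -0.05, 0.05]])
        )
        assert records["t"].iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert records["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_probe_excluded_and_flagged(self):
        records, degenerate = within_pair_test(
            delta_from_matrix([[0.0, 0.0, 0.0], [0.1, 0.2, 0.3]])
        )
        assert degenerate == ["cg00000000"]
        assert records["probe_id"].tolist() == ["cg00000001"]

    def test_single_pair_directs_to_family_screen(self):
        with pytest.raises(DesignError, match="family_screen"):
            within_pair_test(delta_from_matrix([[0.2]]))

    def test_oracle_agreement_on_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(3, 12)
            deltas = rng.normal(0, 0.05, int(n))
            records, _ = within_pair_test(delta_from_matrix([deltas]))
            t_exp, p_exp = one_sample_t_oracle(deltas)
            assert records["t"].iloc[0] == pytest.approx(t_exp, rel=1e-10)
            assert records["p_value"].iloc[0] == pytest.approx(p_exp, rel=1e-10)


class TestBetweenGroupTest:
    def frame(self, arr, samples):
        probes = [f"cg{i:08d}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=probes, columns=samples)

    def test_identical_groups_give_p_one(self, rng):
        base = rng.uniform(0.2, 0.8, (20, 3))
        arr = np.hstack([base, base])
        samples = [f"c{i}" for i in range(3)] + [f"k{i}" for i in range(3)]
        frame = self.frame(arr, samples)
        records, _ = between_group_test(frame, frame, samples[:3], samples[3:])
        assert (records["t"] == 0).all()
        assert (records["p_value"] == 1).all()

    def test_shifted_probe_attains_smallest_p(self, rng):
        arr = rng.normal(0.0, 1.0, (200, 16))
        arr[17, :6] += 5.0  # cases shifted at one probe
        samples = [f"c{i}" for i in range(6)] + [f"k{i}" for i in range(10)]
        frame = self.frame(arr, samples)
        records, _ = between_group_test(frame, frame, samples[:6], samples[6:])
        # brute-force oracle over all probes
        oracle_p = [
            stats.ttest_ind(arr[g, :6], arr[g, 6:], equal_var=False).pvalue
            for g in range(200)
        ]
        assert records.loc[records["p_value"].idxmin(), "probe_id"] == "cg00000017"
        assert int(np.argmin(oracle_p)) == 17
        np.testing.assert_allclose(records["p_value"], oracle_p, rtol=1e-12)

    def test_unbalanced_sporadic_vs_familial_sizes_accepted(self, rng):
        arr = rng.normal(size=(10, 16))
        samples = [f"s{i}" for i in range(6)] + [f"f{i}" for i in range(10)]
        frame = self.frame(arr, samples)
        records, _ = between_group_test(frame, frame, samples[:6], samples[6:])
        assert len(records) == 10

    def test_overlapping_groups_rejected(self, rng):
        frame = self.frame(rng.normal(size=(3, 4)), list("abcd"))
        with pytest.raises(DesignError, match="overlap"):
            between_group_test(frame, frame, ["a", "b"], ["b", "c"])


class TestCombinedRank:
    def records(self, rows):
        return pd.DataFrame(
            [
                {"probe_id": pid, "mean_delta_beta": mdb, "t": 1.0, "p_value": p}
                for pid, p, mdb in rows
            ]
        )

    def test_hand_computed_example(self):
        # p-ranks A1, C2, B3; magnitude-ranks B1, C2, A3; all rank-sums tie
        # at 4, so the order falls back to smaller p: A, C, B
        ranked = combined_rank(
            self.records([("A", 0.001, 0.02), ("B", 0.01, 0.10),
                          ("C", 0.005, 0.05)])
        )
        assert ranked["probe_id"].tolist() == ["A", "C", "B"]
        assert ranked["combined_score"].tolist() == [4.0, 4.0, 4.0]
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_single_probe_gets_rank_one(self):
        ranked = combined_rank(self.records([("A", 0.5, 0.01)]))
        assert ranked["rank"].tolist() == [1]

    def test_full_tie_breaks_on_probe_id(self):
        ranked = combined_rank(
            self.records([("B", 0.01, 0.05), ("A", 0.01, 0.05)])
        )
        assert ranked["probe_id"].tolist() == ["A", "B"]

    def test_invariant_to_input_order_and_monotone_rescaling(self, rng):
        rows = [
            (f"cg{i:04d}", float(p), float(m))
            for i, (p, m) in enumerate(
                zip(rng.uniform(1e-6, 1, 50), rng.uniform(0, 0.3, 50))
            )
        ]
        base = combined_rank(self.records(rows))["probe_id"].tolist()
        shuffled = [rows[i] for i in rng.permutation(50)]
        assert combined_rank(self.records(shuffled))["probe_id"].tolist() == base
        rescaled = [(pid, p / 7.0, m * 3.0) for pid, p, m in rows]
        assert combined_rank(self.records(rescaled))["probe_id"].tolist() == base

    def test_bonferroni_flag_annotates_not_truncates(self):
        rows = [("A", 1e-9, 0.1)] + [
            (f"B{i}", 0.5, 0.01) for i in range(9)
        ]
        ranked = combined_rank(self.records(rows))
        assert len(ranked) == 10
        flagged = ranked.loc[ranked["bonferroni_significant"], "probe_id"]
        assert flagged.tolist() == ["A"]


class TestFamilyScreen:
    def test_inclusive_boundary(self):
        delta = delta_from_matrix(
            np.array([[0.15], [0.149], [-0.20]])
        )
        hits = family_screen(delta, threshold=0.15)
        assert hits["probe_id"].tolist() == ["cg00000000", "cg00000002"]

    def test_shared_direction_annotation(self):
        # one probe hit in two pairs, both hypomethylated
        values = np.zeros((2, 4))
        values[0, 1] = -0.19  # pair 2
        values[0, 3] = -0.28  # pair 4
        values[1, 1] = 0.21
        hits = family_screen(delta_from_matrix(values), threshold=0.15)
        probe0 = hits[hits["probe_id"] == "cg00000000"].set_index("pair_id")
        assert probe0.loc["P02", "shared_with"] == "P04"
        assert probe0.loc["P04", "shared_with"] == "P02"
        assert (probe0["direction"] == "hypo").all()
        assert hits.loc[hits["probe_id"] == "cg00000001",
                        "shared_with"].iloc[0] == ""

    def test_opposite_signs_not_shared(self):
        values = np.array([[0.2, -0.2]])
        hits = family_screen(delta_from_matrix(values), threshold=0.15)
        assert (hits["shared_with"] == "").all()

    def test_no_hits_gives_empty_frame(self):
        hits = family_screen(delta_from_matrix([[0.01, 0.02]]), threshold=0.15)
        assert hits.empty

    def test_threshold_validated(self):
        with pytest.raises(TwinMethError, match="threshold"):
            family_screen(delta_from_matrix([[0.1]]), threshold=1.5)


class TestSkewTest:
    def test_identical_distributions(self, rng):
        values = rng.normal(0, 0.02, (500, 6))
        a = delta_from_matrix(values)
        b = delta_from_matrix(values.copy(), design="unaffected")
        res = skew_test(a, b)
        assert res.ks_statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_shift_equals_ecdf_gap(self, rng):
        x = rng.normal(0.05, 0.01, (400, 1))
        y = x + 0.004
        res = skew_test(delta_from_matrix(x), delta_from_matrix(y, "unaffected"))
        # brute-force empirical CDF comparison
        xs = np.abs(x).mean(axis=1)
        ys = np.abs(y).mean(axis=1)
        grid = np.sort(np.concatenate([xs, ys]))
        gap = max(
            abs((xs <= g).mean() - (ys <= g).mean()) for g in grid
        )
        assert res.ks_statistic == pytest.approx(gap, abs=1e-12)
        assert 0 < res.p_value < 1

    def test_inflated_variance_minority_detected(self, rng):
        n = 23000
        disc = rng.normal(0, 0.028, (n, 6))
        disc[: n // 20] *= 3.0  # 5% of probes with inflated spread
        conc = rng.normal(0, 0.028, (n, 6))
        res = skew_test(delta_from_matrix(disc),
                        delta_from_matrix(conc, "unaffected"))
        assert res.p_value < 1e-6

    def test_top_k_means_reported(self, rng):
        values = rng.normal(0, 0.02, (100, 4))
        ranked = pd.DataFrame(
            {"probe_id": [f"cg{i:08d}" for i in range(100)],
             "rank": np.arange(1, 101)}
        )
        res = skew_test(
            delta_from_matrix(values),
            delta_from_matrix(values * 0.5, "unaffected"),
            ranked=ranked,
            top_k=10,
        )
        top = [f"cg{i:08d}" for i in range(10)]
        expected = np.abs(values[:10]).mean()
        assert res.top_mean_abs_discordant == pytest.approx(expected)
        assert res.top_mean_abs_comparison == pytest.approx(expected / 2)


def results_from_order(order, design):
    n = len(order)
    records = pd.DataFrame(
        {
            "probe_id": order,
            "rank": np.arange(1, n + 1),
            "combined_score": np.arange(1, n + 1, dtype=float),
        }
    )
    return DmrResults(records=records, design=design, n_units=6,
                      n_probes_tested=n, bonferroni_cutoff=0.05 / n)


class TestCrossDesignOverlap:
    def test_identical_lists(self):
        probes = [f"cg{i:08d}" for i in range(100)]
        res = {d: results_from_order(probes, d) for d in ("a", "b")}
        overlap, corr = cross_design_overlap(res, k=50)
        assert len(overlap) == 50
        assert (overlap["n_designs_top_k"] == 2).all()
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_lists_near_zero_correlation(self, rng):
        probes = [f"cg{i:08d}" for i in range(20000)]
        res = {
            "a": results_from_order(list(rng.permutation(probes)), "a"),
            "b": results_from_order(list(rng.permutation(probes)), "b"),
        }
        _, corr = cross_design_overlap(res, k=50)
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_probe_in_two_top_lists_appears_once_with_both_ranks(self):
        probes = [f"cg{i:08d}" for i in range(200)]
        order_b = [probes[0]] + probes[:0:-1]  # top hit shared, rest reversed
        res = {
            "a": results_from_order(probes, "a"),
            "b": results_from_order(order_b, "b"),
        }
        overlap, _ = cross_design_overlap(res, k=50)
        shared = overlap[overlap["probe_id"] == probes[0]]
        assert len(shared) == 1
        assert shared["rank_a"].iloc[0] == 1
        assert shared["rank_b"].iloc[0] == 1

    def test_needs_two_designs(self):
        with pytest.raises(DesignError):
            cross_design_overlap({"a": results_from_order(["x"], "a")})
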