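"""QC filtering, quantile normalization, beta computation and both VSTs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twinmeth as tm
import twinmeth.arrayio as aio
from twinmeth.exceptions import ValidationError
from twinmeth.preprocess import EmpiricalNormalVST, EmpiricalVarianceVST


def signals_from_frames(meth, unmeth, detp) -> aio.SignalSet:
    return aio.SignalSet(meth, unmeth, detp)


def simple_signals(detp_values, blacklist=()):
    probes = ["A", "B", "C"]
    samples = ["s1", "s2"]
    ones = pd.DataFrame(1000.0, index=probes, columns=samples)
    detp = pd.DataFrame(detp_values, index=probes, columns=samples)
    manifest = pd.DataFrame(
        {
            "probe_id": probes,
            "chromosome": ["1", "2", "3"],
            "position": [100, 200, 300],
            "gene": ["GA", "GB", "GC"],
            "blacklisted": [p in blacklist for p in probes],
        }
    )
    return signals_from_frames(ones, ones.copy(), detp), manifest


class TestFilterProbes:
    def test_detection_then_blacklist_rules(self):
        signals, manifest = simple_signals(
            [[0.01, 0.01], [0.01, 0.06], [0.01, 0.01]], blacklist=("C",)
        )
        filtered, report = tm.filter_probes(signals, manifest)
        assert list(filtered.probes) == ["A"]
        assert report.removed["detection"] == ["B"]
        assert report.removed["blacklist"] == ["C"]
        assert report.n_retained == 1

    def test_threshold_boundary_is_strict(self):
        signals, manifest = simple_signals([[0.05, 0.05]] * 3)
        _, report = tm.filter_probes(signals, manifest)
        assert report.n_removed_detection == 0
        assert report.n_retained == 3

    def test_clean_input_removes_nothing(self):
        signals, manifest = simple_signals([[0.0, 0.0]] * 3)
        _, report = tm.filter_probes(signals, manifest)
        assert (report.n_removed_detection, report.n_removed_blacklist) == (0, 0)

    def test_everything_removed_is_hard_error(self):
        signals, manifest = simple_signals([[0.9, 0.9]] * 3)
        with pytest.raises(ValidationError, match="all probes removed"):
            tm.filter_probes(signals, manifest)

    def test_blacklisted_failing_probe_counts_under_detection(self):
        signals, manifest = simple_signals(
            [[0.01, 0.01], [0.06, 0.01], [0.01, 0.01]], blacklist=("B",)
        )
        _, report = tm.filter_probes(signals, manifest)
        assert report.removed["detection"] == ["B"]
        assert report.n_removed_blacklist == 0


class TestQuantileNormalize:
    def test_two_column_oracle(self):
        layer = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = tm.quantile_normalize(layer)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_identical_columns_unchanged(self):
        layer = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = tm.quantile_normalize(layer)
        pd.testing.assert_frame_equal(out, layer)

    def test_idempotent(self, rng):
        layer = pd.DataFrame(rng.uniform(0, 100, (200, 5)))
        once = tm.quantile_normalize(layer)
        twice = tm.quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(),
                                   atol=1e-12)

    def test_ties_get_mean_of_spanned_reference(self):
        layer = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [10.0, 20.0, 30.0]})
        out = tm.quantile_normalize(layer)
        ref = [(1 + 10) / 2, (1 + 20) / 2, (2 + 30) / 2]  # [5.5, 10.5, 16]
        # the tied pair in column a spans reference ranks 1-2
        assert out["a"].tolist() == [8.0, 8.0, 16.0]
        assert out["b"].tolist() == ref

    def test_rank_order_preserved_and_columns_identical(self, rng):
        layer = pd.DataFrame(rng.normal(size=(500, 8)))
        out = tm.quantile_normalize(layer)
        for col in layer:
            assert (
                out[col].rank().to_numpy() == layer[col].rank().to_numpy()
            ).all()
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.ptp(sorted_cols, axis=1).max() == 0.0

    def test_single_column_warns_and_returns_identity(self):
        layer = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning, match=">=2 samples"):
            out = tm.quantile_normalize(layer)
        pd.testing.assert_frame_equal(out, layer)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(100.0, 0.0, 1.0), (0.0, 100.0, 0.0), (50.0, 150.0, 0.25)],
    )
    def test_closed_form(self, m, u, expected):
        beta, undefined = tm.compute_beta(
            pd.DataFrame([[m]]), pd.DataFrame([[u]])
        )
        assert beta.iloc[0, 0] == expected
        assert not undefined.iloc[0, 0]

    def test_zero_total_flagged_not_imputed(self):
        beta, undefined = tm.compute_beta(
            pd.DataFrame([[0.0]]), pd.DataFrame([[0.0]])
        )
        assert np.isnan(beta.iloc[0, 0])
        assert undefined.iloc[0, 0]

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            tm.compute_beta(pd.DataFrame([[-1.0]]), pd.DataFrame([[1.0]]))

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e6, allow_nan=False),
                st.floats(1e-9, 1e6, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_beta_bounded_and_exact(self, pairs):
        m = pd.DataFrame([p[0] for p in pairs])
        u = pd.DataFrame([p[1] for p in pairs])
        beta, _ = tm.compute_beta(m, u)
        vals = beta.to_numpy().ravel()
        assert ((vals >= 0) & (vals <= 1)).all()
        expected = np.array([a / (a + b) for a, b in pairs])
        np.testing.assert_allclose(vals, expected, rtol=0, atol=0)


class TestProbitVST:
    def test_pooled_median_maps_to_zero(self):
        vals = pd.DataFrame(np.linspace(0.1, 0.9, 9).reshape(3, 3))
        vst = EmpiricalNormalVST().fit(vals)
        assert vst.transform(np.array([0.5]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_known_quantile_maps_to_probit(self):
        vals = np.arange(1, 1001) / 1001.0
        vst = EmpiricalNormalVST().fit(vals.reshape(1, -1))
        x = 975.5 / 1001.0  # interpolated empirical CDF value 0.975
        assert vst.transform(np.array([x]))[0] == pytest.approx(1.959964, abs=1e-3)

    def test_strictly_monotone(self, rng):
        vst = EmpiricalNormalVST().fit(rng.beta(0.5, 0.5, size=(100, 20)))
        xs = np.sort(rng.uniform(0.01, 0.99, 200))
        zs = vst.transform(xs)
        assert (np.diff(zs) > 0).all()

    def test_invertible_on_reference_range(self, rng):
        vst = EmpiricalNormalVST().fit(rng.beta(0.5, 0.5, size=(200, 20)))
        xs = np.linspace(0.01, 0.99, 99)
        back = vst.inverse(vst.transform(xs))
        np.testing.assert_allclose(back, xs, atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            EmpiricalNormalVST().fit(np.full((5, 4), 0.3))

    def test_reference_frame_reproduces_transform(self, rng):
        vst = EmpiricalNormalVST().fit(rng.beta(0.5, 0.5, size=(100, 10)))
        clone = EmpiricalNormalVST.from_reference_frame(vst.reference_frame())
        xs = rng.uniform(0.05, 0.95, 50)
        np.testing.assert_allclose(clone.transform(xs), vst.transform(xs),
                                   atol=1e-3)


class TestVarianceVST:
    def test_strictly_monotone_and_invertible(self, rng):
        beta = pd.DataFrame(np.clip(rng.normal(0.5, 0.2, (500, 12)), 0, 1))
        vst = EmpiricalVarianceVST().fit(beta)
        xs = np.linspace(0.0, 1.0, 101)
        zs = vst.transform(xs)
        assert (np.diff(zs) > 0).all()
        np.testing.assert_allclose(vst.inverse(zs), xs, atol=1e-9)

    def test_pooled_median_maps_to_zero(self, rng):
        beta = pd.DataFrame(rng.beta(2, 2, size=(400, 10)))
        vst = EmpiricalVarianceVST().fit(beta)
        med = float(np.median(beta.to_numpy()))
        assert vst.transform(np.array([med]))[0] == pytest.approx(0.0, abs=1e-6)

    def test_flat_noise_profile_gives_affine_transform(self, rng):
        # homoskedastic data: the transform must not distort t-statistics,
        # i.e. it is affine up to the estimation noise of the bin profile
        means = rng.uniform(0.2, 0.8, 800)
        beta = pd.DataFrame(means[:, None] + rng.normal(0, 0.02, (800, 20)))
        vst = EmpiricalVarianceVST().fit(beta)
        xs = np.linspace(0.25, 0.75, 51)
        zs = vst.transform(xs)
        slopes = np.diff(zs) / np.diff(xs)
        assert slopes.max() / slopes.min() < 1.3

    def test_stretches_low_variance_regions(self, rng):
        # heteroskedastic data: compressed tails get magnified
        means = rng.uniform(0.05, 0.95, 2000)
        sd = 0.002 + 0.1 * means * (1 - means)
        beta = pd.DataFrame(
            np.clip(means[:, None] + rng.normal(0, 1, (2000, 20)) * sd[:, None],
                    0, 1)
        )
        vst = EmpiricalVarianceVST().fit(beta)
        d_edge = vst.transform(np.array([0.06]))[0] - vst.transform(np.array([0.02]))[0]
        d_mid = vst.transform(np.array([0.52]))[0] - vst.transform(np.array([0.48]))[0]
        assert d_edge > d_mid

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            EmpiricalVarianceVST().fit(np.full((50, 4), 0.3))


class TestRestrictAutosomes:
    def make_manifest(self, chroms):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(len(chroms))],
                "chromosome": chroms,
                "position": np.arange(1, len(chroms) + 1),
                "gene": "",
                "blacklisted": False,
            }
        )

    def test_removes_sex_probes(self):
        manifest = self.make_manifest(["1", "X", "2", "X", "3"])
        keep, removed = tm.restrict_autosomes(manifest["probe_id"], manifest)
        assert list(keep) == ["p0", "p2", "p4"]
        assert removed == 2

    def test_identity_without_sex_probes(self):
        manifest = self.make_manifest(["1", "2", "3"])
        keep, removed = tm.restrict_autosomes(manifest["probe_id"], manifest)
        assert removed == 0 and len(keep) == 3

    def test_missing_probe_is_hard_error(self):
        manifest = self.make_manifest(["1", "2"])
        with pytest.raises(ValidationError, match="missing from manifest"):
            tm.restrict_autosomes(pd.Index(["p0", "p9"]), manifest)

    def test_counts_mirror_array_scale_split(self, rng):
        # 23,494 QC-passing probes of which 22,678 autosomal
        n, n_sex = 23494, 816
        chroms = np.array(["7"] * n, dtype=object)
        chroms[rng.choice(n, n_sex, replace=False)] = "X"
        manifest = self.make_manifest(chroms)
        keep, removed = tm.restrict_autosomes(manifest["probe_id"], manifest)
        assert len(keep) == 22678
        assert removed == 816


class TestPreprocessPipeline:
    def test_report_reconciles_with_matrix(self, small_cohort,
                                           small_preprocessed):
        pp = small_preprocessed
        r = pp.report
        assert r.n_input == small_cohort.signals.shape[0]
        assert (
            r.n_retained
            == r.n_input
            - r.n_removed_detection
            - r.n_removed_blacklist
            - r.n_removed_undefined
        )
        assert len(pp.beta) == r.n_retained
        assert pp.beta.shape == pp.transformed.shape

    def test_probit_strategy_selectable(self, small_cohort):
        pp = tm.preprocess(small_cohort.signals, small_cohort.manifest,
                           vst="probit")
        assert isinstance(pp.vst, EmpiricalNormalVST)

    def test_unknown_strategy_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="unknown VST strategy"):
            tm.preprocess(small_cohort.signals, small_cohort.manifest,
                          vst="nope")
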