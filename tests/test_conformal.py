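import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import confomer as cf
from confomer.conformal import fold_indices, half_width_from_alpha
from confomer.errors import (
    ConfigError,
    EmptyCalibrationError,
    InsufficientDataError,
)
from confomer.linear_model import predict_many, vectors_to_csr


def bias_only_icp(midpoint, width, ncm=None):
    """An ICP whose every prediction is `midpoint` with `width` at
    confidence 0.5 (single calibration alpha, rank 1 of 1)."""
    ncm = ncm or cf.NonconformityConfig(kind="abs_diff")
    endpoint = cf.LinearModel(weights={}, bias=midpoint,
                              params=cf.SvrParams(), n_features=1)
    return cf.IcpModel(endpoint=endpoint, error_model=None,
                       alphas=np.array([width / 2.0]), ncm=ncm)


class TestNonconformity:
    def test_absolute_difference(self):
        ncm = cf.NonconformityConfig(kind="abs_diff")
        assert cf.nonconformity(1.2, 0.5, None, ncm) == pytest.approx(0.7)

    def test_normalized(self):
        ncm = cf.NonconformityConfig(kind="normalized")
        assert cf.nonconformity(1.0, 0.4, 0.3, ncm) == pytest.approx(2.0)

    def test_log_normalized_with_smoothing(self):
        ncm = cf.NonconformityConfig(kind="log_normalized", beta=1.0)
        assert cf.nonconformity(2.0, 1.0, 0.0, ncm) == pytest.approx(0.5)

    def test_missing_error_prediction_rejected(self):
        ncm = cf.NonconformityConfig(kind="normalized")
        with pytest.raises(ConfigError):
            cf.nonconformity(1.0, 0.4, None, ncm)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            cf.NonconformityConfig(kind="mahalanobis")

    def test_round_trip_is_algebraically_exact(self):
        """Inverting the measure recovers the score to machine precision."""
        rng = np.random.default_rng(123)
        for kind in ("abs_diff", "normalized", "log_normalized"):
            for _ in range(1000):
                y, y_hat = rng.normal(0, 2, 2)
                mu = float(rng.normal(0, 1)) if kind != "abs_diff" else None
                beta = float(rng.uniform(0, 2)) if kind == "log_normalized" else 0.0
                ncm = cf.NonconformityConfig(kind=kind, beta=beta)
                alpha = cf.nonconformity(float(y), float(y_hat), mu, ncm)
                half = half_width_from_alpha(alpha, mu, ncm)
                back = cf.nonconformity(float(y_hat) + half, float(y_hat),
                                        mu, ncm)
                assert back == pytest.approx(alpha, rel=1e-12, abs=1e-15)


class TestAlphaAtConfidence:
    alphas = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]

    def test_rank_convention_at_80(self):
        assert cf.alpha_at_confidence(self.alphas, 0.8) == pytest.approx(0.9)

    def test_rank_overflow_gives_infinite(self):
        assert cf.alpha_at_confidence(self.alphas, 0.95) == math.inf

    @pytest.mark.parametrize("conf", [0.1, 0.3, 0.5])
    def test_single_alpha_list(self, conf):
        assert cf.alpha_at_confidence([0.42], conf) == 0.42

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyCalibrationError):
            cf.alpha_at_confidence([], 0.8)

    def test_confidence_bounds(self):
        with pytest.raises(ValueError):
            cf.alpha_at_confidence(self.alphas, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        alphas=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1,
                        max_size=50).map(sorted),
        c1=st.floats(0.01, 0.98),
        c2=st.floats(0.01, 0.98),
    )
    def test_result_is_list_member_and_monotone(self, alphas, c1, c2):
        lo, hi = sorted((c1, c2))
        a_lo = cf.alpha_at_confidence(alphas, lo)
        a_hi = cf.alpha_at_confidence(alphas, hi)
        for a in (a_lo, a_hi):
            assert a == math.inf or a in alphas
        assert a_lo <= a_hi


@pytest.fixture(scope="module")
def small_data():
    X, y = cf.make_vector_dataset(
        cf.SyntheticSpec(n=300, p=40, density=0.1, noise_base=0.3, seed=9)
    )
    return (X[:200], y[:200]), (X[200:], y[200:])


class TestIcpFit:
    def test_abs_diff_alphas_are_sorted_calibration_residuals(self, small_data):
        proper, calibration = small_data
        icp = cf.icp_fit(proper, calibration,
                         ncm=cf.NonconformityConfig(kind="abs_diff"))
        Xc = vectors_to_csr(calibration[0], icp.endpoint.n_features)
        resid = np.abs(
            np.asarray(calibration[1]) - predict_many(icp.endpoint, Xc)
        )
        assert np.allclose(icp.alphas, np.sort(resid))
        assert icp.error_model is None

    def test_normalized_fit_has_error_model(self, small_data):
        proper, calibration = small_data
        icp = cf.icp_fit(proper, calibration,
                         ncm=cf.NonconformityConfig(kind="normalized"))
        assert icp.error_model is not None
        assert np.all(np.diff(icp.alphas) >= 0)
        assert np.all(icp.alphas >= 0)

    def test_memorized_compound_has_near_zero_alpha(self):
        # noiseless linear data; a calibration point identical to a
        # training point must be predicted almost exactly
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 5, size=(60, 3))
        y = counts @ np.array([1.0, -2.0, 0.5]) + 3.0
        X = [cf.FeatureVector(counts={j: int(c) for j, c in enumerate(row)
                                      if c}) for row in counts]
        icp = cf.icp_fit((X, y), ([X[0]], [y[0]]),
                         params=cf.SvrParams(cost=100.0, epsilon=1e-5),
                         ncm=cf.NonconformityConfig(kind="abs_diff"),
                         n_features=3)
        assert icp.alphas[0] < 0.15

    def test_mismatched_error_model_rejected(self):
        endpoint = cf.LinearModel(weights={}, bias=0.0,
                                  params=cf.SvrParams(), n_features=1)
        with pytest.raises(ConfigError):
            cf.IcpModel(endpoint=endpoint, error_model=None,
                        alphas=np.array([1.0]),
                        ncm=cf.NonconformityConfig(kind="normalized"))


class TestIcpPredict:
    def test_normalized_interval_inverts_the_measure(self):
        # alpha_conf = 2.0, mu = 0.3, midpoint 0.4 -> (-0.2, 1.0)
        ncm = cf.NonconformityConfig(kind="normalized")
        endpoint = cf.LinearModel(weights={}, bias=0.4,
                                  params=cf.SvrParams(), n_features=1)
        error = cf.LinearModel(weights={}, bias=0.3,
                               params=cf.SvrParams(), n_features=1)
        icp = cf.IcpModel(endpoint=endpoint, error_model=error,
                          alphas=np.array([2.0]), ncm=ncm)
        iv = cf.icp_predict(icp, {}, 0.5)
        assert iv.lower == pytest.approx(-0.2)
        assert iv.upper == pytest.approx(1.0)
        # round trip: the upper bound scores exactly alpha_conf
        assert cf.nonconformity(iv.upper, iv.midpoint, 0.3, ncm) == (
            pytest.approx(2.0)
        )

    def test_rank_overflow_flags_unbounded_interval(self):
        icp = bias_only_icp(0.0, 1.0)
        iv = cf.icp_predict(icp, {}, 0.9)  # rank 2 > n=1
        assert iv.unbounded
        assert iv.lower == -math.inf and iv.upper == math.inf

    def test_interval_is_symmetric(self):
        icp = bias_only_icp(1.5, 0.8)
        iv = cf.icp_predict(icp, {}, 0.5)
        assert iv.midpoint - iv.lower == pytest.approx(iv.upper - iv.midpoint)
        assert iv.width == pytest.approx(0.8)


class TestCcpFit:
    def test_folds_partition_the_data(self):
        folds = fold_indices(100, 10, seed=0)
        assert [len(f) for f in folds] == [10] * 10
        assert sorted(np.concatenate(folds)) == list(range(100))

    def test_remainder_rule(self):
        folds = fold_indices(101, 10, seed=0)
        assert sorted(len(f) for f in folds) == [10] * 9 + [11]

    def test_same_seed_same_assignment(self):
        f1 = fold_indices(57, 5, seed=3)
        f2 = fold_indices(57, 5, seed=3)
        assert all((a == b).all() for a, b in zip(f1, f2))

    def test_insufficient_data_rejected(self):
        X, y = cf.make_vector_dataset(cf.SyntheticSpec(n=10, p=5, seed=1))
        with pytest.raises(InsufficientDataError):
            cf.ccp_fit((X, y), k=10)

    def test_k1_uses_single_split(self):
        X, y = cf.make_vector_dataset(
            cf.SyntheticSpec(n=100, p=20, density=0.2, seed=4)
        )
        ccp = cf.ccp_fit((X, y), k=1, seed=5, n_features=20)
        assert ccp.k == 1
        assert len(ccp.members[0].alphas) == 20  # 20% calibration

    def test_determinism(self, hetero_split):
        train, _ = hetero_split
        sub = (train[0][:200], train[1][:200])
        a = cf.ccp_fit(sub, k=5, seed=11, n_features=200)
        b = cf.ccp_fit(sub, k=5, seed=11, n_features=200)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.alphas, mb.alphas)
            assert ma.endpoint.weights == mb.endpoint.weights


class TestCcpPredict:
    def test_median_of_odd_members(self):
        ccp = cf.CcpModel(
            members=[bias_only_icp(1, 0.2), bias_only_icp(2, 0.4),
                     bias_only_icp(3, 0.6)],
            vocabulary=None, seed=0)
        iv = cf.ccp_predict(ccp, {}, 0.5)
        assert iv.midpoint == pytest.approx(2.0)
        assert iv.width == pytest.approx(0.4)

    def test_even_member_count_averages_central_pair(self):
        ccp = cf.CcpModel(
            members=[bias_only_icp(m, 0.1) for m in (1, 2, 3, 4)],
            vocabulary=None, seed=0)
        assert cf.ccp_predict(ccp, {}, 0.5).midpoint == pytest.approx(2.5)

    def test_k1_equals_single_icp(self, hetero_split):
        train, test = hetero_split
        sub = (train[0][:300], train[1][:300])
        ccp = cf.ccp_fit(sub, k=1, seed=2, n_features=200)
        for fv in test[0][:100]:
            a = cf.ccp_predict(ccp, fv, 0.8)
            b = cf.icp_predict(ccp.members[0], fv, 0.8)
            assert a.midpoint == pytest.approx(b.midpoint)
            assert a.width == pytest.approx(b.width)

    def test_median_against_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for k in (2, 3, 4, 7, 10):
            mids = rng.normal(0, 1, k)
            widths = rng.uniform(0.1, 2.0, k)
            ccp = cf.CcpModel(
                members=[bias_only_icp(m, w) for m, w in zip(mids, widths)],
                vocabulary=None, seed=0)
            iv = cf.ccp_predict(ccp, {}, 0.5)

            def oracle(vals):
                s = sorted(vals)
                n = len(s)
                return (s[n // 2] if n % 2 else
                        0.5 * (s[n // 2 - 1] + s[n // 2]))

            assert iv.midpoint == pytest.approx(oracle(mids))
            assert iv.width == pytest.approx(oracle(widths))

    def test_batch_predictions_match_scalar_path(self, ccp_by_ncm,
                                                 hetero_split):
        _, test = hetero_split
        ccp = ccp_by_ncm["normalized"]
        batch = cf.ccp_predict_many(ccp, test[0][:50], 0.8)
        for fv, iv in zip(test[0][:50], batch):
            ref = cf.ccp_predict(ccp, fv, 0.8)
            assert iv.midpoint == pytest.approx(ref.midpoint)
            assert iv.width == pytest.approx(ref.width)

    @pytest.mark.parametrize("kind", ["abs_diff", "normalized",
                                      "log_normalized"])
    def test_width_monotone_in_confidence(self, ccp_by_ncm, hetero_split,
                                          kind):
        _, test = hetero_split
        ccp = ccp_by_ncm[kind]
        for fv in test[0][:20]:
            widths = [cf.ccp_predict(ccp, fv, c).width
                      for c in (0.5, 0.7, 0.8, 0.9)]
            assert all(a <= b + 1e-12 for a, b in zip(widths, widths[1:]))

    def test_large_beta_flattens_log_normalized_widths(self, hetero_split):
        train, test = hetero_split
        sub = (train[0][:400], train[1][:400])
        widths = {}
        for beta in (0.0, 1e6):
            ccp = cf.ccp_fit(
                sub, k=5, seed=3, n_features=200,
                ncm=cf.NonconformityConfig(kind="log_normalized", beta=beta),
            )
            w = np.array([iv.width for iv in
                          cf.ccp_predict_many(ccp, test[0][:200], 0.8)])
            widths[beta] = w
        rel_spread = {b: np.std(w) / np.mean(w) for b, w in widths.items()}
        assert rel_spread[1e6] < 1e-4      # effectively constant
        assert rel_spread[0.0] > 1e-2      # genuinely per-compound at beta=0


class TestArchive:
    def test_round_trip_preserves_predictions(self, ccp_by_ncm,
                                              hetero_split, tmp_path):
        _, test = hetero_split
        ccp = ccp_by_ncm["normalized"]
        path = tmp_path / "model.ccp"
        cf.save_ccp(ccp, path)
        loaded = cf.load_ccp(path)
        assert loaded.k == ccp.k and loaded.ncm.kind == "normalized"
        for fv in test[0][:20]:
            a = cf.ccp_predict(ccp, fv, 0.8)
            b = cf.ccp_predict(loaded, fv, 0.8)
            assert a.midpoint == b.midpoint and a.width == b.width

    def test_archive_bytes_deterministic(self, ccp_by_ncm, tmp_path):
        ccp = ccp_by_ncm["abs_diff"]
        p1, p2 = tmp_path / "a.ccp", tmp_path / "b.ccp"
        cf.save_ccp(ccp, p1)
        cf.save_ccp(ccp, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_vocabulary_survives_round_trip(self, tmp_path):
        comps = cf.make_molecule_dataset(40, seed=3)
        vocab = cf.build_vocabulary(comps, (1, 2), 1)
        X = [cf.vectorize(c.mol, vocab) for c in comps]
        y = np.array([c.y for c in comps])
        ccp = cf.ccp_fit((X, y), k=3, vocabulary=vocab, seed=1)
        ccp.heights = (1, 2)
        path = tmp_path / "mol.ccp"
        cf.save_ccp(ccp, path)
        loaded = cf.load_ccp(path)
        assert loaded.vocabulary.entries == vocab.entries
        assert loaded.heights == (1, 2)
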