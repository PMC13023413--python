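"""Decoder components: CSP, mutual information, QDA, LOSO, projection."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import linalg as sla

from illusioneeg.containers import EpochSet, concatenate_epochs
from illusioneeg import decoding as dec


def _epochs(data, conditions=None, subjects=None, rate=250.0):
    n, n_ch, n_t = data.shape
    conditions = conditions or [""] * n
    subjects = subjects or ["s0"] * n
    return EpochSet(data=data, rate_hz=rate,
                    time_ms=np.arange(n_t) * 1000.0 / rate,
                    channel_labels=[f"ch{i}" for i in range(n_ch)],
                    condition=np.array(conditions, dtype=object),
                    subject_id=np.array(subjects, dtype=object),
                    stimulus_id=np.array([f"t{i}" for i in range(n)],
                                         dtype=object))


def csp_whitening_oracle(covs_a, covs_b):
    """Brute-force reference: whiten the composite covariance, then
    eigendecompose the whitened class-A covariance."""
    ta = np.trace(covs_a, axis1=1, axis2=2)
    tb = np.trace(covs_b, axis1=1, axis2=2)
    ca = (covs_a / ta[:, None, None]).mean(axis=0)
    cb = (covs_b / tb[:, None, None]).mean(axis=0)
    comp = ca + cb
    evals, evecs = np.linalg.eigh(comp)
    whitener = evecs @ np.diag(evals ** -0.5) @ evecs.T
    lam, u = np.linalg.eigh(whitener @ ca @ whitener)
    filters = whitener @ u
    return np.clip(lam, 0, 1), filters


class TestCSP:
    def test_equal_class_covariances_give_half_eigenvalues(self, rng):
        covs = np.stack([np.eye(4) + 0.1 * np.diag(rng.uniform(size=4))
                         for _ in range(6)])
        model = dec.csp_fit_from_covariances(covs, covs.copy())
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_two_channel_closed_form(self):
        covs_a = np.stack([np.diag([2.0, 1.0])] * 4)
        covs_b = np.stack([np.diag([1.0, 2.0])] * 4)
        model = dec.csp_fit_from_covariances(covs_a, covs_b)
        assert model.eigenvalues[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
        w = model.filters[:, 0]
        assert abs(w[1] / np.linalg.norm(w)) < 1e-10  # aligned with channel 1

    def test_matches_whitening_oracle_on_random_instances(self, rng):
        for _ in range(10):
            covs_a = np.stack([c @ c.T + 0.5 * np.eye(8) for c in
                               rng.standard_normal((5, 8, 8))])
            covs_b = np.stack([c @ c.T + 0.5 * np.eye(8) for c in
                               rng.standard_normal((5, 8, 8))])
            model = dec.csp_fit_from_covariances(covs_a, covs_b)
            lam_ref, filt_ref = csp_whitening_oracle(covs_a, covs_b)
            assert np.allclose(np.sort(model.eigenvalues),
                               np.sort(lam_ref), atol=1e-8)
            # filters agree up to sign/scale: match by eigenvalue
            order_ref = np.argsort(-np.maximum(lam_ref, 1 - lam_ref))
            for k in range(8):
                a = model.filters[:, k] / np.linalg.norm(model.filters[:, k])
                b = filt_ref[:, order_ref[k]]
                b = b / np.linalg.norm(b)
                assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-6

    def test_eigenvalue_complementarity_and_relabeling(self, rng):
        covs_a = np.stack([c @ c.T + np.eye(6) for c in
                           rng.standard_normal((8, 6, 6))])
        covs_b = np.stack([c @ c.T + np.eye(6) for c in
                           rng.standard_normal((8, 6, 6))])
        ab = dec.csp_fit_from_covariances(covs_a, covs_b)
        ba = dec.csp_fit_from_covariances(covs_b, covs_a)
        assert np.allclose(np.sort(ab.eigenvalues),
                           np.sort(1.0 - ba.eigenvalues), atol=1e-8)
        # same discriminative subspace up to sign/scale
        for k in range(2):
            a = ab.filters[:, k] / np.linalg.norm(ab.filters[:, k])
            b = ba.filters[:, k] / np.linalg.norm(ba.filters[:, k])
            assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-6


class TestCSPFeatures:
    def test_unit_variance_projection_gives_zero_feature(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2001)
        x = (x - x.mean()) / x.std(ddof=1)
        data = x[None, None, :]
        model = dec.CSPModel(filters=np.eye(1), eigenvalues=np.array([0.5]),
                             component_order=np.array([0]))
        feats = dec.csp_features(_epochs(data), model, 1)
        assert feats[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_epoch_by_two_adds_log_four(self, rng):
        data = rng.standard_normal((3, 4, 100))
        model = dec.csp_fit_from_covariances(
            dec.epoch_covariances(data), dec.epoch_covariances(data) + 0.0)
        f1 = dec.csp_features(_epochs(data), model, 4)
        f2 = dec.csp_features(_epochs(2.0 * data), model, 4)
        assert np.allclose(f2 - f1, np.log(4.0), atol=1e-10)

    def test_too_many_components_raises(self, rng):
        data = rng.standard_normal((3, 4, 50))
        model = dec.csp_fit_from_covariances(dec.epoch_covariances(data),
                                             dec.epoch_covariances(data))
        with pytest.raises(ValueError):
            dec.csp_features(_epochs(data), model, 5)


class TestMutualInformation:
    def test_constant_feature_scores_zero(self):
        x = np.column_stack([np.zeros(40), np.linspace(0, 1, 40)])
        labels = np.array(["a", "b"] * 20)
        sel = dec.mi_rank(x, labels)
        assert sel.mi_bits[0] == pytest.approx(0.0, abs=1e-12)

    def test_feature_identical_to_label_scores_one_bit(self):
        y = np.array(["a"] * 32 + ["b"] * 32)
        x = (y == "b").astype(float)[:, None]
        sel = dec.mi_rank(x, y)
        assert sel.mi_bits[0] == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_separation_matches_quadrature_oracle(self):
        from scipy.integrate import quad
        delta = 2.0
        rng = np.random.default_rng(42)
        n = 20000
        y = np.repeat(["a", "b"], n // 2)
        x = rng.standard_normal(n) + np.where(y == "b", delta / 2, -delta / 2)
        sel = dec.mi_rank(x[:, None], y)

        def mixture(v):
            pa = np.exp(-(v + delta / 2) ** 2 / 2) / np.sqrt(2 * np.pi)
            pb = np.exp(-(v - delta / 2) ** 2 / 2) / np.sqrt(2 * np.pi)
            return 0.5 * (pa + pb)

        def neg_plogp(v):
            p = mixture(v)
            return -p * np.log2(p) if p > 0 else 0.0

        h_mix = quad(neg_plogp, -12, 12, limit=200)[0]
        h_cond = 0.5 * np.log2(2 * np.pi * np.e)
        true_mi = h_mix - h_cond
        assert sel.mi_bits[0] == pytest.approx(true_mi, abs=0.05)

    def test_ranking_ties_broken_by_lower_index(self):
        x = np.column_stack([np.zeros(20), np.zeros(20)])
        labels = np.array(["a", "b"] * 10)
        sel = dec.mi_rank(x, labels)
        assert list(sel.selected_indices) == [0, 1]


class TestQDA:
    def test_lda_limit_decision_is_linear(self, rng):
        # exact sample moments: shared covariance, means +/- mu
        z = rng.standard_normal((400, 2))
        z = (z - z.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(
            z, rowvar=False, ddof=1)).T)
        mu = np.array([1.0, 0.5])
        x = np.vstack([z + mu, z - mu])
        y = np.array(["pos"] * 400 + ["neg"] * 400)
        model = dec.qda_fit(x, y)
        grid = rng.uniform(-4, 4, size=(500, 2))
        pred, _ = dec.qda_predict(model, grid)
        expected = np.where(grid @ mu > 0, "pos", "neg")
        assert (pred == expected).all()

    def test_1d_unequal_variance_matches_closed_form_boundary(self, rng):
        # construct samples whose sample mean/variance are exactly 0/1 and 0/4
        z = rng.standard_normal(5000)
        z = (z - z.mean()) / z.std(ddof=1)
        x = np.concatenate([z, 2.0 * z])[:, None]
        y = np.array(["narrow"] * 5000 + ["wide"] * 5000)
        model = dec.qda_fit(x, y)
        # closed form: |x| < x* -> narrow, where the discriminants cross
        x_star = np.sqrt(np.log(4.0) / (3.0 / 8.0) / 2.0)
        grid = np.linspace(-5, 5, 1001)[:, None]
        pred, _ = dec.qda_predict(model, grid)
        expected = np.where(np.abs(grid[:, 0]) < x_star, "narrow", "wide")
        assert (pred == expected).all()

    def test_separable_training_data_classified_perfectly(self, rng):
        x = np.vstack([rng.normal(-5, 0.3, size=(30, 2)),
                       rng.normal(5, 0.3, size=(30, 2))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        model = dec.qda_fit(x, y)
        pred, post = dec.qda_predict(model, x)
        assert (pred == y).all()
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_agreement_with_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        x = rng.standard_normal((200, 3))
        y = np.array(["a", "b"] * 100)
        x[y == "b"] += [0.5, -0.3, 0.2]
        model = dec.qda_fit(x, y)
        pred, post = dec.qda_predict(model, x)
        ref = sk.QuadraticDiscriminantAnalysis(store_covariance=True).fit(x, y)
        assert (pred == ref.predict(x)).all()
        assert np.allclose(post, ref.predict_proba(x), atol=1e-8)

    def test_singular_covariance_triggers_shrinkage(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0],
                      [0.1, 0.1], [0.9, 0.9]])
        y = np.array(["a", "a", "b", "b", "a", "b"])
        model = dec.qda_fit(x, y, shrinkage=0.0)  # degenerate: collinear
        assert np.isfinite(model.log_dets).all()


def _separable_cohort(n_subjects=4, n_segments=20, n_ch=6, n_t=200, noise=0.05,
                      seed=0):
    """Classes with disjoint strong spatial variance: trivially decodable."""
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(n_subjects):
        data = noise * rng.standard_normal((2 * n_segments, n_ch, n_t))
        data[:n_segments, 0, :] += 3.0 * rng.standard_normal((n_segments, n_t))
        data[n_segments:, 1, :] += 3.0 * rng.standard_normal((n_segments, n_t))
        conds = ["english"] * n_segments + ["italian"] * n_segments
        sets.append(_epochs(data, conds, [f"s{s}"] * 2 * n_segments))
    return sets


class TestLoso:
    SETTINGS = dec.DecoderSettings(components_grid=(2,),
                                   shrinkage_grid=(0.01,),
                                   inner_k=10, inner_repeats=1, seed=0)

    def test_perfectly_separable_cohort_scores_100_every_fold(self):
        res = dec.loso_evaluate(_separable_cohort(), self.SETTINGS)
        assert all(acc == 1.0 for acc in res.fold_accuracy.values())
        assert res.mean == 1.0

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            dec.loso_evaluate(_separable_cohort(n_subjects=2), self.SETTINGS)

    def test_missing_class_raises(self):
        sets = _separable_cohort()
        for ep in sets:
            ep.condition[:] = "english"
        with pytest.raises(ValueError):
            dec.loso_evaluate(sets, self.SETTINGS)

    def test_loso_is_deterministic(self):
        r1 = dec.loso_evaluate(_separable_cohort(noise=1.5, seed=3),
                               self.SETTINGS)
        r2 = dec.loso_evaluate(_separable_cohort(noise=1.5, seed=3),
                               self.SETTINGS)
        assert r1.fold_accuracy == r2.fold_accuracy


class TestGroupAveragingAndProjection:
    def test_single_subject_average_is_identity(self, rng):
        data = rng.standard_normal((4, 3, 50))
        ep = _epochs(data, ["CEng"] * 4)
        avg = dec.group_average_trials([ep])
        assert np.allclose(avg.data, data)

    def test_opposite_subjects_cancel(self, rng):
        data = rng.standard_normal((4, 3, 50))
        a = _epochs(data, ["CEng"] * 4, ["s0"] * 4)
        b = _epochs(-data, ["CEng"] * 4, ["s1"] * 4)
        avg = dec.group_average_trials([a, b])
        assert np.allclose(avg.data, 0.0, atol=1e-12)

    def test_percentages_sum_to_100(self):
        sets = _separable_cohort()
        covs = np.concatenate([dec.epoch_covariances(s) for s in sets])
        labs = np.concatenate([np.asarray(s.condition) for s in sets])
        model = dec.LanguageDecoder.fit(covs, labs, 2, 2, 0.01)
        trials = _epochs(np.random.default_rng(0).standard_normal((10, 6, 200)),
                         ["CEng"] * 5 + ["CIta"] * 5)
        out = dec.classify_conditions(model, trials)
        for vals in out.values():
            assert vals["pct_english"] + vals["pct_italian"] == pytest.approx(100.0)

    def test_conform_epochs_crops_and_pads(self, rng):
        data = rng.standard_normal((2, 3, 100))
        ep = _epochs(data)
        cropped = dec.conform_epochs(ep, 80)
        assert cropped.n_times == 80
        assert np.array_equal(cropped.data, data[:, :, :80])
        padded = dec.conform_epochs(ep, 150)
        assert padded.n_times == 150
        assert np.array_equal(padded.data[:, :, :100], data)
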