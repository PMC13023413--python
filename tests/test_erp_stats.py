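"""ERP statistics: ROI averaging, window amplitudes, pointwise and
cluster-permutation tests, repeated-measures ANOVA, TANOVA."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from illusioneeg.containers import EpochSet
from illusioneeg import erp


def _epochs(data, conditions, subjects, rate=250.0, labels=None):
    n, n_ch, n_t = data.shape
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    return EpochSet(data=data, rate_hz=rate,
                    time_ms=np.arange(n_t) * 1000.0 / rate,
                    channel_labels=labels,
                    condition=np.array(conditions, dtype=object),
                    subject_id=np.array(subjects, dtype=object),
                    stimulus_id=np.array([""] * n, dtype=object))


class TestRoiAverage:
    def test_single_epoch_single_channel_is_identity(self, rng):
        data = rng.standard_normal((1, 1, 40))
        ep = _epochs(data, ["A"], ["s0"], labels=["Cz"])
        w = erp.roi_average(ep, roi=("Cz",))["A"]
        assert np.allclose(w.values[0], data[0, 0])

    def test_matches_bruteforce_double_mean(self, rng):
        data = rng.standard_normal((3, 4, 20))
        ep = _epochs(data, ["A"] * 3, ["s0"] * 3,
                     labels=["Fz", "Cz", "Pz", "Oz"])
        w = erp.roi_average(ep, roi=("Fz", "Cz", "Pz"))["A"]
        brute = data[:, :3, :].mean(axis=0).mean(axis=0)
        assert np.allclose(w.values[0], brute, atol=1e-12)

    def test_missing_roi_channel_raises_with_name(self, rng):
        ep = _epochs(rng.standard_normal((1, 2, 10)), ["A"], ["s0"],
                     labels=["Cz", "Pz"])
        with pytest.raises(KeyError, match="FCz"):
            erp.roi_average(ep, roi=("Cz", "FCz"))


class TestWindowAmplitude:
    def test_constant_waveform_returns_constant(self):
        t = np.arange(0, 400, 4.0)
        assert erp.window_amplitude(np.full(t.size, 3.0), (100, 150),
                                    time_ms=t) == pytest.approx(3.0)

    def test_closed_interval_includes_endpoints(self):
        t = np.array([100.0, 150.0, 200.0])
        vals = np.array([1.0, 2.0, 4.0])
        assert erp.window_amplitude(vals, (100, 150), time_ms=t) == 1.5

    def test_empty_window_raises(self):
        t = np.arange(0, 100, 4.0)
        with pytest.raises(ValueError):
            erp.window_amplitude(np.zeros(t.size), (500, 600), time_ms=t)


class TestPointwise:
    def test_identical_groups_give_zero_t(self, rng):
        a = rng.standard_normal((5, 30))
        t, p = erp.pointwise_test(a, a.copy(), paired=False)
        assert np.allclose(t, 0.0)

    def test_matches_textbook_formula_n3(self):
        a = np.array([[1.0], [2.0], [4.0]])
        b = np.array([[0.5], [1.0], [2.0]])
        d = (a - b).ravel()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, _ = erp.pointwise_test(a, b, paired=True)
        assert t[0] == pytest.approx(t_hand, rel=1e-12)
        # independent variant against the pooled-variance formula
        sp2 = (a.ravel().var(ddof=1) + b.ravel().var(ddof=1)) / 2
        t_ind_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        t_ind, _ = erp.pointwise_test(a, b, paired=False)
        assert t_ind[0] == pytest.approx(t_ind_hand, rel=1e-12)

    def test_zero_variance_point_is_flagged_nan(self):
        a = np.ones((4, 3))
        b = np.zeros((4, 3))
        t, _ = erp.pointwise_test(a, b, paired=True)
        assert np.isnan(t).all()


class TestClusterPermutation1D:
    def test_identical_conditions_give_no_clusters(self, rng):
        a = rng.standard_normal((8, 50))
        res = erp.cluster_permutation_1d(a, a.copy(), n_perm=200, seed=0)
        assert res.clusters == []

    def test_injected_difference_recovered(self):
        rng = np.random.default_rng(7)
        n, n_t = 20, 100
        noise_a = rng.standard_normal((n, n_t))
        noise_b = rng.standard_normal((n, n_t))
        bump = np.zeros(n_t)
        bump[40:65] = 5.0  # 100 ms at 250 Hz, 5 sigma
        res = erp.cluster_permutation_1d(noise_a + bump, noise_b,
                                         n_perm=1000, seed=1)
        sig = res.significant(0.05)
        assert len(sig) == 1
        c = sig[0]
        assert c.tail == "positive"
        assert c.indices[0] <= 64 and c.indices[-1] >= 40  # overlaps bump

    def test_small_n_uses_exhaustive_enumeration(self, rng):
        a = rng.standard_normal((5, 20))
        b = rng.standard_normal((5, 20)) + 1.5
        res = erp.cluster_permutation_1d(a, b, n_perm=1000, seed=0)
        assert res.enumerated
        assert res.n_permutations == 2 ** 5
        for c in res.clusters:
            assert (c.p_value * 32) == pytest.approx(round(c.p_value * 32))

    def test_mass_monotone_in_injected_gain(self):
        rng = np.random.default_rng(3)
        n, n_t = 12, 80
        noise_a = rng.standard_normal((n, n_t))
        noise_b = rng.standard_normal((n, n_t))
        bump = np.zeros(n_t)
        bump[30:50] = 1.0
        masses = []
        for gain in (1.0, 2.0, 3.0):
            res = erp.cluster_permutation_1d(noise_a + gain * bump, noise_b,
                                             n_perm=200, seed=5)
            pos = [c.mass for c in res.clusters if c.tail == "positive"]
            masses.append(max(pos) if pos else 0.0)
        assert masses[0] <= masses[1] <= masses[2]

    def test_agreement_with_mne_cluster_test(self):
        mne = pytest.importorskip("mne")
        from mne.stats import permutation_cluster_1samp_test
        from scipy import stats as sstats
        rng = np.random.default_rng(11)
        a = rng.standard_normal((15, 60))
        b = rng.standard_normal((15, 60))
        a[:, 20:35] += 1.2
        res = erp.cluster_permutation_1d(a, b, n_perm=500, seed=0)
        thresh = sstats.t.ppf(0.975, 14)
        t_obs, clusters, _, _ = permutation_cluster_1samp_test(
            a - b, threshold=thresh, n_permutations=500, tail=0,
            seed=0, verbose=False)
        mne_extents = sorted((int(c[0][0]), int(c[0][-1])) for c in clusters)
        ours = sorted((int(c.indices[0]), int(c.indices[-1]))
                      for c in res.clusters)
        assert ours == mne_extents
        # cluster masses agree with MNE's summed t values
        for c in res.clusters:
            assert c.mass == pytest.approx(
                t_obs[c.indices[0]: c.indices[-1] + 1].sum(), rel=1e-9)


class TestClusterPermutation2D:
    def test_identical_inputs_empty(self, rng):
        a = rng.standard_normal((6, 10, 20))
        res = erp.cluster_permutation_2d(a, a.copy(), n_perm=200, seed=0)
        assert res.clusters == []

    def test_injected_blob_recovered(self):
        rng = np.random.default_rng(9)
        n, nf, nt = 16, 12, 40
        a = rng.standard_normal((n, nf, nt))
        b = rng.standard_normal((n, nf, nt))
        blob = np.zeros((nf, nt))
        blob[4:8, 10:25] = 5.0
        res = erp.cluster_permutation_2d(a + blob, b, n_perm=500, seed=2)
        sig = [c for c in res.significant(0.05) if c.tail == "positive"]
        assert len(sig) >= 1
        big = max(sig, key=lambda c: c.mass)
        blob_cells = {(f, t) for f in range(4, 8) for t in range(10, 25)}
        covered = blob_cells & {tuple(idx) for idx in big.indices}
        assert len(covered) >= 0.5 * len(blob_cells)


class TestRmAnova:
    def test_constant_table_gives_zero_f(self):
        out = erp.rm_anova_window(np.full((6, 4), 2.5))
        assert out["F"] == 0.0

    def test_toy_table_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(4)
        x = rng.standard_normal((7, 3)) + np.array([0.0, 0.5, 1.0])
        out = erp.rm_anova_window(x)
        long = pd.DataFrame({
            "y": x.ravel(),
            "subject": np.repeat(np.arange(7), 3),
            "cond": np.tile(np.arange(3), 7),
        })
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert out["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert out["p"] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_degrees_of_freedom_for_five_conditions(self, rng):
        x = rng.standard_normal((10, 5))
        out = erp.rm_anova_window(x)
        assert out["df"] == (4, 36)

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            erp.rm_anova_window(np.zeros((5, 1)))


class TestTanova:
    def test_identical_maps_give_zero_diss(self, rng):
        m = rng.standard_normal((6, 1, 8, 1))
        maps = np.concatenate([m, m], axis=1)
        res = erp.tanova(maps, n_perm=100, seed=0)
        assert res.diss[0] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_maps_give_diss_two(self, rng):
        u = rng.standard_normal(8)
        maps = np.stack([np.stack([u, -u])] * 5)[:, :, :, None]
        res = erp.tanova(maps, n_perm=100, seed=0)
        assert res.diss[0] == pytest.approx(2.0, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50.0),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_scale_invariance_under_gfp_normalization(self, scale, seed):
        rng = np.random.default_rng(seed)
        maps = rng.standard_normal((4, 3, 6, 2))
        scaled = maps.copy()
        scaled[:, 1] *= scale
        a = erp.tanova(maps, n_perm=50, seed=0)
        b = erp.tanova(scaled, n_perm=50, seed=0)
        assert np.allclose(a.diss, b.diss, rtol=1e-9)

    def test_effect_detected_in_shifted_topography(self, rng):
        base = rng.standard_normal((12, 2, 10, 1)) * 0.5
        base[:, 1, :5, 0] += 2.0  # condition 2 has a distinct map
        res = erp.tanova(base, n_perm=500, seed=1)
        assert res.p[0] <= 0.05
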