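"""Novelty architecture: window lineage, threshold behaviour, V-measure
oracles, embedding and boundary contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioloop import decode, novelty
from cardioloop.novelty import (
    NoveltyConfig, WindowMatrix, build_windows, fit_autoencoder,
    score_novelty, novelty_threshold, embed_latent, boundary_separation,
    identify_types, v_measure,
)


def _toy_dataset(n_rec=4, T=120, n_feat=13, shift=0.0, seed=0, state="rest"):
    rng = np.random.default_rng(seed)
    seqs = [rng.normal(shift, 0.5, size=(T, n_feat)).astype(np.float32)
            for _ in range(n_rec)]
    labs = [np.zeros(T, dtype=int) for _ in range(n_rec)]
    return decode.LabeledSequenceSet(seqs, labs, [state] * n_rec, list(range(n_rec)))


TOY = NoveltyConfig(lstm_steps=20, sparse_steps=10, train_stride=10,
                    score_stride=20, lstm_epochs=30)


class TestWindows:
    def test_width_times_features_exact(self):
        ds = _toy_dataset()
        w = build_windows(ds, n_steps=20, stride=10)
        assert w.X.shape[1] == 20 * 13
        with pytest.raises(ValueError, match="flat size"):
            WindowMatrix(w.X[:, :-1], 20, 13, w.source, w.record_index, w.lineage)

    def test_windows_never_span_recordings(self):
        ds = _toy_dataset(n_rec=3, T=50)
        w = build_windows(ds, n_steps=20, stride=5)
        # per recording: starts 0,5,...,30 -> 7 windows
        assert len(w) == 21
        assert (np.bincount(w.record_index) == 7).all()

    def test_start_time_filter(self):
        ds = _toy_dataset(n_rec=1, T=100)
        w = build_windows(ds, n_steps=20, stride=10, start_time=8.0)
        assert (w.start_time >= 8.0 - 1e-9).all()

    def test_training_rejects_emerging_lineage(self):
        ds = _toy_dataset()
        w = build_windows(ds, n_steps=20, stride=10, lineage="emerging")
        with pytest.raises(ValueError, match="lineage"):
            fit_autoencoder(w, TOY, kind="lstm")


class TestDetectors:
    def test_known_flag_rate_tracks_percentile_budget(self):
        """Windows drawn from the training distribution flag at roughly the
        configured false-positive budget."""
        ds = _toy_dataset(n_rec=6, T=200, seed=1)
        w = build_windows(ds, n_steps=20, stride=10)
        ae = fit_autoencoder(w, TOY, kind="lstm")
        res = score_novelty(ae, w, config=TOY)
        assert res.flagged.mean() == pytest.approx(0.01, abs=0.02)

    def test_shifted_windows_flagged(self):
        ds = _toy_dataset(n_rec=6, T=200, seed=2)
        w = build_windows(ds, n_steps=20, stride=10)
        ae = fit_autoencoder(w, TOY, kind="lstm")
        far = _toy_dataset(n_rec=2, T=200, shift=6.0, seed=3, state="H-D")
        wf = build_windows(far, n_steps=20, stride=10, lineage="emerging")
        res = score_novelty(ae, wf, config=TOY)
        assert res.sensitivity > 0.95

    def test_threshold_monotonicity(self):
        """Raising the threshold can only lower the flag rate."""
        ds = _toy_dataset(n_rec=4, T=200, seed=4)
        w = build_windows(ds, n_steps=20, stride=10)
        ae = fit_autoencoder(w, TOY, kind="lstm")
        rates = [score_novelty(ae, w, threshold=thr, config=TOY).flagged.mean()
                 for thr in np.linspace(0.0, 2.0, 8)]
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_untrained_model_rejected(self):
        from cardioloop.nn import LSTMAutoencoder
        ds = _toy_dataset()
        w = build_windows(ds, n_steps=20, stride=10)
        with pytest.raises(ValueError, match="fitted"):
            score_novelty(LSTMAutoencoder(n_steps=20, hidden_units=8), w, config=TOY)

    def test_isolation_forest_roundtrip(self):
        ds = _toy_dataset(n_rec=4, T=200, seed=5)
        w = build_windows(ds, n_steps=10, stride=10)
        est = novelty.fit_isolation_forest(w, TOY)
        res = novelty.score_isolation_forest(est, w)
        # contamination fixes the training flag rate near 16 %
        assert res.flagged.mean() == pytest.approx(0.16, abs=0.08)


class TestEmbedding:
    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.5, size=(60, 32))
        b = rng.normal(5, 0.5, size=(60, 32))
        hid = np.vstack([a, b])
        labels = np.array([0] * 60 + [1] * 60)
        pts = embed_latent(hid, labels, seed=0)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(pts, labels) > 0.5

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            embed_latent(np.zeros((5, 16)), np.zeros(5), n_neighbors=15)


class TestBoundary:
    def test_perfect_separation_scores_one(self):
        pts = np.vstack([np.random.default_rng(7).normal(0, 0.2, (40, 2)),
                         np.random.default_rng(8).normal(5, 0.2, (40, 2))])
        truth = np.array(["known"] * 40 + ["emerging"] * 40)
        acc, chance = boundary_separation(pts, truth, seed=0)
        assert acc == 1.0
        # permuted labels fall to roughly the class prior
        assert chance["mean"] == pytest.approx(0.5, abs=0.15)

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(200, 2))
        truth = np.array(["known", "emerging"] * 100)
        acc, _ = boundary_separation(pts, truth, seed=0)
        assert acc == pytest.approx(0.5, abs=0.12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            boundary_separation(np.zeros((10, 2)), np.zeros(10))


class TestVMeasure:
    def test_identical_labelings_perfect(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert v_measure(labels, labels) == (1.0, 1.0, 1.0)

    def test_single_cluster_zero_homogeneity(self):
        truth = np.array([0, 0, 1, 1])
        clusters = np.zeros(4)
        hom, com, v = v_measure(truth, clusters)
        assert hom == 0.0 and com == 1.0 and v == 0.0

    def test_cluster_id_permutation_invariant(self):
        rng = np.random.default_rng(10)
        truth = rng.integers(0, 3, 50)
        clusters = rng.integers(0, 4, 50)
        h1 = v_measure(truth, clusters)
        h2 = v_measure(truth, (clusters + 2) % 4)
        assert h1 == pytest.approx(h2)

    def test_matches_brute_force_entropy_and_reference(self):
        """20 random labelings agree with a direct entropy computation and
        with the library reference within 1e-9."""
        from collections import Counter
        from math import log
        from sklearn.metrics import homogeneity_completeness_v_measure

        def brute(truth, clusters):
            n = len(truth)
            def ent(labels):
                return -sum((c / n) * log(c / n) for c in Counter(labels).values())
            joint = Counter(zip(truth, clusters))
            h_ck = -sum((c / n) * log(c / Counter(clusters)[k[1]])
                        for k, c in joint.items())
            h_kc = -sum((c / n) * log(c / Counter(truth)[k[0]])
                        for k, c in joint.items())
            h_c, h_k = ent(truth), ent(clusters)
            hom = 1.0 if h_c == 0 else 1.0 - h_ck / h_c
            com = 1.0 if h_k == 0 else 1.0 - h_kc / h_k
            v = 0.0 if hom + com == 0 else 2 * hom * com / (hom + com)
            return hom, com, v

        rng = np.random.default_rng(11)
        for _ in range(20):
            truth = rng.integers(0, rng.integers(2, 5), 40)
            clusters = rng.integers(0, rng.integers(2, 6), 40)
            ours = v_measure(truth, clusters)
            assert ours == pytest.approx(brute(list(truth), list(clusters)), abs=1e-9)
            ref = homogeneity_completeness_v_measure(truth, clusters)
            assert ours == pytest.approx(ref, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        truth = rng.integers(0, 4, n)
        clusters = rng.integers(0, 4, n)
        hom, com, v = v_measure(truth, clusters)
        for x in (hom, com, v):
            assert -1e-12 <= x <= 1.0 + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            v_measure(np.array([]), np.array([]))

    def test_random_labels_near_zero(self):
        """V-measure of many random labelings of balanced types ~ 0."""
        rng = np.random.default_rng(12)
        truth = np.repeat(np.arange(3), 200)
        vs = [v_measure(truth, rng.integers(0, 3, truth.size))[2]
              for _ in range(10)]
        assert np.mean(vs) < 0.02


class TestIdentifyTypes:
    def test_well_separated_types_recovered(self):
        rng = np.random.default_rng(13)
        pts = np.vstack([rng.normal(c, 0.3, size=(30, 2))
                         for c in ((0, 0), (6, 0), (0, 6))])
        types = np.array(["H-D"] * 30 + ["H-NE"] * 30 + ["H-D+NE"] * 30, dtype=object)
        rows, mean_perf = identify_types(pts, types)
        assert mean_perf > 95.0
        single = [r for r in rows if "+" not in r["scenario"].replace("H-D+NE", "X")]
        assert all(r["v_measure"] == pytest.approx(1.0) for r in single)

    def test_empty_scenario_rejected(self):
        with pytest.raises(ValueError, match="no windows"):
            identify_types(np.zeros((4, 2)),
                           np.array(["H-D"] * 4, dtype=object))

    def test_sparse_ae_sanity_on_dialect_windows(self):
        ds = _toy_dataset(n_rec=4, T=120, seed=14)
        w = build_windows(ds, n_steps=10, stride=10)
        cfg = NoveltyConfig(sparse_steps=10, sparse_epochs=40)
        sae = fit_autoencoder(w, cfg, kind="sparse")
        assert np.isfinite(sae.train_losses_).all()
        res = score_novelty(sae, w, config=cfg)
        assert res.flagged.mean() <= 0.05
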