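import numpy as np
import pytest

import mdinvert as mi
from mdinvert.dictionary import DictionaryEntry, match


class TestClustering:
    def test_two_separated_groups_get_one_representative_each(self):
        rng = np.random.default_rng(0)
        a = np.array([1.0, 0.0, 0.0, 0.0]) + 0.01 * rng.random((5, 4))
        b = np.array([0.0, 0.0, 1.0, 0.0]) + 0.01 * rng.random((5, 4))
        signals = np.vstack([a, b])
        reps, idx = mi.cluster_training_signals(signals, 2, seed=0)
        groups = {int(i >= 5) for i in idx}
        assert groups == {0, 1}

    def test_identity_when_all_signals_kept(self):
        rng = np.random.default_rng(1)
        signals = rng.random((7, 10))
        reps, idx = mi.cluster_training_signals(signals, 7, seed=0)
        assert np.array_equal(reps, signals)
        assert np.array_equal(idx, np.arange(7))

    def test_representatives_are_members(self):
        rng = np.random.default_rng(2)
        signals = rng.random((30, 12))
        reps, idx = mi.cluster_training_signals(signals, 5, seed=3)
        for rep, i in zip(reps, idx):
            assert np.array_equal(rep, signals[i])

    def test_too_many_representatives_rejected(self):
        with pytest.raises(ValueError):
            mi.cluster_training_signals(np.ones((3, 4)), 5, seed=0)


class TestCosineSimilarity:
    def test_identical_and_scaled_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert mi.cosine_similarity(v, v) == pytest.approx(1.0)
        assert mi.cosine_similarity(v, 2 * v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert mi.cosine_similarity(np.array([1.0, 0.0]),
                                    np.array([0.0, 1.0])) == \
            pytest.approx(0.0, abs=1e-15)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            mi.cosine_similarity(np.zeros(3), np.ones(3))


class TestMatch:
    def _entries(self, signals):
        return [DictionaryEntry(s, s[:, None], np.ones((1, 9)), np.ones(1))
                for s in signals]

    def test_query_contained_in_dictionary(self):
        rng = np.random.default_rng(0)
        signals = rng.random((20, 15))
        j, sim = match(signals[7], self._entries(signals))
        assert j == 7
        assert sim == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_index(self):
        s = np.array([1.0, 2.0, 3.0])
        entries = self._entries([2 * s, s, s])
        j, sim = match(s, entries)
        assert j == 0  # all collinear -> similarity 1, lowest index wins
        assert sim == pytest.approx(1.0)

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(4)
        signals = rng.random((100, 25))
        entries = self._entries(signals)
        for _ in range(10):
            q = rng.random(25)
            j, sim = match(q, entries)
            # independent brute-force loop
            sims = [q @ s / (np.linalg.norm(q) * np.linalg.norm(s))
                    for s in signals]
            assert j == int(np.argmax(sims))
            assert sim == pytest.approx(max(sims), abs=1e-12)

    def test_scale_invariance_of_matching(self):
        rng = np.random.default_rng(5)
        signals = rng.random((10, 8))
        entries = self._entries(signals)
        q = rng.random(8)
        assert match(q, entries)[0] == match(5.0 * q, entries)[0]


class TestBuildDictionary:
    def test_entry_synthesis_identity(self, small_dictionary):
        for ent in small_dictionary.entries:
            for e in ent:
                assert np.allclose(e.signal, e.kernels @ e.weights,
                                   atol=1e-10)

    def test_entry_count_and_plan_sharing(self, small_dictionary, small_plan):
        assert small_dictionary.nb == small_plan.nb
        assert small_dictionary.plan == small_plan
        for ent in small_dictionary.entries:
            assert 1 <= len(ent) <= 6

    def test_deterministic_build(self, phantom, small_protocol, small_plan,
                                 fast_mc_config):
        rng = np.random.default_rng(11)
        train, _ = mi.generate_training_set(
            phantom, 0.2, (130,), 6, small_protocol, rng)
        d1 = mi.build_dictionary(train, small_protocol, small_plan,
                                 fast_mc_config, n_reps=3, seed=5)
        d2 = mi.build_dictionary(train, small_protocol, small_plan,
                                 fast_mc_config, n_reps=3, seed=5)
        for e1, e2 in zip(d1.entries, d2.entries):
            assert len(e1) == len(e2)
            for a, b in zip(e1, e2):
                assert np.array_equal(a.signal, b.signal)
                assert np.array_equal(a.components, b.components)

    def test_empty_training_set_rejected(self, small_protocol, small_plan,
                                         fast_mc_config):
        with pytest.raises(ValueError):
            mi.build_dictionary(np.empty((0, small_protocol.M)),
                                small_protocol, small_plan, fast_mc_config,
                                n_reps=1, seed=0)

    def test_hdf5_roundtrip(self, small_dictionary, tmp_path):
        path = tmp_path / "dict.h5"
        small_dictionary.save(path)
        loaded = mi.InformedDictionary.load(path)
        assert loaded.plan == small_dictionary.plan
        assert loaded.protocol_hash == small_dictionary.protocol_hash
        for e1, e2 in zip(loaded.entries[0], small_dictionary.entries[0]):
            assert np.array_equal(e1.signal, e2.signal)
            assert np.array_equal(e1.kernels, e2.kernels)
            assert np.array_equal(e1.components, e2.components)


class TestDmInversion:
    def test_closure_on_dictionary_signal(self, small_dictionary,
                                          small_protocol, small_plan):
        # feed a signal whose plan-row-0 resampling equals entry 0's signal
        entry = small_dictionary.entries[0][0]
        full = np.zeros(small_protocol.M)
        # build a full signal that resamples to the entry signal on row 0
        full[small_plan.indices[0]] = entry.signal
        sols = mi.dm_invert_voxel(full, small_protocol, small_plan,
                                  small_dictionary)
        assert sols[0].residual_norm == pytest.approx(0.0, abs=1e-8)

    def test_weights_nonnegative(self, small_signal, small_protocol,
                                 small_plan, small_dictionary):
        sols = mi.dm_invert_voxel(small_signal, small_protocol, small_plan,
                                  small_dictionary)
        assert len(sols) == small_plan.nb
        for s in sols:
            assert np.all(s.weights >= 0)

    def test_plan_mismatch_rejected(self, small_signal, small_protocol,
                                    small_dictionary):
        other = mi.draw_bootstrap_plan(small_protocol.M, 5, seed=99)
        with pytest.raises(ValueError):
            mi.dm_invert_voxel(small_signal, small_protocol, other,
                               small_dictionary)

    def test_residual_is_nnls_optimum_in_matched_subspace(
            self, small_signal, small_protocol, small_plan, small_dictionary):
        from mdinvert.dictionary import match as match_fn
        sols = mi.dm_invert_voxel(small_signal, small_protocol, small_plan,
                                  small_dictionary)
        for b in (0, 2):
            s_b = small_signal[small_plan.indices[b]]
            j, _ = match_fn(s_b, small_dictionary.unit_signals(b))
            K = small_dictionary.entries[b][j].kernels
            _, r_opt = mi.nnls_fit(K, s_b)
            assert sols[b].residual_norm == pytest.approx(r_opt, abs=1e-10)
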