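import numpy as np
import pytest

from madeconv import _kernels
from madeconv.data import Dataset, make_records
from madeconv.encoding import (
    ALPHABET,
    AllelePseudoSequence,
    FeatureLayout,
    encode_example,
    encode_peptide_features,
    encode_pseudo,
    enumerate_cores,
)
from madeconv.network import (
    Ensemble,
    OUTPUT_BA,
    OUTPUT_EL,
    TrainConfig,
    build_training_arrays,
    core_output,
    ensemble_predict,
    epoch_order,
    forward,
    init_network,
    load_ensemble,
    loss_gradients,
    run_epoch,
    save_ensemble,
    sgd_update,
    stop_set_error,
    train_fold,
)


def rand_pep(rng, length=9):
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, length))


def rand_pseudo(rng, name="AL", length=34):
    return AllelePseudoSequence(name, rand_pep(rng, length))


@pytest.fixture(scope="module")
def small_layout():
    return FeatureLayout(core_len=9, length_bounds=(8, 11), pseudo_len=10)


@pytest.fixture(scope="module")
def small_net(small_layout):
    return init_network(small_layout, hidden_size=4, seed_key=(0, 1))


class TestForward:
    def test_single_core_equals_manual(self, small_net, small_layout, enc):
        rng = np.random.default_rng(0)
        pep = rand_pep(rng)
        pseudo = rand_pseudo(rng, length=10)
        score, core = forward(small_net, pep, pseudo, small_layout, enc, "EL")
        assert core.core == pep
        x = encode_peptide_features(core, pep, small_layout, enc)
        arow = encode_pseudo(pseudo, small_layout, enc)
        h = 1 / (1 + np.exp(-(small_net.wpt @ x + small_net.wat @ arow
                              + small_net.bh)))
        out = 1 / (1 + np.exp(-(h @ small_net.wo[:, OUTPUT_EL]
                                + small_net.bo[OUTPUT_EL])))
        assert score == pytest.approx(float(out), abs=1e-14)

    def test_max_over_cores_matches_exhaustive(self, small_net, small_layout,
                                               enc):
        rng = np.random.default_rng(1)
        for length in (8, 10, 11):
            pep = rand_pep(rng, length)
            pseudo = rand_pseudo(rng, length=10)
            score, chosen = forward(small_net, pep, pseudo, small_layout,
                                    enc, "EL")
            arow = encode_pseudo(pseudo, small_layout, enc)
            brute = max(
                core_output(small_net,
                            encode_peptide_features(c, pep, small_layout, enc),
                            arow, OUTPUT_EL)
                for c in enumerate_cores(pep, 9, small_layout.length_bounds))
            assert score == pytest.approx(brute, abs=1e-14)

    def test_scores_in_unit_interval(self, small_net, small_layout, enc):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s, _ = forward(small_net, rand_pep(rng), rand_pseudo(rng, length=10),
                           small_layout, enc, "BA")
            assert 0.0 < s < 1.0


class TestGradients:
    def test_finite_difference_property(self, small_layout, enc):
        rng = np.random.default_rng(3)
        eps = 1e-6
        for trial in range(5):
            net = init_network(small_layout, 3, seed_key=(9, trial))
            pep = rand_pep(rng)
            pseudo = rand_pseudo(rng, length=10)
            core = enumerate_cores(pep, 9, small_layout.length_bounds)[0]
            x = encode_peptide_features(core, pep, small_layout, enc)
            arow = encode_pseudo(pseudo, small_layout, enc)
            target, o = 0.7, OUTPUT_EL
            grads = loss_gradients(net, x, arow, target, o)

            def loss():
                out = core_output(net, x, arow, o)
                return 0.5 * (out - target) ** 2

            for name in ("wpt", "wat", "bh", "wo", "bo"):
                w = getattr(net, name)
                flat = w.ravel()
                idx = rng.choice(flat.size, size=min(10, flat.size),
                                 replace=False)
                for i in idx:
                    old = flat[i]
                    flat[i] = old + eps
                    up = loss()
                    flat[i] = old - eps
                    dn = loss()
                    flat[i] = old
                    num = (up - dn) / (2 * eps)
                    ana = grads[name].ravel()[i]
                    assert num == pytest.approx(ana, rel=1e-5, abs=1e-10)

    def test_zero_error_leaves_weights(self, small_layout, enc):
        rng = np.random.default_rng(4)
        net = init_network(small_layout, 3, seed_key=(5,))
        pep, pseudo = rand_pep(rng), rand_pseudo(rng, length=10)
        score, _ = forward(net, pep, pseudo, small_layout, enc, "EL")
        before = net.copy_weights()
        sgd_update(net, pep, pseudo, score, "EL", small_layout, enc, lr=0.05)
        after = net.copy_weights()
        for b, a in zip(before, after):
            assert np.allclose(b, a, atol=1e-15)

    def test_ba_update_leaves_el_private_weights(self, small_layout, enc):
        rng = np.random.default_rng(5)
        net = init_network(small_layout, 3, seed_key=(6,))
        wo_el = net.wo[:, OUTPUT_EL].copy()
        bo_el = net.bo[OUTPUT_EL]
        sgd_update(net, rand_pep(rng), rand_pseudo(rng, length=10), 0.9, "BA",
                   small_layout, enc, lr=0.05)
        assert np.array_equal(net.wo[:, OUTPUT_EL], wo_el)
        assert net.bo[OUTPUT_EL] == bo_el
        # shared input->hidden weights did move
        assert not np.array_equal(net.wpt,
                                  init_network(small_layout, 3, (6,)).wpt)

    def test_kernel_step_matches_reference(self, small_layout, enc):
        """The numba epoch kernel and the numpy reference update must agree."""
        rng = np.random.default_rng(6)
        pseudo = rand_pseudo(rng, length=10)
        peps = [rand_pep(rng, L) for L in (9, 10, 8, 11)]
        df = make_records(peps, [1.0, 0.0, 1.0, 0.3], pseudo.allele, "EL", "SA")
        df.loc[3, "assay"] = "BA"
        arrays = build_training_arrays(df, {pseudo.allele: pseudo},
                                       small_layout, enc)
        net_a = init_network(small_layout, 3, seed_key=(7,))
        net_b = init_network(small_layout, 3, seed_key=(7,))
        order = np.arange(4, dtype=np.int64)
        run_epoch(net_a, arrays, order, lr=0.05)
        for i, pep in enumerate(peps):
            assay = "BA" if i == 3 else "EL"
            sgd_update(net_b, pep, pseudo, float(df["target"][i]), assay,
                       small_layout, enc, lr=0.05)
        for wa, wb in zip(net_a.copy_weights(), net_b.copy_weights()):
            assert np.allclose(wa, wb, atol=1e-12)


def _separable_arrays(layout, enc, n=120, seed=0):
    """EL set where positives carry a fixed anchor pair: separable."""
    rng = np.random.default_rng(seed)
    pseudo = rand_pseudo(rng, "AL-1", 10)
    pos = ["A" + "L" + rand_pep(rng, 7) for _ in range(n // 2)]
    neg = [rand_pep(rng, 9) for _ in range(n // 2)]
    df = make_records(pos + neg, [1.0] * (n // 2) + [0.0] * (n // 2),
                      pseudo.allele, "EL", "SA")
    df["partition"] = np.arange(n) % 5
    return build_training_arrays(df, {pseudo.allele: pseudo}, layout, enc), df


class TestTrainFold:
    def test_converges_on_separable_set(self, small_layout, enc):
        from madeconv.metrics import auc
        arrays, df = _separable_arrays(small_layout, enc)
        config = TrainConfig(hidden_sizes=(5,), seeds_per_size=1,
                             n_iterations=50, burn_in=5, early_stopping=False,
                             length_bounds=small_layout.length_bounds)
        train_idx = np.flatnonzero(arrays.partition != 0)
        model = train_fold(arrays, train_idx, np.array([], dtype=np.int64),
                           5, config, seed_key=(1, 0))
        scores, _ = _kernels.batch_scores(
            model.wpt, model.wat, model.bh, model.wo, model.bo,
            arrays.core_feats, arrays.core_start[train_idx],
            arrays.core_count[train_idx], arrays.allele_enc[0], OUTPUT_EL)
        assert auc(scores, arrays.target[train_idx] > 0) > 0.99

    def test_deterministic_trajectory(self, small_layout, enc):
        arrays, _ = _separable_arrays(small_layout, enc, seed=1)
        config = TrainConfig(hidden_sizes=(4,), n_iterations=10, burn_in=2,
                             early_stopping=False,
                             length_bounds=small_layout.length_bounds)
        idx = np.arange(arrays.n_records)
        m1 = train_fold(arrays, idx, np.array([], dtype=np.int64), 4, config,
                        (3, 1))
        m2 = train_fold(arrays, idx, np.array([], dtype=np.int64), 4, config,
                        (3, 1))
        for a, b in zip(m1.copy_weights(), m2.copy_weights()):
            assert np.array_equal(a, b)

    def test_early_stopping_no_worse_than_final(self, small_layout, enc):
        arrays, _ = _separable_arrays(small_layout, enc, seed=2)
        stop_idx = np.flatnonzero(arrays.partition == 0)
        train_idx = np.flatnonzero(arrays.partition != 0)
        base = dict(hidden_sizes=(4,), n_iterations=15, burn_in=2,
                    length_bounds=small_layout.length_bounds)
        es = train_fold(arrays, train_idx, stop_idx, 4,
                        TrainConfig(early_stopping=True, **base), (4, 0))
        plain = train_fold(arrays, train_idx, stop_idx, 4,
                           TrainConfig(early_stopping=False, **base), (4, 0))
        assert stop_set_error(es, arrays, stop_idx) <= \
            stop_set_error(plain, arrays, stop_idx) + 1e-12

    def test_empty_train_set_errors(self, small_layout, enc):
        arrays, _ = _separable_arrays(small_layout, enc, seed=3)
        config = TrainConfig(length_bounds=small_layout.length_bounds)
        with pytest.raises(ValueError):
            train_fold(arrays, np.array([], dtype=np.int64),
                       np.array([], dtype=np.int64), 4, config, (0,))


class TestEnsemble:
    def _ensemble(self, small_layout, enc, n_members=2):
        rng = np.random.default_rng(8)
        pseudo = rand_pseudo(rng, "AL-1", 10)
        members = [init_network(small_layout, 4, (i,), test_fold=i % 5)
                   for i in range(n_members)]
        config = TrainConfig(length_bounds=small_layout.length_bounds)
        return Ensemble(members=members, layout=small_layout, enc=enc,
                        pseudo_table={pseudo.allele: pseudo}, config=config), \
            pseudo

    def test_single_member_equals_forward(self, small_layout, enc):
        ens, pseudo = self._ensemble(small_layout, enc, 1)
        rng = np.random.default_rng(9)
        pep = rand_pep(rng)
        assert ensemble_predict(ens, pep, pseudo.allele, "EL") == \
            pytest.approx(forward(ens.members[0], pep, pseudo, small_layout,
                                  enc, "EL")[0])

    def test_mean_aggregation(self, small_layout, enc):
        ens, pseudo = self._ensemble(small_layout, enc, 2)
        rng = np.random.default_rng(10)
        pep = rand_pep(rng)
        parts = [forward(m, pep, pseudo, small_layout, enc, "EL")[0]
                 for m in ens.members]
        assert ens.predict(pep, pseudo.allele) == \
            pytest.approx(float(np.mean(parts)))

    def test_order_invariance(self, small_layout, enc):
        ens, pseudo = self._ensemble(small_layout, enc, 3)
        rng = np.random.default_rng(11)
        pep = rand_pep(rng)
        before = ens.predict(pep, pseudo.allele)
        ens.members.reverse()
        assert ens.predict(pep, pseudo.allele) == pytest.approx(before)

    def test_empty_ensemble_rejected(self, small_layout, enc):
        with pytest.raises(ValueError):
            Ensemble(members=[], layout=small_layout, enc=enc,
                     pseudo_table={}, config=TrainConfig(
                         length_bounds=small_layout.length_bounds))

    def test_serialization_round_trip_exact(self, small_layout, enc,
                                            tmp_path):
        ens, pseudo = self._ensemble(small_layout, enc, 2)
        path = tmp_path / "model.json"
        save_ensemble(ens, path)
        back = load_ensemble(path)
        assert back.layout == ens.layout
        assert back.pseudo_table == ens.pseudo_table
        for a, b in zip(ens.members, back.members):
            for wa, wb in zip(a.copy_weights(), b.copy_weights()):
                assert np.array_equal(wa, wb)
        rng = np.random.default_rng(12)
        pep = rand_pep(rng)
        assert back.predict(pep, pseudo.allele) == \
            pytest.approx(ens.predict(pep, pseudo.allele), abs=1e-15)


class TestEpochOrder:
    def test_deterministic_and_permutation(self):
        active = np.arange(50, dtype=np.int64)
        a = epoch_order((1, 2), 3, active)
        b = epoch_order((1, 2), 3, active)
        assert np.array_equal(a, b)
        assert sorted(a) == list(active)
        assert not np.array_equal(epoch_order((1, 2), 4, active), a)
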