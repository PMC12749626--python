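"""Reaction model: message-passing oracle, invariances, training contract."""

import dataclasses

import numpy as np
import pytest

from reactionfunnel import nn
from reactionfunnel.chemgraph import ConditionVocabulary, encode_conditions, mol_to_graph
from reactionfunnel.datasplit import Fold, make_split
from reactionfunnel.errors import SplitError
from reactionfunnel.gtnn import (
    GTNNConfig,
    GTNNModel,
    PhiMLP,
    PsiMLP,
    learning_rate_at,
    message_passing_layer,
    train_fold,
)
from reactionfunnel.surf import ReactionDataset
from reactionfunnel.synthdata import SyntheticSpec, generate_dataset

from conftest import make_record

SMALL_VOCAB = {
    "reagent": ["(NH4)2S2O8"],
    "solvent": ["MeCN/H2O 3:2"],
    "catalyst": ["AgNO3", "AgBF4"],
    "additive": ["TFA", "none"],
    "atmosphere": ["air"],
}


def small_model(mode="2d", seed=0, **overrides) -> GTNNModel:
    cfg = GTNNConfig(
        hidden_dim=8, embed_dim=8, post_pool_dim=8, n_layers=2, pool_heads=2,
        pool_seeds=2, mode=mode, fourier_k=4, seed=seed, **overrides,
    )
    return GTNNModel(cfg, ConditionVocabulary(SMALL_VOCAB))


def silu(x):
    return x / (1.0 + np.exp(-x))


class TestMessagePassingOracle:
    def test_three_node_path_matches_hand_evaluation(self):
        """psi/phi with hand-set tiny weights on a 2-feature, 3-node path
        graph must reproduce an independent element-by-element evaluation
        of the message-passing update to 1e-10."""
        rng = np.random.default_rng(0)
        d = 2
        psi = PsiMLP(d, 0, rng)
        phi = PhiMLP(d, rng)
        # hand-specified small weights
        psi.wi.data = np.array([[0.1, -0.2], [0.3, 0.0]])
        psi.wj.data = np.array([[0.0, 0.5], [-0.1, 0.2]])
        psi.b1.data = np.array([0.05, -0.05])
        psi.lin2.w.data = np.array([[1.0, 0.2], [-0.3, 0.4]])
        psi.lin2.b.data = np.array([0.01, 0.02])
        phi.wh.data = np.array([[0.2, 0.1], [0.0, -0.4]])
        phi.wm.data = np.array([[0.3, -0.3], [0.5, 0.25]])
        phi.b1.data = np.array([-0.02, 0.03])
        phi.lin2.w.data = np.array([[0.6, 0.0], [0.1, 0.9]])
        phi.lin2.b.data = np.array([0.0, -0.01])

        h = np.array([[0.5, -1.0], [0.25, 0.75], [-0.5, 0.1]])
        # path graph 0-1-2, messages flow along both directions of each bond
        directed = np.array([[0, 1], [1, 0], [1, 2], [2, 1]])

        out = message_passing_layer(nn.Tensor(h), directed, psi, phi).data

        # independent brute-force evaluation
        def psi_hand(hi, hj):
            z = hi @ psi.wi.data + hj @ psi.wj.data + psi.b1.data
            return silu(silu(z) @ psi.lin2.w.data + psi.lin2.b.data)

        expected = np.zeros_like(h)
        neighbors = {0: [1], 1: [0, 2], 2: [1]}
        for i in range(3):
            m = np.zeros(d)
            for j in neighbors[i]:
                m += psi_hand(h[i], h[j])
            z = h[i] @ phi.wh.data + m @ phi.wm.data + phi.b1.data
            expected[i] = silu(z) @ phi.lin2.w.data + phi.lin2.b.data
        assert np.abs(out - expected).max() < 1e-10

    def test_isolated_node_gets_zero_message(self):
        rng = np.random.default_rng(1)
        d = 4
        psi, phi = PsiMLP(d, 0, rng), PhiMLP(d, rng)
        h = np.random.default_rng(2).normal(size=(1, d))
        out = message_passing_layer(
            nn.Tensor(h), np.zeros((0, 2), dtype=int), psi, phi
        ).data
        z = h @ phi.wh.data + np.zeros(d) @ phi.wm.data + phi.b1.data
        expected = silu(z) @ phi.lin2.w.data + phi.lin2.b.data
        assert np.allclose(out, expected, atol=1e-12)

    def test_neighbor_order_irrelevant(self):
        rng = np.random.default_rng(3)
        d = 4
        psi, phi = PsiMLP(d, 0, rng), PhiMLP(d, rng)
        h = rng.normal(size=(4, d))
        edges = np.array([[0, 1], [0, 2], [0, 3]])
        out1 = message_passing_layer(nn.Tensor(h), edges, psi, phi).data
        out2 = message_passing_layer(nn.Tensor(h), edges[::-1].copy(), psi, phi).data
        assert np.allclose(out1, out2, atol=1e-12)


def _permute_graph(graph, perm):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    g = dataclasses.replace(
        graph,
        atom_features=graph.atom_features[perm],
        edges=inv[graph.edges],
        conformers=None if graph.conformers is None else graph.conformers[:, perm],
    )
    return g


class TestInvariances:
    def test_forward_invariant_to_atom_relabeling(self, rng):
        model = small_model()
        arene = mol_to_graph("Cc1ccncc1")
        acid = mol_to_graph("CC(C)C(=O)O")
        cond = encode_conditions(make_record(), model.vocab)
        base = model.forward(arene, acid, cond)
        for _ in range(3):
            perm_a = rng.permutation(arene.n_atoms)
            perm_b = rng.permutation(acid.n_atoms)
            v = model.forward(_permute_graph(arene, perm_a),
                              _permute_graph(acid, perm_b), cond)
            assert abs(v - base) < 1e-6

    def test_forward_invariant_to_rigid_motion(self, rng):
        model = small_model(mode="3d")
        arene = mol_to_graph("Cc1ccncc1", with_conformers=True, n_conformers=2, seed=1)
        acid = mol_to_graph("CC(C)C(=O)O", with_conformers=True, n_conformers=2, seed=1)
        cond = encode_conditions(make_record(), model.vocab)
        base = model.forward(arene, acid, cond, conformer=0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        for g in (arene, acid):
            g.conformers[0] = g.conformers[0] @ q + rng.normal(size=3)
        moved = model.forward(arene, acid, cond, conformer=0)
        assert abs(moved - base) < 1e-9

    def test_forward_deterministic_and_in_range(self):
        model = small_model()
        arene = mol_to_graph("c1ccncc1")
        acid = mol_to_graph("CC(=O)O")
        cond = encode_conditions(make_record(), model.vocab)
        v1 = model.forward(arene, acid, cond)
        v2 = model.forward(arene, acid, cond)
        assert v1 == v2
        assert 0.0 <= v1 <= 1.0

    def test_swapping_towers_changes_output(self):
        """The arene and acid towers are unshared, so swapping the inputs
        must (generically) change the prediction."""
        model = small_model(seed=7)
        cond = encode_conditions(make_record(), model.vocab)
        diffs = []
        for smi_a, smi_b in [("c1ccncc1", "CC(=O)O"), ("Cc1ccncc1", "CCC(=O)O"),
                             ("c1cnc(C)nc1", "OC(=O)C1CC1")]:
            a, b = mol_to_graph(smi_a), mol_to_graph(smi_b)
            diffs.append(abs(model.forward(a, b, cond) - model.forward(b, a, cond)))
        assert max(diffs) > 1e-8

    def test_condition_length_mismatch_rejected(self):
        model = small_model()
        g = mol_to_graph("c1ccncc1")
        with pytest.raises(ValueError, match="condition"):
            model.forward(g, g, np.zeros(3))


class TestConformerAveraging:
    def test_predict_equals_mean_of_per_conformer_forwards(self):
        model = small_model(mode="3d")
        rec = make_record(reagent="(NH4)2S2O8", solvent="MeCN/H2O 3:2",
                          catalyst="AgNO3", additive="TFA", atmosphere="air")
        k = 4
        pred = model.predict(rec, n_conformers=k, seed=3)
        cond = encode_conditions(rec, model.vocab)
        arene = mol_to_graph(rec.arene, with_conformers=True, n_conformers=k, seed=3)
        acid = mol_to_graph(rec.acid, with_conformers=True, n_conformers=k, seed=3)
        per_conf = [model.forward(arene, acid, cond, conformer=i) for i in range(k)]
        assert abs(pred - float(np.mean(per_conf))) < 1e-12

    def test_single_conformer_prediction_is_forward(self):
        model = small_model(mode="3d")
        rec = make_record()
        pred = model.predict(rec, n_conformers=1, seed=5)
        cond = encode_conditions(rec, model.vocab)
        arene = mol_to_graph(rec.arene, with_conformers=True, n_conformers=1, seed=5)
        acid = mol_to_graph(rec.acid, with_conformers=True, n_conformers=1, seed=5)
        assert pred == pytest.approx(model.forward(arene, acid, cond, 0), abs=1e-15)


class TestConfigAndSchedule:
    def test_learning_rate_step_decay(self):
        cfg = GTNNConfig()
        assert learning_rate_at(cfg, 0) == pytest.approx(1e-4)
        assert learning_rate_at(cfg, 99) == pytest.approx(1e-4)
        assert learning_rate_at(cfg, 150) == pytest.approx(5e-5)
        assert learning_rate_at(cfg, 250) == pytest.approx(2.5e-5)

    def test_decay_once_variant(self):
        cfg = GTNNConfig(lr_decay_once=True)
        assert learning_rate_at(cfg, 250) == pytest.approx(5e-5)

    def test_parameter_count_near_two_million(self):
        vocab = ConditionVocabulary({
            "reagent": ["r1", "r2", "r3", "r4"],
            "solvent": ["s1", "s2", "s3", "s4"],
            "catalyst": [f"c{i}" for i in range(11)],
            "additive": ["a1", "a2", "a3", "a4"],
            "atmosphere": ["air", "N2"],
        })
        n = GTNNModel(GTNNConfig(), vocab).n_parameters()
        assert 1_500_000 <= n <= 2_500_000

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GTNNConfig(lr_decay=0.0)
        with pytest.raises(ValueError):
            GTNNConfig(ema_factor=1.0)
        with pytest.raises(ValueError):
            GTNNConfig(mode="4d")


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset(
        SyntheticSpec(seed=21, n_arenes=6, n_acids=5, n_reactions=120)
    )


class TestTraining:
    def test_short_training_runs_and_tracks_best(self, tiny_dataset):
        split = make_split(tiny_dataset, "0D", k=3, seed=0)
        cfg = GTNNConfig.reduced(max_epochs=4, seed=0, patience=None,
                                 hidden_dim=16, embed_dim=16, post_pool_dim=16)
        res = train_fold(tiny_dataset, split.folds[0], cfg)
        assert len(res.history["val_mae"]) == 4
        assert res.best_epoch == int(np.argmin(res.history["val_mae"]))
        assert res.history["lr"][0] == pytest.approx(cfg.learning_rate)

    def test_empty_partition_rejected(self, tiny_dataset):
        cfg = GTNNConfig.reduced(max_epochs=1)
        with pytest.raises(SplitError):
            train_fold(tiny_dataset, Fold(train=[], val=["R000001"], test=[]), cfg)

    def test_checkpoint_round_trip(self, tiny_dataset, tmp_path):
        model = small_model(seed=2)
        path = tmp_path / "m.npz"
        model.save(path)
        loaded = GTNNModel.load(path)
        arene, acid = mol_to_graph("c1ccncc1"), mol_to_graph("CC(=O)O")
        cond = encode_conditions(make_record(), model.vocab)
        assert loaded.forward(arene, acid, cond) == model.forward(arene, acid, cond)
        assert loaded.config == model.config
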