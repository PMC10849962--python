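"""Network architecture contracts: message passing vs a plain-loop oracle,
E(3)-invariance, permutation symmetry, pooling, baseline, parameter counts."""

import numpy as np
import pytest

from lsfgdl.autodiff import Tensor
from lsfgdl.graphs import MolGraph, build_graph, generate_conformers
from lsfgdl.networks import (
    BorylationNet,
    ECFP4NN,
    GraphBatch,
    MessagePassingLayer,
    ModelConfig,
    count_parameters,
    ecfp4,
)
from lsfgdl.nn import MLP, Linear

from conftest import small_config


# ------------------------------------------------------------- loop oracles


def _silu(x):
    return x / (1.0 + np.exp(-x))


def _mlp_forward(mlp: MLP, x: np.ndarray) -> np.ndarray:
    """Independent plain-loop re-implementation of the MLP forward pass."""
    h = x
    last = len(mlp.layers) - 1
    for i, lin in enumerate(mlp.layers):
        h = h @ lin.weight.data + lin.bias.data
        if i < last or mlp.activate_last:
            h = _silu(h)
    return h


def _loop_message_pass(layer: MessagePassingLayer, h, edges, efeat=None):
    """Plain-loop oracle for one message-passing update."""
    n = h.shape[0]
    out_dim = layer.psi.layers[-1].weight.data.shape[1]
    agg = np.zeros((n, out_dim))
    for k, (i, j) in enumerate(edges):
        parts = [h[i], h[j]]
        if layer.edge_dim:
            parts.append(efeat[k])
        agg[i] += _mlp_forward(layer.psi, np.concatenate(parts))
    return np.stack(
        [_mlp_forward(layer.phi, np.concatenate([h[i], agg[i]])) for i in range(n)]
    )


def _batch_of(feats, edges, efeat=None, variant="2D"):
    g = MolGraph(
        atom_features=np.asarray(feats, float),
        edges=np.asarray(edges, int).reshape(-1, 2),
        variant=variant,
        distance_features=None if efeat is None else np.asarray(efeat, float),
    )
    return GraphBatch.from_graphs([g])


def test_message_pass_matches_loop_oracle_on_path_graph(rng):
    hidden, edge_dim = 6, 4
    layer = MessagePassingLayer(hidden, edge_dim, 8, np.random.default_rng(0))
    h = rng.normal(size=(3, hidden))
    edges = [(0, 1), (1, 0), (1, 2), (2, 1)]  # 3-node path
    efeat = rng.normal(size=(4, edge_dim))
    batch = _batch_of(np.zeros((3, 1)), edges, efeat)
    got = layer(Tensor(h), batch).data
    np.testing.assert_allclose(got, _loop_message_pass(layer, h, edges, efeat), atol=1e-6)


def test_message_pass_loop_oracle_2d_graphs_up_to_five_atoms(rng):
    hidden = 5
    layer = MessagePassingLayer(hidden, 0, 7, np.random.default_rng(1))
    for n in range(1, 6):
        h = rng.normal(size=(n, hidden))
        edges = [(i, j) for i in range(n) for j in range(n) if i != j and rng.random() < 0.5]
        edges = edges + [(j, i) for i, j in edges if (j, i) not in edges]
        batch = _batch_of(np.zeros((n, 1)), edges if edges else np.zeros((0, 2)))
        got = layer(Tensor(h), batch).data
        np.testing.assert_allclose(got, _loop_message_pass(layer, h, np.array(edges, int).reshape(-1, 2)), atol=1e-6)


def test_isolated_node_uses_empty_neighbour_sum():
    hidden = 4
    layer = MessagePassingLayer(hidden, 0, 4, np.random.default_rng(2))
    h = np.random.default_rng(3).normal(size=(1, hidden))
    batch = _batch_of(np.zeros((1, 1)), np.zeros((0, 2)))
    got = layer(Tensor(h), batch).data
    expected = _mlp_forward(layer.phi, np.concatenate([h[0], np.zeros(hidden)]))
    np.testing.assert_allclose(got[0], expected, atol=1e-12)


# -------------------------------------------------------- symmetry properties


def _permute_graph(g: MolGraph, perm: np.ndarray) -> MolGraph:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return MolGraph(
        atom_features=g.atom_features[perm],
        edges=inv[g.edges] if len(g.edges) else g.edges,
        variant=g.variant,
        coords=None if g.coords is None else g.coords[perm],
        distance_features=g.distance_features,
    )


@pytest.mark.parametrize("arch", ["GNN", "GTNN"])
def test_pooled_output_permutation_invariant(arch, rng):
    cfg = small_config(architecture=arch, graph_variant="3D", task="yield")
    conf = generate_conformers("CCOc1ccccc1", n=1, seed=0).coords[0]
    g = build_graph("CCOc1ccccc1", "3D", conformer=conf, n_frequencies=cfg.n_frequencies)
    net = BorylationNet(cfg, condition_width=5, seed=7)
    cond = np.eye(5)[[0]]
    base = net(GraphBatch.from_graphs([g]), cond).data
    for _ in range(3):
        perm = rng.permutation(g.n_atoms)
        out = net(GraphBatch.from_graphs([_permute_graph(g, perm)]), cond).data
        np.testing.assert_allclose(out, base, atol=1e-6)


def test_atomistic_output_permutation_equivariant(rng):
    cfg = small_config(architecture="aGNN", graph_variant="2D", task="regio")
    g = build_graph("COc1ccncc1", "2D")
    net = BorylationNet(cfg, seed=11)
    base = net(GraphBatch.from_graphs([g])).data.ravel()
    for _ in range(3):
        perm = rng.permutation(g.n_atoms)
        out = net(GraphBatch.from_graphs([_permute_graph(g, perm)])).data.ravel()
        np.testing.assert_allclose(out, base[perm], atol=1e-8)


def test_e3_invariance_of_3d_models(rng):
    cfg = small_config(architecture="GNN", graph_variant="3D", task="yield")
    net = BorylationNet(cfg, condition_width=4, seed=3)
    conf = generate_conformers("CC(C)c1ccccc1", n=1, seed=0).coords[0]
    cond = np.eye(4)[[1]]
    base = net(
        GraphBatch.from_graphs(
            [build_graph("CC(C)c1ccccc1", "3D", conformer=conf, n_frequencies=cfg.n_frequencies)]
        ),
        cond,
    ).data
    for _ in range(20):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = conf @ q.T + rng.uniform(-20, 20, size=3)
        g = build_graph("CC(C)c1ccccc1", "3D", conformer=moved, n_frequencies=cfg.n_frequencies)
        np.testing.assert_allclose(net(GraphBatch.from_graphs([g]), cond).data, base, atol=1e-5)


def test_batched_sum_pool_equals_single(rng):
    cfg = small_config(architecture="GNN", graph_variant="2D", task="yield")
    net = BorylationNet(cfg, condition_width=3, seed=5)
    g1, g2 = build_graph("CCO", "2D"), build_graph("c1ccsc1", "2D")
    cond = np.eye(3)[[0, 1]]
    both = net(GraphBatch.from_graphs([g1, g2]), cond).data.ravel()
    one = net(GraphBatch.from_graphs([g1]), cond[:1]).data.ravel()
    two = net(GraphBatch.from_graphs([g2]), cond[1:]).data.ravel()
    np.testing.assert_allclose(both, np.r_[one, two], atol=1e-10)


# ------------------------------------------------------------- head contracts


def test_binary_head_outputs_are_probabilities(rng):
    cfg = small_config(architecture="GNN", graph_variant="2D", task="binary")
    net = BorylationNet(cfg, condition_width=10, seed=0)
    g = build_graph("Cc1ccccc1", "2D")
    for _ in range(40):
        cond = np.zeros((1, 10))
        cond[0, rng.integers(6)] = 1
        cond[0, 6 + rng.integers(4)] = 1
        out = net(GraphBatch.from_graphs([g]), cond).data
        assert 0.0 <= out[0, 0] <= 1.0


def test_output_sensitive_to_solvent_block():
    cfg = small_config(architecture="GNN", graph_variant="2D", task="yield")
    net = BorylationNet(cfg, condition_width=10, seed=1)
    g = build_graph("Cc1ccccc1", "2D")
    batch = GraphBatch.from_graphs([g])
    a = np.zeros((1, 10)); a[0, 0] = 1; a[0, 6] = 1
    b = a.copy(); b[0, 6] = 0; b[0, 7] = 1  # different solvent
    assert not np.allclose(net(batch, a).data, net(batch, b).data)


def test_agnn_scores_in_unit_interval_and_symmetric_on_benzene():
    cfg = small_config(architecture="aGNN", graph_variant="2D", task="regio")
    net = BorylationNet(cfg, seed=13)
    g = build_graph("c1ccccc1", "2D")
    scores = net(GraphBatch.from_graphs([g])).data.ravel()
    assert np.all(scores >= 0) and np.all(scores <= 1)
    # graph-automorphism oracle: all six aromatic carbons (atoms 0-5) are
    # equivalent, as are the six hydrogens
    np.testing.assert_allclose(scores[:6], scores[0], atol=1e-5)
    np.testing.assert_allclose(scores[6:], scores[6], atol=1e-5)


def test_single_node_gtnn_is_finite():
    cfg = small_config(architecture="GTNN", graph_variant="2D", task="yield")
    net = BorylationNet(cfg, condition_width=2, seed=0)
    g = MolGraph(np.random.default_rng(0).normal(size=(1, 20)), np.zeros((0, 2), int), "2D")
    out = net(GraphBatch.from_graphs([g]), np.array([[1.0, 0.0]]))
    assert np.isfinite(out.data).all()


# ---------------------------------------------------------------- baseline


def test_fingerprint_width_and_discrimination():
    fp = ecfp4("CC")
    assert fp.shape == (256,)
    assert not np.array_equal(ecfp4("CC"), ecfp4("CCO"))
    np.testing.assert_array_equal(ecfp4("CCO"), ecfp4("OCC"))  # same molecule


def test_baseline_identical_inputs_identical_outputs():
    cfg = small_config(architecture="ECFP4NN", task="binary")
    net = ECFP4NN(cfg, ligand_width=6, solvent_width=4, seed=0)
    fp = ecfp4("Cc1ccccc1")[None, :]
    lig, sol = np.eye(6)[[2]], np.eye(4)[[1]]
    np.testing.assert_array_equal(net(fp, lig, sol).data, net(fp, lig, sol).data)
    assert 0 <= net(fp, lig, sol).data[0, 0] <= 1


def test_baseline_rejects_wrong_fingerprint_width():
    cfg = small_config(architecture="ECFP4NN", task="yield")
    net = ECFP4NN(cfg, ligand_width=2, solvent_width=2, seed=0)
    with pytest.raises(ValueError, match="fingerprint"):
        net(np.zeros((1, 128)), np.eye(2)[[0]], np.eye(2)[[0]])


# --------------------------------------------------------- parameter counts


def test_linear_and_mlp_parameter_arithmetic():
    rng = np.random.default_rng(0)
    lin = Linear(3, 5, rng)
    assert sum(p.data.size for p in lin.parameters()) == 3 * 5 + 5
    mlp = MLP([3, 5, 2], rng)
    assert sum(p.data.size for p in mlp.parameters()) == (3 * 5 + 5) + (5 * 2 + 2)


def test_default_gnn_parameter_count_band():
    cfg = ModelConfig(architecture="GNN", graph_variant="3DQM", task="yield")
    net = BorylationNet(cfg, condition_width=10, seed=0)
    assert 1.5e6 <= count_parameters(net) <= 2.5e6  # ~2.0M


def test_default_gtnn_parameter_count_band():
    cfg = ModelConfig(architecture="GTNN", graph_variant="3DQM", task="yield")
    net = BorylationNet(cfg, condition_width=10, seed=0)
    assert 2.25e6 <= count_parameters(net) <= 3.75e6  # ~3.0M


# ------------------------------------------------------------ config guards


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(architecture="aGNN", task="yield")
    with pytest.raises(ValueError):
        ModelConfig(architecture="GNN", task="regio")
    with pytest.raises(ValueError):
        ModelConfig(architecture="GNN", graph_variant="5D")
    assert ModelConfig(architecture="ECFP4NN", task="yield").graph_variant is None


def test_condition_shape_mismatch_raises():
    cfg = small_config(architecture="GNN", graph_variant="2D", task="yield")
    net = BorylationNet(cfg, condition_width=4, seed=0)
    g = build_graph("CC", "2D")
    with pytest.raises(ValueError, match="condition"):
        net(GraphBatch.from_graphs([g]), np.zeros((1, 7)))


# ------------------------------------------------------------ gradient check


def test_autodiff_gradients_match_finite_differences(rng):
    cfg = ModelConfig(architecture="GNN", graph_variant="2D", task="yield",
                      hidden_dim=4, embed_dim=4, post_pool_dim=4, mlp_hidden=4,
                      n_frequencies=2)
    net = BorylationNet(cfg, condition_width=2, seed=0)
    g = MolGraph(rng.normal(size=(3, 20)), np.array([[0, 1], [1, 0], [1, 2], [2, 1]]), "2D")
    batch = GraphBatch.from_graphs([g])
    cond = np.array([[1.0, 0.0]])

    def loss_value():
        return float(net(batch, cond).sum().data)

    loss = net(batch, cond).sum()
    loss.backward()
    eps = 1e-6
    checked = 0
    for p in net.parameters()[::3]:
        flat = p.data.ravel()
        idx = int(rng.integers(flat.size))
        orig = flat[idx]
        flat[idx] = orig + eps
        up = loss_value()
        flat[idx] = orig - eps
        down = loss_value()
        flat[idx] = orig
        numeric = (up - down) / (2 * eps)
        analytic = p.grad.ravel()[idx]
        assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-8)
        checked += 1
    assert checked >= 5
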