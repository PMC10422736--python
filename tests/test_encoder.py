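"""Encoder semantics: message passing, edge updates, readout, gradients."""

import numpy as np
import pytest

from rxnyield._autodiff import Tensor
from rxnyield.encoder import (
    EncoderConfig,
    batch_graphs,
    encode_batch,
    encode_molecule,
    gru_readout,
    init_encoder_params,
    init_states,
    load_params,
    message_passing,
    save_params,
)
from rxnyield.molgraph import ATOM_FDIM, MolGraph, build_graph

from _reference import naive_encode

SMALL_MOLECULES = ["C", "CC", "CCO", "C=O", "CC#N", "CO"]  # all <= 4 atoms


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(hidden_size=0)
    with pytest.raises(ValueError):
        EncoderConfig(depth=0)
    with pytest.raises(ValueError):
        EncoderConfig(aggregation="median")
    with pytest.raises(ValueError):
        EncoderConfig(edge_message="both")


def test_init_states_shapes_and_single_atom(tiny_config, tiny_params):
    batch = batch_graphs([build_graph("C")])
    x, hv, he = init_states(batch, tiny_params)
    assert hv.shape == (1, tiny_config.hidden_size)
    assert he.shape == (0, tiny_config.hidden_size)


def test_hidden_width_matches_config():
    cfg = EncoderConfig(hidden_size=300, depth=1, seed=0)
    params = init_encoder_params(cfg)
    vec = encode_molecule("CCO", params, cfg)
    assert vec.shape == (300,)


def test_initialization_is_seed_deterministic():
    cfg = EncoderConfig(hidden_size=6, depth=2, seed=42)
    p1 = init_encoder_params(cfg)
    p2 = init_encoder_params(cfg)
    for k in p1:
        np.testing.assert_array_equal(p1[k].data, p2[k].data)


def test_encoding_deterministic_and_canonical(tiny_config, tiny_params):
    v1 = encode_molecule("OCC", tiny_params, tiny_config)
    v2 = encode_molecule("CCO", tiny_params, tiny_config)
    np.testing.assert_array_equal(v1, v2)
    v3 = encode_molecule("OCC", tiny_params, tiny_config)
    np.testing.assert_array_equal(v1, v3)


def test_distinct_molecules_get_distinct_vectors(tiny_config, tiny_params):
    v1 = encode_molecule("CCO", tiny_params, tiny_config)
    v2 = encode_molecule("CCN", tiny_params, tiny_config)
    assert not np.allclose(v1, v2)


def test_embeddings_finite_over_fixture_set(drug_smiles, tiny_config, tiny_params):
    batch = batch_graphs([build_graph(s) for s in drug_smiles])
    vecs = encode_batch(batch, tiny_params, tiny_config)
    assert vecs.shape == (len(drug_smiles), tiny_config.hidden_size)
    assert np.isfinite(vecs.data).all()


@pytest.mark.parametrize("aggregation", ["sum", "mean", "max"])
@pytest.mark.parametrize("edge_message", ["reverse", "self"])
def test_encoder_matches_naive_loop_reference(aggregation, edge_message):
    """Vectorized K-step encoder == explicit-loop oracle on tiny graphs."""
    cfg = EncoderConfig(
        hidden_size=4, depth=3, aggregation=aggregation,
        edge_message=edge_message, seed=7,
    )
    params = init_encoder_params(cfg)
    for s in SMALL_MOLECULES:
        g = build_graph(s)
        expected = naive_encode(g, params, cfg)
        got = encode_molecule(s, params, cfg)
        np.testing.assert_allclose(got, expected, atol=1e-6)


def test_batched_equals_single(tiny_config, tiny_params):
    """Packing several molecules into one batch changes nothing."""
    singles = np.stack(
        [encode_molecule(s, tiny_params, tiny_config) for s in SMALL_MOLECULES]
    )
    batch = batch_graphs([build_graph(s) for s in SMALL_MOLECULES])
    together = encode_batch(batch, tiny_params, tiny_config).data
    np.testing.assert_allclose(together, singles, atol=1e-12)


def test_edge_states_nonnegative(tiny_config, tiny_params):
    batch = batch_graphs([build_graph("c1ccccc1C(=O)O")])
    # message_passing output is post-ReLU node embeddings; check >= 0
    out = message_passing(batch, tiny_params, tiny_config)
    assert (out.data >= 0).all()


def test_zero_edge_weight_annihilates_subtraction(tiny_config):
    """W_edge = 0 makes edge states ReLU(h0(e)) = h0(e) at every step, so
    the encoding reduces to a pure function of initial states."""
    params = init_encoder_params(tiny_config)
    params["enc/W_edge"] = Tensor(np.zeros_like(params["enc/W_edge"].data))
    g = build_graph("CCO")
    batch = batch_graphs([g])
    _, _, he0 = init_states(batch, params)
    cfg_self = EncoderConfig(hidden_size=4, depth=3, edge_message="self", seed=11)
    cfg_rev = EncoderConfig(hidden_size=4, depth=3, edge_message="reverse", seed=11)
    # with W=0 the edge-message choice is irrelevant
    v_self = encode_batch(batch, params, cfg_self).data
    v_rev = encode_batch(batch, params, cfg_rev).data
    np.testing.assert_allclose(v_self, v_rev, atol=1e-12)
    assert (he0.data >= 0).all()


def test_hand_worked_two_atom_edge_update():
    """2-atom molecule, d=2, W_edge=I: edge states match hand arithmetic
    ReLU(h0(e) + (h^k(v) - h^{k-1}(e_rev)))."""
    cfg = EncoderConfig(hidden_size=2, depth=1, seed=3)
    params = init_encoder_params(cfg)
    params["enc/W_edge"] = Tensor(np.eye(2))
    g = build_graph("CO")
    batch = batch_graphs([g])
    x, hv0, he0 = init_states(batch, params)

    # hand computation of one step
    W_comm, b_comm = params["enc/W_comm"].data, params["enc/b_comm"].data
    m = np.zeros((2, 2))
    for e, (v, w) in enumerate(g.directed_edges):
        m[w] += he0.data[e]
    hv1 = np.maximum(np.concatenate([hv0.data, m], axis=1) @ W_comm + b_comm, 0)
    he1 = np.zeros_like(he0.data)
    for e, (v, w) in enumerate(g.directed_edges):
        he1[e] = np.maximum(
            he0.data[e] + (hv1[v] - he0.data[g.reverse_index[e]]), 0
        )
    # full forward then readout must equal the naive path (checks the same
    # arithmetic end to end)
    expected = naive_encode(g, params, cfg)
    got = encode_molecule("CO", params, cfg)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert (he1 >= 0).all()


def test_node_stage_permutation_equivariance(tiny_config, tiny_params):
    """Permuting atom numbering permutes node embeddings accordingly, and
    the readout (which follows atom_order) is unchanged."""
    g = build_graph("CC(=O)N")
    rng = np.random.default_rng(0)
    perm = rng.permutation(g.n_atoms)
    inv = np.argsort(perm)
    g_perm = MolGraph(
        n_atoms=g.n_atoms,
        atom_features=g.atom_features[inv],
        directed_edges=np.array([[perm[v], perm[w]] for v, w in g.directed_edges]),
        edge_features=g.edge_features,
        reverse_index=g.reverse_index,
        atom_order=perm[g.atom_order],
        smiles=g.smiles,
    )
    out = message_passing(batch_graphs([g]), tiny_params, tiny_config).data
    out_perm = message_passing(batch_graphs([g_perm]), tiny_params, tiny_config).data
    np.testing.assert_allclose(out_perm[perm], out, atol=1e-12)
    v = gru_readout(
        Tensor(out), batch_graphs([g]), tiny_params
    ).data
    v_perm = gru_readout(
        Tensor(out_perm), batch_graphs([g_perm]), tiny_params
    ).data
    np.testing.assert_allclose(v_perm, v, atol=1e-12)


def test_single_node_readout_equals_one_gru_step(tiny_config, tiny_params):
    """Readout of one node == a single GRU step from the zero state."""
    g = build_graph("C")
    batch = batch_graphs([g])
    node = message_passing(batch, tiny_params, tiny_config)
    got = gru_readout(node, batch, tiny_params).data[0]

    P = {k: v.data for k, v in tiny_params.items()}
    x = node.data[0]
    h = np.zeros(tiny_config.hidden_size)
    z = 1 / (1 + np.exp(-(x @ P["enc/gru_Wz"] + h @ P["enc/gru_Uz"] + P["enc/gru_bz"])))
    r = 1 / (1 + np.exp(-(x @ P["enc/gru_Wr"] + h @ P["enc/gru_Ur"] + P["enc/gru_br"])))
    hc = np.tanh(x @ P["enc/gru_Wh"] + (r * h) @ P["enc/gru_Uh"] + P["enc/gru_bh"])
    expected = (1 - z) * h + z * hc
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_analytic_gradient_matches_finite_differences(tiny_config, tiny_params):
    """d(loss)/d(W_edge) by backprop vs central differences, toy graph."""
    g = build_graph("CCO")

    def loss_value() -> float:
        batch = batch_graphs([g])
        out = encode_batch(batch, tiny_params, tiny_config)
        return float((out * out).sum().data)

    batch = batch_graphs([g])
    out = encode_batch(batch, tiny_params, tiny_config)
    loss = (out * out).sum()
    loss.backward()
    analytic = tiny_params["enc/W_edge"].grad.copy()

    W = tiny_params["enc/W_edge"].data
    eps = 1e-6
    numeric = np.zeros_like(W)
    it = np.nditer(W, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = W[i]
        W[i] = orig + eps
        fp = loss_value()
        W[i] = orig - eps
        fm = loss_value()
        W[i] = orig
        numeric[i] = (fp - fm) / (2 * eps)
        it.iternext()
    denom = np.maximum(np.abs(numeric), 1e-8)
    assert np.max(np.abs(analytic - numeric) / denom) < 1e-4


def test_checkpoint_roundtrip(tmp_path, tiny_config, tiny_params):
    path = tmp_path / "ckpt.npz"
    save_params(path, tiny_params, {"note": "test"})
    loaded, meta = load_params(path)
    assert meta["format_version"] == 1
    for k in tiny_params:
        np.testing.assert_array_equal(loaded[k].data, tiny_params[k].data)
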