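"""Communicative message-passing encoder producing one vector per molecule.

The encoder operates on the directed molecular graph G(V, E). Each of K
iterations performs:

(i)   node message: m^k(v) = agg over incoming edges of h^{k-1}(e_{u,v});
      node update (communicative function): h^k(v) = ReLU(W_comm [h^{k-1}(v);
      m^k(v)] + b)
(ii)  edge message: m^k(e_{v,w}) = h^k(v) - h^{k-1}(e'), where e' is the
      reverse edge e_{w,v} by default (``edge_message="reverse"``, preventing
      a directed edge from echoing its own state back) or the edge itself
      (``edge_message="self"``);
      edge update: h^k(e_{v,w}) = ReLU(h^0(e_{v,w}) + W_edge m^k(e_{v,w}))
(iii) after K steps, a final communicative layer fuses the aggregated
      message m(v), the node state h^K(v) and the raw atom features x(v)
      into the node embedding h(v).

A gated recurrent unit run over the nodes in canonical atom order collapses
the node embeddings into a single molecule vector (the GRU's terminal hidden
state); its width d (default 300) is the molecule feature length.

All parameters live in a flat ``dict[str, Tensor]`` so the same autodiff
machinery trains the encoder and the regression head jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (
    Tensor,
    concat,
    gather_rows,
    matmul,
    relu,
    segment_max,
    segment_sum,
    sigmoid,
    tanh,
)
from .molgraph import ATOM_FDIM, BOND_FDIM, MolGraph, build_graph

AGGREGATIONS = ("sum", "mean", "max")
EDGE_MESSAGE_MODES = ("reverse", "self")


@dataclass
class EncoderConfig:
    """Hyperparameters of the molecule encoder.

    hidden_size is the molecule feature vector length d (default 300);
    depth is the number K of message-passing iterations; aggregation picks
    the node-message operator over incoming edge states; edge_message picks
    which previous edge state is subtracted when forming the edge message.
    """

    hidden_size: int = 300
    depth: int = 3
    aggregation: str = "sum"
    edge_message: str = "reverse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.edge_message not in EDGE_MESSAGE_MODES:
            raise ValueError(f"edge_message must be one of {EDGE_MESSAGE_MODES}")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_encoder_params(
    config: EncoderConfig, rng: np.random.Generator | None = None
) -> dict[str, Tensor]:
    """Seeded Xavier-uniform initialization of all encoder parameters."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = config.hidden_size
    params: dict[str, np.ndarray] = {
        "enc/W_in_node": _xavier(rng, ATOM_FDIM, d),
        "enc/b_in_node": np.zeros(d),
        "enc/W_in_edge": _xavier(rng, ATOM_FDIM + BOND_FDIM, d),
        "enc/b_in_edge": np.zeros(d),
        "enc/W_comm": _xavier(rng, 2 * d, d),
        "enc/b_comm": np.zeros(d),
        "enc/W_edge": _xavier(rng, d, d),
        "enc/W_out": _xavier(rng, 2 * d + ATOM_FDIM, d),
        "enc/b_out": np.zeros(d),
    }
    for gate in ("z", "r", "h"):
        params[f"enc/gru_W{gate}"] = _xavier(rng, d, d)
        params[f"enc/gru_U{gate}"] = _xavier(rng, d, d)
        params[f"enc/gru_b{gate}"] = np.zeros(d)
    return {k: Tensor(v) for k, v in params.items()}


@dataclass
class BatchedGraph:
    """Several molecular graphs packed into one edge/node index space."""

    graphs: list[MolGraph]
    atom_features: np.ndarray  # (N, ATOM_FDIM)
    edge_src: np.ndarray  # (E,) global source-atom index per directed edge
    edge_dst: np.ndarray  # (E,)
    edge_features: np.ndarray  # (E, BOND_FDIM)
    reverse_index: np.ndarray  # (E,)
    readout_index: np.ndarray  # (n_mols, max_atoms) global node ids, canonical order
    readout_mask: np.ndarray  # (n_mols, max_atoms) 1.0 where a real atom
    node_degree: np.ndarray = field(default=None)  # (N,) incoming-edge counts

    @property
    def n_atoms(self) -> int:
        return len(self.atom_features)

    @property
    def n_mols(self) -> int:
        return len(self.graphs)


def batch_graphs(graphs: list[MolGraph]) -> BatchedGraph:
    if not graphs:
        raise ValueError("cannot batch an empty list of graphs")
    atom_offset = 0
    edge_offset = 0
    feats, srcs, dsts, efeats, revs = [], [], [], [], []
    max_atoms = max(g.n_atoms for g in graphs)
    readout_index = np.zeros((len(graphs), max_atoms), dtype=np.intp)
    readout_mask = np.zeros((len(graphs), max_atoms))
    for i, g in enumerate(graphs):
        feats.append(g.atom_features)
        if g.n_edges:
            srcs.append(g.directed_edges[:, 0] + atom_offset)
            dsts.append(g.directed_edges[:, 1] + atom_offset)
            efeats.append(g.edge_features)
            revs.append(g.reverse_index + edge_offset)
        readout_index[i, : g.n_atoms] = g.atom_order + atom_offset
        readout_mask[i, : g.n_atoms] = 1.0
        atom_offset += g.n_atoms
        edge_offset += g.n_edges
    n_atoms = atom_offset
    batch = BatchedGraph(
        graphs=graphs,
        atom_features=np.concatenate(feats),
        edge_src=(np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp)),
        edge_dst=(np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp)),
        edge_features=(
            np.concatenate(efeats) if efeats else np.zeros((0, BOND_FDIM))
        ),
        reverse_index=(np.concatenate(revs) if revs else np.zeros(0, dtype=np.intp)),
        readout_index=readout_index,
        readout_mask=readout_mask,
    )
    degree = np.zeros(n_atoms)
    np.add.at(degree, batch.edge_dst, 1.0)
    batch.node_degree = degree
    return batch


def _linear(x: Tensor, params: dict[str, Tensor], name: str) -> Tensor:
    out = matmul(x, params[f"enc/W_{name}"])
    bias = params.get(f"enc/b_{name}")
    return out + bias if bias is not None else out


def _aggregate(
    edge_hidden: Tensor, batch: BatchedGraph, mode: str
) -> Tensor:
    """Node message m(v): aggregate incoming-edge hidden states per node."""
    n = batch.n_atoms
    if mode == "max":
        return segment_max(edge_hidden, batch.edge_dst, n)
    msg = segment_sum(edge_hidden, batch.edge_dst, n)
    if mode == "mean":
        inv = np.where(batch.node_degree > 0, 1.0 / np.maximum(batch.node_degree, 1), 0.0)
        msg = msg * Tensor(inv[:, None])
    return msg


def init_states(
    batch: BatchedGraph, params: dict[str, Tensor]
) -> tuple[Tensor, Tensor, Tensor]:
    """Initial node/edge hidden states h^0(v), h^0(e) from raw features."""
    x_v = Tensor(batch.atom_features)
    node_hidden = relu(_linear(x_v, params, "in_node"))
    if len(batch.edge_src):
        edge_in = Tensor(
            np.concatenate(
                [batch.atom_features[batch.edge_src], batch.edge_features], axis=1
            )
        )
        edge_hidden = relu(_linear(edge_in, params, "in_edge"))
    else:
        d = params["enc/W_in_edge"].shape[1]
        edge_hidden = Tensor(np.zeros((0, d)))
    return x_v, node_hidden, edge_hidden


def message_passing(
    batch: BatchedGraph, params: dict[str, Tensor], config: EncoderConfig
) -> Tensor:
    """Run K iterations and the final fusion; returns node embeddings h(v)."""
    x_v, node_hidden, edge_hidden = init_states(batch, params)
    edge_hidden_0 = edge_hidden
    for _ in range(config.depth):
        message = _aggregate(edge_hidden, batch, config.aggregation)
        node_hidden = relu(
            _linear(concat([node_hidden, message], axis=1), params, "comm")
        )
        if len(batch.edge_src):
            subtract_idx = (
                batch.reverse_index
                if config.edge_message == "reverse"
                else np.arange(len(batch.edge_src))
            )
            edge_message = gather_rows(node_hidden, batch.edge_src) - gather_rows(
                edge_hidden, subtract_idx
            )
            edge_hidden = relu(
                edge_hidden_0 + matmul(edge_message, params["enc/W_edge"])
            )
    final_message = _aggregate(edge_hidden, batch, config.aggregation)
    return relu(
        _linear(concat([final_message, node_hidden, x_v], axis=1), params, "out")
    )


def gru_readout(
    node_embeddings: Tensor, batch: BatchedGraph, params: dict[str, Tensor]
) -> Tensor:
    """Collapse node embeddings into one vector per molecule.

    A GRU consumes each molecule's nodes in canonical atom order, starting
    from a zero state; the terminal hidden state is the molecule vector.
    Shorter molecules in the batch freeze their state once exhausted.
    """
    n_mols, max_atoms = batch.readout_index.shape
    d = params["enc/gru_Wz"].shape[0]
    h = Tensor(np.zeros((n_mols, d)))
    for t in range(max_atoms):
        x_t = gather_rows(node_embeddings, batch.readout_index[:, t])
        z = sigmoid(
            matmul(x_t, params["enc/gru_Wz"])
            + matmul(h, params["enc/gru_Uz"])
            + params["enc/gru_bz"]
        )
        r = sigmoid(
            matmul(x_t, params["enc/gru_Wr"])
            + matmul(h, params["enc/gru_Ur"])
            + params["enc/gru_br"]
        )
        h_cand = tanh(
            matmul(x_t, params["enc/gru_Wh"])
            + matmul(r * h, params["enc/gru_Uh"])
            + params["enc/gru_bh"]
        )
        h_new = (Tensor(1.0) - z) * h + z * h_cand
        mask = Tensor(batch.readout_mask[:, t : t + 1])
        h = mask * h_new + (Tensor(1.0) - mask) * h
    return h


def encode_batch(
    batch: BatchedGraph, params: dict[str, Tensor], config: EncoderConfig
) -> Tensor:
    """Molecule vectors, shape (n_mols, hidden_size)."""
    node_embeddings = message_passing(batch, params, config)
    return gru_readout(node_embeddings, batch, params)


def encode_molecule(
    smiles: str, params: dict[str, Tensor], config: EncoderConfig
) -> np.ndarray:
    """Encode a single SMILES into its learned d-vector (no gradients kept)."""
    batch = batch_graphs([build_graph(smiles)])
    return encode_batch(batch, params, config).data[0]


def save_params(path, params: dict[str, Tensor], meta: dict | None = None) -> None:
    """Serialize parameters to a single .npz checkpoint with a version tag."""
    import json

    arrays = {k: v.data for k, v in params.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps({"format_version": 1, **(meta or {})}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_params(path) -> tuple[dict[str, Tensor], dict]:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        params = {
            k: Tensor(data[k]) for k in data.files if k != "__meta__"
        }
    return params, meta
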