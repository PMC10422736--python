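"""Naive reference implementation of the molecule encoder.

Written as explicit Python loops over the directed edge list — no batching,
no autodiff — to serve as an independent oracle for the vectorized encoder.
Keep it dumb and readable; it must never share code with the implementation
it checks.
"""

import numpy as np


def _relu(a):
    return np.maximum(a, 0.0)


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


def naive_encode(graph, params, config):
    """Molecule vector for one MolGraph, by explicit iteration."""
    P = {k: t.data for k, t in params.items()}
    d = config.hidden_size
    n = graph.n_atoms
    edges = [tuple(e) for e in graph.directed_edges]
    E = len(edges)
    x = graph.atom_features

    hv = np.zeros((n, d))
    for v in range(n):
        hv[v] = _relu(x[v] @ P["enc/W_in_node"] + P["enc/b_in_node"])
    he0 = np.zeros((E, d))
    for e, (v, w) in enumerate(edges):
        he0[e] = _relu(
            np.concatenate([x[v], graph.edge_features[e]]) @ P["enc/W_in_edge"]
            + P["enc/b_in_edge"]
        )
    he = he0.copy()

    def node_messages(edge_states):
        m = np.zeros((n, d))
        if config.aggregation == "max":
            got = [False] * n
            for e, (v, w) in enumerate(edges):
                if not got[w]:
                    m[w] = edge_states[e]
                    got[w] = True
                else:
                    m[w] = np.maximum(m[w], edge_states[e])
        else:
            count = np.zeros(n)
            for e, (v, w) in enumerate(edges):
                m[w] += edge_states[e]
                count[w] += 1
            if config.aggregation == "mean":
                for v in range(n):
                    if count[v] > 0:
                        m[v] = m[v] / count[v]
        return m

    for _ in range(config.depth):
        m = node_messages(he)
        hv_new = np.zeros_like(hv)
        for v in range(n):
            hv_new[v] = _relu(
                np.concatenate([hv[v], m[v]]) @ P["enc/W_comm"] + P["enc/b_comm"]
            )
        hv = hv_new
        he_prev = he.copy()
        for e, (v, w) in enumerate(edges):
            other = (
                graph.reverse_index[e] if config.edge_message == "reverse" else e
            )
            msg = hv[v] - he_prev[other]
            he[e] = _relu(he0[e] + msg @ P["enc/W_edge"])

    m = node_messages(he)
    hout = np.zeros((n, d))
    for v in range(n):
        hout[v] = _relu(
            np.concatenate([m[v], hv[v], x[v]]) @ P["enc/W_out"] + P["enc/b_out"]
        )

    h = np.zeros(d)
    for v in graph.atom_order:
        xv = hout[v]
        z = _sigmoid(xv @ P["enc/gru_Wz"] + h @ P["enc/gru_Uz"] + P["enc/gru_bz"])
        r = _sigmoid(xv @ P["enc/gru_Wr"] + h @ P["enc/gru_Ur"] + P["enc/gru_br"])
        hc = np.tanh(
            xv @ P["enc/gru_Wh"] + (r * h) @ P["enc/gru_Uh"] + P["enc/gru_bh"]
        )
        h = (1 - z) * h + z * hc
    return h
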