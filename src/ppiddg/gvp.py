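"""Geometric vector perceptrons and the multi-relational GEE layer.

A geometric vector perceptron (GVP) maps a (scalar, vector) feature tuple to
another such tuple: vector channels are linearly mixed, their norms join the
scalar channels, scalars pass through a dense nonlinearity, and output
vectors are gated by a sigmoid of the output scalars. Scalar outputs are
therefore invariant and vector outputs covariant under any rotation of the
input vectors.

The GEE layer runs one GVP-based message function per relation (KNN graph
and radius graph), mean-aggregates incoming messages per relation,
concatenates the two half-width aggregates back to node width, and applies
two residual + layer-normalization stages (the second around a pointwise
feed-forward GVP). Layer normalization on vector channels rescales by the
RMS of the channel norms only, preserving directions and equivariance.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from ._autodiff import (Parameter, Tensor, concat, segment_mean, split_matmul,
                        split_vecmix)


class SV(NamedTuple):
    """A scalar/vector feature tuple; s: (N, ns), v: (N, nv, 3)."""
    s: Tensor
    v: Tensor


def _ensure_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Parameter(rng.uniform(-limit, limit, size=shape))


class Module:
    """Tiny parameter container with recursive collection."""

    def parameters(self):
        out = []
        for name in sorted(vars(self)):
            val = getattr(self, name)
            if isinstance(val, Parameter):
                out.append(val)
            elif isinstance(val, Module):
                out.extend(val.parameters())
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self, prefix=""):
        out = {}
        for name in sorted(vars(self)):
            val = getattr(self, name)
            if isinstance(val, Parameter):
                out[prefix + name] = val.data
            elif isinstance(val, Module):
                out.update(val.state_arrays(prefix + name + "."))
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{prefix}{name}.{k}."))
        return out

    def load_state_arrays(self, arrays, prefix=""):
        for name in sorted(vars(self)):
            val = getattr(self, name)
            if isinstance(val, Parameter):
                key = prefix + name
                if arrays[key].shape != val.data.shape:
                    raise ValueError(f"shape mismatch for {key}")
                val.data = np.array(arrays[key], dtype=np.float64)
            elif isinstance(val, Module):
                val.load_state_arrays(arrays, prefix + name + ".")
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, f"{prefix}{name}.{k}.")


class Linear(Module):
    def __init__(self, rng, n_in, n_out, bias=True):
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class GVP(Module):
    """Geometric vector perceptron with vector gating.

    in_dims/out_dims are (n_scalar, n_vector) pairs; h_dim is the width of
    the intermediate vector mixing (default max(nv_in, nv_out)). With
    ``activations=False`` the module is purely linear (used for input
    lifting and final prediction heads).

    Inputs may arrive as an SV whose fields are *lists* of tensors; they are
    treated as an implicit concatenation (along scalar channels / vector
    channels) without materializing it, which keeps edge-level message
    computation cheap.
    """

    def __init__(self, rng, in_dims, out_dims, h_dim=None, activations=True,
                 vector_gate=True):
        self.si, self.vi = in_dims
        self.so, self.vo = out_dims
        self.h = h_dim or max(self.vi, self.vo)
        self.activations = activations
        self.vector_gate = vector_gate and self.vo > 0
        s_in_width = self.si + (self.h if self.vi > 0 else 0)
        if self.vi > 0:
            self.Wh = _glorot(rng, self.vi, self.h, (self.h, self.vi))
        self.Ws = _glorot(rng, s_in_width, self.so, (s_in_width, self.so))
        self.bs = Parameter(np.zeros(self.so))
        if self.vo > 0:
            if self.vi == 0:
                raise ValueError("cannot produce vector outputs from no vectors")
            self.Wv = _glorot(rng, self.h, self.vo, (self.vo, self.h))
            if self.vector_gate:
                self.Wg = _glorot(rng, self.so, self.vo, (self.so, self.vo))
                self.bg = Parameter(np.zeros(self.vo))

    def __call__(self, x: SV) -> SV:
        s_parts = list(x.s) if isinstance(x.s, (list, tuple)) else [x.s]
        v_parts = list(x.v) if isinstance(x.v, (list, tuple)) else [x.v]
        if self.vi > 0:
            vh = split_vecmix(v_parts, self.Wh)    # (N, h, 3)
            s_out = split_matmul(s_parts + [vh.norm(axis=-1)], self.Ws, self.bs)
        else:
            s_out = split_matmul(s_parts, self.Ws, self.bs)
        if self.activations:
            s_out = s_out.relu()
        if self.vo > 0:
            v_out = vh.vecmix(self.Wv)             # (N, vo, 3)
            if self.vector_gate:
                gate = split_matmul([s_out], self.Wg, self.bg).sigmoid()
                v_out = v_out * gate.reshape(*gate.shape, 1)
            elif self.activations:
                v_out = v_out * v_out.norm(axis=-1, keepdims=True).sigmoid()
        else:
            v_out = Tensor(np.zeros((s_out.shape[0], 0, 3)))
        return SV(s_out, v_out)


class LayerNormSV(Module):
    """Scalar channels: standard affine-free layer norm. Vector channels:
    rescale all channels of a node by the RMS of their norms (directions and
    relative magnitudes preserved, so equivariance holds)."""

    def __init__(self, eps=1e-5):
        self.eps = eps

    def __call__(self, x: SV) -> SV:
        s, v = x
        mu = s.mean(axis=-1, keepdims=True)
        centered = s - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        s_out = centered / (var + self.eps).sqrt()
        if v.shape[1] > 0:
            sq = (v * v).sum(axis=-1)                       # (N, nv)
            rms = (sq.mean(axis=1, keepdims=True) + self.eps).sqrt()
            v_out = v / rms.reshape(rms.shape[0], 1, 1)
        else:
            v_out = v
        return SV(s_out, v_out)


def _dropout_sv(x: SV, rate: float, rng: np.random.Generator,
                training: bool) -> SV:
    """Scalar unit dropout; vector dropout removes whole channels so that
    the surviving geometry still rotates correctly."""
    if not training or rate <= 0:
        return x
    s, v = x
    keep = 1.0 - rate
    ms = (rng.random(s.shape) < keep) / keep
    s_out = s * Tensor(ms)
    if v.shape[1] > 0:
        mv = (rng.random((v.shape[0], v.shape[1], 1)) < keep) / keep
        v_out = v * Tensor(mv)
    else:
        v_out = v
    return SV(s_out, v_out)


def _cat_sv(a: SV, b: SV) -> SV:
    return SV(concat([a.s, b.s], axis=-1), concat([a.v, b.v], axis=1))


class GEELayer(Module):
    """One multi-relational message-passing layer over the KNN/radius pair.

    Each relation r computes messages GVP(concat(f_j, f_(i,j)^r)) at half the
    node width, aggregates them by arithmetic mean over incoming edges
    (empty neighbourhoods aggregate to zero), and the concatenation of the
    two relation aggregates re-enters at node width through the residual.
    """

    def __init__(self, rng, node_dims=(256, 16), edge_dims=(32, 1),
                 drop_rate=0.1):
        ns, nv = node_dims
        es, ev = edge_dims
        msg_dims = (ns // 2, nv // 2)
        self.msg_knn = GVP(rng, (ns + es, nv + ev), msg_dims)
        self.msg_radius = GVP(rng, (ns + es, nv + ev), msg_dims)
        self.ff = GVP(rng, node_dims, node_dims)
        self.norm1 = LayerNormSV()
        self.norm2 = LayerNormSV()
        self.drop_rate = drop_rate

    def _relation(self, gvp, nodes: SV, edges, e_s, e_v, n_nodes) -> SV:
        if len(edges) == 0:
            ns = gvp.so
            nv = gvp.vo
            return SV(Tensor(np.zeros((n_nodes, ns))),
                      Tensor(np.zeros((n_nodes, nv, 3))))
        dst, src = edges[:, 0], edges[:, 1]
        msg = gvp(SV([nodes.s[src], _ensure_tensor(e_s)],
                     [nodes.v[src], _ensure_tensor(e_v)]))
        return SV(segment_mean(msg.s, dst, n_nodes),
                  segment_mean(msg.v, dst, n_nodes))

    def __call__(self, nodes: SV, pair, rng=None, training=False) -> SV:
        N = pair.n_nodes
        agg_k = self._relation(self.msg_knn, nodes, pair.knn_edges,
                               pair.knn_edge_scalar, pair.knn_edge_vector, N)
        agg_r = self._relation(self.msg_radius, nodes, pair.radius_edges,
                               pair.radius_edge_scalar, pair.radius_edge_vector, N)
        update = _dropout_sv(_cat_sv(agg_k, agg_r), self.drop_rate, rng, training)
        nodes = self.norm1(SV(nodes.s + update.s, nodes.v + update.v))
        ff = _dropout_sv(self.ff(nodes), self.drop_rate, rng, training)
        return self.norm2(SV(nodes.s + ff.s, nodes.v + ff.v))


class GEEEncoderCore(Module):
    """Input lifting plus a stack of GEE layers.

    Node features (29, 9) are lifted to (256, 16) by a linear GVP; each
    relation's edge features (32, 1) by their own linear GVP. Five layers by
    default.
    """

    def __init__(self, seed=1234, n_layers=5, node_dims=(256, 16),
                 edge_dims=(32, 1), in_node_dims=(29, 9), in_edge_dims=(32, 1),
                 drop_rate=0.1):
        rng = np.random.default_rng(seed)
        self.node_dims = node_dims
        self.edge_dims = edge_dims
        self.lift_nodes = GVP(rng, in_node_dims, node_dims, activations=False,
                              vector_gate=False)
        self.lift_edges_knn = GVP(rng, in_edge_dims, edge_dims,
                                  activations=False, vector_gate=False)
        self.lift_edges_radius = GVP(rng, in_edge_dims, edge_dims,
                                     activations=False, vector_gate=False)
        self.layers = [GEELayer(rng, node_dims, edge_dims, drop_rate)
                       for _ in range(n_layers)]

    def __call__(self, pair, rng=None, training=False) -> SV:
        nodes = self.lift_nodes(SV(Tensor(pair.node_scalar),
                                   Tensor(pair.node_vector)))
        ek = self.lift_edges_knn(SV(Tensor(pair.knn_edge_scalar),
                                    Tensor(pair.knn_edge_vector)))
        er = self.lift_edges_radius(SV(Tensor(pair.radius_edge_scalar),
                                       Tensor(pair.radius_edge_vector)))
        lifted = _LiftedPair(pair, ek, er)
        for layer in self.layers:
            nodes = layer(nodes, lifted, rng=rng, training=training)
        return nodes


class _LiftedPair:
    """Adapter exposing lifted edge features with the ContactGraphPair API."""

    def __init__(self, pair, ek: SV, er: SV):
        self.n_nodes = pair.n_nodes
        self.knn_edges = pair.knn_edges
        self.radius_edges = pair.radius_edges
        self.knn_edge_scalar = ek.s
        self.knn_edge_vector = ek.v
        self.radius_edge_scalar = er.s
        self.radius_edge_vector = er.v


class MLP(Module):
    """Plain scalar MLP (used by the invariant prediction heads)."""

    def __init__(self, rng, dims):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for k, layer in enumerate(self.layers):
            x = layer(x)
            if k < len(self.layers) - 1:
                x = x.relu()
        return x
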