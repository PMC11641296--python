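"""Graph-transformer affinity regressor.

Per-head attention logits are ``QK^T/sqrt(d_h)`` plus two structural bias
terms: a learned scalar per shortest-path-hop bucket (spatial encoding) and a
learned projection of the expected edge features along shortest paths (edge
encoding).  Node inputs are the 58-dim features plus a degree (centrality)
embedding.  Two graphs of the same complex (e.g. the two water-source
variants) pass through the encoder — weight-shared by default — and their
virtual-node embeddings are concatenated, softmax-weight pooled and mapped to
one scalar (pKd).

Notes on two deliberate readings of the source formulation:

* "softmax for regression" is implemented as softmax-weighted channel pooling
  over the concatenated graph embedding followed by a linear head — the only
  reading that yields a continuous scalar;
* the edge-path bias averages edge terms along the path (per-path average);
  dividing by the global edge count instead is available via
  ``edge_bias_mode="global_n"``.

The edge bias averages over *all* shortest paths between a pair (not one
arbitrarily tie-broken path) so the model output is exactly invariant to node
reordering.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from hydrobind.autodiff import Adam, Parameter, Tensor, concat, gather
from hydrobind.graph import ComplexGraph

__all__ = [
    "ModelConfig",
    "EncodedGraph",
    "AffinityModel",
    "centrality_encode",
    "spatial_encode",
    "encode_graph",
]

NEG_INF = -1.0e9


@dataclass
class ModelConfig:
    layers: int = 4
    heads: int = 12
    hidden_dim: int = 96  # must divide by heads; 96 = 12 * 8
    max_spd_bucket: int = 20
    max_path_len: int = 5
    degree_cap: int = 32
    ffn_mult: int = 2
    dropout: float = 0.0
    seed: int = 0
    shared_weights: bool = True
    edge_bias_mode: str = "path_average"  # or "global_n"

    def __post_init__(self) -> None:
        if self.hidden_dim % self.heads != 0:
            raise ValueError("hidden_dim must be divisible by heads")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.edge_bias_mode not in ("path_average", "global_n"):
            raise ValueError(f"unknown edge_bias_mode {self.edge_bias_mode!r}")


# ---------------------------------------------------------------------------
# Structural encodings (pure numpy, computed once per graph)
# ---------------------------------------------------------------------------

def centrality_encode(g: ComplexGraph, cap: int = 32) -> np.ndarray:
    """Clamped node degrees used to index the centrality embedding table.

    The graphs are undirected, so in-degree and out-degree coincide with the
    plain degree.
    """
    return np.minimum(g.degrees(), cap)


def _bfs(adj: list[list[int]], source: int) -> tuple[np.ndarray, np.ndarray]:
    """Hop distances and shortest-path counts from ``source`` (-1/0 if unreachable)."""
    n = len(adj)
    dist = np.full(n, -1, dtype=int)
    sigma = np.zeros(n)
    dist[source] = 0
    sigma[source] = 1.0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if dist[v] == -1:
                dist[v] = dist[u] + 1
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def _adjacency_lists(g: ComplexGraph) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(g.n_nodes)]
    for i, j, _ in g.edges:
        adj[i].append(j)
        adj[j].append(i)
    return adj


def spatial_encode(g: ComplexGraph) -> np.ndarray:
    """All-pairs unweighted shortest-path hop matrix; -1 marks unreachable."""
    adj = _adjacency_lists(g)
    return np.stack([_bfs(adj, s)[0] for s in range(g.n_nodes)])


def _path_feature_tensor(
    g: ComplexGraph, spd: np.ndarray, sigma: np.ndarray, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Expected edge feature at each path position, averaged over all
    shortest paths of a pair.

    Returns ``P`` of shape (n, n, max_len, 7) and ``inv_len`` (n, n) holding
    1/hops for pairs with 1 <= hops <= max_len (0 elsewhere).
    """
    n = g.n_nodes
    feat_dim = 7
    P = np.zeros((n, n, max_len, feat_dim))
    inv_len = np.zeros((n, n))
    if not g.edges:
        return P, inv_len
    u = np.array([e[0] for e in g.edges] + [e[1] for e in g.edges])
    v = np.array([e[1] for e in g.edges] + [e[0] for e in g.edges])
    feats = np.array([e[2].vector() for e in g.edges])
    feats = np.vstack([feats, feats])  # both orientations

    reach = spd >= 0
    hops = spd.astype(float)
    for i in range(n):
        d_iu = spd[i, u]  # (E,)
        pos_ok = (d_iu >= 0) & (d_iu < max_len)
        if not pos_ok.any():
            continue
        # edge (u->v) lies on a shortest i->j path iff d(i,u) + 1 + d(v,j) = d(i,j)
        lhs = d_iu[:, None] + 1 + spd[v, :]  # (E, n)
        on_path = (
            pos_ok[:, None]
            & (spd[v, :] >= 0)
            & reach[i][None, :]
            & (lhs == spd[i][None, :])
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            w = sigma[i, u][:, None] * sigma[v, :] / sigma[i][None, :]
        w = np.where(on_path, w, 0.0)
        for ell in range(max_len):
            sel = d_iu == ell
            if not sel.any():
                continue
            P[i, :, ell, :] = w[sel].T @ feats[sel]
    valid = reach & (hops >= 1) & (hops <= max_len)
    inv_len[valid] = 1.0 / hops[valid]
    return P, inv_len


@dataclass
class EncodedGraph:
    """Model-ready numpy encodings of one graph (no learned content)."""

    features: np.ndarray      # (n, 58)
    degree_idx: np.ndarray    # (n,) clamped degrees
    spd: np.ndarray           # (n, n) hops, -1 unreachable
    path_feats: np.ndarray    # (n, n, max_len, 7)
    inv_len: np.ndarray       # (n, n)
    n_edges: int
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = self.features.shape[0]


def encode_graph(g: ComplexGraph, config: ModelConfig) -> EncodedGraph:
    if g.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    adj = _adjacency_lists(g)
    pairs = [_bfs(adj, s) for s in range(g.n_nodes)]
    spd = np.stack([p[0] for p in pairs])
    sigma = np.stack([p[1] for p in pairs])
    P, inv_len = _path_feature_tensor(g, spd, sigma, config.max_path_len)
    return EncodedGraph(
        features=g.node_features.astype(float),
        degree_idx=centrality_encode(g, config.degree_cap),
        spd=spd,
        path_feats=P,
        inv_len=inv_len,
        n_edges=len(g.edges),
    )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class AffinityModel:
    """Dual-branch graph transformer with a scalar regression head."""

    EDGE_FEAT_DIM = 7

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self._rng = np.random.default_rng(self.config.seed)
        self.params: dict[str, Parameter] = {}
        self._build()
        self.last_attention: list[np.ndarray] = []

    # -- parameter plumbing ------------------------------------------------
    def _param(self, name: str, shape: tuple[int, ...], scale: float = 0.02,
               zero: bool = False) -> Parameter:
        data = (np.zeros(shape) if zero
                else self._rng.normal(0.0, scale, size=shape))
        p = Parameter(data)
        self.params[name] = p
        return p

    def _build(self) -> None:
        cfg = self.config
        d = cfg.hidden_dim
        n_buckets = cfg.max_spd_bucket + 3  # hops + unreachable + virtual
        self._param("W_in", (58, d))
        self._param("b_in", (d,), zero=True)
        self._param("deg_emb", (cfg.degree_cap + 2, d))
        branches = 1 if cfg.shared_weights else 2
        for b in range(branches):
            self._param(f"spd_bias{b}", (n_buckets, cfg.heads), zero=True)
            self._param(f"edge_w{b}",
                        (cfg.max_path_len * self.EDGE_FEAT_DIM, cfg.heads),
                        scale=0.02)
            self._param(f"virtual{b}", (d,))
            for layer in range(cfg.layers):
                pre = f"b{b}l{layer}_"
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    self._param(pre + w, (d, d))
                self._param(pre + "g1", (d,), zero=True)
                self.params[pre + "g1"].data += 1.0
                self._param(pre + "be1", (d,), zero=True)
                self._param(pre + "g2", (d,), zero=True)
                self.params[pre + "g2"].data += 1.0
                self._param(pre + "be2", (d,), zero=True)
                self._param(pre + "F1", (d, cfg.ffn_mult * d))
                self._param(pre + "f1", (cfg.ffn_mult * d,), zero=True)
                self._param(pre + "F2", (cfg.ffn_mult * d, d))
                self._param(pre + "f2", (d,), zero=True)
        self._param("W_pool", (2 * d, 2 * d))
        self._param("b_pool", (2 * d,), zero=True)
        self._param("w_out", (2 * d, 1))
        self._param("b_out", (1,), zero=True)

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    # -- batching ----------------------------------------------------------
    def _pad_batch(self, graphs: list[EncodedGraph]) -> dict[str, np.ndarray]:
        cfg = self.config
        B = len(graphs)
        n1 = max(eg.n for eg in graphs) + 1  # slot 0 = virtual node
        L, F = cfg.max_path_len, self.EDGE_FEAT_DIM
        unreachable = cfg.max_spd_bucket + 1
        virtual_bucket = cfg.max_spd_bucket + 2

        X = np.zeros((B, n1, 58))
        deg = np.full((B, n1), cfg.degree_cap + 1, dtype=int)
        spd_idx = np.full((B, n1, n1), unreachable, dtype=int)
        key_mask = np.full((B, n1), NEG_INF)
        vmask = np.zeros((B, n1))
        for b, eg in enumerate(graphs):
            n = eg.n
            X[b, 1 : n + 1] = eg.features
            deg[b, 1 : n + 1] = eg.degree_idx
            buckets = np.where(
                eg.spd < 0, unreachable, np.minimum(eg.spd, cfg.max_spd_bucket)
            )
            spd_idx[b, 1 : n + 1, 1 : n + 1] = buckets
            spd_idx[b, 0, 1 : n + 1] = virtual_bucket
            spd_idx[b, 1 : n + 1, 0] = virtual_bucket
            spd_idx[b, 0, 0] = 0
            key_mask[b, : n + 1] = 0.0
            vmask[b, 0] = 1.0
        return {
            "X": X, "deg": deg, "spd_idx": spd_idx,
            "key_mask": key_mask, "vmask": vmask, "graphs": graphs,
        }

    # -- forward -----------------------------------------------------------
    def _edge_bias(self, batch: dict, branch: int) -> Tensor:
        """(B, heads, n1, n1) edge-path bias, computed per graph pre-padding."""
        cfg = self.config
        n1 = batch["X"].shape[1]
        L, F = cfg.max_path_len, self.EDGE_FEAT_DIM
        per_graph = []
        for eg in batch["graphs"]:
            n = eg.n
            flat = Tensor(eg.path_feats.reshape(n * n, L * F))
            c = (flat @ self.params[f"edge_w{branch}"]).reshape(n, n, cfg.heads)
            if cfg.edge_bias_mode == "path_average":
                scale = eg.inv_len[..., None]
            else:  # literal division by the total edge count of the graph
                scale = ((eg.inv_len > 0).astype(float)
                         / max(eg.n_edges, 1))[..., None]
            padded = (c * Tensor(scale)).pad_to((n1, n1, cfg.heads), (1, 1, 0))
            per_graph.append(padded.reshape(1, n1, n1, cfg.heads))
        return concat(per_graph, axis=0).transpose(0, 3, 1, 2)

    def _branch(self, batch: dict[str, np.ndarray], branch: int,
                collect_attention: bool) -> Tensor:
        cfg = self.config
        d, h = cfg.hidden_dim, cfg.heads
        dh = d // h
        B, n1 = batch["X"].shape[:2]

        H = Tensor(batch["X"]) @ self.params["W_in"] + self.params["b_in"]
        H = H + gather(self.params["deg_emb"], batch["deg"])
        H = H + Tensor(batch["vmask"][..., None]) * self.params[f"virtual{branch}"]

        spd_bias = gather(self.params[f"spd_bias{branch}"],
                          batch["spd_idx"]).transpose(0, 3, 1, 2)
        bias = spd_bias + self._edge_bias(batch, branch)
        bias = bias + Tensor(batch["key_mask"][:, None, None, :])

        for layer in range(cfg.layers):
            pre = f"b{branch}l{layer}_"

            def heads_of(t: Tensor) -> Tensor:
                return t.reshape(B, n1, h, dh).transpose(0, 2, 1, 3)

            q = heads_of(H @ self.params[pre + "Wq"])
            k = heads_of(H @ self.params[pre + "Wk"])
            v = heads_of(H @ self.params[pre + "Wv"])
            logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)) + bias
            A = logits.softmax(axis=-1)
            if collect_attention:
                self.last_attention.append(A.data.copy())
            out = (A @ v).transpose(0, 2, 1, 3).reshape(B, n1, d)
            out = out @ self.params[pre + "Wo"]
            H = ((H + out).layer_norm() * self.params[pre + "g1"]
                 + self.params[pre + "be1"])
            ff = (H @ self.params[pre + "F1"] + self.params[pre + "f1"]).relu()
            ff = ff @ self.params[pre + "F2"] + self.params[pre + "f2"]
            H = ((H + ff).layer_norm() * self.params[pre + "g2"]
                 + self.params[pre + "be2"])
            if not np.all(np.isfinite(H.data)):
                raise FloatingPointError(
                    f"non-finite activations in layer {layer}"
                )
        return H[:, 0, :]  # virtual-node readout, (B, d)

    def forward(
        self,
        graphs_b: list[EncodedGraph | ComplexGraph],
        graphs_c: list[EncodedGraph | ComplexGraph],
        collect_attention: bool = False,
    ) -> Tensor:
        """Predict pKd for a batch of complexes given their two graph views."""
        if len(graphs_b) != len(graphs_c) or not graphs_b:
            raise ValueError("need equal, non-empty graph lists")
        enc_b = [g if isinstance(g, EncodedGraph) else encode_graph(g, self.config)
                 for g in graphs_b]
        enc_c = [g if isinstance(g, EncodedGraph) else encode_graph(g, self.config)
                 for g in graphs_c]
        self.last_attention = []
        second = 0 if self.config.shared_weights else 1
        hb = self._branch(self._pad_batch(enc_b), 0, collect_attention)
        hc = self._branch(self._pad_batch(enc_c), second, collect_attention)
        z = concat([hb, hc], axis=-1)                       # (B, 2d)
        weights = (z @ self.params["W_pool"] + self.params["b_pool"]).softmax(axis=-1)
        pooled = weights * z
        y = pooled @ self.params["w_out"] + self.params["b_out"]
        return y.reshape(-1)

    def predict(
        self,
        graphs_b: list[EncodedGraph | ComplexGraph],
        graphs_c: list[EncodedGraph | ComplexGraph],
        batch_size: int = 16,
    ) -> np.ndarray:
        out = []
        for lo in range(0, len(graphs_b), batch_size):
            out.append(
                self.forward(graphs_b[lo : lo + batch_size],
                             graphs_c[lo : lo + batch_size]).data
            )
        return np.concatenate(out)

    def edge_path_bias(self, g: ComplexGraph, branch: int = 0) -> np.ndarray:
        """Per-head edge-path attention bias for one graph, (heads, n, n)."""
        eg = encode_graph(g, self.config)
        batch = self._pad_batch([eg])
        c = self._edge_bias(batch, branch).data[0]
        return c[:, 1 : eg.n + 1, 1 : eg.n + 1]

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            **{k: p.data for k, p in self.params.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "AffinityModel":
        with np.load(Path(path), allow_pickle=False) as blob:
            config = ModelConfig(**json.loads(str(blob["__config__"])))
            model = cls(config)
            for k, p in model.params.items():
                p.data = blob[k].astype(float)
        return model


def make_optimizer(model: AffinityModel, lr: float = 1e-3) -> Adam:
    return Adam(model.parameters(), lr=lr)
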