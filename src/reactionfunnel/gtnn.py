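"""Graph transformer neural network for reaction forward prediction.

Twin message-passing towers encode the N-arene and the carboxylic acid as
featurized graphs; no weights are shared between towers except the initial
atom embedding. Each tower applies layers of the update

    h_i^(l+1) = phi( h_i^l, sum_{j in N(i)} psi(h_i^l, h_j^l [, r_ij]) )

where psi and phi are MLPs, N(i) are covalently bonded neighbors, and r_ij
is a Fourier sine/cosine encoding of the inter-atomic distance (3D mode
only). The per-layer atom representations are concatenated, transformed by
an MLP, and pooled with a graph multiset transformer (GMT): multi-head
attention from learned seed vectors over the atom set, a self-attention
block over the seeds, and a final single-seed pooling. The two molecular
vectors are concatenated with a learned embedding of the one-hot reaction
conditions and mapped through an output MLP with a logistic squashing to
[0, 1].

Both targets (continuous yield and binary outcome) are treated as
regression with MSE loss. Training uses Adam, a step learning-rate decay,
exponential moving averaging of the weights for evaluation, and early
stopping on validation MAE.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .chemgraph import (
    ConditionVocabulary,
    MolecularGraph,
    default_fourier_frequencies,
    encode_conditions,
    fourier_distance,
    mol_to_graph,
)
from .datasplit import Fold, SplitAssignment
from .errors import EmptyInputError, SplitError
from .nn import ScatterPlan, Tensor, concat, gather_rows, segment_softmax, segment_sum
from .surf import ReactionDataset, ReactionRecord, total_yield


@dataclasses.dataclass
class GTNNConfig:
    hidden_dim: int = 128
    embed_dim: int = 64
    post_pool_dim: int = 256
    n_layers: int = 3
    pool_heads: int = 2  # 4 also supported
    pool_seeds: int = 4
    batch_size: int = 16
    learning_rate: float = 1e-4
    lr_decay: float = 0.5
    lr_decay_every: int = 100
    lr_decay_once: bool = False
    ema_factor: float = 0.9
    use_ema: bool = True
    max_epochs: int = 1000
    mode: str = "2d"  # "2d" or "3d"
    n_conformers: int = 10
    fourier_k: int = 16
    patience: int | None = None  # early-stop after this many non-improving epochs
    dtype: str = "float64"
    seed: int = 0

    def __post_init__(self):
        for f in ("hidden_dim", "embed_dim", "post_pool_dim", "n_layers",
                  "pool_heads", "pool_seeds", "batch_size", "max_epochs"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if not 0.0 <= self.ema_factor < 1.0:
            raise ValueError("ema_factor must be in [0, 1)")
        self.mode = self.mode.lower()
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.hidden_dim % self.pool_heads:
            raise ValueError("hidden_dim must be divisible by pool_heads")
        if self.dtype not in ("float64", "float32"):
            raise ValueError("dtype must be 'float64' or 'float32'")

    @classmethod
    def reduced(cls, **overrides) -> "GTNNConfig":
        """A CPU-scale configuration for experiments on synthetic data."""
        base = dict(
            hidden_dim=32,
            embed_dim=32,
            post_pool_dim=64,
            n_layers=2,
            pool_heads=2,
            pool_seeds=2,
            batch_size=128,
            max_epochs=200,
            learning_rate=1e-3,
            patience=30,
            dtype="float32",
        )
        base.update(overrides)
        return cls(**base)


def learning_rate_at(config: GTNNConfig, epoch: int) -> float:
    """Step-decayed learning rate for a given (0-based) epoch."""
    if config.lr_decay_once:
        steps = 1 if epoch >= config.lr_decay_every else 0
    else:
        steps = epoch // config.lr_decay_every
    return config.learning_rate * config.lr_decay**steps


# -- message passing ---------------------------------------------------------


class PsiMLP:
    """Edge message MLP psi(h_i, h_j [, r_ij]) with partitioned weights.

    The first layer of the concatenated-input MLP is computed as
    ``h @ Wi`` / ``h @ Wj`` projections over atoms followed by cheap row
    gathers, which is algebraically identical to concatenating per-edge
    inputs but avoids materializing edge-wide matrices at full width.
    """

    def __init__(self, d: int, edge_extra: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (2 * d + edge_extra + d))
        self.wi = Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
        self.wj = Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
        self.wr = (
            Tensor(rng.normal(0, scale, (edge_extra, d)), requires_grad=True)
            if edge_extra
            else None
        )
        self.b1 = Tensor(np.zeros(d), requires_grad=True)
        self.lin2 = nn.Linear(d, d, rng)

    @property
    def out_dim(self) -> int:
        return self.lin2.b.shape[0]

    def parameters(self):
        params = [self.wi, self.wj, self.b1] + self.lin2.parameters()
        if self.wr is not None:
            params.insert(3, self.wr)
        return params

    def __call__(self, h: Tensor, src: np.ndarray, dst: np.ndarray,
                 distance_features: Tensor | None,
                 src_plan: ScatterPlan | None = None,
                 dst_plan: ScatterPlan | None = None) -> Tensor:
        z = (
            gather_rows(h @ self.wi, src, plan=src_plan)
            + gather_rows(h @ self.wj, dst, plan=dst_plan)
            + self.b1
        )
        if self.wr is not None:
            if distance_features is None:
                raise ValueError("3D message layer requires distance features")
            z = z + distance_features @ self.wr
        return self.lin2(z.silu()).silu()


class PhiMLP:
    """Node update MLP phi(h_i, m_i), first layer partitioned like PsiMLP."""

    def __init__(self, d: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (3 * d))
        self.wh = Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
        self.wm = Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
        self.b1 = Tensor(np.zeros(d), requires_grad=True)
        self.lin2 = nn.Linear(d, d, rng)

    def parameters(self):
        return [self.wh, self.wm, self.b1] + self.lin2.parameters()

    def __call__(self, h: Tensor, m_agg: Tensor) -> Tensor:
        return self.lin2((h @ self.wh + m_agg @ self.wm + self.b1).silu())


class ConcatMLP:
    """MLP over concatenated per-layer atom features, weight-partitioned."""

    def __init__(self, d: int, n_layers: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_layers * d + d))
        self.ws = [
            Tensor(rng.normal(0, scale, (d, d)), requires_grad=True)
            for _ in range(n_layers)
        ]
        self.b1 = Tensor(np.zeros(d), requires_grad=True)
        self.lin2 = nn.Linear(d, d, rng)

    def parameters(self):
        return self.ws + [self.b1] + self.lin2.parameters()

    def __call__(self, layer_outputs: list[Tensor]) -> Tensor:
        z = layer_outputs[0] @ self.ws[0]
        for h, w in zip(layer_outputs[1:], self.ws[1:]):
            z = z + h @ w
        return self.lin2((z + self.b1).silu())


def message_passing_layer(
    h: Tensor,
    directed_edges: np.ndarray,
    psi: PsiMLP,
    phi: PhiMLP,
    distance_features: Tensor | None = None,
    recv_plan: ScatterPlan | None = None,
    dst_plan: ScatterPlan | None = None,
) -> Tensor:
    """One update h -> phi(h, sum_j psi(h_i, h_j [, r_ij])).

    ``directed_edges`` holds (receiver i, sender j) rows; messages are
    summed at the receiver. Nodes without neighbors receive the zero
    vector (empty-sum convention). The optional :class:`ScatterPlan` pair
    (receiver- and sender-index incidence) accelerates repeated calls.
    """
    n = h.shape[0]
    if directed_edges.shape[0] == 0:
        m_agg = Tensor(np.zeros((n, psi.out_dim), dtype=h.data.dtype))
    else:
        m = psi(h, directed_edges[:, 0], directed_edges[:, 1], distance_features,
                src_plan=recv_plan, dst_plan=dst_plan)
        m_agg = segment_sum(m, directed_edges[:, 0], n, plan=recv_plan)
    return phi(h, m_agg)


# -- GMT pooling -------------------------------------------------------------


class _MAB:
    """Multi-head attention block with residual + feed-forward residual."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.dim = dim
        self.heads = heads
        self.dh = dim // heads
        self.wq = nn.Linear(dim, dim, rng)
        self.wk = nn.Linear(dim, dim, rng)
        self.wv = nn.Linear(dim, dim, rng)
        self.wo = nn.Linear(dim, dim, rng)
        self.ff = nn.MLP([dim, 2 * dim, dim], rng)

    def parameters(self):
        return (
            self.wq.parameters() + self.wk.parameters() + self.wv.parameters()
            + self.wo.parameters() + self.ff.parameters()
        )


class GMTPooling:
    """Graph multiset transformer: seeded attention pooling over atom sets.

    Stage 1 attends from `n_seeds` learned seed vectors to the atoms of
    each graph (segment softmax over variable-size atom sets), stage 2 is
    self-attention among the seeds, stage 3 pools the seeds with a single
    learned query.
    """

    def __init__(self, dim: int, heads: int, n_seeds: int, rng: np.random.Generator):
        self.dim = dim
        self.heads = heads
        self.dh = dim // heads
        self.n_seeds = n_seeds
        self.seeds = Tensor(rng.normal(0, 1.0, size=(n_seeds, dim)), requires_grad=True)
        self.final_seed = Tensor(rng.normal(0, 1.0, size=(1, dim)), requires_grad=True)
        self.pool_g = _MAB(dim, heads, rng)
        self.sab = _MAB(dim, heads, rng)
        self.pool_i = _MAB(dim, heads, rng)

    def parameters(self):
        return (
            [self.seeds, self.final_seed]
            + self.pool_g.parameters()
            + self.sab.parameters()
            + self.pool_i.parameters()
        )

    def _split_heads(self, t: Tensor, lead: int) -> Tensor:
        # [lead, dim] -> [heads, lead, dh]
        return t.reshape(lead, self.heads, self.dh).swapaxes(0, 1)

    def __call__(self, h: Tensor, batch_idx: np.ndarray, n_graphs: int,
                 pool_plan: ScatterPlan | None = None,
                 sorted_starts: np.ndarray | None = None) -> Tensor:
        n = h.shape[0]
        if n == 0:
            raise EmptyInputError("cannot pool an empty graph batch")
        scale = 1.0 / np.sqrt(self.dh)
        # Stage 1: seeds attend over atoms, per graph.
        q = self._split_heads(self.pool_g.wq(self.seeds), self.n_seeds)  # [H,S,dh]
        k = self._split_heads(self.pool_g.wk(h), n)  # [H,N,dh]
        v = self.pool_g.wv(h).reshape(n, self.heads, 1, self.dh)  # [N,H,1,dh]
        scores = (k @ q.swapaxes(-1, -2)) * scale  # [H,N,S]
        scores = scores.swapaxes(0, 1).reshape(n, self.heads * self.n_seeds)
        alpha = segment_softmax(scores, batch_idx, n_graphs,
                                sorted_starts=sorted_starts)  # [N, H*S]
        alpha4 = alpha.reshape(n, self.heads, self.n_seeds, 1)
        contrib = alpha4 * v  # [N,H,S,dh]
        pooled = segment_sum(contrib, batch_idx, n_graphs, plan=pool_plan)  # [G,H,S,dh]
        pooled = pooled.swapaxes(1, 2).reshape(n_graphs, self.n_seeds, self.dim)
        y = self.seeds.reshape(1, self.n_seeds, self.dim) + self.pool_g.wo(pooled)
        y = y + self.pool_g.ff(y)
        # Stage 2: self-attention among seeds (dense, fixed size).
        y = self._dense_mab(self.sab, y, y)
        # Stage 3: single-seed pooling.
        q3 = Tensor(np.zeros((n_graphs, 1, self.dim))) + self.final_seed.reshape(
            1, 1, self.dim
        )
        out = self._dense_mab(self.pool_i, q3, y)  # [G,1,dim]
        return out.reshape(n_graphs, self.dim)

    def _dense_mab(self, mab: _MAB, q_in: Tensor, kv_in: Tensor) -> Tensor:
        g, s_q = q_in.shape[0], q_in.shape[1]
        s_kv = kv_in.shape[1]
        scale = 1.0 / np.sqrt(self.dh)

        def split(t: Tensor, s: int) -> Tensor:
            # [G,s,dim] -> [G,H,s,dh]
            return t.reshape(g, s, self.heads, self.dh).swapaxes(1, 2)

        q = split(mab.wq(q_in), s_q)
        k = split(mab.wk(kv_in), s_kv)
        v = split(mab.wv(kv_in), s_kv)
        att = ((q @ k.swapaxes(-1, -2)) * scale).softmax(-1) @ v  # [G,H,s_q,dh]
        att = att.swapaxes(1, 2).reshape(g, s_q, self.dim)
        y = q_in + mab.wo(att)
        return y + mab.ff(y)


# -- the model ---------------------------------------------------------------


class _Tower:
    def __init__(self, config: GTNNConfig, rng: np.random.Generator):
        d = config.hidden_dim
        edge_extra = 2 * config.fourier_k if config.mode == "3d" else 0
        self.psis = [PsiMLP(d, edge_extra, rng) for _ in range(config.n_layers)]
        self.phis = [PhiMLP(d, rng) for _ in range(config.n_layers)]
        self.final_mlp = ConcatMLP(d, config.n_layers, rng)
        self.pool = GMTPooling(d, config.pool_heads, config.pool_seeds, rng)

    def parameters(self):
        params = []
        for m in self.psis + self.phis + [self.final_mlp]:
            params += m.parameters()
        return params + self.pool.parameters()

    def __call__(
        self,
        h0: Tensor,
        directed_edges: np.ndarray,
        batch_idx: np.ndarray,
        n_graphs: int,
        distance_features: Tensor | None,
        plans: "SidePlans | None" = None,
    ) -> Tensor:
        h = h0
        layer_outputs = []
        recv_plan = plans.recv if plans else None
        dst_plan = plans.dst if plans else None
        for psi, phi in zip(self.psis, self.phis):
            h = message_passing_layer(h, directed_edges, psi, phi, distance_features,
                                      recv_plan=recv_plan, dst_plan=dst_plan)
            layer_outputs.append(h)
        return self.pool(
            self.final_mlp(layer_outputs),
            batch_idx,
            n_graphs,
            pool_plan=plans.pool if plans else None,
            sorted_starts=plans.pool_starts if plans else None,
        )


class GTNNModel:
    """Twin-tower reaction model with shared initial atom embedding."""

    def __init__(self, config: GTNNConfig, vocab: ConditionVocabulary):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dim
        self.embed = nn.MLP([20, config.embed_dim, d], rng, final_activation=True)
        self.tower_arene = _Tower(config, rng)
        self.tower_acid = _Tower(config, rng)
        self.cond_mlp = nn.MLP([vocab.dim, config.embed_dim, config.embed_dim], rng)
        self.head = nn.MLP(
            [2 * d + config.embed_dim, config.post_pool_dim, d, 1], rng
        )
        self.frequencies = default_fourier_frequencies(config.fourier_k)
        self._np_dtype = np.float32 if config.dtype == "float32" else np.float64
        if config.dtype == "float32":
            for p in self.parameters():
                p.data = p.data.astype(np.float32)

    def parameters(self) -> list[Tensor]:
        return (
            self.embed.parameters()
            + self.tower_arene.parameters()
            + self.tower_acid.parameters()
            + self.cond_mlp.parameters()
            + self.head.parameters()
        )

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------

    def forward_batch(self, batch: "Batch") -> Tensor:
        """Predictions in [0, 1] for a prepared batch, shape (B,)."""
        pooled = []
        for side, tower in (("arene", self.tower_arene), ("acid", self.tower_acid)):
            x, edges, bidx, dists, plans = batch.side(side)
            h0 = self.embed(Tensor(np.asarray(x, dtype=self._np_dtype)))
            dist_feats = None
            if self.config.mode == "3d" and dists is not None and len(dists):
                dist_feats = Tensor(
                    fourier_distance(dists, self.frequencies).astype(self._np_dtype)
                )
            pooled.append(tower(h0, edges, bidx, batch.n, dist_feats, plans))
        cond = self.cond_mlp(Tensor(np.asarray(batch.conditions, dtype=self._np_dtype)))
        z = concat(pooled + [cond], axis=1)
        return self.head(z).sigmoid().reshape(batch.n)

    def forward(
        self,
        arene: MolecularGraph,
        acid: MolecularGraph,
        conditions: np.ndarray,
        conformer: int = 0,
    ) -> float:
        """Single-reaction forward pass with a fixed conformer choice."""
        if conditions.shape[0] != self.vocab.dim:
            raise ValueError(
                f"condition vector length {conditions.shape[0]} != vocabulary "
                f"dimension {self.vocab.dim}"
            )
        batch = Batch.single(arene, acid, conditions, conformer, self.config.mode)
        return float(self.forward_batch(batch).data[0])

    def predict(
        self, record: ReactionRecord, n_conformers: int | None = None, seed: int = 0
    ) -> float:
        """Conformer-averaged prediction for one reaction record.

        In 3D mode the prediction is the arithmetic mean of the forward
        passes over the conformer ensemble; 2D mode needs no conformers.
        """
        cond = encode_conditions(record, self.vocab)
        if self.config.mode == "2d":
            arene = mol_to_graph(record.arene)
            acid = mol_to_graph(record.acid)
            return self.forward(arene, acid, cond)
        k = n_conformers if n_conformers is not None else self.config.n_conformers
        arene = mol_to_graph(record.arene, with_conformers=True, n_conformers=k, seed=seed)
        acid = mol_to_graph(record.acid, with_conformers=True, n_conformers=k, seed=seed)
        vals = [self.forward(arene, acid, cond, conformer=i) for i in range(k)]
        return float(np.mean(vals))

    # -- checkpointing -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = {
            "config": dataclasses.asdict(self.config),
            "vocab": {k: list(v) for k, v in self.vocab.labels.items()},
            "unk_categories": sorted(self.vocab.unk_categories),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GTNNModel":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = GTNNConfig(**meta["config"])
        vocab = ConditionVocabulary(meta["vocab"], meta["unk_categories"])
        model = cls(config, vocab)
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i}"].copy()
        return model


# -- batching ----------------------------------------------------------------


@dataclasses.dataclass
class SidePlans:
    """Precomputed sparse scatter plans for one side of a batch."""

    recv: ScatterPlan
    dst: ScatterPlan
    pool: ScatterPlan
    pool_starts: np.ndarray


class Batch:
    """Concatenated graph arrays for a set of reactions."""

    def __init__(self, arene_side, acid_side, conditions: np.ndarray, n: int):
        self._sides = {"arene": arene_side, "acid": acid_side}
        self.conditions = conditions
        self.n = n

    def side(self, name):
        return self._sides[name]

    @staticmethod
    def assemble(
        graphs: Sequence[MolecularGraph],
        conformer_choices: Sequence[int] | None,
        mode: str,
    ):
        feats, edge_blocks, bidx, dists = [], [], [], []
        offset = 0
        for g_i, graph in enumerate(graphs):
            feats.append(graph.atom_features)
            de = graph.directed_edges()
            edge_blocks.append(de + offset)
            bidx.append(np.full(graph.n_atoms, g_i))
            if mode == "3d":
                conf = conformer_choices[g_i] if conformer_choices is not None else 0
                coords = graph.conformers[conf]
                diff = coords[de[:, 0]] - coords[de[:, 1]]
                dists.append(np.sqrt((diff**2).sum(axis=1)))
            offset += graph.n_atoms
        x = np.concatenate(feats, axis=0)
        edges = np.concatenate(edge_blocks, axis=0).astype(int)
        batch_idx = np.concatenate(bidx).astype(int)
        d = np.concatenate(dists) if dists else None
        n_atoms = x.shape[0]
        plans = SidePlans(
            recv=ScatterPlan(edges[:, 0], n_atoms),
            dst=ScatterPlan(edges[:, 1], n_atoms),
            pool=ScatterPlan(batch_idx, len(graphs)),
            pool_starts=np.searchsorted(batch_idx, np.arange(len(graphs))),
        )
        return x, edges, batch_idx, d, plans

    @classmethod
    def single(
        cls,
        arene: MolecularGraph,
        acid: MolecularGraph,
        conditions: np.ndarray,
        conformer: int,
        mode: str,
    ) -> "Batch":
        return cls(
            cls.assemble([arene], [conformer], mode),
            cls.assemble([acid], [conformer], mode),
            conditions.reshape(1, -1),
            1,
        )


class DatasetEncoder:
    """Caches featurized graphs and condition vectors for a dataset."""

    def __init__(self, dataset: ReactionDataset, config: GTNNConfig,
                 vocab: ConditionVocabulary, target: str = "yield"):
        self.config = config
        self.vocab = vocab
        with_conf = config.mode == "3d"
        self._graphs: dict[str, MolecularGraph] = {}
        for rec in dataset.records:
            for smi in (rec.arene, rec.acid):
                if smi not in self._graphs:
                    self._graphs[smi] = mol_to_graph(
                        smi,
                        with_conformers=with_conf,
                        n_conformers=config.n_conformers,
                        seed=config.seed,
                    )
        self.records = {r.reaction_id: r for r in dataset.records}
        self.conditions = {
            r.reaction_id: encode_conditions(r, vocab) for r in dataset.records
        }
        if target == "yield":
            self.targets = {r.reaction_id: total_yield(r) for r in dataset.records}
        elif target == "binary":
            self.targets = {
                r.reaction_id: float(total_yield(r) >= 0.05) for r in dataset.records
            }
        else:
            raise ValueError(f"unknown target {target!r}")

    def graph(self, smiles: str) -> MolecularGraph:
        return self._graphs[smiles]

    def make_batch(
        self, ids: Sequence[str], rng: np.random.Generator | None = None
    ) -> tuple[Batch, np.ndarray]:
        arenes = [self._graphs[self.records[i].arene] for i in ids]
        acids = [self._graphs[self.records[i].acid] for i in ids]
        conf_a = conf_b = None
        if self.config.mode == "3d":
            k = self.config.n_conformers
            if rng is not None:
                conf_a = rng.integers(0, k, size=len(ids))
                conf_b = rng.integers(0, k, size=len(ids))
            else:
                conf_a = conf_b = np.zeros(len(ids), dtype=int)
        batch = Batch(
            Batch.assemble(arenes, conf_a, self.config.mode),
            Batch.assemble(acids, conf_b, self.config.mode),
            np.stack([self.conditions[i] for i in ids]),
            len(ids),
        )
        y = np.array([self.targets[i] for i in ids])
        return batch, y


# -- training ----------------------------------------------------------------


@dataclasses.dataclass
class TrainResult:
    best_model: GTNNModel
    history: dict
    best_epoch: int


def _evaluate_mae(model: GTNNModel, encoder: DatasetEncoder, ids: Sequence[str],
                  batch_size: int = 256) -> float:
    errs = []
    with nn.no_grad():
        for lo in range(0, len(ids), batch_size):
            chunk = list(ids[lo:lo + batch_size])
            batch, y = encoder.make_batch(chunk)  # conformer 0 during training
            pred = model.forward_batch(batch).data
            errs.append(np.abs(pred - y))
    return float(np.concatenate(errs).mean())


def predict_ids(model: GTNNModel, encoder: DatasetEncoder, ids: Sequence[str],
                batch_size: int = 256, conformer_average: bool = True) -> np.ndarray:
    """Predictions for a list of reaction ids (conformer-averaged in 3D)."""
    preds = np.zeros(len(ids))
    confs = (
        range(model.config.n_conformers)
        if (model.config.mode == "3d" and conformer_average)
        else [0]
    )
    with nn.no_grad():
        for lo in range(0, len(ids), batch_size):
            chunk = list(ids[lo:lo + batch_size])
            acc = np.zeros(len(chunk))
            for c in confs:
                arenes = [encoder.graph(encoder.records[i].arene) for i in chunk]
                acids = [encoder.graph(encoder.records[i].acid) for i in chunk]
                batch = Batch(
                    Batch.assemble(arenes, [c] * len(chunk), model.config.mode),
                    Batch.assemble(acids, [c] * len(chunk), model.config.mode),
                    np.stack([encoder.conditions[i] for i in chunk]),
                    len(chunk),
                )
                acc += model.forward_batch(batch).data
            preds[lo:lo + len(chunk)] = acc / len(list(confs))
    return preds


def train_fold(
    dataset: ReactionDataset,
    fold: Fold,
    config: GTNNConfig,
    target: str = "yield",
    vocab: ConditionVocabulary | None = None,
    encoder: DatasetEncoder | None = None,
) -> TrainResult:
    """Train on one fold's train/val partition with early stopping."""
    if not fold.train or not fold.val:
        raise SplitError("fold has an empty train or validation partition")
    vocab = vocab or ConditionVocabulary(dataset.condition_vocabulary)
    if encoder is None:
        encoder = DatasetEncoder(dataset, config, vocab, target=target)
    model = GTNNModel(config, vocab)
    params = model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)
    ema = nn.EMA(params, config.ema_factor) if config.use_ema else None
    rng = np.random.default_rng(config.seed + 1)

    train_ids = list(fold.train)
    history = {"train_loss": [], "val_mae": [], "lr": []}
    best_mae = np.inf
    best_epoch = -1
    best_params = [p.data.copy() for p in params]

    for epoch in range(config.max_epochs):
        opt.lr = learning_rate_at(config, epoch)
        order = rng.permutation(len(train_ids))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(train_ids), config.batch_size):
            ids = [train_ids[i] for i in order[lo:lo + config.batch_size]]
            batch, y = encoder.make_batch(ids, rng=rng)
            pred = model.forward_batch(batch)
            diff = pred - Tensor(y.astype(model._np_dtype))
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema.update()
            epoch_loss += float(loss.data)
            n_batches += 1
        # Validation with EMA (smoothed) weights.
        if ema is not None:
            live = ema.swap_in()
        val_mae = _evaluate_mae(model, encoder, fold.val)
        if val_mae < best_mae:
            best_mae = val_mae
            best_epoch = epoch
            best_params = [p.data.copy() for p in params]
        if ema is not None:
            ema.swap_out(live)
        history["train_loss"].append(epoch_loss / max(1, n_batches))
        history["val_mae"].append(val_mae)
        history["lr"].append(opt.lr)
        if config.patience is not None and epoch - best_epoch >= config.patience:
            break

    for p, d in zip(params, best_params):
        p.data = d
    return TrainResult(best_model=model, history=history, best_epoch=best_epoch)


def train(
    dataset: ReactionDataset,
    split: SplitAssignment,
    config: GTNNConfig,
    target: str = "yield",
    folds: Sequence[int] | None = None,
) -> list[TrainResult]:
    """Train one model per cross-validation fold (optionally a subset)."""
    vocab = ConditionVocabulary(dataset.condition_vocabulary)
    encoder = DatasetEncoder(dataset, config, vocab, target=target)
    indices = range(len(split.folds)) if folds is None else folds
    return [
        train_fold(dataset, split.folds[i], config, target=target,
                   vocab=vocab, encoder=encoder)
        for i in indices
    ]
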