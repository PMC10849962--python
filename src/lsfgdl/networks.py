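"""The borylation network family: GNN, GTNN, aGNN and the ECFP4NN baseline.

All three graph architectures share an E(3)-invariant message-passing trunk:

    h_i^{l+1} = phi( h_i^l,  sum_{j in N(i)} psi(h_i^l, h_j^l [, r_ij]) )

where r_ij are Fourier distance features, used only by the 3D graph
variants.  Because coordinates enter solely through interatomic distances,
every output is invariant under rotations, translations and reflections of
the conformer.  After three message-passing layers, the per-layer atomic
features [h^1, h^2, h^3] are concatenated and transformed by an MLP into
final atomic features H.

* GNN pools H by summation.
* GTNN pools H with a graph multiset transformer: per attention head a
  learned query vector q attends over keys/values produced by lightweight
  per-head message-passing blocks, o_i = Attn(q K^T) V; the four head
  outputs are concatenated and projected (W^o).  Attention is the raw
  q K^T V product by default, with a scaled-softmax option.
* aGNN applies no pooling: H maps through a final MLP with a sigmoid to
  one reactivity score per atom (regioselectivity).

Molecule-level models concatenate the pooled representation with an
embedded one-hot condition vector and regress the output (yield on the
[0, 1] fraction scale; binary outcome through a sigmoid).  The ECFP4NN
baseline replaces the graph trunk with a 256-bit ECFP4 fingerprint MLP and
two condition embeddings (ligand, solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit.Chem import rdFingerprintGenerator

from .autodiff import Tensor, concat, segment_sum
from .graphs import MolGraph
from .nn import MLP, Linear, Module
from .surf import substrate_mol

__all__ = [
    "ModelConfig",
    "GraphBatch",
    "BorylationNet",
    "ECFP4NN",
    "ecfp4",
    "build_model",
    "count_parameters",
]

ARCHITECTURES = ("GNN", "GTNN", "aGNN", "ECFP4NN")
TASKS = ("yield", "binary", "regio")


@dataclass
class ModelConfig:
    """Architecture variant and dimensions.

    Defaults follow the production-scale settings: internal feature
    dimension 128, embedding dimension 64 for atomic/condition inputs,
    256-wide first layer after pooling, three message-passing layers and
    four attention heads.  `mlp_hidden` (the hidden width of the two-hidden-
    layer SiLU MLPs used throughout) is the one free shape parameter and is
    recorded here so parameter counts are auditable.
    """

    architecture: str = "GTNN"
    graph_variant: str | None = "3DQM"
    task: str = "yield"
    hidden_dim: int = 128
    embed_dim: int = 64
    post_pool_dim: int = 256
    mlp_hidden: int = 320
    n_layers: int = 3
    n_heads: int = 4
    fingerprint_dim: int = 256
    n_frequencies: int = 16
    attention: str = "linear"  # "linear" = raw QK^T V; "softmax" = scaled softmax
    loss: str = "mse"  # "bce" available for the binary task

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.architecture == "aGNN" and self.task != "regio":
            raise ValueError("aGNN is the atomistic model: task must be 'regio'")
        if self.architecture != "aGNN" and self.task == "regio":
            raise ValueError("the regio task requires the aGNN architecture")
        if self.architecture == "ECFP4NN":
            self.graph_variant = None
        elif self.graph_variant not in ("2D", "3D", "2DQM", "3DQM"):
            raise ValueError(f"unknown graph variant {self.graph_variant!r}")

    @property
    def is_3d(self) -> bool:
        return self.graph_variant is not None and self.graph_variant.startswith("3D")

    @property
    def atom_feature_width(self) -> int:
        base = 20
        return base + 1 if (self.graph_variant or "").endswith("QM") else base

    @property
    def edge_feature_width(self) -> int:
        return 2 * self.n_frequencies if self.is_3d else 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------- graph batch


@dataclass
class GraphBatch:
    """Several molecular graphs packed into one disjoint-union graph."""

    atom_features: np.ndarray  # (N, F)
    edges: np.ndarray  # (E, 2) global indices
    edge_features: np.ndarray | None  # (E, 2 * n_frequencies) or None
    graph_ids: np.ndarray  # (N,) molecule index per atom
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty graph batch")
        widths = {g.atom_features.shape[1] for g in graphs}
        if len(widths) != 1:
            raise ValueError(f"inconsistent atom feature widths in batch: {widths}")
        feats, edges, efeats, gids = [], [], [], []
        offset = 0
        has_ef = graphs[0].distance_features is not None
        for gid, g in enumerate(graphs):
            feats.append(g.atom_features)
            edges.append(g.edges + offset if len(g.edges) else g.edges.reshape(0, 2))
            if has_ef:
                efeats.append(g.distance_features)
            gids.append(np.full(g.n_atoms, gid))
            offset += g.n_atoms
        return cls(
            atom_features=np.concatenate(feats, axis=0),
            edges=np.concatenate(edges, axis=0).astype(int),
            edge_features=np.concatenate(efeats, axis=0) if has_ef else None,
            graph_ids=np.concatenate(gids).astype(int),
            n_graphs=len(graphs),
        )


# -------------------------------------------------------------------- modules


class MessagePassingLayer(Module):
    """One E(3)-invariant message-passing update (shared by all trunks)."""

    def __init__(self, hidden: int, edge_dim: int, mlp_hidden: int, rng, out_dim=None):
        out_dim = out_dim or hidden
        self.psi = MLP([2 * hidden + edge_dim, mlp_hidden, mlp_hidden, out_dim], rng)
        self.phi = MLP([hidden + out_dim, mlp_hidden, mlp_hidden, out_dim], rng)
        self.edge_dim = edge_dim

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        n_atoms = h.data.shape[0]
        if len(batch.edges):
            h_i = h.take_rows(batch.edges[:, 0])
            h_j = h.take_rows(batch.edges[:, 1])
            parts = [h_i, h_j]
            if self.edge_dim:
                if batch.edge_features is None:
                    raise ValueError("3D message passing requires edge distance features")
                parts.append(Tensor(batch.edge_features))
            messages = self.psi(concat(parts, axis=1))
            agg = segment_sum(messages, batch.edges[:, 0], n_atoms)
        else:  # isolated nodes: empty neighbour sum is zero
            agg = Tensor(np.zeros((n_atoms, self.psi.layers[-1].weight.data.shape[1])))
        return self.phi(concat([h, agg], axis=1))


class Trunk(Module):
    """Embedding + three message-passing layers + layer-concat MLP -> H."""

    def __init__(self, cfg: ModelConfig, rng):
        self.embed = MLP([cfg.atom_feature_width, cfg.embed_dim, cfg.hidden_dim], rng)
        self.layers = [
            MessagePassingLayer(cfg.hidden_dim, cfg.edge_feature_width, cfg.mlp_hidden, rng)
            for _ in range(cfg.n_layers)
        ]
        self.concat_mlp = MLP(
            [cfg.n_layers * cfg.hidden_dim, cfg.mlp_hidden, cfg.mlp_hidden, cfg.hidden_dim], rng
        )

    def __call__(self, batch: GraphBatch) -> Tensor:
        h = self.embed(Tensor(batch.atom_features))
        states = []
        for layer in self.layers:
            h = layer(h, batch)
            states.append(h)
        return self.concat_mlp(concat(states, axis=1))


class GMTPooling(Module):
    """Graph-multiset-transformer pooling with per-head learned queries.

    Each head owns a query vector q and two lightweight message-passing
    blocks producing keys and values from (H, E); Attn(Q, K, V) = QK^T V
    (optionally scaled softmax over each molecule's atoms).  Head outputs
    are concatenated and projected by W^o.
    """

    def __init__(self, cfg: ModelConfig, rng):
        if cfg.hidden_dim % cfg.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.head_dim = cfg.hidden_dim // cfg.n_heads
        self.attention = cfg.attention
        self.queries = [
            Tensor(rng.normal(0.0, 1.0 / np.sqrt(self.head_dim), size=(self.head_dim,)),
                   requires_grad=True)
            for _ in range(cfg.n_heads)
        ]
        kv_hidden = cfg.hidden_dim  # lightweight: single-hidden-layer MLPs
        self.key_blocks = [
            MessagePassingLayer(cfg.hidden_dim, cfg.edge_feature_width, kv_hidden, rng,
                                out_dim=self.head_dim)
            for _ in range(cfg.n_heads)
        ]
        self.value_blocks = [
            MessagePassingLayer(cfg.hidden_dim, cfg.edge_feature_width, kv_hidden, rng,
                                out_dim=self.head_dim)
            for _ in range(cfg.n_heads)
        ]
        self.w_o = Linear(cfg.n_heads * self.head_dim, cfg.hidden_dim, rng)

    def __call__(self, H: Tensor, batch: GraphBatch) -> Tensor:
        outs = []
        for q, kb, vb in zip(self.queries, self.key_blocks, self.value_blocks):
            K = kb(H, batch)  # (N, head_dim)
            V = vb(H, batch)
            scores = (K * q.reshape(1, -1)).sum(axis=1, keepdims=True)  # q K^T
            if self.attention == "softmax":
                scores = scores * (1.0 / np.sqrt(self.head_dim))
                shift = np.full(batch.n_graphs, -np.inf)
                np.maximum.at(shift, batch.graph_ids, scores.data[:, 0])
                e = (scores - Tensor(shift[batch.graph_ids][:, None])).exp()
                denom = segment_sum(e, batch.graph_ids, batch.n_graphs)
                weights = e * denom.take_rows(batch.graph_ids) ** (-1.0)
            else:
                weights = scores
            outs.append(segment_sum(weights * V, batch.graph_ids, batch.n_graphs))
        return self.w_o(concat(outs, axis=1))


class BorylationNet(Module):
    """GNN / GTNN / aGNN over a molecular graph batch."""

    def __init__(self, cfg: ModelConfig, condition_width: int = 0, seed: int = 0):
        if cfg.architecture == "ECFP4NN":
            raise ValueError("use the ECFP4NN class for the fingerprint baseline")
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.trunk = Trunk(cfg, rng)
        if cfg.architecture == "aGNN":
            self.atom_head = MLP([cfg.hidden_dim, cfg.mlp_hidden, cfg.mlp_hidden, 1], rng)
            return
        if cfg.architecture == "GTNN":
            self.pool = GMTPooling(cfg, rng)
        self.post_pool = MLP([cfg.hidden_dim, cfg.post_pool_dim, cfg.hidden_dim], rng)
        if condition_width <= 0:
            raise ValueError("molecule-level models require a condition vector width")
        self.condition_width = condition_width
        self.cond_embed = MLP([condition_width, cfg.embed_dim, cfg.hidden_dim], rng)
        self.head = MLP([2 * cfg.hidden_dim, cfg.mlp_hidden, cfg.mlp_hidden, 1], rng)

    # -- forward passes ------------------------------------------------------
    def forward_reaction(self, batch: GraphBatch, conditions: np.ndarray) -> Tensor:
        """Per-molecule scalar: yield fraction (linear) or outcome prob (sigmoid)."""
        cfg = self.config
        if cfg.architecture == "aGNN":
            raise ValueError("aGNN has no molecule-level head")
        conditions = np.asarray(conditions, dtype=float)
        if conditions.shape != (batch.n_graphs, self.condition_width):
            raise ValueError(
                f"condition matrix shape {conditions.shape} does not match "
                f"(n_graphs={batch.n_graphs}, width={self.condition_width})"
            )
        H = self.trunk(batch)
        if cfg.architecture == "GTNN":
            pooled = self.pool(H, batch)
        else:
            pooled = segment_sum(H, batch.graph_ids, batch.n_graphs)
        mol = self.post_pool(pooled)
        cond = self.cond_embed(Tensor(conditions))
        out = self.head(concat([mol, cond], axis=1))
        if cfg.task == "binary":
            out = out.sigmoid()
        return out

    def forward_atomistic(self, batch: GraphBatch) -> Tensor:
        """Per-atom reactivity scores in [0, 1] (aGNN only)."""
        if self.config.architecture != "aGNN":
            raise ValueError("forward_atomistic requires the aGNN architecture")
        H = self.trunk(batch)
        return self.atom_head(H).sigmoid()

    def __call__(self, batch: GraphBatch, conditions: np.ndarray | None = None) -> Tensor:
        if self.config.architecture == "aGNN":
            return self.forward_atomistic(batch)
        return self.forward_reaction(batch, conditions)


class ECFP4NN(Module):
    """Fingerprint baseline: three input MLPs (ECFP4, ligand, solvent) + head."""

    def __init__(self, cfg: ModelConfig, ligand_width: int, solvent_width: int, seed: int = 0):
        if cfg.architecture != "ECFP4NN":
            raise ValueError("config architecture must be ECFP4NN")
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.ligand_width = ligand_width
        self.solvent_width = solvent_width
        self.fp_mlp = MLP([cfg.fingerprint_dim, cfg.mlp_hidden, cfg.mlp_hidden, cfg.hidden_dim], rng)
        self.ligand_mlp = MLP([ligand_width, cfg.embed_dim, cfg.hidden_dim], rng)
        self.solvent_mlp = MLP([solvent_width, cfg.embed_dim, cfg.hidden_dim], rng)
        self.head = MLP([3 * cfg.hidden_dim, cfg.mlp_hidden, cfg.mlp_hidden, 1], rng)

    def __call__(self, fingerprints: np.ndarray, ligand_onehot: np.ndarray,
                 solvent_onehot: np.ndarray) -> Tensor:
        fingerprints = np.asarray(fingerprints, dtype=float)
        if fingerprints.ndim != 2 or fingerprints.shape[1] != self.config.fingerprint_dim:
            raise ValueError(
                f"fingerprint width must be {self.config.fingerprint_dim}; "
                f"got shape {fingerprints.shape}"
            )
        out = self.head(
            concat(
                [
                    self.fp_mlp(Tensor(fingerprints)),
                    self.ligand_mlp(Tensor(np.asarray(ligand_onehot, dtype=float))),
                    self.solvent_mlp(Tensor(np.asarray(solvent_onehot, dtype=float))),
                ],
                axis=1,
            )
        )
        if self.config.task == "binary":
            out = out.sigmoid()
        return out


# ------------------------------------------------------------------- helpers


def ecfp4(smiles_or_mol, n_bits: int = 256) -> np.ndarray:
    """ECFP4 (Morgan radius 2) fingerprint folded to `n_bits`."""
    mol = substrate_mol(smiles_or_mol) if isinstance(smiles_or_mol, str) else smiles_or_mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return gen.GetFingerprintAsNumPy(mol).astype(float)


def build_model(cfg: ModelConfig, condition_width: int = 0, seed: int = 0,
                ligand_width: int = 0, solvent_width: int = 0):
    if cfg.architecture == "ECFP4NN":
        return ECFP4NN(cfg, ligand_width, solvent_width, seed)
    return BorylationNet(cfg, condition_width, seed)


def count_parameters(model: Module) -> int:
    """Total trainable scalar count."""
    return model.n_parameters()
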