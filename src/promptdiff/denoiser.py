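"""Prompt-conditioned equivariant denoiser.

The network predicts the clean ligand ``(x0, h0)`` from a noised complex
at step ``t``.  It stacks equivariant blocks; each block runs three
modules in order:

1. *feature update* — residual multi-head attention over the distance
   graph; prompted protein atoms first receive their learnable continuous
   prompt embedding.  Features see coordinates only through pairwise
   distances, so they are invariant under rigid motions.
2. *coordinate update* — attention-weighted sums of relative vectors
   ``x_i - x_j`` added to ligand coordinates (all coordinates in joint
   mode); equivariant by construction.
3. *cross-attention* — ligand atoms attend to the full protein context
   (features concatenated with continuous prompt embeddings) with an
   encoded ligand–protein distance matrix in the similarity network.
   The first half of the heads drives a feature update, the second half
   drives a coordinate update through ligand–protein relative vectors.
   This is the long-range prompt-guidance pathway and can be disabled
   for ablation.

A classification head reads the final protein features and predicts the
per-atom interaction class (none + the four interaction types).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .complexes import INTERACTION_TYPES, ComplexGraph, InteractionPromptSet
from .diffusion import N_INTERACTION_CLASSES, AtomVocabulary
from .nn.autodiff import Tensor, concat, masked_softmax
from .nn.layers import MLP, GaussianDistanceEncoding, Linear

__all__ = ["DenoiserConfig", "Denoiser", "DenoiserOutput"]


@dataclass(frozen=True)
class DenoiserConfig:
    n_blocks: int = 6
    hidden: int = 64
    nheads: int = 4
    dist_dim: int = 32           # width of the encoded ligand-protein distances
    n_rbf: int = 32              # radial-basis centers for the distance encoding
    cross_attention_enabled: bool = True
    joint: bool = False          # unconditional protein+ligand variant (inpainting)
    cutoff: float = 7.0          # Å, neighborhood graph
    rebuild_edges: bool = True   # rebuild the distance graph every denoising step
    time_embedding: str = "t_over_T"

    def __post_init__(self):
        if self.nheads % 2 != 0 or self.nheads < 2:
            raise ValueError("nheads must be even and >= 2 (the head split "
                             "halves it)")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.hidden % self.nheads != 0:
            raise ValueError("hidden must be divisible by nheads")
        if (2 * self.hidden) % self.nheads != 0:
            raise ValueError("2*hidden must be divisible by nheads")


@dataclass
class DenoiserOutput:
    x0_hat: Tensor          # (B, N_L, 3) — (B, N, 3) in joint mode
    h0_hat: Tensor          # (B, N_L, K) rows are distributions
    protein_logits: Tensor  # (B, N_P, 5)


def _heads(t: Tensor, nheads: int):
    *lead, d = t.shape
    return t.reshape(*lead, nheads, d // nheads)


class _Block:
    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        H, nh = cfg.hidden, cfg.nheads
        m_in = 2 * H + 1
        # module 1: feature update over the neighborhood graph
        self.f_k = MLP(m_in, H, H, rng)
        self.f_v = MLP(m_in, H, H, rng)
        self.f_q = MLP(H, H, H, rng)
        # module 2: coordinate update (per-head scalar gates on x_i - x_j)
        self.c_k = MLP(m_in, H, H, rng)
        self.c_v = MLP(m_in, H, nh, rng, zero_last=True)
        self.c_q = MLP(H, H, H, rng)
        # module 3: ligand-protein cross-attention
        if cfg.cross_attention_enabled:
            self.dis_encoding = GaussianDistanceEncoding(cfg.n_rbf, cfg.dist_dim,
                                                         rng)
            self.x_qk_L = Linear(H, H, rng)
            self.x_qk_P = Linear(2 * H, H, rng)
            self.x_v_P = Linear(2 * H, H, rng)
            self.sim = MLP(nh + cfg.dist_dim, H, nh, rng)
            self.out_h = MLP(H, H, H, rng)
            self.out_x = MLP(1, H, 1, rng, zero_last=True)
        self.cfg = cfg

    def params(self):
        mods = [self.f_k, self.f_v, self.f_q, self.c_k, self.c_v, self.c_q]
        if self.cfg.cross_attention_enabled:
            mods += [self.dis_encoding, self.x_qk_L, self.x_qk_P, self.x_v_P,
                     self.sim, self.out_h, self.out_x]
        out = []
        for m in mods:
            out.extend(m.params())
        return out

    # -- helpers -------------------------------------------------------------
    @staticmethod
    def _pairwise(x: Tensor) -> tuple[Tensor, Tensor]:
        """Relative vectors (B,N,N,3) and distances (B,N,N,1) from (B,N,3)."""
        B, N, _ = x.shape
        xi = x.reshape(B, N, 1, 3).broadcast_to((B, N, N, 3))
        xj = x.reshape(B, 1, N, 3).broadcast_to((B, N, N, 3))
        rel = xi - xj
        d = ((rel * rel).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
        return rel, d

    def _messages(self, h: Tensor, d: Tensor) -> Tensor:
        B, N, H = h.shape
        hi = h.reshape(B, N, 1, H).broadcast_to((B, N, N, H))
        hj = h.reshape(B, 1, N, H).broadcast_to((B, N, N, H))
        return concat([d, hi, hj], axis=-1)

    def _graph_attention(self, k: Tensor, q: Tensor, adj: np.ndarray) -> Tensor:
        """Masked per-node attention weights (B,N,N,nh) over neighbors."""
        nh = self.cfg.nheads
        B, N, _, _ = k.shape
        kh = _heads(k, nh)                                   # (B,N,N,nh,dk)
        qh = _heads(q, nh).reshape(B, N, 1, nh, -1)
        dk = kh.shape[-1]
        logits = (kh * qh.broadcast_to(kh.shape)).sum(axis=-1) * (1.0 / np.sqrt(dk))
        return masked_softmax(logits, adj[..., None], axis=2)

    # -- the three modules ----------------------------------------------------
    def feature_update(self, h: Tensor, x: Tensor, adj: np.ndarray,
                       v_c_atoms: Tensor | None, n_L: int) -> Tensor:
        B, N, H = h.shape
        if v_c_atoms is not None:
            # prompted protein atoms receive their continuous prompt embedding
            pad = Tensor(np.zeros((B, n_L, H)))
            h = h + concat([pad, v_c_atoms], axis=1)
        _, d = self._pairwise(x)
        m = self._messages(h, d)
        attn = self._graph_attention(self.f_k(m), self.f_q(h), adj)
        v = _heads(self.f_v(m), self.cfg.nheads)             # (B,N,N,nh,dv)
        agg = (attn.reshape(*attn.shape, 1).broadcast_to(v.shape) * v).sum(axis=2)
        return h + agg.reshape(B, N, H)

    def coordinate_update(self, h: Tensor, x: Tensor, adj: np.ndarray,
                          n_L: int) -> Tensor:
        B, N, _ = x.shape
        rel, d = self._pairwise(x)
        m = self._messages(h, d)
        attn = self._graph_attention(self.c_k(m), self.c_q(h), adj)
        gates = self.c_v(m)                                  # (B,N,N,nh)
        w = (attn * gates).mean(axis=-1)                     # (B,N,N)
        upd = (w.reshape(B, N, N, 1).broadcast_to(rel.shape) * rel).sum(axis=2)
        if self.cfg.joint:
            return x + upd
        return concat([x[:, :n_L] + upd[:, :n_L], x[:, n_L:]], axis=1)

    def cross_attention(self, h_L: Tensor, x_L: Tensor, h_P: Tensor,
                        x_P: Tensor, v_c_atoms: Tensor) -> tuple[Tensor, Tensor]:
        cfg = self.cfg
        nh, half = cfg.nheads, cfg.nheads // 2
        B, NL, H = h_L.shape
        NP = h_P.shape[1]
        xi = x_L.reshape(B, NL, 1, 3).broadcast_to((B, NL, NP, 3))
        xj = x_P.reshape(B, 1, NP, 3).broadcast_to((B, NL, NP, 3))
        rel = xi - xj
        d = ((rel * rel).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
        d_enc = self.dis_encoding(d)                          # (B,NL,NP,dist_dim)
        cxt = concat([h_P, v_c_atoms], axis=-1)               # (B,NP,2H)
        qh = _heads(self.x_qk_L(h_L), nh).reshape(B, NL, 1, nh, -1)
        kh = _heads(self.x_qk_P(cxt), nh).reshape(B, 1, NP, nh, -1)
        dq = qh.shape[-1]
        dot = (qh.broadcast_to((B, NL, NP, nh, dq))
               * kh.broadcast_to((B, NL, NP, nh, dq))).sum(axis=-1) / np.sqrt(dq)
        sim = self.sim(concat([dot, d_enc], axis=-1))         # (B,NL,NP,nh)
        attn = masked_softmax(sim, np.ones((B, NL, NP, nh), bool), axis=2)
        # feature stream: first half of the heads
        vh = _heads(self.x_v_P(cxt), half).reshape(B, 1, NP, half, -1)
        a_h = attn[..., :half]
        h_tilde = (a_h.reshape(B, NL, NP, half, 1).broadcast_to(
            (B, NL, NP, half, vh.shape[-1]))
            * vh.broadcast_to((B, NL, NP, half, vh.shape[-1]))).sum(axis=2)
        h_out = h_L + self.out_h(h_tilde.reshape(B, NL, H))
        # coordinate stream: second half of the heads
        x_tilde = attn[..., half:].mean(axis=-1)              # (B,NL,NP)
        w = self.out_x(x_tilde.reshape(B, NL, NP, 1))
        x_out = x_L + (w.broadcast_to(rel.shape) * rel).sum(axis=2) * (1.0 / NP)
        return h_out, x_out


class Denoiser:
    """The full denoising network Φ: stacked equivariant blocks plus the
    output heads, with one learnable continuous embedding per interaction
    type (shared across residues and blocks)."""

    def __init__(self, config: DenoiserConfig, vocab: AtomVocabulary,
                 protein_feature_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        self.protein_feature_dim = protein_feature_dim
        H = config.hidden
        self.v_continuous = Tensor.param(
            rng.normal(0.0, 0.5, size=(len(INTERACTION_TYPES), H)))
        # +1 input column: the normalized time step t/T
        self.embed_L = Linear(vocab.K + 1, H, rng)
        self.embed_P = Linear(protein_feature_dim + len(INTERACTION_TYPES) + 1,
                              H, rng)
        self.blocks = [_Block(config, rng) for _ in range(config.n_blocks)]
        self.head_h = MLP(H, H, vocab.K, rng)
        self.head_cls = MLP(H, H, N_INTERACTION_CLASSES, rng)

    # -- parameters -----------------------------------------------------------
    def params(self) -> list[Tensor]:
        out = [self.v_continuous]
        out += self.embed_L.params() + self.embed_P.params()
        for b in self.blocks:
            out += b.params()
        out += self.head_h.params() + self.head_cls.params()
        return out

    def named_params(self) -> dict[str, Tensor]:
        return {f"p{i:04d}": p for i, p in enumerate(self.params())}

    # -- forward --------------------------------------------------------------
    def forward(self, x_L: np.ndarray, h_L: np.ndarray, x_P: np.ndarray,
                h_P_raw: np.ndarray, v_discrete: np.ndarray, t: int,
                T: int) -> DenoiserOutput:
        """Batched forward pass.

        x_L: (B, N_L, 3); h_L: (B, N_L, K) one-hot (or distributions);
        x_P: (B, N_P, 3); h_P_raw: (B, N_P, F); v_discrete: (B, N_P, 4);
        t: current step (same for the whole batch); T: schedule length.
        """
        cfg = self.config
        if not (1 <= t <= T):
            raise ValueError(f"step index t={t} outside 1..{T}")
        x_L = np.asarray(x_L, dtype=np.float64)
        B, n_L, _ = x_L.shape
        n_P = x_P.shape[-2]
        x_P = np.broadcast_to(np.asarray(x_P, dtype=np.float64), (B, n_P, 3))
        h_P_raw = np.broadcast_to(np.asarray(h_P_raw, dtype=np.float64),
                                  (B, n_P, h_P_raw.shape[-1]))
        v_discrete = np.broadcast_to(np.asarray(v_discrete, dtype=np.float64),
                                     (B, n_P, len(INTERACTION_TYPES)))
        tt = np.full((B, 1, 1), t / T)
        h0_L = Tensor(np.concatenate(
            [h_L, np.broadcast_to(tt, (B, n_L, 1))], axis=-1)) @ \
            self.embed_L.W + self.embed_L.b
        h0_P = Tensor(np.concatenate(
            [h_P_raw, v_discrete, np.broadcast_to(tt, (B, n_P, 1))], axis=-1)) @ \
            self.embed_P.W + self.embed_P.b

        h = concat([h0_L, h0_P], axis=1)
        x = Tensor(np.concatenate([x_L, x_P], axis=1))
        # per-atom continuous prompts: one-hot codes select the embeddings,
        # so unprompted residues contribute exactly zero
        v_c_atoms = Tensor(v_discrete) @ self.v_continuous   # (B,NP,H)

        adj = self._adjacency(np.concatenate([x_L, x_P], axis=1))
        for block in self.blocks:
            h = block.feature_update(h, x, adj, v_c_atoms, n_L)
            x = block.coordinate_update(h, x, adj, n_L)
            if cfg.cross_attention_enabled and n_L > 0 and n_P > 0:
                h_Lb, x_Lb = block.cross_attention(
                    h[:, :n_L], x[:, :n_L], h[:, n_L:], x[:, n_L:], v_c_atoms)
                h = concat([h_Lb, h[:, n_L:]], axis=1)
                x = concat([x_Lb, x[:, n_L:]], axis=1)
            if cfg.rebuild_edges:
                adj = self._adjacency(x.data)

        x0_hat = x if cfg.joint else x[:, :n_L]
        logits_h = self.head_h(h[:, :n_L])
        h0_hat = masked_softmax(logits_h, np.ones(logits_h.shape, bool), axis=-1)
        protein_logits = self.head_cls(h[:, n_L:])
        return DenoiserOutput(x0_hat=x0_hat, h0_hat=h0_hat,
                              protein_logits=protein_logits)

    def _adjacency(self, coords: np.ndarray) -> np.ndarray:
        diff = coords[:, :, None, :] - coords[:, None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        adj = d < self.config.cutoff
        idx = np.arange(coords.shape[1])
        adj[:, idx, idx] = False
        return adj

    def denoise(self, graph_t: ComplexGraph, t: int,
                prompts: InteractionPromptSet | None, T: int):
        """Single-complex convenience wrapper; returns numpy arrays
        (x0_hat, h0_hat, protein_logits)."""
        prompts = prompts if prompts is not None else InteractionPromptSet(())
        prompts.validate_against(graph_t)
        v_d = prompts.v_discrete(graph_t)[None]
        out = self.forward(graph_t.x_L[None], graph_t.h_L(self.vocab)[None],
                           graph_t.x_P[None], graph_t.h_P()[None], v_d, t, T)
        return (out.x0_hat.data[0], out.h0_hat.data[0],
                out.protein_logits.data[0])

    # -- checkpointing --------------------------------------------------------
    def save(self, path, schedule_config: dict | None = None):
        meta = {
            "format_version": 1,
            "config": asdict(self.config),
            "vocab": list(self.vocab.symbols),
            "protein_feature_dim": self.protein_feature_dim,
            "schedule": schedule_config,
        }
        arrays = {k: p.data for k, p in self.named_params().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Denoiser":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = DenoiserConfig(**meta["config"])
            net = cls(cfg, AtomVocabulary(tuple(meta["vocab"])),
                      meta["protein_feature_dim"])
            for k, p in net.named_params().items():
                p.data = z[k].copy()
        return net
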