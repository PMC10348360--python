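"""The SMG-BERT encoder network.

Pipeline per molecule batch:

1. **Input embedding** — two independent embedding tables (atom tokens, NMR
   tokens), each ``d_model/2`` wide, concatenated per position:
   ``z = E_A(S_A') || E_N(S_N')``.  There are no positional encodings: token
   order inside a molecule is arbitrary, so the whole network is permutation
   equivariant over atoms (and permutation *invariant* at the global node).
2. **Distance encoder** — the raw distance matrix ``Draw`` is transformed by
   one standard transformer encoder layer into the distance fraction matrix
   ``D``.  Each entry ``d_ij`` is featurized with radial basis functions
   (channel 0 carries the raw distance); each column's features are mean-pooled
   into a token summary, contextualized by the transformer layer, and a
   pairwise readout reassembles a square score matrix.  This keeps ``D``
   exactly permutation equivariant, and a readout that selects the raw-distance
   channel reproduces ``Draw`` identically.
3. **Modified attention**, per head and per layer::

       A   = softmax(Q K^T / sqrt(d_k))      (over valid positions)
       A2d = A ⊙ M + λ · Bnorm
       A3d = A2d + D
       out = A3d · V

   followed by the usual residual + layer-norm and position-wise FFN
   (pre-norm placement by default; post-norm via ``pre_norm=False``).
   ``A3d`` is intentionally *not* re-normalized to rows summing to one: the
   element-wise mask and the additive 2D/3D biases produce raw scores, with
   zeros wherever the mask removes a pair.
4. After ``n_layers`` such layers, position 0 of the output — the global node
   ``<G>`` — is the molecule-level representation.

Checkpoints are a single ``.npz`` archive of parameter arrays plus a JSON
header (format version, config, vocabulary sizes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, concat
from .chemfeat import AtomVocab, NmrVocab, PairChannels
from .nn import Dropout, Embedding, LayerNorm, Linear, Module

__all__ = [
    "EncoderConfig",
    "EncoderState",
    "DistanceEncoder",
    "EncoderLayer",
    "SMGBertEncoder",
    "Batch",
    "collate",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = 1
_NEG_INF = -1e9


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture constants.  ``d_model=512`` over six layers are the
    full-scale defaults; tests shrink ``d_model`` for speed."""

    n_layers: int = 6
    d_model: int = 512
    n_heads: int = 8
    lambda_b: float = 0.2        # balance weight on the bond-energy bias
    dropout: float = 0.1
    max_atoms: int = 32          # padding bound (heavy atoms, excl. global node)
    ffn_dim: Optional[int] = None  # defaults to 4 * d_model
    n_rbf: int = 16              # distance featurization channels
    rbf_max: float = 8.0         # Å; RBF centers span [0, rbf_max]
    pre_norm: bool = True        # pre-norm residual placement (trains reliably
                                 # at small step budgets; post-norm available)
    seed: int = 0

    def __post_init__(self):
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even (atom/NMR halves)")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.lambda_b < 0:
            raise ValueError("lambda_b must be >= 0")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @property
    def ffn_width(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.d_model

    @property
    def max_len(self) -> int:
        return self.max_atoms + 1


@dataclass
class Batch:
    """Padded batch of featurized molecules (L = longest token count)."""

    atom_ids: np.ndarray    # (B, L) possibly corrupted
    nmr_ids: np.ndarray     # (B, L)
    M: np.ndarray           # (B, L, L)
    Bnorm: np.ndarray       # (B, L, L)
    Draw: np.ndarray        # (B, L, L)
    pad_mask: np.ndarray    # (B, L) 1 = valid

    @property
    def n_mols(self) -> int:
        return self.atom_ids.shape[0]

    @property
    def length(self) -> int:
        return self.atom_ids.shape[1]


def collate(items: Sequence[Tuple[np.ndarray, np.ndarray, PairChannels]],
            pad_atom: int, pad_nmr: int, length: Optional[int] = None) -> Batch:
    """Pad (atom_ids, nmr_ids, channels) triples to a common length."""
    L = length or max(len(a) for a, _, _ in items)
    B = len(items)
    atom = np.full((B, L), pad_atom, dtype=np.int64)
    nmr = np.full((B, L), pad_nmr, dtype=np.int64)
    M = np.zeros((B, L, L))
    Bn = np.zeros((B, L, L))
    Dr = np.zeros((B, L, L))
    pm = np.zeros((B, L))
    for b, (a, nm, ch) in enumerate(items):
        k = len(a)
        if k > L:
            raise ValueError(f"molecule with {k} tokens exceeds padding bound {L}")
        atom[b, :k] = a
        nmr[b, :k] = nm
        M[b, :k, :k] = ch.M
        Bn[b, :k, :k] = ch.Bnorm
        Dr[b, :k, :k] = ch.Draw
        pm[b, :k] = 1.0
    return Batch(atom_ids=atom, nmr_ids=nmr, M=M, Bnorm=Bn, Draw=Dr, pad_mask=pm)


@dataclass
class EncoderState:
    """Forward-pass record: inputs, outputs and every layer's A3d."""

    z0: Tensor                       # (B, L, d_model)
    r: Tensor                        # (B, L, d_model)
    attn: List[np.ndarray]           # per layer: (B, H, L, L), detached
    D: Tensor                        # (B, L, L) distance fraction matrix
    batch: Batch


class DistanceEncoder(Module):
    """``D = Trans(Draw)``: one transformer encoder layer over distance-profile
    summaries, with an RBF pairwise readout.  Permutation equivariant; padded
    rows/columns of ``D`` are exactly zero."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.centers = np.linspace(0.0, cfg.rbf_max, cfg.n_rbf - 1)
        self.width = cfg.rbf_max / max(cfg.n_rbf - 1, 1)
        self.in_proj = Linear(cfg.n_rbf, d, rng)
        self.layer = EncoderLayer(cfg, rng, biased=False)
        self.w_pair = Linear(cfg.n_rbf, 1, rng, bias=False)
        self.w_row = Linear(d, 1, rng, bias=False)
        self.w_col = Linear(d, 1, rng, bias=False)
        # start the additive 3D bias near zero: raw distances are O(1-10) and a
        # full-scale D at init swamps the softmax term (row sums ~1), collapsing
        # token representations; training grows D from an unbiased start
        self.w_pair.weight.data *= 0.01
        self.w_row.weight.data *= 0.01
        self.w_col.weight.data *= 0.01

    def rbf(self, Draw: np.ndarray) -> np.ndarray:
        """(B, L, L) -> (B, L, L, n_rbf); channel 0 is the raw distance."""
        gauss = np.exp(-((Draw[..., None] - self.centers) ** 2) / (2 * self.width ** 2))
        return np.concatenate([Draw[..., None], gauss], axis=-1)

    def identity_readout(self) -> None:
        """Set the readout so D equals Draw exactly (raw-distance channel)."""
        self.w_pair.weight.data[:] = 0.0
        self.w_pair.weight.data[0, 0] = 1.0
        self.w_row.weight.data[:] = 0.0
        self.w_col.weight.data[:] = 0.0

    def forward(self, Draw: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        if pad_mask.sum() == 0:
            raise ValueError("all-padding input to the distance encoder")
        B, L, _ = Draw.shape
        feats = self.rbf(Draw)                                  # (B,L,L,K)
        pm = pad_mask[:, :, None, None]                         # mask rows i
        pooled = (feats * pm).sum(axis=1) / np.maximum(pad_mask.sum(1), 1.0)[:, None, None]
        h = self.in_proj(Tensor(pooled))                        # (B,L,d)
        h = self.layer(h, pad_mask=pad_mask)                    # contextualize columns
        pair = self.w_pair(Tensor(feats)).reshape(B, L, L)      # (B,L,L)
        row = self.w_row(h).reshape(B, L, 1)
        col = self.w_col(h).reshape(B, 1, L)
        D = pair + row + col
        valid = pad_mask[:, :, None] * pad_mask[:, None, :]
        return D * Tensor(valid)


class EncoderLayer(Module):
    """One post-norm transformer encoder layer with the modified attention.

    With ``biased=False`` (used inside the distance encoder) the 2D/3D terms
    are dropped and this is a plain transformer encoder layer.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator, biased: bool = True):
        super().__init__()
        self.cfg = cfg
        self.biased = biased
        d = cfg.d_model
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ffn1 = Linear(d, cfg.ffn_width, rng)
        self.ffn2 = Linear(cfg.ffn_width, d, rng)
        self.drop_attn = Dropout(cfg.dropout, rng)
        self.drop_ffn = Dropout(cfg.dropout, rng)
        self.last_attn: Optional[np.ndarray] = None  # (B, H, L, L) A3d, detached

    def _split_heads(self, x: Tensor, B: int, L: int) -> Tensor:
        H, dk = self.cfg.n_heads, self.cfg.d_k
        return x.reshape(B, L, H, dk).swapaxes(1, 2)   # (B,H,L,dk)

    def forward(self, z: Tensor, pad_mask: np.ndarray,
                M: Optional[np.ndarray] = None,
                Bnorm: Optional[np.ndarray] = None,
                D: Optional[Tensor] = None) -> Tensor:
        B, L, d = z.shape
        H, dk = self.cfg.n_heads, self.cfg.d_k
        zin = self.ln1(z) if self.cfg.pre_norm else z
        q = self._split_heads(self.wq(zin), B, L)
        k = self._split_heads(self.wk(zin), B, L)
        v = self._split_heads(self.wv(zin), B, L)

        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))   # (B,H,L,L)
        # softmax over valid key positions only
        key_mask = (1.0 - pad_mask)[:, None, None, :] * _NEG_INF
        A = (scores + Tensor(key_mask)).softmax(axis=-1)

        if self.biased:
            A2d = A * Tensor(M[:, None]) + self.cfg.lambda_b * Tensor(Bnorm[:, None])
            A3d = A2d + D.reshape(B, 1, L, L)
        else:
            A3d = A
        # zero padded query rows so nothing propagates from padding
        A3d = A3d * Tensor(pad_mask[:, None, :, None])
        if not np.isfinite(A3d.data).all():
            raise FloatingPointError("non-finite attention scores")
        self.last_attn = A3d.data.copy()

        out = A3d @ v                                            # (B,H,L,dk)
        out = out.swapaxes(1, 2).reshape(B, L, d)
        if self.cfg.pre_norm:
            z = z + self.drop_attn(self.wo(out))
            h = self.ln2(z)
            z = z + self.ffn2(self.drop_ffn(self.ffn1(h).relu()))
        else:
            z = self.ln1(z + self.drop_attn(self.wo(out)))
            ffn = self.ffn2(self.drop_ffn(self.ffn1(z).relu()))
            z = self.ln2(z + ffn)
        if not np.isfinite(z.data).all():
            raise FloatingPointError("non-finite activations in encoder layer")
        return z


class SMGBertEncoder(Module):
    """Embeddings + distance encoder + ``n_layers`` modified-attention layers."""

    def __init__(self, cfg: EncoderConfig,
                 atom_vocab: Optional[AtomVocab] = None,
                 nmr_vocab: Optional[NmrVocab] = None):
        super().__init__()
        self.cfg = cfg
        self.atom_vocab = atom_vocab or AtomVocab()
        self.nmr_vocab = nmr_vocab or NmrVocab()
        rng = np.random.default_rng(cfg.seed)
        half = cfg.d_model // 2
        self.atom_emb = Embedding(len(self.atom_vocab), half, rng)
        self.nmr_emb = Embedding(len(self.nmr_vocab), half, rng)
        self.dist_enc = DistanceEncoder(cfg, rng)
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]
        self.ln_final = LayerNorm(cfg.d_model) if cfg.pre_norm else None

    # ------------------------------------------------------------ sub-steps
    def embed_inputs(self, atom_ids: np.ndarray, nmr_ids: np.ndarray) -> Tensor:
        """``z0``: atom embedding || NMR embedding, width d_model."""
        return concat([self.atom_emb(atom_ids), self.nmr_emb(nmr_ids)], axis=-1)

    def distance_fractions(self, Draw: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        return self.dist_enc(Draw, pad_mask)

    # -------------------------------------------------------------- forward
    def forward(self, batch: Batch, no_3d: bool = False) -> EncoderState:
        """Full encode.  ``no_3d`` zeroes the distance fraction matrix (the
        3D-ablation switch); the distance encoder is skipped entirely."""
        z0 = self.embed_inputs(batch.atom_ids, batch.nmr_ids)
        if no_3d:
            D = Tensor(np.zeros_like(batch.Draw))
        else:
            D = self.distance_fractions(batch.Draw, batch.pad_mask)
        z = z0
        attn = []
        for layer in self.layers:
            z = layer(z, pad_mask=batch.pad_mask, M=batch.M, Bnorm=batch.Bnorm, D=D)
            attn.append(layer.last_attn)
        if self.ln_final is not None:
            z = self.ln_final(z)
        return EncoderState(z0=z0, r=z, attn=attn, D=D, batch=batch)

    def encode(self, batch: Batch, **kw) -> EncoderState:
        return self.forward(batch, **kw)


# ----------------------------------------------------------------- checkpoints

def save_checkpoint(path, model: Module, cfg: EncoderConfig,
                    extra_header: Optional[dict] = None) -> None:
    """Single-archive checkpoint: parameter tensors keyed by name plus a JSON
    header carrying the format version and the encoder config."""
    header = {
        "format_version": CHECKPOINT_VERSION,
        "config": asdict(cfg),
        **(extra_header or {}),
    }
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Tuple[dict, Dict[str, np.ndarray]]:
    """Returns (header, state_dict)."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        if header.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {header.get('format_version')}")
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    return header, state
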