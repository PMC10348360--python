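"""Attention-based interpretability.

The modified attention matrix ``A3d`` recorded at each layer is the model's
pairwise atom-relevance map.  This module extracts those maps for a molecule,
computes atom-atom similarity of attention profiles (cosine between the atoms'
attention-score row vectors; a Euclidean option is provided), and exports
matrices as CSV plus rendered heatmaps.

Default view: last layer, head mean — the deepest, most task-shaped scores.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .autodiff import no_grad
from .encoder import collate
from .train import PretrainModel, featurize

logger = logging.getLogger("smgbert")

__all__ = ["AttentionMap", "attention_map", "atom_similarity", "export_heatmap"]


@dataclass
class AttentionMap:
    """Attention scores for one molecule at one layer."""

    smiles: str
    layer: int
    head: Optional[int]            # None = head mean
    matrix: np.ndarray             # (n+1, n+1) incl. global node at index 0
    atom_labels: List[str]         # canonical atom order, e.g. ["C1", "C2", "O3"]
    channels_used: str             # e.g. "1d+2d+3d+chem"

    @property
    def atom_matrix(self) -> np.ndarray:
        """Atom-only submatrix (global node removed) for plotting."""
        return self.matrix[1:, 1:]


def attention_map(model: PretrainModel, smiles: str, layer: int = -1,
                  reduce: str = "mean", head: Optional[int] = None,
                  seed: int = 0, no_3d: bool = False,
                  no_chem: bool = False) -> AttentionMap:
    """Run one molecule through the encoder and return the recorded ``A3d``.

    ``reduce="mean"`` averages heads; ``reduce="per_head"`` requires ``head``.
    """
    n_layers = len(model.encoder.layers)
    if not (-n_layers <= layer < n_layers):
        raise IndexError(f"layer {layer} out of range for {n_layers} layers")
    md = featurize([smiles], model.feat_cfg, model.atom_vocab, model.nmr_vocab,
                   seed=seed, no_chem=no_chem)
    if not md:
        raise ValueError(f"could not featurize {smiles!r}")
    item = md[0]
    batch = collate([(item.tokens.atom_tokens, item.tokens.nmr_tokens, item.channels)],
                    model.atom_vocab.pad, model.nmr_vocab.pad)
    model.eval()
    with no_grad():
        state = model.encoder(batch, no_3d=no_3d)
    A = state.attn[layer][0]                   # (H, L, L)
    if reduce == "mean":
        mat, head_used = A.mean(axis=0), None
    elif reduce == "per_head":
        if head is None or not (0 <= head < A.shape[0]):
            raise ValueError("reduce='per_head' requires a valid head index")
        mat, head_used = A[head], head
    else:
        raise ValueError(f"unknown reduce {reduce!r}")
    labels = [f"{elem}{i+1}" for i, (elem, _, _) in enumerate(item.molecule.atoms)]
    channels = "1d+2d" + ("" if no_3d else "+3d") + ("" if no_chem else "+chem")
    return AttentionMap(smiles=item.molecule.smiles,
                        layer=layer % n_layers, head=head_used,
                        matrix=mat.copy(), atom_labels=labels,
                        channels_used=channels)


def atom_similarity(amap: AttentionMap, metric: str = "cosine") -> np.ndarray:
    """Pairwise similarity between atoms' attention-score row vectors.

    Cosine (default): symmetric with unit diagonal, invariant to uniform
    scaling of the attention matrix; zero-norm rows get similarity 0.
    ``metric="euclidean"`` returns negative distances instead.
    """
    rows = amap.atom_matrix
    n = rows.shape[0]
    if metric == "euclidean":
        return -np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=-1)
    if metric != "cosine":
        raise ValueError(f"unknown metric {metric!r}")
    norms = np.linalg.norm(rows, axis=1)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if norms[i] < 1e-12 or norms[j] < 1e-12:
                if i == j:
                    sim[i, j] = 1.0
                continue
            sim[i, j] = float(rows[i] @ rows[j] / (norms[i] * norms[j]))
    if (norms < 1e-12).any():
        logger.warning("%d zero-norm attention row(s); similarity set to 0",
                       int((norms < 1e-12).sum()))
    np.fill_diagonal(sim, 1.0)
    return sim


def export_heatmap(amap: AttentionMap, path_prefix: str) -> List[str]:
    """Write ``<prefix>.csv`` (matrix, header = canonical atom labels) and
    ``<prefix>.png`` (rendered heatmap).  Returns the written paths."""
    csv_path = f"{path_prefix}.csv"
    png_path = f"{path_prefix}.png"
    mat = amap.atom_matrix
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(amap.atom_labels)
        for row in mat:
            writer.writerow([repr(float(v)) for v in row])
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, cmap="Greens")
    ax.set_xticks(range(len(amap.atom_labels)))
    ax.set_yticks(range(len(amap.atom_labels)))
    ax.set_xticklabels(amap.atom_labels, rotation=90, fontsize=7)
    ax.set_yticklabels(amap.atom_labels, fontsize=7)
    ax.set_title(f"{amap.smiles}\nlayer {amap.layer}, "
                 f"{'head ' + str(amap.head) if amap.head is not None else 'head mean'}, "
                 f"{amap.channels_used}")
    fig.colorbar(im, ax=ax, label="attention score")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return [csv_path, png_path]


def load_matrix_csv(path) -> np.ndarray:
    """Re-load a matrix written by :func:`export_heatmap` (bit-exact)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        return np.array([[float(v) for v in row] for row in reader])
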