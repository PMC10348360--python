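"""Self-supervised pre-training objectives.

Four losses over the encoder output ``r``:

* ``L_A`` / ``L_N`` — masked atom / NMR token reconstruction: a two-layer MLP
  head on each corrupted position, mean cross-entropy against the original
  token (all corrupted positions count, including "keep" positions, unless
  configured otherwise).
* ``L_B`` — bond-energy regression: a two-layer head on the concatenated
  endpoint representations, symmetrized over the two orderings, mean squared
  error against the *normalized* bond energies over bonded pairs only.
* ``L_3D`` — 3D reconstruction: ``r' = W_r r`` maps each atom representation
  to a 3-vector of virtual coordinates; predicted distances, bond angles and
  torsions are computed by the same geometry kernels that build the ground
  truth, and compared per quantity family by mean squared error (Å², rad²,
  rad², summed).

The total is uncertainty-weighted with learnable per-task scales::

    L = L_A/σ₁² + L_N/σ₂² + L_B/σ₃² + L_3D/σ₄² + log σ₁σ₂σ₃σ₄

σ are parameterized as log σ (positivity) and optimized jointly with the
network; the analytic stationary point for fixed component losses is
σ_k² = 2·L_k.

Losses are means within each family by default, so the total is invariant to
batch and molecule size; the raw-sum reading of the printed formulas is
available with ``mean_losses=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Parameter, Tensor, concat
from .chemfeat import GeometryTargets, bond_angles, pair_distances, torsions
from .corruption import CorruptionPlan
from .nn import MLP, Linear, Module

logger = logging.getLogger("smgbert")

__all__ = [
    "LossBreakdown",
    "PretrainHeads",
    "cross_entropy",
    "token_recon_loss",
    "bond_energy_loss",
    "project_coords",
    "geom_predictions",
    "l3d",
    "total_loss",
]


@dataclass
class LossBreakdown:
    """Scalar record of one loss evaluation (detached)."""

    L_A: float
    L_N: float
    L_B: float
    L_3D: float
    L_total: float
    sigmas: np.ndarray  # (4,) current σ values

    def as_dict(self) -> Dict[str, float]:
        d = {"L_A": self.L_A, "L_N": self.L_N, "L_B": self.L_B,
             "L_3D": self.L_3D, "L_total": self.L_total}
        d.update({f"sigma{k+1}": float(s) for k, s in enumerate(self.sigmas)})
        return d


class PretrainHeads(Module):
    """Prediction heads + learnable log σ for the four SSL tasks."""

    def __init__(self, d_model: int, n_atom_vocab: int, n_nmr_vocab: int,
                 rng: np.random.Generator, hidden: Optional[int] = None):
        super().__init__()
        h = hidden or d_model
        self.atom_head = MLP(d_model, h, n_atom_vocab, rng)
        self.nmr_head = MLP(d_model, h, n_nmr_vocab, rng)
        self.bond_head = MLP(2 * d_model, h, 1, rng)
        self.coord_proj = Linear(d_model, 3, rng, bias=False)   # W_r
        self.log_sigmas = Parameter(np.zeros(4))                # σ = 1 at init


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy; labels are integer class ids."""
    lse = logits.logsumexp(axis=-1)
    picked = logits[np.arange(len(labels)), np.asarray(labels, dtype=np.intp)]
    return (lse - picked).mean()


def token_recon_loss(r: Tensor, head: Module,
                     plans: Sequence[Tuple[int, CorruptionPlan]],
                     include_keep: bool = True) -> Tuple[Tensor, int]:
    """Reconstruction loss for one sequence family (atom or NMR).

    ``plans`` pairs each molecule's batch row with its corruption plan; the
    loss is the mean cross-entropy over the m corrupted positions.  Returns
    ``(loss, m)``; m = 0 yields a constant zero with a warning.
    """
    rows, cols, labels = [], [], []
    for b, plan in plans:
        for pos, act, orig in zip(plan.selected, plan.actions, plan.originals):
            if not include_keep and act == "keep":
                continue
            rows.append(b)
            cols.append(pos)
            labels.append(orig)
    m = len(rows)
    if m == 0:
        logger.warning("no corrupted positions in batch; reconstruction loss = 0")
        return Tensor(0.0), 0
    sel = r[np.array(rows, dtype=np.intp), np.array(cols, dtype=np.intp)]  # (m, d)
    logits = head(sel)
    return cross_entropy(logits, np.array(labels)), m


def bond_energy_loss(r: Tensor, head: Module,
                     bonds: Sequence[Tuple[int, np.ndarray]],
                     targets: Sequence[np.ndarray],
                     mean: bool = True) -> Tuple[Tensor, int]:
    """MSE of predicted vs normalized bond energies over bonded pairs.

    ``bonds[k] = (batch_row, (n_bonds, 2) atom-index array)`` and
    ``targets[k]`` the matching normalized energies.  Each unordered pair is
    counted once, with the prediction symmetrized over both orderings.
    Returns ``(loss, n_pairs)``; molecules without bonds contribute nothing.
    """
    rows_i, rows_j, brow, tvals = [], [], [], []
    for (b, pairs), tg in zip(bonds, targets):
        for (i, j), y in zip(pairs, tg):
            brow.append(b)
            rows_i.append(i + 1)   # +1: token position after the global node
            rows_j.append(j + 1)
            tvals.append(y)
    n_pairs = len(tvals)
    if n_pairs == 0:
        logger.warning("no bonded pairs in batch; bond-energy loss = 0")
        return Tensor(0.0), 0
    b_idx = np.array(brow, dtype=np.intp)
    i_idx = np.array(rows_i, dtype=np.intp)
    j_idx = np.array(rows_j, dtype=np.intp)
    ri = r[b_idx, i_idx]
    rj = r[b_idx, j_idx]
    q = 0.5 * (head(concat([ri, rj], axis=-1)) + head(concat([rj, ri], axis=-1)))
    err = (q.reshape(n_pairs) - Tensor(np.array(tvals))) ** 2
    return (err.mean() if mean else err.sum()), n_pairs


def project_coords(r: Tensor, coord_proj: Linear, n_atoms: int, batch_row: int = 0) -> Tensor:
    """``r' = W_r r`` for one molecule: (n_atoms, 3) virtual coordinates,
    global node excluded."""
    return coord_proj(r[batch_row, 1:n_atoms + 1])


def geom_predictions(r_prime: Tensor, targets: GeometryTargets,
                     signed_torsions: bool = False):
    """Predicted (d̂, θ̂, φ̂) from virtual coordinates, using the identical
    kernels that produced the ground truth.  Torsion quads whose *predicted*
    plane normals degenerate are dropped (returned mask says which survive)."""
    d_hat = pair_distances(r_prime, targets.dist_pairs) if len(targets.dist_pairs) else None
    th_hat = bond_angles(r_prime, targets.angle_triples) if len(targets.angle_triples) else None
    keep = np.arange(len(targets.torsion_quads))
    ph_hat = None
    if len(targets.torsion_quads):
        c = r_prime.data
        q = targets.torsion_quads
        na = np.cross(c[q[:, 1]] - c[q[:, 0]], c[q[:, 2]] - c[q[:, 1]])
        nb = np.cross(c[q[:, 2]] - c[q[:, 1]], c[q[:, 3]] - c[q[:, 2]])
        keep = np.where((np.linalg.norm(na, axis=1) > 1e-8)
                        & (np.linalg.norm(nb, axis=1) > 1e-8))[0]
        n_dropped = len(q) - len(keep)
        if n_dropped:
            logger.info("%d degenerate predicted torsion(s) skipped", n_dropped)
        if len(keep):
            ph_hat = torsions(r_prime, q[keep], signed=signed_torsions)
    return d_hat, th_hat, ph_hat, keep


def l3d(preds, targets: GeometryTargets) -> Tuple[Tensor, Tensor, Tensor]:
    """Squared-error sums for (distances, angles, torsions) of one molecule.

    Returned as per-family (sse, count) so a batch can pool before taking the
    family means; families absent from small molecules contribute zero.
    """
    d_hat, th_hat, ph_hat, keep = preds
    zero = Tensor(0.0)
    sse_d = ((d_hat - Tensor(targets.dist_values)) ** 2).sum() if d_hat is not None else zero
    sse_t = ((th_hat - Tensor(targets.angle_values)) ** 2).sum() if th_hat is not None else zero
    sse_p = ((ph_hat - Tensor(targets.torsion_values[keep])) ** 2).sum() if ph_hat is not None else zero
    counts = (len(targets.dist_values),
              len(targets.angle_values),
              len(keep) if ph_hat is not None else 0)
    return (sse_d, sse_t, sse_p), counts


def l3d_batch(r: Tensor, coord_proj: Linear,
              geo: Sequence[Tuple[int, int, GeometryTargets]],
              mean: bool = True, signed_torsions: bool = False) -> Tensor:
    """Pooled L_3D over a batch: ``geo`` holds (batch_row, n_atoms, targets)."""
    sums = [Tensor(0.0), Tensor(0.0), Tensor(0.0)]
    counts = [0, 0, 0]
    for b, n_atoms, tg in geo:
        rp = project_coords(r, coord_proj, n_atoms, batch_row=b)
        preds = geom_predictions(rp, tg, signed_torsions=signed_torsions)
        (sd, st, sp), (cd, ct, cp) = l3d(preds, tg)
        sums = [sums[0] + sd, sums[1] + st, sums[2] + sp]
        counts = [counts[0] + cd, counts[1] + ct, counts[2] + cp]
    total = Tensor(0.0)
    for s, c in zip(sums, counts):
        if c > 0:
            total = total + (s * (1.0 / c) if mean else s)
    return total


def total_loss(L_A: Tensor, L_N: Tensor, L_B: Tensor, L_3D: Tensor,
               log_sigmas: Parameter) -> Tensor:
    """Uncertainty-weighted total: Σ L_k·exp(−2 log σ_k) + Σ log σ_k."""
    inv_var = (log_sigmas * (-2.0)).exp()
    weighted = (L_A * inv_var[0] + L_N * inv_var[1]
                + L_B * inv_var[2] + L_3D * inv_var[3])
    return weighted + log_sigmas.sum()


def compute_pretrain_loss(r: Tensor, heads: PretrainHeads, *,
                          atom_plans: Sequence[Tuple[int, CorruptionPlan]],
                          nmr_plans: Sequence[Tuple[int, CorruptionPlan]],
                          bonds: Sequence[Tuple[int, np.ndarray]],
                          bond_targets: Sequence[np.ndarray],
                          geo: Sequence[Tuple[int, int, GeometryTargets]],
                          include_keep: bool = True,
                          mean_losses: bool = True,
                          signed_torsions: bool = False) -> Tuple[Tensor, LossBreakdown]:
    """One full SSL loss evaluation over an encoded batch."""
    L_A, _ = token_recon_loss(r, heads.atom_head, atom_plans, include_keep)
    L_N, _ = token_recon_loss(r, heads.nmr_head, nmr_plans, include_keep)
    L_B, _ = bond_energy_loss(r, heads.bond_head, bonds, bond_targets, mean=mean_losses)
    L_3D = l3d_batch(r, heads.coord_proj, geo, mean=mean_losses,
                     signed_torsions=signed_torsions)
    L = total_loss(L_A, L_N, L_B, L_3D, heads.log_sigmas)
    if not np.isfinite(L.data):
        raise FloatingPointError("non-finite total pre-training loss")
    bd = LossBreakdown(
        L_A=float(L_A.data), L_N=float(L_N.data), L_B=float(L_B.data),
        L_3D=float(L_3D.data), L_total=float(L.data),
        sigmas=np.exp(heads.log_sigmas.data.copy()),
    )
    return L, bd
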