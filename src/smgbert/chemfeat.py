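"""Per-molecule feature channels.

From a parsed :class:`~smgbert.molio.Molecule` this module builds everything
the encoder consumes:

* the aligned atom/NMR token pair with the prepended global node ``<G>``,
* the bond-energy matrix ``B`` (kJ/mol) and its min-max normalization
  ``Bnorm`` over bonded entries,
* the binary adjacency/mask matrix ``M`` (diagonal and global row/column set
  to 1 so every token may attend to itself and to/from the molecule node),
* the raw interatomic distance matrix ``Draw`` (Å),
* ground-truth 3D geometry targets: all-pair distances, bond angles over
  bonded paths i–j–k, and unsigned torsions over bonded paths i–j–k–l.

NMR shifts and bond energies come from deterministic environment-keyed
surrogate lookup tables packaged with the module; per-molecule CSV overrides
can inject externally predicted values through the same interface.

The geometry kernels at the bottom operate on the autodiff :class:`Tensor`
API, so the self-supervised 3D reconstruction loss reuses the *same code*
that builds the ground-truth targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import Tensor, stack
from .molio import GeometryError, Molecule

logger = logging.getLogger("smgbert")

__all__ = [
    "AtomVocab",
    "NmrVocab",
    "FeaturizeConfig",
    "TokenPair",
    "PairChannels",
    "GeometryTargets",
    "tokenize",
    "surrogate_nmr",
    "discretize_nmr",
    "surrogate_bde",
    "normalize_b",
    "binarize",
    "distance_matrix",
    "geometry_targets",
    "build_token_pair",
    "build_channels",
    "environment_key",
    "load_nmr_table",
    "load_bde_table",
    "pair_distances",
    "bond_angles",
    "torsions",
]

PAD, GLOBAL, MASK, UNK = "<PAD>", "<G>", "<M>", "<UNK>"
_SPECIALS = [PAD, GLOBAL, MASK, UNK]

#: Elements with first-class atom tokens; anything else maps to <UNK>.
ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si"]


@dataclass(frozen=True)
class FeaturizeConfig:
    """Featurization knobs shared by tokenization and channel construction."""

    use_chiral_tokens: bool = True      # stereocenters get element@ / element@@ tokens
    signed_torsions: bool = False       # unsigned (arccos of plane normals) by default
    nmr_bin_width: float = 1.0          # ppm per NMR token bin
    nmr_range: Tuple[float, float] = (-50.0, 300.0)


class _Vocab:
    """Bidirectional token <-> id map; ids are stable (insertion order)."""

    def __init__(self, tokens: Sequence[str]):
        self.id_of: Dict[str, int] = {t: i for i, t in enumerate(tokens)}
        self.token_of: Dict[int, str] = {i: t for t, i in self.id_of.items()}

    def __len__(self) -> int:
        return len(self.id_of)

    def __contains__(self, tok: str) -> bool:
        return tok in self.id_of

    def __getitem__(self, tok: str) -> int:
        return self.id_of[tok]

    @property
    def pad(self) -> int:
        return self.id_of[PAD]

    @property
    def g(self) -> int:
        return self.id_of[GLOBAL]

    @property
    def mask(self) -> int:
        return self.id_of[MASK]

    @property
    def unk(self) -> int:
        return self.id_of[UNK]

    def special_ids(self) -> set:
        return {self.id_of[t] for t in _SPECIALS}


class AtomVocab(_Vocab):
    """Specials + element tokens + chiral-tagged variants (``C@``, ``C@@``, ...)."""

    def __init__(self):
        tokens = list(_SPECIALS) + list(ELEMENTS)
        tokens += [f"{e}@" for e in ELEMENTS] + [f"{e}@@" for e in ELEMENTS]
        super().__init__(tokens)


class NmrVocab(_Vocab):
    """Specials + one token per ppm bin over the configured shift range."""

    def __init__(self, bin_width: float = 1.0, rng: Tuple[float, float] = (-50.0, 300.0)):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = float(bin_width)
        self.lo, self.hi = float(rng[0]), float(rng[1])
        self.min_bin = int(np.floor(self.lo / self.bin_width))
        self.max_bin = int(np.floor((self.hi - 1e-9) / self.bin_width))
        tokens = list(_SPECIALS) + [
            f"bin{b}" for b in range(self.min_bin, self.max_bin + 1)
        ]
        super().__init__(tokens)

    def bin_id(self, b: int) -> int:
        b = min(max(b, self.min_bin), self.max_bin)  # clamp to edge bins
        return len(_SPECIALS) + (b - self.min_bin)


@dataclass
class TokenPair:
    """Aligned atom and NMR token sequences, position 0 = global node."""

    atom_tokens: np.ndarray      # (n+1,) int ids
    nmr_tokens: np.ndarray       # (n+1,) int ids
    vocab_atoms: AtomVocab
    vocab_nmr: NmrVocab

    def __post_init__(self):
        if len(self.atom_tokens) != len(self.nmr_tokens):
            raise ValueError("atom and NMR sequences must align")
        if self.atom_tokens[0] != self.vocab_atoms.g or self.nmr_tokens[0] != self.vocab_nmr.g:
            raise ValueError("position 0 must be the global node")

    def __len__(self) -> int:
        return len(self.atom_tokens)


@dataclass
class PairChannels:
    """Square per-molecule matrices over tokens (global node at index 0)."""

    B: np.ndarray          # (n+1, n+1) bond energies, kJ/mol
    Bnorm: np.ndarray      # min-max normalized over bonded entries, in [0, 1]
    M: np.ndarray          # binary mask/adjacency, diag & global row/col = 1
    Draw: np.ndarray       # raw interatomic distances, Å (global row/col 0)
    pad_mask: np.ndarray   # (n+1,) 1 for valid tokens

    @property
    def n_tokens(self) -> int:
        return self.B.shape[0]


@dataclass
class GeometryTargets:
    """Ground-truth 3D quantities; indices are atom positions (no global node)."""

    dist_pairs: np.ndarray      # (n_pairs, 2) int
    dist_values: np.ndarray     # (n_pairs,) Å
    angle_triples: np.ndarray   # (n_angles, 3) int, path i-j-k, j central
    angle_values: np.ndarray    # radians in [0, pi]
    torsion_quads: np.ndarray   # (n_torsions, 4) int, path i-j-k-l
    torsion_values: np.ndarray  # radians; unsigned -> [0, pi]


# ----------------------------------------------------------------- tokenization

def tokenize(m: Molecule, vocab: AtomVocab, use_chiral_tokens: bool = True) -> np.ndarray:
    """Atom half of the token pair: one token per heavy atom in canonical
    order, ``<G>`` prepended; unknown elements map to ``<UNK>``."""
    ids = [vocab.g]
    for elem, _charge, chiral in m.atoms:
        tok = elem
        if use_chiral_tokens and chiral != "none":
            tok = f"{elem}@@" if chiral == "CW" else f"{elem}@"
        if tok not in vocab:
            logger.warning("element %r outside vocabulary; using <UNK>", tok)
            ids.append(vocab.unk)
        else:
            ids.append(vocab[tok])
    return np.array(ids, dtype=np.int64)


# ------------------------------------------------------------- surrogate tables

_ORDER_CHAR = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}


def environment_key(m: Molecule, i: int) -> str:
    """Radius-1 environment key: ``element|sorted(order+neighbor, ...)``."""
    elem = m.atoms[i][0]
    descs = []
    for a, b, order in m.bonds:
        if a == i:
            descs.append(_ORDER_CHAR[order] + m.atoms[b][0])
        elif b == i:
            descs.append(_ORDER_CHAR[order] + m.atoms[a][0])
    return f"{elem}|{';'.join(sorted(descs))}"


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("smgbert.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


_NMR_TABLE: Optional[Dict[str, float]] = None
_BDE_TABLE: Optional[Dict[Tuple[str, str, str], float]] = None

#: Per-element fallback shift (ppm) for environments absent from the table;
#: midpoints of each element's surrogate shift band.
ELEMENT_DEFAULT_SHIFT = {
    "C": 60.0, "N": 155.0, "O": 215.0, "S": 270.0, "F": -43.0,
    "Cl": -27.0, "Br": -11.0, "I": 244.0, "P": 295.0,
}
_GLOBAL_DEFAULT_SHIFT = 50.0

#: Per-bond-order fallback BDE (kJ/mol) for bond keys absent from the table.
ORDER_DEFAULT_BDE = {"single": 300.0, "double": 600.0, "triple": 850.0, "aromatic": 500.0}


def load_nmr_table() -> Dict[str, float]:
    global _NMR_TABLE
    if _NMR_TABLE is None:
        df = _read_packaged("nmr_environments.csv")
        _NMR_TABLE = dict(zip(df["env_key"], df["shift_ppm"].astype(float)))
    return _NMR_TABLE


def load_bde_table() -> Dict[Tuple[str, str, str], float]:
    global _BDE_TABLE
    if _BDE_TABLE is None:
        df = _read_packaged("bde_table.csv")
        _BDE_TABLE = {
            (r.elem_a, r.elem_b, r.order): float(r.bde_kj_mol)
            for r in df.itertuples()
        }
    return _BDE_TABLE


def surrogate_nmr(m: Molecule, overrides: Optional[Dict[int, float]] = None) -> np.ndarray:
    """Deterministic per-atom shift values (ppm) from the packaged
    environment table; unknown environments fall back to an element default.

    ``overrides`` maps 0-based atom index -> shift, taking precedence.
    """
    table = load_nmr_table()
    shifts = np.empty(m.n_atoms)
    for i in range(m.n_atoms):
        if overrides and i in overrides:
            shifts[i] = overrides[i]
            continue
        key = environment_key(m, i)
        if key in table:
            shifts[i] = table[key]
        else:
            elem = m.atoms[i][0]
            shifts[i] = ELEMENT_DEFAULT_SHIFT.get(elem, _GLOBAL_DEFAULT_SHIFT)
            logger.debug("NMR environment %r not tabulated; element default used", key)
    return shifts


def discretize_nmr(shifts: np.ndarray, vocab: NmrVocab) -> np.ndarray:
    """Token id = floor(shift / bin_width), clamped to the configured range;
    non-finite shifts map to ``<UNK>``."""
    ids = np.empty(len(shifts), dtype=np.int64)
    for i, s in enumerate(np.asarray(shifts, dtype=float)):
        if not np.isfinite(s):
            ids[i] = vocab.unk
        else:
            ids[i] = vocab.bin_id(int(np.floor(s / vocab.bin_width)))
    return ids


def surrogate_bde(m: Molecule, overrides: Optional[Dict[Tuple[int, int], float]] = None) -> np.ndarray:
    """Bond-energy matrix ``B``: (n+1)x(n+1), kJ/mol, symmetric, zero off-bond
    and on the global row/column.  ``overrides`` maps (i, j) atom-index pairs
    (0-based, either order) -> value."""
    n = m.n_atoms
    table = load_bde_table()
    B = np.zeros((n + 1, n + 1))
    for i, j, order in m.bonds:
        if overrides and ((i, j) in overrides or (j, i) in overrides):
            val = overrides.get((i, j), overrides.get((j, i)))
        else:
            a, b = sorted((m.atoms[i][0], m.atoms[j][0]))
            key = (a, b, order)
            if key in table:
                val = table[key]
            else:
                val = ORDER_DEFAULT_BDE[order]
                logger.warning("bond key %s not tabulated; order default used", key)
        B[i + 1, j + 1] = B[j + 1, i + 1] = val
    return B


def normalize_b(B: np.ndarray) -> np.ndarray:
    """Min-max normalize the *bonded* (nonzero) entries of ``B`` into [0, 1];
    structural zeros stay 0.  A degenerate range (single bond energy value)
    maps all bonded entries to 1."""
    bonded = B != 0
    if not bonded.any():
        raise ValueError("B has no bonded entries to normalize")
    vals = B[bonded]
    bmin, bmax = vals.min(), vals.max()
    out = np.zeros_like(B)
    if bmax == bmin:
        logger.info("degenerate bond-energy range; all bonded entries set to 1.0")
        out[bonded] = 1.0
    else:
        out[bonded] = (B[bonded] - bmin) / (bmax - bmin)
    return out


def binarize(B: np.ndarray) -> np.ndarray:
    """Mask matrix ``M``: 1 where bonded, on the diagonal, and on the global
    node row/column (the molecule token attends everywhere); else 0."""
    M = (B != 0).astype(float)
    np.fill_diagonal(M, 1.0)
    M[0, :] = 1.0
    M[:, 0] = 1.0
    return M


def distance_matrix(m: Molecule) -> np.ndarray:
    """Raw Euclidean distance matrix ``Draw`` over tokens (Å); global node
    row/column are zero."""
    if m.coords is None:
        raise GeometryError(f"no coordinates on {m.smiles!r}; embed a conformer first")
    n = m.n_atoms
    D = np.zeros((n + 1, n + 1))
    diff = m.coords[:, None, :] - m.coords[None, :, :]
    D[1:, 1:] = np.sqrt((diff ** 2).sum(-1))
    return D


# --------------------------------------------------------------------- geometry
# Kernels are written against the autodiff Tensor API and vectorized over the
# leading axis, so the SSL 3D-reconstruction loss differentiates through the
# exact same code that produces the ground-truth targets below.

def _rows(coords, idx: np.ndarray):
    if isinstance(coords, Tensor):
        return coords[np.asarray(idx, dtype=np.intp)]
    return Tensor(np.asarray(coords, dtype=float)[np.asarray(idx, dtype=np.intp)])


def _cross(u: Tensor, v: Tensor) -> Tensor:
    c0 = u[:, 1] * v[:, 2] - u[:, 2] * v[:, 1]
    c1 = u[:, 2] * v[:, 0] - u[:, 0] * v[:, 2]
    c2 = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    return stack([c0, c1, c2], axis=1)


def _norm(u: Tensor, eps: float = 0.0) -> Tensor:
    return ((u * u).sum(axis=1) + eps).sqrt()


def pair_distances(coords, pairs: np.ndarray) -> Tensor:
    """d_ij = ||r_i - r_j||_2 for each (i, j) row of ``pairs``."""
    a = _rows(coords, pairs[:, 0])
    b = _rows(coords, pairs[:, 1])
    d = a - b
    return _norm(d, eps=1e-12)


def bond_angles(coords, triples: np.ndarray) -> Tensor:
    """theta = atan2(||u x v||, u . v) about the central atom j of each
    bonded path i-j-k; collinear triples give exactly pi (or 0)."""
    ri = _rows(coords, triples[:, 0])
    rj = _rows(coords, triples[:, 1])
    rk = _rows(coords, triples[:, 2])
    u = ri - rj
    v = rk - rj
    dot = (u * v).sum(axis=1)
    cross_norm = _norm(_cross(u, v), eps=1e-18)
    return cross_norm.atan2(dot)


def torsions(coords, quads: np.ndarray, signed: bool = False) -> Tensor:
    """Dihedral of each bonded path i-j-k-l from the two bond-plane normals.

    Unsigned (default): phi = arccos(n_a . n_b / (||n_a|| ||n_b||)) in [0, pi],
    which is mirror-invariant.  Signed: atan2 form in (-pi, pi], flipping sign
    under reflection.
    """
    ri = _rows(coords, quads[:, 0])
    rj = _rows(coords, quads[:, 1])
    rk = _rows(coords, quads[:, 2])
    rl = _rows(coords, quads[:, 3])
    b1 = rj - ri
    b2 = rk - rj
    b3 = rl - rk
    na = _cross(b1, b2)
    nb = _cross(b2, b3)
    if signed:
        m1 = _cross(na, nb)
        y = (m1 * b2).sum(axis=1) / _norm(b2, eps=1e-18)
        x = (na * nb).sum(axis=1)
        return y.atan2(x)
    cosphi = (na * nb).sum(axis=1) / (_norm(na, eps=1e-18) * _norm(nb, eps=1e-18))
    # clamp into arccos domain without touching the graph structure
    cosphi.data = np.clip(cosphi.data, -1.0, 1.0)
    return cosphi.arccos()


def _angle_triples(m: Molecule) -> np.ndarray:
    nbrs: List[List[int]] = [[] for _ in range(m.n_atoms)]
    for i, j, _ in m.bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    triples = []
    for j in range(m.n_atoms):
        ns = sorted(nbrs[j])
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                triples.append((ns[a], j, ns[b]))
    return np.array(triples, dtype=np.intp).reshape(-1, 3)


def _torsion_quads(m: Molecule) -> np.ndarray:
    nbrs: List[List[int]] = [[] for _ in range(m.n_atoms)]
    for i, j, _ in m.bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    quads = []
    for j, k, _ in m.bonds:  # central bond j-k, each bond visited once
        for i in sorted(nbrs[j]):
            if i == k:
                continue
            for l in sorted(nbrs[k]):
                if l == j or l == i:
                    continue
                quads.append((i, j, k, l))
    return np.array(quads, dtype=np.intp).reshape(-1, 4)


def geometry_targets(m: Molecule, signed_torsions: bool = False) -> GeometryTargets:
    """Ground-truth distances (all pairs), bond angles (bonded triples) and
    torsions (bonded quads) from the molecule's conformer coordinates.

    Degenerate torsions (three collinear atoms, zero-norm plane normal) are
    skipped with a warning.
    """
    if m.coords is None:
        raise GeometryError(f"no coordinates on {m.smiles!r}")
    n = m.n_atoms
    iu = np.triu_indices(n, 1)
    pairs = np.stack(iu, axis=1).astype(np.intp)
    dvals = pair_distances(m.coords, pairs).data if len(pairs) else np.zeros(0)

    triples = _angle_triples(m)
    avals = bond_angles(m.coords, triples).data if len(triples) else np.zeros(0)

    quads = _torsion_quads(m)
    if len(quads):
        # drop quads whose bond-plane normal degenerates (collinear atoms)
        coords = m.coords
        keep = []
        for q, (i, j, k, l) in enumerate(quads):
            na = np.cross(coords[j] - coords[i], coords[k] - coords[j])
            nb = np.cross(coords[k] - coords[j], coords[l] - coords[k])
            if np.linalg.norm(na) < 1e-8 or np.linalg.norm(nb) < 1e-8:
                logger.warning("degenerate torsion %s in %s skipped", (i, j, k, l), m.smiles)
            else:
                keep.append(q)
        quads = quads[keep]
    tvals = torsions(m.coords, quads, signed=signed_torsions).data if len(quads) else np.zeros(0)

    return GeometryTargets(
        dist_pairs=pairs, dist_values=dvals,
        angle_triples=triples, angle_values=avals,
        torsion_quads=quads, torsion_values=tvals,
    )


# ------------------------------------------------------------------- assembly

def build_token_pair(m: Molecule, cfg: FeaturizeConfig = FeaturizeConfig(),
                     atom_vocab: Optional[AtomVocab] = None,
                     nmr_vocab: Optional[NmrVocab] = None,
                     nmr_overrides: Optional[Dict[int, float]] = None) -> TokenPair:
    atom_vocab = atom_vocab or AtomVocab()
    nmr_vocab = nmr_vocab or NmrVocab(cfg.nmr_bin_width, cfg.nmr_range)
    atom_ids = tokenize(m, atom_vocab, cfg.use_chiral_tokens)
    shifts = surrogate_nmr(m, overrides=nmr_overrides)
    nmr_ids = np.concatenate([[nmr_vocab.g], discretize_nmr(shifts, nmr_vocab)])
    return TokenPair(atom_tokens=atom_ids, nmr_tokens=nmr_ids,
                     vocab_atoms=atom_vocab, vocab_nmr=nmr_vocab)


def build_channels(m: Molecule,
                   bde_overrides: Optional[Dict[Tuple[int, int], float]] = None) -> PairChannels:
    """All square channels for one molecule (requires coordinates)."""
    B = surrogate_bde(m, overrides=bde_overrides)
    Bnorm = normalize_b(B) if (B != 0).any() else np.zeros_like(B)
    M = binarize(B)
    Draw = distance_matrix(m)
    pad_mask = np.ones(m.n_atoms + 1)
    return PairChannels(B=B, Bnorm=Bnorm, M=M, Draw=Draw, pad_mask=pad_mask)
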