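"""Molecule I/O: SMILES parsing, seeded 3D conformer embedding, SDF/CSV
reading and writing, and the synthetic fixture generator used for desk-scale
pre-training and fine-tuning experiments.

All chemistry parsing goes through RDKit; the :class:`Molecule` container is a
thin, immutable snapshot (heavy-atom graph + optional coordinates) that every
downstream featurization channel is built from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger("smgbert")
RDLogger.DisableLog("rdApp.*")  # rdkit warnings routed through our own logging

__all__ = [
    "Molecule",
    "PropertyTable",
    "ParseError",
    "GeometryError",
    "FormatError",
    "parse_smiles",
    "embed_conformer",
    "read_smiles_file",
    "read_sdf",
    "read_table",
    "write_sdf",
    "generate_fixtures",
    "fixture_label",
    "LABEL_WEIGHTS",
    "LABEL_NOISE_SD",
]


class ParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


class GeometryError(RuntimeError):
    """3D coordinates are missing or could not be embedded."""


class FormatError(ValueError):
    """An input file does not follow the expected tabular/SDF layout."""


_CHIRAL_TAG = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "CW",    # '@@'
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "CCW",  # '@'
}
_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom molecular graph with optional 3D conformer coordinates.

    Atom order is the canonical-SMILES order, so the same structure always
    yields the same token sequence regardless of how its SMILES was written.
    """

    atoms: Tuple[Tuple[str, int, str], ...]       # (element, formal charge, chiral tag)
    bonds: Tuple[Tuple[int, int, str], ...]       # (i, j, order), i < j
    smiles: str
    coords: Optional[np.ndarray] = None           # n_atoms x 3, Angstrom

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if (i, j) in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add((i, j))
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=float)
            if c.shape != (n, 3):
                raise ValueError(f"coords shape {c.shape} != ({n}, 3)")
            for i, j, _ in self.bonds:
                d = float(np.linalg.norm(c[i] - c[j]))
                if not (0.5 < d < 3.0):
                    raise ValueError(f"bonded distance {d:.3f} A for ({i},{j}) outside (0.5, 3.0)")
            object.__setattr__(self, "coords", c)

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles is canonical by construction
            raise ParseError(f"stored SMILES no longer parses: {self.smiles!r}")
        return mol


@dataclass
class PropertyTable:
    """SMILES records with one or more named property labels."""

    records: List[Tuple[str, Dict[str, float]]] = field(default_factory=list)
    task_types: Dict[str, str] = field(default_factory=dict)  # name -> regression|binary

    def __len__(self) -> int:
        return len(self.records)

    @property
    def smiles(self) -> List[str]:
        return [s for s, _ in self.records]

    def labels(self, name: str) -> np.ndarray:
        return np.array([vals[name] for _, vals in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.task_types)
        rows = [{"smiles": s, **{k: v.get(k, np.nan) for k in names}} for s, v in self.records]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------- parsing

def parse_smiles(s: str) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    Hydrogens stay implicit; chiral tags (@/@@) are preserved.  The molecule
    is re-canonicalized so atom order follows the canonical SMILES.
    """
    if not s or not s.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {s!r}")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), _CHIRAL_TAG.get(a.GetChiralTag(), "none"))
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        sorted(
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             _BOND_ORDER.get(b.GetBondType(), "single"))
            for b in mol.GetBonds()
        )
    )
    return Molecule(atoms=atoms, bonds=bonds, smiles=canonical)


def _invert_chirality(smiles: str) -> str:
    """Canonical SMILES of the mirror image (all tetrahedral tags flipped)."""
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    return Chem.MolToSmiles(mol)


def embed_conformer(m: Molecule, seed: int) -> Molecule:
    """Attach 3D coordinates from a seeded distance-geometry embedding followed
    by MMFF relaxation; the single relaxed conformer stands in for the ground
    state.

    Enantiomer-consistent: for a chiral molecule, the lexicographically smaller
    canonical SMILES of the (molecule, mirror image) pair is embedded and the
    result reflected if the input was the other enantiomer.  Enantiomer pairs
    therefore get exactly mirror-image conformers — equal distance multisets,
    opposite torsion signs — as mirror symmetry dictates.
    """
    if m.n_atoms < 1:
        raise GeometryError("cannot embed an empty molecule")
    mirror = _invert_chirality(m.smiles)
    reflect = mirror < m.smiles
    source = mirror if reflect else m.smiles
    rd = Chem.MolFromSmiles(source)
    rd = Chem.AddHs(rd)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    conf_id = AllChem.EmbedMolecule(rd, params)
    if conf_id < 0:
        raise GeometryError(f"conformer embedding failed for {m.smiles!r}")
    if rd.GetNumAtoms() > 2 and AllChem.MMFFHasAllMoleculeParams(rd):
        AllChem.MMFFOptimizeMolecule(rd, maxIters=2000)
    conf = rd.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(m.n_atoms)])
    if reflect:
        coords = coords * np.array([1.0, 1.0, -1.0])
    return replace(m, coords=coords)


# ------------------------------------------------------------------- file I/O

def read_smiles_file(path) -> List[Molecule]:
    """Read a .smi file (one SMILES per line); failures logged and skipped."""
    mols, n_failed = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip().split()[0] if line.strip() else ""
            if not s:
                continue
            try:
                mols.append(parse_smiles(s))
            except ParseError:
                n_failed += 1
                logger.warning("line %d: skipping unparseable SMILES %r", lineno, s)
    if n_failed:
        logger.warning("%d record(s) skipped while reading %s", n_failed, path)
    return mols


def read_sdf(path) -> List[Molecule]:
    """Read an SDF file; explicit 3D coordinates, when present, are kept and
    override any later conformer embedding."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    mols, n_failed = [], 0
    for idx, rd in enumerate(supplier):
        if rd is None:
            n_failed += 1
            logger.warning("SDF record %d failed to parse; skipped", idx)
            continue
        canonical = Chem.MolToSmiles(rd)
        m = parse_smiles(canonical)
        if rd.GetNumConformers() > 0:
            conf = rd.GetConformer()
            # re-parse canonicalizes atom order; map via canonical ranking
            order = list(Chem.CanonicalRankAtoms(rd, breakTies=True))
            ref = Chem.MolFromSmiles(canonical)
            ref_order = list(Chem.CanonicalRankAtoms(ref, breakTies=True))
            coords_in = np.array([list(conf.GetAtomPosition(i)) for i in range(rd.GetNumAtoms())])
            coords = np.zeros((m.n_atoms, 3))
            pos_by_rank = {r: i for i, r in enumerate(order)}
            for i_ref, r in enumerate(ref_order):
                coords[i_ref] = coords_in[pos_by_rank[r]]
            m = replace(m, coords=coords)
        mols.append(m)
    if n_failed:
        logger.warning("%d SDF record(s) skipped while reading %s", n_failed, path)
    return mols


def write_sdf(mols: Sequence[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = Chem.MolFromSmiles(m.smiles)
            if m.coords is not None:
                conf = Chem.Conformer(rd.GetNumAtoms())
                for i, xyz in enumerate(m.coords):
                    conf.SetAtomPosition(i, [float(v) for v in xyz])
                rd.AddConformer(conf)
            writer.write(rd)
    finally:
        writer.close()


def read_table(path) -> PropertyTable:
    """Read a CSV with a (case-insensitive) ``smiles`` column plus property
    columns.  Binary columns are those whose non-missing values are all 0/1."""
    df = pd.read_csv(path)
    smiles_col = next((c for c in df.columns if c.lower() == "smiles"), None)
    if smiles_col is None:
        raise FormatError(f"no 'smiles' column in {path} (columns: {list(df.columns)})")
    prop_cols = [c for c in df.columns if c != smiles_col]
    task_types = {}
    for c in prop_cols:
        vals = pd.to_numeric(df[c], errors="coerce").dropna()
        task_types[c] = "binary" if len(vals) and set(vals.unique()) <= {0.0, 1.0} else "regression"
    records, n_skipped = [], 0
    for _, row in df.iterrows():
        try:
            mol = parse_smiles(str(row[smiles_col]))
        except ParseError:
            n_skipped += 1
            logger.warning("skipping unparseable SMILES %r", row[smiles_col])
            continue
        vals = {}
        for c in prop_cols:
            v = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.notna(v):
                vals[c] = float(v)
        if not vals and prop_cols:
            n_skipped += 1
            logger.warning("skipping %r: no usable labels", mol.smiles)
            continue
        records.append((mol.smiles, vals))
    if n_skipped:
        logger.warning("%d record(s) skipped while reading %s", n_skipped, path)
    return PropertyTable(records=records, task_types=task_types)


# -------------------------------------------------------------------- fixtures

#: Weights of the closed-form fixture label: y = sum_e w_e * count_e
#: + AROMATIC_BONUS * (number of aromatic atoms) + Normal(0, LABEL_NOISE_SD).
#: A linear function of heavy-atom composition — learnable from token content
#: alone, so it exercises the encoder's pooling path without external data.
LABEL_WEIGHTS: Dict[str, float] = {
    "C": 1.0, "N": 2.5, "O": 3.0, "F": 1.5, "Cl": 2.0, "Br": 2.2, "S": 2.8,
}
AROMATIC_BONUS = -0.5
LABEL_NOISE_SD = 0.1


def fixture_label(smiles: str, rng: Optional[np.random.Generator] = None) -> float:
    """Closed-form synthetic regression label (see :data:`LABEL_WEIGHTS`)."""
    mol = Chem.MolFromSmiles(smiles)
    y = 0.0
    for atom in mol.GetAtoms():
        y += LABEL_WEIGHTS.get(atom.GetSymbol(), 1.0)
        if atom.GetIsAromatic():
            y += AROMATIC_BONUS
    if rng is not None:
        y += rng.normal(0.0, LABEL_NOISE_SD)
    return y


_HALIDES = ["F", "Cl", "Br"]
_BENZENE_SUBS = ["C", "CC", "O", "N", "Cl", "C(=O)C", "OC", "C#N", "CCO", "CN", "CCC"]
_CHIRAL_X = ["N", "O", "F", "Cl", "OC"]
_CHIRAL_Y = ["C(=O)O", "CC", "CO", "CCO", "C(=O)C"]

# free valence budget per element for the acyclic tree builder
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
_ELEMENTS = ["C", "C", "C", "C", "C", "C", "N", "O", "O", "S", "F", "Cl", "Br"]


def _random_tree_smiles(rng: np.random.Generator, n_min: int = 2, n_max: int = 14) -> str:
    """Random acyclic molecule: a valence-respecting tree over 2-14 heavy atoms
    (alkanes, ethers, amines, alcohols, halides, thioethers, one optional C=O)."""
    n = int(rng.integers(n_min, n_max + 1))
    rw = Chem.RWMol()
    free = []
    first = "C" if n > 1 else str(rng.choice(_ELEMENTS))
    rw.AddAtom(Chem.Atom(first))
    free.append(_VALENCE[first])
    for _ in range(n - 1):
        candidates = [i for i, f in enumerate(free) if f >= 1]
        if not candidates:
            break
        parent = int(rng.choice(candidates))
        elem = str(rng.choice(_ELEMENTS))
        double = (
            elem == "O" and free[parent] >= 2 and rng.random() < 0.15
        )
        idx = rw.AddAtom(Chem.Atom(elem))
        order = Chem.BondType.DOUBLE if double else Chem.BondType.SINGLE
        rw.AddBond(parent, idx, order)
        used = 2 if double else 1
        free[parent] -= used
        free.append(_VALENCE[elem] - used)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _template_smiles(rng: np.random.Generator) -> str:
    kind = rng.integers(0, 4)
    if kind <= 1:    # acyclic tree molecules (the bulk of the space)
        return _random_tree_smiles(rng)
    if kind == 2:    # mono-substituted benzenes
        sub = str(rng.choice(_BENZENE_SUBS))
        return "c1ccccc1" + sub
    # di-substituted benzenes
    s1, s2 = rng.choice(_BENZENE_SUBS, size=2)
    return f"c1ccc({s1})cc1" + str(s2)


def _chiral_pair(rng: np.random.Generator) -> Tuple[str, str]:
    x = str(rng.choice(_CHIRAL_X))
    y = str(rng.choice(_CHIRAL_Y))
    return (f"C[C@H]({x}){y}", f"C[C@@H]({x}){y}")


def generate_fixtures(n: int, seed: int, include_chiral_pairs: bool = False) -> PropertyTable:
    """Generate ``n`` distinct valid molecules (2-16 heavy atoms) from fixed
    structural templates, with the closed-form regression label ``y`` attached.

    Deterministic for fixed ``(n, seed, include_chiral_pairs)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    smiles_list: List[str] = []
    seen = set()

    def _add(s: str) -> None:
        try:
            canonical = parse_smiles(s).smiles
        except ParseError:  # pragma: no cover - templates always parse
            return
        if canonical not in seen:
            seen.add(canonical)
            smiles_list.append(canonical)

    if include_chiral_pairs:
        while len(smiles_list) < min(max(2, n // 5 * 2), n) and len(smiles_list) + 1 < n + 1:
            a, b = _chiral_pair(rng)
            before = len(smiles_list)
            _add(a)
            _add(b)
            if len(smiles_list) == before:  # pair exhausted
                break
            if len(smiles_list) >= n:
                break
    attempts = 0
    while len(smiles_list) < n:
        _add(_template_smiles(rng))
        attempts += 1
        if attempts > 200 * n:  # pragma: no cover
            raise RuntimeError("fixture template space exhausted")
    smiles_list = smiles_list[:n]
    records = [(s, {"y": fixture_label(s, rng)}) for s in smiles_list]
    return PropertyTable(records=records, task_types={"y": "regression"})
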