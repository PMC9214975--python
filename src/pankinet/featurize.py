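"""Molecular graph featurization for the GCN classifier.

Every compound is encoded as an attributed graph ``(AF, L)``:

* ``AF`` — a 50 x 28 atom-feature matrix. Each heavy atom (hydrogens are
  implicit) contributes one row of 28 descriptors: a 10-way atom-type
  one-hot (C, N, O, S, F, P, Cl, Br, I, other), the count of bonded
  hydrogens, a 4-way hybridization one-hot (sp, sp2, sp3, other), formal
  charge, Gasteiger partial charge, radical-electron count, six
  ring-membership bits (ring sizes 3-8), and single bits for chirality,
  aromaticity, H-bond donor and H-bond acceptor character.
* ``L`` — the 50 x 50 modified normalized Laplacian
  ``D^{-1/2} (A + I) D^{-1/2}`` where ``A`` is the (optionally
  bond-order-weighted) adjacency matrix and ``D`` the degree matrix of
  ``A + I``. This is the propagation operator of the graph convolution.

Molecules larger than 50 heavy atoms are rejected; smaller ones are
zero-padded so that every graph has a fixed tensor shape. Atom order is
fixed by RDKit's canonical SMILES ranking so that atom indices are stable
across runs and consistent with SMARTS-match indices elsewhere in the
package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

#: Fixed padded atom dimension of every graph tensor.
MAX_ATOMS = 50

#: Length of the per-atom descriptor vector.
N_ATOM_FEATURES = 28

#: Elements with a dedicated one-hot slot; everything else maps to "other".
ATOM_TYPES = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")

#: Hybridization states with a dedicated one-hot slot.
HYBRIDIZATIONS = ("SP", "SP2", "SP3")

#: Ring sizes with a membership bit.
RING_SIZES = (3, 4, 5, 6, 7, 8)


def _load_hbond_patterns() -> dict:
    path = resources.files("pankinet.data").joinpath("hbond_smarts.tsv")
    patterns = {}
    for line in path.read_text().splitlines()[1:]:
        role, smarts = line.split("\t")
        query = Chem.MolFromSmarts(smarts)
        if query is None:  # pragma: no cover - shipped patterns are valid
            raise ValueError(f"invalid H-bond SMARTS for {role!r}: {smarts}")
        patterns[role] = query
    return patterns


_HBOND = _load_hbond_patterns()


class FeaturizationError(ValueError):
    """Raised when a compound cannot be converted to a graph."""


@dataclass(frozen=True)
class FeaturizerConfig:
    """Options of the graph featurizer.

    adjacency_mode
        ``"weighted"`` writes the bond order into the adjacency matrix
        (single 1, double 2, triple 3, aromatic 1.5); ``"binary"`` writes 1
        for every bond. The normalized-Laplacian construction is identical
        in both modes.
    max_atoms
        Padded atom dimension (and hard cap on heavy-atom count).
    """

    adjacency_mode: str = "weighted"
    max_atoms: int = MAX_ATOMS

    def __post_init__(self):
        if self.adjacency_mode not in ("weighted", "binary"):
            raise ValueError(f"unknown adjacency mode {self.adjacency_mode!r}")


DEFAULT_CONFIG = FeaturizerConfig()


@dataclass
class CompoundGraph:
    """The padded attributed graph of one compound."""

    compound_id: str
    n_atoms: int
    AF: np.ndarray  # (max_atoms, 28)
    L: np.ndarray   # (max_atoms, max_atoms)
    smiles: str = ""
    config: FeaturizerConfig = field(default=DEFAULT_CONFIG)


def prepare_molecule(smiles: str) -> Chem.Mol:
    """Parse a SMILES into a sanitized molecule in canonical atom order.

    Salts/solvents are stripped by keeping the largest covalent fragment.
    Gasteiger partial charges are computed on the prepared molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    # Round-trip through canonical SMILES to fix a reproducible atom order.
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if mol is None or mol.GetNumAtoms() == 0:
        raise FeaturizationError(f"empty molecule from SMILES: {smiles!r}")
    AllChem.ComputeGasteigerCharges(mol)
    return mol


def atom_features(
    symbol: str,
    n_hydrogens: int,
    hybridization: str,
    formal_charge: int,
    partial_charge: float,
    radical_electrons: int,
    ring_sizes: set,
    is_chiral: bool,
    is_aromatic: bool,
    is_donor: bool,
    is_acceptor: bool,
) -> np.ndarray:
    """Assemble the 28-element descriptor vector for one heavy atom.

    ``hybridization`` is compared case-insensitively against sp/sp2/sp3;
    anything else (sp3d, unhybridized, ...) falls in the "other" slot, as
    does any element outside the nine named atom types.
    """
    vec = np.zeros(N_ATOM_FEATURES)
    # atom type one-hot (10)
    try:
        vec[ATOM_TYPES.index(symbol)] = 1.0
    except ValueError:
        vec[9] = 1.0
    vec[10] = float(n_hydrogens)
    # hybridization one-hot (4)
    hyb = str(hybridization).upper()
    if hyb in HYBRIDIZATIONS:
        vec[11 + HYBRIDIZATIONS.index(hyb)] = 1.0
    else:
        vec[14] = 1.0
    vec[15] = float(formal_charge)
    if not np.isfinite(partial_charge):
        warnings.warn("non-finite partial charge replaced by 0", stacklevel=2)
        partial_charge = 0.0
    vec[16] = float(partial_charge)
    vec[17] = float(radical_electrons)
    for k, size in enumerate(RING_SIZES):
        vec[18 + k] = 1.0 if size in ring_sizes else 0.0
    vec[24] = 1.0 if is_chiral else 0.0
    vec[25] = 1.0 if is_aromatic else 0.0
    vec[26] = 1.0 if is_donor else 0.0
    vec[27] = 1.0 if is_acceptor else 0.0
    return vec


def atom_feature_matrix(mol: Chem.Mol) -> np.ndarray:
    """Per-atom descriptor matrix (n_atoms x 28) for a prepared molecule."""
    chiral = {idx for idx, _ in Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False)}
    donors = {m[0] for m in mol.GetSubstructMatches(_HBOND["donor"])}
    acceptors = {m[0] for m in mol.GetSubstructMatches(_HBOND["acceptor"])}
    rows = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        pc = atom.GetDoubleProp("_GasteigerCharge") if atom.HasProp(
            "_GasteigerCharge") else 0.0
        rows.append(atom_features(
            symbol=atom.GetSymbol(),
            n_hydrogens=atom.GetTotalNumHs(),
            hybridization=str(atom.GetHybridization()),
            formal_charge=atom.GetFormalCharge(),
            partial_charge=pc,
            radical_electrons=atom.GetNumRadicalElectrons(),
            ring_sizes={s for s in RING_SIZES if atom.IsInRingSize(s)},
            is_chiral=i in chiral,
            is_aromatic=atom.GetIsAromatic(),
            is_donor=i in donors,
            is_acceptor=i in acceptors,
        ))
    return np.asarray(rows)


def adjacency(bonds, n_atoms: int, mode: str = "weighted") -> np.ndarray:
    """Symmetric adjacency matrix from ``(i, j, order)`` bond triples.

    In ``weighted`` mode the entry is the bond order (aromatic bonds count
    1.5); in ``binary`` mode every bond is 1. The diagonal is zero — the
    self-loop is added later by the Laplacian.
    """
    A = np.zeros((n_atoms, n_atoms))
    for i, j, order in bonds:
        if not (0 <= i < n_atoms and 0 <= j < n_atoms) or i == j:
            raise ValueError(f"invalid bond ({i}, {j}) for {n_atoms} atoms")
        w = float(order) if mode == "weighted" else 1.0
        A[i, j] = A[j, i] = w
    return A


def norm_laplacian(A: np.ndarray) -> np.ndarray:
    """Modified normalized Laplacian ``D^{-1/2} (A + I) D^{-1/2}``.

    ``D`` is the diagonal degree matrix of ``A + I``, so an isolated atom
    has degree 1 and maps to a diagonal entry of exactly 1.
    """
    A = np.asarray(A, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return d_inv_sqrt[:, None] * A_tilde * d_inv_sqrt[None, :]


def pad_graph(AF: np.ndarray, L: np.ndarray, max_atoms: int = MAX_ATOMS):
    """Zero-pad ``AF`` (n x 28) and ``L`` (n x n) to the fixed tensor size."""
    n = AF.shape[0]
    if n > max_atoms:
        raise FeaturizationError(
            f"compound has {n} heavy atoms; the featurizer caps at {max_atoms}")
    AF_p = np.zeros((max_atoms, AF.shape[1]))
    L_p = np.zeros((max_atoms, max_atoms))
    AF_p[:n] = AF
    L_p[:n, :n] = L
    return AF_p, L_p


def featurize_compound(
    smiles: str,
    compound_id: str = "",
    config: FeaturizerConfig = DEFAULT_CONFIG,
) -> CompoundGraph:
    """Full featurization of one compound from its SMILES string."""
    mol = prepare_molecule(smiles)
    n = mol.GetNumAtoms()
    if n > config.max_atoms:
        raise FeaturizationError(
            f"{compound_id or smiles}: {n} heavy atoms exceeds the "
            f"{config.max_atoms}-atom limit")
    AF = atom_feature_matrix(mol)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    A = adjacency(bonds, n, mode=config.adjacency_mode)
    L = norm_laplacian(A)
    AF_p, L_p = pad_graph(AF, L, config.max_atoms)
    return CompoundGraph(
        compound_id=compound_id or Chem.MolToSmiles(mol),
        n_atoms=n, AF=AF_p, L=L_p,
        smiles=Chem.MolToSmiles(mol), config=config)
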