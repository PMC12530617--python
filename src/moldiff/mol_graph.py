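"""Fixed-size categorical graph representation of molecules.

A molecule is encoded as three one-hot arrays: atom types ``A`` (n x d_A),
formal charges ``C`` (n x d_C) and bond types ``E`` (n x n x d_E).  All
graphs share one size ``n``; molecules smaller than ``n`` are completed with
``<PADDING>`` atoms that carry no bonds.  Each channel additionally has a
``<MASK>`` category (always the last index) used by the absorbing corruption
process; clean graphs never contain it.  "No bond" is an ordinary bond
category (index 0), so the dense edge tensor is itself categorical.

Hydrogens are implicit and stereochemistry is stripped on encode; decoding
delegates valence checking to RDKit sanitization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

MASK = "<MASK>"
PADDING = "<PADDING>"
NO_BOND = "no-bond"

_BOND_ORDER = [NO_BOND, "single", "double", "triple", "aromatic"]
_TO_RDKIT_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_FROM_RDKIT_BOND = {v: k for k, v in _TO_RDKIT_BOND.items()}


class VocabularyError(ValueError):
    """A molecule uses an element/charge/bond outside the vocabulary."""


@dataclass(frozen=True)
class Vocabulary:
    """Ordered category lists per channel; ``<MASK>`` is always last.

    ``<PADDING>`` is an ordinary *atom* category: it is corrupted and
    predicted like any element, which is how the model learns the
    distribution of molecule sizes.
    """

    atom_types: tuple
    charge_types: tuple
    bond_types: tuple = tuple(_BOND_ORDER + [MASK])

    def __post_init__(self):
        for types in (self.atom_types, self.charge_types, self.bond_types):
            if types[-1] != MASK:
                raise ValueError(f"{MASK} must be the last category, got {types}")

    # counts of ordinary (non-mask) categories
    @property
    def K_A(self) -> int:
        return len(self.atom_types) - 1

    @property
    def K_C(self) -> int:
        return len(self.charge_types) - 1

    @property
    def K_E(self) -> int:
        return len(self.bond_types) - 1

    @property
    def d_A(self) -> int:
        return len(self.atom_types)

    @property
    def d_C(self) -> int:
        return len(self.charge_types)

    @property
    def d_E(self) -> int:
        return len(self.bond_types)

    @property
    def padding_index(self) -> int:
        return self.atom_types.index(PADDING)

    @property
    def neutral_charge_index(self) -> int:
        return self.charge_types.index(0)

    def atom_index(self, symbol: str) -> int:
        try:
            return self.atom_types.index(symbol)
        except ValueError:
            raise VocabularyError(f"element {symbol!r} not in vocabulary")

    def charge_index(self, charge: int) -> int:
        try:
            return self.charge_types.index(charge)
        except ValueError:
            raise VocabularyError(f"formal charge {charge} not in vocabulary")

    def bond_index(self, name: str) -> int:
        return self.bond_types.index(name)

    def K(self, channel: str) -> int:
        return {"A": self.K_A, "C": self.K_C, "E": self.K_E}[channel]

    def Ks(self) -> dict:
        return {"A": self.K_A, "C": self.K_C, "E": self.K_E}


def parse_smiles(s: str) -> Chem.Mol:
    """Parse and sanitize one SMILES; stereo descriptors are discarded."""
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {s!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


def canonical_smiles(s: str) -> str:
    return Chem.MolToSmiles(parse_smiles(s))


def build_vocabulary(smiles_list) -> Vocabulary:
    """Collect atom/charge categories observed in a corpus.

    Atom types are the sorted distinct element symbols followed by
    ``<PADDING>`` and ``<MASK>``.  Charge types are the sorted distinct
    formal charges (always including 0, which padding rows use) followed by
    ``<MASK>``.  Bond types are fixed.
    """
    if not smiles_list:
        raise ValueError("empty SMILES list")
    elements, charges = set(), {0}
    for s in smiles_list:
        mol = parse_smiles(s)
        for atom in mol.GetAtoms():
            elements.add(atom.GetSymbol())
            charges.add(atom.GetFormalCharge())
    return Vocabulary(
        atom_types=tuple(sorted(elements)) + (PADDING, MASK),
        charge_types=tuple(sorted(charges)) + (MASK,),
    )


def _one_hot(indices: np.ndarray, depth: int) -> np.ndarray:
    out = np.zeros(indices.shape + (depth,), dtype=np.float64)
    np.put_along_axis(out, indices[..., None], 1.0, axis=-1)
    return out


@dataclass
class MoleculeGraph:
    """One molecule as one-hot arrays ``A`` (n x d_A), ``C`` (n x d_C),
    ``E`` (n x n x d_E); ``n_real`` rows encode heavy atoms, the rest are
    padding.  ``E`` is symmetric with a no-bond diagonal."""

    A: np.ndarray
    C: np.ndarray
    E: np.ndarray
    n_real: int

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def atom_indices(self) -> np.ndarray:
        return self.A.argmax(axis=-1)

    @property
    def charge_indices(self) -> np.ndarray:
        return self.C.argmax(axis=-1)

    @property
    def bond_indices(self) -> np.ndarray:
        return self.E.argmax(axis=-1)

    @classmethod
    def from_indices(cls, vocab: Vocabulary, a_idx, c_idx, e_idx, n_real: int):
        a_idx = np.asarray(a_idx)
        e_idx = np.asarray(e_idx)
        return cls(
            A=_one_hot(a_idx, vocab.d_A),
            C=_one_hot(np.asarray(c_idx), vocab.d_C),
            E=_one_hot(e_idx, vocab.d_E),
            n_real=n_real,
        )

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(self.A.copy(), self.C.copy(), self.E.copy(), self.n_real)

    def contains_mask(self, vocab: Vocabulary) -> bool:
        return bool(
            (self.atom_indices == vocab.d_A - 1).any()
            or (self.charge_indices == vocab.d_C - 1).any()
            or (self.bond_indices == vocab.d_E - 1).any()
        )

    def validate(self, vocab: Vocabulary) -> None:
        """Check the one-hot / symmetry invariants; raises on violation."""
        for name, arr in (("A", self.A), ("C", self.C), ("E", self.E)):
            if not np.allclose(arr.sum(axis=-1), 1.0):
                raise ValueError(f"{name} rows are not one-hot")
        if not np.array_equal(self.E, self.E.swapaxes(0, 1)):
            raise ValueError("E is not symmetric")
        if not (self.bond_indices.diagonal() == 0).all():
            raise ValueError("diagonal of E is not no-bond")


def smiles_to_graph(s: str, vocab: Vocabulary, n: int) -> MoleculeGraph:
    """Encode one molecule into a size-``n`` graph, padding the tail rows."""
    mol = parse_smiles(s)
    n_real = mol.GetNumAtoms()
    if n_real > n:
        raise ValueError(f"molecule {s!r} has {n_real} heavy atoms > graph size {n}")
    a_idx = np.full(n, vocab.padding_index, dtype=np.int64)
    c_idx = np.full(n, vocab.neutral_charge_index, dtype=np.int64)
    e_idx = np.zeros((n, n), dtype=np.int64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        a_idx[i] = vocab.atom_index(atom.GetSymbol())
        c_idx[i] = vocab.charge_index(atom.GetFormalCharge())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bt = _FROM_RDKIT_BOND.get(bond.GetBondType())
        if bt is None:
            raise VocabularyError(f"unsupported bond type {bond.GetBondType()} in {s!r}")
        e_idx[i, j] = e_idx[j, i] = vocab.bond_index(bt)
    return MoleculeGraph.from_indices(vocab, a_idx, c_idx, e_idx, n_real)


def _select_component(components, anchor: int | None):
    """Largest component, ties broken by lowest minimum node index; or the
    component containing ``anchor`` when given."""
    if anchor is not None:
        for comp in components:
            if anchor in comp:
                return comp
        return None
    return max(components, key=lambda c: (len(c), -min(c)))


def graph_to_smiles(
    g: MoleculeGraph, vocab: Vocabulary, component: str = "largest"
):
    """Decode a clean graph to canonical SMILES, or ``None`` on failure.

    Padding rows are dropped, then the largest connected component under
    non-"no-bond" edges is kept (``component="scaffold"`` keeps the
    component containing node 0 instead, for scaffold-preserving runs) and
    assembled into an RDKit molecule.  A graph that fails chemical
    sanitization (impossible valences etc.) yields ``None`` and counts as an
    invalid generation — a graph still containing ``<MASK>`` is a contract
    violation and raises.
    """
    if g.contains_mask(vocab):
        raise ValueError("graph contains <MASK> categories; decode expects clean graphs")
    a_idx, c_idx, e_idx = g.atom_indices, g.charge_indices, g.bond_indices
    real = [i for i in range(g.n) if a_idx[i] != vocab.padding_index]
    if not real:
        return None
    graph = nx.Graph()
    graph.add_nodes_from(real)
    for ii, i in enumerate(real):
        for j in real[ii + 1 :]:
            if e_idx[i, j] != 0:
                graph.add_edge(i, j)
    anchor = 0 if component == "scaffold" else None
    comp = _select_component(list(nx.connected_components(graph)), anchor)
    if comp is None:
        return None
    keep = sorted(comp)
    rw = Chem.RWMol()
    pos = {}
    for i in keep:
        atom = Chem.Atom(vocab.atom_types[a_idx[i]])
        atom.SetFormalCharge(int(vocab.charge_types[c_idx[i]]))
        pos[i] = rw.AddAtom(atom)
    aromatic_atoms = set()
    for ii, i in enumerate(keep):
        for j in keep[ii + 1 :]:
            name = vocab.bond_types[e_idx[i, j]]
            if name == NO_BOND:
                continue
            rw.AddBond(pos[i], pos[j], _TO_RDKIT_BOND[name])
            if name == "aromatic":
                aromatic_atoms.update((pos[i], pos[j]))
    for idx in aromatic_atoms:
        rw.GetAtomWithIdx(idx).SetIsAromatic(True)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def permute_graph(g: MoleculeGraph, perm) -> MoleculeGraph:
    """Relabel nodes by ``perm`` (rows of A/C and both axes of E)."""
    perm = np.asarray(perm)
    if sorted(perm.tolist()) != list(range(g.n)):
        raise ValueError("perm is not a bijection on graph nodes")
    return MoleculeGraph(
        A=g.A[perm],
        C=g.C[perm],
        E=g.E[np.ix_(perm, perm)],
        n_real=g.n_real,
    )
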