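"""SMILES -> featurized molecular graph.

Atoms become nodes, chemical bonds become directed edge pairs. Each atom
carries a fixed-length physicochemical descriptor vector (atomic number,
degree, formal charge, one-hot hybridization, aromaticity, hydrogen count,
radical electrons, ring membership, one-hot chirality, explicit valence,
isotopic mass, total valence); each bond carries its bond-order code
(1.0 single, 1.5 aromatic, 2.0 double, 3.0 triple) and a ring flag.

Hydrogens are implicit: graphs contain heavy atoms only, with hydrogen
counts folded into the per-atom feature. No feature scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ATOM_FEATURE_NAMES",
    "BOND_FEATURE_NAMES",
    "D_ATOM",
    "D_BOND",
    "MolecularGraph",
    "SmilesParseError",
    "FeaturizationError",
    "featurize_atom",
    "featurize_bond",
    "smiles_to_graph",
    "save_graph_dataset",
    "load_graph_dataset",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid SMILES: {smiles!r}")


class FeaturizationError(ValueError):
    """Raised when an atom or bond cannot be featurized."""


_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)

ATOM_FEATURE_NAMES: tuple[str, ...] = (
    "atomic_number",
    "degree",
    "formal_charge",
    "hyb_sp",
    "hyb_sp2",
    "hyb_sp3",
    "hyb_other",
    "aromatic",
    "total_num_H",
    "radical_electrons",
    "in_ring",
    "chi_unspecified",
    "chi_cw",
    "chi_ccw",
    "chi_other",
    "explicit_valence",
    "isotopic_mass",
    "total_valence",
)
BOND_FEATURE_NAMES: tuple[str, ...] = ("bond_type_code", "in_ring")

#: Width of the atom feature vector; constant across all molecules.
D_ATOM: int = len(ATOM_FEATURE_NAMES)
#: Width of the bond feature vector.
D_BOND: int = len(BOND_FEATURE_NAMES)

_BOND_TYPE_CODES = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 1.5,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
}


@dataclass
class MolecularGraph:
    """Featurized molecular graph of a single drug molecule.

    Every chemical bond is encoded symmetrically as two directed edges
    with identical feature rows, so ``num_edges`` is twice the bond count.
    """

    smiles: str
    node_features: np.ndarray  # [num_nodes, D_ATOM]
    edge_index: np.ndarray  # [2, num_edges] int, directed
    edge_features: np.ndarray  # [num_edges, D_BOND]
    atom_symbols: tuple[str, ...] = field(default_factory=tuple)

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]


def _one_hot(value, categories) -> list[float]:
    vec = [0.0] * (len(categories) + 1)
    try:
        vec[categories.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # trailing "other" bucket
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Return the fixed-length descriptor vector of one heavy atom.

    One-hot blocks (hybridization, chirality) are expanded in place; all
    remaining descriptors enter as raw numeric values.
    """
    try:
        feats = [
            float(atom.GetAtomicNum()),
            float(atom.GetDegree()),
            float(atom.GetFormalCharge()),
            *_one_hot(atom.GetHybridization(), _HYBRIDIZATIONS),
            float(atom.GetIsAromatic()),
            float(atom.GetTotalNumHs()),
            float(atom.GetNumRadicalElectrons()),
            float(atom.IsInRing()),
            *_one_hot(atom.GetChiralTag(), _CHIRAL_TAGS),
            float(atom.GetExplicitValence()),
            float(atom.GetMass()),
            float(atom.GetTotalValence()),
        ]
    except Exception as exc:  # pragma: no cover - defensive
        raise FeaturizationError(
            f"cannot featurize atom index {atom.GetIdx()}: {exc}"
        ) from exc
    return np.asarray(feats, dtype=np.float64)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Return [bond_type_code, in_ring] for one chemical bond.

    Codes: 1.0 single, 1.5 aromatic, 2.0 double, 3.0 triple.
    """
    code = _BOND_TYPE_CODES.get(bond.GetBondType())
    if code is None:
        raise FeaturizationError(
            f"unknown bond order {bond.GetBondType()} for bond "
            f"{bond.GetBeginAtomIdx()}-{bond.GetEndAtomIdx()}"
        )
    return np.asarray([code, float(bond.IsInRing())], dtype=np.float64)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string and build its featurized molecular graph.

    Node order follows the parser's atom order. Raises
    :class:`SmilesParseError` for unparseable input; the caller decides
    whether to drop the record or abort.
    """
    if not smiles or not isinstance(smiles, str):
        raise SmilesParseError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)

    n = mol.GetNumAtoms()
    x = np.empty((n, D_ATOM), dtype=np.float64)
    symbols = []
    for i, atom in enumerate(mol.GetAtoms()):
        x[i] = featurize_atom(atom)
        symbols.append(atom.GetSymbol())

    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        src += [u, v]
        dst += [v, u]
        efeat += [f, f]

    edge_index = np.asarray([src, dst], dtype=np.int64).reshape(2, -1)
    edge_features = (
        np.stack(efeat) if efeat else np.empty((0, D_BOND), dtype=np.float64)
    )
    return MolecularGraph(
        smiles=smiles,
        node_features=x,
        edge_index=edge_index,
        edge_features=edge_features,
        atom_symbols=tuple(symbols),
    )


def save_graph_dataset(graphs, targets, path) -> None:
    """Serialize graphs + regression targets to one ``.npz`` archive.

    All graphs must share the same feature widths; the archive round-trips
    node/edge tensors bit-exactly.
    """
    graphs = list(graphs)
    targets = np.asarray(targets, dtype=np.float64)
    if len(graphs) != targets.shape[0]:
        raise ValueError(
            f"{len(graphs)} graphs but {targets.shape[0]} targets"
        )
    widths = {(g.node_features.shape[1], g.edge_features.shape[1]) for g in graphs}
    if len(widths) > 1:
        raise ValueError(f"inconsistent feature widths across graphs: {widths}")

    payload = {
        "n_graphs": np.asarray(len(graphs)),
        "targets": targets,
        "smiles": np.asarray([g.smiles for g in graphs], dtype=np.str_),
    }
    for i, g in enumerate(graphs):
        payload[f"g{i}_x"] = g.node_features
        payload[f"g{i}_ei"] = g.edge_index
        payload[f"g{i}_ef"] = g.edge_features
        payload[f"g{i}_sym"] = np.asarray(g.atom_symbols, dtype=np.str_)
    np.savez(path, **payload)


def load_graph_dataset(path) -> tuple[list[MolecularGraph], np.ndarray]:
    """Load a dataset written by :func:`save_graph_dataset`."""
    with np.load(path) as data:
        n = int(data["n_graphs"])
        targets = data["targets"]
        smiles = data["smiles"]
        graphs = [
            MolecularGraph(
                smiles=str(smiles[i]),
                node_features=data[f"g{i}_x"],
                edge_index=data[f"g{i}_ei"],
                edge_features=data[f"g{i}_ef"],
                atom_symbols=tuple(str(s) for s in data[f"g{i}_sym"]),
            )
            for i in range(n)
        ]
    return graphs, targets
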