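"""Molecular graphs and multi-fidelity dataset tables.

Molecules are parsed from SMILES into heavy-atom graphs: a node-feature
matrix ``X`` (one row per atom) and a symmetric binary adjacency matrix ``A``
with unit diagonal (self-loops are added at parse time, so the stored
adjacency is exactly what the probabilistic encoder consumes).

Multi-fidelity datasets are CSV tables with columns
``mol_id,smiles,<fidelity_0>,<fidelity_1>[,...],split``; an empty cell is an
absent label, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # silence per-molecule parse warnings

VALID_SPLITS = ("lf_train", "hf_train", "hf_val", "hf_test", "no_lf_test")

#: version stamp for the atom-feature schema; checkpoints refuse to load on mismatch
FEATURIZATION_VERSION = "mfgnn-atom-v1"


class ParseError(ValueError):
    """Unparseable or empty SMILES."""


class SchemaError(ValueError):
    """Malformed dataset table (missing column, duplicate id, bad split)."""


class CapacityError(ValueError):
    """A graph exceeds the configured maximum node count."""


class ConfigurationError(ValueError):
    """Shape/dimension mismatch between data and parameters."""


# --------------------------------------------------------------------------- #
# Atom featurization
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AtomFeaturizationScheme:
    """Fixed, versioned atom-feature schema.

    Features per atom: element one-hot over ``elements`` (with a final
    "other" slot), degree one-hot (0..4, capped), formal charge (scalar),
    aromatic flag, total H count (scalar).
    """

    elements: tuple = ("C", "N", "O", "F", "S", "Cl", "Br", "I", "P")
    max_degree: int = 4
    version: str = FEATURIZATION_VERSION

    @property
    def d(self) -> int:
        return (len(self.elements) + 1) + (self.max_degree + 1) + 3

    def featurize_atom(self, atom: Chem.Atom) -> np.ndarray:
        vec = np.zeros(self.d)
        sym = atom.GetSymbol()
        idx = self.elements.index(sym) if sym in self.elements else len(self.elements)
        vec[idx] = 1.0
        off = len(self.elements) + 1
        deg = min(atom.GetDegree(), self.max_degree)
        vec[off + deg] = 1.0
        off += self.max_degree + 1
        vec[off] = float(atom.GetFormalCharge())
        vec[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
        vec[off + 2] = float(atom.GetTotalNumHs())
        return vec


DEFAULT_SCHEME = AtomFeaturizationScheme()


# --------------------------------------------------------------------------- #
# Core data types
# --------------------------------------------------------------------------- #

@dataclass
class MolecularGraph:
    """One molecule: node features X (num_nodes × d) and adjacency A with self-loops."""

    node_features: np.ndarray
    adjacency: np.ndarray
    smiles: str
    mol_id: str = ""

    @property
    def num_nodes(self) -> int:
        return self.adjacency.shape[0]

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        x = np.asarray(self.node_features, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConfigurationError("adjacency must be square")
        if x.shape[0] != a.shape[0]:
            raise ConfigurationError(
                f"node_features rows ({x.shape[0]}) != adjacency dim ({a.shape[0]})")
        if a.shape[0] < 1:
            raise ParseError("graph must have at least one node")
        if not np.array_equal(a, a.T):
            raise ConfigurationError("adjacency must be symmetric")
        self.adjacency = a
        self.node_features = x

    def permuted(self, perm: np.ndarray) -> "MolecularGraph":
        """Return the graph with nodes reordered by permutation array `perm`."""
        p = np.asarray(perm)
        return MolecularGraph(self.node_features[p], self.adjacency[np.ix_(p, p)],
                              self.smiles, self.mol_id)


@dataclass
class MultiFidelityRecord:
    mol_id: str
    smiles: str
    lf_label: float | None = None
    hf_label: float | None = None
    split: str | None = None
    extra_lf_labels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lf_label is None and self.hf_label is None and not self.extra_lf_labels:
            raise SchemaError(f"record {self.mol_id!r}: at least one label must be present")
        if self.split is not None and self.split not in VALID_SPLITS:
            raise SchemaError(f"record {self.mol_id!r}: unknown split {self.split!r}")
        if self.split == "no_lf_test" and self.lf_label is not None:
            raise SchemaError(
                f"record {self.mol_id!r}: no_lf_test records cannot carry an lf_label")


@dataclass
class MultiFidelityDataset:
    """A collection of records with unique mol_ids.

    ``fidelity_names`` is ordered least- to most-accurate; the last name is
    the high-fidelity level, the first the primary low-fidelity level, and
    any names in between map to ``extra_lf_labels`` keys.
    """

    records: list
    task_type: str = "regression"
    fidelity_names: tuple = ("lf", "hf")

    def __post_init__(self):
        ids = [r.mol_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise SchemaError(f"duplicate mol_id(s): {list(dup[dup > 1].index)[:5]}")
        if self.task_type not in ("regression", "classification"):
            raise SchemaError(f"unknown task_type {self.task_type!r}")
        if len(self.fidelity_names) < 2:
            raise SchemaError("need at least two fidelity levels")
        self.fidelity_names = tuple(self.fidelity_names)

    def __len__(self):
        return len(self.records)

    def subset(self, split: str) -> list:
        return [r for r in self.records if r.split == split]

    def replace_records(self, records) -> "MultiFidelityDataset":
        return MultiFidelityDataset(list(records), self.task_type, self.fidelity_names)


# --------------------------------------------------------------------------- #
# Parsing
# --------------------------------------------------------------------------- #

def parse_smiles_to_graph(smiles: str, scheme: AtomFeaturizationScheme = DEFAULT_SCHEME,
                          mol_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph with self-loops.

    Node order follows the canonical atom ordering of the RDKit parser.
    Raises :class:`ParseError` on invalid SMILES or zero-atom results.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise ParseError(f"SMILES {smiles!r} yields an empty molecule")
    x = np.stack([scheme.featurize_atom(a) for a in mol.GetAtoms()])
    a = np.eye(n)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        a[i, j] = a[j, i] = 1.0
    return MolecularGraph(x, a, smiles, mol_id or smiles)


def pad_node_matrix(h: np.ndarray, max_nodes: int) -> np.ndarray:
    """Zero-pad an (n × D) node matrix to (max_nodes × D)."""
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    if n > max_nodes:
        raise CapacityError(f"matrix has {n} rows but capacity is {max_nodes}")
    if n == max_nodes:
        return h
    return np.vstack([h, np.zeros((max_nodes - n, h.shape[1]))])


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalisation D^{-1/2} A D^{-1/2} (A already has self-loops)."""
    deg = adjacency.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    return adjacency * dinv[:, None] * dinv[None, :]


def neighbourhood_aggregate(graph: MolecularGraph, params: list, k_layers: int | None = None,
                            activation=np.tanh) -> np.ndarray:
    """Plain k-layer graph-convolution forward pass H = act(Â H W) per layer.

    `params` is a list of weight matrices; layer widths must chain, and the
    first must match the featurization dimension d.  Permutation-equivariant:
    permuting node order permutes the rows of H identically.
    """
    if k_layers is None:
        k_layers = len(params)
    if k_layers != len(params):
        raise ConfigurationError(f"{len(params)} weight matrices for {k_layers} layers")
    ahat = normalized_adjacency(graph.adjacency)
    h = graph.node_features
    for li, w in enumerate(params):
        w = np.asarray(w, dtype=float)
        if h.shape[1] != w.shape[0]:
            raise ConfigurationError(
                f"layer {li}: input width {h.shape[1]} != weight rows {w.shape[0]}")
        h = ahat @ h @ w
        if li < len(params) - 1:
            h = activation(h)
    return h


# --------------------------------------------------------------------------- #
# Table I/O
# --------------------------------------------------------------------------- #

def read_multifidelity_table(path, column_map: dict | None = None,
                             task_type: str = "regression") -> MultiFidelityDataset:
    """Read a delimited multi-fidelity table.

    ``column_map`` maps roles to column names: ``{"smiles": ..., "mol_id": ...,
    "lf": ..., "hf": ..., "split": ..., "extra_lf": [...]}``.  Defaults to the
    package CSV dialect (``mol_id,smiles,lf,hf,split``). Missing cells become
    absent labels.
    """
    df = pd.read_csv(path)
    cmap = {"smiles": "smiles", "mol_id": "mol_id", "lf": "lf", "hf": "hf",
            "split": "split", "extra_lf": []}
    if column_map:
        cmap.update(column_map)
    if cmap["smiles"] not in df.columns:
        raise SchemaError(f"missing SMILES column {cmap['smiles']!r}")
    label_cols = [c for c in (cmap["lf"], cmap["hf"]) if c in df.columns]
    label_cols += [c for c in cmap["extra_lf"] if c in df.columns]
    if not label_cols:
        raise SchemaError("no mapped label column found in table")

    def cell(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    records = []
    for i, row in df.iterrows():
        mol_id = str(row[cmap["mol_id"]]) if cmap["mol_id"] in df.columns else f"row{i}"
        split = None
        if cmap["split"] in df.columns and not pd.isna(row[cmap["split"]]):
            split = str(row[cmap["split"]])
        extra = {c: cell(row, c) for c in cmap["extra_lf"] if cell(row, c) is not None}
        records.append(MultiFidelityRecord(
            mol_id=mol_id, smiles=str(row[cmap["smiles"]]),
            lf_label=cell(row, cmap["lf"]), hf_label=cell(row, cmap["hf"]),
            split=split, extra_lf_labels=extra))
    fidelity_names = ["lf"] + list(cmap["extra_lf"]) + ["hf"] if cmap["extra_lf"] \
        else ("lf", "hf")
    return MultiFidelityDataset(records, task_type=task_type,
                                fidelity_names=tuple(fidelity_names))


def write_multifidelity_table(dataset: MultiFidelityDataset, path) -> None:
    """Write the CSV dialect read back by :func:`read_multifidelity_table`."""
    extra_cols: list = []
    for r in dataset.records:
        for k in r.extra_lf_labels:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = []
    for r in dataset.records:
        row = {"mol_id": r.mol_id, "smiles": r.smiles,
               "lf": r.lf_label, "hf": r.hf_label, "split": r.split}
        for k in extra_cols:
            row[k] = r.extra_lf_labels.get(k)
        rows.append(row)
    cols = ["mol_id", "smiles", "lf"] + extra_cols + ["hf", "split"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False)
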