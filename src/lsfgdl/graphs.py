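"""Molecular graph construction: the 2D / 3D / 2DQM / 3DQM variants.

An input molecule becomes a graph of atoms (explicit hydrogens included)
with a fixed one-hot feature scheme: twelve atom types
(H, C, N, O, F, P, S, Cl, Br, I, Si, Se), two ring flags, two aromaticity
flags and four hybridization types (sp3, sp2, sp, s) — 20 columns in total.
QM variants append one column of atomic partial charges from a pluggable
charge provider.  2D graphs connect covalently bonded atoms; 3D graphs
connect all atom pairs within a 4 Å radius (inclusive) of a conformer and
carry sine/cosine Fourier features of the interatomic distances, so every
coordinate-derived quantity is invariant under rigid motions (E(3)).

Conformer ensembles (ten per molecule by default) come from distance-
geometry embedding followed by UFF minimization and are bit-reproducible
for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .surf import substrate_mol

__all__ = [
    "ATOM_TYPES",
    "HYBRIDIZATIONS",
    "FEATURE_WIDTH",
    "GRAPH_VARIANTS",
    "MolGraph",
    "ConformerSet",
    "FeaturizationError",
    "ChargeProviderError",
    "atom_features",
    "partial_charges",
    "register_charge_provider",
    "covalent_edges",
    "radius_edges",
    "distance_features",
    "generate_conformers",
    "build_graph",
]

ATOM_TYPES = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "Si", "Se")
HYBRIDIZATIONS = ("SP3", "SP2", "SP", "S")  # fixed block order
FEATURE_WIDTH = len(ATOM_TYPES) + 2 + 2 + len(HYBRIDIZATIONS)  # 20
GRAPH_VARIANTS = ("2D", "3D", "2DQM", "3DQM")

DEFAULT_RADIUS = 4.0  # Å
DEFAULT_N_FREQUENCIES = 16
DEFAULT_N_CONFORMERS = 10


class FeaturizationError(ValueError):
    """Element or hybridization outside the supported one-hot scheme."""


class ChargeProviderError(RuntimeError):
    """A partial-charge provider failed; carries provider diagnostics."""


@dataclass
class MolGraph:
    """One molecule as a featurized graph (optionally one conformer)."""

    atom_features: np.ndarray  # (n_atoms, 20) or (n_atoms, 21) for QM
    edges: np.ndarray  # (n_edges, 2) directed pairs, symmetric
    variant: str
    coords: np.ndarray | None = None  # (n_atoms, 3) in Å
    distance_features: np.ndarray | None = None  # (n_edges, 2 * n_frequencies)
    conformer_id: int = -1

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    def to_json(self) -> str:
        payload = {
            "variant": self.variant,
            "conformer_id": self.conformer_id,
            "atom_features": self.atom_features.tolist(),
            "edges": self.edges.tolist(),
            "coords": None if self.coords is None else self.coords.tolist(),
            "distance_features": None
            if self.distance_features is None
            else self.distance_features.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MolGraph":
        d = json.loads(text)
        return cls(
            atom_features=np.array(d["atom_features"], dtype=float),
            edges=np.array(d["edges"], dtype=int).reshape(-1, 2),
            variant=d["variant"],
            coords=None if d["coords"] is None else np.array(d["coords"], dtype=float),
            distance_features=None
            if d["distance_features"] is None
            else np.array(d["distance_features"], dtype=float),
            conformer_id=d["conformer_id"],
        )


@dataclass
class ConformerSet:
    """Ten (by default) UFF-minimized conformers of one molecule."""

    molecule_id: str
    coords: list[np.ndarray]  # each (n_atoms, 3)
    seed: int

    def __len__(self) -> int:
        return len(self.coords)


# -------------------------------------------------------------- featurization


def _as_mol(molecule) -> Chem.Mol:
    if isinstance(molecule, str):
        return substrate_mol(molecule)
    return molecule


def atom_features(molecule) -> np.ndarray:
    """The (n_atoms x 20) one-hot atom feature matrix.

    Column blocks, in order: atom type (12), in-ring (yes/no), aromatic
    (yes/no), hybridization (sp3/sp2/sp/s).  Each block sums to exactly 1
    per atom.  Elements or hybridizations outside the scheme raise
    :class:`FeaturizationError` — no silent buckets.
    """
    mol = _as_mol(molecule)
    n = mol.GetNumAtoms()
    feats = np.zeros((n, FEATURE_WIDTH), dtype=float)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym not in ATOM_TYPES:
            raise FeaturizationError(f"unsupported element {sym!r} at atom {i}")
        feats[i, ATOM_TYPES.index(sym)] = 1.0
        feats[i, 12 + (0 if atom.IsInRing() else 1)] = 1.0
        feats[i, 14 + (0 if atom.GetIsAromatic() else 1)] = 1.0
        hyb = str(atom.GetHybridization())
        if sym == "H":
            hyb = "S"  # hydrogen carries the s slot
        if hyb not in HYBRIDIZATIONS:
            raise FeaturizationError(f"unsupported hybridization {hyb!r} at atom {i} ({sym})")
        feats[i, 16 + HYBRIDIZATIONS.index(hyb)] = 1.0
    return feats


# ------------------------------------------------------------ partial charges

_ELECTRONEGATIVITY = {  # Pauling scale
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98, "P": 2.19,
    "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66, "Si": 1.90, "Se": 2.55,
}


def _gasteiger(mol: Chem.Mol) -> np.ndarray:
    AllChem.ComputeGasteigerCharges(mol)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise ChargeProviderError("gasteiger produced non-finite charges")
    return q


def _electronegativity(mol: Chem.Mol) -> np.ndarray:
    """Bond-increment scheme: charge flows toward the more electronegative
    partner of every covalent bond; formal charges are added on top."""
    kappa = 0.08
    q = np.array([float(a.GetFormalCharge()) for a in mol.GetAtoms()])
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        try:
            ea = _ELECTRONEGATIVITY[a.GetSymbol()]
            eb = _ELECTRONEGATIVITY[b.GetSymbol()]
        except KeyError as exc:
            raise ChargeProviderError(f"no electronegativity for element {exc}") from None
        delta = kappa * (eb - ea)  # positive -> a loses density
        q[a.GetIdx()] += delta
        q[b.GetIdx()] -= delta
    return q


CHARGE_PROVIDERS: dict[str, callable] = {
    "gasteiger": _gasteiger,
    "electronegativity": _electronegativity,
}

DEFAULT_CHARGE_PROVIDER = "gasteiger"


def register_charge_provider(name: str, fn) -> None:
    """Register an external charge provider (e.g. a DFT surrogate)."""
    CHARGE_PROVIDERS[name] = fn


def partial_charges(molecule, provider: str = DEFAULT_CHARGE_PROVIDER) -> np.ndarray:
    """Per-atom partial charges in elementary charge units.

    The provider is looked up in the registry; its output is checked for
    charge conservation (sum equals the molecular formal charge within
    0.05 e).  Failures raise with provider diagnostics, never silent zeros.
    """
    mol = _as_mol(molecule)
    if provider not in CHARGE_PROVIDERS:
        raise ChargeProviderError(
            f"unknown charge provider {provider!r}; available: {sorted(CHARGE_PROVIDERS)}"
        )
    try:
        q = np.asarray(CHARGE_PROVIDERS[provider](mol), dtype=float)
    except ChargeProviderError:
        raise
    except Exception as exc:  # noqa: BLE001 - provider diagnostics forwarded
        raise ChargeProviderError(f"charge provider {provider!r} failed: {exc}") from exc
    if q.shape != (mol.GetNumAtoms(),):
        raise ChargeProviderError(f"provider {provider!r} returned wrong shape {q.shape}")
    formal = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    if abs(q.sum() - formal) > 0.05:
        raise ChargeProviderError(
            f"provider {provider!r} violates charge conservation: "
            f"sum={q.sum():.4f}, formal={formal}"
        )
    return q


# --------------------------------------------------------------------- edges


def covalent_edges(molecule) -> np.ndarray:
    """Directed edge list with one symmetric pair per covalent bond."""
    mol = _as_mol(molecule)
    pairs = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        pairs.append((i, j))
        pairs.append((j, i))
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def radius_edges(coords: np.ndarray, cutoff: float = DEFAULT_RADIUS) -> np.ndarray:
    """All ordered pairs (i, j), i != j, with Euclidean distance <= cutoff."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    n = coords.shape[0]
    mask = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)
    return np.stack([src, dst], axis=1).astype(int)


def distance_features(
    coords: np.ndarray,
    edges: np.ndarray,
    n_frequencies: int = DEFAULT_N_FREQUENCIES,
    d_max: float = DEFAULT_RADIUS,
) -> np.ndarray:
    """Fourier features of interatomic distances.

    For each edge with distance d the feature vector is
    [sin(d * w_1) ... sin(d * w_F), cos(d * w_1) ... cos(d * w_F)] with
    linearly spaced frequencies w_f = f * pi / d_max, f = 1..F.  Depends on
    coordinates only through pairwise distances, hence E(3)-invariant.
    """
    coords = np.asarray(coords, dtype=float)
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    d = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    freqs = np.arange(1, n_frequencies + 1) * np.pi / d_max
    phase = d[:, None] * freqs[None, :]
    return np.concatenate([np.sin(phase), np.cos(phase)], axis=1)


# ----------------------------------------------------------------- conformers


def generate_conformers(
    molecule,
    n: int = DEFAULT_N_CONFORMERS,
    seed: int = 0,
    molecule_id: str = "?",
    max_retries: int = 3,
) -> ConformerSet:
    """Distance-geometry embedding + UFF minimization, seeded.

    Produces exactly `n` conformers; embedding failures are retried a
    bounded number of times with perturbed seeds before raising.  The same
    (molecule, seed) pair always yields bit-identical coordinates.
    """
    base = _as_mol(molecule)
    for attempt in range(max_retries):
        mol = Chem.Mol(base)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + 7919 * attempt
        params.useRandomCoords = attempt > 0
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n, params=params)
        if len(ids) == n:
            AllChem.UFFOptimizeMoleculeConfs(mol)
            coords = [np.array(mol.GetConformer(i).GetPositions(), dtype=float) for i in ids]
            return ConformerSet(molecule_id=molecule_id, coords=coords, seed=int(seed))
    raise RuntimeError(
        f"conformer embedding failed for molecule {molecule_id!r} "
        f"after {max_retries} seed perturbations"
    )


def conformers_from_sdf(path, molecule_id: str = "?") -> ConformerSet:
    """Read externally supplied conformers from an SDF file.

    Every record must describe the same molecule; coordinates are taken in
    file order.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    coords = []
    n_atoms = None
    for mol in supplier:
        if mol is None:
            raise ValueError(f"unparseable SDF record in {path}")
        if n_atoms is None:
            n_atoms = mol.GetNumAtoms()
        elif mol.GetNumAtoms() != n_atoms:
            raise ValueError("SDF records describe molecules of different sizes")
        coords.append(np.array(mol.GetConformer().GetPositions(), dtype=float))
    if not coords:
        raise ValueError(f"no conformers found in {path}")
    return ConformerSet(molecule_id=molecule_id, coords=coords, seed=-1)


# -------------------------------------------------------------- graph builder


def build_graph(
    molecule,
    variant: str,
    conformer: np.ndarray | None = None,
    conformer_id: int = -1,
    charge_provider: str = DEFAULT_CHARGE_PROVIDER,
    cutoff: float = DEFAULT_RADIUS,
    n_frequencies: int = DEFAULT_N_FREQUENCIES,
) -> MolGraph:
    """Assemble one of the four graph variants for a molecule.

    3D variants require `conformer` coordinates and use radius edges plus
    Fourier distance features; QM variants append the partial-charge column
    to the atom features.
    """
    if variant not in GRAPH_VARIANTS:
        raise ValueError(f"unknown graph variant {variant!r}; expected one of {GRAPH_VARIANTS}")
    mol = _as_mol(molecule)
    feats = atom_features(mol)
    if variant.endswith("QM"):
        q = partial_charges(mol, charge_provider)
        feats = np.concatenate([feats, q[:, None]], axis=1)
    if variant.startswith("3D"):
        if conformer is None:
            raise ValueError(f"variant {variant} requires conformer coordinates")
        conformer = np.asarray(conformer, dtype=float)
        if conformer.shape != (mol.GetNumAtoms(), 3):
            raise ValueError(
                f"conformer shape {conformer.shape} does not match molecule "
                f"({mol.GetNumAtoms()} atoms)"
            )
        edges = radius_edges(conformer, cutoff)
        dfeat = distance_features(conformer, edges, n_frequencies, cutoff)
        return MolGraph(feats, edges, variant, conformer, dfeat, conformer_id)
    return MolGraph(feats, covalent_edges(mol), variant)
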