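"""Ligand ingestion and force-field preparation.

Reads small-molecule structures (SDF, MOL2, SMILES), assigns MMFF94 partial
charges, minimizes geometries, and loads the measured dissociation-rate
table.  The regression target throughout is y = -log10(k_off), k_off in 1/s;
residence time is tau = 1/k_off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: fixed seed for 3D embedding of SMILES inputs: one deterministic
#: lowest-effort conformer rather than an ensemble.
EMBED_SEED = 1987


class PreparationError(RuntimeError):
    """Force-field typing or setup failed for a molecule."""


@dataclass
class PreparedMolecule:
    """A 3D ligand with per-atom charges and interaction typing.

    ``lj_types`` are element symbols resolved against the shipped per-element
    LJ table; ``hbond_roles`` are none/donor/acceptor/both and gate the
    H-bond term of the field energy.
    """

    id: str
    elements: list[str]
    coords: np.ndarray  # (n, 3) Angstrom
    charges: np.ndarray  # (n,) e
    lj_types: list[str]
    hbond_roles: list[str]
    formal_charge: int = 0
    provenance: dict = field(default_factory=dict)
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if self.n_atoms < 1:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id!r} has non-finite coordinates")
        if len(self.charges) != self.n_atoms or len(self.elements) != self.n_atoms:
            raise ValueError(f"molecule {self.id!r}: inconsistent atom arrays")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def atoms(self) -> list[tuple[str, tuple[float, float, float], float, str, str]]:
        return [
            (el, tuple(xyz), q, lj, hb)
            for el, xyz, q, lj, hb in zip(
                self.elements, self.coords, self.charges, self.lj_types, self.hbond_roles
            )
        ]

    @property
    def masses(self) -> np.ndarray:
        pt = Chem.GetPeriodicTable()
        return np.array([pt.GetAtomicWeight(el) for el in self.elements])

    @property
    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (self.coords * m[:, None]).sum(axis=0) / m.sum()

    def check_charge_consistency(self, tol: float = 1e-3) -> None:
        total = float(self.charges.sum())
        if abs(total - self.formal_charge) > tol:
            raise ValueError(
                f"molecule {self.id!r}: partial charges sum to {total:.4f}, "
                f"formal charge is {self.formal_charge}"
            )


def _from_rdkit(mol: Chem.Mol, mol_id: str, provenance: dict) -> PreparedMolecule:
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())], dtype=float
    )
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    n = mol.GetNumAtoms()
    return PreparedMolecule(
        id=mol_id,
        elements=elements,
        coords=coords,
        charges=np.zeros(n),
        lj_types=list(elements),
        hbond_roles=["none"] * n,
        formal_charge=Chem.GetFormalCharge(mol),
        provenance=provenance,
        rdmol=mol,
    )


def _unique_id(base: str, seen: set[str]) -> str:
    mol_id = base
    k = 1
    while mol_id in seen:
        mol_id = f"{base}_{k}"
        k += 1
    return mol_id


def read_molecules(
    path: str | Path, fmt: str | None = None
) -> list[PreparedMolecule]:
    """Read molecules from SDF, MOL2 or SMILES into uncharged PreparedMolecules.

    SMILES inputs (one per line, optional tab-separated id) are hydrogen-added
    and embedded into a single fixed-seed 3D conformer.  Unparsable records
    are skipped with a logged per-record error; an input yielding zero
    molecules is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".sdf": "sdf", ".mol2": "mol2", ".smi": "smiles", ".smiles": "smiles"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    fmt = fmt.lower()

    mols: list[PreparedMolecule] = []
    seen: set[str] = set()
    provenance = {"source": str(path), "format": fmt}

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.error("record %d of %s failed to parse", i, path.name)
                continue
            base = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
            mols.append(_from_rdkit(mol, _unique_id(base, seen), dict(provenance)))
            seen.add(mols[-1].id)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
        if mol is not None:
            base = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
            mols.append(_from_rdkit(mol, _unique_id(base, seen), dict(provenance)))
    elif fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            base = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol_{i}"
            pm = molecule_from_smiles(smiles, mol_id=_unique_id(base, seen))
            if pm is None:
                logger.error("line %d of %s: SMILES %r failed", i, path.name, smiles)
                continue
            pm.provenance.update(provenance)
            mols.append(pm)
            seen.add(pm.id)
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    if not mols:
        raise ValueError(f"no molecules could be read from {path}")
    return mols


def molecule_from_smiles(
    smiles: str, mol_id: str = "mol", embed_seed: int = EMBED_SEED
) -> PreparedMolecule | None:
    """Parse a SMILES, add hydrogens and embed one deterministic 3D conformer."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = embed_seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        return None
    pm = _from_rdkit(mol, mol_id, {"smiles": smiles, "embed_seed": embed_seed})
    return pm


def _hbond_role(atom: Chem.Atom) -> str:
    """Heuristic donor/acceptor typing from element and attached hydrogens."""
    el = atom.GetSymbol()
    n_h = atom.GetTotalNumHs(includeNeighbors=True)
    if el == "O":
        return "both" if n_h > 0 else "acceptor"
    if el == "N":
        if n_h > 0:
            return "donor"
        if atom.GetFormalCharge() > 0:
            return "none"
        return "acceptor"
    return "none"


def prepare(
    mol: PreparedMolecule,
    max_steps: int = 5000,
    grad_tol: float = 0.05,
    nb_cutoff: float = 8.0,
) -> PreparedMolecule:
    """MMFF94-charge and minimize a molecule.

    Conjugate-gradient style minimization runs until the force norm drops
    below ``grad_tol`` (kcal/mol/A) or ``max_steps`` iterations; non-
    convergence is a logged warning, not an error.  Atoms MMFF94 cannot type
    abort that molecule with :class:`PreparationError`.
    """
    if mol.rdmol is None:
        raise PreparationError(
            f"molecule {mol.id!r} carries no bond graph; prepare() needs a "
            "structure read from SDF/MOL2/SMILES"
        )
    rdmol = Chem.Mol(mol.rdmol)
    props = AllChem.MMFFGetMoleculeProperties(rdmol)
    if props is None:
        exotic = sorted(
            {
                a.GetSymbol()
                for a in rdmol.GetAtoms()
                if a.GetSymbol() not in {"H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "Si"}
            }
        )
        raise PreparationError(
            f"MMFF94 cannot type molecule {mol.id!r}"
            + (f" (offending elements: {exotic})" if exotic else "")
        )
    ff = AllChem.MMFFGetMoleculeForceField(rdmol, props, nonBondedThresh=nb_cutoff)
    if ff is None:
        raise PreparationError(f"MMFF94 force field setup failed for {mol.id!r}")
    status = ff.Minimize(maxIts=max_steps, forceTol=grad_tol)
    if status == 1:
        logger.warning(
            "minimization of %s did not converge within %d steps", mol.id, max_steps
        )

    conf = rdmol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())]
    )
    charges = np.array(
        [props.GetMMFFPartialCharge(i) for i in range(rdmol.GetNumAtoms())]
    )
    roles = [_hbond_role(a) for a in rdmol.GetAtoms()]
    out = PreparedMolecule(
        id=mol.id,
        elements=[a.GetSymbol() for a in rdmol.GetAtoms()],
        coords=coords,
        charges=charges,
        lj_types=[a.GetSymbol() for a in rdmol.GetAtoms()],
        hbond_roles=roles,
        formal_charge=Chem.GetFormalCharge(rdmol),
        provenance={
            **mol.provenance,
            "prep": {
                "charges": "MMFF94",
                "max_steps": max_steps,
                "grad_tol": grad_tol,
                "nb_cutoff": nb_cutoff,
                "converged": status == 0,
            },
        },
        rdmol=rdmol,
    )
    out.check_charge_consistency()
    return out


@dataclass(frozen=True)
class KineticRecord:
    """A measured dissociation rate and its regression target y = -log10(k_off)."""

    molecule_id: str
    k_off: float  # 1/s
    y: float

    def __post_init__(self) -> None:
        if not self.k_off > 0:
            raise ValueError(f"{self.molecule_id}: k_off must be > 0, got {self.k_off}")
        expected = -math.log10(self.k_off)
        if abs(self.y - expected) > 1e-12:
            raise ValueError(f"{self.molecule_id}: y does not equal -log10(k_off)")


def kinetic_record(molecule_id: str, k_off: float) -> KineticRecord:
    return KineticRecord(molecule_id=molecule_id, k_off=k_off, y=-math.log10(k_off))


def load_kinetics(
    path: str | Path, koff_floor: float | None = None
) -> list[KineticRecord]:
    """Load the k_off table (columns ``molecule_id,k_off``) and transform to y.

    When ``koff_floor`` is given, fast-dissociating records with
    y = -log10(k_off) < koff_floor are dropped (the dropped count is logged),
    mirroring the practice of excluding very fast dissociators before
    modeling.
    """
    df = pd.read_csv(path)
    required = {"molecule_id", "k_off"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinetics CSV must have columns {sorted(required)}")
    dup = df["molecule_id"][df["molecule_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate molecule ids in kinetics CSV: {sorted(set(dup))}")
    bad = df[~(df["k_off"] > 0)]
    if len(bad):
        raise ValueError(
            "k_off must be > 0; offending records: "
            + ", ".join(f"{r.molecule_id}={r.k_off}" for r in bad.itertuples())
        )
    records = [kinetic_record(str(r.molecule_id), float(r.k_off)) for r in df.itertuples()]
    if koff_floor is not None:
        kept = [r for r in records if r.y >= koff_floor]
        n_dropped = len(records) - len(kept)
        logger.info(
            "koff_floor=%g: kept %d records, dropped %d fast dissociators",
            koff_floor,
            len(kept),
            n_dropped,
        )
        records = kept
    return records


def write_kinetics(records: list[KineticRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"molecule_id": [r.molecule_id for r in records], "k_off": [r.k_off for r in records]}
    ).to_csv(path, index=False)
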