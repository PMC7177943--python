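"""Deterministic synthetic inputs for every layer of the pipeline.

Three tiers, all pure functions of their parameters and a seed:

- toy molecules with hand-set coordinates/charges/roles, giving closed-form
  or by-construction field values;
- a congeneric ligand series built from a para-substituted N-methyl
  benzamide scaffold (an H-bond donor/acceptor head plus a tunable tail), so
  polar and hydrophobic fields are both nontrivial;
- planted descriptor tables X (166 manifest-named columns, exchangeable
  correlation rho) with y = X beta + noise, emulating the descriptor ->
  -log10(k_off) regression without any claim to real kinetics physics.

Random streams are namespaced per generator so adding a fixture never
perturbs an existing one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import PreparedMolecule, molecule_from_smiles, prepare
from .descriptors import default_catalog

logger = logging.getLogger(__name__)

_TOY_KINDS = ("lj_sphere", "dipole_pair", "tetrahedral_symmetric", "donor_acceptor_pair")


def _seed_for(namespace: str, seed: int) -> int:
    """Namespaced 31-bit child seed."""
    h = np.uint32(2166136261)
    for ch in f"{namespace}:{seed}".encode():
        h = np.uint32((int(h) ^ ch) * 16777619 & 0xFFFFFFFF)
    return int(h) % (2**31 - 1)


def make_toy_molecule(kind: str, **params) -> PreparedMolecule:
    """Hand-built molecules with known geometry for closed-form field tests.

    kinds:
      lj_sphere               one uncharged atom at the origin
                              (element="C", charge=0.0)
      dipole_pair             +q/-q atoms ``distance`` apart on x
                              (element="C", q=0.5, distance=2.0)
      tetrahedral_symmetric   four identical uncharged atoms on a tetrahedron
                              centered at the origin (element="C", scale=1.5);
                              center of mass at the centroid, zero dipole
      donor_acceptor_pair     an N donor and an O acceptor ``distance`` apart
                              (distance=4.0)
    """
    if kind not in _TOY_KINDS:
        raise ValueError(f"unknown toy kind {kind!r}; expected one of {_TOY_KINDS}")
    if kind == "lj_sphere":
        el = params.get("element", "C")
        q = params.get("charge", 0.0)
        pos = np.asarray(params.get("position", (0.0, 0.0, 0.0)), dtype=float)
        return PreparedMolecule(
            id=params.get("id", "lj_sphere"),
            elements=[el], coords=pos[None, :], charges=np.array([q]),
            lj_types=[el], hbond_roles=["none"],
            formal_charge=int(round(q)), provenance={"fixture": kind},
        )
    if kind == "dipole_pair":
        el = params.get("element", "C")
        q = params.get("q", 0.5)
        d = params.get("distance", 2.0)
        return PreparedMolecule(
            id=params.get("id", "dipole_pair"),
            elements=[el, el],
            coords=np.array([[-d / 2, 0, 0], [d / 2, 0, 0]]),
            charges=np.array([q, -q]),
            lj_types=[el, el], hbond_roles=["none", "none"],
            formal_charge=0, provenance={"fixture": kind},
        )
    if kind == "tetrahedral_symmetric":
        el = params.get("element", "C")
        s = params.get("scale", 1.5)
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) * s / np.sqrt(3.0)
        return PreparedMolecule(
            id=params.get("id", "tetrahedral_symmetric"),
            elements=[el] * 4, coords=verts, charges=np.zeros(4),
            lj_types=[el] * 4, hbond_roles=["none"] * 4,
            formal_charge=0, provenance={"fixture": kind},
        )
    # donor_acceptor_pair
    d = params.get("distance", 4.0)
    return PreparedMolecule(
        id=params.get("id", "donor_acceptor_pair"),
        elements=["N", "O"],
        coords=np.array([[-d / 2, 0, 0], [d / 2, 0, 0]]),
        charges=np.array([0.0, 0.0]),
        lj_types=["N", "O"], hbond_roles=["donor", "acceptor"],
        formal_charge=0, provenance={"fixture": kind},
    )


#: para substituents for the benzamide scaffold, polar and apolar
_SUBSTITUENTS = ("", "F", "Cl", "C", "CC", "C(C)C", "OC", "O", "N", "C(F)(F)F", "OCC", "CNC")


def make_ligand_series(n: int, seed: int = 0) -> list[PreparedMolecule]:
    """Deterministic congeneric series of prepared (charged, minimized) ligands.

    Built from ``CNC(=O)c1ccc(R)cc1`` with seeded para substituents; at
    least 0.9 n molecules are guaranteed (embedding/typing failures are
    skipped with a log message).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(_seed_for("ligand_series", seed))
    order = rng.permutation(len(_SUBSTITUENTS))
    out: list[PreparedMolecule] = []
    i = 0
    attempts = 0
    while len(out) < n and attempts < 3 * n + len(_SUBSTITUENTS):
        sub = _SUBSTITUENTS[order[i % len(_SUBSTITUENTS)]]
        i += 1
        attempts += 1
        smiles = f"CNC(=O)c1ccc({sub})cc1" if sub else "CNC(=O)c1ccccc1"
        mol_id = f"lig_{len(out):02d}"
        pm = molecule_from_smiles(
            smiles, mol_id=mol_id, embed_seed=_seed_for(f"embed:{attempts}", seed)
        )
        if pm is None:
            logger.warning("embedding failed for %s", smiles)
            continue
        try:
            out.append(prepare(pm))
        except Exception as exc:
            logger.warning("preparation failed for %s: %s", smiles, exc)
    if len(out) < int(np.ceil(0.9 * n)):
        raise RuntimeError(f"ligand series generation yielded only {len(out)}/{n}")
    return out[:n]


def write_series_sdf(mols: list[PreparedMolecule], path) -> None:
    """Export prepared fixture molecules as a V2000 SDF (ids as titles)."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for pm in mols:
        if pm.rdmol is None:
            raise ValueError(f"{pm.id} has no bond graph; cannot write SDF")
        mol = Chem.Mol(pm.rdmol)
        mol.SetProp("_Name", pm.id)
        writer.write(mol)
    writer.close()


def make_series_kinetics(mols: list[PreparedMolecule], seed: int = 0,
                         sigma: float = 0.2) -> pd.DataFrame:
    """Synthetic k_off table for a fixture series (columns molecule_id,k_off).

    y = -log10(k_off) is a deterministic linear surrogate in molecular size
    (heavy-atom count) plus seeded noise; no kinetic realism is claimed.
    """
    rng = np.random.default_rng(_seed_for("series_kinetics", seed))
    rows = []
    for pm in mols:
        heavy = sum(1 for el in pm.elements if el != "H")
        y = 0.25 * heavy - 1.5 + sigma * rng.standard_normal()
        rows.append({"molecule_id": pm.id, "k_off": 10.0 ** (-y)})
    return pd.DataFrame(rows)


@dataclass
class PlantedDataset:
    """A feature table with known true predictors and y = X beta + noise."""

    X: pd.DataFrame
    y: pd.Series
    true_vars: list[str]
    beta: np.ndarray
    sigma: float
    rho: float
    seed: int


def make_planted_dataset(
    n: int,
    true_vars: tuple[str, ...] = ("W3-N3+", "D8-DRY"),
    beta: tuple[float, ...] = (2.0, -1.0),
    sigma: float = 0.3,
    rho: float = 0.3,
    seed: int = 0,
) -> PlantedDataset:
    """Gaussian 166-column table with an exchangeable correlation rho.

    X columns carry the manifest names; y = X[true_vars] @ beta + N(0, sigma^2).
    """
    catalog = default_catalog()
    for v in true_vars:
        if v not in catalog:
            raise KeyError(f"true variable {v!r} is not in the descriptor manifest")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0.0 <= rho <= 0.95:
        raise ValueError(f"rho must be in [0, 0.95], got {rho}")
    if len(beta) != len(true_vars):
        raise ValueError("beta and true_vars must have equal length")
    rng = np.random.default_rng(_seed_for("planted", seed))
    p = len(catalog)
    z = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, p))
    X = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
    Xdf = pd.DataFrame(X, columns=catalog.names,
                       index=[f"s{i:03d}" for i in range(n)])
    beta_arr = np.asarray(beta, dtype=float)
    y = Xdf[list(true_vars)].to_numpy() @ beta_arr + sigma * rng.standard_normal(n)
    return PlantedDataset(
        X=Xdf, y=pd.Series(y, index=Xdf.index),
        true_vars=[catalog.resolve(v).name for v in true_vars],
        beta=beta_arr, sigma=sigma, rho=rho, seed=seed,
    )
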