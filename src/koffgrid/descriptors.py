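"""VolSurf-style descriptors: reducing interaction fields to a 166-slot vector.

Families
--------
- V / S: molecular volume and surface of the repulsive core of the water
  field (points with E >= +0.2 kcal/mol), i.e. the water solvent-excluded
  volume, in A^3 / A^2.
- W1-W8 / D1-D8: hydrophilic / hydrophobic region volumes — sublevel-set
  volumes of a probe field on a ladder of energy levels (W ladder: -0.2 to
  -6.0 kcal/mol; D ladder for the DRY probe: -0.2 to -1.6 kcal/mol).
- IW1-8 / ID1-8: integy moments — the distance from the molecular center of
  mass to the barycenter of the sublevel set at each ladder level; the
  spatial unbalance of favorable interaction regions.
- CW1-8: capacity factors, W_k / S.
- Emin1-3 and D12/D13/D23: the three deepest local field minima and the
  pairwise distances between them.
- BV11/BV21 (at -1.0) and BV12/BV22 (at -3.0): best volumes, the largest and
  second-largest connected-component volumes at the two levels.
- A: amphiphilic moment, distance between the hydrophilic-domain barycenter
  (water field below -3.0) and the hydrophobic-domain barycenter (DRY field
  below -0.8).
- Globals: POL (additive polarizability), MW, RUG (rugosity S/V), GLOB
  (globularity), DIAM (molecular diameter).

Missing features (e.g. fewer than three minima) are encoded as 0, never as
missing values, so downstream regression always sees a dense table.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import PreparedMolecule
from .grid import (
    GridSpec,
    MIFGrid,
    build_grid,
    local_minima,
    sublevel_components,
    sublevel_volume,
    superlevel_volume,
)
from .fields import compute_field
from .probes import (
    ProbeDefinition,
    default_polarizability_table,
    default_probe_table,
)

logger = logging.getLogger(__name__)

#: energy ladders (kcal/mol), shallow to deep
W_LADDER = (-0.2, -0.5, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0)
D_LADDER = (-0.2, -0.4, -0.6, -0.8, -1.0, -1.2, -1.4, -1.6)
BV_LEVELS = (-1.0, -3.0)
CORE_LEVEL = 0.2  # kcal/mol, repulsive-core threshold for V and S
AMPHI_PHILIC_LEVEL = -3.0
AMPHI_PHOBIC_LEVEL = -0.8

POLAR_PROBES = ("O", "O::", "N1", "N:=", "N3+", "O-")


@dataclass(frozen=True)
class DescriptorSpec:
    """One manifest entry: name, source probe, family, energy level(s), units."""

    name: str
    probe: str  # probe name, or "-" for probe-independent globals
    family: str
    levels: tuple[float, ...] = ()
    units: str = ""


def _probe_block(probe: str, ladder, with_integy: bool, with_capacity: bool,
                 with_bv: bool) -> list[DescriptorSpec]:
    prefix = "D" if probe == "DRY" else "W"
    iprefix = "ID" if probe == "DRY" else "IW"
    specs = [
        DescriptorSpec(f"{prefix}{k}-{probe}", probe, "ladder", (ladder[k - 1],), "A^3")
        for k in range(1, 9)
    ]
    if with_integy:
        specs += [
            DescriptorSpec(f"{iprefix}{k}-{probe}", probe, "integy", (ladder[k - 1],), "A")
            for k in range(1, 9)
        ]
    if with_capacity:
        specs += [
            DescriptorSpec(f"CW{k}-{probe}", probe, "capacity", (ladder[k - 1],), "A")
            for k in range(1, 9)
        ]
    specs += [
        DescriptorSpec(f"Emin{k}-{probe}", probe, "emin", (), "kcal/mol")
        for k in (1, 2, 3)
    ]
    specs += [
        DescriptorSpec(f"D{ab}-{probe}", probe, "emin_distance", (), "A")
        for ab in ("12", "13", "23")
    ]
    if with_bv:
        specs += [
            DescriptorSpec(f"BV1{lvl}-{probe}", probe, "best_volume",
                           (BV_LEVELS[lvl - 1],), "A^3")
            for lvl in (1, 2)
        ] + [
            DescriptorSpec(f"BV2{lvl}-{probe}", probe, "best_volume_2",
                           (BV_LEVELS[lvl - 1],), "A^3")
            for lvl in (1, 2)
        ]
        # manifest order BV11, BV21, BV12, BV22
        bv = specs[-4:]
        specs[-4:] = [bv[0], bv[2], bv[1], bv[3]]
    return specs


def build_manifest() -> list[DescriptorSpec]:
    """The ordered 166-descriptor manifest over the nine probes."""
    specs: list[DescriptorSpec] = [
        DescriptorSpec("V-OH2", "OH2", "volume", (CORE_LEVEL,), "A^3"),
        DescriptorSpec("S-OH2", "OH2", "surface", (CORE_LEVEL,), "A^2"),
    ]
    specs += _probe_block("OH2", W_LADDER, with_integy=True, with_capacity=True,
                          with_bv=True)
    specs += _probe_block("DRY", D_LADDER, with_integy=True, with_capacity=False,
                          with_bv=True)
    for probe in POLAR_PROBES:
        specs += _probe_block(probe, W_LADDER, with_integy=False,
                              with_capacity=False, with_bv=False)
    specs += _probe_block("BOTH", W_LADDER, with_integy=False,
                          with_capacity=False, with_bv=False)
    specs += [
        DescriptorSpec("POL", "-", "polarizability", (), "A^3"),
        DescriptorSpec("A", "-", "amphiphilic", (AMPHI_PHILIC_LEVEL, AMPHI_PHOBIC_LEVEL), "A"),
        DescriptorSpec("MW", "-", "molecular_weight", (), "Da"),
        DescriptorSpec("RUG", "-", "rugosity", (), "1/A"),
        DescriptorSpec("GLOB", "-", "globularity", (), ""),
        DescriptorSpec("DIAM", "-", "diameter", (), "A"),
    ]
    return specs


#: unsuffixed ladder names conventionally refer to the water probe
_ALIASES = {f"W{k}": f"W{k}-OH2" for k in range(1, 9)}
_ALIASES.update({"V": "V-OH2", "S": "S-OH2"})


class DescriptorCatalog:
    """Ordered, named manifest of the descriptor vector (166 slots)."""

    def __init__(self, manifest: list[DescriptorSpec] | None = None):
        self.manifest = manifest if manifest is not None else build_manifest()
        self.names = [s.name for s in self.manifest]
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        self._by_name = {s.name: s for s in self.manifest}

    def __len__(self) -> int:
        return len(self.manifest)

    def resolve(self, name: str) -> DescriptorSpec:
        """Look a descriptor up by name, accepting unsuffixed water aliases."""
        key = _ALIASES.get(name, name)
        if key not in self._by_name:
            raise KeyError(f"unknown descriptor {name!r}")
        return self._by_name[key]

    def __contains__(self, name: str) -> bool:
        return _ALIASES.get(name, name) in self._by_name

    def to_yaml(self, path: str | Path) -> None:
        payload = [
            {
                "name": s.name,
                "probe": s.probe,
                "family": s.family,
                "levels": list(s.levels),
                "units": s.units,
            }
            for s in self.manifest
        ]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@functools.cache
def default_catalog() -> DescriptorCatalog:
    return DescriptorCatalog()


# ---------------------------------------------------------------------------
# individual descriptor operations
# ---------------------------------------------------------------------------

def molecular_volume(field_oh2: MIFGrid, core_level: float = CORE_LEVEL) -> float:
    """Water solvent-excluded volume: voxels where the water field is repulsive."""
    return superlevel_volume(field_oh2, core_level)


def molecular_surface(field_oh2: MIFGrid, core_level: float = CORE_LEVEL) -> float:
    """Surface (A^2) of the repulsive core: exposed voxel faces x spacing^2."""
    core = field_oh2.energies >= core_level
    sp = field_oh2.grid.spacing
    faces = 0
    for axis in range(3):
        padded = np.pad(core, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
        faces += int(np.count_nonzero(np.diff(padded, axis=axis)))
    return faces * sp * sp


def ladder_volumes(field: MIFGrid, ladder=W_LADDER) -> list[float]:
    """Sublevel-set volumes over an energy ladder (non-increasing sequence)."""
    return [sublevel_volume(field, level) for level in ladder]


def integy_moments(
    field: MIFGrid, mol: PreparedMolecule, ladder=W_LADDER
) -> list[float]:
    """Distance from the center of mass to each ladder level's region barycenter."""
    com = mol.center_of_mass
    origin = np.asarray(field.grid.origin)
    out = []
    for level in ladder:
        idx = np.argwhere(field.energies < level)
        if len(idx) == 0:
            out.append(0.0)
            continue
        bary = origin + idx.mean(axis=0) * field.grid.spacing
        out.append(float(np.linalg.norm(bary - com)))
    return out


def emin_descriptors(field: MIFGrid) -> tuple[float, float, float, float, float, float]:
    """(Emin1, Emin2, Emin3, d12, d13, d23); zeros where minima are absent."""
    minima = local_minima(field, max_count=3)
    energies = [m[0] for m in minima] + [0.0] * (3 - len(minima))
    positions = [m[1] for m in minima]

    def dist(a: int, b: int) -> float:
        if len(positions) <= max(a, b):
            return 0.0
        return float(np.linalg.norm(positions[a] - positions[b]))

    return (energies[0], energies[1], energies[2], dist(0, 1), dist(0, 2), dist(1, 2))


def best_volumes(field: MIFGrid, levels=BV_LEVELS) -> tuple[float, float, float, float]:
    """(BV11, BV21, BV12, BV22): rank-1/rank-2 component volumes at both levels."""
    out = []
    for level in levels:
        comps = sublevel_components(field, level)
        v1 = comps[0][0] if len(comps) > 0 else 0.0
        v2 = comps[1][0] if len(comps) > 1 else 0.0
        out.append((v1, v2))
    return (out[0][0], out[0][1], out[1][0], out[1][1])


def amphiphilic_moment(
    field_oh2: MIFGrid,
    field_dry: MIFGrid,
    philic_level: float = AMPHI_PHILIC_LEVEL,
    phobic_level: float = AMPHI_PHOBIC_LEVEL,
) -> float:
    """Distance between the hydrophilic and hydrophobic domain barycenters."""
    if field_oh2.grid != field_dry.grid:
        raise ValueError("amphiphilic moment requires both fields on the same grid")
    origin = np.asarray(field_oh2.grid.origin)
    sp = field_oh2.grid.spacing
    philic = np.argwhere(field_oh2.energies < philic_level)
    phobic = np.argwhere(field_dry.energies < phobic_level)
    if len(philic) == 0 or len(phobic) == 0:
        return 0.0
    b1 = origin + philic.mean(axis=0) * sp
    b2 = origin + phobic.mean(axis=0) * sp
    return float(np.linalg.norm(b1 - b2))


def polarizability(mol: PreparedMolecule, table: dict[str, float] | None = None) -> float:
    """Additive average molecular polarizability (A^3) from the shipped table."""
    table = table if table is not None else default_polarizability_table()
    if not table:
        raise ValueError("polarizability contribution table is empty")
    total = 0.0
    for el in mol.elements:
        if el not in table:
            raise KeyError(f"no polarizability contribution for element {el!r}")
        total += table[el]
    return total


def molecular_diameter(mol: PreparedMolecule) -> float:
    """Largest interatomic distance (A)."""
    if mol.n_atoms == 1:
        return 0.0
    d = np.linalg.norm(mol.coords[:, None, :] - mol.coords[None, :, :], axis=-1)
    return float(d.max())


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class _FieldBundle:
    """Lazy per-molecule cache of probe fields and derived aggregates."""

    def __init__(self, mol, grid, probe_table, cutoff, shift):
        self.mol = mol
        self.grid = grid
        self.table = probe_table
        self.cutoff = cutoff
        self.shift = shift
        self._fields: dict[str, MIFGrid] = {}
        self._emin: dict[str, tuple] = {}

    def field(self, probe_name: str) -> MIFGrid:
        if probe_name not in self._fields:
            self._fields[probe_name] = compute_field(
                self.mol,
                self.table[probe_name],
                self.grid,
                cutoff=self.cutoff,
                shift=self.shift,
                probe_table=self.table,
            )
        return self._fields[probe_name]

    def emin(self, probe_name: str) -> tuple:
        if probe_name not in self._emin:
            self._emin[probe_name] = emin_descriptors(self.field(probe_name))
        return self._emin[probe_name]


@dataclass
class DescriptorVector:
    """Named 166-slot descriptor profile of one molecule."""

    molecule_id: str
    values: pd.Series
    errors: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError(f"{self.molecule_id}: descriptor values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        key = _ALIASES.get(name, name)
        return float(self.values[key])


def _required_probes(spec: DescriptorSpec) -> tuple[str, ...]:
    if spec.family in ("volume", "surface", "rugosity", "globularity"):
        return ("OH2",)
    if spec.family == "amphiphilic":
        return ("OH2", "DRY")
    if spec.probe == "-":
        return ()
    return (spec.probe,)


def compute_descriptor_vector(
    mol: PreparedMolecule,
    catalog: DescriptorCatalog | None = None,
    spacing: float = 0.5,
    margin: float = 5.0,
    cutoff: float = 8.0,
    shift: bool = False,
    probe_table: dict[str, ProbeDefinition] | None = None,
    polarizability_table: dict[str, float] | None = None,
    names: list[str] | None = None,
    grid: GridSpec | None = None,
) -> DescriptorVector:
    """Compute the (full or restricted) descriptor vector for one molecule.

    With ``names`` given, only those descriptors (and the probe fields they
    need) are evaluated; the remaining slots are 0.  A failing descriptor
    poisons only its own slot (0 + an entry in ``errors``), never the run.
    """
    catalog = catalog or default_catalog()
    table = probe_table if probe_table is not None else default_probe_table()
    grid = grid if grid is not None else build_grid(mol, spacing=spacing, margin=margin)
    bundle = _FieldBundle(mol, grid, table, cutoff, shift)

    wanted = None if names is None else {catalog.resolve(n).name for n in names}
    values = pd.Series(0.0, index=catalog.names, dtype=float)
    errors: dict[str, str] = {}

    ladder_cache: dict[str, list[float]] = {}
    integy_cache: dict[str, list[float]] = {}
    bv_cache: dict[str, tuple] = {}

    def ladder_for(probe: str) -> list[float]:
        if probe not in ladder_cache:
            lad = D_LADDER if probe == "DRY" else W_LADDER
            ladder_cache[probe] = ladder_volumes(bundle.field(probe), lad)
        return ladder_cache[probe]

    def integy_for(probe: str) -> list[float]:
        if probe not in integy_cache:
            lad = D_LADDER if probe == "DRY" else W_LADDER
            integy_cache[probe] = integy_moments(bundle.field(probe), mol, lad)
        return integy_cache[probe]

    def bv_for(probe: str) -> tuple:
        if probe not in bv_cache:
            bv_cache[probe] = best_volumes(bundle.field(probe))
        return bv_cache[probe]

    for spec in catalog.manifest:
        if wanted is not None and spec.name not in wanted:
            continue
        try:
            values[spec.name] = _evaluate(spec, mol, bundle, ladder_for,
                                          integy_for, bv_for,
                                          polarizability_table)
        except Exception as exc:  # pragma: no cover - per-slot containment
            logger.warning("descriptor %s failed for %s: %s", spec.name, mol.id, exc)
            values[spec.name] = 0.0
            errors[spec.name] = str(exc)
    return DescriptorVector(molecule_id=mol.id, values=values, errors=errors)


def _evaluate(spec, mol, bundle, ladder_for, integy_for, bv_for, pol_table) -> float:
    fam = spec.family
    if fam == "volume":
        return molecular_volume(bundle.field("OH2"), spec.levels[0])
    if fam == "surface":
        return molecular_surface(bundle.field("OH2"), spec.levels[0])
    if fam == "ladder":
        k = int(spec.name[1 if spec.probe != "DRY" else 1])  # W<k>- / D<k>-
        return ladder_for(spec.probe)[k - 1]
    if fam == "integy":
        k = int(spec.name[2])  # IW<k>- / ID<k>-
        return integy_for(spec.probe)[k - 1]
    if fam == "capacity":
        k = int(spec.name[2])  # CW<k>-
        s = molecular_surface(bundle.field("OH2"))
        return ladder_for(spec.probe)[k - 1] / s if s > 0 else 0.0
    if fam == "emin":
        k = int(spec.name[4])  # Emin<k>-
        return bundle.emin(spec.probe)[k - 1]
    if fam == "emin_distance":
        ab = spec.name.split("-")[0][1:]  # D<ab>-
        return bundle.emin(spec.probe)[{"12": 3, "13": 4, "23": 5}[ab]]
    if fam == "best_volume":
        lvl = int(spec.name[3])  # BV1<lvl>-
        return bv_for(spec.probe)[{1: 0, 2: 2}[lvl]]
    if fam == "best_volume_2":
        lvl = int(spec.name[3])  # BV2<lvl>-
        return bv_for(spec.probe)[{1: 1, 2: 3}[lvl]]
    if fam == "amphiphilic":
        return amphiphilic_moment(bundle.field("OH2"), bundle.field("DRY"),
                                  spec.levels[0], spec.levels[1])
    if fam == "polarizability":
        return polarizability(mol, pol_table)
    if fam == "molecular_weight":
        return float(mol.masses.sum())
    if fam == "rugosity":
        v = molecular_volume(bundle.field("OH2"))
        s = molecular_surface(bundle.field("OH2"))
        return s / v if v > 0 else 0.0
    if fam == "globularity":
        v = molecular_volume(bundle.field("OH2"))
        s = molecular_surface(bundle.field("OH2"))
        return (36.0 * np.pi * v * v) ** (1.0 / 3.0) / s if s > 0 else 0.0
    if fam == "diameter":
        return molecular_diameter(mol)
    raise ValueError(f"unknown descriptor family {fam!r}")


def descriptor_table(vectors: list[DescriptorVector]) -> pd.DataFrame:
    """Stack descriptor vectors into a molecules x 166 DataFrame."""
    df = pd.DataFrame({v.molecule_id: v.values for v in vectors}).T
    df.index.name = "molecule_id"
    return df


def write_descriptor_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True)


def read_descriptor_csv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps write -> read -> write bit-identical
    df = pd.read_csv(path, index_col="molecule_id", float_precision="round_trip")
    df.index = df.index.astype(str)
    return df
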