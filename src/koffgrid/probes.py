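"""Probe definitions and parameter tables for the interaction-field engine.

The nine probes (OH2, DRY, O, O::, N1, N:=, N3+, O-, BOTH) each carry a
point charge, Lennard-Jones parameters and an H-bonding role/strength.  The
defaults ship as an editable YAML file (``data/probes.yaml``) together with
the per-element LJ parameters used for ligand atoms.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

PROBE_NAMES = ("OH2", "DRY", "O", "BOTH", "O::", "N1", "N:=", "N3+", "O-")

HBOND_ROLES = ("none", "donor", "acceptor", "both")


@dataclass(frozen=True)
class ProbeDefinition:
    """One probe of the interaction-field engine.

    ``components`` is set only for composite probes (BOTH), whose field is
    the pointwise minimum of its component probes' fields.
    """

    name: str
    charge: float  # e
    lj_epsilon: float  # kcal/mol
    lj_sigma: float  # Angstrom
    hbond_role: str = "none"
    hbond_strength: float = 0.0  # kcal/mol well depth
    hbond_r0: float = 2.9  # Angstrom, H-bond optimum distance
    components: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.name not in PROBE_NAMES:
            raise ValueError(f"unknown probe name {self.name!r}; expected one of {PROBE_NAMES}")
        if self.lj_sigma <= 0:
            raise ValueError(f"probe {self.name}: lj_sigma must be > 0")
        if self.hbond_role not in HBOND_ROLES:
            raise ValueError(f"probe {self.name}: bad hbond_role {self.hbond_role!r}")
        if self.name == "DRY" and self.charge != 0.0:
            raise ValueError("DRY probe must be uncharged")


@dataclass(frozen=True)
class AtomLJ:
    """Per-element Lennard-Jones parameters for ligand atoms."""

    element: str
    lj_epsilon: float
    lj_sigma: float


def _default_yaml(name: str) -> str:
    return resources.files("koffgrid.data").joinpath(name).read_text()


def load_probe_table(path: str | Path | None = None) -> dict[str, ProbeDefinition]:
    """Load the probe parameter table (shipped defaults when ``path`` is None)."""
    text = Path(path).read_text() if path is not None else _default_yaml("probes.yaml")
    raw = yaml.safe_load(text)
    table: dict[str, ProbeDefinition] = {}
    for name, params in raw["probes"].items():
        components = tuple(params.pop("components", ()))
        table[name] = ProbeDefinition(name=name, components=components, **params)
    missing = set(PROBE_NAMES) - set(table)
    if missing:
        raise ValueError(f"probe table is missing probes: {sorted(missing)}")
    return table


def load_atom_lj_table(path: str | Path | None = None) -> dict[str, AtomLJ]:
    """Per-element LJ parameters for ligand atoms."""
    text = Path(path).read_text() if path is not None else _default_yaml("probes.yaml")
    raw = yaml.safe_load(text)
    return {
        el: AtomLJ(element=el, **params) for el, params in raw["atoms"].items()
    }


def load_polarizability_table(path: str | Path | None = None) -> dict[str, float]:
    """Additive atomic polarizability contributions (A^3) for POL."""
    text = (
        Path(path).read_text()
        if path is not None
        else _default_yaml("polarizability.yaml")
    )
    raw = yaml.safe_load(text)
    return {el: float(v) for el, v in raw["contributions"].items()}


@functools.cache
def default_probe_table() -> dict[str, ProbeDefinition]:
    return load_probe_table()


@functools.cache
def default_atom_lj_table() -> dict[str, AtomLJ]:
    return load_atom_lj_table()


@functools.cache
def default_polarizability_table() -> dict[str, float]:
    return load_polarizability_table()
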