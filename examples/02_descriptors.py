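"""Compute the 166-slot descriptor vector for a real small molecule.

Embeds aspirin from SMILES, assigns MMFF94 charges, minimizes, then reduces
the nine probe fields to the named volume/moment/minima descriptors.
"""

import koffgrid as kg

mol = kg.molecule_from_smiles("CC(=O)Oc1ccccc1C(=O)O", mol_id="aspirin")
prepared = kg.prepare(mol)
vec = kg.compute_descriptor_vector(prepared)

print(f"{vec.molecule_id}: {len(vec)} descriptors")
for name, meaning in [
    ("V-OH2", "water solvent-excluded molecular volume (A^3)"),
    ("S-OH2", "molecular surface (A^2)"),
    ("W5-N3+", "hydrophilic volume of the NH3+ probe at -3.0 kcal/mol (A^3)"),
    ("D8-DRY", "hydrophobic volume of the DRY probe at -1.6 kcal/mol (A^3)"),
    ("Emin1-OH2", "deepest water-probe energy minimum (kcal/mol)"),
    ("IW8-OH2", "integy moment of the water probe at -6.0 kcal/mol (A)"),
    ("A", "amphiphilic moment (A)"),
    ("POL", "additive molecular polarizability (A^3)"),
]:
    print(f"  {name:10s} = {vec[name]:9.3f}   {meaning}")
# Large V-OH2 with small D8-DRY marks a bulky, weakly hydrophobic ligand --
# the profile associated with slower dissociation in the HSP90 and p38 models.
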