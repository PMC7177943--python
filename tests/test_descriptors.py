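"""Descriptor catalog contract and the individual descriptor operations."""

import numpy as np
import pandas as pd
import pytest

import koffgrid as kg
from conftest import synthetic_field
from koffgrid.descriptors import (
    W_LADDER,
    D_LADDER,
    best_volumes,
    default_catalog,
    emin_descriptors,
    integy_moments,
    ladder_volumes,
    molecular_surface,
    molecular_volume,
    polarizability,
    read_descriptor_csv,
    write_descriptor_csv,
)
from koffgrid.probes import default_polarizability_table

# descriptor names as they appear in published QSKR model tables
FIELD_STANDARD_NAMES = [
    "V-OH2", "D8-DRY", "W3-N3+", "Emin1-OH2", "D4-DRY", "A", "IW8-OH2",
    "W4-N:=", "D13-DRY", "POL", "W5-N3+", "W2-O", "Emin2-DRY", "D13-OH2",
    "BV21-DRY", "ID1-DRY", "BV21-OH2", "IW3-OH2", "W8", "D7-DRY", "D6-DRY",
    "W8-O", "IW7-OH2",
]


class TestCatalog:
    def test_manifest_has_exactly_166_unique_names(self):
        cat = default_catalog()
        assert len(cat) == 166
        assert len(set(cat.names)) == 166

    @pytest.mark.parametrize("name", FIELD_STANDARD_NAMES)
    def test_field_standard_descriptor_names_resolve(self, name):
        spec = default_catalog().resolve(name)
        assert spec.name in default_catalog().names

    def test_ladder_anchor_levels(self):
        cat = default_catalog()
        assert cat.resolve("W3-N3+").levels == (-1.0,)
        assert cat.resolve("W4-N:=").levels == (-2.0,)
        assert cat.resolve("W5-N3+").levels == (-3.0,)
        assert cat.resolve("D4-DRY").levels == (-0.8,)
        assert cat.resolve("D8-DRY").levels == (-1.6,)
        assert cat.resolve("IW8-OH2").levels == (-6.0,)

    def test_yaml_export_round_trips_names(self, tmp_path):
        cat = default_catalog()
        path = tmp_path / "manifest.yaml"
        cat.to_yaml(path)
        import yaml

        loaded = yaml.safe_load(path.read_text())
        assert [e["name"] for e in loaded] == cat.names


class TestVolumeAndSurface:
    def test_zero_field_has_no_repulsive_core(self):
        field = synthetic_field(np.zeros((5, 5, 5)))
        assert molecular_volume(field) == 0.0
        assert molecular_surface(field) == 0.0

    def test_volume_grows_with_lj_radius(self, probe_table):
        vols = []
        for el in ("H", "C", "S"):  # increasing sigma
            mol = kg.make_toy_molecule("lj_sphere", element=el)
            grid = kg.build_grid(mol, spacing=0.5, margin=5.0)
            field = kg.compute_field(mol, probe_table["OH2"], grid)
            vols.append(molecular_volume(field))
        assert vols[0] < vols[1] < vols[2]

    def test_cube_core_surface_matches_hand_count(self):
        e = np.zeros((8, 8, 8))
        e[2:4, 2:4, 2:4] = 1.0  # 2x2x2 voxel cube above +0.2
        field = synthetic_field(e, spacing=0.5)
        # a voxel cube of side 2 has 6 faces x 4 voxel-faces x (0.5 A)^2
        assert molecular_surface(field) == pytest.approx(24 * 0.25)


class TestLadders:
    def test_zero_field_gives_eight_zeros(self):
        field = synthetic_field(np.zeros((5, 5, 5)))
        assert ladder_volumes(field, W_LADDER) == [0.0] * 8

    def test_constructed_two_depth_well(self):
        e = np.zeros((8, 8, 8))
        e[1:4, 1:4, 1] = -0.5  # 9 voxels at -0.5
        e[2, 2, 1] = -3.0  # one deepened to -3.0
        field = synthetic_field(e, spacing=0.5)
        vols = ladder_volumes(field, D_LADDER)
        assert vols[0] == pytest.approx(9 * 0.125)  # level -0.2 counts all
        assert vols[7] == pytest.approx(1 * 0.125)  # level -1.6 counts the deep one

    def test_ladder_is_monotone_nonincreasing_for_real_fields(self, ligand_series, probe_table):
        mol = ligand_series[0]
        grid = kg.build_grid(mol)
        for probe_name in ("OH2", "DRY", "N3+"):
            field = kg.compute_field(mol, probe_table[probe_name], grid)
            ladder = D_LADDER if probe_name == "DRY" else W_LADDER
            vols = ladder_volumes(field, ladder)
            assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestIntegyMoments:
    def test_centrosymmetric_fixture_has_zero_moments(self, probe_table):
        mol = kg.make_toy_molecule("tetrahedral_symmetric")
        grid = kg.build_grid(mol, spacing=0.5, margin=4.0)
        field = kg.compute_field(mol, probe_table["DRY"], grid)
        moments = integy_moments(field, mol, D_LADDER)
        nonempty = [
            m for m, lvl in zip(moments, D_LADDER)
            if kg.sublevel_volume(field, lvl) > 0
        ]
        assert nonempty, "fixture must produce favorable DRY regions"
        assert all(m < 2 * grid.spacing for m in nonempty)

    def test_single_off_center_well_distance_by_hand(self):
        e = np.zeros((9, 9, 9))
        e[6, 4, 4] = -2.0
        field = synthetic_field(e, spacing=0.5)
        mol = kg.make_toy_molecule("lj_sphere", position=(2.0, 2.0, 2.0))
        (m,) = [integy_moments(field, mol, [-1.0])[0]]
        # well voxel at (3.0, 2.0, 2.0); center of mass at (2.0, 2.0, 2.0)
        assert m == pytest.approx(1.0)

    def test_empty_level_gives_zero(self):
        field = synthetic_field(np.zeros((4, 4, 4)))
        mol = kg.make_toy_molecule("lj_sphere")
        assert integy_moments(field, mol, [-1.0]) == [0.0]


class TestEminAndBestVolumes:
    def test_zero_field_gives_six_zeros(self):
        field = synthetic_field(np.zeros((5, 5, 5)))
        assert emin_descriptors(field) == (0.0,) * 6

    def test_two_wells_four_angstrom_apart(self):
        e = np.zeros((12, 12, 12))
        e[2, 2, 2] = -5.0
        e[10, 2, 2] = -3.0  # 8 voxels = 4.0 A along x
        field = synthetic_field(e, spacing=0.5)
        e1, e2, e3, d12, d13, d23 = emin_descriptors(field)
        assert (e1, e2, e3) == (-5.0, -3.0, 0.0)
        assert d12 == pytest.approx(4.0, abs=0.5)
        assert d13 == d23 == 0.0

    def test_emin_ordering_on_random_fields(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            field = synthetic_field(rng.normal(scale=2.0, size=(8, 8, 8)))
            e1, e2, e3, *_ = emin_descriptors(field)
            nonzero = [v for v in (e1, e2, e3) if v != 0.0]
            assert nonzero == sorted(nonzero)
            assert all(v < 0 for v in nonzero)

    def test_best_volumes_rank_and_construction(self):
        e = np.zeros((14, 14, 4))
        e[1:6, 1:3, 1] = -2.0  # 10 voxels
        e[8:11, 8:10, 1] = -2.0  # 6 voxels, disjoint
        field = synthetic_field(e, spacing=0.5)
        bv11, bv21, bv12, bv22 = best_volumes(field)
        assert bv11 == pytest.approx(10 * 0.125)
        assert bv21 == pytest.approx(6 * 0.125)
        assert bv12 == bv22 == 0.0  # nothing below -3.0
        assert bv11 + bv21 <= kg.sublevel_volume(field, -1.0) + 1e-12

    def test_single_well_has_zero_second_best(self):
        e = np.zeros((6, 6, 6))
        e[2:4, 2, 2] = -2.0
        field = synthetic_field(e, spacing=0.5)
        _, bv21, _, _ = best_volumes(field)
        assert bv21 == 0.0


class TestAmphiphilicMoment:
    def test_empty_domains_give_zero(self):
        f1 = synthetic_field(np.zeros((5, 5, 5)))
        f2 = synthetic_field(np.zeros((5, 5, 5)))
        assert kg.amphiphilic_moment(f1, f2) == 0.0

    def test_constructed_blobs_six_angstrom_apart(self):
        philic = np.zeros((16, 6, 6))
        phobic = np.zeros((16, 6, 6))
        philic[1, 2, 2] = -5.0
        phobic[13, 2, 2] = -2.0  # 12 voxels * 0.5 A apart on x
        f1 = synthetic_field(philic, spacing=0.5)
        f2 = synthetic_field(phobic, spacing=0.5)
        assert kg.amphiphilic_moment(f1, f2) == pytest.approx(6.0, abs=0.5)

    def test_coincident_domains_give_zero(self):
        e = np.zeros((6, 6, 6))
        e[3, 3, 3] = -5.0
        f1 = synthetic_field(e, spacing=0.5)
        f2 = synthetic_field(e, spacing=0.5)
        assert kg.amphiphilic_moment(f1, f2) == 0.0

    def test_mismatched_grids_rejected(self):
        f1 = synthetic_field(np.zeros((5, 5, 5)))
        f2 = synthetic_field(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="same grid"):
            kg.amphiphilic_moment(f1, f2)


class TestPolarizability:
    def test_methane_is_hand_sum_of_table_entries(self):
        mol = kg.prepare(kg.molecule_from_smiles("C", mol_id="methane"))
        table = default_polarizability_table()
        assert polarizability(mol) == pytest.approx(table["C"] + 4 * table["H"])

    def test_additive_over_fragments(self):
        a = kg.make_toy_molecule("lj_sphere", element="C")
        b = kg.make_toy_molecule("dipole_pair", element="O")
        combined = kg.PreparedMolecule(
            id="ab",
            elements=a.elements + b.elements,
            coords=np.vstack([a.coords, b.coords + 10.0]),
            charges=np.concatenate([a.charges, b.charges]),
            lj_types=a.lj_types + b.lj_types,
            hbond_roles=a.hbond_roles + b.hbond_roles,
        )
        assert polarizability(combined) == pytest.approx(
            polarizability(a) + polarizability(b)
        )

    def test_empty_table_and_unknown_element_rejected(self):
        mol = kg.make_toy_molecule("lj_sphere")
        with pytest.raises(ValueError):
            polarizability(mol, table={})
        with pytest.raises(KeyError, match="C"):
            polarizability(mol, table={"H": 0.4})


class TestDescriptorVector:
    def test_vector_has_166_finite_values_in_manifest_order(self, series_table):
        assert series_table.shape == (5, 166)
        assert list(series_table.columns) == default_catalog().names
        assert np.isfinite(series_table.to_numpy()).all()

    def test_identical_molecules_give_identical_vectors(self):
        mol = kg.make_toy_molecule("donor_acceptor_pair")
        v1 = kg.compute_descriptor_vector(mol)
        v2 = kg.compute_descriptor_vector(mol)
        pd.testing.assert_series_equal(v1.values, v2.values)

    def test_csv_round_trip_is_lossless(self, series_table, tmp_path):
        path = tmp_path / "desc.csv"
        write_descriptor_csv(series_table, path)
        back = read_descriptor_csv(path)
        pd.testing.assert_frame_equal(back, series_table)

    def test_restricted_computation_matches_full(self, ligand_series):
        mol = ligand_series[0]
        full = kg.compute_descriptor_vector(mol)
        sub = kg.compute_descriptor_vector(mol, names=["V-OH2", "POL", "D8-DRY"])
        for name in ("V-OH2", "POL", "D8-DRY"):
            assert sub[name] == full[name]
        assert sub["W3-N3+"] == 0.0  # untouched slot stays zero-filled

    def test_bv_rank_ordering_holds_for_series(self, series_table):
        for probe in ("OH2", "DRY"):
            assert (series_table[f"BV1{1}-{probe}"] >= series_table[f"BV2{1}-{probe}"]).all()
            assert (series_table[f"BV1{2}-{probe}"] >= series_table[f"BV2{2}-{probe}"]).all()

    def test_ladder_monotonicity_holds_for_series(self, series_table):
        for probe, prefix in (("OH2", "W"), ("DRY", "D"), ("N3+", "W"), ("BOTH", "W")):
            cols = [f"{prefix}{k}-{probe}" for k in range(1, 9)]
            vals = series_table[cols].to_numpy()
            assert (np.diff(vals, axis=1) <= 1e-12).all()
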