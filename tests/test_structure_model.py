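import numpy as np
import pytest

from resmap import structure_model as smod


class TestReadStructure:
    def test_counts_chains_residues_atoms(self, two_chain_pdb):
        st = smod.read_structure(two_chain_pdb)
        assert st.chains == ["A", "B"]
        assert len(st.residues) == 3
        assert len(st.atoms) == 15  # one atom per record

    def test_altloc_highest_occupancy_kept(self, two_chain_pdb):
        lines = two_chain_pdb.splitlines()
        ca = lines[1]
        alt_a = ca[:16] + "A" + ca[17:54] + "  0.60" + ca[60:]
        alt_b = ca[:16] + "B" + ca[17:30] + "  99.000   6.071  -5.147" + "  0.40" + ca[60:]
        text = "\n".join([lines[0], alt_a, alt_b] + lines[2:]) + "\n"
        st = smod.read_structure(text)
        ca_atom = next(a for a in st.atoms if a.name == "CA" and a.residue_id[0] == "A")
        assert ca_atom.coords[0] == pytest.approx(11.639)

    def test_malformed_coordinate_names_line(self, two_chain_pdb):
        bad = two_chain_pdb.replace(" 11.639", " xx.xxx")
        with pytest.raises(smod.PDBParseError, match="line 2"):
            smod.read_structure(bad)

    def test_missing_model_is_error(self, two_chain_pdb):
        with pytest.raises(smod.PDBParseError, match="model index"):
            smod.read_structure(two_chain_pdb, model_index=3)

    def test_waters_dropped(self, two_chain_pdb):
        text = two_chain_pdb.replace(
            "END",
            "HETATM   16  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O\nEND",
        )
        st = smod.read_structure(text)
        assert all(a.res_name != "HOH" for a in st.atoms)


class TestPolarHydrogens:
    def test_amide_h_geometry(self, two_chain_pdb):
        st = smod.place_polar_hydrogens(smod.read_structure(two_chain_pdb))
        h = next(a for a in st.atoms if a.name == "H" and a.residue_id == ("A", 2, ""))
        res = {a.name: a for a in st.residue_atoms(("A", 2, ""))}
        n, ca = res["N"].coords, res["CA"].coords
        c_prev = next(a for a in st.atoms if a.name == "C" and a.residue_id == ("A", 1, "")).coords
        assert np.linalg.norm(h.coords - n) == pytest.approx(1.0, abs=1e-9)
        # in the C(prev)-N-CA plane
        normal = np.cross(c_prev - n, ca - n)
        normal /= np.linalg.norm(normal)
        assert abs((h.coords - n) @ normal) < 1e-9
        # anti to the incoming carbonyl direction
        assert (h.coords - n) @ (n - c_prev) > 0

    def test_idempotent(self, two_chain_pdb):
        once = smod.place_polar_hydrogens(smod.read_structure(two_chain_pdb))
        twice = smod.place_polar_hydrogens(once)
        assert [a.name for a in twice.atoms] == [a.name for a in once.atoms]
        assert np.allclose(
            np.array([a.coords for a in twice.atoms]),
            np.array([a.coords for a in once.atoms]),
        )

    def test_n_terminus_skipped_with_warning(self, two_chain_pdb):
        with pytest.warns(UserWarning, match="no preceding carbonyl"):
            st = smod.place_polar_hydrogens(smod.read_structure(two_chain_pdb))
        assert not any(a.name == "H" and a.residue_id == ("A", 1, "") for a in st.atoms)


class TestAssignParameters:
    def test_lysine_amine_group_charge(self, two_chain_pdb):
        st = smod.assign_parameters(smod.place_polar_hydrogens(smod.read_structure(two_chain_pdb)))
        nz_group = [
            a for a in st.residue_atoms(("B", 1, "")) if a.name == "NZ" or a.name.startswith("HZ")
        ]
        assert sum(a.charge for a in nz_group) == pytest.approx(1.0, abs=0.01)

    def test_glycine_has_no_sidechain_atoms(self, two_chain_pdb):
        st = smod.assign_parameters(smod.place_polar_hydrogens(smod.read_structure(two_chain_pdb)))
        gly = st.residue_atoms(("A", 2, ""))
        assert not any(a.is_sidechain for a in gly)
        assert {a.name for a in gly} >= {"N", "CA", "C", "O"}

    def test_unknown_atom_strict_vs_permissive(self, two_chain_pdb):
        text = two_chain_pdb.replace(
            "ATOM      5  CB  ALA", "ATOM      5  XX1 ALA"
        )
        raw = smod.read_structure(text)
        with pytest.raises(smod.ParameterError, match="XX1"):
            smod.assign_parameters(raw, strict=True)
        with pytest.warns(UserWarning, match="unparameterized"):
            st = smod.assign_parameters(raw, strict=False)
        xx = next(a for a in st.atoms if a.name == "XX1")
        assert xx.charge == 0.0 and xx.radius > 0

    def test_net_residue_charges_integral(self, helix_dimer):
        replicate, _ = helix_dimer
        table = smod.load_parameter_table()
        first = {ch: min(r[1] for r in replicate.complex.residues if r[0] == ch)
                 for ch in replicate.complex.chains}
        for rid, net in replicate.complex.net_residue_charges().items():
            if rid[1] == first[rid[0]]:
                continue  # neutral-terminus patch
            nominal = table.nominal_residue_charge(replicate.complex.residue_name(rid))
            assert net == pytest.approx(nominal, abs=0.01), rid


class TestSplitAndReplicates:
    def test_split_conserves_atoms_and_coordinates(self, helix_dimer):
        replicate, _ = helix_dimer
        mono_a, mono_b = smod.split_complex(replicate)
        assert len(mono_a.atoms) + len(mono_b.atoms) == len(replicate.complex.atoms)
        for a_mono, a_cx in zip(
            mono_a.atoms, [a for a in replicate.complex.atoms if a.residue_id[0] == "A"]
        ):
            assert np.array_equal(a_mono.coords, a_cx.coords)

    def test_overlapping_sides_rejected(self, helix_dimer):
        replicate, _ = helix_dimer
        with pytest.raises(ValueError, match="overlap"):
            smod.DimerReplicate(replicate.complex, frozenset("A"), frozenset("A"))

    def test_single_dimer_yields_one_replicate(self, helix_dimer):
        replicate, _ = helix_dimer
        reps = smod.enumerate_replicates(replicate.complex)
        assert len(reps) == 1
        assert reps[0].side_a_chains | reps[0].side_b_chains == {"A", "B"}

    def test_two_copies_in_one_unit_yield_two_replicates(self, helix_dimer):
        from dataclasses import replace

        replicate, _ = helix_dimer
        shift = np.array([0.0, 0.0, 60.0])
        rename = {"A": "C", "B": "D"}
        n = len(replicate.complex.atoms)
        atoms = [replace(a, coords=a.coords.copy()) for a in replicate.complex.atoms]
        atoms += [
            replace(
                a,
                serial=a.serial + n,
                coords=a.coords + shift,
                residue_id=(rename[a.residue_id[0]],) + a.residue_id[1:],
            )
            for a in replicate.complex.atoms
        ]
        unit = smod.ParameterizedStructure(atoms, "two-dimer-unit")
        reps = smod.enumerate_replicates(unit)
        assert len(reps) == 2
        pairings = {tuple(sorted(r.side_a_chains | r.side_b_chains)) for r in reps}
        assert pairings == {("A", "B"), ("C", "D")}

    def test_isolated_chain_excluded_with_warning(self, helix_dimer):
        from dataclasses import replace

        replicate, _ = helix_dimer
        atoms = [replace(a, coords=a.coords.copy()) for a in replicate.complex.atoms]
        atoms += [
            replace(a, coords=a.coords + np.array([0.0, 80.0, 0.0]),
                    residue_id=("C",) + a.residue_id[1:])
            for a in replicate.complex.atoms
            if a.residue_id[0] == "A"
        ]
        unit = smod.ParameterizedStructure(atoms, "with-isolated")
        with pytest.warns(UserWarning, match="no contacting partner"):
            reps = smod.enumerate_replicates(unit)
        assert len(reps) == 1


def test_pqr_round_trip(helix_dimer):
    replicate, _ = helix_dimer
    text = smod.write_pqr(replicate.complex)
    back = smod.read_pqr(text)
    assert len(back.atoms) == len(replicate.complex.atoms)
    for a, b in zip(replicate.complex.atoms, back.atoms):
        assert np.allclose(a.coords, b.coords, atol=1.5e-3)
        assert b.charge == pytest.approx(a.charge, abs=1e-3)
        assert b.radius == pytest.approx(a.radius, abs=1e-3)


def test_written_pdb_reads_back(helix_dimer):
    replicate, _ = helix_dimer
    heavy = replicate.complex.subset(replicate.complex.heavy_mask)
    st = smod.read_structure(smod.write_pdb(heavy))
    assert len(st.atoms) == len(heavy.atoms)
    assert st.chains == heavy.chains
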