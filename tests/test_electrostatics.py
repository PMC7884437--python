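import numpy as np
import pytest

from resmap import electrostatics as es
from resmap import synthetic_data as syn

UNIFORM80 = es.PBEnvironment(eps_protein=80.0, eps_solvent=80.0, ionic_strength=0.0)
NO_SALT = es.PBEnvironment(eps_protein=1.0, eps_solvent=80.0, ionic_strength=0.0)


class TestGridsAndMaps:
    def test_empty_structure_uniform_solvent(self):
        grid = es.make_grid(np.zeros((1, 3)), spacing=1.0, margin=5.0)
        maps = es.build_dielectric_and_ion_maps(None, grid, NO_SALT)
        for eps in maps.eps_edges:
            assert np.all(eps == 80.0)
        assert maps.ion_accessible.all()

    def test_single_atom_cavity(self):
        grid = es.make_grid(np.zeros((1, 3)), spacing=1.0, margin=6.0)
        maps = es.build_dielectric_and_ion_maps(
            (np.zeros((1, 3)), np.array([2.0])), grid, NO_SALT
        )
        center = tuple(s // 2 for s in grid.shape)
        assert maps.eps_edges[0][center] < 80.0  # edge at the cavity
        assert maps.eps_edges[0][0, 0, 0] == 80.0  # far corner is solvent
        assert not maps.ion_accessible[center]
        assert maps.ion_accessible[0, 0, 0]

    def test_atom_outside_grid_rejected(self):
        grid = es.make_grid(np.zeros((1, 3)), spacing=1.0, margin=3.0)
        with pytest.raises(ValueError, match="outside grid"):
            es.build_dielectric_and_ion_maps(
                (np.array([[50.0, 0, 0]]), np.array([2.0])), grid, NO_SALT
            )

    def test_zero_ionic_strength_is_poisson_limit(self):
        assert es.PBEnvironment(ionic_strength=0.0).kappa2 == 0.0
        # Debye length ~3.07 A at 1 M for eps 80, T 298.15 K
        k2 = es.PBEnvironment(ionic_strength=1.0).kappa2
        assert 1.0 / np.sqrt(k2) == pytest.approx(3.07, abs=0.05)


class TestSolverOracles:
    def test_two_charge_coulomb_interaction(self):
        """Uniform dielectric 80: FD interaction within 5% of Coulomb's law."""
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(1.0, (3.0, 0, 0))])
        dg = es.binding_electrostatics(rep, UNIFORM80)
        assert dg == pytest.approx(332.0636 / (80 * 3), rel=0.05)

    def test_born_ion_transfer_energy(self):
        """eps 1 -> 80 transfer of a unit charge in a 2 A sphere."""
        system = syn.make_point_charge_system([(1.0, (0, 0, 0))], radius=2.0)
        protocol = es.GridProtocol()
        grids = es.make_grid_pair(system.coords, protocol)

        def total_energy(env):
            geo = es.PBGeometry(
                system.coords, system.radii, system.coords, grids, env, protocol
            )
            u = geo.atom_potentials(system.charges)
            return 0.5 * float(system.charges @ u[:, 0])

        uniform1 = es.PBEnvironment(eps_protein=1.0, eps_solvent=1.0, ionic_strength=0.0)
        transfer = total_energy(NO_SALT) - total_energy(uniform1)
        exact = -(332.0636 / 2.0) * (1.0 / 2.0) * (1.0 - 1.0 / 80.0)
        assert transfer == pytest.approx(exact, rel=0.05)

    def test_salt_screening_reduces_binding_magnitude(self):
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(-1.0, (4.0, 0, 0))])
        salt = es.PBEnvironment(eps_protein=80.0, eps_solvent=80.0, ionic_strength=0.145)
        dg0 = es.binding_electrostatics(rep, UNIFORM80)
        dgs = es.binding_electrostatics(rep, salt)
        assert dg0 == pytest.approx(-332.0636 / (80 * 4), rel=0.05)
        assert abs(dgs) < abs(dg0)

    def test_refinement_reduces_coulomb_error_monotonically(self):
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(1.0, (3.0, 0, 0))])
        exact = 332.0636 / (80 * 3)
        errors = []
        for spacing in (1.0, 0.7, 0.5):
            protocol = es.GridProtocol(spacing_coarse=2 * spacing, spacing_focus=spacing)
            dg = es.binding_electrostatics(rep, UNIFORM80, protocol)
            errors.append(abs(dg - exact))
        assert errors[0] >= errors[1] >= errors[2]

    def test_zero_charges_give_zero_potential(self):
        grid = es.make_grid(np.zeros((1, 3)), spacing=1.0, margin=5.0)
        maps = es.build_dielectric_and_ion_maps(None, grid, NO_SALT)
        u, _ = es.solve_lpb(np.zeros((1, 3)), np.zeros(1), maps)
        assert np.all(u == 0.0)

    def test_sor_and_cg_agree(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        q = np.array([1.0, -1.0])
        grid = es.make_grid(coords, spacing=1.0, margin=6.0)
        maps = es.build_dielectric_and_ion_maps((coords, np.full(2, 2.0)), grid, NO_SALT)
        u_cg, _ = es.solve_lpb(coords, q, maps, backend="cg", tolerance=1e-8)
        u_sor, _ = es.solve_lpb(coords, q, maps, backend="sor", tolerance=1e-7)
        assert np.allclose(u_cg, u_sor, atol=1e-3)

    def test_nonconvergence_raises(self):
        coords = np.zeros((1, 3))
        grid = es.make_grid(coords, spacing=1.0, margin=5.0)
        maps = es.build_dielectric_and_ion_maps((coords, np.array([2.0])), grid, NO_SALT)
        with pytest.raises(es.ConvergenceError):
            es.solve_lpb(coords, np.ones(1), maps, backend="sor", max_iter=2)


class TestInterfaceShell:
    def test_far_apart_system_has_empty_shell(self):
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(1.0, (20.0, 0, 0))])
        assert es.interface_shell(rep, cutoff=15.0) == []

    @pytest.mark.parametrize("distance,included", [(14.9, True), (15.1, False)])
    def test_cutoff_boundary_inclusive(self, distance, included):
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(1.0, (distance, 0, 0))])
        shell = es.interface_shell(rep, cutoff=15.0)
        assert (len(shell) == 2) is included

    def test_contact_residues_all_in_shell(self, helix_scan):
        replicate, _, shell, _, _ = helix_scan
        # both chains ~9 A apart: every residue is within the 15 A shell
        assert set(shell) == set(replicate.complex.residues)


class TestResidueDdg:
    def test_additivity_sc_plus_mc_is_res(self, helix_scan):
        _, _, _, elec, _ = helix_scan
        for rec in elec.values():
            assert rec.ddg_elec_sc + rec.ddg_elec_mc == pytest.approx(rec.ddg_elec_res)

    def test_planted_salt_bridge_clears_threshold(self, helix_scan):
        _, truth, _, elec, _ = helix_scan
        for rid in truth.sc_elec:
            assert elec[rid].ddg_elec_sc >= 1.0

    def test_uncharged_sidechain_exact_zero(self, helix_scan):
        """Ala side chains carry no charge: side-chain deletion changes nothing."""
        replicate, truth, _, elec, _ = helix_scan
        ala = [r for r in elec.values() if r.res_name == "ALA"]
        assert ala and all(r.ddg_elec_sc == 0.0 for r in ala)

    def test_single_residue_wrapper_matches_scan(self, helix_scan):
        replicate, truth, _, elec, _ = helix_scan
        rid = sorted(truth.sc_elec)[0]
        val = es.residue_ddg_elec(replicate, rid, mode="sidechain")
        assert val == pytest.approx(elec[rid].ddg_elec_sc, abs=0.05)

    def test_unknown_residue_rejected(self, helix_dimer):
        replicate, _ = helix_dimer
        with pytest.raises(KeyError):
            es.residue_ddg_elec(replicate, ("Z", 99, ""))

    def test_uniform_dielectric_binding_matches_coulomb_sum(self):
        """Opposite charges 4 A apart, uniform eps 80: dG_bind ~ -1.038."""
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(-1.0, (4.0, 0, 0))])
        dg = es.binding_electrostatics(rep, UNIFORM80)
        assert dg == pytest.approx(-332.0636 / (80 * 4), rel=0.05)

    def test_neutral_partner_contributes_nothing(self):
        rep = syn.make_point_charge_dimer([(1.0, (0, 0, 0))], [(0.0, (4.0, 0, 0))])
        dg = es.binding_electrostatics(rep, UNIFORM80)
        assert dg == pytest.approx(0.0, abs=1e-4)
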