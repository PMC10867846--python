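"""Fitting procedures, all checked by parameter recovery from the
synthetic generator (which uses the same physics but a known truth), by
independent oracles, and by their structural invariants."""

import numpy as np
import pytest

from dpolkit.chem_core import (
    Molecule,
    PolarizabilityTypeSet,
    assign_polarizabilities,
    bond_type_matrix,
    symmetry_classes,
)
from dpolkit.fitting import (
    PolFitProblem,
    RestraintSpec,
    UnidentifiableParameterError,
    assign_am1bcc_dpol,
    fit_bccs,
    fit_polarizabilities,
    fit_resp_dpol,
)
from dpolkit.polarization import ESPRecord
from dpolkit.synthetic import (
    GroundTruthModel,
    default_bond_type_table,
    default_ground_truth,
    synth_esp_records,
    true_bcc_vector,
)
from tests.conftest import COARSE_GRID, random_rotation

TRUE_ALPHAS = np.array([9.0, 2.7, 5.6, 7.0])  # C, H, O, N (bohr³)


@pytest.fixture(scope="module")
def pol_problem(synthetic_records, element_skeleton):
    return PolFitProblem(list(synthetic_records), element_skeleton)


class TestPolarizabilityFit:
    def test_zero_noise_recovery_linear(self, pol_problem):
        res = fit_polarizabilities(pol_problem, "linear")
        np.testing.assert_allclose(res.alphas, TRUE_ALPHAS, rtol=1e-8)

    def test_solvers_agree(self, pol_problem):
        lin = fit_polarizabilities(pol_problem, "linear")
        nm = fit_polarizabilities(pol_problem, "nelder-mead")
        np.testing.assert_allclose(nm.alphas, lin.alphas, rtol=1e-6)

    def test_zero_differences_give_zero_alphas(self, synthetic_records,
                                               element_skeleton):
        zeroed = []
        for mol, baseline, diffs in synthetic_records:
            zdiffs = [ESPRecord(d.grid, np.zeros(len(d.grid)),
                                d.applied_field, "difference")
                      for d in diffs]
            zeroed.append((mol, baseline, zdiffs))
        res = fit_polarizabilities(
            PolFitProblem(zeroed, element_skeleton), "linear")
        np.testing.assert_allclose(res.alphas, 0.0, atol=1e-12)

    def test_duplicating_conformers_leaves_fit_unchanged(
            self, synthetic_records, element_skeleton):
        base = list(synthetic_records)
        res1 = fit_polarizabilities(
            PolFitProblem(base, element_skeleton), "linear")
        res2 = fit_polarizabilities(
            PolFitProblem(base + base, element_skeleton), "linear")
        np.testing.assert_allclose(res2.alphas, res1.alphas, rtol=1e-12)

    def test_unsupported_type_raises(self, synthetic_records):
        skeleton = PolarizabilityTypeSet("element", [
            ("C", None), ("H", None), ("O", None), ("N", None),
            ("Cl", None)])
        with pytest.raises(UnidentifiableParameterError, match="Cl"):
            fit_polarizabilities(
                PolFitProblem(list(synthetic_records), skeleton), "linear")

    def test_pattern_scheme_recovers_element_truth(self, synthetic_records):
        """SMARTS typing with one pattern per element matches the truth."""
        skeleton = PolarizabilityTypeSet("pattern", [
            ("[#6]", None), ("[#1]", None), ("[#8]", None), ("[#7]", None)])
        res = fit_polarizabilities(
            PolFitProblem(list(synthetic_records), skeleton), "linear")
        np.testing.assert_allclose(res.alphas, TRUE_ALPHAS, rtol=1e-8)

    def test_invariant_under_rigid_rotation(self, truth, toy_set,
                                            element_skeleton):
        """Rotating a conformer with its grids and fields leaves α fixed."""
        rng = np.random.default_rng(17)
        rot = random_rotation(rng)
        plain, rotated = [], []
        for confs in toy_set[:5]:
            mol = confs[0]
            baseline, diffs = synth_esp_records(mol, truth, COARSE_GRID)
            plain.append((mol, baseline, diffs))
            mol_rot = Molecule(
                mol.atom_elements, mol.coordinates @ rot.T, mol.bonds,
                formal_charge=mol.formal_charge,
                atom_formal_charges=mol.atom_formal_charges,
                conformer_id=mol.conformer_id)
            diffs_rot = []
            for d in diffs:
                grid_rot = type(d.grid)(d.grid.points @ rot.T,
                                        d.grid.shell_index)
                diffs_rot.append(ESPRecord(grid_rot, d.values,
                                           d.applied_field @ rot.T,
                                           "difference"))
            rotated.append((mol_rot, None, diffs_rot))
        res_a = fit_polarizabilities(
            PolFitProblem(plain, element_skeleton), "linear")
        res_b = fit_polarizabilities(
            PolFitProblem(rotated, element_skeleton), "linear")
        np.testing.assert_allclose(res_b.alphas, res_a.alphas, rtol=1e-8)

    def test_noise_degrades_recovery_linearly(self, toy_set,
                                              element_skeleton):
        """Parameter error grows monotonically (≈linearly) with ESP noise."""
        errors = []
        for sigma in (1e-5, 1e-4, 1e-3):
            truth = default_ground_truth(noise_sigma=sigma, seed=123)
            confs = []
            for group in toy_set:
                for mol in group[:2]:
                    _, diffs = synth_esp_records(mol, truth, COARSE_GRID)
                    confs.append((mol, None, diffs))
            res = fit_polarizabilities(
                PolFitProblem(confs, element_skeleton), "linear")
            errors.append(
                float(np.max(np.abs(res.alphas - TRUE_ALPHAS))))
        assert errors[0] < errors[1] < errors[2]
        # scaling is roughly linear in sigma: tenfold noise, about
        # tenfold error (within a factor of 4 either way)
        for e_lo, e_hi in zip(errors, errors[1:]):
            assert 2.5 < e_hi / e_lo < 40


class TestRespDpol:
    def test_unrestrained_recovery(self, synthetic_records, truth):
        for mol, baseline, _ in synthetic_records:
            alphas = assign_polarizabilities(mol, truth.typing)
            res = fit_resp_dpol(mol, baseline, alphas,
                                stages=[RestraintSpec(a=0.0)])
            np.testing.assert_allclose(
                res.charges, truth.charges_for(mol), atol=1e-7,
                err_msg=mol.conformer_id)

    def test_zero_alpha_reduces_to_classic_esp_fit(self, synthetic_records):
        """Oracle: independently coded constrained normal equations."""
        mol, baseline, _ = synthetic_records[4]  # methanol
        n = mol.n_atoms
        res = fit_resp_dpol(mol, baseline, np.zeros(n),
                            stages=[RestraintSpec(a=0.0)])
        # oracle: KKT normal equations for min ||V − Cq|| s.t. Σq = q_tot
        dist = np.linalg.norm(
            baseline.grid.points[:, None, :] -
            mol.coordinates[None, :, :], axis=-1)
        c_mat = 1.0 / dist
        kkt = np.zeros((n + 1, n + 1))
        kkt[:n, :n] = c_mat.T @ c_mat
        kkt[:n, n] = kkt[n, :n] = 1.0
        rhs = np.concatenate([c_mat.T @ baseline.values,
                              [mol.formal_charge]])
        q_oracle = np.linalg.solve(kkt, rhs)[:n]
        np.testing.assert_allclose(res.charges, q_oracle, atol=1e-9)

    def test_total_charge_constraint_with_restraints(self,
                                                     synthetic_records,
                                                     truth):
        for mol, baseline, _ in synthetic_records:
            alphas = assign_polarizabilities(mol, truth.typing)
            res = fit_resp_dpol(mol, baseline, alphas)
            assert abs(res.charges.sum() - mol.formal_charge) < 1e-10

    def test_stage2_symmetry_classes_exactly_equal(self, synthetic_records,
                                                   truth):
        mol, baseline, _ = synthetic_records[2]  # butane
        alphas = assign_polarizabilities(mol, truth.typing)
        res = fit_resp_dpol(mol, baseline, alphas)
        assert res.stage2_refit_atoms
        refit = set(res.stage2_refit_atoms)
        for cls in symmetry_classes(mol):
            members = [j for j in cls if j in refit]
            if len(members) > 1:
                qs = res.charges[members]
                assert qs.max() - qs.min() == 0.0

    def test_objective_monotone_over_reweighting(self, synthetic_records,
                                                 truth):
        for mol, baseline, _ in synthetic_records[:6]:
            alphas = assign_polarizabilities(mol, truth.typing)
            res = fit_resp_dpol(mol, baseline, alphas)
            for hist in (res.objective_history,
                         res.stage2_objective_history):
                diffs = np.diff(np.asarray(hist))
                assert np.all(diffs <= 1e-10), mol.conformer_id

    def test_restrained_charges_shrink_buried_atoms(self, synthetic_records,
                                                    truth):
        """The hyperbolic restraint pulls magnitudes toward zero."""
        mol, baseline, _ = synthetic_records[2]  # butane: buried carbons
        alphas = assign_polarizabilities(mol, truth.typing)
        free = fit_resp_dpol(mol, baseline, alphas,
                             stages=[RestraintSpec(a=0.0)])
        tight = fit_resp_dpol(mol, baseline, alphas,
                              stages=[RestraintSpec(a=0.05)])
        heavy = [j for j, el in enumerate(mol.atom_elements) if el != "H"]
        assert np.abs(tight.charges[heavy]).sum() \
            < np.abs(free.charges[heavy]).sum()

    def test_baseline_with_field_rejected(self, synthetic_records, truth):
        mol, _, diffs = synthetic_records[0]
        alphas = assign_polarizabilities(mol, truth.typing)
        with pytest.raises(ValueError, match="baseline"):
            fit_resp_dpol(mol, diffs[0], alphas)


@pytest.fixture(scope="module")
def bcc_training_module(toy_set, truth):
    table = default_bond_type_table()
    b_true = true_bcc_vector(table)
    training = []
    for confs in toy_set:
        for mol in confs[:2]:
            q_pre = truth.charges_for(mol)
            t_mat = bond_type_matrix(mol, table)
            name = mol.conformer_id.split("/")[0]
            gt = GroundTruthModel(
                typing=truth.typing,
                charges={name: q_pre + t_mat @ b_true})
            baseline, _ = synth_esp_records(mol, gt, COARSE_GRID)
            training.append((mol, q_pre, baseline))
    return table, b_true, training


class TestBccDpol:
    @pytest.fixture()
    def bcc_training(self, bcc_training_module):
        return bcc_training_module

    def test_recovery_on_supported_types(self, bcc_training, truth):
        table, b_true, training = bcc_training
        res = fit_bccs(training, table, truth.typing)
        np.testing.assert_allclose(
            res.bcc_values[res.covered_types],
            b_true[res.covered_types], atol=1e-7)

    def test_zero_truth_fits_zero(self, synthetic_records, truth):
        table = default_bond_type_table()
        training = [(mol, truth.charges_for(mol), baseline)
                    for mol, baseline, _ in synthetic_records]
        res = fit_bccs(training, table, truth.typing)
        np.testing.assert_allclose(res.bcc_values, 0.0, atol=1e-9)

    def test_unsupported_types_reported_and_zero(self, bcc_training, truth):
        table, _, training = bcc_training
        res = fit_bccs(training, table, truth.typing)
        labels = [table.types[k].label for k in range(len(table.types))]
        # the order-4 C-H type exists in the table but no toy has it
        missing = labels.index("c-H")
        assert missing not in res.covered_types
        assert res.bcc_values[missing] == 0.0

    def test_total_charge_preserved_by_corrections(self, bcc_training,
                                                   truth):
        table, _, training = bcc_training
        res = fit_bccs(training, table, truth.typing)
        for mol, q_pre, _ in training:
            q = assign_am1bcc_dpol(mol, q_pre, table, res)
            assert abs(q.sum() - np.sum(q_pre)) < 1e-12


class TestAssignment:
    def test_zero_bccs_return_precharges(self, toy_set):
        mol = toy_set[0][0]
        table = default_bond_type_table()
        q_pre = np.linspace(-0.2, 0.2, mol.n_atoms)
        q = assign_am1bcc_dpol(mol, q_pre, table,
                               np.zeros(len(table.types)))
        np.testing.assert_array_equal(q, q_pre)

    def test_diatomic_transfer_by_hand(self):
        from dpolkit.chem_core import BondType, BondTypeTable

        mol = Molecule.from_angstrom(
            ["O", "C"], [[0, 0, 0], [1.2, 0, 0]], [(0, 1, 1)])
        table = BondTypeTable([BondType("O", "C", 1)])
        q = assign_am1bcc_dpol(mol, [0.0, 0.0], table, np.array([0.1]))
        np.testing.assert_allclose(q, [0.1, -0.1], atol=1e-15)

    def test_conservation_under_random_bccs(self, toy_set):
        rng = np.random.default_rng(3)
        table = default_bond_type_table()
        for confs in toy_set:
            mol = confs[0]
            q_pre = rng.normal(0, 0.2, mol.n_atoms)
            bccs = rng.normal(0, 0.1, len(table.types))
            q = assign_am1bcc_dpol(mol, q_pre, table, bccs)
            assert abs(q.sum() - q_pre.sum()) < 1e-12

    def test_missing_value_for_matched_type_raises(self, toy_set):
        from dpolkit.chem_core import TypeAssignmentError

        mol = toy_set[2][0]  # methanol: O-C and O-H bonds present
        table = default_bond_type_table()
        values = np.full(len(table.types), np.nan)
        with pytest.raises(TypeAssignmentError):
            assign_am1bcc_dpol(mol, np.zeros(mol.n_atoms), table, values)
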