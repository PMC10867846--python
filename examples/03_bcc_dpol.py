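"""Train bond charge corrections (BCC-dPol) and assign charges.

Emulates the BCC workflow: reference ESPs are generated from "corrected"
charges q_pre + T·B* with known corrections B*, the fit recovers B from
the precharges and ESPs alone, and charge assignment for a new molecule
is then just table lookup — no per-molecule ESP fit required.
"""

import numpy as np

from dpolkit import assign_am1bcc_dpol, bond_type_matrix, fit_bccs
from dpolkit.grid import GridSpec
from dpolkit.synthetic import (
    GroundTruthModel,
    default_bond_type_table,
    default_ground_truth,
    make_toy_set,
    synth_esp_records,
    true_bcc_vector,
)

truth = default_ground_truth()
table = default_bond_type_table()
b_true = true_bcc_vector(table)
grid = GridSpec(n_layers=3, density_per_angstrom2=2.0)

training = []
for conformers in make_toy_set():
    mol = conformers[0]
    q_pre = truth.charges_for(mol)
    t_mat = bond_type_matrix(mol, table)
    corrected = GroundTruthModel(
        typing=truth.typing,
        charges={mol.conformer_id.split("/")[0]: q_pre + t_mat @ b_true})
    baseline, _ = synth_esp_records(mol, corrected, grid)
    training.append((mol, q_pre, baseline))

fit = fit_bccs(training, table, truth.typing)

print("bond type          true B (e)   fitted B (e)")
for k, bt in enumerate(table.types):
    tag = "" if k in fit.covered_types else "   (no support -> 0)"
    print(f"{bt.label:<16s} {b_true[k]:10.4f} {fit.bcc_values[k]:14.10f}"
          f"{tag}")

methanol = next(c[0] for c in make_toy_set()
                if c[0].conformer_id.startswith("methanol"))
q_pre = truth.charges_for(methanol)
q = assign_am1bcc_dpol(methanol, q_pre, table, fit)
print("\nmethanol assignment: q = q_pre + T.B")
for el, qp, qq in zip(methanol.atom_elements, q_pre, q):
    print(f"{el:>3s} {qp:10.4f} -> {qq:10.4f} e")
print(f"total charge preserved: {q.sum():+.2e} e")
print("Supported corrections are recovered exactly; homonuclear types")
print("transfer no charge by antisymmetry and fit to zero.")
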