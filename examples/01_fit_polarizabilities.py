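"""Fit typed atomic polarizabilities to field-perturbed ESP differences.

Builds a small synthetic training set (the built-in CHON toys with known
element polarizabilities), generates baseline plus six field-perturbed ESP
records per conformer, and recovers the typed α values with both the
closed-form linear solver and Nelder–Mead.
"""

import numpy as np

from dpolkit import PolFitProblem, PolarizabilityTypeSet, fit_polarizabilities
from dpolkit.grid import GridSpec
from dpolkit.synthetic import default_ground_truth, make_toy_set, \
    synth_esp_records

truth = default_ground_truth()
grid = GridSpec(n_layers=3, density_per_angstrom2=2.0)  # reduced for speed

records = []
for conformers in make_toy_set():
    for mol in conformers[:2]:
        baseline, diffs = synth_esp_records(mol, truth, grid)
        records.append((mol, baseline, diffs))

skeleton = PolarizabilityTypeSet(
    "element", [("C", None), ("H", None), ("O", None), ("N", None)])
problem = PolFitProblem(records, skeleton)

linear = fit_polarizabilities(problem, "linear")
simplex = fit_polarizabilities(problem, "nelder-mead")

print("typed polarizabilities (bohr^3):")
print(f"{'type':>6s} {'true':>8s} {'linear':>12s} {'nelder-mead':>12s}")
for (el, true_alpha), a_lin, a_nm in zip(
        truth.typing.entries, linear.alphas, simplex.alphas):
    print(f"{el:>6s} {true_alpha:8.3f} {a_lin:12.8f} {a_nm:12.8f}")
print(f"\nmax relative recovery error: "
      f"{np.max(np.abs(linear.alphas - truth.typing.values) / truth.typing.values):.2e}")
print("Both solvers recover the generating polarizabilities: the ESP")
print("difference under a uniform field identifies each type's alpha.")
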