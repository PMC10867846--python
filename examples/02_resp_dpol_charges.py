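"""Derive RESP-dPol charges for ethanol and score the resulting ESP.

Fits polarization-consistent partial charges to a baseline ESP with the
standard two-stage restrained procedure (weak restraint on all atoms,
then a strong restraint refitting only methyl/methylene groups under
forced symmetry), and reports the RRMSE and molecular dipole.
"""

import numpy as np

from dpolkit import (
    RestraintSpec,
    assign_polarizabilities,
    fit_resp_dpol,
    molecular_dipole,
    rrmse,
    scaling_factors,
)
from dpolkit import esp, field_at_atoms, induced_dipoles, units
from dpolkit.grid import GridSpec
from dpolkit.synthetic import default_ground_truth, make_toy_set, \
    synth_esp_records

truth = default_ground_truth()
ethanol = next(c[0] for c in make_toy_set()
               if c[0].conformer_id.startswith("ethanol"))
baseline, _ = synth_esp_records(
    ethanol, truth, GridSpec(n_layers=4, density_per_angstrom2=4.0))
alphas = assign_polarizabilities(ethanol, truth.typing)

result = fit_resp_dpol(ethanol, baseline, alphas)  # default two stages
free = fit_resp_dpol(ethanol, baseline, alphas,
                     stages=[RestraintSpec(a=0.0)])

print("atom   unrestrained   two-stage RESP-dPol   (e)")
for el, qf, qr in zip(ethanol.atom_elements, free.charges, result.charges):
    print(f"{el:>4s} {qf:14.6f} {qr:20.6f}")
print(f" sum {free.charges.sum():14.6f} {result.charges.sum():20.6f}")
print(f"stage-2 refit atoms (methyl/methylene): "
      f"{result.stage2_refit_atoms}")

fields = field_at_atoms(ethanol, result.charges, scaling_factors(ethanol))
mu_ind = induced_dipoles(alphas, fields)
model = esp(ethanol, result.charges, mu_ind, baseline.grid)
mu = molecular_dipole(ethanol, result.charges, mu_ind)
print(f"\nRRMSE vs reference ESP: {rrmse(model, baseline.values):.4f}")
print(f"molecular dipole: {np.linalg.norm(units.au_to_debye(mu)):.3f} D")
print("The restraint shrinks buried-atom charges slightly, trading a")
print("small ESP error for transferable, conformation-stable charges;")
print("the total charge is pinned to the formal charge exactly.")
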