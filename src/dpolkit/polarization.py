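"""Physics core of the direct polarization approximation.

Each atom carries a fixed partial charge q_j and an isotropic point
polarizability α_j.  Under the direct approximation the induced dipole on
atom j responds only to the permanent charges and any external field,

    μ_ind,j = α_j (E_ext + Σ_{k≠j} f_jk q_k (r_j − r_k)/|r_j − r_k|³),

never to the other induced dipoles — so there is no self-consistent-field
iteration and no polarization catastrophe, and no Thole damping is needed.
The attenuation f_jk excludes 1–2/1–3 pairs and halves 1–4 pairs; it
applies only to fields evaluated *at atom sites*.  The ESP observed at a
grid point sums all atoms' charges and dipoles unattenuated:

    V_i = Σ_j q_j/|r_ij| + Σ_j μ_j·r_ij/|r_ij|³,   r_ij = r_i − r_j.

Everything in this module is in atomic units (bohr, e, hartree/e).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np

from dpolkit import units
from dpolkit.chem_core import Molecule, ScalingTable
from dpolkit.grid import ESPGrid, read_potential, write_potential

_SINGULARITY_EPS_BOHR = 1e-8

_ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16, "Cl": 17,
}


class SingularGeometryError(ValueError):
    """Coincident charge sites or a grid point on top of an atom."""


@dataclass
class ESPRecord:
    """An ESP dataset: grid, values (hartree/e), and the applied field.

    ``kind`` is "baseline" (zero applied field) or "difference"
    (field-perturbed ESP minus baseline; the default protocol uses six
    fields of magnitude 0.01 au along ±x, ±y, ±z).
    """

    grid: ESPGrid
    values: np.ndarray
    applied_field: np.ndarray
    kind: str = "baseline"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.applied_field = np.asarray(self.applied_field, dtype=float)
        if len(self.values) != len(self.grid):
            raise ValueError("values length != grid length")
        if self.applied_field.shape != (3,):
            raise ValueError("applied_field must be a 3-vector")
        if self.kind not in ("baseline", "difference"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "baseline" and np.any(self.applied_field != 0.0):
            raise ValueError("baseline records carry zero applied field")

    def write(self, grid_path, values_path, sidecar_path) -> None:
        self.grid.write(grid_path)
        write_potential(values_path, self.values)
        Path(sidecar_path).write_text(json.dumps({
            "field_au": list(self.applied_field), "kind": self.kind,
        }) + "\n")

    @classmethod
    def read(cls, grid_path, values_path, sidecar_path) -> "ESPRecord":
        meta = json.loads(Path(sidecar_path).read_text())
        return cls(ESPGrid.read(grid_path), read_potential(values_path),
                   np.asarray(meta["field_au"], float), meta["kind"])


@dataclass
class InducedDipoleSet:
    """Per-atom induced point dipoles μ_ind (e·bohr)."""

    dipoles: np.ndarray

    def __post_init__(self):
        self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.dipoles)

    @classmethod
    def zeros(cls, n_atoms: int) -> "InducedDipoleSet":
        return cls(np.zeros((n_atoms, 3)))


def field_at_atoms(molecule: Molecule, charges, scaling: ScalingTable,
                   external_field=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Scaled permanent-charge field plus external field at every atom.

    E_j = E_ext + Σ_{k≠j} f_jk q_k (r_j − r_k)/|r_j − r_k|³.  Induced
    dipoles never contribute (the direct approximation).
    """
    q = np.asarray(charges, dtype=float)
    r = molecule.coordinates
    n = molecule.n_atoms
    if len(q) != n:
        raise ValueError("charges length != atom count")
    diff = r[:, None, :] - r[None, :, :]           # r_j − r_k
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if np.any(dist < _SINGULARITY_EPS_BOHR):
        raise SingularGeometryError("coincident atom positions")
    w = scaling.factors * q[None, :] / dist**3     # f_jk q_k / d³
    fields = np.einsum("jk,jkx->jx", w, diff)
    return fields + np.asarray(external_field, dtype=float)[None, :]


def induced_dipoles(alphas, fields) -> InducedDipoleSet:
    """μ_ind,j = α_j E_j — the pure scalar isotropic linear response."""
    a = np.asarray(alphas, dtype=float)
    e = np.asarray(fields, dtype=float).reshape(-1, 3)
    if len(a) != len(e):
        raise ValueError("alphas and fields length mismatch")
    if np.any(a < 0):
        raise ValueError("negative polarizability")
    return InducedDipoleSet(a[:, None] * e)


def esp(molecule: Molecule, charges, dipoles: InducedDipoleSet | None,
        grid: ESPGrid) -> np.ndarray:
    """Potential at the grid from point charges and point dipoles.

    No attenuation and no damping at observer points; superposition of the
    bare Coulomb and point-dipole kernels.
    """
    q = np.asarray(charges, dtype=float)
    r = molecule.coordinates
    p = grid.points
    diff = p[:, None, :] - r[None, :, :]           # r_ij = r_i − r_j
    dist = np.linalg.norm(diff, axis=-1)
    if np.any(dist < _SINGULARITY_EPS_BOHR):
        raise SingularGeometryError("grid point coincides with an atom")
    v = diff / dist[..., None] ** 3
    out = (q[None, :] / dist).sum(axis=1)
    if dipoles is not None:
        out = out + np.einsum("ijx,jx->i", v, dipoles.dipoles)
    return out


def rrmse(model_values, reference_values) -> float:
    """Relative root-mean-square error of a model ESP against a reference.

    sqrt(Σ_i (V_ref,i − V_model,i)² / Σ_i V_ref,i²): 0 for a perfect
    model, 1 for a model that predicts nothing (all zeros).
    """
    m = np.asarray(model_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if m.shape != ref.shape or m.size == 0:
        raise ValueError("model and reference must be equal nonzero length")
    denom = float(ref @ ref)
    if denom == 0.0:
        raise ZeroDivisionError("reference ESP is identically zero")
    return float(np.sqrt(((ref - m) @ (ref - m)) / denom))


def molecular_dipole(molecule: Molecule, charges,
                     dipoles: InducedDipoleSet | None = None) -> np.ndarray:
    """Total molecular dipole μ = Σ_j q_j r_j + Σ_j μ_ind,j (e·bohr).

    Origin-independent for neutral molecules.  For charged species the
    dipole depends on the origin; the convention here is the center of
    nuclear charge, which is fixed by the structure alone.
    """
    q = np.asarray(charges, dtype=float)
    r = molecule.coordinates
    if abs(q.sum()) > 1e-9:
        z = np.array([_ATOMIC_NUMBERS[el] for el in molecule.atom_elements],
                     dtype=float)
        r = r - (z[:, None] * r).sum(axis=0) / z.sum()
    mu = (q[:, None] * r).sum(axis=0)
    if dipoles is not None:
        mu = mu + dipoles.dipoles.sum(axis=0)
    return mu


def molecular_polarizability(alphas) -> float:
    """α_M = Σ_j α_j — additive under the direct approximation (bohr³)."""
    a = np.asarray(alphas, dtype=float)
    if a.size and np.any(a < 0):
        raise ValueError("negative polarizability")
    return float(a.sum())
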