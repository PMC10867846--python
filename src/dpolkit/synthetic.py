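"""Ground-truth emulator standing in for the QM and MD engines.

Every fitting procedure in this package is testable by parameter recovery:
this module generates ESP records and liquid time series from a *known*
charge + polarizability model, so a fit applied to its output should
return the generating parameters (exactly at zero noise, gracefully
degrading with noise).

* :func:`make_toy_set` — a deterministic CHON toy set (alkanes, alcohols,
  an amide, an amine, a carboxylate anion, an ammonium cation, an
  aromatic) with 2–4 conformers each, pairwise ≥ 0.5 Å RMSD.
* :func:`synth_esp_records` — baseline ESP plus six field-perturbed
  difference records (±x, ±y, ±z at 0.01 au), emulating the reference
  protocol: multiple conformers fitted as if independent molecules.
* :func:`synth_dipole_series` — an ideal dipolar gas (independent rotors)
  whose static dielectric constant has a closed form.
* :func:`make_frozen_box` — a frozen multi-molecule configuration for
  checking the analytic high-frequency dielectric against the
  finite-difference polarization response of the implemented model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import zlib

import numpy as np

from dpolkit import units
from dpolkit._geometries import TOY_MOLECULES
from dpolkit.chem_core import (
    Molecule,
    PolarizabilityTypeSet,
    assign_polarizabilities,
    scaling_factors,
)
from dpolkit.grid import GridSpec, generate_msk_grid
from dpolkit.liquids import LiquidSeries
from dpolkit.polarization import (
    ESPRecord,
    esp,
    field_at_atoms,
    induced_dipoles,
)

DEFAULT_FIELD_AU = 0.01

FIELD_DIRECTIONS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=float)

#: Element-typed ground-truth polarizabilities (bohr³), of the magnitude
#: typical for organic molecules (≈0.4–1.4 Å³ per atom).
DEFAULT_TRUE_ALPHAS = PolarizabilityTypeSet("element", [
    ("C", 9.0), ("H", 2.7), ("O", 5.6), ("N", 7.0),
])


@dataclass
class GroundTruthModel:
    """The generating model: typed α, per-molecule charges, noise, seed."""

    typing: PolarizabilityTypeSet = field(
        default_factory=lambda: DEFAULT_TRUE_ALPHAS)
    charges: dict = field(default_factory=dict)  # molecule name -> e array
    noise_sigma: float = 0.0                     # hartree/e, i.i.d.
    seed: int = 0

    def charges_for(self, molecule: Molecule) -> np.ndarray:
        name = molecule.conformer_id.split("/")[0]
        if name not in self.charges:
            raise KeyError(f"no ground-truth charges for {name!r}")
        return np.asarray(self.charges[name], dtype=float)


def default_ground_truth(noise_sigma: float = 0.0,
                         seed: int = 0) -> GroundTruthModel:
    """Ground truth covering the built-in toy set."""
    charges = {name: np.array(entry["true_charges"])
               for name, entry in TOY_MOLECULES.items()}
    return GroundTruthModel(charges=charges, noise_sigma=noise_sigma,
                            seed=seed)


def make_toy_set(seed: int = 0) -> list[list[Molecule]]:
    """The deterministic CHON toy set, one list of conformers per molecule.

    Geometries are frozen idealized structures; ``seed`` is accepted for
    interface symmetry with the stochastic generators but the structures
    do not depend on it.  Conformer ids are ``"name/k"``.
    """
    out = []
    for name, entry in TOY_MOLECULES.items():
        confs = []
        for k, coords in enumerate(entry["conformers"]):
            confs.append(Molecule.from_angstrom(
                entry["elements"], coords,
                [tuple(b) for b in entry["bonds"]],
                formal_charge=entry["formal_charge"],
                atom_formal_charges=list(entry["atom_formal_charges"]),
                conformer_id=f"{name}/{k}",
            ))
        out.append(confs)
    return out


def synth_esp_records(
    molecule: Molecule,
    truth: GroundTruthModel,
    grid_spec: GridSpec = GridSpec(),
    field_au: float = DEFAULT_FIELD_AU,
) -> tuple[ESPRecord, list[ESPRecord]]:
    """Baseline plus six difference ESP records from the truth model.

    The baseline is the model's own ESP (charges + induced dipoles driven
    by the attenuated permanent fields).  Each perturbed record adds a
    uniform field of magnitude ``field_au`` along ±x/±y/±z; the returned
    difference records are perturbed minus baseline.  Gaussian noise, when
    configured, is added after differencing (independently per record,
    reproducibly from the truth seed and the conformer id).
    """
    q = truth.charges_for(molecule)
    alphas = assign_polarizabilities(molecule, truth.typing)
    scaling = scaling_factors(molecule)
    grid = generate_msk_grid(molecule, grid_spec)

    def model_esp(ext):
        fields = field_at_atoms(molecule, q, scaling, ext)
        mu = induced_dipoles(alphas, fields)
        return esp(molecule, q, mu, grid)

    v0 = model_esp(np.zeros(3))
    # stable per-conformer noise stream (process-independent hash)
    rng = np.random.default_rng(
        [truth.seed, zlib.crc32(molecule.conformer_id.encode()) % 2**31])
    baseline_vals = v0
    if truth.noise_sigma > 0:
        baseline_vals = v0 + rng.normal(0, truth.noise_sigma, len(v0))
    baseline = ESPRecord(grid, baseline_vals, np.zeros(3), "baseline")

    diffs = []
    for direction in FIELD_DIRECTIONS:
        ext = field_au * direction
        dv = model_esp(ext) - v0
        if truth.noise_sigma > 0:
            dv = dv + rng.normal(0, truth.noise_sigma, len(dv))
        diffs.append(ESPRecord(grid, dv, ext, "difference"))
    return baseline, diffs


def synth_dipole_series(
    n_molecules: int = 256,
    dipole_magnitude: float = 0.7,
    temperature: float = 298.15,
    n_frames: int = 100_000,
    volume: float = 52_000.0,
    seed: int = 0,
    alphas_total: float = 0.0,
    total_mass: float = 0.0,
) -> tuple[LiquidSeries, float]:
    """Ideal dipolar gas: independent random orientations each frame.

    Each of ``n_molecules`` rigid dipoles of magnitude μ₀ (e·bohr) points
    in an independent uniform direction every frame, in a fixed box of
    ``volume`` bohr³ at ``temperature`` K.  Returns the series and the
    closed-form dielectric constant of this model,

        D = 1 + 4π n μ₀² / (3 V k_B T) + 4π Σα/V,

    since uncorrelated unit vectors give ⟨μ·μ⟩ − ⟨μ⟩·⟨μ⟩ = n μ₀².
    Defaults emulate a 256-molecule box of a moderately polar liquid.
    """
    if min(n_molecules, n_frames) < 1 or volume <= 0 or temperature <= 0:
        raise ValueError("arguments must be positive")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_frames, n_molecules, 3))
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    mu = dipole_magnitude * u.sum(axis=1)
    series = LiquidSeries(
        dipoles=mu,
        volumes=np.full(n_frames, float(volume)),
        temperature=temperature,
        total_mass=total_mass,
        alphas_total=alphas_total,
    )
    eps_inf = 1.0 + 4.0 * np.pi * alphas_total / volume
    d_analytic = eps_inf + 4.0 * np.pi * n_molecules * dipole_magnitude**2 \
        / (3.0 * volume * units.KB_HARTREE_PER_K * temperature)
    return series, d_analytic


def default_bond_type_table():
    """Element-level bond types covering the toy set's CHON chemistry.

    Correction charge flows toward the pattern1 end (the more
    electronegative atom by convention).  Homonuclear types (C–C single,
    aromatic C–C) are included for completeness; their antisymmetric
    transfer cancels, so they carry no identifiable correction and fit
    to zero.
    """
    from dpolkit.chem_core import BondType, BondTypeTable

    return BondTypeTable([
        BondType("C", "H", 1, "C-H"),
        BondType("O", "C", 1, "O-C"),
        BondType("O", "H", 1, "O-H"),
        BondType("N", "C", 1, "N-C"),
        BondType("N", "H", 1, "N-H"),
        BondType("O", "C", 2, "O=C"),
        BondType("C", "C", 1, "C-C"),
        BondType("C", "C", 4, "C~C aromatic"),
        BondType("C", "H", 4, "c-H"),
    ])


#: Ground-truth bond charge corrections (e) for recovery studies; the
#: homonuclear types are unidentifiable by antisymmetry and stay 0.
DEFAULT_TRUE_BCCS = {
    "C-H": -0.035, "O-C": 0.12, "O-H": 0.18, "N-C": 0.09,
    "N-H": 0.14, "O=C": 0.25, "C-C": 0.0, "C~C aromatic": 0.0, "c-H": 0.0,
}


def true_bcc_vector(table=None) -> np.ndarray:
    table = table or default_bond_type_table()
    return np.array([DEFAULT_TRUE_BCCS[bt.label] for bt in table.types])


# ---------------------------------------------------------------------------
# frozen box for the high-frequency dielectric cross-check
# ---------------------------------------------------------------------------

@dataclass
class FrozenBox:
    """A frozen multi-molecule configuration of the direct model.

    Holds every atom's position (bohr), charge, polarizability and
    molecule membership; intramolecular charge–polarizability pairs are
    attenuated by the molecule's f_jk table, intermolecular pairs are
    not.  ``total_dipole(E)`` evaluates the box dipole under a uniform
    external field — the quantity whose field derivative defines the
    high-frequency dielectric.
    """

    positions: np.ndarray
    charges: np.ndarray
    alphas: np.ndarray
    molecule_index: np.ndarray
    scaling: np.ndarray          # full pairwise f table, intermolecular = 1
    volume: float

    def total_dipole(self, external_field=(0.0, 0.0, 0.0)) -> np.ndarray:
        r = self.positions
        diff = r[:, None, :] - r[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        w = self.scaling * self.charges[None, :] / dist**3
        fields = np.einsum("jk,jkx->jx", w, diff) \
            + np.asarray(external_field, float)[None, :]
        mu_ind = self.alphas[:, None] * fields
        return (self.charges[:, None] * r).sum(axis=0) + mu_ind.sum(axis=0)

    def epsilon_infinity_analytic(self) -> float:
        return 1.0 + 4.0 * np.pi * float(self.alphas.sum()) / self.volume

    def epsilon_infinity_finite_difference(
            self, field_au: float = 1e-3) -> float:
        """ε_∞ from the numeric polarization response ∂⟨P⟩/∂E.

        Central difference along each axis, averaged: χ = ΔP/ΔE and
        ε = 1 + 4πχ.  Under the direct approximation the response is
        exactly linear, so the step size barely matters.
        """
        chi = 0.0
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = field_au
            dmu = self.total_dipole(e) - self.total_dipole(-e)
            chi += dmu[axis] / (2.0 * field_au * self.volume)
        return 1.0 + 4.0 * np.pi * chi / 3.0


def make_frozen_box(
    n_molecules: int = 50,
    seed: int = 0,
    truth: GroundTruthModel | None = None,
    molecule_name: str = "methanol",
    box_length: float | None = None,
) -> FrozenBox:
    """Randomly oriented copies of a toy molecule on a jittered lattice.

    Molecules are placed on a cubic lattice with seeded random rotations
    and small jitter (no overlaps), carrying the truth model's charges
    and polarizabilities.  Default box length gives liquid-like spacing
    (~7 bohr between lattice sites per molecule).
    """
    truth = truth or default_ground_truth()
    entry = TOY_MOLECULES[molecule_name]
    template = Molecule.from_angstrom(
        entry["elements"], entry["conformers"][0],
        [tuple(b) for b in entry["bonds"]],
        formal_charge=entry["formal_charge"],
        atom_formal_charges=list(entry["atom_formal_charges"]),
        conformer_id=f"{molecule_name}/0",
    )
    q_mol = truth.charges_for(template)
    a_mol = assign_polarizabilities(template, truth.typing)
    f_mol = scaling_factors(template).factors
    n_at = template.n_atoms

    n_side = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = 9.0  # bohr; generous enough to avoid atom overlaps
    if box_length is None:
        box_length = n_side * spacing
    rng = np.random.default_rng(seed)

    pos, mol_idx = [], []
    sites = [(i, j, k) for i in range(n_side) for j in range(n_side)
             for k in range(n_side)][:n_molecules]
    base = template.coordinates - template.coordinates.mean(axis=0)
    for m, (i, j, k) in enumerate(sites):
        # seeded random rotation via QR of a Gaussian matrix
        mat = rng.normal(size=(3, 3))
        qmat, rmat = np.linalg.qr(mat)
        qmat *= np.sign(np.diag(rmat))
        if np.linalg.det(qmat) < 0:
            qmat[:, 0] = -qmat[:, 0]
        center = (np.array([i, j, k]) + 0.5) * spacing \
            + rng.uniform(-0.5, 0.5, 3)
        pos.append(base @ qmat.T + center)
        mol_idx.append(np.full(n_at, m))
    positions = np.concatenate(pos)
    mol_idx = np.concatenate(mol_idx)

    n_total = len(positions)
    scaling = np.ones((n_total, n_total))
    for m in range(n_molecules):
        sl = slice(m * n_at, (m + 1) * n_at)
        scaling[sl, sl] = f_mol
    return FrozenBox(
        positions=positions,
        charges=np.tile(q_mol, n_molecules),
        alphas=np.tile(a_mol, n_molecules),
        molecule_index=mol_idx,
        scaling=scaling,
        volume=float(box_length**3),
    )
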