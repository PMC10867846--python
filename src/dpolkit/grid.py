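"""Merz–Singh–Kollman-style ESP sampling shells and grid/potential files.

Grid points are laid on nested unions of per-atom spheres at scaled van der
Waals radii.  The default protocol is 10 layers, a surface density of
17 points/Å², a radial increment of 0.126 Å between layers, and an inner
scale factor of 1.4 on Bondi radii.  Points falling inside any other atom's
same-layer sphere are discarded, so every retained point lies outside the
scaled vdW surface of the whole molecule.

Sphere sampling uses a deterministic golden-spiral (Fibonacci) lattice:
quasi-uniform at any density and bit-reproducible for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from dpolkit import units
from dpolkit.chem_core import Molecule

# Bondi van der Waals radii, Å
BONDI_RADII_ANGSTROM = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "P": 1.80, "S": 1.80, "Cl": 1.75,
}

_DEDUPE_EPS_BOHR = 1e-8


class GridConfigError(ValueError):
    """An element lacks a van der Waals radius in the configured set."""


@dataclass(frozen=True)
class GridSpec:
    """MSK shell parameters: layer count, density, spacing, inner scale."""

    n_layers: int = 10
    density_per_angstrom2: float = 17.0
    layer_spacing_angstrom: float = 0.126
    inner_scale: float = 1.4
    radius_set: str = "bondi"


@dataclass
class ESPGrid:
    """ESP sampling points (bohr) with per-point shell provenance."""

    points: np.ndarray
    shell_index: np.ndarray
    spec: GridSpec | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.shell_index = np.asarray(self.shell_index, dtype=int)
        if len(self.shell_index) != len(self.points):
            raise ValueError("shell_index length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def points_angstrom(self) -> np.ndarray:
        return units.bohr_to_angstrom(self.points)

    def write(self, path) -> None:
        """Write x y z in Å, one point per line (Psi4 grid.dat dialect)."""
        lines = [f"{x:.12g} {y:.12g} {z:.12g}"
                 for x, y, z in self.points_angstrom]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "ESPGrid":
        pts = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line:
                pts.append([float(v) for v in line.split()[:3]])
        pts = np.asarray(pts, dtype=float)
        return cls(units.angstrom_to_bohr(pts), np.zeros(len(pts), int))


def write_potential(path, values) -> None:
    """One potential value per line (hartree/e), aligned with the grid file."""
    Path(path).write_text(
        "\n".join(f"{v:.12g}" for v in np.asarray(values)) + "\n")


def read_potential(path) -> np.ndarray:
    return np.array([float(s) for s in Path(path).read_text().split()])


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the golden-spiral lattice."""
    if n <= 0:
        return np.zeros((0, 3))
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _molecular_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed molecule-fixed frame (columns = axes).

    Principal axes of the coordinate spread about the centroid, signs fixed
    against the first atoms with a nonzero projection.  Built entirely from
    the coordinates, so rotating the molecule rotates the frame — this is
    what makes the sampling grid rotation-equivariant.  Degenerate spreads
    (single atoms, perfectly symmetric tops) fall back to identity axes.
    """
    center = coords.mean(axis=0)
    rel = coords - center
    cov = rel.T @ rel
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scale = max(float(w[0]), 1.0)
    if w[0] < 1e-12 or (w[0] - w[1]) / scale < 1e-9 \
            or abs(w[1] - w[2]) / scale < 1e-9 and w[1] > 1e-12:
        return np.eye(3)
    axes = []
    for i in range(2):
        a = v[:, i]
        for r in rel:
            p = float(a @ r)
            if abs(p) > 1e-9:
                if p < 0:
                    a = -a
                break
        axes.append(a)
    axes.append(np.cross(axes[0], axes[1]))
    return np.column_stack(axes)


def generate_msk_grid(molecule: Molecule,
                      spec: GridSpec = GridSpec()) -> ESPGrid:
    """Build MSK-style nested shells around a molecule.

    Layer k (k = 0..n_layers−1) puts points on each atom's sphere of
    radius ``inner_scale·r_vdW + k·layer_spacing`` at the requested surface
    density, then removes points lying inside any other atom's same-layer
    sphere.  Deterministic for fixed input.
    """
    radii_a = {}
    for el in set(molecule.atom_elements):
        if el not in BONDI_RADII_ANGSTROM:
            raise GridConfigError(f"no vdW radius for element {el!r}")
        radii_a[el] = BONDI_RADII_ANGSTROM[el]

    centers = molecule.coordinates  # bohr
    frame = _molecular_frame(centers)
    base_r = np.array([
        spec.inner_scale * radii_a[el] for el in molecule.atom_elements])

    all_points, all_shells = [], []
    for layer in range(spec.n_layers):
        layer_r_a = base_r + layer * spec.layer_spacing_angstrom  # Å
        layer_r = units.angstrom_to_bohr(layer_r_a)
        for a in range(molecule.n_atoms):
            n_pts = int(round(
                4.0 * np.pi * layer_r_a[a] ** 2 * spec.density_per_angstrom2))
            if n_pts == 0:
                continue
            pts = centers[a] + layer_r[a] * fibonacci_sphere(n_pts) @ frame.T
            keep = np.ones(len(pts), dtype=bool)
            for b in range(molecule.n_atoms):
                if b == a:
                    continue
                d = np.linalg.norm(pts - centers[b], axis=1)
                keep &= d >= layer_r[b] - 1e-12
            all_points.append(pts[keep])
            all_shells.append(np.full(int(keep.sum()), layer, dtype=int))

    if not all_points:
        raise ValueError("empty grid")
    points = np.concatenate(all_points)
    shells = np.concatenate(all_shells)

    # drop near-duplicate points (touching spheres can coincide)
    order = np.lexsort(points.T)
    keep = np.ones(len(points), dtype=bool)
    sorted_pts = points[order]
    dup = np.all(np.abs(np.diff(sorted_pts, axis=0)) < _DEDUPE_EPS_BOHR,
                 axis=1)
    keep[order[1:][dup]] = False
    return ESPGrid(points[keep], shells[keep], spec=spec)
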