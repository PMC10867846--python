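"""Condensed-phase observables from dipole/volume time series.

Post-processing estimators for liquid simulations of the direct-polarization
model: mass density, the static dielectric constant from total-dipole
fluctuations, the analytic high-frequency dielectric constant, and the
Lorentz–Lorenz molecular polarizability from refractive indices.

Internally everything is in Gaussian atomic units (dipoles in e·bohr,
volumes in bohr³, temperature in K with k_B in hartree/K), in which the
dielectric expressions take their textbook Gaussian form:

    ε_∞ = 1 + 4π Σ_j α_j / ⟨V⟩
    D   = ε_∞ + 4π (⟨μ·μ⟩ − ⟨μ⟩·⟨μ⟩) / (3 ⟨V⟩ k_B T)

The ε_∞ formula is exact for the direct approximation: induced dipoles feel
only the macroscopic field (and the permanent charges, whose contribution
is field-independent), so the electronic susceptibility is strictly
additive over atoms — no Clausius–Mossotti self-field correction appears.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd

from dpolkit import units


@dataclass
class LiquidSeries:
    """Per-frame total dipole (e·bohr) and box volume (bohr³) plus metadata.

    ``total_mass`` is the summed molar mass of everything in the box
    (g/mol); ``alphas_total`` is Σ α_j over all atoms in the box (bohr³).
    """

    dipoles: np.ndarray
    volumes: np.ndarray
    temperature: float
    total_mass: float = 0.0
    alphas_total: float = 0.0

    def __post_init__(self):
        self.dipoles = np.asarray(self.dipoles, dtype=float).reshape(-1, 3)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if len(self.volumes) != len(self.dipoles):
            raise ValueError("volumes and dipoles length mismatch")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.volumes)

    @classmethod
    def from_csv(cls, csv_path, meta_path) -> "LiquidSeries":
        """Read frame, mux, muy, muz, volume columns plus a metadata JSON.

        Dipole units (``debye`` or ``e_bohr``) and volume units (``nm3``
        or ``bohr3``) are declared in the metadata, which also carries
        temperature (K), total mass (g/mol) and Σα (bohr³).
        """
        df = pd.read_csv(csv_path)
        meta = json.loads(Path(meta_path).read_text())
        mu = df[["mux", "muy", "muz"]].to_numpy(float)
        if meta.get("dipole_unit", "e_bohr") == "debye":
            mu = units.debye_to_au(mu)
        vol = df["volume"].to_numpy(float)
        if meta.get("volume_unit", "bohr3") == "nm3":
            vol = vol * units.BOHR3_PER_NM3
        return cls(mu, vol,
                   temperature=float(meta["temperature_K"]),
                   total_mass=float(meta.get("total_mass_g_mol", 0.0)),
                   alphas_total=float(meta.get("alphas_total_bohr3", 0.0)))

    def to_csv(self, csv_path, meta_path) -> None:
        df = pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "mux": self.dipoles[:, 0], "muy": self.dipoles[:, 1],
            "muz": self.dipoles[:, 2], "volume": self.volumes,
        })
        df.to_csv(csv_path, index=False)
        Path(meta_path).write_text(json.dumps({
            "dipole_unit": "e_bohr", "volume_unit": "bohr3",
            "temperature_K": self.temperature,
            "total_mass_g_mol": self.total_mass,
            "alphas_total_bohr3": self.alphas_total,
        }, indent=1) + "\n")


def mass_density(series: LiquidSeries) -> float:
    """Mass density ρ = M/⟨V⟩ in g/mL (M per box, Avogadro-scaled)."""
    if series.n_frames == 0:
        raise ValueError("empty series")
    mean_v_ml = float(series.volumes.mean()) * units.ML_PER_BOHR3
    if mean_v_ml <= 0:
        raise ValueError("nonpositive mean volume")
    return series.total_mass / units.AVOGADRO / mean_v_ml


def epsilon_infinity(series: LiquidSeries) -> float:
    """High-frequency dielectric ε_∞ = 1 + 4π Σα/⟨V⟩ (exact, see module)."""
    return 1.0 + 4.0 * np.pi * series.alphas_total \
        / float(series.volumes.mean())


def dielectric_from_fluctuations(
        series: LiquidSeries) -> tuple[float, float]:
    """Static dielectric constant D and its reciprocal 1/D.

    D = ε_∞ + 4π(⟨μ·μ⟩ − ⟨μ⟩·⟨μ⟩)/(3⟨V⟩k_BT).  Both D and 1/D are
    returned because sampling error in the fluctuation term is closer to
    symmetric in 1/D, and electrostatic screening is proportional to the
    reciprocal.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuations")
    if series.temperature <= 0:
        raise ValueError("temperature must be positive")
    mu = series.dipoles
    mean_mu = mu.mean(axis=0)
    fluct = float((mu * mu).sum(axis=1).mean() - mean_mu @ mean_mu)
    eps_inf = epsilon_infinity(series)
    d = eps_inf + 4.0 * np.pi * fluct / (
        3.0 * float(series.volumes.mean())
        * units.KB_HARTREE_PER_K * series.temperature)
    return d, 1.0 / d


def lorentz_lorenz_alpha(refractive_index: float,
                         number_density: float) -> float:
    """Molecular polarizability (Å³) from the Lorentz–Lorenz relation.

    α_M = (3/(4πρ))·(n²−1)/(n²+2) with ρ the number density in
    molecules/Å³.  Used as an experimental magnitude check on fitted
    atomic polarizabilities (α_M = Σα_j under the additive model).
    """
    if refractive_index < 1.0:
        raise ValueError("refractive index must be >= 1")
    if number_density <= 0:
        raise ValueError("number density must be positive")
    n2 = refractive_index**2
    return 3.0 / (4.0 * np.pi * number_density) * (n2 - 1.0) / (n2 + 2.0)


def refractive_index_from_alpha(alpha_m: float,
                                number_density: float) -> float:
    """Inverse of :func:`lorentz_lorenz_alpha` (round-trip check)."""
    x = 4.0 * np.pi * number_density * alpha_m / 3.0
    if x >= 1.0:
        raise ValueError("polarizability too large for a real index")
    return float(np.sqrt((1.0 + 2.0 * x) / (1.0 - x)))
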