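"""Parameter estimation: typed polarizabilities, RESP-dPol, BCC-dPol.

Three fits, all against ESP data and all linear (or made linear) in their
parameters:

* ``fit_polarizabilities`` — typed atomic polarizabilities from
  field-perturbed ESP *differences*.  Under the direct approximation the
  permanent-charge contribution cancels in the difference, so the induced
  dipole driving each difference record is just α_type·E_ext and the
  objective is linear least squares in the typed α (solved in closed form
  with a nonnegativity bound, and independently by Nelder–Mead simplex —
  the two must agree).

* ``fit_resp_dpol`` — two-stage restrained ESP charge fitting where the
  model ESP includes the induced-dipole contribution driven by the scaled
  permanent-charge fields.  Stage 1 fits all atoms under a weak hyperbolic
  restraint; stage 2 freezes everything except methyl/methylene carbons and
  their topologically equivalent hydrogens, forces within-class equality,
  and refits under a strong restraint.  The total charge is pinned to the
  molecular charge with a Lagrange multiplier; the hyperbolic restraint is
  handled by majorize–minimize diagonal reweighting, which makes the
  objective provably non-increasing across iterations.

* ``fit_bccs`` / ``assign_am1bcc_dpol`` — bond charge corrections trained
  so that precharges + T·B reproduce reference ESPs in the presence of the
  typed polarizabilities; assignment is then q = q_pre + T·B, conserving
  total charge exactly because T's columns sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.optimize

from dpolkit.chem_core import (
    Molecule,
    PolarizabilityTypeSet,
    BondTypeTable,
    TypeAssignmentError,
    bond_type_matrix,
    scaling_factors,
    symmetry_classes,
)
from dpolkit.polarization import ESPRecord, SingularGeometryError

__all__ = [
    "PolFitProblem", "PolFitResult", "RestraintSpec", "ChargeFitResult",
    "BCCFitResult", "fit_polarizabilities", "fit_resp_dpol", "fit_bccs",
    "assign_am1bcc_dpol", "esp_design_matrices",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """The fitting design is singular (degenerate grid or topology)."""


class UnidentifiableParameterError(ValueError):
    """A typed parameter has no support anywhere in the training data."""


# ---------------------------------------------------------------------------
# shared design matrices
# ---------------------------------------------------------------------------

def esp_design_matrices(molecule: Molecule, alphas,
                        grid) -> tuple[np.ndarray, np.ndarray]:
    """Coulomb and induced-dipole design matrices (C, G) with V = (C+G)·q.

    C[i, k] = 1/|r_i − r_k| is the bare Coulomb kernel.  G captures the
    induced-dipole contribution: the scaled field each charge q_k creates
    at every polarizable atom j, turned into a dipole α_j·E and observed
    at grid point i through the point-dipole kernel.  Both are exactly
    linear in the charge vector — the direct approximation has no
    self-consistency loop.
    """
    a = np.asarray(alphas, dtype=float)
    r = molecule.coordinates
    p = grid.points
    scaling = scaling_factors(molecule)

    diff_pa = p[:, None, :] - r[None, :, :]              # grid i ← atom j
    dist_pa = np.linalg.norm(diff_pa, axis=-1)
    if np.any(dist_pa < 1e-8):
        raise SingularGeometryError("grid point coincides with an atom")
    coulomb = 1.0 / dist_pa                              # C[i, k]
    kernel = diff_pa / dist_pa[..., None] ** 3           # K[i, j, :]

    diff_aa = r[:, None, :] - r[None, :, :]              # r_j − r_k
    dist_aa = np.linalg.norm(diff_aa, axis=-1)
    np.fill_diagonal(dist_aa, np.inf)
    if np.any(dist_aa < 1e-8):
        raise SingularGeometryError("coincident atom positions")
    # F[j, :, k]: field at atom j per unit charge at atom k, attenuated
    fop = scaling.factors[:, None, :] * (
        diff_aa.transpose(0, 2, 1) / dist_aa[:, None, :] ** 3)
    induced = np.einsum("ijx,j,jxk->ik", kernel, a, fop)
    return coulomb, induced


# ---------------------------------------------------------------------------
# typed polarizability fitting
# ---------------------------------------------------------------------------

@dataclass
class PolFitProblem:
    """Training data for the typed-polarizability fit.

    ``conformers`` holds (Molecule, baseline ESPRecord, difference
    ESPRecords) triples — the default protocol supplies six difference
    records per conformer (fields of 0.01 au along ±x, ±y, ±z, sharing the
    conformer's grid).  ``typing`` is the type-set skeleton whose values
    the fit determines.
    """

    conformers: list[tuple[Molecule, ESPRecord | None, list[ESPRecord]]]
    typing: PolarizabilityTypeSet


@dataclass
class PolFitResult:
    types: PolarizabilityTypeSet
    alphas: np.ndarray
    objective: float
    method: str
    n_residuals: int
    nm_iterations: int = 0


def _pol_design(problem: PolFitProblem) -> tuple[np.ndarray, np.ndarray]:
    """Stacked design matrix (rows: conformer × field × point; cols: type)."""
    n_types = len(problem.typing.entries)
    blocks, targets = [], []
    support = np.zeros(n_types, dtype=bool)
    for mol, _baseline, diffs in problem.conformers:
        if not diffs:
            raise ValueError(f"conformer {mol.conformer_id!r} has no "
                             "difference records")
        t_idx = problem.typing.atom_type_indices(mol)
        support[np.unique(t_idx)] = True
        member = np.zeros((mol.n_atoms, n_types))
        member[np.arange(mol.n_atoms), t_idx] = 1.0
        for rec in diffs:
            p = rec.grid.points
            diff = p[:, None, :] - mol.coordinates[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            kernel = diff / dist[..., None] ** 3
            # potential at point i from a unit-α dipole E_ext on atom j,
            # summed over the atoms of each type
            per_atom = kernel @ rec.applied_field     # (points, atoms)
            blocks.append(per_atom @ member)
            targets.append(rec.values)
    unsupported = [problem.typing.matchers[k]
                   for k in range(n_types) if not support[k]]
    if unsupported:
        raise UnidentifiableParameterError(
            f"no atoms match type(s) {unsupported} in any conformer")
    return np.concatenate(blocks), np.concatenate(targets)


def fit_polarizabilities(
    problem: PolFitProblem,
    method: Literal["linear", "nelder-mead"] = "linear",
) -> PolFitResult:
    """Fit typed polarizabilities to field-perturbed ESP differences.

    Minimizes Σ_{k,l,i} (V_diff,ikl − Σ_j μ_ind,jkl·r_ijk/|r_ijk|³)² with
    μ_ind,jkl = α_type(j)·E_ext,l, subject to α ≥ 0.  ``method="linear"``
    solves the nonnegative least-squares problem in closed form;
    ``method="nelder-mead"`` minimizes the identical objective with the
    derivative-free simplex (with restarts).  The two agree to high
    precision on well-posed problems — a built-in solver cross-check.
    """
    design, target = _pol_design(problem)
    n_types = design.shape[1]

    def objective(alpha):
        res = target - design @ alpha
        return float(res @ res)

    if method == "linear":
        alpha, _ = scipy.optimize.nnls(design, target)
        nm_iter = 0
    elif method == "nelder-mead":
        # penalized objective keeps the simplex in the α ≥ 0 orthant
        scale = float(target @ target) + 1.0

        def penalized(alpha):
            if np.any(alpha < 0):
                return objective(np.maximum(alpha, 0.0)) \
                    + scale * float(np.sum(np.minimum(alpha, 0.0) ** 2))
            return objective(alpha)

        x = np.ones(n_types)
        nm_iter = 0
        for _restart in range(5):
            res = scipy.optimize.minimize(
                penalized, x, method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14,
                         "maxiter": 4000 * n_types})
            nm_iter += res.nit
            if np.allclose(res.x, x, rtol=0, atol=1e-10):
                x = res.x
                break
            x = res.x
        alpha = np.maximum(x, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    return PolFitResult(
        types=problem.typing.with_values(alpha),
        alphas=np.asarray(alpha, dtype=float),
        objective=objective(np.asarray(alpha, dtype=float)),
        method=method,
        n_residuals=len(target),
        nm_iterations=nm_iter,
    )


# ---------------------------------------------------------------------------
# RESP-dPol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestraintSpec:
    """Hyperbolic-restraint settings for one RESP stage.

    ``a`` (au) is the strength, ``b`` (au) the tightness of the penalty
    2a(√(q²+b²) − b) applied to each restrained atom; hydrogens are left
    unrestrained by default, following standard RESP practice.
    """

    a: float = 0.005
    b: float = 0.1
    restrain_hydrogens: bool = False
    stage: int = 1

    def __post_init__(self):
        if self.a < 0:
            raise ValueError("restraint strength a must be >= 0")
        if self.b <= 0:
            raise ValueError("restraint tightness b must be > 0")


DEFAULT_STAGES = (RestraintSpec(a=0.005, b=0.1, stage=1),
                  RestraintSpec(a=0.01, b=0.1, stage=2))


@dataclass
class ChargeFitResult:
    """Fitted per-atom charges plus solver diagnostics."""

    charges: np.ndarray
    lagrange_multiplier: float
    iterations: int
    converged: bool
    objective: float
    objective_history: list[float] = field(default_factory=list)
    stage2_objective_history: list[float] = field(default_factory=list)
    stage2_refit_atoms: list[int] = field(default_factory=list)


def stage2_refit_atoms(molecule: Molecule) -> tuple[list[int], list[list[int]]]:
    """Atoms refit in stage 2 and their equality classes.

    The refit set is every sp³ carbon (four single bonds) carrying at least
    two topologically equivalent hydrogens — methyl and methylene groups —
    together with those hydrogens; everything else keeps its stage-1
    charge.  Equality classes are the topological symmetry classes
    restricted to the refit set.
    """
    classes = symmetry_classes(molecule)
    cls_of = {}
    for c_id, members in enumerate(classes):
        for j in members:
            cls_of[j] = c_id
    neighbors: dict[int, list[tuple[int, int]]] = {
        j: [] for j in range(molecule.n_atoms)}
    for i, j, order in molecule.bonds:
        neighbors[i].append((j, order))
        neighbors[j].append((i, order))

    refit: set[int] = set()
    for j, el in enumerate(molecule.atom_elements):
        if el != "C":
            continue
        nbrs = neighbors[j]
        if len(nbrs) != 4 or any(order != 1 for _, order in nbrs):
            continue
        h_nbrs = [k for k, _ in nbrs if molecule.atom_elements[k] == "H"]
        by_class: dict[int, list[int]] = {}
        for h in h_nbrs:
            by_class.setdefault(cls_of[h], []).append(h)
        equiv_h = [hs for hs in by_class.values() if len(hs) >= 2]
        if equiv_h:
            refit.add(j)
            for hs in equiv_h:
                refit.update(hs)

    eq_classes: dict[int, list[int]] = {}
    for j in sorted(refit):
        eq_classes.setdefault(cls_of[j], []).append(j)
    return sorted(refit), sorted(eq_classes.values(), key=lambda g: g[0])


def _restrained_solve(design, target, *, restraint_mask, a, b, q_total,
                      group_map=None, q_init=None, max_iter=200,
                      tol=1e-8):
    """Charge fit with hyperbolic restraint and a total-charge constraint.

    Minimizes ||target − design·q||² + Σ_j 2a(√(q_j²+b²) − b) over the
    restrained atoms, subject to Σq = q_total, by majorize–minimize: each
    round replaces the hyperbola with its quadratic majorizer at the
    current charges (an effective diagonal a/√(q_j²+b²)) and solves the
    resulting KKT system.  The true objective never increases.

    ``group_map`` (atoms × groups), when given, forces within-group charge
    equality by reparametrizing q = group_map·u.
    """
    n = design.shape[1]
    p = np.eye(n) if group_map is None else np.asarray(group_map, float)
    n_var = p.shape[1]
    a_var = design @ p                     # design on reduced variables
    m_vec = p.T @ np.ones(n)               # constraint: m·u = q_total
    # orthonormal basis of the constraint nullspace (via complete QR of m)
    full_q, _ = np.linalg.qr(m_vec.reshape(-1, 1), mode="complete")
    nullspace = full_q[:, 1:]              # (n_var, n_var-1)
    u_part = m_vec * (q_total / float(m_vec @ m_vec))  # particular solution

    def objective(q):
        res = target - design @ q
        pen = 2.0 * a * np.sum(
            np.sqrt(q[restraint_mask] ** 2 + b * b) - b)
        return float(res @ res + pen)

    if q_init is None:
        q = np.full(n, q_total / n)  # feasible start: uniform spread
    else:
        # project the warm start onto the equality groups and rescale the
        # total so the start is feasible — the monotone-descent guarantee
        # of the majorize-minimize iteration needs a feasible iterate
        q = np.asarray(q_init, float).copy()
        if group_map is not None:
            counts = p.sum(axis=0)
            q = p @ ((p.T @ q) / counts)
        q = q + (q_total - q.sum()) / n
    history = [objective(q)]
    converged = False
    lam = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        # quadratic majorizer of the hyperbola at the current charges:
        # effective diagonal a/sqrt(q²+b²) on restrained atoms
        d_atom = np.where(
            restraint_mask, a / np.sqrt(q ** 2 + b * b), 0.0)
        s_var = np.sqrt(p.T @ d_atom)      # disjoint groups: diagonal
        # eliminate the charge constraint: u = u_part + N z, solve the
        # stacked regularized least squares for z by SVD (well-conditioned,
        # unlike normal equations)
        top = a_var @ nullspace
        bottom = s_var[:, None] * nullspace
        rhs_top = target - a_var @ u_part
        rhs_bottom = -s_var * u_part
        stacked = np.vstack([top, bottom])
        rhs = np.concatenate([rhs_top, rhs_bottom])
        z, residuals, rank, _sv = np.linalg.lstsq(stacked, rhs, rcond=None)
        if rank < stacked.shape[1]:
            raise RankDeficiencyError(
                "singular charge-fitting design (degenerate grid or "
                "topology)")
        u = u_part + nullspace @ z
        q_new = p @ u
        # Lagrange multiplier from stationarity: λ·m = 2Aᵀ(V−Aq) − 2Dq
        grad = 2.0 * (a_var.T @ (target - a_var @ u)) \
            - 2.0 * (p.T @ d_atom) * u
        lam = float(m_vec @ grad / (m_vec @ m_vec))
        delta = float(np.max(np.abs(q_new - q)))
        q = q_new
        history.append(objective(q))
        if delta < tol or a == 0.0:
            converged = True  # a == 0: the single solve is exact
            break
    return q, lam, it, converged, history


def fit_resp_dpol(
    molecule: Molecule,
    baseline: ESPRecord,
    alphas,
    stages: Sequence[RestraintSpec] = DEFAULT_STAGES,
) -> ChargeFitResult:
    """Two-stage RESP-dPol charge fit to a baseline ESP.

    The model ESP is (C + G)·q — bare Coulomb plus the induced-dipole
    contribution driven by the attenuated permanent-charge fields — so the
    fitted charges are polarization-consistent.  Stage 1 fits every atom
    with the weak restraint; stage 2 refits methyl/methylene carbons and
    their equivalent hydrogens under forced symmetry and the strong
    restraint, holding all other (polar-region) charges fixed.
    """
    if baseline.kind != "baseline" or np.any(baseline.applied_field != 0):
        raise ValueError("RESP-dPol fits the zero-field baseline ESP")
    a = np.asarray(alphas, dtype=float)
    if len(a) != molecule.n_atoms:
        raise ValueError("alphas length != atom count")
    coulomb, induced = esp_design_matrices(molecule, a, baseline.grid)
    design = coulomb + induced
    target = baseline.values
    q_tot = float(molecule.formal_charge)
    is_h = np.array([el == "H" for el in molecule.atom_elements])

    stage_list = list(stages)
    s1 = stage_list[0]
    mask1 = np.ones(molecule.n_atoms, bool) if s1.restrain_hydrogens \
        else ~is_h
    q, lam, it1, conv1, hist = _restrained_solve(
        design, target, restraint_mask=mask1, a=s1.a, b=s1.b,
        q_total=q_tot)

    refit: list[int] = []
    hist2: list[float] = []
    it2, conv2 = 0, True
    if len(stage_list) > 1:
        s2 = stage_list[1]
        refit, eq_classes = stage2_refit_atoms(molecule)
        if refit:
            frozen = [j for j in range(molecule.n_atoms) if j not in refit]
            target2 = target - design[:, frozen] @ q[frozen]
            group_map = np.zeros((len(refit), len(eq_classes)))
            pos = {j: k for k, j in enumerate(refit)}
            for g, members in enumerate(eq_classes):
                for j in members:
                    group_map[pos[j], g] = 1.0
            mask2 = np.array([not is_h[j] or s2.restrain_hydrogens
                              for j in refit])
            q_free_tot = q_tot - float(q[frozen].sum())
            q_sub, lam, it2, conv2, hist2 = _restrained_solve(
                design[:, refit], target2, restraint_mask=mask2,
                a=s2.a, b=s2.b, q_total=q_free_tot, group_map=group_map,
                q_init=q[refit])
            q = q.copy()
            q[refit] = q_sub

    res = target - design @ q
    objective = float(res @ res)
    return ChargeFitResult(
        charges=q,
        lagrange_multiplier=lam,
        iterations=it1 + it2,
        converged=conv1 and conv2,
        objective=objective,
        objective_history=hist,
        stage2_objective_history=hist2,
        stage2_refit_atoms=refit,
    )


# ---------------------------------------------------------------------------
# BCC-dPol
# ---------------------------------------------------------------------------

@dataclass
class BCCFitResult:
    """Fitted bond charge corrections B_β (e) per bond type."""

    bcc_values: np.ndarray
    covered_types: list[int]
    objective: float


def fit_bccs(
    training: Sequence[tuple[Molecule, Sequence[float], ESPRecord]],
    table: BondTypeTable,
    alpha_types: PolarizabilityTypeSet,
    induced_on: Literal["corrected", "precharges"] = "corrected",
) -> BCCFitResult:
    """Train bond charge corrections against reference ESPs.

    For each training conformer the model ESP is V_pre + Coulomb ESP of
    the correction charges T·B + the induced-dipole contribution; with
    ``induced_on="corrected"`` (default) the dipoles respond to the full
    corrected charges q_pre + T·B, with ``"precharges"`` to the precharges
    only.  Either way the objective is linear in B and is minimized by a
    single minimum-norm least-squares solve over all conformers stacked.
    Bond types with no support anywhere get B = 0 and are excluded from
    ``covered_types``.
    """
    from dpolkit.chem_core import assign_polarizabilities

    n_types = len(table.types)
    blocks, targets = [], []
    for mol, precharges, baseline in training:
        q_pre = np.asarray(precharges, dtype=float)
        if len(q_pre) != mol.n_atoms:
            raise ValueError("precharges length != atom count")
        a = assign_polarizabilities(mol, alpha_types)
        t_mat = bond_type_matrix(mol, table)
        coulomb, induced = esp_design_matrices(mol, a, baseline.grid)
        full = coulomb + induced
        if induced_on == "corrected":
            blocks.append(full @ t_mat)
            targets.append(baseline.values - full @ q_pre)
        elif induced_on == "precharges":
            blocks.append(coulomb @ t_mat)
            targets.append(baseline.values - full @ q_pre)
        else:
            raise ValueError(f"unknown induced_on {induced_on!r}")
    design = np.concatenate(blocks)
    target = np.concatenate(targets)

    col_norm = np.linalg.norm(design, axis=0)
    covered = [k for k in range(n_types) if col_norm[k] > 0.0]
    bcc, *_ = np.linalg.lstsq(design, target, rcond=None)
    bcc[col_norm == 0.0] = 0.0
    res = target - design @ bcc
    return BCCFitResult(bcc_values=bcc, covered_types=covered,
                        objective=float(res @ res))


def assign_am1bcc_dpol(molecule: Molecule, precharges,
                       table: BondTypeTable,
                       bccs: BCCFitResult | np.ndarray) -> np.ndarray:
    """Assign charges q_j = q_j^pre + Σ_β T_jβ B_β.

    Deterministic, and conserves the total charge exactly because every
    column of T sums to zero.
    """
    q_pre = np.asarray(precharges, dtype=float)
    if len(q_pre) != molecule.n_atoms:
        raise ValueError("precharges length != atom count")
    values = bccs.bcc_values if isinstance(bccs, BCCFitResult) \
        else np.asarray(bccs, dtype=float)
    t_mat = bond_type_matrix(molecule, table)
    used = np.where(np.any(t_mat != 0.0, axis=0))[0]
    if np.any(~np.isfinite(values[used])):
        missing = [int(k) for k in used if not np.isfinite(values[k])]
        raise TypeAssignmentError(
            f"bond type(s) {missing} matched but have no fitted value")
    return q_pre + t_mat @ values
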