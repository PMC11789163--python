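"""Pseudo-random structure generation, local minimization and duplicate
clustering.

This is both the baseline search (PR: sample a random packing, minimize
its lattice energy) and the inner engine of every EVCCP step (minimize
the biased energy U(X, H | S) from a seeded start).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .crystal import (
    EVState,
    PackingState,
    RigidMolecule,
    SpaceGroup,
    cell_matrix,
    density,
)
from .energy import (
    CouplingSpec,
    PotentialConfig,
    _objective_grad_nb,
    _replicated_params,
    harmonic_penalty,
    lattice_energy,
)

__all__ = [
    "SamplerBounds",
    "BoundsInfeasibleError",
    "Provenance",
    "PolymorphRecord",
    "DedupTolerances",
    "sample_random_start",
    "local_minimize",
    "prefilter",
    "is_duplicate",
    "deduplicate",
    "pr_search",
]


class BoundsInfeasibleError(RuntimeError):
    """Sampling bounds reject every draw (density window unreachable)."""


@dataclass(frozen=True)
class SamplerBounds:
    """Domains for pseudo-random packing generation.

    Cell lengths are drawn uniformly per free parameter from
    ``length_range``; free cell angles from ``angle_range``; draws outside
    the density window are rejected and redrawn.  COMs are uniform in the
    cell, Euler angles uniform on [0, 360).
    """

    length_range: tuple = (3.0, 10.0)
    angle_range: tuple = (60.0, 120.0)
    density_range: tuple = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")
        if self.density_range[0] >= self.density_range[1]:
            raise ValueError("density window must satisfy rho_min < rho_max")


@dataclass(frozen=True)
class Provenance:
    run_id: str = ""
    step: int = -1
    batch_index: int = -1
    replica: int = -1


@dataclass
class PolymorphRecord:
    """A locally minimized structure with its energy decomposition.

    ``penalty`` is the harmonic coupling energy at the optimum (0 for
    unbiased searches); the invariant U_biased = U_unb + penalty always
    holds.  Non-converged records are kept and flagged, never dropped.
    """

    state: PackingState
    U_unb: float
    penalty: float
    U_biased: float
    converged: bool
    provenance: Provenance = field(default_factory=Provenance)
    seed: int = 0

    def __post_init__(self) -> None:
        if math.isfinite(self.U_unb):
            assert abs(self.U_biased - (self.U_unb + self.penalty)) < 1e-6


def sample_random_start(
    bounds: SamplerBounds,
    sg: SpaceGroup,
    z_prime: int,
    mol: RigidMolecule,
    rng: np.random.Generator,
    max_density_rejects: int = 1000,
) -> PackingState:
    """Draw one pseudo-random packing within the bounds.

    Cell parameters respect the space group's fixed angles; densities are
    enforced by rejection sampling on the drawn cell.
    """
    lo, hi = bounds.length_range
    alo, ahi = bounds.angle_range
    for _ in range(max_density_rejects):
        H = np.empty(6)
        H[:3] = rng.uniform(lo, hi, size=3)
        for i in (3, 4, 5):
            H[i] = sg.fixed_angles.get(i, rng.uniform(alo, ahi))
        try:
            A = cell_matrix(H)
        except Exception:
            continue
        X = np.empty((z_prime, 6))
        frac = rng.uniform(0.0, 1.0, size=(z_prime, 3))
        X[:, :3] = frac @ A
        X[:, 3:] = rng.uniform(0.0, 360.0, size=(z_prime, 3))
        st = PackingState(X, H)
        rho = density(st, mol, sg)
        if bounds.density_range[0] <= rho <= bounds.density_range[1]:
            return st
    raise BoundsInfeasibleError(
        f"no draw satisfied density window {bounds.density_range} "
        f"after {max_density_rejects} attempts"
    )


def _wrap_state(state: PackingState) -> PackingState:
    """Wrap COMs into the cell (fractional) and Euler angles into [0, 360)."""
    A = cell_matrix(state.H)
    Ainv = np.linalg.inv(A)
    frac = (state.X[:, :3] @ Ainv) % 1.0
    X = state.X.copy()
    X[:, :3] = frac @ A
    X[:, 3:] = X[:, 3:] % 360.0
    return PackingState(X, state.H.copy())


def local_minimize(
    start: PackingState,
    mol: RigidMolecule,
    sg: SpaceGroup,
    pot: PotentialConfig = PotentialConfig(),
    S: Optional[EVState] = None,
    coupling: Optional[CouplingSpec] = None,
    gtol: float = 1e-4,
    maxiter: int = 500,
    provenance: Provenance = Provenance(),
    seed: int = 0,
) -> PolymorphRecord:
    """Quasi-Newton (L-BFGS-B) minimization of U(X, H) or U(X, H | S).

    The free coordinates are the Z'*6 packing CVs plus the symmetry-free
    cell parameters; S, when given, is held fixed (adiabatic decoupling)
    and the harmonic coupling enters the objective.  The returned record
    stores both the unbiased energy and the coupling penalty at the
    optimum.
    """
    if S is not None and coupling is None:
        raise ValueError("coupling must be given when minimizing against S")
    z = start.z_prime
    free_idx = sg.free_cell_indices
    params0 = np.concatenate([start.flat, start.H[free_idx]])
    k_com = coupling.k_com if coupling else 0.0
    k_eul = coupling.k_euler if coupling else 0.0
    Sflat = S.flat if S is not None else np.zeros(z * 6)
    eps, sig, q = _replicated_params(mol, sg, z)  # per cell atom
    args = (
        z, mol.sites, eps, sig, q,
        sg.rot_array(), sg.tran_array(), start.H.copy(), free_idx,
        pot.cutoff_radius, mol.radius, pot.image_shell_margin,
        pot.coulomb_constant, Sflat, k_com, k_eul,
    )

    lb = np.full(params0.size, -np.inf)
    ub = np.full(params0.size, np.inf)
    for i, ci in enumerate(free_idx):
        j = z * 6 + i
        if ci < 3:  # length
            lb[j], ub[j] = 1.5, 60.0
        else:  # angle
            lb[j], ub[j] = 30.0, 150.0
    res = _scipy_minimize(
        _objective_grad_nb, params0, args=args, jac=True, method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11},
    )
    X = res.x[: z * 6].reshape(z, 6)
    H = start.H.copy()
    H[free_idx] = res.x[z * 6 :]
    if S is None:
        state = _wrap_state(PackingState(X, H))
    else:
        # keep COMs unwrapped: the tether to S breaks translation
        # symmetry, and the stored penalty must match the objective's
        X = X.copy()
        X[:, 3:] = X[:, 3:] % 360.0
        state = PackingState(X, H)
    U_unb = lattice_energy(state, mol, sg, pot)
    pen = (
        harmonic_penalty(state.X, S.S, coupling) if S is not None else 0.0
    )
    converged = bool(res.success) and math.isfinite(U_unb)
    return PolymorphRecord(
        state=state, U_unb=U_unb, penalty=pen, U_biased=U_unb + pen,
        converged=converged, provenance=provenance, seed=seed,
    )


def prefilter(
    state: PackingState,
    mol: RigidMolecule,
    sg: SpaceGroup,
    pot: PotentialConfig,
    E_threshold: float,
) -> bool:
    """True iff the pre-optimization energy U(X = S_test, H) is at or
    below the threshold (unsuitable configurations are rejected before
    the costly minimization)."""
    return lattice_energy(state, mol, sg, pot) <= E_threshold


# ---------------------------------------------------------------------------
# duplicate clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DedupTolerances:
    tol_E: float = 0.1          # kJ/mol
    tol_len: float = 0.1        # Å
    tol_ang: float = 0.5        # deg
    tol_r: float = 0.3          # Å  (COM RMSD)


def _best_com_rmsd(a: PackingState, b: PackingState, sg: SpaceGroup) -> float:
    """Minimum COM RMSD between two packings over symmetry images of b,
    molecule permutations, and lattice translations.

    The global origin is handled discretely by anchoring molecule pairs
    (a_0 to every molecule of the b image) before minimum-image matching;
    continuous origin freedom beyond that (e.g. polar axes) is absorbed
    into the anchoring.
    """
    A = cell_matrix(a.H)
    Ainv = np.linalg.inv(A)
    fa = (a.X[:, :3] @ Ainv) % 1.0
    fb0 = (b.X[:, :3] @ np.linalg.inv(cell_matrix(b.H))) % 1.0
    z = fa.shape[0]
    best = math.inf
    perms = list(permutations(range(z))) if z <= 4 else [tuple(range(z))]
    for w, t in sg.ops:
        fb = (fb0 @ w.T + t) % 1.0
        for anchor in range(z):
            shift = fa[0] - fb[anchor]
            fbs = (fb + shift) % 1.0
            for perm in perms:
                d = fa - fbs[list(perm)]
                d -= np.round(d)  # minimum image in fractional space
                cart = d @ A
                r = math.sqrt(float((cart * cart).sum()) / z)
                if r < best:
                    best = r
    return best


def _niggli_params(H: np.ndarray) -> np.ndarray:
    """Canonical (Niggli-reduced) cell parameters, for setting-independent
    lattice comparison."""
    import gemmi

    gv = gemmi.GruberVector(gemmi.UnitCell(*np.asarray(H, float)), None)
    gv.niggli_reduce()
    return np.array(gv.cell_parameters())


def is_duplicate(
    a: PolymorphRecord,
    b: PolymorphRecord,
    sg: SpaceGroup,
    tol: DedupTolerances = DedupTolerances(),
) -> bool:
    """Structural identity test.

    Energies must agree within ``tol_E``.  Same-setting cells are then
    compared parameter-by-parameter together with the best-match COM
    geometry; cells in different (but lattice-equivalent) settings are
    recognised through their Niggli-reduced parameters, where the COM
    check is not applicable and energy + reduced lattice decide.
    """
    if not (math.isfinite(a.U_unb) and math.isfinite(b.U_unb)):
        return a.U_unb == b.U_unb and np.allclose(a.state.H, b.state.H)
    if abs(a.U_unb - b.U_unb) >= tol.tol_E:
        return False
    dH = np.abs(a.state.H - b.state.H)
    if np.all(dH[:3] < tol.tol_len) and np.all(dH[3:] < tol.tol_ang):
        return _best_com_rmsd(a.state, b.state, sg) < tol.tol_r
    dN = np.abs(_niggli_params(a.state.H) - _niggli_params(b.state.H))
    return bool(np.all(dN[:3] < tol.tol_len) and np.all(dN[3:] < tol.tol_ang))


def deduplicate(
    records: Sequence[PolymorphRecord],
    sg: SpaceGroup,
    tol: DedupTolerances = DedupTolerances(),
) -> list:
    """Distinct-structure list, keeping the lowest-energy representative
    of every duplicate group.  Idempotent."""
    reps: list = []
    for rec in sorted(records, key=lambda r: r.U_unb):
        dup = False
        for rep in reps:
            if abs(rec.U_unb - rep.U_unb) >= tol.tol_E:
                continue
            if is_duplicate(rec, rep, sg, tol):
                dup = True
                break
        if not dup:
            reps.append(rec)
    return reps


def pr_search(
    N: int,
    bounds: SamplerBounds,
    mol: RigidMolecule,
    sg: SpaceGroup,
    z_prime: int,
    pot: PotentialConfig = PotentialConfig(),
    rng: np.random.Generator | int = 0,
    maxiter: int = 500,
    gtol: float = 1e-4,
    run_id: str = "pr",
) -> list:
    """Baseline pseudo-random search: N independent sample -> minimize
    draws.  Reproducible for a given seed."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = []
    for i in range(N):
        start = sample_random_start(bounds, sg, z_prime, mol, rng)
        rec = local_minimize(
            start, mol, sg, pot, maxiter=maxiter, gtol=gtol,
            provenance=Provenance(run_id=run_id, step=i),
        )
        out.append(rec)
    return out
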