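"""Coordinate conventions, space-group symmetry and shared structural types.

A crystal configuration is a pair (X, H): X holds the collective variables
of the Z' molecules of the asymmetric unit -- Cartesian centre-of-mass
triples (Å) and intrinsic ZYZ Euler angles (degrees) -- and H the six unit
cell parameters (a, b, c in Å; alpha, beta, gamma in degrees).  The
extended-variable state S shares the layout of X but lives in an orthogonal
reference box.  The flat dimensionality of either is d = Z' * 6.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np

from .constants import N_AVOGADRO

__all__ = [
    "RigidMolecule",
    "PackingState",
    "EVState",
    "SpaceGroup",
    "get_space_group",
    "SHIPPED_SPACE_GROUPS",
    "euler_to_matrix",
    "matrix_to_euler",
    "cell_matrix",
    "cell_volume",
    "expand_to_cell",
    "density",
]


class InvalidCellError(ValueError):
    """Raised when unit-cell parameters are degenerate or violate symmetry."""


# ---------------------------------------------------------------------------
# Euler angles: intrinsic ZYZ, degrees.
# ---------------------------------------------------------------------------

def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(euler: Sequence[float]) -> np.ndarray:
    """Rotation matrix of intrinsic ZYZ Euler angles given in degrees.

    R = Rz(alpha) @ Ry(beta) @ Rz(gamma); the returned matrix is proper
    orthonormal (det +1).
    """
    e = np.asarray(euler, dtype=float)
    if e.shape != (3,) or not np.all(np.isfinite(e)):
        raise ValueError(f"need 3 finite Euler angles, got {euler!r}")
    a, b, g = np.deg2rad(e)
    return _rz(a) @ _ry(b) @ _rz(g)


def matrix_to_euler(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix` (degrees).

    At gimbal lock (beta = 0 or 180 deg) alpha and gamma are degenerate;
    the canonical form gamma = 0 is returned.
    """
    R = np.asarray(R, dtype=float)
    cb = min(1.0, max(-1.0, R[2, 2]))
    b = np.arccos(cb)
    if np.sin(b) > 1e-9:
        a = np.arctan2(R[1, 2], R[0, 2])
        g = np.arctan2(R[2, 1], -R[2, 0])
    elif cb > 0.0:  # beta ~ 0: R = Rz(a+g)
        a = np.arctan2(R[1, 0], R[0, 0])
        g = 0.0
    else:  # beta ~ 180: R = Rz(a-g) . Ry(180)
        a = np.arctan2(-R[1, 0], -R[0, 0])
        g = 0.0
    return np.rad2deg(np.array([a, b, g]))


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

def cell_matrix(H: Sequence[float]) -> np.ndarray:
    """3x3 matrix whose *rows* are the lattice vectors a, b, c.

    Standard crystallographic setting: a along x, b in the xy plane.
    """
    a, b, c, al, be, ga = np.asarray(H, dtype=float)
    if a <= 0 or b <= 0 or c <= 0:
        raise InvalidCellError(f"non-positive cell length in {H!r}")
    if not (0 < al < 180 and 0 < be < 180 and 0 < ga < 180):
        raise InvalidCellError(f"cell angle outside (0, 180) in {H!r}")
    alr, ber, gar = np.deg2rad([al, be, ga])
    ca, cb, cg = np.cos([alr, ber, gar])
    sg = np.sin(gar)
    cx = c * cb
    cy = c * (ca - cb * cg) / sg
    arg = c * c - cx * cx - cy * cy
    if arg <= 0:
        raise InvalidCellError(f"degenerate cell {H!r}")
    cz = np.sqrt(arg)
    return np.array([[a, 0.0, 0.0], [b * cg, b * sg, 0.0], [cx, cy, cz]])


def cell_volume(H: Sequence[float]) -> float:
    return float(np.linalg.det(cell_matrix(H)))


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidMolecule:
    """A rigid molecular unit in its body frame.

    ``sites`` are Cartesian body-frame coordinates (Å) whose unweighted
    centroid is forced to the origin at construction.  ``site_params`` holds
    one (epsilon kJ/mol, sigma Å, charge e) triple per site.
    """

    label: str
    sites: np.ndarray
    site_params: np.ndarray
    molar_mass: float

    def __post_init__(self) -> None:
        sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        params = np.atleast_2d(np.asarray(self.site_params, dtype=float))
        if sites.ndim != 2 or sites.shape[1] != 3 or sites.shape[0] < 1:
            raise ValueError("sites must be an (n, 3) array with n >= 1")
        if params.shape != (sites.shape[0], 3):
            raise ValueError("site_params must be (n_sites, 3): eps, sigma, q")
        if np.any(params[:, 0] < 0):
            raise ValueError("epsilon must be >= 0")
        if np.any(params[:, 1] <= 0):
            raise ValueError("sigma must be > 0")
        sites = sites - sites.mean(axis=0)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "site_params", params)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    @property
    def diameter(self) -> float:
        """Largest site-site extent plus one sigma (Å), a collision scale."""
        if self.n_sites == 1:
            return float(self.site_params[0, 1])
        d = np.linalg.norm(self.sites[:, None] - self.sites[None, :], axis=-1)
        return float(d.max() + self.site_params[:, 1].max())

    @property
    def radius(self) -> float:
        """Largest body-frame site distance from the centroid (Å)."""
        return float(np.linalg.norm(self.sites, axis=1).max())


@dataclass
class PackingState:
    """One crystal configuration: asymmetric-unit CVs plus cell parameters.

    ``X`` has shape (Z', 6): columns 0-2 Cartesian COM (Å), columns 3-5
    intrinsic ZYZ Euler angles (deg).  ``H`` is (a, b, c, alpha, beta,
    gamma).
    """

    X: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.H = np.asarray(self.H, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != 6:
            raise ValueError("X must have shape (Z', 6)")
        if self.H.shape != (6,):
            raise ValueError("H must be the 6 cell parameters")
        cell_matrix(self.H)  # validates

    @property
    def z_prime(self) -> int:
        return self.X.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.X.ravel().copy()

    def copy(self) -> "PackingState":
        return PackingState(self.X.copy(), self.H.copy())


@dataclass
class EVState:
    """Extended variables S in an orthogonal, non-self-interacting box.

    Layout-compatible with :class:`PackingState.X`.  The box must dominate
    the molecular volume (edge >= 3x molecule diameter when validated
    against a molecule).
    """

    S: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        if self.S.ndim != 2 or self.S.shape[1] != 6:
            raise ValueError("S must have shape (Z', 6)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive edge lengths")

    @property
    def z_prime(self) -> int:
        return self.S.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.S.ravel().copy()

    def with_flat(self, v: np.ndarray) -> "EVState":
        return EVState(np.asarray(v, float).reshape(self.S.shape), self.box.copy())

    def validate_box(self, mol: RigidMolecule) -> None:
        if np.any(self.box < 3.0 * mol.diameter):
            raise ValueError(
                "reference box edge must be >= 3x the molecule diameter"
            )


@dataclass(frozen=True)
class SpaceGroup:
    """A space group as an explicit list of (rotation, translation) ops.

    ``ops`` act on fractional coordinates: f' = W f + t.  ``fixed_angles``
    maps an index in (alpha, beta, gamma) = (3, 4, 5) to its symmetry-fixed
    value in degrees; the remaining cell parameters are free.
    """

    symbol: str
    ops: tuple
    fixed_angles: dict = field(default_factory=dict)

    @property
    def n_ops(self) -> int:
        return len(self.ops)

    @property
    def free_cell_indices(self) -> np.ndarray:
        return np.array([i for i in range(6) if i not in self.fixed_angles])

    def full_cell(self, free_values: np.ndarray) -> np.ndarray:
        H = np.empty(6)
        H[self.free_cell_indices] = free_values
        for i, v in self.fixed_angles.items():
            H[i] = v
        return H

    def check_cell(self, H: Sequence[float], tol: float = 1e-8) -> None:
        H = np.asarray(H, dtype=float)
        for i, v in self.fixed_angles.items():
            if abs(H[i] - v) > tol:
                raise InvalidCellError(
                    f"{self.symbol}: cell parameter {i} must be {v}, got {H[i]}"
                )
        cell_matrix(H)

    def rot_array(self) -> np.ndarray:
        return np.array([w for w, _ in self.ops], dtype=float)

    def tran_array(self) -> np.ndarray:
        return np.array([t for _, t in self.ops], dtype=float)


#: Hermann-Mauguin symbols of the shipped groups (one monoclinic setting
#: each, unique axis b).
SHIPPED_SPACE_GROUPS = (
    "P1", "P-1", "P21", "P21/c", "P212121", "Pca21", "C2", "C2/c",
    "Pbca", "Pna21", "P21/m", "Cc", "P2/c",
)

_SG_CACHE: dict = {}


def get_space_group(symbol: str) -> SpaceGroup:
    """Look up one of the shipped space groups by short H-M symbol.

    Operator lists come from gemmi's space-group tables; only the 13
    shipped triclinic/monoclinic/orthorhombic groups are exposed.
    """
    if symbol not in SHIPPED_SPACE_GROUPS:
        raise KeyError(
            f"unknown space group {symbol!r}; shipped: {SHIPPED_SPACE_GROUPS}"
        )
    if symbol in _SG_CACHE:
        return _SG_CACHE[symbol]
    gsg = gemmi.SpaceGroup(symbol)
    den = float(gemmi.Op.DEN)
    ops = []
    for op in gsg.operations():
        w = np.array(op.rot, dtype=float) / den
        t = np.array(op.tran, dtype=float) / den
        ops.append((w, t))
    system = gsg.crystal_system_str()
    if system == "triclinic":
        fixed = {}
    elif system == "monoclinic":
        fixed = {3: 90.0, 5: 90.0}
    elif system == "orthorhombic":
        fixed = {3: 90.0, 4: 90.0, 5: 90.0}
    else:  # pragma: no cover - shipped list excludes higher symmetry
        raise ValueError(f"unsupported crystal system {system}")
    sg = SpaceGroup(symbol=symbol, ops=tuple(ops), fixed_angles=fixed)
    _SG_CACHE[symbol] = sg
    return sg


# ---------------------------------------------------------------------------
# Expansion and density
# ---------------------------------------------------------------------------

def expand_to_cell(
    state: PackingState, mol: RigidMolecule, sg: SpaceGroup
) -> np.ndarray:
    """Cartesian atomic sites (Å) of the full unit cell.

    COMs are wrapped into [0, 1)^3 fractionally before applying the
    symmetry operators; orientations are carried along by the Cartesian
    image of each operator's rotation part.  Returns an
    (n_ops * Z' * n_sites, 3) array.
    """
    sg.check_cell(state.H)
    A = cell_matrix(state.H)
    Ainv_T = np.linalg.inv(A.T)
    atoms = []
    for m in range(state.z_prime):
        com = state.X[m, :3]
        R = euler_to_matrix(state.X[m, 3:])
        offsets = mol.sites @ R.T  # rotated body sites, Cartesian
        com_frac = (Ainv_T @ com) % 1.0
        for w, t in sg.ops:
            new_frac = (w @ com_frac + t) % 1.0
            new_com = A.T @ new_frac
            C = A.T @ w @ Ainv_T  # Cartesian image of the op's linear part
            atoms.append(offsets @ C.T + new_com)
    return np.concatenate(atoms, axis=0)


def density(state: PackingState, mol: RigidMolecule, sg: SpaceGroup) -> float:
    """Crystal density in g/cm^3."""
    V = cell_volume(state.H)  # Å^3
    if V <= 0:
        raise InvalidCellError("degenerate cell")
    n_mol = sg.n_ops * state.z_prime
    return n_mol * mol.molar_mass / (N_AVOGADRO * V * 1e-24)
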