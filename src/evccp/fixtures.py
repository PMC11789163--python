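"""Synthetic fixture systems: toy rigid molecules, reference polymorphs
and analytic surrogates.

The shipped molecules are deliberately small Lennard-Jones bodies
(epsilon = 1 kJ/mol, sigma = 3.4 Å, charges zero by default -- a charged
variant covers the Coulomb path).  They are chosen for numerical
robustness and for the structural features the samplers assume: multiple
local minima, orientation-sensitive packing, and duplicate degeneracy
under lattice resetting.  Reference polymorphs are produced by seeded
pseudo-random searches and cached in-process.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .crystal import EVState, RigidMolecule, SpaceGroup, get_space_group
from .energy import PotentialConfig
from .search import (
    PolymorphRecord,
    SamplerBounds,
    deduplicate,
    pr_search,
)
from .surrogates import make_surrogate_ev_system  # re-export

__all__ = [
    "molecule",
    "FixtureSystem",
    "fixture_system",
    "make_reference_polymorph",
    "make_surrogate_ev_system",
    "reference_ev",
    "MOLECULES",
    "SYSTEMS",
]

_EPS = 1.0
_SIG = 3.4


def _mol_atom() -> RigidMolecule:
    return RigidMolecule(
        "atom", np.zeros((1, 3)), np.array([[_EPS, _SIG, 0.0]]), 40.0
    )


def _mol_bent3() -> RigidMolecule:
    # bent triatomic, ~104 deg apex angle, 1.3 Å arms
    sites = np.array(
        [[0.0, 0.0, 0.0], [1.3, 0.0, 0.0], [-0.32, 1.26, 0.0]]
    )
    params = np.tile([_EPS, _SIG, 0.0], (3, 1))
    return RigidMolecule("bent3", sites, params, 42.0)


def _mol_bent3q() -> RigidMolecule:
    # charged variant: +0.2 on the apex, -0.1 on each arm site
    sites = np.array(
        [[0.0, 0.0, 0.0], [1.3, 0.0, 0.0], [-0.32, 1.26, 0.0]]
    )
    params = np.array(
        [[_EPS, _SIG, 0.2], [_EPS, _SIG, -0.1], [_EPS, _SIG, -0.1]]
    )
    return RigidMolecule("bent3q", sites, params, 42.0)


def _mol_planar5() -> RigidMolecule:
    # planar fused-ring-like pentad (aromatic-molecule aspect ratio)
    sites = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.4, 0.0, 0.0],
            [2.1, 1.2, 0.0],
            [1.4, 2.4, 0.0],
            [0.0, 2.4, 0.0],
        ]
    )
    params = np.tile([_EPS, _SIG, 0.0], (5, 1))
    return RigidMolecule("planar5", sites, params, 90.0)


MOLECULES = {
    "atom": _mol_atom,
    "bent3": _mol_bent3,
    "bent3q": _mol_bent3q,
    "planar5": _mol_planar5,
}


def molecule(name: str) -> RigidMolecule:
    """One of the shipped toy molecules by name."""
    try:
        return MOLECULES[name]()
    except KeyError:
        raise KeyError(f"unknown molecule {name!r}; shipped: {sorted(MOLECULES)}")


@dataclass(frozen=True)
class FixtureSystem:
    """A ready-to-search (molecule, space group, Z', bounds, potential)
    bundle."""

    name: str
    mol: RigidMolecule
    sg: SpaceGroup
    z_prime: int
    bounds: SamplerBounds
    pot: PotentialConfig

    @property
    def dim(self) -> int:
        return self.z_prime * 6


def _sys(name, mol_name, sg_symbol, z, lengths, dens, cutoff) -> FixtureSystem:
    return FixtureSystem(
        name=name,
        mol=molecule(mol_name),
        sg=get_space_group(sg_symbol),
        z_prime=z,
        bounds=SamplerBounds(length_range=lengths, density_range=dens),
        pot=PotentialConfig(cutoff_radius=cutoff),
    )


SYSTEMS = {
    # 1-site atom in P1: the cheapest lattice; energy is independent of
    # COM/orientation, ideal for pure-lattice reduction checks
    "atom_p1": lambda: _sys("atom_p1", "atom", "P1", 1, (3.2, 6.5), (0.8, 2.6), 6.0),
    # screw-axis mate makes the COM energetically meaningful at Z' = 1
    # while staying nearly as cheap as atom_p1
    "atom_p21": lambda: _sys("atom_p21", "atom", "P21", 1, (3.2, 7.0), (0.8, 2.6), 6.0),
    # the workhorse: orientation- and COM-sensitive, several minima
    "bent3_p1": lambda: _sys("bent3_p1", "bent3", "P1", 1, (3.6, 7.5), (0.5, 1.8), 6.0),
    "bent3_p21": lambda: _sys("bent3_p21", "bent3", "P21", 1, (3.6, 8.0), (0.5, 1.8), 6.0),
    # two independent molecules: relative COMs carry real forces, so
    # packing CVs move during relaxation (coupling-bias fixtures)
    "bent3_p1_z2": lambda: _sys("bent3_p1_z2", "bent3", "P1", 2, (4.2, 9.0), (0.5, 1.8), 6.0),
    "bent3_p21_z2": lambda: _sys("bent3_p21_z2", "bent3", "P21", 2, (4.0, 9.0), (0.5, 1.8), 6.0),
    "bent3q_p1": lambda: _sys("bent3q_p1", "bent3q", "P1", 1, (3.6, 7.5), (0.5, 1.8), 6.0),
    "planar5_p212121": lambda: _sys(
        "planar5_p212121", "planar5", "P212121", 1, (4.5, 11.0), (0.6, 1.8), 6.0
    ),
}


def fixture_system(name: str) -> FixtureSystem:
    """A shipped fixture system by name."""
    try:
        return SYSTEMS[name]()
    except KeyError:
        raise KeyError(f"unknown system {name!r}; shipped: {sorted(SYSTEMS)}")


@lru_cache(maxsize=32)
def _reference_cached(name: str, seed: int, n: int, maxiter: int):
    fs = fixture_system(name)
    recs = pr_search(
        n, fs.bounds, fs.mol, fs.sg, fs.z_prime, fs.pot,
        rng=seed, maxiter=maxiter, run_id=f"ref-{name}-{seed}",
    )
    finite = [r for r in recs if np.isfinite(r.U_unb)]
    if not finite:
        raise RuntimeError(f"fixture search produced no converged structure "
                           f"({name}, seed={seed})")
    distinct = deduplicate(finite, fs.sg)
    return tuple(distinct)


def make_reference_polymorph(
    name: str, seed: int = 0, n: int = 200, maxiter: int = 400
) -> PolymorphRecord:
    """Global-minimum reference polymorph of a fixture system.

    Runs a seeded PR search of ``n`` draws, deduplicates, and returns the
    lowest-energy distinct structure.  Deterministic per seed and cached
    in-process.
    """
    return _reference_cached(name, seed, n, maxiter)[0]


def reference_minima(
    name: str, seed: int = 0, n: int = 200, maxiter: int = 400
) -> tuple:
    """All distinct minima found by the seeded reference search,
    ascending in energy."""
    return _reference_cached(name, seed, n, maxiter)


def reference_ev(record: PolymorphRecord, mol: RigidMolecule) -> EVState:
    """EV state seeded at a polymorph's packing CVs, in a reference box
    three molecule diameters on edge (per cluster molecule)."""
    z = record.state.z_prime
    edge = max(3.0, 3.0 * mol.diameter * z)
    return EVState(record.state.X.copy(), np.full(3, edge))
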