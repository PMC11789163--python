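"""Analytic surrogate energy surfaces with documented, closed-form facts.

These stand in for the crystal PES in exact tests of the samplers: every
surface is deterministic, cheap, and ships the analytic quantities
(minima, Boltzmann variances, free-energy differences) that the Monte
Carlo machinery must reproduce.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import KB

__all__ = ["SurrogateSystem", "surrogate_surface", "make_surrogate_ev_system"]

_REGISTRY = ("quadratic", "double_well", "rough_quadratic", "gaussian_pair",
             "rare_well")


@dataclass
class SurrogateSystem:
    """An analytic EV energy surface plus its closed-form facts.

    ``energy`` maps a flat EV vector to kJ/mol.  ``facts`` holds analytic
    reference quantities keyed by name (documented per surface below).
    """

    name: str
    dim: int
    energy: Callable[[np.ndarray], float]
    facts: dict = field(default_factory=dict)

    def __call__(self, s: np.ndarray) -> float:
        return self.energy(np.atleast_1d(np.asarray(s, dtype=float)))


def _quadratic(params: dict) -> SurrogateSystem:
    """U(s) = 0.5 * k_eff * |s - center|^2.

    Facts: ``minima`` (the center), ``variance(T)`` = kB*T/k_eff per
    component (Boltzmann-exact).
    """
    dim = int(params.get("dim", 1))
    k = float(params.get("k_eff", 1.0))
    center = np.asarray(params.get("center", np.zeros(dim)), dtype=float)

    def energy(s: np.ndarray) -> float:
        d = s - center
        return 0.5 * k * float(d @ d)

    return SurrogateSystem(
        "quadratic", dim, energy,
        facts={
            "minima": [center.copy()],
            "k_eff": k,
            "variance": lambda T: KB * T / k,
            "sample": lambda T, n, rng: rng.normal(
                center, np.sqrt(KB * T / k), size=(n, dim)
            ),
        },
    )


def _double_well(params: dict) -> SurrogateSystem:
    """U(s) = a*(s0^2 - b^2)^2 + 0.5*k_rest*|s_rest|^2.

    Two minima at s0 = +/- b (energy 0), barrier height a*b^4 at s0 = 0.
    """
    dim = int(params.get("dim", 1))
    a = float(params.get("a", 1.0))
    b = float(params.get("b", 1.0))
    k_rest = float(params.get("k_rest", 1.0))

    def energy(s: np.ndarray) -> float:
        e = a * (s[0] ** 2 - b * b) ** 2
        if dim > 1:
            e += 0.5 * k_rest * float(s[1:] @ s[1:])
        return e

    m1 = np.zeros(dim)
    m1[0] = b
    m2 = np.zeros(dim)
    m2[0] = -b
    return SurrogateSystem(
        "double_well", dim, energy,
        facts={"minima": [m1, m2], "barrier": a * b**4, "a": a, "b": b},
    )


def _rough_quadratic(params: dict) -> SurrogateSystem:
    """Quadratic bowl roughened with seeded cosine ripples.

    U(s) = sum_i [0.5*k*s_i^2 + amp*cos(2*pi*s_i/lam + phi_i)] with phases
    drawn once from ``seed`` -- bit-exactly reproducible across calls.
    Local minima are enumerable by a dense per-dimension grid scan
    (``facts['minima_1d']`` for dim 1).
    """
    dim = int(params.get("dim", 1))
    k = float(params.get("k_eff", 1.0))
    amp = float(params.get("amp", 2.0))
    lam = float(params.get("wavelength", 1.0))
    seed = int(params.get("seed", 0))
    phases = np.random.default_rng(seed).uniform(0, 2 * np.pi, size=dim)

    def energy(s: np.ndarray) -> float:
        return float(
            np.sum(0.5 * k * s**2 + amp * np.cos(2 * np.pi * s / lam + phases))
        )

    def minima_1d(span: float = 6.0, n: int = 200001) -> np.ndarray:
        """Grid-scan enumeration of the 1D minima (dim must be 1)."""
        x = np.linspace(-span, span, n)
        u = 0.5 * k * x**2 + amp * np.cos(2 * np.pi * x / lam + phases[0])
        interior = (u[1:-1] < u[:-2]) & (u[1:-1] <= u[2:])
        return x[1:-1][interior]

    return SurrogateSystem(
        "rough_quadratic", dim, energy,
        facts={"k_eff": k, "amp": amp, "wavelength": lam, "seed": seed,
               "phases": phases, "minima_1d": minima_1d},
    )


def _gaussian_pair(params: dict) -> SurrogateSystem:
    """A pair of harmonic 'generators' A and B with exact Delta F(T).

    U_A(s) = 0.5*k_a*|s|^2;  U_B(s) = offset + 0.5*k_b*|s|^2.
    Free energies from the Gaussian partition functions give
    Delta F(T) = F_B - F_A = offset + (dim/2)*kB*T*ln(k_b/k_a).
    ``facts['sample_a']`` draws exact Boltzmann samples of ensemble A.
    """
    dim = int(params.get("dim", 2))
    k_a = float(params.get("k_a", 1.0))
    k_b = float(params.get("k_b", 4.0))
    offset = float(params.get("offset", 1.0))

    def energy_a(s: np.ndarray) -> float:
        return 0.5 * k_a * float(s @ s)

    def energy_b(s: np.ndarray) -> float:
        return offset + 0.5 * k_b * float(s @ s)

    def delta_f(T: float) -> float:
        return offset + 0.5 * dim * KB * T * np.log(k_b / k_a)

    def sample_a(T: float, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(KB * T / k_a), size=(n, dim))

    return SurrogateSystem(
        "gaussian_pair", dim, energy_a,
        facts={"energy_a": energy_a, "energy_b": energy_b,
               "delta_f": delta_f, "sample_a": sample_a,
               "k_a": k_a, "k_b": k_b, "offset": offset},
    )


def _rare_well(params: dict) -> SurrogateSystem:
    """A corrugated 1D EV landscape with one deep, narrow 'rare' well.

    U(x) = 0.5*k*x^2 + amp*cos(2*pi*x/lam + phase)
           - depth*exp(-(x - x_rare)^2 / (2*width^2))

    Many broad shallow minima (the corrugation) surround a single deep
    well of tiny basin volume at ``x_rare`` — the landscape topology of
    a rare low-energy polymorph.  A random-start descent finds the rare
    well with probability roughly its basin fraction of the domain,
    while a Boltzmann walker concentrates there once it is discovered.
    Facts: ``x_rare``, ``descend`` (Nelder-Mead local descent),
    ``is_rare`` (basin membership of a descended point), ``domain``.
    """
    k = float(params.get("k_eff", 0.2))
    amp = float(params.get("amp", 3.5))
    lam = float(params.get("wavelength", 1.1))
    phase = float(params.get("phase", 0.7))
    depth = float(params.get("depth", 12.0))
    width = float(params.get("width", 0.05))
    x_rare = float(params.get("x_rare", 3.31))
    domain = float(params.get("domain", 4.0))

    def energy(s: np.ndarray) -> float:
        x = float(s[0])
        return (
            0.5 * k * x * x
            + amp * np.cos(2 * np.pi * x / lam + phase)
            - depth * np.exp(-((x - x_rare) ** 2) / (2 * width * width))
        )

    def descend(x0: float) -> float:
        from scipy.optimize import minimize

        r = minimize(
            lambda v: energy(v), np.array([float(x0)]), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10},
        )
        return float(r.x[0])

    def is_rare(x_min: float) -> bool:
        return abs(x_min - x_rare) < 2.0 * width + 1e-9

    return SurrogateSystem(
        "rare_well", 1, energy,
        facts={"x_rare": x_rare, "depth": depth, "width": width,
               "domain": domain, "descend": descend, "is_rare": is_rare},
    )


_BUILDERS = {
    "quadratic": _quadratic,
    "double_well": _double_well,
    "rough_quadratic": _rough_quadratic,
    "gaussian_pair": _gaussian_pair,
    "rare_well": _rare_well,
}


def surrogate_surface(name: str, params: dict | None = None) -> SurrogateSystem:
    """Build one of the registered analytic surfaces by name."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown surrogate {name!r}; known: {_REGISTRY}")
    return _BUILDERS[name](dict(params or {}))


def make_surrogate_ev_system(
    name: str, params: dict | None = None, seed: int | None = None
) -> SurrogateSystem:
    """Like :func:`surrogate_surface`, seeding the roughened surface."""
    p = dict(params or {})
    if seed is not None:
        p.setdefault("seed", seed)
    return surrogate_surface(name, p)
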