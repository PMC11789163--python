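"""The core EVCCP Markov chain.

Each step holds the extended variables S fixed, generates a mini-batch of
M locally minimized polymorphs seeded at X0 = S with freshly drawn random
cells, takes the batch minimum of the biased energy as the conditional
configuration energy U(X, H | S), and propagates S by a Metropolis update
at bath temperature T.  Every generated polymorph is archived, whether or
not the proposal that produced it was accepted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .constants import KB
from .crystal import EVState, PackingState, RigidMolecule, SpaceGroup
from .energy import CouplingSpec, PotentialConfig
from .search import (
    Provenance,
    SamplerBounds,
    local_minimize,
    prefilter,
    sample_random_start,
)
from .surrogates import SurrogateSystem

__all__ = [
    "EvccpConfig",
    "BatchResult",
    "StepRecord",
    "StepInfeasibleError",
    "CrystalEvccpSystem",
    "SurrogateEvccpSystem",
    "mini_batch",
    "metropolis_update",
    "run_evccpmc",
]


class StepInfeasibleError(RuntimeError):
    """Every mini-batch member was pre-rejected, even after redraws."""

    def __init__(self, msg: str, n_prefiltered: int = 0):
        super().__init__(msg)
        self.n_prefiltered = n_prefiltered


@dataclass(frozen=True)
class EvccpConfig:
    """Sampler configuration for one EVCCP chain.

    ``E_threshold`` is an absolute pre-rejection energy for the
    unminimized X = S_test configuration; when None, the threshold floats
    at (running best unbiased energy + E_threshold_offset).  ``step_com``
    / ``step_euler`` are the per-class |dS|_max of the uniform proposal;
    with ``scale_step_with_kbt`` they are multiplied by kB*T.
    Mini-batch minimizations run loose by default (on-the-fly setting);
    full convergence belongs to post-processing.
    """

    coupling: CouplingSpec = CouplingSpec()
    M: int = 10
    T: float = 300.0
    step_com: float = 0.5
    step_euler: float = 15.0
    E_threshold: Optional[float] = None
    E_threshold_offset: float = 1000.0
    n_steps: int = 100
    seed: int = 0
    scale_step_with_kbt: bool = False
    batch_smoothing_T: Optional[float] = None
    prefilter_retries: int = 20
    minimize_maxiter: int = 80
    minimize_gtol: float = 1e-2

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.step_com <= 0 or self.step_euler <= 0:
            raise ValueError("step sizes must be > 0")


@dataclass
class BatchResult:
    """Outcome of evaluating one EV state."""

    records: list
    U_min: float
    X_min: Optional[PackingState]
    U_cond: float
    n_prefiltered: int = 0


@dataclass
class StepRecord:
    """One node of the EVCCP Markov chain.

    ``S`` is the current EV state after the update; ``U_cond`` its
    conditional energy.  ``batch`` holds the polymorphs generated for the
    *proposal* evaluated at this step (archived even when rejected);
    ``U_min`` / ``X_min`` are the proposal batch's biased minimum.
    """

    iter: int
    S: np.ndarray
    U_cond: float
    U_min: float
    X_min: Optional[PackingState]
    batch: list
    accepted: bool
    n_prefiltered: int = 0


# ---------------------------------------------------------------------------
# systems: what "evaluate S" means
# ---------------------------------------------------------------------------

class CrystalEvccpSystem:
    """Conditional-energy evaluator backed by the crystal generator.

    Evaluating S runs a mini-batch: M draws of a random cell H, packing
    seeded at X0 = S, threshold pre-rejection, biased local minimization.
    """

    def __init__(
        self,
        mol: RigidMolecule,
        sg: SpaceGroup,
        z_prime: int,
        bounds: SamplerBounds,
        pot: PotentialConfig,
        cfg: EvccpConfig,
        box: Optional[np.ndarray] = None,
        run_id: str = "evccp",
        replica: int = -1,
    ):
        self.mol, self.sg, self.z_prime = mol, sg, z_prime
        self.bounds, self.pot, self.cfg = bounds, pot, cfg
        self.box = (
            np.asarray(box, float)
            if box is not None
            else np.full(3, max(3.0 * mol.diameter, 3.0 * mol.diameter * z_prime))
        )
        self.run_id = run_id
        self.replica = replica
        self.running_best = math.inf

    @property
    def dim(self) -> int:
        return self.z_prime * 6

    @property
    def step_sizes(self) -> np.ndarray:
        s = np.empty((self.z_prime, 6))
        s[:, :3] = self.cfg.step_com
        s[:, 3:] = self.cfg.step_euler
        if self.cfg.scale_step_with_kbt:
            s *= KB * self.cfg.T
        return s.ravel()

    @property
    def angle_mask(self) -> np.ndarray:
        m = np.zeros((self.z_prime, 6), dtype=bool)
        m[:, 3:] = True
        return m.ravel()

    def threshold(self) -> float:
        if self.cfg.E_threshold is not None:
            return self.cfg.E_threshold
        if not math.isfinite(self.running_best):
            return math.inf
        return self.running_best + self.cfg.E_threshold_offset

    def evaluate(self, S_flat: np.ndarray, rng: np.random.Generator,
                 step: int = -1) -> BatchResult:
        S = EVState(S_flat.reshape(self.z_prime, 6), self.box)
        cfg = self.cfg
        records: list = []
        n_pref = 0
        thr = self.threshold()
        for m in range(cfg.M):
            state = None
            for _ in range(cfg.prefilter_retries):
                trial = sample_random_start(
                    self.bounds, self.sg, self.z_prime, self.mol, rng
                )
                cand = PackingState(S.S.copy(), trial.H)
                if prefilter(cand, self.mol, self.sg, self.pot, thr):
                    state = cand
                    break
                n_pref += 1
            if state is None:
                raise StepInfeasibleError(
                    f"all {cfg.prefilter_retries} redraws of batch member {m} "
                    f"exceeded E_threshold={thr:.3g}",
                    n_prefiltered=n_pref,
                )
            rec = local_minimize(
                state, self.mol, self.sg, self.pot, S=S, coupling=cfg.coupling,
                gtol=cfg.minimize_gtol, maxiter=cfg.minimize_maxiter,
                provenance=Provenance(
                    run_id=self.run_id, step=step, batch_index=m,
                    replica=self.replica,
                ),
            )
            records.append(rec)
            if rec.U_unb < self.running_best:
                self.running_best = rec.U_unb
        u_biased = np.array([r.U_biased for r in records])
        i_min = int(np.argmin(u_biased))
        U_min = float(u_biased[i_min])
        if cfg.batch_smoothing_T is not None:
            # soft-min hook: log-sum-exp over the batch at a smoothing T
            beta = 1.0 / (KB * cfg.batch_smoothing_T)
            w = -beta * u_biased
            wmax = w.max()
            U_cond = float(-(wmax + np.log(np.mean(np.exp(w - wmax)))) / beta)
        else:
            U_cond = U_min
        return BatchResult(records, U_min, records[i_min].state, U_cond, n_pref)


class SurrogateEvccpSystem:
    """Conditional-energy evaluator backed by an analytic surface (the
    generator is bypassed; U_cond(S) is the surface value)."""

    def __init__(self, surface: SurrogateSystem, step_sizes=0.5,
                 angle_mask: Optional[np.ndarray] = None):
        self.surface = surface
        self.dim = surface.dim
        self.step_sizes = np.broadcast_to(
            np.asarray(step_sizes, float), (self.dim,)
        ).copy()
        self.angle_mask = (
            np.zeros(self.dim, dtype=bool) if angle_mask is None else angle_mask
        )

    def evaluate(self, S_flat, rng, step: int = -1) -> BatchResult:
        u = float(self.surface(S_flat))
        return BatchResult([], u, None, u, 0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def mini_batch(
    S: EVState,
    cfg: EvccpConfig,
    mol: RigidMolecule,
    sg: SpaceGroup,
    bounds: SamplerBounds,
    rng: np.random.Generator,
    pot: PotentialConfig = PotentialConfig(),
):
    """Generate M biased-minimized polymorphs under a fixed S.

    Returns (records, U_min, X_min); see :class:`CrystalEvccpSystem`.
    """
    sys_ = CrystalEvccpSystem(mol, sg, S.z_prime, bounds, pot, cfg, box=S.box)
    res = sys_.evaluate(S.flat, rng)
    return res.records, res.U_min, res.X_min


def metropolis_update(
    S_flat: np.ndarray,
    U_cond: float,
    system,
    cfg: EvccpConfig,
    rng: np.random.Generator,
    extra_bias: Optional[Callable[[np.ndarray], float]] = None,
    step: int = -1,
):
    """One Metropolis proposal of the extended variables.

    Proposes S_test = S + dS with each component uniform on
    (-step_max, +step_max), evaluates U(X, H | S_test) through the
    system's generator (plus ``extra_bias`` if given, as in the
    history-biased MRE1 variant) and accepts with probability
    min(1, exp(-dU / kB T)).  Infeasible proposals count as rejections.

    Returns (S_next, U_cond_next, accepted, BatchResult-or-None).
    """
    steps = system.step_sizes
    dS = rng.uniform(-steps, steps)
    S_test = S_flat + dS
    S_test[system.angle_mask] %= 360.0
    try:
        res = system.evaluate(S_test, rng, step=step)
    except StepInfeasibleError as err:
        return S_flat, U_cond, False, BatchResult(
            [], math.inf, None, math.inf, err.n_prefiltered
        )
    u_test = res.U_cond
    u_cur = U_cond
    if extra_bias is not None:
        u_test = u_test + extra_bias(S_test)
        u_cur = u_cur + extra_bias(S_flat)
    dU = u_test - u_cur
    accept = dU <= 0 or rng.random() < math.exp(-dU / (KB * cfg.T))
    if accept:
        return S_test, res.U_cond, True, res
    return S_flat, U_cond, False, res


def run_evccpmc(
    S0,
    cfg: EvccpConfig,
    system,
    extra_bias: Optional[Callable[[np.ndarray], float]] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Drive an EVCCP Markov chain for cfg.n_steps updates.

    ``S0`` may be an :class:`EVState` or a flat vector.  The trajectory
    starts with an initial evaluation at S0 (iteration 0) and archives
    every proposal's mini-batch.  Bit-reproducible for a given seed.
    """
    S = S0.flat if isinstance(S0, EVState) else np.asarray(S0, float).copy()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    res0 = system.evaluate(S, rng, step=0)
    traj = [StepRecord(0, S.copy(), res0.U_cond, res0.U_min, res0.X_min,
                       res0.records, True, res0.n_prefiltered)]
    U = res0.U_cond
    for it in range(1, cfg.n_steps + 1):
        S, U, acc, res = metropolis_update(
            S, U, system, cfg, rng, extra_bias=extra_bias, step=it
        )
        traj.append(StepRecord(it, S.copy(), U, res.U_min, res.X_min,
                               res.records, acc, res.n_prefiltered))
    return traj
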