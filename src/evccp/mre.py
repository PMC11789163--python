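"""Modified replica exchange (MRE) over EVCCP chains.

Only the extended-variable vector S (with its cached conditional energy)
traverses between temperature baths; the packing system itself never
swaps, which is what permits non-ordinal search variables to ride along
in S.  Variant moves:

* MRE0 - plain replica exchange.
* MRE1 - metadynamics-style history bias: Gaussian kernels deposited at
  accepted EV states penalize revisits.
* MRE2 - forced relaxation: at the start of each MC cycle every bath's S
  is reset to its best basin seen so far.
* MRE3 - relaxation restart: after each cycle the archived candidates are
  re-converged with tight tolerances and every bath restarts from the
  global unbiased minimum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .constants import KB
from .crystal import PackingState
from .mc import BatchResult, EvccpConfig, StepRecord, metropolis_update
from .search import local_minimize

__all__ = [
    "ReplicaLadder",
    "HistoryBias",
    "BasinArchive",
    "BathState",
    "MreResult",
    "attempt_exchange",
    "history_bias_energy",
    "forced_relaxation",
    "relaxation_restart",
    "run_mre",
    "tune_ladder",
    "geometric_ladder",
]

VARIANTS = ("MRE0", "MRE1", "MRE2", "MRE3")


@dataclass(frozen=True)
class ReplicaLadder:
    """Temperature ladder shared by all baths of one MRE run."""

    temperatures: tuple
    base_cfg: EvccpConfig
    exchange_interval: int = 5
    steps_per_cycle: int = 40
    cycles: int = 1

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.temperatures)
        object.__setattr__(self, "temperatures", t)
        if len(t) < 2:
            raise ValueError("need at least 2 baths")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def n_baths(self) -> int:
        return len(self.temperatures)

    def bath_configs(self) -> list:
        return [
            replace(self.base_cfg, T=t, seed=self.base_cfg.seed + i)
            for i, t in enumerate(self.temperatures)
        ]


@dataclass
class HistoryBias:
    """Gaussian-kernel history potential over EV space (MRE1).

    Each kernel contributes w * exp(-q/2) with q the squared distance of
    S from the center, scaled per coordinate class (sigma_com for COM
    components, sigma_euler for angle components, wrapped).  The kernel
    list is FIFO-capped.
    """

    w: float = 2.0
    sigma_com: float = 0.5
    sigma_euler: float = 10.0
    max_kernels: int = 2000
    angle_mask: Optional[np.ndarray] = None
    centers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.sigma_com <= 0 or self.sigma_euler <= 0:
            raise ValueError("widths must be > 0")

    def deposit(self, S: np.ndarray) -> None:
        self.centers.append(np.asarray(S, float).copy())
        if len(self.centers) > self.max_kernels:
            self.centers.pop(0)

    def __call__(self, S: np.ndarray) -> float:
        return history_bias_energy(S, self)


def history_bias_energy(S: np.ndarray, bias: HistoryBias) -> float:
    """Total history-bias energy at S (0 for an empty history)."""
    if not bias.centers:
        return 0.0
    S = np.asarray(S, float)
    mask = (
        bias.angle_mask
        if bias.angle_mask is not None
        else np.zeros(S.shape, dtype=bool)
    )
    sig = np.where(mask, bias.sigma_euler, bias.sigma_com)
    e = 0.0
    for c in bias.centers:
        d = S - c
        d[mask] = (d[mask] + 180.0) % 360.0 - 180.0
        q = float(np.sum((d / sig) ** 2))
        e += bias.w * math.exp(-0.5 * q)
    return e


@dataclass
class BasinEntry:
    S: np.ndarray
    X_min: Optional[PackingState]
    U_unb: float
    U_cond: float


@dataclass
class BasinArchive:
    """Best-seen basins per bath plus the global best (by U_cond for the
    per-bath entries, the restart logic re-ranks by U_unb)."""

    per_bath: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)

    def update(self, bath: int, S: np.ndarray, res: BatchResult) -> None:
        if not math.isfinite(res.U_cond):
            return
        ent = self.per_bath.get(bath)
        if ent is None or res.U_cond < ent.U_cond:
            u_unb = min(
                (r.U_unb for r in res.records), default=res.U_min
            )
            self.per_bath[bath] = BasinEntry(
                np.asarray(S, float).copy(), res.X_min, u_unb, res.U_cond
            )

    def add_candidates(self, records) -> None:
        self.candidates.extend(records)

    @property
    def empty(self) -> bool:
        return not self.per_bath


@dataclass
class BathState:
    index: int
    cfg: EvccpConfig
    system: object
    rng: np.random.Generator
    S: np.ndarray
    U_cond: float
    trajectory: list = field(default_factory=list)


@dataclass
class MreResult:
    trajectories: list
    records: list
    exchange_attempts: int = 0
    exchange_accepts: int = 0
    baths: list = field(default_factory=list)
    restarts: int = 0

    @property
    def exchange_rate(self) -> float:
        if self.exchange_attempts == 0:
            return math.nan
        return self.exchange_accepts / self.exchange_attempts


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------

def attempt_exchange(
    bath_i: BathState, bath_j: BathState, rng: np.random.Generator,
    strict: bool = False,
) -> bool:
    """Swap S (and cached U_cond) between two baths with the replica-
    exchange Metropolis probability min(1, exp[(b_i - b_j)(U_i - U_j)]).

    By default the cached conditional energies are swapped along with S;
    ``strict`` re-evaluates both swapped states through the generators
    (costlier, removes the caching approximation).
    """
    bi = 1.0 / (KB * bath_i.cfg.T)
    bj = 1.0 / (KB * bath_j.cfg.T)
    arg = (bi - bj) * (bath_i.U_cond - bath_j.U_cond)
    if arg >= 0 or rng.random() < math.exp(arg):
        bath_i.S, bath_j.S = bath_j.S, bath_i.S
        if strict:
            ri = bath_i.system.evaluate(bath_i.S, bath_i.rng)
            rj = bath_j.system.evaluate(bath_j.S, bath_j.rng)
            bath_i.U_cond, bath_j.U_cond = ri.U_cond, rj.U_cond
        else:
            bath_i.U_cond, bath_j.U_cond = bath_j.U_cond, bath_i.U_cond
        return True
    return False


def forced_relaxation(baths: list, archive: BasinArchive) -> int:
    """MRE2 move: reset each bath's S to its archived best basin.

    Returns the number of baths reset; an empty archive is a no-op.
    """
    if archive.empty:
        return 0
    n = 0
    for bath in baths:
        ent = archive.per_bath.get(bath.index)
        if ent is not None:
            bath.S = ent.S.copy()
            bath.U_cond = ent.U_cond
            n += 1
    return n


def relaxation_restart(
    baths: list,
    archive: BasinArchive,
    mol=None,
    sg=None,
    pot=None,
    top_n: int = 50,
    gtol: float = 1e-4,
    maxiter: int = 500,
):
    """MRE3 move: fully re-converge archived candidates and restart every
    bath from the packing CVs of the global *unbiased* minimum.

    Candidates (lowest-U_unb ``top_n`` of the archive) are re-minimized
    without bias at tightened tolerances; re-minimization can only lower
    U_unb.  Returns the winning record (None when the archive is empty).
    """
    cands = sorted(
        (r for r in archive.candidates if math.isfinite(r.U_unb)),
        key=lambda r: r.U_unb,
    )[:top_n]
    if not cands:
        return None
    best = None
    for rec in cands:
        if mol is not None:
            tight = local_minimize(
                rec.state, mol, sg, pot, gtol=gtol, maxiter=maxiter,
                provenance=rec.provenance,
            )
            if tight.U_unb > rec.U_unb + 1e-9:  # optimizer contract
                tight = rec
        else:  # surrogate / pre-converged archives
            tight = rec
        if best is None or tight.U_unb < best.U_unb:
            best = tight
    for bath in baths:
        bath.S = best.state.flat
        bath.U_cond = math.inf  # force re-evaluation semantics downstream
    return best


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mre(
    variant: str,
    ladder: ReplicaLadder,
    system_factory: Callable[[int, EvccpConfig], object],
    S0=None,
    exchange: bool = True,
    strict_exchange: bool = False,
    history: Optional[HistoryBias] = None,
    exchange_seed: Optional[int] = None,
    restart_kwargs: Optional[dict] = None,
) -> MreResult:
    """Round-robin MRE driver.

    ``system_factory(bath_index, cfg)`` builds the per-bath conditional-
    energy evaluator.  ``S0`` seeds every bath (one flat vector) or each
    bath individually (a list of vectors); when omitted, each system must
    carry an ``S0`` attribute.  Baths advance one Metropolis step at a
    time; an
    exchange sweep (nearest-neighbour pairs, alternating parity) runs
    every ``exchange_interval`` steps.  With ``exchange=False`` and no
    variant moves the chains are bit-identical to independent
    :func:`evccp.mc.run_evccpmc` runs at the same per-bath seeds.
    """
    variant = variant.upper()
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "MRE1" and history is None:
        history = HistoryBias()
    cfgs = ladder.bath_configs()
    baths = []
    archive = BasinArchive()
    records: list = []
    for i, cfg in enumerate(cfgs):
        system = system_factory(i, cfg)
        rng = np.random.default_rng(cfg.seed)
        if S0 is None:
            s0 = np.asarray(getattr(system, "S0"), float).copy()
        elif isinstance(S0, (list, tuple)):
            s0 = np.asarray(S0[i], float).copy()
        else:
            s0 = np.asarray(S0, float).copy()
        res = system.evaluate(s0, rng, step=0)
        bath = BathState(i, cfg, system, rng, s0, res.U_cond)
        bath.trajectory.append(
            StepRecord(0, s0.copy(), res.U_cond, res.U_min, res.X_min,
                       res.records, True, res.n_prefiltered)
        )
        archive.update(i, s0, res)
        archive.add_candidates(res.records)
        records.extend(res.records)
        baths.append(bath)
    ex_rng = np.random.default_rng(
        exchange_seed if exchange_seed is not None else ladder.base_cfg.seed + 7919
    )
    result = MreResult([], [], baths=baths)
    sweep_parity = 0
    it = 0
    for cycle in range(ladder.cycles):
        if variant == "MRE2" and cycle > 0:
            forced_relaxation(baths, archive)
        for _ in range(ladder.steps_per_cycle):
            it += 1
            for bath in baths:
                # a caller-supplied history applies to any variant (e.g.
                # forced relaxation + history bias combined)
                extra = history
                S, U, acc, res = metropolis_update(
                    bath.S, bath.U_cond, bath.system, bath.cfg, bath.rng,
                    extra_bias=extra, step=it,
                )
                bath.S, bath.U_cond = S, U
                bath.trajectory.append(
                    StepRecord(it, S.copy(), U, res.U_min, res.X_min,
                               res.records, acc, res.n_prefiltered)
                )
                archive.update(bath.index, S, res)
                archive.add_candidates(res.records)
                records.extend(res.records)
                if history is not None and acc:
                    history.deposit(S)
            if exchange and it % ladder.exchange_interval == 0:
                for i in range(sweep_parity, len(baths) - 1, 2):
                    result.exchange_attempts += 1
                    if attempt_exchange(
                        baths[i], baths[i + 1], ex_rng, strict=strict_exchange
                    ):
                        result.exchange_accepts += 1
                sweep_parity = 1 - sweep_parity
        if variant == "MRE3" and cycle < ladder.cycles - 1:
            best = relaxation_restart(baths, archive, **(restart_kwargs or {}))
            if best is not None:
                result.restarts += 1
                for bath in baths:
                    r0 = bath.system.evaluate(bath.S, bath.rng, step=it)
                    bath.U_cond = r0.U_cond
    result.trajectories = [b.trajectory for b in baths]
    result.records = records
    return result


# ---------------------------------------------------------------------------
# ladder helpers
# ---------------------------------------------------------------------------

def geometric_ladder(T_min: float, T_max: float, n_baths: int) -> tuple:
    """Geometrically (exponentially) spaced bath temperatures."""
    if n_baths < 2 or T_min <= 0 or T_max <= T_min:
        raise ValueError("need n_baths >= 2 and 0 < T_min < T_max")
    return tuple(T_min * (T_max / T_min) ** (i / (n_baths - 1))
                 for i in range(n_baths))


def tune_ladder(
    system_factory: Callable[[int, EvccpConfig], object],
    base_cfg: EvccpConfig,
    T_min: float,
    n_baths: int = 2,
    S0=None,
    target: float = 0.5,
    band: tuple = (0.3, 0.7),
    pilot_steps: int = 200,
    exchange_interval: int = 2,
    initial_ratio: float = 3.0,
    max_rounds: int = 12,
) -> tuple:
    """Auto-space a geometric ladder so the mean exchange acceptance sits
    near ``target`` (within ``band``), using short pilot MRE0 runs.

    The per-rung temperature ratio is adjusted multiplicatively: too-high
    acceptance widens the ladder, too-low narrows it.
    """
    ratio = initial_ratio
    temps = None
    for _ in range(max_rounds):
        T_max = T_min * ratio ** (n_baths - 1)
        temps = geometric_ladder(T_min, T_max, n_baths)
        ladder = ReplicaLadder(
            temps, replace(base_cfg, n_steps=pilot_steps),
            exchange_interval=exchange_interval,
            steps_per_cycle=pilot_steps, cycles=1,
        )
        res = run_mre("MRE0", ladder, system_factory, S0=S0)
        acc = res.exchange_rate
        if band[0] <= acc <= band[1]:
            return temps
        # harmonic-like energies: acceptance falls with the rung ratio
        ratio = max(1.02, ratio * (1.6 if acc > target else 0.625))
    return temps
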