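"""Search statistics: generation probabilities, RMSD_com, the top-20
ergodic metric, cross-search comparisons and landscape summaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crystal import RigidMolecule, SpaceGroup, density
from .search import DedupTolerances, PolymorphRecord, deduplicate, is_duplicate

__all__ = [
    "SearchSummary",
    "ComparisonResult",
    "estimate_probability",
    "rmsd_com",
    "top20_gap",
    "metric_trace",
    "compare_groups",
    "summarize",
    "landscape_table",
]


@dataclass
class SearchSummary:
    """Composite unbiased-energy metrics of one search."""

    N: int
    N_distinct: int
    E_min: float
    E_mean: float
    E_top20: float
    percentiles: dict = field(default_factory=dict)


@dataclass
class ComparisonResult:
    """Cross-space-group comparison of an enhanced search against the
    pseudo-random baseline.

    R_g is the fraction of groups where the enhanced metric is strictly
    lower; delta_E_g the mean metric difference (negative favours the
    enhanced search).
    """

    R_g: float
    delta_E_g: float
    pairs: list = field(default_factory=list)


def estimate_probability(
    records: Sequence[PolymorphRecord],
    target: PolymorphRecord,
    sg: SpaceGroup,
    denominator: int,
    tol: DedupTolerances = DedupTolerances(),
) -> float:
    """Generation probability N_hits / denominator of a specified
    polymorph.

    The denominator is the number of generation trials: N for a PR
    search, M (or the total archived count) for EVCCP streams.  Hits are
    structural duplicates of the target.  Order-invariant.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    hits = sum(1 for r in records if is_duplicate(r, target, sg, tol))
    return hits / denominator


def rmsd_com(X: np.ndarray, X_ref: np.ndarray) -> float:
    """Root-mean squared COM displacement over the Z' molecules (Å).

    Zero identifies the reference (e.g. global-minimum) packing itself.
    Euler columns, if present, are ignored.
    """
    Xa = np.atleast_2d(np.asarray(X, float))
    Xb = np.atleast_2d(np.asarray(X_ref, float))
    if Xa.shape != Xb.shape:
        raise ValueError(f"layout mismatch {Xa.shape} vs {Xb.shape}")
    d = Xa[:, :3] - Xb[:, :3]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def top20_gap(energies: Sequence[float], window: int = 20) -> float:
    """Mean of the ``window`` lowest energies minus the mean of all.

    The mean-shifted low-energy-window average <U>_T20 - <U>; never
    positive, and zero when the window covers the whole set.
    """
    e = np.asarray([x for x in energies if math.isfinite(x)], dtype=float)
    if e.size == 0:
        raise ValueError("need at least one finite energy")
    low = np.sort(e)[: min(window, e.size)]
    return float(low.mean() - e.mean())


def metric_trace(
    energies: Sequence[float], window: int = 20
) -> np.ndarray:
    """Stepwise top20_gap over growing prefixes (generation order).

    Entry i uses the first i+1 energies; the final entry equals the
    full-set metric.  Not monotone in general: the global mean shifts.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one energy")
    out = np.empty(e.size)
    for i in range(e.size):
        out[i] = top20_gap(e[: i + 1], window=window)
    return out


def compare_groups(
    metric_mre: Sequence[float], metric_pr: Sequence[float]
) -> ComparisonResult:
    """Summarize paired per-space-group metrics.

    Ties count as "not lower" (strict inequality), so identical lists
    give R_g = 0 and delta_E_g = 0.  Swapping the lists negates
    delta_E_g.
    """
    a = np.asarray(metric_mre, dtype=float)
    b = np.asarray(metric_pr, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need equal-length non-empty paired metric lists")
    r_g = float(np.mean(a < b))
    de = float(np.mean(a - b))
    return ComparisonResult(R_g=r_g, delta_E_g=de, pairs=list(zip(a, b)))


def _nearest_rank(sorted_e: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile on ascending energies (pct in percent)."""
    n = sorted_e.size
    k = max(1, int(math.ceil(pct / 100.0 * n)))
    return float(sorted_e[k - 1])


def summarize(
    records: Sequence[PolymorphRecord],
    sg: SpaceGroup,
    tol: DedupTolerances = DedupTolerances(),
    percent_levels: Sequence[float] = (0.05, 1.0, 5.0),
    dedup: bool = True,
) -> SearchSummary:
    """Search summary on deduplicated unbiased energies.

    E_min <= <E>_T20 <= mean(E); percentiles follow the nearest-rank
    rule.
    """
    if not records:
        raise ValueError("no records")
    recs = [r for r in records if math.isfinite(r.U_unb)]
    if not recs:
        raise ValueError("no finite-energy records")
    distinct = deduplicate(recs, sg, tol) if dedup else list(recs)
    e = np.sort(np.asarray([r.U_unb for r in distinct]))
    return SearchSummary(
        N=len(records),
        N_distinct=len(distinct),
        E_min=float(e[0]),
        E_mean=float(e.mean()),
        E_top20=float(e[: min(20, e.size)].mean()),
        percentiles={p: _nearest_rank(e, p) for p in percent_levels},
    )


def landscape_table(
    records: Sequence[PolymorphRecord],
    mol: RigidMolecule,
    sg: SpaceGroup,
    tol: DedupTolerances = DedupTolerances(),
):
    """(density g/cm^3, energy kJ/mol) rows of the distinct polymorphs,
    as a pandas DataFrame with provenance columns."""
    import pandas as pd

    recs = deduplicate([r for r in records if math.isfinite(r.U_unb)], sg, tol)
    rows = []
    for i, r in enumerate(recs):
        rows.append(
            {
                "distinct_id": i,
                "density_g_cm3": density(r.state, mol, sg),
                "energy_kj_mol": r.U_unb,
                "run_id": r.provenance.run_id,
                "step": r.provenance.step,
                "batch_index": r.provenance.batch_index,
                "replica": r.provenance.replica,
            }
        )
    return pd.DataFrame(rows)
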