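"""Replica exchange over EV chains and the MRE variant moves."""
import math

import numpy as np
import pytest

from evccp.constants import KB
from evccp.crystal import PackingState
from evccp.energy import CouplingSpec
from evccp.mc import (
    CrystalEvccpSystem,
    EvccpConfig,
    SurrogateEvccpSystem,
    run_evccpmc,
)
from evccp.mre import (
    BasinArchive,
    BasinEntry,
    BathState,
    HistoryBias,
    ReplicaLadder,
    attempt_exchange,
    forced_relaxation,
    geometric_ladder,
    history_bias_energy,
    relaxation_restart,
    run_mre,
)
from evccp.search import PolymorphRecord, Provenance
from evccp.surrogates import surrogate_surface


def _cfg(**kw):
    base = dict(coupling=CouplingSpec(0.0, 0.0), M=1, T=300.0, n_steps=10,
                seed=0, minimize_maxiter=60, minimize_gtol=1e-2)
    base.update(kw)
    return EvccpConfig(**base)


def _bath(T, U, index=0, seed=0):
    surf = surrogate_surface("quadratic", {"dim": 1})
    sys_ = SurrogateEvccpSystem(surf)
    return BathState(index, _cfg(T=T, seed=seed), sys_,
                     np.random.default_rng(seed), np.zeros(1), U)


class TestExchange:
    def test_equal_temperature_always_swaps(self, rng):
        for _ in range(20):
            bi, bj = _bath(300.0, 5.0), _bath(300.0, -3.0, index=1)
            assert attempt_exchange(bi, bj, rng)

    def test_equal_energy_always_swaps(self, rng):
        for _ in range(20):
            bi, bj = _bath(200.0, 1.5), _bath(800.0, 1.5, index=1)
            assert attempt_exchange(bi, bj, rng)

    def test_swap_moves_state_and_cache(self, rng):
        bi, bj = _bath(300.0, 5.0), _bath(300.0, -3.0, index=1)
        bi.S, bj.S = np.array([1.0]), np.array([2.0])
        attempt_exchange(bi, bj, rng)
        assert bi.S[0] == 2.0 and bj.S[0] == 1.0
        assert bi.U_cond == -3.0 and bj.U_cond == 5.0

    def test_swap_rate_matches_analytic(self):
        """Fixed-energy baths: empirical rate equals min(1, e^{arg})."""
        Ti, Tj, Ui, Uj = 300.0, 600.0, 2.0, -1.0
        arg = (1 / (KB * Ti) - 1 / (KB * Tj)) * (Ui - Uj)
        expected = min(1.0, math.exp(arg)) if arg < 0 else 1.0
        expected = min(1.0, math.exp(min(arg, 0.0))) if arg < 0 else 1.0
        expected = math.exp(arg) if arg < 0 else 1.0
        rng = np.random.default_rng(0)
        n, acc = 10_000, 0
        for _ in range(n):
            bi, bj = _bath(Ti, Ui), _bath(Tj, Uj, index=1)
            acc += attempt_exchange(bi, bj, rng)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(acc / n - expected) <= 3 * se + 1e-12


class TestHistoryBias:
    def test_empty_history_zero(self):
        assert history_bias_energy(np.zeros(6), HistoryBias()) == 0.0

    def test_kernel_center_value(self):
        b = HistoryBias(w=2.5)
        b.deposit(np.zeros(6))
        assert b(np.zeros(6)) == pytest.approx(2.5)

    def test_far_tail_negligible(self):
        b = HistoryBias(w=2.0, sigma_com=0.5)
        b.deposit(np.zeros(3))
        far = np.full(3, 10 * 0.5)
        assert b(far) < 2.0 * 1e-20

    def test_angle_wrap(self):
        mask = np.array([False, False, False, True, True, True])
        b = HistoryBias(w=1.0, angle_mask=mask)
        b.deposit(np.array([0.0, 0, 0, 5.0, 0, 0]))
        assert b(np.array([0.0, 0, 0, 365.0, 0, 0])) == pytest.approx(1.0)

    def test_fifo_cap(self):
        b = HistoryBias(max_kernels=3)
        for i in range(5):
            b.deposit(np.array([float(i)]))
        assert len(b.centers) == 3 and b.centers[0][0] == 2.0


class TestForcedRelaxation:
    def test_empty_archive_noop(self):
        baths = [_bath(300.0, 1.0), _bath(600.0, 2.0, index=1)]
        assert forced_relaxation(baths, BasinArchive()) == 0

    def test_reset_to_best(self):
        baths = [_bath(300.0, 5.0, index=0), _bath(600.0, 7.0, index=1)]
        arch = BasinArchive()
        arch.per_bath[0] = BasinEntry(np.array([1.5]), None, -2.0, -1.0)
        arch.per_bath[1] = BasinEntry(np.array([2.5]), None, -3.0, -2.0)
        n = forced_relaxation(baths, arch)
        assert n == 2
        assert baths[0].S[0] == 1.5 and baths[0].U_cond == -1.0
        # archive minimality: reset U_cond never above the running value
        assert baths[0].U_cond <= 5.0 and baths[1].U_cond <= 7.0


def _dummy_record(u_unb, penalty=0.0, H=(8.0, 8, 8, 90, 90, 90)):
    st = PackingState(np.array([[1.0, 1, 1, 0, 0, 0]]), np.array(H, float))
    return PolymorphRecord(
        state=st, U_unb=u_unb, penalty=penalty, U_biased=u_unb + penalty,
        converged=True, provenance=Provenance("t"),
    )


class TestRelaxationRestart:
    def test_restart_selects_unbiased_minimum(self):
        """Winner chosen by U_unb even when the U_biased ranking differs."""
        arch = BasinArchive()
        a = _dummy_record(-5.0, penalty=10.0)   # U_biased = 5
        b = _dummy_record(-4.0, penalty=0.0)    # U_biased = -4 (biased argmin)
        arch.add_candidates([a, b])
        baths = [_bath(300.0, 0.0), _bath(600.0, 0.0, index=1)]
        best = relaxation_restart(baths, arch)
        assert best is a
        assert all(np.array_equal(x.S, a.state.flat) for x in baths)

    def test_tight_reminimization_never_raises(self, bent3_p1, bent3_minima):
        arch = BasinArchive()
        arch.add_candidates(list(bent3_minima[:10]))
        baths = [_bath(300.0, 0.0)]
        best = relaxation_restart(
            baths, arch, mol=bent3_p1.mol, sg=bent3_p1.sg, pot=bent3_p1.pot,
            top_n=10,
        )
        assert best.U_unb <= min(r.U_unb for r in bent3_minima[:10]) + 1e-9


class TestRunMre:
    def _surf_factory(self):
        surf = surrogate_surface("double_well", {"a": 2.0, "b": 1.0, "dim": 1})
        return lambda i, cfg: SurrogateEvccpSystem(surf, step_sizes=0.6)

    def test_exchange_off_is_independent_chains(self):
        """Bit-exact reduction to independent EVCCP chains."""
        base = _cfg(seed=21, n_steps=30)
        ladder = ReplicaLadder((300.0, 700.0), base, steps_per_cycle=30)
        res = run_mre("MRE0", ladder, self._surf_factory(),
                      S0=np.array([1.0]), exchange=False)
        for i, cfg in enumerate(ladder.bath_configs()):
            surf_sys = self._surf_factory()(i, cfg)
            solo = run_evccpmc(np.array([1.0]), cfg, surf_sys)
            mre_traj = res.trajectories[i]
            assert [s.U_cond for s in solo] == [s.U_cond for s in mre_traj]
            assert all(
                np.array_equal(a.S, b.S) for a, b in zip(solo, mre_traj)
            )

    def test_record_accounting(self, bent3_p1, bent3_ref_ev):
        """baths x (steps+1) x M polymorphs archived (no prefilter
        losses)."""
        base = _cfg(M=2, seed=3, coupling=CouplingSpec(100.0, 10.0),
                    E_threshold=math.inf)

        def factory(i, cfg):
            return CrystalEvccpSystem(
                bent3_p1.mol, bent3_p1.sg, 1, bent3_p1.bounds, bent3_p1.pot,
                cfg, replica=i,
            )

        ladder = ReplicaLadder((300.0, 600.0), base, steps_per_cycle=3,
                               cycles=1)
        res = run_mre("MRE0", ladder, factory, S0=bent3_ref_ev.flat)
        assert len(res.records) == 2 * (3 + 1) * 2

    def test_mre1_repels_revisits(self):
        """History bias lowers the revisit count of the starting basin
        (paired over seeds)."""
        surf = surrogate_surface("double_well", {"a": 2.0, "b": 1.0, "dim": 1})
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            counts = {}
            for w in (0.0, 3.0):
                base = _cfg(seed=seed * 31, n_steps=60, T=150.0)
                ladder = ReplicaLadder((150.0, 450.0), base,
                                       steps_per_cycle=60)
                hist = HistoryBias(w=w, sigma_com=0.4)
                res = run_mre(
                    "MRE1", ladder,
                    lambda i, cfg: SurrogateEvccpSystem(surf, step_sizes=0.5),
                    S0=np.array([1.0]), history=hist,
                )
                s0 = 1.0
                xs = np.array([s.S[0] for s in res.trajectories[0]])
                counts[w] = int(np.sum(np.abs(xs - s0) < 0.4))
            wins += counts[3.0] <= counts[0.0]
        assert wins >= 7  # strictly lower on average across seeds

    def test_variant_validation(self):
        base = _cfg()
        ladder = ReplicaLadder((300.0, 600.0), base)
        with pytest.raises(ValueError):
            run_mre("MRE9", ladder, self._surf_factory(), S0=np.zeros(1))


class TestLadders:
    def test_geometric_spacing(self):
        t = geometric_ladder(263.0, 1142.0, 4)
        ratios = np.diff(np.log(t))
        assert np.allclose(ratios, ratios[0])
        assert t[0] == 263.0 and t[-1] == pytest.approx(1142.0)

    def test_invalid_ladder(self):
        with pytest.raises(ValueError):
            geometric_ladder(500.0, 300.0, 3)
        with pytest.raises(ValueError):
            ReplicaLadder((300.0,), _cfg())
        with pytest.raises(ValueError):
            ReplicaLadder((300.0, 300.0), _cfg())
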