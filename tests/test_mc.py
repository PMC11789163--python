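"""EVCCP Markov chain: mini-batches, Metropolis propagation, reductions."""
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
    metropolis_update,
    mini_batch,
    run_evccpmc,
)
from evccp.search import local_minimize, sample_random_start
from evccp.surrogates import surrogate_surface


def _cfg(**kw):
    base = dict(
        coupling=CouplingSpec(0.0, 0.0), M=1, T=300.0, n_steps=5, seed=0,
        minimize_maxiter=60, minimize_gtol=1e-2,
    )
    base.update(kw)
    return EvccpConfig(**base)


class TestMiniBatch:
    def test_reduction_single_unbiased(self, bent3_p1, bent3_ref_ev):
        """M = 1, k = 0 reproduces a single unbiased local_minimize from
        X0 = S with the same random cell draw."""
        cfg = _cfg()
        system = CrystalEvccpSystem(
            bent3_p1.mol, bent3_p1.sg, 1, bent3_p1.bounds, bent3_p1.pot, cfg
        )
        res = system.evaluate(bent3_ref_ev.flat, np.random.default_rng(42))
        trial = sample_random_start(
            bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol,
            np.random.default_rng(42),
        )
        manual = local_minimize(
            PackingState(bent3_ref_ev.S.copy(), trial.H),
            bent3_p1.mol, bent3_p1.sg, bent3_p1.pot,
            gtol=cfg.minimize_gtol, maxiter=cfg.minimize_maxiter,
        )
        assert res.records[0].U_unb == pytest.approx(manual.U_unb, abs=1e-9)
        assert res.U_min == pytest.approx(manual.U_unb, abs=1e-9)

    def test_umin_is_batch_minimum(self, bent3_p1, bent3_ref_ev):
        cfg = _cfg(M=4, coupling=CouplingSpec(100.0, 10.0))
        recs, u_min, x_min = mini_batch(
            bent3_ref_ev, cfg, bent3_p1.mol, bent3_p1.sg, bent3_p1.bounds,
            np.random.default_rng(1), pot=bent3_p1.pot,
        )
        assert len(recs) == 4
        assert all(u_min <= r.U_biased for r in recs)
        assert x_min is not None

    def test_strong_coupling_stays_near_reference(
        self, bent3_p1, bent3_ref, bent3_ref_ev
    ):
        """With S at a minimum and k = 1000, the batch argmin stays close
        to S (the conditional-sampling signature)."""
        from evccp.analysis import rmsd_com

        cfg = _cfg(M=3, coupling=CouplingSpec(1000.0, 1000.0))
        close = 0
        n = 20
        for i in range(n):
            _, _, x_min = mini_batch(
                bent3_ref_ev, cfg, bent3_p1.mol, bent3_p1.sg, bent3_p1.bounds,
                np.random.default_rng(100 + i), pot=bent3_p1.pot,
            )
            if rmsd_com(x_min.X, bent3_ref_ev.S) < 0.2:
                close += 1
        assert close >= int(0.8 * n)


class TestMetropolis:
    def test_downhill_always_accepted(self):
        surf = surrogate_surface("quadratic", {"dim": 1, "k_eff": 4.0})
        system = SurrogateEvccpSystem(surf, step_sizes=0.3)
        cfg = _cfg(T=1e-9)
        rng = np.random.default_rng(0)
        S = np.array([3.0])
        U = float(surf(S))
        for _ in range(100):
            S2, U2, acc, _ = metropolis_update(S, U, system, cfg, rng)
            if U2 < U:
                assert acc
            assert U2 <= U + 1e-12  # at T -> 0 only downhill moves pass
            S, U = S2, U2

    def test_infinite_temperature_accepts_everything(self):
        surf = surrogate_surface("quadratic", {"dim": 1, "k_eff": 4.0})
        system = SurrogateEvccpSystem(surf, step_sizes=0.5)
        cfg = _cfg(T=1e9)
        rng = np.random.default_rng(1)
        S, U = np.array([0.0]), 0.0
        n_acc = 0
        for _ in range(200):
            S, U, acc, _ = metropolis_update(S, U, system, cfg, rng)
            n_acc += acc
        assert n_acc == 200

    def test_acceptance_rate_matches_integrated_value(self):
        """On the quadratic surrogate the empirical acceptance matches
        the numerically integrated Metropolis acceptance within 3 SE."""
        k, T, step = 2.0, 300.0, 1.0
        beta = 1.0 / (KB * T)
        surf = surrogate_surface("quadratic", {"dim": 1, "k_eff": k})
        system = SurrogateEvccpSystem(surf, step_sizes=step)
        cfg = _cfg(T=T, n_steps=20_000)
        traj = run_evccpmc(np.zeros(1), cfg, system)
        emp = np.mean([s.accepted for s in traj[1:]])
        # E_x E_d min(1, exp(-beta dU)), x ~ Boltzmann, d ~ U(-step, step)
        sd = math.sqrt(1.0 / (beta * k))
        xs = np.linspace(-6 * sd, 6 * sd, 801)
        px = np.exp(-beta * 0.5 * k * xs**2)
        px /= px.sum()
        ds = np.linspace(-step, step, 401)
        du = 0.5 * k * ((xs[:, None] + ds[None, :]) ** 2 - xs[:, None] ** 2)
        acc = np.minimum(1.0, np.exp(-beta * du)).mean(axis=1)
        expected = float((px * acc).sum())
        se = math.sqrt(expected * (1 - expected) / 20_000) * 3
        # MC correlation inflates the error; allow 3 SE on 5x fewer
        assert abs(emp - expected) < max(5 * se, 0.02)


class TestRunEvccpmc:
    def test_zero_steps(self, bent3_p1, bent3_ref_ev):
        cfg = _cfg(n_steps=0)
        system = CrystalEvccpSystem(
            bent3_p1.mol, bent3_p1.sg, 1, bent3_p1.bounds, bent3_p1.pot, cfg
        )
        traj = run_evccpmc(bent3_ref_ev, cfg, system)
        assert len(traj) == 1 and traj[0].iter == 0

    def test_bit_identical_reruns(self, bent3_p1, bent3_ref_ev):
        cfg = _cfg(M=2, n_steps=4, coupling=CouplingSpec(500.0, 100.0), seed=5)

        def once():
            system = CrystalEvccpSystem(
                bent3_p1.mol, bent3_p1.sg, 1, bent3_p1.bounds, bent3_p1.pot, cfg
            )
            return run_evccpmc(bent3_ref_ev, cfg, system)

        t1, t2 = once(), once()
        assert [s.accepted for s in t1] == [s.accepted for s in t2]
        assert all(
            np.array_equal(a.S, b.S) and a.U_cond == b.U_cond
            for a, b in zip(t1, t2)
        )

    def test_archives_rejected_batches(self, bent3_p1, bent3_ref_ev):
        cfg = _cfg(M=2, n_steps=6, coupling=CouplingSpec(1000.0, 1000.0),
                   T=50.0, seed=2)
        system = CrystalEvccpSystem(
            bent3_p1.mol, bent3_p1.sg, 1, bent3_p1.bounds, bent3_p1.pot, cfg
        )
        traj = run_evccpmc(bent3_ref_ev, cfg, system)
        # every step archives its proposal's batch, accepted or not
        assert all(len(s.batch) == 2 for s in traj)
        assert sum(len(s.batch) for s in traj) == 14

    def test_stationary_variance_quick(self):
        """Short sanity check of the Boltzmann marginal (the full test is
        an acceptance criterion)."""
        k, T = 5.0, 300.0
        surf = surrogate_surface("quadratic", {"dim": 1, "k_eff": k})
        system = SurrogateEvccpSystem(surf, step_sizes=1.2)
        cfg = _cfg(T=T, n_steps=20_000, seed=4)
        traj = run_evccpmc(np.zeros(1), cfg, system)
        xs = np.array([s.S[0] for s in traj[2_000:]])
        assert np.var(xs) == pytest.approx(KB * T / k, rel=0.15)
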