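"""Random starts, local minimization, pre-rejection and dedup."""
import math

import numpy as np
import pytest
from scipy.stats import kstest

from evccp.crystal import cell_matrix
from evccp.energy import CouplingSpec, lattice_energy
from evccp.search import (
    BoundsInfeasibleError,
    DedupTolerances,
    SamplerBounds,
    deduplicate,
    is_duplicate,
    local_minimize,
    pr_search,
    prefilter,
    sample_random_start,
)

from conftest import dimer_state


class TestSampleRandomStart:
    def test_density_window_enforced(self, bent3_p1, rng):
        for _ in range(50):
            st = sample_random_start(
                bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, rng
            )
            from evccp.crystal import density

            rho = density(st, bent3_p1.mol, bent3_p1.sg)
            lo, hi = bent3_p1.bounds.density_range
            assert lo <= rho <= hi

    def test_seeded_determinism(self, bent3_p1):
        a = sample_random_start(
            bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, np.random.default_rng(7)
        )
        b = sample_random_start(
            bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, np.random.default_rng(7)
        )
        assert np.array_equal(a.X, b.X) and np.array_equal(a.H, b.H)

    def test_cell_length_marginal_uniform(self, atom_p1, rng):
        """Without density rejection the marginal of a is U(a_min, a_max)."""
        bounds = SamplerBounds(
            length_range=atom_p1.bounds.length_range, density_range=(0.0, math.inf)
        )
        lo, hi = bounds.length_range
        draws = np.array(
            [
                sample_random_start(bounds, atom_p1.sg, 1, atom_p1.mol, rng).H[0]
                for _ in range(10_000)
            ]
        )
        p = kstest(draws, "uniform", args=(lo, hi - lo)).pvalue
        assert p > 0.01

    def test_infeasible_window(self, atom_p1, rng):
        bounds = SamplerBounds(
            length_range=(3.2, 6.5), density_range=(50.0, 60.0)
        )
        with pytest.raises(BoundsInfeasibleError):
            sample_random_start(bounds, atom_p1.sg, 1, atom_p1.mol, rng)


class TestLocalMinimize:
    def test_fixed_point(self, bent3_p1, bent3_ref):
        rec = local_minimize(
            bent3_ref.state, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot,
            gtol=1e-4, maxiter=400,
        )
        assert rec.U_unb == pytest.approx(bent3_ref.U_unb, abs=1e-5)

    def test_zero_coupling_equals_unbiased(self, bent3_p1, bent3_ref_ev, rng):
        start = sample_random_start(
            bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, rng
        )
        a = local_minimize(start, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot,
                           maxiter=100)
        b = local_minimize(
            start, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot,
            S=bent3_ref_ev, coupling=CouplingSpec(0.0, 0.0), maxiter=100,
        )
        # identical minimization path; energies agree to float noise
        # (the unbiased path additionally wraps COMs before evaluating)
        assert a.U_unb == pytest.approx(b.U_unb, abs=1e-9)
        assert b.penalty == 0.0

    def test_descent(self, bent3_p1, rng):
        """Minimization never raises the (finite) starting energy."""
        for _ in range(5):
            start = sample_random_start(
                bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, rng
            )
            e0 = lattice_energy(start, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot)
            rec = local_minimize(
                start, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot, maxiter=150
            )
            if math.isfinite(e0):
                assert rec.U_unb <= e0 + 1e-9

    def test_biased_record_decomposition(self, bent3_p1, bent3_ref_ev, rng):
        start = sample_random_start(
            bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, rng
        )
        rec = local_minimize(
            start, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot,
            S=bent3_ref_ev, coupling=CouplingSpec(100.0, 10.0), maxiter=100,
        )
        assert rec.penalty >= 0
        assert rec.U_biased == pytest.approx(rec.U_unb + rec.penalty)


class TestPrefilter:
    def test_infinite_threshold(self, bent3_p1, rng):
        st = sample_random_start(bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, rng)
        assert prefilter(st, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot, math.inf)

    def test_overlap_rejected(self, atom_p1):
        st = dimer_state(0.05)
        assert not prefilter(st, atom_p1.mol, atom_p1.sg, atom_p1.pot, 1e6)

    def test_batch_count_matches_direct_loop(self, bent3_p1, rng):
        states = [
            sample_random_start(bent3_p1.bounds, bent3_p1.sg, 1, bent3_p1.mol, rng)
            for _ in range(50)
        ]
        thr = 50.0
        n_fast = sum(
            prefilter(s, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot, thr)
            for s in states
        )
        n_loop = 0
        for s in states:
            if lattice_energy(s, bent3_p1.mol, bent3_p1.sg, bent3_p1.pot) <= thr:
                n_loop += 1
        assert n_fast == n_loop


class TestDedup:
    def test_self_duplicate(self, bent3_p1, bent3_ref):
        assert is_duplicate(bent3_ref, bent3_ref, bent3_p1.sg)

    def test_lattice_shift_duplicate(self, bent3_p1, bent3_ref):
        import copy

        shifted = copy.deepcopy(bent3_ref)
        A = cell_matrix(shifted.state.H)
        shifted.state.X[:, :3] += A[1]
        assert is_duplicate(bent3_ref, shifted, bent3_p1.sg)

    def test_energy_gap_not_duplicate(self, bent3_p1, bent3_ref):
        import copy

        other = copy.deepcopy(bent3_ref)
        other.U_unb += 10 * DedupTolerances().tol_E
        other.U_biased = other.U_unb + other.penalty
        assert not is_duplicate(bent3_ref, other, bent3_p1.sg)

    def test_dedup_idempotent(self, bent3_p1, bent3_minima):
        once = deduplicate(list(bent3_minima), bent3_p1.sg)
        twice = deduplicate(once, bent3_p1.sg)
        assert len(once) == len(twice)
        assert all(a is b for a, b in zip(once, twice))

    def test_dedup_keeps_lowest(self, bent3_p1, bent3_minima):
        distinct = deduplicate(list(bent3_minima), bent3_p1.sg)
        assert len(distinct) <= len(bent3_minima)
        assert distinct[0].U_unb == min(r.U_unb for r in bent3_minima)


class TestPrSearch:
    def test_basic_run(self, bent3_p1):
        recs = pr_search(
            5, bent3_p1.bounds, bent3_p1.mol, bent3_p1.sg, 1, bent3_p1.pot,
            rng=3, maxiter=200,
        )
        assert len(recs) == 5
        assert all(np.isfinite(r.U_unb) for r in recs)

    def test_seeded_reproducibility(self, bent3_p1):
        a = pr_search(4, bent3_p1.bounds, bent3_p1.mol, bent3_p1.sg, 1,
                      bent3_p1.pot, rng=9, maxiter=80)
        b = pr_search(4, bent3_p1.bounds, bent3_p1.mol, bent3_p1.sg, 1,
                      bent3_p1.pot, rng=9, maxiter=80)
        assert [r.U_unb for r in a] == [r.U_unb for r in b]

    def test_invalid_n(self, bent3_p1):
        with pytest.raises(ValueError):
            pr_search(0, bent3_p1.bounds, bent3_p1.mol, bent3_p1.sg, 1,
                      bent3_p1.pot, rng=1)
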