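"""Fragment spaces, pair screening and the DEC assembly."""

import numpy as np
import pytest

from deccp.cc import ccsd_solve, mp2, pt_energy, triples_intermediates
from deccp.dec import (DECResult, FragmentSpaces, assemble, dec_driver,
                       error_estimate, estimate_pairs, fragment_energy,
                       optimize_fragment, pair_energy, screen_pairs,
                       solve_fragment_amplitudes, _energy_block)
from deccp.integrals import make_localized_random
from deccp.scf import mo_transform, run_rhf

from conftest import localized_setup


def _full_space_partition(s, scf, method, conv_tol=1e-11):
    lo, g_loc, F_loc = localized_setup(s, scf)
    occ = np.arange(scf.n_occ)
    virt = np.arange(scf.n_occ, s.n_orb)
    t1, t2 = solve_fragment_amplitudes(occ, virt, g_loc, F_loc, method,
                                       conv_tol=conv_tol)
    frags = {P: FragmentSpaces(P, lo.site_orbitals(P, "occ"), occ, virt, 0.0)
             for P in range(s.n_sites)}
    total = sum(fragment_energy(frags[P], t1, t2, g_loc)
                for P in range(s.n_sites))
    pairs = {}
    for P in range(s.n_sites):
        for Q in range(P + 1, s.n_sites):
            if len(frags[P].eos_occ) and len(frags[Q].eos_occ):
                pairs[(P, Q)] = pair_energy(frags[P], frags[Q], t1, t2,
                                            g_loc, occ, virt)
    return total + sum(pairs.values()), pairs, lo, g_loc, F_loc


class TestPartitionIdentity:
    def test_mp2_fragments_sum_to_canonical(self, dec_fixture_6):
        s, scf, _, g_mo = dec_fixture_6
        can = mp2(g_mo, scf.eps, scf.n_occ).e_corr
        total, *_ = _full_space_partition(s, scf, "mp2")
        assert total == pytest.approx(can, abs=1e-10)

    def test_ccsd_fragments_sum_to_canonical(self, dec_fixture_6):
        s, scf, h_mo, g_mo = dec_fixture_6
        can = ccsd_solve(g_mo, h_mo, scf.eps, scf.n_occ, conv_tol=1e-11).e_corr
        total, *_ = _full_space_partition(s, scf, "ccsd")
        assert total == pytest.approx(can, abs=1e-10)

    def test_triples_driver_matches_single_fragment(self, medium_random):
        """DEC-CCSD(T) with untruncated spaces must equal canonical CCSD
        plus the full-space perturbative-triples correction."""
        s, scf, h_mo, g_mo = medium_random
        amps = ccsd_solve(g_mo, h_mo, scf.eps, scf.n_occ, conv_tol=1e-11)
        tri = triples_intermediates(amps.t2, g_mo, scf.eps[:scf.n_occ],
                                    scf.eps[scf.n_occ:])
        can = amps.e_corr + pt_energy(amps.t1, amps.t2, tri)
        res = dec_driver(s, method="ccsd_t", fot=1e-9, r_screen=100.0)
        assert res.e_corr == pytest.approx(can, abs=1e-8)

    def test_single_site_owns_everything(self, small_random):
        s, scf, _, g_mo = small_random
        can = mp2(g_mo, scf.eps, scf.n_occ).e_corr
        occ = np.arange(scf.n_occ)
        virt = np.arange(scf.n_occ, s.n_orb)
        frag = FragmentSpaces(0, occ, occ, virt, 0.0)
        lo, g_loc, F_loc = localized_setup(s, scf)
        t1, t2 = solve_fragment_amplitudes(occ, virt, g_loc, F_loc, "mp2")
        assert fragment_energy(frag, t1, t2, g_loc) == pytest.approx(can, abs=1e-10)


class TestFragmentOps:
    def test_empty_virtual_space_gives_zero(self):
        frag = FragmentSpaces(0, [0], [0], [], 0.0)
        assert fragment_energy(frag, np.zeros((1, 0)),
                               np.zeros((1, 1, 0, 0)), None) == 0.0

    def test_pair_requires_distinct_fragments(self):
        f = FragmentSpaces(0, [0], [0], [2], 0.0)
        with pytest.raises(ValueError):
            pair_energy(f, f, None, None, None, [0], [2])

    def test_mp2_noniterative_matches_iterative_local_solver(self, medium_random):
        """Two-path oracle: pseudo-canonical non-iterative MP2 amplitudes
        must satisfy the local-basis residual equations solved by plain
        Jacobi iteration."""
        s, scf, _, _ = medium_random
        lo, g_loc, F_loc = localized_setup(s, scf)
        occ = lo.site_orbitals(0, "occ")
        occ = np.array(sorted(set(occ) | set(lo.site_orbitals(2, "occ"))))
        virt = np.concatenate([lo.site_orbitals(0, "virt"),
                               lo.site_orbitals(2, "virt")])
        t1, t2 = solve_fragment_amplitudes(occ, virt, g_loc, F_loc, "mp2")
        Foo = F_loc[np.ix_(occ, occ)]
        Fvv = F_loc[np.ix_(virt, virt)]
        g_ijab = g_loc[np.ix_(virt, occ, virt, occ)].transpose(1, 3, 0, 2)
        # Jacobi iteration on the local-basis MP2 residual
        #   R = (ai|bj) + F_vv t + t F_vv - F_oo t - t F_oo = 0
        t = np.zeros_like(t2)
        do, dv = np.diag(Foo), np.diag(Fvv)
        denom = (do[:, None, None, None] + do[None, :, None, None]
                 - dv[None, None, :, None] - dv[None, None, None, :])
        for _ in range(2000):
            R = (g_ijab
                 + np.einsum("ac,ijcb->ijab", Fvv, t, optimize=True)
                 + np.einsum("bc,ijac->ijab", Fvv, t, optimize=True)
                 - np.einsum("ik,kjab->ijab", Foo, t, optimize=True)
                 - np.einsum("jk,ikab->ijab", Foo, t, optimize=True))
            t_new = t - R / (-denom)
            if np.abs(t_new - t).max() < 1e-13:
                t = t_new
                break
            t = t_new
        # residual check and elementwise agreement with the direct solver
        assert np.abs(R).max() < 1e-10
        assert np.allclose(t, t2, atol=1e-8)

    def test_huge_fot_terminates_at_first_comparison(self, dec_fixture_6):
        s, scf, _, _ = dec_fixture_6
        lo, g_loc, F_loc = localized_setup(s, scf)
        frag = optimize_fragment(0, 1e3, lo, g_loc, F_loc, s.sites)
        assert len(frag.expansion_history) <= 2
        assert len(frag.virt) <= s.n_orb - scf.n_occ

    def test_optimized_fragment_energy_within_fot_of_full_space(self, dec_fixture_6):
        s, scf, _, _ = dec_fixture_6
        lo, g_loc, F_loc = localized_setup(s, scf)
        occ = np.arange(scf.n_occ)
        virt = np.arange(scf.n_occ, s.n_orb)
        t1f, t2f = solve_fragment_amplitudes(occ, virt, g_loc, F_loc, "mp2")
        fot = 1e-4
        for P in range(s.n_sites):
            frag = optimize_fragment(P, fot, lo, g_loc, F_loc, s.sites)
            if len(frag.eos_occ) == 0:
                continue
            full = FragmentSpaces(P, frag.eos_occ, occ, virt, fot)
            e_full = fragment_energy(full, t1f, t2f, g_loc)
            t1, t2 = solve_fragment_amplitudes(frag.aos_occ, frag.virt,
                                               g_loc, F_loc, "mp2")
            e_opt = fragment_energy(frag, t1, t2, g_loc)
            assert abs(e_opt - e_full) <= 3 * fot


class TestEstimatesAndScreening:
    def test_block_diagonal_interaction_gives_zero_estimates(self):
        s = make_localized_random(3, 2, 4, 1e3, seed=2)   # locality limit
        scf = run_rhf(s)
        lo, g_loc, F_loc = localized_setup(s, scf)
        est = estimate_pairs(lo, g_loc, F_loc, s.sites)
        assert all(abs(v) < 1e-8 for v in est.values())

    def test_estimates_recover_most_of_exact_pairs(self, reference_fixture_8):
        s, scf, _, _ = reference_fixture_8
        total, exact, lo, g_loc, F_loc = _full_space_partition(s, scf, "mp2")
        est = estimate_pairs(lo, g_loc, F_loc, s.sites)
        se = sum(abs(v) for v in est.values())
        sx = sum(abs(v) for v in exact.values())
        assert se >= 0.80 * sx

    def test_estimate_magnitude_decays_with_distance(self, reference_fixture_8):
        """Median |estimate| at larger site separation should not grow;
        recorded on the reference fixture."""
        s, scf, _, _ = reference_fixture_8
        lo, g_loc, F_loc = localized_setup(s, scf)
        est = estimate_pairs(lo, g_loc, F_loc, s.sites)
        by_d = {}
        for (P, Q), v in est.items():
            if v != 0.0:
                by_d.setdefault(abs(P - Q), []).append(abs(v))
        ds = sorted(by_d)
        medians = [np.median(by_d[d]) for d in ds]
        assert all(m2 <= m1 for m1, m2 in zip(medians, medians[1:]))

    def test_fot_zero_screens_nothing_inside_cutoff(self):
        sites = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        est = {(0, 1): -1e-3, (0, 2): -1e-5, (1, 2): -1e-4, (2, 3): -2e-3,
               (0, 3): -1e-6, (1, 3): -1e-5}
        screened, retained = screen_pairs(est, 0.0, sites, r_screen=30.0)
        assert screened == set()
        assert retained == set(est)

    def test_boundary_pair_at_twice_fot_is_screened(self):
        sites = np.column_stack([np.arange(2.0), np.zeros(2), np.zeros(2)])
        fot = 1e-4
        est = {(0, 1): 2 * fot}
        screened, retained = screen_pairs(est, fot, sites, r_screen=30.0)
        assert (0, 1) in screened and retained == set()

    def test_per_site_screened_mass_bounded_by_fot(self, reference_fixture_8):
        s, scf, _, _ = reference_fixture_8
        lo, g_loc, F_loc = localized_setup(s, scf)
        est = estimate_pairs(lo, g_loc, F_loc, s.sites)
        fot = 1e-5
        screened, _ = screen_pairs(est, fot, s.sites, r_screen=30.0)
        for P in range(s.n_sites):
            mass = 0.5 * sum(abs(est[pq]) for pq in screened
                             if pq in est and P in pq)
            assert mass <= s.n_sites * fot + 1e-15

    def test_beyond_cutoff_pairs_discarded(self):
        sites = np.column_stack([np.array([0.0, 1.0, 50.0]),
                                 np.zeros(3), np.zeros(3)])
        est = {(0, 1): -1e-3}
        screened, retained = screen_pairs(est, 0.0, sites, r_screen=30.0)
        assert (0, 2) in screened and (1, 2) in screened
        assert retained == {(0, 1)}


class TestAssembly:
    def test_effective_energies_sum_to_total(self):
        frag = {0: -0.5, 1: -0.3}
        pairs = {(0, 1): -0.02}
        res = assemble(frag, pairs, set(), 1e-4, "mp2")
        assert res.e_corr == pytest.approx(-0.82, abs=1e-12)
        assert sum(res.effective_energies.values()) == pytest.approx(
            res.e_corr, abs=1e-12)

    def test_symmetric_fragments_get_equal_effective_energies(self):
        res = assemble({0: -0.4, 1: -0.4}, {(0, 1): -0.1}, set(), 1e-4, "mp2")
        assert res.effective_energies[0] == res.effective_energies[1]

    def test_no_pairs_single_fragment(self):
        res = assemble({0: -0.7}, {}, set(), 1e-4, "mp2")
        assert res.e_corr == -0.7

    def test_error_estimate_arithmetic(self):
        assert error_estimate(5, 1e-4) == pytest.approx(1e-3)
        assert error_estimate(3, 0.0) == 0.0
        with pytest.raises(ValueError):
            error_estimate(0, 1e-4)


class TestDriver:
    def test_tight_fot_reproduces_canonical_mp2(self, dec_fixture_6):
        s, scf, _, g_mo = dec_fixture_6
        can = mp2(g_mo, scf.eps, scf.n_occ).e_corr
        res = dec_driver(s, method="mp2", fot=1e-10, r_screen=1e6)
        assert res.e_corr == pytest.approx(can, abs=1e-8)

    def test_serial_and_process_schedulers_agree(self, medium_random):
        s, scf, _, _ = medium_random
        a = dec_driver(s, method="mp2", fot=1e-5, scheduler="serial")
        b = dec_driver(s, method="mp2", fot=1e-5, scheduler="procs", n_procs=2)
        assert a.e_corr == b.e_corr
        assert a.fragment_energies == b.fragment_energies
        assert a.pair_energies == b.pair_energies

    def test_recovery_monotone_in_fot(self, reference_fixture_8):
        s, scf, _, g_mo = reference_fixture_8
        can = mp2(g_mo, scf.eps, scf.n_occ).e_corr
        rec = []
        for fot in (1e-3, 1e-4, 1e-5, 1e-6):
            r = dec_driver(s, method="mp2", fot=fot)
            rec.append(r.e_corr / can)
        assert all(r2 >= r1 - 1e-9 for r1, r2 in zip(rec, rec[1:]))

    def test_unknown_method_rejected(self, small_random):
        s, *_ = small_random
        with pytest.raises(ValueError):
            dec_driver(s, method="mp3")
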