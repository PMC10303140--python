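"""Divide-Expand-Consolidate fragment correlation energies.

The correlation energy of a closed-shell system is partitioned over atomic
sites P into fragment energies E_P and pair interaction energies dE_PQ,

    E_corr = sum_P E_P + sum_{Q<P} dE_PQ,

evaluated with localized occupied and virtual orbitals.  E_P sums the
energy expression over occupied orbitals assigned to P (the energy orbital
space, EOS) and a truncated virtual space [P-bar]; amplitudes are solved in
a larger amplitude orbital space (AOS) whose extent is optimized until the
fragment energy is converged to the fragment optimization threshold (FOT).
Pair energies beyond a real-space cutoff, or estimated (minimal-space MP2)
to be collectively negligible per site, are screened away.  With full
spaces and no screening the partitioning is exact: the fragment sums
reproduce the canonical correlation energy of the same method.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass, field

import numpy as np

from .cc import ccsd_solve, triples_intermediates
from .integrals import IntegralSet
from .localization import LocalOrbitalSet, build_local_orbitals
from .scf import mo_transform, pseudo_canonicalize, run_rhf

__all__ = ["FragmentSpaces", "DECResult", "solve_fragment_amplitudes",
           "fragment_energy", "pair_energy", "optimize_fragment",
           "estimate_pairs", "screen_pairs", "assemble", "error_estimate",
           "dec_driver"]


@dataclass
class FragmentSpaces:
    site: int
    eos_occ: np.ndarray            # occupied orbitals assigned to the site
    aos_occ: np.ndarray            # occupied amplitude space (superset)
    virt: np.ndarray               # virtual space [P-bar]
    fot: float
    own_virt: np.ndarray = None    # virtuals assigned to the site itself
    expansion_history: list = field(default_factory=list)
    exhausted: bool = False        # expansion reached the full system

    def __post_init__(self):
        self.eos_occ = np.asarray(self.eos_occ, dtype=int)
        self.aos_occ = np.asarray(self.aos_occ, dtype=int)
        self.virt = np.asarray(self.virt, dtype=int)
        if self.own_virt is None:
            self.own_virt = self.virt
        self.own_virt = np.asarray(self.own_virt, dtype=int)
        if not set(self.eos_occ).issubset(set(self.aos_occ)):
            raise ValueError("eos_occ must be a subset of aos_occ")


@dataclass
class DECResult:
    fragment_energies: dict        # site -> E_P
    pair_energies: dict            # (P, Q) with P < Q -> dE_PQ
    pair_estimates: dict           # (P, Q) -> minimal-space MP2 estimate
    screened_pairs: set            # pairs not computed at target level
    effective_energies: dict       # site -> eps_P
    e_corr: float
    error_estimate: float
    method: str
    e_hf: float = 0.0
    fragments: dict = None         # site -> FragmentSpaces
    n_frag: int = 0

    @property
    def e_total(self):
        return self.e_hf + self.e_corr


# --------------------------------------------------------------------------
# fragment amplitude solves (pseudo-canonical basis)
# --------------------------------------------------------------------------

def _subspace_tensors(occ_idx, virt_idx, g_loc, F_loc):
    idx = np.concatenate([occ_idx, virt_idx]).astype(int)
    g_frag = g_loc[np.ix_(idx, idx, idx, idx)]
    F_oo = F_loc[np.ix_(occ_idx, occ_idx)]
    F_vv = F_loc[np.ix_(virt_idx, virt_idx)]
    return g_frag, F_oo, F_vv


def solve_fragment_amplitudes(occ_idx, virt_idx, g_loc, F_loc, method: str = "mp2",
                              conv_tol: float = 1e-9, return_pc: bool = False):
    """Solve MP2 or CCSD amplitude equations on an orbital subspace.

    The occupied-occupied and virtual-virtual blocks of the full Fock
    matrix, restricted to the subspace, are diagonalized (pseudo-canonical
    basis); the amplitude equations are solved there (MP2 non-iteratively)
    and the amplitudes rotated back to the local basis.  Returns
    ``(t1, t2)`` indexed by position in ``occ_idx`` / ``virt_idx``.
    """
    occ_idx = np.asarray(occ_idx, dtype=int)
    virt_idx = np.asarray(virt_idx, dtype=int)
    no, nv = len(occ_idx), len(virt_idx)
    if no == 0 or nv == 0:
        t1 = np.zeros((no, nv))
        t2 = np.zeros((no, no, nv, nv))
        return (t1, t2) if not return_pc else (t1, t2, None)
    g_frag, F_oo, F_vv = _subspace_tensors(occ_idx, virt_idx, g_loc, F_loc)
    U_o, eps_o = pseudo_canonicalize(F_oo)
    U_v, eps_v = pseudo_canonicalize(F_vv)
    U = np.zeros((no + nv, no + nv))
    U[:no, :no] = U_o
    U[no:, no:] = U_v
    g_pc = np.einsum("pqrs,pi,qj,rk,sl->ijkl", g_frag, U, U, U, U, optimize=True)
    eps = np.concatenate([eps_o, eps_v])
    if method == "mp2":
        o, v = slice(0, no), slice(no, no + nv)
        denom = (eps_o[:, None, None, None] + eps_o[None, :, None, None]
                 - eps_v[None, None, :, None] - eps_v[None, None, None, :])
        g_ovov = g_pc[v, o, v, o].transpose(1, 0, 3, 2)       # [i,a,j,b] = (ai|bj)
        t2_pc = g_ovov.transpose(0, 2, 1, 3) / denom
        t1_pc = np.zeros((no, nv))
    elif method == "ccsd":
        amps = ccsd_solve(g_pc, None, eps, no, conv_tol=max(conv_tol, 1e-10))
        if not amps.converged:
            amps = ccsd_solve(g_pc, None, eps, no, conv_tol=max(conv_tol, 1e-10),
                              max_iter=300, diis_window=10)
        t1_pc, t2_pc = amps.t1, amps.t2
    else:
        raise ValueError(f"unknown fragment method {method!r}")
    t1 = np.einsum("iI,aA,IA->ia", U_o, U_v, t1_pc, optimize=True)
    t2 = np.einsum("iI,jJ,aA,bB,IJAB->ijab", U_o, U_o, U_v, U_v, t2_pc, optimize=True)
    if return_pc:
        return t1, t2, (U_o, U_v, eps_o, eps_v, g_pc, t1_pc, t2_pc)
    return t1, t2


def _energy_block(t1, t2, g_loc, occ_rows, occ_cols, occ_idx, virt_idx):
    """sum_{i in rows, j in cols} sum_{ab} (t2+t1 t1)(2(ai|bj)-(bi|aj)).

    ``occ_rows``/``occ_cols`` are positions into ``occ_idx``.
    """
    if len(occ_rows) == 0 or len(occ_cols) == 0 or len(virt_idx) == 0:
        return 0.0
    oi = np.asarray(occ_idx, dtype=int)
    vi = np.asarray(virt_idx, dtype=int)
    r = np.asarray(occ_rows, dtype=int)
    c = np.asarray(occ_cols, dtype=int)
    g_aibj = g_loc[np.ix_(vi, oi[r], vi, oi[c])]          # [a,i,b,j] = (ai|bj)
    tau = t2 + np.einsum("ia,jb->ijab", t1, t1)
    tau_rc = tau[np.ix_(r, c)]
    # L[i,a,j,b] = 2 (ai|bj) - (bi|aj); the exchange entry (bi|aj) sits at
    # [b, i, a, j] of the same block because rows pair with the first
    # virtual slot and columns with the second
    L = 2.0 * g_aibj.transpose(1, 0, 3, 2) - g_aibj.transpose(1, 2, 3, 0)
    return float(np.einsum("ijab,iajb->", tau_rc, L, optimize=True))


def fragment_energy(P: FragmentSpaces, t1, t2, g_loc) -> float:
    """E_P: energy expression restricted to EOS occupied rows and columns."""
    if len(P.eos_occ) == 0:
        return 0.0
    pos = {o: k for k, o in enumerate(P.aos_occ)}
    rows = [pos[o] for o in P.eos_occ]
    return _energy_block(t1, t2, g_loc, rows, rows, P.aos_occ, P.virt)


def pair_energy(P: FragmentSpaces, Q: FragmentSpaces, t1, t2, g_loc,
                occ_union, virt_union) -> float:
    """dE_PQ: the two cross blocks i in P, j in Q and i in Q, j in P."""
    if P.site == Q.site:
        raise ValueError("pair energy requires distinct fragments")
    pos = {o: k for k, o in enumerate(occ_union)}
    rp = [pos[o] for o in P.eos_occ]
    rq = [pos[o] for o in Q.eos_occ]
    e = _energy_block(t1, t2, g_loc, rp, rq, occ_union, virt_union)
    e += _energy_block(t1, t2, g_loc, rq, rp, occ_union, virt_union)
    return e


# --------------------------------------------------------------------------
# fragment optimization: expansion then reduction
# --------------------------------------------------------------------------

def _site_distances(sites: np.ndarray) -> np.ndarray:
    return np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=2)


def _fragment_energy_for_spaces(site, eos_occ, occ_idx, virt_idx, g_loc, F_loc,
                                method, fot):
    frag = FragmentSpaces(site, eos_occ, occ_idx, virt_idx, fot)
    t1, t2 = solve_fragment_amplitudes(occ_idx, virt_idx, g_loc, F_loc, method)
    return fragment_energy(frag, t1, t2, g_loc)


def optimize_fragment(site: int, fot: float, lo: LocalOrbitalSet,
                      g_loc: np.ndarray, F_loc: np.ndarray, sites: np.ndarray,
                      method: str = "mp2") -> FragmentSpaces:
    """Expand fragment spaces site layer by site layer, then reduce.

    Expansion starts from the EOS plus the nearest-neighbour sites and adds
    one site (its occupied and virtual orbitals) per step in order of
    distance from P, until the fragment energy changes by less than the
    FOT.  Reduction then binary-searches the distance-ordered tail of
    included sites for the largest block that can be removed while keeping
    the energy within the FOT of the converged value.
    """
    eos_occ = lo.site_orbitals(site, "occ")
    n_sites = sites.shape[0]
    dist = _site_distances(sites)
    order = np.lexsort((np.arange(n_sites), np.round(dist[site], 12)))
    if len(eos_occ) == 0:
        frag = FragmentSpaces(site, eos_occ, eos_occ, np.array([], dtype=int), fot,
                              own_virt=lo.site_orbitals(site, "virt"))
        frag.expansion_history.append((0, 0, 0.0))
        return frag

    pos_d = dist[site][dist[site] > 1e-12]
    d_min = pos_d.min() if pos_d.size else 1.0

    def spaces_for(included_sites):
        mask = np.isin(lo.assignment, included_sites)
        occ = np.where(mask & (np.arange(len(lo.assignment)) < lo.n_occ))[0]
        occ = np.array(sorted(set(occ) | set(eos_occ)), dtype=int)
        virt = np.where(mask & (np.arange(len(lo.assignment)) >= lo.n_occ))[0]
        return occ, virt

    # initial layer: P and its nearest neighbours
    included = [s for s in order if dist[site][s] <= d_min * (1 + 1e-9)]
    remaining = [s for s in order if s not in included]
    occ_idx, virt_idx = spaces_for(included)
    e_prev = _fragment_energy_for_spaces(site, eos_occ, occ_idx, virt_idx,
                                         g_loc, F_loc, method, fot)
    history = [(len(occ_idx), len(virt_idx), e_prev)]
    exhausted = len(remaining) == 0
    converged = exhausted
    while remaining:
        included.append(remaining.pop(0))
        occ_idx, virt_idx = spaces_for(included)
        e_new = _fragment_energy_for_spaces(site, eos_occ, occ_idx, virt_idx,
                                            g_loc, F_loc, method, fot)
        history.append((len(occ_idx), len(virt_idx), e_new))
        if abs(e_new - e_prev) < fot:
            e_prev = e_new
            converged = True
            break
        e_prev = e_new
        if not remaining:
            exhausted = True
    e_conv = e_prev

    # reduction: drop the farthest included sites (never P itself)
    tail = [s for s in included if s != site]
    tail.sort(key=lambda s: (dist[site][s], s))          # ascending distance
    # candidate k = number of farthest tail sites removed; binary search
    def energy_drop(k):
        keep = [site] + tail[:len(tail) - k]
        occ_k, virt_k = spaces_for(keep)
        e_k = _fragment_energy_for_spaces(site, eos_occ, occ_k, virt_k,
                                          g_loc, F_loc, method, fot)
        return e_k, occ_k, virt_k

    best_k = 0
    lo_k, hi_k = 0, len(tail)
    while lo_k < hi_k:
        mid = (lo_k + hi_k + 1) // 2
        e_k, _, _ = energy_drop(mid)
        if abs(e_k - e_conv) <= fot:
            lo_k = mid
        else:
            hi_k = mid - 1
    best_k = lo_k
    _, occ_idx, virt_idx = energy_drop(best_k)

    frag = FragmentSpaces(site, eos_occ, occ_idx, virt_idx, fot,
                          own_virt=lo.site_orbitals(site, "virt"))
    frag.expansion_history = history
    frag.exhausted = exhausted and not converged
    return frag


# --------------------------------------------------------------------------
# pair estimation and screening
# --------------------------------------------------------------------------

def estimate_pairs(lo: LocalOrbitalSet, g_loc, F_loc, sites: np.ndarray,
                   r_screen: float = 30.0) -> dict:
    """Minimal-space MP2 pair energy estimates for pairs within r_screen.

    The minimal space of pair (P, Q) is: occupied = EOS(P) + EOS(Q),
    virtual = virtuals assigned to P, Q, or any site within one lattice
    spacing of either (the same nearest-neighbour rule that seeds the
    fragment expansion); local excitations out of P and Q dominate the
    pair interaction but frequently terminate on adjacent sites.
    """
    n_sites = sites.shape[0]
    dist = _site_distances(sites)
    pos_d = dist[dist > 1e-12]
    d_min = pos_d.min() if pos_d.size else 1.0
    estimates = {}
    for P in range(n_sites):
        for Q in range(P + 1, n_sites):
            if dist[P, Q] > r_screen:
                continue
            eP = lo.site_orbitals(P, "occ")
            eQ = lo.site_orbitals(Q, "occ")
            if len(eP) == 0 or len(eQ) == 0:
                estimates[(P, Q)] = 0.0
                continue
            occ_idx = np.array(sorted(set(eP) | set(eQ)), dtype=int)
            near = [s for s in range(n_sites)
                    if min(dist[s, P], dist[s, Q]) <= d_min * (1 + 1e-9)]
            virt_set = set()
            for s in near:
                virt_set |= set(lo.site_orbitals(s, "virt"))
            virt_idx = np.array(sorted(virt_set), dtype=int)
            fragP = FragmentSpaces(P, eP, occ_idx, virt_idx, 0.0)
            fragQ = FragmentSpaces(Q, eQ, occ_idx, virt_idx, 0.0)
            if len(virt_idx) == 0:
                estimates[(P, Q)] = 0.0
                continue
            t1, t2 = solve_fragment_amplitudes(occ_idx, virt_idx, g_loc, F_loc, "mp2")
            estimates[(P, Q)] = pair_energy(fragP, fragQ, t1, t2, g_loc,
                                            occ_idx, virt_idx)
    return estimates


def screen_pairs(estimates: dict, fot: float, sites: np.ndarray,
                 r_screen: float = 30.0):
    """Per-site cumulative screening of estimated pair energies.

    For each site the pairs are ordered by ascending |estimate| and the
    largest prefix whose half-sum of magnitudes stays within the FOT is
    screened from that site's list.  A pair is discarded only when screened
    from the lists of both of its sites; pairs beyond ``r_screen`` never
    enter ``estimates`` and are discarded outright.
    """
    n_sites = sites.shape[0]
    dist = _site_distances(sites)
    screened_from = {P: set() for P in range(n_sites)}
    for P in range(n_sites):
        plist = [(min(P, Q2), max(P, Q2)) for Q2 in range(n_sites)
                 if Q2 != P and (min(P, Q2), max(P, Q2)) in estimates]
        plist.sort(key=lambda pq: (abs(estimates[pq]),
                                   pq[1] if pq[0] == P else pq[0]))
        acc = 0.0
        for pq in plist:
            if acc + 0.5 * abs(estimates[pq]) <= fot:
                acc += 0.5 * abs(estimates[pq])
                screened_from[P].add(pq)
            else:
                break
    screened = {pq for pq in estimates
                if pq in screened_from[pq[0]] and pq in screened_from[pq[1]]}
    all_pairs = {(P, Q) for P in range(n_sites) for Q in range(P + 1, n_sites)}
    beyond = {pq for pq in all_pairs if dist[pq[0], pq[1]] > r_screen}
    retained = {pq for pq in estimates if pq not in screened}
    return screened | beyond, retained


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def error_estimate(n_frag: int, fot: float) -> float:
    """Expected DEC correlation-energy error, 2 * N_frag * FOT."""
    if n_frag < 1:
        raise ValueError("n_frag must be >= 1")
    return 2.0 * n_frag * fot


def assemble(fragment_energies: dict, pair_energies: dict, screened: set,
             fot: float, method: str, pair_estimates: dict = None,
             fragments: dict = None, e_hf: float = 0.0) -> DECResult:
    """Total and effective fragment energies from computed contributions."""
    e_corr = sum(fragment_energies.values()) + sum(pair_energies.values())
    eff = {}
    for P, eP in fragment_energies.items():
        pair_sum = sum(v for (A, B), v in pair_energies.items() if P in (A, B))
        eff[P] = eP + 0.5 * pair_sum
    checksum = abs(sum(eff.values()) - e_corr)
    if checksum > 1e-9:
        raise RuntimeError(f"effective-energy checksum violated: {checksum:.3e}")
    n_frag = len(fragment_energies)
    return DECResult(fragment_energies=dict(fragment_energies),
                     pair_energies=dict(pair_energies),
                     pair_estimates=dict(pair_estimates or {}),
                     screened_pairs=set(screened),
                     effective_energies=eff,
                     e_corr=float(e_corr),
                     error_estimate=error_estimate(max(n_frag, 1), fot),
                     method=method, e_hf=e_hf,
                     fragments=fragments, n_frag=n_frag)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def _pair_task(args):
    (P_site, Q_site, eosP, eosQ, occ_idx, virt_idx, g_loc, F_loc,
     method, fot, ownP, ownQ) = args
    fragP = FragmentSpaces(P_site, eosP, occ_idx, virt_idx, fot, own_virt=ownP)
    fragQ = FragmentSpaces(Q_site, eosQ, occ_idx, virt_idx, fot, own_virt=ownQ)
    solver_method = "ccsd" if method in ("ccsd", "ccsd_t") else "mp2"
    if method == "ccsd_t":
        t1, t2, pc = solve_fragment_amplitudes(occ_idx, virt_idx, g_loc, F_loc,
                                               solver_method, return_pc=True)
    else:
        t1, t2 = solve_fragment_amplitudes(occ_idx, virt_idx, g_loc, F_loc,
                                           solver_method)
    e = pair_energy(fragP, fragQ, t1, t2, g_loc, occ_idx, virt_idx)
    if method == "ccsd_t":
        e += _pt_pair_contribution(fragP, fragQ, occ_idx, virt_idx, pc, g_loc)
    return ((P_site, Q_site), e)


def _pt_intermediates_local(occ_idx, virt_idx, pc, g_loc):
    """(T) intermediates on a fragment space, back-rotated to local basis."""
    U_o, U_v, eps_o, eps_v, g_pc, t1_pc, t2_pc = pc
    tri = triples_intermediates(t2_pc, g_pc, eps_o, eps_v)
    T2 = np.einsum("iI,jJ,aA,bB,IJAB->ijab", U_o, U_o, U_v, U_v, tri.T2bar,
                   optimize=True)
    T1 = np.einsum("iI,aA,IA->ia", U_o, U_v, tri.T1bar, optimize=True)
    t1 = np.einsum("iI,aA,IA->ia", U_o, U_v, t1_pc, optimize=True)
    t2 = np.einsum("iI,jJ,aA,bB,IJAB->ijab", U_o, U_o, U_v, U_v, t2_pc,
                   optimize=True)
    return t1, t2, T1, T2


def _pt_fragment_contribution(frag: FragmentSpaces, occ_idx, virt_idx, pc, g_loc):
    """Triples fragment energy: doubles rows over the EOS occupied pairs;
    the singles term runs over the virtuals assigned to the site itself so
    that, together with the pair cross terms, every (i, a) pair is counted
    exactly once even when fragment virtual spaces overlap."""
    t1, t2, T1, T2 = _pt_intermediates_local(occ_idx, virt_idx, pc, g_loc)
    pos = {o: k for k, o in enumerate(occ_idx)}
    vpos = {o: k for k, o in enumerate(virt_idx)}
    rows = [pos[o] for o in frag.eos_occ]
    own = [vpos[a] for a in frag.own_virt if a in vpos]
    u = 2.0 * t2 - t2.transpose(1, 0, 2, 3)
    e = 2.0 * np.einsum("ijab,ijab->", u[np.ix_(rows, rows)],
                        T2[np.ix_(rows, rows)], optimize=True)
    e += 2.0 * np.einsum("ia,ia->", t1[np.ix_(rows, own)], T1[np.ix_(rows, own)])
    return float(e)


def _pt_pair_contribution(fragP, fragQ, occ_idx, virt_idx, pc, g_loc):
    t1, t2, T1, T2 = _pt_intermediates_local(occ_idx, virt_idx, pc, g_loc)
    pos = {o: k for k, o in enumerate(occ_idx)}
    vpos = {o: k for k, o in enumerate(virt_idx)}
    rp = [pos[o] for o in fragP.eos_occ]
    rq = [pos[o] for o in fragQ.eos_occ]
    u = 2.0 * t2 - t2.transpose(1, 0, 2, 3)
    e = 2.0 * np.einsum("ijab,ijab->", u[np.ix_(rp, rq)], T2[np.ix_(rp, rq)],
                        optimize=True)
    e += 2.0 * np.einsum("ijab,ijab->", u[np.ix_(rq, rp)], T2[np.ix_(rq, rp)],
                         optimize=True)
    # singles cross terms: a assigned to one site, i in the other site's EOS
    vP = [vpos[a] for a in fragP.own_virt if a in vpos]
    vQ = [vpos[a] for a in fragQ.own_virt if a in vpos]
    e += 2.0 * float(np.einsum("ia,ia->", t1[np.ix_(rq, vP)], T1[np.ix_(rq, vP)]))
    e += 2.0 * float(np.einsum("ia,ia->", t1[np.ix_(rp, vQ)], T1[np.ix_(rp, vQ)]))
    return float(e)


def dec_driver(intset: IntegralSet, method: str = "mp2", fot: float = 1e-4,
               r_screen: float = 30.0, scheduler: str = "serial",
               n_procs: int = 4, localization: str = "PM2",
               frag_opt_method: str = None, scf_tol: float = 1e-10) -> DECResult:
    """Full DEC pipeline on an integral set.

    RHF -> localization -> per-site fragment optimization -> minimal-space
    pair estimation -> screening -> retained pair calculations -> assembly.
    Fragment optimization for CCSD / CCSD(T) targets runs at MP2 by default.
    """
    if method not in ("mp2", "ccsd", "ccsd_t"):
        raise ValueError(f"unknown method {method!r}")
    scf = run_rhf(intset, conv_tol=scf_tol)
    lo = build_local_orbitals(scf, intset, functional=localization)
    _, g_loc = mo_transform(intset, lo.C_loc)
    F_loc = lo.C_loc.T @ (scf.C @ np.diag(scf.eps) @ scf.C.T) @ lo.C_loc
    sites = intset.sites
    n_sites = sites.shape[0]
    opt_method = frag_opt_method or ("mp2" if method != "mp2" else "mp2")

    # fragment optimization, largest sites (most orbitals) first
    site_order = sorted(range(n_sites),
                        key=lambda s: (-len(lo.site_orbitals(s)), s))
    fragments = {}
    for s in site_order:
        fragments[s] = optimize_fragment(s, fot, lo, g_loc, F_loc, sites,
                                         method=opt_method)

    # fragment energies at the target level
    fragment_energies = {}
    solver_method = "ccsd" if method in ("ccsd", "ccsd_t") else "mp2"
    for s in range(n_sites):
        frag = fragments[s]
        if len(frag.eos_occ) == 0 or len(frag.virt) == 0:
            fragment_energies[s] = 0.0
            continue
        if method == "ccsd_t":
            t1, t2, pc = solve_fragment_amplitudes(frag.aos_occ, frag.virt,
                                                   g_loc, F_loc, solver_method,
                                                   return_pc=True)
            e = fragment_energy(frag, t1, t2, g_loc)
            e += _pt_fragment_contribution(frag, frag.aos_occ, frag.virt, pc, g_loc)
        else:
            t1, t2 = solve_fragment_amplitudes(frag.aos_occ, frag.virt,
                                               g_loc, F_loc, solver_method)
            e = fragment_energy(frag, t1, t2, g_loc)
        fragment_energies[s] = e

    # pair estimation and screening
    estimates = estimate_pairs(lo, g_loc, F_loc, sites, r_screen=r_screen)
    screened, retained = screen_pairs(estimates, fot, sites, r_screen=r_screen)

    # retained pair calculations, largest union spaces first
    # pairs where one site owns only virtual orbitals never contribute at
    # the MP2/CCSD level (both cross blocks need occupied orbitals on both
    # sites), but the perturbative-triples singles cross terms do reach
    # them, so the ccsd_t path keeps them regardless of screening
    pair_list = set(retained)
    if method == "ccsd_t":
        for P in range(n_sites):
            for Q in range(P + 1, n_sites):
                fP, fQ = fragments[P], fragments[Q]
                one_sided = (len(fP.eos_occ) == 0) != (len(fQ.eos_occ) == 0)
                if one_sided:
                    pair_list.add((P, Q))
    tasks = []
    for (P, Q) in sorted(pair_list):
        fP, fQ = fragments[P], fragments[Q]
        if len(fP.eos_occ) == 0 and len(fQ.eos_occ) == 0:
            continue
        if method != "ccsd_t" and (len(fP.eos_occ) == 0 or len(fQ.eos_occ) == 0):
            continue
        occ_idx = np.array(sorted(set(fP.aos_occ) | set(fQ.aos_occ)), dtype=int)
        virt_idx = np.array(sorted(set(fP.virt) | set(fQ.virt)), dtype=int)
        if method == "ccsd_t":
            virt_idx = np.array(sorted(set(virt_idx) | set(fP.own_virt)
                                       | set(fQ.own_virt)), dtype=int)
        if len(virt_idx) == 0 or len(occ_idx) == 0:
            continue
        tasks.append((P, Q, fP.eos_occ, fQ.eos_occ, occ_idx, virt_idx,
                      g_loc, F_loc, method, fot, fP.own_virt, fQ.own_virt))
    tasks.sort(key=lambda t: (-(len(t[4]) + len(t[5])), t[0], t[1]))

    pair_energies = {}
    if scheduler == "serial" or len(tasks) == 0:
        results = [_pair_task(t) for t in tasks]
    elif scheduler == "procs":
        with concurrent.futures.ProcessPoolExecutor(max_workers=n_procs) as ex:
            results = list(ex.map(_pair_task, tasks))
    else:
        raise ValueError(f"unknown scheduler {scheduler!r}")
    for key, val in sorted(results, key=lambda kv: kv[0]):
        pair_energies[key] = val

    return assemble(fragment_energies, pair_energies, screened, fot, method,
                    pair_estimates=estimates, fragments=fragments,
                    e_hf=scf.e_hf)
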