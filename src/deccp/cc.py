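"""Canonical correlation methods and brute-force oracles.

MP2, CCSD, perturbative-triples intermediates, CCS/CIS excitations, a dense
finite-difference EOM-CCSD Jacobian, and determinant full CI.  Public
amplitudes are closed-shell spatial quantities: ``t1[i, a]`` and
``t2[i, j, a, b]`` with the singlet permutational symmetry
``t2[i, j, a, b] = t2[j, i, b, a]``, paired with chemist-notation
integrals so that the correlation energy reads

    E_corr = sum_ijab (t2[ijab] + t1[ia] t1[jb]) (2 (ai|bj) - (bi|aj)).

The CCSD amplitude equations themselves are iterated in the spin-orbital
representation (the standard antisymmetrized-integral working equations
with effective one- and two-particle intermediates), which keeps the code
short and lets determinant-space operator algebra serve as a fully
independent residual oracle; the closed-shell amplitudes are extracted
from the mixed-spin components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .determinants import DetSpace, build_hamiltonian, spin_squared
from .integrals import IntegralSet

__all__ = [
    "Amplitudes", "TriplesIntermediates", "ExcitationResult",
    "mp2", "ccsd_solve", "triples_intermediates", "pt_energy",
    "ccs_excitations", "eom_ccsd_dense", "fci_solve", "fci_ground_energy",
    "spatial_to_spin_orbital", "spin_orbital_residual", "ccs_matrix",
]


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class Amplitudes:
    """Closed-shell singles/doubles amplitudes with convergence metadata."""
    t1: np.ndarray                 # (n_occ, n_virt)
    t2: np.ndarray                 # (n_occ, n_occ, n_virt, n_virt)
    e_corr: float
    residual_norm: float = 0.0
    converged: bool = True
    n_iter: int = 0
    method: str = "mp2"


@dataclass
class TriplesIntermediates:
    T2bar: np.ndarray              # T_ij^ab
    T1bar: np.ndarray              # T_i^a


@dataclass
class ExcitationResult:
    omegas: np.ndarray
    R: np.ndarray                  # right eigenvectors, columns
    L: np.ndarray                  # left eigenvectors, columns
    biorthonormal: bool


# --------------------------------------------------------------------------
# energies from closed-shell amplitudes
# --------------------------------------------------------------------------

def _corr_energy(t1, t2, g_ovov, f_ov=None):
    """E_corr = sum (t2 + t1 t1)(2 (ai|bj) - (bi|aj)) [+ 2 f_ia t_ia]."""
    # g_ovov[i, a, j, b] = (ai|bj)  (equal to (ia|jb) for real integrals)
    L = 2.0 * g_ovov - g_ovov.transpose(2, 1, 0, 3)      # 2(ai|bj)-(bi|aj)
    tau = t2 + np.einsum("ia,jb->ijab", t1, t1)
    e = np.einsum("ijab,iajb->", tau, L, optimize=True)
    if f_ov is not None:
        e += 2.0 * np.einsum("ia,ia->", f_ov, t1)
    return float(e)


def mp2(g_mo: np.ndarray, eps: np.ndarray, n_occ: int) -> Amplitudes:
    """Canonical MP2: t2[ijab] = (ai|bj) / (e_i + e_j - e_a - e_b)."""
    n = g_mo.shape[0]
    o, v = slice(0, n_occ), slice(n_occ, n)
    eo, ev = eps[o], eps[v]
    if n_occ == 0 or n_occ == n:
        z = np.zeros((n_occ, n - n_occ))
        return Amplitudes(z, np.zeros((n_occ, n_occ, n - n_occ, n - n_occ)), 0.0)
    denom = (eo[:, None, None, None] + eo[None, :, None, None]
             - ev[None, None, :, None] - ev[None, None, None, :])
    if np.abs(denom).min() < 1e-10:
        raise ValueError("degenerate reference: vanishing MP2 denominator")
    g_ovov = g_mo[v, o, v, o].transpose(1, 0, 3, 2)      # (ai|bj) -> [i,a,j,b]
    t2 = g_ovov.transpose(0, 2, 1, 3) / denom            # [i,j,a,b]
    t1 = np.zeros((n_occ, n - n_occ))
    return Amplitudes(t1, t2, _corr_energy(t1, t2, g_ovov), method="mp2")


# --------------------------------------------------------------------------
# spin-orbital machinery (internal)
# --------------------------------------------------------------------------

def _spin_expand(g_mo: np.ndarray, F_mo: np.ndarray):
    """Interleaved spin-orbital antisymmetrized integrals <pq||rs> and Fock."""
    n = g_mo.shape[0]
    n_so = 2 * n
    sp = np.arange(n_so) // 2
    sz = np.arange(n_so) % 2
    g_phys = g_mo.transpose(0, 2, 1, 3)                  # <pq|rs> = (pr|qs)
    same13 = (sz[:, None, None, None] == sz[None, None, :, None])
    same24 = (sz[None, :, None, None] == sz[None, None, None, :])
    gs = g_phys[np.ix_(sp, sp, sp, sp)] * same13 * same24
    gso = gs - gs.transpose(0, 1, 3, 2)
    f_so = F_mo[np.ix_(sp, sp)] * (sz[:, None] == sz[None, :])
    return gso, f_so


def spatial_to_spin_orbital(t1, t2):
    """Closed-shell spatial amplitudes -> interleaved spin-orbital ones."""
    no, nv = t1.shape
    t1_so = np.zeros((2 * no, 2 * nv))
    t1_so[0::2, 0::2] = t1
    t1_so[1::2, 1::2] = t1
    t2_so = np.zeros((2 * no, 2 * no, 2 * nv, 2 * nv))
    t2a = t2 - t2.transpose(0, 1, 3, 2)                  # same-spin part
    t2_so[0::2, 0::2, 0::2, 0::2] = t2a
    t2_so[1::2, 1::2, 1::2, 1::2] = t2a
    t2_so[0::2, 1::2, 0::2, 1::2] = t2
    t2_so[1::2, 0::2, 1::2, 0::2] = t2
    t2_so[0::2, 1::2, 1::2, 0::2] = -t2.transpose(0, 1, 3, 2)
    t2_so[1::2, 0::2, 0::2, 1::2] = -t2.transpose(0, 1, 3, 2)
    return t1_so, t2_so


def _so_residual(t1, t2, f, g, o, v):
    """Spin-orbital CCSD residual (RHS - D*t form) and intermediates.

    Standard working equations with effective intermediates; ``f`` and ``g``
    are the spin-orbital Fock matrix and antisymmetrized integrals, ``o``
    and ``v`` occupied/virtual slices.  Returns (r1, r2) such that the
    amplitude equations read r1 = 0, r2 = 0.
    """
    tau_t = t2 + 0.5 * (np.einsum("ia,jb->ijab", t1, t1)
                        - np.einsum("ib,ja->ijab", t1, t1))
    tau = t2 + (np.einsum("ia,jb->ijab", t1, t1)
                - np.einsum("ib,ja->ijab", t1, t1))

    Fae = f[v, v] - np.diag(np.diag(f[v, v]))
    Fae = Fae - 0.5 * np.einsum("me,ma->ae", f[o, v], t1)
    Fae = Fae + np.einsum("mf,mafe->ae", t1, g[o, v, v, v], optimize=True)
    Fae = Fae - 0.5 * np.einsum("mnaf,mnef->ae", tau_t, g[o, o, v, v], optimize=True)

    Fmi = f[o, o] - np.diag(np.diag(f[o, o]))
    Fmi = Fmi + 0.5 * np.einsum("ie,me->mi", t1, f[o, v])
    Fmi = Fmi + np.einsum("ne,mnie->mi", t1, g[o, o, o, v], optimize=True)
    Fmi = Fmi + 0.5 * np.einsum("inef,mnef->mi", tau_t, g[o, o, v, v], optimize=True)

    Fme = f[o, v] + np.einsum("nf,mnef->me", t1, g[o, o, v, v], optimize=True)

    Wmnij = g[o, o, o, o] + (np.einsum("je,mnie->mnij", t1, g[o, o, o, v], optimize=True)
                             - np.einsum("ie,mnje->mnij", t1, g[o, o, o, v], optimize=True))
    Wmnij = Wmnij + 0.25 * np.einsum("ijef,mnef->mnij", tau, g[o, o, v, v], optimize=True)

    Wabef = g[v, v, v, v] - (np.einsum("mb,amef->abef", t1, g[v, o, v, v], optimize=True)
                             - np.einsum("ma,bmef->abef", t1, g[v, o, v, v], optimize=True))
    Wabef = Wabef + 0.25 * np.einsum("mnab,mnef->abef", tau, g[o, o, v, v], optimize=True)

    Wmbej = g[o, v, v, o].copy()
    Wmbej = Wmbej + np.einsum("jf,mbef->mbej", t1, g[o, v, v, v], optimize=True)
    Wmbej = Wmbej - np.einsum("nb,mnej->mbej", t1, g[o, o, v, o], optimize=True)
    Wmbej = Wmbej - np.einsum("jnfb,mnef->mbej",
                              0.5 * t2 + np.einsum("jf,nb->jnfb", t1, t1),
                              g[o, o, v, v], optimize=True)

    # T1 residual
    r1 = f[o, v].copy()
    r1 = r1 + np.einsum("ie,ae->ia", t1, Fae)
    r1 = r1 - np.einsum("ma,mi->ia", t1, Fmi)
    r1 = r1 + np.einsum("imae,me->ia", t2, Fme, optimize=True)
    r1 = r1 - np.einsum("nf,naif->ia", t1, g[o, v, o, v], optimize=True)
    r1 = r1 - 0.5 * np.einsum("imef,maef->ia", t2, g[o, v, v, v], optimize=True)
    r1 = r1 - 0.5 * np.einsum("mnae,nmei->ia", t2, g[o, o, v, o], optimize=True)

    # T2 residual
    r2 = g[o, o, v, v].copy()
    tmp = np.einsum("ijae,be->ijab", t2, Fae - 0.5 * np.einsum("mb,me->be", t1, Fme),
                    optimize=True)
    r2 = r2 + tmp - tmp.transpose(0, 1, 3, 2)
    tmp = np.einsum("imab,mj->ijab", t2, Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme),
                    optimize=True)
    r2 = r2 - (tmp - tmp.transpose(1, 0, 2, 3))
    r2 = r2 + 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij, optimize=True)
    r2 = r2 + 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef, optimize=True)
    tmp = (np.einsum("imae,mbej->ijab", t2, Wmbej, optimize=True)
           - np.einsum("ie,ma,mbej->ijab", t1, t1, g[o, v, v, o], optimize=True))
    r2 = r2 + (tmp - tmp.transpose(0, 1, 3, 2)
               - tmp.transpose(1, 0, 2, 3) + tmp.transpose(1, 0, 3, 2))
    tmp = np.einsum("ie,abej->ijab", t1, g[v, v, v, o], optimize=True)
    r2 = r2 + tmp - tmp.transpose(1, 0, 2, 3)
    tmp = np.einsum("ma,mbij->ijab", t1, g[o, v, o, o], optimize=True)
    r2 = r2 - (tmp - tmp.transpose(0, 1, 3, 2))

    # fold the diagonal Fock part back in: full residual  r = RHS - D t,
    # so that  dr/dt  is the CC Jacobian (positive excitation diagonals)
    eps_o = np.diag(f)[o]
    eps_v = np.diag(f)[v]
    r1 = r1 - (eps_o[:, None] - eps_v[None, :]) * t1
    r2 = r2 - (eps_o[:, None, None, None] + eps_o[None, :, None, None]
               - eps_v[None, None, :, None] - eps_v[None, None, None, :]) * t2
    return r1, r2


def spin_orbital_residual(t1, t2, g_mo, F_mo, n_occ):
    """Spin-orbital CCSD residual of closed-shell spatial amplitudes."""
    g_so, f_so = _spin_expand(g_mo, F_mo)
    o, v = slice(0, 2 * n_occ), slice(2 * n_occ, 2 * g_mo.shape[0])
    t1_so, t2_so = spatial_to_spin_orbital(t1, t2)
    return _so_residual(t1_so, t2_so, f_so, g_so, o, v)


def ccsd_solve(g_mo: np.ndarray, h_mo, eps: np.ndarray, n_occ: int,
               conv_tol: float = 1e-8, max_iter: int = 100,
               diis_window: int = 6, F_mo: np.ndarray = None) -> Amplitudes:
    """Solve closed-shell CCSD amplitude equations.

    ``F_mo`` (or ``diag(eps)`` when omitted) supplies the one-particle
    operator; this admits fragment problems where the Fock matrix of the
    full system is restricted to an orbital subset (the occupied-virtual
    block must vanish or be supplied explicitly).  ``h_mo`` is accepted for
    interface compatibility and used only to rebuild the Fock matrix when
    ``F_mo`` is not given and ``eps`` is None.
    """
    n = g_mo.shape[0]
    n_virt = n - n_occ
    if F_mo is None:
        F_mo = np.diag(np.asarray(eps, dtype=float))
    if n_occ == 0 or n_virt == 0:
        return Amplitudes(np.zeros((n_occ, n_virt)),
                          np.zeros((n_occ, n_occ, n_virt, n_virt)), 0.0,
                          method="ccsd")
    g_so, f_so = _spin_expand(g_mo, F_mo)
    o, v = slice(0, 2 * n_occ), slice(2 * n_occ, 2 * n)
    eps_so = np.diag(f_so)
    d1 = eps_so[o][:, None] - eps_so[v][None, :]
    d2 = (eps_so[o][:, None, None, None] + eps_so[o][None, :, None, None]
          - eps_so[v][None, None, :, None] - eps_so[v][None, None, None, :])
    if np.abs(d2).min() < 1e-10:
        raise ValueError("degenerate reference: vanishing CCSD denominator")

    # MP2 start
    t1 = np.zeros((2 * n_occ, 2 * n_virt))
    t2 = g_so[o, o, v, v] / d2
    err_list, amp_list = [], []
    converged = False
    res_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        r1, r2 = _so_residual(t1, t2, f_so, g_so, o, v)
        res_norm = max(np.abs(r1).max() if r1.size else 0.0,
                       np.abs(r2).max() if r2.size else 0.0)
        if res_norm < conv_tol:
            converged = True
            break
        t1 = t1 + r1 / d1
        t2 = t2 + r2 / d2
        # amplitude DIIS
        amp = np.concatenate([t1.ravel(), t2.ravel()])
        err = np.concatenate([(r1 / d1).ravel(), (r2 / d2).ravel()])
        amp_list.append(amp)
        err_list.append(err)
        if len(amp_list) > diis_window:
            amp_list.pop(0)
            err_list.pop(0)
        m = len(amp_list)
        if m >= 2:
            B = np.empty((m + 1, m + 1))
            B[:m, :m] = np.array([[e1 @ e2 for e2 in err_list] for e1 in err_list])
            B[m, :], B[:, m], B[m, m] = -1.0, -1.0, 0.0
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:m]
                new = sum(ci * ai for ci, ai in zip(c, amp_list))
                t1 = new[:t1.size].reshape(t1.shape)
                t2 = new[t1.size:].reshape(t2.shape)
            except np.linalg.LinAlgError:
                pass

    # extract closed-shell spatial amplitudes from mixed-spin components
    t1_sp = t1[0::2, 0::2].copy()
    t2_sp = t2[0::2, 1::2, 0::2, 1::2].copy()
    g_ovov = g_mo[np.ix_(range(n_occ, n), range(n_occ), range(n_occ, n),
                         range(n_occ))].transpose(1, 0, 3, 2)
    e_corr = _corr_energy(t1_sp, t2_sp, g_ovov, f_ov=F_mo[:n_occ, n_occ:])
    return Amplitudes(t1_sp, t2_sp, e_corr, residual_norm=float(res_norm),
                      converged=converged, n_iter=it, method="ccsd")


# --------------------------------------------------------------------------
# perturbative triples intermediates (fragment-partitionable form)
# --------------------------------------------------------------------------

def _pair_permutations(expr):
    """Sum expr over the 6 simultaneous permutations of pairs (ai)(bj)(ck).

    ``expr`` has axes ordered (i, j, k, a, b, c); pair m carries (occ m,
    virt m), so permuting pairs permutes occupied and virtual axes together.
    """
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    out = np.zeros_like(expr)
    for p in perms:
        out += expr.transpose(p[0], p[1], p[2], p[0] + 3, p[1] + 3, p[2] + 3)
    return out


def triples_amplitudes(t2: np.ndarray, g_occ_virt, eps_occ, eps_virt):
    """Perturbative triples from converged doubles.

    t3[ijkabc] = P [ sum_d t2[ijad] (db|kc) - sum_l t2[ilab] (lj|kc) ] / D
    with P the sixfold simultaneous pair permutation and D the orbital-energy
    denominator.  ``g_occ_virt`` is the chemist-notation integral tensor over
    the supplied (occupied + virtual) spaces: g[(o+v), (o+v), ...].
    """
    no = t2.shape[0]
    nv = t2.shape[2]
    g = g_occ_virt
    o = slice(0, no)
    v = slice(no, no + nv)
    g_vvvo_db_kc = g[v, v, o, v]          # (db|kc) indexed [d,b,k,c]
    w1 = np.einsum("ijad,dbkc->ijkabc", t2, g[v, v, o, v], optimize=True)
    w2 = np.einsum("ilab,ljkc->ijkabc", t2, g[o, o, o, v], optimize=True)
    W = _pair_permutations(w1 - w2)
    D = (eps_occ[:, None, None, None, None, None]
         + eps_occ[None, :, None, None, None, None]
         + eps_occ[None, None, :, None, None, None]
         - eps_virt[None, None, None, :, None, None]
         - eps_virt[None, None, None, None, :, None]
         - eps_virt[None, None, None, None, None, :])
    return W / D


def triples_intermediates(t2: np.ndarray, g_space: np.ndarray,
                          eps_occ: np.ndarray, eps_virt: np.ndarray,
                          t3: np.ndarray = None) -> TriplesIntermediates:
    """Contract triples amplitudes into the doubles/singles intermediates.

    T2bar[ijab] = sum_{cd,k} ( t3[ijkacd] L_bckd - t3[kjiacd] g_kdbc )
                - sum_{c,kl} ( t3[iklabc] L_kjlc - t3[lkiabc] g_kjlc )
    T1bar[ia]   = sum_{cd,kl} ( t3[iklacd] - t3[lkiacd] ) L_kcld

    with L_pqrs = 2 (pq|rs) - (ps|rq).  ``g_space`` holds chemist integrals
    over the occupied+virtual spaces (occupied block first).
    """
    no = t2.shape[0]
    nv = t2.shape[2]
    if no == 0 or nv == 0:
        return TriplesIntermediates(np.zeros_like(t2), np.zeros((no, nv)))
    if t3 is None:
        t3 = triples_amplitudes(t2, g_space, eps_occ, eps_virt)
    o = slice(0, no)
    v = slice(no, no + nv)
    g = g_space

    # L tensors for the patterns used, L_pqrs = 2 (pq|rs) - (ps|rq)
    L_bckd = 2.0 * g[v, v, o, v] - g[v, v, o, v].transpose(0, 3, 2, 1)  # (bc|kd)-(bd|kc)
    g_kdbc = g[o, v, v, v]                                              # (kd|bc)
    L_kjlc = 2.0 * g[o, o, o, v] - g[o, v, o, o].transpose(0, 3, 2, 1)  # 2(kj|lc)-(kc|lj)
    g_kjlc = g[o, o, o, v]
    L_kcld = 2.0 * g[o, v, o, v] - g[o, v, o, v].transpose(0, 3, 2, 1)  # 2(kc|ld)-(kd|lc)

    T2bar = np.einsum("ijkacd,bckd->ijab", t3, L_bckd, optimize=True)
    T2bar -= np.einsum("kjiacd,kdbc->ijab", t3, g_kdbc, optimize=True)
    T2bar -= np.einsum("iklabc,kjlc->ijab", t3, L_kjlc, optimize=True)
    T2bar += np.einsum("lkiabc,kjlc->ijab", t3, g_kjlc, optimize=True)

    T1bar = (np.einsum("iklacd,kcld->ia", t3, L_kcld, optimize=True)
             - np.einsum("lkiacd,kcld->ia", t3, L_kcld, optimize=True))
    return TriplesIntermediates(T2bar=T2bar, T1bar=T1bar)


def pt_energy(t1: np.ndarray, t2: np.ndarray, tri: TriplesIntermediates,
              occ_idx=None, virt_idx=None) -> float:
    """Fragment-form perturbative triples energy.

    E = 2 sum_{ij in O, ab} (2 t2[ijab] - t2[jiab]) T2bar[ijab]
      + 2 sum_{i in O, a} t1[ia] T1bar[ia]

    ``occ_idx`` restricts the energy-summation occupied rows (fragment EOS);
    default is the full space.
    """
    no = t2.shape[0]
    occ_idx = list(range(no)) if occ_idx is None else list(occ_idx)
    u = 2.0 * t2 - t2.transpose(1, 0, 2, 3)
    e = 2.0 * np.einsum("ijab,ijab->", u[np.ix_(occ_idx, range(no))],
                        tri.T2bar[np.ix_(occ_idx, range(no))], optimize=True)
    e += 2.0 * np.einsum("ia,ia->", t1[occ_idx], tri.T1bar[occ_idx])
    return float(e)


# --------------------------------------------------------------------------
# excitation energies
# --------------------------------------------------------------------------

def ccs_matrix(g_mo: np.ndarray, F_mo: np.ndarray, n_occ: int) -> np.ndarray:
    """Singlet CCS/CIS Jacobian over singles (a, i), row-major a-then-i.

    A[(ai),(bj)] = F_ab d_ij - F_ij d_ab + 2 (ia|jb) - (ij|ab).
    For a canonical RHF reference the CCS ground-state singles vanish, so
    this is the full parent-state Jacobian.
    """
    n = g_mo.shape[0]
    o, v = slice(0, n_occ), slice(n_occ, n)
    nv = n - n_occ
    A = (np.einsum("ab,ij->aibj", F_mo[v, v], np.eye(n_occ))
         - np.einsum("ij,ab->aibj", F_mo[o, o], np.eye(nv))
         + 2.0 * g_mo[o, v, o, v].transpose(1, 0, 3, 2)
         - g_mo[o, o, v, v].transpose(2, 0, 3, 1))
    return A.reshape(nv * n_occ, nv * n_occ)


def _biorthonormalize(w, R, L):
    """Sort roots ascending, match L to R, normalize L_x . R_y = d_xy."""
    order = np.argsort(w.real)
    w = w[order]
    R = R[:, order]
    L = L[:, order]
    ok = np.all(np.abs(w.imag) < 1e-8)
    M = L.T @ R
    try:
        L = L @ np.linalg.inv(M).T
    except np.linalg.LinAlgError:
        ok = False
    # fix phases: largest-magnitude R component positive
    for k in range(R.shape[1]):
        imax = np.argmax(np.abs(R[:, k]))
        if R[imax, k].real < 0:
            R[:, k] = -R[:, k]
            L[:, k] = -L[:, k]
    return w, R, L, ok


def ccs_excitations(g_mo: np.ndarray, F_mo: np.ndarray, n_occ: int,
                    n_roots: int = None) -> ExcitationResult:
    """CCS excitation energies: dense diagonalization of the singles block."""
    A = ccs_matrix(g_mo, F_mo, n_occ)
    w, R = np.linalg.eig(A)
    wl, L = np.linalg.eig(A.T)
    # pair left/right eigenvectors by eigenvalue
    order_r = np.argsort(w.real)
    order_l = np.argsort(wl.real)
    w, R, L = w[order_r], R[:, order_r], L[:, order_l]
    w2, R, L, ok = _biorthonormalize(w, R, L)
    n_roots = len(w2) if n_roots is None else min(n_roots, len(w2))
    return ExcitationResult(omegas=w2.real[:n_roots], R=R[:, :n_roots].real,
                            L=L[:, :n_roots].real, biorthonormal=ok)


# ---- dense EOM-CCSD via finite differences of the residual --------------

def _pack(t1, t2, pair_index):
    """Closed-shell amplitudes -> unique parameter vector."""
    no, nv = t1.shape
    vec = [t1.ravel()]
    vals = np.empty(len(pair_index))
    for m, (i, j, a, b) in enumerate(pair_index):
        vals[m] = t2[i, j, a, b]
    vec.append(vals)
    return np.concatenate(vec)


def _unpack(vec, no, nv, pair_index):
    t1 = vec[:no * nv].reshape(no, nv).copy()
    t2 = np.zeros((no, no, nv, nv))
    for m, (i, j, a, b) in enumerate(pair_index):
        val = vec[no * nv + m]
        t2[i, j, a, b] = val
        t2[j, i, b, a] = val
    return t1, t2


def _unique_pairs(no, nv):
    """Composite pairs (ai) <= (bj), stored as (i, j, a, b)."""
    singles = [(a, i) for a in range(nv) for i in range(no)]
    pairs = []
    for m1, (a, i) in enumerate(singles):
        for m2, (b, j) in enumerate(singles):
            if m2 < m1:
                continue
            pairs.append((i, j, a, b))
    return pairs


def eom_ccsd_dense(amps: Amplitudes, g_mo: np.ndarray, F_mo: np.ndarray,
                   n_occ: int, n_roots: int = None, step: float = 1e-5,
                   max_dim: int = 2000) -> ExcitationResult:
    """EOM-CCSD excitation energies from a finite-difference Jacobian.

    The CC Jacobian is assembled column by column via central differences of
    the full amplitude residual around the converged amplitudes, in the
    unique singlet parameter space, then densely diagonalized.  Desk-scale
    oracle only.
    """
    n = g_mo.shape[0]
    no, nv = n_occ, n - n_occ
    pair_index = _unique_pairs(no, nv)
    dim = no * nv + len(pair_index)
    if dim > max_dim:
        raise ValueError(f"singles+doubles space {dim} exceeds {max_dim}: "
                         "the dense finite-difference Jacobian is desk-scale only")

    def residual_vec(vec):
        t1, t2 = _unpack(vec, no, nv, pair_index)
        r1, r2 = spin_orbital_residual(t1, t2, g_mo, F_mo, n_occ)
        r1_sp = r1[0::2, 0::2]
        r2_sp = r2[0::2, 1::2, 0::2, 1::2]
        return _pack(r1_sp, r2_sp, pair_index)

    v0 = _pack(amps.t1, amps.t2, pair_index)
    J = np.empty((dim, dim))
    for col in range(dim):
        vp = v0.copy()
        vm = v0.copy()
        vp[col] += step
        vm[col] -= step
        J[:, col] = (residual_vec(vp) - residual_vec(vm)) / (2.0 * step)
    w_all, R = np.linalg.eig(J)
    wl_all, L = np.linalg.eig(J.T)
    order_r = np.argsort(w_all.real)
    order_l = np.argsort(wl_all.real)
    w2, R, L, ok = _biorthonormalize(w_all[order_r], R[:, order_r], L[:, order_l])
    n_roots = len(w2) if n_roots is None else min(n_roots, len(w2))
    return ExcitationResult(omegas=w2.real[:n_roots], R=R[:, :n_roots].real,
                            L=L[:, :n_roots].real, biorthonormal=ok)


# --------------------------------------------------------------------------
# full CI
# --------------------------------------------------------------------------

def fci_solve(intset: IntegralSet, n_roots: int = 1, max_dim: int = 100000,
              return_space: bool = False):
    """Exact diagonalization over all Sz=0 determinants.

    Returns ``(energies, vectors)`` (and the DetSpace when requested).
    """
    n = intset.n_orb
    n_half = intset.n_elec // 2
    space = DetSpace(n, n_half, n_half)
    if space.dim > max_dim:
        raise ValueError(f"FCI space {space.dim} exceeds {max_dim}")
    H = build_hamiltonian(space, intset.h, intset.g, intset.e_core)
    if space.dim > 1200 and n_roots < space.dim // 4:
        w, V = spla.eigsh(H, k=max(n_roots, 2), which="SA")
        order = np.argsort(w)
        w, V = w[order], V[:, order]
    else:
        w, V = np.linalg.eigh(H)
    w, V = w[:n_roots], V[:, :n_roots]
    if return_space:
        return w, V, space
    return w, V


def fci_ground_energy(intset: IntegralSet) -> float:
    return float(fci_solve(intset, 1)[0][0])


def fci_singlet_spectrum(intset: IntegralSet, s2_tol: float = 1e-6):
    """All FCI eigenvalues restricted to singlet states (dense, desk scale)."""
    n = intset.n_orb
    n_half = intset.n_elec // 2
    space = DetSpace(n, n_half, n_half)
    H = build_hamiltonian(space, intset.h, intset.g, intset.e_core)
    w, V = np.linalg.eigh(H)
    S2 = spin_squared(space)
    s2_vals = np.einsum("ik,ij,jk->k", V, S2, V)
    mask = np.abs(s2_vals) < max(s2_tol, 1e-6)
    return w[mask]
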