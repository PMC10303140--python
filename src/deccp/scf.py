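"""Restricted Hartree-Fock in an orthonormal basis.

The basis is orthonormal by construction (overlap = identity), so the SCF
loop is plain repeated diagonalization of the Fock matrix with DIIS
extrapolation.  Convergence requires both the occupied-virtual Fock block
(Brillouin condition) and the energy change to fall below ``conv_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import IntegralSet

__all__ = ["SCFResult", "run_rhf", "mo_transform", "pseudo_canonicalize", "fock_matrix"]


@dataclass
class SCFResult:
    C: np.ndarray            # orbital coefficients, columns energy-ordered
    eps: np.ndarray          # orbital energies
    F_mo: np.ndarray         # Fock matrix in the MO basis
    e_hf: float              # total HF energy (incl. core)
    n_occ: int
    converged: bool
    n_iter: int

    @property
    def n_virt(self) -> int:
        return self.C.shape[0] - self.n_occ

    @property
    def homo_lumo_gap(self) -> float:
        if self.n_occ == 0 or self.n_virt == 0:
            return np.inf
        return float(self.eps[self.n_occ] - self.eps[self.n_occ - 1])


def fock_matrix(intset: IntegralSet, D: np.ndarray) -> np.ndarray:
    """Closed-shell Fock matrix from the (doubled) density D = 2 C_occ C_occ^T."""
    J = np.einsum("pqrs,rs->pq", intset.g, D, optimize=True)
    K = np.einsum("psrq,rs->pq", intset.g, D, optimize=True)
    return intset.h + J - 0.5 * K


def _fix_phases_and_order(eps: np.ndarray, C: np.ndarray):
    """Energy-ascending order with deterministic tie-breaks and phases.

    Degenerate columns are ordered by the index of their largest-magnitude
    coefficient; phases are fixed so that the largest-magnitude component of
    each column is positive.
    """
    order = np.lexsort((np.abs(C).argmax(axis=0), np.round(eps, 10)))
    eps = eps[order]
    C = C[:, order]
    for k in range(C.shape[1]):
        imax = np.argmax(np.abs(C[:, k]))
        if C[imax, k] < 0:
            C[:, k] = -C[:, k]
    return eps, C


def run_rhf(intset: IntegralSet, conv_tol: float = 1e-9, max_iter: int = 200,
            use_diis: bool = True, diis_window: int = 8) -> SCFResult:
    """Solve the closed-shell RHF equations; core-Hamiltonian initial guess.

    If plain DIIS iteration fails to converge (orbital-ordering
    oscillations near level crossings), the solve is retried with density
    damping and a virtual-space level shift before giving up.
    """
    res = _rhf_attempt(intset, conv_tol, max_iter, use_diis, diis_window,
                       damping=0.0, level_shift=0.0)
    if not res.converged:
        for damping, shift in [(0.3, 0.5), (0.6, 1.0)]:
            res2 = _rhf_attempt(intset, conv_tol, 2 * max_iter, use_diis,
                                diis_window, damping=damping, level_shift=shift)
            if res2.converged:
                return res2
        return res
    return res


def _rhf_attempt(intset: IntegralSet, conv_tol: float, max_iter: int,
                 use_diis: bool, diis_window: int, damping: float,
                 level_shift: float) -> SCFResult:
    if intset.n_elec % 2:
        raise ValueError("RHF requires an even electron count")
    n = intset.n_orb
    n_occ = intset.n_elec // 2

    eps, C = np.linalg.eigh(intset.h)
    eps, C = _fix_phases_and_order(eps, C)
    e_old = np.inf
    err_vecs, fock_list = [], []
    converged = False
    it = 0
    F = intset.h.copy()
    D_old = None
    for it in range(1, max_iter + 1):
        Cocc = C[:, :n_occ]
        D = 2.0 * Cocc @ Cocc.T
        if damping > 0.0 and D_old is not None:
            D = (1.0 - damping) * D + damping * D_old
        D_old = D
        F = fock_matrix(intset, D)
        e_hf = 0.5 * np.sum(D * (intset.h + F)) + intset.e_core

        # DIIS error: [F, D] (orthonormal basis)
        err = F @ D - D @ F
        ov_norm = np.abs(C[:, :n_occ].T @ F @ C[:, n_occ:]).max() if 0 < n_occ < n else 0.0
        if ov_norm < conv_tol and abs(e_hf - e_old) < conv_tol:
            converged = True
            break
        e_old = e_hf

        F_eff = F
        if use_diis:
            err_vecs.append(err.ravel())
            fock_list.append(F.copy())
            if len(err_vecs) > diis_window:
                err_vecs.pop(0)
                fock_list.pop(0)
            m = len(err_vecs)
            if m >= 2:
                Bm = np.empty((m + 1, m + 1))
                Bm[:m, :m] = np.array([[e1 @ e2 for e2 in err_vecs] for e1 in err_vecs])
                Bm[m, :], Bm[:, m], Bm[m, m] = -1.0, -1.0, 0.0
                rhs = np.zeros(m + 1)
                rhs[m] = -1.0
                try:
                    coef = np.linalg.solve(Bm, rhs)[:m]
                    F_eff = sum(c * Fk for c, Fk in zip(coef, fock_list))
                except np.linalg.LinAlgError:
                    F_eff = F
        if level_shift > 0.0:
            # shift the current virtual space up to damp orbital swapping
            P_virt = np.eye(n) - 0.5 * D
            F_eff = F_eff + level_shift * (P_virt @ P_virt)
        eps, C = np.linalg.eigh(F_eff)
        eps, C = _fix_phases_and_order(eps, C)

    Cocc = C[:, :n_occ]
    D = 2.0 * Cocc @ Cocc.T
    F = fock_matrix(intset, D)
    e_hf = 0.5 * np.sum(D * (intset.h + F)) + intset.e_core
    # canonicalize: diagonalize occ-occ and virt-virt blocks of the final Fock
    F_mo = C.T @ F @ C
    for sl in (slice(0, n_occ), slice(n_occ, n)):
        blk = F_mo[sl, sl]
        if blk.size:
            w, U = np.linalg.eigh(0.5 * (blk + blk.T))
            w, U = _fix_phases_and_order(w, U)
            C[:, sl] = C[:, sl] @ U
    F_mo = C.T @ F @ C
    eps = np.diag(F_mo).copy()
    return SCFResult(C=C, eps=eps, F_mo=F_mo, e_hf=float(e_hf),
                     n_occ=n_occ, converged=converged, n_iter=it)


def mo_transform(intset: IntegralSet, C: np.ndarray):
    """Transform h and g to the basis given by the columns of C.

    Quarter transforms preserve the chemist-index ordering, so the result
    retains the 8-fold permutational symmetry for orthogonal real C.
    """
    n = intset.n_orb
    if C.shape != (n, n):
        raise ValueError(f"C has shape {C.shape}, expected {(n, n)}")
    h_mo = C.T @ intset.h @ C
    g_mo = np.einsum("pqrs,pi->iqrs", intset.g, C, optimize=True)
    g_mo = np.einsum("iqrs,qj->ijrs", g_mo, C, optimize=True)
    g_mo = np.einsum("ijrs,rk->ijks", g_mo, C, optimize=True)
    g_mo = np.einsum("ijks,sl->ijkl", g_mo, C, optimize=True)
    return h_mo, g_mo


def pseudo_canonicalize(F_block: np.ndarray, sym_tol: float = 1e-8):
    """Diagonalize a symmetric Fock block; deterministic order and phases.

    Returns ``(U, w)`` with eigenvector columns in ascending eigenvalue
    order, phase fixed so the largest-magnitude component is positive.
    """
    F_block = np.asarray(F_block, dtype=float)
    if F_block.ndim != 2 or F_block.shape[0] != F_block.shape[1]:
        raise ValueError("F_block must be square")
    if F_block.size and np.abs(F_block - F_block.T).max() > sym_tol:
        raise ValueError("F_block is not symmetric")
    if F_block.size == 0:
        return np.zeros((0, 0)), np.zeros(0)
    w, U = np.linalg.eigh(0.5 * (F_block + F_block.T))
    w, U = _fix_phases_and_order(w, U)
    return U, w
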