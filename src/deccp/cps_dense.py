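"""Dense determinant-space reference path for cluster perturbation theory.

Everything here works with explicit operator matrices over the Sz=0
determinant space: the Hamiltonian H, the Fock operator f, the fluctuation
potential Phi = H - f, and the singlet excitation operators theta_mu of the
singles (parent) and doubles (auxiliary) spaces.  The parent state is CCS;
for a canonical RHF reference the CCS ground-state amplitudes vanish, so
the similarity transformation of the parent state is the identity and the
extended parent Jacobian is simply the matrix of [H, theta_nu] projected
onto the biorthonormal dual basis of the singles+doubles excitation
manifold.

Two independent quantities are produced:

* the order-by-order corrections (omega0..omega3, dt(1), dt(2), R(1), R(2))
  assembled literally from the order-expansion recursions, and
* a lambda-dressed nonlinear eigenvalue problem whose exact eigenvalue,
  Taylor-expanded in the coupling lambda that scales every first-order
  block (parent-auxiliary, auxiliary-parent and auxiliary-internal
  fluctuation couplings, and the fluctuation-driven amplitude corrections),
  reproduces those corrections as its polynomial coefficients.  The second
  path never touches the recursions and serves as their oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .determinants import DetSpace, singlet_excitation_ops

__all__ = ["DenseCPWorkspace", "cp_order_corrections", "cp_lambda_eigenvalue",
           "OrderCorrections"]


@dataclass
class OrderCorrections:
    omega0: float
    omega1: float
    omega2: float
    omega3: float
    dt1: np.ndarray            # first-order amplitude corrections (full space)
    dt2: np.ndarray            # second-order amplitude corrections
    R1: np.ndarray             # first-order eigenvector correction
    R2: np.ndarray             # second-order eigenvector correction
    eps_mu: np.ndarray
    n_parent: int


class DenseCPWorkspace:
    """Operator matrices and biorthonormal projections for one system."""

    def __init__(self, h_mo: np.ndarray, g_mo: np.ndarray, eps: np.ndarray,
                 n_occ: int, max_dim: int = 2500):
        n = h_mo.shape[0]
        self.n_orb = n
        self.n_occ = n_occ
        space = DetSpace(n, n_occ, n_occ)
        if space.dim > max_dim:
            raise ValueError(f"determinant space {space.dim} exceeds {max_dim}")
        self.space = space
        from .determinants import build_hamiltonian
        self.H = build_hamiltonian(space, h_mo, g_mo, 0.0)
        eops = space.all_excitation_ops()
        f = np.zeros((space.dim, space.dim))
        for p in range(n):
            f += eps[p] * eops[(p, p)].toarray()
        self.f = f
        self.Phi = self.H - f
        self.hf = space.hf_vector()

        labels, ops = singlet_excitation_ops(space, n_occ)
        self.labels = labels
        self.ops = [op.toarray() for op in ops]
        self.n_parent = sum(1 for lab in labels if lab[0] == "s")
        self.t_dim = len(labels)
        B = np.column_stack([op @ self.hf for op in self.ops])
        self.B = B
        S = B.T @ B
        self.D = B @ np.linalg.inv(S)          # dual vectors, D^T B = I

        # excitation-level orbital-energy differences eps_mu
        eps_mu = np.empty(self.t_dim)
        for m, lab in enumerate(labels):
            if lab[0] == "s":
                _, a, i = lab
                eps_mu[m] = eps[a] - eps[i]
            else:
                _, a, i, b, j = lab
                eps_mu[m] = eps[a] + eps[b] - eps[i] - eps[j]
        self.eps_mu = eps_mu

        # M[mu, nu] = <mu~|[Phi, theta_nu]|HF>
        Phi_hf = self.Phi @ self.hf
        cols = []
        for op in self.ops:
            w = self.Phi @ (op @ self.hf) - op @ Phi_hf
            cols.append(self.D.T @ w)
        self.M = np.column_stack(cols)
        self.eta = self.D.T @ Phi_hf            # <mu~|Phi|HF>

    # -- helpers ----------------------------------------------------------

    def operator(self, coeffs: np.ndarray) -> np.ndarray:
        """sum_mu c_mu theta_mu as a dense determinant-space matrix."""
        out = np.zeros((self.space.dim, self.space.dim))
        for c, op in zip(coeffs, self.ops):
            if c != 0.0:
                out += c * op
        return out

    def project(self, vec: np.ndarray) -> np.ndarray:
        return self.D.T @ vec

    def comm_apply(self, A: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        """<mu~| [A, T(c)] |HF> for an operator matrix A."""
        T = self.operator(coeffs)
        return self.project(A @ (T @ self.hf) - T @ (A @ self.hf))

    def parent_jacobian(self) -> np.ndarray:
        p = self.n_parent
        return np.diag(self.eps_mu[:p]) + self.M[:p, :p]

    def ccs_roots(self):
        """Parent (CCS) eigenpairs with L_x . R_y = delta_xy."""
        JP = self.parent_jacobian()
        w, R = np.linalg.eig(JP)
        wl, L = np.linalg.eig(JP.T)
        order = np.argsort(w.real)
        w, R = w[order].real, R[:, order].real
        L = L[:, np.argsort(wl.real)].real
        L = L @ np.linalg.inv(L.T @ R).T
        return w, R, L


def cp_order_corrections(ws: DenseCPWorkspace, root: int = 0,
                         r2_sign: float = -1.0) -> OrderCorrections:
    """Order-by-order excitation-energy corrections through third order.

    Implements the recursion rows literally: first- and second-order
    amplitude corrections, first- and second-order right-eigenvector
    corrections (the parent-block second-order equation is solved in the
    complement of the parent root with a biorthogonality constraint), and
    the energy corrections as nested-commutator expectation values.
    ``r2_sign`` is the sign with which the [Phi, R(1)] term enters the
    auxiliary second-order eigenvector equation.
    """
    p = ws.n_parent
    t = ws.t_dim
    aux = slice(p, t)
    w, Rm, Lm = ws.ccs_roots()
    omega0 = w[root]
    Rs = Rm[:, root]
    Ls = Lm[:, root]

    # first-order amplitudes: parent components vanish, auxiliary -eta/eps
    dt1 = np.zeros(t)
    dt1[aux] = -ws.eta[aux] / ws.eps_mu[aux]

    # first-order Jacobian: the fluctuation coupling blocks, with the
    # parent-parent block excluded (it is resummed into J(0) via the step
    # functions); omega1 = L . J1_PP . R is therefore identically zero,
    # computed here from the masked matrix rather than asserted.
    J1 = ws.M.copy()
    J1[:p, :p] = 0.0
    omega1 = float(Ls @ (J1[:p, :p] @ Rs))

    # K_col(c) = <mu~|[[Phi, T(dt1)], T(c)]|HF> via commutator matrices
    T1m = ws.operator(dt1)
    C1 = ws.Phi @ T1m - T1m @ ws.Phi           # [Phi, dT1]

    def proj_comm(A, coeffs):
        T = ws.operator(coeffs)
        return ws.project(A @ (T @ ws.hf) - T @ (A @ ws.hf))

    Rs_full = np.zeros(t)
    Rs_full[:p] = Rs

    # R(1): auxiliary only
    MR = ws.M @ Rs_full                        # <mu~|[Phi, R*]|HF>
    R1 = np.zeros(t)
    R1[aux] = -MR[aux] / (ws.eps_mu[aux] - omega0)

    KR = proj_comm(C1, Rs_full)                # <mu~|[[Phi,dT1],R*]|HF>
    MR1 = ws.M @ R1                            # <mu~|[Phi, R(1)]|HF>
    omega2 = float(Ls @ (KR[:p] + MR1[:p]))

    # second-order amplitudes
    Mdt1 = ws.M @ dt1                          # <mu~|[Phi, dT1]|HF>
    dt2 = np.zeros(t)
    JP = ws.parent_jacobian()
    dt2[:p] = np.linalg.solve(JP, -Mdt1[:p])
    dt2[aux] = -Mdt1[aux] / ws.eps_mu[aux]

    # second-order eigenvector
    R2 = np.zeros(t)
    R2[aux] = (-KR[aux] + r2_sign * MR1[aux]) / (ws.eps_mu[aux] - omega0)
    # parent block: (JP - w0) R2_P = w2 R* - KR_P - MR1_P, with Ls.R2_P = 0
    A = JP - omega0 * np.eye(p)
    rhs = omega2 * Rs - KR[:p] - MR1[:p]
    # bordered system enforcing the biorthogonality constraint
    Ab = np.zeros((p + 1, p + 1))
    Ab[:p, :p] = A
    Ab[:p, p] = Rs
    Ab[p, :p] = Ls
    bb = np.zeros(p + 1)
    bb[:p] = rhs
    sol = np.linalg.solve(Ab, bb)
    R2[:p] = sol[:p]

    # third-order energy
    T2m = ws.operator(dt2)
    C2 = ws.Phi @ T2m - T2m @ ws.Phi           # [Phi, dT2]
    C11 = C1 @ T1m - T1m @ C1                  # [[Phi, dT1], dT1]
    term1 = proj_comm(C2, Rs_full)[:p]
    term2 = 0.5 * proj_comm(C11, Rs_full)[:p]
    term3 = proj_comm(C1, R1)[:p]
    # J(1) R(2): the first-order Jacobian has no parent-parent block (that
    # coupling is resummed into J(0)), so only the auxiliary part of R(2)
    # contributes here.
    R2_aux_only = R2.copy()
    R2_aux_only[:p] = 0.0
    term4 = (ws.M @ R2_aux_only)[:p]
    omega3 = float(Ls @ (term1 + term2 + term3 + term4))

    return OrderCorrections(omega0=float(omega0), omega1=omega1,
                            omega2=omega2, omega3=omega3,
                            dt1=dt1, dt2=dt2, R1=R1, R2=R2,
                            eps_mu=ws.eps_mu.copy(), n_parent=p)


# --------------------------------------------------------------------------
# lambda-dressed exact eigenvalue (oracle for the recursions)
# --------------------------------------------------------------------------

def _lambda_residual(ws: DenseCPWorkspace, dt: np.ndarray, lam: float):
    """Amplitude residual of the lambda-dressed target equations.

    Omega(dt; lam) = <mu~| e^(-dT) (f + lam Phi) e^(dT) |HF>
                     + (1 - lam) * [mu in parent] (M_PP dt_P)_mu
    The correction term keeps the parent-internal fluctuation coupling at
    zeroth order, which is what makes the parent Jacobian the unperturbed
    problem of the expansion.
    """
    p = ws.n_parent
    T = ws.operator(dt)
    U = sla.expm(T)
    Uinv = sla.expm(-T)
    Hlam = ws.f + lam * ws.Phi
    res = ws.project(Uinv @ (Hlam @ (U @ ws.hf)))
    res[:p] += (1.0 - lam) * (ws.M[:p, :p] @ dt[:p])
    return res


def _lambda_jacobian_matrix(ws: DenseCPWorkspace, dt: np.ndarray, lam: float):
    p = ws.n_parent
    T = ws.operator(dt)
    U = sla.expm(T)
    Uinv = sla.expm(-T)
    Htil = Uinv @ (ws.f + lam * ws.Phi) @ U
    Htil_hf = Htil @ ws.hf
    cols = []
    for op in ws.ops:
        w = Htil @ (op @ ws.hf) - op @ Htil_hf
        cols.append(ws.project(w))
    J = np.column_stack(cols)
    J[:p, :p] += (1.0 - lam) * ws.M[:p, :p]
    return J


def cp_lambda_eigenvalue(ws: DenseCPWorkspace, root: int, lam: float,
                         newton_tol: float = 1e-12, max_newton: int = 50):
    """Exact eigenvalue of the lambda-dressed target problem for one root.

    Solves the dressed amplitude equations by Newton iteration (finite-
    difference Jacobian), builds the dressed Jacobian at the solution, and
    follows the chosen parent root by eigenvector overlap.
    """
    t = ws.t_dim
    p = ws.n_parent
    dt = np.zeros(t)
    for _ in range(max_newton):
        res = _lambda_residual(ws, dt, lam)
        if np.abs(res).max() < newton_tol:
            break
        h = 1e-7
        Jn = np.empty((t, t))
        for k in range(t):
            d = dt.copy()
            d[k] += h
            Jn[:, k] = (_lambda_residual(ws, d, lam) - res) / h
        dt = dt - np.linalg.solve(Jn, res)
    else:
        raise RuntimeError("lambda-dressed amplitude equations did not converge")

    J = _lambda_jacobian_matrix(ws, dt, lam)
    w, V = np.linalg.eig(J)
    _, Rm, _ = ws.ccs_roots()
    ref = np.zeros(t)
    ref[:p] = Rm[:, root]
    overlaps = np.abs(ref @ V) / np.linalg.norm(V, axis=0)
    k = int(np.argmax(overlaps))
    return float(w[k].real)


def lambda_series_coefficients(ws: DenseCPWorkspace, root: int = 0,
                               lams=None, degree: int = 5):
    """Taylor coefficients of the dressed eigenvalue by polynomial fit."""
    if lams is None:
        lams = np.arange(0.02, 0.121, 0.02)
    vals = [cp_lambda_eigenvalue(ws, root, lam) for lam in lams]
    # include lambda = 0 exactly: omega0 from the parent problem
    w, _, _ = ws.ccs_roots()
    lams_all = np.concatenate([[0.0], lams])
    vals_all = np.concatenate([[w[root]], vals])
    coeffs = np.polynomial.polynomial.polyfit(lams_all, vals_all, degree)
    return coeffs
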