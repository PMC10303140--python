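"""CPS(D-2) / CPS(D-3) excitation-energy corrections (production path).

Perturbative corrections to CCS excitation energies with a CC singles
parent space and a doubles auxiliary space.  The parent Jacobian is the
zeroth-order problem; the fluctuation potential couples it to the doubles
space.  For a canonical RHF reference the corrections through third order
reduce to non-iterative tensor contractions:

    omega(1) = 0
    omega(2) = L . [ A1(gbar, vbar; t(1)) + A1(g, v; R(1)) ]
    omega(3) = L . [ A1(gbar, vbar; t(2)_d) + APP(gbar, vbar) t(2)_s
                     + A1(g, v; R(2)_aux) ]

where t(1) are first-order doubles, R(1) the first-order eigenvector
correction (built from one-index R-transformed "barred" integrals), t(2)
and R(2) the second-order quantities, and A1 / A2 / APP the singles- and
doubles-space projections of the commutator of the (dressed) fluctuation
potential with a doubles or singles excitation operator.  The second-order
correction is equivalent to CIS(D).

Heavy contractions stream over batches of a virtual orbital index in two
passes (an amplitude pass for t(2), an eigenvector pass for R(2)), and all
two-electron tensors can be consumed through three-index Cholesky fitting
coefficients, so no all-virtual four-index block needs to be resident.
Every formula is validated against the dense determinant-space reference
in :mod:`deccp.cps_dense`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cc import ExcitationResult, ccs_excitations
from .cps_dense import DenseCPWorkspace, OrderCorrections, cp_order_corrections
from .integrals import IntegralSet
from .scf import mo_transform, run_rhf

__all__ = ["FittingCoefficients", "CPSResult", "cholesky_fit",
           "cps_omega2", "cps_omega3", "cps_dense_reference", "cps_driver",
           "one_index_transformed", "transformed_onebody"]


class DegenerateRootError(RuntimeError):
    """A doubles denominator (eps_mu - omega) vanished for this root."""


@dataclass
class FittingCoefficients:
    """Three-index factors B[p, q, P] with (pq|rs) = sum_P B[pq,P] B[rs,P]."""
    B: np.ndarray
    n_aux: int
    recon_error: float

    def reconstruct(self) -> np.ndarray:
        n = self.B.shape[0]
        M = self.B.reshape(n * n, self.n_aux)
        return (M @ M.T).reshape(n, n, n, n)


@dataclass
class CPSResult:
    omegas_ccs: np.ndarray
    omega2: np.ndarray
    omega3: np.ndarray
    order: int
    n_roots: int
    clipped: bool = False

    @property
    def totals(self):
        tot = self.omegas_ccs + self.omega2
        if self.order >= 3:
            tot = tot + self.omega3
        return tot


def cholesky_fit(g_mo: np.ndarray, tol: float = 1e-8) -> FittingCoefficients:
    """Pivoted Cholesky factorization of the pair-index integral matrix.

    Realizes the resolution-of-identity structure (pq|rs) = sum_P B^P_pq
    B^P_rs without an external auxiliary basis: the auxiliary vectors are
    the pivoted Cholesky factors of the positive-semidefinite pair matrix.
    Factorization stops when the residual diagonal drops below ``tol``.
    """
    n = g_mo.shape[0]
    G = g_mo.reshape(n * n, n * n).copy()
    d = np.diag(G).copy()
    if d.min() < -1e-10:
        raise ValueError(f"pair matrix not PSD: diagonal minimum {d.min():.3e} "
                         f"at pivot {int(np.argmin(d))}")
    npair = n * n
    L = np.zeros((npair, npair))
    k = 0
    while k < npair:
        j = int(np.argmax(d))
        if d[j] <= tol:
            break
        Ljj = np.sqrt(d[j])
        col = (G[:, j] - L[:, :k] @ L[j, :k]) / Ljj
        col[j] = Ljj
        L[:, k] = col
        d = d - col ** 2
        d[j] = 0.0
        np.clip(d, 0.0, None, out=d)
        k += 1
    B = L[:, :k].reshape(n, n, k)
    B = 0.5 * (B + B.transpose(1, 0, 2))
    M = B.reshape(npair, k)
    recon = (M @ M.T).reshape(n, n, n, n)
    err = float(np.abs(recon - g_mo).max())
    return FittingCoefficients(B=B, n_aux=k, recon_error=err)


# --------------------------------------------------------------------------
# dressed tensors
# --------------------------------------------------------------------------

def one_index_transformed(g_mo: np.ndarray, R: np.ndarray, n_occ: int):
    """Barred integrals: g one-index transformed by a singles vector R[a,i].

    In the orthonormal basis the transformation vectors reduce to
    "replace a virtual index by -R times an occupied one" on bra-left /
    ket-left positions, and "replace an occupied index by +R times a
    virtual one" on bra-right / ket-right positions.  The result keeps the
    (pq) <-> (rs) pair-swap symmetry but not the within-pair symmetries.
    """
    n = g_mo.shape[0]
    o, v = slice(0, n_occ), slice(n_occ, n)
    gb = np.zeros_like(g_mo)
    gb[v, :, :, :] += -np.einsum("ak,kqrs->aqrs", R, g_mo[o, :, :, :], optimize=True)
    gb[:, o, :, :] += np.einsum("ci,pcrs->pirs", R, g_mo[:, v, :, :], optimize=True)
    gb[:, :, v, :] += -np.einsum("ak,pqks->pqas", R, g_mo[:, :, o, :], optimize=True)
    gb[:, :, :, o] += np.einsum("ci,pqrc->pqri", R, g_mo[:, :, :, v], optimize=True)
    return gb


def _transform_B(B: np.ndarray, R: np.ndarray, n_occ: int):
    """One-index transform of Cholesky factors: Bbar with
    (pq|~rs) = sum_P [Bbar_pq B_rs + B_pq Bbar_rs]."""
    n = B.shape[0]
    o, v = slice(0, n_occ), slice(n_occ, n)
    Bb = np.zeros_like(B)
    Bb[v, :, :] += -np.einsum("ak,kqP->aqP", R, B[o, :, :], optimize=True)
    Bb[:, o, :] += np.einsum("ci,pcP->piP", R, B[:, v, :], optimize=True)
    return Bb


def _hf_potential(g_mo: np.ndarray, n_occ: int) -> np.ndarray:
    """Mean-field potential v[p,q] = sum_k [2 (pq|kk) - (pk|kq)]."""
    o = slice(0, n_occ)
    return (2.0 * np.einsum("pqkk->pq", g_mo[:, :, o, o])
            - np.einsum("pkkq->pq", g_mo[:, o, o, :]))


def transformed_onebody(g_mo: np.ndarray, R: np.ndarray, n_occ: int):
    """One-body part of the R-transformed fluctuation potential, -[v_HF, r]."""
    n = g_mo.shape[0]
    vhf = _hf_potential(g_mo, n_occ)
    Rfull = np.zeros((n, n))
    Rfull[n_occ:, :n_occ] = R
    return -(vhf @ Rfull - Rfull @ vhf)


class TensorSet:
    """Block access to a (possibly dressed) two-electron tensor.

    Backed either by a dense tensor or by Cholesky factors.  For dressed
    tensors in factorized form the representation is
    (pq|~rs) = sum_P [Bbar_pq B_rs + B_pq Bbar_rs], preserving the
    sum-of-products structure of the fitting approximation.  ``vp`` is the
    accompanying one-particle operator (zero for the bare fluctuation
    potential in a canonical basis; -[v_HF, r] for the R-transformed one).
    """

    def __init__(self, n_occ: int, n_orb: int, vp: np.ndarray = None,
                 dense: np.ndarray = None, B: np.ndarray = None,
                 Bbar: np.ndarray = None):
        self.n_occ = n_occ
        self.n_orb = n_orb
        self.dense = dense
        self.B = B
        self.Bbar = Bbar
        self.vp = vp if vp is not None else np.zeros((n_orb, n_orb))
        self._meff = None

    def _idx(self, c, batch):
        if c == "o":
            return np.arange(0, self.n_occ)
        if c == "v":
            return np.arange(self.n_occ, self.n_orb)
        if c == "B":
            return np.asarray(batch)
        raise ValueError(c)

    def block(self, spec: str, batch=None) -> np.ndarray:
        """Integral block for spec like 'vvoo' or 'Bvoo' (B = batched virt)."""
        idx = [self._idx(c, batch) for c in spec]
        if self.dense is not None:
            return self.dense[np.ix_(*idx)]
        B1 = self.B[np.ix_(idx[0], idx[1])]
        B2 = self.B[np.ix_(idx[2], idx[3])]
        if self.Bbar is None:
            return np.einsum("pqP,rsP->pqrs", B1, B2, optimize=True)
        Bb1 = self.Bbar[np.ix_(idx[0], idx[1])]
        Bb2 = self.Bbar[np.ix_(idx[2], idx[3])]
        return (np.einsum("pqP,rsP->pqrs", Bb1, B2, optimize=True)
                + np.einsum("pqP,rsP->pqrs", B1, Bb2, optimize=True))

    def meff(self) -> np.ndarray:
        """Effective one-particle dressing v' + 2 J(g') - K(g').

        Vanishes identically for the bare fluctuation potential of a
        canonical reference; finite for dressed tensors.
        """
        if self._meff is None:
            no, n = self.n_occ, self.n_orb
            o = slice(0, no)
            if self.dense is not None:
                J = np.einsum("pqkk->pq", self.dense[:, :, o, o])
                K = np.einsum("pkkq->pq", self.dense[:, o, o, :])
            else:
                def JK(Ba, Bb):
                    j = np.einsum("pqP,kkP->pq", Ba, Bb[o, o], optimize=True)
                    k = np.einsum("pkP,kqP->pq", Ba[:, o], Bb[o, :], optimize=True)
                    return j, k
                J, K = JK(self.B, self.B)
                if self.Bbar is not None:
                    J1, K1 = JK(self.Bbar, self.B)
                    J2, K2 = JK(self.B, self.Bbar)
                    J, K = J1 + J2, K1 + K2
            self._meff = self.vp + 2.0 * J - K
        return self._meff


def _tensorsets(g_mo, n_occ, fit: FittingCoefficients = None, R=None):
    """Bare and (optionally) R-dressed tensor sets."""
    n = g_mo.shape[0]
    if fit is not None:
        bare = TensorSet(n_occ, n, B=fit.B)
        # mean-field potential from the factorized integrals
        vhf = (2.0 * np.einsum("pqP,kkP->pq", fit.B,
                               fit.B[:n_occ, :n_occ], optimize=True)
               - np.einsum("pkP,kqP->pq", fit.B[:, :n_occ],
                           fit.B[:n_occ, :], optimize=True))
        bare.vp = -vhf
        if R is None:
            return bare
        Bbar = _transform_B(fit.B, R, n_occ)
        r_full = _embed_r(R, n, n_occ)
        dressed = TensorSet(n_occ, n, vp=-(vhf @ r_full - r_full @ vhf),
                            B=fit.B, Bbar=Bbar)
        return bare, dressed
    bare = TensorSet(n_occ, n, dense=g_mo)
    bare.vp = -_hf_potential(g_mo, n_occ)
    if R is None:
        return bare
    gbar = one_index_transformed(g_mo, R, n_occ)
    dressed = TensorSet(n_occ, n, dense=gbar,
                        vp=transformed_onebody(g_mo, R, n_occ))
    return bare, dressed


def _embed_r(R, n, n_occ):
    r_full = np.zeros((n, n))
    r_full[n_occ:, :n_occ] = R
    return r_full


# --------------------------------------------------------------------------
# projection transforms (coefficients fixed against the dense reference)
# --------------------------------------------------------------------------

def _lin_doubles_raw(ts: TensorSet, u: np.ndarray, bat, first: bool):
    """Unsymmetrized doubles transform, output rows restricted to a batch of
    the first (``first=True``) or second pair's virtual index."""
    no, n = ts.n_occ, ts.n_orb
    o, v = slice(0, no), slice(no, n)
    M = ts.meff()
    rel = np.asarray(bat) - no
    if first:
        X = np.einsum("acbd,icjd->iajb", ts.block("Bvvv", bat), u, optimize=True)
        X += np.einsum("kilj,kalb->iajb", ts.block("oooo"), u[:, rel], optimize=True)
        X += 4.0 * np.einsum("aikc,kcjb->iajb", ts.block("Boov", bat), u, optimize=True)
        X -= 2.0 * np.einsum("aikc,jckb->iajb", ts.block("Boov", bat), u, optimize=True)
        X -= 2.0 * np.einsum("acki,kcjb->iajb", ts.block("Bvoo", bat), u, optimize=True)
        X -= 2.0 * np.einsum("ackj,ickb->iajb", ts.block("Bvoo", bat), u, optimize=True)
        X += 2.0 * np.einsum("ac,icjb->iajb", M[np.ix_(bat, np.arange(no, n))],
                             u, optimize=True)
        X -= 2.0 * np.einsum("ki,kajb->iajb", M[o, o], u[:, rel], optimize=True)
    else:
        us = u[:, :, :, rel]
        X = np.einsum("acbd,icjd->iajb", ts.block("vvBv", bat), u, optimize=True)
        X += np.einsum("kilj,kalb->iajb", ts.block("oooo"), us, optimize=True)
        X += 4.0 * np.einsum("aikc,kcjb->iajb", ts.block("voov"), us, optimize=True)
        X -= 2.0 * np.einsum("aikc,jckb->iajb", ts.block("voov"), us, optimize=True)
        X -= 2.0 * np.einsum("acki,kcjb->iajb", ts.block("vvoo"), us, optimize=True)
        X -= 2.0 * np.einsum("ackj,ickb->iajb", ts.block("vvoo"), us, optimize=True)
        X += 2.0 * np.einsum("ac,icjb->iajb", M[v, v], us, optimize=True)
        X -= 2.0 * np.einsum("ki,kajb->iajb", M[o, o], us, optimize=True)
    return X


def lin_doubles(ts: TensorSet, u: np.ndarray, batch=None) -> np.ndarray:
    """Doubles projection X[i,a,j,b] = <(aibj)~|[W(g') + V(v'), T2(u)]|HF>.

    ``u[i,a,j,b]`` is a covariant doubles tensor symmetric under
    (ia) <-> (jb).  With ``batch`` (absolute virtual indices) only the
    output rows whose first virtual index lies in the batch are formed.
    """
    bat = np.asarray(batch) if batch is not None else np.arange(ts.n_occ, ts.n_orb)
    Xf = _lin_doubles_raw(ts, u, bat, first=True)       # [i, bat, j, b]
    Xs = _lin_doubles_raw(ts, u, bat, first=False)      # [i, a, j, bat]
    return 0.5 * (Xf + Xs.transpose(2, 3, 0, 1))


def lin_singles(ts: TensorSet, u: np.ndarray) -> np.ndarray:
    """Singles projection y[i,a] = <(ai)~|[W(g') + V(v'), T2(u)]|HF>."""
    no, n = ts.n_occ, ts.n_orb
    o, v = slice(0, no), slice(no, n)
    y = 2.0 * np.einsum("acdk,ickd->ia", ts.block("vvvo"), u, optimize=True)
    y -= np.einsum("adkc,ickd->ia", ts.block("vvov"), u, optimize=True)
    y -= 2.0 * np.einsum("cadk,ickd->ia", ts.block("vvvo"), u, optimize=True)
    y += 2.0 * np.einsum("cakd,ickd->ia", ts.block("vvov"), u, optimize=True)
    y += 2.0 * np.einsum("ikcl,kalc->ia", ts.block("oovo"), u, optimize=True)
    y -= 2.0 * np.einsum("iklc,kalc->ia", ts.block("ooov"), u, optimize=True)
    y -= 2.0 * np.einsum("kicl,kalc->ia", ts.block("oovo"), u, optimize=True)
    y += np.einsum("likc,kalc->ia", ts.block("ooov"), u, optimize=True)
    M = ts.meff()
    y -= np.einsum("kc,icka->ia", M[o, v], u, optimize=True)
    y += 2.0 * np.einsum("kc,iakc->ia", M[o, v], u, optimize=True)
    return y


def singles_block(ts: TensorSet) -> np.ndarray:
    """Singles-singles block A'[(ai),(bj)] = <(ai)~|[W + V, E_bj]|HF> in
    (a, i)-major matrix layout.  For the bare fluctuation potential this is
    the CCS Jacobian minus its orbital-energy diagonal."""
    no, n = ts.n_occ, ts.n_orb
    o, v = slice(0, no), slice(no, n)
    nv = n - no
    T = 2.0 * np.einsum("aibj->iajb", ts.block("vovo"))
    T += 2.0 * np.einsum("iajb->iajb", ts.block("ovov"))
    T -= 2.0 * np.einsum("iabj->iajb", ts.block("ovvo"))
    T -= np.einsum("abji->iajb", ts.block("vvoo"))
    M = ts.meff()
    T += np.einsum("ab,ij->iajb", M[v, v], np.eye(no))
    T -= np.einsum("ji,ab->iajb", M[o, o], np.eye(nv))
    return T.transpose(1, 0, 3, 2).reshape(no * nv, no * nv)


# --------------------------------------------------------------------------
# order corrections, production path
# --------------------------------------------------------------------------

def _batches(n_occ, n_orb, batch_size):
    virt = np.arange(n_occ, n_orb)
    if batch_size is None or batch_size <= 0 or batch_size >= len(virt):
        return [virt]
    return [virt[k:k + batch_size] for k in range(0, len(virt), batch_size)]


def _root_quantities(ccs: ExcitationResult, root: int, g_mo, eps, n_occ,
                     fit: FittingCoefficients = None):
    n = g_mo.shape[0]
    no, nv = n_occ, n - n_occ
    o, v = slice(0, no), slice(no, n)
    om0 = float(ccs.omegas[root])
    Rvec = ccs.R[:, root]
    Lvec = ccs.L[:, root]
    Rm = Rvec.reshape(nv, no)
    bare, dressed = _tensorsets(g_mo, no, fit=fit, R=Rm)
    Dt = (eps[o][:, None, None, None] - eps[v][None, :, None, None]
          + eps[o][None, None, :, None] - eps[v][None, None, None, :])
    if np.abs(Dt + om0).min() < 1e-8:
        raise DegenerateRootError(
            f"root {root}: vanishing doubles denominator eps - omega")
    dt1 = bare.block("vovo").transpose(1, 0, 3, 2) / Dt
    etabar = dressed.block("vovo").transpose(1, 0, 3, 2)
    R1 = etabar / (Dt + om0)
    return bare, dressed, om0, Rvec, Lvec, Dt, dt1, R1


def cps_omega2(ccs: ExcitationResult, root: int, g_mo: np.ndarray,
               eps: np.ndarray, n_occ: int,
               fit: FittingCoefficients = None) -> float:
    """Second-order (CIS(D)-equivalent) correction for one CCS root."""
    bare, dressed, om0, Rvec, Lvec, Dt, dt1, R1 = _root_quantities(
        ccs, root, g_mo, eps, n_occ, fit)
    y = lin_singles(dressed, dt1) + lin_singles(bare, R1)
    return float(Lvec @ y.T.ravel())


def cps_omega3(ccs: ExcitationResult, root: int, g_mo: np.ndarray,
               eps: np.ndarray, n_occ: int, batch_size: int = 0,
               fit: FittingCoefficients = None) -> float:
    """Third-order correction for one CCS root, batched over a virtual index.

    Two passes: an amplitude pass accumulating the second-order doubles
    t(2) contribution, and an eigenvector pass accumulating the
    second-order eigenvector R(2) contribution; each pass streams batches
    of the leading virtual index of the doubles-space intermediates.
    """
    n = g_mo.shape[0]
    no, nv = n_occ, n - n_occ
    bare, dressed, om0, Rvec, Lvec, Dt, dt1, R1 = _root_quantities(
        ccs, root, g_mo, eps, n_occ, fit)
    eps_s = np.repeat(eps[no:], no) - np.tile(eps[:no], nv)
    JP = np.diag(eps_s) + singles_block(bare)

    # second-order singles amplitudes (parent-space linear equation)
    y1 = lin_singles(bare, dt1)
    dt2s = np.linalg.solve(JP, -y1.T.ravel())

    omega3 = 0.0
    batches = _batches(no, n, batch_size)
    # ---- pass 1: amplitude (t) pass
    for bat in batches:
        rel = bat - no
        Xt = lin_doubles(bare, dt1, batch=bat)          # [i, bat, j, b]
        dt2_batch = Xt / Dt[:, rel, :, :]
        omega3 += float(Lvec @ lin_singles(
            dressed, _embed(dt2_batch, rel, no, nv)).T.ravel())
    # singles part of t(2) (cheap, unbatched)
    omega3 += float(Lvec @ (singles_block(dressed) @ dt2s))
    # ---- pass 2: eigenvector (R) pass
    for bat in batches:
        rel = bat - no
        KR = lin_doubles(dressed, dt1, batch=bat)
        MR1 = lin_doubles(bare, R1, batch=bat)
        R2_batch = (KR + MR1) / (Dt[:, rel, :, :] + om0)
        omega3 += float(Lvec @ lin_singles(
            bare, _embed(R2_batch, rel, no, nv)).T.ravel())
    return omega3


def _embed(batch_tensor, rel, no, nv):
    """Embed a first-virtual-batched [i, bat, j, b] block into a full
    [i, a, j, b] tensor (contributions are linear in the doubles argument,
    so batch sums reproduce the unbatched contraction exactly)."""
    full = np.zeros((no, nv, no, nv))
    full[:, rel, :, :] = batch_tensor
    return full


def cps_dense_reference(g_mo: np.ndarray, eps: np.ndarray, n_occ: int,
                        root: int = 0, max_dim: int = 2500) -> OrderCorrections:
    """Dense determinant-space order corrections (desk-scale oracle).

    The one-electron Hamiltonian is reconstructed from the canonical
    orbital energies, h = diag(eps) - v_HF, which holds for any converged
    RHF solution in its own MO basis.
    """
    h_mo = np.diag(eps) - _hf_potential(g_mo, n_occ)
    ws = DenseCPWorkspace(h_mo, g_mo, eps, n_occ, max_dim=max_dim)
    return cp_order_corrections(ws, root=root)


def cps_driver(intset: IntegralSet, n_roots: int = 3, order: int = 3,
               batch_size: int = 0, use_fit: bool = False,
               fit_tol: float = 1e-8, scf_tol: float = 1e-10) -> CPSResult:
    """RHF -> CCS -> per-root CPS(D-2)/CPS(D-3) corrections."""
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    scf = run_rhf(intset, conv_tol=scf_tol)
    _, g_mo = mo_transform(intset, scf.C)
    no = scf.n_occ
    nv = intset.n_orb - no
    dim = no * nv
    clipped = False
    if n_roots > dim:
        n_roots = dim
        clipped = True
    ccs = ccs_excitations(g_mo, np.diag(scf.eps), no)
    fit = cholesky_fit(g_mo, tol=fit_tol) if use_fit else None
    w2 = np.zeros(n_roots)
    w3 = np.zeros(n_roots)
    for x in range(n_roots):
        w2[x] = cps_omega2(ccs, x, g_mo, scf.eps, no, fit=fit)
        if order >= 3:
            w3[x] = cps_omega3(ccs, x, g_mo, scf.eps, no,
                               batch_size=batch_size, fit=fit)
    return CPSResult(omegas_ccs=ccs.omegas[:n_roots].copy(), omega2=w2,
                     omega3=w3, order=order, n_roots=n_roots, clipped=clipped)
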