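"""Determinant-space operator algebra.

This module is the package's brute-force oracle foundation: it builds
explicit (sparse) matrix representations of second-quantized operators over
Slater-determinant bases with fixed (n_alpha, n_beta).  Everything else
that claims exactness at desk scale -- full CI, the dense cluster-
perturbation reference path, the lambda-series expansions -- reduces to
linear algebra over these matrices.

Determinants are stored as pairs of occupation bitmasks ``(alpha, beta)``
with the fermion ordering "all alpha spin-orbitals first, then all beta".
With that ordering a same-spin single excitation only picks up parity from
its own spin string.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse as sp

__all__ = ["DetSpace", "build_hamiltonian", "spin_squared", "singlet_excitation_ops"]


def _bit_count_below(bits: int, p: int) -> int:
    return bin(bits & ((1 << p) - 1)).count("1")


class DetSpace:
    """All Slater determinants with given electron counts per spin."""

    def __init__(self, n_orb: int, n_alpha: int, n_beta: int):
        self.n_orb = n_orb
        self.n_alpha = n_alpha
        self.n_beta = n_beta
        self.alpha_strings = [self._bits(c) for c in combinations(range(n_orb), n_alpha)]
        self.beta_strings = [self._bits(c) for c in combinations(range(n_orb), n_beta)]
        self.dets = [(a, b) for a in self.alpha_strings for b in self.beta_strings]
        self.index = {d: i for i, d in enumerate(self.dets)}

    @staticmethod
    def _bits(occ) -> int:
        bits = 0
        for p in occ:
            bits |= 1 << p
        return bits

    @property
    def dim(self) -> int:
        return len(self.dets)

    def hf_index(self) -> int:
        """Index of the Aufbau determinant (lowest orbitals occupied)."""
        a = self._bits(range(self.n_alpha))
        b = self._bits(range(self.n_beta))
        return self.index[(a, b)]

    def hf_vector(self) -> np.ndarray:
        v = np.zeros(self.dim)
        v[self.hf_index()] = 1.0
        return v

    def excitation_op(self, p: int, q: int) -> sp.csr_matrix:
        """Spin-summed singlet excitation operator E_pq = sum_s a+_ps a_qs."""
        rows, cols, vals = [], [], []
        for j, (a, b) in enumerate(self.dets):
            # alpha branch
            if (a >> q) & 1:
                a1 = a & ~(1 << q)
                if not (a1 >> p) & 1:
                    sign = (-1) ** (_bit_count_below(a, q) + _bit_count_below(a1, p))
                    rows.append(self.index[(a1 | (1 << p), b)])
                    cols.append(j)
                    vals.append(float(sign))
            # beta branch
            if (b >> q) & 1:
                b1 = b & ~(1 << q)
                if not (b1 >> p) & 1:
                    sign = (-1) ** (_bit_count_below(b, q) + _bit_count_below(b1, p))
                    rows.append(self.index[(a, b1 | (1 << p))])
                    cols.append(j)
                    vals.append(float(sign))
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.dim, self.dim))

    def all_excitation_ops(self):
        """Cache of all E_pq operators as a dict {(p, q): csr}."""
        if not hasattr(self, "_eops"):
            self._eops = {(p, q): self.excitation_op(p, q)
                          for p in range(self.n_orb) for q in range(self.n_orb)}
        return self._eops

    def raise_sz_op(self, target: "DetSpace") -> sp.csr_matrix:
        """S_+ = sum_p a+_pa a_pb mapping this space into ``target``."""
        rows, cols, vals = [], [], []
        for j, (a, b) in enumerate(self.dets):
            for p in range(self.n_orb):
                if (b >> p) & 1 and not (a >> p) & 1:
                    b1 = b & ~(1 << p)
                    sign = (-1) ** (self.n_alpha + _bit_count_below(b, p)
                                    + _bit_count_below(a, p))
                    rows.append(target.index[(a | (1 << p), b1)])
                    cols.append(j)
                    vals.append(float(sign))
        return sp.csr_matrix((vals, (rows, cols)), shape=(target.dim, self.dim))


def build_hamiltonian(space: DetSpace, h: np.ndarray, g: np.ndarray,
                      e_core: float = 0.0) -> np.ndarray:
    """Dense Hamiltonian over the determinant space.

    H = e_core + sum_pq h_pq E_pq + 1/2 sum_pqrs (pq|rs) (E_pq E_rs - d_qr E_ps)
    with g in chemist notation.
    """
    n = space.n_orb
    eops = space.all_excitation_ops()
    # effective one-body part folds in the -1/2 d_qr E_ps contraction
    h_eff = h - 0.5 * np.einsum("pqqs->ps", g)
    H = sp.csr_matrix((space.dim, space.dim))
    for p in range(n):
        for q in range(n):
            if h_eff[p, q] != 0.0:
                H = H + h_eff[p, q] * eops[(p, q)]
    for r in range(n):
        for s in range(n):
            grs = g[:, :, r, s]
            if not np.any(grs):
                continue
            A = sp.csr_matrix((space.dim, space.dim))
            for p in range(n):
                for q in range(n):
                    if grs[p, q] != 0.0:
                        A = A + grs[p, q] * eops[(p, q)]
            H = H + 0.5 * (A @ eops[(r, s)])
    H = H.toarray()
    if e_core:
        H = H + e_core * np.eye(space.dim)
    return H


def spin_squared(space: DetSpace) -> np.ndarray:
    """Dense S^2 matrix over a determinant space (hartree-free units)."""
    if space.n_alpha < space.n_orb and space.n_beta > 0:
        up = DetSpace(space.n_orb, space.n_alpha + 1, space.n_beta - 1)
        Sp = space.raise_sz_op(up)
        SmSp = (Sp.T @ Sp).toarray()
    else:
        SmSp = np.zeros((space.dim, space.dim))
    sz = 0.5 * (space.n_alpha - space.n_beta)
    return SmSp + sz * (sz + 1.0) * np.eye(space.dim)


def singlet_excitation_ops(space: DetSpace, n_occ: int):
    """Singlet singles and doubles excitation operators over ``space``.

    Returns ``(labels, ops)`` where singles come first as ``("s", a, i)``
    with E_ai, followed by unique doubles ``("d", a, i, b, j)`` with
    E_ai E_bj for composite pair index (a,i) <= (b,j).  Orbital indices are
    global (occupied 0..n_occ-1, virtual n_occ..n_orb-1).
    """
    n = space.n_orb
    eops = space.all_excitation_ops()
    labels, ops = [], []
    singles = [(a, i) for i in range(n_occ) for a in range(n_occ, n)]
    for (a, i) in singles:
        labels.append(("s", a, i))
        ops.append(eops[(a, i)])
    for idx1, (a, i) in enumerate(singles):
        for idx2, (b, j) in enumerate(singles):
            if idx2 < idx1:
                continue
            labels.append(("d", a, i, b, j))
            ops.append(eops[(a, i)] @ eops[(b, j)])
    return labels, ops
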