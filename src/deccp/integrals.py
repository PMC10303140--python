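"""Model systems and integral file I/O.

All Hamiltonians live in an orthonormal orbital basis.  Two-electron
integrals are stored in chemist (Mulliken) notation, ``g[p, q, r, s] =
(pq|rs)``, with the full 8-fold permutational symmetry.  Site coordinates
(in angstrom) ride alongside the integrals so that spatial-locality driven
methods (orbital assignment, fragment expansion, pair screening) can be
exercised on synthetic systems without any external data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "IntegralSet",
    "read_fcidump",
    "write_fcidump",
    "make_hubbard_chain",
    "make_localized_random",
]


class FCIDumpError(ValueError):
    """Raised when an FCIDUMP file cannot be parsed."""


@dataclass
class IntegralSet:
    """One- and two-electron integrals of a closed-shell model system.

    Attributes
    ----------
    n_orb : int
        Number of spatial orbitals.
    n_elec : int
        Number of electrons (must be even; closed-shell singlet only).
    e_core : float
        Scalar core energy in hartree.
    h : (n_orb, n_orb) ndarray
        Symmetric one-electron integrals, hartree.
    g : (n_orb,) * 4 ndarray
        Two-electron integrals ``(pq|rs)`` in chemist notation, hartree.
    sites : (n_sites, 3) ndarray
        Site coordinates in angstrom.
    orbital_positions : (n_orb, 3) ndarray
        Charge-center coordinate of each basis orbital, angstrom.
    """

    n_orb: int
    n_elec: int
    e_core: float
    h: np.ndarray
    g: np.ndarray
    sites: np.ndarray = field(default=None)
    orbital_positions: np.ndarray = field(default=None)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.sites is None:
            self.sites = np.zeros((1, 3))
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if self.orbital_positions is None:
            self.orbital_positions = np.zeros((self.n_orb, 3))
        self.orbital_positions = np.atleast_2d(
            np.asarray(self.orbital_positions, dtype=float))
        self.validate()

    def validate(self, tol: float = 1e-8):
        n = self.n_orb
        if self.h.shape != (n, n):
            raise ValueError(f"h has shape {self.h.shape}, expected {(n, n)}")
        if self.g.shape != (n, n, n, n):
            raise ValueError(f"g has shape {self.g.shape}, expected rank-4 {n}")
        if self.n_elec % 2 != 0:
            raise ValueError("only closed-shell (even electron) systems are supported")
        if not (0 <= self.n_elec <= 2 * n):
            raise ValueError(f"n_elec={self.n_elec} out of range for {n} orbitals")
        if not np.allclose(self.h, self.h.T, atol=tol):
            raise ValueError("h is not symmetric")
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(self.g, self.g.transpose(perm), atol=tol):
                raise ValueError(f"g violates permutational symmetry {perm}")

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    def pair_matrix(self) -> np.ndarray:
        """g viewed as a symmetric matrix over composite pair indices (pq),(rs)."""
        n = self.n_orb
        return self.g.reshape(n * n, n * n)

    def min_pair_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.pair_matrix())[0])

    def copy(self) -> "IntegralSet":
        return IntegralSet(self.n_orb, self.n_elec, self.e_core,
                           self.h.copy(), self.g.copy(),
                           self.sites.copy(), self.orbital_positions.copy())


def _symmetrize_g_entry(g: np.ndarray, i: int, j: int, k: int, l: int, val: float):
    for (a, b, c, d) in {(i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
                         (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i)}:
        g[a, b, c, d] = val


def read_fcidump(path, sites=None) -> IntegralSet:
    """Read an FCIDUMP file (namelist header, 1-based value-index records).

    Parameters
    ----------
    path : path-like
        FCIDUMP file.  Records ``value i j k l`` carry two-electron integrals
        ``(ij|kl)``; ``k = l = 0`` marks a one-electron element; all indices
        zero marks the core energy.
    sites : path-like, optional
        Sidecar with one ``x y z`` line (angstrom) per site.  When absent,
        each orbital is placed on its own site on a 1 angstrom spaced line.
    """
    path = Path(path)
    text = path.read_text()
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, flags=re.S | re.I)
    if m is None:
        raise FCIDumpError(f"{path}: missing &FCI ... &END namelist header")
    header = m.group(1)

    def _get(key, default=None):
        km = re.search(rf"{key}\s*=\s*([0-9+-]+)", header, flags=re.I)
        if km is None:
            if default is None:
                raise FCIDumpError(f"{path}: header lacks {key}")
            return default
        return int(km.group(1))

    n_orb = _get("NORB")
    n_elec = _get("NELEC")
    if n_elec % 2:
        raise ValueError(f"{path}: odd electron count {n_elec} is unsupported")

    body = text[m.end():]
    h = np.zeros((n_orb, n_orb))
    g = np.zeros((n_orb, n_orb, n_orb, n_orb))
    e_core = 0.0
    for lineno, line in enumerate(body.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FCIDumpError(f"{path}: malformed record on body line {lineno}: {line!r}")
        try:
            val = float(parts[0])
            i, j, k, l = (int(p) for p in parts[1:])
        except ValueError as exc:
            raise FCIDumpError(f"{path}: unparsable record on body line {lineno}: {line!r}") from exc
        for idx in (i, j, k, l):
            if idx < 0 or idx > n_orb:
                raise FCIDumpError(
                    f"{path}: index {idx} out of range 1..{n_orb} on body line {lineno}")
        if i == j == k == l == 0:
            e_core = val
        elif k == l == 0:
            if i == 0 or j == 0:
                raise FCIDumpError(f"{path}: bad one-electron record on body line {lineno}")
            h[i - 1, j - 1] = val
            h[j - 1, i - 1] = val
        else:
            if min(i, j, k, l) == 0:
                raise FCIDumpError(f"{path}: bad two-electron record on body line {lineno}")
            _symmetrize_g_entry(g, i - 1, j - 1, k - 1, l - 1, val)

    if sites is not None:
        coords = np.loadtxt(sites, ndmin=2)
        if coords.shape[1] != 3:
            raise FCIDumpError(f"{sites}: sidecar must have three columns")
        site_arr = coords
        # one orbital per site when counts match, else spread evenly
        if site_arr.shape[0] == n_orb:
            orb_pos = site_arr.copy()
        else:
            reps = int(np.ceil(n_orb / site_arr.shape[0]))
            orb_pos = np.repeat(site_arr, reps, axis=0)[:n_orb]
    else:
        site_arr = np.column_stack([np.arange(n_orb, dtype=float),
                                    np.zeros(n_orb), np.zeros(n_orb)])
        orb_pos = site_arr.copy()
    return IntegralSet(n_orb, n_elec, e_core, h, g, site_arr, orb_pos)


def write_fcidump(intset: IntegralSet, path, sites_path=None, thresh: float = 1e-12):
    """Write a canonical FCIDUMP (symmetry-unique records only).

    Two-electron records come first, then one-electron records, then the
    core energy.  ``sites_path`` optionally writes the coordinate sidecar.
    """
    intset.validate()
    n = intset.n_orb
    lines = [f"&FCI NORB={n}, NELEC={intset.n_elec}, MS2=0,",
             " ORBSYM=" + ",".join(["1"] * n) + ",",
             " ISYM=1,",
             "&END"]
    seen = set()
    for p in range(n):
        for q in range(p + 1):
            for r in range(p + 1):
                smax = r if r < p else q
                for s in range(smax + 1):
                    key = (p, q, r, s)
                    if key in seen:
                        continue
                    seen.add(key)
                    val = intset.g[p, q, r, s]
                    if abs(val) > thresh:
                        lines.append(f"{val: .16e} {p+1:d} {q+1:d} {r+1:d} {s+1:d}")
    for p in range(n):
        for q in range(p + 1):
            val = intset.h[p, q]
            if abs(val) > thresh:
                lines.append(f"{val: .16e} {p+1:d} {q+1:d} 0 0")
    lines.append(f"{intset.e_core: .16e} 0 0 0 0")
    Path(path).write_text("\n".join(lines) + "\n")
    if sites_path is not None:
        site_lines = [f"{x: .12f} {y: .12f} {z: .12f}" for x, y, z in intset.sites]
        Path(sites_path).write_text("\n".join(site_lines) + "\n")


def make_hubbard_chain(n_sites: int, n_elec: int, t: float = 1.0, U: float = 4.0,
                       spacing: float = 1.0) -> IntegralSet:
    """Hubbard chain: nearest-neighbour hopping -t, on-site repulsion U.

    One orbital per site, sites collinear with the given spacing (angstrom).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_elec % 2:
        raise ValueError("n_elec must be even")
    h = np.zeros((n_sites, n_sites))
    for p in range(n_sites - 1):
        h[p, p + 1] = h[p + 1, p] = -t
    g = np.zeros((n_sites,) * 4)
    for p in range(n_sites):
        g[p, p, p, p] = U
    sites = np.column_stack([spacing * np.arange(n_sites, dtype=float),
                             np.zeros(n_sites), np.zeros(n_sites)])
    return IntegralSet(n_sites, n_elec, 0.0, h, g, sites, sites.copy())


def make_localized_random(n_sites: int, orbs_per_site: int, n_elec: int,
                          decay: float, seed: int,
                          g_scale: float = 0.6,
                          band_scale: float = 0.25) -> IntegralSet:
    """Randomized integral set with exponential spatial locality.

    Sites sit on a line 1 angstrom apart, ``orbs_per_site`` orbitals per
    site.  Two-electron integrals are assembled as ``g = B @ B.T`` over
    composite pair indices, which guarantees positive semidefiniteness.
    Each auxiliary vector is anchored at a site, and the factor for orbital
    pair (p, q) against an auxiliary at site S is damped by
    ``exp(-decay * (d(p,S) + d(q,S)))``; by the triangle inequality the
    assembled integrals then decay at least as ``exp(-decay * d(p,q))`` in
    the intra-pair distance, emulating the locality of electron repulsion
    integrals over well-localized molecular orbitals.

    The one-electron part is a short-range random band on top of a
    deterministic site-diagonal well.  The well alternates in depth between
    even and odd sites so that, with one electron pair per two sites, the
    occupied space localizes on the deep sites and the RHF gap stays
    positive.

    Identical seeds give bitwise identical output.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_elec % 2:
        raise ValueError("n_elec must be even")
    rng = np.random.default_rng(seed)
    n_orb = n_sites * orbs_per_site
    site_of = np.repeat(np.arange(n_sites), orbs_per_site)
    sites = np.column_stack([np.arange(n_sites, dtype=float),
                             np.zeros(n_sites), np.zeros(n_sites)])
    orb_pos = sites[site_of]

    # --- two-electron part: local auxiliary expansion, PSD by construction
    n_aux_per_site = max(2, orbs_per_site + 1)
    dist = np.abs(np.arange(n_sites)[:, None] - np.arange(n_sites)[None, :]) * 1.0
    B = np.zeros((n_orb * n_orb, n_sites * n_aux_per_site))
    damp_ps = np.exp(-decay * dist)          # site x aux-site damping
    for k_site in range(n_sites):
        w = damp_ps[site_of, k_site]         # per-orbital damping to this aux site
        pair_damp = np.outer(w, w).ravel()   # exp(-decay*(d_pS + d_qS)) over (p,q)
        for k in range(n_aux_per_site):
            fac = rng.standard_normal((n_orb, n_orb))
            fac = 0.5 * (fac + fac.T)        # keep B^K_pq = B^K_qp
            B[:, k_site * n_aux_per_site + k] = g_scale * pair_damp * fac.ravel()
    g = (B @ B.T).reshape(n_orb, n_orb, n_orb, n_orb)
    # enforce exact 8-fold symmetry (B construction gives it up to round-off)
    g = 0.125 * (g + g.transpose(1, 0, 2, 3) + g.transpose(0, 1, 3, 2)
                 + g.transpose(1, 0, 3, 2) + g.transpose(2, 3, 0, 1)
                 + g.transpose(3, 2, 0, 1) + g.transpose(2, 3, 1, 0)
                 + g.transpose(3, 2, 1, 0))

    # --- one-electron part: site-diagonal well + damped random band.
    # The mean field of the assembled interaction for the designed Aufbau
    # occupation is folded back into h with opposite sign -- the analogue
    # of nuclear attraction cancelling the bulk of the electron repulsion
    # in a molecule -- so the Fock operator reproduces the designed level
    # structure (deep occupied, shallow and excited virtual), the RHF gap
    # stays positive across seeds, and the correlation strength is set by
    # ``g_scale`` alone.
    h = np.zeros((n_orb, n_orb))
    deep, shallow = [], []
    for p in range(n_orb):
        s = site_of[p]
        k = p - s * orbs_per_site
        if k == 0:
            h[p, p] = -2.4 if s % 2 == 0 else -0.2
            (deep if s % 2 == 0 else shallow).append(p)
        else:
            h[p, p] = 1.2 + 0.5 * (k - 1)
    band = rng.standard_normal((n_orb, n_orb))
    band = 0.5 * (band + band.T)
    orb_dist = np.abs(orb_pos[:, 0][:, None] - orb_pos[:, 0][None, :])
    h += band_scale * band * np.exp(-decay * orb_dist)

    occ0 = (deep + shallow)[: n_elec // 2]
    D0 = np.zeros((n_orb, n_orb))
    for p in occ0:
        D0[p, p] = 2.0
    J0 = np.einsum("pqrs,rs->pq", g, D0, optimize=True)
    K0 = np.einsum("psrq,rs->pq", g, D0, optimize=True)
    h -= J0 - 0.5 * K0

    return IntegralSet(n_orb, n_elec, 0.0, h, g, sites, orb_pos)
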