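"""Orbital localization, site assignment and priority lists.

Occupied and virtual blocks are localized independently by Jacobi 2x2
sweeps.  Two objectives are provided:

* ``PM2`` -- maximize the Pipek-Mezey-type sum of squared site populations,
  ``sum_r sum_A Q_A(r)^2``, where ``Q_A(r)`` is orbital r's population on
  site A (sum of squared coefficients over that site's basis functions; in
  an orthonormal basis Mulliken and Loewdin populations coincide).
* ``FM4`` -- minimize the sum of squared fourth central moments of the
  orbital charge distributions, a simple stand-in for fourth-moment
  localization functionals that penalizes orbitals with fat tails.  It is
  not claimed to be equivalent to any published fourth-moment functional.

Each orbital is assigned to the nearest site of its charge center
(population-weighted mean of basis-function positions), and per-site
priority lists order all orbitals by charge-center distance from the site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LocalOrbitalSet", "localize", "assign_to_sites", "priority_list",
           "build_local_orbitals", "charge_centers"]


@dataclass
class LocalOrbitalSet:
    C_loc: np.ndarray            # full orbital matrix, occupied block first
    n_occ: int
    centers: np.ndarray          # per-orbital charge centroid (n_orb, 3)
    assignment: np.ndarray       # orbital -> site index
    spreads: np.ndarray          # per-orbital (second, fourth) central moments
    priority: dict               # site -> ordered orbital index list
    converged: bool = True

    @property
    def occ_indices(self):
        return np.arange(self.n_occ)

    @property
    def virt_indices(self):
        return np.arange(self.n_occ, self.C_loc.shape[1])

    def site_orbitals(self, site: int, kind: str = "all"):
        """Orbitals assigned to ``site``; kind in {'all', 'occ', 'virt'}."""
        idx = np.where(self.assignment == site)[0]
        if kind == "occ":
            idx = idx[idx < self.n_occ]
        elif kind == "virt":
            idx = idx[idx >= self.n_occ]
        return idx


def _populations(C_block: np.ndarray, site_of_basis: np.ndarray, n_sites: int):
    """Q[A, r]: population of orbital r on site A (orthonormal basis)."""
    C2 = C_block ** 2
    Q = np.zeros((n_sites, C_block.shape[1]))
    for A in range(n_sites):
        Q[A] = C2[site_of_basis == A].sum(axis=0)
    return Q


def charge_centers(C_block: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Population-weighted mean position of each orbital (column)."""
    C2 = C_block ** 2
    w = C2.sum(axis=0)
    w[w == 0] = 1.0
    return (C2.T @ positions) / w[:, None]


def _pm2_value(C, site_of_basis, n_sites):
    Q = _populations(C, site_of_basis, n_sites)
    return float((Q ** 2).sum())


def _fm4_value(C, positions):
    centers = charge_centers(C, positions)
    C2 = C ** 2
    m4 = np.empty(C.shape[1])
    for r in range(C.shape[1]):
        d2 = ((positions - centers[r]) ** 2).sum(axis=1)
        m4[r] = C2[:, r] @ (d2 ** 2)
    return float((m4 ** 2).sum())


def localize(C_block: np.ndarray, positions: np.ndarray, functional: str = "PM2",
             tol: float = 1e-10, max_sweeps: int = 200,
             site_of_basis: np.ndarray = None, n_sites: int = None):
    """Jacobi-sweep localization of one orbital block.

    Returns ``(U, converged)``: the accumulated orthogonal rotation (apply as
    ``C_block @ U``) and a convergence flag.  PM2 is maximized, FM4
    minimized; each 2x2 angle is found by a deterministic grid scan refined
    by golden-section search, which is robust against the multimodality of
    the localization surface at desk scale.
    """
    positions = np.asarray(positions, dtype=float)
    if site_of_basis is None:
        # each basis function its own site
        site_of_basis = np.arange(C_block.shape[0])
        n_sites = C_block.shape[0]
    if n_sites is None:
        n_sites = int(site_of_basis.max()) + 1
    nmo = C_block.shape[1]
    U = np.eye(nmo)
    if nmo < 2:
        return U, True

    sign = 1.0 if functional.upper() == "PM2" else -1.0

    def value(C):
        if functional.upper() == "PM2":
            return _pm2_value(C, site_of_basis, n_sites)
        elif functional.upper() == "FM4":
            return -_fm4_value(C, positions)   # maximize the negative
        raise ValueError(f"unknown localization functional {functional!r}")

    C = C_block.copy()
    current = value(C)
    converged = False
    for sweep in range(max_sweeps):
        start = current
        for r in range(nmo - 1):
            for s in range(r + 1, nmo):
                cr, cs = C[:, r].copy(), C[:, s].copy()

                def pair_val(theta):
                    ct, st = np.cos(theta), np.sin(theta)
                    C[:, r] = ct * cr + st * cs
                    C[:, s] = -st * cr + ct * cs
                    return value(C)

                # coarse deterministic scan, then golden-section refine
                grid = np.linspace(-np.pi / 4, np.pi / 4, 49)
                vals = np.array([pair_val(th) for th in grid])
                k = int(np.argmax(vals))
                lo = grid[max(k - 1, 0)]
                hi = grid[min(k + 1, len(grid) - 1)]
                gr = 0.5 * (np.sqrt(5.0) - 1.0)
                a, b = lo, hi
                x1 = b - gr * (b - a)
                x2 = a + gr * (b - a)
                f1, f2 = pair_val(x1), pair_val(x2)
                for _ in range(60):
                    if f1 < f2:
                        a, x1, f1 = x1, x2, f2
                        x2 = a + gr * (b - a)
                        f2 = pair_val(x2)
                    else:
                        b, x2, f2 = x2, x1, f1
                        x1 = b - gr * (b - a)
                        f1 = pair_val(x1)
                theta = 0.5 * (a + b)
                new = pair_val(theta)
                if new <= current + 1e-14:
                    # no improvement: undo
                    C[:, r], C[:, s] = cr, cs
                else:
                    current = new
                    ct, st = np.cos(theta), np.sin(theta)
                    ur, us = U[:, r].copy(), U[:, s].copy()
                    U[:, r] = ct * ur + st * us
                    U[:, s] = -st * ur + ct * us
        if abs(current - start) < tol:
            converged = True
            break
    # deterministic phases
    for k in range(nmo):
        imax = np.argmax(np.abs(C[:, k]))
        if C[imax, k] < 0:
            C[:, k] = -C[:, k]
            U[:, k] = -U[:, k]
    return U, converged


def assign_to_sites(centers: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Map each orbital to the nearest site (ties -> lowest site index)."""
    sites = np.atleast_2d(sites)
    if sites.shape[0] == 0:
        raise ValueError("need at least one site")
    d = np.linalg.norm(centers[:, None, :] - sites[None, :, :], axis=2)
    return np.argmin(d, axis=1)     # argmin takes the first (lowest) index on ties


def priority_list(P: int, centers: np.ndarray, sites: np.ndarray,
                  subset=None) -> np.ndarray:
    """Orbitals sorted by charge-center distance from site P (stable ties)."""
    sites = np.atleast_2d(sites)
    idx = np.arange(centers.shape[0]) if subset is None else np.asarray(subset)
    d = np.linalg.norm(centers[idx] - sites[P], axis=1)
    order = np.lexsort((idx, np.round(d, 12)))
    return idx[order]


def build_local_orbitals(scf, intset, functional: str = "PM2",
                         tol: float = 1e-10, max_sweeps: int = 200) -> LocalOrbitalSet:
    """Localize occupied and virtual blocks of an SCF solution.

    The basis functions are the site orbitals of ``intset`` (orthonormal),
    positioned at ``intset.orbital_positions`` and grouped by nearest site.
    """
    C = scf.C.copy()
    n_occ = scf.n_occ
    positions = intset.orbital_positions
    site_of_basis = assign_to_sites(positions, intset.sites)
    n_sites = intset.n_sites
    conv = True
    for sl in (slice(0, n_occ), slice(n_occ, C.shape[1])):
        block = C[:, sl]
        if block.shape[1] >= 2:
            U, ok = localize(block, positions, functional, tol, max_sweeps,
                             site_of_basis=site_of_basis, n_sites=n_sites)
            C[:, sl] = block @ U
            conv = conv and ok
    centers = charge_centers(C, positions)
    assignment = assign_to_sites(centers, intset.sites)
    C2 = C ** 2
    spreads = np.empty((C.shape[1], 2))
    for r in range(C.shape[1]):
        d2 = ((positions - centers[r]) ** 2).sum(axis=1)
        spreads[r, 0] = C2[:, r] @ d2
        spreads[r, 1] = C2[:, r] @ (d2 ** 2)
    priority = {P: priority_list(P, centers, intset.sites)
                for P in range(n_sites)}
    return LocalOrbitalSet(C_loc=C, n_occ=n_occ, centers=centers,
                           assignment=assignment, spreads=spreads,
                           priority=priority, converged=conv)
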