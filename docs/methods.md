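# Methods

This note records the models implemented in `deccp`, the conventions and
numerical choices they rest on, what the synthetic systems do and do not
emulate, and the package's known limitations.

## Hamiltonians and conventions

All systems live in an orthonormal spatial-orbital basis (overlap =
identity), closed-shell singlet only; odd electron counts are rejected
rather than truncated.  Two-electron integrals are stored in chemist
(Mulliken) notation `(pq|rs)` with the full 8-fold permutational symmetry,
and the pair-index matrix `G[(pq),(rs)]` is required to be positive
semidefinite (physical realizability; it also makes the Cholesky fitting
well-posed).  FCIDUMP files are 1-based at the file boundary only; site
coordinates travel in a plain-text sidecar (one `x y z` line per site,
angstrom) because the format has no geometry field.

### The random local generator

`make_localized_random` places `orbs_per_site` orbitals per site on a line
1 angstrom apart and assembles the interaction as `g = B Bᵀ` over composite
pair indices, which is positive semidefinite by construction.  Each
auxiliary vector is anchored at a site and the factor for orbital pair
(p, q) is damped by `exp(-decay·(d(p,S) + d(q,S)))`; by the triangle
inequality the assembled integrals decay at least as `exp(-decay·d(p,q))`
in the intra-pair distance, and interactions between compact, well-separated
pairs decay through the shared auxiliary centers — the behaviour that makes
fragment methods work on real molecules.

The one-electron part is a site-diagonal well (deep on even sites, shallow
on odd, excited levels above) plus a short-range random band, **minus the
mean field of the designed Aufbau occupation**.  This compensation mirrors
how nuclear attraction cancels the bulk of electron repulsion in a
molecule: it makes the Fock operator reproduce the designed level
structure, keeps the RHF gap at roughly 1.5–2 hartree across seeds, and
decouples the correlation strength (set by `g_scale`) from mean-field
stability.  The default `g_scale = 0.6` was chosen so the MP2 correlation
energy per valence pair falls in the range typical of molecular valence
pairs (tens of millihartree); at the default, 12-seed ensembles of the
8-site reference geometry give total MP2 correlation energies between
roughly −0.04 and −0.5 hartree.

What the generator does *not* emulate: long-range `1/r` Coulomb tails (the
decay is exponential, so pair energies fall off faster than the `R⁻⁶`
dispersion law of real molecules), core/valence separation, point-group
symmetry, and basis-set incompleteness.  Passing tests therefore validate
the *machinery* — exact partitioning, threshold-driven error control,
order-by-order perturbation structure — not basis-set-quality energetics of
any real compound.

## Mean field and orbitals

RHF iterates Fock diagonalization with DIIS (window 8) from a
core-Hamiltonian guess; convergence requires both the occupied–virtual
Fock block and the energy change below `conv_tol` (default 1e-9, max 200
iterations).  If plain DIIS oscillates (level crossings), the solve is
retried with density damping (0.3, then 0.6) and a virtual-space level
shift (0.5, then 1.0 hartree).  Degenerate orbital orders and phases are
fixed deterministically (energy, then index of the largest coefficient;
largest component positive) so downstream localization is reproducible.

Localization maximizes the Pipek–Mezey-type sum of squared site populations
(`PM2`; populations are sums of squared coefficients per site, Mulliken =
Löwdin in an orthonormal basis) or minimizes the sum of squared fourth
central moments (`FM4`) by Jacobi 2×2 sweeps; each pair angle is located by
a deterministic 49-point grid scan refined by golden-section search, which
is robust to the multimodality of localization surfaces at this scale.
`FM4` is a simple stand-in in the spirit of fourth-moment localization
functionals, not a claim of equivalence to any published one.  Occupied and
virtual blocks are localized independently; charge centers are
population-weighted means of basis-function positions; each orbital is
assigned to its nearest site (ties to the lowest site index).

## Canonical correlation methods

Public amplitudes are closed-shell spatial tensors, `t2[i,j,a,b] =
t2[j,i,b,a]`, with the energy `E = Σ (t2 + t1 t1)(2(ai|bj) − (bi|aj))`.
The CCSD equations are iterated internally in the spin-orbital
representation (standard effective-intermediate working equations,
amplitude DIIS with window 6, pseudo-canonical denominators, defaults
`conv_tol = 1e-8`, 100 iterations); the closed-shell amplitudes are
extracted from the mixed-spin components.  At desk scale the two
formulations are interchangeable, and the determinant-space residual
oracle — projecting `e^{-T} H e^{T}|HF⟩` onto the biorthonormal duals of
the singles+doubles manifold with exact matrix exponentials — checks the
solver without sharing a line of contraction code.

The perturbative-triples correction uses the fragment-partitionable form:
triples amplitudes from converged doubles,

    t_ijk^abc = P̂ [ Σ_d t_ij^ad (db|kc) − Σ_l t_il^ab (lj|kc) ] / D_ijk^abc,

with `P̂` the six simultaneous pair permutations of (ai)(bj)(ck), contracted
into doubles/singles intermediates `T_ij^ab`, `T_i^a` (with `L_pqrs =
2(pq|rs) − (ps|rq)`), and the energy `E^(T) = 2Σ(2t_ij^ab − t_ji^ab)T_ij^ab
+ 2Σ t_i^a T_i^a`.  This correction is *defined* by these working equations
(validated internally by naive-loop oracles and the fragment partition
identity); no claim is made that it coincides with every textbook (T)
variant, and its sign on ground-state fixtures is recorded by test, not
assumed.

Full CI diagonalizes the Hamiltonian over all Sz = 0 determinants built
from explicit spin-summed excitation-operator matrices; S² labels separate
singlets from triplets when comparing with the (singlet) EOM-CCSD spectrum.
The dense EOM-CCSD oracle assembles the CC Jacobian column by column from
central finite differences (step 1e-5) of the amplitude residual in the
unique singlet parameter space.

## The fragment scheme

Occupied partitioning only: `E_P` sums occupied pairs inside the EOS,
`ΔE_PQ` the two cross blocks, with virtual sums over the fragment (or pair
union) virtual space.  Fragment amplitude equations are solved in the AOS
after diagonalizing the occupied–occupied and virtual–virtual blocks of the
full Fock matrix restricted to the fragment (pseudo-canonical basis: MP2
and the triples become non-iterative), then rotated back to the local
basis; the occupied–virtual Fock block vanishes in any occ/virt rotation of
a converged reference, so no extra coupling terms arise.

Fragment optimization: the initial space is the EOS plus all orbitals of
sites within one lattice spacing; expansion adds one whole site per step in
priority order (orbital distance from P) until the fragment energy changes
by less than the FOT; reduction then binary-searches the distance-ordered
tail of included sites for the largest block removable within the FOT.  If
expansion exhausts the system the fragment is exact and flagged.  For CCSD
and triples targets the optimization runs at MP2 by default.

Pair estimates use minimal spaces: occupied = EOS(P) ∪ EOS(Q), virtual =
virtuals assigned to P, Q or any nearest-neighbour site of either.  The
nearest-neighbour extension matters: local excitations out of P and Q
frequently terminate on adjacent sites, and with EOS-only virtuals the
estimates captured only about a third of the exact pair magnitudes on the
reference fixture, versus essentially all of them with the extension.
Screening is applied per site (ascending `|estimate|`, largest prefix whose
half-sum stays within the FOT); a pair is discarded only when screened from
*both* of its sites' lists, or when beyond `R_screen` (default 30 Å — at
desk scale this cutoff is inactive and only the estimate-based screening
operates).  The error estimate `2·N_frag·FOT` is reported with every run.

Two subtleties in the triples partitioning deserve record.  First, the
doubles sums of `E_P^(T)` restrict *both* occupied indices to the EOS.
Second, the singles terms `t_i^a T_i^a` are partitioned over virtuals
*assigned* to each site (a disjoint partition), not over the overlapping
fragment virtual spaces — otherwise the pair cross terms double-count; and
pairs in which one site owns only virtual orbitals, which are invisible to
MP2/CCSD screening, still carry triples singles cross terms and are
retained by the `ccsd_t` driver regardless of screening.  Both choices are
fixed by demanding the exact partition identity with untruncated spaces.

The driver dispatches fragment and pair tasks largest-first through a
scheduler contract; the serial and process-pool backends reduce results in
sorted key order and agree bitwise.

## Cluster perturbation corrections

For a canonical RHF reference the CCS ground-state singles vanish, so the
parent-state similarity transform is the identity and the parent Jacobian
is the (symmetric) singlet singles block `F_ab δ_ij − F_ij δ_ab + 2(ia|jb)
− (ij|ab)`.  The order expansion assigns the fluctuation potential first
order *except* its parent-internal block, which is resummed into the
zeroth-order Jacobian; consequently `ω⁽¹⁾ = 0` identically (it is computed
from the step-function-masked first-order Jacobian, not asserted).

Production working equations (validated to machine precision against the
dense reference):

- first-order doubles `t⁽¹⁾ = (ai|bj)/Δ` and, per root, the first-order
  eigenvector correction `R⁽¹⁾ = (ai|̄bj)/(Δ + ω)` built from one-index
  R-transformed *barred* integrals (X̄/Ȳ transformation vectors collapse in
  an orthonormal basis to "virtual row ← −R · occupied" and "occupied
  column ← +R · virtual" replacements on each index in turn);
- `ω⁽²⁾ = L·[A₁(ḡ, v̄; t⁽¹⁾) + A₁(g, v; R⁽¹⁾)]`, the CIS(D)-equivalent
  second order;
- second-order amplitudes: doubles `t⁽²⁾ = A₂(g, v; t⁽¹⁾)/Δ` and singles
  from the parent-space linear system `J^P t⁽²⁾_s = −A₁(g, v; t⁽¹⁾)`;
- second-order eigenvector (auxiliary part) `R⁽²⁾ = [A₂(ḡ, v̄; t⁽¹⁾) +
  A₂(g, v; R⁽¹⁾)]/(Δ + ω)`;
- `ω⁽³⁾ = L·[A₁(ḡ, v̄; t⁽²⁾_d) + A'(ḡ, v̄)·t⁽²⁾_s + A₁(g, v; R⁽²⁾)]`.

Here `A₂`, `A₁` and `A'` are the doubles-space, singles-space and
singles–singles projections of the commutator of a (possibly dressed)
two-body-plus-one-body fluctuation operator with a doubles or singles
excitation operator, written as explicit closed-shell contractions whose
integer coefficients were *derived* by exact least-squares identification
against determinant-space ground truth (residual below 1e-13) and then
frozen.  The effective one-particle dressing `v' + 2J(g') − K(g')` vanishes
identically for the bare fluctuation potential of a canonical reference and
is finite for barred tensors.  Two structural facts keep third order this
compact: excitation operators commute, and a two-body operator cannot
de-excite by three — so the singles projection of double commutators with
two doubles operators vanishes identically, and the first-order Jacobian
(no parent-parent block) couples only the auxiliary part of `R⁽²⁾` into
`ω⁽³⁾`.

The heavy `A₂` contractions stream over batches of the leading virtual
index in two passes (an amplitude pass for the `t⁽²⁾` contribution, an
eigenvector pass for `R⁽²⁾`); results are batch-size invariant to 1e-12.
With `use_fit`, all two-electron blocks — including barred ones, via
`(pq|̄rs) = Σ_K [B̄_pq B_rs + B_pq B̄_rs]` — are assembled from pivoted-
Cholesky three-index factors of the pair-index matrix; an external
auxiliary basis does not exist for model Hamiltonians, so the pivoted
factorization realizes the same sum-of-products algebra self-contained.
Degenerate cases (a doubles denominator `Δ + ω` within 1e-8 of zero, e.g.
the U = 4 Hubbard dimer) raise a dedicated error for that root.

### The two independent oracles

The dense reference path carries out the order recursions literally with
determinant-space operator matrices (duals of the singlet excitation basis,
nested commutators, a bordered solve with biorthogonality constraint for
the parent part of `R⁽²⁾`).  Independently, a λ-dressed nonlinear
eigenproblem — amplitude equations and Jacobian with every first-order
block scaled by λ, the parent-internal coupling restored at full strength,
solved by Newton iteration with exact matrix exponentials — yields an exact
eigenvalue ω(λ) whose Taylor coefficients reproduce ω⁽⁰⁾…ω⁽³⁾; a
degree-8 polynomial fit over λ ∈ [0.01, 0.12] recovers the quadratic and
cubic coefficients to ~1e-8.  The printed recursion tables contain one sign
ambiguity (the `[Φ, R⁽¹⁾]` term of the auxiliary second-order eigenvector
equation); the λ-series fixes it to the minus sign used here.

## Problem sizes and defaults

All shipped computations are desk scale by design: reference systems have
8–16 orbitals, determinant spaces at most a few thousand, and the full test
suite plus the acceptance script run in a few minutes on one CPU.
Key defaults: SCF `conv_tol` 1e-9; CCSD `conv_tol` 1e-8; localization tol
1e-10, 200 sweeps max; FOT 1e-4; `R_screen` 30 Å; Cholesky `tol` 1e-8;
finite-difference step 1e-5; dense reference capped at ~2500 determinants
and the finite-difference EOM at ~2000 amplitude parameters.

## Known limitations

- Closed-shell singlets only; no open shells, no symmetry adaptation.
- Occupied partitioning only; virtual and Lagrangian schemes, multi-layer
  fragmentation, gradients and densities are out of scope.
- The triples correction follows the fragment-partitionable working
  equations above; for two-electron systems it is not constrained to
  vanish, unlike the spin-orbital perturbative triples.
- Excitation corrections assume a canonical RHF parent (zero CCS singles);
  nearly degenerate doubles denominators are rejected, not regularized.
- The process-pool scheduler is a task-queue contract demonstrator, not a
  distributed-memory implementation; no GPU or MPI paths exist.
- Dense oracles (FCI, determinant-space reference, finite-difference
  Jacobians) are intentionally capped at small dimensions.
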