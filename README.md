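# deccp

Fragment-partitioned coupled-cluster correlation energies and
cluster-perturbation excitation energies for desk-scale model Hamiltonians,
with built-in brute-force oracles for every approximation.

## The problem

Canonical correlated wave-function methods (MP2, CCSD, CCSD(T)) scale so
steeply with system size that large molecules are out of reach unless the
correlation problem is broken into pieces.  Two complementary strategies are
implemented here in full, at a scale where every claim can be checked
against exact diagonalization:

**Divide–Expand–Consolidate (DEC).**  With occupied and virtual Hartree–Fock
orbitals localized and assigned to atomic sites, the correlation energy
partitions exactly over sites *P*:

    E_corr = Σ_P E_P + Σ_{Q<P} ΔE_PQ,
    E_P    = Σ_{ij∈P̲} Σ_{ab∈P̄} (t_ij^ab + t_i^a t_j^b) (2(ai|bj) − (bi|aj)),

where `P̲` is the set of occupied orbitals assigned to P (the *energy
orbital space*, EOS) and `P̄` a truncated virtual space.  Amplitudes for
each fragment are solved in a larger *amplitude orbital space* (AOS) that is
expanded site layer by site layer, then reduced, until the fragment energy
is stable to the **fragment optimization threshold** (FOT).  Pair energies
`ΔE_PQ` are screened with cheap minimal-space MP2 estimates — per site, the
smallest estimates whose half-sum stays below the FOT are discarded — plus a
real-space cutoff `R_screen`.  The total error obeys `δE ≈ 2·N_frag·FOT`.
MP2, CCSD and a fragment-partitionable perturbative-triples correction are
supported.

**Cluster perturbation theory for excitations, CPS(D-2)/CPS(D-3).**  The
singles (CCS) problem is the zeroth-order parent; the doubles space is a
perturbing auxiliary.  The corrections `ω⁽¹⁾ = 0`, `ω⁽²⁾` (equivalent to
CIS(D)) and the non-iterative `ω⁽³⁾` are evaluated from orbital-level
contractions with one-index R-transformed ("barred") integrals, batched over
a virtual index in two passes, optionally consuming all two-electron tensors
through three-index pivoted-Cholesky fitting coefficients,
`(pq|rs) = Σ_K B^K_pq B^K_rs`.

Everything runs on orthonormal model Hamiltonians: FCIDUMP files, Hubbard
chains, and a generator of randomized integral sets with tunable exponential
spatial locality — so fragment behaviour (recovery vs. FOT, pair decay) is
exercisable without any external data.  A determinant-space toolkit
(explicit operator matrices, full CI, matrix-exponential similarity
transforms) provides oracles that share no code with the production tensor
contractions.

## Worked example

Generate a 6-site random local system (12 orbitals, 6 electrons) and run
DEC-MP2 at FOT = 10⁻⁴:

```bash
deccp fixtures random --sites 6 --elec 6 --seed 3 -o demo.fcidump --sidecar demo.sites
deccp dec --method mp2 --fot 1e-4 demo.fcidump --sidecar demo.sites
deccp cc --method mp2 demo.fcidump
```

The DEC record reports (abridged)

```json
{
  "e_hf": -17.196995477,
  "e_corr": -0.231128394981,
  "e_total": -17.428123872,
  "error_estimate": 0.0012,
  "effective_energies": { "0": -0.149986545264, "2": -0.0576587420522, "4": -0.0234831076648, ... }
}
```

while the canonical reference gives `e_corr = -0.231285850268`: the fragment
scheme recovers 99.93% of the correlation energy, well within the error
model `2·N_frag·FOT = 1.2e-3`.  The effective site energies `ϵ_P = E_P +
½Σ_Q ΔE_PQ` sum to `e_corr` by construction; sites that own no occupied
orbitals contribute zero.  Excitation energies with cluster-perturbation
corrections:

```bash
deccp cps --order 3 --nroots 2 demo.fcidump
# root 0: omega_ccs = 1.93375268, omega2 = +0.04280728, omega3 = -0.03819134, total = 1.93836862
```

`deccp validate` runs a built-in oracle battery (closed-form Hubbard-dimer
FCI, two-electron CCSD exactness, production-vs-dense equality of the
perturbative corrections) and exits nonzero on any failure.

## Layout

| module | contents |
| --- | --- |
| `deccp.integrals` | `IntegralSet`, FCIDUMP read/write, Hubbard and random-local generators |
| `deccp.scf` | restricted Hartree–Fock, MO transforms, pseudo-canonicalization |
| `deccp.localization` | Jacobi-sweep PM2/FM4 localization, site assignment, priority lists |
| `deccp.cc` | MP2, CCSD, triples intermediates, CCS, dense EOM-CCSD, determinant FCI |
| `deccp.dec` | fragment spaces, optimization, pair estimation/screening, assembly, driver |
| `deccp.cps` | Cholesky fitting, barred/breve-dressed transforms, ω⁽²⁾/ω⁽³⁾, driver |
| `deccp.cps_dense` | determinant-space order-expansion reference and λ-series oracle |
| `deccp.determinants` | determinant spaces, operator matrices, Hamiltonian builder |
| `deccp.cli` | the `deccp` command: `fixtures`, `scf`, `cc`, `dec`, `cps`, `validate` |

See `docs/methods.md` for the models, conventions, numerical choices and
known limitations.
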