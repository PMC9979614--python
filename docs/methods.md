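# Methods

## Model and conventions

`spinblock` treats a cluster of `n` magnetic sites with local spins `s_i`,
each realized as `2s_i` singly occupied spin-1/2 orbitals. The Hamiltonian is

```
H = − Σ_{i<j} J_ij Ŝ_i·Ŝ_j − J_Hund Σ_i Σ_{p<q ∈ i} ŝ_p·ŝ_q ,
```

with the sign convention fixed so that `J < 0` is antiferromagnetic (the
dimer singlet lies below the triplet for J = −1) and `J_Hund ≥ 0` is an
intra-site ferromagnetic term that stabilizes local high-spin (Hund)
configurations. Only exchange is included: no double occupations, no hopping
or charge-transfer terms, no anisotropy. The constant (number-operator) shift
that appears in spin-free second-quantized formulations is omitted — all
energies refer to the pure exchange operator. ħ = 1 and `J` is carried in
whatever units the user supplies. Every serialized artifact embeds this
convention metadata.

Spins are stored as twice-spin integers everywhere (`twice_S`, `2s_i`,
cumulative path heights), so parity checks and eigenvalue labels are exact
integer comparisons, never float equality.

## CSF basis

A CSF over `n` open orbitals is a u/d walk with non-negative cumulative spin,
ending at the target `2S`. Counting uses the ballot-number closed form
`C(n, (n−2S)/2) − C(n, (n−2S)/2 − 1)`; the full spin-adapted dimension with
empty/double occupations uses the standard Weyl formula
`(2S+1)/(n+1)·C(n+1, N/2−S)·C(n+1, N/2+S+1)`. Both are validated in the test
suite against brute-force enumerators (all `2^n` walks; all occupation
patterns with an M-sector difference count), which serve as the independent
oracles rather than any printed table. Enumeration order is lexicographic
with `u < d`, a documented arbitrary choice that makes matrices reproducible.

Prefix constraints (e.g. "local Hund spin 3/2 after the first site,
intermediate spin 1 after two sites") restrict the walk at given prefix
lengths; counting is done by dynamic programming over (position, height) and
always equals the length of the explicit enumeration. Contradictory
constraints yield an empty basis, not an error, since "no compatible path"
is a legitimate physical answer.

## Determinant expansion

The CSF → determinant map is the genealogical Clebsch–Gordan product: the
coefficient of a spin-assignment bitstring is the product over steps of the
factor for coupling one spin-1/2 onto the running (S, M). Phases follow the
standard convention in which u-step α-coefficients are positive and the
d-step α-coefficient is negative; only relative phases are observable, and
the tests assert the basis-independent property (each expansion is a
unit-norm S² eigenvector against an independently coded S⁻S⁺ + S_z² + S_z
matrix) rather than coefficient tables. Work happens in the highest-weight
sector `M = S` by default — the smallest determinant space complete for
spin-S content. Determinants are ordered as unsigned integers (bit k = α on
orbital k).

Operators are assembled from one primitive: `Σ w_pq ŝ_p·ŝ_q` realized as
`s_pz s_qz + (s_p⁺s_q⁻ + s_p⁻s_q⁺)/2` on bitstrings. Because every orbital
is singly occupied and nothing hops, no fermionic sign bookkeeping arises.
Site products `Ŝ_i·Ŝ_j`, local squares `Ŝ_i²` and cumulative squares
`(Σ_{i≤m} Ŝ_i)²` are all weighted instances of this primitive.

## Blocking theory and detection

The prediction rule: `(Ŝ_1+…+Ŝ_m)²` commutes with `H` iff every site beyond
the prefix couples with one common `J` to all prefix members (prefix 1 and
prefix n always commute). `predict_blocking_orderings` applies this test to
every site permutation (exhaustive up to 8 sites, deduplicated by
automorphisms of the weighted coupling graph; beyond 8 only the supplied
ordering's shell pattern is checked), returning the guaranteed depth per
equivalence class. Coupling equality uses relative tolerance 1e−12; an
optional looser `quasi_rtol` reports "quasi-blocked" orderings, whose small
residual commutator norm users can query directly — near-isosceles clusters
still compress usefully.

`commutator_norm` reports `‖[S²_prefix, H]‖_F / ‖H‖_F` in the lowest-|M|
determinant sector, which contains every spin multiplet, so one sector
certifies all of them. `make_cumulative_blocked_model` constructs the n-site
family in which site k couples uniformly to the first `min(k, m)` sites —
commuting with the first `m` cumulative spins by construction (the 2-J
square is the m = 2 special case in the diagonal-pair-first ordering).

Block detection is purely numerical: zero elements below `tol·max|H|`
(default 1e−10, well above the ~1e−15 round-off dust of the projection and
well below genuine couplings at these matrix scales) and take connected
components of the sparsity graph (scipy.sparse.csgraph). Blocks are labeled
with whatever cumulative-site twice-spins are constant across their members —
exact path lookups, not expectation values — plus a first-site Hund flag.
The internal sparsity observed inside non-Hund blocks is reported but
nothing is asserted about it.

## Spectra, targeting, compression

`diagonalize` uses dense `eigh`; within degenerate clusters (relative gap
< 1e−8) eigenvectors are rotated to simultaneously diagonalize the
prefix-spin labels in prefix order. This matters because L1/L4 norms are
basis-dependent inside a degenerate subspace; the canonical choice is the
intermediate-spin eigenstates, which is also what a state-specific solver
would converge to. For non-site-separated orbital permutations the labels
are undefined and the raw eigenvectors are returned.

`target_state` finds the detected block containing a trial CSF and
diagonalizes only that submatrix — the operational payoff of blocking:
excited states cost one small eigenproblem and no lower states.

Kambe ladders (dimer, isosceles/equilateral, 2-J square) are evaluated from
the closed forms obtained by rewriting exchange through cumulative-spin
squares, e.g. `E(S_AB, S) = −J_AB/2[S_AB(S_AB+1) − 2s(s+1)] −
J_AC/2[S(S+1) − S_AB(S_AB+1) − s(s+1)]`, plus the (diagonal) Hund-term energy
of the all-Hund sector. They are used as oracles against the numerical
spectra; the scalene triangle has no such form and raises.

The compression scan fixes `J_AB = −150`, `J_AC = −20` (the literature
parameterization of a strongly asymmetric trimer), sweeps `J_BC` over
[−20, −150] on a 40-point grid, computes the lowest-quartet L1/L4 in the ABC
and ACB orderings, and locates the L1 crossing by bisection (interval
tolerance 1e−3 in J_BC, decoupling the answer from grid density). The
computed flipping ratio is J_AC/J_BC ≈ 0.362 (J_BC ≈ −55.3). It is
independent of `J_Hund`: all local site spins commute with `H`, so the
lowest quartet is an exact Hund-sector state and the scan defaults to pure
exchange.

## Synthetic fixtures

`generate_fixtures` emits the preset topologies at their stated parameters
(s=3/2 sites; the isosceles triangle at J_AB = −150, J_AC = −20; a 2-J
square; chains; the fully cumulative-blocked 4-site model) plus seeded random
scalene triangles with |J| uniform in [10, 200] — a realistic exchange range
for oxo-bridged transition-metal clusters in cm⁻¹-scale units. These models
emulate topology and coupling asymmetry only; they do not emulate ab initio
features (ligand fields, anisotropy, charge transfer, more than one J scale
per bond), so a green test establishes correctness of the spin algebra and
blocking logic, not chemical accuracy for any particular compound.

## Known limitations

- Exhaustive ordering search is factorial; beyond 8 sites only pattern
  matching on the given ordering runs.
- Dense diagonalization limits practical sizes to a few thousand CSFs —
  ample for the desk-scale clusters targeted here.
- No thermodynamic observables, no fitting of J to experiment, no
  anisotropic or antisymmetric exchange.
- Degenerate-subspace canonicalization uses only cumulative-site labels;
  accidental degeneracies between states sharing all such labels are left
  in whatever basis `eigh` returns.
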