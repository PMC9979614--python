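# spinblock

Spin-adapted exact diagonalization of isotropic Heisenberg cluster models —
the effective Hamiltonians of polynuclear transition-metal centers such as
Mn₃O₄ cores or Fe₄S₄ cubanes — with a focus on *why and when* the many-body
Hamiltonian matrix becomes block-diagonal, and on how much a wave function
compresses when it does.

It is aimed at quantum/magneto-chemists studying exchange-coupled metal
clusters: people who want the full spin ladder of a small cluster, a spin-pure
basis for a stochastic or iterative CI solver, or a principled way to pick the
site ordering that makes ground *and excited* states single-reference.

## The model

A cluster of `n` magnetic sites with local spins `s_i` (each represented by
`2s_i` singly occupied spin-1/2 orbitals) interacts through

```
H = − Σ_{i<j} J_ij Ŝ_i·Ŝ_j  −  J_Hund Σ_i Σ_{p<q ∈ i} ŝ_p·ŝ_q
```

with `J < 0` antiferromagnetic and `J_Hund ≥ 0` favoring the maximal local
spin (pushing non-Hund states up). The spin-adapted basis is built
genealogically: each electron raises (`u`) or lowers (`d`) the cumulative
spin, and a basis state (CSF) is a non-negative walk `|uududd…⟩` on the
branching diagram ending at the target total spin S. Sector sizes follow the
van Vleck–Sherman ballot count, and CSFs are expanded into determinants by
products of Clebsch–Gordan factors.

The central structural result the package operationalizes: the cumulative
spin square `(Ŝ_1 + … + Ŝ_m)²` commutes with `H` exactly when every site
outside the prefix couples with a single common `J` to all sites inside it.
In a site-separated orbital ordering every CSF is already an eigenfunction of
all cumulative spins, so each such commuting prefix splits the Hamiltonian
into blocks labeled by intermediate spins (`S_A`, `S_AB`, …) — blocks that can
be diagonalized independently, letting a trial CSF target an excited state
directly. For symmetric topologies (dimer, isosceles triangle, 2-J square)
the spectrum also follows in closed form from Kambe vector coupling, which
the package uses as an independent oracle.

## Worked example

Three s=3/2 sites in an isosceles triangle (J_AB = −150, J_AC = J_BC = −20,
arbitrary units), quartet sector:

```python
import numpy as np
from spinblock import (SiteOrdering, build_hamiltonian_csf, detect_blocks,
                       diagonalize, make_preset, target_state)

model = make_preset("isosceles", 3, {"J_AB": -150.0, "J_AC": -20.0})
H = build_hamiltonian_csf(model, SiteOrdering.identity(3), twice_S=3)
print(H.dim)                       # 48  (CSFs with 9 electrons, S = 3/2)

blocks = detect_blocks(H)
hund = [(len(b), lab["twice_prefix_spins"][2])
        for b, lab in zip(blocks.blocks, blocks.labels)
        if lab["first_site_hund"]]
print(sorted(hund))                # [(1, 0), (1, 6), (9, 2), (9, 4)]

w, V = diagonalize(H)
print(round(w[0], 2))              # -562.5  (ground quartet, S_AB = 0)

e, v, k = target_state(H, "uuudduduu")
print(round(e, 2))                 # -432.5  (lowest S_AB = 1 state, reached
                                   #          without touching lower blocks)
```

The 48-dimensional quartet matrix splits into 12 decoupled blocks; the four
first-site-Hund blocks carry intermediate spins 2S_AB = 0, 2, 4, 6 with sizes
1, 9, 9, 1. The ansatz `|uuu,ddu,duu⟩` lies in the 2S_AB = 2 block, so the
block-restricted diagonalization lands on an *excited* state (−432.5) even
though the global ground state (−562.5) lies below it — state-specific
optimization by basis-state choice alone.

The command line mirrors the library:

```bash
spinblock fixtures --seed 0 --out-dir models/
spinblock blocks --model models/isosceles_s32.json
spinblock scan --n-grid 40 --out scan.csv     # L1/L4 compression flip
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, by running the package end to end: the 9-electron CSF sector
sizes at S = 1/2, 3/2, 5/2; the s=3/2 dimer singlet basis size; the multiplet
count of the three-spin vector-coupling ladder; the number of decoupled
first-site-Hund blocks of the isosceles quartet matrix; and the J_AC/J_BC
ratio at which the L1-compression preference between the ABC and ACB
orderings flips (grid scan plus bisection). Results are written as JSON.
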