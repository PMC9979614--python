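"""Cumulative-spin commutator analysis and block detection.

A cumulative spin square (Σ_{i≤m} Ŝ_i)² commutes with the Heisenberg
Hamiltonian whenever every site outside the prefix couples with one common
J value to all sites inside it; a site ordering satisfying this for every
prefix yields a fully blocked spin-adapted matrix.  The first-site operator
Ŝ_1² always commutes (a local spin commutes with each Ŝ_i·Ŝ_j it appears
in), which is why Hund / non-Hund separation survives even for scalene
couplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .model import ClusterModel, SiteOrdering, SpinAdaptedMatrix, build_hamiltonian_sd
from .determinants import csf_matrix, spin_operator_matrices

__all__ = [
    "BlockStructure",
    "cumulative_spin_squared",
    "commutator_norm",
    "commutator_profile",
    "predict_blocking_orderings",
    "PredictedOrdering",
    "detect_blocks",
]


def _operators(model: ClusterModel, ordering: SiteOrdering, twice_M: int):
    partition = ordering.site_partition(model)
    return spin_operator_matrices(model.n_open, partition, twice_M)


def cumulative_spin_squared(
    prefix_len_sites: int,
    model: ClusterModel,
    ordering: SiteOrdering,
    basis: str = "determinant",
    *,
    twice_M: int | None = None,
    twice_S: int | None = None,
) -> np.ndarray | sp.csr_matrix:
    """(Σ_{i≤m} Ŝ_i)² in the determinant or CSF basis.

    In the determinant basis (default) ``twice_M`` selects the sector
    (lowest |M| if omitted).  In the CSF basis ``twice_S`` is required and
    the operator is projected with the orthonormal CSF transform.
    """
    if not 1 <= prefix_len_sites <= model.n_sites:
        raise ValueError(f"prefix_len_sites={prefix_len_sites} out of range")
    if basis == "determinant":
        tM = model.n_open % 2 if twice_M is None else twice_M
        return _operators(model, ordering, tM).prefix_spin_squared(prefix_len_sites)
    if basis == "csf":
        if twice_S is None:
            raise ValueError("twice_S required for the CSF basis")
        from .csf import enumerate_csfs

        csfs = enumerate_csfs(model.n_open, twice_S)
        C = csf_matrix(csfs, twice_M=twice_S)
        P = _operators(model, ordering, twice_S).prefix_spin_squared(prefix_len_sites)
        M = C.T @ (P @ C)
        return 0.5 * (M + M.T)
    raise ValueError(f"unknown basis {basis!r}; use 'determinant' or 'csf'")


def commutator_norm(
    model: ClusterModel,
    ordering: SiteOrdering,
    prefix_len_sites: int,
    twice_M: int | None = None,
) -> float:
    """Relative Frobenius norm ‖[S²_prefix, H]‖_F / ‖H‖_F in the determinant
    basis; ≤ ~1e-10 iff a common eigenbasis exists in the sector."""
    tM = model.n_open % 2 if twice_M is None else twice_M
    H = build_hamiltonian_sd(model, ordering, tM)
    P = _operators(model, ordering, tM).prefix_spin_squared(prefix_len_sites)
    comm = P @ H - H @ P
    h_norm = sp.linalg.norm(H)
    if h_norm == 0.0:
        return 0.0
    return float(sp.linalg.norm(comm) / h_norm)


def commutator_profile(
    model: ClusterModel, ordering: SiteOrdering, twice_M: int | None = None
) -> list[float]:
    """Commutator norms for every prefix length 1..n_sites."""
    return [
        commutator_norm(model, ordering, p, twice_M)
        for p in range(1, model.n_sites + 1)
    ]


def _guaranteed_depth(model: ClusterModel, perm: Sequence[int], rtol: float) -> int:
    """Largest d such that every prefix p ≤ d satisfies the uniform-coupling
    condition: each site after the prefix couples identically to all its
    members.  Prefix 1 (a local spin) and prefix n (total spin) always
    qualify."""
    n = model.n_sites
    scale = max((abs(v) for v in model.couplings.values()), default=0.0)
    tol = rtol * scale

    def prefix_ok(p: int) -> bool:
        if p == 1 or p == n:
            return True
        for k in range(p, n):
            js = [model.coupling(perm[i], perm[k]) for i in range(p)]
            if max(js) - min(js) > tol:
                return False
        return True

    depth = 1
    for p in range(2, n + 1):
        if prefix_ok(p):
            depth = p
        else:
            break
    return depth


@dataclass(frozen=True)
class PredictedOrdering:
    ordering: SiteOrdering
    depth: int
    quasi: bool = False
    coupling_spread: float = 0.0  # max relative J spread tolerated (quasi only)


def predict_blocking_orderings(
    model: ClusterModel,
    rtol: float = 1e-12,
    quasi_rtol: float | None = None,
    max_exhaustive_sites: int = 8,
) -> list[PredictedOrdering]:
    """Site orderings with a guaranteed cumulative-spin blocking depth.

    Exhaustive over permutations up to ``max_exhaustive_sites`` sites,
    deduplicated by automorphisms of the weighted coupling map (orderings
    related by a J- and spin-preserving site relabeling block identically).
    Beyond that only the identity ordering's shell pattern is examined.
    With ``quasi_rtol`` set, orderings whose couplings are equal only within
    that looser tolerance are also returned, flagged ``quasi`` with the
    relative coupling spread attached.
    """
    n = model.n_sites
    if n > max_exhaustive_sites:
        perms: list[tuple[int, ...]] = [tuple(range(n))]
    else:
        perms = [tuple(p) for p in permutations(range(n))]

    autos = _automorphisms(model) if n <= max_exhaustive_sites else []
    seen: set[tuple[int, ...]] = set()
    out: list[PredictedOrdering] = []
    for perm in perms:
        if perm in seen:
            continue
        orbit = {tuple(a[s] for s in perm) for a in autos} or {perm}
        seen |= orbit
        depth = _guaranteed_depth(model, perm, rtol)
        entry = PredictedOrdering(SiteOrdering(perm), depth)
        if quasi_rtol is not None and quasi_rtol > rtol:
            qdepth = _guaranteed_depth(model, perm, quasi_rtol)
            if qdepth > depth:
                entry = PredictedOrdering(
                    SiteOrdering(perm), qdepth, quasi=True, coupling_spread=quasi_rtol
                )
        out.append(entry)
    out.sort(key=lambda e: (-e.depth, e.quasi, e.ordering.permutation))
    return out


def _automorphisms(model: ClusterModel) -> list[tuple[int, ...]]:
    """Site permutations preserving local spins and the coupling map."""
    n = model.n_sites
    autos = []
    for a in permutations(range(n)):
        if any(
            model.site_twice_spins[a[i]] != model.site_twice_spins[i] for i in range(n)
        ):
            continue
        ok = all(
            model.coupling(a[i], a[j]) == model.coupling(i, j)
            for i in range(n)
            for j in range(i + 1, n)
        )
        if ok:
            autos.append(a)
    return autos


@dataclass(frozen=True)
class BlockStructure:
    """Ordered partition of a CSF basis into mutually decoupled blocks."""

    blocks: tuple[tuple[int, ...], ...]
    labels: tuple[dict, ...]  # per block: prefix twice-spin labels + Hund flag

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]

    def block_of(self, index: int) -> int:
        for k, b in enumerate(self.blocks):
            if index in b:
                return k
        raise KeyError(f"index {index} not in any block")

    def to_json_dict(self, basis_labels: Sequence[str] | None = None) -> dict:
        blocks = []
        for k, b in enumerate(self.blocks):
            entry: dict = {
                "indices": list(b),
                "dimension": len(b),
                **self.labels[k],
            }
            if basis_labels is not None:
                entry["csfs"] = [basis_labels[i] for i in b]
            blocks.append(entry)
        return {"n_blocks": self.n_blocks, "blocks": blocks}


def detect_blocks(H: SpinAdaptedMatrix, tol: float = 1e-10) -> BlockStructure:
    """Partition the basis into connected components of the thresholded
    sparsity graph (|H_ij| > tol·max|H|), ordered by smallest member index.

    Each block is labeled with the cumulative-site twice-spin values that are
    constant across its members (always the case for eigen-sector blocks in
    a site-separated ordering) and a Hund flag for the first site.
    """
    A = np.abs(H.matrix)
    scale = A.max() if A.size else 0.0
    adj = sp.csr_matrix(A > tol * scale) if scale > 0 else sp.csr_matrix(A.shape)
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for idx, c in enumerate(comp):
        groups.setdefault(int(c), []).append(idx)
    blocks = sorted(groups.values(), key=lambda g: g[0])

    first_site = H.ordering.permutation[0]
    max_first = H.model.site_twice_spins[first_site]
    labels = []
    for b in blocks:
        lab: dict = {"twice_prefix_spins": {}, "first_site_hund": None}
        if H.site_separated:
            for p in range(1, H.model.n_sites + 1):
                vals = set(int(v) for v in H.prefix_twice_spin_labels(p)[b])
                if len(vals) == 1:
                    lab["twice_prefix_spins"][p] = vals.pop()
            t1 = lab["twice_prefix_spins"].get(1)
            if t1 is not None:
                lab["first_site_hund"] = t1 == max_first
        labels.append(lab)
    return BlockStructure(
        blocks=tuple(tuple(b) for b in blocks), labels=tuple(labels)
    )
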