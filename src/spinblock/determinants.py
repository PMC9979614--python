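"""CSF ↔ determinant algebra for spin-1/2 orbital chains.

Determinants here are spin-flip configurations: every orbital is singly
occupied and only the up/down assignment varies.  A determinant is stored as
an integer bitstring, bit ``k`` = 1 meaning orbital ``k`` carries an α spin.
Since no orbital is ever doubly occupied and no hopping occurs, spins behave
as distinguishable lattice sites and no fermionic sign bookkeeping is needed.

The CSF → determinant expansion is the genealogical Clebsch–Gordan product:
the coefficient of a determinant in a CSF is the product over steps of the
coupling factor for adding one spin-1/2 to the running (S, M) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .csf import CSF

__all__ = [
    "DeterminantExpansion",
    "determinant_basis",
    "expand_csf",
    "csf_matrix",
    "pair_coupling_matrix",
    "spin_operator_matrices",
    "SpinOperators",
]


def determinant_basis(n_open: int, twice_M: int) -> list[int]:
    """All bitstrings with ``n_open`` singly occupied orbitals and spin
    projection ``twice_M``/2, sorted as unsigned integers."""
    if (n_open - twice_M) % 2 != 0 or abs(twice_M) > n_open:
        raise ValueError(f"twice_M={twice_M} infeasible for n_open={n_open}")
    n_up = (n_open + twice_M) // 2
    dets = [sum(1 << i for i in c) for c in combinations(range(n_open), n_up)]
    dets.sort()
    return dets


@dataclass(frozen=True)
class DeterminantExpansion:
    """A CSF expressed in the fixed-M determinant basis."""

    n_open: int
    twice_M: int
    terms: Mapping[int, float]  # bitstring -> coefficient

    def to_vector(self, det_order: Sequence[int]) -> np.ndarray:
        index = {d: i for i, d in enumerate(det_order)}
        v = np.zeros(len(det_order))
        for d, c in self.terms.items():
            v[index[d]] = c
        return v

    def to_json_dict(self) -> dict:
        return {
            "n_open": self.n_open,
            "twice_M": self.twice_M,
            "terms": {
                format(d, f"0{self.n_open}b")[::-1]: c for d, c in self.terms.items()
            },
        }


def _step_factor(step: str, twice_S: int, twice_M: int, up: bool) -> float:
    """Genealogical coupling factor after the step, at the new (2S, 2M).

    u-step α-coefficients are positive; the d-step α-coefficient carries the
    minus sign (a fixed phase convention — only relative phases within a CSF
    are observable).
    """
    if step == "u":
        num = twice_S + twice_M if up else twice_S - twice_M
        return sqrt(num / (2 * twice_S)) if num > 0 else 0.0
    num = twice_S - twice_M + 2 if up else twice_S + twice_M + 2
    c = sqrt(num / (2 * twice_S + 4)) if num > 0 else 0.0
    return -c if up else c


def expand_csf(csf: CSF, twice_M: int) -> DeterminantExpansion:
    """Expand a CSF into determinants at fixed spin projection ``twice_M``/2.

    The result is a unit-norm eigenvector of total S² with eigenvalue
    S(S+1) where 2S is the CSF's final cumulative spin.
    """
    n = csf.n_open
    if abs(twice_M) > csf.twice_s_final or (n - twice_M) % 2 != 0:
        raise ValueError(
            f"twice_M={twice_M} infeasible for CSF {csf.steps!r} "
            f"with twice_S={csf.twice_s_final}"
        )
    terms: dict[int, float] = {}
    for det in determinant_basis(n, twice_M):
        coeff = 1.0
        t_s = 0
        t_m = 0
        for k, step in enumerate(csf.steps):
            up = bool((det >> k) & 1)
            t_m += 1 if up else -1
            t_s += 1 if step == "u" else -1
            if abs(t_m) > t_s:
                coeff = 0.0
                break
            coeff *= _step_factor(step, t_s, t_m, up)
            if coeff == 0.0:
                break
        if coeff != 0.0:
            terms[det] = coeff
    return DeterminantExpansion(n_open=n, twice_M=twice_M, terms=terms)


def csf_matrix(basis: Sequence[CSF], twice_M: int) -> np.ndarray:
    """Orthonormal transform matrix from a CSF basis to the determinant basis.

    Columns are :func:`expand_csf` vectors over the canonical determinant
    order of the common (n_open, twice_M) sector, so ``C.T @ C = I``.
    Returns an ``(n_dets, 0)`` matrix for an empty basis.
    """
    if len(set(c.steps for c in basis)) != len(basis):
        raise ValueError("duplicate CSFs in basis")
    if not basis:
        return np.zeros((0, 0))
    n = basis[0].n_open
    if any(c.n_open != n for c in basis):
        raise ValueError("all basis CSFs must share n_open")
    det_order = determinant_basis(n, twice_M)
    cols = [expand_csf(c, twice_M).to_vector(det_order) for c in basis]
    return np.column_stack(cols)


def pair_coupling_matrix(
    n_open: int,
    weights: Mapping[tuple[int, int], float],
    twice_M: int,
    det_order: Sequence[int] | None = None,
) -> sp.csr_matrix:
    """Sparse matrix of ``Σ w_pq  ŝ_p·ŝ_q`` in the determinant basis.

    Each elementary term is realized as
    ``s_pz s_qz + (s_p⁺ s_q⁻ + s_p⁻ s_q⁺)/2``: a diagonal ±1/4 plus a
    spin-flip off-diagonal 1/2 between determinants with opposite (p, q)
    spins.  This is the workhorse behind Hamiltonians, site spin products
    and cumulative-spin-squared operators.
    """
    if det_order is None:
        det_order = determinant_basis(n_open, twice_M)
    index = {d: i for i, d in enumerate(det_order)}
    m = len(det_order)
    diag = np.zeros(m)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    pairs = [((p, q) if p < q else (q, p), w) for (p, q), w in weights.items()]
    for d in det_order:
        i = index[d]
        for (p, q), w in pairs:
            if w == 0.0:
                continue
            bp = (d >> p) & 1
            bq = (d >> q) & 1
            if bp == bq:
                diag[i] += 0.25 * w
            else:
                diag[i] -= 0.25 * w
                j = index[d ^ (1 << p) ^ (1 << q)]
                rows.append(j)
                cols.append(i)
                vals.append(0.5 * w)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
    mat += sp.diags(diag)
    return mat.tocsr()


def _all_pairs(orbs: Sequence[int]) -> dict[tuple[int, int], float]:
    return {(p, q): 1.0 for p, q in combinations(orbs, 2)}


@dataclass(frozen=True)
class SpinOperators:
    """Determinant-basis realizations of site and cumulative spin operators
    for a contiguous partition of the orbital chain into sites."""

    n_open: int
    twice_M: int
    site_partition: tuple[tuple[int, ...], ...]
    det_order: tuple[int, ...]

    def _pairs(self, weights: Mapping[tuple[int, int], float]) -> sp.csr_matrix:
        return pair_coupling_matrix(self.n_open, weights, self.twice_M, self.det_order)

    def site_dot(self, i: int, j: int) -> sp.csr_matrix:
        """``Ŝ_i · Ŝ_j`` for two distinct sites (sum over orbital pairs)."""
        if i == j:
            raise ValueError("use site_spin_squared for i == j")
        w = {
            (p, q): 1.0
            for p in self.site_partition[i]
            for q in self.site_partition[j]
        }
        return self._pairs(w)

    def site_spin_squared(self, i: int) -> sp.csr_matrix:
        """``Ŝ_i²`` = (3/4)·n_i·1 + 2 Σ_{p<q ∈ i} ŝ_p·ŝ_q."""
        orbs = self.site_partition[i]
        mat = self._pairs({k: 2.0 for k in _all_pairs(orbs)})
        return (mat + 0.75 * len(orbs) * sp.identity(mat.shape[0])).tocsr()

    def intra_site_exchange(self, i: int) -> sp.csr_matrix:
        """``Σ_{p<q ∈ i} ŝ_p·ŝ_q`` — the Hund-term operator for one site."""
        return self._pairs(_all_pairs(self.site_partition[i]))

    def prefix_spin_squared(self, m_sites: int) -> sp.csr_matrix:
        """``(Σ_{i ≤ m} Ŝ_i)²``, the cumulative spin square of the first
        ``m_sites`` sites in partition order."""
        if not 1 <= m_sites <= len(self.site_partition):
            raise ValueError(f"m_sites={m_sites} out of range")
        orbs = [p for site in self.site_partition[:m_sites] for p in site]
        mat = self._pairs({k: 2.0 for k in _all_pairs(orbs)})
        return (mat + 0.75 * len(orbs) * sp.identity(mat.shape[0])).tocsr()

    def total_spin_squared(self) -> sp.csr_matrix:
        return self.prefix_spin_squared(len(self.site_partition))


def spin_operator_matrices(
    n_open: int,
    site_partition: Sequence[Sequence[int]],
    twice_M: int,
) -> SpinOperators:
    """Build the operator factory for a contiguous site partition.

    ``site_partition`` lists each site's orbital indices; they must tile
    ``0..n_open-1`` contiguously in order (the site-separated convention).
    """
    flat = [p for site in site_partition for p in site]
    if flat != list(range(n_open)):
        raise ValueError(
            "site_partition must tile orbitals 0..n_open-1 contiguously in order"
        )
    det_order = tuple(determinant_basis(n_open, twice_M))
    return SpinOperators(
        n_open=n_open,
        twice_M=twice_M,
        site_partition=tuple(tuple(site) for site in site_partition),
        det_order=det_order,
    )
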