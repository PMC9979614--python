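"""Diagonalization, Kambe closed-form spectra, state targeting and
wave-function compression metrics.

The Kambe vector-coupling construction solves symmetric Heisenberg clusters
in closed form by rewriting exchange terms through cumulative-spin squares,
e.g. for the isosceles triangle (J_BC = J_AC)::

    E(S_AB, S) = -J_AB/2 [S_AB(S_AB+1) - 2 s(s+1)]
                 -J_AC/2 [S(S+1) - S_AB(S_AB+1) - s(s+1)]

These ladders serve as independent oracles for the numerical spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .blocking import detect_blocks
from .csf import CSF
from .model import (
    ClusterModel,
    SiteOrdering,
    SpinAdaptedMatrix,
    build_hamiltonian_csf,
    make_preset,
)

__all__ = [
    "KambeLevel",
    "CompressionReport",
    "diagonalize",
    "kambe_spectrum",
    "target_state",
    "compression_report",
    "compression_scan",
]

_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class KambeLevel:
    """One spin multiplet of a vector-coupling ladder."""

    intermediate_twice_spins: tuple[int, ...]
    twice_S_total: int
    energy: float
    degeneracy: int = 1

    @property
    def multiplicity(self) -> int:
        return self.twice_S_total + 1


@dataclass(frozen=True)
class CompressionReport:
    """L1/L4 compression metrics of an L2-normalized CSF-space vector."""

    l1: float
    l4: float
    leading_coeff: float
    leading_csf: str


def _degenerate_clusters(w: np.ndarray) -> list[list[int]]:
    scale = max(1.0, float(np.abs(w).max())) if w.size else 1.0
    clusters: list[list[int]] = []
    for i in range(len(w)):
        if clusters and w[i] - w[clusters[-1][-1]] < _DEGENERACY_RTOL * scale:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return clusters


def diagonalize(H: SpinAdaptedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of a spin-adapted matrix.

    Within each degenerate eigenvalue cluster the eigenvectors are rotated
    to simultaneously diagonalize the cumulative-site spin operators in
    prefix order (these are diagonal in a site-separated CSF basis, with
    eigenvalues read off the genealogical paths).  Compression metrics are
    basis-dependent inside degenerate subspaces; this canonicalization picks
    the prefix-spin eigenstates.
    """
    w, V = np.linalg.eigh(H.matrix)
    if not H.site_separated:
        return w, V
    for cluster in _degenerate_clusters(w):
        if len(cluster) == 1:
            continue
        sub = [cluster]
        for p in range(1, H.model.n_sites + 1):
            d = H.prefix_twice_spin_labels(p).astype(float)
            new_sub: list[list[int]] = []
            for grp in sub:
                Vg = V[:, grp]
                M = Vg.T @ (d[:, None] * Vg)
                lam, U = np.linalg.eigh(0.5 * (M + M.T))
                V[:, grp] = Vg @ U
                # refine grouping by the new labels
                start = 0
                for k in range(1, len(grp) + 1):
                    if k == len(grp) or lam[k] - lam[start] > 1e-6 * max(
                        1.0, abs(lam[start])
                    ):
                        new_sub.append([grp[i] for i in range(start, k)])
                        start = k
            sub = new_sub
    # fix global signs: leading coefficient positive
    lead = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[lead, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return w, V * signs


def _pair_energy(J: float, twice_big: int, twice_a: int, twice_b: int) -> float:
    """-J * <S_a . S_b> via S_a.S_b = (S_ab^2 - S_a^2 - S_b^2)/2."""

    def ss(t: int) -> float:
        return (t / 2) * (t / 2 + 1)

    return -J * 0.5 * (ss(twice_big) - ss(twice_a) - ss(twice_b))


def _hund_energy(model_twice_s: int, n_sites: int, j_hund: float) -> float:
    """Hund-term energy of the all-Hund sector: each site's orbitals couple
    to the maximal local spin s, so sum_{p<q} s_p.s_q = [s(s+1) - 3n/4]/2."""
    s = model_twice_s / 2
    n_orb = model_twice_s
    per_site = 0.5 * (s * (s + 1) - 0.75 * n_orb)
    return -j_hund * n_sites * per_site


def kambe_spectrum(
    preset: str,
    twice_s: int,
    params: dict[str, float],
    j_hund: float = 0.0,
) -> list[KambeLevel]:
    """Closed-form Hund-sector ladder for a Kambe-solvable preset.

    Supported: ``dimer``, ``equilateral``, ``isosceles``, ``square_2J``
    (and the chains that reduce to them).  The scalene triangle admits no
    intermediate-spin closed form and raises ``ValueError``.
    """
    levels: list[KambeLevel] = []
    if preset == "dimer":
        J = float(params["J"])
        e0 = _hund_energy(twice_s, 2, j_hund)
        for tS in range(0, 2 * twice_s + 1, 2):
            E = _pair_energy(J, tS, twice_s, twice_s) + e0
            levels.append(KambeLevel((), tS, E))
    elif preset in ("isosceles", "equilateral"):
        if preset == "equilateral":
            J_AB = J_AC = float(params["J"])
        else:
            J_AB, J_AC = float(params["J_AB"]), float(params["J_AC"])
        e0 = _hund_energy(twice_s, 3, j_hund)
        for t_ab in range(0, 2 * twice_s + 1, 2):
            for tS in range(abs(t_ab - twice_s), t_ab + twice_s + 1, 2):
                E = (
                    _pair_energy(J_AB, t_ab, twice_s, twice_s)
                    + _pair_energy(J_AC, tS, t_ab, twice_s)
                    + e0
                )
                levels.append(KambeLevel((t_ab,), tS, E))
    elif preset == "square_2J":
        J_s, J_l = float(params["J_short"]), float(params["J_long"])
        e0 = _hund_energy(twice_s, 4, j_hund)
        for t13 in range(0, 2 * twice_s + 1, 2):
            for t24 in range(0, 2 * twice_s + 1, 2):
                for tS in range(abs(t13 - t24), t13 + t24 + 1, 2):
                    E = (
                        _pair_energy(J_l, t13, twice_s, twice_s)
                        + _pair_energy(J_l, t24, twice_s, twice_s)
                        + _pair_energy(J_s, tS, t13, t24)
                        + e0
                    )
                    levels.append(KambeLevel((t13, t24), tS, E))
    else:
        raise ValueError(f"preset {preset!r} has no Kambe closed form")
    levels.sort(key=lambda l: (l.energy, l.twice_S_total))
    return levels


def target_state(
    H: SpinAdaptedMatrix, ansatz: CSF | str, tol: float = 1e-10
) -> tuple[float, np.ndarray, int]:
    """Lowest eigenpair of the decoupled block containing the ansatz CSF.

    Only the block's submatrix is diagonalized, so excited states in higher
    blocks are reached without computing any lower block's states.  Returns
    (energy, full-dimension eigenvector, block id).
    """
    idx = H.basis_index(ansatz)
    structure = detect_blocks(H, tol=tol)
    block_id = structure.block_of(idx)
    members = list(structure.blocks[block_id])
    sub = H.matrix[np.ix_(members, members)]
    w, V = np.linalg.eigh(sub)
    vec = np.zeros(H.dim)
    vec[members] = V[:, 0]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    return float(w[0]), vec, block_id


def compression_report(
    vector: np.ndarray, basis: Sequence[CSF] | None = None
) -> CompressionReport:
    """L1 and L4 norms plus the leading CSF of an L2-normalized vector."""
    v = np.asarray(vector, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise ValueError("zero vector has no compression metrics")
    if abs(nrm - 1.0) > 1e-9:
        raise ValueError(f"vector must be L2-normalized (got |v| = {nrm})")
    l1 = float(np.abs(v).sum())
    l4 = float(np.sum(v**4) ** 0.25)
    lead = int(np.argmax(np.abs(v)))
    label = str(basis[lead]) if basis is not None else str(lead)
    return CompressionReport(
        l1=l1, l4=l4, leading_coeff=float(v[lead]), leading_csf=label
    )


def _lowest_state_metrics(
    model: ClusterModel, ordering: SiteOrdering, twice_S: int
) -> CompressionReport:
    H = build_hamiltonian_csf(model, ordering, twice_S)
    w, V = diagonalize(H)
    return compression_report(V[:, 0], H.basis)


def compression_scan(
    j_ab: float = -150.0,
    j_ac: float = -20.0,
    j_bc_range: tuple[float, float] = (-20.0, -150.0),
    twice_s: int = 3,
    twice_S: int = 3,
    orderings: tuple[str, str] = ("ABC", "ACB"),
    n_grid: int = 40,
    bisect_tol: float = 1e-3,
) -> tuple[pd.DataFrame, float | None]:
    """Scan J_BC from the isosceles limit toward/beyond the scalene regime,
    tracking L1/L4 compression of the lowest spin-``twice_S``/2 state in two
    site orderings, and locate the L1 crossing (compression flipping point).

    Returns a table with one row per grid point (columns ``j_bc``, ``ratio``
    = J_AC/J_BC, and ``l1``/``l4``/``leading`` per ordering) and the crossing
    ratio J_AC/J_BC refined by bisection on the L1 difference (None if the
    difference does not change sign on the grid).
    """

    def metrics_at(j_bc: float) -> dict[str, CompressionReport]:
        model = make_preset(
            "scalene", twice_s, {"J_AB": j_ab, "J_AC": j_ac, "J_BC": j_bc}
        )
        out = {}
        for name in orderings:
            ordering = SiteOrdering.from_labels(name, model)
            out[name] = _lowest_state_metrics(model, ordering, twice_S)
        return out

    lo, hi = j_bc_range
    grid = np.linspace(lo, hi, n_grid)
    rows = []
    for j_bc in grid:
        reps = metrics_at(float(j_bc))
        row: dict[str, float | str] = {"j_bc": float(j_bc), "ratio": j_ac / j_bc}
        for name, rep in reps.items():
            row[f"l1_{name}"] = rep.l1
            row[f"l4_{name}"] = rep.l4
            row[f"leading_{name}"] = rep.leading_csf
        row["l1_diff"] = row[f"l1_{orderings[0]}"] - row[f"l1_{orderings[1]}"]
        rows.append(row)
    table = pd.DataFrame(rows)

    diffs = table["l1_diff"].to_numpy()
    crossing = None
    for k in range(len(grid) - 1):
        if diffs[k] == 0.0:
            crossing = j_ac / float(grid[k])
            break
        if diffs[k] * diffs[k + 1] < 0:
            a, b = float(grid[k]), float(grid[k + 1])
            fa = diffs[k]
            while abs(b - a) > bisect_tol:
                mid = 0.5 * (a + b)
                reps = metrics_at(mid)
                fm = reps[orderings[0]].l1 - reps[orderings[1]].l1
                if fa * fm <= 0:
                    b = mid
                else:
                    a, fa = mid, fm
            crossing = j_ac / (0.5 * (a + b))
            break
    return table, crossing
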