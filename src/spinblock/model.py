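"""Heisenberg cluster models, site orderings and Hamiltonian builders.

Sign convention
---------------
The Hamiltonian is ``H = −Σ_{i<j} J_ij Ŝ_i·Ŝ_j − J_Hund Σ_i Σ_{p<q∈i} ŝ_p·ŝ_q``
with ``J < 0`` antiferromagnetic and ``J_Hund ≥ 0`` ferromagnetic within a
site (it favors the maximal local spin and pushes non-Hund states up in
energy).  Every site ``i`` with local spin ``s_i`` is represented by ``2s_i``
singly occupied spin-1/2 orbitals; the site-separated orbital ordering
concatenates each site's orbitals in the order the sites appear.

Energies are reported for the pure exchange operator: the constant
number-operator shift of the spin-free formulation is omitted, and ħ = 1
with J carried in arbitrary units.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .csf import CSF, enumerate_csfs
from .determinants import csf_matrix

__all__ = [
    "ClusterModel",
    "SiteOrdering",
    "SpinAdaptedMatrix",
    "make_preset",
    "make_cumulative_blocked_model",
    "build_hamiltonian_sd",
    "build_hamiltonian_csf",
    "PRESET_NAMES",
]

SIGN_CONVENTION = "H = -sum_{i<j} J_ij S_i.S_j - J_Hund sum_i sum_{p<q in i} s_p.s_q"


def _canon_pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class ClusterModel:
    """A cluster of exchange-coupled local spins.

    Parameters
    ----------
    site_twice_spins:
        ``2s_i`` for each site (a site with 2s_i orbitals of spin 1/2).
    couplings:
        Symmetric exchange map ``{(i, j): J_ij}`` with ``i < j`` after
        canonicalization; absent pairs couple with J = 0.
    j_hund:
        Intra-site ferromagnetic coupling strength (non-negative).
    labels:
        Site display labels; defaults to A, B, C, ...
    """

    site_twice_spins: tuple[int, ...]
    couplings: Mapping[tuple[int, int], float]
    j_hund: float = 0.0
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.site_twice_spins)
        if n == 0:
            raise ValueError("model needs at least one site")
        if any(t <= 0 for t in self.site_twice_spins):
            raise ValueError("site twice-spins must be positive integers")
        canon: dict[tuple[int, int], float] = {}
        for (i, j), v in self.couplings.items():
            if i == j:
                raise ValueError(f"self-coupling on site {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"coupling ({i},{j}) references unknown site")
            key = _canon_pair(i, j)
            if key in canon and canon[key] != v:
                raise ValueError(f"conflicting values for coupling {key}")
            canon[key] = float(v)
        object.__setattr__(self, "couplings", canon)
        if self.j_hund < 0:
            raise ValueError("j_hund must be non-negative")
        if not self.labels:
            object.__setattr__(self, "labels", tuple(_default_labels(n)))
        elif len(self.labels) != n:
            raise ValueError("labels length must match number of sites")

    @property
    def n_sites(self) -> int:
        return len(self.site_twice_spins)

    @property
    def n_open(self) -> int:
        return sum(self.site_twice_spins)

    def coupling(self, i: int, j: int) -> float:
        return self.couplings.get(_canon_pair(i, j), 0.0)

    def label_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown site label {label!r}") from None

    def to_dict(self) -> dict:
        return {
            "sites": list(self.site_twice_spins),
            "couplings": [
                [self.labels[i], self.labels[j], v]
                for (i, j), v in sorted(self.couplings.items())
            ],
            "j_hund": self.j_hund,
            "labels": list(self.labels),
        }


def _default_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"S{i}" for i in range(n)]


@dataclass(frozen=True)
class SiteOrdering:
    """A permutation of site indices; the induced orbital order is the
    site-separated concatenation of each site's orbitals."""

    permutation: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.permutation) != list(range(len(self.permutation))):
            raise ValueError(f"{self.permutation} is not a permutation")

    @classmethod
    def identity(cls, n_sites: int) -> "SiteOrdering":
        return cls(tuple(range(n_sites)))

    @classmethod
    def from_labels(cls, labels_spec: str | Sequence[str], model: ClusterModel) -> "SiteOrdering":
        """Parse 'ACB' or ['A','C','B'] or 'A,C,B' against the model labels."""
        if isinstance(labels_spec, str):
            parts = labels_spec.split(",") if "," in labels_spec else list(labels_spec)
        else:
            parts = list(labels_spec)
        perm = tuple(model.label_index(p.strip()) for p in parts)
        if len(perm) != model.n_sites:
            raise ValueError("ordering must mention every site exactly once")
        return cls(perm)

    def site_partition(self, model: ClusterModel) -> list[list[int]]:
        """Orbital indices per site, in permuted site order."""
        out: list[list[int]] = []
        off = 0
        for site in self.permutation:
            n_orb = model.site_twice_spins[site]
            out.append(list(range(off, off + n_orb)))
            off += n_orb
        return out

    def labels_for(self, model: ClusterModel) -> str:
        return "".join(model.labels[i] for i in self.permutation)


@dataclass(frozen=True)
class SpinAdaptedMatrix:
    """A symmetric operator matrix with its ordered CSF basis and the site
    ordering that produced it.

    ``orbital_permutation`` (optional) records an explicit non-site-separated
    orbital order: position ``k`` of the genealogical chain holds orbital
    ``orbital_permutation[k]`` of the site-separated list.  Prefix-spin
    labels are only defined for site-separated matrices.
    """

    matrix: np.ndarray
    basis: tuple[CSF, ...]
    ordering: SiteOrdering
    twice_S: int
    model: ClusterModel
    orbital_permutation: tuple[int, ...] | None = None

    @property
    def site_separated(self) -> bool:
        return self.orbital_permutation is None or tuple(
            self.orbital_permutation
        ) == tuple(range(self.model.n_open))

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.basis):
            raise ValueError("matrix shape must match basis length")
        scale = np.abs(m).max() if m.size else 0.0
        if scale > 0 and np.abs(m - m.T).max() > 1e-12 * scale:
            raise ValueError("matrix is not symmetric")

    @property
    def dim(self) -> int:
        return len(self.basis)

    def site_boundaries(self) -> list[int]:
        """Cumulative orbital counts at the end of each site in ordering
        order — the step indices at which CSF paths carry cumulative-site
        spin eigenvalues."""
        out: list[int] = []
        off = 0
        for site in self.ordering.permutation:
            off += self.model.site_twice_spins[site]
            out.append(off)
        return out

    def prefix_twice_spin_labels(self, prefix_sites: int) -> np.ndarray:
        """Per-basis-CSF eigenvalue 2S of the cumulative spin of the first
        ``prefix_sites`` sites (exact: read off the genealogical path)."""
        if not self.site_separated:
            raise ValueError(
                "prefix-spin labels are undefined for a non-site-separated "
                "orbital permutation"
            )
        b = self.site_boundaries()[prefix_sites - 1]
        return np.array([c.twice_cumulative[b - 1] for c in self.basis])

    def basis_index(self, csf: CSF | str) -> int:
        steps = csf.steps if isinstance(csf, CSF) else csf
        for k, c in enumerate(self.basis):
            if c.steps == steps:
                return k
        raise KeyError(f"CSF {steps!r} not in basis")


PRESET_NAMES = (
    "dimer",
    "isosceles",
    "equilateral",
    "scalene",
    "square_2J",
    "tetrahedron",
    "chain_open",
    "chain_periodic",
)


def make_preset(
    name: str,
    twice_s: int,
    params: Mapping[str, float] | None = None,
    *,
    j_hund: float = 0.0,
    n_sites: int | None = None,
) -> ClusterModel:
    """Construct a preset cluster topology with uniform local spin.

    Presets and their required ``params`` keys:

    - ``dimer``: ``J``
    - ``isosceles``: ``J_AB``, ``J_AC`` (J_BC = J_AC)
    - ``equilateral``: ``J``
    - ``scalene``: ``J_AB``, ``J_AC``, ``J_BC``
    - ``square_2J``: ``J_short`` (edges AB, BC, CD, DA), ``J_long``
      (diagonals AC, BD)
    - ``tetrahedron``: ``J`` (all six pairs)
    - ``chain_open`` / ``chain_periodic``: ``J`` and ``n_sites``
    """
    params = dict(params or {})

    def need(*keys: str) -> list[float]:
        missing = [k for k in keys if k not in params]
        if missing:
            raise ValueError(f"preset {name!r} requires params {missing}")
        return [float(params[k]) for k in keys]

    if name == "dimer":
        (J,) = need("J")
        coup = {(0, 1): J}
        n = 2
    elif name == "isosceles":
        J_AB, J_AC = need("J_AB", "J_AC")
        coup = {(0, 1): J_AB, (0, 2): J_AC, (1, 2): J_AC}
        n = 3
    elif name == "equilateral":
        (J,) = need("J")
        coup = {(0, 1): J, (0, 2): J, (1, 2): J}
        n = 3
    elif name == "scalene":
        J_AB, J_AC, J_BC = need("J_AB", "J_AC", "J_BC")
        coup = {(0, 1): J_AB, (0, 2): J_AC, (1, 2): J_BC}
        n = 3
    elif name == "square_2J":
        J_s, J_l = need("J_short", "J_long")
        coup = {
            (0, 1): J_s,
            (1, 2): J_s,
            (2, 3): J_s,
            (0, 3): J_s,
            (0, 2): J_l,
            (1, 3): J_l,
        }
        n = 4
    elif name == "tetrahedron":
        (J,) = need("J")
        n = 4
        coup = {(i, j): J for i in range(n) for j in range(i + 1, n)}
    elif name in ("chain_open", "chain_periodic"):
        (J,) = need("J")
        n = int(params.get("n_sites", n_sites or 0))
        if n < 2:
            raise ValueError(f"preset {name!r} requires n_sites >= 2")
        coup = {(i, i + 1): J for i in range(n - 1)}
        if name == "chain_periodic" and n > 2:
            coup[(0, n - 1)] = J
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    return ClusterModel(
        site_twice_spins=tuple([twice_s] * n), couplings=coup, j_hund=j_hund
    )


def make_cumulative_blocked_model(
    site_twice_spins: Sequence[int],
    shell_couplings: Sequence[float],
    m: int | None = None,
    extra_couplings: Mapping[tuple[int, int], float] | None = None,
    j_hund: float = 0.0,
) -> ClusterModel:
    """A Heisenberg Hamiltonian built to commute with cumulative spins.

    Site ``k`` (0-based, k ≥ 1) couples with the single value
    ``shell_couplings[k-1]`` to *every* site among the first
    ``min(k, m)`` sites.  With ``m = n`` (default) the Hamiltonian commutes
    with all cumulative spins S_1², S_12², S_123², …; with smaller ``m``
    only the first ``m`` cumulative spins are guaranteed, and pairs (i, k)
    with ``m ≤ i < k`` may take arbitrary values via ``extra_couplings``.
    """
    n = len(site_twice_spins)
    if n < 2:
        raise ValueError("need at least two sites")
    if len(shell_couplings) != n - 1:
        raise ValueError(f"shell_couplings must have length {n - 1}")
    if m is None:
        m = n
    if not 1 <= m <= n:
        raise ValueError(f"blocking depth m={m} out of range 1..{n}")
    coup: dict[tuple[int, int], float] = {}
    for k in range(1, n):
        for i in range(min(k, m)):
            coup[(i, k)] = float(shell_couplings[k - 1])
    for (i, j), v in (extra_couplings or {}).items():
        i, j = _canon_pair(i, j)
        if i < m:
            raise ValueError(
                f"extra coupling ({i},{j}) conflicts with the uniform shell "
                f"region (first {m} sites)"
            )
        coup[(i, j)] = float(v)
    return ClusterModel(
        site_twice_spins=tuple(site_twice_spins), couplings=coup, j_hund=j_hund
    )


def _exchange_weights(
    model: ClusterModel, ordering: SiteOrdering
) -> dict[tuple[int, int], float]:
    """Orbital-pair weights realizing −Σ J_ij S_i·S_j − J_Hund Σ intra-site."""
    partition = ordering.site_partition(model)
    perm = ordering.permutation
    weights: dict[tuple[int, int], float] = {}
    n_pos = len(perm)
    for a in range(n_pos):
        for b in range(a + 1, n_pos):
            J = model.coupling(perm[a], perm[b])
            if J == 0.0:
                continue
            for p in partition[a]:
                for q in partition[b]:
                    weights[(p, q)] = -J
    if model.j_hund != 0.0:
        for a in range(n_pos):
            orbs = partition[a]
            for x in range(len(orbs)):
                for y in range(x + 1, len(orbs)):
                    weights[(orbs[x], orbs[y])] = -model.j_hund
    return weights


def _permute_weights(
    weights: dict[tuple[int, int], float],
    orbital_permutation: Sequence[int],
    n_open: int,
) -> dict[tuple[int, int], float]:
    """Reassign orbital-pair weights when chain position k holds orbital
    ``orbital_permutation[k]`` of the site-separated list."""
    perm = tuple(orbital_permutation)
    if sorted(perm) != list(range(n_open)):
        raise ValueError("orbital_permutation must permute 0..n_open-1")
    pos_of = {orb: k for k, orb in enumerate(perm)}
    out: dict[tuple[int, int], float] = {}
    for (p, q), w in weights.items():
        a, b = pos_of[p], pos_of[q]
        out[_canon_pair(a, b)] = w
    return out


def build_hamiltonian_sd(
    model: ClusterModel,
    ordering: SiteOrdering,
    twice_M: int,
    orbital_permutation: Sequence[int] | None = None,
) -> sp.csr_matrix:
    """Heisenberg Hamiltonian in the determinant (spin-flip) basis of the
    fixed-M sector, under the orbital order induced by ``ordering`` (and an
    optional explicit non-site-separated orbital permutation on top)."""
    from .determinants import pair_coupling_matrix

    weights = _exchange_weights(model, ordering)
    if orbital_permutation is not None:
        weights = _permute_weights(weights, orbital_permutation, model.n_open)
    return pair_coupling_matrix(model.n_open, weights, twice_M)


def build_hamiltonian_csf(
    model: ClusterModel,
    ordering: SiteOrdering,
    twice_S: int,
    orbital_permutation: Sequence[int] | None = None,
) -> SpinAdaptedMatrix:
    """Heisenberg Hamiltonian in the spin-adapted CSF basis of total spin
    ``twice_S``/2, computed as ``Cᵀ H_sd C`` in the highest-weight sector
    ``twice_M = twice_S`` (complete for spin-S content)."""
    basis = enumerate_csfs(model.n_open, twice_S)
    C = csf_matrix(basis, twice_M=twice_S)
    H_sd = build_hamiltonian_sd(model, ordering, twice_S, orbital_permutation)
    H = C.T @ (H_sd @ C)
    H = 0.5 * (H + H.T)  # scrub antisymmetric round-off
    return SpinAdaptedMatrix(
        matrix=np.asarray(H),
        basis=tuple(basis),
        ordering=ordering,
        twice_S=twice_S,
        model=model,
        orbital_permutation=(
            None if orbital_permutation is None else tuple(orbital_permutation)
        ),
    )
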