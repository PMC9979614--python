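"""Genealogical spin-coupling (CSF) bases for singly occupied orbitals.

A configuration state function (CSF) over ``n`` singly occupied orbitals is a
walk on the branching diagram: each electron either raises (``u``) or lowers
(``d``) the cumulative spin, which must stay non-negative at every step.  The
walk ending at total spin S is a spin eigenfunction with quantum number S.
All spins are carried as *twice*-spin integers so that parity and equality
checks are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

__all__ = [
    "CSF",
    "PrefixConstraint",
    "count_csfs",
    "weyl_paldus_dim",
    "enumerate_csfs",
    "count_constrained_paths",
]


@dataclass(frozen=True)
class CSF:
    """One spin-adapted basis state, written as a u/d step string.

    Parameters
    ----------
    steps:
        String over the alphabet ``{u, d}``; ``u`` couples the next electron
        to raise the cumulative spin by 1/2, ``d`` to lower it.
    """

    steps: str
    twice_cumulative: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cum: list[int] = []
        t = 0
        for k, ch in enumerate(self.steps):
            if ch == "u":
                t += 1
            elif ch == "d":
                t -= 1
            else:
                raise ValueError(f"invalid step {ch!r} at position {k}; expected 'u' or 'd'")
            if t < 0:
                raise ValueError(
                    f"cumulative spin becomes negative at step {k} of {self.steps!r}"
                )
            cum.append(t)
        object.__setattr__(self, "twice_cumulative", tuple(cum))

    @property
    def n_open(self) -> int:
        return len(self.steps)

    @property
    def twice_s_final(self) -> int:
        return self.twice_cumulative[-1] if self.steps else 0

    def __str__(self) -> str:
        return self.steps

    def to_dict(self) -> dict:
        return {"steps": self.steps, "twice_cumulative": list(self.twice_cumulative)}


@dataclass(frozen=True)
class PrefixConstraint:
    """Require the cumulative spin after ``prefix_length`` steps to equal
    ``twice_spin``/2 (e.g. a local-Hund or intermediate-spin condition)."""

    prefix_length: int
    twice_spin: int

    def __post_init__(self) -> None:
        if self.prefix_length <= 0:
            raise ValueError("prefix_length must be positive")
        if self.twice_spin < 0:
            raise ValueError("twice_spin must be non-negative")
        if (self.prefix_length - self.twice_spin) % 2 != 0:
            raise ValueError(
                f"twice_spin={self.twice_spin} has wrong parity for "
                f"prefix_length={self.prefix_length}"
            )


def _validate_sector(n_open: int, twice_S: int) -> None:
    if n_open <= 0:
        raise ValueError("n_open must be a positive integer")
    if twice_S < 0:
        raise ValueError("twice_S must be non-negative")
    if twice_S > n_open:
        raise ValueError(f"twice_S={twice_S} exceeds n_open={n_open}")
    if (n_open - twice_S) % 2 != 0:
        raise ValueError(f"twice_S={twice_S} and n_open={n_open} differ in parity")


def count_csfs(n_open: int, twice_S: int) -> int:
    """Number of CSFs for ``n_open`` singly occupied orbitals at total spin
    ``twice_S``/2 (the van Vleck–Sherman count).

    Implemented as the ballot-number (reflection) closed form
    ``C(n, (n-2S)/2) - C(n, (n-2S)/2 - 1)``, which counts non-negative
    u/d lattice paths of length ``n`` ending at height ``2S``.
    """
    _validate_sector(n_open, twice_S)
    k = (n_open - twice_S) // 2
    return comb(n_open, k) - (comb(n_open, k - 1) if k >= 1 else 0)


def weyl_paldus_dim(N: int, n: int, twice_S: int) -> int:
    """Dimension of the full spin-adapted space of ``N`` electrons in ``n``
    orbitals at total spin ``twice_S``/2, allowing empty and doubly occupied
    orbitals (the Weyl–Paldus formula)::

        D = (2S+1)/(n+1) * C(n+1, N/2 - S) * C(n+1, N/2 + S + 1)

    Note this is the *full-space* dimension; it reduces to :func:`count_csfs`
    only when double occupations are excluded and every orbital is singly
    occupied.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= N <= 2 * n:
        raise ValueError(f"N={N} outside [0, {2 * n}] for n={n} orbitals")
    if twice_S < 0 or twice_S > N:
        raise ValueError(f"twice_S={twice_S} infeasible for N={N} electrons")
    if (N - twice_S) % 2 != 0:
        raise ValueError(f"twice_S={twice_S} and N={N} differ in parity")
    a = (N - twice_S) // 2
    b = (N + twice_S) // 2 + 1
    num = (twice_S + 1) * comb(n + 1, a) * comb(n + 1, b)
    if num % (n + 1) != 0:  # pragma: no cover - Weyl dimension is integral
        raise AssertionError("Weyl-Paldus dimension is not an integer")
    dim = num // (n + 1)
    if dim <= 0:
        raise ValueError(f"no spin-adapted states for N={N}, n={n}, twice_S={twice_S}")
    return dim


def _constraint_map(
    n_open: int, constraints: Iterable[PrefixConstraint]
) -> dict[int, int]:
    cmap: dict[int, int] = {}
    for c in constraints:
        if c.prefix_length > n_open:
            raise ValueError(
                f"constraint prefix_length={c.prefix_length} exceeds n_open={n_open}"
            )
        if c.prefix_length in cmap and cmap[c.prefix_length] != c.twice_spin:
            # contradictory at the same prefix: no path can satisfy both
            cmap[c.prefix_length] = -1
        else:
            cmap.setdefault(c.prefix_length, c.twice_spin)
    return cmap


def enumerate_csfs(
    n_open: int,
    twice_S: int,
    constraints: Sequence[PrefixConstraint] = (),
) -> list[CSF]:
    """All CSFs of the (``n_open``, ``twice_S``) sector satisfying every prefix
    constraint, in lexicographic order of the step string with ``u`` < ``d``.

    Contradictory constraints yield an empty list rather than an error.
    """
    _validate_sector(n_open, twice_S)
    cmap = _constraint_map(n_open, constraints)
    out: list[CSF] = []
    steps: list[str] = []

    def rec(pos: int, t: int) -> None:
        if pos == n_open:
            out.append(CSF("".join(steps)))
            return
        rem = n_open - pos - 1
        for ch, t2 in (("u", t + 1), ("d", t - 1)):
            if t2 < 0:
                continue
            # final-height reachability prune
            if abs(t2 - twice_S) > rem or (rem - (t2 - twice_S)) % 2 != 0:
                continue
            req = cmap.get(pos + 1)
            if req is not None and t2 != req:
                continue
            steps.append(ch)
            rec(pos + 1, t2)
            steps.pop()

    rec(0, 0)
    return out


def count_constrained_paths(
    n_open: int,
    twice_S: int,
    constraints: Sequence[PrefixConstraint] = (),
) -> int:
    """Count branching-diagram paths subject to prefix-spin constraints.

    Dynamic programming over (position, cumulative twice-spin); equals
    ``len(enumerate_csfs(...))`` and reduces to :func:`count_csfs` with no
    constraints.
    """
    _validate_sector(n_open, twice_S)
    cmap = _constraint_map(n_open, constraints)
    # counts[t] = number of admissible prefixes of current length ending at t
    counts = {0: 1}
    for pos in range(1, n_open + 1):
        nxt: dict[int, int] = {}
        for t, c in counts.items():
            for t2 in (t + 1, t - 1):
                if t2 >= 0:
                    nxt[t2] = nxt.get(t2, 0) + c
        req = cmap.get(pos)
        if req is not None:
            nxt = {t: c for t, c in nxt.items() if t == req}
        counts = nxt
        if not counts:
            return 0
    return counts.get(twice_S, 0)
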