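"""Configuration files, fixtures and serialized outputs.

Model config files are JSON::

    {
      "sites": [3, 3, 3],             # per-site twice-spins
      "couplings": [["A", "B", -150.0], ["A", "C", -20.0], ["B", "C", -20.0]],
      "j_hund": 0.0,
      "ordering": ["A", "B", "C"],    # optional
      "twice_S": 3                    # optional
    }

Coupling endpoints may be site labels or 0-based indices.  Unknown keys are
rejected.  Every emitted artifact embeds the convention metadata (sign
convention, J_Hund, ordering, tolerances, version) needed to reproduce it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.io
import scipy.sparse as sp
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .blocking import BlockStructure
from .model import SIGN_CONVENTION, ClusterModel, SiteOrdering, SpinAdaptedMatrix

__all__ = [
    "ModelConfig",
    "RunConfig",
    "read_model_config",
    "write_model_config",
    "generate_fixtures",
    "write_matrix",
    "write_spectrum",
    "write_block_report",
    "convention_metadata",
]


class ModelConfig(BaseModel):
    """Schema for a cluster model file."""

    model_config = ConfigDict(extra="forbid")

    sites: list[int] = Field(min_length=1)
    couplings: list[tuple[Union[int, str], Union[int, str], float]]
    j_hund: float = 0.0
    labels: Optional[list[str]] = None
    ordering: Optional[list[str]] = None
    twice_S: Optional[int] = None

    @field_validator("sites")
    @classmethod
    def _sites_positive(cls, v: list[int]) -> list[int]:
        if any(t <= 0 for t in v):
            raise ValueError("site twice-spins must be positive")
        return v


class RunConfig(BaseModel):
    """Operational settings around a model: tolerances, outputs, seed."""

    model_config = ConfigDict(extra="forbid")

    model_file: Optional[str] = None
    twice_S: Optional[int] = None
    ordering: Optional[list[str]] = None
    block_tol: float = 1e-10
    coupling_rtol: float = 1e-12
    out_dir: str = "."
    seed: int = 0


def _resolve_site(ref: Union[int, str], labels: Sequence[str]) -> int:
    if isinstance(ref, int):
        if not 0 <= ref < len(labels):
            raise ValueError(f"site index {ref} out of range")
        return ref
    try:
        return list(labels).index(ref)
    except ValueError:
        raise ValueError(f"unknown site label {ref!r}") from None


def model_from_config(cfg: ModelConfig) -> tuple[ClusterModel, Optional[SiteOrdering], dict]:
    labels = cfg.labels or [chr(ord("A") + i) for i in range(len(cfg.sites))]
    couplings = {}
    for a, b, J in cfg.couplings:
        i, j = _resolve_site(a, labels), _resolve_site(b, labels)
        couplings[(i, j)] = J
    model = ClusterModel(
        site_twice_spins=tuple(cfg.sites),
        couplings=couplings,
        j_hund=cfg.j_hund,
        labels=tuple(labels),
    )
    ordering = None
    if cfg.ordering is not None:
        ordering = SiteOrdering.from_labels(cfg.ordering, model)
    options = {"twice_S": cfg.twice_S}
    return model, ordering, options


def read_model_config(path: Union[str, Path]) -> tuple[ClusterModel, Optional[SiteOrdering], dict]:
    """Load and validate a model config file; round-trips with
    :func:`write_model_config`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model config not found: {path}")
    cfg = ModelConfig.model_validate_json(path.read_text())
    return model_from_config(cfg)


def write_model_config(
    path: Union[str, Path],
    model: ClusterModel,
    ordering: Optional[SiteOrdering] = None,
    twice_S: Optional[int] = None,
) -> None:
    doc = model.to_dict()
    if ordering is not None:
        doc["ordering"] = [model.labels[i] for i in ordering.permutation]
    if twice_S is not None:
        doc["twice_S"] = twice_S
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def convention_metadata(**extra) -> dict:
    meta = {
        "sign_convention": SIGN_CONVENTION,
        "constant_shift": "omitted (pure exchange operator)",
        "hbar": 1,
        "units": "arbitrary (J carried unchanged)",
        "version": __version__,
    }
    meta.update(extra)
    return meta


def write_matrix(
    path: Union[str, Path],
    H: SpinAdaptedMatrix,
    tol: float = 1e-12,
) -> None:
    """Matrix Market (coordinate, symmetric) plus a JSON sidecar listing the
    CSF labels in row order and the convention metadata.  Entries below
    ``tol``·max|H| are dropped as round-off dust."""
    path = Path(path)
    A = H.matrix.copy()
    scale = np.abs(A).max() if A.size else 0.0
    if scale > 0:
        A[np.abs(A) < tol * scale] = 0.0
    scipy.io.mmwrite(str(path), sp.coo_matrix(A), symmetry="symmetric")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "basis": [str(c) for c in H.basis],
                "twice_S": H.twice_S,
                "ordering": [H.model.labels[i] for i in H.ordering.permutation],
                "j_hund": H.model.j_hund,
                "drop_tolerance_relative": tol,
                "metadata": convention_metadata(),
            },
            indent=1,
        )
        + "\n"
    )


def write_spectrum(
    path: Union[str, Path],
    eigenvalues: np.ndarray,
    H: Optional[SpinAdaptedMatrix] = None,
    **extra,
) -> None:
    doc = {
        "eigenvalues": [float(x) for x in eigenvalues],
        "metadata": convention_metadata(**extra),
    }
    if H is not None:
        doc["twice_S"] = H.twice_S
        doc["ordering"] = [H.model.labels[i] for i in H.ordering.permutation]
        doc["j_hund"] = H.model.j_hund
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def write_block_report(
    path: Union[str, Path],
    structure: BlockStructure,
    H: SpinAdaptedMatrix,
    tol: float,
) -> None:
    doc = structure.to_json_dict(basis_labels=[str(c) for c in H.basis])
    doc["twice_S"] = H.twice_S
    doc["ordering"] = [H.model.labels[i] for i in H.ordering.permutation]
    doc["metadata"] = convention_metadata(block_tolerance_relative=tol)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def generate_fixtures(seed: int, out_dir: Union[str, Path]) -> list[Path]:
    """Write the preset model files used throughout: the spin-3/2 dimer,
    the three triangle topologies, the 2-J square, the tetrahedron, short
    chains, the fully cumulative-blocked 4-site model, plus three seeded
    random scalene variants.  Deterministic given the seed."""
    from .model import make_cumulative_blocked_model, make_preset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    def emit(name: str, model: ClusterModel, twice_S: Optional[int] = None) -> None:
        p = out / f"{name}.json"
        write_model_config(p, model, twice_S=twice_S)
        written.append(p)

    emit("dimer_s32", make_preset("dimer", 3, {"J": -1.0}), twice_S=0)
    emit(
        "isosceles_s32",
        make_preset("isosceles", 3, {"J_AB": -150.0, "J_AC": -20.0}),
        twice_S=3,
    )
    emit("equilateral_s32", make_preset("equilateral", 3, {"J": -1.0}), twice_S=3)
    emit(
        "scalene_s32",
        make_preset("scalene", 3, {"J_AB": -150.0, "J_AC": -20.0, "J_BC": -50.0}),
        twice_S=3,
    )
    emit(
        "square_2J_s32",
        make_preset("square_2J", 3, {"J_short": -1.0, "J_long": -0.4}),
        twice_S=0,
    )
    emit("tetrahedron_s32", make_preset("tetrahedron", 3, {"J": -1.0}), twice_S=0)
    emit("chain3_open_s32", make_preset("chain_open", 3, {"J": -1.0, "n_sites": 3}))
    emit(
        "chain3_periodic_s32",
        make_preset("chain_periodic", 3, {"J": -1.0, "n_sites": 3}),
    )
    emit("chain4_open_s12", make_preset("chain_open", 1, {"J": -1.0, "n_sites": 4}))
    emit(
        "chain4_periodic_s12",
        make_preset("chain_periodic", 1, {"J": -1.0, "n_sites": 4}),
    )
    emit(
        "blocked4_s32",
        make_cumulative_blocked_model((3, 3, 3, 3), [-1.0, -0.5, -0.25]),
        twice_S=0,
    )
    for k in range(3):
        js = -np.sort(rng.uniform(10.0, 200.0, size=3))[::-1]
        emit(
            f"random_scalene_{k}",
            make_preset(
                "scalene",
                3,
                {"J_AB": float(js[0]), "J_AC": float(js[1]), "J_BC": float(js[2])},
            ),
            twice_S=3,
        )
    return written
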