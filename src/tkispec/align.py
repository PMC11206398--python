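"""Rigid superposition of conformer and crystal geometries.

Two alignment routes are provided, mirroring the two ways the quinazoline
series is compared in practice:

* :func:`kabsch_superpose` — least-squares optimal rotation + translation
  over a set of mapped atom pairs (the Kabsch construction via SVD, proper
  rotation branch).
* :func:`plane_anchor_align` — deterministic anchoring on three named atoms
  of the quinazoline core (C1, C4, C10): the anchor plane is brought to
  z = 0 with the first anchor at the origin and the second on the +x axis.
  Anchoring both structures of a pair puts them in a common frame without
  letting flexible appendages (methoxy arms, the halogenated phenyl ring)
  pull the fit.

RMSD is always the root-mean-square deviation over the compared atom subset
after the chosen alignment, in Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .ensembles import CompoundEnsemble, Geometry
from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "AtomMapping",
    "AlignmentResult",
    "kabsch_superpose",
    "plane_anchor_align",
    "rmsd_between",
    "crystal_vs_minimum_rmsd",
]

SubsetPolicy = Literal["all_atoms", "heavy_atoms", "explicit_list"]


@dataclass(frozen=True)
class AtomMapping:
    """Ordered atom-index pairs (index in A, index in B) used for superposition."""

    pairs: tuple[tuple[int, int], ...]
    subset_policy: SubsetPolicy = "explicit_list"

    def __post_init__(self):
        object.__setattr__(
            self, "pairs", tuple((int(i), int(j)) for i, j in self.pairs)
        )
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("atom mapping contains duplicate pairs")
        if len(self.pairs) < 3:
            raise ValidationError("superposition needs >= 3 mapped atom pairs")

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    @classmethod
    def identity(cls, n_atoms: int, policy: SubsetPolicy = "all_atoms") -> "AtomMapping":
        return cls(tuple((i, i) for i in range(n_atoms)), subset_policy=policy)

    @classmethod
    def heavy_atoms(cls, a: Geometry, b: Geometry) -> "AtomMapping":
        """Identity mapping restricted to non-hydrogen atoms.

        Requires identical element ordering in both structures.
        """
        if a.symbols != b.symbols:
            raise ValidationError(
                "heavy-atom mapping requires identical atom ordering; "
                "supply an explicit mapping otherwise"
            )
        return cls(
            tuple((int(i), int(i)) for i in a.heavy_indices),
            subset_policy="heavy_atoms",
        )


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a rigid superposition of B onto A."""

    rmsd: float  # Å
    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, Å
    mapping: AtomMapping
    reflection_suppressed: bool = False  # best unconstrained fit was improper

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation must be proper orthogonal (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform B-frame coordinates into the A frame."""
        return coords @ self.rotation.T + self.translation


def _as_coords(x) -> np.ndarray:
    coords = x.coords if isinstance(x, Geometry) else np.asarray(x, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) coordinates, got shape {coords.shape}")
    return coords


def _check_not_collinear(points: np.ndarray, context: str) -> None:
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateGeometryError(f"{context}: mapped points are collinear or coincident")


def kabsch_superpose(
    a, b, mapping: Optional[AtomMapping] = None
) -> AlignmentResult:
    """Least-squares optimal rigid superposition of B onto A.

    The optimal rotation is built from the SVD of the covariance of the
    centred mapped points; if the unconstrained optimum is a reflection, the
    proper-rotation branch is taken and ``reflection_suppressed`` is set on
    the result. RMSD is evaluated over the mapped atoms after the transform.
    """
    pa = _as_coords(a)
    pb = _as_coords(b)
    if mapping is None:
        if len(pa) != len(pb):
            raise ValidationError("atom counts differ; supply an explicit mapping")
        mapping = AtomMapping.identity(len(pa))
    sel_a = pa[mapping.a_indices]
    sel_b = pb[mapping.b_indices]
    _check_not_collinear(sel_a, "reference")
    _check_not_collinear(sel_b, "moving structure")

    ca = sel_a.mean(axis=0)
    cb = sel_b.mean(axis=0)
    H = (sel_b - cb).T @ (sel_a - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    reflection = d < 0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = sel_b @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - sel_a) ** 2, axis=1))))
    return AlignmentResult(
        rmsd=rmsd,
        rotation=R,
        translation=t,
        mapping=mapping,
        reflection_suppressed=bool(reflection),
    )


def plane_anchor_align(structure, anchor_indices: Sequence[int]) -> np.ndarray:
    """Rigidly move a structure into the canonical frame of three anchor atoms.

    After the transform the first anchor sits at the origin, the second on
    the +x axis, and the anchor plane coincides with z = 0 (third anchor at
    positive y). Collinear anchors raise :class:`DegenerateGeometryError`.
    """
    coords = _as_coords(structure)
    idx = [int(i) for i in anchor_indices]
    if len(set(idx)) != 3:
        raise ValidationError("plane anchoring needs three distinct atom indices")
    p0, p1, p2 = coords[idx[0]], coords[idx[1]], coords[idx[2]]
    ex = p1 - p0
    nx = np.linalg.norm(ex)
    normal = np.cross(ex, p2 - p0)
    nz = np.linalg.norm(normal)
    if nx < 1e-10 or nz < 1e-10:
        raise DegenerateGeometryError("anchor atoms are collinear or coincident")
    ex = ex / nx
    ez = normal / nz
    ey = np.cross(ez, ex)
    basis = np.stack([ex, ey, ez])  # rows are the new axes
    return (coords - p0) @ basis.T


def rmsd_between(a, b, indices: Optional[Sequence[int]] = None) -> float:
    """Plain RMSD over (a subset of) positionally matched atoms — no alignment."""
    pa = _as_coords(a)
    pb = _as_coords(b)
    if pa.shape != pb.shape:
        raise ValidationError("coordinate arrays must have identical shapes")
    if indices is not None:
        pa = pa[list(indices)]
        pb = pb[list(indices)]
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def crystal_vs_minimum_rmsd(
    ensemble: CompoundEnsemble,
    policy: SubsetPolicy = "heavy_atoms",
    anchors: Optional[Sequence[int] | Sequence[str]] = None,
    method: Literal["auto", "plane_anchor", "kabsch"] = "auto",
) -> float:
    """RMSD between a compound's crystal pose and its global-minimum conformer.

    With anchor atoms configured (indices, or names resolved through the
    ensemble's ``atom_map``) both structures are plane-anchored on the
    quinazoline core before the deviation is measured; otherwise a full
    Kabsch superposition is used. ``policy`` selects the compared atom
    subset (default heavy atoms: hydrogen positions from electronic-structure
    optimizations are conformation-noisy).
    """
    crystal = ensemble.crystal_reference
    if crystal is None:
        raise ValidationError(f"ensemble {ensemble.substituent!r} has no crystal_reference")
    gm = ensemble.global_minimum
    ga, gb = gm.geometry, crystal.geometry
    if ga.symbols != gb.symbols:
        raise ValidationError(
            f"ensemble {ensemble.substituent!r}: crystal and minimum atom "
            f"ordering differ; provide an explicit mapping"
        )
    if anchors is not None:
        anchor_idx = [
            ensemble.atom_map[a] if isinstance(a, str) else int(a) for a in anchors
        ]
    else:
        anchor_idx = None
    if method == "auto":
        method = "plane_anchor" if anchor_idx is not None else "kabsch"

    if policy == "heavy_atoms":
        subset = ga.heavy_indices
    elif policy == "all_atoms":
        subset = np.arange(len(ga))
    else:
        raise ValidationError(
            "explicit_list policy requires calling kabsch_superpose with a mapping"
        )

    if method == "plane_anchor":
        if anchor_idx is None:
            raise ValidationError("plane_anchor method requires anchor atoms")
        aa = plane_anchor_align(ga, anchor_idx)
        bb = plane_anchor_align(gb, anchor_idx)
        return rmsd_between(aa, bb, indices=subset)
    mapping = AtomMapping(tuple((int(i), int(i)) for i in subset), subset_policy=policy)
    return kabsch_superpose(ga, gb, mapping).rmsd
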