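"""Rigid-body superposition, RMSD and rotation-angle measurements.

The interdomain rotation between two conformations of the same chain is
quantified with a three-point angle: superpose conformation B onto
conformation A over an *anchor* domain (the part that is held fixed), then
measure the angle at a vertex Cα of the fixed domain between the tip Cα of
the mobile domain in A and the same tip Cα of the superposed B.  This is the
standard way of reporting a hinge rotation as a single number without
committing to a screw-axis decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structio import AtomSelector, CaTrace, SelectionError, StructureModel, resolve_atom

logger = logging.getLogger(__name__)


class GeometryError(Exception):
    pass


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map ``x -> x @ rotation.T + translation``."""

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, after applying the map

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Uses the SVD of the weighted covariance matrix with the usual
    determinant correction so that the returned rotation is proper
    (no reflection).  Degenerate point sets (fewer than 3 points, or all
    points collinear) are rejected because the rotation about the common
    axis would be arbitrary.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("coordinate arrays must both be N×3")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative, length N, not all zero")
        w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    x = mobile - mu_m
    y = reference - mu_r
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    # collinear (or coincident) points: at most one non-negligible singular value
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise GeometryError("degenerate point set (collinear points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def _shared_residues(a: CaTrace, b: CaTrace) -> np.ndarray:
    shared = np.intersect1d(a.residue_numbers, b.residue_numbers)
    if shared.size < len(a) or shared.size < len(b):
        logger.info(
            "residue sets differ (%d vs %d); using %d shared residues",
            len(a),
            len(b),
            shared.size,
        )
    return shared


def rmsd_after_superposition(
    a: CaTrace,
    b: CaTrace,
    selection: tuple[int, int] | None = None,
) -> float:
    """Kabsch-minimised Cα RMSD between two traces over shared residues.

    ``selection`` restricts the comparison to a residue-number interval
    (inclusive).  Residue correspondence is by author residue number.
    """
    shared = _shared_residues(a, b)
    if selection is not None:
        lo, hi = selection
        shared = shared[(shared >= lo) & (shared <= hi)]
    if shared.size < 3:
        raise GeometryError("fewer than 3 shared residues in selection")
    ca = a.select(shared)
    cb = b.select(shared)
    return kabsch(cb.coords, ca.coords).rmsd


def interdomain_angle(
    confA: CaTrace,
    confB: CaTrace,
    anchor: tuple[int, int],
    vertex_res: int,
    tip_res: int,
) -> float:
    """Hinge rotation angle between two conformations, in degrees.

    Conformation B is superposed onto A over the ``anchor`` residue interval
    (the fixed domain); the returned value is the angle at Cα(``vertex_res``)
    of A between Cα(``tip_res``) of A and Cα(``tip_res``) of the superposed
    B.  Symmetric under swapping A and B.
    """
    shared = _shared_residues(confA, confB)
    lo, hi = anchor
    anchor_res = shared[(shared >= lo) & (shared <= hi)]
    if anchor_res.size < 3:
        raise GeometryError("anchor interval covers fewer than 3 shared residues")
    sup = kabsch(
        confB.select(anchor_res).coords, confA.select(anchor_res).coords
    )
    vertex = confA.coords[confA.index_of(vertex_res)]
    tip_a = confA.coords[confA.index_of(tip_res)]
    tip_b = sup.apply(confB.coords[confB.index_of(tip_res)])
    va = tip_a - vertex
    vb = tip_b - vertex
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na < 1e-6 or nb < 1e-6:
        raise GeometryError("vertex coincides with a tip atom")
    cosang = np.clip(va @ vb / (na * nb), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    # report the alternative convention (vertex from superposed B) for awareness
    vertex_b = sup.apply(confB.coords[confB.index_of(vertex_res)])
    vb2 = tip_b - vertex_b
    if np.linalg.norm(vb2) > 1e-6:
        alt = float(
            np.degrees(
                np.arccos(
                    np.clip(
                        (tip_a - vertex_b) @ vb2
                        / (np.linalg.norm(tip_a - vertex_b) * np.linalg.norm(vb2)),
                        -1.0,
                        1.0,
                    )
                )
            )
        )
        logger.debug("angle with vertex from conformation B: %.2f°", alt)
    return angle


def atom_pair_distance(
    model: StructureModel, sel1: AtomSelector, sel2: AtomSelector
) -> float:
    """Euclidean distance in Å between two uniquely selected atoms."""
    p1 = resolve_atom(model, sel1)
    p2 = resolve_atom(model, sel2)
    return float(np.linalg.norm(p1 - p2))
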