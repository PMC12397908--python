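"""Difference-distance-matrix comparison of two conformations.

Pairwise Cα distance matrices describe a conformation in internal
coordinates, so comparing the matrices of two conformations is independent
of any superposition.  Residue pairs whose distance is unchanged belong to
the same rigid body; the segmentation below groups residues into maximal
blocks in which *every* pair moves by at most a threshold.

The segmentation is a deterministic greedy agglomeration: blocks are seeded
from contiguous sequence runs (a rigid domain is mostly sequence-local) and
then allowed to absorb sequence-discontinuous residues, because real domains
are frequently discontinuous (an inserted domain splits its host in two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import CaTrace

logger = logging.getLogger(__name__)

#: Default |ΔD| tolerance for two residues to be called mutually rigid, Å.
DEFAULT_THRESHOLD = 2.0
#: Default minimum rigid-block size, residues.
DEFAULT_MIN_SIZE = 15


class DomainError(Exception):
    pass


@dataclass
class DistanceMatrix:
    residue_numbers: np.ndarray  # (N,)
    values: np.ndarray  # (N, N), Å

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = self.residue_numbers.size
        if self.values.shape != (n, n):
            raise DomainError("matrix shape does not match residue count")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise DomainError("distance matrix must be symmetric")
        if np.any(self.values < 0) or np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise DomainError("distance matrix needs non-negative entries, zero diagonal")


@dataclass
class DiffMatrix:
    """Elementwise |D_A − D_B| between two conformations."""

    residue_numbers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = self.residue_numbers.size
        if self.values.shape != (n, n):
            raise DomainError("matrix shape does not match residue count")


@dataclass
class DomainSegmentation:
    """Per-residue rigid-block labels: 0 = unassigned/flexible, 1..k = blocks."""

    residue_numbers: np.ndarray
    labels: np.ndarray
    threshold: float
    min_size: int

    def blocks(self) -> dict[int, np.ndarray]:
        """Residue numbers per block label (excluding 0)."""
        out = {}
        for lab in np.unique(self.labels):
            if lab == 0:
                continue
            out[int(lab)] = self.residue_numbers[self.labels == lab]
        return out

    @property
    def n_blocks(self) -> int:
        return len(self.blocks())


def ca_distance_matrix(trace: CaTrace) -> DistanceMatrix:
    """All-pairs Cα distance matrix of one trace."""
    if len(trace) < 2:
        raise DomainError("need at least 2 residues")
    values = squareform(pdist(trace.coords))
    return DistanceMatrix(residue_numbers=trace.residue_numbers.copy(), values=values)


def difference_matrix(da: DistanceMatrix, db: DistanceMatrix) -> DiffMatrix:
    """|D_A − D_B| over the shared residue-number set."""
    shared = np.intersect1d(da.residue_numbers, db.residue_numbers)
    if shared.size == 0:
        raise DomainError("no shared residues between the two matrices")
    if shared.size < da.residue_numbers.size or shared.size < db.residue_numbers.size:
        logger.info("residue sets differ; comparing %d shared residues", shared.size)
    ia = _indices_for(da.residue_numbers, shared)
    ib = _indices_for(db.residue_numbers, shared)
    va = da.values[np.ix_(ia, ia)]
    vb = db.values[np.ix_(ib, ib)]
    return DiffMatrix(residue_numbers=shared, values=np.abs(va - vb))


def _indices_for(nums: np.ndarray, wanted: np.ndarray) -> np.ndarray:
    pos = {int(r): i for i, r in enumerate(nums)}
    return np.array([pos[int(r)] for r in wanted], dtype=int)


def segment_rigid_domains(
    diff: DiffMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
) -> DomainSegmentation:
    """Partition residues into rigid blocks from a difference matrix.

    Two residues are *compatible* when their difference-matrix entry is at
    most ``threshold``; a block admits a residue only if it is compatible
    with every current member, so every emitted block is a clique of the
    compatibility graph.  Blocks are grown greedily: first along the
    sequence (contiguous seeding), then by absorbing any remaining residues
    (allowing discontinuous domains).  A residue compatible with several
    blocks goes to the block with the smaller mean difference.  Blocks
    smaller than ``min_size`` are relabelled 0.
    """
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    d = diff.values
    n = d.shape[0]
    compat = d <= threshold
    labels = np.zeros(n, dtype=int)
    blocks: list[list[int]] = []

    # pass 1: contiguous seeds
    i = 0
    while i < n:
        if labels[i] != 0:
            i += 1
            continue
        members = [i]
        j = i + 1
        while j < n and labels[j] == 0 and all(compat[j, m] for m in members):
            members.append(j)
            j += 1
        blocks.append(members)
        lab = len(blocks)
        for m in members:
            labels[m] = lab
        i = j

    # pass 2: refinement sweeps.  Each residue is re-assigned to the
    # compatible block (clique membership against every other member) with
    # the smallest mean difference; this lets blocks absorb
    # sequence-discontinuous residues, dissolves pass-1 singletons, and
    # settles hinge-adjacent residues that are within threshold of both
    # sides onto the block they track most closely.  Sweeps are capped to
    # guarantee termination; assignment order is sequence order, so the
    # result is deterministic.
    for _sweep in range(100):
        changed = False
        for idx in range(n):
            cur = labels[idx]
            best_mean, best_lab = np.inf, cur
            if cur != 0:
                others = [m for m in blocks[cur - 1] if m != idx]
                if others:
                    best_mean = float(d[idx, others].mean())
            for k, members in enumerate(blocks):
                lab = k + 1
                if lab == cur:
                    continue
                others = [m for m in members if m != idx]
                if others and all(compat[idx, m] for m in others):
                    mean = float(d[idx, others].mean())
                    if mean < best_mean - 1e-12:
                        best_mean, best_lab = mean, lab
            if best_lab != cur:
                if cur != 0:
                    blocks[cur - 1].remove(idx)
                blocks[best_lab - 1].append(idx)
                labels[idx] = best_lab
                changed = True
        if not changed:
            break

    # drop undersized blocks, then relabel 1..k in order of first residue
    for k, members in enumerate(blocks):
        if len(members) < min_size:
            for m in members:
                labels[m] = 0
    out = np.zeros(n, dtype=int)
    next_lab = 0
    remap: dict[int, int] = {}
    for idx in range(n):
        lab = labels[idx]
        if lab == 0:
            continue
        if lab not in remap:
            next_lab += 1
            remap[lab] = next_lab
        out[idx] = remap[lab]

    seg = DomainSegmentation(
        residue_numbers=diff.residue_numbers.copy(),
        labels=out,
        threshold=threshold,
        min_size=min_size,
    )
    _assert_block_invariant(seg, d)
    return seg


def _assert_block_invariant(seg: DomainSegmentation, d: np.ndarray) -> None:
    for lab in np.unique(seg.labels):
        if lab == 0:
            continue
        idx = np.flatnonzero(seg.labels == lab)
        sub = d[np.ix_(idx, idx)]
        if sub.max() > seg.threshold + 1e-9:
            raise DomainError(
                f"internal error: block {lab} violates its threshold "
                f"({sub.max():.3f} > {seg.threshold})"
            )
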