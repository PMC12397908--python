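"""Desk-scale synthetic inputs with the geometry and statistics the analyses assume.

Three generators:

* :func:`make_hinge_protein` — a two-conformation, multi-domain Cα model: two
  idealised helical segments joined at a hinge; conformation B rotates the
  second segment rigidly about the hinge and, optionally, relocates a
  C-terminal tail segment to a distinct docking site (mimicking a terminal
  helix that swaps binding pockets between conformations).  Ground-truth
  rigid-block labels are returned so segmentation and morphing can be scored
  exactly.

* :func:`simulate_titration` — fluorescence dilution titrations following the
  quadratic (ligand-depletion) binding model plus i.i.d. Gaussian noise.

* :func:`simulate_itc` — per-injection heats following the one-set-of-sites
  calorimetric model plus i.i.d. Gaussian noise.

Each generator consumes a single integer seed driving one NumPy Generator
stream, so every stochastic test is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import binding
from .structio import CaTrace

# idealised α-helix geometry: 1.5 Å rise and 100° turn per residue on a
# 2.3 Å radius gives consecutive Cα–Cα distances of ≈3.8 Å
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
HELIX_RADIUS = 2.3

#: Minimum allowed non-bonded Cα–Cα distance before the generator retries.
CLASH_DISTANCE = 2.0


class SyntheticError(Exception):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation in signal units + seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SyntheticError("sigma must be non-negative")


@dataclass
class HingePair:
    """Two conformations of one synthetic chain plus ground truth."""

    confA: CaTrace
    confB: CaTrace
    domain_labels: np.ndarray  # per-residue rigid-block id (1-based)
    hinge_angle: float  # degrees
    tail_range: tuple[int, int] | None  # residue-number interval of the tail


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def _ideal_helix(n: int, phase: float = 0.0, z0: float = 0.0) -> np.ndarray:
    i = np.arange(n)
    phi = np.radians(HELIX_TURN_DEG) * i + phase
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(phi),
            HELIX_RADIUS * np.sin(phi),
            z0 + HELIX_RISE * i,
        ]
    )


def _ranked_hinge_axes(
    coords: np.ndarray, n1: int, hinge_angle: float, n_candidates: int = 12
) -> list[np.ndarray]:
    """Candidate hinge axes (unit vectors ⊥ hinge→segment-2 direction).

    All candidates preserve the subtended centroid angle; they are ranked by
    the segment-1 / segment-2 clearance the rotation produces, so the
    clash-free one is tried first.  Purely deterministic.
    """
    from scipy.spatial.distance import cdist

    hinge_pos = coords[n1 - 1]
    v = coords[n1:].mean(axis=0) - hinge_pos
    v = v / np.linalg.norm(v)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, ref)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    scored = []
    for phi in np.linspace(0.0, 2.0 * np.pi, n_candidates, endpoint=False):
        axis = np.cos(phi) * e1 + np.sin(phi) * e2
        rot = _rotation_about_axis(axis, hinge_angle) if hinge_angle > 0 else np.eye(3)
        moved = (coords[n1:] - hinge_pos) @ rot.T + hinge_pos
        clearance = float(cdist(coords[: n1 - 1], moved[1:]).min())
        scored.append((clearance, tuple(axis)))
    scored.sort(reverse=True)
    return [np.array(a) for _, a in scored]


def _min_nonbonded_distance(coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(coords))
    n = d.shape[0]
    d[np.arange(n), np.arange(n)] = np.inf
    d[np.arange(n - 1), np.arange(1, n)] = np.inf
    d[np.arange(1, n), np.arange(n - 1)] = np.inf
    return float(d.min())


def make_hinge_protein(
    n1: int,
    n2: int,
    hinge_angle: float,
    tail_len: int = 0,
    seed: int = 0,
) -> HingePair:
    """Build a two-conformation hinge protein from idealised helices.

    Conformation A is a continuous idealised helix of ``n1 + n2 + tail_len``
    residues.  Conformation B applies a rigid rotation of ``hinge_angle``
    degrees to segment 2 (and tail) about an axis through the hinge Cα (the
    last residue of segment 1), chosen perpendicular to the hinge→segment-2
    direction so that the rotation angle equals the subtended angle of the
    segment-2 centroid.  If ``tail_len`` > 0, the tail is additionally
    relocated rigidly to a docking site alongside segment 1, breaking its
    backbone connection to segment 2 (the trace is flagged accordingly).

    Geometries producing non-bonded Cα contacts below 2.0 Å are retried with
    jittered placement, up to 10 attempts.
    """
    if n1 < 10 or n2 < 10:
        raise SyntheticError("segments need at least 10 residues each")
    if not (0.0 <= hinge_angle < 180.0):
        raise SyntheticError("hinge angle must be in [0, 180)")
    if tail_len < 0:
        raise SyntheticError("tail length must be non-negative")

    rng = np.random.default_rng(seed)
    n_total = n1 + n2 + tail_len
    coords_a = _ideal_helix(n_total)

    labels = np.empty(n_total, dtype=int)
    labels[:n1] = 1
    labels[n1 : n1 + n2] = 2
    if tail_len:
        labels[n1 + n2 :] = 3

    hinge_idx = n1 - 1
    seg2 = slice(n1, n1 + n2)
    tail = slice(n1 + n2, n_total) if tail_len else None

    hinge_pos = coords_a[hinge_idx]
    axis_candidates = _ranked_hinge_axes(coords_a, n1, hinge_angle)

    for attempt in range(10):
        coords_b = coords_a.copy()

        if hinge_angle > 0:
            axis = axis_candidates[attempt % len(axis_candidates)]
            if attempt >= len(axis_candidates):
                axis = axis + 0.15 * rng.standard_normal(3)
                axis = axis / np.linalg.norm(axis)
            rot = _rotation_about_axis(axis, hinge_angle)
            moving = slice(n1, n_total)  # tail follows segment 2 before docking
            coords_b[moving] = (coords_b[moving] - hinge_pos) @ rot.T + hinge_pos

        if tail is not None and tail_len:
            # dock the tail alongside segment 1, roughly antiparallel; each
            # retry rotates the docking direction around segment 1 so the
            # site clears the rotated segment 2
            tail_xyz = coords_b[tail]
            centroid = tail_xyz.mean(axis=0)
            flip = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), 160.0)
            seg1_mid = coords_a[:n1].mean(axis=0)
            base = np.array([2.0 * HELIX_RADIUS + 3.5, 0.0, 0.0])
            spin = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), 36.0 * attempt)
            offset = spin @ base
            if attempt > 4:
                offset = offset + rng.normal(0.0, 1.0, size=3)
            target = seg1_mid + offset
            coords_b[tail] = (tail_xyz - centroid) @ flip.T + target

        if _min_nonbonded_distance(coords_b) >= CLASH_DISTANCE:
            break
    else:
        raise SyntheticError("could not place segments without clashes in 10 attempts")

    resnums = np.arange(1, n_total + 1)
    resnames = np.array(["ALA"] * n_total, dtype=object)
    conf_a = CaTrace("A", resnums, resnames, coords_a)
    conf_b = CaTrace("A", resnums.copy(), resnames.copy(), coords_b)
    tail_range = (n1 + n2 + 1, n_total) if tail_len else None
    return HingePair(
        confA=conf_a,
        confB=conf_b,
        domain_labels=labels,
        hinge_angle=hinge_angle,
        tail_range=tail_range,
    )


def simulate_titration(
    Kd: float,
    L_total: float,
    P_series: np.ndarray,
    F_free: float,
    F_bound: float,
    noise: NoiseSpec = NoiseSpec(),
) -> binding.TitrationCurve:
    """Fluorescence dilution titration under the quadratic binding model."""
    P_series = np.asarray(P_series, dtype=float)
    signal = binding.quadratic_signal(P_series, L_total, Kd, F_free, F_bound)
    signal = np.atleast_1d(np.asarray(signal, dtype=float))
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        signal = signal + rng.normal(0.0, noise.sigma, size=signal.shape)
    return binding.TitrationCurve(P_total=P_series, L_total=L_total, signal=signal)


def simulate_itc(
    Kd: float,
    n: float,
    dH: float,
    cell_conc: float,
    syringe_conc: float,
    injections: np.ndarray,
    V0: float = 200.0,
    noise: NoiseSpec = NoiseSpec(),
) -> binding.ItcExperiment:
    """Per-injection heats under the one-set-of-sites model (μcal)."""
    exp = binding.ItcExperiment(
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=np.asarray(injections, dtype=float),
        cell_volume=V0,
    )
    heats = binding.itc_heats(Kd, n, dH, exp)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        heats = heats + rng.normal(0.0, noise.sigma, size=heats.shape)
    exp.heats = heats
    return exp


def standard_injection_schedule(
    n_injections: int = 18, volume: float = 2.0
) -> np.ndarray:
    """The conventional small-cell ITC schedule: equal-volume injections."""
    return np.full(n_injections, float(volume))
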