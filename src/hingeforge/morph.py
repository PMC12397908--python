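"""Iterative dual-endpoint biased morphing between two conformations.

The protocol finds a plausible transition pathway between two conformations
of the same chain by running *biased* relaxations from both endpoints
simultaneously.  Each iteration:

1. superpose endpoint B onto endpoint A (Kabsch over all shared residues),
   so both ends live in a common frame;
2. compute the per-residue Cα–Cα vectors between the current endpoints;
3. place each endpoint's harmonic bias centers a fraction of the way along
   those vectors toward the *midpoint* between the endpoints (so with
   advance fraction 1 both ends are pulled to the same interpolated
   structure);
4. relax both endpoints under their own elastic network plus the bias;
5. recompute the endpoint Cα RMSD; stop when it drops below the tolerance.

The physical backend is a Cα elastic network (springs between all Cα pairs
within a cutoff, at their native separations) relaxed by overdamped Langevin
dynamics; at temperature 0 the relaxation is a steepest descent.  The bias
logic is independent of the backend, which keeps the iterative protocol —
the part of scientific interest — separate from the force field.

All energies are in reduced units; only the tolerance (Å) and the geometry
are in physical units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryError, kabsch
from .structio import CaTrace

logger = logging.getLogger(__name__)


class MorphError(Exception):
    pass


@dataclass
class MorphParams:
    """Tunable knobs of the morphing protocol (reduced units unless noted)."""

    cutoff: float = 10.0  # Å, ENM spring cutoff
    k_enm: float = 1.0  # ENM contact spring constant
    chain_factor: float = 20.0  # stiffening of sequence-adjacent springs
    k_bias: float = 200.0  # harmonic bias spring constant (must dominate the ENM)
    advance_fraction: float = 0.6  # per-iteration fraction of the way to the midpoint
    steps_per_iteration: int = 400
    strain_release_steps: int = 150  # unbiased ENM steps after each biased relax
    tolerance: float = 1.2  # Å, endpoint RMSD stopping rule
    max_iterations: int = 100
    temperature: float = 0.0  # reduced; 0 = deterministic steepest descent
    dt: float = 0.0025  # integrator step (mobility is 1); dt·k_bias < 1 for stability
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.advance_fraction <= 1.0):
            raise MorphError("advance fraction must be in (0, 1]")
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise MorphError("tolerance and max iterations must be positive")


@dataclass
class EnmSystem:
    """Cα elastic network: springs at native separations within a cutoff.

    Sequence-adjacent (backbone) springs are stiffer than generic contact
    springs — the usual Cα-model device for keeping virtual bond lengths
    near 3.8 Å while the soft collective modes stay soft.
    """

    coords: np.ndarray  # (N, 3) Å — the native (rest) conformation
    pairs: np.ndarray  # (M, 2) int, i < j
    rest_lengths: np.ndarray  # (M,) Å
    k: float  # base (contact) spring constant
    cutoff: float
    k_pairs: np.ndarray | None = None  # (M,) per-spring constants

    def _k(self) -> np.ndarray | float:
        return self.k if self.k_pairs is None else self.k_pairs

    def energy(self, coords: np.ndarray) -> float:
        d = np.linalg.norm(coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]], axis=1)
        return float(0.5 * np.sum(self._k() * (d - self.rest_lengths) ** 2))

    def forces(self, coords: np.ndarray) -> np.ndarray:
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        dvec = coords[i] - coords[j]
        d = np.linalg.norm(dvec, axis=1)
        d = np.maximum(d, 1e-12)
        fmag = -self._k() * (d - self.rest_lengths)  # restoring
        fvec = (fmag / d)[:, None] * dvec
        out = np.zeros_like(coords)
        np.add.at(out, i, fvec)
        np.add.at(out, j, -fvec)
        return out


@dataclass
class BiasState:
    """Per-residue harmonic bias: E = ½·k_bias·Σ|x_i − c_i|²."""

    centers: np.ndarray  # (N, 3) Å
    k_bias: float
    advance_fraction: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centers)):
            raise MorphError("bias centers must be finite")
        if not (0.0 < self.advance_fraction <= 1.0):
            raise MorphError("advance fraction must be in (0, 1]")

    def energy(self, coords: np.ndarray) -> float:
        return float(0.5 * self.k_bias * np.sum((coords - self.centers) ** 2))

    def forces(self, coords: np.ndarray) -> np.ndarray:
        return -self.k_bias * (coords - self.centers)


@dataclass
class MorphResult:
    """Converged (or not) dual-endpoint trajectory pair."""

    trajectory_a: list[CaTrace]
    trajectory_b: list[CaTrace]
    rmsd_series: np.ndarray  # endpoint RMSD after each iteration (index 0 = start)
    converged: bool
    iterations_used: int
    tolerance: float = 1.2

    @property
    def final_rmsd(self) -> float:
        return float(self.rmsd_series[-1])


def build_enm(
    trace: CaTrace,
    cutoff: float = 10.0,
    k: float = 1.0,
    chain_factor: float = 20.0,
) -> EnmSystem:
    """Build the elastic network of a trace.

    Contact springs connect all Cα pairs within ``cutoff`` at their native
    separation with constant ``k``; springs between sequence-adjacent
    residues are stiffened by ``chain_factor`` to preserve virtual bond
    geometry.  Every residue must acquire at least one spring, otherwise
    the network is disconnected and the dynamics ill-posed.
    """
    if cutoff <= 3.8:
        raise MorphError("cutoff must exceed the 3.8 Å Cα–Cα bond distance")
    coords = trace.coords
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
    if pairs.size == 0:
        raise MorphError("no springs within cutoff")
    degree = np.zeros(len(trace), dtype=int)
    np.add.at(degree, pairs.ravel(), 1)
    if np.any(degree == 0):
        lonely = trace.residue_numbers[degree == 0]
        raise MorphError(f"disconnected network: residues {lonely.tolist()} have no springs")
    rest = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    k_pairs = np.full(len(pairs), float(k))
    k_pairs[np.abs(pairs[:, 0] - pairs[:, 1]) == 1] *= chain_factor
    return EnmSystem(
        coords=coords.copy(),
        pairs=pairs,
        rest_lengths=rest,
        k=k,
        cutoff=cutoff,
        k_pairs=k_pairs,
    )


def compute_bias_vectors(current: CaTrace, target: CaTrace) -> np.ndarray:
    """Per-residue vectors from ``current`` to the superposed ``target``.

    The target is first superposed onto the current structure, so any rigid
    part of the difference is removed and the vectors express internal
    deformation only.
    """
    shared = np.intersect1d(current.residue_numbers, target.residue_numbers)
    if shared.size < 3:
        raise GeometryError("fewer than 3 shared residues")
    cur = current.select(shared)
    tgt = target.select(shared)
    sup = kabsch(tgt.coords, cur.coords)
    return sup.apply(tgt.coords) - cur.coords


def relax_step(
    system: EnmSystem,
    bias: BiasState | None,
    coords: np.ndarray,
    n_steps: int,
    temperature: float = 0.0,
    dt: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Overdamped Langevin relaxation under ENM + bias.

    With unit mobility the update is ``x += dt·F + √(2·T·dt)·ξ``.  At
    temperature 0 this is steepest descent; a sustained energy increase then
    indicates an unstable step size and raises.
    """
    coords = np.asarray(coords, dtype=float).copy()
    rng = np.random.default_rng(seed)
    noise_scale = np.sqrt(2.0 * temperature * dt)
    prev_energy = np.inf
    n_increases = 0
    for _ in range(n_steps):
        f = system.forces(coords)
        if bias is not None:
            f = f + bias.forces(coords)
        coords += dt * f
        if temperature > 0:
            coords += noise_scale * rng.standard_normal(coords.shape)
        else:
            e = system.energy(coords) + (bias.energy(coords) if bias else 0.0)
            if e > prev_energy + 1e-12:
                n_increases += 1
                if n_increases > 5:
                    raise MorphError(
                        "energy increased for >5 consecutive descent steps; "
                        "reduce dt or the bias spring constant"
                    )
            else:
                n_increases = 0
            prev_energy = e
    return coords


def _superposed_rmsd(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, float]:
    sup = kabsch(xb, xa)
    moved = sup.apply(xb)
    return moved, float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))


def biased_morph(
    endA: CaTrace,
    endB: CaTrace,
    params: MorphParams | None = None,
) -> MorphResult:
    """Run the iterative dual-endpoint biased morphing protocol.

    Both endpoints keep their own elastic network (rest lengths at their own
    native conformation) and are pulled toward each other by harmonic biases
    whose centers advance along the endpoint-to-endpoint Cα vectors each
    iteration.  Non-convergence within ``max_iterations`` is reported in the
    result, not raised.
    """
    p = params or MorphParams()
    shared = np.intersect1d(endA.residue_numbers, endB.residue_numbers)
    if shared.size < 3:
        raise MorphError("endpoints share fewer than 3 residues")
    ta = endA.select(shared)
    tb = endB.select(shared)

    enm_a = build_enm(ta, cutoff=p.cutoff, k=p.k_enm, chain_factor=p.chain_factor)
    enm_b = build_enm(tb, cutoff=p.cutoff, k=p.k_enm, chain_factor=p.chain_factor)

    xa = ta.coords.copy()
    xb, rmsd = _superposed_rmsd(xa, tb.coords)

    traj_a = [ta.with_coords(xa)]
    traj_b = [tb.with_coords(xb)]
    rmsd_series = [rmsd]

    if rmsd < p.tolerance:
        return MorphResult(traj_a, traj_b, np.array(rmsd_series), True, 0, p.tolerance)

    rng = np.random.default_rng(p.seed)
    seed_a = int(rng.integers(2**31 - 1))
    seed_b = int(rng.integers(2**31 - 1))

    converged = False
    iterations = 0
    for it in range(1, p.max_iterations + 1):
        iterations = it
        # midpoint-directed bias: with advance_fraction 1 both endpoints are
        # pulled to the same interpolated structure
        gap = xb - xa
        centers_a = xa + p.advance_fraction * 0.5 * gap
        centers_b = xb - p.advance_fraction * 0.5 * gap
        bias_a = BiasState(centers_a, p.k_bias, p.advance_fraction)
        bias_b = BiasState(centers_b, p.k_bias, p.advance_fraction)
        xa = relax_step(
            enm_a, bias_a, xa, p.steps_per_iteration, p.temperature, p.dt,
            seed=(seed_a + it) % (2**31 - 1),
        )
        xb = relax_step(
            enm_b, bias_b, xb, p.steps_per_iteration, p.temperature, p.dt,
            seed=(seed_b + it) % (2**31 - 1),
        )
        if p.strain_release_steps:
            # short unbiased relaxation: the stiff local modes (bond and
            # contact geometry) recover their native lengths while the soft
            # collective modes, which carry the transition progress, barely
            # move
            xa = relax_step(
                enm_a, None, xa, p.strain_release_steps, p.temperature, p.dt,
                seed=(seed_a + it + 7919) % (2**31 - 1),
            )
            xb = relax_step(
                enm_b, None, xb, p.strain_release_steps, p.temperature, p.dt,
                seed=(seed_b + it + 7919) % (2**31 - 1),
            )
        xb, rmsd = _superposed_rmsd(xa, xb)
        traj_a.append(ta.with_coords(xa))
        traj_b.append(tb.with_coords(xb))
        rmsd_series.append(rmsd)
        if rmsd < p.tolerance:
            converged = True
            break

    return MorphResult(
        trajectory_a=traj_a,
        trajectory_b=traj_b,
        rmsd_series=np.array(rmsd_series),
        converged=converged,
        iterations_used=iterations,
        tolerance=p.tolerance,
    )


def dual_reference_rmsd(
    trajectory: list[CaTrace], refA: CaTrace, refB: CaTrace
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Kabsch RMSD of a trajectory to two reference conformations.

    Tracking both references shows progress along a transition: frames
    leaving reference A should drift up in the first series and down in the
    second.
    """
    from .geometry import rmsd_after_superposition

    series_a = np.array([rmsd_after_superposition(f, refA) for f in trajectory])
    series_b = np.array([rmsd_after_superposition(f, refB) for f in trajectory])
    return series_a, series_b
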