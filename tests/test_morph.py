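import numpy as np
import pytest
from scipy.stats import spearmanr

from hingeforge.morph import (
    BiasState,
    MorphError,
    MorphParams,
    biased_morph,
    build_enm,
    compute_bias_vectors,
    dual_reference_rmsd,
    relax_step,
)
from hingeforge.structio import CaTrace

from conftest import random_rigid_transform


def make_trace(coords):
    coords = np.asarray(coords, float)
    n = len(coords)
    return CaTrace("A", np.arange(1, n + 1), np.array(["ALA"] * n, dtype=object), coords)


class TestBuildEnm:
    def test_two_residue_network(self):
        sys = build_enm(make_trace([[0, 0, 0], [3.8, 0, 0]]), cutoff=10.0)
        assert len(sys.pairs) == 1
        assert sys.rest_lengths[0] == pytest.approx(3.8)

    def test_rest_state_energy_zero(self, hinge_pair):
        sys = build_enm(hinge_pair.confA)
        assert sys.energy(hinge_pair.confA.coords) == pytest.approx(0.0, abs=1e-12)

    def test_spring_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        # jittered helix so the pair count is irregular
        from hingeforge.synthetic_data import _ideal_helix

        coords = _ideal_helix(40) + rng.normal(0, 0.3, size=(40, 3))
        cutoff = 9.0
        sys = build_enm(make_trace(coords), cutoff=cutoff)
        brute = sum(
            1
            for i in range(40)
            for j in range(i + 1, 40)
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff
        )
        assert len(sys.pairs) == brute

    def test_disconnected_residue_rejected(self):
        coords = [[0, 0, 0], [3.8, 0, 0], [500.0, 0, 0], [503.8, 0, 0]]
        # residues 3,4 form their own component but each still has a spring;
        # a lone far-away residue has none
        lonely = [[0, 0, 0], [3.8, 0, 0], [500.0, 0, 0]]
        with pytest.raises(MorphError, match="disconnected"):
            build_enm(make_trace(lonely), cutoff=10.0)
        build_enm(make_trace(coords), cutoff=10.0)  # no raise


class TestBiasVectors:
    def test_identical_structures_zero(self, hinge_pair):
        v = compute_bias_vectors(hinge_pair.confA, hinge_pair.confA)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_rigid_transform_removed(self, hinge_pair):
        rot, t = random_rigid_transform(np.random.default_rng(1))
        moved = hinge_pair.confA.with_coords(hinge_pair.confA.coords @ rot.T + t)
        v = compute_bias_vectors(hinge_pair.confA, moved)
        assert np.abs(v).max() < 1e-8

    def test_vectors_localised_to_moving_segment(self):
        # the superposition is a global least-squares fit, so it locks onto
        # the larger body; a small rotated segment then carries the vectors
        from hingeforge.synthetic_data import make_hinge_protein

        pair = make_hinge_protein(100, 20, 60.0, tail_len=0, seed=4)
        v = compute_bias_vectors(pair.confA, pair.confB)
        norms = np.linalg.norm(v, axis=1)
        # the global fit spreads some residual over the anchor, but the
        # moving segment must clearly dominate
        assert np.median(norms[:100]) < 0.5 * np.median(norms[100:])


class TestRelaxStep:
    def test_rest_state_is_fixed_point(self, hinge_pair):
        sys = build_enm(hinge_pair.confA)
        out = relax_step(sys, None, hinge_pair.confA.coords, n_steps=50, dt=0.0025)
        np.testing.assert_allclose(out, hinge_pair.confA.coords, atol=1e-12)

    def test_stiff_bias_dominates(self, hinge_pair):
        sys = build_enm(hinge_pair.confA)
        rng = np.random.default_rng(0)
        centers = hinge_pair.confA.coords + rng.normal(0, 1.0, size=(132, 3))
        bias = BiasState(centers, k_bias=1e4, advance_fraction=1.0)
        out = relax_step(
            sys, bias, hinge_pair.confA.coords, n_steps=200, dt=1e-4
        )
        assert np.linalg.norm(out - centers, axis=1).max() < 0.1

    def test_unstable_step_size_raises(self, hinge_pair):
        sys = build_enm(hinge_pair.confA)
        bias = BiasState(hinge_pair.confB.coords, k_bias=1e4, advance_fraction=1.0)
        with pytest.raises(MorphError, match="dt"):
            relax_step(sys, bias, hinge_pair.confA.coords, n_steps=100, dt=0.01)

    def test_thermal_noise_reproducible(self, hinge_pair):
        sys = build_enm(hinge_pair.confA)
        kw = dict(n_steps=20, temperature=0.01, dt=0.0025, seed=42)
        a = relax_step(sys, None, hinge_pair.confA.coords, **kw)
        b = relax_step(sys, None, hinge_pair.confA.coords, **kw)
        np.testing.assert_array_equal(a, b)


class TestBiasedMorph:
    def test_identical_endpoints_converge_immediately(self, hinge_pair):
        res = biased_morph(hinge_pair.confA, hinge_pair.confA)
        assert res.converged
        assert res.iterations_used == 0
        assert res.rmsd_series.tolist() == [pytest.approx(0.0, abs=1e-9)]

    def test_rigid_transform_endpoints_converge_immediately(self, hinge_pair):
        rot, t = random_rigid_transform(np.random.default_rng(5))
        moved = hinge_pair.confA.with_coords(hinge_pair.confA.coords @ rot.T + t)
        res = biased_morph(hinge_pair.confA, moved)
        assert res.converged and res.iterations_used == 0

    def test_hinge_pair_converges(self, hinge_pair):
        res = biased_morph(hinge_pair.confA, hinge_pair.confB, MorphParams(seed=1))
        assert res.converged
        assert res.final_rmsd <= 1.2
        assert res.iterations_used <= 100
        # RMSD decreases monotonically at temperature 0
        assert np.all(np.diff(res.rmsd_series) < 0)

    def test_stiff_limit_single_iteration(self, hinge_pair):
        # with full advance and a dominating bias, one iteration lands both
        # endpoints on the same interpolated structure; strain release is
        # disabled so the bias logic is tested in isolation
        p = MorphParams(
            advance_fraction=1.0, k_bias=1e4, dt=1e-4, steps_per_iteration=100,
            strain_release_steps=0, seed=0,
        )
        res = biased_morph(hinge_pair.confA, hinge_pair.confB, p)
        assert res.converged
        assert res.iterations_used == 1

    def test_endpoint_swap_symmetry(self, hinge_pair):
        finals_fwd, finals_rev = [], []
        for seed in range(5):
            p = MorphParams(seed=seed)
            finals_fwd.append(
                biased_morph(hinge_pair.confA, hinge_pair.confB, p).final_rmsd
            )
            finals_rev.append(
                biased_morph(hinge_pair.confB, hinge_pair.confA, p).final_rmsd
            )
        fwd, rev = np.mean(finals_fwd), np.mean(finals_rev)
        assert abs(fwd - rev) / fwd < 0.10

    def test_no_chain_tearing_outside_relocated_tail(self, hinge_pair):
        res = biased_morph(hinge_pair.confA, hinge_pair.confB, MorphParams(seed=1))
        assert res.converged
        # the tail–body junction is broken by construction in conformation B;
        # every other bond must stay in a physical range throughout, and the
        # elastic energy of the converged endpoints must be finite
        for frame in res.trajectory_a + res.trajectory_b:
            d = np.linalg.norm(np.diff(frame.coords[:120], axis=0), axis=1)
            assert d.min() > 2.5 and d.max() < 5.0
        from hingeforge.morph import build_enm

        enm_a = build_enm(hinge_pair.confA)
        enm_b = build_enm(hinge_pair.confB)
        assert np.isfinite(enm_a.energy(res.trajectory_a[-1].coords))
        assert np.isfinite(enm_b.energy(res.trajectory_b[-1].coords))

    def test_nonconvergence_reported_not_raised(self, hinge_pair):
        p = MorphParams(max_iterations=2, seed=0)
        res = biased_morph(hinge_pair.confA, hinge_pair.confB, p)
        assert not res.converged
        assert res.iterations_used == 2


class TestDualReferenceRmsd:
    def test_reference_frame_distances(self, hinge_pair):
        sa, sb = dual_reference_rmsd(
            [hinge_pair.confA], hinge_pair.confA, hinge_pair.confB
        )
        assert sa[0] == pytest.approx(0.0, abs=1e-9)
        from hingeforge.geometry import rmsd_after_superposition

        assert sb[0] == pytest.approx(
            rmsd_after_superposition(hinge_pair.confA, hinge_pair.confB), abs=1e-9
        )

    def test_rigid_transforms_stay_at_zero(self, hinge_pair):
        rng = np.random.default_rng(3)
        frames = []
        for _ in range(4):
            rot, t = random_rigid_transform(rng)
            frames.append(
                hinge_pair.confA.with_coords(hinge_pair.confA.coords @ rot.T + t)
            )
        sa, _ = dual_reference_rmsd(frames, hinge_pair.confA, hinge_pair.confB)
        np.testing.assert_allclose(sa, 0.0, atol=1e-8)

    def test_morph_trajectory_trends(self, hinge_pair_no_tail):
        res = biased_morph(
            hinge_pair_no_tail.confA, hinge_pair_no_tail.confB, MorphParams(seed=1)
        )
        sa, sb = dual_reference_rmsd(
            res.trajectory_a, hinge_pair_no_tail.confA, hinge_pair_no_tail.confB
        )
        frames = np.arange(len(sa))
        rho_a = spearmanr(frames, sa).statistic
        rho_b = spearmanr(frames, sb).statistic
        assert rho_a > 0.9  # drifting away from its own start
        assert rho_b < -0.9  # approaching the other endpoint
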