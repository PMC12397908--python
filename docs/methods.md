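# Methods

This note documents the models implemented in `hingeforge`, the parameter
choices that matter, and what the synthetic test suite does and does not
establish about real data.

## Structure handling

PDB and mmCIF files are parsed with gemmi into a flat atom-record model.
Author residue numbering (number + insertion code) identifies residues
throughout, matching how residues are cited in structural papers (N118,
K454, …).  Alternative locations are collapsed to the highest-occupancy
conformer (ties broken alphabetically) so all downstream geometry is
single-valued.  Waters are dropped by default; other heteroatom residues
(FAD, nucleotide analogues) are kept because cofactor atoms participate in
distance measurements and line binding interfaces.  Cα traces flag chain
breaks whenever a consecutive Cα–Cα distance leaves [2.5, 4.5] Å rather
than refusing to build — deposited models contain unmodelled loops.

## Rigid-domain segmentation

Given Cα traces of two conformations, the difference matrix
|D_A − D_B| is superposition-independent; residues of one rigid body have
near-zero entries against each other.  Segmentation declares residues i, j
*compatible* when |ΔD|(i,j) ≤ threshold and grows blocks greedily:

1. contiguous sequence runs are grown first, each new residue checked
   against **every** member (blocks are cliques of the compatibility
   graph);
2. refinement sweeps then re-assign every residue to the compatible block
   with the smallest mean difference.  This lets blocks absorb
   sequence-discontinuous members (real domains are frequently
   discontinuous — an inserted domain splits its host), dissolves
   single-residue fragments, and settles hinge-adjacent residues that are
   within threshold of both sides onto the body they track most closely.
   Sweeps run in sequence order and are capped at 100, so the result is
   deterministic;
3. blocks smaller than `min_size` are relabelled 0 (flexible/unassigned).

Defaults: threshold 2.0 Å, min_size 15 residues.  The threshold sits above
the coordinate uncertainty of maps in the 3–4 Å resolution range but well
below hinge-scale motion; the minimum size suppresses spurious blocks in
linkers.  Both are exposed because no universal values exist.  Every
emitted block is re-checked against its own invariant (max intra-block
difference ≤ threshold) before being returned.

## Interdomain rotation angle

The rotation between two conformations is reported as a three-point angle:
superpose B onto A over an anchor interval (the fixed domain, Kabsch
least-squares), then measure the angle at a chosen vertex Cα of A between
the tip Cα of A and the tip Cα of superposed B.  The vertex is taken from
conformation A (the fixed subunit); the value obtained with B's vertex is
logged for comparison.  The measure is symmetric under swapping the
conformations and intentionally avoids a screw-axis decomposition — it is
the number a structural paper quotes, not a full motion model.  Note that
published residue choices can be idiosyncratic (a "tip" residue may fall
inside the anchor's nominal range), so anchor, vertex and tip are always
caller-supplied configuration, never hard-coded.

## Dual-endpoint biased morphing

The transition-path protocol iterates, starting from conformations A and B
of the same chain:

1. superpose endpoint B onto endpoint A over all shared residues;
2. compute per-residue gap vectors g_i = x_i^B − x_i^A;
3. set bias centers c_i^A = x_i^A + (f/2)·g_i and c_i^B = x_i^B − (f/2)·g_i
   with advance fraction f — both centers move toward the per-residue
   *midpoint*, so f = 1 pulls both endpoints onto the same interpolated
   structure (the stiff-bias limit then converges in a single iteration);
4. relax each endpoint under its own elastic network plus the harmonic
   bias E = ½·k_bias·Σ|x_i − c_i|², then release strain with a short
   unbiased relaxation;
5. recompute the endpoint RMSD; stop when it falls below the tolerance.

The backend is a Cα elastic network: springs between all Cα pairs within a
10 Å cutoff, at their native separations, contact constant k = 1 (reduced
units).  Sequence-adjacent springs are stiffened 20× — the standard Cα-model
device that keeps virtual bond lengths near 3.8 Å while leaving the soft
collective modes (the hinge motion) soft.  Relaxation is overdamped
Langevin with unit mobility, x ← x + dt·F + √(2T·dt)·ξ; the default
temperature is 0, making the whole protocol deterministic, and a sustained
energy increase at T = 0 aborts with advice to reduce dt.

Defaults: k_bias = 200, advance fraction 0.6, 400 biased + 150 unbiased
steps per iteration, dt = 0.0025 (stability requires dt·k_bias < 1),
tolerance 1.2 Å, at most 100 iterations.  The tolerance is the stopping
rule of the original protocol; the remaining values were calibrated on the
synthetic hinge suite and are exposed as parameters.  Two of them deserve
comment:

* **k_bias ≫ k_enm.**  The two endpoints carry *different* elastic
  networks (each is at rest in its own conformation).  Wherever the
  networks disagree — most strongly where a segment changes binding site —
  their residual tug sets an RMSD floor; the bias must dominate to push
  the endpoints below the 1.2 Å tolerance.  Weak-bias settings stall at a
  few Å.
* **Strain release.**  A strong bias drags atoms along straight chords of
  what is really a rotation, compressing local geometry.  The short
  unbiased relaxation after each biased step lets the stiff local modes
  recover their native lengths while barely moving the soft modes that
  carry the transition.  With it, all virtual bonds outside a deliberately
  relocated segment stay in [2.5, 5.0] Å along the whole trajectory.

The per-iteration simulation effort of the original all-atom protocol is
not a meaningful quantity for an elastic network, so iteration counts are
not comparable across backends; only the endpoint-RMSD stopping rule
carries over.  The result records both trajectories, the RMSD series, and
a converged flag — non-convergence is reported, not raised.  A companion
`dual_reference_rmsd` computes per-frame RMSD of any trajectory against
both endpoint conformations, the standard way to display progress along a
transition.

Limitations: the pathway is biased toward minimal Cartesian rearrangement
and makes no claim of being a minimum-energy path; there is no excluded
volume, solvent, or sequence specificity.

## Solvent-accessible surface area and interfaces

SASA uses the Shrake–Rupley method: each atom's probe-expanded sphere
(van der Waals radius + 1.4 Å) is sampled with a Fibonacci (golden-spiral)
point lattice, and the accessible fraction is the share of points outside
every neighbour's expanded sphere.  Element-keyed radii follow the common
protein set (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å …); unknown elements
raise unless a fallback radius is supplied.  960 points per atom keep the
isolated-sphere error around 1%; point counts are exposed for convergence
checks.

Buried interface area between two chain groups is computed from three SASA
evaluations, buried = SASA(1) + SASA(2) − SASA(1∪2).  Because the
literature is split between reporting this total and reporting its half
(the per-partner "interface area" convention used by interface servers),
the report always carries both.  Heteroatom residues travel with the chain
that owns them, since cofactors can line the interface.  Contacts are all
inter-group atom pairs within 4.0 Å, sorted by distance.

## Binding models

**Quadratic titration model.**  For 1:1 binding with ligand depletion, the
bound fraction of the fixed species L at titrated protein P is the exact
quadratic root f = [(P+L+K_D) − √((P+L+K_D)² − 4PL)]/(2L), and the signal
is F_free + (F_bound − F_free)·f.  The fit is bounded trust-region least
squares over (K_D, F_free, F_bound) with five log-spaced K_D starts;
standard errors come from the Jacobian covariance at the optimum.
Concentrations are treated as monomer concentrations.  A constant signal
is rejected as unidentifiable, and a K_D landing on a bound is flagged.

**One-set-of-sites ITC model.**  Cumulative heat after injection i follows
the Wiseman isotherm
Q = (n·M_t·ΔH·V0/2)·[1 + X_t/(n·M_t) + K_D/(n·M_t) − √((…)² − 4X_t/(n·M_t))]
at the post-injection total concentrations, which include the perfusion
dilution of an overfilled cell (each injection of dV multiplies cell
contents by 1 − dV/V0, applied cumulatively).  Per-injection heats are
ΔQ(i) = Q(i) − Q(i−1) + (dV_i/V0)·(Q(i)+Q(i−1))/2, the last term being the
heat carried out with displaced volume; refining a schedule into smaller
injections converges to a schedule-independent profile.  The fit is over
(K_D, n, ΔH), same optimizer strategy; the c-value n·M_t/K_D is reported
and a value outside [1, 1000] triggers a warning because the isotherm then
carries little information about K_D.  The cell volume defaults to 200 μl
(nominal small-cell instrument); it is configuration, not constant.

**Identifiability at the standard design.**  At the regime used for the
bundled simulations (cell 70 μM, syringe 700 μM, 18×2 μl) and per-injection
noise of 2% of the largest heat, the Cramér–Rao bound on K_D already
implies a best-case median relative error of ≈6% at K_D = 3.4 μM (c ≈ 18)
and ≈10% at K_D = 0.42 μM (c ≈ 100): most injections sit on the plateaus,
and only the few transition points inform K_D.  The test suite therefore
checks the ITC fitter for *efficiency* — its median error over 100 seeded
replicates must stay within 1.6× the bound — rather than for an accuracy
the data cannot support.  The quadratic titration model, whose 38-point
dilution series spreads information across the whole curve, reaches ~3%
median error at the same relative noise.

## Synthetic data

`make_hinge_protein` builds the two-conformation test system: a continuous
idealised helix (rise 1.5 Å, 100° turn, radius 2.3 Å → 3.8 Å Cα spacing)
split into two rigid segments at a hinge residue.  Conformation B rotates
segment 2 rigidly about an axis through the hinge Cα, chosen perpendicular
to the hinge→segment-2 direction so the subtended centroid angle equals
the requested hinge angle; candidate axis orientations are ranked by the
segment–segment clearance they produce and tried in order, with jitter on
late retries, until the structure is clash-free (non-bonded Cα pairs
≥ 2.0 Å).  An optional C-terminal tail is additionally relocated as a
rigid body to a docking site alongside segment 1 — emulating a terminal
helix that changes binding pockets — which deliberately breaks its
backbone junction (the trace is flagged).  Ground-truth labels make
segmentation and morph tests exact.

Titration and ITC simulators add i.i.d. Gaussian noise from a single
seeded stream; defaults for demonstration fixtures are 1–2% of the signal
range.  What the synthetic suite shows: the algorithms recover known
ground truth under the stated geometric and noise models.  What it cannot
show: robustness to coordinate error correlated with map quality,
non-Gaussian instrument baselines, oligomer bookkeeping (monomer vs dimer
concentrations), or conformational heterogeneity within one "state".

## Numerical conventions

* Kabsch superposition uses the SVD with determinant correction; fewer
  than 3 points or collinear point sets are rejected (the rotation would
  be arbitrary around the common axis).  An independent quaternion
  eigenvalue implementation serves as the test oracle.
* Residue correspondence between conformations is by author residue
  number; mismatched sets use the intersection and log it.
* All random behaviour flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated calls are bit-identical.
* Å for lengths, degrees for angles, μM/μl/kcal·mol⁻¹/μcal for binding
  quantities; elastic-network energies are in reduced units.
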