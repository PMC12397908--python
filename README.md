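# hingeforge

Tools for dissecting large-scale conformational changes between two
conformations of one protein chain, and for fitting the binding isotherms
that usually accompany such studies.

The motivating system is the bacterial tRNA-modifying MnmE–MnmG complex:
upon binding its partner, one subunit of the MnmE dimer undergoes a ~112°
rotation of its helical domain relative to the N-terminal domain, while a
C-terminal "swivel" helix relocates from one cofactor pocket to another.
Characterising that kind of transition needs four bespoke computations that
`hingeforge` packages as reusable, tested code:

1. **Rigid-domain detection** from Cα difference-distance matrices.  The
   pairwise Cα distance matrix describes a conformation in internal
   coordinates, so the elementwise difference |D_A − D_B| between two
   conformations is superposition-independent: near-zero blocks mark rigid
   bodies.  `segment_rigid_domains` turns that matrix into per-residue
   rigid-block labels.
2. **Interdomain rotation angle**: superpose conformation B onto A over an
   anchor domain, then measure the angle at a vertex Cα between the two
   positions of a tip Cα (`interdomain_angle`).
3. **Dual-endpoint biased morphing** (`biased_morph`): an iterative
   protocol that runs biased relaxations from *both* endpoints — superpose,
   compute per-residue Cα–Cα vectors, advance harmonic bias centers along
   them, relax each endpoint on its own Cα elastic network, repeat — until
   the endpoint RMSD drops below a tolerance (default 1.2 Å).
4. **Binding isotherm fitting**: the quadratic (ligand-depletion) equation
   for fluorescence titrations,
   f = [(P+L+K_D) − √((P+L+K_D)² − 4PL)]/(2L),
   and the one-set-of-sites (Wiseman) model for ITC per-injection heats,
   both as simulators and bounded least-squares fitters with multi-start.

Supporting modules handle PDB/mmCIF I/O (via gemmi), Kabsch superposition,
Shrake–Rupley solvent-accessible surface area and buried interface areas,
and a synthetic-data generator that builds two-conformation hinge proteins
with known ground truth plus noisy titration/ITC data.

## Worked example

```python
import numpy as np
from hingeforge import (
    make_hinge_protein, ca_distance_matrix, difference_matrix,
    segment_rigid_domains, interdomain_angle, biased_morph, MorphParams,
    simulate_titration, fit_quadratic,
)

# two conformations of a 132-residue chain: 60+60-residue segments related
# by a 60° hinge rotation, plus a 12-residue tail that changes binding site
pair = make_hinge_protein(n1=60, n2=60, hinge_angle=60.0, tail_len=12, seed=1)

diff = difference_matrix(ca_distance_matrix(pair.confA),
                         ca_distance_matrix(pair.confB))
seg = segment_rigid_domains(diff, threshold=2.0, min_size=15)
print(seg.n_blocks)                       # 2
print(np.unique(seg.labels, return_counts=True))
# (array([0, 1, 2]), array([12, 60, 60])) — both segments recovered,
# the 12-residue tail is below min_size and stays unassigned

print(interdomain_angle(pair.confA, pair.confB,
                        anchor=(1, 60), vertex_res=60, tip_res=90))
# 59.99928844838902 — the generating hinge angle

result = biased_morph(pair.confA, pair.confB, MorphParams(seed=1))
print(result.converged, result.iterations_used, round(result.final_rmsd, 3))
# True 51 1.165 — endpoints meet below the 1.2 Å stopping tolerance

curve = simulate_titration(Kd=74.0, L_total=1.0,
                           P_series=400.0 / 2.0 ** np.arange(13),
                           F_free=1000.0, F_bound=3000.0)
print(round(fit_quadratic(curve).Kd, 3))  # 74.0 — exact recovery, no noise
```

## Command line

Every analysis is also exposed as a `hingeforge` subcommand:
`inspect`, `simulate`, `domains`, `angle`, `dist`, `morph`, `interface`,
`fit-titration`, `fit-itc`.  For example:

```sh
hingeforge simulate hinge --seed 1 --out-prefix hinge
hingeforge domains hinge_A.pdb hinge_B.pdb --threshold 2.0 --min-size 15
hingeforge morph hinge_A.pdb hinge_B.pdb --tol 1.2 --seed 1 --out-prefix run1
```

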