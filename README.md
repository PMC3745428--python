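# raydock

Shape-complementarity docking of small molecules into protein surface
pockets by ray casting, with particle-swarm pose optimization — a
self-contained implementation of the DARC (Docking Approach using Ray
Casting) scoring and docking scheme.

`raydock` is aimed at structure-based virtual screening against shallow
surface pockets, such as those targeted by small-molecule inhibitors of
protein–protein interactions, where fast low-resolution pose search
matters more than detailed energetics.  It maps a pocket once, as a set
of rays cast from an origin buried inside the protein, then scores and
docks thousands of rigid ligand conformers against that map without ever
touching the protein structure again.

## The method

**Pocket mapping.**  A grid (0.5 Å spacing) over the target site labels
points protein (P) or solvent (S) from atom coordinates and van der
Waals radii.  Solvent points flanked by protein along a scan line become
*pocket* points; pocket points touching the protein form the pocket
*shell*, and a collar of surface points just outside the pocket becomes
the *forbidden* set.  An origin is placed 30 Å from the pocket center of
mass toward the protein center of mass, and every shell/forbidden point
is stored as a ray (θ, φ, ρ) in spherical coordinates about it — the
pocket topography as seen from the protein interior.

**Scoring.**  For a ligand pose, each ray's first intersection distance
d with the ligand's atom spheres is compared with its stored surface
distance ρ.  With constants c₁, c₂, c₃, c₄ = 1.0, 1.4, 21.6, 9.5, a
pocket ray contributes c₁(d − ρ) for a gap (unpacking), c₂(ρ − d) for a
penetration (clash), or c₃ on a miss (pocket unfilled); a forbidden ray
contributes c₄ if hit and is otherwise excluded from the normalization.
The DARC score is the mean contribution over contributing rays — 0 is a
perfect shape complement, lower is better.  Conservative per-pose
angular bounds let rays that cannot hit the ligand skip their
intersection tests ("ray elimination") without changing the score, and a
two-stage batch scorer evaluates a whole swarm at once as a rays × poses
contribution table followed by a per-pose reduction.

**Docking.**  Each rigid conformer is docked by particle swarm
optimization over translation + rotation (defaults: 200 particles, 200
iterations, Clerc constriction), the best conformer is kept per
compound, and a library screen ranks compounds by best score, flagging
the top 10% as hits.

## Worked example

The package generates its own analytic fixture: a pocket whose ray
distances are the exact first-hit distances of a known single-sphere
ligand, so the planted pose is a perfect shape complement.

```sh
$ raydock synth --n-pocket-rays 500 --seed 7 \
    --out-rayfile pocket.rays --out-ligand ligand.pdb
planted pose: 0,0,12,0,0,0

$ raydock score --rayfile pocket.rays --ligand ligand.pdb --pose 0,0,12,0,0,0
conformer 1: total 0.000000 (500 contributing rays)

$ raydock score --rayfile pocket.rays --ligand ligand.pdb --pose 0,0,13,0,0,0
conformer 1: total 3.533840 (500 contributing rays)

$ raydock dock --rayfile pocket.rays --ligand ligand.pdb \
    --n-particles 50 --n-iterations 50 --seed 1 --out dock.tsv
best score 0.000513 (conformer 1)
```

At the planted pose every pocket ray meets the ligand exactly where it
meets the pocket wall, so the score is 0 over all 500 contributing rays.
Pulling the ligand 1 Å out of the pocket costs 3.53 score units per ray
on average (a mix of unpacking and outright misses).  The swarm, knowing
nothing of the planted pose, recovers it: `dock.tsv` reports the best
pose at translation (0.0003, 0.0005, 12.000) with score 0.0005 after
50×50 evaluations.

For a real protein you would start from a PDB file instead:

```sh
raydock make-rayfiles --protein target.pdb --chain A --residue 105 --out pocket.rays
raydock screen --rayfile pocket.rays --library-dir conformers/ \
    --seed 1 --out screen.tsv
```

## Layout

- `raydock.structures` — PDB/SDF input, radii assignment
- `raydock.pocket` — grid labeling, pocket/shell/forbidden extraction
- `raydock.rays` — spherical rays and the rayfile text format
- `raydock.scoring` — pose scoring, ray elimination, batch scorer
- `raydock.pso` — particle swarm docking and library screening
- `raydock.fixtures` — analytic fixtures and the brute-force oracle
- `raydock.cli` — the `raydock` command

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and known limitations.
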