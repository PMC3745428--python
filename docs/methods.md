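# Methods

## The model

`raydock` scores and docks rigid small-molecule conformers into protein
surface pockets using shape complementarity alone, evaluated by ray
casting.  The pocket is described once, as a set of rays cast from an
origin buried inside the protein toward points on the pocket surface; a
ligand pose is then scored by how well the distances at which those same
rays first strike the ligand match the stored distances to the pocket
wall.  This viewpoint — the pocket topography as seen from the protein
interior — is the DARC family of scoring functions.  The score carries no
electrostatics, chemistry, or flexibility; it is a fast, low-resolution
objective meant for pose search and coarse ranking, not for binding
free-energy prediction.

### Pocket mapping

A cubic lattice (default spacing 0.5 Å, half-extent 15 Å) is centered on
the centroid of a user-chosen target residue.  Each grid point is labeled
protein (P) when it lies within the van der Waals radius of any atom
(inclusive boundary, a deterministic tie rule) and solvent (S) otherwise.
An S point becomes a *pocket* point when protein flanks it on both sides
along at least one scan line — the protein–solvent–protein criterion of
the LIGSITE family of pocket detectors.  Seven scan directions are used
(the 3 axes plus the 4 body diagonals) with a default maximum flank
distance of 12 grid steps; both are configuration parameters, since
pocket detectors in this family vary in exactly these choices.  With the
nearest flanking P point taken on each side, the intervening points are
necessarily non-protein, so no separate gap test is needed and marking is
order-independent.

The pocket *shell* is the set of pocket points with at least one
face-adjacent P neighbor.  The shell is reduced to its largest connected
component under 26-neighbor connectivity; face (6-neighbor) connectivity
was rejected for this filter because a discretized curved surface is one
sheet under vertex adjacency but shatters into dozens of fragments under
face adjacency, which would defeat the filter's purpose (removing stray
disjoint pockets).  Contact definitions themselves (shell and forbidden)
remain face-based.  *Forbidden* points are surface solvent points
(face-adjacent to P) within `ring_width × spacing` (default 2 steps =
1 Å) of a shell point: a thin collar around the pocket mouth marking
where a bound ligand should not protrude.

The ray origin is placed 30 Å from the shell center of mass along the
direction toward the protein center of mass.  Both centers of mass are
unweighted coordinate means: mass weighting would move them by far less
than the 30 Å offset and would add a dependency on element masses for no
observable benefit.  The pocket center uses shell points only (not all
pocket points), keeping it tied to the surface the rays must describe.

### Rays and the rayfile

Each shell point defines a *pocket* ray and each forbidden point a
*forbidden* ray: direction in spherical coordinates about the origin
(theta from +z in [0°, 180°], phi from +x in (−180°, 180°], phi pinned to
0 at the poles) plus the distance rho from origin to the defining point.
Rays whose (theta, phi) agree after rounding to 10⁻⁶ degrees collapse to
the nearer point, since the farther one is shadowed.  A typical real
pocket at 0.5 Å spacing yields on the order of 7,000 rays.

The rayfile is a versioned text format — header `DARC_RAYFILE v1`, an
`origin x y z` line, then one `kind theta phi rho` record per ray — with
fixed 6-decimal fields.  Parsing a written file and re-writing it is
byte-stable, because each field re-formats to the same 6-decimal string.

### Scoring

For a posed ligand, every ray gets the first-intersection distance d
against the ligand's atom spheres (smallest positive root of the
ray–sphere quadratic; tangency counts as a hit).  Contributions are:

| condition | contribution | contributes to normalization |
|---|---|---|
| pocket ray, hit at d ≥ rho | c1 · (d − rho)  (unpacking) | yes |
| pocket ray, hit at d < rho | c2 · (rho − d)  (clash) | yes |
| pocket ray, miss | c3 (pocket unfilled) | yes |
| forbidden ray, hit | c4 (ligand overflows pocket) | yes |
| forbidden ray, miss | 0 | no |

with defaults c1, c2, c3, c4 = 1.0, 1.4, 21.6, 9.5.  The pose score is
the sum of contributions divided by the number of contributing rays;
0 is a perfect shape complement and lower is better.  The distance-linear
form of the unpacking and clash terms is the simplest form consistent
with the four conditions; all four weights are configurable so alternate
forms can be explored.  Forbidden rays are penalized for any
intersection, at any depth — penalizing only hits beyond the forbidden
point would be a plausible alternative, but the flat penalty is the
stricter and simpler reading.  An absent or far-away ligand scores
exactly c3: every pocket ray misses, no forbidden ray contributes.

Two numerical guarantees matter for testing and are implemented
explicitly.  First, when every contributing ray has the same contribution
the mean is returned as that value exactly, rather than through a
summation that would accumulate round-off (this makes the all-miss score
exactly c3 and the planted fixture's score exactly 0.0).  Second, the
stored rho values in the planted fixture are computed with the same
operation ordering as the scorer's quadratic, so the perfect-complement
score is exact to the bit, not merely small.

### Ray elimination

Given a pose, each atom at distance d > r from the origin subtends a cone
of half-angle α = asin(r/d) about its center direction.  The theta extent
of the cone is [theta_c − α, theta_c + α]; its azimuth extent is
asin(sin α / sin theta_c), the exact bounding-box half-width of a
spherical cap, falling back to all azimuths when the cap touches a pole
or when the union of atom intervals crosses the ±180° cut.  The union box
over atoms, padded by a 10⁻⁶-degree safety margin so grazing rays are
never pruned, is a conservative bound: any ray outside it cannot
intersect the ligand and is treated as a miss without an intersection
test.  Elimination is therefore exactly score-neutral — the test suite
asserts bitwise equality with and without it — and only reduces work,
which is the same trade the method's CPU implementation makes.

### Batch (swarm) scoring

Scoring a swarm decomposes into two stages: stage 1 computes the
(n_rays × n_poses) contribution table, each ray independent of every
other; stage 2 reduces each pose's column to its mean over contributing
rays.  Stage 1 deliberately does no ray elimination so the per-ray
workload is uniform across poses — the decomposition that makes the score
embarrassingly parallel.  The implementation vectorizes over rays in
chunks of 1024 to bound the (rays × poses × atoms) intermediate.  At the
standard operating point (7,000 rays, 30 atoms, 200 particles) one pass
touches 6,000 swarm atoms per ray and produces 1,400,000 ray
contributions per iteration; a full 200-iteration run evaluates 40,000
poses and 8.4×10⁹ candidate ray–atom tests.

### Pose optimization

Docking is rigid-body search over a 6-vector pose (3 translations, 3
extrinsic z-y-x rotation angles about the conformer centroid) by particle
swarm optimization with Clerc constriction: χ = 0.7298, c_p = c_g = 2.05,
velocity clamped to half of each dimension's range.  These are the
standard constriction-PSO settings; the original method's exact PSO
variant is not pinned down publicly, so the defensible textbook variant
is used and every hyperparameter is exposed in `PSOConfig`.  Translation
bounds default to the bounding box of the pocket-ray surface points
padded by 2 Å; rotations wrap modulo 2π, translations clip to the bounds
with the clipped velocity component zeroed.  Personal and global bests
update only on strict improvement, so ties keep the incumbent and the
global-best trajectory is non-increasing by construction.

Each iteration scores the whole swarm (one batch call), updates bests,
and steps, so a run evaluates exactly n_particles × n_iterations poses
(defaults 200 × 200 = 40,000).  `n_iterations = 0` is a degenerate mode
that scores the initial swarm once and reports its best.  Conformers of a
compound are docked serially and independently, conformer k reusing the
run seed offset by k; a library screen offsets the seed per compound by a
stride of 10007 (an arbitrary prime larger than any per-compound
conformer count).  All randomness flows from `PSOConfig.seed` through
`numpy.random.default_rng`, so every result is reproducible bit for bit.

Screening ranks compounds by best score ascending (ties broken by input
order, for determinism) and flags the top ceil(hit_fraction · N) as hits,
default hit fraction 10%.

## Synthetic fixtures

The test and acceptance inputs are generated, not stored.

**Planted fixture.**  A single-sphere "ligand" of radius r sits at
distance D along +z from the origin (defaults r = 2 Å, D = 12 Å).  Pocket
rays are Fibonacci-spiral directions inside a cone about +z (default
half-angle 8°, necessarily less than asin(r/D) ≈ 9.6° so every ray hits),
with rho set to the closed-form first-hit distance
t(u) = u·c − sqrt((u·c)² − D² + r²).  Forbidden rays ring the cone 10°
outside the ligand's angular radius, so they are guaranteed misses.  The
planted pose therefore scores exactly 0, any displacement scores
positive, and the known translation makes pose-recovery measurable.  A
single sphere is used deliberately: it is the only ligand for which exact
zero is achievable along every ray; multi-sphere ligands are exercised
through the oracle-scored decoy library instead.

**Decoy library.**  Random multi-sphere compounds (radii 1.4–2.0 Å,
~1.5 Å step chains, 1–3 rigid-rotation conformers each) stand in for a
screening deck.  They share nothing with the planted complement, so a
screen containing both must rank the complement first.

**Toy receptor.**  A slab of pseudo-atoms (radius 1.7 Å) on a 0.5 Å
simple-cubic lattice, with a hemispherical pit carved from the top face
by removing atoms within pit_radius + atom_radius of the face midpoint.
The accessible cavity boundary then tracks the analytic sphere of radius
pit_radius, and the full analytic surface (sphere patch joined to the
flat face at z = atom_radius) gives an exact distance oracle for shell
validation.  The atom lattice is aligned with the default grid so the
flat face cannot alias into spurious one-point "pockets"; a pit radius of
0 carves nothing and must yield no pocket.

**Brute-force oracle.**  `brute_force_score` re-implements the score as
explicit ray → atom → root loops with no vectorization, batching, or
elimination, and is kept independent of the production scorers so the two
code paths can be checked against each other (agreement to ≤10⁻⁹
relative on random poses; in practice ~10⁻¹⁵).

### What the fixtures do and do not show

The fixtures are purely geometric.  Passing tests demonstrate that the
grid labeling, ray geometry, score arithmetic, pruning, batching, and
optimizer behave exactly as specified, and that the optimizer reliably
recovers a planted optimum in a smooth single-atom landscape.  They say
nothing about chemistry: no protonation, charge, flexibility, solvation,
or the rugged multi-atom score landscapes of real pockets.  Scoring-level
behavior on realistic geometry is exercised through the toy receptor and
multi-sphere decoys, but screening enrichment on real targets is outside
what synthetic data can establish.

## Problem sizes used in the checks

Scorer-equivalence and elimination checks use 100 random poses over
planted fixtures of 150–330 rays.  Pose recovery runs the full standard
operating point (200 particles × 200 iterations) over 20 seeds, with
success defined as the planted translation recovered within 0.5 Å.
Convergence medians use 10 seeds at (200 p, 200 i), (200 p, 10 i) and
(10 p, 200 i).  Pocket-marking is verified against the line-scan oracle
on 21³ grids with 12 random atoms, and the toy pit uses a 6 Å pit in a
24×24×12 Å slab (~52,000 atoms, 61³ grid).  The synthetic screen ranks
the planted complement against 9 decoys at 50 particles × 50 iterations.
These sizes keep a full verification run to a few minutes while
exercising every code path at the method's standard settings.

## Known limitations

- The score's unpacking/clash terms are linear in the distance mismatch;
  the original implementation's exact functional form is not publicly
  machine-readable, and only the four conditions and constants are pinned.
- Forbidden-ray penalties ignore intersection depth.
- Uniform-angle initialization of Euler rotations is not uniform over
  SO(3); acceptable for a local search seeded across the whole range, and
  documented rather than corrected.
- Pocket-mapping scan directions and maximum flank span are family-level
  conventions, not canonical values; both are exposed as configuration.
- No post-docking all-atom refinement or re-ranking is included; the
  package ends where shape-only scoring ends.
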