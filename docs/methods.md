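# Methods

`casim` is a Monte Carlo model of chromosome-aberration formation in an
irradiated interphase nucleus.  It chains five stages — genome geometry,
ion-track irradiation, DSB induction, stochastic repair, aberration
classification — and a dose-response analysis layer.  This note documents
the model, its parameters, the numerical choices, and what the package's
synthetic conditions do and do not represent.

## Genome geometry

The nucleus is a water-filled sphere or ellipsoid with semi-axes `(x, y, z)`
in µm, centred at the origin.  Chromatin is a coarse-grained polymer: one
monomer represents 2 kbp of DNA and sits on a cubic lattice of 20 nm pitch
(10 nm of fibre per kbp).  The default karyotype is a 46,XY human male
genome using GRCh38 chromosome lengths and approximate centromere midpoints
(5.96 Gbp, ~2.98 × 10⁶ monomers); a 46,XX variant (+1.7 % DNA) and reduced
equal-length fixtures are provided.  Monomer count — and therefore DNA
content and expected damage — is invariant under all geometry changes.

Each chromosome owns a *territory*: an ellipsoid similar in shape to the
nucleus, with volume proportional to chromosome length (radius ∝ L^{1/3},
i.e. uniform DNA density across territories; pure radius ∝ L would make 46
disjoint territories unpackable).  Territory radii are defined in a
reference 6 µm sphere and every axis scales linearly with the nuclear
semi-axes, so halving the nucleus halves every territory.  The summed
territory volume is 15 % of the nuclear volume — chosen once, comfortably
below the ~38 % jamming density of random sequential addition so that
placement (largest-first, uniform rejection sampling in the shape-scaled
frame, 10⁴ retries per territory) always succeeds.  Because all territories
share the nucleus shape, containment and pairwise-overlap tests are exact
sphere tests in the scaled frame.

Conformations are random walks on the lattice: the first monomer is uniform
in the territory; the chain then alternates 60-monomer loops (120 kbp) and
60-monomer linkers.  A loop is generated brute force — fresh 59-step
candidates until the 60th monomer lands on a lattice neighbour of the loop
start (exact coincidence is impossible for an odd step count on a cubic
lattice, so adjacency is the closure criterion); the retry budget is 10⁶.
Any proposed step leaving the nucleus is rejected and resampled; with the
*no-intermingling* option the walk is also confined to its territory.
Unconstrained walks wander out of their territory (the intermingling
fraction is reported per genome), which deliberately over-represents
intermingling for small nuclei; the two modes bound the real situation.
One conformation per geometry is the default protocol (repeat builds with
different seeds vary yields within statistical error); the seed is exposed.
No intermediate chromatin organisation (compartments, TADs) is modelled.

## Irradiation

Beams are mono-energetic ions specified by (species, energy in MeV/n, LET in
keV/µm); a registry of 16 standard space-radiation beams from 0.22 to
195 keV/µm is built in.  Dose, fluence and LET are related by
`D[Gy] = 1.6×10⁻⁹ · φ[cm⁻²] · LET[keV/µm]`.  The number of tracks crossing
the parallelepiped irradiation volume (lateral side ≥ 15 µm, enclosing the
nucleus) is Poisson with mean fluence × face area; entry points are uniform
on the face; tracks are straight full-length chords (the registered beams
have ranges ≥ 3 cm, so curvature and stopping are negligible on nuclear
scales).  The mean number of *nuclear* traversals is fluence × π·a·b with
a, b the semi-axes perpendicular to the beam.

Energy deposition uses an amorphous radial-dose model rather than
event-by-event electron transport: a fraction f = 0.5 of the LET is
deposited uniformly within the core radius r_c = 0.0116·β µm (β the ion
speed) and the rest follows 1/r² out to the penumbra radius
r_p = 0.0616·E^1.7 µm (the maximum δ-ray range).  Dose is scored in
20 nm voxels.  Because tracks are axis-aligned chords, the voxel dose is
invariant along the beam axis and the grid is stored as a lateral 2D map;
the 3D (i, j, k) interface is preserved.

Discretisation and energy closure: each track's lateral kernel assigns the
central voxel the analytic energy within half a voxel width and the
off-centre voxels the 1/r² profile at their centre distance, rescaled so
the kernel total equals the analytic energy within the near-field cutoff
(2 µm by default); kernels are placed with periodic lateral wrapping; the
energy beyond the cutoff is spread uniformly over the lateral cell.  The
wrap-plus-bath construction realises the periodic-boundary contract: every
track deposits exactly LET × (volume length along the beam), so the
ensemble-mean scored dose equals the prescribed dose identically, and the
expected dose at any interior point is the prescribed dose.  The surrogate
reproduces the core/penumbra structure and exact energy balance but not the
stochastic clustering of real δ-ray transport — absolute aberration yields
and LQ coefficients are therefore *not* expected to match values computed
with full track-structure codes; size, shape, orientation and intermingling
comparisons are the intended use.  An optional stochastic-deposition mode
re-samples voxel energies as discrete ~60 eV events for rougher
microdosimetric texture (off by default).

## DSB induction

Each monomer receives N ~ Poisson(Q · D_voxel) breaks, with D_voxel the
dose of the voxel containing the monomer centre and Q = 1.14 × 10⁻⁵ Gy⁻¹,
the break intensity per unit dose calibrated so a uniformly irradiated
human genome accumulates ≈35 DSB/Gy/cell at low LET (with the GRCh38
karyotype: 34.0).  Because total energy is conserved, the expected yield is
Q · n_monomers · D for every nuclear geometry — damage *amount* is
geometry-independent; only its spatial pattern varies.  Breaks in voxels at
or above 500 eV deposited energy per slab (≈10⁴ Gy voxel dose) are
*complex*, the rest *simple*; only complex breaks can misrejoin.  Multiple
breaks per monomer are allowed (relevant only at high LET) and receive
distinct uniform genomic offsets within the monomer's 2 kbp.  Sampling uses
the Poisson-total + inverse-CDF allocation, distributionally identical to
independent per-monomer draws.

## Repair

Each break has two cognate free ends at the break position.  Over a 24 h
horizon (configurable; lymphocyte protocols use ~50 h) in δt = 1 s steps:

* each *simple* pair closes properly with probability δt/τ1, τ1 = 1.7 h;
* each open *complex* end fires with probability 0.5·δt/τ2, τ2 = 23.7 h
  (the 0.5 compensates double-counting of end pairs); a fired end picks a
  partner among all other open complex ends — its cognate included, at
  r = 0 — with Gaussian proximity weight I(r) = (1/W)·exp(−r²/σ²),
  W = 50, σ² = 0.8 µm².  The cognate choice restores the break; any other
  closes an improper junction.

Kernel normalisation was a genuinely open design point.  The weights are
normalised by default, so a fired end always closes and the complex-break
population decays as exp(−t/τ2) — consistent with the bi-exponential
kinetics N(t) = N1·e^{−t/τ1} + N2·e^{−t/τ2} that the repair constants were
calibrated against, with N1/N2 the simple/complex counts.  The alternative
reading, implemented behind `normalize_kernel=False`, treats each I(r) as
an absolute per-candidate probability with an abort branch
(p_j = I_j / max(ΣI, 1)); it preserves a role for the absolute scale W but
at W = 50 closes only a few percent of complex ends per τ2, which is
irreconcilable with the stated kinetics — hence not the default.
Misrepair can be disabled entirely (cognate-only channel at the same rate)
for kinetics verification.

Ends closed earlier in a step are out of play later in that step (random
per-step processing order).  The production driver does not sweep 86 400
steps: simple-pair closure steps are geometric variates, and complex firing
steps are sampled as geometric waiting times in the any-end-fires
probability with the firing set drawn from the exact conditional binomial
law — distributionally identical to the literal sweep (which is also
implemented and statistically cross-checked against it).  Ends still open
at the horizon are scored unrepaired.

## Aberration classification

Chromosomes are partitioned at break positions into segments; logged
junctions glue segment ends; following the junctions yields linear
fragments (terminated by telomeres or open ends) and circular ones.
Categories, which are not mutually exclusive:

* *simple exchange*: a connected component of exactly 2 breaks on 2
  chromosomes under improper junctions (dicentric/translocation formers);
* *complex exchange*: a component of >2 breaks on ≥2 chromosomes;
  single-chromosome components are intrachanges, tallied separately and
  never as exchanges;
* *dicentric*: fragment with ≥2 centromeres; *ring*: circular fragment
  (centric if it carries a centromere); *translocation*: linear fragment
  joining ≥2 chromosomes with exactly one centromere; *inversion*:
  fragment containing material of one chromosome in both orientations;
  *deletion*: acentric fragment; *intact* / *properly repaired*: complete
  single chromosome with zero / only-restoring junctions.

Genome length and centromere number are conserved exactly in every
assembly.  Fragments of any size are counted by default; a minimum-
fragment-size filter (e.g. a 10 Mbp FISH-like detection limit) is available
but off.  The classifier is verified against an independent bead-level
enumerator over all end pairings of ≤4 breaks on ≤3 chromosomes.

## Dose response

An experiment runs a dose ladder (default 7 points, 0.05–1 Gy:
{0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0}) with many histories per dose
(default 1 000 at desk scale; 10⁴ is the full-scale setting), seeding each
history from (master seed, dose index, history index) via SeedSequence
splitting so runs are reproducible and parallelisable.  Per category the
mean yield, its standard error, and the mean scored dose Dav (the LQ
regressor; within ~1 % of the prescription) are aggregated.

y(Dav) = α·Dav + β·Dav² is fitted by weighted least squares (weights
1/SE²; equal weights when SEs are zero) with a parametric bootstrap
(resample each point from Normal(mean, SE), ≥1000 refits) supplying SDs and
percentile 95 % intervals; β may be negative.  Population averaging over a
distribution of nuclear radii is the frequency-weighted pointwise mean with
SEs combined in weighted quadrature.  The simple:complex ratio "at one
traversal" inverts the linear λ(D) for the dose giving one mean nuclear
traversal and evaluates both fits there.

## Problem sizes and numerical notes

* Default test/acceptance runs use scaled-down ensembles (hundreds of
  histories per condition, single 1 Gy dose point for trend comparisons);
  statistical assertions use 3-SE bands.
* The walk kernel is JIT-compiled (numba) with its own seeded RNG stream;
  a full 46-chromosome genome builds in ~15 s and is cached per geometry.
* The near-field kernel cutoff (2 µm) bounds per-track cost; for low-LET
  beams most penumbra energy is carried by the uniform wrapped bath, which
  is exact in total energy but flattens far-penumbra texture.
* Degenerate inputs: zero dose yields zero tracks/breaks everywhere;
  a break at bp 0 is disallowed (offsets are kept interior); coincident
  breakpoints on one chromosome are rejected; an end appearing in two
  junctions raises an inconsistent-log error.

## Known limitations

* Absolute α/β values depend on the track-structure surrogate and the
  normalisation reading of the proximity kernel; only structural and
  comparative behaviour is validated.
* The deterministic amorphous track confines all above-threshold (complex)
  damage to a single 20 nm core column, whereas event-by-event transport
  scatters complex clusters over the δ-ray range.  Combined with the
  recurrence of the lattice walk, short-chord (thin-axis) traversals
  produce same-chromosome break multiplets — intrachanges — where spread
  clusters would hit distinct chromosomes.  Size, volume and intermingling
  comparisons survive this distortion; the beam-orientation comparison of
  simple-exchange yields in strongly flattened nuclei does not (the model
  shows no significant short-vs-long-axis excess), and is exercised by a
  deliberately strict test that documents the discrepancy.
* No chromatin motion, repair-pathway biology, cell-cycle or survival
  effects; repair constants are fibroblast-derived and fixed across cell
  types.
* Chromosome territories are rigid similar ellipsoids at fixed positions;
  real territories deform, tile the nucleus, and intermingle at their
  edges rather than wholesale.
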