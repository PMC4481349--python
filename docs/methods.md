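# Methods

## Scope and data model

The package post-processes coordinate trajectories; it never runs
dynamics.  Coordinates are used exactly as stored (Å), so periodic
boundaries must be unwrapped beforehand (ligand whole, protein whole) —
re-imaging is deliberately out of scope.  Distances are Å, times ns,
angles degrees everywhere; internal radians are never exposed.  Atom
masses default to standard atomic weights keyed by element symbol and may
be overridden per atom.

A trajectory is a topology (`AtomRecord`: chain, 1-based residue id, atom
name, element, mass) plus time-ordered frames.  Multi-model PDB is the
native format; XTC/DCD/TRR go through the same MDAnalysis adapter with a
PDB topology.  PDB carries no time axis, so frame *i* is stamped
(i+1)·frame_interval with a default interval of 0.01 ns (one stored frame
per 10 ps).

## Pocket distances and occupancy labels

The tracked probe is the centre of mass of the last three heavy atoms of
the acyl chain (configurable count).  Two distance conventions are
provided because the field uses both: `com_per_residue` (default) takes
the minimum over pocket residues of |COM(probe) − COM(residue)|;
`atom_pair` takes the minimum interatomic distance, the convention of
GROMACS g_mindist.  The two differ by ~1–3 Å on real side chains; the COM
convention is the default because it matches the way the cutoff rules are
phrased.  Both are exposed in the configuration.

Label rules (strict inequalities; equality with a cutoff fails that
condition): NB if min(d-MA, d-AB, d-T) exceeds the not-bound threshold;
else MA if d-MA < 6 and d-AB > 6; else AB if d-MA > 6 and d-AB < 6; else T
if d-T < 5; else UNASSIGNED.  The 6/6/5 Å cutoffs encode the ~16/17 Å
MA–AB centre separation: ~6 Å of channel either side and a ~4–5 Å
interface.  The NB threshold is not fixed by that geometry; the default of
12 Å (≈ the channel length scale) on the minimum of all three distances is
a package choice and is configurable.  UNASSIGNED is kept as an explicit
label; occupancy reports renormalise over the assigned labels
(MA/AB/T/NB) by default — the convention occupancy bar graphs use — with
the raw counts always retained, and renormalisation can be switched off.

Unbinding episodes are maximal NB runs of at least `min_dwell` frames
(default 10, suppressing single-frame flicker); shorter NB runs are
reported separately as transient excursions.

## Chain-shape taxonomy

Torsions ω are computed over every sliding four-atom window of the
declared chain path; geometrically degenerate (collinear) windows are
recorded as missing, and a profile with more than 20 % missing windows is
refused rather than guessed at.

The torsion-pattern policy uses a trans threshold |ω| ≥ 150° and treats
everything else as non-trans (gauche 30–90°, cis < 30° by the same
boundaries).  The pattern of non-trans windows decides the fine class:

- no non-trans window → Ex (extended);
- exactly one non-trans window → Uex (extended-U);
- one contiguous block wholly inside a terminal third → J or J′ by the
  sign of the block's torsion sum (hooked);
- one block elsewhere (central) → U (curved);
- two or more blocks → Hx, or Hx-A / Hx-B when every block midpoint falls
  in the first / second half (curved).

The fine→coarse map ({Ex, Uex}→elongated, {J, J′}→hooked, {U, Hx,
Hx-A/B}→curved) is fixed and total.  The numeric boundaries
(150°/90°/30°, terminal third, half split) are this package's published
defaults, chosen to make the classes mutually exclusive and exhaustive;
all are configurable.  Non-rotatable double-bond windows can be excluded
from pattern matching via the chain-path declaration.

For saturated chains the end-to-end policy uses only coordinate-level
descriptors: r = end-to-end / contour length and the position of the
largest bend between successive chain segments (non-overlapping windows of
4 atoms by default).  Defaults: elongated if r ≥ 0.75; hooked if r < 0.75
with the bend within 35 % of either end (a terminal fold); curved
otherwise.  The fine class is then NA.

## Paddle dihedrals, gate states, pre-reactive criteria

φF/φW are the side-chain torsions N–Cα–Cβ–Cγ (χ1; a C–Cα–Cβ–Cγ policy is
available since the axis definition alone does not fix the flanking
atoms), mapped to [0°, 360°).  Gate bins bracket the two observed φF
modes: CLOSED for [45°, 85°] (crystallographic ≈ 65°), OPEN for
[140°, 200°] (≈ 150–180°), INTERMEDIATE otherwise; bins are configurable
and classification is invariant under adding full turns.

Pre-reactive ("catalytically significant") frames are defined by a
configurable list of distance/angle/dihedral criteria with inclusive
bounds, combined by all-of (default) or any-of.  The shipped defaults —
attack distance Ser241:Oγ to the substrate carbonyl carbon ≤ 4.0 Å, a
Bürgi–Dunitz-like attack angle Oγ···C=O in [75°, 115°], and oxyanion-hole
H-bond distances (Gly239/Gly240 backbone N to carbonyl O) ≤ 3.5 Å — are
package choices in the spirit of near-attack-conformation analysis, not
literature-fixed values, and should be reviewed per system.  Tightening
any bound can only shrink the flagged set; criteria with open bounds are
vacuously true.

Polar records pair each pre-reactive frame's (φF, φW) with the pocket
distance matching its label (d-MA, d-T or d-AB), giving the
φ-versus-position data behind polar-plot analyses.

## Aggregation

Statistics run over frames after an equilibration cutoff (default 150 ns
for real trajectories; synthetic fixtures use 0).  MA↔AB transfer events
are counted by a dwell automaton: a run of ≥ `min_dwell` frames in one
channel followed by a qualified run in the other, with T and UNASSIGNED
frames transparent (the chain transits through the interface) and NB
breaking chains.  Gate flips use the same automaton over CLOSED/OPEN with
INTERMEDIATE transparent.  Monomer pooling adds raw label counts, so the
pooled summary is exactly the summary of the concatenated streams;
per-region disagreements beyond a threshold (default 5 points) raise a
warning — an equilibration alarm, not an error.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes —
not the physics.  Per frame it draws a pocket state from a 4-state Markov
chain over (MA, T, AB, NB), a coarse shape from a per-state emission
distribution, a pre-reactive flag from a per-state Bernoulli probability,
and φF/φW from per-state von Mises mixtures (concentration 50 ≈ 8°
spread, matching the tight open/closed modes).  Coordinates realise those
draws: pocket residue groups are static pseudo-residues at anchor points
(MA and AB 16.5 Å apart, T midway, NB 20 Å off in the "membrane"); the
16-atom chain is built kinematically (1.53 Å bonds, 111° angles) with
torsion templates per shape class, randomly rotated rigidly, and placed
with its tail COM at the current anchor plus isotropic Gaussian noise
(σ = 0.8 Å); paddle Cγ atoms are placed by natural-extension-reference-
frame construction so the computed dihedral equals the drawn angle; and a
marker cluster (Ser241 Oγ, substrate carbonyl, oxyanion-hole amides)
satisfies or violates the default near-attack criteria according to the
flag.  One `numpy` Generator seeded once drives everything; identical
seeds give bit-identical output.

Default parameters are the study conditions: stationary occupancy
(0.24, 0.68, 0.07, 0.01) over (MA, T, AB, NB) and pre-reactive injection
(0.10, 0.40, 0.05, 0).  The transition matrix is the rank-one mixing
kernel (1−a)I + a·1πᵀ with a = 0.4, whose stationary vector is exactly π
and whose autocorrelation time is ≈ 4 frames, so a 20,000-frame run
resolves each occupancy to well under one percentage point of sampling
error.  The dwell times are therefore deliberately short compared with
real pocket kinetics (ns-scale dwells at 10 ps frames): the generator
targets statistical recoverability at desk scale, not kinetic realism.
Other knowingly unrealistic simplifications: no forces or excluded
volume, static pocket groups, a marker cluster decoupled from the chain,
and shape templates rather than continuous torsion dynamics.  Passing
recovery tests therefore demonstrates that the measurement chain
(geometry → labels → statistics) is correct under the assumed statistical
structure, not that the analysis is robust to force-field or sampling
artefacts in real MD.

Closed-form expectations accompany the generator: occupancy is the
stationary vector of the (irreducible) transition matrix, the overall
pre-reactive fraction is Σ π_s·p_s over assigned states, and the
conditional cross-tab is π_s·p_s normalised over MA/T/AB.

## Kinetics

Michaelis–Menten fits are unweighted nonlinear least squares (optional
1/y weighting was considered and left out of the default because the
reference fits name only the plain equation), started from the
Hanes–Woolf linearisation S/v = S/V + Km/V; the standard assay design is
six concentrations (3.3, 6.25, 12.5, 25, 33, 50 µM).  Decay fits
y = A·e^(−kt) (+ plateau c on request, since the plateau question is
assay-dependent) start from log-linear regression and sample at 0, 5, 15,
30 min; a fitted rate below its own standard error is flagged as
indistinguishable from zero.  Selectivity ratios propagate standard
errors to first order.  Published Km values (5.26 µM and 12.53 µM for the
two reference substrates) are used only as realistic ground-truth
parameters for simulation-recovery studies — raw assay data are not
reproduced.

## Numerical choices and degenerate inputs

Torsions follow the IUPAC sign convention (cis 0°, trans 180°, range
(−180°, 180°]), computed by the atan2 formulation, which is stable away
from collinear triples; collinear windows (cross-product norm < 1e-10)
raise in scalar calls and yield missing values in vectorised profiles.
Gate and criterion bounds are inclusive; occupancy cutoffs are strict.
Empty selections, zero-frame trajectories, all-zero decay signals,
reducible transition matrices and anchor sets closer than twice the
placement noise all fail fast with named errors.  Reports are serialised
with sorted keys so identical inputs give byte-identical files.

## Known limitations

No periodic-boundary handling, no trajectory alignment, no block-average
or bootstrap error bars on real-MD statistics (a future hook), no
channel-volume/tunnel analysis, and no quantum or reaction-path
energetics.  The shape taxonomy boundaries and the pre-reactive defaults
are package conventions — sensible, documented, configurable — and
results quoted from them should state the thresholds used.
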