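# Methods

## The analysis

`cartraj` quantifies how monomethylation of Rps3 R146 changes the behaviour
of the ribosome's CAR interaction surface (18S rRNA C1054, A1196 and the
R146 guanidinium group) and its hydrogen bonding to the +1 mRNA codon, from
replicate MD-style trajectories of a twelve-residue neighborhood: the CAR
triple, the +1 codon (G1, C2, U3), the A-site codon and the tRNA anticodon
(nt34–36). All measurements operate on two conditions — methylated (mR146)
and unmethylated (R146) — and every inferential statement treats the
*trajectory*, never the frame, as the unit of replication, because frames
within a run are strongly autocorrelated. The replicate schedule emulated
throughout is 20 runs of 60 ns plus 10 runs of 100 ns per condition,
sampled at 1 frame/ns, with the first 20 ns of every run discarded as
equilibration. This makes a 60-ns run contribute 41 production frames
(endpoint-inclusive sampling) and the pooled 20-run set 820 frames; the
100-ns arm contributes 81 and 810.

### Atom-selection conventions

Two named rules drive all geometric measurements:

* **core** — heavy atoms of the base rings (N1, C2, N3, C4, C5, C6 for C/U;
  plus N7, C8, N9 for A/G) and the four guanidinium heavy atoms CZ, NE,
  NH1, NH2 of (methyl)arginine. The methyl carbon of monomethylarginine is
  excluded so that the methylated and unmethylated systems are measured
  over identical atom sets.
* **backbone** — N, CA, C, carbonyl O for amino acids; sugar-phosphate P,
  O5′, C5′, O3′ for nucleotides (a 5′-terminal residue legitimately lacks
  P and is skipped with a log note).

Prime, typographic-prime and asterisk sugar-atom dialects are normalised
before name matching. Role labels (C1054, A1196, R146, the codon and
anticodon positions) are resolved to `(chain, residue number)` through the
run configuration, never hard-coded, because the source structures mix
*E. coli* rRNA numbering with yeast protein numbering.

### Superposition and fluctuation statistics

Rigid-body superposition is least-squares (Kabsch, via SVD with the
determinant sign correction so reflections are never returned), unweighted
by default — every selected atom carries weight 1, matching the cpptraj
lineage of the protocol — with mass-weighting available. The average
structure is computed by superposing all frames onto the first frame,
averaging, and iterating superposition onto the running average until it
moves by less than 1e-6 Å. RMSF is measured about that average after
superposing every frame onto it over the union of the twelve residues'
selected atoms (the fit region is configurable; the twelve-residue union is
the default because the original fit region is not recorded anywhere we can
consult). The per-residue RMSF is the unweighted mean of atomic RMSFs
("byres" convention), not their RMS. The pairwise 2D-RMSD matrix pools
production frames at 1 frame/ns within a schedule group — the twenty 60-ns
runs form one 820-frame pool, the ten 100-ns runs a separate 810-frame
pool — and computes the best-fit RMSD between every frame pair with batched
3×3 SVDs. It is always computed for core and backbone rules and for both
the 12-residue and the 11-residue ((m)R146 excluded) selections.

The equilibration-time estimator (earliest window start after which the
running 10-ns-window mean never moves by ≥ 0.2 Å) is a diagnostic only; the
configured 20-ns cutoff is applied regardless. A verdict of "settled"
requires at least one full window of later window-starts, otherwise the
final window would trivially qualify on any series.

### Stacking readouts

Cation-pi stacking of the guanidinium group on the A1196 base is read out
two ways. First, the per-frame distance between the mass-weighted centers
of the two groups' core heavy atoms ("center of mass" is taken literally —
atomic masses, not a centroid). Second, the **stripped SASA** protocol: the
trajectory is stripped to exactly the 4 guanidinium heavy atoms and the 9
adenine ring atoms (enforced, to guarantee condition-comparable
measurements), and the solvent-accessible surface area of each group alone
and of the pair together is computed per frame. Stacking buries interface
area, so SASA(A+B) falls when the groups stack; the buried interface area
(SASA_A + SASA_B − SASA_AB)/2 is emitted as a derived column because it is
the direct burial readout, while the combined SASA remains the primary
comparison.

SASA uses sphere-point sampling (Shrake–Rupley scheme): each atom's sphere
of radius r_vdW + probe is covered with a deterministic golden-spiral point
set (960 points/atom by default; probe 1.4 Å, a water-sized probe), and the
accessible fraction scales 4π(r+probe)². The deterministic point set makes
results reproducible bit-for-bit, and using the *same* point set for the
single-group and combined computations makes subadditivity
(SASA_AB ≤ SASA_A + SASA_B, hence buried ≥ 0) hold exactly rather than
statistically. vdW radii are Bondi-style (C 1.70, N 1.55, O 1.52, P 1.80,
S 1.80, H 1.20 Å) and overridable; absolute areas therefore carry the usual
radii-choice caveat, but condition comparisons do not.

### Hydrogen bonds

Detection is geometric: donor-heavy-atom-to-acceptor distance ≤ 3.0 Å and
D–H⋯A angle ≥ 135° (cpptraj defaults; both configurable). The packaged
chemistry table lists donors and acceptors for the four RNA bases
(including 2′-OH and phosphate/sugar oxygens) and for arginine
(NE/NH1/NH2); monomethylarginine's modified NH2 keeps a single donor
hydrogen. Occupancy f of a (donor heavy atom, acceptor atom) pair is the
fraction of frames with the bond present — hydrogens collapsed by OR — and
is classified strong (f > 0.095), weak (0.025 < f ≤ 0.095) or
below-threshold. Per-residue counts are the mean number of simultaneous
bonds per frame between a focus residue (+1 G1/C2/U3, A-site nt2/nt3) and
the CAR + anticodon partner set; counting at the same collapsed granularity
as occupancy makes "mean count = Σ pair occupancies" an exact identity,
which the tests cross-check.

### Inference

Per-condition, per-replicate means feed two-sided Welch (unequal-variance)
t-tests with Bonferroni correction; family sizes default to the panel
widths (12 residues for RMSF, 4 COM pairs, 5 H-bond residues). Welch is
used rather than Student's t as the safer default when condition variances
differ (they do here by construction).

For the cross-replicate comparison, each trajectory's divergence D(e) is
its frames' mean best-fit RMSD to all frames of the *other* trajectories in
the pooled matrix, and the per-trajectory gap is D_core − D_backbone. The
two conditions' gap sets are compared by bootstrap: the null resamples,
with replacement and at the original group sizes, from the pooled values
after centering each group on its own mean (so only dispersion, not the
observed shift, enters the null), with the add-one two-sided p-value
p = (1 + #{|Δ*| ≥ |Δ|})/(B + 1) and B = 10,000 by default. The pooled
values are sorted before resampling so the result is exactly invariant to
relabeling within groups; the seed is recorded in the output. A
label-permutation test is available as an alternative. The type-I error of
the bootstrap at α = 0.05 is verified by simulation (1,000 null
repetitions at B = 2,000) in the acceptance suite.

## The synthetic-data generator

No trajectory data ship with the package (the study's archives are
request-only), so a generator produces replicate sets with the statistical
structure the analysis assumes, plus a per-frame ground-truth record
sufficient to score every metric. Dynamics are **kinematic**: geometry is
sampled directly from target statistics, with no forces — the artifact
tests the analysis, not MD physics.

* **Topology.** Twelve residues with full atom-name inventories (so the
  selection rules hit their documented counts: 82 core atoms = 9×4 purines
  + 6×7 pyrimidines + 4 guanidinium; 48 backbone atoms), donor hydrogens
  included. The methylated topology swaps one NH2 hydrogen for a methyl
  carbon. Base rings are idealized planar polygons; the
  anticodon/C1054/A1196 stack runs along one axis with the guanidinium
  above A1196 and the codon strands flanking it.
* **Stacking.** A two-state (stacked/unstacked) Markov chain per frame;
  the guanidinium core COM is placed at *exactly* the drawn distance
  d(t) ~ N(μ_state, σ_state) from the A1196 core COM along a jittered
  direction, so the analysis-side COM distance equals the ground truth to
  machine precision. Only the arginine side chain moves; the backbone
  stays anchored, as in the folded protein. Defaults: μ_stacked 3.8 Å,
  σ_stacked 0.25 Å, σ_unstacked 0.8 Å; stacked fraction 0.9 (R146) vs 0.5
  (mR146). μ_unstacked = 5.5 Å was chosen once as a typical destacked
  guanidinium–base separation (≈ 1.5–2 Å beyond stacking contact);
  nothing in the protocol pins it. These values reproduce the
  *directions* of the condition differences, explicitly not any published
  magnitudes.
* **Between-replicate heterogeneity.** Each replicate draws its stacked
  fraction from Beta(κf, κ(1−f)) with κ = 40. This models the slow modes
  that make independently-initiated replicates genuinely differ — the
  signal the pooled 2D-RMSD blocks and the divergence gap read out. With
  κ → ∞ replicates become exchangeable and the gap contrast vanishes.
  Heterogeneity enters *only* through the guanidinium stacking mode, so
  the 12-residue core-vs-backbone gap carries the condition contrast while
  the 11-residue ((m)R146-excluded) variant is close to null by
  construction; the pipeline still computes and reports both.
* **Switching rate** defaults to 1.0 /ns at 1 frame/ns, i.e. successive
  frame states are independent given the replicate's stacked fraction.
  This keeps per-replicate statistics well-mixed at 41-frame windows;
  slower, more persistent switching is available via the rate parameter.
* **Hydrogen bonds.** Configured donor–acceptor pairs (defaults:
  +1 G1 N2–H21 → C1054 O2 and +1 C2 N4–H41 → A1196 N1, with target
  occupancies 0.30/0.25 under R146 and 0.20/0.10 under mR146) toggle
  between a bond-satisfying geometry (2.8 Å, collinear) and a broken one
  (3.6 Å) by rigid translation of the donor residue along the bond axis,
  in exactly the frames drawn Bernoulli(f). Only the base moiety moves —
  the physical analog is base motion about the glycosidic bond — so the
  backbone panels stay condition-blind, matching the expectation that
  backbone fluctuations do not distinguish the conditions. The three
  defining atoms are exempt from thermal noise so per-frame detection is
  deterministic and occupancy recovery is exact at the frame level; optional Markov
  smoothing of the bond state is off by default so the frame process is
  exactly Bernoulli. Incidental contacts between other atoms do occur and
  are left in — they are realistic clutter and affect both conditions
  alike.
* **Noise and global motion.** All other atoms receive isotropic Gaussian
  thermal noise (σ 0.15 Å per coordinate, a plausible fluctuation scale
  for restrained residues; baseline residue RMSF ≈ σ√3 ≈ 0.26 Å), and
  every frame receives a uniformly random global rotation plus a
  translation (σ 5 Å per axis) that the analysis' superposition must
  absorb.
* **Demethylation restart** regenerates continuation trajectories under
  the unmethylated parameters from a chosen frame, recording the
  changepoint, mirroring the restart protocol in which the methyl group
  is removed from the final frames and dynamics resumed.

**What passing tests show, and what they do not.** The generator contains
exactly the effects the analysis is meant to detect, with known magnitudes;
green end-to-end tests therefore demonstrate the pipeline's *sensitivity
and correctness*, not the biological result. Real trajectories add
features the generator deliberately omits: solvent, correlated collective
motions beyond the single stacking mode, force-field physics, non-ideal
base geometry, and H-bond networks that rearrange rather than toggle.
Absolute RMSF/SASA/occupancy values from the generator are not comparable
to published magnitudes and are never asserted against them.

## The onion-shell subsystem builder

A neighborhood is the residue set of a sphere (default 35 Å) around a
center residue — membership measured from the center residue's center of
mass (configurable to a named atom) with a residue included if *any* atom
is inside, all-or-none, matching restraint semantics — split into an inner
unrestrained region and an outer shell (default thickness 8 Å, an exact
parameter standing in for an "approximately 8 Å" construction) whose
residues an MD engine would restrain at 20 kcal/mol Å². Single-residue
gaps in a chain's selected run are auto-filled into the shell
(idempotently); larger gaps are reported as chain breaks, and shell
residues with fewer than two selected neighbors within 5 Å are reported as
holes but never auto-acted on, because the original curation criteria are
not recorded. Manual curation is supported via explicit include/exclude
lists rather than heuristics that would pretend to reproduce it. The
restraint mask is emitted in Amber residue-mask syntax over 1-based global
residue ordinals, with a parser provided so masks round-trip exactly. The
mRNA sequence-edit planner marks, per differing position, the atoms whose
resolved coordinates can be retained (backbone + sugar always; base atoms
by shared name only within purine→purine or pyrimidine→pyrimidine) and the
atoms an MD-prep tool must grow.

## Numerical choices and degenerate inputs

* Kabsch requires ≥ 3 non-collinear reference atoms; the single-fit RMSD
  is evaluated directly from the transformed coordinates (the E0 − 2·trace
  shortcut loses ~1e-7 Å to cancellation near zero and is used only inside
  the batched all-pairs matrix, where values are far from zero).
* Drawn COM distances are floored at 2.5 Å to keep the groups from
  interpenetrating; with the default parameters the clip probability is
  negligible (≈ 10⁻⁷).
* Welch on two zero-variance groups returns p = 1 when means are equal
  (and p = 0 otherwise); the bootstrap returns p = 1 when the pooled
  centered values are all equal.
* Frame times must be strictly increasing; sampling windows are matched to
  frame times within 1e-9 ns.
* The 100-ns and 60-ns arms are never pooled into one RMS2D matrix; each
  schedule group is pooled separately and the divergence/gap/bootstrap
  layer reports each group.

## Problem sizes used by the shipped tests and acceptance script

The test suite exercises the full twenty-replicate 60-ns arm per condition
(820 pooled frames, the primary heat-map schedule) for the end-to-end
directional checks, 5,000-frame single replicates for parameter recovery,
and 1,000 null repetitions at B = 2,000 for bootstrap calibration. The
acceptance script runs the complete 30-replicate study schedule per
condition (20 × 60 ns + 10 × 100 ns, 2.2 µs total emulated time per run of
the script) and reports both the 820- and 810-frame RMS2D pools. These
sizes are the package's chosen study conditions; enlarging them only
sharpens the same comparisons.

## Known limitations

* No autocorrelation-time estimation or block averaging; the replicate is
  the unit of inference instead.
* No clustering of the RMS2D matrix (it is read as a heat map / via the
  divergence summary only).
* H-bond hydrogens must exist in the topology; positions are never
  reconstructed by idealized geometry (the generator always emits donor
  hydrogens, and donors lacking hydrogens in external data are reported
  and skipped rather than guessed).
* The restraint-mask parser reads only the residue-range syntax the writer
  emits, not general Amber mask grammar.
* PDB and DCD are the only trajectory formats; no mmCIF/NetCDF, no
  velocities or box information.
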