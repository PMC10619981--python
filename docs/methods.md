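# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generators do and do not emulate, and the design
choices made where the design was genuinely open.

## Coordinate model and geometry

Structures are flat collections of atoms keyed by (chain, residue number,
atom name), coordinates in Å, residue numbers 1-based and equal to the
position in the full-length protein sequence. Fragments keep native
numbering (a fragment spanning residues 401–690 holds residues numbered
401–690), which makes crosslink sites and fragment overlaps joinable without
bookkeeping. I/O goes through gemmi; on reading, hydrogens are dropped and
alternate locations keep the highest-occupancy conformer (ties: first
encountered). Multi-model files yield the first model unless an index is
given.

Superposition is the least-squares proper-rotation (Kabsch) fit via
`scipy.spatial.transform.Rotation.align_vectors`; reflections are never
returned, so chiral point sets keep a positive residual against their mirror
image. Degenerate inputs (< 3 points, collinear sets) raise rather than
returning an arbitrary frame.

The crosslink anchor atom defaults to CA, with NZ available by option. CA is
always present in predicted models and in CA-only synthetic models, and the
~24 Å crosslinker limit is conventionally quoted for either choice; nothing
downstream depends on which is used as long as it is used consistently.

## Crosslink parsing and validation

Input tables are pLink-style text (comma or tab, sniffed), with
case-insensitive header aliases for the two protein/site columns and the
E-value; explicit column names can be configured. The E-value filter is
strict (< 0.01 keeps). Unordered duplicate pairs collapse to the minimum
E-value — the best-evidence representative — and self-pairs are dropped.

Chain assignment on homodimers minimizes the anchor distance over all chain
combinations, including intra-chain; ties break lexicographically so reports
are reproducible. Satisfaction is inclusive (distance ≤ threshold), matching
the reading of "within the limit". The threshold defaults to 24 Å, the
theoretical BS3 span.

Contact groups: within-motor, motor–tail, motor–CC2, within-stalk, plus
`interprotein` and `other`. Motor↔CC4 contacts are grouped with motor–tail
because the inhibitory contacts at the motor interface come from the CC4
C-terminus and adjacent tail. Domain boundaries are configuration, not code:
the bundled KIF5B map uses the printed fragment limits where available and
approximate interior boundaries read off the domain diagram; users with
better annotations should supply their own YAML.

## Fragment assembly

Stitching superposes the shared CA atoms of consecutive fragments under an
explicit chain pairing (identity by default) and reports the post-fit RMSD.
At least 3 shared positions are required; in practice overlaps should be
tens of residues — with ~0.5 Å coordinate noise, a 20-residue (2-chain)
overlap leaves enough rotational slack to displace the far end of a long
fragment by several Å, while 60-residue overlaps keep whole-assembly
recovery under ~1 Å. Duplicated residues in the combined model are kept from
the earlier-placed (anchor-ward) fragment, privileging the anchor's
conformation.

Placement of non-overlapping fragments replaces the density-map guidance
used in the original manual modeling with restraint optimization, because
map fitting was visual while the crosslinks are the quantitative evidence.
The objective is lexicographic: maximize the number of restraints satisfied
at the distance limit, then minimize Σ|d_r − t_r|, where the target t_r is
the restraint's known distance when one is available (the simulator records
ground-truth distances) and 0 otherwise — with t_r = 0 this reduces to the
plain summed-distance tie-break. Targets are what make parameter recovery
well-posed: pure upper-bound restraints admit a wide feasible set, and the
minimum-summed-distance point of that set collapses the fragment onto its
partners rather than onto the truth.

A restraint's effective distance is the minimum over its chain combinations,
mirroring the validation convention. Two consequences are worth knowing:

- at least ~6 independent restraints are needed to pin the 6 rigid-body
  degrees of freedom; below that the optimum is a family of placements;
- a coiled-coil dimer has a twofold pseudo-symmetry about its own axis, so
  restraints that all connect to sites on one coiled coil admit an exact
  mirror-like alternative. Restraints bridging a fragment cut *within* one
  arm (short intra-stalk crosslinks) break this degeneracy; without them the
  two placements are genuinely indistinguishable to XL-MS — this is the
  homodimer ambiguity, not an optimizer artifact. Recovery is therefore
  assessed up to chain relabeling (`dimer_rmsd`), since swapping the labels
  of identical chains describes the same molecule.

The search is deterministic per seed: identity + a 30° Euler grid (with a
translation start chosen from a small offset grid around the endpoint
least-squares translation), least-squares refinement of an angularly diverse
subset of the best candidates, then up to 80 basin hops (perturb, refit,
accept on improvement). The identity placement is always a candidate, so the
result never satisfies fewer restraints than not moving the fragment at all.
Assembly scoring wraps restraint validation plus a CA–CA clash count
(default cutoff 3 Å, same-chain neighbours within 2 positions excluded).

## Hinge detection

Axes come from a 9-residue sliding window (about 2.5 helical turns: long
enough to average out the ~100°/residue CA wobble, short enough to localize
a break), oriented N→C. The kink angle at a position compares the windows
ending and starting there; the default 45° threshold sits far above the <5°
axis noise of an ideal helix and far below the ~120–180° reversal of a
fold-back hinge, for which no numeric criterion is published. A sharp break
produces an above-threshold plateau roughly one window wide, so calls report
the angle-weighted centre of each plateau (the raw argmax jitters between
plateau edges under coordinate noise); runs are separated by at least 10
residues. Dimer hinges are detected per chain and merged within 3 residues.

## Motility statistics

Dwell uses the interval convention (end − start frames) × frame interval,
matching the kymograph y-axis extent; a minimal 3-frame event spans 2
intervals (0.4 s at the default 200 ms/frame). The 3-frame filter and the
event definitions follow standard TIRF practice. Velocities use the absolute
displacement over dwell; zero-dwell events are excluded with a warning.
Landing rate normalizes the event count by total microtubule length,
duration and motor concentration. For group comparison the unit of
replication is the per-microtubule landing rate (microtubules with zero
events count as rate 0); one-way ANOVA is followed by Dunnett's many-to-one
test (`scipy.stats.dunnett` — the statistical test is called, not
re-derived), reporting mean ± SEM per group and adjusted p-values.

Censored events (truncated by movie start/end) are retained, flagged, and
bias dwell estimates slightly downward; the 3-frame filter biases them
upward (for an exponential dwell the filtered mean exceeds the true mean by
about the cutoff). Parameter-recovery checks therefore run on unfiltered
events.

## Synthetic generators

The toy dimer is a CA-only two-chain model: ideal helices (1.5 Å/residue
rise, 2.3 Å radius, 100°/residue twist) along segment axes, chains A and B
offset 10 Å. The default layout mirrors a kinesin-1 heavy chain — motor stub
1–400, CC2 401–540, CC3a 541–690, CC3b 691–820, CC4 821–907, tail 908–963 —
with the planted hinge at the CC3a/CC3b junction (residue 690). Folded mode
reverses direction there and offsets the returning arm 12 Å laterally, so
the end-to-end length is roughly half the extended contour and cross-hinge
site pairs (i, j) with small |i + j − 2·hinge| sit within crosslinking
range. Default crosslinkable sites pair across the hinge with irregular
offsets (0/3/6/9 residues) and ≥ 17-residue spacing along each helix: the
irregularity gives restraints distinct targets (a perfectly regular layout
leaves mirror-like placement degeneracies), and the spacing guarantees that
*no* site pair is within 24 Å in the extended conformer, which is what makes
folded-vs-extended discrimination exact. Homodimer self-links (same residue
on both chains) are excluded by default for the same reason — in a coiled
coil they sit at the inter-helix spacing in both conformations.

What the toy does **not** emulate: real coiled-coil packing and registry,
side chains (the 24 Å limit is applied to CA positions), disorder, the
asymmetric motor-domain docking of the real autoinhibited motor, and
measurement noise in identification (E-values are decorative, drawn
log-uniform in [10⁻⁸, 10⁻²), with an optional decoy fraction ≥ 0.01 to
exercise the parser filter). Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical structure, not
performance on experimental data.

Crosslink simulation emits each site pair whose ground-truth minimum
inter-anchor distance is ≤ 24 Å with a detection probability, plus false
positives drawn uniformly from the distant pairs so the expected FP fraction
is as requested (optionally at a fixed total table size). Motility
simulation draws per-microtubule Poisson landing counts
(rate × length × duration × concentration), exponential dwells quantized to
frames and censored at movie end, and Gaussian velocities; start positions
are drawn so events stay on the microtubule, leaving dwell and velocity
distributions undistorted. All generators are deterministic per seed.

## Problem sizes

Default analyses use a 963-residue 2-chain toy (1926 CA atoms), ~10–30
crosslinks per simulated table (200 for calibration runs), 20-seed
replication for placement recovery, 100-seed replication for stitching noise
and hinge recovery, ~80 microtubules (≈ 360 events) for motility parameter
recovery, and 1000 simulated null datasets for the Dunnett family-wise error
check. These sizes put Monte-Carlo error comfortably inside the asserted
tolerances while keeping a full run in the low minutes on one CPU.

## Known limitations

- The published "22 of 25" intra-motor control requires the deposited
  crosslink table and the tail-bound motor structure; the pipeline computes
  the identical quantity on any such inputs placed under `data/external/`,
  but the numbers cannot be reproduced from this repository alone. The
  published assembled-model distance ranges (motor–CC4 10–40 Å, motor–CC2
  10–35 Å, KLC1(CC) 5–50 Å) are likewise documentation references: the
  assembled coordinates are not deposited.
- Placement treats fragments as rigid; there is no torsional refinement, no
  density-map scoring, and no prediction-confidence weighting.
- Coiled-coil register, knob-into-holes packing and sequence-based
  coiled-coil prediction are out of scope.
- Tetramer (heavy chain + light chain) validation works through the same
  chain-assignment machinery via per-protein chain maps, but no
  TPR-placement-specific logic is attempted; long TPR crosslinks exceeding
  the linker span remain unexplained in the source analyses too.
- The hinge detector reports geometric breaks in a given model; it does not
  judge whether a break is a flexible hinge or a static kink.
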