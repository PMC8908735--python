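# Methods

`arrestkin` models the force-assisted release of a translational arrest
peptide (AP) from the ribosome exit tunnel as a replica ensemble of
first-passage events, and provides every analysis stage of a
ratchet-biased (ABMD-style) extraction study: event-level simulation,
coordinate-level rendering, a desk-scale biased Langevin engine,
contact-persistence analysis, the five detachment/extraction metrics, and
variant ranking.  This note records the model, its parameters, the design
choices that were genuinely open, and what the synthetic data can and
cannot show.

## The release model

The AP is the 24-residue XBP1u arrest sequence (residues 237–260,
DPVPYQPPFLCQWGRHQPSWKPLM), partitioned into an N-terminal region
(NT, 237–246), an intermediate region (I, 247–253) and the C-terminal
turn region (CT, 254–260).  Under a gentle pulling bias applied at the
N-terminus, residues release from their tunnel sites strictly in N→C
order.  The event model therefore draws, per replica, independent Gamma
residence increments Δt_i with per-residue mean μ_i and common shape k;
release times are the cumulative sums t_i = Σ_{j≤i} Δt_j.  A replica is
censored at the 100 ns time bound: any residue whose cumulative time
exceeds the bound — or that sits C-ward of a residue with infinite mean —
carries no release time.  Censored values are represented as `None`
end-to-end, never as sentinel numbers, and never enter a mean; every mean
is reported with the number of contributing replicas and the standard
error SE = SD/√n (the uncertainty of the mean, not the spread of the
non-equilibrium process).

The five extraction observables per replica are:

1. **Detach time** t_M260 — first time the C-terminal residue (Met260)
   moves > 3.8 Å from its starting position (3.8 Å ≈ one Cα–Cα step).
2. **Detached** — flag that metric 1 occurred within the bound.
3. **Extraction time** T — time from PTC detachment until no AP heavy
   atom is within 3.5 Å of any ribosome-complex atom (ribosome, tRNAs,
   mRNA); the Met260 detach time is subtracted.
4. **Exited** — flag that metric 3 occurred.
5. **Covered distance** D — initial minus final value of the pulling CV
   (see below), in nm.

Per-residue release times t_i use the 3.5 Å displacement threshold; the
3.8 Å value is reserved for the Met260 PTC-detach metric (both are
configurable in `AnalysisConfig`).  The Leu259 release time — loss of the
Leu259 / P-tRNA-A76 contact, the proxy for when translation could resume —
is the residue-259 entry in the event model and the first frame whose
Leu259↔A76 minimum heavy-atom distance exceeds 3.5 Å at the coordinate
level.

The kinetic signature of a variant is the profile ⟨t^i⟩ together with the
finite difference ⟨Δt^i⟩ = ⟨t^i⟩ − ⟨t^{i−1}⟩, computed as the difference
of ensemble means (the per-replica mean-of-differences variant is exposed
via `kinetics.delta_profile`; the two coincide when every replica
contributes to both residues).  Δt at the first residue is defined as its
release time.  Negative increments in user-supplied data are reported
as-is with a warning, never clipped.

## Default variant calibration

The packaged configurations (`data/variants.yaml`) encode the study
conditions: 20 replicas, 100 ns bound, and per-residue means chosen so the
ensemble observables reproduce the published replica study:

* **WT** — background residence 0.1 ns; Pro240/Tyr241 at 5× background;
  the conserved stretch 247–260 (minus the short-residence Trp249 and
  His252) at 8.5–13× background.  The means sum to 13.2 ns (detach) with
  12.5 ns through Leu259.  Gamma shape 4.0 reproduces the published
  replica-to-replica dispersion (SE ≈ 0.4 ns at n = 20); a shape this far
  from 1 encodes that a residue's escape is a multi-step, not a
  single-barrier, event.  Extraction mean 47.2 ns (shape 66), exit
  probability 1.
* **S255A** — WT with the residue-255 mean × 1.9.  With the published WT
  values fixed, the S255A Leu259 release (13.7 ns) and Met260 detach
  (14.0 ns) cannot both hold exactly under this one-residue rule; the WT
  residue-255 mean (4/3 ns) was set so the Leu259 release matches exactly,
  leaving the implied detach mean at 14.4 ns, inside the published
  uncertainty.
* **W256A** — WT with the residue-256 mean reduced by 70%; extraction mean
  78.1 ns (the emptied Trp pocket slows the chain's passage), exit
  probability 15/20.
* **C247K/S255A** — S255A with an infinite residence at residue 247 (the
  lysine salt bridge to the rRNA backbone): residues 247–260 always
  censor, 0/20 detach.
* **C247S/P254C/S255A** — elevated means from Leu246 C-ward with the
  mutated sites 247 and 254 highest, and a heavy-tailed shape of 0.04.
  The published numbers for this variant (17/20 detach, conditional detach
  mean 27.1 ns with SE 5.6 over 17 replicas, i.e. replica SD ≈ 23 ns)
  demand exactly this combination: a mean total of ~46 ns with extreme
  skew, so that ~15% of replicas censor while the uncensored mean stays
  near 27 ns.  The shape and a global ×1.1 scale on the elevated means
  were fitted once against these three constraints by large-n simulation
  and frozen.

Covered distance: an exited replica covers the full CV span (12.5 nm) by
definition.  For non-exited replicas D = 12.5 nm × (fraction of residues
released) × a per-variant partial-exit scale — the fraction is a monotone
proxy for N-terminal progress, and the scale absorbs how far short of the
CV target a stalled N-terminus drifts (0.09 for the pinned double mutant,
0.62 for the triple, 0.75 for W256A's non-exited replicas).

Extraction censoring is carried by the per-variant exit probability rather
than by re-applying the time bound to the extraction draw; the published
exit counts already encode the bound, and a double-censoring would bias
the extraction means low.

Seed discipline: one master seed expands to per-replica child seeds by a
fixed SeedSequence splitting rule (`synth.child_seeds`), recorded in the
run manifest; the event path is bit-reproducible from the manifest.

## The toy tunnel and renderer

`render_trajectory` turns an event table into a 3D bead trajectory that
the trajectory-level kinetics must invert — the pipeline's central
round-trip oracle (100 random replicas, every release time recovered
within one frame interval).

Geometry (Å): one Cα bead per residue, anchored on the tunnel axis at
3.8 Å spacing with residue 237 nearest the mouth; extraction proceeds down
the axis.  Wall sites ring the axis at 3.2 Å radius: a contiguous lining
at half-spacing keeps any bead on the axis within the 3.5 Å contact cutoff
until it passes the mouth, and per-residue rings carry 1/2/3 sites in the
NT/I/CT regions, encoding the observation that the stalled chain's
C-terminal region makes the most persistent tunnel contacts.  A P-tRNA
pseudo-nucleobase (A76) sits beside the Leu259 anchor.

Dynamics: a bead sits exactly at its anchor until its release time, then
jumps 4.2 Å down-axis (clearing both displacement thresholds within one
frame) and travels at constant speed.  For an exited replica the speed is
set so the C-terminal bead loses its last wall contact exactly T after its
release, and the N-terminal bead parks on the CV virtual point, making the
covered distance exactly 12.5 nm; for non-exited replicas released beads
park just inside the mouth (still in contact) and the N-terminal bead
parks at the event table's partial covered distance.  The renderer is
deliberately kinematic — no thermal jitter — because its contract is
metric inversion, not realism.

## The pulling CV and the ratchet bias

The CV is the distance ρ between the heavy-atom centre of the N-terminal
residue (Asp237) and a virtual point fixed on the tunnel axis beyond the
mouth, 12.5 nm from the residue's starting position; the bead models carry
no per-atom masses, so the centre is unweighted (equal masses).  The bias
is the ratchet-and-pawl one-sided harmonic

    V(ρ) = ½ K (ρ − ρ_best)²  if ρ > ρ_best, else 0,

where ρ_best is the running minimum of ρ.  Toward-target motion costs
nothing and advances the pawl; backward fluctuations are damped.  The
default K = 25 (kJ/mol)/nm².  The source study prints the unit as
(kJ/mol)/nm⁴, which is dimensionally inconsistent for a harmonic distance
bias; it is read here as a typographical artifact of the biasing plugin's
conventions and the numeric value 25 is kept.  The ½K prefactor is a
convention choice (the plugin literature uses both ½K and K); it only
rescales the K axis of the calibration sweep.

The desk-scale engine integrates a bead chain (harmonic bonds, r₀ =
0.38 nm; attractive Gaussian wall sites; confining cylinder) with the
BAOAB Langevin splitting — chosen for its configurational accuracy at
large steps — in GROMACS-like units (kJ/mol, nm, amu, ps internally; ns at
the interface).  The bias force enters through the chain rule on the
N-terminal bead.  Verified physics: zero-temperature rest at a minimum,
bit-reproducibility given the seed, the Einstein relation D = kT/(mγ)
within 5% at K = 0, and < 1% energy drift over 2·10⁴ frictionless steps.
Stability requires dt·√((bond_k + K)/m) ≲ 1; the default dt = 0.05 ps
covers the K = 10⁴ end of the sweep.

The packaged toy system (3 beads, 11 kJ/mol wells, 4 nm target, 1 ns
bound, γ = 2 ps⁻¹) is calibrated so the sweep over K = {10, 25, 100, 10³,
10⁴} at 20 replicas (common random numbers across K) shows monotonically
decreasing time-to-target, while the unbiased K = 0 control reaches the
target in 0/20 replicas: escapes within the bound are ratchet-driven, not
free diffusion.  In this toy the meaningful "escape" is arrival at the CV
target; mere loss of wall contact is thermally trivial at these well
depths.  These sizes (and the 0.5 ns frame spacing of rendered
trajectories) were chosen as the smallest systems that exercise every
contract cleanly.

## Contacts, persistence, networks, RMSD

A contact is a heavy-atom pair within 3.5 Å (ties count as in contact);
hydrogen bonds and hydrophobic interactions are pooled under this single
distance criterion with no angular terms, hydrogens excluded, and no
hysteresis — a contact is lost the moment the distance exceeds the same
cutoff.  Intramolecular AP contacts exclude bonded neighbours
(|i−j| ≤ 1).  Persistence is the fraction of frames a pair is present,
computed over the union of pairs ever in contact and filtered at 50% and
75% (two thresholds to confirm stability of the counts).  Counts are
aggregated per residue and per NT/I/CT region.

The three intramolecular networks are CN1 = {247, 248, 249},
CN2 = {251, 254, 255, 257}, CN3 = {250, 253, 256}.  A network is intact
in a frame iff every member is within the cutoff of at least one other
member at |i−j| ≥ 2.  Because CN1's members are consecutive, its middle
residue has no admissible partner inside the network and CN1 intactness
is structurally zero under this rule — the degenerate extreme of the
CN3 > CN1 stability ordering.

RMSD uses the standard Kabsch SVD superposition (with the reflection
guard), cross-checked against MDAnalysis on fixed coordinates.  Contact
detection uses a k-d tree, tested for exact agreement with the all-pairs
double loop on random 500-atom frames.

## Ranking

Variants are ordered strongest-staller first: fully censored detachment
(no replica detaches) outranks everything, then descending mean detach
time.  Pairs whose means differ by less than one combined SE are flagged
as "≈".  Concordance with experiment is the Spearman correlation between
this ranking and (1 − f_L), the fraction of full-length protein read out
by the arrest-potency assays.  Under the defaults the order is
C247K/S255A > C247S/P254C/S255A > S255A > WT ≈ W256A, Spearman ≈ 0.87:
positive and high, with the known double/triple inversion relative to the
in-vitro potencies.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure of the replica
study: sequential release, variant-specific residence signatures,
censoring, exit counts, covered distances, and their dispersions.  It does
not contain tunnel physics — no real geometry from the cryo-EM structure,
no secondary structure or turn conformation, no force-field energetics,
and release-order inversions are never generated (the analysis tolerates
them in user data).  A passing suite therefore certifies the *analysis
machinery* — metric definitions, censoring discipline, ensemble
statistics, round-trip consistency — and the calibration of the event
model, not the molecular mechanism itself.  Real trajectories can enter
through the PDB (multi-model) and XYZ readers with an explicit
chain→entity map; entity assignment is never guessed from residue names.

Known limitations: the event model's extraction censoring by exit
probability ignores the small correlation between slow detach and failure
to exit; the Gamma-shape defaults are modeling choices constrained only by
the published SEs (replica-level distributions were not published); the
toy engine's time scales are ~100× compressed relative to the all-atom
study and only order relations (monotonicity in K, stall vs release)
carry over.
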