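# Methods

## The problem

A disulphide bridge between two cysteines closes part of a polypeptide
chain into a covalently closed loop. When another part of the same chain
passes through that loop, the protein carries a *pierced lasso*: a
knot-like topology that cannot untie while the bridge is intact. Pierced
lasso bundles (PLBs) are four-helix proteins carrying this motif; the
motif's covalent loop may sit at the N terminus, the C terminus, or
between two internal cysteines, and its size and position control both
how the chain threads during folding (slipknotting versus plugging) and
how oxidation of the bridge changes stability and native-state dynamics.

`plasso` implements the complete computational pipeline for this system:
topology classification of structures, a synthetic-bundle generator that
realizes every loop topology, a C-alpha structure-based folding model
with three bridge oxidation states, Langevin/NVE dynamics, WHAM
thermodynamics, threading-route classification, and slow-mode
native-state dynamics.

## Topology classification

The covalent loop spanned by a bridge (i, j) is the C-alpha polygon
i..j closed by the i-j chord. The loop is smoothed by Chaikin corner
cutting (2 rounds by default; smoothing never increases curve length and
keeps closure) and spanned by a centroid triangle fan. Each chain tail
(the residues before i, and after j, walked from the free terminus; the
bridging cysteines belong to the loop and are excluded) is intersected
with the fan by a vectorized segment-triangle test; hits on shared
internal fan edges are de-duplicated, opposite-sign grazing pairs within
a small distance cancel, and segments lying exactly in a triangle plane
trigger a deterministic jitter retry. The net signed crossing number of a
tail is a topological quantity — invariant under any deformation of the
spanning surface that crosses neither the loop nor the tail — which is
why the cheap fan stands in for a minimal surface; the classifier
recomputes the counts at several smoothing levels and flags disagreement
as ambiguous rather than answering silently.

Labels follow the field taxonomy: `zero_knot` (both cysteines within
``terminal_margin`` = 10 residues of their termini), `cinch` (both
internal, nothing threaded), `empty_lasso` (one terminal cysteine,
nothing threaded), `pierced_lasso` (a tail with nonzero net crossing).
Loop size is the sequence separation j − i, the convention under which
the leptin bridge C96–C146 closes a 50-residue loop. The threaded
segment is the longest contiguous run of tail residues on the far side
of the surface, sides assigned by crossing parity walking from the free
terminus; the measurement convention for threaded-element length is ours
(the literature prints lengths without stating a rule, so we document
but do not assert against those numbers).

## Synthetic bundles

The generator builds idealized four-helix bundles at C-alpha resolution
(rise 1.5 Å/residue, radius 2.3 Å, 100°/residue, antiparallel axes
~10 Å apart) with connecting loops drawn as arclength-resampled cubic
splines. Two generator details matter for the physics downstream:

* **Coil wiggle.** Straight C-alpha stretches put virtual-bond angles
  near 180°, where the torsional geometry degenerates and an angle-anchored
  force field leaks energy. Every loop is therefore overlaid with a small
  helical perturbation (amplitude ~1 Å, period ~3.4 residues,
  parallel-transported normal frames, phase chosen per loop to maximize
  the worst bend). Real backbone traces always carry this local
  curvature; ideal splines do not.
* **Buried threads.** In natural PLBs the threaded element packs inside
  the bundle, so unthreading breaks many native contacts. Early designs
  that passed the thread through a peripheral window made the threaded
  and unthreaded near-native states nearly degenerate — biased folding
  runs reached Q ≈ 0.96 without ever threading. The final pierced
  layouts spread the ring-helix pair to 13.2 Å and pass the thread
  through the ring mid-face packed against both ring helices (4.3–6.6 Å),
  restoring a clear energetic preference for the threaded native state.

The eight lasso kinds: `none`, `zero_knot`, `cinch`, `empty_loop`
(hGH-style large empty loop), `lasso_N`, `lasso_C`, `pierced_N`,
`pierced_C`. The two pierced fixtures realize the loop-size/thread-position
contrast of the natural proteins at reduced scale: `pierced_C` has a
small C-terminal loop (~30 residues standing in for leptin's 50) pierced
by a *mid-chain* element (slipknot-friendly), while `pierced_N` has a
large N-terminal loop (~39 standing in for ≥68) pierced by the
*C-terminal tail* (plug-friendly). `pierced_C` uses an up-up-down-up
helix order and `pierced_N` up-down-up-down so each covalent loop can
close between spatially adjacent cysteines; these are the generator's own
scaled-analog choices — real PLBs are up-up-down-down with longer loops.
Every bundle is self-validated at build time: virtual bonds within
[2.8, 4.5] Å, no nonconsecutive pair below 3.8 Å, and the classifier
must reproduce the requested kind with |net crossing| = 1 on the
designated tail for pierced kinds.

`leptin_analog()` returns a pierced_C geometry sized so that the
bridging cysteines carry author numbers 96 and 146 (loop size 50),
matching the leptin bridge as printed.

## The structure-based model

The Hamiltonian is the standard C-alpha Gō form:

    V = Σ k_b (r − r0)²  +  Σ k_a (θ − θ0)²
      + Σ k_d¹ [1 − cos(φ − φ0)] + k_d² [1 − cos 3(φ − φ0)]
      + Σ_native ε [(1 + (σ/r)¹²)(1 − e^{−(r−r0)²/2w²}) − 1]
      + Σ_nonnative ε (σ/r)¹²   (truncated, force-shifted at 0.8 nm)

with k_b = 2×10⁴ ε/nm², k_a = 40 ε/rad², k_d¹ = ε, k_d² = 0.5 ε and
σ = 4 Å. Native contacts are C-alpha pairs within 8 Å at sequence
separation ≥ 4 (an approximate shadow-screened variant is available);
each contributes exactly −ε at its native distance. The Gaussian well
width w defaults to 0.5 Å and is configurable. All internal units are
nm and ε with k_B = 1.

The disulphide bridge has three states: **oxidized** — an unbreakable
harmonic bond at the native S–S distance, with the native SS contact kept
in the map so contact counts are comparable across states; **dynamic** —
a breakable Gaussian contact of depth ε_ss (default ε), able to form and
break during folding; **reduced** — excluded volume only.

Dihedral forces use a trigonometry-free angle-addition evaluation with
the denominator clamped at sin²θ ≥ 10⁻³ against grazing collinear
angles; the clamp only engages beyond ~178°, which the generator's coil
wiggle makes energetically remote.

## Dynamics

BAOAB Langevin integration with friction γ = 1/coupling; the coupling
constant is 2 reduced time units read as the thermostat time constant.
γ = 0 reduces the scheme exactly to velocity Verlet (NVE). Beads carry a
uniform mass of 100 — the GROMACS-style convention of roughly one
amino-acid mass in amu when energies are in ε and lengths in nm — which
makes the conventional dt = 0.005 stable against the stiff bonds
(ω·dt = 0.1); it is equivalent to unit masses with dt = 5×10⁻⁴. With
unit masses, dt = 0.005 is beyond the bond stability limit (ω·dt = 1),
which is why the mass convention matters. Thermostat noise comes from an
inlined xorshift128+/Marsaglia-polar generator seeded from the run seed;
runs are bit-reproducible given seed and build. Nonbonded repulsion uses
a Verlet neighbor list (0.3 nm skin, rebuilt on half-skin displacement)
and is force-shifted so NVE runs do not pump energy at the cutoff;
measured secular drift for a cold folded bundle is ~10⁻⁵ ε per 10⁴ steps
at dt = 0.005.

Umbrella runs add ½ k (Q_s − Q_c)² on a differentiable contact fraction
built from logistic switches of width 0.1·r0 at 1.2·r0; the sharp-count
Q (formed iff r < λ r0, λ = 1.2) is used for all analysis.

## Thermodynamics and folding order

Cv(T) and the folding temperature Tf (the Cv maximum) come from
Ferrenberg–Swendsen reweighting of potential-energy histograms over a
four-temperature ladder (0.85, 0.95, 1.05, 1.15 ε) bracketing both
oxidation states' folding temperatures; runs start from the native state
with a discarded equilibration segment. Folding-order signatures use
q_segment (contacts owning at least one endpoint in a segment — our
documented ownership convention) conditioned on global Q with bootstrap
confidence intervals.

On the N-lasso fixture the model reproduces the three qualitative
behaviors expected of these topologies: the oxidized bridge raises Tf
relative to reduced (loop closure stabilizes the fold); helix A — the
terminal receptor-binding helix analog, deliberately given mostly
tertiary contacts — stays below the q = Q diagonal at high Q in both
states (last element to complete); and oxidation raises helix-A contact
formation at low Q (the bridge pins helix A to the bundle before global
folding).

## Threading mechanism

Per analyzed frame the covalent loop surface is rebuilt from the
instantaneous coordinates (smoothing 2) and the thread tail's signed
crossings recorded; degenerate (collapsed) loop frames are marked
undefined and excluded. A folding transition is labeled at the first
frame from which the tail's net crossing holds the native value for at
least ``min_dwell`` analyzed frames; walking back over the contiguous
crossing episode that produced establishment, the episode's first frame
decides the route: a single crossing within 3 residues of the free
terminus means the terminus led (**plug**); an opposite-sign crossing
pair or a first crossing far from the terminus means a doubled chain
went through first (**slipknot**). Transitions that reach the native
basin without establishing parity are labeled **none** — possible only
when the bridge is dynamic or reduced during threading. The frame-level
rule is this package's documented reconstruction; the source taxonomy
names the routes but gives no operational criterion.

Because an oxidized chain can neither thread nor unthread spontaneously
on accessible timescales (the threaded state is topologically trapped,
and the unthreaded chain stalls in a near-native trap), threading
statistics use an *oxidative refolding* protocol: unfolded, unthreaded,
bridge-closable conformations are harvested from a high-temperature run
of the reduced model; the bridge is closed by a short steepest-descent
relaxation (discarding the rare conformations that closure accidentally
threads); folding is then driven by a staircase of umbrella windows
along Q with annealing cycles — whenever the chain stalls unthreaded, a
hot window (T = 1.45, Q-center 0.55) fully re-melts it and the push
restarts, so successive folding transitions are independent first-passage
events; after the native parity establishes, a short confirmation block
extends the trajectory so the classifier sees a full dwell. Biasing
along the global coordinate Q accelerates barrier
crossing without prescribing the threading route. On the two pierced
fixtures this reproduces the loop-size/mechanism switch: the small-loop
C-lasso threads predominantly by slipknotting (hairpin-first signatures,
opposite-sign crossing pairs mid-tail), the large-loop N-lasso
predominantly by plugging (terminus-led single crossings).

## Native-state dynamics

The folded basin is sampled well below Tf (frames with Q ≤ 0.85 are
discarded and must stay below 1% of the run; the bundles' soft basins
put the workable window at ~0.5–0.62·Tf — at 0.7·Tf the discard rule
already rejects the runs, and ``sample_native`` raises with exactly that
advice); frames are Kabsch-aligned to their mean and the 3n×3n C-alpha
covariance diagonalized. The per-residue amplitude is the RMS of the
trajectory projected onto the first four principal components, summed
over the subspace and reported in Å (whether such profiles should be
per-component or summed is unstated in the literature; we sum and
document it).

Comparing oxidation states required care with the statistics. Slow-mode
amplitudes converge very slowly within one trajectory, so a frame-level
permutation null is badly anticonservative (it destroys autocorrelation;
even two independent runs of the *same* state test "significant").
The shipped design averages profiles over six independent replicas per
state and permutes whole replicas — an exact test whose null we verified
on same-state comparisons. Under it, the redundant-bridge cinch control
behaves as expected (oxidation effects not significant outside ±10
residues of the bridge, p ≈ 0.2). The pierced fixture, however, does
*not* show a significant non-local effect at any basin temperature the
discard rule allows (p 0.4–0.8): the reduced fixture remains
topologically trapped in the threaded basin on these timescales — the
thread fraying that underlies the natural proteins' reduced-state
flexibility is a rare event this sampling cannot reach — and the
ring-opening mode that does respond to oxidation lies inside the ±10
local window by construction. The corresponding acceptance check is
therefore expected to fail on the pierced half; we report the computed
p-values rather than relax the test. This module works at C-alpha
resolution — an all-atom treatment would resolve side-chain packing
these profiles cannot — so only the local-versus-global pattern is
meaningful, never per-residue amplitudes.

## Problem sizes and determinism

The shipped study conditions are desk scale by design: fixtures of
~70–90 residues (leptin-sized classification fixtures up to ~140),
four-temperature thermodynamic ladders of ~1M steps per run, ≥30
classified threading transitions per pierced fixture, and ~450k-step
native-basin samples. Every stochastic stage takes an explicit seed;
generation, integration and analysis are deterministic given seeds.

## Known limitations

* The synthetic bundles are geometric idealizations: poly-alanine-like
  sequences, no side chains beyond cysteine S-gamma pseudo-atoms, helix
  orders adjusted per pierced kind, loops with constructed curvature.
  Passing tests demonstrate the machinery and the topology-conditional
  physics on these fixtures, not quantitative agreement with any real
  protein's values.
* The threading statistics are collected under a Q-ladder bias with
  annealing; the bias is mechanism-agnostic by construction but the
  absolute transition rates are not physical observables here — only the
  route fractions are interpreted.
* The centroid-fan surface can misjudge pathological curve geometries;
  the multi-smoothing ambiguity flag marks those instead of silently
  answering.
* Backbone (open-knot) invariants, cystine-knot motifs, structure-database
  discovery scans, and all-atom force fields are out of scope.
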