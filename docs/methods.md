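# Methods

`allopep` implements the computational arm of an allosteric peptide-inhibitor
screen against the CDK2/Cyclin E protein–protein interface: a pentapeptide
library is enumerated, candidate peptides are selected from an
ensemble-docking decoy table by three complementary criteria, trajectory
analysis scores how peptide binding perturbs the coupled motion of the
CDK2/Cyclin interface, a triage step classifies whether a docked peptide
remains in the allosteric pocket, and a two-state kinetic model simulates
and fits SPR sensorgrams to quantify binding. Because no docking decoys,
trajectories or raw sensorgrams are distributed with the original study,
every input is produced by a synthetic-data generator with known ground
truth; what the tests demonstrate is therefore correctness of the
*statistics and procedures*, not reproduction of the study's absolute
trajectory-derived numbers (see Limitations).

## Peptide library

The library is the set of double mutants x-A-A-L-z of the parent inhibitor
TAALS: the central A-A-L core is conserved (single-mutation scanning
identified the middle residues as conserved), both termini vary over the
20 standard amino acids, giving 20² = 400 pentapeptides. Enumeration is
lexicographic for determinism; the output order carries no scientific
meaning. Synthesis chemistry (free N-terminal amine, free C-terminal acid)
is not modelled.

## Decoy selection

A decoy table has one row per retained docked pose: receptor conformation
id (the CDK2 ensemble spans three sets of ten T-loop conformations),
peptide, energy-cluster rank and binding energy in kcal/mol. Three
selectors operate on it:

* **Frequency** — the 1000 lowest-energy decoys of the whole ensemble are
  tallied by receptor conformation; the three most frequent conformations
  are taken as the receptor states selected by peptide binding, and the
  five peptides with lowest best energy *within those conformations* are
  returned. The ordering rule inside the favoured pool (minimum energy per
  peptide) is our choice; the source protocol specifies only "top peptide
  list", and minimum energy is the criterion it uses globally.
* **Energy** — peptides ranked by their minimum docking energy over all
  poses; top five.
* **Rescoring** — identical ranking logic driven by an external
  knowledge-based potential. The potential is a pluggable callable; the
  bundled `ToyContactPotential` (12-6 profile on hydropathy-product well
  depths at sequence-separation distances) exists to exercise the contract
  in tests and demos and has no claim to accuracy. Published statistical
  potentials can be plugged in unchanged.

Ties in any energy-like score break lexicographically by (peptide,
receptor, cluster rank), which makes every selector invariant to input row
order. The combined candidate list is the first-seen-order union of the
three selections; on the published per-method lists this union has 13
members.

## Trajectory representation and windowing

A trajectory is frames × atoms × 3 in Å with per-atom (chain, residue,
atom-name) labels; a *node* is one residue. Correlation analysis uses one
representative point per node — CA by default (the convention of the
trajectory-correlation tool this analysis follows), residue centroid as
the alternative, exposed as a parameter because the original protocol does
not state the choice. Contact detection can use all atoms of a node
(heavy-atom mode, the default) so that the contact rule and the
correlation statistic operate at their native granularities. Windowing
discards an equilibration prefix and resamples by an integer stride; the
production setting of the protocol this emulates is a 30 ns trajectory
sampled every 100 ps with the first 10 ns discarded (200 analysis frames).
I/O formats are multi-frame PDB (MODEL/ENDMDL, via Biopython) and a plain
XYZ dialect with a TSV metadata sidecar; both round-trip losslessly up to
format precision.

## Dynamical network and interface score

Two nodes form an edge when the minimum distance between their (heavy)
atoms is **strictly below 4.5 Å** in **at least 75%** of frames
(threshold inclusive — the defining text says "at least"), excluding
same-chain sequence neighbours, whose contact is trivial. For edge pairs
the normalized displacement cross-correlation

C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩),  Δr_i(t) = r_i(t) − ⟨r_i⟩

is computed from the representative points (scalar-product form over the
3-D displacement vectors); non-edge entries are set to zero. The
interface-stability score of a two-chain complex is the mean **signed**
C_ij over cross-chain edges. Signed, not absolute: a stable interface
moves as a unit (positive coupling), and anti-correlated interface motion
is a physically distinct signature that should pull the score down, not
up. "Interface residues" are operationalized as exactly the cross-chain
pairs passing the edge rule; the source narrative does not define the set
otherwise. Conditions (peptide-bound states) are ranked by ascending
score: lower mean coupling = less stable interface = better disruptor
candidate. On the published per-peptide scores (0.27–0.44 against the
0.38 peptide-free baseline) this ranking reproduces the published
stability order YAALQ < DAALT < KAALE < RAALW < FAALA < RAALG.

A node that never moves has undefined correlation; strict mode raises,
non-strict mode marks its rows NaN. For ≤5-node, ≤10-frame inputs the
matrix implementation is verified against a literal double-loop
transcription of the definition to 1e-12.

## Pocket residence

The triage statistic is the per-frame minimum distance between any peptide
node and the anchor residues of the CDK2 allosteric pocket (R150, K178,
Y180 — the residues point mutation identified as the binding hot spot and
that were held flexible during docking). Minimum distance, not center of
mass, because pocket *contact* is the visual criterion being quantified.
Classification: **blow_up** if any value is non-finite or exceeds 50 Å;
otherwise **leave** if the mean over the final 20% of frames exceeds the
initial-window mean by more than 3 Å; otherwise **stay**. All three
thresholds quantify a judgement the original protocol made by eye, so they
are artifact choices, fully configurable, and chosen to separate the
generator's regimes cleanly: a stay series fluctuates by ~0.5 Å, a leave
series drifts tens of Å, a blow-up diverges super-linearly. The defaults
are mutually coherent: the leave generator's default drift (0.3 Å/frame
over 100 frames) keeps a leave series below the 50 Å divergence sentinel,
since a "leave" trajectory that crosses the sentinel is by definition a
blow-up.

## Two-state SPR kinetics

Binding follows A + B ⇌ [AB]\* ⇌ AB (encounter complex, then
conformational change). With piecewise-constant analyte concentration
C(t):

d[AB\*]/dt = k_a1·C·(Rmax − [AB\*] − [AB]) − k_d1·[AB\*] − k_a2·[AB\*] + k_d2·[AB]
d[AB]/dt = k_a2·[AB\*] − k_d2·[AB]

response R = [AB\*] + [AB] (both bound states carry mass at the surface —
the standard instrument convention). k_a2 is first-order (1/s): the second
step is a conformational transition, not a second encounter (a published
"1/Ms" unit on that column is treated as a typographical slip).
Equilibrium constants: K_1 = k_a1/k_d1, K_2 = k_a2/k_d2,
K_A = K_1(1+K_2), K_D = 1/K_A. The eight published rate sets reproduce
their printed K_D values to within 4%.

Integration is phase-by-phase (concentration constant within a phase) with
LSODA at rtol 1e-8 — the published rates span six orders of magnitude —
and the state carries across injections: single-cycle kinetics never
regenerates the surface. In the k_a2 → 0 limit the simulator matches the
analytic 1:1 Langmuir solution to integrator tolerance.

Global fitting shares all four rates and Rmax across curves (per-curve
Rmax is a documented possible extension; shared is the default because the
curves come from one surface). Parameters are fit in log10 space, which
enforces positivity and conditions the problem; default bounds are
[1e-8, 1e8] — wide enough to contain the slowest published
conformational dissociation rates (~7e-6 1/s), which a tighter
conventional lower bound would clip. Standard errors come from the
Gauss–Newton approximation at the optimum, propagated out of log space.

The default single-cycle schedule (five 300 s injections at 0.2, 1, 5, 25,
100 µM with 100 s gaps, then a buffer-only tail to 12,000 s, sampled every
2 s) was designed for identifiability: the top concentration approaches
surface saturation and pins Rmax, the injection shapes constrain k_a1 and
k_a2, the early dissociation constrains k_d1, and the long tail makes the
slow k_d2 observable. With 1 RU i.i.d. read noise this design recovers all
four DAALT-like rates to within a few percent.

The ATP-competition rule compares K_D with and without ATP in the buffer:
a fold change (in either direction) above 10 flags possible competition;
smaller shifts are within the uncertainty of SPR kinetic fitting. On the
published constants only DAALT is flagged (~76-fold).

## Synthetic-data generators

Every generator draws from one `numpy` Generator seeded by its spec, so a
fixed seed gives bit-identical output.

* **Decoys** — energies are Gaussian per (receptor, peptide) cell (base
  mean −8 kcal/mol, sd 1.5, per-cell overrides), plus an additive receptor
  bias that lets chosen conformations dominate the low-energy tail; the k
  draws per cell are sorted ascending and labelled cluster ranks 1..k,
  mirroring energy-ranked cluster representatives. An optional dropout
  probability emulates docking runs that return fewer clusters than
  requested. The Gaussian noise model is an artifact choice — the original
  protocol publishes no energy distribution.
* **Trajectories** — frames are reference + displacement with per-frame,
  per-axis i.i.d. draws from N(0, Σ) over nodes; Σ is the spec'd (block)
  covariance. Displacements have no autocorrelation in time because the
  downstream statistic is a per-frame covariance — temporal correlation
  would not change its expectation, only its convergence rate; this is a
  stated limitation relative to real MD. Contact-occupancy targets are
  met by moving the pair's *reference separation*: given the
  covariance-implied relative-displacement variance v, the occupancy at
  separation s is the noncentral-χ²(3) probability
  P(χ'² < cutoff²/v | nc = s²/v), which is exact and monotone in s, so the
  separation is found by root bisection. Calibrating the separation rather
  than the jitter keeps the independently specified covariance — and hence
  the correlation ground truth — untouched.
* **Residence series** — stay: stationary Gaussian noise (sd 0.5 Å) around
  the initial 4 Å distance; leave: linear mean drift (default 0.3 Å/frame);
  blow-up: stay-like until the divergence frame, then +2(t−t_div)² Å.
  Values are clipped at zero. The divergence shape is an artifact choice:
  the behaviour it emulates was never defined quantitatively.
* **Sensorgrams** — the deterministic two-state simulation plus i.i.d.
  Gaussian read noise per time point. Instrument drift, bulk
  refractive-index jumps and mass-transport limitation are deliberately
  absent.

## Problem sizes in the shipped checks

The test suite and the reproduction script use 5000-frame toy trajectories
for correlation/occupancy recovery (Fisher-z 3-SE bands), 100 seeded
replicates per residence regime, 5–10 noisy fit replicates, and one full
30 × 400 × 10 decoy generation (120,000 rows). These sizes give the
statistical checks comfortable power while keeping a full run in seconds
to a few minutes on one core.

## Limitations

* Absolute interface-correlation values (the published 0.27–0.44 band and
  0.38 baseline) cannot be recomputed without the original MD
  trajectories; the package validates the statistic and reproduces the
  published *ordering* from the published scores instead.
* The stay/leave triage cannot reproduce the specific published
  per-peptide outcomes, which depend on the original 5 ns simulations; it
  reproduces the generating regime labels of the synthetic series.
* The bundled toy rescoring potential is a contract stand-in, not a
  validated statistical potential.
* Synthetic trajectories have no temporal autocorrelation, no solvent, no
  periodic boundary handling; synthetic sensorgrams have no instrument
  artifacts. Passing tests certify the estimators and procedures, not
  robustness to those real-data features.
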