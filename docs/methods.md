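# Methods

## Model and protocol

A titration run is a chain of constant-temperature simulation windows over
an increasing ramp.  The default ramp — start 300 K, end 450 K, increment
10 K, 10 ns per window — is the protocol's standard operating condition;
per-window durations may differ (`build_ramp` accepts a list).  Windows are
chained, not restarted: the end state of window *k* seeds window *k + 1*,
so the titration is one continuous heating experiment.  The first
production window runs *at* 300 K; the titration's anchor state
(300 K, −1) represents the equilibrated native complex itself.  The ramp
must be chosen so the protein fold survives: the run loop monitors mean
backbone RMSD per window and logs a warning above 5 Å (configurable), but
never terminates on it — fold integrity is a ramp-design check, not a
scoring signal.

### Interaction fingerprint

Each frame is encoded as an integer vector of length `r × 8` (slot of
residue *i*, class *c* is `i*8 + c`); entries are occurrence counts, one
per qualifying atom pair or ring pair, not binary bits.  Residue ordering
is frozen at parse time (file order), so reference and query vectors are
always slot-aligned.  Geometric detection rules and defaults
(ODDT-compatible, all configurable via `InteractionGeometryConfig`):

| class | rule | default |
| --- | --- | --- |
| hydrophobic | hydrophobic–hydrophobic heavy-atom pair | ≤ 4.0 Å |
| H-bond (either direction) | donor-heavy···acceptor distance, plus donor–H···acceptor angle when hydrogens are recorded | ≤ 3.5 Å, ≥ 130° |
| salt bridge | cationic···anionic heavy atoms, classed by the protein side's charge | ≤ 4.0 Å |
| aromatic face / edge | ring-centroid distance with folded inter-normal angle | ≤ 5.0 Å; ≤ 30° face, 60–90° edge |
| metal ionic | protein-bound metal to ligand anion/acceptor | ≤ 3.0 Å |

An atom is *hydrophobic* when it is carbon or halogen bonded only to
carbon, halogen or hydrogen.  Protein donors/acceptors/charges come from a
fixed per-residue-name table at pH ≈ 7.4 (Lys/Arg cationic, Asp/Glu
anionic, His neutral with both ring nitrogens donor + acceptor, backbone
N donor / O acceptor); ligand features come from the input file's
elements, bonds and formal charges and are never re-perceived.  Two
deliberate conventions:

* **Salt-bridge precedence.** A cationic–anionic pair is counted only as a
  salt bridge, never additionally as a hydrogen bond, since charged N/O
  atoms are also donors/acceptors under any reasonable table and would
  otherwise double-count every ionic contact.
* **Missing hydrogens.** When a donor has no recorded hydrogen (stripped
  trajectories), the H-bond test degrades to the heavy-atom distance
  alone.  Both code paths are exercised in the tests.

### Scoring and termination

`IFP_CS = −cos(reference, frame)`.  The cosine of two non-negative count
vectors lies in [0, 1], so IFP_CS lies in [−1, 0]; an all-zero query
scores 0 by convention (a dissociated ligand shares nothing with the
reference), and an all-zero *reference* is rejected — a pose with no
detectable native interactions cannot be titrated.  The denominator is
computed as `sqrt(dot(a,a)·dot(b,b))` so self-similarity is exactly 1.
After each window the mean frame score is taken; the run terminates
after the first window whose mean is **exactly** zero.  Exact equality is
sound here, not a numerical hazard: with integer fingerprints a frame
scores zero iff its dot product with the reference is the integer zero, so
a zero mean certifies the native mode was absent in every frame of the
window.

### MS coefficient

The printed definition of the titration slope,
`MS = (meanIFP_CS(T_end) + 1) / (T_end − T_start)`, cannot span the
stated [0, 1] range under the default ramp: total first-window loss would
give at most 1/10 per kelvin.  The package therefore measures the
temperature axis in ramp-increment units with a cap at 1 — total loss in
window 1 (T_end = T_start) is defined as MS = 1, full-ramp retention at
mean −1 gives MS = 0, and intermediate outcomes interpolate while
preserving "earlier loss ⇒ higher MS".  `MSResult` carries the raw
per-kelvin slope alongside the normalised value, plus T_end and the final
window mean (the per-window average, not the last frame).  Replicates
aggregate by dropping exactly one maximum and one minimum (one instance
each on ties) and averaging the rest — 3 of the default 5 survive; the
rule applies unchanged for any n ≥ 3.

### Trajectory analyses

Frames are superposed on backbone N/CA/C/O by least-squares rigid
superposition (Kabsch, via `scipy.spatial.transform.Rotation`); ligand
heavy-atom RMSD is computed in the backbone-fitted frame without
refitting, so it measures ligand motion relative to the protein.  No
ligand symmetry correction is applied (a documented limitation for
symmetric ligands).  The contact report ranks residues by the fraction of
frames with any heavy-atom pair within 4.5 Å and caps the table at 25
rows, ties broken by residue order; it replaces force-field interaction-
energy decomposition, which is out of scope here.

## Synthetic backend

`make_fixture_complex` lays interaction sites 16 Å apart along one axis —
one minimal residue fragment per declared interaction (Ala for
hydrophobic, His rings for both aromatic modes, backbone N–H/C=O for the
two H-bond directions, Lys/Asp for the salt bridges, a Zn ion for metal
coordination) — with the matching ligand moiety placed strictly inside the
detection threshold (margin ≥ 0.3 Å / 10°) and all non-participating atoms
kept beyond threshold + 0.5 Å.  Protein aromatic sites use histidine and
the ligand ring is carbons-only benzene so ring stacking creates no
incidental hydrophobic or H-bond contacts: His ring atoms all border a
nitrogen (non-hydrophobic) and benzene carbons are neither donors nor
acceptors.  The reference fingerprint of every fixture therefore equals
the declared interaction multiset exactly, which is the oracle the
detection tests rely on.

The toy dynamics keeps the protein rigid and evolves only the ligand: per
frame, interaction *i* survives independently with logistic probability
`p_i(T) = 1/(1 + exp((T − T_i)/s))` (sharpness default `s` = 5 K — a loss
transition spread over roughly ±25 K, narrow enough that 30 K pose spacing
separates cleanly); a lost interaction's moiety is displaced 10 Å away,
an intact one keeps template geometry with sub-0.2 Å jitter.  Once a whole
window passes with no interaction intact the ligand is flagged
dissociated, after which interactions only reappear with the per-frame
`rebind_probability` (default 0).  This reproduces the qualitative
features the protocol exploits — temperature-ordered loss of interactions,
partial binding-mode degradation (per-moiety displacement), sticky
dissociation — but none of the physics: no forces, solvent, kinetics or
entropy.  Passing tests therefore demonstrate that the *scoring and
ranking machinery* recovers a known stability order, not that the protocol
ranks real poses; that evidence must come from real MD through the
`ttmd score` path.

Pose sets for recovery experiments share one topology and differ only in
characteristic temperatures: pose *k* centres its temperatures at
320 + k·spread K with small seeded per-interaction offsets (±5 K), so the
true stability order is the construction's pose order.  All randomness
derives from one master seed through `numpy.random.SeedSequence` spawn
keys (pose, replicate, window), making replicates independent but fully
reproducible below 2³¹.

## Numerical choices and problem sizes

* Frame stride 100 ps (100 frames per default 10 ns window), configurable.
* Ring plane normals come from the smallest singular vector of the
  centred member coordinates; inter-normal angles are folded into
  [0, 90°].
* Ramp spans must be integer multiples of the increment; scalar durations
  broadcast.
* Pose ranking breaks exact MS ties lexicographically by pose id and flags
  them in the report.
* Statistical surfaces run at deliberately compact sizes chosen to give
  stable statistics on a single CPU: 9-residue / 4-interaction fixtures,
  5-pose sets spread 30 K apart with 5 replicates at 100 frames/window
  over 10 master seeds for rank recovery, and 20 seed-paired runs for MS
  monotonicity.

## Known limitations

* Protein feature typing is table-driven at fixed pH; no protonation-state
  prediction, and nonstandard residues fall back to backbone-only typing.
* Ligand perception trusts the input file completely: missing charges or
  aromatic flags silently remove the corresponding interaction classes.
* Water-mediated interactions, halogen bonds and cation–π are not encoded
  (not part of the 8-class vector).
* The synthetic backend is a scoring testbed, not a physical model; MS
  values from it carry no free-energy or residence-time meaning.
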