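# Methods

## The model

`apoptonet` analyses a signed-threshold Boolean network of the neuronal
apoptosis decision. Vertices are proteins (plus a DNA-damage marker and
two stimulus inputs); edges carry +1 (activation) or −1 (inhibition).
All vertices update synchronously:

* input sum `W_i(t) = b_i + Σ_j a_ij S_j(t)` over incoming edges whose
  persistence gates are open,
* `S_i(t+1) = 1` if `W_i > 0`, `0` if `W_i < 0`,
* at `W_i = 0` an ordinary vertex holds its state (protein persists until
  actively removed), a *self-degrading* vertex decays to OFF,
* a *constitutive* vertex carries `b_i = 1`, modelling basal synthesis:
  it is ON unless actively inhibited (IκB, BAD, NF-κB in the curated
  asset — proteins whose activity is controlled by removal, not by
  induction).

Inputs (GF, FasL, and the HSP vertices of the extended networks) are
clamped to their condition value for the whole run; perturbations use the
same mechanism (knockout = clamp OFF, overexpression = clamp ON).

### Persistence gates

Three regulatory events in the curated network are delayed until their
source has been ON for a run of consecutive steps: DNA damage activates
p53 only after three consecutive ON steps; caspase-3's inhibition of IAP
and p53's transcriptional programme (BAX up, BCL2 down, MDM2 up,
self-limitation) require two consecutive ON steps. A gate can be
*sustained* (the edge contributes whenever the run is at or above the
threshold) or *pulse*-like (the edge fires exactly at the step where the
run reaches the threshold — a one-shot event per run, modelling a
cleavage or a transcriptional burst rather than a steady influence).
Consecutive-ON counters start at 1 for initially-ON vertices and reset
to 0 whenever the vertex switches OFF.

### Attractors and stability

A trajectory runs 15 synchronous steps, matching the longest regulatory
path of the curated network. The **attractor** of a trajectory is its
final state. The attractor is **stable** when it is a *robust fixed
point*: the synchronous map leaves it unchanged both with every
persistence counter saturated (sustained gates open, pulses spent) and
with every gated edge silent (fresh counters) — no gate history can move
it. It is **transient** otherwise: a pending or spent gate event can
still push the state somewhere, so the network merely passes through or
pauses in it — such quasi-stable states appear as genuine endpoints of
the finite horizon. This two-regime test was chosen over re-simulation
because the gate refractory periods make any single counter convention
misclassify either the held states or the pass-through states.
``find_attractor`` additionally flags period>1 endpoints of a single
trajectory as *unresolved* (the curated network produces only
singletons).

Exhaustive enumeration sweeps all `2^(free vertices)` initial states per
clamp condition in blocks of 2^18, so a full 2^19 sweep of the curated
network takes under ten seconds on one CPU.

### Fate classification

Attractor states map onto three cellular fates by inspecting the
executioner machinery: **apoptosis** when both caspase-8 and caspase-3
are ON; **DNA repair** when caspase-8 is ON together with persistent DNA
damage but caspase-3 has not fired; **survival** otherwise (including
states with downstream caspase activity but no caspase-8 initiator).
The rule is pinned by a consistency test against all seventeen curated
attractor labels. Fate probabilities are exact rationals on basin
counts; rounding happens only at presentation.

## The curated network asset

The 21-vertex wiring is shipped as a plain-text signed interaction file
plus a YAML rule configuration (vertex order, input/self-degrading/
constitutive flags, gates). The wiring was transcribed from the
literature-curated interaction map of the neuronal apoptosis pathway —
FasL → caspase-8 (checked by cFLIP), the BID/BAX mitochondrial arm
releasing cytochrome-c and SMAC, the apoptosome (APAF → caspase-9 →
caspase-3) checked by IAP, the growth-factor arm (AKT, IKK/IκB/NF-κB,
BCL2, BAD, MDM2) and the DNA-damage/p53 axis — under the constraint
that the nine published stable attractor strings are exact fixed points
of the update map and the eight published transient strings are not.
The per-vertex flags and gate modes were selected against the published
attractor table (strings, stability classes and basin sizes); where the
table does not pin a choice down, the more literal reading of the update
rule was kept. Known limitations of this reconstruction are listed at
the end of this note.

## Synthetic networks

`apoptonet.synthetic` generates random signed-threshold networks
(configurable vertex/edge counts, activation and self-degradation
fractions, input count, gates with thresholds in {2, 3} mirroring the
curated magnitudes; pure function of the seed). These drive the
property-based tests: enumeration versus the explicit transition-graph
oracle, batch-versus-serial simulation equivalence, and validation
invariants. Random networks have arbitrary topology — they emulate the
*update semantics*, not apoptosis biology, so passing property tests
demonstrates the engine's correctness, not biological realism. The
hand-built fixtures (single decaying vertex, mutual inhibition, a gated
chain, a four-vertex stress/protector/effector/readout motif) have fully
hand-enumerable transition tables documented in their docstrings.

## Numerical choices

* Exhaustive enumeration is exact integer counting; fate fractions are
  `fractions.Fraction` values, bit-identical across runs and platforms.
* State blocks are `int8` matrices; the update is a vectorised
  matrix product over the ungated adjacency plus per-gated-edge
  corrections, then a three-way `where`.
* The brute-force oracle caps counters one step past the largest gate
  threshold, which is exact because gates only test `run >= threshold`
  or `run == threshold`.
* Ties (`W = 0`) are resolved by the hold/decay rule above; there are no
  stochastic components anywhere in the engine.

## Known limitations

* The wiring is a constrained reconstruction, not a copy of the original
  curated rule table. What is pinned down exactly: the nine stable
  attractor strings are bit-exact robust fixed points with the published
  stability classes; the two single-input conditions collapse onto their
  single attractors with the full 2^19 basin; the fate classifier
  reproduces all seventeen published labels. What is not: under the two
  growth-factor conditions the timing races between the survival arm and
  the mitochondrial cascade allocate a minority of initial states to
  different endpoints than the published basin sizes, four of the eight
  published transient snapshot states do not arise as 15-step endpoints,
  and the knockout-screen and HSP-extension probabilities deviate
  accordingly. `tests/test_acceptance.py` records both the reproduced
  and the non-reproduced published values; failures there document the
  residual gap rather than implementation defects.
* Only synchronous updating is implemented; asynchronous or stochastic
  schemes explore different transient structure.
* The HSP extensions model overexpression as a clamped input; HSP
  induction dynamics are out of scope.
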