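# Methods

## Model class

`erbbsim` simulates *logical* (Boolean) models of signal transduction
with semi-quantitative, continuous inputs and outputs.  A network is a
set of named nodes partitioned into **external inputs** (stimuli with no
rule) and **internal nodes**, each governed by one Boolean expression
over other nodes (AND/OR/NOT, constants allowed; precedence
NOT > AND > OR, case-insensitive keywords, case-sensitive identifiers).

The continuous layer is the **activity level (%ON)**: each external
input is assigned a level in [0, 100], and at every discrete time step
the input is ON with probability level/100, independently across steps.
A node's output activity is the percentage of measured steps it spends
ON.  %ON is a relative activity measure, not a concentration; the
scientific claims the package makes are directional (which node goes up
or down under a perturbation) and ordinal (dose-response monotonicity),
not metric.

## Simulation protocol

Per replicate:

1. one level per non-locked external input is drawn uniformly from its
   environment interval (degenerate intervals return their endpoint;
   inputs absent from an environment are 0);
2. internal nodes start OFF; locked (mutated) nodes are pinned to their
   bit and ignore rules and environment alike;
3. at each step, every non-locked internal node is updated
   synchronously from the full state at the previous step, and every
   non-locked external input is resampled;
4. the first `transient_steps` states are discarded and %ON is averaged
   over the next `window_steps` states.

Defaults are `transient_steps=200`, `window_steps=800` — comfortably
past the longest feedback cycle in the bundled network (the six-step
endocytic loop), as confirmed by the exact-oracle agreement tests.  The
update scheme (synchronous internal update with per-step stochastic
resampling of inputs, levels drawn once per replicate) is declared, not
derived: it is the simplest scheme consistent with continuous %ON
inputs and outputs, and every quantitative claim in the test suite is
made under it.

**Seeding.**  Replicate *r* draws from a generator seeded with
`SeedSequence(seed, spawn_key=(..., r))`, so results are bitwise
reproducible, independent of batching, and comparison arms can be given
disjoint streams from one scenario seed.  Internally, replicates are
advanced in vectorized batches (all replicates' node states held in one
boolean matrix; each rule compiled once into a vectorized kernel), which
is why window sizes of 10^4 steps and thousands of replicates run in
seconds.

## Exact oracle

For networks with at most 16 free internal and 10 free external nodes,
`exact_activity` computes expected %ON exactly: the distribution over
all 2^N internal states is propagated by a sparse transition operator
that averages the deterministic synchronous image over all 2^K external
assignments, weighted by the product of per-input Bernoulli
probabilities.  Starting from the all-OFF state it replays the same
transient/window schedule as the sampler, so the two agree in
expectation *exactly*, not just asymptotically.  The test suite checks
|simulated − exact| ≤ 4 SE on dozens of random networks; the SE is the
empirical SEM across independent replicates, which is robust to the
within-replicate autocorrelation of Boolean dynamics.

One caveat surfaced by the tests: when a subsystem's dynamics are fully
deterministic (e.g. the endocytic cycle under constitutively active
Src), the replicate SEM collapses to zero while finite-window averages
of a periodic signal retain a phase dependence of order
(cycle length)/window.  Comparisons against embeddings with different
boot phase therefore carry an explicit windowing slack of 2 steps.

## Experiments layer

* **Dose response** — every replicate draws all input levels (including
  the swept one); replicates are binned by the drawn sweep level into
  equal-width bins (default 10) and output %ON is averaged per bin.
  Binning replicates rather than gridding the input mirrors how the
  condition ranges are specified and gives honest per-bin SEMs.
* **Mutation comparison** — a wild-type arm and a perturbed arm
  (scenario mutations plus the requested locks) are simulated with
  disjoint seed streams, and each output node gets a two-sided
  pooled-variance Student's t-test (Welch available behind a flag).  A
  `paired` option reuses the wild-type streams in the perturbed arm
  (common random numbers); it makes an empty perturbation exactly null
  and is used as an identity check.  Degenerate cases are explicit:
  both arms constant and equal → t = 0, p = 1; zero pooled variance with
  unequal means → t = ±inf, p = 0, flagged.  p-values are reported
  per node without multiple-testing correction, matching how such
  in-silico screens are conventionally read; the tables carry every
  p-value so any correction can be applied downstream.
* **Scenario library** — the ten published external-condition sets
  (eight validation experiments and the two Src experiments), with the
  receptor-expression series as three named variants of one scenario.
  These are frozen data, asserted against an independent transcription
  in the tests.

## The hMEC reconstruction

The bundled network (38 internal nodes, 14 inputs) is an explicit,
documented *reconstruction* of the ErbB/endocytosis core of a human
mammary epithelial cell — not a copy of any full-scale rule set.  It
captures: the dimerization hierarchy (ErbB2–ErbB3 > EGFR–ErbB2 >
EGFR–EGFR when partners are expressed, with ErbB2 availability =
expression AND NOT degradation); ligand-specific endocytic chains
(EGF-bound homodimer → coated pit → vesicle → early endosome → MVB →
lysosome; TGFα-bound receptor → a shorter, lysosome-free recycling
chain); MAPK and PI3K/Akt arms fed by receptors and integrin/FAK; a
GPCR arm in which Gi attenuates Gs-driven adenylyl cyclase; and token
stress inputs.  `ExtPump` is accepted in environments but intentionally
unwired.  Src is receptor-driven (homodimer or EGFR–ErbB2); the
integrin→Src route is deliberately omitted because under the high-ECM
backgrounds of the published conditions it would saturate Src and erase
the receptor-level contrast the Src experiments measure.

**Internalization design.**  The wild-type homodimer internalizes via
cCbl engagement, which requires two consecutive active steps at the
membrane; active Src additionally drives a *ligand-independent*
internalization route for the surface receptor
(`CCP_E = (PM AND cCbl) OR (Src AND EGFR AND NOT ErbB2 AND NOT
(CCV OR EE OR MVB))`).  We first evaluated a weaker design in which Src
merely reduced the two-step requirement to one step.  It reproduced the
right directions, but at 0–5% EGF the plasma-membrane effect was
~0.25 %ON against a between-replicate SD of ~1.5 %ON (dominated by the
drawn EGF level), i.e. expected t ≈ 2 at n = 300 — a coin-flip
significance.  The ligand-independent route was adopted instead: it is
the mechanism the biology actually suggests (Src overexpression
depletes surface EGFR even without added ligand), and it yields a
robust effect (t ≈ −23 at low EGF) while leaving every validation
phenomenon intact.  The route is wired only into the homodimer (EGF)
chain that the prediction tracks; the TGFα chain keeps the simpler
single/double-step logic.

Consequence worth noting: with Src locked ON, compartment occupancy is
driven even at EGF = 0 (that is the prediction), so "no ligand ⇒ empty
chain" holds only for wild-type Src.

## Synthetic networks

`random_network` draws, per internal node, 1..`max_in_degree` distinct
regulators and a random truth table whose rows are ON with probability
`bias`, rendered by plain minterm expansion (no minimization).  Cycles
and self-loops are allowed by default; `feedforward=True` restricts
regulators to inputs and earlier nodes.  These generators share the
engine's structural assumptions but none of the biology: agreement
between sampler and oracle on them validates the *engine*, not the
reconstruction, and passing tests on synthetic networks says nothing
about how faithfully the reconstruction abstracts a real cell.
`chain_fixture` builds pass-through/negation chains with closed-form
stationary activities for the engine's anchor tests.

## File formats

* **Rule text**: one `Name = EXPR` per line, `#` comments, duplicate
  assignments rejected with line numbers; identifiers never assigned
  are externals, and a `# @external:` directive declares inputs
  referenced by no rule so they survive round trips.
* **SBML-qual**: Boolean subset (all species `maxLevel=1`, externals
  `constant=true`, one transition per internal node, MathML
  and/or/not over `eq(ci, 1)` atoms), written and parsed with `lxml`.
  Multi-level species and unsupported MathML constructs are rejected
  with messages naming the offender.
* **Results**: TSV, LF endings, 6-significant-digit floats, and a `#`
  provenance header (tool version, seed, model hash) so every table is
  traceable; the header does not break standard TSV parsers.

## Problem sizes and limitations

The shipped analyses use n = 2000 runs per dose-response sweep (10
bins), n = 1000 replicates for the dimer-hierarchy means, and n = 300
per arm for the Src comparisons with the default 200/800 step schedule;
the oracle-equivalence sweep uses 50 random networks at a 10^4-step
window.  Known limitations: no asynchronous or continuous-time update
semantics; no attractor analysis (only empirical %ON); no
phosphorylation-site resolution, ErbB4, STAT/E-cadherin depth, or
drug/antibody nodes in the reconstruction; p-values are conditional on
the declared update scheme and initial condition (all-OFF plus
transient) rather than on any biologically measured initial state.
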