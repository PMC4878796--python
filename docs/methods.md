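# Methods

## Model

The pathway is modeled as a place/transition Petri net: 18 places
(genes, proteins, complexes), 11 transitions (complex formation,
dissociation, translocation, gene expression) and 41 arcs. Token counts
are coarse relative protein levels, not concentrations, and simulation
steps order events without mapping to physical time; only relative
differences between conditions are interpreted.

Core assumptions, chosen to isolate the immediate logic of β-catenin
stabilization:

- Production and degradation of every protein except β-catenin are
  balanced and omitted; their token mass is conserved by construction.
- β-catenin is produced once per step by the gene-expression motif
  (gene place holding 1 token, required and re-produced, never
  consumed) and removed only through the destruction-complex cycle.
- AXIN1 and AXIN2 are one entity (`AXIN`); cytoplasmic and nuclear
  β-catenin are one pool; GSK3/CK1 receptor-level action is ignored.
- AXIN is the only destruction-complex component sequestered at the
  membrane.
- Nuclear translocation/TCF-binding (t10) requires 3 free β-catenin
  tokens but consumes 1 (weights 3 in / 2 out), encoding the lower
  affinity of β-catenin for TCF/LEF than for the destruction complex.
- TCF/LEF and the TCF/LEF–β-catenin complex act catalytically
  (symmetric read-arc pairs on t10 and t11 respectively), so t10 can
  fire repeatedly at TCF/LEF = 1 and t11 requires, but does not
  destroy, the activator complex. With this choice total β-catenin is
  conserved by t10/t11, which is what makes the GSK3 = 0 endpoint
  exactly 100 tokens. See *Known limitations* for the consequence.

## Execution semantics

**Maximal parallelism with random conflict resolution.** Each step
builds a firing multiset by iterated uniform-random reservation: among
the transitions enabled against the not-yet-reserved tokens, draw one
uniformly, reserve its inputs, repeat until none is enabled. The result
is maximal by construction and unbiased between competitors (two
transitions contending for one token each win 50 % of draws). The
scheme re-evaluates the enabled set after every reservation; a
once-per-step permutation would be an alternative sampling scheme —
the per-reservation redraw is the simplest one satisfying both
maximality and uniform conflict resolution.

**End-of-step production.** Tokens produced in step *k* are first
consumable in step *k + 1*. This is the standard maximal-step
convention and prevents unbounded within-step cascades (e.g. the
t6→t7→t6 loop).

**Fractional weights as firing rates.** Each fractional arc owns an
exact-rational credit accumulator in [0, 1). A firing adds the weight;
the integer part of the credit is transferred and the remainder kept.
Credit advances only on steps in which the transition fires, so a
transition waiting on an empty input place accrues nothing. Because the
arithmetic is exact (`fractions.Fraction`), a continuously enabled
transition at weight *p/q* transfers exactly *p* tokens in every *q*
consecutive steps — 0.1 yields transfers at steps 10, 20, 30, …; 0.15
at steps 7, 14, 20 of every 20-step window; 0.05 once per 20 steps —
with no floating-point drift over any horizon.

**One-firing cap.** Per-firing credit is only well defined at one
firing per step, so every transition carrying a fractional arc is
capped at a single firing per step (this generalizes the explicit cap
on signalosome dissociation to the APC-mutant t5 and the feedback-mode
t11, which need it for the same reason). A transition with no input
arcs is capped identically — otherwise it would be enabled forever
within a step and maximal sampling would not terminate. The pathway net
contains no such transition; the rule matters only for user-supplied
nets.

**Weight-0 arcs.** A weight of exactly 0 is legal on transition→place
arcs only, where it is inert: it imposes no enabling requirement,
transfers nothing, and leaves the executed system — including the
random number stream — identical to a net without the arc. This lets
the t11→AXIN feedback arc stay in the net (keeping the 41-arc topology
stable) while switched off. Zero-weight input arcs are rejected by the
validator as meaningless.

## Scenario parameters

| parameter | range | default | meaning |
|---|---|---|---|
| `initial_wnt` | 0–5 tokens | 0 | WNT stimulus strength |
| `initial_gsk3` | 0–5 tokens | 5 | 5 = wildtype, 0 = complete inhibition |
| `axin2_feedback_weight` | [0, 0.15] | 0 | t11→AXIN rate; 0.15 = 3 transfers / 20 steps |
| `apc_dc_production_weight` | [0, 1] | 1 | t5→DC rate; 0.2/0.1/0.05 = one complex per 5/10/20 steps, 0 = null mutation |
| `steps` | ≥ 1 | 100 | horizon of the early stabilization phase |
| `replicates` | ≥ 1 | 100 | ensemble size |

Initial protein pools are 5 tokens (a concise but sufficient working
pool; the dose-response knobs WNT and GSK3 sweep 0–5), TCF/LEF and both
gene places hold 1, and all complexes plus free β-catenin start at 0.
In APC-mutant mode the four t5 return arcs carry weight 1 − w so that
components are net-consumed exactly once per 1/w firings. The campaign
defaults (100 steps × 100 replicates; APC weights {0.2, 0.1, 0.05, 0};
feedback grid {0, 0.05, 0.10, 0.15} × WNT {3, 4, 5}) are the standard
study conditions and also comfortably cheap: a full campaign is ~10⁵
transition evaluations and runs in about a second per ensemble.

## Statistics and estimators

- Replicate *r* of an ensemble uses seed `base_seed + r`; every result
  is a pure function of (net, steps, seed). SD is the sample standard
  deviation (ddof = 1); with one replicate it is reported as 0 with a
  warning.
- **Degradation rate** (tokens per 3 steps): since production is
  exactly 1 token/step, cumulative degradation at step *n* is
  *n* − mean total β-catenin(*n*). The rate is 3× the least-squares
  slope of that series over a late window (default steps 40–100),
  which excludes the initial transient in which the destruction-complex
  cycle fills up. Measured values: ≈ 0.85 per 3 steps at GSK3 = 1,
  ≈ 1.72 at GSK3 = 2, 3.0 (saturated, equal to production) at
  wildtype. The GSK3 = 1 and 2 values sit slightly below the nominal
  1 and 2 because the complex-reuse route (t7, a 2-step cycle) and the
  dissociation route (t8, a 3-step cycle including re-formation) are
  drawn with equal probability; a scheduler biased toward reuse would
  push the rates toward their nominal values.
- **Qualitative classifications** are operationalized once and kept
  fixed: a curve is *flat* if its ensemble-mean endpoint is below 10
  tokens (`FLAT_RESPONSE_THRESHOLD`, a config constant); a response is
  *delayed* if the mean stays below 5 tokens through step 5 (WNT
  stimulation is, complete GSK3 inhibition — which reaches 5 tokens at
  step 5 exactly — is not); feedback *peak-then-decline* requires an
  interior maximum exceeding the endpoint by at least 1 token, with
  peak steps non-decreasing in WNT and strictly later at WNT 5 than 3.

## Synthetic fixture nets

`random_net` generates small connected bipartite nets (integer weights
≤ 3, random marking) for engine property tests: a backbone chain
guarantees connectivity and at least one input per transition, plus
random extra arcs. In conservative mode every transition's input weight
sum equals its output weight sum (extras are added as balanced
read-arc pairs), making total token count an exact invariant — used to
test conservation. These fixtures exercise the engine's combinatorics;
they do not emulate biological structure, so passing them says nothing
about pathway realism — that is what the mass-balance and dose-response
checks on the pathway net itself are for. An independent brute-force
enumerator of all maximal firing multisets (test-suite code, sharing
nothing with the engine) provides the oracle the sampler is checked
against on nets with ≤ 5 places.

## Known limitations

- **The feedback response plateaus instead of overshooting.** Because
  t10 carries a read-arc on TCF/LEF, every spell of free β-catenin
  above 3 tokens feeds the TCF/LEF–β-catenin pool, which no transition
  degrades. The reported total therefore has a non-decreasing floor,
  and under strong feedback (weight 0.15) the mean curve rises to an
  attenuated plateau (e.g. ~16 tokens at WNT = 5, versus ~65 without
  feedback) rather than passing through an interior maximum and
  declining to baseline. A variant in which t10 consumes its TCF/LEF
  token (a single long-lived transcription complex; 40 arcs) does
  produce the overshoot-and-return shape, but breaks the 41-arc
  topology and was not adopted; the catalytic choice was kept because
  it also guarantees exact β-catenin conservation through t10/t11
  (GSK3 = 0 → exactly 100 tokens) and sustains transcriptional
  signaling at TCF/LEF = 1.
- Token levels and steps have no physical units; comparisons are
  relative between conditions only.
- The conflict sampler's per-reservation redraw is one of several
  schemes consistent with uniform random resolution; rate estimates
  (the 0.85/1.72 above) are scheme-dependent at the ±20 % level.
- No inhibitor arcs, capacities, timed/colored extensions; PNML export
  writes fractional inscriptions as decimal strings, which stock
  integer-only P/T tools will not read.
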