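# Methods

## The model

`segpol` implements the segment polarity network (SPN) of the early fly
embryo as a deterministic ODE model on a sheet of hexagonal cells.  Five
genes operate in every cell — *engrailed* (en), *wingless* (wg),
*patched* (ptc), *cubitus interruptus* (ci) and *hedgehog* (hh) — with 33
state variables per cell: the five mRNAs, the cytosolic proteins EN, IWG
(intracellular wingless), CI and CN (the cleaved repressor fragment of
CI), and four membrane proteins (EWG, PTC, HH and the patched–hedgehog
complex PH) each resolved into six per-side pools.  The default 1 × 4
periodic row therefore has 132 state variables; the row is a thin torus
(single-row grids wrap vertically onto themselves), which is the smallest
geometry on which the parasegmental pattern — wg high in cell 2, en/hh
high in cell 3 — can be posed.

Regulatory wiring (all edges, per cell):

* **en** — induced by EWG_T, the total wingless protein on the six apposed
  neighbor faces; repressed by CN.  EN translates from en.
* **ci** — transcribed constitutively under EN repression.  CI translates
  from ci and is cleaved to CN at rate `C_CI · CI · φ(PTC_T)`, where
  PTC_T is the cell's total free patched.
* **wg** — composite law: CI activation (with CN competing at the CI
  sites) plus autoactivation through IWG,
  `V · S/(1+S)` with `S = α_CIwg·φ(CI)·ψ(CN) + α_WGwg·φ(IWG)`.
  IWG exchanges with the six EWG pools by exo-/endocytosis; EWG diffuses
  laterally between adjacent sides.
* **ptc** — induced by CI, repressed by CN.  PTC is translated equally to
  the six sides, diffuses laterally, and captures HH arriving from the
  apposed neighbor face, forming PH on the PTC-owning side.
* **hh** — induced by EN, repressed by CN.  HH per-side pools as for PTC.

φ and ψ are activating/repressing Hill responses.  Transcription with an
inducer–repressor pair uses `V·(I·ψ(R))^h1 / (k1^h1 + (I·ψ(R))^h1)`.

**Normalization.**  Concentrations are dimensionless fractions of each
species' attainable range.  Maximal transcription rates are tied to mRNA
decay (`V = ln2/H_mRNA`) and translation rates default to
`ln2/H_protein`, so every cytosolic species saturates at 1 under full
drive; a membrane pool's range is one sixth of that (translation splits
across sides).  Only the bimolecular PTC–HH capture needs absolute
scales: PTC0 and HH0 convert the normalized concentrations, entering the
flux asymmetrically (`k·HH0·PTC·HH` on the PTC/PH balances,
`k·PTC0·PTC·HH` on the HH balance).  Time is the model's generic "time
unit" (plots run 0–1100 without naming minutes).

**Guarded exponentiation.**  Hill terms evaluate `base^ν` via
`exp(ν·log base)`, which is NaN the moment an integrator step pushes a
concentration infinitesimally negative.  All rate laws therefore exist in
a guarded variant that replaces `base^ν` by `max(ε, base)^ν` with
ε = 10⁻⁸⁰ (configurable).  Constants such as `κ^ν` are never guarded.
The unguarded variant is retained deliberately: screening uses the
failure fraction with and without the guard as a study in its own right.

## Parameters

The catalog (`segpol/data/catalog.yaml`) names 53 parameters for the
4-cell build and flags the 48 that the screens sample log-uniformly:
13 half-lives (5–100 time units), 12 κ (10⁻³–1, including the capture
rate κ_PTCHH), 12 ν (1–10, including an effective capture cooperativity
ν_PTCHH whose default 1 is plain mass action), the two wg input weights
α (1–10), six membrane transport rates (10⁻³–1), the cleavage rate C_CI
(10⁻³–1) and the scales PTC0/HH0 (1–1000).  The five translation rates
are unsampled and tied to the product protein's half-life.  Which 48 of
the 53 are sampled, and most of the ranges, are reconstructions: the
archival description states the counts and the PTC0/HH0 range but not the
full table, so the YAML is deliberately the single editable source of
truth.  Two entries (r_MxferPH, ν_PTCHH) exist to complete the pinned
48-sampled count; at their defaults they reproduce the wiring above
exactly, and r_MxferPH (lateral diffusion of PH) cannot affect any
regulatory input because only per-side PH, never its total, is
redistributed.

## Simulation and steady states

Time courses default to the reference conditions: t_end 1100, reporting
every 5 time units (221 points), LSODA with absolute tolerance 10⁻¹³ and
relative tolerance 10⁻⁸.  A non-stiff variable-order Adams–Moulton
integrator (VODE) is available as an independent cross-check; the two
agree to better than 10⁻³ in the sup-norm on the reference run.  Numeric
failures (NaN states, solver aborts) are returned as flagged
trajectories, never exceptions, so screens can tally them.

Steady states are found by integration only — no Newton polishing — with
a "distance and time" acceptance: starting from T = 1000 and doubling,
the state is accepted when both `‖f(x)‖∞` and the displacement
`‖x(2T) − x(T)‖∞` fall below the resolution 10⁻⁴.  The search integrates
at rtol 10⁻⁶ / atol 10⁻¹⁰ — two orders below anything the resolution can
distinguish — and caps the horizon at 16,000 time units; runs that reach
the cap with bounded, non-decaying motion (limit-cycle suspects) report
"not found".  Both the tolerances and the cap are resource-conscious
choices for single-CPU runs and are configurable.

## The synthetic-data generator

The sampling module is the study's data source; nothing external is
read.  Parameter sets draw the 48 sampled entries log-uniformly over the
catalog ranges.  Initial conditions come in seven named schemes built
from a three-level vocabulary — 0.15, 0.4, 0.9, standing for "< 20 %",
"20–60 %" and "60–100 %" of a species' range.  Levels annotate the
species a scheme names (a striped species carries 0.15 in its OFF
cells); species a scheme does not mention start at 0, which is what
makes "crisp plus ubiquitous low-level ci and ptc" a different condition
from plain crisp.  Membrane levels are divided by 6 across the side
pools.  The derived products CN and PH are not part of the pre-pattern
vocabulary and start at 0 in the pre-pattern schemes; the near-target
scheme, whose meaning is "close to the solution state", does assign CN
its target profile (high in cells 1 and 4, low in the HH-cleared wg
cell, 0 in the en cell, where ci/ptc/CI are likewise exactly 0).  The
degraded scheme's numbers ship in `data/degraded_ic.yaml` and are
explicitly an editable reconstruction — the original values were never
published as numbers.  The exact per-species composition of the
stripe/band schemes is likewise best-effort and configurable.

The multistability screen samples all 132 concentrations uniformly in
[0, 1] — deliberately unrelated to the level vocabulary.

## Scoring

A simulated end state is scored at t = 1000 by a worst-case contrast
ratio: per scored species, `(max over OFF cells + δ) / (min over ON
cells + δ)` with δ = 10⁻⁶, aggregated as the max over species; a hit is
a score strictly below 0.2 ("every OFF cell at most ~20 % of the weakest
ON cell").  There is no stability term.  The screens score {wg, en, hh}.
ptc is available in the template (`include_ptc=True`) but excluded by
default for a structural reason: ptc transcription reads only CI and CN,
both of which are exactly symmetric between the two cells flanking the
en stripe on the periodic row, so a ptc target confined to one flank is
unattainable for *any* parameters and would veto every otherwise-correct
pattern.  This scorer is a reconstruction of a contrast-only score and
is expected to be permissive relative to a contrast-plus-stability
composite.

## Screens

`run_screen` draws one parameter set per attempt (one child RNG stream
each, so tallies are bit-reproducible under the master seed), integrates
the guarded model from the scheme's starting state, and classifies
hit/miss/failure.  "Tries" counts completed integrations only; failures
are tallied separately.  The spoke-plot table maps each hit's displayed
parameters (half-lives and cooperativities omitted) to the normalized
log-position in its sampling range, with mean/SD rows.

`multistability_screen` runs p parameter sets × i = 15 random initial
conditions (defaults p = 5000 at full scale; the test suite runs p = 60
and the documented full run is cluster-scale).  Found states are grouped
by single-linkage clustering in the max-norm with tolerance 10⁻² — two
orders above the steady-state resolution, so one basin is not split by
integration error; the rule itself is a design choice, no published rule
exists.  Unconverged and failed searches contribute no steady state.
Mono- vs multistable parameter distributions are compared by the
per-parameter ratio of medians, sorted by |log fold|.

## What the generator does and does not emulate

The generator reproduces the study's stated structure: 48 log-sampled
parameters, the 1 × 4 guarded model, preset/level-coded or uniform
initial conditions, failure tallying.  It does not emulate the exact
archival sampling ranges (unpublished beyond the PTC0/HH0 range), the
exact initial-condition numbers of the degraded row, or the original
composite score.  Consequently, passing the scaled screen checks shows
the reconstruction produces the same phenomena — rare pattern-holding
parameter sets, an order-of-magnitude failure drop from the guard,
widespread mono- and occasional multistability — at the same rank order;
the measured hit rates themselves are sensitive to those unpublished
choices.  In this build the desk-scale reciprocal hit rates come out
several-fold rarer than the reference values (patterns of hit quality
form and hold transiently in ~5 % of draws but are asymptotically stable
in fewer), while the steady-state fractions of the multistability screen
and the guard contrast land on the reference values.

## SBML

`export_sbml` writes SBML Level 3 Version 1 as a reaction network — one
compartment per cell, 33 species per cell, ~480 reactions for the 1 × 4
model — with every kinetic law in MathML, guards rendered as `piecewise`
so foreign simulators reproduce guard semantics, and the capture
asymmetry encoded as non-integer stoichiometries (HH0 on the PTC/PH
side, PTC0 on the HH side).  The reader is scoped: it rebuilds the
native model from documents this package wrote (identified by a model
annotation), validates structure, preserves parameter values bit-exactly
and raises an explicit unsupported-feature error otherwise.  The test
suite additionally evaluates the document's own MathML with an
independent interpreter and checks it against the compiled right-hand
side at random states, so the exported math — not just the counts — is
verified.

## Numerical and degenerate-input choices

* The compiled right-hand side (numba) and an interpreted evaluator over
  the explicit reaction table are held in agreement by tests; the
  reaction table is also the source for SBML export, so the three
  representations cannot drift apart silently.
* Unguarded negative-base powers follow IEEE pow semantics (NaN), which
  propagates to a flagged trajectory.
* `max(ε, ·)^ν` may underflow to exactly 0 for large ν; the guard's
  contract is "never NaN/inf", not "never zero".
* Grids: the apposition map is built from forward sides only (per-side
  translations are bijections on the torus), which keeps it a total
  involution even for single-row tori where naive per-slot geometry is
  inconsistent across the wrap seam.  Non-periodic walls appose a slot
  to itself (documented clamp).
* Empty hit sets: the spoke-table builder warns and returns an empty
  table rather than raising.

## Problem sizes used by the test suite

Structural and property checks run in seconds.  The screen checks run at
desk scale: 400 + 400 runs for the guard contrast, 2,500 crisp and 1,000
near-target tries for the hit rates (compared against
Poisson-consistency bands around the reference rates at those sizes),
and p = 60 × 15 for the multistability screen (binomial bands).  The
acceptance script runs the stated sizes: 5,000 / 2,000 / 1,000 / 1,000.
Full-scale reproductions (240,000-try screens, p = 5,000) are documented
long-running modes of the same functions.
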