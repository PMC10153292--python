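# segpol

Simulation and analysis of the *segment polarity network* (SPN) — the
gene circuit (*engrailed*, *wingless*, *hedgehog*, *cubitus
interruptus*, *patched*) that maintains segment boundaries in the fly
embryo — as a reusable, tested Python package.

The model is a deterministic ODE system on a sheet of hexagonal cells:
33 species per cell (5 mRNAs, 4 cytosolic proteins, 4 membrane proteins
in six per-side pools), coupled across cells by wingless protein on
apposed membrane faces and by hedgehog–patched capture.  A 1 × 4
periodic row (132 state variables) is the default geometry; the target
pattern has *wg*/*ptc* high in cell 2 and *en*/*hh* high in cell 3, with
the parasegment boundary between them.

For whom: systems biologists and modelers who want to

* simulate the SPN with guarded Hill kinetics
  (`base^ν → max(ε, base)^ν`, ε = 10⁻⁸⁰, so tiny negative solver
  excursions cannot produce NaNs),
* rerun the classic robustness question — *how often do random
  parameter sets produce the segment-polarity pattern?* — as a
  log-uniform sampling screen over 48 kinetic parameters,
* screen for multistability (distinct steady states reached from random
  initial conditions, found by integration only), and
* exchange the model as an SBML Level 3 Version 1 reaction network.

## The core quantities

For a parameter set θ drawn log-uniformly over the catalog ranges, the
model is integrated from a preset starting state and the end state is
scored by a worst-case ON/OFF contrast at t = 1000:

    score(θ) = max over scored species s of
               (max over OFF cells of [s] + δ) / (min over ON cells of [s] + δ)

A *hit* is score < 0.2.  Screens report hits, completed tries, failures
and the hit rate; the multistability screen reports, per parameter set,
the number of distinct steady states reached from 15 uniform-random
initial states (single-linkage clustering, max-norm tolerance 10⁻²).

## Worked example

Run a desk-scale robustness screen from starting states close to the
target pattern:

```bash
segpol screen --scheme near_target --n 800 --seed 102 -o screen.csv
```

prints

```
4 hits / 800 tries (0 failures); hit rate 1/200
```

meaning: of 800 random parameter sets, 4 maintained the segment-polarity
pattern (every OFF cell below 20 % of the weakest ON cell for *wg*,
*en* and *hh* at t = 1000), no integration failed, and the reciprocal
hit rate is 200 tries per hit.  `screen.csv` holds one row per attempt
(outcome, score, and the 48 sampled parameter values);
`screen.csv.summary.json` the tallies with a provenance block, and
`screen.csv.spokes.csv` the normalized log-position table behind the
spoke plot of the hit parameter sets.

The same from Python:

```python
from segpol import run_screen
res = run_screen(800, scheme="near_target", seed=102)
print(res.hits, res.tries, res.hit_rate)   # 4 800 0.005
```

Other entry points: `segpol simulate` (time course CSV, 221 points at
the default t_end 1100 / Δt 5), `segpol multistable` (p × i steady-state
screen), `segpol export` (SBML L3V1), `segpol compare` (stiff LSODA vs
non-stiff Adams cross-check), `segpol build` (model summary JSON).

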