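# stateresp

Mechanistic derivation of predator–prey functional and numerical responses
from fast behavioural-state transitions.

Prey and predator populations are structured into behavioural states
(exposed/hiding, searching/handling, well-fed/starving, ...) whose
transitions are fast relative to birth and death, so the state
distribution equilibrates while the totals `(X, Y)` stay constant. The
package

- specifies such models as conservative transition matrices `A`, `D` and
  mediated-transition tensors `B`, `C` (column sums zero, so totals are
  invariants of the fast dynamics);
- solves the fast equilibrium at fixed totals — exact stationary solves
  (GTH elimination, entrywise-accurate) for the linear/triangular cases
  and a damped alternating fixed point for the fully coupled case — with
  hyperbolic-stability assessment and a multistart uniqueness probe;
- evaluates the emergent population-level responses: functional response
  `f(X,Y)`, prey numerical response `g(X,Y)`, predator conversion and
  mortality factors `γ(X,Y)`, `δ(X,Y)`, and sweeps them over grids;
- ships closed-form reference implementations of the classic
  applications (Holling II, generalised Beddington–DeAngelis, density-
  dependent handling time, type III via starvation or experience
  structure, and a panic model with a predator Allee effect), each
  cross-validated against the generic solver path;
- simulates the full two-timescale system and the reduced totals-only
  system and quantifies the quality of the timescale-separation
  reduction as the scale separation `ε → 0`;
- generates random consistency-valid models and degenerate fixtures so
  everything is testable without external data.

## CLI

The `stateresp` entry point works on JSON model configs (see the
`stateresp.io_cli` docstring for the schema):

```sh
stateresp zoo panic --out panic.json          # emit an application model
stateresp validate panic.json
stateresp equilibrium panic.json --X 1 --Y 1 --starts 20
stateresp responses panic.json --X-grid 0.5,1,2 --Y-grid 1,2 --out table.csv
stateresp simulate panic.json --epsilon 0.01 --t-end 10 --X0 1 --Y0 0.5 \
    --mode both --out traj.csv
```

Available zoo models: `tiered`, `two_state_prey`, `dd_handling`,
`starvation`, `experience`, `panic`; builder parameters can be
overridden with repeated `--params k=v`.

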