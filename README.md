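# biopetri

Structural analysis of place/transition Petri nets for qualitative
biological models: token-game execution, incidence matrices, minimal
semi-positive S-/T-invariant enumeration, reachability/deadlock/
boundedness analysis, and biologically annotated analysis reports.

The package ships a fully verified built-in model, **DANA** (Dopamine
And Norepinephrine Analyze): an 8-place / 6-transition net describing
state changes triggered by low norepinephrine and dopamine levels in
depression. Its structural analysis yields two conserved place sets
(S-invariants), no T-invariants, and a finite acyclic state space in
which every run terminates.

## Library quick start

```python
from biopetri import build_dana, full_report, minimal_s_invariants

dana = build_dana()                      # AnnotatedNet with labels + initial marking
invs = minimal_s_invariants(dana.net)    # [(0,1,1,0,2,1,0,1), (1,0,1,1,1,1,0,1)]
print(full_report(dana).to_markdown())   # full structural/behavioral report
```

Key operations (all exported from the top-level package):

| area | functions |
| --- | --- |
| token game | `is_enabled`, `enabled_set`, `fire`, `fire_sequence`, `random_run`, `is_dead` |
| structure | `input_matrix`, `output_matrix`, `incidence_matrix`, `apply_firing_count`, `minimal_s_invariants`, `minimal_t_invariants`, `verify_invariant`, `coverage`, `brute_force_invariants` |
| behavior | `reachability_graph`, `place_bounds`, `check_conservation` |
| annotation | `annotate`, `shared_support`, `full_report` |
| models | `build_dana`, `random_ordinary_net` |

Matrix orientation is fixed everywhere: **rows = transitions, columns =
places** (both conventions exist in the literature; this package uses
this one in memory and in every serialized artifact).

Invariant enumeration uses Farkas-style (Martínez–Silva) row
elimination with exact integer arithmetic, minimal-support filtering
and gcd normalization; `brute_force_invariants` is an independent
bounded-enumeration oracle used by the test suite to cross-check it.

## CLI

A console script `biopetri` is installed:

```sh
biopetri invariants --model dana --kind s        # two S-invariants, labeled
biopetri invariants --model dana --kind t        # none found
biopetri analyze    --model dana --out report.json
biopetri analyze    --model dana --format markdown
biopetri simulate   --model dana --steps 10 --seed 7
biopetri export     --model dana --to pnml   --out dana.pnml
biopetri export     --model dana --to matrix --out dana.txt
biopetri export     --model dana --to dot    --out reach.dot
```

`--model dana` selects the built-in model; `--input FILE` reads a PNML
(`.pnml`/`.xml`) or matrix-text file instead. Logging goes to stderr
(`--verbose` for debug), results to stdout or `--out`. Exit codes:
0 success, 1 usage error, 2 format/data error.

## File formats

**PNML** — ISO/IEC 15909-2 place/transition subset. Written with
biological labels in `name` elements and tokens in `initialMarking`;
identifiers are sanitized to XML NCNames (originals preserved in a
tool-specific subtree). Unknown subtrees are ignored with a warning on
read.

**Matrix text** — a three-section tab-separated format (``#`` lines are
comments):

```
PLACES
<place-id> TAB <initial-tokens> TAB <label>
TRANSITIONS
<transition-id> TAB <label>
A_MINUS
<one row of integers per transition, one column per place>
A_PLUS
<same shape>
```

`A_MINUS`/`A_PLUS` are stored separately (never just their difference)
so self-loop arcs survive round-trips. Both formats round-trip places,
transitions, arcs, weights, labels and the initial marking exactly.

**Report JSON** (from `full_report(...).to_json()` or
`biopetri analyze`): an object with keys

- `net`: places/transitions, label maps, `initial_marking`
- `incidence`: `a_minus`, `a_plus`, `a` as row-major integer lists plus
  `row_order`/`column_order` markers
- `s_invariants`, `t_invariants`: list of `{kind, vector, support,
  support_labels, normalized}`
- `shared_support`: `{places, labels}` — intersection of all
  S-invariant supports
- `uncovered`: places/transitions in no minimal invariant's support
- `reachability`: `{truncated, n_markings, n_dead, place_bounds,
  conservation_holds, conserved_values}` (the last three are `null`
  when exploration was truncated)
- `warnings`: list of strings (e.g. self-loop cancellation notice)

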