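# Methods

## Model and search procedure

`rnamct` treats inverse folding as sequential decision making over
*assignment events*. The target structure with N positions defines
ℓ = (number of base pairs) + (number of free bases) design sites; the
complete decision tree has depth ℓ, with arity 4 at single sites (A, C, G,
U) and 6 at paired sites (AU, UA, GU, UG, CG, GC — Watson–Crick plus the
GU wobble). The tree is grown lazily by Monte Carlo tree search: UCB1
selection (`u = w/v + C·sqrt(2 ln v_parent / v)`, infinite at `v = 0`),
expansion gated by the visit threshold β, a playout that scores k
fully-specified sequences, and backpropagation of the playout's best
reward along the path. All children of a node are created together and
cover every event of one randomly drawn remaining site; the root is
expanded in the very first round.

The reward of a candidate with predicted structure at Hamming distance d
from the target (both strings canonicalized first) is

    r = R_GC + (N − d)/N   if |α − α*| ≤ δ   (closed interval)
    r = (N − d)/N          otherwise, or when no GC target is given,

bounded by 1 + R_GC. The GC bonus is a step of exactly R_GC, which is what
lets the tree discriminate branches that can still reach the GC window
from branches that cannot.

Playouts hold the path's positions *essential* (never altered). The
initial sequence places G/C (singles) or GC/CG (pairs) at randomly picked
non-essential positions until the GC count reaches N·α* — a paired
placement may overshoot by one base; no correction pass is applied, as the
δ-window absorbs ±1 base at realistic lengths — then fills the rest with
A/U (AU/UA). Each local update folds the current sequence once and applies
one exhaustive rewrite pass: rule (i) re-randomizes target pairs missing
from the prediction over {AU, UA, CG, GC}; rule (ii) breaks spurious
predicted pairs with the GC-count-conserving maps AU/UA→{AA, UU},
GC/CG→{CC, GG}, GU/UG→{AC, CA, AG, GA, CU, UC}. Pairs touching an
essential position, and positions already rewritten by the other rule in
the same pass, are skipped. One pass per fold keeps the fold-call
accounting exact: a playout of length k spends exactly k predictions
(fewer on early success). Rules are applied in ascending opening position
so a (structure, parameters, seed) triple fully determines a run on a
deterministic backend.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| C | UCB exploration constant | 0.5 | recommended operating point |
| β | expansion threshold (visits) | 1 | leaf expands at second arrival; gate uses pre-increment counts |
| k | playout length (folds per simulation) | 50 | 1 initial + k−1 updates |
| R_GC | GC bonus weight | 1.0 | step size of the reward discontinuity |
| δ | GC tolerance | 0.01 nested / 0.02 pseudoknot | the pseudoknot default applies only when δ is unset |
| α\* | target GC content | none | without it the reward is purely structural |
| budget | `max_iterations`, `max_fold_calls`, `time_limit` | — | at least one required; iteration/fold budgets keep tests wall-clock-free |

Successful termination requires structure identity; with `--require-gc`
the design must also sit inside the GC window before the run stops. The
returned diagnostics include iterations, fold calls, tree depth at the
solving round, and the realized GC content.

## Folding backends

`vienna` uses the ViennaRNA bindings when importable (RNAfold CLI as a
fallback) for nested minimum-free-energy structures; `pkiss` drives the
pKiss CLI for pseudoknots. Backend output is canonicalized — parsed and
re-rendered with a fixed bracket-layer order — before any comparison, so
two engines that place the same crossing pairs in different bracket layers
are at structural distance zero. Backend versions are recorded in the run
diagnostics rather than pinned.

`reference` is a self-contained deterministic folder: a Nussinov-style
dynamic program maximizing the number of admissible pairs with hairpin
loops of at least 3 unpaired bases. Traceback tie-breaking is fixed
(pair the leftmost position of an interval whenever pairing attains the
optimum, choosing the smallest partner). It is a combinatorial test
harness, not a thermodynamic model: design runs that use it are judged
against its own predictions, which is internally consistent. Sequences are
capped at 200 nt (cubic-time fill; a numba JIT accelerates it when
available, with an identical pure-Python path otherwise).

## The synthetic target generator

Random valid targets are sampled by recursive interval splitting: an
interval either opens a helix — `min_stack` pairs plus a geometric tail
with continuation probability `stack_p`, honoring the minimum loop — and
recurses inside and after it, or advances one unpaired position. The
attempt probability is calibrated so the expected pair density matches the
requested `density`. An optional pseudoknot flag adds one crossing pair
over free positions.

The defaults (density 0.4, helices of mean length 3.5, no unpaired run
longer than 5) emulate the compact stem-loop architectures of short
structured RNAs, which is also the family a maximum-pairing folding
criterion can reproduce: every unpaired run must be kept unpairable purely
by base composition, so long free runs admit spurious pairs that the
GC-conserving rewrite rules purge only slowly. Relaxing `min_stack`,
`stack_p` and `max_free_run` yields sparse targets with lone pairs and
long loops — rare in natural structures, thermodynamically unstable, and a
deliberately hard family. What passing tests on generated targets show is
therefore design power against the bundled combinatorial folder on
stem-loop-like structures; they do not certify performance on long
natural structures under a thermodynamic model, nor targets whose loops
are long relative to their stems.

## Design choices made where the procedure was open

- **Backpropagation includes the simulated node itself** (not only strict
  ancestors): the cumulative value w is the sum of playout values over a
  node's subtree *including its own* simulations, which keeps `w/v` a mean
  of per-playout maxima for any β and makes the β-gate well-defined.
- **The expansion gate uses pre-increment visit counts**: a fresh leaf
  (v = 0) under β = 1 is simulated first and expands on its next arrival;
  the root alone is expanded unconditionally in round 1.
- **One rewrite pass per fold**: "apply the rules as often as possible" is
  realized as one exhaustive pass against the current prediction followed
  by a re-fold, because rule applicability is defined relative to a single
  predicted structure and this keeps the fold budget exactly k per playout.
- **Rule (i) draws from {AU, UA, CG, GC} only** (no wobble), and pairs
  with exactly one essential position are skipped by both rules.
- **GC window on the closed interval**, with α rounded to 12 decimals
  before the comparison so representation noise cannot flip the bonus.
- **Structure identity alone terminates a run by default**; `--require-gc`
  additionally demands the GC window, which is the mode used whenever GC
  compliance of successful designs is audited.
- **Full-depth corner**: if selection reaches depth ℓ the sequence is
  fully determined, so the playout folds once instead of k times.
- **Restart baseline**: `random_restart_design` repeats the identical
  playout with no essential positions. Its initial sequences are uniform
  random assignments — the classical "randomly designed" starting points —
  with `gc_targeted_init=True` available to give the restarts the same
  GC-budgeted initials as the tree's playouts. At desk scale the tree's
  advantage comes from the GC-aware playouts plus branch selection at
  extreme GC targets; against the GC-targeted restart variant the tree
  adds little on small targets, and the bundled ablation states exactly
  what it compares.

## Problem sizes used in tests and the acceptance script

End-to-end suites design 14–28 nt stem-loop targets (20 random fixtures
plus a 12-nt hairpin) at up to 500 search rounds per seed; the GC-strict
audits use α* = 0.5, δ = 0.01 on the same family. The ablation fixes 300
structure predictions per run on 20–30 nt targets at α* = 0.2 and counts
successes of tree search versus uniform-initial restarts. Oracle checks
run the reference folder against explicit exhaustive enumeration on
sequences of length ≤ 12, where enumeration is affordable. These sizes
were chosen so each property is measured at full strength by the bundled
deterministic folder.

## Known limitations

- The reference folder maximizes pair count; its optima can differ
  arbitrarily from thermodynamic minimum-free-energy structures, and
  designing against it is intrinsically harder for targets with long
  unpaired runs (see above).
- pKiss is not bundled; pseudoknot design requires it on PATH. The
  structure model, canonicalization and distance support pseudoknots of up
  to 4 crossing layers regardless.
- No sequence constraints (IUPAC masks), forbidden motifs, ensemble-defect
  objectives, or parallel search.
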