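# Methods

## The charge-assignment model

`knapcharge` assigns partial atomic charges to a query molecule from the
statistics of chemical environments observed in a reference corpus of
previously parameterised molecules.  A molecule is a vertex-coloured graph
`G = (V, E, t)`: atoms, bonds (untyped — bond orders in input files are read
but ignored), and an atom-type labelling `t : V → Σ`.  The default alphabet
Σ is the chemical elements; richer force-field typings work transparently as
different alphabets.

The chemical environment of atom `v` at shell size `k` is the subgraph
induced on its k-neighbourhood `N_k(v)` — all atoms within graph distance k —
rooted at `v`.  Environments are grouped into isomorphism classes under
type-preserving isomorphisms that map root to root; the root is
distinguished because the stored charge belongs specifically to the central
atom (the alternative, unrooted classes with post-hoc orbit resolution,
would conflate atoms that sit at different positions of the same subgraph).
Each class collects the central-atom charges observed across the corpus, at
every shell 0..k, and condenses them into a histogram.

A query atom is matched to the class of its shell-k environment, falling
back through shells k−1, …, 0 until a class is found; an atom whose bare
atom type is absent from the database is *uncovered* and reported as an
error rather than guessed.  The matched histogram's bin centers become the
atom's candidate charges (weights `w_{i,j}`), each scored by the natural log
of its bin count (profit `p_{i,j} = ln n_{i,j}`).  Log counts are used
rather than z-score-style scores because empirical per-environment charge
distributions are heavy-tailed and often multimodal; a count-1 bin scores
`ln 1 = 0` and remains selectable, with no pseudo-count.  The log base is
immaterial — any fixed base rescales all profits uniformly and cannot change
the optimiser's argmax — so it is not configurable.

Choosing one candidate per atom so that the total lands within ε of the
molecule's target total charge, while maximising the summed score, is the
ε-variant of the multiple-choice knapsack problem (ε-MCKP): weights and
capacity may carry either sign and the weight sum must fall in
`[c − ε, c + ε]` instead of merely below `c`.  Defaults are `k = 3` and
`ε = 0.01 e`, with ε treated as an absolute per-molecule tolerance.

## Solvers

Two exact solvers are provided, plus an enumeration oracle for testing.

**Integer transform.**  Charges live on a 0.001 e grid, so weights, capacity
and ε are scaled by 10³ into exact integers (the package stores charges as
integer millicharges internally; the scale factor is configurable for data
requiring a finer grid, e.g. a halved capacity needs 2·10³).  Per-set minima
`w*_i = min_j w̃_{i,j}` are then subtracted from each set's weights and from
the capacity, making all weights non-negative without changing the set of
feasible selections, since exactly one item per set is always chosen.

**Dynamic programming.**  A table `P[k, d]` holds the best profit achievable
with one item from each of the first k sets considered and a transformed
weight sum of *exactly* d; the base row is 0 at `d = 0` and −∞ elsewhere,
which is what makes exact sums (and hence the two-sided window) expressible.
The optimum is the maximum of the final row over
`max(c̃ − ε̃, 0) ≤ d ≤ c̃ + ε̃`.  Running time is `O(n·(c̃ + ε̃))` for n total
items; the implementation keeps all m+1 rows (`O(m·(c̃ + ε̃))` memory) to
support backtracking — a profit-only variant would need just one row.  Sets
are processed in reverse order so that backtracking fixes the first set
first and the tie-break below is exact.  An empty window (`c̃ + ε̃ < 0`) is
declared infeasible immediately.  Unreachable states use IEEE −inf; profit
comparisons across methods use a 1e-9 tolerance, while weights are exact
integers throughout.

**Integer linear programming.**  The direct formulation — binary selection
variables, two window constraints on the (integer-scaled) weight sum, one
choose-exactly-one constraint per set — is solved with HiGHS via
`scipy.optimize.milp`.  On rare infeasible instances with a tight window
HiGHS's presolve exits with a solve error instead of an infeasibility proof;
the backend retries once with presolve disabled.

**Tie-breaking.**  Among co-optimal selections, the DP and the brute-force
oracle deterministically return the lexicographically smallest item-index
vector, so their selections are comparable bit for bit; the ILP may return
any co-optimal selection, and only profits are compared across all three.
A consequence worth noting: because the tie-break is defined relative to
atom order, permuting the query's atoms can switch between co-optimal
selections; the optimal profit and the feasibility window are order-free.

**Reduction.**  A standard MCKP with capacity `c ≥ 0` is the special case
`(c′, ε) = (c/2, c/2)`, turning the window into `[0, c]`; the test suite
uses this to cross-check the solvers against an independent brute-force
MCKP oracle.

## Histograms

Bin widths follow the Freedman–Diaconis rule `2·IQR·n^(−1/3)` (linear-
interpolation quantiles), computed per class from its own values.  The
width is rounded to the 0.001 e grid so that bin centers are themselves
3-decimal charges and the spacing is exact in millicharge arithmetic; the
grid is anchored so one center equals the 3-decimal-rounded median charge
and extends to cover the observed range.  Values join the nearest center,
with boundary ties to the lower center; empty bins are dropped.  Two
degenerate situations fall back to discrete per-value bins (`bin_width = 0`,
one bin per distinct 3-decimal value): a width that rounds below 0.001
(including IQR = 0), and the rare even-n case where the median falls in an
unpopulated gap wider than a bin, which would otherwise leave the
median-aligned bin empty.  Observations are rounded to 0.001 e *before*
binning, matching the precision at which reference charges are published.

Baselines used in the evaluation take, per atom, the mean or median of the
matched class's raw values, or the mode — the center of the highest-count
bin, with multimodal ties resolved by the mode closest to the median and
remaining ties to the lower charge.  Baseline totals are deliberately
unconstrained; contrasting their total-charge error with the ε-window of the
knapsack solution is the point of the comparison.

## Synthetic corpus generator

No public corpus ships with the package; the generator produces corpora
whose statistical structure mirrors a quantum-mechanically parameterised
repository, with full ground truth:

* molecules are random trees grown under per-type valence caps (default
  alphabet H/C/N/O with caps 1/4/3/2), plus optional ring-closing edges
  (`ring_probability`, default 0.15); sizes default to 5–25 atoms;
* every shell-k class (k default 3) carries a latent charge model: a base
  mean drawn once per class from `N(0, 0.3 e)` (hashed from the canonical
  key and the seed, so the model is consistent across molecules without
  enumerating keys up front), Gaussian observation noise `σ = 0.02 e`, and
  with probability 0.1 a second mixture mode offset by 0.2 e (weight 0.3) to
  produce the heavy-tailed, multimodal class histograms seen in real data;
* real reference charges sum to an integer total per molecule.  The gap
  between the integer target and the sum of latent means is spread evenly
  over the atoms and becomes part of each atom's *effective* ground-truth
  mean (recorded as `atom_mean` in the truth table) — this is the
  molecule-context broadening that makes environment-conditional
  distributions wider than the pure observation noise.  After noise is added
  and charges are rounded to 0.001 e, the remaining (noise-rounding)
  residual is distributed in 0.001 steps over the atoms with the largest
  noise draws; an adjustment exceeding 3σ is warned about and flagged.
  Setting `adjust_total=False` disables both mechanisms, giving exactly
  noise-free class means when `σ = 0` — the controlled setting used by the
  exact-recovery test;
* `structure_copies = c` instantiates each random structure c times with
  independent noise, guaranteeing constructively that every environment
  occurs in ≥ c molecules — the condition the leave-one-out study needs so
  that a held-out molecule's environments survive in its twin.

What the generator does *not* emulate: chemical realism (valence rules are
caps, not chemistry; no aromaticity, no real charge physics) and the
size/diversity of a production corpus.  Passing tests therefore demonstrate
the correctness of the machinery — matching, binning, optimisation,
evaluation protocol — not the chemical accuracy achievable on real data.

## Evaluation protocol and expected desk-scale behaviour

The leave-one-out harness removes each molecule's own observations from the
database (per-value source tracking), re-assigns its charges with the
knapsack solver and the three baselines, and reports per-atom absolute
distances to the held-out charges (aggregated per element) plus per-molecule
total-charge errors.  Molecules with an uncovered atom are counted and
skipped; by default, so are molecules not fully covered at shell k without
fallback, mirroring the evaluation restriction to fully covered molecules.

At the package's study scale (200 molecules) many classes hold only the
held-out molecule's twin observations; after Freedman–Diaconis merging their
candidate sets are small and coarse, so for a fraction of molecules no
candidate combination lands inside the ±0.01 e window at all.  These are
reported as structured infeasibilities (with the achievable total range),
never silently widened — infeasibility rates drop as the corpus grows and
classes gain bins.  Every assignment that *is* produced satisfies the window
by construction, while the baselines routinely miss the target total; the
acceptance script quantifies both.  The CLI offers an explicit
`--max-epsilon` doubling retry for users who prefer a looser window over an
error; it is off by default.

Problem sizes used by the test suite and `scripts/acceptance.py` — 1000
random instances for the three-solver cross-check, 200 instances each for
the reduction and transform checks, 100 for the ε-sweep, a 200-molecule
corpus (100 structures × 2 copies) for the end-to-end study, 500 graphs for
the neighbourhood oracle, all ≤5-atom rooted two-letter graphs for the
exhaustive canonicalisation check, and 500 value sets for the histogram
contract — were chosen so the whole suite completes in a few minutes on one
CPU while each check still exercises the full code path at a statistically
meaningful size.

## Canonical keys

Environment classes are keyed by a canonical form of the rooted typed
graph: iterative colour refinement seeded with (distance from root, atom
type), followed, when refinement stalls on a non-discrete partition, by
individualisation of each vertex in the smallest non-singleton colour class
and recursion, keeping the lexicographically smallest result.  The key is
the canonically relabelled graph itself serialised as JSON (size, root
position, type sequence, edge list), not a hash — so equal keys imply
isomorphism by construction, and the converse is what the exhaustive test
verifies.  This is exponential in the worst case but fast for the tree-like,
≤ ~60-atom environments that occur in practice.

## Known limitations

* Scores are not normalised across atoms: a 2-observation class contributes
  at most ln 2 where a 10⁴-observation class contributes ln 10⁴, so
  well-sampled environments dominate the objective.  No normalisation is
  applied; `n_values` and `n_molecules` are reported per match so users can
  judge support.
* The DP's memory grows with the candidate charge span; pathological
  instances (hundreds of atoms with multi-e candidate ranges) favour the ILP
  backend.
* Database serialisation is plain JSON, adequate for desk-scale corpora but
  not for 10⁵-molecule production databases.
* Raw values (and per-value sources) are serialised only when the database
  is built with source tracking; a database loaded without them still
  supports assignment and the mode baseline exactly, while mean/median
  baselines then fall back to the binned representation.
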