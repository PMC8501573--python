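# Methods

## Model

`phirank` treats host prediction as a rank-similarity problem. A similarity
search of a phage sequence against a reference database of prokaryote
genomes yields an ordered list of matches; so does a search of each
candidate host genome against the same database. If the phage's list and a
host's list agree — especially near the top — the pair is likely related,
because phage and host genomes exchange sequence with the same neighbourhood
of taxa. The interaction score is the rank-biased overlap (RBO; Webber,
Moffat & Zobel, ACM TOIS 2010) of the two lists:

    RBO(S, T, p) = (1 − p) Σ_{d=1}^{n} p^(d−1) A(S, T, d)
    A(S, T, d)   = |S_:d ∩ T_:d| / |S_:d ∪ T_:d|

with `S_:d` the set of species in the first `d` ranks of `S`. The measure
accommodates the four awkward features of similarity-search rankings: top
ranks matter more (geometric weighting); the lists need not contain the same
species (Jaccard handles non-conjoint sets); the lists may differ in length
(a prefix past a list's end saturates at the whole list); and several
species may tie at one rank (a rank's whole label set enters the prefix at
that rank's depth).

### Ranked-list construction

Hits are ordered best-first — decreasing bit-score for BLAST, increasing
distance for Mash — keeping each subject once at its best score, with input
order preserved among exact score ties. Genome-level subjects are collapsed
to species **before** tie grouping: a species is represented by its
best-scoring genome, and lower-scoring genomes of an already-ranked species
are dropped, so they cannot create spurious ties. Exact equality of the
representative scores (no epsilon) defines a tie; bit-scores are discrete
enough that this matches how ties arise in practice. A subject missing from
the genome→species map falls back to its own label with a warning, which
keeps expanded reference sets — where viral sequences without a species
label sit in the database alongside prokaryote genomes — flowing through the
same code path.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `p` (persistence) | 0.75 | — | geometric decay of rank weight; at 0.75 the first 10 ranks carry ≈ 98.6 % of the total weight (closed-form mass `W(1:k) = 1 − p^(k−1) + ((1−p)/p)·k·(ln(1/(1−p)) − Σ_{i<k} p^i/i)`), so agreement beyond the teens of ranks is negligible |
| `normalize` | on | — | divide the truncated sum by `1 − pⁿ` (see below) |
| `n` | max(|S|, |T|) ranks | — | truncation depth of the sum; taking the max lets all content of both lists contribute |
| `workers` | 1 | — | row-parallelism of the score matrix (joblib); output is independent of worker count |

### Normalization

On finite lists the truncated geometric series sums to `1 − pⁿ`, so the raw
formula gives `RBO(S, S) < 1`. To honour the contract that identical lists
score exactly 1 and disjoint lists exactly 0, scores are divided by
`1 − pⁿ` by default; the raw truncated sum remains available
(`normalize=False`, CLI `--no-normalize`). One consequence worth knowing:
the normalized score is a weighted *mean* of the per-depth agreements, so
appending a shared label to the tail of both lists can lower it when that
depth agrees less than the running average; the raw sum, by contrast, can
only grow. Two empty lists score 0 (a query with no hits is treated as
unrelated to everything, which keeps score matrices total).

## Evaluation protocol

For each virus the predicted host set is every host attaining the row
maximum (exact equality). Accuracy at a taxonomic level is the percentage of
viruses for which *any* predicted host shares the level label with *any*
known host; a missing lineage entry makes that single comparison a non-match
rather than an error. Pair-level metrics treat the known interacting pairs
as positives and **all** other virus–host pairs in the matrix as negatives
(an optional subsample of negatives exists for quick runs and is off by
default). ROC AUC uses the Mann–Whitney formulation (ties count half); the
precision–recall area uses step-wise summation with no linear interpolation,
the appropriate convention for heavily imbalanced interaction benchmarks, so
a random scorer attains the positive prevalence. The F1-maximising threshold
is found by scanning every distinct observed score plus one value above the
maximum (allowing "predict nothing"); F1 ties break toward the higher, more
conservative threshold. Specificity at that threshold is reported but never
used for selection. Both AUC and the PR area are computed via scikit-learn
(`roc_auc_score`, `average_precision_score`) and are cross-checked in the
test suite against hand-written exhaustive oracles.

## Synthetic benchmark generator

`make_planted_universe` emulates the *structure* of a real benchmark: a
shared pool of reference species, one ranked list per candidate host (a
random permutation prefix of the pool), one true host per virus, and a virus
list that is a noisy copy of its host's list. The noise model applies, at
rate `noise`, per-position label replacement from the pool (at `noise = 1`
the virus list shares content with its host only by chance), neighbour
swaps at rate `noise/2`, and adjacent-rank tie merges at rate `noise/2`.
Defaults are 50 hosts, 200 viruses, noise 0.1, a pool of 250 species and
lists of 25 ranks — a pool a few times larger than the host panel and lists
covering a few dozen species match what similarity searches against
reference sets of a few hundred genomes typically return. All draws flow
from one seeded NumPy PCG64 generator, so universes are bit-reproducible.

What the generator does **not** emulate: sequence evolution, prophage
content, alignment noise correlated across hosts, shared taxonomy between
host lists (each host's list is independent), or databases much larger than
the host panel. Passing tests on planted universes therefore demonstrate
that the ranking, scoring and evaluation machinery is correct and that the
score separates signal from noise under controlled perturbation — not that
any particular accuracy will be attained on real genome collections.

`subsample_contigs` draws fixed-length fragments (defaults 20/10/5/3/1 kb,
10 replicates) uniformly from a linear genome, 0-based half-open, no
wraparound, overlaps between replicates allowed; lengths exceeding the
genome are skipped with a warning, and ambiguous bases are not filtered.
Together with `exclude_self` (which removes a contig's parent genome from
its own ranked list, dropping emptied ranks) it provides the input
preparation for incomplete-sequence experiments.

## Numerical choices and degenerate inputs

- Tie detection and top-host selection use exact float equality; score
  matrices are serialised with `repr` (shortest round-trip) so file I/O is
  bit-stable.
- RBO accumulates prefix intersection/union counts incrementally; results
  match a brute-force per-depth set-arithmetic oracle to 1e−12 and are
  clamped to [0, 1] against round-off at the endpoints.
- A row of all-equal scores predicts *every* host; downstream accuracy then
  applies the "correct if among the predictions" rule unchanged.
- Empty ranked lists are legal everywhere and score 0 against everything.
- Label handling trims surrounding whitespace only and is case-sensitive;
  accession identity is never silently merged.

## Design choices

- The truncation depth `n` is the larger of the two lists' rank counts;
  depth counts ranks, not items, so a tied rank's whole set enters at once.
- The per-subject score used for ranking is the best single HSP bit-score
  (not a sum over HSPs).
- No e-value or score floor is applied beyond what the upstream search
  emitted.
- Score matrices are dense; benchmark scale tops out around 10⁸ pairs and
  each entry is a few hundred set operations, so sparsity buys nothing at
  desk scale.
- The scikit-learn estimator (`RboHostPredictor`) is the primary API; the
  module-level functions (`score_all`, `predict_hosts`, …) are the same
  computations without the fitted-state wrapper.

## Problem sizes

The shipped tests and the reproduction script run entirely on synthetic
inputs: oracle equivalence on 10,000 random list pairs over ≤ 6 labels,
planted-host recovery on 50 hosts × 200 viruses, and metric oracles on
instances of ≤ 50 scores. These sizes were chosen as the smallest at which
each property is meaningfully exercised — tie structures of every shape,
host panels large enough that chance-level accuracy (2 %) is far from the
95 % recovery bar — while keeping the whole suite in the tens of seconds.

## Known limitations

- Scores are relative rank agreements, not probabilities; thresholds do not
  transfer between reference databases of different size or composition.
- A virus whose search returns no hits scores 0 everywhere and is predicted
  to every host at once (a degenerate tie); callers should filter empty
  lists if that is not wanted.
- The within-rank order of tied species is immaterial to the score, but very
  long ties at rank 1 (e.g. many identical bit-scores from low-complexity
  matches) dilute the Jaccard prefix and can mask real signal.
- Only the truncated, tie-aware form of rank-biased overlap is implemented;
  the classic extrapolated RBO for conjoint lists and per-item fractional
  tie weighting are out of scope.
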