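# Methods

This note documents the scoring definitions, the null model, the
synthetic generator and the numerical/design choices behind
`recallseq`, in the package's own terms.

## Protocol representation

A trial is one presented list of n distinct item tokens plus the
ordered recall events produced for it. Events are `ITEM` (a presented
item, carrying its input serial position), `INTRUSION` (any token not
in the list; prior-list and extra-list intrusions are not
distinguished), or `OMISSION_MARK` (an explicit skip token, reserved
word `blank` in TSV files and `-` in letter notation, for paradigms in
which participants mark omitted positions). Repetitions are stored
losslessly as multiple `ITEM` events sharing an input position; the
parser never classifies, so protocols round-trip exactly. Positions
are 1-based throughout. Scoring uses the temporal response order
(spoken/typed order), never written grid positions; grid scoring is out
of scope.

## Start- and end-sequence detection

A start-sequence is a maximal run of recalls of items from consecutive
input positions 1, 2, …, s in forward order, located anywhere in the
output; an end-sequence is the symmetric run n−e+1, …, n terminating
with the last item. A singleton occurrence of item 1 (item n) anywhere
is a length-1 start (end) sequence; length 0 means the anchoring item
was never recalled eligibly. The scanner anchors on eligible
occurrences of item 1 (item n) and extends greedily; an independent
brute-force oracle that enumerates every contiguous output window is
tested against it exhaustively for n ≤ 6 and protocols of length ≤ 6.

Choices the run definition leaves open, fixed here as policy:

* **Eligibility** (`first_occurrence_only`, default): only the first
  occurrence of each item may join a run; later occurrences are
  labelled REPETITION. The alternative `any_occurrence` policy lets
  every occurrence participate, which is required to realise
  cross-tabulation cells with s + e > n (the overlapping boundary item
  must be output twice, e.g. `1 2 3 4 4 5 6` for s = 4, e = 3, n = 6).
  Published cross-tabulations of this shape contain such cells without
  stating how their scorer treated repetitions; both policies are
  provided and the replay of those tables uses `any_occurrence`.
* **Contiguity**: runs are runs of consecutive *response events*.
  Intrusions and omission marks break contiguity by default
  (`runs_broken_by`); removing a kind from that set makes it
  transparent, for sensitivity analysis. An ITEM event that is
  ineligible or does not continue the expected position always
  terminates a run.
* **Maximality and ties**: the longest qualifying run wins; among equal
  lengths, the earliest output index wins. This makes annotation a
  total, deterministic function of (trial, policy).
* **Start priority**: each event receives exactly one label. When the
  same events could serve both runs (e.g. `1 2 3 4 X` over n = 4,
  where the full recall is simultaneously a complete start run and a
  complete end run), the start-sequence is detected first and the
  end-sequence is sought among the remaining events. This keeps START
  and END labels disjoint and s + e bounded by the number of distinct
  items recalled. Start priority matches the forward-ordered reading
  of serial-recall outputs; no published example turns on the choice.
* **Complete-correct convention**: a recall equal to exactly 1..n with
  no intrusions, marks or repetitions is recorded as s = n, e = 0 (the
  whole output is the start-sequence), matching the printed tables
  that place fully correct trials in the full-start row.

Remaining list-item events are labelled OTHER; their count is k and
their input positions feed the null model.

## Scoring rules and curves

* **SR**: item i is correct iff its first occurrence is output at
  output index i. Intrusions and omission marks occupy output indices
  and shift later slots; unmarked early termination does not back-fill.
  This spoken-recall convention is what makes prematurely output
  end-sequences score as incorrect, the phenomenon the start/end
  analysis targets.
* **FR**: item i is correct iff recalled anywhere.
* **START_END**: item i is correct iff its eligible event is labelled
  START or END; per trial the correct count is s + e (n for complete
  trials). FR correctness dominates both other rules item-wise.
* **Residual Other curves** plot the proportion of trials on which each
  item was recalled as OTHER, recency-justified (distance 0 = last
  item), exposing residual recency once sequences are removed.

Curves are computed per list length and never averaged across lengths.
Transposition matrices count first occurrences only; the error-only
gradient removes the diagonal (input = output) and normalises by the
total error count, so defined gradients sum to 1.

## The start + guess + end null model

Given only each trial's annotation, the null outputs start items at
slots 1..s, end items at the last e slots, and permutes the k Other
items uniformly over the intervening slots. The slot count equals the
number of counted recall events, not n. Intrusions and repetitions are
excluded by default (the estimate concerns order errors among presented
items); an `occupy_slot` policy adds intrusion slots to the middle
window for sensitivity analysis.

The expectation is available in closed form: each Other item with input
position i contributes probability 1/m to each of the m middle slots
(error mass only where slot ≠ i); start items are always correct; end
items err deterministically whenever s + k + e ≠ n shifts them off the
diagonal. The Monte Carlo estimator (default 1000 replications per
trial) draws uniform permutations via per-trial generator streams
seeded from (seed, CRC-32 of trial id), making results independent of
trial order and reproducible; tests verify agreement with the analytic
form at total-variation distance < 0.01 with 10^5 replications, and
against exhaustive k! enumeration for k ≤ 5. Whether the original
estimates were simulated or computed in expectation is not documented;
the two coincide, and the analytic estimator is the reference.

## Synthetic protocol generation

The generator emulates the statistical structure of recall protocols —
not any cognitive process. A trial is built as: with probability
`p_complete`, the fully correct recall; otherwise sample (s, e, k) from
independent configurable distributions, draw k Other items from the
eligible positions, order them uniformly, and assemble
`[1..s] + [Others with injected noise] + [n−e+1..n]`. Defaults target
the regimes the packaged data represent: 6-item lists (the packaged
cross-tabulation) and 8-item lists (the worked examples); lengths 2–15
are supported.

* **Truncation**: when s + e + k > n, k is resampled first, then e,
  then s — the start length, the rehearsal-linked quantity, is
  preserved preferentially.
* **Eligible Others**: items 1..s and n−e+1..n are in use; item n is
  excluded whenever e = 0 is intended (any recall of item n forces
  e ≥ 1 under the content-based definition) and, in strict mode, item
  1 is excluded symmetrically when s = 0.
* **Strict mode** guarantees the annotator recovers exactly the sampled
  (s, e): candidate arrangements are accepted only if annotating them
  returns the target pair (rejection sampling validated by the scorer
  itself, capped at 500 attempts before an explicit error). Some
  requests are genuinely unsatisfiable — e.g. n = 6, s = 2, e = 2,
  k = 1, where the single middle item is adjacent to both runs and
  necessarily extends one — and raise immediately. One boundary case
  deviates from the canonical assembly order: k = 0 with 0 < s, 0 < e
  and s + e = n would collapse into the fully correct recall, so the
  end block is emitted first (`[n−e+1..n] + [1..s]`), the only
  arrangement realising that annotation.
* **Non-strict mode** keeps lucky arrangements, so recovered mean start
  length exceeds the configured mean — the same inflation that affects
  observed sequence lengths in real data, where guessed Other items can
  extend a true sequence.
* Intrusion tokens come from a disjoint lowercase alphabet; noise
  events (intrusion / repetition / omission mark, independent per-event
  rates) are injected into the middle block only, so strict-mode
  acceptance still applies unchanged.

`generate_from_crosstab` replays a (s, e) cross-tabulation cell for
cell with k = 0: cells with s + e < n (or s = 0 or e = 0) as
`[1..s] + [n−e+1..n]`, cells with s + e = n with the end block first,
and overlap cells (s + e > n) by duplicating the boundary items, which
requires `any_occurrence`. Round-tripping (annotate, re-cross-tabulate)
reproduces the input table exactly; this is how the printed
completely-correct proportions (0.472 / 0.383 / 0.209 / 0.152) are
recomputed rather than copied. The printed per-cell counts do not
include Other counts, so replay defaults to k = 0.

### What the generator does and does not emulate

It reproduces output-protocol statistics: sequence-length
distributions, Other counts, noise rates, and their interaction with
the scorer. It contains no temporal-context, primacy-gradient or
phonological-loop mechanism, no inter-trial dependencies, no
word-level effects, and its (s, e, k) are sampled independently,
unlike real data where they covary. Passing tests therefore certify
the pipeline's correctness and internal consistency on protocols of
realistic shape — not any claim about human memory beyond what the
replayed printed data carry.

## Fixture provenance and a known discrepancy

The packaged cross-tabulation transcribes a printed table of four
groups of 6-item typed ISR (open set, open set with typed "blank"
omission marks, closed set, and reconstruction of order). Unprinted
cells are stored as zero. The group totals quoted in the source text
(6128 / 6186 / 6198 / 5797) disagree with the printed block sums
(Closed 6128, Open 6186, Blanks 6198, RoO 5797) — three of the four
appear rotated. Both are packaged (`TEXT_TRIAL_COUNTS`, `BLOCK_SUMS`);
all derived proportions use the printed block sums, which reproduce the
printed proportions exactly.

## Problem sizes in the test suite

The exhaustive scanner-vs-oracle check covers every protocol of length
≤ 6 over lists of n ≤ 6 with one intrusion and one omission symbol
(~520,000 protocols, ~35 s); the `any_occurrence` variant is checked
exhaustively on the reduced n ≤ 4, length ≤ 4 grid and on random
protocols, which exercises the same code paths. Estimator agreement
uses 50 trials × 10^5 replications; parameter recovery uses 10,000
trials; structural properties use 10,000 noisy trials. These sizes make
the checks statistically decisive while keeping the default suite under
a minute.

## Known limitations

* Only temporal response order is scored; written grid-position
  protocols must be linearised by the user first.
* Prior-list vs extra-list intrusions are not distinguished (would
  require cross-trial state).
* The null model takes annotations as given; it does not model which
  items form sequences, and observed sequences are themselves inflated
  by lucky Other placement (quantified via non-strict generation).
* Latency, modality and grouping analyses are out of scope.
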