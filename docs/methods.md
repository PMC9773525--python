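# Methods

This note documents the model, the synthetic data, the numerical choices, and
the limits of what the test suite demonstrates.

## Dialogue model and assumptions

An episode is a simulated consultation. The patient simulator is initialized
with one diagnosis case (record); it volunteers the record's explicit
symptoms, then answers each query with the recorded status if the symptom is
in the record and with a denial otherwise — the standard goal-oriented
simulator convention, and the only consistent completion given that records
enumerate known findings only. Answers are binary; there is no "not sure".

The dialogue state tracks a three-valued status per symptom (true / false /
unknown), the turn counter, the last query, the current top-K association
recommendations and the last shaped reward. Statuses move only from unknown
to known within an episode. The feature vector consumed by every policy has a
fixed layout of length `5n + 2` over an `n`-symptom vocabulary: status
triples, last-query one-hot, recommendation K-hot, normalized turn, and the
last reward scaled by the maximum attainable per-turn magnitude
(`max(t) · N + 2 t4`) so all features stay bounded — bounded inputs
noticeably stabilize the Q-regression.

A dialogue ends when the controller triggers the classifier, or at the turn
limit `N` (counted as agent symptom queries), in which case no disease is
predicted and the episode is a failure.

## Hierarchical policies

The controller's action space is the nine departments plus a diagnose action
(available from turn 0); each department worker owns the symptoms observed in
its group's training records, plus a return-control action. Both levels use a
one-hidden-layer rectified value network trained by plain gradient descent on
the squared TD error, with uniform replay sampling and a target network
synchronized once per epoch. DQN and Double DQN targets are both implemented;
DQN is the default.

Liveness: re-activating a department whose worker just returned control
without querying would reproduce the identical state, so such departments are
masked until a query changes the state. After at most nine fruitless
activations the diagnose action is the only one left, which guarantees
termination without relying on the backstop activation cap.

During greedy evaluation, already-answered symptom actions are masked (asking
them is a wasted turn by construction); during training the mask is off so
the repetition penalty remains learnable. Both behaviors are configurable.

## Association module and critics

Co-occurrence counts come from the *training split only* — computing them on
the full corpus would leak test-set statistics into the policy. The
association measure is directional (each row normalizes by its own total), so
`Association(a, b) ≠ Association(b, a)` when the two symptoms differ in
overall frequency. The context score of a query sums its association with
each confirmed symptom (query's row normalizes); the recommender sums each
*anchor's* row toward the candidate. The two argument orders are deliberate
and kept as stated by the method. A symptom that never co-occurs scores 0
with every partner rather than raising an error; ties in the recommendation
ranking break by vocabulary index; an empty confirmed set (rare — self-reports
are nonempty) falls back to global co-occurrence frequency.

Reward defaults are `t1..t5 = 3, 2, 2, 15, 2` and `N = 28`. The association
critic's thresholds are nowhere stated numerically in the source method; the
defaults `l = 0.05`, `h = 0.20` put the middle band in the range that summed
associations actually reach on SD-like data (single-anchor associations are
typically a few percent). The failed-diagnosis terminal reward is `−t1·N`,
mirroring the success magnitude. Boundary handling of the association bands:
strictly above `h` earns `+t4`; exactly `h` falls in the middle (`+1`) band;
at or below `l` is penalized.

## Disease classifier

A two-layer network (256 rectified hidden units, softmax output,
cross-entropy) over the 3n status encoding. It is trained once, before policy
training, and frozen — staged training keeps diagnosis quality constant across
policy variants so success differences are attributable to investigation
behavior. Unknown statuses keep their own indicator at prediction time; they
are not collapsed to false.

Two training regimes exist. `reveal="full"` uses fully-revealed records
(recorded symptoms at their status, everything else unknown). Because
generated records contain no false findings by default, a full-reveal
classifier never sees a denial during training, yet episode encodings are
full of them — a genuine train/serve mismatch. `reveal="episode"` therefore
augments each record with one simulated partial observation (self-report,
each implicit symptom revealed with probability 1/2, and a Poisson(3) number
of random denials), matching the distribution the agent produces. The
episode-revealed regime is used in the desk-scale experiments.

## Synthetic corpus generator

The generator emulates the SD benchmark's structure: 9 groups × 10 diseases,
266 symptoms, one self-report symptom and a mean of 2.6 implicit symptoms per
record, 30,000 records by default. Per-record counts are drawn as
`1 + Poisson(mean − 1)`, which preserves the configured mean exactly while
guaranteeing at least one explicit symptom (with `mean_explicit = 1` the
self-report is always a single symptom, as in the emulated corpus). Each
disease's fixed symptom profile (12 symptoms by default) is sampled without
replacement from its group's pool; a configurable fraction of the vocabulary
(15% by default) is shared across all groups, reproducing the cross-disease
symptom overlap that drives within-group confusion in real corpora. Disease
labels are balanced across records; implicit findings can be negated at a
configurable rate (0 by default).

What the generator does **not** emulate: long-tailed disease prevalence,
correlated symptom noise (false reports), demographic covariates, and any
natural-language variability. Tests passing on this corpus therefore
demonstrate mechanism correctness and directional effects, not clinical
performance.

## Evaluation metrics

Success rate, average turns and average reward are plain means over episode
logs. AMR averages per-dialogue `matches / queries` (×100) over dialogues
with at least one query; AMR2 averages `matches / true implicit count` over
dialogues with at least one true implicit symptom. IReS-1/2 divide the summed
anchor associations of every query by the total number of query turns (the
per-turn average); the IReS-2 anchor set is snapshotted *before* each turn's
answer is applied, so a query never anchors itself, and repetitions still
count as turns the patient experienced. Group confusion counts failed
episodes by true group × predicted group; turn-limit episodes without a
prediction appear in the success rate but not in the confusion table.

## Desk-scale experiment sizes

The package's end-to-end checks run on one CPU at deliberately small problem
sizes, chosen as the smallest scales at which each effect is stable:
Q-learning vs. value iteration on a 3-state process; learnability on a fully
separable 9-disease corpus (200 epochs × 20 episodes); and the
association-guidance comparison on the default-structure corpus with a
reduced schedule (60 epochs × 20 episodes, 5 seeds, 300 evaluation records,
shared frozen classifier across variants). At this scale absolute success
rates are far below what thousands of training epochs would produce; the
experiment is designed to compare variants under identical conditions, not to
reach benchmark numbers.

## Known limitations

- Workers receive no terminal success signal (it accrues to the controller's
  diagnose transition); at desk scale this occasionally leaves workers
  querying until the turn limit.
- Plain SGD with a fixed learning rate; no gradient clipping, no annealing of
  the exploration rate (a single ε = 0.1 is used throughout, as in the
  emulated setup).
- The replay buffer is uniform; no prioritization.
- The classifier is frozen after staged training; a joint fine-tuning switch
  exists in design but episode-revealed *training* (augmentation) proved
  sufficient for the desk-scale studies.
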