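# Methods

## The simulation model

The framework simulates cross-silo horizontal federated learning with full
client participation. A federation of K clients minimises the weighted
objective Σᵢ pᵢ Fᵢ(w) with pᵢ = nᵢ/n: each round the server broadcasts the
global weights, every client runs R local epochs of mini-batch updates and
returns its weights, and the server takes the pᵢ-weighted average. Clients
execute sequentially in one process; there is no transport layer, client
sampling, or asynchrony, and privacy mechanisms (differential privacy,
secure aggregation) are out of scope.

Two algorithms share this loop. **FedAvg** applies plain local updates.
**FedProx** adds (μ/2)·‖w − w_global‖² to the local objective, i.e. the
gradient gains the term μ·(w − w_global). The *squared* L2 norm is used
throughout (the form under which the proximal gradient is linear and the
μ = 0 case reduces exactly to FedAvg). `FedConfig.algorithm` selects the
code path explicitly so that FedProx with μ = 0 and FedAvg are distinct
computations whose bit-identity is a testable property rather than a
tautology.

Design choices where the literature is silent or implementations vary:

- **Optimizer state is reset at the start of every local update and never
  averaged.** Only weights cross the wire; averaging Adam moments has no
  standard semantics in weight-averaging FL.
- **Loss normalisation is the per-sample mean within each batch**, which is
  what makes the sample-count weights pᵢ = nᵢ/n consistent with the pooled
  objective: with SGD, one local epoch, one full batch and no scheduler, a
  federated round is *exactly* one full-batch gradient-descent step on the
  pooled per-sample-mean objective. The test suite asserts this identity to
  1e−6 relative over 10 consecutive rounds with unequal client sizes.
- **Local shuffle seeds derive from (seed, client position, round, epoch).**
  Using the position rather than the client name makes the K = 1 degeneracies
  exact: a one-client federation, a centralized run, and a single-client run
  on the same data produce bit-identical trajectories.
- **Vocabulary synchronisation.** Weight averaging requires identical
  shapes, so federated and centralized runs build the token vocabulary from
  the union of client training data; single-client runs use client-local
  vocabularies (unknown tokens map to a reserved UNK row).
- **Scheduler**: linear warmup over 10 % of the client's total local steps,
  then linear decay to zero; a `"none"` setting gives a constant rate (used
  by the equivalence identities).

## Models

All models are float64 numpy with hand-derived analytic gradients, verified
against central finite differences (directional derivative, relative error
≤ 1e−5) with and without the proximal term.

- **LinearTagger** — per-token softmax over current/previous/next token
  identity features. Convex in its parameters, so full-batch gradient
  descent on separable data provably reaches the optimum; it serves as the
  oracle model for the federation-equivalence identities and as the default
  model of the experiment designs (its small capacity is what makes the
  federation-scale degradation visible at desk scale).
- **TaggerModel** — embedding (d = 16) → single-layer bidirectional tanh
  RNN (h = 16) → linear emissions → linear-chain CRF. The CRF log-partition
  uses the forward recursion in log space; NLL gradients are the
  forward–backward marginals minus gold indicators; decoding is Viterbi with
  ties broken to the lexicographically smallest tag-index sequence
  (implemented via suffix maxima so the tie-break is exact). Both inference
  routines are checked against exhaustive path enumeration for L ≤ 4, T ≤ 4.
  This is the classical bidirectional-recurrent + CRF sequence-labelling
  architecture at a deliberately small size; BIO structure is learned
  through the transition matrix, not hard-masked.
- **REModel** — embedding mean-pools over the head span, tail span and full
  sentence, concatenated into a linear classifier. The negative relation
  class is an explicit label, not a score threshold.

## Synthetic data

Each source owns per-type entity lexicons (50 surface forms per type, 1–3
tokens each), 16 sentence templates, and a 150-word context vocabulary, all
fabricated from deterministic pseudo-words. `make_sources(n, overlap, seed)`
draws round(overlap × pool) of each pool from a shared pool and the rest
privately and disjointly, so overlap = 1 gives identically distributed
sources and overlap = 0 fully disjoint sublanguages. The default non-IID
setting uses overlap 0.2, emulating two corpora that target the same entity
schema but were collected at different sites.

Generation instantiates a template, fills entity slots from the lexicons
(tagged B-/I-), and fills context positions from the context vocabulary.
With probability `tag_noise_rate` (default 0.05 in the experiment designs —
mild annotation-miss noise) one entity token is re-tagged O, followed by an
IOB repair pass so every emitted sentence is valid BIO. RE templates carry
the gold label in their identity (label-specific marker tokens between the
two entity slots), with labels drawn uniformly; the canonical
"Mutations of *GENE* gene are associated with *DISEASE*" template is always
included for the `associated_with` label.

The cross-source distribution distance is measured as the base-2
Jensen–Shannon divergence between unigram token distributions — bounded in
[0, 1], symmetric, 0 iff identical and 1 iff disjoint supports — and is
empirically monotone in the overlap knob (averaged over seeds).

What the generator does *not* emulate: real clinical discourse, ambiguous or
context-dependent entity mentions, nested/overlapping entities, subword
phenomena, label noise beyond single-token misses, and document-level
context. Passing trend tests on this data therefore demonstrates the
*mechanics* of federation (aggregation, drift, proximal control, capacity
effects), not expected F1 levels on real corpora.

## Preprocessing and evaluation conventions

- Corpora are deduplicated (byte-identical tokens + labels, first occurrence
  kept), shuffled, and split 80/10/10 with floor-based dev/test sizes and the
  remainder to train. Sentences are truncated to 512 raw tokens (the limit is
  counted in raw tokens, not subtokens).
- Token indices are 0-based, half-open everywhere.
- Strict matching requires identical (start, end, type); lenient requires
  the same type and ≥1 token of overlap. Requiring the type under lenient
  matching is a deliberate strengthening — type-free overlap would make
  multi-type macro averaging incoherent. Matching is one-to-one and greedy
  in start order; for strict matching greedy attains the bipartite-matching
  optimum (gold spans are disjoint, so each prediction has at most one
  strict partner); for lenient matching greedy is compared against the
  assignment optimum in tests and may in principle undercount, which is
  accepted as the fixed convention.
- Macro scores average over types/labels with at least one gold occurrence;
  0/0 ratios are 0. Repeats are summarised as mean ± sample sd (ddof = 1,
  sd = 0 for a single run), formatted to three decimals.
- Predicted tag sequences are IOB-repaired before span decoding so
  structurally unconstrained taggers can be scored.

## Experiment designs and their desk-scale defaults

All designs default to the LinearTagger, Adam (β₁ = 0.9) with learning rate
0.05, batch size 32, one local epoch, 15 rounds, warmup scheduler, 3 repeat
seeds (base, base+1, base+2). These budgets are declared desk-scale choices:
they are large enough for the centralized model to saturate (≈0.98 lenient
F1) while keeping every design in the minutes range on one CPU.

- **comparison** — 1250 generated sentences → ≈1000 train after
  dedup/split; IID split into k = 10 clients; centralized, FedAvg, and
  single-client (per-client models, unweighted score average) on a global
  test set.
- **scale** — the same ≈1000 training sentences re-partitioned for
  k ∈ {2, 4, 6, 8, 10}; total volume is asserted constant across k.
- **heterogeneity** — two sources at overlap 0.2, 700 generated sentences
  each (≈560 train); source-based non-IID clients vs an IID control split of
  the pooled data; FedAvg and FedProx for μ ∈ {1, 0.5, 0.1, 0.01, 0.001}.
  With the zero-initialised linear model, large μ pins clients at the
  uninformative broadcast weights, so its failure mode appears as F1 ≈ 0
  rather than the graceful degradation a pre-trained model would show; the
  monotone μ trend is the claim under test.

Numerical conventions: float64 throughout; aggregation weight sums are
validated to 1e−12; a non-finite training loss aborts with a diagnostic;
Viterbi ties break lexicographically; empty corpora, zero-length spans, and
overlapping span sets are rejected at construction or call time.

## Known limitations

- Sequential simulation only — no communication cost, stragglers, or client
  sampling, so "rounds" measure optimisation progress, not wall-clock
  federation cost.
- The trend findings are qualitative analogues at small scale; absolute
  scores are not comparable to transformer-based results on real corpora.
- Greedy lenient matching can undercount relative to optimal assignment on
  adversarial span sets (logged by the property tests; not observed on
  generated data).
- The few-shot prompting module builds and parses prompt bundles but never
  queries a language model.
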