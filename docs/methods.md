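# Methods

## Model

A lexicon of m words is coded twice: a binary cue matrix **C** ∈ {0,1}^(m×r)
whose row i marks which form cues word i contains, and a semantic matrix
**S** ∈ ℝ^(m×q) whose row i is the word's embedding. Comprehension is the
linear map **F** minimizing ‖**CF** − **S**‖²; production swaps the roles of
the two matrices. The linearity assumption is deliberate: the model is a
multivariate multiple regression, not a deep network, so every estimator has
a closed form or a simple recurrence, and measures derived from it
(target correlations, accuracies, 1 − r) are fully interpretable.

### Cues

Forms are padded with a single boundary marker (`#`) per side and decomposed
into overlapping n-grams, deduplicated (presence/absence coding — repeated
grams collapse to one cue). The inventory is the union over the lexicon in
first-occurrence order, which makes cue matrices reproducible and monotone
under lexicon growth. A frozen inventory can be applied to held-out forms;
rows that activate no known cue are flagged rather than silently zeroed.
Identical forms yield identical rows, so homophones share predictions by
construction — the tie-handling in evaluation exists for exactly this case.

For tonal transcriptions (`wen4ti2`), the `tonal_union` scheme emits three
cue families: segmental triphones over the concatenated segments
(#we, wen, ent, nti, ti#), tritone cues over the tone-digit sequence
(#42, 42#), and tone-segment triphones in which each vowel carries its
syllable's tone digit as one compound symbol (#we4, we4n, e4nt, nti2, ti2#).
Tone marks attach to vowels only, and a marked vowel occupies a single
symbol position in the triphone window; this is the only convention
consistent with sets like `e4nt` spanning e4–n–t. The vowel set is
language-specific and therefore a required argument, not a constant.

### Estimators

**EL.** The normal equations (**C**ᵀ**C**)**F** = **C**ᵀ**S** are solved via
a Cholesky factorization of the Gram matrix. If the smallest Cholesky pivot
falls below 1e−6 of the largest (a scale-invariant rank check — duplicate
homophone rows make the Gram matrix exactly singular), the solver falls
back to the minimum-norm least-squares solution (`numpy.linalg.lstsq`).
Scale invariance of the check matters: a weighted system and its
row-replicated equivalent have proportional Gram matrices and must take the
same branch, otherwise the two valid least-squares solutions can differ in
the null space. Ridge regularization is available but defaults to 0.

**FIL.** The weighted objective Σᵢ fᵢ‖**c**ᵢ**F** − **s**ᵢ‖² is solved by
scaling row i of **C** and **S** by pᵢ = √(fᵢ / max f) and calling the EL
solver. The square root is forced by the definition: the minimizer must
coincide with EL on matrices whose rows are physically repeated fᵢ times
(the package's primary correctness oracle, checked on hundreds of random
instances to 1e−8). Normalizing by the largest frequency keeps the scaled
system well-conditioned; since weights are defined only up to a positive
constant, it changes nothing else. Zero-frequency words get weight zero:
they do not constrain the fit but remain rows of the universe and are still
evaluated (and still count for type accuracy, but cost nothing in token
accuracy).

**WHL.** The delta rule **F** ← **F** + **c**ᵗᵀ(**s**ᵗ − **c**ᵗ**F**)·η,
applied once per learning event, starting from the zero matrix (the
conventional tabula-rasa start; it also gives the one-event closed form
η·**c**ᵀ**s**). The implementation updates only the active cue rows of
**F**, so an event costs O(cues-per-word · q) regardless of r. Non-finite
errors abort with the event index (the usual cause is η ≥ 2/‖c‖²).
Snapshots of **F** can be retained every N events for trajectory analyses.

**Frequencies to events.** Three translations of counts into event
multiplicities: `raw` (fᵢ events), `scaled` (⌈fᵢ/divisor⌉, so attested words
keep at least one event), and `log_backoff` (round(ln(fᵢ+1)), floored at 1
for attested words — the rounding is this package's choice; the transform
itself is standard). Event order is a seeded global shuffle by default.

### Evaluation

Similarity is the Pearson correlation between rows (not cosine). A word is
correct@k when its own gold vector is among the k gold vectors most
correlated with its prediction; ties within 1e−12 resolve in the target's
favor so homophone sets are not automatically failed. Zero-variance
predicted rows (e.g., untrained WHL rows) get the sentinel r = 0, a
degeneracy flag, and rank m — they can only be "correct" at k = m, which
preserves the invariant accuracy@m = 1. Type accuracy averages correctness
over words; token accuracy weights each word by its frequency
(Σfᵢ·flagᵢ/Σfᵢ). The per-word latency proxy is 1 − r, expected to correlate
positively with reaction times.

Priming designs (columns prime/target/condition) are scored as
1 − cor(ŝ_prime, **s**_target): the prime's *predicted* semantics against
the target's *gold* semantics, so identity primes under a perfect mapping
score exactly 0. Condition comparisons use a label-permutation test of mean
differences — a deliberately assumption-free toy-data analogue of the
post-hoc tests used on empirical reaction times, which are out of scope
here.

### Trajectories

`run_trajectory` trains WHL over an ordered stream, recording after every
batch (default 5,000 events; the state at the batch end, not mid-batch) all
words' target correlations and the within-batch token counts, and fits FIL
on the stream's aggregate counts as the order-agnostic reference.
`occurrence_moments` treats each word's batch index as a random variable
with mass proportional to its per-batch count and reports the weighted
mean, mode (smallest maximizing batch on ties, for determinism), skewness,
and excess kurtosis, with sentinel 0 and a flag for zero-variance words.
Kurtosis is additionally reported through the sign-preserving damping
x ↦ sign(x)·log(1+|x|); this transform is a stand-in of this package's own
choosing (tagged as such in the output metadata) for outlier control.
`whl_fil_delta` joins per-word r_WHL − r_FIL with the moments; on planted
schedules, late-bursting words show positive deltas (recency advantage)
and early-bursting words with cue overlap show negative ones (unlearning).

## Synthetic data

The generator emulates the statistical structure of the lexical resources
this kind of model is normally fit to, and is itself tested code:

- **Frequencies** are deterministic rounded Zipf: the rank-i word gets
  round(f_max·i^(−a)) ⩾ 1 with f_max = m by default, so the max/min ratio is
  ≈ m^a and oracle tests are exactly reproducible (no sampling noise in the
  weights).
- **Semantics** are either i.i.d. Gaussian rows or, by default, a planted
  linear map: S = **C**F* + ε with F* i.i.d. standard normal and
  ε ~ N(0, σ²). With σ = 0 the system is consistent and EL must be exact —
  the parameter-recovery tests. The default σ = 3 was calibrated so that
  least-squares mappings on the default 500-word lexicon are learnable but
  clearly imperfect (type accuracy in the tens of percent), the regime real
  lexicon–embedding pairings occupy; at small σ everything saturates and
  frequency has nothing to explain.
- **Homophones** are injected as distinct entries sharing a form, so
  evaluation tie-handling is exercised rather than assumed.
- **Tonal forms** are onset+rime+tone syllables (1–2 per word) over a small
  Mandarin-like inventory, dense enough that segment-sharing and
  tone-sharing prime–target pairs exist by construction.
- **Streams** are i.i.d. multinomial draws proportional to frequency
  (stationary), optionally with designated words' tokens confined to the
  first or last fraction of the stream (early/late burst) to plant order
  effects of known sign.

What the generator does *not* emulate: the covariance structure of real
embeddings, realistic n-gram phonotactics, morphological families, or
polysemy. Passing tests therefore establish the estimators' mathematical
properties and the direction of frequency and order effects under the
model's own assumptions — not behavioral coverage of any particular
language.

## Problem sizes and numerical choices

The default study conditions are m = 500 words, bigram cues over an
8-letter alphabet (r ≈ 80), q = 20 semantic dimensions, Zipf exponent 1.
For the WHL–FIL per-word comparison, WHL is trained on 30 passes over the
frequency-derived events (≈ 40 tokens per type, the density typical of the
longitudinal child-directed-speech corpora such comparisons target); with
far fewer tokens per type WHL is undertrained relative to any converged
solution and the comparison is uninformative. The WHL→EL convergence check
uses a 50-word noise-free lexicon with long forms (22–30 symbols over 26
letters): the delta rule's slowest mode contracts like exp(−η·λ⁺min·epochs)
and λ⁺min is of the order of cues-per-word for nearly orthogonal rows, so
long forms are what make the η = 10⁻³ / 500-epoch budget sufficient.
Degenerate inputs are rejected loudly (empty lexicons, all-zero cue
matrices, all-zero weights, empty event sequences, divergent updates), and
all generators and training loops are pure functions of their seeds.

## Known limitations

- The production direction is estimated (fit **G** by swapping matrices)
  but no decoding of predicted cue vectors into word forms is provided.
- FIL treats frequencies as exchangeable evidence; genuinely ordered data
  lose recency/unlearning effects, which is precisely what the trajectory
  module quantifies.
- The permutation summary for priming conditions tests mean differences
  only; it is not a substitute for a full mixed-model analysis of
  empirical latencies.
- Weighted fitting is exact for the weighted least-squares objective, but
  with heavy rank deficiency the minimum-norm convention (not any
  psychological principle) picks the representative solution.
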