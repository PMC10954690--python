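# Methods

This note documents the models, definitions, defaults and numerical choices
behind `speechmarkers`, and what the synthetic-cohort tests do and do not
establish about real speech data.

## Transcripts and tokenization

A transcript is one ~1-minute prompt-elicited excerpt in one of two
versions, `manual` or `automated`.  Sentences split on terminal punctuation
(`. ! ?`); the recognizer's punctuation is trusted as-is because the
sentence-level semantic measures are intentionally sensitive to it — a
recognizer that mis-places sentence boundaries *should* degrade those
markers.  Tokens are lowercased with edge punctuation stripped; hyphenated
words split, apostrophe contractions stay whole; no lemmatization or
stemming, since the word graphs are defined over surface forms.

Stop-word/filler filtering applies **only** to the semantic-embedding path.
Graph and POS features always use the unfiltered token stream, and the
verbosity counts (number of words, words per sentence, total tags) count
unfiltered tokens.  The packaged stop list is a small function-word list and
is overridable; no standard list is canonical for this task, and the
coherence statistics are robust to its exact content because SIF weighting
already down-weights frequent words.

## Word-graph connectivity

For a token window, the graph has one node per unique word and one directed
multi-edge per adjacent token pair, so E = window length − 1 always.
Definitions chosen where the literature is loose:

* repeated edges RE = multigraph edge count − number of distinct ordered
  node pairs with at least one edge (surplus same-direction duplicates);
* parallel edges PE = number of unordered pairs {u, v}, u ≠ v, with edges in
  both directions;
* L1 = number of immediate word repeats (multigraph self-loops);
  L2 = tr(A²)/2 and L3 = tr(A³)/3 on the binary adjacency with zeroed
  diagonal, so self-loops never contaminate higher cycle counts.  Note that
  with these (binary) definitions L2 ≡ PE — both are reported because the
  marker panels of the field list both;
* LCC on the undirected projection, LSC by strong-component decomposition;
* density = E_simple/(N(N−1)) excluding self-loops, 0 for N = 1;
* diameter and average shortest path over the *reachable* ordered node pairs
  of the directed simple graph; a graph with no reachable pair scores 0.
  Ignoring unreachable pairs (rather than imputing ∞ or N) keeps the
  measures finite and comparable across windows;
* clustering = mean undirected local clustering, 0 for degree < 2 nodes.

Windows are exactly `window_size` (default 30) tokens starting at multiples
of `window_step` (default 15); trailing tokens beyond the last full window
are dropped when at least one full window exists, because fixed-size windows
are the whole point of the verbosity control; a transcript shorter than one
window is analyzed whole.  Measures are arithmetic means over windows.

The shuffle null permutes the *entire excerpt token sequence* uniformly
(seeded), re-windows, and reports per-measure null mean, SD and
z = (observed − mean)/SD; z is NaN where the null SD is 0 (N and E are
permutation-invariant for whole-sequence windows).  Downstream analyses use
raw measures by default; z-scores are opt-in columns.

The measures are computed with dense numpy adjacency algebra, union-find,
an iterative Tarjan strong-components pass and vectorized Floyd–Warshall —
windows are ≤ 30 nodes, so dense O(N³) beats sparse-library overhead by
about 3×.  The test suite verifies every measure against networkx and
against brute-force cycle enumeration on random sequences.

## SIF coherence statistics

Sentence embedding: v = (1/k) Σ over in-vocabulary filtered tokens of
a/(a + p(w)) · vec(w), with smoothing a = 1e-3 (the standard SIF default)
and p(w) from a supplied frequency table — never from the analyzed corpus,
so the same lexicon gives the same embeddings on any corpus.  Sentences with
no in-vocabulary token, or whose weighted sum cancels to the zero vector,
have no direction: they are *dropped and counted* (`n_dropped_sentences`),
never scored as similarity 0.  Common-component (first principal component)
removal is available per-corpus but off by default: one-minute excerpts have
~10–15 sentences, too few to estimate a common direction stably.

From the valid sentence vectors s_1..s_m and stimulus vector c:

* coherence = mean_i cos(s_i, s_{i+1});
* on_topic = mean_i cos(s_i, c);
* tangentiality = OLS slope of cos(s_i, c) on i = 0..m−1.  The slope is
  taken on the stimulus-similarity series (not the adjacent-similarity
  series): tangential speech is speech that *drifts away from the prompt*,
  and this makes tangentiality the temporal derivative of the on-topic
  series;
* repetition = max over pairs cos(s_i, s_j), which bounds coherence above
  by construction.

Coherence, tangentiality and repetition need ≥ 2 valid sentences, on-topic
≥ 1; otherwise NaN (missing, excluded pairwise downstream).

## POS features

The tagger backend is pluggable (`tag_sentence(tokens) -> tags`, Penn
tagset).  Two deterministic backends ship: a dictionary tagger and a small
closed-class-lexicon + suffix-rule English tagger.  The marker categories —
personal (PRP) and possessive (PRP$) pronouns, WH-determiners, WH-pronouns,
WH-adverbs — are closed classes, exactly where a lexicon tagger is reliable;
open-class words only feed the total tag count, which equals the word count
by construction.  Both pronoun categories are reported because marker panels
in the field are inconsistent about which they mean; analyses default to
PRP.  Frequencies are raw counts (verbosity-tracking, like the word count),
with per-word rates available.

## Transcription quality

Alignment is the unit-cost minimum-edit-distance DP.  Among equal-cost
alignments the hit count is not unique, so the DP minimizes
(cost, −hits) lexicographically via a combined integer weight; this makes
H, S, D, I canonical and swap-symmetric (swapping reference and hypothesis
exchanges D and I and preserves MER).  WER = (S+D+I)/N_ref may exceed 1;
MER and WIL are bounded in [0, 1]; an empty hypothesis scores WIL = 1.
Words are compared after the same normalization as tokenization, so
punctuation style never counts as a word error.  Per-excerpt metrics are
macro-averaged per participant; corpus-level metrics pool counts before
dividing (micro-average).  Both are emitted because field reports rarely say
which they used.

## Synthetic cohorts

The generator emulates the study design the analysis chain assumes: 8
one-minute picture descriptions per participant (~120 ± 15 words each,
sentences ~10 ± 3 words), two transcript versions, and SPQ-like (0–74
integer) and PDI-like (0–21 integer) outcomes with Table-1-like
demographics (age ~ N(28, 6.3) clipped to 18–40; gender 65/34/1%
female/male/other; six ordered education levels; device 73/26/1%
computer/smartphone/tablet).

A latent disorganization trait θ ~ N(0, 1) per participant drives
everything:

* each sentence abandons the prompt's topic with probability
  clip(0.15 + 0.12·θ, 0, 0.95) — off-topic sentences sample a random other
  topic, lowering on-topic and coherence scores;
* immediate word repeats are injected with probability
  clip(0.01 + 0.02·θ, 0, 0.5) per word.  Word sampling otherwise redraws
  any naturally adjacent duplicate, so the one-node-loop count L1 is
  *exactly* the planted repetition signal;
* outcomes are linear in θ plus N(0, 3) noise, rounded and clipped to the
  questionnaire ranges: SPQ = 7.5 + 3.0·θ + ε, PDI = 4.0 + 1.8·θ + ε
  (intercepts and spreads match the published sample-1 descriptives).
  Positive loadings encode the empirical direction: more disorganized
  speech with higher schizotypy/delusional ideation, hence *negative*
  marker–outcome correlations for on-topic.

Vocabulary is 8 topics × 60 words with Zipf-like probabilities; word
vectors are unit vectors clustered around orthonormal topic centers
(within-topic cosine ≈ 0.85, between ≈ 0), so embedding dimension must be
≥ the number of topics.  Every word carries a Penn tag, making the
dictionary tagger exact on synthetic text.

The recognizer channel corrupts each word independently with probability
`asr_error_rate`, choosing substitution/deletion/insertion with mix
(0.6, 0.25, 0.15); substitutions and insertions draw random vocabulary
words.  Sentence punctuation is perturbed separately (boundaries merged or
inserted with probability `punct_error_rate`) because the sentence-level
semantic measures are punctuation-sensitive while word-error metrics ignore
punctuation entirely.  With unit-cost alignment each corrupted word
contributes one error, so measured WER converges to the nominal rate as
excerpts grow — the calibration test checks ±0.03 at ~120 words.  Presets:
`sample1_like` (rate 0.21, punctuation 0.05) and `sample2_like` (0.08,
0.02), named for the two transcription-quality regimes reported for online
ASR pipelines.

**What the generator does not emulate:** natural-language syntax and
semantics (sentences are bags of topic words), acoustic or speaker effects,
correlated ASR errors (real recognizers err in bursts and on rare words),
demographic–trait correlations, and item-level questionnaire structure.
Passing end-to-end tests therefore shows the *pipeline* recovers planted
structure through the full extract→analyze chain at realistic sample sizes
and noise levels — not that these markers separate clinical groups in real
recordings.

## Statistical chain

Markers are averaged per participant and version over available excerpts
(pairwise deletion of missing excerpt values).  Spearman correlations run
per (marker, outcome, version); Benjamini–Hochberg step-up control applies
per (outcome × version) family with flags at α = 0.05 and 0.01; constant
markers get missing rho and leave the family.  Group contrasts use
two-sided Mann–Whitney U (reported as min(U₁, U₂); exact p for small
tie-free samples via scipy), BH-corrected across markers per version.

The regression ladders fit five regressor sets — demographics; markers from
each version; demographics + markers from each version — on one shared
complete-case row set, so in-sample R² (linear) and log-likelihood
(logistic) are monotone across nested sets by construction.  Demographics
enter as numeric age, ordered-integer education, and one-hot gender/device
with first-level reference.  The full marker panel contains definitional
identities (total tags = word count; L2 = parallel edges; LCC = nodes on
connected windows; edges constant at window_size − 1 for full windows), so
exactly collinear columns are dropped keeping the first occurrence and
recorded on the fitted ladder (`dropped_columns_`); `drop_collinear=False`
raises instead, naming the columns.

Logistic fits are maximum likelihood (statsmodels); under perfect
separation the fit is flagged and bounded L-BFGS estimates are reported.
Metrics are in-sample (no held-out split), matching the two-step study
design being reproduced; a cross-validation switch is deliberately out of
scope.  Classification threshold is fixed at 0.5; AUC is the rank statistic
(tie-aware).  Pseudo-R²: Cox & Snell = 1 − (L₀/L₁)^{2/n}, Nagelkerke
rescales it by its maximum 1 − L₀^{2/n}, Tjur = mean p̂ | y=1 − mean p̂ | y=0.
All three are 0 for the intercept-only model and Cox & Snell ≤ Nagelkerke.

## Numerical choices and edge cases

* Cosine with a zero-norm vector is NaN, never 0.
* z-scores with zero null SD are NaN ("missing"), never ±∞.
* BH families exclude NaN p-values; NaN is never "rejected".
* Alignment tie-break: maximize hits among minimum-cost alignments
  (globally, via the lexicographic DP) — metric values are then canonical.
* All randomness flows from `numpy.random.default_rng(seed)`; a (config,
  seed) pair reproduces a cohort bit-for-bit.

## Problem sizes in the test suite

Unit and property tests run on sequences of ≤ 40 tokens and cohorts of
12–40 participants.  The end-to-end recovery test uses 50 planted cohorts
of n = 400 (the analysis sample size regime of the emulated design, markers
extracted from the automated version, where recovery is hardest) and 50
null cohorts of n = 100 (type-I error of the BH step does not depend on n).
The acceptance script analyzes one 400-participant cohort per noise preset
with both transcript versions.
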