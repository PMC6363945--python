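# Methods

This note documents the models and procedures `chunklex` implements, the
numerical and design choices made where the problem left them open, and
what the synthetic-data generator does and does not emulate.

## Units and representations

The analysis unit is the **multi-syllable utterance (MSU)**: a full
caregiver utterance of at least two syllables, taken as the candidate unit
a child might store as an undersegmented chunk. Words are mapped to
syllables through a syllabified pronouncing lexicon; a syllable's identity
is its phoneme sequence (rendered as phonemes joined with `.`), not its
spelling, so two word strings with the same syllabification collapse to
one MSU type. Stress digits on phonemes are stripped at parse time: the
source dictionaries mark lexical stress on vowels, but stress plays no
role in any of the statistics here, and keeping it would split otherwise
identical syllables. Words with several dictionary pronunciations keep the
first (deterministic, order-of-file). Utterances containing any
out-of-lexicon word are dropped; the retained fraction is reported as
coverage. Ingestion expects a simple tabular format (TSV/JSONL) with
pre-tokenized, punctuation-stripped utterances; dialect normalization of
raw transcript formats is deliberately upstream of this package.

## Chunk candidacy and ranking

Three filters define the candidate pool: (1) at least two syllables —
single-syllable utterances are already fully segmented under the
syllables-as-primitives assumption; (2) not a repetition of a single word
(*no no no*); (3) produced by caretakers in at least two source corpora,
which screens out utterances idiosyncratic to one child–caregiver dyad.
Token frequency is counted over the whole aggregated corpus and is not
re-restricted by the two-corpus filter (the filter gates membership, not
counting).

The **predictability score** of an MSU *u₁…uₙ* averages 2(n−1) conditional
probabilities: forward terms p(uᵢ|uᵢ₋₁) for i = 2…n and backward terms
p(uᵢ|uᵢ₊₁) for i = 1…n−1, duplicates kept. Conditionals come from bigram
counts over adjacent within-utterance syllable pairs (never across
utterance boundaries). The forward denominator is the number of
occurrences of the conditioning syllable *that have a right neighbor*, and
symmetrically for backward terms, so each conditional is a proper
probability distribution over observed alternatives (Σᵥ p(v|u) = 1). The
alternative convention — normalizing by all occurrences including
utterance-final ones — would make scores depend on how often a syllable
ends an utterance; the chosen convention is the one under which a pair of
syllables that only ever occur together scores exactly 1.0, which is the
defining behavior of the score.

Top-N selection uses a deterministic, seed-free tie-break: the primary
metric, then descending frequency, then ascending lexicographic syllable
string. This makes chunk sets monotonically nested in N and reproducible
without any random state.

## Classification of single-word MSUs

A chunk set is scored as a classifier whose positive predictions are its
members and whose ground truth is "the MSU's word list has length one".
Precision = W_C/N, recall = W_C/(W_C+W), F = harmonic mean (0 when both
are 0). Confidence intervals are percentile bootstraps (default 100
resamples, sample size = pool size, resampling the MSU *type* as the data
point). Within a resample, precision's denominator is the resample's
in-set count, not the nominal N, since a resample generally draws a
different number of members. Resamples on which a statistic is undefined
(no in-set draws) are excluded from the percentiles and counted in the
result; at realistic pool sizes this is vanishingly rare. Differences
between chunk sets are bootstrapped on *shared* resamples (paired), so the
difference of a set with itself is identically zero; significance is "the
95% interval excludes zero", with no multiple-testing correction across
the N grid (the grid is a descriptive curve, not a hypothesis family).

## Age of first production

**Corpus-derived AoFP.** Developmental stage is the transcript's mean
length of utterance (MLU) in word tokens, estimated by bootstrap: 10,000
resamples of the transcript's child utterances, sample size equal to the
transcript; the estimate is the mean of resample means (for a
constant-length transcript this is exact). Each transcript's bootstrap
seed combines the caller's base seed with an FNV hash of the transcript
id, so estimates do not depend on corpus order. A child production of a
target word is *valid* only if no contiguous word n-gram (n ≥ 2) of the
child utterance covering that occurrence matches a contiguous
sub-sequence (length ≥ 2) of any adult MSU; isolated productions are
always valid, and with several occurrences one valid occurrence suffices.
"Sub-sequence" is strictly contiguous — non-contiguous matching has no
support in the motivating example (*it's a great day* vs. *what a great
day*). The exclusion uses the full filtered candidate pool, not a top-N
chunk set: the point is to discard any production that could be an echo
of *any* adult-produced chunk. A word's AoFP is the minimum MLU over
transcripts containing a valid production, provided valid productions
occur in at least two corpora (valid productions only — the stricter
reading of the two-corpus requirement, flagged as an interpretation).

**CDI-derived AoFP.** From a word × month (16–30) table of reported
production proportions, AoFP is the earliest month at which the
proportion reaches the threshold (default 50%). Proportion curves are
taken as given: non-monotone curves use the first crossing, with no
smoothing. When predicting CDI outcomes, the MSU pool is restricted to
types with at least one token addressed to a child aged ≤ 30 months
(frequencies recomputed over qualifying tokens; missing ages never
qualify — the conservative choice).

**Validation.** `rank_validation` computes Spearman's ρ over the shared
words of two AoFP tables; the p-value uses the large-sample t
approximation, replaced below n = 10 by an exact permutation p.

## Regressions

For a chunk set and target word, #MSU is the number of distinct MSU
*types* containing the word (an MSU with the word twice counts once).
Covariates: corpus token frequency (Freq), concreteness (Con), syllable
count (Nsyl), and phonological neighborhood density (PhonN = homophones
plus words at one phoneme addition/deletion/substitution, computed over
flattened stress-free pronunciations; a deletion-variant index makes this
near-linear in lexicon size). The analysis sample is the inner join of
words with AoFP, a lexicon entry, a concreteness rating, and Freq > 0;
words with #MSU = 0 are retained (the +1 offset exists precisely for
them).

All variables, outcome included, are natural-log-transformed and
standardized to z-scores on the analysis sample: AoFP, Freq and Nsyl are
strictly positive; #MSU and PhonN can be zero and get +1 before the log
(the offset for PhonN is forced by zeros and is applied for the same
reason as the #MSU offset); Con is a positive bounded rating and is
logged like every other variable — standardization makes the fits
insensitive to that choice up to the monotone transform. Fits are
ordinary least squares; the #MSU effect is its standardized coefficient β
and the R² gain over the covariate-only baseline (ΔR², nonnegative for
nested OLS on the same rows). Bootstrap CIs (default 100 resamples)
resample *target words*, the regression's data points, and refit —
standardization included — inside each resample; refitting the
standardization keeps every resample a self-contained version of the same
analysis. Metric comparisons at a given N reuse identical word resamples
on both sides (paired), which is what makes a CI for "β(S) − β(F)"
well-defined. Degenerate inputs fail loudly: zero-variance predictors and
rank-deficient designs raise with the offending term named; cells with
fewer words than predictors + 3 are skipped with a warning.

The cross-corpus design de-couples predictors from outcomes: with two
corpora A and B, #MSU and Freq from A predict AoFP from B's children and
vice versa; a CDI table adds a third pairing with predictors from the
age-restricted union of both corpora.

## The synthetic-data generator

The generator emulates, at configurable scale, the features of
child-directed speech corpora the analysis depends on — and nothing else.
What it reproduces: Zipfian word frequencies in running speech; short
utterances (filler lengths max(2, 1+Poisson), mean ≈ 4 words, with ~25%
single-word utterances); multiple sub-corpora sharing a controlled family
of template MSUs while each also produces corpus-specific speech (every
idiosyncratic utterance carries one of the corpus's caregiver/child name
words, which guarantees it cannot survive the two-corpus filter); child
transcripts whose MLU grows linearly with developmental stage; a planted
negative effect of #MSU on AoFP; and logistic CDI curves crossing 50% at
the planted month. What it does not attempt: realistic phonotactics,
prosody, discourse structure, or morphology. Passing tests therefore show
that the *pipeline* recovers structure it is pointed at, not that real
corpora contain that structure.

Design of the planted effect. Each target word receives independent
Poisson numbers of **short templates** (the word plus a monosyllabic
partner; 2–3 syllables; 2–3 tokens each) and **long frequent templates**
(≥ 6 syllables; ≥ 4 tokens each). The frequency bands are disjoint, so
the top-N-by-frequency set at N = (number of long templates) is exactly
the long family; 4–5-syllable padding templates built from partner words
top the pool up so the equally sized shortest set contains the *entire*
short family regardless of target syllable counts. Together these make
the per-word #MSU-S and #MSU-F counts statistically independent across
targets — the property that lets a no-effect-on-F specification actually
test specificity rather than collinearity. Each target also gets a
heavy-tailed lognormal "base usage" in ordinary marked utterances
(log-mean 4.0, log-sd 1.1), so its corpus frequency is dominated by
running usage rather than template membership; without this, Freq acts
as a collider between the two #MSU counts and biases the no-effect
coefficient away from zero. Controlled single-word MSU types come from a
disyllabic pool plus a few **sealed** words whose syllables use reserved
onsets and occur nowhere else — their predictability is exactly 1.0 by
construction, pinning the top of the P ranking. Single-word *filler*
utterances use monosyllabic words so they never enter the MSU pool.

The outcome is planted on the log scale: log AoFP = μ − b·z(log(1 +
#MSU_predictor)) + ε, with b in SD units, ε ~ N(0, √(1−b²)) by default
(unit total variance), μ = 1.0 and scale 0.25 mapping into a plausible
MLU range (≈ 1.3–5.7); CDI months are 23 + 4·(standardized outcome),
clipped by the instrument's 16–30 window (later months are simply never
reported at 50%). Crucially the generator computes the #MSU counts it
plants from by running the package's own extraction and ranking on the
corpus it just generated, so the truth record and any downstream analysis
refer to the same realized quantities. Child corpora realize the plant:
each word's first valid production is placed (isolated, or framed by
child-only vocabulary) in the transcript whose realized mean utterance
length is closest to the word's planted AoFP, in every corpus; with the
configured contamination probability a corpus's production is instead a
verbatim adult template at the earliest stage — which the exclusion rule
must discard — and a word contained in no adult MSU cannot be
contaminated, so that corpus contributes no production. The truth record
stores realized transcript MLUs and the expected corpus-derived AoFP per
word (None when fewer than two corpora hold a valid production).

Determinism: one integer seed drives four independent sub-streams
(lexicon, adult corpus, child corpus, plant), and identical configurations
produce byte-identical bundles.

## Problem sizes and test design

The test suite verifies exact identities and oracle equivalences at toy
scale (random corpora of ≤ 50 utterances against literal brute-force
re-implementations; OLS against normal equations to 1e-8) and statistical
recovery at moderate scale: 20 replicate synthetic worlds with 2,000
target words for the planted-effect recovery test (β(#MSU-S) negative,
CI covering the planted −0.5, paired S−F difference significant, and
β(#MSU-F) covering zero, each in ≥ 18/20 replicates), and one world with
5,000 targets for the ΔR² construction (a planted 5% unique-variance
share recovered within [0.03, 0.07]). These sizes give each check
comfortable statistical margin while keeping the full suite to a few
minutes on a single core. `scripts/acceptance.py` runs the same pipeline
at 1,000 target words and writes every stage's headline numbers.

## Known limitations

- The spec of the predictability conditionals prints the medial backward
  term as p(u|uᵢ₊₁); it is read as p(uᵢ|uᵢ₊₁). The denominator convention
  (neighbor-restricted counts) is a documented choice, not the only
  defensible one.
- Corpus-derived AoFP is a population-level minimum statistic: it is
  sensitive to sampling density and says nothing about individual
  children.
- The generator's decorrelated template families are a deliberately
  *identifiable* world; real corpora confound length, frequency, and
  predictability far more heavily, and the pipeline's CIs — not the
  generator — are what must carry that burden on real data.
- Grapheme-to-phoneme fallback for out-of-lexicon words and full
  transcript-dialect (.cha) parsing are out of scope; prepare corpora
  upstream.
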