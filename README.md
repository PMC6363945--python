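# chunklex

**Which chunks of child-directed speech do children store?**

Early in language acquisition, children appear to store some stretches of
speech as *undersegmented chunks* — multi-word sequences held in memory
before their internal structure (words, morphemes) has been discovered.
`chunklex` implements a corpus-analysis pipeline that asks what kind of
chunks those are likely to be: **frequent** sequences, **internally
predictable** sequences, or simply **short** ones.

The pipeline operates on syllabified *multi-syllable utterances* (MSUs) —
full caregiver utterances of at least two syllables — and proceeds in three
stages:

1. **Chunk selection.** From adult (child-directed) speech, candidate MSUs
   are extracted (≥ 2 syllables, not a single-word repetition, used by
   caretakers in at least two source corpora) and ranked three ways: by
   syllable length (S), token frequency (F), and syllabic predictability
   (P). The top *N* under each ranking form a *chunk set*.

   The predictability of an MSU *u*₁…*u*ₙ is the mean of the
   forward and backward conditional probabilities between adjacent
   syllables: each medial syllable contributes *p*(*u*ᵢ|*u*ᵢ₋₁) and
   *p*(*u*ᵢ|*u*ᵢ₊₁); the edges contribute one term each — 2(*n*−1) values
   in total, estimated from syllable-bigram counts over the corpus.

2. **Word classification.** Each chunk set is scored as a classifier of
   single-word utterances: with *W*\_C single-word MSUs inside the set and
   *W* outside, precision = *W*\_C/*N*, recall = *W*\_C/(*W*\_C + *W*), and
   the F-score is their harmonic mean, with percentile-bootstrap 95%
   confidence intervals (and paired-bootstrap CIs for differences between
   chunk sets).

3. **Age-of-first-production (AoFP) regression.** For each target word,
   \#MSU counts the MSU types in a chunk set containing it. AoFP is
   estimated either from child transcripts (developmental stage =
   bootstrapped mean length of utterance per transcript; productions inside
   adult-MSU contexts are excluded; a word's AoFP is the minimum MLU over
   transcripts with a valid production in ≥ 2 corpora) or from CDI
   parent-report tables (earliest month where ≥ 50% of children produce the
   word). Ordinary least squares then fits

   `z(log AoFP) ~ z(log(#MSU+1)) + z(log Freq) + z(log Con) + z(log Nsyl) + z(log(PhonN+1))`

   and the \#MSU effect is summarized by its standardized coefficient β and
   by ΔR² over the covariate-only baseline, both with
   resample-target-words bootstrap CIs.

Because the transcript and parent-report databases the method was designed
for are external resources, the package ships a first-class
**synthetic-data generator** (`chunklex.synthetic_data`) that produces
corpora, pronouncing lexica, concreteness tables, and CDI curves with the
statistical structure the analysis assumes — including a *planted*,
known-size effect of \#MSU on AoFP — so the whole pipeline is testable
end to end.

## Worked example

```python
from chunklex import *
from chunklex.msu_regression import assemble_features, sweep_regression
from chunklex.synthetic_data import GeneratorConfig, PlantedEffect, generate_bundle

cfg = GeneratorConfig(seed=1, n_target_words=1000,
                      planted_effect=PlantedEffect(predictor="S", slope=0.5))
bundle = generate_bundle(cfg)

syll, coverage = syllabify_corpus(bundle.adult_corpus, bundle.lexicon)
adult, _ = split_speakers(syll)
pool = extract_candidate_msus(adult)
N = bundle.truth["planted_N"]

aofp = AoFPTable({w: d["aofp_mlu"] for w, d in bundle.truth["targets"].items()},
                 "corpus")
cells = {(m, N): assemble_features(aofp, rank_and_select(pool, m, N),
                                   adult, bundle.lexicon, bundle.concreteness)
         for m in ("S", "F")}
results, diffs = sweep_regression(cells, n_resamples=100, seed=1)
for r in results:
    print(f"{r.metric}: beta={r.beta_msu.point:+.3f} "
          f"[{r.beta_msu.lo:+.3f}, {r.beta_msu.hi:+.3f}]  "
          f"dR2={100*r.delta_r2.point:.1f}%")
```

prints (seed 1):

```
F: beta=-0.018 [-0.082, +0.044]  dR2=0.0%
S: beta=-0.517 [-0.557, -0.469]  dR2=26.5%
```

The generator planted a −0.5 SD effect of the shortest-chunk count
(\#MSU-S) on log AoFP and none for the most-frequent-chunk count
(\#MSU-F). The fitted coefficients recover exactly that: words contained
in many *short* chunks are produced earlier (β ≈ −0.5, CI excluding 0),
while \#MSU-F shows no effect (CI covering 0).

## Command line

A thin CLI wraps the library:

```bash
chunklex simulate --seed 3 --out bundle/          # write a synthetic bundle
chunklex select-chunks --metric S --n 1000 --corpus bundle/adult_corpus.tsv \
    --lexicon bundle/lexicon.tsv
chunklex classify-words --corpus bundle/adult_corpus.tsv --lexicon bundle/lexicon.tsv \
    --n-grid 500:5000:500 --resamples 100 --seed 1
chunklex estimate-aofp --mode cdi --cdi bundle/cdi.tsv --threshold 0.5
chunklex regress --predictor-corpus bundle/adult_corpus.tsv \
    --outcome-corpus combined.tsv --lexicon bundle/lexicon.tsv \
    --concreteness bundle/concreteness.tsv --metrics S,F --n-grid 1000:5000:1000
```

Input formats: utterance TSV (`corpus_id`, `transcript_id`,
`speaker_role`, `child_age_months`, `utterance`), a syllabified
pronouncing dictionary (`word<TAB>syllables`, syllables separated by
`" - "`, phonemes by spaces), a concreteness TSV (`lemma`, `rating`) and a
CDI TSV (word plus one proportion column per month, 16–30).

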