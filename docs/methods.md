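# Methods

`adrfilter` separates genuine adverse-drug-reaction (ADR) mentions from
other drug–disorder co-occurrences in patient forum posts using a single
signal: the signed distance, in words, between the drug name and the
disorder term. This note documents the model, the conventions the
implementation fixes where the design was open, what the synthetic data
emulate, and the limits of both.

## The distance statistic

A *word* is a maximal run of non-whitespace characters after preprocessing.
Preprocessing inserts a space around every punctuation character (Unicode
category P plus the ASCII symbol set), lowercases Unicode-aware with
accents preserved, collapses whitespace, and splits on spaces, assigning
1-based positions. Consequences that matter downstream:

* punctuation marks are tokens and count toward distances;
* stop words are never removed — removing them would deform the distance
  distribution the whole method rests on;
* French elisions are split (`l'insuline` → `l ' insuline`), which affects
  token counts; the choice is fixed and uniform on both the corpus and the
  lexicon so term span lengths stay consistent;
* digits are word characters; symbol emoticons behave as punctuation.

For a drug mention *a* and disorder mention *b* (positions taken at the
first token of a multi-word span),

```
distance(a, b) = pos(b) − pos(a)
```

negative when the disorder precedes the drug. When the same drug name
occurs several times in a message, each disorder keeps only the occurrence
minimising |distance|; a tie between an equally distant occurrence before
and after keeps the positive distance, on the observation that reaction
narration tends to follow the drug mention. "Minimises the distance" is
read as minimising the absolute value: a signed minimum would always pick
the most negative candidate, contradicting the two-sided concentration of
ADRs around the drug name. Distinct drug names are paired independently;
only occurrences of the *same* name are collapsed.

## Entity recognition

Matching is lexicon-driven and runs drugs first, disorders second, with
drug-claimed tokens masked so a drug name that is also a lexicon word
cannot double-count.

* **Disorders** match by exact equality of per-token stems against an
  LLT-level lexicon (MedDRA-like `LLT → PT → SOC` linkage, surface terms
  including lay expressions). Overlaps resolve longest-span-first, ties
  leftmost — implemented globally rather than per-position left-to-right so
  the policy is exactly the one an exhaustive enumeration oracle applies,
  including on straddling configurations where the two differ.
* **Drugs** match by equality of *fuzzy keys of stems*. The fuzzy key folds
  accents, strips every vowel after the first vowel occurrence ('y' counts
  as a vowel), and collapses runs of an identical consonant; "modeling" and
  "modelling" share a key, as do "zolpidem" and the vowel-dropped
  "zolpidme". Key equality replaces any edit-distance threshold: it is
  deterministic and reuses the same machinery that conflates misspellings
  in lexicon construction. Vowels are stripped before consonant runs are
  collapsed; the order is unobservable for double-consonant variants but is
  fixed for determinism.
* **Stemming** uses a light French suffix stripper in the Savoy family
  (plural/feminine `-s/-x/-r/-e/-é`, `-aux → -al`, doubled final
  consonant), iterated to a fixed point so stemming is idempotent. Tokens
  under 6 characters pass through. The stemmer is pluggable: any
  deterministic idempotent token map can replace the default, and lexicons
  built for a different stemmer remain usable because the same function is
  applied to both sides of every match.
* A surface form shared by several LLTs resolves to the lexicographically
  smallest LLT id, with a warning — the tie must break deterministically
  and no context model is in scope to do better.

## Mixture model of distances

Signed distances are modelled as a K-component univariate Gaussian mixture
(K = 3 throughout: a tight, a middle and a wide component), fitted by EM
with free weights, means and variances. Clusters with near-equal means and
very different variances produce exactly the observed geometry: the tight
component claims an interval around zero, the middle one a union of two
flanking intervals, the wide one the tails.

Numerical choices:

* log-sum-exp for every density aggregation;
* deterministic initialisation by quantile split (sort, cut into K equal
  blocks, use block means/SDs/proportions) — no random restarts needed for
  unimodal-by-component 1-D data, though seeded restarts are available;
* convergence at relative log-likelihood change < 1e-8, max 500
  iterations; variance floored at 1e-6 words² (degenerate components are
  clamped with a warning);
* components reported in ascending-σ order, so cluster indices are stable:
  index 0 is always the tight (ADR-enriched) cluster;
* observations are assigned by maximum weighted density (MAP); ties break
  to the lowest index.

Assignment regions are computed exactly, not by scanning: the boundaries
are the real roots of the pairwise quadratics
`log π_i φ_i(x) = log π_j φ_j(x)`; segments between consecutive candidate
boundaries are attributed by evaluating the MAP winner at the midpoint and
merged. Intervals are rounded to whole words for reporting only.

Fitting is unsupervised; gold labels enter only at evaluation. An
alternative reading of the original design — per-class Gaussians fitted on
labelled data — is deliberately not the default, because it makes the
filter circular (it would need the labels it is meant to produce).
Model selection over K is out of scope; K = 3 is part of the method.

## Filtering and scoring

A filtering strategy removes whole clusters. Because the filter's positive
class is the *removed non-ADR pair* (the point is to discard noise, not to
detect ADRs), precision and recall invert the usual convention:

```
precision = removed non-ADR / removed        recall = reduction
          = removed non-ADR / all non-ADR
```

Strategy "1" removes the middle and wide clusters (high reduction at high
precision); strategy "2" removes only the wide cluster (nearly lossless
for ADRs — its complement keeps ~98% of true ADRs — but lower reduction).
Percentages are printed rounded half-up at 1–2 decimals; full-precision
rates are always carried alongside, and tables recomputed from raw pair
records must equal the aggregated counts.

The packaged reference table (1654 pairs: 732/157, 412/29, 321/3 in
ascending-σ cluster order) reproduces the published behaviour of the
method: strategy 1 at 95.8% precision / 50.03% reduction, strategy 2 at
99.07% / 21.91%. Note the overall ADR prevalence 189/1654 = 11.4268% —
sources print it truncated to 11.42.

## Synthetic study conditions

The corpus the method was developed on (French health-forum posts) and its
licensed terminology cannot be redistributed, so the generator in
`adrfilter.simulate` defines the study conditions every test runs under.
Defaults, chosen once to emulate the original corpus summary statistics:

| parameter | default | emulates |
|---|---|---|
| `n_messages` | 648 | corpus size |
| `adr_prevalence` | 0.114 | ≈11.4% of pairs are ADRs |
| `adr_distance_law` | N(+10, 30) words | tight, slightly-after concentration of ADRs |
| `other_distance_law` | 0.6·N(0, 80) + 0.4·N(0, 450) | wide, heavy-tailed incidental co-occurrence |
| `message_length_law` | logN(4.6, 1.1) tokens | median ≈ 100 words, tail past 1000 |
| `no_disorder_fraction` | 0.41 | messages with a drug but no disorder term |
| `disorders_per_message` | Poisson mean 3.3 (+1) | ≈4.3 disorders per disorder-bearing message |
| `duplicate_drug_rate` | 0.2 | far echo of the drug name, exercising dedup |
| `misspelling_rate` | 0 | colloquial spelling noise (opt-in) |

Messages are filler tokens (a closed vocabulary verified disjoint, under
stems and fuzzy keys, from the lexicon and drug names) with one drug and
the disorders planted at offsets drawn from the class-conditional law; the
planted offset is recorded, making the generator an exact oracle: with
misspellings off, the pipeline must recover every planted distance, and
does. The optional echo occurrence of the drug is placed strictly farther
from every disorder than the planted occurrence, so minimum-distance
deduplication is exercised without disturbing the truth.

What the generator does **not** emulate: real syntax and discourse
(fillers are i.i.d. tokens), negation and speculation, terms the lexicon
lacks, boundary ambiguity between overlapping disorders, and any
correlation between message length and ADR content. Passing tests
therefore show the machinery is correct under the stated distributional
conditions, not that the filter achieves any particular precision on real
forum data.

Misspelling perturbations: consonant doubling and post-first-vowel drops
preserve the fuzzy key by construction (planted drugs remain findable);
adjacent-letter swaps may break it — note that a vowel–consonant swap is
erased by vowel stripping, so only consonant–consonant swaps actually
defeat the key. This is the documented limit of fuzzy matching.

## Known limitations

* The distance signal is weakest exactly where it matters most: near the
  drug name, ADRs and indications mix (the tight cluster is only ~18% ADR
  in the reference table).
* Statistical limits on parameter recovery: with 5000 observations and a
  σ=300 component of weight 0.2, the component mean's sampling error alone
  is ±9–10 words; recovery beyond that is impossible for any fitter, and a
  reference EM implementation shows the same deviations.
* Distances assume a single flat token stream; sentence and thread
  structure are ignored, and very short texts (microblogs) do not provide
  enough distance spread for the mixture to separate.
* The light stemmer under- and over-stems at the margins like every
  suffix stripper; matching quality on real French forum text depends on
  the lexicon carrying the lay variants (accented and otherwise) users
  actually write.

## Problem sizes used in the test suite

Unit and property tests run on messages of ≤ 50 tokens with exhaustive
oracles; mixture tests use 5000-point samples (20 seeds for the recovery
study); pipeline round trips run on generated corpora of 80–800 messages,
and the acceptance checks use the full 648-message default corpus
(~1600–2200 pairs). These sizes were chosen so every oracle can be
exhaustive where it needs to be while the whole suite stays fast.
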