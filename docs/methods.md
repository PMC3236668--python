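# Methods

This note documents the procedures implemented in `clinicolloc`, the
parameters that matter, the numerical conventions, and what the synthetic
corpus does and does not establish about behaviour on real data.

## The retrieval problem

A practitioner mailing list produces thousands of informal messages per
year, most of them off-topic for any given research question. The package
supports a two-stage strategy: first *discover* the clinical vocabulary of
the community bottom-up (token filtering, PMI collocations), let domain
experts classify the discovered phrases into categories, then *retrieve*
messages by turning the classified phrases and keywords into proximity
search strings over lightly cleaned text. Discovery runs on heavily
filtered tokens; retrieval deliberately runs on cleaned-but-unfiltered
text, because the words of a discovered phrase may be separated, reordered
or re-inflected in the original messages.

## Cleaning

Noise classes handled: quoted reply lines (leading `>` or `|`), reply
attributions ("On … wrote:"), forwarded-message blocks (marker line to end
of message), signature blocks (a `--` delimiter line to end, plus a
heuristic that removes a trailing block of ≤ 6 lines containing a phone
number, URL or professional credential), virus/spam notices, mail-client
notices, advertisements/footers (line-level), and bracketed image
placeholders (span-level). The exact patterns ship in an editable file
(`data/noise_patterns.txt`); each group can be disabled independently,
since no two archives share identical boilerplate.

Numerical/behavioural conventions:

- **Fixpoint application.** Rules can interact (deleting an image
  placeholder can expose a quoted-looking line), so the stripping core is
  iterated until the text stabilises. This makes `clean(clean(x)) ==
  clean(x)` a hard guarantee, which the property suite checks on random
  text.
- **Deidentification** replaces whole-word, case-insensitive occurrences
  of listed names/places with the two-letter placeholder `xx`. The
  placeholder is deliberately shorter than the 4-character token floor, so
  deidentification can never inject vocabulary into the analysis.
- **Whitespace** is normalised last: runs of spaces/tabs collapse to one
  space, blank-line runs to one blank line. Character offsets used
  downstream (token offsets, match spans, gap measurements) always refer
  to this normalised text.

## Token filtering

Stage 1 keeps lowercase maximal runs of Unicode letters with length ≥ 4
(digits and hyphens split runs: "x-ray" contributes no token) and removes
the 127 stopwords of the classic English list (replaceable by file).
Stage 2 keeps tokens with length ≥ 6 **and** corpus-wide frequency ≥ 8,
computed over the merged date-sorted corpus rather than per message. The
thresholds are the strict readings of the "> 3", "> 5", "> 7" filter
convention; both are exposed as parameters. The stage-2 type set is the
community vocabulary and the only input to collocation discovery.

## Collocations

Bigram/trigram windows are contiguous token pairs/triples. By default
windows do not cross message boundaries (`span_messages=False`); the flag
exists because counting over one concatenated file is the other defensible
convention, and linguistically spurious cross-message windows are the
price of it. PMI uses unigram probabilities over the content-stream total
*T* and window probabilities over the window total *W*; the trigram
denominator is the product of the three unigram probabilities. Candidates
need count ≥ 2 (PMI at count 1 maximally rewards hapax noise). Ranking is
PMI descending, count descending, then lexicographic — fully
deterministic. Headline n-gram totals are reported both as distinct types
and as window counts, since the two readings differ.

The PMI implementation is verified in the test suite against an
independent brute-force enumeration of windows on streams of ≤ 200
tokens, plus algebraic properties (independence limit 0, scale
invariance, marginal symmetry).

## Keywords and equivalence

A keyword is a word with ≥ 2 occurrences across all word slots of the
selected collocations. Occurrences are counted per equivalence class:
user-declared classes (for closely related words such as
cardiac/myocardial, which no mechanical rule can infer) take precedence; a
switchable suffix rule additionally folds simple plurals (−s, −es); every
other token is a singleton. A class emits its lexicographically first
observed member. With equivalences disabled the rule reduces to exact
multiset counting, which is the oracle the tests compare against.

## Proximity retrieval

A phrase query is the *set* of a phrase's 2–3 words with a gap bound
(default 100 characters, chosen conservatively above the sub-80 gaps
observed when probing discovered phrases against real messages). A
message matches when one occurrence of each word can be chosen, in text
order, with every consecutive inclusive gap ≤ the bound. Two gap measures
are kept on each match: the inclusive character count between the end of
one matched word and the start of the next (this drives matching), and a
secondary count excluding whitespace and punctuation (the convention under
which observed gaps ranged up to 75).

Matching details that required a decision:

- **Whole-word only, no stemming**: "plaques" does not match keyword
  "plaque"; variants are separate search strings, as in the source
  classification scheme.
- **Instances** are leftmost non-overlapping windows; each instance
  consumes its matched occurrences. Within a window the chain of
  occurrences is found by exhaustive search with gap pruning (word sets
  have ≤ 3 members, so this is cheap) — a greedy earliest-occurrence scan
  can miss valid chains through a later duplicate of a middle word.
- **Keyword concatenation**: keywords adjacent inside a phrase also
  produce an ordered concatenated search string ("mutans streptococci"),
  matched with any non-letter run between the words.
- The retrieval report's totals row sums instance counts but unions
  message sets — messages matching several categories are delivered to
  each category folder yet counted once in aggregates.

## Synthetic corpora

`SimConfig` defaults are the emulated study conditions: 14,576 messages,
a 450-subscriber list with 245 posting authors, spanning 2008-04-18 to
2009-05-28, with the top 5% of subscribers contributing 50% of messages.
Participation weights follow a Zipf law 1/rank^s; the exponent is found by
bisection so the configured top-share is hit after a one-message floor per
posting author (largest-remainder apportionment). The realized top-5%
share lands within a fraction of a percentage point of the target;
the acceptance tolerance is ±3 points.

Bodies are filler prose from a word list *disjoint* from the planted
clinical vocabulary, so the manifest is exact ground truth. Phrase
plantings realise a requested inter-word gap exactly (single-spaced junk
text of the right length, immune to whitespace normalisation); a
requested gap of 0 is emitted as a single space, because a literal
zero-character gap would fuse the two words into one letter run and make
whole-word matching impossible. Plans may deliberately include gaps above
the retrieval bound and plantings inside quoted blocks; the manifest marks
both as non-retrievable, which is how the boundary and cleaning tests get
their negatives. Noise blocks are drawn verbatim from the cleaner's own
pattern families, closing the loop on the cleaning tests.

What passing tests therefore show: the pipeline retrieves exactly the
plantings it should on corpora whose noise matches the shipped patterns
and whose filler cannot collide with query vocabulary. What they do not
show: robustness to noise families absent from the pattern file,
misspellings and inflection of real clinical text, or accidental
proximity collisions in natural prose — on real data precision below 1.0
is expected and the pattern file will need per-archive additions.

## Reporting conventions

Percentages round half-up (not banker's) at the printed number of
decimals, matching every published-style table value the suite checks
(36.32, 19.02, 2.02, 54.4, 2.1, …). The total-subscriber count used for
participation shares is config metadata, not derivable from a corpus,
because passive subscribers post nothing. Date ties in ingestion break by
original mailbox order; messages without a parseable date go to the corpus
end, flagged, rather than being dropped.

## Problem sizes

The default test and acceptance runs use corpora of 60–2,000 messages for
behavioural checks and one study-scale corpus (14,576 messages) for the
participation calibration; the whole suite plus the acceptance script
completes in a few seconds, and the quantities measured are stable across
seeds (calibration is deterministic given the configuration; recall and
precision are exact by construction).
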