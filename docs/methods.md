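# Methods

This note documents the models, conventions and design choices behind
`narraquery`: what exactly the preprocessing, matching, classification and
evaluation steps compute, and what the synthetic data generator does and
does not emulate.

## Corpus model and preprocessing

A corpus is a directory of UTF-8 plain-text files, one story per file,
edited upstream to the convention *capital letter at the start of each
sentence, period at the end*; illegible words are replaced by the
placeholder `xxx`.

**Sentence segmentation.** A sentence ends at a period followed by
whitespace or end of text. Only `.` terminates sentences (the editorial
convention normalizes everything to periods), and a period between two
digits (`3.5`) never splits. A trailing fragment without a period becomes
a final sentence; spans with no word token are dropped rather than
emitted as empty sentences.

**Tokenization.** Word tokens are maximal alphabetic runs; an apostrophe
flanked by letters stays inside its token (`didn't` is one token). Digit
runs and punctuation are kept as non-word tokens so offsets stay
recoverable, but every count and matching rule sees word tokens only.
Hyphenated compounds therefore split (`wi-fi` → two tokens); the lexicon
lists the parts where that matters. All comparison is on the lowercased
form, so sentence-initial capitals never defeat a lookup.

**The `xxx` placeholder** counts as a word token — it stands for a real
word — but can never satisfy any frame constituent or lexicon entry.
Whether such placeholders belong in token counts is a genuine judgement
call; counting them (and excluding numerals) is this package's explicit
choice, applied consistently everywhere.

**Summary statistics** report, per unit (sentences, wordform tokens,
wordform types), the corpus total, the mean per text, and per-text
min/max. Every mean, including the type mean, is the corpus total divided
by the number of texts — for types this is a deliberate convention
(distinct types corpus-wide over n texts), not the average of per-text
type counts, which the per-text min/max columns cover instead. Means are
rounded to two decimals.

## Lexicon

Word groups are stored one per comma-separated file; the filename is the
group name, and an optional `#semantic=…,syntactic=…` first line carries
labels. Members are lowercased, trimmed and deduplicated; an empty group
file is an error. Membership is non-exclusive by design, and two groups
may be independent, overlapping, equal, or subordinate/superordinate
(proper subset/superset) — `group_relation` classifies the pair by plain
set arithmetic.

Frequency lists order forms by descending token count, ties broken
alphabetically, so output is deterministic. The function-word filter
keeps forms of at least `min_len` characters (default 4, counting
apostrophes): in English, closed-class words are predominantly 1–3
letters, so the filter removes most of them cheaply without a stopword
list.

The shipped lexicon (11 groups: physician and non-physician personnel
nouns, communication nouns/verbs, difficulty nouns, illness nouns,
facility nouns, event nouns with a negative-event subgroup, and a
`medical` adjective/noun overlap pair) is an illustrative reconstruction
for testing and demonstration — it makes no claim to reproduce any
specific study's appendix.

## Frame matching

A frame is parsed from a one-line expression: quoted literals, `G:name`
group references, `++` (adjacent) and `+` (within-sentence) operators,
whitespace-insensitive. Malformed expressions (dangling or stacked
operators, empty or bare constituents) raise a parse error carrying the
character position.

Matching semantics, in full:

* The search space is the sentence's **word tokens**. Punctuation is
  transparent: a comma between two words does not break their adjacency.
  The paper trail for narrative text is unedited punctuation, and a
  brittle adjacency rule would silently lose matches; transparency is the
  robust reading and is applied uniformly.
* `++` requires consecutive word-token positions; `+` requires strictly
  increasing positions within the same sentence with any amount of
  intervening material. A match never crosses a sentence boundary.
* A literal matches a token whose lowercased form equals it; a group
  reference matches a token whose form is a member. `xxx` matches
  nothing. There are no part-of-speech checks at match time — syntactic
  class lives extensionally in group membership.
* **All** matches are returned in left-to-right order of position tuples,
  not just the first: classification needs only existence, but the audit
  trail needs every supporting span.
* A frame referencing a group absent from the active lexicon is a
  configuration error, raised rather than treated as a non-match.

The matcher enumerates candidate positions per constituent and extends
partial assignments left to right; on the short sentences of this domain
(≤ ~40 words) this is effectively instantaneous, and its output is
verified against a brute-force enumeration oracle in the test suite.

## Classification and summaries

A query = id + question text + non-empty frame set. A document scores 1
for a query iff any frame matches anywhere in it. Results are a document
× query 0/1 matrix plus, for every positive cell, the list of supporting
matches. Summary percentages are count/n·100 rounded **half-up** to one
decimal, matching how such tables are conventionally printed; the same
rounding is used for agreement percentages.

## Evaluation against human readers

Two readers' yes/no answers per text are condensed to a consensus rank:
1 (both yes), 0.5 (split), 0 (both no) — arithmetically `(r1 + r2) / 2`.
Raw inter-rater agreement is the percentage of texts with identical
answers.

Spearman ρ between the automatic 0/1 vector and the 0/0.5/1 consensus
vector uses **midranks** (average ranks for ties) followed by the
product-moment correlation of the ranks. A tie policy is not optional
here: both vectors are massively tied, and midranks are the standard
choice. On tie-free data this reduces to the classical
1 − 6Σd²/(n(n²−1)), which the tests cross-check.

The two-sided p-value uses the *t* approximation
t = ρ√((n−2)/(1−ρ²)) with n−2 degrees of freedom for n ≥ 10, and an
exact enumeration over all n! permutations of one rank vector below
that. A constant vector (a query nobody ever answers yes to) leaves ρ
undefined; the result is explicitly flagged rather than silently NaN.
Percentages are reported to 1 decimal and ρ to 3, as such tables are
printed.

## Synthetic data generator

The generator exists so that every module is testable without any real
narrative data. It emulates the *shape* of a handwritten story
collection and the *presence* of query-relevant statements:

* defaults of 104 texts and 3–23 sentences per text, the shape of a
  typical collection of this kind;
* default per-query prevalences (Q1 0.394, Q2 0.808, Q3a 0.769,
  Q3b 0.577, Q4 0.115) equal to the mean positive rates two human
  readers reported for the five default questions;
* positives receive at least one sentence realized directly from one of
  the query's frames, with group references instantiated by sampled
  members and within-sentence gaps filled with neutral connectives;
* every sentence — planted, filler or distractor — is screened against
  *all* queries' frames, so a planted sentence matches exactly its own
  query and fillers match none; label purity holds by construction;
* optional distractor pairs split query vocabulary across a sentence
  boundary, exercising the within-sentence constraint;
* simulated readers flip each true label independently with probability
  p (default 0.1), giving expected raw agreement 100·((1−p)² + p²);
* everything is driven by one `numpy` generator seed; a fixed seed gives
  byte-identical corpora.

What it does **not** emulate: second-language grammar and spelling
variation, discourse structure, backgrounded references to personnel
("they", "the lady"), topic drift, or vocabulary outside the shipped
lexicon. Passing the end-to-end recovery tests therefore demonstrates
that the machinery is faithful to its own rules, not that the shipped
illustrative frames would reach any particular accuracy on real
narratives — on real data, rule inventories must be developed against
the collection itself, which is exactly the workflow the library
supports (frequency list → groups → frames → classify → benchmark).

## Problem sizes and numerical choices

The test suite and the acceptance script run at the scale the method was
designed for: corpora of 20–500 texts, the randomized matcher-vs-oracle
check at 1,000 sentence/frame pairs (sentences ≤ 15 words, frames ≤ 4
constituents), reader-simulation checks at n = 1,000 labels, and exact
permutation p-values up to n = 8 (enumeration is vectorized; 8! = 40,320
orderings). Determinism: every stochastic component takes an explicit
seed; sorting breaks all ordering ties (filenames for documents,
count-then-alphabet for frequency lists, position tuples for matches).

## Known limitations

* Frames have no negation scoping, wildcards, bounded gaps or
  morphological patterns; what a frame cannot say, a query cannot ask.
* The length-4 function-word filter also drops short content words
  ("flu" survives only because lexicon curation is manual and may
  re-add any form).
* Agreement is raw proportion, not chance-corrected; with two readers
  and skewed prevalence, high agreement can overstate reliability.
* Exactly two readers are supported, mirroring the benchmark protocol.
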