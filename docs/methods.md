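# Methods

## Model and procedure

The package scores the association between a key phrase and each of a
list of target terms by document-level co-occurrence in a corpus of
dated abstracts. For each term three counts are taken over the
eligible corpus of size `N`: `T` documents containing the term, `K`
containing the key phrase, and `a` containing both. Counting is
document-level: any number of matches inside one abstract contributes
one document. The 2×2 table `(a, T−a, K−a, N−T−K+a)` is tested with a
one-sided Fisher's exact test; the p-value is the upper-tail
hypergeometric probability of an overlap at least as large as `a` with
both margins fixed. Terms with `p` strictly below the threshold
(default 10⁻⁵, a list-size heuristic rather than a corrected
significance level — no multiple-testing adjustment is applied, by
design) are ranked by the proportion `a/T` descending.

The assumptions are those of string-matching co-occurrence mining: a
term is whatever its exact token sequence matches (no synonyms, no
stemming, no disambiguation of gene symbols from English words), and
co-occurrence is taken as evidence of association regardless of the
sentence-level relation (no negation handling). These are deliberate
scope boundaries, not oversights; they trade recall per term for the
ability to query any free-text term list.

## Text processing and the index

Tokenization is fully specified rather than delegated to a search
engine's analyzer: text is lowercased and split at every maximal run
of non-alphanumeric characters (underscore included as a split point).
A hyphenated symbol such as `NKX2-5` therefore matches as the
two-token phrase `["nkx2", "5"]`. Multi-token phrases match only
consecutive, in-order tokens; bag-of-words co-location within a
document is not a phrase match. Co-occurrence is the intersection of
the two phrase-matching document sets.

The inverted index stores token positions (needed only for phrase
matching) and per-document publication years. Censoring at year `Y`
restricts every count — `T`, `K`, `a` and `N` alike — to documents
with a known year ≤ `Y`; documents whose year could not be resolved
are included in uncensored queries but excluded from censored ones,
the only choice consistent with a timeline cutoff. Censoring is
inclusive ("through December 31 of year Y").

PubMed citation XML is consumed streaming, one article in memory at a
time; only the PMID, PubDate and AbstractText fields are read. A
4-digit `Year` field wins; otherwise the first 4-digit run of
`MedlineDate` is used; otherwise the year is unknown. Structured
abstracts are joined section-by-section with single spaces, labels
discarded, preserving all tokens. Duplicate PMIDs (baseline/update
overlap) are collapsed last-record-wins with a logged count.
Citations without an abstract are excluded from indexing by default —
they can never match a phrase but would inflate `N` — with a
`--keep-empty-abstracts` flag to include them, since whether
abstract-less citations count toward corpus size is a modeling choice.

## Numerical choices

The Fisher tail is computed in log space from an incrementally cached
table of log-factorials and combined with `logsumexp`; this is exact
enough (≤10⁻¹² relative error against rational arithmetic, verified
exhaustively for all tables with `N` ≤ 60) and does not overflow at
`N` ~ 3×10⁷. Margins are swapped internally so `T ≤ K`, making the
test's margin symmetry exact in floating point. A tail that covers
the whole support returns exactly 1.0. The test is the standard
(non-mid-p) one-sided test; the enrichment (upper-tail) direction is
the default and a depletion (lower-tail) mode is exposed for novelty-
style queries. Extremely strong associations on very large corpora
can underflow to p = 0 in double precision; ranking is unaffected
because order among passing terms is decided by the ratio.

Filtering is strict (`p < threshold`). Ties in the ratio ranking are
broken by p ascending, then case-folded term order, making every
output byte-deterministic. Terms whose margin is zero (never seen in
the corpus, or tokenizing to nothing) are retained in the full results
list with `p = 1`, ratio 0 and a note — the full downloadable list
never drops rows silently.

## Synthetic corpora

The generator emulates the statistical skeleton of a literature
corpus: each document independently contains the key phrase with
probability `q`, each background term with its own marginal
probability `p`, and each planted term with conditional probability
`min(1, λp)` given the key phrase, where the lift `λ ≥ 1` controls
the strength of the planted association. The off-key conditional is
chosen to preserve the marginal `p` whenever feasible (clipped at 0
otherwise, with the infeasible-lift case warned about and clipped at
1), so expected contingency cells have closed forms —
`E[a] = Nq·min(1, λp)`, `E[T] = Np` in the feasible regime — and
empirical counts can be asserted within a few binomial standard
errors. Publication years are uniform over an inclusive range;
neutral filler tokens from a disjoint `qfiller…` vocabulary pad each
abstract so phrase matching is exercised without accidental
collisions. Lift is parameterized as a conditional-probability
multiplier rather than an odds ratio precisely because it yields
those closed forms.

Defaults represent a plausible desk-scale slice of a literature
corpus: a key phrase in ~10% of documents (as "cardiomyocyte"-like
topics are in their subfields), term document frequencies of a few
percent (typical of established gene symbols), 200 filler vocabulary
words with 20 filler tokens per document, years 2000–2010. What the
generator does *not* emulate — natural-language structure, citation
growth over time, field richness, correlated term families — bounds
what passing tests show: they validate the counting and inference
machinery exactly, and the ranking behavior under a known dependence
structure, but say nothing about tokenization adequacy or term
ambiguity on real abstracts.

## Evaluation utilities

`recall_at_k` and `max_landmark_rank` score a ranked list against a
landmark reference set using exact case-folded string equality. No
synonym bracketing is applied: published rankings list synonym pairs
(HNF1B and TCF2) as separate terms, and the reference recall
arithmetic (e.g. 4/7 for the hepatocyte task) is reproduced only
under exact matching. The packaged rediscovery fixtures are the top-20
transcription-factor rankings from censored queries over a PubMed-
scale index, shipped as plain text so the evaluation surface needs no
corpus; which hepatocyte landmarks matched (HNF4A, HNF1A, FOXA3,
FOXA2) is derived here from those fixtures. `pvalue_curve` emits the
sorted p-value list behind interactive threshold filtering, and
`search_space_size` the exact binomial coefficients (with a
2-significant-figure scientific rendering) that quantify the
experimental search space ranking is meant to prune.

## Problem sizes

The test suite and the acceptance script run everything at desk
scale, chosen so each check is statistically meaningful: exhaustive
Fisher-oracle equivalence over all ~3.3×10⁵ feasible tables with
`N ≤ 60`; index-versus-scan equivalence on 200 random corpora of up
to 500 documents; null calibration with 1,000 independent terms over
2,000 documents (the fraction with `p < α` must stay within 2
standard errors of `α`, and in practice sits well below it — the
discrete test is conservative); and planted recovery with five λ=8
terms among 200 nulls over 5,000 documents, 20 seeded replicates, in
which the planted terms are required to fill the top 5 in ≥95% of
replicates. Production-scale corpora (10⁷ documents) differ only in
the size of the postings lists, not in any code path.

## Known limitations

The in-memory index targets desk-scale corpora; a 3×10⁷-document
corpus needs an external index, which this package deliberately does
not ship. String matching limitations (synonyms, stemming, negation,
entity ambiguity) are inherited from the method. Year resolution uses
only the year component; month-level censoring at year boundaries is
not modeled.
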