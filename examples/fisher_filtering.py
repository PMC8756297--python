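"""The statistic itself: contingency tables, one-sided Fisher p-values
and the sorted p-value curve behind threshold filtering.

Walks one (term, key phrase) pair through the three document counts,
shows how the p-value responds to the overlap, and renders the
search-space combinatorics that motivate ranking in the first place.
"""

from kinderminer import (
    fisher_one_sided,
    make_contingency,
    render_scientific,
    search_space_size,
)

# a corpus of 100,000 abstracts: 500 mention the term, 2,000 the key
# phrase.  Under independence we expect 500 * 2000 / 100000 = 10 to
# mention both.
N, T, K = 100_000, 500, 2_000
print("overlap a   p (enrichment)")
for a in (10, 20, 40, 80):
    p = fisher_one_sided(make_contingency(a, T, K, N))
    print(f"{a:9d}   {p:.3e}")

# an overlap at its independence expectation gives p ~ 0.5; each
# doubling of the overlap drives the upper-tail probability down by
# orders of magnitude, which is what the 1e-5 filter acts on.

pairs = search_space_size(2000, 2)
triples = search_space_size(2000, 3)
print(
    f"\nchoosing 2 of ~2,000 candidate factors: {pairs:,} pairs "
    f"({render_scientific(pairs)}); 3: {triples:,} triples "
    f"({render_scientific(triples)})"
)
# experimental search at that scale is infeasible without
# prioritization — the reason to rank candidates by literature
# co-occurrence before going to the bench.
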