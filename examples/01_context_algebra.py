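"""Mutation-context algebra: subcontexts, complements, enumeration.

A mutation context {src>dst|pos, WORD} is a substitution at a fixed
position of a short word; its subcontexts are the same substitution seen
in every contiguous subword that still contains the site.
"""

from mutcontext import complement, enumerate_contexts, enumerate_pairs, parse_context, subcontexts

ctx = parse_context("C>T|2,ACG")
print(f"context            : {ctx}")
print(f"subcontexts        : {[str(s) for s in subcontexts(ctx)]}")
# Three subcontexts: the statistics compare the context against each.

print(f"reverse complement : {complement(ctx)}")
# Strand-unaware SNP data cannot tell a context from its complement, so
# results always come in complementary pairs.

n_ctx = len(enumerate_contexts(2, 4))
n_pairs = len(enumerate_pairs(2, 4))
print(f"2-4 bp contexts    : {n_ctx}")
print(f"(context, subcontext) pairs for lengths 2-4: {n_pairs}")
# 3744 contexts and 13728 pairs — the family over which the Bonferroni
# correction is applied.
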