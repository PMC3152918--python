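"""Combinatorial algebra of mutation contexts.

A *mutation context* couples a short nucleotide word with a point
substitution at a fixed position inside it, written ``{src>dst|pos, WORD}``
— e.g. ``{C>T|1,CG}`` is a C-to-T transition at the first position of the
dinucleotide CG (the classic hypermutable CpG site).  A *subcontext* is the
same substitution viewed inside a contiguous subword that still contains the
mutated position.  Contexts form a lattice under the subword relation; the
enrichment statistics in :mod:`mutcontext.stats` compare each context
against its subcontexts.

Positions are stored 0-based internally and rendered 1-based in the
canonical identifier ``SRC>DST|POS,WORD`` used throughout serialized
output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Iterator

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_CTX_RE = re.compile(
    r"^\s*\{?\s*([ACGT])\s*>\s*([ACGT])\s*\|\s*(\d+)\s*,\s*([ACGT]+)\s*\}?\s*$"
)


class ContextError(ValueError):
    """Raised for malformed mutation contexts or invalid length bounds."""


@dataclass(frozen=True, order=True)
class MutationContext:
    """A substitution ``src``>``dst`` at (0-based) ``pos`` of ``word``.

    Invariants enforced at construction: ``word[pos] == src``,
    ``src != dst``, ``0 <= pos < len(word)`` and ``word`` over ACGT.
    """

    word: str
    pos: int
    src: str
    dst: str

    def __post_init__(self) -> None:
        if not self.word or any(b not in BASES for b in self.word):
            raise ContextError(f"word must be a non-empty ACGT string: {self.word!r}")
        if not 0 <= self.pos < len(self.word):
            raise ContextError(f"pos {self.pos} outside word {self.word!r}")
        if self.src not in BASES or self.dst not in BASES:
            raise ContextError(f"invalid bases {self.src!r}>{self.dst!r}")
        if self.src == self.dst:
            raise ContextError(f"src and dst must differ, got {self.src!r}")
        if self.word[self.pos] != self.src:
            raise ContextError(
                f"word {self.word!r} does not carry {self.src!r} at position {self.pos}"
            )

    @property
    def length(self) -> int:
        return len(self.word)

    @property
    def pos1(self) -> int:
        """1-based position, as used in the canonical identifier."""
        return self.pos + 1

    @property
    def id(self) -> str:
        return f"{self.src}>{self.dst}|{self.pos1},{self.word}"

    @property
    def mutation_type(self) -> str:
        return f"{self.src}>{self.dst}"

    def __str__(self) -> str:
        return self.id

    @classmethod
    def parse(cls, text: str) -> "MutationContext":
        """Parse ``"C>T|1,CG"`` (whitespace and surrounding braces allowed)."""
        m = _CTX_RE.match(text)
        if m is None:
            raise ContextError(f"cannot parse context identifier {text!r}")
        src, dst, pos1, word = m.groups()
        return cls(word=word, pos=int(pos1) - 1, src=src, dst=dst)


def parse_context(text: str) -> MutationContext:
    """Alias for :meth:`MutationContext.parse`."""
    return MutationContext.parse(text)


def subcontexts(ctx: MutationContext) -> list[MutationContext]:
    """All strict contiguous subwords of ``ctx.word`` containing the site.

    For a word of length L with the mutation at 1-based position p there are
    exactly ``p*(L-p+1) - 1`` such subcontexts (every start <= pos combined
    with every end > pos, minus the full word itself).  A 1-letter context
    has none.  Discontiguous subwords are deliberately not considered.
    """
    out = []
    L = ctx.length
    for start in range(0, ctx.pos + 1):
        for end in range(ctx.pos + 1, L + 1):
            if start == 0 and end == L:
                continue
            out.append(
                MutationContext(
                    word=ctx.word[start:end],
                    pos=ctx.pos - start,
                    src=ctx.src,
                    dst=ctx.dst,
                )
            )
    return out


def complement(ctx: MutationContext) -> MutationContext:
    """The reverse-complement context on the opposite strand.

    ``{C>T|1,CG}`` pairs with ``{G>A|2,CG}``; strand-unaware SNP data cannot
    distinguish a context from its complement, so both are always reported.
    The operation is an involution.
    """
    rc = ctx.word.translate(_COMPLEMENT)[::-1]
    return MutationContext(
        word=rc,
        pos=ctx.length - 1 - ctx.pos,
        src=ctx.src.translate(_COMPLEMENT),
        dst=ctx.dst.translate(_COMPLEMENT),
    )


def _check_bounds(min_len: int, max_len: int) -> None:
    if not 1 <= min_len <= max_len:
        raise ContextError(f"invalid length bounds [{min_len}, {max_len}]")


def iter_contexts(min_len: int, max_len: int) -> Iterator[MutationContext]:
    _check_bounds(min_len, max_len)
    for L in range(min_len, max_len + 1):
        for letters in product(BASES, repeat=L):
            word = "".join(letters)
            for pos in range(L):
                src = word[pos]
                for dst in BASES:
                    if dst != src:
                        yield MutationContext(word=word, pos=pos, src=src, dst=dst)


def enumerate_contexts(min_len: int, max_len: int) -> list[MutationContext]:
    """Every valid context with word length in ``[min_len, max_len]``.

    The count for a single length L is ``3 * L * 4**L`` (word, position,
    and 3 possible target bases): 12, 96, 576, 3072 for L = 1..4.
    """
    return list(iter_contexts(min_len, max_len))


def enumerate_pairs(
    min_len: int, max_len: int
) -> list[tuple[MutationContext, MutationContext]]:
    """Every (context, subcontext) pair with the context length in range.

    Subcontext lengths may fall below ``min_len``.  For lengths 2–4 this is
    the 13728-pair family over which multiple-testing correction is applied.
    """
    return [
        (ctx, sub) for ctx in iter_contexts(min_len, max_len) for sub in subcontexts(ctx)
    ]


def n_subcontexts(length: int, pos1: int) -> int:
    """Closed-form subcontext count for word length and 1-based position."""
    return pos1 * (length - pos1 + 1) - 1
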