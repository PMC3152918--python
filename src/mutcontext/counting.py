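"""Tallies of mutations per context, and background word frequencies.

Each accepted mutation contributes one count to *every* context whose word
can be placed over its ancestralized window so that the mutated site falls
at the context's position: a record with a full ±(max_len-1) flank feeds
``sum(L for L in 1..max_len)`` contexts.

Word frequencies P_W estimate how often each word occurs regardless of
mutation.  Two sources are supported: the two 5 bp intervals at window
positions -10..-6 and +6..+10 (far enough from the site to be unaffected by
the context under test), or a whole-genome sliding count as a control.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contexts import BASES, MutationContext
from .records import MutationRecord

logger = logging.getLogger(__name__)

FLANK_INTERVALS = ((-10, -6), (6, 10))  # inclusive offsets from the site
FLANK_SOURCE = "flank-intervals"
GENOME_SOURCE = "whole-genome"

_ACGT = set(BASES)


class FrequencyError(ValueError):
    """Raised for unusable frequency configurations or empty inputs."""


@dataclass
class ContextCounts:
    """N{mut|pos,W} per context identifier."""

    counts: dict[str, int] = field(default_factory=dict)
    total_records: int = 0
    max_len: int = 4

    def get(self, ctx: MutationContext | str) -> int:
        key = ctx if isinstance(ctx, str) else ctx.id
        return self.counts.get(key, 0)


@dataclass
class WordFreqs:
    """Per-length word frequencies P_W; frequencies sum to 1 within each length."""

    freqs: dict[int, dict[str, float]]
    totals: dict[int, int]
    source: str

    def freq(self, word: str) -> float:
        return self.freqs.get(len(word), {}).get(word, 0.0)


def count_mutation_contexts(
    records: Iterable[MutationRecord], max_len: int = 4
) -> ContextCounts:
    """Count every (word, position) placement covering the mutated site.

    Records whose window is too short for a full max_len-1 flank on both
    sides are skipped (and logged); windows are the ancestralized sequence,
    so the word carries the pre-mutation base at the site.
    """
    counts: Counter = Counter()
    total = 0
    skipped = 0
    for rec in records:
        window = rec.window
        center = len(window) // 2
        if center < max_len - 1 or len(window) - center - 1 < max_len - 1:
            skipped += 1
            continue
        total += 1
        mut = f"{rec.ancestral}>{rec.derived}"
        for L in range(1, max_len + 1):
            for start in range(center - L + 1, center + 1):
                word = window[start : start + L]
                if any(c not in _ACGT for c in word):
                    continue
                counts[f"{mut}|{center - start + 1},{word}"] += 1
    if skipped:
        logger.warning("%d records skipped: window too short for max_len=%d", skipped, max_len)
    return ContextCounts(counts=dict(counts), total_records=total, max_len=max_len)


def flank_word_freqs(
    records: Iterable[MutationRecord], max_len: int = 4
) -> WordFreqs:
    """P_W from the two 5 bp intervals flanking each mutation's window.

    Placements must lie fully inside an interval, so each record yields
    ``2 * (6 - L)`` words of length L; lengths above 5 have no placements
    and are rejected as a configuration error.
    """
    if max_len > 5:
        raise FrequencyError(
            f"flank-interval frequencies support word lengths up to 5, got max_len={max_len}"
        )
    counters: dict[int, Counter] = {L: Counter() for L in range(1, max_len + 1)}
    n_records = 0
    for rec in records:
        window = rec.window
        center = len(window) // 2
        n_records += 1
        for lo, hi in FLANK_INTERVALS:
            seg = window[center + lo : center + hi + 1]
            if len(seg) != hi - lo + 1:
                continue
            for L in range(1, max_len + 1):
                for i in range(len(seg) - L + 1):
                    word = seg[i : i + L]
                    if all(c in _ACGT for c in word):
                        counters[L][word] += 1
    if n_records == 0 or not counters[1]:
        raise FrequencyError("no flank words counted; frequencies unusable")
    return _normalize(counters, FLANK_SOURCE)


def genome_word_freqs(
    genome: str | Path | Mapping[str, str] | Sequence[str], max_len: int = 4
) -> WordFreqs:
    """P_W from a sliding count over whole genome sequence(s).

    ``genome`` may be a FASTA path, a raw sequence string, or a mapping /
    sequence of sequences.  Windows containing non-ACGT characters are
    skipped.  Implemented with vectorized k-mer codes so multi-megabase
    genomes count in seconds.
    """
    looks_like_path = (
        isinstance(genome, (str, Path))
        and 0 < len(str(genome)) < 4096
        and Path(str(genome)).is_file()
    )
    if looks_like_path:
        from .io import read_fasta

        seqs: list[str] = list(read_fasta(genome).values())
    elif isinstance(genome, str):
        seqs = [genome]
    elif isinstance(genome, Mapping):
        seqs = list(genome.values())
    else:
        seqs = list(genome)
    if not seqs or all(len(s) == 0 for s in seqs):
        raise FrequencyError("empty genome input")

    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i

    counters: dict[int, Counter] = {L: Counter() for L in range(1, max_len + 1)}
    for seq in seqs:
        codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        valid = codes >= 0
        n = len(codes)
        for L in range(1, max_len + 1):
            if n < L:
                continue
            kmer = np.zeros(n - L + 1, dtype=np.int64)
            ok = np.ones(n - L + 1, dtype=bool)
            for j in range(L):
                kmer = kmer * 4 + np.maximum(codes[j : n - L + 1 + j], 0)
                ok &= valid[j : n - L + 1 + j]
            binc = np.bincount(kmer[ok], minlength=4**L)
            nz = np.nonzero(binc)[0]
            words = _decode_words(nz, L)
            for w, c in zip(words, binc[nz]):
                counters[L][w] += int(c)
    if not counters[1]:
        raise FrequencyError("no ACGT content in genome input")
    return _normalize(counters, GENOME_SOURCE)


def _decode_words(codes: np.ndarray, L: int) -> list[str]:
    out = []
    for code in codes:
        letters = []
        for _ in range(L):
            letters.append(BASES[code % 4])
            code //= 4
        out.append("".join(reversed(letters)))
    return out


def _normalize(counters: dict[int, Counter], source: str) -> WordFreqs:
    freqs: dict[int, dict[str, float]] = {}
    totals: dict[int, int] = {}
    for L, counter in counters.items():
        total = sum(counter.values())
        totals[L] = total
        freqs[L] = (
            {w: c / total for w, c in counter.items()} if total else {}
        )
    return WordFreqs(freqs=freqs, totals=totals, source=source)
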