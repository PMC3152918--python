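"""SNP inclusion criteria and two-outgroup polarization.

A SNP enters the mutation set only if (1) it is biallelic, (2) one allele
matches the orthologous base in both chimpanzee and orangutan, (3) both
21 bp outgroup windows are present, (4) no window contains a gap or N,
(5) the human flanks differ from chimp by at most one substitution
(the SNP position itself not counted), (6) from orangutan by at most six,
and (7) the three bases on each side of the site are identical between
human and chimp.  Accepted SNPs are polarized by parsimony: the allele
shared with both outgroups is ancestral, the other derived.

Region exclusion (genes ± a flank, CpG islands) removes sites where
selection or island composition would distort the neutral-mutation signal.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .records import CENTER, WINDOW_LEN, FilterDecision, MutationRecord, SnpRecord

logger = logging.getLogger(__name__)

# reason codes, in evaluation order
NOT_BIALLELIC = "NOT_BIALLELIC"
NO_OUTGROUP_MATCH = "NO_OUTGROUP_MATCH"
UNALIGNED = "UNALIGNED"
GAP_OR_N = "GAP_OR_N"
CHIMP_MISMATCH_LIMIT = "CHIMP_MISMATCH_LIMIT"
ORANG_MISMATCH_LIMIT = "ORANG_MISMATCH_LIMIT"
NEAR_FLANK_MISMATCH = "NEAR_FLANK_MISMATCH"
REGION_EXCLUDED = "REGION_EXCLUDED"

CHIMP_MISMATCH_MAX = 1
ORANG_MISMATCH_MAX = 6
NEAR_FLANK_BP = 3
DEFAULT_GENE_FLANK_BP = 1000


class PolarizationError(RuntimeError):
    """Raised when polarize() is called on a record that fails the criteria."""


class RegionIndex:
    """Genomic intervals (0-based half-open) queryable by point position."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                continue
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path) -> "RegionIndex":
        from .io import read_bed

        return cls(read_bed(path))

    def contains(self, chrom: str, pos: int, pad: int = 0) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        if pad == 0:
            return bool(tree[pos])
        return bool(tree.overlap(pos - pad, pos + pad + 1))

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def exclude_by_region(
    snp: SnpRecord,
    genes: RegionIndex | None,
    cpg_islands: RegionIndex | None,
    flank_bp: int = DEFAULT_GENE_FLANK_BP,
) -> bool:
    """True iff the site lies in a gene, within ``flank_bp`` of one, or in a CpG island."""
    known = (genes.chroms if genes else set()) | (cpg_islands.chroms if cpg_islands else set())
    if known and snp.chrom not in known:
        logger.debug("chromosome %s absent from region files; not excluded", snp.chrom)
        return False
    if genes is not None and genes.contains(snp.chrom, snp.pos, pad=flank_bp):
        return True
    if cpg_islands is not None and cpg_islands.contains(snp.chrom, snp.pos):
        return True
    return False


def _flank_mismatches(a: str, b: str) -> int:
    """Mismatches over the 20 non-center positions of two 21-mers."""
    return sum(1 for i in range(WINDOW_LEN) if i != CENTER and a[i] != b[i])


def check_criteria(
    snp: SnpRecord,
    chimp_mismatch_max: int = CHIMP_MISMATCH_MAX,
    orang_mismatch_max: int = ORANG_MISMATCH_MAX,
    near_flank_bp: int = NEAR_FLANK_BP,
) -> FilterDecision:
    """Evaluate all inclusion criteria; returns every failed code, not the first."""
    codes: list[str] = []
    a1, a2 = snp.alleles
    biallelic = a1 != a2 and a1 in "ACGT" and a2 in "ACGT"
    if not biallelic:
        codes.append(NOT_BIALLELIC)

    windows = [snp.human_window, snp.chimp_window, snp.orang_window]
    aligned = snp.chimp_window is not None and snp.orang_window is not None
    if not aligned:
        codes.append(UNALIGNED)

    clean = True
    for w in windows:
        if w is None:
            continue
        if len(w) != WINDOW_LEN:
            logger.warning(
                "%s:%d malformed window length %d (expected %d)",
                snp.chrom, snp.pos, len(w), WINDOW_LEN,
            )
            clean = False
        elif "N" in w or "-" in w:
            clean = False
    if not clean:
        codes.append(GAP_OR_N)

    if aligned and clean:
        chimp = snp.chimp_window
        orang = snp.orang_window
        if biallelic:
            out_c, out_o = chimp[CENTER], orang[CENTER]
            if not (out_c == out_o and out_c in (a1, a2)):
                codes.append(NO_OUTGROUP_MATCH)
        if _flank_mismatches(snp.human_window, chimp) > chimp_mismatch_max:
            codes.append(CHIMP_MISMATCH_LIMIT)
        if _flank_mismatches(snp.human_window, orang) > orang_mismatch_max:
            codes.append(ORANG_MISMATCH_LIMIT)
        k = near_flank_bp
        if (
            snp.human_window[CENTER - k : CENTER] != chimp[CENTER - k : CENTER]
            or snp.human_window[CENTER + 1 : CENTER + 1 + k] != chimp[CENTER + 1 : CENTER + 1 + k]
        ):
            codes.append(NEAR_FLANK_MISMATCH)

    # stable, documented order
    order = [
        NOT_BIALLELIC, NO_OUTGROUP_MATCH, UNALIGNED, GAP_OR_N,
        CHIMP_MISMATCH_LIMIT, ORANG_MISMATCH_LIMIT, NEAR_FLANK_MISMATCH,
    ]
    codes.sort(key=order.index)
    return FilterDecision(accepted=not codes, reason_codes=tuple(codes))


def polarize(snp: SnpRecord) -> MutationRecord:
    """Ancestral = the allele matching both outgroup centers; window ancestralized."""
    decision = check_criteria(snp)
    if not decision.accepted:
        raise PolarizationError(
            f"{snp.chrom}:{snp.pos} failed criteria {decision.reason_codes}"
        )
    out = snp.chimp_window[CENTER]
    a1, a2 = snp.alleles
    ancestral, derived = (a1, a2) if out == a1 else (a2, a1)
    window = snp.human_window[:CENTER] + ancestral + snp.human_window[CENTER + 1 :]
    return MutationRecord(
        chrom=snp.chrom, pos=snp.pos, ancestral=ancestral, derived=derived, window=window
    )


def filter_snps(
    snps: Iterable[SnpRecord],
    genes: RegionIndex | None = None,
    cpg_islands: RegionIndex | None = None,
    flank_bp: int = DEFAULT_GENE_FLANK_BP,
    apply_region_filter: bool = True,
) -> tuple[list[MutationRecord], Counter]:
    """Run region exclusion + criteria over a SNP stream.

    Returns accepted, polarized mutations and a per-reason rejection tally;
    ``accepted + sum(rejections) == input count`` (rejected records are
    tallied once, under their first failed code).
    """
    accepted: list[MutationRecord] = []
    rejections: Counter = Counter()
    for snp in snps:
        if apply_region_filter and exclude_by_region(snp, genes, cpg_islands, flank_bp):
            rejections[REGION_EXCLUDED] += 1
            continue
        decision = check_criteria(snp)
        if not decision.accepted:
            rejections[decision.reason_codes[0]] += 1
            continue
        accepted.append(polarize(snp))
    return accepted, rejections
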