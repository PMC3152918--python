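"""Core record types shared by the filtering and counting stages."""

from __future__ import annotations

from dataclasses import dataclass

WINDOW_LEN = 21  # 10 bp flank + site + 10 bp flank
CENTER = WINDOW_LEN // 2
WINDOW_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class SnpRecord:
    """One human SNP with its ±10 bp window and orthologous ape windows.

    The center base of ``human_window`` encodes the site per the input
    convention (reference or either allele); ancestry inference never reads
    it — the alleles field and the outgroup window centers decide.
    """

    chrom: str
    pos: int
    alleles: tuple[str, str]
    human_window: str
    chimp_window: str | None = None
    orang_window: str | None = None

    def __post_init__(self) -> None:
        for name in ("human_window", "chimp_window", "orang_window"):
            w = getattr(self, name)
            if w is not None and any(c not in WINDOW_ALPHABET for c in w):
                raise ValueError(f"{name} contains characters outside ACGTN-: {w!r}")


@dataclass(frozen=True)
class MutationRecord:
    """An accepted, polarized mutation with its ancestralized window.

    ``window[CENTER]`` carries the ancestral base: the context of a mutation
    describes the sequence it arose in, not the sequence it produced.
    """

    chrom: str
    pos: int
    ancestral: str
    derived: str
    window: str

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles must differ")
        mid = len(self.window) // 2
        if self.window[mid] != self.ancestral:
            raise ValueError(
                f"window center {self.window[mid]!r} != ancestral {self.ancestral!r}"
            )


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the inclusion criteria for one SNP."""

    accepted: bool
    reason_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.accepted != (len(self.reason_codes) == 0):
            raise ValueError("accepted flag inconsistent with reason codes")
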