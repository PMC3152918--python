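"""Shared fixtures: hand-built SNP windows and small cached simulations."""

from __future__ import annotations

import pytest

from mutcontext import SimulationConfig, simulate
from mutcontext.records import CENTER, SnpRecord

# a fixed, gap-free 21-mer scaffold with C at the center
BASE_WINDOW = "ACGTACGTAC" + "C" + "GTACGTACGT"


def mutate_window(window: str, positions: dict[int, str]) -> str:
    chars = list(window)
    for i, b in positions.items():
        chars[i] = b
    return "".join(chars)


def make_snp(
    alleles=("C", "T"),
    human=BASE_WINDOW,
    chimp=BASE_WINDOW,
    orang=BASE_WINDOW,
    chrom="chr1",
    pos=1000,
) -> SnpRecord:
    return SnpRecord(
        chrom=chrom,
        pos=pos,
        alleles=tuple(alleles),
        human_window=human,
        chimp_window=chimp,
        orang_window=orang,
    )


@pytest.fixture
def clean_snp() -> SnpRecord:
    """Biallelic C/T SNP whose outgroups both carry C with identical flanks."""
    return make_snp()


@pytest.fixture(scope="session")
def cg_sim():
    """1 Mb simulation with a strand-symmetric 5-fold CpG C>T excess."""
    cfg = SimulationConfig(
        genome_length=1_000_000,
        planted_effects={"C>T|1,CG": 5.0},
        seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def null_sim_small():
    """300 kb simulation with no planted effects."""
    cfg = SimulationConfig(genome_length=300_000, seed=11)
    return simulate(cfg)
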