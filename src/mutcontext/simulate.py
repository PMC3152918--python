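"""Forward simulation of context-biased point mutation with known truth.

The generator draws an i.i.d. ancestral sequence, mutates the human lineage
with per-site, per-target probabilities that are a baseline rate times the
largest planted fold-excess whose context word matches the ancestral
sequence around the site, and emits each realized mutation as a biallelic
SNP record in exactly the real-data table format.  Outgroup windows are the
ancestral sequence with independent substitution noise at the configured
divergences (never at the site itself, so parsimony polarization stays
well-posed by construction).  A truth file records the planted multipliers
and every SNP's true ancestral allele, enabling parameter-recovery tests of
the whole pipeline.

Defaults emulate the study conditions at desk scale: a human-like base
composition (GC ≈ 41%), baseline per-site per-target mutation probability
1e-3, chimp-like (1%) and orangutan-like (3%) flank divergences, and
strand-symmetric effects (a planted context is mirrored to its reverse
complement, as strand-unaware data demands).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import contexts as ctxmod
from .contexts import BASES, MutationContext
from .records import CENTER, WINDOW_LEN, SnpRecord

HUMAN_LIKE_COMPOSITION = (0.295, 0.205, 0.205, 0.295)  # A, C, G, T

_B2C = {b: i for i, b in enumerate(BASES)}
# the 3 possible targets for each ancestral base code, in fixed order
_TARGETS = np.array([[c for c in range(4) if c != b] for b in range(4)], dtype=np.uint8)
_LETTERS = np.frombuffer("ACGT".encode(), dtype="S1")


class SimulationConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``planted_effects`` maps context identifiers (``"C>T|1,CG"``) to
    fold-excess multipliers applied to ``baseline_rate`` wherever the
    ancestral word matches; overlapping effects resolve to the largest
    multiplier (no compounding).
    """

    genome_length: int = 1_000_000
    base_composition: tuple[float, float, float, float] = HUMAN_LIKE_COMPOSITION
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    baseline_rate: float = 1e-3
    chimp_divergence: float = 0.01
    orang_divergence: float = 0.03
    strand_symmetric: bool = True
    seed: int = 0
    chrom: str = "chr1"
    gene_regions: Sequence[tuple[int, int]] = ()
    cpg_island_regions: Sequence[tuple[int, int]] = ()

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise SimulationConfigError("base composition must sum to 1")
        if any(not 0 <= p <= 1 for p in self.base_composition):
            raise SimulationConfigError("base composition outside [0,1]")
        for rate in (self.baseline_rate, self.chimp_divergence, self.orang_divergence):
            if not 0 <= rate <= 1:
                raise SimulationConfigError(f"probability {rate} outside [0,1]")
        if any(m <= 0 for m in self.planted_effects.values()):
            raise SimulationConfigError("multipliers must be positive")
        if self.genome_length < WINDOW_LEN:
            raise SimulationConfigError(
                f"genome shorter than one window ({WINDOW_LEN} bp)"
            )


@dataclass
class SimulationTruth:
    """Planted multipliers (after strand mirroring) and per-SNP ancestry."""

    multipliers: dict[str, float]
    ancestral_alleles: list[tuple[str, int, str]]  # (chrom, pos, base)


@dataclass
class SimulationResult:
    genome: dict[str, str]
    snps: list[SnpRecord]
    truth: SimulationTruth
    config: SimulationConfig


def resolve_effects(config: SimulationConfig) -> dict[str, float]:
    """Planted effects after optional strand mirroring.

    Under ``strand_symmetric`` each context is mirrored to its reverse
    complement; planting a context and its mirror with different
    multipliers is a configuration error.
    """
    resolved: dict[str, float] = {}

    def _add(ctx_id: str, mult: float) -> None:
        if ctx_id in resolved and resolved[ctx_id] != mult:
            raise SimulationConfigError(
                f"conflicting multipliers for {ctx_id}: "
                f"{resolved[ctx_id]} vs {mult}"
            )
        resolved[ctx_id] = mult

    for ctx_id, mult in config.planted_effects.items():
        ctx = MutationContext.parse(ctx_id)
        _add(ctx.id, float(mult))
        if config.strand_symmetric:
            _add(ctxmod.complement(ctx).id, float(mult))
    return resolved


def _match_sites(codes: np.ndarray, ctx: MutationContext) -> np.ndarray:
    """Genome positions whose surrounding word realizes ``ctx``."""
    word = np.array([_B2C[b] for b in ctx.word], dtype=np.uint8)
    L, n = len(word), len(codes)
    if n < L:
        return np.empty(0, dtype=np.int64)
    match = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        match &= codes[j : n - L + 1 + j] == word[j]
    return np.nonzero(match)[0] + ctx.pos


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the generator; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    codes = rng.choice(4, size=n, p=config.base_composition).astype(np.uint8)

    effects = resolve_effects(config)
    baseline = config.baseline_rate

    # per-target sparse multiplier maps: dst code -> (sorted sites, multipliers)
    extra: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    per_dst: dict[int, dict] = {}
    for ctx_id, mult in effects.items():
        ctx = MutationContext.parse(ctx_id)
        sites = _match_sites(codes, ctx)
        d = per_dst.setdefault(_B2C[ctx.dst], {})
        d.setdefault("sites", []).append(sites)
        d.setdefault("mults", []).append(np.full(sites.shape, mult))
    for dst, d in per_dst.items():
        sites = np.concatenate(d["sites"])
        mults = np.concatenate(d["mults"])
        order = np.argsort(sites, kind="stable")
        sites, mults = sites[order], mults[order]
        # largest multiplier wins where effects overlap at one (site, target)
        uniq, start = np.unique(sites, return_index=True)
        best = np.maximum.reduceat(mults, start)
        extra[dst] = (uniq, best)

    total = np.full(n, 3.0 * baseline, dtype=np.float64)
    for _, (sites, mults) in extra.items():
        total[sites] += baseline * (mults - 1.0)
    # only sites with a full ±10 bp window can become SNP records
    total[:CENTER] = 0.0
    total[n - CENTER :] = 0.0

    mut_sites = np.nonzero(rng.random(n) < total)[0]
    n_mut = len(mut_sites)

    src = codes[mut_sites]
    targets = _TARGETS[src]  # (n_mut, 3)
    weights = np.ones((n_mut, 3), dtype=np.float64)
    for dst, (sites, mults) in extra.items():
        idx = np.searchsorted(sites, mut_sites)
        idx_c = np.minimum(idx, len(sites) - 1) if len(sites) else idx
        hit = (len(sites) > 0) & (sites[idx_c] == mut_sites) if len(sites) else np.zeros(n_mut, bool)
        mvals = np.where(hit, mults[idx_c] if len(sites) else 1.0, 1.0)
        weights = np.where(targets == dst, weights * mvals[:, None], weights)
    probs = weights / weights.sum(axis=1, keepdims=True)
    u = rng.random(n_mut)
    choice = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    dst_codes = targets[np.arange(n_mut), choice]

    # windows from the ancestral sequence
    win_idx = mut_sites[:, None] + np.arange(-CENTER, CENTER + 1)[None, :]
    anc_windows = codes[win_idx]
    chimp = _diverge(anc_windows, config.chimp_divergence, rng)
    orang = _diverge(anc_windows, config.orang_divergence, rng)

    human_w = _decode(anc_windows)
    chimp_w = _decode(chimp)
    orang_w = _decode(orang)

    snps: list[SnpRecord] = []
    ancestry: list[tuple[str, int, str]] = []
    for i in range(n_mut):
        anc = BASES[src[i]]
        der = BASES[dst_codes[i]]
        alleles = tuple(sorted((anc, der)))
        snps.append(
            SnpRecord(
                chrom=config.chrom,
                pos=int(mut_sites[i]),
                alleles=alleles,  # type: ignore[arg-type]
                human_window=human_w[i],
                chimp_window=chimp_w[i],
                orang_window=orang_w[i],
            )
        )
        ancestry.append((config.chrom, int(mut_sites[i]), anc))

    genome_str = codes.view("|u1").tobytes().translate(
        bytes.maketrans(bytes(range(4)), b"ACGT")
    ).decode()
    return SimulationResult(
        genome={config.chrom: genome_str},
        snps=snps,
        truth=SimulationTruth(multipliers=effects, ancestral_alleles=ancestry),
        config=config,
    )


def _diverge(windows: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitutions at the non-center window positions."""
    out = windows.copy()
    mask = rng.random(windows.shape) < rate
    mask[:, CENTER] = False  # ancestral allele stays observable in outgroups
    shift = rng.integers(1, 4, size=windows.shape, dtype=np.uint8)
    out[mask] = (windows[mask] + shift[mask]) % 4
    return out


def _decode(code_rows: np.ndarray) -> list[str]:
    chars = _LETTERS[code_rows]
    return [row.tobytes().decode() for row in chars]


def emit_region_beds(
    config: SimulationConfig, outdir: str | Path
) -> tuple[Path, Path]:
    """Write the configured gene / CpG-island intervals as BED3 (default empty)."""
    from .io import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = outdir / "genes.bed"
    cpg = outdir / "cpg_islands.bed"
    write_bed([(config.chrom, s, e) for s, e in config.gene_regions], genes)
    write_bed([(config.chrom, s, e) for s, e in config.cpg_island_regions], cpg)
    return genes, cpg


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Single TSV with ``kind`` = effect (context_id, multiplier) or snp rows."""
    with Path(path).open("w") as fh:
        fh.write("kind\tcontext_id\tmultiplier\tchrom\tpos\tancestral\n")
        for ctx_id, mult in sorted(truth.multipliers.items()):
            fh.write(f"effect\t{ctx_id}\t{mult}\t.\t.\t.\n")
        for chrom, pos, anc in truth.ancestral_alleles:
            fh.write(f"snp\t.\t.\t{chrom}\t{pos}\t{anc}\n")


def read_truth(path: str | Path) -> SimulationTruth:
    multipliers: dict[str, float] = {}
    ancestry: list[tuple[str, int, str]] = []
    with Path(path).open() as fh:
        next(fh)
        for line in fh:
            kind, ctx_id, mult, chrom, pos, anc = line.rstrip("\n").split("\t")
            if kind == "effect":
                multipliers[ctx_id] = float(mult)
            else:
                ancestry.append((chrom, int(pos), anc))
    return SimulationTruth(multipliers=multipliers, ancestral_alleles=ancestry)


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Emit genome FASTA, SNP table, truth file and region BEDs."""
    from .io import write_fasta, write_snp_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "snps": outdir / "snps.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(result.genome, paths["genome"])
    write_snp_table(result.snps, paths["snps"])
    write_truth(result.truth, paths["truth"])
    genes, cpg = emit_region_beds(result.config, outdir)
    paths["genes"] = genes
    paths["cpg_islands"] = cpg
    return paths


def expected_observed_bias(multiplier: float, context_site_fraction: float) -> float:
    """The mutation bias the pipeline converges to for a planted multiplier.

    The bias denominator counts *all* mutations of the substitution type,
    including those inside the planted context, so the estimator is
    attenuated:  bias -> m / (1 + (m - 1) * f)  where f is the fraction of
    the 1-letter subcontext's sites that realize the full context word
    (for an i.i.d. genome, the product of the flanking-base probabilities).
    """
    m, f = multiplier, context_site_fraction
    if not 0 <= f <= 1:
        raise ValueError("context_site_fraction must be in [0,1]")
    return m / (1.0 + (m - 1.0) * f)


def context_site_fraction(ctx: MutationContext | str, base_composition) -> float:
    """f for :func:`expected_observed_bias` under an i.i.d. composition."""
    if isinstance(ctx, str):
        ctx = MutationContext.parse(ctx)
    comp = dict(zip(BASES, base_composition))
    f = 1.0
    for i, b in enumerate(ctx.word):
        if i != ctx.pos:
            f *= comp[b]
    return f
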