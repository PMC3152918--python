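"""Contrast, minimal contrast, mutation bias, and binomial significance.

For a context C = {mut|pos, W} and one of its subcontexts S = {mut|pos', W'}
the *contrast* is

    contrast(C, S) = ( N_C / N_S ) / ( P_W / P_W' )

the observed ratio of mutation counts divided by its expectation under
context-independent rates (P_W/P_W' is the probability that an occurrence of
W' extends to W).  Values above 1 mean excess mutation in the fuller
context.  Two summaries per context:

* *mutation bias* — contrast against the unique 1-letter subcontext: the
  total fold-excess relative to the genome-average rate of that substitution;
* *minimal contrast* — the contrast closest to 1 over all subcontexts: the
  excess not explained by any single subcontext.

Significance of each (context, subcontext) pair uses a binomial model:
conditional on the N_S subcontext mutations, each falls in the fuller
context with probability q = P_W/P_W' under the null, so N_C ~ Bin(N_S, q);
a one-sided tail in the observed direction is reported and compared against
a Bonferroni-controlled threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import contexts as ctxmod
from .contexts import MutationContext
from .counting import ContextCounts, WordFreqs

PAPER_ALPHA = 1e-15
# size of the (context, subcontext) family for word lengths 2-4
BONFERRONI_FAMILY_2_4 = 13728

Q_CLAMP_TOL = 1.25  # sampling noise may push P_W/P_W' slightly above 1


class UndefinedContrastError(ValueError):
    """A required count or frequency is zero/missing; no contrast defined."""


class FrequencyInconsistencyError(ValueError):
    """P_W/P_W' exceeds 1 beyond what sampling noise can explain."""


def contrast(n_ctx: int, n_sub: int, p_w: float, p_wsub: float) -> float:
    """(n_ctx/n_sub) / (p_w/p_wsub); requires positive denominators."""
    if n_sub <= 0 or p_w <= 0.0 or p_wsub <= 0.0:
        raise UndefinedContrastError(
            f"undefined contrast: n_sub={n_sub}, p_w={p_w}, p_wsub={p_wsub}"
        )
    return (n_ctx / n_sub) / (p_w / p_wsub)


def select_minimal(values: Sequence[float]) -> float:
    """The value minimizing |x - 1|; ties go to the value below 1."""
    if not values:
        raise ValueError("no contrast values to select from")
    return min(values, key=lambda v: (abs(v - 1.0), v))


def subcontext_contrasts(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFreqs
) -> list[tuple[MutationContext, float]]:
    """Contrast of ``ctx`` against each of its subcontexts."""
    subs = ctxmod.subcontexts(ctx)
    if not subs:
        raise UndefinedContrastError(f"{ctx.id} has no subcontexts")
    n_ctx = counts.get(ctx)
    p_w = freqs.freq(ctx.word)
    return [
        (sub, contrast(n_ctx, counts.get(sub), p_w, freqs.freq(sub.word)))
        for sub in subs
    ]


def minimal_contrast(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFreqs
) -> tuple[float, MutationContext]:
    """The subcontext contrast closest to 1, and the subcontext attaining it."""
    pairs = subcontext_contrasts(ctx, counts, freqs)
    value = select_minimal([v for _, v in pairs])
    for sub, v in pairs:
        if v == value:
            return value, sub
    raise AssertionError("unreachable")


def mutation_bias(
    ctx: MutationContext, counts: ContextCounts, freqs: WordFreqs
) -> float:
    """Contrast against the unique 1-letter subcontext."""
    if ctx.length == 1:
        raise UndefinedContrastError("a 1-letter context has no mutation bias")
    sub = MutationContext(word=ctx.src, pos=0, src=ctx.src, dst=ctx.dst)
    return contrast(
        counts.get(ctx), counts.get(sub), freqs.freq(ctx.word), freqs.freq(sub.word)
    )


def binomial_pvalue(
    n_ctx: int, n_sub: int, p_w: float, p_wsub: float, clamp_tol: float = Q_CLAMP_TOL
) -> float:
    """One-sided binomial tail for N_ctx ~ Bin(N_sub, P_W/P_W').

    Upper tail if the observed count meets or exceeds its expectation,
    lower tail otherwise.  q marginally above 1 (sampling noise in the two
    frequency estimates) is clamped to 1; beyond ``clamp_tol`` it is an
    inconsistency error.
    """
    if n_sub < 0 or n_ctx < 0 or n_ctx > n_sub:
        raise ValueError(f"require 0 <= n_ctx <= n_sub, got {n_ctx}, {n_sub}")
    if n_sub == 0:
        return 1.0
    if p_w <= 0.0 or p_wsub <= 0.0:
        raise UndefinedContrastError("zero frequency; p-value undefined")
    q = p_w / p_wsub
    if q > clamp_tol:
        raise FrequencyInconsistencyError(
            f"P_W/P_W' = {q:.4g} exceeds 1 beyond tolerance {clamp_tol}"
        )
    q = min(q, 1.0)
    if n_ctx >= n_sub * q:
        return float(sps.binom.sf(n_ctx - 1, n_sub, q))
    return float(sps.binom.cdf(n_ctx, n_sub, q))


def apply_bonferroni(
    pvalues: Iterable[float],
    alpha: float = PAPER_ALPHA,
    m: int | None = None,
    mode: str = "paper",
) -> np.ndarray:
    """Significance flags under Bonferroni control.

    ``paper`` mode flags p < alpha with the family size m documented as
    already incorporated in alpha (the study's convention: alpha = 1e-15,
    m = 13728).  ``corrected`` mode flags p < alpha/m.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if mode == "paper":
        return p < alpha
    if mode == "corrected":
        if not m or m < len(p):
            raise ValueError("corrected mode needs m >= number of tests")
        return p < alpha / m
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ContrastDiagnostics:
    """Contexts excluded from ranking, with the reason."""

    context: str
    reason: str


def contrast_table(
    counts: ContextCounts,
    freqs: WordFreqs,
    min_len: int = 2,
    max_len: int = 4,
    alpha: float = PAPER_ALPHA,
    mode: str = "paper",
) -> tuple[pd.DataFrame, list[ContrastDiagnostics]]:
    """Per-context summary table (the study's main output).

    One row per context of length in [min_len, max_len]: mutation bias,
    minimal contrast with its argmin subcontext, the binomial p-value of the
    minimal-contrast pair, and the Bonferroni significance flag.  Contexts
    with a zero count or missing frequency anywhere in their subcontext
    lattice are excluded from the table and listed in the diagnostics
    instead of being given sentinel values.
    """
    rows = []
    diagnostics: list[ContrastDiagnostics] = []
    m_family = len(ctxmod.enumerate_pairs(min_len, max_len))
    for ctx in ctxmod.iter_contexts(min_len, max_len):
        try:
            pairs = subcontext_contrasts(ctx, counts, freqs)
            bias = mutation_bias(ctx, counts, freqs)
        except UndefinedContrastError as exc:
            diagnostics.append(ContrastDiagnostics(ctx.id, str(exc)))
            continue
        if counts.get(ctx) == 0:
            diagnostics.append(ContrastDiagnostics(ctx.id, "zero context count"))
            continue
        mc = select_minimal([v for _, v in pairs])
        argmin = next(sub for sub, v in pairs if v == mc)
        try:
            pval = binomial_pvalue(
                counts.get(ctx),
                counts.get(argmin),
                freqs.freq(ctx.word),
                freqs.freq(argmin.word),
            )
        except FrequencyInconsistencyError as exc:
            diagnostics.append(ContrastDiagnostics(ctx.id, str(exc)))
            continue
        rows.append(
            {
                "context": ctx.id,
                "mutation_type": ctx.mutation_type,
                "complement": ctxmod.complement(ctx).id,
                "n_context": counts.get(ctx),
                "mutation_bias": bias,
                "minimal_contrast": mc,
                "argmin_subcontext": argmin.id,
                "n_subcontext_min": counts.get(argmin),
                "pvalue_min": pval,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["significant"] = apply_bonferroni(df["pvalue_min"], alpha, m_family, mode)
        df.attrs["bonferroni_m"] = m_family
        df.attrs["alpha"] = alpha
    return df, diagnostics


def pair_pvalues(
    counts: ContextCounts,
    freqs: WordFreqs,
    min_len: int = 2,
    max_len: int = 4,
) -> pd.DataFrame:
    """Binomial p-value for every (context, subcontext) pair with defined inputs."""
    rows = []
    for ctx, sub in ctxmod.enumerate_pairs(min_len, max_len):
        n_ctx, n_sub = counts.get(ctx), counts.get(sub)
        p_w, p_ws = freqs.freq(ctx.word), freqs.freq(sub.word)
        if n_sub == 0 or p_w <= 0 or p_ws <= 0:
            continue
        try:
            pval = binomial_pvalue(n_ctx, n_sub, p_w, p_ws)
        except FrequencyInconsistencyError:
            continue
        rows.append({"context": ctx.id, "subcontext": sub.id, "pvalue": pval})
    return pd.DataFrame(rows)


def bias_standard_error(n_ctx: int, n_sub: int, bias: float) -> float:
    """Delta-method SE of an estimated mutation bias.

    Treats N_ctx as binomial within the N_sub subcontext mutations:
    SE(bias) ≈ bias * sqrt((1 - N_ctx/N_sub) / N_ctx).
    """
    if n_ctx <= 0 or n_sub <= 0:
        return math.inf
    return bias * math.sqrt(max(1.0 - n_ctx / n_sub, 0.0) / n_ctx)
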