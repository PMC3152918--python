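"""Distribution summaries: scatter table, cluster labels, normal fit.

The scatter table places every ranked context in the (mutation bias,
minimal contrast) plane, where hypermutable contexts separate from the main
cloud.  Cluster labels are structural, derived from the subcontext lattice
(e.g. "contains a CpG transition subcontext"), not from the plotted
positions, so they are reproducible.  The bulk of minimal-contrast values is
summarized by a normal fit on a central range with a chi-square tail
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import contexts as ctxmod
from .contexts import MutationContext

CG_CORE_IDS = frozenset({"C>T|1,CG", "G>A|2,CG"})

LABEL_CG_CORE = "cg-core"
LABEL_CG_CONTAINING = "cg-containing"
LABEL_TOP_OUTLIER = "top-outlier"
LABEL_MAIN = "main"

DEFAULT_FIT_RANGE = (0.7, 1.2)
DEFAULT_TEST_RANGE = (1.2, 5.1)


def cg_cluster_membership(ctx: MutationContext | str) -> str:
    """Structural label w.r.t. the CpG-transition contexts.

    ``cg-core`` for {C>T|1,CG} / {G>A|2,CG} themselves, ``cg-containing``
    for any context having one of them as a subcontext, ``other`` otherwise.
    Invariant under complementation because the subcontext lattice commutes
    with reverse complement.
    """
    if isinstance(ctx, str):
        ctx = MutationContext.parse(ctx)
    if ctx.id in CG_CORE_IDS:
        return "cg-core"
    if any(sub.id in CG_CORE_IDS for sub in ctxmod.subcontexts(ctx)):
        return "cg-containing"
    return "other"


def scatter_table(
    results: pd.DataFrame,
    bias_threshold: float = 2.5,
    mc_threshold: float = 1.5,
) -> pd.DataFrame:
    """One row per ranked context: coordinates plus a cluster label.

    Labels, in precedence order: ``cg-core``, ``cg-containing``,
    ``top-outlier`` (both coordinates above the configurable thresholds),
    ``main``.
    """
    if results.empty:
        raise ValueError("no ranked contexts to tabulate")
    rows = []
    for row in results.itertuples():
        membership = cg_cluster_membership(row.context)
        if membership == "cg-core":
            label = LABEL_CG_CORE
        elif membership == "cg-containing":
            label = LABEL_CG_CONTAINING
        elif row.mutation_bias >= bias_threshold and row.minimal_contrast >= mc_threshold:
            label = LABEL_TOP_OUTLIER
        else:
            label = LABEL_MAIN
        rows.append(
            {
                "context": row.context,
                "complement": row.complement,
                "mutation_bias": row.mutation_bias,
                "minimal_contrast": row.minimal_contrast,
                "cluster": label,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DistributionSummary:
    """Histogram + normal approximation of a contrast distribution."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    n_values: int
    fit_range: tuple[float, float]
    test_range: tuple[float, float]
    n_fit: int
    mean: float
    sd: float
    chi2: float = np.nan
    dof: int = 0
    pvalue: float = np.nan
    test_observed: np.ndarray = field(default_factory=lambda: np.array([]))
    test_expected: np.ndarray = field(default_factory=lambda: np.array([]))


def histogram(values, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Plain histogram; counts always sum to the number of values."""
    v = np.asarray(values, dtype=float)
    counts, edges = np.histogram(v, bins=bins)
    return counts, edges


def fit_minimal_contrast_normal(
    values,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    test_range: tuple[float, float] = DEFAULT_TEST_RANGE,
    n_test_bins: int = 10,
    min_fit: int = 30,
    bins: int = 50,
) -> DistributionSummary:
    """Moment fit of a normal on ``fit_range`` + chi-square tail comparison.

    The mean and sd are plain sample moments of the values inside
    ``fit_range`` (no truncation correction — a deliberate, documented
    simplification).  The tail comparison is conditional on falling in the
    test range: observed counts in ``test_range`` bins (values beyond the
    range fold into the last bin) are compared against the fitted normal's
    conditional bin probabilities, scaled to the observed tail total, by a
    chi-square statistic; sparse bins (expected < 1) are pooled.  An empty
    tail therefore yields chi2 = 0 / p = 1, while values far beyond the
    fitted bulk register as a significant shape excess.
    """
    v = np.asarray(values, dtype=float)
    inside = v[(v >= fit_range[0]) & (v <= fit_range[1])]
    if inside.size < min_fit:
        raise ValueError(
            f"only {inside.size} values in fit range {fit_range}; need >= {min_fit}"
        )
    mean = float(np.mean(inside))
    sd = float(np.std(inside, ddof=1))
    counts, edges = histogram(v, bins=bins)

    dist = sps.norm(mean, sd)
    test_edges = np.linspace(test_range[0], test_range[1], n_test_bins + 1)
    observed = np.histogram(v, bins=test_edges)[0].astype(float)
    # everything beyond the test range folds into the last bin
    observed[-1] += float(np.sum(v > test_range[1]))
    n_tail = float(observed.sum())
    if n_tail == 0:
        chi2, dof, pvalue = 0.0, max(n_test_bins - 1, 1), 1.0
        expected = np.zeros_like(observed)
    else:
        bin_mass = np.diff(dist.cdf(test_edges))
        bin_mass[-1] += dist.sf(test_range[1])
        tail_mass = float(bin_mass.sum())
        if tail_mass <= 0:
            raise ValueError("fitted normal places no mass in the test range")
        expected = n_tail * bin_mass / tail_mass
        observed, expected = _pool_sparse(observed, expected, min_expected=1.0)
        # guard the denominator when observations land where the fitted
        # normal predicts essentially nothing
        expected = np.maximum(expected, 0.5)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        dof = max(len(observed) - 1, 1)
        pvalue = float(sps.chi2.sf(chi2, dof))
    return DistributionSummary(
        bin_edges=edges,
        bin_counts=counts,
        n_values=int(v.size),
        fit_range=fit_range,
        test_range=test_range,
        n_fit=int(inside.size),
        mean=mean,
        sd=sd,
        chi2=chi2,
        dof=dof,
        pvalue=pvalue,
        test_observed=observed,
        test_expected=expected,
    )


def _pool_sparse(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge bins with tiny expectation into their left neighbour."""
    obs, exp = [], []
    for o, e in zip(observed, expected):
        if exp and exp[-1] < min_expected:
            obs[-1] += o
            exp[-1] += e
        else:
            obs.append(float(o))
            exp.append(float(e))
    return np.asarray(obs), np.asarray(exp)
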