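"""Protein divergence of 1:1 orthologues, tercile binning, group
comparisons, and chi-square enrichment across functional categories.

Divergence is measured on the global protein alignment of each orthologue
pair: p_diff is the proportion of aligned columns that differ (gap columns
count as differences by default) and the protein distance is sqrt(p_diff).
Pairs under 30% identity are excluded — alignments that diverged are not
trustworthy enough to score. Pairs are binned Low / Intermediate / High
either at fixed cutoffs (<=0.058 / >=0.138) or at the empirical terciles of
the data, so a third of pairs lands in each bin by construction. Category
enrichment asks, per functional category with at least 15 members, whether
its bin counts depart from the expected proportions (chi-square, df=2) at a
Bonferroni-corrected alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chisquare, mannwhitneyu

from .aligners import PairwiseAlignment

MIN_IDENTITY = 0.30
PAPER_LOW_CUTOFF = 0.058  # Low: p_diff <= this
PAPER_HIGH_CUTOFF = 0.138  # High: p_diff >= this
MIN_CATEGORY_N = 15
FAMILY_ALPHA = 0.05
BINS = ("Low", "Intermediate", "High")


@dataclass(slots=True)
class DivergenceRecord:
    contig_id: str
    peptide_id: str
    p_diff: float
    dist: float  # sqrt(p_diff)
    identity: float  # fraction identical over non-gap columns
    bin: str = ""
    categories: set[str] = field(default_factory=set)


@dataclass(slots=True)
class EnrichmentResult:
    category: str
    n: int
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p: float
    alpha: float
    significant: bool
    direction: str  # bin with the largest standardized residual, signed


def protein_divergence(
    aln: PairwiseAlignment, count_gaps: bool = True
) -> tuple[float, float, float]:
    """(p_diff, dist, identity) of an orthologous protein alignment.

    With ``count_gaps`` (default) every aligned column enters the
    denominator and gap columns count as differences; otherwise only
    columns where both sequences have residues are scored.
    """
    ga, gb = aln.aligned_a, aln.aligned_b
    if not ga:
        raise ValueError("zero-length alignment")
    matches = nongap = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            nongap += 1
            if x.upper() == y.upper():
                matches += 1
    ncols = len(ga) if count_gaps else nongap
    if ncols == 0:
        raise ValueError("alignment has no scored columns")
    p_diff = (ncols - matches) / ncols
    identity = matches / nongap if nongap else 0.0
    return p_diff, math.sqrt(p_diff), identity


def identity_filter(
    records: Sequence[DivergenceRecord], min_identity: float = MIN_IDENTITY
) -> list[DivergenceRecord]:
    """Keep records with identity >= ``min_identity`` (strict 'less than'
    excluded)."""
    return [r for r in records if r.identity >= min_identity]


def tercile_cutoffs(p_diffs: Sequence[float]) -> tuple[float, float]:
    """(low, high) cutoffs putting one third of values in each bin:
    Low <= low, High >= high, Intermediate strictly between."""
    n = len(p_diffs)
    if n < 3:
        raise ValueError("need at least 3 values for empirical terciles")
    s = sorted(p_diffs)
    third = math.ceil(n / 3)
    return s[third - 1], s[n - third]


def assign_bin(p_diff: float, low: float, high: float) -> str:
    if p_diff >= high:
        return "High"
    if p_diff <= low:
        return "Low"
    return "Intermediate"


def bin_divergence(
    records: Sequence[DivergenceRecord], mode: str = "empirical_terciles"
) -> tuple[list[DivergenceRecord], tuple[float, float]]:
    """Assign divergence bins in place; returns (records, (low, high)).

    ``paper_cutoffs`` uses the fixed 0.058/0.138 thresholds;
    ``empirical_terciles`` derives them from the data.
    """
    if mode == "paper_cutoffs":
        low, high = PAPER_LOW_CUTOFF, PAPER_HIGH_CUTOFF
    elif mode == "empirical_terciles":
        low, high = tercile_cutoffs([r.p_diff for r in records])
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    for r in records:
        r.bin = assign_bin(r.p_diff, low, high)
    return list(records), (low, high)


def group_compare(
    div_a: Sequence[float], div_b: Sequence[float], exact_max: int = 10_000
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two divergence samples.

    Exact enumeration when n_a * n_b <= ``exact_max`` and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    if not div_a or not div_b:
        raise ValueError("both groups must be non-empty")
    has_ties = len(set(div_a) | set(div_b)) < len(div_a) + len(div_b)
    method = "exact" if (len(div_a) * len(div_b) <= exact_max and not has_ties) else "asymptotic"
    res = mannwhitneyu(div_a, div_b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def category_enrichment(
    records: Sequence[DivergenceRecord],
    annotations: Mapping[str, set[str]] | None = None,
    min_n: int = MIN_CATEGORY_N,
    alpha_family: float = FAMILY_ALPHA,
    expected: str = "global",
) -> list[EnrichmentResult]:
    """Chi-square goodness-of-fit of each category's bin counts.

    ``expected='global'`` tests against the bin proportions of the whole
    record set (which are thirds by construction under tercile binning);
    ``expected='thirds'`` forces exact (1/3, 1/3, 1/3). Only categories
    with at least ``min_n`` members are tested; the per-test alpha is
    ``alpha_family`` / number of tested categories. A record carrying
    several categories contributes to each.
    """
    if annotations is not None:
        for r in records:
            r.categories = set(annotations.get(r.contig_id, set()))
    if expected == "global":
        totals = np.array([sum(1 for r in records if r.bin == b) for b in BINS], float)
        if totals.sum() == 0:
            raise ValueError("records are not binned")
        props = totals / totals.sum()
    elif expected == "thirds":
        props = np.full(3, 1.0 / 3.0)
    else:
        raise ValueError(f"unknown expected mode {expected!r}")

    by_cat: dict[str, list[DivergenceRecord]] = {}
    for r in records:
        for cat in r.categories:
            by_cat.setdefault(cat, []).append(r)
    tested = {cat: rs for cat, rs in by_cat.items() if len(rs) >= min_n}
    if not tested:
        return []
    alpha = alpha_family / len(tested)
    results: list[EnrichmentResult] = []
    for cat in sorted(tested):
        rs = tested[cat]
        obs = np.array([sum(1 for r in rs if r.bin == b) for b in BINS], float)
        n = int(obs.sum())
        exp = props * n
        if (exp == 0).any():  # degenerate global proportions: skip zero cells
            keep = exp > 0
            stat, p = chisquare(obs[keep], exp[keep])
            df = int(keep.sum()) - 1
        else:
            stat, p = chisquare(obs, exp)
            df = 2
        resid = (obs - exp) / np.sqrt(np.where(exp > 0, exp, 1.0))
        top = int(np.argmax(np.abs(resid)))
        sign = "enriched" if resid[top] > 0 else "depleted"
        results.append(
            EnrichmentResult(
                category=cat, n=n,
                observed=tuple(int(x) for x in obs),
                expected=tuple(float(x) for x in exp),
                chi2=float(stat), df=df, p=float(p), alpha=alpha,
                significant=bool(p < alpha),
                direction=f"{BINS[top]}:{sign}",
            )
        )
    return results
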