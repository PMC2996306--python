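"""SND calling, depth-corrected nucleotide diversity, and RPKM expression.

SNDs (short nucleotide discrepancies: SNPs and short indels) are called
from MAPQ-filtered pileups under four rules: mapping quality >= 20 (applied
by the pileup reader), alternative allele seen at least twice — or at least
0.025 x coverage once coverage exceeds 80, exactly one alternative allele at
or above that threshold, and depth >= 6.

Raw per-contig diversity is the SND count divided by the *callable length*
(positions with depth >= 6). Because a truly heterozygous site can fail the
allele-count threshold by sampling alone, raw diversity is biased downward
at low depth; the adjusted value divides by the detection probability
Phi(d) — the chance a balanced biallelic site (alt fraction 0.5, binomial
sampling) clears the caller's own threshold at the contig's median callable
depth. Phi is an explicit binomial detection model; a user-supplied
Phi(d) table can replace it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from scipy.stats import binom

from .io_formats import PileupSite

MIN_DEPTH = 6
MIN_ALT = 2
FRAC_WHEN_DEEP = 0.025
DEEP_CUTOFF = 80


@dataclass(slots=True)
class SNDCall:
    contig_id: str
    pos: int  # 1-based
    ref_base: str
    alt: str  # base, or indel string like "+AT" / "-A"
    alt_count: int
    depth: int
    kind: str  # "snp" or "indel"


@dataclass(slots=True)
class ContigDiversity:
    contig_id: str
    n_snd: int
    callable_len: int
    pi_raw: float
    median_depth: float
    detect_p: float
    pi_adj: float


@dataclass(slots=True)
class ExpressionRecord:
    contig_id: str
    read_count: int
    length_bp: int
    rpkm: float


def alt_threshold(
    depth: int,
    min_alt: int = MIN_ALT,
    frac_when_deep: float = FRAC_WHEN_DEEP,
    deep_cutoff: int = DEEP_CUTOFF,
) -> int:
    """Minimum alternative-allele count at a site of the given depth."""
    if depth > deep_cutoff:
        return max(min_alt, math.ceil(frac_when_deep * depth))
    return min_alt


def call_site(
    site: PileupSite,
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT,
    frac_when_deep: float = FRAC_WHEN_DEEP,
    deep_cutoff: int = DEEP_CUTOFF,
) -> SNDCall | None:
    """Apply the calling rules to one pileup site.

    Indel alleles compete with SNP alleles under the same threshold; a site
    with two qualifying alternative alleles is rejected.
    """
    if site.depth < min_depth:
        return None
    t = alt_threshold(site.depth, min_alt, frac_when_deep, deep_cutoff)
    qualifying: list[tuple[str, int, str]] = []
    for base, count in site.base_counts.items():
        if base != site.ref_base and count >= t:
            qualifying.append((base, count, "snp"))
    for indel, count in site.indel_counts.items():
        if count >= t:
            qualifying.append((indel, count, "indel"))
    if len(qualifying) != 1:
        return None
    alt, count, kind = qualifying[0]
    return SNDCall(site.contig_id, site.pos, site.ref_base, alt, count, site.depth, kind)


def call_snds(
    sites: Iterable[PileupSite],
    min_depth: int = MIN_DEPTH,
    min_alt: int = MIN_ALT,
    frac_when_deep: float = FRAC_WHEN_DEEP,
    deep_cutoff: int = DEEP_CUTOFF,
) -> list[SNDCall]:
    """All SND calls over a site stream (order-independent per site)."""
    calls = []
    for site in sites:
        call = call_site(site, min_depth, min_alt, frac_when_deep, deep_cutoff)
        if call is not None:
            calls.append(call)
    return calls


def callable_length(sites: Iterable[PileupSite], min_depth: int = MIN_DEPTH) -> int:
    """Number of positions covered by at least ``min_depth`` reads.

    Positions absent from the stream have depth 0 and never count.
    """
    return sum(1 for s in sites if s.depth >= min_depth)


def detect_prob(
    median_depth: float,
    min_alt: int = MIN_ALT,
    frac_when_deep: float = FRAC_WHEN_DEEP,
    deep_cutoff: int = DEEP_CUTOFF,
) -> float:
    """Phi(d): probability that a balanced biallelic site clears the
    alt-count threshold at depth d = round(median_depth) (half-up).

    Phi(d) = P[Binomial(d, 0.5) >= t(d)] = 1 - sum_{j<t} C(d,j) 0.5^d.
    """
    if median_depth < 1:
        raise ValueError(f"median depth must be >= 1, got {median_depth}")
    d = math.floor(median_depth + 0.5)
    t = alt_threshold(d, min_alt, frac_when_deep, deep_cutoff)
    return float(binom.sf(t - 1, d, 0.5))


def _median(values: Sequence[float]) -> float:
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    return float(vals[mid]) if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0


def contig_diversity(
    calls: Sequence[SNDCall],
    sites: Sequence[PileupSite],
    contig_id: str | None = None,
    min_depth: int = MIN_DEPTH,
    phi: Callable[[float], float] | None = None,
) -> ContigDiversity:
    """Length- and depth-corrected nucleotide diversity for one contig.

    pi_raw = SNDs / callable length; pi_adj = pi_raw / Phi(median callable
    depth). ``phi`` overrides the built-in binomial detection model.
    """
    if contig_id is None:
        contig_id = sites[0].contig_id if sites else (calls[0].contig_id if calls else "")
    depths = [s.depth for s in sites if s.depth >= min_depth]
    n_callable = len(depths)
    n_snd = len(calls)
    if n_callable == 0:
        return ContigDiversity(contig_id, n_snd, 0, 0.0, 0.0, 1.0, 0.0)
    med = _median(depths)
    p = phi(med) if phi is not None else detect_prob(med)
    pi_raw = n_snd / n_callable
    return ContigDiversity(contig_id, n_snd, n_callable, pi_raw, med, p, pi_raw / p)


def rpkm(
    read_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    total_mapped: int | None = None,
) -> list[ExpressionRecord]:
    """Reads per kilobase of contig per million mapped reads.

    rpkm_i = c_i * 1e9 / (N * L_i) with N the total mapped reads (defaults
    to the sum of the counts). Conservation: sum(rpkm_i * L_i / 1000) = 1e6
    when N equals the count total.
    """
    n = total_mapped if total_mapped is not None else sum(read_counts.values())
    out: list[ExpressionRecord] = []
    for cid in sorted(read_counts):
        length = lengths[cid]
        if length <= 0:
            raise ValueError(f"contig {cid}: non-positive length {length}")
        c = read_counts[cid]
        value = 0.0 if n == 0 else c * 1e9 / (n * length)
        out.append(ExpressionRecord(cid, c, length, value))
    return out
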