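"""Reciprocal best-hit (RBH) 1:1 orthologue assignment.

A one-directional best hit is declared for a query when it has a single hit,
or when the second-best score is less than 0.7 of the best (an unambiguous
top match; equal top scores therefore declare nothing). A contig and a
peptide that are each other's best hits form an orthologue pair. Reference
peptides shorter than 50 aa are omitted before the reverse search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .aligners import ScoringScheme, search_all
from .assembler import Contig
from .io_formats import SeqRecord, TabularHit

RATIO_CUTOFF = 0.7
MIN_PEPTIDE_AA = 50


@dataclass(slots=True)
class OrthologPair:
    contig_id: str
    peptide_id: str
    fwd_score: float
    rev_score: float


def declare_best_hit(
    hits_for_query: Sequence[TabularHit], ratio_cutoff: float = RATIO_CUTOFF
) -> str | None:
    """The query's unambiguous top target, or None.

    Per-target score is the best single HSP raw score. Declared when only
    one target was hit, or second-best/best < ``ratio_cutoff``.
    """
    if not hits_for_query:
        return None
    per_target: dict[str, float] = {}
    for h in hits_for_query:
        per_target[h.target_id] = max(per_target.get(h.target_id, 0.0), h.raw_score)
    ranked = sorted(per_target.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        return ranked[0][0]
    (top_id, top), (_, second) = ranked[0], ranked[1]
    if second / top < ratio_cutoff:
        return top_id
    return None


def _best_hit_map(
    hits: Sequence[TabularHit], ratio_cutoff: float = RATIO_CUTOFF
) -> dict[str, str | None]:
    by_query: dict[str, list[TabularHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return {q: declare_best_hit(hs, ratio_cutoff) for q, hs in by_query.items()}


def reciprocal_best_hits(
    fwd: Mapping[str, str | None],
    rev: Mapping[str, str | None],
    fwd_scores: Mapping[tuple[str, str], float] | None = None,
    rev_scores: Mapping[tuple[str, str], float] | None = None,
) -> list[OrthologPair]:
    """Pairs (contig, peptide) declared best in both directions, ordered by
    contig id. The pair set is a partial bijection by construction."""
    pairs: list[OrthologPair] = []
    for contig_id in sorted(fwd):
        pep = fwd[contig_id]
        if pep is None:
            continue
        if rev.get(pep) == contig_id:
            pairs.append(
                OrthologPair(
                    contig_id,
                    pep,
                    (fwd_scores or {}).get((contig_id, pep), 0.0),
                    (rev_scores or {}).get((pep, contig_id), 0.0),
                )
            )
    return pairs


def find_orthologs(
    contigs: Sequence[Contig],
    peptides: Sequence[SeqRecord],
    fwd_hits: Sequence[TabularHit] | None = None,
    rev_hits: Sequence[TabularHit] | None = None,
    scheme: ScoringScheme | None = None,
    min_pep_aa: int = MIN_PEPTIDE_AA,
    ratio_cutoff: float = RATIO_CUTOFF,
) -> list[OrthologPair]:
    """End-to-end RBH between contigs and a reference peptide set.

    Without pre-tabulated hits the built-in translated search runs both
    ways (contig vs peptide and, reciprocally, with roles swapped).
    """
    peptides = [p for p in peptides if len(p.seq) >= min_pep_aa]
    contig_records = [SeqRecord(c.id, c.seq) for c in contigs]
    if fwd_hits is None:
        fwd_hits = search_all(contig_records, peptides, "x", scheme)
    if rev_hits is None:
        # reverse direction: peptide query vs translated contigs; realised by
        # swapping roles of the same translated comparison
        swapped = search_all(contig_records, peptides, "x", scheme)
        rev_hits = [
            TabularHit(
                query_id=h.target_id, target_id=h.query_id,
                raw_score=h.raw_score, evalue=h.evalue,
                q_start=h.t_start, q_end=h.t_end,
                t_start=h.q_start, t_end=h.q_end,
                frame=h.frame, minus=h.minus,
            )
            for h in swapped
        ]
    pep_ids = {p.id for p in peptides}
    rev_hits = [h for h in rev_hits if h.query_id in pep_ids]
    fwd = _best_hit_map(fwd_hits, ratio_cutoff)
    rev = _best_hit_map(rev_hits, ratio_cutoff)
    fwd_scores = {(h.query_id, h.target_id): h.raw_score for h in fwd_hits}
    rev_scores = {(h.query_id, h.target_id): h.raw_score for h in rev_hits}
    return reciprocal_best_hits(fwd, rev, fwd_scores, rev_scores)
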