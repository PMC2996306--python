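"""Target-based contig clustering: join fragmented contigs around shared
homology targets.

Stage one uses conspecific ESTs: contigs hitting an EST are filtered by an
absolute alignment-score rule (raw score must exceed 50 + 3 × the shorter
sequence's length), then by a normalised-score rule (raw local-search score
divided by the group maximum must be >= 0.7), then re-filtered on
EST-alignment scores, and the survivors' overhangs are grafted onto the
EST. Stage two treats contigs untouched by stage one analogously against a
related species' peptide set: groups are filtered at the same 0.7
normalised cutoff; overlapping survivors are merged when their percent
identity clears 90 (two survivors) or 80 (larger groups, transitively);
non-overlapping pairs are scaffolded with an N-run sized from the peptide
HSP coordinates (3 nt per residue of gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .aligners import (
    PairwiseAlignment,
    ScoringScheme,
    global_align,
    overlap_align,
    revcomp,
    search_all,
)
from .assembler import Contig
from .io_formats import SeqRecord, TabularHit, get_logger

logger = get_logger(__name__)

NORM_CUTOFF = 0.7
PAIRWISE_JOIN_CUTOFF = 80.0  # >2 survivors
OVERLAP_JOIN_CUTOFF = 90.0  # exactly 2 survivors


@dataclass(slots=True)
class GroupMember:
    contig_id: str
    raw_score: float
    norm_score: float = 1.0
    minus: bool = False
    hit: TabularHit | None = None


@dataclass(slots=True)
class TargetGroup:
    target_id: str
    target_kind: str  # "est" or "peptide"
    members: list[GroupMember] = field(default_factory=list)
    survivors: list[GroupMember] = field(default_factory=list)


@dataclass(slots=True)
class JoinRecord:
    new_contig_id: str
    parts: list[tuple[str, tuple[int, int], int]]  # (source_id, interval, orientation)
    n_gap_len: int = 0
    rule: str = "est_extend"  # pep_overlap_merge, pep_n_scaffold

    def __post_init__(self) -> None:
        if (self.n_gap_len > 0) != (self.rule == "pep_n_scaffold"):
            raise ValueError("n_gap_len > 0 iff rule is pep_n_scaffold")


# ---------------------------------------------------------------------------
# shared filters


def dedupe_ests(ests: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Drop exact duplicates and ESTs contained in a longer EST (either
    strand, case-insensitive). Longest kept; ties broken by id."""
    ordered = sorted(ests, key=lambda e: (-len(e.seq), e.id))
    kept: list[SeqRecord] = []
    for est in ordered:
        s = est.seq.upper()
        rc = revcomp(s)
        if any(s in k.seq.upper() or rc in k.seq.upper() for k in kept):
            continue
        kept.append(est)
    return sorted(kept, key=lambda e: e.id)


def group_hits_by_target(
    hits: Sequence[TabularHit], target_kind: str
) -> list[TargetGroup]:
    """Assign each query to its best target (max raw score over HSPs) and
    form one group per target."""
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.raw_score > cur.raw_score:
            best[h.query_id] = h
    groups: dict[str, TargetGroup] = {}
    for h in best.values():
        g = groups.setdefault(h.target_id, TargetGroup(h.target_id, target_kind))
        g.members.append(GroupMember(h.query_id, h.raw_score, minus=h.minus, hit=h))
    for g in groups.values():
        g.members.sort(key=lambda m: (-m.raw_score, m.contig_id))
    return sorted(groups.values(), key=lambda g: g.target_id)


def norm_score_filter(group: TargetGroup, cutoff: float = NORM_CUTOFF) -> TargetGroup:
    """Keep members whose raw score is >= ``cutoff`` of the group maximum."""
    if not group.members:
        raise ValueError(f"group {group.target_id}: no members")
    top = max(m.raw_score for m in group.members)
    group.survivors = []
    for m in group.members:
        m.norm_score = m.raw_score / top
        if m.norm_score >= cutoff:
            group.survivors.append(m)
    return group


def est_prefilter(contig: SeqRecord, est: SeqRecord, aln: PairwiseAlignment) -> bool:
    """Keep iff the alignment raw score exceeds 50 + 3 × shorter length."""
    return aln.raw_score > 50.0 + 3.0 * min(len(contig.seq), len(est.seq))


def est_group_refine(
    group: TargetGroup,
    contigs: dict[str, SeqRecord],
    est: SeqRecord,
    scheme: ScoringScheme | None = None,
    cutoff: float = NORM_CUTOFF,
) -> TargetGroup:
    """Renormalise survivors by their EST-alignment scores; applies only
    when more than one survivor remains."""
    if len(group.survivors) < 2:
        return group
    scores: dict[str, float] = {}
    for m in group.survivors:
        seq = contigs[m.contig_id]
        if m.minus:
            seq = SeqRecord(seq.id, revcomp(seq.seq))
        scores[m.contig_id] = overlap_align(seq, est, scheme).raw_score
    top = max(scores.values())
    group.survivors = [
        m for m in group.survivors if top > 0 and scores[m.contig_id] / top >= cutoff
    ]
    return group


# ---------------------------------------------------------------------------
# EST joining


def _overhangs(aln: PairwiseAlignment) -> tuple[str, str]:
    """Leading/trailing contig sequence beyond the EST in an overlap
    alignment of (oriented contig, EST)."""
    ga, gb = aln.aligned_a, aln.aligned_b
    left = right = ""
    i = 0
    while i < len(gb) and gb[i] == "-":
        i += 1
    left = ga[:i].replace("-", "")
    j = len(gb)
    while j > 0 and gb[j - 1] == "-":
        j -= 1
    right = ga[j:].replace("-", "")
    return left, right


def join_to_est(
    est: SeqRecord,
    survivors: Sequence[GroupMember],
    contigs: dict[str, SeqRecord],
    scheme: ScoringScheme | None = None,
    new_id: str | None = None,
) -> tuple[Contig, JoinRecord]:
    """Graft the longest left and right survivor overhangs onto the EST."""
    best_left = best_right = ""
    left_src = right_src = None
    parts: list[tuple[str, tuple[int, int], int]] = []
    for m in survivors:
        seq = contigs[m.contig_id]
        orient = -1 if m.minus else 1
        if m.minus:
            seq = SeqRecord(seq.id, revcomp(seq.seq))
        aln = overlap_align(seq, est, scheme)
        left, right = _overhangs(aln)
        parts.append((m.contig_id, (0, len(seq.seq)), orient))
        if len(left) > len(best_left):
            best_left, left_src = left, m.contig_id
        if len(right) > len(best_right):
            best_right, right_src = right, m.contig_id
    seq = best_left + est.seq + best_right
    cid = new_id or f"join_{est.id}"
    contig = Contig(
        cid, seq, provenance="est_joined",
        source_ids=[m.contig_id for m in survivors] + [est.id],
    )
    rec = JoinRecord(cid, parts, 0, "est_extend")
    logger.debug(
        "join_to_est %s: left %dnt from %s, right %dnt from %s",
        est.id, len(best_left), left_src, len(best_right), right_src,
    )
    return contig, rec


def est_cluster(
    contigs: Sequence[Contig],
    ests: Sequence[SeqRecord],
    hits: Sequence[TabularHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> tuple[list[Contig], list[JoinRecord]]:
    """The full EST stage. Returns the new contig set (joined products plus
    untouched contigs with provenance ``unchanged``) and the join records.

    ``hits`` may come from an external tabular file; otherwise the built-in
    search runs in nucleotide mode at e-value 1e-6.
    """
    ests = dedupe_ests(ests)
    by_id = {c.id: SeqRecord(c.id, c.seq) for c in contigs}
    est_by_id = {e.id: e for e in ests}
    if hits is None:
        hits = search_all(list(by_id.values()), ests, "n2n", scheme)
    # absolute-score prefilter on each contig-EST match
    strong: list[TabularHit] = []
    for h in hits:
        contig, est = by_id.get(h.query_id), est_by_id.get(h.target_id)
        if contig is None or est is None:
            continue
        oriented = SeqRecord(contig.id, revcomp(contig.seq) if h.minus else contig.seq)
        if est_prefilter(oriented, est, overlap_align(oriented, est, scheme)):
            strong.append(h)
    joined: list[Contig] = []
    records: list[JoinRecord] = []
    consumed: set[str] = set()
    for i, group in enumerate(group_hits_by_target(strong, "est")):
        group.members = [m for m in group.members if m.contig_id not in consumed]
        if not group.members:
            continue
        norm_score_filter(group)
        est = est_by_id[group.target_id]
        est_group_refine(group, by_id, est, scheme)
        if not group.survivors:
            continue
        contig, rec = join_to_est(
            est, group.survivors, by_id, scheme, new_id=f"estjoin_{i:05d}"
        )
        joined.append(contig)
        records.append(rec)
        consumed.update(m.contig_id for m in group.survivors)
    passthrough = [
        Contig(c.id, c.seq, provenance="unchanged", source_ids=[c.id])
        for c in contigs
        if c.id not in consumed
    ]
    return joined + passthrough, records


# ---------------------------------------------------------------------------
# peptide joining


def _merge_overlap(
    a: SeqRecord, b: SeqRecord, score_a: float, score_b: float, scheme: ScoringScheme | None
) -> str:
    """Consensus of two overlapping contigs; the higher-scoring contig wins
    disagreeing columns (ties: first by id)."""
    aln = overlap_align(a, b, scheme)
    prefer_a = score_a > score_b or (score_a == score_b and a.id <= b.id)
    out: list[str] = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-":
            out.append(y)
        elif y == "-":
            out.append(x)
        else:
            out.append(x if prefer_a else y)
    return "".join(out)


def peptide_cluster(
    contigs: Sequence[Contig],
    peptides: Sequence[SeqRecord],
    hits: Sequence[TabularHit] | None = None,
    scheme: ScoringScheme | None = None,
) -> tuple[list[Contig], list[JoinRecord]]:
    """The peptide stage, applied to contigs the EST stage did not join.

    Per peptide group (after the 0.7 normalised-score filter): two
    overlapping survivors merge when identity > 90; non-overlapping pairs
    are N-scaffolded, the run sized 3 × the residue gap between their HSPs;
    three or more survivors merge transitively along pairs with identity
    > 80.
    """
    by_id = {c.id: SeqRecord(c.id, c.seq) for c in contigs}
    if hits is None:
        hits = search_all(list(by_id.values()), peptides, "x", scheme)
    hits = [h for h in hits if h.query_id in by_id]
    out: list[Contig] = []
    records: list[JoinRecord] = []
    consumed: set[str] = set()
    for gi, group in enumerate(group_hits_by_target(hits, "peptide")):
        group.members = [m for m in group.members if m.contig_id not in consumed]
        if not group.members:
            continue
        norm_score_filter(group)
        surv = group.survivors
        if len(surv) < 2:
            continue
        score = {m.contig_id: m.raw_score for m in surv}
        oriented = {}
        for m in surv:
            s = by_id[m.contig_id]
            oriented[m.contig_id] = SeqRecord(s.id, revcomp(s.seq) if m.minus else s.seq)
        if len(surv) == 2:
            m1, m2 = sorted(surv, key=lambda m: m.hit.t_start)
            gap_aa = m2.hit.t_start - m1.hit.t_end - 1
            if gap_aa >= 0:
                n_run = max(1, 3 * gap_aa)
                seq = oriented[m1.contig_id].seq + "N" * n_run + oriented[m2.contig_id].seq
                cid = f"pepscaf_{gi:05d}"
                out.append(
                    Contig(cid, seq, "n_scaffolded", [m1.contig_id, m2.contig_id])
                )
                records.append(
                    JoinRecord(
                        cid,
                        [
                            (m1.contig_id, (0, len(oriented[m1.contig_id].seq)), -1 if m1.minus else 1),
                            (m2.contig_id, (0, len(oriented[m2.contig_id].seq)), -1 if m2.minus else 1),
                        ],
                        n_run,
                        "pep_n_scaffold",
                    )
                )
                consumed.update(score)
            else:
                aln = overlap_align(oriented[m1.contig_id], oriented[m2.contig_id], scheme)
                if aln.norm_score > OVERLAP_JOIN_CUTOFF:
                    seq = _merge_overlap(
                        oriented[m1.contig_id], oriented[m2.contig_id],
                        score[m1.contig_id], score[m2.contig_id], scheme,
                    )
                    cid = f"pepjoin_{gi:05d}"
                    out.append(
                        Contig(cid, seq, "peptide_joined", [m1.contig_id, m2.contig_id])
                    )
                    records.append(
                        JoinRecord(
                            cid,
                            [
                                (m1.contig_id, (0, len(oriented[m1.contig_id].seq)), -1 if m1.minus else 1),
                                (m2.contig_id, (0, len(oriented[m2.contig_id].seq)), -1 if m2.minus else 1),
                            ],
                            0,
                            "pep_overlap_merge",
                        )
                    )
                    consumed.update(score)
        else:
            # >2 survivors: all-pairs identity, transitive union above 80
            graph = nx.Graph()
            graph.add_nodes_from(score)
            ids = sorted(score)
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    aln = overlap_align(oriented[a], oriented[b], scheme)
                    if aln.norm_score > PAIRWISE_JOIN_CUTOFF:
                        graph.add_edge(a, b)
            hsp_start = {m.contig_id: m.hit.t_start for m in surv}
            orient = {m.contig_id: (-1 if m.minus else 1) for m in surv}
            for comp in sorted(nx.connected_components(graph), key=min):
                if len(comp) < 2:
                    continue
                ordered = sorted(comp, key=lambda c: (hsp_start[c], c))
                merged = oriented[ordered[0]]
                for nxt in ordered[1:]:
                    merged = SeqRecord(
                        merged.id,
                        _merge_overlap(merged, oriented[nxt], score[merged.id], score[nxt], scheme),
                    )
                cid = f"pepjoin_{gi:05d}_{min(comp)}"
                out.append(Contig(cid, merged.seq, "peptide_joined", ordered))
                records.append(
                    JoinRecord(
                        cid,
                        [(c, (0, len(oriented[c].seq)), orient[c]) for c in ordered],
                        0,
                        "pep_overlap_merge",
                    )
                )
                consumed.update(comp)
    passthrough = [
        Contig(c.id, c.seq, c.provenance, c.source_ids or [c.id], c.orf, c.evidence)
        for c in contigs
        if c.id not in consumed
    ]
    return out + passthrough, records
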