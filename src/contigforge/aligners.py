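"""Pairwise alignment, six-frame translation, and a seeded local search.

``global_align`` is Needleman–Wunsch with affine gaps (the stand-in for a
pairwise ClustalW run); ``overlap_align`` is the same with free end gaps,
used when two sequences are expected to overlap rather than be colinear.
``local_search`` is a word-seeded, ungapped-then-gapped local search with
Karlin–Altschul e-values — enough to reproduce the score thresholds and
orderings the clustering, validation and orthology stages rely on; it makes
no claim to full BLAST statistics. Pre-tabulated hit files can be used in
its place everywhere.

Two score scales are in play and must not be confused: the *raw* alignment
score (scheme-dependent; the "50 + 3 × shorter length" EST rule operates on
it) and the 0–100 *normalised* score, the percent of aligned non-gap
columns that are identical (the ">80"/">90" peptide-joining rules operate
on it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import SeqRecord, TabularHit

DEFAULT_MAX_EVALUE = 1e-6
_WORD_NUC = 11
_WORD_PROT = 3
_XDROP = 20.0


@dataclass(slots=True)
class ScoringScheme:
    """Alignment scoring. The nucleotide scale (+5/−4, −10/−1) makes a
    perfect alignment of length L score 5L, which keeps the absolute
    "50 + 3L" EST-acceptance rule satisfiable for L > 25."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    protein_matrix: str = "BLOSUM62"
    protein_gap_open: float = -11.0
    protein_gap_extend: float = -1.0
    # Karlin–Altschul constants (approximate; used for thresholding/ordering)
    ka_lambda_nuc: float = 1.28
    ka_k_nuc: float = 0.46
    ka_lambda_prot: float = 0.267
    ka_k_prot: float = 0.041

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass(slots=True)
class PairwiseAlignment:
    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    raw_score: float
    norm_score: float  # 0-100, identity over non-gap columns
    p_diff: float  # fraction of all aligned columns differing (gaps differ)


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(kind: str, scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if mode == "local" else "global"
    if kind == "protein":
        aligner.substitution_matrix = _matrix(scheme.protein_matrix)
        aligner.open_gap_score = scheme.protein_gap_open
        aligner.extend_gap_score = scheme.protein_gap_extend
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
        aligner.open_gap_score = scheme.gap_open
        aligner.extend_gap_score = scheme.gap_extend
    if mode == "overlap":
        if hasattr(aligner, "open_end_insertion_score"):
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        else:  # Biopython < 1.86 attribute names
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
            aligner.query_end_open_gap_score = 0.0
            aligner.query_end_extend_gap_score = 0.0
    return aligner


def _column_stats(ga: str, gb: str) -> tuple[float, float]:
    """(p_diff over all columns, norm_score over non-gap columns)."""
    ncols = len(ga)
    matches = nongap = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            nongap += 1
            if x.upper() == y.upper():
                matches += 1
    p_diff = (ncols - matches) / ncols if ncols else 0.0
    norm = 100.0 * matches / nongap if nongap else 0.0
    return p_diff, norm


def _align(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme, mode: str) -> PairwiseAlignment:
    if a.kind != b.kind:
        raise ValueError(f"mixed alphabets: {a.kind} vs {b.kind}")
    if not a.seq or not b.seq:
        # forced all-gap alignment; one affine gap spanning the longer side
        long, short = (a.seq, b.seq) if len(a.seq) >= len(b.seq) else (b.seq, a.seq)
        if not long:
            raise ValueError("cannot align two empty sequences")
        if a.kind == "protein":
            score = scheme.protein_gap_open + (len(long) - 1) * scheme.protein_gap_extend
        else:
            score = scheme.gap_open + (len(long) - 1) * scheme.gap_extend
        ga = a.seq.upper() or "-" * len(long)
        gb = b.seq.upper() or "-" * len(long)
        return PairwiseAlignment(a.id, b.id, ga, gb, score, 0.0, 1.0)
    aligner = _make_aligner(a.kind, scheme, mode)
    result = aligner.align(a.seq.upper(), b.seq.upper())
    aln = result[0]
    ga, gb = str(aln[0]), str(aln[1])
    p_diff, norm = _column_stats(ga, gb)
    return PairwiseAlignment(a.id, b.id, ga, gb, float(result.score), norm, p_diff)


def global_align(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch) alignment with affine gaps."""
    return _align(a, b, scheme or ScoringScheme(), "global")


def overlap_align(a: SeqRecord, b: SeqRecord, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Global alignment with cost-free end gaps (dovetail/containment)."""
    return _align(a, b, scheme or ScoringScheme(), "overlap")


# ---------------------------------------------------------------------------
# translation

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, −1..−3 on the reverse
    complement); stops as '*', ambiguous codons as 'X', partial tail codon
    dropped."""
    if frame == 0 or abs(frame) > 3:
        raise ValueError(f"frame must be in ±1..±3, got {frame}")
    s = seq.upper() if frame > 0 else revcomp(seq.upper())
    offset = abs(frame) - 1
    sub = s[offset : offset + 3 * ((len(s) - offset) // 3)]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def six_frame_translate(record: SeqRecord) -> dict[int, str]:
    """All six reading frames of a nucleotide sequence, keyed by frame."""
    if record.kind != "nucleotide":
        raise ValueError("six-frame translation needs a nucleotide sequence")
    return {f: translate_frame(record.seq, f) for f in (1, 2, 3, -1, -2, -3)}


# ---------------------------------------------------------------------------
# seeded local search


def _pair_score(kind: str, scheme: ScoringScheme):
    if kind == "protein":
        mat = _matrix(scheme.protein_matrix)
        alphabet = mat.alphabet

        def score(x: str, y: str) -> float:
            if x not in alphabet or y not in alphabet:
                return -1.0
            return float(mat[x, y])

    else:

        def score(x: str, y: str) -> float:
            if x == "N" or y == "N":
                return 0.0
            return scheme.match if x == y else scheme.mismatch

    return score


def _index_words(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if "N" in word or "X" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _ungapped_extend(q: str, t: str, qi: int, ti: int, w: int, score_fn) -> tuple[int, int, float]:
    """X-drop ungapped extension of an exact w-mer seed.

    Returns 0-based (q_start, q_end exclusive, score) with t offsets implied
    by the shared diagonal.
    """
    best = cur = sum(score_fn(q[qi + j], t[ti + j]) for j in range(w))
    # right
    best_r = 0
    j = w
    while qi + j < len(q) and ti + j < len(t):
        cur += score_fn(q[qi + j], t[ti + j])
        if cur > best:
            best, best_r = cur, j - w + 1
        if cur < best - _XDROP:
            break
        j += 1
    # left
    cur = best
    best_l = 0
    j = 1
    while qi - j >= 0 and ti - j >= 0:
        cur += score_fn(q[qi - j], t[ti - j])
        if cur > best:
            best, best_l = cur, j
        if cur < best - _XDROP:
            break
        j += 1
    return qi - best_l, qi + w + best_r, best


def _search_one(
    qseq: str, tseq: str, kind: str, scheme: ScoringScheme, tindex: dict[str, list[int]], w: int
) -> list[tuple[int, int, int, int, float]]:
    """All non-redundant HSPs of qseq vs tseq as 0-based half-open
    (qs, qe, ts, te, score)."""
    score_fn = _pair_score(kind, scheme)
    seen_diag: dict[int, int] = {}
    hsps: list[tuple[int, int, int, int, float]] = []
    for qi in range(len(qseq) - w + 1):
        word = qseq[qi : qi + w]
        for ti in tindex.get(word, ()):  # exact seeds only
            diag = qi - ti
            if seen_diag.get(diag, -1) >= qi:
                continue
            qs, qe, s = _ungapped_extend(qseq, tseq, qi, ti, w, score_fn)
            seen_diag[diag] = qe
            if s > 0:
                hsps.append((qs, qe, qs - diag, qe - diag, s))
    # drop HSPs contained in a stronger one
    hsps.sort(key=lambda h: -h[4])
    kept: list[tuple[int, int, int, int, float]] = []
    for h in hsps:
        if any(h[0] >= k[0] and h[1] <= k[1] and h[2] >= k[2] and h[3] <= k[3] for k in kept):
            continue
        kept.append(h)
    return kept


def _gapped_refine(
    qseq: str, tseq: str, hsp, kind: str, scheme: ScoringScheme, margin: int = 25
) -> tuple[int, int, int, int, float]:
    """Re-align a window around an ungapped HSP locally, allowing gaps."""
    qs, qe, ts, te, _ = hsp
    q0, q1 = max(0, qs - margin), min(len(qseq), qe + margin)
    t0, t1 = max(0, ts - margin), min(len(tseq), te + margin)
    aligner = _make_aligner(kind, scheme, "local")
    result = aligner.align(qseq[q0:q1], tseq[t0:t1])
    aln = result[0]
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return hsp
    return (
        q0 + int(qblocks[0][0]),
        q0 + int(qblocks[-1][1]),
        t0 + int(tblocks[0][0]),
        t0 + int(tblocks[-1][1]),
        float(result.score),
    )


def _evalue(score: float, m: int, n: int, kind: str, scheme: ScoringScheme) -> float:
    lam = scheme.ka_lambda_prot if kind == "protein" else scheme.ka_lambda_nuc
    kk = scheme.ka_k_prot if kind == "protein" else scheme.ka_k_nuc
    return kk * m * n * math.exp(-lam * score)


def local_search(
    query: SeqRecord,
    targets: Sequence[SeqRecord],
    mode: str = "n2n",
    scheme: ScoringScheme | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[TabularHit]:
    """Seeded local similarity search of one query against a target set.

    Modes: ``n2n`` nucleotide vs nucleotide (both strands); ``x``
    six-frame-translated nucleotide query vs protein targets (query
    coordinates in nt, target coordinates in aa); ``tx`` both translated
    (coordinates in nt on both). Hits at e-value <= ``max_evalue``, sorted
    by raw score descending.
    """
    scheme = scheme or ScoringScheme()
    hits: list[TabularHit] = []
    db_len = sum(len(t) for t in targets)

    def emit(target_id, qs, qe, ts, te, s, kind, m, frame, minus):
        e = _evalue(s, m, db_len, kind, scheme)
        if e <= max_evalue:
            hits.append(
                TabularHit(
                    query_id=query.id, target_id=target_id, raw_score=s, evalue=e,
                    q_start=qs, q_end=qe, t_start=ts, t_end=te, frame=frame, minus=minus,
                )
            )

    if mode == "n2n":
        if query.kind != "nucleotide" or any(t.kind != "nucleotide" for t in targets):
            raise ValueError("n2n mode needs nucleotide query and targets")
        qlen = len(query.seq)
        for target in targets:
            tindex = _index_words(target.seq.upper(), _WORD_NUC)
            for strand, qseq in ((1, query.seq.upper()), (-1, revcomp(query.seq.upper()))):
                for hsp in _search_one(qseq, target.seq.upper(), "nucleotide", scheme, tindex, _WORD_NUC):
                    qs, qe, ts, te, s = _gapped_refine(qseq, target.seq.upper(), hsp, "nucleotide", scheme)
                    if strand == -1:
                        qs, qe = qlen - qe, qlen - qs
                    emit(target.id, qs + 1, qe, ts + 1, te, s, "nucleotide", qlen, strand, strand == -1)
    elif mode in ("x", "tx"):
        if query.kind != "nucleotide":
            raise ValueError(f"{mode} mode needs a nucleotide query")
        frames = six_frame_translate(query)
        qlen = len(query.seq)
        for target in targets:
            if mode == "x":
                tviews = [(0, target.seq.upper())]
                if target.kind != "protein":
                    raise ValueError("x mode needs protein targets")
            else:
                tviews = [(tf, pseq) for tf, pseq in six_frame_translate(target).items()]
            for tf, tseq in tviews:
                tindex = _index_words(tseq, _WORD_PROT)
                for f, pseq in frames.items():
                    if len(pseq) < _WORD_PROT:
                        continue
                    for hsp in _search_one(pseq, tseq, "protein", scheme, tindex, _WORD_PROT):
                        qs_aa, qe_aa, ts_aa, te_aa, s = _gapped_refine(pseq, tseq, hsp, "protein", scheme)
                        off = abs(f) - 1
                        if f > 0:
                            q1, q2 = off + 3 * qs_aa + 1, off + 3 * qe_aa
                        else:  # positions counted on the reverse complement
                            rc1, rc2 = off + 3 * qs_aa + 1, off + 3 * qe_aa
                            q1, q2 = qlen - rc2 + 1, qlen - rc1 + 1
                        if mode == "x":
                            t1, t2 = ts_aa + 1, te_aa
                            minus = f < 0
                        else:
                            toff = abs(tf) - 1
                            if tf > 0:
                                t1, t2 = toff + 3 * ts_aa + 1, toff + 3 * te_aa
                            else:
                                tl = len(target.seq)
                                r1, r2 = toff + 3 * ts_aa + 1, toff + 3 * te_aa
                                t1, t2 = tl - r2 + 1, tl - r1 + 1
                            minus = (f < 0) != (tf < 0)
                        emit(target.id, q1, q2, t1, t2, s, "protein", len(pseq), f, minus)
    else:
        raise ValueError(f"unknown search mode {mode!r}")

    hits.sort(key=lambda h: (-h.raw_score, h.target_id, h.q_start))
    return hits


def search_all(
    queries: Iterable[SeqRecord],
    targets: Sequence[SeqRecord],
    mode: str = "n2n",
    scheme: ScoringScheme | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[TabularHit]:
    """``local_search`` over many queries, concatenated."""
    out: list[TabularHit] = []
    for q in queries:
        out.extend(local_search(q, targets, mode, scheme, max_evalue))
    return out
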