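"""ORF extraction and selection, evidence-based contig retention, and
assembly summary statistics.

Two ORF flavours are scanned in all six frames: type A, a translated region
bounded by a Methionine and a stop codon, and type B, a region merely free
of stop codons (so a contig that truncates the true start can still present
its coding stretch). The selected ORF is the best type A unless the best
type B runs further 5' and reaches the contig edge in its frame — the
signature of a truncated start — or no type A exists. Contigs whose
selected ORF is shorter than 50 aa are discarded, and of the remainder only
those with at least one homology/domain evidence tag are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .aligners import revcomp, translate_frame
from .assembler import Contig
from .io_formats import TabularHit

MIN_ORF_AA = 50
EVIDENCE_EVALUE = 1e-6
#: N-runs at least this long split a frame into independently scanned segments
N_SPLIT_RUN = 10

EVIDENCE_TAGS = frozenset(
    {"agam_pep", "aaeg_pep", "cqui_pep", "dmel_pep", "agam_genome",
     "cdd", "smart", "pfam", "kog", "go"}
)
PROTEOME_TAGS = frozenset({"agam_pep", "aaeg_pep", "cqui_pep", "dmel_pep"})
FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(slots=True)
class ORFCall:
    contig_id: str
    frame: int
    start: int  # 0-based half-open, contig forward strand
    end: int
    aa_len: int
    orf_type: str  # "A" (Met..stop) or "B" (stop-free)
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) // 3 != self.aa_len and self.orf_type == "B":
            raise ValueError("aa_len inconsistent with coordinates")


def _frame_segments(contig_seq: str, frame: int) -> list[tuple[int, str]]:
    """(offset-in-reading-direction, protein) segments of one frame, with
    runs of >= N_SPLIT_RUN Ns acting as breaks."""
    seq = contig_seq.upper() if frame > 0 else revcomp(contig_seq.upper())
    off = abs(frame) - 1
    segments: list[tuple[int, str]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= N_SPLIT_RUN:
                i = j
                continue
        j = i
        while j < n:
            if seq[j] == "N":
                run = j
                while run < n and seq[run] == "N":
                    run += 1
                if run - j >= N_SPLIT_RUN:
                    break
            j += 1
        # align segment start to the frame
        start = i + (off - i) % 3
        if start < j:
            prot = translate_frame_raw(seq[start:j])
            if prot:
                segments.append((start, prot))
        i = j
    return segments


def translate_frame_raw(sub: str) -> str:
    """Translate a frame-aligned nucleotide string, dropping the partial
    tail codon."""
    from Bio.Seq import Seq

    sub = sub[: 3 * (len(sub) // 3)]
    return str(Seq(sub).translate()) if sub else ""


def _to_forward(contig_len: int, frame: int, aa_start: int, aa_end: int, seg_off: int) -> tuple[int, int]:
    """Map aa coordinates within a frame segment to forward-strand
    nucleotide coordinates (0-based half-open)."""
    s = seg_off + 3 * aa_start
    e = seg_off + 3 * aa_end
    if frame > 0:
        return s, e
    return contig_len - e, contig_len - s


def extract_orfs(contig: Contig) -> tuple[ORFCall | None, ORFCall | None]:
    """Best type A and best type B ORF over all six frames.

    Ties go to the earlier frame in (+1, +2, +3, −1, −2, −3), then to the
    leftmost start within the frame. N-containing codons translate to X and
    are not stops.
    """
    seq = contig.seq.upper()
    L = len(seq)
    best_a: ORFCall | None = None
    best_b: ORFCall | None = None

    def better(cand: ORFCall, cur: ORFCall | None) -> bool:
        if cur is None:
            return True
        if cand.aa_len != cur.aa_len:
            return cand.aa_len > cur.aa_len
        return False  # scan order already encodes the tie-break

    for frame in FRAME_ORDER:
        for seg_off, prot in _frame_segments(seq, frame):
            # type B: stop-free stretches
            start = 0
            for i, aa in enumerate(prot + "*"):
                if aa == "*":
                    if i > start:
                        s, e = _to_forward(L, frame, start, i, seg_off)
                        cand = ORFCall(contig.id, frame, s, e, i - start, "B", prot[start:i])
                        if better(cand, best_b):
                            best_b = cand
                    start = i + 1
            # type A: Met .. stop
            i = 0
            while i < len(prot):
                if prot[i] == "M":
                    j = prot.find("*", i)
                    if j == -1:
                        break  # no stop downstream in this segment
                    s, e = _to_forward(L, frame, i, j + 1, seg_off)
                    cand = ORFCall(contig.id, frame, s, e, j - i, "A", prot[i:j])
                    if better(cand, best_a):
                        best_a = cand
                    i = j + 1
                else:
                    i += 1
    return best_a, best_b


def _reaches_five_prime(orf: ORFCall, contig_len: int) -> bool:
    """Whether the ORF starts at the contig boundary in its reading frame
    (no complete codon upstream)."""
    if orf.frame > 0:
        return orf.start < 3
    return orf.end > contig_len - 3


def select_orf(a: ORFCall | None, b: ORFCall | None, contig_len: int) -> ORFCall | None:
    """Prefer the start-codon-anchored ORF; fall back to the stop-free one
    when it extends further 5' right up to the contig edge (truncated-start
    signature), or when no type A exists."""
    if b is None:
        return a
    if a is None:
        return b
    if _reaches_five_prime(b, contig_len):
        if (a.frame > 0) == (b.frame > 0):
            upstream = b.start < a.start if b.frame > 0 else b.end > a.end
        else:
            # opposite strands: no shared reading direction; fall back to
            # preferring the stop-free ORF only when it is the longer one
            upstream = b.aa_len > a.aa_len
        if upstream:
            return b
    return a


def annotate_orfs(contigs: Iterable[Contig]) -> None:
    """Attach the selected ORF to each contig in place."""
    for c in contigs:
        a, b = extract_orfs(c)
        c.orf = select_orf(a, b, len(c.seq))


def orf_length_filter(
    contigs: Sequence[Contig], min_aa: int = MIN_ORF_AA
) -> tuple[list[Contig], list[Contig]]:
    """Partition contigs on the selected ORF length; shorter than ``min_aa``
    is discarded (strict)."""
    kept: list[Contig] = []
    discarded: list[Contig] = []
    for c in contigs:
        if c.orf is None:
            a, b = extract_orfs(c)
            c.orf = select_orf(a, b, len(c.seq))
        if c.orf is not None and c.orf.aa_len >= min_aa:
            kept.append(c)
        else:
            discarded.append(c)
    return kept, discarded


@dataclass(slots=True)
class EvidenceTable:
    tags: dict[str, set[str]] = field(default_factory=dict)

    def add(self, contig_id: str, tag: str) -> None:
        if tag not in EVIDENCE_TAGS:
            raise ValueError(f"unknown evidence tag {tag!r}")
        self.tags.setdefault(contig_id, set()).add(tag)

    def get(self, contig_id: str) -> set[str]:
        return self.tags.get(contig_id, set())


def build_evidence(
    hit_sets: Mapping[str, Sequence[TabularHit]], max_evalue: float = EVIDENCE_EVALUE
) -> EvidenceTable:
    """Evidence tags from per-source tabular hits at the uniform e-value
    cutoff."""
    table = EvidenceTable()
    for tag, hits in hit_sets.items():
        for h in hits:
            if h.evalue <= max_evalue:
                table.add(h.query_id, tag)
    return table


@dataclass(slots=True)
class SelectionReport:
    n_input: int
    n_orf_pass: int
    n_final: int
    per_source: dict[str, int]
    n_core: int  # contigs tagged by all four proteomes


def select_final(
    contigs: Sequence[Contig], evidence: EvidenceTable, min_aa: int = MIN_ORF_AA
) -> tuple[list[Contig], SelectionReport]:
    """Final set: ORF >= ``min_aa`` aa AND at least one evidence tag."""
    orf_pass, _ = orf_length_filter(contigs, min_aa)
    final: list[Contig] = []
    per_source: dict[str, int] = {}
    n_core = 0
    for c in orf_pass:
        tags = evidence.get(c.id)
        c.evidence = tags
        if not tags:
            continue
        final.append(c)
        for t in tags:
            per_source[t] = per_source.get(t, 0) + 1
        if PROTEOME_TAGS <= tags:
            n_core += 1
    report = SelectionReport(len(contigs), len(orf_pass), len(final), per_source, n_core)
    return final, report


def n50(lengths: Sequence[int]) -> int:
    """The largest L such that contigs of length >= L hold at least half
    the total assembled bases."""
    if not lengths:
        raise ValueError("n50 of an empty length list")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")
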