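"""Minimal de Bruijn unitig assembler and the iterative assembly strategy.

The assembler proper is deliberately simple: canonical k-mers, a coverage
floor, and maximal non-branching paths (unitigs) — no bubble popping and no
paired-end scaffolding. The contribution it supports is the *iteration*
strategy: many exploratory assemblies at different k, an extra assembly of
reads left unused by a subset of them, then "summary" assemblies that
re-assemble all of those contigs (treated as reads, coverage floor 1) at a
few k values, and a final re-assembly that merges the summaries. Small k
recovers low-coverage transcripts, large k resolves repeats; the summary
stages union the strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import QualRead, SeqRecord, get_logger

logger = get_logger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(slots=True)
class AssemblyPlan:
    """Which k values to run at each stage of the iterative assembly."""

    exploratory_ks: Sequence[int] = (21, 25, 31, 35, 41, 49, 59)
    unused_read_k: int = 57
    unused_from_ks: Sequence[int] = (21, 35, 49, 59)
    summary_ks: Sequence[int] = (29, 39, 49)
    final_k: int = 39
    min_kmer_coverage: int = 2  # read-stage; summary stages always use 1

    def __post_init__(self) -> None:
        ks = [*self.exploratory_ks, self.unused_read_k, *self.summary_ks, self.final_k]
        if not self.exploratory_ks or not self.summary_ks:
            raise ValueError("k lists must be non-empty")
        for k in ks:
            if k % 2 == 0 or k < 15:
                raise ValueError(f"k must be odd and >= 15, got {k}")


@dataclass(slots=True)
class Contig:
    """An assembled or merged sequence with provenance."""

    id: str
    seq: str
    provenance: str = "assembled"  # est_joined, peptide_joined, n_scaffolded, unchanged
    source_ids: list[str] = field(default_factory=list)
    orf: object | None = None
    evidence: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.seq)

    def to_record(self) -> SeqRecord:
        return SeqRecord(self.id, self.seq, "nucleotide")


class DeBruijnGraph:
    """A de Bruijn graph over canonical k-mers with coverage counts."""

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError(f"k must be odd (palindrome avoidance), got {k}")
        self.k = k
        self.coverage: dict[str, int] = {}

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.coverage

    def __len__(self) -> int:
        return len(self.coverage)

    def add_sequence(self, seq: str) -> None:
        k = self.k
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            self.coverage[c] = self.coverage.get(c, 0) + 1

    def prune(self, min_coverage: int) -> None:
        if min_coverage > 1:
            self.coverage = {
                km: c for km, c in self.coverage.items() if c >= min_coverage
            }

    # oriented k-mer adjacency -------------------------------------------

    def successors(self, kmer: str) -> list[str]:
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if suffix + b in self]

    def predecessors(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in "ACGT" if b + prefix in self]


def build_graph(
    reads: Iterable[QualRead | SeqRecord | str], k: int, min_kmer_coverage: int = 2
) -> DeBruijnGraph:
    """Count canonical k-mers of the reads and drop those below the floor.

    k-mers containing N are skipped. Sequences shorter than k contribute
    nothing (a warning is logged once).
    """
    graph = DeBruijnGraph(k)
    n_short = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        if len(seq) < k:
            n_short += 1
            continue
        graph.add_sequence(seq)
    if n_short:
        logger.warning("build_graph(k=%d): skipped %d sequences shorter than k", k, n_short)
    graph.prune(min_kmer_coverage)
    return graph


def _unique_extension(graph: DeBruijnGraph, kmer: str) -> str | None:
    """The unique forward extension of an oriented k-mer, or None.

    x -> y is followed only when y is x's sole successor and x is y's sole
    predecessor (maximal non-branching path condition).
    """
    succ = graph.successors(kmer)
    if len(succ) != 1:
        return None
    nxt = succ[0]
    if len(graph.predecessors(nxt)) != 1:
        return None
    return nxt


def extract_unitigs(graph: DeBruijnGraph, id_prefix: str = "utg") -> list[Contig]:
    """Spell maximal non-branching paths, one per canonical k-mer class.

    Unitigs are reported in canonical orientation and sorted by sequence so
    output order is deterministic.
    """
    visited: set[str] = set()
    seqs: list[str] = []
    for start_c in graph.coverage:
        if start_c in visited:
            continue
        # walk left from the oriented start, then right, collecting the path
        path = [start_c]
        used = {start_c}
        # extend right
        cur = start_c
        while True:
            nxt = _unique_extension(graph, cur)
            if nxt is None or canonical(nxt) in used or canonical(nxt) in visited:
                break
            path.append(nxt)
            used.add(canonical(nxt))
            cur = nxt
        # extend left (walk right from the reverse complement of the start)
        cur = revcomp(start_c)
        left: list[str] = []
        while True:
            nxt = _unique_extension(graph, cur)
            if nxt is None or canonical(nxt) in used or canonical(nxt) in visited:
                break
            left.append(nxt)
            used.add(canonical(nxt))
            cur = nxt
        path = [revcomp(km) for km in reversed(left)] + path
        visited |= used
        seq = path[0] + "".join(km[-1] for km in path[1:])
        seqs.append(min(seq, revcomp(seq)))
    seqs.sort()
    return [
        Contig(f"{id_prefix}_{i:06d}", seq, provenance="assembled")
        for i, seq in enumerate(seqs)
    ]


def assemble(
    reads: Iterable[QualRead | SeqRecord | str],
    k: int,
    min_kmer_coverage: int = 2,
    id_prefix: str = "utg",
) -> list[Contig]:
    """One single-k assembly: graph construction followed by unitig extraction."""
    return extract_unitigs(build_graph(reads, k, min_kmer_coverage), id_prefix)


def assign_unused_reads(
    reads: Sequence[QualRead], contigs: Sequence[Contig], k: int
) -> list[QualRead]:
    """Reads none of whose k-mers occur in any contig (the 'unused' set)."""
    contig_kmers: set[str] = set()
    for c in contigs:
        seq = c.seq.upper()
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" not in km:
                contig_kmers.add(canonical(km))
    unused = []
    for read in reads:
        seq = read.seq.upper()
        n_kmers = len(seq) - k + 1
        if n_kmers <= 0:
            unused.append(read)
            continue
        if not any(
            canonical(seq[i : i + k]) in contig_kmers
            for i in range(n_kmers)
            if "N" not in seq[i : i + k]
        ):
            unused.append(read)
    return unused


def iterative_assemble(
    reads: Sequence[QualRead], plan: AssemblyPlan | None = None
) -> list[Contig]:
    """Run the full exploratory → unused-reads → summary assembly cascade.

    Exploratory assemblies run at each k in ``plan.exploratory_ks`` with the
    read-stage coverage floor. Reads untouched by the assemblies at
    ``plan.unused_from_ks`` are re-assembled once more at
    ``plan.unused_read_k``. All contigs from every stage so far are then
    k-merised as single observations (coverage floor 1) in summary
    assemblies at ``plan.summary_ks``, whose outputs are merged by one final
    assembly at ``plan.final_k``.

    Deterministic for a given input order.
    """
    plan = plan or AssemblyPlan()
    reads = list(reads)
    per_k: dict[int, list[Contig]] = {}
    for k in plan.exploratory_ks:
        per_k[k] = assemble(reads, k, plan.min_kmer_coverage, id_prefix=f"exp{k}")
        logger.info("exploratory k=%d: %d contigs", k, len(per_k[k]))
    pool: list[Contig] = [c for k in plan.exploratory_ks for c in per_k[k]]

    anchor = [c for k in plan.unused_from_ks if k in per_k for c in per_k[k]]
    unused = assign_unused_reads(reads, anchor, min(plan.unused_from_ks))
    if unused:
        unused_contigs = assemble(
            unused, plan.unused_read_k, plan.min_kmer_coverage, id_prefix="unused"
        )
        logger.info(
            "unused-read assembly k=%d: %d reads -> %d contigs",
            plan.unused_read_k, len(unused), len(unused_contigs),
        )
        pool.extend(unused_contigs)

    # the summary assemblies each consume the whole pool; their outputs are
    # merged by the final assembly
    summary_out: list[Contig] = []
    for k in plan.summary_ks:
        out = assemble(pool, k, min_kmer_coverage=1, id_prefix=f"sum{k}")
        logger.info("summary k=%d: %d contigs", k, len(out))
        summary_out.extend(out)
    final = assemble(summary_out, plan.final_k, min_kmer_coverage=1, id_prefix="contig")
    logger.info("final k=%d: %d contigs", plan.final_k, len(final))
    return final


def n_stats(lengths: Sequence[int]) -> dict[str, float]:
    """Total bp, contig count, longest, and N50 of an assembly."""
    from .contig_validation import n50

    if not lengths:
        return {"n_contigs": 0, "total_bp": 0, "max_len": 0, "n50": 0}
    return {
        "n_contigs": len(lengths),
        "total_bp": int(sum(lengths)),
        "max_len": int(max(lengths)),
        "n50": n50(lengths),
    }
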