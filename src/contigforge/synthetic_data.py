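"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the shape of a colony RNA-seq experiment: random
coding transcripts (ATG ... stop, uniform codon usage), a diverged
orthologous peptide set from a related species, transcript fragments
standing in for an under-merged assembly, conspecific ESTs spanning
fragment junctions, paired short reads at a chosen depth and error rate,
pileups with biallelic sites planted at a chosen per-base heterozygosity
(pool frequency 0.5), and per-transcript read counts for expression.

Defaults mirror the study conditions at desk scale: 75-bp paired reads
(the post-trim mapping length), 30x assembly coverage, 1% planted per-base
diversity, ~10% amino-acid divergence to the reference proteome with an
elevated-divergence "immune" category block. Read starts are stratified
(one uniform draw per coverage stratum, plus both transcript ends) so a
seed never leaves a coverage hole, which keeps exact-reconstruction
comparisons meaningful at any seed.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .aligners import revcomp, translate_frame
from .io_formats import PileupSite, QualRead, SeqRecord

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_READ_Q = 40


@dataclass(slots=True)
class SimConfig:
    seed: int = 0
    n_transcripts: int = 30
    len_range: tuple[int, int] = (402, 1500)  # nt, rounded to codons
    split_fraction: float = 0.5  # transcripts fragmented into two pieces
    fragment_overlap: int = 60  # nt shared by overlapping fragments
    fragment_gap: int = 30  # nt missing between gapped fragments
    est_fraction: float = 0.5  # of split transcripts that get a spanning EST
    read_len: int = 75
    depth: float = 30.0
    insert_len: int = 250
    error_rate: float = 0.001
    pileup_depth: int = 30
    planted_pi: float = 0.01
    ortholog_divergence: float = 0.10
    immune_divergence: float = 0.16
    n_categories: int = 6
    immune_category: str = "immune"

    def __post_init__(self) -> None:
        for rate in (self.split_fraction, self.est_fraction, self.error_rate, self.planted_pi):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.ortholog_divergence < 0.5:
            raise ValueError("ortholog divergence must lie in [0, 0.5)")


@dataclass(slots=True)
class GroundTruth:
    transcripts: list[SeqRecord] = field(default_factory=list)
    proteins: list[SeqRecord] = field(default_factory=list)
    orthologs: list[SeqRecord] = field(default_factory=list)  # diverged peptide set
    ortholog_pairs: dict[str, str] = field(default_factory=dict)  # transcript -> peptide
    fragments: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    ests: list[SeqRecord] = field(default_factory=list)
    est_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    categories: dict[str, set[str]] = field(default_factory=dict)
    snp_positions: dict[str, list[int]] = field(default_factory=dict)  # 1-based
    expression: dict[str, float] = field(default_factory=dict)
    read_counts: dict[str, int] = field(default_factory=dict)


def gen_transcriptome(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Random CDS transcripts (ATG ... stop) and their translations."""
    transcripts: list[SeqRecord] = []
    proteins: list[SeqRecord] = []
    lo, hi = cfg.len_range
    for i in range(cfg.n_transcripts):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        body = "".join(
            _SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
        )
        seq = "ATG" + body + _STOPS[int(rng.integers(0, 3))]
        tid = f"tx{i:04d}"
        transcripts.append(SeqRecord(tid, seq))
        proteins.append(SeqRecord(f"{tid}_p", translate_frame(seq, 1).rstrip("*"), "protein"))
    return transcripts, proteins


def gen_orthologs(
    proteins: Sequence[SeqRecord],
    divergence: float | Sequence[float],
    rng: np.random.Generator,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Per-site substituted copies of the proteins (the related species'
    peptide set) plus the true pairing. ``divergence`` may be per-protein."""
    if isinstance(divergence, (int, float)):
        divergence = [float(divergence)] * len(proteins)
    out: list[SeqRecord] = []
    pairs: dict[str, str] = {}
    for prot, d in zip(proteins, divergence):
        residues = list(prot.seq)
        flips = rng.random(len(residues)) < d
        for i in np.flatnonzero(flips):
            cur = residues[i]
            choices = [a for a in _AA if a != cur]
            residues[i] = choices[int(rng.integers(0, len(choices)))]
        pid = prot.id.replace("_p", "_ref")
        out.append(SeqRecord(pid, "".join(residues), "protein"))
        pairs[prot.id] = pid
    return out, pairs


def assign_categories(cfg: SimConfig, transcripts: Sequence[SeqRecord]) -> dict[str, set[str]]:
    """Block assignment: consecutive transcripts share a category; the first
    block is the elevated-divergence immune-like one."""
    cats: dict[str, set[str]] = {}
    block = max(1, len(transcripts) // cfg.n_categories)
    for i, t in enumerate(transcripts):
        idx = min(i // block, cfg.n_categories - 1)
        label = cfg.immune_category if idx == 0 else f"cat{idx:02d}"
        cats[t.id] = {label}
    return cats


def _stratified_starts(n: int, max_start: int, rng: np.random.Generator) -> np.ndarray:
    """n start positions: one uniform draw per equal stratum of
    [0, max_start], plus the two extremes — no seed can leave a wide gap."""
    if max_start <= 0:
        return np.zeros(max(n, 1), dtype=int)
    edges = np.linspace(0, max_start + 1, n + 1)
    starts = (edges[:-1] + rng.random(n) * np.diff(edges)).astype(int)
    # duplicate both extremes so terminal k-mers clear a coverage floor of 2
    starts[0] = starts[1] = 0
    starts[-2:] = max_start
    return np.clip(starts, 0, max_start)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < rate):
        arr[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(arr)


def gen_reads(
    transcripts: Sequence[SeqRecord], cfg: SimConfig, rng: np.random.Generator
) -> list[QualRead]:
    """Paired reads at ``cfg.depth`` with stratified fragment starts."""
    reads: list[QualRead] = []
    rl = cfg.read_len
    for t in transcripts:
        L = len(t.seq)
        insert = min(cfg.insert_len, L)
        n_pairs = max(4, int(round(L * cfg.depth / (2 * rl))))
        for j, s in enumerate(_stratified_starts(n_pairs, L - insert, rng)):
            frag = t.seq[s : s + insert]
            r1 = _mutate(frag[:rl], cfg.error_rate, rng)
            r2 = _mutate(revcomp(frag[-rl:]), cfg.error_rate, rng)
            quals = [_READ_Q] * rl
            reads.append(QualRead(f"{t.id}_r{j:05d}", r1, list(quals), 1))
            reads.append(QualRead(f"{t.id}_r{j:05d}", r2, list(quals), 2))
    return reads


def gen_fragments(
    transcripts: Sequence[SeqRecord], cfg: SimConfig, rng: np.random.Generator, truth: GroundTruth
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Split a fraction of transcripts into two fragments and give some of
    the split transcripts a junction-spanning EST.

    Odd split transcripts get overlapping fragments, even ones gapped
    fragments, so both peptide-stage join rules are exercised when no EST
    claims the pair first.
    """
    fragments: list[SeqRecord] = []
    ests: list[SeqRecord] = []
    n_split = 0
    for t in transcripts:
        L = len(t.seq)
        split = rng.random() < cfg.split_fraction and L >= 6 * cfg.fragment_overlap
        if not split:
            fragments.append(SeqRecord(f"{t.id}_f0", t.seq))
            truth.fragments[f"{t.id}_f0"] = (t.id, 0, L)
            continue
        mid = L // 2
        if n_split % 2 == 0:
            a_end = mid + cfg.fragment_overlap // 2
            b_start = mid - cfg.fragment_overlap // 2
        else:
            a_end = mid - cfg.fragment_gap // 2
            b_start = mid + cfg.fragment_gap // 2
        f1 = SeqRecord(f"{t.id}_f0", t.seq[:a_end])
        f2 = SeqRecord(f"{t.id}_f1", t.seq[b_start:])
        fragments.extend([f1, f2])
        truth.fragments[f1.id] = (t.id, 0, a_end)
        truth.fragments[f2.id] = (t.id, b_start, L)
        if rng.random() < cfg.est_fraction:
            margin = L // 8
            est = SeqRecord(f"{t.id}_est", t.seq[margin : L - margin])
            ests.append(est)
            truth.est_spans[est.id] = (t.id, margin, L - margin)
        n_split += 1
    return fragments, ests


def gen_pileups(
    transcripts: Sequence[SeqRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> list[PileupSite]:
    """Uniform-depth pileups with biallelic sites planted at
    ``cfg.planted_pi`` (pool frequency 0.5) and per-read errors."""
    sites: list[PileupSite] = []
    d = cfg.pileup_depth
    for t in transcripts:
        seq = t.seq.upper()
        L = len(seq)
        het = rng.random(L) < cfg.planted_pi
        alt_counts = rng.binomial(d, 0.5, size=L)
        n_err = rng.binomial(d, cfg.error_rate, size=L)
        if truth is not None:
            truth.snp_positions[t.id] = [int(i) + 1 for i in np.flatnonzero(het)]
        for i in range(L):
            ref = seq[i]
            counts = {ref: d}
            if het[i]:
                k = int(alt_counts[i])
                if k:
                    alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
                    counts[ref] = d - k
                    counts[alt] = k
                    if counts[ref] == 0:
                        del counts[ref]
            for _ in range(int(n_err[i])):
                base = "ACGT"[int(rng.integers(0, 4))]
                victim = max(counts, key=counts.get)
                if base != victim and counts.get(victim, 0) > 0:
                    counts[victim] -= 1
                    counts[base] = counts.get(base, 0) + 1
                    if counts[victim] == 0:
                        del counts[victim]
            sites.append(PileupSite(t.id, i + 1, ref, d, counts))
    return sites


def gen_read_counts(
    transcripts: Sequence[SeqRecord], rng: np.random.Generator, truth: GroundTruth | None = None
) -> dict[str, int]:
    """Per-transcript read counts from log-normal expression levels."""
    counts: dict[str, int] = {}
    for t in transcripts:
        expr = float(rng.lognormal(mean=2.0, sigma=1.0))
        c = int(rng.poisson(expr * len(t.seq) / 100.0))
        counts[t.id] = c
        if truth is not None:
            truth.expression[t.id] = expr
            truth.read_counts[t.id] = c
    return counts


def simulate(cfg: SimConfig) -> tuple[GroundTruth, list[QualRead], list[SeqRecord], list[PileupSite]]:
    """Full fixture: ground truth, reads, fragments (with ESTs and
    orthologous peptides recorded on the truth object), and pileups."""
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    truth.transcripts, truth.proteins = gen_transcriptome(cfg, rng)
    truth.categories = assign_categories(cfg, truth.transcripts)
    divergences = [
        cfg.immune_divergence
        if truth.categories[p.id.replace("_p", "")] == {cfg.immune_category}
        else cfg.ortholog_divergence
        for p in truth.proteins
    ]
    truth.orthologs, truth.ortholog_pairs = gen_orthologs(truth.proteins, divergences, rng)
    fragments, truth.ests = gen_fragments(truth.transcripts, cfg, rng, truth)
    reads = gen_reads(truth.transcripts, cfg, rng)
    pileups = gen_pileups(truth.transcripts, cfg, rng, truth)
    gen_read_counts(truth.transcripts, rng, truth)
    return truth, reads, fragments, pileups


def write_fixture(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Emit the full fixture to disk (FASTA/FASTQ/pileup/TSV + truth JSON)."""
    from . import io_formats as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, reads, fragments, pileups = simulate(cfg)
    io.write_fastq([r for r in reads if r.mate == 1], outdir / "reads_1.fastq")
    io.write_fastq([r for r in reads if r.mate == 2], outdir / "reads_2.fastq")
    io.write_fasta(truth.transcripts, outdir / "transcripts.fasta")
    io.write_fasta(fragments, outdir / "fragments.fasta")
    io.write_fasta(truth.ests, outdir / "ests.fasta")
    io.write_fasta(truth.orthologs, outdir / "peptides.fasta")
    io.write_pileup(pileups, outdir / "sites.pileup")
    with open(outdir / "categories.tsv", "w") as fh:
        for tid, cats in sorted(truth.categories.items()):
            for cat in sorted(cats):
                fh.write(f"{tid}\t{cat}\n")
    with open(outdir / "read_counts.tsv", "w") as fh:
        for tid, c in sorted(truth.read_counts.items()):
            fh.write(f"{tid}\t{c}\n")
    serializable = asdict(truth)
    for key in ("transcripts", "proteins", "orthologs", "ests"):
        serializable[key] = [{"id": r.id, "seq": r.seq} for r in getattr(truth, key)]
    serializable["categories"] = {k: sorted(v) for k, v in truth.categories.items()}
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1)
    return truth
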