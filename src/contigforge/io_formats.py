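"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; the pileup and
tabular-hit dialects are 1-based inclusive and are converted only at
these format boundaries.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

PHRED_OFFSET = 33
#: highest quality char accepted before warning of a suspected Phred+64 file
_MAX_SANE_QUAL_CHAR = "J"


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


def get_logger(name: str = "contigforge") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


logger = get_logger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass(slots=True)
class QualRead:
    """A sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    quals: list[int]
    mate: int = 0  # 1, 2 or 0 for unpaired

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.seq)} bases but {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class SeqRecord:
    """A named nucleotide or protein sequence."""

    id: str
    seq: str
    kind: str = "nucleotide"  # or "protein"; empty seq allowed for edge cases

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class TabularHit:
    """One local-alignment match in the 12-column tabular dialect.

    Coordinates are 1-based inclusive as in the dialect; ``minus`` records
    whether the target coordinates arrived reversed (minus-strand hit)
    before normalisation to t_start <= t_end.
    """

    query_id: str
    target_id: str
    raw_score: float
    evalue: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    frame: int = 0
    minus: bool = False

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.raw_score <= 0:
            raise ValueError("raw_score must be > 0")


@dataclass(slots=True)
class PileupSite:
    """One reference position with MAPQ-filtered base counts."""

    contig_id: str
    pos: int  # 1-based, as in the dialect
    ref_base: str
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)
    indel_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pileup positions are 1-based")
        if sum(self.base_counts.values()) + sum(self.indel_counts.values()) > self.depth:
            raise ValueError(
                f"{self.contig_id}:{self.pos}: counts exceed depth {self.depth}"
            )


# ---------------------------------------------------------------------------
# helpers


def phred_error_rate(q: float) -> float:
    """Expected per-base error rate for Phred score ``q``: 10^(-q/10)."""
    return 10.0 ** (-q / 10.0)


def _open(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ (Sanger, Phred+33)


def read_fastq(path: str | Path) -> Iterator[QualRead]:
    """Stream Phred+33 FASTQ records.

    Mate numbers are recovered from ``/1``-``/2`` id suffixes when present.
    A malformed 4-line block raises :class:`ParseError` naming the line.
    """
    with _open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {header!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not seq:
                raise ParseError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}:{lineno}: sequence/quality length mismatch"
                )
            if any(c < "!" for c in qual):
                raise ParseError(f"{path}:{lineno}: quality char below '!' — not Phred+33")
            if all(c > _MAX_SANE_QUAL_CHAR for c in qual):
                logger.warning(
                    "%s:%d: all quality chars above %r; input may be Phred+64 "
                    "(only Phred+33 is supported)",
                    path, lineno, _MAX_SANE_QUAL_CHAR,
                )
            rid = header[1:].split()[0]
            mate = 0
            if rid.endswith("/1"):
                rid, mate = rid[:-2], 1
            elif rid.endswith("/2"):
                rid, mate = rid[:-2], 2
            yield QualRead(rid, seq, [ord(c) - PHRED_OFFSET for c in qual], mate)


def write_fastq(reads: Iterable[QualRead], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            suffix = f"/{r.mate}" if r.mate else ""
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            fh.write(f"@{r.id}{suffix}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SeqRecord]:
    with _open(path) as fh:
        return [SeqRecord(rec.id, str(rec.seq).upper(), kind) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    bio = (BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# samtools-style text pileup

_INDEL_CHARS = "+-"


def _decode_pileup_bases(
    bases: str, quals: str, mapqs: list[int], ref: str, min_mapq: int
) -> tuple[dict[str, int], dict[str, int], int]:
    """Decode one pileup base string into per-base and per-indel counts.

    Returns (base_counts, indel_counts, n_read_bases). Reads whose MAPQ is
    below ``min_mapq`` are excluded from the counts but still advance the
    per-read cursor (so depth stays interpretable).
    """
    base_counts: dict[str, int] = {}
    indel_counts: dict[str, int] = {}
    i = 0
    read_idx = 0
    n = len(bases)
    ref = ref.upper()
    prev_base: str | None = None  # last counted base, retracted if an indel attaches
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # read start; next char is the read's mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in _INDEL_CHARS:
            # +NNseq / -NNseq, attached to the preceding read; that read is
            # tallied as indel support only (counts stay within depth)
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            length = int(bases[i + 1 : j])
            indel = c + bases[j : j + length].upper()
            prev_mapq = mapqs[read_idx - 1] if read_idx > 0 else 0
            if prev_mapq >= min_mapq:
                indel_counts[indel] = indel_counts.get(indel, 0) + 1
                if prev_base is not None:
                    base_counts[prev_base] -= 1
                    if base_counts[prev_base] == 0:
                        del base_counts[prev_base]
            i = j + length
            prev_base = None
            continue
        # an actual read base column
        mq = mapqs[read_idx] if read_idx < len(mapqs) else 0
        if c in ".,":
            base = ref
        elif c == "*":
            base = None  # deleted base placeholder: occupies depth, counts nothing
        else:
            base = c.upper()
        prev_base = None
        if base is not None and mq >= min_mapq:
            base_counts[base] = base_counts.get(base, 0) + 1
            prev_base = base
        read_idx += 1
        i += 1
    return base_counts, indel_counts, read_idx


def read_pileup(
    path: str | Path, min_mapq: int = 20, default_mapq: int | None = None
) -> Iterator[PileupSite]:
    """Stream sites from a samtools-style text pileup.

    Columns: contig, pos, ref, depth, bases, base-quals and, optionally, a
    seventh column of per-read mapping qualities (Phred+33 chars, as emitted
    by ``samtools mpileup -s``). Without that column every read is assumed
    to have ``default_mapq`` (required then).
    """
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 pileup columns")
            contig, pos_s, ref, depth_s = fields[:4]
            bases, quals = fields[4], fields[5]
            depth = int(depth_s)
            if depth == 0:
                yield PileupSite(contig, int(pos_s), ref.upper(), 0)
                continue
            if len(fields) >= 7:
                mapqs = [ord(c) - PHRED_OFFSET for c in fields[6]]
            else:
                if default_mapq is None:
                    raise ParseError(
                        f"{path}:{lineno}: no MAPQ column and no default_mapq given"
                    )
                mapqs = [default_mapq] * depth
            base_counts, indel_counts, n_bases = _decode_pileup_bases(
                bases, quals, mapqs, ref, min_mapq
            )
            if n_bases != depth:
                raise ParseError(
                    f"{path}:{lineno}: depth {depth} but {n_bases} read bases decoded"
                )
            yield PileupSite(contig, int(pos_s), ref.upper(), depth, base_counts, indel_counts)


def write_pileup(sites: Iterable[PileupSite], path: str | Path, mapq: int = 60) -> None:
    """Write sites back to the text dialect (constant MAPQ/baseQ columns)."""
    with _open(path, "wt") as fh:
        for s in sites:
            parts: list[str] = []
            mq_chars: list[str] = []
            n = 0
            for base, count in sorted(s.base_counts.items()):
                parts.append(("." if base == s.ref_base else base) * count)
                mq_chars.append(chr(mapq + PHRED_OFFSET) * count)
                n += count
            for indel, count in sorted(s.indel_counts.items()):
                # carrier read per indel: '*' occupies depth without a base count
                parts.append(f"*{indel[0]}{len(indel) - 1}{indel[1:]}" * count)
                mq_chars.append(chr(mapq + PHRED_OFFSET) * count)
                n += count
            # remaining depth: reads that failed the MAPQ filter, written at MAPQ 0
            hidden = s.depth - n
            parts.append("." * hidden)
            mq_chars.append(chr(PHRED_OFFSET) * hidden)
            bases = "".join(parts)
            quals = chr(40 + PHRED_OFFSET) * s.depth
            mapqs = "".join(mq_chars)
            fh.write(
                f"{s.contig_id}\t{s.pos}\t{s.ref_base}\t{s.depth}\t{bases}\t{quals}\t{mapqs}\n"
            )


# ---------------------------------------------------------------------------
# 12-column tabular hits (outfmt-6 dialect)

_TAB_COLUMNS = 12


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Read a 12-column tab-separated hit file.

    Column order follows the common dialect: query, target, pct-identity,
    aln-length, mismatches, gap-opens, q_start, q_end, t_start, t_end,
    e-value, score. Reversed target coordinates mark a minus-strand hit:
    they are normalised and the orientation kept in ``minus``.
    """
    hits: list[TabularHit] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _TAB_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_TAB_COLUMNS} columns, got {len(cols)}"
                )
            t_start, t_end = int(cols[8]), int(cols[9])
            minus = t_start > t_end
            frame = 0
            if minus:
                t_start, t_end = t_end, t_start
                frame = -1
            hits.append(
                TabularHit(
                    query_id=cols[0],
                    target_id=cols[1],
                    raw_score=float(cols[11]),
                    evalue=float(cols[10]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    t_start=t_start,
                    t_end=t_end,
                    frame=frame,
                    minus=minus,
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for h in hits:
            t_start, t_end = h.t_start, h.t_end
            if h.minus:
                t_start, t_end = t_end, t_start
            aln_len = h.q_end - h.q_start + 1
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            h.query_id, h.target_id, "0.0", aln_len, 0, 0,
                            h.q_start, h.q_end, t_start, t_end,
                            f"{h.evalue:.2g}", f"{h.raw_score:g}",
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# annotation tables and run configuration


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV mapping contig id -> category label (many rows per id)."""
    out: dict[str, set[str]] = {}
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, cat = line.split("\t")[:2]
            out.setdefault(cid, set()).add(cat)
    return out


def load_config(path: str | Path) -> dict:
    with _open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
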