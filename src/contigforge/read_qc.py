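"""Read filters and trimming applied before assembly and before mapping.

Three rules, each with a strict ("more than") boundary:

* quality filter — drop a read when more than 33% of its bases are N, or
  more than 34% of its bases have Phred quality below 20;
* poly-A filter — drop a read when more than 33% of its bases are A
  (suspected poly-adenine tail);
* fixed-length tail trim — keep only the first ``keep_len`` bases (used to
  cut the error-prone cycles 76-87 of 87-bp reads down to 75 bp).

Fractions are computed on the full read length, case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import QualRead

MAX_N_FRAC = 0.33
MAX_LOWQ_FRAC = 0.34
MIN_Q = 20
MAX_A_FRAC = 0.33


@dataclass(slots=True)
class QCReport:
    n_input: int = 0
    n_removed_quality: int = 0
    n_removed_polya: int = 0
    n_trimmed: int = 0
    n_passed: int = 0

    def __post_init__(self) -> None:
        if self.n_passed != self.n_input - self.n_removed_quality - self.n_removed_polya:
            raise ValueError("QC counts do not reconcile")


def quality_filter(
    read: QualRead,
    max_n_frac: float = MAX_N_FRAC,
    max_lowq_frac: float = MAX_LOWQ_FRAC,
    min_q: int = MIN_Q,
) -> bool:
    """True when the read passes (is kept). Boundaries are strict."""
    n = len(read)
    n_frac = read.seq.upper().count("N") / n
    lowq_frac = sum(1 for q in read.quals if q < min_q) / n
    return not (n_frac > max_n_frac or lowq_frac > max_lowq_frac)


def polya_filter(read: QualRead, max_a_frac: float = MAX_A_FRAC) -> bool:
    """True when the read passes. Counts A only (not T); strict boundary."""
    return read.seq.upper().count("A") / len(read) <= max_a_frac


def trim_tail(read: QualRead, keep_len: int) -> QualRead:
    """Return the first ``keep_len`` bases; shorter reads pass unchanged."""
    if keep_len <= 0:
        raise ValueError(f"keep_len must be positive, got {keep_len}")
    if len(read) <= keep_len:
        return read
    return QualRead(read.id, read.seq[:keep_len], read.quals[:keep_len], read.mate)


def apply_qc(
    reads: Iterable[QualRead],
    trim_to: int | None = None,
    drop_pairs: bool = False,
    max_n_frac: float = MAX_N_FRAC,
    max_lowq_frac: float = MAX_LOWQ_FRAC,
    min_q: int = MIN_Q,
    max_a_frac: float = MAX_A_FRAC,
) -> tuple[list[QualRead], QCReport]:
    """Run both filters then the trim over a read stream.

    A read failing both filters is tallied against the quality filter only,
    so the report reconciles exactly. With ``drop_pairs`` both mates of a
    pair are removed when either fails (mates are matched by read id).
    """
    kept: list[QualRead] = []
    n_input = n_rm_q = n_rm_a = n_trim = 0
    failed_ids: set[str] = set()
    decisions: list[tuple[QualRead, str]] = []
    for read in reads:
        n_input += 1
        if not quality_filter(read, max_n_frac, max_lowq_frac, min_q):
            decisions.append((read, "quality"))
            failed_ids.add(read.id)
        elif not polya_filter(read, max_a_frac):
            decisions.append((read, "polya"))
            failed_ids.add(read.id)
        else:
            decisions.append((read, "pass"))
    for read, verdict in decisions:
        if verdict == "quality":
            n_rm_q += 1
            continue
        if verdict == "polya":
            n_rm_a += 1
            continue
        if drop_pairs and read.mate and read.id in failed_ids:
            n_rm_q += 1  # charged to the mate's failure category is ambiguous; count as quality
            continue
        if trim_to is not None and len(read) > trim_to:
            read = trim_tail(read, trim_to)
            n_trim += 1
        kept.append(read)
    report = QCReport(
        n_input=n_input,
        n_removed_quality=n_rm_q,
        n_removed_polya=n_rm_a,
        n_trimmed=n_trim,
        n_passed=n_input - n_rm_q - n_rm_a,
    )
    return kept, report
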