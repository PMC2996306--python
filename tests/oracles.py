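"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive — enumeration or a direct transcription
of a definition — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from typing import Sequence

_COMP = str.maketrans("ACGTN", "TGCAN")

CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    i = 0
    for a in bases:
        for b in bases:
            for c in bases:
                CODON_TABLE[a + b + c] = aas[i]
                i += 1


_build_codon_table()


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# exhaustive global alignment with affine gaps


def brute_force_global_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> float:
    """Enumerate every gapped alignment of a and b and return the best
    affine-gap score. Exponential; only for short sequences."""

    def score_alignment(ga: str, gb: str) -> float:
        s = 0.0
        in_gap_a = in_gap_b = False
        for x, y in zip(ga, gb):
            if x == "-":
                s += gap_extend if in_gap_a else gap_open
                in_gap_a, in_gap_b = True, False
            elif y == "-":
                s += gap_extend if in_gap_b else gap_open
                in_gap_b, in_gap_a = True, False
            else:
                s += match if x == y else mismatch
                in_gap_a = in_gap_b = False
        return s

    best = float("-inf")

    def rec(i: int, j: int, ga: str, gb: str):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_alignment(ga, gb))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ga + a[i], gb + b[j])
        if i < len(a):
            rec(i + 1, j, ga + a[i], gb + "-")
        if j < len(b):
            rec(i, j + 1, ga + "-", gb + b[j])

    rec(0, 0, "", "")
    return best


# ---------------------------------------------------------------------------
# six-frame ORF scan


def six_frame_orfs(seq: str) -> tuple[tuple[int, str] | None, tuple[int, str] | None]:
    """(best type A, best type B) as (aa_len, protein), by regex-style scan
    over all six frames in order +1,+2,+3,-1,-2,-3."""
    best_a = best_b = None
    for frame in (1, 2, 3, -1, -2, -3):
        s = seq.upper() if frame > 0 else rc(seq.upper())
        prot = translate(s[abs(frame) - 1 :])
        # type B: stop-free stretches
        for chunk in prot.split("*"):
            if chunk and (best_b is None or len(chunk) > best_b[0]):
                best_b = (len(chunk), chunk)
        # type A: M .. * (first M of each stop-delimited block, greedy scan)
        i = 0
        while i < len(prot):
            if prot[i] == "M":
                j = prot.find("*", i)
                if j == -1:
                    break
                cand = prot[i:j]
                if best_a is None or len(cand) > best_a[0]:
                    best_a = (len(cand), cand)
                i = j + 1
            else:
                i += 1
    return best_a, best_b


# ---------------------------------------------------------------------------
# N50 by the cumulative-sum definition


def n50_brute(lengths: Sequence[int]) -> int:
    total = sum(lengths)
    best = 0
    for L in set(lengths):
        covered = sum(x for x in lengths if x >= L)
        if covered * 2 >= total and L > best:
            best = L
    return best


# ---------------------------------------------------------------------------
# exact Mann-Whitney by enumerating rank splits


def mannwhitney_exact(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """U for sample a and the exact two-sided p by full enumeration of all
    C(n_a+n_b, n_a) assignments (no ties supported)."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), n_a):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        us.append(sum(1 for x in xs for y in ys if x > y))
    mean_u = n_a * (n - n_a) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return float(u_obs), extreme / len(us)


# ---------------------------------------------------------------------------
# chi-square statistic straight from the definition


def chi2_stat(observed: Sequence[float], expected: Sequence[float]) -> float:
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))
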