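"""Secondary-structure prediction for candidate pre-miRNA hairpins.

A weighted Nussinov dynamic program maximises the sum of pair weights
(GC: 3, AU: 2, GU: 1) over all nested structures with a minimum hairpin
loop, and a structural gate (``is_hairpin``) decides whether the optimal
structure looks like a pre-miRNA: enough pairs, at least half the bases
paired, and a single terminal loop. This plays the role of a thermodynamic
folder used purely as a binary hairpin filter; scores are in arbitrary
weight units, not kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .util import revcomp

DEFAULT_PAIR_WEIGHTS = {"GC": 3, "AU": 2, "GU": 1}
DEFAULT_MIN_LOOP = 3
DEFAULT_HAIRPIN_CRITERIA = {
    "min_pairs": 16,
    "min_paired_fraction": 0.5,
    "max_terminal_loops": 1,
}
DEFAULT_FLANK_LONG = 70
DEFAULT_FLANK_SHORT = 20
MIN_WINDOW_LEN = 40


@dataclass
class FoldResult:
    sequence: str
    dot_bracket: str
    score: float
    pairs: list[tuple[int, int]]
    n_terminal_loops: int
    paired_fraction: float
    max_stem_run: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _weight_matrix(seq: str, pair_weights: dict[str, int]) -> np.ndarray:
    """w[i, j] = weight of pairing bases i and j (0 when not complementary)."""
    table = {}
    for pair, w in pair_weights.items():
        a, b = pair[0], pair[1]
        a = "T" if a == "U" else a
        b = "T" if b == "U" else b
        table[(a, b)] = w
        table[(b, a)] = w
    n = len(seq)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            w[i, j] = table.get((seq[i], seq[j]), 0)
    return w


def fold(
    sequence: str,
    pair_weights: dict[str, int] | None = None,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> FoldResult:
    """Maximum-weight nested structure of ``sequence`` (ACGT/ACGU).

    The traceback is deterministic: when closing a subsequence, pairing the
    first base is preferred over leaving it unpaired, and among equally
    scoring partners the smallest index wins.
    """
    seq = sequence.upper().replace("U", "T")
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must be non-empty ACGU/ACGT")
    pair_weights = pair_weights or DEFAULT_PAIR_WEIGHTS
    n = len(seq)
    w = _weight_matrix(seq, pair_weights)
    W = np.zeros((n + 1, n + 1))  # W[i, j] over inclusive span i..j; i > j -> 0

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            ks = np.arange(i + min_loop + 1, j + 1)
            wi = w[i, ks]
            mask = wi > 0
            if mask.any():
                ks_v = ks[mask]
                inner = W[i + 1, ks_v - 1]
                after = np.where(ks_v < j, W[np.minimum(ks_v + 1, j), j], 0.0)
                best = max(best, float(np.max(wi[mask] + inner + after)))
            W[i, j] = best

    # deterministic traceback
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or W[i, j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if w[i, k] <= 0:
                continue
            after = W[k + 1, j] if k < j else 0.0
            if w[i, k] + W[i + 1, k - 1] + after == W[i, j]:
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                if k < j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    pairs.sort()
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    dot_bracket = "".join(db)
    return FoldResult(
        sequence=sequence,
        dot_bracket=dot_bracket,
        score=float(W[0, n - 1]) if n > 1 else 0.0,
        pairs=pairs,
        n_terminal_loops=count_terminal_loops(dot_bracket),
        paired_fraction=2 * len(pairs) / n,
        max_stem_run=_max_stem_run(pairs),
    )


def count_terminal_loops(dot_bracket: str) -> int:
    """Number of hairpin loops: '(' whose next bracket is the matching ')'."""
    count = 0
    prev = ""
    for c in dot_bracket:
        if c == ")" and prev == "(":
            count += 1
        if c in "()":
            prev = c
    return count


def _max_stem_run(pairs: list[tuple[int, int]]) -> int:
    if not pairs:
        return 0
    best = run = 1
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if i1 == i0 + 1 and j1 == j0 - 1:
            run += 1
            best = max(best, run)
        else:
            run = 1
    return best


def is_hairpin(result: FoldResult, criteria: dict | None = None) -> bool:
    """Does the optimal structure look like a single pre-miRNA hairpin?"""
    c = dict(DEFAULT_HAIRPIN_CRITERIA)
    if criteria:
        c.update(criteria)
    return (
        result.n_pairs >= c["min_pairs"]
        and result.paired_fraction >= c["min_paired_fraction"]
        and 1 <= result.n_terminal_loops <= c["max_terminal_loops"]
    )


@dataclass
class CandidateWindow:
    """A genomic window around a tag hit, oriented 5'->3' on the tag strand."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    arm_hint: str  # 'five_prime' or 'three_prime': which arm the tag is assumed on


def extract_candidate_windows(
    genome: dict[str, str],
    hit,
    flank_long: int = DEFAULT_FLANK_LONG,
    flank_short: int = DEFAULT_FLANK_SHORT,
) -> list[CandidateWindow]:
    """Two precursor-sized windows around a genomic tag hit.

    One window assumes the tag sits on the 5' arm (short upstream flank,
    long downstream), the other the 3' arm (mirrored); up/downstream are in
    the tag's transcriptional orientation, so the genomic picture flips on
    the − strand and window sequences are reverse-complemented there.
    Windows clipped below 40 nt at chromosome edges are dropped.
    """
    chrom_seq = genome[hit.ref_name]
    out = []
    for arm_hint, up, down in (
        ("five_prime", flank_short, flank_long),
        ("three_prime", flank_long, flank_short),
    ):
        if hit.strand == "+":
            s, e = hit.start - up, hit.end + down
        else:
            s, e = hit.start - down, hit.end + up
        s, e = max(0, s), min(len(chrom_seq), e)
        if e - s < MIN_WINDOW_LEN:
            continue
        seq = chrom_seq[s:e]
        if hit.strand == "-":
            seq = revcomp(seq)
        out.append(CandidateWindow(hit.ref_name, s, e, hit.strand, seq, arm_hint))
    return out


DEFAULT_GATE_LENGTHS = tuple(range(46, 68, 3))
GATE_UPSTREAM_SLACK = 3


@dataclass
class HairpinCall:
    """Outcome of the hairpin gate on one candidate window."""

    passed: bool
    span: tuple[int, int]  # window-local interval of the best subwindow
    fold_result: FoldResult


def tag_offset_in_window(window: CandidateWindow, hit) -> int:
    """Start of the tag within the window's oriented sequence."""
    if window.strand == "+":
        return hit.start - window.start
    return window.end - hit.end


def gate_hairpin_in_window(
    window: CandidateWindow,
    hit,
    criteria: dict | None = None,
    lengths: tuple[int, ...] = DEFAULT_GATE_LENGTHS,
    slack: int = GATE_UPSTREAM_SLACK,
) -> HairpinCall:
    """Hairpin gate: fold precursor-sized subwindows anchored at the tag.

    A pre-miRNA is at most ~65 nt, so hairpin-ness is judged on
    precursor-length subwindows starting just upstream of the tag (5'-arm
    hypothesis) or ending just downstream of it (3'-arm hypothesis), rather
    than on the full flanked window, whose unrelated flanking sequence
    would otherwise dominate the optimal structure. The gate passes when
    any subwindow's optimal fold satisfies ``is_hairpin``; the best-scoring
    subwindow (preferring passing ones) is reported.
    """
    seq = window.sequence
    tag_len = hit.end - hit.start
    t0 = tag_offset_in_window(window, hit)
    best: HairpinCall | None = None
    for length in lengths:
        if window.arm_hint == "five_prime":
            a = max(0, t0 - slack)
            b = min(len(seq), a + length)
        else:
            b = min(len(seq), t0 + tag_len + slack)
            a = max(0, b - length)
        if b - a < MIN_WINDOW_LEN:
            continue
        fr = fold(seq[a:b])
        ok = is_hairpin(fr, criteria)
        call = HairpinCall(ok, (a, b), fr)
        if best is None or (ok, fr.score) > (best.passed, best.fold_result.score):
            best = call
    if best is None:
        fr = fold(seq)
        return HairpinCall(False, (0, len(seq)), fr)
    return best


def format_fold_report(result: FoldResult) -> str:
    """Plain-text display: sequence over dot-bracket plus the score."""
    return f"{result.sequence}\n{result.dot_bracket}\nscore={result.score:g}"
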