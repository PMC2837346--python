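"""Stochastic context-free grammar filter for pre-miRNA candidates.

A hairpin is modelled as a stem interrupted by symmetric and asymmetric
bulges and closed by a terminal loop. The grammar below captures exactly
that decomposition with five nonterminals:

    S         -> Stem
    Stem      -> a Stem b | a SymBulge b | a AsymBulge | AsymBulge b | Loop
    SymBulge  -> a SymBulge b | Stem
    AsymBulge -> a AsymBulge | AsymBulge b | Stem
    Loop      -> a Loop | a

Pair emissions (a ... b) range over all 16 base combinations so every
sequence has nonzero probability; production probabilities are learned from
known hairpins by parsing their dot-bracket structures into the unique
corresponding state path and counting rule usage. Candidates are scored by
the inside algorithm (total log probability over all derivations, natural
log), length-normalised, and passed when the score exceeds a cutoff
calibrated as a specificity quantile on dinucleotide-shuffled negatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .util import spawn_rng

BASES = "ACGT"
NEG_INF = float("-inf")

#: production = (lhs, left_emission or '', rhs nonterminal or '', right_emission or '')
Production = tuple[str, str, str, str]


def _norm_base(b: str) -> str:
    return "T" if b == "U" else b


def default_production_set() -> list[Production]:
    prods: list[Production] = [("S", "", "Stem", "")]
    for a in BASES:
        for b in BASES:
            prods.append(("Stem", a, "Stem", b))
            prods.append(("Stem", a, "SymBulge", b))
            prods.append(("SymBulge", a, "SymBulge", b))
    for a in BASES:
        prods.append(("Stem", a, "AsymBulge", ""))
        prods.append(("Stem", "", "AsymBulge", a))
        prods.append(("AsymBulge", a, "AsymBulge", ""))
        prods.append(("AsymBulge", "", "AsymBulge", a))
        prods.append(("Loop", a, "Loop", ""))
        prods.append(("Loop", a, "", ""))
    prods.append(("Stem", "", "Loop", ""))
    prods.append(("SymBulge", "", "Stem", ""))
    prods.append(("AsymBulge", "", "Stem", ""))
    return prods


@dataclass
class Grammar:
    """An SCFG as a map production -> probability, start symbol S."""

    probabilities: dict[Production, float]
    start: str = "S"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def nonterminals(self) -> list[str]:
        return sorted({p[0] for p in self.probabilities})

    def validate(self) -> None:
        sums: dict[str, float] = {}
        for (lhs, _, rhs, _), p in self.probabilities.items():
            if p < 0:
                raise ValueError(f"negative probability for {lhs}")
            sums[lhs] = sums.get(lhs, 0.0) + p
        for lhs, total in sums.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"probabilities of {lhs} sum to {total}, not 1")
        # reachability from the start symbol
        reached = {self.start}
        frontier = [self.start]
        while frontier:
            v = frontier.pop()
            for (lhs, _, rhs, _), p in self.probabilities.items():
                if lhs == v and rhs and p > 0 and rhs not in reached:
                    reached.add(rhs)
                    frontier.append(rhs)
        unreachable = {
            lhs for (lhs, _, _, _), p in self.probabilities.items()
            if p > 0 and lhs not in reached
        }
        if unreachable:
            raise ValueError(f"nonterminals unreachable from start: {sorted(unreachable)}")

    def same_span_order(self) -> list[str]:
        """Nonterminal order such that non-emitting rules point backwards."""
        nts = self.nonterminals
        deps = {v: set() for v in nts}
        for (lhs, a, rhs, b), p in self.probabilities.items():
            if p > 0 and rhs and not a and not b and rhs != lhs:
                deps[lhs].add(rhs)
        order: list[str] = []
        temp: set[str] = set()

        def visit(v: str) -> None:
            if v in order:
                return
            if v in temp:
                raise ValueError("non-emitting production cycle in grammar")
            temp.add(v)
            for d in deps[v]:
                visit(d)
            temp.discard(v)
            order.append(v)

        for v in nts:
            visit(v)
        return order

    def to_yaml(self, path) -> None:
        rows = [
            {"lhs": lhs, "left": a, "rhs": rhs, "right": b, "prob": float(p)}
            for (lhs, a, rhs, b), p in sorted(self.probabilities.items())
        ]
        with open(path, "w") as fh:
            yaml.safe_dump({"start": self.start, "productions": rows}, fh)

    @classmethod
    def from_yaml(cls, path) -> "Grammar":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        probs = {
            (r["lhs"], r["left"], r["rhs"], r["right"]): float(r["prob"])
            for r in doc["productions"]
        }
        return cls(probs, start=doc["start"])


@dataclass
class ScfgScore:
    log_probability: float
    normalized_score: float
    cutoff_pass: Optional[bool] = None


class MultiloopStructureError(ValueError):
    pass


def parse_structure_path(
    sequence: str, dot_bracket: str, record_name: str = "<anon>"
) -> list[Production]:
    """Deterministically parse a single-loop structure into production usages.

    Paired columns map to Stem pair emissions, columns unpaired on both ends
    to SymBulge, one-sided unpaired columns to AsymBulge, and the terminal
    unpaired run to Loop. Multiloop structures (two ends paired, but not
    with each other) are rejected by name.
    """
    seq = [_norm_base(c) for c in sequence.upper()]
    if len(seq) != len(dot_bracket):
        raise ValueError(f"{record_name}: sequence/structure length mismatch")
    pair = {}
    stack = []
    for idx, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError(f"{record_name}: unbalanced brackets")
            j = stack.pop()
            pair[j] = idx
            pair[idx] = j
    if stack:
        raise ValueError(f"{record_name}: unbalanced brackets")

    usages: list[Production] = [("S", "", "Stem", "")]
    state = "Stem"
    i, j = 0, len(seq) - 1

    def close_to_stem() -> None:
        nonlocal state
        if state != "Stem":
            usages.append((state, "", "Stem", ""))
            state = "Stem"

    while True:
        if all(k not in pair for k in range(i, j + 1)):
            close_to_stem()
            usages.append(("Stem", "", "Loop", ""))
            if i > j:
                raise ValueError(f"{record_name}: empty terminal loop")
            for k in range(i, j):
                usages.append(("Loop", seq[k], "Loop", ""))
            usages.append(("Loop", seq[j], "", ""))
            return usages
        left_paired = i in pair
        right_paired = j in pair
        if left_paired and pair[i] == j:
            close_to_stem()
            usages.append(("Stem", seq[i], "Stem", seq[j]))
            i, j = i + 1, j - 1
        elif left_paired and right_paired:
            raise MultiloopStructureError(
                f"{record_name}: multiloop structure (two stems) not parseable"
            )
        elif not left_paired and not right_paired:
            if state == "AsymBulge":
                close_to_stem()
            lhs = state if state == "SymBulge" else "Stem"
            usages.append((lhs, seq[i], "SymBulge", seq[j]))
            state = "SymBulge"
            i, j = i + 1, j - 1
        elif not left_paired:
            if state == "SymBulge":
                close_to_stem()
            lhs = state if state == "AsymBulge" else "Stem"
            usages.append((lhs, seq[i], "AsymBulge", ""))
            state = "AsymBulge"
            i += 1
        else:
            if state == "SymBulge":
                close_to_stem()
            lhs = state if state == "AsymBulge" else "Stem"
            usages.append((lhs, "", "AsymBulge", seq[j]))
            state = "AsymBulge"
            j -= 1


def train_grammar(
    annotated_hairpins: Sequence[tuple[str, str]], smoothing: float = 1.0
) -> Grammar:
    """Learn production probabilities from (sequence, dot_bracket) hairpins.

    Probabilities are smoothed relative rule-usage frequencies (pseudocount
    ``smoothing`` per production); a nonterminal never used and unsmoothed
    falls back to a uniform distribution over its productions.
    """
    template = default_production_set()
    counts = {p: float(smoothing) for p in template}
    for idx, (seq, db) in enumerate(annotated_hairpins):
        usages = parse_structure_path(seq, db, record_name=f"record {idx}")
        for u in usages:
            if u not in counts:
                raise ValueError(f"record {idx}: usage {u} outside grammar template")
            counts[u] += 1.0
    sums: dict[str, float] = {}
    for (lhs, _, _, _), c in counts.items():
        sums[lhs] = sums.get(lhs, 0.0) + c
    probs = {}
    for prod, c in counts.items():
        lhs = prod[0]
        if sums[lhs] == 0:
            n_prods = sum(1 for p in counts if p[0] == lhs)
            probs[prod] = 1.0 / n_prods
        else:
            probs[prod] = c / sums[lhs]
    # prune nonterminals unreachable from S (possible when smoothing == 0)
    reached, frontier = {"S"}, ["S"]
    while frontier:
        v = frontier.pop()
        for (lhs, _, rhs, _), p in probs.items():
            if lhs == v and rhs and p > 0 and rhs not in reached:
                reached.add(rhs)
                frontier.append(rhs)
    probs = {prod: p for prod, p in probs.items() if prod[0] in reached}
    return Grammar(probs)


def inside_log_probability(grammar: Grammar, sequence: str) -> ScfgScore:
    """Natural-log inside probability of ``sequence`` under the grammar.

    Sums the probability of every derivation by dynamic programming over
    subintervals; returns -inf when no derivation exists.
    """
    seq = [_norm_base(c) for c in sequence.upper()]
    if not seq or any(c not in BASES for c in seq):
        raise ValueError("sequence must be non-empty ACGU/ACGT")
    n = len(seq)
    if n > 200:
        raise ValueError("sequence longer than 200 nt")
    order = grammar.same_span_order()
    logp = {
        prod: (math.log(p) if p > 0 else NEG_INF)
        for prod, p in grammar.probabilities.items()
    }
    match = {b: np.array([c == b for c in seq]) for b in BASES}
    inside = {v: np.full((n + 1, n + 1), NEG_INF) for v in order}

    by_lhs: dict[str, list[tuple[Production, float]]] = {v: [] for v in order}
    for prod, lp in logp.items():
        if lp > NEG_INF:
            by_lhs[prod[0]].append((prod, lp))

    for length in range(1, n + 1):
        starts = np.arange(0, n - length + 1)
        ends = starts + length
        for v in order:
            acc = np.full(len(starts), NEG_INF)
            for (lhs, a, rhs, b), lp in by_lhs[v]:
                la, lb = (1 if a else 0), (1 if b else 0)
                if not rhs:  # terminal emission
                    if length == la + lb and la:
                        vals = np.where(match[a][starts], lp, NEG_INF)
                        acc = np.logaddexp(acc, vals)
                    continue
                if length - la - lb < 1:
                    continue
                mask = np.ones(len(starts), dtype=bool)
                if la:
                    mask &= match[a][starts]
                if lb:
                    mask &= match[b][ends - 1]
                if not mask.any():
                    continue
                sub = inside[rhs][starts + la, ends - lb]
                vals = np.where(mask, lp + sub, NEG_INF)
                acc = np.logaddexp(acc, vals)
            inside[v][starts, ends] = acc

    lp_total = float(inside[grammar.start][0, n])
    return ScfgScore(log_probability=lp_total, normalized_score=lp_total / n)


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide counts (Euler walk)."""
    seq = [_norm_base(c) for c in sequence.upper()]
    n = len(seq)
    if n < 3:
        return "".join(seq)
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(200):
        chosen = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        ok = True
        for v in vertices:
            cur, hops = v, 0
            while cur != last and cur in chosen and hops <= len(chosen) + 1:
                cur = chosen[cur]
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # no tree found (degenerate composition); plain order is valid
        return "".join(seq)
    ordering = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in chosen:
            rest.remove(chosen[v])
        rest = [rest[i] for i in rng.permutation(len(rest))]
        if v in chosen:
            rest.append(chosen[v])
        ordering[v] = rest
    out = [seq[0]]
    cursors = {v: 0 for v in ordering}
    cur = seq[0]
    for _ in range(n - 1):
        nxt = ordering[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def cutoff_from_scores(
    negative_scores: Sequence[float], target_specificity: float = 0.95
) -> float:
    """Specificity-quantile cutoff: pass = normalized score > cutoff."""
    if not 0 < target_specificity <= 1:
        raise ValueError("target_specificity must be in (0, 1]")
    scores = sorted(negative_scores)
    if not scores:
        raise ValueError("no negative scores supplied")
    idx = min(len(scores) - 1, max(0, math.ceil(target_specificity * len(scores)) - 1))
    return scores[idx]


def calibrate_cutoff(
    grammar: Grammar,
    positives: Sequence[str],
    negatives: Optional[Sequence[str]] = None,
    target_specificity: float = 0.95,
    seed: int = 0,
) -> float:
    """Calibrate the pass cutoff on normalized scores of negative sequences.

    When ``negatives`` is omitted they are generated by dinucleotide-
    shuffling the positives (seeded), preserving composition.
    """
    if not positives:
        raise ValueError("no positive sequences supplied")
    if negatives is None:
        rng = spawn_rng(seed, 777)
        negatives = [dinucleotide_shuffle(s, rng) for s in positives]
    if not negatives:
        raise ValueError("no negative sequences supplied")
    if len(negatives) < 50:
        warnings.warn(
            f"only {len(negatives)} negatives; cutoff quantile will be coarse"
        )
    neg_scores = [inside_log_probability(grammar, s).normalized_score for s in negatives]
    return cutoff_from_scores(neg_scores, target_specificity)


def classify(grammar: Grammar, sequence: str, cutoff: float) -> ScfgScore:
    score = inside_log_probability(grammar, sequence)
    score.cutoff_pass = score.normalized_score > cutoff
    return score
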