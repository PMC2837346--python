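"""Independent oracles: brute-force reimplementations used only for checking.

These deliberately avoid the package's algorithms: the aligner oracle is a
naive substring scan, the folding oracle exhaustively enumerates nested
structures, the SCFG oracle enumerates derivations by forward generation,
and the clustering oracle is scipy's agglomerative linkage.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ------------------------------------------------------------- aligner oracle

def naive_scan(tag: str, references: dict[str, str], minus_strand: bool) -> set:
    """All exact placements of tag by direct string scanning."""
    hits = set()
    queries = [(tag, "+")]
    if minus_strand:
        queries.append((revcomp(tag), "-"))
    for query, strand in queries:
        for name, ref in references.items():
            start = ref.find(query)
            while start != -1:
                hits.add((name, start, start + len(query), strand))
                start = ref.find(query, start + 1)
    return hits


# ------------------------------------------------------------- folding oracle

PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


def enumerate_structures(seq: str, i: int, j: int, min_loop: int = 3):
    """Yield every nested structure (list of pair index tuples) of seq[i..j]."""
    if i >= j:
        yield []
        return
    # position i unpaired
    for s in enumerate_structures(seq, i + 1, j, min_loop):
        yield s
    # position i paired with k
    for k in range(i + min_loop + 1, j + 1):
        w = PAIR_WEIGHTS.get((seq[i], seq[k]))
        if w is None:
            continue
        for left in enumerate_structures(seq, i + 1, k - 1, min_loop):
            for right in enumerate_structures(seq, k + 1, j, min_loop):
                yield [(i, k)] + left + right


def brute_force_fold_score(seq: str, min_loop: int = 3) -> float:
    """Maximum weighted pair sum over all exhaustively enumerated structures."""
    seq = seq.upper().replace("U", "T")
    best = 0
    for structure in enumerate_structures(seq, 0, len(seq) - 1, min_loop):
        score = sum(PAIR_WEIGHTS[(seq[i], seq[j])] for i, j in structure)
        best = max(best, score)
    return float(best)


# ----------------------------------------------------------------- SCFG oracle

def enumerate_language(grammar, max_len: int) -> dict[str, float]:
    """Map string -> total derivation probability, by forward generation.

    Expands sentential forms (left terminals, one nonterminal, right
    terminals) breadth-first, pruning when the emitted length exceeds
    ``max_len``. Works for the linear grammars used here (every production
    has at most one nonterminal).
    """
    by_lhs: dict[str, list] = {}
    for (lhs, a, rhs, b), p in grammar.probabilities.items():
        if p > 0:
            by_lhs.setdefault(lhs, []).append((a, rhs, b, p))
    out: dict[str, float] = {}
    stack = [("", grammar.start, "", 1.0)]
    while stack:
        left, nt, right, prob = stack.pop()
        for a, rhs, b, p in by_lhs.get(nt, []):
            l2, r2 = left + a, b + right
            if not rhs:
                s = l2 + r2
                if len(s) <= max_len:
                    out[s] = out.get(s, 0.0) + prob * p
            elif len(l2) + len(r2) + 1 <= max_len:
                stack.append((l2, rhs, r2, prob * p))
    return out


# ----------------------------------------------------------- clustering oracle

def scipy_average_linkage_heights(matrix) -> list[float]:
    """Merge heights of UPGMA clustering on Pearson distance, via scipy."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    cols = list(matrix.columns)
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = matrix[cols[i]].to_numpy()
            y = matrix[cols[j]].to_numpy()
            r = np.corrcoef(x, y)[0, 1]
            d[i, j] = d[j, i] = 1.0 - r
    Z = linkage(squareform(d, checks=False), method="average")
    return sorted(Z[:, 2].tolist())
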