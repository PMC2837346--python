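"""Perfect-match placement of short tags on reference sequence sets.

A k-mer seed index with full verification: every hit reported is an exact
substring match (or exact reverse-complement match when the minus strand is
searched), and every occurrence a naive scan would find is found. Tags with
more genomic placements than ``max_hits`` are flagged as multimapped so that
repeat-driven loci can be excluded from candidate calling.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from .util import revcomp

DEFAULT_SEED_K = 12
DEFAULT_MAX_HITS = 10


@dataclass(frozen=True, order=True)
class Hit:
    """An exact placement of a query on a named reference sequence.

    ``start``/``end`` are 0-based half-open on the reference plus strand; on
    strand '-' the reverse complement of the reference substring equals the
    query.
    """

    ref_name: str
    start: int
    end: int
    strand: str


class ReferenceIndex:
    """Substring lookup over named sequences, keyed on k-mer seeds."""

    def __init__(self, sequences: dict[str, str], k: int = DEFAULT_SEED_K):
        if len(set(sequences)) != len(sequences):
            raise ValueError("duplicate reference names")
        self.k = k
        self.sequences = dict(sequences)
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name in sorted(self.sequences):
            seq = self.sequences[name]
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((name, i))

    def _plus_strand_hits(self, query: str) -> list[tuple[str, int]]:
        """All (ref_name, start) exact occurrences of query on the plus strand."""
        k = self.k
        out = []
        for name, pos in self._seeds.get(query[:k], ()):
            ref = self.sequences[name]
            if ref[pos : pos + len(query)] == query:
                out.append((name, pos))
        return out


def build_index(sequences: dict[str, str], k: int = DEFAULT_SEED_K) -> ReferenceIndex:
    return ReferenceIndex(sequences, k=k)


def find_perfect_matches(
    tag: str,
    index: ReferenceIndex,
    search_minus_strand: bool = False,
    max_hits: int = DEFAULT_MAX_HITS,
) -> tuple[list[Hit], bool]:
    """Exact occurrences of ``tag`` in the index, as (hits, multimapped).

    Hits are sorted by (ref_name, start, strand) and truncated at
    ``max_hits``; ``multimapped`` is True when the untruncated hit count
    exceeds ``max_hits``. Tags shorter than the seed length or containing
    non-ACGT characters yield no hits (the latter with a warning).
    """
    if not tag or any(c not in "ACGT" for c in tag):
        warnings.warn(f"tag {tag[:30]!r} contains non-ACGT characters; skipped")
        return [], False
    if len(tag) < index.k:
        raise ValueError(f"tag shorter than seed length {index.k}")
    hits = [
        Hit(name, pos, pos + len(tag), "+")
        for name, pos in index._plus_strand_hits(tag)
    ]
    if search_minus_strand:
        rc = revcomp(tag)
        hits += [
            Hit(name, pos, pos + len(tag), "-")
            for name, pos in index._plus_strand_hits(rc)
        ]
    hits.sort(key=lambda h: (h.ref_name, h.start, h.strand))
    multimapped = len(hits) > max_hits
    return hits[:max_hits], multimapped


def hits_to_bed(hits_by_tag: dict[str, tuple[list[Hit], int]]) -> list[str]:
    """Render hits as BED6 lines (name = tag sequence, score = tag count)."""
    lines = []
    for tag, (hits, count) in hits_by_tag.items():
        for h in hits:
            lines.append(
                f"{h.ref_name}\t{h.start}\t{h.end}\t{tag}\t{count}\t{h.strand}"
            )
    return lines
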