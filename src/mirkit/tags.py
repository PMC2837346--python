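"""Read trimming, collapsing into counted unique tags, and admission filters.

Deep-sequenced small RNA reads are 3' adapter-ligated; the insert is
recovered as the prefix preceding the adapter, identical inserts are
collapsed into unique sequence tags with copy numbers, and tags are admitted
downstream only when seen at least ``min_count`` times (default 2, which
removes almost all singleton sequencing noise) and within a length window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

DEFAULT_MIN_COUNT = 2
DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 27
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed read sequence with its per-library copy number."""

    sequence: str
    count: int
    library_id: str


@dataclass
class LibrarySummary:
    library_id: str
    total_reads: int = 0
    reads_after_trim: int = 0
    reads_in_retained_tags: int = 0
    unique_tag_count: int = 0


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
) -> str | None:
    """Strip the 3' adapter from a read by exact prefix match.

    Returns the read prefix preceding the leftmost exact occurrence of an
    adapter prefix of length >= ``min_overlap``; the read unchanged when no
    such occurrence exists; ``None`` (rejection) when the remaining insert is
    shorter than ``min_len`` or the read is empty.
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    if not read:
        return None
    probe = adapter[:min_overlap]
    pos = read.find(probe) if probe else -1
    insert = read[:pos] if pos >= 0 else read
    if len(insert) < min_len:
        return None
    return insert


def collapse(
    reads: list[str], library_id: str
) -> tuple[list[UniqueTag], LibrarySummary]:
    """Collapse trimmed reads into unique tags with copy numbers.

    Reads containing any base outside ACGT are dropped. Output order is
    deterministic: descending count, then lexicographic sequence. The counts
    of the returned tags sum to the number of clean input reads.
    """
    clean = [r for r in reads if r and all(c in "ACGT" for c in r)]
    counts = Counter(clean)
    tags = [
        UniqueTag(seq, n, library_id)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    summary = LibrarySummary(
        library_id=library_id,
        total_reads=len(reads),
        reads_after_trim=len(clean),
        reads_in_retained_tags=len(clean),
        unique_tag_count=len(tags),
    )
    return tags, summary


def filter_tags(
    tags: list[UniqueTag],
    min_count: int = DEFAULT_MIN_COUNT,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[UniqueTag]:
    """Admission filter: copy number >= min_count and length within bounds."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [
        t
        for t in tags
        if t.count >= min_count and min_len <= len(t.sequence) <= max_len
    ]


def process_library(
    reads: list[str],
    library_id: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_count: int = DEFAULT_MIN_COUNT,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[UniqueTag], LibrarySummary]:
    """Trim, collapse and filter one library's raw reads end to end."""
    trimmed = []
    for read in reads:
        insert = trim_adapter(read, adapter, min_overlap=min_overlap, min_len=min_len)
        if insert is not None:
            trimmed.append(insert)
    tags, summary = collapse(trimmed, library_id)
    summary.total_reads = len(reads)
    kept = filter_tags(tags, min_count=min_count, min_len=min_len, max_len=max_len)
    summary.reads_in_retained_tags = sum(t.count for t in kept)
    summary.unique_tag_count = len(kept)
    return kept, summary
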