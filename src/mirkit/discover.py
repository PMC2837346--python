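"""Novel miRNA discovery: subtractive cascade, candidate calling, post-filters.

Filtered tags are classified sequentially — known precursors first, then
the transcriptome (degraded mRNA), then the genome; tags matching an
earlier reference never reach a later one, and tags matching nothing are
dropped. Genome-residual tags are merged into loci, gated on hairpin
foldability and SCFG score, and filtered against rRNA, exon overhang
(> 2 nt removes), a 16-nt mature-length exclusion, and a > 5 total-read
abundance requirement for final naming.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .align import Hit, ReferenceIndex, find_perfect_matches
from .context import GeneModel
from .fold import (
    CandidateWindow,
    extract_candidate_windows,
    gate_hairpin_in_window,
)
from .scfg import Grammar, inside_log_probability
from .tags import UniqueTag

MAX_EXON_OVERHANG = 2
EXCLUDED_MATURE_LENGTH = 16
NAMING_MIN_TOTAL_READS = 5  # strict: total must exceed this
DEFAULT_ID_PREFIX = "NOVmiR_"

BUCKETS = ("known_precursor", "transcriptome", "genome_residual", "unmatched")


@dataclass
class CascadeBuckets:
    """Per-tag classification of one library's tags (a partition)."""

    library_id: str
    assignment: dict[str, str]  # tag sequence -> bucket
    known_hits: dict[str, list[Hit]] = field(default_factory=dict)
    genome_hits: dict[str, tuple[list[Hit], bool]] = field(default_factory=dict)

    def sizes(self) -> dict[str, int]:
        out = {b: 0 for b in BUCKETS}
        for bucket in self.assignment.values():
            out[bucket] += 1
        return out


def subtractive_cascade(
    tags: list[UniqueTag],
    known_index: ReferenceIndex,
    transcriptome_index: ReferenceIndex,
    genome_index: ReferenceIndex,
    max_hits: int = 10,
) -> CascadeBuckets:
    """Classify tags against references in fixed order.

    Precursor and transcriptome searches are plus-strand only (small RNA
    reads are sense to the mature); the genome is searched on both strands.
    """
    library_id = tags[0].library_id if tags else ""
    buckets = CascadeBuckets(library_id, {})
    for tag in tags:
        seq = tag.sequence
        hits, _ = find_perfect_matches(seq, known_index, search_minus_strand=False,
                                       max_hits=max_hits)
        if hits:
            buckets.assignment[seq] = "known_precursor"
            buckets.known_hits[seq] = hits
            continue
        hits, _ = find_perfect_matches(seq, transcriptome_index,
                                       search_minus_strand=False, max_hits=max_hits)
        if hits:
            buckets.assignment[seq] = "transcriptome"
            continue
        hits, multi = find_perfect_matches(seq, genome_index,
                                           search_minus_strand=True,
                                           max_hits=max_hits)
        if hits:
            buckets.assignment[seq] = "genome_residual"
            buckets.genome_hits[seq] = (hits, multi)
        else:
            buckets.assignment[seq] = "unmatched"
    return buckets


@dataclass
class CandidateMiRNA:
    candidate_id: str
    mature_seq: str
    genome_hit: Hit
    precursor_window: Optional[CandidateWindow]
    counts: dict[str, int]  # per library
    hairpin_ok: bool = False
    scfg_ok: bool = False
    scfg_score: float = float("-inf")
    rrna_hit: bool = False
    exon_overhang_nt: int = 0
    length_ok: bool = True
    abundance_ok: bool = False
    status: str = "raw"
    member_sequences: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def _merge_loci(
    placements: list[tuple[str, Hit]],
) -> list[list[tuple[str, Hit]]]:
    """Group (sequence, hit) placements into same-strand overlapping loci."""
    placements = sorted(
        placements, key=lambda p: (p[1].ref_name, p[1].strand, p[1].start, p[1].end)
    )
    loci: list[list[tuple[str, Hit]]] = []
    cur: list[tuple[str, Hit]] = []
    cur_end = -1
    cur_key = None
    for seq, hit in placements:
        key = (hit.ref_name, hit.strand)
        if cur and key == cur_key and hit.start < cur_end:
            cur.append((seq, hit))
            cur_end = max(cur_end, hit.end)
        else:
            if cur:
                loci.append(cur)
            cur = [(seq, hit)]
            cur_key = key
            cur_end = hit.end
    if cur:
        loci.append(cur)
    return loci


def call_candidates(
    buckets_per_library: list[CascadeBuckets],
    tag_counts: dict[str, dict[str, int]],
    genome: dict[str, str],
    grammar: Grammar,
    cutoff: float,
    fold_criteria: Optional[dict] = None,
    flank_long: int = 70,
    flank_short: int = 20,
    id_prefix: str = DEFAULT_ID_PREFIX,
) -> list[CandidateMiRNA]:
    """Call one candidate per merged genomic locus of residual tags.

    ``tag_counts`` maps tag sequence -> {library: count}. Tags flagged
    multimapped are excluded. Same-strand tags with overlapping placements
    merge into a single locus whose most abundant tag defines the mature
    sequence. Both flanking windows are folded; the candidate's hairpin
    flag is set when either window passes, and the SCFG score is the best
    normalized inside score over the windows.
    """
    placements: list[tuple[str, Hit]] = []
    seen: set[tuple[str, str, int, int, str]] = set()
    for buckets in buckets_per_library:
        for seq, (hits, multi) in buckets.genome_hits.items():
            if multi:
                continue
            for hit in hits:
                key = (seq, hit.ref_name, hit.start, hit.end, hit.strand)
                if key not in seen:
                    seen.add(key)
                    placements.append((seq, hit))

    candidates: list[CandidateMiRNA] = []
    for locus in _merge_loci(placements):
        sequences = sorted({seq for seq, _ in locus})
        counts: dict[str, int] = defaultdict(int)
        for seq in sequences:
            for lib, c in tag_counts.get(seq, {}).items():
                counts[lib] += c
        totals = {
            seq: sum(tag_counts.get(seq, {}).values()) for seq in sequences
        }
        mature = min(sequences, key=lambda s: (-totals[s], s))
        mature_hit = next(hit for seq, hit in locus if seq == mature)

        windows = extract_candidate_windows(
            genome, mature_hit, flank_long=flank_long, flank_short=flank_short
        )
        best_window: Optional[CandidateWindow] = None
        hairpin_ok = False
        best_key: Optional[tuple[bool, float]] = None
        scfg_score = float("-inf")
        for w in windows:
            call = gate_hairpin_in_window(w, mature_hit, criteria=fold_criteria)
            hairpin_ok = hairpin_ok or call.passed
            a, b = call.span
            s = inside_log_probability(grammar, w.sequence[a:b]).normalized_score
            scfg_score = max(scfg_score, s)
            key = (call.passed, call.fold_result.score)
            if best_key is None or key > best_key:  # ties keep the 5'-arm window
                best_key = key
                best_window = CandidateWindow(
                    w.chrom,
                    w.start + (a if w.strand == "+" else (len(w.sequence) - b)),
                    w.start + (b if w.strand == "+" else (len(w.sequence) - a)),
                    w.strand,
                    w.sequence[a:b],
                    w.arm_hint,
                )
        candidates.append(
            CandidateMiRNA(
                candidate_id="",
                mature_seq=mature,
                genome_hit=mature_hit,
                precursor_window=best_window,
                counts=dict(counts),
                hairpin_ok=hairpin_ok,
                scfg_ok=scfg_score > cutoff,
                scfg_score=scfg_score,
                member_sequences=sequences,
            )
        )

    # deterministic ids: descending total count, then genomic coordinate
    candidates.sort(
        key=lambda c: (
            -c.total_count,
            c.genome_hit.ref_name,
            c.genome_hit.start,
            c.genome_hit.strand,
        )
    )
    for i, cand in enumerate(candidates, 1):
        cand.candidate_id = f"{id_prefix}{i}"
    return candidates


def apply_post_filters(
    candidates: list[CandidateMiRNA],
    rrna_index: ReferenceIndex,
    gene_models: list[GeneModel],
    max_exon_overhang: int = MAX_EXON_OVERHANG,
    excluded_length: int = EXCLUDED_MATURE_LENGTH,
    naming_min_total: int = NAMING_MIN_TOTAL_READS,
) -> list[CandidateMiRNA]:
    """Set rRNA / exon-overhang / length / abundance flags and final status.

    Removal reasons are recorded in ``status`` as ``filtered_out:<reason>``;
    survivors are ``candidate``, and those whose total read count strictly
    exceeds ``naming_min_total`` are ``named``. The exon overhang is the
    maximal overlap of the mature interval with any annotated exon on
    either strand; > ``max_exon_overhang`` nt removes the candidate.
    """
    exons_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for m in gene_models:
        exons_by_chrom[m.chrom].extend(m.exons)

    for cand in candidates:
        hits, _ = find_perfect_matches(
            cand.mature_seq, rrna_index, search_minus_strand=True
        ) if rrna_index.sequences else ([], False)
        cand.rrna_hit = bool(hits)
        h = cand.genome_hit
        overhang = 0
        for s, e in exons_by_chrom.get(h.ref_name, ()):
            overhang = max(overhang, min(h.end, e) - max(h.start, s))
        cand.exon_overhang_nt = max(0, overhang)
        cand.length_ok = len(cand.mature_seq) != excluded_length
        cand.abundance_ok = cand.total_count > naming_min_total

        if not cand.hairpin_ok:
            cand.status = "filtered_out:no_hairpin"
        elif not cand.scfg_ok:
            cand.status = "filtered_out:scfg"
        elif cand.rrna_hit:
            cand.status = "filtered_out:rrna"
        elif cand.exon_overhang_nt > max_exon_overhang:
            cand.status = "filtered_out:exon_overhang"
        elif not cand.length_ok:
            cand.status = "filtered_out:length_16nt"
        elif cand.abundance_ok:
            cand.status = "named"
        else:
            cand.status = "candidate"
    return candidates


@dataclass
class CrossLibraryTally:
    unique: dict[str, int]
    shared: dict[str, int]
    totals: dict[str, int]
    present_in_all: list[str]


def cross_library_tally(
    candidates: list[CandidateMiRNA],
    libraries: list[str],
    statuses: tuple[str, ...] = ("candidate", "named"),
) -> CrossLibraryTally:
    """Per-library unique / shared / total counts of surviving candidates.

    A candidate is present in a library when its count there is >= 1;
    unique = present in exactly one library, shared = present in two or
    more, and per library total = unique + shared.
    """
    if not libraries:
        raise ValueError("at least one library required")
    unique = {lib: 0 for lib in libraries}
    shared = {lib: 0 for lib in libraries}
    in_all: list[str] = []
    for cand in candidates:
        if cand.status not in statuses:
            continue
        present = [lib for lib in libraries if cand.counts.get(lib, 0) >= 1]
        if not present:
            continue
        if len(present) == 1:
            unique[present[0]] += 1
        else:
            for lib in present:
                shared[lib] += 1
        if len(present) == len(libraries):
            in_all.append(cand.candidate_id)
    totals = {lib: unique[lib] + shared[lib] for lib in libraries}
    return CrossLibraryTally(unique, shared, totals, sorted(in_all))
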