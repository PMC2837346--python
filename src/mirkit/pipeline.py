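"""End-to-end orchestration: reads in, annotated miRNAs and candidates out.

Ties the stages together the way the analysis is meant to run: per-library
trimming/collapsing/filtering, the subtractive cascade against known
precursors / transcriptome / genome, known-miRNA annotation (arm counts,
isomiRs, ratios, presence), SCFG training and cutoff calibration on the
known hairpins, novel candidate calling with post-filters, and the
expression matrix with library clustering.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

from . import known as kn
from .align import ReferenceIndex, build_index
from .discover import (
    CandidateMiRNA,
    CascadeBuckets,
    CrossLibraryTally,
    apply_post_filters,
    call_candidates,
    cross_library_tally,
    subtractive_cascade,
)
from .expression import DendrogramNode, build_matrix, hierarchical_cluster
from .fold import count_terminal_loops, fold
from .scfg import Grammar, calibrate_cutoff, train_grammar
from .simulate import ReadSimConfig, ReferenceSet, simulate_library
from .tags import LibrarySummary, UniqueTag, process_library


@dataclass
class PipelineResult:
    summaries: dict[str, LibrarySummary]
    tags: dict[str, list[UniqueTag]]
    buckets: dict[str, CascadeBuckets]
    known_records: dict[str, kn.KnownMiRNARecord]
    isomirs: dict[str, list[kn.Isomir]]
    arm_ratios: dict[str, kn.ArmRatio]
    presence: kn.PresenceTally
    grammar: Grammar
    scfg_cutoff: float
    candidates: list[CandidateMiRNA]
    tally: CrossLibraryTally
    matrix: "object" = None  # pandas DataFrame
    dendrogram: Optional[DendrogramNode] = None
    ground_truth: dict = field(default_factory=dict)


def train_scfg_on_known(
    records: dict[str, kn.KnownMiRNARecord],
    target_specificity: float = 0.95,
    seed: int = 0,
    min_negatives: int = 60,
) -> tuple[Grammar, float]:
    """Train the SCFG on known precursor hairpins and calibrate its cutoff.

    Training structures come from folding the known precursors; records
    whose optimal fold is not a single stem-loop are skipped (the grammar
    only parses single-loop structures). Negatives are dinucleotide
    shuffles of the positives, repeated until at least ``min_negatives``.
    """
    training = []
    positives = []
    for mir_id in sorted(records):
        seq = records[mir_id].precursor_seq
        fr = fold(seq)
        if count_terminal_loops(fr.dot_bracket) == 1:
            training.append((seq, fr.dot_bracket))
        positives.append(seq)
    if not training:
        raise ValueError("no single-loop known precursors to train on")
    grammar = train_grammar(training)
    reps = max(1, -(-min_negatives // len(positives)))
    from .scfg import dinucleotide_shuffle
    from .util import spawn_rng

    rng = spawn_rng(seed, 21)
    negatives = [
        dinucleotide_shuffle(s, rng) for _ in range(reps) for s in positives
    ]
    cutoff = calibrate_cutoff(
        grammar, positives, negatives, target_specificity=target_specificity
    )
    return grammar, cutoff


def run_pipeline(
    refs: ReferenceSet,
    reads_per_library: dict[str, list[str]],
    adapter: str,
    min_count: int = 2,
    arm_tolerance: int = 4,
    seed: int = 0,
    cluster: bool = True,
) -> PipelineResult:
    """Run the full analysis over raw (untrimmed) reads of several libraries."""
    libraries = list(reads_per_library)
    summaries: dict[str, LibrarySummary] = {}
    tags: dict[str, list[UniqueTag]] = {}
    for lib, reads in reads_per_library.items():
        t, s = process_library(reads, lib, adapter, min_count=min_count)
        tags[lib], summaries[lib] = t, s

    known_index = build_index(
        {k: v.precursor_seq for k, v in refs.known_records.items()}
    ) if refs.known_records else build_index({})
    tx_index = build_index(refs.transcriptome)
    genome_index = build_index(refs.genome)
    rrna_index = build_index(refs.rrna)

    buckets: dict[str, CascadeBuckets] = {}
    for lib in libraries:
        buckets[lib] = subtractive_cascade(
            tags[lib], known_index, tx_index, genome_index
        )

    # known annotation (fresh copies: counts accumulate per run)
    records = {k: copy.deepcopy(v) for k, v in refs.known_records.items()}
    for k in records.values():
        k.mature_counts.clear(); k.star_counts.clear(); k.hairpin_counts.clear()
    isomirs: dict[str, list[kn.Isomir]] = {}
    per_lib_arm_counts: dict[str, dict[str, int]] = {}
    for lib in libraries:
        tag_by_seq = {t.sequence: t for t in tags[lib]}
        pairs = []
        for seq, hits in buckets[lib].known_hits.items():
            for hit in hits:
                pairs.append((tag_by_seq[seq], hit))
        per_lib_arm_counts[lib], isomirs[lib] = kn.annotate_library(
            pairs, records, arm_tolerance=arm_tolerance
        )
    presence = kn.tally_presence(per_lib_arm_counts)
    arm_ratios = {}
    for mir_id, rec in records.items():
        m = sum(rec.mature_counts.values())
        s = sum(rec.star_counts.values())
        if m + s:
            arm_ratios[mir_id] = kn.compute_arm_ratio(mir_id, m, s)

    grammar, cutoff = train_scfg_on_known(records, seed=seed)

    tag_counts: dict[str, dict[str, int]] = {}
    for lib in libraries:
        for t in tags[lib]:
            tag_counts.setdefault(t.sequence, {})[lib] = t.count
    candidates = call_candidates(
        [buckets[lib] for lib in libraries], tag_counts, refs.genome,
        grammar, cutoff,
    )
    candidates = apply_post_filters(candidates, rrna_index, refs.gene_models)
    tally = cross_library_tally(candidates, libraries)

    # expression matrix over known miRNAs + surviving candidates
    counts: dict[str, dict[str, int]] = {lib: {} for lib in libraries}
    for lib in libraries:
        for mir_id, rec in records.items():
            c = rec.mature_counts.get(lib, 0) + rec.star_counts.get(lib, 0)
            if c:
                counts[lib][mir_id] = c
        for cand in candidates:
            if cand.status in ("candidate", "named") and cand.counts.get(lib, 0):
                counts[lib][cand.candidate_id] = cand.counts[lib]
    totals = {lib: summaries[lib].total_reads for lib in libraries}
    matrix = build_matrix(counts, totals)
    dendrogram = None
    if cluster and len(matrix.columns) >= 2:
        dendrogram = hierarchical_cluster(matrix)

    return PipelineResult(
        summaries=summaries, tags=tags, buckets=buckets,
        known_records=records, isomirs=isomirs, arm_ratios=arm_ratios,
        presence=presence, grammar=grammar, scfg_cutoff=cutoff,
        candidates=candidates, tally=tally, matrix=matrix,
        dendrogram=dendrogram,
    )


def run_simulated_study(
    refs: ReferenceSet,
    configs: list[ReadSimConfig],
    seed: int = 0,
    cluster: bool = True,
) -> PipelineResult:
    """Simulate every configured library and run the pipeline on the reads."""
    reads_per_library = {}
    truths = {}
    adapter = configs[0].adapter if configs else ""
    for cfg in configs:
        reads, truth = simulate_library(refs, cfg)
        reads_per_library[cfg.library_id] = [seq for _, seq in reads]
        truths[cfg.library_id] = truth
    result = run_pipeline(
        refs, reads_per_library, adapter=adapter, seed=seed, cluster=cluster
    )
    result.ground_truth = truths
    return result
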