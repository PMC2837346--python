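"""Collapse reads into counted tags and classify them subtractively.

Simulates one library, trims the 3' adapter, collapses reads into unique
tags with copy numbers, applies the >= 2-copy and length filters, and
classifies the surviving tags against known precursors, transcriptome and
genome in that fixed order.
"""

from mirkit import build_reference_set, build_index, default_library_configs
from mirkit.discover import subtractive_cascade
from mirkit.simulate import simulate_library
from mirkit.tags import process_library

refs = build_reference_set(seed=1)
cfg = default_library_configs(refs, n_libraries=1, n_reads=20_000, seed=1)[0]
reads, _ = simulate_library(refs, cfg)

tags, summary = process_library([seq for _, seq in reads], cfg.library_id, cfg.adapter)
print(f"{summary.total_reads} reads -> {summary.unique_tag_count} unique tags "
      f"(>= 2 copies, 17-27 nt), covering {summary.reads_in_retained_tags} reads")

buckets = subtractive_cascade(
    tags,
    build_index({k: v.precursor_seq for k, v in refs.known_records.items()}),
    build_index(refs.transcriptome),
    build_index(refs.genome),
)
print("cascade buckets:", buckets.sizes())
# known_precursor tags feed the known-miRNA annotation, transcriptome tags
# are degraded-mRNA contamination, genome_residual tags are the novel-miRNA
# search space, and unmatched tags (sequencing errors) are dropped.
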