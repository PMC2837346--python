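"""Ground-truth evaluation helpers for simulated studies.

Quantify how well a pipeline run recovers what the simulator planted:
named-candidate recovery of planted novel loci, decoy contamination,
genomic-context label recovery, replicate clustering, and simulator
self-checks (binomial agreement of arm-ratio and isomiR-offset
frequencies with their configured values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .context import classify_location
from .discover import CandidateMiRNA
from .expression import DendrogramNode
from .pipeline import PipelineResult
from .simulate import PlantedLocus, ReadSimConfig, ReferenceSet

NOVEL_CLASSES = ("novel_mirna", "mirtron_typical", "mirtron_atypical")


def _overlaps_locus(locus: PlantedLocus, cand: CandidateMiRNA) -> bool:
    h = cand.genome_hit
    return (
        h.ref_name == locus.chrom
        and h.strand == locus.strand
        and h.start < locus.precursor_interval[1]
        and h.end > locus.precursor_interval[0]
    )


@dataclass
class RecoveryReport:
    n_eligible: int
    n_recovered: int
    n_named_from_decoys: int

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else float("nan")


def planted_novel_recovery(
    refs: ReferenceSet, result: PipelineResult, min_expected: float = 5.0
) -> RecoveryReport:
    """Recovery of planted novel loci as named candidates.

    A planted novel/mirtron locus is eligible when its expected read count
    summed over libraries exceeds ``min_expected`` (the naming threshold);
    it is recovered when a named candidate overlaps its precursor on the
    same strand. Decoy contamination counts named candidates overlapping
    any planted rRNA or mRNA-decoy locus.
    """
    expected_total: dict[str, float] = {}
    for truth in result.ground_truth.values():
        for lid, e in truth.expected_counts.items():
            expected_total[lid] = expected_total.get(lid, 0.0) + e
    named = [c for c in result.candidates if c.status == "named"]
    eligible = [
        l for l in refs.loci_of_class(*NOVEL_CLASSES)
        if expected_total.get(l.locus_id, 0.0) > min_expected
    ]
    recovered = sum(
        1 for l in eligible if any(_overlaps_locus(l, c) for c in named)
    )
    decoys = refs.loci_of_class("rrna", "mrna_decoy")
    contaminated = sum(
        1 for c in named if any(_overlaps_locus(l, c) for l in decoys)
    )
    return RecoveryReport(len(eligible), recovered, contaminated)


def context_label_recovery(refs: ReferenceSet) -> float:
    """Fraction of planted loci whose genomic context is classified as planted."""
    ok = 0
    for locus in refs.manifest:
        call = classify_location(
            locus.precursor_interval, locus.strand, refs.gene_models,
            locus.chrom, promoter_len=refs.promoter_len,
        )
        ok += call.feature == locus.expected_feature
    return ok / len(refs.manifest) if refs.manifest else float("nan")


def _clades(node: DendrogramNode) -> list[frozenset]:
    out = [frozenset(node.leaves())]
    for c in node.children:
        out.extend(_clades(c))
    return out


def replicate_groups(configs: list[ReadSimConfig]) -> dict[str, list[str]]:
    """Group library ids by identical locus-weight profiles."""
    groups: dict[tuple, list[str]] = {}
    for cfg in configs:
        key = tuple(sorted(cfg.locus_weights.items()))
        groups.setdefault(key, []).append(cfg.library_id)
    return {libs[0]: libs for libs in groups.values()}


def replicates_form_clades(
    dendrogram: DendrogramNode, groups: dict[str, list[str]]
) -> bool:
    """Do same-profile replicate libraries pair up before anything else?

    True when every replicate group appears as its own clade in the
    dendrogram (its leaf set is exactly the leaf set of some node).
    """
    clades = set(_clades(dendrogram))
    return all(frozenset(libs) in clades for libs in groups.values())


@dataclass
class BinomialCheck:
    n_checked: int
    n_within: int

    @property
    def fraction(self) -> float:
        return self.n_within / self.n_checked if self.n_checked else float("nan")


def _within_ci(k: int, n: int, p: float, level: float = 0.99) -> bool:
    lo = binom.ppf((1 - level) / 2, n, p)
    hi = binom.ppf(1 - (1 - level) / 2, n, p)
    return lo <= k <= hi


def arm_ratio_binomial_check(
    result: PipelineResult, configs: list[ReadSimConfig], level: float = 0.99
) -> BinomialCheck:
    """Per (locus, library): is the mature fraction of simulated arm reads
    inside the central binomial interval implied by the configured ratio?"""
    checked = within = 0
    cfg_by_lib = {c.library_id: c for c in configs}
    for lib, truth in result.ground_truth.items():
        cfg = cfg_by_lib[lib]
        arms = truth.origins[truth.origins["arm"].isin(["mature", "star"])]
        for lid, sub in arms.groupby("locus_id"):
            if lid not in cfg.arm_ratio or len(sub) < 20:
                continue
            r = cfg.arm_ratio[lid]
            k = int((sub["arm"] == "mature").sum())
            checked += 1
            within += _within_ci(k, len(sub), r / (1 + r), level)
    return BinomialCheck(checked, within)


def isomir_offset_binomial_check(
    result: PipelineResult, configs: list[ReadSimConfig], level: float = 0.99
) -> BinomialCheck:
    """Per (library, offset pair): simulated frequency vs configured probability."""
    checked = within = 0
    cfg_by_lib = {c.library_id: c for c in configs}
    for lib, truth in result.ground_truth.items():
        cfg = cfg_by_lib[lib]
        non_noise = truth.origins[truth.origins["locus_id"] != "noise"]
        n = len(non_noise)
        if n == 0:
            continue
        observed = non_noise.groupby(
            ["five_prime_offset", "three_prime_offset"]
        ).size()
        for off, p in cfg.isomir_probs.items():
            k = int(observed.get(off, 0))
            checked += 1
            within += _within_ci(k, n, p, level)
    return BinomialCheck(checked, within)


def offset_end_masses(result: PipelineResult) -> tuple[float, float]:
    """(3' nonzero-offset fraction, 5' nonzero-offset fraction) of mature reads."""
    three = five = total = 0
    for truth in result.ground_truth.values():
        mat = truth.origins[truth.origins["arm"] == "mature"]
        total += len(mat)
        three += int((mat["three_prime_offset"] != 0).sum())
        five += int((mat["five_prime_offset"] != 0).sum())
    if total == 0:
        return float("nan"), float("nan")
    return three / total, five / total
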