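"""Annotation of tags against known miRNA precursors.

Tags hitting a known precursor are assigned to the mature arm, the star
arm, or the hairpin (loop) region; end offsets relative to the annotated
mature sequence quantify isomiRs; per-arm totals give the mature:star
ratio, binned into star-dominant (< 0.75), equivalent (0.75-2.2) and
mature-dominant (> 2.2) classes; presence tallies across libraries report
which miRNAs are common to all libraries or unique to one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .align import Hit
from .tags import UniqueTag

DEFAULT_ARM_TOLERANCE = 4

RATIO_EQUIVALENT_LOW = 0.75
RATIO_EQUIVALENT_HIGH = 2.2


@dataclass
class KnownMiRNARecord:
    """A known precursor with arm intervals (precursor-local, half-open)."""

    mir_id: str
    precursor_seq: str
    mature_interval: tuple[int, int]
    star_interval: Optional[tuple[int, int]] = None
    # per-library counts, filled by annotation
    mature_counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)
    hairpin_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.precursor_seq)
        for name, iv in (("mature", self.mature_interval), ("star", self.star_interval)):
            if iv is None:
                continue
            if not (0 <= iv[0] < iv[1] <= n):
                raise ValueError(f"{self.mir_id}: {name} interval outside precursor")
        if self.star_interval is not None:
            a, b = sorted([self.mature_interval, self.star_interval])
            if a[1] > b[0]:
                raise ValueError(f"{self.mir_id}: arm intervals overlap")


@dataclass(frozen=True)
class Isomir:
    mir_id: str
    five_prime_offset: int
    three_prime_offset: int
    count: int


@dataclass
class ArmRatio:
    mir_id: str
    mature_count: int
    star_count: int
    ratio: Optional[float]
    ratio_class: str


@dataclass
class TagAssignment:
    mir_id: str
    region: str  # mature | star | hairpin_region
    five_prime_offset: Optional[int]
    three_prime_offset: Optional[int]


def _arm_offsets(hit: Hit, arm: tuple[int, int]) -> tuple[int, int]:
    """Signed (5', 3') end offsets of the tag relative to an arm interval."""
    return hit.start - arm[0], hit.end - arm[1]


def assign_tag(
    tag: UniqueTag,
    hit: Hit,
    record: KnownMiRNARecord,
    arm_tolerance: int = DEFAULT_ARM_TOLERANCE,
) -> TagAssignment:
    """Assign one precursor hit to mature / star / hairpin_region.

    A tag belongs to an arm when both of its ends lie within
    ``arm_tolerance`` nt of that arm's ends; otherwise it counts toward the
    hairpin region. When a tiny precursor lets a tag fit both arm windows,
    the arm with the smaller total end offset wins (mature on a tie).
    """
    candidates = []
    arms = [("mature", record.mature_interval)]
    if record.star_interval is not None:
        arms.append(("star", record.star_interval))
    for region, arm in arms:
        o5, o3 = _arm_offsets(hit, arm)
        if abs(o5) <= arm_tolerance and abs(o3) <= arm_tolerance:
            candidates.append((abs(o5) + abs(o3), region == "star", region, o5, o3))
    if not candidates:
        return TagAssignment(record.mir_id, "hairpin_region", None, None)
    candidates.sort()
    _, _, region, o5, o3 = candidates[0]
    return TagAssignment(record.mir_id, region, o5, o3)


def compute_arm_ratio(mir_id: str, mature_count: int, star_count: int) -> ArmRatio:
    """Mature:star count ratio and its class.

    equivalent in [0.75, 2.2]; star_dominant below; mature_dominant above;
    undefined when the star count is zero (no pseudocount is applied).
    """
    if mature_count < 0 or star_count < 0:
        raise ValueError("counts must be non-negative")
    if star_count == 0:
        return ArmRatio(mir_id, mature_count, star_count, None, "undefined")
    ratio = mature_count / star_count
    if ratio < RATIO_EQUIVALENT_LOW:
        cls = "star_dominant"
    elif ratio <= RATIO_EQUIVALENT_HIGH:
        cls = "equivalent"
    else:
        cls = "mature_dominant"
    return ArmRatio(mir_id, mature_count, star_count, ratio, cls)


@dataclass
class PresenceTally:
    per_library: dict[str, set[str]]
    common_to_all: set[str]
    unique_to_one: set[str]


def tally_presence(per_library_counts: dict[str, dict[str, int]]) -> PresenceTally:
    """Presence sets across libraries.

    ``per_library_counts`` maps library -> {mir_id: mature + star count}.
    A miRNA is present in a library when its count there is >= 1.
    """
    if not per_library_counts:
        raise ValueError("at least one library required")
    present = {
        lib: {m for m, c in counts.items() if c >= 1}
        for lib, counts in per_library_counts.items()
    }
    sets = list(present.values())
    common = set.intersection(*sets) if sets else set()
    seen_in = defaultdict(int)
    for s in sets:
        for m in s:
            seen_in[m] += 1
    unique = {m for m, k in seen_in.items() if k == 1}
    return PresenceTally(present, common, unique)


@dataclass
class KnownAnnotationResult:
    records: dict[str, KnownMiRNARecord]
    isomirs: dict[str, list[Isomir]]  # per library
    per_library_arm_counts: dict[str, dict[str, int]]  # lib -> mir -> mature+star


def annotate_library(
    tags_with_hits: list[tuple[UniqueTag, Hit]],
    records: dict[str, KnownMiRNARecord],
    arm_tolerance: int = DEFAULT_ARM_TOLERANCE,
) -> tuple[dict[str, int], list[Isomir]]:
    """Accumulate arm counts and isomiR spectra for one library.

    Returns (mir -> mature+star count, isomir list). Counts are summed over
    all isomiR variants of an arm, and the per-record mature/star/hairpin
    counters on ``records`` are updated in place.
    """
    isomir_counts: dict[tuple[str, int, int], int] = defaultdict(int)
    arm_totals: dict[str, int] = defaultdict(int)
    for tag, hit in tags_with_hits:
        rec = records[hit.ref_name]
        lib = tag.library_id
        asg = assign_tag(tag, hit, rec, arm_tolerance)
        if asg.region == "mature":
            rec.mature_counts[lib] = rec.mature_counts.get(lib, 0) + tag.count
            arm_totals[rec.mir_id] += tag.count
            isomir_counts[(rec.mir_id, asg.five_prime_offset, asg.three_prime_offset)] += tag.count
        elif asg.region == "star":
            rec.star_counts[lib] = rec.star_counts.get(lib, 0) + tag.count
            arm_totals[rec.mir_id] += tag.count
        else:
            rec.hairpin_counts[lib] = rec.hairpin_counts.get(lib, 0) + tag.count
    isomirs = [
        Isomir(mir, o5, o3, c)
        for (mir, o5, o3), c in sorted(isomir_counts.items())
    ]
    return dict(arm_totals), isomirs
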