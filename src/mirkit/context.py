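"""Genomic context classification for miRNA precursors.

Maps precursor intervals onto gene structures: UTRs are derived on the fly
from transcript and CDS coordinates, precursors are classified as
mirtron/exon/UTR/intron/promoter/intergenic, and intron-resident precursors
whose ends coincide with splice sites are typed as mirtrons (typical: both
ends anchored; atypical: exactly one end anchored).

All coordinates are 0-based half-open genomic intervals; GFF3 conversion
happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]

#: precedence among feature labels, highest first
FEATURE_PRECEDENCE = (
    "mirtron_typical",
    "mirtron_atypical",
    "exon",
    "five_utr",
    "three_utr",
    "intron",
    "promoter",
    "intergenic",
)


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class GeneModel:
    """A transcript model: exons plus an optional CDS.

    Exons are sorted, disjoint half-open intervals covering the transcript
    interval end to end (introns are the gaps between them). ``cds_interval``
    is absent for non-coding transcripts.
    """

    transcript_id: str
    chrom: str
    strand: str
    transcript_interval: Interval
    exons: list[Interval]
    cds_interval: Optional[Interval] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ts, te = self.transcript_interval
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if e0 >= s1:
                raise ValueError(f"{self.transcript_id}: exons overlap or touch")
        if exons[0][0] != ts or exons[-1][1] != te:
            raise ValueError(
                f"{self.transcript_id}: exons must span the transcript interval"
            )
        self.exons = exons
        if self.cds_interval is not None:
            cs, ce = self.cds_interval
            if not (ts <= cs < ce <= te):
                raise ValueError(f"{self.transcript_id}: CDS outside transcript")
            # CDS endpoints must land in exons (CDS within the exon union)
            if not any(s <= cs < e for s, e in exons) or not any(
                s < ce <= e for s, e in exons
            ):
                raise ValueError(f"{self.transcript_id}: CDS outside exon union")

    @property
    def introns(self) -> list[Interval]:
        return [
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])
        ]

    def promoter_interval(self, promoter_len: int = 1000) -> Interval:
        """Window immediately upstream of the TSS, strand-aware."""
        ts, te = self.transcript_interval
        if self.strand == "+":
            return (max(0, ts - promoter_len), ts)
        return (te, te + promoter_len)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class FeatureCall:
    candidate_id: str
    feature: str
    transcript_id: Optional[str]
    overlap_nt: int


def _clip_to_exons(exons: list[Interval], window: Interval) -> list[Interval]:
    out = []
    for s, e in exons:
        s2, e2 = max(s, window[0]), min(e, window[1])
        if s2 < e2:
            out.append((s2, e2))
    return out


def derive_utrs(model: GeneModel) -> tuple[list[Interval], list[Interval]]:
    """Derive 5'UTR and 3'UTR exonic intervals from transcript + CDS bounds.

    Returns ``(five_utr, three_utr)`` interval lists. Non-coding models yield
    two empty lists. On the + strand the 5'UTR is the exonic sequence left of
    the CDS start; on the − strand the picture is mirrored, so the 5'UTR lies
    at higher genomic coordinates.
    """
    if model.cds_interval is None:
        return [], []
    ts, te = model.transcript_interval
    cs, ce = model.cds_interval
    left = _clip_to_exons(model.exons, (ts, cs))
    right = _clip_to_exons(model.exons, (ce, te))
    if model.strand == "+":
        return left, right
    return right, left


def classify_mirtron(
    precursor_interval: Interval,
    intron_interval: Interval,
    tolerance: int = 0,
) -> str:
    """Type a precursor against one intron: 'typical', 'atypical' or 'none'.

    Typical mirtrons are anchored to splice sites at both ends; atypical
    mirtrons at exactly one end. Anchoring is coordinate equality within
    ``tolerance`` nt (default exact).
    """
    if _overlap(precursor_interval, intron_interval) == 0:
        return "none"
    left = abs(precursor_interval[0] - intron_interval[0]) <= tolerance
    right = abs(precursor_interval[1] - intron_interval[1]) <= tolerance
    if left and right:
        return "typical"
    if left or right:
        return "atypical"
    return "none"


def _classify_against_transcript(
    precursor: Interval,
    model: GeneModel,
    promoter_len: int,
    splice_tolerance: int,
) -> Optional[tuple[str, int]]:
    """Best (feature, overlap) of a precursor against one transcript, or None."""
    tx_olap = _overlap(precursor, model.transcript_interval)
    if tx_olap == 0:
        p_olap = _overlap(precursor, model.promoter_interval(promoter_len))
        if p_olap > 0:
            return ("promoter", p_olap)
        return None
    five, three = derive_utrs(model)
    if model.cds_interval is not None:
        coding = _clip_to_exons(model.exons, model.cds_interval)
    else:
        coding = model.exons
    regions = {
        "exon": coding,
        "five_utr": five,
        "three_utr": three,
        "intron": model.introns,
    }
    best: Optional[tuple[str, int]] = None
    for feature in ("exon", "five_utr", "three_utr", "intron"):
        olap = sum(_overlap(precursor, iv) for iv in regions[feature])
        if olap > 0 and (best is None or olap > best[1]):
            best = (feature, olap)
    if best is None:
        return None
    if best[0] == "intron":
        # the maximally-overlapped intron decides mirtron typing
        intron = max(model.introns, key=lambda iv: _overlap(precursor, iv))
        kind = classify_mirtron(precursor, intron, splice_tolerance)
        if kind != "none":
            return (f"mirtron_{kind}", best[1])
    return best


def classify_location(
    precursor_interval: Interval,
    strand: str,
    models: list[GeneModel],
    chrom: str,
    promoter_len: int = 1000,
    splice_tolerance: int = 0,
    candidate_id: str = "",
) -> FeatureCall:
    """Classify a precursor's genomic context against a set of gene models.

    Each overlapping transcript proposes the feature with maximal overlap;
    across transcripts the highest-precedence feature wins, ties broken by
    transcript_id. No overlapping model yields 'intergenic'.
    """
    proposals: list[tuple[int, str, str, int]] = []
    for model in models:
        if model.chrom != chrom:
            continue
        res = _classify_against_transcript(
            precursor_interval, model, promoter_len, splice_tolerance
        )
        if res is not None:
            feature, olap = res
            proposals.append(
                (FEATURE_PRECEDENCE.index(feature), model.transcript_id, feature, olap)
            )
    if not proposals:
        return FeatureCall(candidate_id, "intergenic", None, 0)
    proposals.sort(key=lambda t: (t[0], t[1]))
    _, tx_id, feature, olap = proposals[0]
    return FeatureCall(candidate_id, feature, tx_id, olap)
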