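"""Synthetic reference and small RNA library generator with ground truth.

Builds a toy genome with gene models, planted miRNA loci (known, novel,
mirtrons anchored to splice sites), rRNA genes and mRNA-decoy windows, and
simulates adapter-ligated small RNA libraries from them: reads are
mature/star/decoy subsequences modified by isomiR end offsets (3' end
heterogeneity more common than 5' by default), per-base substitution
errors, and uniform singleton noise. Every read carries a ground-truth
origin record, so each stage of the analysis is testable without real data.

Planted hairpins are built as a 20-24 nt 5' arm, an 8-15 nt loop and a 3'
arm that reverse-complements the 5' arm with 1-2 mismatches; the mismatches
keep the two arms sequence-distinct, so a mature tag has a unique perfect
genomic placement. Every planted precursor is verified to pass the hairpin
gate at generation time (resampled otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .context import GeneModel
from .fold import fold, is_hairpin
from .io import spliced_sequence
from .known import KnownMiRNARecord
from .util import random_dna, revcomp, spawn_rng

LOCUS_CLASSES = (
    "known_mirna", "novel_mirna", "mirtron_typical", "mirtron_atypical",
    "rrna", "mrna_decoy",
)

DEFAULT_N_PLANTED = {
    "known_mirna": 24,
    "novel_mirna": 16,
    "mirtron_typical": 2,
    "mirtron_atypical": 2,
    "rrna": 2,
    "mrna_decoy": 4,
}

DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ISOMIR_PROBS = {
    (0, 0): 0.65,
    (0, 1): 0.14,
    (0, -1): 0.10,
    (0, 2): 0.06,
    (1, 0): 0.03,
    (-1, 0): 0.02,
}
#: mature:star ratio grid spanning star-dominant to extreme mature-dominant
DEFAULT_ARM_RATIO_GRID = (0.03, 0.3, 1.0, 10.0, 100.0, 2000.0)
PRECURSOR_FLANK = 5
CHROM = "chr1"


class GenerationError(RuntimeError):
    pass


@dataclass
class PlantedLocus:
    """Ground-truth record of one planted genomic locus."""

    locus_id: str
    locus_class: str
    chrom: str
    strand: str
    precursor_interval: tuple[int, int]
    mature_interval: tuple[int, int]
    star_interval: Optional[tuple[int, int]]
    context_label: str

    @property
    def expected_feature(self) -> str:
        """Feature that classify_location should report for this locus."""
        if self.locus_class in ("mirtron_typical", "mirtron_atypical"):
            return self.locus_class
        if self.locus_class == "mrna_decoy":
            return "exon"
        if self.locus_class == "rrna":
            return "intergenic"
        return self.context_label

    @property
    def is_mirna(self) -> bool:
        return self.locus_class in (
            "known_mirna", "novel_mirna", "mirtron_typical", "mirtron_atypical"
        )


@dataclass
class SimLocus:
    """Sampling record: the sequence reads of a locus are drawn from."""

    locus_id: str
    locus_class: str
    ext_seq: str  # oriented 5'->3'; includes flanks so end offsets stay in range
    mature_local: tuple[int, int]
    star_local: Optional[tuple[int, int]] = None


@dataclass
class ReferenceSet:
    genome: dict[str, str]
    gene_models: list[GeneModel]
    manifest: list[PlantedLocus]
    known_records: dict[str, KnownMiRNARecord]
    transcriptome: dict[str, str]
    rrna: dict[str, str]
    sampling: dict[str, SimLocus]
    promoter_len: int = 1000

    def loci_of_class(self, *classes: str) -> list[PlantedLocus]:
        return [l for l in self.manifest if l.locus_class in classes]


@dataclass
class ReadSimConfig:
    library_id: str
    n_reads: int
    locus_weights: dict[str, float]
    arm_ratio: dict[str, float] = field(default_factory=dict)
    isomir_probs: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROBS)
    )
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    singleton_noise_fraction: float = 0.05
    read_length: int = 36
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.isomir_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isomir_probs sum to {total}, not 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.n_reads > 0 and sum(self.locus_weights.values()) <= 0:
            raise ValueError("locus weights must sum > 0 when n_reads > 0")
        if not 0 <= self.singleton_noise_fraction < 1:
            raise ValueError("singleton_noise_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Per-read origins plus per-locus expectations for one library."""

    library_id: str
    origins: pd.DataFrame  # read_id, locus_id, arm, five_prime_offset, three_prime_offset
    expected_counts: dict[str, float]

    def realized_counts(self) -> dict[str, int]:
        counts = self.origins["locus_id"].value_counts()
        return {k: int(v) for k, v in counts.items() if k != "noise"}


# --------------------------------------------------------------- hairpin build

def _make_hairpin(
    rng: np.random.Generator,
    arm_len: tuple[int, int] = (20, 24),
    loop_len: tuple[int, int] = (8, 15),
    mismatches: tuple[int, int] = (1, 2),
    adapter_probe: str = DEFAULT_ADAPTER[:5],
    max_tries: int = 200,
) -> tuple[str, str, tuple[int, int], tuple[int, int]]:
    """Sample a verified hairpin: (core, flanked, mature_core, star_core).

    The mature arm (5' or 3', chosen at random) and star arm are the two
    stem arms in core-local coordinates. The flanked sequence (5 nt random
    flanks) and the core must both pass the default hairpin gate and avoid
    the adapter probe.
    """
    for _ in range(max_tries):
        la = int(rng.integers(arm_len[0], arm_len[1] + 1))
        ll = int(rng.integers(loop_len[0], loop_len[1] + 1))
        n_mm = int(rng.integers(mismatches[0], mismatches[1] + 1))
        arm5 = random_dna(rng, la)
        arm3 = list(revcomp(arm5))
        if n_mm:
            for pos in rng.choice(la, size=min(n_mm, la), replace=False):
                alts = [b for b in "ACGT" if b != arm3[pos]]
                arm3[pos] = alts[int(rng.integers(3))]
        loop = random_dna(rng, ll)
        core = arm5 + loop + "".join(arm3)
        flanked = random_dna(rng, PRECURSOR_FLANK) + core + random_dna(rng, PRECURSOR_FLANK)
        probe_bad = adapter_probe and (
            adapter_probe in flanked or adapter_probe in revcomp(flanked)
        )
        if probe_bad:
            continue
        if not is_hairpin(fold(core)) or not is_hairpin(fold(flanked)):
            continue
        if rng.random() < 0.5:
            mature, star = (0, la), (la + ll, len(core))
        else:
            mature, star = (la + ll, len(core)), (0, la)
        return core, flanked, mature, star
    raise GenerationError("could not construct a verified hairpin")


def _local_to_genomic(
    prec: tuple[int, int], local: tuple[int, int], strand: str
) -> tuple[int, int]:
    if strand == "+":
        return (prec[0] + local[0], prec[0] + local[1])
    return (prec[1] - local[1], prec[1] - local[0])


# ------------------------------------------------------------- reference build

def build_reference_set(
    genome_length: int = 300_000,
    n_genes: int = 30,
    n_planted: Optional[dict[str, int]] = None,
    seed: int = 0,
    promoter_len: int = 1000,
    adapter_probe: str = DEFAULT_ADAPTER[:5],
) -> ReferenceSet:
    """Generate genome, gene models, planted loci and reference sequence sets.

    Planted miRNA loci rotate through intron / intergenic / promoter
    contexts; mirtrons occupy introns whose boundaries they anchor; rRNA
    genes are intergenic; mRNA decoys are windows of fully coding exons.
    Raises :class:`GenerationError` naming the locus class when the genome
    is too short to place everything.
    """
    if genome_length < 10_000:
        raise ValueError("genome_length must be >= 10,000")
    n_planted = dict(DEFAULT_N_PLANTED if n_planted is None else n_planted)
    for cls in n_planted:
        if cls not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {cls}")
    rng = spawn_rng(seed, 1)

    # ---- plan jobs
    contexts = ["intron", "intergenic", "promoter"]
    gene_jobs: list[dict] = []   # placed inside a gene
    gap_jobs: list[dict] = []    # placed in intergenic gaps
    prom_jobs: list[dict] = []   # placed in the promoter window before a + gene
    counter = 0
    for cls in ("known_mirna", "novel_mirna"):
        for i in range(n_planted.get(cls, 0)):
            ctx = contexts[i % 3]
            job = {"cls": cls, "ctx": ctx, "id": f"{cls}_{i + 1:03d}"}
            {"intron": gene_jobs, "intergenic": gap_jobs, "promoter": prom_jobs}[ctx].append(job)
    for cls in ("mirtron_typical", "mirtron_atypical"):
        for i in range(n_planted.get(cls, 0)):
            gene_jobs.append({"cls": cls, "ctx": "intron", "id": f"{cls}_{i + 1:03d}"})
    for i in range(n_planted.get("mrna_decoy", 0)):
        gene_jobs.append({"cls": "mrna_decoy", "ctx": "exon", "id": f"mrna_decoy_{i + 1:03d}"})
    for i in range(n_planted.get("rrna", 0)):
        gap_jobs.append({"cls": "rrna", "ctx": "intergenic", "id": f"rrna_{i + 1:03d}"})

    if len(gene_jobs) > n_genes:
        raise GenerationError(
            f"need {len(gene_jobs)} host genes for intron/exon loci but only "
            f"{n_genes} genes requested"
        )
    if len(gap_jobs) > n_genes:
        raise GenerationError(
            f"need {len(gap_jobs)} intergenic gaps but only {n_genes} available"
        )
    if len(prom_jobs) > n_genes:
        raise GenerationError(
            f"need {len(prom_jobs)} promoter windows but only {n_genes} genes"
        )

    # hairpins for all miRNA jobs
    for job in gene_jobs + gap_jobs + prom_jobs:
        if job["cls"] in ("known_mirna", "novel_mirna", "mirtron_typical", "mirtron_atypical"):
            job["hairpin"] = _make_hairpin(rng, adapter_probe=adapter_probe)

    # ---- lay out the genome left to right: gap, gene, gap, gene, ...
    overwrite: list[tuple[int, str]] = []  # (genomic start, plus-strand sequence)
    manifest: list[PlantedLocus] = []
    sampling: dict[str, SimLocus] = {}
    models: list[GeneModel] = []
    rrna_seqs: dict[str, str] = {}
    decoy_jobs_by_gene: dict[int, dict] = {}

    def plant_mirna(job: dict, prec_start: int, strand: str, context: str) -> None:
        core, flanked, mature_c, star_c = job["hairpin"]
        plen = len(core)
        prec = (prec_start, prec_start + plen)
        block = flanked if strand == "+" else revcomp(flanked)
        overwrite.append((prec_start - PRECURSOR_FLANK, block))
        manifest.append(
            PlantedLocus(
                job["id"], job["cls"], CHROM, strand, prec,
                _local_to_genomic(prec, mature_c, strand),
                _local_to_genomic(prec, star_c, strand),
                context,
            )
        )
        shift = PRECURSOR_FLANK
        sampling[job["id"]] = SimLocus(
            job["id"], job["cls"], flanked,
            (mature_c[0] + shift, mature_c[1] + shift),
            (star_c[0] + shift, star_c[1] + shift),
        )

    cursor = 0
    gap_queue = list(gap_jobs)
    for gi in range(n_genes):
        gap_len = 2400 + int(rng.integers(0, 301))
        gap_start, gene_start = cursor, cursor + gap_len
        # intergenic job in this gap's free zone (clear of both promoter windows)
        if gap_queue:
            job = gap_queue.pop(0)
            free_lo = gap_start + promoter_len + 100
            free_hi = gene_start - promoter_len - 100
            if job["cls"] == "rrna":
                rlen = 140
                if free_hi - free_lo < rlen + 20:
                    raise GenerationError("gap too small for rrna locus")
                s = free_lo + int(rng.integers(0, free_hi - free_lo - rlen))
                seq = random_dna(rng, rlen)
                overwrite.append((s, seq))
                rrna_seqs[job["id"]] = seq
                iv = (s, s + rlen)
                win = (60, 81)
                manifest.append(
                    PlantedLocus(job["id"], "rrna", CHROM, "+", iv,
                                 (s + win[0], s + win[1]), None, "intergenic")
                )
                sampling[job["id"]] = SimLocus(job["id"], "rrna", seq, win, None)
            else:
                plen = len(job["hairpin"][0])
                if free_hi - free_lo < plen + 20:
                    raise GenerationError(f"gap too small for {job['cls']} locus")
                s = free_lo + int(rng.integers(0, free_hi - free_lo - plen))
                strand = "+" if rng.random() < 0.5 else "-"
                plant_mirna(job, s, strand, "intergenic")
        # promoter job right before this gene (gene forced to + strand)
        gene_forced_plus = False
        if gi < len(prom_jobs):
            job = prom_jobs[gi]
            gene_forced_plus = True
            plen = len(job["hairpin"][0])
            lo = gene_start - promoter_len + 20
            hi = gene_start - plen - 20
            s = lo + int(rng.integers(0, hi - lo))
            strand = "+" if rng.random() < 0.5 else "-"
            plant_mirna(job, s, strand, "promoter")

        # ---- the gene itself
        special = gene_jobs[gi] if gi < len(gene_jobs) else None
        strand = "+" if (gene_forced_plus or rng.random() < 0.5) else "-"
        n_exons = int(rng.integers(3, 6))
        exon_lens = [int(rng.integers(120, 251)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(150, 401)) for _ in range(n_exons - 1)]
        intron_offset = None  # (intron index, offset of precursor in intron)
        if special is not None and special["ctx"] == "intron":
            plen = len(special["hairpin"][0])
            k = int(rng.integers(0, n_exons - 1))
            if special["cls"] == "mirtron_typical":
                intron_lens[k] = plen
                intron_offset = (k, 0)
            elif special["cls"] == "mirtron_atypical":
                extra = int(rng.integers(15, 41))
                intron_lens[k] = plen + extra
                intron_offset = (k, 0 if rng.random() < 0.5 else extra)
            else:
                intron_lens[k] = max(intron_lens[k], plen + 40)
                intron_offset = (k, 12 + int(rng.integers(0, intron_lens[k] - plen - 24)))
        exons: list[tuple[int, int]] = []
        pos = gene_start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if i < n_exons - 1:
                if intron_offset is not None and intron_offset[0] == i:
                    job = special
                    plant_mirna(job, pos + intron_offset[1], strand, "intron")
                pos += intron_lens[i]
        gene_end = pos
        utr5, utr3 = int(rng.integers(30, 81)), int(rng.integers(30, 81))
        if strand == "+":
            cds = (gene_start + utr5, gene_end - utr3)
        else:
            cds = (gene_start + utr3, gene_end - utr5)
        tx_id = f"tx{gi + 1:03d}"
        models.append(
            GeneModel(tx_id, CHROM, strand, (gene_start, gene_end), exons, cds)
        )
        if special is not None and special["cls"] == "mrna_decoy":
            k = int(rng.integers(1, n_exons - 1))  # fully coding middle exon
            es, ee = exons[k]
            dlen = 21
            ds = es + 8 + int(rng.integers(0, (ee - es) - dlen - 16))
            manifest.append(
                PlantedLocus(special["id"], "mrna_decoy", CHROM, strand,
                             (ds, ds + dlen), (ds, ds + dlen), None, "exon")
            )
            decoy_jobs_by_gene[gi] = {
                "id": special["id"], "window": (ds, ds + dlen), "tx": tx_id,
            }
        cursor = gene_end
        if cursor + 2800 > genome_length:
            raise GenerationError(
                "genome_length too small for requested genes and planted loci"
            )
    if gap_queue:
        raise GenerationError(f"no gap left for {gap_queue[0]['cls']} locus")

    # ---- materialise the genome and overwrite planted blocks
    genome_arr = np.array(list(random_dna(rng, genome_length)))
    for start, block in overwrite:
        if start < 0 or start + len(block) > genome_length:
            raise GenerationError("planted block outside genome bounds")
        genome_arr[start : start + len(block)] = list(block)
    genome = {CHROM: "".join(genome_arr)}

    # ---- derived reference sets
    transcriptome = {m.transcript_id: spliced_sequence(genome, m) for m in models}
    known_records: dict[str, KnownMiRNARecord] = {}
    for locus in manifest:
        if locus.locus_class == "known_mirna":
            sim = sampling[locus.locus_id]
            known_records[locus.locus_id] = KnownMiRNARecord(
                locus.locus_id, sim.ext_seq, sim.mature_local, sim.star_local
            )
    # decoy sampling uses the spliced transcript so reads can cross junctions
    for gi, job in decoy_jobs_by_gene.items():
        m = models[gi]
        tx_seq = transcriptome[job["tx"]]
        ds, de = job["window"]
        offset = 0
        local = None
        for s, e in m.exons:
            if s <= ds < e:
                local = offset + (ds - s)
                break
            offset += e - s
        if local is None:
            raise GenerationError("mrna_decoy window not inside an exon")
        if m.strand == "-":
            local = len(tx_seq) - (local + (de - ds))
        sampling[job["id"]] = SimLocus(
            job["id"], "mrna_decoy", tx_seq, (local, local + (de - ds)), None
        )

    manifest.sort(key=lambda l: l.precursor_interval)
    return ReferenceSet(
        genome=genome,
        gene_models=models,
        manifest=manifest,
        known_records=known_records,
        transcriptome=transcriptome,
        rrna=rrna_seqs,
        sampling=sampling,
        promoter_len=promoter_len,
    )


# ------------------------------------------------------------------ simulation

def simulate_library(
    refs: ReferenceSet, config: ReadSimConfig
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Simulate one library: (read_id, sequence) pairs plus ground truth.

    Each non-noise read is a mature/star/decoy subsequence of its locus,
    end-shifted by sampled isomiR offsets, substituted at ``error_rate``
    per base, and extended with the 3' adapter up to the read length.
    """
    config.validate()
    for locus_id in config.locus_weights:
        if locus_id not in refs.sampling:
            raise ValueError(f"unknown locus_id in weights: {locus_id}")
    rng = spawn_rng(config.seed, 11)
    n = config.n_reads
    if n == 0:
        return [], GroundTruth(
            config.library_id,
            pd.DataFrame(columns=["read_id", "locus_id", "arm",
                                  "five_prime_offset", "three_prime_offset"]),
            {},
        )
    locus_ids = sorted(k for k, w in config.locus_weights.items() if w > 0)
    weights = np.array([config.locus_weights[k] for k in locus_ids], dtype=float)
    probs = weights / weights.sum()
    offsets = sorted(config.isomir_probs)
    off_probs = np.array([config.isomir_probs[o] for o in offsets])
    off_probs = off_probs / off_probs.sum()

    noise_mask = rng.random(n) < config.singleton_noise_fraction
    locus_idx = rng.choice(len(locus_ids), size=n, p=probs)
    off_idx = rng.choice(len(offsets), size=n, p=off_probs)
    arm_rand = rng.random(n)

    p_mature = np.ones(len(locus_ids))
    for i, lid in enumerate(locus_ids):
        sim = refs.sampling[lid]
        if sim.star_local is not None:
            r = config.arm_ratio.get(lid, 10.0)
            p_mature[i] = r / (1.0 + r)

    reads: list[tuple[str, str]] = []
    recs: list[tuple[str, str, str, int, int]] = []
    variant_cache: dict[tuple[str, str, int, int], str] = {}
    expected: dict[str, float] = {
        lid: float(n * (1 - config.singleton_noise_fraction) * p)
        for lid, p in zip(locus_ids, probs)
    }

    for i in range(n):
        read_id = f"{config.library_id}:{i}"
        if noise_mask[i]:
            insert = random_dna(rng, int(rng.integers(18, 27)))
            recs.append((read_id, "noise", "noise", 0, 0))
        else:
            lid = locus_ids[locus_idx[i]]
            sim = refs.sampling[lid]
            if sim.star_local is not None and arm_rand[i] >= p_mature[locus_idx[i]]:
                arm, (s, e) = "star", sim.star_local
            else:
                arm = "mature" if sim.locus_class != "rrna" and sim.locus_class != "mrna_decoy" else "decoy"
                s, e = sim.mature_local
            o5, o3 = offsets[off_idx[i]]
            key = (lid, arm, o5, o3)
            insert = variant_cache.get(key)
            if insert is None:
                lo = max(0, s + o5)
                hi = min(len(sim.ext_seq), e + o3)
                insert = sim.ext_seq[lo:hi]
                variant_cache[key] = insert
            recs.append((read_id, lid, arm, o5, o3))
        read = (insert + config.adapter)[: config.read_length]
        n_err = rng.binomial(len(read), config.error_rate)
        if n_err:
            arr = list(read)
            for pos in rng.choice(len(read), size=n_err, replace=False):
                arr[pos] = random_dna(rng, 1)
            read = "".join(arr)
        reads.append((read_id, read))

    origins = pd.DataFrame(
        recs,
        columns=["read_id", "locus_id", "arm", "five_prime_offset", "three_prime_offset"],
    )
    return reads, GroundTruth(config.library_id, origins, expected)


# ------------------------------------------------------------ default libraries

def default_library_configs(
    refs: ReferenceSet,
    n_libraries: int = 12,
    n_reads: int = 50_000,
    n_profiles: int = 4,
    seed: int = 0,
) -> list[ReadSimConfig]:
    """Library configurations for the default study design.

    Libraries are grouped into ``n_profiles`` expression profiles with
    replicate libraries per profile: replicates share the profile's
    locus-weight vector (log-normal across loci) and differ only in their
    read-sampling seed, so same-profile libraries should cluster together.
    Arm ratios are a per-locus property shared by all libraries, drawn from
    a grid spanning star-dominant (0.03) to extreme mature-dominant (2000).
    """
    rng = spawn_rng(seed, 2)
    locus_ids = sorted(refs.sampling)
    arm_ratio = {
        lid: float(DEFAULT_ARM_RATIO_GRID[rng.integers(len(DEFAULT_ARM_RATIO_GRID))])
        for lid in locus_ids
        if refs.sampling[lid].star_local is not None
    }
    profiles = []
    for _ in range(n_profiles):
        w = np.exp(rng.normal(0.0, 1.2, size=len(locus_ids)))
        # decoy/rRNA loci carry less weight than true miRNA loci
        for i, lid in enumerate(locus_ids):
            if refs.sampling[lid].locus_class in ("rrna", "mrna_decoy"):
                w[i] *= 0.3
        profiles.append({lid: float(wi) for lid, wi in zip(locus_ids, w)})
    configs = []
    for i in range(n_libraries):
        g = i % n_profiles
        rep = i // n_profiles + 1
        configs.append(
            ReadSimConfig(
                library_id=f"{chr(ord('A') + g)}{rep}",
                n_reads=n_reads,
                locus_weights=dict(profiles[g]),
                arm_ratio=dict(arm_ratio),
                seed=int(spawn_rng(seed, 3, i).integers(2**31 - 1)),
            )
        )
    return configs


# ----------------------------------------------------------------- persistence

MANIFEST_COLUMNS = [
    "locus_id", "locus_class", "chrom", "strand", "precursor_start",
    "precursor_end", "mature_start", "mature_end", "star_start", "star_end",
    "context_label",
]


def manifest_to_frame(manifest: list[PlantedLocus]) -> pd.DataFrame:
    rows = []
    for l in manifest:
        rows.append({
            "locus_id": l.locus_id, "locus_class": l.locus_class,
            "chrom": l.chrom, "strand": l.strand,
            "precursor_start": l.precursor_interval[0],
            "precursor_end": l.precursor_interval[1],
            "mature_start": l.mature_interval[0],
            "mature_end": l.mature_interval[1],
            "star_start": l.star_interval[0] if l.star_interval else "",
            "star_end": l.star_interval[1] if l.star_interval else "",
            "context_label": l.context_label,
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def frame_to_manifest(df: pd.DataFrame) -> list[PlantedLocus]:
    out = []
    for _, r in df.iterrows():
        star = None
        if str(r["star_start"]) not in ("", "nan"):
            star = (int(float(r["star_start"])), int(float(r["star_end"])))
        out.append(
            PlantedLocus(
                str(r["locus_id"]), str(r["locus_class"]), str(r["chrom"]),
                str(r["strand"]),
                (int(r["precursor_start"]), int(r["precursor_end"])),
                (int(r["mature_start"]), int(r["mature_end"])),
                star, str(r["context_label"]),
            )
        )
    return out


def write_reference_set(refs: ReferenceSet, outdir) -> None:
    import os

    from . import io as mio

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    mio.write_fasta(j("genome.fa"), refs.genome)
    mio.write_fasta(j("transcriptome.fa"), refs.transcriptome)
    mio.write_fasta(j("rrna.fa"), refs.rrna)
    mio.write_fasta(
        j("precursors.fa"), {k: v.precursor_seq for k, v in refs.known_records.items()}
    )
    reg = pd.DataFrame(
        [
            {
                "precursor_id": k,
                "mature_start": v.mature_interval[0],
                "mature_end": v.mature_interval[1],
                "star_start": v.star_interval[0] if v.star_interval else "",
                "star_end": v.star_interval[1] if v.star_interval else "",
            }
            for k, v in sorted(refs.known_records.items())
        ],
        columns=mio.REGISTRY_COLUMNS,
    )
    mio.write_registry(j("registry.tsv"), reg)
    mio.write_gff3(j("genes.gff3"), refs.gene_models)
    mio.write_tsv(j("manifest.tsv"), manifest_to_frame(refs.manifest))
    samp = pd.DataFrame(
        [
            {
                "locus_id": s.locus_id, "locus_class": s.locus_class,
                "ext_seq": s.ext_seq,
                "mature_start": s.mature_local[0], "mature_end": s.mature_local[1],
                "star_start": s.star_local[0] if s.star_local else "",
                "star_end": s.star_local[1] if s.star_local else "",
            }
            for s in sorted(refs.sampling.values(), key=lambda x: x.locus_id)
        ]
    )
    mio.write_tsv(j("sampling.tsv"), samp)


def load_reference_set(outdir) -> ReferenceSet:
    import os

    from . import io as mio

    j = lambda name: os.path.join(outdir, name)
    genome = mio.read_fasta(j("genome.fa"))
    models = mio.read_gff3(j("genes.gff3"))
    manifest = frame_to_manifest(mio.read_tsv(
        j("manifest.tsv"), dtype={"star_start": str, "star_end": str},
        keep_default_na=False,
    ))
    precursors = mio.read_fasta(j("precursors.fa"))
    reg = mio.read_registry(j("registry.tsv"))
    known = {}
    for _, r in reg.iterrows():
        star = None
        if str(r["star_start"]) not in ("", "nan"):
            star = (int(float(r["star_start"])), int(float(r["star_end"])))
        known[r["precursor_id"]] = KnownMiRNARecord(
            r["precursor_id"], precursors[r["precursor_id"]],
            (int(r["mature_start"]), int(r["mature_end"])), star,
        )
    samp_df = mio.read_tsv(
        j("sampling.tsv"), dtype={"star_start": str, "star_end": str},
        keep_default_na=False,
    )
    sampling = {}
    for _, r in samp_df.iterrows():
        star = None
        if str(r["star_start"]) not in ("", "nan"):
            star = (int(float(r["star_start"])), int(float(r["star_end"])))
        sampling[r["locus_id"]] = SimLocus(
            r["locus_id"], r["locus_class"], r["ext_seq"],
            (int(r["mature_start"]), int(r["mature_end"])), star,
        )
    return ReferenceSet(
        genome=genome, gene_models=models, manifest=manifest,
        known_records=known, transcriptome=mio.read_fasta(j("transcriptome.fa")),
        rrna=mio.read_fasta(j("rrna.fa")), sampling=sampling,
    )
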