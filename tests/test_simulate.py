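"""Synthetic reference and read-library generation."""

import numpy as np
import pytest
from scipy.stats import binom

from mirkit.fold import fold, is_hairpin
from mirkit.simulate import (
    GenerationError,
    ReadSimConfig,
    build_reference_set,
    frame_to_manifest,
    manifest_to_frame,
    simulate_library,
)
from mirkit.util import revcomp


class TestBuildReferenceSet:
    def test_no_planted_loci_gives_genes_only(self):
        refs = build_reference_set(
            genome_length=60_000, n_genes=5,
            n_planted={c: 0 for c in ("known_mirna", "novel_mirna")}, seed=3,
        )
        assert refs.manifest == []
        assert len(refs.gene_models) == 5
        assert len(refs.transcriptome) == 5

    def test_determinism_same_seed_identical_output(self):
        a = build_reference_set(seed=5)
        b = build_reference_set(seed=5)
        assert a.genome == b.genome
        assert a.manifest == b.manifest
        assert a.transcriptome == b.transcriptome

    def test_genome_too_small_raises_generation_error(self):
        with pytest.raises((GenerationError, ValueError)):
            build_reference_set(genome_length=10_000, n_genes=30, seed=1)

    def test_mirtron_ends_coincide_with_intron_boundaries(self, refs):
        from mirkit.io import read_gff3, write_gff3

        for locus in refs.loci_of_class("mirtron_typical", "mirtron_atypical"):
            ps, pe = locus.precursor_interval
            anchors = []
            for m in refs.gene_models:
                for isv, iev in m.introns:
                    anchors.append((ps == isv) + (pe == iev))
            want = 2 if locus.locus_class == "mirtron_typical" else 1
            assert max(anchors) == want

    def test_arm_intervals_within_precursor_and_disjoint(self, refs):
        for locus in refs.manifest:
            ps, pe = locus.precursor_interval
            ms, me = locus.mature_interval
            assert ps <= ms < me <= pe
            if locus.star_interval:
                ss, se = locus.star_interval
                assert ps <= ss < se <= pe
                assert me <= ss or se <= ms

    def test_every_planted_precursor_passes_hairpin_gate(self, refs):
        for locus in refs.manifest:
            if not locus.is_mirna:
                continue
            s, e = locus.precursor_interval
            seq = refs.genome[locus.chrom][s:e]
            if locus.strand == "-":
                seq = revcomp(seq)
            assert is_hairpin(fold(seq)), locus.locus_id

    def test_transcriptome_contains_spliced_sequences(self, refs):
        from mirkit.io import spliced_sequence

        for m in refs.gene_models[:5]:
            assert refs.transcriptome[m.transcript_id] == spliced_sequence(
                refs.genome, m
            )

    def test_manifest_round_trips_losslessly(self, refs):
        frame = manifest_to_frame(refs.manifest)
        assert frame_to_manifest(frame) == refs.manifest


class TestSimulateLibrary:
    def _config(self, refs, **kw):
        lid = sorted(refs.sampling)[0]
        defaults = dict(
            library_id="T1", n_reads=1000,
            locus_weights={lid: 1.0}, arm_ratio={lid: 1.0}, seed=9,
        )
        defaults.update(kw)
        return ReadSimConfig(**defaults)

    def test_zero_reads_gives_empty_outputs(self, refs):
        reads, truth = simulate_library(refs, self._config(refs, n_reads=0))
        assert reads == [] and len(truth.origins) == 0

    def test_unknown_locus_is_a_configuration_error(self, refs):
        with pytest.raises(ValueError, match="unknown locus"):
            simulate_library(
                refs, self._config(refs, locus_weights={"nope": 1.0})
            )

    def test_read_count_and_origin_conservation(self, refs):
        cfg = self._config(refs, n_reads=500, singleton_noise_fraction=0.1)
        reads, truth = simulate_library(refs, cfg)
        assert len(reads) == 500
        assert len(truth.origins) == 500  # exactly one origin per read
        noise = (truth.origins["locus_id"] == "noise").sum()
        assert noise + sum(truth.realized_counts().values()) == 500

    def test_determinism_identical_seed_identical_reads(self, refs):
        cfg = self._config(refs)
        a, _ = simulate_library(refs, cfg)
        b, _ = simulate_library(refs, cfg)
        assert a == b

    def test_equal_arm_ratio_within_binomial_interval(self, refs):
        lid = sorted(
            l for l, s in refs.sampling.items() if s.star_local is not None
        )[0]
        cfg = ReadSimConfig(
            library_id="T2", n_reads=1000, locus_weights={lid: 1.0},
            arm_ratio={lid: 1.0}, isomir_probs={(0, 0): 1.0},
            error_rate=0.0, singleton_noise_fraction=0.0, seed=13,
        )
        _, truth = simulate_library(refs, cfg)
        k = int((truth.origins["arm"] == "mature").sum())
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= k <= hi

    def test_configured_isomir_offsets_within_binomial_intervals(self, refs):
        lid = sorted(refs.sampling)[0]
        probs = {(0, 0): 0.65, (0, 1): 0.3, (1, 0): 0.05}
        cfg = ReadSimConfig(
            library_id="T3", n_reads=2000, locus_weights={lid: 1.0},
            arm_ratio={lid: 10.0}, isomir_probs=probs,
            error_rate=0.0, singleton_noise_fraction=0.0, seed=17,
        )
        _, truth = simulate_library(refs, cfg)
        for off, p in probs.items():
            k = int(
                (
                    (truth.origins["five_prime_offset"] == off[0])
                    & (truth.origins["three_prime_offset"] == off[1])
                ).sum()
            )
            lo, hi = binom.ppf([0.005, 0.995], 2000, p)
            assert lo <= k <= hi, off

    def test_isomir_probs_must_sum_to_one(self, refs):
        with pytest.raises(ValueError, match="sum"):
            simulate_library(
                refs,
                self._config(refs, isomir_probs={(0, 0): 0.5, (0, 1): 0.2}),
            )

    def test_reads_carry_adapter_readthrough(self, refs):
        cfg = self._config(refs, error_rate=0.0, singleton_noise_fraction=0.0)
        reads, _ = simulate_library(refs, cfg)
        assert all(len(seq) == cfg.read_length for _, seq in reads)
        assert any(cfg.adapter[:5] in seq for _, seq in reads)
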