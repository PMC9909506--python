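"""Tandem-array detection, monomer clustering, centromere calls."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_dna
from t2tkit.centromere import (
    cluster_monomers, dominant_monomer, extract_monomers, feature_density,
    find_tandem_arrays, locate_centromere, representative_length,
    window_similarity_matrix,
)
from t2tkit.pairwise import canonical_monomer
from t2tkit.seqio import GenomicInterval, SeqRecord
from t2tkit.synthetic import SimParams, generate_genome, mutate_sequence


def _monomer_array(rng, period, copies, divergence):
    mono = random_dna(rng, period)
    return mono, "".join(mutate_sequence(mono, divergence, rng)
                         for _ in range(copies))


class TestFindTandemArrays:
    def test_pure_short_repeat(self):
        arrs = find_tandem_arrays(SeqRecord("r", "ACG" * 100))
        assert len(arrs) == 1
        a = arrs[0]
        assert a.period == 3
        assert a.copy_number == pytest.approx(100, rel=0.05)

    def test_diverged_153_monomer(self):
        rng = np.random.default_rng(70)
        mono, arr = _monomer_array(rng, 153, 500, 0.02)
        seq = random_dna(rng, 20_000) + arr + random_dna(rng, 20_000)
        arrs = find_tandem_arrays(SeqRecord("r", seq))
        assert [a.period for a in arrs] == [153]
        a = arrs[0]
        assert a.copy_number == pytest.approx(500, rel=0.05)
        assert GenomicInterval("r", 20_000, 20_000 + len(arr)) \
            .reciprocal_overlap(a.interval) > 0.99
        assert len(a.consensus) == 153

    def test_random_sequence_yields_no_monomer_scale_arrays(self):
        rec = SeqRecord("r", random_dna(np.random.default_rng(71),
                                        100_000))
        arrs = find_tandem_arrays(rec)
        assert not [a for a in arrs
                    if 100 <= a.period <= 200 and a.copy_number >= 5]

    def test_higher_order_unit_detected_at_unit_period(self):
        # three distinct ~150-bp monomers repeated head-to-tail: the
        # repeating unit is their concatenation
        rng = np.random.default_rng(72)
        unit = random_dna(rng, 152) + random_dna(rng, 149) \
            + random_dna(rng, 151)
        arr = "".join(mutate_sequence(unit, 0.02, rng)
                      for _ in range(120))
        seq = random_dna(rng, 10_000) + arr + random_dna(rng, 10_000)
        arrs = find_tandem_arrays(SeqRecord("r", seq))
        assert [a.period for a in arrs] == [452]

    def test_score_threshold_filters_tiny_arrays(self, cfg):
        # two perfect copies of a 12-mer score 2*24 = 48 < 50
        seq = random_dna(np.random.default_rng(73), 5000)
        rec = SeqRecord("r", seq + "ACGTTGCAACGT" * 2 + seq[:5000])
        assert [a for a in find_tandem_arrays(rec, cfg)
                if a.period == 12] == []


class TestMonomers:
    def test_length_filter_inclusive(self, cfg):
        from t2tkit.centromere import TandemArray

        def arr(period):
            iv = GenomicInterval("r", 0, period * 4)
            return TandemArray(
                iv, period, 4.0, random_dna(np.random.default_rng(period),
                                            period), 999)
        periods = [3, 99, 100, 153, 200, 201, 500]
        kept = extract_monomers([arr(p) for p in periods], cfg)
        assert sorted(m.length for m in kept) == [100, 153, 200]

    def test_empty(self, cfg):
        assert extract_monomers([], cfg) == []

    def test_canonical_forms_attached(self, cfg):
        rng = np.random.default_rng(74)
        mono, arrseq = _monomer_array(rng, 120, 50, 0.0)
        arrs = find_tandem_arrays(SeqRecord("r", arrseq), cfg)
        monomers = extract_monomers(arrs, cfg)
        assert monomers[0].canonical == canonical_monomer(
            monomers[0].sequence)


class TestClustering:
    def test_identical_monomers_one_cluster(self, cfg):
        from t2tkit.centromere import Monomer
        m = random_dna(np.random.default_rng(75), 150)
        monos = [Monomer(m, canonical_monomer(m),
                         GenomicInterval("r", i * 1000, i * 1000 + 600))
                 for i in range(2)]
        cl = cluster_monomers(monos, cfg)
        assert len(cl) == 1 and cl[0].size == 2

    def test_unrelated_monomers_two_clusters(self, cfg):
        from t2tkit.centromere import Monomer
        rng = np.random.default_rng(76)
        monos = []
        for i in range(2):
            m = random_dna(rng, 150)
            monos.append(Monomer(m, canonical_monomer(m),
                                 GenomicInterval("r", i * 1000,
                                                 i * 1000 + 600)))
        assert len(cluster_monomers(monos, cfg)) == 2

    def test_mutated_families_partition(self, cfg):
        from t2tkit.centromere import Monomer
        rng = np.random.default_rng(77)
        fams = [random_dna(rng, 150), random_dna(rng, 170)]
        monos = []
        for i in range(40):
            base = fams[i % 2]
            seq = mutate_sequence(base, 0.05, rng, indel_rate=0.0)
            monos.append(Monomer(seq, canonical_monomer(seq),
                                 GenomicInterval("r", i * 1000,
                                                 i * 1000 + 600)))
        clusters = cluster_monomers(monos, cfg)
        assert len(clusters) == 2
        assert sorted(c.size for c in clusters) == [20, 20]
        # partition law + member-representative identity bound
        from t2tkit.centromere import monomer_identity
        seen = set()
        for c in clusters:
            for m in c.members:
                key = (m.source.start, m.source.end)
                assert key not in seen
                seen.add(key)
                assert monomer_identity(
                    m.canonical, c.representative.canonical, cfg
                ) >= cfg.cluster_identity
        assert len(seen) == 40


@pytest.fixture(scope="module")
def called_genome(cfg):
    params = SimParams(telomere_units_5p=100, telomere_units_3p=100,
                       centromere_span=150_000, divergence=0.02)
    hap1, _, man = generate_genome(1, 800_000, params, seed=78)
    rec = hap1[0]
    arrays = find_tandem_arrays(rec, cfg)
    monomers = extract_monomers(arrays, cfg)
    clusters = cluster_monomers(monomers, cfg)
    reps = [c.representative for c in clusters]
    call = locate_centromere(rec, reps, cfg, arrays)
    return rec, man, arrays, clusters, call


class TestLocate:
    def test_planted_interval_recovered(self, called_genome):
        rec, man, arrays, clusters, call = called_genome
        truth = man.haplotypes["hap1"]["Chr01"].centromere
        assert call is not None
        assert call.interval.reciprocal_overlap(
            GenomicInterval("Chr01", truth.start, truth.end)) >= 0.9
        assert 0 <= call.interval.start < call.interval.end <= len(rec)

    def test_dominant_single_monomer(self, called_genome):
        rec, man, arrays, clusters, call = called_genome
        cid, mono, frac = dominant_monomer(call, arrays, clusters)
        assert frac == 1.0
        assert mono.length == 153

    def test_no_array_no_call(self, cfg):
        rec = SeqRecord("r", random_dna(np.random.default_rng(79),
                                        400_000))
        from t2tkit.centromere import Monomer
        m = random_dna(np.random.default_rng(80), 150)
        rep = Monomer(m, canonical_monomer(m),
                      GenomicInterval("x", 0, 600))
        assert locate_centromere(rec, [rep], cfg) is None

    def test_largest_of_two_arrays_wins(self, cfg):
        rng = np.random.default_rng(81)
        mono = random_dna(rng, 153)
        big = "".join(mutate_sequence(mono, 0.02, rng)
                      for _ in range(1000))   # ~153 kb
        small = "".join(mutate_sequence(mono, 0.02, rng)
                        for _ in range(400))  # ~61 kb
        seq = random_dna(rng, 50_000) + big + random_dna(rng, 300_000) \
            + small + random_dna(rng, 50_000)
        rec = SeqRecord("r", seq)
        arrays = find_tandem_arrays(rec, cfg)
        clusters = cluster_monomers(extract_monomers(arrays, cfg), cfg)
        call = locate_centromere(
            rec, [c.representative for c in clusters], cfg, arrays)
        big_iv = GenomicInterval("r", 50_000, 50_000 + len(big))
        assert call.interval.reciprocal_overlap(big_iv) >= 0.9

    def test_mixture_dominant_fraction(self, cfg):
        params = SimParams(monomer_lengths=(153, 120),
                           mixture_fractions=(0.7, 0.3),
                           telomere_units_5p=100, telomere_units_3p=100,
                           centromere_span=150_000, divergence=0.02)
        hap1, _, man = generate_genome(1, 800_000, params, seed=82)
        rec = hap1[0]
        arrays = find_tandem_arrays(rec, cfg)
        clusters = cluster_monomers(extract_monomers(arrays, cfg), cfg)
        call = locate_centromere(
            rec, [c.representative for c in clusters], cfg, arrays)
        cid, mono, frac = dominant_monomer(call, arrays, clusters)
        assert mono.length == 153
        assert frac == pytest.approx(0.7, abs=0.05)


class TestRepresentativeLength:
    def test_mode(self):
        from t2tkit.centromere import CentromereCall, Monomer
        def call(length, i):
            m = "A" * length
            c = CentromereCall(
                f"c{i}", GenomicInterval(f"c{i}", 0, 100_000),
                np.zeros(1))
            c.dominant_monomer = Monomer(
                m, canonical_monomer(m), GenomicInterval(f"c{i}", 0, 600))
            return c
        calls = [call(L, i)
                 for i, L in enumerate([153, 153, 152, 195])]
        assert representative_length(calls) == 153
        assert representative_length([call(160, 0)]) == 160
        # tie resolves to the smaller length
        calls = [call(L, i) for i, L in enumerate([152, 152, 190, 190])]
        assert representative_length(calls) == 152

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            representative_length([])


class TestSimilarityMatrix:
    def test_identical_and_random_windows(self, cfg):
        rng = np.random.default_rng(83)
        w = random_dna(rng, 50_000)
        other = random_dna(rng, 50_000)
        rec = SeqRecord("r", w + other + w)
        M = window_similarity_matrix(rec, cfg)
        assert M.shape == (3, 3)
        assert np.allclose(M, M.T) and np.allclose(np.diag(M), 1.0)
        assert M[0, 2] == pytest.approx(1.0)
        assert M[0, 1] < 0.01

    def test_satellite_block_has_high_internal_similarity(self, cfg):
        rng = np.random.default_rng(84)
        mono = random_dna(rng, 153)
        arr = "".join(mutate_sequence(mono, 0.02, rng)
                      for _ in range(1000))  # ~153 kb = 3 windows
        rec = SeqRecord("r", random_dna(rng, 100_000) + arr
                        + random_dna(rng, 100_000))
        M = window_similarity_matrix(rec, cfg)
        inside = M[2, 3]
        flank = M[0, 1]
        assert inside > 10 * max(flank, 1e-6)


class TestFeatureDensity:
    def test_exact_bin_coverage(self):
        track = feature_density(
            [GenomicInterval("c", 100_000, 200_000)], 400_000)
        assert track.tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_empty(self):
        assert feature_density([], 250_000).sum() == 0.0

    def test_covered_base_conservation(self):
        rng = np.random.default_rng(85)
        ivs = []
        for _ in range(40):
            s = int(rng.integers(0, 900_000))
            ivs.append(GenomicInterval("c", s,
                                       s + int(rng.integers(1, 80_000))))
        chrom_len = 1_000_000
        track = feature_density(ivs, chrom_len)
        nbins = len(track)
        starts = np.arange(nbins) * 100_000
        widths = np.minimum(starts + 100_000, chrom_len) - starts
        total = float((track * widths).sum())
        # merged-interval union length
        merged_end, union = -1, 0
        for iv in sorted(ivs, key=lambda v: v.start):
            s, e = iv.start, min(iv.end, chrom_len)
            if s > merged_end:
                union += e - s
                merged_end = e
            elif e > merged_end:
                union += e - merged_end
                merged_end = e
        assert total == pytest.approx(union)

    def test_count_mode(self):
        ivs = [GenomicInterval("c", 10, 20),
               GenomicInterval("c", 150_000, 150_001)]
        track = feature_density(ivs, 300_000, mode="count")
        assert track.tolist() == [1.0, 1.0, 0.0]
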