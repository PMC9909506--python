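"""Gap filling: constructed donors, inclusive threshold boundaries,
conservation outside replaced intervals, idempotence."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_dna
from t2tkit.gapfill import collect_candidates, fill_gaps, select_donor
from t2tkit.pairwise import revcomp
from t2tkit.seqio import SeqRecord, find_n_runs
from t2tkit.synthetic import SimParams, generate_genome, \
    make_gapped_object_and_donors


@pytest.fixture(scope="module")
def scene():
    """Object L + N*100 + R with 5-kb unique flanks."""
    rng = np.random.default_rng(50)
    left = random_dna(rng, 5000)
    right = random_dna(rng, 5000)
    obj = SeqRecord("o", left + "N" * 100 + right)
    gap = find_n_runs(obj)[0]
    return left, right, obj, gap


def _substitute_block(seq: str, start: int, n: int) -> str:
    """Replace n consecutive bases by N.  N matches nothing under the
    alignment scoring, so the flank identity is exactly
    (len - n) / len whatever path the aligner picks — ordinary base
    substitutions can be partially recovered by gapped realignment and
    do not pin the identity."""
    return seq[:start] + "N" * n + seq[start + n:]


class TestCollectAndSelect:
    def test_spanning_donor_with_novel_insert(self, scene, cfg):
        left, right, obj, gap = scene
        insert = random_dna(np.random.default_rng(51), 5000)
        donor = SeqRecord("d", left[-2000:] + insert + right[:2000])
        cands, _ = collect_candidates(obj, gap, [donor], cfg)
        assert len(cands) == 1
        c = cands[0]
        assert c.mean_flank_identity == pytest.approx(1.0)
        assert c.spanning[1] - c.spanning[0] == 5000

    def test_donor_on_reverse_strand(self, scene, cfg):
        left, right, obj, gap = scene
        insert = random_dna(np.random.default_rng(52), 3000)
        donor = SeqRecord("d", revcomp(left[-2000:] + insert
                                       + right[:2000]))
        cands, _ = collect_candidates(obj, gap, [donor], cfg)
        assert len(cands) == 1 and cands[0].donor_strand == "-"

    def test_flank_order_inverted_on_donor_excluded(self, scene, cfg):
        left, right, obj, gap = scene
        donor = SeqRecord("d", right[:2000]
                          + random_dna(np.random.default_rng(53), 3000)
                          + left[-2000:])
        cands, _ = collect_candidates(obj, gap, [donor], cfg)
        assert cands == []

    def test_gap_at_object_edge(self, cfg):
        rng = np.random.default_rng(54)
        obj = SeqRecord("o", "N" * 100 + random_dna(rng, 5000))
        gap = find_n_runs(obj)[0]
        cands, saw = collect_candidates(obj, gap, [], cfg)
        assert cands == [] and saw is False

    def test_select_prefers_identity_then_block_then_id(self, scene, cfg):
        left, right, obj, gap = scene
        ins = random_dna(np.random.default_rng(55), 1000)
        exact = SeqRecord("b_exact", left[-2000:] + ins + right[:2000])
        worse = SeqRecord("a_mut",
                          _substitute_block(left[-2000:], 500, 300)
                          + ins + right[:2000])
        cands, _ = collect_candidates(obj, gap, [exact, worse], cfg)
        assert select_donor(cands).donor_id == "b_exact"
        # longer flanks win at equal identity
        long = SeqRecord("z_long", left[-4000:] + ins + right[:4000])
        cands, _ = collect_candidates(obj, gap, [exact, long], cfg)
        assert select_donor(cands).donor_id == "z_long"
        # full tie: lexicographically smaller id
        twin_a = SeqRecord("aa", left[-2000:] + ins + right[:2000])
        twin_b = SeqRecord("ab", left[-2000:] + ins + right[:2000])
        cands, _ = collect_candidates(obj, gap, [twin_b, twin_a], cfg)
        assert select_donor(cands).donor_id == "aa"

    def test_select_empty_raises(self):
        with pytest.raises(ValueError):
            select_donor([])


class TestThresholdSharpness:
    """Inclusive >= semantics at 1000 bp / 0.80 identity on each flank."""

    @pytest.mark.parametrize("flank_len,accept", [(999, False),
                                                  (1000, True)])
    def test_flank_length_boundary(self, scene, cfg, flank_len, accept):
        left, right, obj, gap = scene
        ins = random_dna(np.random.default_rng(56), 2000)
        donor = SeqRecord("d", left[-flank_len:] + ins + right[:2000])
        cands, _ = collect_candidates(obj, gap, [donor], cfg)
        assert bool(cands) is accept
        if accept:
            assert cands[0].left_stats.block_length == 1000

    @pytest.mark.parametrize("n_sub,accept", [(210, False), (200, True)])
    def test_flank_identity_boundary(self, scene, cfg, n_sub, accept):
        left, right, obj, gap = scene
        ins = random_dna(np.random.default_rng(57), 2000)
        flank = _substitute_block(left[-1000:], 400, n_sub)
        donor = SeqRecord("d", flank + ins + right[:2000])
        cands, _ = collect_candidates(obj, gap, [donor], cfg)
        assert bool(cands) is accept
        if accept:
            assert cands[0].left_stats.identity == pytest.approx(0.80)


class TestFillGaps:
    def test_exact_splice(self, scene, cfg):
        left, right, obj, gap = scene
        insert = random_dna(np.random.default_rng(58), 3000)
        donor = SeqRecord("d", left[-2000:] + insert + right[:2000])
        filled, results, lift = fill_gaps(obj, [gap], [donor], cfg)
        assert results[0].status == "filled"
        assert results[0].inserted_length == 3000
        assert filled.sequence == left + insert + right

    def test_no_donors_identity(self, scene, cfg):
        _, _, obj, gap = scene
        filled, results, _ = fill_gaps(obj, [gap], [], cfg)
        assert filled.sequence == obj.sequence
        assert results[0].status == "no_candidate"

    def test_conservation_via_liftover(self, scene, cfg):
        left, right, obj, gap = scene
        insert = random_dna(np.random.default_rng(59), 700)
        donor = SeqRecord("d", left[-2000:] + insert + right[:2000])
        filled, results, lift = fill_gaps(obj, [gap], [donor], cfg)
        for row in lift.itertuples():
            old = obj.sequence[row.old_start:row.old_end]
            new_start = int(row.new_start)
            assert filled.sequence[
                new_start:new_start + (row.old_end - row.old_start)] == old

    def test_idempotence_when_gapless(self, scene, cfg):
        left, right, obj, gap = scene
        donor = SeqRecord("d", left[-2000:] + right[:2000])
        filled, _, _ = fill_gaps(obj, [gap], [donor], cfg)
        assert "N" not in filled.sequence
        again, results, _ = fill_gaps(filled, None, [donor], cfg)
        assert again.sequence == filled.sequence and results == []

    def test_nine_planted_gaps_all_restored(self, cfg):
        """A chromosome with nine hidden stretches and exact spanning
        donors is restored byte-identically (the all-gaps-closed
        outcome)."""
        params = SimParams(telomere_units_5p=100, telomere_units_3p=100,
                           centromere_span=40_000)
        hap1, _, _ = generate_genome(1, 2_200_000, params, seed=60)
        gapped, donors, truths = make_gapped_object_and_donors(
            hap1, 9, gap_len=4000, donor_flank=2000, seed=61)
        gaps = find_n_runs(gapped[0])
        assert len(gaps) == 9
        filled, results, _ = fill_gaps(gapped[0], gaps, donors, cfg)
        assert all(r.status == "filled" for r in results)
        assert find_n_runs(filled) == []
        assert filled.sequence == hap1[0].sequence

    def test_abutting_donor_closes_spacer_gap(self, cfg):
        """A donor spanning a junction whose true gap length is zero
        splices the flanks back together exactly."""
        rng = np.random.default_rng(62)
        truth = random_dna(rng, 30_000)
        bp = 14_000
        obj = SeqRecord("o", truth[:bp] + "N" * 100 + truth[bp:])
        donor = SeqRecord("d", truth[bp - 2500:bp + 2500])
        gaps = find_n_runs(obj)
        filled, results, _ = fill_gaps(obj, gaps, [donor], cfg)
        assert results[0].status == "filled"
        assert results[0].inserted_length == 0
        assert filled.sequence == truth
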