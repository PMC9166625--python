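"""Amplicon outcome classification, ratios, tag counts, RFLP."""

import collections

import numpy as np
import pytest

from spacernick.amplicon import (classify_amplicon_read,
                                 count_tag_integrations, indel_rate,
                                 profile_from_counts, quantify_outcomes,
                                 rflp_hdr_estimate)
from spacernick.design import DesignError, OutcomeClass
from spacernick.seqs import DSODN_TAG, random_dna, revcomp
from spacernick.simulate import (SimulationConfig, simulate_amplicon_reads,
                                 simulate_site_amplicon_reads)


def _amp(amplicons, cls):
    return next(a for a in amplicons if a.outcome_class == cls)


class TestClassify:
    def test_template_reads(self, amplicons):
        wt = _amp(amplicons, OutcomeClass.WT)
        hdr = _amp(amplicons, OutcomeClass.HDR)
        assert classify_amplicon_read(wt.sequence, amplicons).category == \
            OutcomeClass.WT
        assert classify_amplicon_read(hdr.sequence, amplicons).category == \
            OutcomeClass.HDR

    def test_deletion_at_nick_is_indel(self, amplicons):
        wt = _amp(amplicons, OutcomeClass.WT)
        nick = wt.junction_coords[0]
        read = wt.sequence[:nick] + wt.sequence[nick + 5:]
        call = classify_amplicon_read(read, amplicons)
        assert call.category == OutcomeClass.INDEL

    def test_hdr_with_nick_indel_is_imperfect(self, amplicons):
        hdr = _amp(amplicons, OutcomeClass.HDR)
        p = hdr.junction_coords[0]
        read = hdr.sequence[:p] + hdr.sequence[p + 4:]
        call = classify_amplicon_read(read, amplicons)
        assert call.category == OutcomeClass.HDR_IMPERFECT

    def test_short_read_ambiguous_with_reason(self, amplicons):
        call = classify_amplicon_read("ACGT" * 10, amplicons)
        assert call.category == OutcomeClass.AMBIGUOUS
        assert call.detail["reason"] == "TOO_SHORT"

    def test_unrelated_read_ambiguous(self, amplicons, rng):
        wt = _amp(amplicons, OutcomeClass.WT)
        call = classify_amplicon_read(random_dna(rng, len(wt.sequence)),
                                      amplicons)
        assert call.category == OutcomeClass.AMBIGUOUS
        assert call.detail["reason"] == "LOW_IDENTITY"

    def test_error_free_simulation_fully_concordant(self, genome_design,
                                                    amplicons):
        g, d = genome_design
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.25, "HDR": 0.35,
                                 "HDR_IMPERFECT": 0.1, "INDEL": 0.3},
            n_reads=400, seed=31)
        reads, truths = simulate_amplicon_reads(d, g, cfg)
        calls = [classify_amplicon_read(seq, amplicons, read_id=rid)
                 for rid, seq in reads]
        assert all(c.category.value == t.true_class
                   for c, t in zip(calls, truths))


class TestQuantify:
    def test_fraction_and_ratio_arithmetic(self):
        prof = profile_from_counts({"WT": 60, "INDEL": 20, "HDR": 20})
        assert prof.three_way == {"WT": 0.6, "NHEJ": 0.2, "HDR": 0.2}
        assert prof.hdr_nhej_ratio == 1.0
        assert prof.hdr_nhej_defined

    def test_zero_nhej_flagged_with_pseudocount(self):
        prof = profile_from_counts({"HDR": 40})
        assert not prof.hdr_nhej_defined
        assert prof.hdr_nhej_ratio == 40.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quantify_outcomes([])

    def test_fractions_sum_to_one(self, genome_design, amplicons):
        g, d = genome_design
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.5, "INDEL": 0.5}, n_reads=120,
            error_rate=0.002, seed=32)
        reads, _ = simulate_amplicon_reads(d, g, cfg)
        calls = [classify_amplicon_read(seq, amplicons) for _, seq in reads]
        prof = quantify_outcomes(calls)
        assert sum(prof.fractions.values()) == pytest.approx(1.0)
        assert sum(prof.counts.values()) == prof.total

    def test_counts_monotone_under_more_reads(self, genome_design,
                                              amplicons):
        g, d = genome_design
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.4, "HDR": 0.3, "INDEL": 0.3},
            n_reads=150, seed=33)
        reads, _ = simulate_amplicon_reads(d, g, cfg)
        calls = [classify_amplicon_read(seq, amplicons) for _, seq in reads]
        small = quantify_outcomes(calls[:80]).counts
        full = quantify_outcomes(calls).counts
        for k, v in small.items():
            assert full.get(k, 0) >= v

    def test_parameter_recovery_against_truth(self, genome_design,
                                              amplicons):
        g, d = genome_design
        props = {"WT": 0.2, "HDR": 0.4, "INDEL": 0.4}
        n = 1200
        cfg = SimulationConfig(outcome_proportions=props, n_reads=n,
                               seed=34)
        reads, truths = simulate_amplicon_reads(d, g, cfg)
        calls = [classify_amplicon_read(seq, amplicons) for _, seq in reads]
        prof = quantify_outcomes(calls)
        truth_counts = collections.Counter(t.true_class for t in truths)
        for cls in props:
            key = "NHEJ" if cls == "INDEL" else cls
            assert prof.three_way[key] == truth_counts[cls] / n


class TestIndelRate:
    def test_error_free_wt_reads_rate_zero(self, amplicons):
        wt = _amp(amplicons, OutcomeClass.WT)
        nick = wt.junction_coords[0]
        reads = [wt.sequence] * 40
        assert indel_rate(reads, wt, (nick - 10, nick + 10)) == 0.0

    def test_constructed_ten_percent(self, amplicons):
        wt = _amp(amplicons, OutcomeClass.WT)
        nick = wt.junction_coords[0]
        mut = wt.sequence[:nick] + wt.sequence[nick + 7:]
        reads = [wt.sequence] * 90 + [mut] * 10
        assert indel_rate(reads, wt, (nick - 10, nick + 10)) == \
            pytest.approx(0.10)

    def test_substitutions_never_count(self, genome_design, amplicons):
        g, d = genome_design
        wt = _amp(amplicons, OutcomeClass.WT)
        nick = wt.junction_coords[0]
        cfg = SimulationConfig(outcome_proportions={"WT": 1.0}, n_reads=150,
                               error_rate=0.01, seed=35)
        reads, _ = simulate_amplicon_reads(d, g, cfg)
        assert indel_rate([s for _, s in reads], wt,
                          (nick - 10, nick + 10)) == 0.0

    def test_read_order_invariance(self, amplicons, rng):
        wt = _amp(amplicons, OutcomeClass.WT)
        nick = wt.junction_coords[0]
        mut = wt.sequence[:nick] + "ACGTT" + wt.sequence[nick:]
        reads = [wt.sequence] * 30 + [mut] * 10
        shuffled = list(reads)
        rng.shuffle(shuffled)
        w = (nick - 10, nick + 10)
        assert indel_rate(reads, wt, w) == indel_rate(shuffled, wt, w)

    def test_no_classifiable_reads_is_error(self, amplicons, rng):
        wt = _amp(amplicons, OutcomeClass.WT)
        with pytest.raises(ValueError):
            indel_rate([random_dna(rng, 300)], wt, (0, 10))


class TestTagCount:
    def test_counts_both_orientations(self, rng):
        bg = [random_dna(rng, 300) for _ in range(10)]
        with_f = [r[:100] + DSODN_TAG + r[100:] for r in bg[:7]]
        with_r = [r[:80] + revcomp(DSODN_TAG) + r[80:] for r in bg[7:]]
        assert count_tag_integrations(with_f + with_r, DSODN_TAG) == 10
        assert count_tag_integrations(bg, DSODN_TAG) == 0

    def test_partial_tag_at_read_end(self, rng):
        r = random_dna(rng, 200)
        read = r + DSODN_TAG[:22]   # 22 nt of tag spilling off the end
        assert count_tag_integrations([read], DSODN_TAG) == 1
        read_short = r + DSODN_TAG[:12]
        assert count_tag_integrations([read_short], DSODN_TAG) == 0

    def test_simulated_site_panel(self, genome_design):
        g, d = genome_design
        rec = g.planted_off_targets[0]
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.7, "INDEL": 0.2, "DSODN_TAG": 0.1},
            n_reads=200, seed=36)
        reads, truths = simulate_site_amplicon_reads(g, rec, cfg)
        expected = sum(t.true_class == "DSODN_TAG" for t in truths)
        assert count_tag_integrations([s for _, s in reads],
                                      DSODN_TAG) == expected


class TestRflp:
    def test_all_and_half(self, amplicons):
        wt = _amp(amplicons, OutcomeClass.WT)
        hdr = _amp(amplicons, OutcomeClass.HDR)
        assert rflp_hdr_estimate([hdr.sequence] * 10, hdr,
                                 wt_amplicon=wt) == 1.0
        reads = [hdr.sequence] * 5 + [wt.sequence] * 5
        assert rflp_hdr_estimate(reads, hdr, wt_amplicon=wt) == 0.5

    def test_missing_site_is_config_error(self, amplicons):
        wt = _amp(amplicons, OutcomeClass.WT)
        with pytest.raises(DesignError):
            rflp_hdr_estimate([wt.sequence], wt)

    def test_matches_sequence_classification_error_free(self, genome_design,
                                                        amplicons):
        g, d = genome_design
        hdr = _amp(amplicons, OutcomeClass.HDR)
        wt = _amp(amplicons, OutcomeClass.WT)
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.3, "HDR": 0.4,
                                 "HDR_IMPERFECT": 0.1, "INDEL": 0.2},
            n_reads=500, seed=37)
        reads, _ = simulate_amplicon_reads(d, g, cfg)
        calls = [classify_amplicon_read(seq, amplicons) for _, seq in reads]
        seq_based = sum(c.category in (OutcomeClass.HDR,
                                       OutcomeClass.HDR_IMPERFECT)
                        for c in calls) / len(calls)
        rflp = rflp_hdr_estimate([s for _, s in reads], hdr, wt_amplicon=wt)
        assert rflp == seq_based
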