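"""Simulator contracts: determinism, truth-table fidelity, read structure."""

import numpy as np
import pytest

from spacernick.align import best_genomic_hit, guide_match_string
from spacernick.design import OutcomeClass
from spacernick.io import write_fasta, write_fastq
from spacernick.seqs import DSODN_TAG, revcomp
from spacernick.simulate import (ConfigError, IntegrationEvent,
                                 SimulationConfig, build_mini_genome,
                                 simulate_amplicon_reads,
                                 simulate_htgts_reads, simulate_tag_reads)


class TestMiniGenome:
    def test_guide_unique_without_off_targets(self):
        genome, design = build_mini_genome(seed=21, n_off_targets=0)
        for g in design.guides:
            q = g.interval.sequence(genome)  # guide-strand 23-mer
            res = best_genomic_hit(q, genome, min_length=23)
            assert res.status == "OK"
            assert res.placement.start == g.interval.start

    def test_planted_mismatch_counts_verified_independently(self, genome,
                                                            design):
        # recompute each planted site's mismatch count from the genome
        # sequence via the matching operation, independent of planting
        guides = {g.id: g for g in design.guides}
        for rec in genome.planted_off_targets:
            g = guides[rec.guide_id]
            site = rec.interval.sequence(genome)
            ann = guide_match_string(g.protospacer + g.pam, site)
            assert ann.mismatch_count == rec.mismatch_count
            assert 2 <= ann.mismatch_count <= 4

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        paths = []
        for i in range(2):
            g, _ = build_mini_genome(seed=33)
            p = tmp_path / f"g{i}.fa"
            write_fasta(p, g.contigs)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_contig_too_short_rejected(self):
        with pytest.raises(ConfigError, match="too short"):
            build_mini_genome(seed=1, n_off_targets=3, contig_length=10000)

    def test_off_target_spacing_exceeds_annotation_window(self, genome):
        starts = sorted(r.interval.start
                        for r in genome.planted_off_targets)
        gaps = np.diff(starts)
        assert (gaps > 10000).all()


class TestAmpliconSim:
    def test_pure_wt_error_free(self, genome_design, amplicons):
        g, d = genome_design
        wt = next(a for a in amplicons if a.outcome_class == OutcomeClass.WT)
        cfg = SimulationConfig(outcome_proportions={"WT": 1.0}, n_reads=50,
                               seed=5)
        reads, truths = simulate_amplicon_reads(d, g, cfg)
        assert all(seq == wt.sequence for _, seq in reads)
        assert all(t.true_class == "WT" for t in truths)

    def test_error_rate_mean_substitutions(self, genome_design, amplicons):
        g, d = genome_design
        wt = next(a for a in amplicons if a.outcome_class == OutcomeClass.WT)
        L, p, n = len(wt.sequence), 0.001, 800
        cfg = SimulationConfig(outcome_proportions={"WT": 1.0}, n_reads=n,
                               error_rate=p, seed=6)
        reads, _ = simulate_amplicon_reads(d, g, cfg)
        subs = [sum(1 for a, b in zip(seq, wt.sequence) if a != b)
                for _, seq in reads]
        se = np.sqrt(L * p * (1 - p) / n)
        assert abs(np.mean(subs) - L * p) < 3 * se

    def test_same_seed_byte_identical_fastq(self, genome_design, tmp_path):
        g, d = genome_design
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.5, "INDEL": 0.5}, n_reads=100,
            error_rate=0.01, seed=9)
        out = []
        for i in range(2):
            reads, _ = simulate_amplicon_reads(d, g, cfg)
            p = tmp_path / f"r{i}.fastq"
            write_fastq(p, reads)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_hdr_without_donor_is_config_error(self, genome_design):
        from spacernick.design import LocusDesign
        g, d = genome_design
        bare = LocusDesign(name="bare",
                           reference_window=d.reference_window, pair=d.pair)
        cfg = SimulationConfig(outcome_proportions={"HDR": 1.0}, n_reads=10,
                               seed=1)
        with pytest.warns(UserWarning):
            with pytest.raises(ConfigError, match="donor"):
                simulate_amplicon_reads(bare, g, cfg)

    def test_multinomial_counts_and_unique_ids(self, genome_design):
        g, d = genome_design
        props = {"WT": 0.2, "HDR": 0.4, "HDR_IMPERFECT": 0.1, "INDEL": 0.3}
        n = 5000
        cfg = SimulationConfig(outcome_proportions=props, n_reads=n, seed=8)
        reads, truths = simulate_amplicon_reads(d, g, cfg)
        assert len({t.read_id for t in truths}) == n
        assert {rid for rid, _ in reads} == {t.read_id for t in truths}
        for cls, p in props.items():
            obs = sum(t.true_class == cls for t in truths)
            assert abs(obs - n * p) <= 4 * np.sqrt(n * p * (1 - p))

    def test_error_free_reads_are_template_exact(self, genome_design,
                                                 amplicons):
        g, d = genome_design
        wt = next(a for a in amplicons if a.outcome_class == OutcomeClass.WT)
        hdr = next(a for a in amplicons
                   if a.outcome_class == OutcomeClass.HDR)
        cfg = SimulationConfig(
            outcome_proportions={"WT": 0.3, "HDR": 0.3, "INDEL": 0.4},
            n_reads=200, seed=10)
        reads, truths = simulate_amplicon_reads(d, g, cfg)
        tpl = {"WT": wt.sequence, "HDR": hdr.sequence}
        for (rid, seq), t in zip(reads, truths):
            if t.true_class in tpl:
                assert seq == tpl[t.true_class]
            else:
                kind, pos, size = t.detail["indel"]
                # flanks outside the indel are untouched wild type
                assert seq[:pos] == wt.sequence[:pos]
                if kind == "deletion":
                    assert seq[pos:] == wt.sequence[pos + size:]
                else:
                    assert seq[pos + size:] == wt.sequence[pos:]


class TestTagSim:
    def test_zero_events_reads_are_tag_free(self, genome_design):
        g, d = genome_design
        cfg = SimulationConfig(assay="TAG_JUNCTION", n_reads=1,
                               read_length=650, background_reads=100,
                               seed=12)
        reads, truths = simulate_tag_reads(d, g, [], cfg)
        assert len(reads) == 100
        for _, seq in reads:
            assert DSODN_TAG not in seq and revcomp(DSODN_TAG) not in seq

    def test_junctions_land_at_event_site(self, genome_design):
        g, d = genome_design
        rec = g.planted_off_targets[0]
        ev = IntegrationEvent(rec.interval.contig, rec.cut_position,
                              "both", 12)
        cfg = SimulationConfig(assay="TAG_JUNCTION", n_reads=1,
                               read_length=650, seed=13)
        reads, truths = simulate_tag_reads(d, g, [ev], cfg)
        assert all(t.detail["site"] == rec.cut_position for t in truths)
        assert len(reads) >= 12

    def test_orientation_balance(self, genome_design):
        g, d = genome_design
        ev = IntegrationEvent(d.reference_window.contig,
                              d.nick_positions[0], "both", 400)
        cfg = SimulationConfig(assay="TAG_JUNCTION", n_reads=1,
                               read_length=650, duplication_mean=0.0,
                               seed=14)
        _, truths = simulate_tag_reads(d, g, [ev], cfg)
        fwd = sum(t.detail["orientation"] == "forward" for t in truths)
        n = len(truths)
        assert abs(fwd - n / 2) <= 3 * np.sqrt(n * 0.25)

    def test_event_outside_genome_rejected(self, genome_design):
        g, d = genome_design
        cfg = SimulationConfig(assay="TAG_JUNCTION", seed=1)
        with pytest.raises(ConfigError):
            simulate_tag_reads(d, g, [IntegrationEvent("nope", 100)], cfg)


class TestHtgtsSim:
    @pytest.mark.parametrize("side", ["5p", "3p"])
    def test_pure_wt_reads_anchor_at_primer(self, genome_design, side):
        g, d = genome_design
        wt = d.reference_window.sequence(g)
        w0 = d.reference_window.start
        cfg = SimulationConfig(assay="HTGTS",
                               outcome_proportions={"WT": 1.0},
                               n_reads=30, read_length=250, side=side,
                               seed=15)
        reads, _ = simulate_htgts_reads(d, g, cfg)
        if side == "5p":
            s = d.htgts_nested_primers["5p"][0] - w0
            expect = wt[s:s + 250]
        else:
            e = d.htgts_nested_primers["3p"][1] - w0
            expect = revcomp(wt[e - 250:e])
        assert all(seq == expect for _, seq in reads)

    def test_inversion_read_contains_junction(self, genome_design,
                                              amplicons_itr):
        g, d = genome_design
        inv = next(a for a in amplicons_itr
                   if a.outcome_class == OutcomeClass.INVERSION)
        a_rel = inv.junction_coords[0]
        junction = inv.sequence[a_rel - 15:a_rel + 15]
        cfg = SimulationConfig(assay="HTGTS",
                               outcome_proportions={"INVERSION": 1.0},
                               n_reads=5, read_length=250, side="5p",
                               seed=16)
        reads, _ = simulate_htgts_reads(d, g, cfg)
        assert all(junction in seq for _, seq in reads)

    def test_same_seed_identical_output(self, genome_design):
        g, d = genome_design
        props = {"WT": 0.4, "INDEL": 0.3, "TRANSLOCATION": 0.3}
        cfg = SimulationConfig(assay="HTGTS", outcome_proportions=props,
                               n_reads=100, read_length=250, seed=17)
        r1, t1 = simulate_htgts_reads(d, g, cfg)
        r2, t2 = simulate_htgts_reads(d, g, cfg)
        assert r1 == r2 and t1 == t2

    def test_translocation_without_partners_rejected(self):
        genome, design = build_mini_genome(seed=22, n_off_targets=0)
        cfg = SimulationConfig(assay="HTGTS",
                               outcome_proportions={"TRANSLOCATION": 1.0},
                               n_reads=10, seed=1)
        with pytest.raises(ConfigError, match="off-targets"):
            simulate_htgts_reads(design, genome, cfg)

    def test_proportions_must_sum_to_one(self):
        cfg = SimulationConfig(outcome_proportions={"WT": 0.6, "INDEL": 0.3},
                               n_reads=10, seed=1)
        with pytest.raises(ConfigError, match="sum"):
            cfg.validate()
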