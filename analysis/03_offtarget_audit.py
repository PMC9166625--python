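#!/usr/bin/env python
"""GUIDE-seq off-target audit: dsODN junction sites, per-site indel
rates and tag counts, nuclease vs spacer-nick.

Simulates matched dsODN-junction libraries — the nuclease-like condition
integrates the tag at the on-target nick and at every planted off-target
site, the spacer-nick-like condition only sparsely at the on-target —
then calls, deduplicates and annotates integration sites under the
5000-bp rule and computes per-site fold changes.  An amplicon panel over
the same sites quantifies indel rates and dsODN tag counts per
condition.  Writes ``results/guideseq_sites_<condition>.tsv``,
``results/guideseq_fold_change.tsv`` and ``results/offtarget_panel.tsv``.
"""

import sys
from pathlib import Path

import pandas as pd

from spacernick import io
from spacernick.amplicon import count_tag_integrations, indel_rate
from spacernick.design import GenomicInterval, OffTargetRecord
from spacernick.junctions import (call_integration_sites,
                                  compare_conditions, sites_table)
from spacernick.seqs import DSODN_TAG
from spacernick.simulate import (IntegrationEvent, SimulationConfig,
                                 build_mini_genome,
                                 simulate_site_amplicon_reads,
                                 simulate_tag_reads)

SEED = 20240917
RESULTS = Path("results")


def tag_library(genome, design, events, seed):
    cfg = SimulationConfig(assay="TAG_JUNCTION", n_reads=1, read_length=650,
                           background_reads=150, error_rate=0.001,
                           seed=seed)
    reads, _ = simulate_tag_reads(design, genome, events, cfg)
    return call_integration_sites(reads, DSODN_TAG, genome, design,
                                  genome.planted_off_targets)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    genome, design = build_mini_genome(seed=SEED)
    c = design.reference_window.contig

    nuclease_events = [IntegrationEvent(c, design.nick_positions[0],
                                        "both", 60)]
    nuclease_events += [IntegrationEvent(r.interval.contig, r.cut_position,
                                         "both", m)
                        for r, m in zip(genome.planted_off_targets,
                                        (20, 10, 5))]
    nick_events = [IntegrationEvent(c, design.nick_positions[0], "both", 2)]

    tables = {}
    for name, events, seed in (("nuclease", nuclease_events, SEED + 20),
                               ("spacer_nick", nick_events, SEED + 21)):
        sites, suppressed, rejects = tag_library(genome, design, events,
                                                 seed)
        df = sites_table(sites + suppressed)
        tables[name] = df
        io.write_tsv(RESULTS / f"guideseq_sites_{name}.tsv", df,
                     {"condition": name, "rejects": rejects})
        print(f"{name}: {len(sites)} sites ({len(suppressed)} below the "
              f"molecule floor), rejects {rejects}")

    fold = compare_conditions(tables["nuclease"], tables["spacer_nick"])
    io.write_tsv(RESULTS / "guideseq_fold_change.tsv", fold,
                 {"a": "nuclease", "b": "spacer_nick"})
    on = fold[fold["site"] == "ON_TARGET"].iloc[0]
    print(f"\nOn-target dsODN reads: {on['reads_a']} (nuclease) vs "
          f"{on['reads_b']} (spacer-nick) -> "
          f"{on['fold_a_over_b']:.0f}-fold reduction under spacer-nick; "
          f"off-target sites are detected only under nuclease.")

    # per-site amplicon panel: indel rate + tag count per condition
    panel_rows = []
    on_rec = OffTargetRecord(
        GenomicInterval(c, design.pair.guide_a.interval.start,
                        design.pair.guide_a.interval.end, "-"),
        design.pair.guide_a.id, 0)
    panel = [("on_target", on_rec)] + \
        [(f"off_target_{i+1}", r)
         for i, r in enumerate(genome.planted_off_targets)]
    mixes = {"nuclease": [0.35, 0.20, 0.10, 0.05],
             "spacer_nick": [0.01, 0.0, 0.0, 0.0]}
    for ci, (cond, rates) in enumerate(mixes.items()):
        for si, ((label, rec), r) in enumerate(zip(panel, rates)):
            props = {"WT": round(1 - r - r / 2, 6)}
            if r:
                props.update({"INDEL": r, "DSODN_TAG": r / 2})
            cfg = SimulationConfig(outcome_proportions=props, n_reads=600,
                                   error_rate=0.001,
                                   seed=SEED + 30 + 10 * ci + si)
            reads, _ = simulate_site_amplicon_reads(genome, rec, cfg)
            seqs = [s for _, s in reads]
            site_rate = indel_rate(seqs, genome.contigs[c][
                rec.cut_position - 200:rec.cut_position + 200],
                (190, 210))
            tags = count_tag_integrations(seqs, DSODN_TAG)
            # a dsODN integration is itself a 34-nt insertion at the cut,
            # so the expected indel-read rate includes the tag fraction
            panel_rows.append({"condition": cond, "site": label,
                               "expected_indel_rate": round(1.5 * r, 4),
                               "indel_rate": round(site_rate, 4),
                               "dsodn_tag_reads": tags})
    dfp = pd.DataFrame(panel_rows)
    io.write_tsv(RESULTS / "offtarget_panel.tsv", dfp,
                 {"n_reads_per_site": 600, "error_rate": 0.001})
    print("\n" + dfp.to_string(index=False))
    print("\nIndel rates track the planted mixes; dsODN tags appear only "
          "where integrations were simulated (nuclease condition).")


if __name__ == "__main__":
    sys.exit(main())
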