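#!/usr/bin/env python
"""Simulate the full study bench: mini-genome, locus design, and one
labelled library per assay.

Writes the genome/design/off-target artifacts and FASTQ+truth for an
amplicon, a GUIDE-seq, an AAV-seq and a LAM-HTGTS library under
``scratch/sim/`` (large, regenerable) and a one-row-per-library summary
under ``results/library_summary.tsv``.
"""

import sys
from pathlib import Path

import pandas as pd

from spacernick import io
from spacernick.seqs import SYNTHETIC_ITR
from spacernick.simulate import (IntegrationEvent, SimulationConfig,
                                 build_mini_genome, simulate_amplicon_reads,
                                 simulate_htgts_reads, simulate_tag_reads)

SEED = 20240917
SCRATCH = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    genome, design = build_mini_genome(seed=SEED)
    io.write_fasta(SCRATCH / "genome.fa", genome.contigs)
    io.save_design(SCRATCH / "design.yaml", design)
    io.write_offtarget_bed(SCRATCH / "offtargets.bed",
                           genome.planted_off_targets)

    rows = []

    def emit(name, reads, truths):
        io.write_fastq(SCRATCH / f"{name}.fastq", reads)
        io.write_truth(SCRATCH / f"{name}.truth.tsv", truths)
        classes = pd.Series([t.true_class for t in truths]).value_counts()
        rows.append({"library": name, "n_reads": len(reads),
                     "classes": ";".join(f"{k}:{v}"
                                         for k, v in classes.items())})

    cfg = SimulationConfig(
        outcome_proportions={"WT": 0.18, "HDR": 0.40, "INDEL": 0.42},
        n_reads=3000, error_rate=0.001, seed=SEED + 1)
    emit("amplicon_nuclease", *simulate_amplicon_reads(design, genome, cfg))

    c = design.reference_window.contig
    events = [IntegrationEvent(c, design.nick_positions[0], "both", 40)]
    events += [IntegrationEvent(r.interval.contig, r.cut_position, "both",
                                12)
               for r in genome.planted_off_targets]
    tcfg = SimulationConfig(assay="TAG_JUNCTION", n_reads=1,
                            read_length=650, background_reads=200,
                            error_rate=0.001, seed=SEED + 2)
    emit("guideseq_nuclease",
         *simulate_tag_reads(design, genome, events, tcfg))

    aav_events = [IntegrationEvent(c, p, "both", 10)
                  for p in design.nick_positions]
    acfg = SimulationConfig(assay="TAG_JUNCTION", n_reads=1,
                            read_length=650, background_reads=100,
                            tag=SYNTHETIC_ITR, seed=SEED + 3)
    emit("aavseq", *simulate_tag_reads(design, genome, aav_events, acfg))

    hcfg = SimulationConfig(
        assay="HTGTS",
        outcome_proportions={"WT": 0.30, "HDR": 0.35, "INDEL": 0.15,
                             "DELETION": 0.08, "INVERSION": 0.05,
                             "AAV_INTEGRATION": 0.05,
                             "TRANSLOCATION": 0.02},
        n_reads=2000, read_length=250, side="5p", seed=SEED + 4)
    emit("htgts_5p", *simulate_htgts_reads(design, genome, hcfg))

    df = pd.DataFrame(rows)
    io.write_tsv(RESULTS / "library_summary.tsv", df, {"seed": SEED})
    print(df.to_string(index=False))
    print(f"\nSimulated {len(rows)} libraries into {SCRATCH}/ "
          f"(summary: {RESULTS / 'library_summary.tsv'})")


if __name__ == "__main__":
    sys.exit(main())
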