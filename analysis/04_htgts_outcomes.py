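#!/usr/bin/env python
"""LAM-HTGTS structural-outcome heatmap: all editing outcomes per
enrichment side, nuclease-like vs spacer-nick-like.

Simulates primer-anchored HTGTS libraries from both the 5' and 3'
nested primers under two outcome mixes — a nuclease-like mix rich in
indels, deletions, inversions and translocations, and a spacer-nick-like
mix dominated by WT and HDR — classifies every read through the
priming -> ITR -> amplicon -> break-site -> translocation cascade, and
tabulates per-class frequencies, HDR efficiencies and WT:mutated
ratios.  Writes ``results/htgts_outcomes.tsv`` and
``results/htgts_ratios.tsv``.
"""

import sys
from pathlib import Path

import pandas as pd

from spacernick import io
from spacernick.htgts import (build_context, classify_htgts_reads,
                              summarize_htgts)
from spacernick.seqs import SYNTHETIC_ITR
from spacernick.simulate import (SimulationConfig, build_mini_genome,
                                 simulate_htgts_reads)

SEED = 20240917
RESULTS = Path("results")

MIXES = {
    "nuclease": {"WT": 0.22, "HDR": 0.35, "INDEL": 0.20, "DELETION": 0.10,
                 "INVERSION": 0.05, "AAV_INTEGRATION": 0.05,
                 "TRANSLOCATION": 0.03},
    "spacer_nick": {"WT": 0.55, "HDR": 0.40, "INDEL": 0.02,
                    "DELETION": 0.005, "INVERSION": 0.005,
                    "AAV_INTEGRATION": 0.02},
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    genome, design = build_mini_genome(seed=SEED)
    tables, ratio_rows = [], []
    for ci, (cond, props) in enumerate(MIXES.items()):
        for si, side in enumerate(("5p", "3p")):
            ctx = build_context(design, genome, side, itr=SYNTHETIC_ITR,
                                off_targets=genome.planted_off_targets)
            cfg = SimulationConfig(assay="HTGTS",
                                   outcome_proportions=props,
                                   n_reads=1500, read_length=250,
                                   side=side, error_rate=0.001,
                                   seed=SEED + 40 + 10 * ci + si)
            reads, _ = simulate_htgts_reads(design, genome, cfg)
            calls = classify_htgts_reads(reads, ctx)
            profile, table, hdr_eff = summarize_htgts(calls, side)
            table.insert(0, "condition", cond)
            tables.append(table)
            ratio_rows.append({
                "condition": cond, "side": side,
                "hdr_efficiency": round(hdr_eff, 4),
                "wt_mutated_ratio": round(profile.wt_mutated_ratio, 3),
                "wt_mutated_defined": profile.wt_mutated_defined,
                "classified": profile.classified,
                "ambiguous_or_uninformative": profile.ambiguous})

    outcomes = pd.concat(tables, ignore_index=True)
    io.write_tsv(RESULTS / "htgts_outcomes.tsv", outcomes,
                 {"seed": SEED, "n_reads": 1500, "error_rate": 0.001})
    ratios = pd.DataFrame(ratio_rows)
    io.write_tsv(RESULTS / "htgts_ratios.tsv", ratios, {"seed": SEED})

    print(outcomes.pivot_table(index=["condition", "side"],
                               columns="outcome", values="count",
                               aggfunc="sum").to_string())
    print("\n" + ratios.to_string(index=False))
    wm = ratios.set_index(["condition", "side"])["wt_mutated_ratio"]
    gain = wm["spacer_nick"].mean() / wm["nuclease"].mean()
    print(f"\nWT:mutated improves ~{gain:.0f}-fold under the "
          "spacer-nick-like mix; HDR efficiency holds, mutagenic classes "
          "(indel/deletion/inversion/translocation) all but vanish.")


if __name__ == "__main__":
    sys.exit(main())
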