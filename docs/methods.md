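# Methods

This note documents the models, conventions, parameters and known
limitations of the `spacernick` pipelines — what is computed, which
knobs matter, and what the simulator-based tests do and do not show
about real data.

## Coordinates and the nick model

All coordinates are 0-based, half-open, plus-strand (BED-style). A
guide is a 20-nt protospacer plus an NGG PAM (SpCas9 / SpCas9-D10A
only; other PAMs are rejected). The nick coordinate sits 3 nt 5′ of the
PAM — between protospacer positions 17 and 18, the canonical Cas9 cut
site — i.e. at `interval.start + 17` for a plus-strand guide and
`interval.start + 6` for a minus-strand guide. Published distances for
paired-guide designs rarely state which coordinate they refer to
(nick-to-nick, protospacer end-to-end, PAM-to-PAM); this package uses
nick-to-nick everywhere, so all distances are internally coherent even
if they differ by a handful of bp from numbers quoted elsewhere.

A guide pair is PAM-out when both PAMs face away from the intervening
spacer: the upstream guide on the minus strand, the downstream guide on
the plus strand. Spacer distances outside 200–350 bp raise a warning
(not an error): shorter pairs behave like a double-nick/DSB design,
longer pairs lose HDR efficiency.

## Expected-outcome amplicons

From a validated design the package builds one in-silico sequence per
outcome class, shared verbatim by the simulator and every classifier:

| class | construction |
|---|---|
| WT | the reference window itself |
| HDR | reference with the donor payload substituted between the HA anchors |
| DELETION | precise nick-to-nick join (length = WT − spacer distance) |
| INVERSION | nick-to-nick segment reverse-complemented in place |
| AAV_INTEGRATION | ITR cassette (ITR + revcomp(ITR) + ITR) joined at each nick, both orientations and both sides |

Small indel alleles at a single nick are *not* enumerated as amplicons
(the set would be infinite); they are produced by the simulator and
recovered by break-site analysis. Each amplicon carries its junction
coordinates, per-nick quantification windows (±10 nt; standard
amplicon-indel practice — no published window convention exists for
this assay family), and, for HDR, the positions of the donor-diagnostic
substitutions.

## Alignment machinery

Three aligners with distinct roles:

* `global_align` / `local_align` / `prefix_align` — Biopython
  `PairwiseAligner`, affine gaps, defaults match +1 / mismatch −4 /
  gap open −6 / extend −1 (a length-L gap costs 6 + (L−1)). Gaps are
  deliberately expensive: junction assays need crisp breakpoints.
  `prefix_align` anchors a primer-anchored read at the reference start
  and leaves the reference tail free.
* `edit_align` — edlib unit-cost edit alignment, used for
  whole-amplicon read classification where thousands of near-identical
  kb-scale pairs make quadratic affine DP needlessly slow. Per-class
  decisions depend on indel presence/position and diagnostic bases, not
  on gap-cost fine structure, so the unit-cost path is equivalent there
  (and is cross-checked against truth in the acceptance tests).
* `best_genomic_hit` — the "perfect mapped" contract: a read is placed
  only where it matches end-to-end with 0 mismatches by default
  (`max_mismatch` is config-exposed; a vectorised Hamming scan serves
  that mode), on either strand, and only if no second placement scores
  within a 5-unit margin — ambiguous reads are counted and reported,
  never silently assigned. `N` counts as a mismatch everywhere.

Tie-breaks: of co-optimal alignments the aligner's first reported one
is taken (deterministic); co-optimal placements make a read ambiguous.

## Amplicon classification

Each read is aligned to the WT and HDR amplicons; the better alignment
is interpreted. HDR requires **all** diagnostic substitutions present
and no indel overlapping a quantification window; diagnostic bases plus
a window indel is HDR_IMPERFECT (reported separately but pooled into
NHEJ for three-way summaries — an indel-bearing allele is not a precise
repair); a window indel alone is INDEL (=NHEJ); substitutions never
count as NHEJ. Reads under 50 nt or below 0.85 identity to both
amplicons are AMBIGUOUS with a reason code. The in-silico Sal I RFLP
estimate counts reads whose digest cuts within 40 nt of the expected
donor-introduced site; on error-free reads it equals the
HDR + HDR_IMPERFECT fraction exactly (the tolerance absorbs ≤20-nt
break-site indels next to an intact site, mirroring a gel readout).

## Tag-junction (GUIDE-seq / AAV-seq) calling

One code path, switched by the tag constant (34-nt dsODN or ITR).
Reads must begin with the expected 16-nt tag-primer suffix in either
orientation (≤1 mismatch; blunt-end ligation is orientation-agnostic);
the genomic remainder (≥25 nt) is perfect-mapped; the junction
coordinate is the tag-adjacent placement end, the other end is the Tn5
shear point. The protocol has no UMI, so molecules are deduplicated by
the (junction, orientation, shear) triple — the standard proxy; read
counts are kept alongside. Junctions within 25 nt merge into a site
(single linkage); sites under 2 unique molecules are suppressed but
logged. Annotation: within 5000 bp of the nick interval → ON_TARGET;
else nearest predicted off-target within 5000 bp → KNOWN_OFF_TARGET
(ties: fewer mismatches, then leftmost); else NOVEL. `merge_window`,
`min_molecules` and the 5000-bp window are config-exposed.

## LAM-HTGTS classification

A strict priority cascade; every read receives exactly one terminal
label and stage counts always sum to the input:

1. **priming** — reads must start with the nested primer (≤1
   substitution; the tolerance is a design choice, config-exposed).
   Free AAV donor molecules carry no genomic primer site because the
   linear-amplification primer anneals outside the homology arms, so
   donor contamination is structurally excluded here.
2. **ITR detection** — local alignment of the ITR constant, both
   orientations; span ≥20 nt, gapless identity ≥0.8, score ≥18.
3. **expected amplicons** — a perfect (0 mismatch, 0 indel over the
   read span) match assigns HDR / WT / DELETION / INVERSION /
   AAV_INTEGRATION; ties broken HDR > WT > DELETION > INVERSION. An
   HDR call additionally requires the read to span at least one
   diagnostic substitution; a read too short to reach one is counted
   WT (conservative: it cannot evidence repair). "Perfect" tolerance
   is config-exposed (default 0; raise for noisy data).
4. **break-site analysis** — reads ≥0.9 gapless identity to the WT
   frame with ≤50 total inserted bases: an indel overlapping a nick
   window → INDEL; a deletion bridging both windows → DELETION; reads
   ending before the proximal window → UNINFORMATIVE (reported, never
   dropped). The insertion cap matters: without it a translocation
   partner segment can masquerade as a large "insertion" at the nick.
5. **translocation** — the remainder is split at the proximal nick;
   the distal segment (≥25 nt) is perfect-mapped; a unique placement
   within 5000 bp of a predicted off-target is a TRANSLOCATION with
   that partner; everything else stays AMBIGUOUS and is never counted
   as a translocation.

5′ and 3′ enrichments are independent runs (internally rotated into a
shared primer-anchored frame) combined only at reporting. The
WT:mutated ratio excludes HDR from both numerator and denominator; the
convention is stated here because published ratio definitions leave it
open.

## The simulator

The simulator defines the study conditions; its defaults are fixed and
the tests are run against its per-read truth table.

* **Mini-genome**: one random contig (~75 kb at defaults) with the
  locus window planted once and `n_off_targets` (default 3) protospacer
  variants carrying 2–4 substitutions, spaced 12 kb apart so their
  5000-bp annotation windows never overlap. The default design is a
  PAM-out pair at 250 bp spacer distance with 800-bp homology arms, a
  donor payload carrying a planted Sal I site (silent substitutions at
  the payload centre) plus two further diagnostic substitutions, outer
  primers outside the HAs and nested HTGTS primers 60–80 bp from the
  nicks. The window is scrubbed of spurious Sal I sites so the RFLP
  diagnostic is unique.
* **Amplicon reads** are whole-window molecules (as from merged or
  long-read amplicon sequencing). INDEL/HDR_IMPERFECT alleles carry one
  insertion or deletion (geometric size, p = 0.35, clipped to 1–20 nt)
  at a uniformly chosen nick ± 3 nt.
* **Tag-junction reads**: per integration event, each molecule draws a
  Tn5 shear point uniform 100–600 nt from the junction and
  1 + Poisson(0.5) PCR copies; reads are the 16-nt tag suffix plus the
  genomic flank. The default 650-nt read length spans the whole
  fragment — a single-end stand-in for the shear-point information a
  paired-end mate would carry, which shear-point deduplication needs.
  Background (tag-free) reads are config-exposed; no published value
  exists for the background fraction or duplication level.
* **HTGTS reads** start at the nested primer and read 250 nt across the
  proximal nick into the class template. Translocation partners are
  planted off-target cut sites, or (for specificity testing) random
  loci ≥6 kb from every predicted site.
* Substitution errors are iid at `error_rate` (no quality model: the
  pipeline ignores base qualities, written as constant Q30). One
  integer seed drives a single numpy PRNG stream; identical configs are
  byte-identical, cross-implementation reproducibility is statistical.

**What passing tests show — and don't.** The simulator covers the read
*structures* of the four assays, not PCR bias, chimeras, quality decay,
homopolymer errors, or paired-end mechanics. Recall/specificity of 1.0
on error-free simulated reads demonstrates the classification logic is
correct under the stated contracts; real libraries will sit below that
ceiling, and the config-exposed tolerances (priming mismatches,
perfect-match tolerance, identity gates) are the intended adjustment
points.

## Problem sizes

Defaults are desk-scale by design: 2,000–5,000 reads per amplicon
condition, 20-seed false-positive sweeps, 500 reads per HTGTS class,
and a ~75-kb genome — large enough for the 3–4σ statistical bounds used
in the tests, small enough to run anywhere in minutes.

## Known limitations

* Off-target prediction is consumed as a BED input, never computed;
  guide scoring and chromatin context are out of scope.
* The mini-genome has no repeats beyond chance, so ambiguous-placement
  handling is exercised only by constructed duplications in tests.
* The deletion/inversion amplicons model precise nick-to-nick joins;
  junction-resected variants are handled by break-site analysis, not
  enumerated.
* `wt_mutated_ratio` and `hdr_nhej_ratio` use a flagged pseudocount of
  1 at zero denominators; downstream statistics should use the flag,
  not the raw ratio.
* The bundled ITR is a synthetic 130-nt stand-in (only length and
  detectability matter to the pipeline); any tag/ITR sequence can be
  configured.
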