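"""Synthetic read simulator with per-read ground truth.

Emulates the four library structures of a paired-nickase editing audit on
a desk-scale mini-genome:

* **amplicon-seq** of the targeted window (and of off-target sites):
  whole-amplicon reads drawn from WT / HDR / imperfect-HDR / indel
  alleles, optionally carrying an integrated dsODN tag;
* **tag-junction libraries** (GUIDE-seq with the dsODN tag, AAV-seq with
  an ITR tag): Tn5-sheared fragments sequenced from a primer inside the
  tag out into flanking genomic DNA;
* **LAM-HTGTS**: reads anchored at a nested primer ~50-100 bp from a
  nick, reading across the break into whichever structure the allele
  carries (WT, HDR, deletion, inversion, AAV integration, translocation).

The mini-genome plants the targeted locus once plus a configurable set
of off-target sites carrying known mismatch counts, standing in for a
full genome reference so the 5000-bp off-target window rule is
exercisable.  Every emitted read has a :class:`TruthRecord`; truth tables
are the oracle for the whole test suite.  One integer seed drives a
single numpy PRNG stream, so identical configs give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import guide_match_string
from .design import (DonorTemplate, GenomicInterval, GuideSite,
                     LocusDesign, NickPair, OffTargetRecord, OutcomeClass,
                     build_expected_amplicons)
from .seqs import (DSODN_TAG, SYNTHETIC_ITR, add_sequencing_errors,
                   mutate_positions, random_dna, revcomp, scrub_motif)

#: number of tag bases left on a junction read (the sequencing primer
#: anneals inside the tag, so reads start with this suffix of it)
TAG_SUFFIX_LEN = 16

#: constant Phred quality written to FASTQ (Q30); the pipeline ignores
#: base qualities
QUAL_CHAR = "?"


class ConfigError(ValueError):
    """An inconsistent simulation request."""


@dataclass
class MiniGenome:
    """Contig map plus the off-target sites planted into it."""

    contigs: dict
    planted_off_targets: list = field(default_factory=list)


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    true_class: str
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IntegrationEvent:
    """A tag-integration site with a number of independent molecules."""

    contig: str
    site: int
    orientation: str = "both"   # forward | reverse | both
    molecule_count: int = 5


@dataclass
class SimulationConfig:
    """Knobs for one simulated library.

    ``outcome_proportions`` maps class names to fractions (must sum to
    1); ``indel_size_geometric_p`` sets the geometric indel-size law
    (sizes clipped to 1-20 nt); ``tag`` is the 34-nt dsODN by default and
    the ITR constant for AAV-seq; HTGTS reads are primed from ``side``.
    """

    assay: str = "AMPLICON"           # AMPLICON | TAG_JUNCTION | HTGTS
    outcome_proportions: dict = field(default_factory=lambda: {"WT": 1.0})
    n_reads: int = 1000
    read_length: int = 250
    error_rate: float = 0.0
    indel_size_geometric_p: float = 0.35
    tag: str = DSODN_TAG
    itr: str = SYNTHETIC_ITR
    seed: int | None = None
    side: str = "5p"                  # HTGTS enrichment side: 5p | 3p
    background_reads: int = 0         # tag-free reads in junction libraries
    duplication_mean: float = 0.5     # extra PCR copies per molecule (Poisson)
    translocation_partner: str = "planted"   # planted | random_far

    def validate(self) -> None:
        total = sum(self.outcome_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"outcome proportions sum to {total}, not 1")
        if not 0 <= self.error_rate <= 0.1:
            raise ConfigError("error_rate must lie in [0, 0.1]")
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")
        if self.side not in ("5p", "3p"):
            raise ConfigError("side must be 5p or 3p")


def _rng(config: SimulationConfig, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    if config.seed is None:
        raise ConfigError("a seed (or an explicit rng) is required")
    return np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# mini-genome construction


def build_mini_genome(seed=None, n_off_targets: int = 3,
                      mismatch_range: tuple = (2, 4),
                      contig_length: int | None = None,
                      spacer_distance: int = 250, ha_length: int = 800,
                      contig: str = "mini1", rng=None,
                      n_diagnostic_extras: int = 2):
    """Build the study locus embedded in a random mini-genome.

    Returns ``(MiniGenome, LocusDesign)``.  The design is a PAM-out
    nickase pair at the requested spacer distance with an HDR donor whose
    payload carries a diagnostic Sal I site (planted by silent
    substitutions at the payload centre) plus ``n_diagnostic_extras``
    further diagnostic substitutions.  ``n_off_targets`` protospacer
    variants with ``k`` substitutions (k drawn from ``mismatch_range``)
    are planted >= 6 kb apart so their 5000-bp annotation windows never
    overlap.  Deterministic per seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    margin = ha_length + 100
    wlen = 2 * margin + spacer_distance
    a_rel, b_rel = margin, margin + spacer_distance

    # window sequence with planted PAMs; re-scrub until Sal I free
    for _ in range(10):
        w = list(scrub_motif(random_dna(rng, wlen), "GTCGAC", rng))
        s_up = a_rel - 6           # upstream guide, minus strand: CCN PAM
        w[s_up], w[s_up + 1] = "C", "C"
        s_dn = b_rel - 17          # downstream guide, plus strand: NGG PAM
        w[s_dn + 21], w[s_dn + 22] = "G", "G"
        wseq = "".join(w)
        if "GTCGAC" not in wseq and "GTCGAC" not in revcomp(wseq):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not scrub diagnostic motif from window")

    # donor payload: spacer segment with a planted Sal I site + extras
    spacer_seq = wseq[a_rel:b_rel]
    centre = len(spacer_seq) // 2 - 3
    payload = list(spacer_seq)
    variants = []
    for i, base in enumerate("GTCGAC"):
        p = centre + i
        if payload[p] != base:
            variants.append((p, payload[p], base))
            payload[p] = base
    extra_slots = np.linspace(len(spacer_seq) // 4,
                              3 * len(spacer_seq) // 4,
                              num=n_diagnostic_extras + 2, dtype=int)[1:-1]
    for p in extra_slots:
        p = int(p)
        if any(abs(p - v[0]) < 8 for v in variants):
            continue
        _, muts = mutate_positions("".join(payload), rng, 1, positions=[p])
        pos, ref, alt = muts[0]
        payload[pos] = alt
        variants.append((pos, ref, alt))
    payload = "".join(payload)
    variants.sort()

    # contig with the window and off-target sites planted
    if contig_length is None:
        contig_length = 6000 + wlen + 12000 * max(1, n_off_targets) + 6000
    min_len = wlen + 6000 + 12000 * n_off_targets
    if contig_length < min_len:
        raise ConfigError(
            f"contig_length {contig_length} too short; needs >= {min_len}")
    cseq = list(random_dna(rng, contig_length))
    offset = 3000
    cseq[offset:offset + wlen] = wseq
    w0 = offset

    genome = MiniGenome(contigs={contig: "".join(cseq)})
    guide_a = GuideSite.from_genome("sgA", contig, w0 + a_rel - 6, "-", genome)
    guide_b = GuideSite.from_genome("sgB", contig, w0 + b_rel - 17, "+",
                                    genome)
    pair = NickPair(guide_a, guide_b)

    records = []
    pos = w0 + wlen + 6000
    lo, hi = mismatch_range
    for i in range(n_off_targets):
        g = (guide_a, guide_b)[i % 2]
        site_plus = g.interval.sequence(genome) if g.strand == "+" else \
            revcomp(g.interval.sequence(genome))
        k = int(rng.integers(lo, hi + 1))
        proto_positions = (list(range(0, 20)) if g.strand == "+"
                           else list(range(3, 23)))
        subs = sorted(rng.choice(proto_positions, size=k, replace=False)
                      .tolist())
        mutated, _ = mutate_positions(site_plus, rng, k, positions=subs)
        cseq[pos:pos + 23] = mutated
        iv = GenomicInterval(contig, pos, pos + 23, g.strand)
        site_guide_strand = mutated if g.strand == "+" else revcomp(mutated)
        ann = guide_match_string(g.protospacer + g.pam, site_guide_strand)
        records.append(OffTargetRecord(iv, g.id, ann.mismatch_count,
                                       ann.bulge_count, ann.marks))
        pos += 12000
    genome.contigs[contig] = "".join(cseq)
    genome.planted_off_targets = records

    window = GenomicInterval(contig, w0, w0 + wlen)
    donor = DonorTemplate(
        left_ha=wseq[a_rel - ha_length:a_rel],
        left_anchor=GenomicInterval(contig, w0 + a_rel - ha_length,
                                    w0 + a_rel),
        payload=payload,
        right_ha=wseq[b_rel:b_rel + ha_length],
        right_anchor=GenomicInterval(contig, w0 + b_rel,
                                     w0 + b_rel + ha_length),
        diagnostic_variants=tuple(variants), min_ha_length=ha_length)
    design = LocusDesign(
        name="synthetic_locus", reference_window=window, pair=pair,
        donor=donor,
        outer_primers=(w0 + 20, w0 + wlen - 40),
        htgts_nested_primers={
            "5p": (w0 + a_rel - 80, w0 + a_rel - 60),
            "3p": (w0 + b_rel + 60, w0 + b_rel + 80)})
    design.validate(genome)
    return genome, design


# ---------------------------------------------------------------------------
# shared read-construction helpers


def _indel_spec(rng, config) -> tuple:
    kind = "deletion" if rng.random() < 0.5 else "insertion"
    size = int(min(20, rng.geometric(config.indel_size_geometric_p)))
    return kind, size


def _apply_indel(seq: str, pos: int, kind: str, size: int, rng) -> str:
    if kind == "deletion":
        return seq[:pos] + seq[pos + size:]
    return seq[:pos] + random_dna(rng, size) + seq[pos:]


def _emit(seq: str, rng, config) -> str:
    return add_sequencing_errors(seq, rng, config.error_rate)


def _draw_classes(rng, config) -> list:
    classes = sorted(config.outcome_proportions)
    probs = np.array([config.outcome_proportions[c] for c in classes])
    idx = rng.choice(len(classes), size=config.n_reads, p=probs)
    return [classes[i] for i in idx]


# ---------------------------------------------------------------------------
# amplicon-seq


def simulate_amplicon_reads(design: LocusDesign, genome: MiniGenome,
                            config: SimulationConfig, rng=None):
    """Whole-amplicon reads over the targeted window.

    Classes: WT, HDR (exact repair), HDR_IMPERFECT (repair plus a
    break-site indel), INDEL (WT plus a break-site indel) and DSODN_TAG
    (WT with the dsODN integrated at a nick).  Returns
    ``(reads, truths)`` with reads as (id, sequence) pairs.
    """
    config.validate()
    rng = _rng(config, rng)
    amplicons = build_expected_amplicons(design, genome)
    by_class = {a.outcome_class: a for a in amplicons}
    wt = by_class[OutcomeClass.WT]
    hdr = by_class.get(OutcomeClass.HDR)
    wants_hdr = any(c.startswith("HDR")
                    for c in config.outcome_proportions)
    if wants_hdr and hdr is None:
        raise ConfigError("HDR class requested but the design has no donor")
    w0 = design.reference_window.start
    nicks_wt = [p - w0 for p in design.nick_positions]
    nicks_hdr = list(hdr.junction_coords) if hdr is not None else []

    reads, truths = [], []
    for i, cls in enumerate(_draw_classes(rng, config)):
        rid = f"amp_{i:06d}"
        detail: dict = {}
        if cls == "WT":
            seq = wt.sequence
        elif cls == "HDR":
            seq = hdr.sequence
        elif cls in ("INDEL", "HDR_IMPERFECT"):
            base = wt.sequence if cls == "INDEL" else hdr.sequence
            anchors = nicks_wt if cls == "INDEL" else nicks_hdr
            nick = anchors[int(rng.integers(len(anchors)))]
            pos = nick + int(rng.integers(-3, 4))
            kind, size = _indel_spec(rng, config)
            seq = _apply_indel(base, pos, kind, size, rng)
            detail = {"indel": [kind, pos, size]}
        elif cls == "DSODN_TAG":
            nick = nicks_wt[int(rng.integers(len(nicks_wt)))]
            tag = config.tag if rng.random() < 0.5 else revcomp(config.tag)
            seq = wt.sequence[:nick] + tag + wt.sequence[nick:]
            detail = {"tag_site": nick}
        else:
            raise ConfigError(f"unknown amplicon class {cls!r}")
        reads.append((rid, _emit(seq, rng, config)))
        truths.append(TruthRecord(rid, cls, detail))
    return reads, truths


def simulate_site_amplicon_reads(genome: MiniGenome, record: OffTargetRecord,
                                 config: SimulationConfig, rng=None,
                                 flank: int = 200):
    """Amplicon reads over one (off-)target site window.

    Classes: WT, INDEL (at the site's cut position), DSODN_TAG.  Used to
    emulate per-site indel-rate and tag-count amplicon panels.
    """
    config.validate()
    rng = _rng(config, rng)
    contig = genome.contigs[record.interval.contig]
    cut = record.cut_position
    site_seq = contig[cut - flank:cut + flank]
    reads, truths = [], []
    for i, cls in enumerate(_draw_classes(rng, config)):
        rid = f"site_{record.interval.start}_{i:06d}"
        detail: dict = {}
        if cls == "WT":
            seq = site_seq
        elif cls == "INDEL":
            pos = flank + int(rng.integers(-3, 4))
            kind, size = _indel_spec(rng, config)
            seq = _apply_indel(site_seq, pos, kind, size, rng)
            detail = {"indel": [kind, pos, size]}
        elif cls == "DSODN_TAG":
            tag = config.tag if rng.random() < 0.5 else revcomp(config.tag)
            seq = site_seq[:flank] + tag + site_seq[flank:]
            detail = {"tag_site": flank}
        else:
            raise ConfigError(f"unknown site-amplicon class {cls!r}")
        reads.append((rid, _emit(seq, rng, config)))
        truths.append(TruthRecord(rid, cls, detail))
    return reads, truths


# ---------------------------------------------------------------------------
# tag-junction libraries (GUIDE-seq / AAV-seq)


def simulate_tag_reads(design: LocusDesign, genome: MiniGenome, events,
                       config: SimulationConfig, rng=None):
    """Tn5 junction-library reads around tag integration sites.

    Every molecule of an :class:`IntegrationEvent` gets an independent
    shear point 100-600 nt from the junction and 1 + Poisson(dup) PCR
    copies; each read is the terminal ``TAG_SUFFIX_LEN`` nt of the tag
    (forward or reverse-complement orientation) followed by genomic
    sequence from the integration point to the shear point.  Tag-free
    background reads are appended at ``config.background_reads``.
    """
    config.validate()
    rng = _rng(config, rng)
    tag_f = config.tag[-TAG_SUFFIX_LEN:]
    tag_r = revcomp(config.tag)[-TAG_SUFFIX_LEN:]
    reads, truths = [], []
    n = 0
    for ev in events:
        if ev.contig not in genome.contigs:
            raise ConfigError(f"event contig {ev.contig!r} not in genome")
        contig = genome.contigs[ev.contig]
        if not 0 <= ev.site < len(contig):
            raise ConfigError(f"event site {ev.site} outside contig")
        for mol in range(ev.molecule_count):
            orient = ev.orientation
            if orient == "both":
                orient = "forward" if rng.random() < 0.5 else "reverse"
            side = "right" if rng.random() < 0.5 else "left"
            shear = int(rng.integers(100, 601))
            if side == "right":
                flank = contig[ev.site:ev.site + shear]
                shear_coord = ev.site + len(flank)
            else:
                flank = revcomp(contig[max(0, ev.site - shear):ev.site])
                shear_coord = max(0, ev.site - shear)
            suffix = tag_f if orient == "forward" else tag_r
            frag = (suffix + flank)[:config.read_length]
            copies = 1 + int(rng.poisson(config.duplication_mean))
            for _ in range(copies):
                rid = f"tag_{n:06d}"
                n += 1
                reads.append((rid, _emit(frag, rng, config)))
                truths.append(TruthRecord(rid, "TAG_JUNCTION", {
                    "site": ev.site, "orientation": orient, "side": side,
                    "shear": shear_coord, "molecule": f"{ev.site}:{mol}"}))
    contig_names = sorted(genome.contigs)
    for _ in range(config.background_reads):
        name = contig_names[int(rng.integers(len(contig_names)))]
        contig = genome.contigs[name]
        start = int(rng.integers(0, len(contig) - config.read_length))
        seq = contig[start:start + config.read_length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        rid = f"tag_{n:06d}"
        n += 1
        reads.append((rid, _emit(seq, rng, config)))
        truths.append(TruthRecord(rid, "BACKGROUND", {"start": start}))
    return reads, truths


# ---------------------------------------------------------------------------
# LAM-HTGTS


HTGTS_CLASSES = ("WT", "HDR", "INDEL", "DELETION", "INVERSION",
                 "AAV_INTEGRATION", "TRANSLOCATION")


def simulate_htgts_reads(design: LocusDesign, genome: MiniGenome,
                         config: SimulationConfig, rng=None):
    """Primer-anchored reads across the proximal nick, one per allele.

    Reads start at the nested primer of ``config.side`` and run
    ``read_length`` nt into the class-defining structure.  TRANSLOCATION
    reads join the on-target proximal segment to a planted off-target cut
    site (or, with ``translocation_partner='random_far'``, to a random
    locus more than 5 kb from every predicted site, for testing the
    rejection rule).  The extra class AAV_DONOR represents free AAV
    donor contamination, which carries no genomic primer and must be
    rejected at the priming check.
    """
    config.validate()
    rng = _rng(config, rng)
    unknown = set(config.outcome_proportions) - set(HTGTS_CLASSES) - \
        {"AAV_DONOR"}
    if unknown:
        raise ConfigError(f"unknown HTGTS classes: {sorted(unknown)}")
    if "HDR" in config.outcome_proportions and design.donor is None:
        raise ConfigError("HDR class requested but the design has no donor")
    if "TRANSLOCATION" in config.outcome_proportions and \
            config.translocation_partner == "planted" and \
            not genome.planted_off_targets:
        raise ConfigError("TRANSLOCATION requested but no off-targets "
                          "planted and random partners disabled")

    w = design.reference_window
    w0 = w.start
    contig = genome.contigs[w.contig]
    wt_seq = w.sequence(genome)
    amplicons = build_expected_amplicons(design, genome, itr=config.itr)
    by_name = {a.name: a for a in amplicons}
    a_rel, b_rel = [p - w0 for p in design.nick_positions]
    p5s, p5e = [p - w0 for p in design.htgts_nested_primers["5p"]]
    p3s, p3e = [p - w0 for p in design.htgts_nested_primers["3p"]]
    side = config.side
    proximal = a_rel if side == "5p" else b_rel
    L = config.read_length

    def partner_flank(rng) -> tuple:
        if config.translocation_partner == "planted":
            rec = genome.planted_off_targets[
                int(rng.integers(len(genome.planted_off_targets)))]
            cut, cname = rec.cut_position, rec.interval.contig
        else:
            cname = w.contig
            cut = _random_far_position(rng, genome, design)
        pcontig = genome.contigs[cname]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            seq = pcontig[cut:cut + L]
        else:
            seq = revcomp(pcontig[max(0, cut - L):cut])
        return seq, cname, cut, strand

    def read_from_template(tpl: str) -> str:
        if side == "5p":
            return tpl[p5s:p5s + L]
        return revcomp(tpl[max(0, p3e - L):p3e])

    donor_seq = ""
    if design.donor is not None:
        donor_seq = (design.donor.left_ha + design.donor.payload +
                     design.donor.right_ha)

    reads, truths = [], []
    for i, cls in enumerate(_draw_classes(rng, config)):
        rid = f"htgts_{i:06d}"
        detail: dict = {"side": side}
        if cls in ("WT", "HDR", "DELETION", "INVERSION"):
            tpl = by_name[cls].sequence
            # HDR/DELETION shift the 3' coordinate frame
            if side == "3p":
                shift = len(tpl) - len(wt_seq)
                seq = revcomp(tpl[max(0, p3e + shift - L):p3e + shift])
            else:
                seq = read_from_template(tpl)
        elif cls == "INDEL":
            kind, size = _indel_spec(rng, config)
            pos = proximal + int(rng.integers(-3, 4))
            tpl = _apply_indel(wt_seq, pos, kind, size, rng)
            if side == "3p":
                shift = len(tpl) - len(wt_seq)
                seq = revcomp(tpl[max(0, p3e + shift - L):p3e + shift])
            else:
                seq = read_from_template(tpl)
            detail["indel"] = [kind, pos, size]
        elif cls == "AAV_INTEGRATION":
            orient = "fwd" if rng.random() < 0.5 else "rev"
            name = (f"AAV_left_{a_rel}_{orient}" if side == "5p"
                    else f"AAV_right_{b_rel}_{orient}")
            tpl = by_name[name].sequence
            if side == "5p":
                seq = read_from_template(tpl)
            else:
                end = len(tpl)   # right-anchored cassette + wt suffix
                anchor = end - (len(wt_seq) - p3e)
                seq = revcomp(tpl[max(0, anchor - L):anchor])
            detail["orientation"] = orient
        elif cls == "TRANSLOCATION":
            flank, cname, cut, strand = partner_flank(rng)
            if side == "5p":
                tpl = wt_seq[:a_rel] + flank
                seq = tpl[p5s:p5s + L]
            else:
                tpl = revcomp(flank) + wt_seq[b_rel:]
                anchor = len(tpl) - (len(wt_seq) - p3e)
                seq = revcomp(tpl[max(0, anchor - L):anchor])
            detail.update({"partner_contig": cname, "partner_cut": cut,
                           "partner_strand": strand})
        elif cls == "AAV_DONOR":
            seq = (config.itr + donor_seq)[:L]
        else:  # pragma: no cover
            raise ConfigError(f"unknown HTGTS class {cls!r}")
        reads.append((rid, _emit(seq, rng, config)))
        truths.append(TruthRecord(rid, cls, detail))
    return reads, truths


def _random_far_position(rng, genome: MiniGenome, design: LocusDesign,
                         min_distance: int = 6000) -> int:
    """Random coordinate > ``min_distance`` from every predicted site."""
    contig = genome.contigs[design.reference_window.contig]
    keep_out = [(design.reference_window.start - min_distance,
                 design.reference_window.end + min_distance)]
    for rec in genome.planted_off_targets:
        keep_out.append((rec.interval.start - min_distance,
                         rec.interval.end + min_distance))
    for _ in range(1000):
        pos = int(rng.integers(500, len(contig) - 500))
        if all(not lo <= pos < hi for lo, hi in keep_out):
            return pos
    raise ConfigError("mini-genome too crowded for a far partner")
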