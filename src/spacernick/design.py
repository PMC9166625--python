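"""Locus design model for paired-nickase (spacer-nick) gene correction.

A :class:`LocusDesign` ties together the reference window of a targeted
locus, one guide or a PAM-out guide pair, an optional homology-directed
repair (HDR) donor, primer positions for the amplicon and LAM-HTGTS
assays, and per-nick quantification windows.  From a validated design the
module constructs the in-silico *expected-outcome amplicons* — WT, HDR,
nick-to-nick deletion, inversion, and AAV-integration sequences — that are
shared between the read simulator and every classifier.

Conventions
-----------
* Coordinates are 0-based, half-open, on the plus strand (BED-style).
* The nick coordinate of a guide is placed 3 nt 5' of the PAM, i.e.
  between protospacer positions 17 and 18 (the canonical Cas9 cut site).
* PAMs are constrained to NGG (SpCas9 / SpCas9-D10A nickase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from .seqs import revcomp

#: Spacer-distance band (bp between the two nicks) recommended for the
#: spacer-nick design: wide enough to suppress double-strand breaks,
#: narrow enough to retain HDR.
SPACER_RANGE = (200, 350)

#: Default minimum homology-arm length (bp) outside each nick site.
MIN_HA_LENGTH = 800

#: Half-width (nt) of the per-nick indel quantification window.
NICK_WINDOW_PAD = 10


class DesignError(ValueError):
    """A locus design that contradicts the reference genome or itself."""


class Orientation(str, Enum):
    PAM_OUT = "PAM_OUT"
    PAM_IN = "PAM_IN"
    TANDEM = "TANDEM"


class OutcomeClass(str, Enum):
    """Editing-outcome classes used by simulator and classifiers."""

    WT = "WT"
    HDR = "HDR"
    HDR_IMPERFECT = "HDR_IMPERFECT"
    INDEL = "INDEL"
    DELETION = "DELETION"
    INVERSION = "INVERSION"
    AAV_INTEGRATION = "AAV_INTEGRATION"
    TRANSLOCATION = "TRANSLOCATION"
    AMBIGUOUS = "AMBIGUOUS"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise DesignError(
                f"invalid interval {self.contig}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise DesignError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def sequence(self, genome) -> str:
        """Strand-aware sequence of this interval from a contig map."""
        contigs = genome.contigs if hasattr(genome, "contigs") else genome
        if self.contig not in contigs:
            raise DesignError(f"contig {self.contig!r} not in genome")
        s = contigs[self.contig][self.start:self.end]
        if len(s) != len(self):
            raise DesignError(
                f"interval {self.contig}:{self.start}-{self.end} exceeds contig")
        return revcomp(s) if self.strand == "-" else s

    def distance_to(self, pos: int) -> int:
        """Distance from a point to this interval (0 when inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class GuideSite:
    """A validated SpCas9(n) guide: 20-nt protospacer plus NGG PAM."""

    id: str
    protospacer: str
    pam: str
    interval: GenomicInterval

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise DesignError(f"{self.id}: protospacer must be 20 nt")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise DesignError(f"{self.id}: PAM {self.pam!r} is not NGG")
        if len(self.interval) != 23:
            raise DesignError(f"{self.id}: interval must span 23 nt")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def nick_position(self) -> int:
        return nick_position(self)

    def validate(self, genome) -> None:
        """Check the genome carries protospacer+PAM at the interval."""
        seq = self.interval.sequence(genome)
        if seq.upper() != (self.protospacer + self.pam).upper():
            raise DesignError(
                f"guide {self.id}: genome sequence at "
                f"{self.interval.contig}:{self.interval.start}-"
                f"{self.interval.end}({self.strand}) does not match "
                f"protospacer+PAM")

    @classmethod
    def from_genome(cls, id: str, contig: str, start: int, strand: str,
                    genome) -> "GuideSite":
        """Build a guide by reading 23 nt off the genome at ``start``."""
        iv = GenomicInterval(contig, start, start + 23, strand)
        seq = iv.sequence(genome)
        return cls(id=id, protospacer=seq[:20], pam=seq[20:], interval=iv)


def nick_position(guide: GuideSite) -> int:
    """Genome coordinate of the nick, 3 nt 5' of the PAM.

    On the plus strand the PAM occupies the last 3 nt of the interval and
    the nick sits at ``start + 17``; on the minus strand the PAM is at the
    left edge and the mirror coordinate is ``start + 6``.
    """
    if guide.strand == "+":
        return guide.interval.start + 17
    return guide.interval.start + 6


@dataclass(frozen=True)
class NickPair:
    """Two nickase guides on one contig; spacer-nick wants PAM-out pairs."""

    guide_a: GuideSite
    guide_b: GuideSite

    def __post_init__(self):
        if self.guide_a.interval.contig != self.guide_b.interval.contig:
            raise DesignError("paired guides must target one contig")

    @property
    def nick_a(self) -> int:
        return min(self.guide_a.nick_position, self.guide_b.nick_position)

    @property
    def nick_b(self) -> int:
        return max(self.guide_a.nick_position, self.guide_b.nick_position)

    @property
    def spacer_distance(self) -> int:
        return spacer_distance(self)

    @property
    def orientation(self) -> Orientation:
        return validate_pam_out(self)[0]


def spacer_distance(pair: NickPair) -> int:
    """bp between the two nick positions (symmetric in guide order)."""
    return abs(pair.guide_a.nick_position - pair.guide_b.nick_position)


def validate_pam_out(pair: NickPair) -> tuple[Orientation, list[str]]:
    """Classify pair orientation and warn when outside the spacer band.

    PAM-out means both PAMs face away from the intervening spacer: the
    upstream guide lies on the minus strand (PAM leftward) and the
    downstream guide on the plus strand (PAM rightward).
    """
    a, b = pair.guide_a, pair.guide_b
    warnings_: list[str] = []
    if a.strand == b.strand:
        orient = Orientation.TANDEM
    else:
        upstream, downstream = sorted((a, b), key=lambda g: g.nick_position)
        if upstream.strand == "-" and downstream.strand == "+":
            orient = Orientation.PAM_OUT
        else:
            orient = Orientation.PAM_IN
    d = spacer_distance(pair)
    lo, hi = SPACER_RANGE
    if not lo <= d <= hi:
        warnings_.append(
            f"spacer distance {d} bp outside the recommended "
            f"{lo}-{hi} bp band")
    return orient, warnings_


@dataclass(frozen=True)
class DonorTemplate:
    """HDR donor: two genome-anchored homology arms around a payload.

    ``diagnostic_variants`` are (position-in-payload, ref, alt) base
    substitutions distinguishing a repaired allele from wild type (e.g.
    silent mutations forming a Sal I site).
    """

    left_ha: str
    left_anchor: GenomicInterval
    payload: str
    right_ha: str
    right_anchor: GenomicInterval
    diagnostic_variants: tuple = ()
    min_ha_length: int = MIN_HA_LENGTH

    def validate(self, genome, pair: NickPair | None = None,
                 strict: bool = False) -> list[str]:
        """Check HA anchors against the genome and the nick interval.

        Returns warnings; raises :class:`DesignError` on anchor mismatch
        (always) or short HAs (only when ``strict``).
        """
        msgs: list[str] = []
        for name, ha, anchor in (("left", self.left_ha, self.left_anchor),
                                 ("right", self.right_ha, self.right_anchor)):
            if anchor.sequence(genome).upper() != ha.upper():
                raise DesignError(f"{name} HA does not match its genomic anchor")
            if len(ha) < self.min_ha_length:
                msg = (f"{name} HA is {len(ha)} bp, below the "
                       f"{self.min_ha_length} bp minimum")
                if strict:
                    raise DesignError(msg)
                msgs.append(msg)
                warnings.warn(msg)
        if pair is not None:
            if self.left_anchor.end > pair.nick_a or \
               self.right_anchor.start < pair.nick_b:
                raise DesignError(
                    "homology arms must lie entirely outside the "
                    "nick-to-nick interval")
        for p, ref, alt in self.diagnostic_variants:
            if not 0 <= p < len(self.payload):
                raise DesignError("diagnostic variant outside payload")
            if self.payload[p].upper() != alt.upper():
                raise DesignError(
                    f"payload base at {p} is {self.payload[p]}, expected "
                    f"alt {alt}")
        return msgs


@dataclass
class LocusDesign:
    """A targeted locus: window, guides, donor, primers, assay windows."""

    name: str
    reference_window: GenomicInterval
    pair: NickPair | None = None
    guide: GuideSite | None = None
    donor: DonorTemplate | None = None
    #: genomic start positions of the outer (amplicon / linear-PCR)
    #: primer pair; both lie outside the homology arms
    outer_primers: tuple[int, int] | None = None
    #: genomic (start, end) of the 5' and 3' nested HTGTS primers,
    #: ~50-100 bp from the nicks; the 3' primer anneals on the minus strand
    htgts_nested_primers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pair is None and self.guide is None:
            raise DesignError(f"{self.name}: needs a guide or a guide pair")

    @property
    def nick_positions(self) -> list[int]:
        if self.pair is not None:
            return [self.pair.nick_a, self.pair.nick_b]
        return [self.guide.nick_position]

    @property
    def guides(self) -> list[GuideSite]:
        if self.pair is not None:
            return [self.pair.guide_a, self.pair.guide_b]
        return [self.guide]

    @property
    def quantification_windows(self) -> list[GenomicInterval]:
        """Per-nick +/-10 nt windows used for indel calling."""
        c = self.reference_window.contig
        return [GenomicInterval(c, p - NICK_WINDOW_PAD, p + NICK_WINDOW_PAD)
                for p in self.nick_positions]

    def validate(self, genome) -> list[str]:
        """Validate every component against the genome; return warnings."""
        w = self.reference_window
        msgs: list[str] = []
        for g in self.guides:
            g.validate(genome)
            if not (w.start <= g.interval.start and g.interval.end <= w.end):
                raise DesignError(f"guide {g.id} outside reference window")
        if self.pair is not None:
            _, pw = validate_pam_out(self.pair)
            msgs.extend(pw)
        if self.donor is not None:
            msgs.extend(self.donor.validate(genome, self.pair))
        if self.outer_primers is not None and self.donor is not None:
            lo, hi = self.outer_primers
            if not (lo < self.donor.left_anchor.start
                    and hi >= self.donor.right_anchor.end):
                raise DesignError("outer primers must flank the homology arms")
        return msgs


@dataclass(frozen=True)
class OffTargetRecord:
    """A predicted or planted off-target site for one guide."""

    interval: GenomicInterval
    guide_id: str
    mismatch_count: int
    bulge_count: int = 0
    match_string: str = ""

    def __post_init__(self):
        if self.bulge_count > 1:
            raise DesignError("at most one bulge per off-target record")
        if self.match_string:
            marks = sum(1 for c in self.match_string if c == "X")
            if marks != self.mismatch_count:
                raise DesignError(
                    "mismatch_count disagrees with match_string marks")

    @property
    def cut_position(self) -> int:
        """Nick/cut-equivalent coordinate at the planted site."""
        if self.interval.strand == "+":
            return self.interval.start + 17
        return self.interval.start + 6


@dataclass(frozen=True)
class ExpectedAmplicon:
    """In-silico sequence for one expected editing outcome.

    ``junction_coords`` are the class-defining junction positions within
    ``sequence``; ``windows`` are (start, end) indel-quantification spans
    in amplicon coordinates; ``diagnostic_positions`` are (pos, alt_base)
    pairs marking HDR-diagnostic substitutions.
    """

    outcome_class: OutcomeClass
    name: str
    sequence: str
    junction_coords: tuple = ()
    windows: tuple = ()
    diagnostic_positions: tuple = ()
    meta: tuple = ()


def build_hdr_sequence(design: LocusDesign, genome) -> str:
    """Reference window with the donor payload swapped in between the HAs."""
    if design.donor is None:
        raise DesignError(f"{design.name}: no donor template")
    design.donor.validate(genome, design.pair)
    w = design.reference_window
    wt = w.sequence(genome)
    p = design.donor.left_anchor.end - w.start
    q = design.donor.right_anchor.start - w.start
    if not (0 <= p <= q <= len(wt)):
        raise DesignError("HA anchors outside the reference window")
    return wt[:p] + design.donor.payload + wt[q:]


def build_expected_amplicons(design: LocusDesign, genome,
                             itr: str | None = None) -> list[ExpectedAmplicon]:
    """Construct the expected-outcome amplicon set for a design.

    Always yields WT; with a guide pair also the precise nick-to-nick
    DELETION and the in-place INVERSION; with a donor the HDR amplicon;
    with an ITR sequence the four AAV-integration joins (each nick, both
    tag orientations).  Single-nick indel alleles are left to the
    simulator/classifiers: enumerating them would make the set infinite.
    """
    w = design.reference_window
    wt = w.sequence(genome)
    pad = NICK_WINDOW_PAD
    nicks = [p - w.start for p in design.nick_positions]
    wt_windows = tuple((n - pad, n + pad) for n in nicks)
    out = [ExpectedAmplicon(OutcomeClass.WT, "WT", wt,
                            junction_coords=tuple(nicks), windows=wt_windows)]

    if design.donor is not None:
        hdr = build_hdr_sequence(design, genome)
        p = design.donor.left_anchor.end - w.start
        q = p + len(design.donor.payload)
        diag = tuple((p + off, alt)
                     for off, _ref, alt in design.donor.diagnostic_variants)
        out.append(ExpectedAmplicon(
            OutcomeClass.HDR, "HDR", hdr,
            junction_coords=(p, q), windows=((p - pad, q + pad),),
            diagnostic_positions=diag))
    else:
        warnings.warn(f"{design.name}: no donor, HDR amplicon omitted")

    if len(nicks) == 2:
        a, b = nicks
        out.append(ExpectedAmplicon(
            OutcomeClass.DELETION, "DELETION", wt[:a] + wt[b:],
            junction_coords=(a,), windows=((a - pad, a + pad),)))
        out.append(ExpectedAmplicon(
            OutcomeClass.INVERSION, "INVERSION",
            wt[:a] + revcomp(wt[a:b]) + wt[b:],
            junction_coords=(a, b), windows=wt_windows))

    if itr:
        cassette_f = itr + revcomp(itr) + itr
        cassette_r = revcomp(cassette_f)
        for n in nicks:
            for tag, cassette in (("fwd", cassette_f), ("rev", cassette_r)):
                out.append(ExpectedAmplicon(
                    OutcomeClass.AAV_INTEGRATION, f"AAV_left_{n}_{tag}",
                    wt[:n] + cassette, junction_coords=(n,),
                    windows=((n - pad, n + pad),),
                    meta=(("nick", n), ("orientation", tag), ("side", "left"))))
                out.append(ExpectedAmplicon(
                    OutcomeClass.AAV_INTEGRATION, f"AAV_right_{n}_{tag}",
                    cassette + wt[n:],
                    junction_coords=(len(cassette),),
                    windows=((len(cassette) - pad, len(cassette) + pad),),
                    meta=(("nick", n), ("orientation", tag), ("side", "right"))))
    return out
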