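"""LAM-HTGTS outcome classification.

Reads are anchored at a nested primer ~50-100 bp from one nick and read
across the break.  Classification is a strict priority cascade; every
read gets exactly one terminal label:

1. **priming** — the read must begin with the expected nested primer
   (one substitution tolerated); mis-primed reads (including free AAV
   donor contamination, which carries no genomic primer) are rejected;
2. **ITR detection** — a local alignment to the AAV ITR in either
   orientation marks the read AAV_INTEGRATION;
3. **expected amplicons** — a perfect (0 mismatch, 0 indel) match over
   the read's span to the HDR / WT / deletion / inversion amplicon
   assigns that class; HDR additionally requires the read to span a
   donor-diagnostic substitution;
4. **break-site analysis** — reads similar to WT are scanned for indels
   overlapping a nick window (INDEL) or deletions bridging the two
   windows (DELETION); reads ending before the window are UNINFORMATIVE;
5. **translocation** — the remainder is split at the proximal nick and
   the distal segment placed on the genome; a perfect unique placement
   within 5000 bp of a predicted off-target site is a TRANSLOCATION,
   anything else stays AMBIGUOUS and is never counted as one.

The 5' and 3' enrichments are independent runs combined only at
reporting.  Internally every read is rotated into an "anchored" frame
(read coordinates increasing away from the primer) so one code path
serves both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import best_genomic_hit, local_align, prefix_align
from .amplicon import (OutcomeCall, OutcomeProfile, _window_indels,
                       profile_from_counts)
from .design import (ExpectedAmplicon, LocusDesign, OutcomeClass,
                     build_expected_amplicons)
from .seqs import revcomp

#: amplicon tie-break priority when a read matches several templates
CLASS_PRIORITY = (OutcomeClass.HDR, OutcomeClass.WT, OutcomeClass.DELETION,
                  OutcomeClass.INVERSION, OutcomeClass.AAV_INTEGRATION)


@dataclass(frozen=True)
class HtgtsThresholds:
    primer_max_mismatch: int = 1
    #: mismatches tolerated in a "perfect" amplicon match; 0 per the
    #: perfect-mapped contract, raise for noisy data
    perfect_max_mismatch: int = 0
    itr_min_identity: float = 0.8
    itr_min_span: int = 20
    itr_min_score: float = 18.0
    breaksite_min_identity: float = 0.9
    #: total inserted bases beyond this are not an NHEJ-scale event;
    #: the read is handed to translocation detection instead
    breaksite_max_insertion: int = 50
    min_distal: int = 25
    offtarget_window: int = 5000


DEFAULT_HTGTS = HtgtsThresholds()


@dataclass
class HtgtsContext:
    """Per-side precomputed frame: primer, anchored templates, windows."""

    side: str
    primer: str
    #: anchored view per amplicon: sequence downstream of the primer,
    #: in read orientation
    views: list                   # (ExpectedAmplicon, view_seq, diag, windows)
    wt_view: str
    nick_windows: list            # [(lo, hi)] in anchored coordinates
    proximal_nick: int            # anchored coordinate of the proximal nick
    genome: object
    off_targets: list
    thresholds: HtgtsThresholds = DEFAULT_HTGTS
    itr: str = ""


def build_context(design: LocusDesign, genome, side: str,
                  itr: str, thresholds: HtgtsThresholds = DEFAULT_HTGTS,
                  off_targets=None) -> HtgtsContext:
    """Precompute the anchored frame for one enrichment side."""
    w = design.reference_window
    w0 = w.start
    wt_seq = w.sequence(genome)
    amplicons = build_expected_amplicons(design, genome, itr=itr)
    nicks = sorted(p - w0 for p in design.nick_positions)
    p_start, p_end = [p - w0 for p in design.htgts_nested_primers[side]]
    if side == "5p":
        primer = wt_seq[p_start:p_end]
        interface = p_end
        proximal = nicks[0] - interface
        nick_windows = [(n - interface - 10, n - interface + 10)
                        for n in nicks]
    else:
        primer = revcomp(wt_seq[p_start:p_end])
        interface = p_start
        proximal = interface - nicks[-1]
        nick_windows = [(interface - n - 10, interface - n + 10)
                        for n in reversed(nicks)]

    views = []
    for amp in amplicons:
        meta = dict(amp.meta)
        if side == "5p":
            if meta.get("side") == "right":
                continue
            shift = _coord_shift(amp, wt_seq, interface, "5p")
            if shift is None:
                continue
            view = amp.sequence[interface + shift:]
            diag = tuple((p - interface - shift, alt)
                         for p, alt in amp.diagnostic_positions
                         if p - interface - shift >= 0)
        else:
            if meta.get("side") == "left":
                continue
            shift = _coord_shift(amp, wt_seq, interface, "3p")
            if shift is None:
                continue
            view = revcomp(amp.sequence[:interface + shift])
            diag = tuple((interface + shift - 1 - p, _rc_base(alt))
                         for p, alt in amp.diagnostic_positions
                         if interface + shift - 1 - p >= 0)
        if view:
            views.append((amp, view, diag))
    return HtgtsContext(side=side, primer=primer, views=views,
                        wt_view=next(v for a, v, _ in views
                                     if a.outcome_class == OutcomeClass.WT),
                        nick_windows=nick_windows, proximal_nick=proximal,
                        genome=genome,
                        off_targets=list(off_targets or []),
                        thresholds=thresholds, itr=itr)


def _rc_base(b: str) -> str:
    return revcomp(b)


def _coord_shift(amp: ExpectedAmplicon, wt_seq: str, interface: int,
                 side: str) -> int | None:
    """Offset mapping the WT interface coordinate into amplicon coords.

    The primer lies in flanking sequence shared by every amplicon; for
    5' reads that flank is the amplicon prefix (shift 0); for 3' reads
    the flank is a suffix whose coordinates move with the amplicon's
    length change.
    """
    if side == "5p":
        return 0
    shift = len(amp.sequence) - len(wt_seq)
    if amp.outcome_class == OutcomeClass.AAV_INTEGRATION:
        # right-side cassette amplicons: suffix starts at the junction
        meta = dict(amp.meta)
        nick = meta["nick"]
        return len(amp.sequence) - (len(wt_seq) - nick) - nick
    return shift


def check_priming_and_trim(read: str, primer: str,
                           max_mismatch: int = 1) -> tuple:
    """Verify and strip the nested primer; returns (status, remainder)."""
    if len(read) <= len(primer):
        return ("MISPRIMED", "")
    mm = sum(1 for a, b in zip(read, primer) if a != b)
    if mm > max_mismatch:
        return ("MISPRIMED", "")
    return ("OK", read[len(primer):])


def detect_itr(read: str, itr: str,
               thresholds: HtgtsThresholds = DEFAULT_HTGTS):
    """AAV ITR detection by local alignment, both orientations.

    Returns the junction coordinate within the read (start of the ITR
    segment) or None.
    """
    res = local_align(itr, read, min_score=thresholds.itr_min_score,
                      search_rc=True)
    if res is None:
        return None
    span = res.ref_interval[1] - res.ref_interval[0]
    if span < thresholds.itr_min_span or \
            res.gapless_identity() < thresholds.itr_min_identity:
        return None
    return res.ref_interval[0]


def _perfect_matches(remainder: str, ctx: HtgtsContext):
    """Amplicon views matched by the read with <= tol mismatches, no indels."""
    tol = ctx.thresholds.perfect_max_mismatch
    out = []
    for amp, view, diag in ctx.views:
        if len(view) < len(remainder):
            continue
        seg = view[:len(remainder)]
        if tol == 0:
            ok = seg == remainder
        else:
            mm = sum(1 for a, b in zip(seg, remainder) if a != b)
            ok = mm <= tol
        if ok:
            out.append((amp, diag))
    return out


def classify_htgts_read(read: str, ctx: HtgtsContext,
                        read_id: str = "") -> OutcomeCall:
    """Run the full priority cascade on one read."""
    t = ctx.thresholds
    status, remainder = check_priming_and_trim(read, ctx.primer,
                                               t.primer_max_mismatch)
    if status != "OK":
        return OutcomeCall(read_id, OutcomeClass.AMBIGUOUS,
                           {"reason": "MISPRIMED"})

    itr_pos = detect_itr(remainder, ctx.itr, t) if ctx.itr else None
    if itr_pos is not None:
        return OutcomeCall(read_id, OutcomeClass.AAV_INTEGRATION,
                           {"junction": itr_pos})

    matches = _perfect_matches(remainder, ctx)
    if matches:
        best = None
        for amp, diag in matches:
            if amp.outcome_class == OutcomeClass.HDR:
                if not diag or len(remainder) <= min(p for p, _ in diag):
                    continue  # read does not span a diagnostic variant
            rank = CLASS_PRIORITY.index(amp.outcome_class)
            if best is None or rank < best[0]:
                best = (rank, amp)
        if best is not None:
            amp = best[1]
            return OutcomeCall(read_id, amp.outcome_class,
                               {"amplicon": amp.name})

    call = analyze_breaksite(remainder, ctx, read_id)
    if call is not None:
        return call
    return detect_translocation(remainder, ctx, read_id)


def analyze_breaksite(remainder: str, ctx: HtgtsContext,
                      read_id: str = "") -> OutcomeCall | None:
    """Indel / deletion calling against the WT frame at the nick windows.

    Returns None when the read is not WT-like (handed to translocation
    detection), UNINFORMATIVE when it ends before the proximal window.
    """
    t = ctx.thresholds
    win = ctx.nick_windows
    if len(remainder) <= win[0][0]:
        return OutcomeCall(read_id, OutcomeClass.UNINFORMATIVE,
                           {"reason": "SHORT_OF_BREAK"})
    ref = ctx.wt_view
    res = prefix_align(ref, remainder)
    if res.gapless_identity() < t.breaksite_min_identity:
        return None
    indels = [iv for iv in res.ref_indels()]
    if sum(n for op, _s, _e, n in indels if op == "insertion") > \
            t.breaksite_max_insertion:
        return None
    window_hits = _window_indels(res, win)
    if not window_hits:
        # perfect-ish WT read that failed the strict perfect check
        # (e.g. a sequencing substitution): count as WT-like only when
        # it actually crosses the proximal window
        if res.ref_interval[1] >= win[0][1]:
            return OutcomeCall(read_id, OutcomeClass.WT,
                               {"note": "imperfect_wt"})
        return OutcomeCall(read_id, OutcomeClass.UNINFORMATIVE,
                           {"reason": "SHORT_OF_BREAK"})
    if len(win) == 2:
        for op, s, e, n in indels:
            if op == "deletion" and s < win[0][1] and e > win[1][0]:
                return OutcomeCall(read_id, OutcomeClass.DELETION,
                                   {"span": [s, e]})
    op, s, n = window_hits[0]
    return OutcomeCall(read_id, OutcomeClass.INDEL,
                       {"kind": op, "position": s, "size": n})


def detect_translocation(remainder: str, ctx: HtgtsContext,
                         read_id: str = "") -> OutcomeCall:
    """Map the distal (post-nick) segment; apply the 5000-bp rule.

    A unique perfect placement within 5000 bp of a predicted off-target
    is a nuclease-driven translocation; any other outcome (no placement,
    ambiguous placement, placement far from every predicted site) leaves
    the read AMBIGUOUS.
    """
    t = ctx.thresholds
    distal = remainder[max(ctx.proximal_nick, 0):]
    if len(distal) < t.min_distal:
        return OutcomeCall(read_id, OutcomeClass.AMBIGUOUS,
                           {"reason": "DISTAL_TOO_SHORT"})
    res = best_genomic_hit(distal, ctx.genome, min_length=t.min_distal)
    if res.status != "OK":
        return OutcomeCall(read_id, OutcomeClass.AMBIGUOUS,
                           {"reason": f"DISTAL_{res.status}"})
    p = res.placement
    junction = p.start if p.strand == "+" else p.end
    for rec in sorted(ctx.off_targets,
                      key=lambda r: r.interval.distance_to(junction)):
        if rec.interval.contig != p.contig:
            continue
        if rec.interval.distance_to(junction) <= t.offtarget_window:
            return OutcomeCall(read_id, OutcomeClass.TRANSLOCATION,
                               {"partner": f"{p.contig}:{junction}",
                                "partner_site": rec.interval.start,
                                "strand": p.strand})
    return OutcomeCall(read_id, OutcomeClass.AMBIGUOUS,
                       {"reason": "DISTAL_UNANNOTATED",
                        "placement": f"{p.contig}:{junction}"})


def classify_htgts_reads(reads, ctx: HtgtsContext) -> list:
    """Classify (read_id, sequence) pairs; one call per read."""
    return [classify_htgts_read(seq, ctx, read_id=rid) for rid, seq in reads]


def summarize_htgts(calls, enrichment_side: str = "5p"):
    """Outcome profile and heatmap-ready table for one enrichment side.

    HDR efficiency is HDR / classified reads; the WT:mutated ratio is
    WT over (INDEL + DELETION + INVERSION + AAV_INTEGRATION +
    TRANSLOCATION), HDR excluded from both terms.  AMBIGUOUS and
    UNINFORMATIVE reads are excluded from denominators but reported.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("summarize_htgts requires calls")
    profile = _profile(calls)
    rows = []
    total = profile.classified if profile.classified else 1
    for cls in ("WT", "HDR", "INDEL", "DELETION", "INVERSION",
                "AAV_INTEGRATION", "TRANSLOCATION"):
        n = profile.counts.get(cls, 0)
        rows.append({"side": enrichment_side, "outcome": cls, "count": n,
                     "fraction_of_classified": n / total})
    for cls in ("UNINFORMATIVE", "AMBIGUOUS"):
        rows.append({"side": enrichment_side, "outcome": cls,
                     "count": profile.counts.get(cls, 0),
                     "fraction_of_classified": float("nan")})
    table = pd.DataFrame(rows)
    hdr_eff = profile.counts.get("HDR", 0) / total
    return profile, table, hdr_eff


def _profile(calls) -> OutcomeProfile:
    counts: dict = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    return profile_from_counts(counts)
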