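"""Amplicon-seq outcome classification: WT / NHEJ / HDR quantification.

Each read is aligned globally to the WT and HDR expected amplicons.  A
read is HDR when it carries every donor-diagnostic substitution and no
indel inside a quantification window; an indel overlapping a window makes
it NHEJ (reported as INDEL, or HDR_IMPERFECT when the diagnostic
substitutions are also present); substitutions alone never count as
NHEJ.  The module also provides per-site indel rates, dsODN-tag
integration counts, and the in-silico RFLP estimate of HDR used as an
orthogonal check on the sequence-based classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (AlignmentResult, cut_positions, edit_align,
                    local_align)
from .design import DesignError, ExpectedAmplicon, OutcomeClass

#: classes pooled into "NHEJ" for pie-chart-style three-way reporting;
#: an HDR allele carrying an indel is not a precise repair, so
#: HDR_IMPERFECT pools with NHEJ (while staying visible in raw counts)
NHEJ_COMPONENTS = (OutcomeClass.INDEL, OutcomeClass.DELETION,
                   OutcomeClass.INVERSION, OutcomeClass.HDR_IMPERFECT)

#: mutated classes for the WT:mutated ratio (HDR excluded from both terms)
MUTATED_COMPONENTS = (OutcomeClass.INDEL, OutcomeClass.DELETION,
                      OutcomeClass.INVERSION, OutcomeClass.AAV_INTEGRATION,
                      OutcomeClass.TRANSLOCATION)


@dataclass
class OutcomeCall:
    read_id: str
    category: OutcomeClass
    detail: dict = field(default_factory=dict)


@dataclass
class OutcomeProfile:
    """Aggregated outcome counts, fractions and headline ratios.

    ``fractions`` run over every category including AMBIGUOUS /
    UNINFORMATIVE and sum to 1; ``three_way`` pools NHEJ components and
    runs over classified (WT+NHEJ+HDR) reads only.  Zero denominators
    are flagged and replaced by a pseudocount of 1 so a ratio is always
    reportable.
    """

    counts: dict
    total: int
    fractions: dict
    three_way: dict
    hdr_nhej_ratio: float
    hdr_nhej_defined: bool
    wt_mutated_ratio: float
    wt_mutated_defined: bool
    classified: int
    ambiguous: int


@dataclass(frozen=True)
class ClassifyThresholds:
    min_identity: float = 0.85
    min_read_length: int = 50


DEFAULT_THRESHOLDS = ClassifyThresholds()


def _window_indels(res: AlignmentResult, windows) -> list:
    """Indel runs of an alignment overlapping any quantification window."""
    hits = []
    for op, s, e, n in res.ref_indels():
        for w0, w1 in windows:
            if op == "insertion":
                if w0 <= s <= w1:
                    hits.append((op, s, n))
                    break
            elif s < w1 and e > w0:
                hits.append((op, s, n))
                break
    return hits


def _diagnostics_present(res: AlignmentResult, read: str,
                         diagnostic_positions) -> bool:
    if not diagnostic_positions:
        return False
    for pos, alt in diagnostic_positions:
        base = res.query_base_at_ref(read, pos)
        if base is None or base.upper() != alt.upper():
            return False
    return True


def classify_amplicon_read(read: str, amplicons,
                           thresholds: ClassifyThresholds = DEFAULT_THRESHOLDS,
                           read_id: str = "") -> OutcomeCall:
    """Assign one amplicon read to WT / HDR / HDR_IMPERFECT / INDEL.

    ``amplicons`` is the expected-amplicon list; only the WT entry (and
    the HDR entry when a donor exists) participate.  Reads shorter than
    the minimum or dissimilar to both amplicons come back AMBIGUOUS with
    a reason, never dropped.
    """
    by_class = {a.outcome_class: a for a in amplicons}
    wt = by_class[OutcomeClass.WT]
    hdr = by_class.get(OutcomeClass.HDR)
    if len(read) < thresholds.min_read_length:
        return OutcomeCall(read_id, OutcomeClass.AMBIGUOUS,
                           {"reason": "TOO_SHORT"})
    # fast paths: exact template match
    if read == wt.sequence:
        return OutcomeCall(read_id, OutcomeClass.WT, {"amplicon": "WT"})
    if hdr is not None and read == hdr.sequence:
        return OutcomeCall(read_id, OutcomeClass.HDR, {"amplicon": "HDR"})

    res_wt = edit_align(wt.sequence, read)
    res_hdr = edit_align(hdr.sequence, read) if hdr is not None else None
    if res_hdr is not None and res_hdr.score > res_wt.score:
        chosen, res = hdr, res_hdr
    else:
        chosen, res = wt, res_wt
    best_identity = max(res_wt.identity,
                        res_hdr.identity if res_hdr else 0.0)
    if best_identity < thresholds.min_identity:
        return OutcomeCall(read_id, OutcomeClass.AMBIGUOUS,
                           {"reason": "LOW_IDENTITY",
                            "identity": round(best_identity, 4)})

    indels = _window_indels(res, chosen.windows)
    detail = {"amplicon": chosen.name, "identity": round(res.identity, 4),
              "window_indels": indels}
    if chosen.outcome_class == OutcomeClass.HDR:
        diag_ok = _diagnostics_present(res, read, chosen.diagnostic_positions)
        if diag_ok and not indels:
            return OutcomeCall(read_id, OutcomeClass.HDR, detail)
        if diag_ok and indels:
            return OutcomeCall(read_id, OutcomeClass.HDR_IMPERFECT, detail)
        # partial/absent diagnostics: fall back on indel evidence vs WT
        indels_wt = _window_indels(res_wt, wt.windows)
        detail["window_indels"] = indels_wt
        if indels_wt:
            return OutcomeCall(read_id, OutcomeClass.INDEL, detail)
        return OutcomeCall(read_id, OutcomeClass.WT, detail)
    if indels:
        return OutcomeCall(read_id, OutcomeClass.INDEL, detail)
    return OutcomeCall(read_id, OutcomeClass.WT, detail)


def quantify_outcomes(calls) -> OutcomeProfile:
    """Aggregate per-read calls into counts, fractions and ratios."""
    calls = list(calls)
    if not calls:
        raise ValueError("quantify_outcomes requires at least one call")
    counts: dict = {}
    for c in calls:
        cat = c.category if isinstance(c, OutcomeCall) else OutcomeClass(c)
        counts[cat] = counts.get(cat, 0) + 1
    return profile_from_counts(counts)


def profile_from_counts(counts: dict) -> OutcomeProfile:
    counts = {OutcomeClass(k): v for k, v in counts.items()}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty outcome counts")
    fractions = {k.value: v / total for k, v in counts.items()}
    ambiguous = counts.get(OutcomeClass.AMBIGUOUS, 0) + \
        counts.get(OutcomeClass.UNINFORMATIVE, 0)
    classified = total - ambiguous
    n_hdr = counts.get(OutcomeClass.HDR, 0)
    n_nhej = sum(counts.get(k, 0) for k in NHEJ_COMPONENTS)
    n_wt = counts.get(OutcomeClass.WT, 0)
    n_mut = sum(counts.get(k, 0) for k in MUTATED_COMPONENTS) + \
        counts.get(OutcomeClass.HDR_IMPERFECT, 0)
    three_total = n_wt + n_nhej + n_hdr
    three_way = ({"WT": n_wt / three_total, "NHEJ": n_nhej / three_total,
                  "HDR": n_hdr / three_total} if three_total else
                 {"WT": 0.0, "NHEJ": 0.0, "HDR": 0.0})
    hdr_nhej_defined = n_nhej > 0
    hdr_nhej = n_hdr / n_nhej if hdr_nhej_defined else n_hdr / 1.0
    wt_mut_defined = n_mut > 0
    wt_mut = n_wt / n_mut if wt_mut_defined else n_wt / 1.0
    return OutcomeProfile(
        counts={k.value: v for k, v in counts.items()}, total=total,
        fractions=fractions, three_way=three_way,
        hdr_nhej_ratio=hdr_nhej, hdr_nhej_defined=hdr_nhej_defined,
        wt_mutated_ratio=wt_mut, wt_mutated_defined=wt_mut_defined,
        classified=classified, ambiguous=ambiguous)


def indel_rate(reads, wt_amplicon, window,
               min_identity: float = 0.85) -> float:
    """Fraction of classifiable reads with an indel overlapping ``window``.

    ``wt_amplicon`` may be an :class:`ExpectedAmplicon` or a plain
    sequence; ``window`` is a (start, end) span in amplicon coordinates
    overlapping the cut position.  Substitutions never count.
    """
    seq = wt_amplicon.sequence if isinstance(wt_amplicon, ExpectedAmplicon) \
        else wt_amplicon
    n_class = 0
    n_indel = 0
    for read in reads:
        if read == seq:
            n_class += 1
            continue
        res = edit_align(seq, read)
        if res.identity < min_identity:
            continue
        n_class += 1
        if _window_indels(res, [tuple(window)]):
            n_indel += 1
    if n_class == 0:
        raise ValueError("no classifiable reads for indel_rate")
    return n_indel / n_class


def count_tag_integrations(reads, tag_seq: str, min_span: int = 20,
                           min_identity: float = 0.9) -> int:
    """Number of reads containing the tag in either orientation.

    A partial tag at a read end counts once it spans ``min_span`` nt at
    ``min_identity``.
    """
    if len(tag_seq) < 20:
        raise ValueError("tag must be at least 20 nt")
    from .seqs import revcomp
    tag_rc = revcomp(tag_seq)
    n = 0
    for read in reads:
        if tag_seq in read or tag_rc in read:
            n += 1
            continue
        res = local_align(tag_seq, read, min_score=float(min_span) * 0.6,
                          search_rc=True)
        if res is None:
            continue
        span = res.query_interval[1] - res.query_interval[0]
        if span >= min_span and res.gapless_identity() >= min_identity:
            n += 1
    return n


def rflp_hdr_estimate(reads, hdr_amplicon: ExpectedAmplicon,
                      recognition: str = "GTCGAC", cut_offset: int = 1,
                      tolerance: int = 40,
                      wt_amplicon: ExpectedAmplicon | None = None) -> float:
    """HDR fraction from an in-silico restriction (RFLP) digest.

    A read counts when digestion cuts it within ``tolerance`` nt of the
    donor-introduced site's expected position, so alleles with small
    break-site indels next to an intact diagnostic site still score —
    mirroring what a gel-based RFLP measures.  On error-free reads this
    equals the sequence-based HDR + HDR_IMPERFECT fraction.
    """
    expected = cut_positions(hdr_amplicon.sequence, recognition, cut_offset)
    if not expected:
        raise DesignError("donor/HDR amplicon lacks the recognition site")
    if wt_amplicon is not None and \
            cut_positions(wt_amplicon.sequence, recognition, cut_offset):
        raise DesignError("WT amplicon already contains the recognition site")
    reads = list(reads)
    if not reads:
        raise ValueError("rflp_hdr_estimate requires reads")
    n_cut = 0
    for read in reads:
        cuts = cut_positions(read, recognition, cut_offset)
        if any(abs(c - e) <= tolerance for c in cuts for e in expected):
            n_cut += 1
    return n_cut / len(reads)
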