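"""Pairwise-alignment and matching primitives shared by all classifiers.

Global and local alignment are thin wrappers over Biopython's
``PairwiseAligner`` (affine gaps), exposing a uniform
:class:`AlignmentResult` with an explicit operation list.  Genomic
placement follows a "perfect mapped" contract: by default a read is
placed only where it matches the genome end-to-end with zero mismatches,
and placements are discarded as ambiguous when a second placement scores
within a margin of the best.  Gap penalties default to heavy because the
junction assays need crisp breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import re

import edlib
import numpy as np
from Bio import Align

from .seqs import revcomp


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -4.0
    gap_open: float = -6.0   # score of the first gapped column
    gap_extend: float = -1.0  # each additional gapped column


DEFAULT_SCORING = Scoring()


def _aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


@dataclass
class AlignmentResult:
    """One pairwise alignment: score, identity and an op run list.

    ``op_list`` holds (op, length) runs with op in {match, mismatch,
    insertion, deletion}; insertion means extra bases in the query,
    deletion means reference bases absent from the query.  ``identity``
    is the fraction of aligned columns (gap columns included) that match.
    """

    score: float
    identity: float
    op_list: list = field(default_factory=list)
    ref_interval: tuple = (0, 0)
    query_interval: tuple = (0, 0)
    strand: str = "+"

    @property
    def cigar(self) -> str:
        sym = {"match": "=", "mismatch": "X", "insertion": "I", "deletion": "D"}
        return "".join(f"{n}{sym[op]}" for op, n in self.op_list)

    def gapless_identity(self) -> float:
        """Match fraction over non-gap columns only."""
        m = sum(n for op, n in self.op_list if op == "match")
        mm = sum(n for op, n in self.op_list if op == "mismatch")
        return m / (m + mm) if m + mm else 0.0

    def ref_indels(self):
        """Yield (op, ref_start, ref_end, length) for every indel run.

        For insertions the ref span is zero-length at the insertion
        point; for deletions it covers the deleted reference bases.
        """
        r = self.ref_interval[0]
        for op, n in self.op_list:
            if op in ("match", "mismatch"):
                r += n
            elif op == "deletion":
                yield ("deletion", r, r + n, n)
                r += n
            else:
                yield ("insertion", r, r, n)

    def query_base_at_ref(self, query: str, ref_pos: int) -> str | None:
        """Query base aligned to a reference position (None if gapped/outside)."""
        r = self.ref_interval[0]
        q = self.query_interval[0]
        for op, n in self.op_list:
            if op in ("match", "mismatch"):
                if r <= ref_pos < r + n:
                    return query[q + (ref_pos - r)]
                r += n
                q += n
            elif op == "deletion":
                if r <= ref_pos < r + n:
                    return None
                r += n
            else:
                q += n
        return None


def _ops_from_alignment(aln, ref: str, query: str) -> list:
    """Convert a Biopython alignment into merged (op, length) runs."""
    t_blocks, q_blocks = aln.aligned
    ops: list[list] = []

    def push(op, n):
        n = int(n)
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1][1] += n
        else:
            ops.append([op, n])

    t_prev = t_blocks[0][0] if len(t_blocks) else 0
    q_prev = q_blocks[0][0] if len(q_blocks) else 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        push("deletion", ts - t_prev)
        push("insertion", qs - q_prev)
        run_op, run_len = None, 0
        for i in range(te - ts):
            op = "match" if ref[ts + i] == query[qs + i] and ref[ts + i] != "N" \
                else "mismatch"
            if op == run_op:
                run_len += 1
            else:
                if run_op:
                    push(run_op, run_len)
                run_op, run_len = op, 1
        if run_op:
            push(run_op, run_len)
        t_prev, q_prev = te, qe
    return [tuple(x) for x in ops]


def _result_from_alignment(aln, ref: str, query: str,
                           mode: str) -> AlignmentResult:
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks):
        ref_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
        query_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    else:  # degenerate: all-gap alignment
        ref_iv, query_iv = (0, 0), (0, 0)
    ops = _ops_from_alignment(aln, ref, query)
    if mode == "global":
        # account for end gaps so op lengths cover both full sequences
        lead_d, lead_i = ref_iv[0], query_iv[0]
        tail_d, tail_i = len(ref) - ref_iv[1], len(query) - query_iv[1]
        if lead_i:
            ops.insert(0, ("insertion", lead_i))
        if lead_d:
            ops.insert(0, ("deletion", lead_d))
        if tail_d:
            ops.append(("deletion", tail_d))
        if tail_i:
            ops.append(("insertion", tail_i))
        ref_iv, query_iv = (0, len(ref)), (0, len(query))
    n_cols = sum(n for _, n in ops)
    n_match = sum(n for op, n in ops if op == "match")
    return AlignmentResult(score=float(aln.score),
                           identity=n_match / n_cols if n_cols else 0.0,
                           op_list=ops, ref_interval=ref_iv,
                           query_interval=query_iv)


def global_align(a: str, b: str,
                 scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal end-to-end alignment of query ``b`` against reference ``a``.

    Deterministic: of all co-optimal alignments the aligner's first
    reported one is taken.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    al = _aligner(scoring, "global")
    aln = al.align(a, b)[0]
    return _result_from_alignment(aln, a, b, "global")


def local_align(query: str, target: str, scoring: Scoring = DEFAULT_SCORING,
                min_score: float = 15.0,
                search_rc: bool = False) -> AlignmentResult | None:
    """Best local placement of ``query`` within ``target``.

    Returns None below ``min_score``.  With ``search_rc`` the reverse
    complement of the query is also tried and the better strand wins.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    al = _aligner(scoring, "local")
    candidates = [("+", query)]
    if search_rc:
        candidates.append(("-", revcomp(query)))
    best = None
    for strand, q in candidates:
        alns = al.align(target, q)
        if len(alns) == 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best[0].score:
            best = (aln, strand, q)
    if best is None or best[0].score < min_score:
        return None
    res = _result_from_alignment(best[0], target, best[2], "local")
    res.strand = best[1]
    return res


_CIGAR_OP = {"=": "match", "X": "mismatch", "I": "insertion",
             "D": "deletion"}


def edit_align(ref: str, query: str) -> AlignmentResult:
    """End-to-end unit-cost (edit-distance) alignment via edlib.

    The workhorse for whole-amplicon read classification, where
    thousands of near-identical kilobase-scale pairs make quadratic
    affine DP needlessly slow; ``score`` is the negated edit distance.
    Op conventions match :func:`global_align`.
    """
    if not ref or not query:
        raise ValueError("edit_align requires non-empty sequences")
    r = edlib.align(query, ref, task="path", mode="NW")
    ops = [( _CIGAR_OP[m[1]], int(m[0]))
           for m in re.findall(r"(\d+)([=XID])", r["cigar"])]
    merged: list = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    n_cols = sum(n for _, n in merged)
    n_match = sum(n for op, n in merged if op == "match")
    return AlignmentResult(score=-float(r["editDistance"]),
                           identity=n_match / n_cols if n_cols else 0.0,
                           op_list=merged, ref_interval=(0, len(ref)),
                           query_interval=(0, len(query)))


def prefix_align(ref: str, query: str,
                 scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Align the full query against a prefix of the reference.

    Anchored on the left (both sequences start together, as primer-anchored
    reads do); the reference may extend past the query on the right at no
    cost.  Used to place a trimmed junction read on an expected amplicon.
    """
    if not ref or not query:
        raise ValueError("prefix_align requires non-empty sequences")
    al = _aligner(scoring, "global")
    # reference tail beyond the query is free (gap in the query at the
    # right end of the alignment)
    if hasattr(al, "open_right_deletion_score"):
        al.open_right_deletion_score = 0.0
        al.extend_right_deletion_score = 0.0
    else:  # pragma: no cover - older Biopython naming
        al.query_right_open_gap_score = 0.0
        al.query_right_extend_gap_score = 0.0
    aln = al.align(ref, query)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return AlignmentResult(float(aln.score), 0.0, [], (0, 0), (0, 0))
    ops = _ops_from_alignment(aln, ref, query)
    ref_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    query_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    if ref_iv[0]:
        ops.insert(0, ("deletion", ref_iv[0]))
    if query_iv[0]:
        ops.insert(0, ("insertion", query_iv[0]))
    if len(query) - query_iv[1]:
        ops.append(("insertion", len(query) - query_iv[1]))
    n_cols = sum(n for _, n in ops)
    n_match = sum(n for op, n in ops if op == "match")
    return AlignmentResult(score=float(aln.score),
                           identity=n_match / n_cols if n_cols else 0.0,
                           op_list=ops, ref_interval=(0, ref_iv[1]),
                           query_interval=(0, len(query)))


@dataclass(frozen=True)
class Placement:
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    score: float


@dataclass(frozen=True)
class MappingResult:
    status: str  # OK | TOO_SHORT | NO_HIT | AMBIGUOUS
    placement: Placement | None = None


def _contigs_of(genome) -> dict:
    return genome.contigs if hasattr(genome, "contigs") else genome


def _exact_hits(contig_seq: str, query: str):
    i = contig_seq.find(query)
    while i >= 0:
        yield i
        i = contig_seq.find(query, i + 1)


def _hamming_scan(contig: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Mismatch count of the query at every contig offset (vectorised)."""
    n, m = len(contig), len(query)
    if n < m:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mm += contig[j:n - m + 1 + j] != query[j]
    return mm


def best_genomic_hit(query: str, genome, min_length: int = 25,
                     max_mismatch: int = 0,
                     margin: float = 5.0) -> MappingResult:
    """Unique best placement of a read on the (mini-)genome.

    Scoring is match +1 / mismatch -4 with no gaps (end-to-end over the
    query).  Placements beyond ``max_mismatch`` substitutions are
    ignored; when the runner-up placement scores within ``margin`` of the
    best the read is reported AMBIGUOUS rather than placed.
    """
    if len(query) < min_length:
        return MappingResult("TOO_SHORT")
    contigs = _contigs_of(genome)
    L = len(query)
    hits: list[Placement] = []
    if max_mismatch == 0:
        for name, seq in contigs.items():
            for strand, q in (("+", query), ("-", revcomp(query))):
                for i in _exact_hits(seq, q):
                    hits.append(Placement(name, i, i + L, strand, 0, float(L)))
    else:
        for name, seq in contigs.items():
            carr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for strand, q in (("+", query), ("-", revcomp(query))):
                qarr = np.frombuffer(q.encode(), dtype=np.uint8)
                mm = _hamming_scan(carr, qarr)
                for i in np.nonzero(mm <= max_mismatch)[0]:
                    k = int(mm[i])
                    hits.append(Placement(name, int(i), int(i) + L, strand, k,
                                          float(L - 5 * k)))
    if not hits:
        return MappingResult("NO_HIT")
    hits.sort(key=lambda h: (-h.score, h.contig, h.start, h.strand))
    if len(hits) > 1 and hits[0].score - hits[1].score < margin:
        return MappingResult("AMBIGUOUS")
    return MappingResult("OK", hits[0])


@dataclass(frozen=True)
class MatchAnnotation:
    """Protospacer+PAM vs genomic site: mismatch marks and bulge."""

    mismatch_count: int
    bulge_count: int
    marks: str            # per protospacer+PAM position: . match, X mismatch,
    #                       - guide base skipped (RNA bulge)
    bulge_position: int = -1
    bulge_sequence: str = ""  # extra site bases (DNA bulge)


def _mark_hamming(ps: str, site: str) -> tuple[int, str]:
    marks = ["." if a == b and a != "N" else "X" for a, b in zip(ps, site)]
    return marks.count("X"), "".join(marks)


def guide_match_string(protospacer_pam: str, site_seq: str) -> MatchAnnotation:
    """Best substitution + (at most) one-bulge annotation of a site.

    The site may be up to 2 nt longer (DNA bulge: extra genomic bases) or
    shorter (RNA bulge: unpaired guide bases) than protospacer+PAM; the
    single bulge position minimising mismatches wins, leftmost on ties.
    """
    ps, site = protospacer_pam.upper(), site_seq.upper()
    d = len(site) - len(ps)
    if abs(d) > 2:
        raise ValueError("site length differs from protospacer+PAM by > 2 nt")
    if d == 0:
        mm, marks = _mark_hamming(ps, site)
        return MatchAnnotation(mm, 0, marks)
    best = None
    if d > 0:  # extra bases in the site
        for i in range(len(site) - d + 1):
            trimmed = site[:i] + site[i + d:]
            mm, marks = _mark_hamming(ps, trimmed)
            if best is None or mm < best[0]:
                best = (mm, marks, i, site[i:i + d])
        mm, marks, pos, extra = best
        return MatchAnnotation(mm, 1, marks, pos, extra)
    k = -d  # guide bases without a site partner
    for i in range(len(ps) - k + 1):
        trimmed = ps[:i] + ps[i + k:]
        mm, marks = _mark_hamming(trimmed, site)
        if best is None or mm < best[0]:
            best = (mm, marks[:i] + "-" * k + marks[i:], i)
    mm, marks, pos = best
    return MatchAnnotation(mm, 1, marks, pos, "")


def in_silico_digest(seq: str, recognition: str = "GTCGAC",
                     cut_offset: int = 1) -> list[str]:
    """Fragments of ``seq`` cut after ``cut_offset`` bases of each site.

    The default emulates Sal I (G^TCGAC).  Fragment concatenation always
    reproduces the input.
    """
    if not recognition:
        raise ValueError("recognition sequence must be non-empty")
    cuts = sorted({i + cut_offset for i in _exact_hits(seq, recognition)})
    frags, prev = [], 0
    for c in cuts:
        frags.append(seq[prev:c])
        prev = c
    frags.append(seq[prev:])
    return frags


def cut_positions(seq: str, recognition: str = "GTCGAC",
                  cut_offset: int = 1) -> list[int]:
    """Cut coordinates produced by :func:`in_silico_digest`."""
    return sorted({i + cut_offset for i in _exact_hits(seq, recognition)})
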