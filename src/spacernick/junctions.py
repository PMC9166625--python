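"""Tag-junction (GUIDE-seq / AAV-seq) integration-site calling.

Reads begin inside the integrated tag (dsODN or AAV ITR).  The caller
verifies the tag-primer suffix in either orientation, trims it, places
the adjacent genomic sequence on the genome under the perfect-mapped
contract, collapses PCR duplicates by their Tn5 shear point (the
protocol has no UMI), merges junction coordinates into sites, and
annotates each site against the design and the predicted off-target
list using the 5000-bp window rule.  GUIDE-seq and AAV-seq share this
code path; only the tag constant differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import best_genomic_hit
from .design import GenomicInterval, LocusDesign, OffTargetRecord
from .seqs import revcomp
from .simulate import TAG_SUFFIX_LEN


@dataclass(frozen=True)
class Junction:
    read_id: str
    genomic_seq: str
    orientation: str  # tag orientation: forward | reverse


@dataclass(frozen=True)
class PlacedJunction:
    read_id: str
    contig: str
    position: int      # tag-adjacent genomic coordinate
    shear: int         # fragment (Tn5) end coordinate
    strand: str
    orientation: str


@dataclass(frozen=True)
class Molecule:
    contig: str
    position: int
    shear: int
    strand: str
    orientation: str
    read_count: int


@dataclass
class IntegrationSiteCall:
    interval: GenomicInterval
    read_count: int
    unique_molecule_count: int
    orientation_counts: dict
    annotation: str = "NOVEL"   # ON_TARGET | KNOWN_OFF_TARGET | NOVEL
    matched_record: OffTargetRecord | None = None
    match_string: str = ""

    @property
    def position(self) -> int:
        return (self.interval.start + self.interval.end) // 2


def _prefix_mismatch(read: str, probe: str) -> int:
    if len(read) < len(probe):
        return len(probe)
    return sum(1 for a, b in zip(read, probe) if a != b)


def extract_junction(read: str, tag: str, min_genomic: int = 25,
                     max_mismatch: int = 1,
                     read_id: str = "") -> tuple:
    """Trim the tag-primer suffix off a read.

    Returns ``("OK", Junction)`` or ``(reason, None)`` with reason in
    {NO_TAG, TOO_SHORT}.  Both tag orientations are accepted (blunt-end
    ligation is orientation-agnostic); up to ``max_mismatch``
    substitutions are tolerated in the expected suffix.
    """
    probes = (("forward", tag[-TAG_SUFFIX_LEN:]),
              ("reverse", revcomp(tag)[-TAG_SUFFIX_LEN:]))
    for orientation, probe in probes:
        if _prefix_mismatch(read, probe) <= max_mismatch:
            genomic = read[len(probe):]
            if len(genomic) < min_genomic:
                return ("TOO_SHORT", None)
            return ("OK", Junction(read_id, genomic, orientation))
    return ("NO_TAG", None)


def map_junctions(junctions, genome, min_length: int = 25,
                  max_mismatch: int = 0, margin: float = 5.0):
    """Place trimmed junctions on the genome (perfect-mapped contract).

    Returns ``(placed, reject_counts)``.  The junction coordinate is the
    tag-adjacent end of the placement: the left edge on the plus strand,
    the right edge on the minus strand; the other end is the shear point.
    """
    placed: list[PlacedJunction] = []
    rejects: dict = {}
    for j in junctions:
        res = best_genomic_hit(j.genomic_seq, genome, min_length=min_length,
                               max_mismatch=max_mismatch, margin=margin)
        if res.status != "OK":
            rejects[res.status] = rejects.get(res.status, 0) + 1
            continue
        p = res.placement
        if p.strand == "+":
            pos, shear = p.start, p.end
        else:
            pos, shear = p.end, p.start
        placed.append(PlacedJunction(j.read_id, p.contig, pos, shear,
                                     p.strand, j.orientation))
    return placed, rejects


def dedupe_molecules(placed) -> list:
    """Collapse reads sharing (position, orientation, shear) into molecules."""
    groups: dict = {}
    for p in placed:
        key = (p.contig, p.position, p.shear, p.strand, p.orientation)
        groups[key] = groups.get(key, 0) + 1
    return [Molecule(c, pos, sh, st, o, n)
            for (c, pos, sh, st, o), n in sorted(groups.items())]


def aggregate_sites(molecules, merge_window: int = 25,
                    min_molecules: int = 2):
    """Single-linkage merge of junction coordinates into sites.

    Sites supported by fewer than ``min_molecules`` unique molecules are
    suppressed but returned separately, never silently dropped.
    """
    by_contig: dict = {}
    for m in molecules:
        by_contig.setdefault(m.contig, []).append(m)
    sites: list[IntegrationSiteCall] = []
    suppressed: list[IntegrationSiteCall] = []
    for contig in sorted(by_contig):
        ms = sorted(by_contig[contig], key=lambda m: m.position)
        cluster: list = []
        for m in ms + [None]:
            if m is not None and (not cluster or
                                  m.position - cluster[-1].position
                                  <= merge_window):
                cluster.append(m)
                continue
            if cluster:
                pos = [x.position for x in cluster]
                oc: dict = {"forward": 0, "reverse": 0}
                for x in cluster:
                    oc[x.orientation] += x.read_count
                site = IntegrationSiteCall(
                    interval=GenomicInterval(contig, min(pos), max(pos) + 1),
                    read_count=sum(x.read_count for x in cluster),
                    unique_molecule_count=len(cluster),
                    orientation_counts=oc)
                (sites if len(cluster) >= min_molecules
                 else suppressed).append(site)
            cluster = [m] if m is not None else []
    return sites, suppressed


def annotate_sites(sites, design: LocusDesign, off_targets,
                   window: int = 5000) -> list:
    """Label sites ON_TARGET / KNOWN_OFF_TARGET / NOVEL (5000-bp rule).

    A site within ``window`` of the design's nick interval is on-target;
    otherwise the nearest predicted record within ``window`` wins, ties
    broken by smaller mismatch count then leftmost coordinate.
    Annotation order is irrelevant: each site is labelled independently.
    """
    c = design.reference_window.contig
    nick_lo = min(design.nick_positions)
    nick_hi = max(design.nick_positions) + 1
    nick_iv = GenomicInterval(c, nick_lo, nick_hi)
    out = []
    for site in sites:
        pos = site.position
        if site.interval.contig == c and nick_iv.distance_to(pos) <= window:
            site.annotation = "ON_TARGET"
            site.match_string = "." * 23
            out.append(site)
            continue
        cands = []
        for rec in off_targets:
            if rec.interval.contig != site.interval.contig:
                continue
            d = rec.interval.distance_to(pos)
            if d <= window:
                cands.append((d, rec.mismatch_count, rec.interval.start, rec))
        if cands:
            cands.sort(key=lambda t: t[:3])
            rec = cands[0][3]
            site.annotation = "KNOWN_OFF_TARGET"
            site.matched_record = rec
            site.match_string = rec.match_string
        else:
            site.annotation = "NOVEL"
        out.append(site)
    return out


def call_integration_sites(reads, tag: str, genome, design: LocusDesign,
                           off_targets, min_genomic: int = 25,
                           merge_window: int = 25, min_molecules: int = 2,
                           annotation_window: int = 5000):
    """Full caller: trim, map, dedupe, aggregate, annotate.

    ``reads`` are (read_id, sequence) pairs.  Returns
    ``(sites, suppressed, rejects)`` where rejects counts reads removed
    at each stage.
    """
    junctions = []
    rejects: dict = {}
    for rid, seq in reads:
        status, j = extract_junction(seq, tag, min_genomic=min_genomic,
                                     read_id=rid)
        if status == "OK":
            junctions.append(j)
        else:
            rejects[status] = rejects.get(status, 0) + 1
    placed, map_rejects = map_junctions(junctions, genome)
    for k, v in map_rejects.items():
        rejects[k] = rejects.get(k, 0) + v
    molecules = dedupe_molecules(placed)
    sites, suppressed = aggregate_sites(molecules, merge_window=merge_window,
                                        min_molecules=min_molecules)
    annotate_sites(sites, design, off_targets, window=annotation_window)
    annotate_sites(suppressed, design, off_targets, window=annotation_window)
    return sites, suppressed, rejects


def sites_table(sites) -> pd.DataFrame:
    """Flat site table (one row per called site)."""
    rows = []
    for s in sites:
        rows.append({
            "contig": s.interval.contig, "start": s.interval.start,
            "end": s.interval.end, "position": s.position,
            "read_count": s.read_count,
            "unique_molecules": s.unique_molecule_count,
            "tag_forward": s.orientation_counts.get("forward", 0),
            "tag_reverse": s.orientation_counts.get("reverse", 0),
            "annotation": s.annotation,
            "matched_site": (f"{s.matched_record.interval.contig}:"
                             f"{s.matched_record.interval.start}"
                             if s.matched_record else ""),
            "mismatches": (s.matched_record.mismatch_count
                           if s.matched_record else 0),
            "match_string": s.match_string})
    return pd.DataFrame(rows)


def _site_key(row) -> str:
    if row["annotation"] == "KNOWN_OFF_TARGET" and row["matched_site"]:
        return f"OT:{row['matched_site']}"
    if row["annotation"] == "ON_TARGET":
        return "ON_TARGET"
    return f"NOVEL:{row['contig']}:{row['position'] // 1000}kb"


def compare_conditions(sites_a, sites_b) -> pd.DataFrame:
    """Per-site fold-change table between two conditions.

    Accepts site lists or :func:`sites_table` frames.  Sites are matched
    by annotation and matched locus; missing counterparts count 0 and
    the fold uses a pseudocount of 1 in the denominator (flagged).  Fold
    is on read counts, condition A over B.
    """
    frames = []
    for sites in (sites_a, sites_b):
        df = sites if isinstance(sites, pd.DataFrame) else sites_table(sites)
        frames.append(df)
    keyed = []
    for df in frames:
        d = {}
        for _, row in df.iterrows():
            d[_site_key(row)] = row
        keyed.append(d)
    ka, kb = keyed
    rows = []
    for k in sorted(set(ka) | set(kb)):
        ca = int(ka[k]["read_count"]) if k in ka else 0
        cb = int(kb[k]["read_count"]) if k in kb else 0
        flagged = cb == 0
        fold = ca / (cb if cb else 1)
        rows.append({"site": k, "reads_a": ca, "reads_b": cb,
                     "molecules_a": int(ka[k]["unique_molecules"])
                     if k in ka else 0,
                     "molecules_b": int(kb[k]["unique_molecules"])
                     if k in kb else 0,
                     "fold_a_over_b": fold, "denominator_zero": flagged})
    return pd.DataFrame(rows)
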