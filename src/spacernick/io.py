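"""Standard-format I/O: FASTA, FASTQ, BED6, commented TSV, design YAML.

Every table the pipeline writes is a TSV with ``# key=value`` provenance
header lines, re-parseable by :func:`read_tsv`.  Off-target predictions
travel as BED6 (name = guide id, score = mismatch count).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .design import (DonorTemplate, GenomicInterval, GuideSite, LocusDesign,
                     NickPair, OffTargetRecord)
from .simulate import QUAL_CHAR, TruthRecord


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, contigs: dict, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path, reads, qual_char: str = QUAL_CHAR) -> None:
    """Write (id, sequence) pairs as Phred+33 FASTQ, constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path) -> list:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# truth tables and BED


def write_truth(path, truths) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tclass\tdetail\n")
        for t in truths:
            fh.write(f"{t.read_id}\t{t.true_class}\t"
                     f"{json.dumps(t.detail, sort_keys=True)}\n")


def read_truth(path) -> list:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            rid, cls, detail = line.rstrip("\n").split("\t")
            out.append(TruthRecord(rid, cls, json.loads(detail)))
    return out


def write_offtarget_bed(path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{r.guide_id}\t"
                     f"{r.mismatch_count}\t{iv.strand}\n")


def read_offtarget_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(OffTargetRecord(
                GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                guide_id=f[3], mismatch_count=int(f[4])))
    return out


# ---------------------------------------------------------------------------
# commented TSV


def write_tsv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            k, _, v = line[2:].rstrip("\n").partition("=")
            meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# design configs


def design_to_dict(design: LocusDesign) -> dict:
    d: dict = {
        "name": design.name,
        "reference_window": _iv_to_dict(design.reference_window),
        "guides": [{"id": g.id, "contig": g.interval.contig,
                    "start": g.interval.start, "strand": g.strand}
                   for g in design.guides],
    }
    if design.donor is not None:
        don = design.donor
        d["donor"] = {
            "left_anchor": _iv_to_dict(don.left_anchor),
            "right_anchor": _iv_to_dict(don.right_anchor),
            "payload": don.payload,
            "diagnostic_variants": [list(v) for v in
                                    don.diagnostic_variants],
            "min_ha_length": don.min_ha_length,
        }
    if design.outer_primers is not None:
        d["outer_primers"] = list(design.outer_primers)
    if design.htgts_nested_primers:
        d["htgts_nested_primers"] = {k: list(v) for k, v in
                                     design.htgts_nested_primers.items()}
    return d


def design_from_dict(d: dict, genome) -> LocusDesign:
    guides = [GuideSite.from_genome(g["id"], g["contig"], g["start"],
                                    g["strand"], genome)
              for g in d["guides"]]
    pair = NickPair(*guides) if len(guides) == 2 else None
    guide = guides[0] if len(guides) == 1 else None
    donor = None
    if "donor" in d:
        don = d["donor"]
        la = _iv_from_dict(don["left_anchor"])
        ra = _iv_from_dict(don["right_anchor"])
        donor = DonorTemplate(
            left_ha=la.sequence(genome), left_anchor=la,
            payload=don["payload"],
            right_ha=ra.sequence(genome), right_anchor=ra,
            diagnostic_variants=tuple(tuple(v) for v in
                                      don["diagnostic_variants"]),
            min_ha_length=don.get("min_ha_length", 800))
    design = LocusDesign(
        name=d["name"],
        reference_window=_iv_from_dict(d["reference_window"]),
        pair=pair, guide=guide, donor=donor,
        outer_primers=tuple(d["outer_primers"])
        if "outer_primers" in d else None,
        htgts_nested_primers={k: tuple(v) for k, v in
                              d.get("htgts_nested_primers", {}).items()})
    design.validate(genome)
    return design


def _iv_to_dict(iv: GenomicInterval) -> dict:
    return {"contig": iv.contig, "start": iv.start, "end": iv.end,
            "strand": iv.strand}


def _iv_from_dict(d: dict) -> GenomicInterval:
    return GenomicInterval(d["contig"], d["start"], d["end"],
                           d.get("strand", "+"))


def save_design(path, design: LocusDesign) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def load_design(path, genome) -> LocusDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh), genome)


# ---------------------------------------------------------------------------
# run manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config: dict, seed, inputs=()) -> Path:
    from . import __version__
    outdir = Path(outdir)
    manifest = {
        "seed": seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
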