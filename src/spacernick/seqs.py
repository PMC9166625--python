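"""Small DNA helpers and the fixed tag constants used across assays.

The dsODN is the canonical 34-nt blunt double-stranded tag captured at
double-strand breaks in GUIDE-seq libraries.  The ITR constant is a
synthetic 130-nt stand-in for an AAV inverted terminal repeat: only its
length and detectability by local alignment matter to the pipeline, and
both constants are configurable wherever they are consumed.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: 34-nt blunt dsODN tag integrated at DSBs (GUIDE-seq).
DSODN_TAG = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"

#: Synthetic 130-nt AAV ITR stand-in (GC-rich, partially palindromic).
SYNTHETIC_ITR = (
    "TTGGCCACTCCCTCTCTGCGCGCTCGCTCGCTCACTGAGGCCGGGCGACCAAAGGTCGCCC"
    "GACGCCCGGGCTTTGCCCGGGCGGCCTCAGTGAGCGAGCGAGCGCGCAGAGAGGGAGTGGCCAACTCC"
)

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(rng.choice(list(BASES), size=length))


def scrub_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Remove every occurrence of ``motif`` (both strands) by point changes.

    Used by the simulator so that a diagnostic restriction site planted in
    a donor payload is unique within the locus.
    """
    targets = {motif, revcomp(motif)}
    out = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(out)
        for m in targets:
            i = s.find(m)
            if i >= 0:
                j = i + len(m) // 2
                old = out[j]
                choices = [b for b in BASES if b != old]
                out[j] = choices[int(rng.integers(len(choices)))]
                changed = True
                break
    return "".join(out)


def mutate_positions(seq: str, rng: np.random.Generator, n: int,
                     positions=None) -> tuple[str, list[tuple[int, str, str]]]:
    """Substitute ``n`` distinct positions; return new seq and (pos, ref, alt)."""
    if positions is None:
        positions = sorted(rng.choice(len(seq), size=n, replace=False).tolist())
    out = list(seq)
    muts = []
    for p in positions:
        ref = out[p]
        choices = [b for b in BASES if b != ref]
        alt = choices[int(rng.integers(len(choices)))]
        out[p] = alt
        muts.append((int(p), ref, alt))
    return "".join(out), muts


def add_sequencing_errors(seq: str, rng: np.random.Generator,
                          error_rate: float) -> str:
    """Inject iid substitution errors at the given per-base rate."""
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N counts as mismatch."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")
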