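"""Error-correcting demultiplexing and barcode-to-mutant mapping.

Reads carry a 9-nt sample index (from a codebook with pairwise Hamming
distance >= 3, so any single substitution is uniquely correctable) followed by
the uptag barcode between the universal flanks U1 and U2.  Sample assignment
corrects up to one substitution in the index; mutant assignment tolerates one
edit (substitution, insertion or deletion) in the barcode, with ambiguous
distance-1 hits dropped rather than guessed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import edlib
import numpy as np
import pandas as pd

from .synthetic import U1, U2

UNASSIGNED = "UNASSIGNED"
UNMAPPED = "UNMAPPED"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_codebook(codebook: dict[str, str], length: int = 9) -> None:
    """Check single-error-correction is well defined (min distance >= 3)."""
    idx = list(codebook)
    for c in idx:
        if len(c) != length or set(c) - set("ACGT"):
            raise ValueError(f"bad index {c!r}")
    for i, a in enumerate(idx):
        for b in idx[i + 1:]:
            if hamming(a, b) < 3:
                raise ValueError(f"indices {a} and {b} at Hamming distance < 3")


def decode_index(observed: str, codebook: dict[str, str]) -> str:
    """Sample of the unique codeword at Hamming distance <= 1, else UNASSIGNED."""
    hit = codebook.get(observed)
    if hit is not None:
        return hit
    if len(observed) != len(next(iter(codebook))):
        return UNASSIGNED
    best = None
    for code, sid in codebook.items():
        if hamming(observed, code) <= 1:
            if best is not None:      # two codewords within distance 1 would
                return UNASSIGNED     # violate the codebook contract; be safe
            best = sid
    return best if best is not None else UNASSIGNED


@dataclass
class BarcodeLibrary:
    """mutant_id -> uptag, plus the universal flanks."""

    barcodes: dict[str, str]
    u1: str = U1
    u2: str = U2

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("empty barcode library")
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        self._by_seq = {v: k for k, v in self.barcodes.items()}

    def exact(self, seq: str) -> str | None:
        return self._by_seq.get(seq)


def _find_flank(read: str, flank: str, max_mm: int = 1) -> int | None:
    """Start position of the best flank match with <= max_mm substitutions."""
    pos = read.find(flank)
    if pos >= 0:
        return pos
    best_pos, best_mm = None, max_mm + 1
    for i in range(0, len(read) - len(flank) + 1):
        mm = hamming(read[i:i + len(flank)], flank)
        if mm < best_mm:
            best_pos, best_mm = i, mm
    return best_pos if best_mm <= max_mm else None


def extract_barcode(read_tail: str, library: BarcodeLibrary) -> str | None:
    """Sequence between U1 and U2 in the read (after the index), flanks
    matched with <= 1 mismatch each; None if the flanks cannot be located."""
    p1 = _find_flank(read_tail, library.u1)
    if p1 is None:
        return None
    start = p1 + len(library.u1)
    p2_rel = _find_flank(read_tail[start:], library.u2)
    if p2_rel is None:
        return None
    return read_tail[start:start + p2_rel]


def map_barcode(observed: str, library: BarcodeLibrary) -> str:
    """Mutant of the unique barcode within edit distance 1, else UNMAPPED.

    Exact hits win outright; otherwise all barcodes at Levenshtein distance 1
    are collected and an ambiguous (>= 2 candidates) result is dropped.
    """
    hit = library.exact(observed)
    if hit is not None:
        return hit
    candidates = []
    for mid, bc in library.barcodes.items():
        d = edlib.align(observed, bc, k=1)["editDistance"]
        if d == 1:
            candidates.append(mid)
            if len(candidates) > 1:
                return UNMAPPED
    return candidates[0] if len(candidates) == 1 else UNMAPPED


@dataclass
class DemuxReport:
    total: int = 0
    assigned: int = 0
    unassigned_index: int = 0
    unmapped_barcode: int = 0
    flank_not_found: int = 0
    skipped_records: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses_asdict(self), indent=2)


def dataclasses_asdict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def iter_fastq(source) -> Iterator[tuple[str, str]]:
    """(title, sequence) pairs from a FASTQ path/handle (plain or gzip)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    if hasattr(source, "read"):
        for title, seq, _q in FastqGeneralIterator(source):
            yield title, seq
        return
    import gzip

    opener = gzip.open if str(source).endswith(".gz") else open
    with opener(source, "rt") as fh:
        for title, seq, _q in FastqGeneralIterator(fh):
            yield title, seq


def build_counts(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    codebook: dict[str, str],
    library: BarcodeLibrary,
    index_length: int = 9,
) -> tuple[pd.DataFrame, DemuxReport]:
    """Assign each read to (mutant, sample) and tally the count table.

    ``reads`` may be (title, seq) pairs (from :func:`iter_fastq`) or bare
    sequences.  Unassignable reads are tallied in the report; conservation
    ``assigned + unassigned + unmapped = total`` always holds (flank failures
    count as unmapped-barcode, broken out separately).
    """
    report = DemuxReport()
    samples = sorted(set(codebook.values()))
    mutants = list(library.barcodes)
    counts = pd.DataFrame(
        np.zeros((len(mutants), len(samples)), dtype=np.int64),
        index=pd.Index(mutants, name="mutant_id"),
        columns=samples,
    )
    mat = counts.values
    m_pos = {m: i for i, m in enumerate(mutants)}
    s_pos = {s: j for j, s in enumerate(samples)}
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        if not seq or not isinstance(seq, str):
            report.skipped_records += 1
            continue
        report.total += 1
        sid = decode_index(seq[:index_length], codebook)
        if sid == UNASSIGNED:
            report.unassigned_index += 1
            continue
        bc = extract_barcode(seq[index_length:], library)
        if bc is None:
            report.flank_not_found += 1
            report.unmapped_barcode += 1
            continue
        mid = map_barcode(bc, library)
        if mid == UNMAPPED:
            report.unmapped_barcode += 1
            continue
        mat[m_pos[mid], s_pos[sid]] += 1
        report.assigned += 1
    return counts, report
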