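"""Read preparation: exact dual-barcode demultiplexing, trimming, Q30 filter, dedup.

Demultiplexing is strict: a read is assigned to a sample only when both the
forward barcode (read prefix) and the reverse barcode (reverse complement of
the read suffix) match a catalog entry exactly — no mismatches tolerated.
Read-level quality is the mean per-base error probability converted back to
the Phred scale; reads below Q30 are rejected ("no less than Q30" keeps an
exactly-Q30 read). Deduplication collapses byte-identical inserts within a
sample, keeping the highest-quality read (ties break to the smallest id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import revcomp


@dataclass
class BarcodedRead:
    read_id: str
    sequence: str
    qualities: np.ndarray  # phred ints
    fwd_observed: str = ""
    rev_observed: str = ""

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str  # insert after flank removal
    qualities: np.ndarray
    read_quality: float


@dataclass
class SampleBin:
    sample_id: str
    fwd_barcode: str
    rev_barcode: str
    reads: List[TrimmedRead] = field(default_factory=list)
    assigned: int = 0
    q30_failed: int = 0
    duplicates_removed: int = 0


@dataclass
class DemuxResult:
    bins: Dict[str, SampleBin]
    unassigned: List[Tuple[BarcodedRead, str]]  # (read, reason)
    total: int = 0


def read_quality(qualities: np.ndarray) -> float:
    """Read-level quality: mean per-base error probability on the Phred scale."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        return 0.0
    mean_err = np.mean(10.0 ** (-q / 10.0))
    return float(-10.0 * np.log10(mean_err))


def demultiplex(
    reads: Sequence[BarcodedRead],
    forward_barcodes: Sequence[str],
    reverse_barcodes: Sequence[str],
    sample_sheet: Dict[Tuple[str, str], str],
    allow_revcomp_rescue: bool = False,
) -> DemuxResult:
    """Assign reads to sample bins by exact dual-barcode match.

    ``sample_sheet`` maps (fwd, rev) barcode pairs to sample ids; the
    combination space is |forward| x |reverse|. Unassigned reads are retained
    with a reason. Duplicate barcodes within a set raise.
    """
    for name, cat in (("forward", forward_barcodes), ("reverse", reverse_barcodes)):
        if len(set(cat)) != len(cat):
            raise ValueError(f"duplicate {name} barcode in catalog")
    fset, rset = set(forward_barcodes), set(reverse_barcodes)
    flen = {len(b) for b in forward_barcodes}
    rlen = {len(b) for b in reverse_barcodes}
    if len(flen) != 1 or len(rlen) != 1:
        raise ValueError("barcodes within a set must share one length")
    flen, rlen = flen.pop(), rlen.pop()

    bins = {
        sid: SampleBin(sid, f, r) for (f, r), sid in sample_sheet.items()
    }
    unassigned: List[Tuple[BarcodedRead, str]] = []

    def observe(read: BarcodedRead) -> Tuple[str, str]:
        return read.sequence[:flen], revcomp(read.sequence[-rlen:])

    for read in reads:
        fwd, rev = observe(read)
        if allow_revcomp_rescue and (fwd not in fset or rev not in rset):
            flipped = BarcodedRead(
                read.read_id, revcomp(read.sequence), read.qualities[::-1]
            )
            f2, r2 = observe(flipped)
            if f2 in fset and r2 in rset:
                read, (fwd, rev) = flipped, (f2, r2)
        read.fwd_observed, read.rev_observed = fwd, rev
        if fwd not in fset or rev not in rset:
            unassigned.append((read, "barcode_mismatch"))
            continue
        sid = sample_sheet.get((fwd, rev))
        if sid is None:
            unassigned.append((read, "pair_not_in_sheet"))
            continue
        bins[sid].assigned += 1
        bins[sid].reads.append(
            TrimmedRead(
                read.read_id,
                read.sequence,
                read.qualities,
                read_quality(read.qualities),
            )
        )
    return DemuxResult(bins=bins, unassigned=unassigned, total=len(reads))


def trim_and_filter(
    read: TrimmedRead,
    adapter_spec: Tuple[str, str],
    min_read_quality: float = 30.0,
) -> Tuple[Optional[TrimmedRead], Optional[str]]:
    """Strip flanking adapter/barcode sequences and apply the read-quality gate.

    Returns (trimmed read, None) or (None, rejection reason). A flank longer
    than the read rejects the read rather than raising.
    """
    left, right = adapter_spec
    seq, qual = read.sequence, read.qualities
    if len(left) + len(right) >= len(seq):
        return None, "adapter_longer_than_read"
    if left and seq.startswith(left):
        seq, qual = seq[len(left) :], qual[len(left) :]
    if right and seq.endswith(right):
        seq, qual = seq[: len(seq) - len(right)], qual[: len(qual) - len(right)]
    q = read_quality(qual)
    if q < min_read_quality:
        return None, "below_q30"
    return TrimmedRead(read.read_id, seq, qual, q), None


def trim_bin(
    bin_: SampleBin, min_read_quality: float = 30.0
) -> SampleBin:
    """Trim every read in a bin using its own barcode pair as flanks."""
    flanks = (bin_.fwd_barcode, revcomp(bin_.rev_barcode))
    kept: List[TrimmedRead] = []
    for read in bin_.reads:
        trimmed, reason = trim_and_filter(read, flanks, min_read_quality)
        if trimmed is None:
            bin_.q30_failed += 1
        else:
            kept.append(trimmed)
    bin_.reads = kept
    return bin_


def deduplicate(bin_: SampleBin) -> SampleBin:
    """Collapse reads with identical insert sequence to one representative.

    The survivor is the highest-quality read; ties break to the
    lexicographically smallest read id. Idempotent.
    """
    best: Dict[str, TrimmedRead] = {}
    for read in bin_.reads:
        cur = best.get(read.sequence)
        if cur is None or read.read_quality > cur.read_quality or (
            read.read_quality == cur.read_quality and read.read_id < cur.read_id
        ):
            best[read.sequence] = read
    removed = len(bin_.reads) - len(best)
    bin_.duplicates_removed += removed
    # preserve input order of survivors
    survivors = {id(r) for r in best.values()}
    bin_.reads = [r for r in bin_.reads if id(r) in survivors]
    return bin_
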