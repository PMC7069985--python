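"""Conversion-aware global alignment of bisulfite reads to amplicon references.

Because the amplicons are pre-defined, each read is aligned globally
(Needleman-Wunsch with affine gaps, Gotoh recursion) to its known reference
rather than mapped to a genome. The scoring is bisulfite-aware and run twice:
under the OT model a reference C matched by a read C *or T* scores as a
match (conversion-consistent), under the OB model a reference G is matched
by read G *or A*. The higher-scoring strand wins; this doubles as the
bisulfite-strand inference.

Scoring defaults (fixed for bit-for-bit reproducibility): match +2,
conversion-consistent pair +2, mismatch -3; opening a gap costs
gap_open + gap_extend (-7), each further gapped base gap_extend (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .core import AmpliconReference, CytosineSite, Marker
from .markers import resolve_marker

MATCH = 2
MISMATCH = -3
GAP_OPEN = -6
GAP_EXTEND = -1
MIN_IDENTITY = 0.9
MIN_READ_LENGTH = 50

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

CONVERTED = "converted"
UNCONVERTED = "unconverted"
MISMATCH_STATE = "mismatch"
MISSING = "missing"


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq], dtype=np.int8)


@njit(cache=True)
def _affine_nw(ref, read, ot, match, mismatch, gap_open, gap_extend):
    """Gotoh global alignment; returns (score, ref_idx, read_idx) arrays.

    ot selects the conversion model: 1 -> ref C vs read T is a match,
    0 -> ref G vs read A is a match. Gap arrays use -1 for a gap.
    """
    n, m = ref.shape[0], read.shape[0]
    NEG = -10**9
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in read (ref consumed)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in ref (read consumed)
    # pointers: 0 from M, 1 from X, 2 from Y
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * j
        pY[0, j] = 2
    for i in range(1, n + 1):
        rb = ref[i - 1]
        for j in range(1, m + 1):
            qb = read[j - 1]
            if rb == qb:
                s = match
            elif ot == 1 and rb == 1 and qb == 3:  # ref C / read T
                s = match
            elif ot == 0 and rb == 2 and qb == 0:  # ref G / read A
                s = match
            else:
                s = mismatch
            # M
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: consume ref base, gap in read
            open_x = M[i - 1, j] + gap_open + gap_extend
            ext_x = X[i - 1, j] + gap_extend
            if open_x >= ext_x:
                X[i, j] = open_x
                pX[i, j] = 0
            else:
                X[i, j] = ext_x
                pX[i, j] = 1
            # Y: consume read base, gap in ref
            open_y = M[i, j - 1] + gap_open + gap_extend
            ext_y = Y[i, j - 1] + gap_extend
            if open_y >= ext_y:
                Y[i, j] = open_y
                pY[i, j] = 0
            else:
                Y[i, j] = ext_y
                pY[i, j] = 2
    # traceback from the best of the three end states
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    ref_idx = np.empty(n + m, dtype=np.int32)
    read_idx = np.empty(n + m, dtype=np.int32)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            nxt = pM[i, j]
            ref_idx[k] = i - 1
            read_idx[k] = j - 1
            i -= 1
            j -= 1
            state = nxt
        elif state == 1:
            nxt = pX[i, j]
            ref_idx[k] = i - 1
            read_idx[k] = -1
            i -= 1
            state = nxt
        else:
            nxt = pY[i, j]
            ref_idx[k] = -1
            read_idx[k] = j - 1
            j -= 1
            state = nxt
        k += 1
    return score, ref_idx[:k][::-1].copy(), read_idx[:k][::-1].copy()


@dataclass
class AlignedMolecule:
    """One read's alignment, conversion states and marker observations."""

    read_id: str
    amplicon_id: str
    bs_strand: str  # OT | OB
    score: int
    identity: float
    read_sequence: str
    ref_cols: np.ndarray  # aligned ref offsets (-1 = gap)
    read_cols: np.ndarray  # aligned read offsets (-1 = gap)
    subject_id: str = ""
    site_states: Dict[str, str] = field(default_factory=dict)
    marker_obs: Dict[str, str] = field(default_factory=dict)
    unconverted_cph_fraction: Optional[float] = None
    no_cph_covered: bool = False
    rejected_reason: Optional[str] = None

    @property
    def rejected(self) -> bool:
        return self.rejected_reason is not None


def align_read(
    read_id: str,
    sequence: str,
    amplicon: AmpliconReference,
    min_identity: float = MIN_IDENTITY,
    min_length: int = MIN_READ_LENGTH,
) -> AlignedMolecule:
    """Align one read under both conversion models and keep the better strand."""
    if len(sequence) < min_length:
        return AlignedMolecule(
            read_id, amplicon.amplicon_id, "OT", 0, 0.0, sequence,
            np.empty(0, np.int32), np.empty(0, np.int32),
            rejected_reason="read_too_short",
        )
    ref = encode(amplicon.sequence)
    qry = encode(sequence)
    s_ot, r_ot, q_ot = _affine_nw(ref, qry, 1, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    s_ob, r_ob, q_ob = _affine_nw(ref, qry, 0, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    if s_ot >= s_ob:  # tie breaks to OT
        strand, score, rcols, qcols = "OT", int(s_ot), r_ot, q_ot
    else:
        strand, score, rcols, qcols = "OB", int(s_ob), r_ob, q_ob
    identity = _identity(ref, qry, rcols, qcols, strand)
    mol = AlignedMolecule(
        read_id, amplicon.amplicon_id, strand, score, identity, sequence,
        rcols, qcols,
    )
    if identity < min_identity:
        mol.rejected_reason = "low_identity"
    return mol


def _identity(ref, qry, rcols, qcols, strand) -> float:
    if len(rcols) == 0:
        return 0.0
    matches = 0
    for r, q in zip(rcols, qcols):
        if r < 0 or q < 0:
            continue
        rb, qb = ref[r], qry[q]
        if rb == qb:
            matches += 1
        elif strand == "OT" and rb == 1 and qb == 3:
            matches += 1
        elif strand == "OB" and rb == 2 and qb == 0:
            matches += 1
    return matches / len(rcols)


def extract_states(
    aligned: AlignedMolecule,
    amplicon: AmpliconReference,
    sites: Sequence[CytosineSite],
    markers: Sequence[Marker],
) -> AlignedMolecule:
    """Fill per-site conversion states and per-marker allele observations.

    A plus-strand cytosine is informative on OT reads only (read C ->
    unconverted, T -> converted, anything else -> mismatch); minus-strand
    cytosines symmetrically on OB reads (G / A). Sites on the non-informative
    strand are "missing". Marker windows include one anchor base on each side
    so indel alleles resolve by length; conversion-confounded observations
    come back "ambiguous".
    """
    if aligned.rejected:
        raise ValueError(f"cannot extract states from rejected read {aligned.read_id}")
    n = len(amplicon.sequence)
    ref_to_read = np.full(n, -1, dtype=np.int64)
    for r, q in zip(aligned.ref_cols, aligned.read_cols):
        if r >= 0:
            ref_to_read[r] = q
    seq = aligned.read_sequence
    strand = aligned.bs_strand

    for site in sites:
        off = amplicon.offset(site.coord)
        informative = (site.strand == "+") == (strand == "OT")
        if not informative:
            aligned.site_states[site.site_id] = MISSING
            continue
        q = ref_to_read[off]
        if q < 0:
            aligned.site_states[site.site_id] = MISSING
            continue
        base = seq[q]
        if site.strand == "+":
            state = (
                UNCONVERTED if base == "C" else CONVERTED if base == "T" else MISMATCH_STATE
            )
        else:
            state = (
                UNCONVERTED if base == "G" else CONVERTED if base == "A" else MISMATCH_STATE
            )
        aligned.site_states[site.site_id] = state

    # effective ref position of every alignment column (insertions borrow the
    # previous consumed reference offset), for marker window collection
    eff_ref = np.empty(len(aligned.ref_cols), dtype=np.int64)
    last = -1
    for k, r in enumerate(aligned.ref_cols):
        if r >= 0:
            last = r
        eff_ref[k] = last

    for m in markers:
        lo = amplicon.offset(m.coord)
        w_lo, w_hi = lo - 1, lo + len(m.ref_allele)  # anchored window, inclusive
        if w_lo < 0 or w_hi >= n:
            aligned.marker_obs[m.marker_id] = "missing"
            continue
        if ref_to_read[w_lo] < 0 or ref_to_read[w_hi] < 0:
            aligned.marker_obs[m.marker_id] = "missing"
            continue
        chars: List[str] = []
        for k in range(len(aligned.ref_cols)):
            if w_lo <= eff_ref[k] <= w_hi:
                q = aligned.read_cols[k]
                if q >= 0:
                    chars.append(seq[q])
            elif eff_ref[k] > w_hi:
                break
        aligned.marker_obs[m.marker_id] = resolve_marker("".join(chars), m, strand)

    covered = [
        s for s in sites
        if s.context == "CpH" and aligned.site_states.get(s.site_id) in (CONVERTED, UNCONVERTED)
    ]
    if covered:
        unconv = sum(
            1 for s in covered if aligned.site_states[s.site_id] == UNCONVERTED
        )
        aligned.unconverted_cph_fraction = unconv / len(covered)
        aligned.no_cph_covered = False
    else:
        aligned.unconverted_cph_fraction = None
        aligned.no_cph_covered = True
    return aligned


def underconversion_filter(
    aligned: AlignedMolecule, threshold: float = 0.05
) -> bool:
    """Keep a molecule iff its unconverted-CpH fraction is strictly below
    the threshold (a molecule at exactly 5% is discarded). Molecules covering
    no CpH site are kept, flagged via ``no_cph_covered``."""
    if aligned.unconverted_cph_fraction is None:
        return True
    return aligned.unconverted_cph_fraction < threshold
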