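"""Core domain types: amplicon reference frame, cytosine sites, markers, haplotypes.

Coordinates follow the genomics convention used throughout the package:
genomic positions are 1-based inclusive (``chr14:104,060,285-104,060,422``
spans 138 bp); internal amplicon offsets are 0-based half-open. The helpers
:func:`AmpliconReference.offset` / :func:`AmpliconReference.coord` convert
between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def segment_length(start: int, end: int) -> int:
    """Inclusive length of a 1-based genomic interval.

    >>> segment_length(104_060_285, 104_060_422)
    138
    """
    if end < start:
        raise ValueError(f"end {end} precedes start {start}")
    return end - start + 1


def last5(coord: int) -> str:
    """Last five digits of a chromosome coordinate, zero-padded.

    Cytosine names embed these digits, e.g. coordinate 104,060,054 -> "60054".
    """
    return f"{coord % 100_000:05d}"


def site_name(context: str, serial: int, coord: int) -> str:
    """Canonical cytosine name: context + serial + "_" + last-5 coordinate digits.

    >>> site_name("CpG", 59, 104_029_024)
    'CpG59_29024'
    """
    return f"{context}{serial}_{last5(coord)}"


@dataclass(frozen=True)
class AmpliconReference:
    """A target amplicon: the fixed reference frame every read is interpreted in."""

    amplicon_id: str
    chrom: str
    start_coord: int  # 1-based genomic position of the first base
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty amplicon sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGT characters in amplicon: {sorted(bad)}")

    @property
    def end_coord(self) -> int:
        return self.start_coord + len(self.sequence) - 1

    def offset(self, coord: int) -> int:
        """0-based offset of a 1-based genomic coordinate within the amplicon."""
        if not (self.start_coord <= coord <= self.end_coord):
            raise ValueError(
                f"coordinate {coord} outside {self.amplicon_id} "
                f"({self.start_coord}-{self.end_coord})"
            )
        return coord - self.start_coord

    def coord(self, offset: int) -> int:
        if not (0 <= offset < len(self.sequence)):
            raise ValueError(f"offset {offset} outside amplicon")
        return self.start_coord + offset


@dataclass(frozen=True)
class Marker:
    """A genetic marker (SNP or short indel) used for read haplotyping.

    Alleles are given on the plus strand. A length difference between
    ``ref_allele`` and ``alt_allele`` encodes an indel; for those the shorter
    allele must be a prefix or suffix of the longer one.
    """

    marker_id: str
    coord: int  # 1-based position of the first ref_allele base
    ref_allele: str
    alt_allele: str
    creates_cpg: bool = False

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.marker_id}: identical alleles")
        if self.is_indel:
            a, b = sorted((self.ref_allele, self.alt_allele), key=len)
            if not (b.startswith(a) or b.endswith(a)):
                raise ValueError(
                    f"{self.marker_id}: indel alleles must nest as prefix/suffix"
                )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def alleles(self) -> Tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    def strand_ambiguity(self) -> Dict[str, bool]:
        """Which bisulfite read strands confound the two alleles.

        On OT reads unmethylated C appears as T, so a C/T SNP is unreadable
        there; on OB reads (emitted plus-stranded) template conversion shows
        as G->A, confounding G/A SNPs.
        """
        pair = set(self.alleles)
        return {"OT": pair == {"C", "T"}, "OB": pair == {"G", "A"}}


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine position on one strand of the amplicon.

    ``context_by_haplotype`` records whether the haplotype's local sequence
    keeps the cytosine in CpG context, shifts it to CpH, or removes it
    entirely ("absent", e.g. a C/T SNP on the alternative allele).
    ``maskable_by_haplotype`` flags haplotypes whose allele makes the
    methylation call indistinguishable from the genotype on the only
    informative strand (the classic CpG-SNP masking situation).
    """

    site_id: str
    coord: int
    strand: str  # '+' or '-'
    context: str  # reference-sequence context: 'CpG' or 'CpH'
    context_by_haplotype: Dict[str, str] = field(default_factory=dict)
    maskable_by_haplotype: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context not in ("CpG", "CpH"):
            raise ValueError(f"bad context {self.context!r}")


@dataclass
class HaplotypeCatalog:
    """Ordered marker list plus the haplotypes (allele vectors) they define."""

    markers: List[Marker]
    haplotypes: Dict[str, Tuple[str, ...]]
    risk_haplotype: str

    def __post_init__(self):
        n = len(self.markers)
        for name, vec in self.haplotypes.items():
            if len(vec) != n:
                raise ValueError(f"haplotype {name}: {len(vec)} alleles for {n} markers")
            for allele, m in zip(vec, self.markers):
                if allele not in m.alleles:
                    raise ValueError(
                        f"haplotype {name}: allele {allele!r} not in {m.marker_id}"
                    )
        if self.risk_haplotype not in self.haplotypes:
            raise ValueError(f"unknown risk haplotype {self.risk_haplotype!r}")

    @property
    def names(self) -> List[str]:
        return list(self.haplotypes)

    def allele_of(self, haplotype: str, marker_id: str) -> str:
        idx = [m.marker_id for m in self.markers].index(marker_id)
        return self.haplotypes[haplotype][idx]


@dataclass
class Subject:
    """Study participant with phenotype and (true or called) diplotype."""

    subject_id: str
    group: str  # 'case' | 'control'
    age: float
    sex: str  # 'F' | 'M'
    cognitive_T: float
    smoking: str  # 'yes' | 'no' | 'unknown'
    genotype: Tuple[str, str]  # unordered haplotype pair

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ValueError(f"bad group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"bad sex {self.sex!r}")


def sequence_context(seq: str, pos: int, strand: str) -> Optional[str]:
    """Cytosine context of ``seq[pos]`` on the given strand, or None if no C.

    Plus strand: seq[pos] must be 'C'; CpG iff the next base is 'G'.
    Minus strand: seq[pos] must be 'G' (a C on the bottom strand); CpG iff the
    preceding base is 'C' (the palindromic partner).
    """
    if strand == "+":
        if seq[pos] != "C":
            return None
        return "CpG" if pos + 1 < len(seq) and seq[pos + 1] == "G" else "CpH"
    if seq[pos] != "G":
        return None
    return "CpG" if pos > 0 and seq[pos - 1] == "C" else "CpH"


def haplotype_sequence(
    amplicon: AmpliconReference,
    catalog: HaplotypeCatalog,
    haplotype: str,
) -> Tuple[str, List[Optional[int]]]:
    """Apply a haplotype's alleles to the reference sequence.

    Returns the haplotype sequence and a per-reference-offset map to haplotype
    offsets (None where the reference base is deleted on this haplotype).
    Markers must not overlap.
    """
    seq = list(amplicon.sequence)
    # ref offset -> list of bases the ref base expands to (may be '' or multi)
    pieces = {i: b for i, b in enumerate(seq)}
    occupied: set = set()
    for m, allele in zip(catalog.markers, catalog.haplotypes[haplotype]):
        lo = amplicon.offset(m.coord)
        span = range(lo, lo + len(m.ref_allele))
        if occupied & set(span):
            raise ValueError(f"marker {m.marker_id} overlaps another marker")
        occupied |= set(span)
        ref = m.ref_allele
        if amplicon.sequence[lo : lo + len(ref)] != ref:
            raise ValueError(
                f"marker {m.marker_id}: reference disagrees with ref_allele at {m.coord}"
            )
        if allele == ref:
            continue
        if len(allele) == len(ref):
            for k, b in enumerate(allele):
                pieces[lo + k] = b
        elif len(allele) > len(ref):  # insertion relative to reference
            extra = len(allele) - len(ref)
            if allele.endswith(ref):  # inserted bases go before the ref span
                pieces[lo] = allele[:extra] + ref[0]
            elif allele.startswith(ref):
                last = lo + len(ref) - 1
                pieces[last] = ref[-1] + allele[len(ref) :]
            else:  # pragma: no cover - excluded by Marker validation
                raise ValueError(f"unsupported indel shape for {m.marker_id}")
        else:  # deletion relative to reference
            if ref.startswith(allele):
                for k in range(len(allele), len(ref)):
                    pieces[lo + k] = ""
            else:  # ref.endswith(allele)
                for k in range(len(ref) - len(allele)):
                    pieces[lo + k] = ""
    hap_chars: List[str] = []
    ref_to_hap: List[Optional[int]] = []
    for i in range(len(seq)):
        piece = pieces[i]
        if piece == "":
            ref_to_hap.append(None)
            continue
        # the ref base maps to the *last* char of its piece when bases are
        # inserted before it, and to the *first* when appended after it
        if len(piece) > 1 and piece.endswith(amplicon.sequence[i]):
            ref_to_hap.append(len(hap_chars) + len(piece) - 1)
        else:
            ref_to_hap.append(len(hap_chars))
        hap_chars.extend(piece)
    return "".join(hap_chars), ref_to_hap
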