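"""Conversion-aware marker allele resolution.

Bisulfite conversion rewrites the read alphabet: on OT reads every
unmethylated template C appears as T, on OB reads (emitted in plus
orientation) template conversion appears as G->A. Genotype calls from
converted reads must therefore use a truth table: a C/T SNP read as T on OT
is *ambiguous* (unmethylated C and the T allele are indistinguishable),
while the same SNP on an OB read resolves cleanly because the plus-strand
C/T difference lives on the unconverted base there.

These rules are shared by the alignment state extractor and the haplotyper.
"""

from __future__ import annotations

from typing import Optional

from .core import Marker

REF = "ref"
ALT = "alt"
AMBIGUOUS = "ambiguous"
MISSING = "missing"


def conversion_equal(expected: str, observed: str, bs_strand: str) -> bool:
    """Does an observed read string match an expected reference-like string,
    allowing the bisulfite substitutions of the given strand?"""
    if len(expected) != len(observed):
        return False
    for e, o in zip(expected, observed):
        if e == o:
            continue
        if bs_strand == "OT" and e == "C" and o == "T":
            continue
        if bs_strand == "OB" and e == "G" and o == "A":
            continue
        return False
    return True


def resolve_marker(observed: Optional[str], marker: Marker, bs_strand: str) -> str:
    """Resolve an observed read window over a marker to an allele call.

    ``observed`` is the read sequence aligned across the marker span,
    *including* one anchoring reference base on each side (so that indel
    alleles of different lengths produce windows of different lengths);
    ``None`` means the read did not cover the span.

    Returns one of ``"ref"``, ``"alt"``, ``"ambiguous"`` (both alleles are
    conversion-consistent with the observation) or ``"missing"``.
    """
    if bs_strand not in ("OT", "OB"):
        raise ValueError(f"bad bisulfite strand {bs_strand!r}")
    if observed is None:
        return MISSING
    hit_ref = conversion_equal(marker.ref_allele, strip_anchor(observed, marker, REF), bs_strand)
    hit_alt = conversion_equal(marker.alt_allele, strip_anchor(observed, marker, ALT), bs_strand)
    if hit_ref and hit_alt:
        return AMBIGUOUS
    if hit_ref:
        return REF
    if hit_alt:
        return ALT
    return MISSING


def strip_anchor(observed: str, marker: Marker, which: str) -> str:
    """Remove the two anchor bases from an observed window, if present.

    The expected window for allele a is anchor + a + anchor; an observed
    window shorter than that cannot match and is returned unchanged (it will
    fail the length check in :func:`conversion_equal`).
    """
    allele = marker.ref_allele if which == REF else marker.alt_allele
    if len(observed) == len(allele) + 2:
        return observed[1:-1]
    return observed


def resolve_base(observed: Optional[str], marker: Marker, bs_strand: str) -> str:
    """Single-base convenience wrapper for substitution SNPs.

    ``observed`` is the read base aligned to the marker coordinate (no
    anchors). Used where only a point observation is available.
    """
    if marker.is_indel:
        raise ValueError("resolve_base only applies to substitution markers")
    if observed is None:
        return MISSING
    hit_ref = conversion_equal(marker.ref_allele, observed, bs_strand)
    hit_alt = conversion_equal(marker.alt_allele, observed, bs_strand)
    if hit_ref and hit_alt:
        return AMBIGUOUS
    if hit_ref:
        return REF
    if hit_alt:
        return ALT
    return MISSING
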