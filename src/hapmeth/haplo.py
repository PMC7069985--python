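"""Per-read haplotype assignment and per-subject genotype calling.

Haplotypes are read directly off the bisulfite reads: each read's resolved
marker alleles (conversion-aware, see :mod:`hapmeth.markers`) are compared
with the catalog; the read is assigned only when exactly one haplotype is
compatible with every resolved allele and enough markers were informative.
A subject's genotype is the two best-supported haplotypes, analysable only
with >= 5 supporting reads per carried haplotype (optionally per bisulfite
strand).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import HaplotypeCatalog
from .markers import ALT, AMBIGUOUS, MISSING, REF, resolve_base, resolve_marker  # noqa: F401  (re-exported)

OK = "ok"
CONFLICT = "conflict"
INSUFFICIENT = "insufficient_markers"
MULTI = "multi_compatible"


@dataclass
class HaplotypeCall:
    read_id: str
    assigned: Optional[str]  # haplotype name or None
    reason: str
    informative_marker_count: int
    bs_strand: str = ""


@dataclass
class GenotypeCall:
    subject_id: str
    genotype: Optional[Tuple[str, str]]  # unordered pair, or None if uncalled
    analysable: bool
    homozygous: bool
    support: Dict[str, int] = field(default_factory=dict)
    strand_support: Dict[Tuple[str, str], int] = field(default_factory=dict)


def assign_haplotype(
    read_id: str,
    marker_obs: Dict[str, str],
    catalog: HaplotypeCatalog,
    min_informative: int = 2,
    bs_strand: str = "",
) -> HaplotypeCall:
    """Assign a read to the unique catalog haplotype compatible with its alleles.

    ``marker_obs`` maps marker_id -> {"ref", "alt", "ambiguous", "missing"}.
    Ambiguous and missing markers are uninformative; with two or more fully
    compatible haplotypes the read stays unassigned (multi_compatible), with
    none it is a conflict.
    """
    if not catalog.haplotypes:
        raise ValueError("empty haplotype catalog")
    resolved: Dict[str, str] = {}
    for m in catalog.markers:
        call = marker_obs.get(m.marker_id, MISSING)
        if call == REF:
            resolved[m.marker_id] = m.ref_allele
        elif call == ALT:
            resolved[m.marker_id] = m.alt_allele
    informative = len(resolved)
    if informative < min_informative:
        return HaplotypeCall(read_id, None, INSUFFICIENT, informative, bs_strand)
    compatible = [
        name
        for name, vec in catalog.haplotypes.items()
        if all(
            vec[i] == resolved[m.marker_id]
            for i, m in enumerate(catalog.markers)
            if m.marker_id in resolved
        )
    ]
    if len(compatible) == 1:
        return HaplotypeCall(read_id, compatible[0], OK, informative, bs_strand)
    if len(compatible) == 0:
        return HaplotypeCall(read_id, None, CONFLICT, informative, bs_strand)
    return HaplotypeCall(read_id, None, MULTI, informative, bs_strand)


def call_genotype(
    subject_id: str,
    calls: Sequence[HaplotypeCall],
    min_depth: int = 5,
    per_strand: bool = False,
    allow_homozygous: bool = True,
) -> GenotypeCall:
    """Call a subject's diplotype from its assigned reads.

    The two most-supported haplotypes form the genotype (ties break on
    haplotype name); a subject is analysable iff every carried haplotype has
    at least ``min_depth`` supporting reads, counted per bisulfite strand
    when ``per_strand`` is set. Invariant to read order.
    """
    support: Counter = Counter()
    strand_support: Counter = Counter()
    for c in calls:
        if c.assigned is None:
            continue
        support[c.assigned] += 1
        strand_support[(c.assigned, c.bs_strand or "?")] += 1
    if not support:
        return GenotypeCall(subject_id, None, False, False, {}, {})
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [h for h, _ in ranked[:2]]
    homozygous = len(top) == 1
    if homozygous:
        if not allow_homozygous:
            return GenotypeCall(
                subject_id, None, False, True, dict(support), dict(strand_support)
            )
        genotype = (top[0], top[0])
    else:
        genotype = tuple(sorted(top))  # type: ignore[assignment]
    carried = set(genotype)

    def depth_ok(h: str) -> bool:
        if per_strand:
            return all(
                strand_support.get((h, s), 0) >= min_depth for s in ("OT", "OB")
            )
        return support.get(h, 0) >= min_depth

    analysable = all(depth_ok(h) for h in carried)
    return GenotypeCall(
        subject_id,
        genotype,
        analysable,
        homozygous,
        dict(support),
        dict(strand_support),
    )
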