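"""Synthetic study generator: amplicons, cohorts, barcoded bisulfite reads, melt curves.

The generator emulates a targeted long-read bisulfite amplicon experiment:
~1 kb amplicons carrying SNP / indel / CpG-SNP markers that define 2-3
common haplotypes, per-haplotype single-cytosine methylation truth, dual
(8 forward x 12 reverse) barcoding, bisulfite conversion with per-molecule
failure, PCR duplication and substitution sequencing error. Every emitted
read is traceable to a molecule record in the :class:`TruthTable`, so
downstream modules can be tested for parameter recovery.

The packaged :func:`fr_apopt1_klc1_like` design mirrors the published
intron-enhancer fragment: three haplotypes (ADAGAGD, ADAGAGI and the risk
haplotype TIGACAI) over seven markers, with the per-haplotype methylation
truth of the twenty haplotype-specific cytosines shipped in
``data/asm_truth_profile.tsv``. Unlisted CpGs default to M = 0.90 and unlisted
CpHs to M = 0.004 (CpH methylation is rare and strand-specific).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AmpliconReference,
    CytosineSite,
    HaplotypeCatalog,
    Marker,
    Subject,
    haplotype_sequence,
    revcomp,
    sequence_context,
    site_name,
)
from .hrm import MeltCurve

DEFAULT_CPG_TRUTH = 0.90
DEFAULT_CPH_TRUTH = 0.004

# Dual-barcode catalog: 8 forward x 12 reverse = 96 combinations per run.
# Barcode sequences avoid C so they are inert to bisulfite conversion checks.
FORWARD_BARCODES = [
    "AGTGATGA", "TGAGTAGT", "GATAGGTT", "TTGAGGAT",
    "AGGATTGA", "GTTGATAG", "TAGGTGTA", "GGTATTGT",
]
REVERSE_BARCODES = [
    "ATGATGGA", "TGTAGAGT", "GAGTTAGA", "TTAGGTGT",
    "AGAGGTTA", "GTGATTGT", "TATGGAGA", "GGAGTATT",
    "ATTGGTAG", "TGGTTGAT", "GAATGTGG", "TTGTGAAG",
]

DEFAULT_PHENO = {
    "case_T": (38.66, 6.53),
    "control_T": (49.63, 5.04),
    "age": (27.0, 6.8),
    "age_range": (18.0, 45.0),
    "smoking_yes": {"case": 0.34, "control": 0.29},
    "smoking_unknown": 0.10,
}

DEFAULT_HAPLOTYPE_FREQS = {"ADAGAGD": 0.40, "TIGACAI": 0.30, "ADAGAGI": 0.30}


@dataclass
class SimParams:
    """Tunable rates of the read simulator (all probabilities)."""

    conversion_efficiency: float = 0.995
    molecule_failure_rate: float = 0.01
    sequencing_error_rate: float = 0.002
    duplication_rate: float = 0.1
    reads_per_subject: int = 40
    low_quality_read_fraction: float = 0.0
    base_quality: int = 40
    low_quality: int = 20
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "conversion_efficiency",
            "molecule_failure_rate",
            "sequencing_error_rate",
            "duplication_rate",
            "low_quality_read_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.reads_per_subject <= 0:
            raise ValueError("reads_per_subject must be positive")


@dataclass
class MoleculeRecord:
    read_id: str
    subject_id: str
    haplotype: str
    bs_strand: str
    states: Dict[str, bool]  # site_id -> methylated
    conversion_failed: bool
    duplicate_of: Optional[str] = None


@dataclass
class TruthTable:
    """Simulator ground truth: per-(haplotype, site) M plus per-molecule states."""

    meth: Dict[Tuple[str, str], float]  # (haplotype, site_id) -> true M
    molecules: List[MoleculeRecord] = field(default_factory=list)

    def __post_init__(self):
        for key, p in self.meth.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"truth M {p} outside [0,1] at {key}")

    def true_m(self, haplotype: str, site_id: str) -> float:
        return self.meth[(haplotype, site_id)]


@dataclass
class SimRead:
    read_id: str
    sequence: str
    qualities: np.ndarray  # phred ints, same length as sequence


# ---------------------------------------------------------------------------
# site catalog construction


def build_sites(
    amplicon: AmpliconReference, catalog: HaplotypeCatalog
) -> List[CytosineSite]:
    """Enumerate every cytosine on both strands, across all haplotypes.

    A site is listed if at least one haplotype (or the reference) carries a
    cytosine there; ``context_by_haplotype`` records CpG / CpH / "absent" per
    haplotype, and ``maskable_by_haplotype`` flags conversion-genotype
    confounds (a C/T SNP at the cytosine itself on its only informative
    strand).
    """
    haps = {}
    for name in catalog.names:
        haps[name] = haplotype_sequence(amplicon, catalog, name)
    markers_at = {amplicon.offset(m.coord): m for m in catalog.markers if not m.is_indel}

    entries = []  # (offset, strand, ref_context, ctx_by_hap, mask_by_hap)
    n = len(amplicon.sequence)
    for off in range(n):
        for strand in "+-":
            ref_ctx = sequence_context(amplicon.sequence, off, strand)
            ctx_by_hap: Dict[str, str] = {}
            for name, (hseq, ref2hap) in haps.items():
                hoff = ref2hap[off]
                ctx = (
                    sequence_context(hseq, hoff, strand)
                    if hoff is not None
                    else None
                )
                ctx_by_hap[name] = ctx if ctx is not None else "absent"
            if ref_ctx is None and all(c == "absent" for c in ctx_by_hap.values()):
                continue
            mask_by_hap: Dict[str, bool] = {}
            m = markers_at.get(off)
            for name in catalog.names:
                masked = False
                if ctx_by_hap[name] != "absent" and m is not None:
                    allele = catalog.allele_of(name, m.marker_id)
                    other = m.alt_allele if allele == m.ref_allele else m.ref_allele
                    # plus-strand C observed only on OT where unmethylated C
                    # reads T: a T alternative allele is indistinguishable.
                    if strand == "+" and allele == "C" and other == "T":
                        masked = True
                    if strand == "-" and allele == "G" and other == "A":
                        masked = True
                mask_by_hap[name] = masked
            entries.append((off, strand, ref_ctx, ctx_by_hap, mask_by_hap))

    sites: List[CytosineSite] = []
    serial = {"CpG": 0, "CpH": 0}
    for off, strand, ref_ctx, ctx_by_hap, mask_by_hap in entries:
        context = ref_ctx
        if context is None:  # variant-created cytosine: no reference context
            context = next(c for c in ctx_by_hap.values() if c != "absent")
        serial[context] += 1
        coord = amplicon.coord(off)
        sites.append(
            CytosineSite(
                site_id=site_name(context, serial[context], coord),
                coord=coord,
                strand=strand,
                context=context,
                context_by_haplotype=ctx_by_hap,
                maskable_by_haplotype=mask_by_hap,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# amplicon generators


def make_amplicon(
    length: int,
    cpg_density: float,
    marker_plan: Sequence[Tuple[str, int]],
    rng: np.random.Generator,
    amplicon_id: str = "amp1",
    chrom: str = "chr14",
    start_coord: int = 104_000_001,
    n_haplotypes: int = 3,
) -> Tuple[AmpliconReference, List[CytosineSite], HaplotypeCatalog]:
    """Generate a random amplicon with embedded markers and haplotype catalog.

    ``marker_plan`` lists (kind, count) with kind in {"SNP", "indel",
    "CpG-SNP"}. Marker positions are spaced >= 10 bp apart; collisions raise.
    """
    if length < 200:
        raise ValueError("amplicon length must be >= 200")
    if not 2 <= n_haplotypes <= 3:
        raise ValueError("2-3 haplotypes supported")
    seq = list(rng.choice(list("ACGT"), size=length, p=[0.30, 0.22, 0.22, 0.26]))
    n_cpg = max(1, round(cpg_density * length))
    cpg_pos = rng.choice(np.arange(10, length - 10, 4), size=n_cpg, replace=False)
    for p in cpg_pos:
        seq[p], seq[p + 1] = "C", "G"

    kinds: List[str] = []
    for kind, count in marker_plan:
        if kind not in ("SNP", "indel", "CpG-SNP"):
            raise ValueError(f"unknown marker kind {kind!r}")
        kinds.extend([kind] * count)
    rng.shuffle(kinds)

    markers: List[Marker] = []
    used: set = set()
    candidates = list(rng.permutation(np.arange(20, length - 20)))
    cpg_set = {int(p) for p in cpg_pos}

    def reserve(pos: int, span: int) -> bool:
        block = set(range(pos - 10, pos + span + 10))
        if block & used:
            return False
        used.update(range(pos, pos + span))
        used.update(range(pos - 10, pos + span + 10))
        return True

    serial = 0
    for kind in kinds:
        placed = False
        for pos in list(candidates):
            pos = int(pos)
            if kind == "CpG-SNP":
                # abolish an existing CpG by mutating its G
                if pos not in cpg_set:
                    continue
                gpos = pos + 1
                if not reserve(gpos, 1):
                    continue
                markers.append(
                    Marker(f"sim_rs{serial}", start_coord + gpos, "G", "A")
                )
            elif kind == "SNP":
                base = seq[pos]
                if base in "CG" or not reserve(pos, 1):
                    continue
                alt = "T" if base == "A" else "A"
                markers.append(Marker(f"sim_rs{serial}", start_coord + pos, base, alt))
            else:  # indel: CCG-style insertion after this base
                base = seq[pos]
                if not reserve(pos, 1):
                    continue
                markers.append(
                    Marker(
                        f"sim_rs{serial}",
                        start_coord + pos,
                        base,
                        base + "CCG",
                        creates_cpg=True,
                    )
                )
            serial += 1
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place {kind} marker without collision; "
                f"occupied positions near {sorted(used)[:5]}..."
            )

    markers.sort(key=lambda m: m.coord)
    reference = AmpliconReference(amplicon_id, chrom, start_coord, "".join(seq))

    n_markers = len(markers)
    vec_ref = tuple(m.ref_allele for m in markers)
    vec_alt = tuple(m.alt_allele for m in markers)
    haplotypes: Dict[str, Tuple[str, ...]] = {"hap_ref": vec_ref, "hap_risk": vec_alt}
    if n_haplotypes == 3 and n_markers >= 1:
        mixed = list(vec_ref)
        mixed[-1] = markers[-1].alt_allele
        haplotypes["hap_mid"] = tuple(mixed)
    catalog = HaplotypeCatalog(markers, haplotypes, risk_haplotype="hap_risk")
    sites = build_sites(reference, catalog)
    return reference, sites, catalog


FR_CHROM = "chr14"
FR_START = 104_060_001
FR_LENGTH = 900
_FR_SEED = 140_601  # fixed design constant: the packaged reference is frozen

_FR_MARKERS = [
    ("rs67899457", 104_060_030, "A", "T"),
    ("rs151151346", 104_060_368, "G", "A"),
    ("rs376515669", 104_060_379, "A", "G"),
    ("rs55798212", 104_060_385, "G", "AG"),
    ("rs12147174", 104_060_392, "G", "A"),
    ("rs147690804", 104_060_300, "A", "C"),
    ("rs143940337", 104_060_422, "A", "GA"),
]
# marker order as in the haplotype names (ADAGAGD etc.)
_FR_ORDER = [
    "rs67899457",
    "rs55798212",
    "rs376515669",
    "rs151151346",
    "rs147690804",
    "rs12147174",
    "rs143940337",
]
_FR_HAPLOTYPES = {
    "ADAGAGD": {"rs143940337": "ref"},  # all reference alleles
    "ADAGAGI": {},  # alt only at the trailing indel
    "TIGACAI": {},  # all alternative alleles (risk)
}

# fixed-base constraints: profiled cytosines and marker reference contexts
_FR_FIXED = {
    104_060_030: "A",
    104_060_054: "C", 104_060_055: "G",
    104_060_087: "C", 104_060_088: "G",
    104_060_156: "C", 104_060_157: "G",
    104_060_164: "C", 104_060_165: "G",
    104_060_226: "C", 104_060_227: "G",
    104_060_300: "A", 104_060_301: "T",
    104_060_367: "C", 104_060_368: "G",
    104_060_373: "C", 104_060_374: "T",
    104_060_378: "C", 104_060_379: "A",
    104_060_380: "C", 104_060_381: "C", 104_060_382: "A",
    104_060_384: "C", 104_060_385: "G", 104_060_386: "C", 104_060_387: "A",
    104_060_389: "C", 104_060_390: "C", 104_060_391: "C", 104_060_392: "G",
    104_060_421: "C", 104_060_422: "A", 104_060_423: "T",
    104_060_427: "C", 104_060_428: "G",
    104_060_464: "C", 104_060_465: "G",
    104_060_678: "C", 104_060_679: "G",
    104_060_845: "C", 104_060_846: "G",
}


def load_asm_truth_profile() -> pd.DataFrame:
    """Per-haplotype truth means for the twenty haplotype-specific cytosines."""
    ref = importlib.resources.files("hapmeth.data") / "asm_truth_profile.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def fr_apopt1_klc1_like() -> Tuple[
    AmpliconReference, List[CytosineSite], HaplotypeCatalog, TruthTable
]:
    """The packaged intron-enhancer amplicon design with its truth profile.

    Deterministic: the filler sequence comes from a frozen seed, all
    functional positions (markers, profiled cytosines) are pinned.
    """
    rng = np.random.default_rng(_FR_SEED)
    seq = list(rng.choice(list("ACGT"), size=FR_LENGTH, p=[0.30, 0.22, 0.22, 0.26]))
    for coord, base in _FR_FIXED.items():
        seq[coord - FR_START] = base
    # keep pinned CpH sites out of accidental CpG context and pinned
    # single-marker neighbourhoods clean of accidental extra cytosines
    for coord in (104_060_374, 104_060_382, 104_060_387, 104_060_423):
        off = coord - FR_START
        if seq[off] == "G":  # would turn the upstream pinned C into a CpG
            seq[off] = "T"
    reference = AmpliconReference("Fr_APOPT1_KLC1", FR_CHROM, FR_START, "".join(seq))

    by_id = {}
    for mid, coord, ref_a, alt_a in _FR_MARKERS:
        by_id[mid] = Marker(mid, coord, ref_a, alt_a, creates_cpg=mid in ("rs376515669", "rs143940337"))
    markers = [by_id[mid] for mid in sorted(by_id, key=lambda m: by_id[m].coord)]

    def vec(alleles: str) -> Tuple[str, ...]:
        # alleles: 'ref'/'alt' per marker in catalog (coordinate) order
        return tuple(
            m.ref_allele if a == "ref" else m.alt_allele
            for m, a in zip(markers, alleles)
        )

    order = {m.marker_id: i for i, m in enumerate(markers)}
    hapdefs = {
        "ADAGAGD": ["ref"] * len(markers),
        "ADAGAGI": ["ref"] * len(markers),
        "TIGACAI": ["alt"] * len(markers),
    }
    hapdefs["ADAGAGI"][order["rs143940337"]] = "alt"
    haplotypes = {name: vec(alleles) for name, alleles in hapdefs.items()}
    catalog = HaplotypeCatalog(markers, haplotypes, risk_haplotype="TIGACAI")

    sites = build_sites(reference, catalog)
    truth = build_truth(sites, catalog, load_asm_truth_profile())
    return reference, sites, catalog, truth


def build_truth(
    sites: Sequence[CytosineSite],
    catalog: HaplotypeCatalog,
    profile: Optional[pd.DataFrame] = None,
    default_cpg: float = DEFAULT_CPG_TRUTH,
    default_cph: float = DEFAULT_CPH_TRUTH,
) -> TruthTable:
    """Assemble the (haplotype, site) -> true M table.

    ``profile`` rows pin plus-strand cytosines by coordinate; the minus-strand
    CpG partner of a pinned CpG inherits the same value (CpG methylation is
    symmetric), while CpH methylation stays strand-specific at the default.
    """
    pinned: Dict[int, Dict[str, float]] = {}
    if profile is not None:
        for _, row in profile.iterrows():
            pinned[int(row["coord"])] = {
                h: float(row[h]) for h in catalog.names if h in row
            }
    meth: Dict[Tuple[str, str], float] = {}
    for site in sites:
        for hap in catalog.names:
            ctx = site.context_by_haplotype.get(hap, "absent")
            if ctx == "absent":
                continue
            if site.strand == "+" and site.coord in pinned:
                value = pinned[site.coord][hap]
            elif site.strand == "-" and (site.coord - 1) in pinned and ctx == "CpG":
                value = pinned[site.coord - 1][hap]
            else:
                value = default_cpg if ctx == "CpG" else default_cph
            meth[(hap, site.site_id)] = value
    return TruthTable(meth=meth)


# ---------------------------------------------------------------------------
# cohort


def make_cohort(
    n_cases: int,
    n_controls: int,
    haplotype_freqs: Dict[str, float],
    pheno_params: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Subject]:
    """Draw a case/control cohort with Hardy-Weinberg genotypes.

    Cognitive T-scores default to Normal(38.66, 6.53) for cases and
    Normal(49.63, 5.04) for controls; age and sex are balanced across groups.
    """
    if n_cases < 0 or n_controls < 0 or n_cases + n_controls == 0:
        raise ValueError("need a positive number of subjects")
    total = sum(haplotype_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {total}, not 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    pheno = dict(DEFAULT_PHENO)
    if pheno_params:
        pheno.update(pheno_params)
    names = list(haplotype_freqs)
    freqs = np.array([haplotype_freqs[h] for h in names])
    subjects: List[Subject] = []
    counter = 0
    for group, n in (("case", n_cases), ("control", n_controls)):
        mu, sd = pheno["case_T"] if group == "case" else pheno["control_T"]
        for _ in range(n):
            counter += 1
            h1, h2 = rng.choice(names, size=2, p=freqs)
            age = float(
                np.clip(rng.normal(*pheno["age"]), *pheno["age_range"])
            )
            if rng.random() < pheno["smoking_unknown"]:
                smoking = "unknown"
            else:
                smoking = (
                    "yes" if rng.random() < pheno["smoking_yes"][group] else "no"
                )
            subjects.append(
                Subject(
                    subject_id=f"S{counter:04d}",
                    group=group,
                    age=age,
                    sex="F" if rng.random() < 0.5 else "M",
                    cognitive_T=float(rng.normal(mu, sd)),
                    smoking=smoking,
                    genotype=(str(h1), str(h2)),
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# read simulation


def _hap_layout(
    amplicon: AmpliconReference,
    catalog: HaplotypeCatalog,
    sites: Sequence[CytosineSite],
    truth: TruthTable,
    haplotype: str,
):
    """Per-haplotype template info: sequence plus per-strand cytosine tables."""
    hseq, ref2hap = haplotype_sequence(amplicon, catalog, haplotype)
    site_at: Dict[Tuple[int, str], CytosineSite] = {}
    for site in sites:
        hoff = ref2hap[amplicon.offset(site.coord)]
        if hoff is None:
            continue
        if site.context_by_haplotype.get(haplotype, "absent") == "absent":
            continue
        site_at[(hoff, site.strand)] = site
    plus_c = [i for i, b in enumerate(hseq) if b == "C"]
    minus_c = [i for i, b in enumerate(hseq) if b == "G"]
    tables = {}
    for strand, positions in (("+", plus_c), ("-", minus_c)):
        rows = []
        for pos in positions:
            site = site_at.get((pos, strand))
            if site is not None:
                p = truth.meth.get((haplotype, site.site_id))
                if p is None:
                    raise ValueError(
                        f"truth table misses ({haplotype}, {site.site_id})"
                    )
                rows.append((pos, site.site_id, p))
            else:
                ctx = sequence_context(hseq, pos, strand) or "CpH"
                rows.append(
                    (pos, None, DEFAULT_CPG_TRUTH if ctx == "CpG" else DEFAULT_CPH_TRUTH)
                )
        tables[strand] = rows
    return hseq, tables


def simulate_reads(
    subjects: Sequence[Subject],
    amplicon: AmpliconReference,
    sites: Sequence[CytosineSite],
    catalog: HaplotypeCatalog,
    truth: TruthTable,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[SimRead], TruthTable, pd.DataFrame]:
    """Emit barcoded bisulfite reads plus the molecule-level truth table.

    Returns (reads, truth-with-molecules, sample sheet). One FASTQ record is
    emitted per molecule record; PCR duplicates are byte-identical copies of
    an earlier molecule's read with ``duplicate_of`` set.
    """
    if len(subjects) > len(FORWARD_BARCODES) * len(REVERSE_BARCODES):
        raise ValueError(
            f"{len(subjects)} subjects exceed the "
            f"{len(FORWARD_BARCODES) * len(REVERSE_BARCODES)} barcode combinations"
        )
    rng = rng if rng is not None else np.random.default_rng(params.rng_seed)
    layouts = {
        h: _hap_layout(amplicon, catalog, sites, truth, h) for h in catalog.names
    }
    for subj in subjects:
        for h in subj.genotype:
            if h not in layouts:
                raise ValueError(f"haplotype {h!r} absent from truth/catalog")

    sheet_rows = []
    reads: List[SimRead] = []
    molecules: List[MoleculeRecord] = []
    bases = np.array(list("ACGT"))
    counter = 0
    for idx, subj in enumerate(subjects):
        fwd = FORWARD_BARCODES[idx % len(FORWARD_BARCODES)]
        rev = REVERSE_BARCODES[idx // len(FORWARD_BARCODES)]
        sheet_rows.append(
            {"sample_id": subj.subject_id, "fwd_barcode": fwd, "rev_barcode": rev}
        )
        subject_reads: List[Tuple[str, str]] = []  # (read_id, insert)
        by_id: Dict[str, MoleculeRecord] = {}
        for _ in range(params.reads_per_subject):
            counter += 1
            read_id = f"r{counter:07d}"
            if subject_reads and rng.random() < params.duplication_rate:
                src_id, insert = subject_reads[rng.integers(len(subject_reads))]
                src = by_id[src_id]
                molecules.append(
                    MoleculeRecord(
                        read_id,
                        subj.subject_id,
                        src.haplotype,
                        src.bs_strand,
                        dict(src.states),
                        src.conversion_failed,
                        duplicate_of=src_id,
                    )
                )
            else:
                hap = subj.genotype[rng.integers(2)]
                strand = "OT" if rng.random() < 0.5 else "OB"
                hseq, tables = layouts[hap]
                chars = list(hseq)
                failed = rng.random() < params.molecule_failure_rate
                states: Dict[str, bool] = {}
                rows = tables["+" if strand == "OT" else "-"]
                for pos, site_id, p in rows:
                    methylated = rng.random() < p
                    if site_id is not None:
                        states[site_id] = methylated
                    if failed or methylated:
                        continue
                    if rng.random() < params.conversion_efficiency:
                        chars[pos] = "T" if strand == "OT" else "A"
                insert = "".join(chars)
                err = rng.random(len(insert)) < params.sequencing_error_rate
                if err.any():
                    chars = list(insert)
                    for pos in np.flatnonzero(err):
                        choices = [b for b in "ACGT" if b != chars[pos]]
                        chars[pos] = choices[rng.integers(3)]
                    insert = "".join(chars)
                mol = MoleculeRecord(
                    read_id, subj.subject_id, hap, strand, states, failed
                )
                molecules.append(mol)
                by_id[read_id] = mol
                subject_reads.append((read_id, insert))
            seq = fwd + insert + revcomp(rev)
            q = (
                params.low_quality
                if rng.random() < params.low_quality_read_fraction
                else params.base_quality
            )
            reads.append(
                SimRead(read_id, seq, np.full(len(seq), q, dtype=np.int16))
            )
    out_truth = TruthTable(meth=dict(truth.meth), molecules=molecules)
    sheet = pd.DataFrame(sheet_rows)
    return reads, out_truth, sheet


# ---------------------------------------------------------------------------
# melt curves


@dataclass
class MeltParams:
    tm_unmethylated: float = 75.0
    delta_tm: float = 5.0  # Tm shift from 0% to 100% methylation retention
    slope: float = 1.5  # logistic width, degrees C
    noise_sd: float = 0.0
    t_min: float = 60.0
    t_max: float = 95.0
    t_step: float = 0.25

    def grid(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1e-9, self.t_step)


def simulate_melt(
    meth_fractions: Sequence[float],
    melt_params: MeltParams,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sample",
    genotype: str = "",
    role: str = "sample",
) -> MeltCurve:
    """Two-state melt model: a mixture of logistic components, one per allele.

    Each allele contributes F(T) = 1 / (1 + exp((T - Tm)/s)) with
    Tm = Tm0 + dTm * (fraction of methylation-retained CpGs on that allele);
    a fully methylated template therefore melts last.
    """
    p = melt_params
    grid = p.grid()
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("temperature grid must be strictly ascending")
    if grid[0] < 60.0 - 1e-9 or grid[-1] > 95.0 + 1e-9:
        raise ValueError("temperature grid must lie within [60, 95] degrees C")
    fr = np.asarray(list(meth_fractions), dtype=float)
    if fr.size == 0:
        raise ValueError("need at least one allele methylation fraction")
    tm = p.tm_unmethylated + p.delta_tm * fr
    f = np.mean(
        [1.0 / (1.0 + np.exp((grid - t) / p.slope)) for t in tm], axis=0
    )
    if p.noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested but no rng supplied")
        f = f + rng.normal(0.0, p.noise_sd, size=grid.size)
    return MeltCurve(
        sample_id=sample_id,
        genotype=genotype,
        role=role,
        temperatures=grid,
        fluorescence=f,
    )
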