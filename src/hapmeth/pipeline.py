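"""End-to-end orchestration: simulate -> readprep -> align -> haplotype ->
methylation -> statistics (-> structure, -> melt validation), with artifacts,
a manifest of input hashes, and a per-fragment report table.

All randomness flows from one root seed, split per stage with
``numpy.random.SeedSequence.spawn``, so a config + seed pair reproduces every
artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import asmstats, bsalign, haplo, io, methcall, readprep, simdata, structure
from .core import AmpliconReference, CytosineSite, HaplotypeCatalog

DEFAULT_CONFIG: Dict[str, object] = {
    "seed": 0,
    "n_cases": 48,
    "n_controls": 48,
    "haplotype_frequencies": None,  # None -> packaged defaults
    "reads_per_subject": 40,
    "conversion_efficiency": 0.995,
    "molecule_failure_rate": 0.01,
    "sequencing_error_rate": 0.002,
    "duplication_rate": 0.1,
    "low_quality_read_fraction": 0.0,
    "min_read_quality": 30.0,
    "min_identity": 0.9,
    "underconversion_threshold": 0.05,
    "min_informative_markers": 2,
    "min_depth": 5,
    "per_strand_depth": False,
    "fdr_alpha": 0.05,
    "run_structure": True,
    "stages": None,  # None -> all
}


def validate_config(config: Dict[str, object]) -> Dict[str, object]:
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(DEFAULT_CONFIG)
    merged.update(config)
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineResult:
    """In-memory handles to every stage output of one run."""

    def __init__(self):
        self.amplicon: Optional[AmpliconReference] = None
        self.sites: List[CytosineSite] = []
        self.catalog: Optional[HaplotypeCatalog] = None
        self.truth = None
        self.subjects: Optional[pd.DataFrame] = None
        self.reads = []
        self.sheet: Optional[pd.DataFrame] = None
        self.molecules = []
        self.hap_calls: Dict[str, haplo.HaplotypeCall] = {}
        self.genotype_calls: Dict[str, haplo.GenotypeCall] = {}
        self.records: Optional[pd.DataFrame] = None
        self.matrix: Optional[pd.DataFrame] = None
        self.per_hap_matrix: Optional[pd.DataFrame] = None
        self.classes: Optional[pd.DataFrame] = None
        self.site_stats: Optional[pd.DataFrame] = None
        self.pairs = []
        self.efa = None
        self.network = None
        self.qc: Dict[str, int] = {}


def run_pipeline(
    config: Dict[str, object],
    out_dir: Optional[Path] = None,
) -> PipelineResult:
    """Execute the full synthetic-study pipeline under one config + seed."""
    cfg = validate_config(config)
    res = PipelineResult()
    root = np.random.SeedSequence(int(cfg["seed"]))
    seeds = root.spawn(6)

    # --- simdata ------------------------------------------------------------
    amp, sites, catalog, truth = simdata.fr_apopt1_klc1_like()
    res.amplicon, res.sites, res.catalog = amp, sites, catalog
    freqs = cfg["haplotype_frequencies"] or simdata.DEFAULT_HAPLOTYPE_FREQS
    rng_cohort = np.random.default_rng(seeds[0])
    subjects = simdata.make_cohort(
        int(cfg["n_cases"]), int(cfg["n_controls"]), freqs, rng=rng_cohort
    )
    params = simdata.SimParams(
        conversion_efficiency=float(cfg["conversion_efficiency"]),
        molecule_failure_rate=float(cfg["molecule_failure_rate"]),
        sequencing_error_rate=float(cfg["sequencing_error_rate"]),
        duplication_rate=float(cfg["duplication_rate"]),
        reads_per_subject=int(cfg["reads_per_subject"]),
        low_quality_read_fraction=float(cfg["low_quality_read_fraction"]),
        rng_seed=int(cfg["seed"]),
    )
    rng_reads = np.random.default_rng(seeds[1])
    reads, truth, sheet = simdata.simulate_reads(
        subjects, amp, sites, catalog, truth, params, rng_reads
    )
    res.truth, res.reads, res.sheet = truth, reads, sheet
    res.subjects = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "cognitive_T": s.cognitive_T,
                "smoking": s.smoking,
                "hap1": s.genotype[0],
                "hap2": s.genotype[1],
            }
            for s in subjects
        ]
    )

    # --- readprep -----------------------------------------------------------
    sheet_map = {
        (r["fwd_barcode"], r["rev_barcode"]): r["sample_id"]
        for _, r in sheet.iterrows()
    }
    demux = readprep.demultiplex(
        [readprep.BarcodedRead(r.read_id, r.sequence, r.qualities) for r in reads],
        simdata.FORWARD_BARCODES,
        simdata.REVERSE_BARCODES,
        sheet_map,
    )
    res.qc["input_reads"] = demux.total
    res.qc["unassigned"] = len(demux.unassigned)
    kept_reads: List[Tuple[str, str, str]] = []  # (subject, read_id, insert)
    for sid, bin_ in demux.bins.items():
        readprep.trim_bin(bin_, float(cfg["min_read_quality"]))
        readprep.deduplicate(bin_)
        for t in bin_.reads:
            kept_reads.append((sid, t.read_id, t.sequence))
    res.qc["after_readprep"] = len(kept_reads)

    # --- bsalign ------------------------------------------------------------
    molecules = []
    n_rejected = n_underconverted = 0
    for sid, read_id, insert in kept_reads:
        mol = bsalign.align_read(read_id, insert, amp, float(cfg["min_identity"]))
        if mol.rejected:
            n_rejected += 1
            continue
        mol.subject_id = sid
        bsalign.extract_states(mol, amp, sites, catalog.markers)
        if not bsalign.underconversion_filter(
            mol, float(cfg["underconversion_threshold"])
        ):
            n_underconverted += 1
            continue
        molecules.append(mol)
    res.molecules = molecules
    res.qc["alignment_rejected"] = n_rejected
    res.qc["underconversion_discarded"] = n_underconverted
    res.qc["qc_passed_reads"] = len(molecules)

    # --- haplo --------------------------------------------------------------
    for mol in molecules:
        res.hap_calls[mol.read_id] = haplo.assign_haplotype(
            mol.read_id,
            mol.marker_obs,
            catalog,
            int(cfg["min_informative_markers"]),
            bs_strand=mol.bs_strand,
        )
    by_subject: Dict[str, List[haplo.HaplotypeCall]] = {}
    for mol in molecules:
        by_subject.setdefault(mol.subject_id, []).append(res.hap_calls[mol.read_id])
    for sid, calls in by_subject.items():
        res.genotype_calls[sid] = haplo.call_genotype(
            sid, calls, int(cfg["min_depth"]), bool(cfg["per_strand_depth"])
        )

    # --- methcall -----------------------------------------------------------
    analysable = {
        sid: gc for sid, gc in res.genotype_calls.items() if gc.analysable
    }
    states = methcall.state_table(
        [m for m in molecules if m.subject_id in analysable], res.hap_calls
    )
    records = methcall.aggregate_methylation(states, sites, int(cfg["min_depth"]))
    res.records = records
    genotypes = {sid: gc.genotype for sid, gc in analysable.items()}
    if len(records):
        res.per_hap_matrix = methcall.subject_site_matrix(
            records, genotypes, "per_haplotype"
        )
        res.matrix = methcall.subject_site_matrix(records, genotypes, "allele_averaged")
        res.classes = methcall.classify_sites(res.matrix)

    # --- asmstats -----------------------------------------------------------
    if len(records):
        subjects_df = res.subjects[res.subjects["subject_id"].isin(analysable)]
        stats_df = asmstats.rank_tests(records, catalog.risk_haplotype)
        alpha = float(cfg["fdr_alpha"])
        stats_df["kw_q"], stats_df["kw_significant"] = asmstats.bh_fdr(
            stats_df["kw_p"].to_numpy(), alpha
        )
        analysis_set = res.classes.loc[
            res.classes["in_analysis_set"], "site_id"
        ].tolist()
        logit = asmstats.logistic_per_site(
            res.matrix, subjects_df, analysis_set, catalog.names
        )
        if len(logit):
            logit["logistic_q"], _ = asmstats.bh_fdr(
                logit["logistic_p"].to_numpy(), alpha
            )
        coverage = {
            sid: sum(gc.support.values()) for sid, gc in analysable.items()
        }
        rng_pairs = np.random.default_rng(seeds[2])
        pairs, wil = asmstats.matched_pair_analysis(
            subjects_df, coverage, res.matrix, rng_pairs
        )
        res.pairs = pairs
        screen = asmstats.covariate_screen(res.matrix, subjects_df)
        stats_df = (
            stats_df.merge(screen, on="site_id", how="left", suffixes=("", "_scr"))
            .merge(logit, on="site_id", how="left")
            .merge(wil, on="site_id", how="left")
            .merge(res.classes, on="site_id", how="left")
        )
        res.site_stats = stats_df

        # --- structure on the ASM site set ---------------------------------
        if cfg["run_structure"]:
            asm_sites = stats_df.loc[
                stats_df["kw_significant"].fillna(False), "site_id"
            ].tolist()
            asm_sites = [s for s in asm_sites if s in res.matrix.columns]
            if len(asm_sites) >= 3:
                sub = structure.nonparanormal_transform(res.matrix[asm_sites])
                complete = sub.dropna(axis=0)
                if complete.shape[0] > sub.shape[1] + 2:
                    nf = structure.parallel_analysis(
                        sub, n_sims=500, seed=int(seeds[3].generate_state(1)[0] % 2**31)
                    )
                    if 1 <= nf < sub.shape[1]:
                        try:
                            res.efa = structure.efa_promax(sub, nf)
                        except RuntimeError:
                            res.efa = None
                try:
                    res.network = structure.ebicglasso(sub)
                except (ValueError, RuntimeError):
                    res.network = None

    if out_dir is not None:
        write_artifacts(res, cfg, Path(out_dir))
    return res


def write_artifacts(res: PipelineResult, cfg: Dict[str, object], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_fasta(res.amplicon, out / "amplicon.fasta")
    io.write_sites(res.sites, res.catalog.names, out / "sites.tsv")
    io.write_catalog(res.catalog, out / "catalog.tsv")
    res.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    io.write_fastq(res.reads, out / "reads.fastq")
    res.sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    if res.records is not None:
        res.records.to_csv(out / "methylation_records.tsv", sep="\t", index=False)
    if res.matrix is not None:
        res.matrix.to_csv(out / "matrix_allele_averaged.tsv", sep="\t")
    if res.site_stats is not None:
        res.site_stats.to_csv(out / "site_stats.tsv", sep="\t", index=False)
        write_report(res, out)
    if res.network is not None:
        res.network.edges().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    if res.efa is not None:
        res.efa.loadings.to_csv(out / "factor_loadings.tsv", sep="\t")
    manifest = {
        "seed": cfg["seed"],
        "config": {k: v for k, v in cfg.items()},
        "qc": res.qc,
        "files": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    io.write_json(manifest, out / "manifest.json")


def write_report(res: PipelineResult, out: Path) -> None:
    """Human-readable per-site report: per-haplotype mean +/- sd, tests, classes."""
    df = res.site_stats
    haps = res.catalog.names
    lines = [
        f"Haplotype-specific methylation report - {res.amplicon.amplicon_id}",
        f"analysable subjects: {res.matrix.shape[0]}; sites reported: {len(df)}",
        "",
    ]
    if len(df) == 0:
        lines.append("(empty analysis set: no site met the depth and masking rules)")
    else:
        header = ["site_id"] + [f"{h} mean+/-sd (n)" for h in haps] + [
            "KW p", "KW q", "posthoc p", "class",
        ]
        lines.append("\t".join(header))
        for _, r in df.iterrows():
            cells = [str(r["site_id"])]
            for h in haps:
                m, s, n = r.get(f"mean_{h}"), r.get(f"sd_{h}"), r.get(f"n_{h}")
                cells.append(
                    f"{m:.3f}+/-{s:.3f} ({int(n)})"
                    if pd.notna(m) and pd.notna(s)
                    else "-"
                )
            for c in ("kw_p", "kw_q", "posthoc_p"):
                v = r.get(c)
                cells.append(f"{v:.2e}" if pd.notna(v) else "-")
            cells.append(str(r.get("site_class", "-")))
            lines.append("\t".join(cells))
    (out / "report.txt").write_text("\n".join(lines) + "\n")
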