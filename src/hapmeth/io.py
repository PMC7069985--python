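"""Readers/writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; tabular artifacts are TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AmpliconReference, CytosineSite, HaplotypeCatalog, Marker, Subject
from .readprep import BarcodedRead
from .simdata import SimRead


def write_fasta(amplicon: AmpliconReference, path: Path) -> None:
    rec = SeqRecord(
        Seq(amplicon.sequence),
        id=amplicon.amplicon_id,
        description=f"{amplicon.chrom}:{amplicon.start_coord}-{amplicon.end_coord}",
    )
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: Path) -> AmpliconReference:
    rec = next(SeqIO.parse(str(path), "fasta"))
    chrom, span = rec.description.split()[-1].split(":")
    start = int(span.split("-")[0].replace(",", ""))
    return AmpliconReference(rec.id, chrom, start, str(rec.seq).upper())


def write_fastq(reads: Sequence[SimRead], path: Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: Path) -> List[BarcodedRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            BarcodedRead(
                rec.id,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return out


def write_sites(sites: Sequence[CytosineSite], haplotypes: Sequence[str], path: Path) -> None:
    rows = []
    for s in sites:
        row = {
            "site_id": s.site_id,
            "coord": s.coord,
            "strand": s.strand,
            "context": s.context,
        }
        for h in haplotypes:
            row[f"context_{h}"] = s.context_by_haplotype.get(h, "absent")
            row[f"maskable_{h}"] = s.maskable_by_haplotype.get(h, False)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path: Path) -> List[CytosineSite]:
    df = pd.read_csv(path, sep="\t")
    haps = [c[len("context_") :] for c in df.columns if c.startswith("context_")]
    out = []
    for _, r in df.iterrows():
        out.append(
            CytosineSite(
                site_id=r["site_id"],
                coord=int(r["coord"]),
                strand=r["strand"],
                context=r["context"],
                context_by_haplotype={h: r[f"context_{h}"] for h in haps},
                maskable_by_haplotype={h: bool(r[f"maskable_{h}"]) for h in haps},
            )
        )
    return out


def write_catalog(catalog: HaplotypeCatalog, path: Path) -> None:
    rows = []
    for m in catalog.markers:
        row = {
            "marker_id": m.marker_id,
            "coord": m.coord,
            "ref_allele": m.ref_allele,
            "alt_allele": m.alt_allele,
            "creates_cpg": m.creates_cpg,
        }
        for name, vec in catalog.haplotypes.items():
            idx = catalog.markers.index(m)
            row[f"hap_{name}"] = vec[idx]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["risk"] = catalog.risk_haplotype
    with open(path, "w") as fh:
        fh.write(f"#risk_haplotype={catalog.risk_haplotype}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_catalog(path: Path) -> HaplotypeCatalog:
    with open(path) as fh:
        first = fh.readline().strip()
        risk = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t")
    markers = [
        Marker(r["marker_id"], int(r["coord"]), r["ref_allele"], r["alt_allele"], bool(r["creates_cpg"]))
        for _, r in df.iterrows()
    ]
    hap_cols = [c for c in df.columns if c.startswith("hap_")]
    haplotypes = {
        c[len("hap_") :]: tuple(df[c].tolist()) for c in hap_cols
    }
    return HaplotypeCatalog(markers, haplotypes, risk)


def write_subjects(subjects: Sequence[Subject], path: Path) -> None:
    pd.DataFrame(
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
    ).to_csv(path, sep="\t", index=False)


def read_subjects(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
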