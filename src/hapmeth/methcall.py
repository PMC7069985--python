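"""Aggregation of per-read conversion states into methylation levels.

The methylation level M of a cytosine is the ratio of reads with an
unconverted cytosine to all reads informative for it, per subject and
haplotype. Records below the minimum depth, and (haplotype, site) pairs
where the cytosine is absent or conversion-confounded with the genotype,
are *absent* rather than zero so downstream tests cannot silently use them.

Site classes follow the study's conventions: unmethylated (mean M <= 1%),
intermediate (20% < mean M < 80%), hypermethylated (mean M > 80%), low
otherwise; association testing is restricted to 1% < mean M < 99%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bsalign import CONVERTED, UNCONVERTED, AlignedMolecule
from .core import CytosineSite
from .haplo import HaplotypeCall

UNMETHYLATED = "unmethylated"
LOW = "low"
INTERMEDIATE = "intermediate"
HYPERMETHYLATED = "hypermethylated"

RECORD_COLUMNS = ["subject_id", "haplotype", "site_id", "n_unconverted", "n_total", "M"]


def state_table(
    molecules: Sequence[AlignedMolecule],
    calls: Dict[str, HaplotypeCall],
) -> pd.DataFrame:
    """Long table of per-read per-site states for haplotype-assigned reads."""
    rows = []
    for mol in molecules:
        call = calls.get(mol.read_id)
        if call is None or call.assigned is None:
            continue
        for site_id, state in mol.site_states.items():
            if state in (CONVERTED, UNCONVERTED):
                rows.append(
                    (mol.subject_id, call.assigned, site_id, state)
                )
    return pd.DataFrame(rows, columns=["subject_id", "haplotype", "site_id", "state"])


def aggregate_methylation(
    states: pd.DataFrame,
    sites: Sequence[CytosineSite],
    min_depth: int = 5,
) -> pd.DataFrame:
    """Pool counts per (subject, haplotype, site) into methylation records.

    Records are emitted only at depth >= min_depth; masked (haplotype, site)
    pairs — cytosine absent on that haplotype, or genotype-confounded on the
    only informative strand — yield no record at all.
    """
    if states.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    site_info = {s.site_id: s for s in sites}
    g = (
        states.assign(unconv=(states["state"] == UNCONVERTED).astype(int))
        .groupby(["subject_id", "haplotype", "site_id"], sort=True)
        .agg(n_unconverted=("unconv", "sum"), n_total=("state", "size"))
        .reset_index()
    )
    keep = []
    for _, row in g.iterrows():
        site = site_info.get(row["site_id"])
        if site is None:
            raise KeyError(f"state table references unknown site {row['site_id']!r}")
        hap = row["haplotype"]
        if site.context_by_haplotype.get(hap, "absent") == "absent":
            continue
        if site.maskable_by_haplotype.get(hap, False):
            continue
        if row["n_total"] < min_depth:
            continue
        keep.append(row)
    if not keep:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    out = pd.DataFrame(keep)
    out["M"] = out["n_unconverted"] / out["n_total"]
    return out.reset_index(drop=True)[RECORD_COLUMNS]


def subject_site_matrix(
    records: pd.DataFrame,
    genotypes: Dict[str, Tuple[str, str]],
    mode: str = "allele_averaged",
) -> pd.DataFrame:
    """Wide matrix of M values.

    ``per_haplotype``: one row per (subject, haplotype). ``allele_averaged``:
    one row per subject, heterozygote values averaged over the two haplotype
    records (missing if either allele is masked or under-covered);
    homozygotes carry their single haplotype's value.
    """
    if mode == "per_haplotype":
        return records.pivot_table(
            index=["subject_id", "haplotype"], columns="site_id", values="M",
            aggfunc="first",
        )
    if mode != "allele_averaged":
        raise ValueError(f"unknown mode {mode!r}")
    per_hap = records.pivot_table(
        index=["subject_id", "haplotype"], columns="site_id", values="M",
        aggfunc="first",
    )
    rows = {}
    for subject_id, (h1, h2) in genotypes.items():
        try:
            a = per_hap.loc[(subject_id, h1)]
        except KeyError:
            a = None
        if h1 == h2:
            rows[subject_id] = a
            continue
        try:
            b = per_hap.loc[(subject_id, h2)]
        except KeyError:
            b = None
        if a is None or b is None:
            rows[subject_id] = None
        else:
            rows[subject_id] = (a + b) / 2.0  # NaN where either allele missing
    index = list(rows)
    data = [
        rows[s] if rows[s] is not None else pd.Series(np.nan, index=per_hap.columns)
        for s in index
    ]
    out = pd.DataFrame(data, index=pd.Index(index, name="subject_id"))
    out.columns.name = "site_id"
    return out


def classify_sites(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classify sites by their mean M across analysable subjects.

    Boundaries are strict per the class definitions: mean M = 0.01 is
    unmethylated, 0.20 and 0.80 fall in the 'low' band. The analysis set for
    association testing is 0.01 < mean M < 0.99.
    """
    mean_m = matrix.mean(axis=0, skipna=True)
    rows = []
    for site_id, m in mean_m.items():
        if np.isnan(m):
            continue
        if m <= 0.01:
            cls = UNMETHYLATED
        elif m > 0.80:
            cls = HYPERMETHYLATED
        elif 0.20 < m < 0.80:
            cls = INTERMEDIATE
        else:
            cls = LOW
        rows.append(
            {
                "site_id": site_id,
                "mean_M": float(m),
                "site_class": cls,
                "in_analysis_set": bool(0.01 < m < 0.99),
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "mean_M", "site_class", "in_analysis_set"])
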